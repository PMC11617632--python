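"""Peak lists, titration series and their I/O.

The observational unit is a *probe*: an Ile/Leu/Val methyl group (or a backbone
amide) followed through a titration in a 2D heteronuclear correlation spectrum.
A titration series is an ordered set of points, each at a ligand:protein molar
ratio ``x``, carrying one peak list.  Two interchange formats are supported:

* the *tabular* dialect (TSV/CSV with explicit volume and error columns) —
  the normative format, written and read losslessly;
* Sparky ``.list`` peak lists — import only (no volume errors guaranteed).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

from .exceptions import (
    DuplicatePeakError,
    ManifestError,
    PeakListFormatError,
)

__all__ = [
    "Probe",
    "Peak",
    "TitrationPoint",
    "TitrationSeries",
    "Finding",
    "parse_probe_id",
    "read_peak_list",
    "read_titration_manifest",
    "validate_series",
    "write_report",
    "write_peak_list",
]

Nucleus = Literal["C13", "N15"]
Form = Literal["free", "bound", "merged"]

#: Columns of the tabular peak-list dialect, in canonical order.
TABULAR_COLUMNS = [
    "probe_id",
    "residue_number",
    "residue_type",
    "site_label",
    "nucleus",
    "shift_h",
    "shift_x",
    "volume",
    "volume_rel_err",
    "form",
]

_PROBE_RE = re.compile(r"^([A-Z])(\d+)([ab]?)$")


@dataclass(frozen=True, order=True)
class Probe:
    """One resonance probe, canonically identified e.g. ``V195`` or ``L220a``.

    ``site_label`` distinguishes the two non-stereospecifically assigned
    methyls of a Leu/Val diastereotopic pair: ``a`` is the methyl with the
    lower 1H shift, ``b`` the other; Ile methyls and amides carry ``""``.
    """

    residue_number: int
    residue_type: str
    site_label: str = ""
    nucleus: Nucleus = "C13"

    def __post_init__(self) -> None:
        if self.residue_number < 1:
            raise ValueError(f"residue_number must be >= 1, got {self.residue_number}")
        if self.site_label not in ("", "a", "b"):
            raise ValueError(f"site_label must be '', 'a' or 'b', got {self.site_label!r}")
        if self.site_label and self.residue_type not in ("L", "V"):
            raise ValueError(
                "site_label is only meaningful for Leu/Val diastereotopic pairs, "
                f"got {self.residue_type}{self.residue_number}{self.site_label}"
            )
        if self.nucleus not in ("C13", "N15"):
            raise ValueError(f"nucleus must be 'C13' or 'N15', got {self.nucleus!r}")

    @property
    def probe_id(self) -> str:
        return f"{self.residue_type}{self.residue_number}{self.site_label}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.probe_id


def parse_probe_id(probe_id: str, nucleus: Nucleus = "C13") -> Probe:
    """Parse a canonical probe identifier like ``L220a`` into a :class:`Probe`."""
    m = _PROBE_RE.match(probe_id.strip())
    if not m:
        raise PeakListFormatError(f"cannot parse probe identifier {probe_id!r}")
    rtype, num, site = m.groups()
    return Probe(int(num), rtype, site, nucleus)


@dataclass(frozen=True)
class Peak:
    """A single resonance observation: position, volume and form label."""

    probe: Probe
    shift_h: float
    shift_x: float
    volume: float = 1.0
    volume_rel_err: float = 0.0
    form: Form = "free"

    def __post_init__(self) -> None:
        if self.volume < 0:
            raise ValueError(f"volume must be >= 0, got {self.volume}")
        if not (self.volume_rel_err >= 0):
            raise ValueError(f"volume_rel_err must be finite and >= 0, got {self.volume_rel_err}")
        if self.form not in ("free", "bound", "merged"):
            raise ValueError(f"form must be free/bound/merged, got {self.form!r}")


@dataclass
class TitrationPoint:
    """One titration point: molar ratio, protein concentration, peak list."""

    ratio_x: float
    protein_conc: float  # µM
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ratio_x < 0:
            raise ValueError(f"ratio_x must be >= 0, got {self.ratio_x}")
        if self.protein_conc <= 0:
            raise ValueError(f"protein_conc must be > 0 µM, got {self.protein_conc}")
        seen: set[tuple[Probe, str]] = set()
        for p in self.peaks:
            key = (p.probe, p.form)
            if key in seen:
                raise DuplicatePeakError(
                    f"duplicate peak for probe {p.probe} form {p.form!r} at x={self.ratio_x}"
                )
            seen.add(key)

    def peak(self, probe: Probe, form: Form) -> Peak | None:
        for p in self.peaks:
            if p.probe == probe and p.form == form:
                return p
        return None

    @property
    def probes(self) -> set[Probe]:
        return {p.probe for p in self.peaks}


@dataclass
class TitrationSeries:
    """An ordered titration (first point apo, ratios strictly increasing)."""

    ligand_name: str
    points: list[TitrationPoint]
    regime_hint: Literal["fast", "slow", "unknown"] = "unknown"
    #: free-form metadata (e.g. ground truth from the synthetic generators)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.points:
            raise ManifestError("a titration series needs at least one point")
        ratios = [p.ratio_x for p in self.points]
        if ratios[0] != 0:
            raise ManifestError(f"first titration point must be apo (x=0), got x={ratios[0]}")
        for a, b in zip(ratios, ratios[1:]):
            if b <= a:
                raise ManifestError(f"ratio_x must be strictly increasing, got {a} then {b}")

    @property
    def apo(self) -> TitrationPoint:
        return self.points[0]

    @property
    def ratios(self) -> list[float]:
        return [p.ratio_x for p in self.points]

    def point_at(self, ratio_x: float) -> TitrationPoint:
        for p in self.points:
            if p.ratio_x == ratio_x:
                return p
        raise KeyError(f"no titration point at x={ratio_x}")


@dataclass(frozen=True)
class Finding:
    """Machine-readable validation finding (non-fatal)."""

    code: str
    message: str
    probe: Probe | None = None
    ratio_x: float | None = None


# ---------------------------------------------------------------------------
# reading


def _parse_tabular(path: Path, sep: str) -> list[Peak]:
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in TABULAR_COLUMNS if c not in df.columns]
    if missing:
        raise PeakListFormatError(f"{path}: missing column(s) {', '.join(missing)}")
    peaks: list[Peak] = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            probe = Probe(
                residue_number=int(row["residue_number"]),
                residue_type=row["residue_type"].strip(),
                site_label=row["site_label"].strip(),
                nucleus=row["nucleus"].strip(),
            )
            peak = Peak(
                probe=probe,
                shift_h=float(row["shift_h"]),
                shift_x=float(row["shift_x"]),
                volume=float(row["volume"]),
                volume_rel_err=float(row["volume_rel_err"]),
                form=row["form"].strip(),
            )
        except (ValueError, KeyError) as exc:
            raise PeakListFormatError(f"{path}:{line}: {exc}") from exc
        declared = row["probe_id"].strip()
        if declared and declared != probe.probe_id:
            raise PeakListFormatError(
                f"{path}:{line}: probe_id {declared!r} does not match fields "
                f"({probe.probe_id})"
            )
        peaks.append(peak)
    _check_duplicates(peaks, path)
    return peaks


_SPARKY_ASSIGN_RE = re.compile(r"^([A-Z])(\d+)([ab]?)(?:C[DG]\d?[ab]?)?-?(?:Q[DG]\d?|H[DGN]?\d*)?$")


def _parse_sparky(path: Path, default_rel_err: float, nucleus: Nucleus) -> list[Peak]:
    """Parse a Sparky .list export: Assignment  w1  w2  [Data Height].

    w1 is the heteronuclear dimension, w2 the 1H dimension (Sparky convention
    for 2D correlation lists).  Heights, when present, are taken as volumes
    with the configured default relative error.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            tokens = raw.split()
            if not tokens:
                continue
            if tokens[0].lower() == "assignment":
                continue
            if len(tokens) < 3:
                raise PeakListFormatError(f"{path}:{lineno}: expected at least 3 columns")
            assignment = tokens[0]
            # strip atom names: "L220a-QD1" / "V195CG1a-HG1" -> residue + site
            res_part = assignment.split("-")[0]
            m = re.match(r"^([A-Z])(\d+)([ab]?)", res_part)
            if not m:
                raise PeakListFormatError(
                    f"{path}:{lineno}: cannot parse assignment {assignment!r}"
                )
            rtype, num, site = m.groups()
            try:
                w1, w2 = float(tokens[1]), float(tokens[2])
                height = float(tokens[3]) if len(tokens) > 3 else 1.0
            except ValueError as exc:
                raise PeakListFormatError(f"{path}:{lineno}: {exc}") from exc
            probe = Probe(int(num), rtype, site, nucleus)
            peaks.append(
                Peak(
                    probe=probe,
                    shift_h=w2,
                    shift_x=w1,
                    volume=abs(height),
                    volume_rel_err=default_rel_err,
                    form="free",
                )
            )
    _check_duplicates(peaks, path)
    return peaks


def _check_duplicates(peaks: Sequence[Peak], path: Path) -> None:
    seen: set[tuple[Probe, str]] = set()
    for p in peaks:
        key = (p.probe, p.form)
        if key in seen:
            raise DuplicatePeakError(
                f"{path}: duplicate peak for probe {p.probe} form {p.form!r}"
            )
        seen.add(key)


def read_peak_list(
    path: str | Path,
    dialect: Literal["tabular", "sparky"] = "tabular",
    *,
    default_rel_err: float = 0.10,
    nucleus: Nucleus = "C13",
) -> list[Peak]:
    """Read a peak list, preserving row order.

    Parameters
    ----------
    path
        Peak-list file.  Tabular files may be TSV or CSV (sniffed from the
        header line); Sparky lists are whitespace-delimited.
    dialect
        ``"tabular"`` (normative dialect, all columns) or ``"sparky"``
        (import-only; volumes default to Data Height with ``default_rel_err``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"peak list not found: {path}")
    if dialect == "tabular":
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
        return _parse_tabular(path, sep)
    if dialect == "sparky":
        return _parse_sparky(path, default_rel_err, nucleus)
    raise PeakListFormatError(f"unknown dialect {dialect!r}")


def read_titration_manifest(path: str | Path) -> TitrationSeries:
    """Load a YAML titration manifest and all referenced peak lists.

    Expected layout::

        ligand: ADP
        regime_hint: slow        # optional
        points:
          - {ratio_x: 0, protein_conc_uM: 160, peaks: apo.tsv}
          - {ratio_x: 1, protein_conc_uM: 160, peaks: x1.tsv}

    Peak-list paths are resolved relative to the manifest's directory.
    """
    import yaml

    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "points" not in doc:
        raise ManifestError(f"{path}: manifest must be a mapping with a 'points' array")
    points: list[TitrationPoint] = []
    for entry in doc["points"]:
        try:
            ratio_x = float(entry["ratio_x"])
            conc = float(entry["protein_conc_uM"])
            peaks_path = path.parent / entry["peaks"]
        except (KeyError, TypeError, ValueError) as exc:
            raise ManifestError(f"{path}: bad point entry {entry!r}: {exc}") from exc
        if not peaks_path.exists():
            raise FileNotFoundError(f"{path}: referenced peak list not found: {peaks_path}")
        dialect = entry.get("dialect", "tabular")
        peaks = read_peak_list(peaks_path, dialect)
        points.append(TitrationPoint(ratio_x=ratio_x, protein_conc=conc, peaks=peaks))
    points.sort(key=lambda p: p.ratio_x)
    if not points or points[0].ratio_x != 0:
        raise ManifestError(f"{path}: manifest must include an apo (ratio_x=0) point")
    ratios = [p.ratio_x for p in points]
    if len(set(ratios)) != len(ratios):
        raise ManifestError(f"{path}: duplicate ratio_x values {ratios}")
    return TitrationSeries(
        ligand_name=str(doc.get("ligand", "ligand")),
        points=points,
        regime_hint=doc.get("regime_hint", "unknown"),
    )


# ---------------------------------------------------------------------------
# validation


def validate_series(series: TitrationSeries) -> list[Finding]:
    """Check series-level invariants; returns findings instead of raising.

    An empty list means the series is internally consistent: apo point holds
    only free-form peaks, later probe sets are subsets of the apo probe set,
    volumes are nonnegative and forms are coherent with the exchange regime.
    """
    findings: list[Finding] = []
    apo = series.apo
    for peak in apo.peaks:
        if peak.form != "free":
            findings.append(
                Finding("bound_at_apo", f"{peak.form} form at apo for {peak.probe}", peak.probe, 0.0)
            )
    apo_probes = apo.probes
    for point in series.points[1:]:
        extra = point.probes - apo_probes
        for probe in sorted(extra):
            findings.append(
                Finding(
                    "probe_not_in_apo",
                    f"probe {probe} at x={point.ratio_x} missing from apo point",
                    probe,
                    point.ratio_x,
                )
            )
        forms = {p.form for p in point.peaks}
        if "merged" in forms and ("free" in forms or "bound" in forms):
            findings.append(
                Finding(
                    "mixed_forms",
                    f"x={point.ratio_x} mixes merged with free/bound forms",
                    None,
                    point.ratio_x,
                )
            )
    if len(series.points) > 1:
        later = set().union(*(p.probes for p in series.points[1:]))
        for probe in sorted(apo_probes - later):
            findings.append(
                Finding("probe_dropout", f"probe {probe} absent from all post-apo points", probe)
            )
    return findings


# ---------------------------------------------------------------------------
# writing


def _fmt(value) -> str:
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def write_report(records, path: str | Path) -> Path:
    """Write a result table as deterministic TSV.

    Accepts a DataFrame or any iterable of dataclasses/dicts.  Rows are sorted
    by ``residue_number`` then ``site_label`` when those columns exist; floats
    are rendered with 6 significant digits, so identical records always give a
    byte-identical file.
    """
    import dataclasses

    path = Path(path)
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        rows = []
        for rec in records:
            if dataclasses.is_dataclass(rec):
                rows.append(dataclasses.asdict(rec))
            elif isinstance(rec, dict):
                rows.append(dict(rec))
            else:
                raise TypeError(f"cannot serialise record of type {type(rec).__name__}")
        df = pd.DataFrame(rows)
    sort_cols = [c for c in ("residue_number", "site_label", "probe") if c in df.columns]
    if sort_cols:
        df = df.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("\t".join(map(str, df.columns)) + "\n")
        for _, row in df.iterrows():
            fh.write("\t".join(_fmt(v) for v in row) + "\n")
    return path


def peaks_to_frame(peaks: Iterable[Peak]) -> pd.DataFrame:
    """Flatten peaks to the tabular dialect (canonical column order)."""
    rows = []
    for p in peaks:
        rows.append(
            {
                "probe_id": p.probe.probe_id,
                "residue_number": p.probe.residue_number,
                "residue_type": p.probe.residue_type,
                "site_label": p.probe.site_label,
                "nucleus": p.probe.nucleus,
                "shift_h": p.shift_h,
                "shift_x": p.shift_x,
                "volume": p.volume,
                "volume_rel_err": p.volume_rel_err,
                "form": p.form,
            }
        )
    return pd.DataFrame(rows, columns=TABULAR_COLUMNS)


def write_peak_list(peaks: Iterable[Peak], path: str | Path) -> Path:
    """Write peaks in the tabular dialect (TSV), preserving input order."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = peaks_to_frame(peaks)
    with open(path, "w") as fh:
        fh.write("\t".join(TABULAR_COLUMNS) + "\n")
        for _, row in df.iterrows():
            fh.write("\t".join(_fmt(v) for v in row) + "\n")
    return path
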