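"""Chemical-shift-perturbation (CSP) computation and classification.

The composite CSP combines the 1H and heteronuclear shift changes into a
single scaled quadrature norm,

    composite = sqrt(d_h^2 + (s_X * d_x)^2),

with s_X = 0.18 for 13C and 0.15 for 15N, so that a given composite value
represents comparable perturbations in either dimension.  Perturbed residues
are classified against thresholds derived from the 10%-trimmed mean of all
composite CSPs (trimmed mean, and trimmed mean + 1 SD), a residue counting as
perturbed if *at least one* of its methyl groups crosses the threshold.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .exceptions import ConfigError, DataError
from .peaks import Finding, Peak, Probe, TitrationPoint, TitrationSeries

__all__ = [
    "SCALE_X",
    "CSPRecord",
    "CSPProfile",
    "ClassificationResult",
    "compute_csp",
    "csp_profile",
    "trimmed_stats",
    "classify_probes",
    "intensity_ratio_screen",
]

#: Heteronuclear scaling factors of the composite CSP.
SCALE_X: dict[str, float] = {"C13": 0.18, "N15": 0.15}

Category = Literal["baseline", "above_mean", "above_mean_plus_sd"]


def compute_csp(
    d_h: float,
    d_x: float,
    nucleus: str,
    scale_x: dict[str, float] | None = None,
) -> float:
    """Composite CSP: ``sqrt(d_h**2 + (s_X*d_x)**2)`` in ppm.

    Symmetric under sign flips of either component and homogeneous of degree
    one under joint scaling — it is a weighted Euclidean norm on the
    (1H, heteronucleus) shift-change plane.
    """
    scales = SCALE_X if scale_x is None else scale_x
    try:
        s = scales[nucleus]
    except KeyError:
        raise ConfigError(f"unknown nucleus {nucleus!r}; expected one of {sorted(scales)}")
    return float(np.hypot(d_h, s * d_x))


@dataclass(frozen=True)
class CSPRecord:
    """Per-probe shift-change vector and its composite magnitude."""

    probe: Probe
    d_h: float
    d_x: float
    scale_x: float
    composite: float

    @classmethod
    def from_shifts(
        cls,
        probe: Probe,
        d_h: float,
        d_x: float,
        scale_x: dict[str, float] | None = None,
    ) -> "CSPRecord":
        scales = SCALE_X if scale_x is None else scale_x
        s = scales[probe.nucleus]
        return cls(probe, d_h, d_x, s, compute_csp(d_h, d_x, probe.nucleus, scales))

    @property
    def vector(self) -> tuple[float, float]:
        """The (d_h, s_X*d_x) vector in the scaled-shift plane."""
        return (self.d_h, self.scale_x * self.d_x)


@dataclass
class CSPProfile:
    """CSP records per titration point, relative to a reference point."""

    reference_x: float
    records: dict[float, list[CSPRecord]]
    gaps: list[Finding] = field(default_factory=list)

    def at(self, ratio_x: float) -> list[CSPRecord]:
        return self.records[ratio_x]

    def endpoint(self) -> list[CSPRecord]:
        """Records at the largest titration ratio."""
        return self.records[max(self.records)]

    def per_probe(self) -> dict[Probe, list[tuple[float, float]]]:
        """(x, composite) trajectories keyed by probe, including (x_ref, 0)."""
        out: dict[Probe, list[tuple[float, float]]] = {}
        for x in sorted(self.records):
            for rec in self.records[x]:
                out.setdefault(rec.probe, []).append((x, rec.composite))
        return out


def _tracking_peak(point: TitrationPoint, probe: Probe) -> Peak | None:
    """The peak whose position tracks the bound state at this point.

    Fast exchange: the single merged (population-averaged) peak.  Slow
    exchange: the bound-form peak.  The apo reference uses the free peak.
    """
    for form in ("merged", "bound", "free"):
        peak = point.peak(probe, form)
        if peak is not None:
            return peak
    return None


def csp_profile(
    series: TitrationSeries,
    reference_x: float = 0.0,
    scale_x: dict[str, float] | None = None,
) -> CSPProfile:
    """Per-probe CSPs of every non-reference point against the reference.

    For each probe present at both the reference and a given point, the CSP
    is the displacement of the tracking peak (merged peak in fast exchange,
    bound-form peak in slow exchange) from the probe's reference position.
    Probes missing at a point are recorded as gaps, not errors — weak peaks
    routinely disappear near the ends of a slow-exchange titration.
    """
    try:
        ref_point = series.point_at(reference_x)
    except KeyError:
        raise DataError(f"reference point x={reference_x} not present in series")
    ref_pos: dict[Probe, tuple[float, float]] = {}
    for probe in ref_point.probes:
        peak = ref_point.peak(probe, "free") or _tracking_peak(ref_point, probe)
        ref_pos[probe] = (peak.shift_h, peak.shift_x)

    records: dict[float, list[CSPRecord]] = {}
    gaps: list[Finding] = []
    for point in series.points:
        if point.ratio_x == reference_x:
            continue
        recs: list[CSPRecord] = []
        for probe in sorted(ref_pos):
            peak = _tracking_peak(point, probe)
            if peak is None:
                gaps.append(
                    Finding(
                        "probe_gap",
                        f"probe {probe} absent at x={point.ratio_x}",
                        probe,
                        point.ratio_x,
                    )
                )
                continue
            h0, x0 = ref_pos[probe]
            recs.append(
                CSPRecord.from_shifts(probe, peak.shift_h - h0, peak.shift_x - x0, scale_x)
            )
        records[point.ratio_x] = recs
    return CSPProfile(reference_x=reference_x, records=records, gaps=gaps)


def trimmed_stats(
    csps: Sequence[float],
    trim_fraction: float = 0.10,
) -> tuple[float, float]:
    """Trimmed mean and SD of composite CSPs.

    ``trim_fraction`` of the values (count rounded down) is removed from each
    tail before computing the mean and the *sample* standard deviation of the
    surviving values.  ``trim_fraction=0`` reduces to the ordinary mean/SD.
    """
    if len(csps) == 0:
        raise DataError("cannot compute trimmed statistics of an empty list")
    if not 0 <= trim_fraction < 0.5:
        raise ConfigError(f"trim_fraction must be in [0, 0.5), got {trim_fraction}")
    values = sorted(float(v) for v in csps)
    k = int(len(values) * trim_fraction)
    trimmed = values[k : len(values) - k] if k else values
    mean = statistics.fmean(trimmed)
    sd = statistics.stdev(trimmed) if len(trimmed) > 1 else 0.0
    return (mean, sd)


@dataclass
class ClassificationResult:
    """Residue-level perturbation categories and the thresholds used."""

    trimmed_mean: float
    sd: float
    categories: dict[int, Category]

    def residues(self, category: Category) -> list[int]:
        return sorted(r for r, c in self.categories.items() if c == category)


def classify_probes(
    records: Iterable[CSPRecord],
    stats: tuple[float, float],
) -> ClassificationResult:
    """Classify residues by their most-perturbed methyl group.

    A residue is ``above_mean_plus_sd`` if any of its methyls has a composite
    CSP above ``trimmed_mean + sd``, else ``above_mean`` if any exceeds
    ``trimmed_mean``, else ``baseline``.
    """
    mean, sd = stats
    best: dict[int, float] = {}
    for rec in records:
        n = rec.probe.residue_number
        best[n] = max(best.get(n, 0.0), rec.composite)
    categories: dict[int, Category] = {}
    for n, top in best.items():
        if top > mean + sd:
            categories[n] = "above_mean_plus_sd"
        elif top > mean:
            categories[n] = "above_mean"
        else:
            categories[n] = "baseline"
    return ClassificationResult(trimmed_mean=mean, sd=sd, categories=categories)


@dataclass
class IntensityRatioScreen:
    """Per-probe volume ratios between two matched peak lists."""

    ratios: dict[Probe, float]
    median_ratio: float
    flagged: list[Probe]
    findings: list[Finding]


def intensity_ratio_screen(
    peaks_a: Sequence[Peak],
    peaks_b: Sequence[Peak],
    flag_margin: float = 0.15,
) -> IntensityRatioScreen:
    """Screen for probes whose intensity dropped more than the sample average.

    Computes per-probe volume ratios B/A over the probes common to both
    lists.  The median ratio serves as the dilution baseline (adding ligand
    stock dilutes the sample uniformly); probes with ratio below
    ``median*(1 - flag_margin)`` are flagged as decreased more than average —
    e.g. residues responding to phosphate binding on top of the dilution.
    """
    vol_a = {p.probe: p.volume for p in peaks_a}
    vol_b = {p.probe: p.volume for p in peaks_b}
    common = sorted(set(vol_a) & set(vol_b))
    if not common:
        raise DataError("no probes common to the two peak lists")
    ratios: dict[Probe, float] = {}
    findings: list[Finding] = []
    for probe in common:
        if vol_a[probe] == 0:
            findings.append(
                Finding("zero_denominator", f"probe {probe} has zero volume in list A", probe)
            )
            continue
        ratios[probe] = vol_b[probe] / vol_a[probe]
    if not ratios:
        raise DataError("no probe with nonzero reference volume")
    median = float(np.median(list(ratios.values())))
    cutoff = median * (1.0 - flag_margin)
    flagged = sorted(p for p, r in ratios.items() if r < cutoff)
    return IntensityRatioScreen(ratios=ratios, median_ratio=median, flagged=flagged, findings=findings)
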