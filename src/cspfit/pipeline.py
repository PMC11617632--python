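"""End-to-end runs: manifest -> CSP -> fit -> reports, with run records.

Every run writes a ``run_record.yaml`` into the output directory echoing all
resolved parameters (including seeds), so a run can be reproduced exactly
from the record alone.  With identical config and seeds, reports are
byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Literal

import pandas as pd
import yaml

from .csp import csp_profile, trimmed_stats, classify_probes
from .exceptions import ConfigError
from .models import (
    CSPComparison,
    ComparisonResults,
    FastExchangeModel,
    KdResults,
    SlowExchangeModel,
    detect_regime,
)
from .peaks import TitrationSeries, read_titration_manifest, write_report

__all__ = ["RunConfig", "run_fit", "run_compare", "run_csp"]


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run (echoed to the run record)."""

    manifest: str | None = None
    out_dir: str = "cspfit_out"
    regime: Literal["auto", "fast", "slow"] = "auto"
    protein_conc_override: float | None = None
    rel_err_threshold: float = 0.20
    trim_fraction: float = 0.10
    scale_c13: float = 0.18
    scale_n15: float = 0.15
    k_mad: float | None = None
    cosine_threshold: float = -0.2
    noise_floor: float = 0.005
    through_origin: bool = False
    #: probe subset entering the K_D average; "auto" uses the regime's default
    #: (trimmed-mean CSP selection for fast exchange, all fitted probes for slow)
    selection: Literal["auto", "trimmed", "all"] = "auto"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**doc)

    @property
    def scale_x(self) -> dict[str, float]:
        return {"C13": self.scale_c13, "N15": self.scale_n15}

    def write_record(self, out_dir: Path) -> Path:
        out_dir.mkdir(parents=True, exist_ok=True)
        record = out_dir / "run_record.yaml"
        with open(record, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
        return record


def _load_series(config: RunConfig, series: TitrationSeries | None) -> TitrationSeries:
    if series is not None:
        return series
    if config.manifest is None:
        raise ConfigError("a manifest path (or an in-memory series) is required")
    return read_titration_manifest(config.manifest)


def run_csp(config: RunConfig, series: TitrationSeries | None = None) -> pd.DataFrame:
    """Compute the endpoint CSP table with trimmed-threshold categories."""
    series = _load_series(config, series)
    out_dir = Path(config.out_dir)
    config.write_record(out_dir)
    profile = csp_profile(series, scale_x=config.scale_x)
    endpoint = profile.endpoint()
    stats = trimmed_stats([r.composite for r in endpoint], config.trim_fraction)
    classes = classify_probes(endpoint, stats)
    rows = []
    for rec in endpoint:
        rows.append(
            {
                "probe": rec.probe.probe_id,
                "residue_number": rec.probe.residue_number,
                "site_label": rec.probe.site_label,
                "d_h": rec.d_h,
                "d_x": rec.d_x,
                "composite": rec.composite,
                "category": classes.categories[rec.probe.residue_number],
            }
        )
    df = pd.DataFrame(rows)
    write_report(df, out_dir / "csp_endpoint.tsv")
    return df


def run_fit(config: RunConfig, series: TitrationSeries | None = None) -> KdResults:
    """Fit K_D from a titration manifest (regime auto-detected by default)."""
    series = _load_series(config, series)
    out_dir = Path(config.out_dir)
    config.write_record(out_dir)
    regime = config.regime
    if regime == "auto":
        regime = detect_regime(series)
    conc = config.protein_conc_override
    if regime == "fast":
        model = FastExchangeModel(series, protein_conc=conc)
        selection = "trimmed" if config.selection == "auto" else config.selection
    else:
        model = SlowExchangeModel(
            series, protein_conc=conc, rel_err_threshold=config.rel_err_threshold
        )
        selection = "all" if config.selection == "auto" else config.selection
    results = model.fit(selection=selection)
    results.to_report(out_dir / "kd_fits.tsv")
    summary_df = pd.DataFrame(
        [
            {
                "ligand": results.summary_.ligand_name,
                "regime": regime,
                "n_probes": results.summary_.n_probes,
                "mean_kd_uM": results.mean_kd,
                "sd_kd_uM": results.sd_kd,
                "selection_rule": results.summary_.selection_rule,
            }
        ]
    )
    write_report(summary_df, out_dir / "kd_summary.tsv")
    return results


def run_compare(
    config: RunConfig,
    series_a: TitrationSeries | str | Path,
    series_b: TitrationSeries | str | Path,
) -> ComparisonResults:
    """Two-ligand endpoint comparison from two manifests or series."""
    if not isinstance(series_a, TitrationSeries):
        series_a = read_titration_manifest(series_a)
    if not isinstance(series_b, TitrationSeries):
        series_b = read_titration_manifest(series_b)
    out_dir = Path(config.out_dir)
    config.write_record(out_dir)
    comparison = CSPComparison.from_series(series_a, series_b, noise_floor=config.noise_floor)
    results = comparison.fit(
        k_mad=config.k_mad,
        cosine_threshold=config.cosine_threshold,
        through_origin=config.through_origin,
    )
    results.to_report(out_dir / "comparison.tsv")
    summary_df = pd.DataFrame(
        [
            {
                "ligand_a": results.ligand_a,
                "ligand_b": results.ligand_b,
                "gradient": results.gradient,
                "intercept": results.intercept,
                "r_squared": results.r_squared,
                "n_outliers": len(results.magnitude_outliers),
                "n_reversals": len(results.direction_reversals),
            }
        ]
    )
    write_report(summary_df, out_dir / "comparison_summary.tsv")
    return results
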