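"""Model/Results interface over the titration-analysis machinery.

Three model classes cover the package's fits:

* :class:`FastExchangeModel` / :class:`SlowExchangeModel` — per-probe K_D
  extraction from a titration series, aggregated to a mean ± SD
  (:class:`KdResults`);
* :class:`CSPComparison` — the two-ligand CSP fingerprint comparison
  (:class:`ComparisonResults`);
* :class:`HydrolysisModel` — turnover rate from a 1D integral time course
  (:class:`HydrolysisResults`).

Each model is built from data (a :class:`~cspfit.peaks.TitrationSeries`,
paired CSP endpoints, or a :class:`~cspfit.kinetics.HydrolysisSeries`),
``fit()`` returns a results object carrying estimates, uncertainties and
diagnostics, and every results object has ``summary()`` (printable table),
``to_frame()`` and ``to_report(path)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import binding, compare as _compare
from .binding import FastFitResult, IsothermParams, KdSummary, fraction_bound
from .csp import CSPProfile, CSPRecord, csp_profile, trimmed_stats
from .exceptions import (
    AmbiguousRegimeError,
    DataError,
    InsufficientDataError,
)
from .kinetics import HydrolysisSeries, hydrolysis_rate, project_conversion
from .peaks import Finding, Probe, TitrationSeries, write_report

__all__ = [
    "detect_regime",
    "FastExchangeModel",
    "SlowExchangeModel",
    "CSPComparison",
    "HydrolysisModel",
    "KdResults",
    "ComparisonResults",
    "HydrolysisResults",
]


def detect_regime(series: TitrationSeries) -> Literal["fast", "slow"]:
    """Infer the exchange regime from the peak forms in a series.

    Merged peaks moving with saturation mean fast exchange; separate
    free/bound peak pairs mean slow exchange.  A series mixing both forms at
    nonzero ratios is ambiguous and needs an explicit regime.
    """
    forms: set[str] = set()
    for point in series.points[1:]:
        forms |= {p.form for p in point.peaks}
    has_merged = "merged" in forms
    has_split = "bound" in forms
    if has_merged and has_split:
        raise AmbiguousRegimeError(
            "series mixes merged and free/bound forms; pass an explicit regime"
        )
    if has_merged:
        return "fast"
    if has_split:
        return "slow"
    raise DataError("no peaks beyond the apo point; cannot detect regime")


# ---------------------------------------------------------------------------
# K_D models


@dataclass
class KdResults:
    """Per-probe K_D fits with their aggregate mean ± SD."""

    model: object
    summary_: KdSummary
    fits: list[FastFitResult]
    skipped: list[Finding]
    regime: str

    @property
    def mean_kd(self) -> float:
        return self.summary_.mean_kd

    @property
    def sd_kd(self) -> float:
        return self.summary_.sd_kd

    @property
    def per_probe(self) -> list[tuple[Probe, float]]:
        return self.summary_.per_probe

    def to_frame(self) -> pd.DataFrame:
        rows = []
        selected = {p for p, _ in self.summary_.per_probe}
        for fit in self.fits:
            rows.append(
                {
                    "probe": fit.probe.probe_id,
                    "residue_number": fit.probe.residue_number,
                    "site_label": fit.probe.site_label,
                    "kd_uM": fit.kd,
                    "kd_stderr_uM": fit.kd_stderr if fit.kd_stderr is not None else float("nan"),
                    "d_max_ppm": fit.d_max,
                    "residual_rms": fit.residual_rms,
                    "n_points": fit.n_points,
                    "selected": fit.probe in selected,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        s = self.summary_
        lines = [
            f"K_D fit summary — ligand {s.ligand_name} ({self.regime} exchange)",
            f"  probes fitted   : {len(self.fits)} ({len(self.skipped)} skipped)",
            f"  probes selected : {s.n_probes} (rule: {s.selection_rule})",
            f"  mean K_D        : {s.mean_kd:.4g} µM",
            f"  SD K_D          : {s.sd_kd:.4g} µM",
        ]
        for w in s.warnings:
            lines.append(f"  warning: {w}")
        return "\n".join(lines)

    def to_report(self, path: str | Path) -> Path:
        return write_report(self.to_frame(), path)

    def plot(self, ax=None):
        """Histogram of per-probe K_D values with the mean ± SD band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        kds = [f.kd for f in self.fits]
        ax.hist(kds, bins=min(20, max(5, len(kds) // 3)), color="steelblue", alpha=0.8)
        ax.axvline(self.mean_kd, color="k")
        ax.axvspan(self.mean_kd - self.sd_kd, self.mean_kd + self.sd_kd, color="k", alpha=0.15)
        ax.set_xlabel("K_D (µM)")
        ax.set_ylabel("probes")
        return ax


def _default_selection(endpoint_value: dict[Probe, float]) -> set[Probe]:
    """Probes whose endpoint response exceeds the 10%-trimmed mean of all."""
    if not endpoint_value:
        return set()
    mean, _ = trimmed_stats(list(endpoint_value.values()), 0.10)
    return {p for p, v in endpoint_value.items() if v > mean}


class FastExchangeModel:
    """Per-probe (K_D, Δδ_max) fits to fast-exchange CSP trajectories.

    Parameters
    ----------
    series
        Titration with merged peaks at nonzero ratios.
    protein_conc
        Total protein concentration in µM; defaults to the apo point's value.
    """

    def __init__(self, series: TitrationSeries, protein_conc: float | None = None):
        self.series = series
        self.protein_conc = protein_conc if protein_conc is not None else series.apo.protein_conc
        self.profile: CSPProfile = csp_profile(series)

    def fit(
        self,
        selection: Literal["trimmed", "all"] = "trimmed",
        min_points: int = 3,
    ) -> KdResults:
        fits: list[FastFitResult] = []
        skipped: list[Finding] = []
        trajectories = self.profile.per_probe()
        for probe, pts in sorted(trajectories.items()):
            data = [(0.0, 0.0)] + pts
            try:
                fits.append(binding.fit_fast_exchange(data, self.protein_conc, probe))
            except DataError as exc:
                skipped.append(Finding("fit_skipped", str(exc), probe))
        if not fits:
            raise InsufficientDataError("no probe could be fitted")
        endpoint = {r.probe: r.composite for r in self.profile.endpoint()}
        summary = _aggregate(fits, endpoint, selection, self.series.ligand_name,
                             rule_noun="endpoint composite CSP")
        return KdResults(self, summary, fits, skipped, "fast")


class SlowExchangeModel:
    """Per-probe K_D fits to slow-exchange volume-redistribution data.

    Bound fractions are estimated per probe and point from the free- and
    bound-form peak volumes (see
    :func:`~cspfit.binding.estimate_fractions_slow`); an estimate enters only
    when the relevant volume errors pass ``rel_err_threshold``.  With
    ``saturation_correction`` (default), fitting iterates a rescaling of the
    bound-route estimates by the fitted endpoint saturation f(x_max; K_D),
    removing the bias of the I_PL(x)/I_PL(x_max) estimator when the final
    point is not fully saturated; without it, the normalization point itself
    is excluded from the fit as carrying no independent information.
    """

    def __init__(
        self,
        series: TitrationSeries,
        protein_conc: float | None = None,
        rel_err_threshold: float = 0.20,
    ):
        self.series = series
        self.protein_conc = protein_conc if protein_conc is not None else series.apo.protein_conc
        self.rel_err_threshold = rel_err_threshold
        apo = series.apo
        max_point = series.points[-1]
        self.x_max = max_point.ratio_x
        self.estimates = {
            point.ratio_x: binding.estimate_fractions_slow(
                point, apo, max_point, rel_err_threshold
            )
            for point in series.points[1:]
        }

    def _probe_routes(self) -> dict[Probe, list[tuple[float, float | None, float | None]]]:
        routes: dict[Probe, list[tuple[float, float | None, float | None]]] = {}
        for x, ests in self.estimates.items():
            for est in ests:
                routes.setdefault(est.probe, []).append((x, est.f_from_free, est.f_from_bound))
        return routes

    def fit(
        self,
        selection: Literal["all", "trimmed"] = "all",
        saturation_correction: bool = True,
        max_iter: int = 25,
        tol: float = 1e-10,
    ) -> KdResults:
        fits: list[FastFitResult] = []
        skipped: list[Finding] = []
        for probe, routes in sorted(self._probe_routes().items()):
            try:
                fits.append(self._fit_probe(probe, routes, saturation_correction, max_iter, tol))
            except DataError as exc:
                skipped.append(Finding("fit_skipped", str(exc), probe))
        if not fits:
            raise InsufficientDataError("no probe could be fitted")
        bound_at_max = {}
        max_point = self.series.points[-1]
        for probe in {f.probe for f in fits}:
            pk = max_point.peak(probe, "bound")
            bound_at_max[probe] = pk.volume if pk is not None else 0.0
        summary = _aggregate(fits, bound_at_max, selection, self.series.ligand_name,
                             rule_noun="endpoint bound-peak volume")
        return KdResults(self, summary, fits, skipped, "slow")

    def _fit_probe(
        self,
        probe: Probe,
        routes: list[tuple[float, float | None, float | None]],
        saturation_correction: bool,
        max_iter: int,
        tol: float,
    ) -> FastFitResult:
        def combined(scale_bound: float, include_xmax: bool) -> list[tuple[float, float]]:
            pts = []
            for x, f_free, f_bound in routes:
                if not include_xmax and x == self.x_max and f_free is None:
                    continue
                vals = []
                if f_free is not None:
                    vals.append(f_free)
                if f_bound is not None:
                    vals.append(f_bound * scale_bound)
                if vals:
                    pts.append((x, float(np.clip(np.mean(vals), 0.0, 1.0))))
            return pts

        if not saturation_correction:
            return binding.fit_slow_exchange(combined(1.0, False), self.protein_conc, probe)
        fit = binding.fit_slow_exchange(combined(1.0, False), self.protein_conc, probe)
        for _ in range(max_iter):
            scale = fraction_bound(self.x_max, IsothermParams(fit.kd, self.protein_conc))
            new = binding.fit_slow_exchange(combined(scale, True), self.protein_conc, probe)
            if abs(new.kd - fit.kd) <= tol * max(fit.kd, 1e-12):
                return new
            fit = new
        return fit


def _aggregate(
    fits: list[FastFitResult],
    endpoint_value: dict[Probe, float],
    selection: str,
    ligand_name: str,
    rule_noun: str,
) -> KdSummary:
    pairs = [(f.probe, f.kd) for f in fits]
    if selection == "all":
        return binding.aggregate_kd(pairs, "all probes", ligand_name)
    if selection == "trimmed":
        chosen = _default_selection(endpoint_value)
        selected = [(p, kd) for p, kd in pairs if p in chosen]
        if not selected:
            selected = pairs
            rule = "all probes (trimmed-mean selection empty)"
        else:
            rule = f"probes with {rule_noun} above the 10%-trimmed mean"
        summary = binding.aggregate_kd(selected, rule, ligand_name)
        return summary
    raise DataError(f"unknown selection rule {selection!r}")


# ---------------------------------------------------------------------------
# two-ligand comparison


@dataclass
class ComparisonResults:
    """Gradient/R² of the CSP correlation plus flagged probe sets."""

    summary_: _compare.ComparisonSummary
    records: list[_compare.ComparisonRecord]
    ligand_a: str
    ligand_b: str

    @property
    def gradient(self) -> float:
        return self.summary_.gradient

    @property
    def intercept(self) -> float:
        return self.summary_.intercept

    @property
    def r_squared(self) -> float:
        return self.summary_.r_squared

    @property
    def magnitude_outliers(self) -> list[Probe]:
        return self.summary_.magnitude_outliers

    @property
    def direction_reversals(self) -> list[Probe]:
        return self.summary_.direction_reversals

    def to_frame(self) -> pd.DataFrame:
        rows = []
        outl = set(self.summary_.magnitude_outliers)
        revs = set(self.summary_.direction_reversals)
        for r in self.records:
            rows.append(
                {
                    "probe": r.probe.probe_id,
                    "residue_number": r.probe.residue_number,
                    "site_label": r.probe.site_label,
                    "mag_a": r.mag_a,
                    "mag_b": r.mag_b,
                    "dot": r.dot,
                    "cosine": r.cosine if r.cosine is not None else float("nan"),
                    "residual": r.residual if r.residual is not None else float("nan"),
                    "outlier": r.probe in outl,
                    "reversal": r.probe in revs,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        s = self.summary_
        out = ", ".join(p.probe_id for p in s.magnitude_outliers) or "none"
        rev = ", ".join(p.probe_id for p in s.direction_reversals) or "none"
        mode = "through origin" if s.through_origin else "free intercept"
        return "\n".join(
            [
                f"CSP comparison — {self.ligand_b} vs {self.ligand_a} ({s.n_pairs} probes, {mode})",
                f"  gradient  : {s.gradient:.4g}",
                f"  intercept : {s.intercept:.4g} ppm",
                f"  R²        : {s.r_squared:.4g}",
                f"  magnitude outliers  : {out}",
                f"  direction reversals : {rev}",
            ]
        )

    def to_report(self, path: str | Path) -> Path:
        return write_report(self.to_frame(), path)

    def plot(self, ax=None):
        """Magnitude correlation plot with the best-fit line and flags."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.to_frame()
        ax.scatter(df.mag_a, df.mag_b, s=18, c="grey", label="probes")
        if df.outlier.any():
            sel = df[df.outlier]
            ax.scatter(sel.mag_a, sel.mag_b, s=30, c="crimson", label="outliers")
        xs = np.linspace(0, float(df.mag_a.max()) * 1.05, 50)
        ax.plot(xs, self.gradient * xs + self.intercept, "k--",
                label=f"slope {self.gradient:.2f}, R²={self.r_squared:.2f}")
        ax.set_xlabel(f"CSP {self.ligand_a} (ppm)")
        ax.set_ylabel(f"CSP {self.ligand_b} (ppm)")
        ax.legend(frameon=False)
        return ax


class CSPComparison:
    """Compare two ligands' endpoint CSP fingerprints.

    Built from two per-probe CSP tables (e.g. the endpoints of two
    titrations of the same protein with different ligands).
    """

    def __init__(
        self,
        records_a: Sequence[CSPRecord],
        records_b: Sequence[CSPRecord],
        ligand_a: str = "A",
        ligand_b: str = "B",
        noise_floor: float = _compare.DEFAULT_NOISE_FLOOR,
    ):
        self.records = _compare.build_comparison_records(records_a, records_b, noise_floor)
        if len(self.records) < 3:
            raise InsufficientDataError(
                f"need >= 3 probes common to both ligands, got {len(self.records)}"
            )
        self.ligand_a = ligand_a
        self.ligand_b = ligand_b

    @classmethod
    def from_series(
        cls,
        series_a: TitrationSeries,
        series_b: TitrationSeries,
        **kwargs,
    ) -> "CSPComparison":
        recs_a = csp_profile(series_a).endpoint()
        recs_b = csp_profile(series_b).endpoint()
        kwargs.setdefault("ligand_a", series_a.ligand_name)
        kwargs.setdefault("ligand_b", series_b.ligand_name)
        return cls(recs_a, recs_b, **kwargs)

    def fit(
        self,
        k_mad: float | None = None,
        cosine_threshold: float = -0.2,
        through_origin: bool = False,
    ) -> ComparisonResults:
        pairs = [(r.mag_a, r.mag_b) for r in self.records]
        gradient, intercept, r2 = _compare.csp_regression(pairs, through_origin)
        outliers = _compare.flag_magnitude_outliers(self.records, (gradient, intercept), k_mad)
        reversals = _compare.flag_direction_reversals(self.records, cosine_threshold)
        summary = _compare.ComparisonSummary(
            gradient=gradient,
            intercept=intercept,
            r_squared=r2,
            magnitude_outliers=outliers,
            direction_reversals=reversals,
            n_pairs=len(self.records),
            through_origin=through_origin,
        )
        return ComparisonResults(summary, self.records, self.ligand_a, self.ligand_b)


# ---------------------------------------------------------------------------
# hydrolysis


@dataclass
class HydrolysisResults:
    """Turnover rate with the linear-phase window used to measure it."""

    series: HydrolysisSeries
    rate: float  # molar equivalents of substrate per enzyme per hour
    linear_min_fraction: float

    def project(self, t_hours: float) -> float:
        """Percent substrate converted after ``t_hours`` at the fitted rate."""
        return project_conversion(
            self.rate, self.series.enzyme_conc, self.series.substrate_conc0, t_hours
        )

    def summary(self) -> str:
        return "\n".join(
            [
                "Hydrolysis fit",
                f"  turnover rate : {self.rate:.4g} eq substrate / enzyme / h",
                f"  enzyme        : {self.series.enzyme_conc:.4g} mM",
                f"  substrate(0)  : {self.series.substrate_conc0:.4g} mM",
                f"  24 h conversion projection : {self.project(24.0):.3g} %",
            ]
        )

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.series
        ax.plot(s.times, s.atp_fraction, "o", color="steelblue")
        slope = -self.rate * s.enzyme_conc / s.substrate_conc0
        ax.plot(s.times, 1.0 + slope * s.times, "k--")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("normalized substrate integral")
        return ax


class HydrolysisModel:
    """Turnover rate from a normalized substrate-integral time course."""

    def __init__(self, series: HydrolysisSeries):
        self.series = series

    def fit(self, linear_min_fraction: float = 0.8) -> HydrolysisResults:
        rate = hydrolysis_rate(self.series, linear_min_fraction)
        return HydrolysisResults(self.series, rate, linear_min_fraction)
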