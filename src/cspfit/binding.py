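"""Bimolecular binding isotherm and dissociation-constant extraction.

For a protein P at total concentration [P]_T titrated with ligand L at molar
ratio x = [L]_T/[P]_T, exact mass action for 1:1 binding gives the bound
fraction

    f(x) = 1/2 * [ (1 + K_D/[P]_T + x) - sqrt((1 + K_D/[P]_T + x)^2 - 4x) ],

the physical root of the binding quadratic.  Two observational encodings of
f(x) are supported:

* **fast exchange** (k_ex >> Δν): one population-averaged peak moves with
  saturation; the composite CSP obeys Δδ(x) = Δδ_max * f(x), and (K_D,
  Δδ_max) are fitted per probe by nonlinear least squares;
* **slow exchange** (k_ex << Δν): separate free- and bound-form peaks whose
  volumes redistribute.  The free peak gives f = 1 - I_P(x)/I_P(0); the bound
  peak gives f = I_PL(x)/I_PL(x_max), normalising by the bound-form volume at
  the final (saturating) titration point rather than the apo free-form volume
  so that the estimate does not inherit the apo point's scaling.  Estimates
  are used only when the relative volume errors of both peaks involved pass a
  threshold; when only one estimate survives, it is used alone; when both
  survive they are averaged.  K_D is then fitted directly to f(x).

Per-probe K_D values are aggregated to a mean ± sample SD over a recorded
probe subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from lmfit import Parameters, minimize

from .exceptions import (
    ConfigError,
    DataError,
    FitConvergenceError,
    InsufficientDataError,
    UnidentifiableKdError,
)
from .peaks import Finding, Probe, TitrationPoint

__all__ = [
    "IsothermParams",
    "FastFitResult",
    "FractionEstimate",
    "KdSummary",
    "fraction_bound",
    "fit_fast_exchange",
    "estimate_fractions_slow",
    "fit_slow_exchange",
    "aggregate_kd",
    "expected_saturation_gradient",
]


@dataclass(frozen=True)
class IsothermParams:
    """Dissociation constant and total protein concentration, both in µM."""

    kd: float
    protein_conc: float

    def __post_init__(self) -> None:
        if not (self.kd > 0 and np.isfinite(self.kd)):
            raise ConfigError(f"kd must be finite and > 0 µM, got {self.kd}")
        if not (self.protein_conc > 0 and np.isfinite(self.protein_conc)):
            raise ConfigError(f"protein_conc must be finite and > 0 µM, got {self.protein_conc}")


def fraction_bound(x, params: IsothermParams):
    """Bound protein fraction f(x) from exact 1:1 mass action.

    Evaluated in the algebraically equivalent form ``2x / (A + sqrt(A^2-4x))``
    with ``A = 1 + K_D/[P]_T + x``, which avoids the cancellation the direct
    root expression suffers at large K_D/[P]_T.  Accepts scalars or arrays.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise DataError("ligand:protein ratio x must be >= 0")
    a = 1.0 + params.kd / params.protein_conc + x
    disc = np.maximum(a * a - 4.0 * x, 0.0)
    f = 2.0 * x / (a + np.sqrt(disc))
    return float(f) if f.ndim == 0 else f


@dataclass
class FastFitResult:
    """Per-probe fast-exchange fit: K_D (µM) and Δδ_max (ppm)."""

    probe: Probe | None
    kd: float
    d_max: float
    kd_stderr: float | None
    d_max_stderr: float | None
    residual_rms: float
    n_points: int


def fit_fast_exchange(
    csp_vs_x: Sequence[tuple[float, float]],
    protein_conc: float,
    probe: Probe | None = None,
) -> FastFitResult:
    """Fit (K_D, Δδ_max) to composite CSPs vs molar ratio.

    Minimises sum over points of ``(Δδ(x) - Δδ_max * f(x; K_D))**2`` with
    both parameters bounded positive.  Initialisation: Δδ_max at 1.1x the
    largest observed CSP and K_D at [P]_T times the ratio at half-maximal
    CSP — adequate over the µM-to-mM range encountered in practice.
    """
    pts = sorted((float(x), float(d)) for x, d in csp_vs_x)
    xs = np.array([p[0] for p in pts])
    ds = np.array([p[1] for p in pts])
    nonzero = xs > 0
    if np.unique(xs[nonzero]).size < 3:
        raise InsufficientDataError(
            f"fast-exchange fit needs >= 3 distinct nonzero ratios, got {np.unique(xs[nonzero]).size}"
        )
    d_top = float(ds.max())
    if d_top <= 0:
        raise DataError("all CSPs are zero; nothing to fit")
    half = np.argmin(np.abs(ds - d_top / 2))
    kd0 = max(protein_conc * max(xs[half], 0.1), 1e-3)

    params = Parameters()
    params.add("kd", value=kd0, min=1e-9)
    params.add("d_max", value=1.1 * d_top, min=1e-12)

    def residual(p):
        iso = IsothermParams(p["kd"].value, protein_conc)
        return ds - p["d_max"].value * fraction_bound(xs, iso)

    out = minimize(residual, params, method="leastsq")
    if not out.success:
        raise FitConvergenceError(f"fast-exchange fit failed: {out.message}")
    kd = out.params["kd"].value
    d_max = out.params["d_max"].value
    rms = float(np.sqrt(np.mean(out.residual**2)))
    return FastFitResult(
        probe=probe,
        kd=float(kd),
        d_max=float(d_max),
        kd_stderr=out.params["kd"].stderr,
        d_max_stderr=out.params["d_max"].stderr,
        residual_rms=rms,
        n_points=int(xs.size),
    )


@dataclass
class FractionEstimate:
    """Bound-fraction estimate at one titration point for one probe."""

    probe: Probe
    ratio_x: float
    f_from_free: float | None
    f_from_bound: float | None
    f_combined: float | None
    sources: tuple[str, ...]
    findings: list[Finding] = field(default_factory=list)

    @property
    def f_clipped(self) -> float | None:
        if self.f_combined is None:
            return None
        return min(1.0, max(0.0, self.f_combined))


def _passes(peak, threshold: float) -> bool:
    return peak is not None and peak.volume_rel_err <= threshold


def estimate_fractions_slow(
    point: TitrationPoint,
    apo: TitrationPoint,
    max_point: TitrationPoint,
    rel_err_threshold: float = 0.20,
) -> list[FractionEstimate]:
    """Per-probe bound-fraction estimates at one slow-exchange point.

    Free-peak route: ``f = 1 - I_P(x)/I_P(0)``; bound-peak route:
    ``f = I_PL(x)/I_PL(x_max)``.  A route contributes only if both volumes it
    uses carry relative errors at or below ``rel_err_threshold``; raw route
    estimates outside [-0.05, 1.05] are discarded with a finding.  The
    combined value is the mean of the surviving routes, or the single
    available value when only one survives.
    """
    out: list[FractionEstimate] = []
    for probe in sorted(apo.probes):
        findings: list[Finding] = []
        apo_free = apo.peak(probe, "free")
        if apo_free is None:
            continue
        if point.ratio_x == 0:
            out.append(
                FractionEstimate(probe, 0.0, 0.0, None, 0.0, ("free",))
            )
            continue
        free_pk = point.peak(probe, "free")
        bound_pk = point.peak(probe, "bound")
        max_bound = max_point.peak(probe, "bound")

        f_free: float | None = None
        if _passes(free_pk, rel_err_threshold) and _passes(apo_free, rel_err_threshold):
            if apo_free.volume > 0:
                f_free = 1.0 - free_pk.volume / apo_free.volume

        f_bound: float | None = None
        if _passes(bound_pk, rel_err_threshold) and _passes(max_bound, rel_err_threshold):
            if max_bound.volume > 0:
                f_bound = bound_pk.volume / max_bound.volume

        sources = []
        usable = []
        for name, value in (("free", f_free), ("bound", f_bound)):
            if value is None:
                continue
            if not (-0.05 <= value <= 1.05):
                findings.append(
                    Finding(
                        "implausible_fraction",
                        f"{name}-route estimate {value:.3f} outside [-0.05, 1.05] "
                        f"for {probe} at x={point.ratio_x}",
                        probe,
                        point.ratio_x,
                    )
                )
                if name == "free":
                    f_free = None
                else:
                    f_bound = None
                continue
            sources.append(name)
            usable.append(value)
        f_combined = float(np.mean(usable)) if usable else None
        out.append(
            FractionEstimate(
                probe=probe,
                ratio_x=point.ratio_x,
                f_from_free=f_free,
                f_from_bound=f_bound,
                f_combined=f_combined,
                sources=tuple(sources),
                findings=findings,
            )
        )
    return out


def fit_slow_exchange(
    fractions: Sequence[tuple[float, float]],
    protein_conc: float,
    probe: Probe | None = None,
) -> FastFitResult:
    """Fit K_D to bound fractions vs molar ratio (slow-exchange route).

    One-parameter least squares of ``f_combined(x)`` against ``f(x; K_D)``.
    Identifiability requires at least two informative points (nonzero x with
    0.02 < f < 0.98); a titration whose every nonzero point is saturated
    carries no K_D information and raises an error advising lower ratios.
    Returns a :class:`FastFitResult` with ``d_max`` fixed at 1.
    """
    pts = sorted((float(x), float(f)) for x, f in fractions)
    xs = np.array([p[0] for p in pts])
    fs = np.array([p[1] for p in pts])
    nz = xs > 0
    informative = nz & (fs > 0.02) & (fs < 0.98)
    if not informative.any():
        if nz.any() and np.all(fs[nz] > 0.98):
            raise UnidentifiableKdError(
                "all titration points are saturated (f > 0.98); K_D is not "
                "identifiable — repeat with lower ligand:protein ratios"
            )
        raise InsufficientDataError("no informative titration points (0.02 < f < 0.98, x > 0)")
    if np.unique(xs[nz]).size < 2:
        raise InsufficientDataError("slow-exchange fit needs >= 2 distinct nonzero ratios")

    # invert mass action at the point nearest half-saturation for the start value
    i0 = np.argmin(np.abs(fs[informative] - 0.5))
    x0, f0 = xs[informative][i0], np.clip(fs[informative][i0], 0.02, 0.98)
    kd0 = max(protein_conc * (1 - f0) * max(x0 - f0, 1e-3) / f0, 1e-3)

    params = Parameters()
    params.add("kd", value=kd0, min=1e-9)

    def residual(p):
        iso = IsothermParams(p["kd"].value, protein_conc)
        return fs - fraction_bound(xs, iso)

    out = minimize(residual, params, method="leastsq")
    if not out.success:
        raise FitConvergenceError(f"slow-exchange fit failed: {out.message}")
    rms = float(np.sqrt(np.mean(out.residual**2)))
    return FastFitResult(
        probe=probe,
        kd=float(out.params["kd"].value),
        d_max=1.0,
        kd_stderr=out.params["kd"].stderr,
        d_max_stderr=None,
        residual_rms=rms,
        n_points=int(xs.size),
    )


@dataclass
class KdSummary:
    """Per-probe K_D fits aggregated to a mean ± sample SD."""

    ligand_name: str
    per_probe: list[tuple[Probe, float]]
    mean_kd: float
    sd_kd: float
    selection_rule: str
    warnings: list[str] = field(default_factory=list)

    @property
    def n_probes(self) -> int:
        return len(self.per_probe)


def aggregate_kd(
    fits: Sequence[tuple[Probe, float]],
    selection: str | Callable[[Sequence[tuple[Probe, float]]], Sequence[tuple[Probe, float]]] = "all",
    ligand_name: str = "ligand",
) -> KdSummary:
    """Aggregate per-probe K_D values to mean ± sample SD (n-1 denominator).

    ``selection`` is either the string describing an identity rule ("all")
    or a callable returning the selected subset; the rule applied is recorded
    verbatim in the summary so a report always states which probes entered
    the average.
    """
    if callable(selection):
        selected = list(selection(fits))
        rule = getattr(selection, "__doc__", None) or getattr(selection, "__name__", "custom")
    else:
        selected = list(fits)
        rule = str(selection)
    if not selected:
        raise DataError("no probes selected for K_D aggregation")
    kds = np.array([kd for _, kd in selected], dtype=float)
    warns: list[str] = []
    mean = float(kds.mean())
    if kds.size == 1:
        sd = 0.0
        warns.append("single-probe summary: SD reported as 0")
        warnings.warn("K_D summary is based on a single probe", stacklevel=2)
    else:
        sd = float(kds.std(ddof=1))
    return KdSummary(
        ligand_name=ligand_name,
        per_probe=selected,
        mean_kd=mean,
        sd_kd=sd,
        selection_rule=rule,
        warnings=warns,
    )


def expected_saturation_gradient(
    params_a: IsothermParams,
    x_a: float,
    params_b: IsothermParams,
    x_b: float,
    assume_a_saturated: bool = False,
) -> float:
    """Expected CSP-correlation slope under identical bound-state shifts.

    If two ligands perturbed every probe identically at full saturation, the
    slope of ligand-B CSPs regressed on ligand-A CSPs would equal the ratio
    of their saturation fractions, f_b/f_a, at the endpoints compared.  With
    ``assume_a_saturated``, f_a is taken as exactly 1.
    """
    f_a = 1.0 if assume_a_saturated else fraction_bound(x_a, params_a)
    if f_a == 0:
        raise DataError("ligand-A saturation fraction is zero; gradient undefined")
    f_b = fraction_bound(x_b, params_b)
    return float(f_b / f_a)
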