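"""Two-ligand CSP fingerprint comparison.

If two ligands induced identical bound-state shifts, the per-probe CSP
magnitudes of one endpoint regressed on the other would fall on a line whose
slope equals the ratio of the two saturation fractions, with R² close to 1.
Departures carry structural information and are detected two ways:

* **magnitude outliers** — probes whose residual from the best-fit line
  exceeds ``k_mad`` robust SDs (median absolute deviation scaled by 1.4826);
* **direction reversals** — probes whose CSP vectors (in the s_X-scaled
  2D shift plane, the same space as the composite CSP) point in opposing
  directions for the two ligands: cosine below a negative threshold, with
  both magnitudes above a noise floor so that pure-noise vectors cannot be
  flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _stats

from .csp import CSPRecord
from .exceptions import DataError, DegenerateInputError
from .peaks import Probe

__all__ = [
    "ComparisonRecord",
    "ComparisonSummary",
    "build_comparison_records",
    "csp_regression",
    "flag_magnitude_outliers",
    "direction_product",
    "flag_direction_reversals",
]

#: Composite-CSP magnitude below which a vector's direction is noise (ppm).
DEFAULT_NOISE_FLOOR = 0.005


@dataclass
class ComparisonRecord:
    """Matched pair of CSP vectors for one probe under two ligands."""

    probe: Probe
    vec_a: tuple[float, float]  # (d_h, sX*d_x) for ligand A, ppm
    vec_b: tuple[float, float]
    mag_a: float
    mag_b: float
    dot: float
    cosine: float | None
    residual: float | None = None


@dataclass
class ComparisonSummary:
    """Regression line plus flagged probe sets for a two-ligand comparison."""

    gradient: float
    intercept: float
    r_squared: float
    magnitude_outliers: list[Probe]
    direction_reversals: list[Probe]
    n_pairs: int
    through_origin: bool = False


def direction_product(
    vec_a: Sequence[float],
    vec_b: Sequence[float],
    noise_floor: float = DEFAULT_NOISE_FLOOR,
) -> tuple[float, float | None]:
    """Dot product and cosine of two CSP vectors in the scaled-shift plane.

    The cosine is reported as ``None`` when either vector's magnitude is at
    or below ``noise_floor`` — the direction of a near-zero CSP is undefined.
    """
    a = np.asarray(vec_a, dtype=float)
    b = np.asarray(vec_b, dtype=float)
    dot = float(a @ b)
    na, nb = float(np.hypot(*a)), float(np.hypot(*b))
    if na <= noise_floor or nb <= noise_floor:
        return dot, None
    return dot, float(np.clip(dot / (na * nb), -1.0, 1.0))


def build_comparison_records(
    records_a: Sequence[CSPRecord],
    records_b: Sequence[CSPRecord],
    noise_floor: float = DEFAULT_NOISE_FLOOR,
) -> list[ComparisonRecord]:
    """Match two endpoint CSP tables by probe and form the vector pairs."""
    by_probe_a = {r.probe: r for r in records_a}
    by_probe_b = {r.probe: r for r in records_b}
    common = sorted(set(by_probe_a) & set(by_probe_b))
    if not common:
        raise DataError("no probes common to the two CSP endpoints")
    out: list[ComparisonRecord] = []
    for probe in common:
        ra, rb = by_probe_a[probe], by_probe_b[probe]
        dot, cosine = direction_product(ra.vector, rb.vector, noise_floor)
        out.append(
            ComparisonRecord(
                probe=probe,
                vec_a=ra.vector,
                vec_b=rb.vector,
                mag_a=ra.composite,
                mag_b=rb.composite,
                dot=dot,
                cosine=cosine,
            )
        )
    return out


def csp_regression(
    pairs: Sequence[tuple[float, float]],
    through_origin: bool = False,
) -> tuple[float, float, float]:
    """Best-fit line of ligand-B magnitudes on ligand-A magnitudes.

    Ordinary least squares with a free intercept by default (slope,
    intercept, R² as the squared Pearson correlation).  With
    ``through_origin`` the intercept is constrained to zero and R² is the
    fraction of (uncentred) variance explained.
    """
    if len(pairs) < 3:
        raise DataError(f"regression needs >= 3 pairs, got {len(pairs)}")
    a = np.array([p[0] for p in pairs], dtype=float)
    b = np.array([p[1] for p in pairs], dtype=float)
    if np.allclose(a, a[0]):
        raise DegenerateInputError("zero variance in ligand-A magnitudes")
    if through_origin:
        slope = float(a @ b / (a @ a))
        ss_res = float(np.sum((b - slope * a) ** 2))
        ss_tot = float(b @ b)
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        return slope, 0.0, float(np.clip(r2, 0.0, 1.0))
    res = _stats.linregress(a, b)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def calibrated_k(n: int, alpha: float = 0.001) -> float:
    """Outlier cutoff (in robust SDs) Bonferroni-calibrated for n probes.

    Chosen so a clean Gaussian dataset of n probes is flagged entirely clean
    with probability 1 - alpha; grows ~sqrt(2 log n), staying far below the
    >= 10-sigma displacement of a genuine outlier.
    """
    return float(_stats.norm.isf(alpha / (2 * n)))


def flag_magnitude_outliers(
    records: Sequence[ComparisonRecord],
    summary: ComparisonSummary | tuple[float, float],
    k_mad: float | None = None,
    robust_line: bool = True,
) -> list[Probe]:
    """Probes departing from the magnitude correlation line.

    With ``robust_line`` (default) residuals are measured from a Theil-Sen
    fit of the magnitude pairs rather than from the ordinary least-squares
    summary line: the outliers being hunted are exactly the points that drag
    an OLS line, so measuring departure from a high-breakdown line keeps
    detection reliable even when a quarter of the probes are aberrant.  (The
    Theil-Sen intercept is taken as the median residual about the slope,
    which unlike scipy's ``median(y) - slope*median(x)`` is insensitive to
    one-sided contamination.)  Residuals are centred at their median; their
    median absolute deviation (scaled by 1.4826 to estimate sigma under
    normal noise) sets the robust scale, and probes beyond ``k_mad`` robust
    SDs are flagged.  ``k_mad=None`` (default) uses a multiplicity-aware
    cutoff (:func:`calibrated_k`) so that the expected number of
    false flags per dataset stays ~0.001 regardless of probe count; pass an
    explicit value (e.g. 3) for a fixed per-probe rule.  ``records`` are
    annotated in place with the residuals used.
    """
    if isinstance(summary, ComparisonSummary):
        slope, intercept = summary.gradient, summary.intercept
        through_origin = summary.through_origin
    else:
        slope, intercept = summary
        through_origin = False
    a = np.array([r.mag_a for r in records])
    b = np.array([r.mag_b for r in records])
    if robust_line and len(records) >= 3 and not np.allclose(a, a[0]):
        if through_origin:
            slope = float(np.median(b[a > 0] / a[a > 0]))
            intercept = 0.0
        else:
            slope = float(_stats.theilslopes(b, a).slope)
            intercept = float(np.median(b - slope * a))
    resid = b - (slope * a + intercept)
    for rec, value in zip(records, resid):
        rec.residual = float(value)
    if k_mad is None:
        k_mad = calibrated_k(len(records))
    centred = resid - np.median(resid)
    mad = float(np.median(np.abs(centred)))
    scale = 1.4826 * mad
    if scale == 0:
        # perfectly collinear data: anything off the line is an outlier
        # (beyond float round-off of the collinear values themselves)
        eps = 1e-9 * max(float(np.max(np.abs(b))), 1.0e-3)
        flagged = [r.probe for r, c in zip(records, centred) if abs(c) > eps]
    else:
        flagged = [r.probe for r, c in zip(records, centred) if abs(c) > k_mad * scale]
    return sorted(flagged)


def flag_direction_reversals(
    records: Sequence[ComparisonRecord],
    cosine_threshold: float = -0.2,
) -> list[Probe]:
    """Probes whose two CSP vectors point in opposing directions.

    A probe is flagged when its cosine is defined (both magnitudes above the
    noise floor used when the records were built) and below
    ``cosine_threshold`` (a value in [-1, 0]).
    """
    if not -1.0 <= cosine_threshold <= 0.0:
        raise DataError(f"cosine_threshold must be in [-1, 0], got {cosine_threshold}")
    return sorted(
        r.probe for r in records if r.cosine is not None and r.cosine < cosine_threshold
    )
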