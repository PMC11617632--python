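"""Synthetic titration, two-ligand and hydrolysis data with known truth.

The generators emulate the statistical structure of methyl-HMQC titration
data so every analysis stage can be verified against ground truth:

* **fast exchange** — one merged peak per probe whose position moves from
  the apo position toward the bound position in proportion to the bound
  fraction f(x); volumes stay constant up to multiplicative noise;
* **slow exchange** — two peaks per probe at fixed positions whose volumes
  redistribute as V0*(1-f(x)) and V0*f(x) under log-normal multiplicative
  noise; peaks below a visibility floor are omitted, emulating peaks too
  weak for accurate volume quantification near either end of a titration;
* **two-ligand endpoints** — ligand-B bound-state vectors equal to
  ``gradient``x the ligand-A vectors, except for programmed magnitude
  outliers (displaced along their own direction) and programmed direction
  reversals (sign-flipped), giving exact truth tables for the comparison
  stage;
* **hydrolysis** — a linear early-phase decay of the normalized substrate
  integral.

Bound-state shift magnitudes are drawn log-normally (median =
``bound_shift_scale``), mimicking the heavy right tail of real CSP
profiles, with directions uniform on the circle.  All draws flow from one
integer seed via ``numpy.random.default_rng``; equal seeds give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .binding import IsothermParams, fraction_bound
from .csp import SCALE_X, CSPRecord
from .exceptions import ConfigError
from .kinetics import HydrolysisSeries
from .peaks import Peak, Probe, TitrationPoint, TitrationSeries

__all__ = [
    "SyntheticConfig",
    "TwoLigandConfig",
    "gen_probes",
    "gen_bound_shifts",
    "simulate_fast_titration",
    "simulate_slow_titration",
    "simulate_two_ligand",
    "simulate_hydrolysis",
]

# default study designs: a weak-binding fast-exchange titration at 200 µM
# protein up to 10x ligand, and a tighter slow-exchange titration at 160 µM
# protein up to 16x ligand.
FAST_RATIOS = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 10.0)
SLOW_RATIOS = (0.0, 1.0, 2.0, 4.0, 8.0, 16.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth parameters of one synthetic titration."""

    kd: float = 53.0  # µM
    protein_conc: float | Sequence[float] = 160.0  # µM, scalar or per point
    ratios: Sequence[float] = SLOW_RATIOS
    regime: str = "slow"
    n_probes: int = 30
    bound_shift_scale: float = 0.05  # ppm, median composite shift at saturation
    shift_lognorm_sigma: float = 0.6  # log-sd of the magnitude distribution
    shift_noise_sd_h: float = 0.002  # ppm, additive 1H noise
    shift_noise_sd_x: float = 0.01  # ppm, additive 13C noise
    volume_noise_cv: float = 0.05  # multiplicative log-normal CV
    apo_volume: float = 1.0
    visibility_floor: float = 0.05  # fraction of apo volume below which peaks vanish
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ratios[0] != 0:
            raise ConfigError("ratios must start at 0 (apo point)")
        if any(b <= a for a, b in zip(self.ratios, self.ratios[1:])):
            raise ConfigError("ratios must be strictly increasing")
        if self.n_probes < 1:
            raise ConfigError("n_probes must be >= 1")
        for name in ("shift_noise_sd_h", "shift_noise_sd_x", "volume_noise_cv", "bound_shift_scale"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.regime not in ("fast", "slow"):
            raise ConfigError(f"regime must be 'fast' or 'slow', got {self.regime!r}")

    def conc_at(self, i: int) -> float:
        if np.isscalar(self.protein_conc):
            return float(self.protein_conc)
        return float(self.protein_conc[i])


@dataclass(frozen=True)
class TwoLigandConfig:
    """Parameters of a paired two-ligand CSP endpoint dataset."""

    base: SyntheticConfig = field(default_factory=SyntheticConfig)
    gradient: float = 0.17
    n_outliers: int = 0
    n_reversals: int = 0
    outlier_displacement: float = 0.05  # ppm added to the B magnitude

    def __post_init__(self) -> None:
        if self.n_outliers + self.n_reversals > self.base.n_probes:
            raise ConfigError("programmed outliers + reversals exceed n_probes")


_RESIDUE_TYPES = ("I", "L", "V")


def gen_probes(n_probes: int, rng: np.random.Generator) -> list[Probe]:
    """A deterministic set of ILV methyl probes with plausible numbering."""
    numbers = rng.choice(np.arange(140, 140 + 3 * n_probes), size=n_probes, replace=False)
    numbers.sort()
    probes = []
    for num in numbers:
        rtype = _RESIDUE_TYPES[int(rng.integers(3))]
        site = "" if rtype == "I" else ("a", "b")[int(rng.integers(2))]
        probes.append(Probe(int(num), rtype, site, "C13"))
    return probes


def gen_bound_shifts(config: SyntheticConfig) -> dict[Probe, tuple[float, float]]:
    """Per-probe bound-state shift vectors (ΔδH, ΔδX), deterministic by seed.

    Composite magnitudes are log-normal with median ``bound_shift_scale``;
    directions are uniform on the circle of the scaled-shift plane, then the
    heteronuclear component is divided by s_X so that the *composite* CSP of
    the vector equals the drawn magnitude.
    """
    if config.n_probes == 0:
        raise ConfigError("n_probes must be >= 1")
    rng = np.random.default_rng(config.seed)
    probes = gen_probes(config.n_probes, rng)
    mags = config.bound_shift_scale * np.exp(
        rng.normal(0.0, config.shift_lognorm_sigma, size=config.n_probes)
    )
    if config.bound_shift_scale == 0:
        mags = np.zeros(config.n_probes)
    angles = rng.uniform(0.0, 2 * np.pi, size=config.n_probes)
    out: dict[Probe, tuple[float, float]] = {}
    for probe, mag, theta in zip(probes, mags, angles):
        s = SCALE_X[probe.nucleus]
        d_h = mag * np.cos(theta)
        d_x = mag * np.sin(theta) / s
        out[probe] = (float(d_h), float(d_x))
    return out


def _apo_positions(probes: Sequence[Probe], rng: np.random.Generator) -> dict[Probe, tuple[float, float]]:
    # typical ILV methyl region: 1H ~ 0.2-1.2 ppm, 13C ~ 10-25 ppm
    return {
        p: (float(rng.uniform(0.2, 1.2)), float(rng.uniform(10.0, 25.0))) for p in probes
    }


def simulate_fast_titration(config: SyntheticConfig) -> TitrationSeries:
    """Fast-exchange series: one merged peak per probe moving with f(x)."""
    if config.regime != "fast":
        raise ConfigError("simulate_fast_titration requires regime='fast'")
    shifts = gen_bound_shifts(config)
    probes = list(shifts)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    apo_pos = _apo_positions(probes, rng)
    points: list[TitrationPoint] = []
    for i, x in enumerate(config.ratios):
        conc = config.conc_at(i)
        f = fraction_bound(x, IsothermParams(config.kd, conc)) if x > 0 else 0.0
        peaks = []
        for probe in probes:
            h0, x0 = apo_pos[probe]
            dh, dx = shifts[probe]
            noise_h = rng.normal(0.0, config.shift_noise_sd_h) if config.shift_noise_sd_h else 0.0
            noise_x = rng.normal(0.0, config.shift_noise_sd_x) if config.shift_noise_sd_x else 0.0
            vol = config.apo_volume * _lognorm_factor(rng, config.volume_noise_cv)
            peaks.append(
                Peak(
                    probe=probe,
                    shift_h=h0 + f * dh + noise_h,
                    shift_x=x0 + f * dx + noise_x,
                    volume=vol,
                    volume_rel_err=config.volume_noise_cv,
                    form="free" if x == 0 else "merged",
                )
            )
        points.append(TitrationPoint(ratio_x=x, protein_conc=conc, peaks=peaks))
    return TitrationSeries(
        ligand_name="synthetic-fast",
        points=points,
        regime_hint="fast",
        meta={"kd": config.kd, "bound_shifts": shifts, "config": config},
    )


def _lognorm_factor(rng: np.random.Generator, cv: float) -> float:
    """Multiplicative log-normal noise factor with unit mean and given CV."""
    if cv == 0:
        return 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return float(rng.lognormal(-0.5 * sigma * sigma, sigma))


def simulate_slow_titration(config: SyntheticConfig) -> TitrationSeries:
    """Slow-exchange series: free/bound peak pairs redistributing volume."""
    if config.regime != "slow":
        raise ConfigError("simulate_slow_titration requires regime='slow'")
    shifts = gen_bound_shifts(config)
    probes = list(shifts)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 2)))
    apo_pos = _apo_positions(probes, rng)
    floor = config.visibility_floor * config.apo_volume
    points: list[TitrationPoint] = []
    for i, x in enumerate(config.ratios):
        conc = config.conc_at(i)
        f = fraction_bound(x, IsothermParams(config.kd, conc)) if x > 0 else 0.0
        peaks = []
        for probe in probes:
            h0, x0 = apo_pos[probe]
            dh, dx = shifts[probe]
            v_free = config.apo_volume * (1.0 - f) * _lognorm_factor(rng, config.volume_noise_cv)
            v_bound = config.apo_volume * f * _lognorm_factor(rng, config.volume_noise_cv)
            nh = rng.normal(0.0, config.shift_noise_sd_h) if config.shift_noise_sd_h else 0.0
            nx = rng.normal(0.0, config.shift_noise_sd_x) if config.shift_noise_sd_x else 0.0
            if v_free > floor or x == 0:
                peaks.append(
                    Peak(
                        probe=probe,
                        shift_h=h0 + nh,
                        shift_x=x0 + nx,
                        volume=max(v_free, 0.0),
                        volume_rel_err=config.volume_noise_cv,
                        form="free",
                    )
                )
            if x > 0 and v_bound > floor:
                nh2 = rng.normal(0.0, config.shift_noise_sd_h) if config.shift_noise_sd_h else 0.0
                nx2 = rng.normal(0.0, config.shift_noise_sd_x) if config.shift_noise_sd_x else 0.0
                peaks.append(
                    Peak(
                        probe=probe,
                        shift_h=h0 + dh + nh2,
                        shift_x=x0 + dx + nx2,
                        volume=v_bound,
                        volume_rel_err=config.volume_noise_cv,
                        form="bound",
                    )
                )
        points.append(TitrationPoint(ratio_x=x, protein_conc=conc, peaks=peaks))
    return TitrationSeries(
        ligand_name="synthetic-slow",
        points=points,
        regime_hint="slow",
        meta={"kd": config.kd, "bound_shifts": shifts, "config": config},
    )


@dataclass
class TwoLigandTruth:
    """Programmed ground truth of a synthetic two-ligand dataset."""

    gradient: float
    outliers: list[Probe]
    reversals: list[Probe]
    #: noise-free composite magnitudes of the B-ligand vectors
    true_mag_b: dict[Probe, float] = field(default_factory=dict)

    def detectable_reversals(self, noise_floor: float = 0.005) -> list[Probe]:
        """Programmed reversals whose true B magnitude clears the floor.

        A reversed vector smaller than the noise floor has no measurable
        direction, so the noise-floor rule excludes it from flagging by
        construction.
        """
        return sorted(p for p in self.reversals if self.true_mag_b.get(p, 0.0) > noise_floor)


def simulate_two_ligand(
    config: TwoLigandConfig,
) -> tuple[list[CSPRecord], list[CSPRecord], TwoLigandTruth]:
    """Paired endpoint CSP tables for two ligands sharing a common component.

    Ligand-B vectors are ``gradient`` times the ligand-A vectors except for
    the programmed probes: magnitude outliers are displaced along their own
    direction by ``outlier_displacement`` (alternating sign so outliers fall
    on both sides of the correlation line) and reversal probes have their B
    vector sign-flipped.  Gaussian shift noise is added to both datasets.
    The programmed outlier and reversal sets are disjoint and returned as a
    truth table.
    """
    base = config.base
    shifts_a = gen_bound_shifts(base)
    probes = list(shifts_a)
    rng = np.random.default_rng(np.random.SeedSequence((base.seed, 3)))
    special = rng.choice(len(probes), size=config.n_outliers + config.n_reversals, replace=False)
    outlier_idx = set(special[: config.n_outliers].tolist())
    reversal_idx = set(special[config.n_outliers :].tolist())

    records_a: list[CSPRecord] = []
    records_b: list[CSPRecord] = []
    outliers: list[Probe] = []
    reversals: list[Probe] = []
    true_mag_b: dict[Probe, float] = {}
    for i, probe in enumerate(probes):
        dh_a, dx_a = shifts_a[probe]
        dh_b, dx_b = config.gradient * dh_a, config.gradient * dx_a
        if i in outlier_idx:
            s = SCALE_X[probe.nucleus]
            mag = float(np.hypot(dh_a, s * dx_a))
            sign = 1.0 if len(outliers) % 2 == 0 else -1.0
            if mag > 0 and config.gradient > 0:
                # displace the B magnitude along its own direction; alternate
                # sign so outliers fall on both sides of the line, but go
                # downward only when the full displacement fits above the
                # direction noise floor (a fold through zero would scramble
                # the programmed direction)
                if sign < 0 and config.gradient * mag - config.outlier_displacement <= 0.005:
                    sign = 1.0
                target = config.gradient * mag + sign * config.outlier_displacement
                factor = target / (config.gradient * mag)
                dh_b, dx_b = factor * dh_b, factor * dx_b
            else:
                dh_b += config.outlier_displacement
            outliers.append(probe)
        if i in reversal_idx:
            dh_b, dx_b = -dh_b, -dx_b
            reversals.append(probe)
        true_mag_b[probe] = float(np.hypot(dh_b, SCALE_X[probe.nucleus] * dx_b))
        nh_a = rng.normal(0.0, base.shift_noise_sd_h) if base.shift_noise_sd_h else 0.0
        nx_a = rng.normal(0.0, base.shift_noise_sd_x) if base.shift_noise_sd_x else 0.0
        nh_b = rng.normal(0.0, base.shift_noise_sd_h) if base.shift_noise_sd_h else 0.0
        nx_b = rng.normal(0.0, base.shift_noise_sd_x) if base.shift_noise_sd_x else 0.0
        records_a.append(CSPRecord.from_shifts(probe, dh_a + nh_a, dx_a + nx_a))
        records_b.append(CSPRecord.from_shifts(probe, dh_b + nh_b, dx_b + nx_b))
    truth = TwoLigandTruth(
        gradient=config.gradient,
        outliers=sorted(outliers),
        reversals=sorted(reversals),
        true_mag_b=true_mag_b,
    )
    return records_a, records_b, truth


def simulate_hydrolysis(
    rate: float,
    enzyme_conc: float,
    substrate_conc0: float,
    times: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> HydrolysisSeries:
    """Linear early-phase substrate decay with additive Gaussian noise.

    ``atp_fraction(t) = 1 - rate*enzyme*t/substrate`` (floored at 0); the
    time-zero point is kept noise-free so the series stays normalized.
    """
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    frac = 1.0 - rate * enzyme_conc * times / substrate_conc0
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=times.size)
        noise[0] = 0.0
        frac = frac + noise
    frac = np.maximum(frac, 0.0)
    frac[0] = 1.0
    return HydrolysisSeries(
        times=times, atp_fraction=frac, enzyme_conc=enzyme_conc, substrate_conc0=substrate_conc0
    )
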