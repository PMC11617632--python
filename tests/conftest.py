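import numpy as np
import pytest

from cspfit import (
    Peak,
    Probe,
    SyntheticConfig,
    TitrationPoint,
    TitrationSeries,
    simulate_fast_titration,
    simulate_slow_titration,
)

# canonical noiseless configs used across modules: a weak fast-exchange
# titration (mM-range K_D at 200 µM protein) and a tighter slow-exchange one
# (high-µM K_D at 160 µM protein, titrated to saturation)
FAST_KD, FAST_CONC = 1600.0, 200.0
SLOW_KD, SLOW_CONC = 53.0, 160.0


@pytest.fixture
def noiseless_fast_config():
    return SyntheticConfig(
        kd=FAST_KD,
        protein_conc=FAST_CONC,
        ratios=(0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 10.0),
        regime="fast",
        n_probes=6,
        bound_shift_scale=0.12,
        shift_noise_sd_h=0.0,
        shift_noise_sd_x=0.0,
        volume_noise_cv=0.0,
        seed=7,
    )


@pytest.fixture
def noiseless_slow_config():
    # final ratio chosen high enough that the endpoint is effectively
    # saturated, which the bound-volume normalization assumes
    return SyntheticConfig(
        kd=SLOW_KD,
        protein_conc=SLOW_CONC,
        ratios=(0.0, 1.0, 2.0, 4.0, 8.0, 16.0),
        regime="slow",
        n_probes=6,
        shift_noise_sd_h=0.0,
        shift_noise_sd_x=0.0,
        volume_noise_cv=0.0,
        seed=7,
    )


@pytest.fixture
def fast_series(noiseless_fast_config):
    return simulate_fast_titration(noiseless_fast_config)


@pytest.fixture
def slow_series(noiseless_slow_config):
    return simulate_slow_titration(noiseless_slow_config)


def make_probe(pid="V195", nucleus="C13"):
    from cspfit import parse_probe_id

    return parse_probe_id(pid, nucleus)


@pytest.fixture
def tiny_series():
    """Hand-built two-point fast-exchange series for I/O tests."""
    p1, p2 = make_probe("V195"), make_probe("L220a")
    apo = TitrationPoint(
        0.0,
        160.0,
        [
            Peak(p1, 0.80, 21.0, 1.0, 0.05, "free"),
            Peak(p2, 0.55, 23.5, 1.0, 0.05, "free"),
        ],
    )
    pt = TitrationPoint(
        4.0,
        160.0,
        [
            Peak(p1, 0.90, 21.5, 1.0, 0.05, "merged"),
            Peak(p2, 0.56, 23.4, 1.0, 0.05, "merged"),
        ],
    )
    return TitrationSeries("ADP", [apo, pt], regime_hint="fast")


def mass_action_fraction(x, kd, pt):
    """Independent oracle: solve mass action for [PL] by bisection."""
    from scipy.optimize import brentq

    if x == 0:
        return 0.0
    lt = x * pt

    def balance(pl):
        return (pt - pl) * (lt - pl) - kd * pl

    hi = min(pt, lt)
    return brentq(balance, 0.0, hi, xtol=1e-15, rtol=8.9e-16) / pt
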