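"""Binding isotherm, K_D extraction in both regimes, aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cspfit import (
    IsothermParams,
    Peak,
    TitrationPoint,
    aggregate_kd,
    estimate_fractions_slow,
    expected_saturation_gradient,
    fit_fast_exchange,
    fit_slow_exchange,
    fraction_bound,
    parse_probe_id,
)
from cspfit.exceptions import (
    DataError,
    InsufficientDataError,
    UnidentifiableKdError,
)
from conftest import mass_action_fraction


class TestFractionBound:
    def test_zero_ratio_gives_zero(self):
        assert fraction_bound(0.0, IsothermParams(100, 100)) == 0.0

    def test_stoichiometric_limit(self):
        tight = IsothermParams(1e-9, 100.0)
        assert fraction_bound(0.5, tight) == pytest.approx(0.5, abs=1e-6)
        assert fraction_bound(2.0, tight) == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize(
        "kd,pt,x,expected",
        [(1600, 500, 20, 0.857), (53, 160, 4, 0.903)],
    )
    def test_reference_points_vs_oracle(self, kd, pt, x, expected):
        f = fraction_bound(x, IsothermParams(kd, pt))
        assert f == pytest.approx(expected, abs=5e-4)
        assert f == pytest.approx(mass_action_fraction(x, kd, pt), abs=1e-10)

    @given(
        kd=st.floats(1e-2, 1e6),
        pt=st.floats(1.0, 2000.0),
        x=st.floats(1e-3, 100.0),
    )
    @settings(derandomize=True, max_examples=300)
    def test_matches_mass_action_solver(self, kd, pt, x):
        assert fraction_bound(x, IsothermParams(kd, pt)) == pytest.approx(
            mass_action_fraction(x, kd, pt), abs=1e-9
        )

    def test_monotonicity_and_limits(self):
        params = IsothermParams(300, 200)
        xs = np.linspace(0, 30, 200)
        fs = fraction_bound(xs, params)
        assert np.all(np.diff(fs) > 0)
        assert np.all((fs >= 0) & (fs <= 1))
        # decreasing in K_D
        assert fraction_bound(2.0, IsothermParams(10, 200)) > fraction_bound(
            2.0, IsothermParams(1000, 200)
        )
        # K_D -> 0: f -> min(x, 1); K_D -> inf: f -> x*PT/KD
        assert fraction_bound(0.7, IsothermParams(1e-8, 200)) == pytest.approx(0.7, abs=1e-5)
        huge = IsothermParams(1e9, 200)
        assert fraction_bound(3.0, huge) == pytest.approx(3.0 * 200 / 1e9, rel=1e-3)

    def test_negative_ratio_rejected(self):
        with pytest.raises(DataError):
            fraction_bound(-1.0, IsothermParams(100, 100))


class TestFastExchangeFit:
    def _data(self, kd, pt, d_max, xs):
        params = IsothermParams(kd, pt)
        return [(x, d_max * fraction_bound(x, params)) for x in xs]

    def test_noiseless_round_trip(self):
        data = self._data(1600, 200, 0.12, (0, 0.5, 1, 2, 4, 8, 10))
        fit = fit_fast_exchange(data, 200)
        assert fit.kd == pytest.approx(1600, rel=1e-6)
        assert fit.d_max == pytest.approx(0.12, rel=1e-6)
        assert fit.residual_rms < 1e-10

    def test_tight_binding_limit(self):
        tight = IsothermParams(1e-9, 200.0)
        data = [(x, 0.1 * fraction_bound(x, tight)) for x in (0, 0.25, 0.5, 0.75, 2, 4)]
        fit = fit_fast_exchange(data, 200)
        assert fit.kd < 1e-3 * 200

    def test_two_points_insufficient(self):
        with pytest.raises(InsufficientDataError):
            fit_fast_exchange([(0, 0), (1, 0.05), (2, 0.08)], 200)


def _slow_point(x, conc, fractions, rel_err=0.05, v0=1.0, fmax=None):
    """Build a slow-exchange TitrationPoint from per-probe bound fractions."""
    peaks = []
    for pid, f in fractions.items():
        probe = parse_probe_id(pid)
        if 1 - f > 0:
            peaks.append(Peak(probe, 0.8, 21.0, v0 * (1 - f), rel_err, "free"))
        if x > 0 and f > 0:
            peaks.append(Peak(probe, 0.9, 21.5, v0 * (fmax if fmax is not None else f), rel_err, "bound"))
    return TitrationPoint(x, conc, peaks)


class TestSlowFractions:
    def test_mean_of_both_routes(self):
        probe = parse_probe_id("V195")
        apo = TitrationPoint(0, 160, [Peak(probe, 0.8, 21.0, 1.0, 0.05, "free")])
        point = TitrationPoint(
            2,
            160,
            [
                Peak(probe, 0.8, 21.0, 0.6, 0.05, "free"),
                Peak(probe, 0.9, 21.5, 0.42, 0.08, "bound"),
            ],
        )
        max_point = TitrationPoint(
            16, 160, [Peak(probe, 0.9, 21.5, 1.0, 0.05, "bound")]
        )
        (est,) = estimate_fractions_slow(point, apo, max_point, rel_err_threshold=0.20)
        assert est.f_from_free == pytest.approx(0.40)
        assert est.f_from_bound == pytest.approx(0.42)
        assert est.f_combined == pytest.approx(0.41)
        assert est.sources == ("free", "bound")

    def test_single_available_value_when_route_fails_threshold(self):
        probe = parse_probe_id("V195")
        apo = TitrationPoint(0, 160, [Peak(probe, 0.8, 21.0, 1.0, 0.05, "free")])
        point = TitrationPoint(
            2,
            160,
            [
                Peak(probe, 0.8, 21.0, 0.6, 0.05, "free"),
                Peak(probe, 0.9, 21.5, 0.42, 0.40, "bound"),  # 40% error fails
            ],
        )
        max_point = TitrationPoint(16, 160, [Peak(probe, 0.9, 21.5, 1.0, 0.05, "bound")])
        (est,) = estimate_fractions_slow(point, apo, max_point, rel_err_threshold=0.20)
        assert est.f_from_bound is None
        assert est.f_combined == pytest.approx(0.40)
        assert est.sources == ("free",)

    def test_apo_point_is_zero(self):
        probe = parse_probe_id("V195")
        apo = TitrationPoint(0, 160, [Peak(probe, 0.8, 21.0, 1.0, 0.05, "free")])
        (est,) = estimate_fractions_slow(apo, apo, apo, 0.2)
        assert est.f_combined == 0.0

    def test_implausible_estimate_discarded(self):
        probe = parse_probe_id("V195")
        apo = TitrationPoint(0, 160, [Peak(probe, 0.8, 21.0, 1.0, 0.05, "free")])
        point = TitrationPoint(
            2, 160, [Peak(probe, 0.9, 21.5, 1.5, 0.05, "bound")]
        )
        max_point = TitrationPoint(16, 160, [Peak(probe, 0.9, 21.5, 1.0, 0.05, "bound")])
        (est,) = estimate_fractions_slow(point, apo, max_point, 0.2)
        assert est.f_from_bound is None  # 1.5 > 1.05 is unphysical
        assert any(f.code == "implausible_fraction" for f in est.findings)


class TestSlowExchangeFit:
    def test_noiseless_round_trip(self):
        params = IsothermParams(53, 160)
        data = [(x, fraction_bound(x, params)) for x in (1, 2, 4, 8, 16)]
        fit = fit_slow_exchange(data, 160)
        assert fit.kd == pytest.approx(53, rel=1e-6)

    def test_all_saturated_unidentifiable(self):
        with pytest.raises(UnidentifiableKdError):
            fit_slow_exchange([(1, 1.0), (2, 1.0), (4, 1.0)], 160)

    def test_tight_binding_limit(self):
        tight = IsothermParams(1e-9, 160.0)
        data = [(x, fraction_bound(x, tight)) for x in (0.25, 0.5, 0.75, 2)]
        fit = fit_slow_exchange(data, 160)
        assert fit.kd < 1e-3 * 160

    def test_agrees_with_fast_encoding_of_same_isotherm(self):
        """Both fit routes see the same f(x); fitted K_D must agree < 2%."""
        params = IsothermParams(300, 200)
        xs = (0.5, 1, 2, 4, 8, 16)
        fs = [fraction_bound(x, params) for x in xs]
        slow = fit_slow_exchange(list(zip(xs, fs)), 200)
        fast = fit_fast_exchange([(0, 0)] + [(x, 0.1 * f) for x, f in zip(xs, fs)], 200)
        assert slow.kd == pytest.approx(fast.kd, rel=0.02)


class TestAggregateKd:
    def test_mean_and_sample_sd(self):
        probes = [parse_probe_id(p) for p in ("V195", "L220a", "I352")]
        summary = aggregate_kd(list(zip(probes, [40.0, 55.0, 64.0])), "all", "ADP")
        assert summary.mean_kd == pytest.approx(53.0)
        assert summary.sd_kd == pytest.approx(12.124, abs=1e-3)
        assert summary.selection_rule == "all"

    def test_single_probe_sd_zero_with_warning(self):
        with pytest.warns(UserWarning):
            summary = aggregate_kd([(parse_probe_id("V195"), 42.0)], "all")
        assert summary.mean_kd == 42.0
        assert summary.sd_kd == 0.0
        assert summary.warnings

    def test_empty_selection_errors(self):
        with pytest.raises(DataError):
            aggregate_kd([], "all")


class TestSaturationGradient:
    def test_identical_conditions_give_unity(self):
        p = IsothermParams(100, 200)
        assert expected_saturation_gradient(p, 4, p, 4) == pytest.approx(1.0)

    def test_atp_side_with_saturated_adp(self):
        atp = IsothermParams(1600, 500)
        adp = IsothermParams(53, 160)
        g = expected_saturation_gradient(adp, 8, atp, 20, assume_a_saturated=True)
        assert g == pytest.approx(0.857, abs=1e-3)

    def test_exact_adp_side(self):
        atp = IsothermParams(1600, 500)
        adp = IsothermParams(53, 160)
        f_adp = fraction_bound(8, adp)
        assert f_adp == pytest.approx(0.955, abs=1e-3)
        g = expected_saturation_gradient(adp, 8, atp, 20)
        assert g == pytest.approx(0.897, abs=1e-3)
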