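"""Composite CSP math, trimmed statistics, classification, intensity screen."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cspfit import (
    Peak,
    compute_csp,
    classify_probes,
    csp_profile,
    intensity_ratio_screen,
    parse_probe_id,
    simulate_fast_titration,
    trimmed_stats,
)
from cspfit.csp import CSPRecord
from cspfit.exceptions import ConfigError, DataError

finite = st.floats(-5, 5, allow_nan=False)


class TestComputeCsp:
    @pytest.mark.parametrize(
        "d_h,d_x,nucleus,expected",
        [
            (0.0, 0.0, "C13", 0.0),
            (0.0, 1.0, "N15", 0.15),
            (0.1, 0.5, "C13", math.sqrt(0.01 + (0.18 * 0.5) ** 2)),
            (0.1, 0.0, "C13", 0.1),
        ],
    )
    def test_values(self, d_h, d_x, nucleus, expected):
        assert compute_csp(d_h, d_x, nucleus) == pytest.approx(expected, abs=1e-12)

    def test_unknown_nucleus(self):
        with pytest.raises(ConfigError):
            compute_csp(0.1, 0.1, "P31")

    @given(d_h=finite, d_x=finite, scale=st.floats(0.01, 10))
    @settings(derandomize=True, max_examples=100)
    def test_is_a_norm(self, d_h, d_x, scale):
        """Nonnegative, sign-symmetric, homogeneous of degree one."""
        v = compute_csp(d_h, d_x, "C13")
        assert v >= 0
        assert compute_csp(-d_h, d_x, "C13") == pytest.approx(v)
        assert compute_csp(d_h, -d_x, "C13") == pytest.approx(v)
        assert compute_csp(scale * d_h, scale * d_x, "C13") == pytest.approx(
            scale * v, rel=1e-9, abs=1e-12
        )
        if v == 0:
            assert d_h == 0 and d_x == 0


class TestCspProfile:
    def test_identical_points_give_zero_csp(self, tiny_series):
        from cspfit import TitrationPoint, TitrationSeries

        apo = tiny_series.apo
        clone = TitrationPoint(
            2.0,
            apo.protein_conc,
            [Peak(p.probe, p.shift_h, p.shift_x, p.volume, p.volume_rel_err, "merged") for p in apo.peaks],
        )
        series = TitrationSeries("X", [apo, clone])
        profile = csp_profile(series)
        assert all(rec.composite == 0 for rec in profile.at(2.0))

    def test_saturation_endpoint_matches_bound_shift(self, noiseless_fast_config):
        """At f(x)->1 the composite CSP equals the bound-state magnitude."""
        from dataclasses import replace
        from cspfit import gen_bound_shifts

        config = replace(noiseless_fast_config, kd=1e-6, ratios=(0.0, 1.0, 2.0, 4.0))
        series = simulate_fast_titration(config)
        shifts = gen_bound_shifts(config)
        endpoint = {r.probe: r for r in csp_profile(series).endpoint()}
        for probe, (dh, dx) in shifts.items():
            expected = compute_csp(dh, dx, probe.nucleus)
            assert endpoint[probe].composite == pytest.approx(expected, rel=1e-6)

    def test_fraction_scaling_of_fast_series(self, fast_series, noiseless_fast_config):
        """Composite CSP at x equals f(x) x the saturation composite (no noise)."""
        from cspfit import IsothermParams, fraction_bound, gen_bound_shifts

        shifts = gen_bound_shifts(noiseless_fast_config)
        params = IsothermParams(noiseless_fast_config.kd, noiseless_fast_config.protein_conc)
        profile = csp_profile(fast_series)
        for x, records in profile.records.items():
            f = fraction_bound(x, params)
            for rec in records:
                dh, dx = shifts[rec.probe]
                assert rec.composite == pytest.approx(f * compute_csp(dh, dx, "C13"), abs=1e-12)

    def test_dropped_probe_recorded_as_gap(self, tiny_series):
        from cspfit import TitrationPoint, TitrationSeries

        pt = tiny_series.points[1]
        reduced = TitrationPoint(8.0, pt.protein_conc, pt.peaks[:1])
        series = TitrationSeries("X", [tiny_series.apo, pt, reduced])
        profile = csp_profile(series)
        assert any(g.ratio_x == 8.0 and g.probe.probe_id == "L220a" for g in profile.gaps)

    def test_missing_reference_errors(self, tiny_series):
        with pytest.raises(DataError):
            csp_profile(tiny_series, reference_x=3.0)


class TestTrimmedStats:
    def test_constant_list(self):
        assert trimmed_stats([5, 5, 5, 5], 0.10) == (5.0, 0.0)

    def test_one_value_trimmed_per_tail(self):
        mean, sd = trimmed_stats([0, 1, 2, 3, 4, 5, 6, 7, 8, 100], 0.10)
        assert mean == pytest.approx(4.5)
        assert sd == pytest.approx(math.sqrt(6.0))  # sample SD of 1..8

    def test_zero_trim_is_plain_mean_sd(self):
        values = [1.0, 2.0, 4.0]
        mean, sd = trimmed_stats(values, 0.0)
        assert mean == pytest.approx(np.mean(values))
        assert sd == pytest.approx(np.std(values, ddof=1))

    def test_empty_list_errors(self):
        with pytest.raises(DataError):
            trimmed_stats([], 0.1)


class TestClassification:
    def _records(self, spec):
        # spec: list of (residue_number, site, composite)
        records = []
        for num, site, comp in spec:
            probe = parse_probe_id(f"L{num}{site}")
            records.append(CSPRecord(probe, comp, 0.0, 0.18, comp))
        return records

    def test_threshold_logic_and_at_least_one_rule(self):
        mean, sd = 0.05, 0.02
        records = self._records(
            [
                (200, "a", 0.049), (200, "b", 0.049),  # baseline
                (201, "a", 0.06), (201, "b", 0.01),    # above mean via one methyl
                (202, "a", 0.049), (202, "b", 0.08),   # above mean + sd via one methyl
            ]
        )
        result = classify_probes(records, (mean, sd))
        assert result.categories[200] == "baseline"
        assert result.categories[201] == "above_mean"
        assert result.categories[202] == "above_mean_plus_sd"

    def test_order_invariance_and_category_nesting(self):
        rng = np.random.default_rng(5)
        spec = [(n, s, float(rng.lognormal(-3, 0.8))) for n in range(140, 170) for s in ("a", "b")]
        records = self._records(spec)
        stats = trimmed_stats([r.composite for r in records], 0.10)
        forward = classify_probes(records, stats)
        backward = classify_probes(list(reversed(records)), stats)
        assert forward.categories == backward.categories
        # every above_mean_plus_sd residue also satisfies the above_mean criterion
        mean, sd = stats
        for res in forward.residues("above_mean_plus_sd"):
            best = max(r.composite for r in records if r.probe.residue_number == res)
            assert best > mean


class TestIntensityRatioScreen:
    def _peaks(self, volumes):
        return [
            Peak(parse_probe_id(f"I{200 + i}"), 0.5, 12.0, v, 0.05, "free")
            for i, v in enumerate(volumes)
        ]

    def test_identical_lists_no_flags(self):
        peaks = self._peaks([1.0, 2.0, 3.0])
        screen = intensity_ratio_screen(peaks, peaks, flag_margin=0.2)
        assert screen.median_ratio == 1.0
        assert all(r == 1.0 for r in screen.ratios.values())
        assert screen.flagged == []

    def test_uniform_dilution_with_one_extra_drop(self):
        a = self._peaks([1.0] * 9 + [1.0])
        b_vols = [0.9] * 9 + [0.5]
        b = self._peaks(b_vols)
        screen = intensity_ratio_screen(a, b, flag_margin=0.2)
        assert screen.median_ratio == pytest.approx(0.9)
        assert [p.probe_id for p in screen.flagged] == ["I209"]

    def test_zero_denominator_excluded_with_finding(self):
        a = self._peaks([0.0, 1.0, 1.0])
        b = self._peaks([1.0, 1.0, 1.0])
        screen = intensity_ratio_screen(a, b, flag_margin=0.2)
        assert len(screen.findings) == 1
        assert len(screen.ratios) == 2

    def test_disjoint_probe_sets_error(self):
        a = self._peaks([1.0])
        b = [Peak(parse_probe_id("V300"), 0.5, 12.0, 1.0, 0.05, "free")]
        with pytest.raises(DataError):
            intensity_ratio_screen(a, b)
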