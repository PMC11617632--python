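"""Peak-list parsing, manifest loading, validation and report writing."""

import textwrap

import pytest

from cspfit import (
    Peak,
    Probe,
    TitrationPoint,
    TitrationSeries,
    parse_probe_id,
    read_peak_list,
    read_titration_manifest,
    validate_series,
    write_peak_list,
    write_report,
)
from cspfit.exceptions import (
    DuplicatePeakError,
    ManifestError,
    PeakListFormatError,
)

HEADER = "probe_id\tresidue_number\tresidue_type\tsite_label\tnucleus\tshift_h\tshift_x\tvolume\tvolume_rel_err\tform"


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(textwrap.dedent(text))
    return path


class TestProbe:
    @pytest.mark.parametrize(
        "pid,num,rtype,site",
        [("V195", 195, "V", ""), ("L220a", 220, "L", "a"), ("I352", 352, "I", "")],
    )
    def test_parse_canonical_ids(self, pid, num, rtype, site):
        probe = parse_probe_id(pid)
        assert (probe.residue_number, probe.residue_type, probe.site_label) == (num, rtype, site)
        assert probe.probe_id == pid

    def test_site_label_restricted_to_leu_val(self):
        with pytest.raises(ValueError):
            Probe(100, "I", "a")

    def test_bad_id_rejected(self):
        with pytest.raises(PeakListFormatError):
            parse_probe_id("195V")


class TestReadPeakList:
    def test_tabular_rows_parsed_in_order(self, tmp_path):
        path = _write(
            tmp_path,
            "p.tsv",
            f"""\
            {HEADER}
            V195\t195\tV\t\tC13\t0.8\t21.0\t1.5\t0.05\tfree
            L220a\t220\tL\ta\tC13\t0.55\t23.5\t1.2\t0.08\tfree
            I352\t352\tI\t\tC13\t0.3\t12.1\t0.9\t0.02\tbound
            """,
        )
        peaks = read_peak_list(path)
        assert [p.probe.probe_id for p in peaks] == ["V195", "L220a", "I352"]
        assert peaks[0].shift_h == 0.8
        assert peaks[2].form == "bound"

    def test_header_only_gives_empty_list(self, tmp_path):
        path = _write(tmp_path, "empty.tsv", HEADER + "\n")
        assert read_peak_list(path) == []

    def test_missing_column_named_in_error(self, tmp_path):
        path = _write(tmp_path, "bad.tsv", "probe_id\tshift_h\nV195\t0.8\n")
        with pytest.raises(PeakListFormatError, match="residue_number"):
            read_peak_list(path)

    def test_non_numeric_value_reports_line(self, tmp_path):
        path = _write(
            tmp_path,
            "bad.tsv",
            f"{HEADER}\nV195\t195\tV\t\tC13\tnot_a_number\t21.0\t1.0\t0.05\tfree\n",
        )
        with pytest.raises(PeakListFormatError, match=":2"):
            read_peak_list(path)

    def test_duplicate_probe_form_rejected(self, tmp_path):
        row = "L220a\t220\tL\ta\tC13\t0.55\t23.5\t1.0\t0.05\tfree"
        path = _write(tmp_path, "dup.tsv", f"{HEADER}\n{row}\n{row}\n")
        with pytest.raises(DuplicatePeakError):
            read_peak_list(path)

    def test_sparky_import(self, tmp_path):
        path = _write(
            tmp_path,
            "s.list",
            """\
            Assignment  w1  w2  Data Height
            V195a-HG1  21.03  0.81  153000
            L220b-QD2  23.51  0.56  98000
            """,
        )
        peaks = read_peak_list(path, dialect="sparky", default_rel_err=0.12)
        assert [p.probe.probe_id for p in peaks] == ["V195a", "L220b"]
        assert peaks[0].shift_x == 21.03 and peaks[0].shift_h == 0.81
        assert peaks[0].volume == 153000
        assert peaks[0].volume_rel_err == 0.12

    def test_round_trip_preserves_fields(self, tmp_path, slow_series):
        peaks = slow_series.points[2].peaks
        path = tmp_path / "rt.tsv"
        write_peak_list(peaks, path)
        back = read_peak_list(path)
        assert len(back) == len(peaks)
        for orig, new in zip(peaks, back):
            assert new.probe == orig.probe
            assert new.form == orig.form
            assert new.shift_h == pytest.approx(orig.shift_h, rel=1e-5)
            assert new.volume == pytest.approx(orig.volume, rel=1e-5)


class TestManifest:
    def _manifest(self, tmp_path, ratios):
        lines = ["ligand: ADP", "points:"]
        for x in ratios:
            name = f"x{x:g}.tsv"
            form = "free" if x == 0 else "bound"
            _write(
                tmp_path,
                name,
                f"{HEADER}\nV195\t195\tV\t\tC13\t0.8\t21.0\t1.0\t0.05\tfree\n"
                + (f"I352\t352\tI\t\tC13\t0.3\t12.1\t0.5\t0.05\t{form}\n" if x > 0 else ""),
            )
            lines.append(f"  - {{ratio_x: {x}, protein_conc_uM: 160, peaks: {name}}}")
        return _write(tmp_path, "manifest.yaml", "\n".join(lines) + "\n")

    def test_points_sorted_ascending(self, tmp_path):
        path = self._manifest(tmp_path, [4, 0, 1, 8, 2])
        series = read_titration_manifest(path)
        assert series.ratios == [0, 1, 2, 4, 8]
        assert series.ligand_name == "ADP"

    def test_missing_apo_point_rejected(self, tmp_path):
        path = self._manifest(tmp_path, [1, 2, 4])
        with pytest.raises(ManifestError):
            read_titration_manifest(path)

    def test_dangling_peak_path_named(self, tmp_path):
        _write(tmp_path, "m.yaml", "ligand: X\npoints:\n  - {ratio_x: 0, protein_conc_uM: 100, peaks: nope.tsv}\n")
        with pytest.raises(FileNotFoundError, match="nope.tsv"):
            read_titration_manifest(tmp_path / "m.yaml")


class TestValidateSeries:
    def test_clean_synthetic_series_has_no_findings(self, fast_series, slow_series):
        assert validate_series(fast_series) == []
        assert validate_series(slow_series) == []

    def test_bound_form_at_apo_flagged(self, tiny_series):
        probe = tiny_series.apo.peaks[0].probe
        bad_apo = TitrationPoint(
            0.0, 160.0, [Peak(probe, 0.8, 21.0, 1.0, 0.05, "bound")]
        )
        series = TitrationSeries("X", [bad_apo, tiny_series.points[1]])
        codes = {f.code for f in validate_series(series)}
        assert "bound_at_apo" in codes

    def test_probe_dropout_flagged(self, tiny_series):
        # keep only one of the two apo probes at the titration point
        pt = tiny_series.points[1]
        reduced = TitrationPoint(pt.ratio_x, pt.protein_conc, pt.peaks[:1])
        series = TitrationSeries("X", [tiny_series.apo, reduced])
        findings = validate_series(series)
        assert any(f.code == "probe_dropout" and f.probe.probe_id == "L220a" for f in findings)


class TestWriteReport:
    def test_deterministic_and_sorted(self, tmp_path):
        records = [
            {"probe": "V236", "residue_number": 236, "site_label": "", "kd_uM": 55.12345678},
            {"probe": "L220a", "residue_number": 220, "site_label": "a", "kd_uM": 40.0},
        ]
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_report(records, p1)
        write_report(list(reversed(records)), p2)
        assert p1.read_bytes() == p2.read_bytes()
        lines = p1.read_text().splitlines()
        assert lines[0] == "probe\tresidue_number\tsite_label\tkd_uM"
        assert lines[1].startswith("L220a")
        assert "55.1235" in lines[2]  # 6 significant digits

    def test_empty_frame_writes_header_only(self, tmp_path):
        import pandas as pd

        path = tmp_path / "empty.tsv"
        write_report(pd.DataFrame(columns=["probe", "kd_uM"]), path)
        assert path.read_text() == "probe\tkd_uM\n"
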