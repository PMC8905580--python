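"""Spectrum reading, referencing and integration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pepagg.nmr.io import (IntegralRecord, ReferencingError, RegionDefinition,
                           SeriesTable, SpectrumParseError, integrate_region,
                           load_series, read_jcampdx, read_regions_config,
                           read_spectrum, reference_spectrum, write_spectrum)
from pepagg.nmr.io import Spectrum
from pepagg.synth.nmr import NmrSeriesConfig, generate_nmr_series, lorentzian


def make_lorentzian_spectrum(center=5.0, area=1.0, fwhm=0.02, n=4096,
                             lo=0.0, hi=10.0, **meta):
    x = np.linspace(lo, hi, n)
    return Spectrum(x, lorentzian(x, center, area, fwhm), **meta)


class TestReadSpectrum:
    def test_three_column_file_names_offending_line(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("1.0 2.0\n2.0 3.0 4.0\n")
        with pytest.raises(SpectrumParseError, match="line 2"):
            read_spectrum(p)

    def test_non_numeric_row_names_line(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("1.0 2.0\nppm intensity\n")
        with pytest.raises(SpectrumParseError, match="line 2"):
            read_spectrum(p)

    def test_too_few_points_rejected(self, tmp_path):
        p = tmp_path / "short.txt"
        p.write_text("\n".join(f"{i} 1.0" for i in range(10)))
        with pytest.raises(SpectrumParseError, match="16"):
            read_spectrum(p)

    def test_ascending_input_stored_descending_same_values(self, tmp_path):
        x = np.linspace(0, 10, 32)
        y = np.arange(32, dtype=float)
        p = tmp_path / "asc.txt"
        p.write_text("\n".join(f"{a} {b}" for a, b in zip(x, y)))
        s = read_spectrum(p)
        assert s.ppm[0] > s.ppm[-1]
        np.testing.assert_array_equal(s.ppm, x[::-1])
        np.testing.assert_array_equal(s.intensity, y[::-1])

    def test_comments_and_commas_accepted(self, tmp_path):
        x = np.linspace(0, 1, 20)
        body = "# header\n" + "\n".join(f"{a},{a * 2}" for a in x)
        p = tmp_path / "csvish.txt"
        p.write_text(body)
        s = read_spectrum(p)
        assert s.ppm.size == 20

    def test_write_read_round_trip_bit_identical(self, tmp_path):
        s = make_lorentzian_spectrum(center=0.74, area=0.3, fwhm=0.015,
                                     label="rt", concentration=1.0)
        p = tmp_path / "rt.txt"
        write_spectrum(s, p)
        back = read_spectrum(p, label="rt", concentration=1.0)
        np.testing.assert_array_equal(back.ppm, s.ppm)
        np.testing.assert_array_equal(back.intensity, s.intensity)


class TestJcampDx:
    def test_affn_xydata_matches_plain_text(self, tmp_path):
        x = np.linspace(0.0, 10.0, 64)
        y = lorentzian(x, 5.0, 1.0, 0.5)
        lines = ["##TITLE=synthetic", "##XUNITS=PPM",
                 f"##FIRSTX={x[0]}", f"##LASTX={x[-1]}",
                 f"##NPOINTS={x.size}", "##XFACTOR=1", "##YFACTOR=1",
                 "##XYDATA=(X++(Y..Y))"]
        for i in range(0, x.size, 8):
            row = [f"{x[i]:.10f}"] + [f"{v:.10f}" for v in y[i:i + 8]]
            lines.append(" ".join(row))
        lines.append("##END=")
        p = tmp_path / "sample.jdx"
        p.write_text("\n".join(lines))
        s = read_jcampdx(p)
        np.testing.assert_allclose(np.sort(s.ppm), x, atol=1e-8)
        np.testing.assert_allclose(s.intensity[::-1], y, atol=1e-8)


class TestReferencing:
    def test_apex_moved_to_target(self):
        s = make_lorentzian_spectrum(center=0.74, fwhm=0.02)
        out = reference_spectrum(s, 0.6, 0.9, target=0.7)
        apex = out.ppm[np.argmax(out.intensity)]
        assert apex == pytest.approx(0.7, abs=1e-9)
        np.testing.assert_array_equal(out.intensity, s.intensity)

    def test_apex_already_at_target_is_identity(self):
        x = np.linspace(0, 2, 512)
        s = Spectrum(x, lorentzian(x, x[180], 1.0, 0.02))
        out = reference_spectrum(s, 0.5, 0.9, target=float(x[180]))
        np.testing.assert_array_equal(out.ppm, s.ppm)

    def test_tie_broken_toward_lowest_ppm(self):
        x = np.linspace(0, 2, 1001)
        y = np.zeros_like(x)
        y[300] = 1.0  # apex at 0.6
        y[400] = 1.0  # equal apex at 0.8
        s = Spectrum(x, y)
        out = reference_spectrum(s, 0.5, 0.9, target=0.7)
        # both candidate shifts enumerated: choosing the lowest-ppm apex
        # moves 0.6 -> 0.7, i.e. axis shifted by +0.1
        assert out.ppm.max() == pytest.approx(s.ppm.max() + 0.1)

    def test_all_zero_window_raises(self):
        x = np.linspace(0, 2, 64)
        s = Spectrum(x, np.zeros_like(x))
        with pytest.raises(ReferencingError):
            reference_spectrum(s, 0.5, 0.9)


class TestIntegration:
    def test_zero_spectrum_integrates_to_zero(self):
        x = np.linspace(0, 10, 256)
        s = Spectrum(x, np.zeros_like(x))
        rec = integrate_region(s, RegionDefinition("r", 2.0, 3.0))
        assert rec.int_c == 0.0
        assert rec.i_max == 0.0

    def test_lorentzian_area_near_closed_form(self):
        # unit height: area = pi*w*I_max/2; compare on a wide region where
        # tail truncation is negligible, against both the closed form and a
        # dense-grid numeric oracle over the same region
        w = 0.02
        area = np.pi * w / 2.0  # gives I_max = 1
        x = np.linspace(0, 10, 4096)
        center = float(x[2048])  # on-grid center: apex sampled exactly
        s = Spectrum(x, lorentzian(x, center, area, w))
        region = RegionDefinition("r", center - 50 * w, center + 50 * w)
        rec = integrate_region(s, region)
        xd = np.linspace(region.ppm_lo, region.ppm_hi, 200001)
        dense = np.trapezoid(lorentzian(xd, center, area, w), xd)
        assert rec.int_c == pytest.approx(dense, rel=1e-2)
        assert rec.int_c == pytest.approx(area, rel=1e-2)
        assert rec.i_max == pytest.approx(2 * area / (np.pi * w), rel=1e-2)

    def test_region_outside_axis_raises(self):
        s = make_lorentzian_spectrum()
        with pytest.raises(ValueError, match="outside axis"):
            integrate_region(s, RegionDefinition("r", 20.0, 21.0))

    def test_integration_linear_in_intensity(self):
        s = make_lorentzian_spectrum(center=0.75, area=0.2, fwhm=0.02)
        r = RegionDefinition("r", 0.7, 0.8)
        base = integrate_region(s, r)
        for a in (0.0, 0.5, 3.0):
            scaled = Spectrum(s.ppm.copy(), a * s.intensity)
            rec = integrate_region(scaled, r)
            assert rec.int_c == pytest.approx(a * base.int_c, abs=1e-12)

    def test_rigid_referencing_preserves_region_integrals(self):
        s = make_lorentzian_spectrum(center=0.74, area=0.3, fwhm=0.02)
        ref = reference_spectrum(s, 0.6, 0.9, target=0.7)
        shift = ref.ppm[0] - s.ppm[0]
        rec0 = integrate_region(s, RegionDefinition("r", 0.64, 0.84))
        rec1 = integrate_region(ref, RegionDefinition("r", 0.64 + shift,
                                                      0.84 + shift))
        assert rec1.int_c == pytest.approx(rec0.int_c, rel=1e-12)
        assert rec1.i_max == rec0.i_max

    def test_baseline_subtraction_removes_linear_offset(self):
        x = np.linspace(0, 10, 2048)
        slope_part = 0.3 * x + 1.0
        s = Spectrum(x, lorentzian(x, 5.0, 1.0, 0.05) + slope_part)
        r = RegionDefinition("r", 4.0, 6.0)
        rec = integrate_region(s, r, baseline=True)
        pure = integrate_region(
            Spectrum(x, lorentzian(x, 5.0, 1.0, 0.05)), r, baseline=True)
        assert rec.int_c == pytest.approx(pure.int_c, rel=5e-3)


class TestSeries:
    def _write_series(self, tmp_path, n_conc=6, n_time=1, regions=1):
        cfg = NmrSeriesConfig(
            concentrations=tuple(0.1 * 2 ** i for i in range(n_conc)),
            time_points=tuple(24.0 * (i + 1) for i in range(n_time)),
            seed=7)
        manifest, _ = generate_nmr_series(cfg, tmp_path)
        return manifest

    def test_six_concentrations_one_region_six_records(self, tmp_path):
        manifest = self._write_series(tmp_path)
        regions = {"leu": RegionDefinition("leu", 0.7, 0.8)}
        table = load_series(manifest, regions=regions)
        assert len(table.records) == 6

    def test_product_count_concentrations_times_regions_times_times(
            self, tmp_path):
        manifest = self._write_series(tmp_path, n_conc=6, n_time=3)
        table = load_series(manifest)  # manifest defines 2 regions
        assert len(table.records) == 6 * 3 * 2

    def test_missing_file_error_names_path(self, tmp_path):
        manifest = self._write_series(tmp_path)
        import pandas as pd
        df = pd.read_csv(manifest)
        df.loc[0, "file"] = "absent.txt"
        df.to_csv(manifest, index=False)
        with pytest.raises(FileNotFoundError, match="absent.txt"):
            load_series(manifest)

    def test_missing_manifest_error_names_path(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="nope.csv"):
            load_series(tmp_path / "nope.csv")

    def test_duplicate_record_rejected(self):
        r = RegionDefinition("leu", 0.7, 0.8)
        rec = IntegralRecord(r, 1.0, 1.0, 0.1, 48.0)
        with pytest.raises(ValueError, match="duplicate"):
            SeriesTable([rec, rec])

    def test_records_sorted_by_concentration(self, tmp_path):
        manifest = self._write_series(tmp_path)
        table = load_series(manifest)
        concs = [r.concentration for r in table.records]
        assert concs == sorted(concs)

    def test_regions_config_file(self, tmp_path):
        p = tmp_path / "regions.cfg"
        p.write_text("leu_methyl = 0.7 0.8  # methyls\nacetate = 1.7 1.9\n")
        regions = read_regions_config(p)
        assert set(regions) == {"leu_methyl", "acetate"}
        assert regions["acetate"].ppm_lo == 1.7


@settings(max_examples=25, deadline=None)
@given(scale=st.floats(0.0, 50.0),
       center=st.floats(1.0, 9.0),
       fwhm=st.floats(0.01, 0.5))
def test_integral_scales_linearly_property(scale, center, fwhm):
    """integrate(a*s) == a*integrate(s) exactly up to floating point."""
    x = np.linspace(0, 10, 1024)
    y = lorentzian(x, center, 1.0, fwhm)
    r = RegionDefinition("r", max(0.0, center - 1), min(10.0, center + 1))
    base = integrate_region(Spectrum(x, y), r)
    rec = integrate_region(Spectrum(x, scale * y), r)
    assert rec.int_c == pytest.approx(scale * base.int_c, abs=1e-9)
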