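"""Clinical metric arithmetic, probe planes, report invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from portaflow.metrics import (MMHG_PA, ProbePlane, area_averaged_pressure,
                               flow_ratio, load_reference_table, mmhg_to_pa,
                               pa_to_mmhg, percent_reduction, pvv_ratio,
                               reference_value, wss_ratio)


class TestRatioArithmetic:
    @pytest.mark.parametrize("sten,pre,expect", [
        (48.91, 15.21, 3.21),      # pre-angioplasty severity
        (16.53, 16.32, 1.01),      # 1 week post
        (17.13, 17.06, 1.004),     # 6 months post
    ])
    def test_pvv_ratio_from_printed_velocities(self, sten, pre, expect):
        assert pvv_ratio(sten, pre) == pytest.approx(expect, abs=0.006)

    @pytest.mark.parametrize("post,pre,expect", [
        (5.29, 0.57, 9.28), (2.27, 0.48, 4.73), (0.71, 0.25, 2.84),
    ])
    def test_wss_ratio_from_printed_extrema(self, post, pre, expect):
        assert wss_ratio(post, pre) == pytest.approx(expect, abs=0.01)

    @pytest.mark.parametrize("ant,post,expect", [
        (347.73, 681.84, 0.51), (309.59, 719.97, 0.43), (298.02, 731.54, 0.41),
    ])
    def test_branch_flow_ratio_from_printed_flows(self, ant, post, expect):
        assert flow_ratio(ant, post) == pytest.approx(expect, abs=0.005)

    @pytest.mark.parametrize("earlier,later,expect", [
        (197.13, 12.86, 93.47),    # pressure gradient, post-angioplasty
        (12.86, 4.67, 63.69),      # further decline at 6 months
        (30.21, 3.09, 89.8),       # peak WSS
        (3.09, 0.77, 75.1),
        (48.91, 16.53, 66.2),      # stenotic-site velocity
    ])
    def test_percent_reduction_from_printed_values(self, earlier, later, expect):
        assert percent_reduction(earlier, later) == pytest.approx(expect, abs=0.05)

    def test_equal_values_no_reduction(self):
        assert percent_reduction(7.0, 7.0) == 0.0
        assert pvv_ratio(3.0, 3.0) == 1.0
        assert wss_ratio(2.0, 2.0) == 1.0

    def test_zero_denominators_rejected(self):
        for fn in (pvv_ratio, wss_ratio, flow_ratio):
            with pytest.raises(ZeroDivisionError):
                fn(1.0, 0.0)
        with pytest.raises(ZeroDivisionError):
            percent_reduction(0.0, 1.0)

    @settings(derandomize=True, max_examples=50)
    @given(a=st.floats(1e-3, 1e3), b=st.floats(1e-3, 1e3),
           s=st.floats(1e-3, 1e3))
    def test_ratios_scale_invariant(self, a, b, s):
        assert pvv_ratio(s * a, s * b) == pytest.approx(pvv_ratio(a, b), rel=1e-9)
        assert flow_ratio(s * a, s * b) == pytest.approx(flow_ratio(a, b), rel=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(a=st.floats(1e-3, 1e3), b=st.floats(1e-3, 1e3))
    def test_reduction_complement_identity(self, a, b):
        assert percent_reduction(a, b) + 100.0 * b / a == pytest.approx(100.0, abs=1e-9)


class TestUnitConversion:
    def test_printed_gradient_in_mmhg(self):
        assert pa_to_mmhg(197.13) == pytest.approx(1.48, abs=0.005)

    def test_unit_definition(self):
        assert pa_to_mmhg(MMHG_PA) == 1.0
        assert pa_to_mmhg(0.0) == 0.0

    def test_round_trip(self):
        for p in (1.0, 197.13, 1e4):
            assert mmhg_to_pa(pa_to_mmhg(p)) == pytest.approx(p, rel=1e-12)


class TestProbePlanes:
    def test_uniform_pressure_field_exact(self, tube_field):
        f = tube_field
        saved = f.cell_pressure.copy()
        try:
            f.cell_pressure = np.full_like(saved, 42.0)
            got = area_averaged_pressure(f, ProbePlane(10e-3, "stenotic"))
            assert got == pytest.approx(42.0, rel=1e-12)
        finally:
            f.cell_pressure = saved

    def test_linear_axial_decrease(self, tube_case, tube_field):
        zs = np.array([4e-3, 8e-3, 12e-3, 16e-3])
        ps = [area_averaged_pressure(tube_field, ProbePlane(z, "stenotic"))
              for z in zs]
        slopes = np.diff(ps) / np.diff(zs)
        assert np.all(slopes < 0.0)
        assert np.allclose(slopes, -tube_case.dpdz, rtol=0.02)

    def test_plane_outside_domain_rejected(self, tube_field):
        with pytest.raises(ValueError, match="outside"):
            area_averaged_pressure(tube_field, ProbePlane(1.0, "stenotic"))

    def test_invalid_region_label(self):
        with pytest.raises(ValueError):
            ProbePlane(0.01, "mid")


class TestReportInvariants:
    def test_pvv_ratio_definition(self, preop_report):
        r = preop_report
        assert r.pvv_ratio == pytest.approx(
            r.peak_velocity["stenotic"] / r.peak_velocity["pre_stenotic"], rel=1e-12)

    def test_wss_ratio_definition(self, preop_report):
        r = preop_report
        assert r.wss_ratio == pytest.approx(
            r.wss_max["post_stenotic"] / r.wss_max["pre_stenotic"], rel=1e-12)

    def test_gradient_definition(self, preop_report):
        r = preop_report
        assert r.trans_stenotic_gradient == pytest.approx(
            r.plane_pressures["pre_stenotic"] - r.plane_pressures["post_stenotic"],
            rel=1e-12)
        assert r.trans_stenotic_gradient_mmhg == pytest.approx(
            pa_to_mmhg(r.trans_stenotic_gradient), rel=1e-12)

    def test_regions_recorded(self, preop_report):
        assert set(preop_report.regions) == {"pre_stenotic", "stenotic",
                                             "post_stenotic"}


class TestReferenceTable:
    def test_well_formed(self):
        df = load_reference_table()
        assert set(df.columns) == {"timepoint", "metric", "value", "units", "source"}
        assert reference_value(df, "preop", "trans_stenotic_gradient") == 197.13
        assert reference_value(df, "preop", "pvv_ratio") == 3.21

    def test_doppler_and_simulation_agree_on_severity(self):
        df = load_reference_table()
        us = reference_value(df, "preop", "doppler_peak_velocity_stenotic") \
            / reference_value(df, "preop", "doppler_peak_velocity_prestenotic")
        cfd = reference_value(df, "preop", "pvv_ratio")
        assert us == pytest.approx(cfd, rel=0.2)    # 3.81 vs 3.21: same severity class
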