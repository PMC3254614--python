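"""T2* fitting must invert the mono-exponential generator exactly, degrade
gracefully on degenerate voxels, and feed an exact relaxivity regression."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fionmri.errors import EmptyROIError, GridMismatchError, ValidationError
from fionmri.relaxometry import (
    REASON_NON_DECAYING,
    REASON_NONPOSITIVE_SIGNAL,
    REASON_UNDERDETERMINED,
    fit_relaxivity,
    fit_t2star_map,
    fit_t2star_voxel,
    roi_mean_t2star,
)
from fionmri.containers import EchoSeries
from fionmri.synthetic import PhantomSpec, simulate_phantom, true_r2star


def decay(si0, t2star, te):
    return si0 * np.exp(-np.asarray(te) / t2star)


class TestVoxelFit:
    @pytest.mark.parametrize("t2star,si0", [(20.0, 1000.0), (9.09, 350.0), (100.0, 1.0)])
    def test_noiseless_recovery_is_exact(self, t2star, si0, acquisition_tes):
        fit = fit_t2star_voxel(decay(si0, t2star, acquisition_tes), acquisition_tes)
        assert fit.valid
        assert fit.t2star == pytest.approx(t2star, rel=1e-12)
        assert fit.si0 == pytest.approx(si0, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_two_points_match_the_algebraic_solution(self, rng):
        te = np.array([5.0, 30.0])
        s = np.array([800.0, 90.0])
        fit = fit_t2star_voxel(s, te)
        closed_form = (te[1] - te[0]) / np.log(s[0] / s[1])
        assert fit.t2star == pytest.approx(closed_form, rel=1e-12)

    def test_constant_signal_is_non_decaying(self, acquisition_tes):
        fit = fit_t2star_voxel([500.0] * 4, acquisition_tes)
        assert not fit.valid and fit.reason == REASON_NON_DECAYING

    def test_increasing_signal_is_non_decaying(self, acquisition_tes):
        fit = fit_t2star_voxel([10.0, 20.0, 30.0, 40.0], acquisition_tes)
        assert not fit.valid and fit.reason == REASON_NON_DECAYING

    def test_nonpositive_signal_invalidates_voxel(self, acquisition_tes):
        fit = fit_t2star_voxel([100.0, 50.0, 0.0, 10.0], acquisition_tes)
        assert not fit.valid and fit.reason == REASON_NONPOSITIVE_SIGNAL

    def test_single_echo_is_underdetermined(self):
        fit = fit_t2star_voxel([100.0], [10.0])
        assert not fit.valid and fit.reason == REASON_UNDERDETERMINED

    def test_signal_floor_option(self, acquisition_tes):
        s = decay(1000.0, 20.0, acquisition_tes)
        assert fit_t2star_voxel(s, acquisition_tes, signal_floor=100.0).reason == (
            REASON_NONPOSITIVE_SIGNAL
        )

    def test_t2star_cap_marks_slow_decay_invalid(self):
        te = np.array([4.9, 13.6, 22.3, 57.0])
        fit = fit_t2star_voxel(decay(1000.0, 5000.0, te), te, t2star_cap=2000.0)
        assert not fit.valid and fit.reason == REASON_NON_DECAYING

    def test_nls_agrees_with_loglinear_on_noiseless_data(self, acquisition_tes):
        s = decay(1000.0, 9.09, acquisition_tes)
        a = fit_t2star_voxel(s, acquisition_tes, method="loglinear")
        b = fit_t2star_voxel(s, acquisition_tes, method="nls")
        assert b.t2star == pytest.approx(a.t2star, rel=1e-6)
        assert b.si0 == pytest.approx(a.si0, rel=1e-6)


@settings(deadline=None, max_examples=60)
@given(
    t2star=st.floats(2.0, 500.0),
    si0=st.floats(1.0, 1e5),
    extra_te=st.floats(60.0, 200.0),
)
def test_loglinear_recovery_property(t2star, si0, extra_te):
    """Exact inversion holds for any mono-exponential voxel and echo set."""
    te = np.array([4.9, 13.6, 22.3, 57.0, extra_te])
    fit = fit_t2star_voxel(decay(si0, t2star, te), te, t2star_cap=1e9)
    assert fit.valid
    assert fit.t2star == pytest.approx(t2star, rel=1e-8)
    assert fit.si0 == pytest.approx(si0, rel=1e-8)


class TestMap:
    def test_map_inverts_the_noiseless_phantom(self, acquisition_tes):
        series, rois, truth = simulate_phantom(PhantomSpec(), acquisition_tes)
        t2map = fit_t2star_map(series)
        assert t2map.valid.all()
        np.testing.assert_allclose(t2map.t2star, truth.t2star_ms, rtol=1e-9)

    def test_all_zero_volume_is_invalid_everywhere(self, acquisition_tes):
        series = EchoSeries(np.zeros((4, 8, 8)), acquisition_tes)
        t2map = fit_t2star_map(series)
        assert not t2map.valid.any()
        assert (t2map.reason == REASON_NONPOSITIVE_SIGNAL).all()

    def test_mask_restricts_the_fit(self, acquisition_tes):
        series, rois, _ = simulate_phantom(PhantomSpec(), acquisition_tes)
        mask = rois["50 ugFe/mL"]
        t2map = fit_t2star_map(series, mask)
        assert t2map.valid[mask].all()
        assert not t2map.valid[~mask].any()

    def test_grid_mismatch_raises(self, acquisition_tes):
        series = EchoSeries(np.ones((4, 8, 8)), acquisition_tes)
        with pytest.raises(GridMismatchError):
            fit_t2star_map(series, np.ones((9, 9), dtype=bool))

    def test_map_and_voxel_fit_agree(self, acquisition_tes, rng):
        data = rng.uniform(10, 1000, (4, 6, 6))
        data.sort(axis=0)
        data = data[::-1].copy()  # decreasing per voxel
        series = EchoSeries(data, acquisition_tes)
        t2map = fit_t2star_map(series, t2star_cap=1e12)
        for i in range(6):
            for j in range(6):
                vf = fit_t2star_voxel(data[:, i, j], acquisition_tes, t2star_cap=1e12)
                if vf.valid:
                    assert t2map.t2star[i, j] == pytest.approx(vf.t2star, rel=1e-10)
                else:
                    assert not t2map.valid[i, j]


class TestROIMean:
    def test_uniform_region(self):
        series, rois, _ = simulate_phantom(PhantomSpec(), [4.9, 13.6, 22.3, 57.0])
        t2map = fit_t2star_map(series)
        control = roi_mean_t2star(t2map, rois["0 ugFe/mL"])
        assert control.mean == pytest.approx(100.0, rel=1e-9)
        assert control.sd == pytest.approx(0.0, abs=1e-9)

    def test_mean_of_mixed_values_and_single_voxel(self):
        from fionmri.relaxometry import T2StarMap

        t2 = np.array([[10.0, 20.0], [10.0, 20.0]])
        m = T2StarMap(
            t2star=t2, si0=np.ones_like(t2), r_squared=np.ones_like(t2),
            valid=np.ones_like(t2, dtype=bool), reason=np.zeros_like(t2, dtype=np.int8),
        )
        assert roi_mean_t2star(m, np.ones_like(t2, bool)).mean == pytest.approx(15.0)
        one = np.zeros_like(t2, bool)
        one[0, 1] = True
        assert roi_mean_t2star(m, one).mean == pytest.approx(20.0)

    def test_invalid_voxels_do_not_contribute(self):
        from fionmri.relaxometry import T2StarMap

        t2 = np.array([[10.0, 9999.0]])
        valid = np.array([[True, False]])
        m = T2StarMap(t2, t2, t2, valid, np.zeros_like(valid, dtype=np.int8))
        res = roi_mean_t2star(m, np.ones_like(valid))
        assert res.mean == pytest.approx(10.0) and res.n == 1
        with pytest.raises(EmptyROIError):
            roi_mean_t2star(m, np.array([[False, True]]))


class TestRelaxivity:
    def test_noiseless_line_is_recovered_exactly(self):
        conc_ug = np.array([0.0, 12.5, 25.0, 50.0, 100.0])
        r2s = np.array([true_r2star(c, 100.0, 324.0) for c in conc_ug])
        fit = fit_relaxivity(list(zip(conc_ug, 1000.0 / r2s)))
        assert fit.r2star == pytest.approx(324.0, rel=1e-9)
        assert fit.intercept == pytest.approx(10.0, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_two_points_give_the_exact_line(self):
        fit = fit_relaxivity([(0.0, 100.0), (55.845, 5.0)])
        # slope = (200 - 10) s^-1 over 1 mM
        assert fit.r2star == pytest.approx(190.0, rel=1e-12)
        assert fit.intercept == pytest.approx(10.0, rel=1e-12)

    def test_slope_invariant_under_point_order(self, rng):
        pts = [(c, 1000.0 / true_r2star(c, 80.0, 250.0)) for c in (0, 5, 10, 20, 40)]
        base = fit_relaxivity(pts).r2star
        shuffled = list(pts)
        rng.shuffle(shuffled)
        assert fit_relaxivity(shuffled).r2star == pytest.approx(base, rel=1e-12)

    def test_identical_concentrations_rejected(self):
        with pytest.raises(ValidationError):
            fit_relaxivity([(10.0, 50.0), (10.0, 40.0)])

    def test_slope_invariant_under_intensity_rescaling(self, acquisition_tes):
        """R2* is intensity-scale free: scaling every si0 changes nothing."""
        import dataclasses

        spec = PhantomSpec()
        scaled = dataclasses.replace(
            spec,
            tubes=tuple(dataclasses.replace(t, si0=t.si0 * 37.5) for t in spec.tubes),
        )
        slopes = []
        for sp in (spec, scaled):
            series, rois, _ = simulate_phantom(sp, acquisition_tes)
            t2map = fit_t2star_map(series)
            pts = [
                (t.iron_concentration, roi_mean_t2star(t2map, rois[t.label]).mean)
                for t in sp.tubes
            ]
            slopes.append(fit_relaxivity(pts).r2star)
        assert slopes[0] == pytest.approx(slopes[1], rel=1e-9)
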