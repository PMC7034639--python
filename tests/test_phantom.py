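import dataclasses

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from petquant.errors import ParameterError, SpecError
from petquant.io import FrameSchedule
from petquant.phantom import (
    EX527_DEFAULT,
    MC1568_DEFAULT,
    DEFAULT_KINETICS,
    PhantomSpec,
    PlasmaInputParams,
    RegionKinetics,
    SubjectMeta,
    TreatmentEffect,
    apply_treatment,
    build_phantom,
    default_phantom_spec,
    frame_averaged_tac,
    make_cohort,
    plasma_input,
    solve_1tcm,
    spec_from_dict,
    spec_to_dict,
)


class TestPlasmaInput:
    def test_null_input_is_zero(self):
        p = PlasmaInputParams((0.0, 0.0), (0.1, 1.0))
        assert plasma_input(p, 5.0) == 0.0

    @pytest.mark.parametrize(
        "t,expected", [(0.0, 1.0), (10.0, np.exp(-1.0))]
    )
    def test_single_exponential_closed_form(self, mono_exp_input, t, expected):
        assert plasma_input(mono_exp_input, t) == pytest.approx(expected, rel=1e-12)

    def test_negative_time_rejected(self, mono_exp_input):
        with pytest.raises(ParameterError):
            plasma_input(mono_exp_input, -1.0)

    def test_delay_shifts_onset(self):
        p = PlasmaInputParams((1.0, -1.0), (0.3, 3.0), delay=2.0)
        assert plasma_input(p, 1.0) == 0.0
        assert plasma_input(p, 3.0) > 0.0

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ParameterError):
            PlasmaInputParams((1.0,), (0.0,))

    def test_negative_curve_rejected(self):
        # a dominant negative amplitude makes the curve negative somewhere
        with pytest.raises(ParameterError):
            PlasmaInputParams((1.0, -2.0), (3.0, 0.3))


class TestSolve1TCM:
    def test_zero_input_gives_zero_tissue(self):
        kin = RegionKinetics("r", K1=1.0, k2=0.5)
        p = PlasmaInputParams((0.0,), (0.1,))
        tac = solve_1tcm(kin, p, np.linspace(0, 60, 61))
        assert np.all(tac.values == 0.0)

    def test_closed_form_convolution(self, mono_exp_input):
        # K1=1, k2=1, Cp=e^{-0.1t}: Ct(1) = (e^{-0.1}-e^{-1})/0.9
        kin = RegionKinetics("r", K1=1.0, k2=1.0)
        tac = solve_1tcm(kin, mono_exp_input, np.array([1.0]))
        assert tac.values[0] == pytest.approx(
            (np.exp(-0.1) - np.exp(-1.0)) / 0.9, rel=1e-12
        )

    def test_degenerate_k2_equals_lambda_uses_limit_form(self):
        kin = RegionKinetics("r", K1=2.0, k2=0.1)
        tac = solve_1tcm(kin, PlasmaInputParams((1.0,), (0.1,)), np.array([3.0]))
        assert tac.values[0] == pytest.approx(2.0 * 3.0 * np.exp(-0.3), rel=1e-10)

    def test_invalid_k2_rejected(self):
        with pytest.raises(ParameterError):
            RegionKinetics("r", K1=1.0, k2=0.0)

    def test_ode_oracle_agrees_with_closed_form(self):
        """Independent ODE integration of dCt/dt = K1 Cp - k2 Ct matches the
        analytic convolution to better than 1e-4 relative error."""
        p = PlasmaInputParams((1.5, -1.5), (0.25, 3.0), delay=0.0)
        kin = RegionKinetics("r", K1=0.3, k2=0.15)
        t_grid = np.linspace(1.0, 60.0, 60)
        analytic = solve_1tcm(kin, p, t_grid).values
        sol = solve_ivp(
            lambda t, y: kin.K1 * plasma_input(p, t) - kin.k2 * y,
            (0.0, 60.0),
            [0.0],
            t_eval=t_grid,
            rtol=1e-10,
            atol=1e-12,
        )
        rel = np.abs(sol.y[0] - analytic) / np.max(np.abs(analytic))
        assert rel.max() < 1e-4


class TestBuildPhantom:
    def test_noiseless_voxels_equal_frame_averaged_tac(self, default_noiseless):
        spec, image, labels, meta, gt = default_noiseless
        for name in ("tumor_rim", "brainstem"):
            tac = frame_averaged_tac(spec.region_kinetics[name], spec.input, spec.frames)
            mask = labels.mask(name)
            region_vox = image.voxels[mask]
            assert np.allclose(region_vox, tac.values[None, :].astype(np.float32), rtol=1e-6)

    def test_unlabeled_voxels_are_zero(self, default_noiseless):
        _, image, labels, _, _ = default_noiseless
        assert np.all(image.voxels[labels.labels == 0] == 0.0)

    def test_seed_determinism_and_sensitivity(self, tiny_spec):
        noisy = dataclasses.replace(tiny_spec, noise_level=0.1)
        a = build_phantom(noisy).image.voxels
        b = build_phantom(noisy).image.voxels
        c = build_phantom(dataclasses.replace(noisy, seed=4)).image.voxels
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_default_ground_truth_dvr_readback(self):
        spec = default_phantom_spec()
        gt = spec.ground_truth_dv()
        kin = spec.region_kinetics
        assert gt["tumor_rim"] == pytest.approx(kin["tumor_rim"].K1 / kin["tumor_rim"].k2)
        bs = kin["brainstem"]
        dv_bs = bs.K1 * ((1 - bs.slow_fraction) / bs.k2 + bs.slow_fraction / bs.k2_slow)
        assert gt["tumor_rim"] / gt["brainstem"] == pytest.approx(
            (kin["tumor_rim"].K1 / kin["tumor_rim"].k2) / dv_bs
        )
        assert gt["tumor_rim"] > gt["tumor_core"]

    def test_overlapping_geometry_rejected(self, tiny_spec):
        geom = dict(tiny_spec.region_geometry)
        geom["right"] = {"shape": "sphere", "center": (6, 8, 8), "radius": 3}
        bad = dataclasses.replace(tiny_spec, region_geometry=geom)
        with pytest.raises(SpecError, match="overlap"):
            build_phantom(bad)

    def test_noncontiguous_frames_rejected(self):
        with pytest.raises(ParameterError, match="contiguous"):
            FrameSchedule(np.array([0.0, 2.0]), np.array([1.0, 1.0]))

    def test_noiseless_activity_conservation(self, default_noiseless):
        """Per frame, total image content equals the sum over regions of
        voxel count x frame-averaged TAC (unlabeled voxels are zero)."""
        spec, image, labels, _, _ = default_noiseless
        totals = image.voxels.sum(axis=(0, 1, 2), dtype=np.float64)
        expected = np.zeros(len(spec.frames))
        for name in spec.region_geometry:
            tac = frame_averaged_tac(spec.region_kinetics[name], spec.input, spec.frames)
            n = int(labels.mask(name).sum())
            expected += n * tac.values
        assert np.allclose(totals, expected, rtol=1e-5)

    def test_k1_monotonicity_in_late_frames(self, tiny_spec):
        base = build_phantom(tiny_spec)
        kin = dict(tiny_spec.region_kinetics)
        kin["left"] = dataclasses.replace(kin["left"], K1=kin["left"].K1 * 1.5)
        boosted = build_phantom(dataclasses.replace(tiny_spec, region_kinetics=kin))
        m = base.labels.mask("left")
        assert np.all(boosted.image.voxels[m, -1] > base.image.voxels[m, -1])

    def test_peak_contrast_in_15_20_min_window(self, default_noiseless):
        """The tumor-rim/brainstem contrast is transient, maximal at 15-20 min."""
        spec, image, labels, _, _ = default_noiseless
        rim = image.voxels[labels.mask("tumor_rim")].mean(axis=0)
        bs = image.voxels[labels.mask("brainstem")].mean(axis=0)
        peak = image.frames.midpoints[np.argmax(rim / bs)]
        assert 15.0 <= peak <= 20.0

    def test_physical_decay_option(self, tiny_spec):
        corrected = build_phantom(tiny_spec).image
        decayed = build_phantom(tiny_spec, apply_decay=True).image
        assert corrected.decay_corrected and not decayed.decay_corrected
        factors = 0.5 ** (tiny_spec.frames.midpoints / 109.77)
        m = build_phantom(tiny_spec).labels.mask("left")
        assert np.allclose(
            decayed.voxels[m], corrected.voxels[m] * factors[None, :].astype(np.float32),
            rtol=1e-6,
        )


class TestApplyTreatment:
    def test_null_effect_leaves_ground_truth(self):
        spec = default_phantom_spec()
        treated = apply_treatment(spec, MC1568_DEFAULT)
        assert treated.ground_truth_dv() == spec.ground_truth_dv()

    def test_tumor_dv_scaling(self):
        spec = default_phantom_spec()
        treated = apply_treatment(
            spec, TreatmentEffect("X", tumor_dv_fraction=0.6, offtarget_dv_fraction=1.0)
        )
        gt0, gt1 = spec.ground_truth_dv(), treated.ground_truth_dv()
        assert gt1["tumor_rim"] == pytest.approx(0.6 * gt0["tumor_rim"])
        assert gt1["tumor_core"] == pytest.approx(0.6 * gt0["tumor_core"])

    def test_ex527_default_spares_offtarget_regions(self):
        spec = default_phantom_spec()
        gt0, gt1 = spec.ground_truth_dv(), apply_treatment(spec, EX527_DEFAULT).ground_truth_dv()
        for region in ("hippocampus", "nucleus_accumbens", "cortex", "brainstem"):
            assert gt1[region] == gt0[region]

    def test_original_spec_unmodified(self):
        spec = default_phantom_spec()
        before = spec.ground_truth_dv()
        apply_treatment(spec, EX527_DEFAULT)
        assert spec.ground_truth_dv() == before
        assert spec.treatment is None

    def test_unknown_tumor_region_rejected(self, tiny_spec):
        bad = dataclasses.replace(tiny_spec, tumor_regions=("nonesuch",))
        with pytest.raises(SpecError, match="nonesuch"):
            apply_treatment(bad, EX527_DEFAULT)

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            TreatmentEffect("X", tumor_dv_fraction=1.2)


class TestMakeCohort:
    def test_degenerate_cohort_matches_base(self):
        base = default_phantom_spec()
        (only,) = make_cohort(
            1, base, seed=5, dose_range=(400.0, 400.0), weight_range=(450.0, 450.0),
            jitter_cv=0.0,
        )
        assert only.region_kinetics == base.region_kinetics
        assert only.input == base.input
        assert only.ground_truth_dv() == base.ground_truth_dv()
        assert only.subject.subject_id == "S01"

    def test_reproducible_across_runs(self):
        base = default_phantom_spec()
        a = make_cohort(6, base, seed=11)
        b = make_cohort(6, base, seed=11)
        assert [spec_to_dict(s) for s in a] == [spec_to_dict(s) for s in b]

    def test_jitter_cv_controls_dv_spread(self):
        """Monte-Carlo check of the generator's own between-subject model:
        with CV=0.05 the sample SD of true tumor DV is 5% of the mean."""
        base = default_phantom_spec()
        cohort = make_cohort(200, base, seed=13, jitter_cv=0.05)
        dvs = np.array([s.ground_truth_dv()["tumor_rim"] for s in cohort])
        assert abs(dvs.std(ddof=1) / dvs.mean() - 0.05) < 0.2 * 0.05

    def test_suv_scale_preserved_via_input_scaling(self):
        """Plasma amplitude tracks dose/weight, so concentration/(dose/weight)
        is subject-independent at zero jitter."""
        base = default_phantom_spec()
        cohort = make_cohort(5, base, seed=17, jitter_cv=0.0)
        base_ratio = base.subject.injected_dose / base.subject.body_weight
        for s in cohort:
            ratio = s.subject.injected_dose / s.subject.body_weight
            np.testing.assert_allclose(
                np.array(s.input.amplitudes),
                np.array(base.input.amplitudes) * ratio / base_ratio,
            )


def test_spec_yaml_round_trip():
    spec = apply_treatment(default_phantom_spec(seed=9, noise_level=0.02), EX527_DEFAULT)
    again = spec_from_dict(spec_to_dict(spec))
    assert spec_to_dict(again) == spec_to_dict(spec)
    assert again.ground_truth_dv() == spec.ground_truth_dv()
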