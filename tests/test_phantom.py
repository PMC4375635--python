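"""Phantom geometry, signal simulation and cohort sampling."""

import math

import numpy as np
import pytest

from hippoquant.cohort import (
    CohortSpec,
    draw_control_values,
    sample_cohort,
    sample_ground_truth,
    standardize_sample,
)
from hippoquant.errors import CohortValidationError, ConfigurationError, SizingError
from hippoquant.phantom import (
    build_label_volume,
    flair_signal,
    simulate_dual_echo,
    simulate_flair,
    spin_echo_signal,
)
from hippoquant.tissue import AcquisitionParams, Tissue, TissueParams, default_tissue_table


class TestLabelVolume:
    def test_contains_all_classes_and_hippocampal_extent(self):
        vol = build_label_volume(geometry_seed=1)
        present = set(np.unique(vol.data).tolist())
        required = {int(t) for t in Tissue if t != Tissue.CHOROID_PLEXUS}
        assert required <= present
        for label in (Tissue.HIPPOCAMPUS_LEFT, Tissue.HIPPOCAMPUS_RIGHT):
            slices = [
                z for z in range(vol.n_slices) if (vol.slice(z) == label).any()
            ]
            assert len(slices) >= 5
            assert slices == list(range(slices[0], slices[0] + len(slices)))

    def test_hippocampi_have_csf_rim(self):
        from scipy import ndimage

        vol = build_label_volume(geometry_seed=3)
        for label in (Tissue.HIPPOCAMPUS_LEFT, Tissue.HIPPOCAMPUS_RIGHT):
            hippo = vol.data == label
            border = ndimage.binary_dilation(hippo, np.ones((3, 3, 3))) & ~hippo
            neighbours = set(np.unique(vol.data[border]).tolist())
            # everything touching a hippocampus is fluid (or plexus)
            assert neighbours <= {int(Tissue.CSF), int(Tissue.CHOROID_PLEXUS)}

    def test_deterministic_under_seed(self):
        a = build_label_volume(geometry_seed=1)
        b = build_label_volume(geometry_seed=1)
        assert np.array_equal(a.data, b.data)

    def test_seed_changes_placement_not_inventory(self):
        a = build_label_volume(geometry_seed=1)
        b = build_label_volume(geometry_seed=2)
        assert not np.array_equal(a.data, b.data)
        assert set(np.unique(a.data).tolist()) == set(np.unique(b.data).tolist())

    def test_too_small_matrix_raises(self):
        with pytest.raises(SizingError):
            build_label_volume(AcquisitionParams(matrix=(16, 16), n_slices=12))


class TestDualEcho:
    def test_closed_form_decay(self):
        # PD 1000, T2 100 ms at TE 30/80
        assert spin_echo_signal(1000, 100, 30) == pytest.approx(740.8182, abs=1e-3)
        assert spin_echo_signal(1000, 100, 80) == pytest.approx(449.3290, abs=1e-3)

    def test_noiseless_volumes_match_decay_law(self, acq):
        vol = build_label_volume(acq, geometry_seed=1)
        tissues = default_tissue_table()
        s1, s2 = simulate_dual_echo(vol, tissues, acq)
        for cls in (Tissue.WHITE_MATTER, Tissue.CSF, Tissue.HIPPOCAMPUS_LEFT):
            p = tissues[cls]
            where = vol.data == cls
            assert np.allclose(s1.data[where], spin_echo_signal(p.proton_density, p.t2, acq.te1))
            assert np.allclose(s2.data[where], spin_echo_signal(p.proton_density, p.t2, acq.te2))

    def test_t2_formula_inverts_simulation_exactly(self, acq):
        vol = build_label_volume(acq, geometry_seed=5)
        overrides = {Tissue.HIPPOCAMPUS_LEFT: 115.0, Tissue.HIPPOCAMPUS_RIGHT: 99.5}
        s1, s2 = simulate_dual_echo(vol, acq=acq, t2_overrides=overrides)
        where = vol.data == Tissue.HIPPOCAMPUS_LEFT
        t2 = (acq.te2 - acq.te1) / np.log(s1.data[where] / s2.data[where])
        assert np.allclose(t2, 115.0, rtol=1e-12)

    def test_noise_is_seed_deterministic(self, acq):
        vol = build_label_volume(acq, geometry_seed=1)
        a = simulate_dual_echo(vol, acq=acq, noise_sigma=5.0, seed=11)
        b = simulate_dual_echo(vol, acq=acq, noise_sigma=5.0, seed=11)
        c = simulate_dual_echo(vol, acq=acq, noise_sigma=5.0, seed=12)
        assert np.array_equal(a[0].data, b[0].data)
        assert np.array_equal(a[1].data, b[1].data)
        assert not np.array_equal(a[0].data, c[0].data)

    @pytest.mark.parametrize("model", ["gaussian", "rician"])
    def test_noise_sd_approaches_sigma_in_uniform_region(self, acq, model):
        vol = build_label_volume(acq, geometry_seed=1)
        sigma = 4.0
        s1, _ = simulate_dual_echo(vol, acq=acq, noise_sigma=sigma, seed=3, noise_model=model)
        where = vol.data == Tissue.WHITE_MATTER  # ~20k voxels, high SNR
        sd = s1.data[where].std()
        assert sd == pytest.approx(sigma, rel=0.05)

    def test_missing_tissue_parameters_raise(self, acq):
        vol = build_label_volume(acq, geometry_seed=1)
        tissues = default_tissue_table()
        del tissues[Tissue.PONS_WM]
        with pytest.raises(ConfigurationError):
            simulate_dual_echo(vol, tissues, acq)


class TestFlair:
    def test_inversion_null_condition(self, acq):
        # T1 = TI / ln 2 makes the inversion factor collapse to e^(-TR/T1)
        t1 = acq.ti_flair / math.log(2.0)
        s = flair_signal(1000.0, t1, 100.0, acq)
        assert s < 1000.0 * math.exp(-acq.tr_flair / t1) * 1.01

    def test_csf_attenuated_below_5pct_of_wm(self, acq):
        tissues = default_tissue_table()
        wm, csf = tissues[Tissue.WHITE_MATTER], tissues[Tissue.CSF]
        s_wm = flair_signal(wm.proton_density, wm.t1, wm.t2, acq)
        s_csf = flair_signal(csf.proton_density, csf.t1, csf.t2, acq)
        assert s_csf < 0.05 * s_wm

    def test_wm_exceeds_csf_for_generic_parameters(self, acq):
        s_wm = flair_signal(700.0, 850.0, 80.0, acq)
        s_csf = flair_signal(1000.0, 4000.0, 2000.0, acq)
        assert s_wm > s_csf

    def test_unit_override_is_identity(self, acq):
        vol = build_label_volume(acq, geometry_seed=2)
        base = simulate_flair(vol, acq=acq)
        unit = simulate_flair(
            vol, acq=acq, intensity_overrides={t: 1.0 for t in Tissue}
        )
        assert np.array_equal(base.data, unit.data)

    def test_override_scales_only_target_class(self, acq):
        vol = build_label_volume(acq, geometry_seed=2)
        base = simulate_flair(vol, acq=acq)
        up = simulate_flair(vol, acq=acq, intensity_overrides={Tissue.HIPPOCAMPUS_LEFT: 2.0})
        hippo = vol.data == Tissue.HIPPOCAMPUS_LEFT
        assert np.allclose(up.data[hippo], 2.0 * base.data[hippo])
        assert np.array_equal(up.data[~hippo], base.data[~hippo])


class TestCohort:
    def test_default_structure_matches_study(self, default_cohort):
        man = default_cohort.manifest()
        assert (man.group == "control").sum() == 14
        assert (man.group == "patient").sum() == 27
        pat = man[man.group == "patient"]
        assert (pat.hs_side == "left").sum() == 14
        assert (pat.hs_side == "right").sum() == 13
        assert pat.bilateral.sum() == 6

    def test_controls_have_no_hs_side(self, default_cohort):
        for gt in default_cohort.ground_truth:
            if gt.group == "control":
                assert gt.hs_side == "none" and not gt.bilateral
            else:
                assert gt.hs_side in ("left", "right")

    def test_sclerotic_t2_within_support(self, default_cohort):
        spec = default_cohort.spec
        for gt in default_cohort.ground_truth:
            if gt.group != "patient":
                continue
            ipsi = gt.true_t2_left if gt.hs_side == "left" else gt.true_t2_right
            assert spec.sclerotic_t2_low <= ipsi <= spec.sclerotic_t2_high

    def test_bilateral_fraction_zero_degenerate(self):
        spec = CohortSpec(n_controls=2, n_patients=6, bilateral_fraction=0.0, seed=3)
        limit = spec.control_t2_mean + 2 * spec.control_t2_sd
        for gt in sample_ground_truth(spec):
            if gt.group == "patient":
                contra = gt.true_t2_right if gt.hs_side == "left" else gt.true_t2_left
                assert not gt.bilateral
                assert contra <= limit

    def test_large_replicate_bilateral_fraction(self):
        spec = CohortSpec(n_patients=2700, seed=9)
        pats = [g for g in sample_ground_truth(spec) if g.group == "patient"]
        frac = sum(g.bilateral for g in pats) / len(pats)
        se = math.sqrt(spec.bilateral_fraction * (1 - spec.bilateral_fraction) / 2700)
        assert abs(frac - spec.bilateral_fraction) <= 2 * se

    def test_cohort_bit_identical_under_seed(self, tiny_spec):
        a = sample_cohort(tiny_spec)
        b = sample_cohort(tiny_spec)
        for sa, sb in zip(a.subjects, b.subjects):
            assert sa.ground_truth == sb.ground_truth
            assert np.array_equal(sa.labels.data, sb.labels.data)
            assert np.array_equal(sa.s1.data, sb.s1.data)
            assert np.array_equal(sa.flair.data, sb.flair.data)

    def test_infeasible_fraction_rejected(self):
        with pytest.raises(CohortValidationError):
            CohortSpec(patient_nfsi_detectable_fraction=1.5).validate()
        with pytest.raises(CohortValidationError):
            CohortSpec(sclerotic_t2_low=105.0).validate()  # below control limit

    def test_standardize_sample_pins_moments(self):
        rng = np.random.default_rng(0)
        x = rng.normal(50, 9, size=28)
        y = standardize_sample(x, 99.0, 5.0)
        assert y.mean() == pytest.approx(99.0, abs=1e-9)
        assert y.std(ddof=1) == pytest.approx(5.0, abs=1e-9)
        # order (and hence every sample z-score) is preserved
        assert np.array_equal(np.argsort(x), np.argsort(y))

    def test_bootstrap_calibration_of_control_limit(self):
        """Mean of (mean + 2 SD) over many 28-hippocampus control samples
        brackets the 109 ms normal limit."""
        spec = CohortSpec()
        rng = np.random.default_rng(2024)
        limits = []
        for _ in range(1000):
            draws = draw_control_values(rng, spec, 28, "t2", moment_match=True)
            limits.append(draws.mean() + 2 * draws.std(ddof=1))
        assert 107.0 <= float(np.mean(limits)) <= 111.0
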