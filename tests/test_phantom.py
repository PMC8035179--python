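import numpy as np
import pytest

from salispect.phantom import (
    PhantomSpec,
    generate_cohort,
    generate_study,
    simulate_manual_labels,
)
from salispect.physics import decay_factor
from salispect.quantify import quantify_study
from salispect.evaluate import dice
from salispect.volumes import GlandLabelMap


class TestPhantomSpec:
    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(parotid_ef=(101.0, 5.0))
        with pytest.raises(ValueError):
            PhantomSpec(psf_fwhm_mm=0.0)
        with pytest.raises(ValueError):
            PhantomSpec(count_scale_counts_per_Bq=0.0)

    def test_noiseless_flag_allows_zero_count_scale(self):
        PhantomSpec(noiseless=True, count_scale_counts_per_Bq=0.0)


class TestGenerateStudy:
    def test_seed_determinism_bit_identical(self):
        spec = PhantomSpec.desk_small(seed=5)
        a = generate_study(spec, 3)
        b = generate_study(spec, 3)
        np.testing.assert_array_equal(a.ct20.voxels, b.ct20.voxels)
        np.testing.assert_array_equal(a.spect20.voxels, b.spect20.voxels)
        np.testing.assert_array_equal(a.spect40.voxels, b.spect40.voxels)
        assert a.applied_misalignment == b.applied_misalignment

    def test_zero_misalignment_is_identity(self):
        spec = PhantomSpec.desk_small(
            seed=5, misalign_translation_mm=0.0, misalign_rotation_deg=0.0
        )
        rec = generate_study(spec, 0)
        assert rec.applied_misalignment.is_identity

    def test_noiseless_activity_budget(self, aligned_noiseless_study):
        """Truth-VOI %ID equals the programmed value on noiseless phantoms.

        Oracle: the per-gland activity budget — programmed %ID x injected
        activity — recovered by the independent VOI-sum arithmetic.
        """
        rec = aligned_noiseless_study
        prog = rec.meta["programmed"]
        quants = quantify_study(
            rec.spect20, rec.spect40, rec.truth_labels, rec.injected_activity_MBq
        )
        for q in quants:
            p = prog[q.gland_name]
            assert q.pid20 == pytest.approx(p["pid20"], rel=0.02)
            assert q.pid40 == pytest.approx(p["pid40"], rel=0.02)
            assert q.ef_percent == pytest.approx(p["ef"], rel=0.02)

    def test_ef_consistency_pre_noise(self, aligned_noiseless_study):
        """Programmed 40/20 in-VOI activity ratio is exactly 1 - EF/100
        after removing physical decay."""
        rec = aligned_noiseless_study
        vox_mL = rec.spect20.voxel_volume_mL
        dec = decay_factor(40.0) / decay_factor(20.0)
        for code, name in ((1, "parotid_r"), (3, "submandibular_r")):
            m = rec.truth_labels.labels == code
            a20 = rec.spect20.voxels[m].sum() * vox_mL
            a40 = rec.spect40.voxels[m].sum() * vox_mL
            ef = rec.meta["programmed"][name]["ef"]
            assert a40 / a20 / dec == pytest.approx(1 - ef / 100.0, rel=5e-3)

    def test_labels_match_drawn_volume_within_voxel_shell(self, default_study):
        lab = default_study.truth_labels
        vox_mL = lab.voxel_volume_mL
        for code, g in zip((1, 2, 3, 4), ("parotid_r", "parotid_l",
                                          "submandibular_r", "submandibular_l")):
            drawn = default_study.meta["programmed"][g]["volume_mL"]
            vol = (lab.labels == code).sum() * vox_mL
            # one-voxel surface shell of an equivalent sphere
            r_mm = (3 * drawn * 1000 / (4 * np.pi)) ** (1 / 3)
            shell_mL = 4 * np.pi * r_mm ** 2 * max(lab.spacing) / 1000
            assert abs(vol - drawn) <= shell_mL

    def test_decay_simulation_toggle(self):
        base = dict(noiseless=True, misalign_translation_mm=0.0,
                    misalign_rotation_deg=0.0, seed=9)
        with_decay = generate_study(PhantomSpec.desk_small(**base), 0)
        without = generate_study(
            PhantomSpec.desk_small(simulate_decay=False, **base), 0
        )
        m = with_decay.truth_labels.labels == 1
        ratio = with_decay.spect20.voxels[m].sum() / without.spect20.voxels[m].sum()
        assert ratio == pytest.approx(decay_factor(20.0), rel=1e-6)


class TestGenerateCohort:
    def test_distinct_ids_and_reproducibility(self):
        spec = PhantomSpec.desk_small(seed=2)
        a = generate_cohort(spec, 5)
        b = generate_cohort(spec, 5)
        assert len({r.study_id for r in a}) == 5
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.ct20.voxels, rb.ct20.voxels)

    def test_n_below_one_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(PhantomSpec.desk_small(), 0)

    def test_parotid_volume_population_mean(self):
        """Sample mean of truth-VOI parotid volume tracks the population
        mean (law of large numbers over 50 studies, 100 glands)."""
        spec = PhantomSpec.desk_small(seed=31, noiseless=True,
                                      misalign_translation_mm=0.0,
                                      misalign_rotation_deg=0.0)
        cohort = generate_cohort(spec, 50)
        vols = []
        for rec in cohort:
            vox_mL = rec.truth_labels.voxel_volume_mL
            for code in (1, 2):
                vols.append((rec.truth_labels.labels == code).sum() * vox_mL)
        se = spec.parotid_volume_mL[1] / np.sqrt(len(vols))
        assert abs(np.mean(vols) - spec.parotid_volume_mL[0]) < 3 * se


class TestSimulateManualLabels:
    def _cylinder(self, r=6.0, shape=(24, 24, 12)):
        idx = np.indices(shape, dtype=float)
        c = (np.asarray(shape) - 1) / 2.0
        mask = (idx[0] - c[0]) ** 2 + (idx[1] - c[1]) ** 2 <= r ** 2
        lab = np.where(mask, 1, 0).astype(np.int16)
        lab[..., :2] = 0
        lab[..., -2:] = 0
        return GlandLabelMap(labels=lab, spacing=(2, 2, 3))

    def test_cylinder_identity_without_jitter(self):
        truth = self._cylinder()
        out = simulate_manual_labels(truth, every_k_slices=2, jitter_prob=0.0, seed=0)
        np.testing.assert_array_equal(out.labels, truth.labels)

    def test_empty_class_stays_empty(self, default_study):
        truth = default_study.truth_labels
        lab = truth.labels.copy()
        lab[lab == 4] = 0
        out = simulate_manual_labels(truth.with_labels(lab), 2, 0.5, seed=1)
        assert not (out.labels == 4).any()

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            simulate_manual_labels(self._cylinder(), every_k_slices=4)

    @pytest.mark.parametrize("k", [2, 3])
    def test_two_raters_dice_in_expert_band(self, default_study, k):
        truth = default_study.truth_labels
        ds = []
        for s in range(3):
            a = simulate_manual_labels(truth, k, jitter_prob=1.0, seed=100 + s)
            b = simulate_manual_labels(truth, k, jitter_prob=1.0, seed=200 + s)
            for c in (1, 2, 3, 4):
                d = dice(a.labels == c, b.labels == c)
                if d is not None:
                    ds.append(d)
        assert 0.70 <= np.mean(ds) <= 0.95
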