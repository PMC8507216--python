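"""Cohort generator calibration, phantom contracts, mask perturbation, splits."""

import copy

import numpy as np
import pytest

from strokerad.synthetic import (
    CohortSpec,
    PhantomSpec,
    generate_cohort,
    generate_phantom,
    generate_tabular_cohort,
    perturb_mask,
    split_cohort,
)


class TestGenerateCohort:
    def test_replica_counts_default(self):
        recs = generate_cohort(CohortSpec(seed=3))
        assert sum(r.tfs_class == "early" for r in recs) == 46
        assert sum(r.tfs_class == "late" for r in recs) == 77

    def test_empty_stratum(self):
        recs = generate_cohort(CohortSpec(n_early=0, n_late=10, seed=3))
        assert all(r.tfs_class == "late" for r in recs)

    def test_same_seed_identical_cohort(self):
        a = generate_cohort(CohortSpec(seed=17))
        b = generate_cohort(CohortSpec(seed=17))
        assert all(x.covariates == y.covariates for x, y in zip(a, b))

    def test_different_seed_differs(self):
        a = generate_cohort(CohortSpec(seed=17))
        b = generate_cohort(CohortSpec(seed=18))
        assert any(x.covariates != y.covariates for x, y in zip(a, b))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(CohortSpec(n_early=0, n_late=0))
        bad = CohortSpec()
        bad.early.prevalence["hypertension"] = 1.5
        with pytest.raises(ValueError):
            generate_cohort(bad)

    def test_covariate_invariants_over_seed_sweep(self):
        for seed in range(100):
            recs = generate_cohort(CohortSpec(n_early=3, n_late=3, seed=seed))
            for r in recs:
                c = r.covariates
                assert 0 <= c.aspects <= 10
                assert 0 <= c.nihss <= 42
                assert c.collateral_grade in (0, 1, 2, 3)
                assert 18.0 <= c.age <= 100.0

    def test_large_n_calibration(self):
        recs = generate_cohort(CohortSpec(n_early=10000, n_late=0, seed=5))
        ages = np.array([r.covariates.age for r in recs])
        asp = np.array([r.covariates.aspects for r in recs])
        booleans = {
            "hypertension": 0.6739,
            "atrial_fibrillation": 0.5435,
            "hvs": 0.6087,
        }
        se = ages.std(ddof=1) / np.sqrt(len(ages))
        assert abs(ages.mean() - 75.17) < 3 * se
        assert np.median(asp) == 8
        for name, p in booleans.items():
            got = np.mean([getattr(r.covariates, name) for r in recs])
            assert abs(got - p) < 3 * np.sqrt(p * (1 - p) / len(recs))

    def test_late_stratum_median_aspects(self):
        recs = generate_cohort(CohortSpec(n_early=0, n_late=10000, seed=6))
        asp = np.array([r.covariates.aspects for r in recs])
        assert np.median(asp) == 6

    def test_sampling_mode_prevalence(self):
        spec = CohortSpec(n_early=46, n_late=77, seed=4, mode="sampling")
        spec.n_early, spec.n_late = 4600, 7700
        recs = generate_cohort(spec)
        prev = np.mean([r.tfs_class == "early" for r in recs])
        p = 46 / 123
        assert abs(prev - p) < 3 * np.sqrt(p * (1 - p) / len(recs))


class TestGeneratePhantom:
    def test_grid_and_mask_contracts(self):
        rec = generate_cohort(CohortSpec(n_early=1, n_late=0, seed=1))[0]
        pspec = PhantomSpec(shape=(32, 32, 32))
        vol, mask = generate_phantom(rec, pspec)
        assert vol.shape == mask.shape == (32, 32, 32)
        assert vol.spacing == mask.spacing
        assert mask.count > 0
        from scipy import ndimage

        _, n_comp = ndimage.label(mask.voxels)
        assert n_comp == 1  # connected VOI

    def test_deterministic(self):
        rec = generate_cohort(CohortSpec(n_early=1, n_late=0, seed=1))[0]
        pspec = PhantomSpec(shape=(24, 24, 24), seed=9)
        v1, m1 = generate_phantom(rec, pspec)
        v2, m2 = generate_phantom(rec, pspec)
        np.testing.assert_array_equal(v1.voxels, v2.voxels)
        np.testing.assert_array_equal(m1.voxels, m2.voxels)

    def test_zero_decrement_null_effect(self):
        rec = generate_cohort(CohortSpec(n_early=1, n_late=0, seed=1))[0]
        pspec = PhantomSpec(
            shape=(32, 32, 32),
            lesion_decrement={"early": 0.0, "late": 0.0},
            decrement_between_sd=0.0,
            texture_sd={"early": 0.0, "late": 0.0},
        )
        vol, mask = generate_phantom(rec, pspec)
        lesion = _lesion_region(rec, pspec)
        bg = mask.voxels & ~lesion
        # same generating distribution inside and outside the lesion
        assert abs(vol.voxels[lesion].mean() - vol.voxels[bg].mean()) < 1.0

    def test_late_lesion_strictly_more_hypodense_same_seed(self):
        rec = generate_cohort(CohortSpec(n_early=1, n_late=0, seed=2))[0]
        late = copy.deepcopy(rec)
        late.tfs_class = "late"
        diffs = []
        for seed in range(50):
            pspec = PhantomSpec(shape=(24, 24, 24), seed=seed)
            ve, _ = generate_phantom(rec, pspec)
            vl, _ = generate_phantom(late, pspec)
            lesion = _lesion_region(rec, pspec)
            diffs.append(vl.voxels[lesion].mean() - ve.voxels[lesion].mean())
        diffs = np.array(diffs)
        assert np.all(diffs < 0)  # same seed: late strictly lower
        assert diffs.mean() == pytest.approx(-2.0, abs=0.5)

    def test_aspects_controls_lesion_extent(self):
        base = generate_cohort(CohortSpec(n_early=1, n_late=0, seed=3))[0]
        big, small = copy.deepcopy(base), copy.deepcopy(base)
        big.covariates.aspects = 0
        small.covariates.aspects = 10
        pspec = PhantomSpec(shape=(32, 32, 32))
        n_big = _lesion_region(big, pspec).sum()
        n_small = _lesion_region(small, pspec).sum()
        assert n_big > n_small > 0


def _lesion_region(rec, pspec):
    return generate_phantom(rec, pspec, return_lesion=True)[2]


class TestPerturbMask:
    def _mask(self):
        rec = generate_cohort(CohortSpec(n_early=1, n_late=0, seed=1))[0]
        _, mask = generate_phantom(rec, PhantomSpec(shape=(32, 32, 32)))
        return mask

    def test_zero_magnitude_identity(self):
        mask = self._mask()
        out = perturb_mask(mask, 0.0, seed=1)
        np.testing.assert_array_equal(out.voxels, mask.voxels)

    def test_reproducible(self):
        mask = self._mask()
        a = perturb_mask(mask, 0.05, seed=42)
        b = perturb_mask(mask, 0.05, seed=42)
        np.testing.assert_array_equal(a.voxels, b.voxels)

    def test_dice_decreases_with_magnitude(self):
        mask = self._mask()

        def dice(a, b):
            return 2 * (a & b).sum() / (a.sum() + b.sum())

        d_small = np.mean(
            [dice(mask.voxels, perturb_mask(mask, 0.02, s).voxels) for s in range(50)]
        )
        d_large = np.mean(
            [dice(mask.voxels, perturb_mask(mask, 0.2, s).voxels) for s in range(50)]
        )
        assert d_small > d_large

    def test_negative_magnitude_rejected(self):
        with pytest.raises(ValueError):
            perturb_mask(self._mask(), -0.1, seed=0)


class TestSplitCohort:
    def test_published_split_sizes(self):
        recs = generate_cohort(CohortSpec(seed=1))
        split_cohort(recs, 85, 38, stratify=True, seed=1)
        assert sum(r.split == "development" for r in recs) == 85
        assert sum(r.split == "validation" for r in recs) == 38

    def test_degenerate_split(self):
        recs = generate_cohort(CohortSpec(n_early=5, n_late=5, seed=1))
        split_cohort(recs, 10, 0, seed=1)
        assert all(r.split == "development" for r in recs)

    def test_stratified_validation_early_count(self):
        # integer apportionment of 46 * 38 / 123 = 14.2
        for seed in range(10):
            recs = generate_cohort(CohortSpec(seed=seed))
            split_cohort(recs, 85, 38, stratify=True, seed=seed)
            n = sum(r.split == "validation" and r.tfs_class == "early" for r in recs)
            assert n in (14, 15)

    def test_inconsistent_sizes_rejected(self):
        recs = generate_cohort(CohortSpec(n_early=5, n_late=5, seed=1))
        with pytest.raises(ValueError):
            split_cohort(recs, 3, 3, seed=1)

    def test_seeded_reproducible(self):
        a = generate_cohort(CohortSpec(seed=2))
        b = generate_cohort(CohortSpec(seed=2))
        split_cohort(a, 85, 38, seed=7)
        split_cohort(b, 85, 38, seed=7)
        assert [r.split for r in a] == [r.split for r in b]


def test_tabular_cohort_signal_direction():
    feats, clinical, y = generate_tabular_cohort(n=2000, seed=1)
    assert set(np.unique(y)) == {0, 1}
    # informative features separate the classes; noise does not
    gap_sig = abs(feats.loc[y == 1, "signal_0"].mean() - feats.loc[y == 0, "signal_0"].mean())
    gap_noise = abs(feats.loc[y == 1, "noise_0"].mean() - feats.loc[y == 0, "noise_0"].mean())
    assert gap_sig > gap_noise
    assert clinical.loc[y == 1, "age"].mean() > clinical.loc[y == 0, "age"].mean()
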