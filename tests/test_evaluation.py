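"""DeLong ROC machinery, operating points, McNemar, DCA, ICC, Spearman."""

import numpy as np
import pandas as pd
import pytest

from oracles import auc_paircount, mcnemar_exact_bruteforce
from strokerad import evaluation


class TestAucDelong:
    def test_perfect_separation(self):
        r = evaluation.auc_delong([3, 4, 1, 2], [1, 1, 0, 0])
        assert r.auc == 1.0

    def test_micro_example_variance(self):
        r = evaluation.auc_delong([0.9, 0.4, 0.5, 0.1], [1, 1, 0, 0])
        assert r.auc == pytest.approx(0.75)
        assert r.se**2 == pytest.approx(0.125)

    def test_all_ties(self):
        r = evaluation.auc_delong([1.0] * 6, [1, 1, 1, 0, 0, 0])
        assert r.auc == pytest.approx(0.5)

    def test_ci_contains_auc_and_truncated(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=40)
        y = (rng.random(40) < 0.5).astype(int)
        r = evaluation.auc_delong(s, y)
        assert 0.0 <= r.ci[0] <= r.auc <= r.ci[1] <= 1.0

    @pytest.mark.parametrize("trial", range(30))
    def test_equals_pair_counting(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(4, 31))
        scores = np.round(rng.normal(size=n), 1)  # force some ties
        labels = np.zeros(n, dtype=int)
        labels[: max(1, n // 3)] = 1
        rng.shuffle(labels)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        r = evaluation.auc_delong(scores, labels)
        assert r.auc == pytest.approx(auc_paircount(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluation.auc_delong([1, 2, 3], [1, 1, 1])


class TestYouden:
    def test_perfect_classifier(self):
        roc = evaluation.auc_delong([4, 3, 2, 1], [1, 1, 0, 0])
        op = evaluation.youden_point(roc)
        assert (op.sensitivity, op.specificity, op.youden_j) == (1.0, 1.0, 1.0)

    def test_micro_example(self):
        # J = 0.5 is attained both at threshold 0.9 (sens .5, spec 1) and at
        # 0.4 (sens 1, spec .5); the tie rule prefers higher sensitivity
        roc = evaluation.auc_delong([0.9, 0.4, 0.5, 0.1], [1, 1, 0, 0])
        op = evaluation.youden_point(roc)
        assert op.youden_j == pytest.approx(0.5)
        assert op.sensitivity == 1.0
        assert op.threshold == pytest.approx(0.4)

    def test_uninformative_scores(self):
        roc = evaluation.auc_delong([1.0] * 8, [1, 0] * 4)
        op = evaluation.youden_point(roc)
        assert op.youden_j == pytest.approx(0.0)


class TestDelongCompare:
    def test_identical_scores_p_one(self):
        s = [0.9, 0.4, 0.5, 0.1]
        r = evaluation.delong_compare(s, s, [1, 1, 0, 0])
        assert r.p == 1.0
        assert r.degenerate

    def test_symmetric(self):
        rng = np.random.default_rng(1)
        y = (rng.random(60) < 0.5).astype(int)
        a, b = rng.normal(size=60) + y, rng.normal(size=60)
        r1 = evaluation.delong_compare(a, b, y)
        r2 = evaluation.delong_compare(b, a, y)
        assert r1.p == pytest.approx(r2.p)
        assert r1.z == pytest.approx(-r2.z)

    def test_power_against_noise(self):
        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(200 + seed)
            n = 500
            y = np.repeat([0, 1], n // 2)
            informative = rng.normal(size=n) + 1.2 * y
            noise = rng.normal(size=n)
            if evaluation.delong_compare(informative, noise, y).p < 0.05:
                wins += 1
        assert wins >= 95

    def test_unpaired_shapes_rejected(self):
        with pytest.raises(ValueError):
            evaluation.delong_compare([1, 2], [1, 2, 3], [0, 1, 1])


class TestMcNemar:
    def test_identical_predictions(self):
        r = evaluation.mcnemar_compare([1, 0, 1], [1, 0, 1], [1, 0, 0])
        assert r.p == 1.0

    def test_one_sided_discordance(self):
        y = np.zeros(8, dtype=int)
        a = np.zeros(8, dtype=int)  # all correct
        b = np.ones(8, dtype=int)  # all wrong
        r = evaluation.mcnemar_compare(a, b, y)
        assert (r.b, r.c) == (8, 0)
        assert r.p == pytest.approx(2 * 0.5**8)

    def test_balanced_discordance(self):
        y = np.zeros(10, dtype=int)
        a = np.array([0] * 5 + [1] * 5)
        b = np.array([1] * 5 + [0] * 5)
        r = evaluation.mcnemar_compare(a, b, y)
        assert (r.b, r.c) == (5, 5)
        assert r.p == 1.0

    @pytest.mark.parametrize("b", range(0, 13))
    def test_exact_matches_enumeration(self, b):
        for c in range(0, 13 - b):
            y = np.zeros(b + c + 3, dtype=int)
            pa = np.zeros_like(y)
            pb = np.zeros_like(y)
            pb[:b] = 1  # A correct, B wrong
            pa[b : b + c] = 1  # A wrong, B correct
            r = evaluation.mcnemar_compare(pa, pb, y)
            assert r.p == pytest.approx(mcnemar_exact_bruteforce(b, c), abs=1e-12)

    def test_large_discordance_uses_chi2(self):
        y = np.zeros(60, dtype=int)
        pa = np.zeros_like(y)
        pb = np.zeros_like(y)
        pb[:20] = 1
        pa[20:35] = 1
        r = evaluation.mcnemar_compare(pa, pb, y)
        assert r.method == "chi2"
        from scipy import stats

        assert r.p == pytest.approx(stats.chi2.sf((abs(20 - 15) - 1) ** 2 / 35, 1))


class TestDecisionCurve:
    def test_perfect_probabilities_replica_prevalence(self):
        y = np.array([1] * 46 + [0] * 77)
        p = np.where(y == 1, 0.99, 0.01)
        dca = evaluation.decision_curve(p, y)
        k = int(np.argmin(np.abs(dca.thresholds - 0.5)))
        assert dca.nb_model[k] == pytest.approx(46 / 123)

    def test_treat_all_limit_is_prevalence(self):
        y = np.array([1] * 46 + [0] * 77)
        p = np.full(123, 0.5)
        dca = evaluation.decision_curve(p, y, grid_step=0.001)
        assert dca.nb_all[0] == pytest.approx(y.mean(), abs=0.01)

    def test_treat_none_is_zero_and_bounds(self):
        rng = np.random.default_rng(2)
        y = (rng.random(200) < 0.4).astype(int)
        p = rng.uniform(0.01, 0.99, 200)
        dca = evaluation.decision_curve(p, y)
        assert np.all(dca.nb_none == 0.0)
        prevalence = y.mean()
        assert np.all(dca.nb_model <= prevalence + 1e-12)
        assert np.all(dca.nb_all <= prevalence + 1e-12)

    def test_null_scores_rarely_beneficial(self):
        """Label-independent scores should not beat both comparators over any
        sustained threshold interval (beyond grid-multiplicity flukes)."""
        nonempty = 0
        n = 2000
        for seed in range(50):
            rng = np.random.default_rng(300 + seed)
            y = (rng.random(n) < 46 / 123).astype(int)
            p = rng.uniform(0.01, 0.99, n)
            dca = evaluation.decision_curve(p, y)
            if dca.beneficial_range is not None:
                lo, hi = dca.beneficial_range
                if hi - lo > 0.02:  # longer than a couple of grid steps
                    nonempty += 1
        assert nonempty <= 5  # <= 10% false-positive ranges


class TestICC:
    def test_identical_raters_unity(self):
        x = np.arange(10.0)
        v, flag = evaluation.icc_single(np.column_stack([x, x]), "inter")
        assert v == pytest.approx(1.0)
        assert not flag

    def test_variance_ratio_half(self):
        rng = np.random.default_rng(5)
        n = 500
        subject = rng.normal(size=n)
        ratings = np.column_stack(
            [subject + rng.normal(size=n), subject + rng.normal(size=n)]
        )
        v, _ = evaluation.icc_single(ratings, "inter")
        assert v == pytest.approx(0.5, abs=0.05)

    def test_zero_between_subject_variance_flagged(self):
        x = np.ones((6, 2))
        v, flag = evaluation.icc_single(x, "inter")
        assert v == 0.0 and flag

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(6)
        n = 30
        subject = rng.normal(size=n)
        ratings = np.column_stack(
            [subject + 0.3 * rng.normal(size=n) + 0.2, subject + 0.3 * rng.normal(size=n)]
        )
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(n), 2),
                "raters": np.tile(["A", "B"], n),
                "ratings": ratings.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(df, "targets", "raters", "ratings")
        # rows: ICC(1,1), ICC(A,1) two-way random absolute, ICC(C,1) consistency
        got_inter, _ = evaluation.icc_single(ratings, "inter")
        got_intra, _ = evaluation.icc_single(ratings, "intra")
        assert got_inter == pytest.approx(ref["ICC"].iloc[1], abs=1e-9)
        assert got_intra == pytest.approx(ref["ICC"].iloc[2], abs=1e-9)

    def test_minimum_sizes(self):
        with pytest.raises(ValueError):
            evaluation.icc_single(np.ones((3, 2)), "inter")


class TestSpearman:
    def test_monotone_transform_rho_one(self):
        age = np.linspace(40, 90, 30)
        feats = pd.DataFrame({"f": np.exp(age / 30)})
        cov = pd.DataFrame({"age": age})
        out = evaluation.spearman_feature_clinical(feats, cov)
        assert out.loc[0, "rho"] == pytest.approx(1.0)

    def test_negated_covariate(self):
        age = np.linspace(40, 90, 30)
        out = evaluation.spearman_feature_clinical(
            pd.DataFrame({"f": -age}), pd.DataFrame({"age": age})
        )
        assert out.loc[0, "rho"] == pytest.approx(-1.0)

    def test_constant_column_flagged_nan(self):
        out = evaluation.spearman_feature_clinical(
            pd.DataFrame({"f": np.ones(10)}), pd.DataFrame({"age": np.arange(10.0)})
        )
        assert np.isnan(out.loc[0, "rho"])

    def test_surface_area_age_coupling_recovered(self):
        """The generator couples VOI size negatively with age; SurfaceArea's
        Spearman sign is recovered across seeds."""
        from strokerad.features.shape import shape_features
        from strokerad.synthetic import CohortSpec, PhantomSpec, generate_cohort, generate_phantom

        negative = 0
        n_seeds = 30
        for seed in range(n_seeds):
            recs = generate_cohort(CohortSpec(n_early=8, n_late=12, seed=seed))
            pspec = PhantomSpec(shape=(24, 24, 24), seed=seed)
            ages, areas = [], []
            for rec in recs:
                _, mask = generate_phantom(rec, pspec)
                ages.append(rec.covariates.age)
                areas.append(shape_features(mask)["SurfaceArea"])
            out = evaluation.spearman_feature_clinical(
                pd.DataFrame({"SurfaceArea": areas}), pd.DataFrame({"age": ages})
            )
            if out.loc[0, "rho"] < 0:
                negative += 1
        assert negative >= int(0.95 * n_seeds)
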