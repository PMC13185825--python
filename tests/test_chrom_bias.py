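"""Regression influence diagnostics, density ratios, Grubbs test and ratio PCA."""

import numpy as np
import pandas as pd
import pytest

from repsv.chrom_bias import (
    chromosome_counts,
    cook_distance_sweep,
    density_ratio_profile,
    grubbs_single_outlier,
    individual_ratio_pca,
    per_individual_x_ratio,
    regression_outlier_test,
)
from repsv.simulate import GenomeModel


def loo_oracle(x, y):
    """Leave-one-out refit oracle for externally studentized residuals and Cook's D."""
    n = len(x)
    X = np.column_stack([np.ones(n), x])
    H = X @ np.linalg.inv(X.T @ X) @ X.T
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    resid = y - X @ beta
    k = 2
    rstud = np.empty(n)
    cooks = np.empty(n)
    mse = resid @ resid / (n - k)
    yhat = X @ beta
    for i in range(n):
        keep = np.arange(n) != i
        bi = np.linalg.lstsq(X[keep], y[keep], rcond=None)[0]
        ri = y[keep] - X[keep] @ bi
        s2i = ri @ ri / (n - 1 - k)
        rstud[i] = resid[i] / np.sqrt(s2i * (1 - H[i, i]))
        yhat_i = X @ bi
        cooks[i] = ((yhat - yhat_i) ** 2).sum() / (k * mse)
    return rstud, cooks


class TestRegressionOutlierTest:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = regression_outlier_test(x, 2 * x)
        assert res.r2 == pytest.approx(1.0)
        assert np.allclose(res.studentized, 0.0, atol=1e-8)

    def test_displaced_point_flagged(self):
        x = np.arange(11.0)
        y = 3 * x + 1
        y[7] += 25
        res = regression_outlier_test(x, y)
        assert res.outlier_index == 7
        assert res.bonferroni_p < 0.05

    def test_matches_loo_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            n = int(rng.integers(6, 12))
            x = rng.normal(size=n) * 5
            y = 1.5 * x + rng.normal(size=n)
            res = regression_outlier_test(x, y)
            rstud, cooks = loo_oracle(x, y)
            assert np.allclose(res.studentized, rstud, atol=1e-10)
            assert np.allclose(res.cooks_d, cooks, atol=1e-10)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            regression_outlier_test([1, 1, 1, 1], [1, 2, 3, 4])
        with pytest.raises(ValueError):
            regression_outlier_test([1, 2, 3], [1, 2, 3])


class TestCookSweep:
    def test_linear_counts_small_distances(self, small_annotations, small_cohort):
        diags = cook_distance_sweep(small_annotations, small_cohort.genome,
                                    thresholds=(50,), mode="counts")
        assert len(diags) == 1
        assert np.all(diags[0].cooks_d < 1.0)

    def test_influential_point_exceeds_4_over_n(self):
        # 5-point fixture with one influential chromosome, checked against
        # the hat-matrix/LOO oracle
        x = np.array([1.0, 2, 3, 4, 10])
        y = np.array([1.0, 2, 3, 4, 30])
        res = regression_outlier_test(x, y)
        rstud, cooks = loo_oracle(x, y)
        assert np.allclose(res.cooks_d, cooks, atol=1e-10)
        assert res.cooks_d.argmax() == 4
        assert res.cooks_d.max() > 4 / 5

    def test_sparse_threshold_skipped(self, small_annotations, small_cohort):
        with pytest.warns(UserWarning):
            diags = cook_distance_sweep(small_annotations, small_cohort.genome,
                                        thresholds=(50, 50_000))
        assert [d.threshold for d in diags] == [50]


class TestDensityRatio:
    @staticmethod
    def _ann(chroms, svlens, reps):
        return pd.DataFrame({"chrom": chroms, "svlen": svlens, "is_rep": reps,
                             "is_young": False,
                             "state": "shared", "rep_type": ""})

    def test_relabeling_and_scale_invariance(self):
        g1 = GenomeModel((("1", 100), ("2", 100), ("3", 100), ("X", 150)))
        g2 = GenomeModel((("a", 1000), ("b", 1000), ("c", 1000), ("X", 1500)))
        ann1 = self._ann(["1", "2", "3", "X"], [100] * 4, [True] * 4)
        ann2 = self._ann(["a", "b", "c", "X"], [100] * 4, [True] * 4)
        r1 = density_ratio_profile(ann1, g1, thresholds=(50,))
        r2 = density_ratio_profile(ann2, g2, thresholds=(50,))
        assert r1["rep_ratio"][0] == pytest.approx(r2["rep_ratio"][0])

    def test_zero_x_count_gives_zero(self):
        g = GenomeModel((("1", 100), ("2", 100), ("3", 100), ("X", 150)))
        ann = self._ann(["1", "2"], [100, 100], [True, True])
        r = density_ratio_profile(ann, g, thresholds=(50,))
        assert r["rep_ratio"][0] == 0.0

    def test_unknown_chromosome_raises(self, small_cohort):
        g = small_cohort.genome
        bad = self._ann(["weird"], [100], [True])
        with pytest.raises(ValueError):
            chromosome_counts(bad, g)


class TestGrubbs:
    def test_known_outlier(self):
        v = np.array([1.0, 1, 1, 1, 10])
        g, p, flagged, shp = grubbs_single_outlier(v, labels=list("abcdX"))
        sd = v.std(ddof=1)
        assert g == pytest.approx((10 - v.mean()) / sd)
        assert flagged == "X" and p < 0.05

    def test_p_consistent_with_critical_value(self):
        # at n=5, alpha=0.05 two-sided the Grubbs critical value is ~1.715;
        # samples straddling it should straddle p=0.05
        base = np.array([0.0, -1.0, 1.0, -0.5])
        for extreme in (8.0, 4.0):
            g, p, *_ = grubbs_single_outlier(np.append(base, extreme))
            assert (p < 0.05) == (g > 1.715)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            grubbs_single_outlier([2.0, 2.0, 2.0, 2.0])


class TestRatioPCA:
    def test_rank_one_data(self):
        rng = np.random.default_rng(0)
        direction = np.array([1.0, 2.0, 3.0])
        X = pd.DataFrame(np.outer(rng.normal(size=20), direction))
        res = individual_ratio_pca(X)
        assert res.variance_explained[0] == pytest.approx(1.0)

    def test_sign_convention_and_idempotence(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(15, 4)))
        res = individual_ratio_pca(X)
        for c in res.loadings.columns:
            v = res.loadings[c].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0
        res2 = individual_ratio_pca(res.scores)
        assert np.allclose(res2.variance_explained, res.variance_explained, atol=1e-10)

    def test_constant_feature_with_scaling(self):
        X = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            individual_ratio_pca(X, scale=True)

    def test_subspecies_separate_on_pc1(self, big_genome):
        """With a strong X bias the large/small X ratio separates groups."""
        from repsv.annotate import annotate_cohort
        from repsv.simulate import CohortConfig, simulate_cohort

        cfg = CohortConfig(seed=29, n_svs=4000, x_bias=4.0)
        sim = simulate_cohort(cfg, genome=big_genome)
        ann = annotate_cohort(sim.cohort, sim.repeats, metadata=sim.metadata)
        feats = per_individual_x_ratio(ann, sim.cohort, sim.genome)
        # add a subspecies-informative feature: taurine carry private_taurine SVs
        pres = sim.cohort.presence_matrix() == 1
        priv_t = (ann["state"] == "private_taurine").to_numpy()
        priv_i = (ann["state"] == "private_indicine").to_numpy()
        feats["priv_contrast"] = pres[priv_t].sum(axis=0) - pres[priv_i].sum(axis=0)
        res = individual_ratio_pca(feats[["ratio", "priv_contrast"]], scale=True)
        lab = sim.metadata.set_index("individual").loc[feats.index, "subspecies"]
        t = res.scores.loc[(lab == "taurine").to_numpy(), "PC1"]
        i = res.scores.loc[(lab == "indicine").to_numpy(), "PC1"]
        # group means separated beyond within-group spread (positive silhouette-like gap)
        gap = abs(t.mean() - i.mean())
        assert gap > max(t.std(), i.std())
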