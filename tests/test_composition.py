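"""Compositional geometry, clustering, correlation, and PCA."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import pearsonr, rankdata
from sklearn.metrics import adjusted_rand_score

from glshet.composition import (
    aitchison_distance,
    clr,
    hierarchical_cluster,
    pca,
    replace_zeros,
    spearman_matrix,
    standardize,
)
from glshet.panels import genotype_means
from glshet.simulate import SimulationConfig, simulate_concentrations, simulate_pedigree

positive_part = st.floats(min_value=1e-3, max_value=1e3)
compositions = st.lists(positive_part, min_size=3, max_size=13).map(np.asarray)


class TestReplaceZeros:
    def test_no_zeros_unchanged(self):
        m = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], columns=["a", "b"])
        pd.testing.assert_frame_equal(replace_zeros(m), m)

    def test_multiplicative_arithmetic(self):
        # (0, 1, 1) with delta 0.01: zero → 0.01, positives shrink to keep the total
        m = pd.DataFrame([[0.0, 1.0, 1.0]], columns=list("abc"))
        out = replace_zeros(m, delta=0.01)
        assert out.iloc[0, 0] == pytest.approx(0.01)
        assert out.iloc[0, 1] == pytest.approx(0.995)
        assert out.iloc[0].sum() == pytest.approx(2.0)

    def test_strictly_positive_on_gns_fixture(self, means):
        assert (means == 0).any().any()  # the panel plants GNS-null genotypes
        out = replace_zeros(means)
        assert (out > 0).all().all()
        # row totals preserved
        assert np.allclose(out.sum(axis=1), means.sum(axis=1))

    def test_all_zero_column_errors(self):
        m = pd.DataFrame([[0.0, 1.0], [0.0, 2.0]], columns=["a", "b"])
        with pytest.raises(ValueError, match="no positive value"):
            replace_zeros(m)


class TestClr:
    def test_uniform_composition_maps_to_zero(self):
        assert np.allclose(clr(np.full(5, 0.2)), 0.0)

    def test_hand_computed_value(self):
        expected = np.array([2 * np.log(2) / 3, -np.log(2) / 3, -np.log(2) / 3])
        assert np.allclose(clr([0.5, 0.25, 0.25]), expected)

    def test_non_positive_part_rejected(self):
        with pytest.raises(ValueError):
            clr([1.0, 0.0, 1.0])

    @given(x=compositions)
    @settings(max_examples=50, deadline=None)
    def test_image_sums_to_zero(self, x):
        assert abs(clr(x).sum()) < 1e-9


class TestAitchison:
    def test_identity_and_scale_invariance(self):
        x = np.array([0.2, 0.3, 0.5])
        assert aitchison_distance(x, x) == 0.0
        assert aitchison_distance(x, 7.3 * x) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        d = aitchison_distance([0.5, 0.25, 0.25], [0.25, 0.25, 0.5])
        assert d == pytest.approx(np.sqrt(2) * np.log(2), rel=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            aitchison_distance([1, 2], [1, 2, 3])


class TestClustering:
    def test_duplicates_co_clustered(self):
        m = pd.DataFrame(
            [[1, 1, 1], [1, 1, 1], [100, 1, 0.01]], columns=list("abc"), dtype=float
        )
        res = hierarchical_cluster(m, k=2)
        assert res.labels.iloc[0] == res.labels.iloc[1] != res.labels.iloc[2]

    def test_k_exceeding_n_errors(self):
        m = pd.DataFrame([[1.0, 2.0], [2.0, 1.0]], columns=["a", "b"])
        with pytest.raises(ValueError, match="exceeds"):
            hierarchical_cluster(m, k=3)

    def test_permutation_invariance(self, means):
        comp = replace_zeros(means)
        res = hierarchical_cluster(comp, k=2)
        perm = comp.sample(frac=1.0, random_state=0)
        res_p = hierarchical_cluster(perm, k=2)
        aligned = res_p.labels.reindex(res.labels.index)
        assert adjusted_rand_score(res.labels, aligned) == 1.0

    def test_row_rescaling_invariance(self, means):
        comp = replace_zeros(means)
        scaled = comp.copy()
        scaled.iloc[0] *= 50.0
        scaled.iloc[3] *= 0.02
        a = hierarchical_cluster(comp, k=2).labels
        b = hierarchical_cluster(scaled, k=2).labels
        assert adjusted_rand_score(a, b) == 1.0

    def test_recovers_planted_3c_4c_dichotomy(self):
        cfg = SimulationConfig(seed=5, cluster_separation=0.9, replicate_cv=0.05)
        ped = simulate_pedigree(cfg)
        panel, truth = simulate_concentrations(cfg, ped)
        line_ids = [g.genotype_id for g in ped.lines]
        comp = replace_zeros(genotype_means(panel).mean.loc[line_ids])
        labels = hierarchical_cluster(comp, k=2).labels
        assert adjusted_rand_score(truth.cluster_labels[line_ids], labels[line_ids]) == 1.0


class TestStandardize:
    def test_column_z_scores(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        z = standardize(m)  # population SD = sqrt(2/3)
        assert np.allclose(z["a"], np.array([-1, 0, 1]) / np.sqrt(2 / 3))
        assert z["a"].mean() == pytest.approx(0.0, abs=1e-12)
        assert z["a"].std(ddof=0) == pytest.approx(1.0)

    def test_constant_column_zeroed_with_warning(self):
        m = pd.DataFrame({"a": [2.0, 2.0, 2.0], "b": [1.0, 2.0, 3.0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            z = standardize(m)
        assert (z["a"] == 0).all()


class TestSpearman:
    def test_monotone_pairs(self):
        m = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0], "y": [2.0, 4.0, 9.0, 16.0]})
        rho = spearman_matrix(m, include_total=False)
        assert rho.loc["x", "y"] == pytest.approx(1.0)
        rho_rev = spearman_matrix(m.assign(y=-m["y"]), include_total=False)
        assert rho_rev.loc["x", "y"] == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self, rng):
        m = pd.DataFrame(rng.integers(0, 4, size=(10, 4)).astype(float), columns=list("abcd"))
        rho = spearman_matrix(m, include_total=False)
        for i in "abcd":
            for j in "abcd":
                expected = pearsonr(rankdata(m[i]), rankdata(m[j])).statistic
                assert rho.loc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_monotone_transform_invariance(self, means):
        # ranks are unchanged by a strictly increasing transform of one column
        # (the derived total is excluded: it depends on the raw values)
        rho = spearman_matrix(means, include_total=False)
        transformed = means.copy()
        transformed["SIN"] = np.exp(transformed["SIN"] / transformed["SIN"].max())
        rho_t = spearman_matrix(transformed, include_total=False)
        pd.testing.assert_frame_equal(rho, rho_t, atol=1e-12)

    def test_total_column_present(self, means):
        rho = spearman_matrix(means)
        assert rho.shape == (14, 14)
        assert "TOTAL" in rho.columns
        assert np.allclose(np.diag(rho), 1.0)

    def test_constant_column_flagged(self):
        m = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.warns(UserWarning, match="constant"):
            rho = spearman_matrix(m, include_total=False)
        assert np.isnan(rho.loc["a", "b"])


class TestPca:
    def test_rank_one_data(self):
        rng = np.random.default_rng(1)
        t = rng.normal(size=12)
        m = pd.DataFrame(np.outer(t, [1.0, 2.0, 3.0]), columns=list("abc"))
        res = pca(m, scale_mode="raw", n_components=2)
        assert res.variance_fractions[0] == pytest.approx(1.0)

    def test_variance_fractions_monotone(self, means):
        res = pca(means)
        vf = res.variance_fractions
        assert np.all(np.diff(vf) <= 1e-12)
        assert vf.sum() <= 1.0 + 1e-12

    def test_truncation_warning(self):
        m = pd.DataFrame(np.random.default_rng(0).normal(size=(4, 6)))
        with pytest.warns(UserWarning, match="truncating"):
            pca(m, n_components=5)

    def test_recovers_planted_orthogonal_axes(self):
        rng = np.random.default_rng(0)
        n, p = 30, 13
        v1 = np.zeros(p); v1[3:8] = 1; v1 /= np.linalg.norm(v1)   # 4C-aliphatic axis
        v2 = np.zeros(p); v2[8:12] = 1; v2 /= np.linalg.norm(v2)  # indolyl axis
        scores1, scores2 = rng.normal(0, 3, n), rng.normal(0, 1.5, n)
        X = pd.DataFrame(
            10 + np.outer(scores1, v1) + np.outer(scores2, v2) + rng.normal(0, 0.05, (n, p)),
            columns=[f"c{i}" for i in range(p)],
        )
        res = pca(X, scale_mode="raw")
        assert abs(res.loadings["PC1"] @ v1) > 0.9
        assert abs(res.loadings["PC2"] @ v2) > 0.9
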