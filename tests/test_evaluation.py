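import numpy as np
import pandas as pd
import pytest

from droughteval import (
    EvaluationConfig,
    SampleMatrix,
    composite_score,
    compute_weights,
    evaluate,
    membership,
    run_pca,
    select_components,
    standardize,
)
from droughteval import fixtures
from droughteval.errors import DegenerateDataError, EvaluationError


def _matrix(values, genotypes=None, columns=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    genotypes = genotypes or [f"g{i}" for i in range(n)]
    index = pd.Index([(g, "s") for g in genotypes])
    columns = columns or [f"ind{j}" for j in range(p)]
    return SampleMatrix(pd.DataFrame(values, index=index, columns=columns))


def _random_matrix(n, p, seed):
    rng = np.random.default_rng(seed)
    return _matrix(rng.normal(size=(n, p)))


class TestStandardize:
    def test_column_moments(self):
        m = standardize(_matrix([[1, 5], [2, 9], [3, 4]]))
        assert np.allclose(m.values.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(m.values.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_idempotence(self):
        m = standardize(_random_matrix(6, 4, 0))
        again = standardize(m)
        assert np.allclose(m.values, again.values, atol=1e-12)

    def test_constant_column_names_indicator(self):
        m = _matrix([[1, 5], [2, 5], [3, 5]], columns=["Lth", "MDA"])
        with pytest.raises(DegenerateDataError, match="MDA"):
            standardize(m)

    def test_ddof_choice_does_not_change_d(self):
        m = _random_matrix(10, 18, 42)
        d0 = evaluate(m, EvaluationConfig(ddof=0)).result.per_sample["D"]
        d1 = evaluate(m, EvaluationConfig(ddof=1)).result.per_sample["D"]
        assert np.allclose(d0, d1, atol=1e-10)


class TestRunPCA:
    def test_uncorrelated_columns_give_unit_eigenvalues(self):
        x = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        pca = run_pca(_matrix(x))
        assert np.allclose(pca.eigenvalues, [1.0, 1.0], atol=1e-12)

    def test_duplicated_column_block_gives_leading_eigenvalue_two(self):
        rng = np.random.default_rng(3)
        col = rng.normal(size=6)
        other = rng.normal(size=6)
        pca = run_pca(_matrix(np.column_stack([col, col, other])))
        assert pca.eigenvalues[0] >= 2.0 - 1e-8

    def test_invariants_on_random_matrix(self):
        m = _random_matrix(10, 7, 5)
        pca = run_pca(m)
        p = len(m.indicators)
        assert pca.eigenvalues.sum() == pytest.approx(p, abs=1e-8)
        load = pca.loadings.to_numpy()
        assert np.allclose(load.T @ load, np.eye(p), atol=1e-8)
        assert np.allclose(pca.scores.to_numpy().mean(axis=0), 0.0, atol=1e-8)
        assert np.allclose(pca.variance_fraction, pca.eigenvalues / p)
        assert np.all(np.diff(pca.eigenvalues) <= 1e-12)

    def test_agrees_with_svd_oracle_up_to_sign(self):
        m = _random_matrix(6, 4, 9)
        pca = run_pca(m)
        # independent oracle: SVD of the standardized data matrix
        x = m.values
        z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
        _, s, vt = np.linalg.svd(z, full_matrices=False)
        lam = s**2 / (z.shape[0] - 1)
        assert np.allclose(pca.eigenvalues[: len(lam)], lam, atol=1e-8)
        for j in range(4):
            got = pca.loadings.iloc[:, j].to_numpy()
            want = vt[j]
            assert np.allclose(got, want, atol=1e-8) or np.allclose(
                got, -want, atol=1e-8
            )

    def test_agrees_with_sklearn_cross_check(self):
        sklearn_pca = pytest.importorskip("sklearn.decomposition").PCA
        m = _random_matrix(9, 5, 21)
        pca = run_pca(m)
        z = standardize(m).values
        ref = sklearn_pca(n_components=5).fit(z)
        assert np.allclose(pca.eigenvalues, ref.explained_variance_, atol=1e-8)
        for j in range(5):
            got = pca.loadings.iloc[:, j].to_numpy()
            want = ref.components_[j]
            assert np.allclose(got, want, atol=1e-8) or np.allclose(
                got, -want, atol=1e-8
            )

    def test_orientation_makes_largest_coefficient_positive(self):
        pca = run_pca(_random_matrix(8, 5, 1))
        for pc in pca.components:
            col = pca.loadings[pc].to_numpy()
            assert col[np.argmax(np.abs(col))] > 0

    def test_anchor_override(self):
        m = _random_matrix(8, 5, 1)
        pca = run_pca(m, anchors={"PC1": "ind2"})
        assert pca.loadings.loc["ind2", "PC1"] > 0

    def test_leading_eigenvalue_fraction_matches_published_scale(self):
        # an eigenvalue of 12.550 out of 18 indicators carries 69.7% of variance
        assert round(12.550 / 18 * 100, 1) == 69.7

    def test_too_few_samples(self):
        with pytest.raises(EvaluationError):
            run_pca(_matrix([[1.0, 2.0], [2.0, 1.0]]))


class TestSelectComponents:
    def _pca_with_fractions(self, fracs):
        fracs = np.asarray(fracs, dtype=float)
        p = fracs.size
        load = pd.DataFrame(np.eye(p), columns=[f"PC{j+1}" for j in range(p)])
        scores = pd.DataFrame(np.zeros((3, p)), columns=load.columns)
        from droughteval.evaluation import PCAResult

        return PCAResult(fracs * p, load, fracs, scores)

    def test_threshold_rule(self):
        pca = self._pca_with_fractions([0.697, 0.199, 0.037, 0.034, 0.033])
        assert select_components(pca, threshold=0.85) == ["PC1", "PC2"]

    def test_forced_count_override(self):
        pca = self._pca_with_fractions([0.697, 0.199, 0.037, 0.034, 0.033])
        assert select_components(pca, force_k=3) == ["PC1", "PC2", "PC3"]

    def test_single_component(self):
        assert select_components(self._pca_with_fractions([1.0]), 0.5) == ["PC1"]

    def test_boundary_met_exactly(self):
        pca = self._pca_with_fractions([0.5, 0.3, 0.2])
        assert select_components(pca, threshold=0.8) == ["PC1", "PC2"]


class TestMembership:
    def test_boundaries_and_midpoint(self):
        x = [2.0, 4.0, 6.0]
        assert membership(x).tolist() == [0.0, 0.5, 1.0]
        assert membership(x, "anti").tolist() == [1.0, 0.5, 0.0]

    def test_constant_column_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            membership([1.0, 1.0, 1.0])

    def test_positive_rescaling_invariance(self):
        x = np.array([3.0, -1.0, 2.5, 0.0])
        assert np.allclose(membership(x), membership(5.0 * x + 2.0), atol=1e-12)


class TestWeights:
    def test_published_variance_percentages(self):
        w = compute_weights([69.720, 19.868, 3.675])
        assert np.round(w, 3).tolist() == [0.748, 0.213, 0.039]
        assert w.sum() == pytest.approx(1.0, abs=1e-10)

    def test_equal_and_degenerate_mass(self):
        assert compute_weights([1, 1]).tolist() == [0.5, 0.5]
        assert compute_weights([5, 0, 0]).tolist() == [1.0, 0.0, 0.0]

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateDataError):
            compute_weights([0.0, 0.0])


class TestCompositeScore:
    def test_weighted_sum_of_membership_row(self):
        mu = pd.DataFrame(
            [[0.780, 0.045, 0.784]], index=pd.Index([("g", "control")])
        )
        res = composite_score(mu, [0.748, 0.213, 0.039])
        assert res.per_sample["D"].iloc[0] == pytest.approx(0.624, abs=5e-4)

    def test_all_one_membership_gives_unit_d(self):
        mu = pd.DataFrame(
            np.ones((2, 3)), index=pd.Index([("a", "s"), ("b", "s")])
        )
        res = composite_score(mu, compute_weights([3.0, 2.0, 1.0]))
        assert np.allclose(res.per_sample["D"], 1.0)

    def test_dimension_mismatch(self):
        mu = pd.DataFrame(np.ones((2, 3)), index=pd.Index([("a", "s"), ("b", "s")]))
        with pytest.raises(EvaluationError):
            composite_score(mu, [0.5, 0.5])

    def test_exact_tie_shares_dense_rank(self):
        mu = pd.DataFrame(
            [[1.0], [1.0], [0.0]],
            index=pd.Index([("a", "s"), ("b", "s"), ("c", "s")]),
        )
        res = composite_score(mu, [1.0])
        assert res.ties
        assert res.per_genotype["rank"].tolist() == [1, 1, 2]


class TestReferenceFixture:
    """Recomputation of the published camellia evaluation from its tables."""

    def test_average_d_and_ranking(self):
        result, weights = fixtures.reference_evaluation()
        avg = result.per_genotype["average_D"]
        assert avg["C. reticulata"] == pytest.approx(0.338, abs=1e-3)
        assert avg["C. sasanqua"] == pytest.approx(0.551, abs=1e-3)
        assert result.ranking == ["C. sasanqua", "C. reticulata"]
        assert np.round(weights.to_numpy(), 3).tolist() == [0.748, 0.213, 0.039]

    def test_published_membership_extremes_are_pooled(self):
        mu = fixtures.load_membership()
        # each retained component attains 0 and 1 over the pooled samples
        for col in mu.columns:
            assert mu[col].min() == 0.0 and mu[col].max() == 1.0

    def test_loading_table_shape(self):
        load = fixtures.load_loadings()
        assert load.shape == (18, 3)
        summary = fixtures.load_pca_summary()
        assert summary.loc["eigenvalue", "PC1"] == pytest.approx(12.550)


class TestEndToEnd:
    def test_pipeline_invariants_on_synthetic_data(self, sample_matrix):
        out = evaluate(sample_matrix)
        d = out.result.per_sample["D"].to_numpy()
        assert np.all((d >= 0) & (d <= 1))
        assert out.weights.sum() == pytest.approx(1.0, abs=1e-10)
        for pc in out.retained:
            col = out.membership[pc]
            assert col.min() == 0.0 and col.max() == pytest.approx(1.0)
        assert sorted(out.result.per_genotype["rank"]) == [1, 2]

    def test_d_invariant_under_positive_affine_indicator_transform(self, sample_matrix):
        base = evaluate(sample_matrix).result.per_sample["D"]
        df = sample_matrix.df.copy()
        df["MDA"] = 3.7 * df["MDA"] + 12.0
        df["Lth"] = 0.01 * df["Lth"] + 5.0
        moved = evaluate(SampleMatrix(df, registry=sample_matrix.registry))
        assert np.allclose(base, moved.result.per_sample["D"], atol=1e-10)

    def test_double_flip_identity(self, sample_matrix):
        base = evaluate(sample_matrix)
        pc1_anchor = base.pca.loadings["PC1"].abs().idxmax()
        flipped = evaluate(
            sample_matrix,
            EvaluationConfig(
                anchors={"PC1": pc1_anchor},
                membership_orientation={"PC1": "direct"},
            ),
        )
        # anchoring at the max-|loading| indicator reproduces the default
        assert np.allclose(
            base.result.per_sample["D"], flipped.result.per_sample["D"], atol=1e-12
        )
        # a sign flip of a component turns mu into 1 - mu
        anti = evaluate(
            sample_matrix, EvaluationConfig(membership_orientation={"PC1": "anti"})
        )
        assert np.allclose(
            anti.membership["PC1"], 1.0 - base.membership["PC1"], atol=1e-12
        )

    def test_with_all_components_weights_equal_variance_fractions(self):
        # needs n > p so every component has a non-degenerate score column
        m = _random_matrix(12, 5, 3)
        out = evaluate(m, EvaluationConfig(retention_threshold=1.0))
        assert len(out.retained) == 5
        assert out.pca.variance_fraction.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(out.weights, out.pca.variance_fraction, atol=1e-10)

    def test_constant_indicator_fails_with_named_error(self, sample_matrix):
        df = sample_matrix.df.copy()
        df["CRC"] = 5.0
        with pytest.raises(DegenerateDataError, match="CRC"):
            evaluate(SampleMatrix(df, registry=sample_matrix.registry))
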