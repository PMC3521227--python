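import numpy as np
import pytest

from pathagg.aggregate_projection import (
    fit_pathway_pca,
    fit_pathway_pls,
    sign_correct,
    transform_projection,
)
from pathagg.data_io import CASE, CONTROL, DataError
from pathagg.preprocess import zscale_apply, zscale_fit
from conftest import balanced_labels, collection_of, make_dataset, random_dataset


def zscaled(ds):
    params = zscale_fit(ds)
    return zscale_apply(ds, params), params


class TestSignCorrect:
    def test_positive_correlation_keeps_sign(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert sign_correct(x, x + 0.5) == +1

    def test_negative_correlation_flips(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert sign_correct(x, -x) == -1

    def test_constant_profile_defaults_positive(self):
        with pytest.warns(UserWarning):
            assert sign_correct(np.array([1.0, 2.0, 3.0]), np.zeros(3)) == +1


class TestPCA:
    def test_identical_rows_give_equal_weights_and_positive_scores(self):
        row = [0.0, 1.0, 2.0, 5.0]
        ds = make_dataset([row, row], balanced_labels(2))
        zds, params = zscaled(ds)
        model = fit_pathway_pca(zds, collection_of(["g0", "g1"]), params)
        proj = model.pathways["P0"]
        np.testing.assert_allclose(np.abs(proj.weights), [1 / np.sqrt(2)] * 2, atol=1e-9)
        pe = transform_projection(zds, model)
        mean_profile = zds.values.loc[["g0", "g1"]].mean(axis=0).to_numpy()
        r = np.corrcoef(pe.values.loc["P0"].to_numpy(), mean_profile)[0, 1]
        assert r == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self, rng):
        # scores from the fitted model vs an independent eigh route
        for _ in range(20):
            ds = random_dataset(rng, 5, 10, 10)
            zds, params = zscaled(ds)
            model = fit_pathway_pca(zds, collection_of([f"g{i}" for i in range(5)]), params)
            Z = zds.values.to_numpy().T
            corr = np.corrcoef(zds.values.to_numpy())
            vals, vecs = np.linalg.eigh(corr)
            w_oracle = vecs[:, np.argmax(vals)]
            scores_oracle = Z @ w_oracle
            scores = (
                model.pathways["P0"].sign
                * (Z @ model.pathways["P0"].weights)
            )
            # align orientation before comparing
            if np.dot(scores_oracle, scores) < 0:
                scores_oracle = -scores_oracle
            np.testing.assert_allclose(scores, scores_oracle, atol=1e-6)

    def test_score_variance_equals_top_eigenvalue(self, rng):
        ds = random_dataset(rng, 5, 10, 10)
        zds, params = zscaled(ds)
        model = fit_pathway_pca(zds, collection_of([f"g{i}" for i in range(5)]), params)
        pe = transform_projection(zds, model)
        top = np.linalg.eigvalsh(np.corrcoef(zds.values.to_numpy())).max()
        assert np.var(pe.values.loc["P0"].to_numpy(), ddof=1) == pytest.approx(top)

    def test_scores_uncorrelated_with_second_component(self, rng):
        ds = random_dataset(rng, 6, 12, 12)
        zds, params = zscaled(ds)
        model = fit_pathway_pca(zds, collection_of([f"g{i}" for i in range(6)]), params)
        Z = zds.values.to_numpy().T
        vals, vecs = np.linalg.eigh(np.corrcoef(zds.values.to_numpy()))
        second = Z @ vecs[:, np.argsort(vals)[-2]]
        first = Z @ model.pathways["P0"].weights
        assert abs(np.corrcoef(first, second)[0, 1]) < 1e-6

    def test_zero_variance_pathway_dropped(self, rng):
        ds = make_dataset(
            np.vstack([np.full((2, 6), 3.0), np.random.default_rng(0).normal(size=(2, 6))]),
            balanced_labels(3),
        )
        zds, params = zscaled(ds)
        with pytest.warns(UserWarning, match="P0"):
            model = fit_pathway_pca(zds, collection_of(["g0", "g1"], ["g2", "g3"]), params)
        assert list(model.pathways) == ["P1"]

    def test_single_member_fallback(self, rng):
        ds = random_dataset(rng, 2, 3, 3)
        zds, params = zscaled(ds)
        model = fit_pathway_pca(zds, collection_of(["g0"]), params)
        np.testing.assert_array_equal(model.pathways["P0"].weights, [1.0])


class TestPLS:
    def test_weights_match_closed_form(self, rng):
        for _ in range(10):
            ds = random_dataset(rng, 6, 8, 8)
            zds, params = zscaled(ds)
            model = fit_pathway_pls(zds, collection_of([f"g{i}" for i in range(6)]), params)
            Z = zds.values.to_numpy().T
            y = (zds.labels == CASE).to_numpy(dtype=float)
            yc = y - y.mean()
            w_closed = Z.T @ yc
            w_closed /= np.linalg.norm(w_closed)
            got = model.pathways["P0"].weights
            if np.dot(got, w_closed) < 0:
                w_closed = -w_closed
            np.testing.assert_allclose(got, w_closed, atol=1e-9)

    def test_perfectly_separating_gene_gives_monotone_scores(self):
        ds = make_dataset([[0, 0, 0, 5, 5, 5]], balanced_labels(3))
        zds, params = zscaled(ds)
        model = fit_pathway_pls(zds, collection_of(["g0"]), params)
        pe = transform_projection(zds, model)
        scores = pe.values.loc["P0"]
        assert scores.iloc[3:].min() > scores.iloc[:3].max()

    def test_label_swap_absorbed_by_sign_correction(self, rng):
        ds = random_dataset(rng, 5, 6, 6)
        swapped = make_dataset(
            ds.values.to_numpy(), [CASE if l == CONTROL else CONTROL for l in ds.labels]
        )
        col = collection_of([f"g{i}" for i in range(5)])
        zds, params = zscaled(ds)
        zsw, psw = zscaled(swapped)
        pe1 = transform_projection(zds, fit_pathway_pls(zds, col, params))
        pe2 = transform_projection(zsw, fit_pathway_pls(zsw, col, psw))
        np.testing.assert_allclose(pe1.values.to_numpy(), pe2.values.to_numpy(), atol=1e-12)

    def test_first_component_maximizes_class_covariance(self, rng):
        ds = random_dataset(rng, 5, 10, 10)
        zds, params = zscaled(ds)
        model = fit_pathway_pls(zds, collection_of([f"g{i}" for i in range(5)]), params)
        Z = zds.values.to_numpy().T
        y = (zds.labels == CASE).to_numpy(dtype=float)
        yc = y - y.mean()
        best = abs(np.dot(Z @ model.pathways["P0"].weights, yc))
        for _ in range(1000):
            v = rng.normal(size=5)
            v /= np.linalg.norm(v)
            assert abs(np.dot(Z @ v, yc)) <= best + 1e-9

    def test_no_covariance_pathway_dropped(self):
        # a gene constant across samples has zero covariance with the class
        ds = make_dataset(
            [[1, 1, 1, 1], [0, 1, 2, 3]],
            balanced_labels(2),
        )
        zds, params = zscaled(ds)
        with pytest.warns(UserWarning, match="P0"):
            model = fit_pathway_pls(zds, collection_of(["g0"], ["g1"]), params)
        assert list(model.pathways) == ["P1"]


class TestTransformProjection:
    def test_training_scores_reproduced_bit_identically(self, rng):
        ds = random_dataset(rng, 5, 6, 6)
        zds, params = zscaled(ds)
        col = collection_of([f"g{i}" for i in range(5)])
        for fit in (fit_pathway_pca, fit_pathway_pls):
            model = fit(zds, col, params)
            pe1 = transform_projection(zds, model)
            pe2 = transform_projection(zds, model)
            np.testing.assert_array_equal(pe1.values.to_numpy(), pe2.values.to_numpy())

    def test_column_permutation_equivariance(self, rng):
        ds = random_dataset(rng, 4, 5, 5)
        zds, params = zscaled(ds)
        model = fit_pathway_pca(zds, collection_of([f"g{i}" for i in range(4)]), params)
        perm = list(rng.permutation(list(zds.sample_ids)))
        pe = transform_projection(zds, model)
        pe_perm = transform_projection(zds.subset_samples(perm), model)
        np.testing.assert_allclose(
            pe_perm.values.to_numpy(), pe.values.loc[:, perm].to_numpy()
        )

    def test_missing_gene_is_error(self, rng):
        ds = random_dataset(rng, 3, 4, 4)
        zds, params = zscaled(ds)
        model = fit_pathway_pca(zds, collection_of(["g0", "g1"]), params)
        with pytest.raises(DataError, match="g1"):
            transform_projection(zds.subset_genes(["g0", "g2"]), model)

    def test_coherent_pathway_agrees_with_mean_profile(self, rng):
        # all members shift together -> projection profiles track the mean
        shift = np.concatenate([np.zeros(20), np.full(20, 2.0)])
        values = rng.normal(size=(10, 40)) * 0.5 + shift
        ds = make_dataset(values, [CONTROL] * 20 + [CASE] * 20)
        zds, params = zscaled(ds)
        col = collection_of([f"g{i}" for i in range(10)])
        mean_profile = zds.values.mean(axis=0).to_numpy()
        for fit in (fit_pathway_pca, fit_pathway_pls):
            model = fit(zds, col, params)
            scores = transform_projection(zds, model).values.loc["P0"].to_numpy()
            assert np.corrcoef(scores, mean_profile)[0, 1] > 0.9
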