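"""MRM fit and permutation machinery against independent oracles.

Oracles: closed-form OLS via statsmodels on the vectorized data; sequential
SS from successive statsmodels fits; exhaustive permutation enumeration.
"""

import itertools

import numpy as np
import pytest
import statsmodels.api as sm

from phylomrm import (
    DistanceMatrix,
    mrm_fit,
    mrm_permutation_test,
    simulate_mrm_dataset,
    variance_decomposition,
    vectorize_lower,
)
from phylomrm.matrix_regression import CollinearityError, MRMError


def random_distance_matrix(rng, n, labels=None, integer=False):
    raw = rng.integers(1, 20, size=(n, n)) if integer else rng.uniform(0.5, 10, size=(n, n))
    values = np.tril(raw.astype(float), k=-1)
    values = values + values.T
    labels = labels or tuple(f"t{i}" for i in range(n))
    return DistanceMatrix(labels, values)


class TestVectorize:
    def test_length_and_order(self):
        values = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        dm = DistanceMatrix(("a", "b", "c"), values)
        np.testing.assert_array_equal(vectorize_lower(dm), [1, 2, 3])

    def test_zero_matrix(self):
        dm = DistanceMatrix(("a", "b", "c"), np.zeros((3, 3)))
        assert np.all(vectorize_lower(dm) == 0)

    def test_relabeling_commutes_with_vectorization(self, rng):
        """Permuting rows/columns then vectorizing equals vectorizing then
        applying the induced pair permutation (checked by explicit index
        bookkeeping)."""
        n = 6
        dm = random_distance_matrix(rng, n)
        perm = list(rng.permutation(n))
        reordered = dm.reorder(tuple(dm.labels[k] for k in perm))
        direct = vectorize_lower(reordered)
        # oracle: explicit pair lookup
        expected = [
            dm.values[dm.labels.index(reordered.labels[i]), dm.labels.index(reordered.labels[j])]
            for i in range(n)
            for j in range(i)
        ]
        np.testing.assert_allclose(direct, expected)


class TestFit:
    def test_perfect_fit_single_predictor(self, rng):
        X = random_distance_matrix(rng, 8)
        res = mrm_fit(X, [X], names=["self"])
        assert res.predictors[0].coefficient == pytest.approx(1.0)
        assert res.sse == pytest.approx(0.0, abs=1e-8)
        assert res.percent_variance == pytest.approx(100.0)

    def test_independent_predictor_explains_little(self, rng):
        n = 50
        Y = random_distance_matrix(rng, n)
        X = random_distance_matrix(rng, n)
        res = mrm_fit(Y, [X])
        # independent noise: R^2 of order 1/m with m = 1225 pairs
        assert res.percent_variance < 2.0

    def test_matches_statsmodels_ols(self, rng):
        """Coefficients, SSE and sequential SS against the statsmodels oracle."""
        n = 12
        Y = random_distance_matrix(rng, n)
        Xs = [random_distance_matrix(rng, n) for _ in range(3)]
        res = mrm_fit(Y, Xs, names=["x1", "x2", "x3"])
        y = vectorize_lower(Y)
        cols = [vectorize_lower(X) for X in Xs]
        design = sm.add_constant(np.column_stack(cols))
        fit = sm.OLS(y, design).fit()
        np.testing.assert_allclose(
            [p.coefficient for p in res.predictors], fit.params[1:], rtol=1e-8
        )
        assert res.intercept == pytest.approx(fit.params[0], rel=1e-8)
        assert res.sse == pytest.approx(fit.ssr, rel=1e-8)
        assert res.sst == pytest.approx(fit.centered_tss, rel=1e-8)
        # sequential SS oracle: SSR gains over successive nested fits
        prev_ssr = 0.0
        for k, p in enumerate(res.predictors, start=1):
            sub = sm.OLS(y, sm.add_constant(np.column_stack(cols[:k]))).fit()
            ssr = sub.ess
            assert p.seq_ss == pytest.approx(ssr - prev_ssr, rel=1e-7, abs=1e-9)
            prev_ssr = ssr

    def test_partial_correlation_matches_residual_oracle(self, rng):
        n = 10
        Y = random_distance_matrix(rng, n)
        Xs = [random_distance_matrix(rng, n) for _ in range(2)]
        res = mrm_fit(Y, Xs)
        y = vectorize_lower(Y)
        x1, x2 = (vectorize_lower(X) for X in Xs)
        others = sm.add_constant(x2)
        ry = sm.OLS(y, others).fit().resid
        rx = sm.OLS(x1, others).fit().resid
        expected = np.corrcoef(ry, rx)[0, 1]
        assert res.predictors[0].partial_correlation == pytest.approx(expected, rel=1e-8)

    @pytest.mark.parametrize("trial", range(25))
    def test_additivity_sst_equals_ss_plus_sse(self, trial):
        """SST = sum(sequential SS) + SSE on randomized matrices."""
        local = np.random.default_rng(trial)
        n = int(local.integers(5, 15))
        Y = random_distance_matrix(local, n)
        Xs = [random_distance_matrix(local, n) for _ in range(int(local.integers(1, 4)))]
        res = mrm_fit(Y, Xs)
        total = sum(p.seq_ss for p in res.predictors) + res.sse
        assert total == pytest.approx(res.sst, rel=1e-8)
        sse, pct = variance_decomposition(res.sst, [p.seq_ss for p in res.predictors])
        assert sse == pytest.approx(res.sse, rel=1e-8, abs=1e-10)
        assert pct == pytest.approx(res.percent_variance, rel=1e-8)

    def test_sign_convention_positive_effect(self):
        """Larger response on predictor-1 pairs gives positive beta and
        partial correlation."""
        labels = tuple("abcdef")
        group = {"a": 0, "b": 0, "c": 0, "d": 1, "e": 1, "f": 1}
        X = np.array(
            [[0.0 if group[i] == group[j] else 1.0 for j in labels] for i in labels]
        )
        np.fill_diagonal(X, 0.0)
        rng = np.random.default_rng(5)
        noise = np.tril(rng.normal(0, 0.01, (6, 6)), -1)
        Y = 2.0 + 3.0 * X + noise + noise.T
        np.fill_diagonal(Y, 0.0)
        res = mrm_fit(
            DistanceMatrix(labels, Y), [DistanceMatrix(labels, X)], names=["grp"]
        )
        assert res.predictors[0].coefficient > 0
        assert res.predictors[0].partial_correlation > 0

    def test_collinear_predictors_named(self, rng):
        X = random_distance_matrix(rng, 6)
        X2 = DistanceMatrix(X.labels, 2.0 * X.values)
        Y = random_distance_matrix(rng, 6)
        with pytest.raises(CollinearityError, match="dup"):
            mrm_fit(Y, [X, X2], names=["orig", "dup"])

    def test_degenerate_all_zero_predictor_rejected(self, rng):
        Y = random_distance_matrix(rng, 6)
        flat = DistanceMatrix(Y.labels, np.zeros((6, 6)))
        with pytest.raises(CollinearityError):
            mrm_fit(Y, [flat], names=["flat"])

    def test_zero_variance_response_rejected(self, rng):
        X = random_distance_matrix(rng, 6)
        ones = np.ones((6, 6)) - np.eye(6)
        with pytest.raises(MRMError, match="zero variance"):
            mrm_fit(DistanceMatrix(X.labels, ones), [X])


def exhaustive_oracle(Y, Xs, names):
    """Enumerate all n! joint row/column permutations of Y and refit."""
    obs = mrm_fit(Y, Xs, names=names)
    n = Y.n
    abs_beta = np.abs([p.coefficient for p in obs.predictors])
    ss = np.array([p.seq_ss for p in obs.predictors])
    cb = np.zeros(len(Xs))
    cs = np.zeros(len(Xs))
    total = 0
    for perm in itertools.permutations(range(n)):
        total += 1
        idx = np.array(perm)
        Yp = DistanceMatrix(Y.labels, Y.values[np.ix_(idx, idx)])
        fit = mrm_fit(Yp, Xs, names=names)
        cb += np.abs([p.coefficient for p in fit.predictors]) >= abs_beta - 1e-12
        cs += np.array([p.seq_ss for p in fit.predictors]) >= ss - 1e-12
    return cb / total, cs / total


class TestPermutationTest:
    def test_perfect_fit_minimum_p(self):
        """Y = X with strictly distinct distances: only the identity
        reproduces |beta| = 1, so p attains its floor 1/(R+1)."""
        n = 6
        values = np.zeros((n, n))
        k = 1.0
        for i in range(n):
            for j in range(i + 1, n):
                values[i, j] = values[j, i] = k
                k += 1.0
        labels = tuple(f"t{i}" for i in range(n))
        Y = DistanceMatrix(labels, values)
        res = mrm_permutation_test(Y, [Y], permutations=119, seed=11, names=["self"])
        assert res.predictors[0].p_beta == pytest.approx(1.0 / 120.0)

    def test_exhaustive_matches_enumeration_oracle(self):
        """Exhaustive mode equals an independent full-enumeration oracle."""
        local = np.random.default_rng(7)
        Y = random_distance_matrix(local, 5)
        Xs = [random_distance_matrix(local, 5)]
        res = mrm_permutation_test(Y, Xs, permutations="exhaustive", names=["x"])
        pb, ps = exhaustive_oracle(Y, Xs, ["x"])
        assert res.predictors[0].p_beta == pytest.approx(pb[0])
        assert res.predictors[0].p_ss == pytest.approx(ps[0])
        assert res.randomizations == 120

    def test_exhaustive_equals_saturated_sampling(self):
        """Sampling that covers every non-identity permutation reproduces
        the exhaustive p-value exactly (n=4: 24 permutations)."""
        local = np.random.default_rng(3)
        Y = random_distance_matrix(local, 4, integer=True)
        Xs = [random_distance_matrix(local, 4, integer=True)]
        exact = mrm_permutation_test(Y, Xs, permutations="exhaustive", names=["x"])
        # draw many sampled runs; each p must be a multiple of 1/24 no
        # smaller than the exact value's floor, and a long run converges
        sampled = mrm_permutation_test(Y, Xs, permutations=23 * 400, seed=2, names=["x"])
        assert sampled.predictors[0].p_beta == pytest.approx(
            exact.predictors[0].p_beta, abs=0.02
        )
        assert sampled.predictors[0].p_ss == pytest.approx(
            exact.predictors[0].p_ss, abs=0.02
        )

    def test_observed_statistics_unchanged_by_testing(self, rng):
        Y = random_distance_matrix(rng, 8)
        Xs = [random_distance_matrix(rng, 8) for _ in range(2)]
        plain = mrm_fit(Y, Xs)
        tested = mrm_permutation_test(Y, Xs, permutations=49, seed=1)
        for a, b in zip(plain.predictors, tested.predictors):
            assert a.coefficient == pytest.approx(b.coefficient)
            assert a.seq_ss == pytest.approx(b.seq_ss)
        assert plain.sse == pytest.approx(tested.sse)

    def test_relabeling_invariance(self, rng):
        """Consistently relabeling taxa in Y and all Xs leaves every
        statistic unchanged."""
        n = 7
        Y = random_distance_matrix(rng, n)
        Xs = [random_distance_matrix(rng, n) for _ in range(2)]
        perm = list(rng.permutation(n))
        new_order = tuple(Y.labels[k] for k in perm)
        res1 = mrm_permutation_test(Y, Xs, permutations=99, seed=42)
        res2 = mrm_permutation_test(
            Y.reorder(new_order), [X.reorder(new_order) for X in Xs],
            permutations=99, seed=42,
        )
        for a, b in zip(res1.predictors, res2.predictors):
            assert a.coefficient == pytest.approx(b.coefficient)
            assert a.seq_ss == pytest.approx(b.seq_ss)
            assert a.partial_correlation == pytest.approx(b.partial_correlation)
        assert res1.sst == pytest.approx(res2.sst)

    def test_p_value_bounds(self, rng):
        Y = random_distance_matrix(rng, 8)
        Xs = [random_distance_matrix(rng, 8)]
        res = mrm_permutation_test(Y, Xs, permutations=99, seed=0)
        for p in res.predictors:
            assert 1.0 / 100.0 <= p.p_beta <= 1.0
            assert 1.0 / 100.0 <= p.p_ss <= 1.0

    def test_predictor_permutation_variant_runs(self, rng):
        Y = random_distance_matrix(rng, 8)
        Xs = [random_distance_matrix(rng, 8)]
        res = mrm_permutation_test(Y, Xs, permutations=99, seed=0, permute="predictors")
        assert res.permute == "predictors"
        assert 0 < res.predictors[0].p_beta <= 1

    def test_power_nondecreasing_in_effect_size(self):
        """Planted taxonomy effects of increasing magnitude give
        nondecreasing rejection rates at fixed n and R."""
        rates = []
        for effect in (0.0, 2.0, 8.0):
            rejections = 0
            for rep in range(20):
                Y, Xs, names = simulate_mrm_dataset(
                    16, true_betas=(effect, 0.0, 0.0), noise_sd=2.0, seed=1000 + rep
                )
                res = mrm_permutation_test(Y, Xs, permutations=99, seed=rep, names=names)
                rejections += res.predictors[0].p_beta <= 0.05
            rates.append(rejections / 20)
        assert rates[0] <= rates[1] + 0.15  # null can fluctuate slightly
        assert rates[2] >= rates[1]
        assert rates[2] > rates[0]
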