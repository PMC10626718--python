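import itertools
import math

import numpy as np
import pandas as pd
import pytest

from coexcons.ec import (
    PairedExpression,
    compare_ec_distributions,
    correlation_matrix,
    ec_from_paired,
    ec_initial,
    ec_iterate,
    ec_quantile_placement,
    run_until_converged,
    weighted_pcc,
)


def oracle_pearson_matrix(values):
    """Covariance-based reference computation."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            xi = values[i] - values[i].mean()
            xj = values[j] - values[j].mean()
            out[i, j] = (xi @ xj) / math.sqrt((xi @ xi) * (xj @ xj))
    return out


def oracle_weighted_pcc(x, y, w):
    """From-definition summation, scalar loops only."""
    sw = sum(w)
    xbar = sum(wi * xi for wi, xi in zip(w, x)) / sw
    ybar = sum(wi * yi for wi, yi in zip(w, y)) / sw
    num = sum(wi * (xi - xbar) * (yi - ybar) for wi, xi, yi in zip(w, x, y))
    dx = sum(wi * (xi - xbar) ** 2 for wi, xi in zip(w, x))
    dy = sum(wi * (yi - ybar) ** 2 for wi, yi in zip(w, y))
    return num / math.sqrt(dx) / math.sqrt(dy)


def random_corr(rng, n=10, conditions=8):
    return correlation_matrix(rng.normal(size=(n, conditions)))


class TestCorrelationMatrix:
    def test_identical_rows(self):
        vals = np.vstack([np.arange(6.0), np.arange(6.0) * 2 + 1, np.random.default_rng(0).normal(size=6)])
        r = correlation_matrix(vals)
        assert r[0, 1] == pytest.approx(1.0)

    def test_negated_row(self):
        vals = np.vstack([np.arange(6.0), -np.arange(6.0), np.random.default_rng(0).normal(size=6)])
        assert correlation_matrix(vals)[0, 1] == pytest.approx(-1.0)

    def test_matches_covariance_oracle(self, rng):
        vals = rng.normal(size=(10, 6))
        assert np.allclose(correlation_matrix(vals), oracle_pearson_matrix(vals), atol=1e-12)

    def test_symmetric_unit_diagonal(self, rng):
        r = random_corr(rng)
        assert np.allclose(r, r.T)
        assert np.allclose(np.diag(r), 1.0)
        assert (np.abs(r) <= 1.0).all()

    def test_zero_variance_row_rejected(self):
        vals = np.vstack([np.ones(5), np.arange(5.0)])
        with pytest.raises(ValueError, match="zero-variance"):
            correlation_matrix(vals)


class TestEcInitial:
    def test_identical_matrices_give_unity(self, rng):
        r = random_corr(rng)
        assert np.allclose(ec_initial(r, r), 1.0)

    def test_sign_flipped_off_diagonals_give_minus_one(self, rng):
        ra = random_corr(rng)
        rb = -ra.copy()
        np.fill_diagonal(rb, 1.0)
        assert np.allclose(ec_initial(ra, rb), -1.0)

    def test_self_entry_is_excluded(self, rng):
        # if the unit diagonal entered the rows, EC of independent matrices
        # would be biased upward; with exclusion the null is centred at 0
        means = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            means.append(ec_initial(random_corr(r, n=50, conditions=20),
                                    random_corr(r, n=50, conditions=20)).mean())
        assert abs(np.mean(means)) < 0.05

    def test_degenerate_row_yields_nan(self):
        # constant off-diagonal rows have no variance: EC_0 undefined
        ra = np.full((4, 4), 0.5)
        np.fill_diagonal(ra, 1.0)
        rb = random_corr(np.random.default_rng(1), n=4)
        ec = ec_initial(ra, rb)
        assert np.isnan(ec).all()  # every off-diagonal row of ra is constant


class TestWeightedPcc:
    def test_uniform_weights_reduce_to_pearson(self, rng):
        for _ in range(20):
            x, y = rng.normal(size=(2, 12))
            expected = np.corrcoef(x, y)[0, 1]
            assert weighted_pcc(x, y, np.ones(12)) == pytest.approx(expected, abs=1e-12)
            assert weighted_pcc(x, y, np.full(12, 0.37)) == pytest.approx(expected, abs=1e-12)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=10)
        w = rng.uniform(0.1, 2.0, size=10)
        assert weighted_pcc(x, 2.0 * x + 3.0, w) == pytest.approx(1.0, abs=1e-12)
        assert weighted_pcc(x, -0.5 * x + 1.0, w) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_summation_oracle(self, rng):
        for _ in range(20):
            x, y = rng.normal(size=(2, 9))
            w = rng.uniform(0.01, 3.0, size=9)
            assert weighted_pcc(x, y, w) == pytest.approx(
                oracle_weighted_pcc(list(x), list(y), list(w)), abs=1e-12
            )

    def test_insufficient_support(self):
        with pytest.raises(ValueError, match="insufficient support"):
            weighted_pcc(np.arange(5.0), np.arange(5.0), np.array([1.0, 1.0, 0, 0, 0]))

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            weighted_pcc(np.arange(5.0), np.arange(5.0), np.array([1.0, -0.1, 1, 1, 1]))


class TestEcIterate:
    def test_fixed_point(self, rng):
        r = random_corr(rng)
        res = ec_iterate(r, r)
        assert res.converged
        assert res.n_iterations == 1
        assert np.allclose(res.ec, 1.0)
        assert res.delta_history[0] == pytest.approx(0.0)

    def test_every_iteration_bounded(self, rng):
        ra, rb = random_corr(rng, n=20), random_corr(rng, n=20)
        res = ec_iterate(ra, rb)
        for v in res.trace:
            ok = v[~np.isnan(v)]
            assert ((ok >= -1.0) & (ok <= 1.0)).all()

    def test_permutation_invariance(self, rng):
        ra, rb = random_corr(rng, n=12), random_corr(rng, n=12)
        perm = rng.permutation(12)
        res = ec_iterate(ra, rb)
        res_p = ec_iterate(ra[np.ix_(perm, perm)], rb[np.ix_(perm, perm)])
        assert np.allclose(res_p.ec, res.ec[perm], atol=1e-10)
        assert res_p.n_iterations == res.n_iterations

    def test_symmetric_in_species(self, rng):
        ra, rb = random_corr(rng, n=12), random_corr(rng, n=12)
        assert np.allclose(ec_iterate(ra, rb).ec, ec_iterate(rb, ra).ec, atol=1e-10)

    def test_weight_support_collapse(self):
        # two anti-aligned matrices: every EC_0 is negative -> no usable weights
        rng = np.random.default_rng(5)
        ra = random_corr(rng, n=6)
        rb = -ra.copy()
        np.fill_diagonal(rb, 1.0)
        with pytest.raises(ValueError, match="weight support collapsed"):
            ec_iterate(ra, rb)

    def test_uniform_previous_ec_reduces_to_unweighted(self, rng):
        # one update step under uniform positive weights equals ec_initial
        ra, rb = random_corr(rng, n=10), random_corr(rng, n=10)
        ec0 = ec_initial(ra, rb)
        uniform = np.ones(10)
        step = [
            weighted_pcc(np.delete(ra[i], i), np.delete(rb[i], i), np.delete(uniform, i))
            for i in range(10)
        ]
        assert np.allclose(step, ec0, atol=1e-12)


class TestRunUntilConverged:
    def test_stops_at_first_delta_below_tolerance(self):
        # engineered trace: squared-change sums 0.5, 0.3, 0.09 -> stop at k=3
        ec0 = np.zeros(10)
        steps = {1: math.sqrt(0.05), 2: math.sqrt(0.03), 3: math.sqrt(0.009), 4: 99.0}

        def update(prev, k):
            return prev + steps[k]

        res = run_until_converged(update, ec0, tolerance=0.1, max_iter=50)
        assert res.converged
        assert res.n_iterations == 3
        assert res.delta_history == pytest.approx([0.5, 0.3, 0.09])

    def test_stop_rule_arithmetic(self):
        # n = 10 with every per-pair change 0.09: sum = 0.081 < 0.1 -> stop
        def update(prev, k):
            return prev + 0.09

        res = run_until_converged(update, np.zeros(10), tolerance=0.1)
        assert res.converged and res.n_iterations == 1
        assert res.delta_history[0] == pytest.approx(0.081)

    def test_max_iter_cap_flags_non_convergence(self):
        def update(prev, k):
            return prev + 1.0

        res = run_until_converged(update, np.zeros(4), tolerance=0.1, max_iter=7)
        assert not res.converged
        assert res.n_iterations == 7


class TestCompareEcDistributions:
    def test_identical_samples(self, rng):
        x = rng.normal(size=30)
        out = compare_ec_distributions(x, x)
        assert out.pvalue > 0.9

    def test_complete_separation(self):
        ec1 = np.linspace(0.5, 0.9, 20)
        ec2 = np.linspace(-0.9, -0.5, 20)
        out = compare_ec_distributions(ec1, ec2)
        assert out.u_statistic == 400.0
        assert out.pvalue < 0.01
        assert out.median1 > out.median2

    def test_agrees_with_exact_enumeration(self, rng):
        def exact_two_sided_p(x, y):
            pooled = np.concatenate([x, y])
            n1 = len(x)
            obs = sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)
            count = total = 0
            for comb in itertools.combinations(range(len(pooled)), n1):
                mask = np.zeros(len(pooled), bool)
                mask[list(comb)] = True
                u = sum((a > b) + 0.5 * (a == b) for a in pooled[mask] for b in pooled[~mask])
                mean_u = n1 * (len(pooled) - n1) / 2
                if abs(u - mean_u) >= abs(obs - mean_u) - 1e-12:
                    count += 1
                total += 1
            return count / total

        for seed in range(3):
            r = np.random.default_rng(seed)
            x = r.normal(0.4, 0.3, size=7)
            y = r.normal(0.0, 0.3, size=7)
            p_exact = exact_two_sided_p(x, y)
            p_asym = compare_ec_distributions(x, y).pvalue
            assert p_asym == pytest.approx(p_exact, abs=0.05)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            compare_ec_distributions([], [0.1])


class TestQuantilePlacement:
    def test_top_slice_fraction_one(self, rng):
        genome = np.sort(rng.normal(size=100))
        subset = genome[95:]
        assert ec_quantile_placement(genome, subset) == 1.0

    def test_below_median_fraction_zero(self, rng):
        genome = np.sort(rng.normal(size=100))
        assert ec_quantile_placement(genome, genome[:40]) == 0.0

    def test_random_subset_near_nominal(self):
        fracs = []
        for seed in range(200):
            r = np.random.default_rng(seed)
            genome = r.normal(0.0, 0.1, size=500)
            subset = r.choice(genome, size=50, replace=False)
            fracs.append(ec_quantile_placement(genome, subset, q=0.95))
        assert np.mean(fracs) == pytest.approx(0.05, abs=0.02)

    def test_small_genome_rejected(self):
        with pytest.raises(ValueError):
            ec_quantile_placement(np.arange(10.0), np.arange(3.0))


class TestPairedExpression:
    def _paired(self, n=5, conditions=6, seed=0):
        rng = np.random.default_rng(seed)
        ga = [f"a{i}" for i in range(n)]
        gb = [f"b{i}" for i in range(n)]
        return PairedExpression(
            pairs=pd.DataFrame({"gene_a": ga, "gene_b": gb}),
            matrix_a=pd.DataFrame(rng.normal(size=(n, conditions)), index=ga),
            matrix_b=pd.DataFrame(rng.normal(size=(n, conditions)), index=gb),
        )

    def test_identical_species_give_unit_ec(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(8)]
        vals = pd.DataFrame(rng.normal(size=(8, 6)), index=genes)
        paired = PairedExpression(
            pairs=pd.DataFrame({"gene_a": genes, "gene_b": genes}),
            matrix_a=vals,
            matrix_b=vals.copy(),
        )
        res = ec_from_paired(paired)
        assert np.allclose(res.ec, 1.0)
        assert ec_quantile_placement(np.repeat(res.ec, 3), res.ec) == 1.0

    def test_rejects_small_pair_sets(self):
        with pytest.raises(ValueError, match="at least 4"):
            self._paired(n=3)

    def test_rejects_misaligned_rows(self):
        p = self._paired()
        with pytest.raises(ValueError, match="aligned"):
            PairedExpression(
                pairs=p.pairs, matrix_a=p.matrix_a.iloc[::-1], matrix_b=p.matrix_b
            )
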