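"""Model fits, permutation schemes and p-value arithmetic."""

import numpy as np
import pandas as pd
import pytest

from flocknet import (
    GbiMatrix,
    fit_network_model,
    fit_node_model,
    fit_shade_thi_model,
    node_label_permute,
    permutation_pvalue,
    pre_network_permute,
    scale_covariate,
)
from flocknet.mixedmodels import fit_lmm, fit_poisson_glmm


class TestOls:
    def test_noiseless_line(self):
        thi = np.array([20.0, 22.0, 25.0, 28.0, 31.0])
        fit = fit_network_model(2 * thi + 1, thi)
        assert fit.coef("thi") == pytest.approx(2.0)
        assert fit.coef("intercept") == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_closed_form_slope(self):
        x = np.array([1.0, 2.0, 4.0, 7.0, 11.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 9.0])
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        fit = fit_network_model(y, x)
        assert fit.coef("thi") == pytest.approx(slope, abs=1e-12)

    def test_null_slope_consistent(self):
        rng = np.random.default_rng(0)
        x = rng.normal(28, 3, 10_000)
        y = rng.normal(0, 1, 10_000)
        fit = fit_network_model(y, x)
        assert abs(fit.coef("thi")) < 3 * fit.se("thi")
        assert fit.r_squared < 0.01

    def test_constant_thi_rejected(self):
        with pytest.raises(ValueError):
            fit_network_model([1.0, 2.0, 3.0], [28.0, 28.0, 28.0])


class TestScaling:
    def test_zero_mean_unit_sd(self):
        rng = np.random.default_rng(1)
        cov = scale_covariate(rng.uniform(0, 180, 500))
        assert cov.scaled.mean() == pytest.approx(0.0, abs=1e-12)
        assert cov.scaled.std(ddof=1) == pytest.approx(1.0)
        np.testing.assert_allclose(cov.squared, cov.scaled**2)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            scale_covariate([3.0, 3.0, 3.0])


class TestGaussianLmm:
    def test_matches_statsmodels_mixedlm(self):
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(42)
        G, m = 20, 12
        ids = np.repeat(np.arange(G), m)
        x = rng.normal(0, 1, G * m)
        y = 1.5 + 0.8 * x + rng.normal(0, 2.0, G)[ids] + rng.normal(0, 1.3, G * m)
        fit = fit_lmm(y, np.column_stack([np.ones_like(x), x]), ids)
        ref = smf.mixedlm(
            "y ~ x", pd.DataFrame({"y": y, "x": x, "g": ids}), groups="g"
        ).fit(reml=True)
        np.testing.assert_allclose(fit.params, np.asarray(ref.params[:2]),
                                   atol=1e-5)
        np.testing.assert_allclose(fit.se, np.asarray(ref.bse[:2]), atol=1e-4)
        assert fit.sigma_u == pytest.approx(
            np.sqrt(ref.cov_re.iloc[0, 0]), abs=1e-4
        )

    def test_no_group_variance_degenerates_to_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 300)
        ids = np.tile(np.arange(30), 10)
        y = 2.0 - 0.5 * x + rng.normal(0, 1, 300)  # no group effect at all
        X = np.column_stack([np.ones_like(x), x])
        fit = fit_lmm(y, X, ids)
        ols = sm.OLS(y, X).fit()
        np.testing.assert_allclose(fit.params, ols.params, atol=1e-6)

    def test_shade_thi_slope_recovery(self):
        # generator uses the observed field-scale effect: slope 6.88,
        # intercept SD 10, residual SD 20, 48 individuals x 82 days
        rng = np.random.default_rng(123)
        n_ind, n_days = 48, 82
        ids = np.repeat(np.arange(n_ind), n_days)
        thi = np.tile(rng.uniform(20.72, 34.29, n_days), n_ind)
        y = (
            -120.0
            + 6.88 * thi
            + rng.normal(0, 10, n_ind)[ids]
            + rng.normal(0, 20, n_ind * n_days)
        )
        fit = fit_shade_thi_model(y, thi, ids)
        assert abs(fit.coef("thi") - 6.88) < 3 * fit.se("thi")
        assert fit.random_intercept_variance == pytest.approx(100, rel=0.5)

    def test_null_slope_recovery(self):
        rng = np.random.default_rng(7)
        n_ind, n_days = 30, 40
        ids = np.repeat(np.arange(n_ind), n_days)
        thi = np.tile(rng.uniform(21, 34, n_days), n_ind)
        y = 50 + rng.normal(0, 5, n_ind)[ids] + rng.normal(0, 15, len(ids))
        fit = fit_shade_thi_model(y, thi, ids)
        assert abs(fit.coef("thi")) < 3 * fit.se("thi")


class TestPoissonGlmm:
    def test_matches_glmer_reference(self):
        """Frozen oracle: lme4::glmer(y ~ z + I(z^2) + (1|g), poisson,
        nAGQ=25) on the identical generated dataset."""
        rng = np.random.default_rng(7)
        G, m = 15, 10
        ids = np.repeat(np.arange(G), m)
        u = rng.normal(0, 0.5, G)
        z = rng.normal(0, 1, G * m)
        y = rng.poisson(np.exp(1.0 + 0.3 * z - 0.2 * z**2 + u[ids]))
        X = np.column_stack([np.ones_like(z), z, z**2])
        fit = fit_poisson_glmm(y, X, ids)
        np.testing.assert_allclose(
            fit.params, [0.921372, 0.269819, -0.192703], atol=5e-3
        )
        np.testing.assert_allclose(
            fit.se, [0.109945, 0.070599, 0.064953], atol=2e-3
        )
        assert fit.sigma_u == pytest.approx(0.3231639, abs=5e-3)

    def test_quadratic_vertex_recovered(self):
        rng = np.random.default_rng(11)
        n_ind, n_days = 48, 60
        ids = np.repeat(np.arange(n_ind), n_days)
        z = rng.normal(0, 1, len(ids))
        b, c = 0.4, -0.25
        y = rng.poisson(np.exp(1.2 + b * z + c * z**2
                               + rng.normal(0, 0.3, n_ind)[ids]))
        cov = scale_covariate(z)
        fit = fit_node_model(y, cov, ids, family="poisson")
        vertex = -fit.coef("shade") / (2 * fit.coef("shade_sq"))
        # the scaled covariate is close to z itself here (z ~ N(0,1))
        assert vertex == pytest.approx(-b / (2 * c), abs=0.35)

    def test_non_integer_counts_rejected(self):
        cov = scale_covariate(np.arange(10.0))
        with pytest.raises(ValueError):
            fit_node_model(np.linspace(0, 1, 10), cov, np.zeros(10),
                           family="poisson")

    def test_label_shuffle_centres_coefficients_on_zero(self):
        rng = np.random.default_rng(3)
        n_ind, m = 12, 8
        ids = np.repeat(np.arange(n_ind), m)
        z = rng.normal(0, 1, len(ids))
        y = rng.poisson(np.exp(1.0 + 0.5 * z))
        coefs = []
        for _ in range(50):
            zp = z[rng.permutation(len(z))]
            fit = fit_poisson_glmm(
                y, np.column_stack([np.ones_like(zp), zp]), ids
            )
            coefs.append(fit.params[1])
        coefs = np.asarray(coefs)
        assert abs(coefs.mean()) < 3 * coefs.std(ddof=1) / np.sqrt(len(coefs))


class TestNodeLabelPermute:
    def test_multiset_preserved(self):
        vals = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        out = node_label_permute(vals, seed=2)
        assert sorted(out) == sorted(vals)

    def test_all_equal_unchanged(self):
        vals = np.full(6, 2.5)
        np.testing.assert_array_equal(node_label_permute(vals, seed=0), vals)

    def test_two_values_swap_half_the_time(self):
        rng = np.random.default_rng(0)
        vals = np.array([0.0, 1.0])
        swaps = sum(
            node_label_permute(vals, seed=rng)[0] == 1.0 for _ in range(10_000)
        )
        # binomial 99% band around 5000
        assert 4871 <= swaps <= 5129

    def test_single_individual_rejected(self):
        with pytest.raises(ValueError):
            node_label_permute([1.0], seed=0)


class TestPermutationPvalue:
    def test_observed_beyond_all_nulls(self):
        assert permutation_pvalue(10.0, np.zeros(1000)) == 0.0

    def test_observed_at_null_median(self):
        null = np.concatenate([np.full(500, -1.0), np.full(500, 1.0)])
        assert permutation_pvalue(0.0, null) == 1.0

    def test_tail_count_arithmetic(self):
        null = np.concatenate([np.full(975, -1.0), np.full(25, 2.0)])
        assert permutation_pvalue(1.0, null) == pytest.approx(0.05)

    def test_two_sidedness_under_sign_flip(self):
        rng = np.random.default_rng(8)
        null = rng.normal(size=999)
        obs = 1.7
        assert permutation_pvalue(obs, null) == pytest.approx(
            permutation_pvalue(-obs, -null)
        )

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            permutation_pvalue(0.0, [])


def toy_gbi(matrix, n_inst=None):
    matrix = np.asarray(matrix, np.uint8)
    n_rows, n_ind = matrix.shape
    inst = np.arange(n_rows)
    n_inst = n_inst or n_rows
    return GbiMatrix(
        ids=[f"s{k}" for k in range(n_ind)],
        matrix=matrix,
        instant_of_row=inst,
        present=np.ones((n_ind, n_inst), bool),
        validate=False,
    )


class TestPreNetworkPermute:
    @pytest.mark.parametrize("scope", ["day", "instant"])
    def test_row_and_column_sums_conserved(self, scope):
        rng = np.random.default_rng(0)
        mats = []
        for _ in range(3):
            m = np.zeros((30, 8), np.uint8)
            for r in range(30):
                members = rng.choice(8, size=rng.integers(1, 5), replace=False)
                m[r, members] = 1
            mats.append(toy_gbi(m, n_inst=30))
        stream = pre_network_permute(mats, n_perm=20, swaps_per_step=5,
                                     seed=1, burn_in=50, swap_scope=scope)
        for perm in stream:
            for orig, p in zip(mats, perm):
                np.testing.assert_array_equal(
                    p.matrix.sum(axis=1), orig.matrix.sum(axis=1)
                )
                np.testing.assert_array_equal(
                    p.matrix.sum(axis=0), orig.matrix.sum(axis=0)
                )

    def test_instant_scope_keeps_one_group_per_instant(self):
        rng = np.random.default_rng(1)
        # 10 instants, each partitioning 6 individuals into two groups
        rows, inst = [], []
        for t in range(10):
            members = rng.permutation(6)
            cut = int(rng.integers(1, 6))
            for half in (members[:cut], members[cut:]):
                row = np.zeros(6, np.uint8)
                row[half] = 1
                rows.append(row)
                inst.append(t)
        gbi = GbiMatrix(
            ids=[f"s{k}" for k in range(6)],
            matrix=np.vstack(rows),
            instant_of_row=np.asarray(inst),
            present=np.ones((6, 10), bool),
        )
        stream = pre_network_permute([gbi], n_perm=10, swaps_per_step=5,
                                     seed=2, burn_in=40, swap_scope="instant")
        for perm in stream:
            m = perm[0].matrix
            for t in range(10):
                per_ind = m[perm[0].instant_of_row == t].sum(axis=0)
                np.testing.assert_array_equal(per_ind, np.ones(6))

    def test_checkerboard_alternates(self):
        # two singleton groups: the only legal day-scope swap exchanges
        # the members, so the chain flips state on every accepted swap
        gbi = toy_gbi(np.array([[1, 0], [0, 1]]))
        states = []
        stream = pre_network_permute([gbi], n_perm=6, swaps_per_step=1,
                                     seed=3, burn_in=0, swap_scope="day")
        for perm in stream:
            states.append(perm[0].matrix.copy())
        flipped = np.array([[0, 1], [1, 0]], np.uint8)
        original = np.array([[1, 0], [0, 1]], np.uint8)
        for k, s in enumerate(states):
            expect = flipped if k % 2 == 0 else original
            np.testing.assert_array_equal(s, expect)

    def test_day_without_legal_swap_emitted_unchanged(self):
        gbi = toy_gbi(np.array([[1, 1]]))  # single group: nothing to swap
        stream = pre_network_permute([gbi], n_perm=3, swaps_per_step=2,
                                     seed=0, burn_in=5)
        for perm in stream:
            np.testing.assert_array_equal(perm[0].matrix, gbi.matrix)

    def test_mean_sri_conserved_with_full_presence(self):
        """Group sizes are conserved, so the dyad-total of 'together' —
        hence the mean SRI under full presence — is invariant."""
        from flocknet import sri_network

        rng = np.random.default_rng(6)
        m = np.zeros((40, 4), np.uint8)
        for r in range(40):
            members = rng.choice(4, size=rng.integers(1, 4), replace=False)
            m[r, members] = 1
        gbi = toy_gbi(m, n_inst=40)
        base = sri_network(gbi)
        base_mean = base.weights[np.triu_indices(4, 1)].mean()
        stream = pre_network_permute([gbi], n_perm=15, swaps_per_step=3,
                                     seed=2, burn_in=30, swap_scope="day")
        for perm in stream:
            net = sri_network(perm[0])
            mean = net.weights[np.triu_indices(4, 1)].mean()
            assert mean == pytest.approx(base_mean, abs=1e-12)
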