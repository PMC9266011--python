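import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gwrisk.apportion import (
    ApportionmentError,
    apcs,
    bartlett_sphericity,
    fit_mlr,
    fit_pca_varimax,
    kmo_statistic,
    metal_source_contributions,
    overall_source_contributions,
    pearson_matrix,
    varimax,
)
from gwrisk.core_data import ConcentrationTable
from gwrisk.synthetic import generate, three_source_spec


def table_from(values, metals=None):
    values = np.asarray(values, dtype=float)
    metals = metals or [f"M{j}" for j in range(values.shape[1])]
    return ConcentrationTable(
        [f"s{i}" for i in range(values.shape[0])], list(metals), values
    )


# --- independent oracles ----------------------------------------------------


def kmo_oracle(R):
    """Brute-force KMO via explicit pairwise partial correlations."""
    Rinv = np.linalg.inv(R)
    m = R.shape[0]
    r2 = q2 = 0.0
    for i in range(m):
        for j in range(m):
            if i == j:
                continue
            q = -Rinv[i, j] / np.sqrt(Rinv[i, i] * Rinv[j, j])
            r2 += R[i, j] ** 2
            q2 += q**2
    return r2 / (r2 + q2)


def random_correlation(rng, m=7, n=60):
    X = rng.normal(size=(n, m)) @ rng.normal(size=(m, m))
    return np.corrcoef(X, rowvar=False)


# --- Pearson ----------------------------------------------------------------


class TestPearson:
    def test_self_correlation_is_one(self, random_table):
        corr = pearson_matrix(random_table)
        np.testing.assert_allclose(np.diag(corr.r.to_numpy()), 1.0)

    def test_anticorrelated_pair(self):
        x = np.arange(1.0, 11.0)
        t = table_from(np.column_stack([x, 100.0 - x]))
        corr = pearson_matrix(t)
        assert corr.r.iloc[0, 1] == pytest.approx(-1.0)

    def test_small_pair_against_formula(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 9.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 8.0])
        t = table_from(np.column_stack([x, y]))
        corr = pearson_matrix(t)
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        r_oracle = cov / (x.std() * y.std())
        assert corr.r.iloc[0, 1] == pytest.approx(r_oracle, rel=1e-12)
        # p-value via the t transform
        r = r_oracle
        tstat = r * np.sqrt(3 / (1 - r**2))
        p_oracle = 2 * sps.t.sf(abs(tstat), 3)
        assert corr.p.iloc[0, 1] == pytest.approx(p_oracle, rel=1e-6)

    def test_constant_column_is_nan(self):
        t = table_from(np.column_stack([np.arange(5.0), np.full(5, 2.0)]))
        corr = pearson_matrix(t)
        assert np.isnan(corr.r.iloc[0, 1])
        assert np.isnan(corr.r.iloc[1, 1])

    def test_symmetry_and_range(self, random_table):
        corr = pearson_matrix(random_table)
        R = corr.r.to_numpy()
        np.testing.assert_allclose(R, R.T, atol=1e-12)
        assert np.all(R <= 1.0 + 1e-12) and np.all(R >= -1.0 - 1e-12)


# --- KMO and Bartlett -------------------------------------------------------


class TestKmo:
    def test_two_variables_exactly_half(self, rng):
        R = random_correlation(rng, m=2)
        assert kmo_statistic(R) == pytest.approx(0.5, abs=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(5):
            R = random_correlation(rng)
            assert kmo_statistic(R) == pytest.approx(kmo_oracle(R), rel=1e-10)

    def test_near_singular_block(self, rng):
        # two nearly duplicated variables: still matches the oracle
        x = rng.normal(size=200)
        X = np.column_stack([x, x + 1e-4 * rng.normal(size=200), rng.normal(size=200)])
        R = np.corrcoef(X, rowvar=False)
        assert kmo_statistic(R) == pytest.approx(kmo_oracle(R), rel=1e-8)

    def test_in_unit_interval(self, rng):
        for _ in range(5):
            v = kmo_statistic(random_correlation(rng))
            assert 0.0 <= v <= 1.0


class TestBartlett:
    def test_identity_matrix(self):
        chi2, dof, p = bartlett_sphericity(np.eye(7), 60)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert dof == 21
        assert p == pytest.approx(1.0)

    def test_against_direct_formula(self):
        R = np.array([[1.0, 0.6], [0.6, 1.0]])
        chi2, dof, p = bartlett_sphericity(R, 60)
        oracle = -(60 - 1 - (2 * 2 + 5) / 6) * np.log(np.linalg.det(R))
        assert chi2 == pytest.approx(oracle, rel=1e-12)
        assert dof == 1
        assert p == pytest.approx(sps.chi2.sf(oracle, 1), rel=1e-12)

    def test_dof_for_seven_metals(self, random_table):
        corr = pearson_matrix(random_table)
        _, dof, _ = bartlett_sphericity(corr, random_table.n_sites)
        assert dof == 21

    def test_requires_more_sites_than_metals(self):
        with pytest.raises(ApportionmentError):
            bartlett_sphericity(np.eye(7), 7)


# --- PCA + varimax ----------------------------------------------------------


class TestPcaVarimax:
    def test_recovers_three_blocks(self, benchmark_table):
        table, truth = benchmark_table
        model = fit_pca_varimax(table, retention=3)
        assert model.n_components == 3
        # every metal's largest |loading| is on the same component as the
        # other members of its generating block
        comp_of = {
            m: model.loadings.loc[m].abs().idxmax() for m in table.metals
        }
        # Zn is cross-loaded by design, so it is excluded from the strict check
        assert comp_of["Cu"] == comp_of["Pb"]
        assert comp_of["Mn"] == comp_of["Cd"]
        assert comp_of["Fe"] == comp_of["Cr"]
        assert len({comp_of["Cu"], comp_of["Mn"], comp_of["Fe"]}) == 3

    def test_duplicate_columns_first_eigenvalue(self, rng):
        x = rng.lognormal(size=50)
        t = table_from(np.column_stack([x, x, rng.lognormal(size=50)]))
        model = fit_pca_varimax(t, retention=2)
        assert model.eigenvalues[0] >= 2.0 - 1e-9

    def test_cumulative_equals_sum(self, benchmark_table):
        model = fit_pca_varimax(benchmark_table[0], retention=3)
        assert model.cumulative_percent == pytest.approx(
            model.explained_percent.sum(), rel=1e-12
        )
        assert model.cumulative_percent <= 100.0 + 1e-9

    def test_varimax_preserves_communalities(self, benchmark_table):
        model = fit_pca_varimax(benchmark_table[0], retention=3)
        pre = (model.unrotated_loadings.to_numpy() ** 2).sum(axis=1)
        post = (model.loadings.to_numpy() ** 2).sum(axis=1)
        np.testing.assert_allclose(pre, post, rtol=1e-10)
        # total explained variance also preserved
        assert pre.sum() == pytest.approx(post.sum(), rel=1e-10)

    def test_varimax_rotation_is_orthogonal(self, rng):
        L = rng.normal(size=(7, 3))
        rotated, R = varimax(L)
        np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(
            (L**2).sum(axis=1), (rotated**2).sum(axis=1), rtol=1e-10
        )

    def test_sign_convention(self, benchmark_table):
        model = fit_pca_varimax(benchmark_table[0], retention=3)
        for c in model.component_names:
            col = model.loadings[c]
            assert col[col.abs().idxmax()] > 0

    def test_kaiser_retention(self, benchmark_table):
        model = fit_pca_varimax(benchmark_table[0], retention="kaiser")
        assert model.n_components == int(np.sum(model.eigenvalues > 1.0))

    def test_constant_column_rejected(self):
        t = table_from(np.column_stack([np.arange(10.0), np.full(10, 3.0)]))
        with pytest.raises(ApportionmentError, match="constant"):
            fit_pca_varimax(t, retention=1)


# --- APCS -------------------------------------------------------------------


class TestApcs:
    def test_zero_sample_scores_zero(self, benchmark_table):
        table, _ = benchmark_table
        model = fit_pca_varimax(table, retention=3)
        # scoring an artificial all-zero site through the same path
        zero = ConcentrationTable(
            ["zero"], list(table.metals), np.zeros((1, table.n_metals))
        )
        scores = apcs(model, zero)
        np.testing.assert_allclose(scores.scores.to_numpy(), 0.0, atol=1e-12)

    def test_site_at_mean(self, benchmark_table):
        table, _ = benchmark_table
        model = fit_pca_varimax(table, retention=3)
        mean_site = ConcentrationTable(
            ["mean"], list(table.metals), model.means[None, :]
        )
        scores = apcs(model, mean_site)
        # z = 0 → APCS = −score(zero-sample) = Σ W_ki · mean_i/sd_i
        oracle = (model.means / model.sds) @ model.score_coefficients.to_numpy()
        np.testing.assert_allclose(scores.scores.to_numpy()[0], oracle, rtol=1e-10)

    def test_shift_linearity(self, benchmark_table):
        table, _ = benchmark_table
        model = fit_pca_varimax(table, retention=3)
        base = apcs(model, table).scores.to_numpy()
        shifted_values = table.values.copy()
        shifted_values[:, 0] += 5.0
        shifted = ConcentrationTable(
            list(table.site_ids), list(table.metals), shifted_values
        )
        out = apcs(model, shifted).scores.to_numpy()
        delta = out - base
        # identical shift across all sites
        np.testing.assert_allclose(
            delta, np.tile(delta[0], (delta.shape[0], 1)), rtol=1e-9, atol=1e-12
        )

    def test_metal_mismatch_rejected(self, benchmark_table):
        table, _ = benchmark_table
        model = fit_pca_varimax(table, retention=3)
        other = table_from(table.values[:, :3], metals=["A", "B", "C"])
        with pytest.raises(ApportionmentError):
            apcs(model, other)


# --- MLR and contributions --------------------------------------------------


class TestMlr:
    def test_noiseless_recovery(self, benchmark_table, rng):
        table, _ = benchmark_table
        model = fit_pca_varimax(table, retention=3)
        scores = apcs(model, table)
        A = scores.scores.to_numpy()
        beta = rng.uniform(0.5, 2.0, size=(3, 4))
        intercept = np.array([1.0, 2.0, 3.0, 4.0])
        constructed = table_from(intercept + A @ beta)
        reg = fit_mlr(scores, constructed)
        np.testing.assert_allclose(reg.coefficients.to_numpy(), beta.T, rtol=1e-8)
        np.testing.assert_allclose(reg.intercepts.to_numpy(), intercept, rtol=1e-8)
        np.testing.assert_allclose(reg.r_squared.to_numpy(), 1.0, atol=1e-10)

    def test_fit_identity(self, benchmark_table):
        table, _ = benchmark_table
        model = fit_pca_varimax(table, retention=3)
        scores = apcs(model, table)
        reg = fit_mlr(scores, table)
        A = scores.scores.to_numpy()
        rebuilt = reg.intercepts.to_numpy() + A @ reg.coefficients.to_numpy().T
        np.testing.assert_allclose(
            reg.predicted.to_numpy(), rebuilt, rtol=1e-12, atol=1e-12
        )

    def test_pure_noise_low_r2(self):
        r2s = []
        for seed in range(5):
            # independent stream for the noise column (the generator consumes
            # the seed's own stream)
            rng = np.random.default_rng(10_000 + seed)
            table, _ = generate(three_source_spec(seed=seed, noise_cv=0.1))
            model = fit_pca_varimax(table, retention=3)
            scores = apcs(model, table)
            noise_col = rng.normal(10.0, 1.0, size=table.n_sites).clip(min=0.1)
            values = np.column_stack([table.values, noise_col])
            extended = ConcentrationTable(
                list(table.site_ids), list(table.metals) + ["X"], values
            )
            reg = fit_mlr(scores, extended)
            r2s.append(reg.r_squared["X"])
        assert np.mean(r2s) < 0.2

    def test_predicted_measured_ratio_near_one(self, benchmark_table):
        table, _ = benchmark_table
        model = fit_pca_varimax(table, retention=3)
        scores = apcs(model, table)
        reg = fit_mlr(scores, table)
        np.testing.assert_allclose(
            reg.predicted_measured_ratio.to_numpy(), 1.0, rtol=1e-9
        )

    def test_collinear_apcs_rejected(self, benchmark_table):
        table, _ = benchmark_table
        model = fit_pca_varimax(table, retention=3)
        scores = apcs(model, table)
        scores.scores.iloc[:, 1] = scores.scores.iloc[:, 0]
        with pytest.raises(ApportionmentError, match="collinear"):
            fit_mlr(scores, table)


class TestContributions:
    def _pipeline(self, seed=11, noise=0.1):
        table, truth = generate(three_source_spec(seed=seed, noise_cv=noise))
        model = fit_pca_varimax(table, retention=3)
        scores = apcs(model, table)
        reg = fit_mlr(scores, table)
        return table, truth, scores, reg

    def test_single_source_all_attributed(self):
        # concentrations exactly proportional to one (everywhere-positive)
        # APCS column, zero intercept → that source carries 100%
        table, _, scores, _ = self._pipeline()
        A = scores.scores.to_numpy()
        j = int(np.argmax(A.min(axis=0)))     # a column with all entries > 0
        assert A[:, j].min() > 0
        comp = scores.component_names[j]
        single = table_from(np.column_stack([2.0 * A[:, j], 3.0 * A[:, j]]))
        reg = fit_mlr(scores, single)
        contribs = metal_source_contributions(reg, scores)
        shares = contribs.per_metal_percent
        assert shares.iloc[0][comp] == pytest.approx(100.0, abs=1e-6)
        assert shares.iloc[1][comp] == pytest.approx(100.0, abs=1e-6)

    def test_shares_plus_residual_sum_100(self):
        _, _, scores, reg = self._pipeline()
        contribs = metal_source_contributions(reg, scores)
        sums = contribs.per_metal_percent.sum(axis=1)
        np.testing.assert_allclose(sums, 100.0, atol=1e-9)

    def test_equal_terms_split_evenly(self):
        # two metals each built from one source with equal mean terms
        table, _, scores, _ = self._pipeline()
        A = scores.scores.to_numpy()
        m1 = A[:, 0] / A[:, 0].mean()
        m2 = A[:, 1] / A[:, 1].mean()
        built = table_from(np.column_stack([m1 + m2]))
        model = fit_pca_varimax(table, retention=3)
        sc = apcs(model, table)
        reg = fit_mlr(sc, built)
        contribs = metal_source_contributions(reg, sc)
        row = contribs.per_metal_percent.iloc[0]
        assert row["PC1"] == pytest.approx(row["PC2"], abs=1e-6)

    def test_overall_single_source(self):
        _, _, scores, reg = self._pipeline()
        contribs = metal_source_contributions(reg, scores)
        forced = contribs.per_metal_percent.copy()
        forced[contribs.source_names] = 0.0
        forced["PC1"] = 100.0
        contribs.per_metal_percent = forced
        overall = overall_source_contributions(contribs)
        assert overall["PC1"] == pytest.approx(100.0)

    def test_overall_symmetry(self):
        _, _, scores, reg = self._pipeline()
        contribs = metal_source_contributions(reg, scores)
        two = contribs.per_metal_percent.iloc[:2].copy()
        two.loc[:, :] = 0.0
        two.iloc[0, two.columns.get_loc("PC1")] = 80.0
        two.iloc[0, two.columns.get_loc("PC2")] = 20.0
        two.iloc[1, two.columns.get_loc("PC1")] = 20.0
        two.iloc[1, two.columns.get_loc("PC2")] = 80.0
        contribs.per_metal_percent = two
        overall = overall_source_contributions(contribs)
        assert overall["PC1"] == pytest.approx(50.0)
        assert overall["PC2"] == pytest.approx(50.0)

    def test_overall_sums_100(self):
        _, _, scores, reg = self._pipeline()
        contribs = metal_source_contributions(reg, scores)
        overall = overall_source_contributions(contribs)
        assert overall.sum() == pytest.approx(100.0, abs=1e-9)
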