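import numpy as np
import pytest
import statsmodels.api as sm
from scipy.stats import chi2, kstest

from gweistat import (
    DesignBundle,
    TestedDesign,
    fit_null,
    gaussian_rescale,
    genome_scan,
    joint_gxe_stat,
    marginal_stat,
    simulate_genotypes,
)


def _geno(n, L, seed):
    return simulate_genotypes(n, L, seed).dosages.astype(float)


class TestJointStat:
    def test_monomorphic_locus_skipped(self, gaussian_fixture):
        bundle, fit = gaussian_fixture
        g = np.zeros(bundle.n)
        assert np.isnan(joint_gxe_stat(TestedDesign(g, bundle.X), fit))

    def test_invariant_to_affine_environment(self, gaussian_fixture):
        """Score statistic unchanged by invertible recoding of E in X,
        because Z contains X and the tested span is preserved."""
        bundle, _ = gaussian_fixture
        g = _geno(bundle.n, 1, 1)[:, 0]
        E = bundle.X[:, 1]
        t_ref = joint_gxe_stat(TestedDesign(g, bundle.X), fit_null(bundle))
        X2 = np.column_stack([np.ones(bundle.n), 3.0 - 2.0 * E])
        Z2 = np.column_stack([bundle.Z[:, :2], X2[:, 1]])
        b2 = DesignBundle(y=bundle.y, Z=Z2, X=X2, family=bundle.family)
        t2 = joint_gxe_stat(TestedDesign(g, X2), fit_null(b2))
        assert t2 == pytest.approx(t_ref, abs=1e-8)

    @pytest.mark.parametrize("family", ["gaussian", "binomial"])
    def test_matches_glm_rao_score(self, family, gaussian_fixture, binomial_fixture):
        """Independent oracle: statsmodels' generic GLM score test of the
        2-column added block.  The gaussian quadratic form carries unit
        dispersion, so the statsmodels statistic is rescaled by the null
        fit's estimated scale."""
        bundle, fit = gaussian_fixture if family == "gaussian" else binomial_fixture
        G = _geno(bundle.n, 5, 2)
        E = bundle.X[:, 1]
        fam = (
            sm.families.Gaussian() if family == "gaussian" else sm.families.Binomial()
        )
        null = sm.GLM(bundle.y, bundle.Z, family=fam).fit()
        for j in range(G.shape[1]):
            g = G[:, j]
            W = np.column_stack([g, g * E])
            mine = joint_gxe_stat(TestedDesign(g, bundle.X), fit)
            ref, _, _ = null.model.score_test(null.params, exog_extra=W)
            ref = float(np.ravel(ref)[0])
            if family == "gaussian":
                ref *= null.scale
            assert mine == pytest.approx(ref, abs=1e-8)


class TestMarginalStat:
    def test_specializes_joint_with_ones(self, gaussian_fixture):
        bundle, fit = gaussian_fixture
        G = _geno(bundle.n, 100, 3)
        ones = np.ones((bundle.n, 1))
        for j in range(G.shape[1]):
            tj = joint_gxe_stat(TestedDesign(G[:, j], ones), fit)
            tm = marginal_stat(G[:, j], fit)
            assert tm == pytest.approx(tj, abs=1e-10)

    def test_explicit_residualization_oracle(self, gaussian_fixture):
        """((Qg)'y)^2 / (g'Qg) assembled by direct least-squares
        residualization of g on Z."""
        bundle, fit = gaussian_fixture
        g = _geno(bundle.n, 1, 4)[:, 0]
        beta, *_ = np.linalg.lstsq(bundle.Z, g, rcond=None)
        qg = g - bundle.Z @ beta
        expected = float((qg @ bundle.y) ** 2 / (qg @ qg))
        assert marginal_stat(g, fit) == pytest.approx(expected, abs=1e-8)

    def test_orthogonal_genotype_gives_zero(self, gaussian_fixture):
        bundle, fit = gaussian_fixture
        # build g orthogonal to the projected residual but not in span(Z)
        rng = np.random.default_rng(9)
        g = rng.standard_normal(bundle.n)
        g = fit.project_complement(g)
        g -= (g @ fit.q_u) / (fit.q_u @ fit.q_u) * fit.q_u
        assert marginal_stat(g, fit) == pytest.approx(0.0, abs=1e-12)

    def test_constant_genotype_skipped(self, gaussian_fixture):
        _, fit = gaussian_fixture
        assert np.isnan(marginal_stat(np.ones(fit.n), fit))


class TestGaussianRescale:
    def test_zero_maps_to_zero(self):
        assert gaussian_rescale(0.0, 10.0, 100) == 0.0

    def test_plug_in(self):
        assert gaussian_rescale(5.0, 10.0, 100) == pytest.approx(100.0)

    def test_monotone_in_t(self):
        grid = np.linspace(0, 9, 50)
        vals = gaussian_rescale(grid, 10.0, 100)
        assert np.all(np.diff(vals) > 0)

    def test_degenerate_raises(self):
        with pytest.raises(ValueError):
            gaussian_rescale(10.0, 10.0, 100)


class TestGenomeScan:
    def test_monomorphic_locus_excluded_from_means(self, gaussian_fixture):
        bundle, fit = gaussian_fixture
        G = _geno(bundle.n, 3, 5)
        G[:, 1] = 0.0
        res = genome_scan(G, bundle, fit)
        assert res.n_skipped == 1
        assert np.isnan(res.t[1]) and np.isfinite(res.t[[0, 2]]).all()
        finite_T = res.T[np.isfinite(res.T)]
        assert res.l_mean == pytest.approx(finite_T.mean() / 2)

    def test_all_skipped_raises(self, gaussian_fixture):
        bundle, fit = gaussian_fixture
        with pytest.raises(ValueError):
            genome_scan(np.zeros((bundle.n, 3)), bundle, fit)

    def test_null_calibration(self, large_gaussian_fixture):
        """Correct gaussian null: l_mean within 3 Monte-Carlo SEs of 1."""
        bundle, fit = large_gaussian_fixture
        G = _geno(bundle.n, 2000, 6)
        res = genome_scan(G, bundle, fit)
        se = np.nanstd(res.T) / np.sqrt(2000) / res.p_df
        assert abs(res.l_mean - 1.0) < 3 * se + 0.02

    def test_chi2_distribution_under_null(self, large_gaussian_fixture):
        """Empirical t_l distribution consistent with chi-squared(p)."""
        bundle, fit = large_gaussian_fixture
        G = _geno(bundle.n, 5000, 12)
        res = genome_scan(G, bundle, fit)
        stat = res.T[np.isfinite(res.T)]
        assert kstest(stat, chi2(df=2).cdf).pvalue > 0.001

    def test_engines_agree(self, binomial_fixture):
        bundle, fit = binomial_fixture
        G = _geno(bundle.n, 60, 7)
        G[:, 5] = 0.0  # degenerate locus handled identically
        t_loop = genome_scan(G, bundle, fit, engine="loop").t
        t_vec = genome_scan(G, bundle, fit, engine="vectorized").t
        np.testing.assert_allclose(t_loop, t_vec, atol=1e-10)

    def test_invariance_to_locus_order_and_sample_permutation(
        self, gaussian_fixture
    ):
        bundle, fit = gaussian_fixture
        G = _geno(bundle.n, 20, 8)
        base = genome_scan(G, bundle, fit)
        order = np.random.default_rng(1).permutation(20)
        reordered = genome_scan(G[:, order], bundle, fit)
        np.testing.assert_allclose(reordered.t, base.t[order], atol=1e-10)
        assert reordered.l_mean == pytest.approx(base.l_mean, abs=1e-12)
        perm = np.random.default_rng(2).permutation(bundle.n)
        b2 = DesignBundle(y=bundle.y[perm], Z=bundle.Z[perm], X=bundle.X[perm])
        res2 = genome_scan(G[perm], b2, fit_null(b2))
        np.testing.assert_allclose(res2.t, base.t, atol=1e-8)

    def test_missing_dosages_mean_imputed(self, gaussian_fixture):
        bundle, fit = gaussian_fixture
        G = _geno(bundle.n, 4, 9)
        Gm = G.copy()
        Gm[:5, 2] = np.nan
        Gi = G.copy()
        Gi[:5, 2] = np.nanmean(Gm[:, 2])
        np.testing.assert_allclose(
            genome_scan(Gm, bundle, fit).t, genome_scan(Gi, bundle, fit).t,
            atol=1e-12,
        )
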