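import numpy as np
import pandas as pd
import pytest
from scipy import stats

from divscan import (
    AssocResult,
    GeneSet,
    Kinship,
    SimConfig,
    annotate_hits,
    assoc_scan,
    fit_null_lmm,
    kinship_matrix,
    significant_snps,
    simulate_frequencies,
    simulate_genotypes,
    simulate_phenotypes,
    structure_covariates,
)

from conftest import make_gm


def sim_cohort(seed, n_a=100, n_b=100, **kw):
    defaults = dict(
        chrom_length=200_000, snp_density=0.005, f_background=0.05,
        ld_decay_length=0, h2_background=0.0,
    )
    defaults.update(kw)
    cfg = SimConfig(seed=seed, n_pop_a=n_a, n_pop_b=n_b, **defaults)
    truth = simulate_frequencies(cfg)
    gm = simulate_genotypes(truth, cfg)
    return cfg, truth, gm


class TestKinship:
    def test_single_site_outer_product(self):
        gm = make_gm(np.array([[0, 2]]))
        K = kinship_matrix(gm).K
        assert np.allclose(K, [[1, -1], [-1, 1]])

    def test_identical_samples_identical_rows(self):
        gm = make_gm(np.array([[0, 0, 2], [1, 1, 0], [2, 2, 1]]))
        K = kinship_matrix(gm).K
        assert np.allclose(K[0], K[1])

    def test_symmetric_on_random_input(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(100, 20)).astype(np.int8)
        d[rng.random(d.shape) < 0.05] = -1
        K = kinship_matrix(make_gm(d)).K
        assert np.allclose(K, K.T)

    def test_monomorphic_only_error(self):
        with pytest.raises(ValueError):
            kinship_matrix(make_gm(np.zeros((3, 4))))


class TestStructureCovariates:
    def test_pc1_separates_populations(self):
        _, _, gm = sim_cohort(1, n_a=20, n_b=20, f_background=0.2)
        X = structure_covariates(kinship_matrix(gm), n_pc=1)
        pc1 = X[:, 1]
        pops = np.array([gm.pop_of[s] for s in gm.samples])
        assert len({np.sign(v) for v in pc1[pops == "A"]}) == 1
        assert np.sign(pc1[pops == "A"][0]) != np.sign(pc1[pops == "B"][0])

    def test_zero_pcs_intercept_only(self):
        gm = make_gm(np.array([[0, 1, 2]]))
        X = structure_covariates(gm, n_pc=0)
        assert X.shape == (3, 1) and np.all(X == 1)

    def test_deterministic_sign(self):
        _, _, gm = sim_cohort(2, n_a=15, n_b=15)
        X1 = structure_covariates(kinship_matrix(gm), n_pc=2)
        X2 = structure_covariates(kinship_matrix(gm), n_pc=2)
        assert np.array_equal(X1, X2)

    def test_too_many_pcs(self):
        gm = make_gm(np.array([[0, 1, 2]]))
        with pytest.raises(ValueError):
            structure_covariates(gm, n_pc=3)


def ols_reml_loglik(y, X):
    n, p = X.shape
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    s2 = rss / (n - p)
    _, logdet = np.linalg.slogdet(X.T @ X)
    return -0.5 * ((n - p) * (np.log(2 * np.pi * s2) + 1.0) + logdet)


class TestNullModel:
    def test_identity_kinship_collapses_to_ols(self):
        rng = np.random.default_rng(3)
        n = 60
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ np.array([1.0, 0.5]) + rng.standard_normal(n)
        fit = fit_null_lmm(y, X, Kinship([str(i) for i in range(n)], np.eye(n)))
        assert fit.loglik == pytest.approx(ols_reml_loglik(y, X), abs=1e-6)

    def test_pure_noise_low_heritability(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 300
            Z = rng.standard_normal((n, 400))
            K = Z @ Z.T / 400
            y = rng.standard_normal(n)
            fit = fit_null_lmm(y, np.ones((n, 1)), Kinship([str(i) for i in range(n)], K))
            hits += fit.sigma_g2 / (fit.sigma_g2 + fit.sigma_e2) <= 0.1
        assert hits >= 8

    def test_equal_variance_recovery(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n = 500
            Z = rng.standard_normal((n, 600))
            K = Z @ Z.T / 600
            L = np.linalg.cholesky(K + 1e-9 * np.eye(n))
            y = L @ rng.standard_normal(n) + rng.standard_normal(n)
            fit = fit_null_lmm(y, np.ones((n, 1)), Kinship([str(i) for i in range(n)], K))
            h2 = fit.sigma_g2 / (fit.sigma_g2 + fit.sigma_e2)
            hits += 0.3 <= h2 <= 0.7
        assert hits >= 8

    def test_rank_deficient_design_rejected(self):
        n = 20
        X = np.column_stack([np.ones(n), np.ones(n)])
        with pytest.raises(ValueError, match="rank"):
            fit_null_lmm(np.zeros(n), X, Kinship([str(i) for i in range(n)], np.eye(n)))


class TestAssocScan:
    def test_matches_ols_with_identity_kinship(self):
        """With K = I and negligible fitted genetic variance the GLS Wald
        p-values equal ordinary least-squares Wald p-values (direct OLS
        oracle computed in the test)."""
        rng = np.random.default_rng(5)
        n, m = 120, 30
        d = rng.integers(0, 3, size=(m, n)).astype(np.int8)
        gm = make_gm(d)
        y = rng.standard_normal(n)
        X = np.ones((n, 1))
        kin = Kinship(gm.samples, np.eye(n))
        res = assoc_scan(gm, y, X=X, kin=kin)
        for k, row in res.table.iterrows():
            g = d[(gm.pos == row["pos"]).argmax()].astype(float)
            Xg = np.column_stack([X, g])
            beta, _, _, _ = np.linalg.lstsq(Xg, y, rcond=None)
            r = y - Xg @ beta
            s2 = float(r @ r) / (n - 2)
            cov = s2 * np.linalg.inv(Xg.T @ Xg)
            wald = beta[1] ** 2 / cov[1, 1]
            p_ols = stats.chi2.sf(wald, 1)
            assert row["wald_p"] == pytest.approx(p_ols, rel=1e-6)

    def test_beta_halves_when_dosage_doubles(self):
        rng = np.random.default_rng(6)
        n = 80
        half = rng.integers(0, 2, size=n)  # 0/1 pattern
        d = np.vstack([half, 2 * half]).astype(np.int8)
        gm = make_gm(d)
        y = rng.standard_normal(n) + half
        res = assoc_scan(gm, y, X=np.ones((n, 1)), kin=Kinship(gm.samples, np.eye(n)))
        b = res.table.set_index("pos")["beta"]
        assert b.loc[200] == pytest.approx(b.loc[100] / 2)

    def test_type_i_error_calibrated(self):
        pooled = []
        for seed in range(3):
            cfg, truth, gm = sim_cohort(seed)
            y = simulate_phenotypes(gm, truth, cfg)["trait"].to_numpy()
            kin = kinship_matrix(gm)
            res = assoc_scan(gm, y, X=structure_covariates(kin, 2), kin=kin)
            pooled.append(res.table["wald_p"].to_numpy())
        p = np.concatenate(pooled)
        frac = (p < 0.01).mean()
        assert 0.005 <= frac <= 0.02

    def test_structured_confounding_controlled(self):
        """Population-shifted phenotypes: with kinship + structure
        covariates the median Wald statistic stays in the central
        chi-square band, while naive OLS without correction is inflated."""
        lo, hi = stats.chi2.ppf([0.3, 0.7], 1)
        for seed in range(5):
            _, _, gm = sim_cohort(seed + 10, n_a=50, n_b=50, f_background=0.2)
            rng = np.random.default_rng(seed)
            pops = np.array([gm.pop_of[s] for s in gm.samples])
            y = (pops == "B") * 1.0 + rng.standard_normal(gm.n_samples)
            kin = kinship_matrix(gm)
            res = assoc_scan(gm, y, X=structure_covariates(kin, 2), kin=kin)
            med = np.median((res.table["beta"] / res.table["se"]) ** 2)
            assert lo <= med <= hi
            # naive single-SNP OLS on the same data
            D = gm.dosage.astype(float)
            Dc = D - D.mean(axis=1, keepdims=True)
            yc = y - y.mean()
            gg = (Dc**2).sum(axis=1)
            ok = gg > 0
            beta = (Dc[ok] @ yc) / gg[ok]
            rss = (yc @ yc) - beta**2 * gg[ok]
            se2 = rss / (gm.n_samples - 2) / gg[ok]
            naive_med = np.median(beta**2 / se2)
            assert naive_med > hi

    def test_permutation_destroys_signal(self):
        cfg, truth, gm = sim_cohort(
            20, n_a=150, n_b=150, chrom_length=60_000,
            causal_snps=((100, 1.0),), causal_var_frac=0.2,
        )
        y = simulate_phenotypes(gm, truth, cfg)["trait"].to_numpy()
        kin = kinship_matrix(gm)
        X = structure_covariates(kin, 2)
        res = assoc_scan(gm, y, X=X, kin=kin)
        t = res.table.set_index("pos")
        causal_pos = gm.pos[100]
        assert t.loc[causal_pos, "neg_log10_p"] > 4
        rng = np.random.default_rng(0)
        perm_nlp = []
        for _ in range(20):
            yp = rng.permutation(y)
            rp = assoc_scan(gm, yp, X=X, kin=kin)
            perm_nlp.append(rp.table.set_index("pos").loc[causal_pos, "neg_log10_p"])
        assert np.median(perm_nlp) < 2


class TestSignificance:
    def make_result(self, nlp):
        t = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": 100 * (1 + np.arange(len(nlp))),
                "beta": 0.1,
                "se": 0.01,
                "wald_p": 10.0 ** (-np.asarray(nlp)),
                "neg_log10_p": nlp,
                "significant": np.asarray(nlp) > 4,
            }
        )
        return AssocResult(table=t)

    def test_strictly_above_threshold_kept(self):
        res = significant_snps(self.make_result([4.2, 4.0, 3.9]))
        assert list(res.table["neg_log10_p"]) == [4.2]

    def test_exact_boundary_dropped(self):
        res = significant_snps(self.make_result([4.0]))
        assert res.table.empty

    def test_empty_input(self):
        res = significant_snps(self.make_result([]))
        assert res.table.empty


class TestAnnotateHits:
    def genes(self):
        return GeneSet(
            pd.DataFrame(
                [("g1", "chr1", 1000, 2000, "+")],
                columns=["gene_id", "chrom", "start", "end", "strand"],
            )
        )

    def make_result(self, positions):
        t = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": positions,
                "beta": 0.1,
                "se": 0.01,
                "wald_p": 1e-5,
                "neg_log10_p": 5.0,
                "significant": True,
            }
        )
        return AssocResult(table=t)

    def test_containment_and_boundaries(self):
        res = annotate_hits(self.make_result([1500, 2000, 2001]), self.genes())
        assert list(res.table["genes"]) == ["g1", "g1", ""]

    def test_flank_extends_interval(self):
        res = annotate_hits(self.make_result([5000]), self.genes(), flank=5000)
        assert res.table.loc[0, "genes"] == "g1"


def test_power_planted_snp_is_top_hit():
    hits = 0
    for seed in range(10):
        cfg, truth, gm = sim_cohort(
            seed + 200, n_a=250, n_b=250, chrom_length=100_000,
            causal_snps=((250, 1.0),), causal_var_frac=0.2, h2_background=0.2,
        )
        y = simulate_phenotypes(gm, truth, cfg)["trait"].to_numpy()
        kin = kinship_matrix(gm)
        res = assoc_scan(gm, y, X=structure_covariates(kin, 2), kin=kin)
        t = res.table
        hits += t.loc[t["neg_log10_p"].idxmax(), "pos"] == gm.pos[250]
    assert hits >= 9
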