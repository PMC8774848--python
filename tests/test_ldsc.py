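"""LD scores, munging, and LD-score regression (h2, genetic covariance)."""

import numpy as np
import pandas as pd
import pytest

from cogres.datatypes import GenotypeDataset
from cogres.ldsc import compute_ld_scores, ldsc_bivariate, ldsc_univariate, munge
from cogres.simulate import SimulationConfig, simulate_genotypes

from conftest import make_genotypes


class TestLDScores:
    def test_isolated_variant_self_term_only(self):
        rng = np.random.default_rng(0)
        cols = [rng.binomial(2, 0.3, 100).astype(float) for _ in range(2)]
        geno = make_genotypes(cols, bp=[1, 5_000_000])  # far beyond the window
        l2 = compute_ld_scores(geno, window_kb=1000)["L2"]
        assert np.allclose(l2, 1.0)

    def test_perfect_ld_pair(self):
        rng = np.random.default_rng(1)
        g = rng.binomial(2, 0.4, 200).astype(float)
        geno = make_genotypes([g, g.copy()], bp=[1000, 2000])
        l2 = compute_ld_scores(geno, window_kb=1000)["L2"]
        assert np.allclose(l2, 2.0)  # r2 = 1 has zero adjustment

    def test_independent_panel_mean_near_one(self):
        # adjusted r2 has null expectation 0, so l2 should average ~1
        cfg = SimulationConfig(
            n_individuals=1000, n_snps=100, n_causal_edu=10, n_causal_res=10,
            snp_spacing_bp=100, seed=3,
        )
        geno = simulate_genotypes(cfg)
        l2 = compute_ld_scores(geno, window_kb=1000)["L2"].to_numpy()
        # null SE of mean adjusted-r2 sum: ~sqrt(2*m_win)/n per variant
        se_bound = 3 * np.sqrt(2 * 99) / 1000
        assert abs(l2.mean() - 1.0) < se_bound

    def test_too_few_individuals(self):
        geno = make_genotypes([[0.0, 1.0]])
        with pytest.raises(ValueError):
            compute_ld_scores(geno)


def _ref(snps, a1="G", a2="A"):
    return pd.DataFrame({"SNP": snps, "A1": a1, "A2": a2})


class TestMunge:
    def test_swap_flips_z(self):
        ss = pd.DataFrame(
            {"SNP": ["rs1"], "A1": ["A"], "A2": ["G"], "Z": [2.0], "N": [100], "FRQ": [0.3]}
        )
        out = munge(ss, _ref(["rs1"]))
        assert out["Z"].iloc[0] == -2.0
        assert out["A1"].iloc[0] == "G"
        assert out["FRQ"].iloc[0] == pytest.approx(0.7)

    def test_toy_retention_count(self):
        # 10 records: 2 strand-ambiguous + 1 below the MAF floor -> 7 kept
        snps = [f"rs{i}" for i in range(10)]
        a1 = ["G"] * 8 + ["A", "C"]
        a2 = ["A"] * 8 + ["T", "G"]
        frq = [0.3] * 7 + [0.005, 0.3, 0.3]
        ss = pd.DataFrame(
            {"SNP": snps, "A1": a1, "A2": a2, "Z": 1.0, "N": 100, "FRQ": frq}
        )
        ref = pd.DataFrame({"SNP": snps, "A1": a1, "A2": a2})
        assert len(munge(ss, ref, min_maf=0.01)) == 7

    def test_z_from_beta_se_and_mismatch_dropped(self):
        ss = pd.DataFrame(
            {
                "SNP": ["rs1", "rs2"],
                "A1": ["G", "C"],
                "A2": ["A", "A"],
                "BETA": [0.5, 0.5],
                "SE": [0.1, 0.1],
                "N": [50, 50],
            }
        )
        out = munge(ss, _ref(["rs1", "rs2"]))  # rs2 alleles mismatch
        assert list(out["SNP"]) == ["rs1"]
        assert out["Z"].iloc[0] == pytest.approx(5.0)

    def test_chisq_cap_drops_outliers_only_when_asked(self):
        ss = pd.DataFrame(
            {"SNP": ["rs1", "rs2"], "A1": "G", "A2": "A", "Z": [10.0, 2.0], "N": 1000}
        )
        ref = _ref(["rs1", "rs2"])
        assert len(munge(ss, ref)) == 2
        out = munge(ss, ref, max_chisq=80.0)
        assert list(out["SNP"]) == ["rs2"]  # Z^2 = 100 exceeds the cap

    def test_no_overlap_raises(self):
        ss = pd.DataFrame({"SNP": ["rs1"], "A1": ["G"], "A2": ["A"], "Z": [1.0], "N": [10]})
        with pytest.raises(ValueError):
            munge(ss, _ref(["rsX"]))


def _ld_panel(seed, n=2000, m=1000, block=10, decay=0.8):
    cfg = SimulationConfig(
        n_individuals=n, n_snps=m, n_causal_edu=10, n_causal_res=10,
        ld_block_size=block, ld_decay=decay, seed=seed,
    )
    geno = simulate_genotypes(cfg)
    return geno, compute_ld_scores(geno, window_kb=1000)


@pytest.fixture(scope="module")
def ldsc_panel():
    """Reference panel sized so the LDSC regressions are well conditioned."""
    geno, ld = _ld_panel(seed=6, n=5000, m=2000)
    return geno, ld, geno.standardized_dosages()


def _munged_from_z(geno, z, n):
    return pd.DataFrame(
        {
            "SNP": geno.variants["SNP"],
            "A1": geno.variants["A1"],
            "A2": geno.variants["A2"],
            "Z": z,
            "N": float(n),
        }
    )


def _fast_linear_z(geno, y):
    """Marginal association Z of a quantitative trait (correlation form)."""
    g = geno.standardized_dosages()
    n = len(y)
    yc = (y - y.mean()) / y.std()
    r = yc @ g / n
    return r * np.sqrt((n - 2) / np.maximum(1 - r * r, 1e-12))


class TestLdscUnivariate:
    def test_exact_linear_relation_recovers_slope(self):
        geno, ld = _ld_panel(seed=4, n=500, m=200)
        n_eff, m, h2 = 10_000.0, 200, 0.4
        z = np.sqrt(1.0 + n_eff * ld["L2"].to_numpy() * h2 / m)
        fit = ldsc_univariate(_munged_from_z(geno, z, n_eff), ld, m=m)
        assert fit.h2 == pytest.approx(h2, abs=1e-8)
        assert fit.intercept == pytest.approx(1.0, abs=1e-8)

    def test_scale_equivariance(self):
        geno, ld = _ld_panel(seed=4, n=500, m=200)
        n_eff, m, h2, c = 10_000.0, 200, 0.3, 1.7
        z = np.sqrt(1.0 + n_eff * ld["L2"].to_numpy() * h2 / m)
        fit_c = ldsc_univariate(_munged_from_z(geno, c * z, n_eff), ld, m=m)
        assert fit_c.h2 == pytest.approx(c * c * h2, rel=1e-6)
        assert fit_c.intercept == pytest.approx(c * c, rel=1e-6)

    def test_null_trait(self, ldsc_panel):
        geno, ld, _ = ldsc_panel
        rng = np.random.default_rng(50)
        z = _fast_linear_z(geno, rng.standard_normal(geno.n_individuals))
        fit = ldsc_univariate(_munged_from_z(geno, z, geno.n_individuals), ld)
        assert abs(fit.h2) < 2 * fit.h2_se
        assert abs(fit.intercept - 1.0) < 2 * fit.intercept_se

    def test_h2_parameter_recovery(self, ldsc_panel):
        geno, ld, g = ldsc_panel
        rng = np.random.default_rng(60)
        m = geno.n_variants
        h2 = 0.5
        beta = np.zeros(m)
        causal = rng.choice(m, 600, replace=False)
        raw = rng.standard_normal(600)
        beta[causal] = raw * np.sqrt(h2 / (raw**2).sum())
        y = g @ beta + rng.normal(0, np.sqrt(1 - h2), geno.n_individuals)
        z = _fast_linear_z(geno, y)
        fit = ldsc_univariate(_munged_from_z(geno, z, geno.n_individuals), ld)
        assert abs(fit.h2 - h2) < 2 * fit.h2_se
        assert fit.h2_se < 0.5  # chi-square noise at desk-scale M is large but bounded

    def test_block_reduction_for_small_m(self):
        geno, ld = _ld_panel(seed=4, n=500, m=200)
        z = np.ones(200)
        fit = ldsc_univariate(_munged_from_z(geno, z, 1000.0), ld, n_blocks=200)
        assert fit.n_blocks == 20  # reduced to keep >= 10 SNPs per block


def _paired_traits(geno, g, rng, rho, h2=0.4, m_causal=500):
    """Two traits whose causal effects correlate rho (shared + unique parts)."""
    m = geno.n_variants
    causal = rng.choice(m, m_causal, replace=False)
    shared = rng.standard_normal(m_causal)
    raws = []
    for _ in range(2):
        raws.append(
            np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.standard_normal(m_causal)
            if rho > 0
            else rng.standard_normal(m_causal)
        )
    ys = []
    for raw in raws:
        beta = np.zeros(m)
        beta[causal] = raw * np.sqrt(h2 / (raw**2).sum())
        ys.append(g @ beta + rng.normal(0, np.sqrt(1 - h2), geno.n_individuals))
    return ys


class TestLdscBivariate:
    def test_trait_with_itself_gives_rg_one(self, ldsc_panel):
        geno, ld, g = ldsc_panel
        rng = np.random.default_rng(70)
        y, _ = _paired_traits(geno, g, rng, rho=0.0)
        mz = _munged_from_z(geno, _fast_linear_z(geno, y), geno.n_individuals)
        gc = ldsc_bivariate(mz, mz.copy(), ld)
        assert gc.rg == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("rho", [0.0, 0.5])
    def test_effect_correlation_recovery(self, ldsc_panel, rho):
        geno, ld, g = ldsc_panel
        rng = np.random.default_rng(80)
        y1, y2 = _paired_traits(geno, g, rng, rho=rho)
        m1 = _munged_from_z(geno, _fast_linear_z(geno, y1), geno.n_individuals)
        m2 = _munged_from_z(geno, _fast_linear_z(geno, y2), geno.n_individuals)
        gc = ldsc_bivariate(m1, m2, ld)
        assert abs(gc.rg - rho) < 2 * gc.rg_se

    def test_v_diagonal_matches_jackknife_ses(self, ldsc_panel):
        geno, ld, g = ldsc_panel
        rng = np.random.default_rng(71)
        y1, y2 = _paired_traits(geno, g, rng, rho=0.5)
        m1 = _munged_from_z(geno, _fast_linear_z(geno, y1), geno.n_individuals)
        m2 = _munged_from_z(geno, _fast_linear_z(geno, y2), geno.n_individuals)
        gc = ldsc_bivariate(m1, m2, ld)
        fit1 = ldsc_univariate(m1, ld)
        # same SNP set, same weights scheme -> V[0,0] is the squared
        # jackknife SE of S11 and matches the univariate route
        assert np.sqrt(gc.v[0, 0]) == pytest.approx(fit1.h2_se, rel=1e-6)
        assert gc.v == pytest.approx(gc.v.T)
        assert np.all(np.linalg.eigvalsh(gc.v) > -1e-12)

    def test_rg_invariant_under_consistent_allele_flip(self, ldsc_panel):
        geno, ld, g = ldsc_panel
        rng = np.random.default_rng(72)
        y1, y2 = _paired_traits(geno, g, rng, rho=0.5)
        m1 = _munged_from_z(geno, _fast_linear_z(geno, y1), geno.n_individuals)
        m2 = _munged_from_z(geno, _fast_linear_z(geno, y2), geno.n_individuals)
        gc = ldsc_bivariate(m1, m2, ld)
        # flip a subset of variants in trait 2 only: the bivariate routine
        # must re-harmonise and reproduce the same genetic covariance
        m2_flip = m2.copy()
        flip = m2_flip.index % 3 == 0
        m2_flip.loc[flip, ["A1", "A2"]] = m2_flip.loc[flip, ["A2", "A1"]].to_numpy()
        m2_flip.loc[flip, "Z"] = -m2_flip.loc[flip, "Z"]
        gc_flip = ldsc_bivariate(m1, m2_flip, ld)
        assert gc_flip.s == pytest.approx(gc.s, rel=1e-9)
        assert gc_flip.rg == pytest.approx(gc.rg, rel=1e-9)

    def test_empty_intersection_raises(self):
        geno, ld = _ld_panel(seed=4, n=500, m=200)
        m1 = _munged_from_z(geno, np.ones(200), 100)
        m2 = m1.copy()
        m2["SNP"] = [f"x{i}" for i in range(200)]
        with pytest.raises(ValueError):
            ldsc_bivariate(m1, m2, ld)
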