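"""Association scan, variant QC, HWE exact test, thresholds, sign test."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given
from hypothesis import strategies as st

from cogres.gwas import (
    QCThresholds,
    bonferroni_threshold,
    hwe_exact_test,
    run_gwas,
    sign_test_replication,
    variant_qc,
)

from conftest import make_genotypes


def hwe_exact_oracle(n_het, n_hom_minor, n_hom_major):
    """Exact-rational enumeration of the conditional genotype distribution."""
    n = n_het + n_hom_minor + n_hom_major
    rare = 2 * n_hom_minor + n_het
    if rare > n:
        rare = 2 * n - rare

    def ways(h):
        a = (rare - h) // 2
        b = (2 * n - rare - h) // 2
        return Fraction(math.factorial(n), math.factorial(a) * math.factorial(h) * math.factorial(b)) * 2**h

    total = sum(ways(h) for h in range(rare % 2, rare + 1, 2))
    p_obs = ways(n_het) / total
    return float(sum(w for h in range(rare % 2, rare + 1, 2) if (w := ways(h) / total) <= p_obs))


class TestHWE:
    @pytest.mark.parametrize(
        "het, hom_min, hom_maj",
        [(57, 14, 50), (100, 0, 0), (0, 50, 50), (21, 10, 69), (3, 0, 997), (250, 125, 625)],
    )
    def test_matches_exact_enumeration(self, het, hom_min, hom_maj):
        assert hwe_exact_test(het, hom_min, hom_maj) == pytest.approx(
            hwe_exact_oracle(het, hom_min, hom_maj), rel=1e-9
        )

    @given(st.integers(0, 60), st.integers(0, 30), st.integers(0, 30))
    def test_valid_probability_and_symmetry(self, het, a, b):
        p = hwe_exact_test(het, a, b)
        assert 0 <= p <= 1
        assert p == pytest.approx(hwe_exact_test(het, b, a), rel=1e-12)


def _hwe_column(n, maf):
    """Dosage column with genotype counts at exact HWE proportions."""
    n_alt = int(round(n * maf * maf))
    n_het = int(round(n * 2 * maf * (1 - maf)))
    return np.repeat([2.0, 1.0, 0.0], [n_alt, n_het, n - n_alt - n_het])


class TestVariantQC:
    def test_toy_panel_counts(self):
        n = 1000
        clean = _hwe_column(n, 0.3)
        low_maf = np.zeros(n)
        low_maf[0] = 1.0  # MAF 0.0005 < 0.001
        all_het = np.ones(n)  # massive heterozygote excess -> HWE p ~ 0
        missing = _hwe_column(n, 0.5)
        missing[:60] = np.nan  # 6% missing > 2%
        dup = clean.copy()
        geno = make_genotypes(
            [clean, low_maf, all_het, missing, dup],
            bp=[100, 200, 300, 400, 100],
            ids=["clean", "lowmaf", "hwefail", "miss", "dupclean"],
        )
        kept, report = variant_qc(geno, QCThresholds())
        assert list(kept.variants["SNP"]) == ["clean"]
        assert report["maf"] == 1 and report["hwe"] == 1
        assert report["geno"] == 1 and report["dup"] == 1

    def test_all_pass_identity(self):
        geno = make_genotypes([_hwe_column(500, 0.2), _hwe_column(500, 0.4)])
        kept, report = variant_qc(geno, QCThresholds())
        assert kept.n_variants == 2 and report["retained"] == 2

    def test_vacuous_thresholds_only_remove_duplicates(self):
        col = _hwe_column(200, 0.25)
        odd = np.ones(200)  # HWE-violating but thresholds are zero
        geno = make_genotypes([col, odd, col.copy()], bp=[1, 2, 1], ids=["a", "b", "c"])
        kept, report = variant_qc(geno, QCThresholds(geno=1.0, maf=0.0, info=0.0, hwe=0.0))
        assert list(kept.variants["SNP"]) == ["a", "b"]
        assert report["dup"] == 1

    def test_all_removed_raises(self):
        geno = make_genotypes([np.ones(100)])
        with pytest.raises(ValueError):
            variant_qc(geno, QCThresholds(hwe=0.5))


class TestRunGwas:
    def test_logistic_beta_equals_2x2_log_odds_ratio(self):
        # haploid-coded variant: cases 60 carriers / 40 non-carriers,
        # controls 40 / 60 -> log OR = ln(2.25)
        g = np.r_[np.ones(60), np.zeros(40), np.ones(40), np.zeros(60)]
        y = np.r_[np.ones(100), np.zeros(100)]
        ss = run_gwas(make_genotypes([g]), y)
        assert ss["BETA"].iloc[0] == pytest.approx(np.log(2.25), abs=1e-6)
        assert ss["N"].iloc[0] == 200

    def test_matches_statsmodels_with_covariates(self):
        rng = np.random.default_rng(5)
        n = 400
        g = rng.binomial(2, 0.3, n).astype(float)
        covar = pd.DataFrame({"c1": rng.normal(size=n), "c2": rng.normal(size=n)})
        logit = 0.3 * g - 0.5 * covar["c1"]
        y = rng.binomial(1, 1 / (1 + np.exp(-logit))).astype(float)
        ss = run_gwas(make_genotypes([g]), y, covariates=covar)
        x = sm.add_constant(np.column_stack([covar, g]))
        ref = sm.Logit(y, x).fit(disp=0)
        assert ss["BETA"].iloc[0] == pytest.approx(ref.params[-1], abs=1e-7)
        assert ss["SE"].iloc[0] == pytest.approx(ref.bse[-1], rel=1e-5)

    def test_linear_matches_statsmodels(self):
        rng = np.random.default_rng(6)
        n = 300
        g = rng.binomial(2, 0.4, n).astype(float)
        covar = pd.DataFrame({"c": rng.normal(size=n)})
        y = 0.2 * g + 0.4 * covar["c"] + rng.normal(size=n)
        ss = run_gwas(make_genotypes([g]), y, covariates=covar, model="linear")
        ref = sm.OLS(np.asarray(y), sm.add_constant(np.column_stack([covar, g]))).fit()
        assert ss["BETA"].iloc[0] == pytest.approx(np.asarray(ref.params)[-1], rel=1e-8)
        assert ss["SE"].iloc[0] == pytest.approx(np.asarray(ref.bse)[-1], rel=1e-8)

    def test_null_calibration(self):
        # phenotype independent of genotypes: ~5% of tests reach p < 0.05
        rng = np.random.default_rng(17)
        n, m = 800, 1000
        geno = make_genotypes([rng.binomial(2, 0.3, n).astype(float) for _ in range(m)])
        y = rng.binomial(1, 0.5, n).astype(float)
        ss = run_gwas(geno, y)
        frac = (ss.loc[ss["FLAG"] == "ok", "P"] < 0.05).mean()
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / m)

    def test_allele_flip_antisymmetry(self):
        rng = np.random.default_rng(8)
        n = 500
        g = rng.binomial(2, 0.35, n).astype(float)
        y = rng.binomial(1, 1 / (1 + np.exp(-0.4 * (g - g.mean())))).astype(float)
        ss = run_gwas(make_genotypes([g]), y)
        ss_flip = run_gwas(make_genotypes([2.0 - g]), y)
        assert ss_flip["BETA"].iloc[0] == pytest.approx(-ss["BETA"].iloc[0], abs=1e-8)
        assert ss_flip["P"].iloc[0] == pytest.approx(ss["P"].iloc[0], rel=1e-6)
        assert ss_flip["FRQ"].iloc[0] == pytest.approx(1 - ss["FRQ"].iloc[0])

    def test_condition_on_self_flags_collinear(self):
        rng = np.random.default_rng(9)
        g = rng.binomial(2, 0.3, 300).astype(float)
        y = rng.binomial(1, 0.5, 300).astype(float)
        ss = run_gwas(make_genotypes([g]), y, condition_snp="snp1")
        assert ss["FLAG"].iloc[0] == "collinear"
        assert np.isnan(ss["BETA"].iloc[0])

    def test_conditioning_on_causal_snp_weakens_ld_partner(self):
        # partner associates only through LD with the causal variant, so
        # conditioning must raise its p-value
        rng = np.random.default_rng(10)
        n = 3000
        causal = rng.binomial(2, 0.5, n).astype(float)
        partner = causal.copy()
        swap = rng.random(n) < 0.15
        partner[swap] = rng.binomial(2, 0.5, swap.sum())
        y = rng.binomial(1, 1 / (1 + np.exp(-0.5 * (causal - 1)))).astype(float)
        geno = make_genotypes([causal, partner])
        plain = run_gwas(geno, y)
        cond = run_gwas(geno, y, condition_snp="snp1")
        assert plain["P"].iloc[1] < 1e-4
        assert cond["P"].iloc[1] > plain["P"].iloc[1]

    def test_single_class_phenotype_raises(self):
        g = np.ones(50)
        with pytest.raises(ValueError):
            run_gwas(make_genotypes([g]), np.ones(50))


class TestThresholdsAndSignTest:
    def test_bonferroni_values(self):
        assert bonferroni_threshold(0.05, 18_879) == pytest.approx(2.648e-6, rel=5e-4)
        assert bonferroni_threshold(0.05, 10) == pytest.approx(0.005)
        assert bonferroni_threshold(0.05, 1) == pytest.approx(0.05)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)

    @staticmethod
    def _stats(betas, alleles=None, ids=None):
        n = len(betas)
        return pd.DataFrame(
            {
                "SNP": ids if ids else [f"rs{i}" for i in range(n)],
                "A1": [a[0] for a in alleles] if alleles else ["G"] * n,
                "A2": [a[1] for a in alleles] if alleles else ["A"] * n,
                "BETA": betas,
                "P": [0.01] * n,
            }
        )

    def test_ten_of_ten(self):
        disc = self._stats([0.1] * 10)
        rep = self._stats([0.2] * 10)
        res = sign_test_replication(disc, rep)
        assert res.n_concordant == 10
        assert res.p_value == pytest.approx(9.77e-4, rel=1e-3)  # 1/1024

    def test_eight_of_ten_exact_tail(self):
        disc = self._stats([0.1] * 10)
        rep = self._stats([0.2] * 8 + [-0.2] * 2)
        res = sign_test_replication(disc, rep)
        assert res.p_value == pytest.approx(56 / 1024)

    def test_one_of_one(self):
        res = sign_test_replication(self._stats([0.5]), self._stats([0.5]))
        assert res.p_value == pytest.approx(0.5)

    def test_allele_harmonisation_flips_direction(self):
        disc = self._stats([0.3], alleles=[("G", "A")])
        rep = self._stats([-0.3], alleles=[("A", "G")])  # same direction once flipped
        res = sign_test_replication(disc, rep)
        assert res.n_concordant == 1

    def test_missing_lead_reduces_n(self):
        disc = self._stats([0.3, 0.4], ids=["rs1", "rs2"])
        rep = self._stats([0.3], ids=["rs1"])
        res = sign_test_replication(disc, rep)
        assert res.n_leads == 1 and res.n_missing == 1
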