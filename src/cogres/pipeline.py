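"""End-to-end driver: synthetic cohort -> quadrant GWAS -> subtraction.

Chains the full analysis on a simulated cohort with known truth and gathers
everything an evaluation needs: the two contrast GWAS, LD scores, the LDSC
genetic covariance (S, V), Cholesky loadings, latent *Resilience* /
*EduYears* summary statistics with effective sample sizes, the genetic
correlation between the two latent outputs, and the simulation-truth
counterparts of S and the loadings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gbs, ldsc
from .datatypes import GenotypeDataset
from .gwas import run_gwas
from .phenotypes import build_phenotypes, contrast_phenotype
from .simulate import (
    FactorSet,
    SimulationConfig,
    TruthSet,
    simulate_cohort,
    true_s_matrix,
)

GWAS_COVARIATES = ["SEX", "AGE", "CENTRE", "ARRAY"] + [f"PC{i}" for i in range(1, 9)]


def study_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Reference end-to-end conditions: the generator defaults plus
    heterogeneous AR(1) LD blocks (sizes cycling 1/5/20/40, decay 0.95).
    The block-size heterogeneity gives LD scores a wide spread — as in real
    genomes — which is what identifies the free-intercept LD-score
    regressions."""
    base = dict(ld_block_pattern=(1, 5, 20, 40), ld_decay=0.95)
    base.update(overrides)
    return SimulationConfig(seed=seed, **base)


@dataclass
class SubtractionStudy:
    """All artefacts of one end-to-end run."""

    config: SimulationConfig
    genotypes: GenotypeDataset = field(repr=False, default=None)
    cohort: pd.DataFrame = field(repr=False, default=None)
    factors: FactorSet = field(repr=False, default=None)
    truth: TruthSet = field(repr=False, default=None)
    sumstats_eyres: pd.DataFrame = field(repr=False, default=None)
    sumstats_nonres: pd.DataFrame = field(repr=False, default=None)
    ldscores: pd.DataFrame = field(repr=False, default=None)
    gc: ldsc.GeneticCovariance = None
    loadings: gbs.CholeskyLoadings = None
    latent: pd.DataFrame = field(repr=False, default=None)
    neff_res: float = np.nan
    neff_edu: float = np.nan
    resilience_sumstats: pd.DataFrame = field(repr=False, default=None)
    eduyears_sumstats: pd.DataFrame = field(repr=False, default=None)
    latent_gc: ldsc.GeneticCovariance = None
    s_true: np.ndarray = None
    loadings_true: gbs.CholeskyLoadings = None


def _aligned_contrast(pheno: pd.DataFrame, samples, contrast: str) -> np.ndarray:
    """1/0/NaN contrast indicator in genotype sample order."""
    y = contrast_phenotype(pheno, contrast)
    lookup = pd.Series(y.to_numpy(), index=pheno["IID"].to_numpy())
    return lookup.reindex(samples).to_numpy(dtype=float)


def run_subtraction_study(
    config: SimulationConfig | None = None,
    n_blocks: int = 100,
    window_kb: float = 1000.0,
    run_latent_rg: bool = True,
) -> SubtractionStudy:
    """Simulate, run both quadrant GWAS, and perform the subtraction.

    The LDSC stages apply the standard max(80, 0.001*N) chi-square cap to
    regression SNPs; the per-SNP subtraction keeps every harmonised variant.
    """
    config = config or study_config()
    genotypes, cohort, factors, truth = simulate_cohort(config)
    pheno, _ = build_phenotypes(cohort)
    covars = cohort[GWAS_COVARIATES]

    y_eyres = _aligned_contrast(pheno, genotypes.samples, "EYRES")
    y_nonres = _aligned_contrast(pheno, genotypes.samples, "NONRES")
    ss1 = run_gwas(genotypes, y_eyres, covariates=covars, model="logistic")
    ss2 = run_gwas(genotypes, y_nonres, covariates=covars, model="logistic")

    ld = ldsc.compute_ld_scores(genotypes, window_kb=window_kb)
    ref_alleles = genotypes.variants[["SNP", "A1", "A2"]]
    m1 = ldsc.munge(ss1[ss1["FLAG"] == "ok"], ref_alleles)
    m2 = ldsc.munge(ss2[ss2["FLAG"] == "ok"], ref_alleles)
    # S is estimated on outlier-capped regression SNPs (standard LDSC
    # filter); the subtraction below keeps every harmonised variant
    cap1, cap2 = ldsc.standard_chisq_cap(m1["N"]), ldsc.standard_chisq_cap(m2["N"])
    gc = ldsc.ldsc_bivariate(
        m1[m1["Z"] ** 2 <= cap1],
        m2[m2["Z"] ** 2 <= cap2],
        ld,
        m=len(m1),
        n_blocks=n_blocks,
    )
    loadings = gbs.fit_cholesky(gc)

    freqs = pd.DataFrame(
        {"SNP": genotypes.variants["SNP"], "FRQ": genotypes.allele_frequencies()}
    )
    # the two contrasts use disjoint individuals, so the per-SNP sampling
    # covariance between them is zero by design (using the noisy estimated
    # cross-intercept instead would rescale every latent Z)
    latent = gbs.subtract_snp(m1, m2, loadings, freqs, cross_intercept=0.0)
    neff_res = gbs.effective_n(latent, "res")
    neff_edu = gbs.effective_n(latent, "edu")
    res_ss = gbs.latent_to_sumstats(latent, "res", neff=neff_res)
    edu_ss = gbs.latent_to_sumstats(latent, "edu", neff=neff_edu)

    latent_gc = None
    if run_latent_rg:
        mres = ldsc.munge(res_ss, ref_alleles)
        medu = ldsc.munge(edu_ss, ref_alleles)
        cap_r, cap_e = ldsc.standard_chisq_cap(mres["N"]), ldsc.standard_chisq_cap(medu["N"])
        latent_gc = ldsc.ldsc_bivariate(
            mres[mres["Z"] ** 2 <= cap_r],
            medu[medu["Z"] ** 2 <= cap_e],
            ld,
            m=len(mres),
            n_blocks=n_blocks,
        )

    covar_mat = covars.to_numpy(dtype=float)
    s_true = true_s_matrix(factors, y_eyres, y_nonres, covar_mat, truth=truth)
    loadings_true = gbs.fit_cholesky(s_true)

    return SubtractionStudy(
        config=config,
        genotypes=genotypes,
        cohort=cohort,
        factors=factors,
        truth=truth,
        sumstats_eyres=ss1,
        sumstats_nonres=ss2,
        ldscores=ld,
        gc=gc,
        loadings=loadings,
        latent=latent,
        neff_res=neff_res,
        neff_edu=neff_edu,
        resilience_sumstats=res_ss,
        eduyears_sumstats=edu_ss,
        latent_gc=latent_gc,
        s_true=s_true,
        loadings_true=loadings_true,
    )
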