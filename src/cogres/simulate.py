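"""Synthetic cohort generator with known genetic truth.

Emulates the statistical structure the resilience analysis assumes: a
middle-aged cohort (ages 40-69) with

* two latent, genetically *independent* factors — an education factor
  ``F_Edu`` and a resilience factor ``F_Res`` — each with unit total
  variance and configurable SNP heritability,
* education years derived monotonically from ``F_Edu`` (college attendees
  recorded with missing years, mirroring how age-completed-education is
  captured in biobank questionnaires),
* reaction time (ms) that slows linearly with age and speeds up with both
  factors (higher factor score => faster), plus nuisance covariates
  (sex, assessment centre, genotyping array, principal components).

Genotypes are independent binomial draws by default; an optional AR(1)
haplotype-copula block structure provides realistic local LD for the
LD-score and clumping machinery. Every stage draws from a child stream of
one master seed, so a config is fully reproducible down to byte-identical
fixture files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeDataset
from .io import write_table, write_vcf

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "FactorSet",
    "ContrastTruth",
    "simulate_genotypes",
    "simulate_latent_factors",
    "simulate_cohort_phenotypes",
    "simulate_cohort",
    "export_fixtures",
    "contrast_truth",
    "true_s_matrix",
]

COVARIATE_COLUMNS = (
    ["IID", "SEX", "AGE", "CENTRE", "ARRAY"]
    + [f"PC{i}" for i in range(1, 9)]
    + ["EDU_YEARS", "COLLEGE", "RT_MS"]
)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults are the package's reference conditions."""

    n_individuals: int = 20_000
    n_snps: int = 2_000
    maf_range: tuple = (0.05, 0.5)
    n_causal_edu: int = 500
    n_causal_res: int = 500
    h2_edu: float = 0.3
    h2_res: float = 0.2
    age_range: tuple = (40, 69)
    rt_age_slope: float = 3.0  # ms per year of age
    rt_base: float = 550.0  # ms, cohort mean at mean age
    noise_sd_ey: float = 0.5  # education noise on the latent (F_Edu) scale
    noise_sd_rt: float = 60.0  # ms
    college_rate: float = 0.30
    kappa_edu: float = 25.0  # ms of RT speed-up per SD of F_Edu
    kappa_res: float = 40.0  # ms of RT speed-up per SD of F_Res
    sex_effect_rt: float = 8.0  # ms
    array_effect_rt: float = 2.0  # ms
    centre_effect_rt: float = 0.2  # ms per centre index
    pc_effect_rt: float = 1.5  # ms per SD of PC1, decaying over PCs
    # LD structure: block_size 1 => independent sites; a block-size pattern
    # cycles through heterogeneous sizes (realistic LD-score spread)
    ld_block_size: int = 1
    ld_block_pattern: tuple | None = None
    ld_decay: float = 0.9  # AR(1) haplotype correlation between adjacent sites
    snp_spacing_bp: int = 5_000
    chrom: str = "1"
    # optional large-effect resilience regions (for locus-definition tests):
    # each region spreads major_res_var over major_region_snps consecutive
    # SNPs aligned to an LD block, so no single variant becomes an extreme
    # outlier for the LD-score regressions
    n_major_res_loci: int = 0
    major_res_var: float = 0.04  # standardized variance per major region
    major_region_snps: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals <= 0 or self.n_snps <= 0:
            raise ValueError("n_individuals and n_snps must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for h2, name in [(self.h2_edu, "h2_edu"), (self.h2_res, "h2_res")]:
            if not (0 <= h2 <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_causal_edu > self.n_snps or self.n_causal_res > self.n_snps:
            raise ValueError("n_causal_* cannot exceed n_snps")
        if not (0 <= self.college_rate < 1):
            raise ValueError("college_rate must be in [0, 1)")
        if self.age_range[0] > self.age_range[1]:
            raise ValueError("age_range must be (low, high)")
        if self.ld_block_size < 1 or not (0 <= self.ld_decay < 1):
            raise ValueError("ld_block_size >= 1 and ld_decay in [0, 1) required")
        if self.ld_block_pattern is not None and any(b < 1 for b in self.ld_block_pattern):
            raise ValueError("ld_block_pattern sizes must be >= 1")
        if self.n_major_res_loci * self.major_res_var > self.h2_res:
            raise ValueError("major resilience loci exceed h2_res")
        if self.major_region_snps < 1:
            raise ValueError("major_region_snps must be >= 1")

    def child_rngs(self) -> dict:
        """Named, deterministically derived per-stage random streams."""
        names = ["genotypes", "effects", "factors", "cohort"]
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def _block_partition(config: SimulationConfig, m: int) -> list:
    """(start, size) of each LD block covering the m variants."""
    if config.ld_block_pattern:
        sizes = list(config.ld_block_pattern)
    else:
        sizes = [max(1, config.ld_block_size)]
    blocks, pos, i = [], 0, 0
    while pos < m:
        size = min(sizes[i % len(sizes)], m - pos)
        blocks.append((pos, size))
        pos += size
        i += 1
    return blocks


@dataclass
class TruthSet:
    """Per-variant true standardized effects and realized factor heritabilities."""

    beta_e_true: np.ndarray
    beta_r_true: np.ndarray
    h2_edu_realized: float = np.nan
    h2_res_realized: float = np.nan

    def as_frame(self, variants: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "SNP": variants["SNP"].to_numpy(),
                "BETA_E_TRUE": self.beta_e_true,
                "BETA_R_TRUE": self.beta_r_true,
            }
        )


@dataclass
class FactorSet:
    """Per-individual factor scores and their genetic components."""

    f_edu: np.ndarray
    f_res: np.ndarray
    g_edu: np.ndarray
    g_res: np.ndarray


def simulate_genotypes(config: SimulationConfig) -> GenotypeDataset:
    """Draw a dosage panel with per-variant MAF uniform on ``maf_range``.

    With ``ld_block_size > 1`` adjacent sites within a block share an AR(1)
    latent Gaussian per haplotype (correlation ``ld_decay`` between
    neighbours), yielding a block-diagonal LD pattern; blocks are mutually
    independent. Alleles are written as REF=A / ALT=G so the panel survives
    strand-ambiguity filtering intact.
    """
    config.validate()
    rng = config.child_rngs()["genotypes"]
    n, m = config.n_individuals, config.n_snps
    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    thresh = stats.norm.ppf(maf)

    dosages = np.zeros((n, m))
    blocks = _block_partition(config, m)
    chained = np.zeros(m, dtype=bool)  # True where the AR(1) chain continues
    for start, size in blocks:
        chained[start + 1 : start + size] = True
    for _hap in range(2):
        z = rng.standard_normal((n, m))
        if chained.any() and config.ld_decay > 0:
            rho = config.ld_decay
            w = np.sqrt(1.0 - rho * rho)
            for j in range(1, m):
                if chained[j]:
                    z[:, j] = rho * z[:, j - 1] + w * z[:, j]
        dosages += (z < thresh).astype(float)

    variants = pd.DataFrame(
        {
            "SNP": [f"rs{j + 1}" for j in range(m)],
            "CHR": config.chrom,
            "BP": 1 + np.arange(m) * config.snp_spacing_bp,
            "A1": "G",
            "A2": "A",
            "INFO": 1.0,
        }
    )
    return GenotypeDataset(dosages=dosages, variants=variants)


def _draw_effects(rng, m, causal_idx, total_var):
    """iid normal effects on the causal set, rescaled so sum of squares == total_var."""
    beta = np.zeros(m)
    if total_var <= 0 or len(causal_idx) == 0:
        return beta
    raw = rng.standard_normal(len(causal_idx))
    beta[causal_idx] = raw * np.sqrt(total_var / np.sum(raw**2))
    return beta


def _orthogonal_noise(rng, g, var, n):
    """Noise with exact variance ``var``, empirically orthogonal to ``g``."""
    e = rng.standard_normal(n)
    if np.var(g) > 0:
        gc = g - g.mean()
        e = e - gc * (e @ gc) / (gc @ gc)
    e = e - e.mean()
    sd = e.std()
    return e * (np.sqrt(var) / sd) if sd > 0 and var > 0 else np.zeros(n)


def simulate_latent_factors(
    genotypes: GenotypeDataset, config: SimulationConfig
) -> tuple[FactorSet, TruthSet]:
    """Build the two independent latent factors from the genotype panel.

    Each factor is ``F = sum_j beta_j g_std_j + e`` with effects drawn
    independently per factor on random causal sets, scaled so the summed
    squared standardized effects equal the configured heritability, and an
    environmental term with exact complementary variance orthogonalized
    against the genetic value. Optional "major" resilience regions each
    spread a fixed standardized variance over consecutive block-aligned SNPs
    at evenly spaced, well-separated positions.
    """
    config.validate()
    rngs = config.child_rngs()
    rng_eff, rng_fac = rngs["effects"], rngs["factors"]
    m, n = genotypes.n_variants, genotypes.n_individuals
    g_std = genotypes.standardized_dosages()

    causal_e = np.sort(rng_eff.choice(m, size=config.n_causal_edu, replace=False))
    causal_r = np.sort(rng_eff.choice(m, size=config.n_causal_res, replace=False))
    beta_e = _draw_effects(rng_eff, m, causal_e, config.h2_edu)

    k = config.n_major_res_loci
    major_idx = np.array([], dtype=int)
    if k > 0:
        span = min(config.major_region_snps, m)
        blocks = _block_partition(config, m)
        hosts = [b for b in blocks if b[1] >= span] or blocks
        # k host blocks spread evenly across the panel; clamp so every
        # region has its full span even at the panel edge
        picks = np.round(np.linspace(0, len(hosts) - 1, k)).astype(int)
        starts = [min(hosts[p][0], m - span) for p in picks]
        major_idx = np.unique(
            np.concatenate([np.arange(s, s + span) for s in starts])
        )
    poly_var = config.h2_res - k * config.major_res_var
    poly_causal = np.setdiff1d(causal_r, major_idx)
    beta_r = _draw_effects(rng_eff, m, poly_causal, poly_var)
    if len(major_idx):
        beta_r[major_idx] = np.sqrt(config.major_res_var / config.major_region_snps)

    g_edu = g_std @ beta_e
    g_res = g_std @ beta_r
    e_edu = _orthogonal_noise(rng_fac, g_edu, 1.0 - config.h2_edu, n)
    e_res = _orthogonal_noise(rng_fac, g_res, 1.0 - config.h2_res, n)
    f_edu = g_edu + e_edu
    f_res = g_res + e_res

    truth = TruthSet(
        beta_e_true=beta_e,
        beta_r_true=beta_r,
        h2_edu_realized=float(np.var(g_edu) / np.var(f_edu)) if np.var(f_edu) else 0.0,
        h2_res_realized=float(np.var(g_res) / np.var(f_res)) if np.var(f_res) else 0.0,
    )
    return FactorSet(f_edu, f_res, g_edu, g_res), truth


def simulate_cohort_phenotypes(
    factors: FactorSet, genotypes: GenotypeDataset, config: SimulationConfig
) -> pd.DataFrame:
    """Generate the per-individual covariate/phenotype table.

    Education years: the quantile of ``F_Edu`` plus noise maps monotonically
    onto years 14-19; the top ``college_rate`` quantile is flagged COLLEGE=1
    with years recorded as missing. Reaction time:
    ``rt_base + slope*(age - mean age) - kappa_E*F_Edu - kappa_R*F_Res +
    nuisance + noise`` — higher factor scores mean faster (smaller) RT.
    """
    config.validate()
    rng = config.child_rngs()["cohort"]
    n = genotypes.n_individuals

    age = rng.integers(config.age_range[0], config.age_range[1] + 1, size=n)
    sex = rng.integers(0, 2, size=n)
    centre = rng.integers(1, 23, size=n)
    array = rng.integers(0, 2, size=n)
    pcs = rng.standard_normal((n, 8))

    z_ey = factors.f_edu + config.noise_sd_ey * rng.standard_normal(n)
    q = (stats.rankdata(z_ey) - 0.5) / n
    college = q >= 1.0 - config.college_rate
    years = np.full(n, np.nan)
    if config.college_rate < 1:
        scaled = q[~college] / (1.0 - config.college_rate)
        years[~college] = 14 + np.minimum((scaled * 6).astype(int), 5)

    pc_w = config.pc_effect_rt / np.arange(1, 9)
    rt = (
        config.rt_base
        + config.rt_age_slope * (age - age.mean())
        - config.kappa_edu * factors.f_edu
        - config.kappa_res * factors.f_res
        + config.sex_effect_rt * (sex - 0.5)
        + config.array_effect_rt * (array - 0.5)
        + config.centre_effect_rt * (centre - 11.5)
        + pcs @ pc_w
        + config.noise_sd_rt * rng.standard_normal(n)
    )
    rt = np.maximum(rt, 1.0)

    cohort = pd.DataFrame(
        {
            "IID": genotypes.samples,
            "SEX": sex,
            "AGE": age,
            "CENTRE": centre,
            "ARRAY": array,
            **{f"PC{i + 1}": pcs[:, i] for i in range(8)},
            "EDU_YEARS": years,
            "COLLEGE": college.astype(int),
            "RT_MS": rt,
        }
    )
    return cohort[COVARIATE_COLUMNS]


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[GenotypeDataset, pd.DataFrame, FactorSet, TruthSet]:
    """One-call convenience wrapper running all three simulation stages."""
    genotypes = simulate_genotypes(config)
    factors, truth = simulate_latent_factors(genotypes, config)
    cohort = simulate_cohort_phenotypes(factors, genotypes, config)
    return genotypes, cohort, factors, truth


def export_fixtures(
    genotypes: GenotypeDataset,
    cohort: pd.DataFrame,
    truth: TruthSet,
    out_dir: str,
) -> dict:
    """Write genotypes.vcf, covariates.tsv and truth.tsv under ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "genotypes.vcf"),
        "covariates": os.path.join(out_dir, "covariates.tsv"),
        "truth": os.path.join(out_dir, "truth.tsv"),
    }
    write_vcf(genotypes, paths["vcf"])
    write_table(cohort, paths["covariates"])
    write_table(truth.as_frame(genotypes.variants), paths["truth"])
    return paths


@dataclass
class ContrastTruth:
    """True factor loadings of a binary contrast on the standardized-phenotype scale."""

    gamma_edu: float
    gamma_res: float
    h2_obs: float


def _residualize(y: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    if covariates is None:
        return y - y.mean()
    x = np.column_stack([np.ones(len(y)), covariates])
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ coef


def contrast_truth(
    factors: FactorSet,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
) -> ContrastTruth:
    """Empirical truth for a binary contrast: regress the (covariate-residualized,
    standardized) case indicator on the factors' genetic values within the
    contrast sample. ``y`` holds 1/0 for case/control and NaN elsewhere.
    """
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(y)
    yr = _residualize(y[mask], None if covariates is None else covariates[mask])
    yr = yr / yr.std()
    g = np.column_stack([factors.g_edu[mask], factors.g_res[mask]])
    x = np.column_stack([np.ones(mask.sum()), g])
    coef, *_ = np.linalg.lstsq(x, yr, rcond=None)
    fitted = g @ coef[1:]
    return ContrastTruth(
        gamma_edu=float(coef[1]),
        gamma_res=float(coef[2]),
        h2_obs=float(np.var(fitted) / np.var(yr)),
    )


def true_s_matrix(
    factors: FactorSet,
    y1: np.ndarray,
    y2: np.ndarray,
    covariates: np.ndarray | None = None,
    truth: TruthSet | None = None,
) -> np.ndarray:
    """True 2x2 genetic covariance of two binary contrasts on the observed scale.

    Each contrast's standardized case indicator loads on the factors with the
    in-sample coefficients gamma; under random causal placement the LD-score
    regression estimand for a pair of contrasts is ``gamma_k' B gamma_l``
    where B is the covariance of the causal standardized effects. With a
    truth set, B is exact (``sum beta_E^2``, ``sum beta_E*beta_R``,
    ``sum beta_R^2``); otherwise the empirical covariance of the factors'
    genetic values stands in.
    """
    t1 = contrast_truth(factors, y1, covariates)
    t2 = contrast_truth(factors, y2, covariates)
    if truth is not None:
        b = np.array(
            [
                [truth.beta_e_true @ truth.beta_e_true, truth.beta_e_true @ truth.beta_r_true],
                [truth.beta_e_true @ truth.beta_r_true, truth.beta_r_true @ truth.beta_r_true],
            ]
        )
    else:
        b = np.cov(np.vstack([factors.g_edu, factors.g_res]))
    gam1 = np.array([t1.gamma_edu, t1.gamma_res])
    gam2 = np.array([t2.gamma_edu, t2.gamma_res])
    s = np.array(
        [
            [gam1 @ b @ gam1, gam1 @ b @ gam2],
            [gam1 @ b @ gam2, gam2 @ b @ gam2],
        ]
    )
    return s
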