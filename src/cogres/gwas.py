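"""Per-SNP covariate-adjusted association, variant QC and replication testing.

The binary contrasts are analysed with logistic regression (log-odds per
effect-allele copy, Wald standard errors from the observed information);
quantitative phenotypes use ordinary least squares with the same output
schema. Conditional analysis adds a named SNP's dosage as an extra
covariate. The per-SNP fits are an in-package iteratively reweighted
least-squares solver, warm-started from the covariate-only null fit, so a
panel of thousands of variants fits in seconds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, gammaln

from .datatypes import GenotypeDataset

logger = logging.getLogger(__name__)

__all__ = [
    "QCThresholds",
    "SignTestResult",
    "hwe_exact_test",
    "variant_qc",
    "run_gwas",
    "bonferroni_threshold",
    "sign_test_replication",
]


@dataclass
class QCThresholds:
    """Variant-level quality-control cutoffs (defaults follow the study protocol)."""

    geno: float = 0.02  # max per-variant missingness
    maf: float = 0.001  # min minor-allele frequency
    info: float = 0.09  # min imputation info score
    hwe: float = 0.0001  # min Hardy-Weinberg exact p

    def validate(self) -> None:
        for name in ("geno", "maf", "info", "hwe"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"QC threshold {name}={v} outside [0, 1]")


def hwe_exact_test(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Two-sided Hardy-Weinberg exact p-value from genotype counts.

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the conditional probabilities no larger than that of the observed
    configuration (the standard exact formulation for biallelic genotypes).
    """
    n_het, n_hom_minor, n_hom_major = int(n_het), int(n_hom_minor), int(n_hom_major)
    if min(n_het, n_hom_minor, n_hom_major) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_het + n_hom_minor + n_hom_major
    if n == 0:
        return 1.0
    rare = 2 * n_hom_minor + n_het
    if rare > n:  # ensure 'rare' really is the minor allele count
        rare = 2 * n - rare
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(h het | allele counts) up to a shared constant
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln((rare - hets) / 2 + 1)
        - gammaln((2 * n - rare - hets) / 2 + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    p_obs = p[hets == n_het][0]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


def _hwe_pvalues(dosages: np.ndarray) -> np.ndarray:
    out = np.empty(dosages.shape[1])
    for j in range(dosages.shape[1]):
        d = dosages[:, j]
        d = d[np.isfinite(d)]
        counts = np.round(d).astype(int)
        n_het = int((counts == 1).sum())
        n_alt = int((counts == 2).sum())
        n_ref = int((counts == 0).sum())
        n_minor = n_alt if 2 * n_alt + n_het <= 2 * n_ref + n_het else n_ref
        n_major = n_ref + n_alt - n_minor
        out[j] = hwe_exact_test(n_het, n_minor, n_major)
    return out


def variant_qc(
    genotypes: GenotypeDataset, thresholds: QCThresholds | None = None
) -> tuple[GenotypeDataset, dict]:
    """Apply missingness / MAF / info / HWE filters and drop duplicates.

    A variant failing any filter is removed; duplicates (same chrom:pos with
    the same allele pair in either orientation, or a repeated id) keep the
    first occurrence. Returns the filtered dataset and a per-filter report of
    failure counts (a variant can be counted under several filters).
    """
    thresholds = thresholds or QCThresholds()
    thresholds.validate()
    dos, var = genotypes.dosages, genotypes.variants
    miss = np.mean(np.isnan(dos), axis=0)
    maf = genotypes.minor_allele_frequencies()
    info = var["INFO"].to_numpy(dtype=float)
    hwe_p = _hwe_pvalues(dos)

    fail_geno = miss > thresholds.geno
    fail_maf = maf < thresholds.maf
    fail_info = info < thresholds.info
    fail_hwe = hwe_p < thresholds.hwe

    key_pos = [
        (c, b, tuple(sorted((a1, a2))))
        for c, b, a1, a2 in zip(var["CHR"], var["BP"], var["A1"], var["A2"])
    ]
    dup = pd.Series(key_pos).duplicated().to_numpy() | var["SNP"].duplicated().to_numpy()

    keep = ~(fail_geno | fail_maf | fail_info | fail_hwe | dup)
    report = {
        "geno": int(fail_geno.sum()),
        "maf": int(fail_maf.sum()),
        "info": int(fail_info.sum()),
        "hwe": int(fail_hwe.sum()),
        "dup": int(dup.sum()),
        "retained": int(keep.sum()),
    }
    logger.info("variant_qc: %s", report)
    if not keep.any():
        raise ValueError("variant QC removed every variant")
    return genotypes.subset_variants(keep), report


def _logistic_fit(x, y, beta0=None, max_iter=50, tol=1e-10):
    """Newton/IRLS logistic fit; returns (beta, cov, converged)."""
    n, p = x.shape
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    converged = False
    h = None
    for _ in range(max_iter):
        eta = np.clip(x @ beta, -35, 35)
        mu = expit(eta)
        w = np.maximum(mu * (1 - mu), 1e-12)
        grad = x.T @ (y - mu)
        h = (x * w[:, None]).T @ x
        try:
            step = np.linalg.solve(h, grad)
        except np.linalg.LinAlgError:
            return beta, None, False
        beta += step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    if converged and np.max(np.abs(beta)) > 30:
        converged = False  # quasi-separation: estimates diverging
    try:
        cov = np.linalg.inv(h)
    except np.linalg.LinAlgError:
        return beta, None, False
    return beta, cov, converged


def _linear_fit(x, y):
    n, p = x.shape
    xtx = x.T @ x
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError:
        return None, None
    beta = xtx_inv @ (x.T @ y)
    resid = y - x @ beta
    dof = max(n - p, 1)
    cov = xtx_inv * (resid @ resid / dof)
    return beta, cov


def run_gwas(
    genotypes: GenotypeDataset,
    phenotype,
    covariates: pd.DataFrame | None = None,
    condition_snp: str | None = None,
    model: str = "logistic",
) -> pd.DataFrame:
    """Per-variant association scan.

    Parameters
    ----------
    phenotype
        Per-individual outcome aligned to ``genotypes.samples``: 1/0 for
        case/control (logistic) or continuous (linear); NaN = excluded.
    covariates
        Optional numeric covariate table (one row per individual).
    condition_snp
        Variant id whose dosage is added as a covariate (conditional scan);
        testing that same variant, or any variant in perfect LD with it,
        yields a flagged record rather than an estimate.

    Returns the standard summary-statistics frame (``SNP CHR BP A1 A2 FRQ
    BETA SE Z P N``) plus a ``FLAG`` column ('ok', 'no_converge',
    'collinear'); flagged records carry NaN effect estimates, never silent
    omissions.
    """
    if model not in {"logistic", "linear"}:
        raise ValueError("model must be 'logistic' or 'linear'")
    y_all = np.asarray(phenotype, dtype=float)
    if y_all.shape[0] != genotypes.n_individuals:
        raise ValueError("phenotype length does not match genotype rows")

    cov_mat = None
    if covariates is not None:
        cov_mat = np.asarray(covariates, dtype=float)
        if cov_mat.ndim == 1:
            cov_mat = cov_mat[:, None]

    cond_dose = None
    if condition_snp is not None:
        vidx = genotypes.variant_index()
        if condition_snp not in vidx.index:
            raise KeyError(f"condition SNP {condition_snp!r} not in dataset")
        cond_dose = genotypes.dosages[:, int(vidx[condition_snp])]

    base_cols = [np.ones(genotypes.n_individuals)]
    if cov_mat is not None:
        base_cols.append(cov_mat)
    if cond_dose is not None:
        base_cols.append(cond_dose[:, None])
    base = np.column_stack(base_cols)

    base_mask = np.isfinite(y_all) & np.all(np.isfinite(base), axis=1)
    if model == "logistic":
        classes = np.unique(y_all[base_mask])
        if not np.isin(classes, [0.0, 1.0]).all() or len(classes) < 2:
            raise ValueError("logistic model needs a 0/1 phenotype with both classes")
    if np.linalg.matrix_rank(base[base_mask]) < base.shape[1]:
        raise ValueError("covariate matrix (with intercept/condition SNP) is rank deficient")

    dos = genotypes.dosages
    clean_dose = not np.isnan(dos).any()
    p0 = base.shape[1]

    def prepare(mask):
        xb, yb = base[mask], y_all[mask]
        if model == "logistic":
            b0, _, _ = _logistic_fit(xb, yb)
            null_beta = np.append(b0, 0.0)
        else:
            null_beta = None
        x = np.empty((mask.sum(), p0 + 1))
        x[:, :p0] = xb
        return x, yb, null_beta

    x_shared, y_shared, null_shared = prepare(base_mask)

    m = genotypes.n_variants
    beta_out = np.full(m, np.nan)
    se_out = np.full(m, np.nan)
    frq = np.full(m, np.nan)
    n_out = np.zeros(m, dtype=int)
    flags = np.array(["ok"] * m, dtype=object)

    for j in range(m):
        g = dos[:, j]
        if clean_dose or not np.isnan(g[base_mask]).any():
            mask, x, y, null_beta = base_mask, x_shared, y_shared, null_shared
            gm = g[base_mask]
        else:
            mask = base_mask & np.isfinite(g)
            x, y, null_beta = prepare(mask)
            gm = g[mask]
        n_out[j] = mask.sum()
        frq[j] = gm.mean() / 2.0
        if gm.std() == 0:
            flags[j] = "collinear"
            continue
        if cond_dose is not None:
            c = cond_dose[mask]
            r = np.corrcoef(gm, c)[0, 1] if c.std() > 0 else 0.0
            if r * r > 1 - 1e-10:
                flags[j] = "collinear"
                continue
        x[:, p0] = gm
        if model == "logistic":
            beta, cov, ok = _logistic_fit(x, y, beta0=null_beta)
            if not ok or cov is None:
                flags[j] = "no_converge"
                continue
        else:
            beta, cov = _linear_fit(x, y)
            if beta is None:
                flags[j] = "collinear"
                continue
        beta_out[j] = beta[p0]
        se_out[j] = np.sqrt(cov[p0, p0])

    z = beta_out / se_out
    out = genotypes.variants[["SNP", "CHR", "BP", "A1", "A2"]].copy()
    out["FRQ"] = frq
    out["BETA"] = beta_out
    out["SE"] = se_out
    out["Z"] = z
    out["P"] = 2 * stats.norm.sf(np.abs(z))
    out["N"] = n_out
    out["FLAG"] = flags
    n_bad = int((flags != "ok").sum())
    if n_bad:
        logger.warning("run_gwas: %d variants flagged (%s)", n_bad, model)
    return out


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha/m."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m


@dataclass
class SignTestResult:
    """Directional-concordance replication of discovery lead SNPs."""

    n_leads: int
    n_concordant: int
    p_value: float  # exact one-sided binomial P(X >= k | n, 0.5)
    table: pd.DataFrame = field(repr=False, default=None)
    n_missing: int = 0


def sign_test_replication(
    lead_snps: pd.DataFrame, replication: pd.DataFrame, alpha: float = 0.05
) -> SignTestResult:
    """Exact binomial sign test of effect-direction concordance.

    Replication records are harmonised to the discovery effect allele (Z and
    beta flipped when A1/A2 are reversed); lead SNPs absent from the
    replication set are dropped with a warning. Per-SNP replication
    significance uses the Bonferroni threshold ``alpha / n_leads``.
    """
    rep = replication.set_index("SNP")
    rows = []
    n_missing = 0
    for _, snp in lead_snps.iterrows():
        if snp["SNP"] not in rep.index:
            n_missing += 1
            continue
        r = rep.loc[snp["SNP"]]
        if (snp["A1"], snp["A2"]) == (r["A1"], r["A2"]):
            flip = 1.0
        elif (snp["A1"], snp["A2"]) == (r["A2"], r["A1"]):
            flip = -1.0
        else:
            n_missing += 1
            continue
        rows.append(
            {
                "SNP": snp["SNP"],
                "BETA_DISC": snp["BETA"],
                "BETA_REP": flip * r["BETA"],
                "P_REP": r["P"],
            }
        )
    if n_missing:
        logger.warning("sign_test_replication: %d lead SNPs not usable in replication", n_missing)
    table = pd.DataFrame(rows)
    n = len(table)
    if n == 0:
        raise ValueError("no lead SNPs present in the replication statistics")
    table["CONCORDANT"] = np.sign(table["BETA_DISC"]) == np.sign(table["BETA_REP"])
    table["REPLICATED"] = table["P_REP"] < bonferroni_threshold(alpha, n)
    k = int(table["CONCORDANT"].sum())
    p = stats.binomtest(k, n, 0.5, alternative="greater").pvalue
    return SignTestResult(n_leads=n, n_concordant=k, p_value=float(p), table=table, n_missing=n_missing)
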