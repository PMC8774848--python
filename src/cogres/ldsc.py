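"""LD-score regression machinery: scores, munging, h2 and genetic covariance.

Under a polygenic model the expected squared association Z-statistic of
variant ``j`` is ``E[Z_j^2] = 1 + N * l_j * h2 / M`` where ``l_j`` is the
variant's LD score (sum of squared correlations with neighbours); products
of Z-statistics from two traits regress the same way on
``sqrt(N1*N2) * l_j / M`` with slope equal to the genetic covariance. Both
regressions use a free intercept (which absorbs confounding and, for the
cross-trait case, phenotypic overlap) and heteroskedasticity/over-counting
weights, with standard errors and the sampling covariance ``V`` of the
genetic covariance matrix ``S`` from a contiguous block jackknife.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GenotypeDataset

logger = logging.getLogger(__name__)

__all__ = [
    "LDSCFit",
    "GeneticCovariance",
    "compute_ld_scores",
    "munge",
    "standard_chisq_cap",
    "ldsc_univariate",
    "ldsc_bivariate",
]

_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}


def compute_ld_scores(reference: GenotypeDataset, window_kb: float = 1000.0) -> pd.DataFrame:
    """Per-variant LD scores from a reference dosage panel.

    ``l2_j = 1 + sum_k adj_r2(j, k)`` over neighbours within ``window_kb`` on
    the same chromosome, with the small-sample adjustment
    ``adj_r2 = r2 - (1 - r2) / (n - 2)`` (the self term is exactly 1).
    """
    n = reference.n_individuals
    if n <= 2:
        raise ValueError("need more than 2 individuals to estimate LD scores")
    var = reference.variants
    g = reference.standardized_dosages()
    window_bp = window_kb * 1000.0
    l2 = np.ones(reference.n_variants)

    for chrom in pd.unique(var["CHR"]):
        idx = np.flatnonzero((var["CHR"] == chrom).to_numpy())
        order = idx[np.argsort(var["BP"].to_numpy()[idx], kind="stable")]
        bp = var["BP"].to_numpy()[order].astype(float)
        gc = g[:, order]
        m = len(order)
        chunk = 256
        for start in range(0, m, chunk):
            stop = min(start + chunk, m)
            lo = np.searchsorted(bp, bp[start] - window_bp, side="left")
            hi = np.searchsorted(bp, bp[stop - 1] + window_bp, side="right")
            r = gc[:, start:stop].T @ gc[:, lo:hi] / n
            r2 = r * r
            adj = r2 - (1.0 - r2) / (n - 2)
            near = np.abs(bp[start:stop, None] - bp[None, lo:hi]) <= window_bp
            self_col = np.arange(start, stop) - lo
            near[np.arange(stop - start), self_col] = False
            l2[order[start:stop]] = 1.0 + (adj * near).sum(axis=1)
    return pd.DataFrame(
        {"CHR": var["CHR"], "SNP": var["SNP"], "BP": var["BP"], "L2": l2}
    )


def standard_chisq_cap(n) -> float:
    """The reference LDSC outlier cap for regression SNPs: max(80, 0.001*N)."""
    return float(max(80.0, 0.001 * float(np.median(n))))


def munge(
    sumstats: pd.DataFrame,
    reference_alleles: pd.DataFrame,
    min_maf: float = 0.01,
    min_info: float = 0.9,
    max_chisq: float | None = None,
) -> pd.DataFrame:
    """Harmonise summary statistics to reference alleles for LDSC input.

    Z is taken from the ``Z`` column or computed as BETA/SE; records are
    flipped (Z negated, frequency complemented) when A1/A2 are reversed
    relative to the reference and dropped when the alleles do not match at
    all. Strand-ambiguous (A/T, C/G) variants and variants failing the
    MAF/info filters are removed. ``max_chisq`` optionally drops Z^2
    outliers (the reference implementation's regression-SNP filter — see
    :func:`standard_chisq_cap`); leave it unset when the table feeds the
    per-SNP subtraction, where large-effect variants must be retained.
    Output columns: SNP A1 A2 Z N (+ FRQ).
    """
    df = sumstats.copy()
    if "Z" not in df.columns:
        df["Z"] = df["BETA"] / df["SE"]
    ref = reference_alleles[["SNP", "A1", "A2"]].rename(
        columns={"A1": "_A1R", "A2": "_A2R"}
    )
    df = df.merge(ref, on="SNP", how="inner")
    if df.empty:
        raise ValueError("no variants overlap the allele reference")

    same = (df["A1"] == df["_A1R"]) & (df["A2"] == df["_A2R"])
    swap = (df["A1"] == df["_A2R"]) & (df["A2"] == df["_A1R"])
    n_mismatch = int((~(same | swap)).sum())
    if n_mismatch:
        logger.info("munge: dropped %d variants with mismatching alleles", n_mismatch)
    df = df[same | swap].copy()
    flip = (df["A1"] == df["_A2R"]).to_numpy()
    df.loc[flip, "Z"] = -df.loc[flip, "Z"]
    if "BETA" in df.columns:
        df.loc[flip, "BETA"] = -df.loc[flip, "BETA"]
    if "FRQ" in df.columns:
        df.loc[flip, "FRQ"] = 1.0 - df.loc[flip, "FRQ"]
    df["A1"], df["A2"] = df["_A1R"], df["_A2R"]

    ambiguous = df.apply(lambda r: frozenset((r["A1"], r["A2"])) in _AMBIGUOUS, axis=1)
    df = df[~ambiguous.to_numpy()]
    if "FRQ" in df.columns:
        maf = np.minimum(df["FRQ"], 1.0 - df["FRQ"])
        df = df[maf >= min_maf]
    if "INFO" in df.columns:
        df = df[df["INFO"] >= min_info]
    df = df[np.isfinite(df["Z"])]
    if max_chisq is not None:
        n_out = int((df["Z"] ** 2 > max_chisq).sum())
        if n_out:
            logger.info("munge: dropped %d variants with chi^2 > %.1f", n_out, max_chisq)
        df = df[df["Z"] ** 2 <= max_chisq]
    keep = ["SNP", "A1", "A2", "Z", "N"] + (["FRQ"] if "FRQ" in df.columns else [])
    if "CHR" in df.columns:
        keep += ["CHR", "BP"]
    return df[keep].reset_index(drop=True)


def _resolve_blocks(m: int, n_blocks: int) -> np.ndarray:
    """Contiguous block labels; blocks reduced (and logged) when M is small."""
    eff = min(n_blocks, max(2, m // 10))
    if eff < n_blocks:
        logger.info("jackknife blocks reduced from %d to %d for M=%d", n_blocks, eff, m)
    return np.floor(np.arange(m) * eff / m).astype(int), eff


def _wls(x, y, w):
    """Weighted least squares of y on [x, 1]; returns (slope, intercept)."""
    sw = np.sqrt(w)
    design = np.column_stack([x * sw, sw])
    coef, *_ = np.linalg.lstsq(design, y * sw, rcond=None)
    return coef


def _expected_chi2(x, y, l2c, clip_lo):
    """Pass-1 fitted E[Z1*Z2] per variant (1/l2 weights), slope clipped."""
    slope0, int0 = _wls(x, y, 1.0 / l2c)
    return int0 + np.clip(slope0, clip_lo, 1.0) * x


def _wls_blocks(x, y, w, block_ids, n_blocks):
    """Full-sample WLS plus delete-one-block estimates (fixed weights)."""
    design = np.column_stack([x, np.ones_like(x)])
    wd = design * w[:, None]
    a_full = wd.T @ design
    c_full = wd.T @ y
    a_blocks = np.zeros((n_blocks, 2, 2))
    c_blocks = np.zeros((n_blocks, 2))
    for b in range(n_blocks):
        sel = block_ids == b
        a_blocks[b] = wd[sel].T @ design[sel]
        c_blocks[b] = wd[sel].T @ y[sel]
    full = np.linalg.solve(a_full, c_full)
    deletes = np.stack(
        [np.linalg.solve(a_full - a_blocks[b], c_full - c_blocks[b]) for b in range(n_blocks)]
    )
    return full, deletes


def _jackknife_cov(deletes: np.ndarray) -> np.ndarray:
    b = deletes.shape[0]
    centred = deletes - deletes.mean(axis=0)
    return (b - 1) / b * (centred.T @ centred)


@dataclass
class LDSCFit:
    """Univariate LD-score regression result."""

    h2: float
    h2_se: float
    intercept: float
    intercept_se: float
    m: int
    n_blocks: int
    deletes: np.ndarray = field(repr=False, default=None)  # (B, 2) slope/intercept


def _merge_ldscores(munged: pd.DataFrame, ldscores: pd.DataFrame) -> pd.DataFrame:
    # positions come from the LD-score table; drop any copies in the stats
    df = munged.drop(columns=[c for c in ("CHR", "BP") if c in munged.columns])
    df = df.merge(ldscores[["SNP", "BP", "L2"]], on="SNP", how="inner")
    if df.empty:
        raise ValueError("no overlap between summary statistics and LD scores")
    return df.sort_values("BP", kind="stable").reset_index(drop=True)


def ldsc_univariate(
    munged: pd.DataFrame,
    ldscores: pd.DataFrame,
    m: int | None = None,
    n_blocks: int = 200,
) -> LDSCFit:
    """Heritability and intercept by weighted regression of Z^2 on N*l2/M.

    Two weighting passes: an initial 1/l2 fit supplies a provisional h2 used
    to build the standard ``1 / (l2 * (1 + N*h2*l2/M)^2)`` weights for the
    final fit; the block jackknife reuses the final weights.
    """
    df = _merge_ldscores(munged, ldscores)
    n_snps = len(df)
    m = int(m) if m else n_snps
    if m <= 0:
        raise ValueError("M must be positive")
    l2 = df["L2"].to_numpy(dtype=float)
    n = df["N"].to_numpy(dtype=float)
    z2 = df["Z"].to_numpy(dtype=float) ** 2
    x = n * l2 / m
    l2c = np.maximum(l2, 1.0)

    # heteroskedasticity + over-counting weights: Var(Z^2) ~ 2*E[Z^2]^2
    a = np.maximum(_expected_chi2(x, z2, l2c, 0.0), 0.1)
    w = 1.0 / (l2c * 2.0 * a**2)

    block_ids, n_blk = _resolve_blocks(n_snps, n_blocks)
    full, deletes = _wls_blocks(x, z2, w, block_ids, n_blk)
    cov = _jackknife_cov(deletes)
    return LDSCFit(
        h2=float(full[0]),
        h2_se=float(np.sqrt(cov[0, 0])),
        intercept=float(full[1]),
        intercept_se=float(np.sqrt(cov[1, 1])),
        m=m,
        n_blocks=n_blk,
        deletes=deletes,
    )


@dataclass
class GeneticCovariance:
    """2x2 genetic covariance S with jackknife sampling covariance V.

    ``S`` is ordered [trait1, trait2] (for the resilience pipeline:
    [EY+Res, EY/NonRes]); ``V`` covers the half-vectorized unique elements
    (S11, S12, S22).
    """

    s: np.ndarray
    v: np.ndarray
    intercepts: dict
    m: int
    rg: float
    rg_se: float
    n_blocks: int

    @property
    def h2(self) -> tuple[float, float]:
        return float(self.s[0, 0]), float(self.s[1, 1])


def ldsc_bivariate(
    munged1: pd.DataFrame,
    munged2: pd.DataFrame,
    ldscores: pd.DataFrame,
    m: int | None = None,
    n_blocks: int = 200,
) -> GeneticCovariance:
    """Genetic covariance matrix of two traits with joint block jackknife.

    The three regressions (Z1^2, Z1*Z2, Z2^2 on the LD-score regressor) run
    on the intersected variant set; V is assembled from joint delete-block
    estimates of (S11, S12, S22), so its diagonal equals the squared
    jackknife SEs of the corresponding elements.
    """
    pair = munged1.merge(munged2, on="SNP", suffixes=("_1", "_2"))
    if pair.empty:
        raise ValueError("no variants shared between the two munged inputs")
    swap = (pair["A1_1"] == pair["A2_2"]) & (pair["A2_1"] == pair["A1_2"])
    pair.loc[swap, "Z_2"] = -pair.loc[swap, "Z_2"]
    aligned = swap | ((pair["A1_1"] == pair["A1_2"]) & (pair["A2_1"] == pair["A2_2"]))
    pair = pair[aligned]
    df = pair.rename(columns={"A1_1": "A1", "A2_1": "A2"}).merge(
        ldscores[["SNP", "BP", "L2"]], on="SNP", how="inner"
    )
    if df.empty:
        raise ValueError("no overlap with LD scores")
    df = df.sort_values("BP", kind="stable").reset_index(drop=True)

    n_snps = len(df)
    m = int(m) if m else n_snps
    l2 = df["L2"].to_numpy(dtype=float)
    l2c = np.maximum(l2, 1.0)
    z1 = df["Z_1"].to_numpy(dtype=float)
    z2 = df["Z_2"].to_numpy(dtype=float)
    n1 = df["N_1"].to_numpy(dtype=float)
    n2 = df["N_2"].to_numpy(dtype=float)

    x11 = n1 * l2 / m
    x22 = n2 * l2 / m
    x12 = np.sqrt(n1 * n2) * l2 / m

    # pass-1 expected values feed the standard variance approximations
    # Var(Z1^2) ~ 2*A1^2, Var(Z1*Z2) ~ A1*A2 + C^2 (reduces to the
    # univariate form when the two traits coincide)
    a1 = np.maximum(_expected_chi2(x11, z1**2, l2c, 0.0), 0.1)
    a2 = np.maximum(_expected_chi2(x22, z2**2, l2c, 0.0), 0.1)
    c = _expected_chi2(x12, z1 * z2, l2c, -1.0)
    w11 = 1.0 / (l2c * 2.0 * a1**2)
    w22 = 1.0 / (l2c * 2.0 * a2**2)
    w12 = 1.0 / (l2c * (a1 * a2 + c**2))

    block_ids, n_blk = _resolve_blocks(n_snps, n_blocks)
    full11, del11 = _wls_blocks(x11, z1**2, w11, block_ids, n_blk)
    full12, del12 = _wls_blocks(x12, z1 * z2, w12, block_ids, n_blk)
    full22, del22 = _wls_blocks(x22, z2**2, w22, block_ids, n_blk)

    s = np.array([[full11[0], full12[0]], [full12[0], full22[0]]])
    theta = np.column_stack([del11[:, 0], del12[:, 0], del22[:, 0]])
    v = _jackknife_cov(theta)

    # rg and its SE by the delta method from the jackknife V (a direct
    # jackknife of the ratio blows up when a delete-block h2 crosses zero)
    s11, s12, s22 = s[0, 0], s[0, 1], s[1, 1]
    if s11 > 0 and s22 > 0:
        rg = float(s12 / np.sqrt(s11 * s22))
        grad = np.array([-rg / (2 * s11), 1.0 / np.sqrt(s11 * s22), -rg / (2 * s22)])
        rg_se = float(np.sqrt(grad @ v @ grad))
    else:
        rg, rg_se = np.nan, np.nan

    return GeneticCovariance(
        s=s,
        v=v,
        intercepts={
            "trait1": float(full11[1]),
            "trait2": float(full22[1]),
            "cross": float(full12[1]),
        },
        m=m,
        rg=rg,
        rg_se=rg_se,
        n_blocks=n_blk,
    )
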