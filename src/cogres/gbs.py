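"""GWAS-by-subtraction: the two-indicator Cholesky model and per-SNP subtraction.

The genetic covariance matrix S of the two quadrant contrasts ([EY+Res,
EY/NonRes]) is decomposed into a shared *EduYears* factor (loading on both
indicators) and a residual *Resilience* factor (loading on EY+Res only):

    S11 = lambda_ee^2 + lambda_re^2
    S12 = lambda_ee * lambda_en
    S22 = lambda_en^2

where ``lambda_en`` = EduYears->EY/NonRes, ``lambda_ee`` = EduYears->EY+Res,
``lambda_re`` = Resilience->EY+Res. The model is just-identified, so the
closed-form Cholesky solution coincides with a weighted-least-squares fit of
the implied to the observed S. Regressing both latent factors on each SNP
and solving the (again just-identified) per-variant system turns the two
observed GWAS into *EduYears* and *Resilience* summary statistics; per-SNP
standardized effects use the ``Z / sqrt(N * 2pq)`` metric with allele
frequencies from a reference panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .ldsc import GeneticCovariance

logger = logging.getLogger(__name__)

__all__ = [
    "CholeskyLoadings",
    "fit_cholesky",
    "fit_cholesky_numerical",
    "subtract_snp",
    "effective_n",
    "latent_to_sumstats",
]


@dataclass
class CholeskyLoadings:
    """Path loadings of the two-indicator Cholesky model with sampling covariance."""

    lambda_edu_eyres: float  # EduYears -> EY+Res
    lambda_edu_nonres: float  # EduYears -> EY/NonRes (>= 0 by convention)
    lambda_res_eyres: float  # Resilience -> EY+Res (>= 0 by convention)
    cov: np.ndarray = field(default=None, repr=False)  # 3x3, order as fields above

    def implied_s(self) -> np.ndarray:
        lee, len_, lre = self.lambda_edu_eyres, self.lambda_edu_nonres, self.lambda_res_eyres
        return np.array(
            [[lee**2 + lre**2, lee * len_], [lee * len_, len_**2]]
        )

    def standard_errors(self) -> np.ndarray:
        if self.cov is None:
            return np.full(3, np.nan)
        return np.sqrt(np.diag(self.cov))


def fit_cholesky(s_v: GeneticCovariance | np.ndarray, v: np.ndarray | None = None) -> CholeskyLoadings:
    """Closed-form loadings from the 2x2 genetic covariance matrix.

    ``lambda_en = sqrt(S22)``, ``lambda_ee = S12 / sqrt(S22)``,
    ``lambda_re = sqrt(S11 - S12^2 / S22)``. A non-positive-semidefinite S
    (negative residual variance for the Resilience factor) raises rather than
    being silently clamped. Loading covariance is delta-propagated from V.
    """
    if isinstance(s_v, GeneticCovariance):
        s, v = s_v.s, s_v.v
    else:
        s = np.asarray(s_v, dtype=float)
    s11, s12, s22 = float(s[0, 0]), float(s[0, 1]), float(s[1, 1])
    if s22 <= 0:
        raise ValueError("S22 <= 0: the EduYears factor is undefined")
    if s11 <= 0:
        raise ValueError("S11 <= 0: EY+Res has no genetic variance")
    resid = s11 - s12**2 / s22
    if resid < 0:
        raise ValueError(
            f"S is not positive semidefinite (residual Resilience variance {resid:.3g} < 0); "
            "model inadmissible"
        )
    len_ = np.sqrt(s22)
    lee = s12 / len_
    lre = np.sqrt(resid)

    cov = None
    if v is not None:
        lre_safe = max(lre, 1e-12)
        # rows: d lambda / d (s11, s12, s22)
        jac = np.array(
            [
                [0.0, 1.0 / len_, -s12 / (2.0 * s22 * len_)],
                [0.0, 0.0, 1.0 / (2.0 * len_)],
                [
                    1.0 / (2.0 * lre_safe),
                    -s12 / (s22 * lre_safe),
                    s12**2 / (2.0 * s22**2 * lre_safe),
                ],
            ]
        )
        cov = jac @ np.asarray(v, dtype=float) @ jac.T
    return CholeskyLoadings(
        lambda_edu_eyres=float(lee),
        lambda_edu_nonres=float(len_),
        lambda_res_eyres=float(lre),
        cov=cov,
    )


def fit_cholesky_numerical(
    s: np.ndarray, v: np.ndarray | None = None
) -> CholeskyLoadings:
    """Numerical weighted-least-squares fit of the same model.

    Minimizes the V^-1-weighted discrepancy between the implied and observed
    unique elements of S. The model being just-identified, this coincides
    with the closed form; it exists as an independent route for
    cross-checking.
    """
    s = np.asarray(s, dtype=float)
    obs = np.array([s[0, 0], s[0, 1], s[1, 1]])
    if v is None:
        w_half = np.eye(3)
    else:
        w_half = np.linalg.cholesky(np.linalg.inv(np.asarray(v, dtype=float)))

    def residuals(params):
        lee, len_, lre = params
        implied = np.array([lee**2 + lre**2, lee * len_, len_**2])
        return w_half.T @ (implied - obs)

    x0 = np.array([np.sign(s[0, 1]) * 0.5 * np.sqrt(abs(s[0, 0])), np.sqrt(abs(s[1, 1])), 0.5 * np.sqrt(abs(s[0, 0]))])
    sol = optimize.least_squares(
        residuals, x0, bounds=([-np.inf, 0.0, 0.0], np.inf), xtol=1e-15, ftol=1e-15, gtol=1e-15
    )
    lee, len_, lre = sol.x
    return CholeskyLoadings(float(lee), float(len_), float(lre))


def subtract_snp(
    obs_eyres: pd.DataFrame,
    obs_nonres: pd.DataFrame,
    loadings: CholeskyLoadings,
    snp_freqs: pd.DataFrame,
    cross_intercept: float = 0.0,
    include_loading_uncertainty: bool = False,
) -> pd.DataFrame:
    """Regress the latent factors on each SNP and return latent summary stats.

    Inputs are munged tables (``SNP A1 A2 Z N``) already harmonised to a
    shared allele reference; ``snp_freqs`` supplies the A1 frequency used for
    the ``2pq`` standardization. Per variant the observed standardized
    effects are ``b1 = Z1 / sqrt(N1 * 2pq)`` (EY+Res) and ``b2`` likewise
    (EY/NonRes), and the just-identified system gives

        beta_edu = b2 / lambda_en
        beta_res = (b1 - lambda_ee * beta_edu) / lambda_re.

    Sampling variances follow by the delta method from var(b) = 1/(N*2pq)
    and the cross-trait covariance ``cross_intercept / (sqrt(N1*N2)*2pq)``
    (zero for disjoint samples); loading uncertainty can optionally be folded
    in (off by default — genome-wide loadings are treated as fixed).
    """
    lee, len_, lre = (
        loadings.lambda_edu_eyres,
        loadings.lambda_edu_nonres,
        loadings.lambda_res_eyres,
    )
    if len_ <= 0:
        raise ValueError("lambda_edu_nonres must be positive")
    if lre <= 0:
        raise ValueError("lambda_res_eyres is zero: subtraction undefined")

    freq = snp_freqs[["SNP", "FRQ"]]
    n_in = len(obs_eyres)
    df = (
        obs_eyres.merge(obs_nonres, on=["SNP", "A1", "A2"], suffixes=("_1", "_2"))
        .merge(freq, on="SNP", how="inner")
        .reset_index(drop=True)
    )
    dropped = n_in - len(df)
    if dropped:
        logger.info("subtract_snp: dropped %d variants missing from an input", dropped)
    if df.empty:
        raise ValueError("no variants shared across both inputs and the frequency reference")

    p = df["FRQ"].to_numpy(dtype=float)
    two_pq = 2.0 * p * (1.0 - p)
    n1 = df["N_1"].to_numpy(dtype=float)
    n2 = df["N_2"].to_numpy(dtype=float)
    b1 = df["Z_1"].to_numpy(dtype=float) / np.sqrt(n1 * two_pq)
    b2 = df["Z_2"].to_numpy(dtype=float) / np.sqrt(n2 * two_pq)

    beta_edu = b2 / len_
    beta_res = (b1 - lee * beta_edu) / lre

    var_b1 = 1.0 / (n1 * two_pq)
    var_b2 = 1.0 / (n2 * two_pq)
    cov_b = cross_intercept / (np.sqrt(n1 * n2) * two_pq)
    var_edu = var_b2 / len_**2
    ratio = lee / len_
    var_res = (var_b1 + ratio**2 * var_b2 - 2.0 * ratio * cov_b) / lre**2

    if include_loading_uncertainty and loadings.cov is not None:
        # gradients of (beta_edu, beta_res) w.r.t. (lee, len, lre) per variant
        d_edu = np.stack(
            [np.zeros_like(b2), -b2 / len_**2, np.zeros_like(b2)], axis=1
        )
        d_res = np.stack(
            [-beta_edu / lre, lee * b2 / (len_**2 * lre), -beta_res / lre], axis=1
        )
        var_edu = var_edu + np.einsum("ij,jk,ik->i", d_edu, loadings.cov, d_edu)
        var_res = var_res + np.einsum("ij,jk,ik->i", d_res, loadings.cov, d_res)

    se_edu = np.sqrt(var_edu)
    se_res = np.sqrt(var_res)
    z_edu = beta_edu / se_edu
    z_res = beta_res / se_res

    out = df[["SNP", "A1", "A2", "FRQ"]].copy()
    for col in ("CHR", "BP"):
        if f"{col}_1" in df.columns:
            out[col] = df[f"{col}_1"]
    out["BETA_RES"] = beta_res
    out["SE_RES"] = se_res
    out["Z_RES"] = z_res
    out["P_RES"] = 2 * stats.norm.sf(np.abs(z_res))
    out["BETA_EDU"] = beta_edu
    out["SE_EDU"] = se_edu
    out["Z_EDU"] = z_edu
    out["P_EDU"] = 2 * stats.norm.sf(np.abs(z_edu))
    out["N_1"] = n1
    out["N_2"] = n2
    return out


def effective_n(
    latent: pd.DataFrame,
    trait: str = "res",
    maf_lo: float = 0.10,
    maf_hi: float = 0.40,
) -> float:
    """Effective sample size of a latent-factor GWAS.

    Over variants with MAF strictly inside (maf_lo, maf_hi) — low and high
    MAF bias the inversion — each variant implies
    ``N_hat = (Z/beta)^2 / (2*MAF*(1-MAF))``; the effective N is their mean.
    Variants with beta == 0 are excluded (counted in the log).
    """
    key = trait.upper()
    beta = latent[f"BETA_{key}"].to_numpy(dtype=float)
    z = latent[f"Z_{key}"].to_numpy(dtype=float)
    frq = latent["FRQ"].to_numpy(dtype=float)
    maf = np.minimum(frq, 1.0 - frq)
    inside = (maf > maf_lo) & (maf < maf_hi)
    nonzero = beta != 0
    if int((inside & ~nonzero).sum()):
        logger.info("effective_n: excluded %d beta==0 variants", int((inside & ~nonzero).sum()))
    use = inside & nonzero & np.isfinite(beta) & np.isfinite(z)
    if not use.any():
        raise ValueError(f"no variants inside the MAF window ({maf_lo}, {maf_hi})")
    n_hat = (z[use] / beta[use]) ** 2 / (2.0 * maf[use] * (1.0 - maf[use]))
    return float(n_hat.mean())


def latent_to_sumstats(latent: pd.DataFrame, trait: str = "res", neff: float | None = None) -> pd.DataFrame:
    """Standard sumstats table (SNP CHR BP A1 A2 FRQ BETA SE Z P N) for one latent trait."""
    key = trait.upper()
    if neff is None:
        neff = effective_n(latent, trait)
    out = latent[[c for c in ("SNP", "CHR", "BP", "A1", "A2", "FRQ") if c in latent.columns]].copy()
    out["BETA"] = latent[f"BETA_{key}"]
    out["SE"] = latent[f"SE_{key}"]
    out["Z"] = latent[f"Z_{key}"]
    out["P"] = latent[f"P_{key}"]
    out["N"] = float(neff)
    return out
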