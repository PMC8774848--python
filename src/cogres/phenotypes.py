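"""Quadrant proxy-phenotype construction.

Education years stand in for early-adult cognitive performance and reaction
time (RT, ms) for current processing speed. Education is binarized at
<= 17 years with college attendees assigned 20; RT is age-corrected with the
least-squares slope of RT on age, log-transformed, and split at the sample
mean of ln corrected RT (ties count as "faster"). Crossing the two binaries
yields four groups, giving two case-control contrasts:

* ``EYRES``   — cases (below-average EY, faster RT: resilient) vs
  controls (above-average EY, slower RT: declined);
* ``NONRES``  — cases (below EY, slower RT) vs controls (above EY, faster
  RT), i.e. temporally consistent performance, carrying the education
  signal but not the resilience signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GROUPS",
    "RTCorrectionModel",
    "binarize_education",
    "correct_rt",
    "assign_quadrants",
    "build_phenotypes",
    "split_discovery_replication",
    "contrast_phenotype",
]

GROUPS = ["EYRES_CASE", "EYRES_CONTROL", "NONRES_CASE", "NONRES_CONTROL"]

COLLEGE_YEARS = 20.0
EY_SPLIT_YEARS = 17.0


@dataclass
class RTCorrectionModel:
    """Age-correction fit for reaction time."""

    slope: float  # ms per year
    reference_age: float  # years (sample mean age)
    ln_mean_threshold: float  # natural-log units of corrected RT


def binarize_education(cohort: pd.DataFrame) -> pd.Series:
    """Binary education phenotype: 'below' if years <= 17 else 'above'.

    College attendees (COLLEGE == 1) receive 20 years regardless of the
    recorded value; individuals missing both EDU_YEARS and COLLEGE are left
    NaN and their count logged.
    """
    years = pd.to_numeric(cohort.get("EDU_YEARS"), errors="coerce").astype(float).copy()
    if "COLLEGE" in cohort.columns:
        college = cohort["COLLEGE"].fillna(0).astype(float) > 0
        years[college] = COLLEGE_YEARS
    missing = years.isna()
    if missing.all():
        raise ValueError("no individual has usable education information")
    if missing.any():
        logger.info("binarize_education: excluded %d individuals missing education", missing.sum())
    out = pd.Series(np.where(years <= EY_SPLIT_YEARS, "below", "above"), index=cohort.index, dtype=object)
    out[missing] = np.nan
    return out


def correct_rt(cohort: pd.DataFrame) -> tuple[RTCorrectionModel, pd.DataFrame]:
    """Age-correct and log-transform RT, then split at the ln-mean.

    The slope is the least-squares slope of RT on age on the analysis sample
    (the standard reading of correcting "using the slope of the Pearson
    correlation"); correction is centred at the sample mean age so the mean
    RT is preserved. Returns the fitted model and a frame with ``RT_CORR``,
    ``LN_RT_CORR`` and ``RT_BINARY`` ('faster' iff ln corrected RT <= mean).
    """
    rt = pd.to_numeric(cohort["RT_MS"], errors="coerce").astype(float)
    age = pd.to_numeric(cohort["AGE"], errors="coerce").astype(float)
    usable = rt.notna() & age.notna() & (rt > 0)
    if usable.sum() < 2:
        raise ValueError("need at least two individuals with RT and age")
    a, r = age[usable].to_numpy(), rt[usable].to_numpy()
    var_age = np.var(a)
    if var_age == 0:
        raise ValueError("age has zero variance; RT age slope undefined")
    slope = float(np.cov(a, r, bias=True)[0, 1] / var_age)
    ref_age = float(a.mean())

    corr = rt - slope * (age - ref_age)
    nonpos = usable & (corr <= 0)
    if nonpos.any():
        logger.warning("correct_rt: excluded %d individuals with non-positive corrected RT", nonpos.sum())
    keep = usable & (corr > 0)
    ln_rt = pd.Series(np.nan, index=cohort.index)
    ln_rt[keep] = np.log(corr[keep])
    threshold = float(ln_rt[keep].mean())

    binary = pd.Series(np.nan, index=cohort.index, dtype=object)
    binary[keep] = np.where(ln_rt[keep] <= threshold, "faster", "slower")
    model = RTCorrectionModel(slope=slope, reference_age=ref_age, ln_mean_threshold=threshold)
    out = pd.DataFrame({"RT_CORR": corr.where(keep), "LN_RT_CORR": ln_rt, "RT_BINARY": binary})
    return model, out


def assign_quadrants(ey_binary: pd.Series, rt_binary: pd.Series) -> pd.Series:
    """Map the two binaries onto the four case-control groups.

    (below, faster) -> EYRES_CASE; (above, slower) -> EYRES_CONTROL;
    (below, slower) -> NONRES_CASE; (above, faster) -> NONRES_CONTROL.
    """
    mapping = {
        ("below", "faster"): "EYRES_CASE",
        ("above", "slower"): "EYRES_CONTROL",
        ("below", "slower"): "NONRES_CASE",
        ("above", "faster"): "NONRES_CONTROL",
    }
    out = pd.Series(np.nan, index=ey_binary.index, dtype=object)
    both = ey_binary.notna() & rt_binary.notna()
    out[both] = [mapping[(e, r)] for e, r in zip(ey_binary[both], rt_binary[both])]
    return out


def build_phenotypes(cohort: pd.DataFrame) -> tuple[pd.DataFrame, RTCorrectionModel]:
    """Add EY_BINARY, RT_BINARY and GROUP columns to a cohort table.

    Individuals missing either measure are dropped before the RT threshold is
    computed, so both binaries are defined on the final analysis sample.
    """
    ey = binarize_education(cohort)
    analysis = cohort[ey.notna() & cohort["RT_MS"].notna()].copy()
    model, rt_frame = correct_rt(analysis)
    out = analysis.assign(
        EY_BINARY=ey[analysis.index],
        RT_BINARY=rt_frame["RT_BINARY"],
        LN_RT_CORR=rt_frame["LN_RT_CORR"],
    )
    out["GROUP"] = assign_quadrants(out["EY_BINARY"], out["RT_BINARY"])
    out = out[out["GROUP"].notna()]
    return out, model


def split_discovery_replication(
    cohort: pd.DataFrame,
    fraction_discovery: float = 0.81,
    seed: int = 0,
    force_replication: list | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive discovery/replication split (default 81/19).

    ``force_replication`` lists IIDs reserved for the replication half (the
    real study reserved imaging participants this way); remaining membership
    is a seeded permutation. Discovery size is round(fraction * N).
    """
    if not (0 < fraction_discovery < 1):
        raise ValueError("fraction_discovery must be in (0, 1)")
    n = len(cohort)
    n_disc = int(round(fraction_discovery * n))
    rng = np.random.default_rng(seed)

    forced = np.zeros(n, dtype=bool)
    if force_replication:
        forced = cohort["IID"].isin(set(force_replication)).to_numpy()
    if forced.sum() > n - n_disc:
        n_disc = n - int(forced.sum())
    free = np.flatnonzero(~forced)
    picked = rng.permutation(free)[:n_disc]
    is_disc = np.zeros(n, dtype=bool)
    is_disc[picked] = True
    return cohort[is_disc].copy(), cohort[~is_disc].copy()


def contrast_phenotype(pheno: pd.DataFrame, contrast: str = "EYRES") -> pd.Series:
    """1/0/NaN case-control indicator for the EYRES or NONRES contrast."""
    if contrast not in {"EYRES", "NONRES"}:
        raise ValueError("contrast must be 'EYRES' or 'NONRES'")
    y = pd.Series(np.nan, index=pheno.index)
    y[pheno["GROUP"] == f"{contrast}_CASE"] = 1.0
    y[pheno["GROUP"] == f"{contrast}_CONTROL"] = 0.0
    return y
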