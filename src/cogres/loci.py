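"""Two-stage LD clumping and genomic locus definition.

Mirrors the FUMA convention: genome-wide significant variants (p < 5e-8)
are greedily clumped at r^2 < 0.6 into *independent significant SNPs*; a
second clumping pass at r^2 < 0.1 picks *lead SNPs*; every reference
variant with r^2 >= 0.6 to an independent significant SNP is a *candidate
SNP*, the candidate hull forms the locus interval, and intervals separated
by at most 250 kb are merged. r^2 is the squared Pearson correlation of
unphased dosages in the reference panel.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import GenotypeDataset

logger = logging.getLogger(__name__)

__all__ = ["find_independent_significant", "define_leads_and_loci"]

GENOME_WIDE_P = 5e-8


def _greedy_clump(cand: pd.DataFrame, g_std: np.ndarray, col_of: dict, r2_max: float, n: int):
    """Greedy p-ascending clump; keeps a variant iff r^2 < r2_max with all kept ones."""
    kept_rows = []
    kept_cols: dict = {}  # chrom -> list of reference columns
    n_unref = 0
    for _, row in cand.iterrows():
        col = col_of.get(row["SNP"])
        if col is None:
            n_unref += 1
            kept_rows.append(row)
            continue
        cols_same = kept_cols.get(row["CHR"], [])
        if cols_same:
            g = g_std[:, col]
            r = g @ g_std[:, cols_same] / n
            if np.any(r * r >= r2_max):
                continue
        kept_rows.append(row)
        kept_cols.setdefault(row["CHR"], []).append(col)
    return pd.DataFrame(kept_rows).reset_index(drop=True), n_unref


def _sorted_significant(sumstats: pd.DataFrame, p_threshold: float) -> pd.DataFrame:
    sig = sumstats[sumstats["P"] < p_threshold].copy()
    return sig.sort_values(["P", "CHR", "BP", "SNP"], kind="stable").reset_index(drop=True)


def find_independent_significant(
    sumstats: pd.DataFrame,
    reference: GenotypeDataset,
    p_threshold: float = GENOME_WIDE_P,
    r2: float = 0.6,
) -> pd.DataFrame:
    """Independent significant SNPs by greedy clumping at ``r^2 < r2``.

    Significant variants are visited in ascending p (ties broken by position
    then id); one is accepted iff its r^2 with every previously accepted
    variant on the same chromosome stays below the threshold. Variants
    absent from the reference panel are retained as independent with a
    warning.
    """
    sig = _sorted_significant(sumstats, p_threshold)
    if sig.empty:
        return sig
    g_std = reference.standardized_dosages()
    col_of = {s: int(i) for i, s in enumerate(reference.variants["SNP"])}
    kept, n_unref = _greedy_clump(sig, g_std, col_of, r2, reference.n_individuals)
    if n_unref:
        logger.warning(
            "find_independent_significant: %d significant variants absent from reference "
            "(treated as independent)",
            n_unref,
        )
    return kept


def define_leads_and_loci(
    independent_significant: pd.DataFrame,
    sumstats: pd.DataFrame,
    reference: GenotypeDataset,
    r2_ind: float = 0.6,
    r2_lead: float = 0.1,
    merge_kb: float = 250.0,
) -> pd.DataFrame:
    """Lead SNPs (second-stage clump at ``r^2 < r2_lead``) and merged loci.

    Each independent significant SNP contributes a candidate set (reference
    variants with ``r^2 >= r2_ind`` to it, itself included); the locus
    interval spans the candidate hull, hulls separated by at most
    ``merge_kb`` kb (end-to-start) merge, and the per-locus index SNP is the
    member with the smallest p. Returns one row per locus:
    ``LOCUS CHR START END INDEX_SNP N_LEAD N_IND_SIG N_CANDIDATE LEAD_SNPS``.
    """
    ind = independent_significant
    if ind.empty:
        raise ValueError("independent significant set is empty")
    ind = ind.sort_values(["P", "CHR", "BP", "SNP"], kind="stable").reset_index(drop=True)
    g_std = reference.standardized_dosages()
    n = reference.n_individuals
    col_of = {s: int(i) for i, s in enumerate(reference.variants["SNP"])}
    leads, _ = _greedy_clump(ind, g_std, col_of, r2_lead, n)
    lead_ids = set(leads["SNP"])

    ref_var = reference.variants
    ref_bp = ref_var["BP"].to_numpy()
    # candidate hull and membership per independent significant SNP
    records = []
    for _, row in ind.iterrows():
        col = col_of.get(row["SNP"])
        if col is None:
            start = end = int(row["BP"])
            n_cand = 1
            cand_cols = frozenset()
        else:
            same_chr = np.flatnonzero((ref_var["CHR"] == row["CHR"]).to_numpy())
            r = g_std[:, col] @ g_std[:, same_chr] / n
            cand = same_chr[r * r >= r2_ind]
            start, end = int(ref_bp[cand].min()), int(ref_bp[cand].max())
            start, end = min(start, int(row["BP"])), max(end, int(row["BP"]))
            n_cand = len(cand)
            cand_cols = frozenset(int(c) for c in cand)
        records.append(
            {
                "SNP": row["SNP"],
                "CHR": row["CHR"],
                "BP": int(row["BP"]),
                "P": row["P"],
                "START": start,
                "END": end,
                "cand": cand_cols,
            }
        )
    hull = pd.DataFrame(records).sort_values(["CHR", "START", "END"], kind="stable")

    loci = []
    for chrom, grp in hull.groupby("CHR", sort=False):
        current = None
        for _, row in grp.iterrows():
            if current is not None and row["START"] - current["END"] <= merge_kb * 1000:
                current["END"] = max(current["END"], row["END"])
                current["members"].append(row)
            else:
                if current is not None:
                    loci.append(current)
                current = {
                    "CHR": chrom,
                    "START": row["START"],
                    "END": row["END"],
                    "members": [row],
                }
        if current is not None:
            loci.append(current)

    rows = []
    for i, loc in enumerate(sorted(loci, key=lambda d: (str(d["CHR"]), d["START"]))):
        members = pd.DataFrame(loc["members"])
        index_row = members.loc[members["P"].idxmin()]
        cand_union = frozenset().union(*members["cand"])
        lead_here = sorted(s for s in members["SNP"] if s in lead_ids)
        rows.append(
            {
                "LOCUS": i + 1,
                "CHR": loc["CHR"],
                "START": int(loc["START"]),
                "END": int(loc["END"]),
                "INDEX_SNP": index_row["SNP"],
                "N_LEAD": len(lead_here),
                "N_IND_SIG": len(members),
                "N_CANDIDATE": max(len(cand_union), len(members)),
                "LEAD_SNPS": ",".join(lead_here),
            }
        )
    return pd.DataFrame(rows)
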