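"""Reading and writing of the on-disk formats used by the pipeline.

Genotypes travel as VCF v4.2 with hard GT calls (dosages are integral by
construction); tabular artefacts (phenotypes, summary statistics, LD scores,
truth tables, locus tables) are tab-delimited text with a header row.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datatypes import SUMSTATS_COLUMNS, GenotypeDataset

_VCF_HEADER = """##fileformat=VCFv4.2
##source=cogres
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation info score">
"""

_GT_CODES = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(genotypes: GenotypeDataset, path: str) -> str:
    """Write hard-call genotypes as a VCF v4.2 text file.

    A1 (the counted/effect allele) is written as ALT; dosage ``k`` becomes a
    genotype with ``k`` ALT alleles, ``NaN`` becomes ``./.``.
    """
    var = genotypes.variants
    dos = genotypes.dosages
    contigs = "".join(
        f"##contig=<ID={c}>\n" for c in pd.unique(var["CHR"].astype(str))
    )
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(contigs)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in genotypes.samples)
            + "\n"
        )
        for j in range(genotypes.n_variants):
            row = var.iloc[j]
            calls = []
            for d in dos[:, j]:
                if np.isnan(d):
                    calls.append("./.")
                else:
                    calls.append(_GT_CODES[int(round(d))])
            fh.write(
                f"{row['CHR']}\t{int(row['BP'])}\t{row['SNP']}\t{row['A2']}\t"
                f"{row['A1']}\t.\tPASS\tINFO={float(row.get('INFO', 1.0)):g}\tGT\t"
                + "\t".join(calls)
                + "\n"
            )
    return path


def read_vcf(path: str) -> GenotypeDataset:
    """Load a VCF into a :class:`GenotypeDataset` (ALT-allele dosages from GT)."""
    vcf = VCF(path)
    samples = list(vcf.samples)
    rows, dosage_cols = [], []
    for v in vcf:
        info = v.INFO.get("INFO")
        rows.append(
            {
                "SNP": v.ID if v.ID else f"{v.CHROM}:{v.POS}",
                "CHR": v.CHROM,
                "BP": v.POS,
                "A1": v.ALT[0] if v.ALT else ".",
                "A2": v.REF,
                "INFO": float(info) if info is not None else 1.0,
            }
        )
        gts = np.array(v.genotypes, dtype=object)
        col = np.empty(len(samples))
        for i, gt in enumerate(gts):
            a, b = gt[0], gt[1]
            col[i] = np.nan if (a < 0 or b < 0) else float(a + b)
        dosage_cols.append(col)
    if not rows:
        raise ValueError(f"no variants found in {path}")
    return GenotypeDataset(
        dosages=np.column_stack(dosage_cols),
        variants=pd.DataFrame(rows),
        samples=samples,
    )


def write_table(df: pd.DataFrame, path: str) -> str:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
    return path


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def write_sumstats(df: pd.DataFrame, path: str) -> str:
    """Write summary statistics with the canonical column order first."""
    cols = [c for c in SUMSTATS_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    return write_table(df[cols], path)


read_sumstats = read_table


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
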