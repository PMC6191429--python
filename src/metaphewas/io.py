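"""Tabular and VCF input/output.

TSV dialect: tab-separated, UTF-8, '.' decimal, mandatory header, 'NA' for
missing values, scientific notation rendered with %.6g.  VCF support covers
the narrow use case of a few dozen hard-called biallelic SNPs: written as
minimal VCFv4.2 with a GT-only FORMAT (diploid, unphased), read back through
cyvcf2 with multi-allelic records rejected.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from metaphewas._errors import ConfigError

NA = "NA"


def write_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False, na_rep=NA, float_format="%.6g")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA])


_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(dosages: pd.DataFrame, path: str | Path, chrom: str = "1") -> None:
    """Write a dosage table (snp_id, effect_allele, other_allele, samples...) as VCF.

    The effect (minor) allele is the ALT allele; dosages count ALT copies.
    Positions are synthetic (1-based row order spaced 1 kb apart).
    """
    meta_cols = ("snp_id", "effect_allele", "other_allele")
    samples = [c for c in dosages.columns if c not in meta_cols]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for i in range(len(dosages)):
            vals = dosages.iloc[i]
            calls = "\t".join(
                _GT.get(int(vals[s]), "./.") if np.isfinite(vals[s]) else "./."
                for s in samples
            )
            fh.write(
                f"{chrom}\t{(i + 1) * 1000}\t{vals['snp_id']}\t{vals['other_allele']}\t"
                f"{vals['effect_allele']}\t.\tPASS\t.\tGT\t{calls}\n"
            )


def read_vcf_dosages(path: str | Path) -> pd.DataFrame:
    """Read a VCF into the dosage-table layout; rejects multi-allelic records."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise ConfigError(
                f"multi-allelic record at {variant.CHROM}:{variant.POS} not supported"
            )
        gts = variant.gt_types  # 0/1/2 copies of ALT, 3 = missing
        dos = np.where(gts == 3, np.nan, gts).astype(float)
        rows.append(
            {
                "snp_id": variant.ID or f"{variant.CHROM}:{variant.POS}",
                "effect_allele": variant.ALT[0],
                "other_allele": variant.REF,
                **dict(zip(samples, dos)),
            }
        )
    return pd.DataFrame(rows)


def read_regional_stats(path: str | Path, trait_type: str = "cc"):
    """Load a regional summary TSV (snp_id, beta, se [, ...]) for colocalization."""
    from metaphewas.coloc import RegionalStats

    frame = read_tsv(path)
    for col in ("snp_id", "beta", "se"):
        if col not in frame.columns:
            raise ConfigError(f"{path}: missing required column {col!r}")
    return RegionalStats(
        snp_ids=frame.snp_id.astype(str).tolist(),
        beta=frame.beta.to_numpy(dtype=float),
        se=frame.se.to_numpy(dtype=float),
        trait_type=trait_type,
    )
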