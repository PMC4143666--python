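"""Genotype-dosage input/output: VCF 4.2 with a DS FORMAT field, and a
plain TSV dosage matrix (rows = SNPs, columns = individuals)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simdata import GenotypeDosages

__all__ = ["write_vcf", "read_vcf", "write_dosage_tsv", "read_dosage_tsv"]


def write_vcf(geno: GenotypeDosages, path) -> None:
    """Write dosages as an uncompressed VCF with per-sample DS values."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of the alternate allele">')
    for chrom in dict.fromkeys(geno.chroms):
        max_pos = int(
            max(p for c, p in zip(geno.chroms, geno.positions) if c == chrom)
        )
        header.add_line(f"##contig=<ID={chrom},length={max_pos + 1000}>")
    for s in geno.ids:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for j, (snp, chrom, pos) in enumerate(
            zip(geno.snp_ids, geno.chroms, geno.positions)
        ):
            rec = vf.new_record(
                contig=chrom, start=int(pos) - 1, stop=int(pos),
                alleles=("A", "G"), id=snp,
            )
            for i, s in enumerate(geno.ids):
                rec.samples[s]["DS"] = float(geno.dosages[i, j])
            vf.write(rec)


def read_vcf(path) -> GenotypeDosages:
    """Read per-sample DS dosages from a VCF."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    snp_ids, chroms, positions, rows = [], [], [], []
    for var in vcf:
        ds = var.format("DS")
        if ds is None:
            raise ValueError(f"variant {var.ID or var.POS} lacks a DS FORMAT field")
        snp_ids.append(var.ID if var.ID else f"{var.CHROM}_{var.POS}")
        chroms.append(var.CHROM)
        positions.append(var.POS)
        rows.append(np.asarray(ds, dtype=float).ravel())
    vcf.close()
    dosages = np.column_stack(rows) if rows else np.zeros((len(ids), 0))
    return GenotypeDosages(
        ids=ids, snp_ids=snp_ids, chroms=chroms,
        positions=np.asarray(positions, dtype=np.int64), dosages=dosages,
    )


def write_dosage_tsv(geno: GenotypeDosages, path) -> None:
    df = pd.DataFrame(geno.dosages.T, index=geno.snp_ids, columns=geno.ids)
    df.insert(0, "chrom", geno.chroms)
    df.insert(1, "pos", geno.positions)
    df.to_csv(path, sep="\t", index_label="snp_id", float_format="%.6g")


def read_dosage_tsv(path) -> GenotypeDosages:
    df = pd.read_csv(path, sep="\t", index_col="snp_id")
    chroms = df.pop("chrom").astype(str).tolist()
    positions = df.pop("pos").to_numpy(dtype=np.int64)
    return GenotypeDosages(
        ids=[str(c) for c in df.columns],
        snp_ids=[str(s) for s in df.index],
        chroms=chroms,
        positions=positions,
        dosages=df.to_numpy(dtype=float).T,
    )
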