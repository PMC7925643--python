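"""Readers and writers for the standard formats the pipeline exchanges.

VCF is read with cyvcf2 and written with pysam; FASTA goes through
Biopython; everything tabular (sample sheets, site-call tables, BED gene
intervals, 12-column alignment tables, term annotations) is plain TSV via
pandas.  All writers round-trip through the matching reader.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

from .containers import (
    MISSING,
    SITE_CALL_COLUMNS,
    GenotypeMatrix,
    PopulationMap,
    new_presence_matrix,
    validate_site_calls,
)

# ---------------------------------------------------------------------------
# VCF

_DOSAGE_TO_GT_FIELD = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}


def write_vcf(gm: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a diploid biallelic SNP VCF ("./." for missing genotypes)."""
    header = pysam.VariantHeader()
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"), ("Type", "String"), ("Description", "Genotype")])
    for chrom in pd.unique(gm.sites["chrom"]):
        max_pos = int(gm.sites.loc[gm.sites["chrom"] == chrom, "pos"].max())
        header.contigs.add(str(chrom), length=max_pos + 1)
    for iso in gm.isolates:
        header.add_sample(iso)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i, row in enumerate(gm.sites.itertuples(index=False)):
            rec = out.new_record(
                contig=str(row.chrom),
                start=int(row.pos) - 1,
                stop=int(row.pos),
                alleles=(str(row.ref), str(row.alt)),
            )
            for j, iso in enumerate(gm.isolates):
                rec.samples[iso]["GT"] = _DOSAGE_TO_GT_FIELD[int(gm.dosages[i, j])]
            out.write(rec)


def read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Read a biallelic SNP VCF into a :class:`GenotypeMatrix`.

    Multiallelic or non-SNP records raise ``ValueError``: the pipeline is
    defined on biallelic SNPs only.
    """
    vcf = VCF(str(path))
    isolates = list(vcf.samples)
    chroms, poss, refs, alts = [], [], [], []
    rows = []
    # cyvcf2 gt_types: 0=hom_ref 1=het 2=unknown 3=hom_alt
    remap = np.array([0, 1, MISSING, 2], dtype=np.int8)
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"non-biallelic record at {var.CHROM}:{var.POS}")
        if len(var.REF) != 1 or len(var.ALT[0]) != 1:
            raise ValueError(f"non-SNP record at {var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        rows.append(remap[var.gt_types])
    vcf.close()
    sites = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    dosages = np.vstack(rows) if rows else np.zeros((0, len(isolates)), dtype=np.int8)
    return GenotypeMatrix(sites=sites, isolates=isolates, dosages=dosages)


# ---------------------------------------------------------------------------
# sample sheet / tabular

def write_sample_sheet(pm: PopulationMap, path: str | os.PathLike) -> None:
    pm.table[PopulationMap.REQUIRED].to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | os.PathLike) -> PopulationMap:
    return PopulationMap(pd.read_csv(path, sep="\t", dtype=str))


def write_site_calls(calls: pd.DataFrame, path: str | os.PathLike) -> None:
    validate_site_calls(calls)[SITE_CALL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_site_calls(path: str | os.PathLike) -> pd.DataFrame:
    return validate_site_calls(pd.read_csv(path, sep="\t"))


def write_presence_matrix(pm_mat: pd.DataFrame, path: str | os.PathLike) -> None:
    pm_mat.astype(int).to_csv(path, sep="\t", index_label="isolate")


def read_presence_matrix(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="isolate")
    return new_presence_matrix(df.index, df.columns, df.values.astype(bool))


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(seqs: dict[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# 12-column tabular alignment (blast outfmt-6 layout)

ALN_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def write_alignment_table(records: pd.DataFrame, path: str | os.PathLike) -> None:
    records[ALN_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def read_alignment_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=ALN_COLUMNS)
    return df


def write_alignment_tables(aln: pd.DataFrame, outdir: str | os.PathLike) -> list[Path]:
    """One 12-column table per isolate; ``aln`` carries an ``isolate`` column."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for iso, sub in aln.groupby("isolate", sort=True):
        p = outdir / f"{iso}.aln.tsv"
        write_alignment_table(sub, p)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# BED gene intervals

def write_bed(genes: pd.DataFrame, path: str | os.PathLike) -> None:
    genes[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    genes = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    if ((genes["start"] < 0) | (genes["start"] >= genes["end"])).any():
        raise ValueError("malformed BED interval (need 0 <= start < end)")
    return genes


# ---------------------------------------------------------------------------
# term annotations (two-column: term id, gene) + term names

def read_term_annotations(path: str | os.PathLike) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"term", "gene"} <= set(df.columns):
        raise ValueError("term annotation TSV needs 'term' and 'gene' columns")
    return {term: set(sub["gene"]) for term, sub in df.groupby("term")}


def write_term_annotations(terms: dict[str, set[str]], path: str | os.PathLike) -> None:
    rows = [(t, g) for t in sorted(terms) for g in sorted(terms[t])]
    pd.DataFrame(rows, columns=["term", "gene"]).to_csv(path, sep="\t", index=False)
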