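"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA through Bio.SeqIO, GFF3 reading through gffutils, VCF reading through
pysam; count tables and F2 tables are TSV via pandas. All coordinates on
disk are 1-based as the formats require.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .effects import GeneModel
from .synthetic_data import F2Individual, ReadCountTable, VariantSite

COUNT_COLUMNS = ["chrom", "pos", "ref", "alt"]


# -- FASTA ------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# -- GFF3 -------------------------------------------------------------------

def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            start = min(s for s, _ in g.cds)
            end = max(e for _, e in g.cds)
            fh.write(
                f"{g.chrom}\tintrobsa\tgene\t{start}\t{end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            fh.write(
                f"{g.chrom}\tintrobsa\tmRNA\t{start}\t{end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.1;Parent={g.gene_id}\n"
            )
            cds = sorted(g.cds)
            phases = g.cds_phases()
            for (s, e), ph in zip(cds, phases):
                fh.write(
                    f"{g.chrom}\tintrobsa\tCDS\t{s}\t{e}\t.\t{g.strand}\t{ph}\t"
                    f"ID={g.gene_id}.cds;Parent={g.gene_id}.1\n"
                )


def read_gff3(path: str | Path) -> list[GeneModel]:
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        parent = mrnas[0] if mrnas else gene
        cds = [(c.start, c.end) for c in db.children(parent, featuretype="CDS")]
        first = sorted(
            db.children(parent, featuretype="CDS"),
            key=lambda c: c.start,
            reverse=(gene.strand == "-"),
        )[0]
        phase = int(first.frame) if first.frame not in (None, ".") else 0
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                cds=sorted(cds),
                phase=phase,
            )
        )
    return genes


# -- read-count tables ------------------------------------------------------

def write_counts_tsv(table: ReadCountTable, path: str | Path) -> None:
    """Header ``chrom pos ref alt <bulk>_ref <bulk>_alt ...`` (tab-separated)."""
    cols = COUNT_COLUMNS + [f"{b}_{k}" for b in table.bulks for k in ("ref", "alt")]
    table.df[cols].to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | Path) -> ReadCountTable:
    df = pd.read_csv(path, sep="\t")
    bulks = sorted({c[:-4] for c in df.columns if c.endswith("_ref")})
    return ReadCountTable(df, bulks)


def write_counts_vcf(table: ReadCountTable, path: str | Path) -> None:
    """VCF 4.2 with one sample per bulk and per-sample AD (ref,alt depths)."""
    df = table.df.sort_values(["chrom", "pos"], kind="stable")
    chroms = list(dict.fromkeys(df["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths (ref,alt)">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.bulks) + "\n"
        )
        for row in df.itertuples(index=False):
            sample_fields = "\t".join(
                f"{getattr(row, f'{b}_ref')},{getattr(row, f'{b}_alt')}"
                for b in table.bulks
            )
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\t.\t.\tAD\t"
                f"{sample_fields}\n"
            )


def read_counts_vcf(path: str | Path) -> ReadCountTable:
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        bulks = list(vf.header.samples)
        for rec in vf:
            row = [rec.chrom, rec.pos, rec.ref, rec.alts[0]]
            for b in bulks:
                ad = rec.samples[b]["AD"]
                row += [int(ad[0]), int(ad[1])]
            rows.append(row)
    cols = COUNT_COLUMNS + [f"{b}_{k}" for b in bulks for k in ("ref", "alt")]
    return ReadCountTable(pd.DataFrame(rows, columns=cols), bulks)


# -- panel VCF --------------------------------------------------------------

def write_panel_vcf(variants: Iterable[VariantSite], path: str | Path) -> None:
    variants = sorted(variants, key=lambda v: (v.chrom, v.pos, v.alt))
    chroms = list(dict.fromkeys(v.chrom for v in variants))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            ident = v.label or "."
            fh.write(f"{v.chrom}\t{v.pos}\t{ident}\t{v.ref}\t{v.alt}\t.\t.\t.\n")


def read_panel_vcf(path: str | Path) -> set[tuple[str, int, str]]:
    """Panel membership as (chrom, pos, alt) set semantics."""
    panel = set()
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            for alt in rec.alts or ():
                panel.add((rec.chrom, rec.pos, alt))
    return panel


# -- F2 tables --------------------------------------------------------------

def write_f2_tsv(individuals: Sequence[F2Individual], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "individual": [f"F2_{i + 1}" for i in range(len(individuals))],
            "genotype": [x.genotype for x in individuals],
            "phenotype": [x.phenotype for x in individuals],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_f2_tsv(path: str | Path) -> list[F2Individual]:
    df = pd.read_csv(path, sep="\t")
    return [F2Individual(g, p) for g, p in zip(df["genotype"], df["phenotype"])]
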