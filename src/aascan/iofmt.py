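"""Readers and writers for the pipeline's file formats.

Variant tables are tab-separated (sample_id, cancer_type, chrom, pos,
ref, alt) or minimal VCF; gene models travel as GFF3 (gene/mRNA/CDS
features, 1-based inclusive) with a FASTA reference; gene sets as GMT;
networks as SIF.  FASTA goes through Biopython.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import GeneModel
from .enrich import GeneSetCollection

VARIANT_COLUMNS = ("sample_id", "cancer_type", "chrom", "pos", "ref", "alt")


class FormatError(ValueError):
    pass


# -- variants -------------------------------------------------------------

def read_variants(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df["pos"] = df["pos"].astype(int)
    return df[list(VARIANT_COLUMNS)]


def read_vcf_variants(path, sample_map: Mapping[str, tuple[str, str]] | None = None) -> pd.DataFrame:
    """Minimal VCF reader: CHROM/POS/REF/ALT plus a sample-id column.

    ``sample_map`` maps the VCF sample column (column 10 onward is
    ignored; the ID column is used as sample id when no map is given) to
    (sample_id, cancer_type) pairs.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 5:
                continue
            chrom, pos, vid, ref, alt = f[:5]
            if len(ref) != 1 or len(alt) != 1:
                continue  # SNVs only
            sample, cancer = (vid, "unknown")
            if sample_map and vid in sample_map:
                sample, cancer = sample_map[vid]
            rows.append((sample, cancer, chrom, int(pos), ref, alt))
    return pd.DataFrame(rows, columns=list(VARIANT_COLUMNS))


# -- FASTA ---------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# -- GFF3 ----------------------------------------------------------------

def write_gff3(path, models: Iterable[GeneModel], gene_chrom: Mapping[str, str]) -> None:
    models = list(models)
    by_gene: dict[str, list[GeneModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id in sorted(by_gene):
            ms = by_gene[gene_id]
            chrom = gene_chrom[gene_id]
            strand = ms[0].strand
            gs = min(m.span[0] for m in ms)
            ge = max(m.span[1] for m in ms)
            fh.write(
                f"{chrom}\tsynth\tgene\t{gs}\t{ge}\t.\t{strand}\t.\tID={gene_id}\n"
            )
            for m in sorted(ms, key=lambda m: m.transcript_id):
                s, e = m.span
                fh.write(
                    f"{chrom}\tsynth\tmRNA\t{s}\t{e}\t.\t{strand}\t.\t"
                    f"ID={m.transcript_id};Parent={gene_id}\n"
                )
                for (cs, ce) in m.cds_exons:
                    fh.write(
                        f"{chrom}\tsynth\tCDS\t{cs}\t{ce}\t.\t{strand}\t0\t"
                        f"Parent={m.transcript_id}\n"
                    )


def read_gff3(path) -> tuple[list[GeneModel], dict[str, str]]:
    """Parse gene/mRNA/CDS features into GeneModels + gene->chrom map."""
    tx_gene: dict[str, str] = {}
    tx_strand: dict[str, str] = {}
    tx_chrom: dict[str, str] = {}
    tx_exons: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise FormatError(f"{path}: malformed GFF3 line: {line!r}")
            chrom, _, ftype, start, end, _, strand, _, attrs = f[:9]
            a = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "mRNA":
                tid = a["ID"]
                tx_gene[tid] = a.get("Parent", tid)
                tx_strand[tid] = strand
                tx_chrom[tid] = chrom
                tx_exons.setdefault(tid, [])
            elif ftype == "CDS":
                tid = a["Parent"]
                tx_exons.setdefault(tid, []).append((int(start), int(end)))
                tx_strand.setdefault(tid, strand)
                tx_chrom.setdefault(tid, chrom)
                tx_gene.setdefault(tid, tid)
    models = []
    gene_chrom: dict[str, str] = {}
    for tid in sorted(tx_exons):
        exons = tuple(sorted(tx_exons[tid]))
        if not exons:
            continue
        m = GeneModel(tx_gene[tid], tid, tx_strand[tid], exons)
        models.append(m)
        gene_chrom[m.gene_id] = tx_chrom[tid]
    return models, gene_chrom


# -- GMT / gene lists ----------------------------------------------------

def read_gmt(path, universe: Iterable[str] | None = None) -> GeneSetCollection:
    sets = {}
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                continue
            name, _desc, *genes = f
            genes = [g for g in genes if g]
            if genes:
                sets[name] = frozenset(genes)
    return GeneSetCollection(sets=sets, universe=frozenset(universe or ()))


def write_gmt(path, collection: GeneSetCollection) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            genes = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\tsynthetic\t{genes}\n")


def read_gene_list(path) -> set[str]:
    return {
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    }


# -- SIF -----------------------------------------------------------------

def write_sif(path, graph) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(map(lambda e: tuple(sorted(map(str, e))), graph.edges())):
            fh.write(f"{a}\tinteracts\t{b}\n")
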