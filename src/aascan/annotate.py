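"""Coding-consequence annotation of somatic SNVs.

Each genomic single-nucleotide variant is projected onto the CDS of the
*longest* transcript (largest encoded protein) of the gene it overlaps and
classified as synonymous, missense (an amino-acid substitution, AAS),
nonsense (stop gain), or stop_loss.  Variants outside any CDS are
noncoding; intronic positions within 2 nt of an exon boundary are splice
sites and are excluded from substitution analyses.

Coordinates are 1-based and inclusive throughout, genomic and protein
alike.  For minus-strand genes, alleles and codons are handled on the
coding strand while the reported trinucleotide context stays on the plus
strand of the reference (canonicalization to pyrimidine reference happens
later, in :mod:`aascan.spectra`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .genetics import BASES, CODON_TO_AA, STOP, complement

log = logging.getLogger(__name__)

CONSEQUENCE_CLASSES = ("synonymous", "missense", "nonsense", "stop_loss")

#: columns of the AAS record table produced by :func:`annotate_catalog`
AAS_COLUMNS = (
    "sample_id",
    "cancer_type",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene_id",
    "protein_id",
    "residue_pos",
    "ref_aa",
    "alt_aa",
    "consequence",
    "ref_codon",
    "alt_codon",
    "context",
)

SPLICE_FLANK = 2  # intronic nt on each side of an exon counted as splice site


class AnnotationError(ValueError):
    pass


class ReferenceMismatchError(AnnotationError):
    """Variant ref allele disagrees with the reference sequence."""

    def __init__(self, chrom, pos, expected, found):
        self.expected = expected
        self.found = found
        super().__init__(
            f"{chrom}:{pos} variant ref {found!r} != reference base {expected!r}"
        )


@dataclass(frozen=True)
class GeneModel:
    """CDS structure of one transcript.

    ``cds_exons`` are genomic [start, end] intervals, 1-based inclusive,
    sorted by genomic start regardless of strand.  The total CDS length
    must be a multiple of 3 and includes the terminal stop codon, so the
    protein length is CDS/3 - 1.
    """

    gene_id: str
    transcript_id: str
    strand: str
    cds_exons: tuple[tuple[int, int], ...]
    protein_id: str = ""

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"bad strand {self.strand!r}")
        exons = tuple((int(s), int(e)) for s, e in self.cds_exons)
        if not exons:
            raise AnnotationError(f"{self.transcript_id}: no CDS exons")
        for s, e in exons:
            if s > e:
                raise AnnotationError(f"{self.transcript_id}: exon {s}>{e}")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise AnnotationError(
                    f"{self.transcript_id}: exons overlap or unsorted"
                )
        if self.cds_length % 3 != 0:
            raise AnnotationError(
                f"{self.transcript_id}: CDS length {self.cds_length} not multiple of 3"
            )
        object.__setattr__(self, "cds_exons", exons)
        if not self.protein_id:
            object.__setattr__(self, "protein_id", self.transcript_id)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_exons)

    @property
    def protein_length(self) -> int:
        return self.cds_length // 3 - 1

    @property
    def span(self) -> tuple[int, int]:
        return self.cds_exons[0][0], self.cds_exons[-1][1]

    # -- coordinate projection -------------------------------------------

    def _plus_offset(self, pos: int) -> int | None:
        """1-based offset of ``pos`` in the exon concatenation (genomic order)."""
        off = 0
        for s, e in self.cds_exons:
            if pos < s:
                return None
            if pos <= e:
                return off + (pos - s) + 1
            off += e - s + 1
        return None

    def cds_position(self, pos: int) -> int | None:
        """Map a genomic position to a 1-based CDS coordinate, or None."""
        off = self._plus_offset(pos)
        if off is None:
            return None
        return off if self.strand == "+" else self.cds_length - off + 1

    def genomic_position(self, cds_pos: int) -> int:
        """Inverse of :meth:`cds_position` (1-based both ways)."""
        if not 1 <= cds_pos <= self.cds_length:
            raise AnnotationError(f"CDS position {cds_pos} out of range")
        off = cds_pos if self.strand == "+" else self.cds_length - cds_pos + 1
        for s, e in self.cds_exons:
            n = e - s + 1
            if off <= n:
                return s + off - 1
            off -= n
        raise AssertionError("unreachable")

    def is_splice_site(self, pos: int) -> bool:
        """True for intronic positions within SPLICE_FLANK nt of an exon."""
        for (s1, e1), (s2, e2) in zip(self.cds_exons, self.cds_exons[1:]):
            if e1 < pos < s2:  # inside this intron
                return pos - e1 <= SPLICE_FLANK or s2 - pos <= SPLICE_FLANK
        return False


@dataclass(frozen=True)
class VariantRecord:
    sample_id: str
    cancer_type: str
    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self):
        if self.ref not in BASES or self.alt not in BASES:
            raise AnnotationError(f"bad alleles {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise AnnotationError("ref == alt")


@dataclass(frozen=True)
class Projection:
    """Result of projecting one variant onto one transcript."""

    kind: str  # "coding" | "noncoding" | "splice_site"
    cds_pos: int | None = None
    codon_number: int | None = None
    codon_offset: int | None = None  # 1..3 within the codon
    ref_codon: str | None = None
    alt_codon: str | None = None
    coding_ref: str | None = None
    coding_alt: str | None = None
    context: str | None = None  # plus-strand 5'-ref-3' trinucleotide


NONCODING = Projection(kind="noncoding")
SPLICE_SITE = Projection(kind="splice_site")


def select_longest_transcript(models: Sequence[GeneModel]) -> GeneModel:
    """Transcript encoding the longest protein; ties broken by id.

    The per-gene analyses of the package all run on this single
    representative transcript.
    """
    models = list(models)
    if not models:
        raise AnnotationError("no transcript models given")
    return min(models, key=lambda m: (-m.protein_length, m.transcript_id))


def project_variant(variant: VariantRecord, model: GeneModel, refseq: str) -> Projection:
    """Project a genomic SNV onto a transcript's CDS.

    ``refseq`` is the full plus-strand chromosome sequence.  Raises
    :class:`ReferenceMismatchError` if the variant's ref allele does not
    match the reference base at its position.
    """
    pos = variant.pos
    ref_base = refseq[pos - 1]
    if ref_base != variant.ref:
        raise ReferenceMismatchError(variant.chrom, pos, ref_base, variant.ref)

    cds_pos = model.cds_position(pos)
    if cds_pos is None:
        return SPLICE_SITE if model.is_splice_site(pos) else NONCODING

    minus = model.strand == "-"
    coding_ref = complement(variant.ref) if minus else variant.ref
    coding_alt = complement(variant.alt) if minus else variant.alt

    codon_number = (cds_pos - 1) // 3 + 1
    codon_offset = (cds_pos - 1) % 3 + 1
    codon_start = (codon_number - 1) * 3 + 1
    bases = []
    for cp in range(codon_start, codon_start + 3):
        gpos = model.genomic_position(cp)
        b = refseq[gpos - 1]
        bases.append(complement(b) if minus else b)
    ref_codon = "".join(bases)
    alt_codon = (
        ref_codon[: codon_offset - 1] + coding_alt + ref_codon[codon_offset:]
    )
    context = refseq[pos - 2 : pos + 1] if pos >= 2 else None
    if context is not None and len(context) < 3:
        context = None
    return Projection(
        kind="coding",
        cds_pos=cds_pos,
        codon_number=codon_number,
        codon_offset=codon_offset,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        coding_ref=coding_ref,
        coding_alt=coding_alt,
        context=context,
    )


def classify_consequence(ref_codon: str, alt_codon: str) -> tuple[str, str, str]:
    """Classify a single-base codon change; returns (consequence, ref_aa, alt_aa)."""
    if len(ref_codon) != 3 or len(alt_codon) != 3:
        raise AnnotationError("codons must be length 3")
    diffs = sum(a != b for a, b in zip(ref_codon, alt_codon))
    if diffs != 1:
        raise AnnotationError(
            f"codons {ref_codon}>{alt_codon} differ at {diffs} positions, expected 1"
        )
    try:
        ref_aa = CODON_TO_AA[ref_codon]
        alt_aa = CODON_TO_AA[alt_codon]
    except KeyError as exc:
        raise AnnotationError(f"invalid codon: {exc}") from None
    if ref_aa == alt_aa:
        cons = "synonymous"
    elif alt_aa == STOP:
        cons = "nonsense"
    elif ref_aa == STOP:
        cons = "stop_loss"
    else:
        cons = "missense"
    return cons, ref_aa, alt_aa


@dataclass
class AnnotationSummary:
    """Per-cancer consequence tallies with a conservation guarantee.

    ``counts`` is indexed by cancer type with one column per consequence
    class plus ``noncoding``, ``splice_site`` and ``malformed``; the row
    sums equal the number of input variants of that cancer.
    """

    counts: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=list(CONSEQUENCE_CLASSES) + ["noncoding", "splice_site", "malformed"]
        )
    )

    def total(self) -> int:
        return int(self.counts.to_numpy().sum()) if len(self.counts) else 0

    def class_count(self, cls: str, cancer: str | None = None) -> int:
        if cls not in self.counts.columns:
            return 0
        col = self.counts[cls]
        if cancer is not None:
            return int(col.get(cancer, 0))
        return int(col.sum())


class _GeneIndex:
    """Interval lookup from genomic position to longest-transcript models."""

    def __init__(self, models: Iterable[GeneModel]):
        by_gene: dict[str, list[GeneModel]] = {}
        for m in models:
            by_gene.setdefault(m.gene_id, []).append(m)
        self.longest = {g: select_longest_transcript(ms) for g, ms in by_gene.items()}
        self.trees: dict[str, IntervalTree] = {}

    def build(self, chrom_of: Mapping[str, str]):
        for gene, model in self.longest.items():
            chrom = chrom_of[gene]
            s, e = model.span
            self.trees.setdefault(chrom, IntervalTree()).addi(s, e + 1, model)
        return self

    def overlapping(self, chrom: str, pos: int) -> list[GeneModel]:
        tree = self.trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree[pos]]


def annotate_catalog(
    variants: pd.DataFrame,
    models: Iterable[GeneModel],
    reference: Mapping[str, str],
    gene_chrom: Mapping[str, str],
) -> tuple[pd.DataFrame, AnnotationSummary]:
    """Annotate a variant table against the longest transcript per gene.

    ``variants`` needs columns sample_id, cancer_type, chrom, pos, ref, alt.
    A variant overlapping several genes is annotated against each of them
    independently; its bookkeeping contribution is taken from the first.
    Malformed rows (bad alleles, reference mismatches) are counted per
    cancer and skipped, never fatal.

    Returns the coding-consequence record table (one row per variant x
    overlapped gene) and an :class:`AnnotationSummary` whose per-cancer row
    sums equal the input row count.
    """
    index = _GeneIndex(models).build(gene_chrom)
    rows: list[tuple] = []
    tally: dict[str, dict[str, int]] = {}

    def bump(cancer: str, cls: str):
        tally.setdefault(cancer, {})[cls] = tally.setdefault(cancer, {}).get(cls, 0) + 1

    cols = ["sample_id", "cancer_type", "chrom", "pos", "ref", "alt"]
    for sample_id, cancer, chrom, pos, ref, alt in variants[cols].itertuples(index=False):
        pos = int(pos)
        try:
            var = VariantRecord(str(sample_id), str(cancer), str(chrom), pos, ref, alt)
        except AnnotationError:
            bump(cancer, "malformed")
            continue
        refseq = reference.get(str(chrom))
        if refseq is None or not 1 <= pos <= len(refseq):
            bump(cancer, "malformed")
            continue
        first_kind = None
        for model in index.overlapping(str(chrom), pos):
            try:
                proj = project_variant(var, model, refseq)
            except ReferenceMismatchError:
                proj = None
            if proj is None:
                first_kind = first_kind or "malformed"
                continue
            if proj.kind != "coding":
                first_kind = first_kind or proj.kind
                continue
            cons, ref_aa, alt_aa = classify_consequence(proj.ref_codon, proj.alt_codon)
            if first_kind is None:
                first_kind = cons
            rows.append(
                (
                    var.sample_id,
                    var.cancer_type,
                    var.chrom,
                    var.pos,
                    var.ref,
                    var.alt,
                    model.gene_id,
                    model.protein_id,
                    proj.codon_number,
                    ref_aa,
                    alt_aa,
                    cons,
                    proj.ref_codon,
                    proj.alt_codon,
                    proj.context,
                )
            )
        bump(cancer, first_kind or "noncoding")

    aas = pd.DataFrame(rows, columns=list(AAS_COLUMNS))
    all_cols = list(CONSEQUENCE_CLASSES) + ["noncoding", "splice_site", "malformed"]
    counts = (
        pd.DataFrame.from_dict(tally, orient="index")
        .reindex(columns=all_cols)
        .fillna(0)
        .astype(int)
        .sort_index()
    )
    counts.index.name = "cancer_type"
    return aas, AnnotationSummary(counts=counts)


def ns_syn_ratio(
    summary: AnnotationSummary,
    cancer: str | None = None,
    nonsynonymous_classes: Sequence[str] = ("missense",),
) -> float:
    """Ratio of nonsynonymous to synonymous coding SNVs.

    The class set counted as nonsynonymous is a parameter; by default only
    missense changes (AASs) are counted, which reproduces the cohort-level
    arithmetic where stop gains are tabulated separately.
    """
    syn = summary.class_count("synonymous", cancer)
    if syn == 0:
        raise AnnotationError("synonymous count is zero; ratio undefined")
    ns = sum(summary.class_count(c, cancer) for c in nonsynonymous_classes)
    return ns / syn


def ratio_from_counts(nonsynonymous: int, synonymous: int) -> float:
    """ns/syn ratio straight from two tallies (used for printed-count checks)."""
    if synonymous == 0:
        raise AnnotationError("synonymous count is zero; ratio undefined")
    return nonsynonymous / synonymous
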