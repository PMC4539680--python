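"""Variant-to-consequence annotation on longest transcripts."""

from itertools import product

import numpy as np
import pytest

from aascan.annotate import (
    AnnotationError,
    GeneModel,
    ReferenceMismatchError,
    VariantRecord,
    annotate_catalog,
    classify_consequence,
    ns_syn_ratio,
    project_variant,
    ratio_from_counts,
    select_longest_transcript,
)
from aascan.genetics import (
    BASES,
    CODON_TO_AA,
    STOP,
    reverse_complement,
    translate_cds,
)

from conftest import make_variants


def model(tid, exons, strand="+", gene="G1"):
    return GeneModel(gene, tid, strand, exons)


class TestLongestTranscript:
    def test_unique_maximum_and_identity(self):
        short = model("T_a", ((1, 1053),))  # 350 residues
        long_ = model("T_b", ((2000, 3262),))  # 420 residues
        assert select_longest_transcript([short, long_]) is long_
        assert select_longest_transcript([short]) is short

    def test_tie_broken_lexicographically(self):
        t2 = model("T2", ((1, 300),))
        t1 = model("T1", ((1000, 1299),))
        assert select_longest_transcript([t2, t1]).transcript_id == "T1"

    def test_empty_input_rejected(self):
        with pytest.raises(AnnotationError):
            select_longest_transcript([])


class TestProjectVariant:
    def test_plus_strand_coordinate_arithmetic(self):
        # single CDS exon starting at genomic 101; variant at 103 is the
        # third base of the first codon
        cds = "ATGCGTTAA"
        ref = "C" * 100 + cds + "C" * 20
        m = model("T1", ((101, 109),))
        var = VariantRecord("s", "c", "chr1", 103, "G", "T")
        proj = project_variant(var, m, ref)
        assert (proj.cds_pos, proj.codon_number, proj.codon_offset) == (3, 1, 3)
        assert proj.ref_codon == "ATG"

    def test_minus_strand_reverse_complement(self):
        # plus-strand 101-106 is ACGCAT; the minus-strand CDS is its
        # reverse complement ATGCGT; plus variant 102 C>T lands at CDS
        # position 5 with coding alleles G>A (hand-derived oracle)
        ref = "T" * 100 + "ACGCAT" + "T" * 20
        m = model("T1", ((101, 106),), strand="-")
        var = VariantRecord("s", "c", "chr1", 102, "C", "T")
        proj = project_variant(var, m, ref)
        assert proj.cds_pos == 5
        assert (proj.coding_ref, proj.coding_alt) == ("G", "A")

    def test_intron_edge_is_splice_site(self):
        # two exons with an intron 110..149; 1 nt inside the intron
        ref = "A" * 300
        m = model("T1", ((101, 109), (150, 158)))
        var = VariantRecord("s", "c", "chr1", 110, "A", "G")
        assert project_variant(var, m, ref).kind == "splice_site"
        # deep intron -> noncoding
        var = VariantRecord("s", "c", "chr1", 130, "A", "G")
        assert project_variant(var, m, ref).kind == "noncoding"

    def test_reference_mismatch_carries_both_bases(self):
        ref = "A" * 200
        m = model("T1", ((101, 109),))
        with pytest.raises(ReferenceMismatchError) as err:
            project_variant(VariantRecord("s", "c", "chr1", 105, "C", "T"), m, ref)
        assert err.value.expected == "A"
        assert err.value.found == "C"


class TestClassifyConsequence:
    @pytest.mark.parametrize(
        "ref_codon,alt_codon,expected",
        [
            ("CGT", "TGT", ("missense", "R", "C")),
            ("CGT", "CGC", ("synonymous", "R", "R")),
            ("TGG", "TGA", ("nonsense", "W", "*")),
            ("TAA", "CAA", ("stop_loss", "*", "Q")),
        ],
    )
    def test_examples(self, ref_codon, alt_codon, expected):
        assert classify_consequence(ref_codon, alt_codon) == expected

    @pytest.mark.parametrize("alt", ["CGT", "TGC"])
    def test_wrong_hamming_distance_rejected(self, alt):
        with pytest.raises(AnnotationError):
            classify_consequence("CGT", alt)

    def test_exhaustive_agreement_with_translation_oracle(self):
        """All 576 single-base codon changes vs translate-and-compare."""
        n = 0
        for codon in map("".join, product(BASES, repeat=3)):
            for i in range(3):
                for b in BASES:
                    if b == codon[i]:
                        continue
                    alt = codon[:i] + b + codon[i + 1 :]
                    cons, ref_aa, alt_aa = classify_consequence(codon, alt)
                    # independent oracle: plain genetic-code lookup
                    o_ref, o_alt = CODON_TO_AA[codon], CODON_TO_AA[alt]
                    if o_ref == o_alt:
                        expect = "synonymous"
                    elif o_alt == STOP:
                        expect = "nonsense"
                    elif o_ref == STOP:
                        expect = "stop_loss"
                    else:
                        expect = "missense"
                    assert (cons, ref_aa, alt_aa) == (expect, o_ref, o_alt)
                    n += 1
        assert n == 576


class TestAnnotateCatalog:
    def test_empty_table(self, toy_gene):
        m, ref = toy_gene
        aas, summary = annotate_catalog(
            make_variants([]), [m], ref, {"G1": "chr1"}
        )
        assert aas.empty
        assert summary.total() == 0

    def test_handcrafted_one_variant_per_class(self, toy_gene):
        m, ref = toy_gene  # CDS ATG CGT TGG CGA TCA TAA at 101..118
        variants = make_variants(
            [
                ("s1", "c1", "chr1", 104, "C", "T"),  # CGT->TGT missense R>C
                ("s1", "c1", "chr1", 106, "T", "C"),  # CGT->CGC synonymous
                ("s2", "c1", "chr1", 109, "G", "A"),  # TGG->TGA nonsense W>*
            ]
        )
        aas, summary = annotate_catalog(variants, [m], ref, {"G1": "chr1"})
        assert len(aas) == 3
        got = aas.set_index("consequence")
        assert got.loc["missense", ["residue_pos", "ref_aa", "alt_aa"]].tolist() == [2, "R", "C"]
        assert got.loc["synonymous", "residue_pos"] == 2
        assert got.loc["nonsense", ["ref_aa", "alt_aa"]].tolist() == ["W", "*"]
        assert summary.class_count("missense") == 1
        assert summary.total() == 3

    def test_counts_conserved_and_match_planted_truth(self, small_dataset):
        """Pipeline annotation equals the generator's independent bookkeeping."""
        ds = small_dataset
        truth_counts = ds.truth.consequence_counts(ds.variants)
        got = ds.summary.counts
        # conservation: per-cancer row sums equal input rows
        per_cancer = ds.variants.groupby("cancer_type").size()
        assert (got.sum(axis=1).sort_index() == per_cancer.sort_index()).all()
        for cls in truth_counts.columns:
            assert (
                got[cls].sort_index() == truth_counts[cls].sort_index()
            ).all(), cls

    def test_strand_equivalence_mirror_oracle(self):
        """Annotating a minus-strand gene equals annotating its mirrored
        plus-strand copy, for 1,000 random variants."""
        rng = np.random.default_rng(7)
        cds = "ATG" + "".join(
            rng.choice(["CGT", "GCA", "TTC", "GGA", "CTG"], 40)
        ) + "TAA"
        intron = "".join(rng.choice(list(BASES), 50))
        pad = "".join(rng.choice(list(BASES), 80))
        half = len(cds) // 2 // 3 * 3
        pre = cds[:half] + intron + cds[half:]
        fwd = pad + pre + pad
        rev = reverse_complement(fwd)
        L = len(fwd)
        e1 = (len(pad) + 1, len(pad) + half)
        e2 = (len(pad) + half + 51, len(pad) + len(pre))
        m_fwd = model("TF", (e1, e2), strand="+")
        m_rev = model(
            "TR",
            (
                (L - e2[1] + 1, L - e2[0] + 1),
                (L - e1[1] + 1, L - e1[0] + 1),
            ),
            strand="-",
        )
        n_checked = 0
        for _ in range(1000):
            pos = int(rng.integers(2, L))
            ref_b = fwd[pos - 1]
            alt_b = rng.choice([b for b in BASES if b != ref_b])
            vf = VariantRecord("s", "c", "chr1", pos, ref_b, alt_b)
            vr = VariantRecord(
                "s",
                "c",
                "chr1",
                L - pos + 1,
                reverse_complement(ref_b),
                reverse_complement(alt_b),
            )
            pf = project_variant(vf, m_fwd, fwd)
            pr = project_variant(vr, m_rev, rev)
            assert pf.kind == pr.kind
            if pf.kind == "coding":
                assert pf.cds_pos == pr.cds_pos
                assert pf.ref_codon == pr.ref_codon
                assert pf.alt_codon == pr.alt_codon
                n_checked += 1
        assert n_checked > 100

    def test_generated_cds_translate_cleanly(self, small_dataset):
        """Every generated transcript translates start-to-stop without
        internal stops (independent genetic-code oracle)."""
        ds = small_dataset
        ref = ds.genome.reference["chr1"]
        for gene in ds.genome.genes:
            for m in gene.transcripts:
                seq = "".join(ref[s - 1 : e] for s, e in m.cds_exons)
                if m.strand == "-":
                    seq = reverse_complement(seq)
                prot = translate_cds(seq)
                assert prot[0] == "M" and prot[-1] == STOP
                assert STOP not in prot[:-1]
                assert len(prot) - 1 == m.protein_length


class TestNsSynRatio:
    def test_cohort_scale_printed_counts(self):
        # genome-wide tallies: 824,336 substitutions vs 308,896 synonymous
        assert round(ratio_from_counts(824336, 308896), 1) == 2.7

    def test_equal_and_zero_numerator(self):
        assert ratio_from_counts(10, 10) == 1.0
        assert ratio_from_counts(0, 10) == 0.0

    def test_zero_synonymous_is_undefined(self):
        with pytest.raises(AnnotationError):
            ratio_from_counts(5, 0)

    def test_summary_based_ratio(self, small_dataset):
        s = small_dataset.summary
        expected = s.class_count("missense") / s.class_count("synonymous")
        assert ns_syn_ratio(s) == pytest.approx(expected)
        with_stops = ns_syn_ratio(s, nonsynonymous_classes=("missense", "nonsense"))
        assert with_stops >= ns_syn_ratio(s)
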