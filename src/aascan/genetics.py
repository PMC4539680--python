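"""Small genetic-code utilities shared across the package.

The standard (NCBI table 1) genetic code is taken from Biopython; stop
codons are rendered as ``*`` throughout.
"""

from __future__ import annotations

from itertools import product

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

BASES = ("A", "C", "G", "T")
PYRIMIDINES = ("C", "T")
STOP = "*"

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: codon -> one-letter amino acid, ``*`` for stop; all 64 codons present
CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TO_AA[_stop] = STOP

AMINO_ACIDS = tuple(sorted(set(CODON_TO_AA.values()) - {STOP}))  # 20 letters


def complement(base: str) -> str:
    try:
        return COMPLEMENT[base]
    except KeyError:
        raise ValueError(f"invalid base {base!r}") from None


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate_cds(cds: str) -> str:
    """Translate a CDS (length divisible by 3) codon by codon.

    Returns the protein including a trailing ``*`` if the final codon is a
    stop.  Raises ``ValueError`` on length or alphabet problems.
    """
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    aas = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        try:
            aas.append(CODON_TO_AA[codon])
        except KeyError:
            raise ValueError(f"invalid codon {codon!r} at CDS offset {i}") from None
    return "".join(aas)


def single_base_neighbors(codon: str):
    """Yield (position 0-2, alt_base, alt_codon) for the 9 single-base changes."""
    for i in range(3):
        for b in BASES:
            if b != codon[i]:
                yield i, b, codon[:i] + b + codon[i + 1 :]


def reachable_aa_pairs() -> set[tuple[str, str]]:
    """All ordered (ref_aa, alt_aa) pairs reachable by one base change.

    Enumerates the 64 x 9 single-base codon substitutions; includes pairs
    with ``*`` on either side and excludes identical pairs.
    """
    pairs = set()
    for codon in map("".join, product(BASES, repeat=3)):
        ref_aa = CODON_TO_AA[codon]
        for _, _, alt_codon in single_base_neighbors(codon):
            alt_aa = CODON_TO_AA[alt_codon]
            if alt_aa != ref_aa:
                pairs.add((ref_aa, alt_aa))
    return pairs
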