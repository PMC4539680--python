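"""Trinucleotide substitution spectra and amino-acid substitution matrices.

Single-base substitutions are reduced to the 6 pyrimidine-reference
classes (C>A, C>G, C>T, T>A, T>C, T>G); together with the immediate 5' and
3' reference bases this gives the standard 96-channel spectrum ("lego
plot" layout).  A substitution observed with a purine reference base is
reverse-complemented — substitution and flanking context together — before
binning.

Amino-acid substitution matrices count (ref_aa, alt_aa) pairs, including
stop gains, and carry a reachability mask: only pairs attainable through a
single base change in some codon can ever have nonzero counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetics import AMINO_ACIDS, BASES, PYRIMIDINES, STOP, complement, reachable_aa_pairs

SUB_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: 96 channel labels in class-major order: "A[C>A]A", "A[C>A]C", ...
CHANNEL_LABELS = tuple(
    f"{fp}[{cls}]{tp}"
    for cls in SUB_CLASSES
    for fp in BASES
    for tp in BASES
)


class SpectrumError(ValueError):
    pass


def pyrimidine_canonical(
    ref: str, alt: str, five_prime: str, three_prime: str
) -> tuple[str, str, str]:
    """Canonicalize a substitution-in-context to pyrimidine reference.

    Returns (class, 5' base, 3' base) after reverse-complementing the
    whole triplet when the reference base is a purine.  Idempotent on
    already-canonical input.
    """
    for b in (ref, alt, five_prime, three_prime):
        if b not in BASES:
            raise SpectrumError(f"invalid base {b!r}")
    if ref == alt:
        raise SpectrumError("ref == alt")
    if ref not in PYRIMIDINES:
        ref, alt = complement(ref), complement(alt)
        five_prime, three_prime = complement(three_prime), complement(five_prime)
    return f"{ref}>{alt}", five_prime, three_prime


def channel_index(ref: str, alt: str, five_prime: str, three_prime: str) -> int:
    """Index into the 96-channel spectrum (class-major, contexts A..T x A..T)."""
    cls, fp, tp = pyrimidine_canonical(ref, alt, five_prime, three_prime)
    return SUB_CLASSES.index(cls) * 16 + BASES.index(fp) * 4 + BASES.index(tp)


@dataclass
class SpectrumMatrix:
    """96-channel substitution counts for one cancer type."""

    cancer_type: str
    counts: np.ndarray = field(default_factory=lambda: np.zeros(96, dtype=np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def frequencies(self) -> np.ndarray:
        t = self.total
        return self.counts / t if t else self.counts.astype(float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel": CHANNEL_LABELS,
                "count": self.counts,
                "frequency": self.frequencies(),
            }
        )

    def by_class(self) -> pd.Series:
        return pd.Series(
            self.counts.reshape(6, 16).sum(axis=1), index=list(SUB_CLASSES)
        )


def build_spectrum(records: pd.DataFrame, cancer_type: str | None = None) -> SpectrumMatrix:
    """Bin annotated substitution records into a 96-channel spectrum.

    ``records`` must carry plus-strand ``ref``-equivalent information via
    the ``context`` column (5' base, reference base, 3' base on the plus
    strand) plus an ``alt`` column with the plus-strand alternate base.
    Records flagged as splice sites, and records with a missing context,
    are skipped (skips are reflected only in ``total`` being smaller than
    the input).
    """
    m = SpectrumMatrix(cancer_type=cancer_type or "all")
    df = records
    if cancer_type is not None:
        df = df[df["cancer_type"] == cancer_type]
    if "consequence" in df.columns:
        df = df[df["consequence"] != "splice_site"]
    for ctx, alt in df[["context", "alt"]].itertuples(index=False):
        if not isinstance(ctx, str) or len(ctx) != 3:
            continue
        try:
            m.counts[channel_index(ctx[1], alt, ctx[0], ctx[2])] += 1
        except SpectrumError:
            continue
    return m


#: row/column order of the AAS matrix: 20 residues + stop as alt only
AA_ORDER = AMINO_ACIDS
ALT_ORDER = AMINO_ACIDS + (STOP,)


@dataclass
class AASMatrix:
    """Counts of (ref residue, alt residue) substitutions for one cancer.

    ``mask`` marks the pairs reachable by a single base change in some
    codon; counts outside the mask are impossible for true SNV data.
    """

    cancer_type: str
    counts: np.ndarray = field(
        default_factory=lambda: np.zeros((len(AA_ORDER), len(ALT_ORDER)), dtype=np.int64)
    )
    mask: np.ndarray = field(default_factory=lambda: _reachable_mask())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(AA_ORDER), columns=list(ALT_ORDER))

    def top_pairs(self, k: int = 5) -> list[tuple[str, str, int]]:
        flat = [
            (AA_ORDER[i], ALT_ORDER[j], int(self.counts[i, j]))
            for i in range(len(AA_ORDER))
            for j in range(len(ALT_ORDER))
            if self.counts[i, j] > 0
        ]
        flat.sort(key=lambda t: (-t[2], t[0], t[1]))
        return flat[:k]


def _reachable_mask() -> np.ndarray:
    mask = np.zeros((len(AA_ORDER), len(ALT_ORDER)), dtype=bool)
    for ref_aa, alt_aa in reachable_aa_pairs():
        if ref_aa == STOP:
            continue  # stop-loss tracked elsewhere
        mask[AA_ORDER.index(ref_aa), ALT_ORDER.index(alt_aa)] = True
    return mask


def build_aas_matrix(
    records: pd.DataFrame, cancer_type: str | None = None, unique: bool = False
) -> AASMatrix:
    """Tally AAS records into a (ref_aa, alt_aa) matrix.

    Only missense and nonsense records are counted.  With ``unique=True``
    each distinct substitution (protein, position, ref, alt) counts once
    instead of once per occurrence.
    """
    m = AASMatrix(cancer_type=cancer_type or "all")
    df = records[records["consequence"].isin(("missense", "nonsense"))]
    if cancer_type is not None:
        df = df[df["cancer_type"] == cancer_type]
    if unique:
        df = df.drop_duplicates(subset=["protein_id", "residue_pos", "ref_aa", "alt_aa"])
    for ref_aa, alt_aa in df[["ref_aa", "alt_aa"]].itertuples(index=False):
        i = AA_ORDER.index(ref_aa)
        j = ALT_ORDER.index(alt_aa)
        if not m.mask[i, j]:
            raise SpectrumError(
                f"substitution {ref_aa}>{alt_aa} is not reachable by one base change"
            )
        m.counts[i, j] += 1
    return m


def plot_spectrum(matrix: SpectrumMatrix, path) -> None:
    """Write a 96-bar spectrum figure (cosmetic; matrices are the artifact)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = ["#03bcee", "#010101", "#e32926", "#cac9c9", "#a1cf63", "#edc8c5"]
    fig, ax = plt.subplots(figsize=(14, 3.2))
    x = np.arange(96)
    bar_colors = [colors[i // 16] for i in x]
    ax.bar(x, matrix.counts, color=bar_colors, width=0.8)
    for i, cls in enumerate(SUB_CLASSES):
        ax.text(i * 16 + 8, ax.get_ylim()[1] * 0.95, cls, ha="center", fontsize=9)
    ax.set_xticks(x[::4])
    ax.set_xticklabels([CHANNEL_LABELS[i] for i in x[::4]], rotation=90, fontsize=5)
    ax.set_ylabel("count")
    ax.set_title(f"{matrix.cancer_type} (n={matrix.total})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
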