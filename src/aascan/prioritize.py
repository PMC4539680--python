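"""Recurrence-based prioritization of proteins carrying harmful AASs.

For one cancer type, each protein is scored by the number of distinct
samples containing at least one confidently harmful AAS in it.  Selection
then applies three rules:

1. proteins with harmful AASs in fewer than ``min_samples`` samples
   (default 2) are eliminated;
2. a threshold is set at the nearest-rank 95th percentile of the
   surviving sample counts, and proteins with counts *strictly above* the
   threshold are selected — approximately the top 5 %;
3. when more than ``recurrence_gate`` samples (default 100) contain
   harmful AASs, proteins carrying one identical harmful substitution in
   more than ``recurrence_fraction`` (default 2 %) of all samples of the
   cancer are additionally admitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd


class SelectionError(ValueError):
    pass


@dataclass(frozen=True)
class SelectionParams:
    min_samples: int = 2
    percentile: float = 95.0
    recurrence_fraction: float = 0.02
    recurrence_gate: int = 100

    def __post_init__(self):
        if not 0 < self.percentile < 100:
            raise SelectionError("percentile must be in (0, 100)")
        if not 0 < self.recurrence_fraction < 1:
            raise SelectionError("recurrence_fraction must be in (0, 1)")
        if self.min_samples < 1:
            raise SelectionError("min_samples must be >= 1")


@dataclass
class SelectionResult:
    cancer_type: str
    table: pd.DataFrame  # protein_id, n_samples, reason
    threshold: float | None
    n_samples_with_harmful: int
    params: SelectionParams = field(default_factory=SelectionParams)

    @property
    def proteins(self) -> list[str]:
        return list(self.table["protein_id"])


def nearest_rank_percentile(values, p: float) -> float:
    """Nearest-rank percentile: the ceil(p/100 * n)-th smallest value."""
    vals = sorted(values)
    if not vals:
        raise SelectionError("empty sample")
    rank = math.ceil(p / 100.0 * len(vals))
    return vals[max(rank, 1) - 1]


def sample_counts(harmful: pd.DataFrame, cancer_type: str | None = None) -> pd.Series:
    """Distinct samples with >=1 harmful AAS, per protein.

    A sample with several harmful AASs in the same protein contributes 1.
    """
    df = harmful
    if cancer_type is not None:
        df = df[df["cancer_type"] == cancer_type]
    if df.empty:
        return pd.Series(dtype=int, name="n_samples")
    counts = df.groupby("protein_id")["sample_id"].nunique()
    counts.name = "n_samples"
    return counts


def recurrent_proteins(
    harmful: pd.DataFrame, n_samples_in_cancer: int, fraction: float
) -> set[str]:
    """Proteins with one identical harmful substitution in > fraction of samples.

    Identity is (protein, residue position, ref residue, alt residue); the
    denominator is all samples of the cancer type, mutated or not.
    """
    if harmful.empty or n_samples_in_cancer <= 0:
        return set()
    per_sub = harmful.groupby(["protein_id", "residue_pos", "ref_aa", "alt_aa"])[
        "sample_id"
    ].nunique()
    hot = per_sub[per_sub > fraction * n_samples_in_cancer]
    return set(hot.index.get_level_values("protein_id"))


def select_proteins(
    counts: pd.Series,
    n_samples_in_cancer: int,
    harmful: pd.DataFrame,
    params: SelectionParams = SelectionParams(),
    cancer_type: str = "",
) -> SelectionResult:
    """Apply the sample-count / percentile / recurrence selection rules.

    ``counts`` is the per-protein distinct-sample tally for one cancer
    (from :func:`sample_counts`); ``harmful`` the harmful AAS table of the
    same cancer, used for the recurrence rule and the gate.
    """
    surviving = counts[counts >= params.min_samples]
    n_with_harmful = int(harmful["sample_id"].nunique()) if len(harmful) else 0

    rows: list[tuple[str, int, str]] = []
    threshold = None
    if len(surviving):
        threshold = nearest_rank_percentile(surviving.values, params.percentile)
        for protein, n in surviving.items():
            if n > threshold:
                rows.append((protein, int(n), "percentile"))

    if n_with_harmful > params.recurrence_gate:
        chosen = {r[0] for r in rows}
        for protein in sorted(
            recurrent_proteins(harmful, n_samples_in_cancer, params.recurrence_fraction)
        ):
            if protein not in chosen:
                rows.append((protein, int(counts.get(protein, 0)), "recurrence"))

    table = pd.DataFrame(rows, columns=["protein_id", "n_samples", "reason"])
    table = table.sort_values(
        ["n_samples", "protein_id"], ascending=[False, True]
    ).reset_index(drop=True)
    return SelectionResult(
        cancer_type=cancer_type,
        table=table,
        threshold=threshold,
        n_samples_with_harmful=n_with_harmful,
        params=params,
    )


def normalize_by_length(
    harmful_counts: pd.Series, protein_lengths: pd.Series
) -> pd.Series:
    """Harmful-AAS occurrences per residue of the reference protein."""
    lengths = protein_lengths.reindex(harmful_counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()][:3])
        raise SelectionError(f"missing protein lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise SelectionError("protein length must be > 0")
    out = harmful_counts / lengths
    out.name = "normalized_frequency"
    return out


def cgc_overlap(
    selected: list[str], cancer_genes: set[str]
) -> tuple[int, list[str], list[str]]:
    """Partition a selection into known cancer genes and novel candidates."""
    known = sorted(p for p in selected if p in cancer_genes)
    novel = sorted(p for p in selected if p not in cancer_genes)
    return len(known), known, novel
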