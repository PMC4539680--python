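"""Protein-domain mutation statistics.

AASs are mapped onto domain instances — (protein, accession, start, end)
rows in 1-based inclusive protein coordinates — and aggregated per
accession with a length-normalized frequency:

    normalized_frequency = n_aas / cumulative_length

where the cumulative length sums the lengths of only those instances that
contain at least one AAS.  Domains with a single AAS are dropped from the
output; by default the filter (and the counts) use AAS occurrences, with
``unique=True`` switching to distinct substitutions.
"""

from __future__ import annotations

import pandas as pd

DOMAIN_COLUMNS = ("protein_id", "accession", "name", "start", "end")


class DomainError(ValueError):
    pass


def read_domains(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "accession": str})
    missing = [c for c in DOMAIN_COLUMNS if c not in df.columns]
    if missing:
        raise DomainError(f"{path}: missing columns {missing}")
    if (df["start"] > df["end"]).any() or (df["start"] < 1).any():
        raise DomainError(f"{path}: invalid interval (need 1 <= start <= end)")
    return df


def map_aas_to_domains(aas: pd.DataFrame, domains: pd.DataFrame) -> pd.DataFrame:
    """Assign each AAS to every domain instance containing its residue.

    Intervals are inclusive on both ends; overlapping instances each
    receive the AAS.  Returns the merged assignment table with one row per
    (AAS record, matching instance).
    """
    if aas.empty or domains.empty:
        return pd.DataFrame(
            columns=list(aas.columns) + ["accession", "name", "start", "end"]
        )
    dom = domains.reset_index().rename(columns={"index": "instance_id"})
    merged = aas.merge(dom, on="protein_id", how="inner")
    hit = (merged["residue_pos"] >= merged["start"]) & (
        merged["residue_pos"] <= merged["end"]
    )
    return merged[hit].reset_index(drop=True)


def domain_normalized_frequency(
    aas: pd.DataFrame,
    domains: pd.DataFrame,
    min_aas: int = 2,
    unique: bool = False,
) -> pd.DataFrame:
    """Length-normalized AAS frequency per domain accession.

    Instances without any AAS contribute nothing to the cumulative
    length.  Accessions with fewer than ``min_aas`` AASs (default: more
    than one required) are absent from the output.  Sorted by descending
    frequency, accession as tie-break.
    """
    assigned = map_aas_to_domains(aas, domains)
    if assigned.empty:
        return pd.DataFrame(
            columns=["accession", "n_aas", "cumulative_length", "normalized_frequency"]
        )
    if unique:
        assigned = assigned.drop_duplicates(
            subset=["protein_id", "residue_pos", "ref_aa", "alt_aa", "instance_id"]
        )
    per_instance = assigned.groupby(
        ["accession", "instance_id", "start", "end"], as_index=False
    ).size()
    per_instance["length"] = per_instance["end"] - per_instance["start"] + 1
    out = (
        per_instance.groupby("accession")
        .agg(n_aas=("size", "sum"), cumulative_length=("length", "sum"))
        .reset_index()
    )
    out = out[out["n_aas"] >= min_aas].copy()
    out["normalized_frequency"] = out["n_aas"] / out["cumulative_length"]
    return out.sort_values(
        ["normalized_frequency", "accession"], ascending=[False, True]
    ).reset_index(drop=True)


def top_domains(frequencies: pd.DataFrame, k: int = 20) -> pd.DataFrame:
    """Top-k accessions by normalized frequency (accession breaks ties)."""
    if k < 1:
        raise DomainError("k must be >= 1")
    ranked = frequencies.sort_values(
        ["normalized_frequency", "accession"], ascending=[False, True]
    )
    return ranked.head(k).reset_index(drop=True)


def domain_cancer_prevalence(aas: pd.DataFrame, domains: pd.DataFrame) -> pd.Series:
    """Number of cancer types in which each domain accession carries >=1 AAS."""
    assigned = map_aas_to_domains(aas, domains)
    if assigned.empty:
        return pd.Series(dtype=int, name="n_cancer_types")
    out = assigned.groupby("accession")["cancer_type"].nunique()
    out.name = "n_cancer_types"
    return out.sort_values(ascending=False)
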