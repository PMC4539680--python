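"""Harmfulness filtering of amino-acid substitutions.

The harmfulness predictor itself is an external tool consumed as a
prediction file: one row per substitution with a probability of
harmfulness in [0, 1] and a three-way class (harmful / neutral / unknown).
This module loads such files, joins them onto AAS records, keeps the
confidently harmful subset, and computes evaluation statistics
(false/true positive rates, class fractions) against labelled variant
sets.

Substitutions classified "unknown" are excluded from every downstream
harmful-AAS statistic: the predictions are not considered reliable for
them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

log = logging.getLogger(__name__)

CLASSES = ("harmful", "neutral", "unknown")
KEY = ["protein_id", "residue_pos", "ref_aa", "alt_aa"]

#: stub mapping of the predictor's confidence-based three-way call onto
#: plain probability cutoffs; real prediction files carry their own class
#: column, which takes precedence over this rule.
DEFAULT_THRESHOLDS = (0.05, 0.95)


class PredictionError(ValueError):
    pass


def classify_stub(probability: float, thresholds=DEFAULT_THRESHOLDS) -> str:
    """Three-way call from a harmfulness probability.

    ``>= high`` is harmful, ``<= low`` neutral, anything between is
    unknown.  This is a declared approximation of the external
    predictor's confidence-based classification, used only where no class
    column is available (and by the synthetic generator).
    """
    low, high = thresholds
    if not 0 <= low < high <= 1:
        raise PredictionError(f"bad thresholds {thresholds}")
    if probability >= high:
        return "harmful"
    if probability <= low:
        return "neutral"
    return "unknown"


def load_predictions(path) -> pd.DataFrame:
    """Read a tab-separated prediction file.

    Expected header: protein_id, residue_pos, ref_aa, alt_aa, probability,
    class.  Duplicate substitution keys and out-of-range probabilities are
    rejected with the offending line number (header = line 1).
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    missing = [c for c in KEY + ["probability", "class"] if c not in df.columns]
    if missing:
        raise PredictionError(f"{path}: missing columns {missing}")
    bad = df.index[(df["probability"] < 0) | (df["probability"] > 1)]
    if len(bad):
        raise PredictionError(
            f"{path}: probability out of [0,1] on line {int(bad[0]) + 2}"
        )
    bad = df.index[~df["class"].isin(CLASSES)]
    if len(bad):
        raise PredictionError(f"{path}: unknown class on line {int(bad[0]) + 2}")
    dup = df.duplicated(subset=KEY)
    if dup.any():
        raise PredictionError(
            f"{path}: duplicate substitution key on line {int(df.index[dup][0]) + 2}"
        )
    df["residue_pos"] = df["residue_pos"].astype(int)
    return df


def join_predictions(aas: pd.DataFrame, predictions: pd.DataFrame) -> pd.DataFrame:
    """Left-join prediction probability/class onto missense AAS records.

    Records without a prediction get class "unknown" and a missing
    probability.  Non-missense records are dropped (the predictor scores
    amino-acid substitutions only).
    """
    missense = aas[aas["consequence"] == "missense"]
    merged = missense.merge(
        predictions[KEY + ["probability", "class"]], on=KEY, how="left"
    )
    n_missing = int(merged["class"].isna().sum())
    if n_missing:
        log.warning("%d AAS records had no prediction; treated as unknown", n_missing)
    merged["class"] = merged["class"].fillna("unknown")
    return merged


def join_harmful(aas: pd.DataFrame, predictions: pd.DataFrame) -> pd.DataFrame:
    """The confidently harmful AAS records, sample/cancer columns intact."""
    merged = join_predictions(aas, predictions)
    return merged[merged["class"] == "harmful"].reset_index(drop=True)


@dataclass
class ConfusionSummary:
    """Predictor-vs-label tallies on a benign/pathogenic evaluation set.

    Rates are percentages over *all* labelled variants of the relevant
    label, including those the predictor left unclassified — e.g. the
    false positive rate is 100 x (predicted harmful among labelled benign)
    / (labelled benign).  A rate over an empty label class is None.
    """

    n_total: int
    n_predicted_harmful: int
    n_predicted_neutral: int
    n_unclassified: int
    fpr: float | None
    tpr: float | None


def confusion_stats(calls: pd.DataFrame, label_col: str = "label") -> ConfusionSummary:
    """Evaluate three-way calls against benign/pathogenic labels.

    ``calls`` needs a ``class`` column (harmful/neutral/unknown) and a
    label column with values "benign" / "pathogenic".
    """
    labels = calls[label_col]
    bad = set(labels.unique()) - {"benign", "pathogenic"}
    if bad:
        raise PredictionError(f"unexpected labels {sorted(bad)}")
    cls = calls["class"]
    benign = cls[labels == "benign"]
    patho = cls[labels == "pathogenic"]
    fpr = 100.0 * (benign == "harmful").sum() / len(benign) if len(benign) else None
    tpr = 100.0 * (patho == "harmful").sum() / len(patho) if len(patho) else None
    return ConfusionSummary(
        n_total=len(calls),
        n_predicted_harmful=int((cls == "harmful").sum()),
        n_predicted_neutral=int((cls == "neutral").sum()),
        n_unclassified=int((cls == "unknown").sum()),
        fpr=fpr,
        tpr=tpr,
    )


def fpr_from_counts(n_benign: int, n_predicted_harmful: int) -> float:
    """False positive rate (%) from printed tallies of a benign set."""
    if n_benign <= 0:
        raise PredictionError("empty benign set")
    return 100.0 * n_predicted_harmful / n_benign


def fraction_class(calls: pd.DataFrame, cls: str) -> float:
    """Percentage of calls in one class (harmful/neutral/unknown)."""
    if cls not in CLASSES:
        raise PredictionError(f"unknown class {cls!r}")
    if len(calls) == 0:
        raise PredictionError("no calls")
    return 100.0 * (calls["class"] == cls).sum() / len(calls)


def fraction_from_counts(n_class: int, n_total: int) -> float:
    if n_total <= 0:
        raise PredictionError("no calls")
    return 100.0 * n_class / n_total
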