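"""Scoring pipeline output against a generator's planted ground truth.

Planted clusters are identified with recovered clusters by exact interval
equality — the generator plants each cluster as the exact union of its
member alignments, so with zero noise any mismatch is a genuine pipeline
defect, not a tolerance question.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .est_preprocess import UESTCluster


@dataclass(frozen=True)
class PrecisionRecall:
    n_true: int
    n_called: int
    n_correct: int

    @property
    def precision(self) -> float:
        return self.n_correct / self.n_called if self.n_called else 1.0

    @property
    def recall(self) -> float:
        return self.n_correct / self.n_true if self.n_true else 1.0


def match_clusters(
    truth: pd.DataFrame, clusters: list[UESTCluster]
) -> pd.DataFrame:
    """Join planted clusters to recovered clusters on (chrom, start, end).

    Returns the truth table with a ``cluster_id`` column (NaN where a plant
    was not recovered); unmatched recovered clusters appear in the
    ``extra_clusters`` attribute of the result.
    """
    recovered = pd.DataFrame(
        {
            "chrom": [c.interval.chrom for c in clusters],
            "start": [c.interval.start for c in clusters],
            "end": [c.interval.end for c in clusters],
            "cluster_id": [c.cluster_id for c in clusters],
        }
    )
    merged = truth.merge(recovered, on=["chrom", "start", "end"], how="left")
    extra = set(recovered["cluster_id"]) - set(merged["cluster_id"].dropna())
    merged.attrs["extra_clusters"] = sorted(extra)
    return merged


def score_labels(
    matched: pd.DataFrame, truth_col: str, predicted: dict[str, object]
) -> PrecisionRecall:
    """Exact-label agreement between planted truth and per-cluster calls.

    Unrecovered plants count against recall; extra clusters against
    precision.
    """
    n_true = len(matched)
    n_correct = 0
    n_called = len(matched.attrs.get("extra_clusters", ())) + n_true
    for _, row in matched.iterrows():
        cid = row["cluster_id"]
        if pd.isna(cid):
            continue
        if str(predicted.get(cid)) == str(row[truth_col]):
            n_correct += 1
    return PrecisionRecall(n_true=n_true, n_called=n_called, n_correct=n_correct)


def score_flag_set(true_ids: set, called_ids: set) -> PrecisionRecall:
    """Precision/recall of a called id set against the planted id set."""
    return PrecisionRecall(
        n_true=len(true_ids),
        n_called=len(called_ids),
        n_correct=len(true_ids & called_ids),
    )
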