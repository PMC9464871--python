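"""Selective prediction and reporting on top of vote matrices.

A tile is "classifiable" at agreement threshold t if at least t members match
the majority label; sweeping t from the bare majority to unanimity trades
coverage for accuracy.  The positive class for FP/FN bookkeeping is class 1
("cancer").  Where zero tiles survive a threshold, accuracy is reported as a
flagged missing value (NaN), never as 0 or 1.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .cohort import Cohort
from .ensemble import VoteMatrix

__all__ = [
    "agreement_filter",
    "accuracy_by_agreement",
    "stratified_performance",
    "apply_exclusion_list",
    "exclusion_delta",
    "flag_suspect_labels",
    "min_threshold",
]


def min_threshold(n_members: int) -> int:
    """The bare-majority agreement level ⌈n/2⌉ (n odd)."""
    return n_members // 2 + 1


def agreement_filter(
    votes: VoteMatrix, threshold: int
) -> tuple[pd.DataFrame, tuple[str, ...]]:
    """Partition tiles into retained (agreement >= t) and discarded.

    Returns a frame of retained tiles (tile_id, ensemble_label, agreement)
    and the tuple of discarded tile ids; the two always partition the input.
    """
    n = votes.n_members
    lo = min_threshold(n)
    if not lo <= threshold <= n:
        raise ValueError(f"threshold must be in [{lo}, {n}], got {threshold}")
    agreement = votes.agreement
    labels = votes.ensemble_label
    keep = agreement >= threshold
    retained = pd.DataFrame(
        {
            "tile_id": [t for t, k in zip(votes.tile_ids, keep) if k],
            "ensemble_label": labels[keep],
            "agreement": agreement[keep],
        }
    )
    discarded = tuple(t for t, k in zip(votes.tile_ids, keep) if not k)
    return retained, discarded


def accuracy_by_agreement(votes: VoteMatrix, truth: Mapping[str, int]) -> pd.DataFrame:
    """Coverage/accuracy/error curve over all agreement thresholds.

    One row per threshold t in {⌈n/2⌉..n}: retained count, accuracy on
    retained tiles (NaN when none retained), false positives/negatives among
    retained (class 1 positive), and how many of the discarded tiles would
    have been correct/incorrect ensemble calls.
    """
    y = np.array([truth[t] for t in votes.tile_ids])
    labels = votes.ensemble_label
    agreement = votes.agreement
    correct = labels == y
    n = votes.n_members
    rows = []
    for t in range(min_threshold(n), n + 1):
        keep = agreement >= t
        n_ret = int(keep.sum())
        fp = int(((labels == 1) & (y == 0) & keep).sum())
        fn = int(((labels == 0) & (y == 1) & keep).sum())
        rows.append(
            {
                "threshold": t,
                "n_retained": n_ret,
                "accuracy": float(correct[keep].mean()) if n_ret else np.nan,
                "false_positives": fp,
                "false_negatives": fn,
                "n_discarded_correct": int((correct & ~keep).sum()),
                "n_discarded_incorrect": int((~correct & ~keep).sum()),
            }
        )
    return pd.DataFrame(rows)


def stratified_performance(
    votes: VoteMatrix,
    cohort: Cohort,
    by: str = "site",
    truth: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Ensemble accuracy per site, quality grade or patient.

    AUC uses the fraction of member votes for class 1 as the score and is
    reported only for groups containing both classes.
    """
    if by not in ("site", "quality", "patient"):
        raise ValueError("by must be one of 'site', 'quality', 'patient'")
    truth = dict(truth) if truth is not None else cohort.truth()
    key = {
        "site": lambda t: cohort.tile(t).site_id,
        "quality": lambda t: cohort.tile(t).quality_grade,
        "patient": lambda t: cohort.tile(t).patient_id,
    }[by]
    df = pd.DataFrame(
        {
            "tile_id": votes.tile_ids,
            "group": [key(t) for t in votes.tile_ids],
            "label": votes.ensemble_label,
            "score": votes.votes_for_1 / votes.n_members,
            "truth": [truth[t] for t in votes.tile_ids],
        }
    )
    rows = []
    for g, sub in df.groupby("group", sort=True):
        both = sub["truth"].nunique() == 2
        rows.append(
            {
                by: g,
                "n_tiles": len(sub),
                "accuracy": float((sub["label"] == sub["truth"]).mean()),
                "auc": float(roc_auc_score(sub["truth"], sub["score"])) if both else np.nan,
            }
        )
    return pd.DataFrame(rows)


def apply_exclusion_list(
    tile_ids: Iterable[str], excluded: Iterable[str]
) -> tuple[tuple[str, ...], int]:
    """Set-difference a tile list against any third-party rejection mask.

    Unknown excluded ids are ignored; their count is returned so callers can
    log it.  Order of the retained tiles is preserved.
    """
    tile_ids = list(tile_ids)
    excluded = set(excluded)
    unknown = len(excluded - set(tile_ids))
    retained = tuple(t for t in tile_ids if t not in excluded)
    return retained, unknown


def exclusion_delta(
    votes: VoteMatrix, truth: Mapping[str, int], excluded: Iterable[str]
) -> dict:
    """Accuracy before/after removing an exclusion list from the test tiles
    (the quality-control comparison: does masking flagged tiles help?)."""
    y = np.array([truth[t] for t in votes.tile_ids])
    correct = votes.ensemble_label == y
    before = float(correct.mean())
    retained, unknown = apply_exclusion_list(votes.tile_ids, excluded)
    keep = np.isin(np.array(votes.tile_ids), np.array(retained, dtype=object))
    after = float(correct[keep].mean()) if keep.any() else np.nan
    return {
        "accuracy_before": before,
        "accuracy_after": after,
        "delta": after - before if keep.any() else np.nan,
        "n_excluded": int((~keep).sum()),
        "n_unknown_ids": unknown,
    }


def flag_suspect_labels(
    votes: VoteMatrix,
    truth: Mapping[str, int],
    review_threshold: int | None = None,
) -> pd.DataFrame:
    """Tiles whose recorded label the ensemble confidently contradicts.

    Intended to prioritise human re-review of possible annotation mistakes:
    rows are sorted by agreement descending (most confidently contradicted
    first).  Labels are never changed automatically.
    """
    n = votes.n_members
    if review_threshold is None:
        review_threshold = min_threshold(n)
    y = np.array([truth[t] for t in votes.tile_ids])
    labels = votes.ensemble_label
    agreement = votes.agreement
    mask = (labels != y) & (agreement >= review_threshold)
    df = pd.DataFrame(
        {
            "tile_id": [t for t, m in zip(votes.tile_ids, mask) if m],
            "recorded_label": y[mask],
            "ensemble_label": labels[mask],
            "agreement": agreement[mask],
        }
    )
    return df.sort_values(
        ["agreement", "tile_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
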