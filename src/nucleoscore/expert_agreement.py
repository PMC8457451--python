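"""Expert-panel agreement analysis.

A panel of pathologists votes each case PTC-like or non-PTC-like.  The
mean expert rating of case i is

    c_i = max(c_i_n, c_i_p) / (c_i_n + c_i_p)

where c_i_n and c_i_p are the non-PTC-like and PTC-like vote counts; it
ranges from 0.5 (full dissent) to 1 (unanimity).  Consensus labels follow
the panel-study protocol: cases re-reviewed with nuclear scoring are
PTC-like when more than 15 of the re-reviewers assign a PTC-like score,
non-PTC-like when fewer than 13 do, and excluded in between; all other
cases take the majority vote, with exact ties excluded.  Classifier
performance can then be evaluated on the subsets of cases whose agreement
c_i reaches a minimum threshold, against the "distribution accuracy"
baseline (always predicting the subset's majority class).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CaseLabel",
    "VoteRecord",
    "LabeledCase",
    "expert_rating",
    "derive_labels",
    "mean_expert_rating",
    "threshold_evaluation",
    "votes_from_frame",
]

#: Re-review decision bounds: < LOW -> non-PTC-like, > HIGH -> PTC-like,
#: the closed interval [LOW, HIGH] -> excluded (borderline gray zone).
REREVIEW_LOW = 13
REREVIEW_HIGH = 15


class CaseLabel(str, enum.Enum):
    PTC_LIKE = "PTC"
    NON_PTC_LIKE = "nonPTC"
    EXCLUDED = "excluded"


@dataclass(frozen=True)
class VoteRecord:
    case_id: str
    votes_non_ptc: int
    votes_ptc: int
    rereviewed: bool = False
    rereview_ptc_count: int | None = None

    def __post_init__(self):
        if self.votes_non_ptc < 0 or self.votes_ptc < 0:
            raise ValueError("vote counts must be non-negative")
        if self.votes_non_ptc + self.votes_ptc == 0:
            raise ValueError("total votes must be positive")
        if self.rereviewed != (self.rereview_ptc_count is not None):
            raise ValueError("rereview_ptc_count present iff rereviewed")


@dataclass(frozen=True)
class LabeledCase:
    case_id: str
    label: CaseLabel
    c_i: float  # NaN when excluded by tie


def expert_rating(v: VoteRecord) -> float:
    """Mean expert pathologist rating c_i = max(votes) / total votes."""
    total = v.votes_non_ptc + v.votes_ptc
    return max(v.votes_non_ptc, v.votes_ptc) / total


def derive_labels(votes: list[VoteRecord]) -> list[LabeledCase]:
    """Consensus labels from vote records (re-review rule, majority, ties)."""
    out: list[LabeledCase] = []
    for v in votes:
        c_i = expert_rating(v)
        if v.rereviewed:
            if v.rereview_ptc_count < REREVIEW_LOW:
                label = CaseLabel.NON_PTC_LIKE
            elif v.rereview_ptc_count > REREVIEW_HIGH:
                label = CaseLabel.PTC_LIKE
            else:
                label = CaseLabel.EXCLUDED
        elif v.votes_ptc > v.votes_non_ptc:
            label = CaseLabel.PTC_LIKE
        elif v.votes_ptc < v.votes_non_ptc:
            label = CaseLabel.NON_PTC_LIKE
        else:
            label = CaseLabel.EXCLUDED
            c_i = float("nan")
        out.append(LabeledCase(v.case_id, label, c_i))
    return out


def mean_expert_rating(cases: list[LabeledCase]) -> float:
    """Arithmetic mean of c_i over included (non-excluded) cases."""
    vals = [c.c_i for c in cases if c.label is not CaseLabel.EXCLUDED]
    if not vals:
        return float("nan")
    return float(np.mean(vals))


def threshold_evaluation(
    cases: list[LabeledCase],
    predictions: dict[str, str] | None,
    thresholds,
) -> pd.DataFrame:
    """Per-threshold evaluation on high-agreement subsets.

    For every threshold t the subset is the included cases with c_i >= t
    (inclusive).  Reports the subset size, per-class counts, the PTC-like
    fraction, the subset's mean expert rating, the distribution accuracy
    (majority-class fraction — the accuracy achievable knowing only the
    class distribution) and, when ``predictions`` maps case ids to
    ``"PTC"``/``"nonPTC"``, the classifier accuracy on the subset.
    """
    included = [c for c in cases if c.label is not CaseLabel.EXCLUDED]
    rows = []
    for t in thresholds:
        subset = [c for c in included if c.c_i >= t]
        n = len(subset)
        n_ptc = sum(1 for c in subset if c.label is CaseLabel.PTC_LIKE)
        n_non = n - n_ptc
        row: dict = {
            "threshold": float(t),
            "n": n,
            "n_ptc": n_ptc,
            "n_non_ptc": n_non,
        }
        if n == 0:
            row.update(
                ptc_fraction=np.nan,
                mean_c_i=np.nan,
                distribution_accuracy=np.nan,
                classifier_accuracy=np.nan,
            )
        else:
            row["ptc_fraction"] = n_ptc / n
            row["mean_c_i"] = float(np.mean([c.c_i for c in subset]))
            row["distribution_accuracy"] = max(n_ptc, n_non) / n
            if predictions is not None:
                missing = [c.case_id for c in subset if c.case_id not in predictions]
                if missing:
                    raise ValueError(f"missing predictions for cases: {missing[:5]}")
                correct = sum(
                    1 for c in subset if predictions[c.case_id] == c.label.value
                )
                row["classifier_accuracy"] = correct / n
            else:
                row["classifier_accuracy"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def votes_from_frame(df: pd.DataFrame) -> list[VoteRecord]:
    """Build vote records from a vote-table DataFrame (see io_manifest)."""
    records = []
    for _, r in df.iterrows():
        rereviewed = bool(r.get("rereviewed", False))
        cnt = r.get("rereview_ptc_count")
        cnt = int(cnt) if rereviewed and pd.notna(cnt) else None
        records.append(
            VoteRecord(
                case_id=str(r["case_id"]),
                votes_non_ptc=int(r["votes_non_ptc"]),
                votes_ptc=int(r["votes_ptc"]),
                rereviewed=rereviewed,
                rereview_ptc_count=cnt,
            )
        )
    return records
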