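"""Aggregate per-pathway connectivity into per-instance reports.

Each reference instance is summarized by how many selected pathways it
scores significantly positive in (mimics the treatment) and how many
significantly negative (reverses it). Instances are then ranked by total
signed-pathway count and the top k reported with counts rendered in the
compact "20+ 1−" style.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .connectivity import ConnectivityCell
from .containers import ReferenceBank

__all__ = [
    "InstanceSummary",
    "count_pathways",
    "top_k_report",
    "render_counts",
    "shared_hits_report",
]


@dataclass
class InstanceSummary:
    instance_id: str
    compound: str
    dose: str
    positive_count: int
    negative_count: int
    sum_abs_score: float

    @property
    def total_count(self) -> int:
        return self.positive_count + self.negative_count


def count_pathways(
    cells: list[ConnectivityCell],
    bank: ReferenceBank,
    alpha: float = 0.05,
    min_abs_score: float = 0.0,
) -> list[InstanceSummary]:
    """Count significantly positive/negative pathways per instance.

    A pathway counts as positive for an instance when its score is > 0,
    |score| >= ``min_abs_score`` and (when ``alpha`` < 1) its permutation
    p-value is < alpha; negative analogously. ``alpha=1`` with
    ``min_abs_score=0`` reduces to a pure sign count over nonzero scores.
    Every bank instance gets a summary, including all-zero ones.
    """
    if alpha < 1:
        missing = [c for c in cells if c.p_value is None]
        if missing:
            raise ValueError(
                "cells lack permutation p-values; run connectivity_significance "
                "or set alpha=1"
            )
    meta = {i.instance_id: i for i in bank}
    pos: dict[str, int] = {i: 0 for i in meta}
    neg: dict[str, int] = {i: 0 for i in meta}
    sabs: dict[str, float] = {i: 0.0 for i in meta}
    for c in cells:
        if c.score == 0 or abs(c.score) < min_abs_score:
            continue
        if alpha < 1 and not (c.p_value < alpha):
            continue
        if c.score > 0:
            pos[c.instance_id] += 1
        else:
            neg[c.instance_id] += 1
        sabs[c.instance_id] += abs(c.score)
    return [
        InstanceSummary(
            instance_id=iid,
            compound=meta[iid].compound,
            dose=meta[iid].dose,
            positive_count=pos[iid],
            negative_count=neg[iid],
            sum_abs_score=sabs[iid],
        )
        for iid in meta
    ]


def render_counts(positive: int, negative: int) -> str:
    """Render signed pathway counts, e.g. (20, 1) -> "20+ 1−"."""
    parts = []
    if positive > 0:
        parts.append(f"{positive}+")
    if negative > 0:
        parts.append(f"{negative}−")
    return " ".join(parts) if parts else "0"


def top_k_report(
    summaries: list[InstanceSummary],
    k: int = 10,
    rank_by: str = "total",
) -> pd.DataFrame:
    """Top-k instances by signed pathway count.

    Ordered by count descending (``rank_by`` = "total" for
    positive + negative, "max" for max(positive, negative)), then by
    summed |score| descending, then by instance id — a fully
    deterministic ordering.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if rank_by == "total":
        key_count = lambda s: s.total_count  # noqa: E731
    elif rank_by == "max":
        key_count = lambda s: max(s.positive_count, s.negative_count)  # noqa: E731
    else:
        raise ValueError(f"unknown rank_by {rank_by!r}")
    ordered = sorted(
        summaries, key=lambda s: (-key_count(s), -s.sum_abs_score, s.instance_id)
    )[:k]
    return pd.DataFrame(
        {
            "instance_id": [s.instance_id for s in ordered],
            "compound": [s.compound for s in ordered],
            "dose": [s.dose for s in ordered],
            "positive_count": [s.positive_count for s in ordered],
            "negative_count": [s.negative_count for s in ordered],
            "pathway_counts": [
                render_counts(s.positive_count, s.negative_count) for s in ordered
            ],
            "sum_abs_score": [s.sum_abs_score for s in ordered],
        }
    )


def shared_hits_report(reports: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Instances appearing in more than one patient's top-k report.

    Takes ``patient_id -> top_k_report frame`` and returns one row per
    instance found in >= 2 reports, with the patients it hit and its signed
    counts per patient — a post-hoc intersection, not a joint model.
    """
    rows: dict[str, dict] = {}
    for patient in sorted(reports):
        for r in reports[patient].itertuples(index=False):
            entry = rows.setdefault(
                r.instance_id,
                {"instance_id": r.instance_id, "compound": r.compound,
                 "dose": r.dose, "patients": [], "counts": []},
            )
            entry["patients"].append(patient)
            entry["counts"].append(f"{patient}:{r.pathway_counts}")
    shared = [e for e in rows.values() if len(e["patients"]) >= 2]
    shared.sort(key=lambda e: (-len(e["patients"]), e["instance_id"]))
    return pd.DataFrame(
        {
            "instance_id": [e["instance_id"] for e in shared],
            "compound": [e["compound"] for e in shared],
            "dose": [e["dose"] for e in shared],
            "n_patients": [len(e["patients"]) for e in shared],
            "pathway_counts": ["; ".join(e["counts"]) for e in shared],
        }
    )
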