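"""Cross-track consensus: intersect per-track aggregated lists (SGLs).

A gene becomes a reliable housekeeping candidate when it appears in at least
``threshold`` of the per-track top-K lists (default 3 when six tracks are
aggregated, otherwise the majority ceil(M/2)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .rankagg import AggregatedList


@dataclass
class ConsensusReport:
    """Per-gene SGL membership counts and candidate flags."""

    table: pd.DataFrame     # index gene_id: count, tracks, candidate
    threshold: int
    n_lists: int

    @property
    def candidates(self) -> list[str]:
        return list(self.table.index[self.table["candidate"]])


def default_threshold(n_lists: int) -> int:
    """Rule of three for six lists; majority-of-lists otherwise."""
    return 3 if n_lists == 6 else math.ceil(n_lists / 2)


def intersect_sgls(sgls: list[AggregatedList],
                   threshold: int | None = None) -> ConsensusReport:
    """Count per-gene SGL membership and flag candidates.

    Ordering of the report is deterministic: descending membership count,
    then gene id.
    """
    if len(sgls) < 2:
        raise ValueError("need at least 2 aggregated lists")
    if threshold is None:
        threshold = default_threshold(len(sgls))
    if not 1 <= threshold <= len(sgls):
        raise ValueError(
            f"threshold must lie in [1, {len(sgls)}], got {threshold}"
        )
    membership: dict[str, list[str]] = {}
    for sgl in sgls:
        for g in sgl.items:
            membership.setdefault(g, []).append(sgl.track)
    rows = sorted(membership.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    table = pd.DataFrame(
        {
            "count": [len(tr) for _, tr in rows],
            "tracks": [",".join(tr) for _, tr in rows],
            "candidate": [len(tr) >= threshold for _, tr in rows],
        },
        index=pd.Index([g for g, _ in rows], name="gene_id"),
    )
    return ConsensusReport(table, threshold, len(sgls))


def sharing_histogram(report: ConsensusReport) -> pd.Series:
    """Number of genes at each exact membership level 1..M.

    The histogram sums to the size of the union of the aggregated lists.
    """
    levels = range(1, report.n_lists + 1)
    counts = report.table["count"].value_counts()
    return pd.Series([int(counts.get(lv, 0)) for lv in levels],
                     index=pd.Index(levels, name="level"), name="n_genes")
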