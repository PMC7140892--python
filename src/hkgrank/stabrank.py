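"""First-round per-study gene-stability ranking.

Three filters/criteria produce a ranked gene list (GL) per study and track:

1. detection — every sample of a gene must reach a detection floor (default:
   the 1st percentile of the study's full expression matrix, a stand-in for
   platform present/absent calls);
2. no exceptional expression — a gene is excluded if any single sample
   deviates from the gene's mean log2 expression by two-fold or more
   (>= 1.0 log2 units by default);
3. survivors are sorted by ascending population standard deviation
   (divisor n), ties broken lexicographically by gene id, and truncated to
   the top N.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genemap import GeneExpressionMatrix

log = logging.getLogger(__name__)


@dataclass
class RankedGeneList:
    """Ordered per-study gene list, most stable first."""

    study_id: str
    track: str
    gene_ids: list[str]
    sd_scores: np.ndarray
    cut_size: int

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.sd_scores):
            raise ValueError("gene_ids and sd_scores must align")
        if len(self.gene_ids) > self.cut_size:
            raise ValueError("list longer than its cut size N")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids in ranked list")
        if np.any(np.diff(self.sd_scores) < -1e-12):
            raise ValueError("SD scores must be non-decreasing along the list")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rank": np.arange(1, len(self.gene_ids) + 1),
            "gene_id": self.gene_ids,
            "sd": self.sd_scores,
        })


def rank_first_round(gem: GeneExpressionMatrix, N: int = 5000,
                     detect_floor: float | None = None,
                     fold_limit: float = 1.0) -> RankedGeneList:
    """Rank genes of one GEM by expression stability (ascending SD)."""
    if len(gem.values) == 0:
        raise ValueError("empty GEM")
    if N < 1:
        raise ValueError("N must be >= 1")
    if fold_limit <= 0:
        raise ValueError("fold_limit must be positive")
    x = gem.values.to_numpy(dtype=float)
    genes = gem.values.index.to_numpy()

    if detect_floor is None:
        detect_floor = float(np.quantile(x, 0.01))
    detected = x.min(axis=1) >= detect_floor
    deviation = np.abs(x - x.mean(axis=1, keepdims=True)).max(axis=1)
    unexceptional = deviation < fold_limit
    keep = detected & unexceptional
    if not keep.any():
        log.warning("study %s track %s: all genes excluded by first-round "
                    "criteria", gem.study_id, gem.track)
        return RankedGeneList(gem.study_id, gem.track, [], np.empty(0), N)

    sd = x[keep].std(axis=1)            # population convention (divisor n)
    kept_genes = genes[keep]
    order = np.lexsort((kept_genes, sd))[:N]
    return RankedGeneList(gem.study_id, gem.track,
                          list(kept_genes[order]), sd[order], N)
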