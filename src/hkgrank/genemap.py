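"""Collapse probeset-level expression to gene-level matrices (GEMs).

Matching rules: a probeset annotated to more than one gene is deleted; rows
with any missing value are dropped; a gene measured by several probesets gets
the per-sample median of their values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .normtracks import ProbesetExpressionMatrix
from .synthgen import ProbeAnnotation


@dataclass
class GeneExpressionMatrix:
    """Gene x sample log2 expression for one study under one track."""

    study_id: str
    track: str
    values: pd.DataFrame            # index gene_id, columns sample_ids
    census: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("gene ids must be unique")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("GEM must be free of missing values")


def build_gem(mat: ProbesetExpressionMatrix, ann: ProbeAnnotation) -> GeneExpressionMatrix:
    """Apply the probe-matching rules and collapse to gene level.

    The median of an even number of probesets is the mean of the two central
    values (plain numerical median).
    """
    missing = [ps for ps in mat.values.index if ps not in ann.mapping]
    if missing:
        raise KeyError(
            f"probesets missing from annotation: {missing[:10]}"
            + ("..." if len(missing) > 10 else "")
        )
    n_probesets = len(mat.values.index)

    single = [ps for ps in mat.values.index if len(ann.mapping[ps]) == 1]
    vals = mat.values.loc[single]
    finite = np.isfinite(vals.to_numpy()).all(axis=1)
    vals = vals.loc[finite]
    rows_kept = len(vals)

    genes = pd.Index([ann.mapping[ps][0] for ps in vals.index], name="gene_id")
    collapsed = vals.groupby(genes).median().sort_index()
    census = {
        "n_probesets": n_probesets,
        "rows_kept": rows_kept,
        "n_genes": len(collapsed),
    }
    return GeneExpressionMatrix(mat.study_id, mat.track, collapsed, census)


def gem_census(gems: list[GeneExpressionMatrix]) -> pd.DataFrame:
    """Bookkeeping table: probeset count, post-filter rows, final gene count."""
    rows = [
        {
            "study_id": g.study_id,
            "track": g.track,
            "n_probesets": g.census.get("n_probesets"),
            "rows_kept": g.census.get("rows_kept"),
            "n_genes": g.census.get("n_genes", len(g.values)),
        }
        for g in gems
    ]
    return pd.DataFrame(rows, columns=["study_id", "track", "n_probesets",
                                       "rows_kept", "n_genes"])
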