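"""Validation-stage stability metrics and gene-set comparison reports.

Two independent stability indexes are used throughout:

* Gini coefficient (GC) on non-negative expression values,
  GC = 2 * sum_i i*x_(i) / (n * sum_i x_i) - (n+1)/n with x sorted ascending
  (0 for perfectly even expression);
* population standard deviation (SD), divisor n.

Comparison reports rank the union of two disjoint gene sets (e.g. newly
identified vs commonly used reference genes) by both indexes and measure how
much of the top-n each set occupies.  GC is computed on linear-scale values
(2^x for a log2 matrix) and SD on the log2 values, each labeled in output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .normtracks import quantile_normalize


def gini(x) -> float:
    """Gini coefficient of a non-negative, not-all-zero vector."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 1:
        raise ValueError("gini expects a non-empty 1-D vector")
    if (x < 0).any():
        raise ValueError("gini requires non-negative values")
    total = x.sum()
    if total == 0:
        raise ValueError("gini is undefined for an all-zero vector")
    n = len(x)
    xs = np.sort(x)
    i = np.arange(1, n + 1)
    return float(2.0 * (i * xs).sum() / (n * total) - (n + 1) / n)


def sd(x) -> float:
    """Population standard deviation (divisor n)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 1:
        raise ValueError("sd expects a non-empty 1-D vector")
    return float(np.std(x))


def log2_cpm(counts) -> pd.DataFrame:
    """log2(CPM + 1) normalization of a gene x sample count matrix."""
    df = counts if isinstance(counts, pd.DataFrame) else pd.DataFrame(counts)
    x = df.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    colsum = x.sum(axis=0)
    bad = np.flatnonzero(colsum == 0)
    if len(bad):
        names = [str(df.columns[j]) for j in bad]
        raise ValueError(f"zero column sum for sample(s): {names}")
    cpm = x * 1e6 / colsum[None, :]
    return pd.DataFrame(np.log2(cpm + 1.0), index=df.index, columns=df.columns)


def log_quantile(matrix) -> pd.DataFrame:
    """log2 transform followed by quantile normalization (linear input)."""
    df = matrix if isinstance(matrix, pd.DataFrame) else pd.DataFrame(matrix)
    x = df.to_numpy(dtype=float)
    if (x <= 0).any():
        raise ValueError("log-quantile normalization requires positive entries")
    return quantile_normalize(pd.DataFrame(np.log2(x), index=df.index,
                                           columns=df.columns))


@dataclass
class GeneSetComparison:
    table: pd.DataFrame                 # gene, set, sd_log2, gc_linear, ranks
    occupancy: dict                     # set label -> {"sd": frac, "gc": frac}
    top_sd: list[str]
    top_gc: list[str]
    missing: dict = field(default_factory=dict)
    top_n: int = 10


def compare_gene_sets(matrix: pd.DataFrame, set_a, set_b, top_n: int = 10,
                      labels: tuple[str, str] = ("set_a", "set_b")) -> GeneSetComparison:
    """Rank two disjoint gene sets jointly by SD and by Gini coefficient.

    ``matrix`` is a gene x sample log2-scale expression matrix.  Genes absent
    from the matrix are reported and skipped.  Rankings are ascending (most
    stable first) with lexicographic tie-break; occupancy is the fraction of
    the top-n positions held by each set under each ranking.
    """
    set_a, set_b = list(set_a), list(set_b)
    if set(set_a) & set(set_b):
        raise ValueError("gene sets must be disjoint")
    missing = {
        labels[0]: [g for g in set_a if g not in matrix.index],
        labels[1]: [g for g in set_b if g not in matrix.index],
    }
    present_a = [g for g in set_a if g in matrix.index]
    present_b = [g for g in set_b if g in matrix.index]
    if not present_a and not present_b:
        raise ValueError("no genes of either set are present in the matrix")

    rows = []
    for label, genes in ((labels[0], present_a), (labels[1], present_b)):
        for g in genes:
            v = matrix.loc[g].to_numpy(dtype=float)
            rows.append({
                "gene_id": g,
                "set": label,
                "sd_log2": sd(v),
                "gc_linear": gini(np.exp2(v)),
            })
    table = pd.DataFrame(rows).set_index("gene_id")
    lex = table.sort_index()            # stable sort => lexicographic tie-break
    for metric, col in (("sd", "sd_log2"), ("gc", "gc_linear")):
        order = lex.sort_values(col, kind="stable").index
        table[f"{metric}_rank"] = pd.Series(
            np.arange(1, len(order) + 1), index=order
        )
    top_sd = list(table.sort_values(["sd_rank"]).index[:top_n])
    top_gc = list(table.sort_values(["gc_rank"]).index[:top_n])
    occupancy = {
        label: {
            "sd": sum(table.loc[g, "set"] == label for g in top_sd) / len(top_sd),
            "gc": sum(table.loc[g, "set"] == label for g in top_gc) / len(top_gc),
        }
        for label in labels
    }
    return GeneSetComparison(table, occupancy, top_sd, top_gc, missing, top_n)
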