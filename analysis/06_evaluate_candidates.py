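"""Evaluate the candidate set: recovery vs truth and held-out validation.

Computes precision/recall of the candidate set against the embedded
housekeeping archetype, per-track SGL recall, and a Table-2-style comparison
on a held-out RNA-seq-style count matrix: the embedded-stable set vs a set
of moderately stable condition-responsive genes, ranked by SD and by Gini
coefficient of log2(CPM+1) expression.
"""

import json

from common import parse_args

from hkgrank.pipeline import stage_evaluate


def main() -> None:
    cfg, out = parse_args(__doc__)
    metrics = stage_evaluate(cfg, out)
    print(f"candidates: {metrics['n_candidates']} "
          f"(true positives {metrics['true_positives']} of "
          f"{metrics['n_housekeeping']} embedded housekeeping genes)")
    print(f"precision {metrics['precision']:.3f}, recall {metrics['recall']:.3f}")
    print("per-track SGL recall: "
          + ", ".join(f"{t}={v:.2f}" for t, v in metrics["sgl_recall"].items()))
    print(f"top-10 occupancy of the embedded-stable set: "
          f"SD ranking {metrics['occupancy_stable_sd']:.0%}, "
          f"Gini ranking {metrics['occupancy_stable_gc']:.0%}")
    print(json.dumps({k: v for k, v in metrics.items() if k != "sgl_recall"},
                     indent=1, sort_keys=True))


if __name__ == "__main__":
    main()
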