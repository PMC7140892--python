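"""Cross-track consensus: intersect the SGLs into the candidate set.

A gene appearing in at least `consensus_threshold` of the per-track SGLs is
flagged as a reliable housekeeping-gene candidate; the sharing histogram
shows how many genes reach each membership level.
"""

import pandas as pd
from common import parse_args

from hkgrank.pipeline import stage_consensus


def main() -> None:
    cfg, out = parse_args(__doc__)
    stage_consensus(cfg, out)
    report = pd.read_csv(out / "consensus" / "report.tsv", sep="\t",
                         index_col="gene_id")
    hist = pd.read_csv(out / "consensus" / "sharing_histogram.tsv", sep="\t")
    n_cand = int(report["candidate"].sum())
    print(f"{n_cand} candidates appear in >= {cfg.consensus_threshold} of "
          f"{len(cfg.tracks)} SGLs")
    print("sharing histogram (genes per membership level):")
    print(hist.to_string(index=False))


if __name__ == "__main__":
    main()
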