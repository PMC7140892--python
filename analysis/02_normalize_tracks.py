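"""Normalize every study under the four tracks and collapse to gene level.

Runs the RMA-, MAS5-, Li-Wong- and VSN-style tracks on each study's
probe-level intensities, then applies the probe-matching rules (multi-gene
probesets deleted, multi-probe genes collapsed by the per-sample median) to
obtain one gene expression matrix (GEM) per study and track.
"""

import pandas as pd
from common import parse_args

from hkgrank.pipeline import stage_normalize


def main() -> None:
    cfg, out = parse_args(__doc__)
    stage_normalize(cfg, out)
    census = pd.read_csv(out / "gems" / "census.tsv", sep="\t")
    by_track = census.groupby("track")[["n_probesets", "rows_kept", "n_genes"]].first()
    print("probeset bookkeeping per track (identical across studies):")
    print(by_track.to_string())
    print(f"{len(census)} GEMs written under {out / 'gems'}")


if __name__ == "__main__":
    main()
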