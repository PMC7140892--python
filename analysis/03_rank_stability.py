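"""First-round stability ranking of every GEM.

Applies the three ranking criteria per study and track — detection in all
samples, no single-sample deviation of two-fold (1 log2 unit) or more, and
ascending population-SD ordering — and keeps the top N genes as the
first-round ranked gene list (GL).
"""

import pandas as pd
from common import parse_args

from hkgrank.pipeline import stage_rank


def main() -> None:
    cfg, out = parse_args(__doc__)
    stage_rank(cfg, out)
    sizes = []
    for track_dir in sorted((out / "gls").iterdir()):
        for f in sorted(track_dir.glob("*.tsv")):
            sizes.append(len(pd.read_csv(f, sep="\t")))
    print(f"wrote {len(sizes)} first-round lists (cut size N={cfg.stab_N}); "
          f"list lengths {min(sizes)}-{max(sizes)}")


if __name__ == "__main__":
    main()
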