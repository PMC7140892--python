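"""Second-round rank aggregation per track via Cross-Entropy Monte Carlo.

For each normalization track, the top-K truncations of the per-study lists
are aggregated into a single second-round gene list (SGL) minimizing the
mean Spearman footrule distance to the inputs.
"""

import json

from common import parse_args

from hkgrank.pipeline import stage_aggregate


def main() -> None:
    cfg, out = parse_args(__doc__)
    stage_aggregate(cfg, out)
    for track in cfg.tracks:
        diag = json.loads((out / "sgls" / f"{track}_diagnostics.json").read_text())
        print(f"{track}: footrule objective {diag['objective']:.2f}, "
              f"{diag['iterations']} iterations, converged={diag['converged']}")
    print(f"SGLs of length K={cfg.agg_K} under {out / 'sgls'}")


if __name__ == "__main__":
    main()
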