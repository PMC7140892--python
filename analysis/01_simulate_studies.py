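"""Simulate the multi-study compendium and apply the study-level filter.

Generates 30 synthetic microarray-style studies (2,000 genes, 2% embedded
housekeeping genes, two-condition designs of 4-24 samples) with probe-level
PM/MM intensities, probe annotation including multi-probe genes and
multi-gene probesets, and a ground-truth table; then keeps the studies that
pass the filtration rules (more than three samples, not a duplicate, raw
data available).
"""

from common import parse_args

from hkgrank import synthgen
from hkgrank.pipeline import stage_synth, _kept_studies


def main() -> None:
    cfg, out = parse_args(__doc__)
    stage_synth(cfg, out)
    truth = synthgen.read_truth(out / "synth")
    kept = _kept_studies(out)
    counts = truth.table["archetype"].value_counts()
    print(f"simulated {cfg.n_studies} studies, {cfg.n_genes} genes "
          f"({counts.get('housekeeping', 0)} housekeeping, "
          f"{counts.get('responsive', 0)} responsive, "
          f"{counts.get('noisy', 0)} noisy)")
    print(f"{len(kept)} studies pass the sample-count/duplication/raw-data filter")
    print(f"outputs under {out / 'synth'}")


if __name__ == "__main__":
    main()
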