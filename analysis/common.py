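"""Shared setup for the numbered analysis drivers.

Each driver runs one stage of the reference-gene identification study into a
shared run directory (default ``results/analysis_run``) so the sequence
01 -> 06 reproduces the full analysis step by step.
"""

import argparse
import logging
from pathlib import Path

from hkgrank.pipeline import RunConfig


def parse_args(description: str):
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/analysis_run"))
    args = ap.parse_args()
    logging.basicConfig(level=logging.INFO, format="%(message)s")
    args.out.mkdir(parents=True, exist_ok=True)
    cfg = RunConfig(seed=args.seed)
    cfg.to_yaml(args.out / "config.yaml")
    return cfg, args.out
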