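#!/usr/bin/env python
"""Run every stage end to end and write the markdown report.

Equivalent to `rewardsdt all --seed <seed> --out <dir>`; prints the location
of the summary bundle.
"""

import argparse
from pathlib import Path

from rewardsdt.config import load_config
from rewardsdt.pipeline import run_pipeline

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out", default="results")
args = parser.parse_args()

cfg = load_config(overrides={"seed": args.seed})
run_pipeline(cfg, Path(args.out), stages=("all",))
print(f"report: {Path(args.out) / 'report.md'}")
print(f"summary: {Path(args.out) / 'summary.json'}")
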