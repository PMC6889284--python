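#!/usr/bin/env python
"""Simulate the default study-scale cohort and write the input bundle."""

import argparse
from pathlib import Path

from agreenet.io import write_answer_key, write_motion, write_responses
from agreenet.profiles import write_module_catalog
from agreenet.simulate import default_config, simulate_catalog, simulate_motion, simulate_responses

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results/bundle"))
args = parser.parse_args()

cfg = default_config()
key, cat = simulate_catalog(cfg, args.seed)
rm, truth = simulate_responses(cfg, key, cat, args.seed + 1)
motion = simulate_motion(cfg, truth, args.seed + 2)

args.out.mkdir(parents=True, exist_ok=True)
write_responses(rm, args.out / "responses.csv")
write_answer_key(key, args.out / "answer_key.csv")
write_module_catalog(cat, args.out / "module_catalog.json")
write_motion(motion, args.out / "motion.csv")
truth.to_json(args.out / "truth.json")
print(f"{rm.n_students} students x {rm.n_questions} questions -> {args.out}")
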