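#!/usr/bin/env python
"""Motion-screen the normative groups (ANOVA + Tukey HSD, iterated)."""

import argparse
import json
from pathlib import Path

import pandas as pd

from agreenet.io import read_motion
from agreenet.profiles import screen_groups_motion

parser = argparse.ArgumentParser()
parser.add_argument("--bundle", type=Path, default=Path("results/bundle"))
parser.add_argument("--groups", type=Path, default=Path("results/groups"))
parser.add_argument("--min-group-size", type=int, default=10)
parser.add_argument("--alpha", type=float, default=0.05)
parser.add_argument("--out", type=Path, default=Path("results/screening.json"))
args = parser.parse_args()

partition = pd.read_csv(args.groups / "partition.csv", dtype={"student_id": str})
members: dict[int, list[str]] = {}
for r in partition.itertuples():
    members.setdefault(int(r.community), []).append(r.student_id)
normative = {c: m for c, m in members.items() if len(m) >= args.min_group_size}

report = screen_groups_motion(normative, read_motion(args.bundle / "motion.csv"), args.alpha)
payload = {"retained": report.retained, "excluded": report.excluded, "rounds": report.rounds}
args.out.parent.mkdir(parents=True, exist_ok=True)
args.out.write_text(json.dumps(payload, indent=1))
print(f"retained={report.retained} excluded={report.excluded}")
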