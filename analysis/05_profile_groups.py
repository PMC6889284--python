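#!/usr/bin/env python
"""Module-overlap profiles and figures for the retained groups."""

import argparse
import json
from pathlib import Path

import pandas as pd

from agreenet.communities import Partition, modularity
from agreenet.io import read_answer_key, read_responses, score_accuracy
from agreenet.profiles import classify_profile, overlap_profile, read_module_catalog
from agreenet.viz import plot_profile_bars, plot_response_heatmap

parser = argparse.ArgumentParser()
parser.add_argument("--bundle", type=Path, default=Path("results/bundle"))
parser.add_argument("--groups", type=Path, default=Path("results/groups"))
parser.add_argument("--screening", type=Path, default=Path("results/screening.json"))
parser.add_argument("--out", type=Path, default=Path("results/profiles"))
args = parser.parse_args()

rm = read_responses(args.bundle / "responses.csv")
key = read_answer_key(args.bundle / "answer_key.csv")
cat = read_module_catalog(args.bundle / "module_catalog.json", key)
partition = pd.read_csv(args.groups / "partition.csv", dtype={"student_id": str})
assign = dict(zip(partition["student_id"], partition["community"].astype(int)))
retained = json.loads(args.screening.read_text())["retained"]

args.out.mkdir(parents=True, exist_ok=True)
rows, summary, profiles = [], {}, {}
for c in retained:
    members = [s for s, cc in assign.items() if cc == c]
    prof = overlap_profile(members, rm, key, cat, group_id=c)
    profiles[c] = prof
    desc = classify_profile(prof)
    for m in cat.module_ids:
        rows.append(
            {
                "group": c, "module": m, "module_name": cat.display_names.get(m, m),
                "raw": prof.raw[m], "scaled_overlap": prof.scaled_overlap[m],
                "share": prof.share[m],
            }
        )
    summary[str(c)] = {
        "size": prof.size,
        "accuracy": prof.accuracy,
        "dominant_modules": list(desc.dominant_modules),
        "coherence_class": desc.coherence_class,
    }
pd.DataFrame(rows).to_csv(args.out / "profiles.csv", index=False)
acc = score_accuracy(rm, key)
(args.out / "groups.json").write_text(
    json.dumps({"groups": summary, "cohort_mean_accuracy": acc.mean_accuracy}, indent=1)
)

part = Partition(assign=assign, map_score=0.0, modularity_q=0.0)
plot_response_heatmap(rm, part, args.out / "heatmap.png")
plot_profile_bars(profiles, args.out / "profile_bars.png")
for c, info in summary.items():
    print(f"group {c}: n={info['size']} accuracy={info['accuracy']:.1%} dominant={info['dominant_modules']}")
print(f"cohort mean accuracy {acc.mean_accuracy:.1%}")
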