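#!/usr/bin/env python
"""Project the agreement network and extract its significance backbone."""

import argparse
from pathlib import Path

from agreenet.io import read_responses
from agreenet.network import BackboneConfig, build_bipartite, lans_backbone, project_agreement, write_edge_list

parser = argparse.ArgumentParser()
parser.add_argument("--bundle", type=Path, default=Path("results/bundle"))
parser.add_argument("--alpha", type=float, default=0.01)
parser.add_argument("--out", type=Path, default=Path("results/network"))
args = parser.parse_args()

rm = read_responses(args.bundle / "responses.csv")
g = project_agreement(build_bipartite(rm))
bb = lans_backbone(g, BackboneConfig(alpha=args.alpha))
args.out.mkdir(parents=True, exist_ok=True)
write_edge_list(g, bb, args.out / "edges.csv", args.out / "nodes.csv")
print(
    f"{g.number_of_nodes()} students, {g.number_of_edges()} edges, "
    f"{bb.number_of_edges()} retained at alpha={args.alpha}"
)
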