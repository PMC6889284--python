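"""Minimal plots: the response heatmap ordered by community, and
per-group module-profile bars."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .communities import Partition
from .io import ResponseMatrix
from .profiles import GroupProfile


def plot_response_heatmap(
    rm: ResponseMatrix, part: Partition, path: str | Path
) -> None:
    """Students x questions heatmap, rows grouped by detected community.

    Cell color encodes the chosen option index; black horizontal lines
    separate communities.
    """
    order = sorted(rm.students, key=lambda s: (part.assign[s], s))
    opt_index = {
        q: {o: k for k, o in enumerate(rm.options[q])} for q in rm.questions
    }
    mat = np.full((len(order), rm.n_questions), np.nan)
    for i, s in enumerate(order):
        for j, q in enumerate(rm.questions):
            v = rm.choices.at[s, q]
            if isinstance(v, str):
                mat[i, j] = opt_index[q][v]
    fig, ax = plt.subplots(figsize=(6, 8))
    ax.imshow(mat, aspect="auto", cmap="viridis", interpolation="nearest")
    prev = None
    for i, s in enumerate(order):
        if prev is not None and part.assign[s] != prev:
            ax.axhline(i - 0.5, color="black", lw=1.0)
        prev = part.assign[s]
    ax.set_xlabel("question")
    ax.set_ylabel("student (grouped by community)")
    ax.set_xticks(range(rm.n_questions), rm.questions, rotation=90, fontsize=6)
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_profile_bars(
    profiles: Mapping[object, GroupProfile], path: str | Path
) -> None:
    """Scaled within-group overlap per conceptual module, one panel per group."""
    groups = list(profiles)
    fig, axes = plt.subplots(
        len(groups), 1, figsize=(6, 2.2 * len(groups)), squeeze=False
    )
    for ax, g in zip(axes[:, 0], groups):
        prof = profiles[g]
        mods = list(prof.scaled_overlap)
        ax.bar(mods, [prof.scaled_overlap[m] for m in mods], color="#3b6ea5")
        ax.set_title(
            f"group {g} (n={prof.size}, accuracy={prof.accuracy:.0%})", fontsize=9
        )
        ax.set_ylabel("errors / student")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
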