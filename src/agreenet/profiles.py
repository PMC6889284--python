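"""Group reasoning profiles against a catalog of misconception modules.

A *conceptual module* is a named set of incorrect (question, option) pairs
that students tend to co-select — a coherent non-Newtonian conception such
as the impetus-force idea. Each detected student group is characterized by
its accuracy and by how its incorrect responses distribute over the
modules, on two complementary scales:

* ``scaled_overlap[m]`` — module-m responses per group member (raw count
  divided by group size, so groups of different sizes are comparable);
* ``share[m]`` — fraction of the group's incorrect responses in module m
  (shares over modules sum to at most 1; the remainder is unaffiliated).

The module also provides the group-level motion screen: a one-way ANOVA on
per-run framewise displacement across groups, with Tukey HSD post hocs to
drop any group moving significantly more than the rest.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import AnswerKey, ResponseMatrix, ValidationError

__all__ = [
    "ModuleCatalog",
    "GroupProfile",
    "ProfileDescriptor",
    "read_module_catalog",
    "write_module_catalog",
    "overlap_profile",
    "classify_profile",
    "one_way_anova",
    "tukey_hsd",
    "screen_groups_motion",
    "AnovaResult",
    "TukeyResult",
    "ScreeningReport",
]


@dataclass(frozen=True)
class ModuleCatalog:
    """Map from module ID to its set of incorrect (question, option) pairs."""

    modules: Mapping[str, frozenset[tuple[str, str]]]
    display_names: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str], str] = {}
        for mid, pairs in self.modules.items():
            for pair in pairs:
                if pair in seen:
                    raise ValidationError(
                        f"pair {pair} claimed by both {seen[pair]!r} and {mid!r}"
                    )
                seen[pair] = mid

    @property
    def module_ids(self) -> list[str]:
        return list(self.modules)

    def module_of(self, question: str, option: str) -> str | None:
        for mid, pairs in self.modules.items():
            if (question, option) in pairs:
                return mid
        return None

    def validate_against(self, key: AnswerKey) -> None:
        for mid, pairs in self.modules.items():
            for q, opt in pairs:
                if q in key.correct and key[q] == opt:
                    raise ValidationError(
                        f"module {mid!r} contains the correct answer ({q!r}, {opt!r})"
                    )


def read_module_catalog(path: str | Path, key: AnswerKey | None = None) -> ModuleCatalog:
    """Load a module catalog from JSON and validate it.

    Schema: ``{"modules": {"m1": {"name": ..., "items": [{"question": ...,
    "option": ...}, ...]}, ...}}``. Entries matching the keyed correct
    answer, or pairs claimed by two modules, are hard errors.
    """
    with open(path) as fh:
        raw = json.load(fh)
    modules = {}
    names = {}
    for mid, spec in raw["modules"].items():
        modules[mid] = frozenset(
            (item["question"], item["option"]) for item in spec["items"]
        )
        names[mid] = spec.get("name", mid)
    cat = ModuleCatalog(modules=modules, display_names=names)
    if key is not None:
        cat.validate_against(key)
    return cat


def write_module_catalog(cat: ModuleCatalog, path: str | Path) -> None:
    payload = {
        "modules": {
            mid: {
                "name": cat.display_names.get(mid, mid),
                "items": [
                    {"question": q, "option": o} for q, o in sorted(pairs)
                ],
            }
            for mid, pairs in cat.modules.items()
        }
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


@dataclass(frozen=True)
class GroupProfile:
    group_id: object
    size: int
    accuracy: float
    raw: Mapping[str, int]            # incorrect responses per module
    scaled_overlap: Mapping[str, float]  # responses per group member
    share: Mapping[str, float]        # fraction of the group's errors
    n_incorrect: int
    n_unaffiliated: int               # errors outside every module


def overlap_profile(
    group: Iterable[str],
    rm: ResponseMatrix,
    key: AnswerKey,
    cat: ModuleCatalog,
    group_id: object = None,
) -> GroupProfile:
    """Profile one student group against the module catalog.

    Counts every incorrect response of the group's members, attributes it
    to the module owning that (question, option) pair (or to the
    unaffiliated pool), and reports per-capita and share normalizations.
    A group with no incorrect responses gets an all-zero share vector.
    """
    members = list(group)
    if not members:
        raise ValueError("group is empty")
    missing = [s for s in members if s not in rm.choices.index]
    if missing:
        raise ValueError(f"group members not in response matrix: {missing}")
    key.validate_against(rm)

    raw = dict.fromkeys(cat.module_ids, 0)
    n_incorrect = 0
    n_answered = 0
    n_correct = 0
    sub = rm.choices.loc[members]
    for q in rm.questions:
        corr = key[q]
        col = sub[q].dropna()
        n_answered += len(col)
        n_correct += int((col == corr).sum())
        wrong = col[col != corr]
        n_incorrect += len(wrong)
        for opt, cnt in wrong.value_counts().items():
            mid = cat.module_of(q, opt)
            if mid is not None:
                raw[mid] += int(cnt)
    size = len(members)
    affiliated = sum(raw.values())
    scaled = {m: raw[m] / size for m in raw}
    if n_incorrect > 0:
        share = {m: raw[m] / n_incorrect for m in raw}
    else:
        share = dict.fromkeys(raw, 0.0)
    return GroupProfile(
        group_id=group_id,
        size=size,
        accuracy=n_correct / n_answered if n_answered else float("nan"),
        raw=raw,
        scaled_overlap=scaled,
        share=share,
        n_incorrect=n_incorrect,
        n_unaffiliated=n_incorrect - affiliated,
    )


@dataclass(frozen=True)
class ProfileDescriptor:
    """Coherence classification of a group's module-share vector."""

    dominant_modules: tuple[str, ...]
    coherence_class: str              # 'concentrated' or 'fragmented'
    fragmentation_index: float        # normalized share entropy in [0, 1]


def classify_profile(
    profile: GroupProfile, dominance_threshold: float = 0.5
) -> ProfileDescriptor:
    """Classify a profile as concentrated vs fragmented.

    A module is *dominant* if it holds more than ``dominance_threshold``
    of the group's incorrect responses (share >= threshold). The
    fragmentation index is the entropy of the share vector (restricted to
    modules with positive share) normalized by log2 of their count, so a
    point mass scores 0 and a uniform spread scores 1.
    """
    share = {m: v for m, v in profile.share.items() if v > 0}
    dominant = tuple(m for m, v in profile.share.items() if v >= dominance_threshold)
    if len(share) <= 1:
        entropy = 0.0
    else:
        total = sum(share.values())
        ps = [v / total for v in share.values()]
        entropy = -sum(p * math.log2(p) for p in ps) / math.log2(len(ps))
    return ProfileDescriptor(
        dominant_modules=dominant,
        coherence_class="concentrated" if dominant else "fragmented",
        fragmentation_index=entropy,
    )


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    degenerate: bool = False


def one_way_anova(groups: Mapping[object, Sequence[float]]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA.

    F = MSB / MSW from the between/within sum-of-squares decomposition;
    p from the F(df_between, df_within) distribution. All-identical data
    is the null case (F = 0, p = 1); zero within-group variance with
    unequal means is flagged degenerate with p = 0.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("ANOVA requires at least 2 groups")
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group needs at least one observation")
    n_total = sum(a.size for a in arrays)
    k = len(arrays)
    if n_total <= k:
        raise ValueError("total n must exceed the number of groups")
    grand = np.concatenate(arrays).mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b, df_w = k - 1, n_total - k
    if ssw == 0.0:
        if ssb == 0.0:
            return AnovaResult(0.0, df_b, df_w, 1.0)
        return AnovaResult(np.inf, df_b, df_w, 0.0, degenerate=True)
    f = (ssb / df_b) / (ssw / df_w)
    if ssb == 0.0:
        return AnovaResult(0.0, df_b, df_w, 1.0)
    p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(float(f), df_b, df_w, p)


@dataclass(frozen=True)
class TukeyResult:
    table: pd.DataFrame               # one row per unordered group pair
    alpha: float

    def significantly_greater_than_all(self) -> list:
        """Groups whose mean is significantly above every other group's."""
        out = []
        groups = set(self.table["group_a"]).union(self.table["group_b"])
        for g in groups:
            rows = self.table[
                (self.table["group_a"] == g) | (self.table["group_b"] == g)
            ]
            def greater(r):
                diff = r.mean_diff if r.group_a == g else -r.mean_diff
                return r.significant and diff > 0
            if len(rows) and all(greater(r) for r in rows.itertuples()):
                out.append(g)
        return out


def tukey_hsd(
    groups: Mapping[object, Sequence[float]], alpha: float = 0.05
) -> TukeyResult:
    """Tukey HSD pairwise comparisons (Tukey-Kramer for unequal sizes).

    For groups a, b the studentized-range statistic is
    q = |mean_a - mean_b| / sqrt( MSW/2 * (1/n_a + 1/n_b) ), with the
    adjusted p from the studentized-range distribution with k groups and
    the ANOVA's within degrees of freedom.
    """
    labels = list(groups)
    arrays = {g: np.asarray(groups[g], dtype=float) for g in labels}
    anova = one_way_anova(groups)
    k, df_w = len(labels), anova.df_within
    msw = sum(((a - a.mean()) ** 2).sum() for a in arrays.values()) / df_w
    rows = []
    for i, ga in enumerate(labels):
        for gb in labels[i + 1:]:
            a, b = arrays[ga], arrays[gb]
            diff = a.mean() - b.mean()
            if msw == 0.0:
                q = 0.0 if diff == 0 else np.inf
                p = 1.0 if diff == 0 else 0.0
            else:
                se = math.sqrt(msw / 2.0 * (1.0 / a.size + 1.0 / b.size))
                q = abs(diff) / se
                p = float(stats.studentized_range.sf(q, k, df_w))
            rows.append(
                {
                    "group_a": ga,
                    "group_b": gb,
                    "mean_diff": float(diff),
                    "q_statistic": float(q),
                    "p_adjusted": min(p, 1.0),
                    "significant": p < alpha,
                }
            )
    return TukeyResult(table=pd.DataFrame(rows), alpha=alpha)


@dataclass(frozen=True)
class ScreeningReport:
    retained: list
    excluded: list
    rounds: list[dict]                # per-round ANOVA + exclusions audit


def screen_groups_motion(
    group_members: Mapping[object, Sequence[str]],
    motion: pd.DataFrame,
    alpha: float = 0.05,
) -> ScreeningReport:
    """Screen student groups for head-motion confounds.

    Runs a one-way ANOVA on per-run framewise displacement across groups.
    If the omnibus test is significant, groups that Tukey HSD flags as
    moving significantly more than every remaining group are excluded and
    the test repeats, until no omnibus difference remains or only two
    groups are left. Observations are per run, not per student.
    """
    current = {g: list(m) for g, m in group_members.items()}
    for g, members in current.items():
        for s in members:
            if not (motion["student_id"] == s).any():
                raise ValidationError(f"group {g!r}: student {s!r} has no motion rows")
    excluded: list = []
    rounds: list[dict] = []
    while len(current) > 2:
        fd = {
            g: motion.loc[motion["student_id"].isin(m), "mean_fd_mm"].to_numpy()
            for g, m in current.items()
        }
        anova = one_way_anova(fd)
        record = {
            "groups": list(current),
            "f": anova.f_statistic,
            "df_between": anova.df_between,
            "df_within": anova.df_within,
            "p": anova.p_value,
            "excluded": [],
        }
        if anova.p_value >= alpha:
            rounds.append(record)
            break
        tukey = tukey_hsd(fd, alpha=alpha)
        offenders = tukey.significantly_greater_than_all()
        record["excluded"] = list(offenders)
        rounds.append(record)
        if not offenders:
            break
        for g in offenders:
            excluded.append(g)
            del current[g]
    else:
        if not rounds:  # started with <= 2 groups: single omnibus test only
            fd = {
                g: motion.loc[motion["student_id"].isin(m), "mean_fd_mm"].to_numpy()
                for g, m in current.items()
            }
            if len(fd) == 2:
                anova = one_way_anova(fd)
                rounds.append(
                    {
                        "groups": list(current),
                        "f": anova.f_statistic,
                        "df_between": anova.df_between,
                        "df_within": anova.df_within,
                        "p": anova.p_value,
                        "excluded": [],
                    }
                )
    return ScreeningReport(retained=list(current), excluded=excluded, rounds=rounds)
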