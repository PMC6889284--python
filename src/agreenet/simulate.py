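"""Synthetic response data with planted group structure.

Generates answer keys, misconception-module catalogs, response matrices
and head-motion tables whose ground truth is known, so that every stage
of the agreement-network pipeline can be verified by recovery tests.

The generative model plants groups of students who (i) share a per-group
difficulty profile — which questions they tend to miss — and (ii) share a
module-weight vector governing *which* wrong answer they give when they
miss. Both features mirror what makes real response data clusterable:
students holding the same conception miss the same questions and choose
the same distractors. The default configuration reproduces the scale of
the in-scanner study this package models: 107 students, 9 questions with
4 options, normative groups of 24/17/10 students at accuracies
0.77/0.73/0.53 with distinct dominant modules, one additional group with
inflated head motion, and a population of small background groups.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .communities import Partition, compare_partitions
from .io import AnswerKey, ResponseMatrix
from .profiles import GroupProfile, ModuleCatalog

__all__ = [
    "GroupSpec",
    "SimulationConfig",
    "PlantedTruth",
    "default_config",
    "simulate_catalog",
    "simulate_responses",
    "simulate_motion",
    "recovery_report",
    "RecoveryScorecard",
]


@dataclass(frozen=True)
class GroupSpec:
    """One planted student group.

    module_weights
        Relative preference over catalog modules when answering
        incorrectly; normalized internally. Empty means unaffiliated
        (uniform) errors.
    concentration
        Probability in [0, 1] that an erring member gives the group's
        modal wrong answer for that question (the prototype distractor,
        drawn once per group from the module weights restricted to the
        question); otherwise the member errs idiosyncratically, sampling
        a module from the weights and an option within it.
    difficulty_spread
        Gamma shape of the group-idiosyncratic per-question difficulty
        jitter (smaller = the group's errors concentrate on fewer
        questions). None gives a flat profile: every question missed with
        probability 1 - p_correct. The error budget is additionally
        weighted toward questions covered by the group's modules — a
        group holding a conception misses the questions probing it.
    """

    name: str
    size: int
    p_correct: float
    module_weights: Mapping[str, float] = field(default_factory=dict)
    concentration: float = 0.95
    difficulty_spread: float | None = 0.2
    fd_mean_mm: float = 0.15
    fd_sd_mm: float = 0.05

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError(f"group {self.name!r}: size must be >= 1")
        if not 0.0 <= self.p_correct <= 1.0:
            raise ValueError(f"group {self.name!r}: p_correct must be in [0, 1]")
        if any(w < 0 for w in self.module_weights.values()):
            raise ValueError(f"group {self.name!r}: negative module weight")


@dataclass(frozen=True)
class SimulationConfig:
    n_questions: int = 9
    n_options: int = 4
    n_modules: int = 9
    groups: tuple[GroupSpec, ...] = ()
    runs_per_student: int = 3
    p_missing: float = 0.0
    seed: int = 0

    @property
    def n_students(self) -> int:
        return sum(g.size for g in self.groups)


_MODULE_NAMES = {
    "m1": "impetus force",
    "m2": "more force yields more result",
    "m5": "confusion relating speed and path",
    "m6": "sudden forces induce instantaneous path change",
    "m7": "an object's mass determines how it falls",
    "m9": "confusion about gravitational action",
}


def default_config() -> SimulationConfig:
    """The study-scale default: 13 planted groups totalling 107 students.

    Three normative groups carry the planted accuracies 0.77/0.73/0.53
    and the dominant-module structure of the population being modeled
    (group A nearly pure impetus-force errors; group B impetus force or
    gravitation confusion; group C five modules at similar rates). A
    fourth normative-sized group D has head motion inflated by +0.2 mm.
    The remainder of the cohort is small background groups, each with its
    own dominant conception and mid-range accuracy.
    """
    groups = [
        GroupSpec("A", 24, 0.77, {"m1": 1.0}),
        GroupSpec("B", 17, 0.73, {"m1": 0.5, "m9": 0.5}),
        GroupSpec("C", 10, 0.53, {m: 0.2 for m in ("m1", "m2", "m5", "m6", "m7")}),
        GroupSpec("D", 13, 0.65, {"m2": 0.6, "m3": 0.4}, fd_mean_mm=0.35),
    ]
    # each background group holds its own dominant conception; keeping the
    # catalogs mostly disjoint keeps the groups' hard-question prototypes
    # from colliding
    bg_modules = [
        ("m2",), ("m3",), ("m4",), ("m5",), ("m6",),
        ("m7",), ("m8",), ("m9",), ("m5", "m8"),
    ]
    bg_sizes = [5, 5, 5, 5, 5, 5, 5, 4, 4]
    bg_p = [0.55, 0.60, 0.65, 0.55, 0.60, 0.65, 0.55, 0.60, 0.65]
    for i, (mods, n, p) in enumerate(zip(bg_modules, bg_sizes, bg_p)):
        w = 1.0 / len(mods)
        groups.append(GroupSpec(f"bg{i + 1}", n, p, {m: w for m in mods}))
    return SimulationConfig(groups=tuple(groups))


def simulate_catalog(
    cfg: SimulationConfig, seed: int
) -> tuple[AnswerKey, ModuleCatalog]:
    """Generate an answer key and a module catalog partitioning distractors.

    One option per question is correct. The incorrect (question, option)
    pairs are partitioned among the modules such that the first module
    spans every question (the broad, dominant conception) and every other
    module spans at least two distinct questions, so modules are
    cross-question constructs. Deterministic per (config, seed).
    """
    rng = np.random.default_rng(seed)
    nq, nopt, nm = cfg.n_questions, cfg.n_options, cfg.n_modules
    if nopt < 2:
        raise ValueError("need at least 2 options per question")
    total_incorrect = nq * (nopt - 1)
    if nm > total_incorrect / 2:
        raise ValueError(
            f"infeasible: {nm} modules cannot each span 2 questions with "
            f"only {total_incorrect} incorrect pairs"
        )
    questions = [f"q{i + 1}" for i in range(nq)]
    option_labels = [chr(ord("A") + k) for k in range(nopt)]
    correct = {q: option_labels[int(rng.integers(nopt))] for q in questions}

    for _ in range(50):
        incorrect: dict[str, list[str]] = {}
        for q in questions:
            opts = [o for o in option_labels if o != correct[q]]
            rng.shuffle(opts)
            incorrect[q] = opts
        modules: dict[str, set[tuple[str, str]]] = {
            f"m{i + 1}": set() for i in range(nm)
        }
        if nm == 1:
            for q in questions:
                modules["m1"].update((q, o) for o in incorrect[q])
        else:
            # the first module gets one distractor on every question
            for q in questions:
                modules["m1"].add((q, incorrect[q][0]))
            rest = [(q, o) for q in questions for o in incorrect[q][1:]]
            others = [f"m{i + 2}" for i in range(nm - 1)]
            for k, pair in enumerate(rest):
                modules[others[k % len(others)]].add(pair)
        spans = {m: len({q for q, _ in pairs}) for m, pairs in modules.items()}
        if all(s >= 2 for s in spans.values()) or nm == 1:
            break
    else:
        raise ValueError("could not allocate modules across >= 2 questions each")

    key = AnswerKey(correct=correct)
    names = {m: _MODULE_NAMES.get(m, f"conception {m}") for m in modules}
    cat = ModuleCatalog(
        modules={m: frozenset(p) for m, p in modules.items()}, display_names=names
    )
    cat.validate_against(key)
    return key, cat


_DIFFICULTY_FLOOR = 1.0  # residual miss weight on questions outside the group's modules


def _difficulty_profile(
    spec: GroupSpec,
    coverage: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-question error probabilities averaging to 1 - p_correct.

    ``coverage[q]`` is the group's normalized module weight present on
    question q. The error budget (1 - p_correct) * n_questions goes
    preferentially to covered questions, modulated by a seeded
    group-level difficulty jitter.
    """
    n_questions = len(coverage)
    budget = (1.0 - spec.p_correct) * n_questions
    if spec.difficulty_spread is None or budget == 0.0:
        return np.full(n_questions, 1.0 - spec.p_correct)
    # The profile is a fixed number of near-certain-miss "hard" questions
    # plus a flat, low residual on the rest: k = floor(budget / cap) hard
    # questions, chosen by weighted sampling without replacement so the
    # group's conceptual modules pull its hard set toward their questions.
    cap = 0.98
    jitter = np.maximum(rng.gamma(spec.difficulty_spread, size=n_questions), 1e-12)
    w = (_DIFFICULTY_FLOOR + coverage) * jitter
    k = min(int(budget // cap), n_questions)
    e = np.full(n_questions, 0.0)
    hard = rng.choice(n_questions, size=k, replace=False, p=w / w.sum()) if k else []
    e[hard] = cap
    rest = np.setdiff1d(np.arange(n_questions), hard)
    if rest.size:
        e[rest] = min(budget - k * cap, cap * rest.size) / rest.size
    return np.clip(e, 0.0, cap)


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth emitted alongside a simulated response matrix."""

    group_of: dict[str, str]
    p_correct: dict[str, float]                 # planted accuracy per group
    module_weights: dict[str, dict[str, float]]  # planted weights per group
    realized_accuracy: pd.Series
    attributions: pd.DataFrame  # student_id, question_id, outcome

    def group_members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s, g in self.group_of.items():
            out.setdefault(g, []).append(s)
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "group_of": self.group_of,
            "p_correct": self.p_correct,
            "module_weights": self.module_weights,
            "realized_accuracy": {
                k: float(v) for k, v in self.realized_accuracy.items()
            },
            "attributions": self.attributions.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            group_of=raw["group_of"],
            p_correct=raw["p_correct"],
            module_weights=raw["module_weights"],
            realized_accuracy=pd.Series(raw["realized_accuracy"]),
            attributions=pd.DataFrame(raw["attributions"]),
        )


def simulate_responses(
    cfg: SimulationConfig, key: AnswerKey, cat: ModuleCatalog, seed: int
) -> tuple[ResponseMatrix, PlantedTruth]:
    """Draw a response matrix from the planted-group model.

    Each group first gets (i) a difficulty profile — per-question error
    probabilities averaging 1 - p_correct, weighted toward the questions
    its modules cover — and (ii) a prototype wrong answer per question,
    drawn from its module weights restricted to the modules present
    there. Per student and question: the response is missing with
    probability ``p_missing``; otherwise correct with the group's
    per-question probability; otherwise the student errs — following the
    group prototype with probability ``concentration``, else sampling a
    module from the group's weights restricted to the question and an
    option uniformly within module cap question. If no weighted module
    covers the question, the error is uniform over incorrect options and
    attributed "unaffiliated".
    """
    if not cfg.groups:
        raise ValueError("simulation config declares no groups")
    rng = np.random.default_rng(seed)
    questions = [f"q{i + 1}" for i in range(cfg.n_questions)]
    module_ids = cat.module_ids
    # per question: which modules own which incorrect options
    on_q: dict[str, dict[str, list[str]]] = {q: {} for q in questions}
    for m, pairs in cat.modules.items():
        for q, opt in pairs:
            on_q[q].setdefault(m, []).append(opt)
    all_incorrect = {
        q: sorted({o for opts in on_q[q].values() for o in opts}) for q in questions
    }

    width = len(str(cfg.n_students))
    rows, group_of, attr_rows = {}, {}, []
    sid = 0
    for spec in cfg.groups:
        weights = {m: w for m, w in spec.module_weights.items() if w > 0}
        total_w = sum(weights.values()) or 1.0
        coverage = np.array(
            [
                sum(w for m, w in weights.items() if m in on_q[q]) / total_w
                for q in questions
            ]
        )
        err_p = _difficulty_profile(spec, coverage, rng)
        # group prototype: the modal wrong answer per question; on questions
        # outside the group's modules the prototype is an arbitrary
        # distractor, attributed to no conception
        prototype: dict[str, tuple[str | None, str]] = {}
        for q in questions:
            present = [m for m in weights if m in on_q[q]]
            if present:
                base = np.array([weights[m] for m in present], dtype=float)
                m = present[int(rng.choice(len(present), p=base / base.sum()))]
                opts = on_q[q][m]
                prototype[q] = (m, opts[int(rng.integers(len(opts)))])
            else:
                opts = all_incorrect[q]
                prototype[q] = (None, opts[int(rng.integers(len(opts)))])
        for _ in range(spec.size):
            sid += 1
            student = f"s{sid:0{width}d}"
            group_of[student] = spec.name
            row = {}
            for qi, q in enumerate(questions):
                if cfg.p_missing > 0 and rng.random() < cfg.p_missing:
                    row[q] = np.nan
                    attr_rows.append((student, q, "missing"))
                    continue
                if rng.random() >= err_p[qi]:
                    row[q] = key[q]
                    attr_rows.append((student, q, "correct"))
                    continue
                present = [mm for mm in weights if mm in on_q[q]]
                if rng.random() < spec.concentration:
                    m, opt = prototype[q]
                elif present:  # idiosyncratic conception-driven error
                    base = np.array([weights[mm] for mm in present], dtype=float)
                    m = present[int(rng.choice(len(present), p=base / base.sum()))]
                    opts = on_q[q][m]
                    opt = opts[int(rng.integers(len(opts)))]
                else:  # idiosyncratic unaffiliated error
                    m = None
                    opts = all_incorrect[q]
                    opt = opts[int(rng.integers(len(opts)))]
                row[q] = opt
                attr_rows.append((student, q, m if m is not None else "unaffiliated"))
            rows[student] = row

    choices = pd.DataFrame.from_dict(rows, orient="index")[questions]
    choices.index.name = "student_id"
    choices.columns.name = "question_id"
    option_labels = tuple(chr(ord("A") + k) for k in range(cfg.n_options))
    rm = ResponseMatrix(choices=choices, options={q: option_labels for q in questions})

    answered = rm.choices.notna()
    correct_row = pd.Series({q: key[q] for q in questions})
    acc = (rm.choices.eq(correct_row, axis=1) & answered).sum(axis=1) / answered.sum(
        axis=1
    ).replace(0, np.nan)
    truth = PlantedTruth(
        group_of=group_of,
        p_correct={g.name: g.p_correct for g in cfg.groups},
        module_weights={
            g.name: {m: float(w) for m, w in g.module_weights.items()}
            for g in cfg.groups
        },
        realized_accuracy=acc,
        attributions=pd.DataFrame(
            attr_rows, columns=["student_id", "question_id", "outcome"]
        ),
    )
    return rm, truth


def simulate_motion(
    cfg: SimulationConfig, truth: PlantedTruth, seed: int
) -> pd.DataFrame:
    """Per-run framewise displacement, Normal(group mean, sd) truncated at 0."""
    rng = np.random.default_rng(seed)
    specs = {g.name: g for g in cfg.groups}
    rows = []
    for student, gname in truth.group_of.items():
        spec = specs[gname]
        for run in range(1, cfg.runs_per_student + 1):
            if spec.fd_sd_mm <= 0:
                fd = spec.fd_mean_mm
            else:
                a = (0.0 - spec.fd_mean_mm) / spec.fd_sd_mm
                fd = float(
                    stats.truncnorm.rvs(
                        a, np.inf, loc=spec.fd_mean_mm, scale=spec.fd_sd_mm,
                        random_state=rng,
                    )
                )
            rows.append((student, f"run{run}", fd))
    return pd.DataFrame(rows, columns=["student_id", "run_id", "mean_fd_mm"])


@dataclass(frozen=True)
class RecoveryScorecard:
    ari: float
    nmi: float
    per_group: pd.DataFrame  # planted group, matched community, overlap, errors


def recovery_report(
    truth: PlantedTruth,
    part: Partition,
    profiles: Mapping[int, GroupProfile] | None = None,
) -> RecoveryScorecard:
    """Score how well an inferred partition recovers the planted one.

    Each planted group is matched to the inferred community sharing the
    most members; the scorecard reports partition-level ARI/NMI plus, per
    planted group, the accuracy estimation error of the matched community
    (vs the planted p_correct) and, when profiles are given, the cosine
    similarity between the matched community's module-share vector and
    the planted module weights.
    """
    planted = {s: g for s, g in truth.group_of.items()}
    if set(planted) != set(part.assign):
        raise ValueError("truth and partition cover different students")
    scores = compare_partitions(planted, part.assign)

    members = truth.group_members()
    rows = []
    for g, studs in members.items():
        counts: dict[int, int] = {}
        for s in studs:
            c = part.assign[s]
            counts[c] = counts.get(c, 0) + 1
        matched = max(counts, key=lambda c: (counts[c], -c))
        overlap = counts[matched] / len(studs)
        row = {
            "planted_group": g,
            "matched_community": matched,
            "overlap": overlap,
            "accuracy_error": np.nan,
            "profile_cosine": np.nan,
        }
        if profiles is not None and matched in profiles:
            prof = profiles[matched]
            row["accuracy_error"] = abs(prof.accuracy - truth.p_correct[g])
            w = truth.module_weights.get(g, {})
            mods = sorted(set(prof.share) | set(w))
            a = np.array([prof.share.get(m, 0.0) for m in mods])
            b = np.array([w.get(m, 0.0) for m in mods])
            if a.any() and b.any():
                row["profile_cosine"] = float(
                    a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
                )
        rows.append(row)
    return RecoveryScorecard(
        ari=scores["ari"], nmi=scores["nmi"], per_group=pd.DataFrame(rows)
    )
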