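"""Reading, writing and scoring of multiple-choice response data.

The central container is :class:`ResponseMatrix`: an ordered students x
questions table of categorical option labels with explicit missingness.
Long CSV (``student_id,question_id,choice``) is the canonical interchange
format; wide CSV (one column per question) is supported read-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

MISSING = None  # sentinel used in user-facing docs; internally pd.NA/NaN

__all__ = [
    "ResponseMatrix",
    "AnswerKey",
    "AccuracySummary",
    "BehaviorSummary",
    "read_responses",
    "write_responses",
    "read_answer_key",
    "write_answer_key",
    "read_motion",
    "write_motion",
    "score_accuracy",
    "summarize_behavior",
]


class ValidationError(ValueError):
    """Raised when an input file or container violates a format invariant."""


@dataclass(frozen=True)
class ResponseMatrix:
    """Students x questions table of chosen option labels.

    Parameters
    ----------
    choices
        DataFrame indexed by student ID with one column per question.
        Cells hold option labels (opaque strings); missing responses are NaN.
    options
        Mapping from question ID to the ordered tuple of valid option
        labels for that question. Option sets may differ per question.
    """

    choices: pd.DataFrame
    options: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if self.choices.index.has_duplicates:
            dupes = self.choices.index[self.choices.index.duplicated()].tolist()
            raise ValidationError(f"duplicate student IDs: {dupes}")
        if self.choices.columns.has_duplicates:
            dupes = self.choices.columns[self.choices.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate question IDs: {dupes}")
        for q in self.choices.columns:
            if q not in self.options:
                raise ValidationError(f"no option set declared for question {q!r}")
            valid = set(self.options[q])
            col = self.choices[q]
            bad = col.dropna()[~col.dropna().isin(valid)]
            if len(bad):
                s, v = bad.index[0], bad.iloc[0]
                raise ValidationError(
                    f"unknown option label {v!r} at (student={s!r}, question={q!r}); "
                    f"valid options for {q!r}: {sorted(valid)}"
                )

    @property
    def students(self) -> list[str]:
        return list(self.choices.index)

    @property
    def questions(self) -> list[str]:
        return list(self.choices.columns)

    @property
    def n_students(self) -> int:
        return len(self.choices.index)

    @property
    def n_questions(self) -> int:
        return len(self.choices.columns)

    def n_options(self, question: str) -> int:
        return len(self.options[question])

    def answered_counts(self) -> pd.Series:
        """Number of non-missing responses per student."""
        return self.choices.notna().sum(axis=1)

    def equals(self, other: "ResponseMatrix") -> bool:
        if dict(self.options) != dict(other.options):
            return False
        a, b = self.choices, other.choices
        if list(a.index) != list(b.index) or list(a.columns) != list(b.columns):
            return False
        return bool(((a == b) | (a.isna() & b.isna())).all().all())


@dataclass(frozen=True)
class AnswerKey:
    """Correct option label per question."""

    correct: Mapping[str, str]

    def __getitem__(self, question: str) -> str:
        return self.correct[question]

    def covers(self, questions: Iterable[str]) -> bool:
        return all(q in self.correct for q in questions)

    def validate_against(self, rm: ResponseMatrix) -> None:
        for q in rm.questions:
            if q not in self.correct:
                raise ValidationError(f"answer key does not cover question {q!r}")
            if self.correct[q] not in rm.options[q]:
                raise ValidationError(
                    f"correct answer {self.correct[q]!r} is not a valid option "
                    f"of question {q!r}"
                )


@dataclass(frozen=True)
class AccuracySummary:
    """Per-student accuracy and per-question miss rates.

    ``accuracy`` is #correct / #answered per student (NaN if the student
    answered nothing; such students are listed in ``undefined_students``
    and excluded from ``mean_accuracy``). Missing responses count in
    neither numerator nor denominator; they are tallied separately.
    """

    accuracy: pd.Series
    miss_rate: pd.Series
    n_missing_by_student: pd.Series
    n_missing_by_question: pd.Series
    undefined_students: tuple[str, ...]

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracy.dropna().mean())


def score_accuracy(rm: ResponseMatrix, key: AnswerKey) -> AccuracySummary:
    """Score a response matrix against an answer key.

    Raises
    ------
    ValidationError
        If the key does not cover every question of ``rm``.
    """
    key.validate_against(rm)
    correct_row = pd.Series({q: key[q] for q in rm.questions})
    answered = rm.choices.notna()
    is_correct = rm.choices.eq(correct_row, axis=1) & answered

    n_answered_s = answered.sum(axis=1)
    accuracy = is_correct.sum(axis=1) / n_answered_s.replace(0, np.nan)
    undefined = tuple(accuracy.index[n_answered_s == 0])

    n_answered_q = answered.sum(axis=0)
    n_wrong_q = (answered & ~is_correct).sum(axis=0)
    miss_rate = n_wrong_q / n_answered_q.replace(0, np.nan)

    return AccuracySummary(
        accuracy=accuracy,
        miss_rate=miss_rate,
        n_missing_by_student=(~answered).sum(axis=1),
        n_missing_by_question=(~answered).sum(axis=0),
        undefined_students=undefined,
    )


@dataclass(frozen=True)
class BehaviorSummary:
    """Paired two-condition comparison of per-student behavioral measures."""

    mean_a: float
    mean_b: float
    t_statistic: float
    df: int
    p_value: float
    degenerate: bool = False


def summarize_behavior(values_a: pd.Series, values_b: pd.Series) -> BehaviorSummary:
    """Paired two-sided t test between two aligned per-student vectors.

    Conditions must share the same student index. With zero difference
    everywhere the test is the null case (t = 0, p = 1); with a constant
    nonzero difference the variance of differences is zero and the result
    is flagged ``degenerate`` with p = 0.
    """
    if not values_a.index.equals(values_b.index):
        raise ValidationError("condition vectors are not aligned by student")
    n = len(values_a)
    if n < 2:
        raise ValidationError("paired comparison requires at least 2 students")
    diff = (values_a - values_b).to_numpy(dtype=float)
    mean_a, mean_b = float(values_a.mean()), float(values_b.mean())
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff, 0.0):
            return BehaviorSummary(mean_a, mean_b, 0.0, n - 1, 1.0)
        return BehaviorSummary(
            mean_a, mean_b, np.inf if diff.mean() > 0 else -np.inf, n - 1, 0.0, True
        )
    t, p = stats.ttest_rel(values_a, values_b)
    return BehaviorSummary(mean_a, mean_b, float(t), n - 1, float(p))


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def _infer_options(
    long: pd.DataFrame, declared: Mapping[str, Sequence[str]] | Sequence[str] | None
) -> dict[str, tuple[str, ...]]:
    questions = list(dict.fromkeys(long["question_id"]))
    if declared is None:
        out = {}
        for q in questions:
            seen = sorted(set(long.loc[long["question_id"] == q, "choice"].dropna()))
            out[q] = tuple(seen)
        return out
    if isinstance(declared, Mapping):
        return {q: tuple(declared[q]) for q in questions}
    return {q: tuple(declared) for q in questions}


def read_responses(
    path: str | Path,
    dialect: str = "long",
    options: Mapping[str, Sequence[str]] | Sequence[str] | None = None,
) -> ResponseMatrix:
    """Read a response table from CSV.

    Parameters
    ----------
    path
        CSV file. Long dialect needs columns ``student_id, question_id,
        choice``; wide dialect needs ``student_id`` plus one column per
        question. Empty cells are missing responses.
    dialect
        ``"long"`` (canonical) or ``"wide"``.
    options
        Option sets per question: a mapping ``{question: [labels]}``, a
        single shared label sequence, or None to infer from observed data.

    Raises
    ------
    ValidationError
        On duplicate (student, question) rows or option labels outside the
        declared set.
    """
    path = Path(path)
    if dialect == "long":
        df = pd.read_csv(path, dtype=str)
        required = {"student_id", "question_id", "choice"}
        if not required.issubset(df.columns):
            raise ValidationError(f"{path}: long dialect requires columns {sorted(required)}")
        dup = df.duplicated(subset=["student_id", "question_id"], keep=False)
        if dup.any():
            pairs = df.loc[dup, ["student_id", "question_id"]].drop_duplicates()
            raise ValidationError(
                f"{path}: duplicate (student, question) rows: "
                + ", ".join(f"({r.student_id}, {r.question_id})" for r in pairs.itertuples())
            )
        opts = _infer_options(df, options)
        students = list(dict.fromkeys(df["student_id"]))
        questions = list(dict.fromkeys(df["question_id"]))
        choices = df.pivot(index="student_id", columns="question_id", values="choice")
        choices = choices.reindex(index=students, columns=questions)
        choices.index.name = "student_id"
        choices.columns.name = "question_id"
        return ResponseMatrix(choices=choices, options=opts)
    if dialect == "wide":
        df = pd.read_csv(path, dtype=str)
        if "student_id" not in df.columns:
            raise ValidationError(f"{path}: wide dialect requires a student_id column")
        if df["student_id"].duplicated().any():
            d = df["student_id"][df["student_id"].duplicated()].tolist()
            raise ValidationError(f"{path}: duplicate student rows: {d}")
        long = df.melt(id_vars="student_id", var_name="question_id", value_name="choice")
        questions = [c for c in df.columns if c != "student_id"]
        opts = _infer_options(long, options)
        choices = df.set_index("student_id")[questions]
        choices.columns.name = "question_id"
        return ResponseMatrix(choices=choices, options=opts)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_responses(rm: ResponseMatrix, path: str | Path) -> None:
    """Write a response matrix as canonical long CSV (missing cells kept)."""
    long = rm.choices.stack(future_stack=True).reset_index()
    long.columns = ["student_id", "question_id", "choice"]
    long.to_csv(path, index=False)


def read_answer_key(path: str | Path) -> AnswerKey:
    df = pd.read_csv(path, dtype=str)
    if not {"question_id", "correct"}.issubset(df.columns):
        raise ValidationError(f"{path}: answer key requires columns question_id,correct")
    if df["question_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate question_id in answer key")
    if df["correct"].isna().any():
        raise ValidationError(f"{path}: missing correct option in answer key")
    return AnswerKey(correct=dict(zip(df["question_id"], df["correct"])))


def write_answer_key(key: AnswerKey, path: str | Path) -> None:
    pd.DataFrame(
        {"question_id": list(key.correct), "correct": list(key.correct.values())}
    ).to_csv(path, index=False)


def read_motion(path: str | Path) -> pd.DataFrame:
    """Read per-run head-motion table (student_id, run_id, mean_fd_mm)."""
    df = pd.read_csv(path, dtype={"student_id": str, "run_id": str})
    required = {"student_id", "run_id", "mean_fd_mm"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: motion table requires columns {sorted(required)}")
    if df.duplicated(subset=["student_id", "run_id"]).any():
        raise ValidationError(f"{path}: duplicate (student_id, run_id) rows")
    if (df["mean_fd_mm"].astype(float) < 0).any():
        raise ValidationError(f"{path}: negative mean_fd_mm values")
    df["mean_fd_mm"] = df["mean_fd_mm"].astype(float)
    return df


def write_motion(motion: pd.DataFrame, path: str | Path) -> None:
    motion.to_csv(path, index=False)
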