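"""Unit and property tests for module catalogs, profiles and the motion screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from agreenet.io import AnswerKey, ValidationError
from agreenet.profiles import (
    ModuleCatalog,
    classify_profile,
    one_way_anova,
    overlap_profile,
    read_module_catalog,
    screen_groups_motion,
    tukey_hsd,
    write_module_catalog,
)
from agreenet.simulate import default_config, simulate_catalog, simulate_responses


def test_catalog_rejects_pair_in_two_modules():
    with pytest.raises(ValidationError, match="claimed by both"):
        ModuleCatalog(
            modules={
                "m1": frozenset({("q1", "B")}),
                "m2": frozenset({("q1", "B"), ("q2", "A")}),
            }
        )


def test_catalog_rejects_correct_answer_pair(small_key):
    cat = ModuleCatalog(modules={"m1": frozenset({("q1", "A")})})
    with pytest.raises(ValidationError, match="correct answer"):
        cat.validate_against(small_key)


def test_catalog_json_roundtrip(tmp_path, small_cat, small_key):
    p = tmp_path / "cat.json"
    write_module_catalog(small_cat, p)
    back = read_module_catalog(p, small_key)
    assert dict(back.modules) == dict(small_cat.modules)
    assert back.display_names["m1"] == "conception one"


def test_overlap_profile_small_example(small_rm, small_key, small_cat):
    # errors: s2 q3=A (m1), s3 q1=B (m1), s4 q1=C (m2), s4 q2=A (m1)
    prof = overlap_profile(["s1", "s2", "s3", "s4"], small_rm, small_key, small_cat)
    assert prof.raw == {"m1": 3, "m2": 1}
    assert prof.n_incorrect == 4
    assert prof.n_unaffiliated == 0
    assert prof.scaled_overlap["m1"] == pytest.approx(0.75)
    assert prof.share["m1"] == pytest.approx(0.75)
    assert prof.accuracy == pytest.approx(7 / 11)  # 11 answered, 7 correct


def test_overlap_profile_errors(small_rm, small_key, small_cat):
    with pytest.raises(ValueError, match="empty"):
        overlap_profile([], small_rm, small_key, small_cat)
    with pytest.raises(ValueError, match="not in response matrix"):
        overlap_profile(["nobody"], small_rm, small_key, small_cat)


@given(st.integers(0, 19))
def test_profile_conservation_property(case):
    """Sum of module raw counts + unaffiliated == total incorrect, exactly."""
    cfg = default_config()
    key, cat = simulate_catalog(cfg, case)
    rm, truth = simulate_responses(cfg, key, cat, case + 1)
    rng = np.random.default_rng(case)
    members = list(rng.choice(rm.students, size=15, replace=False))
    prof = overlap_profile(members, rm, key, cat)
    assert sum(prof.raw.values()) + prof.n_unaffiliated == prof.n_incorrect
    assert sum(prof.share.values()) <= 1.0 + 1e-12


def test_single_module_group_has_share_one(small_rm, small_key, small_cat):
    # s3's only error is q1=B, owned by m1
    prof = overlap_profile(["s3"], small_rm, small_key, small_cat)
    assert prof.share == {"m1": 1.0, "m2": 0.0}
    desc = classify_profile(prof)
    assert desc.dominant_modules == ("m1",)
    assert desc.coherence_class == "concentrated"
    assert desc.fragmentation_index == 0.0


def test_classify_profile_fragmented(small_rm, small_key, small_cat):
    prof = overlap_profile(["s2", "s4"], small_rm, small_key, small_cat)
    # shares m1=2/3, m2=1/3 at threshold 0.7 -> no dominant module
    desc = classify_profile(prof, dominance_threshold=0.7)
    assert desc.dominant_modules == ()
    assert desc.coherence_class == "fragmented"
    assert 0.0 < desc.fragmentation_index <= 1.0


def test_anova_matches_scipy_f_oneway():
    rng = np.random.default_rng(3)
    groups = {i: rng.normal(i * 0.3, 1.0, size=12) for i in range(4)}
    res = one_way_anova(groups)
    f, p = stats.f_oneway(*groups.values())
    assert res.f_statistic == pytest.approx(float(f), rel=1e-12)
    assert res.p_value == pytest.approx(float(p), rel=1e-9)
    assert (res.df_between, res.df_within) == (3, 44)


def test_anova_degenerate_cases():
    same = one_way_anova({"a": [1.0, 1.0], "b": [1.0, 1.0, 1.0]})
    assert same.f_statistic == 0.0 and same.p_value == 1.0
    split = one_way_anova({"a": [1.0, 1.0], "b": [2.0, 2.0]})
    assert split.degenerate and split.p_value == 0.0
    with pytest.raises(ValueError):
        one_way_anova({"a": [1.0]})


def test_tukey_matches_scipy_reference():
    rng = np.random.default_rng(4)
    data = [rng.normal(m, 1.0, size=10) for m in (0.0, 0.0, 1.0)]
    mine = tukey_hsd({i: d for i, d in enumerate(data)})
    ref = stats.tukey_hsd(*data)
    for r in mine.table.itertuples():
        assert r.p_adjusted == pytest.approx(
            float(ref.pvalue[r.group_a, r.group_b]), abs=1e-8
        )


def test_tukey_greater_than_all_detection():
    rng = np.random.default_rng(5)
    groups = {
        "low1": rng.normal(0.15, 0.05, 30),
        "low2": rng.normal(0.15, 0.05, 30),
        "high": rng.normal(0.45, 0.05, 30),
    }
    res = tukey_hsd(groups)
    assert res.significantly_greater_than_all() == ["high"]


def _motion_frame(members, means, rng, sd=0.05, runs=3):
    rows = []
    for g, studs in members.items():
        for s in studs:
            for r in range(1, runs + 1):
                rows.append((s, f"run{r}", max(float(rng.normal(means[g], sd)), 0.0)))
    return pd.DataFrame(rows, columns=["student_id", "run_id", "mean_fd_mm"])


def test_screening_excludes_high_motion_group():
    rng = np.random.default_rng(6)
    members = {g: [f"{g}{i}" for i in range(12)] for g in ("a", "b", "c", "d")}
    motion = _motion_frame(members, {"a": 0.15, "b": 0.15, "c": 0.15, "d": 0.40}, rng)
    rep = screen_groups_motion(members, motion)
    assert rep.excluded == ["d"]
    assert sorted(rep.retained) == ["a", "b", "c"]
    assert rep.rounds[0]["p"] < 0.05


def test_screening_keeps_all_under_null():
    rng = np.random.default_rng(7)
    members = {g: [f"{g}{i}" for i in range(12)] for g in ("a", "b", "c")}
    motion = _motion_frame(members, {"a": 0.15, "b": 0.15, "c": 0.15}, rng)
    rep = screen_groups_motion(members, motion)
    assert rep.excluded == []
    assert sorted(rep.retained) == ["a", "b", "c"]


def test_screening_two_groups_reports_but_never_excludes():
    rng = np.random.default_rng(8)
    members = {g: [f"{g}{i}" for i in range(12)] for g in ("a", "b")}
    motion = _motion_frame(members, {"a": 0.15, "b": 0.40}, rng)
    rep = screen_groups_motion(members, motion)
    assert rep.excluded == []
    assert len(rep.rounds) == 1 and rep.rounds[0]["p"] < 0.05


def test_screening_missing_motion_rows_is_hard_error():
    motion = pd.DataFrame(
        {"student_id": ["x1"], "run_id": ["run1"], "mean_fd_mm": [0.1]}
    )
    with pytest.raises(ValidationError, match="no motion rows"):
        screen_groups_motion({"a": ["x1"], "b": ["x2"], "c": ["x3"]}, motion)
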