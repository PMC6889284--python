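"""Tests for the planted-group synthetic generator."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from agreenet.io import score_accuracy
from agreenet.simulate import (
    GroupSpec,
    PlantedTruth,
    SimulationConfig,
    default_config,
    simulate_catalog,
    simulate_motion,
    simulate_responses,
)


def test_default_config_study_conditions():
    cfg = default_config()
    assert cfg.n_students == 107
    assert (cfg.n_questions, cfg.n_options, cfg.n_modules) == (9, 4, 9)
    by_name = {g.name: g for g in cfg.groups}
    assert (by_name["A"].size, by_name["A"].p_correct) == (24, 0.77)
    assert (by_name["B"].size, by_name["B"].p_correct) == (17, 0.73)
    assert (by_name["C"].size, by_name["C"].p_correct) == (10, 0.53)
    # the planted high-motion group
    assert by_name["D"].fd_mean_mm > by_name["A"].fd_mean_mm
    # distinct dominant modules for the normative groups
    doms = [max(by_name[g].module_weights, key=by_name[g].module_weights.get) for g in "AB"]
    assert by_name["A"].module_weights == {"m1": 1.0}
    assert len(by_name["C"].module_weights) == 5


def test_group_spec_validation():
    with pytest.raises(ValueError, match="size"):
        GroupSpec("x", 0, 0.5)
    with pytest.raises(ValueError, match="p_correct"):
        GroupSpec("x", 5, 1.5)
    with pytest.raises(ValueError, match="negative"):
        GroupSpec("x", 5, 0.5, {"m1": -1.0})


@given(st.integers(0, 9))
def test_generators_are_pure_functions_of_seed(seed):
    cfg = default_config()
    k1, c1 = simulate_catalog(cfg, seed)
    k2, c2 = simulate_catalog(cfg, seed)
    assert dict(k1.correct) == dict(k2.correct)
    assert dict(c1.modules) == dict(c2.modules)
    r1, t1 = simulate_responses(cfg, k1, c1, seed + 1)
    r2, t2 = simulate_responses(cfg, k2, c2, seed + 1)
    assert r1.equals(r2)
    assert t1.group_of == t2.group_of
    m1 = simulate_motion(cfg, t1, seed + 2)
    m2 = simulate_motion(cfg, t2, seed + 2)
    assert m1.equals(m2)


def test_different_seeds_differ():
    cfg = default_config()
    k, c = simulate_catalog(cfg, 0)
    r1, _ = simulate_responses(cfg, k, c, 1)
    r2, _ = simulate_responses(cfg, k, c, 2)
    assert not r1.equals(r2)


def test_catalog_structure():
    cfg = default_config()
    key, cat = simulate_catalog(cfg, 0)
    cat.validate_against(key)  # no module contains a correct answer
    # modules partition all 27 incorrect pairs
    all_pairs = {p for pairs in cat.modules.values() for p in pairs}
    assert len(all_pairs) == 9 * 3
    # m1 spans every question; every module spans >= 2 questions
    spans = {m: len({q for q, _ in pairs}) for m, pairs in cat.modules.items()}
    assert spans["m1"] == 9
    assert all(s >= 2 for s in spans.values())


def test_catalog_infeasible_module_count():
    cfg = SimulationConfig(
        n_questions=2, n_options=3, n_modules=5, groups=(GroupSpec("a", 2, 0.5),)
    )
    with pytest.raises(ValueError, match="infeasible"):
        simulate_catalog(cfg, 0)


def test_emitted_artifacts_pass_validators(tmp_path):
    from agreenet.io import (
        read_answer_key,
        read_motion,
        read_responses,
        write_answer_key,
        write_motion,
        write_responses,
    )
    from agreenet.profiles import read_module_catalog, write_module_catalog

    cfg = default_config()
    key, cat = simulate_catalog(cfg, 3)
    rm, truth = simulate_responses(cfg, key, cat, 4)
    motion = simulate_motion(cfg, truth, 5)
    write_responses(rm, tmp_path / "r.csv")
    write_answer_key(key, tmp_path / "k.csv")
    write_module_catalog(cat, tmp_path / "c.json")
    write_motion(motion, tmp_path / "m.csv")
    rm2 = read_responses(tmp_path / "r.csv", options=rm.options)
    key2 = read_answer_key(tmp_path / "k.csv")
    key2.validate_against(rm2)
    read_module_catalog(tmp_path / "c.json", key2)
    m2 = read_motion(tmp_path / "m.csv")
    assert len(m2) == cfg.n_students * cfg.runs_per_student


def test_realized_accuracy_converges_to_planted():
    """Law of large numbers at three scales: mean |realized - planted| shrinks."""
    devs = []
    for scale, n_q in ((10, 9), (40, 18), (160, 36)):
        cfg = SimulationConfig(
            n_questions=n_q,
            n_modules=9,
            groups=(GroupSpec("g", scale, 0.7, {"m1": 1.0}, difficulty_spread=None),),
        )
        key, cat = simulate_catalog(cfg, 0)
        rm, truth = simulate_responses(cfg, key, cat, 1)
        devs.append(abs(truth.realized_accuracy.mean() - 0.7))
    assert devs[2] < devs[0] + 0.02  # noisy but shrinking envelope
    assert devs[2] < 0.02


def test_difficulty_profile_budget_conserved():
    """Mean per-question error probability equals 1 - p_correct by design:
    realized group accuracy is unbiased for the planted value."""
    cfg = default_config()
    key, cat = simulate_catalog(cfg, 0)
    accs = []
    for seed in range(30):
        _, truth = simulate_responses(cfg, key, cat, seed)
        members = truth.group_members()
        accs.append(truth.realized_accuracy[members["A"]].mean())
    # planted 0.77; SE of the 30-replicate mean is ~0.006
    assert np.mean(accs) == pytest.approx(0.77, abs=0.02)


def test_missingness_honored():
    cfg = SimulationConfig(
        groups=(GroupSpec("g", 50, 0.7),), p_missing=0.2, n_modules=9
    )
    key, cat = simulate_catalog(cfg, 0)
    rm, truth = simulate_responses(cfg, key, cat, 1)
    frac = rm.choices.isna().to_numpy().mean()
    assert 0.1 < frac < 0.3
    # attributions tally missing cells exactly
    n_missing_attr = (truth.attributions["outcome"] == "missing").sum()
    assert n_missing_attr == int(rm.choices.isna().to_numpy().sum())


def test_truth_json_roundtrip(tmp_path):
    cfg = default_config()
    key, cat = simulate_catalog(cfg, 0)
    _, truth = simulate_responses(cfg, key, cat, 1)
    truth.to_json(tmp_path / "t.json")
    back = PlantedTruth.from_json(tmp_path / "t.json")
    assert back.group_of == truth.group_of
    assert back.p_correct == truth.p_correct
    assert np.allclose(back.realized_accuracy, truth.realized_accuracy)


def test_motion_nonnegative_and_group_shift():
    cfg = default_config()
    key, cat = simulate_catalog(cfg, 0)
    _, truth = simulate_responses(cfg, key, cat, 1)
    motion = simulate_motion(cfg, truth, 2)
    assert (motion["mean_fd_mm"] >= 0).all()
    members = truth.group_members()
    fd_d = motion[motion["student_id"].isin(members["D"])]["mean_fd_mm"].mean()
    fd_a = motion[motion["student_id"].isin(members["A"])]["mean_fd_mm"].mean()
    assert fd_d - fd_a > 0.1  # planted +0.2 mm shift


def test_attributions_consistent_with_catalog():
    cfg = default_config()
    key, cat = simulate_catalog(cfg, 0)
    rm, truth = simulate_responses(cfg, key, cat, 1)
    attr = truth.attributions.set_index(["student_id", "question_id"])["outcome"]
    for s in rm.students[:20]:
        for q in rm.questions:
            v = rm.choices.at[s, q]
            out = attr.loc[(s, q)]
            if out == "correct":
                assert v == key[q]
            elif out == "unaffiliated":
                assert cat.module_of(q, v) is None
            elif out != "missing":
                assert cat.module_of(q, v) == out
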