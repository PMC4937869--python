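"""Consensus layer: weighted voting, concordance, potency aggregation,
correction rules and the concordance-threshold sweep."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from erconsensus import consensus as cns
from erconsensus.scoring import CALL_ACTIVE, CALL_INACTIVE, CALL_NOT_PREDICTED


# ---------------------------------------------------------------------------
# concordance


@pytest.mark.parametrize(
    "calls, expected",
    [
        (["active", "active", "active", "inactive"], (0.75, 0.25)),
        (["active", "not_predicted", "inactive"], (0.5, 0.5)),
        (["active", "active"], (1.0, 0.0)),
    ],
)
def test_concordance_fractions(calls, expected):
    assert cns.concordance(calls) == pytest.approx(expected)


def test_concordance_requires_a_predicting_model():
    with pytest.raises(ValueError):
        cns.concordance(["not_predicted"])


@given(st.lists(st.sampled_from([CALL_ACTIVE, CALL_INACTIVE, CALL_NOT_PREDICTED]),
                min_size=1, max_size=30))
def test_concordance_pair_sums_to_one(calls):
    if all(c == CALL_NOT_PREDICTED for c in calls):
        return
    a, i = cns.concordance(calls)
    assert a + i == pytest.approx(1.0)
    assert 0.0 <= a <= 1.0


# ---------------------------------------------------------------------------
# categorical consensus (score-weighted vote)


def test_single_dissenter_does_not_override_majority():
    # active sum 0.8 / 3 < inactive sum 1.3 / 3, despite the dissenter's
    # higher individual score
    call = cns.categorical_consensus(
        "x", "binding",
        {"m1": CALL_ACTIVE, "m2": CALL_INACTIVE, "m3": CALL_INACTIVE},
        {"m1": 0.8, "m2": 0.7, "m3": 0.6},
    )
    assert call.call == CALL_INACTIVE
    assert call.avg_score_active == pytest.approx(0.8 / 3)
    assert call.avg_score_inactive == pytest.approx(1.3 / 3)


def test_weighted_majority_wins():
    call = cns.categorical_consensus(
        "x", "binding",
        {"m1": CALL_ACTIVE, "m2": CALL_ACTIVE, "m3": CALL_INACTIVE},
        {"m1": 0.8, "m2": 0.9, "m3": 0.4},
    )
    assert call.call == CALL_ACTIVE
    assert call.concordance_active == pytest.approx(2 / 3)


def test_unanimous_inactive():
    call = cns.categorical_consensus(
        "x", "binding", {"m1": CALL_INACTIVE, "m2": CALL_INACTIVE},
        {"m1": 0.8, "m2": 0.6},
    )
    assert call.call == CALL_INACTIVE
    assert call.concordance_inactive == 1.0


def test_zero_predicting_models():
    call = cns.categorical_consensus(
        "x", "binding", {"m1": CALL_NOT_PREDICTED}, {"m1": 0.8}
    )
    assert call.call == CALL_NOT_PREDICTED and call.n_models == 0


def test_score_tie_resolved_as_active():
    call = cns.categorical_consensus(
        "x", "binding", {"m1": CALL_ACTIVE, "m2": CALL_INACTIVE},
        {"m1": 0.7, "m2": 0.7},
    )
    assert call.call == CALL_ACTIVE


def test_frame_consensus_matches_per_chemical_path():
    rng = np.random.default_rng(21)
    models = [f"m{j}" for j in range(7)]
    score2 = {m: float(rng.uniform(0.5, 0.9)) for m in models}
    chems = [f"c{i}" for i in range(100)]
    raw = rng.integers(0, 3, size=(100, 7))  # 0 inactive, 1 active, 2 missing
    calls_df = pd.DataFrame(
        np.where(raw == 2, np.nan, raw).astype(float), index=chems, columns=models
    )
    frame = cns.categorical_consensus_frame(calls_df, score2, "binding")
    for i, c in enumerate(chems):
        per_model = {
            m: (CALL_NOT_PREDICTED if raw[i, j] == 2
                else CALL_ACTIVE if raw[i, j] == 1 else CALL_INACTIVE)
            for j, m in enumerate(models)
        }
        expected = cns.categorical_consensus(c, "binding", per_model, score2)
        assert frame.loc[c, "call"] == expected.call
        if expected.concordance_active is not None:
            assert frame.loc[c, "concordance_active"] == pytest.approx(
                expected.concordance_active)
            assert frame.loc[c, "avg_score_active"] == pytest.approx(
                expected.avg_score_active)


# ---------------------------------------------------------------------------
# potency consensus


def test_potency_weights_normalize():
    assert cns.potency_weights([0.5, 0.5, 0.5]).w == pytest.approx([1 / 3] * 3)
    assert cns.potency_weights([0.7]).w == pytest.approx([1.0])
    assert cns.potency_weights([0.9, 0.45]).w == pytest.approx([2 / 3, 1 / 3])


def test_potency_weights_zero_scores_fall_back_uniform():
    assert cns.potency_weights([0.0, 0.0]).w == pytest.approx([0.5, 0.5])


@pytest.mark.parametrize(
    "classes, weights, expected_C, expected_class",
    [
        (["weak", "weak"], [0.5, 0.5], 0.5, "weak"),
        (["strong"], [1.0], 1.0, "strong"),
        (["weak", "strong"], [0.5, 0.5], 0.75, "moderate"),
        (["moderate", "strong"], [0.5, 0.5], 0.875, "strong"),  # tie -> potent
        (["inactive", "inactive"], [0.5, 0.5], 0.0, "inactive"),
    ],
)
def test_potency_consensus_weighted_rounding(classes, weights, expected_C,
                                             expected_class):
    out = cns.potency_consensus("x", "binding", classes, weights)
    assert out.C == pytest.approx(expected_C)
    assert out.potency_class == expected_class


def test_potency_consensus_empty_is_not_predicted():
    out = cns.potency_consensus("x", "binding", [], [])
    assert out.potency_class == CALL_NOT_PREDICTED and out.C is None


def test_potency_frame_matches_scalar_path():
    rng = np.random.default_rng(3)
    models = ["a", "b", "c"]
    score2 = {"a": 0.9, "b": 0.6, "c": 0.3}
    scores = [0.0, 0.25, 0.5, 0.75, 1.0]
    frame_rows = {}
    for i in range(50):
        vals = [scores[rng.integers(5)] if rng.random() < 0.8 else np.nan
                for _ in models]
        frame_rows[f"c{i}"] = vals
    cf = pd.DataFrame.from_dict(frame_rows, orient="index", columns=models)
    out = cns.potency_consensus_frame(cf, score2, "binding")
    inv_scores = {v: k for k, v in cns.CLASS_SCORES.items()}
    for c, vals in frame_rows.items():
        present = [(m, v) for m, v in zip(models, vals) if not np.isnan(v)]
        if not present:
            assert out.loc[c, "potency_class"] == CALL_NOT_PREDICTED
            continue
        w = cns.potency_weights([score2[m] for m, _ in present]).w
        expected = cns.potency_consensus(
            c, "binding", [inv_scores[v] for _, v in present], w)
        assert out.loc[c, "potency_class"] == expected.potency_class
        assert out.loc[c, "C"] == pytest.approx(expected.C)


# ---------------------------------------------------------------------------
# concordance -> potency mapping


@pytest.mark.parametrize(
    "conc, expected",
    [
        (0.95, "strong"), (0.9, "strong"),
        (0.8, "moderate"), (0.75, "moderate"),
        (0.7, "weak"), (0.6, "weak"),
        (0.5, "very_weak"), (0.0, "very_weak"),
    ],
)
def test_concordance_to_potency(conc, expected):
    assert cns.concordance_to_potency(conc) == expected


# ---------------------------------------------------------------------------
# correction rules


def consensus_row(call, conc_active, n_active, n_models=10):
    return {
        "activity_type": "binding",
        "call": call,
        "avg_score_active": np.nan,
        "avg_score_inactive": np.nan,
        "concordance_active": conc_active,
        "concordance_inactive": 1 - conc_active,
        "n_models": n_models,
        "n_active_models": n_active,
    }


def frames(cat_rows, pot_classes, atype="binding"):
    cat = pd.DataFrame.from_dict(cat_rows, orient="index")
    cat["activity_type"] = atype
    pot = pd.DataFrame(
        {"activity_type": atype, "potency_class": pd.Series(pot_classes)}
    )
    return {atype: cat}, {atype: pot}


def test_rule1_promotes_categorical_active_with_concordance_potency():
    cat, pot = frames({"x": consensus_row(CALL_ACTIVE, 0.8, 5)}, {"x": "inactive"})
    ccat, cpot, log = cns.apply_corrections(cat, pot)
    assert cpot["binding"].loc["x", "potency_class"] == "moderate"
    assert [(r.rule, r.inchi) for r in log] == [(1, "x")]


def test_rule2_activates_categorical_with_quantitative_support():
    cat, pot = frames({"x": consensus_row(CALL_INACTIVE, 0.4, 4)}, {"x": "weak"})
    ccat, _, log = cns.apply_corrections(cat, pot)
    assert ccat["binding"].loc["x", "call"] == CALL_ACTIVE
    assert [r.rule for r in log] == [2]


def test_rule3_forces_quantitative_inactive_without_support():
    cat, pot = frames({"x": consensus_row(CALL_INACTIVE, 0.2, 2)}, {"x": "strong"})
    _, cpot, log = cns.apply_corrections(cat, pot)
    assert cpot["binding"].loc["x", "potency_class"] == "inactive"
    assert [r.rule for r in log] == [3]


def test_rule4_propagates_agonist_activity_to_binding():
    ag_cat = pd.DataFrame.from_dict(
        {"x": consensus_row(CALL_ACTIVE, 0.9, 6)}, orient="index")
    ag_cat["activity_type"] = "agonist"
    bind_cat = pd.DataFrame.from_dict(
        {"x": consensus_row(CALL_INACTIVE, 0.1, 1)}, orient="index")
    ag_pot = pd.DataFrame({"activity_type": "agonist",
                           "potency_class": pd.Series({"x": "weak"})})
    bind_pot = pd.DataFrame({"activity_type": "binding",
                             "potency_class": pd.Series({"x": "inactive"})})
    ccat, cpot, log = cns.apply_corrections(
        {"agonist": ag_cat, "binding": bind_cat},
        {"agonist": ag_pot, "binding": bind_pot},
    )
    assert ccat["binding"].loc["x", "call"] == CALL_ACTIVE
    assert cpot["binding"].loc["x", "potency_class"] == "weak"
    assert {r.rule for r in log if r.activity_type == "binding"} == {4}


def test_rule4_takes_more_potent_of_both_endpoints():
    def endpoint(atype, potency):
        cat = pd.DataFrame.from_dict(
            {"x": consensus_row(CALL_ACTIVE, 0.95, 6)}, orient="index")
        cat["activity_type"] = atype
        pot = pd.DataFrame({"activity_type": atype,
                            "potency_class": pd.Series({"x": potency})})
        return cat, pot

    ag_cat, ag_pot = endpoint("agonist", "weak")
    ant_cat, ant_pot = endpoint("antagonist", "strong")
    bind_cat = pd.DataFrame.from_dict(
        {"x": consensus_row(CALL_INACTIVE, 0.0, 0)}, orient="index")
    bind_cat["activity_type"] = "binding"
    ccat, cpot, _ = cns.apply_corrections(
        {"agonist": ag_cat, "antagonist": ant_cat, "binding": bind_cat},
        {"agonist": ag_pot, "antagonist": ant_pot},
    )
    assert cpot["binding"].loc["x", "potency_class"] == "strong"
    assert ccat["binding"].loc["x", "call"] == CALL_ACTIVE


def test_corrections_are_idempotent_on_microcases():
    cat, pot = frames(
        {
            "a": consensus_row(CALL_ACTIVE, 0.8, 5),
            "b": consensus_row(CALL_INACTIVE, 0.4, 4),
            "c": consensus_row(CALL_INACTIVE, 0.2, 2),
            "d": consensus_row(CALL_ACTIVE, 0.95, 2),  # active but unsupported
        },
        {"a": "inactive", "b": "weak", "c": "strong", "d": "inactive"},
    )
    ccat, cpot, log1 = cns.apply_corrections(cat, pot)
    _, _, log2 = cns.apply_corrections(ccat, cpot)
    assert log1 and not log2


# ---------------------------------------------------------------------------
# threshold sweep


@pytest.fixture()
def sweep_inputs():
    rng = np.random.default_rng(17)
    n = 300
    chems = [f"c{i}" for i in range(n)]
    n_active_models = rng.integers(0, 11, n)
    conc = np.where(n_active_models > 0, n_active_models / 10.0, np.nan)
    frame = pd.DataFrame(
        {"concordance_active": conc, "n_active_models": n_active_models},
        index=chems,
    )
    reference = {c: bool(rng.random() < 0.3) for c in chems}
    counts = {c: int(rng.integers(1, 9)) for c in chems}
    return frame, reference, counts


def test_sweep_boundary_thresholds(sweep_inputs):
    frame, reference, counts = sweep_inputs
    out = cns.threshold_sweep(frame, reference, [0.0, 1.0], counts, strata=[1])
    at0 = out[out.threshold == 0.0].iloc[0]
    at1 = out[out.threshold == 1.0].iloc[0]
    n_any_active = int((frame["n_active_models"] >= 1).sum())
    n_unanimous = int((frame["concordance_active"] == 1.0).sum())
    assert at0["n_active"] == n_any_active
    assert at1["n_active"] == n_unanimous


def test_sweep_counts_monotone_non_increasing(sweep_inputs):
    frame, reference, counts = sweep_inputs
    grid = [i / 20 for i in range(21)]
    out = cns.threshold_sweep(frame, reference, grid, counts, strata=[1, 3])
    for stratum, group in out.groupby("stratum"):
        counts_by_t = group.sort_values("threshold")["n_active"].to_numpy()
        assert (np.diff(counts_by_t) <= 0).all()
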