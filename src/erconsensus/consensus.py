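"""Score-weighted consensus of model predictions, with consistency corrections.

The categorical consensus for a chemical is a score-weighted vote: the
``score_2`` values of the models calling it active and of those calling it
inactive are each summed and normalized by the number of predicting models,
and the larger average wins (ties go to active, since the exercise is a
prioritization screen and false negatives are the costly error).  The two
averages therefore track the active/inactive concordances -- the active
average is high exactly when many (good) models agree on active -- and sum
to the mean model score.  Concordance is the fraction of predicting models
on each side; active and inactive concordance sum to 1.

The potency (quantitative) consensus weights each continuous model's
predicted potency class ``P_j`` by its normalized score and rounds the
weighted class score ``C = sum_j w_j s(P_j)`` to the nearest class, ties
toward the more potent class.

Four correction rules reconcile the categorical and quantitative layers and
the three activity classes (agonist/antagonist first, binding last):

1. categorically active chemicals become quantitatively active, with a
   potency class read off the active-model concordance;
2. quantitatively active chemicals with at least three active categorical
   calls become categorically active;
3. chemicals with fewer than three active categorical calls are forced
   quantitatively inactive;
4. an active agonist or antagonist becomes an active binder, inheriting the
   (more potent, if both) agonist/antagonist potency class.

A single pass reaches the fixed point: rule 1 only promotes chemicals rule 3
would not immediately demote, and binding rules 1/3 defer to rule 4 where it
applies, so reapplying the corrections changes nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from erconsensus.reference import CLASS_SCORES, POTENCY_CLASSES
from erconsensus.scoring import (
    CALL_ACTIVE,
    CALL_INACTIVE,
    CALL_NOT_PREDICTED,
    PredictionSet,
)

logger = logging.getLogger(__name__)

#: Minimum number of active categorical calls for rules 2 and 3.
MIN_ACTIVE_MODELS = 3

_EPS = 1e-9


@dataclass
class ConsensusCall:
    inchi: str
    activity_type: str
    call: str  # active | inactive | not_predicted
    avg_score_active: float | None
    avg_score_inactive: float | None
    concordance_active: float | None
    concordance_inactive: float | None
    n_models: int = 0
    n_active_models: int = 0


@dataclass
class PotencyWeightVector:
    model_ids: list[str]
    w: np.ndarray
    scores: np.ndarray


@dataclass
class ConsensusPotency:
    inchi: str
    activity_type: str
    C: float | None  # weighted class score in [0, 1]
    P: list[str] = field(default_factory=list)  # contributing predicted classes
    potency_class: str = "inactive"


@dataclass
class CorrectionRecord:
    inchi: str
    activity_type: str
    rule: int
    before: str
    after: str


# ---------------------------------------------------------------------------
# categorical consensus


def concordance(calls: Iterable[str]) -> tuple[float, float]:
    """Fractions of predicting models calling active vs inactive (sum 1)."""
    calls = [c for c in calls if c != CALL_NOT_PREDICTED]
    if not calls:
        raise ValueError("no predicting models")
    n_active = sum(1 for c in calls if c == CALL_ACTIVE)
    c_act = n_active / len(calls)
    return c_act, 1.0 - c_act


def categorical_consensus(
    inchi: str,
    activity_type: str,
    calls: Mapping[str, str],
    score2: Mapping[str, float],
) -> ConsensusCall:
    """Higher-average classification of one chemical from per-model calls.

    Each side's average is the sum of its callers' scores over the number
    of predicting models, so it scales with both model quality and
    concordance; with equal scores the vote reduces to simple majority.
    """
    predicting = {m: c for m, c in calls.items() if c != CALL_NOT_PREDICTED}
    if not predicting:
        return ConsensusCall(inchi, activity_type, CALL_NOT_PREDICTED,
                             None, None, None, None, 0, 0)
    n = len(predicting)
    active_scores = [score2[m] for m, c in predicting.items() if c == CALL_ACTIVE]
    inactive_scores = [score2[m] for m, c in predicting.items() if c == CALL_INACTIVE]
    avg_a = sum(active_scores) / n
    avg_i = sum(inactive_scores) / n
    if not active_scores:
        call = CALL_INACTIVE
    elif not inactive_scores:
        call = CALL_ACTIVE
    else:  # tie resolved as active (prioritization errs against false negatives)
        call = CALL_ACTIVE if avg_a >= avg_i else CALL_INACTIVE
    c_act, c_inact = concordance(predicting.values())
    return ConsensusCall(
        inchi, activity_type, call, avg_a, avg_i, c_act, c_inact,
        n_models=n, n_active_models=len(active_scores),
    )


def call_matrix(preds: Sequence[PredictionSet]) -> pd.DataFrame:
    """Per-model calls as a float frame: 1 active, 0 inactive, NaN missing."""
    cols = {}
    for p in preds:
        s = pd.Series(
            {k: (1.0 if v == CALL_ACTIVE else 0.0)
             for k, v in p.calls.items() if v != CALL_NOT_PREDICTED},
            dtype=float,
        )
        cols[p.model_id] = s
    return pd.DataFrame(cols)


def categorical_consensus_frame(
    calls: pd.DataFrame, score2: Mapping[str, float], activity_type: str
) -> pd.DataFrame:
    """Vectorized categorical consensus over a call matrix.

    ``calls`` has one row per chemical (index = InChI) and one column per
    model, values 1/0/NaN.  Returns one row per chemical with the consensus
    call, score averages, concordances and predicting-model counts.
    """
    s = np.array([score2[m] for m in calls.columns], dtype=float)
    a = (calls == 1.0).to_numpy()
    i = (calls == 0.0).to_numpy()
    n_a = a.sum(axis=1)
    n_i = i.sum(axis=1)
    n = n_a + n_i
    with np.errstate(invalid="ignore", divide="ignore"):
        avg_a = np.where(n > 0, a @ s / np.maximum(n, 1), np.nan)
        avg_i = np.where(n > 0, i @ s / np.maximum(n, 1), np.nan)
        c_act = np.where(n > 0, n_a / np.maximum(n, 1), np.nan)
    call = np.where(
        n == 0,
        CALL_NOT_PREDICTED,
        np.where(
            (n_a > 0) & ((n_i == 0) | (np.nan_to_num(avg_a, nan=-1.0)
                                       >= np.nan_to_num(avg_i, nan=-1.0))),
            CALL_ACTIVE,
            CALL_INACTIVE,
        ),
    )
    return pd.DataFrame(
        {
            "activity_type": activity_type,
            "call": call,
            "avg_score_active": avg_a,
            "avg_score_inactive": avg_i,
            "concordance_active": c_act,
            "concordance_inactive": 1.0 - c_act,
            "n_models": n,
            "n_active_models": n_a,
        },
        index=calls.index,
    )


# ---------------------------------------------------------------------------
# potency consensus


def potency_weights(
    scores: Sequence[float], model_ids: Sequence[str] | None = None
) -> PotencyWeightVector:
    """Weights proportional to model scores, normalized to sum to 1."""
    if len(scores) == 0:
        raise ValueError("need at least one model")
    arr = np.asarray(scores, dtype=float)
    if np.any(arr < 0):
        raise ValueError("scores must be non-negative")
    total = arr.sum()
    if total <= 0:
        logger.warning("all model scores are zero; falling back to uniform weights")
        w = np.full(len(arr), 1.0 / len(arr))
    else:
        w = arr / total
    ids = list(model_ids) if model_ids is not None else [str(j) for j in range(len(arr))]
    return PotencyWeightVector(model_ids=ids, w=w, scores=arr)


def round_class_score(c: float) -> str:
    """Nearest potency class to a score in [0, 1]; ties toward more potent."""
    best = "inactive"
    best_dist = float("inf")
    for cls in reversed(POTENCY_CLASSES):  # most potent first wins ties
        d = abs(c - CLASS_SCORES[cls])
        if d < best_dist - _EPS:
            best, best_dist = cls, d
    return best


def potency_consensus(
    inchi: str,
    activity_type: str,
    predicted_classes: Sequence[str],
    weights: Sequence[float],
) -> ConsensusPotency:
    """Weighted class-score consensus potency level."""
    if len(predicted_classes) != len(weights):
        raise ValueError("classes and weights must align")
    if not predicted_classes:
        return ConsensusPotency(inchi, activity_type, None, [], CALL_NOT_PREDICTED)
    c = float(
        sum(w * CLASS_SCORES[p] for w, p in zip(weights, predicted_classes))
    )
    return ConsensusPotency(inchi, activity_type, c, list(predicted_classes),
                            round_class_score(c))


def potency_consensus_frame(
    class_frame: pd.DataFrame, score2: Mapping[str, float], activity_type: str
) -> pd.DataFrame:
    """Vectorized potency consensus.

    ``class_frame``: one row per chemical, one column per continuous model,
    values are class scores in {0, .25, .5, .75, 1} or NaN when the model
    did not predict the chemical.  Weights renormalize over the predicting
    models of each chemical.
    """
    s = np.array([score2[m] for m in class_frame.columns], dtype=float)
    mask = class_frame.notna().to_numpy()
    vals = class_frame.fillna(0.0).to_numpy()
    denom = mask @ s
    with np.errstate(invalid="ignore", divide="ignore"):
        c = (vals * mask) @ s / denom
    cls = [round_class_score(x) if np.isfinite(x) else CALL_NOT_PREDICTED for x in c]
    return pd.DataFrame(
        {
            "activity_type": activity_type,
            "C": c,
            "potency_class": cls,
            "n_models": mask.sum(axis=1),
        },
        index=class_frame.index,
    )


# ---------------------------------------------------------------------------
# concordance -> potency mapping and corrections


def concordance_to_potency(concordance_active: float) -> str:
    """Potency class implied by active-model concordance (rule-1 potencies)."""
    if not 0.0 <= concordance_active <= 1.0:
        raise ValueError("concordance must lie in [0, 1]")
    if concordance_active >= 0.9:
        return "strong"
    if concordance_active >= 0.75:
        return "moderate"
    if concordance_active >= 0.6:
        return "weak"
    return "very_weak"


_MISSING_POTENCY = (CALL_NOT_PREDICTED, None)


def _more_potent(a: str, b: str) -> str:
    return a if POTENCY_CLASSES.index(a) >= POTENCY_CLASSES.index(b) else b


def apply_corrections(
    categorical: Mapping[str, pd.DataFrame],
    potency: Mapping[str, pd.DataFrame],
    min_active_models: int = MIN_ACTIVE_MODELS,
) -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame], list[CorrectionRecord]]:
    """Apply the four correction rules; agonist and antagonist first.

    ``categorical[atype]`` is a consensus frame (``categorical_consensus_frame``
    output); ``potency[atype]`` a potency frame with a ``potency_class``
    column (missing chemicals count as quantitatively not predicted).
    Returns corrected copies of both layers plus a log with one record per
    state change.  The pass is idempotent: corrections applied to corrected
    output produce an empty log.
    """
    cat = {t: df.copy() for t, df in categorical.items()}
    pot: dict[str, pd.DataFrame] = {}
    log: list[CorrectionRecord] = []

    for atype, cdf in cat.items():
        pdf = potency.get(atype)
        pdf = pdf.copy() if pdf is not None else pd.DataFrame(columns=["potency_class"])
        pdf = pdf.reindex(cdf.index.union(pdf.index))
        pdf["potency_class"] = pdf["potency_class"].fillna(CALL_NOT_PREDICTED)
        if "activity_type" in pdf.columns:
            pdf["activity_type"] = atype
        pot[atype] = pdf

    def pclass(atype: str, inchi: str) -> str:
        v = pot[atype]["potency_class"].get(inchi, CALL_NOT_PREDICTED)
        return v if isinstance(v, str) else CALL_NOT_PREDICTED

    def quant_active(atype: str, inchi: str) -> bool:
        return pclass(atype, inchi) not in ("inactive",) + _MISSING_POTENCY

    def set_pclass(atype: str, inchi: str, new: str, rule: int) -> None:
        old = pclass(atype, inchi)
        if old != new:
            pot[atype].loc[inchi, "potency_class"] = new
            log.append(CorrectionRecord(inchi, atype, rule, f"quant:{old}", f"quant:{new}"))

    def set_call(atype: str, inchi: str, new: str, rule: int) -> None:
        old = cat[atype].loc[inchi, "call"]
        if old != new:
            cat[atype].loc[inchi, "call"] = new
            log.append(CorrectionRecord(inchi, atype, rule, f"cat:{old}", f"cat:{new}"))

    def correct_endpoint(atype: str, skip: set[str]) -> None:
        cdf = cat[atype]
        for inchi in cdf.index:
            reliable = cdf.loc[inchi, "n_active_models"] >= min_active_models
            is_cat_active = cdf.loc[inchi, "call"] == CALL_ACTIVE
            in_skip = inchi in skip
            # rule 1: categorical active => quantitative active
            if (is_cat_active and not quant_active(atype, inchi)
                    and reliable and not in_skip):
                set_pclass(
                    atype, inchi,
                    concordance_to_potency(float(cdf.loc[inchi, "concordance_active"])),
                    rule=1,
                )
            # rule 2: quantitative active with enough categorical support
            if quant_active(atype, inchi) and reliable and not is_cat_active:
                set_call(atype, inchi, CALL_ACTIVE, rule=2)
            # rule 3: too few active categorical calls => quantitative inactive
            if quant_active(atype, inchi) and not reliable and not in_skip:
                set_pclass(atype, inchi, "inactive", rule=3)

    for atype in ("agonist", "antagonist"):
        if atype in cat:
            correct_endpoint(atype, skip=set())

    if "binding" in cat:
        # rule 4 overrides binding potency wherever an agonist/antagonist is
        # active, so rules 1/3 skip those chemicals (the net state matches a
        # literal rule-1..4 sequence; only log churn is avoided)
        rule4_src: dict[str, str] = {}
        for atype in ("agonist", "antagonist"):
            if atype not in cat:
                continue
            active_idx = cat[atype].index[cat[atype]["call"] == CALL_ACTIVE]
            for inchi in active_idx:
                p = pclass(atype, inchi)
                p = p if p not in _MISSING_POTENCY else "inactive"
                rule4_src[inchi] = (
                    _more_potent(rule4_src[inchi], p) if inchi in rule4_src else p
                )
        correct_endpoint("binding", skip=set(rule4_src))
        bdf = cat["binding"]
        for inchi, src_potency in rule4_src.items():
            if inchi not in bdf.index:
                continue
            if bdf.loc[inchi, "call"] != CALL_ACTIVE:
                set_call("binding", inchi, CALL_ACTIVE, rule=4)
            if pclass("binding", inchi) != src_potency:
                set_pclass("binding", inchi, src_potency, rule=4)

    return cat, pot, log


# ---------------------------------------------------------------------------
# concordance-threshold sweep (potential actives)


def threshold_sweep(
    consensus_frame: pd.DataFrame,
    reference: Mapping[str, bool],
    thresholds: Sequence[float],
    source_counts: Mapping[str, int] | None = None,
    strata: Sequence[int] = (1,),
) -> pd.DataFrame:
    """Potential-active counts and accuracy across concordance thresholds.

    A chemical is a potential active at threshold ``t`` when at least one
    model called it active and its active concordance is >= t.  Metrics are
    computed against ``reference`` within each source-count stratum
    (chemicals with at least ``stratum`` literature sources); pass
    ``source_counts=None`` with ``strata=(1,)`` for an unstratified sweep.
    """
    idx = consensus_frame.index
    conc = consensus_frame["concordance_active"].to_numpy(dtype=float)
    n_act = consensus_frame["n_active_models"].to_numpy(dtype=float)
    ref_keys = [k for k in idx if k in reference]
    ref_mask = np.array([k in reference for k in idx])
    truth = np.array([bool(reference[k]) for k in ref_keys])
    counts = (
        np.array([source_counts.get(k, 0) for k in ref_keys])
        if source_counts is not None
        else np.ones(len(ref_keys), dtype=int)
    )
    rows = []
    for t in thresholds:
        potential = (n_act >= 1) & (np.nan_to_num(conc, nan=-1.0) >= t)
        pot_ref = potential[ref_mask]
        for stratum in strata:
            in_stratum = counts >= stratum
            p, y = pot_ref[in_stratum], truth[in_stratum]
            tp = int(np.sum(p & y))
            fn = int(np.sum(~p & y))
            fp = int(np.sum(p & ~y))
            tn = int(np.sum(~p & ~y))
            sens = tp / (tp + fn) if tp + fn else np.nan
            spec = tn / (fp + tn) if fp + tn else np.nan
            rows.append(
                {
                    "threshold": t,
                    "stratum": stratum,
                    "n_chemicals": int(in_stratum.sum()),
                    "n_active": int(p.sum()),
                    "sensitivity": sens,
                    "specificity": spec,
                    "balanced_accuracy": (sens + spec) / 2,
                }
            )
    return pd.DataFrame(rows)
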