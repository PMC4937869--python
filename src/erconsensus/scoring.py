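"""Per-model evaluation: confusion matrices, balanced accuracy, summary scores.

Every prediction model (categorical or continuous, for binding, agonist or
antagonist activity) is evaluated on six chemical subsets:

1. the HTS training chemicals, excluding those whose activity (AUC) score
   falls in the ambiguous 0.01-0.1 band;
2. all literature-reference chemicals;
3. literature chemicals with at least two sources;
4. literature chemicals excluding very-weak actives;
5. literature chemicals inside the model's applicability domain (equals 2
   when the model supplied no AD);
6. the intersection of 3, 4 and 5 ("all filters").

Two summary scores are derived from the subset balanced accuracies (BA):
``score_1`` weights each literature-subset BA by the model's coverage of
that subset and by its coverage of the full prediction universe (favoring
wide-AD models); ``score_2`` is the mean of the HTS BA and the all-filters
BA (favoring accuracy over coverage).  Undefined metrics (an empty margin)
are reported as ``None``, never coerced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from erconsensus.reference import (
    CategoricalReference,
    PotencyReference,
    PotencyThresholds,
    DEFAULT_THRESHOLDS,
    POTENCY_CLASSES,
    classify_potency,
)

logger = logging.getLogger(__name__)

SUBSET_IDS = (
    "toxcast",
    "lit_all",
    "lit_min2src",
    "lit_no_veryweak",
    "lit_in_ad",
    "lit_all_filters",
)
LITERATURE_SUBSETS = SUBSET_IDS[1:]
N_FILTERS = 5  # the five literature evaluation steps entering score_1

AUC_ACTIVE_THRESHOLD = 0.01
AUC_AMBIGUOUS_BAND = (0.01, 0.1)  # [low, high) excluded from the HTS subset

CALL_ACTIVE = "active"
CALL_INACTIVE = "inactive"
CALL_NOT_PREDICTED = "not_predicted"


@dataclass
class PredictionSet:
    """One model's calls over the prediction universe."""

    model_id: str
    activity_type: str
    calls: dict[str, str]  # inchi -> active | inactive | not_predicted
    in_ad: dict[str, bool] | None = None
    potency_uM: dict[str, float] | None = None
    is_continuous: bool = False

    def predicted_keys(self) -> set[str]:
        return {k for k, v in self.calls.items() if v != CALL_NOT_PREDICTED}


@dataclass
class ConfusionMatrix:
    tp: int = 0
    fn: int = 0
    fp: int = 0
    tn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class Metrics:
    sensitivity: float | None
    specificity: float | None
    balanced_accuracy: float | None


@dataclass
class SubsetEvaluation:
    subset_id: str
    confusion: ConfusionMatrix
    sensitivity: float | None
    specificity: float | None
    balanced_accuracy: float | None
    n_pred_in_subset: int
    n_subset: int


@dataclass
class ModelScore:
    model_id: str
    activity_type: str
    subset_evals: dict[str, SubsetEvaluation]
    n_pred: int
    n_total: int
    n_filters: int = N_FILTERS
    score_1: float | None = None
    score_2: float | None = None
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# confusion matrices and metrics


def confusion_matrix(
    calls: Mapping[str, str], reference: Mapping[str, bool]
) -> ConfusionMatrix:
    """Count calls against a boolean reference over the shared key space.

    ``not_predicted`` calls and chemicals absent from either side are
    excluded; an empty intersection yields an all-zero (flagged) matrix.
    """
    cm = ConfusionMatrix()
    for key, truth in reference.items():
        call = calls.get(key, CALL_NOT_PREDICTED)
        if call == CALL_NOT_PREDICTED:
            continue
        predicted_active = call == CALL_ACTIVE
        if truth and predicted_active:
            cm.tp += 1
        elif truth:
            cm.fn += 1
        elif predicted_active:
            cm.fp += 1
        else:
            cm.tn += 1
    if cm.total == 0:
        logger.debug("empty confusion matrix (no overlap)")
    return cm


def classification_metrics(cm: ConfusionMatrix) -> Metrics:
    """Sensitivity, specificity and their mean (balanced accuracy).

    A zero margin leaves the corresponding metric (and the BA) undefined.
    """
    sens = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) > 0 else None
    spec = cm.tn / (cm.fp + cm.tn) if (cm.fp + cm.tn) > 0 else None
    ba = (sens + spec) / 2 if sens is not None and spec is not None else None
    return Metrics(sens, spec, ba)


# ---------------------------------------------------------------------------
# training (HTS) reference


def training_reference(
    training: pd.DataFrame,
    activity_type: str,
    active_threshold: float = AUC_ACTIVE_THRESHOLD,
    ambiguous_band: tuple[float, float] = AUC_AMBIGUOUS_BAND,
) -> dict[str, bool]:
    """Binary HTS reference from AUC activity scores.

    A chemical is active when its activity-type-relevant AUC exceeds the
    threshold; chemicals with AUC inside the ambiguous band [low, high) are
    excluded entirely.
    """
    col = f"auc_{activity_type}"
    lo, hi = ambiguous_band
    out: dict[str, bool] = {}
    for inchi, auc in zip(training["inchi"], training[col]):
        if lo <= auc < hi:
            continue
        out[str(inchi)] = bool(auc > active_threshold)
    return out


# ---------------------------------------------------------------------------
# the six evaluation subsets


def build_evaluation_subsets(
    categorical_ref: Sequence[CategoricalReference],
    potency_ref: Sequence[PotencyReference],
    training: pd.DataFrame,
    pred: PredictionSet,
    min_sources: int = 2,
) -> dict[str, dict[str, bool]]:
    """Reference labels for each of the six subsets, for one model.

    Returns ``subset_id -> {inchi: active}``.  Subset 1 labels come from the
    HTS AUC scores; subsets 2-6 from the literature categorical reference of
    the model's activity type.
    """
    atype = pred.activity_type
    lit = {r.inchi: r for r in categorical_ref if r.activity_type == atype}
    potency = {r.inchi: r for r in potency_ref if r.activity_type == atype}

    toxcast = training_reference(training, atype)
    lit_all = {inchi: r.active for inchi, r in lit.items()}
    lit_min2 = {i: a for i, a in lit_all.items()
                if lit[i].n_sources >= min_sources}
    lit_no_vw = {
        i: a for i, a in lit_all.items()
        if not (a and i in potency and potency[i].potency_class == "very_weak")
    }
    if pred.in_ad is not None:
        lit_ad = {i: a for i, a in lit_all.items() if pred.in_ad.get(i, False)}
    else:
        lit_ad = dict(lit_all)
    lit_filters = {
        i: a for i, a in lit_all.items()
        if i in lit_min2 and i in lit_no_vw and i in lit_ad
    }
    return {
        "toxcast": toxcast,
        "lit_all": lit_all,
        "lit_min2src": lit_min2,
        "lit_no_veryweak": lit_no_vw,
        "lit_in_ad": lit_ad,
        "lit_all_filters": lit_filters,
    }


# ---------------------------------------------------------------------------
# summary scores


def score_1(
    subset_evals: Mapping[str, SubsetEvaluation],
    n_pred: int,
    n_total: int,
    n_filters: int = N_FILTERS,
) -> float:
    """Coverage-weighted literature-BA summary (favors wide-AD models).

    score_1 = (N_pred / N_total) * (1 / n_filters)
              * sum over literature subsets of BA_i * (n_pred_i / n_i).

    A subset with an undefined BA (or no chemicals) contributes 0.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    acc = 0.0
    for sid in LITERATURE_SUBSETS:
        ev = subset_evals[sid]
        if ev.balanced_accuracy is None or ev.n_subset == 0:
            logger.debug("subset %s contributes 0 to score_1", sid)
            continue
        acc += ev.balanced_accuracy * ev.n_pred_in_subset / ev.n_subset
    return (n_pred / n_total) * acc / n_filters


def score_2(ba_toxcast: float | None, ba_all_filters: float | None) -> float | None:
    """Mean of the HTS BA and the all-filters literature BA."""
    if ba_toxcast is None or ba_all_filters is None:
        return None
    return (ba_toxcast + ba_all_filters) / 2


# ---------------------------------------------------------------------------
# full per-model evaluation


def _evaluate_subset(
    pred: PredictionSet, subset_id: str, reference: dict[str, bool]
) -> SubsetEvaluation:
    cm = confusion_matrix(pred.calls, reference)
    m = classification_metrics(cm)
    return SubsetEvaluation(
        subset_id=subset_id,
        confusion=cm,
        sensitivity=m.sensitivity,
        specificity=m.specificity,
        balanced_accuracy=m.balanced_accuracy,
        n_pred_in_subset=cm.total,
        n_subset=len(reference),
    )


def evaluate_categorical(
    pred: PredictionSet,
    categorical_ref: Sequence[CategoricalReference],
    potency_ref: Sequence[PotencyReference],
    training: pd.DataFrame,
    n_total: int,
) -> ModelScore:
    """Evaluate a categorical model on the six subsets and derive scores."""
    subsets = build_evaluation_subsets(categorical_ref, potency_ref, training, pred)
    evals = {sid: _evaluate_subset(pred, sid, ref) for sid, ref in subsets.items()}
    ms = ModelScore(
        model_id=pred.model_id,
        activity_type=pred.activity_type,
        subset_evals=evals,
        n_pred=len(pred.predicted_keys()),
        n_total=n_total,
    )
    ms.score_1 = score_1(evals, ms.n_pred, n_total)
    ms.score_2 = score_2(
        evals["toxcast"].balanced_accuracy,
        evals["lit_all_filters"].balanced_accuracy,
    )
    if ms.score_2 is None:
        ms.warnings.append("score_2 undefined; model excluded from consensus")
    return ms


def _predicted_classes(
    pred: PredictionSet, thresholds: PotencyThresholds
) -> tuple[dict[str, str], list[str]]:
    """Map a continuous model's output to potency classes."""
    classes: dict[str, str] = {}
    warnings: list[str] = []
    potency = pred.potency_uM or {}
    for inchi, call in pred.calls.items():
        if call == CALL_NOT_PREDICTED:
            continue
        if call == CALL_INACTIVE:
            classes[inchi] = "inactive"
            continue
        conc = potency.get(inchi)
        if conc is None:
            warnings.append(f"{inchi}: active call without potency, skipped")
            continue
        classes[inchi] = classify_potency(conc, thresholds)
    return classes, warnings


def multiclass_balanced_accuracy(
    predicted: Mapping[str, str], reference: Mapping[str, str]
) -> float | None:
    """Unweighted mean of the five one-vs-rest BAs over the shared keys.

    Classes absent from the reference (undefined one-vs-rest sensitivity)
    are skipped rather than coerced; returns ``None`` when no class has a
    defined BA.
    """
    keys = [k for k in reference if k in predicted]
    if not keys:
        return None
    bas = []
    for cls in POTENCY_CLASSES:
        cm = ConfusionMatrix()
        for k in keys:
            truth = reference[k] == cls
            called = predicted[k] == cls
            if truth and called:
                cm.tp += 1
            elif truth:
                cm.fn += 1
            elif called:
                cm.fp += 1
            else:
                cm.tn += 1
        ba = classification_metrics(cm).balanced_accuracy
        if ba is not None:
            bas.append(ba)
    return sum(bas) / len(bas) if bas else None


def evaluate_continuous(
    pred: PredictionSet,
    categorical_ref: Sequence[CategoricalReference],
    potency_ref: Sequence[PotencyReference],
    training: pd.DataFrame,
    n_total: int,
    thresholds: PotencyThresholds = DEFAULT_THRESHOLDS,
) -> ModelScore:
    """Evaluate a continuous model as a five-class categorical model.

    Predicted concentrations are binned into the five potency classes; each
    literature subset's BA is the unweighted mean of the per-class
    one-vs-rest BAs.  On the HTS subset, where only a binary activity label
    exists, the model is scored on active = any non-inactive class.
    score_2 applies as for categorical models.
    """
    if not pred.is_continuous:
        raise ValueError("model is not continuous")
    atype = pred.activity_type
    classes, warns = _predicted_classes(pred, thresholds)
    ref_classes = {
        r.inchi: r.potency_class for r in potency_ref if r.activity_type == atype
    }
    binary_calls = {
        k: (CALL_ACTIVE if c != "inactive" else CALL_INACTIVE)
        for k, c in classes.items()
    }
    binary_pred = PredictionSet(pred.model_id, atype, binary_calls)
    subsets = build_evaluation_subsets(categorical_ref, potency_ref, training, pred)

    evals: dict[str, SubsetEvaluation] = {}
    evals["toxcast"] = _evaluate_subset(binary_pred, "toxcast", subsets["toxcast"])
    for sid in LITERATURE_SUBSETS:
        keys = set(subsets[sid]) & set(ref_classes)
        sub_ref = {k: ref_classes[k] for k in keys}
        ba = multiclass_balanced_accuracy(classes, sub_ref)
        n_pred_in = sum(1 for k in sub_ref if k in classes)
        evals[sid] = SubsetEvaluation(
            subset_id=sid,
            confusion=ConfusionMatrix(),
            sensitivity=None,
            specificity=None,
            balanced_accuracy=ba,
            n_pred_in_subset=n_pred_in,
            n_subset=len(sub_ref),
        )
    ms = ModelScore(
        model_id=pred.model_id,
        activity_type=atype,
        subset_evals=evals,
        n_pred=len(classes),
        n_total=n_total,
        warnings=warns,
    )
    ms.score_1 = score_1(evals, ms.n_pred, n_total)
    ms.score_2 = score_2(
        evals["toxcast"].balanced_accuracy,
        evals["lit_all_filters"].balanced_accuracy,
    )
    return ms


def evaluate_models(
    preds: Iterable[PredictionSet],
    categorical_ref: Sequence[CategoricalReference],
    potency_ref: Sequence[PotencyReference],
    training: pd.DataFrame,
    n_total: int,
) -> list[ModelScore]:
    out = []
    for pred in preds:
        if pred.is_continuous:
            out.append(evaluate_continuous(pred, categorical_ref, potency_ref,
                                           training, n_total))
        else:
            out.append(evaluate_categorical(pred, categorical_ref, potency_ref,
                                            training, n_total))
    return out


def scores_table(model_scores: Sequence[ModelScore]) -> pd.DataFrame:
    """Per-model score table: subset BAs, coverage, score_1, score_2."""
    rows = []
    for ms in model_scores:
        row: dict = {
            "model_id": ms.model_id,
            "activity_type": ms.activity_type,
            "n_pred": ms.n_pred,
            "n_total": ms.n_total,
        }
        for sid, ev in ms.subset_evals.items():
            row[f"ba_{sid}"] = ev.balanced_accuracy
        row["score_1"] = ms.score_1
        row["score_2"] = ms.score_2
        rows.append(row)
    return pd.DataFrame(rows)
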