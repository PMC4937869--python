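"""End-to-end orchestration: simulate/load, build references, score models,
build the consensus, correct it, sweep thresholds, and report.

A run writes one directory of delimited text outputs, each stamped (in
``report.json``) with the config hash and master seed; reruns of an
identical config are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from erconsensus import consensus as cns
from erconsensus import reference as ref
from erconsensus import scoring as sc
from erconsensus import simulate as sim
from erconsensus.config import RunConfig

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message points at the offending stage."""


# ---------------------------------------------------------------------------
# loading externally supplied tables (used when simulation is off)


def read_predictions(path: str | Path) -> list[sc.PredictionSet]:
    """Read prediction tables from a directory of TSV files.

    Each file carries columns ``model_id, activity_type, inchi, call``
    (1/0/NA) and optional ``in_ad`` (1/0/NA) and ``potency_uM`` columns.
    """
    path = Path(path)
    if not path.is_dir():
        raise PipelineError(f"prediction directory not found: {path}")
    preds: dict[tuple[str, str], sc.PredictionSet] = {}
    for file in sorted(path.glob("*.tsv")):
        df = pd.read_csv(file, sep="\t")
        for (model_id, atype), group in df.groupby(["model_id", "activity_type"]):
            calls: dict[str, str] = {}
            in_ad: dict[str, bool] = {}
            potency: dict[str, float] = {}
            has_ad = "in_ad" in group.columns and group["in_ad"].notna().any()
            has_pot = "potency_uM" in group.columns and group["potency_uM"].notna().any()
            for row in group.itertuples(index=False):
                call = getattr(row, "call")
                if pd.isna(call):
                    continue
                calls[row.inchi] = sc.CALL_ACTIVE if int(call) == 1 else sc.CALL_INACTIVE
                if has_ad and not pd.isna(getattr(row, "in_ad", None)):
                    in_ad[row.inchi] = bool(int(row.in_ad))
                if has_pot and not pd.isna(getattr(row, "potency_uM", None)):
                    potency[row.inchi] = float(row.potency_uM)
            preds[(model_id, atype)] = sc.PredictionSet(
                model_id=model_id,
                activity_type=atype,
                calls=calls,
                in_ad=in_ad if has_ad else None,
                potency_uM=potency if has_pot else None,
                is_continuous=has_pot,
            )
    return list(preds.values())


def write_predictions(preds: Sequence[sc.PredictionSet], path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for p in preds:
        rows = []
        for inchi, call in sorted(p.calls.items()):
            rows.append({
                "model_id": p.model_id,
                "activity_type": p.activity_type,
                "inchi": inchi,
                "call": 1 if call == sc.CALL_ACTIVE else 0,
                "in_ad": (int(p.in_ad[inchi]) if p.in_ad and inchi in p.in_ad else None),
                "potency_uM": (p.potency_uM.get(inchi) if p.potency_uM else None),
            })
        pd.DataFrame(rows).to_csv(path / f"{p.model_id}.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# consensus helpers


def _usable_scores(model_scores: Sequence[sc.ModelScore]) -> dict[str, float]:
    out = {}
    for ms in model_scores:
        if ms.score_2 is None:
            logger.warning("model %s has undefined score_2; excluded from consensus",
                           ms.model_id)
            continue
        out[ms.model_id] = ms.score_2
    return out


def class_score_matrix(
    preds: Sequence[sc.PredictionSet],
    thresholds: ref.PotencyThresholds = ref.DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Predicted potency-class scores of continuous models (NaN = no call)."""
    cols = {}
    for p in preds:
        classes, _ = sc._predicted_classes(p, thresholds)
        cols[p.model_id] = pd.Series(
            {k: ref.CLASS_SCORES[c] for k, c in classes.items()}, dtype=float
        )
    return pd.DataFrame(cols)


def build_consensus(
    preds_by_type: Mapping[str, Sequence[sc.PredictionSet]],
    score2: Mapping[str, float],
    thresholds: ref.PotencyThresholds = ref.DEFAULT_THRESHOLDS,
    min_active_models: int = cns.MIN_ACTIVE_MODELS,
) -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame], list[cns.CorrectionRecord]]:
    """Uncorrected + corrected consensus for every activity type."""
    categorical: dict[str, pd.DataFrame] = {}
    potency: dict[str, pd.DataFrame] = {}
    for atype, preds in preds_by_type.items():
        scored = [p for p in preds if p.model_id in score2]
        cat_models = [p for p in scored if not p.is_continuous]
        cont_models = [p for p in scored if p.is_continuous]
        if cat_models:
            calls = cns.call_matrix(cat_models)
            categorical[atype] = cns.categorical_consensus_frame(calls, score2, atype)
        if cont_models:
            classes = class_score_matrix(cont_models, thresholds)
            potency[atype] = cns.potency_consensus_frame(classes, score2, atype)
    corrected_cat, corrected_pot, log = cns.apply_corrections(
        categorical, potency, min_active_models=min_active_models
    )
    return corrected_cat, corrected_pot, log


# ---------------------------------------------------------------------------
# reporting


def statistics_row(cm: sc.ConfusionMatrix, ndigits: int = 2) -> dict:
    """Sensitivity/specificity/BA of one confusion matrix, rounded for the
    report (round-half-even); undefined metrics stay ``None``."""
    m = sc.classification_metrics(cm)

    def r(x: float | None) -> float | None:
        return None if x is None else round(x, ndigits)

    return {
        "tp": cm.tp, "fn": cm.fn, "fp": cm.fp, "tn": cm.tn,
        "sensitivity": r(m.sensitivity),
        "specificity": r(m.specificity),
        "balanced_accuracy": r(m.balanced_accuracy),
    }


def report_metrics(
    corrected_cat: Mapping[str, pd.DataFrame],
    categorical_ref: Sequence[ref.CategoricalReference],
    training: pd.DataFrame,
    source_counts: Mapping[tuple[str, str], int],
    min_sources_stratum: int = 7,
) -> pd.DataFrame:
    """Consensus statistics per activity type and evaluation data slice.

    For each activity type, reports the confusion matrix and the derived
    sensitivity/specificity/BA against (a) the HTS (AUC-derived) labels,
    (b) the full literature reference and (c) the high-evidence slice with
    at least ``min_sources_stratum`` literature sources.  Empty slices are
    reported with undefined (blank) metrics rather than zeros.
    """
    rows = []
    for atype, frame in corrected_cat.items():
        calls = dict(frame["call"])
        lit = {r_.inchi: r_.active for r_ in categorical_ref
               if r_.activity_type == atype}
        lit_hi = {
            i: a for i, a in lit.items()
            if source_counts.get((i, atype), 0) >= min_sources_stratum
        }
        tox = sc.training_reference(training, atype)
        for slice_name, reference in (
            ("toxcast", tox),
            ("literature_all", lit),
            (f"literature_min{min_sources_stratum}src", lit_hi),
        ):
            cm = sc.confusion_matrix(calls, reference)
            rows.append(
                {"activity_type": atype, "data_slice": slice_name,
                 "n_reference": len(reference)} | statistics_row(cm)
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the full run


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage in order and write the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thresholds = ref.PotencyThresholds(
        strong=config.potency_strong_uM,
        moderate=config.potency_moderate_uM,
        weak=config.potency_weak_uM,
        very_weak=config.potency_very_weak_uM,
    )

    # --- stage: inputs (simulated world or externally supplied tables)
    if config.simulate:
        sim_config = sim.SimulationConfig(
            n_chemicals=config.n_chemicals,
            seed=config.seed,
            n_models=config.n_models,
        )
        world = sim.generate_world(sim_config)
        truth, literature, training = world.truth, world.literature, world.training_auc
        preds_by_type = world.predictions
        truth.to_csv(out / "ground_truth.tsv", sep="\t")
        n_total = config.n_chemicals
    else:
        if not config.predictions_dir:
            raise PipelineError("predictions_dir required when simulation is off")
        all_preds = read_predictions(config.predictions_dir)
        preds_by_type = {}
        for p in all_preds:
            preds_by_type.setdefault(p.activity_type, []).append(p)
        if not config.entries_file or not Path(config.entries_file).exists():
            raise PipelineError("entries_file required when simulation is off")
        literature = pd.read_csv(config.entries_file, sep="\t")
        if not config.training_file or not Path(config.training_file).exists():
            raise PipelineError("training_file required when simulation is off")
        training = pd.read_csv(config.training_file, sep="\t")
        universe = {i for p in all_preds for i in p.calls}
        n_total = len(universe)
    literature.to_csv(out / "literature_entries.tsv", sep="\t", index=False)
    training.to_csv(out / "training_auc.tsv", sep="\t", index=False)
    for preds in preds_by_type.values():
        write_predictions(preds, out / "predictions")

    # --- stage: reference sets
    entries = ref.harmonize_entries(literature.to_dict("records"))
    cat_ref, removed = ref.build_categorical_reference(
        entries, disagreement_threshold=config.disagreement_threshold
    )
    pot_ref = ref.build_potency_reference(entries, thresholds)
    src_counts = ref.count_sources(entries)
    pd.DataFrame([asdict_ref(r) for r in cat_ref]).to_csv(
        out / "categorical_reference.tsv", sep="\t", index=False)
    pd.DataFrame([asdict_ref(r) for r in pot_ref]).to_csv(
        out / "potency_reference.tsv", sep="\t", index=False)
    pd.DataFrame(removed).to_csv(out / "reference_removals.tsv", sep="\t", index=False)

    # --- stage: model scoring
    all_preds = [p for preds in preds_by_type.values() for p in preds]
    model_scores = sc.evaluate_models(all_preds, cat_ref, pot_ref, training, n_total)
    sc.scores_table(model_scores).to_csv(out / "model_scores.tsv", sep="\t",
                                         index=False)

    # --- stage: consensus + corrections
    score2 = _usable_scores(model_scores)
    corrected_cat, corrected_pot, log = build_consensus(
        preds_by_type, score2, thresholds, config.min_active_models
    )
    for atype, frame in corrected_cat.items():
        frame.to_csv(out / f"consensus_categorical_{atype}.tsv", sep="\t")
    for atype, frame in corrected_pot.items():
        frame.to_csv(out / f"consensus_potency_{atype}.tsv", sep="\t")
    pd.DataFrame(
        [{"inchi": r_.inchi, "activity_type": r_.activity_type, "rule": r_.rule,
          "before": r_.before, "after": r_.after} for r_ in log]
    ).to_csv(out / "correction_log.tsv", sep="\t", index=False)

    # --- stage: threshold sweep (binding)
    sweep = pd.DataFrame()
    if "binding" in corrected_cat:
        lit_binding = {r_.inchi: r_.active for r_ in cat_ref
                       if r_.activity_type == "binding"}
        sweep = cns.threshold_sweep(
            corrected_cat["binding"],
            lit_binding,
            thresholds=config.sweep_thresholds,
            source_counts={i: c for (i, a), c in src_counts.items() if a == "binding"},
            strata=config.sweep_strata,
        )
    sweep.to_csv(out / "threshold_sweep.tsv", sep="\t", index=False)

    # --- stage: report
    stats = report_metrics(corrected_cat, cat_ref, training, src_counts)
    stats.to_csv(out / "consensus_statistics.tsv", sep="\t", index=False)
    rule_counts: dict[str, int] = {}
    for r_ in log:
        key = f"rule{r_.rule}_{r_.activity_type}"
        rule_counts[key] = rule_counts.get(key, 0) + 1
    report = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_models": {t: len(p) for t, p in preds_by_type.items()},
        "n_reference_categorical": len(cat_ref),
        "n_reference_removed": len(removed),
        "correction_counts": rule_counts,
        "consensus_counts": {
            t: dict(frame["call"].value_counts())
            for t, frame in corrected_cat.items()
        },
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True,
                                                default=int) + "\n")
    return out


def asdict_ref(obj) -> dict:
    from dataclasses import asdict
    return asdict(obj)
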