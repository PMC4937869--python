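"""Seeded synthetic worlds for end-to-end testing of the consensus pipeline.

The generator emulates the statistical structure of the real study inputs:

* a ground-truth potency landscape with ~10% active prevalence and log10
  AC50 uniform across the active potency range, with agonist/antagonist
  activity coupled to binding (an active agonist or antagonist is always a
  true binder, and antagonists are the rarer endpoint);
* an ensemble of participant models with configurable sensitivity,
  specificity, coverage and applicability-domain fractions -- detection is
  potency dependent (strong actives are easier to call), which is what
  drives the concordance-vs-potency trend in the consensus;
* multi-source literature records with per-source error rates, mixed molar
  units, proliferation-assay records, and in-vivo decoys that the
  harmonization step must drop;
* HTS-style training activity (AUC) scores in [0, 1], monotone in true
  potency, with a configurable fraction landing in the ambiguous 0.01-0.1
  band.

All outputs are bit-reproducible under (config, seed); each generator
operation draws from its own child stream of the master seed, so adding a
generator never perturbs existing draws.

Chemical identifiers are syntactically valid standard InChIs computed (via
RDKit) from an enumerable family of small substituted amino-chloro alkane
chains, so the curation stage can be smoke-tested on them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from erconsensus.reference import (
    ACTIVITY_TYPES,
    CLASS_SCORES,
    INACTIVE_SENTINEL_UM,
    classify_potency,
)
from erconsensus.scoring import (
    CALL_ACTIVE,
    CALL_INACTIVE,
    PredictionSet,
)

__all__ = [
    "SimulationConfig",
    "SyntheticWorld",
    "synthetic_inchis",
    "generate_ground_truth",
    "simulate_model_predictions",
    "simulate_literature",
    "generate_training_auc",
    "generate_world",
]

#: Upper end of the active log10-AC50 range: log10(800 uM), the very-weak /
#: inactive boundary, so that every true active falls in an active class.
_LOG10_VERY_WEAK_MAX = math.log10(800.0)

#: Mean potency-class score of an active chemical under the default uniform
#: log10-AC50 distribution; centers the potency-dependent sensitivity shift
#: so the marginal sensitivity matches the nominal parameter.
_CLASS_SCORE_CENTER = 0.53


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic world; ``seed`` is mandatory."""

    n_chemicals: int
    seed: int
    active_prevalence: float = 0.10
    log10_ac50_range: tuple[float, float] = (-2.0, _LOG10_VERY_WEAK_MAX)
    p_agonist_given_binding: float = 0.6
    p_antagonist_given_binding: float = 0.25
    n_models: int = 15
    sens_range: tuple[float, float] = (0.7, 0.9)
    spec_range: tuple[float, float] = (0.7, 0.9)
    coverage_range: tuple[float, float] = (0.8, 1.0)
    ad_fraction: float = 0.8
    n_continuous_models: int = 3
    potency_noise_sd: float = 0.5  # log10 units on continuous predictions
    potency_sens_slope: float = 1.0  # logit shift per unit class score
    source_count_p: float = 1.0 / 3.0  # geometric; mean 3
    source_count_max: int = 20
    source_fp_rate: float = 0.10
    source_fn_rate: float = 0.10
    lit_noise_sd: float = 0.3  # log10 units on reported AC50s
    unit_mix: tuple[str, ...] = ("M", "mM", "uM", "nM")
    proliferation_fraction: float = 0.10
    in_vivo_fraction: float = 0.05
    auc_noise_sd: float = 0.005
    auc_ambiguous_fraction: float = 0.05

    def __post_init__(self) -> None:
        for name in ("active_prevalence", "p_agonist_given_binding",
                     "p_antagonist_given_binding", "ad_fraction",
                     "source_fp_rate", "source_fn_rate",
                     "proliferation_fraction", "in_vivo_fraction",
                     "auc_ambiguous_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_chemicals <= 0:
            raise ValueError("n_chemicals must be positive")

    def stream(self, *key: int) -> np.random.Generator:
        """Independent child stream of the master seed for one operation."""
        return np.random.default_rng(np.random.SeedSequence((self.seed, *key)))


# ---------------------------------------------------------------------------
# synthetic identifiers

_UNITS = ("C", "C(C)", "C(O)")
_INCHI_CACHE: list[str] = []


def synthetic_inchis(n: int) -> list[str]:
    """First ``n`` identifiers of the enumerable synthetic molecule family.

    Molecule ``k`` is an amino/chloro-terminated carbon chain whose methyl
    and hydroxyl substitution pattern encodes ``k`` in base 3 (the N/Cl
    termini break reversal symmetry, so patterns are never equivalent by
    chain flipping and all InChIs are distinct).
    """
    from rdkit import Chem  # deferred: only needed when ids are generated

    width = max(8, math.ceil(math.log(max(n, 2), 3)))
    while len(_INCHI_CACHE) < n:
        k = len(_INCHI_CACHE)
        digits = []
        q = k
        for _ in range(width):
            q, r = divmod(q, 3)
            digits.append(r)
        smiles = "N" + "".join(_UNITS[d] for d in digits) + "Cl"
        mol = Chem.MolFromSmiles(smiles)
        inchi = Chem.MolToInchi(mol, treatWarningAsError=False)
        _INCHI_CACHE.append(inchi)
    return _INCHI_CACHE[:n]


# ---------------------------------------------------------------------------
# ground truth


def generate_ground_truth(config: SimulationConfig) -> pd.DataFrame:
    """Ground-truth activity and AC50 per chemical for the three endpoints.

    Returns a frame indexed by InChI with, per activity type ``t``, columns
    ``{t}_active`` (bool), ``{t}_ac50`` (uM; 1e6 sentinel when inactive) and
    ``{t}_class`` (five-level potency class).  Binding AC50 is the more
    potent of the chemical's agonist/antagonist activities when present.
    """
    rng = config.stream(0)
    n = config.n_chemicals
    inchis = synthetic_inchis(n)
    lo, hi = config.log10_ac50_range

    binding = rng.random(n) < config.active_prevalence
    agonist = binding & (rng.random(n) < config.p_agonist_given_binding)
    antagonist = binding & (rng.random(n) < config.p_antagonist_given_binding)

    def draw_ac50(active: np.ndarray) -> np.ndarray:
        ac50 = np.full(n, INACTIVE_SENTINEL_UM)
        ac50[active] = 10.0 ** rng.uniform(lo, hi, int(active.sum()))
        return ac50

    ag_ac50 = draw_ac50(agonist)
    ant_ac50 = draw_ac50(antagonist)
    bind_ac50 = draw_ac50(binding)
    bind_ac50 = np.minimum(bind_ac50, np.minimum(ag_ac50, ant_ac50))

    data: dict[str, np.ndarray | list] = {}
    for atype, active, ac50 in (
        ("binding", binding, bind_ac50),
        ("agonist", agonist, ag_ac50),
        ("antagonist", antagonist, ant_ac50),
    ):
        data[f"{atype}_active"] = active
        data[f"{atype}_ac50"] = ac50
        data[f"{atype}_class"] = [classify_potency(v) for v in ac50]
    return pd.DataFrame(data, index=pd.Index(inchis, name="inchi"))


# ---------------------------------------------------------------------------
# model ensembles


def simulate_model_predictions(
    truth: pd.DataFrame,
    activity_type: str,
    sens: float,
    spec: float,
    coverage: float,
    ad_fraction: float,
    seed: int | np.random.SeedSequence,
    model_id: str = "model",
    continuous: bool = False,
    potency_noise_sd: float = 0.5,
    potency_sens_slope: float = 1.0,
    class_score_center: float = _CLASS_SCORE_CENTER,
) -> PredictionSet:
    """One synthetic participant model.

    Covered chemicals are called active with a per-chemical probability:
    nominal sensitivity for true actives (shifted on the logit scale by
    ``potency_sens_slope * (class score - center)``, so stronger actives are
    detected more often), and 1 - specificity for true inactives.  Uncovered
    chemicals are ``not_predicted``.  AD flags mark ``ad_fraction`` of the
    covered chemicals.  The continuous variant adds log-normal noise around
    the true log10 AC50 for its active calls (false positives draw from the
    active potency range).
    """
    for name, v in (("sens", sens), ("spec", spec), ("coverage", coverage),
                    ("ad_fraction", ad_fraction)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(truth)
    active = truth[f"{activity_type}_active"].to_numpy()
    ac50 = truth[f"{activity_type}_ac50"].to_numpy()
    scores = np.array([CLASS_SCORES[c] for c in truth[f"{activity_type}_class"]])

    covered = rng.random(n) < coverage
    with np.errstate(over="ignore"):
        sens_eff = expit(logit(sens) + potency_sens_slope * (scores - class_score_center))
    p_active = np.where(active, sens_eff, 1.0 - spec)
    called_active = rng.random(n) < p_active
    in_ad_flags = rng.random(n) < ad_fraction

    inchis = list(truth.index)
    calls: dict[str, str] = {}
    in_ad: dict[str, bool] = {}
    potency: dict[str, float] = {}
    if continuous:
        noise = rng.normal(0.0, potency_noise_sd, n)
        lo, hi = -2.0, _LOG10_VERY_WEAK_MAX
        fp_pot = 10.0 ** rng.uniform(lo, hi, n)
    for i, inchi in enumerate(inchis):
        if not covered[i]:
            continue
        in_ad[inchi] = bool(in_ad_flags[i])
        if called_active[i]:
            calls[inchi] = CALL_ACTIVE
            if continuous:
                potency[inchi] = (
                    10.0 ** (math.log10(ac50[i]) + noise[i]) if active[i] else fp_pot[i]
                )
        else:
            calls[inchi] = CALL_INACTIVE
    return PredictionSet(
        model_id=model_id,
        activity_type=activity_type,
        calls=calls,
        in_ad=in_ad,
        potency_uM=potency if continuous else None,
        is_continuous=continuous,
    )


def simulate_ensemble(
    truth: pd.DataFrame, config: SimulationConfig, activity_type: str
) -> list[PredictionSet]:
    """A seeded ensemble of categorical + continuous models for one endpoint."""
    rng = config.stream(1, ACTIVITY_TYPES.index(activity_type))
    preds = []
    total = config.n_models
    for j in range(total):
        continuous = j < config.n_continuous_models
        preds.append(
            simulate_model_predictions(
                truth,
                activity_type,
                sens=rng.uniform(*config.sens_range),
                spec=rng.uniform(*config.spec_range),
                coverage=rng.uniform(*config.coverage_range),
                ad_fraction=config.ad_fraction,
                seed=np.random.SeedSequence((config.seed, 1000 + j,
                                             ACTIVITY_TYPES.index(activity_type))),
                model_id=f"{activity_type}_m{j:02d}",
                continuous=continuous,
                potency_noise_sd=config.potency_noise_sd,
                potency_sens_slope=config.potency_sens_slope,
            )
        )
    return preds


# ---------------------------------------------------------------------------
# literature records


def simulate_literature(
    truth: pd.DataFrame, config: SimulationConfig, seed: int | None = None
) -> pd.DataFrame:
    """Raw multi-source literature records, pre-harmonization.

    Per chemical and activity type the number of sources follows a
    truncated geometric distribution; each source reports the true call
    flipped with the configured false-positive/false-negative rates.
    Active reports carry an AC50 with log-normal error in a random molar
    unit; inactive reports carry 1 M.  A configurable fraction of records
    is emitted as cell-proliferation assays (% response, concentration in
    the assay field) and additional in-vivo decoy records are interleaved
    for the cleaning rules to drop.
    """
    rng = config.stream(2) if seed is None else np.random.default_rng(seed)
    rows: list[dict] = []
    units = list(config.unit_mix)
    from erconsensus.reference import _UNIT_TO_UM  # single source of truth

    lo, hi = config.log10_ac50_range
    for atype in ACTIVITY_TYPES:
        active = truth[f"{atype}_active"].to_numpy()
        ac50 = truth[f"{atype}_ac50"].to_numpy()
        counts = np.minimum(
            rng.geometric(config.source_count_p, len(truth)),
            config.source_count_max,
        )
        assay_class = "binding" if atype == "binding" else "transactivation"
        for i, inchi in enumerate(truth.index):
            source_ids = rng.choice(200, size=counts[i], replace=False)
            for src in source_ids:
                if active[i]:
                    observed_active = rng.random() >= config.source_fn_rate
                else:
                    observed_active = rng.random() < config.source_fp_rate
                if observed_active:
                    obs_uM = 10.0 ** (
                        (math.log10(ac50[i]) if active[i] else rng.uniform(lo, hi))
                        + rng.normal(0.0, config.lit_noise_sd)
                    )
                else:
                    obs_uM = None
                as_proliferation = rng.random() < config.proliferation_fraction
                unit = units[rng.integers(len(units))]
                base = {"inchi": inchi, "activity_type": atype,
                        "source_ref": f"src{src:03d}"}
                if as_proliferation:
                    if observed_active:
                        rows.append(base | {
                            "assay_class": "proliferation",
                            "value": float(rng.uniform(130.0, 220.0)),
                            "unit": "%",
                            "active": None,
                            "assay_conc": obs_uM / _UNIT_TO_UM[unit],
                            "assay_conc_unit": unit,
                        })
                    else:
                        rows.append(base | {
                            "assay_class": "proliferation",
                            "value": float(rng.uniform(80.0, 120.0)),
                            "unit": "%",
                            "active": None,
                        })
                elif observed_active:
                    rows.append(base | {
                        "assay_class": assay_class,
                        "value": obs_uM / _UNIT_TO_UM[unit],
                        "unit": unit,
                        "active": True,
                    })
                else:
                    rows.append(base | {
                        "assay_class": assay_class,
                        "value": 1.0,
                        "unit": "M",
                        "active": False,
                    })
                if rng.random() < config.in_vivo_fraction:
                    rows.append(base | {
                        "assay_class": "in_vivo",
                        "value": float(rng.uniform(0.0, 100.0)),
                        "unit": "mg/kg",
                        "active": bool(active[i]),
                    })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# training activity (AUC) scores

_AUC_BASE = {
    "inactive": 0.0,
    "very_weak": 0.15,
    "weak": 0.35,
    "moderate": 0.6,
    "strong": 0.9,
}


def generate_training_auc(
    truth: pd.DataFrame,
    noise_sd: float = 0.005,
    ambiguous_fraction: float = 0.05,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """HTS-style AUC activity scores, monotone in true potency.

    Inactive chemicals score below the 0.01 activity threshold (at zero
    noise), strong actives near 1; additive Gaussian noise is clipped to
    [0, 1].  A configured fraction of scores is relocated into the
    ambiguous [0.01, 0.1) band that the HTS evaluation subset excludes.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n = len(truth)
    data: dict[str, np.ndarray] = {}
    for atype in ACTIVITY_TYPES:
        base = np.array([_AUC_BASE[c] for c in truth[f"{atype}_class"]])
        auc = np.clip(base + rng.normal(0.0, noise_sd, n), 0.0, 1.0)
        ambiguous = rng.random(n) < ambiguous_fraction
        auc[ambiguous] = rng.uniform(0.01, 0.1, int(ambiguous.sum()))
        data[f"auc_{atype}"] = auc
    out = pd.DataFrame(data, index=truth.index)
    return out.reset_index().rename(columns={"index": "inchi"})


# ---------------------------------------------------------------------------
# one-call world


@dataclass
class SyntheticWorld:
    config: SimulationConfig
    truth: pd.DataFrame
    predictions: dict[str, list[PredictionSet]] = field(default_factory=dict)
    literature: pd.DataFrame | None = None
    training_auc: pd.DataFrame | None = None


def generate_world(
    config: SimulationConfig, activity_types: Sequence[str] = ACTIVITY_TYPES
) -> SyntheticWorld:
    """Ground truth, model ensembles, literature and training AUCs, seeded."""
    truth = generate_ground_truth(config)
    preds = {t: simulate_ensemble(truth, config, t) for t in activity_types}
    literature = simulate_literature(truth, config)
    auc = generate_training_auc(
        truth,
        noise_sd=config.auc_noise_sd,
        ambiguous_fraction=config.auc_ambiguous_fraction,
        seed=np.random.SeedSequence((config.seed, 3)),
    )
    return SyntheticWorld(config=config, truth=truth, predictions=preds,
                          literature=literature, training_auc=auc)


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of a config with a different master seed."""
    return replace(config, seed=seed)
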