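"""Build evaluation reference sets from heterogeneous activity records.

Literature in-vitro estrogen-receptor data mixes assay designs (binding,
reporter-gene transactivation, cell proliferation), concentration units and
contradictory calls from different sources.  This module harmonizes raw
records into :class:`ActivityEntry` rows (AC50 in uM, inactives carrying a
1 M sentinel), then distills them into

* a categorical reference (active/inactive per chemical per activity class,
  dropping chemicals whose sources disagree by more than 20%, and
  propagating agonist/antagonist calls to the binding class), and
* a five-level potency reference (inactive / very weak / weak / moderate /
  strong) from AC50 class scores averaged over sources.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from statistics import median
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

ACTIVITY_TYPES = ("binding", "agonist", "antagonist")
ASSAY_CLASSES = ("binding", "transactivation", "proliferation")

#: AC50 assigned to inactive records: 1 M expressed in uM.
INACTIVE_SENTINEL_UM = 1.0e6

#: Cell-proliferation response (% of control) above which a record is active.
PROLIFERATION_THRESHOLD = 125.0

#: Molar units only; mass-per-volume units are ambiguous without molweight
#: and such records are dropped.
_UNIT_TO_UM = {
    "M": 1e6,
    "mM": 1e3,
    "uM": 1.0,
    "μM": 1.0,  # μM
    "µM": 1.0,  # µM
    "nM": 1e-3,
    "pM": 1e-6,
}

POTENCY_CLASSES = ("inactive", "very_weak", "weak", "moderate", "strong")
CLASS_SCORES = {
    "inactive": 0.0,
    "very_weak": 0.25,
    "weak": 0.5,
    "moderate": 0.75,
    "strong": 1.0,
}

_EPS = 1e-9


class UnsupportedUnitError(ValueError):
    """Concentration unit cannot be converted to uM exactly."""


@dataclass
class ActivityEntry:
    """One harmonized literature/assay record."""

    inchi: str
    activity_type: str  # binding | agonist | antagonist
    assay_class: str  # binding | transactivation | proliferation
    ac50: float  # uM; INACTIVE_SENTINEL_UM when inactive
    active: bool
    source_ref: str
    raw_value: float | None = None
    raw_unit: str | None = None

    def __post_init__(self) -> None:
        if self.activity_type not in ACTIVITY_TYPES:
            raise ValueError(f"unknown activity_type {self.activity_type!r}")
        if self.assay_class not in ASSAY_CLASSES:
            raise ValueError(f"unknown assay_class {self.assay_class!r}")
        if not self.ac50 > 0:
            raise ValueError("ac50 must be positive")
        if not self.active and self.ac50 != INACTIVE_SENTINEL_UM:
            raise ValueError("inactive entries must carry the 1 M sentinel AC50")


@dataclass
class CategoricalReference:
    inchi: str
    activity_type: str
    active: bool
    n_sources: int
    provenance: str = "observed"  # observed | propagated_rule2 | propagated_rule3


@dataclass
class PotencyReference:
    inchi: str
    activity_type: str
    potency_class: str
    avg_score: float
    log10_median_uM: float
    n_sources: int = 1


# ---------------------------------------------------------------------------
# unit conversion and record harmonization


def _missing_to_none(v):
    """NaN (e.g. from a delimited-table round trip) counts as missing."""
    if isinstance(v, float) and math.isnan(v):
        return None
    return v


def convert_to_micromolar(value: float, unit: str) -> float:
    """Exact power-of-ten conversion of a molar concentration to uM."""
    factor = _UNIT_TO_UM.get(unit.strip())
    if factor is None:
        raise UnsupportedUnitError(f"unsupported unit {unit!r}")
    return float(value) * factor


def harmonize_entry(raw: Mapping) -> ActivityEntry | None:
    """Turn one raw activity record into an :class:`ActivityEntry`.

    Returns ``None`` (and logs the reason) for records the cleaning rules
    drop: in vivo data, cytotoxicity readouts, unknown assay classes,
    unconvertible units, and records with neither an endpoint value nor an
    activity flag.  Proliferation records are called active iff the response
    exceeds 125% of control, taking their AC50 from the tested concentration
    when one was reported.  Inactive records receive the 1 M sentinel.
    """
    assay_class = str(raw.get("assay_class", "")).strip().lower().replace(" ", "_")
    if assay_class in ("in_vivo", "cytotoxicity"):
        logger.debug("dropping %s record for %s", assay_class, raw.get("inchi"))
        return None
    if assay_class not in ASSAY_CLASSES:
        logger.debug("dropping record with assay class %r", assay_class)
        return None
    inchi = raw.get("inchi")
    activity_type = raw.get("activity_type")
    source_ref = str(raw.get("source_ref", ""))
    value = _missing_to_none(raw.get("value"))
    unit = _missing_to_none(raw.get("unit"))
    active = _missing_to_none(raw.get("active"))
    if active is not None and not isinstance(active, bool):
        active = bool(int(active))

    if assay_class == "proliferation":
        # value is the % proliferation response
        if value is None:
            logger.debug("dropping ambiguous proliferation record (no response)")
            return None
        active = float(value) > PROLIFERATION_THRESHOLD
        if not active:
            return ActivityEntry(inchi, activity_type, assay_class,
                                 INACTIVE_SENTINEL_UM, False, source_ref,
                                 float(value), "%")
        conc = _missing_to_none(raw.get("assay_conc"))
        conc_unit = _missing_to_none(raw.get("assay_conc_unit"))
        if conc is None or conc_unit is None:
            logger.debug("dropping active proliferation record without concentration")
            return None
        try:
            ac50 = convert_to_micromolar(float(conc), str(conc_unit))
        except UnsupportedUnitError:
            return None
        return ActivityEntry(inchi, activity_type, assay_class, ac50, True,
                             source_ref, float(conc), str(conc_unit))

    if active is None and value is None:
        logger.debug("dropping ambiguous record (no endpoint, no flag)")
        return None
    if active is False or (active is None and value is None):
        return ActivityEntry(inchi, activity_type, assay_class,
                             INACTIVE_SENTINEL_UM, False, source_ref,
                             float(value) if value is not None else None,
                             str(unit) if unit is not None else None)
    # active, or unflagged with a reported concentration (treated as active)
    if value is None or unit is None:
        logger.debug("dropping active record without a convertible endpoint")
        return None
    try:
        ac50 = convert_to_micromolar(float(value), str(unit))
    except UnsupportedUnitError:
        logger.debug("dropping record with unit %r", unit)
        return None
    return ActivityEntry(inchi, activity_type, assay_class, ac50, True,
                         source_ref, float(value), str(unit))


def harmonize_entries(rows: Iterable[Mapping]) -> list[ActivityEntry]:
    out = []
    for row in rows:
        entry = harmonize_entry(row)
        if entry is not None:
            out.append(entry)
    return out


# ---------------------------------------------------------------------------
# categorical reference (majority call + 20% disagreement rule + propagation)


def count_sources(entries: Iterable[ActivityEntry]) -> dict[tuple[str, str], int]:
    """Distinct source count per (inchi, activity_type) group."""
    seen: dict[tuple[str, str], set[str]] = {}
    for e in entries:
        seen.setdefault((e.inchi, e.activity_type), set()).add(e.source_ref)
    return {k: len(v) for k, v in sorted(seen.items())}


def build_categorical_reference(
    entries: Sequence[ActivityEntry],
    disagreement_threshold: float = 0.20,
) -> tuple[list[CategoricalReference], list[dict]]:
    """Majority calls with the disagreement rule, then binding propagation.

    Rule 1: within each (chemical, activity class) group the minority-call
    fraction is computed; the group is removed when it strictly exceeds the
    threshold (default 20%), otherwise the majority call is kept.
    Rule 2: an active agonist or antagonist becomes an active binder when no
    binding call survived.  Rule 3: a chemical inactive as both agonist and
    antagonist becomes an inactive binder when no binding call survived.
    Propagation never overwrites a surviving observed binding reference.

    Returns the reference list and a removals log (one dict per removed
    group with its disagreement fraction).
    """
    groups: dict[tuple[str, str], list[ActivityEntry]] = {}
    for e in entries:
        groups.setdefault((e.inchi, e.activity_type), []).append(e)

    refs: dict[tuple[str, str], CategoricalReference] = {}
    removed: list[dict] = []
    for (inchi, atype), group in sorted(groups.items()):
        n_active = sum(1 for e in group if e.active)
        n = len(group)
        minority = min(n_active, n - n_active) / n
        if minority > disagreement_threshold + _EPS:
            removed.append(
                {"inchi": inchi, "activity_type": atype,
                 "disagreement": minority, "n_entries": n}
            )
            continue
        refs[(inchi, atype)] = CategoricalReference(
            inchi=inchi,
            activity_type=atype,
            active=n_active * 2 > n,
            n_sources=len({e.source_ref for e in group}),
        )

    # rules 2 and 3: fill missing binding calls from agonist/antagonist
    chemicals = {inchi for inchi, _ in groups}
    for inchi in sorted(chemicals):
        if (inchi, "binding") in refs:
            continue
        ag = refs.get((inchi, "agonist"))
        ant = refs.get((inchi, "antagonist"))
        actives = [r for r in (ag, ant) if r is not None and r.active]
        if actives:
            refs[(inchi, "binding")] = CategoricalReference(
                inchi=inchi, activity_type="binding", active=True,
                n_sources=max(r.n_sources for r in actives),
                provenance="propagated_rule2",
            )
        elif ag is not None and ant is not None and not ag.active and not ant.active:
            refs[(inchi, "binding")] = CategoricalReference(
                inchi=inchi, activity_type="binding", active=False,
                n_sources=max(ag.n_sources, ant.n_sources),
                provenance="propagated_rule3",
            )
    return list(refs.values()), removed


# ---------------------------------------------------------------------------
# potency classes


@dataclass(frozen=True)
class PotencyThresholds:
    """AC50 (uM) boundaries of the five potency classes.

    Boundaries are half-open [low, high) except the very-weak upper bound,
    which is inclusive so that only concentrations *higher than* 800 uM are
    inactive.
    """

    strong: float = 0.09
    moderate: float = 0.18
    weak: float = 20.0
    very_weak: float = 800.0


DEFAULT_THRESHOLDS = PotencyThresholds()


def classify_potency(
    ac50: float, thresholds: PotencyThresholds = DEFAULT_THRESHOLDS
) -> str:
    """Map an AC50 in uM to one of the five potency classes."""
    if not ac50 > 0:
        raise ValueError("ac50 must be positive")
    if ac50 < thresholds.strong:
        return "strong"
    if ac50 < thresholds.moderate:
        return "moderate"
    if ac50 < thresholds.weak:
        return "weak"
    if ac50 <= thresholds.very_weak:
        return "very_weak"
    return "inactive"


def score_and_merge(source_classes: Sequence[str]) -> tuple[float, str]:
    """Average the class scores of merged entries and re-class the mean.

    Scores are inactive 0, very weak 0.25, weak 0.5, moderate 0.75,
    strong 1; the merged class uses strong > 0.75, moderate (0.5, 0.75],
    weak (0.25, 0.5], very weak (0, 0.25], inactive = 0.
    """
    if not source_classes:
        raise ValueError("need at least one class")
    avg = sum(CLASS_SCORES[c] for c in source_classes) / len(source_classes)
    if avg > 0.75 + _EPS:
        merged = "strong"
    elif avg > 0.5 + _EPS:
        merged = "moderate"
    elif avg > 0.25 + _EPS:
        merged = "weak"
    elif avg > _EPS:
        merged = "very_weak"
    else:
        merged = "inactive"
    return avg, merged


def log10_median(ac50_values: Sequence[float]) -> float:
    """Median of log10-transformed AC50 values (uM)."""
    if not ac50_values:
        raise ValueError("need at least one value")
    if any(v <= 0 for v in ac50_values):
        raise ValueError("ac50 values must be positive")
    return float(median(math.log10(v) for v in ac50_values))


def build_potency_reference(
    entries: Sequence[ActivityEntry],
    thresholds: PotencyThresholds = DEFAULT_THRESHOLDS,
) -> list[PotencyReference]:
    """Five-level potency reference from per-entry class scores.

    Each entry's AC50 is classed individually; the arithmetic mean of the
    class scores drives the merged class.  The log10-median AC50 is stored
    as a descriptive field alongside.
    """
    groups: dict[tuple[str, str], list[ActivityEntry]] = {}
    for e in entries:
        groups.setdefault((e.inchi, e.activity_type), []).append(e)
    out = []
    for (inchi, atype), group in sorted(groups.items()):
        classes = [classify_potency(e.ac50, thresholds) for e in group]
        avg, merged = score_and_merge(classes)
        out.append(
            PotencyReference(
                inchi=inchi,
                activity_type=atype,
                potency_class=merged,
                avg_score=avg,
                log10_median_uM=log10_median([e.ac50 for e in group]),
                n_sources=len({e.source_ref for e in group}),
            )
        )
    return out
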