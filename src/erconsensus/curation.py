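"""Chemical structure curation: raw structures to a unique QSAR-ready set.

Heterogeneous chemical inventories carry salts, charged species, stereo
annotations, tautomer variants and duplicates, all of which fragment a
modeling set.  The workflow here applies, in order:

1. parse and validity-check (invalid records are dropped and logged;
   no online structure retrieval is attempted, but a resolver hook can be
   plugged in);
2. inorganic filter (no carbon -> drop);
3. desalting (keep the largest organic fragment, strip counterions);
4. molecular-weight filter (> 1000 g/mol -> drop, strict);
5-7. standardization: mesomer normalization (nitro, azide, ...), tautomer
   canonicalization (keto-enol, enamine-imine, ynol-ketene, ...), charge
   neutralization where an H can be added/removed, stereo stripping,
   aromatization by Hueckel perception;
8. duplicate removal keyed on the standard InChI;
9. metal/metalloid filter.

The output is a list of :class:`CuratedStructure` with unique InChIs plus a
:class:`CurationReport` of per-step removal and correction counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

#: Elements tolerated in organic structures; everything else counts as a
#: metal/metalloid for the final filter.  Si, Se and B are organic-chemistry
#: borderline cases kept by default; pass ``allowed_elements`` to change.
ORGANIC_ELEMENTS = frozenset(
    ["H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I"]
)

DEFAULT_MAX_MOLWEIGHT = 1000.0


class CurationError(ValueError):
    """Raised when a structure cannot be processed."""


class NoOrganicFragmentError(CurationError):
    """Desalting found no carbon-containing fragment to keep."""


@dataclass
class RawStructureRecord:
    """One input record prior to curation."""

    record_id: str
    structure_text: str  # SMILES or an SDF molblock
    casrn: str | None = None
    name: str | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if not self.record_id:
            raise ValueError("record_id must be non-empty")
        if not self.structure_text:
            raise ValueError("structure_text must be non-empty")


@dataclass
class CuratedStructure:
    """A standardized, desalted, neutral, stereo-free structure.

    The standard InChI is the unique key; ``merged_ids`` lists every input
    record collapsed into this structure (duplicates included).
    """

    inchi: str
    canonical_structure: str  # canonical SMILES of the standardized molecule
    molweight: float
    provenance: list[str] = field(default_factory=list)
    merged_ids: list[str] = field(default_factory=list)


@dataclass
class CurationReport:
    n_input: int = 0
    n_output: int = 0
    removals: dict[str, int] = field(default_factory=dict)
    corrections: dict[str, int] = field(default_factory=dict)
    n_merged: int = 0  # records merged into an earlier duplicate

    def check(self) -> None:
        total = self.n_output + sum(self.removals.values()) + self.n_merged
        if self.n_input != total:
            raise AssertionError(
                f"curation bookkeeping broken: {self.n_input} != {total}"
            )


# ---------------------------------------------------------------------------
# parsing


def _mol_from_text(text: str) -> Chem.Mol | None:
    """Parse SMILES or a molblock; None when invalid (bad valence etc.)."""
    if "\n" in text or "M  END" in text:
        return Chem.MolFromMolBlock(text, sanitize=True)
    return Chem.MolFromSmiles(text, sanitize=True)


def parse_structures(
    path: str | Path, format: str  # noqa: A002 - mirrors the CLI flag
) -> list[RawStructureRecord]:
    """Read an SDF (V2000) or newline-delimited SMILES file.

    Records that fail valence or integrity checks are dropped and logged;
    unreadable files raise ``FileNotFoundError``/``ValueError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format not in ("sdf", "smiles"):
        raise ValueError(f"unknown format {format!r}")
    text = path.read_text()
    records: list[RawStructureRecord] = []
    if format == "sdf":
        blocks = [b for b in text.split("$$$$") if b.strip()]
        for i, block in enumerate(blocks):
            block = block.lstrip("\n") + "\n"
            mol = Chem.MolFromMolBlock(block, sanitize=True)
            name = block.splitlines()[0].strip() if block.splitlines() else ""
            rid = name or f"record_{i}"
            if mol is None:
                logger.warning("dropping invalid structure %s", rid)
                continue
            records.append(
                RawStructureRecord(record_id=rid, structure_text=block, source=str(path))
            )
    else:
        for i, line in enumerate(text.splitlines()):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            smiles = parts[0].strip()
            rid = parts[1].strip() if len(parts) > 1 and parts[1].strip() else f"record_{i}"
            if Chem.MolFromSmiles(smiles) is None:
                logger.warning("dropping invalid structure %s", rid)
                continue
            records.append(
                RawStructureRecord(record_id=rid, structure_text=smiles, source=str(path))
            )
    if not records:
        logger.warning("no parseable records in %s", path)
    return records


# ---------------------------------------------------------------------------
# individual curation steps (each operates on an RDKit Mol)


def filter_inorganic(mol: Chem.Mol) -> bool:
    """Keep iff the structure contains at least one carbon atom."""
    return any(a.GetAtomicNum() == 6 for a in mol.GetAtoms())


def desalt(mol: Chem.Mol) -> Chem.Mol:
    """Keep only the largest organic fragment; drop counterions.

    Largest = most heavy atoms among carbon-containing fragments; ties
    broken by molecular weight, then by the lexicographically smallest
    canonical SMILES.  Single-fragment input is returned unchanged.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return mol
    organic = [f for f in frags if filter_inorganic(f)]
    if not organic:
        raise NoOrganicFragmentError("all fragments are inorganic")

    def key(f: Chem.Mol) -> tuple:
        return (-f.GetNumHeavyAtoms(), -Descriptors.MolWt(f), Chem.MolToSmiles(f))

    return sorted(organic, key=key)[0]


def filter_molweight(mol: Chem.Mol, max_mw: float = DEFAULT_MAX_MOLWEIGHT) -> bool:
    """Keep iff molweight does not strictly exceed ``max_mw`` g/mol."""
    return Descriptors.MolWt(mol) <= max_mw


_NORMALIZER = rdMolStandardize.Normalizer()
_UNCHARGER = rdMolStandardize.Uncharger()
_TAUTOMER = rdMolStandardize.TautomerEnumerator()


def standardize(mol: Chem.Mol) -> Chem.Mol:
    """Mesomer/tautomer canonicalization, neutralization, stereo stripping.

    Applies the deterministic rule set: functional-group normalization
    (unifies nitro and azide mesomer drawings), charge neutralization by H
    add/remove where the net charge permits (quaternary ammonium and other
    permanent ions stay charged), removal of all tetrahedral and double-bond
    stereo descriptors, and canonical-tautomer selection covering keto-enol,
    enamine-imine and ynol-ketene interconversions.  Aromaticity is
    reperceived during sanitization.  The result is a fixed point:
    standardizing twice changes nothing.
    """
    mol = Chem.Mol(mol)
    try:
        Chem.SanitizeMol(mol)
        mol = _NORMALIZER.normalize(mol)
        mol = _UNCHARGER.uncharge(mol)
        Chem.RemoveStereochemistry(mol)
        mol = _TAUTOMER.Canonicalize(mol)
        Chem.SanitizeMol(mol)
    except Exception as exc:  # pragma: no cover - defensive
        raise CurationError(f"structure failed standardization: {exc}") from exc
    return mol


def filter_metals(
    mol: Chem.Mol, allowed_elements: frozenset[str] | set[str] = ORGANIC_ELEMENTS
) -> bool:
    """Keep iff every atom belongs to the allowed (organic) element set."""
    return all(a.GetSymbol() in allowed_elements for a in mol.GetAtoms())


def to_inchi(mol: Chem.Mol) -> str:
    """Standard InChI, the sole duplicate key."""
    inchi = Chem.MolToInchi(mol, treatWarningAsError=False)
    if not inchi:
        raise CurationError("InChI generation failed")
    return inchi


# ---------------------------------------------------------------------------
# full cascade

#: A resolver hook may return a replacement SMILES for an invalid record
#: (the original workflow queried structure databases online); the default
#: is to drop and log.
StructureResolver = Callable[[RawStructureRecord], str | None]


def curate(
    records: Iterable[RawStructureRecord],
    max_mw: float = DEFAULT_MAX_MOLWEIGHT,
    allowed_elements: frozenset[str] | set[str] = ORGANIC_ELEMENTS,
    resolver: StructureResolver | None = None,
) -> tuple[list[CuratedStructure], CurationReport]:
    """Run the full curation cascade and deduplicate on standard InChI."""
    report = CurationReport()
    removals = report.removals
    corrections = report.corrections
    by_inchi: dict[str, CuratedStructure] = {}

    def _removed(reason: str) -> None:
        removals[reason] = removals.get(reason, 0) + 1

    def _corrected(what: str) -> None:
        corrections[what] = corrections.get(what, 0) + 1

    for rec in records:
        report.n_input += 1
        mol = _mol_from_text(rec.structure_text)
        if mol is None and resolver is not None:
            replacement = resolver(rec)
            if replacement:
                mol = _mol_from_text(replacement)
        if mol is None:
            logger.info("record %s: invalid structure, dropped", rec.record_id)
            _removed("invalid_structure")
            continue
        provenance = ["parsed"]
        if not filter_inorganic(mol):
            _removed("inorganic")
            continue
        try:
            desalted = desalt(mol)
        except NoOrganicFragmentError:
            _removed("inorganic")
            continue
        if desalted.GetNumAtoms() != mol.GetNumAtoms():
            provenance.append("desalted")
            _corrected("desalted")
        mol = desalted
        if not filter_molweight(mol, max_mw=max_mw):
            _removed("molweight")
            continue
        before = Chem.MolToSmiles(Chem.Mol(mol))
        try:
            mol = standardize(mol)
        except CurationError:
            _removed("standardization_failed")
            continue
        if Chem.MolToSmiles(mol) != before:
            provenance.append("standardized")
            _corrected("standardized")
        if not filter_metals(mol, allowed_elements=allowed_elements):
            _removed("metal")
            continue
        try:
            inchi = to_inchi(mol)
        except CurationError:
            _removed("standardization_failed")
            continue
        if inchi in by_inchi:
            by_inchi[inchi].merged_ids.append(rec.record_id)
            report.n_merged += 1
            continue
        by_inchi[inchi] = CuratedStructure(
            inchi=inchi,
            canonical_structure=Chem.MolToSmiles(mol),
            molweight=Descriptors.MolWt(mol),
            provenance=provenance,
            merged_ids=[rec.record_id],
        )

    report.n_output = len(by_inchi)
    report.check()
    return list(by_inchi.values()), report


# ---------------------------------------------------------------------------
# serialization helpers


def write_outputs(
    structures: Sequence[CuratedStructure], report: CurationReport, out_dir: str | Path
) -> None:
    """Write the QSAR-ready SDF, a delimited summary table and the report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with Chem.SDWriter(str(out / "curated.sdf")) as writer:
        for s in structures:
            mol = Chem.MolFromSmiles(s.canonical_structure)
            mol.SetProp("_Name", s.merged_ids[0])
            mol.SetProp("InChI", s.inchi)
            writer.write(mol)
    lines = ["record_id\tinchi\tcanonical_smiles\tmolweight\tmerged_ids"]
    for s in structures:
        lines.append(
            "\t".join(
                [
                    s.merged_ids[0],
                    s.inchi,
                    s.canonical_structure,
                    f"{s.molweight:.2f}",
                    ";".join(s.merged_ids),
                ]
            )
        )
    (out / "curated.tsv").write_text("\n".join(lines) + "\n")
    rep = [f"n_input\t{report.n_input}", f"n_output\t{report.n_output}",
           f"n_merged\t{report.n_merged}"]
    rep += [f"removed_{k}\t{v}" for k, v in sorted(report.removals.items())]
    rep += [f"corrected_{k}\t{v}" for k, v in sorted(report.corrections.items())]
    (out / "curation_report.tsv").write_text("\n".join(rep) + "\n")
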