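"""Molecule standardisation, filtering and deduplication.

Every raw record runs through the same pipeline before training or storage:

    parse -> strip stereochemistry -> keep largest component
          -> element/size filter -> structural key (InChI) -> merge duplicates

Stereochemistry is stripped because its presence and depiction vary wildly
between source databases and stereo descriptors would split otherwise
identical fragments.  Duplicates across sources are merged on a stereo-free
InChI; the merged molecule is labelled NP if *any* source labels it NP
(conflicts are logged — mislabelled entries are known to occur in public
databases).  Biogenic records are curated and stored but excluded from both
training classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

from rdkit import Chem

from .chem_io import MoleculeRecord, Status
from .sugar_removal import SugarRules, DEFAULT_RULES, remove_sugars

logger = logging.getLogger("nplikeness")

#: Elements permitted in curated molecules; anything else rejects the record.
ALLOWED_ELEMENTS = frozenset(
    ["C", "H", "N", "O", "P", "S", "Cl", "F", "As", "Se", "Br", "I", "B", "Na", "Si", "K", "Fe"]
)

#: Minimum molecule size. "Atoms" are counted as heavy atoms by default:
#: hydrogen counts depend on how a given file writes them, heavy-atom counts
#: do not (configurable via min_atoms / count_hydrogens).
MIN_ATOMS = 6


@dataclass
class CuratedMolecule:
    """A standardised, filter-passing, deduplicated structure."""

    molecule_id: int
    structural_key: str
    smiles: str
    is_np: bool
    is_biogenic: bool
    contains_sugar: bool
    heavy_atom_count: int
    total_atom_count: int
    heavy_atom_count_no_sugar: Optional[int]
    total_atom_count_no_sugar: Optional[int]
    ring_count: int
    c_count: int
    o_count: int
    n_count: int
    aglycone_smiles: Optional[str]
    sources: Set[Tuple[str, str]] = field(default_factory=set)


@dataclass
class CurationReport:
    parsed: int = 0
    rejected_parse: int = 0
    rejected_size: int = 0
    rejected_element: int = 0
    unique: int = 0
    label_conflicts: int = 0
    rejections: List[Tuple[str, str]] = field(default_factory=list)  # (record_id, reason)


def strip_stereochemistry(mol: Chem.Mol) -> Chem.Mol:
    """Remove all tetrahedral and double-bond stereo descriptors (copy)."""
    out = Chem.Mol(mol)
    Chem.RemoveStereochemistry(out)
    return out


def _total_atoms(mol: Chem.Mol) -> int:
    return mol.GetNumAtoms() + sum(a.GetTotalNumHs() for a in mol.GetAtoms())


def largest_component(mol: Chem.Mol) -> Chem.Mol:
    """Keep the connected component with the most heavy atoms.

    Ties break by most total atoms, then by lexicographically smallest
    canonical SMILES, so the choice is order-independent.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return mol
    return min(frags, key=lambda m: (-m.GetNumAtoms(), -_total_atoms(m), Chem.MolToSmiles(m)))


def filter_elements_and_size(
    mol: Chem.Mol, min_atoms: int = MIN_ATOMS, count_hydrogens: bool = False
) -> bool:
    """True iff the molecule is large enough and all-organic (allowed set)."""
    n = _total_atoms(mol) if count_hydrogens else mol.GetNumAtoms()
    if n < min_atoms:
        return False
    return all(a.GetSymbol() in ALLOWED_ELEMENTS for a in mol.GetAtoms())


def structural_key(mol: Chem.Mol) -> Optional[str]:
    """Standard InChI of the (already stereo-free) structure, or None."""
    try:
        key = Chem.MolToInchi(mol, treatWarningAsError=False)
    except Exception:
        return None
    return key or None


def _describe(mol: Chem.Mol, sugar_rules: SugarRules):
    """Descriptors plus sugar-removal results for one standardised mol."""
    res = remove_sugars(mol, sugar_rules)
    contains_sugar = res.had_circular_sugar or res.had_linear_sugar
    heavy = mol.GetNumAtoms()
    total = _total_atoms(mol)
    if not contains_sugar:
        heavy_ns, total_ns = heavy, total
        aglycone_smiles = Chem.MolToSmiles(mol)
    elif res.aglycone is not None:
        heavy_ns, total_ns = res.aglycone.GetNumAtoms(), _total_atoms(res.aglycone)
        aglycone_smiles = Chem.MolToSmiles(res.aglycone)
    else:
        heavy_ns = total_ns = None
        aglycone_smiles = None
    counts = {"C": 0, "O": 0, "N": 0}
    for a in mol.GetAtoms():
        if a.GetSymbol() in counts:
            counts[a.GetSymbol()] += 1
    return contains_sugar, heavy_ns, total_ns, aglycone_smiles, counts, heavy, total


def curate(
    records: List[MoleculeRecord],
    min_atoms: int = MIN_ATOMS,
    count_hydrogens: bool = False,
    sugar_rules: SugarRules = DEFAULT_RULES,
) -> Tuple[List[CuratedMolecule], CurationReport]:
    """Run the full curation pipeline and merge records by structural key.

    Returns curated molecules in order of first appearance, plus a report
    satisfying ``parsed = rejected_parse + rejected_size + rejected_element
    + sum(multiplicity of each unique key)``.
    """
    report = CurationReport()
    by_key: Dict[str, CuratedMolecule] = {}
    statuses: Dict[str, Set[Status]] = {}
    out: List[CuratedMolecule] = []

    for rec in records:
        report.parsed += 1
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None or mol.GetNumAtoms() == 0:
            report.rejected_parse += 1
            report.rejections.append((rec.record_id, "parse"))
            continue
        mol = strip_stereochemistry(mol)
        mol = largest_component(mol)
        if not all(a.GetSymbol() in ALLOWED_ELEMENTS for a in mol.GetAtoms()):
            report.rejected_element += 1
            report.rejections.append((rec.record_id, "element"))
            continue
        n = _total_atoms(mol) if count_hydrogens else mol.GetNumAtoms()
        if n < min_atoms:
            report.rejected_size += 1
            report.rejections.append((rec.record_id, "size"))
            continue
        key = structural_key(mol)
        if key is None:
            report.rejected_parse += 1
            report.rejections.append((rec.record_id, "inchi"))
            logger.warning("record %s: InChI generation failed — rejected", rec.record_id)
            continue

        if key in by_key:
            cur = by_key[key]
            cur.sources.add((rec.source_db, rec.record_id))
            prior = statuses[key]
            if rec.status not in prior and (prior - {Status.BIOGENIC}) and rec.status is not Status.BIOGENIC:
                report.label_conflicts += 1
                logger.warning(
                    "record %s: class label %s conflicts with earlier label(s) %s for the same "
                    "structure — resolving to NP if any source says NP",
                    rec.record_id, rec.status.value, sorted(s.value for s in prior),
                )
            prior.add(rec.status)
            cur.is_np = Status.NP in prior
            cur.is_biogenic = prior == {Status.BIOGENIC}
            continue

        contains_sugar, heavy_ns, total_ns, aglycone_smiles, counts, heavy, total = _describe(mol, sugar_rules)
        cur = CuratedMolecule(
            molecule_id=len(by_key) + 1,
            structural_key=key,
            smiles=Chem.MolToSmiles(mol),
            is_np=rec.status is Status.NP,
            is_biogenic=rec.status is Status.BIOGENIC,
            contains_sugar=contains_sugar,
            heavy_atom_count=heavy,
            total_atom_count=total,
            heavy_atom_count_no_sugar=heavy_ns,
            total_atom_count_no_sugar=total_ns,
            ring_count=mol.GetRingInfo().NumRings(),
            c_count=counts["C"],
            o_count=counts["O"],
            n_count=counts["N"],
            aglycone_smiles=aglycone_smiles,
            sources={(rec.source_db, rec.record_id)},
        )
        by_key[key] = cur
        statuses[key] = {rec.status}
        out.append(cur)

    report.unique = len(out)
    return out, report


def standardise_for_scoring(
    rec: MoleculeRecord, sugar_rules: SugarRules = DEFAULT_RULES
) -> Optional[CuratedMolecule]:
    """Standardise one record for scoring only: stereo stripped, largest
    component kept, descriptors computed — but no size/element filter and
    no deduplication, since any submitted molecule may be scored.

    Returns None for an unparseable record.
    """
    mol = Chem.MolFromSmiles(rec.smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        return None
    mol = largest_component(strip_stereochemistry(mol))
    key = structural_key(mol) or ""
    contains_sugar, heavy_ns, total_ns, aglycone_smiles, counts, heavy, total = _describe(mol, sugar_rules)
    return CuratedMolecule(
        molecule_id=0,
        structural_key=key,
        smiles=Chem.MolToSmiles(mol),
        is_np=rec.status is Status.NP,
        is_biogenic=rec.status is Status.BIOGENIC,
        contains_sugar=contains_sugar,
        heavy_atom_count=heavy,
        total_atom_count=total,
        heavy_atom_count_no_sugar=heavy_ns,
        total_atom_count_no_sugar=total_ns,
        ring_count=mol.GetRingInfo().NumRings(),
        c_count=counts["C"],
        o_count=counts["O"],
        n_count=counts["N"],
        aglycone_smiles=aglycone_smiles,
        sources={(rec.source_db, rec.record_id)},
    )
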