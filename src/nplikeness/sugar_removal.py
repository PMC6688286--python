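"""Detection and removal of linear and circular sugar moieties.

Glycosylation is ubiquitous in natural products, and sugar rings are
repetitive, oxygen-dense substructures that carry little information about
the aglycone scaffold a molecule is built on.  Removing them before
fragmentation keeps the fragment statistics focused on the distinctive part
of the structure.

Operational definitions (thresholds live in ``sugar_rules.json`` and in
:class:`SugarRules` so alternative definitions can be swapped in):

* **circular sugar** — a 5- or 6-membered non-aromatic ring with exactly one
  ring oxygen and otherwise carbons, not fused to any other ring, whose ring
  carbons together carry at least ``ring size − 2`` exocyclic single-bonded
  oxygen substituents (hydroxyl, glycosidic or other ether oxygen).  This
  captures pyranoses and furanoses while sparing plain cyclic ethers such as
  tetrahydropyran or morpholine.
* **linear sugar** — a maximal acyclic chain of 3–7 carbons, none in a ring,
  in which every carbon bears exactly one oxygen substituent (hydroxyl,
  carbonyl or connecting oxygen).  This captures open-chain polyols and
  aldoses while sparing plain alkyl chains and esters (an ester carbon bears
  two oxygens).

Removal deletes the detected sugar atoms together with their oxygen
substituents; a bridging (glycosidic) oxygen survives only if it bonds to
two non-sugar heavy atoms.  Circular sugars are removed before linear ones,
then the largest remaining component is kept.  If nothing remains, or the
remainder is below the minimum aglycone size, the aglycone is ``None`` while
the detection flags still report what was found.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import FrozenSet, List, Optional, Set

from rdkit import Chem

MIN_AGLYCONE_HEAVY_ATOMS = 6


def _load_default_rules() -> dict:
    with resources.files("nplikeness").joinpath("sugar_rules.json").open() as fh:
        return json.load(fh)


@dataclass(frozen=True)
class SugarRules:
    """Tunable thresholds of the sugar definitions above."""

    ring_sizes: tuple = (5, 6)
    # a ring of size s needs >= s - exocyclic_oxygen_deficit exocyclic oxygens
    exocyclic_oxygen_deficit: int = 2
    min_chain_length: int = 3
    max_chain_length: int = 7
    min_aglycone_heavy_atoms: int = MIN_AGLYCONE_HEAVY_ATOMS

    @classmethod
    def from_config(cls, cfg: Optional[dict] = None) -> "SugarRules":
        cfg = cfg if cfg is not None else _load_default_rules()
        return cls(
            ring_sizes=tuple(cfg["circular"]["ring_sizes"]),
            exocyclic_oxygen_deficit=cfg["circular"]["exocyclic_oxygen_deficit"],
            min_chain_length=cfg["linear"]["min_chain_length"],
            max_chain_length=cfg["linear"]["max_chain_length"],
            min_aglycone_heavy_atoms=cfg["min_aglycone_heavy_atoms"],
        )


DEFAULT_RULES = SugarRules()


@dataclass
class SugarRemovalResult:
    aglycone: Optional[Chem.Mol]
    had_circular_sugar: bool
    had_linear_sugar: bool
    removed_atom_count: int


def _exocyclic_oxygens(mol: Chem.Mol, ring: FrozenSet[int]) -> Set[int]:
    """Oxygens single-bonded to ring carbons from outside the ring."""
    oxy = set()
    for idx in ring:
        atom = mol.GetAtomWithIdx(idx)
        if atom.GetAtomicNum() != 6:
            continue
        for nb in atom.GetNeighbors():
            j = nb.GetIdx()
            if j in ring or nb.GetAtomicNum() != 8:
                continue
            if mol.GetBondBetweenAtoms(idx, j).GetBondType() == Chem.BondType.SINGLE:
                oxy.add(j)
    return oxy


def detect_circular_sugars(mol: Chem.Mol, rules: SugarRules = DEFAULT_RULES) -> List[FrozenSet[int]]:
    """Return the atom-index sets of sugar-like rings (ring atoms only)."""
    ring_info = mol.GetRingInfo()
    membership = [0] * mol.GetNumAtoms()
    for ring in ring_info.AtomRings():
        for idx in ring:
            membership[idx] += 1

    found: List[FrozenSet[int]] = []
    claimed: Set[int] = set()
    for ring in ring_info.AtomRings():
        size = len(ring)
        if size not in rules.ring_sizes:
            continue
        atoms = [mol.GetAtomWithIdx(i) for i in ring]
        if sum(a.GetAtomicNum() == 8 for a in atoms) != 1:
            continue
        if any(a.GetAtomicNum() not in (6, 8) for a in atoms):
            continue
        if any(a.GetIsAromatic() for a in atoms):
            continue
        if any(membership[i] > 1 for i in ring):  # fused to another ring
            continue
        if claimed.intersection(ring):
            continue
        ring_set = frozenset(ring)
        if len(_exocyclic_oxygens(mol, ring_set)) < size - rules.exocyclic_oxygen_deficit:
            continue
        found.append(ring_set)
        claimed.update(ring)
    return found


def detect_linear_sugars(mol: Chem.Mol, rules: SugarRules = DEFAULT_RULES) -> List[FrozenSet[int]]:
    """Return atom-index sets of open-chain sugar moieties (chain carbons
    plus their oxygen substituents)."""
    candidates = set()
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 6 or atom.IsInRing():
            continue
        oxygens = [nb.GetIdx() for nb in atom.GetNeighbors()
                   if nb.GetAtomicNum() == 8 and not nb.IsInRing()]
        if len(oxygens) == 1:
            candidates.add(atom.GetIdx())

    # connected components of candidate carbons over C–C bonds
    seen: Set[int] = set()
    found: List[FrozenSet[int]] = []
    for start in sorted(candidates):
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        while stack:
            i = stack.pop()
            for nb in mol.GetAtomWithIdx(i).GetNeighbors():
                j = nb.GetIdx()
                if j in candidates and j not in comp:
                    comp.add(j)
                    stack.append(j)
        seen |= comp
        if rules.min_chain_length <= len(comp) <= rules.max_chain_length:
            oxy = {nb.GetIdx() for i in comp for nb in mol.GetAtomWithIdx(i).GetNeighbors()
                   if nb.GetAtomicNum() == 8}
            found.append(frozenset(comp | oxy))
    return found


def _removal_set(mol: Chem.Mol, core: Set[int]) -> Set[int]:
    """Core sugar atoms plus their oxygen substituents, keeping any oxygen
    that bridges two non-sugar heavy atoms."""
    to_remove = set(core)
    for idx in core:
        for nb in mol.GetAtomWithIdx(idx).GetNeighbors():
            if nb.GetAtomicNum() != 8 or nb.GetIdx() in core:
                continue
            outside = sum(
                1 for nb2 in nb.GetNeighbors()
                if nb2.GetIdx() not in core and nb2.GetAtomicNum() > 1
            )
            if outside < 2:
                to_remove.add(nb.GetIdx())
    return to_remove


def remove_sugars(mol: Chem.Mol, rules: SugarRules = DEFAULT_RULES) -> SugarRemovalResult:
    """Strip circular then linear sugar moieties and return the aglycone.

    Sugar-free molecules come back unchanged (identical canonical SMILES);
    the operation is idempotent on its own output.
    """
    circular = detect_circular_sugars(mol, rules)
    linear_core: Set[int] = set()
    claimed = {i for ring in circular for i in ring}
    for chain in detect_linear_sugars(mol, rules):
        if not claimed.intersection(chain):
            linear_core |= {i for i in chain if mol.GetAtomWithIdx(i).GetAtomicNum() == 6}

    had_circular = bool(circular)
    had_linear = bool(linear_core)
    if not had_circular and not had_linear:
        return SugarRemovalResult(mol, False, False, 0)

    core = {i for ring in circular for i in ring} | linear_core
    to_remove = _removal_set(mol, core)

    rw = Chem.RWMol(mol)
    for idx in sorted(to_remove, reverse=True):
        rw.RemoveAtom(idx)
    remainder = rw.GetMol()

    aglycone: Optional[Chem.Mol] = None
    if remainder.GetNumAtoms():
        try:
            Chem.SanitizeMol(remainder)
            frags = Chem.GetMolFrags(remainder, asMols=True, sanitizeFrags=True)
            best = max(frags, key=lambda m: (m.GetNumAtoms(), Chem.MolToSmiles(m)))
            if best.GetNumAtoms() >= rules.min_aglycone_heavy_atoms:
                aglycone = best
        except Chem.MolSanitizeException:
            aglycone = None

    removed = sum(1 for i in to_remove if mol.GetAtomWithIdx(i).GetAtomicNum() > 1)
    return SugarRemovalResult(aglycone, had_circular, had_linear, removed)
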