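"""Deterministic synthetic corpora for training and testing.

Real NP/SM training corpora are hundreds of thousands of molecules pulled
from public databases; these fixtures emulate, at desk scale, the
statistical contrast the scorer relies on: natural-product-like molecules
are assembled from an oxygen-rich template grammar (polyol-decorated
carbocycles, lactones, terpenoid chains, a flavanone scaffold, optional
pyranose decoration on a configurable fraction), synthetic-like molecules
from a halogenated-aromatic / sulfonamide / urea / nitroarene grammar.  The
two grammars deliberately share benzene cores so that scoring exercises
mixed and unknown-fragment paths rather than trivially disjoint fragment
sets.

Template-grammar assembly (not random graph generation) guarantees chemical
validity by construction; every generated structure is nevertheless checked
with RDKit and deduplicated on canonical SMILES.  The same
:class:`FixtureSpec` always produces byte-identical output files.

What these fixtures do *not* have: the structural breadth, ring-system
diversity, or label noise of real corpora.  Separation results on them show
the training/scoring machinery works, not how well the score transfers to
real chemical space.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import List, Tuple

from rdkit import Chem

#: glycosyl units attached through a glycosidic oxygen: a glucopyranose and
#: a ribofuranose (ring-closure digit 8 cannot collide with any template's
#: open ring bonds)
GLUCOSYL = "OC8OC(CO)C(O)C(O)C8O"
RIBOSYL = "OC8OC(CO)C(O)C8O"
SUGAR_UNITS = [GLUCOSYL, RIBOSYL]

NP_TEMPLATES = [
    "OC1CC({y})CC(O)C1{x}",
    "CC1(C)CC(O)C({y})C(O)C1{x}",
    "O=C1OC(C{y})CC1{x}",
    "CC(C)=CCCC(C)(O)C1CC(O)C({y})CC1{x}",
    "O=C1CC(c2ccc({x})cc2)Oc2cc({y})cc(O)c12",
    "OCC1OC(=O)C({y})C1{x}",
]

NP_SUBSTITUENTS = [
    "O", "C", "CO", "OC", "CC", "CCO", "CC(C)O", "C(C)C", "CCC",
    "C(=O)O", "C(=O)OC", "CC=C", "C(C)(C)O", "CCCO",
]

SM_TEMPLATES = [
    "Clc1ccc({x})c({y})c1",
    "CN(C{x})S(=O)(=O)c1ccc({y})cc1",
    "O=C(Nc1ccc(Cl)cc1{x})N{y}",
    "Clc1cc({x})ccc1C(=O)N{y}",
    "FC(F)(F)c1ccc({x})cc1{y}",
    "Brc1cc({y})ccc1{x}",
]

SM_SUBSTITUENTS = [
    "Cl", "F", "Br", "C", "CC", "N", "C#N", "OC", "N(C)C",
    "C(F)(F)F", "[N+](=O)[O-]",
]


@dataclass(frozen=True)
class FixtureSpec:
    n_np: int
    n_sm: int
    seed: int
    sugar_fraction: float = 0.4

    def __post_init__(self):
        if self.n_np < 10 or self.n_sm < 10:
            raise ValueError("need at least 10 molecules per class")
        if not 0.0 <= self.sugar_fraction <= 1.0:
            raise ValueError("sugar_fraction must be in [0, 1]")


def _generate_class(
    rng: random.Random,
    n: int,
    templates: List[str],
    substituents: List[str],
    sugar_fraction: float,
) -> List[Tuple[str, bool]]:
    """Return n unique (smiles, sugar_decorated) pairs.

    Exactly ``round(n * sugar_fraction)`` molecules carry a glycosyl unit;
    decorated and plain molecules are generated to target counts so that
    canonical-SMILES deduplication cannot skew the sugar fraction.
    """
    n_sugared = round(n * sugar_fraction)
    out: List[Tuple[str, bool]] = []
    seen = set()
    attempts = 0
    max_attempts = 400 * n
    n_have_sugared = 0
    while len(out) < n:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"fixture grammar exhausted: only {len(out)} of {n} unique molecules"
            )
        template = rng.choice(templates)
        sugared = n_have_sugared < n_sugared
        if sugared:
            sugar = rng.choice(SUGAR_UNITS)
            if rng.random() < 0.5:
                x, y = sugar, rng.choice(substituents)
            else:
                x, y = rng.choice(substituents), sugar
        else:
            x, y = rng.choice(substituents), rng.choice(substituents)
        smiles = template.format(x=x, y=y)
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:  # grammar should never produce this
            continue
        key = Chem.MolToSmiles(mol)
        if key in seen:
            continue
        seen.add(key)
        out.append((smiles, sugared))
        n_have_sugared += int(sugared)
    rng.shuffle(out)
    return out


def generate_molecules(spec: FixtureSpec):
    """In-memory generation: two lists of (smiles, sugar_decorated)."""
    rng = random.Random(spec.seed)
    np_mols = _generate_class(rng, spec.n_np, NP_TEMPLATES, NP_SUBSTITUENTS, spec.sugar_fraction)
    sm_mols = _generate_class(rng, spec.n_sm, SM_TEMPLATES, SM_SUBSTITUENTS, 0.0)
    return np_mols, sm_mols


def generate_corpora(spec: FixtureSpec, out_dir) -> Tuple[Path, Path, Path]:
    """Write np.smi, sm.smi and an answer-key TSV; returns the three paths.

    The answer key lists, per molecule: id, class, whether a pyranose was
    attached (the expected circular-sugar flag) and the expected score sign.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np_mols, sm_mols = generate_molecules(spec)

    np_path = out_dir / "np.smi"
    sm_path = out_dir / "sm.smi"
    key_path = out_dir / "answer_key.tsv"

    with open(np_path, "w") as fh:
        fh.write("# synthetic NP-like fixture corpus\n")
        for i, (smiles, _) in enumerate(np_mols, start=1):
            fh.write(f"{smiles} np{i}\n")
    with open(sm_path, "w") as fh:
        fh.write("# synthetic SM-like fixture corpus\n")
        for i, (smiles, _) in enumerate(sm_mols, start=1):
            fh.write(f"{smiles} sm{i}\n")
    with open(key_path, "w") as fh:
        fh.write("record_id\tclass\texpected_sugar\texpected_score_sign\n")
        for i, (_, sugared) in enumerate(np_mols, start=1):
            fh.write(f"np{i}\tNP\t{int(sugared)}\t+\n")
        for i, (_, sugared) in enumerate(sm_mols, start=1):
            fh.write(f"sm{i}\tSM\t{int(sugared)}\t-\n")
    return np_path, sm_path, key_path
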