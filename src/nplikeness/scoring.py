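"""Fragment frequency training and natural-product-likeness scoring.

Training counts, for every height-``h`` atom-signature fragment *i*, its
occurrences ``NP_i`` across a natural-product corpus and ``SM_i`` across a
synthetic-molecule corpus (a fragment occurring three times in one molecule
contributes 3).  Its score is the per-molecule-normalised log odds

    Frag_i = log[ (NP_i / SM_i) * (SM_t / NP_t) ]

with ``NP_t``/``SM_t`` the number of molecules per corpus: positive scores
mark fragments over-represented in natural products, negative ones mark
synthetic-leaning fragments, and the totals ratio corrects for corpus-size
imbalance.  A molecule's NP-likeness is the size-normalised sum

    NPls = sum_i Frag_i / N

over its fragments with multiplicity, where ``N`` counts only fragments
known to the trained table: unknown fragments raise an alert and are
excluded from both numerator and denominator, so the score stays a weighted
average of known fragment scores (and is null when no fragment is known).

Numerical form: ``Frag_i`` is evaluated as a single sign-canonical log of
the integer products ``(NP_i + p) * SM_t`` and ``(SM_i + p) * NP_t`` so that
swapping the two corpora negates every score bit-exactly, and multiplying
all counts and totals by a common factor changes nothing bit-exactly
(pseudocount 0).  The additive pseudocount ``p`` (default 1, on the
fragment counts only) keeps the score defined when a fragment is absent
from one class, which is common; it preserves score 0 for fragments equally
frequent in balanced corpora.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, List, Optional, Tuple

from rdkit import Chem

from .curation import CuratedMolecule
from .signatures import DEFAULT_HEIGHT, molecular_signature

logger = logging.getLogger("nplikeness")

DEFAULT_PSEUDOCOUNT = 1.0


class SugarMode(str, Enum):
    WITH_SUGAR = "WITH_SUGAR"
    WITHOUT_SUGAR = "WITHOUT_SUGAR"


class LogBase(str, Enum):
    NATURAL = "natural"
    TEN = "10"


def fragment_score(
    np_count: int,
    sm_count: int,
    np_total: int,
    sm_total: int,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    log_base: LogBase | str = LogBase.NATURAL,
) -> float:
    """Log-ratio frequency score of one fragment (see module docstring)."""
    if np_total < 1 or sm_total < 1:
        raise ValueError("both corpus totals must be >= 1")
    if np_count + sm_count < 1:
        raise ValueError("a fragment absent from both classes has no score")
    num = (np_count + pseudocount) * sm_total
    den = (sm_count + pseudocount) * np_total
    if num == 0:
        return -math.inf  # fragment never seen in NPs, no smoothing
    if den == 0:
        return math.inf
    log = math.log if LogBase(log_base) is LogBase.NATURAL else math.log10
    # sign-canonical: swapping the classes swaps num/den and negates exactly
    return log(num / den) if num >= den else -log(den / num)


@dataclass
class FragmentEntry:
    fragment_id: int
    height: int
    np_count: int
    sm_count: int
    score: float


@dataclass
class FragmentTable:
    """Trained mapping signature string -> counts and score, plus totals."""

    entries: Dict[str, FragmentEntry]
    np_total: int
    sm_total: int
    height: int
    sugar_mode: SugarMode
    log_base: LogBase = LogBase.NATURAL
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def score_of(self, signature: str) -> Optional[float]:
        entry = self.entries.get(signature)
        return entry.score if entry is not None else None


def _training_smiles(mol: CuratedMolecule, sugar_mode: SugarMode) -> Optional[str]:
    if sugar_mode is SugarMode.WITH_SUGAR:
        return mol.smiles
    return mol.aglycone_smiles


def count_fragments(
    np_mols: List[CuratedMolecule],
    sm_mols: List[CuratedMolecule],
    height: int = DEFAULT_HEIGHT,
    sugar_mode: SugarMode = SugarMode.WITHOUT_SUGAR,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    log_base: LogBase = LogBase.NATURAL,
) -> FragmentTable:
    """Count fragment occurrences per class and build a scored table.

    In WITHOUT_SUGAR mode, molecules whose sugar removal left no aglycone
    are skipped (logged) and do not count towards the corpus totals.
    Fragment ids are assigned in sorted signature order, so identical
    corpora always yield an identical table.
    """
    if not np_mols or not sm_mols:
        raise ValueError("both training classes must be non-empty")

    counts: Dict[str, List[int]] = {}
    totals = [0, 0]
    for cls, mols in enumerate((np_mols, sm_mols)):
        for mol in mols:
            smiles = _training_smiles(mol, sugar_mode)
            if smiles is None:
                logger.info("molecule %d: no aglycone after sugar removal — skipped from %s training",
                            mol.molecule_id, sugar_mode.value)
                continue
            sig = molecular_signature(Chem.MolFromSmiles(smiles), height)
            totals[cls] += 1
            for s, mult in sig.counts.items():
                counts.setdefault(s, [0, 0])[cls] += mult
    if not totals[0] or not totals[1]:
        raise ValueError("a training class is empty after sugar removal")

    entries = {}
    for fid, s in enumerate(sorted(counts), start=1):
        npc, smc = counts[s]
        entries[s] = FragmentEntry(
            fid, height, npc, smc,
            fragment_score(npc, smc, totals[0], totals[1], pseudocount, log_base),
        )
    return FragmentTable(entries, totals[0], totals[1], height, sugar_mode, log_base, pseudocount)


@dataclass
class ScoreResult:
    """Per-molecule NP-likeness with unknown-fragment accounting."""

    record_id: str
    smiles: str = ""
    np_likeness: Optional[float] = None
    np_likeness_with_sugar: Optional[float] = None
    n_fragments_used: int = 0
    n_unknown_fragments: int = 0
    heavy_atom_count: int = 0
    total_atom_count: int = 0
    ring_count: int = 0
    alerts: List[str] = field(default_factory=list)


def _average_score(sig_counts: Dict[str, int], table: FragmentTable) -> Tuple[Optional[float], int, int]:
    """(score, n_used, n_unknown): multiplicity-weighted mean of known
    fragment scores; None when every fragment is unknown."""
    used = 0
    unknown = 0
    terms = []
    for s, mult in sig_counts.items():
        score = table.score_of(s)
        if score is None:
            unknown += mult
            continue
        used += mult
        terms.append(mult * score)
    if used == 0:
        return None, 0, unknown
    return math.fsum(terms) / used, used, unknown


def score_molecule(mol: CuratedMolecule, table: FragmentTable, record_id: str = "") -> ScoreResult:
    """Score one curated molecule against a trained table.

    With a WITHOUT_SUGAR table the aglycone is scored; a molecule that is
    entirely sugar gets a null score and an alert.  Unknown fragments are
    excluded from the computation and alerted.
    """
    result = ScoreResult(
        record_id=record_id or str(mol.molecule_id),
        smiles=mol.smiles,
        heavy_atom_count=mol.heavy_atom_count,
        total_atom_count=mol.total_atom_count,
        ring_count=mol.ring_count,
    )
    smiles = _training_smiles(mol, table.sugar_mode)
    if smiles is None:
        result.alerts.append("no aglycone left after sugar removal; no score")
        return result
    sig = molecular_signature(Chem.MolFromSmiles(smiles), table.height)
    score, used, unknown = _average_score(sig.counts, table)
    result.np_likeness = score
    result.n_fragments_used = used
    result.n_unknown_fragments = unknown
    if table.sugar_mode is SugarMode.WITH_SUGAR:
        result.np_likeness_with_sugar = score
    if unknown:
        result.alerts.append(f"{unknown} fragment occurrence(s) not in the trained table; excluded from the score")
    if score is None and unknown:
        result.alerts.append("no known fragments; score undefined")
    return result


def score_molecule_both(
    mol: CuratedMolecule,
    table_without: FragmentTable,
    table_with: FragmentTable,
    record_id: str = "",
) -> ScoreResult:
    """Score against both sugar modes; np_likeness is the sugar-free score."""
    result = score_molecule(mol, table_without, record_id)
    with_res = score_molecule(mol, table_with, record_id)
    result.np_likeness_with_sugar = with_res.np_likeness
    for alert in with_res.alerts:
        tagged = f"[with sugar] {alert}"
        if tagged not in result.alerts:
            result.alerts.append(tagged)
    return result


def retrain_scores(store, height: int = DEFAULT_HEIGHT) -> None:
    """Recompute every fragment score and every stored molecule score.

    Useful after new molecules have been ingested: counts and totals are
    read back from the store, scores re-derived from them, and each stored
    molecule rescored through its fragment relations.  Running it twice in
    a row changes nothing.
    """
    store.retrain(height)


# --- FragmentTable persistence (TSV + JSON sidecar, lossless) ---------------

TABLE_COLUMNS = ["canonical_string", "height", "np_count", "sm_count", "score"]


def save_fragment_table(table: FragmentTable, tsv_path) -> None:
    tsv_path = Path(tsv_path)
    with open(tsv_path, "w") as fh:
        fh.write("\t".join(TABLE_COLUMNS) + "\n")
        for s, e in sorted(table.entries.items()):
            fh.write(f"{s}\t{e.height}\t{e.np_count}\t{e.sm_count}\t{e.score!r}\n")
    sidecar = {
        "np_total": table.np_total,
        "sm_total": table.sm_total,
        "height": table.height,
        "sugar_mode": table.sugar_mode.value,
        "log_base": table.log_base.value,
        "pseudocount": table.pseudocount,
    }
    with open(tsv_path.with_suffix(tsv_path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_fragment_table(tsv_path) -> FragmentTable:
    tsv_path = Path(tsv_path)
    with open(tsv_path.with_suffix(tsv_path.suffix + ".json")) as fh:
        meta = json.load(fh)
    entries: Dict[str, FragmentEntry] = {}
    with open(tsv_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != TABLE_COLUMNS:
            raise ValueError(f"unexpected fragment-table header in {tsv_path}")
        for fid, line in enumerate(fh, start=1):
            s, h, npc, smc, score = line.rstrip("\n").split("\t")
            entries[s] = FragmentEntry(fid, int(h), int(npc), int(smc), float(score))
    return FragmentTable(
        entries,
        np_total=meta["np_total"],
        sm_total=meta["sm_total"],
        height=meta["height"],
        sugar_mode=SugarMode(meta["sugar_mode"]),
        log_base=LogBase(meta["log_base"]),
        pseudocount=meta["pseudocount"],
    )
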