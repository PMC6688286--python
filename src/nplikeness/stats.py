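"""Corpus-level statistics: score distributions and repeated-fragment
profiles.

A fragment is *repeated* in a molecule when its signature occurs there with
multiplicity >= 2.  Hydrogen-centred fragments are not informative for this
(almost every molecule repeats some H-centred environment), so the headline
count is restricted to non-H centres; oxygen- and nitrogen-centred repeats
are profiled separately because the density of repeated oxygen environments
is a hallmark that separates natural products from synthetic molecules.
The O/N fractions are conditioned on element presence: only molecules that
contain at least one O (resp. N) enter the denominator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Dict, Optional, Tuple

import numpy as np

from .scoring import SugarMode
from .signatures import MolecularSignature, center_element


@dataclass
class RepeatedFragmentProfile:
    n_repeated_non_h: int
    has_repeated_o: bool
    has_repeated_n: bool


def repeated_fragment_profile(sig: MolecularSignature) -> RepeatedFragmentProfile:
    """Count distinct repeated non-H-centred signatures; flag O/N centres."""
    n_non_h = 0
    has_o = False
    has_n = False
    for s, mult in sig.counts.items():
        if mult < 2:
            continue
        center = center_element(s)
        if center == "H":
            continue
        n_non_h += 1
        has_o = has_o or center == "O"
        has_n = has_n or center == "N"
    return RepeatedFragmentProfile(n_non_h, has_o, has_n)


@dataclass
class ClassStats:
    n: int
    score_min: Optional[float]
    score_max: Optional[float]
    score_mean: Optional[float]
    frac_repeated_non_h: Optional[float]
    frac_repeated_o_centred: Optional[float]  # among O-containing molecules
    frac_repeated_n_centred: Optional[float]  # among N-containing molecules
    top_fragments: list


@dataclass
class CorpusStats:
    np_stats: Optional[ClassStats]
    sm_stats: Optional[ClassStats]

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _has_repeated_center(store, molecule_id: int, center: str) -> bool:
    for (signature,) in store.conn.execute(
        "SELECT f.signature FROM molecule_fragment_cpd c"
        " JOIN fragment_with_sugar f ON f.fragment_id = c.fragment_id"
        " WHERE c.molecule_id = ? AND c.with_sugar = 1 AND c.occurrences >= 2",
        (molecule_id,),
    ):
        if center_element(signature) == center:
            return True
    return False


def _class_stats(store, is_np: bool, score_column: str, top_k: int) -> Optional[ClassStats]:
    rows = store.conn.execute(
        f"SELECT molecule_id, {score_column}, n_repeated_fragments, o_count, n_count"
        " FROM molecule WHERE is_np = ? AND is_biogenic = 0 ORDER BY molecule_id",
        (int(is_np),),
    ).fetchall()
    if not rows:
        return None
    scores = np.array([r[1] for r in rows if r[1] is not None], dtype=float)
    n_repeated = sum(1 for r in rows if (r[2] or 0) > 0)

    with_o = [r for r in rows if r[3] > 0]
    with_n = [r for r in rows if r[4] > 0]
    frac_o = (
        sum(_has_repeated_center(store, r[0], "O") for r in with_o) / len(with_o)
        if with_o else None
    )
    frac_n = (
        sum(_has_repeated_center(store, r[0], "N") for r in with_n) / len(with_n)
        if with_n else None
    )

    table = "fragment_with_sugar"
    order = "DESC" if is_np else "ASC"
    top = store.conn.execute(
        f"SELECT signature, score FROM {table} WHERE score IS NOT NULL"
        f" ORDER BY score {order}, signature LIMIT ?", (top_k,)
    ).fetchall()

    return ClassStats(
        n=len(rows),
        score_min=float(scores.min()) if scores.size else None,
        score_max=float(scores.max()) if scores.size else None,
        score_mean=float(scores.mean()) if scores.size else None,
        frac_repeated_non_h=n_repeated / len(rows),
        frac_repeated_o_centred=frac_o,
        frac_repeated_n_centred=frac_n,
        top_fragments=[list(t) for t in top],
    )


def corpus_stats(store, sugar_mode: SugarMode = SugarMode.WITHOUT_SUGAR, top_k: int = 10) -> CorpusStats:
    """Aggregate per-class statistics over a trained, scored store."""
    column = "score_with_sugar" if sugar_mode is SugarMode.WITH_SUGAR else "score_without_sugar"
    return CorpusStats(
        np_stats=_class_stats(store, True, column, top_k),
        sm_stats=_class_stats(store, False, column, top_k),
    )


def score_histogram(store, sugar_mode: SugarMode = SugarMode.WITHOUT_SUGAR,
                    bin_width: float = 0.25) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """Per-class score histograms (counts, bin edges) at fixed bin width."""
    column = "score_with_sugar" if sugar_mode is SugarMode.WITH_SUGAR else "score_without_sugar"
    out = {}
    for label, is_np in (("NP", 1), ("SM", 0)):
        scores = [
            r[0] for r in store.conn.execute(
                f"SELECT {column} FROM molecule WHERE is_np = ? AND is_biogenic = 0"
                f" AND {column} IS NOT NULL", (is_np,)
            )
        ]
        if not scores:
            continue
        lo = np.floor(min(scores) / bin_width) * bin_width
        hi = np.ceil(max(scores) / bin_width) * bin_width
        edges = np.arange(lo, hi + bin_width / 2, bin_width)
        if len(edges) < 2:
            edges = np.array([lo, lo + bin_width])
        counts, edges = np.histogram(scores, bins=edges)
        out[label] = (counts, edges)
    return out
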