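"""Embedded relational store for molecules, fragments and their relations.

A single-file SQLite database with five content tables (see ``schema.sql``)
plus a key/value ``meta`` table that records the run configuration (height,
log base, pseudocount) so any trained store is self-describing.  Fragment
counts and corpus totals are all derivable from the stored rows, which is
what makes full retraining (execution option "rescore") possible without
the original input files.
"""

from __future__ import annotations

import json
import logging
import sqlite3
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

from rdkit import Chem

from .chem_io import MoleculeRecord
from .curation import CuratedMolecule
from .scoring import (
    DEFAULT_PSEUDOCOUNT,
    FragmentEntry,
    FragmentTable,
    LogBase,
    SugarMode,
    fragment_score,
)
from .signatures import DEFAULT_HEIGHT, center_element, molecular_signature

logger = logging.getLogger("nplikeness")

TABLES = ["ori_molecule", "molecule", "fragment_with_sugar", "fragment_without_sugar",
          "molecule_fragment_cpd", "meta"]

_NULL = "\\N"  # TSV dump token for SQL NULL


def _fragment_table_name(sugar_mode: SugarMode) -> str:
    return "fragment_with_sugar" if sugar_mode is SugarMode.WITH_SUGAR else "fragment_without_sugar"


class NPStore:
    """Handle on one store file.  Use as a context manager or call close()."""

    def __init__(self, path, create: bool = False,
                 height: int = DEFAULT_HEIGHT,
                 log_base: LogBase = LogBase.NATURAL,
                 pseudocount: float = DEFAULT_PSEUDOCOUNT):
        self.path = str(path)
        exists = Path(self.path).exists() and Path(self.path).stat().st_size > 0
        self.conn = sqlite3.connect(self.path)
        self.conn.execute("PRAGMA foreign_keys = ON")
        if not exists:
            if not create:
                raise FileNotFoundError(f"store not found: {path}")
            ddl = resources.files("nplikeness").joinpath("schema.sql").read_text()
            with self.conn:
                self.conn.executescript(ddl)
                self._set_meta("height", str(height))
                self._set_meta("log_base", LogBase(log_base).value)
                self._set_meta("pseudocount", repr(float(pseudocount)))

    # -- meta ----------------------------------------------------------------

    def _set_meta(self, key: str, value: str) -> None:
        self.conn.execute("INSERT OR REPLACE INTO meta (key, value) VALUES (?, ?)", (key, value))

    def get_meta(self, key: str) -> Optional[str]:
        row = self.conn.execute("SELECT value FROM meta WHERE key = ?", (key,)).fetchone()
        return row[0] if row else None

    @property
    def height(self) -> int:
        return int(self.get_meta("height") or DEFAULT_HEIGHT)

    @property
    def log_base(self) -> LogBase:
        return LogBase(self.get_meta("log_base") or LogBase.NATURAL.value)

    @property
    def pseudocount(self) -> float:
        value = self.get_meta("pseudocount")
        return float(value) if value is not None else DEFAULT_PSEUDOCOUNT

    def set_config_snapshot(self, config: dict) -> None:
        with self.conn:
            self._set_meta("config_snapshot", json.dumps(config, sort_keys=True))

    # -- ingest ---------------------------------------------------------------

    def ingest(self, curated: List[CuratedMolecule], raw: List[MoleculeRecord]) -> None:
        """Append raw records, upsert curated molecules, insert fragments.

        Raw rows always accumulate (``ori_molecule`` is allowed to be
        redundant); a curated molecule whose structural key is already
        present changes nothing, so re-ingesting a file never double-counts
        fragments.  Everything happens in one transaction.
        """
        height = self.height
        try:
            with self.conn:
                for rec in raw:
                    mol = Chem.MolFromSmiles(rec.smiles)
                    inchikey = Chem.MolToInchiKey(mol) if mol is not None else None
                    self.conn.execute(
                        "INSERT INTO ori_molecule (record_id, source_id, source_db, smiles,"
                        " inchikey, submission_date, status) VALUES (?, ?, ?, ?, ?, ?, ?)",
                        (rec.record_id, rec.source_id, rec.source_db, rec.smiles,
                         inchikey, rec.submission_date, rec.status.value),
                    )
                for mol in curated:
                    self._ingest_curated(mol, height)
        except sqlite3.Error as exc:
            raise RuntimeError(f"store ingest failed and was rolled back: {exc}") from exc

    def _ingest_curated(self, mol: CuratedMolecule, height: int) -> None:
        row = self.conn.execute(
            "SELECT molecule_id FROM molecule WHERE structural_key = ?", (mol.structural_key,)
        ).fetchone()
        if row is not None:
            return
        sig_with = molecular_signature(Chem.MolFromSmiles(mol.smiles), height)
        n_repeated = sum(
            1 for s, m in sig_with.counts.items() if m >= 2 and center_element(s) != "H"
        )
        cur = self.conn.execute(
            "INSERT INTO molecule (structural_key, smiles, aglycone_smiles, is_np, is_biogenic,"
            " contains_sugar, heavy_atom_count, total_atom_count, heavy_atom_count_no_sugar,"
            " total_atom_count_no_sugar, ring_count, n_repeated_fragments, c_count, o_count, n_count)"
            " VALUES (?, ?, ?, ?, ?, ?, ?, ?, ?, ?, ?, ?, ?, ?, ?)",
            (mol.structural_key, mol.smiles, mol.aglycone_smiles, int(mol.is_np),
             int(mol.is_biogenic), int(mol.contains_sugar), mol.heavy_atom_count,
             mol.total_atom_count, mol.heavy_atom_count_no_sugar, mol.total_atom_count_no_sugar,
             mol.ring_count, n_repeated, mol.c_count, mol.o_count, mol.n_count),
        )
        molecule_id = cur.lastrowid
        self._insert_fragments(molecule_id, mol, sig_with.counts, SugarMode.WITH_SUGAR, height)
        if mol.aglycone_smiles is not None:
            sig_wo = molecular_signature(Chem.MolFromSmiles(mol.aglycone_smiles), height)
            self._insert_fragments(molecule_id, mol, sig_wo.counts, SugarMode.WITHOUT_SUGAR, height)

    def _insert_fragments(self, molecule_id: int, mol: CuratedMolecule,
                          counts: Dict[str, int], sugar_mode: SugarMode, height: int) -> None:
        table = _fragment_table_name(sugar_mode)
        train_np = mol.is_np and not mol.is_biogenic
        train_sm = not mol.is_np and not mol.is_biogenic
        for signature, mult in counts.items():
            row = self.conn.execute(
                f"SELECT fragment_id FROM {table} WHERE signature = ?", (signature,)
            ).fetchone()
            if row is None:
                fragment_id = self.conn.execute(
                    f"INSERT INTO {table} (signature, height) VALUES (?, ?)", (signature, height)
                ).lastrowid
            else:
                fragment_id = row[0]
            if train_np:
                self.conn.execute(
                    f"UPDATE {table} SET np_count = np_count + ? WHERE fragment_id = ?",
                    (mult, fragment_id),
                )
            elif train_sm:
                self.conn.execute(
                    f"UPDATE {table} SET sm_count = sm_count + ? WHERE fragment_id = ?",
                    (mult, fragment_id),
                )
            self.conn.execute(
                "INSERT INTO molecule_fragment_cpd (molecule_id, fragment_id, with_sugar,"
                " occurrences) VALUES (?, ?, ?, ?)",
                (molecule_id, fragment_id, int(sugar_mode is SugarMode.WITH_SUGAR), mult),
            )

    # -- queries --------------------------------------------------------------

    def class_totals(self, sugar_mode: SugarMode) -> Tuple[int, int]:
        """(NP total, SM total): molecule counts per training class.

        In WITHOUT_SUGAR mode only molecules with an aglycone count, since
        only those contributed fragments.
        """
        cond = "" if sugar_mode is SugarMode.WITH_SUGAR else " AND aglycone_smiles IS NOT NULL"
        np_total = self.conn.execute(
            f"SELECT COUNT(*) FROM molecule WHERE is_np = 1 AND is_biogenic = 0{cond}"
        ).fetchone()[0]
        sm_total = self.conn.execute(
            f"SELECT COUNT(*) FROM molecule WHERE is_np = 0 AND is_biogenic = 0{cond}"
        ).fetchone()[0]
        return np_total, sm_total

    def query_fragment_scores(self, signatures: Iterable[str], sugar_mode: SugarMode) -> Dict[str, float]:
        """Scores of the given signatures; unknown ones are simply absent."""
        table = _fragment_table_name(sugar_mode)
        out: Dict[str, float] = {}
        for signature in signatures:
            row = self.conn.execute(
                f"SELECT score FROM {table} WHERE signature = ? AND score IS NOT NULL", (signature,)
            ).fetchone()
            if row is not None:
                out[signature] = row[0]
        return out

    def fragment_table(self, sugar_mode: SugarMode) -> FragmentTable:
        """Materialise one trained fragment table from the store."""
        table = _fragment_table_name(sugar_mode)
        np_total, sm_total = self.class_totals(sugar_mode)
        entries: Dict[str, FragmentEntry] = {}
        for fid, signature, height, npc, smc, score in self.conn.execute(
            f"SELECT fragment_id, signature, height, np_count, sm_count, score FROM {table}"
            " WHERE score IS NOT NULL ORDER BY fragment_id"
        ):
            entries[signature] = FragmentEntry(fid, height, npc, smc, score)
        return FragmentTable(entries, np_total, sm_total, self.height, sugar_mode,
                             self.log_base, self.pseudocount)

    def n_molecules(self) -> int:
        return self.conn.execute("SELECT COUNT(*) FROM molecule").fetchone()[0]

    # -- retraining -----------------------------------------------------------

    def retrain(self, height: Optional[int] = None) -> None:
        """Recompute all fragment scores from counts, then rescore every
        stored molecule through its fragment relations (both sugar modes)."""
        if self.n_molecules() == 0:
            raise ValueError("cannot retrain an empty store")
        log_base, pseudocount = self.log_base, self.pseudocount
        with self.conn:
            for sugar_mode in SugarMode:
                table = _fragment_table_name(sugar_mode)
                np_total, sm_total = self.class_totals(sugar_mode)
                if np_total < 1 or sm_total < 1:
                    logger.warning("%s: a training class is empty; scores left untouched", table)
                    continue
                for fid, npc, smc in self.conn.execute(
                    f"SELECT fragment_id, np_count, sm_count FROM {table}"
                ).fetchall():
                    score = (
                        fragment_score(npc, smc, np_total, sm_total, pseudocount, log_base)
                        if npc + smc >= 1 else None
                    )
                    self.conn.execute(
                        f"UPDATE {table} SET score = ? WHERE fragment_id = ?", (score, fid)
                    )
                self._rescore_molecules(sugar_mode)

    def _rescore_molecules(self, sugar_mode: SugarMode) -> None:
        table = _fragment_table_name(sugar_mode)
        column = "score_with_sugar" if sugar_mode is SugarMode.WITH_SUGAR else "score_without_sugar"
        flag = int(sugar_mode is SugarMode.WITH_SUGAR)
        rows = self.conn.execute(
            f"SELECT c.molecule_id, SUM(c.occurrences * f.score), SUM(c.occurrences)"
            f" FROM molecule_fragment_cpd c JOIN {table} f ON f.fragment_id = c.fragment_id"
            f" WHERE c.with_sugar = ? AND f.score IS NOT NULL GROUP BY c.molecule_id",
            (flag,),
        ).fetchall()
        self.conn.execute(f"UPDATE molecule SET {column} = NULL")
        for molecule_id, total, n in rows:
            self.conn.execute(
                f"UPDATE molecule SET {column} = ? WHERE molecule_id = ?", (total / n, molecule_id)
            )

    # -- dump / load ----------------------------------------------------------

    def dump(self, out_dir) -> None:
        """Write each table as a TSV (deterministic row order, lossless)."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for table in TABLES:
            cols = [r[1] for r in self.conn.execute(f"PRAGMA table_info({table})")]
            order = ", ".join(cols)
            with open(out_dir / f"{table}.tsv", "w") as fh:
                fh.write("\t".join(cols) + "\n")
                for row in self.conn.execute(f"SELECT {order} FROM {table} ORDER BY {order}"):
                    fh.write("\t".join(
                        _NULL if v is None else (repr(v) if isinstance(v, float) else str(v))
                        for v in row
                    ) + "\n")

    def load(self, in_dir) -> None:
        """Load TSV dumps into this (empty) store; inverse of :meth:`dump`."""
        in_dir = Path(in_dir)
        if self.n_molecules() or self.conn.execute("SELECT COUNT(*) FROM ori_molecule").fetchone()[0]:
            raise ValueError("refusing to load a dump into a non-empty store")
        with self.conn:
            self.conn.execute("DELETE FROM meta")
            for table in TABLES:
                info = self.conn.execute(f"PRAGMA table_info({table})").fetchall()
                cols = [r[1] for r in info]
                types = [r[2].upper() for r in info]
                with open(in_dir / f"{table}.tsv") as fh:
                    header = fh.readline().rstrip("\n").split("\t")
                    if header != cols:
                        raise ValueError(f"dump column mismatch for table {table}")
                    placeholders = ", ".join("?" for _ in cols)
                    for line in fh:
                        raw = line.rstrip("\n").split("\t")
                        values = []
                        for v, t in zip(raw, types):
                            if v == _NULL:
                                values.append(None)
                            elif t == "INTEGER":
                                values.append(int(v))
                            elif t == "REAL":
                                values.append(float(v))
                            else:
                                values.append(v)
                        self.conn.execute(
                            f"INSERT INTO {table} ({', '.join(cols)}) VALUES ({placeholders})",
                            values,
                        )

    def close(self) -> None:
        self.conn.close()

    def __enter__(self) -> "NPStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()
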