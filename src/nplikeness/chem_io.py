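"""Reading molecule files (SDF / MOL / SMILES) and writing score tables.

Input records keep their provenance: the source database they came from and
their class label — natural product (NP), synthetic molecule (SM) or
biogenic (biogenic molecules are curated and stored but belong to neither
training class).

The ``.smi`` dialect is one molecule per line, whitespace-separated
``SMILES [identifier]``; blank lines and lines starting with ``#`` are
ignored.  Records without an identifier get a generated one, ``m<i>`` with
the 1-based record index.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import List, Optional

from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger("nplikeness")

RDLogger.DisableLog("rdApp.error")  # parse failures are reported through our own log
RDLogger.DisableLog("rdApp.warning")  # InChI stereo warnings are expected: stereo is stripped


class Status(str, Enum):
    NP = "NP"
    SM = "SM"
    BIOGENIC = "BIOGENIC"


class Format(str, Enum):
    SDF = "SDF"
    MOL = "MOL"
    SMI = "SMI"


@dataclass
class MoleculeRecord:
    """One raw input molecule with provenance and class label."""

    record_id: str
    smiles: str
    status: Status
    source_db: str = ""
    source_id: str = ""
    submission_date: str = ""


@dataclass
class ReadReport:
    """Per-file parse accounting; skipped entries are also logged."""

    n_read: int = 0
    n_skipped: int = 0
    skipped: List[str] = field(default_factory=list)


def _read_smi(path: Path, status: Status, source_db: str, report: ReadReport) -> List[MoleculeRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            smiles, name = parts[0], (parts[1] if len(parts) > 1 else "")
            mol = Chem.MolFromSmiles(smiles)
            if mol is None or mol.GetNumAtoms() == 0:
                report.n_skipped += 1
                report.skipped.append(f"line {lineno}")
                logger.warning("%s: line %d: unparseable SMILES %r — skipped", path, lineno, smiles)
                continue
            rid = name or f"m{len(records) + 1}"
            records.append(
                MoleculeRecord(record_id=rid, smiles=smiles, status=status, source_db=source_db, source_id=name)
            )
    return records


def _read_sdf(path: Path, status: Status, source_db: str, report: ReadReport) -> List[MoleculeRecord]:
    records = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
    for idx, mol in enumerate(supplier, start=1):
        if mol is None or mol.GetNumAtoms() == 0:
            report.n_skipped += 1
            report.skipped.append(f"record {idx}")
            logger.warning("%s: record %d: unparseable molblock — skipped", path, idx)
            continue
        name = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
        rid = name or f"m{len(records) + 1}"
        records.append(
            MoleculeRecord(
                record_id=rid, smiles=Chem.MolToSmiles(mol), status=status, source_db=source_db, source_id=name
            )
        )
    return records


def read_molecules(
    path,
    format: Format | str,
    status: Status | str = Status.NP,
    source_db: str = "",
    report: Optional[ReadReport] = None,
) -> List[MoleculeRecord]:
    """Read an SDF, MOL or SMILES file into an ordered list of records.

    Input order is preserved.  Unparseable entries are logged with their
    line/record index and skipped (counted in ``report`` when given).  A
    missing file or a file with zero parseable records is a fatal error.
    MOL files are treated as single-record SDF.
    """
    path = Path(path)
    fmt = Format(format.upper() if isinstance(format, str) else format)
    status = Status(status)
    if not path.exists():
        raise FileNotFoundError(f"molecule file not found: {path}")
    report = report if report is not None else ReadReport()

    if fmt is Format.SMI:
        records = _read_smi(path, status, source_db, report)
    else:  # SDF and MOL share the molblock reader
        records = _read_sdf(path, status, source_db, report)

    report.n_read = len(records)
    if report.n_skipped:
        logger.warning("%s: skipped %d unparseable entr%s", path, report.n_skipped,
                       "y" if report.n_skipped == 1 else "ies")
    if not records:
        raise ValueError(f"no parseable molecule records in {path}")
    return records


RESULT_COLUMNS = [
    "record_id",
    "smiles",
    "np_likeness",
    "np_likeness_with_sugar",
    "heavy_atom_count",
    "total_atom_count",
    "ring_count",
    "n_unknown_fragments",
    "alerts",
]


def write_results(results, path) -> None:
    """Write score results as CSV, one row per molecule, input order kept.

    Raises ``ValueError`` on an empty result list (no file is created) and
    ``OSError`` on an unwritable path.
    """
    if not results:
        raise ValueError("refusing to write an empty result list")
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(RESULT_COLUMNS)
        for r in results:
            writer.writerow(
                [
                    r.record_id,
                    r.smiles,
                    "" if r.np_likeness is None else repr(r.np_likeness),
                    "" if r.np_likeness_with_sugar is None else repr(r.np_likeness_with_sugar),
                    r.heavy_atom_count,
                    r.total_atom_count,
                    r.ring_count,
                    r.n_unknown_fragments,
                    "; ".join(r.alerts),
                ]
            )
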