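-- Relational schema of the NP-likeness fragment store (embedded SQLite).
--
-- ori_molecule keeps every raw submission, redundantly, with provenance;
-- molecule holds unique curated structures (stereo-free structural identity);
-- fragment_with_sugar / fragment_without_sugar hold the trained atom-signature
-- fragments for the two sugar modes; molecule_fragment_cpd relates molecules
-- to fragments with per-molecule occurrence counts.

CREATE TABLE ori_molecule (
    ori_id          INTEGER PRIMARY KEY,
    record_id       TEXT NOT NULL,
    source_id       TEXT,
    source_db       TEXT,
    smiles          TEXT NOT NULL,
    inchikey        TEXT,
    submission_date TEXT,
    status          TEXT NOT NULL CHECK (status IN ('NP', 'SM', 'BIOGENIC'))
);

CREATE TABLE molecule (
    molecule_id               INTEGER PRIMARY KEY,
    structural_key            TEXT NOT NULL UNIQUE,
    smiles                    TEXT NOT NULL,
    aglycone_smiles           TEXT,
    is_np                     INTEGER NOT NULL,
    is_biogenic               INTEGER NOT NULL,
    contains_sugar            INTEGER NOT NULL,
    score_with_sugar          REAL,
    score_without_sugar       REAL,
    heavy_atom_count          INTEGER NOT NULL,
    total_atom_count          INTEGER NOT NULL,
    heavy_atom_count_no_sugar INTEGER,
    total_atom_count_no_sugar INTEGER,
    ring_count                INTEGER NOT NULL,
    n_repeated_fragments      INTEGER,
    c_count                   INTEGER NOT NULL,
    o_count                   INTEGER NOT NULL,
    n_count                   INTEGER NOT NULL
);

CREATE TABLE fragment_with_sugar (
    fragment_id INTEGER PRIMARY KEY,
    signature   TEXT NOT NULL UNIQUE,
    height      INTEGER NOT NULL,
    np_count    INTEGER NOT NULL DEFAULT 0,
    sm_count    INTEGER NOT NULL DEFAULT 0,
    score       REAL
);

CREATE TABLE fragment_without_sugar (
    fragment_id INTEGER PRIMARY KEY,
    signature   TEXT NOT NULL UNIQUE,
    height      INTEGER NOT NULL,
    np_count    INTEGER NOT NULL DEFAULT 0,
    sm_count    INTEGER NOT NULL DEFAULT 0,
    score       REAL
);

-- with_sugar = 1 references fragment_with_sugar, 0 references
-- fragment_without_sugar (SQLite cannot express the conditional FK).
CREATE TABLE molecule_fragment_cpd (
    molecule_id INTEGER NOT NULL REFERENCES molecule (molecule_id),
    fragment_id INTEGER NOT NULL,
    with_sugar  INTEGER NOT NULL CHECK (with_sugar IN (0, 1)),
    occurrences INTEGER NOT NULL CHECK (occurrences >= 1),
    PRIMARY KEY (molecule_id, fragment_id, with_sugar)
);

CREATE TABLE meta (
    key   TEXT PRIMARY KEY,
    value TEXT
);
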