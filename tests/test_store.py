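import filecmp

import pytest

from nplikeness import (
    MoleculeRecord,
    NPStore,
    Status,
    SugarMode,
    curate,
    retrain_scores,
)
from tests.conftest import records_from


@pytest.fixture()
def trained_store(tmp_path, small_corpora):
    np_pairs, sm_pairs = small_corpora
    records = records_from(np_pairs, Status.NP, "np") + records_from(sm_pairs, Status.SM, "sm")
    curated, _ = curate(records)
    store = NPStore(tmp_path / "store.db", create=True)
    store.ingest(curated, records)
    retrain_scores(store)
    yield store
    store.close()


def test_ingest_deduplicates_into_molecule_table(tmp_path):
    records = [
        MoleculeRecord("a", "c1ccccc1O", Status.NP),
        MoleculeRecord("b", "C1=CC=CC=C1O", Status.NP),
        MoleculeRecord("c", "ClCCCCCl", Status.SM),
    ]
    curated, _ = curate(records)
    with NPStore(tmp_path / "s.db", create=True) as store:
        store.ingest(curated, records)
        n_ori = store.conn.execute("SELECT COUNT(*) FROM ori_molecule").fetchone()[0]
        assert n_ori == 3 and store.n_molecules() == 2


def test_reingest_grows_ori_but_not_molecule(tmp_path):
    records = [MoleculeRecord("a", "c1ccccc1O", Status.NP),
               MoleculeRecord("c", "ClCCCCCl", Status.SM)]
    curated, _ = curate(records)
    with NPStore(tmp_path / "s.db", create=True) as store:
        store.ingest(curated, records)
        store.ingest(curated, records)
        assert store.conn.execute("SELECT COUNT(*) FROM ori_molecule").fetchone()[0] == 4
        assert store.n_molecules() == 2
        # fragment counts must not have double-counted
        total_np = store.conn.execute(
            "SELECT SUM(np_count) FROM fragment_with_sugar").fetchone()[0]
        assert total_np == store.conn.execute(
            "SELECT total_atom_count FROM molecule WHERE is_np = 1").fetchone()[0]


def test_ingest_with_empty_curated_list(tmp_path):
    records = [MoleculeRecord("a", "c1ccccc1O", Status.NP)]
    with NPStore(tmp_path / "s.db", create=True) as store:
        store.ingest([], records)
        assert store.conn.execute("SELECT COUNT(*) FROM ori_molecule").fetchone()[0] == 1
        assert store.n_molecules() == 0


def test_occurrence_sums_equal_total_atom_counts(trained_store):
    rows = trained_store.conn.execute(
        "SELECT m.molecule_id, m.total_atom_count, SUM(c.occurrences)"
        " FROM molecule m JOIN molecule_fragment_cpd c ON c.molecule_id = m.molecule_id"
        " WHERE c.with_sugar = 1 GROUP BY m.molecule_id"
    ).fetchall()
    assert rows
    for _, total, occ_sum in rows:
        assert occ_sum == total


def test_referential_integrity(trained_store):
    orphans = trained_store.conn.execute(
        "SELECT COUNT(*) FROM molecule_fragment_cpd c"
        " LEFT JOIN molecule m ON m.molecule_id = c.molecule_id WHERE m.molecule_id IS NULL"
    ).fetchone()[0]
    assert orphans == 0
    for flag, table in ((1, "fragment_with_sugar"), (0, "fragment_without_sugar")):
        missing = trained_store.conn.execute(
            f"SELECT COUNT(*) FROM molecule_fragment_cpd c LEFT JOIN {table} f"
            " ON f.fragment_id = c.fragment_id WHERE c.with_sugar = ? AND f.fragment_id IS NULL",
            (flag,),
        ).fetchone()[0]
        assert missing == 0


def test_query_fragment_scores_only_returns_known(trained_store):
    sig = trained_store.conn.execute(
        "SELECT signature FROM fragment_with_sugar LIMIT 1").fetchone()[0]
    out = trained_store.query_fragment_scores([sig, "sig1/h2/Xx/"], SugarMode.WITH_SUGAR)
    assert sig in out and "sig1/h2/Xx/" not in out
    assert trained_store.query_fragment_scores([], SugarMode.WITH_SUGAR) == {}


def test_dump_load_round_trip(trained_store, tmp_path):
    dump1 = tmp_path / "dump1"
    trained_store.dump(dump1)
    with NPStore(tmp_path / "copy.db", create=True) as copy:
        copy.load(dump1)
        dump2 = tmp_path / "dump2"
        copy.dump(dump2)
    match, mismatch, errors = filecmp.cmpfiles(
        dump1, dump2, [p.name for p in dump1.iterdir()], shallow=False
    )
    assert not mismatch and not errors


def test_rescore_is_byte_stable(trained_store, tmp_path):
    before = tmp_path / "before"
    after = tmp_path / "after"
    trained_store.dump(before)
    retrain_scores(trained_store)
    trained_store.dump(after)
    match, mismatch, errors = filecmp.cmpfiles(
        before, after, [p.name for p in before.iterdir()], shallow=False
    )
    assert not mismatch and not errors


def test_retrain_empty_store_raises(tmp_path):
    with NPStore(tmp_path / "e.db", create=True) as store:
        with pytest.raises(ValueError):
            store.retrain()


def test_molecule_scores_are_set_after_training(trained_store):
    unscored = trained_store.conn.execute(
        "SELECT COUNT(*) FROM molecule WHERE score_with_sugar IS NULL"
    ).fetchone()[0]
    assert unscored == 0
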