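import random

import pytest
from rdkit import Chem

from nplikeness import (
    MoleculeRecord,
    Status,
    curate,
    filter_elements_and_size,
    largest_component,
    strip_stereochemistry,
    structural_key,
)


def canon(mol):
    return Chem.MolToSmiles(mol)


@pytest.mark.parametrize(
    "stereo,flat",
    [
        ("C[C@H](N)C(=O)O", "CC(N)C(=O)O"),
        ("C/C=C/C", "CC=CC"),
        ("CCO", "CCO"),  # achiral input unchanged
    ],
)
def test_strip_stereochemistry(stereo, flat):
    out = strip_stereochemistry(Chem.MolFromSmiles(stereo))
    assert canon(out) == canon(Chem.MolFromSmiles(flat))
    assert out.GetNumAtoms() == Chem.MolFromSmiles(stereo).GetNumAtoms()


@pytest.mark.parametrize(
    "smiles,expected",
    [
        ("CC(=O)[O-].[Na+]", "CC(=O)[O-]"),
        ("c1ccccc1", "c1ccccc1"),
        ("O.O.c1ccccc1", "c1ccccc1"),
    ],
)
def test_largest_component(smiles, expected):
    out = largest_component(Chem.MolFromSmiles(smiles))
    assert canon(out) == canon(Chem.MolFromSmiles(expected))


@pytest.mark.parametrize(
    "smiles,keep",
    [
        ("c1ccccc1", True),       # exactly 6 heavy atoms passes
        ("C[Sn](C)(C)C", False),  # tin is not an allowed element
        ("CCO", False),           # under the size floor
        ("CCOP(=O)(O)OC", True),  # P allowed
    ],
)
def test_filter_elements_and_size(smiles, keep):
    mol = Chem.MolFromSmiles(smiles)
    assert filter_elements_and_size(mol) is keep


def test_structural_key_ignores_stereo_and_atom_order():
    k1 = structural_key(strip_stereochemistry(Chem.MolFromSmiles("C[C@H](N)C(=O)O")))
    k2 = structural_key(strip_stereochemistry(Chem.MolFromSmiles("C[C@@H](N)C(=O)O")))
    assert k1 == k2
    assert structural_key(Chem.MolFromSmiles("c1ccccc1")) == structural_key(
        Chem.MolFromSmiles("C1=CC=CC=C1")
    )
    assert structural_key(Chem.MolFromSmiles("c1ccccc1")) != structural_key(
        Chem.MolFromSmiles("Cc1ccccc1")
    )


def _rec(i, smiles, status=Status.NP, db="t"):
    return MoleculeRecord(record_id=f"r{i}", smiles=smiles, status=status, source_db=db)


def test_curate_merges_identical_graphs():
    curated, report = curate([_rec(1, "c1ccccc1"), _rec(2, "C1=CC=CC=C1")])
    assert len(curated) == 1 and len(curated[0].sources) == 2
    assert report.unique == 1 and report.parsed == 2


def test_curate_rejects_by_size():
    curated, report = curate([_rec(1, "CCO"), _rec(2, "c1ccccc1")])
    assert [m.smiles for m in curated] == ["c1ccccc1"]
    assert report.rejected_size == 1


def test_curate_empty_input():
    curated, report = curate([])
    assert curated == [] and report.parsed == 0 and report.unique == 0


def test_curate_label_conflict_resolves_to_np():
    curated, report = curate(
        [_rec(1, "Cc1ccccc1O", Status.SM), _rec(2, "Cc1ccccc1O", Status.NP)]
    )
    assert curated[0].is_np and report.label_conflicts == 1


def test_biogenic_records_excluded_from_classes():
    curated, _ = curate([_rec(1, "Cc1ccccc1O", Status.BIOGENIC)])
    assert curated[0].is_biogenic and not curated[0].is_np


def test_curation_counters_balance(small_corpora):
    np_pairs, sm_pairs = small_corpora
    records = [_rec(i, s) for i, (s, _) in enumerate(np_pairs + sm_pairs)]
    records += [_rec(900, "CCO"), _rec(901, "C[Sn](C)(C)C"), _rec(902, "not_a_smiles")]
    curated, report = curate(records)
    multiplicity = sum(len(m.sources) for m in curated)
    assert report.parsed == (
        report.rejected_parse + report.rejected_size + report.rejected_element + multiplicity
    )
    assert report.rejected_parse == 1 and report.rejected_size == 1 and report.rejected_element == 1


def test_curate_is_permutation_invariant(small_corpora):
    np_pairs, _ = small_corpora
    records = [_rec(i, s) for i, (s, _) in enumerate(np_pairs)]
    shuffled = records[:]
    random.Random(5).shuffle(shuffled)
    a, _ = curate(records)
    b, _ = curate(shuffled)
    assert {m.structural_key for m in a} == {m.structural_key for m in b}
    keys_a = {m.structural_key: (m.smiles, m.heavy_atom_count, frozenset(m.sources)) for m in a}
    keys_b = {m.structural_key: (m.smiles, m.heavy_atom_count, frozenset(m.sources)) for m in b}
    assert keys_a == keys_b


def test_curate_idempotent_on_own_output(small_corpora):
    np_pairs, _ = small_corpora
    curated, _ = curate([_rec(i, s) for i, (s, _) in enumerate(np_pairs)])
    again, report = curate(
        [_rec(i, m.smiles) for i, m in enumerate(curated)]
    )
    assert {m.structural_key for m in again} == {m.structural_key for m in curated}
    assert report.unique == len(curated)
    counts = {m.structural_key: (m.heavy_atom_count, m.total_atom_count) for m in curated}
    for m in again:
        assert counts[m.structural_key] == (m.heavy_atom_count, m.total_atom_count)


def test_no_sugar_counts_equal_when_sugar_free():
    curated, _ = curate([_rec(1, "Cc1ccccc1O")])
    m = curated[0]
    assert not m.contains_sugar
    assert m.heavy_atom_count_no_sugar == m.heavy_atom_count
    assert m.total_atom_count_no_sugar == m.total_atom_count
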