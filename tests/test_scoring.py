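import math

import pytest
from hypothesis import given, settings, strategies as st
from rdkit import Chem

from nplikeness import (
    MoleculeRecord,
    Status,
    SugarMode,
    count_fragments,
    curate,
    fragment_score,
    load_fragment_table,
    save_fragment_table,
    score_molecule,
    standardise_for_scoring,
)


@pytest.mark.parametrize(
    "npc,smc,npt,smt,p,expected",
    [
        (10, 10, 100, 100, 1, 0.0),                 # balanced ratios
        (20, 5, 100, 100, 0, math.log(4)),          # plain log ratio
        (5, 0, 100, 100, 1, math.log(6)),           # smoothing rescues SM-absent fragment
        (3, 3, 50, 100, 1, math.log(2)),            # totals ratio corrects imbalance
    ],
)
def test_fragment_score_values(npc, smc, npt, smt, p, expected):
    assert fragment_score(npc, smc, npt, smt, pseudocount=p) == pytest.approx(expected, abs=1e-12)


def test_fragment_score_one_sided_without_smoothing_is_infinite():
    assert fragment_score(5, 0, 10, 10, pseudocount=0) == math.inf
    assert fragment_score(0, 5, 10, 10, pseudocount=0) == -math.inf


def test_fragment_score_rejects_absent_fragment():
    with pytest.raises(ValueError):
        fragment_score(0, 0, 10, 10)


@settings(deadline=None, max_examples=200)
@given(
    npc=st.integers(0, 10_000), smc=st.integers(0, 10_000),
    npt=st.integers(1, 100_000), smt=st.integers(1, 100_000),
    p=st.sampled_from([0.0, 0.5, 1.0]),
)
def test_antisymmetry_under_class_swap_is_exact(npc, smc, npt, smt, p):
    if npc + smc < 1:
        return
    assert fragment_score(npc, smc, npt, smt, p) == -fragment_score(smc, npc, smt, npt, p)


@settings(deadline=None, max_examples=200)
@given(
    npc=st.integers(1, 10_000), smc=st.integers(1, 10_000),
    npt=st.integers(1, 100_000), smt=st.integers(1, 100_000),
    k=st.integers(2, 64),
)
def test_ratio_scale_invariance_is_exact_without_smoothing(npc, smc, npt, smt, k):
    base = fragment_score(npc, smc, npt, smt, pseudocount=0)
    scaled = fragment_score(k * npc, k * smc, k * npt, k * smt, pseudocount=0)
    assert base == scaled


def test_antisymmetry_holds_for_every_fragment_of_a_trained_table(small_curated):
    np_mols, sm_mols, _ = small_curated
    table = count_fragments(np_mols, sm_mols, sugar_mode=SugarMode.WITH_SUGAR)
    swapped = count_fragments(sm_mols, np_mols, sugar_mode=SugarMode.WITH_SUGAR)
    assert set(table.entries) == set(swapped.entries)
    for s, e in table.entries.items():
        assert swapped.entries[s].score == -e.score


def _benzene_vs_cyclohexane_table():
    records = [
        MoleculeRecord("b", "c1ccccc1", Status.NP),
        MoleculeRecord("c", "C1CCCCC1", Status.SM),
    ]
    curated, _ = curate(records)
    np_mols = [m for m in curated if m.is_np]
    sm_mols = [m for m in curated if not m.is_np]
    return count_fragments(np_mols, sm_mols, sugar_mode=SugarMode.WITH_SUGAR)


def test_constant_fragment_molecule_scores_that_constant():
    table = _benzene_vs_cyclohexane_table()
    benzene = standardise_for_scoring(MoleculeRecord("q", "c1ccccc1", Status.NP))
    result = score_molecule(benzene, table)
    # every benzene fragment has NP count 6 / SM count 0: single shared score
    assert result.np_likeness == pytest.approx(math.log(7), abs=1e-12)
    assert result.n_unknown_fragments == 0


def test_sign_separation_in_two_molecule_training():
    table = _benzene_vs_cyclohexane_table()
    benzene = standardise_for_scoring(MoleculeRecord("q", "c1ccccc1", Status.NP))
    cyclohexane = standardise_for_scoring(MoleculeRecord("r", "C1CCCCC1", Status.NP))
    assert score_molecule(benzene, table).np_likeness > 0
    assert score_molecule(cyclohexane, table).np_likeness < 0


def test_unknown_fragments_are_excluded_and_alerted():
    table = _benzene_vs_cyclohexane_table()
    # hexamethyldisilane: every atom within distance 2 of a silicon
    disilane = standardise_for_scoring(MoleculeRecord("p", "C[Si](C)(C)[Si](C)(C)C", Status.NP))
    result = score_molecule(disilane, table)
    assert result.np_likeness is None
    assert result.n_fragments_used == 0
    assert result.n_unknown_fragments == Chem.AddHs(
        Chem.MolFromSmiles("C[Si](C)(C)[Si](C)(C)C")).GetNumAtoms()
    assert result.alerts


def test_partial_unknown_fragments_reduce_n(small_tables):
    table, _ = small_tables
    toluene = standardise_for_scoring(MoleculeRecord("t", "Cc1ccccc1", Status.NP))
    result = score_molecule(toluene, table)
    n_total = Chem.AddHs(Chem.MolFromSmiles("Cc1ccccc1")).GetNumAtoms()
    assert result.n_fragments_used + result.n_unknown_fragments == n_total
    if result.n_unknown_fragments:
        assert result.alerts


def test_score_is_bounded_by_used_fragment_scores(small_curated, small_tables):
    np_mols, sm_mols, _ = small_curated
    table, _ = small_tables
    from nplikeness.signatures import molecular_signature

    for mol in (np_mols + sm_mols)[:60]:
        if mol.aglycone_smiles is None:
            continue
        result = score_molecule(mol, table)
        sig = molecular_signature(Chem.MolFromSmiles(mol.aglycone_smiles), table.height)
        used = [table.entries[s].score for s in sig.counts if s in table.entries]
        assert min(used) - 1e-9 <= result.np_likeness <= max(used) + 1e-9


def test_table_tsv_round_trip_is_lossless(small_tables, tmp_path):
    table, _ = small_tables
    path = tmp_path / "table.tsv"
    save_fragment_table(table, path)
    loaded = load_fragment_table(path)
    assert loaded.np_total == table.np_total and loaded.sm_total == table.sm_total
    assert loaded.sugar_mode is table.sugar_mode and loaded.pseudocount == table.pseudocount
    assert set(loaded.entries) == set(table.entries)
    for s, e in table.entries.items():
        le = loaded.entries[s]
        assert (le.np_count, le.sm_count, le.score, le.height) == (
            e.np_count, e.sm_count, e.score, e.height
        )


def test_totals_are_molecule_counts_not_fragment_sums(small_curated, small_tables):
    np_mols, sm_mols, _ = small_curated
    without, with_ = small_tables
    assert with_.np_total == len(np_mols)
    assert with_.sm_total == len(sm_mols)
    assert without.np_total == sum(1 for m in np_mols if m.aglycone_smiles is not None)


def test_multiplicity_counts_accumulate():
    # hexane-1,6-diol: symmetric, several environments occur twice
    records = [
        MoleculeRecord("d", "OCCCCCCO", Status.NP),
        MoleculeRecord("b", "ClCCCCCCCl", Status.SM),
    ]
    curated, _ = curate(records)
    table = count_fragments(
        [m for m in curated if m.is_np], [m for m in curated if not m.is_np],
        sugar_mode=SugarMode.WITH_SUGAR,
    )
    n_atoms = Chem.AddHs(Chem.MolFromSmiles("OCCCCCCO")).GetNumAtoms()
    assert sum(e.np_count for e in table.entries.values()) == n_atoms
    assert any(e.np_count >= 2 for e in table.entries.values())
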