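import pytest
from rdkit import Chem

from nplikeness import (
    FixtureSpec,
    MoleculeRecord,
    Status,
    SugarMode,
    count_fragments,
    curate,
    generate_molecules,
)


def records_from(pairs, status, prefix):
    return [
        MoleculeRecord(record_id=f"{prefix}{i}", smiles=smiles, status=status)
        for i, (smiles, _) in enumerate(pairs, start=1)
    ]


@pytest.fixture(scope="session")
def small_corpora():
    """Two 40-molecule corpora: (np_pairs, sm_pairs) of (smiles, sugared)."""
    return generate_molecules(FixtureSpec(n_np=40, n_sm=40, seed=7, sugar_fraction=0.4))


@pytest.fixture(scope="session")
def small_curated(small_corpora):
    np_pairs, sm_pairs = small_corpora
    np_records = records_from(np_pairs, Status.NP, "np")
    sm_records = records_from(sm_pairs, Status.SM, "sm")
    curated, report = curate(np_records + sm_records)
    np_mols = [m for m in curated if m.is_np]
    sm_mols = [m for m in curated if not m.is_np]
    return np_mols, sm_mols, report


@pytest.fixture(scope="session")
def small_tables(small_curated):
    np_mols, sm_mols, _ = small_curated
    without = count_fragments(np_mols, sm_mols, sugar_mode=SugarMode.WITHOUT_SUGAR)
    with_ = count_fragments(np_mols, sm_mols, sugar_mode=SugarMode.WITH_SUGAR)
    return without, with_


@pytest.fixture(scope="session")
def fixture_mols(small_corpora):
    """Parsed RDKit molecules of both fixture classes."""
    np_pairs, sm_pairs = small_corpora
    return [Chem.MolFromSmiles(s) for s, _ in np_pairs + sm_pairs]
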