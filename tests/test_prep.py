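"""Preparation pipeline: loading, standardization, filters, dedup."""

import time

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit import Chem

from fragcomb.prep import (
    FilterConfig,
    KeyStore,
    MoleculeRecord,
    apply_filters,
    deduplicate,
    extract_murcko,
    identity_key,
    load_molecules,
    prepare_records,
    remove_sugars,
    run_with_timeout,
    select_main_component,
    standardize_structure,
)

from conftest import std_record


def can(smiles: str) -> str:
    return Chem.MolToSmiles(Chem.MolFromSmiles(smiles))


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def _write_sdf(path, smiles_list):
    writer = Chem.SDWriter(str(path))
    for i, smi in enumerate(smiles_list):
        mol = Chem.MolFromSmiles(smi)
        mol.SetProp("_Name", f"m{i}")
        writer.write(mol)
    writer.close()


def test_load_sdf_isolates_corrupt_block(tmp_path):
    sdf = tmp_path / "in.sdf"
    _write_sdf(sdf, ["C1CCCCC1", "CCO", "C1CCNCC1"])
    blocks = sdf.read_text().split("$$$$\n")
    blocks[1] = "m1\n\ngarbage atom block\nnot a counts line\nM  END\n"
    sdf.write_text("$$$$\n".join(blocks))
    records = list(load_molecules(sdf, "sdf"))
    assert [r.status for r in records] == ["passed", "error", "passed"]
    assert records[1].removal_reason == "parse"


def test_load_smiles_with_id_column(tmp_path):
    f = tmp_path / "in.smi"
    f.write_text("C1CCCCC1 frag1\nnot_a_smiles bad1\n")
    records = list(load_molecules(f, "smiles"))
    assert records[0].record_id == "frag1"
    assert records[0].mol.GetNumAtoms() == 6
    assert records[1].status == "error"


def test_load_empty_structure_filtered(tmp_path):
    sdf = tmp_path / "in.sdf"
    writer = Chem.SDWriter(str(sdf))
    writer.write(Chem.MolFromSmiles(""))
    writer.close()
    records = list(load_molecules(sdf, "sdf"))
    assert records[0].status == "filtered"
    assert records[0].removal_reason == "empty"


def test_load_missing_file_is_fatal():
    with pytest.raises(FileNotFoundError):
        list(load_molecules("/nonexistent/file.sdf", "sdf"))


# ---------------------------------------------------------------------------
# Mixtures
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "smiles,expected",
    [
        ("C1CCCCC1.[Na+].[Cl-]", "C1CCCCC1"),          # organic wins over salts
        ("CCCCCCCCCC.C1CCNCC1", "C1CCNCC1"),            # ring beats longer chain
        ("C1CCNCC1", "C1CCNCC1"),                       # single component unchanged
        ("CCO.CCCCO", "CCCCO"),                         # no ring: most heavy atoms
    ],
)
def test_select_main_component(smiles, expected):
    out = select_main_component(Chem.MolFromSmiles(smiles))
    assert Chem.MolToSmiles(out) == can(expected)


def test_select_main_component_matches_brute_force_ranking():
    smiles = "CCCCCCCCCC.C1CCNCC1.CC.[Na+]"
    mol = Chem.MolFromSmiles(smiles)
    frags = Chem.GetMolFrags(mol, asMols=True)
    # brute-force: sort every component by the documented criteria
    def rank(m):
        has_c = any(a.GetAtomicNum() == 6 for a in m.GetAtoms())
        return (has_c, m.GetRingInfo().NumRings() > 0, m.GetNumHeavyAtoms())
    best = max(frags, key=rank)
    assert Chem.MolToSmiles(select_main_component(mol)) == Chem.MolToSmiles(best)


# ---------------------------------------------------------------------------
# Sugar removal
# ---------------------------------------------------------------------------

def test_remove_sugars_glucoside():
    mol = Chem.MolFromSmiles("OCC1OC(OC2CCCCC2)C(O)C(O)C1O")
    out = remove_sugars(mol)
    assert Chem.MolToSmiles(out) == can("OC1CCCCC1")


def test_remove_sugars_keeps_sugar_free_rings():
    mol = Chem.MolFromSmiles("C1CCC2CCCCC2C1")
    out = remove_sugars(mol)
    assert Chem.MolToSmiles(out) == can("C1CCC2CCCCC2C1")


def test_remove_sugars_disaccharide_two_layers():
    # outer pyranose -> inner pyranose -> cyclohexanol aglycone
    smi = "OCC1OC(OC2C(O)C(O)C(CO)OC2OC2CCCCC2)C(O)C(O)C1O"
    mol = Chem.MolFromSmiles(smi)
    from fragcomb.prep import _peel_one_sugar

    first = _peel_one_sugar(mol)
    assert first is not None and first.GetNumAtoms() < mol.GetNumAtoms()
    second = _peel_one_sugar(first)
    assert second is not None
    assert _peel_one_sugar(second) is None  # exactly two iterations
    assert Chem.MolToSmiles(remove_sugars(mol)) == can("OC1CCCCC1")


def test_remove_sugars_pure_sugar_becomes_empty():
    mol = Chem.MolFromSmiles("OCC1OC(O)C(O)C(O)C1O")  # glucose
    assert remove_sugars(mol).GetNumAtoms() == 0


def test_sugar_peeling_strictly_decreases_rings():
    smi = "OCC1OC(OC2C(O)C(O)C(CO)OC2OC2CCCCC2)C(O)C(O)C1O"
    from fragcomb.prep import _peel_one_sugar

    mol = Chem.MolFromSmiles(smi)
    rings = mol.GetRingInfo().NumRings()
    while True:
        peeled = _peel_one_sugar(mol)
        if peeled is None:
            break
        assert peeled.GetRingInfo().NumRings() < rings
        rings = peeled.GetRingInfo().NumRings()
        mol = peeled


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "smiles,ok,reason",
    [
        ("CCC", False, "num_heavy_atoms"),      # propane: 3 heavy atoms
        ("C1CCCCC1", True, None),               # cyclohexane passes
        ("CCCCCC", False, "num_rings"),         # hexane: no ring
        ("C1CC[Se]CC1", False, "elements"),     # selenium not allowed
    ],
)
def test_apply_filters(smiles, ok, reason, cfg):
    mol = Chem.MolFromSmiles(smiles)
    got_ok, got_reason = apply_filters(mol, cfg)
    assert (got_ok, got_reason) == (ok, reason)


def test_filter_order_reports_first_violation(cfg):
    # ethane violates both the heavy-atom and the ring rule; the heavy-atom
    # rule comes first in the fixed order
    ok, reason = apply_filters(Chem.MolFromSmiles("CC"), cfg)
    assert not ok and reason == "num_heavy_atoms"


def test_filterconfig_rejects_nonpositive():
    with pytest.raises(ValueError):
        FilterConfig(min_heavy_atoms=0)


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "smiles,expected",
    [
        ("[2H]C1CCCCC1", "C1CCCCC1"),            # isotope reset
        ("CC(=O)[O-]", "CC(=O)O"),                # charge neutralization
        ("C1CC[C@@H]2CCCC[C@H]2C1", "C1CCC2CCCCC2C1"),  # stereo removal
    ],
)
def test_standardize_examples(smiles, expected):
    out = standardize_structure(Chem.MolFromSmiles(smiles))
    assert Chem.MolToSmiles(out) == can(expected)


def test_standardize_idempotent_on_fixture_molecules(category_fixtures):
    for fx in category_fixtures:
        once = standardize_structure(Chem.MolFromSmiles(fx.molecule_smiles))
        twice = standardize_structure(once)
        assert identity_key(once) == identity_key(twice)


# ---------------------------------------------------------------------------
# Murcko
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "smiles,expected",
    [
        ("CCC1CCNCC1", "C1CCNCC1"),                      # side chain pruned
        ("C1CCC2CCCCC2C1", "C1CCC2CCCCC2C1"),            # scaffold fixpoint
        ("C1CCC(CCN2CCCCC2)CC1", "C1CCC(CCN2CCCCC2)CC1"),  # linker retained
    ],
)
def test_extract_murcko(smiles, expected):
    out = extract_murcko(Chem.MolFromSmiles(smiles))
    assert Chem.MolToSmiles(out) == can(expected)


def test_extract_murcko_acyclic_empty():
    assert extract_murcko(Chem.MolFromSmiles("CCCCO")).GetNumAtoms() == 0


# ---------------------------------------------------------------------------
# Timeout
# ---------------------------------------------------------------------------

def test_timeout_fast_task_unchanged():
    rec = std_record("C1CCCCC1")
    out = run_with_timeout(lambda r: r, rec, 10.0)
    assert out.status == "passed"


def test_timeout_forced():
    rec = std_record("C1CCCCC1")

    def slow(r):
        time.sleep(0.02)
        return r

    out = run_with_timeout(slow, rec, 0.001)
    assert out.status == "timeout"
    assert out.removal_reason == "timeout"


def test_timeout_disabled_with_none():
    rec = std_record("C1CCCCC1")

    def slow(r):
        time.sleep(0.02)
        return r

    assert run_with_timeout(slow, rec, None).status == "passed"
    assert run_with_timeout(slow, rec, float("inf")).status == "passed"


# ---------------------------------------------------------------------------
# Deduplication
# ---------------------------------------------------------------------------

def _passed_records(smiles_list):
    out = []
    for i, smi in enumerate(smiles_list):
        rec = std_record(smi, f"m{i}")
        rec.identity_key = identity_key(rec.mol)
        out.append(rec)
    return out


def test_deduplicate_exact_duplicates():
    records = _passed_records(["C1CCCCC1", "C1CCCCC1"])
    out = list(deduplicate(records))
    assert [r.status for r in out] == ["passed", "filtered"]
    assert out[1].removal_reason == "duplicate"


def test_deduplicate_tautomer_collision():
    # keto and enol forms standardize to the same canonical tautomer
    records = _passed_records(["CCC(C)=O", "CC(O)=CC"])
    assert records[0].identity_key == records[1].identity_key
    out = list(deduplicate(records))
    assert [r.status for r in out] == ["passed", "filtered"]


def test_deduplicate_across_chunks_with_locked_store(tmp_path):
    store_path = tmp_path / "keys.txt"
    chunk1 = _passed_records(["C1CCC2CCCCC2C1", "C1CCCCC1"])
    chunk2 = _passed_records(["C1CCC2CCCCC2C1", "C1CCNCC1"])
    out1 = list(deduplicate(chunk1, KeyStore(store_path)))
    out2 = list(deduplicate(chunk2, KeyStore(store_path)))
    survivors = [r.record_id for r in out1 + out2 if r.status == "passed"]
    assert len([r for r in out1 + out2 if r.removal_reason == "duplicate"]) == 1
    assert len(survivors) == 3


@settings(derandomize=True, max_examples=20)
@given(perm=st.permutations(list(range(6))))
def test_dedup_survivor_key_set_is_order_invariant(perm, tmp_path_factory):
    smiles = ["C1CCCCC1", "C1CCNCC1", "C1CCCCC1", "C1CCOCC1", "C1CCNCC1", "C1CCCC1"]
    records = _passed_records([smiles[i] for i in perm])
    out = list(deduplicate(records))
    surviving = {r.identity_key for r in out if r.status == "passed"}
    baseline = {r.identity_key for r in _passed_records(smiles)}
    assert surviving == baseline


def test_prepare_records_conserves_every_record(tmp_path):
    smi = tmp_path / "in.smi"
    smi.write_text(
        "C1CCCCC1 a\nCCC b\nnot_a_smiles c\nC1CCCCC1 d\nCCCCCC e\n"
    )
    records = list(load_molecules(smi, "smiles"))
    out = list(prepare_records(records, FilterConfig(), mode="molecules"))
    assert len(out) == 5
    statuses = sorted(r.status for r in out)
    assert statuses.count("passed") == 1          # one cyclohexane survives
    assert statuses.count("error") == 1           # parse failure
    assert statuses.count("filtered") == 3        # size, rings, duplicate
    for r in out:
        assert (r.identity_key is not None) == (r.status == "passed")
        assert (r.removal_reason is not None) == (r.status != "passed")
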