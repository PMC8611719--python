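"""The fragment-pair decision tree: fusions, connections, false positives."""

import itertools

import pytest
from rdkit import Chem

from fragcomb.classify import (
    CATEGORY_TABLE,
    classify_fusion,
    classify_molecule,
    classify_pair,
    fused_atoms,
    intermediary_rings,
)
from fragcomb.fixtures import bridged_pair_smiles, fused_bicyclo_smiles
from fragcomb.prep import FilterConfig

from conftest import classify_smiles, oracle_intermediary_rings, oracle_min_linker


# ---------------------------------------------------------------------------
# Fused atoms
# ---------------------------------------------------------------------------

def test_fused_atoms_decalin_pair():
    _, hits, _ = classify_smiles("C1CCC2CCCCC2C1", ("cyclohexane",))
    assert len(fused_atoms(hits[0], hits[1])) == 2


def test_fused_atoms_spiro_single_atom():
    _, hits, _ = classify_smiles("C1CCC2(C1)CCCCC2", ("cyclopentane", "cyclohexane"))
    assert len(fused_atoms(hits[0], hits[1])) == 1


def test_fused_atoms_disjoint_rings_empty():
    _, hits, _ = classify_smiles("C1CCC(CC1)C1CCCCC1", ("cyclohexane",))
    assert fused_atoms(hits[0], hits[1]) == frozenset()


def test_fused_atoms_same_hit_twice_is_error():
    _, hits, _ = classify_smiles("C1CCC2CCCCC2C1", ("cyclohexane",))
    with pytest.raises(ValueError):
        fused_atoms(hits[0], hits[0])


# ---------------------------------------------------------------------------
# Fusion boundary sweep: 1..7 fused atoms -> fs, fe, fb, fb, fb, fl, fl
# ---------------------------------------------------------------------------

FUSION_SWEEP = [
    (1, "C1CCC2(C1)CCCCC2", ("cyclopentane", "cyclohexane"), "fs"),
    (2, "C1CCC2CCCCC2C1", ("cyclohexane",), "fe"),
    (3, fused_bicyclo_smiles(2, 1), ("cyclopentane",), "fb"),
    (4, fused_bicyclo_smiles(2, 2), ("cyclohexane",), "fb"),
    (5, fused_bicyclo_smiles(3, 3), ("cyclooctane",), "fb"),
    (6, fused_bicyclo_smiles(4, 4), ("cyclodecane",), "fl"),
    (7, fused_bicyclo_smiles(5, 5), ("cyclododecane",), "fl"),
]


@pytest.mark.parametrize("n,smiles,frags,expected", FUSION_SWEEP)
def test_fusion_boundary_sweep(n, smiles, frags, expected):
    rec, hits, combos = classify_smiles(smiles, frags)
    assert combos, f"no combination for n={n}"
    pair_codes = {c.code for c in combos}
    assert pair_codes == {expected}
    # the designed fused-atom count is actually observed
    sizes = {len(c.fused_atoms) for c in combos}
    assert sizes == {n}


def test_classify_fusion_mapping_is_total():
    assert [classify_fusion(n) for n in range(1, 8)] == [
        "fs", "fe", "fb", "fb", "fb", "fl", "fl"
    ]


# ---------------------------------------------------------------------------
# Linker sweep: 1..4 intermediary atoms -> cm, cm, cm, cfc
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("k,expected", [(1, "cm"), (2, "cm"), (3, "cm"), (4, "cfc")])
def test_linker_cutoff_sweep(k, expected):
    smiles = f"C1CCC({'C' * k}N2CCCCC2)CC1"
    rec, hits, _ = classify_smiles(smiles, ("cyclohexane", "piperidine"))
    combo = classify_pair(rec.mol, hits[0], hits[1], FilterConfig())
    assert combo.code == expected
    # oracle: exhaustive simple-path enumeration finds the same linker length
    assert oracle_min_linker(rec.mol, hits[0], hits[1]) == k


def test_direct_ring_ring_bond_is_monopodal():
    rec, hits, combos = classify_smiles("C1CCC(CC1)C1CCCCC1", ("cyclohexane",))
    assert [c.code for c in combos] == ["cm"]


# ---------------------------------------------------------------------------
# Intermediary rings
# ---------------------------------------------------------------------------

def test_intermediary_rings_middle_ring_of_linear_tricyclic():
    rec, hits, _ = classify_smiles("C1CCC2CC3CCCCC3CC2C1", ("cyclohexane",))
    outer = [h for h in hits]
    # identify the two outermost hits: they share no atoms
    pairs = [
        (a, b) for a, b in itertools.combinations(outer, 2)
        if not (a.ring_atoms & b.ring_atoms)
    ]
    assert len(pairs) == 1
    a, b = pairs[0]
    rings = intermediary_rings(rec.mol, a, b)
    assert len(rings) == 1
    assert len(rings[0]) == 6


def test_intermediary_rings_zero_for_tetracyclic_outer_pair():
    rec, hits, _ = classify_smiles("C1CCC2CC3CC4CCCCC4CC3CC2C1", ("cyclohexane",))
    # outermost pair: hits sharing no atoms with the two middle rings' hits
    by_min = sorted(hits, key=lambda h: min(h.atom_map))
    a, b = by_min[0], by_min[-1]
    assert not (a.ring_atoms & b.ring_atoms)
    assert intermediary_rings(rec.mol, a, b) == []


def test_intermediary_rings_agree_with_brute_force_on_fixtures(category_fixtures):
    for fx in category_fixtures:
        rec, hits, _ = classify_smiles(fx.molecule_smiles, fx.fragment_ids)
        for a, b in itertools.combinations(hits, 2):
            if a.ring_atoms & b.ring_atoms:
                continue
            got = {frozenset(r) for r in intermediary_rings(rec.mol, a, b)}
            expected = {frozenset(r) for r in oracle_intermediary_rings(rec.mol, a, b)}
            assert got == expected, fx.name


def test_connection_point_counts_match_brute_force(category_fixtures):
    for fx in category_fixtures:
        rec, hits, combos = classify_smiles(fx.molecule_smiles, fx.fragment_ids)
        for c in combos:
            for ring in c.intermediary_rings:
                cp_a = len(ring & c.hit_a.ring_atoms)
                cp_b = len(ring & c.hit_b.ring_atoms)
                assert cp_a >= 1 and cp_b >= 1
                # recount from scratch against the raw atom sets
                assert cp_a == sum(1 for x in ring if x in c.hit_a.ring_atoms)
                assert cp_b == sum(1 for x in ring if x in c.hit_b.ring_atoms)


# ---------------------------------------------------------------------------
# Connection subtypes via designed bridge constructs
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "code,ring_a,frags,bridges",
    [
        ("cbs", 6, ("cyclohexane",), [(0, 0, "O"), (0, 1, "N")]),
        ("cbe", 6, ("cyclohexane",), [(0, 0, "O"), (1, 1, "N")]),
        ("cbb", 6, ("cyclohexane",), [(0, 0, "O"), (2, 1, "N")]),
        ("cbl", 11, ("cycloundecane", "cyclohexane"), [(0, 0, "O"), (5, 1, "CC")]),
        ("cts", 6, ("cyclohexane",), [(0, 0, "O"), (0, 1, "N"), (2, 2, "C")]),
        ("cte", 6, ("cyclohexane",), [(0, 0, "O"), (1, 1, "N"), (2, 2, "C")]),
        ("ctb", 6, ("cyclohexane",), [(0, 0, "O"), (2, 1, "N"), (4, 2, "C")]),
        ("ctl", 11, ("cycloundecane", "cyclohexane"),
         [(0, 0, "O"), (0, 1, "N"), (5, 2, "CC")]),
        ("cos", 10, ("cyclodecane", "cyclohexane"),
         [(0, 0, "O"), (0, 1, "N"), (4, 2, "C"), (4, 3, "S")]),
        ("coe", 6, ("cyclohexane",),
         [(0, 0, "O"), (1, 1, "N"), (2, 2, "C"), (3, 3, "S")]),
        ("cob", 10, ("cyclodecane", "cyclohexane"),
         [(0, 0, "O"), (2, 1, "N"), (4, 2, "C"), (6, 3, "S")]),
        ("col", 11, ("cycloundecane", "cyclohexane"),
         [(0, 0, "O"), (0, 1, "N"), (5, 2, "C"), (5, 3, "S")]),
    ],
)
def test_connection_subtypes(code, ring_a, frags, bridges):
    smiles = bridged_pair_smiles(ring_a, 6, bridges)
    _, hits, combos = classify_smiles(smiles, frags)
    assert len(hits) == 2
    assert [c.code for c in combos] == [code]
    # degree letter encodes the number of intermediary rings
    degree = {"b": 1, "t": 2, "o": 3}[code[1]]
    k = len(combos[0].intermediary_rings)
    assert (k if k <= 2 else 3) == degree


# ---------------------------------------------------------------------------
# False positives and the full tree
# ---------------------------------------------------------------------------

def test_substructure_pair_is_ffs():
    _, hits, combos = classify_smiles("C1CCC2CCCCC2C1", ("decalin", "cyclohexane"))
    codes = sorted(c.code for c in combos)
    assert codes == ["fe", "ffs", "ffs"]


def test_full_ring_overlap_is_ffo():
    _, hits, combos = classify_smiles("C1CCC2CC3CCCCC3CC2C1", ("decalin",))
    assert [c.code for c in combos] == ["ffo"]
    # the shared atoms contain a complete molecule ring
    assert len(combos[0].fused_atoms) == 6


def test_classification_is_symmetric_on_all_fixture_pairs(category_fixtures):
    for fx in category_fixtures:
        rec, hits, _ = classify_smiles(fx.molecule_smiles, fx.fragment_ids)
        for a, b in itertools.combinations(hits, 2):
            ab = classify_pair(rec.mol, a, b, FilterConfig())
            ba = classify_pair(rec.mol, b, a, FilterConfig())
            assert ab.code == ba.code, fx.name


def test_every_fixture_pair_receives_exactly_one_code(category_fixtures):
    for fx in category_fixtures:
        rec, hits, _ = classify_smiles(fx.molecule_smiles, fx.fragment_ids)
        for a, b in itertools.combinations(hits, 2):
            combo = classify_pair(rec.mol, a, b, FilterConfig())
            assert combo is not None, fx.name
            assert combo.code in CATEGORY_TABLE, fx.name


def test_classify_molecule_pair_count():
    # three mutually-combined hits yield C(3,2) = 3 combinations
    _, hits, combos = classify_smiles("C1CCC2CC3CCCCC3CC2C1", ("cyclohexane",))
    assert len(hits) == 3
    assert len(combos) == 3
    assert sorted(c.code for c in combos) == ["cbe", "fe", "fe"]


def test_classify_molecule_drops_cfc_entirely():
    _, hits, combos = classify_smiles(
        "C1CCC(CCCCN2CCCCC2)CC1", ("cyclohexane", "piperidine")
    )
    assert len(hits) == 2
    assert combos == []


def test_combination_invariants(category_fixtures):
    for fx in category_fixtures:
        rec, hits, combos = classify_smiles(fx.molecule_smiles, fx.fragment_ids)
        for c in combos:
            if c.code in {"fs", "fe", "fb", "fl", "ffs", "ffo"}:
                if c.code != "ffs":
                    assert c.fused_atoms, (fx.name, c.code)
            if c.code.startswith("cb") and c.code != "ca":
                assert len(c.intermediary_rings) == 1
            if c.code.startswith("ct"):
                assert len(c.intermediary_rings) == 2
            if c.code.startswith("co"):
                assert len(c.intermediary_rings) > 2
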