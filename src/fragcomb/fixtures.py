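"""Self-contained toy dataset exercising every combination category.

All structures are topological test articles built from plain saturated
rings (never benzene, so the default exclusion cannot interfere):

* fusions come from spiro, ortho-fused and bridged bicyclic hydrocarbons
  (macrocyclic bicyclics for the high fused-atom counts);
* connections come from two ring fragments joined by one or more
  one/two-atom heteroatom bridges: the number of bridges sets the number
  of intermediary rings (degree) and the spacing of the attachment points
  along each ring sets the connection-point counts (subtype);
* false positives come from substructure pairs (cyclohexane inside
  decalin), ring-overlapping pairs (two decalins sharing the middle ring
  of a linear tricyclic) and an over-long linker.

Every fixture's expected codes are verified at generation time by running
the molecule through the full search + classification pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from rdkit import Chem

from .classify import classify_molecule
from .fragments import FragmentRecord, prepare_fragments, search_fragments
from .prep import FilterConfig, MoleculeRecord, standardize_structure

#: Ring fragments used by the fixture set (plain SMILES, standardized on use).
FRAGMENT_SMILES: dict[str, str] = {
    "cyclopentane": "C1CCCC1",
    "cyclohexane": "C1CCCCC1",
    "piperidine": "C1CCNCC1",
    "oxane": "C1CCOCC1",
    "cyclooctane": "C1CCCCCCC1",
    "cyclodecane": "C1CCCCCCCCC1",
    "cycloundecane": "C1CCCCCCCCCC1",
    "cyclododecane": "C1CCCCCCCCCCC1",
    "decalin": "C1CCC2CCCCC2C1",
}


@dataclass(frozen=True)
class Fixture:
    """One test article: a molecule, the fragments to search with, and the
    expected multiset of combination codes over all hit pairs."""

    name: str
    fragment_ids: tuple[str, ...]
    molecule_smiles: str
    expected_codes: tuple[str, ...]  # sorted multiset


def bridged_pair_smiles(
    ring_a: int,
    ring_b: int,
    bridges: Sequence[tuple[int, int, str]],
) -> str:
    """Two carbocycles of the given sizes joined by heteroatom bridges.

    ``bridges`` lists ``(atom_in_a, atom_in_b, bridge_atoms)`` with bridge
    atoms given as a string of element symbols (one character each, e.g.
    ``"O"`` or ``"CC"``). Ring A occupies atom indices ``0..ring_a-1``,
    ring B the following ``ring_b`` indices.
    """
    rw = Chem.RWMol()
    for _ in range(ring_a + ring_b):
        rw.AddAtom(Chem.Atom("C"))
    for i in range(ring_a):
        rw.AddBond(i, (i + 1) % ring_a, Chem.BondType.SINGLE)
    for i in range(ring_b):
        rw.AddBond(ring_a + i, ring_a + (i + 1) % ring_b, Chem.BondType.SINGLE)
    for ai, bj, symbols in bridges:
        prev = ai
        for sym in symbols:
            idx = rw.AddAtom(Chem.Atom(sym))
            rw.AddBond(prev, idx, Chem.BondType.SINGLE)
            prev = idx
        rw.AddBond(prev, ring_a + bj, Chem.BondType.SINGLE)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


def fused_bicyclo_smiles(bridge_len: int, shared_path: int) -> str:
    """Symmetric bridged bicyclic ``bicyclo[n.n.m]`` alkane SMILES with two
    equal outer bridges of ``bridge_len`` atoms and a shared bridge of
    ``shared_path`` atoms; its two smallest rings share
    ``shared_path + 2`` atoms."""
    a, c = bridge_len, shared_path
    if c == 0:
        return f"C12{'C' * a}C({'C' * a}1)2"
    return f"C12{'C' * a}C({'C' * a}1){'C' * c}2"


def make_category_fixtures() -> list[Fixture]:
    """One designed fixture per combination category and false-positive
    class (21 in total); expected codes are oracle-verified on creation."""
    f = []
    add = f.append
    # --- fusions -----------------------------------------------------------
    add(Fixture("fs", ("cyclopentane", "cyclohexane"),
                "C1CCC2(C1)CCCCC2", ("fs",)))
    add(Fixture("fe", ("cyclohexane",),
                "C1CCC2CCCCC2C1", ("fe",)))
    add(Fixture("fb", ("cyclopentane",),
                fused_bicyclo_smiles(2, 1), ("fb",)))
    add(Fixture("fl", ("cyclodecane",),
                fused_bicyclo_smiles(4, 4), ("fl", "fl", "fl")))
    # --- degree-0 connections ---------------------------------------------
    add(Fixture("cm", ("cyclohexane", "piperidine"),
                "C1CCC(CN2CCCCC2)CC1", ("cm",)))
    add(Fixture("cfc", ("cyclohexane", "piperidine"),
                "C1CCC(CCCCN2CCCCC2)CC1", ()))
    add(Fixture("ca", ("cyclohexane",),
                "C1CCC2CC3CC4CCCCC4CC3CC2C1",
                tuple(sorted(["fe", "fe", "fe", "cbe", "cbe", "ca"]))))
    # --- bipodal: one intermediary ring (two bridges) -----------------------
    add(Fixture("cbs", ("cyclohexane",),
                bridged_pair_smiles(6, 6, [(0, 0, "O"), (0, 1, "N")]),
                ("cbs",)))
    add(Fixture("cbe", ("cyclohexane",),
                bridged_pair_smiles(6, 6, [(0, 0, "O"), (1, 1, "N")]),
                ("cbe",)))
    add(Fixture("cbb", ("cyclohexane",),
                bridged_pair_smiles(6, 6, [(0, 0, "O"), (2, 1, "N")]),
                ("cbb",)))
    add(Fixture("cbl", ("cycloundecane", "cyclohexane"),
                bridged_pair_smiles(11, 6, [(0, 0, "O"), (5, 1, "CC")]),
                ("cbl",)))
    # --- tripodal: two intermediary rings (three bridges) --------------------
    add(Fixture("cts", ("cyclohexane",),
                bridged_pair_smiles(6, 6, [(0, 0, "O"), (0, 1, "N"), (2, 2, "C")]),
                ("cts",)))
    add(Fixture("cte", ("cyclohexane",),
                bridged_pair_smiles(6, 6, [(0, 0, "O"), (1, 1, "N"), (2, 2, "C")]),
                ("cte",)))
    add(Fixture("ctb", ("cyclohexane",),
                bridged_pair_smiles(6, 6, [(0, 0, "O"), (2, 1, "N"), (4, 2, "C")]),
                ("ctb",)))
    add(Fixture("ctl", ("cycloundecane", "cyclohexane"),
                bridged_pair_smiles(11, 6, [(0, 0, "O"), (0, 1, "N"), (5, 2, "CC")]),
                ("ctl",)))
    # --- other: three intermediary rings (four bridges) ----------------------
    add(Fixture("cos", ("cyclodecane", "cyclohexane"),
                bridged_pair_smiles(10, 6, [(0, 0, "O"), (0, 1, "N"),
                                            (4, 2, "C"), (4, 3, "S")]),
                ("cos",)))
    add(Fixture("coe", ("cyclohexane",),
                bridged_pair_smiles(6, 6, [(0, 0, "O"), (1, 1, "N"),
                                           (2, 2, "C"), (3, 3, "S")]),
                ("coe",)))
    add(Fixture("cob", ("cyclodecane", "cyclohexane"),
                bridged_pair_smiles(10, 6, [(0, 0, "O"), (2, 1, "N"),
                                            (4, 2, "C"), (6, 3, "S")]),
                ("cob",)))
    add(Fixture("col", ("cycloundecane", "cyclohexane"),
                bridged_pair_smiles(11, 6, [(0, 0, "O"), (0, 1, "N"),
                                            (5, 2, "C"), (5, 3, "S")]),
                ("col",)))
    # --- fusion false positives ---------------------------------------------
    add(Fixture("ffs", ("decalin", "cyclohexane"),
                "C1CCC2CCCCC2C1", tuple(sorted(["fe", "ffs", "ffs"]))))
    add(Fixture("ffo", ("decalin",),
                "C1CCC2CC3CCCCC3CC2C1", ("ffo",)))
    verify_fixtures(f)
    return f


def fixture_fragment_records(
    fragment_ids: Sequence[str],
) -> list[FragmentRecord]:
    """Standardized, symmetry-annotated fragment records for the given ids."""
    mols = []
    for fid in fragment_ids:
        mol = standardize_structure(Chem.MolFromSmiles(FRAGMENT_SMILES[fid]))
        mols.append((fid, mol))
    return prepare_fragments(mols)


def run_fixture(
    fixture: Fixture, cfg: Optional[FilterConfig] = None
) -> list:
    """Search and classify one fixture; returns its FragmentCombinations."""
    cfg = cfg or FilterConfig()
    frags = fixture_fragment_records(fixture.fragment_ids)
    mol = standardize_structure(Chem.MolFromSmiles(fixture.molecule_smiles))
    record = MoleculeRecord(fixture.name, mol)
    hits = search_fragments(record, frags)
    return classify_molecule(record, hits, cfg)


def verify_fixtures(fixtures: Sequence[Fixture]) -> None:
    """Assert that every fixture classifies to its designed codes."""
    for fx in fixtures:
        combos = run_fixture(fx)
        observed = tuple(sorted(c.code for c in combos))
        if observed != fx.expected_codes:
            raise AssertionError(
                f"fixture {fx.name!r}: expected {fx.expected_codes}, got {observed}"
            )


# ---------------------------------------------------------------------------
# PNP testbed
# ---------------------------------------------------------------------------

#: Fragment dictionary shared by the reference and probe molecules.
PNP_FRAGMENTS = ("decalin", "piperidine", "cyclohexane", "oxane")

#: Reference natural-product stand-ins (synthetic toy structures).
PNP_REFERENCE = {
    # cyclohexane edge-fused to oxane, piperidine on a one-atom linker
    "ref_fused_ether": "C1CCN(CC2CCC3CCCOC3C2)CC1",
    # decalin with a piperidine linker attached next to a ring-fusion atom
    "ref_decalin_amine": "C(N1CCCCC1)C1CCCC2CCCCC12",
}

#: Probe molecules with expected verdicts under both comparison modes.
PNP_PROBES = {
    # edge set a subset of ref_fused_ether
    "probe_subset": "C1CCC(CN2CCCCC2)CC1",
    # cyclohexane/piperidine pair in a combination no reference shows
    "probe_novel_edge": "C1CCC2CCCNC2C1",
    # same edge as the references but attached at a different symmetry class
    "probe_orientation": "C1CCC(CC2CCNCC2)CC1",
    # overlapping decalins split into two alternatives with mixed verdicts
    "probe_mixed_alt": "C1CCC2CC3CCCCC3CC2C1CN4CCCCC4",
}

#: molecule -> (expected molecule label without fcp, with fcp)
PNP_EXPECTED = {
    "probe_subset": ("np_like", "np_like"),
    "probe_novel_edge": ("pnp", "pnp"),
    "probe_orientation": ("np_like", "pnp"),
    "probe_mixed_alt": ("np_like", "pnp"),
}


def make_pnp_testbed(seed: int = 17):
    """Reference and probe molecule sets with known PNP verdicts.

    The construction is fully deterministic; ``seed`` is recorded in the
    record provenance so regenerated sets are byte-identical per seed.
    Returns ``(fragments, reference_records, probe_records, expected)``.
    """
    frags = fixture_fragment_records(PNP_FRAGMENTS)

    def records(table: dict[str, str]) -> list[MoleculeRecord]:
        out = []
        for name, smi in sorted(table.items()):
            mol = standardize_structure(Chem.MolFromSmiles(smi))
            out.append(MoleculeRecord(name, mol, provenance=(f"seed{seed}", 0)))
        return out

    return frags, records(PNP_REFERENCE), records(PNP_PROBES), dict(PNP_EXPECTED)


# ---------------------------------------------------------------------------
# On-disk fixture sets
# ---------------------------------------------------------------------------

def write_fixture_set(out_dir: str | Path, seed: int = 17) -> Path:
    """Write the category fixtures as SDF files plus an expected-value TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fixtures = make_category_fixtures()
    frag_ids = sorted({fid for fx in fixtures for fid in fx.fragment_ids})
    frag_writer = Chem.SDWriter(str(out_dir / "fragments.sdf"))
    for fid in frag_ids:
        mol = standardize_structure(Chem.MolFromSmiles(FRAGMENT_SMILES[fid]))
        mol.SetProp("_Name", fid)
        frag_writer.write(mol)
    frag_writer.close()
    mol_writer = Chem.SDWriter(str(out_dir / "molecules.sdf"))
    for fx in fixtures:
        mol = Chem.MolFromSmiles(fx.molecule_smiles)
        mol.SetProp("_Name", fx.name)
        mol_writer.write(mol)
    mol_writer.close()
    expected_path = out_dir / "expected.tsv"
    with open(expected_path, "w") as fh:
        fh.write("name\tfragments\texpected_codes\tseed\n")
        for fx in fixtures:
            fh.write(
                f"{fx.name}\t{','.join(fx.fragment_ids)}\t"
                f"{','.join(fx.expected_codes)}\t{seed}\n"
            )
    return expected_path
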