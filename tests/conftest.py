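"""Shared fixtures and brute-force oracles for the test suite."""

from __future__ import annotations

import itertools

import networkx as nx
import pytest
from rdkit import Chem

from fragcomb.classify import classify_molecule
from fragcomb.fixtures import (
    Fixture,
    fixture_fragment_records,
    make_category_fixtures,
    make_pnp_testbed,
)
from fragcomb.fragments import search_fragments
from fragcomb.prep import FilterConfig, MoleculeRecord, standardize_structure


@pytest.fixture(scope="session")
def cfg() -> FilterConfig:
    return FilterConfig()


@pytest.fixture(scope="session")
def category_fixtures() -> list[Fixture]:
    return make_category_fixtures()


@pytest.fixture(scope="session")
def pnp_testbed():
    return make_pnp_testbed(17)


def std_record(smiles: str, name: str = "mol") -> MoleculeRecord:
    """Standardized record from a SMILES (test helper)."""
    return MoleculeRecord(name, standardize_structure(Chem.MolFromSmiles(smiles)))


def classify_smiles(mol_smiles: str, fragment_ids: tuple[str, ...], cfg=None):
    """Search + classify one molecule against named fixture fragments."""
    rec = std_record(mol_smiles)
    frags = fixture_fragment_records(fragment_ids)
    hits = search_fragments(rec, frags)
    return rec, hits, classify_molecule(rec, hits, cfg or FilterConfig())


# ---------------------------------------------------------------------------
# Brute-force oracles (independent of the implementation paths they check)
# ---------------------------------------------------------------------------

def mol_to_nx(mol: Chem.Mol) -> nx.Graph:
    g = nx.Graph()
    for atom in mol.GetAtoms():
        g.add_node(
            atom.GetIdx(),
            element=atom.GetAtomicNum(),
            aromatic=atom.GetIsAromatic(),
        )
    for bond in mol.GetBonds():
        g.add_edge(
            bond.GetBeginAtomIdx(),
            bond.GetEndAtomIdx(),
            order=str(bond.GetBondType()),
        )
    return g


def is_subgraph_match(mol: Chem.Mol, frag: Chem.Mol, atom_map: tuple[int, ...]) -> bool:
    """Independently re-test that atom_map embeds frag into mol (elements,
    aromaticity and bond orders all preserved)."""
    if len(set(atom_map)) != len(atom_map):
        return False
    for i, m in enumerate(atom_map):
        fa, ma = frag.GetAtomWithIdx(i), mol.GetAtomWithIdx(m)
        if fa.GetAtomicNum() != ma.GetAtomicNum():
            return False
        if fa.GetIsAromatic() != ma.GetIsAromatic():
            return False
    for bond in frag.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        mb = mol.GetBondBetweenAtoms(atom_map[i], atom_map[j])
        if mb is None or mb.GetBondType() != bond.GetBondType():
            return False
    return True


def brute_force_orbits(mol: Chem.Mol) -> list[set[int]]:
    """Automorphism orbits via exhaustive networkx isomorphism enumeration."""
    g = mol_to_nx(mol)
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        g, g,
        node_match=lambda a, b: (a["element"], a["aromatic"]) == (b["element"], b["aromatic"]),
        edge_match=lambda a, b: a["order"] == b["order"],
    )
    parent = list(range(mol.GetNumAtoms()))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for mapping in matcher.isomorphisms_iter():
        for i, j in mapping.items():
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
    orbits: dict[int, set[int]] = {}
    for i in range(mol.GetNumAtoms()):
        orbits.setdefault(find(i), set()).add(i)
    return list(orbits.values())


def oracle_intermediary_rings(mol, hit_a, hit_b) -> list[frozenset[int]]:
    """Brute-force enumeration over the molecule's perceived ring sets."""
    out = []
    for ring in mol.GetRingInfo().AtomRings():
        ring = frozenset(ring)
        touches_a = bool(ring & hit_a.ring_atoms)
        touches_b = bool(ring & hit_b.ring_atoms)
        inside = ring <= hit_a.atom_set or ring <= hit_b.atom_set
        if touches_a and touches_b and not inside:
            out.append(ring)
    return out


def oracle_min_linker(mol: Chem.Mol, hit_a, hit_b):
    """Minimum intermediary-atom count by exhaustive simple-path search."""
    g = mol_to_nx(mol)
    blocked = hit_a.atom_set | hit_b.atom_set
    best = None
    for u in hit_a.ring_atoms:
        for v in hit_b.ring_atoms:
            for path in nx.all_simple_paths(g, u, v, cutoff=8):
                interior = [x for x in path[1:-1]]
                if any(x in blocked for x in interior):
                    continue
                n = len(interior)
                best = n if best is None else min(best, n)
    return best
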