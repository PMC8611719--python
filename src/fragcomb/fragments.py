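"""Fragment symmetry annotation and substructure search.

Fragments are Murcko ring scaffolds used as exact substructure queries.
Each fragment carries per-atom symmetry classes (automorphism orbits,
computed by matching the fragment onto itself) which later serve as
fragment combination points when graph comparison is orientation-aware.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from rdkit import Chem

from .prep import MoleculeRecord

_MAX_MATCHES = 1 << 16


@dataclass(frozen=True)
class FragmentRecord:
    """A prepared fragment with automorphism-orbit labels per atom.

    Two atoms share a ``symmetry_class`` label iff some automorphism of the
    fragment maps one onto the other; labels are the smallest canonical
    atom rank within each orbit, so they are stable across atom orderings.
    """

    fragment_id: str
    mol: Chem.Mol
    symmetry_class: tuple[int, ...] = ()

    @property
    def n_classes(self) -> int:
        return len(set(self.symmetry_class))


@dataclass(frozen=True)
class FragmentHit:
    """One substructure match of a fragment in a molecule.

    ``atom_map[i]`` is the molecule atom matched by fragment atom ``i``
    (injective); ``ring_atoms`` is the subset of matched molecule atoms
    lying in rings of the molecule, the only atoms considered during
    combination classification.
    """

    molecule_id: str
    fragment_id: str
    hit_index: int
    atom_map: tuple[int, ...]
    ring_atoms: frozenset[int]

    @property
    def atom_set(self) -> frozenset[int]:
        return frozenset(self.atom_map)

    def fragment_atoms_of(self, molecule_atoms: Iterable[int]) -> tuple[int, ...]:
        """Fragment atom indices mapping onto the given molecule atoms."""
        rev = {m: f for f, m in enumerate(self.atom_map)}
        return tuple(sorted(rev[a] for a in molecule_atoms if a in rev))


def annotate_symmetry_classes(fragment: FragmentRecord) -> FragmentRecord:
    """Label every fragment atom with its automorphism orbit.

    Orbits are derived from all self-substructure matches of the fragment
    (the automorphism group acting on atoms); the orbit label is the
    minimum canonical rank over the orbit's members.
    """
    mol = fragment.mol
    n = mol.GetNumAtoms()
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for match in mol.GetSubstructMatches(mol, uniquify=False, maxMatches=_MAX_MATCHES):
        for i, j in enumerate(match):
            union(i, j)

    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=True))
    orbit_label: dict[int, int] = {}
    for i in range(n):
        root = find(i)
        orbit_label[root] = min(orbit_label.get(root, ranks[i]), ranks[i])
    labels = tuple(orbit_label[find(i)] for i in range(n))
    return FragmentRecord(fragment.fragment_id, mol, labels)


def prepare_fragments(
    named_mols: Iterable[tuple[str, Chem.Mol]]
) -> list[FragmentRecord]:
    """Wrap and annotate already-standardized fragment structures."""
    return [
        annotate_symmetry_classes(FragmentRecord(name, mol))
        for name, mol in named_mols
    ]


def search_fragments(
    record: MoleculeRecord,
    fragments: Sequence[FragmentRecord],
    excluded: Optional[Iterable[str]] = None,
) -> list[FragmentHit]:
    """Find all distinct fragment matches in a prepared molecule.

    Distinct hits are distinct matched atom-sets: automorphic re-mappings
    of one atom-set collapse to a single canonical representative, so the
    fragment's internal symmetry never inflates combination counts. Hits
    of different fragments may overlap and a fragment may hit several
    times. ``excluded`` fragment ids (e.g. benzene) are skipped entirely.
    """
    excluded = set(excluded or ())
    mol = record.mol
    hits: list[FragmentHit] = []
    idx = 0
    for frag in fragments:
        if frag.fragment_id in excluded:
            continue
        matches = mol.GetSubstructMatches(
            frag.mol, uniquify=True, maxMatches=_MAX_MATCHES
        )
        for match in matches:
            ring_atoms = frozenset(
                a for a in match if mol.GetAtomWithIdx(a).IsInRing()
            )
            hits.append(
                FragmentHit(record.record_id, frag.fragment_id, idx, tuple(match), ring_atoms)
            )
            idx += 1
    return hits


def write_hits_tsv(hits: Iterable[FragmentHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("molecule_id\tfragment_id\thit_index\tatom_map\tring_atoms\n")
        for h in hits:
            fh.write(
                f"{h.molecule_id}\t{h.fragment_id}\t{h.hit_index}\t"
                f"{','.join(map(str, h.atom_map))}\t"
                f"{','.join(map(str, sorted(h.ring_atoms)))}\n"
            )


def read_hits_tsv(path) -> dict[str, list[FragmentHit]]:
    """Load hits grouped by molecule id, preserving file order."""
    out: dict[str, list[FragmentHit]] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            mol_id, frag_id, idx, amap, ratoms = line.rstrip("\n").split("\t")
            hit = FragmentHit(
                mol_id,
                frag_id,
                int(idx),
                tuple(int(x) for x in amap.split(",") if x),
                frozenset(int(x) for x in ratoms.split(",") if x),
            )
            out.setdefault(mol_id, []).append(hit)
    return out
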