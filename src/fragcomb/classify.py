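"""Classification of fragment pair combinations.

Every pair of fragment hits in a molecule is assigned one of 18 valid
combination categories or one of 3 false-positive classes, based purely on
the relative position of the two matches in the molecular graph:

* fusion (shared ring atoms): spiro ``fs`` (1 fused atom), edge ``fe``
  (2), bridged ``fb`` (3-5), linker ``fl`` (>5);
* connection (no shared ring atoms): the number of intermediary rings
  (molecule rings touching both hits) sets the degree — monopodal ``cm``
  or annulated ``ca`` (0 rings), bipodal ``cb*`` (1), tripodal ``ct*``
  (2), other ``co*`` (>2) — and per-ring connection point counts set the
  subtype (spiro/edge/bridged/linker) with priority
  linker > spiro > bridged > edge;
* false positives: ``cfc`` (linker longer than the cutoff, dropped),
  ``ffs`` (one hit a substructure of the other), ``ffo`` (hits overlapping
  on a complete molecule ring).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional, Sequence

from rdkit import Chem

from .fragments import FragmentHit
from .prep import FilterConfig, MoleculeRecord

#: code -> (category, type, subtype)
CATEGORY_TABLE: dict[str, tuple[str, str, Optional[str]]] = {
    "fs": ("fusion", "spiro", None),
    "fe": ("fusion", "edge", None),
    "fb": ("fusion", "bridged", None),
    "fl": ("fusion", "linker", None),
    "cm": ("connection", "monopodal", None),
    "ca": ("connection", "annulated", None),
    "cbs": ("connection", "bipodal", "spiro"),
    "cbe": ("connection", "bipodal", "edge"),
    "cbb": ("connection", "bipodal", "bridged"),
    "cbl": ("connection", "bipodal", "linker"),
    "cts": ("connection", "tripodal", "spiro"),
    "cte": ("connection", "tripodal", "edge"),
    "ctb": ("connection", "tripodal", "bridged"),
    "ctl": ("connection", "tripodal", "linker"),
    "cos": ("connection", "other", "spiro"),
    "coe": ("connection", "other", "edge"),
    "cob": ("connection", "other", "bridged"),
    "col": ("connection", "other", "linker"),
    "cfc": ("false_positive", "cutoff", None),
    "ffs": ("false_positive", "substructure", None),
    "ffo": ("false_positive", "overlap", None),
}

VALID_CODES = frozenset(c for c, (cat, _, _) in CATEGORY_TABLE.items() if cat != "false_positive")
FALSE_POSITIVE_CODES = frozenset(CATEGORY_TABLE) - VALID_CODES


@dataclass(frozen=True)
class FragmentCombination:
    """A classified hit pair with the evidence behind the verdict.

    ``engaged_a``/``engaged_b`` hold the molecule atoms of each hit that
    take part in the combination (fused atoms for fusions, connection
    point or linker attachment atoms for connections); they feed the
    orientation-aware fcp edge labels downstream.
    """

    molecule_id: str
    hit_a: FragmentHit
    hit_b: FragmentHit
    code: str
    fused_atoms: frozenset[int] = frozenset()
    intermediary_rings: tuple[frozenset[int], ...] = ()
    engaged_a: frozenset[int] = frozenset()
    engaged_b: frozenset[int] = frozenset()

    @property
    def category(self) -> str:
        return CATEGORY_TABLE[self.code][0]


def molecule_rings(mol: Chem.Mol) -> list[frozenset[int]]:
    """Perceived rings of the molecule (RDKit's symmetrized SSSR)."""
    return [frozenset(r) for r in mol.GetRingInfo().AtomRings()]


def fused_atoms(a: FragmentHit, b: FragmentHit) -> frozenset[int]:
    """Molecule atoms shared by the ring-atom sets of both hits."""
    if a.atom_map == b.atom_map and a.fragment_id == b.fragment_id:
        raise ValueError("fused_atoms requires two distinct hits")
    return a.ring_atoms & b.ring_atoms


def classify_fusion(n_fused: int) -> str:
    """Fusion type from the fused atom count."""
    if n_fused == 1:
        return "fs"
    if n_fused == 2:
        return "fe"
    if 3 <= n_fused <= 5:
        return "fb"
    return "fl"


def intermediary_rings(
    mol: Chem.Mol, a: FragmentHit, b: FragmentHit
) -> list[frozenset[int]]:
    """Molecule rings sharing atoms with both hits but contained in neither."""
    out = []
    for ring in molecule_rings(mol):
        if ring & a.ring_atoms and ring & b.ring_atoms:
            if not (ring <= a.atom_set or ring <= b.atom_set):
                out.append(ring)
    return out


def _ring_system_components(mol: Chem.Mol) -> dict[int, int]:
    """Map each ring atom to a ring-system component id (ring atoms joined
    by ring bonds)."""
    parent: dict[int, int] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for atom in mol.GetAtoms():
        if atom.IsInRing():
            parent[atom.GetIdx()] = atom.GetIdx()
    for bond in mol.GetBonds():
        if bond.IsInRing():
            i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
    return {i: find(i) for i in parent}


def _shared_ring_system(mol: Chem.Mol, a: FragmentHit, b: FragmentHit) -> bool:
    comp = _ring_system_components(mol)
    comps_a = {comp[i] for i in a.ring_atoms if i in comp}
    comps_b = {comp[i] for i in b.ring_atoms if i in comp}
    return bool(comps_a & comps_b)


def _linker_search(
    mol: Chem.Mol, a: FragmentHit, b: FragmentHit
) -> tuple[Optional[int], frozenset[int], frozenset[int]]:
    """Minimum number of intermediary atoms between the hits' ring atoms,
    plus the attachment atoms of each hit on the optimal paths.

    Intermediary atoms are path atoms belonging to neither hit; paths run
    through atoms outside both hits. Returns (None, ..) if the hits are
    not connected outside themselves.
    """
    blocked = a.atom_set | b.atom_set
    adj = [
        [n.GetIdx() for n in mol.GetAtomWithIdx(i).GetNeighbors()]
        for i in range(mol.GetNumAtoms())
    ]

    def bfs_levels(sources: frozenset[int]) -> dict[int, int]:
        # dist[x] = number of intermediary atoms up to and including x
        dist: dict[int, int] = {}
        q = deque()
        for s in sources:
            for n in adj[s]:
                if n not in blocked and n not in dist:
                    dist[n] = 1
                    q.append(n)
        while q:
            x = q.popleft()
            for n in adj[x]:
                if n not in blocked and n not in dist:
                    dist[n] = dist[x] + 1
                    q.append(n)
        return dist

    # direct bond between the two hits' ring atoms: zero intermediary atoms
    direct_a, direct_b = set(), set()
    for u in a.ring_atoms:
        for n in adj[u]:
            if n in b.ring_atoms:
                direct_a.add(u)
                direct_b.add(n)
    if direct_a:
        return 0, frozenset(direct_a), frozenset(direct_b)

    da = bfs_levels(a.ring_atoms)
    db = bfs_levels(b.ring_atoms)
    common = set(da) & set(db)
    if not common:
        return None, frozenset(), frozenset()
    best = min(da[x] + db[x] - 1 for x in common)
    on_path = {x for x in common if da[x] + db[x] - 1 == best}
    # propagate optimality backwards to find all first-step atoms
    attach_a = {
        u for u in a.ring_atoms
        for n in adj[u]
        if n in on_path and da.get(n) == 1
    }
    attach_b = {
        v for v in b.ring_atoms
        for n in adj[v]
        if n in on_path and db.get(n) == 1
    }
    return best, frozenset(attach_a), frozenset(attach_b)


def _ring_subtype(cp_a: int, cp_b: int) -> str:
    """Subtype contributed by one intermediary ring from its CP counts."""
    if cp_a > 5 or cp_b > 5:
        return "linker"
    if cp_a == 1 or cp_b == 1:
        return "spiro"
    if 3 <= cp_a <= 5 or 3 <= cp_b <= 5:
        return "bridged"
    return "edge"


_SUBTYPE_PRIORITY = ("linker", "spiro", "bridged", "edge")
_SUBTYPE_LETTER = {"linker": "l", "spiro": "s", "bridged": "b", "edge": "e"}
_DEGREE_LETTER = {1: "b", 2: "t"}


def classify_connection(
    mol: Chem.Mol, a: FragmentHit, b: FragmentHit, cfg: FilterConfig
) -> tuple[str, list[frozenset[int]], frozenset[int], frozenset[int]]:
    """Classify a pair with no fused atoms.

    Returns (code, intermediary rings, engaged atoms of a, engaged atoms
    of b). ``cfc`` marks pairs whose shortest linker exceeds the cutoff.
    """
    rings = intermediary_rings(mol, a, b)
    k = len(rings)
    if k == 0:
        if _shared_ring_system(mol, a, b):
            _, attach_a, attach_b = _linker_search(mol, a, b)
            return "ca", rings, attach_a, attach_b
        n_linker, attach_a, attach_b = _linker_search(mol, a, b)
        if n_linker is None or n_linker > cfg.linker_cutoff:
            return "cfc", rings, attach_a, attach_b
        return "cm", rings, attach_a, attach_b
    subtypes = set()
    for ring in rings:
        cp_a = len(ring & a.ring_atoms)
        cp_b = len(ring & b.ring_atoms)
        subtypes.add(_ring_subtype(cp_a, cp_b))
    subtype = next(s for s in _SUBTYPE_PRIORITY if s in subtypes)
    degree = _DEGREE_LETTER.get(k, "o")
    code = f"c{degree}{_SUBTYPE_LETTER[subtype]}"
    engaged_a = frozenset().union(*[ring & a.ring_atoms for ring in rings])
    engaged_b = frozenset().union(*[ring & b.ring_atoms for ring in rings])
    return code, rings, engaged_a, engaged_b


def classify_pair(
    mol: Chem.Mol, a: FragmentHit, b: FragmentHit, cfg: Optional[FilterConfig] = None
) -> Optional[FragmentCombination]:
    """Run one hit pair through the full decision tree.

    Order of checks: substructure inclusion (``ffs``), ring-atom
    intersection covering a complete molecule ring (``ffo``), fusion by
    fused-atom count, then connection. Self-duplicate pairs (same fragment
    matched on the same atoms) are skipped and return None.
    """
    cfg = cfg or FilterConfig()
    if a.fragment_id == b.fragment_id and a.atom_set == b.atom_set:
        return None
    mid = a.molecule_id
    if a.atom_set <= b.atom_set or b.atom_set <= a.atom_set:
        fused = a.ring_atoms & b.ring_atoms
        return FragmentCombination(mid, a, b, "ffs", fused_atoms=fused,
                                   engaged_a=fused & a.ring_atoms,
                                   engaged_b=fused & b.ring_atoms)
    fused = fused_atoms(a, b)
    if fused:
        if any(ring <= fused for ring in molecule_rings(mol)):
            return FragmentCombination(mid, a, b, "ffo", fused_atoms=fused,
                                       engaged_a=fused, engaged_b=fused)
        code = classify_fusion(len(fused))
        return FragmentCombination(mid, a, b, code, fused_atoms=fused,
                                   engaged_a=fused, engaged_b=fused)
    code, rings, engaged_a, engaged_b = classify_connection(mol, a, b, cfg)
    return FragmentCombination(
        mid, a, b, code,
        intermediary_rings=tuple(rings),
        engaged_a=engaged_a, engaged_b=engaged_b,
    )


def classify_molecule(
    record: MoleculeRecord,
    hits: Sequence[FragmentHit],
    cfg: Optional[FilterConfig] = None,
) -> list[FragmentCombination]:
    """Classify every unordered hit pair of a molecule.

    ``cfc`` pairs are dropped from the output entirely; ``ffs``/``ffo``
    pairs are reported so that graph assembly can prune and split on them.
    A molecule whose list comes back empty has no meaningful combination
    and is removed downstream.
    """
    cfg = cfg or FilterConfig()
    out = []
    for a, b in combinations(hits, 2):
        combo = classify_pair(record.mol, a, b, cfg)
        if combo is not None and combo.code != "cfc":
            out.append(combo)
    return out


def write_combinations_tsv(combos: Iterable[FragmentCombination], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "molecule_id\thit_a\thit_b\tfragment_a\tfragment_b\tcode\t"
            "fused_atoms\tn_intermediary_rings\tengaged_a\tengaged_b\n"
        )
        for c in combos:
            fh.write(
                f"{c.molecule_id}\t{c.hit_a.hit_index}\t{c.hit_b.hit_index}\t"
                f"{c.hit_a.fragment_id}\t{c.hit_b.fragment_id}\t{c.code}\t"
                f"{','.join(map(str, sorted(c.fused_atoms)))}\t"
                f"{len(c.intermediary_rings)}\t"
                f"{','.join(map(str, sorted(c.engaged_a)))}\t"
                f"{','.join(map(str, sorted(c.engaged_b)))}\n"
            )


def read_combinations_tsv(
    path, hits_by_mol: dict[str, Sequence[FragmentHit]]
) -> dict[str, list[FragmentCombination]]:
    """Load combinations grouped by molecule, resolving hit references."""

    def _ints(s: str) -> frozenset[int]:
        return frozenset(int(x) for x in s.split(",") if x)

    out: dict[str, list[FragmentCombination]] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            (mid, ia, ib, _, _, code, fused, _, eng_a, eng_b) = (
                line.rstrip("\n").split("\t")
            )
            index = {h.hit_index: h for h in hits_by_mol[mid]}
            out.setdefault(mid, []).append(
                FragmentCombination(
                    mid, index[int(ia)], index[int(ib)], code,
                    fused_atoms=_ints(fused),
                    engaged_a=_ints(eng_a), engaged_b=_ints(eng_b),
                )
            )
    return out
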