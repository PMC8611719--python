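"""Fragment combination graphs (FCGs).

Classified combinations of a molecule are assembled into graphs with
fragment occurrences as nodes and combination categories as edges.
Substructure false positives (``ffs``) prune the smaller hit; overlap
false positives (``ffo``) split the molecule into alternative graphs (one
per choice of which overlapping hit to keep), capped at a maximum number
of overlaps per molecule; disconnected components become separate graphs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx

from .classify import FragmentCombination, FALSE_POSITIVE_CODES
from .fragments import FragmentHit, FragmentRecord
from .prep import FilterConfig, MoleculeRecord


@dataclass
class FragmentCombinationGraph:
    """One (alternative) fragment combination graph of a molecule.

    Nodes are hit indices carrying ``fragment_id``; edges carry the
    combination ``code`` and optional fcp labels (the symmetry classes of
    the engaged fragment atoms at each endpoint). ``merged`` graphs are
    unions of alternatives and may be disconnected.
    """

    molecule_id: str
    alt_index: int
    graph: nx.Graph
    merged: bool = False

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def fragment_ids(self) -> list[str]:
        return [d["fragment_id"] for _, d in self.graph.nodes(data=True)]


def _fcp_label(
    hit: FragmentHit,
    engaged: frozenset[int],
    fragments: Optional[dict[str, FragmentRecord]],
) -> Optional[tuple[int, ...]]:
    """Sorted multiset of symmetry classes of the hit's engaged atoms."""
    if fragments is None:
        return None
    frag = fragments.get(hit.fragment_id)
    if frag is None or not frag.symmetry_class:
        return None
    frag_atoms = hit.fragment_atoms_of(engaged)
    return tuple(sorted(frag.symmetry_class[i] for i in frag_atoms))


def _add_edge(
    g: nx.Graph,
    combo: FragmentCombination,
    fragments: Optional[dict[str, FragmentRecord]],
) -> None:
    a, b = combo.hit_a, combo.hit_b
    g.add_node(a.hit_index, fragment_id=a.fragment_id, hit=a)
    g.add_node(b.hit_index, fragment_id=b.fragment_id, hit=b)
    g.add_edge(
        a.hit_index,
        b.hit_index,
        code=combo.code,
        fcp={
            a.hit_index: _fcp_label(a, combo.engaged_a, fragments),
            b.hit_index: _fcp_label(b, combo.engaged_b, fragments),
        },
    )


def count_overlaps(combos: Sequence[FragmentCombination]) -> int:
    return sum(1 for c in combos if c.code == "ffo")


def build_fcgs(
    record: MoleculeRecord,
    combos: Sequence[FragmentCombination],
    cfg: Optional[FilterConfig] = None,
    fragments: Optional[Sequence[FragmentRecord]] = None,
) -> list[FragmentCombinationGraph]:
    """Assemble the alternative FCGs of one molecule.

    Steps: drop substructure hits (``ffs``) with all their combinations;
    filter the molecule out entirely (empty result) when it has more than
    ``cfg.max_overlaps`` ``ffo`` pairs; take the Cartesian product of
    keep-one choices over ``ffo`` pairs; per alternative, build the graph
    from valid edges, split connected components, discard edgeless graphs
    and deduplicate identical alternatives.
    """
    cfg = cfg or FilterConfig()
    frag_index = (
        {f.fragment_id: f for f in fragments} if fragments is not None else None
    )

    # 1. ffs pruning: delete the substructure (smaller) hit everywhere
    dropped: set[int] = set()
    for c in combos:
        if c.code != "ffs":
            continue
        small, large = sorted(
            (c.hit_a, c.hit_b), key=lambda h: (len(h.atom_set), h.hit_index)
        )
        if small.atom_set <= large.atom_set:
            dropped.add(small.hit_index)
        else:
            dropped.add(large.hit_index)
    live = [
        c for c in combos
        if c.hit_a.hit_index not in dropped and c.hit_b.hit_index not in dropped
    ]

    # 2. overlap cap
    ffo_pairs = [c for c in live if c.code == "ffo"]
    if len(ffo_pairs) > cfg.max_overlaps:
        return []

    valid = [c for c in live if c.code not in FALSE_POSITIVE_CODES]

    # 3. overlap splitting: keep exactly one hit per ffo pair
    removal_sets: set[frozenset[int]] = set()
    if ffo_pairs:
        for choice in itertools.product(*[
            (c.hit_a.hit_index, c.hit_b.hit_index) for c in ffo_pairs
        ]):
            removal_sets.add(frozenset(choice))
    else:
        removal_sets.add(frozenset())

    out: list[FragmentCombinationGraph] = []
    seen: set[frozenset] = set()
    for removal in sorted(removal_sets, key=sorted):
        g = nx.Graph()
        for c in valid:
            if c.hit_a.hit_index in removal or c.hit_b.hit_index in removal:
                continue
            _add_edge(g, c, frag_index)
        for comp in sorted(nx.connected_components(g), key=min):
            sub = g.subgraph(comp).copy()
            if sub.number_of_edges() == 0:
                continue
            key = frozenset(
                (u, v, d["code"]) for u, v, d in sub.edges(data=True)
            ) | frozenset(sub.nodes)
            if key in seen:
                continue
            seen.add(key)
            out.append(
                FragmentCombinationGraph(record.record_id, len(out), sub)
            )
    return out


def merge_fcgs(
    graphs: Sequence[FragmentCombinationGraph],
) -> FragmentCombinationGraph:
    """Union of a molecule's FCGs with common parts counted once."""
    if not graphs:
        raise ValueError("cannot merge an empty list of graphs")
    mol_ids = {g.molecule_id for g in graphs}
    if len(mol_ids) != 1:
        raise ValueError("merge requires graphs of a single molecule")
    merged = nx.Graph()
    for g in graphs:
        merged.add_nodes_from(g.graph.nodes(data=True))
        merged.add_edges_from(g.graph.edges(data=True))
    return FragmentCombinationGraph(graphs[0].molecule_id, 0, merged, merged=True)


# ---------------------------------------------------------------------------
# Canonical signatures and edge tokens
# ---------------------------------------------------------------------------

def edge_token(
    g: nx.Graph, u: int, v: int, with_fcp: bool = False
) -> str:
    """Canonical token for one edge: ``fragmin|fragmax|code[|fcpA|fcpB]``.

    Endpoints are oriented by fragment id; ties on equal fragment ids are
    resolved by sorting the two fcp serializations, keeping the token
    deterministic for symmetric fragment pairs.
    """
    data = g.edges[u, v]
    fu = g.nodes[u]["fragment_id"]
    fv = g.nodes[v]["fragment_id"]
    if not with_fcp:
        a, b = sorted((fu, fv))
        return f"{a}|{b}|{data['code']}"
    fcp = data.get("fcp") or {}
    su = _fcp_str(fcp.get(u))
    sv = _fcp_str(fcp.get(v))
    (a, sa), (b, sb) = sorted(((fu, su), (fv, sv)))
    return f"{a}|{b}|{data['code']}|{sa}|{sb}"


def _fcp_str(label: Optional[tuple[int, ...]]) -> str:
    return "" if label is None else ",".join(map(str, label))


def graph_signature(fcg: FragmentCombinationGraph, with_fcp: bool = False) -> str:
    """Canonical serialization invariant under node relabeling.

    The sorted multiset of edge tokens plus tokens for isolated nodes:
    two graphs share a signature iff their labeled node/edge multisets are
    identical. Parallel identical edges collapse (occurrences are not
    counted in comparisons).
    """
    g = fcg.graph
    tokens = sorted(edge_token(g, u, v, with_fcp) for u, v in g.edges)
    isolated = sorted(
        g.nodes[n]["fragment_id"] for n in g.nodes if g.degree(n) == 0
    )
    return ";".join(tokens + [f"node:{f}" for f in isolated])


# ---------------------------------------------------------------------------
# Persistence (GraphML + index TSV)
# ---------------------------------------------------------------------------

def write_fcgs(
    graphs: Iterable[FragmentCombinationGraph], out_dir: str | Path
) -> Path:
    """Write one GraphML per graph plus a TSV index; returns the index path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    index_path = out_dir / "fcg_index.tsv"
    with open(index_path, "w") as idx:
        idx.write("molecule_id\talt_index\tn_nodes\tn_edges\tsignature\tfile\n")
        for fcg in graphs:
            g = nx.Graph()
            for n, d in fcg.graph.nodes(data=True):
                g.add_node(n, fragment_id=d["fragment_id"])
            for u, v, d in fcg.graph.edges(data=True):
                fcp = d.get("fcp") or {}
                g.add_edge(
                    u, v, code=d["code"],
                    fcp_a=_fcp_str(fcp.get(u)), fcp_b=_fcp_str(fcp.get(v)),
                )
            name = f"{fcg.molecule_id}_{fcg.alt_index}.graphml"
            nx.write_graphml(g, out_dir / name)
            idx.write(
                f"{fcg.molecule_id}\t{fcg.alt_index}\t{fcg.n_nodes}\t"
                f"{fcg.n_edges}\t{graph_signature(fcg)}\t{name}\n"
            )
    return index_path


def read_fcgs(in_dir: str | Path) -> list[FragmentCombinationGraph]:
    """Load FCGs written by :func:`write_fcgs`."""
    in_dir = Path(in_dir)
    out = []
    index_path = in_dir / "fcg_index.tsv"
    with open(index_path) as fh:
        header = fh.readline()
        for line in fh:
            mol_id, alt, _, _, _, name = line.rstrip("\n").split("\t")
            raw = nx.read_graphml(in_dir / name)
            g = nx.Graph()
            relabel = {n: int(n) for n in raw.nodes}
            for n, d in raw.nodes(data=True):
                g.add_node(relabel[n], fragment_id=d["fragment_id"])
            for u, v, d in raw.edges(data=True):
                iu, iv = relabel[u], relabel[v]
                fcp = {}
                for node, key in ((iu, "fcp_a"), (iv, "fcp_b")):
                    s = d.get(key, "")
                    fcp[node] = tuple(int(x) for x in s.split(",")) if s else None
                g.add_edge(iu, iv, code=d["code"], fcp=fcp)
            out.append(FragmentCombinationGraph(mol_id, int(alt), g))
    return out
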