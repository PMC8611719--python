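"""Pseudo-natural-product (PNP) annotation.

A probe FCG is *NP-like* when some natural-product reference FCG contains
every one of its fragment combinations (edge tokens, occurrences ignored);
otherwise it is a *PNP* — a fragment connectivity not found in any known
natural product. A molecule is a PNP as soon as at least one of its
alternative graphs is.

With ``with_fcp=True`` the edge tokens additionally carry the symmetry
classes of the engaged fragment atoms, so two combinations only match
when the fragments are attached in equivalent orientations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .fcg import FragmentCombinationGraph, edge_token


def edge_token_set(fcg: FragmentCombinationGraph, with_fcp: bool = False) -> frozenset[str]:
    """Set (not multiset) of canonical edge tokens of a graph."""
    g = fcg.graph
    return frozenset(edge_token(g, u, v, with_fcp) for u, v in g.edges)


@dataclass
class ReferenceGraphSet:
    """Natural-product reference FCGs with an inverted token index.

    ``index`` maps each edge token to the ids of reference graphs holding
    it, pruning the candidate set during containment queries.
    """

    graphs: list[FragmentCombinationGraph]
    with_fcp: bool = False
    token_sets: list[frozenset[str]] = field(default_factory=list)
    index: dict[str, set[int]] = field(default_factory=dict)

    @classmethod
    def build(
        cls, graphs: Sequence[FragmentCombinationGraph], with_fcp: bool = False
    ) -> "ReferenceGraphSet":
        for g in graphs:
            if g.n_edges == 0:
                raise ValueError("reference graphs must have at least one edge")
        ref = cls(list(graphs), with_fcp)
        for gid, g in enumerate(ref.graphs):
            tokens = edge_token_set(g, with_fcp)
            ref.token_sets.append(tokens)
            for t in tokens:
                ref.index.setdefault(t, set()).add(gid)
        return ref

    def containing(self, tokens: frozenset[str]) -> Optional[int]:
        """Id of one reference graph whose token set contains ``tokens``."""
        if not tokens:
            return None
        candidates: Optional[set[int]] = None
        for t in tokens:
            ids = self.index.get(t)
            if not ids:
                return None
            candidates = ids.copy() if candidates is None else candidates & ids
            if not candidates:
                return None
        return min(candidates)


@dataclass
class PNPVerdict:
    """Per-graph and per-molecule PNP / NP-like labels for one molecule."""

    molecule_id: str
    per_graph: list[dict]
    molecule_label: str  # "pnp" | "np_like"


def annotate_pnp(
    probe_graphs: Sequence[FragmentCombinationGraph],
    ref: ReferenceGraphSet,
    with_fcp: bool = False,
    known_fragments: Optional[Iterable[str]] = None,
) -> PNPVerdict:
    """Label every alternative FCG of one molecule against the reference.

    A graph is ``np_like`` iff some reference graph's token set is a
    superset of its own; otherwise ``pnp``. The molecule is ``pnp`` iff at
    least one of its graphs is. ``known_fragments``, when given, guards
    against probe graphs built from a different fragment dictionary.
    """
    if not probe_graphs:
        raise ValueError("no probe graphs given")
    mol_ids = {g.molecule_id for g in probe_graphs}
    if len(mol_ids) != 1:
        raise ValueError("probe graphs must belong to a single molecule")
    if known_fragments is not None:
        known = set(known_fragments)
        for g in probe_graphs:
            unknown = set(g.fragment_ids()) - known
            if unknown:
                raise ValueError(f"unknown fragment ids in probe: {sorted(unknown)}")
    per_graph = []
    any_pnp = False
    for g in probe_graphs:
        tokens = edge_token_set(g, with_fcp)
        witness = ref.containing(tokens)
        label = "np_like" if witness is not None else "pnp"
        any_pnp = any_pnp or label == "pnp"
        per_graph.append(
            {
                "alt_index": g.alt_index,
                "label": label,
                "matching_reference": (
                    ref.graphs[witness].molecule_id if witness is not None else None
                ),
            }
        )
    return PNPVerdict(
        molecule_id=next(iter(mol_ids)),
        per_graph=per_graph,
        molecule_label="pnp" if any_pnp else "np_like",
    )


def annotate_dataset(
    probe_graphs: Sequence[FragmentCombinationGraph],
    ref: ReferenceGraphSet,
    with_fcp: bool = False,
) -> list[PNPVerdict]:
    """Group probe graphs by molecule and annotate each molecule."""
    by_mol: dict[str, list[FragmentCombinationGraph]] = {}
    for g in probe_graphs:
        by_mol.setdefault(g.molecule_id, []).append(g)
    return [
        annotate_pnp(graphs, ref, with_fcp) for _, graphs in sorted(by_mol.items())
    ]


def read_verdicts_tsv(path) -> list[PNPVerdict]:
    """Load verdicts written by :func:`write_verdicts_tsv`."""
    by_mol: dict[str, PNPVerdict] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            mid, alt, label, witness, mol_label = line.rstrip("\n").split("\t")
            v = by_mol.setdefault(mid, PNPVerdict(mid, [], mol_label))
            v.per_graph.append(
                {
                    "alt_index": int(alt),
                    "label": label,
                    "matching_reference": witness or None,
                }
            )
    return list(by_mol.values())


def write_verdicts_tsv(verdicts: Iterable[PNPVerdict], path) -> None:
    with open(path, "w") as fh:
        fh.write("molecule_id\talt_index\tlabel\twitness_reference_id\tmolecule_label\n")
        for v in verdicts:
            for pg in v.per_graph:
                fh.write(
                    f"{v.molecule_id}\t{pg['alt_index']}\t{pg['label']}\t"
                    f"{pg['matching_reference'] or ''}\t{v.molecule_label}\n"
                )
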