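"""Dataset-level comparison statistics.

Per-molecule fragment counts and coverages computed on merged fragment
combination graphs, plus dataset tables: fragment and combination-code
frequencies, members-per-scaffold histograms (FCG-signature scaffolds and
Murcko scaffolds) and moment statistics of the coverage distribution.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from rdkit import Chem
from scipy import stats

from .fcg import FragmentCombinationGraph, graph_signature, merge_fcgs
from .fragments import FragmentHit
from .pnp import PNPVerdict
from .prep import MoleculeRecord, extract_murcko


def molecule_coverage(
    mol: Chem.Mol, hits: Sequence[FragmentHit], scaffold_only: bool = False
) -> float:
    """Fraction of heavy atoms covered by the retained fragment hits.

    ``scaffold_only`` restricts the denominator (and the covered set) to
    the molecule's Murcko scaffold atoms — rings and linkers only.
    """
    if scaffold_only:
        scaffold = extract_murcko(mol)
        matches = mol.GetSubstructMatches(scaffold, maxMatches=1)
        if not matches:
            raise ValueError("molecule has no scaffold atoms")
        denom = set(matches[0])
    else:
        denom = set(range(mol.GetNumAtoms()))
    if not denom:
        raise ValueError("coverage undefined for an empty structure")
    covered = set()
    for h in hits:
        covered |= h.atom_set
    return len(covered & denom) / len(denom)


@dataclass
class DatasetSummary:
    """Per-molecule rows plus dataset-level frequency tables."""

    per_molecule: pd.DataFrame
    fragment_frequency: pd.Series
    code_frequency: pd.Series
    fcg_scaffold_histogram: pd.Series  # members-per-scaffold counts
    murcko_scaffold_histogram: pd.Series
    coverage_stats: dict[str, float]

    def fragment_count_band(self, lo: int, hi: int) -> float:
        """Fraction of molecules with between lo and hi fragments."""
        n = self.per_molecule["n_fragments"]
        if len(n) == 0:
            return 0.0
        return float(((n >= lo) & (n <= hi)).mean())


def summarize_dataset(
    records: Sequence[MoleculeRecord],
    graphs_by_mol: dict[str, list[FragmentCombinationGraph]],
    verdicts: Optional[Sequence[PNPVerdict]] = None,
) -> DatasetSummary:
    """Compute the comparison statistics over an annotated dataset.

    Fragment counts are taken on the merged FCG of each molecule; skew and
    excess kurtosis use standard moment estimators.
    """
    labels = {v.molecule_id: v.molecule_label for v in (verdicts or [])}
    rec_index = {r.record_id: r for r in records}
    rows = []
    frag_counter: Counter = Counter()
    code_counter: Counter = Counter()
    fcg_signatures: Counter = Counter()
    murcko_smiles: Counter = Counter()
    for mol_id, graphs in sorted(graphs_by_mol.items()):
        if not graphs:
            continue
        rec = rec_index[mol_id]
        merged = merge_fcgs(graphs)
        hits = [d["hit"] for _, d in merged.graph.nodes(data=True)]
        frag_ids = merged.fragment_ids()
        frag_counter.update(frag_ids)
        for _, _, d in merged.graph.edges(data=True):
            code_counter[d["code"]] += 1
        fcg_signatures[graph_signature(merged)] += 1
        murcko_smiles[Chem.MolToSmiles(extract_murcko(rec.mol))] += 1
        rows.append(
            {
                "molecule_id": mol_id,
                "n_fragments": len(frag_ids),
                "n_unique_fragment_types": len(set(frag_ids)),
                "coverage_all": molecule_coverage(rec.mol, hits, False),
                "coverage_scaffold": molecule_coverage(rec.mol, hits, True),
                "n_fcgs": len(graphs),
                "molecule_label": labels.get(mol_id, ""),
            }
        )
    per_molecule = pd.DataFrame(
        rows,
        columns=[
            "molecule_id", "n_fragments", "n_unique_fragment_types",
            "coverage_all", "coverage_scaffold", "n_fcgs", "molecule_label",
        ],
    )
    cov = per_molecule["coverage_all"]
    import warnings

    with warnings.catch_warnings():
        # moment estimators degenerate harmlessly on near-constant samples
        warnings.simplefilter("ignore", RuntimeWarning)
        coverage_stats = {
            "mean": float(cov.mean()) if len(cov) else float("nan"),
            "sd": float(cov.std(ddof=1)) if len(cov) > 1 else 0.0,
            "skew": float(stats.skew(cov)) if len(cov) > 1 else 0.0,
            "kurtosis": float(stats.kurtosis(cov)) if len(cov) > 1 else 0.0,
        }
    return DatasetSummary(
        per_molecule=per_molecule,
        fragment_frequency=_sorted_series(frag_counter, "fragment_id"),
        code_frequency=_sorted_series(code_counter, "code"),
        fcg_scaffold_histogram=_members_histogram(fcg_signatures),
        murcko_scaffold_histogram=_members_histogram(murcko_smiles),
        coverage_stats=coverage_stats,
    )


def attach_hits(
    graphs_by_mol: dict[str, list[FragmentCombinationGraph]],
    hits_by_mol: dict[str, Sequence[FragmentHit]],
) -> None:
    """Re-attach hit objects to graphs loaded from GraphML (nodes are hit
    indices, so the lookup is direct)."""
    for mol_id, graphs in graphs_by_mol.items():
        index = {h.hit_index: h for h in hits_by_mol.get(mol_id, [])}
        for fcg_obj in graphs:
            for n in fcg_obj.graph.nodes:
                fcg_obj.graph.nodes[n]["hit"] = index[n]


def _sorted_series(counter: Counter, name: str) -> pd.Series:
    s = pd.Series(dict(counter), dtype="int64", name="count")
    s.index.name = name
    return s.sort_values(ascending=False).sort_index(kind="stable").sort_values(
        ascending=False, kind="stable"
    )


def _members_histogram(counter: Counter) -> pd.Series:
    """Histogram of members-per-scaffold: index = collection size,
    value = number of scaffolds of that size."""
    sizes = Counter(counter.values())
    s = pd.Series(dict(sizes), dtype="int64", name="n_scaffolds")
    s.index.name = "members"
    return s.sort_index()


def write_summary(summary: DatasetSummary, out_dir) -> None:
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary.per_molecule.to_csv(out_dir / "per_molecule.tsv", sep="\t", index=False)
    summary.fragment_frequency.to_csv(out_dir / "fragment_frequency.tsv", sep="\t")
    summary.code_frequency.to_csv(out_dir / "code_frequency.tsv", sep="\t")
    summary.fcg_scaffold_histogram.to_csv(out_dir / "fcg_scaffolds.tsv", sep="\t")
    summary.murcko_scaffold_histogram.to_csv(out_dir / "murcko_scaffolds.tsv", sep="\t")
    with open(out_dir / "coverage_stats.tsv", "w") as fh:
        fh.write("stat\tvalue\n")
        for k, v in summary.coverage_stats.items():
            fh.write(f"{k}\t{v}\n")


def plot_summary(summary: DatasetSummary, out_dir) -> None:
    """Optional bar charts of the frequency tables (PNG)."""
    from pathlib import Path

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for series, fname, title in (
        (summary.fragment_frequency, "fragment_frequency.png", "Fragment frequency"),
        (summary.code_frequency, "code_frequency.png", "Combination categories"),
    ):
        if len(series) == 0:
            continue
        fig, ax = plt.subplots(figsize=(6, 3))
        series.head(20).plot.bar(ax=ax)
        ax.set_title(title)
        fig.tight_layout()
        fig.savefig(out_dir / fname, dpi=120)
        plt.close(fig)
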