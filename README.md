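# fragcomb

Fragment combination analysis for pseudo-natural products.

Natural products (NPs) are a proven source of biologically relevant
chemical matter, and *pseudo-natural products* (PNPs) extend that space:
synthetic compounds built from NP-derived ring fragments arranged in
combinations that no known natural product shows. Deciding whether a
compound is a PNP therefore requires three things — finding NP fragments
inside molecules, describing *how* each pair of fragments is combined, and
comparing that combination pattern against an NP reference collection.
`fragcomb` implements that entire pipeline for medicinal chemists and
cheminformaticians profiling compound libraries.

## What it computes

**Preparation.** Input SDF/SMILES records are standardized (mixture
resolution keeping the largest nonlinear organic component, iterative
removal of terminal sugar-like rings, isotope reset, functional-group
normalization, charge neutralization, canonical tautomer, stereo removal)
and deduplicated on stereo-free InChIKeys with a lock-protected key store
that stays consistent across processing chunks. Fragment sets additionally
get Murcko scaffold extraction and per-atom symmetry classes (automorphism
orbits).

**Classification.** Every pair of fragment matches in a molecule is placed
into one of 18 categories by the relative position of the two matches,
using only their ring atoms. With *n* the number of fused atoms (ring
atoms shared by both matches):

* fusions (*n* ≥ 1): spiro `fs` (*n* = 1), edge `fe` (*n* = 2), bridged
  `fb` (3 ≤ *n* ≤ 5), linker `fl` (*n* > 5);
* connections (*n* = 0): the count *k* of intermediary rings (molecule
  rings touching both matches) sets the degree — monopodal `cm` or
  annulated `ca` for *k* = 0, bipodal `cb?` (*k* = 1), tripodal `ct?`
  (*k* = 2), other `co?` (*k* > 2) — and the per-ring connection-point
  counts CP = |ring ∩ fragment| set the subtype (spiro CP = 1, edge
  CP = 2, bridged 3–5, linker > 5) aggregated with priority
  linker > spiro > bridged > edge;
* false positives: linkers longer than 3 atoms (`cfc`, discarded), one
  match contained in another (`ffs`, the smaller match is pruned), and
  matches overlapping on a complete molecule ring (`ffo`, the molecule is
  split into alternative interpretations, capped at 5 overlaps).

**Graphs and PNP verdicts.** Valid combinations are assembled into
fragment combination graphs (FCGs) — fragments as nodes, category codes
as edges. A probe FCG is *NP-like* if some reference FCG contains all of
its fragment combinations (occurrences are not counted); otherwise it is a
*PNP*, and a molecule is a PNP as soon as one of its alternative graphs
is. Optionally the comparison also requires the fragments to be attached
through the same symmetry classes (`fcp`, fragment combination points),
which makes matching orientation-aware and strictly increases the PNP
rate.

## Worked example

The bundled testbed builds a toy NP reference (two molecules) and probes
it with four compounds of known character:

```python
from fragcomb.fixtures import make_pnp_testbed
from fragcomb.fragments import search_fragments
from fragcomb.classify import classify_molecule
from fragcomb.fcg import build_fcgs, graph_signature
from fragcomb.pnp import ReferenceGraphSet, annotate_pnp

frags, refs, probes, _ = make_pnp_testbed(17)

def graphs_of(rec):
    hits = search_fragments(rec, frags)
    return build_fcgs(rec, classify_molecule(rec, hits), fragments=frags)

ref = ReferenceGraphSet.build(
    [g for r in refs for g in graphs_of(r)], with_fcp=True)
for p in probes:
    gs = graphs_of(p)
    v = annotate_pnp(gs, ref, with_fcp=True)
    print(p.record_id, "->", v.molecule_label,
          "| graphs:", [graph_signature(g) for g in gs])
```

prints

```
probe_mixed_alt -> pnp | graphs: ['decalin|piperidine|cm', 'decalin|piperidine|cm']
probe_novel_edge -> pnp | graphs: ['cyclohexane|piperidine|fe']
probe_orientation -> pnp | graphs: ['cyclohexane|piperidine|cm']
probe_subset -> np_like | graphs: ['cyclohexane|piperidine|cm']
```

`probe_subset` repeats a fragment combination present in a reference, so
it is NP-like. `probe_novel_edge` combines the same two fragments through
an unprecedented edge fusion, and `probe_orientation` uses a known
combination but attaches the piperidine through carbon instead of
nitrogen — with orientation-aware comparison both are PNPs.
`probe_mixed_alt` contains two overlapping decalin matches: one resulting
alternative graph matches a reference and one does not, so the molecule is
labeled PNP. With `with_fcp=False` only `probe_novel_edge` remains a PNP.

The same pipeline is scriptable from the shell (`fragcomb prep`,
`search`, `classify`, `fcg`, `pnp`, `report`, or `fragcomb run
--config run.yaml` for the whole chunked chain).

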