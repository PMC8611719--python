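# Methods

This note documents the models and procedures implemented in `fragcomb`,
the choices made where the design was genuinely open, and what the
bundled synthetic test articles do and do not demonstrate.

## Molecule preparation

Records are parsed with RDKit (SDF V2000/V3000 or one-SMILES-per-line
with an optional id column). Unparsable entries are kept as `error`
records, empty structures as `filtered`; every input record reappears
exactly once with a definite status, so stage counts always conserve the
input (`passed + filtered + error + timeout = input`).

**Mixtures.** Metal–nonmetal bonds are disconnected first
(`rdMolStandardize.MetalDisconnector`), then the preferred component is
chosen by ordered criteria: organic (contains carbon), contains a ring,
heavy-atom count, with canonical-SMILES lexicographic order as the final
deterministic tie-break. The ring criterion deliberately outranks size:
a small ringed alkaloid wins over a long fatty chain.

**Sugar removal.** There is no universal definition of a "sugar ring", so
the detector targets the pyranose/furanose chemotype without a template
library: a 5- or 6-membered saturated ring with exactly one ring oxygen
in which at least (ring size − 2) ring carbons bear an exocyclic
single-bonded oxygen. Rings are peeled only when *terminal*: removing the
ring together with its small substituents (≤ 2 heavy atoms, C/O only,
acyclic) leaves at most one larger component, and that aglycone must be
attached through a glycosidic C–O bond whose oxygen is retained as a
hydroxyl. Peeling iterates outer layer first — an inner sugar of an
oligosaccharide becomes terminal in a later round — and terminates
because every peel strictly decreases the ring count. C-glycosides are
deliberately not peeled (no glycosidic oxygen). A molecule that is
entirely sugar collapses to an empty structure and is removed by the
filters.

**Filters.** Applied in a fixed order, reporting the first violation:
heavy atoms ≥ 4, molecular weight ≤ 1000.0 Da (standard average atomic
weights, the conventional scale for such a cutoff), rings ≥ 1, elements
within {H, B, C, N, O, F, P, S, Cl, Br, I}. All thresholds live in
`FilterConfig` and a YAML mirror.

**Standardization.** Isotope reset → functional-group normalization →
charge neutralization (`Uncharger`) → canonical tautomer
(`TautomerEnumerator.Canonicalize`) → stereo removal → round-trip through
canonical SMILES. The charge/tautomer interleaving is one defensible
ordering among several; the chosen fixed order makes the operation
idempotent (verified property: re-applying never changes the identity
key). Fragment preparation appends Murcko scaffold extraction followed by
another charge-removal round.

**Timeout.** Standardization of a record is wall-clock limited (default
10 s). The check is cooperative — the task completes and the elapsed
time is compared afterwards — which keeps bookkeeping exact and avoids
interrupting native code; timed-out records are counted separately from
errors. `None`/infinity disables the check.

**Deduplication.** Identity is the stereo-free InChIKey (full 27
characters) of the standardized structure; because stereo is stripped
upstream, stereoisomers and tautomers collide by construction. The first
occurrence in processing order survives. Cross-chunk consistency uses a
plain text key store updated under an exclusive `flock` covering the
whole read–check–append cycle, so the surviving *key set* is invariant
under chunk reordering (the surviving *record ids* follow processing
order, as in any first-wins scheme).

## Fragment search

Fragments are matched as exact substructures (element, bond order,
aromaticity; no stereo — none survives preparation). Distinct hits are
distinct matched atom-sets: automorphic re-mappings of the same atoms
collapse to one canonical representative, so a symmetric fragment never
double-counts a combination. The symmetry information is not lost — each
fragment carries per-atom symmetry classes (automorphism orbits computed
from all self-matches, labeled by the smallest canonical rank in the
orbit), which reappear in orientation-aware graph comparison. Benzene (or
any user-listed fragment) is excluded from the pool before search, as the
single aromatic ring otherwise dominates hit statistics.

Ring perception everywhere is RDKit's perceived ring set (symmetrized
smallest set of smallest rings); `ring_atoms` of a hit are its mapped
atoms lying in molecule rings.

## Pair classification

The decision tree, in check order for a hit pair (a, b):

1. one atom-set contained in the other → `ffs`; the substructure hit is
   later removed with all its combinations;
2. fused atoms = ring_atoms(a) ∩ ring_atoms(b); if the fused set covers a
   complete molecule ring → `ffo` (an artifact of overlapping matches,
   not a designed fusion); multi-ring overlaps still count as one `ffo`;
3. fused atoms present → fusion by count (1 spiro, 2 edge, 3–5 bridged,
   > 5 linker);
4. otherwise a connection. Intermediary rings are molecule rings touching
   both hits and contained in neither. With none, hits sharing a ring
   system (connected ring-atom/ring-bond subgraph) are annulated (`ca`);
   otherwise the linker length is the minimum, over all shortest paths
   between ring atoms of the two hits running outside both hits, of the
   number of path atoms in neither hit — ≤ 3 gives `cm`, longer pairs
   are `cfc` and dropped at classification time (they never appear as
   counted false positives). With intermediary rings, the degree is the
   ring count (1/2/> 2 → bipodal/tripodal/other) and each ring
   contributes a subtype from its two CP counts; subtypes aggregate by
   priority linker > spiro > bridged > edge, highlighting the rarer
   arrangements.

The linker measure counts atoms on one shortest path (not a union of
paths) — the natural reading of "atoms between the fragments" and the
only definition that makes the 1,2,3,4 → `cm,cm,cm,cfc` boundary sweep
well-defined. Pairs of the same fragment matched on identical atoms are
degenerate and skipped. Classification is symmetric in the two hits, and
on the bundled fixtures fused-atom, intermediary-ring and CP counts are
cross-checked against brute-force enumeration (exhaustive path search,
independent ring-set scans, networkx isomorphism for hits and orbits).

## Graph assembly

Nodes are fragment *occurrences* (hit indices labeled with fragment ids),
edges are valid combination codes; `ffs`, `ffo` and `cfc` never label an
edge. Assembly per molecule: prune `ffs` substructure hits; reject the
molecule outright above 5 `ffo` pairs (combinatorial-explosion guard);
otherwise take the Cartesian product of keep-one choices over `ffo`
pairs — per pair, not per overlap cluster, with identical alternatives
deduplicated, which bounds alternatives by 2^overlaps and collapses
chained overlaps correctly; split disconnected components; discard
edgeless graphs. Merging a molecule's graphs for statistics takes the
union of nodes and edges, common parts once.

Edge fcp labels record, per endpoint, the multiset of symmetry classes of
the fragment atoms engaged in the combination: the fused atoms for
fusions, the connection-point atoms in intermediary rings for higher
connections, and the attachment atoms on optimal linker paths for
monopodal/annulated connections. The canonical signature is the sorted
multiset of edge tokens `fragmin|fragmax|code[|fcpA|fcpB]` (tokens
oriented by fragment id, ties by sorting the two fcp serializations) plus
isolated-node tokens; signature equality coincides with labeled graph
isomorphism on all graphs the testbed produces, and repeated identical
edges collapse — occurrence counts are deliberately not compared.

## PNP annotation

A probe graph is NP-like iff some reference graph's edge-token set is a
superset of the probe's (containment, not equality: a molecule repeating
a known combination is not novel). The reference set keeps an inverted
token index for pruning. Probe graphs are the individual alternative
FCGs, not the merged graph; a molecule is a PNP as soon as one
alternative is. Turning fcp on only refines tokens, so verdicts are
monotone (np_like can become pnp, never the reverse), and adding
reference graphs is anti-monotone in the number of PNP verdicts; both are
verified as properties. Reference structures present in the query set are
removed beforehand by identity-key intersection in the pipeline driver.

## Pipeline driver

A plain sequential file-based task chain (prepare fragments → chunked
molecule preparation with locked dedup → optional reference removal →
search → classify → graphs → PNP → report). Every stage reads its input
files and writes its outputs; existing outputs are skipped, making runs
resumable per stage, and two runs on the same inputs are byte-identical.
Chunk size defaults to 5000 records. No workflow engine is required; the
orchestration is deliberately minimal.

## Synthetic test articles

The fixture set contains one designed molecule per category (21 total):
spiro/fused/bridged bicyclics for fusions, with symmetric macrocyclic
bicyclics (`bicyclo[n.n.m]` alkanes) providing the 6- and 7-fused-atom
cases; and two carbocycles joined by short heteroatom bridges for
connections, where the bridge count sets the degree and the attachment
spacing sets the CP counts. Bridge atoms are heteroatoms (O, N, C, S
mixes) chosen to break ring-size ties — RDKit's perceived ring set drops
symmetric duplicates and, in tightly tied cage topologies, can omit a
cross ring once all bonds are covered, so the constructs keep candidate
rings strictly ordered by size. Every fixture is verified at generation
time by running the full search + classification pipeline against its
designed code multiset; generation is deterministic and byte-identical
per seed.

These articles are topological probes, not chemically realistic natural
products: they contain no stereocenters (irrelevant by construction), no
charged or tautomer-rich functionality, and far fewer fragments per
molecule than real NP libraries. Passing them demonstrates that the
decision tree, graph assembly and comparison semantics are correct on
every branch; it does not calibrate rates or distributions expected on
real compound collections, which depend on the fragment library and
reference database used. The acceptance sweeps run in seconds on one CPU
at these sizes (21 fixture molecules, 6-step linker sweep, 5-step fusion
sweep).

## Known limitations

* Sugar detection is a chemotype rule, not a template library; exotic
  sugars (uronic acids, deoxy sugars with few hydroxyls, C-glycosides)
  are left in place by design.
* The cooperative timeout cannot interrupt a single pathological RDKit
  call mid-flight; it bounds bookkeeping, not worst-case latency of one
  record.
* Ring-dependent decisions inherit RDKit's ring perception; in rare
  highly symmetric cage topologies the perceived ring set is smaller than
  the cycle space dimension, which can lower the intermediary-ring count
  for such pairs.
* 2D depiction, depiction scoring and publication-date analyses are out
  of scope, as are stereochemistry-aware categories.
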