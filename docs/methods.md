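# Methods

## The model

A protein structure is reduced to an **amino-acid network** (AAN): an
undirected graph whose nodes are the standard amino-acid residues of the
selected chains and whose edges link residue pairs with at least one pair
of heavy atoms at Euclidean distance ≤ `cutoff` (default 5 Å, a closed
comparison). 5 Å captures first-shell chemical contacts; the cutoff is a
parameter but no multi-cutoff machinery is provided. Hydrogens are always
excluded — X-ray structures usually lack them, and protonation would make
the network depend on a modeling step rather than on deposited
coordinates. For alternate locations only the highest-occupancy conformer
is kept (ties broken by altloc code) so parsing is deterministic. Residues
are identified by author numbering `(chain, seqnum, icode)`, never by
sequential index, so positions keep their crystallographic names.

The **position neighborhood** of *i* is its AAN adjacency set. Given the
wild type and a mutant structure, a position *j* "changes" when its
neighbor set differs between the two AANs — gaining, losing or swapping
neighbors all count, and the comparison is plain set inequality. For every
mutation at site *i*, each changed *j ≠ i* contributes a directed edge
*i → j* to the **GCAT network**; the site's own neighborhood change is
discarded entirely (no self-edge, no in-edge to *i*). Edges are
deduplicated over the 19 mutations per site (each edge retains the set of
mutations that produced it as a `provenance` attribute for diagnostics);
positions with zero total degree are dropped from the graph but reported
separately as mutationally independent.

Nodes are classified into the four influence categories by quadrant:
G (k_in ≤ k̄, k_out > k̄), C (≤, ≤), A (>, ≤), T (>, >), where
k̄ = |E|/N is kept as an exact rational, not a rounded integer — a node
sitting exactly on the mean in both degrees is C. Since mean in-degree and
mean out-degree both equal |E|/N in any digraph, one threshold serves both
axes.

## Surface exposure

Relative accessible surface area is absolute per-residue ASA divided by a
per-type reference maximum. The default backend is Shrake–Rupley (probe
radius 1.4 Å, 960 sphere points) because it is pure Python and available
everywhere; an external DSSP binary can be selected (`backend="dssp"`)
and is the convention matching published DSSP-based splits. The reference
maxima default to the Sander–Rost table, with the Wilke and Miller tables
selectable; the choice shifts individual rASA values by a few percent and
can move residues near the threshold across it, which is why backend and
scale are recorded in the `RasaTable`. Classification is strict:
surface-exposed iff rASA > 0.2; exactly 0.2 is buried. Values are not
clamped above 1 (small or terminal residues can exceed their reference
maximum).

## Mutant providers

The scan design is always the full 19·N enumeration, ordered by position
then target type. Structures for those specs come from:

* **external-dir** — one PDB per mutation, named
  `{from}{chain}{seqnum}{to}.pdb` by default (configurable regex with
  named groups). Files are validated against the fixed-backbone,
  single-substitution contract; violators are rejected with a per-file
  reason, absent mutations are listed, and partial sets are usable with a
  warning (per-position coverage is reported so degrees stay
  interpretable). The backbone-identity tolerance defaults to exact
  coordinate equality; external pipelines that re-minimize may need a
  small tolerance, which is why it is a parameter.
* **naive engine** — deterministic geometric substitution. The target
  side chain is an idealized heavy-atom template (Chemical Component
  Dictionary ideal coordinates); it is placed by least-squares
  superposition of its N/CA/C frame onto the wild-type residue's N/CA/C,
  and the first side-chain torsion (chi-1, N–CA–CB–γ) is rotated to match
  the wild type whenever both old and new types have one. Glycine has no
  side chain, alanine no chi-1, and proline's ring torsion is never
  copied. Backbone atoms (N, CA, C, O, OXT) keep wild-type coordinates
  exactly and no other residue is touched.

The engine's fixed-backbone model implies a theorem the tests assert
exactly: only AAN edges incident to the mutated position can change, so
every naive-engine GCAT edge *i → j* has *j* adjacent to *i* in the wild
type or in some mutant. Energy-based mutators do not satisfy this (their
side-chain placement responds to the environment), and the GCAT layer
never assumes it. Consequently, naive-engine networks are sparser and
more local than networks built from energy-minimized mutants; published
GCAT statistics obtained with FoldX output are reproducible only through
the external provider, and the engine is documented as a structural
stand-in, not a replacement.

## Network measures

Strongly connected components come from networkx's Tarjan-equivalent
algorithm, with output ordered by each component's smallest residue id
for determinism; the tests check the partition against a transitive-
closure reachability oracle and that the condensation is acyclic.

The clustering coefficient of a node uses the directed Watts–Strogatz
convention with denominator k(k−1): k is the number of distinct in∪out
neighbors (excluding the node), the numerator counts directed edges among
those neighbors with each ordered pair at most once, so a reciprocal pair
contributes 2; k < 2 gives 0. The global coefficient is the unweighted
mean over nodes. Alternative conventions exist (e.g. counting a
reciprocal pair once, or Fagiolo's degree-based variant implemented in
networkx); comparisons of absolute CC values across tools are therefore
convention-sensitive, and the brute-force oracle tests define this
package's convention.

A bidirectional edge is an unordered pair with both directions present —
mutual mutational influence. Reports count each pair once, and per-node
statistics count partner nodes.

Attribute sub-networks are induced subgraphs on a boolean flag: edges
with either endpoint outside the selection are dropped and SCC/CC are
recomputed on the subgraph. Influence mixing, by contrast, is computed on
the full graph: each flagged node is exclusive-homogeneous (all incident
edges link to same-flag partners), exclusive-heterogeneous (all cross-
flag), or combined; the same trichotomy is applied to each node's
bidirectional partners. Annotations (surface exposure, sector membership,
functional sensitivity, hotspots) are input data read from CSV — the
package computes only the surface flag itself (from rASA) and never
infers the others.

## Synthetic structures

`make_synthetic_structure` emulates what the analysis needs from a real
structure: a set of full-heavy-atom residues whose pairwise atomic
distances straddle the 5 Å cutoff, under two geometries — a self-avoiding
chain walk with 3.8 Å CA–CA steps (the virtual bond length of a
polypeptide), giving a connected AAN with incidental longer-range
contacts, and a cluster layout (3.8 Å local lattice, 40 Å between cluster
centers) giving disconnected regions. Residues are idealized templates in
seeded random orientations, so side-chain substitution, rASA and contact
detection all exercise realistic atom counts and reaches. It does **not**
emulate folded-core packing, secondary structure, realistic backbone
connectivity between consecutive residues, or crystallographic artifacts
(altloc disorder, missing atoms); those are covered by hand-built
fixtures in the tests. Passing tests on synthetic structures therefore
validate the network logic and the substitution geometry, not any claim
about real-protein energetics. Problem sizes used by the tests and the
acceptance script — 20–30 residues for full 19·N scans (380–570 mutant
AANs), 115 residues for enumeration and numbering checks — keep a
complete run in seconds while leaving every code path exercised.

## Numerical choices and degenerate inputs

* Distance rule is closed (`d ≤ cutoff`); the k-d tree pair search is
  boundary-inclusive and agrees with the all-pairs scan.
* Mean-degree comparisons use exact floats of |E|/N; no rounding.
* PDB coordinates round-trip at the format's 3-decimal precision; a
  second write/read cycle is exact.
* Empty structures, empty mutant sets, empty GCAT graphs and unknown
  positions raise immediately rather than returning empty results, except
  that an all-empty diff set legitimately yields an empty GCAT.
* Tie-breaks: altloc by occupancy then code; exports sort nodes and edges
  by string id so artifacts are byte-stable across runs.

## Known limitations

* The naive engine places one idealized rotamer with chi-1 copy only; no
  rotamer search, clash relief or energy criterion. Its GCATs
  under-estimate influence ranges relative to energy-based mutants.
* DSSP-backed rASA requires an external `mkdssp` binary; without it the
  Shrake–Rupley backend may classify threshold-adjacent residues
  differently than DSSP-based reference splits.
* Only the first model of multi-model (NMR) files is read; mmCIF is not
  supported.
* Weighted AANs, atom-level networks and per-mutation-type (unaggregated)
  influence networks are out of scope.
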