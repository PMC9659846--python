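# gcatnet

Directed mutational-influence networks from protein structures.

A point mutation at sequence position *i* can perturb the structural
environment of another position *j* without the reverse being true:
mutational influence is asymmetric. `gcatnet` models this asymmetry for a
whole protein. It represents a structure as an **amino-acid network**
(AAN) — residues as nodes, an undirected edge whenever any two heavy atoms
of two residues lie within a distance cutoff (5 Å by default) — performs
an in-silico **saturation scan** (all 19 substitutions at every position),
and records, for each mutation at *i*, every position *j* whose AAN
neighbor set changes (neighbors gained, lost or swapped). Aggregating
those changes over the 19 mutations of each site yields a directed graph,
the **GCAT network**: an edge *i → j* means "some mutation of *i* changes
the neighborhood of *j*". No self-edges are added, and positions with no
influence in either direction are excluded.

Each GCAT node is then classified by its in-degree k_in and out-degree
k_out relative to the network mean degree k̄ = |E|/N (for any directed
graph, mean in-degree = mean out-degree = |E|/N):

| category | k_in | k_out | reading |
|---|---|---|---|
| **G** (Generate) | ≤ k̄ | > k̄ | influences many, influenced by few |
| **C** (Connect)  | ≤ k̄ | ≤ k̄ | tolerant: little influence either way |
| **A** (Absorb)   | > k̄ | ≤ k̄ | influenced by many, influences few |
| **T** (Transmit) | > k̄ | > k̄ | influences and is influenced strongly |

C and A neighborhoods tolerate mutations at their own position; G and T
neighborhoods do not and would need corrective neighbor motions or
compensatory mutations. The package also computes the measures used to
analyze such networks — strongly connected components, the directed
clustering coefficient with denominator k(k−1), bidirectional
(mutual-influence) edges — and attribute overlays (surface-exposed vs
buried from rASA, co-evolving sector membership, functionally sensitive
positions, ligand-binding hotspots) with homogeneous/heterogeneous
influence-mixing statistics per node.

Mutant structures come from two providers:

* **external-dir** — a directory of single-mutant PDBs produced by an
  external mutator such as FoldX (fixed backbone, side chain replaced at
  the site only), with FoldX-style file naming and strict validation of
  the single-substitution and fixed-backbone contract;
* **naive engine** — a built-in deterministic geometric substitution:
  the side chain at the site is swapped for an idealized template placed
  on the wild-type N/CA/C frame, copying chi-1 from the wild type when
  both types have one. It is a structural stand-in, not an energy model;
  analyses of published FoldX-based networks require the external
  provider.

Audience: structural bioinformaticians studying mutation tolerance,
perturbation propagation and protein sustainable design.

## Worked example

```python
from gcatnet import (build_aan, build_gcat, classify_gcat,
                     enumerate_mutations, make_synthetic_structure,
                     naive_mutant_set)
from gcatnet.gcat import category_counts, mean_degree

wildtype = make_synthetic_structure(20, geometry="chain-walk", seed=42)
specs = enumerate_mutations(wildtype)          # 380 = 19 x 20
wt_aan = build_aan(wildtype, cutoff=5.0)       # 20 nodes, 58 edges
gcat = build_gcat(wt_aan, naive_mutant_set(wildtype, specs))
labels = classify_gcat(gcat)
print(gcat.number_of_nodes(), gcat.number_of_edges(),
      round(mean_degree(gcat), 3), category_counts(labels))
```

prints

```
20 39 1.95 {'G': 4, 'C': 5, 'A': 5, 'T': 6}
```

— all 20 positions influence or are influenced by at least one other
position; with a mean degree of 1.95 influences per position, 4 positions
mainly generate changes (G), 5 mainly absorb them (A), 5 are quiet in both
directions (C, the most mutation-tolerant class) and 6 both send and
receive above-average influence (T, the least tolerant). The scripts in
`examples/` walk through each capability (AAN construction, rASA
classification, the saturation scan, attribute sub-network analysis, and
the four-position toy replay of the aggregation rule) and print a short
interpretation with their numbers.

The same run from the shell:

```sh
gcatnet fixtures --n 20 --seed 42 --out wt.pdb
gcatnet run --pdb wt.pdb --out-dir out/
```

which writes Gephi-readable GraphML/GEXF exports, edge and node tables
(k_in, k_out, category, rASA, attribute flags), per-attribute sub-network
reports (SCC count, global clustering coefficient, bidirectional-node and
influence-mixing classes) and a manifest; reruns are byte-identical.

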