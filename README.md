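# strandscape

Quality-diversity exploration of DNA strand-set self-assembly networks.

Given a library of abstract DNA strands (each strand a short run of
domains, `x*` denoting the complement of `x`), strandscape

1. **enumerates** the domain-level chemical reaction network (CRN) of any
   strand subset — hybridization, dissociation, three-way and four-way
   branch migration, with transient-complex condensation and bounded
   growth (`strandscape.enumerator`);
2. **explores** the space of strand subsets with MAP-Elites over a
   3 × 50 × 55 archive of (strand count, log₁₀ #reactions, #structures),
   maximizing either mean structure size (MSS) or the entropy of reaction
   types (ERT) (`strandscape.qd_explore`);
3. **optimizes nucleotide sequences** per CRN so that predicted
   minimum-free-energy structures are *well formed* (fold according to the
   domain design), via an elitist GA or random search, scored by the
   overlap between folded and enumerated structures
   (`strandscape.folding_match`, `strandscape.seq_opt`);
4. **analyses** the resulting reaction graphs: density, degree
   assortativity, discrete power-law/KS scale-freeness test, clustering,
   global reaching centrality, flow hierarchy, betweenness and eigenvector
   centralities (`strandscape.net_analysis`).

Complexes are modeled in kernel notation (`a( a*( + ) )` is the duplex of
two `a a*` strands) with canonicalization under circular permutation of
strand order (`strandscape.kernel_model`).  Library presets `L1`
(16 strands), `L2` (256) and `L3` (1728) are built in
(`strandscape.library`).

The thermodynamic folding engine is a pluggable contract; the bundled
stand-in deterministically maximizes paired nucleotides over aligned,
fully sequence-complementary domains (connected, pseudoknot-free), so the
whole pipeline runs offline with no external packages.

## CLI

```sh
# library manifest
strandscape library --library L1 --out l1.csv

# enumerate the CRN of strands 3, 7 and 12 of L1
strandscape enumerate --library L1 --strands 3,7,12 --max-complex-size 6 --out crn.json

# MAP-Elites exploration (use --exhaustive on small libraries)
strandscape explore --library L2 --fitness mss --budget 300000 --runs 10 --seed 1 --out grid.json

# sequence optimization against a saved CRN
strandscape seqopt --crn crn.json --algo ga --budget 1000 --seed 1 --out-prefix best

# graph statistics (full network or --overlap sub-network)
strandscape analyze --crn crn.json --wellformed matched.json --k-paths 6
```

Every stochastic command is reproducible from `--seed`.

## Layout

```
src/strandscape/
  kernel_model.py   # domains, strands, complexes, kernel notation, canonical form
  library.py        # (n, m) libraries, presets, genomes
  enumerator.py     # move generators, closure, condensation, CRN metrics
  qd_explore.py     # MAP-Elites archive, descriptors, aggregation
  folding_match.py  # folding oracle, well-formedness, structure matching
  seq_opt.py        # GA / random sequence search, re-evaluation
  net_analysis.py   # reaction graphs, robustness/hierarchy/centrality metrics
  cli.py
tests/              # unit + property tests; oracles.py holds brute-force checks
scripts/acceptance.py
```
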