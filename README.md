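# rnaloopkit

Tools for building datasets of RNA loop motifs — internal loops and n-way
junctions — and for benchmarking RNA inverse-folding (design) algorithms
against them.

RNA secondary structure decomposes into stems (maximal runs of stacked base
pairs), hairpin loops, internal loops, and multibranch loops: an *n-way
junction* is a loop from which n helices emanate (n ≥ 3; an internal loop is
the 2-way case, bulges included). Junctions are where structure prediction
and sequence design are hardest, which makes curated collections of them
valuable both as design benchmarks and as machine-learning training data.
`rnaloopkit` implements the full data-preparation pipeline and the
evaluation protocol around such collections:

* **Formats** (`structio`): multi-layer dot-bracket, BPSEQ, CT, FASTA,
  STOCKHOLM with WUSS consensus lines, and a fixed dataset CSV schema.
* **Structure transforms** (`structcore`): pseudoknot elimination as a
  maximum-cardinality nested subset (dynamic programming, exact), projection
  of an alignment-level consensus structure onto each gapped member
  sequence, and suitability filters (empty / gapped / multistrand) for
  annotated 3D chains.
* **Annotator consensus** (`consensus`): the unification protocol that merges
  base-pair lists from A annotators into one conflict-free structure by
  descending agreement level, labelling the result with category
  1..A (A ⇔ unanimous).
* **Motifs** (`motifs`): stem/loop decomposition, junction feature vectors,
  a seeded random-structure generator, a brute-force decomposition oracle,
  and generation of the three design-target instances per loop:
  (1) the isolated loop, (2) the loop with its connecting stems,
  (3) the full structure.
* **Dataset assembly** (`dataset`): the alignment route and the
  3D-annotation route end to end, with per-loop-type summary statistics.
* **Benchmark metrics** (`evalbench`): base-pair F1 (TP = exact pair
  identity), ordered-tree edit distance (Zhang–Shasha on the
  pair/unpaired-base tree, calibrated to reproduce ViennaRNA's
  `RNAdistance`), length normalisation d/L, failure-aware aggregation
  (failures count +∞ for distances, 0 for F1), one-sided Wilcoxon
  signed-rank matrices (exact for n ≤ 25, ties handled), the
  highest-Psum/lowest-MFE candidate-selection rule
  (P_t = exp((EE − E_t)/RT)), and subprocess wrappers for `RNAfold`,
  `RNApdist`, `RNAdistance`.
* **ML harness** (`mlharness`): junction-feature tables (unpaired counts of
  the three strands of each 3-way junction) and stratified k-fold
  cross-validation with macro-F1 reporting, plus a group-aware split that
  never lets one family straddle train and test.

## Worked example

Extract the loops of a 24-nt structure containing a 3-way junction:

```sh
$ printf '((..((...))..((...))..))\n' > s.db
$ printf '>s\nGGAAGGAAACCAAGGAAACCAACC\n' > s.fa
$ rnaloopkit extract --in s.db --seq s.fa --out records.csv --family RF00077
1 records written to records.csv
$ rnaloopkit stats --in records.csv --out summary.csv
loop_type  count  percent  min  max  mean  std
     3way      1    100.0   18   18  18.0  0.0
```

The single record is the junction closed by pair (2, 23) with three
2-nt strands. Its three instances, as stored in `records.csv`:

```
loop_seq       GAAGNNNCAAGNNNCAAC        loop_db       (..(...)..(...)..)
loop_stems_seq GGAAGGNNNCCAAGGNNNCCAACC  loop_stems_db ((..((...))..((...))..))
full_seq       GGAAGGAAACCAAGGAAACCAACC  full_db       ((..((...))..((...))..))
len_loop 12    len_loop_stems 18         len_full 24
```

The isolated loop keeps the closing pair, the outermost pair of each child
helix and the loop strands (12 original residues); excised subtrees are
spliced with 3-nt `N`/`.` caps so every emitted dot-bracket stays
well-formed and foldable. The loop-with-stems instance adds the complete
helices (18 original residues); reported lengths never count caps.

The same decomposition is available programmatically:

```python
>>> from rnaloopkit import parse_dotbracket, decompose_loops
>>> [(L.loop_class, L.order, L.strand_lengths)
...  for L in decompose_loops(parse_dotbracket("((..((...))..((...))..))"))]
[('junction', 3, (2, 2, 2)), ('hairpin', 1, (3,)), ('hairpin', 1, (3,)),
 ('exterior', 1, (0, 0))]
```

Other subcommands: `rnaloopkit unify` (annotator BPSEQ files → consensus +
agreement category), `build-rfam` (STOCKHOLM seeds → records CSV),
`evaluate` / `compare` (designed sequences → metrics CSV → Wilcoxon
p-value matrix), `features` / `cv` (junction features → stratified-CV
macro-F1 report).

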