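# Methods

## Structural model and conventions

A secondary structure is a residue count L, a set of base pairs
{(i, j) : 1 ≤ i < j ≤ L} in which no residue appears twice, and optionally
a sequence over {A, C, G, U, N}. Positions are 1-based inclusive
everywhere, matching the BPSEQ/CT convention; the dataset CSV stores only
subsequences, never coordinates, so no off-by-one ambiguity can leak out of
the library. A structure is *nested* when no two pairs cross
(i < k < j < l); crossing pairs are pseudoknots.

Stems are maximal runs of stacked pairs (i, j), (i+1, j−1), …; a lone pair
is a stem of length one. Each stem's inner face closes exactly one loop:
hairpin (order 1), internal loop (order 2, bulges included — one strand may
be empty), or n-way junction (order n ≥ 3, i.e. 1 + number of child
helices). The unenclosed exterior region is tracked as its own motif and is
never classified as a junction, no matter how many top-level stems it
touches: junction order counts helices around a closing pair. A useful
consequence checked by the tests: the number of closed loops of order ≥ 2
equals #stems − #hairpins.

Loop membership of helix ends: a loop owns its closing pair and the
outermost pair of each child helix; stems own all their paired positions.
This makes the loop-with-stems instance exactly (stem positions ∪ strand
positions) with no double counting.

## Pseudoknot removal

Annotator outputs and pseudoknot layers of consensus structures can
contain crossing pairs, but the downstream design tools require nested
input. We return the **maximum-cardinality nested subset** of the given
pairs, computed by a Nussinov-style dynamic program restricted to the
candidate pair set. Only pair endpoints matter for nestedness, so
coordinates are compressed first; the DP is then quadratic in the number of
pairs rather than the sequence length. Among equally large subsets, pairs
from preferred notation layers win (primary bracket layer before pseudoknot
letter layers, configurable), and remaining ties resolve to the
lexicographically smallest pair set under ascending (i, j) — the traceback
prefers pairing the leftmost endpoint with its smallest partner. The
operation is deterministic and idempotent, and its optimality is verified
against exhaustive subset search for inputs with ≤ 12 pairs.

This subset-selection approach was chosen over "drop all non-primary
layers" because annotator pair lists carry no layer labels at all.

## Consensus projection (alignment route)

A family consensus structure lives on alignment columns. For each member
row we drop gap characters ('-', '.'), build the column → ungapped-position
map, keep a consensus pair iff **both** columns are non-gap in that row,
and re-index. Half-gapped pairs are dropped, never re-paired: re-pairing
would invent interactions with no support in the annotation. Pseudoknot
removal runs after projection (per sequence); dropping consensus letter
layers before projection is available as an option, since both orders are
defensible and the difference is confined to families with annotated
pseudoknots.

## Annotator unification (3D route)

Base-pair annotators disagree most often at helix ends and around
non-canonical interactions. The unification protocol visits candidate
pairs in order of decreasing support (number of annotators reporting the
pair), ties broken by ascending (i, j) — any deterministic rule works; this
one is reproducible and independent of annotation input order. A candidate
is admitted iff neither residue is already claimed. "Compatible" is
residue-disjointness only: nestedness is enforced by the downstream
pseudoknot-removal step, mirroring a build-then-clean pipeline; a strict
mode that rejects crossings at insertion is available. The structure-level
agreement category is the **minimum** support among admitted pairs (so
category A ⇔ unanimous across A annotators); empty results are labelled
`empty`. Chains are first filtered by precedence multistrand → gapped →
empty, judged from chain count, author-residue-number continuity, and pair
count respectively — residue numbering is what annotator outputs carry, so
it is the practical gap detector.

Category semantics note: with minimum-support labelling, "category 3" means
the least-supported retained pair had 3 of 7 annotators behind it. Mean or
modal support would be alternative readings; minimum is the conservative
one and is the documented default.

## Design-target instances

For every loop of order ≥ 2 three instances are emitted: the isolated
loop, the loop with its complete connecting helices, and the full
structure. Excising a child helix's enclosed subtree leaves a
discontinuity; we splice in `cap_length` unpaired positions (sequence 'N',
structure '.'), default 3 — the minimum hairpin length of standard folding
engines — so every emitted dot-bracket re-parses and is foldable by design
tools. Reported lengths (`len_loop`, `len_loop_stems`, `len_full`) count
only original residues, never caps. `cap_length=0` gives an as-is mode for
consumers with their own splicing convention, which is configurable
precisely because deposited datasets differ on this point.

## Synthetic structure generator

Fixtures are produced by a recursive region sampler: each region spawns k
child helices with probability proportional to branching weights
(default {0: 0.50, 1: 0.28, 2: 0.14, 3: 0.06, 4: 0.02}, renormalised over
the feasible k), slack length is distributed multinomially over subtree
enlargements and spacers, helix lengths are uniform in 1–6, and hairpin
loops never fall below 3 nt. Paired positions draw complementary
nucleotides with Watson–Crick pairs favoured over wobble (GC 52%, AU 34%,
GU 14%); unpaired positions are uniform. The same seed always yields the
same structure and sequence.

The generator emulates the *topological* diversity of loop datasets —
realistic mixes of hairpins, bulges, internal loops and junctions at
lengths 20–200 — which is what the decomposition, instance-generation and
metric machinery care about. It does not emulate covariation signal,
family-specific conservation, modified residues, or thermodynamically
optimised sequences; consequently, passing tests demonstrate correctness
of the pipeline's combinatorics and statistics, not predictive claims
about any particular RNA family. Sequence realism matters only to the
RNAfold-refolded mini-benchmark, where the generator's
structure-compatible sequences fold imperfectly — exactly the regime in
which failure handling and rank statistics must behave.

## Benchmark metrics

* **Base-pair F1**: TP is exact (i, j) identity; precision = TP/|predicted|,
  recall = TP/|target|, F1 their harmonic mean. Both-empty compares to 1,
  empty-prediction-vs-nonempty-target to 0.
* **Tree edit distance**: the full-structure tree (virtual root, one
  internal node per pair, one leaf per unpaired base) compared by the
  Zhang–Shasha ordered-tree algorithm. The cost table — unpaired indel 1,
  pair indel 2, pair↔unpaired relabel 1 — was fixed by probing the
  ViennaRNA `RNAdistance` program's defaults on small hand cases before
  implementation, and the test suite verifies exact agreement with the
  binary on 100 random structure pairs. Normalisation divides by the
  target length L.
* **Failure handling**: a tool that produced no output for a case scores
  +∞ on distance metrics and 0 on F1, so it loses that case in any
  pairwise comparison; headline aggregates are additionally computed on
  the subset of cases solved by every tool, with full-coverage values kept
  visible so coverage differences are not hidden.
* **Wilcoxon signed-rank**: one-sided, zero differences dropped, all-zero
  vectors give p = 1. Infinite values are handled by rank (any finite value
  beats +∞; two +∞ tie and drop out). For n ≤ 25 the exact sign-flip
  distribution is computed by dynamic programming over doubled midranks —
  exactness with tied |differences| is required for the five-pair
  strict-dominance case, whose one-sided p is 1/32 — and beyond that a
  normal approximation with continuity and tie corrections is used.
* **Candidate selection** for Boltzmann samplers: per-target probability
  P_t = exp((EE − E_t)/RT) with RT = 0.61633 kcal/mol (37 °C, the folding
  engine's convention; configurable); the chosen candidate maximises
  ΣP_t, ties broken by lowest MFE, then input order.
* **External wrappers**: RNAfold (MFE + partition function), constrained
  refolding, RNApdist and RNAdistance are subprocess wrappers; a missing
  binary raises a clear "backend unavailable" error, never silent zeros.
  RNApdist is wrapped rather than reimplemented because it requires the
  full McCaskill partition function; F1 and tree-edit are native.

## Summary statistics and the CV harness

Per-loop-type summaries report count, percent of total (rounded to two
decimals), and min/max/mean/sample-standard-deviation (ddof = 1, reported
as 0 for single-record groups) of the loop-with-stems length.

The family-recognition harness keeps only 3-way junction records,
represents each as the three strand unpaired counts (u1, u2, u3) read back
from the loop instance's dot-bracket, and labels rows by membership in the
chosen positive family. Evaluation uses stratified k-fold CV
(scikit-learn, shuffled with a fixed seed; folds preserve class
proportions to ±1 row) over three baseline classifiers — kNN (k = 3),
decision tree, Gaussian naive Bayes — scored by macro-averaged F1, the
appropriate summary under heavy class imbalance. Per-fold values plus
min/max/median/mean are reported; a group-aware split utility guarantees
no family appears on both sides of a train/test divide.

## Problem sizes

The default verification scales are: 500 random structures (lengths
20–200) for the decomposition oracle, 150 random pair sets (≤ 12 pairs)
for exhaustive pseudoknot-removal checks, 1,000 random annotator ensembles
for the unification invariants, 200 structures for format round-trips, 100
structure pairs for the RNAdistance cross-check, a 25-target refolding
mini-benchmark, and a 600-row CV table. These sizes give exhaustive or
high-multiplicity coverage of each component while keeping the whole
verification run in well under a minute of compute plus a few seconds of
external-binary calls.

## Known limitations

* The pipeline consumes annotator outputs and design-tool outputs; it does
  not run the seven base-pair annotators or the design tools themselves.
* Covariation analysis is delegated to an optional external R-scape/
  CaCoFold wrapper; without it, consensus pairs come from the alignment's
  WUSS line alone.
* Constrained refolding is off by default: its outcome depends on the
  folding engine's version and constraint semantics, so pipelines needing
  it must pin those externally.
* Non-canonical pair taxonomy (edge/orientation classes) is out of scope;
  an optional canonical filter {AU, UA, GC, CG, GU, UG} is provided when a
  sequence is available.
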