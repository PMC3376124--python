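# Methods

This note documents the models and procedures implemented in
`domainsweep`, their assumptions, the tunable parameters, the synthetic
data used to exercise them, and the numerical and design choices made
where the behavior was genuinely open.

## Per-residue encoding

Every residue carries a 31-value feature block in a fixed internal
order: 20 PSSM conservation scores (columns in alphabetical amino-acid
order), 1 disorder score in [0, 1], the 5 Atchley factors, a one-hot
secondary-structure triple (helix, strand, other) and a one-hot solvent
accessibility pair (buried, exposed). The Atchley factors are the
published standardized scores per amino acid; each factor column has
mean ≈ 0 over the 20 amino acids by construction. The nominal residue
`X` — used both for unknown input characters and for window padding
beyond the sequence ends — contributes an all-zero block, the only case
where the one-hot groups do not sum to 1.

A window of *w* residues (odd; 13 by default, 15 and 17 supported)
centered on the classified residue is flattened subsite-major:
subsite 1 is the left edge of the window, subsite ⌈*w*/2⌉ the center.
Feature names follow `AA<subsite>_<type>_<index>`. The `pssm_<k>` index
follows the conventional PSI-BLAST residue column order
(`ARNDCQEGHILKMFPSTWYV`), so externally reported feature identifiers
resolve to the expected amino acid (e.g. `pssm_13` is methionine) even
though the internal column layout is alphabetical. Coordinates in all
files are 1-based inclusive; internal arrays are 0-based.

The PSSM reader accepts the PSI-BLAST ASCII dialect (free-form header,
20-letter column header, one row per position with at least 20 integer
score columns, ignored trailing statistics). Which 20-column group
feeds the features is configurable: the log-odds scores (default) or
the weighted observed percentages; the file's column order is remapped
to the canonical internal order, so column permutations in the input
are immaterial.

Window deduplication is a greedy single-linkage scan in input order: a
sample is dropped when its *w*-mer has identity ≥ *t* (matching
positions / *w*, with `X` matching nothing) to an already-retained
sample of the same label. This approximates production sequence
clustering with an order-dependent stand-in; the default *t* = 1.0
removes exact duplicates only, because a defensible sub-unit threshold
for *w*-mers is dataset-dependent.

## mRMR ranking

Mutual information is estimated by the plug-in formula on discretized
variables, in nats. Continuous features are discretized to three states
at mean ± *k*σ with *k* = 1 by default (the convention of the published
mRMR program); the thresholds are boundary-inclusive toward the outer
states so an exact 0/1 indicator keeps two states. Constant features
get arity 1 and therefore zero MI with everything. The choice of log
base scales relevance and redundancy jointly and cannot change the
greedy ordering (asserted by test).

The greedy loop is exact, not approximated: each round picks the
remaining feature maximizing *D* − *R*, where *R* is the mean MI to the
selected set, maintained incrementally (one new MI term per candidate
per round). Ties break to the lower feature index, making the ranking
deterministic. The first pick maximizes *D* alone and therefore equals
the MaxRel top feature. Full ranking of *M* features costs
O(*M*²) MI evaluations; the `n_select` parameter bounds the rounds when
only a prefix is needed.

## Random forest

The forest is implemented from first principles: `n_trees` = 10 trees,
each grown on a bootstrap replicate of all *N* training cases (sampling
with replacement, size exactly *N*). At each node, *m* features are
drawn without replacement — *m* = ⌊log₂ *M*⌋ + 1 by default, constant
during growth — and the best split over midpoint thresholds between
consecutive distinct sorted values is chosen by impurity decrease
(Shannon entropy by default; Gini as an option).

Trees are fully grown and unpruned: a node becomes a leaf only when it
is class-pure or none of the drawn candidate features separates its
samples. Zero-gain splits of impure nodes are admissible — this is what
makes consistent but non-linearly-separable labelings (XOR-like) fit
exactly, and it matches the "fully grown" contract (every leaf pure or
without an admissible split) rather than a gain-positive stopping rule.
Leaf ties in majority class break to the lower class code.

Prediction is the majority vote over trees. Vote ties (possible with
even ensemble sizes) resolve to the first class in sorted label order —
the negative/non-domain class for 0/1 labels — a conservative choice
for a task whose downstream consumer assembles positive runs into
domains. Per-tree seeds are spawned from the master seed, so a fixed
seed gives bit-identical trees and predictions. Models serialize to a
versioned JSON with trees, parameters and feature names.

## Cross-validation, IFS and winnowing

Five-fold cross-validation partitions samples at random into folds
whose sizes differ by at most one; each fold is predicted by a forest
trained on the other four and confusion counts are pooled before
computing sensitivity, specificity, accuracy and MCC (any zero factor
under the MCC square root yields 0 by convention). The partition is
unstratified sample-level by default; a protein-grouped mode keeps all
windows of a protein in one fold for leakage-free protein-level
estimates (windows of neighboring residues overlap, so sample-level CV
is optimistic — see Limitations).

The IFS curve evaluates nested prefixes of the mRMR ranking: prefix *i*
holds the first *i*·*l* features, *i* = 1..⌊*N*/*l*⌋, step *l* = 5 by
default; trailing features beyond the last full block are never
evaluated (403 ranked features yield exactly 80 prefixes). All prefixes
share one CV partition so rows are comparable. The optimal set is the
prefix with maximal MCC, ties to the smaller prefix. The final
winnowing walks the curve pairwise: block *i* (features
(*i*−1)·5+1..*i*·5) is kept iff MCC(S_i) > MCC(S_{i−1}); block 1 has no
predecessor and is always kept as the baseline, so the final set is
never empty and is always a subset of the curve's features.

## Scanning refinement

Classifier output per protein is a code track over {'1', '2'}. The
refinement is a single left-to-right pass; at position *p*:

- rule (i): a '2' becomes '1' if the preceding run of '1's (measured on
  the working, already-modified track) has length ≥ 5 and the following
  run of '2's (positions *p*+1 onward) has length ≤ 3;
- rule (ii): a '1' becomes '2' if the preceding '2'-run has length ≥ 5
  and the following '1'-run has length ≤ 2.

Reading choices, fixed and documented here because the prose rule is
ambiguous: "more than four" is ≥ 5, "less than four" ≤ 3, "less than
three" ≤ 2; the examined position does not count toward its own
following run (the only reading making the two run measurements
disjoint); and the scan is one pass, not iterated to a fixpoint —
earlier flips can extend the preceding run seen later (cascade), while
following runs are effectively measured on the original track since
positions ahead of the cursor are still unmodified. Consequences worth
knowing: a trailing '2'-run of length ≤ 4 after ≥ 5 '1's is absorbed
entirely (each flip shortens the remaining run), and interiors of runs
of length ≥ 6 are provably never altered (their predecessors share
their code, so neither rule fires) — both are regression-tested.
Maximal '1'-runs of the refined track are the predicted domain regions.

## Synthetic data generator

The generator emulates the external per-residue feature sources so the
pipeline is testable offline. Proteins (default lengths 100–400) are
alternating linker/domain segments with geometric lengths, domain mean
60 and linker mean 15 residues — realistic run structure for the
refinement stage and a domain fraction of 0.8. The initial segment
state is drawn with the stationary probability 60/75 rather than 1/2;
a uniform start would make terminal residues systematically less
domain-like than the interior, leaking label signal through window
padding even when every feature channel is null.

Class-conditional channels, given the (optionally noise-flipped)
residue class:

- PSSM-like: Normal(0, 2) rounded to integers, domain residues shifted
  by `effect × sd` on designated channels — integer rounding mimics
  log-odds scores without running any alignment;
- disorder: Normal(0.5, 0.15) clipped to [0, 1], with a negative
  default shift for domains (domains are more ordered); clipping
  attenuates large shifts, which the tests account for;
- amino-acid letters: uniform for linkers; domain letters can be
  exponentially tilted along the Atchley factors (factor values are
  deterministic per letter, so a factor-channel mean shift can only
  arise from composition bias — the tilt direction is exact, the
  magnitude approximate);
- secondary structure / solvent accessibility: categorical with
  class-conditional probabilities; the planted configuration leans
  domains toward buried and regular structure, mirroring the direction
  seen in real annotated data.

The standard study conditions used by the tests and the acceptance
script, chosen once: a **strong planted** condition (10 informative
continuous channels — 9 conservation + disorder — at 3 σ, ~2000
residues) for recovery of planted features in the mRMR top 20 and for
end-to-end cross-validated MCC; a **null** condition (all effects zero,
~5000 residues) where CV MCC must sit at chance; and a **moderate**
condition (1 σ, ~2000 residues) for winnowing recall, because at 3 σ
the MCC saturates within the first feature block and the winnowing rule
then has nothing to compare. `label_noise` flips the class used for
feature generation (annotation intervals stay intact), emulating
annotation error.

What passing these tests does **not** show about real data: synthetic
channels are conditionally independent given the class, whereas real
conservation scores are strongly correlated across window positions and
channels; real disorder and secondary structure are themselves
predictions with structured errors; and sequence composition here is
uniform rather than protein-like. The tests validate the machinery —
ranking, selection, classification, refinement — not biological
accuracy.

## Numerical and design choices

- MI plug-in estimates are exact sums over contingency tables; no
  pseudocounts. Agreement with direct summation is held to 1e-12.
- Split thresholds are midpoints of consecutive distinct values; split
  candidate ties keep the first-drawn feature and first boundary, so
  growth is deterministic under the seed.
- CV seeds for each prefix evaluation come from one recorded seed; the
  resolved configuration (including derived seeds) is written next to
  every pipeline run's outputs.
- Degenerate inputs: constant features discretize to arity 1; empty
  selected sets have redundancy 0; single-class training folds are
  logged and still evaluated (the forest then predicts the constant
  class); MCC with a zero denominator is 0.
- Problem sizes in the test suite and acceptance script (8–20 proteins,
  200–300 residues each; mRMR prefixes of 20–40 features) are the
  package's standard desk-scale conditions; the combinatorial constants
  (403/465/527-length vectors, 80 IFS subsets) are exercised at full
  size since they cost nothing.

## Known limitations

- Sample-level CV shares overlapping windows of the same protein across
  folds; use the protein-grouped mode for honest protein-level error.
- The dedup stand-in is order-dependent greedy single-linkage, not a
  clustering tool; at production scale use a dedicated clusterer.
- The forest stores bootstrap indices per tree for reproducibility;
  memory grows linearly with ensemble size and N.
- The refinement is a single pass by design; tracks engineered so that
  a flip enables a later rule application in a second pass will not be
  re-scanned.
- No probability calibration or variable importance; the forest emits
  votes only.
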