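# Methods

## Data model

A dataset is an ordered list of proteins, each with an uppercase amino-acid
sequence, a biological category name, and a label y ∈ {+1 (allergen), −1
(nonallergen)}. Categories are typed *paired* (both classes present),
*positive-only*, or *negative-only*; the type drives the category-specificity
screen and the cross-validation folds. Each protein belongs to exactly one
category. Nonstandard residue codes (B, J, O, U, X, Z) are accepted verbatim
as alphabet symbols unless strict parsing is requested: real databases carry
ambiguity codes, and pattern matching is plain string equality, so no
special-casing is needed.

## Pattern enumeration

A pattern is any nonempty contiguous subsequence. Patterns form a prefix
tree (children append one residue on the right); the miner walks it
depth-first with projected occurrence lists: a node stores the end positions
of all matches, and a child's occurrences are computed by extending the
parent's by one position. Support is document frequency — a protein counts
once however many times the pattern occurs. Support is anti-monotone along
the tree, so a support threshold prunes exhaustively and any anti-monotone
predicate can cut subtrees soundly. Children are expanded in residue order,
making the visit sequence deterministic. Occurrence coordinates are 0-based,
half-open throughout (one convention end to end avoids off-by-one drift into
the concatenation step).

Counting *distinct* patterns in a dataset uses a generalized suffix automaton
(linear in total sequence length; the number of distinct substrings is
Σ len(v) − len(link(v)) over states). The quadratic hash-set count is kept
as the test oracle.

## Significance and FWER calibration

The two-tailed Fisher exact test uses the doubled-tail convention: twice the
sum of hypergeometric probabilities no larger than the observed table's,
capped at 1. Capping is needed because doubling can exceed 1 (e.g. a single
attainable table); it never changes decisions at practical δ. For
n = n₊ + n₋ ≤ 64 the probabilities are computed in exact rational arithmetic
(so probability ties — which are common by the symmetry of the
hypergeometric — are resolved exactly); above that, log-gamma arithmetic
with a 10⁻⁹ log-space tie tolerance. Per-(n₊, n₋) calculators cache the full
p-value table per support value, so the permutation loop is a vectorized
table lookup.

The Westfall–Young calibration shuffles the label vector globally
(preserving n₊) M times, records the per-permutation minimum p-value over
all patterns with support ≥ the threshold, and sets δ to the k-th smallest
minimum with k = ⌈αM⌉ (duplicates kept when sorting, for determinism).
Rejection is strict (p < δ), so the estimated FWER is at most (k−1)/M < α.
Adjusted p-values are empirical: #{m : min_p[m] ≤ p}/M.

The fast calibration maintains the M running minima in one tree traversal
and prunes a subtree when the label-free lower bound

p_low(D[q]) = min{ g(n₊, n₋, min(D[q], n₊), min(D[q], n₊)),
                   g(n₊, n₋, min(D[q], n₋), 0) }

exceeds the pruning threshold. The bound is the smallest attainable
single-tail probability at any support ≤ D[q]; it bounds the (doubled,
capped) p-value of the node and of every extension, under every label
permutation. Two threshold policies are provided:

* `distribution` (default): the current **maximum** of the running minima.
  A p-value above it can never update any minimum, so the result —
  including the entire min-p vector, hence δ, the FWER estimate and all
  adjusted p-values — is bit-for-bit identical to the exhaustive
  computation. This is the mode the equivalence tests assert against.
* `quantile`: the current k-th smallest running minimum. Prunes more
  aggressively; δ and every minimum that ends below δ are still exact, but
  minima above δ may be left at a larger value, so adjusted p-values above
  α become conservative. Used where only δ matters (e.g. the repeated null
  calibrations in the FWER experiment).

Bonferroni (α/T) is provided only as a reference computation.

## ASP and non-ASP screens

Significant patterns are split by empirical direction (d₊/n₊ vs d₋/n₋; the
two-tailed p-value cannot encode direction). An allergen-enriched
significant pattern is an **ASP** iff it occurs in zero nonallergens
(condition 2) and passes the category screen (condition 3): present in ≥ 1
paired category (3a) or in ≥ 2 distinct positive-only categories (3b). All
nested significant patterns are reported; merging is deferred to the
concatenation step. Nonallergen-enriched patterns (**non-ASPs**, used only
as predictive features) may occur in some allergens; their category screen —
present in a paired category or in ≥ 2 distinct categories overall — mirrors
3a/3b, since a pattern confined to the single negative-only category cannot
be told apart from a category-specific one.

## ConcASPs

Within each allergenic protein, all occurrence intervals of all ASPs are
merged when they overlap **or abut** (an empty overlap is ordinary
concatenation); each maximal merged interval yields a candidate string.
These witnessed interval unions realize exactly the chains of overlapped
concatenations that occur inside a real allergen, which is what the
definition requires, without enumerating abstract overlap combinations.
Candidates identical as strings are deduplicated with witnesses unioned
(ConcASPs are sequences, not loci), then a maximality filter drops any
candidate contained in another. The filter is a length-descending pairwise
substring scan; at the scale this package targets (up to a few thousand
candidates) the C-accelerated scan beats building a substring index, and a
quadratic oracle checks it in the tests. Epitope lists are compared by exact
substring inclusion only — homology search is out of scope.

## Prediction

Features: binary indicators x_ij = 1[pattern j ⊑ sequence i] for mined
ASP/non-ASP features and for 6-mers filtered to support ≥ 15 (the 6-mer
baseline); ratio features (occurrences / number of k-mer windows) for 1-mers
and 2-mers. The classifier is the soft-margin linear SVM
min ½‖w‖² + C Σ max{0, 1 − y_i(w·x_i + b)}, fitted with scikit-learn's
libsvm backend (`SVC(kernel="linear")`, intercept unregularized); an
independent slack-variable QP solved by SLSQP verifies the objective in the
tests. Weights on pattern features are directly interpretable.

Evaluation is leave-category-out cross-validation over paired categories:
the fold's test set is every protein of one paired category, and features
are re-derived from the training portion only (per-fold permutation seeds
derive from the master seed and the fold index). C is chosen by a nested
leave-category-out CV inside the training categories over the grid
log₁₀ C ∈ {−27/9, −23/9, …, 9/9} (10 points, step 4/9), extended outward in
the same step while a boundary point remains best; the inner criterion is
the mean per-inner-fold metric and ties go to the smallest C. The C chosen
by AUC is reused for AUC-10%.

Metrics: predictions are positive when the score ≥ θ. AUC is the
rank/pairwise statistic (identical to step-integrating the ROC, ties
counted ½); AUC-10% integrates the piecewise-linear ROC over FPR ∈ [0, 0.1]
and multiplies by 10; F1 and MCC are evaluated at θ = 0, with MCC defined
as 0 when a confusion marginal vanishes. AUC is NaN (with a warning) when
the test fold contains one class. Both pooled-concatenated and per-fold
metrics are reported, since either pooling convention is defensible.

## Synthetic data

The generator emulates the category taxonomy of curated allergen databases.
Default desk-scale profile: 5 paired categories (10 allergens + 10
nonallergens each), 4 positive-only categories (10 allergens each), 1
negative-only category (20 nonallergens) — 160 proteins, lengths uniform on
[50, 150], residues i.i.d. uniform over the 20 amino acids. Planted motifs
**overwrite** a uniformly chosen window (length-preserving, so planting
cannot shift the length distribution) independently per protein with a
class-specific probability in their eligible categories; windows within a
protein are chosen non-overlapping so every realized insertion stays intact
and the ground truth is exactly re-scannable. Insertion rates of 0.9 for
planted allergen motifs (0.3 in nonallergens for the condition-2 control
motif) give unambiguous signals at this sample size.

What the generator does *not* emulate: homologous families within a
category, realistic residue composition, or length/label confounding.
Passing tests therefore demonstrate correctness of the statistics and the
screens under the stated null and planted-signal models, not performance on
real proteomes, where within-category homology is precisely the reason the
category screen and leave-category-out evaluation exist.

## Problem sizes and numerical choices

The bundled experiments run at desk scale, chosen so the full suite and the
reproduction script complete in minutes on one CPU: calibration equivalence
on dozens of datasets of ≤ 50 proteins with M ≤ 100; empirical FWER over
100–200 independent null datasets at M = 100–200 (the binomial 3σ band
around α = 0.05 is the acceptance region); recovery and prediction on the
160-protein profile with M = 60–200. Exact-table FET verification covers
all contingency tables with n ≤ 40 against a rational-arithmetic oracle.

Degenerate inputs: empty candidate/ASP lists flow through every stage
(empty reports, empty feature sets score zero with a warning); single-class
folds yield NaN AUC; sequences shorter than k yield zero ratio rows with a
warning; p-value ties in the order statistic are resolved by sorted position.

## Known limitations

* The miner is single-threaded Python over numpy-projected occurrence
  lists; full-scale datasets (~10⁹ patterns) need hours, not the minutes of
  the desk-scale profile.
* The quantile pruning mode makes adjusted p-values above α conservative
  (they are exact below α).
* Non-ASP category screening has no published reference rule; the mirrored
  rule here is a design choice.
* Epitope comparison is exact inclusion only; no homology or binding
  prediction is included.
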