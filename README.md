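# aspmine

Exhaustive mining of **allergen-specific patterns (ASPs)** — contiguous
amino-acid subsequences statistically enriched in allergenic proteins — from
a labeled, categorized protein dataset, with rigorous family-wise error
control, and an interpretable linear-SVM allergenicity predictor built on the
mined patterns.

## Who this is for

Safety assessment of novel proteins (synthetic foods, genome-edited crops)
needs motifs that flag allergenicity even in proteins with no close homolog
among known allergens. `aspmine` searches *every* contiguous pattern occurring
in a protein database — not fixed-length k-mers — and reports exactly those
whose association with allergenicity survives a multiplicity correction over
the billions of patterns implicitly tested.

## The statistics

For a pattern *q* in a dataset of *n₊* allergens and *n₋* nonallergens with
support *D[q]* (number of proteins containing *q*, of which *D⁺[q]* are
allergens), the association is tested by a two-tailed Fisher exact test on
the 2×2 table, with the doubled-tail convention

> p(q) = min(1, 2 · Σ { g(a) : g(a) ≤ g(D⁺[q]) } ),  g(a) = C(n₊,a) C(n₋,D[q]−a) / C(n,D[q]).

Per-test significance is calibrated by the **Westfall–Young permutation
procedure**: labels are shuffled *M* times, the minimum p-value over all
patterns is recorded per shuffle, and the adjusted level δ is the ⌈αM⌉-th
smallest of those minima; a pattern is significant when p < δ, which bounds
the estimated FWER below α. The quadratic blow-up (every pattern × every
permutation) is tamed by branch-and-bound pruning on the pattern prefix tree
using the label-free bound

> p_low(q) = min{ g(n₊, n₋, min(D[q], n₊), min(D[q], n₊)), g(n₊, n₋, min(D[q], n₋), 0) } ≤ p(q′) for every extension q′ of q,

so whole subtrees are skipped once they can no longer change the permutation
minima. The default pruning mode is *exactly* equivalent to the exhaustive
computation (bit-for-bit, verified in the test suite).

A significant pattern is an **ASP** when it additionally occurs in **no**
nonallergenic protein and is not attributable to a single biological
category (it must occur in a *paired* category — one with both classes — or
in ≥ 2 distinct positive-only categories). ASP occurrences that overlap or
abut within an allergenic protein are merged into maximal **ConcASPs** for
downstream epitope comparison. Prediction uses indicator features
x_ij = 1[Q_j ⊑ z_i] over ASPs and non-ASPs in a soft-margin linear SVM
(½‖w‖² + C Σ hinge), evaluated by **leave-category-out cross-validation**
with features re-mined per fold so category homology never leaks.

## Worked example

```python
from aspmine import PatternSignificanceModel
from aspmine.synthetic import PlantedMotif, generate_dataset, small_profile

config = small_profile(seed=11, motifs=(PlantedMotif("WQHKW", 0.9, 0.0),))
dataset, truth = generate_dataset(config)           # 160 proteins, 10 categories
model = PatternSignificanceModel(dataset, alpha=0.05, m_perms=200, seed=5)
results = model.fit()
print(results.summary())
```

```
Allergen-specific pattern mining results
========================================================
proteins                 160 (90 allergen / 70 nonallergen)
categories               10 (paired 5, positive-only 4, negative-only 1)
sequence length          mean 99.8, min 50, max 150
--------------------------------------------------------
FWER level alpha         0.05
permutations M           200 (seed 5)
adjusted level delta     0.0005694
estimated FWER           0.045
tree nodes visited       17058
subtrees pruned          10196
--------------------------------------------------------
significant (allergen)   10
significant (nonallerg.) 0
ASPs                     4
non-ASPs                 0
ConcASPs                 1
ConcASPs length >= 15    0
ASP length               median 4, range 3-5
```

The planted motif `WQHKW` (inserted in 90 % of allergens, never in
nonallergens) is recovered: `results.asp_table()` lists the patterns `QHK`,
`QHKW`, `WQHK`, `WQHKW`, each contained in 83 allergens and 0 nonallergens
with raw p ≈ 1.8 × 10⁻³⁷ — far below δ = 5.7 × 10⁻⁴ — and adjusted p-value 0
(smaller than every permutation minimum). Overlapped concatenation collapses
the four nested patterns into the single ConcASP `WQHKW` witnessed by all 83
carriers. The calibration visited 17,058 tree nodes and pruned 10,196
subtrees while remaining exactly equal to the exhaustive computation.

Prediction on the same data:

```python
from aspmine import leave_category_out_cv
cv = leave_category_out_cv(dataset, feature_source="asp", m_perms=60, seed=5)
print(cv.mean_auc)          # held-out AUC across the 5 paired-category folds
```

There is also a CLI mirroring the library
(`aspmine simulate | summary | mine | concat | match | predict`).

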