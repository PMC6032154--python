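# Methods

## Model and procedure

`ggapnb` classifies phage proteins as virion / non-virion in four stages.

**1. Feature space.** Gapped templates are enumerated by a binary tree
rooted at `x`; a left child appends a residue symbol, a right child a gap.
A branch stops as soon as appending would exceed the budgets (defaults:
three residues, two gaps). Templates that begin or end with a gap are
discarded; the survivors are canonically ordered by (gap count, residue
count, number of gap runs, lexicographic) — the order that lists the ten
default templates as `x, xx, xxx, x-x, x-xx, xx-x, x--x, x--xx, xx--x,
x-x-x`. Each template with r residues is instantiated with all 20^r residue
tuples in alphabetical order, giving a 49,220-column vocabulary whose
column indices are stable across runs (and exportable as TSV).

**2. Density encoding.** For a pattern of width w and a sequence of length
L, all L' = L − w + 1 contiguous windows are scanned (overlap allowed, no
wraparound); a window matches a feature when its residue positions equal
the feature's residue tuple, gaps matching anything. Density = matches /
L'. Sequences shorter than w get density 0 for that pattern's columns.
Windows are scanned per pattern, so L' differs across widths. The encoder
maps each window to its base-20 column index and accumulates counts with a
bincount, which keeps the 49,220-column encoding fast and exactly
equivalent to the per-feature definition (property-tested against a
regex-counting oracle).

**3. Feature selection and discretization.** Columns are scored by the
one-way ANOVA F ratio and ranked descending, ties broken by column index.
Columns that are constant everywhere get F = 0; columns with zero
within-class variance but distinct class means get F = +inf and rank above
every finite score (they are perfect separators on the training data).
Incremental feature selection evaluates nested top-K prefixes over a
user-supplied K grid by cross-validating the downstream pipeline and picks
the K with the highest mean accuracy (smallest K on ties). Selected
densities are discretized per column into {0, 1, 2}: zero stays 0; the
cutoff m is the median of the strictly positive training values (even
counts take the midpoint of the two central values); (0, m] maps to 1 and
(m, ∞) to 2. The upper interval is open-ended — the printed-bracket
variant "(m, ∞]" has no other reading. A column with no positive training
values maps any positive value seen at prediction time to 2, keeping
labels monotone in the raw density.

**4. Classification.** Multinomial naive Bayes treats the discrete level
of each column as a count. Per class, n_j^(μ) is the column-j sum over the
class's training rows; with pseudo-count α the event probability is
θ_{μ,j} = (n_j^(μ) + α) / (Σ_j n_j^(μ) + n·α), the standard smoothed
multinomial estimator (cross-checked against scikit-learn's
`MultinomialNB` in the tests, which is never used as the implementation).
An alternative categorical (per-level) naive Bayes would model
P(x_j = l | μ) separately per level l; the multinomial reading is the
default and only implementation because the density levels behave like
abundance counts. Scoring is entirely in the log domain, so posteriors
stay finite at the full 49,220-column width. Exact posterior ties predict
the negative (non-virion) class — a deliberate conservative-call rule.

## Evaluation protocols

Sn, Sp, Acc and MCC follow the usual binary definitions, reported as
percentages; MCC with any zero marginal is defined as 0. Cross-validation
uses stratified folds from a seeded shuffle; the headline metrics come
from the *pooled* confusion counts across folds rather than the mean of
per-fold percentages (pooling is what makes small-fold arithmetic exact),
and the AUC is the trapezoidal area of the ROC over pooled out-of-fold
posteriors, equal to the Mann–Whitney concordance with ties counting 1/2.
k = N degenerates to the (deterministic) jackknife, where stratification
is impossible and plain leave-one-out splits are used.

Two leakage policies are provided. The default, `fold`, re-fits the ANOVA
ranking and the discretizer inside each training fold — the correct,
leakage-free protocol. `global` fits both once on the full dataset before
splitting, reproducing the simpler protocol common in older pipelines; it
typically inflates accuracy and exists for comparability only.

## Parameters

| parameter | default | meaning |
|---|---|---|
| max_residues / max_gaps | 3 / 2 | feature-tree budgets; defaults give the 10-template space |
| K (`n_features`) | full vocabulary | top-K ANOVA-ranked columns kept |
| α | 1.0 | Laplace pseudo-count; any positive value accepted |
| folds | 10 | stratified CV folds |
| leakage | `fold` | see above |
| residue policy | `reject` | drop records with X/B/Z etc. (or `error` to abort) |

## Synthetic data

The generator emulates a two-class FASTA benchmark: i.i.d. background
residues (uniform by default), lengths uniform on 100–300 (protein scale,
cheap to encode), and class-specific motif planting — at every eligible
window start an independent draw at the insertion rate overwrites the
pattern's residue positions with the motif's residues, gaps untouched.
Overlapping insertions follow last-write-wins semantics. The default class
sizes are 99 positive / 208 negative so imbalance-sensitive code paths are
exercised at benchmark scale. Randomness is numpy's PCG64, recorded in the
provenance; a fixed seed reproduces the dataset byte-for-byte.

`expected_density_uplift` gives the analytic between-class density gap
ρ·(1−ρ)^c·(1−20^−r), where c counts the self-overlap offsets at which a
later insertion of the same motif overwrites one of the motif's residue
positions with a different letter (c = 0 for `WW`, c = 1 for `A--C`). Edge
effects and cross-motif collisions are ignored; Monte-Carlo agreement is
verified in the tests at n = 200 sequences.

What the generator does *not* emulate: real phage proteome composition,
domain architecture, homology between sequences, or length/composition
correlations. Passing tests on synthetic data therefore demonstrate that
the pipeline recovers planted gapped-motif signal under i.i.d. backgrounds
— not that it attains any particular accuracy on real phage proteins.

## Numerical and design choices

- The window-match indicator is 1 on match, 0 otherwise, making the
  density a frequency that normalizes to 1 per pattern.
- F ranking is descending (higher F = more discriminative); an "ascending"
  sort would select the least informative features.
- ANOVA 0/0 → 0; positive/0 → +inf (ranked first). Ranking uses a stable
  sort so equal scores preserve vocabulary order.
- Class labels are fixed as {1 = virion = positive, 0 = non-virion};
  the classifier itself supports M ≥ 2 classes.
- Model bundles are plain text (TSV + JSON) with a SHA-256 vocabulary
  checksum embedded in every part; loading verifies all parts agree.
- Test problem sizes (60 sequences per class, 100–300 residues, K ≤ 500,
  10 replicates for parameter-recovery checks) were chosen as the smallest
  sizes at which the planted-motif signal-to-noise regime is clearly
  resolved; they keep the full suite under ten seconds.

## Known limitations

- Density columns for rare patterns are mostly zero for short proteins;
  the dense float64 matrix costs 8·49,220 bytes per sequence (~0.4 MB), so
  datasets beyond ~10⁴ sequences warrant the sparse triplet export and a
  chunked encoding loop.
- The incremental-selection accuracy curve depends on the CV seed; the
  best K is reported with its full curve so the flatness of the optimum is
  visible.
- No correction is made for homology between input sequences; redundancy
  reduction (e.g. clustering at 40% identity) is the caller's
  responsibility.
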