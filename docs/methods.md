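# Methods

## The model

`commtensor` models multi-context cell–cell communication as a non-negative
4-way tensor `chi` of shape contexts × LR pairs × senders × receivers and
approximates it by a rank-R non-negative CP decomposition,
`chi ≈ Σ_r c^r ⊗ p^r ⊗ s^r ⊗ t^r`. Non-negativity of both the data and the
loadings is what makes factors readable as additive communication modules:
a factor cannot "cancel" another, so high loadings always mean presence of
signal. The reported fit statistic is the normalized reconstruction error
`||chi − chi_hat||_F² / ||chi||_F²` ∈ [0, 1], the tensor analogue of the
fraction of variance a PCA leaves unexplained.

Assumptions worth stating explicitly:

- Communication scores are assumed comparable across contexts; the builder
  therefore works from within-cell normalised summaries (non-zero fraction
  or log2(CPM+1)) rather than raw counts.
- The tensor covers only cell types present in **every** context. Types
  observed in a subset of samples are dropped rather than NaN-masked; the
  ALS solver is not missing-value aware, and a masked variant is an explicit
  non-goal here.
- Multi-subunit ligand or receptor complexes are summarised by the minimum
  expression over subunits — a complex is only as available as its scarcest
  subunit.

## Tensor construction

Per context: counts are aggregated to cell-type × gene (three aggregations,
see below), each LR pair is scored for every sender/receiver cell-type pair,
and the per-context slices are stacked. Scoring functions: `mean`
((L+R)/2, the default), `product` (L·R) and `gmean` (√(L·R)); with
non-zero-fraction profiles and the mean score all tensor entries fall in
[0, 1]. The LR catalog is first filtered to pairs whose every subunit gene
is measured in every context. Edge lists from external scoring tools are
restructured the same way, with the pair axis cut to the intersection of
pairs scored in all contexts and absent triples filled with 0; negative
external scores are rejected unless the user opts into a single global
shift (the decomposition requires non-negative input).

Aggregation methods and their intent:

| method | definition | when |
|---|---|---|
| `nonzero_fraction` | share of the type's cells with count > 0 | default; robust for lowly expressed surface genes |
| `mean_logcpm` | per-cell CPM, log2(x+1), mean within type | standard normalised expression (log base configurable) |
| `mean_raw` | mean raw count | comparison/diagnostics only |

## Fitting

The ALS solver updates one factor matrix at a time, holding the others
fixed, with hierarchical (column-wise) non-negative least-squares updates;
each outer iteration touches all four modes. Initialisation is elementwise
|N(0,1)| (seeded), since a signed SVD-style start would violate the
constraint; `n_restarts = 3` independent initialisations are fitted and the
lowest-error fit kept, which in practice removes restart-to-restart scatter
at the problem sizes the package targets. Convergence is declared when the
relative change of the normalized error falls below `tol = 1e-7` (or the
error itself falls below 1e-14, which happens for exactly low-rank input),
with `max_iter = 500` as the cap. A column driven entirely to zero during
an update is revived at machine epsilon so the update stays defined; a
genuinely superfluous factor then simply carries negligible norm. Everything
is deterministic given `(seed, tol, max_iter, n_restarts)`, and factors are
reported sorted by descending context-loading norm.

Rank selection fits every rank in a candidate range (default 1..10) and
takes the elbow of the (rank, error) curve: after min–max scaling both axes,
the selected rank maximises the vertical distance below the chord joining
the first and last points. This is an automated stand-in for the visual
elbow read; the full curve is always exported so a user can override the
choice. The chord makes the rule sensitive to the scanned range — scanning
1..10 on the simulated design finds the embedded rank, while a truncated
range (e.g. 1..6) can shift the knee — so the default range is part of the
protocol.

For reporting, factor columns are rescaled to unit Euclidean norm per
dimension. This discards the factor magnitudes (they are a property of the
joint product, not of any single dimension) and makes loadings comparable
across factors and datasets; all downstream analyses operate on normalized
loadings.

## The simulator

The generator emulates a time-course communication experiment at the level
of communication scores (it does not synthesise counts): 3 cell types ×
300 LR pairs × 12 contexts, the pairs partitioned into 3 disjoint
"pathways" of 100. Four pathway × (sender, receiver) combinations are drawn
(seeded), one per temporal pattern — oscillation (1.5 sine cycles), pulse
(elevated middle third), exponential decay (rate 0.4 per context step) and
linear decrease — with curves min–max scaled to [0.05, 1] over the context
axis. Combinations sharing a pathway must involve disjoint cell types;
without that constraint, two correlated curves (decay and linear) placed on
the same pathway block with a shared sender or receiver can be absorbed by
a single rank-1 factor, and the recovered rank honestly drops to 3. Every
other tensor entry sits at the background score 0.05, so the noiseless
tensor has non-negative rank ≤ 5 (four patterns + background) with the
background carrying ~5% of the mass. Optional noise is additive Gaussian
with SD expressed as a fraction of the peak curve amplitude, clipped at 0.

What the simulator does *not* emulate: count-level sampling noise, gene-level
dropout, cell-type abundance differences, batch effects, or correlated
background communication. Passing the recovery tests therefore demonstrates
that the decomposition machinery recovers planted low-rank temporal
structure under the stated noise model — not that any particular biological
dataset is this clean.

Recovery is scored by greedily matching factors to patterns on the Pearson
correlation between context loadings and curves, then taking the Jaccard
index between each combination's pair block and the matched factor's
equally-many top-loaded pairs.

## Downstream analyses

**CorrIndex.** To compare two decompositions of tensors with identical axis
labels and equal rank, the four factor matrices are vertically stacked,
columns normalized to unit length, and with C = |AᵀB| the distance is
`(1/2R)·[Σ_i (1 − max_j C_ij) + Σ_j (1 − max_i C_ij)]` — zero iff the runs
agree up to factor permutation and positive column rescaling, bounded by 1.
Similarity is conventionally reported as 1 − CorrIndex. A per-dimension mode
reports the same statistic on each dimension's matrix separately alongside
the stacked headline value; the per-dimension minimum is stricter but blind
to combinatorial agreement across dimensions, so the stacked value is the
default.

**Factor networks and Gini.** For factor r the outer product `s^r ⊗ t^r` is
the adjacency of a rank-1 sender × receiver communication network. The Gini
coefficient of its edge weights, `Σ_ij |w_i − w_j| / (2 n² mean w)`
(pairwise mean-absolute-difference form, no small-sample correction),
measures communication imbalance: 0 when all cell pairs communicate equally,
(n−1)/n → 1 when one pair dominates. The uncorrected form is used precisely
so these two limit cases hit the stated bounds.

**Context statistics.** Ordinal phenotype association is Spearman's rho with
average-rank ties (flagged, not numeric, for constant loadings). Group
differences use two-sided independent t-tests for every factor × group pair,
Bonferroni-corrected over all performed comparisons jointly and capped at 1.
Sample clustering z-scores each factor column across samples (zero-variance
columns dropped with a warning), then applies Ward-linkage agglomerative
clustering on Euclidean distances; cluster labels are renumbered by first
occurrence so runs are comparable.

**LR-set enrichment.** LR pathway sets assign a pair to a pathway iff every
ligand and receptor subunit gene belongs to the pathway's gene set; sets
with fewer than 15 pairs are dropped (configurable). Pre-ranked GSEA ranks
pairs by loading (descending, ties broken by pair id for determinism) and
computes the weighted Kolmogorov–Smirnov running-sum enrichment score with
weight exponent 1 on loading magnitudes. The null is built from 999 seeded
permutations of the pair labels per set; NES divides the ES by the mean
|null ES| of matching sign and the empirical p-value is the
(1 + exceedances)/(1 + n) rank among matching-sign nulls, which keeps
p-values uniform for random sets. Benjamini–Hochberg adjustment is applied
across all (factor, set) results jointly.

## Numerical and design choices

- **Seeds.** Every stochastic stage (ALS restarts, simulation draws, GSEA
  permutations) derives its generator from a user seed through numpy
  `SeedSequence` spawning, so a single seed reproduces a whole run bitwise.
- **Axis order.** Cell types and pair intersections are sorted
  lexicographically; the paperwork of label alignment is deterministic.
- **Degenerate inputs.** All-zero tensors are rejected (the error ratio is
  undefined); all-zero factor columns are rejected at normalization;
  all-zero weight vectors are rejected by the Gini; constant loadings yield
  a flagged, not numeric, Spearman result.
- **Problem sizes.** The test suite and the acceptance script run the
  simulated design at its native size (12 × 300 × 3 × 3, ten replicates for
  rank-selection stability, 200 random sets × 999 permutations for GSEA
  calibration); a full rank scan takes a few seconds on one CPU.

## Known limitations

- No missing-value-aware decomposition: cell types absent from some
  contexts are excluded, which loses rare populations.
- The elbow rule is a heuristic; flat or noisy error curves can produce
  range-dependent knees. The exported curve is the authoritative output.
- CP factors are identifiable only up to permutation and scaling;
  comparisons across runs must go through CorrIndex, not direct column
  alignment.
- The built-in scorers (mean / product / geometric mean) are deliberately
  simple; probability- or network-based scores should be computed by a
  dedicated tool and imported as edge lists.
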