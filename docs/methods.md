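# Methods

## Scope and model

`sigscreen` implements a ligand-based vHTS cycle: fragment-count
featurization (Signatures), unsupervised descriptor filtering (PCA), wrapper
feature selection (GA) scored by cross-validated linear SVMs, an ensemble
screening rule with an overlap applicability-domain guard, plate-assay
reduction, and training-set augmentation for retraining rounds. It assumes
activity is attributable to constitutional substructure patterns: no 3D
conformations, tautomers, protonation states or stereochemistry enter the
descriptor.

## Signature dialect and conventions

An atomic Signature of height h is the canonical rendering of the subtree
grown from a root atom by breadth-first expansion, excluding only the edge
just traversed (ring atoms may recur on distinct paths; there are no
ring-closure labels). Rendering: atoms as `[X]` (aromatic atoms lower-case,
formal charge appended), children prefixed `''/=/#/:` for
single/double/triple/aromatic bonds and ordered lexicographically by their
fully rendered strings. Any injective canonical grammar would do — only
signature identity matters downstream — but one must be fixed; this one
keeps strings short and sortable.

Conventions fixed here:

* hydrogens are implicit; Signatures are computed on heavy atoms only;
* multi-fragment inputs are reduced to the largest covalent fragment
  (the assayed entity is the organic species; counter-ions are noise);
* aromaticity is as perceived by the parser (RDKit), i.e. Kekulé input is
  aromatized before fragmentation — aromatic vs. Kekulé changes signature
  identity, so one convention must be fixed and this is the standard one;
* an atom whose neighborhood is exhausted below the requested height
  renders as its lower-height form but is recorded under the requested
  height, preserving "per-height total = heavy-atom count". The
  `dedupe_degenerate_heights` switch in `build_matrix` merges such
  degenerate strings into their lowest height instead, since descriptor-set
  size bookkeeping differs between the two conventions in other
  implementations.

## Filtering

PAINS removal matches the published PAINS SMARTS families via RDKit's
built-in FilterCatalog; a user-supplied `(SMARTS, family)` list replaces the
default when given, and an explicitly empty list is a configuration error
rather than a silent no-op. "Similar structure" removal is a signature-set
Tanimoto against a reference set (default threshold 0.9, default reference =
the PAINS hits themselves); the original workflow delegated both steps to a
web service whose exact list/metric is not recoverable, so both are local
and replaceable here.

## PCA filter

Columns are centered (not scaled — counts share a scale and zero inflation
is informative), the SVD taken, components kept to 95% cumulative variance
by default, and importance(j) = Σ_k |V_kj|·f_k over kept components k with
variance fractions f_k. The default rule keeps columns with importance ≥
the mean importance; `"nonzero"` keeps every non-constant column. The
original work states only that "significant" contributors were kept, so the
rule is a config knob and both options are tested.

## GA-SVM search

Chromosomes are bit vectors over the PCA-surviving columns. Fitness of a
subset is the best 10-fold cross-validated score over the cost grid
(accuracy for SVC, negative RMSE on log₁₀ IC50 for ν-SVR with ν = 0.2);
ties between costs resolve to the first best in grid order. The GA uses
linear-rank selection, single-point crossover with probability 0.8, one
random bit flip with probability 0.1 per offspring, elitism fraction 0.7,
and stops at the iteration cap or after a stall window without improvement.
Fold assignment is stratified (classification) and depends only on the
seed, so fitness is deterministic given (data, seed) and is cached per
subset. The all-zero chromosome gets infinite error and can never be
returned. After termination every distinct final-population subset tied
with the best (cv_error, training_error) is refit on the full data and
returned — tied-model counts are seed- and population-dependent and are
treated as run-specific, not as a reproducible statistic.

Defaults (population 1000, 1000 iterations, stall 100, cost grid
0.01…1 step 0.01) are the screening-scale settings. The test suite and the
acceptance script run fixture-scale searches — population 20–24, ≤ 15
generations, stall 4–5, cost grid {0.1, 1.0}, training sets of 200
compounds — chosen as the smallest sizes at which the planted-rule fixture
is still a meaningful search problem (≈ 30–60 candidate columns after PCA).

Class coding is active = +1, inactive = −1, so a larger decision value means
greater confidence of activity; the "SVM-C score" used by the criteria is
the raw linear decision value (margin-normalization would rescale every
threshold without changing the ordering, and the printed thresholds are on
the raw scale). The QSAR target is log₁₀(IC50/µM) by default (IC50s are
log-normally distributed in practice); predictions are exponentiated back
to µM for reporting, with `regression_target="linear"` available.

## Screening

Ω counts only *unique* signatures and uses closed windows
[train_min, train_max]. Criteria comparisons are exactly as printed:
Ω ≥ min_overlap, decision value strictly > the floor, predicted IC50
strictly < the cap. An infinite cap disables the IC50 criterion, which is
how classifier-only ensembles screen. Out-of-vocabulary signatures never
reach the models: a linear model over the training vocabulary simply has no
weight for them, which is also why Ω must accompany the scores as the
extrapolation control. Libraries are screened in chunks of configurable
size; verdicts are pure functions of (candidate, ensemble, criteria), so
chunking cannot change results, only memory.

## Assay reduction

Blank and control are arithmetic means of their column wells. IC50
interpolation is linear in concentration by default because the source
protocol interpolates the bracketing points without a transform;
`scale="log"` interpolates in log₁₀ concentration, which is the standard
dose–response choice and is what the Monte-Carlo recovery checks use — on a
1:1 binding curve sampled at four-fold dilutions, linear-in-concentration
interpolation carries an inherent upward bias of roughly 20–30% (bounded by
the bracketing interval), while log-linear interpolation is nearly unbiased
(< 2% at 5 µM). With a non-monotone curve the bracket nearest the highest
concentration is used and flagged; a curve already above 50% at the lowest
tested concentration is flagged as below-range. The protein-check column is
reduced to a QC ratio only. Activity calls require all replicates to cross
50%; partial crossing is recorded as inactive with a weak-activity flag.

## Synthetic fixtures

`fixtures` plants a known structure–activity rule: molecules are aromatic
scaffolds (benzene, pyridine, thiophene) with substituents at
ortho/meta/para positions; actives carry a primary sulfonamide and decoy
substituents are sulfur-free, so the diagnostic signatures are exactly those
whose subtree reaches the non-aromatic `[S]`. Defaults mirror the study
conditions: active fraction 0.118, deterministic label rule
(P(active|match) = 1, P(active|no match) = 0, both configurable for label
noise), IC50s log-normal with median 5 µM and σ = 0.4 log units so nearly
all actives fall inside the 50 µM assay window. Plates are simulated from
f = c/(c + IC50) between blank and control fluorescence levels plus
Gaussian well noise.

What the fixtures do **not** emulate: real chemical diversity (a few dozen
scaffold/substituent combinations versus millions of purchasable
structures), activity cliffs not aligned with a single substructure,
assay artifacts other than i.i.d. Gaussian noise, and correlated plate
effects. Passing the recovery tests therefore shows the pipeline machinery
is correct and self-consistent, not that the models would reach comparable
precision on real screening data.

## Numerical choices and degenerate inputs

* Deterministic orderings throughout: matrix columns sorted by
  (height, canon); tied models sorted by feature subset; GA population
  sorted with chromosome bytes as the final tie-break.
* PCA cumulative-variance cutoff uses a 1e-12 tolerance; a rank-0 matrix or
  a single-row matrix is rejected.
* `hit_rate` refuses empty input and non-predicted-positive entries;
  `overlap` refuses an empty signature set; degenerate plates
  (control = blank) are errors, not NaNs.
* Seeds: every stochastic component (library generation, GA, CV fold
  shuffling, plate noise) takes an explicit seed; derived seeds stay below
  2³¹.

## Known limitations

* The bioassay-record reproduction (183 → 136 compounds and the 1072/230
  signature tallies) needs a local export of the public record
  (`data/aid787.csv`); the exact PAINS list that produced the published
  reduction is unknown, so the filter list/threshold are exposed as
  configuration and the reproduction reports whichever counts the chosen
  variant yields.
* Tied-model counts are not comparable across toolkits or seeds.
* ν-SVR behavior at very small cost values can be poorly conditioned; the
  cost grid's lower bound of 0.01 is also a numerical floor.
* The GA evaluates subsets serially; screening-scale runs (population 1000)
  are compute-heavy and expect caching to absorb converged populations.
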