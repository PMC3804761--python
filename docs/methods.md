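# Methods

This note documents the models, algorithms, numerical conventions, and
design decisions behind `emicconn`, and what the synthetic-data experiments
do and do not demonstrate.

## Association measures

**Grid mutual information.** For a paired sample binned into the cells of a
column/row partition, MI = H(X) + H(Y) − H(X,Y) is computed on the discrete
cell distribution with base-2 logarithms (values in bits).

**Normalized grid score.** m_{x×y} divides the best achievable MI over
partitions with x columns and y rows by log2 min{x, y}, the upper bound of
MI on such a grid, giving a score in [0, 1].  The log base cancels in the
ratio; bits are used throughout.

**MIC.** The maximum of m_{x×y} over all grid shapes with x·y ≤ B and
x, y ≥ 2.  The resolution budget is B = ⌊n^0.6⌋, floored at 4 so the 2×2
grid is always admissible (relevant only for n ≤ 10).  1×k grids carry no
information and are excluded.

**Search heuristic.** Exact maximization over all grids is exponential, so
the search follows the ApproxMaxMI scheme:

- one axis is equipartitioned on ranks into y rows (tied values are never
  split; each tie group is assigned the row of its first rank position);
- cut placement on the other axis is optimized *exactly* by dynamic
  programming over clump boundaries.  A clump is a maximal run of
  column-rank-consecutive points lying in a single row; an optimal
  partition never needs to cut inside a clump.  One DP run scores all
  column counts 2..⌊B/y⌋ at once;
- both orientations are evaluated and the maximum taken, because the
  equipartition step is not symmetric;
- a clump budget c (default 15) caps the number of candidate boundaries at
  c·max_columns by merging clumps with near-equal point mass.

Because every step depends only on ranks and tie patterns, MIC here is
invariant — bit-identical, not merely approximately equal — under strictly
increasing transforms of either variable, and symmetric in its arguments.

**Exact mode and oracle.** With `exhaustive=True` the row equipartition is
replaced by enumeration of all placements of y−1 row cuts between distinct
values, and the clump cap is disabled.  Since the column DP is exact given
fixed rows, this searches every admissible grid: by the refinement
monotonicity of MI, partitions with empty rows/columns never beat their
reduced forms, so enumerating "true" cut sets suffices.  An independent
brute-force oracle (`mic_oracle`, itertools enumeration + plug-in
entropies, no DP) confirms exact-mode values to 1e-12; it refuses n > 10.

**eMIC.** eMIC = MIC − PCC².  At finite n the heuristic MIC is not an
upper bound on PCC², so eMIC can be slightly negative; values are reported
signed and never clipped, and group means are computed on signed values.
A constant input vector raises a typed `DegenerateInputError` rather than
returning 0 — the caller decides; the connectivity layer maps such edges
to 0 with a logged warning.

## Temporal preprocessing

Order: discard initial volumes (default 5; a 180-volume session retains
175) → linear detrend → band-pass → motion regression.  The band-pass is a
Chebyshev Type-I design, order 4, 0.5 dB passband ripple, 0.01–0.08 Hz,
applied forward-backward (`sosfiltfilt`).  Zero-phase filtering was chosen
because phase distortion would corrupt precisely the zero-lag association
structure the measures quantify; the filter type/order/ripple are
conventional values for this band.  Motion correction regresses each
regional series on the six rigid-body parameters plus intercept and keeps
the residuals; rank-deficient regressor sets fall back to the minimum-norm
solution with a logged warning.  Regional averaging of voxel matrices is an
unweighted mean per labelled region.

## Edge space, ranking, classification

Edges are the upper triangle in row-major (i < j) order; 0-based indices
internally, 1-based atlas numbering in all written reports.  The diagonal
stores the measure's self-value but is never vectorized.

The group-label Kendall tau counts only cross-group pairs: with m controls
(+1) and n patients (−1), tau = (n_c − n_d)/(m·n).  Cross-group ties count
toward neither term while the denominator stays m·n, matching the signum
formulation literally; |tau| = 1 therefore occurs exactly when the groups
are perfectly separated on that edge.  tau > 0 means the edge value is
lower in patients.  Ranking sorts by |tau| descending with ties broken by
edge index (stable), making selection deterministic across platforms.
Selection is top-k (default k = 200); an absolute-|tau| threshold is
available as an alternative selector.

LOOCV re-ranks edges on the N−1 training subjects in every fold — the
held-out subject never influences its own fold's selection (a dedicated
test plants a subject that would flip the top edge and asserts the fold
ignores it).  Features are standardized with training-fold mean/sd by
default (switchable; MIC/eMIC features already live on comparable scales,
but PCC features are signed) and classified by a linear SVM with C = 1
(libsvm via scikit-learn's `SVC`).  A decision score of exactly 0 predicts
control (+1) — a fixed rule instead of solver-dependent behaviour.  The
pipeline contains no random state, so reports are exactly reproducible.

## Consensus networks

Consensus edges are the exact intersection of all fold selections.  Per
edge: mean_power = mean |tau| over folds; direction = majority sign of tau
over folds with 'tied' on an exact balance (any sign flip across folds is
logged); normalized_strength maps the mean rank order linearly so the best
consensus edge gets 1 and the worst gets a floor of ε = 0.05 — a display
quantity only (thickness scaling), not a statistic.  Region weights are
consensus-edge degrees, so they always sum to 2·|edges|.  A static,
editable lookup table assigns AAL-116 regions to coarse functional systems
(CON, DMN, visual, sensorimotor, frontal-parietal, cerebellum); it is
data, not computation.

## Synthetic cohorts

The generator emulates the acquisition geometry of a typical resting-state
study: 116 regions, 175 retained volumes at TR = 2 s, 32 controls + 32
patients by default.  Base signals are independent white-noise series
band-passed to 0.01–0.08 Hz (same filter as the pipeline, with a trimmed
padding margin) and z-scored.  A coupling of strength s replaces the
target by √(1−s²)·own + s·f(source) with f the identity, the centered
square (z-scored), or sin(π·) (z-scored), then adds white observation
noise (sd 0.3 by default — a moderate level at which planted effects are
clearly detectable but individual edge estimates remain noisy, as in real
data).  The centered square is nearly uncorrelated with a symmetric
band-limited Gaussian source, so planted quadratic edges have near-zero
PCC by construction and isolate what eMIC must detect.

The "paper-like" preset plants linear couplings that weaken from controls
to patients (0.6 → 0.3) and quadratic couplings that strengthen
(0.2 → 0.6) on disjoint region pairs (5 of each by default), encoding the
qualitative clinical contrast: linear connectivity decreased, non-linear
connectivity increased in patients.  Because synthetic cohorts emit the
retained volumes directly, the pipeline-level default for volume discard
is 0; the preprocessing function's own default stays 5 for raw sessions.

Seeding: one master seed; subject i draws from a stream seeded by
(master, i), so existing subjects are unchanged when a cohort is extended.
Cohort files are byte-identical across runs of the same configuration.

**What the simulations do not show.** No hemodynamics are modelled
(couplings act in signal space, not through an HRF), noise is white rather
than physiological, and region counts/subject numbers in the test-suite
experiments are reduced.  Passing tests demonstrate that the estimators
recover the association structure they target under controlled conditions;
they say nothing about effect sizes in real BOLD data.

## Problem sizes used in the test experiments

Simulation-backed checks run at sizes chosen to probe the relevant
statistics without excess: parameter-recovery and directional-contrast
experiments use 20 regions and 16+16 subjects over 20 replicates (the
planted-edge recovery criterion: ≥80% of planted quadratic edges in
eMIC's top-10 and of planted linear edges in PCC's top-10); the
classification contrast (eMIC beats PCC when only non-linear differences
are planted) uses 14 regions, 16+16 subjects, 10 replicates; the null-MIC
median comparison uses 400 independent draws at n ∈ {50, 175, 500}.  For
the directional-contrast *edge-fraction* property the selection size
equals the planted-edge count: with k far above the number of real
effects, null edges (whose direction is arbitrary) enter the consensus
and dilute a fraction that is only meaningful for signal edges; the
acceptance-level check therefore asserts a per-replicate majority
direction instead.

## Known limitations

- The heuristic MIC can differ slightly from other implementations at
  identical inputs (clump budget, equipartition details); exactness is
  guaranteed only in exhaustive mode.
- eMIC's null distribution at short, autocorrelated series is elevated
  (median null MIC ≈ 0.22 at n = 175), so single-edge eMIC values are not
  interpretable as effect sizes without a cohort-level contrast.
- The consensus-strength normalization (ε floor, min-max on mean ranks)
  is a rendering convention.
- No NIfTI/DICOM ingestion: regional extraction from voxel data is exposed
  only through `regional_average` on plain matrices.
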