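# Methods

`sdefc` implements a functional-connectivity analysis pipeline for
placebo-controlled within-subject pharmaco-fMRI designs: each participant is
scanned under placebo and under an acute drug, each scan is split into a
first and second half (the drug's peak and offset), and every analysis is run
over the four resulting design cells. The package computes three per-edge
connectivity measures, aggregates them to a network scheme, runs the
drug-by-time statistics, and asks — via connectome-based classification —
which measures and network interactions carry the drug signal.

## Connectivity measures

**Static FC (sFC).** Pearson correlation between two nodes' timeseries.
All inferential statistics operate on the Fisher-z scale (z = arctanh r),
which is variance-stabilizing; reports may back-transform. The diagonal of a
z-matrix is undefined and stored as NaN.

**Conditional-correlation series (DCC).** Each edge's time-resolved coupling
is estimated with a bivariate DCC(1,1)-GARCH(1,1) model fit by two-stage
Gaussian quasi-maximum likelihood, independently per edge. Stage one fits
GARCH(1,1), h_t = ω + α ε²_{t−1} + β h_{t−1}, to each demeaned series (no
ARMA mean model — demeaning is the simplest defensible specification for
nuisance-regressed BOLD) with *variance targeting*: ω is tied to the sample
variance via ω = s²(1 − α − β), leaving a 2-parameter problem. Stage two
runs the DCC recursion Q_t = (1 − a − b)S̄ + a z_{t−1}z'_{t−1} + b Q_{t−1} on
the standardized residuals with *correlation targeting* (S̄ = their sample
correlation) and reports R_t = Q_t,12/√(Q_t,11 Q_t,22). Unlike
sliding-window estimates, R_t involves no window-length choice.

Numerical choices: both stages are minimized by bound-constrained L-BFGS-B
(α ∈ [0, 0.5], β ∈ [0, 0.995], a ∈ [0, 0.3], b ∈ [0, 0.995], persistence
< 0.998 enforced by penalty) from a 4-point multi-start grid; ties in
log-likelihood within 1e−6 go to the smallest persistence, making the
estimator deterministic. The recursions are numba-compiled. If no start
converges, the edge falls back to an exponentially weighted moving
correlation (λ = 0.94) and is flagged; flagged edges propagate as NaN and
are excluded from aggregation and classification features. With a = b = 0
the recursion collapses to the constant residual correlation — a closed-form
limit the tests exploit.

**Dynamic FC (dFC).** Sample variance (T−1 denominator) of R_t per edge:
sensitive to large swings between coupling states.

**Entropic FC (eFC).** Histogram approximation to the differential entropy
of R_t, H = −Σ f_i ln(f_i/w_i), where f are empirical bin proportions and w
the bin width; for uniform bins this equals the Shannon entropy of the
proportions plus ln(w), which is the exact identity used as a unit test.
Defaults: 60 bins over each edge's own data range, natural log (nats);
a 15–120-bin sweep (step 15) is available and estimates are stable across it.
Entropy is computed on the raw correlation scale, not Fisher-z — both because
the series is the object of interest and because the transform choice is
configurable. Empty bins contribute 0 (x ln x → 0). A constant series has no
defined bin width under data-range binning; such edges are flagged NaN
rather than aborting the run. eFC and dFC are deliberately distinct: an edge
flipping between two extreme states has high variance but low entropy; an
edge wandering across many nearby states has the reverse.

## Network statistics

Nodes belong to one of eight canonical resting-state networks (medial
frontal, frontoparietal, default mode, subcortical-cerebellum,
somatosensory-motor, medial visual, occipital pole, lateral visual). Every
within-network edge set (8) and between-network pairing (28) is averaged
without edge selection, giving 36 interaction means per scan. Each
interaction enters a 2×2 within-subject ANOVA (drug × half), computed from
per-participant contrast scores: each effect's F equals the squared paired t
of its contrast on (1, n−1) df — an identity the tests verify to 1e−10 and
cross-check against pingouin — with partial η² = F/(F + df_error).
Families of 36 p-values are Holm-Bonferroni corrected per effect.

Edge-wise mapping uses a deliberately conservative two-stage procedure: a
one-sample t of z against 0 per design cell with Bonferroni correction over
all edges (two-sided — the sign of FC is meaningful), keeping edges that
survive in *any* cell, then paired drug-vs-placebo t-tests per scan half at
uncorrected α on the surviving union.

Drug-strength AUC is the trapezoid over observed (time, rating) pairs up to
20 min, interpolating at the boundary when ratings bracket it and never
extrapolating before the first rating (no implicit (0, 0) point); its
relation to connectivity change is a plain Pearson correlation.

## Connectome-based classification

One observation per (participant, cell) — 48 rows at the full design.
PLS-DA: PLS2 regression of the one-hot cell labels on edge features,
predicted label = argmax of predicted responses, ties to the earliest cell
in the fixed order (placebo-first, placebo-second, drug-first, drug-second).
Cross-validation leaves out every participant pair (C(12, 2) = 66 folds),
training on the rest; features are standardized with training-fold means and
scales only, and zero-variance training columns are dropped. Confusion
matrices pool the 8 test rows per fold; balanced chance is 25%.
Discrimination of the drug-first-half cell is d′ = Φ⁻¹(hit) − Φ⁻¹(fa) with
rates pooled over folds and extreme rates corrected by 1/(2n). Three PLS
components by default — fixed a priori, never tuned on test folds. The
36-interaction sweep retrains the full CV on each interaction's edges;
below-chance d′ is floored at 0 for display only, raw values are kept.
Combined-measure connectomes are plain column concatenation (standardization
happens per training fold anyway).

## Synthetic study generator

The generator is the pipeline's ground-truth instrument, not a fixture. A
scan is correlated Gaussian innovations — block correlation matrix built
from per-network/per-pair targets, eigenvalue-clipped (floor 1e−8) and
re-normalized to the nearest unit-diagonal PSD matrix, with an explicit
failure naming contradictory blocks if the repair moves any block mean by
more than 0.1 — passed through a node-wise AR(1) filter (φ = 0.4 default)
with a 100-sample discarded warm-up. Because φ is shared across nodes, the
stationary cross-correlation equals the innovation correlation, so sample
correlations converge to the target as T grows. Optional correlation
*regimes* partition a scan into blocks with different targets, providing
the time-varying coupling that dFC/eFC should detect.

Defaults (the study conditions): 12 participants × 4 cells; 40 nodes in 8
networks of 5 (keeps the 8-network structure at tractable per-edge DCC
cost); 400 timepoints per half; base within-network r = 0.4, between = 0.1;
participant heterogeneity as uniform(−0.05, 0.05) shifts on every block
correlation, drawn once per participant and shared across their four cells
so it cancels in within-subject contrasts; the default drug effect lowers
within-network r by 0.10 and raises between-network r by 0.05 in the
drug-first-half cell. Each participant uses an independent child stream of
the study seed, so output is bit-reproducible and participants are
independent.

What the generator does *not* emulate: hemodynamics beyond AR(1) smoothness,
motion or physiological artifacts, spatial structure within a network,
non-Gaussian BOLD marginals, and session/scanner effects. Passing tests
therefore demonstrate that the estimators recover the statistical structure
they target — not that real preprocessing choices are handled.

## Verification strategy and scale choices

Estimator correctness is checked against closed forms (uniform and Gaussian
differential entropy, the Shannon+ln w identity, Fisher z values, the
F = t² identity, hand-stepped Holm corrections, inverse-normal d′) and
against independent oracles (brute-force Pearson loops, per-regime sample
correlations for DCC, pingouin's repeated-measures ANOVA). Calibration is
checked by simulation: a null study classifies at 25% with d′ ≈ 0 averaged
over seeds, and the interaction F-test rejects at ≈ α under pure noise.
Effect recovery runs the full pipeline at the default desk scale with a
within-DM Fisher-z reduction of 0.10 and requires the qualitative signature:
per-participant reductions and the within-DM model topping the 36-model d′
sweep. Test problem sizes (e.g. 30-node null studies at T = 200/half,
4-node DCC studies at T = 300) are chosen so the whole suite runs on a
single CPU in minutes while leaving the assertions' Monte-Carlo bands
honest.

## Known limitations

- DCC is fit per edge; the implied whole-brain correlation matrix need not
  be jointly PSD across edges (none of the downstream analyses need it).
- Gaussian QML standard errors are not computed; the pipeline uses the
  fitted series, not parameter inference.
- The histogram entropy estimator carries the usual O(w²) discretization
  bias; it is negligible at the default 60 bins for series of a few hundred
  points but the sweep exists precisely to check sensitivity.
- With very short halves (T near the 30-volume floor) GARCH persistence is
  weakly identified; the multi-start grid plus EWMA fallback keep the
  pipeline running but flagged-edge counts should be inspected.
- When the true coupling is constant, a = 0 is the correct DCC solution and
  R_t is a flat line: its variance is 0 and its entropy undefined. At very
  small problem sizes this can flag most eFC edges; the classify stage then
  skips that measure with a logged warning rather than aborting the run.
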