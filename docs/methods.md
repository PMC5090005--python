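# Methods

This note records the models, conventions, and design choices behind
`effconn`, in the spirit of a package methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Behavioral model: inverse efficiency

Behavior is summarized per condition as inverse efficiency,
`IE = mean correct-trial RT / accuracy` (ms). Accuracy is the fraction of
correct trials. IE is undefined when no trial is correct; the package
raises rather than imputes. The trial generator draws correctness as
Bernoulli(accuracy) and correct-trial RTs as lognormal (shape
`rt_sigma_log = 0.2`, a typical RT coefficient of variation) with mean
`accuracy · target_IE`, so the expected IE equals the target for any
accuracy. Only the lognormal's mean matters to IE; the shape affects
trial-to-trial noise only.

## Signal conditioning

Order: drop `n_drop` initial volumes (default 5 of 240, TR = 2 s, leaving
235) → zero-phase band-pass → linear detrend → OLS residualization on
[intercept, Friston-24 motion expansion, WM, CSF]. The filter is an
order-2 Butterworth applied forward–backward (`sosfiltfilt`), pass band
0.01–0.08 Hz; no equivalence to any specific neuroimaging toolbox's filter
is claimed — only band selectivity, which the tests verify by FFT oracle
(≥ 90 % variance retained in-band, ≤ 10 % out-of-band). Filtering before
detrend/regression is the default because the alternative order is
contested practice; `detrend_first=True` and `band=None` expose the
alternatives. The Friston-24 expansion is `[m, m(t−1), m², m(t−1)²]` per
motion parameter with the lagged row 0 zero-filled (deterministic and
length-preserving). Rank-deficient nuisance designs are reported and
handled by SVD least squares, which is equivalent to dropping collinear
directions; residuals are exactly orthogonal to the retained design.

## Connectome construction

Pearson correlations among ROI-averaged series are Fisher-z transformed
with |r| capped at 1 − 1e−7 so duplicated signals stay finite. Only
positive connections enter the network (negative-weight analysis is out of
scope). Sparsity `S` is the fraction of the `N(N−1)/2` possible edges
retained; at each grid level the `round(S·N(N−1)/2)` largest positive
edges are kept (round-half-up; ties broken by ascending node-index pair,
for cross-platform determinism), weighted by their Fisher z (a `weights="r"`
switch keeps raw r — thresholding is identical because atanh is monotone;
only metric magnitudes change). Graphs across the grid are therefore
nested. The default grid 0.03–0.51 in steps of 0.02 (25 levels) spans the
small-world regime; `min_sparsity(N) = 2·log10(N)/(N−1)` implements the
mean-degree-2·log10(N) rule used to *validate* the lower bound (0.0277 for
N = 160, just below 0.03) — base-10 logarithm, because the natural-log
reading would give 0.064, inconsistent with that grid.

## Graph efficiency

Edge length is ℓ = 1/w: stronger connections are shorter. (A literal
ℓ = w option exists for audit; it is not the analysis default, as the
inverse convention is standard for weighted efficiency.) Shortest paths
come from Dijkstra on the length matrix; disconnected pairs have d = ∞ and
contribute 0 to every efficiency sum. Formulas:

- `E_glob` and nodal `E_glob(i)`: means of 1/d over (ordered) pairs.
- Nodal `E_loc(i)`: cube-root weighted form on the neighbor subgraph
  `G_i`, with inter-neighbor paths computed *within* `G_i`; degree < 2
  gives 0.
- Whole-network `E_loc`: mean over nodes of the neighbor-subgraph global
  efficiency (this is a distinct quantity from the mean of the nodal
  cube-root form; both appear in the literature and the package computes
  each where specified).
- `C_w`: mean over nodes of `Σ_{j,h}(W_ij W_ih W_jh)^{1/3} / (K_i(K_i−1))`.
- `L_w`: reciprocal of the mean of 1/d (harmonic form), so
  `L_w · E_glob = 1` whenever the graph is connected — an identity the
  tests assert on every connected random graph.

All formulas are verified to 1e−10 against an exhaustive-path brute-force
oracle on hundreds of random weighted graphs.

**Null models.** γ, λ, σ use Maslov–Sneppen double-edge-swap rewiring of
the binary topology (exact degree-sequence preservation; 10 × edge-count
successful swaps per null, a standard mixing heuristic) with the original
weight multiset randomly permuted onto the rewired edges, 100 nulls by
default. This preserves node count, edge count, degree sequence, and
weight distribution. The swap loop is numba-compiled; the test suite
cross-checks the resulting null ensembles against networkx's independent
rewiring implementation. Graphs too sparse to rewire are flagged and their
nulls left equal to the original.

**Integration and normalization.** Nodal curves are integrated over the
grid by the trapezoid rule (a left-Riemann option is provided; with a
0.02 step the difference is negligible). A single level integrates to the
value itself. Integrated values are divided by their mean over nodes
within each subject, so normalized values average to 1 per subject.

## Association, discrimination, validation

Feature selection computes per-node Pearson r against IE with two-tailed p
from the t transform; nodes pass at uncorrected p < α (default 0.05). The
analytic threshold `critical_r(n, α) = t_{1−α/2,n−2}/√(t² + n − 2)` is
exposed and the selection flags are asserted to agree with it at the
boundary. The selected nodes enter an OLS regression with intercept;
standardized coefficients are reported alongside raw ones (F, R², and
p-values are invariant to the standardization), with Benjamini–Hochberg
FDR over each model's coefficient set. Models with predictors ≥ n/2 are
near-saturated; the package fits them faithfully and flags them.
Sub-network models restrict to each sub-network's selected nodes; local
and global efficiency are always analyzed in separate models.

Selection and regression deliberately reuse the same subjects — the
circular two-stage design whose behavior the package is partly built to
study. Under a pure null this inflates R² above the unconditional
`E[R²] = k/(n−1)`; every report carries this caveat, and the validation
stage quantifies it: shuffling IE across subjects and refitting gives the
permutation null of the overall F (default 1000 permutations; `n_perm=1`
reproduces a single-shuffle sanity check), and fitting equal-sized random
subsets of non-selected nodes against the true IE shows chance-level R².

Discrimination uses a median split (above the median → high, below → low;
subjects exactly at the median are assigned low-first in stable subject
order, with a warning — group sizes never differ by more than one), a
pooled-variance t-test (df = n₁ + n₂ − 2), and per-node ROC: AUC as the
Mann–Whitney probability with ties counted ½, oriented so AUC ≥ 0.5 with
the direction recorded; Hanley–McNeil standard error; two-sided normal
test against 0.5 (an exact Mann–Whitney option exists for very small
groups); 95 % CI clipped to [0, 1]; operating point maximizing Youden's J
with ties resolved to the lower threshold. With 12/12 groups every AUC is
a multiple of 1/288 (1/144 without ties).

## Synthetic cohort generator

The generator emulates a small resting-state study: default 24 subjects,
160 nodes in 6 modules (module sizes follow the canonical six functional
sub-networks of the bundled 160-node atlas), 240 volumes at TR = 2 s, 30
trials per behavioral block, 95 % accuracy. A group backbone has Gaussian
weights around 0.35 within modules and 0.10 between (SD 0.05), clipped to
[0, 0.95]; each subject adds symmetric Gaussian noise (SD 0.03). The
subject weight matrix with unit diagonal is the target correlation,
repaired to positive definite by clipping eigenvalues at 1e−6 and
rescaling (repairs are counted and reported); ROI series are zero-mean
multivariate normal under that correlation. Optional voxel expansion
replicates each ROI signal into noisy voxel columns. Nuisance signals are
smooth random walks (motion) and sub-0.01 Hz confounds (WM/CSF) mixed in
with amplitude 0.4. Everything derives from one seed.

Behavior is planted *post hoc* on the computed, normalized nodal local
efficiencies: `IE = μ + Σ β_k m_k + ε` with the effect centered so μ
(530 ms, a typical direction-task IE) sets the scale, and ε calibrated so
the population R² equals a target (default 0.7). Planting on computed
metrics, rather than jointly simulating behavior and networks, guarantees
an exact known linear target for recovery tests. The default plants two
default-mode nodes with equal negative betas (higher DMN local efficiency
→ better, i.e. lower, IE). Two nodes is an a-priori power choice: at
n = 24, α = 0.05 and total R² = 0.7 split over k independent columns, the
per-node marginal detection power is ≈ 0.89 for k = 2 but cannot be
guaranteed ≥ 0.8 for k ≥ 3; positive inter-column correlation (which
modular structure induces) only raises it.

**What the generator does not emulate** — hemodynamic response shapes,
spatial autocorrelation and smoothing, scanner drift/spike artifacts,
physiological cycles, or head-motion-coupled signal changes. Passing
tests therefore certify the *statistical machinery* (metric correctness,
calibration, power under the stated linear model), not robustness to real
fMRI artifacts.

## Problem sizes and numerical choices

- Small-world summaries in tests and the acceptance script use 2–4
  subjects × 25 levels × 100 nulls; per-subject analysis at any scale is
  available through the API. The pipeline's built-in summary defaults to
  4 subjects for the same reason (a sizing choice of this package).
- Planted-recovery statistics use 100 behavior replicates on one computed
  cohort (the post-hoc planting design makes replicates cheap and exact);
  null calibration uses 500 replicates; shuffle-uniformity uses 200
  replicates × 99 permutations.
- "λ ≈ 1" is operationalized as: γ > 1 at every grid level, median λ over
  the grid within 0.15 of 1, σ = γ/λ > 1 everywhere and > 1.1 at the grid
  minimum — the threshold that defines the small-world regime's lower
  sparsity bound. λ at the sparsest level is intrinsically elevated in
  sparse connectomes and is not forced into a flat band.
- Degenerate inputs: zero-variance series columns get zeroed correlations
  (reported); graphs with fewer positive edges than a sparsity level
  requests keep all positive edges (achievable sparsity reported); empty
  graphs have E = 0 and L_w = ∞; all-identical IE refuses a median split.
- Master-seed discipline: every stochastic stage draws from a child of a
  single `SeedSequence`, so pipeline reruns are bit-identical and stages
  can be re-run independently.

## Known limitations

- The regression stage reproduces (by design) the optimism of
  select-then-fit on the same subjects; it does not provide
  cross-validated prediction.
- Weighted-null γ depends on the choice to permute weights over rewired
  edges; other weighted null families (e.g. strength-preserving) would
  give different γ magnitudes.
- The generator's correlation-targeting bridge (weights → nearest-PD
  correlation) slightly shrinks extreme weights when repair is needed;
  ground-truth weight matrices are returned so tests can account for it.
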