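# Methods

## The problem

Classical early-warning indicators of critical transitions rest on
critical slowing down: as a system approaches a saddle-node (fold)
bifurcation, its dominant restoring rate vanishes, so fluctuation variance
and lag-1 autocorrelation rise. Those indicators assume a roughly linear
restoring force, i.e. *small* noise. When the noise is strong, the
transition is triggered stochastically far before the deterministic
bifurcation, the fluctuations are large and nonlinear, and the raw-series
indicators become unreliable. The package addresses this regime.

## Distribution embedding

Let x(t) ∈ R^n obey dx = f(x, p) dt + Σ^{1/2} dW. Instead of analyzing
x itself, we analyze the evolution of its probability distribution,
summarized by moments up to second order: the means u_i = ⟨x_i⟩ and the
central second moments v_ij = ⟨(x_i − u_i)(x_j − u_j)⟩ — in total
N = n(n+3)/2 distribution variables. Empirically the moments are
estimated per sliding window (length L samples, advancing by `step`
samples; unbiased covariance, denominator L−1), giving the *embedded*
series. Window averaging shrinks the sampling noise of the means by about
1/√L, so the embedded series is a low-noise image of the distribution
dynamics. If a window carries S replicate samples per time point, the
window pools its L·S samples; with a single trajectory the L within-window
time samples serve as the ergodic surrogate. Both cases run through one
pooled-sample code path.

Analytically, the moment hierarchy closes exactly for linear drift:
du/dt = A u + b, dV/dt = A V + V Aᵀ + D, with D the noise covariance
(`linear_moment_field`). For a nonlinear scalar drift we use the Gaussian
(second-order) closure — Taylor-expand f about the mean and set the third
central moment to zero:

    du/dt = f(u) + ½ f″(u) v,        dv/dt = 2 f′(u) v + σ².

For linear f the closure error is identically zero; the package asserts
this equivalence exactly. The closed moment system is itself a dynamical
system whose fold can be located by equilibrium continuation
(`moment_bifurcation_scan`): root-tracking along a parameter grid, with
the branch declared lost when the root finder fails or the solution jumps
beyond a tolerance. For the fold normal form dx/dt = p + 3x − x³ + σξ the
closed system on the lower branch reduces to
p(u) = u³ − 3u + uσ²/(2(u² − 1)); its maximum — the fold of the moment
system — sits at p = 2.000, 1.867, 1.533, 0.773 for σ = 0, 0.2, 0.5, 1.0.
The fold advances monotonically with noise: the distribution-transition
precedes the state bifurcation, which is why warnings derived from the
embedded series fire earlier and more reliably under big noise.

## Indicators and trend criterion

Per window and variable: unbiased SD; lag-1 autocorrelation as the
Pearson correlation between the window's leading and trailing sub-series
(for a linear ramp this estimator attains its maximal value 1, which is
the intended degenerate behavior); adjusted Fisher–Pearson skewness.
Windows with zero variance yield missing values, which are dropped from
trend statistics, never interpolated. Trends are Kendall rank
correlations of an indicator trajectory against time — a quantitative
stand-in for the visual inspection common in this literature.

The CSD criterion for a series: at least one variable has strictly
positive Kendall trends in both SD and lag-1 autocorrelation. For a
one-variable series this is the usual "SD and AR rise"; for a
multivariate (e.g. embedded) series any signaling variable counts, in the
same spirit in which the network marker looks for a signaling subgroup.

Signal-to-noise ratio of a series: power of a centered moving-average
trend (span 2L+1) divided by the power of the residual about it. This
model-free definition is symmetric and reproducible; on the packaged
big-noise fold sweep the embedded series' aggregate (median) SNR exceeds
the raw one's.

## The DNM score

Per window, the absolute Pearson correlation matrix is clustered
(average linkage on distance 1 − |r|), and every cluster of size ≥ 2
appearing at any cut height of the dendrogram is a candidate dominant
group, plus always the all-variables set. Each candidate is scored with
I = SD_d · PCC_in / (PCC_out + ε), where SD_d is the mean member SD,
PCC_in the mean |r| over member pairs, and PCC_out the mean |r| between
members and outsiders, defined as 0 when the candidate is the whole
system. The per-window maximizer forms the score track; ties resolve
toward the smaller, then lexicographically earlier group. The reported
DNM members are the maximizer at the peak-score window; ranked
runner-ups at that window are kept as `runner_ups_`.

A warning fires at the first window whose score exceeds
baseline mean + z·baseline SD, the baseline being the earliest
`baseline_fraction` of windows (defaults 0.25 and z = 2); a flat baseline
falls back to the ratio rule I > 2 × baseline mean. The global argmax is
reported separately as the peak.

Known structural property: because the whole-system candidate has
PCC_out = 0, its score carries a 1/ε advantage and in practice dominates
the per-window maximization at the default ε = 10⁻³. The warning then
tracks SD_d · PCC_in of the full system — exactly the collective
fluctuation-plus-correlation signature the score is meant to amplify.
Sub-system structure is visible through the runner-ups or a larger ε.
With short windows over many variables, |r|-based subgroup selection is
dominated by sampling noise (spurious perfect pairs); membership claims
from 10-sample windows should not be over-interpreted.

ε defaults to 10⁻³ on the scale of the correlation terms; it only guards
the division and rescales the full-system score. |r| (not signed r) is
used throughout, since the dominant-group conditions concern correlation
strength. For a single-variable system the DNM construction degenerates:
group scoring requires two members, and with the correlation terms
removed the score reduces to the SD track — CSD is the one-dimensional
special case of the network marker.

## Model systems and study protocol

`fold_model(σ)`: dx/dt = p + 3x − x³ + σξ, saddle-nodes of the skeleton at
p = ±2. This normal form is the canonical local model of any fold
transition; results on it transfer qualitatively to systems whose
transition is fold-like.

`network_model(σ)`: an 18-gene regulatory stand-in. Three core genes share
a Hill-type collective self-activation h(m) = m²/(1+m²) of their mean m
with unit decay; the offset constant places the saddle-node of the
low-expression branch exactly at control parameter P = 0, and the
rank-one coupling keeps all off-symmetric core modes at decay rate 1, so
precisely one collective mode softens at the fold. Fifteen downstream
genes follow core or earlier downstream parents through Hill activation
or repression with unit decay (triangular Jacobian, hence never
destabilizing on their own). Parameters live in the versioned
`data/network18.yaml`. Its second-order embedding has 189 moment
variables.

Simulation is fixed-step Euler–Maruyama (the noise is additive, so
higher-order schemes buy little), default dt = 0.01 model-time units.
Weak bias is first order in dt; validation tests that compare ensemble
moments against moment-ODE solutions use dt = 0.005 so the bias stays
below the Monte-Carlo standard error at 5000 replicates. Seeding is
counter-based: an integer seed s maps to SeedSequence([s]) and replicate
r of an ensemble uses SeedSequence([s, r]), so every replicate is
individually reproducible and identical inputs give bitwise-identical
trajectories.

The canonical contrast experiment (`dnmark.experiments`) sweeps the fold
model quasi-statically: 121 parameter values from −6 to 6 (step 0.1), one
time unit of dwell per value, recording the last 10 states of each dwell
— the standard quasi-static protocol for slow parameter drift with burn-in.
Noise amplitudes are σ_small = 0.1 and σ_big = 1.0. Per replicate the
state jump is detected (first sample above x = 1 whose next 20 samples
also average above 1) and all analysis uses only the pre-jump segment,
matching the assumption that only before-transition data are observable
(no flickering). Windows are 10 samples, step 1, labeled at their right
edge so all statistics are causal. Measured over 300 replicates, the raw
CSD criterion holds in 97% of small-noise sweeps but only 83% of
big-noise sweeps, while on the embedded (u, v) series it holds in 96% of
big-noise sweeps and the DNM warning fires on the pre-transition segment
in 100%. The acceptance tests assert the spec'd thresholds (≥90%, <90%,
≥90%, ≥80%) over 50 fixed seeds.

## What the generators do and do not emulate

The synthetic systems give ground truth — known bifurcation points, known
destabilizing nodes, exact moment dynamics for the linear oracles — which
real data never provide. They emulate additive Gaussian noise, slow
(quasi-static) parameter drift and fold-type transitions. They do not
emulate measurement noise distinct from dynamical noise, irregular or
sparse sampling, multiplicative noise, flickering between basins, or
non-fold (e.g. Hopf) transitions. Passing tests therefore demonstrate the
method's correctness and its behavior in the fold-with-additive-noise
regime, not performance guarantees on arbitrary real data.

## Numerical choices and degenerate inputs

- Moment ODE integration: adaptive RK45, rtol 1e−8, atol 1e−10; diagonal
  variance entries are floored at zero (logged) both inside the Gaussian
  closure field and on integrator output.
- Continuation: Powell hybrid root-finding warm-started from the previous
  parameter value; branch-loss tolerance 0.5 in the packed norm; stability
  from finite-difference Jacobian eigenvalues.
- Packing order of v is row-major upper triangle (1,1), (1,2), …, (1,n),
  (2,2), … and is stable across versions; CSV round-trips use 17
  significant digits and round-trip float parsing, hence are bit-exact.
- Zero-variance variables in a correlation window keep their index, get
  |r| = 0 off-diagonal and are logged; all-constant windows produce
  missing scores; an entirely degenerate series raises.
- Detrending for the noise-reduction ratio subtracts a centered moving
  average of span equal to the window length, computed only where the full
  span exists, so sweep-induced drift is not counted as fluctuation.

## Limitations

- The Gaussian closure is exact only for linear drift or truly Gaussian
  states; near the fold the state distribution skews, and the closed
  system is an approximation whose fold location is itself an estimate.
- DNM membership from short windows is noisy (see above); scores and
  warning times are far more stable than memberships.
- The null behavior of the maximized score is an extreme-value statistic:
  with many short windows its peak-to-median ratio can exceed 2 even in
  stationary data; null calibration should use generous windows.
- Real-data ingestion is limited to delimited text in the two documented
  dialects; acquisition or preprocessing of public datasets is out of
  scope.
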