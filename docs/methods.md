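# Methods

## Overview

`ppdecode` implements Bayesian decoding of 2D arm kinematics from
multielectrode spike trains treated as point processes, with tuning models
that include recent ensemble spiking history, and the goodness-of-fit and
evaluation machinery needed to compare such models. Because suitable
public recordings are not available, a synthetic coupled-ensemble
generator reproduces the statistical regime of cortical multielectrode
sessions and closes the encode → decode → evaluate loop.

## Observation model

A spike train on (0, T] is characterized by its conditional intensity
λ(t). In bins of width Δ = 10 ms the probability of the binary count dN is
approximated by

    P(dN) = exp(dN log(λΔ) − λΔ),

a truncated-Poisson form whose total mass (1 + λΔ)e^{−λΔ} is below 1 and
approaches 1 as Δ → 0. Bins are half-open `[kΔ, (k+1)Δ)`, 0-based; an
event exactly on an edge belongs to the later bin (a convention we fix
because sub-sample event times make it observable). Bins with more than
one event — under 1% of bins at this resolution — are clamped to 1 for the
likelihood, with a warning; history covariates keep the raw counts.

The tuning model maps covariates to intensity:

    λ(x_t, H_t) = exp(α0 + Σ_i α_i x_t^i + Σ_j β_j H_t^j)

with x_t the 6-dimensional kinematic vector (2D position, velocity,
acceleration), and H_t^j the count of neuron j's spikes in the strict-past
window [t − l, t). The "full" kind carries the β term (including the
target neuron's own index, so self-history/refractoriness is modelled);
the "mov" kind drops it. The default window l = 100 ms; the window is
selected by a held-out AUC sweep (see below).

### Fitting

The binary bin observations have exact likelihood
P(spike) = 1 − exp(−λΔ), which is a binomial GLM with a complementary
log-log link and offset log Δ. We fit that by default (statsmodels IRLS,
deterministic initialisation at α0 = log mean rate, relative tolerance
1e-8, 100 iterations, convergence flagged). The Poisson point-process
pseudo-likelihood Σ dN log(λΔ) − λΔ — the Δ → 0 limit — is available via
`likelihood="poisson"`. The distinction matters only for interval
calibration: at λΔ ≈ 0.05–0.1 the Poisson form carries an O(λΔ)
coefficient bias comparable to the standard error of a 400-s fit, which
the exact likelihood avoids; point predictions are indistinguishable.

Kinematic columns are z-scored with training-span mean/SD at the pipeline
level (`SMCDecoder`), and the scaler is stored with the fitted parameters.
The GLM itself sees whatever design it is given, so coefficients fitted on
raw covariates are directly comparable to generative parameters in
recovery experiments.

## Goodness of fit

* **ROC/AUC** — thresholding λ(t) at every level c yields per-bin
  spike predictions; AUC of TPR vs FPR equals the probability that a
  random spike bin receives higher intensity than a random non-spike bin
  (ties half). Computed on held-out data by default.
* **Time-rescaling KS** — z_j = 1 − exp(−∫_{u_j}^{u_{j+1}} λ dt) are
  i.i.d. uniform under the true intensity. The integral over the
  piecewise-constant λ is evaluated exactly (partial bins prorated).
  Order statistics are plotted against b_k = (k − ½)/n with the
  large-sample 95% band 1.36/√n.
* The `one_event_per_bin` option to `time_rescale` treats the intensity
  as vanishing from an event to the end of its bin. This is the exact
  conditional intensity of a binary-bin generator (at most one event per
  bin with probability 1 − e^{−λΔ}): without it, such data show a
  spurious O(λΔ) calibration bias (≈ 0.01–0.02 in the KS statistic) that
  becomes detectable once a neuron has ≳10³ spikes. Calibration tests
  against the generator's ground truth use this option; comparisons of
  fitted models are unaffected by it in direction.

## History-window selection

For each candidate l, full models are fitted per neuron on the training
span; held-out AUC is averaged over neurons and the argmax returned, ties
broken toward the shorter window. The default grid is
{20, 50, 100, 150, 200} ms.

## State-space model and decoder

The kinematic state evolves linearly with the observed ensemble history as
an exogenous regressor:

    x_k = A [x_{k−1}; H_{k−1}] + w,  w ~ N(0, Q).

H is observable at decode time (it is a function of past spikes), so it is
treated as a known input rather than a latent state; the "mov" kind drops
the H block, leaving the usual autoregressive kinematic prior. A is
estimated by per-row ordinary least squares and Q by the residual sample
covariance (the MLE for this linear-Gaussian form, and deterministic). Q
is factored by symmetric eigendecomposition with eigenvalues floored at
zero (tolerance 1e-10·trace); a negative eigenvalue beyond tolerance is an
error.

The sequential Monte Carlo filter runs per bin:

1. propagate N_s particles through the transition model with seeded
   Gaussian noise;
2. multiply each particle's weight by Π_j P(dN_k^j | λ_j(x_k^i, H_k)),
   in the log domain with max-subtraction (stable up to hundreds of
   neurons);
3. normalize; record the weighted mean (the point estimate, taken before
   resampling) and the effective sample size 1/Σw²;
4. systematic resampling with one shared uniform draw, cumulative weights
   from the balanced-tree prefix scan; weights reset to 1/N_s.

Resampling runs every bin. If all weights underflow at a bin the filter
resets them to uniform and logs the bin index — a recoverable degeneracy
event, not an error. Initial particles are drawn from a Gaussian matched
to the training-span kinematic mean and covariance. The posterior kernel
bandwidth δ used in kernel representations of the posterior is recorded in
the result config but plays no role in the mean output. Default
N_s = 1000.

The decoded trajectory is reported in the normalized kinematic space; the
fitted scaler maps it back to raw units.

## Prefix scan

Cumulative weights use the work-efficient balanced-binary-tree scan: an
up-sweep computing pairwise partial sums at strides 2^d (n/2^{d+1}
additions at level d), then a down-sweep in which each parent passes its
value to the left child, yielding the exclusive scan; shifting by the
input element gives the inclusive form. Inputs are zero-padded to the next
power of two and truncated back. The schedule performs O(n) additions over
O(log₂ n) levels and is the algorithm that parallelises on wide hardware;
the serial running sum is retained in the tests as the equivalence oracle,
and the decoder accepts `scan="serial"` for cross-checking.

## Synthetic sessions

The generator emulates a target-pursuit motor session:

* **Kinematics** — per axis, a jerk-driven damped oscillator
  (damping γ = 3 /s, velocity friction θ = 3 /s², position restoring
  κ = 2 /s³, jerk noise σ = 3) integrated at the 20 Hz source rate, giving
  smooth, bounded positions with near-unit variance. Velocity is the first
  difference of position over the source interval and acceleration the
  first difference of velocity, matching how such quantities are derived
  from joystick samples; all six columns are linearly interpolated to the
  10-ms grid.
* **Tuning** — background rates exp(α0) log-uniform on 4–8 Hz; kinematic
  modulation depths 0.25 (position), 0.25 (velocity), 0.10 (acceleration)
  per unit of the column's stationary SD; coupling on 20% of incoming
  links with per-link SD 0.8/√max(0.2·C, 4) (so the summed coupling
  variance does not grow with ensemble size), a mean shift of −0.5 link-SD
  (inhibition-dominated, which prevents positive feedback loops from
  running away under the exponential link), and a refractory self-history
  coefficient N(−0.5, 0.1²). `coupling_scale=0` produces uncoupled
  control sessions.
* **Spikes** — bins are visited in order; each λ_j is evaluated from the
  realized past spikes, and a spike is emitted with probability
  1 − exp(−λΔ), at most one per bin (the >99% binary regime of 10-ms
  bins). The event time inside a spiking bin is the first arrival of a
  rate-λ process conditioned on at least one arrival (truncated
  exponential), so the generator's conditional intensity is known exactly
  and time-rescaling calibration holds. Any λΔ > 5 aborts with an error
  naming the neuron.

With defaults the ensemble-mean rate falls in the 4–11 Hz range typical of
curated multielectrode sessions. What the generator does **not** emulate:
task/trial structure, target onsets, non-Poisson bursting beyond the
modelled history terms, electrode noise, unit drift, or multi-spike bins.
Passing tests therefore demonstrate internal consistency of the method —
encode → fit recovery, calibration, effect directions — not performance on
real recordings.

An intrinsic limit worth stating: under the exponential link, strong
mutually excitatory coupling is unstable (bursts self-amplify), so the
generator's coupling magnitude — and with it the decodable advantage of
the full model — is bounded by the stability frontier. The full-vs-mov
decoding improvement on synthetic sessions is accordingly a few percent
of position RMSE: reliably positive in direction, but smaller than what
strongly coupled real populations can show. On uncoupled control sessions
the comparison is slightly *negative* (≈ −5% at C = 15 with 120 s of
training): the full pipeline's extra history parameters — in particular
the 6·C additional transition coefficients — cost estimation variance
when they carry no signal. The coupled-session improvement is therefore
net of this overfitting penalty, and the control check asserts the
absence of a spurious positive effect rather than an exact zero.

## Evaluation protocol

Sessions are split into a training span (first 200 s by convention; 120 s
in the scaled runs below) and a test span. Per session and model kind the
pipeline is fitted on the training span and the test span decoded; RMSE is
computed per kinematic dimension in the normalized space (so 1.0 is the
score of the constant train-mean predictor). Session RMSEs are averaged —
not pooled over bins — and full vs mov is tested with a left-tail paired
Student t-test (α = 0.05) per dimension; no multiple-testing correction is
applied across the six dimensions (the per-dimension p-values are reported
raw). The filter's Monte-Carlo variance is reduced by averaging each
session's RMSE over `n_decode_runs` independent filter seeds (3 in the
comparison runs) — this averages noise in the *estimate* and does not
touch the generative conditions.

## Problem sizes used in the shipped tests and acceptance script

Chosen once as a single-CPU workload:

* encoding recovery: 50 replicates, C = 10, T = 400 s;
* history-window recovery: 10 seeds, C = 10, T = 400 s, 200 s train;
* model comparison: 8 coupled and 8 uncoupled sessions, C = 15,
  T = 240 s (120 s train / 120 s test), N_s = 300, 3 decode runs;
* particle-count sweep: same coupled sessions, N_s ∈ {50, 200, 1000};
* acceptance script: 4 + 4 sessions of the same shape, plus a 3-seed
  history sweep at C = 10, T = 400 s.

## Numerical and degenerate-input choices

* Linear predictors are clipped at ±50 before exponentiation.
* Weight vectors must sum to 1 within 1e-8 before resampling; the
  cumulative vector is renormalized so its last edge is exactly 1.
* A neuron with no spikes in the training span cannot be fitted
  (degenerate MLE) and is dropped from the decoding ensemble, with its
  index recorded.
* Rank-deficient transition regressors raise an error naming the
  near-constant columns.
* `select_history_length` breaks AUC ties toward the shorter window.
* All stochastic components take explicit seeds; identical seeds give
  byte-identical reports.

## Known limitations

* Single summed history count per neuron (no multi-lag filters) and no
  sparsity-aware coupling estimation.
* No smoothing pass, adaptive resampling, or auxiliary particle filter.
* The tree scan is a faithful serial implementation of the parallel
  schedule; no GPU execution is provided.
* KS bands use the large-sample 1.36/√n approximation, slightly
  conservative below ~50 spikes.
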