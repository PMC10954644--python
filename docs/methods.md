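# Methods

## The model

`hogrc` treats a nonlinear dynamical network dx/dt = f(x) of N observed
variables as a collection of *nodes*, one per variable, and asks two
questions about each node u:

1. **Which groups of variables drive u jointly?**  Writing u's governing
   equation as a sum of inseparable terms, each term's variable set is a
   *higher-order neighbor* of u — a (k−1)-dimensional simplicial complex on
   k variables.  For the Lorenz63 equation dz/dt = −βz + xy the neighbor
   set of z is S_z = {{z}, {x,y}}: two terms, one univariate and one
   genuinely pairwise.  The collection over all nodes is a hypergraph
   G = (V, S).
2. **Given S_u, how well can u's next value be predicted?**  Each node gets
   its own echo-state reservoir whose wiring *encodes* S_u: the input
   matrix is split into D_u = |S_u| row blocks, block i reading only the
   variables of complex s_{u,i}, and the recurrent matrix is block-diagonal
   so the D_u hidden sub-populations never mix.  Only a 1 × n linear
   readout is trained (ridge regression on the one-step residual
   u(t+Δt) − u(t)).

Structure inference (question 1) is answered *through* prediction
(question 2): a candidate complex is non-causal for u, in the Granger
sense, when deleting it from the wiring does not worsen the held-out
one-step error by more than a threshold ε_e.  A greedy search alternates
deletions of non-causal complexes and refinements of complexes into their
facets, starting from a coarse candidate set (by default the single
complex of all variables), until a fixed point.

Two baselines share every component except the wiring: the classic RC (one
fully random reservoir, an N × n readout) and the parallel RC (PRC;
node-level reservoirs whose single undivided block reads the node's
pairwise neighbors).  Both are literal special cases of the block
construction — the classic RC is a node reservoir with the single complex
of all variables — which the test suite exploits to check the structural
containment property (driving the generic update with the block matrices
reproduces the structured states exactly).

## Reservoir update and training

    r(t+Δt) = (1−l)·r(t) + l·tanh(W_in x(t) + A r(t) + b)
    û(t+Δt) = u(t) + W_out r(t+Δt)

All inputs are standardised per variable (z-scored with the training
window's mean and standard deviation) before reaching the reservoir; the
tanh units otherwise saturate on attractors whose variables span tens of
units, and one-step errors degrade by two orders of magnitude.  Forecasts
are mapped back to raw units.  W_out minimises the Tikhonov-regularised
squared loss in closed form via the regularised normal equations; the
penalty is the squared Frobenius norm (the standard ridge reading of the
regularised regression).  With λ_W = 0 a rank-deficient system falls back
to the minimum-norm least-squares solution with a warning.

Forecasting defaults (per node): n = 600 neurons, leak l = 0.6, spectral
radius 0.9 (applied per block; blocks are decoupled so the whole-matrix
radius equals the block maximum), input scale 0.5, density 0.05, bias
scale 0.1, λ_W = 1e-6, washout 200.  These are standard echo-state ranges;
all are overridable through `ReservoirConfig`.  The classic-RC baseline
receives the same *total* budget (n × N neurons) so method comparisons are
capacity-matched.  An optional training-time state-noise injection
(`state_noise`, default 0) is available as a regulariser; the default
pipelines do not use it.

Closed-loop forecasting stacks all node reservoirs into one block-diagonal
sparse update, feeds the predicted full state back as the next input, and
truncates with a divergence flag if the state leaves floating-point range.
Reservoirs are synchronised on the last 200 true samples before the
forecast anchor.

Phase variables (the higher-order Kuramoto system) are handled by a codec:
inputs are the interleaved pairs (sin θ_i, cos θ_i), readout targets are
phase increments, and forecasts decode through θ(t+Δt) = θ(t) + Δθ·Δt.
Forecast RMSE for phase systems is evaluated on the encoded states to
avoid 2π-wrap artifacts.

## Candidate scoring (structure inference)

The error of a candidate set C for node u is the mean absolute one-step
error of a reservoir wired by C: the readout is fitted on the first 80% of
the training window (washout excluded) and the error is measured on the
held-out final 20%, teacher-forced.  The empty candidate set is scored as
the persistence forecast.  Scores are aggregated as the median over 5
independently drawn reservoir realisations; each complex's block matrices
are keyed by the complex itself, so a complex keeps identical wiring in
every candidate set containing it (a common-random-numbers variance
reduction for the greedy comparisons).

The scoring reservoir deliberately differs from the forecasting defaults:
n = 900, leak 1.0, spectral radius 0.4, input scale 1.0, bias scale 0.5,
λ_W = 1e-6, washout 100.  The full leak and modest spectral radius keep
the hidden state close to a static function of the current input, with
only short memory.  This matters because a leaky reservoir with rich
memory can *reconstruct* an excluded variable from lagged differences of
the variables it does see (for Lorenz63, y = x + ẋ/σ is recoverable from
two lags of x alone), which masks genuinely causal complexes from the
deletion test.  Short memory cannot be removed entirely: the one-step
residual over a finite Δt is the flow map, not the vector field, and its
Taylor expansion contains O(Δt²) cross-terms (for node z, an x²z term)
that only lagged information can absorb.  The default is the compromise
between these two failure modes.

Traversal order is deterministic: complexes are kept sorted from high
dimension to low, descending lexicographically within a dimension, and
deletions re-evaluate the base error after each accepted removal.
Refinement replaces a complex by all of its facets at once, dropping any
facet subsumed by another retained complex, and accepts when the refined
wiring predicts at least as well (e_old + ε_e ≥ e_new).

ε_e defaults to 1e-7 for noise-free data.  For noisy data
(`epsilon=None`) the threshold is set adaptively to 5× the standard error
of the candidate error across 5 reservoir-seed replicates — wide enough to
absorb reservoir-draw variability, narrow enough to stay below the error
jump of deleting a complex that carries real dynamical information.

### Known limitation: finite-Δt separability

Structure recovery targets the separability of the *vector field*, but
the observable one-step map is the time-Δt flow, whose higher-order Taylor
terms mix variables across complexes.  With abundant noise-free data the
scoring is precise enough (errors ~1e-5 in standardised units) that these
O(Δt²) terms, and residual differences in how well different wirings
absorb them, exceed ε_e = 1e-7 by orders of magnitude.  In practice the
greedy search then prefers the inseparable structure *of the map* where it
differs from that of the field: on Lorenz63 node z's neighbor set
{{z},{x,y}} is recovered reliably, while node x often stops at the coarser
{{x,y}} and node y at {{x,y},{x,z}} (the map's x²y cross-term makes the
{x,y} block genuinely more predictive than {y}).  The subsystem-level
leave-one-out scan is unaffected — deleting a truly coupled subsystem
always costs far more than any finite-Δt effect — and recovers coupling
networks exactly.  Users who need exact field-level separability should
sample at smaller Δt, where the cross-terms shrink quadratically.

## Simulators

All systems are integrated with a fixed-step RK4 scheme at the step sizes
the study conditions specify (Lorenz63 and its coupled variant Δt = 0.02,
FitzHugh–Nagumo 0.25, Rössler 0.1, simplified Hodgkin–Huxley 0.04,
higher-order Kuramoto 0.08), recording T = 5000 samples (10 000 for
Kuramoto) after a discarded transient of 1000 steps.  Initial conditions
are drawn uniformly from a system-specific box; coupling weights come from
[0.5, 1.5] under named substreams of the master seed (the study conditions
use heterogeneous weights without printing values).  Per-subsystem scales:
the coupled-Lorenz drive term is ρ(1+h_i)x_i, and h_i is a ±10%
heterogeneity (uniform in [−0.1, 0.1]) so each subsystem stays
Lorenz-like; the Rössler network's h_i multiplies the state directly and
is drawn from [0.9, 1.1], the standard regime.  Coupling
topologies: ring-like regular graphs, Erdős–Rényi graphs with a requested
edge count, and Barabási–Albert preferential attachment; Kuramoto
2-simplex interactions are either supplied explicitly or enumerated as the
3-cliques of the pairwise graph, each triangle entering the double sum
symmetrically in its last two indices.

Observational noise is i.i.d. Gaussian per sample.  The default mode
scales the noise standard deviation by each variable's standard deviation
(σ_n is then a relative intensity, matching the normalised RMSE metric);
an absolute mode is available.  Noise is observational only — it perturbs
the recorded trajectory, never the integration.

What the synthetic data does *not* emulate: measurement irregularity
(sampling is strictly uniform), missing values, non-Gaussian or
correlated noise, parameter drift, and transient switching between
attractors.  Passing tests therefore demonstrate correctness of the
machinery under the stated generative conditions, not robustness to the
full complexity of experimental recordings.

## Evaluation

Forecast quality uses the per-variable-normalised RMSE

    RMSE(t) = sqrt( (1/N) Σ_i [ (x̂_i(t) − x_i(t)) / σ_i ]² )

with σ_i the standard deviation of the *test* segment of the truth, and
the valid prediction steps VPS = inf{s : RMSE(sΔt) > ε_r}, ε_r = 0.01
(0.03 under observational noise).  Comparisons train each method once on
the first 60% of the data and forecast from anchors drawn uniformly
without replacement from the test segment, each leaving a full horizon of
truth ahead; the summary reports the median and quartiles of VPS per
method.

Problem sizes in the shipped test suite and acceptance script are chosen
to keep a full run on one CPU comfortable: method comparisons use
n = 1000 neurons per reservoir, a 300-step horizon and 20 anchors;
structure-recovery checks use 3–10 master seeds as stated per test.  The
qualitative behaviour is insensitive to these sizes beyond slower,
noisier summaries.

The same-hyperparameters convention applies across methods: the classic
RC's single reservoir uses the same n as one node-level reservoir, which
is the setting in which the structured models form a subset of the
classic model class.  Structure-aware wiring shows its advantage most
clearly on strongly coupled chaotic networks (the coupled-Lorenz
system); on slowly sampled systems (the FitzHugh–Nagumo network at
Δt = 0.25) the one-step map's cross-complex terms grow with Δt and an
unmasked reservoir can model them directly, eroding that advantage —
see the finite-Δt limitation above.

## Numerical choices

- Spectral radius is computed per block: dense eigenvalues up to 400×400,
  ARPACK (with a power-iteration fallback) above.
- Ridge systems are solved with `numpy.linalg.solve` on the regularised
  normal equations (symmetric positive definite by construction).
- Degenerate inputs: a constant variable passes standardisation unscaled
  (σ guarded to 1); a constant *target* yields a zero readout; zero-noise
  injection returns the input trajectory object unchanged.
- Ties in the greedy search cannot occur in exact arithmetic (errors are
  continuous); the deterministic traversal order resolves any floating-
  point coincidences reproducibly.
- All randomness flows from one master seed through named substreams
  (simulation, network weights, subsystem scales, reservoir matrices per
  complex and realisation, forecast anchors, observation noise), so
  changing one stage's draw never perturbs another stage.
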