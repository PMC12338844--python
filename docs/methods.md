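# Methods

## The problem

A run-and-tumble microorganism converts a scalar stimulus s(t) (chemoattractant
concentration in uM for *E. coli*, light intensity for phototactic algae) into
a behavioral response, summarized by the tumbling fraction f(t) in [0, 1].
Between stimulus and response sits a hidden intracellular pathway, modeled as
J internal variables **m** obeying d**m**/dt = **H**(**m**, s) with output
f = F(**m**, s).  Neither **H**, F, nor **m** is observable; only (s, f) pairs
are.  This package identifies governing equations relating s and f directly,
with the internal variables eliminated.

## Internal-variable elimination

If J = 1 and F is monotone in the internal variable, m can be expressed as a
function of (f, s); applying the chain rule to f = F(m, s) and substituting
yields the single-internal-variable form (SIVM)

    f' = G1(f, s) + G2(f, s) s'.

For J = 2 (monotone F), differentiating twice eliminates both variables and
gives the dual-internal-variable form (DIVM)

    f'' = G3(f, s, f', s') + G4(f, s, f', s') s''.

G1..G4 are unknown scalar functions represented by fully connected networks
(4 hidden tanh layers of width 20, Glorot-uniform initialization).  Training
minimizes the mean squared residual of the corresponding relation over all
valid sample points, with derivatives estimated from data (below).  The loss
is a physics-informed residual, but the derivative estimates come from finite
differences of the (smoothed) data, not autodifferentiation, so the time
variable never enters the network.

Because PyTorch is not a dependency, the networks, backpropagation and the
Adam optimizer (lr 1e-3, default moments) are implemented directly in NumPy;
at this size (two 4x20 networks, ~1.4k parameters each) that is faster than
GPU frameworks on one CPU and bitwise reproducible under a seed in
single-threaded mode.

Inputs are affinely whitened with training-set statistics, and each network
output carries a fixed physical scale (the standard deviation of the training
target, divided by the standard deviation of s' or s'' for the coefficient
network).  Any function pair remains representable; the scales only keep the
tanh stacks in their responsive range.  The statistics are stored on the
surrogate so a saved model is self-contained.

### Identifiability of the coefficient networks

The coefficient network G2 (resp. G4) multiplies s' (s'').  A training set in
which s' == 0 almost everywhere (piecewise constant stimuli, with jump
neighborhoods masked) provides no gradient signal for G2: the network stays at
initialization and the surrogate is flagged `coefficient_untrained` rather
than assigned an error.  The same applies to G4 when s'' == 0 a.e.
(piecewise constant-and-linear stimuli).

## Ground-truth generators: E. coli chemotaxis models

All three models share the MWC receptor-cluster activity

    A(m, s) = 1 / (1 + exp(N_r F_A)),
    F_A = alpha (m0 - m) + ln(1 + s/K_I) - ln(1 + s/K_A),

with N_r = 6, alpha = 1.7, m0 = 1, K_I = 18.2 uM, K_A = 3000 uM (standard
Tar/MeAsp constants), linear methylation kinetics dm/dt = k_R(1-A) - k_B A
with k_R = k_B = 0.01 /s (adapted activity exactly 1/2; adaptation time
~20 s), CheY-P production dY_p/dt = k_a A - Y_p / tau_Z with tau_Z = 0.5 s,
and a motor Hill map f = Y^h / (Y^h + K_Y^h) with h = 4, K_Y = 2.93 uM
(baseline tumbling fraction 0.20).  The CheY-P scale k_a = 8.3 uM/s is
calibrated once so that the analytic gradient threshold below reproduces
0.59 uM/s over the reference box; with k_R = k_B the adapted methylation
level for s in [0, 2] uM spans [1, 1.06], inside the reference box [1, 1.07].

* **Model I** (J = 1): CheY-P in quasi-steady state, f = Hill(k_a tau_Z A(m, s)).
* **Model II** (J = 2, separated timescales): explicit CheY-P dynamics,
  f = Hill(Y_p).  Perfectly adapting; the fast variable is slaved to its
  quasi-steady state whenever s changes slowly.
* **Model III** (J = 2, comparable slow timescales): FliM motor-ring
  remodeling tracks CheY-P deviations, dFliM/dt = (FliM0 + kappa (Y* -
  Y_qss) - FliM) / tau_M with tau_M = 8 s, kappa = 40 FliM/uM, and
  f = Hill(Y_qss(m, s) FliM / FliM0).  The two slow variables make the
  response genuinely two-dimensional: the same (f, s, s') is reached with
  different internal states and different f', so no SIVM can fit the data.
  The step response overshoots its baseline before settling (the motor
  adaptation signature).  tau_M and kappa were chosen by screening candidates
  with a nearest-neighbor estimate of the conditional spread of f' given
  (f, s, s') — a direct, network-free measure of SIVM identifiability — so
  that the violation is first-order (conditional/total spread ~0.28) while f
  stays in a measurable range; with near-equal timescales or weak coupling
  the two internal deviations are almost perfectly correlated and the model
  collapses to an effectively one-dimensional manifold.

Simulation uses forward Euler at dt_sim = 0.01 s (first-order convergence
verified), initialized at the exact closed-form steady state of the initial
stimulus, recording every 0.1 s.

## The gradient threshold S_g

When s changes slowly, Model II's fast variable stays within a tolerance Dn
of its quasi-steady state n_ss(m, s) and a single internal variable suffices.
Linearizing the fast dynamics gives the largest admissible stimulus rate

    S_g = Dn / max_{(s, m)} | (dH2/dn)^{-1} dn_ss/ds |,

evaluated over s in [0, 2] uM, m in [1, 1.07] with Dn = 0.1.  For the CheY-P
equation dH2/dn = -1/tau_Z and dn_ss/ds = -k_a tau_Z N_r A(1-A) (1/(K_I+s) -
1/(K_A+s)); the maximand peaks at the adapted corner (m = 1, s = 0) where
A = 1/2.  A 201x201 grid search plus local refinement gives S_g = 0.588 uM/s.
The same threshold is estimated empirically by compressing stimuli in time
(s(t) -> s(t T/T1), which multiplies every gradient by T/T1), retraining the
SIVM at each compression level, and locating (by linear interpolation in
(max|s'|, error)) where its relative test error crosses 5%.

## Stimulus families

* PWC: K_t = 10 random constant segments on [0, 200] s, values uniform in
  [0, 2] uM, minimum segment length 5 s.  The minimum length keeps every
  smoothing segment long relative to the sampling grid; shorter segments make
  per-segment spline fits interpolate noise.
* PWCL: constants joined by linear ramps; slopes K*_k = (c_{2k+1} -
  c_{2k-1})/(T_{2k+1} - T_{2k}) bounded by 0.3 uM/s by drawing consecutive
  constants within reach of each other, so test gradients stay in the range
  excited by training data — a precondition of the identification protocol.
* LCC: (1/P) sum a_p (1 - cos(2 pi t / b_p)), P = 3, a_p in [0.25, 1] uM,
  b_p in [20, 100] s.  Maximum gradient 2 pi / 20 ~ 0.31 uM/s, below S_g, so
  uncompressed data are SIVM-identifiable for Model II; compression to
  T1 = 100 s doubles gradients past S_g.
* ELCC: exp(sum a_q (1 - cos(2 pi t / b_q)) - c), same a, b ranges; the
  offset c is solved so the maximum equals the configured bound (2 uM).

All derivatives are analytic (closed forms carried with each trace); traces
read from files fall back to finite differences.

## Preprocessing

Measurement noise is Gaussian with sigma_eps = sqrt(P_signal / 10^(SNR/10)),
P_signal = mean(f_i^2); per-series SNR is drawn from U(20, 22) dB.  Noisy
responses are smoothed with a penalized cubic spline minimizing
p sum |y_i - f~(t_i)|^2 + (1-p) int |f~''|^2; the penalty is selected per
segment by generalized cross-validation unless p is given, and segments of
constant stimulation are smoothed independently so jumps are never bridged.
Derivatives then come from fixed stencils: backward for f', central for s',
central second differences for f'' and s''.  The backward/central asymmetry
for first derivatives is kept deliberately: the rollout applies the same
backward difference to its own predictions, so training and prediction see
identically constructed inputs.

Points within 15 samples (1.5 s = 3 tau_Z) of a stimulus jump are masked in
both modes, and points near kinks of s' are additionally masked for DIVM
training.  The wide window matters for the second-order pipeline: the
post-jump CheY-P transient produces |f''| values two orders of magnitude
above the slow-manifold signal, and a mean-squared loss dominated by those
few points degrades G3/G4 everywhere else.

A noisy-stimulus mode adds Gaussian noise to s itself, smooths it with the
same spline operator, and switches the stimulus derivatives to stencils.

## Rollout and metrics

Prediction uses only the stimulus and the reference value at the first grid
point (SIVM) or first two (DIVM):

    f^_{i+1} = f^_i + dt (G1 + G2 s'_i)                       (SIVM)
    f^_{i+1} = 2 f^_i - f^_{i-1} + dt^2 (G3 + G4 s''_i)       (DIVM),

with f^'_i the backward difference of predictions.  The stimulus derivatives
fed to the rollout are the central stencils of the sampled s, not analytic
values.  This matters at stimulus jumps: the stencil spike, multiplied by
G2(f, s) — whose evaluation stays in range because G2 takes no derivative
inputs — and integrated by the Euler update, carries the response
discontinuity (the integral of G2 s' across the jump).  For DIVM the
coefficient networks take s' as an input and are untrained at spike values,
so the stencils are zeroed inside the jump window for second-order rollouts.

Evaluation cuts each test series at its stimulus jumps: every continuous
stimulation segment is rolled out independently, initialized from the
reference at its first unmasked index (the masked post-jump neighborhood is
excluded from training, so the networks are only trusted — and only scored —
beyond it).  Derivative relations never need information across a
discontinuity, so series may be cut freely; full-series rollout remains
available and is the default of ``predict``.  Validation error E_vali
is the mean squared rollout error; test error E_test the relative mean
squared error, with denominators floored at 1e-6 (the generators keep f well
above this).  Training computes E_vali by full rollout on held-out validation
series every 50 epochs, keeps the best snapshot, and stops after 10 checks
without a 0.1% relative improvement.  Predictions are not clamped to [0, 1]
by default (an optional flag exists); unboundedness is informative — a
surrogate mis-identified off the training manifold drifts visibly.

## Study protocols and problem sizes

Every study derives all randomness (stimulus draws, noise, initialization,
batch order) from one master seed and is bitwise reproducible single-threaded.

* **Combination study** (training-set design): 10 series of 2002 samples
  (20,020 pairs); 5 training + 2 validation series cycle through the combo's
  stimulus kinds, 3 test series (one PWC, one PWCL, one LCC) are shared by
  all combos.  Noiseless data: the study isolates the information content of
  the stimulus families at matched budgets; reported errors are means over
  three replicate seeds.  Test series are evaluated segment-wise (cut at
  jumps) as described above.
* **Compression sweep**: T = 200 s LCC training / ELCC test stimuli
  compressed to T1 = 180...100 s; per level 4 training + 2 validation + 3
  test series, noisy pipeline (SNR U(20, 22)), 3 replicate seeds per level,
  mean errors.  The threshold estimate is the first upward crossing of the
  SIVM mean error through 5%.
* **Extrapolation study**: noiseless; stimuli span the nonlinear receptor
  range (LCC amplitudes 2.5-10 uM, s up to ~20 uM ~ K_I) — for s << K_I the
  ligand response is linear in s and value extrapolation is trivially easy,
  so the study must operate where the response saturates.  One surrogate is
  trained in-range; value-deviation test stimuli are single cosines whose
  maximum is pinned to exactly (1+R) times the training set's realized
  maximum with periods chosen to keep gradients at 80% of the training
  gradient maximum (value range deviates, gradient range stays in-range);
  gradient deviation compresses time at fixed values.
* **Order inference**: both surrogates accurate (<= 10% relative error) ->
  one internal variable suffices; only DIVM accurate -> two required;
  neither -> inconclusive.

## What the synthetic data do and do not show

The generators produce the full stimulus-response phenomenology the method
targets — adaptation, overshoot, fast/slow timescale separation, bounded
noisy observations — under exactly known ground truth, which is what permits
quantitative error statements.  They do not emulate non-Gaussian or
state-dependent measurement noise, irregular sampling, trial-to-trial
parameter variability, or finite-population counting noise in the tumbling
fraction; passing tests therefore demonstrate correctness of the method and
implementation, not performance guarantees on any particular experimental
recording.

## Numerical choices and degenerate inputs

Steady states are closed-form (the methylation equation is linear in A), so
initialization is exact.  Forward-Euler stability requires dt_sim < tau_Z
for Model II; divergence aborts with a diagnostic.  Grid uniformity is
enforced to 1e-6 relative on file input.  Smoothing segments need >= 4
points (5 for GCV).  The S_g maximization uses a dense grid plus one local
refinement; the maximand's peak lies at a box corner, which a grid search
hits exactly.  Non-finite rollout steps hold the last value and warn.  A
degenerate coefficient channel (zero-variance s' or s'') keeps the
coefficient network at initialization and flags the surrogate.

## Known limitations

* The empirical 5%-criterion gradient threshold is right-censored under the
  default sweep: SIVM mean errors rise monotonically with max|s'| but stay
  below 5% through ~0.7 uM/s, because the first-order quasi-steady-state
  correction is itself a function of (f, s, s') and the whitened,
  rollout-validated networks learn it.  The analytic threshold (0.59 uM/s)
  remains the sharper statement; the empirical sweep bounds it from below
  only at this error criterion.

* DIVM training on noisy data is fragile: the f'' signal on the slow
  manifold is ~1e-4 while even optimally smoothed targets carry comparable
  noise, and the shared smoothing errors in (f', f'') inputs and targets
  bias the learned damping (errors-in-variables).  Occasional replicate runs
  drift badly; replicate averaging and rollout-based model selection
  mitigate but do not remove this.
* Rollouts across stimulus jumps accumulate a landing offset over the masked
  transient (the fast dynamics there are deliberately excluded from both
  training and scoring); post-jump errors decay on the adaptation timescale.
* The uniform grid is required per series; irregular sampling would need
  stencil generalizations.
* Model III is a reconstruction constrained by qualitative published
  behavior (overshoot, monotone output, two slow variables, SIVM failure);
  its quantitative error levels are specific to the chosen parameters.
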