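# Methods

## Model and assumptions

The simulator implements a discrete-time, rate-coding abstraction of a
cortical pyramidal neuron with two synaptic integration zones. The
proximal (basal) stream is a weighted sum of `N` afferents; the distal
(apical) stream carries a one-dimensional signal "as is". The transfer
function has three activity regimes — silent, a plateau of height α
when only basal drive is suprathreshold, and a burst regime of rate 1
when basal and apical drive coincide — which is the essential
nonlinearity: coincidence of the two streams is visible in the output
rate itself. One timestep corresponds loosely to a burst-scale window
(order 100 ms); no spike timing, conductances or dendritic morphology
are modelled. Currents are signed (excitation and inhibition are
subsumed) and thresholds sit at zero, so homeostasis centres the
operating point on the nonlinear part of the transfer function.

## Parameters

| parameter | meaning | default |
|---|---|---|
| θ_p0, θ_p1 | proximal thresholds of the plateau / burst branches (current units) | 0, −1 |
| θ_d | distal threshold | 0 |
| α | plateau rate, fraction of the burst maximum | 0.3 |
| θ (point) | point-model threshold | 0 |
| μ_b | bias learning rate (1/steps) | 10⁻³ |
| μ_n | gain learning rate | 10⁻⁴ |
| μ_av | running-average rate (averaging window ≈ 200 steps) | 5·10⁻³ |
| I_p^t, I_d^t | mean-current targets | 0 |
| V_p^t, V_d^t | variance targets | 0.25 |
| μ_w | weight learning rate | 5·10⁻⁵ |
| ε | proportional weight decay | 0.1 |
| θ_M | BCM threshold: fixed (1+α)/2 = 0.65 (compartment) or sliding ⟨y²⟩ (point) | — |
| σ_a | within-class std along the class normal (classification) | 0.25 |

The point-model threshold θ = 0 is a package choice: it is not part of
the reference parameter set, and with both currents homeostatically centred at 0
it places the operating point at the sigmoid's steepest region. It is
exposed as a configuration parameter.

The variance target 0.25 means current fluctuations of standard
deviation 0.5 around threshold — large enough to traverse the
nonlinearity, small enough not to saturate.

## Update ordering and initialization

The per-timestep composition is: (1) compose `I_p`, `I_d` from the
current state; (2) evaluate the rate; (3) plasticity step; (4) bias
step; (5) gain step including the running-average updates. Every rule
consumes trailing averages as they stood *before* the current sample is
folded in; the averages are advanced at the end of each rule's step.
This ordering is a convention of the package (the rules are defined as
independent t→t+1 maps, which fixes no composition order); it makes
every rule see the same timestep-t quantities, and it is pinned down
operationally by the step-function reference implementation against
which the fused loop is tested.

Initialization: biases 0, gains 1; weights i.i.d. N(0, 1/N), which puts
the initial proximal current at order one so homeostasis starts near
its operating regime; all trailing averages (Ĩ_p, Ĩ_d, x̃_p, ỹ, and the
sliding ⟨y²⟩) are seeded from the first observed sample, avoiding a
transient from an arbitrary zero start. The sliding BCM threshold uses
the same rate μ_av as every other running average.

During the test phase *all* adaptation is frozen — weights, biases,
gains and running averages. Freezing only the weights would let the
homeostat keep drifting through the measurement window; the frozen
read-out is a pure affine map of the test inputs.

"Apical input off" (classification testing) clamps the distal current
three units below the distal threshold, so the apical gate σ(I_d − θ_d)
is numerically zero and the compartment neuron operates on its plateau
branch; for the point model the distal term is dropped from the sum. An
alternative interpretation — feeding x_d = 0 through the frozen gain
and bias — is available via the `apical_off="zero_signal"` switch.

## Synthetic inputs

The alignment task draws i.i.d. U(0,1) afferents each step (no temporal
correlation) and reads the apical target `x_d = a·x_p` off the *raw*
samples before the distraction transform, so the target remains exactly
reconstructable at every distraction scale: distraction is orthogonal
variance, not target corruption. The distraction transform rescales the
component of `x_p` inside the distractor subspace about the
distribution mean 0.5·𝟙, so `s` scales the distraction *variance*
without moving the mean input (an uncentred variant is available via
`center_rescale=False`). The distractor basis is built by projecting
Gaussian draws against `a` and orthonormalizing by QR with a
deterministic sign convention.

The classification task draws two Gaussian clusters at `b ± a/2` with
spread σ_a along `a` and `s` along each distractor direction. The
one-hot apical targets follow the *realized* side of the hyperplane
(Heaviside of `(x_p − b)·a`, with Θ(0) = 0 so exact ties — a
measure-zero event — go to class 0), so with σ_a = 0.25 about Φ(−2) ≈
2.3% of samples carry the label of the "wrong" generating class; this
is part of the task definition, and measured accuracy is scored against
these realized labels. The fixed geometry (`a`, `b`, basis) is drawn
once per task spec; batches are bit-reproducible given (spec, seed, T).

What the generators do **not** emulate: temporal correlations in the
input, more than two classes, non-orthogonal or non-isotropic
distractor geometry, nonstationary statistics, and any noise on the
apical signal itself. Passing tests therefore show that the mechanism
works under clean, stationary, factorized input statistics — not that
it is robust to realistic sensory streams.

## Training length and problem sizes

The slowest dynamical variable is the weight vector: with proportional
decay the relaxation time of the Hebbian fixed point is
1/(μ_w·ε) = 2·10⁵ steps. Runs train for 10⁶ steps by default — five
weight-decay time constants — which is stationary for every quantity
the package tracks (currents, gains, ρ); shorter runs measurably
under-read the alignment (for example, the seed-averaged ρ at N = 20
without distraction is ≈ 0.3 after 10⁵ steps, ≈ 0.87 after 3·10⁵, and
≈ 0.999 at 10⁶). The simulation-based tests run at a scaled-down input
dimension N = 20 with 5 seeds and a 2·10⁴-step test phase; the
convergence timescale is set by the learning rates, not by N, so the
scale-down affects statistics (more seed noise per cell) rather than
the dynamics. The full-size experiment (N = 100, the `full` sweep
preset) runs the identical code path.

## Numerical choices

- σ(x) is evaluated as `1/(1 + exp(−4x))` in both the vectorized API
  and the compiled loop, so the two paths are arithmetically identical;
  overflow in `exp` saturates cleanly to 0.
- The training loop is sequential by nature (each step reads state
  written by the previous one), so the hot path is a numba-compiled
  fused loop. A pure-Python reference that composes the public step
  functions is kept alongside and the suite asserts the two
  trajectories agree to 1e−12; the compiled loop is never the sole
  definition of the dynamics.
- Gains are clamped at ≥ 0: the variance-tracking rule is
  sign-symmetric in `n` and could otherwise stabilize at negative gain,
  which has no synaptic-scaling interpretation.
- Pearson correlation on a zero-variance series is reported as 0 with a
  warning (degenerate runs score as unaligned rather than erroring).
- Winner-take-all ties go deterministically to class 0.
- Per-cell sweep seeds are derived by hashing (master seed, task,
  model, rule, s, N_dist) with blake2b, so every cell is independently
  reproducible and cells are statistically independent; a failing cell
  is recorded as NaN without aborting the sweep.
- Identical (config, seed) reruns are bit-for-bit identical; the CLI
  stamps outputs with a config hash and skips unchanged reruns.

## Known limitations

- The distal signal is one-dimensional; multi-dimensional apical
  patterns (and hence multi-layer credit assignment) are out of scope.
- The two output neurons of the classifier are fully independent; no
  lateral interaction or shared normalization is modelled.
- The sliding-threshold BCM point model aligns only weakly on the
  distracted alignment task and its correlation is noisy across seeds;
  the monotone-decorrelation check for that cell is a trend test
  (Spearman ≤ 0), not a strict monotonicity claim.
- Homeostatic convergence of the *variance* is approximate (the gain
  rule balances an instantaneous squared deviation against the target),
  so realized variances sit within a few percent, not exactly at, the
  target.
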