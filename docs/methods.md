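# Methods

## Model

`prospect` implements *prospective configuration*: learning in energy-based
predictive coding networks in which inference precedes plasticity.  A
layered network has `L` weight matrices `w^1..w^L`, `L+1` layers of value
neurons `x^1..x^{L+1}`, no bias terms, and a single elementwise activation
`f` applied presynaptically, so layer `l+1` receives `w^l f(x^l)`.
Prediction-error neurons carry

    eps^l = x^l - w^{l-1} f(x^{l-1}),

and the network's energy is the sum of local terms
`E^l = 1/2 ||eps^l||^2`.  Given a stimulus and an observed outcome, the
input layer is clamped to the stimulus and (a mask of) the output layer to
the target, and the free activities descend the energy,

    dx^l = gamma (-eps^l + f'(x^l) o (w^l)^T eps^{l+1}),

with the feedback term absent at the top layer.  At the settled
("prospective") state, weights consolidate with the purely Hebbian step

    dw^l = alpha eps^{l+1} (f(x^l))^T.

Both phases are exact gradient flows on `E` (in `x` at fixed `w`, then in
`w` at fixed `x`), which the test-suite verifies against central-difference
gradients.  The weight-matched baseline trains the identical network by
backpropagation: gradient descent on `L = 1/2 ||s_target - x^{L+1}||^2` of
the feedforward pass.  Prediction is shared code, so both rules predict
identically from identical weights, and with a single weight layer their
updates coincide exactly (also a test).

## Relaxation schedule

Relaxation starts from hidden activities (and free outputs) at zero and
runs at most `max_steps = 128` sweeps with initial step `gamma0 = 0.1`.  In
adaptive mode, a sweep whose total energy fails to decrease relative to the
previous sweep halves the step; at the second halving (step reaching 0.025)
relaxation terminates early, with no sweep taken at the post-termination
step.  The energy-increasing sweep itself is kept rather than rolled back —
the simplest reading of halving "if the overall energy is not decreased";
rollback is a possible variant we did not adopt.  Reinforcement-learning
runs use a fixed, cheaper schedule (`gamma = 0.05`, 32 sweeps,
non-adaptive) because bootstrapped targets make training less stable and
relaxation is in the inner loop.  Divergence (non-finite activity) raises
an error naming the sweep.

Free prediction is computed by the feedforward shortcut, which is the exact
energy minimum with only the input clamped; a test confirms that free
relaxation converges to it.

## Initialization

Default initialization is Xavier normal, `sd = sqrt(2/(n^l + n^{l+1}))`;
Xavier uniform (`bound = sqrt(6/(n^l + n^{l+1}))`) is available and is used
by the deep-linear interference fixture; the minimal behavioral networks
use a fixed standard deviation that is a fitted parameter.  All randomness
flows through seeded NumPy generators; every fixture and experiment is
reproducible from its seed.

## Interference metric

Target alignment is the cosine between `target - y_before` and
`y_after - y_before`, where both predictions are *free* (target not
clamped) and exactly one weight update separates them.  When either
direction vector is zero the alignment is reported as missing (NaN), never
as 0 — a zero learning vector carries no directional information.  The
depth-sweep protocol uses linear networks 64 units wide, depths 1–25,
Xavier-uniform init, one update at learning rate 0.001, and a
standard-normal input/target pair per repeat, 27 repeats; alignment is
exactly 1 at depth 1 for both rules and decays with depth much faster for
backpropagation.

## Batched training

A training iteration relaxes each minibatch example independently (the
implementation vectorizes the batch as columns; activities never interact
across examples) and applies the average of the per-example Hebbian
updates; the backpropagation baseline averages per-example gradients.
`batch_size=1` is the online regime.  The synthetic classification data
are balanced isotropic Gaussian class blobs with one-hot targets — a
desk-scale stand-in exercising the loop; test error is the fraction of
argmax-misclassified test examples, summarized by its mean over epochs
(speed of learning) and minimum (attainable error).  These blobs contain
none of the structure of natural-image benchmarks, so passing tests here
validates the training loop, not benchmark-level claims.

## Motor simulation

Minimal 2-2-2 network: inputs encode the blue/red background (one-hot),
hidden units the latent context beliefs [B] and [R] (input-to-hidden is
one-to-one; off-diagonal entries are structurally zero and never updated),
outputs the predicted + and − perturbations.  Targets: `+ -> [1,0]`,
`- -> [0,1]`, unperturbed `-> [0,0]`.  Every trial — probes and washout
included — is a learning step; free predictions on testing-triplet probe
trials are recorded before that trial's update, and the adaptation change
of a triplet is the absolute difference of the perturbation prediction
(output difference) between its two probes.  The schedule follows the
published protocol: 24 training blocks (counterbalanced B0/R0 pairs, 32
perturbation trials with 4 B+ and 4 R− per consecutive 8, washouts of
{14,16,18} then {6,8,10} trials sampled without replacement from
replenishing bags, two triplets with alternating exposures), then 8
shuffled repetitions of the four test combinations with {2,4,6}-trial
washouts.  Counterbalancing alternates across consecutive blocks, starting
arm set by participant parity.  Layer learning rates are independent
(plasticity from perception to belief differs from belief to prediction).

## Reversal simulation

Minimal 1-1-2 network; the input is 1 throughout, one hidden unit encodes
which option is currently superior, outputs are the two option values.
Choices are softmax with temperature 1 over the two predicted values;
outcomes are +1/−1.  The learning step clamps the chosen option's output
to the outcome; prospective configuration leaves the other output free
while backpropagation masks its error.  The chosen-option output activity
at choice time is the recorded value signal; consecutive pairs starting
with a punished trial are classified stay/switch by the next choice,
giving four per-type means.  The environment assigns reward probabilities
0.8/0.2 that swap every 20 trials (the source experiment does not print
these; they are exposed as configuration), 16 participants, 128 trials.

## Fitting

Model outputs and behavioral data live on different scales, so model means
`x_c` are fitted to per-condition data `d_c` by `min_a sum_c (a x_c -
d_c)^2` with `a >= 0` resolved in closed form (motor), adding an intercept
`b` for the reversal signal (different baseline units); a negative
closed-form slope is clipped to zero and the intercept refitted.  Grid
search is exhaustive: init s.d. {0.01, 0.05, 0.1} × two layer rates
{0.00005, 0.0001, 0.0005, 0.01, 0.05} for the motor task; init s.d. and
rate both from {0.01, 0.05, 0.1} for the reversal task.  The reversal fit
runs the full grid at 16 participants; the motor fit screens the full grid
at a reduced participant count and refits the leading candidates at the
full 24 participants, taking the refit argmin (relaxation makes each
motor grid point minutes of compute; the screen orders points far apart
in objective reliably, and the refit settles the close ones).  The
selected points are frozen in ``prospect.behavior.fitted``.  The shipped
`examples/data/*.json` targets are approximate figure-read stand-ins and
are labeled as such; users supply their own measured values for real
fitting.

## Activation of the minimal behavioral networks

The source protocol does not state the activation for the 2-2-2 and 1-1-2
networks.  We use the identity (linear) activation: the networks must emit
signed outputs (−1 outcomes, bidirectional perturbation differences) from
one-hot or constant inputs, and in this regime the linear energy landscape
keeps both rules' dynamics transparent; the contrasts of interest
(latent-state inference by relaxation, its absence under backpropagation)
are first-order effects that do not require a nonlinearity.  Sigmoid
hidden units were considered and behave qualitatively similarly for the
motor task but saturate easily in the reversal task, where punishments
drive the single hidden unit's sigmoid into its flat region and learning
stalls.

## Q-learning

Algorithm: per episode, an epsilon-greedy rollout (exploration probability
`max(0.01, 0.08 - 0.01 * episode/200)`, argmax ties broken by lowest
action index) stores transitions in a FIFO buffer of capacity 50000; once
the buffer holds more than 2000 transitions, each episode ends with 10
replay epochs of minibatch-60 training with bootstrap targets
`r + 0.98 max_a Q(s', a)` (plain `r` at terminals), supervising only the
chosen action's output.  Observations are standardized by Welford's online
mean/variance (s.d. floor 1e-8 for constant entries); statistics update on
every observed state, transitions store raw observations, and
normalization applies current statistics at replay time (the alternative —
freezing statistics at storage — is unstated in the source; using current
statistics keeps all replayed inputs on one scale).  Environments attach
through a `reset()/step(action)` contract.  The built-in two-state
deterministic chain has exact value-iteration values
(`Q*(0,advance)=0.98`, `Q*(1,advance)=1`, `Q*(.,quit)=0`), so loop
correctness is testable without external simulators.  Desk-scale toy runs
shrink the replay threshold, episode count and hidden width through
`QConfig` (e.g. threshold 100, 300 episodes, two hidden layers of 16); the
reference defaults are unchanged.

## Problem sizes and tolerances

Finite-difference oracles run on networks of at most 4 layers and 8 units
per layer at tolerance 1e-5 (double precision; central differences with
eps = 1e-6).  Zero-fixed-point and exact-identity checks use 1e-10 or
exact array equality.  The depth sweep runs its full published protocol
(27 repeats, depths 1–25); behavioral tests run the stated participant
counts (24 motor, 16 reversal) at single fitted grid points, with the full
grid search available as library code and demonstrated on reduced grids in
tests.  Statistical checks on samplers use 2 standard errors at sample
sizes large enough that the check is sharp.

## Known limitations

- No convolutional or recurrent operators; dense layers only.
- No optimizers beyond plain gradient descent (no momentum/Adam) and no
  weight decay.
- The synthetic classification data cannot support benchmark-level
  comparisons between the two rules; they only exercise the machinery.
- Behavioral reproductions are qualitative contrasts at fitted parameters;
  the shipped comparison targets are approximate stand-ins, not data.
- Relaxation cost grows with depth and with `max_steps`; the adaptive
  schedule mitigates but does not remove this.
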