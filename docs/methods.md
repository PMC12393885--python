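# Methods

## The model

`klinosim` simulates salt klinotaxis (the "weathervane" mechanism) of
*C. elegans* with a deliberately minimal sensorimotor circuit: the two
amphid salt sensors ASEL/ASER, the first- and second-layer interneuron
pairs AIYL/R and AIZL/R, and the four neck motor neurons SMBDL/VL/DR/VR.
Chemical synapses run ASE -> AIY -> AIZ -> SMB (three synapses, the minimum
the connectome allows); AIY and AIZ pairs are electrically coupled; each
SMB carries a self-connection and a constitutive oscillatory drive.

**Sensory transduction.** The sensors are stateless transducers of the
recent concentration history

    z(t) = (100/N) * int_{t-N}^{t} c dt  -  (100/M) * int_{t-(N+M)}^{t-N} c dt,

a coarse-grained time derivative with averaging windows N (recent) and M
(earlier), both evolvable in [0.1, 4.2] s.  The ON cell ASEL outputs
z_ON = max(z, 0), the OFF cell ASER z_OFF = max(-z, 0); the factor 100
rescales millimolar concentrations into a convenient range.

**Neuron dynamics.** The eight stateful neurons are leaky sigmoid units,

    tau_i dy_i/dt = -y_i + sum_j w_ji z_j + sum_k g_ki (y_k - y_i) + I_i,
    z_i = sigma(y_i + theta_i),  sigma(x) = 1/(1 + e^{-x}),

with y_i the membrane potential relative to rest, theta_i a bias, w_ji
chemical weights, g_ki >= 0 gap conductances.  AIY neurons receive the
sensory current w_ON z_ON + w_OFF z_OFF; SMB neurons receive their
self-connection w_self z_self and the oscillatory current
w_OSC sin(2 pi t / T) (dorsal) or its antiphase (ventral), with T = 4.2 s,
the undulation period on agar.  Dorsoventral symmetry ties the AIZ->SMB
weight, the SMB bias and the SMB self-weight together on each body side,
leaving 22 free parameters in total.  A self-connected unit is unistable
(responds without hysteresis) when w_self < 4; nothing in the model forbids
evolved self-weights above 4.

**Worm kinematics.** The worm is a point moving at constant speed
v = 0.022 cm/s; its heading mu obeys d(mu)/dt = phi with

    phi = w_NMJ * (z_SMBDL + z_SMBDR - z_SMBVL - z_SMBVR),

counterclockwise positive.  Body mechanics and thrust generation are
outside the abstraction; undulation enters only through the oscillatory
drive and the fitness penalty below.

**Environments.** Evolution uses conical gradients c = alpha * (distance to
peak), alpha < 0 drawn per assay from [-0.38, -0.01] mM/cm, whose steepness
is independent of the distance to the peak; evaluation uses a Gaussian
plume (C0 = 1.0 mM, lambda = 1.61 cm) mimicking a laboratory plate.  The
peak sits at (4.5, 0) cm and the worm starts at the origin.

**Chemotaxis index.** CI = 1 - (1/T_sim) int h(t)/h(0) dt, with h the
distance to the peak and h(0) = 4.5 cm the standard start distance.  The
turning rate's sign is checked at the 1/4- and 3/4-cycle marks of every
complete oscillator period; equal signs mean the worm is curving steadily
instead of undulating and deduct 0.008 from the CI.  After the deductions
the CI is clamped to [0, 1].

## Evolutionary search

A population of 60 genomes (22 reals in [-1, 1], linearly mapped onto the
physiological ranges) evolves for 300 generations: the top 20 are copied,
consecutive elite pairs produce two-point-crossover children with
probability 0.6, elite members spawn Gaussian mutants with probability 0.5
(per-gene probability 0.4, SD 0.05, clipped to the box), and fresh random
genomes refill to 60.  Fitness is the penalized CI averaged over 50 conical
assays (T_sim = 500 s) with randomized slope, initial orientation and
initial motor activations.  Optionally the AIY->AIZ weights decode into
[-15, 0], implementing the experimentally motivated constraint that this
synapse be inhibitory while keeping the search space box-shaped.

Design choices where the procedure was genuinely open:

- **Fitness caching.** Every genome is evaluated once, at creation; elite
  copies keep their fitness.  This keeps the recorded best fitness
  monotone (true elitism) and spends no trials on unchanged individuals.
  The alternative -- re-evaluating elites each generation -- makes the
  "best" trace a noisy estimate of the same search.
- **Population composition.** Crossover children and mutants are added
  alongside the verbatim elite copies; randoms fill any remainder, and
  extras beyond 60 are truncated from the end.
- **Initial state.** Interneurons start at rest (y = 0); motor activations
  are drawn in release space ([0, 1]) and converted through the clipped
  inverse sigmoid.

## Behavioral analysis

The curving rate reduces a six-undulation-cycle window to two displacement
vectors r1, r2 (start->midpoint, midpoint->end on the oscillator clock) and
reports the signed angle from r1 to r2 divided by |r1| + |r2| (rad/cm).
Note the estimator's scale: on a perfect circle of curvature kappa it reads
kappa/2 (the chord angle spans three cycles, the path length six); all
analyses here use it for sign and trend, where the factor is immaterial.
Bearing is the signed angle from r1 to the peak direction at the window
midpoint.  Concentration gradients normal to and along the movement
direction are one-sided finite differences with a 0.001 cm probe.  The
first three cycles of every run are discarded: the averaging windows still
contain the pre-filled start concentration there, so the sensory derivative
is not meaningful.  Ensembles start each short assay (200 s) at a random
position within 4.5 cm of the peak with random orientation and motor
activations; starts for the ensemble are not pinned to the standard assay
origin so that bearings and gradients cover their full ranges.

Perturbation experiments operate on decoded parameter sets: shifting both
ASER->AIY weights in increments of +1.5 (variants #0..#15) carries the
synapse from inhibitory to excitatory, emulating the salt-concentration
memory-dependent plasticity of that synapse; multiplying the AIZ->SMB
weights and SMB self-weights by 0.9 (or lowering the SMB biases) emulates
reduced SMB excitability in starved animals; zeroing both gap conductances
probes the electrical coupling.  Step-response probes hold the
concentration spatially uniform (the worm's own motion cannot feed back
into sensing) and step it at an oscillator-phase-locked time, optionally
delayed by half a cycle.

## Numerical choices

- Forward Euler with synchronous updates; dt = 0.01 s for evolution and CI
  evaluation, 0.001 s for displayed trajectories and period measurements.
  Within a step: sense -> update averaging windows -> update all y from
  previous-step values -> recompute releases -> turn -> move.  The heading
  update uses the fresh releases, and the displacement is exactly v*dt, so
  trajectory path length is exactly speed times duration.
- Averaging windows are whole numbers of steps (n = max(1, round(N/dt)));
  the transducer prefactor uses the realized duration n*dt, making z
  exactly zero on constant input.  The window sums are maintained
  incrementally in a ring buffer (drift over 10^5 steps is ~1e-11 and is
  checked against direct summation in the tests).
- Before t = 0 the history buffer is pre-filled with the start
  concentration, so z = 0 at the start; the warm-up bias this leaves in the
  first N+M seconds is why analyses skip the first three cycles.
- The membrane time constants are not part of the evolved parameter set; a
  single configurable tau = 0.1 s applies to every stateful neuron (with
  dt/tau = 0.1 the explicit scheme is comfortably stable for the admissible
  conductances).
- The compiled inner loop (`numba`) is numerically identical to the plain
  reference stepper in `dynamics`; the test suite pins the two against each
  other.  Euler convergence is verified against a 100x finer integration at
  a coarse step of 5e-4 s (the discrepancy scales linearly with the step,
  ~1.6e-3 per 1e-3 s of step size under an oscillatory drive of amplitude
  2).
- Ties in elite selection break by original population order; the bearing
  branch at +/-pi is fixed to +pi; both-zero turning-rate samples count as
  "same sign" for the undulation penalty (a perfectly straight worm is not
  undulating).

## Synthetic conditions and what the tests show

All inputs are generated: there is no recorded behavioral data in the
package.  The bundled reference genome was produced by this package's own
constrained search (see `klinosim.presets` and the JSON metadata).  Scaled
study conditions used in the test suite are: a reduced search (population
30, elite 10, 40 generations, 10 trials, T_sim = 250 s) standing in for the
full 60/20/300/50 search, and 1,000-run behavioral ensembles standing in
for the 100,000-run ensembles; both preserve the qualitative quantities of
interest (fitness trajectory, slope signs) while the full settings remain
the defaults of `GAConfig` and `klinotaxis_ensemble` callers.  Passing
tests show the model reproduces the *mechanisms* (gradient-following by
normal-gradient sensing, penalty bookkeeping, plasticity-sweep behavior) on
this point-worm abstraction; they say nothing about body mechanics,
receptor biochemistry, the pirouette pathway, or quantitative agreement
with calcium imaging, all of which are outside the model.

## Known limitations

- The point-worm abstraction has no body, so "undulation" exists only as a
  heading oscillation and a fitness penalty; head-sweep sensing is implicit
  in the trajectory's sinuosity.
- One-sided 0.001 cm gradient probes carry an O(step) truncation bias from
  field curvature; analyses use them exactly as defined (they are the
  measurement protocol, not an estimate of the analytic gradient).
- Evolved circuits differ across runs; analyses of "the best model" depend
  on which individual ranks highest, and only sign-level behavioral claims
  are stable across high-CI individuals.  The bundled reference individual
  is the highest-Gaussian-CI run-best, among this package's searches, whose
  ASER->AIY weights are both inhibitory (the precondition of the plasticity
  sweep).  The search repeatedly finds two mirror-image solution families
  (inhibitory-OFF/excitatory-ON and the reverse) plus mixed ones.
- The effect of the ASER->AIY plasticity sweep depends strongly on the
  individual: in this package's evolved circuits the fully excitatory
  variant (#15) attenuates the curving-vs-normal-gradient response toward
  zero rather than reversing its sign.  A clean sign reversal requires an
  individual steered almost entirely by the OFF pathway with interneurons
  in the sigmoid's quasi-linear range (so a sign-flipped input mirrors the
  output); circuits that also use the ON pathway, or that operate in
  saturated, rectifying regimes, lose their gradient response under the
  sweep instead of inverting it.  Larger search ensembles make drawing a
  reversing top individual more likely.
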