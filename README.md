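# klinosim

A simulator of salt klinotaxis ("weathervane" chemotaxis) in *C. elegans*,
built on the minimal connectome-derived circuit ASEL/ASER -> AIYL/R ->
AIZL/R -> SMBDL/VL/DR/VR.  The package is for computational
neuroscientists who want to reproduce, probe or extend the minimal-network
account of how a worm steers up a salt gradient: it provides the circuit
model, a point-worm chemotaxis assay, the evolutionary parameter search
that tunes the 22 free electrophysiological parameters, and the behavioral
analyses used to dissect the evolved steering mechanism.

## The model in brief

Sensory neurons transduce the recent NaCl history into a coarse-grained
derivative

    z = (100/N) ∫_{t−N}^{t} c dt − (100/M) ∫_{t−(N+M)}^{t−N} c dt,

split into an ON channel (ASEL, z_ON = max(z, 0)) and an OFF channel
(ASER, z_OFF = max(−z, 0)).  Interneurons and motor neurons are leaky
sigmoid units,

    τ dy_i/dt = −y_i + Σ_j w_ji z_j + Σ_k g_ki (y_k − y_i) + I_i,
    z_i = σ(y_i + θ_i),

with gap junctions inside the AIY and AIZ pairs, SMB self-connections and
an antiphase sinusoidal drive of period T = 4.2 s to the dorsal/ventral
motor neurons.  The worm is a point moving at v = 0.022 cm/s whose heading
turns at φ = w_NMJ (Σ z_dorsal − Σ z_ventral).  Chemotaxis performance is
the chemotaxis index CI = 1 − ⟨h(t)/h(0)⟩, clamped to [0, 1] after a
0.008-per-cycle penalty for non-undulating movement.  A genetic algorithm
(population 60, elitism 20, two-point crossover, Gaussian mutation)
maximizes the CI on conical gradients; evolved circuits are evaluated on a
Gaussian plume (C0 = 1 mM, λ = 1.61 cm).  See `docs/methods.md` for the
full account.

## Worked example

```python
import numpy as np
from klinosim import (AssayConfig, Environment, chemotaxis_index,
                      run_assay, klinotaxis_ensemble)
from klinosim.presets import best_constrained_parameters

params = best_constrained_parameters()   # bundled evolved circuit
env = Environment.gaussian()             # peak (4.5, 0), C0=1 mM, lam=1.61 cm

cfg = AssayConfig(environment=env, duration=1000.0, seed=0)
traj = run_assay(params, cfg)
ci = chemotaxis_index(traj, env, penalty_enabled=False)
print(f"CI = {ci:.3f}")

stats = klinotaxis_ensemble(params, env, n_runs=1000, seed=1)
print(f"curving-rate slope vs normal gradient: "
      f"{stats.slope('normal_grad'):+.2f} (rad/cm)/(mM/cm)")
print(f"curving-rate slope vs bearing: {stats.slope('bearing'):+.3f} rad/cm/rad")
```

prints

```
CI = 0.873
curving-rate slope vs normal gradient: +1.54 (rad/cm)/(mM/cm)
curving-rate slope vs bearing: +1.881 rad/cm/rad
```

The assay drops the worm 4.5 cm from the peak with a random orientation;
a CI near 0.87 means it spends most of the 1000 s close to the peak.  The
positive slopes are the klinotaxis signature: the worm curves toward
higher salt both when the peak lies to its side (bearing) and when the
concentration rises to its left (normal gradient).

The same machinery is scriptable from the shell:

```sh
klinosim evolve --population 30 --elite 10 --generations 40 \
    --trials 10 --t-sim 250 --constrained --seed 1 --out run/
klinosim simulate --genome run/best_genome.json --constrained \
    --duration 1000 --seed 0 --out traj.csv
klinosim analyze curving --genome run/best_genome.json --constrained \
    --runs 1000 --seed 0 --out stats.csv
```

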