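# locustswarm

Marching locust nymphs show *density-dependent alignment*: confined to a
(quasi) one-dimensional arena, sparse groups move in a disordered way, while
dense groups align globally and march in a common direction, with occasional
sudden reversals that become rarer as density grows. `locustswarm` models
this with *learning agents* rather than pre-programmed particles: each
individual perceives the net flow of conspecifics around it, chooses to turn
or continue via a small two-layer projective-simulation memory, and is
rewarded whenever it ends up moving with the local majority. The package is
for behavioural ecologists and collective-motion modellers who want to study
how individual-level response rules — fixed or learned — generate the
group-level order parameter dynamics.

## Model

N agents sit on a ring of W discrete blocks and move one block per
time-step; agent i has heading σᵢ ∈ {−1, +1}. An agent perceives
s = clamp(n_same − n_opp, −2, +2), the net flow of the other agents within
sensory range r. Its memory is a 5 × 2 table of edge weights h(s, a) ≥ 1
over actions a ∈ {−1 (turn), +1 (continue)}, and it responds with

    P(a | s) = h(s, a) / Σ_a' h(s, a').

Agents act asynchronously in a fixed sequence; after its action an agent
receives R = 1 iff it moves with the strict majority of its neighbours, and
(in learning mode) updates

    h'(s, a) − 1 = (1 − γ)(h(s, a) − 1) + R · [(s, a) used],

with forgetting rate γ. The fixed-disposition (self-propelled-particle)
limit freezes h at h(±2, ±1) = 1 + d, h(±1, ±1) = 1 + d/2 (signs matched),
all else 1, with a single decisiveness parameter d.

The group order parameter z = (1/N) Σᵢ σᵢ evolves as a Markov chain on the
grid {(2m − N)/N}; the package estimates its one-sweep transition kernel
P(z′|z), the Fokker–Planck drift F(z) = E[Δz|z] and diffusion
D(z) = ½ Var[Δz|z] (per sweep), and the fixed points of F with their
stability. The control parameter is the effective density N/B, with
B = W/(2r) the number of non-overlapping neighbourhoods.

## Worked example

```python
import numpy as np
from locustswarm import (SimulationConfig, run_simulation, switching_statistics,
                         make_fixed_disposition, meanfield_drift_diffusion,
                         find_fixed_points)

rec = run_simulation(SimulationConfig(N=70, mode="fixed", d=30.0, steps=2000, seed=1))
s = switching_statistics(rec.z)
print(f"mean |z| = {s.mean_abs_z:.3f}, switches = {s.n_switches}, label = {s.label}")

policy = make_fixed_disposition(30.0)
for N in (10, 70):
    pts = find_fixed_points(meanfield_drift_diffusion(N, 8, policy))
    desc = ", ".join(f"z0={p.z0:+.3f} ({p.stability})" for p in pts)
    print(f"N={N}: {desc}")
```

prints

```
mean |z| = 0.937, switches = 0, label = ordered
N=10: z0=-0.000 (stable)
N=70: z0=-0.936 (stable), z0=+0.000 (unstable), z0=+0.936 (stable)
```

The dense swarm (N = 70, i.e. 8.75 agents per neighbourhood) aligns almost
completely and never reverses within 2000 sweeps, and its drift function is
bistable: the disordered state z = 0 is unstable and a symmetric pair of
attractors sits near |z| ≈ 0.94 — ordered marching in either direction. At
low density (N = 10) the only attractor is the disordered state z = 0.

The same machinery runs from the shell:

```sh
locustswarm simulate --preset fig2c --steps 2000 --seed 1 --out traj.csv
locustswarm fpe --method kernel -d 30 -N 70 -B 8 --samples 10000 \
    --out fd.csv --fixed-points-out fp.csv
locustswarm learncurves -N 40 --gamma 0.002 --steps 5000 --runs 4 --out lc.csv
```

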