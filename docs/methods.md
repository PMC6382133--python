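# Methods

## The agent model

Each agent is a two-layer projective-simulation learner. Its episodic
memory is a bipartite clip network: five percept clips s ∈ {−2, −1, 0, +1, +2}
(the net relative flow of conspecifics within sensory range, clipped at ±2)
connected to two action clips a ∈ {−1 turn, +1 continue}. Deliberation is a
single hop of a random walk over this network, with hopping probabilities
given by normalising the edge weights h(s, a) per percept row. Learning
combines reinforcement of the edge actually used with exponential
forgetting toward the neutral value 1:

    h'(s,a) − 1 = (1 − γ)(h(s,a) − 1) + R · [used].

Because rewards are non-negative and damping targets 1, h ≥ 1 is an
invariant; it is enforced at construction and covered by property tests.
The fixed-disposition limit replaces learning with a frozen one-parameter
family, h(+2,+1) = h(−2,−1) = 1 + d and h(+1,+1) = h(−1,−1) = 1 + d/2,
which reduces the agents to conventional self-propelled particles with
response strength d.

An optional inertia ι ≥ 0 sets h(0, +1) = 1 + ι so that an agent facing
zero net flow continues with probability above one half (turning costs
energy for a real animal). It is applied to the initial memory in both
modes; under forgetting it decays unless re-rewarded. It is off by default
and has no discernible effect on the collective phenomena studied here.

## The environment

The world is a ring of W discrete blocks; agents move one block per sweep,
may co-occupy blocks and pass through each other. The sensory window is
ring distance ≤ r on either side (co-located agents count, the focal agent
does not). W and r enter the collective dynamics through the effective
density N/B with B = W/(2r).

One sweep is strictly asynchronous: agents deliberate in a fixed index
order, so within a sweep each agent sees the *current* headings of its
neighbours, including flips already made earlier in the same sweep. The
reward is evaluated immediately after the agent's own action, against those
same neighbours. Two conventions the verbal model leaves open are settled
as follows, both switchable:

* **Tie / isolation rule.** "Majority" is read strictly: an exact tie or an
  empty neighbourhood earns R = 0 (`reward_ties=True` rewards ties).
  Rewarding isolated agents would reinforce arbitrary actions. A useful
  exact consequence: a percept s = 0 arises only from a tie (or isolation),
  and no action can break a tie, so the (0, ·) edges are never rewarded and
  the turn probability at zero net flow stays at exactly one half for
  learning agents — a property the tests assert.
* **Movement timing.** All agents advance one block after the N-th turn
  (`move="per_sweep"`, the default, tying displacement to the time-step);
  `move="per_turn"` moves each agent right after its own turn. The
  collective results reported here are insensitive to this switch.

Initial positions are i.i.d. uniform over blocks and headings i.i.d. ±1.
A single seeded NumPy generator drives the whole run in turn order, so a
configuration plus seed reproduces every output bit-for-bit. The vectorised
core advances many replicate swarms in lock-step from one stream; replicate
ensembles are therefore cheap and statistically independent.

## Drift and diffusion of the alignment parameter

The order parameter z = (1/N) Σ σᵢ lives on the grid {(2m − N)/N}. Its
one-sweep transition kernel P(z′|z) is estimated by Monte Carlo: for each
grid value, swarms are drawn *conditioned on z* (exactly N(1+z)/2 agents
heading +1, random assignment, uniform positions), one sweep is applied and
z′ histogrammed. Conditioning on uniform positions deliberately ignores the
position–heading correlations of the stationary state, matching the
mean-field spirit and making rows comparable; see "Known limitations".

Kramers–Moyal coefficients use the convention F(z) = E[z′ − z | z] and
D(z) = ½ E[(z′ − z − F)² | z] with Δt = one sweep (the central second
moment; the non-central variant differs by F²/2, negligible near fixed
points, and is available via `central=False`). Fixed points are located by
sign changes of F with linear interpolation between grid points — no
polynomial form is assumed — with stability from the local slope and a
low-confidence flag when |F| is indistinguishable from zero at two standard
errors across the neighbourhood.

The mean-field computation evaluates the same quantities in closed form by
treating each agent's turn against an independent background: neighbour
count k ~ Binomial(N−1, 1/B), neighbour headings i.i.d. +1 with probability
(1+z)/2, percept s = clamp(σ(2n₊ − k), −2, +2), flip probability
q(σ, z) = Σ_s P(s|σ,z) P(−1|s). All sums are exact. Two approximations are
involved: the binomial window probability 1/B (the exact uniform-position
value is (2r+1)/W, a ~10% difference that measurably *worsens* agreement
with the kernel, so 1/B is kept), and — dominant — the neglect of
within-sweep sequential feedback. For d ∈ {1, 5}, N ∈ {10, 40} the
resulting systematic drift deviation from the kernel is ≤ 0.1 in absolute
value (measured ≈ 0.03–0.07); the kernel is the model-exact reference
throughout, and this documented tolerance is what the tests assert.

For d = 0 every post-turn heading is uniform ±1 regardless of percepts, so
F(z) = −z and D(z) = 1/(2N) exactly; the mean-field reproduces these to
machine precision and the kernel within Monte-Carlo error — the main
numerical anchor of the estimation stack.

An empirical estimator bins one-step increments of long trajectories
(default minimum 10 samples per bin). Because real trajectories carry the
stationary position–heading correlations, the empirical drift differs
systematically from the uniform-position kernel away from d = 0; at
N = 40, d = 5 the deviation is ≈ 0.04 (asserted < 0.08). At low density
the effect is much larger (≈ 0.2 at N = 10, d = 5): sparse swarms condense
into co-moving clusters that the uniform-position picture cannot represent.

## Learning analyses

Learning curves report, per snapshot time, the mean and dispersion across
agents (and replicates) of the response probabilities for the tracked
pairs (s=+2, a=+1), (s=−2, a=−1) and (s=0, a=−1), computed per agent by row
normalisation and then averaged. Ensemble *policies* (used to feed the
kernel machinery with the behaviour developed by trained agents) average
h-values instead — h is the model's native state; probability averaging is
available as an option.

Two robust qualitative findings, both covered by tests:

* With forgetting (γ = 0.002, N = 40) the keep-direction probability
  P(+1|+2) rises to ≈ 0.9 within a few tens of sweeps (the test asserts the
  median time to 90% of the step-5000 value lies in [30, 500]) and
  saturates near 1, while the turn-around probability P(−1|−2) settles
  visibly lower. The asymmetry is a pure exposure effect: once the group
  aligns, opposing-flow percepts are rare, so reinforcement on the (−2,−1)
  edge cannot keep pace with forgetting.
* Without forgetting (γ = 0) rewarded h-values grow without bound and
  responses become deterministic. The same exposure effect governs the
  *rate*: at N = 10 the group-mean P(+1|+2) exceeds 0.999 within 10⁴
  sweeps, whereas the group-mean P(−1|−2) reaches only ≈ 0.90 there (≈ 0.92
  at 4 × 10⁴) and climbs roughly logarithmically, because s = −2 is
  encountered only during the brief disordered transient and through rare
  later dissenters. Both probabilities grow monotonically toward unity, but
  on very different timescales.

## Regime classification

Direction switches are counted with a two-threshold hysteresis rule: a
switch is registered when z moves from ≤ −θ to ≥ +θ or vice versa, default
θ = 0.3, so noise crossings near zero are ignored. Labels are declared
conventions: disordered if mean |z| < 0.3; ordered if mean |z| ≥ 0.6 and
the switch rate is below 1 per 1000 sweeps; intermediate otherwise. All
thresholds are configurable.

Simulated fixed-d = 30 swarms order more strongly than the uniform-position
kernel predicts: clusters of co-movers form at every density, and at N = 10
the trajectory spends most time at |z| > 0.6 while switching direction
every ~10² sweeps (telegraph-like dynamics), although the kernel stationary
distribution at the same parameters is broad with E|z| ≈ 0.43 and a single
stable drift zero at 0. Under the default thresholds such runs label
"intermediate" rather than "disordered". The monotone density trend is
unambiguous either way: switch rates fall steeply from N = 10 to 40 to 70.

## Problem sizes and numerical choices

Kernel estimates use 10⁴ conditioned samples per grid row for headline
numbers (standard error of F ≈ 0.003 per row) and 3–4 × 10³ in routine
tests; trajectory analyses use 2–15 × 10³ sweeps and ensembles of 3–10
replicates. Kernel row-stochasticity is enforced at 10⁻⁹; probability
normalisation at 10⁻¹²; the h ≥ 1 floor allows 10⁻⁹ slack for float drift.
Degenerate inputs: an identically zero drift is reported as a degenerate
fixed-point set; empty memory collections, off-grid conditioning values,
negative rewards and invalid mode/parameter combinations raise typed
errors.

## Known limitations

* The kernel/mean-field layer conditions on uniform positions; it is exact
  for the conditional one-sweep moments but its stationary implications
  ignore cluster formation, which strengthens order at low density (see
  above). Harvesting states from long runs (conditioning "from trajectory")
  would capture this and is a natural extension.
* The mean-field layer ignores within-sweep sequential feedback entirely;
  use it for structure (parity, fixed-point pattern, bifurcations), not for
  precise drift magnitudes at large d.
* One-dimensional rings only; no exclusion or collision handling; rewards
  are the binary majority-alignment scheme. Synthetic conditions emulate
  the laboratory ring-arena setting — discrete blocks, unit speed, fixed
  turn order — not free two-dimensional marching, individual speed
  variation, or sensory noise, so passing tests validate the model's
  internal consistency and its stated collective phenomenology, not
  agreement with field data.
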