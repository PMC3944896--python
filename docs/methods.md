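# Methods

`grnswarm` simulates the evolution of swarm-robot controllers in a grid-world
artificial-life environment.  Its core is a two-layer, bio-inspired
controller: a static *artificial genome* encoding a full gene regulatory
network (the "core GRN"), and a condition-dependent *agent layer* that
instantiates only the part of that network triggered by the robot's current
sensor input.  Two neural-network comparison controllers, gene-specific
adaptive mutation operators, a shared energy economy and a set of experiment
designs complete the framework.  This note records the model, its
assumptions, the main tunable parameters and the design choices made where
the design space was genuinely open.

## Artificial genome

A genome is 10 chromosomes of 10,000 digits over a base-4 alphabet.  Genes
are not placed; they are *found* wherever the promoter signature `0101`
occurs (first match wins, genes never overlap or span chromosome ends).  A
gene is

```
promoter (4) | type digit (1) | identity tag (3) | content (24)
```

The type digit modulo 3 selects signalling, regulatory or structural.  The
identity tag is the gene's address in regulatory space: a regulator's
content encodes a *target tag*, and every gene whose identity tag matches it
(Hamming distance ≤ `match_tolerance`, default 0 = exact) is a potential
target.  Content decodings:

* **signalling** — target tag, activation strength, three sensor selectors
  (2 digits each), three weights in [-1, 1], and a bias in [-2, 0].  The
  negative-only bias keeps genes off by default, so activation is sparse and
  sensor-contingent.
* **regulatory** — target tag, a parity digit selecting activate/repress,
  and a strength in (0, 1] decoded from six digits.
* **structural** — an actuator selector (2 digits, mod 7) and a signed
  output parameter in [-1, 1].  Negative parameters inhibit their actuator;
  this is deliberate, since without inhibitory contributions a random
  genome's action scores are always positive and the robot can never idle.

With these defaults a random genome carries ≈300 genes (≈Poisson along the
chromosomes; expected count scales linearly with genome length).

## Agent layer

Agents are the translation products of genes: per-gene concentrations with
ages.  One controller step:

1. every signalling gene's micro-network squashes its sensor subset through
   a logistic function (gain 4); values above `activation_threshold` (0.5)
   spawn its agent or boost a live one by the sensed value;
2. live agents drive their matched targets with `±strength × concentration`
   (repression subtracts); signalling drive is additionally gated by the
   *current* sensed value, so signals are transient rather than persistent;
   regulatory strength is spread over a rule's targets, signalling strength
   is not (transduction amplifies);
3. silent genes whose incoming drive reaches the activation threshold are
   translated at concentration `c0 + drive` (transcription amplitude grows
   with regulator activity), capped at `max_concentration` (3);
4. new translations compete for a per-step translation budget (6) —
   strongest drive first — and the pool is hard-capped at 200 agents (no
   eviction);
5. summed concentration is renormalised to a shared proteome budget (30),
   so weakly driven agents are competed out; agents below the deletion
   threshold (0.05) are removed;
6. each actuator outputs the mean concentration-scaled parameter of its
   live structural agents, divided by `max_concentration` onto the shared
   [-1, 1] actuator scale.  The movement pair reports the mean *magnitude*
   of its contributions with the sign of the net drive, so opposing
   movement genes express indecision in direction, not in urge.

Items 2, 3, 4 and 5 go beyond the one-line published description of the
agent layer; they were added because the bare accumulate-and-decay dynamics
saturate the 200-agent cap within ~50 steps on random genomes, which
destroys the condition dependence the architecture exists for.  With them,
typical pools settle at 40–100 live agents — inside the 30–100 band that
the adaptability value rewards.

Decay follows `c ← c·(1 − d·(1 − AV))` with `d = 0.1`.  The multiplicative
form keeps concentrations non-negative and makes lifetime monotone in the
adaptability value.

## Fitness and the adaptability value

Global fitness is the robot's energy divided by its capacity.  The global
AV combines fitness (weight 0.5), the normalised mean agent lifetime
(0.3; mean age / 50 steps, clamped) and a credit for the live-agent count
(0.2; full inside 30–100, linear ramps outside).  On top of the global AV,
each agent carries a *credit* term: an exponential moving average (rate
0.1) of `reward × activity`, where reward is the robot's energy change per
step scaled by 100 and clamped to [-1, 1], and activity is the agent's
concentration relative to the cap.  The per-agent AV is the global AV plus
`credit_gain` (2) times this credit, clamped to [0, 1].  This implements
"the added value of the agent's presence": agents whose activity coincides
with energy gains decay more slowly, agents active during losses fade — the
GRN's within-lifetime optimisation channel, mirrored by the comparison
ANN's per-edge learning.

Three switches ablate the feedback: `av_to_decay` (off → decay uses the
constant neutral AV 0.5 for every agent), `av_to_mutation` (off → the
expression-dependent mutation modifiers are frozen), and
`conditional_activation` (off → every gene is translated unconditionally
each step, up to the pool cap; the sensing gate disappears entirely).

## Adaptive mutation

At each reproduction the offspring genome passes once through the mutation
operator.  Intergenic characters substitute at `mu_intergenic` (2e-3),
coding characters at `mu_coding` (1e-3) further multiplied by 0.1 for
signalling genes and by `1/(1+expr)` for expressed genes; genes duplicate
with probability `dup_rate × (1+expr)` (6e-3 base), the copy overwriting a
random intergenic landing site so total genome size is invariant.
Expression here is the long-run moving average of the gene's agent
concentration, so the fitness coupling of the rates is carried entirely by
which genes were actually active — conserved when useful, preferentially
duplicated when expressed.  Every event is logged, and a child genome can
be reconstructed exactly from its parent by replaying the log.

## Comparison controllers

Both comparison controllers are single-hidden-layer tanh networks (8 hidden
units, biases included) over the same sensor/actuator interface as the GRN
controller, initialised uniformly in [-0.3, 0.3].  The small initialisation
is deliberate: at ±1 a random saturated network is born with a locked
policy and succeeds by luck; small weights keep newborn networks plastic so
that the evolutionary variant's advantage comes from its adaptation
mechanisms.  The *random* controller never updates anything within a
lifetime and, being non-evolvable, gives its offspring fresh random
networks — inheriting parental weights would let selection act on them.

The evolutionary ANN combines two time scales.  Within a lifetime, every
edge carries a private learning vector `v` and updates `w ← w + η·f·v`
(η = 0.05) where `f` is the robot's energy change per step scaled by 100
and clamped to [-1, 1]; after 10 consecutive negative-feedback steps all
learning vectors are re-drawn (random restart).  Across generations the
weight genome receives Gaussian noise (σ = 0.015) and, with probability
0.02, gains or loses a hidden node (layering, and hence acyclicity, is
preserved by construction).  σ was sized by measurement so that the
parent→offspring behavioural change (fraction of probe sensor states on
which parent and child choose different actions, ≈6%) matches the genome
operators' — the comparison is between encodings, not between unequal
mutation magnitudes.

## World and energy economy

A 45×45 toroidal grid (90×90 in the full-scale preset; hard walls are a
flag) with typed food sources.  Sensors: neighbour-robot count and per-type
food counts within Chebyshev radius 3 (normalised), two own-cell channels
(accessible food here / locked food here — access depends on pooled
energy, so the split is what a food-detecting sensor would report), and own
energy.  Seven functionalities: move (one signed actuator per axis;
dominant axis executes), eat, dock, undock, attack, reproduce, idle.  The
largest positive actuator output wins; ties and all-non-positive outputs
idle.  Gaussian arbitration jitter (0.1) and a 10% chance of a random move
direction model actuation noise; without them deterministic stateless
policies freeze into ≤45-cell orbits and the world is unexplorable.

Energy: capacity 1000, start 400; basic upkeep 0.5/step, move 0.5, eat 1,
dock/undock 2, attack 10 (transfers 25% of a co-located victim's energy),
aggregation upkeep 2/member/step for docked groups of ≥2.  Food types:
type 1 (200 energy, no minimum), type 2 (350, minimum 500), type 3 (800,
minimum 1500 — above a single robot's capacity, reachable only by docked
groups pooling energy; group harvests split equally).  Reproduction costs
350 and grants the offspring 300, either deliberately (energy ≥ 500 and
the reproduce functionality wins) or automatically at energy ≥ 800
(surplus conversion — robots with more energy produce more offspring).
Robots that cannot cover the basic upkeep die and are removed that step.

The world starts with 240 food sources (60/25/15% type mix) and adds only
6 per 50 steps (24 at full scale) — a trickle well below the population's
consumption, so the stock exhausts; whenever the population is below the
reset threshold (30 at desk scale, 100 at full scale; rate-limited to once
per 50 steps) the food field is restored to its initial layout.  This produces the boom–crash–
reset cycles that make the environment dynamically changing.  An exact
energy ledger (food credited, attack transfers, costs, dissipation at the
capacity clamp, reproduction conversion, energy removed with the dead) is
checked every step.

The update order within a step is fixed: sense/act for all robots in stable
id order → aggregation upkeep → controller feedback and agent decay →
deaths → reproduction placements → food replenishment → food reset → visit
counting.

## Experiments

* **compare** — one controller type per batch; world layouts share seeds
  across types.
* **compete** — GRN and evolutionary-ANN populations of equal initial size
  in one shared world (the reset threshold scales to half the doubled
  initial population).  Reported outcomes: the fraction of replicates in
  which the GRN population exceeds the ANN population over the second,
  resource-limited half of the run, and the fraction in which the ANN
  population's early growth slope (first 20% of steps) exceeds the GRN's.
* **memory** — one population; the initial food layout is re-imposed on a
  fixed schedule (on top of the below-threshold reset), and the
  energy-gain rate (mean 10-step gain of the population) is scored per
  reset segment.
* **ablation** — the GRN controller with all feedback switches on versus
  all off, scored by post-reset energy-gain rate.

Seeding: replicate `i` of seed base `S` draws its world layout from
`SeedSequence([S, i])` and its dynamics from `SeedSequence([S, i, arm])`,
so every run is bit-exact reproducible and arms share layouts.

## Problem sizes

Desk-scale experiments use a 45×45 world with 60 robots per controller
type and runs of 1,000–4,000 steps with 6–10 replicates; the full-scale
preset (90×90, threshold 100, 960 food sources) is provided for longer
studies.  The synthetic environment emulates the qualitative regime of a
foraging swarm under boom–crash resource cycles; it does not model
continuous kinematics, sensor noise spectra, or physical robot bodies, so
passing tests demonstrate properties of the evolutionary architecture, not
of any physical platform.

## Known limitations

* The agent layer's stabilising mechanisms (translation budget, proteome
  renormalisation) are this package's own design; other resolutions of the
  saturation problem would give quantitatively different dynamics.
* Directional population-level outcomes (who wins a competition and when)
  are emergent and sensitive to the shared economy; they are reported as
  measured fractions over seeded replicates, not guaranteed behaviours.
* Expression levels are concentration averages, so "selection pressure" on
  a gene is inferred from activity, not from a causal fitness attribution.
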