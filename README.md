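# grnswarm

Evolutionary swarm-robot simulation with a bio-inspired gene-regulatory-network
controller.

Robot controllers in evolutionary robotics usually couple their encoding
directly to the network that drives behaviour: every mutation changes the
controller, and every environmental change forces re-optimisation of the
whole network.  Biological cells work differently — the genome encodes the
*full* regulatory network, but only a condition-dependent part of it is ever
transcribed and translated.  `grnswarm` implements that uncoupling for
simulated foraging swarm robots and provides the apparatus to measure what
it buys: an artificial genome (digit-string chromosomes in which signalling,
regulatory and structural genes are found by a promoter signature), an agent
layer that instantiates only the sensor-triggered part of the encoded
network, gene-specific adaptive mutation and duplication operators, two
neural-network comparison controllers (a static random ANN and an
evolutionary ANN with per-edge learning), and a grid-world artificial-life
environment with typed food sources, energy accounting, aggregation,
attack, reproduction and food-reset dynamics.

The package is aimed at researchers in artificial life, evolutionary
robotics and systems-biology-inspired computing who want a reproducible,
desk-scale testbed for questions about evolvability, genotype–phenotype
uncoupling and memory in changing environments.

## Model in brief

A genome is 10 chromosomes of 10,000 base-4 digits.  A gene is
`promoter 0101 | type digit | tag | content`; regulators name their targets
by tag.  A gene becomes active only when translated into an *agent* with a
concentration `c` that decays as

```
c  <-  c * (1 - d * (1 - AV)),          d = 0.1
AV =  0.5 * F  +  0.3 * L  +  0.2 * C(n)
```

where `F` is the robot's energy fraction (global fitness), `L` the
normalised mean agent lifetime and `C(n)` a credit that is full while the
active network holds 30–100 agents.  High adaptability values let useful
agents persist; expression feeds back on the genome by lowering the
mutation rate of active genes (`mu * 1/(1+expr)`) and raising their
duplication odds (`delta * (1+expr)`).  Actuators average the
concentration-scaled parameters of the structural agents that target them;
the strongest actuator output selects one of seven functionalities (move,
eat, dock, undock, attack, reproduce, idle).  See `docs/methods.md` for the
complete specification.

## Worked example

Run a desk-scale world of 60 GRN-controlled robots for 1,000 steps:

```
$ grnswarm simulate --seed 1 --steps 1000 --controller grn \
      --population 60 --out simout
{"steps": 1000, "final_population": 29, "final_avg_energy": 264.9, "resets": 8}
```

The JSON line reports the surviving population, its average energy level
(total robot energy divided by population size) and how often the food
field was restored after a population crash — 8 boom/crash/reset cycles
here, the dynamically changing environment the framework is built around.
`simout/metrics.csv` holds the full per-step indicator series (population,
average energy, 10-step energy gain, food counts, attack and docking
events), `simout/snapshot.json` the final world state and
`simout/visits.txt` the per-cell visit-count matrix used for exploration
histograms.

Batch experiments follow the same pattern, e.g. a three-way controller
comparison or the competition experiment:

```
$ grnswarm experiment compare --controllers grn,evoann,randann \
      --replicates 10 --steps 3000 --seed-base 7 --out expout
$ grnswarm experiment compete --replicates 10 --steps 4000 --seed-base 1
```

Everything is also available as a library:

```python
import grnswarm as g

cfg = g.desk_scale()
genome = g.random_genome(1, cfg.genome)
genes = g.scan_genes(genome, cfg.genome)           # ~300 genes
ctrl = g.GRNController(genome, cfg.genome, cfg.controller, cfg.feedback)
```

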