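"""Simulation configuration.

All tunable constants of the simulator live here, grouped by subsystem, with
YAML round-tripping so whole experimental setups can be checked into a single
file.  Two presets are provided:

* :func:`desk_scale` (the default) — a 45x45 world with 60 robots per
  controller type and a population/reset threshold of 30, sized so that full
  experiments run on a single desktop CPU in minutes.
* :func:`paper_scale` — the 90x90 world with a reset threshold of 100 robots.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Tuple

import yaml

# Actuator indices shared by every controller type.  The first two form the
# movement pair (signed east/west and north/south drives); the remainder map
# one-to-one onto the discrete robot functionalities.
ACTUATOR_MOVE_X = 0
ACTUATOR_MOVE_Y = 1
ACTUATOR_EAT = 2
ACTUATOR_DOCK = 3
ACTUATOR_UNDOCK = 4
ACTUATOR_ATTACK = 5
ACTUATOR_REPRODUCE = 6
N_ACTUATORS = 7

#: Sensor layout: neighbour robot count, one neighbourhood food count per
#: type, food on the robot's own cell (split into an accessible and a
#: locked channel, since access depends on pooled energy), own energy.
N_FOOD_TYPES = 3
SENSOR_ROBOTS = 0
SENSOR_FOOD_BASE = 1            # indices 1..N_FOOD_TYPES
SENSOR_FOOD_HERE = 1 + N_FOOD_TYPES        # accessible food on own cell
SENSOR_FOOD_LOCKED = 2 + N_FOOD_TYPES      # present but not accessible
SENSOR_ENERGY = 3 + N_FOOD_TYPES
N_SENSORS = 4 + N_FOOD_TYPES


@dataclass
class GenomeConfig:
    """Artificial-genome syntax: alphabet, chromosome geometry and gene grammar.

    A gene is ``promoter + type digit + tag (tag_length digits) + content
    (content_length digits)``; genes never span chromosome boundaries.
    """

    alphabet_size: int = 4
    n_chromosomes: int = 10
    chromosome_length: int = 10_000
    promoter: str = "0101"
    tag_length: int = 3
    content_length: int = 24
    match_tolerance: int = 0
    n_sensors: int = N_SENSORS

    @property
    def gene_length(self) -> int:
        return len(self.promoter) + 1 + self.tag_length + self.content_length


@dataclass
class ControllerConfig:
    """Agent-layer dynamics of the GRN controller."""

    activation_threshold: float = 0.5   # sensed value / incoming drive gate
    deletion_threshold: float = 0.05    # agents below this concentration die
    decay_rate: float = 0.1             # default per-step decay d
    initial_concentration: float = 1.0  # concentration at translation (c0)
    max_concentration: float = 3.0      # cap on agent abundance; together
                                        # with strength spreading this keeps
                                        # typical pools in the 30-100 band
    agent_cap: int = 200                # hard cap on live agents per robot
    translation_budget: int = 6         # max new translations per step; the
                                        # strongest-driven candidates win
                                        # (limited translation machinery)
    total_concentration: float = 30.0   # shared proteome budget: summed
                                        # concentration is renormalised to
                                        # this ceiling, so weakly driven
                                        # agents are competed out
    sigmoid_gain: float = 4.0           # slope of the signalling squash
    n_micro_inputs: int = 3             # sensors read by one signalling gene
    expression_ema: float = 0.01        # smoothing of per-gene expression level


@dataclass
class FeedbackConfig:
    """Adaptability-value weights and the environment-feedback switches."""

    weight_fitness: float = 0.5
    weight_lifetime: float = 0.3
    weight_count: float = 0.2
    count_lo: int = 30
    count_hi: int = 100
    reference_lifetime: float = 50.0  # steps; normalises mean agent age
    neutral_av: float = 0.5           # AV used when decay feedback is off
    # per-agent credit: each agent's AV adds a term tracking how its own
    # activity correlates with the robot's recent energy gains ("the added
    # value of the agent's presence"), so useful agents outlive harmful ones
    credit_rate: float = 0.1          # EMA rate of the activity-gain tracker
    credit_gain: float = 2.0          # weight of the credit term in the AV
    credit_scale: float = 100.0       # energy units mapped to reward +/-1
    av_to_decay: bool = True
    av_to_mutation: bool = True
    conditional_activation: bool = True

    def __post_init__(self) -> None:
        total = self.weight_fitness + self.weight_lifetime + self.weight_count
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"AV weights must sum to 1, got {total}")


@dataclass
class MutationConfig:
    """Base rates of the gene-specific adaptive mutation model."""

    mu_intergenic: float = 2e-3   # per character per reproduction event
    mu_coding: float = 1e-3
    signalling_factor: float = 0.1  # extra conservation of signalling genes
    dup_rate: float = 6e-3          # per gene per reproduction event

    def __post_init__(self) -> None:
        if not self.mu_coding < self.mu_intergenic:
            raise ValueError("coding rate must be below the intergenic rate")
        if not 0 < self.signalling_factor < 1:
            raise ValueError("signalling_factor must lie in (0, 1)")


@dataclass
class AnnConfig:
    """Comparison ANN controllers (random and evolutionary)."""

    n_hidden: int = 8
    max_hidden: int = 16
    init_scale: float = 0.3   # uniform weight-init range; small weights keep
                              # newborn networks plastic rather than locked
                              # into a random saturated policy
    learning_rate: float = 0.05
    patience: int = 10            # steps of negative feedback before restart
    feedback_scale: float = 100.0  # energy units mapped to feedback +/-1
    weight_sigma: float = 0.015    # Gaussian mutation at reproduction;
                                   # sized so parent-offspring behavioural
                                   # change matches the genome operators'
    structure_prob: float = 0.02   # chance of a hidden-node add/remove event


@dataclass
class WorldConfig:
    """Grid world geometry, energy economy and food ecology."""

    height: int = 45
    width: int = 45
    torus: bool = True        # wrap-around grid; hard walls available
    max_per_cell: int = 5
    move_noise: float = 0.1   # chance a move goes to a random neighbour
                              # (actuation noise; keeps coverage ergodic)
    action_noise: float = 0.1  # Gaussian jitter on actuator outputs before
                               # arbitration; near-tied functionalities then
                               # alternate instead of freezing
    sense_radius: int = 3
    robot_norm: float = 8.0   # neighbour count mapped to sensor 1.0
    food_norm: float = 4.0    # food count per type mapped to sensor 1.0

    energy_capacity: float = 1000.0
    start_energy: float = 400.0
    offspring_energy: float = 300.0
    reproduce_cost: float = 350.0
    reproduce_threshold: float = 500.0
    # a nearly full robot reproduces even without choosing the reproduce
    # functionality (surplus energy is converted into offspring)
    auto_reproduce_threshold: float = 800.0

    basic_cost: float = 0.5
    move_cost: float = 0.5
    eat_cost: float = 1.0
    dock_cost: float = 2.0
    undock_cost: float = 2.0
    attack_cost: float = 10.0
    attack_fraction: float = 0.25
    aggregation_cost: float = 2.0  # per member per step while grouped

    # (energy content, minimal access energy) per food type 1..3; the type-3
    # access requirement deliberately exceeds a single robot's capacity.
    food_types: Tuple[Tuple[float, float], ...] = (
        (200.0, 0.0),
        (350.0, 500.0),
        (800.0, 1500.0),
    )
    food_type_probs: Tuple[float, ...] = (0.6, 0.25, 0.15)
    initial_food: int = 240
    replenish_interval: int = 50
    replenish_count: int = 6   # trickle only: the stock is meant to exhaust,
                               # producing boom/crash/reset cycles
    pop_reset_threshold: int = 30
    reset_cooldown: int = 50  # min steps between low-population food resets

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.food_types[2][1] <= self.energy_capacity:
            raise ValueError(
                "type-3 food must require more energy than one robot can hold"
            )


@dataclass
class SimConfig:
    """Top-level bundle of all subsystem configurations."""

    genome: GenomeConfig = field(default_factory=GenomeConfig)
    controller: ControllerConfig = field(default_factory=ControllerConfig)
    feedback: FeedbackConfig = field(default_factory=FeedbackConfig)
    mutation: MutationConfig = field(default_factory=MutationConfig)
    ann: AnnConfig = field(default_factory=AnnConfig)
    world: WorldConfig = field(default_factory=WorldConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            sub = data.get(f.name, {})
            sub_cls = f.default_factory  # type: ignore[misc]
            if isinstance(sub, dict):
                # tuples arrive as lists from YAML
                base = sub_cls()
                coerced = {}
                for k, v in sub.items():
                    if isinstance(getattr(base, k, None), tuple) and isinstance(v, list):
                        v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
                    coerced[k] = v
                kwargs[f.name] = type(base)(**coerced)
            else:
                kwargs[f.name] = sub
        return cls(**kwargs)

    def save_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def replace(self, **section_updates) -> "SimConfig":
        """Return a copy with whole sections or section fields replaced.

        ``cfg.replace(world={"height": 30})`` updates a single field.
        """
        new = {}
        for f in dataclasses.fields(self):
            cur = getattr(self, f.name)
            upd = section_updates.get(f.name)
            if upd is None:
                new[f.name] = dataclasses.replace(cur)
            elif isinstance(upd, dict):
                new[f.name] = dataclasses.replace(cur, **upd)
            else:
                new[f.name] = upd
        return SimConfig(**new)


def desk_scale() -> SimConfig:
    """Default desk-scale setup (45x45 grid, reset threshold 30)."""
    return SimConfig()


def paper_scale() -> SimConfig:
    """Full-scale setup: 90x90 grid, 300 food sources, reset threshold 100."""
    cfg = SimConfig()
    return cfg.replace(
        world={
            "height": 90,
            "width": 90,
            "initial_food": 960,       # same areal density as desk scale
            "replenish_count": 24,
            "pop_reset_threshold": 100,
        }
    )
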