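"""Comparison controllers: a static random ANN and an evolutionary ANN.

Both are single-hidden-layer feed-forward networks (tanh units) over the
same sensor/actuator interface as the GRN controller, so either can drive
the world loop unchanged.

* The **random ANN** is initialised once and never changes within a
  lifetime; it is non-evolvable, so offspring receive fresh random networks
  rather than inheriting parental weights.
* The **evolutionary ANN** combines two time scales, mirroring the GRN's
  genome/agent split: within a lifetime, distributed per-edge learning
  nudges every weight along its private learning vector in proportion to
  the robot's performance feedback (the normalised energy change of the
  last step), re-drawing the vectors after a sustained run of negative
  feedback; across generations, the flat weight genome is perturbed with
  Gaussian noise and occasionally gains or loses a hidden node.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
import numpy as np

from .config import AnnConfig, N_ACTUATORS, N_SENSORS


@dataclass
class AnnGenome:
    """Flat weight encoding of a layered feed-forward network.

    ``w1`` has shape (n_hidden, n_sensors + 1) and ``w2`` shape
    (n_outputs, n_hidden + 1); the last column of each holds the biases.
    The layered layout keeps the network acyclic by construction.
    """

    w1: np.ndarray
    w2: np.ndarray

    @property
    def n_hidden(self) -> int:
        return self.w1.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.w1.shape[1] - 1

    @property
    def n_outputs(self) -> int:
        return self.w2.shape[0]

    @property
    def n_edges(self) -> int:
        return self.w1.size + self.w2.size

    def copy(self) -> "AnnGenome":
        return AnnGenome(self.w1.copy(), self.w2.copy())

    def to_json(self) -> str:
        return json.dumps({"w1": self.w1.tolist(), "w2": self.w2.tolist()})

    @classmethod
    def from_json(cls, s: str) -> "AnnGenome":
        d = json.loads(s)
        return cls(np.asarray(d["w1"]), np.asarray(d["w2"]))


def random_ann(rng, config: AnnConfig,
               n_sensors: int = N_SENSORS, n_outputs: int = N_ACTUATORS) -> AnnGenome:
    """All weights and biases drawn uniformly from ``[-init_scale, init_scale]``."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    a = config.init_scale
    w1 = rng.uniform(-a, a, size=(config.n_hidden, n_sensors + 1))
    w2 = rng.uniform(-a, a, size=(n_outputs, config.n_hidden + 1))
    return AnnGenome(w1, w2)


def forward(ann: AnnGenome, sensors: np.ndarray) -> np.ndarray:
    """Deterministic feed-forward pass with tanh squashing."""
    sensors = np.asarray(sensors, dtype=float)
    if sensors.shape != (ann.n_sensors,):
        raise ValueError(
            f"expected {ann.n_sensors} sensor values, got shape {sensors.shape}"
        )
    h = np.tanh(ann.w1[:, :-1] @ sensors + ann.w1[:, -1])
    return np.tanh(ann.w2[:, :-1] @ h + ann.w2[:, -1])


def mutate_ann_genome(ann: AnnGenome, config: AnnConfig,
                      rng: np.random.Generator) -> AnnGenome:
    """Gaussian weight perturbation plus rare hidden-node add/remove."""
    child = ann.copy()
    if config.weight_sigma > 0:
        child.w1 += rng.normal(0.0, config.weight_sigma, size=child.w1.shape)
        child.w2 += rng.normal(0.0, config.weight_sigma, size=child.w2.shape)
    if config.structure_prob > 0 and rng.random() < config.structure_prob:
        if rng.random() < 0.5 and child.n_hidden < config.max_hidden:
            new_in = rng.uniform(-1, 1, size=(1, child.w1.shape[1]))
            new_out = rng.uniform(-1, 1, size=(child.w2.shape[0], 1))
            child.w1 = np.vstack([child.w1, new_in])
            child.w2 = np.hstack([child.w2[:, :-1], new_out, child.w2[:, -1:]])
        elif child.n_hidden > 1:
            k = int(rng.integers(child.n_hidden))
            child.w1 = np.delete(child.w1, k, axis=0)
            child.w2 = np.delete(child.w2, k, axis=1)
    return child


class AnnController:
    """Runtime wrapper giving the ANN the same interface as the GRN controller.

    ``learning=False`` yields the static random controller; ``learning=True``
    the evolutionary controller with distributed edge learning.
    """

    def __init__(self, genome: AnnGenome, config: AnnConfig,
                 rng: np.random.Generator, learning: bool):
        self.ann = genome
        self.cfg = config
        self.learning = learning
        self.kind = "evoann" if learning else "randann"
        self._v1 = rng.uniform(-1, 1, size=genome.w1.shape) if learning else None
        self._v2 = rng.uniform(-1, 1, size=genome.w2.shape) if learning else None
        self._neg_streak = 0

    def step(self, sensors: np.ndarray) -> np.ndarray:
        return forward(self.ann, sensors)

    def edge_learning_step(self, feedback: float, rng: np.random.Generator) -> None:
        """Per-edge update ``w += eta * f * v`` with random restarts.

        ``feedback`` is the robot's energy change over the last step divided
        by ``feedback_scale``, clipped to [-1, 1].  Every edge drifts along
        its private learning vector in proportion to the feedback; after
        ``patience`` consecutive negative-feedback steps every edge re-draws
        its learning vector (a per-edge random restart) and the streak
        resets.
        """
        if not self.learning:
            return
        f = float(np.clip(feedback, -1.0, 1.0))
        if f != 0.0:
            eta = self.cfg.learning_rate
            self.ann.w1 += eta * f * self._v1
            self.ann.w2 += eta * f * self._v2
        if f < 0.0:
            self._neg_streak += 1
            if self._neg_streak >= self.cfg.patience:
                self._v1 = rng.uniform(-1, 1, size=self.ann.w1.shape)
                self._v2 = rng.uniform(-1, 1, size=self.ann.w2.shape)
                self._neg_streak = 0
        else:
            self._neg_streak = 0

    def end_step(self, delta_energy: float, rng: np.random.Generator) -> None:
        self.edge_learning_step(delta_energy / self.cfg.feedback_scale, rng)

    def spawn_offspring(self, rng: np.random.Generator) -> "AnnController":
        if self.learning:
            child = mutate_ann_genome(self.ann, self.cfg, rng)
        else:
            # the random controller is non-evolvable: offspring receive a
            # fresh random network (inheriting the parent's weights would
            # let selection act on the weights, i.e. evolve them)
            child = random_ann(rng, self.cfg,
                               n_sensors=self.ann.n_sensors,
                               n_outputs=self.ann.n_outputs)
        return AnnController(child, self.cfg, rng, self.learning)
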