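"""Condition-dependent agent layer of the GRN controller.

Genes located in the artificial genome are static until *translated* into
agents.  An agent carries a concentration (its abundance), an age and the
decoded rule of its source gene.  The step cycle is:

1. every signalling gene's embedded micro-network squashes its sensor subset
   into a "sensed value"; values above the activation threshold spawn (or
   boost) the corresponding signalling agent;
2. all live signalling/regulatory agents drive their matched targets
   (activation adds ``strength x source concentration`` to the target's
   concentration, repression subtracts); targets that were silent and receive
   enough drive are translated at the initial concentration ``c0``;
3. concentrations decay as ``c <- c * (1 - d * (1 - AV))`` where ``AV`` is
   the robot's adaptability value; agents below the deletion threshold die;
4. each actuator averages the concentration-scaled output parameters of the
   live structural agents that target it.

Propagation uses the concentrations as they stand after the signalling
spawns, so activation travels one network hop per step (a signalling gene
can bring up a direct target within the same step).

The pool is hard-capped: when full, new translations are refused (no
eviction).  For speed the pool is stored as dense per-gene vectors; the
:class:`Agent` objects exposed by :meth:`AgentPool.agents` are views for
inspection and logging.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import scipy.sparse as sp
from numba import njit

from .config import (
    ACTUATOR_MOVE_X,
    ACTUATOR_MOVE_Y,
    ControllerConfig,
    FeedbackConfig,
    GenomeConfig,
    N_ACTUATORS,
)
from .feedback import compute_av, decay_av, global_fitness, normalised_lifetime
from .genome import (
    GeneAnnotation,
    Genome,
    RegulatoryRule,
    SignallingSpec,
    StructuralRule,
    decode_content,
    match_targets,
    scan_genes,
)

_TYPE_CODE = {"signalling": 0, "regulatory": 1, "structural": 2}


class CompiledNetwork:
    """Static, per-genome tables the agent layer consumes.

    Built once per genome (at robot birth): annotations, decoded rules, the
    sparse interaction matrix and the signalling / structural lookup arrays.
    """

    def __init__(self, genome: Genome, config: GenomeConfig,
                 annotations: Optional[List[GeneAnnotation]] = None):
        self.genome = genome
        self.config = config
        self.annotations = scan_genes(genome, config) if annotations is None else annotations
        n = len(self.annotations)
        self.n_genes = n
        self.rules = [decode_content(g, config) for g in self.annotations]
        self.gene_types = np.array(
            [_TYPE_CODE[g.gene_type] for g in self.annotations], dtype=np.int8
        )

        # exact-tag index makes target lookup O(1) per rule (the general
        # Hamming-tolerant path goes through match_targets)
        by_tag: dict = {}
        if config.match_tolerance == 0:
            for g in self.annotations:
                by_tag.setdefault(g.tag, []).append(g.gene_id)

        rows, cols, vals = [], [], []
        for g, rule in zip(self.annotations, self.rules):
            if isinstance(rule, StructuralRule):
                continue
            sign = 1.0
            if isinstance(rule, RegulatoryRule) and rule.mode == "repress":
                sign = -1.0
            if config.match_tolerance == 0:
                targets = by_tag.get(rule.tag, [])
            else:
                targets = match_targets(rule, self.annotations, config)
            # a regulator's strength is spread over its matched targets, so
            # promiscuous regulators do not flood the network; signalling
            # inputs are not spread (signal transduction amplifies)
            spread = 1.0 if g.gene_type == "signalling" else float(len(targets))
            for t in targets:
                rows.append(t)
                cols.append(g.gene_id)
                vals.append(sign * rule.strength / spread)
        self.interactions = sp.csr_matrix(
            (vals, (rows, cols)), shape=(n, n), dtype=np.float64
        )

        sig = [i for i in range(n) if self.gene_types[i] == 0]
        self.sig_idx = np.array(sig, dtype=np.intp)
        n_sensors = config.n_sensors
        self.sig_weights = np.zeros((len(sig), n_sensors))
        self.sig_bias = np.zeros(len(sig))
        for k, i in enumerate(sig):
            spec: SignallingSpec = self.rules[i]  # type: ignore[assignment]
            for s_idx, w in zip(spec.sensor_indices, spec.weights):
                self.sig_weights[k, s_idx] += w
            self.sig_bias[k] = spec.bias

        struct = [i for i in range(n) if self.gene_types[i] == 2]
        self.struct_idx = np.array(struct, dtype=np.intp)
        self.struct_actuator = np.array(
            [self.rules[i].actuator for i in struct], dtype=np.intp
        )
        self.struct_param = np.array(
            [self.rules[i].parameter for i in struct], dtype=np.float64
        )


@dataclass(frozen=True)
class Agent:
    """Inspection view of one live agent."""

    agent_id: int
    gene_id: int
    agent_type: str
    concentration: float
    adaptability_value: float
    age: int


class AgentPool:
    """Live agents of one robot, stored as dense per-gene vectors."""

    def __init__(self, network: CompiledNetwork, config: ControllerConfig):
        self.network = network
        self.config = config
        n = network.n_genes
        self.concentration = np.zeros(n)
        self.age = np.zeros(n, dtype=np.int64)
        self.expression = np.zeros(n)
        self.credit = np.zeros(n)   # activity-gain correlation per gene
        self.last_av = 0.0

    @property
    def live_mask(self) -> np.ndarray:
        return self.concentration > 0.0

    @property
    def n_live(self) -> int:
        return int(np.count_nonzero(self.concentration))

    @property
    def mean_age(self) -> float:
        live = self.live_mask
        if not live.any():
            return 0.0
        return float(self.age[live].mean())

    def agents(self) -> List[Agent]:
        names = ("signalling", "regulatory", "structural")
        out = []
        for i in np.nonzero(self.live_mask)[0]:
            out.append(
                Agent(
                    agent_id=int(i),
                    gene_id=int(i),
                    agent_type=names[self.network.gene_types[i]],
                    concentration=float(self.concentration[i]),
                    adaptability_value=self.last_av,
                    age=int(self.age[i]),
                )
            )
        return out



@njit(cache=True)
def _select_spawns(cand_idx, cand_drive, k, room):
    """Indices of the top ``room`` candidates by drive (ties: lower gene id).

    Partial selection sort; candidate counts are small (budget-limited).
    """
    m = min(room, k)
    chosen = np.empty(m, np.int64)
    used = np.zeros(k, np.bool_)
    for slot in range(m):
        best = -1
        for j in range(k):
            if used[j]:
                continue
            if best < 0:
                best = j
            elif (cand_drive[j] > cand_drive[best]
                  or (cand_drive[j] == cand_drive[best]
                      and cand_idx[j] < cand_idx[best])):
                best = j
        used[best] = True
        chosen[slot] = best
    return chosen


@njit(cache=True)
def _step_kernel(indptr, indices, data, conc, age, sig_idx, sensed,
                 th_act, budget, cap, c0, cmax, c_total, th_del):
    """Fused activation pass over one agent pool (see sense_and_translate)."""
    n = conc.size
    n_live = 0
    for i in range(n):
        if conc[i] > 0.0:
            n_live += 1

    # signalling gate: boost live agents, collect spawn candidates
    m = sig_idx.size
    cand_idx = np.empty(m, np.int64)
    cand_drive = np.empty(m, np.float64)
    k = 0
    for j in range(m):
        if sensed[j] > th_act:
            gi = sig_idx[j]
            if conc[gi] > 0.0:
                conc[gi] += sensed[j]
            else:
                cand_idx[k] = gi
                cand_drive[k] = sensed[j]
                k += 1
    room = budget if budget < cap - n_live else cap - n_live
    if room > 0 and k > 0:
        chosen = _select_spawns(cand_idx, cand_drive, k, room)
        for c in chosen:
            gi = cand_idx[c]
            v = c0 + cand_drive[c]
            conc[gi] = v if v < cmax else cmax
            age[gi] = 0
            n_live += 1
            budget -= 1

    # propagation source: live concentrations, signalling gated by the
    # current sensed value (transient signal transduction)
    src = np.zeros(n)
    live = np.zeros(n, np.bool_)
    for i in range(n):
        if conc[i] > 0.0:
            src[i] = conc[i]
            live[i] = True
    for j in range(m):
        gi = sig_idx[j]
        if src[gi] > 0.0:
            src[gi] = src[gi] * sensed[j] if sensed[j] > th_act else 0.0

    delta = np.zeros(n)
    for t in range(n):
        acc = 0.0
        for p in range(indptr[t], indptr[t + 1]):
            acc += data[p] * src[indices[p]]
        delta[t] = acc

    for i in range(n):
        if live[i]:
            conc[i] += delta[i]
    # cascade spawn candidates (dead genes with enough incoming drive)
    k = 0
    cand2_idx = np.empty(n, np.int64)
    cand2_drive = np.empty(n, np.float64)
    for i in range(n):
        if (not live[i]) and delta[i] >= th_act:
            cand2_idx[k] = i
            cand2_drive[k] = delta[i]
            k += 1
    room = budget if budget < cap - n_live else cap - n_live
    if room > 0 and k > 0:
        chosen = _select_spawns(cand2_idx, cand2_drive, k, room)
        for c in chosen:
            gi = cand2_idx[c]
            v = c0 + cand2_drive[c]
            conc[gi] = v if v < cmax else cmax
            age[gi] = 0

    # clip, shared-proteome renormalisation, deletion threshold
    total = 0.0
    for i in range(n):
        if conc[i] < 0.0:
            conc[i] = 0.0
        elif conc[i] > cmax:
            conc[i] = cmax
        total += conc[i]
    if total > c_total:
        f = c_total / total
        for i in range(n):
            conc[i] *= f
    for i in range(n):
        if conc[i] < th_del:
            conc[i] = 0.0


def sense_and_translate(pool: AgentPool, sensors: np.ndarray,
                        config: ControllerConfig) -> None:
    """One activation pass: signalling gate, propagation, translation.

    New translations compete for the per-step translation budget; the
    candidates with the strongest drive (sensed value for signalling genes,
    incoming regulatory drive for cascade targets) are translated first.
    Signalling spawns are applied before propagation, so a freshly sensed
    signal reaches its direct targets within the same step.  Afterwards
    concentrations are clipped, renormalised against the shared proteome
    budget (weakly driven agents are competed out) and agents below the
    deletion threshold are removed.
    """
    net = pool.network
    if net.sig_idx.size:
        z = net.sig_weights @ sensors + net.sig_bias
        sensed = 1.0 / (1.0 + np.exp(-config.sigmoid_gain * z))
    else:
        sensed = np.empty(0)
    A = net.interactions
    _step_kernel(A.indptr, A.indices, A.data, pool.concentration, pool.age,
                 net.sig_idx, sensed,
                 config.activation_threshold, config.translation_budget,
                 config.agent_cap, config.initial_concentration,
                 config.max_concentration, config.total_concentration,
                 config.deletion_threshold)


def translate_all(pool: AgentPool) -> None:
    """Ablated activation: every gene is translated unconditionally.

    Used when the conditional-activation feedback switch is off.  Genes are
    re-topped to c0 each step (in gene-id order up to the pool cap), so the
    active network is the whole genome regardless of the sensors.
    """
    c0 = pool.config.initial_concentration
    cap = pool.config.agent_cap
    n = min(cap, pool.network.n_genes)
    pool.concentration[:n] = np.maximum(pool.concentration[:n], c0)


@njit(cache=True)
def _decay_kernel(conc, age, expr, av, d, th_del, alpha):
    for i in range(conc.size):
        f = 1.0 - d * (1.0 - av[i])
        c = conc[i] * f
        if c < th_del:
            c = 0.0
        else:
            age[i] += 1
        conc[i] = c
        expr[i] += alpha * (c - expr[i])


@njit(cache=True)
def _pool_stats(conc, age):
    """Live-agent count and age sum (pre-decay, for the AV inputs)."""
    n_live = 0
    age_sum = 0.0
    for i in range(conc.size):
        if conc[i] > 0.0:
            n_live += 1
            age_sum += age[i]
    return n_live, age_sum


@njit(cache=True)
def _feedback_kernel(conc, age, expr, credit, reward, credit_rate,
                     credit_gain, av_global, use_credit, d, th_del, alpha,
                     cmax):
    """Per-agent credit update + AV-modulated decay, fused."""
    for i in range(conc.size):
        activity = conc[i] / cmax
        credit[i] += credit_rate * (reward * activity - credit[i])
        if use_credit:
            av = av_global + credit_gain * credit[i]
            if av < 0.0:
                av = 0.0
            elif av > 1.0:
                av = 1.0
        else:
            av = av_global
        c = conc[i] * (1.0 - d * (1.0 - av))
        if c < th_del:
            c = 0.0
        else:
            age[i] += 1
        conc[i] = c
        expr[i] += alpha * (c - expr[i])


def decay_step(pool: AgentPool, config: ControllerConfig, av) -> None:
    """Apply the AV-modulated decay law, delete faded agents, age the rest.

    ``av`` is each agent's current adaptability value: a scalar (shared by
    all agents) or one value per gene.
    """
    av_arr = np.broadcast_to(np.asarray(av, dtype=float),
                             pool.concentration.shape).copy()
    _decay_kernel(pool.concentration, pool.age, pool.expression, av_arr,
                  config.decay_rate, config.deletion_threshold,
                  config.expression_ema)
    pool.last_av = float(np.mean(av_arr))


@njit(cache=True)
def _actuator_kernel(struct_idx, struct_act, struct_param, conc, n_act):
    sums = np.zeros(n_act)
    mags = np.zeros(n_act)
    counts = np.zeros(n_act)
    for j in range(struct_idx.size):
        c = conc[struct_idx[j]]
        if c > 0.0:
            a = struct_act[j]
            v = struct_param[j] * c
            sums[a] += v
            mags[a] += abs(v)
            counts[a] += 1.0
    out = np.zeros(n_act)
    for a in range(n_act):
        if counts[a] > 0.0:
            out[a] = sums[a] / counts[a]
    # movement pair: mean magnitude with the sign of the net drive, so
    # opposing drives signal indecision in direction but not in urge
    for a in (ACTUATOR_MOVE_X, ACTUATOR_MOVE_Y):
        if counts[a] > 0.0 and sums[a] != 0.0:
            sgn = 1.0 if sums[a] > 0.0 else -1.0
            out[a] = sgn * mags[a] / counts[a]
    return out


def actuator_outputs(pool: AgentPool) -> np.ndarray:
    """Per-actuator mean of concentration-scaled structural parameters.

    Movement actuators carry signed drives; opposing structural agents
    would cancel in a plain mean, so the movement output is the mean
    *magnitude* of its contributions carrying the sign of the net drive
    (the strength of the drive and its direction are read separately).
    """
    net = pool.network
    if net.struct_idx.size == 0:
        return np.zeros(N_ACTUATORS)
    return _actuator_kernel(net.struct_idx, net.struct_actuator,
                            net.struct_param, pool.concentration, N_ACTUATORS)


class GRNController:
    """The full two-layer controller of one robot.

    Owns the compiled network and the agent pool; the world calls
    :meth:`step` with the current sensor vector and :meth:`end_step` with the
    robot's fitness after it has acted.
    """

    kind = "grn"

    def __init__(self, genome: Genome, genome_cfg: GenomeConfig,
                 controller_cfg: ControllerConfig, feedback_cfg: FeedbackConfig):
        self.network = CompiledNetwork(genome, genome_cfg)
        self.genome_cfg = genome_cfg
        self.cfg = controller_cfg
        self.fb = feedback_cfg
        self.pool = AgentPool(self.network, controller_cfg)
        self._prev_energy: Optional[float] = None

    @property
    def genome(self) -> Genome:
        return self.network.genome

    def step(self, sensors: np.ndarray) -> np.ndarray:
        if self.fb.conditional_activation:
            sense_and_translate(self.pool, sensors, self.cfg)
        else:
            translate_all(self.pool)
        # scale onto the shared [-1, 1] actuator range used by every
        # controller type; linear scaling preserves the separation between
        # strongly and weakly driven actuators
        return actuator_outputs(self.pool) / self.cfg.max_concentration

    def end_step(self, energy: float, capacity: float) -> float:
        """Recompute the adaptability values and apply the decay phase.

        The global AV (fitness, mean lifetime, agent-count credit) is shared
        by all agents; on top of it each agent carries a credit term that
        tracks how its own activity has correlated with the robot's energy
        gains, so agents whose presence pays for itself persist longer.
        """
        pool = self.pool
        n_live, age_sum = _pool_stats(pool.concentration, pool.age)
        F = global_fitness(energy, capacity)
        L = normalised_lifetime(age_sum / n_live if n_live else 0.0, self.fb)
        av = compute_av(F, L, n_live, self.fb)

        delta = 0.0 if self._prev_energy is None else energy - self._prev_energy
        self._prev_energy = energy
        reward = min(max(delta / self.fb.credit_scale, -1.0), 1.0)
        _feedback_kernel(
            pool.concentration, pool.age, pool.expression, pool.credit,
            reward, self.fb.credit_rate, self.fb.credit_gain,
            av if self.fb.av_to_decay else decay_av(av, self.fb),
            self.fb.av_to_decay, self.cfg.decay_rate,
            self.cfg.deletion_threshold, self.cfg.expression_ema,
            self.cfg.max_concentration,
        )
        pool.last_av = av
        return av

    def mutation_expression(self) -> np.ndarray:
        from .feedback import mutation_expression

        return mutation_expression(self.pool.expression, self.fb)

    def dump_state(self, step: int, robot_id: int) -> List[str]:
        """JSON-lines records of the live agents (optional diagnostics)."""
        lines = []
        for a in self.pool.agents():
            lines.append(json.dumps({
                "step": step, "robot_id": robot_id, "agent_id": a.agent_id,
                "gene_id": a.gene_id, "type": a.agent_type,
                "concentration": round(a.concentration, 6),
                "AV": round(a.adaptability_value, 6),
            }))
        return lines
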