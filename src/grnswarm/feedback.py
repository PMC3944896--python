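"""Fitness and the adaptability value (AV).

A robot's global fitness is its energy level relative to capacity.  The AV
folds that fitness back into the controller: it is a weighted combination of

* global fitness (50%),
* the normalised mean lifetime of the live agents (30%), and
* a credit for the number of active agents, full inside the 30-100 band (20%).

A high AV slows agent decay (longer-lived network parts) and, through the
expression levels it sustains, lowers the mutation rate of the corresponding
genes.  The three feedback switches reproduce the ablated controllers:
``av_to_decay`` and ``av_to_mutation`` remove the local feedback channels,
``conditional_activation`` removes the sensing gate entirely (all genes are
translated unconditionally every step).
"""

from __future__ import annotations

import numpy as np

from .config import FeedbackConfig


def global_fitness(energy: float, capacity: float) -> float:
    """Robot energy as a fraction of capacity, clamped to [0, 1]."""
    if capacity <= 0:
        raise ValueError("capacity must be positive")
    return min(max(energy / capacity, 0.0), 1.0)


def count_credit(n: int, config: FeedbackConfig) -> float:
    """Credit for the active-agent count.

    1.0 inside [count_lo, count_hi]; linear ramps outside: n/count_lo below
    the band and max(0, 1 - (n - count_hi)/count_hi) above it.
    """
    if n < 0:
        raise ValueError("agent count must be non-negative")
    lo, hi = config.count_lo, config.count_hi
    if n < lo:
        return n / lo
    if n <= hi:
        return 1.0
    return max(0.0, 1.0 - (n - hi) / hi)


def compute_av(F: float, L: float, n: int, config: FeedbackConfig) -> float:
    """Adaptability value 0.5*F + 0.3*L + 0.2*count_credit(n).

    ``F`` is the global fitness and ``L`` the normalised mean agent lifetime;
    both must already lie in [0, 1].
    """
    if not (0.0 <= F <= 1.0 and 0.0 <= L <= 1.0):
        raise ValueError("fitness and lifetime must lie in [0, 1]")
    av = (
        config.weight_fitness * F
        + config.weight_lifetime * L
        + config.weight_count * count_credit(n, config)
    )
    return float(av)


def normalised_lifetime(mean_age: float, config: FeedbackConfig) -> float:
    """Mean agent age scaled by the reference lifetime, clamped to [0, 1]."""
    return min(max(mean_age / config.reference_lifetime, 0.0), 1.0)


def decay_av(av: float, config: FeedbackConfig) -> float:
    """AV actually used by the decay law (constant when the switch is off)."""
    return av if config.av_to_decay else config.neutral_av


def mutation_expression(expression: np.ndarray, config: FeedbackConfig) -> np.ndarray:
    """Expression levels as seen by the mutation operators.

    With ``av_to_mutation`` off the expression-dependent modifiers are frozen
    at their neutral value (equivalent to all-zero expression levels).
    """
    if config.av_to_mutation:
        return expression
    return np.zeros_like(expression)


def apply_feedback(av: float, expression: np.ndarray,
                   config: FeedbackConfig) -> tuple:
    """Route the environment feedback through the ablation switches.

    Returns ``(decay AV, mutation expression levels, conditional)``: the AV
    the decay law should use (constant when ``av_to_decay`` is off), the
    expression levels the mutation operators should see (frozen when
    ``av_to_mutation`` is off) and whether translation remains gated on
    sensing (``conditional_activation``).
    """
    return (
        decay_av(av, config),
        mutation_expression(expression, config),
        config.conditional_activation,
    )
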