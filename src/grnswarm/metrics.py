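"""Population-level adaptability indicators and summaries.

The per-step indicators follow the assessment used throughout the
experiments: population size, average energy level (total robot energy
divided by population size; missing when the population is empty), the
average energy gain accumulated over a sliding 10-step window, the number
of food sources and of untouched food sources, and the per-step attack and
docking event counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .world import StepRecord


@dataclass
class MetricsSeries:
    """Column-oriented per-step indicator series for one simulation run."""

    step: np.ndarray
    population: np.ndarray
    avg_energy: np.ndarray        # NaN where the population is empty
    avg_gain: np.ndarray          # mean per-robot energy gain of each step
    gain10: np.ndarray            # avg_gain summed over the last `window` steps
    food_count: np.ndarray
    untouched_food: np.ndarray
    attacks: np.ndarray
    docks: np.ndarray
    births: np.ndarray
    deaths: np.ndarray
    resets: np.ndarray            # bool: food reset fired this step
    pop_by_kind: Dict[str, np.ndarray]
    window: int = 10

    def __len__(self) -> int:
        return len(self.step)

    @classmethod
    def from_records(cls, records: Sequence[StepRecord],
                     window: int = 10) -> "MetricsSeries":
        kinds = sorted({k for r in records for k in r.pop_by_kind})
        avg_gain = np.array([r.avg_gain for r in records])
        gain10 = np.convolve(avg_gain, np.ones(window), mode="full")[: len(avg_gain)]
        return cls(
            step=np.array([r.step for r in records]),
            population=np.array([r.population for r in records]),
            avg_energy=np.array([r.avg_energy for r in records]),
            avg_gain=avg_gain,
            gain10=gain10,
            food_count=np.array([r.food_count for r in records]),
            untouched_food=np.array([r.untouched_food for r in records]),
            attacks=np.array([r.attacks for r in records]),
            docks=np.array([r.docks for r in records]),
            births=np.array([r.births for r in records]),
            deaths=np.array([r.deaths for r in records]),
            resets=np.array([r.reset for r in records], dtype=bool),
            pop_by_kind={
                k: np.array([r.pop_by_kind.get(k, 0) for r in records])
                for k in kinds
            },
            window=window,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "step": self.step,
            "population": self.population,
            "avg_energy": self.avg_energy,
            "avg_gain": self.avg_gain,
            "gain10": self.gain10,
            "food_count": self.food_count,
            "untouched_food": self.untouched_food,
            "attacks": self.attacks,
            "docks": self.docks,
            "births": self.births,
            "deaths": self.deaths,
            "reset": self.resets,
        })
        for k, v in self.pop_by_kind.items():
            df[f"pop_{k}"] = v
        return df

    def reset_segments(self) -> List[tuple]:
        """Half-open step-index segments delimited by food resets.

        Segment boundaries are the steps at which a reset fired; the stretch
        before the first reset is segment 0.
        """
        bounds = [0] + list(np.nonzero(self.resets)[0] + 1) + [len(self)]
        return [(a, b) for a, b in zip(bounds[:-1], bounds[1:]) if b > a]


def energy_gain_rate(series: MetricsSeries, segment: tuple,
                     window: int = 10) -> float:
    """Mean 10-step energy gain of the population over one reset segment.

    Windows are required to lie fully inside the segment, so the segment
    must span at least ``2 * window`` steps.
    """
    a, b = segment
    if not (0 <= a < b <= len(series)):
        raise ValueError(f"segment {segment} outside the series")
    if b - a < 2 * window:
        raise ValueError(f"segment {segment} shorter than two windows")
    # windows touching a step with no surviving robots are missing (NaN):
    # an extinct population has no gain rate rather than a rate of zero
    sums = np.convolve(series.avg_gain, np.ones(window),
                       mode="full")[: len(series)]
    vals = sums[a + window: b]
    if np.all(np.isnan(vals)):
        return float("nan")
    return float(np.nanmean(vals))


def visit_histogram(visit_matrices: Sequence[np.ndarray]) -> Dict[int, int]:
    """Pool per-cell cumulative visit counts over replicates and bin exactly.

    Returns ``{visit count: number of cells}`` with total count equal to
    cells x replicates.
    """
    shapes = {m.shape for m in visit_matrices}
    if len(shapes) > 1:
        raise ValueError("visit matrices must share one shape")
    pooled = np.concatenate([np.asarray(m).ravel() for m in visit_matrices])
    counts = np.bincount(pooled)
    return {int(v): int(n) for v, n in enumerate(counts) if n > 0}


def summarize_boxplot(batch: Sequence[MetricsSeries],
                      step_grid: Sequence[int]) -> pd.DataFrame:
    """Five-number summary of average energy across replicates per grid step."""
    if not batch:
        raise ValueError("need at least one replicate")
    rows = []
    for s in step_grid:
        idx = s - 1  # series are 1-indexed by step
        vals = np.array([rep.avg_energy[idx] for rep in batch])
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            rows.append((s, *([np.nan] * 5)))
            continue
        rows.append((
            s,
            float(vals.min()),
            float(np.percentile(vals, 25)),
            float(np.median(vals)),
            float(np.percentile(vals, 75)),
            float(vals.max()),
        ))
    return pd.DataFrame(
        rows, columns=["step", "min", "q1", "median", "q3", "max"]
    )
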