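"""Adaptive mutation operators on the artificial genome.

Two mutational events act at reproduction: per-character substitutions and
whole-gene duplications.  Rates are gene specific:

* intergenic characters mutate at the base rate ``mu_intergenic``;
* coding characters mutate at ``mu_coding`` (lower), further reduced for
  signalling genes (factor ``signalling_factor``) and for highly expressed
  genes via ``e(expr) = 1 / (1 + expr)`` — expressed genes are treated as
  under selection and conserved;
* a gene duplicates with probability ``dup_rate * (1 + expr)`` — expressed
  genes are preferentially duplicated.  The copy overwrites a random
  intergenic landing site on a random chromosome, keeping the total genome
  size constant.

Inheritance is asexual: an offspring genome is the parent genome passed once
through :func:`mutate`.  Every event is logged so a child genome can be
reconstructed exactly from its parent (replay equality).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from .config import MutationConfig
from .genome import GeneAnnotation, Genome


def default_expression_modifier(expr: float) -> float:
    """e(expr) = 1/(1+expr): non-increasing, in (0, 1]."""
    return 1.0 / (1.0 + expr)


def default_duplication_preference(expr: float) -> float:
    """p(expr) = 1 + expr: non-decreasing, >= 1."""
    return 1.0 + expr


@dataclass
class MutationProfile:
    """Gene-specific rate model (see module docstring for the semantics)."""

    mu_intergenic: float = 2e-3
    mu_coding: float = 1e-3
    signalling_factor: float = 0.1
    dup_rate: float = 6e-3
    expression_modifier: Callable[[float], float] = default_expression_modifier
    duplication_preference: Callable[[float], float] = default_duplication_preference

    def __post_init__(self) -> None:
        if self.mu_intergenic > 0 and not self.mu_coding < self.mu_intergenic:
            raise ValueError("mu_coding must be below mu_intergenic")
        if not 0 <= self.signalling_factor <= 1:
            raise ValueError("signalling_factor must lie in [0, 1]")

    @classmethod
    def from_config(cls, cfg: MutationConfig) -> "MutationProfile":
        return cls(
            mu_intergenic=cfg.mu_intergenic,
            mu_coding=cfg.mu_coding,
            signalling_factor=cfg.signalling_factor,
            dup_rate=cfg.dup_rate,
        )

    @classmethod
    def zero(cls) -> "MutationProfile":
        return cls(mu_intergenic=0.0, mu_coding=0.0, dup_rate=0.0)


@dataclass(frozen=True)
class MutationEvent:
    kind: str            # "substitution" | "duplication"
    chromosome: int
    position: int
    length: int
    detail: tuple        # sub: (old, new); dup: (src_chrom, src_start, copied digits)


@dataclass
class MutationEventLog:
    events: List[MutationEvent] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.events)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("kind\tchromosome\tposition\tlength\tdetail\n")
            for e in self.events:
                fh.write(f"{e.kind}\t{e.chromosome}\t{e.position}\t{e.length}\t"
                         f"{';'.join(map(str, e.detail))}\n")


def rate_matrix(genome: Genome, annotations: Sequence[GeneAnnotation],
                profile: MutationProfile,
                expression: Optional[np.ndarray] = None) -> List[np.ndarray]:
    """Per-character substitution rates, one array per chromosome."""
    rates = [np.full(c.size, profile.mu_intergenic) for c in genome.chromosomes]
    for g in annotations:
        expr = float(expression[g.gene_id]) if expression is not None else 0.0
        r = profile.mu_coding * profile.expression_modifier(expr)
        if g.gene_type == "signalling":
            r *= profile.signalling_factor
        rates[g.chromosome][g.start:g.end] = r
    return rates


def effective_rate(position: Tuple[int, int], genome: Genome,
                   annotations: Sequence[GeneAnnotation],
                   profile: MutationProfile,
                   expression: Optional[np.ndarray] = None) -> float:
    """Substitution probability of one character ``(chromosome, offset)``."""
    ci, pos = position
    if not (0 <= ci < genome.n_chromosomes):
        raise IndexError(f"chromosome {ci} out of range")
    if not (0 <= pos < genome.chromosomes[ci].size):
        raise IndexError(f"position {pos} out of range on chromosome {ci}")
    for g in annotations:
        if g.chromosome == ci and g.start <= pos < g.end:
            expr = float(expression[g.gene_id]) if expression is not None else 0.0
            r = profile.mu_coding * profile.expression_modifier(expr)
            if g.gene_type == "signalling":
                r *= profile.signalling_factor
            return r
    return profile.mu_intergenic


def _intergenic_mask(genome: Genome,
                     annotations: Sequence[GeneAnnotation]) -> List[np.ndarray]:
    masks = [np.ones(c.size, dtype=bool) for c in genome.chromosomes]
    for g in annotations:
        masks[g.chromosome][g.start:g.end] = False
    return masks


def mutate(genome: Genome, annotations: Sequence[GeneAnnotation],
           profile: MutationProfile, rng: np.random.Generator,
           expression: Optional[np.ndarray] = None,
           ) -> Tuple[Genome, MutationEventLog]:
    """Apply substitutions then duplications; return the child and the log."""
    B = genome.alphabet_size
    child = genome.copy()
    log = MutationEventLog()

    if profile.mu_intergenic > 0 or profile.mu_coding > 0:
        rates = rate_matrix(genome, annotations, profile, expression)
        for ci, chrom in enumerate(child.chromosomes):
            hits = np.nonzero(rng.random(chrom.size) < rates[ci])[0]
            if B <= 1:
                continue  # no alternative symbol exists
            for pos in hits:
                old = int(chrom[pos])
                new = (old + 1 + int(rng.integers(B - 1))) % B
                chrom[pos] = new
                log.events.append(
                    MutationEvent("substitution", ci, int(pos), 1, (old, new))
                )

    if profile.dup_rate > 0 and annotations:
        masks = _intergenic_mask(genome, annotations)
        for g in annotations:
            expr = float(expression[g.gene_id]) if expression is not None else 0.0
            p = profile.dup_rate * profile.duplication_preference(expr)
            if rng.random() >= p:
                continue
            span = child.chromosomes[g.chromosome][g.start:g.end].copy()
            glen = span.size
            placed = False
            for _ in range(20):
                ci = int(rng.integers(genome.n_chromosomes))
                chrom = child.chromosomes[ci]
                if chrom.size < glen:
                    continue
                pos = int(rng.integers(chrom.size - glen + 1))
                if masks[ci][pos]:
                    chrom[pos:pos + glen] = span
                    copied = "".join(str(int(d)) for d in span)
                    log.events.append(
                        MutationEvent("duplication", ci, pos, glen,
                                      (g.chromosome, g.start, copied))
                    )
                    placed = True
                    break
            if not placed:
                continue
    return child, log


def replay(parent: Genome, log: MutationEventLog) -> Genome:
    """Reconstruct a child genome by replaying the event log on the parent."""
    child = parent.copy()
    for e in log.events:
        chrom = child.chromosomes[e.chromosome]
        if e.kind == "substitution":
            old, new = e.detail
            assert int(chrom[e.position]) == old
            chrom[e.position] = new
        elif e.kind == "duplication":
            copied = e.detail[2]
            span = np.frombuffer(copied.encode(), dtype=np.uint8) - ord("0")
            chrom[e.position:e.position + e.length] = span
        else:  # pragma: no cover
            raise ValueError(f"unknown event kind {e.kind}")
    return child


def inherit(parent: Genome, annotations: Sequence[GeneAnnotation],
            profile: MutationProfile, rng: np.random.Generator,
            expression: Optional[np.ndarray] = None) -> Genome:
    """Asexual inheritance: the parent genome passed once through mutate()."""
    child, _ = mutate(parent, annotations, profile, rng, expression)
    return child
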