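"""Artificial genome: digit-string chromosomes and the gene grammar.

The genome is a fixed-size collection of chromosomes, each a string of digits
over a small alphabet (base 4 by default).  Genes are not placed explicitly:
they are *found* wherever the promoter signature occurs, mimicking how open
reading frames are located on real genomes.  A gene consists of

``promoter | type digit | tag | content``

where the type digit selects one of three gene classes (signalling,
regulatory, structural), the tag is the gene's identity label used for
regulator-target matching, and the content region carries the class-specific
payload:

* signalling — a target tag plus an embedded micro-network (sensor subset,
  weights and a bias) that converts raw robot sensor readings into a single
  "sensed value";
* regulatory — a target tag, an activate/repress mode digit and an
  interaction strength;
* structural — an actuator selector and an output parameter.

Everything here is static decoding; the condition-dependent life of genes
(translation into agents, concentration dynamics) lives in
:mod:`grnswarm.controller`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Union

import numpy as np
import pandas as pd

from .config import GenomeConfig, N_ACTUATORS

GENE_TYPES = ("signalling", "regulatory", "structural")


@dataclass
class Genome:
    """Ordered digit-string chromosomes stored as uint8 arrays."""

    chromosomes: List[np.ndarray]
    alphabet_size: int = 4

    def __post_init__(self) -> None:
        self.chromosomes = [np.asarray(c, dtype=np.uint8) for c in self.chromosomes]
        for c in self.chromosomes:
            if c.size and int(c.max()) >= self.alphabet_size:
                raise ValueError("chromosome contains symbols outside the alphabet")

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(int(c.size) for c in self.chromosomes)

    def as_strings(self) -> List[str]:
        return ["".join(str(int(d)) for d in c) for c in self.chromosomes]

    @classmethod
    def from_strings(cls, strings: Sequence[str], alphabet_size: int = 4) -> "Genome":
        chroms = [np.frombuffer(s.encode(), dtype=np.uint8) - ord("0") for s in strings]
        return cls([c.copy() for c in chroms], alphabet_size)

    def copy(self) -> "Genome":
        return Genome([c.copy() for c in self.chromosomes], self.alphabet_size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genome):
            return NotImplemented
        return self.alphabet_size == other.alphabet_size and all(
            np.array_equal(a, b) for a, b in zip(self.chromosomes, other.chromosomes)
        ) and len(self.chromosomes) == len(other.chromosomes)


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene located on a chromosome (0-based half-open coordinates)."""

    gene_id: int
    chromosome: int
    start: int
    end: int
    gene_type: str
    tag: str
    content: str
    expression_level: float = 1.0


@dataclass(frozen=True)
class RegulatoryRule:
    source_gene_id: int
    tag: str            # target-matching tag
    mode: str           # "activate" | "repress"
    strength: float     # in (0, 1]


@dataclass(frozen=True)
class StructuralRule:
    source_gene_id: int
    actuator: int
    parameter: float    # already mapped onto the actuator's range


@dataclass(frozen=True)
class SignallingSpec:
    source_gene_id: int
    tag: str                      # target-matching tag
    strength: float               # activation strength in (0, 1]
    sensor_indices: tuple         # which sensors the micro-network reads
    weights: tuple                # one weight in [-1, 1] per sensor index
    bias: float                   # in [-2, 0]; keeps genes off by default


Rule = Union[RegulatoryRule, StructuralRule, SignallingSpec]


def _digits_value(digits: str, base: int) -> int:
    v = 0
    for d in digits:
        v = v * base + int(d)
    return v


def _digits_unit(digits: str, base: int) -> float:
    """Map a digit string onto [0, 1] (0 for empty / single-symbol alphabets)."""
    top = base ** len(digits) - 1
    if top == 0:
        return 0.0
    return _digits_value(digits, base) / top


def random_genome(seed, config: GenomeConfig) -> Genome:
    """Draw a uniformly random genome.

    ``seed`` may be an integer or a ``numpy.random.Generator``.
    """
    if config.alphabet_size < 1:
        raise ValueError("alphabet size must be >= 1")
    if config.n_chromosomes <= 0 or config.chromosome_length <= 0:
        raise ValueError("chromosome count and length must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chroms = [
        rng.integers(0, config.alphabet_size, size=config.chromosome_length, dtype=np.uint8)
        for _ in range(config.n_chromosomes)
    ]
    return Genome(chroms, config.alphabet_size)


def _promoter_hits(chrom: np.ndarray, promoter: np.ndarray) -> np.ndarray:
    """Sorted start indices of every promoter occurrence on a chromosome."""
    n, m = chrom.size, promoter.size
    if m == 0 or n < m:
        return np.empty(0, dtype=np.intp)
    match = chrom[: n - m + 1] == promoter[0]
    for k in range(1, m):
        match &= chrom[k: n - m + 1 + k] == promoter[k]
    return np.nonzero(match)[0]


def scan_genes(genome: Genome, config: GenomeConfig) -> List[GeneAnnotation]:
    """Locate all genes with a deterministic left-to-right scan.

    First match wins: after emitting a gene the scan resumes at the gene's
    end, so emitted genes never overlap.  Genes truncated by the chromosome
    end are discarded.  Gene ids number the genes in (chromosome, start)
    order and are stable for an unmutated genome.
    """
    promoter = np.frombuffer(config.promoter.encode(), dtype=np.uint8) - ord("0")
    glen = config.gene_length
    plen = len(config.promoter)
    annotations: List[GeneAnnotation] = []
    gene_id = 0
    for ci, chrom in enumerate(genome.chromosomes):
        pos = 0
        for hit in _promoter_hits(chrom, promoter):
            if hit < pos:
                continue  # overlaps the previously emitted gene
            if hit + glen > chrom.size:
                # truncated gene: discard
                continue
            body = chrom[hit + plen: hit + glen]
            type_digit = int(body[0])
            ascii_body = (body + ord("0")).tobytes().decode("ascii")
            tag = ascii_body[1: 1 + config.tag_length]
            content = ascii_body[1 + config.tag_length:]
            annotations.append(
                GeneAnnotation(
                    gene_id=gene_id,
                    chromosome=ci,
                    start=hit,
                    end=hit + glen,
                    gene_type=GENE_TYPES[type_digit % 3],
                    tag=tag,
                    content=content,
                )
            )
            gene_id += 1
            pos = hit + glen
    return annotations


def decode_content(gene: GeneAnnotation, config: GenomeConfig) -> Rule:
    """Decode a gene's content region into its class-specific rule.

    Pure and deterministic; raises if the content region is shorter than the
    configured length (which would indicate a scanning bug).
    """
    B = config.alphabet_size
    T = config.tag_length
    content = gene.content
    if len(content) < config.content_length:
        raise ValueError(
            f"gene {gene.gene_id}: content region of length {len(content)} "
            f"< configured {config.content_length}"
        )
    if gene.gene_type == "regulatory":
        tag = content[:T]
        mode = "activate" if int(content[T]) % 2 == 0 else "repress"
        strength = (_digits_value(content[T + 1: T + 7], B) + 1) / B ** 6
        return RegulatoryRule(gene.gene_id, tag, mode, strength)
    if gene.gene_type == "structural":
        actuator = _digits_value(content[:2], B) % N_ACTUATORS
        unit = _digits_unit(content[2:8], B)
        # all parameters are signed: negative contributions inhibit the
        # actuator, so an actuator's net output can fall to or below zero
        parameter = unit * 2.0 - 1.0
        return StructuralRule(gene.gene_id, actuator, parameter)
    # signalling
    tag = content[:T]
    strength = (int(content[T]) + 1) / B if B > 1 else 1.0
    idx_digits = content[T + 1: T + 7]
    sensor_indices = tuple(
        _digits_value(idx_digits[2 * i: 2 * i + 2], B) % config.n_sensors
        for i in range(3)
    )
    w_digits = content[T + 7: T + 13]
    weights = tuple(
        _digits_unit(w_digits[2 * i: 2 * i + 2], B) * 2.0 - 1.0 for i in range(3)
    )
    bias = -2.0 * _digits_unit(content[T + 13: T + 15], B)
    return SignallingSpec(gene.gene_id, tag, strength, sensor_indices, weights, bias)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def match_targets(
    rule: Union[RegulatoryRule, SignallingSpec],
    genes: Sequence[GeneAnnotation],
    config: GenomeConfig,
) -> List[int]:
    """Gene ids whose identity tag matches the rule's target tag.

    A gene is a potential target iff the Hamming distance between its tag and
    the rule's tag is at most ``config.match_tolerance`` (0 = exact match).
    Self-targeting (autoregulation) is allowed.
    """
    tol = config.match_tolerance
    return [g.gene_id for g in genes if _hamming(rule.tag, g.tag) <= tol]


# ---------------------------------------------------------------------------
# serialisation

def save_genome(genome: Genome, path) -> None:
    """Plain-text serialisation: one chromosome of digits per line."""
    with open(path, "w") as fh:
        for line in genome.as_strings():
            fh.write(line + "\n")


def load_genome(path, alphabet_size: int = 4) -> Genome:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    return Genome.from_strings(lines, alphabet_size)


def annotations_to_bed(annotations: Sequence[GeneAnnotation]) -> pd.DataFrame:
    """Gene table in BED-like form (0-based half-open coordinates)."""
    return pd.DataFrame(
        {
            "chrom": [f"chr{a.chromosome}" for a in annotations],
            "start": [a.start for a in annotations],
            "end": [a.end for a in annotations],
            "gene_id": [a.gene_id for a in annotations],
            "gene_type": [a.gene_type for a in annotations],
        }
    )
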