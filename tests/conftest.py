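"""Shared fixtures: configurations and hand-built genomes."""

from __future__ import annotations

import numpy as np
import pytest

from grnswarm.config import SimConfig, desk_scale
from grnswarm.genome import Genome


@pytest.fixture
def cfg() -> SimConfig:
    return desk_scale()


@pytest.fixture
def tiny_world_cfg() -> SimConfig:
    """A 12x12 world for fast world-loop tests."""
    return desk_scale().replace(
        world={"height": 12, "width": 12, "initial_food": 8,
               "replenish_count": 1, "pop_reset_threshold": 2}
    )


def make_gene(gene_type_digit: str, tag: str, content: str,
              promoter: str = "0101") -> str:
    """Assemble one gene as a digit string (promoter+type+tag+content)."""
    assert len(tag) == 3 and len(content) == 24
    return promoter + gene_type_digit + tag + content


def sig_gene(tag: str, target_tag: str, sensor_pair: str = "10",
             weight_pair: str = "33", bias_pair: str = "00",
             strength_digit: str = "3") -> str:
    """Signalling gene whose three micro-net inputs all read one sensor.

    ``sensor_pair`` is the 2-digit base-4 selector (value mod n_sensors);
    ``weight_pair`` "33" decodes to weight +1, ``bias_pair`` "00" to bias 0.
    """
    content = (target_tag + strength_digit + sensor_pair * 3
               + weight_pair * 3 + bias_pair + "000000")
    return make_gene("0", tag, content)


def reg_gene(tag: str, target_tag: str, mode_digit: str = "0",
             strength_digits: str = "333333") -> str:
    """Regulatory gene; mode digit even = activate, odd = repress."""
    content = (target_tag + mode_digit + strength_digits + "0" * 14)
    return make_gene("1", tag, content)


def struct_gene(tag: str, actuator_pair: str, param_digits: str = "333333") -> str:
    """Structural gene; actuator = 2-digit base-4 value mod 7."""
    content = actuator_pair + param_digits + "0" * 16
    return make_gene("2", tag, content)


def genome_from_genes(genes, n_chromosomes: int = 10,
                      length: int = 10_000, gap: int = 100) -> Genome:
    """Embed genes (in order) in a zero-filled first chromosome."""
    parts = []
    for g in genes:
        parts.append("0" * gap)
        parts.append(g)
    chrom0 = "".join(parts).ljust(length, "0")
    assert len(chrom0) == length
    return Genome.from_strings([chrom0] + ["0" * length] * (n_chromosomes - 1))


@pytest.fixture
def three_gene_chain() -> Genome:
    """sig(A->B) -> reg(B->C, activate) -> struct(C, eat actuator).

    The signalling gene reads the own-cell-food sensor (index 4 of 7,
    selector pair "10"), weights +1 each and bias 0; the regulatory gene
    activates with maximal strength; the structural gene drives the eat
    actuator (pair "02") with maximal parameter.
    """
    return genome_from_genes([
        sig_gene(tag="000", target_tag="111"),
        reg_gene(tag="111", target_tag="222"),
        struct_gene(tag="222", actuator_pair="02"),
    ])


@pytest.fixture
def two_gene_pair() -> Genome:
    """sig(A->B) directly wired to struct(B): minimal reflex arc."""
    return genome_from_genes([
        sig_gene(tag="000", target_tag="111"),
        struct_gene(tag="111", actuator_pair="02"),
    ])
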