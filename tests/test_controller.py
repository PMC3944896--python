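"""Agent layer: translation, propagation, decay, actuator averaging.

The hand-computed oracles below apply the documented update laws step by
step with plain Python arithmetic, independent of the vectorised
implementation.
"""

import math

import numpy as np
import pytest

from grnswarm.config import ControllerConfig, FeedbackConfig, desk_scale
from grnswarm.controller import (
    AgentPool,
    CompiledNetwork,
    GRNController,
    actuator_outputs,
    decay_step,
    sense_and_translate,
    translate_all,
)
from grnswarm.genome import scan_genes

from conftest import genome_from_genes, reg_gene, sig_gene, struct_gene


def sigmoid(x):
    return 1.0 / (1.0 + math.exp(-x))


@pytest.fixture
def ctl_cfg():
    return desk_scale().controller


@pytest.fixture
def fb_cfg():
    return desk_scale().feedback


def make_controller(genome, cfg=None, fb=None):
    base = desk_scale()
    return GRNController(genome, base.genome, cfg or base.controller,
                         fb or base.feedback)


def food_sensors(on_food: bool, energy_frac: float = 0.4) -> np.ndarray:
    s = np.zeros(7)
    s[4] = 1.0 if on_food else 0.0
    s[6] = energy_frac
    return s


class TestThreeGeneChainOracle:
    """sig -> reg -> struct: two controller steps against a hand oracle."""

    def test_two_steps_match_hand_computation(self, three_gene_chain, ctl_cfg):
        ctrl = make_controller(three_gene_chain)
        net = ctrl.network
        assert [a.gene_type for a in net.annotations] == [
            "signalling", "regulatory", "structural"]
        energy, cap = 400.0, 1000.0

        # ---- hand oracle, step 1
        s = sigmoid(ctl_cfg.sigmoid_gain * 3.0)   # three +1 weights on sensor 4
        c_sig = min(1.0 + s, ctl_cfg.max_concentration)
        drive_reg = 1.0 * c_sig * s               # strength 1, gated by sensed
        assert drive_reg >= ctl_cfg.activation_threshold
        c_reg = min(1.0 + drive_reg, ctl_cfg.max_concentration)
        # struct receives nothing: reg was not live during propagation
        av1 = 0.5 * (energy / cap) + 0.3 * 0.0 + 0.2 * (2 / 30)
        f1 = 1.0 - ctl_cfg.decay_rate * (1.0 - av1)
        exp1 = {0: c_sig * f1, 1: c_reg * f1, 2: 0.0}

        out1 = ctrl.step(food_sensors(True))
        ctrl.end_step(energy, cap)
        assert np.allclose(out1, 0.0)
        for gid, val in exp1.items():
            assert ctrl.pool.concentration[gid] == pytest.approx(val, rel=1e-12)

        # ---- hand oracle, step 2
        c_sig2 = exp1[0] + s                       # boost of the live agent
        src_sig = c_sig2 * s
        c_reg2 = exp1[1] + 1.0 * src_sig           # activation of live target
        c_reg2 = min(c_reg2, ctl_cfg.max_concentration)
        drive_struct = 1.0 * exp1[1]               # reg was live, ungated
        assert drive_struct >= ctl_cfg.activation_threshold
        c_struct = min(1.0 + drive_struct, ctl_cfg.max_concentration)
        out_expected = 1.0 * c_struct / ctl_cfg.max_concentration  # param 1.0

        out2 = ctrl.step(food_sensors(True))
        assert out2[2] == pytest.approx(out_expected, rel=1e-12)
        assert ctrl.pool.concentration[0] == pytest.approx(c_sig2, rel=1e-12)
        assert ctrl.pool.concentration[1] == pytest.approx(c_reg2, rel=1e-12)
        assert ctrl.pool.concentration[2] == pytest.approx(c_struct, rel=1e-12)


class TestSenseAndTranslate:
    def test_reflex_arc_two_agents_after_one_step(self, two_gene_pair):
        ctrl = make_controller(two_gene_pair)
        ctrl.step(food_sensors(True))
        assert ctrl.pool.n_live == 2

    def test_zero_sensors_empty_pool_stays_empty(self, two_gene_pair):
        ctrl = make_controller(two_gene_pair)
        for _ in range(5):
            ctrl.step(np.zeros(7))
            ctrl.end_step(400, 1000)
        assert ctrl.pool.n_live == 0

    def test_repression_below_threshold_deletes_target(self, ctl_cfg):
        g = genome_from_genes([
            reg_gene("111", "222", mode_digit="1"),   # repressor, strength 1
            struct_gene("222", "02"),
        ])
        ctrl = make_controller(g)
        pool = ctrl.pool
        pool.concentration[0] = 2.0   # live repressor
        pool.concentration[1] = 0.6   # live target
        sense_and_translate(pool, np.zeros(7), ctl_cfg)
        assert pool.concentration[1] == 0.0   # 0.6 - 2.0 -> clipped, deleted
        assert pool.concentration[0] > 0.0

    def test_translation_budget_limits_spawns_per_step(self, ctl_cfg):
        genes = [sig_gene(tag=f"0{i//4}{i%4}", target_tag="333")
                 for i in range(12)]
        g = genome_from_genes(genes)
        cfg = ControllerConfig(translation_budget=3)
        ctrl = make_controller(g, cfg=cfg)
        ctrl.step(food_sensors(True))
        assert ctrl.pool.n_live == 3

    def test_pool_cap_never_exceeded(self):
        genes = [sig_gene(tag=f"0{i//4}{i%4}", target_tag="333")
                 for i in range(12)]
        g = genome_from_genes(genes)
        cfg = ControllerConfig(agent_cap=5, translation_budget=50)
        ctrl = make_controller(g, cfg=cfg)
        for _ in range(10):
            ctrl.step(food_sensors(True))
            assert ctrl.pool.n_live <= 5


class TestDecay:
    def test_av_one_leaves_concentration_unchanged(self, two_gene_pair, ctl_cfg):
        ctrl = make_controller(two_gene_pair)
        ctrl.pool.concentration[:] = [1.5, 0.7]
        decay_step(ctrl.pool, ctl_cfg, av=1.0)
        assert list(ctrl.pool.concentration) == [1.5, 0.7]

    def test_one_step_arithmetic(self, two_gene_pair, ctl_cfg):
        ctrl = make_controller(two_gene_pair)
        ctrl.pool.concentration[0] = 1.0
        decay_step(ctrl.pool, ctl_cfg, av=0.0)
        assert ctrl.pool.concentration[0] == pytest.approx(0.9)

    def test_deletion_at_threshold(self, two_gene_pair, ctl_cfg):
        ctrl = make_controller(two_gene_pair)
        ctrl.pool.concentration[0] = 0.052
        decay_step(ctrl.pool, ctl_cfg, av=0.0)   # 0.0468 < 0.05
        assert ctrl.pool.concentration[0] == 0.0

    def test_geometric_decay_empties_pool_in_closed_form_steps(
            self, two_gene_pair, ctl_cfg):
        ctrl = make_controller(two_gene_pair)
        ctrl.pool.concentration[:] = 1.0
        # c0 * 0.9^t < 0.05  <=>  t > ln(0.05)/ln(0.9) = 28.4
        t_empty = math.ceil(math.log(ctl_cfg.deletion_threshold)
                            / math.log(1.0 - ctl_cfg.decay_rate))
        for t in range(1, t_empty + 1):
            decay_step(ctrl.pool, ctl_cfg, av=0.0)
            if t < t_empty:
                assert ctrl.pool.n_live == 2, f"emptied early at {t}"
        assert ctrl.pool.n_live == 0

    def test_ages_increment_only_for_live_agents(self, two_gene_pair, ctl_cfg):
        ctrl = make_controller(two_gene_pair)
        ctrl.pool.concentration[0] = 1.0
        for _ in range(3):
            decay_step(ctrl.pool, ctl_cfg, av=1.0)
        assert ctrl.pool.age[0] == 3
        assert ctrl.pool.age[1] == 0


class TestActuatorOutputs:
    def _pool_with_params(self, params, actuators, concs):
        g = genome_from_genes([
            struct_gene(f"1{i//4}{i%4}", "02") for i in range(len(params))
        ])
        base = desk_scale()
        net = CompiledNetwork(g, base.genome)
        net.struct_param = np.asarray(params, dtype=float)
        net.struct_actuator = np.asarray(actuators, dtype=np.intp)
        pool = AgentPool(net, base.controller)
        pool.concentration[net.struct_idx] = concs
        return pool

    def test_plain_mean_of_two_agents(self):
        pool = self._pool_with_params([0.2, 0.8], [2, 2], [1.0, 1.0])
        assert actuator_outputs(pool)[2] == pytest.approx(0.5)

    def test_concentration_scaling_single_agent(self):
        pool = self._pool_with_params([0.6], [2], [0.5])
        assert actuator_outputs(pool)[2] == pytest.approx(0.3)

    def test_empty_pool_neutral_outputs(self, two_gene_pair):
        ctrl = make_controller(two_gene_pair)
        assert np.allclose(actuator_outputs(ctrl.pool), 0.0)

    def test_dead_agents_excluded_from_mean(self):
        pool = self._pool_with_params([0.2, 0.8], [2, 2], [0.0, 1.0])
        assert actuator_outputs(pool)[2] == pytest.approx(0.8)

    def test_movement_uses_magnitude_mean_with_net_sign(self):
        pool = self._pool_with_params([1.0, -0.5], [0, 0], [1.0, 1.0])
        out = actuator_outputs(pool)
        # net drive +0.5 -> positive sign; magnitude mean (1.0+0.5)/2
        assert out[0] == pytest.approx(0.75)


class TestFeedbackIntegration:
    def test_unconditional_translation_ignores_sensors(self, three_gene_chain):
        fb = FeedbackConfig(conditional_activation=False, av_to_decay=False,
                            av_to_mutation=False)
        ctrl = make_controller(three_gene_chain, fb=fb)
        out = ctrl.step(np.zeros(7))
        assert ctrl.pool.n_live == 3          # all genes live, no sensing gate
        assert out[2] > 0.0                   # structural agent active

    def test_neutral_av_used_when_decay_feedback_off(self, three_gene_chain):
        fb = FeedbackConfig(av_to_decay=False)
        ctrl = make_controller(three_gene_chain, fb=fb)
        ctrl.pool.concentration[2] = 1.0
        neutral = fb.neutral_av
        expected = 1.0 * (1.0 - 0.1 * (1.0 - neutral))
        ctrl.end_step(0.0, 1000.0)            # fitness 0; AV would be tiny
        assert ctrl.pool.concentration[2] == pytest.approx(expected)

    def test_feedback_switch_changes_trajectory(self, three_gene_chain):
        on = make_controller(three_gene_chain)
        off = make_controller(three_gene_chain,
                              fb=FeedbackConfig(av_to_decay=False))
        for _ in range(4):
            on.step(food_sensors(True)); on.end_step(900, 1000)
            off.step(food_sensors(True)); off.end_step(900, 1000)
        assert not np.allclose(on.pool.concentration, off.pool.concentration)


def test_controller_stepping_bit_exact_reproducible(cfg):
    from grnswarm.genome import random_genome

    genome = random_genome(21, cfg.genome)
    def run():
        ctrl = GRNController(genome, cfg.genome, cfg.controller, cfg.feedback)
        rng = np.random.default_rng(0)
        for t in range(40):
            s = np.clip(rng.random(7), 0, 1)
            ctrl.step(s)
            ctrl.end_step(300 + 10 * t, 1000.0)
        return ctrl.pool.concentration.copy()
    assert np.array_equal(run(), run())


def test_pool_agents_view_and_dump(two_gene_pair):
    ctrl = make_controller(two_gene_pair)
    ctrl.step(food_sensors(True))
    ctrl.end_step(400, 1000)
    agents = ctrl.pool.agents()
    assert {a.agent_type for a in agents} == {"signalling", "structural"}
    assert all(a.concentration > 0 for a in agents)
    lines = ctrl.dump_state(step=1, robot_id=7)
    assert len(lines) == len(agents)
    import json
    rec = json.loads(lines[0])
    assert rec["robot_id"] == 7 and "concentration" in rec
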