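"""Grid-world artificial-life environment.

Robots live on a bounded rectangular grid together with typed food sources.
Each time step every robot (in stable id order) senses its neighbourhood,
asks its controller for actuator outputs, and executes the single
functionality with the largest output among the seven available: move
(one signed actuator per axis), eat, dock, undock, attack, reproduce and
idle (the tie/default case).  Energy is the only currency: every step costs
a basic upkeep, every functionality has its own cost, aggregated (docked)
robots pay an extra upkeep, and a robot that cannot cover its basic cost is
dead and removed.  Food types differ in energy content and in the minimal
energy required for access; type-3 food exceeds a single robot's capacity
and is reachable only by docked groups pooling their energy.

Update order within one step (fixed and deliberate): sense/act for all
robots, aggregation upkeep, controller feedback and agent decay, deaths,
reproduction placements, food replenishment, food reset, visit counting.
Food is reset to its initial layout whenever the population sits below the
configured threshold (rate-limited by a cooldown), and optionally on a
fixed schedule (used by the memory experiment to re-impose the initial
condition at regular intervals).

An exact energy ledger is kept per step: the change in total robot energy
must equal credited food and attack transfers minus all costs, dissipation
and energy removed with dead robots.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import evolution
from .ann import AnnController, random_ann
from .config import (
    ACTUATOR_ATTACK,
    ACTUATOR_DOCK,
    ACTUATOR_EAT,
    ACTUATOR_MOVE_X,
    ACTUATOR_MOVE_Y,
    ACTUATOR_REPRODUCE,
    ACTUATOR_UNDOCK,
    N_FOOD_TYPES,
    N_SENSORS,
    SimConfig,
)
from .controller import GRNController
from .evolution import MutationProfile
from .genome import Genome, random_genome

ACTIONS = ("idle", "move", "eat", "dock", "undock", "attack", "reproduce")


@dataclass
class FoodSource:
    position: Tuple[int, int]
    food_type: int            # 1..K
    energy: float
    min_access: float
    touched: bool = False


@dataclass
class Robot:
    robot_id: int
    position: Tuple[int, int]
    energy: float
    controller: object        # GRNController | AnnController
    kind: str                 # "grn" | "evoann" | "randann"
    docked: bool = False


@dataclass
class StepRecord:
    """Per-step metrics and the energy-ledger terms."""

    step: int
    population: int
    pop_by_kind: Dict[str, int]
    avg_energy: float
    avg_gain: float
    food_count: int
    untouched_food: int
    attacks: int
    docks: int
    births: int
    deaths: int
    reset: bool
    total_energy: float
    ledger_residual: float


def select_action(outputs: np.ndarray) -> Tuple[str, Tuple[int, int]]:
    """Map actuator outputs to one functionality (argmax; ties -> idle).

    The movement pair scores as the larger magnitude of its two signed
    drives; if movement wins, the dominant axis and its sign give the
    direction.  A non-positive maximum, or a tied maximum, yields idle.
    """
    mx = float(outputs[ACTUATOR_MOVE_X])
    my = float(outputs[ACTUATOR_MOVE_Y])
    scores = (
        max(abs(mx), abs(my)),
        float(outputs[ACTUATOR_EAT]),
        float(outputs[ACTUATOR_DOCK]),
        float(outputs[ACTUATOR_UNDOCK]),
        float(outputs[ACTUATOR_ATTACK]),
        float(outputs[ACTUATOR_REPRODUCE]),
    )
    best = max(scores)
    if best <= 0.0 or scores.count(best) > 1:
        return "idle", (0, 0)
    choice = scores.index(best)
    if choice == 0:
        if abs(mx) >= abs(my):
            return "move", (0, 1 if mx > 0 else -1)
        return "move", (1 if my > 0 else -1, 0)
    return ("eat", "dock", "undock", "attack", "reproduce")[choice - 1], (0, 0)


def _integral(grid: np.ndarray) -> np.ndarray:
    ii = np.zeros((grid.shape[0] + 1, grid.shape[1] + 1), dtype=grid.dtype)
    np.cumsum(np.cumsum(grid, axis=0), axis=1, out=ii[1:, 1:])
    return ii


def _window_sum(ii: np.ndarray, r: int, c: int, radius: int,
                h: int, w: int) -> float:
    r0, r1 = max(0, r - radius), min(h - 1, r + radius)
    c0, c1 = max(0, c - radius), min(w - 1, c + radius)
    return float(ii[r1 + 1, c1 + 1] - ii[r0, c1 + 1] - ii[r1 + 1, c0] + ii[r0, c0])


class World:
    """One simulated world: grid, robots, food, step loop and bookkeeping."""

    def __init__(self, cfg: SimConfig, layout_seed, dynamics_seed,
                 scheduled_reset: Optional[int] = None,
                 check_ledger: bool = True):
        self.cfg = cfg
        w = cfg.world
        self.h, self.w = w.height, w.width
        self.layout_rng = np.random.default_rng(layout_seed)
        self.rng = np.random.default_rng(dynamics_seed)
        self.scheduled_reset = scheduled_reset
        self.check_ledger = check_ledger

        self.robots: Dict[int, Robot] = {}
        self.food: Dict[Tuple[int, int], FoodSource] = {}
        self._occupancy: Dict[Tuple[int, int], int] = {}
        self._next_robot_id = 0
        self.step_count = 0
        self.visit_counts = np.zeros((self.h, self.w), dtype=np.int64)
        self.reset_steps: List[int] = []
        self.history: List[StepRecord] = []
        self._mutation_profile = MutationProfile.from_config(cfg.mutation)

        self._initial_layout = self._draw_food_layout()
        self._apply_food_layout(self._initial_layout)

    # ------------------------------------------------------------------ setup

    def _draw_food_layout(self):
        w = self.cfg.world
        n_cells = self.h * self.w
        n = min(w.initial_food, n_cells)
        flat = self.layout_rng.choice(n_cells, size=n, replace=False)
        types = self.layout_rng.choice(
            len(w.food_types), size=n, p=np.asarray(w.food_type_probs)
        )
        return [((int(f // self.w), int(f % self.w)), int(t) + 1) for f, t in zip(flat, types)]

    def _apply_food_layout(self, layout) -> None:
        w = self.cfg.world
        self.food = {}
        for pos, ftype in layout:
            energy, min_access = w.food_types[ftype - 1]
            self.food[pos] = FoodSource(pos, ftype, energy, min_access)

    def _random_free_cell(self) -> Tuple[int, int]:
        for _ in range(200):
            r = int(self.rng.integers(self.h))
            c = int(self.rng.integers(self.w))
            if self._occupancy.get((r, c), 0) < self.cfg.world.max_per_cell:
                return (r, c)
        raise RuntimeError("no free cell found for robot placement")

    def add_robot(self, controller, kind: str,
                  position: Optional[Tuple[int, int]] = None,
                  energy: Optional[float] = None) -> Robot:
        pos = position if position is not None else self._random_free_cell()
        robot = Robot(
            robot_id=self._next_robot_id,
            position=pos,
            energy=self.cfg.world.start_energy if energy is None else energy,
            controller=controller,
            kind=kind,
        )
        self._next_robot_id += 1
        self.robots[robot.robot_id] = robot
        self._occupancy[pos] = self._occupancy.get(pos, 0) + 1
        return robot

    def make_grn_controller(self, genome: Optional[Genome] = None) -> GRNController:
        g = genome if genome is not None else random_genome(self.rng, self.cfg.genome)
        return GRNController(g, self.cfg.genome, self.cfg.controller, self.cfg.feedback)

    def make_ann_controller(self, learning: bool) -> AnnController:
        genome = random_ann(self.rng, self.cfg.ann)
        return AnnController(genome, self.cfg.ann, self.rng, learning)

    def populate(self, kind: str, n: int) -> None:
        """Add ``n`` robots with fresh random controllers of the given kind."""
        for _ in range(n):
            if kind == "grn":
                ctrl = self.make_grn_controller()
            elif kind == "evoann":
                ctrl = self.make_ann_controller(learning=True)
            elif kind == "randann":
                ctrl = self.make_ann_controller(learning=False)
            else:
                raise ValueError(f"unknown controller kind {kind!r}")
            self.add_robot(ctrl, kind)

    # ---------------------------------------------------------------- sensing

    def _build_grids(self) -> None:
        robot_grid = np.zeros((self.h, self.w), dtype=np.float64)
        for rb in self.robots.values():
            robot_grid[rb.position] += 1
        food_grids = np.zeros((N_FOOD_TYPES, self.h, self.w), dtype=np.float64)
        for f in self.food.values():
            food_grids[f.food_type - 1][f.position] += 1
        self._robot_ii = _integral(robot_grid)
        self._food_ii = [_integral(food_grids[k]) for k in range(N_FOOD_TYPES)]

    def sense(self, robot: Robot) -> np.ndarray:
        """Normalised neighbourhood counts plus own energy fraction."""
        w = self.cfg.world
        r, c = robot.position
        rad = w.sense_radius
        s = np.empty(N_SENSORS)
        n_rb = _window_sum(self._robot_ii, r, c, rad, self.h, self.w) - 1.0
        s[0] = min(n_rb / w.robot_norm, 1.0)
        for k in range(N_FOOD_TYPES):
            nf = _window_sum(self._food_ii[k], r, c, rad, self.h, self.w)
            s[1 + k] = min(nf / w.food_norm, 1.0)
        food = self.food.get(robot.position)
        if food is None:
            s[N_SENSORS - 3] = 0.0
            s[N_SENSORS - 2] = 0.0
        else:
            ok = self.food_access(self._group_of(robot), food)
            s[N_SENSORS - 3] = 1.0 if ok else 0.0
            s[N_SENSORS - 2] = 0.0 if ok else 1.0
        s[N_SENSORS - 1] = robot.energy / w.energy_capacity
        return s

    # ---------------------------------------------------------------- acting

    def _group_of(self, robot: Robot) -> List[Robot]:
        """Docked robots co-located with ``robot`` (including itself).

        An undocked robot is always a singleton group.
        """
        if not robot.docked:
            return [robot]
        return [
            rb for rb in self.robots.values()
            if rb.docked and rb.position == robot.position
        ]

    def food_access(self, group: List[Robot], food: FoodSource) -> bool:
        """True iff the group's pooled energy meets the food's access minimum."""
        return sum(rb.energy for rb in group) >= food.min_access

    def _pay(self, robot: Robot, cost: float) -> bool:
        """Deduct a functionality cost if affordable; report success."""
        if robot.energy < cost:
            return False
        robot.energy -= cost
        self._ledger["costs"] += cost
        return True

    def _credit(self, robot: Robot, amount: float) -> float:
        """Add energy up to capacity; return the amount actually credited."""
        room = self.cfg.world.energy_capacity - robot.energy
        credited = min(amount, room)
        robot.energy += credited
        return credited

    def _act(self, robot: Robot, outputs: np.ndarray,
             intents: List[int]) -> None:
        w = self.cfg.world
        # basic living cost, always due (partial payment when nearly broke
        # keeps the ledger exact; the robot dies this step anyway)
        basic = min(w.basic_cost, robot.energy)
        robot.energy -= basic
        self._ledger["costs"] += basic

        if w.action_noise > 0:
            outputs = outputs + self.rng.normal(0.0, w.action_noise,
                                                size=outputs.shape)
        action, (dr, dc) = select_action(outputs)
        if action == "move":
            if self._pay(robot, w.move_cost):
                if w.move_noise > 0 and self.rng.random() < w.move_noise:
                    dr, dc = ((0, 1), (0, -1), (1, 0), (-1, 0))[
                        int(self.rng.integers(4))
                    ]
                r, c = robot.position
                nr, nc = r + dr, c + dc
                if w.torus:
                    nr, nc = nr % self.h, nc % self.w
                if (0 <= nr < self.h and 0 <= nc < self.w
                        and self._occupancy.get((nr, nc), 0) < w.max_per_cell):
                    self._occupancy[robot.position] -= 1
                    robot.position = (nr, nc)
                    self._occupancy[robot.position] = (
                        self._occupancy.get(robot.position, 0) + 1
                    )
        elif action == "eat":
            if self._pay(robot, w.eat_cost):
                food = self.food.get(robot.position)
                if food is not None:
                    group = self._group_of(robot)
                    if self.food_access(group, food):
                        share = food.energy / len(group)
                        for member in group:
                            self._ledger["eat_credited"] += self._credit(member, share)
                        self._ledger["food_removed"] += food.energy
                        del self.food[robot.position]
        elif action == "dock":
            if self._pay(robot, w.dock_cost):
                robot.docked = True
                self._ledger["docks"] += 1
        elif action == "undock":
            if self._pay(robot, w.undock_cost):
                robot.docked = False
        elif action == "attack":
            if self._pay(robot, w.attack_cost):
                victims = [
                    rb for rb in self.robots.values()
                    if rb.position == robot.position and rb.robot_id != robot.robot_id
                ]
                if victims:
                    victim = victims[int(self.rng.integers(len(victims)))]
                    taken = w.attack_fraction * victim.energy
                    victim.energy -= taken
                    credited = self._credit(robot, taken)
                    self._ledger["attack_taken"] += taken
                    self._ledger["attack_credited"] += credited
                    self._ledger["attacks"] += 1
        elif action == "reproduce":
            if robot.energy >= w.reproduce_threshold:
                intents.append(robot.robot_id)
        # idle: nothing beyond the basic cost

        # surplus-energy reproduction: a nearly full robot spawns offspring
        # even if its controller never selects the reproduce functionality
        if (robot.energy >= w.auto_reproduce_threshold
                and action != "reproduce"):
            intents.append(robot.robot_id)

    def aggregation_step(self) -> Dict[Tuple[int, int], List[Robot]]:
        """Form groups of co-located docked robots and charge the upkeep.

        Singleton "groups" pay nothing; every member of a group of two or
        more pays the per-step aggregation cost.  Returns the groups.
        """
        w = self.cfg.world
        groups: Dict[Tuple[int, int], List[Robot]] = {}
        for rb in self.robots.values():
            if rb.docked:
                groups.setdefault(rb.position, []).append(rb)
        for members in groups.values():
            if len(members) >= 2:
                for rb in members:
                    paid = min(w.aggregation_cost, rb.energy)
                    rb.energy -= paid
                    self._ledger["costs"] += paid
        return groups

    # ------------------------------------------------------------------ births

    def _spawn_offspring(self, parent: Robot) -> Optional[Robot]:
        w = self.cfg.world
        r, c = parent.position
        cells = [(r + dr, c + dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)]
        self.rng.shuffle(cells)
        spot = None
        for (nr, nc) in cells:
            if w.torus:
                nr, nc = nr % self.h, nc % self.w
            if (0 <= nr < self.h and 0 <= nc < self.w
                    and self._occupancy.get((nr, nc), 0) < w.max_per_cell):
                spot = (nr, nc)
                break
        if spot is None:
            return None
        parent.energy -= w.reproduce_cost
        self._ledger["repro_cost"] += w.reproduce_cost
        self._ledger["repro_grant"] += w.offspring_energy
        if parent.kind == "grn":
            ctrl: object = parent.controller
            child_genome = evolution.inherit(
                ctrl.genome, ctrl.network.annotations, self._mutation_profile,
                self.rng, expression=ctrl.mutation_expression(),
            )
            child_ctrl = self.make_grn_controller(child_genome)
        else:
            child_ctrl = parent.controller.spawn_offspring(self.rng)
        return self.add_robot(child_ctrl, parent.kind, position=spot,
                              energy=w.offspring_energy)

    # ------------------------------------------------------------------- step

    def step(self) -> StepRecord:
        w = self.cfg.world
        self.step_count += 1
        self._ledger = {
            "food_removed": 0.0, "eat_credited": 0.0,
            "attack_taken": 0.0, "attack_credited": 0.0,
            "costs": 0.0, "repro_cost": 0.0, "repro_grant": 0.0,
            "death_energy": 0.0, "attacks": 0, "docks": 0,
        }
        energy_before = sum(rb.energy for rb in self.robots.values())
        e0 = {rid: rb.energy for rid, rb in self.robots.items()}

        # 1. sense -> controller -> act, in stable id order
        self._build_grids()
        intents: List[int] = []
        for rid in sorted(self.robots):
            robot = self.robots[rid]
            sensors = self.sense(robot)
            outputs = robot.controller.step(sensors)
            self._act(robot, outputs, intents)

        # 2. aggregation upkeep
        self.aggregation_step()

        # 3. controller feedback / agent decay
        for rid in sorted(self.robots):
            robot = self.robots[rid]
            if robot.kind == "grn":
                robot.controller.end_step(robot.energy, w.energy_capacity)
            else:
                delta = robot.energy - e0.get(rid, robot.energy)
                robot.controller.end_step(delta, self.rng)

        # 4. deaths
        deaths = 0
        for rid in sorted(self.robots):
            robot = self.robots[rid]
            if robot.energy < w.basic_cost:
                self._ledger["death_energy"] += robot.energy
                self._occupancy[robot.position] -= 1
                del self.robots[rid]
                deaths += 1

        # 5. reproduction placements
        births = 0
        for rid in intents:
            parent = self.robots.get(rid)
            if parent is None or parent.energy < w.reproduce_threshold:
                continue
            if self._spawn_offspring(parent) is not None:
                births += 1

        # 6. food replenishment
        if w.replenish_interval > 0 and self.step_count % w.replenish_interval == 0:
            free = [
                (r, c) for r in range(self.h) for c in range(self.w)
                if (r, c) not in self.food
            ]
            k = min(w.replenish_count, len(free))
            if k > 0:
                picks = self.rng.choice(len(free), size=k, replace=False)
                types = self.rng.choice(
                    len(w.food_types), size=k, p=np.asarray(w.food_type_probs)
                )
                for idx, t in zip(picks, types):
                    pos = free[int(idx)]
                    energy, min_access = w.food_types[int(t)]
                    self.food[pos] = FoodSource(pos, int(t) + 1, energy, min_access)

        # 7. food reset: fires while the population sits below the threshold
        #    (rate-limited by the cooldown), plus the optional imposed
        #    schedule used by the memory experiment
        pop = len(self.robots)
        reset = False
        last = self.reset_steps[-1] if self.reset_steps else -w.reset_cooldown
        if (pop < w.pop_reset_threshold
                and self.step_count - last >= w.reset_cooldown):
            reset = True
        if (self.scheduled_reset is not None and self.scheduled_reset > 0
                and self.step_count % self.scheduled_reset == 0):
            reset = True
        if reset:
            self._apply_food_layout(self._initial_layout)
            self.reset_steps.append(self.step_count)

        # 8. visit counts and touched food
        for rb in self.robots.values():
            self.visit_counts[rb.position] += 1
            food = self.food.get(rb.position)
            if food is not None:
                food.touched = True

        # 9. metrics + ledger
        total_energy = sum(rb.energy for rb in self.robots.values())
        L = self._ledger
        residual = (total_energy - energy_before) - (
            L["eat_credited"] + L["attack_credited"] - L["attack_taken"]
            - L["costs"] - L["repro_cost"] + L["repro_grant"] - L["death_energy"]
        )
        if self.check_ledger and abs(residual) > 1e-6 * max(1.0, abs(total_energy)):
            raise AssertionError(f"energy ledger off by {residual}")

        # per-robot gain over robots present at both ends of the step;
        # missing (NaN) when nobody survived, so an extinct population is
        # never scored as gaining zero
        survivors = [rid for rid in self.robots if rid in e0]
        gains = [self.robots[rid].energy - e0[rid] for rid in survivors]
        pop_by_kind: Dict[str, int] = {}
        for rb in self.robots.values():
            pop_by_kind[rb.kind] = pop_by_kind.get(rb.kind, 0) + 1
        record = StepRecord(
            step=self.step_count,
            population=pop,
            pop_by_kind=pop_by_kind,
            avg_energy=(total_energy / pop) if pop else float("nan"),
            avg_gain=(sum(gains) / len(gains)) if gains else float("nan"),
            food_count=len(self.food),
            untouched_food=sum(1 for f in self.food.values() if not f.touched),
            attacks=L["attacks"],
            docks=L["docks"],
            births=births,
            deaths=deaths,
            reset=reset,
            total_energy=total_energy,
            ledger_residual=float(residual),
        )
        self.history.append(record)
        return record

    def run(self, steps: int) -> List[StepRecord]:
        return [self.step() for _ in range(steps)]

    # -------------------------------------------------------------- exports

    def snapshot(self) -> dict:
        """JSON-serialisable snapshot of robots, food and the step counter."""
        return {
            "step": self.step_count,
            "robots": [
                {"id": rb.robot_id, "pos": list(rb.position), "kind": rb.kind,
                 "energy": round(rb.energy, 6), "docked": rb.docked}
                for rb in self.robots.values()
            ],
            "food": [
                {"pos": list(f.position), "type": f.food_type,
                 "energy": f.energy, "min_access": f.min_access,
                 "touched": f.touched}
                for f in self.food.values()
            ],
        }

    def save_snapshot(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.snapshot(), fh, indent=1)

    def save_visit_matrix(self, path) -> None:
        np.savetxt(path, self.visit_counts, fmt="%d")
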