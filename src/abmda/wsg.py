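"""Wolf-Sheep-Grass (WSG) predator-prey agent-based model.

A re-implementation of the classic NetLogo library Wolf Sheep Predation
model: wolves and sheep random-walk on a toroidal patch grid and carry an
energy store; wolves eat co-located sheep, sheep eat green grass (turning
the patch brown), both reproduce with fixed probability splitting energy
with the child, and brown grass regrows after a fixed number of ticks.

Because the model is spatially well mixed, its macrostate is just the three
counts (wolves, sheep, green patches) and microstate synthesis is uniform
random sampling: surplus agents are deleted at random, missing agents are
placed at random with energies drawn from the surviving population.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .macrostate import MacroSchema, Macrostate, Variable

__all__ = [
    "WSGParams",
    "AgentSet",
    "WSGMicrostate",
    "wsg_schema",
    "init_wsg",
    "step_wsg",
    "summarize_wsg",
    "synthesize_wsg",
    "run_wsg_trajectory",
]


@dataclass(frozen=True)
class WSGParams:
    """Model parameters; defaults follow the NetLogo library model."""

    world_size: int = 255
    sheep_reproduce_prob: float = 0.04
    wolf_reproduce_prob: float = 0.05
    sheep_gain: float = 4.0
    wolf_gain: float = 20.0
    move_cost: float = 1.0
    grass_regrowth_time: int = 30
    init_wolves: int = 50
    init_sheep: int = 100
    init_grass_density: float = 0.5
    step_length: float = 1.0

    def __post_init__(self) -> None:
        if self.world_size <= 0:
            raise ValueError("world_size must be positive")
        for name in ("sheep_reproduce_prob", "wolf_reproduce_prob", "init_grass_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("sheep_gain", "wolf_gain", "move_cost", "step_length"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.grass_regrowth_time < 1:
            raise ValueError("grass_regrowth_time must be >= 1")
        if self.init_wolves < 0 or self.init_sheep < 0:
            raise ValueError("initial counts must be nonnegative")

    def with_overrides(self, **kw) -> "WSGParams":
        return replace(self, **kw)


class AgentSet:
    """Struct-of-arrays container for one mobile-agent species."""

    __slots__ = ("pos", "heading", "energy")

    def __init__(self, pos: np.ndarray, heading: np.ndarray, energy: np.ndarray) -> None:
        self.pos = np.asarray(pos, dtype=float).reshape(-1, 2)
        self.heading = np.asarray(heading, dtype=float).reshape(-1)
        self.energy = np.asarray(energy, dtype=float).reshape(-1)
        n = len(self.energy)
        if self.pos.shape != (n, 2) or self.heading.shape != (n,):
            raise ValueError("inconsistent agent array lengths")

    def __len__(self) -> int:
        return len(self.energy)

    @classmethod
    def empty(cls) -> "AgentSet":
        return cls(np.empty((0, 2)), np.empty(0), np.empty(0))

    def copy(self) -> "AgentSet":
        return AgentSet(self.pos.copy(), self.heading.copy(), self.energy.copy())

    def subset(self, idx) -> "AgentSet":
        return AgentSet(self.pos[idx], self.heading[idx], self.energy[idx])

    def extend(self, other: "AgentSet") -> "AgentSet":
        return AgentSet(
            np.concatenate([self.pos, other.pos]),
            np.concatenate([self.heading, other.heading]),
            np.concatenate([self.energy, other.energy]),
        )


@dataclass
class WSGMicrostate:
    """Complete WSG state: the two agent populations plus the grass lattice.

    ``grass`` is True on green patches; ``regrowth`` counts ticks until a
    brown patch regrows and is 0 wherever the patch is green.
    """

    wolves: AgentSet
    sheep: AgentSet
    grass: np.ndarray
    regrowth: np.ndarray

    def copy(self) -> "WSGMicrostate":
        return WSGMicrostate(
            self.wolves.copy(), self.sheep.copy(), self.grass.copy(), self.regrowth.copy()
        )

    def validate(self, params: WSGParams) -> None:
        w = params.world_size
        for a in (self.wolves, self.sheep):
            if len(a) and (a.pos.min() < 0 or a.pos.max() >= w):
                raise ValueError("agent position outside the torus")
            if len(a) and a.energy.min() <= 0:
                raise ValueError("living agent with nonpositive energy")
        if self.grass.shape != (w, w) or self.regrowth.shape != (w, w):
            raise ValueError("lattice shape mismatch")
        if np.any(self.regrowth[self.grass] != 0):
            raise ValueError("green patch with nonzero regrowth counter")
        if self.regrowth.min() < 0 or self.regrowth.max() > params.grass_regrowth_time:
            raise ValueError("regrowth counter out of range")


def wsg_schema(world_size: int) -> MacroSchema:
    """Macrostate registry: wolf count, sheep count, green-patch count."""
    return MacroSchema(
        variables=(
            Variable("wolves", kind="count"),
            Variable("sheep", kind="count"),
            Variable("grass", kind="count", cap=world_size**2),
        )
    )


def _random_agents(
    n: int, world_size: int, gain: float, rng: np.random.Generator
) -> AgentSet:
    pos = rng.uniform(0.0, world_size, size=(n, 2))
    heading = rng.uniform(-np.pi, np.pi, size=n)
    # uniform on (0, 2*gain]: NetLogo seeds energy as a uniform multiple of gain
    energy = (1.0 - rng.uniform(0.0, 1.0, size=n)) * 2.0 * gain
    return AgentSet(pos, heading, energy)


def init_wsg(params: WSGParams, seed: int) -> WSGMicrostate:
    """Uniform random initial microstate for the given parameters."""
    rng = np.random.default_rng(seed)
    w = params.world_size
    wolves = _random_agents(params.init_wolves, w, params.wolf_gain, rng)
    sheep = _random_agents(params.init_sheep, w, params.sheep_gain, rng)
    grass = rng.uniform(size=(w, w)) < params.init_grass_density
    regrowth = np.zeros((w, w), dtype=np.int64)
    brown = ~grass
    regrowth[brown] = rng.integers(0, params.grass_regrowth_time, size=int(brown.sum()))
    return WSGMicrostate(wolves, sheep, grass, regrowth)


def _patch_index(agents: AgentSet, world_size: int) -> np.ndarray:
    col = np.floor(agents.pos[:, 0]).astype(np.int64)
    row = np.floor(agents.pos[:, 1]).astype(np.int64)
    return row * world_size + col


def _within_patch_ranks(patches: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Rank each agent within its patch, in uniformly random order.

    Used to resolve eating conflicts without index bias: the rank-r wolf on
    a patch eats the rank-r sheep, and only the rank-0 sheep on a green
    patch gets the grass.
    """
    n = len(patches)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    perm = rng.permutation(n)
    keys = patches[perm]
    order = np.argsort(keys, kind="stable")
    sorted_keys = keys[order]
    run_start = np.r_[0, np.flatnonzero(np.diff(sorted_keys)) + 1]
    run_id = np.zeros(n, dtype=np.int64)
    run_id[run_start[1:]] = 1
    run_id = np.cumsum(run_id)
    pos_in_run = np.arange(n) - run_start[run_id]
    ranks_perm = np.empty(n, dtype=np.int64)
    ranks_perm[order] = pos_in_run
    ranks = np.empty(n, dtype=np.int64)
    ranks[perm] = ranks_perm
    return ranks


def _move(agents: AgentSet, params: WSGParams, rng: np.random.Generator) -> AgentSet:
    n = len(agents)
    heading = rng.uniform(-np.pi, np.pi, size=n)
    step = params.step_length * np.stack([np.cos(heading), np.sin(heading)], axis=1)
    pos = np.mod(agents.pos + step, params.world_size)
    return AgentSet(pos, heading, agents.energy.copy())


def _reproduce(agents: AgentSet, prob: float, rng: np.random.Generator) -> AgentSet:
    if len(agents) == 0 or prob == 0.0:
        return agents
    parents = rng.uniform(size=len(agents)) < prob
    if not parents.any():
        return agents
    energy = agents.energy.copy()
    child_energy = 0.5 * energy[parents]
    energy[parents] -= child_energy  # exact split: parent + child == pre-split
    children = AgentSet(
        agents.pos[parents].copy(),
        rng.uniform(-np.pi, np.pi, size=int(parents.sum())),
        child_energy,
    )
    return AgentSet(agents.pos, agents.heading, energy).extend(children)


def step_wsg(
    state: WSGMicrostate, params: WSGParams, rng: np.random.Generator
) -> WSGMicrostate:
    """Advance one tick.

    Phase order: move -> pay move cost -> eat (wolves then sheep) -> death at
    energy <= 0 -> reproduce -> grass regrowth.  Patches eaten bare this tick
    keep their full regrowth counter until next tick.
    """
    w = params.world_size
    wolves = _move(state.wolves, params, rng)
    sheep = _move(state.sheep, params, rng)
    wolves.energy -= params.move_cost
    sheep.energy -= params.move_cost

    grass = state.grass.copy()
    regrowth = state.regrowth.copy()
    eaten_patches = np.zeros(w * w, dtype=bool)

    # Wolves eat sheep: within each patch, match wolves and sheep by random
    # rank; each matched wolf eats exactly one sheep.
    if len(wolves) and len(sheep):
        wp = _patch_index(wolves, w)
        sp = _patch_index(sheep, w)
        wr = _within_patch_ranks(wp, rng)
        sr = _within_patch_ranks(sp, rng)
        stride = max(len(wolves), len(sheep)) + 1
        wkey = wp * stride + wr
        skey = sp * stride + sr
        wolf_eats = np.isin(wkey, skey)
        sheep_eaten = np.isin(skey, wkey)
        wolves.energy[wolf_eats] += params.wolf_gain
        sheep = sheep.subset(~sheep_eaten)

    # Sheep eat grass: one random sheep per green patch eats it bare.
    if len(sheep):
        sp = _patch_index(sheep, w)
        sr = _within_patch_ranks(sp, rng)
        flat_green = grass.reshape(-1)
        eaters = (sr == 0) & flat_green[sp]
        if eaters.any():
            sheep.energy[eaters] += params.sheep_gain
            patches = sp[eaters]
            flat_green[patches] = False
            regrowth.reshape(-1)[patches] = params.grass_regrowth_time
            eaten_patches[patches] = True

    wolves = wolves.subset(wolves.energy > 0)
    sheep = sheep.subset(sheep.energy > 0)

    wolves = _reproduce(wolves, params.wolf_reproduce_prob, rng)
    sheep = _reproduce(sheep, params.sheep_reproduce_prob, rng)

    # Grass regrowth on patches that were brown before this tick's eating.
    flat_grass = grass.reshape(-1)
    flat_regrow = regrowth.reshape(-1)
    regrowing = ~flat_grass & ~eaten_patches
    flat_regrow[regrowing] = np.maximum(flat_regrow[regrowing] - 1, 0)
    sprouted = regrowing & (flat_regrow == 0)
    flat_grass[sprouted] = True

    return WSGMicrostate(wolves, sheep, grass, regrowth)


def summarize_wsg(state: WSGMicrostate) -> Macrostate:
    """Macrostate (wolf count, sheep count, green-patch count)."""
    schema = wsg_schema(state.grass.shape[0])
    return Macrostate(
        schema,
        [len(state.wolves), len(state.sheep), int(state.grass.sum())],
    )


def _adjust_population(
    agents: AgentSet,
    target: int,
    world_size: int,
    gain: float,
    rng: np.random.Generator,
) -> AgentSet:
    """Delete a uniform random surplus or add uniform random agents whose
    energies follow the empirical distribution of the survivors."""
    n = len(agents)
    if target == n:
        return agents.copy()
    if target < n:
        keep = rng.choice(n, size=target, replace=False)
        return agents.subset(np.sort(keep))
    deficit = target - n
    pos = rng.uniform(0.0, world_size, size=(deficit, 2))
    heading = rng.uniform(-np.pi, np.pi, size=deficit)
    if n > 0:
        energy = agents.energy[rng.integers(0, n, size=deficit)].copy()
    else:
        energy = (1.0 - rng.uniform(0.0, 1.0, size=deficit)) * 2.0 * gain
    return agents.extend(AgentSet(pos, heading, energy))


def synthesize_wsg(
    target: Macrostate,
    seed_state: WSGMicrostate,
    params: WSGParams,
    rng: np.random.Generator,
) -> WSGMicrostate:
    """Minimal-change microstate for ``target`` seeded by ``seed_state``.

    Agents and patches not needed to close the count gap are left untouched
    (continuity: a nearby macrostate should map to a nearby microstate); all
    additions and deletions are uniform random, matching the model's
    well-mixed spatial statistics.
    """
    w = params.world_size
    wolves_t = int(round(target["wolves"]))
    sheep_t = int(round(target["sheep"]))
    grass_t = int(round(target["grass"]))
    if min(wolves_t, sheep_t, grass_t) < 0:
        raise ValueError("negative target count")
    if grass_t > w * w:
        raise ValueError("grass target exceeds patch capacity")

    wolves = _adjust_population(seed_state.wolves, wolves_t, w, params.wolf_gain, rng)
    sheep = _adjust_population(seed_state.sheep, sheep_t, w, params.sheep_gain, rng)

    grass = seed_state.grass.copy()
    regrowth = seed_state.regrowth.copy()
    current = int(grass.sum())
    flat_grass = grass.reshape(-1)
    flat_regrow = regrowth.reshape(-1)
    if grass_t > current:
        brown_idx = np.flatnonzero(~flat_grass)
        flip = rng.choice(len(brown_idx), size=grass_t - current, replace=False)
        chosen = brown_idx[flip]
        flat_grass[chosen] = True
        flat_regrow[chosen] = 0
    elif grass_t < current:
        green_idx = np.flatnonzero(flat_grass)
        flip = rng.choice(len(green_idx), size=current - grass_t, replace=False)
        chosen = green_idx[flip]
        flat_grass[chosen] = False
        flat_regrow[chosen] = rng.integers(0, params.grass_regrowth_time, size=len(chosen))
    return WSGMicrostate(wolves, sheep, grass, regrowth)


def run_wsg_trajectory(
    params: WSGParams, n_ticks: int, seed: int, state: WSGMicrostate | None = None
) -> tuple[WSGMicrostate, np.ndarray]:
    """Simulate ``n_ticks`` ticks and return (final state, macro trajectory).

    The trajectory has shape (n_ticks + 1, 3) with rows
    (wolves, sheep, grass) including the initial state.
    """
    rng = np.random.default_rng(seed)
    if state is None:
        state = init_wsg(params, seed)
    traj = np.empty((n_ticks + 1, 3))
    traj[0] = summarize_wsg(state).values
    for t in range(n_ticks):
        state = step_wsg(state, params, rng)
        traj[t + 1] = summarize_wsg(state).values
    return state, traj
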