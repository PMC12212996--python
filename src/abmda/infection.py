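"""Reduced spatially heterogeneous viral-infection agent-based model.

A compact immune-response testbed with the state structure that makes
microstate synthesis hard: categorical epithelial and endothelial lattices,
diffusing molecular fields (virus plus nine cytokine/signal species), and
mobile immune agents recruited at activated endothelium.  Infection spreads
outward from a seeded focus, so spatial distributions are dominated by
"hot-spots" rather than being well mixed — exactly the regime where naive
random-cell macrostate updates destroy the geometry and the spatially aware
quantization/error-diffusion synthesis is needed.

The dynamics are deliberately small (about a dozen parameters): a full
physiological virology model is not required to exercise the assimilation
and synthesis machinery, only non-uniform spatial structure, categorical
states and field/agent coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .macrostate import MacroSchema, Macrostate, Variable

__all__ = [
    "EPITHELIAL_LABELS",
    "ENDOTHELIAL_LABELS",
    "IMMUNE_TYPES",
    "FIELD_NAMES",
    "InfectionParams",
    "ImmuneAgents",
    "InfectionMicrostate",
    "infection_schema",
    "init_infection",
    "step_infection",
    "summarize_infection",
]

# Epithelial categorical states, in one-hot basis order.
EPITHELIAL_LABELS = ("Healthy", "Infected", "Necrosed", "Apoptosed", "Empty")
EPI_HEALTHY, EPI_INFECTED, EPI_NECROSED, EPI_APOPTOSED, EPI_EMPTY = range(5)

# Endothelial categorical states.
ENDOTHELIAL_LABELS = ("Normal", "Activated", "Dead")
ENDO_NORMAL, ENDO_ACTIVATED, ENDO_DEAD = range(3)

IMMUNE_TYPES = ("macrophage", "neutrophil", "NK", "DC")

FIELD_NAMES = (
    "virus",
    "T1IFN",
    "TNF",
    "IL1",
    "IL6",
    "IL8",
    "IL10",
    "IL12",
    "IFNg",
    "PDAMPs",
)

# Species secreted by infected epithelial sites per tick (units of the
# per-field secretion rate).
_INFECTED_SECRETES = ("virus", "IL1", "IL6", "TNF", "PDAMPs")

# Type-specific secretion by immune agents at their patch.
_IMMUNE_SECRETES = {
    "macrophage": ("TNF", "IL6", "IL10"),
    "neutrophil": ("IL8",),
    "NK": ("IFNg",),
    "DC": ("IL12", "T1IFN"),
}


@dataclass(frozen=True)
class InfectionParams:
    lattice_side: int = 51
    diffusion: float = 0.1  # per-tick explicit-scheme coefficient, 4*D <= 1
    decay: float = 0.05  # fractional decay per tick
    secretion: float = 1.0  # units emitted per secreting site per tick
    infection_prob_per_unit_virus: float = 0.05
    apoptosis_timer: int = 20  # ticks from infection to apoptosis
    necrosis_virus_threshold: float = 50.0
    recruitment_rate: float = 0.02  # expected recruits per activated site per tick
    immune_kill_prob: float = 0.3
    endothelial_activation_threshold: float = 5.0
    endothelial_death_factor: float = 10.0  # death at factor * activation threshold
    immune_lifespan: int = 60  # ticks before an immune agent is cleared
    initial_infected_focus_radius: int = 2

    def __post_init__(self) -> None:
        if self.lattice_side <= 0:
            raise ValueError("lattice_side must be positive")
        if self.diffusion < 0 or self.diffusion * 4.0 > 1.0:
            raise ValueError("diffusion must satisfy 0 <= 4*D <= 1 for stability")
        if not 0.0 <= self.decay <= 1.0:
            raise ValueError("decay must be in [0, 1]")
        for name in ("infection_prob_per_unit_virus", "immune_kill_prob"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.immune_kill_prob > 1:
            raise ValueError("immune_kill_prob must be <= 1")
        if self.initial_infected_focus_radius >= self.lattice_side / 2:
            raise ValueError("infected focus radius must be < lattice_side / 2")

    def with_overrides(self, **kw) -> "InfectionParams":
        return replace(self, **kw)


class ImmuneAgents:
    """Struct-of-arrays container for the mobile immune agents."""

    __slots__ = ("type_code", "pos", "heading", "age")

    def __init__(self, type_code, pos, heading, age) -> None:
        self.type_code = np.asarray(type_code, dtype=np.int64).reshape(-1)
        self.pos = np.asarray(pos, dtype=float).reshape(-1, 2)
        self.heading = np.asarray(heading, dtype=float).reshape(-1)
        self.age = np.asarray(age, dtype=np.int64).reshape(-1)
        n = len(self.type_code)
        if self.pos.shape != (n, 2) or self.heading.shape != (n,) or self.age.shape != (n,):
            raise ValueError("inconsistent immune-agent array lengths")

    def __len__(self) -> int:
        return len(self.type_code)

    @classmethod
    def empty(cls) -> "ImmuneAgents":
        return cls(np.empty(0, np.int64), np.empty((0, 2)), np.empty(0), np.empty(0, np.int64))

    def copy(self) -> "ImmuneAgents":
        return ImmuneAgents(
            self.type_code.copy(), self.pos.copy(), self.heading.copy(), self.age.copy()
        )

    def subset(self, idx) -> "ImmuneAgents":
        return ImmuneAgents(
            self.type_code[idx], self.pos[idx], self.heading[idx], self.age[idx]
        )

    def extend(self, other: "ImmuneAgents") -> "ImmuneAgents":
        return ImmuneAgents(
            np.concatenate([self.type_code, other.type_code]),
            np.concatenate([self.pos, other.pos]),
            np.concatenate([self.heading, other.heading]),
            np.concatenate([self.age, other.age]),
        )

    def counts(self) -> np.ndarray:
        return np.bincount(self.type_code, minlength=len(IMMUNE_TYPES))


@dataclass
class InfectionMicrostate:
    epithelium: np.ndarray  # int lattice, EPITHELIAL_LABELS codes
    endothelium: np.ndarray  # int lattice, ENDOTHELIAL_LABELS codes
    fields: dict[str, np.ndarray]  # nonnegative float lattices, FIELD_NAMES keys
    immune_agents: ImmuneAgents
    infection_age: np.ndarray  # ticks since infection, per site (0 if not infected)
    apoptosed_by_virus: int = 0

    def copy(self) -> "InfectionMicrostate":
        return InfectionMicrostate(
            self.epithelium.copy(),
            self.endothelium.copy(),
            {k: v.copy() for k, v in self.fields.items()},
            self.immune_agents.copy(),
            self.infection_age.copy(),
            self.apoptosed_by_virus,
        )

    def validate(self, params: InfectionParams) -> None:
        s = params.lattice_side
        if self.epithelium.shape != (s, s) or self.endothelium.shape != (s, s):
            raise ValueError("lattice shape mismatch")
        if self.epithelium.min() < 0 or self.epithelium.max() >= len(EPITHELIAL_LABELS):
            raise ValueError("invalid epithelial label")
        if self.endothelium.min() < 0 or self.endothelium.max() >= len(ENDOTHELIAL_LABELS):
            raise ValueError("invalid endothelial label")
        if set(self.fields) != set(FIELD_NAMES):
            raise ValueError("field roster mismatch")
        for name, f in self.fields.items():
            if f.shape != (s, s) or f.min() < 0:
                raise ValueError(f"field {name} invalid")
        if len(self.immune_agents) and (
            self.immune_agents.pos.min() < 0 or self.immune_agents.pos.max() >= s
        ):
            raise ValueError("immune agent outside the lattice")


def infection_schema(lattice_side: int) -> MacroSchema:
    """Fixed macrostate order: the 10 field totals, 5 epithelial counts,
    3 endothelial counts, 4 immune-agent counts, virus-apoptosis tally."""
    n = lattice_side**2
    variables = [Variable(f"total_{f}", kind="real") for f in FIELD_NAMES]
    variables += [
        Variable(f"epi_{lab}", kind="count", sum_group="epithelium")
        for lab in EPITHELIAL_LABELS
    ]
    variables += [
        Variable(f"endo_{lab}", kind="count", sum_group="endothelium")
        for lab in ENDOTHELIAL_LABELS
    ]
    variables += [Variable(f"n_{t}", kind="count") for t in IMMUNE_TYPES]
    variables.append(Variable("apoptosed_by_virus", kind="count"))
    return MacroSchema(
        variables=tuple(variables),
        sum_totals={"epithelium": n, "endothelium": n},
    )


def init_infection(params: InfectionParams, seed: int) -> InfectionMicrostate:
    """All-healthy tissue with one infected disc at a random center, virus
    seeded inside the disc, quiescent endothelium, no immune agents."""
    rng = np.random.default_rng(seed)
    s = params.lattice_side
    r = params.initial_infected_focus_radius
    epithelium = np.full((s, s), EPI_HEALTHY, dtype=np.int64)
    endothelium = np.full((s, s), ENDO_NORMAL, dtype=np.int64)
    fields = {name: np.zeros((s, s)) for name in FIELD_NAMES}
    cr, cc = rng.integers(r, s - r, size=2)
    rows, cols = np.ogrid[:s, :s]
    disc = (rows - cr) ** 2 + (cols - cc) ** 2 <= r**2
    epithelium[disc] = EPI_INFECTED
    fields["virus"][disc] = 1.0
    infection_age = np.zeros((s, s), dtype=np.int64)
    return InfectionMicrostate(
        epithelium, endothelium, fields, ImmuneAgents.empty(), infection_age, 0
    )


def diffuse_reflect(f: np.ndarray, coeff: float) -> np.ndarray:
    """One explicit step of the 5-point discrete Laplacian with reflecting
    boundaries.  Conserves the lattice total (no flux through walls)."""
    if coeff == 0.0:
        return f.copy()
    p = np.pad(f, 1, mode="edge")
    lap = p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:] - 4.0 * f
    return f + coeff * lap


def _agent_patches(agents: ImmuneAgents, side: int) -> tuple[np.ndarray, np.ndarray]:
    r = np.floor(agents.pos[:, 1]).astype(np.int64)
    c = np.floor(agents.pos[:, 0]).astype(np.int64)
    return r, c


def step_infection(
    state: InfectionMicrostate, params: InfectionParams, rng: np.random.Generator
) -> InfectionMicrostate:
    """Advance one tick.

    Phases: field transport (diffuse, decay, secrete) -> viral infection of
    healthy sites -> infected-site fate (timer apoptosis, NK killing,
    necrosis at high virus) -> endothelial activation/death by local
    pro-inflammatory signal -> immune recruitment, chemotactic movement and
    clearance.
    """
    s = params.lattice_side
    epi = state.epithelium.copy()
    endo = state.endothelium.copy()
    age = state.infection_age.copy()
    tally = state.apoptosed_by_virus
    agents = state.immune_agents.copy()

    # (1) fields: diffuse, decay, secrete
    fields: dict[str, np.ndarray] = {}
    infected_mask = epi == EPI_INFECTED
    ar, ac = _agent_patches(agents, s)
    for name in FIELD_NAMES:
        f = diffuse_reflect(state.fields[name], params.diffusion)
        f *= 1.0 - params.decay
        if name in _INFECTED_SECRETES:
            f[infected_mask] += params.secretion
        fields[name] = f
    for code, tname in enumerate(IMMUNE_TYPES):
        sel = agents.type_code == code
        if sel.any():
            for species in _IMMUNE_SECRETES[tname]:
                np.add.at(fields[species], (ar[sel], ac[sel]), params.secretion)
    for f in fields.values():
        np.maximum(f, 0.0, out=f)

    # (2) infection of healthy sites by local virus
    virus = fields["virus"]
    healthy = epi == EPI_HEALTHY
    p_inf = 1.0 - np.exp(-params.infection_prob_per_unit_virus * virus)
    newly_infected = healthy & (rng.uniform(size=(s, s)) < p_inf)
    epi[newly_infected] = EPI_INFECTED
    age[newly_infected] = 0

    # (3) fate of infected sites (pre-existing infections age first)
    infected_mask = (epi == EPI_INFECTED) & ~newly_infected
    age[infected_mask] += 1
    timed_out = infected_mask & (age >= params.apoptosis_timer)
    epi[timed_out] = EPI_APOPTOSED
    tally += int(timed_out.sum())
    age[timed_out] = 0

    # NK contact killing (apoptosis by immune attack, not counted in the
    # virus-apoptosis tally)
    nk = agents.type_code == IMMUNE_TYPES.index("NK")
    if nk.any():
        still_infected = epi == EPI_INFECTED
        kill_sites = np.zeros((s, s), dtype=bool)
        contact = still_infected[ar[nk], ac[nk]]
        draws = rng.uniform(size=int(nk.sum())) < params.immune_kill_prob
        kr, kc = ar[nk][contact & draws], ac[nk][contact & draws]
        kill_sites[kr, kc] = True
        epi[kill_sites] = EPI_APOPTOSED
        age[kill_sites] = 0

    necrosed = (epi == EPI_INFECTED) & (virus > params.necrosis_virus_threshold)
    epi[necrosed] = EPI_NECROSED
    age[necrosed] = 0

    # (4) endothelial response to local pro-inflammatory signal
    signal = fields["TNF"] + fields["IL1"] + fields["IL6"]
    thr = params.endothelial_activation_threshold
    endo[(endo == ENDO_NORMAL) & (signal > thr)] = ENDO_ACTIVATED
    endo[(endo == ENDO_ACTIVATED) & (signal > params.endothelial_death_factor * thr)] = (
        ENDO_DEAD
    )

    # (5) immune agents: age, clear, recruit at activated endothelium, move
    # up the virus+PDAMPs gradient
    agents.age += 1
    agents = agents.subset(agents.age <= params.immune_lifespan)

    activated = np.argwhere(endo == ENDO_ACTIVATED)
    if len(activated) and params.recruitment_rate > 0:
        n_new = rng.poisson(params.recruitment_rate * len(activated))
        if n_new > 0:
            sites = activated[rng.integers(0, len(activated), size=n_new)]
            jitter = rng.uniform(0.0, 1.0, size=(n_new, 2))
            pos = np.column_stack([sites[:, 1] + jitter[:, 0], sites[:, 0] + jitter[:, 1]])
            new = ImmuneAgents(
                rng.integers(0, len(IMMUNE_TYPES), size=n_new),
                pos,
                rng.uniform(-np.pi, np.pi, size=n_new),
                np.zeros(n_new, dtype=np.int64),
            )
            agents = agents.extend(new)

    if len(agents):
        chemo = fields["virus"] + fields["PDAMPs"]
        gy, gx = np.gradient(chemo)
        ar, ac = _agent_patches(agents, s)
        gvec = np.column_stack([gx[ar, ac], gy[ar, ac]])
        norms = np.linalg.norm(gvec, axis=1, keepdims=True)
        bias = np.where(norms > 1e-12, gvec / np.maximum(norms, 1e-12), 0.0)
        heading = rng.uniform(-np.pi, np.pi, size=len(agents))
        step = np.stack([np.cos(heading), np.sin(heading)], axis=1) + bias
        step /= np.maximum(np.linalg.norm(step, axis=1, keepdims=True), 1e-12)
        pos = np.clip(agents.pos + step, 0.0, s - 1e-9)
        agents = ImmuneAgents(agents.type_code, pos, heading, agents.age)

    return InfectionMicrostate(epi, endo, fields, agents, age, tally)


def summarize_infection(state: InfectionMicrostate) -> Macrostate:
    """Macrostate in the documented fixed order (see infection_schema)."""
    side = state.epithelium.shape[0]
    schema = infection_schema(side)
    values = [float(state.fields[f].sum()) for f in FIELD_NAMES]
    values += list(np.bincount(state.epithelium.reshape(-1), minlength=5))
    values += list(np.bincount(state.endothelium.reshape(-1), minlength=3))
    values += list(state.immune_agents.counts())
    values.append(state.apoptosed_by_virus)
    return Macrostate(schema, values)
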