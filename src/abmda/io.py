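"""Serialization: microstate snapshots to HDF5, macro trajectories to CSV.

Categorical lattices are stored as small-int arrays with their label legend
as an attribute; agent populations as column datasets; fields as float
arrays.  Trajectory CSVs carry a ``tick`` column followed by the schema's
variable names.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .infection import (
    ENDOTHELIAL_LABELS,
    EPITHELIAL_LABELS,
    FIELD_NAMES,
    IMMUNE_TYPES,
    ImmuneAgents,
    InfectionMicrostate,
)
from .wsg import AgentSet, WSGMicrostate

__all__ = [
    "save_wsg_state",
    "load_wsg_state",
    "save_infection_state",
    "load_infection_state",
    "save_macro_trajectory",
    "load_macro_trajectory",
]


def _write_agents(group: h5py.Group, agents: AgentSet) -> None:
    group.create_dataset("pos", data=agents.pos)
    group.create_dataset("heading", data=agents.heading)
    group.create_dataset("energy", data=agents.energy)


def _read_agents(group: h5py.Group) -> AgentSet:
    return AgentSet(group["pos"][...], group["heading"][...], group["energy"][...])


def save_wsg_state(path: str | Path, state: WSGMicrostate) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["model"] = "wsg"
        _write_agents(f.create_group("wolves"), state.wolves)
        _write_agents(f.create_group("sheep"), state.sheep)
        f.create_dataset("grass", data=state.grass)
        f.create_dataset("regrowth", data=state.regrowth)


def load_wsg_state(path: str | Path) -> WSGMicrostate:
    with h5py.File(path, "r") as f:
        if f.attrs.get("model") != "wsg":
            raise ValueError("not a WSG snapshot")
        return WSGMicrostate(
            _read_agents(f["wolves"]),
            _read_agents(f["sheep"]),
            f["grass"][...].astype(bool),
            f["regrowth"][...].astype(np.int64),
        )


def save_infection_state(path: str | Path, state: InfectionMicrostate) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["model"] = "infection"
        epi = f.create_dataset("epithelium", data=state.epithelium.astype(np.int8))
        epi.attrs["labels"] = list(EPITHELIAL_LABELS)
        endo = f.create_dataset("endothelium", data=state.endothelium.astype(np.int8))
        endo.attrs["labels"] = list(ENDOTHELIAL_LABELS)
        fg = f.create_group("fields")
        for name in FIELD_NAMES:
            fg.create_dataset(name, data=state.fields[name])
        ag = f.create_group("immune_agents")
        ag.attrs["types"] = list(IMMUNE_TYPES)
        ag.create_dataset("type_code", data=state.immune_agents.type_code)
        ag.create_dataset("pos", data=state.immune_agents.pos)
        ag.create_dataset("heading", data=state.immune_agents.heading)
        ag.create_dataset("age", data=state.immune_agents.age)
        f.create_dataset("infection_age", data=state.infection_age)
        f.attrs["apoptosed_by_virus"] = int(state.apoptosed_by_virus)


def load_infection_state(path: str | Path) -> InfectionMicrostate:
    with h5py.File(path, "r") as f:
        if f.attrs.get("model") != "infection":
            raise ValueError("not an infection snapshot")
        agents = ImmuneAgents(
            f["immune_agents/type_code"][...],
            f["immune_agents/pos"][...],
            f["immune_agents/heading"][...],
            f["immune_agents/age"][...],
        )
        return InfectionMicrostate(
            f["epithelium"][...].astype(np.int64),
            f["endothelium"][...].astype(np.int64),
            {name: f[f"fields/{name}"][...] for name in FIELD_NAMES},
            agents,
            f["infection_age"][...].astype(np.int64),
            int(f.attrs["apoptosed_by_virus"]),
        )


def save_macro_trajectory(
    path: str | Path, trajectory: np.ndarray, names: tuple[str, ...]
) -> None:
    df = pd.DataFrame(np.asarray(trajectory), columns=list(names))
    df.insert(0, "tick", np.arange(len(df)))
    df.to_csv(path, index=False)


def load_macro_trajectory(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
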