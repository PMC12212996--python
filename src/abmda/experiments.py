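"""Twin-experiment driver: the macrostate predict/update loop.

A *twin experiment* simulates a "virtual patient" truth trajectory with
fixed parameters, derives noisy partial observations from it, and runs the
assimilation loop against those observations so the filter's recovery of
the (known) truth can be scored.

The loop per observation time:

1. advance every ensemble member's microstate with the model;
2. summarize microstates to macrostates and map to filter space (appending
   each member's transformed parameters — parameter augmentation);
3. EnKF-update the member vectors with the perturbed observation, fit the
   Gaussian posterior;
4. sample a fresh macrostate ensemble from the posterior;
5. pair posterior samples with predictive members (stable matching on
   filter-space distance) and synthesize a compatible microstate for each
   member from its own predictive microstate.

Between updates each member's transformed parameters take an additive
N(0, Q) random-walk step; the truth's parameters never move.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import infection as inf
from . import wsg
from .enkf import ObservationSpec, enkf_update, fit_gaussian, perturb_parameters, sample_posterior
from .evaluation import TrajectoryRecord, surprisal
from .macrostate import (
    Identity,
    LogEps,
    Macrostate,
    Scale,
    TransformSpec,
    forward_transform,
    inverse_transform,
)
from .synthesis import QuantizationConfig, stable_match, synthesize_infection

__all__ = [
    "RunConfig",
    "ExperimentResult",
    "wsg_transform_spec",
    "infection_transform_spec",
    "run_assimilation",
    "tuning_sweep",
    "make_fixtures",
]


def wsg_transform_spec(
    world_size: int, augment: tuple[str, ...] = ("wolf_reproduce_prob",)
) -> TransformSpec:
    """Filter-space maps for the WSG macrostate: log(eps + wolves) with
    eps = 0.001 (extinctions concentrate wolf counts at zero), sheep scaled
    by 0.1 and grass by 0.01 to keep all variables in similar ranges.
    Augmented parameters are log-transformed (they are strictly positive
    rates of wolf-count magnitude on the log scale)."""
    schema = wsg.wsg_schema(world_size)
    return TransformSpec(
        schema=schema,
        transforms=(LogEps(1e-3), Scale(0.1), Scale(0.01)),
        param_names=tuple(augment),
        param_transforms=tuple(LogEps(1e-9) for _ in augment),
    )


def infection_transform_spec(
    lattice_side: int, augment: tuple[str, ...] = ("infection_prob_per_unit_virus",)
) -> TransformSpec:
    """Filter-space maps for the infection macrostate: log(eps + x) for the
    field totals and the virus-apoptosis tally (orders of magnitude apart,
    concentrated near zero early on), counts scaled to O(1)."""
    schema = inf.infection_schema(lattice_side)
    n = lattice_side**2
    transforms: list = []
    for v in schema.variables:
        if v.name.startswith("total_") or v.name == "apoptosed_by_virus":
            transforms.append(LogEps(1e-3))
        elif v.name.startswith(("epi_", "endo_")):
            transforms.append(Scale(10.0 / n))
        else:
            transforms.append(Identity())
    return TransformSpec(
        schema=schema,
        transforms=tuple(transforms),
        param_names=tuple(augment),
        param_transforms=tuple(LogEps(1e-9) for _ in augment),
    )


@dataclass
class RunConfig:
    """Everything needed to reproduce one twin experiment."""

    model: str = "wsg"
    params: wsg.WSGParams | inf.InfectionParams = field(default_factory=wsg.WSGParams)
    n_ticks: int = 300
    obs: ObservationSpec = field(
        default_factory=lambda: ObservationSpec(("sheep",), (0.01,), interval=50)
    )
    ensemble_size: int = 20
    Q: float = 0.01
    seed: int = 0
    # Gaussian prior in transformed space for the augmented parameters:
    # name -> (mean, sd).  Defaults to mean at the config value, sd 0.3.
    param_prior: dict[str, tuple[float, float]] | None = None
    # ensemble spread of the initial transformed macrostate around the
    # reference initialization, per variable (scalar -> shared)
    macro_prior_sd: float = 0.1
    spec: TransformSpec | None = None
    quantization: QuantizationConfig = field(default_factory=QuantizationConfig)

    def resolved_spec(self) -> TransformSpec:
        if self.spec is not None:
            return self.spec
        if self.model == "wsg":
            return wsg_transform_spec(self.params.world_size)
        if self.model == "infection":
            return infection_transform_spec(self.params.lattice_side)
        raise ValueError(f"unknown model {self.model!r}")


@dataclass
class ExperimentResult:
    config: RunConfig
    truth: TrajectoryRecord
    members: list[TrajectoryRecord]
    diagnostics: pd.DataFrame  # tick, surprisal_prior, surprisal_post (NaN off-update)
    param_history: pd.DataFrame  # tick, member, name, value (raw space)
    truth_params: dict[str, float]


class _ModelOps:
    """Uniform facade over the two models for the driver loop."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.model = config.model
        if self.model not in ("wsg", "infection"):
            raise ValueError(f"unknown model {self.model!r}")

    def init(self, params, seed: int):
        if self.model == "wsg":
            return wsg.init_wsg(params, seed)
        return inf.init_infection(params, seed)

    def step(self, state, params, rng):
        if self.model == "wsg":
            return wsg.step_wsg(state, params, rng)
        return inf.step_infection(state, params, rng)

    def summarize(self, state) -> Macrostate:
        if self.model == "wsg":
            return wsg.summarize_wsg(state)
        return inf.summarize_infection(state)

    def synthesize(self, target: Macrostate, seed_state, params, rng):
        if self.model == "wsg":
            return wsg.synthesize_wsg(target, seed_state, params, rng)
        return synthesize_infection(target, seed_state, self.config.quantization, rng)


def _apply_params(base, updates: dict[str, float]):
    return replace(base, **updates)


def run_assimilation(config: RunConfig) -> ExperimentResult:
    """Run one twin experiment; see the module docstring for the loop."""
    ops = _ModelOps(config)
    spec = config.resolved_spec()
    names = spec.schema.names + spec.param_names
    H = config.obs.selection_matrix(names)
    R = config.obs.R

    ss = np.random.SeedSequence(config.seed)
    truth_seed, obs_seed, filt_seed = ss.spawn(3)
    member_seeds = ss.spawn(config.ensemble_size)
    truth_rng = np.random.default_rng(truth_seed)
    obs_rng = np.random.default_rng(obs_seed)
    filt_rng = np.random.default_rng(filt_seed)

    truth_params = config.params
    truth_param_dict = {n: float(getattr(truth_params, n)) for n in spec.param_names}
    truth_state = ops.init(truth_params, int(truth_rng.integers(2**31)))

    # --- ensemble initialization from the prior -----------------------------
    prior = dict(config.param_prior or {})
    for name in spec.param_names:
        if name not in prior:
            t = spec.param_transforms[spec.param_names.index(name)]
            prior[name] = (float(t.forward(getattr(config.params, name))), 0.3)

    member_states, member_params, member_rngs = [], [], []
    ref_macro_vec = forward_transform(ops.summarize(truth_state), spec)
    for i in range(config.ensemble_size):
        m_rng = np.random.default_rng(member_seeds[i])
        member_rngs.append(m_rng)
        draws = {
            name: float(
                spec.param_transforms[spec.param_names.index(name)].inverse(
                    m_rng.normal(mu, sd)
                )
            )
            for name, (mu, sd) in prior.items()
        }
        p_i = _apply_params(config.params, draws)
        member_params.append(p_i)
        state_i = ops.init(p_i, int(m_rng.integers(2**31)))
        # spread the initial macrostate around the reference in filter space
        vec0 = ref_macro_vec + m_rng.normal(
            0.0, config.macro_prior_sd, size=spec.macro_dim
        )
        macro0 = inverse_transform(vec0, spec)
        member_states.append(ops.synthesize(macro0, state_i, p_i, m_rng))

    T, n = config.n_ticks, config.ensemble_size
    V = spec.macro_dim
    truth_traj = np.empty((T + 1, V))
    member_traj = np.empty((n, T + 1, V))
    truth_traj[0] = ops.summarize(truth_state).values
    for i in range(n):
        member_traj[i, 0] = ops.summarize(member_states[i]).values

    diag_rows = []
    param_rows = []

    def _log_params(tick: int) -> None:
        for i, p in enumerate(member_params):
            for name in spec.param_names:
                param_rows.append((tick, i, name, float(getattr(p, name))))

    _log_params(0)

    for t in range(1, T + 1):
        truth_state = ops.step(truth_state, truth_params, truth_rng)
        truth_traj[t] = ops.summarize(truth_state).values
        macros = []
        for i in range(n):
            member_states[i] = ops.step(member_states[i], member_params[i], member_rngs[i])
            m = ops.summarize(member_states[i])
            member_traj[i, t] = m.values
            macros.append(m)

        X = np.stack(
            [
                forward_transform(
                    macros[i],
                    spec,
                    {nm: getattr(member_params[i], nm) for nm in spec.param_names},
                )
                for i in range(n)
            ]
        )
        truth_vec = forward_transform(
            Macrostate(spec.schema, truth_traj[t]), spec, truth_param_dict
        )
        s_prior = surprisal(truth_vec, fit_gaussian(X))

        if t % config.obs.interval == 0:
            # forecast-phase process noise: parameter random-walk step in
            # transformed space (ensemble only; the truth never moves)
            X[:, spec.param_slice] = perturb_parameters(
                X[:, spec.param_slice], config.Q, filt_rng
            )
            y = H @ truth_vec + obs_rng.multivariate_normal(np.zeros(H.shape[0]), R)
            Xp = enkf_update(X, y, H, R, filt_rng)
            belief = fit_gaussian(Xp)
            s_post = surprisal(truth_vec, belief)
            samples = sample_posterior(belief, n, filt_rng)
            dist = np.linalg.norm(X[:, None, :] - samples[None, :, :], axis=2)
            perm = stable_match(dist)
            new_states, new_params = [], []
            for i in range(n):
                vec = samples[perm[i]]
                target = inverse_transform(vec, spec)
                p_new = _apply_params(
                    member_params[i], spec.inverse_params(vec[spec.param_slice])
                )
                try:
                    state_new = ops.synthesize(
                        target, member_states[i], p_new, member_rngs[i]
                    )
                except (ValueError, AssertionError):
                    # infeasible target for this seed state: resample and
                    # retry once from the posterior, else keep the forecast
                    vec = sample_posterior(belief, 1, filt_rng)[0]
                    target = inverse_transform(vec, spec)
                    p_new = _apply_params(
                        member_params[i], spec.inverse_params(vec[spec.param_slice])
                    )
                    try:
                        state_new = ops.synthesize(
                            target, member_states[i], p_new, member_rngs[i]
                        )
                    except (ValueError, AssertionError):
                        state_new, p_new = member_states[i], member_params[i]
                new_states.append(state_new)
                new_params.append(p_new)
            member_states, member_params = new_states, new_params
            for i in range(n):
                member_traj[i, t] = ops.summarize(member_states[i]).values
            diag_rows.append((t, s_prior, s_post))
            _log_params(t)
        else:
            diag_rows.append((t, s_prior, np.nan))

    truth_rec = TrajectoryRecord("truth", truth_param_dict, truth_traj, role="truth")
    member_recs = [
        TrajectoryRecord(
            f"member_{i}",
            {nm: float(getattr(member_params[i], nm)) for nm in spec.param_names},
            member_traj[i],
        )
        for i in range(n)
    ]
    diagnostics = pd.DataFrame(
        diag_rows, columns=["tick", "surprisal_prior", "surprisal_post"]
    )
    param_history = pd.DataFrame(
        param_rows, columns=["tick", "member", "name", "value"]
    )
    return ExperimentResult(
        config=config,
        truth=truth_rec,
        members=member_recs,
        diagnostics=diagnostics,
        param_history=param_history,
        truth_params=truth_param_dict,
    )


def tuning_sweep(
    config: RunConfig,
    measured_variable: str,
    R_levels: list[float],
    n_replicates: int,
    seed: int = 0,
    include_control: bool = False,
) -> pd.DataFrame:
    """Median surprisal per tick for each measurement-noise level.

    Each replicate is a fresh twin experiment whose truth parametrization is
    drawn from the ensemble prior.  With ``include_control`` an extra
    condition labelled R = inf runs the same replicates with no updates
    (pure forecast).
    """
    if not R_levels:
        raise ValueError("R_levels must be non-empty")
    spec = config.resolved_spec()
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.spawn(n_replicates)
    levels: list[float] = list(R_levels) + ([np.inf] if include_control else [])
    frames = []
    for R in levels:
        all_surprisal = []
        for rep in range(n_replicates):
            rep_rng = np.random.default_rng(rep_seeds[rep])
            prior = dict(config.param_prior or {})
            for name in spec.param_names:
                if name not in prior:
                    tr = spec.param_transforms[spec.param_names.index(name)]
                    prior[name] = (float(tr.forward(getattr(config.params, name))), 0.3)
            truth_draw = {
                name: float(
                    spec.param_transforms[spec.param_names.index(name)].inverse(
                        rep_rng.normal(mu, sd)
                    )
                )
                for name, (mu, sd) in prior.items()
            }
            params = _apply_params(config.params, truth_draw)
            if np.isinf(R):
                obs = replace(config.obs, interval=config.n_ticks + 1)
            else:
                obs = replace(
                    config.obs,
                    observed=(measured_variable,),
                    noise_var=(float(R),),
                )
            cfg = replace(
                config,
                params=params,
                obs=obs,
                seed=int(rep_rng.integers(2**31)),
            )
            res = run_assimilation(cfg)
            s = res.diagnostics["surprisal_post"].where(
                res.diagnostics["surprisal_post"].notna(),
                res.diagnostics["surprisal_prior"],
            )
            all_surprisal.append(s.to_numpy())
        med = np.median(np.stack(all_surprisal), axis=0)
        frames.append(
            pd.DataFrame(
                {
                    "tick": np.arange(1, config.n_ticks + 1),
                    "R": R,
                    "median_surprisal": med,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def make_fixtures(seed: int = 0) -> dict:
    """Tiny seeded instances used by the test-suite and docs: a 16x16 WSG
    state, a 16x16 infection state, and an 8-member WSG prior ensemble."""
    wsg_params = wsg.WSGParams(
        world_size=16, init_wolves=8, init_sheep=24, init_grass_density=0.5
    )
    inf_params = inf.InfectionParams(lattice_side=16, initial_infected_focus_radius=2)
    wsg_state = wsg.init_wsg(wsg_params, seed)
    inf_state = inf.init_infection(inf_params, seed + 1)
    ensemble = [wsg.init_wsg(wsg_params, seed + 10 + i) for i in range(8)]
    return {
        "wsg_params": wsg_params,
        "wsg_state": wsg_state,
        "infection_params": inf_params,
        "infection_state": inf_state,
        "wsg_ensemble": ensemble,
    }
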