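"""Microstate synthesis: turning posterior macrostates back into full states.

The filter update produces new macrostates, but the model needs complete
microstates to advance.  Synthesis exploits two principles: *continuity*
(nearby macrostates admit nearby microstates, so each posterior sample is
paired with the closest predictive microstate and edited minimally) and
*local similarity* (sites with similar neighbourhoods should evolve
similarly, so categorical edits should respect existing spatial structure).

For continuous lattice fields, multiplicative rescaling to the new total
preserves spatial correlations exactly.  For categorical lattices two
algorithms are provided:

* :func:`random_cell_update` — relabel uniformly chosen sites; minimal in
  the number of changed sites but blind to geometry, so it seeds spurious
  new hot-spots.
* the spatially aware pipeline — one-hot encode the lattice, rescale the
  category weights to the new counts, then quantize site by site under a
  three-term loss (quantization error, neighbourhood dissimilarity,
  neighbourhood log-probability from previous runs) while diffusing each
  site's quantization error onto its not-yet-quantized neighbours so the
  global counts are conserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .infection import (
    ENDOTHELIAL_LABELS,
    ENDO_ACTIVATED,
    EPI_INFECTED,
    EPITHELIAL_LABELS,
    FIELD_NAMES,
    IMMUNE_TYPES,
    ImmuneAgents,
    InfectionMicrostate,
    summarize_infection,
)
from .macrostate import Macrostate, TransformSpec, forward_transform

__all__ = [
    "OneHotField",
    "QuantizationConfig",
    "NeighborhoodModel",
    "match_pairs",
    "stable_match",
    "scale_field",
    "random_cell_update",
    "one_hot_encode",
    "one_hot_decode",
    "rescale_one_hot",
    "quantize_diffuse",
    "fit_neighborhood_model",
    "virus_bin",
    "synthesize_infection",
]


# ---------------------------------------------------------------------------
# Ensemble pairing


def stable_match(dist: np.ndarray) -> np.ndarray:
    """Gale-Shapley stable matching on a square distance matrix.

    Row i (proposer) and column j (responder) both rank partners by
    increasing ``dist[i, j]``, ties broken by lowest index.  Returns ``perm``
    with ``perm[i]`` the column matched to row i.  Proposer-optimal among
    stable matchings, deterministic.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n):
        raise ValueError("distance matrix must be square")
    # preference lists: columns sorted by distance then index
    idx = np.arange(n)
    prop_pref = np.array([np.lexsort((idx, dist[i]))for i in range(n)])
    # responder ranking of proposers: rank[j, i] = position of i in j's list
    resp_rank = np.empty((n, n), dtype=np.int64)
    for j in range(n):
        order = np.lexsort((idx, dist[:, j]))
        resp_rank[j, order] = idx
    next_choice = np.zeros(n, dtype=np.int64)
    engaged_to = np.full(n, -1, dtype=np.int64)  # responder -> proposer
    free = list(range(n - 1, -1, -1))
    while free:
        p = free.pop()
        j = prop_pref[p, next_choice[p]]
        next_choice[p] += 1
        cur = engaged_to[j]
        if cur == -1:
            engaged_to[j] = p
        elif resp_rank[j, p] < resp_rank[j, cur]:
            engaged_to[j] = p
            free.append(cur)
        else:
            free.append(p)
    perm = np.empty(n, dtype=np.int64)
    perm[engaged_to] = idx
    return perm


def match_pairs(
    predicted: list[Macrostate],
    posterior: list[Macrostate],
    spec: TransformSpec,
) -> np.ndarray:
    """Pair posterior macrostates with predictive ones, minimizing pairwise
    change: a stable matching under Euclidean distance in transformed space,
    with the predicted side proposing.  Returns ``perm`` with ``perm[i]``
    the posterior index assigned to predicted member i."""
    if len(predicted) != len(posterior):
        raise ValueError("predicted and posterior lists must have equal length")
    if len(predicted) == 0:
        raise ValueError("empty ensembles cannot be matched")
    A = np.stack([forward_transform(m, spec) for m in predicted])
    B = np.stack([forward_transform(m, spec) for m in posterior])
    dist = np.linalg.norm(A[:, None, :] - B[None, :, :], axis=2)
    return stable_match(dist)


# ---------------------------------------------------------------------------
# Continuous fields


def scale_field(field_arr: np.ndarray, new_total: float) -> np.ndarray:
    """Rescale a nonnegative lattice field to a new total, preserving its
    spatial correlations.  A zero field receiving positive mass is filled
    uniformly (no spatial information exists to preserve)."""
    f = np.asarray(field_arr, dtype=float)
    if new_total < 0:
        raise ValueError("new_total must be nonnegative")
    old_total = f.sum()
    if old_total > 0:
        return f * (new_total / old_total)
    out = np.full_like(f, new_total / f.size)
    return out


# ---------------------------------------------------------------------------
# Categorical lattices — simple random-cell update


def random_cell_update(
    lattice: np.ndarray, target_counts: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Reach the target category counts by relabelling uniformly chosen
    sites; changes exactly sum(max(0, current - target)) sites, the L1
    minimum, but ignores spatial structure."""
    lattice = np.asarray(lattice)
    target = np.asarray(target_counts, dtype=np.int64)
    k = len(target)
    if np.any(target < 0):
        raise ValueError("negative target count")
    if int(target.sum()) != lattice.size:
        raise ValueError("target counts must sum to the lattice size")
    current = np.bincount(lattice.reshape(-1), minlength=k)[:k]
    out = lattice.copy().reshape(-1)
    surplus_sites: list[np.ndarray] = []
    for cat in range(k):
        excess = int(current[cat] - target[cat])
        if excess > 0:
            sites = np.flatnonzero(out == cat)
            surplus_sites.append(rng.choice(sites, size=excess, replace=False))
    if surplus_sites:
        pool = np.concatenate(surplus_sites)
        rng.shuffle(pool)
        deficits = np.repeat(
            np.arange(k), np.maximum(target - current[:k], 0)
        )
        rng.shuffle(deficits)
        out[pool] = deficits
    return out.reshape(lattice.shape)


# ---------------------------------------------------------------------------
# One-hot encoding


@dataclass
class OneHotField:
    """Lattice of nonnegative category-weight vectors, shape (R, C, k)."""

    data: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != len(self.labels):
            raise ValueError("data must be (rows, cols, n_categories)")
        if self.data.min() < 0:
            raise ValueError("one-hot field entries must be nonnegative")

    @property
    def counts(self) -> np.ndarray:
        """Per-category lattice sums — the categorical macrostate."""
        return self.data.sum(axis=(0, 1))


def one_hot_encode(lattice: np.ndarray, labels: tuple[str, ...]) -> OneHotField:
    """Map each categorical site label to its standard basis vector, so
    category counts become the column sums of the encoded field."""
    lattice = np.asarray(lattice)
    k = len(labels)
    if lattice.min() < 0 or lattice.max() >= k:
        raise ValueError("lattice contains labels outside the legend")
    data = np.zeros(lattice.shape + (k,))
    rows, cols = np.indices(lattice.shape)
    data[rows, cols, lattice] = 1.0
    return OneHotField(data, tuple(labels))


def one_hot_decode(field_: OneHotField, atol: float = 1e-9) -> np.ndarray:
    """Inverse of :func:`one_hot_encode`; raises unless every site vector is
    exactly one-hot (within ``atol``)."""
    data = field_.data
    arg = data.argmax(axis=2)
    rows, cols = np.indices(arg.shape)
    expect = np.zeros_like(data)
    expect[rows, cols, arg] = 1.0
    if not np.allclose(data, expect, atol=atol):
        raise ValueError("field is not one-hot; quantize before decoding")
    return arg.astype(np.int64)


def rescale_one_hot(
    field_: OneHotField, old_counts: np.ndarray, new_counts: np.ndarray
) -> OneHotField:
    """Componentwise multiplication of every site vector by the count ratios
    (new/old per category), so the column sums land exactly on the new
    counts.  A category growing from zero has no spatial support to scale;
    its mass is deposited uniformly across all sites."""
    old = np.asarray(old_counts, dtype=float)
    new = np.asarray(new_counts, dtype=float)
    if not np.allclose(field_.counts, old, atol=1e-6):
        raise ValueError("old_counts do not match the field's column sums")
    if not np.isclose(old.sum(), new.sum(), rtol=1e-9, atol=1e-6):
        raise ValueError("rescaling cannot change the total site count")
    if np.any(new < 0):
        raise ValueError("negative target count")
    ratio = np.ones_like(old)
    nonzero = old > 0
    ratio[nonzero] = new[nonzero] / old[nonzero]
    data = field_.data * ratio[None, None, :]
    born = (~nonzero) & (new > 0)
    if born.any():
        size = field_.data.shape[0] * field_.data.shape[1]
        data[:, :, born] = new[born] / size
    return OneHotField(data, field_.labels)


# ---------------------------------------------------------------------------
# Neighbourhood likelihood model


def virus_bin(v: float) -> int:
    """Discretize a local virus level: bin 0 for zero, then decade bins."""
    if v <= 0:
        return 0
    return 1 + int(np.clip(np.floor(np.log10(v)) + 4, 0, 8))


@dataclass
class NeighborhoodModel:
    """Laplace-smoothed frequency table of discretized neighbourhood
    patterns (center category, 8-neighbour category count vector, log-binned
    local virus), scored by negative log probability.  Biases quantization
    toward configurations observed in previous model runs."""

    counts: dict[tuple, int]
    total: int
    n_categories: int
    alpha: float = 1.0

    def score(self, center: int, neighbor_counts: tuple[int, ...], vbin: int) -> float:
        key = (center, neighbor_counts, vbin)
        c = self.counts.get(key, 0)
        denom = self.total + self.alpha * (len(self.counts) + 1)
        return -float(np.log((c + self.alpha) / denom))


def _neighbor_count_vector(
    lattice: np.ndarray, r: int, c: int, k: int, mask: np.ndarray | None = None
) -> np.ndarray:
    """Category counts over the (up to 8) neighbours of (r, c); when
    ``mask`` is given only sites where it is True contribute."""
    rows, cols = lattice.shape
    out = np.zeros(k, dtype=np.int64)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            rr, cc = r + dr, c + dc
            if 0 <= rr < rows and 0 <= cc < cols:
                if mask is None or mask[rr, cc]:
                    out[lattice[rr, cc]] += 1
    return out


def fit_neighborhood_model(
    snapshots: list[InfectionMicrostate],
    alpha: float = 1.0,
    which: str = "epithelium",
) -> NeighborhoodModel:
    """Tabulate neighbourhood patterns over a library of model snapshots."""
    if not snapshots:
        raise ValueError("need at least one snapshot")
    labels = EPITHELIAL_LABELS if which == "epithelium" else ENDOTHELIAL_LABELS
    k = len(labels)
    counts: dict[tuple, int] = {}
    total = 0
    for snap in snapshots:
        lattice = getattr(snap, which)
        virus = snap.fields["virus"]
        rows, cols = lattice.shape
        for r in range(rows):
            for c in range(cols):
                nc = tuple(_neighbor_count_vector(lattice, r, c, k))
                key = (int(lattice[r, c]), nc, virus_bin(float(virus[r, c])))
                counts[key] = counts.get(key, 0) + 1
                total += 1
    return NeighborhoodModel(counts=counts, total=total, n_categories=k, alpha=alpha)


# ---------------------------------------------------------------------------
# Quantization with error diffusion


@dataclass
class QuantizationConfig:
    """Weights and mechanics of the quantization loss
    L(q) = l1*|q - s|^2 + l2*(-log(c . q)) + l3*(neighbourhood score).

    ``lambdas=None`` selects (1, 1, 1) when a neighbourhood model is present
    and (1, 1, 0) otherwise.  ``pseudocount`` regularizes the 3x3 neighbour
    count c so unseen categories keep finite loss.
    """

    lambdas: tuple[float, float, float] | None = None
    pseudocount: float = 1.0
    model: NeighborhoodModel | None = None

    def resolved_lambdas(self) -> tuple[float, float, float]:
        if self.lambdas is not None:
            lam = tuple(float(x) for x in self.lambdas)
        else:
            lam = (1.0, 1.0, 1.0) if self.model is not None else (1.0, 1.0, 0.0)
        if len(lam) != 3 or any(x < 0 for x in lam):
            raise ValueError("lambdas must be three nonnegative weights")
        if all(x == 0 for x in lam):
            raise ValueError("at least one lambda must be positive")
        return lam


def quantize_diffuse(
    field_: OneHotField,
    target_counts: np.ndarray,
    cfg: QuantizationConfig,
    rng: np.random.Generator,
    context: np.ndarray | None = None,
) -> np.ndarray:
    """Quantize a category-weight field back to labels, conserving counts.

    Sites are visited most-confident first (seeded random tie-break; see
    the traversal comment below).  At each site the
    label q minimizing the configured loss is chosen among categories with
    remaining capacity; the quantization error Delta = e_q - s is then
    subtracted, split equally, from the unquantized sites in the 3x3
    neighbourhood (or spread over all remaining unquantized sites if the
    neighbourhood is exhausted).  Components driven negative are clipped at
    zero and the clipped mass re-spread uniformly so per-category mass is
    conserved.  Per-category capacity counters guarantee the output counts
    equal ``target_counts`` exactly.
    """
    target = np.asarray(target_counts, dtype=np.int64)
    rows, cols, k = field_.data.shape
    n_sites = rows * cols
    if len(target) != k or np.any(target < 0):
        raise ValueError("target_counts must be nonnegative, one per category")
    if int(target.sum()) != n_sites:
        raise ValueError("target counts must sum to the number of sites")
    if not np.allclose(field_.counts, target, atol=1e-6 * max(1, n_sites)):
        raise ValueError("field column sums do not match target counts")
    lam1, lam2, lam3 = cfg.resolved_lambdas()
    if lam3 > 0 and cfg.model is None:
        lam3 = 0.0  # no model to score against

    W = field_.data.copy()
    labels_out = np.full((rows, cols), -1, dtype=np.int64)
    unquantized = np.ones((rows, cols), dtype=bool)
    remaining = target.copy()
    n_unq = n_sites

    # Traversal: most-confident sites first (largest max component weight),
    # ties broken by a seeded random permutation.  Confident sites are the
    # ones whose label is essentially decided (e.g. the interior of a
    # hot-spot after rescaling); quantizing them first lets their diffused
    # surplus raise the weights of adjacent uncertain sites before those are
    # visited, so in-demand categories are claimed by affinity instead of by
    # whichever sites happen to remain when capacity runs out.  A purely
    # random order lets capacity exhaustion force labels at arbitrary
    # locations, scattering spatial structure.
    confidence = W.max(axis=2).reshape(-1)
    tie_break = rng.permutation(n_sites)
    order = np.lexsort((tie_break, -confidence))
    neigh_offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]

    def _spread(delta: np.ndarray, sites_r: np.ndarray, sites_c: np.ndarray) -> np.ndarray:
        """Subtract delta/len(sites) from each site; clip negatives and
        return the per-component mass that could not be removed."""
        if len(sites_r) == 0:
            return delta
        share = delta / len(sites_r)
        W[sites_r, sites_c, :] -= share[None, :]
        block = W[sites_r, sites_c, :]
        clipped = np.minimum(block, 0.0)
        residual = -clipped.sum(axis=0)  # mass still to subtract, per component
        np.maximum(block, 0.0, out=block)
        W[sites_r, sites_c, :] = block
        return residual

    for flat in order:
        r, c = divmod(int(flat), cols)
        s = W[r, c]
        cand = np.flatnonzero(remaining > 0)
        if len(cand) == 1:
            q = int(cand[0])
        else:
            ss = float(s @ s)
            loss = lam1 * (1.0 - 2.0 * s[cand] + ss)
            if lam2 > 0 or lam3 > 0:
                ncounts = _neighbor_count_vector(labels_out, r, c, k, mask=~unquantized)
            if lam2 > 0:
                creg = ncounts + cfg.pseudocount
                creg = creg / creg.sum()
                loss = loss - lam2 * np.log(creg[cand])
            if lam3 > 0:
                vb = virus_bin(float(context[r, c])) if context is not None else 0
                nkey = tuple(int(x) for x in ncounts)
                loss = loss + lam3 * np.array(
                    [cfg.model.score(int(q_), nkey, vb) for q_ in cand]
                )
            # ties (e.g. zero-weight sites) go to the category with the most
            # remaining capacity, then lowest index — uninformative sites
            # should absorb the categories most in demand
            near = loss <= loss.min() + 1e-9
            tied = cand[near]
            q = int(tied[int(np.argmax(remaining[tied]))])
        labels_out[r, c] = q
        remaining[q] -= 1
        unquantized[r, c] = False
        n_unq -= 1
        if n_unq == 0:
            break

        delta = -s.copy()
        delta[q] += 1.0  # e_q - s
        nr, nc = [], []
        for dr, dc in neigh_offsets:
            rr, cc = r + dr, c + dc
            if 0 <= rr < rows and 0 <= cc < cols and unquantized[rr, cc]:
                nr.append(rr)
                nc.append(cc)
        if nr:
            residual = _spread(delta, np.asarray(nr), np.asarray(nc))
        else:
            residual = delta
        # re-spread clipped (or orphaned) mass globally over unquantized sites
        tries = 0
        while np.any(np.abs(residual) > 1e-12) and tries < 8:
            ur, uc = np.nonzero(unquantized)
            residual = _spread(residual, ur, uc)
            tries += 1

    assert np.all(remaining == 0)
    return labels_out


# ---------------------------------------------------------------------------
# Full infection-model synthesis


def _adjust_immune(
    agents: ImmuneAgents,
    target_counts: np.ndarray,
    endothelium: np.ndarray,
    rng: np.random.Generator,
) -> ImmuneAgents:
    """Per-type uniform removal of surplus agents; deficits are recruited
    near activated endothelial sites (uniformly on the lattice if none)."""
    side = endothelium.shape[0]
    activated = np.argwhere(endothelium == ENDO_ACTIVATED)
    keep_idx: list[np.ndarray] = []
    new_parts: list[ImmuneAgents] = []
    for code in range(len(IMMUNE_TYPES)):
        idx = np.flatnonzero(agents.type_code == code)
        want = int(target_counts[code])
        if want <= len(idx):
            keep_idx.append(rng.choice(idx, size=want, replace=False) if want else idx[:0])
            continue
        keep_idx.append(idx)
        n_new = want - len(idx)
        if len(activated):
            sites = activated[rng.integers(0, len(activated), size=n_new)]
            jit = rng.uniform(0.0, 1.0, size=(n_new, 2))
            pos = np.column_stack([sites[:, 1] + jit[:, 0], sites[:, 0] + jit[:, 1]])
        else:
            pos = rng.uniform(0.0, side, size=(n_new, 2))
        pos = np.clip(pos, 0.0, side - 1e-9)
        new_parts.append(
            ImmuneAgents(
                np.full(n_new, code, dtype=np.int64),
                pos,
                rng.uniform(-np.pi, np.pi, size=n_new),
                np.zeros(n_new, dtype=np.int64),
            )
        )
    out = agents.subset(np.sort(np.concatenate(keep_idx)))
    for part in new_parts:
        out = out.extend(part)
    return out


def synthesize_infection(
    target: Macrostate,
    seed_state: InfectionMicrostate,
    cfg: QuantizationConfig,
    rng: np.random.Generator,
) -> InfectionMicrostate:
    """Synthesize a full infection microstate matching ``target``, seeded by
    (and minimally edited from) ``seed_state``.

    Fields are rescaled to the target totals; both categorical lattices go
    through one-hot encode -> rescale -> quantize/diffuse; immune agents are
    adjusted per type near activated endothelium.
    """
    side = seed_state.epithelium.shape[0]
    fields = {
        name: scale_field(seed_state.fields[name], target[f"total_{name}"])
        for name in FIELD_NAMES
    }

    def _categorical(lattice: np.ndarray, labels: tuple[str, ...], prefix: str) -> np.ndarray:
        tgt = np.array(
            [int(round(target[f"{prefix}_{lab}"])) for lab in labels], dtype=np.int64
        )
        if int(tgt.sum()) != lattice.size:
            raise ValueError(f"{prefix} target counts do not sum to the lattice size")
        oh = one_hot_encode(lattice, labels)
        oh = rescale_one_hot(oh, oh.counts, tgt.astype(float))
        return quantize_diffuse(oh, tgt, cfg, rng, context=fields["virus"])

    epithelium = _categorical(seed_state.epithelium, EPITHELIAL_LABELS, "epi")
    endothelium = _categorical(seed_state.endothelium, ENDOTHELIAL_LABELS, "endo")

    immune_targets = np.array(
        [int(round(target[f"n_{t}"])) for t in IMMUNE_TYPES], dtype=np.int64
    )
    agents = _adjust_immune(seed_state.immune_agents, immune_targets, endothelium, rng)

    infection_age = np.where(
        (epithelium == EPI_INFECTED) & (seed_state.epithelium == EPI_INFECTED),
        seed_state.infection_age,
        0,
    )
    out = InfectionMicrostate(
        epithelium,
        endothelium,
        fields,
        agents,
        infection_age,
        int(round(target["apoptosed_by_virus"])),
    )
    # postcondition: counts exact, field totals to rounding
    summ = summarize_infection(out)
    if not np.allclose(
        summ.values[len(FIELD_NAMES):], target.values[len(FIELD_NAMES):]
    ):
        raise AssertionError("synthesis failed to reach the target counts")
    return out
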