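"""Macrostate representation and variable transforms.

A *macrostate* is a low-dimensional, permutation-invariant summary of an
agent-based model's full state (a *microstate*): agent counts, lattice-field
totals, coverage fractions.  The Kalman filter operates on macrostates after
mapping each variable into "filter space" with a per-variable invertible
transform; this module owns those transforms, the ordered schema that names
the variables, and the integerization step that turns continuous filter
output back into feasible count vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Variable",
    "MacroSchema",
    "Macrostate",
    "Identity",
    "Scale",
    "LogEps",
    "TransformSpec",
    "forward_transform",
    "inverse_transform",
    "integerize_counts",
]


@dataclass(frozen=True)
class Variable:
    """One named macrostate component.

    kind:
        "count"  — nonnegative integer after integerization;
        "real"   — nonnegative real (field totals);
        "fraction" — real in [0, 1].
    cap: optional upper bound (e.g. grass patches <= side**2).
    sum_group: variables sharing a group name must jointly sum to the
        group's fixed total (e.g. the epithelial category counts).
    """

    name: str
    kind: str = "count"
    cap: float | None = None
    sum_group: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("count", "real", "fraction"):
            raise ValueError(f"unknown variable kind {self.kind!r}")


@dataclass(frozen=True)
class MacroSchema:
    """Ordered macrostate variable registry for one model."""

    variables: tuple[Variable, ...]
    sum_totals: Mapping[str, int] = field(default_factory=dict)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    def __len__(self) -> int:
        return len(self.variables)

    def index(self, name: str) -> int:
        return self.names.index(name)


class Macrostate:
    """Ordered (name, value) vector tied to a :class:`MacroSchema`."""

    __slots__ = ("schema", "values")

    def __init__(self, schema: MacroSchema, values: Sequence[float]) -> None:
        values = np.asarray(values, dtype=float)
        if values.shape != (len(schema),):
            raise ValueError(
                f"expected {len(schema)} values for schema, got shape {values.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("macrostate values must be finite")
        self.schema = schema
        self.values = values

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.schema.index(name)])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.schema.names, self.values))

    def __repr__(self) -> str:  # pragma: no cover
        inner = ", ".join(f"{n}={v:g}" for n, v in self.as_dict().items())
        return f"Macrostate({inner})"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Macrostate):
            return NotImplemented
        return self.schema.names == other.schema.names and np.array_equal(
            self.values, other.values
        )


# ---------------------------------------------------------------------------
# Per-variable transforms


class Identity:
    """x -> x."""

    def forward(self, x):
        return np.asarray(x, dtype=float)

    def inverse(self, y):
        return np.asarray(y, dtype=float)

    def __repr__(self) -> str:
        return "Identity()"


class Scale:
    """x -> c * x, used to bring large counts into the same range as the
    other filter variables (sheep are scaled by 0.1, grass by 0.01)."""

    def __init__(self, c: float) -> None:
        if c == 0:
            raise ValueError("scale factor must be nonzero")
        self.c = float(c)

    def forward(self, x):
        return self.c * np.asarray(x, dtype=float)

    def inverse(self, y):
        return np.asarray(y, dtype=float) / self.c

    def __repr__(self) -> str:
        return f"Scale({self.c!r})"


class LogEps:
    """Shifted log transform x -> log(eps + x) with the clamped inverse
    x = max(0, exp(y) - eps).

    Used for variables whose distribution concentrates near zero (wolf
    counts, strictly positive rate parameters): the plain log is undefined
    at zero, and the clamp keeps filter output in the valid domain.
    """

    def __init__(self, eps: float = 1e-3) -> None:
        if eps <= 0:
            raise ValueError("eps must be positive")
        self.eps = float(eps)

    def forward(self, x):
        x = np.asarray(x, dtype=float)
        if np.any(x < -self.eps):
            raise ValueError("input below -eps is outside the log domain")
        return np.log(self.eps + x)

    def inverse(self, y):
        return np.maximum(0.0, np.exp(np.asarray(y, dtype=float)) - self.eps)

    def __repr__(self) -> str:
        return f"LogEps({self.eps!r})"


Transform = Identity | Scale | LogEps


@dataclass(frozen=True)
class TransformSpec:
    """Per-variable transforms plus the augmented-parameter block.

    ``transforms`` aligns with the schema order.  ``param_names`` lists the
    model parameters appended to the filter state (parameter augmentation);
    each has its own transform, log by default so rates stay positive under
    additive Gaussian process noise.
    """

    schema: MacroSchema
    transforms: tuple[Transform, ...]
    param_names: tuple[str, ...] = ()
    param_transforms: tuple[Transform, ...] = ()

    def __post_init__(self) -> None:
        if len(self.transforms) != len(self.schema):
            raise ValueError("one transform per schema variable required")
        if len(self.param_transforms) != len(self.param_names):
            raise ValueError("one transform per augmented parameter required")

    @property
    def macro_dim(self) -> int:
        return len(self.schema)

    @property
    def dim(self) -> int:
        return len(self.schema) + len(self.param_names)

    @property
    def param_slice(self) -> slice:
        return slice(self.macro_dim, self.dim)

    def forward_params(self, params: Mapping[str, float]) -> np.ndarray:
        return np.array(
            [t.forward(params[n]) for n, t in zip(self.param_names, self.param_transforms)],
            dtype=float,
        )

    def inverse_params(self, vec: Sequence[float]) -> dict[str, float]:
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (len(self.param_names),):
            raise ValueError("parameter vector length mismatch")
        return {
            n: float(t.inverse(v))
            for n, t, v in zip(self.param_names, self.param_transforms, vec)
        }


def forward_transform(
    macro: Macrostate,
    spec: TransformSpec,
    params: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Map a raw macrostate (plus optional augmented parameters) into filter
    space as a flat vector, in schema order then parameter order."""
    if macro.schema.names != spec.schema.names:
        raise ValueError("macrostate schema does not match transform spec")
    out = np.array(
        [t.forward(v) for t, v in zip(spec.transforms, macro.values)], dtype=float
    )
    if spec.param_names and params is not None:
        out = np.concatenate([out, spec.forward_params(params)])
    return out


def inverse_transform(vec: Sequence[float], spec: TransformSpec) -> Macrostate:
    """Invert the macro block of a filter-space vector back to a feasible
    raw macrostate.

    Count variables are integerized (sum-constrained groups via
    largest-remainder apportionment); caps are enforced by clipping;
    fractions are clipped to [0, 1].  The parameter block, if present in
    ``vec``, is ignored here — use :meth:`TransformSpec.inverse_params`.
    """
    vec = np.asarray(vec, dtype=float)
    if vec.shape not in ((spec.macro_dim,), (spec.dim,)):
        raise ValueError(
            f"vector length {vec.shape} matches neither macro ({spec.macro_dim}) "
            f"nor augmented ({spec.dim}) dimension"
        )
    raw = np.array(
        [t.inverse(v) for t, v in zip(spec.transforms, vec[: spec.macro_dim])],
        dtype=float,
    )

    schema = spec.schema
    out = np.empty_like(raw)
    # Variables constrained to a fixed group total are apportioned together;
    # the rest are handled per-entry.
    grouped: dict[str, list[int]] = {}
    for i, v in enumerate(schema.variables):
        if v.sum_group is not None:
            grouped.setdefault(v.sum_group, []).append(i)

    free = [i for i, v in enumerate(schema.variables) if v.sum_group is None]
    for i in free:
        v = schema.variables[i]
        x = raw[i]
        if v.kind == "fraction":
            out[i] = min(max(x, 0.0), 1.0)
            continue
        x = max(x, 0.0)
        if v.cap is not None:
            x = min(x, v.cap)
        if v.kind == "count":
            x = float(np.round(x))  # round-half-to-even
        out[i] = x

    for group, idx in grouped.items():
        total = schema.sum_totals[group]
        vals = np.maximum(raw[idx], 0.0)
        out[idx] = integerize_counts(vals, total=total)

    return Macrostate(schema, out)


def integerize_counts(values: Sequence[float], total: int | None = None) -> np.ndarray:
    """Round nonnegative reals to integers, optionally under an exact-sum
    constraint.

    Without ``total``: numpy round-half-to-even per entry.  With ``total``:
    largest-remainder (Hamilton) apportionment — floor each entry after
    proportional rescaling, then hand the remaining units to the largest
    fractional remainders (ties broken by lowest index).  The result sums to
    ``total`` exactly and each entry is within 1 of its rescaled value.
    """
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValueError("values must be nonnegative")
    if total is None:
        return np.round(values).astype(np.int64)
    total = int(total)
    if total < 0:
        raise ValueError("total must be nonnegative")
    s = values.sum()
    if s == 0:
        # Degenerate: nothing to apportion proportionally; give everything to
        # the largest entry (all zero -> index 0).
        out = np.zeros(len(values), dtype=np.int64)
        out[int(np.argmax(values))] = total
        return out
    scaled = (values / s) * total  # each value <= s, so the ratio never overflows
    out = np.floor(scaled).astype(np.int64)
    remainder = total - int(out.sum())
    if remainder > 0:
        frac = scaled - out
        # stable argsort descending by fraction, ties -> lowest index
        order = np.argsort(-frac, kind="stable")
        out[order[:remainder]] += 1
    return out
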