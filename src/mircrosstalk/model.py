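"""Reaction network and deterministic (mean-field) layer of the titration model.

The network couples one miRNA species ``s`` to two target mRNAs ``r1``, ``r2``
through bimolecular titration: a free miRNA binds a free target with effective
strength ``g_i``; the bound target is always lost, while the miRNA is co-degraded
with probability ``alpha`` and recycled with probability ``1 - alpha``.  Each
unbound target is translated into its protein ``p_i``.  Because both targets
draw on the same finite miRNA pool, they cross-regulate each other: a competing
endogenous RNA (ceRNA) circuit.

Species order used everywhere in the package: ``(s, r1, r2, p1, p2)``.

Units: time is measured in units of mRNA turnover (``g_r1 = 1`` in the default
parameterisations); molecule numbers are absolute copies per cell, in the
10-1000 range where titration crosstalk is physiologically relevant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ModelParams",
    "ConstitutiveLevels",
    "ThresholdEstimate",
    "SPECIES",
    "STOICHIOMETRY",
    "REACTION_LABELS",
    "validate_params",
    "load_params",
    "constitutive_levels",
    "meanfield_steady_state",
    "propensities",
    "sensitivity_threshold",
]

SPECIES = ("s", "r1", "r2", "p1", "p2")

#: Reaction channels, one row per channel, columns in SPECIES order.
#: The s + r_i interaction is split into two channels: joint degradation
#: (rate alpha*g_i*s*r_i, removes both) and recycling (rate (1-alpha)*g_i*s*r_i,
#: removes only the target).
REACTION_LABELS = (
    "birth_s",
    "birth_r1",
    "birth_r2",
    "decay_s",
    "decay_r1",
    "decay_r2",
    "joint_1",
    "recycle_1",
    "joint_2",
    "recycle_2",
    "birth_p1",
    "decay_p1",
    "birth_p2",
    "decay_p2",
)

STOICHIOMETRY = np.array(
    [
        [+1, 0, 0, 0, 0],   # birth_s
        [0, +1, 0, 0, 0],   # birth_r1
        [0, 0, +1, 0, 0],   # birth_r2
        [-1, 0, 0, 0, 0],   # decay_s
        [0, -1, 0, 0, 0],   # decay_r1
        [0, 0, -1, 0, 0],   # decay_r2
        [-1, -1, 0, 0, 0],  # joint_1
        [0, -1, 0, 0, 0],   # recycle_1
        [-1, 0, -1, 0, 0],  # joint_2
        [0, 0, -1, 0, 0],   # recycle_2
        [0, 0, 0, +1, 0],   # birth_p1
        [0, 0, 0, -1, 0],   # decay_p1
        [0, 0, 0, 0, +1],   # birth_p2
        [0, 0, 0, 0, -1],   # decay_p2
    ],
    dtype=np.int64,
)


class ParameterError(ValueError):
    """Raised when a parameter set violates the model's constraints."""


@dataclass(frozen=True)
class ModelParams:
    """Rate constants of the two-target titration network.

    Parameters
    ----------
    k_s, k_r1, k_r2
        Transcription rates of the miRNA and of the two targets
        (molecules/time).
    g_s, g_r1, g_r2
        First-order degradation rates of the free species (1/time).
    g_1, g_2
        Effective miRNA-target interaction strengths
        (1/(molecules*time)).
    alpha
        Probability that the miRNA is degraded together with the target
        upon interaction; recycled with probability ``1 - alpha``.
    k_p1, k_p2
        Translation rates (proteins per mRNA per time).
    g_p1, g_p2
        Protein degradation rates (1/time).
    """

    k_s: float
    k_r1: float
    k_r2: float
    g_s: float
    g_r1: float
    g_r2: float
    g_1: float
    g_2: float
    alpha: float
    k_p1: float
    k_p2: float
    g_p1: float
    g_p2: float

    def __post_init__(self) -> None:
        validate_params(self)

    def swapped(self) -> "ModelParams":
        """Mirror image of the model: exchange the roles of targets 1 and 2."""
        return replace(
            self,
            k_r1=self.k_r2, k_r2=self.k_r1,
            g_r1=self.g_r2, g_r2=self.g_r1,
            g_1=self.g_2, g_2=self.g_1,
            k_p1=self.k_p2, k_p2=self.k_p1,
            g_p1=self.g_p2, g_p2=self.g_p1,
        )

    def with_p0(self, p0: float) -> "ModelParams":
        """Set k_r1 so the constitutive protein-1 mean equals ``p0``."""
        if p0 < 0:
            raise ParameterError("p0 must be >= 0")
        return replace(self, k_r1=p0 * self.g_r1 * self.g_p1 / self.k_p1)

    def as_array(self) -> np.ndarray:
        """Rates as a flat float array in field-declaration order."""
        return np.array([getattr(self, f.name) for f in fields(self)], dtype=float)

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "ModelParams":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
        missing = known - set(mapping)
        if missing:
            raise ParameterError(f"missing parameter keys: {sorted(missing)}")
        return cls(**{k: float(v) for k, v in mapping.items()})


@dataclass(frozen=True)
class ConstitutiveLevels:
    """Unregulated means: what each reporter would express with no miRNA."""

    r0_1: float
    r0_2: float
    p0_1: float
    p0_2: float


@dataclass(frozen=True)
class ThresholdEstimate:
    """Location of maximal logarithmic sensitivity along a response curve."""

    p0_star: float
    index: int
    max_slope: float
    absent: bool
    slopes: np.ndarray


def validate_params(params: ModelParams) -> ModelParams:
    """Check rate positivity and the recycling-probability bound.

    All rates must be >= 0; the degradation rates of free species must be
    strictly positive (otherwise no stationary state exists); ``alpha`` must
    lie in [0, 1].
    """
    for name in ("k_s", "k_r1", "k_r2", "g_s", "g_r1", "g_r2",
                 "g_1", "g_2", "k_p1", "k_p2", "g_p1", "g_p2"):
        v = getattr(params, name)
        if not np.isfinite(v) or v < 0:
            raise ParameterError(f"{name} must be >= 0 and finite, got {v}")
    for name in ("g_s", "g_r1", "g_r2", "g_p1", "g_p2"):
        if getattr(params, name) <= 0:
            raise ParameterError(f"{name} must be > 0")
    if not (0.0 <= params.alpha <= 1.0):
        raise ParameterError(f"alpha must lie in [0,1], got {params.alpha}")
    return params


def load_params(path: str | Path) -> ModelParams:
    """Read a parameter set from a YAML or JSON mapping file.

    The mapping must contain exactly the field names of :class:`ModelParams`;
    unknown keys are rejected.
    """
    import yaml

    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        mapping = json.loads(text)
    else:
        mapping = yaml.safe_load(text)
    if not isinstance(mapping, Mapping):
        raise ParameterError(f"{path} does not contain a parameter mapping")
    return ModelParams.from_mapping(mapping)


def constitutive_levels(params: ModelParams) -> ConstitutiveLevels:
    """Closed-form unregulated means: r0_i = k_ri/g_ri, p0_i = k_pi*r0_i/g_pi."""
    r0_1 = params.k_r1 / params.g_r1
    r0_2 = params.k_r2 / params.g_r2
    return ConstitutiveLevels(
        r0_1=r0_1,
        r0_2=r0_2,
        p0_1=params.k_p1 * r0_1 / params.g_p1,
        p0_2=params.k_p2 * r0_2 / params.g_p2,
    )


def _mirna_balance(s: float, p: ModelParams) -> float:
    """Net miRNA production minus consumption at free-miRNA level ``s``.

    At stationarity the target equations give r_i(s) = k_ri/(g_ri + g_i*s);
    substituting into the miRNA balance leaves one scalar equation.  The
    function is strictly decreasing in s, so the root is unique.
    """
    r1 = p.k_r1 / (p.g_r1 + p.g_1 * s)
    r2 = p.k_r2 / (p.g_r2 + p.g_2 * s)
    return p.k_s - p.g_s * s - p.alpha * s * (p.g_1 * r1 + p.g_2 * r2)


def meanfield_steady_state(params: ModelParams) -> np.ndarray:
    """Unique non-negative stationary state of the deterministic rate equations.

    Returns the 5-vector of means ``(s, r1, r2, p1, p2)``.  The system reduces
    to a single monotone scalar equation for free miRNA, solved by bracketed
    root finding on ``[0, k_s/g_s]``; the other species follow in closed form.
    Relative residual of the full stationary conditions is <= 1e-10.
    """
    p = validate_params(params)
    if p.k_s == 0.0:
        s = 0.0
    elif p.alpha == 0.0 or (p.g_1 == 0.0 and p.g_2 == 0.0):
        # miRNA balance closes on its own: pure catalytic regime.
        s = p.k_s / p.g_s
    else:
        hi = p.k_s / p.g_s
        f_hi = _mirna_balance(hi, p)
        if f_hi >= 0.0:
            s = hi
        else:
            s = brentq(_mirna_balance, 0.0, hi, args=(p,),
                       xtol=1e-14, rtol=8.9e-16, maxiter=200)
    r1 = p.k_r1 / (p.g_r1 + p.g_1 * s)
    r2 = p.k_r2 / (p.g_r2 + p.g_2 * s)
    p1 = p.k_p1 * r1 / p.g_p1
    p2 = p.k_p2 * r2 / p.g_p2
    state = np.array([s, r1, r2, p1, p2], dtype=float)

    resid = np.array([
        p.k_s - p.g_s * s - p.alpha * s * (p.g_1 * r1 + p.g_2 * r2),
        p.k_r1 - p.g_r1 * r1 - p.g_1 * s * r1,
        p.k_r2 - p.g_r2 * r2 - p.g_2 * s * r2,
        p.k_p1 * r1 - p.g_p1 * p1,
        p.k_p2 * r2 - p.g_p2 * p2,
    ])
    scale = max(p.k_s, p.k_r1, p.k_r2, p.k_p1 * r1, p.k_p2 * r2, 1.0)
    if np.max(np.abs(resid)) > 1e-10 * scale:
        raise ArithmeticError(
            f"mean-field residual {np.max(np.abs(resid)):.3e} exceeds tolerance "
            f"(state={state}, params={p.to_dict()})"
        )
    return state


def propensities(params: ModelParams, state: np.ndarray) -> np.ndarray:
    """Reaction propensities at a (possibly real-valued) state, channel order
    as in :data:`REACTION_LABELS`."""
    s, r1, r2, p1, p2 = state
    p = params
    return np.array([
        p.k_s,
        p.k_r1,
        p.k_r2,
        p.g_s * s,
        p.g_r1 * r1,
        p.g_r2 * r2,
        p.alpha * p.g_1 * s * r1,
        (1.0 - p.alpha) * p.g_1 * s * r1,
        p.alpha * p.g_2 * s * r2,
        (1.0 - p.alpha) * p.g_2 * s * r2,
        p.k_p1 * r1,
        p.g_p1 * p1,
        p.k_p2 * r2,
        p.g_p2 * p2,
    ])


def sensitivity_threshold(
    p0_grid: np.ndarray,
    mean_p1: np.ndarray,
    slope_tol: float = 1.05,
) -> ThresholdEstimate:
    """Locate the titration threshold on a response curve.

    The threshold is operationalised as the point of maximal logarithmic slope
    d log<p1> / d log p0 (central differences on the interior grid).  An
    unregulated reporter responds linearly, slope identically 1; the curve is
    flagged as having no threshold when the maximal slope does not exceed
    ``slope_tol``.
    """
    p0 = np.asarray(p0_grid, dtype=float)
    y = np.asarray(mean_p1, dtype=float)
    if p0.ndim != 1 or p0.shape != y.shape:
        raise ValueError("p0_grid and mean_p1 must be 1-D arrays of equal length")
    if len(p0) < 3:
        raise ValueError("need at least 3 grid points to estimate a slope")
    if np.any(np.diff(p0) <= 0):
        raise ValueError("p0_grid must be strictly increasing")
    if np.any(p0 <= 0) or np.any(y <= 0):
        raise ValueError("p0_grid and mean_p1 must be strictly positive")

    lx, ly = np.log(p0), np.log(y)
    slopes = np.gradient(ly, lx)  # central differences, one-sided at the ends
    # restrict the argmax to interior points so the threshold is never an
    # endpoint artifact of the one-sided differences
    interior = slice(1, len(p0) - 1)
    idx = 1 + int(np.argmax(slopes[interior]))
    max_slope = float(slopes[idx])
    return ThresholdEstimate(
        p0_star=float(p0[idx]),
        index=idx,
        max_slope=max_slope,
        absent=bool(max_slope <= slope_tol),
        slopes=slopes,
    )
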