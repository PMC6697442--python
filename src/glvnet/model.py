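"""Generalized Lotka-Volterra (gLV) model objects and forward simulation.

The community model is the discrete-time stochastic gLV update

    x[k+1, i] = x[k, i] + x[k, i] * rate_i(x[k]) * dt_k + w[k, i]

where the per-capita rate of species ``i`` is linear in all abundances,

    rate_i(x) = r_i + sum_j a[i, j] * z[i, j] * x[j],

``r_i`` is the intrinsic growth rate (1/h), ``a[i, j]`` the interaction
coefficient describing the effect of species ``j`` on species ``i``
(1/(h * CFU/ml)), ``z[i, j]`` a binary edge indicator, and ``w[k, i]`` a
Brownian-motion increment with variance ``v_w[i] * dt_k``.  Optional
higher-order terms add ``z3_i * a3_i * prod_{j != i} x_j`` and
``z4_i * a4_i * prod_j x_j`` to the per-capita rate.

Abundances are kept on the raw CFU/ml scale throughout so that interaction
coefficients and the variance hyperpriors retain their physical meaning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "GLVModelError",
    "SimulationBlowupError",
    "SpeciesSet",
    "HigherOrderTerms",
    "GLVParameters",
    "Trajectory",
    "per_capita_growth",
    "step",
    "simulate",
    "equilibrium_single_species",
]


class GLVModelError(ValueError):
    """Invalid model structure or invalid input to a model operation."""


class SimulationBlowupError(RuntimeError):
    """Forward simulation produced a non-finite state; names the failing step."""


@dataclass(frozen=True)
class SpeciesSet:
    """Ordered set of species labels; the ordering fixes all matrix indices."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.labels)
        object.__setattr__(self, "labels", labels)
        if len(labels) < 2:
            raise GLVModelError("SpeciesSet needs at least 2 species")
        if len(set(labels)) != len(labels):
            raise GLVModelError(f"duplicate species labels: {labels}")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)


@dataclass
class HigherOrderTerms:
    """Per-species 3rd-order (product over the other species) and 4th-order
    (product over all species) interaction coefficients with indicators."""

    coeff3: np.ndarray
    coeff4: np.ndarray
    indicator3: np.ndarray
    indicator4: np.ndarray

    def __post_init__(self) -> None:
        self.coeff3 = np.asarray(self.coeff3, dtype=float)
        self.coeff4 = np.asarray(self.coeff4, dtype=float)
        self.indicator3 = np.asarray(self.indicator3, dtype=int)
        self.indicator4 = np.asarray(self.indicator4, dtype=int)
        n = self.coeff3.shape[0]
        for name in ("coeff4", "indicator3", "indicator4"):
            if getattr(self, name).shape != (n,):
                raise GLVModelError(f"higher-order field {name} has wrong shape")
        for ind in (self.indicator3, self.indicator4):
            if not np.isin(ind, (0, 1)).all():
                raise GLVModelError("higher-order indicators must be 0/1")

    @classmethod
    def zeros(cls, n_species: int) -> "HigherOrderTerms":
        z = np.zeros(n_species)
        return cls(z.copy(), z.copy(), z.astype(int), z.astype(int))


@dataclass
class GLVParameters:
    """Full parameterization of the gLV community model.

    ``interaction_matrix`` is oriented row = target, column = source:
    ``a[i, j]`` is the effect of species ``j`` on the growth of species ``i``.
    Diagonal indicators are fixed to 1 (self-limitation is always in the
    model); ``process_noise_variances`` must be strictly positive.
    """

    species: SpeciesSet
    growth_rates: np.ndarray
    interaction_matrix: np.ndarray
    indicator_matrix: np.ndarray = None  # type: ignore[assignment]
    process_noise_variances: np.ndarray = None  # type: ignore[assignment]
    higher_order: Optional[HigherOrderTerms] = None

    def __post_init__(self) -> None:
        s = len(self.species)
        self.growth_rates = np.asarray(self.growth_rates, dtype=float)
        self.interaction_matrix = np.asarray(self.interaction_matrix, dtype=float)
        if self.indicator_matrix is None:
            self.indicator_matrix = np.ones((s, s), dtype=int)
        self.indicator_matrix = np.asarray(self.indicator_matrix, dtype=int)
        if self.process_noise_variances is None:
            self.process_noise_variances = np.full(s, 1.0)
        self.process_noise_variances = np.asarray(
            self.process_noise_variances, dtype=float
        )
        if self.growth_rates.shape != (s,):
            raise GLVModelError(f"growth_rates must have shape ({s},)")
        if self.interaction_matrix.shape != (s, s):
            raise GLVModelError(f"interaction_matrix must be {s}x{s}")
        if self.indicator_matrix.shape != (s, s):
            raise GLVModelError(f"indicator_matrix must be {s}x{s}")
        if not np.isin(self.indicator_matrix, (0, 1)).all():
            raise GLVModelError("indicators must be binary")
        if not (np.diag(self.indicator_matrix) == 1).all():
            raise GLVModelError("diagonal indicators are fixed to 1")
        if self.process_noise_variances.shape != (s,):
            raise GLVModelError(f"process_noise_variances must have shape ({s},)")
        if not (self.process_noise_variances >= 0).all():
            raise GLVModelError("process noise variances must be >= 0")
        if self.higher_order is not None and self.higher_order.coeff3.shape != (s,):
            raise GLVModelError("higher_order terms have wrong length")

    @property
    def n_species(self) -> int:
        return len(self.species)

    def effective_matrix(self) -> np.ndarray:
        """Interaction matrix with masked (z=0) edges zeroed out."""
        return self.interaction_matrix * self.indicator_matrix

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "species": list(self.species.labels),
            "growth_rates": self.growth_rates.tolist(),
            "interaction_matrix": self.interaction_matrix.tolist(),
            "indicator_matrix": self.indicator_matrix.tolist(),
            "process_noise_variances": self.process_noise_variances.tolist(),
        }
        if self.higher_order is not None:
            d["higher_order"] = {
                "coeff3": self.higher_order.coeff3.tolist(),
                "coeff4": self.higher_order.coeff4.tolist(),
                "indicator3": self.higher_order.indicator3.tolist(),
                "indicator4": self.higher_order.indicator4.tolist(),
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GLVParameters":
        ho = None
        if d.get("higher_order") is not None:
            h = d["higher_order"]
            ho = HigherOrderTerms(
                h["coeff3"], h["coeff4"], h["indicator3"], h["indicator4"]
            )
        return cls(
            species=SpeciesSet(tuple(d["species"])),
            growth_rates=np.asarray(d["growth_rates"], dtype=float),
            interaction_matrix=np.asarray(d["interaction_matrix"], dtype=float),
            indicator_matrix=np.asarray(d["indicator_matrix"], dtype=int),
            process_noise_variances=np.asarray(
                d["process_noise_variances"], dtype=float
            ),
            higher_order=ho,
        )


@dataclass
class Trajectory:
    """Abundance time series of one culture (one condition, one replicate).

    ``abundances`` has shape (T, S) in CFU/ml on the time grid ``times``
    (hours, strictly increasing).  ``censored`` optionally flags values that
    were clipped at a detection floor.
    """

    times: np.ndarray
    abundances: np.ndarray
    species: tuple[str, ...]
    condition: str = ""
    replicate: int = 0
    censored: Optional[np.ndarray] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.abundances = np.asarray(self.abundances, dtype=float)
        self.species = tuple(self.species)
        if self.times.ndim != 1:
            raise GLVModelError("times must be 1-D")
        if np.any(np.diff(self.times) <= 0):
            raise GLVModelError("times must be strictly increasing")
        if self.abundances.shape != (self.times.size, len(self.species)):
            raise GLVModelError(
                f"abundances shape {self.abundances.shape} does not match "
                f"({self.times.size}, {len(self.species)})"
            )
        if np.any(self.abundances < 0):
            raise GLVModelError("abundances must be non-negative")
        if self.censored is not None:
            self.censored = np.asarray(self.censored, dtype=bool)
            if self.censored.shape != self.abundances.shape:
                raise GLVModelError("censored mask shape mismatch")

    @property
    def n_times(self) -> int:
        return self.times.size


def _check_state(params: GLVParameters, state: np.ndarray) -> np.ndarray:
    state = np.asarray(state, dtype=float)
    if state.shape != (params.n_species,):
        raise GLVModelError(
            f"state has shape {state.shape}, expected ({params.n_species},)"
        )
    if not np.isfinite(state).all():
        raise GLVModelError("state contains non-finite values")
    if np.any(state < 0):
        raise GLVModelError("state contains negative abundances")
    return state


def per_capita_growth(params: GLVParameters, state: Sequence[float]) -> np.ndarray:
    """Per-capita growth rate ``r + (a*z) @ x`` (+ higher-order terms) in 1/h."""
    x = _check_state(params, state)
    rate = params.growth_rates + params.effective_matrix() @ x
    ho = params.higher_order
    if ho is not None:
        total = np.prod(x)
        # product over the *other* species; at x_i == 0 fall back to a direct
        # product since total/x_i is 0/0 there
        if np.all(x > 0):
            prod_others = total / x
        else:
            prod_others = np.array(
                [np.prod(np.delete(x, i)) for i in range(x.size)]
            )
        rate = rate + ho.indicator3 * ho.coeff3 * prod_others
        rate = rate + ho.indicator4 * ho.coeff4 * total
    return rate


def step(
    params: GLVParameters,
    state: Sequence[float],
    delta_t: float,
    noise_increment: Optional[Sequence[float]] = None,
) -> np.ndarray:
    """One explicit-Euler update; the result is clamped at 0.

    ``noise_increment`` is the realized Brownian increment (absolute
    abundance units); pass ``None`` or zeros for a deterministic step.
    """
    x = _check_state(params, state)
    if delta_t < 0:
        raise GLVModelError(f"delta_t must be >= 0, got {delta_t}")
    if noise_increment is None:
        w = np.zeros_like(x)
    else:
        w = np.asarray(noise_increment, dtype=float)
        if w.shape != x.shape:
            raise GLVModelError("noise_increment has wrong shape")
    nxt = x + x * per_capita_growth(params, x) * delta_t + w
    return np.maximum(nxt, 0.0)


def simulate(
    params: GLVParameters,
    initial_state: Sequence[float],
    time_grid: Sequence[float],
    stochastic: bool = False,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    substeps: int = 1,
    condition: str = "",
    replicate: int = 0,
) -> Trajectory:
    """Simulate forward on ``time_grid`` and return a :class:`Trajectory`.

    With ``stochastic=True`` each (sub)step adds a Gaussian increment of
    variance ``v_w[i] * dt``; the generator is ``rng`` if given, otherwise
    seeded from ``seed`` so identical inputs give bitwise-identical output.
    ``substeps`` refines each grid interval for the forward integration only;
    recorded points stay on ``time_grid``.
    """
    x = _check_state(params, np.asarray(initial_state, dtype=float))
    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or t.size < 1:
        raise GLVModelError("time_grid must be a non-empty 1-D array")
    if np.any(np.diff(t) <= 0):
        raise GLVModelError("time_grid must be strictly increasing")
    if substeps < 1:
        raise GLVModelError("substeps must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    sd = np.sqrt(params.process_noise_variances)
    out = np.empty((t.size, params.n_species))
    out[0] = x
    for k in range(t.size - 1):
        dt = (t[k + 1] - t[k]) / substeps
        for sub in range(substeps):
            if stochastic:
                w = rng.standard_normal(params.n_species) * sd * np.sqrt(dt)
            else:
                w = None
            x = step(params, x, dt, w)
            if not np.isfinite(x).all() or np.any(np.abs(x) > 1e300):
                raise SimulationBlowupError(
                    f"state blew up between t={t[k]:g} h and t={t[k + 1]:g} h "
                    f"(substep {sub + 1}/{substeps})"
                )
        out[k + 1] = x
    return Trajectory(
        times=t,
        abundances=out,
        species=params.species.labels,
        condition=condition,
        replicate=replicate,
    )


def equilibrium_single_species(r: float, a_self: float) -> float:
    """Carrying capacity ``K = -r / a_self`` of a single self-limited species."""
    if r <= 0:
        raise GLVModelError(f"growth rate must be > 0, got {r}")
    if a_self >= 0:
        raise GLVModelError(
            f"self-interaction must be < 0 for a finite equilibrium, got {a_self}"
        )
    return -r / a_self
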