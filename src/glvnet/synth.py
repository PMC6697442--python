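"""Synthetic consortium experiments: knockdown designs, network presets,
measurement noise, and full dataset generation.

Emulates batch-coculture experiments on a four-member gut consortium
(E. coli "Ec", S. Typhimurium "ST", B. thetaiotaomicron "BT",
B. fragilis "BF") quantified by strain-specific qPCR: an equal-inoculum
baseline plus one condition per species with that species' inoculum reduced
10-fold, sampled over a 27 h anaerobic growth window.  Two ground-truth
presets are provided: a wild-type-like community whose interactions are all
antagonistic, and an engineered cross-feeding community with two positive
edges (from BF to Ec and to ST), roughly 3-fold lower growth rates and about
1.5 orders of magnitude lower carrying capacity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import (
    GLVModelError,
    GLVParameters,
    SpeciesSet,
    Trajectory,
    simulate,
)

__all__ = [
    "DEFAULT_SPECIES",
    "DEFAULT_SAMPLING_TIMES",
    "DEFAULT_BASELINE_INOCULUM",
    "StudyDesign",
    "NoiseModel",
    "GroundTruthRecord",
    "make_knockdown_design",
    "preset_wt_network",
    "preset_engineered_network",
    "apply_measurement_noise",
    "generate_dataset",
]

DEFAULT_SPECIES = SpeciesSet(("Ec", "ST", "BT", "BF"))

# 8 sampling points spanning the 27 h batch-culture horizon, denser early
# where growth is fastest.
DEFAULT_SAMPLING_TIMES = (0.0, 2.0, 4.0, 7.0, 11.0, 16.0, 21.0, 27.0)

# CFU/ml per species in the equal-inoculum baseline condition.
DEFAULT_BASELINE_INOCULUM = 1e6


@dataclass
class StudyDesign:
    """Experimental layout: conditions (label, inoculum vector), sampling
    time grid in hours, and replicate count."""

    species: SpeciesSet
    conditions: list[tuple[str, np.ndarray]]
    sampling_times: np.ndarray
    replicates: int = 3

    def __post_init__(self) -> None:
        self.sampling_times = np.asarray(self.sampling_times, dtype=float)
        if len(self.conditions) < 1:
            raise GLVModelError("design needs at least one condition")
        self.conditions = [
            (str(lbl), np.asarray(inoc, dtype=float)) for lbl, inoc in self.conditions
        ]
        s = len(self.species)
        for lbl, inoc in self.conditions:
            if inoc.shape != (s,):
                raise GLVModelError(f"inoculum for {lbl!r} has wrong shape")
            if np.any(inoc <= 0):
                raise GLVModelError(f"inoculum for {lbl!r} must be > 0")
        if np.any(np.diff(self.sampling_times) <= 0):
            raise GLVModelError("sampling_times must be strictly increasing")
        if self.replicates < 1:
            raise GLVModelError("replicates must be >= 1")

    def condition_labels(self) -> list[str]:
        return [lbl for lbl, _ in self.conditions]

    def to_dict(self) -> dict:
        return {
            "species": list(self.species.labels),
            "conditions": [
                {"label": lbl, "inoculum": inoc.tolist()}
                for lbl, inoc in self.conditions
            ],
            "sampling_times": self.sampling_times.tolist(),
            "replicates": int(self.replicates),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyDesign":
        return cls(
            species=SpeciesSet(tuple(d["species"])),
            conditions=[
                (c["label"], np.asarray(c["inoculum"], dtype=float))
                for c in d["conditions"]
            ],
            sampling_times=np.asarray(d["sampling_times"], dtype=float),
            replicates=int(d["replicates"]),
        )


@dataclass
class NoiseModel:
    """Measurement model for qPCR-style quantification: multiplicative
    lognormal error with coefficient of variation ``measurement_cv`` and a
    detection floor below which values are clipped and flagged censored."""

    measurement_cv: float = 0.1
    detection_floor: float = 1e3

    def __post_init__(self) -> None:
        if self.measurement_cv < 0:
            raise GLVModelError("measurement_cv must be >= 0")
        if self.detection_floor < 0:
            raise GLVModelError("detection_floor must be >= 0")

    def to_dict(self) -> dict:
        return {
            "measurement_cv": float(self.measurement_cv),
            "detection_floor": float(self.detection_floor),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseModel":
        return cls(**d)


@dataclass
class GroundTruthRecord:
    """Everything needed to regenerate a synthetic dataset bitwise:
    parameters, design, noise settings and the master seed."""

    params: GLVParameters
    design: StudyDesign
    noise: NoiseModel
    seed: int

    def regenerate(self) -> list[Trajectory]:
        data, _ = generate_dataset(self.params, self.design, self.noise, self.seed)
        return data

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "design": self.design.to_dict(),
            "noise": self.noise.to_dict(),
            "seed": int(self.seed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthRecord":
        return cls(
            params=GLVParameters.from_dict(d["params"]),
            design=StudyDesign.from_dict(d["design"]),
            noise=NoiseModel.from_dict(d["noise"]),
            seed=int(d["seed"]),
        )


def make_knockdown_design(
    species: SpeciesSet,
    baseline_inoculum: Sequence[float] | float = DEFAULT_BASELINE_INOCULUM,
    knockdown_factor: float = 10.0,
    sampling_times: Sequence[float] = DEFAULT_SAMPLING_TIMES,
    replicates: int = 3,
) -> StudyDesign:
    """Equal-inoculum baseline plus one single-species knockdown per species.

    Returns S+1 conditions: ``baseline`` with every species at
    ``baseline_inoculum``, then ``kd_<label>`` for each species with only
    that species' inoculum divided by ``knockdown_factor``.
    """
    if knockdown_factor < 1:
        raise GLVModelError("knockdown_factor must be >= 1")
    s = len(species)
    base = np.asarray(baseline_inoculum, dtype=float)
    if base.ndim == 0:
        base = np.full(s, float(base))
    if base.shape != (s,):
        raise GLVModelError("baseline_inoculum has wrong shape")
    if np.any(base <= 0):
        raise GLVModelError("baseline inoculum must be > 0")
    conditions = [("baseline", base.copy())]
    for i, lbl in enumerate(species.labels):
        inoc = base.copy()
        inoc[i] /= knockdown_factor
        conditions.append((f"kd_{lbl}", inoc))
    return StudyDesign(
        species=species,
        conditions=conditions,
        sampling_times=np.asarray(sampling_times, dtype=float),
        replicates=replicates,
    )


# ---------------------------------------------------------------------------
# Ground-truth presets
# ---------------------------------------------------------------------------

# Off-diagonal edges present in the WT-like preset (target <- source), all
# antagonistic: 7 of the 12 possible interspecies edges.
_WT_EDGES = [
    ("Ec", "ST"),
    ("Ec", "BT"),
    ("ST", "Ec"),
    ("ST", "BF"),
    ("BT", "ST"),
    ("BT", "BF"),
    ("BF", "ST"),
]

# Engineered-like preset: the two positive cross-feeding edges from BF plus
# two residual antagonisms.
_ENG_POSITIVE_EDGES = [("Ec", "BF"), ("ST", "BF")]
_ENG_NEGATIVE_EDGES = [("Ec", "ST"), ("BF", "ST")]

_WT_BASE_RATES = np.array([0.95, 0.85, 0.80, 0.70])  # 1/h for Ec, ST, BT, BF
_WT_CAPACITY = 1e9  # CFU/ml single-species carrying capacity
_WT_EDGE_STRENGTH = 1.4  # |a_ij| relative to r_i / K
_WT_PROCESS_VAR = 1e10  # CFU^2/ml^2 per hour

_ENG_RATE_FACTOR = 3.0  # growth rates ~3x lower than WT
_ENG_CAPACITY_FACTOR = 10 ** 1.5  # capacity ~1.5 orders of magnitude lower
_ENG_EDGE_STRENGTH = 0.6
_ENG_PROCESS_VAR = 1e8


def _jitter(rng: np.random.Generator, scale: float, size) -> np.ndarray:
    """Multiplicative jitter in [1-scale, 1+scale], seeded."""
    return 1.0 + rng.uniform(-scale, scale, size=size)


def preset_wt_network(seed: int = 0) -> GLVParameters:
    """Wild-type-like 4-species ground truth: all interactions antagonistic.

    7 of the 12 off-diagonal edges carry strong negative coefficients; the
    remainder are absent.  Growth rates around 0.7-0.95 /h, carrying
    capacities near 1e9 CFU/ml.  ``seed`` jitters rates and strengths so
    distinct seeds give distinct but qualitatively identical truths.
    """
    rng = np.random.default_rng(seed)
    sp = DEFAULT_SPECIES
    s = len(sp)
    r = _WT_BASE_RATES * _jitter(rng, 0.10, s)
    a = np.zeros((s, s))
    np.fill_diagonal(a, -r / (_WT_CAPACITY * _jitter(rng, 0.10, s)))
    z = np.eye(s, dtype=int)
    for tgt, src in _WT_EDGES:
        i, j = sp.index(tgt), sp.index(src)
        a[i, j] = -_WT_EDGE_STRENGTH * r[i] / _WT_CAPACITY * _jitter(rng, 0.20, None)
        z[i, j] = 1
    return GLVParameters(
        species=sp,
        growth_rates=r,
        interaction_matrix=a,
        indicator_matrix=z,
        process_noise_variances=np.full(s, _WT_PROCESS_VAR),
    )


def preset_engineered_network(seed: int = 0) -> GLVParameters:
    """Engineered-like 4-species ground truth with two positive edges.

    Derived from the WT preset at the same seed: growth rates divided by 3,
    carrying capacities ~1.5 orders of magnitude lower, positive
    cross-feeding edges BF->Ec and BF->ST, and two residual antagonisms.
    """
    wt = preset_wt_network(seed)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 17]))
    sp = wt.species
    s = len(sp)
    r = wt.growth_rates / _ENG_RATE_FACTOR
    cap = -wt.growth_rates / np.diag(wt.interaction_matrix) / _ENG_CAPACITY_FACTOR
    a = np.zeros((s, s))
    np.fill_diagonal(a, -r / cap)
    z = np.eye(s, dtype=int)
    for tgt, src in _ENG_POSITIVE_EDGES:
        i, j = sp.index(tgt), sp.index(src)
        a[i, j] = _ENG_EDGE_STRENGTH * r[i] / cap[i] * _jitter(rng, 0.20, None)
        z[i, j] = 1
    for tgt, src in _ENG_NEGATIVE_EDGES:
        i, j = sp.index(tgt), sp.index(src)
        a[i, j] = -_ENG_EDGE_STRENGTH * r[i] / cap[i] * _jitter(rng, 0.20, None)
        z[i, j] = 1
    return GLVParameters(
        species=sp,
        growth_rates=r,
        interaction_matrix=a,
        indicator_matrix=z,
        process_noise_variances=np.full(s, _ENG_PROCESS_VAR),
    )


# ---------------------------------------------------------------------------
# Measurement model and dataset generation
# ---------------------------------------------------------------------------


def apply_measurement_noise(
    traj: Trajectory,
    noise: NoiseModel,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Trajectory:
    """Multiply abundances by unit-mean lognormal error with the configured
    CV, then clip at the detection floor (clipped values flagged censored)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    x = traj.abundances.copy()
    cv = noise.measurement_cv
    if cv > 0:
        # lognormal with mean 1 and coefficient of variation cv
        sigma2 = np.log1p(cv * cv)
        factors = np.exp(
            rng.standard_normal(x.shape) * np.sqrt(sigma2) - sigma2 / 2.0
        )
        x = x * factors
    censored = x < noise.detection_floor
    x = np.where(censored, noise.detection_floor, x)
    return Trajectory(
        times=traj.times.copy(),
        abundances=x,
        species=traj.species,
        condition=traj.condition,
        replicate=traj.replicate,
        censored=censored,
    )


def generate_dataset(
    params: GLVParameters,
    design: StudyDesign,
    noise: NoiseModel,
    seed: int = 0,
) -> tuple[list[Trajectory], GroundTruthRecord]:
    """Simulate one stochastic trajectory per condition x replicate and pass
    each through the measurement model.

    Child seeds are spawned deterministically from ``seed`` per (condition,
    replicate), so the record regenerates the dataset bitwise.
    """
    record = GroundTruthRecord(params=params, design=design, noise=noise, seed=seed)
    stochastic = bool(np.any(params.process_noise_variances > 0))
    trajectories: list[Trajectory] = []
    ss = np.random.SeedSequence(int(seed))
    children = ss.spawn(len(design.conditions) * design.replicates)
    idx = 0
    for lbl, inoc in design.conditions:
        for rep in range(design.replicates):
            rng = np.random.default_rng(children[idx])
            idx += 1
            traj = simulate(
                params,
                inoc,
                design.sampling_times,
                stochastic=stochastic,
                rng=rng,
                condition=lbl,
                replicate=rep,
            )
            traj = apply_measurement_noise(traj, noise, rng=rng)
            trajectories.append(traj)
    return trajectories, record
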