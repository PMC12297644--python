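"""Archimedes Optimization Algorithm (AOA).

A population metaheuristic in which every candidate solution is an "object"
immersed in a fluid, carrying a position, a density, a volume and an
acceleration.  Objects collide (exploration) early in the run and settle
toward buoyant equilibrium around the best object (exploitation) later; the
switch is governed by a transfer operator that grows with the iteration
count, and step sizes shrink through a decreasing density factor.

Two formula dialects are provided:

``canonical``
    The AOA update rules as established in the metaheuristic literature
    (density factor with a positive exponent, exploitation steps pulled
    toward the best object).  This is the default because it converges
    reliably.

``paper``
    A variant dialect that keeps the literal printed forms some derivative
    write-ups use: the density factor shares the transfer operator's
    (negative) exponent, and the exploitation step tracks a random object
    rather than the best.  Retained for fidelity testing.

The core minimizes; callers wanting maximization negate their objective.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, List, Literal, Sequence

import numpy as np

__all__ = [
    "AOAConfig",
    "MaterialObject",
    "AOAState",
    "AOAResult",
    "transfer_operator",
    "density_factor",
    "update_density_volume",
    "compute_acceleration",
    "normalize_acceleration",
    "select_flag",
    "exploration_move",
    "exploitation_move",
    "initialize_population",
    "step",
    "optimize",
]

Dialect = Literal["paper", "canonical"]

_EPS_DENOM = 1e-12  # floor for acceleration denominators


@dataclass
class AOAConfig:
    """Configuration of an AOA run.

    ``pop_size``/``max_iter`` default to the reference setting of 50 objects
    for 100 iterations.  ``c_explore``/``c_exploit``/``c_T`` are the step
    constants of the exploration move, the exploitation move and the
    time-scaled reference term; ``k4`` enters the direction-flag draw
    I = 2R - K4.  ``chi``/``lam`` define the normalization band
    [lam, lam + chi] for accelerations.
    """

    dim: int
    lower: np.ndarray
    upper: np.ndarray
    pop_size: int = 50
    max_iter: int = 100
    c_explore: float = 2.0
    c_exploit: float = 6.0
    c_T: float = 2.0
    k4: float = 0.5
    chi: float = 0.9
    lam: float = 0.1
    dialect: Dialect = "canonical"
    seed: int = 0

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if self.lower.shape != (self.dim,) or self.upper.shape != (self.dim,):
            raise ValueError("lower/upper must be vectors of length dim")
        if np.any(self.lower > self.upper):
            raise ValueError("lower must be <= upper componentwise")
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not (self.chi > 0 and self.lam >= 0 and self.chi + self.lam <= 1):
            raise ValueError("need 0 < chi, 0 <= lam, chi + lam <= 1")
        if self.dialect not in ("paper", "canonical"):
            raise ValueError(f"unknown dialect {self.dialect!r}")


@dataclass
class MaterialObject:
    """One AOA candidate: a material object with physical attributes."""

    position: np.ndarray
    density: np.ndarray
    volume: np.ndarray
    acceleration: np.ndarray
    fitness: float

    def copy(self) -> "MaterialObject":
        return MaterialObject(
            self.position.copy(),
            self.density.copy(),
            self.volume.copy(),
            self.acceleration.copy(),
            float(self.fitness),
        )


@dataclass
class AOAState:
    """Mutable optimizer state; arrays are (pop_size, dim)."""

    Z: np.ndarray
    den: np.ndarray
    vol: np.ndarray
    acl: np.ndarray
    fitness: np.ndarray
    best: MaterialObject
    iteration: int
    rng: np.random.Generator

    @property
    def population(self) -> List[MaterialObject]:
        return [
            MaterialObject(
                self.Z[j].copy(), self.den[j].copy(), self.vol[j].copy(),
                self.acl[j].copy(), float(self.fitness[j]),
            )
            for j in range(self.Z.shape[0])
        ]


@dataclass
class AOAResult:
    best_position: np.ndarray
    best_fitness: float
    history: np.ndarray  # best-so-far fitness per iteration; non-increasing

    def to_dict(self) -> dict:
        return {
            "best_position": self.best_position.tolist(),
            "best_fitness": float(self.best_fitness),
            "history": self.history.tolist(),
        }


def transfer_operator(T: int, max_T: int) -> float:
    """Exploration→exploitation switch: exp((T - max_T)/max_T), in (e^-1, 1]."""
    if max_T <= 0:
        raise ValueError("max_T must be positive")
    return math.exp((T - max_T) / max_T)


def density_factor(T: int, max_T: int, dialect: Dialect = "canonical") -> float:
    """Decreasing step-size schedule; 0 at T = max_T in both dialects."""
    if max_T <= 0:
        raise ValueError("max_T must be positive")
    if dialect == "paper":
        return math.exp((T - max_T) / max_T) - T / max_T
    return math.exp((max_T - T) / max_T) - T / max_T


def _uniform_nonzero(rng: np.random.Generator, shape) -> np.ndarray:
    """Uniform (0, 1] draws: exact zeros are rejected so densities and
    volumes are strictly positive by construction."""
    r = rng.random(shape)
    while np.any(r == 0.0):
        zero = r == 0.0
        r[zero] = rng.random(int(zero.sum()))
    return r


def update_density_volume(
    obj: MaterialObject,
    best: MaterialObject,
    rng: np.random.Generator | None = None,
    r: np.ndarray | float | None = None,
) -> MaterialObject:
    """Pull density and volume toward the best object by a random fraction.

    ``r`` may be forced (tests); otherwise fresh uniform [0,1] draws are made
    per component.  Position and acceleration are unchanged.
    """
    if r is None:
        if rng is None:
            raise ValueError("provide rng or forced r")
        r_den = rng.random(obj.density.shape)
        r_vol = rng.random(obj.volume.shape)
    else:
        r_den = r_vol = np.asarray(r, dtype=float)
    out = obj.copy()
    out.density = obj.density + r_den * (best.density - obj.density)
    out.volume = obj.volume + r_vol * (best.volume - obj.volume)
    return out


def compute_acceleration(
    obj: MaterialObject, ref: MaterialObject, phase: str = "exploration"
) -> np.ndarray:
    """Acceleration transfer from a reference object.

    ``ref`` is a random collision partner during exploration and the best
    object during exploitation; ``obj`` must already carry its *updated*
    density/volume (the denominator).  The denominator is floored at 1e-12.
    """
    if phase not in ("exploration", "exploitation"):
        raise ValueError(f"unknown phase {phase!r}")
    numer = ref.density + ref.volume * ref.acceleration
    denom = np.maximum(obj.density * obj.volume, _EPS_DENOM)
    return numer / denom


def normalize_acceleration(
    accels: np.ndarray, chi: float = 0.9, lam: float = 0.1
) -> np.ndarray:
    """Min-max normalize accelerations over the population, per component,
    into [lam, lam + chi].  When a component is constant across the
    population the midpoint lam + chi/2 is returned (tie rule) so motion
    never freezes."""
    accels = np.asarray(accels, dtype=float)
    amin = accels.min(axis=0, keepdims=True)
    amax = accels.max(axis=0, keepdims=True)
    span = amax - amin
    out = np.full_like(accels, lam + chi / 2.0)
    nz = np.broadcast_to(span > 0, accels.shape)
    scaled = np.divide(accels - amin, np.where(span == 0, 1.0, span))
    out[nz] = chi * scaled[nz] + lam
    return out


def select_flag(
    rng: np.random.Generator | None = None,
    k4: float = 0.5,
    r: float | None = None,
) -> int:
    """Direction flag of the exploitation move: draw R ~ U[0,1], form
    I = 2R - K4, return +1 if I <= 0.5 else -1."""
    if r is None:
        if rng is None:
            raise ValueError("provide rng or forced r")
        r = float(rng.random())
    i = 2.0 * r - k4
    return 1 if i <= 0.5 else -1


def exploration_move(
    z: np.ndarray,
    z_rand: np.ndarray,
    r: np.ndarray | float,
    acl_norm: np.ndarray | float,
    d: float,
    c_explore: float,
    lower: np.ndarray,
    upper: np.ndarray,
) -> np.ndarray:
    """Collision step toward a random object, clipped into the box."""
    z_new = z + c_explore * r * acl_norm * d * (z_rand - z)
    return np.clip(z_new, lower, upper)


def exploitation_move(
    z: np.ndarray,
    z_best: np.ndarray,
    z_ref: np.ndarray,
    r: np.ndarray | float,
    acl_norm: np.ndarray | float,
    d: float,
    to: float,
    flag: int,
    c_exploit: float,
    c_T: float,
    lower: np.ndarray,
    upper: np.ndarray,
) -> np.ndarray:
    """Buoyancy step around the best object with time-scaled reference
    T_s = c_T * TO, clipped into the box."""
    t_s = c_T * to
    z_new = z_best + flag * c_exploit * r * acl_norm * d * (t_s * z_ref - z)
    return np.clip(z_new, lower, upper)


def initialize_population(
    config: AOAConfig, objective: Callable[[np.ndarray], float]
) -> AOAState:
    """Seeded initialization: positions and accelerations uniform in the box,
    densities and volumes uniform in (0, 1]."""
    rng = np.random.default_rng(config.seed)
    span = config.upper - config.lower
    Z = config.lower + rng.random((config.pop_size, config.dim)) * span
    den = _uniform_nonzero(rng, (config.pop_size, config.dim))
    vol = _uniform_nonzero(rng, (config.pop_size, config.dim))
    acl = config.lower + rng.random((config.pop_size, config.dim)) * span
    fitness = np.empty(config.pop_size)
    for j in range(config.pop_size):
        f = float(objective(Z[j]))
        if not math.isfinite(f):
            raise ValueError(
                f"objective is non-finite at initial position {Z[j].tolist()}"
            )
        fitness[j] = f
    j_best = int(np.argmin(fitness))
    best = MaterialObject(
        Z[j_best].copy(), den[j_best].copy(), vol[j_best].copy(),
        acl[j_best].copy(), float(fitness[j_best]),
    )
    return AOAState(Z=Z, den=den, vol=vol, acl=acl, fitness=fitness,
                    best=best, iteration=0, rng=rng)


def step(
    state: AOAState, objective: Callable[[np.ndarray], float], config: AOAConfig
) -> AOAState:
    """One AOA iteration, in place on ``state`` (returned for chaining).

    Order of operations per iteration T (1-based): density/volume pull toward
    the best; transfer operator and density factor; phase-dependent
    accelerations (random partner if TO <= 0.5, best object otherwise);
    population-wide acceleration normalization; phase-dependent moves with
    box clipping; re-evaluation with greedy best retention.  An objective
    returning NaN leaves that object at its previous position.
    """
    rng = state.rng
    pop, dim = state.Z.shape
    T = state.iteration + 1
    to = transfer_operator(T, config.max_iter)
    d = density_factor(T, config.max_iter, config.dialect)

    den_new = state.den + rng.random((pop, dim)) * (state.best.density - state.den)
    vol_new = state.vol + rng.random((pop, dim)) * (state.best.volume - state.vol)

    explore = to <= 0.5
    if explore:
        # collision partners: previous-iteration properties of a random object
        idx = rng.integers(0, pop, size=pop)
        numer = state.den[idx] + state.vol[idx] * state.acl[idx]
    else:
        numer = state.best.density + state.best.volume * state.best.acceleration
    denom = np.maximum(den_new * vol_new, _EPS_DENOM)
    acl_raw = numer / denom
    acl_norm = normalize_acceleration(acl_raw, config.chi, config.lam)

    R = rng.random((pop, dim))
    if explore:
        Z_new = state.Z + config.c_explore * R * acl_norm * d * (
            state.Z[idx] - state.Z
        )
    else:
        r_flag = rng.random(pop)
        flags = np.where(2.0 * r_flag - config.k4 <= 0.5, 1.0, -1.0)[:, None]
        if config.dialect == "paper":
            ridx = rng.integers(0, pop, size=pop)
            z_ref = state.Z[ridx]
        else:
            z_ref = state.best.position[None, :]
        t_s = config.c_T * to
        Z_new = state.best.position[None, :] + flags * config.c_exploit * R * (
            acl_norm * d * (t_s * z_ref - state.Z)
        )
    Z_new = np.clip(Z_new, config.lower, config.upper)

    fit_new = np.empty(pop)
    for j in range(pop):
        f = float(objective(Z_new[j]))
        if math.isnan(f):
            # keep the previous position for this object
            Z_new[j] = state.Z[j]
            fit_new[j] = state.fitness[j]
        else:
            fit_new[j] = f

    state.Z = Z_new
    state.den = den_new
    state.vol = vol_new
    state.acl = acl_raw
    state.fitness = fit_new
    j_best = int(np.argmin(fit_new))
    if fit_new[j_best] < state.best.fitness:
        state.best = MaterialObject(
            Z_new[j_best].copy(), den_new[j_best].copy(), vol_new[j_best].copy(),
            acl_raw[j_best].copy(), float(fit_new[j_best]),
        )
    state.iteration = T
    return state


def optimize(
    objective: Callable[[np.ndarray], float], config: AOAConfig
) -> AOAResult:
    """Run ``max_iter`` AOA iterations from a seeded initialization."""
    state = initialize_population(config, objective)
    history = np.empty(config.max_iter)
    for t in range(config.max_iter):
        step(state, objective, config)
        history[t] = state.best.fitness
    return AOAResult(
        best_position=state.best.position.copy(),
        best_fitness=float(state.best.fitness),
        history=history,
    )
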