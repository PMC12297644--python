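"""Hyperparameter search: AOA positions decoded into classifier settings.

The four tunables — learning rate (log scale), momentum, epochs, dropout —
live in a unit box [0,1]^4 that the optimizer explores; each position is
decoded into a :class:`~cardiovault.net.NetworkConfig` override and scored
by mean stratified-cross-validated accuracy (the fitness).  The optimizer
minimizes the negated fitness; repeated positions are memoized.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, replace, asdict
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .aoa import AOAConfig, AOAResult, optimize
from .net import NetworkConfig, train, predict

__all__ = [
    "SearchSpace",
    "FitnessSpec",
    "Hyperparameters",
    "decode_position",
    "stratified_folds",
    "fitness",
    "search",
    "baseline_hyperparameters",
    "log_to_csv",
]


@dataclass
class SearchSpace:
    """Bounds of the four tunables; the defaults bracket both the baseline
    setting (lr 0.1, 32 epochs, dropout 0.243) and the example tuned
    optimum (lr 1e-4, momentum 0.9, 30 epochs, dropout 0.2)."""

    lr_bounds: Tuple[float, float] = (1e-5, 1e-1)
    momentum_bounds: Tuple[float, float] = (0.5, 0.99)
    epochs_bounds: Tuple[int, int] = (10, 50)
    dropout_bounds: Tuple[float, float] = (0.0, 0.5)

    def __post_init__(self) -> None:
        for lo, hi in (self.lr_bounds, self.momentum_bounds,
                       self.epochs_bounds, self.dropout_bounds):
            if lo > hi:
                raise ValueError("search-space bounds must be ordered")
        if self.lr_bounds[0] <= 0:
            raise ValueError("learning rate bounds must be positive")


@dataclass
class FitnessSpec:
    """Stratified k-fold accuracy as the search fitness."""

    n_folds: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass
class Hyperparameters:
    learning_rate: float
    momentum: float
    epochs: int
    dropout: float

    def to_dict(self) -> dict:
        return asdict(self)


def baseline_hyperparameters() -> Hyperparameters:
    """The baseline configuration expressed as a search point (momentum at
    the network default 0.9)."""
    return Hyperparameters(learning_rate=0.1, momentum=0.9, epochs=32,
                           dropout=0.243)


def decode_position(position: Sequence[float], space: SearchSpace) -> Hyperparameters:
    """Unit-box position -> hyperparameters.

    Learning rate interpolates on the log10 scale; momentum and dropout are
    linear; epochs round to the nearest integer.  Every coordinate is
    clipped into its bounds first, so any finite position decodes.
    """
    p = np.clip(np.asarray(position, dtype=float), 0.0, 1.0)
    if p.shape != (4,):
        raise ValueError("position must be a 4-vector")
    lo, hi = space.lr_bounds
    lr = 10.0 ** (math.log10(lo) + p[0] * (math.log10(hi) - math.log10(lo)))
    mlo, mhi = space.momentum_bounds
    momentum = mlo + p[1] * (mhi - mlo)
    elo, ehi = space.epochs_bounds
    epochs = int(np.clip(round(elo + p[2] * (ehi - elo)), elo, ehi))
    dlo, dhi = space.dropout_bounds
    dropout = dlo + p[3] * (dhi - dlo)
    return Hyperparameters(float(lr), float(momentum), epochs, float(dropout))


def stratified_folds(y: np.ndarray, n_folds: int, seed: int) -> List[np.ndarray]:
    """Index folds preserving class ratios (round-robin after a seeded
    shuffle within each class)."""
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(seed)
    folds: List[List[int]] = [[] for _ in range(n_folds)]
    for cls in np.unique(y):
        idx = np.where(y == cls)[0]
        idx = idx[rng.permutation(idx.size)]
        for i, j in enumerate(idx):
            folds[i % n_folds].append(int(j))
    return [np.array(sorted(f), dtype=int) for f in folds]


def fitness(
    hp: Hyperparameters,
    X: np.ndarray,
    y: np.ndarray,
    spec: FitnessSpec,
    net_config: NetworkConfig | None = None,
) -> float:
    """Mean validation accuracy over stratified folds, in [0, 1];
    deterministic given ``spec.seed``."""
    base = net_config or NetworkConfig()
    cfg = replace(
        base,
        learning_rate=hp.learning_rate,
        momentum=hp.momentum,
        epochs=hp.epochs,
        dropout_rate=hp.dropout,
        seed=spec.seed,
    )
    folds = stratified_folds(y, spec.n_folds, spec.seed)
    accs = []
    for i, val_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(y)), val_idx)
        if np.unique(y[val_idx]).size < 2 or np.unique(y[train_idx]).size < 2:
            raise ValueError(f"fold {i} contains a single class")
        try:
            params, _ = train(cfg, X[train_idx], y[train_idx])
        except ValueError as exc:
            raise ValueError(f"fold {i}: {exc}") from exc
        labels, _ = predict(params, X[val_idx])
        accs.append(float((labels == y[val_idx]).mean()))
    return float(np.mean(accs))


def search(
    X: np.ndarray,
    y: np.ndarray,
    space: SearchSpace | None = None,
    aoa_config: AOAConfig | None = None,
    spec: FitnessSpec | None = None,
    net_config: NetworkConfig | None = None,
) -> Tuple[Hyperparameters, AOAResult, List[dict]]:
    """AOA search over the unit box, maximizing CV accuracy.

    Returns the best decoded hyperparameters, the optimizer trace (negated
    fitness; best-so-far non-increasing) and the evaluation log, one entry
    per distinct position evaluated: {"position", "hyperparameters",
    "fitness"}.  Repeated positions are served from a memo.
    """
    space = space or SearchSpace()
    spec = spec or FitnessSpec()
    if aoa_config is None:
        aoa_config = AOAConfig(dim=4, lower=np.zeros(4), upper=np.ones(4),
                               pop_size=6, max_iter=8, seed=spec.seed)
    if aoa_config.dim != 4:
        raise ValueError("search requires a 4-dimensional AOA box")
    memo: Dict[tuple, float] = {}
    log: List[dict] = []

    def objective(position: np.ndarray) -> float:
        key = tuple(np.round(position, 12))
        if key not in memo:
            hp = decode_position(position, space)
            fit = fitness(hp, X, y, spec, net_config)
            memo[key] = fit
            log.append({
                "position": [float(v) for v in position],
                "hyperparameters": hp.to_dict(),
                "fitness": fit,
            })
        return -memo[key]

    result = optimize(objective, aoa_config)
    best_hp = decode_position(result.best_position, space)
    return best_hp, result, log


def log_to_csv(log: Sequence[dict], path: str) -> None:
    """Search trace as CSV (position, decoded hp, fitness)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["p0", "p1", "p2", "p3", "learning_rate", "momentum",
                         "epochs", "dropout", "fitness"])
        for entry in log:
            hp = entry["hyperparameters"]
            writer.writerow(entry["position"] + [
                hp["learning_rate"], hp["momentum"], hp["epochs"],
                hp["dropout"], entry["fitness"],
            ])
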