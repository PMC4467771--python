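"""Monte Carlo analysis of statistical sensitivity vs. testing time/accuracy.

For a participant's pool of attended and unattended epochs, the procedure
draws n attended and 7n unattended epochs, optionally swaps a fraction of
attended epochs for unattended ones to emulate a lower accuracy (at
simulated accuracy a, round((1-a)*n) epochs are exchanged), runs a
single-participant cluster-mass test on the two sets, and repeats.  Mean
p-value as a function of n (one stream slot per stimulus: each attended
target accounts for ~4 s of testing time) shows how much testing time a
given accuracy needs before the test becomes significant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cmpt import AdjacencyGraph, build_adjacency, permutation_test

_log = logging.getLogger(__name__)

__all__ = [
    "MonteCarloConfig",
    "MonteCarloCurve",
    "subsample",
    "swap_for_accuracy",
    "mc_curve",
    "required_targets",
]


@dataclass(frozen=True)
class MonteCarloConfig:
    """Grid and repetition settings for the sensitivity analysis."""

    n_grid: tuple[int, ...] = tuple(range(25, 625, 25))  # multiples of 25
    reps_per_n: int = 100
    accuracies: tuple[float, ...] = (0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
    alpha: float = 0.05
    unattended_ratio: int = 7
    n_perm: int = 500  # permutations per repetition's cluster test
    seed: int = 0

    def __post_init__(self) -> None:
        if list(self.n_grid) != sorted(set(self.n_grid)):
            raise ValueError("n_grid must be strictly increasing")
        if any(not 0.0 < a <= 1.0 for a in self.accuracies):
            raise ValueError("accuracies must lie in (0, 1]")
        if self.reps_per_n < 1:
            raise ValueError("reps_per_n must be >= 1")


@dataclass
class MonteCarloCurve:
    """Mean (and dispersion of) cluster-test p as a function of n."""

    accuracy: float
    n: np.ndarray
    mean_p: np.ndarray
    sd_p: np.ndarray
    n_reps: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"accuracy": self.accuracy, "n": self.n, "mean_p": self.mean_p,
             "sd_p": self.sd_p, "n_reps": self.n_reps}
        )


def subsample(
    attended: np.ndarray,
    unattended: np.ndarray,
    n: int,
    rng: np.random.Generator | int | None = None,
    ratio: int = 7,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n attended and ratio*n unattended epochs uniformly.

    Pools smaller than the request are sampled with replacement (sessions
    cap the attended pool near 200 epochs while the analysis extends n well
    beyond that); the switch is logged per draw.
    """
    if len(attended) == 0 or len(unattended) == 0:
        raise ValueError("epoch pools must be nonempty")
    rng = np.random.default_rng(rng)
    out = []
    for pool, k in ((attended, n), (unattended, ratio * n)):
        replace = k > len(pool)
        if replace:
            _log.info("requested %d epochs from a pool of %d; sampling with "
                      "replacement", k, len(pool))
        out.append(pool[rng.choice(len(pool), size=k, replace=replace)])
    return out[0], out[1]


def swap_for_accuracy(
    a: np.ndarray,
    b: np.ndarray,
    accuracy: float,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Exchange round((1-accuracy)*|A|) members of A with members of B.

    Rounding is to nearest integer, ties to even.  Group sizes are
    preserved; at accuracy 1.0 the inputs are returned unchanged.
    """
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError(f"accuracy {accuracy} outside [0, 1]")
    k = round((1.0 - accuracy) * len(a))
    if k == 0:
        return a, b
    rng = np.random.default_rng(rng)
    ia = rng.choice(len(a), size=k, replace=False)
    ib = rng.choice(len(b), size=k, replace=False)
    a2, b2 = a.copy(), b.copy()
    a2[ia], b2[ib] = b[ib], a[ia]
    return a2, b2


def mc_curve(
    attended: np.ndarray,
    unattended: np.ndarray,
    cfg: MonteCarloConfig | None = None,
    adjacency: AdjacencyGraph | None = None,
    stop_when_mean_p_below: float | None = None,
) -> list[MonteCarloCurve]:
    """Run the full grid: one curve per simulated accuracy.

    Inputs are epoch stacks (n_epochs, n_ch, n_times), typically the
    attended/unattended partition of a session restricted to post-stimulus
    samples.  ``stop_when_mean_p_below`` truncates a curve once its mean p
    drops under the given value (the smallest such n is what
    :func:`required_targets` reports, so later grid points are redundant
    for that question).  A repetition whose cluster test fails is logged
    and excluded from the mean.
    """
    cfg = cfg or MonteCarloConfig()
    adjacency = adjacency or build_adjacency()
    master = np.random.default_rng(cfg.seed)
    curves = []
    for accuracy in cfg.accuracies:
        ns, means, sds, reps_used = [], [], [], []
        for n in cfg.n_grid:
            ps = []
            for _ in range(cfg.reps_per_n):
                rng = np.random.default_rng(master.integers(2 ** 31))
                try:
                    a, b = subsample(attended, unattended, n, rng,
                                     ratio=cfg.unattended_ratio)
                    a, b = swap_for_accuracy(a, b, accuracy, rng)
                    res = permutation_test(a, b, level="single",
                                           n_perm=cfg.n_perm, rng=rng,
                                           adjacency=adjacency,
                                           alpha=cfg.alpha, exact=False)
                    ps.append(res.p_value)
                except ValueError as err:  # pragma: no cover - defensive
                    warnings.warn(f"repetition failed at n={n}: {err}")
            ps = np.asarray(ps)
            ns.append(n)
            means.append(ps.mean() if len(ps) else np.nan)
            sds.append(ps.std(ddof=1) if len(ps) > 1 else np.nan)
            reps_used.append(len(ps))
            if (stop_when_mean_p_below is not None
                    and means[-1] < stop_when_mean_p_below):
                break
        curves.append(
            MonteCarloCurve(accuracy, np.array(ns), np.array(means),
                            np.array(sds), np.array(reps_used))
        )
    return curves


def required_targets(curve: MonteCarloCurve, alpha: float = 0.05) -> int | None:
    """Smallest grid n whose mean p is below alpha (None if unattained)."""
    below = np.nonzero(curve.mean_p < alpha)[0]
    return int(curve.n[below[0]]) if len(below) else None


def curves_frame(curves: Sequence[MonteCarloCurve]) -> pd.DataFrame:
    return pd.concat([c.to_frame() for c in curves], ignore_index=True)
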