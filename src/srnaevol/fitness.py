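"""Fitness of an sRNA production phenotype in a given environment.

At each cell division during development, fitness multiplies a production
cost against the benefit of matching the environment::

    W(n, eps, P_b) = 1 / (1 + C_n*n + C_b*P_b)
                     * exp[-(beta + alpha*eps) * (phi(n) - eps)^2]

where ``phi(n) = (e^n - 1) / (e^n + e^h - 2)`` is a logistic-shaped
phenotype in [0, 1): 0 without sRNA, rising to 1 at high amounts (the best
match to the most stressful environment), and equal to 1/2 at ``n = h``.
The penalty weight ``beta + alpha*eps`` grows with stress, so the same
phenotype-environment mismatch costs more in a stressful environment than
in a benign one (excess sRNA is milder than a shortfall).

Fitness is aggregated geometrically: across the ``c + 1`` cell divisions
of one life (``W_LIFE``) and across the ``G`` generations of an
environmental cycle (``W_GEO``). A mutant invades a resident when its
``W_GEO`` is higher; the selection coefficient is the relative excess
``s = W_mut/W_res - 1``, with ``|s| <= 0.001`` treated as effectively
neutral (drift-dominated except in large populations).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .dynamics import Trajectory

__all__ = [
    "FitnessShape",
    "phenotype",
    "instantaneous_fitness",
    "lifetime_fitness",
    "geometric_mean_fitness",
    "selection_coefficient",
    "is_weak_selection",
    "optimal_srna_level",
    "WEAK_SELECTION_THRESHOLD",
]

#: |s| at or below this is classified as weak (drift-dominated) selection.
WEAK_SELECTION_THRESHOLD = 1e-3


@dataclasses.dataclass(frozen=True)
class FitnessShape:
    """Constants of the fitness function.

    alpha : steepness of the stress-dependent mismatch penalty (default 15).
    beta : baseline mismatch penalty in a benign environment (default 0.1).
    h : sRNA amount whose phenotype matches intermediate stress eps = 0.5.
    C_n : cost per unit of sRNA maintained (default 1e-5).
    C_b : cost of plastic amplification, charged as C_b * P_b (default 50*C_n).
    """

    alpha: float = 15.0
    beta: float = 0.1
    h: float = 5.0
    C_n: float = 1e-5
    C_b: float = 50e-5

    def __post_init__(self) -> None:
        vals = (self.alpha, self.beta, self.h, self.C_n, self.C_b)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("all fitness-shape constants must be finite")
        if self.h <= 0:
            raise ValueError("h must be > 0")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if self.C_n < 0 or self.C_b < 0:
            raise ValueError("costs C_n and C_b must be >= 0")

    def replace(self, **changes) -> "FitnessShape":
        return dataclasses.replace(self, **changes)


def phenotype(n, h: float = 5.0):
    """Logistic-shaped sRNA phenotype ``(e^n - 1)/(e^n + e^h - 2)``.

    Computed as ``(1 - e^-n)/(1 + (e^h - 2) e^-n)``, which is stable for
    arbitrarily large ``n`` (no overflow) and exact at ``n = 0``.
    """
    n = np.asarray(n, dtype=float)
    if np.any(n < 0):
        raise ValueError("sRNA amount n must be >= 0")
    if h <= 0:
        raise ValueError("h must be > 0")
    en = np.exp(-n)
    out = -np.expm1(-n) / (1.0 + (math.exp(h) - 2.0) * en)
    return float(out) if out.ndim == 0 else out


def instantaneous_fitness(n, eps: float, P_b: float, shape: FitnessShape):
    """Fitness at a single cell division; strictly positive, at most 1."""
    if not 0.0 <= eps <= 1.0:
        raise ValueError(f"environment eps must be in [0, 1], got {eps}")
    if not 0.0 <= P_b <= 1.0:
        raise ValueError(f"plasticity P_b must be in [0, 1], got {P_b}")
    n = np.asarray(n, dtype=float)
    if np.any(n < 0):
        raise ValueError("sRNA amount n must be >= 0")
    cost = 1.0 / (1.0 + shape.C_n * n + shape.C_b * P_b)
    mismatch = phenotype(n, shape.h) - eps
    out = cost * np.exp(-(shape.beta + shape.alpha * eps) * mismatch**2)
    return float(out) if out.ndim == 0 else out


def _log_lifetime_fitness(n_samples: np.ndarray, eps: float, P_b: float,
                          shape: FitnessShape) -> float:
    """log W_LIFE from n at the c+1 integer times (log-space product)."""
    w = instantaneous_fitness(n_samples, eps, P_b, shape)
    return float(np.mean(np.log(w)))


def lifetime_fitness(traj: Trajectory, eps: float, P_b: float,
                     shape: FitnessShape) -> float:
    """Geometric mean fitness over development.

    The product runs over the ``c + 1`` integer times t = 0..c of the
    trajectory, with exponent ``1/(c + 1)``.
    """
    n = traj.at_integer_times()
    return math.exp(_log_lifetime_fitness(n, eps, P_b, shape))


def geometric_mean_fitness(w_life: Sequence[float]) -> float:
    """Geometric mean of per-generation fitnesses, computed in log space.

    Log-space accumulation keeps products of thousands of small fitnesses
    (e.g. 1e-6 per generation) from underflowing.
    """
    w = np.asarray(w_life, dtype=float)
    if w.size == 0:
        raise ValueError("need at least one per-generation fitness")
    if np.any(w <= 0):
        raise ValueError("per-generation fitnesses must be > 0")
    return math.exp(float(np.mean(np.log(w))))


def selection_coefficient(w_mut: float, w_res: float) -> float:
    """Relative invasion fitness of the mutant: ``w_mut/w_res - 1``."""
    if w_res <= 0:
        raise ValueError("resident fitness must be > 0")
    return w_mut / w_res - 1.0


def is_weak_selection(s: float, threshold: float = WEAK_SELECTION_THRESHOLD) -> bool:
    """True when |s| <= threshold, i.e. drift dominates selection."""
    return abs(s) <= threshold


def optimal_srna_level(eps: float, shape: FitnessShape,
                       n_max: float = 20.0, xatol: float = 1e-6) -> float:
    """The sRNA amount maximizing instantaneous fitness at a given stress.

    Bounded scalar maximization over ``n`` in [0, n_max] with P_b = 0.
    """
    res = minimize_scalar(
        lambda n: -instantaneous_fitness(n, eps, 0.0, shape),
        bounds=(0.0, n_max), method="bounded", options={"xatol": xatol},
    )
    if not res.success:
        raise RuntimeError(f"optimization of n failed: {res.message}")
    return float(res.x)
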