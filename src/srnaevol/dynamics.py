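"""Within-generation sRNA dynamics.

The per-cell amount of a small RNA, ``n``, changes during development through
three processes: transcription from genomic DNA at rate ``mu`` (primary
sRNAs), template-based amplification of existing sRNAs (secondary sRNAs,
e.g. ping-pong or RdRP cycles), and first-order degradation at rate ``d``.
Amplification rises linearly with ``n`` while templates are rare and
saturates at a maximum rate ``m``::

    dn/dt = (b / (1 + b*n/m) - d) * n + mu

Time is measured in cell divisions; a generation spans ``c`` divisions
(default 20). For ``b > 0`` the equation has a single positive equilibrium
(see :func:`steady_state_level`); for ``b = 0`` the dynamics are linear and
solvable in closed form (:func:`closed_form_b0`).

A ``speed`` factor multiplies all four rates at once. This rescales time
without moving the steady state: ``n(t; speed=f)`` equals the unscaled
solution evaluated at ``f*t``.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Union

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "SRNAParams",
    "Trajectory",
    "IntegrationError",
    "srna_rate",
    "steady_state_level",
    "closed_form_b0",
    "integrate_generation",
    "DEFAULT_CELL_DIVISIONS",
]

#: Cell divisions per generation; within the germline range reported for
#: animals (8.5 in C. elegans to 200 in humans).
DEFAULT_CELL_DIVISIONS = 20


class IntegrationError(RuntimeError):
    """Raised when numerical integration of the sRNA dynamics fails."""


@dataclasses.dataclass(frozen=True)
class SRNAParams:
    """Within-generation rate constants.

    Parameters
    ----------
    b : float
        Amplification rate per cell division (>= 0).
    d : float
        Degradation rate per cell division (> 0).
    m : float
        Maximum amplification rate (> 0), the saturation level of the
        template-based birth term.
    mu : float
        Transcription rate from genomic DNA per cell division (>= 0).
    speed : float
        Positive factor applied multiplicatively to all four rates
        (1.0 = default dynamics, 0.75 = slowed, 2.0 = sped up).
    """

    b: float = 0.0
    d: float = 0.1
    m: float = 5.0
    mu: float = 6.798
    speed: float = 1.0

    def __post_init__(self) -> None:
        if not all(math.isfinite(x) for x in (self.b, self.d, self.m, self.mu, self.speed)):
            raise ValueError("all rate parameters must be finite")
        if self.b < 0:
            raise ValueError(f"amplification rate b must be >= 0, got {self.b}")
        if self.mu < 0:
            raise ValueError(f"transcription rate mu must be >= 0, got {self.mu}")
        if self.speed <= 0:
            raise ValueError(f"speed factor must be > 0, got {self.speed}")
        if self.d * self.speed <= 0:
            raise ValueError(f"degradation rate d must be > 0, got {self.d}")
        if self.m * self.speed <= 0:
            raise ValueError(f"maximum amplification m must be > 0, got {self.m}")

    def replace(self, **changes) -> "SRNAParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    @property
    def scaled(self) -> tuple[float, float, float, float]:
        """Effective ``(b, d, m, mu)`` after applying the speed factor."""
        f = self.speed
        return (self.b * f, self.d * f, self.m * f, self.mu * f)


@dataclasses.dataclass(frozen=True)
class Trajectory:
    """Developmental time course of the per-cell sRNA amount.

    ``times`` covers at least the integer grid 0..c (fitness is sampled at
    cell divisions); ``b_soma`` is the somatic amplification rate in effect
    at each time point.
    """

    times: np.ndarray
    n: np.ndarray
    b_soma: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "n", np.asarray(self.n, dtype=float))
        object.__setattr__(self, "b_soma", np.asarray(self.b_soma, dtype=float))
        if not (len(self.times) == len(self.n) == len(self.b_soma)):
            raise ValueError("times, n and b_soma must have equal length")
        if self.times[0] != 0:
            raise ValueError("trajectory must start at t = 0")
        if np.any(self.n < 0):
            raise ValueError("sRNA amounts must be non-negative")

    @property
    def c(self) -> int:
        """Number of cell divisions covered (the last time point)."""
        return int(round(self.times[-1]))

    @property
    def n_final(self) -> float:
        """Adult sRNA amount, n at t = c."""
        return float(self.n[-1])

    def at_integer_times(self) -> np.ndarray:
        """n sampled at t = 0, 1, ..., c; raises if any sample is missing."""
        c = self.c
        grid = np.arange(c + 1, dtype=float)
        idx = np.searchsorted(self.times, grid)
        ok = (idx < len(self.times)) & np.isclose(
            self.times[np.minimum(idx, len(self.times) - 1)], grid, atol=1e-9
        )
        if not ok.all():
            missing = grid[~ok]
            raise ValueError(f"trajectory is missing integer time samples: {missing}")
        return self.n[idx]

    def to_frame(self):
        """Trajectory as a pandas DataFrame with columns (t, n, b_soma)."""
        import pandas as pd

        return pd.DataFrame({"t": self.times, "n": self.n, "b_soma": self.b_soma})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")


BProfile = Union[float, Callable[[float], float]]


def srna_rate(n: float, b_now: float, params: SRNAParams) -> float:
    """Instantaneous rate of change dn/dt of the per-cell sRNA amount.

    ``b_now`` overrides the amplification rate in ``params`` (it may vary
    during development under somatic plasticity); all rates, including
    ``b_now``, are scaled by ``params.speed``.
    """
    if n < 0:
        raise ValueError(f"sRNA amount n must be >= 0, got {n}")
    if b_now < 0:
        raise ValueError(f"amplification rate must be >= 0, got {b_now}")
    f = params.speed
    b, d, m, mu = b_now * f, params.d * f, params.m * f, params.mu * f
    return (b / (1.0 + b * n / m) - d) * n + mu


def steady_state_level(params: SRNAParams) -> float:
    """The biologically relevant (non-negative) equilibrium of the dynamics.

    For ``b > 0`` the quadratic fixed-point condition has exactly one
    positive root; for ``b = 0`` the expression is 0/0 and the analytic
    limit ``mu/d`` is used instead. The result does not depend on the
    speed factor.
    """
    b, d, m, mu = params.scaled
    if d <= 0:
        raise ValueError("degradation rate d must be > 0")
    if b == 0.0:
        return mu / d
    q = b * m + b * mu - d * m
    return (q + math.sqrt(q * q + 4.0 * b * d * m * mu)) / (2.0 * b * d)


def closed_form_b0(n0: float, t, params: SRNAParams):
    """Exact solution of the dynamics without amplification (b = 0).

    ``n(t) = mu/d + (n0 - mu/d) * exp(-d*t)`` with speed-scaled rates.
    Serves as the analytic oracle for the numerical integrator.
    """
    if params.b != 0.0:
        raise ValueError("closed_form_b0 requires b = 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    if n0 < 0:
        raise ValueError("n0 must be >= 0")
    _, d, _, mu = params.scaled
    nhat = mu / d
    out = nhat + (n0 - nhat) * np.exp(-d * t)
    return float(out) if out.ndim == 0 else out


def _constant_b_of(b_profile: BProfile | None, params: SRNAParams) -> float | None:
    """Resolve a b profile to a constant value if possible, else None."""
    if b_profile is None:
        return params.b
    if isinstance(b_profile, (int, float)):
        return float(b_profile)
    const = getattr(b_profile, "constant_value", None)
    if const is not None:
        return float(const)
    return None


def integrate_generation(
    params: SRNAParams,
    n0: float,
    c: int = DEFAULT_CELL_DIVISIONS,
    b_profile: BProfile | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the sRNA dynamics over one generation of ``c`` divisions.

    Parameters
    ----------
    params : SRNAParams
        Rate constants; ``params.b`` is used when ``b_profile`` is None.
    n0 : float
        Zygotic sRNA amount (>= 0).
    c : int
        Number of cell divisions (>= 1). The trajectory reports n at every
        integer time 0..c, where fitness is evaluated.
    b_profile : float, callable or profile object, optional
        Amplification rate during development. A scalar means a constant
        rate; a callable ``b(t)`` supports delayed plastic responses.
        Objects with a ``constant_value`` attribute (e.g. an instant-
        plasticity profile, constant for t > 0) take the fast constant
        path.

    Notes
    -----
    Constant ``b = 0`` uses the closed form; otherwise an adaptive
    Runge-Kutta (scipy ``RK45``) with tight tolerances is used so that
    fitness products over integer times are accurate to ~1e-8 relative.
    """
    if not float(c).is_integer() or c < 1:
        raise ValueError(f"c must be an integer >= 1, got {c}")
    c = int(c)
    if n0 < 0:
        raise ValueError(f"n0 must be >= 0, got {n0}")

    times = np.arange(c + 1, dtype=float)
    const = _constant_b_of(b_profile, params)

    if const is not None:
        if const < 0:
            raise ValueError(f"amplification rate must be >= 0, got {const}")
        if const == 0.0:
            n = closed_form_b0(n0, times, params.replace(b=0.0))
            b_vals = _profile_values(b_profile, params, times, const)
            return Trajectory(times, n, b_vals)

        f = params.speed
        b, d, m, mu = const * f, params.d * f, params.m * f, params.mu * f

        def rhs(t, y):
            n = y[0]
            return ((b / (1.0 + b * n / m) - d) * n + mu,)

    else:
        f = params.speed
        d, m, mu = params.d * f, params.m * f, params.mu * f

        def rhs(t, y):
            n = y[0]
            bt = b_profile(t) * f
            return ((bt / (1.0 + bt * n / m) - d) * n + mu,)

    sol = solve_ivp(rhs, (0.0, float(c)), [float(n0)], t_eval=times,
                    method="RK45", rtol=rtol, atol=atol)
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise IntegrationError(f"sRNA integration failed: {sol.message}")
    n = np.maximum(sol.y[0], 0.0)  # clip tiny negative round-off near n=0
    b_vals = _profile_values(b_profile, params, times, const)
    return Trajectory(times, n, b_vals)


def _profile_values(b_profile, params: SRNAParams, times: np.ndarray, const) -> np.ndarray:
    """Amplification rate in effect at each reported time point."""
    if b_profile is None:
        return np.full_like(times, params.b)
    if const is not None and not callable(b_profile):
        return np.full_like(times, const)
    vals = np.array([float(b_profile(t)) for t in times])
    if np.any(vals < 0):
        raise ValueError("b_profile must be non-negative on [0, c]")
    return vals
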