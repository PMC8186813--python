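"""sRNA production strategies and lineage simulation.

Six strategies differ in how the amplification rate and the sRNA pool are
set within a generation and handed to the next:

- **A** (optimal transcription, the wildtype): transcription only, no
  amplification, plasticity or transmission.
- **B** (fixed amplification): a constant heritable amplification rate
  ``b0 > 0``.
- **C** (sRNA transmission): a fraction ``r_germ`` of the mother's adult
  sRNA pool is deposited in the zygote.
- **D** (somatic plasticity): the somatic rate moves a fraction ``P_b`` of
  the way from the inherited germline rate toward the environment-specific
  optimum; the germline rate itself is reset each generation.
- **E** (full plasticity): both soma and germline shift plastically, and
  the shifted germline rate is inherited.
- **F** (germline plasticity): the soma keeps the inherited rate; only the
  germline shifts plastically, benefiting offspring rather than self.

Plastic shifts target ``b_Wmax``, the amplification rate that maximizes
one-generation fitness for the current environment given the zygote's
inherited sRNA endowment. The developmental delay of the plastic response
is controlled by ``a`` through the factor ``1 - exp(-a*t)``; ``a = INSTANT``
(infinity) makes the shift immediate.

Between generations the zygotic sRNA amount is ``n_initial = r_germ *
n_final`` of the mother. A lineage run iterates the G-generation cycle
until the cycle-start state (n_initial, germline b) is stationary, then
scores the cross-generation geometric mean fitness over the final cycle.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import minimize_scalar

from .dynamics import (
    DEFAULT_CELL_DIVISIONS,
    SRNAParams,
    Trajectory,
    closed_form_b0,
    integrate_generation,
    steady_state_level,
)
from .environment import Scenario
from .fitness import FitnessShape, geometric_mean_fitness, lifetime_fitness

__all__ = [
    "INSTANT",
    "StrategyConfig",
    "strategy_a",
    "strategy_b",
    "strategy_c",
    "strategy_d",
    "strategy_e",
    "strategy_f",
    "custom_strategy",
    "GenerationRecord",
    "LineageState",
    "LineageResult",
    "b_wmax",
    "BwmaxTable",
    "SomaProfile",
    "soma_b_profile",
    "germline_b_update",
    "transmit_srna",
    "simulate_cycle",
    "simulate_to_stationarity",
    "StationarityError",
    "clear_caches",
]

#: Sentinel for an instantaneous plastic response (the delay constant a -> oo).
INSTANT = math.inf


class StationarityError(RuntimeError):
    """Raised when the lineage cycle map fails to reach a stationary state."""


@dataclasses.dataclass(frozen=True)
class StrategyConfig:
    """One strategy's heritable parameters and plasticity flags.

    ``b0`` is the baseline germline amplification rate inherited at the
    start of a lineage; ``a`` is the plasticity delay constant (INSTANT
    for an immediate response).
    """

    id: str
    b0: float = 0.0
    r_germ: float = 0.0
    P_b: float = 0.0
    a: float = INSTANT
    somatic_plastic: bool = False
    germline_plastic: bool = False

    def __post_init__(self) -> None:
        if self.b0 < 0:
            raise ValueError("baseline amplification b0 must be >= 0")
        if not 0.0 <= self.r_germ <= 1.0:
            raise ValueError("transmission fraction r_germ must be in [0, 1]")
        if not 0.0 <= self.P_b <= 1.0:
            raise ValueError("plasticity level P_b must be in [0, 1]")
        if self.a <= 0:
            raise ValueError("plasticity delay constant a must be > 0 (or INSTANT)")
        if self.P_b > 0 and not (self.somatic_plastic or self.germline_plastic):
            raise ValueError("P_b > 0 requires a plastic soma and/or germline")

    @property
    def is_order_free(self) -> bool:
        """True when the lineage dynamics do not depend on the environment
        sequence (no plastic tissue), so every scenario ordering gives the
        same stationary cycle."""
        return not (self.somatic_plastic or self.germline_plastic)

    def replace(self, **changes) -> "StrategyConfig":
        return dataclasses.replace(self, **changes)


def strategy_a() -> StrategyConfig:
    """Wildtype: optimal transcription only."""
    return StrategyConfig(id="A")


def strategy_b(b: float) -> StrategyConfig:
    """Fixed heritable amplification rate b > 0."""
    if b <= 0:
        raise ValueError("strategy B requires b > 0")
    return StrategyConfig(id="B", b0=b)


def strategy_c(r_germ: float) -> StrategyConfig:
    """Maternal transmission of a fraction r_germ of adult sRNA."""
    if r_germ <= 0:
        raise ValueError("strategy C requires r_germ > 0")
    return StrategyConfig(id="C", r_germ=r_germ)


def strategy_d(P_b: float, a: float = INSTANT, r_germ: float = 0.0) -> StrategyConfig:
    """Somatic plasticity only; the germline rate stays at 0."""
    return StrategyConfig(id="D", P_b=P_b, a=a, r_germ=r_germ,
                          somatic_plastic=True)


def strategy_e(P_b: float, a: float = INSTANT, b0: float = 0.0,
               r_germ: float = 0.0) -> StrategyConfig:
    """Full plasticity: soma and germline shift together and are inherited."""
    return StrategyConfig(id="E", P_b=P_b, a=a, b0=b0, r_germ=r_germ,
                          somatic_plastic=True, germline_plastic=True)


def strategy_f(P_b: float, a: float = INSTANT, b0: float = 0.0,
               r_germ: float = 0.0) -> StrategyConfig:
    """Germline-only plasticity; the soma uses the inherited rate."""
    return StrategyConfig(id="F", P_b=P_b, a=a, b0=b0, r_germ=r_germ,
                          germline_plastic=True)


def custom_strategy(**kwargs) -> StrategyConfig:
    kwargs.setdefault("id", "CUSTOM")
    return StrategyConfig(**kwargs)


# ---------------------------------------------------------------------------
# Optimal amplification rate b_Wmax


_bwmax_cache: dict[tuple, float] = {}
_table_cache: dict[tuple, "BwmaxTable"] = {}


def clear_caches() -> None:
    """Drop memoized b_Wmax optima and interpolation tables."""
    _bwmax_cache.clear()
    _table_cache.clear()


def _lifetime_at_b(b: float, eps: float, n0: float, params: SRNAParams,
                   shape: FitnessShape, c: int) -> float:
    traj = integrate_generation(params, n0, c, b_profile=b)
    # The plasticity cost C_b*P_b is constant in b and excluded here: the
    # target is the best achievable match, not the cost of aiming at it.
    return lifetime_fitness(traj, eps, 0.0, shape)


def b_wmax(eps: float, params: SRNAParams, shape: FitnessShape,
           c: int = DEFAULT_CELL_DIVISIONS, n0: float = 0.0,
           b_max: float = 2.0, xatol: float = 1e-7) -> float:
    """Amplification rate maximizing one-generation fitness at stress eps.

    The objective is the lifetime geometric mean fitness of a full
    generation in a constant environment, starting from the zygotic
    endowment ``n0`` with a constant amplification rate. The boundary
    b = 0 competes against the interior Brent optimum; results are cached
    per argument tuple.
    """
    key = (eps, params, shape, int(c), float(n0), float(b_max))
    hit = _bwmax_cache.get(key)
    if hit is not None:
        return hit
    res = minimize_scalar(
        lambda b: -math.log(_lifetime_at_b(b, eps, n0, params, shape, c)),
        bounds=(0.0, b_max), method="bounded", options={"xatol": xatol},
    )
    if not res.success:
        raise RuntimeError(f"b_Wmax optimization failed: {res.message}")
    w_interior = math.exp(-res.fun)
    w_zero = _lifetime_at_b(0.0, eps, n0, params, shape, c)
    best = 0.0 if w_zero >= w_interior else float(res.x)
    _bwmax_cache[key] = best
    return best


class BwmaxTable:
    """Interpolated ``n0 -> b_Wmax`` map for one environment.

    Plastic lineages query the optimal amplification at a continuously
    varying zygotic endowment; re-optimizing at every generation would be
    wasteful. This table runs the exact optimization at fixed ``n0`` nodes
    (including 0) and interpolates monotonically (PCHIP) in between;
    queries beyond the last node clamp to its value. Node spacing 1.0 over
    [0, n_hi] keeps the interpolation error in b well below the scale that
    moves any selection coefficient.
    """

    def __init__(self, eps: float, params: SRNAParams, shape: FitnessShape,
                 c: int = DEFAULT_CELL_DIVISIONS, n_hi: float | None = None,
                 n_nodes: int = 41, b_max: float = 2.0):
        if n_hi is None:
            n_hi = max(40.0, 0.6 * steady_state_level(params.replace(b=0.0)))
        self.eps = eps
        self.n_hi = float(n_hi)
        nodes = np.linspace(0.0, self.n_hi, n_nodes)
        vals = np.array([b_wmax(eps, params, shape, c, n0=float(x), b_max=b_max)
                         for x in nodes])
        self._nodes = nodes
        self._vals = vals
        if np.allclose(vals, vals[0]):
            self._interp = None  # constant (typically all-zero) table
        else:
            self._interp = PchipInterpolator(nodes, vals, extrapolate=False)

    def __call__(self, n0: float) -> float:
        if self._interp is None:
            return float(self._vals[0])
        x = min(max(float(n0), 0.0), self.n_hi)
        return max(float(self._interp(x)), 0.0)


def _target_fn(params: SRNAParams, shape: FitnessShape, c: int,
               b_max: float = 2.0) -> Callable[[float, float], float]:
    """(eps, n0) -> b_Wmax via per-environment cached tables."""

    def target(eps: float, n0: float) -> float:
        key = (eps, params, shape, int(c), float(b_max))
        table = _table_cache.get(key)
        if table is None:
            table = BwmaxTable(eps, params, shape, c, b_max=b_max)
            _table_cache[key] = table
        return table(n0)

    return target


# ---------------------------------------------------------------------------
# Within- and between-generation updates


class SomaProfile:
    """Somatic amplification rate b*(t) during one generation.

    Non-plastic strategies keep the inherited rate; plastic somas relax
    from the inherited rate toward ``P_b`` of the gap to the target with
    delay factor ``1 - exp(-a*t)`` (instant responses jump at t > 0).
    """

    def __init__(self, b_in: float, b_target: float, P_b: float, a: float):
        self.b_in = float(b_in)
        self.b_full = float(b_in + P_b * (b_target - b_in))
        self.P_b = float(P_b)
        self.a = float(a)
        self.plastic = P_b > 0.0 and self.b_full != self.b_in

    @property
    def constant_value(self) -> float | None:
        """The constant rate in effect for t > 0, or None if time-varying."""
        if not self.plastic:
            return self.b_in
        if math.isinf(self.a):
            return self.b_full
        return None

    def __call__(self, t: float) -> float:
        if not self.plastic:
            return self.b_in
        if math.isinf(self.a):
            return self.b_full if t > 0 else self.b_in
        frac = -math.expm1(-self.a * t)
        return self.b_in + (self.b_full - self.b_in) * frac

    def value_at_end(self, c: int) -> float:
        return self(float(c))


def soma_b_profile(b_germ_in: float, strategy: StrategyConfig, eps_now: float,
                   params: SRNAParams, shape: FitnessShape,
                   c: int = DEFAULT_CELL_DIVISIONS, n0: float = 0.0,
                   target: float | None = None) -> SomaProfile:
    """The somatic amplification profile for one generation.

    Strategies without somatic plasticity keep b*(t) = inherited rate.
    Plastic somas (D, E) move toward the environment's optimum; ``target``
    may supply a precomputed b_Wmax, otherwise it is optimized here.
    """
    if not strategy.somatic_plastic or strategy.P_b == 0.0:
        return SomaProfile(b_germ_in, b_germ_in, 0.0, strategy.a)
    if target is None:
        target = b_wmax(eps_now, params, shape, c, n0=n0)
    return SomaProfile(b_germ_in, target, strategy.P_b, strategy.a)


def germline_b_update(b_germ_in: float, strategy: StrategyConfig,
                      eps_now: float, params: SRNAParams, shape: FitnessShape,
                      c: int = DEFAULT_CELL_DIVISIONS, n0: float = 0.0,
                      target: float | None = None) -> float:
    """Germline amplification rate at the end of the generation.

    Non-plastic germlines (A-D) transmit the inherited rate unchanged.
    Plastic germlines (E, F) shift toward the current optimum by
    ``P_b * (1 - exp(-a*c))`` of the gap.
    """
    if not strategy.germline_plastic or strategy.P_b == 0.0:
        return b_germ_in
    if target is None:
        target = b_wmax(eps_now, params, shape, c, n0=n0)
    if math.isinf(strategy.a):
        frac = 1.0
    else:
        frac = -math.expm1(-strategy.a * c)
    return b_germ_in + strategy.P_b * (target - b_germ_in) * frac


def transmit_srna(n_final: float, r_germ: float) -> float:
    """Zygotic sRNA amount of the next generation, ``r_germ * n_final``."""
    if n_final < 0:
        raise ValueError("n_final must be >= 0")
    if not 0.0 <= r_germ <= 1.0:
        raise ValueError("r_germ must be in [0, 1]")
    return r_germ * n_final


# ---------------------------------------------------------------------------
# Lineage simulation


@dataclasses.dataclass(frozen=True)
class GenerationRecord:
    """State and fitness of one generation in a lineage."""

    g: int
    eps: float
    b_germ_in: float
    b_soma_final: float
    b_germ_out: float
    n_initial: float
    n_final: float
    W_LIFE: float


class LineageState(tuple):
    """Cross-generation state: (n_initial, b_germ) at a cycle boundary."""

    __slots__ = ()

    def __new__(cls, n_initial: float, b_germ: float):
        return super().__new__(cls, (float(n_initial), float(b_germ)))

    @property
    def n_initial(self) -> float:
        return self[0]

    @property
    def b_germ(self) -> float:
        return self[1]


@dataclasses.dataclass(frozen=True)
class LineageResult:
    """The stationary cycle of a lineage and its long-term fitness."""

    records: tuple[GenerationRecord, ...]
    W_GEO: float
    burn_in_cycles: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([dataclasses.asdict(r) for r in self.records])


def simulate_cycle(
    strategy: StrategyConfig,
    params: SRNAParams,
    shape: FitnessShape,
    scenario: Scenario,
    state: LineageState,
    c: int = DEFAULT_CELL_DIVISIONS,
    target: Callable[[float, float], float] | None = None,
) -> tuple[list[GenerationRecord], LineageState]:
    """Run one G-generation environmental cycle of a lineage.

    Per generation: build the somatic profile, integrate development,
    score lifetime fitness (the plasticity cost ``C_b * P_b`` is charged
    whenever the strategy is plastic), update the germline rate, transmit
    sRNA to the next zygote. Returns the records and the state carried
    into the next cycle.
    """
    if target is None and strategy.P_b > 0:
        target = _target_fn(params, shape, c)
    n0, b_germ = state
    records: list[GenerationRecord] = []
    for g, eps in enumerate(scenario.eps_seq, start=1):
        tgt = target(eps, n0) if (target is not None and strategy.P_b > 0) else None
        profile = soma_b_profile(b_germ, strategy, eps, params, shape, c,
                                 n0=n0, target=tgt)
        traj = integrate_generation(params, n0, c, b_profile=profile)
        w_life = lifetime_fitness(traj, eps, strategy.P_b, shape)
        b_out = germline_b_update(b_germ, strategy, eps, params, shape, c,
                                  n0=n0, target=tgt)
        records.append(GenerationRecord(
            g=g, eps=eps, b_germ_in=b_germ,
            b_soma_final=profile.value_at_end(c), b_germ_out=b_out,
            n_initial=n0, n_final=traj.n_final, W_LIFE=w_life,
        ))
        n0 = transmit_srna(traj.n_final, strategy.r_germ)
        b_germ = b_out
    return records, LineageState(n0, b_germ)


def _states_close(a: LineageState, b: LineageState, tol: float) -> bool:
    return all(abs(x - y) <= tol * (1.0 + abs(y)) for x, y in zip(a, b))


def _stationary_order_free(
    strategy: StrategyConfig, params: SRNAParams, shape: FitnessShape,
    scenario: Scenario, c: int, tol: float, max_cycles: int,
) -> LineageResult:
    """Exact shortcut for strategies whose dynamics ignore the environment.

    The one-generation map n -> r_germ * n_final(n) with the constant
    inherited amplification rate has the same fixed point as the full
    cycle map; the stationary trajectory is computed once and shared by
    all G generations (only the fitness differs with eps).
    """
    b = strategy.b0
    pars = params.replace(b=b)
    n0 = 0.0
    iterations = 0
    max_iter = max_cycles * scenario.G
    while True:
        traj = integrate_generation(pars, n0, c)
        n_next = transmit_srna(traj.n_final, strategy.r_germ)
        iterations += 1
        if abs(n_next - n0) <= tol * (1.0 + abs(n_next)):
            n0 = n_next
            break
        if iterations >= max_iter:
            raise StationarityError(
                f"lineage map not stationary after {iterations} generations; "
                f"residual {abs(n_next - n0):.3e}"
            )
        n0 = n_next
    traj = integrate_generation(pars, n0, c)
    w_by_eps = {eps: lifetime_fitness(traj, eps, strategy.P_b, shape)
                for eps in set(scenario.eps_seq)}
    records = [
        GenerationRecord(
            g=g, eps=eps, b_germ_in=b, b_soma_final=b, b_germ_out=b,
            n_initial=n0, n_final=traj.n_final, W_LIFE=w_by_eps[eps],
        )
        for g, eps in enumerate(scenario.eps_seq, start=1)
    ]
    w_geo = geometric_mean_fitness([r.W_LIFE for r in records])
    burn_in = -(-iterations // scenario.G)  # ceil
    return LineageResult(tuple(records), w_geo, burn_in)


def simulate_to_stationarity(
    strategy: StrategyConfig,
    params: SRNAParams,
    shape: FitnessShape,
    scenario: Scenario,
    c: int = DEFAULT_CELL_DIVISIONS,
    tol: float = 1e-9,
    max_cycles: int = 200,
    use_fast_path: bool = True,
) -> LineageResult:
    """Iterate the cycle map to its stationary state and score W_GEO.

    Starts from a near-empty zygote (n_initial = 0) carrying the
    strategy's baseline germline rate, and repeats the G-generation cycle
    until the cycle-start state changes by less than ``tol`` (relative)
    in both components. Order-free strategies take an exact one-generation
    shortcut (see the module notes); set ``use_fast_path=False`` to force
    the generic path.
    """
    if use_fast_path and strategy.is_order_free:
        return _stationary_order_free(strategy, params, shape, scenario, c,
                                      tol, max_cycles)
    target = _target_fn(params, shape, c) if strategy.P_b > 0 else None
    state = LineageState(0.0, strategy.b0)
    for cycle in range(1, max_cycles + 1):
        records, state_out = simulate_cycle(strategy, params, shape, scenario,
                                            state, c, target=target)
        if _states_close(state_out, state, tol):
            w_geo = geometric_mean_fitness([r.W_LIFE for r in records])
            return LineageResult(tuple(records), w_geo, cycle)
        state = state_out
    raise StationarityError(
        f"cycle map not stationary after {max_cycles} cycles; last state "
        f"{tuple(state)} -> {tuple(state_out)}"
    )
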