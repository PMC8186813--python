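"""Invasion analysis of mutant sRNA strategies against the wildtype.

The resident is the wildtype (strategy A) whose transcription rate has
evolved to maximize its long-term geometric mean fitness in the given
environmental composition. A rare mutant strategy spreads when its
cross-generation geometric mean fitness exceeds the resident's; selection
is summarized by ``s+ = W_GEO(mutant)/W_GEO(resident) - 1``.

This module provides the transcription-rate optimization, single
invasions, parameter sweeps over scenario ensembles, coarse-grid +
local-refinement optimization of mutant parameters, and pre-configured
experiment runners for the standard analyses (amplification vs
transmission curves, plasticity sweeps, cost and speed sensitivity,
two-parameter fitness surfaces).
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import math
import time
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

from .dynamics import DEFAULT_CELL_DIVISIONS, SRNAParams, closed_form_b0, integrate_generation
from .environment import (
    EPS_BENIGN,
    EPS_STRESS,
    Scenario,
    generate_scenario,
    scenario_ensemble,
    switches_for_similarity,
)
from .fitness import (
    FitnessShape,
    WEAK_SELECTION_THRESHOLD,
    geometric_mean_fitness,
    is_weak_selection,
    lifetime_fitness,
    selection_coefficient,
)
from .strategies import (
    INSTANT,
    LineageResult,
    StrategyConfig,
    simulate_to_stationarity,
    strategy_a,
    strategy_b,
    strategy_c,
    strategy_d,
    strategy_e,
    strategy_f,
)

__all__ = [
    "InvasionResult",
    "SweepTable",
    "TranscriptionOptimum",
    "MutantOptimum",
    "optimize_transcription",
    "optimal_mu_constant_env",
    "adult_level_b0",
    "invade",
    "sweep",
    "optimize_mutant",
    "run_experiment",
    "EXPERIMENTS",
]


# ---------------------------------------------------------------------------
# Wildtype transcription optimum


@dataclasses.dataclass(frozen=True)
class TranscriptionOptimum:
    mu: float
    w_geo: float


def _wlife_b0_log(mu: float, eps: float, params: SRNAParams,
                  shape: FitnessShape, c: int) -> float:
    """log W_LIFE of a transcription-only generation, via the closed form."""
    pars = params.replace(b=0.0, mu=mu)
    times = np.arange(c + 1, dtype=float)
    n = closed_form_b0(0.0, times, pars)
    from .fitness import instantaneous_fitness

    return float(np.mean(np.log(instantaneous_fitness(n, eps, 0.0, shape))))


def optimize_transcription(
    params: SRNAParams | None = None,
    shape: FitnessShape | None = None,
    c: int = DEFAULT_CELL_DIVISIONS,
    eps_levels: Sequence[float] = (EPS_BENIGN, EPS_STRESS),
    weights: Sequence[float] | None = None,
    bounds: tuple[float, float] = (1e-6, 50.0),
    xatol: float = 1e-6,
) -> TranscriptionOptimum:
    """Transcription rate maximizing the wildtype's W_GEO.

    The wildtype has no amplification, plasticity or transmission, so its
    generations are identical and W_GEO reduces to the composition-
    weighted geometric mean of the per-environment lifetime fitnesses,
    independent of environment order. Defaults reproduce an equal split
    between benign and stressful generations.
    """
    params = params or SRNAParams()
    shape = shape or FitnessShape()
    if weights is None:
        weights = [1.0 / len(eps_levels)] * len(eps_levels)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()

    def neg_log_wgeo(mu: float) -> float:
        return -sum(wi * _wlife_b0_log(mu, eps, params, shape, c)
                    for wi, eps in zip(w, eps_levels))

    res = minimize_scalar(neg_log_wgeo, bounds=bounds, method="bounded",
                          options={"xatol": xatol})
    if not res.success:
        raise RuntimeError(f"transcription optimization failed: {res.message}")
    return TranscriptionOptimum(mu=float(res.x), w_geo=math.exp(-res.fun))


def optimal_mu_constant_env(
    eps: float,
    params: SRNAParams | None = None,
    shape: FitnessShape | None = None,
    c: int = DEFAULT_CELL_DIVISIONS,
    bounds: tuple[float, float] = (1e-6, 50.0),
) -> TranscriptionOptimum:
    """Transcription rate maximizing one-generation fitness at constant eps."""
    return optimize_transcription(params, shape, c, eps_levels=(eps,),
                                  weights=(1.0,), bounds=bounds)


def adult_level_b0(mu: float, params: SRNAParams | None = None,
                   c: int = DEFAULT_CELL_DIVISIONS) -> float:
    """Adult sRNA amount n(c) of a transcription-only zygote-empty life."""
    params = (params or SRNAParams()).replace(b=0.0, mu=mu)
    return float(closed_form_b0(0.0, float(c), params))


# ---------------------------------------------------------------------------
# Invasion


@dataclasses.dataclass(frozen=True)
class InvasionResult:
    """Outcome of one mutant-vs-resident comparison on one scenario."""

    s_plus: float
    w_geo_mut: float
    w_geo_res: float
    weak: bool
    scenario_id: str

    def __post_init__(self) -> None:
        expected = self.w_geo_mut / self.w_geo_res - 1.0
        if not math.isclose(self.s_plus, expected, rel_tol=0, abs_tol=1e-15):
            raise ValueError("s_plus must equal w_geo_mut/w_geo_res - 1")


def _scenario_id(scenario: Scenario) -> str:
    return f"G{scenario.G}k{scenario.k}s{scenario.seed}"


class _ResidentCache:
    """W_GEO of a fixed resident per scenario, computed once and reused."""

    def __init__(self, resident: StrategyConfig, params: SRNAParams,
                 shape: FitnessShape, c: int):
        self.resident = resident
        self.params = params
        self.shape = shape
        self.c = c
        self._store: dict[tuple, float] = {}

    def w_geo(self, scenario: Scenario) -> float:
        key = scenario.eps_seq
        if key not in self._store:
            res = simulate_to_stationarity(self.resident, self.params,
                                           self.shape, scenario, self.c)
            self._store[key] = res.W_GEO
        return self._store[key]


def invade(
    resident: StrategyConfig,
    mutant: StrategyConfig,
    params: SRNAParams,
    shape: FitnessShape,
    scenario: Scenario,
    c: int = DEFAULT_CELL_DIVISIONS,
    _resident_cache: _ResidentCache | None = None,
) -> InvasionResult:
    """Selection coefficient of a rare mutant in a resident population.

    Both lineages are run to their stationary cycle on the same scenario;
    they share the within-generation rate constants and differ only in
    strategy parameters.
    """
    if _resident_cache is not None:
        w_res = _resident_cache.w_geo(scenario)
    else:
        w_res = simulate_to_stationarity(resident, params, shape, scenario, c).W_GEO
    w_mut = simulate_to_stationarity(mutant, params, shape, scenario, c).W_GEO
    s = selection_coefficient(w_mut, w_res)
    return InvasionResult(s_plus=s, w_geo_mut=w_mut, w_geo_res=w_res,
                          weak=is_weak_selection(s),
                          scenario_id=_scenario_id(scenario))


# ---------------------------------------------------------------------------
# Sweeps and mutant optimization


@dataclasses.dataclass(frozen=True)
class SweepTable:
    """Factorial selection-coefficient evaluation over scenario realizations.

    ``points`` has one row per (grid point, scenario realization);
    ``mean`` averages s+ arithmetically across realizations per point.
    """

    axes: tuple[str, ...]
    points: pd.DataFrame
    mean: pd.DataFrame


def sweep(
    make_mutant: Callable[..., StrategyConfig],
    grids: Mapping[str, Sequence[float]],
    params: SRNAParams,
    shape: FitnessShape,
    scenarios: Sequence[Scenario],
    c: int = DEFAULT_CELL_DIVISIONS,
    resident: StrategyConfig | None = None,
) -> SweepTable:
    """Evaluate s+ on a full factorial grid of mutant parameters.

    ``make_mutant`` receives one keyword per grid axis and returns the
    mutant strategy. The resident's fitness is computed once per scenario
    and reused bit-identically across the grid.
    """
    if not grids:
        raise ValueError("need at least one sweep axis")
    if not scenarios:
        raise ValueError("need at least one scenario")
    resident = resident or strategy_a()
    cache = _ResidentCache(resident, params, shape, c)
    axes = tuple(grids.keys())
    rows = []
    for values in itertools.product(*(grids[a] for a in axes)):
        coords = dict(zip(axes, values))
        mutant = make_mutant(**coords)
        for scen in scenarios:
            res = invade(resident, mutant, params, shape, scen, c,
                         _resident_cache=cache)
            rows.append({**coords, "scenario_id": res.scenario_id,
                         "s_plus": res.s_plus, "w_geo_mut": res.w_geo_mut,
                         "w_geo_res": res.w_geo_res, "weak": res.weak})
    points = pd.DataFrame(rows)
    mean = (points.groupby(list(axes), as_index=False)["s_plus"].mean()
            .rename(columns={"s_plus": "s_plus_mean"}))
    return SweepTable(axes=axes, points=points, mean=mean)


@dataclasses.dataclass(frozen=True)
class MutantOptimum:
    """Argmax of the mean selection coefficient over mutant parameters."""

    point: dict[str, float]
    s_plus: float
    grid_point: dict[str, float]
    grid_s_plus: float
    all_weak: bool


def optimize_mutant(
    make_mutant: Callable[..., StrategyConfig],
    grids: Mapping[str, Sequence[float]],
    params: SRNAParams,
    shape: FitnessShape,
    scenarios: Sequence[Scenario],
    c: int = DEFAULT_CELL_DIVISIONS,
    refine: bool = True,
    resident: StrategyConfig | None = None,
    table: SweepTable | None = None,
) -> MutantOptimum:
    """Coarse-grid scan of mean s+ followed by local Nelder-Mead refinement.

    A surface on which every point is within the weak-selection band is
    reported as flat (``all_weak=True``), not an error. A precomputed
    ``table`` for the same grids and scenarios skips the scan.
    """
    if table is None:
        table = sweep(make_mutant, grids, params, shape, scenarios, c,
                      resident=resident)
    axes = list(table.axes)
    best_row = table.mean.loc[table.mean["s_plus_mean"].idxmax()]
    grid_point = {a: float(best_row[a]) for a in axes}
    grid_s = float(best_row["s_plus_mean"])
    all_weak = bool((table.mean["s_plus_mean"].abs()
                     <= WEAK_SELECTION_THRESHOLD).all())
    point, s_best = dict(grid_point), grid_s
    if refine:
        resident = resident or strategy_a()
        cache = _ResidentCache(resident, params, shape, c)
        lo = np.array([min(grids[a]) for a in axes], dtype=float)
        hi = np.array([max(grids[a]) for a in axes], dtype=float)
        span = np.where(hi > lo, hi - lo, 1.0)

        def neg_mean_s(x: np.ndarray) -> float:
            x = np.clip(x, lo, hi)
            mutant = make_mutant(**dict(zip(axes, map(float, x))))
            vals = [invade(resident, mutant, params, shape, scen, c,
                           _resident_cache=cache).s_plus for scen in scenarios]
            return -float(np.mean(vals))

        x0 = np.array([grid_point[a] for a in axes])
        res = minimize(neg_mean_s, x0, method="Nelder-Mead",
                       options={"xatol": 1e-4 * float(span.min()),
                                "fatol": 1e-10, "maxiter": 200})
        if -res.fun >= s_best:
            point = {a: float(v) for a, v in
                     zip(axes, np.clip(res.x, lo, hi))}
            s_best = float(-res.fun)
    return MutantOptimum(point=point, s_plus=s_best, grid_point=grid_point,
                         grid_s_plus=grid_s, all_weak=all_weak)


# ---------------------------------------------------------------------------
# Experiment runners


def _b_grid() -> np.ndarray:
    return np.geomspace(1e-3, 2.0, 40)


def _r_grid(step: float = 0.01, hi: float = 0.3) -> np.ndarray:
    return np.round(np.arange(0.0, hi + step / 2, step), 10)


def _pb_grid(lo: float = 0.1) -> np.ndarray:
    return np.round(np.arange(lo, 1.0 + 0.05, 0.1), 10)


def _mutant_bc(r_germ: float = 0.0, b: float = 0.0) -> StrategyConfig:
    """Non-plastic mutant coupling fixed amplification and transmission."""
    return StrategyConfig(id="B+C", b0=b, r_germ=r_germ)


def _mutant_plastic_transmitting(kind: str):
    factory = {"D": strategy_d, "E": strategy_e, "F": strategy_f}[kind]

    def make(r_germ: float = 0.0, P_b: float = 0.0) -> StrategyConfig:
        if P_b == 0.0:
            return StrategyConfig(id=f"{kind}+C", r_germ=r_germ)
        return factory(P_b=P_b, a=INSTANT, r_germ=r_germ)

    return make


def _exp_amplification_transmission(params, shape, c, seed, overrides):
    """s+ curves for fixed amplification (B) and transmission (C) mutants
    at default, slowed (x0.75) and sped-up (x2.0) dynamics."""
    speeds = overrides.get("speeds", (1.0, 0.75, 2.0))
    scen = generate_scenario(G=20, k=9, seed=seed)
    rows = []
    for f in speeds:
        pars = params.replace(speed=f)
        for b in overrides.get("b_grid", _b_grid()):
            t = sweep(lambda b=b: strategy_b(b), {"b": [b]}, pars, shape,
                      [scen], c)
            rows.append({"speed": f, "strategy": "B", "param": "b",
                         "value": b, "s_plus": t.points["s_plus"].iloc[0]})
        for r in overrides.get("r_grid", _r_grid()):
            if r == 0.0:
                continue
            t = sweep(lambda r_germ=r: strategy_c(r_germ),
                      {"r_germ": [r]}, pars, shape, [scen], c)
            rows.append({"speed": f, "strategy": "C", "param": "r_germ",
                         "value": r, "s_plus": t.points["s_plus"].iloc[0]})
    return {"curves": pd.DataFrame(rows)}


def _exp_instant_plasticity(params, shape, c, seed, overrides):
    """s+ vs P_b for instantly plastic strategies D, E, F across
    environmental-similarity levels, with scenario ensembles."""
    ks = overrides.get("k_values", (17, 9, 2))
    n_real = overrides.get("n_realizations", 10)
    pb_grid = overrides.get("pb_grid", _pb_grid())
    a = overrides.get("a", INSTANT)
    factories = {"D": strategy_d, "E": strategy_e, "F": strategy_f}
    which = overrides.get("strategies", ("D", "E", "F"))
    frames = []
    for k in ks:
        scens = scenario_ensemble(20, k, n_real, seed=seed + k)
        for name in which:
            fac = factories[name]
            t = sweep(lambda P_b, fac=fac: fac(P_b=P_b, a=a),
                      {"P_b": pb_grid}, params, shape, scens, c)
            pts = t.points.assign(strategy=name, k=k)
            frames.append(pts)
    points = pd.concat(frames, ignore_index=True)
    mean = (points.groupby(["strategy", "k", "P_b"], as_index=False)
            ["s_plus"].mean().rename(columns={"s_plus": "s_plus_mean"}))
    return {"points": points, "mean": mean}


def _exp_delayed_somatic(params, shape, c, seed, overrides):
    """Gradual (delayed) somatic plasticity: strategy D with a = 0.15."""
    o = dict(overrides)
    o.setdefault("a", 0.15)
    o.setdefault("strategies", ("D",))
    return _exp_instant_plasticity(params, shape, c, seed, o)


def _exp_delayed_inheritance(params, shape, c, seed, overrides):
    """Gradual plasticity with inheritance: strategies D, E, F at a = 0.15."""
    o = dict(overrides)
    o.setdefault("a", 0.15)
    return _exp_instant_plasticity(params, shape, c, seed, o)


def _exp_costly_plasticity(params, shape, c, seed, overrides):
    """Instant plasticity when the plasticity cost is 500x the sRNA cost."""
    shape = shape.replace(C_b=overrides.get("C_b", 500.0 * shape.C_n))
    return _exp_instant_plasticity(params, shape, c, seed, overrides)


def _exp_slow_dynamics(params, shape, c, seed, overrides):
    """Instant plasticity with all within-generation rates slowed to 0.75x."""
    params = params.replace(speed=overrides.get("speed", 0.75))
    return _exp_instant_plasticity(params, shape, c, seed, overrides)


def _exp_transcription_surface(params, shape, c, seed, overrides):
    """Wildtype W_GEO over a (mu, d) grid, marking the ridge."""
    mus = overrides.get("mu_grid", np.linspace(0.5, 20.0, 40))
    ds = overrides.get("d_grid", np.linspace(0.02, 0.4, 39))
    rows = []
    for d in ds:
        pars = params.replace(d=float(d))
        for mu in mus:
            lw = 0.5 * (_wlife_b0_log(mu, EPS_BENIGN, pars, shape, c)
                        + _wlife_b0_log(mu, EPS_STRESS, pars, shape, c))
            rows.append({"mu": float(mu), "d": float(d),
                         "w_geo": math.exp(lw)})
    return {"surface": pd.DataFrame(rows)}


def _exp_amp_trans_surface(params, shape, c, seed, overrides):
    """Joint (r_germ, b) fitness surface of the non-plastic B+C mutant."""
    r_grid = overrides.get("r_grid", _r_grid())
    b_grid = overrides.get("b_grid",
                           np.round(np.arange(0.0, 0.1 + 5e-4, 0.001), 10))
    scen = generate_scenario(G=20, k=9, seed=seed)
    table = sweep(_mutant_bc, {"r_germ": r_grid, "b": b_grid}, params, shape,
                  [scen], c)
    opt = optimize_mutant(_mutant_bc, {"r_germ": r_grid, "b": b_grid},
                          params, shape, [scen], c,
                          refine=overrides.get("refine", True), table=table)
    best = pd.DataFrame([{**opt.point, "s_plus": opt.s_plus,
                          **{f"grid_{k}": v for k, v in opt.grid_point.items()},
                          "grid_s_plus": opt.grid_s_plus}])
    return {"surface": table.points, "optimum": best}


def _exp_plasticity_transmission_surface(params, shape, c, seed, overrides):
    """(r_germ, P_b) fitness surfaces for instantly plastic, transmitting
    mutants under low and high environmental similarity."""
    ks = overrides.get("k_values", (17, 2))
    kinds = overrides.get("strategies", ("D",))
    r_grid = overrides.get("r_grid", _r_grid())
    pb_grid = overrides.get("pb_grid",
                            np.round(np.arange(0.0, 1.0 + 0.05, 0.1), 10))
    frames, optima = [], []
    for k in ks:
        scen = generate_scenario(G=20, k=k, seed=seed + k)
        for kind in kinds:
            make = _mutant_plastic_transmitting(kind)
            t = sweep(make, {"r_germ": r_grid, "P_b": pb_grid}, params,
                      shape, [scen], c)
            frames.append(t.points.assign(strategy=kind, k=k))
            best = t.mean.loc[t.mean["s_plus_mean"].idxmax()]
            optima.append({"strategy": kind, "k": k,
                           "r_germ": float(best["r_germ"]),
                           "P_b": float(best["P_b"]),
                           "s_plus": float(best["s_plus_mean"])})
    return {"surface": pd.concat(frames, ignore_index=True),
            "optimum": pd.DataFrame(optima)}


EXPERIMENTS: dict[str, Callable] = {
    "amplification-transmission": _exp_amplification_transmission,
    "instant-plasticity": _exp_instant_plasticity,
    "delayed-somatic-plasticity": _exp_delayed_somatic,
    "delayed-plasticity-inheritance": _exp_delayed_inheritance,
    "transcription-optimum-surface": _exp_transcription_surface,
    "amplification-transmission-surface": _exp_amp_trans_surface,
    "costly-plasticity": _exp_costly_plasticity,
    "slow-dynamics": _exp_slow_dynamics,
    "plasticity-transmission-surface": _exp_plasticity_transmission_surface,
}


def run_experiment(
    name: str,
    overrides: Mapping | None = None,
    params: SRNAParams | None = None,
    shape: FitnessShape | None = None,
    c: int = DEFAULT_CELL_DIVISIONS,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> dict:
    """Run a named pre-configured analysis and optionally write its tables.

    Returns ``{"tables": {name: DataFrame}, "manifest": {...}}``. With
    ``outdir`` set, tables are written as TSV plus a JSON manifest via
    :func:`srnaevol.io.write_results`.
    """
    if name not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {name!r}; "
                         f"known: {sorted(EXPERIMENTS)}")
    params = params or SRNAParams()
    shape = shape or FitnessShape()
    overrides = dict(overrides or {})
    t0 = time.perf_counter()
    tables = EXPERIMENTS[name](params, shape, c, seed, overrides)
    manifest = {
        "experiment": name,
        "seed": seed,
        "c": c,
        "params": dataclasses.asdict(params),
        "shape": dataclasses.asdict(shape),
        "overrides": {k: (list(v) if isinstance(v, (np.ndarray, tuple)) else v)
                      for k, v in overrides.items()},
        "runtime_s": round(time.perf_counter() - t0, 3),
    }
    if outdir is not None:
        from .io import write_results

        write_results(tables, manifest, outdir)
    return {"tables": tables, "manifest": manifest}
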