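"""Configuration files, result tables and manifests.

Run configuration is a YAML document with four optional blocks
(``dynamics``, ``fitness``, ``strategy``, ``scenario``) plus experiment
settings. Missing fields fall back to the model defaults (d = 0.1,
m = 5.0, mu = 6.798, c = 20, alpha = 15, beta = 0.1, h = 5, C_n = 1e-5,
C_b = 50*C_n, G = 20); unknown keys are rejected with field paths.
Configs round-trip losslessly through :func:`serialize_config`.

Result tables are TSV (UTF-8, '.' decimal separator, 12 significant
digits) with a JSON manifest recording parameters and seeds, so reruns
of identical results are byte-identical.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Literal, Mapping, Union

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .dynamics import DEFAULT_CELL_DIVISIONS, SRNAParams
from .environment import Scenario, generate_scenario, scenario_ensemble, switches_for_similarity
from .fitness import FitnessShape
from .strategies import (
    INSTANT,
    StrategyConfig,
    custom_strategy,
    strategy_a,
    strategy_b,
    strategy_c,
    strategy_d,
    strategy_e,
    strategy_f,
)

__all__ = ["RunConfig", "load_config", "serialize_config", "write_results"]


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DynamicsBlock(_Block):
    b: float = 0.0
    d: float = 0.1
    m: float = 5.0
    mu: float = 6.798
    speed: float = 1.0
    c: int = DEFAULT_CELL_DIVISIONS


class FitnessBlock(_Block):
    alpha: float = 15.0
    beta: float = 0.1
    h: float = 5.0
    C_n: float = 1e-5
    C_b: float = 50e-5


class StrategyBlock(_Block):
    id: Literal["A", "B", "C", "D", "E", "F", "CUSTOM"] = "A"
    b0: float = 0.0
    r_germ: float = 0.0
    P_b: float = 0.0
    a: Union[float, Literal["instant"]] = "instant"
    somatic_plastic: bool = False
    germline_plastic: bool = False

    @field_validator("a")
    @classmethod
    def _positive_delay(cls, v):
        if isinstance(v, float) and not (v > 0 or math.isinf(v)):
            raise ValueError("plasticity delay a must be > 0 or 'instant'")
        return v


class ScenarioBlock(_Block):
    G: int = 20
    k: int | None = None
    p_eps: float | None = None
    seed: int = 0
    n_realizations: int = 1


class RunConfig(_Block):
    dynamics: DynamicsBlock = Field(default_factory=DynamicsBlock)
    fitness: FitnessBlock = Field(default_factory=FitnessBlock)
    strategy: StrategyBlock = Field(default_factory=StrategyBlock)
    scenario: ScenarioBlock = Field(default_factory=ScenarioBlock)
    experiment: str | None = None
    overrides: dict = Field(default_factory=dict)
    outdir: str | None = None

    # -- conversion to model objects ------------------------------------

    def srna_params(self) -> SRNAParams:
        d = self.dynamics
        return SRNAParams(b=d.b, d=d.d, m=d.m, mu=d.mu, speed=d.speed)

    def fitness_shape(self) -> FitnessShape:
        f = self.fitness
        return FitnessShape(alpha=f.alpha, beta=f.beta, h=f.h,
                            C_n=f.C_n, C_b=f.C_b)

    def strategy_config(self) -> StrategyConfig:
        s = self.strategy
        a = INSTANT if s.a == "instant" else float(s.a)
        factories = {
            "A": lambda: strategy_a(),
            "B": lambda: strategy_b(s.b0),
            "C": lambda: strategy_c(s.r_germ),
            "D": lambda: strategy_d(s.P_b, a=a, r_germ=s.r_germ),
            "E": lambda: strategy_e(s.P_b, a=a, b0=s.b0, r_germ=s.r_germ),
            "F": lambda: strategy_f(s.P_b, a=a, b0=s.b0, r_germ=s.r_germ),
        }
        if s.id in factories:
            cfg = factories[s.id]()
            # non-default fields that conflict with the chosen strategy
            mismatches = []
            if s.b0 != cfg.b0:
                mismatches.append(f"b0={s.b0}")
            if s.r_germ != cfg.r_germ:
                mismatches.append(f"r_germ={s.r_germ}")
            if s.P_b != cfg.P_b:
                mismatches.append(f"P_b={s.P_b}")
            if mismatches:
                raise ValueError(
                    f"strategy {s.id} does not admit {', '.join(mismatches)}"
                )
            return cfg
        return custom_strategy(b0=s.b0, r_germ=s.r_germ, P_b=s.P_b, a=a,
                               somatic_plastic=s.somatic_plastic,
                               germline_plastic=s.germline_plastic)

    def scenarios(self) -> list[Scenario]:
        sc = self.scenario
        k = sc.k
        if k is None:
            if sc.p_eps is None:
                k = 9
            else:
                k = switches_for_similarity(sc.p_eps, sc.G)
        if sc.n_realizations == 1:
            return [generate_scenario(G=sc.G, k=k, seed=sc.seed)]
        return scenario_ensemble(sc.G, k, sc.n_realizations, seed=sc.seed)


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    An empty file yields the full defaults; schema violations surface
    pydantic errors with field paths.
    """
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return RunConfig.model_validate(data)


def serialize_config(config: RunConfig) -> str:
    """Canonical YAML form; parse(serialize(x)) == x."""
    return yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True)


def write_results(tables: Mapping[str, pd.DataFrame], manifest: Mapping,
                  outdir) -> list[Path]:
    """Write result tables as TSV plus a JSON manifest.

    Fixed column order, UTF-8, 12 significant digits; rewriting identical
    results produces byte-identical files.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, frame in tables.items():
        path = out / f"{name}.tsv"
        frame.to_csv(path, sep="\t", index=False, float_format="%.12g",
                     encoding="utf-8", lineterminator="\n")
        written.append(path)
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(_jsonable(manifest), indent=2, sort_keys=True)
                     + "\n", encoding="utf-8")
    written.append(mpath)
    return written


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    if isinstance(obj, float) and math.isinf(obj):
        return "inf"
    return obj
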