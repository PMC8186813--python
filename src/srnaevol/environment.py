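"""Cyclic environmental scenarios with controlled autocorrelation.

A scenario is a repeating cycle of ``G`` generations (default 20), each
either benign (eps = 0.1) or stressful (eps = 0.9), with both states
occupying exactly half of the cycle so the mean stress is held at 0.5.
Temporal structure is controlled by the number of adjacent switches ``k``
within the cycle; the parent-offspring environmental similarity is::

    p_eps = 1 - k / (G - 1)

High ``p_eps`` means long runs of the same environment (positively
autocorrelated); ``p_eps = 0`` means switching every generation. Only the
``G - 1`` within-cycle adjacent pairs enter ``k`` (the wrap-around pair
between repeats does not, keeping the printed denominator ``G - 1``
consistent), although the wrap-around does affect lineage dynamics.

Generation is uniform over all balanced length-``G`` sequences with
exactly ``k`` switches: ``k`` switches partition the cycle into ``k + 1``
alternating runs, and run-length compositions are sampled uniformly via
stars-and-bars, weighting the two possible starting states by their
sequence counts.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

__all__ = [
    "EPS_BENIGN",
    "EPS_STRESS",
    "Scenario",
    "similarity",
    "switches_for_similarity",
    "count_switches",
    "generate_scenario",
    "scenario_ensemble",
    "write_scenario_csv",
    "read_scenario_csv",
]

EPS_BENIGN = 0.1
EPS_STRESS = 0.9


def similarity(k: int, G: int) -> float:
    """Parent-offspring environmental similarity, ``1 - k/(G-1)``."""
    if G < 2:
        raise ValueError(f"cycle length G must be >= 2, got {G}")
    if not 0 <= k <= G - 1:
        raise ValueError(f"switch count k must be in [0, {G - 1}], got {k}")
    return 1.0 - k / (G - 1)


def switches_for_similarity(p_eps: float, G: int = 20) -> int:
    """Nearest switch count realizing a requested similarity.

    At G = 20, p_eps of 0.11, 0.53 and 0.89 map to k = 17, 9 and 2.
    """
    if not 0.0 <= p_eps <= 1.0:
        raise ValueError(f"p_eps must be in [0, 1], got {p_eps}")
    return int(round((1.0 - p_eps) * (G - 1)))


def count_switches(eps_seq: Sequence[float]) -> int:
    """Number of adjacent within-cycle environment changes."""
    arr = np.asarray(eps_seq, dtype=float)
    return int(np.sum(arr[1:] != arr[:-1]))


@dataclasses.dataclass(frozen=True)
class Scenario:
    """A balanced cyclic environment sequence with a fixed switch count."""

    eps_seq: tuple[float, ...]
    seed: int | None = None

    def __post_init__(self) -> None:
        seq = tuple(float(e) for e in self.eps_seq)
        object.__setattr__(self, "eps_seq", seq)
        if len(seq) < 2 or len(seq) % 2:
            raise ValueError("scenario length G must be even and >= 2")
        levels = sorted(set(seq))
        if len(levels) != 2:
            raise ValueError("scenario must contain exactly two environment levels")
        lo, hi = levels
        if seq.count(lo) != seq.count(hi):
            raise ValueError("scenario must contain each environment level G/2 times")

    @property
    def G(self) -> int:
        return len(self.eps_seq)

    @property
    def k(self) -> int:
        return count_switches(self.eps_seq)

    @property
    def p_eps(self) -> float:
        return similarity(self.k, self.G)

    @property
    def levels(self) -> tuple[float, float]:
        lo, hi = sorted(set(self.eps_seq))
        return lo, hi


def _random_composition(total: int, parts: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform composition of `total` into `parts` positive integers."""
    if parts == 1:
        return np.array([total])
    cuts = np.sort(rng.choice(total - 1, size=parts - 1, replace=False)) + 1
    edges = np.concatenate(([0], cuts, [total]))
    return np.diff(edges)


def generate_scenario(
    G: int = 20,
    k: int | None = None,
    seed: int | None = None,
    p_eps: float | None = None,
    levels: tuple[float, float] = (EPS_BENIGN, EPS_STRESS),
    rng: np.random.Generator | None = None,
) -> Scenario:
    """Sample a balanced length-G scenario with exactly k switches.

    Exactly one of ``k`` or ``p_eps`` must be given; ``p_eps`` is mapped
    to the nearest feasible integer switch count. Sampling is uniform over
    the constrained set and deterministic for a fixed seed.
    """
    if (k is None) == (p_eps is None):
        raise ValueError("specify exactly one of k or p_eps")
    if p_eps is not None:
        k = switches_for_similarity(p_eps, G)
    if G < 2 or G % 2:
        raise ValueError(f"cycle length G must be even and >= 2, got {G}")
    half = G // 2
    if not 1 <= k <= G - 1:
        raise ValueError(
            f"switch count k={k} infeasible: a balanced two-level sequence "
            f"of length {G} requires 1 <= k <= {G - 1}"
        )
    n_runs = k + 1
    r_start = (n_runs + 1) // 2  # runs of the starting level
    r_other = n_runs // 2
    if r_start > half:
        raise ValueError(
            f"switch count k={k} infeasible at G={G}: {r_start} runs of the "
            f"starting level cannot fit into {half} generations"
        )
    if rng is None:
        rng = np.random.default_rng(seed)

    # The run counts (r_start, r_other) do not depend on WHICH level starts,
    # so the two starting levels head equally many sequences: fair coin.
    start_first = rng.random() < 0.5
    lo, hi = sorted(levels)
    start_level, other_level = (lo, hi) if start_first else (hi, lo)

    runs_start = _random_composition(half, r_start, rng)
    runs_other = _random_composition(half, r_other, rng)

    seq: list[float] = []
    for i in range(n_runs):
        if i % 2 == 0:
            seq.extend([start_level] * int(runs_start[i // 2]))
        else:
            seq.extend([other_level] * int(runs_other[i // 2]))
    scen = Scenario(tuple(seq), seed=seed)
    assert scen.k == k, "internal error: switch count mismatch"
    return scen


def scenario_ensemble(
    G: int,
    k: int,
    n_realizations: int,
    seed: int | None = None,
    levels: tuple[float, float] = (EPS_BENIGN, EPS_STRESS),
) -> list[Scenario]:
    """Independent scenario realizations from one master seed.

    Child seeds are spawned from ``numpy.random.SeedSequence`` so the
    ensemble is reproducible as a whole and each member individually.
    """
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_realizations)
    out = []
    for child in children:
        sub = int(child.generate_state(1)[0] % (2**31))
        out.append(generate_scenario(G=G, k=k, seed=sub, levels=levels))
    return out


def write_scenario_csv(scenario: Scenario, path) -> None:
    """Single-column CSV of eps values with a metadata header comment."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            f"# G={scenario.G} k={scenario.k} p_eps={scenario.p_eps:.12g} "
            f"seed={scenario.seed}\n"
        )
        fh.write("eps\n")
        for e in scenario.eps_seq:
            fh.write(f"{e:.12g}\n")


def read_scenario_csv(path) -> Scenario:
    seed = None
    values: list[float] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("seed="):
                        raw = tok.split("=", 1)[1]
                        seed = None if raw == "None" else int(raw)
                continue
            if line == "eps":
                continue
            values.append(float(line))
    return Scenario(tuple(values), seed=seed)
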