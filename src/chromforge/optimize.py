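"""Elution-program optimization by differential evolution.

The search variables are the parameters of the elution program (initial and
final modifier fraction, gradient time, optionally a mid-node for two-segment
profiles) and operational factors such as temperature.  Each candidate is
decoded into a program, the separation is simulated from the component LSS
parameters, and two objectives scored: the critical resolution (to maximize)
and the analysis runtime, i.e. the elution time of the last component (to
minimize).

Single-objective modes scalarize or constrain; the recommended mode keeps
the full Pareto trade-off, using a GDE3-style dominance replacement (a trial
vector replaces its parent only when it dominates it) plus an external
archive of all non-dominated solutions found.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .gradsim import ElutionProgram, LSSParams, simulate_separation

__all__ = [
    "SearchSpace",
    "ParetoFront",
    "de_minimize",
    "pareto_filter",
    "optimize_separation",
    "decode_program",
]


@dataclass(frozen=True)
class SearchSpace:
    """Box bounds over named program/operational parameters.

    Recognized names for program decoding: phi_initial, phi_final, t_G,
    temperature, and optionally t_mid_frac / phi_mid for a two-segment
    profile.  Unknown names are allowed for generic use of the optimizer.
    """

    parameters: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        for name, lo, hi in self.parameters:
            if not lo < hi:
                raise ValueError(f"parameter {name}: low must be < high")

    @property
    def names(self) -> list[str]:
        return [n for n, _, _ in self.parameters]

    @property
    def lows(self) -> np.ndarray:
        return np.array([lo for _, lo, _ in self.parameters])

    @property
    def highs(self) -> np.ndarray:
        return np.array([hi for _, _, hi in self.parameters])

    @property
    def ndim(self) -> int:
        return len(self.parameters)


def decode_program(
    space: SearchSpace,
    vector: np.ndarray,
    t0: float = 1.0,
    t_dwell: float = 0.0,
    flow: float = 1.0,
    defaults: dict[str, float] | None = None,
) -> ElutionProgram:
    """Decode a search vector into a valid elution program.

    phi values are clipped to [0, 1] and node times sorted, so any in-bounds
    vector decodes to a program satisfying the program invariants.
    """
    vals = dict(zip(space.names, vector))
    d = {"phi_initial": 0.05, "phi_final": 0.95, "t_G": 10.0, "temperature": 25.0}
    if defaults:
        d.update(defaults)
    d.update(vals)
    phi0 = float(np.clip(d["phi_initial"], 0.0, 1.0))
    if d.get("isocratic"):
        d["phi_final"] = phi0
    phi1 = float(np.clip(d["phi_final"], 0.0, 1.0))
    t_g = max(float(d["t_G"]), 1e-3)
    nodes: list[tuple[float, float]] = [(0.0, phi0)]
    if ("t_mid_frac" in vals) or ("phi_mid" in vals):
        frac = float(np.clip(d.get("t_mid_frac", 0.5), 0.0, 1.0))
        phim = float(np.clip(d.get("phi_mid", (phi0 + phi1) / 2), 0.0, 1.0))
        nodes.append((frac * t_g, phim))
    nodes.append((t_g, phi1))
    nodes.sort(key=lambda n: n[0])
    return ElutionProgram(
        nodes=tuple(nodes),
        temperature=float(d["temperature"]),
        t0=t0,
        t_dwell=t_dwell,
        flow=flow,
    )


# ---------------------------------------------------------------------------
# single-objective DE


def de_minimize(
    objective: Callable[[np.ndarray], float],
    space: SearchSpace,
    pop: int = 40,
    gens: int = 200,
    F: float = 0.7,
    CR: float = 0.9,
    seed: int = 0,
    callback: Callable[[int, np.ndarray, float], None] | None = None,
) -> tuple[np.ndarray, float]:
    """DE/rand/1/bin with reflection bound handling.

    Mutation v = a + F (b - c) over three distinct random members, binomial
    crossover with at least one mutated gene, greedy parent replacement.
    Non-finite objective values are treated as +inf (the trial is rejected).
    Fully reproducible under ``seed``.
    """
    if pop < 4:
        raise ValueError("pop must be >= 4")
    if not 0 < F < 2:
        raise ValueError("F must be in (0, 2)")
    if not 0 <= CR <= 1:
        raise ValueError("CR must be in [0, 1]")
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    lo, hi = space.lows, space.highs
    d = space.ndim
    X = lo + rng.random((pop, d)) * (hi - lo)
    fx = np.array([_safe(objective, x) for x in X])
    for g in range(gens):
        for i in range(pop):
            a, b, c = _pick3(rng, pop, i)
            v = X[a] + F * (X[b] - X[c])
            v = _reflect(v, lo, hi)
            cross = rng.random(d) < CR
            cross[rng.integers(d)] = True
            u = np.where(cross, v, X[i])
            fu = _safe(objective, u)
            if fu <= fx[i]:
                X[i], fx[i] = u, fu
        if callback is not None:
            j = int(np.argmin(fx))
            callback(g, X[j], float(fx[j]))
    j = int(np.argmin(fx))
    return X[j].copy(), float(fx[j])


def _safe(objective: Callable[[np.ndarray], float], x: np.ndarray) -> float:
    v = objective(x)
    return float(v) if np.isfinite(v) else math.inf


def _pick3(rng: np.random.Generator, pop: int, i: int) -> tuple[int, int, int]:
    idx = [j for j in range(pop) if j != i]
    a, b, c = rng.choice(idx, size=3, replace=False)
    return int(a), int(b), int(c)


def _reflect(v: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    out = v.copy()
    for _ in range(8):  # repeated reflection for far-out mutants
        below = out < lo
        above = out > hi
        if not (below.any() or above.any()):
            break
        out = np.where(below, 2 * lo - out, out)
        out = np.where(above, 2 * hi - out, out)
    return np.clip(out, lo, hi)


# ---------------------------------------------------------------------------
# Pareto utilities


def _dominates(a: Sequence[float], b: Sequence[float]) -> bool:
    """a dominates b (all objectives minimized): <= everywhere, < somewhere."""
    a = np.asarray(a)
    b = np.asarray(b)
    return bool(np.all(a <= b) and np.any(a < b))


def pareto_filter(points: Sequence[Sequence[float]]) -> list[int]:
    """Indices of the non-dominated points (minimization orientation).

    Duplicates of a non-dominated point are all retained.
    """
    pts = [np.asarray(p, dtype=float) for p in points]
    keep: list[int] = []
    for i, p in enumerate(pts):
        dominated = any(
            _dominates(q, p) for j, q in enumerate(pts) if j != i
        )
        if not dominated:
            keep.append(i)
    return keep


@dataclass
class FrontMember:
    vector: np.ndarray
    objectives: tuple[float, float]  # (critical_Rs, runtime)
    program: ElutionProgram


@dataclass
class ParetoFront:
    members: list[FrontMember]
    generations: int
    evaluations: int

    @property
    def best_critical_Rs(self) -> float:
        return max((m.objectives[0] for m in self.members), default=0.0)

    def best_by_Rs(self) -> FrontMember:
        return max(self.members, key=lambda m: m.objectives[0])

    def to_records(self) -> list[dict]:
        return [
            {
                **{f"x{i}": v for i, v in enumerate(m.vector)},
                "critical_Rs": m.objectives[0],
                "runtime": m.objectives[1],
            }
            for m in self.members
        ]


# ---------------------------------------------------------------------------
# separation optimization


def optimize_separation(
    components: dict[str, LSSParams],
    space: SearchSpace,
    mode: str = "pareto",
    seed: int = 0,
    pop: int = 40,
    gens: int = 100,
    F: float = 0.7,
    CR: float = 0.9,
    plates: float = 8000.0,
    t0: float = 1.0,
    t_dwell: float = 0.0,
    dt: float | None = None,
    rs_cap: float = 10.0,
    rs_target: float = 1.5,
    weight_time: float = 0.05,
    program_defaults: dict[str, float] | None = None,
) -> ParetoFront:
    """Search the program space for optimal separations.

    Modes
    -----
    pareto
        GDE3-style dominance evolution on (-critical_Rs, runtime); returns
        the external archive as a :class:`ParetoFront`.
    weighted
        Scalarized single objective ``-min(Rs, rs_cap) + weight_time *
        runtime``; the front holds the single best program.
    threshold_time
        Minimize runtime subject to critical_Rs >= ``rs_target`` (penalty
        formulation); the front holds the single best program.

    Components flagged non-eluting in a trial simply penalize that trial.
    A single-component mixture is optimized for runtime alone (its infinite
    critical-Rs sentinel is ignored).
    """
    single = len(components) == 1

    def evaluate(x: np.ndarray) -> tuple[tuple[float, float], ElutionProgram]:
        program = decode_program(
            space, x, t0=t0, t_dwell=t_dwell, defaults=program_defaults
        )
        sim = simulate_separation(components, program, plates=plates, dt=dt)
        if not math.isfinite(sim.runtime):
            return (0.0, 1e6), program
        rs = sim.critical_Rs if not single else math.inf
        return (rs, sim.runtime), program

    evals = 0

    if mode in ("weighted", "threshold_time"):

        def scalar(x: np.ndarray) -> float:
            nonlocal evals
            evals += 1
            (rs, rt), _ = evaluate(x)
            if mode == "weighted":
                rs_eff = min(rs, rs_cap) if math.isfinite(rs) else rs_cap
                return -rs_eff + weight_time * rt
            penalty = 0.0 if (single or rs >= rs_target) else 1e3 * (rs_target - rs)
            return rt + penalty

        best_x, _ = de_minimize(scalar, space, pop=pop, gens=gens, F=F, CR=CR, seed=seed)
        obj, program = evaluate(best_x)
        return ParetoFront(
            [FrontMember(best_x, obj, program)], generations=gens, evaluations=evals
        )

    if mode != "pareto":
        raise ValueError(f"unknown mode {mode!r}")

    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    lo, hi = space.lows, space.highs
    d = space.ndim
    X = lo + rng.random((pop, d)) * (hi - lo)
    pool = [evaluate(x) for x in X]
    evals += pop
    objs = [p[0] for p in pool]  # (rs, runtime)

    def as_min(o: tuple[float, float]) -> tuple[float, float]:
        rs, rt = o
        rs_eff = min(rs, rs_cap) if math.isfinite(rs) else rs_cap
        return (-rs_eff, rt)

    archive: list[FrontMember] = []

    def archive_add(x: np.ndarray, o: tuple[float, float], prog: ElutionProgram) -> None:
        cand = FrontMember(x.copy(), o, prog)
        kept = [m for m in archive if not _dominates(as_min(o), as_min(m.objectives))]
        if any(_dominates(as_min(m.objectives), as_min(o)) for m in kept):
            return
        kept.append(cand)
        archive.clear()
        archive.extend(kept)

    for x, (o, prog) in zip(X, pool):
        archive_add(x, o, prog)

    for g in range(gens):
        for i in range(pop):
            a, b, c = _pick3(rng, pop, i)
            v = X[a] + F * (X[b] - X[c])
            v = _reflect(v, lo, hi)
            cross = rng.random(d) < CR
            cross[rng.integers(d)] = True
            u = np.where(cross, v, X[i])
            ou, prog_u = evaluate(u)
            evals += 1
            # GDE3-style greedy rule: the trial replaces its parent only when
            # it dominates it; everything evaluated feeds the archive
            if _dominates(as_min(ou), as_min(objs[i])):
                X[i], objs[i] = u, ou
            archive_add(u, ou, prog_u)

    return ParetoFront(archive, generations=gens, evaluations=evals)
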