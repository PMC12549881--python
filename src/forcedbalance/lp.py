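"""Uniform linear-programming layer.

Every balancing, concordance and screening question in this package reduces
to optimizing a linear functional over the steady-state flux space

    S = { v | N v = 0, v_min <= v <= v_max }

optionally intersected with extra equality rows such as a forced-balancing
constraint A^{i:} v = 0. This module is the single place where those LPs
are assembled and solved (scipy's HiGHS backend), so the zero-tolerance
contract — a value is "zero" iff |value| <= zero_tol — is applied uniformly.

Because preprocessing caps all bounds, S is a bounded polytope; an
"unbounded" solver status therefore indicates a configuration error and is
raised, never silently interpreted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linprog

from .config import Config, DEFAULT_CONFIG
from .model import InfeasibleModelError, MetabolicNetwork

__all__ = ["LPProblem", "LPResult", "LPError", "solve", "fva", "optimize_row"]

ExtraEqualities = Sequence[tuple[np.ndarray, float]]


class LPError(RuntimeError):
    """Solver failure other than plain infeasibility."""


@dataclass(frozen=True)
class LPProblem:
    objective: np.ndarray
    sense: str  # "min" | "max"
    steady_state: np.ndarray  # N, enforced as N v = 0
    bounds: tuple[np.ndarray, np.ndarray]
    extra_equalities: ExtraEqualities = field(default_factory=tuple)

    def __post_init__(self) -> None:
        n = self.steady_state.shape[1]
        if self.sense not in ("min", "max"):
            raise ValueError("sense must be 'min' or 'max'")
        if len(self.objective) != n:
            raise ValueError("objective dimension mismatch")
        lb, ub = self.bounds
        if len(lb) != n or len(ub) != n:
            raise ValueError("bounds dimension mismatch")
        if not (np.all(np.isfinite(lb)) and np.all(np.isfinite(ub))):
            raise ValueError("bounds must be finite (preprocess with a bound cap)")
        for row, _ in self.extra_equalities:
            if len(row) != n:
                raise ValueError("extra equality dimension mismatch")


@dataclass(frozen=True)
class LPResult:
    status: str  # "optimal" | "infeasible"
    objective_value: float | None
    solution: np.ndarray | None


def solve(problem: LPProblem, config: Config = DEFAULT_CONFIG) -> LPResult:
    """Solve an LP over S; deterministic for a fixed backend."""
    N = problem.steady_state
    rows = [N] + [np.asarray(r, dtype=float).reshape(1, -1) for r, _ in problem.extra_equalities]
    rhs = np.concatenate(
        [np.zeros(N.shape[0])] + [[float(b)] for _, b in problem.extra_equalities]
    )
    A_eq = np.vstack(rows) if rows else None
    c = np.asarray(problem.objective, dtype=float)
    sign = 1.0 if problem.sense == "min" else -1.0
    lb, ub = problem.bounds
    res = linprog(
        sign * c,
        A_eq=A_eq,
        b_eq=rhs,
        bounds=list(zip(lb, ub)),
        method=config.solver,
        options={
            "primal_feasibility_tolerance": config.feasibility_tol,
            "dual_feasibility_tolerance": config.feasibility_tol,
        },
    )
    if res.status == 0:
        return LPResult("optimal", sign * float(res.fun), np.asarray(res.x))
    if res.status == 2:
        return LPResult("infeasible", None, None)
    if res.status == 3:
        raise LPError(
            "LP reported unbounded; the flux space should be a bounded polytope "
            "after preprocessing — check flux bounds"
        )
    raise LPError(f"LP solver failure: {res.message}")


def optimize_row(
    net: MetabolicNetwork,
    row: np.ndarray,
    sense: str,
    extra_equalities: ExtraEqualities = (),
    config: Config = DEFAULT_CONFIG,
) -> LPResult:
    """Optimize ``row . v`` over the network's steady-state flux space."""
    return solve(
        LPProblem(
            objective=np.asarray(row, dtype=float),
            sense=sense,
            steady_state=net.stoichiometric_matrix,
            bounds=net.flux_bounds,
            extra_equalities=tuple(extra_equalities),
        ),
        config=config,
    )


def fva(
    net: MetabolicNetwork,
    reactions: Sequence[int] | None = None,
    extra_equalities: ExtraEqualities = (),
    config: Config = DEFAULT_CONFIG,
) -> list[tuple[float, float]]:
    """Per-reaction flux ranges over S (intersected with extra equalities).

    Returns one ``(min, max)`` pair per requested reaction index (all
    reactions when ``reactions`` is None). Infeasibility of the constrained
    space is reported once, as :class:`InfeasibleModelError`.
    """
    n = len(net.reactions)
    idx = list(range(n)) if reactions is None else list(reactions)
    out: list[tuple[float, float]] = []
    for j in idx:
        e = np.zeros(n)
        e[j] = 1.0
        lo = solve_or_raise(net, e, "min", extra_equalities, config)
        hi = solve_or_raise(net, e, "max", extra_equalities, config)
        out.append((lo, hi))
    return out


def solve_or_raise(
    net: MetabolicNetwork,
    row: np.ndarray,
    sense: str,
    extra_equalities: ExtraEqualities = (),
    config: Config = DEFAULT_CONFIG,
) -> float:
    res = optimize_row(net, row, sense, extra_equalities, config)
    if res.status != "optimal":
        raise InfeasibleModelError(
            "steady-state flux space is empty under the given constraints"
        )
    return float(res.objective_value)
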