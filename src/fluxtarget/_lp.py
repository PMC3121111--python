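"""Thin solver-agnostic linear-programming layer over scipy's HiGHS.

The two FBA stages describe their models as a :class:`LinearProgram` —
named variables with box bounds, named sparse constraint rows with lower
and upper row bounds, and a linear objective with a sense.  Solving goes
through :func:`solve_lp` (single objective) or :func:`lexicographic_solve`
(a priority-ordered list of objectives, each later stage restricted to the
optimal face of the previous one within a small slack).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

__all__ = ["LinearProgram", "LPSolution", "solve_lp", "lexicographic_solve"]

STATUS_OPTIMAL = "optimal"
STATUS_INFEASIBLE = "infeasible"
STATUS_UNBOUNDED = "unbounded"

_SCIPY_STATUS = {0: STATUS_OPTIMAL, 2: STATUS_INFEASIBLE, 3: STATUS_UNBOUNDED}


@dataclass
class LinearProgram:
    """Named-variable LP description (all data, no solver state)."""

    sense: str = "max"  # of the primary objective
    objective: dict[str, float] = field(default_factory=dict)
    _vars: dict[str, tuple[float, float]] = field(default_factory=dict)
    _rows: list[tuple[str, dict[str, float], float, float]] = field(default_factory=list)

    def add_variable(self, name: str, lb: float = 0.0, ub: float = np.inf) -> None:
        if name in self._vars:
            raise ValueError(f"duplicate LP variable {name!r}")
        if lb > ub:
            raise ValueError(f"variable {name!r}: lower bound {lb} exceeds upper bound {ub}")
        self._vars[name] = (float(lb), float(ub))

    def set_bounds(self, name: str, lb: float, ub: float) -> None:
        if name not in self._vars:
            raise KeyError(name)
        if lb > ub:
            raise ValueError(f"variable {name!r}: lower bound {lb} exceeds upper bound {ub}")
        self._vars[name] = (float(lb), float(ub))

    def bounds(self, name: str) -> tuple[float, float]:
        return self._vars[name]

    def add_constraint(
        self,
        name: str,
        coeffs: Mapping[str, float],
        lb: float = -np.inf,
        ub: float = np.inf,
    ) -> None:
        """Add the row ``lb <= sum coeffs[v] * v <= ub`` (equality if lb == ub)."""
        unknown = [v for v in coeffs if v not in self._vars]
        if unknown:
            raise ValueError(f"constraint {name!r} references unknown variables {unknown}")
        self._rows.append((name, dict(coeffs), float(lb), float(ub)))

    @property
    def variable_names(self) -> list[str]:
        return list(self._vars)

    @property
    def constraint_names(self) -> list[str]:
        return [r[0] for r in self._rows]


@dataclass
class LPSolution:
    status: str
    values: dict[str, float]
    objective: float
    message: str = ""

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def _solve(lp: LinearProgram, sense: str, objective: Mapping[str, float]) -> LPSolution:
    names = lp.variable_names
    idx = {v: k for k, v in enumerate(names)}
    nv = len(names)
    sign = -1.0 if sense == "max" else 1.0
    c = np.zeros(nv)
    for v, coef in objective.items():
        c[idx[v]] = sign * coef

    a_eq, b_eq, a_ub, b_ub = [], [], [], []
    for _name, coeffs, lb, ub in lp._rows:
        row = np.zeros(nv)
        for v, coef in coeffs.items():
            row[idx[v]] = coef
        if lb == ub:
            a_eq.append(row)
            b_eq.append(lb)
            continue
        if np.isfinite(ub):
            a_ub.append(row)
            b_ub.append(ub)
        if np.isfinite(lb):
            a_ub.append(-row)
            b_ub.append(-lb)

    res = linprog(
        c,
        A_ub=np.array(a_ub) if a_ub else None,
        b_ub=np.array(b_ub) if b_ub else None,
        A_eq=np.array(a_eq) if a_eq else None,
        b_eq=np.array(b_eq) if b_eq else None,
        bounds=[lp._vars[v] for v in names],
        method="highs",
    )
    status = _SCIPY_STATUS.get(res.status, STATUS_INFEASIBLE)
    values = (
        {v: float(res.x[idx[v]]) for v in names}
        if res.x is not None
        else {v: float("nan") for v in names}
    )
    obj = sign * float(res.fun) if res.fun is not None else float("nan")
    return LPSolution(status=status, values=values, objective=obj, message=res.message or "")


def solve_lp(lp: LinearProgram) -> LPSolution:
    return _solve(lp, lp.sense, lp.objective)


def lexicographic_solve(
    lp: LinearProgram,
    stages: Sequence[tuple[str, Mapping[str, float]]],
    eps: float = 1e-9,
) -> LPSolution:
    """Solve a priority-ordered sequence of ``(sense, objective)`` stages.

    After each stage the previous objective is pinned to its optimum (within
    ``eps``, scaled by the optimum's magnitude) via an added row.  Returns
    the final stage's solution with ``objective`` set to the FIRST stage's
    optimum (the model's primary objective).  If any later stage fails
    (numerically infeasible or unbounded, e.g. maximizing total flux under
    infinite capacity), the last successful stage's solution is returned —
    the primary optimum is never sacrificed for a tie-break.
    """
    if not stages:
        raise ValueError("at least one objective stage is required")
    pinned: list[tuple[str, dict[str, float], float, float]] = []
    best: LPSolution | None = None
    primary_opt = float("nan")
    for k, (sense, objective) in enumerate(stages):
        sol = _solve(lp, sense, objective)
        if sol.status != STATUS_OPTIMAL:
            if best is None:
                return sol
            break
        if k == 0:
            primary_opt = sol.objective
        best = sol
        if k < len(stages) - 1:
            slack = eps * max(1.0, abs(sol.objective))
            if sense == "max":
                row = ("_lex_%d" % k, dict(objective), sol.objective - slack, np.inf)
            else:
                row = ("_lex_%d" % k, dict(objective), -np.inf, sol.objective + slack)
            lp._rows.append(row)
            pinned.append(row)
    for row in pinned:
        lp._rows.remove(row)
    assert best is not None
    return LPSolution(
        status=best.status, values=best.values, objective=primary_opt, message=best.message
    )
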