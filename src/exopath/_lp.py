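"""Thin wrappers around scipy's HiGHS LP/MILP solvers.

Infeasibility is a modelling outcome and gets its own exception type;
anything else the solver reports is a genuine solver failure.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog, milp

__all__ = ["InfeasibleProblem", "SolverFailure", "solve_lp", "lp_feasible", "solve_bip"]


class InfeasibleProblem(Exception):
    """The linear program has no feasible point."""


class SolverFailure(RuntimeError):
    """The solver failed for a reason other than infeasibility."""


def solve_lp(c, A_ub=None, b_ub=None, A_eq=None, b_eq=None, bounds=None):
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs"
    )
    if res.status == 2:
        raise InfeasibleProblem(res.message)
    if res.status == 3:
        # unbounded: still a meaningful LP outcome for cones
        return res
    if not res.success:
        raise SolverFailure(res.message)
    return res


def lp_feasible(A_ub=None, b_ub=None, A_eq=None, b_eq=None, bounds=None):
    """Feasibility check (zero objective). Returns the point or None."""
    n = None
    for M in (A_ub, A_eq):
        if M is not None:
            n = np.asarray(M).shape[1]
            break
    if n is None and bounds is not None:
        n = len(bounds)
    try:
        res = solve_lp(np.zeros(n), A_ub, b_ub, A_eq, b_eq, bounds)
    except InfeasibleProblem:
        return None
    return res.x


def solve_bip(c, A_ub=None, b_ub=None, maximize=False):
    """Solve a binary integer program; returns 0/1 vector or None if infeasible."""
    from scipy.optimize import Bounds, LinearConstraint

    c = np.asarray(c, dtype=float)
    if maximize:
        c = -c
    constraints = []
    if A_ub is not None:
        A_ub = np.asarray(A_ub, dtype=float)
        constraints.append(LinearConstraint(A_ub, -np.inf, np.asarray(b_ub, dtype=float)))
    res = milp(
        c,
        integrality=np.ones(len(c)),
        bounds=Bounds(0, 1),
        constraints=constraints or None,
    )
    if res.status == 2:
        return None
    if not res.success:
        raise SolverFailure(res.message)
    return np.round(res.x).astype(int)
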