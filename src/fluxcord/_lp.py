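"""Linear-programming layer shared by FVA, feasibility checks and the
polytope sampler.  All LPs are solved with scipy's HiGHS interface on the
explicit polytope {v : S v = 0, lo <= A v <= hi, lb <= v <= ub}."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .model import MetabolicModel

__all__ = ["InfeasibleModelError", "PolytopeSystem", "build_system", "fva", "interior_point"]

#: constraints whose two sides differ by less than this are treated as
#: equalities (e.g. a ratio row with zero replicate spread)
EQUALITY_TOL = 1e-12


class InfeasibleModelError(RuntimeError):
    """The constraint set admits no feasible flux vector."""


@dataclass
class PolytopeSystem:
    """Explicit matrices of the feasible flux polytope."""

    S: np.ndarray              # (m, n) stoichiometry
    A: np.ndarray              # (k, n) extra constraint rows (may be empty)
    row_lower: np.ndarray      # (k,)
    row_upper: np.ndarray      # (k,)
    lb: np.ndarray             # (n,)
    ub: np.ndarray             # (n,)
    reaction_ids: list[str]
    species_ids: list[str]
    constraint_names: list[str]

    @property
    def n(self) -> int:
        return self.S.shape[1]

    def linprog_parts(self):
        """(A_ub, b_ub, A_eq, b_eq, bounds) encoding of the polytope."""
        A_ub_rows, b_ub = [], []
        A_eq_rows, b_eq = [], []
        for i in range(self.A.shape[0]):
            lo, hi = self.row_lower[i], self.row_upper[i]
            if hi - lo <= EQUALITY_TOL:
                A_eq_rows.append(self.A[i])
                b_eq.append(0.5 * (lo + hi))
                continue
            if np.isfinite(hi):
                A_ub_rows.append(self.A[i])
                b_ub.append(hi)
            if np.isfinite(lo):
                A_ub_rows.append(-self.A[i])
                b_ub.append(-lo)
        A_eq = np.vstack([self.S] + A_eq_rows) if A_eq_rows else self.S
        b_eq = np.concatenate([np.zeros(self.S.shape[0]), np.asarray(b_eq, float)])
        A_ub = np.asarray(A_ub_rows, float) if A_ub_rows else None
        b_ub = np.asarray(b_ub, float) if A_ub_rows else None
        bounds = list(zip(self.lb, self.ub))
        return A_ub, b_ub, A_eq, b_eq, bounds


def build_system(model: MetabolicModel) -> PolytopeSystem:
    S, species_ids, reaction_ids = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    index = {rid: j for j, rid in enumerate(reaction_ids)}
    k = len(model.extra_constraints)
    A = np.zeros((k, len(reaction_ids)))
    lo = np.full(k, -np.inf)
    hi = np.full(k, np.inf)
    names = []
    for i, c in enumerate(model.extra_constraints):
        for rid, a in c.coefficients.items():
            A[i, index[rid]] = a
        lo[i], hi[i] = c.lower, c.upper
        names.append(c.name)
    return PolytopeSystem(S, A, lo, hi, lb, ub, reaction_ids, species_ids, names)


def _solve(system: PolytopeSystem, c: np.ndarray):
    A_ub, b_ub, A_eq, b_eq, bounds = system.linprog_parts()
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds,
                  method="highs")
    return res


def fva(
    model: MetabolicModel,
    reaction_ids: list[str] | None = None,
    zero_tol: float = 1e-9,
) -> pd.DataFrame:
    """Flux variability analysis: per-reaction min/max flux over the
    feasible region, with no objective imposed.

    Returns a DataFrame indexed by reaction id with columns ``minimum``
    and ``maximum``; values with magnitude below ``zero_tol`` are clipped
    to zero.  Raises :class:`InfeasibleModelError` when the region is
    empty.
    """
    system = build_system(model)
    if reaction_ids is None:
        reaction_ids = system.reaction_ids
    index = {rid: j for j, rid in enumerate(system.reaction_ids)}

    # feasibility probe first, so infeasibility is reported once
    res = _solve(system, np.zeros(system.n))
    if res.status == 2:
        raise InfeasibleModelError(
            f"model {model.id!r} is infeasible under the current constraint set "
            f"(bounds, {len(model.extra_constraints)} extra rows)"
        )

    out = np.empty((len(reaction_ids), 2))
    c = np.zeros(system.n)
    for i, rid in enumerate(reaction_ids):
        j = index[rid]
        for sign, col in ((1.0, 0), (-1.0, 1)):
            c[j] = sign
            res = _solve(system, c)
            c[j] = 0.0
            if res.status == 3:  # unbounded
                out[i, col] = -np.inf if sign > 0 else np.inf
                continue
            if not res.success:
                raise InfeasibleModelError(
                    f"FVA LP failed for reaction {rid!r}: {res.message}"
                )
            out[i, col] = res.fun if sign > 0 else -res.fun
    out[np.abs(out) < zero_tol] = 0.0
    # guard against solver jitter producing min slightly above max
    frame = pd.DataFrame(out, index=reaction_ids, columns=["minimum", "maximum"])
    frame["maximum"] = np.maximum(frame["maximum"], frame["minimum"])
    return frame


def interior_point(system: PolytopeSystem, cap: float = 1.0):
    """A point well inside the polytope, found by maximizing the smallest
    slack t of all genuinely two-sided constraints (Chebyshev-like LP).

    Returns ``(v0, t)``; ``t == 0`` signals an empty interior (the
    polytope is a single point or a lower-dimensional face beyond the
    implicit equalities already handled).
    """
    n = system.n
    width = system.ub - system.lb
    free = width > EQUALITY_TOL

    # variables: v (n) then t (1)
    A_ub_rows, b_ub = [], []
    for j in np.where(free)[0]:
        row = np.zeros(n + 1)
        row[j], row[n] = 1.0, 1.0
        A_ub_rows.append(row.copy())          # v_j + t <= ub_j
        b_ub.append(system.ub[j])
        row[j] = -1.0
        A_ub_rows.append(row)                 # -v_j + t <= -lb_j
        b_ub.append(-system.lb[j])

    A_eq_rows = [np.hstack([system.S, np.zeros((system.S.shape[0], 1))])]
    b_eq = [np.zeros(system.S.shape[0])]
    for i in range(system.A.shape[0]):
        lo, hi = system.row_lower[i], system.row_upper[i]
        if hi - lo <= EQUALITY_TOL:
            A_eq_rows.append(np.hstack([system.A[i], [0.0]])[None, :])
            b_eq.append([0.5 * (lo + hi)])
            continue
        scale = max(np.linalg.norm(system.A[i]), 1.0)
        if np.isfinite(hi):
            A_ub_rows.append(np.hstack([system.A[i], [scale]]))
            b_ub.append(hi)
        if np.isfinite(lo):
            A_ub_rows.append(np.hstack([-system.A[i], [scale]]))
            b_ub.append(-lo)

    bounds = [(l, u) for l, u in zip(system.lb, system.ub)] + [(0.0, cap)]
    c = np.zeros(n + 1)
    c[n] = -1.0
    res = linprog(
        c,
        A_ub=np.asarray(A_ub_rows) if A_ub_rows else None,
        b_ub=np.asarray(b_ub, float) if A_ub_rows else None,
        A_eq=np.vstack(A_eq_rows),
        b_eq=np.concatenate([np.atleast_1d(b) for b in b_eq]),
        bounds=bounds,
        method="highs",
    )
    if res.status == 2:
        raise InfeasibleModelError("constraint set is infeasible")
    if not res.success:
        raise InfeasibleModelError(f"interior-point LP failed: {res.message}")
    return res.x[:n], float(res.x[n])
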