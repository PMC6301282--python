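"""Linear-programming core: FBA, flux variability, and geometric FBA.

Flux balance analysis maximizes an objective c.v over the steady-state
polytope {S.v = 0 on internal metabolites, V_min <= v <= V_max}.  Because
the optimal face of that polytope is usually not a single point, plain FBA
returns an arbitrary vertex.  Geometric FBA instead selects a unique,
central point of the optimal face by iterated centering:

1. fix the objective at its optimum,
2. compute flux-variability ranges [a, b] for every reaction,
3. project onto the range midpoints (an L1-minimizing LP, which keeps every
   step a pure linear program),
4. shrink the working box halfway toward the midpoints (always keeping the
   projected point inside, so the restricted polytope stays non-empty) and
   repeat until the largest range width falls below the tolerance.

The box widths contract geometrically, so the result is deterministic to
within the tolerance regardless of which vertex the simplex engine would
otherwise report.  A side effect of centering is that isolated reversible
cycles -- whose variability ranges are symmetric about zero -- collapse to
zero flux, removing thermodynamically infeasible internal loops.

The LP engine is accessed through a thin persistent interface (GLPK via
optlang); any simplex/interior-point engine satisfying the same contract
would do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import cobra
import numpy as np
import pandas as pd
from optlang.glpk_interface import Constraint, Model as LPModel, Objective, Variable

from .errors import ConfigurationError, SolverError

__all__ = [
    "FluxSolution",
    "ModelArrays",
    "GeometricSolver",
    "fba",
    "fva",
    "geometric_fba",
]

#: Numerical slack used when re-imposing the optimal objective value.
OBJECTIVE_SLACK = 1e-9


@dataclass
class FluxSolution:
    """A flux distribution with solver metadata.

    ``fluxes`` is ``None`` unless ``status == "optimal"``.
    """

    fluxes: pd.Series | None
    objective_value: float
    status: str
    method: str = "fba"
    converged: bool = True
    iterations: int = 0


@dataclass
class ModelArrays:
    """Dense array view of a constraint-based model (S, bounds, objective)."""

    S: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    objective: np.ndarray
    reaction_ids: list[str]
    metabolite_ids: list[str]

    @classmethod
    def from_cobra(cls, model: cobra.Model) -> "ModelArrays":
        from cobra.util.array import create_stoichiometric_matrix

        S = create_stoichiometric_matrix(model)
        lower = np.array([r.lower_bound for r in model.reactions], dtype=float)
        upper = np.array([r.upper_bound for r in model.reactions], dtype=float)
        c = np.array([r.objective_coefficient for r in model.reactions],
                     dtype=float)
        if model.objective_direction == "min":
            c = -c
        return cls(
            S=S,
            lower=lower,
            upper=upper,
            objective=c,
            reaction_ids=[r.id for r in model.reactions],
            metabolite_ids=[m.id for m in model.metabolites],
        )


def _as_arrays(model: cobra.Model | ModelArrays) -> ModelArrays:
    if isinstance(model, ModelArrays):
        return model
    return ModelArrays.from_cobra(model)


class _LinearProgram:
    """Persistent LP over flux variables with S.v = 0 and box bounds."""

    def __init__(self, arrays: ModelArrays, with_deviation: bool = False):
        self.n = len(arrays.reaction_ids)
        self.v = [
            Variable(f"v_{j}", lb=arrays.lower[j], ub=arrays.upper[j])
            for j in range(self.n)
        ]
        self.model = LPModel()
        self.model.add(self.v)
        constraints = []
        S = arrays.S
        for i in range(S.shape[0]):
            idx = np.nonzero(S[i])[0]
            if idx.size == 0:
                continue
            expr = sum(float(S[i, j]) * self.v[j] for j in idx)
            constraints.append(Constraint(expr, lb=0, ub=0, name=f"m_{i}"))
        self.obj_fix: Constraint | None = None
        if np.any(arrays.objective):
            idx = np.nonzero(arrays.objective)[0]
            expr = sum(float(arrays.objective[j]) * self.v[j] for j in idx)
            # Disabled until fix_objective() is called.
            self.obj_fix = Constraint(expr, lb=None, ub=None, name="obj_fix")
            constraints.append(self.obj_fix)
        self.dev: list[Variable] = []
        self.dev_lo: list[Constraint] = []
        self.dev_hi: list[Constraint] = []
        if with_deviation:
            self.dev = [Variable(f"d_{j}", lb=0) for j in range(self.n)]
            self.model.add(self.dev)
            for j in range(self.n):
                # v_j - d_j <= m_j  and  v_j + d_j >= m_j
                self.dev_hi.append(
                    Constraint(self.v[j] - self.dev[j], ub=0, name=f"dh_{j}")
                )
                self.dev_lo.append(
                    Constraint(self.v[j] + self.dev[j], lb=0, name=f"dl_{j}")
                )
            constraints += self.dev_hi + self.dev_lo
        self.model.add(constraints)
        self.model.objective = Objective(self.v[0], direction="max")
        self._obj_vars: list[Variable] = [self.v[0]]

    def set_bounds(self, lower: np.ndarray, upper: np.ndarray) -> None:
        for j in range(self.n):
            var = self.v[j]
            lb, ub = float(lower[j]), float(upper[j])
            # Assign in an order that never inverts the pair transiently.
            if lb > (var.ub if var.ub is not None else np.inf):
                var.ub = ub
                var.lb = lb
            else:
                var.lb = lb
                var.ub = ub

    def fix_objective(self, value: float) -> None:
        if self.obj_fix is None:
            raise ConfigurationError("model has a zero objective vector")
        self.obj_fix.lb = value - OBJECTIVE_SLACK * max(1.0, abs(value))

    def release_objective(self) -> None:
        if self.obj_fix is not None:
            self.obj_fix.lb = None

    def set_midpoints(self, mids: np.ndarray) -> None:
        for j in range(self.n):
            m = float(mids[j])
            self.dev_hi[j].ub = m
            self.dev_lo[j].lb = m

    def _set_objective(self, coeffs: dict[Variable, float], direction: str) -> None:
        zero = {var: 0.0 for var in self._obj_vars}
        self.model.objective.direction = direction
        self.model.objective.set_linear_coefficients({**zero, **coeffs})
        self._obj_vars = list(coeffs)

    def optimize(self, coeffs: dict[Variable, float], direction: str) -> str:
        self._set_objective(coeffs, direction)
        return self.model.optimize()

    def objective_value(self) -> float:
        return self.model.objective.value

    def primal(self) -> np.ndarray:
        return np.array([var.primal for var in self.v], dtype=float)


def fba(model: cobra.Model | ModelArrays) -> FluxSolution:
    """Solve the flux balance LP: maximize c.v subject to S.v = 0 and bounds."""
    arrays = _as_arrays(model)
    if not np.any(arrays.objective):
        raise ConfigurationError("model has no objective reaction set")
    lp = _LinearProgram(arrays)
    idx = np.nonzero(arrays.objective)[0]
    status = lp.optimize(
        {lp.v[j]: float(arrays.objective[j]) for j in idx}, "max"
    )
    if status != "optimal":
        status = status if status in ("infeasible", "unbounded") else "infeasible"
        return FluxSolution(None, float("nan"), status)
    fluxes = pd.Series(lp.primal(), index=arrays.reaction_ids, name="flux")
    return FluxSolution(fluxes, float(lp.objective_value()), "optimal")


def fva(
    model: cobra.Model | ModelArrays,
    fraction_of_optimum: float = 1.0,
    reactions: list[str] | None = None,
) -> pd.DataFrame:
    """Per-reaction flux ranges subject to c.v >= fraction x optimum.

    Returns a DataFrame indexed by reaction id with columns ``minimum`` and
    ``maximum``.
    """
    arrays = _as_arrays(model)
    lp = _LinearProgram(arrays)
    if np.any(arrays.objective):
        idx = np.nonzero(arrays.objective)[0]
        status = lp.optimize(
            {lp.v[j]: float(arrays.objective[j]) for j in idx}, "max"
        )
        if status != "optimal":
            raise SolverError(f"base FBA problem is {status}")
        lp.fix_objective(fraction_of_optimum * lp.objective_value())
    pos = {rid: j for j, rid in enumerate(arrays.reaction_ids)}
    if reactions is None:
        targets = arrays.reaction_ids
    else:
        unknown = [r for r in reactions if r not in pos]
        if unknown:
            raise ConfigurationError(f"unknown reactions in FVA subset: {unknown}")
        targets = list(reactions)
    rows = {}
    for rid in targets:
        var = lp.v[pos[rid]]
        lo = hi = np.nan
        for direction in ("min", "max"):
            status = lp.optimize({var: 1.0}, direction)
            if status != "optimal":
                raise SolverError(f"FVA subproblem for {rid} is {status}")
            if direction == "min":
                lo = lp.objective_value()
            else:
                hi = lp.objective_value()
        rows[rid] = (lo, hi)
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["minimum", "maximum"]
    ).loc[targets]


class GeometricSolver:
    """Reusable geometric-FBA solver over a fixed network structure.

    Building the underlying LPs once and re-solving with changed bounds is
    what makes the transcriptome batch (one geometric solve per sample)
    affordable.
    """

    def __init__(self, arrays: ModelArrays, tolerance: float = 1e-6,
                 max_iterations: int = 200):
        if not np.any(arrays.objective):
            raise ConfigurationError("model has no objective reaction set")
        self.arrays = arrays
        self.tolerance = tolerance
        self.max_iterations = max_iterations
        self._lp = _LinearProgram(arrays)
        self._proj = _LinearProgram(arrays, with_deviation=True)
        self._obj_idx = np.nonzero(arrays.objective)[0]

    def solve(self, lower: np.ndarray | None = None,
              upper: np.ndarray | None = None) -> FluxSolution:
        arrays = self.arrays
        lo = arrays.lower.copy() if lower is None else np.asarray(lower, float).copy()
        hi = arrays.upper.copy() if upper is None else np.asarray(upper, float).copy()
        n = self._lp.n

        # A previous sample's objective fix must not constrain this solve.
        self._lp.release_objective()
        self._proj.release_objective()
        self._lp.set_bounds(lo, hi)
        coeffs = {self._lp.v[j]: float(arrays.objective[j]) for j in self._obj_idx}
        status = self._lp.optimize(coeffs, "max")
        if status != "optimal":
            raise SolverError(f"base FBA problem is {status}")
        z_star = float(self._lp.objective_value())
        self._lp.fix_objective(z_star)
        self._proj.fix_objective(z_star)

        dev_coeffs = {d: 1.0 for d in self._proj.dev}
        active = np.arange(n)
        v = None
        converged = False
        iteration = 0
        while iteration < self.max_iterations:
            iteration += 1
            for j in active:
                var = self._lp.v[j]
                st = self._lp.optimize({var: 1.0}, "min")
                if st != "optimal":
                    raise SolverError(f"FVA subproblem is {st}")
                a = self._lp.objective_value()
                st = self._lp.optimize({var: 1.0}, "max")
                if st != "optimal":
                    raise SolverError(f"FVA subproblem is {st}")
                b = self._lp.objective_value()
                # Guard against tiny inversions from solver round-off.
                lo[j], hi[j] = min(a, b), max(a, b)
            width = hi - lo
            active = np.nonzero(width > self.tolerance)[0]
            mids = (lo + hi) / 2.0
            self._proj.set_bounds(lo, hi)
            self._proj.set_midpoints(mids)
            st = self._proj.optimize(dev_coeffs, "min")
            if st != "optimal":
                raise SolverError(f"centering projection is {st}")
            v = self._proj.primal()
            if active.size == 0:
                converged = True
                break
            # Shrink the box halfway toward the midpoints, keeping the
            # projected point inside so the restriction stays feasible.
            new_lo = np.minimum((lo + mids) / 2.0, v)
            new_hi = np.maximum((mids + hi) / 2.0, v)
            lo, hi = new_lo, new_hi
            self._lp.set_bounds(lo, hi)
        fluxes = pd.Series(v, index=arrays.reaction_ids, name="flux")
        fluxes[np.abs(fluxes) < 1e-12] = 0.0
        return FluxSolution(
            fluxes,
            z_star,
            "optimal",
            method="geometric",
            converged=converged,
            iterations=iteration,
        )


def geometric_fba(
    model: cobra.Model | ModelArrays,
    tolerance: float = 1e-6,
    max_iterations: int = 200,
) -> FluxSolution:
    """Unique central solution of the FBA optimal face (see module docs).

    If the iteration cap is reached first, the last iterate is returned with
    ``converged=False``.
    """
    arrays = _as_arrays(model)
    solver = GeometricSolver(arrays, tolerance=tolerance,
                             max_iterations=max_iterations)
    return solver.solve()
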