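"""Shared fixtures and an independent LP oracle.

The oracle builds the stoichiometric LP directly from the cobra container
and solves it with scipy's HiGHS backend — a code path disjoint from the
package's GLPK-based solver layer — so agreement between the two is a real
cross-check, not a tautology.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import linprog

from rlflux.synth import ToyModelSpec, toy_model


def oracle_optimum(model, objective: str | None = None) -> float:
    """Maximum of the FBA LP, solved independently with HiGHS."""
    reactions = list(model.reactions)
    metabolites = list(model.metabolites)
    met_index = {m.id: i for i, m in enumerate(metabolites)}
    S = np.zeros((len(metabolites), len(reactions)))
    c = np.zeros(len(reactions))
    bounds = []
    for j, rxn in enumerate(reactions):
        for met, coeff in rxn.metabolites.items():
            S[met_index[met.id], j] = coeff
        bounds.append((rxn.lower_bound, rxn.upper_bound))
        if objective is None:
            c[j] = rxn.objective_coefficient
        elif rxn.id == objective:
            c[j] = 1.0
    res = linprog(-c, A_eq=S, b_eq=np.zeros(len(metabolites)), bounds=bounds,
                  method="highs")
    assert res.status == 0, f"oracle LP not optimal: {res.message}"
    return -res.fun


def oracle_flux_range(model, reaction: str, objective: str | None = None,
                      fraction: float = 1.0) -> tuple[float, float]:
    """Independent HiGHS FVA of one reaction at a given objective fraction."""
    reactions = list(model.reactions)
    metabolites = list(model.metabolites)
    met_index = {m.id: i for i, m in enumerate(metabolites)}
    S = np.zeros((len(metabolites), len(reactions)))
    obj = np.zeros(len(reactions))
    target = np.zeros(len(reactions))
    bounds = []
    for j, rxn in enumerate(reactions):
        for met, coeff in rxn.metabolites.items():
            S[met_index[met.id], j] = coeff
        bounds.append((rxn.lower_bound, rxn.upper_bound))
        if (objective is None and rxn.objective_coefficient) or rxn.id == objective:
            obj[j] = 1.0
        if rxn.id == reaction:
            target[j] = 1.0
    b_eq = np.zeros(len(metabolites))
    if fraction > 0:
        opt = oracle_optimum(model, objective)
        A_ub, b_ub = -obj[None, :], np.array([-(fraction * opt) + 1e-9])
    else:
        A_ub, b_ub = None, None
    out = []
    for sign in (1.0, -1.0):
        res = linprog(sign * target, A_eq=S, b_eq=b_eq, A_ub=A_ub, b_ub=b_ub,
                      bounds=bounds, method="highs")
        assert res.status == 0
        out.append(sign * res.fun)
    return out[0], out[1]


@pytest.fixture
def toy():
    return toy_model()


@pytest.fixture
def toy_fa():
    return toy_model(ToyModelSpec(with_fa_source=True))


@pytest.fixture
def toy_parallel():
    return toy_model(ToyModelSpec(parallel_glucose_transporters=True))


@pytest.fixture
def toy_loop():
    return toy_model(ToyModelSpec(with_loop=True))
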