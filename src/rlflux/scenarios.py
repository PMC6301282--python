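"""Simulation experiments: carbon-source scans, uptake sweeps, mixed
substrates, pathway attribution, and two-model comparison.

All production fluxes are computed with geometric FBA so that every number
is the unique central representative of the optimal flux polytope, and
repeated runs are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import cobra
import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .fba import FluxSolution, geometric_fba
from .model_io import MediumSpec, resolve_source, set_medium, set_objective

__all__ = [
    "PathwaySets",
    "carbon_source_scan",
    "uptake_sweep",
    "LinearityDiagnostic",
    "mixed_substrate",
    "pathway_attribution",
    "compare_models",
]

#: Reference uptake rate (mmol/gDW/h) of the control growth condition.
CONTROL_RATE = 10.0


@dataclass
class PathwaySets:
    """Named, disjoint sets of reaction ids (e.g. rhamnose vs fatty-acid
    route)."""

    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for name, rids in self.sets.items():
            for rid in rids:
                if rid in seen:
                    raise ConfigurationError(
                        f"reaction {rid!r} appears in both {seen[rid]!r} "
                        f"and {name!r}"
                    )
                seen[rid] = name

    def validate_against(self, model: cobra.Model) -> None:
        unknown = [
            rid for rids in self.sets.values() for rid in rids
            if not model.reactions.has_id(rid)
        ]
        if unknown:
            raise ConfigurationError(f"unknown reactions in pathway sets: {unknown}")


def _resolves(model: cobra.Model, source: str) -> bool:
    try:
        resolve_source(model, source)
        return True
    except ConfigurationError:
        return False


def _single_source_medium(model: cobra.Model, source: str, rate: float,
                          all_sources: list[str]) -> MediumSpec:
    closed = [s for s in all_sources if s != source]
    return MediumSpec(uptakes={source: rate}, closed_sources=closed)


def carbon_source_scan(
    model: cobra.Model,
    sources: list[str],
    rate: float = CONTROL_RATE,
    objective: str | None = None,
    tolerance: float = 1e-6,
) -> pd.DataFrame:
    """Production flux per single carbon source at a fixed uptake rate.

    For each source, a single-source medium is built (the source at *rate*,
    every other listed source closed), geometric FBA is run, and the
    production flux (objective value) recorded.  Returns a tidy frame with
    columns ``source, rate, objective, flux`` plus a ``solution`` column
    holding the :class:`~rlflux.fba.FluxSolution` handles.
    """
    if objective is not None:
        set_objective(model, objective)
    objective_id = _objective_id(model)
    for s in sources:
        resolve_source(model, s)  # fail fast on unknown names
    rows = []
    for source in sources:
        set_medium(model, _single_source_medium(model, source, rate, sources))
        sol = geometric_fba(model, tolerance=tolerance)
        rows.append(
            {
                "source": source,
                "rate": rate,
                "objective": objective_id,
                "flux": sol.objective_value,
                "solution": sol,
            }
        )
    return pd.DataFrame(rows, columns=["source", "rate", "objective", "flux",
                                       "solution"])


def _objective_id(model: cobra.Model) -> str:
    ids = [r.id for r in model.reactions if r.objective_coefficient]
    return ids[0] if ids else ""


@dataclass
class LinearityDiagnostic:
    """Slope and worst relative deviation of production vs uptake rate."""

    slope: float
    max_relative_deviation: float


def uptake_sweep(
    model: cobra.Model,
    source: str,
    rates: list[float],
    objective: str | None = None,
    tolerance: float = 1e-6,
) -> tuple[pd.DataFrame, LinearityDiagnostic]:
    """Production flux across uptake rates of one source, with a linearity
    diagnostic.

    The slope is fitted through the origin (production is zero at zero
    uptake for a production objective); the diagnostic reports the maximal
    relative deviation of production from ``slope * rate``.
    """
    if any(r < 0 for r in rates):
        raise ConfigurationError("uptake rates must be >= 0")
    if objective is not None:
        set_objective(model, objective)
    objective_id = _objective_id(model)
    rows = []
    for rate in rates:
        medium = (
            MediumSpec(uptakes={source: rate})
            if rate > 0
            else MediumSpec(closed_sources=[source])
        )
        set_medium(model, medium)
        sol = geometric_fba(model, tolerance=tolerance)
        rows.append({"source": source, "rate": rate, "objective": objective_id,
                     "flux": sol.objective_value, "solution": sol})
    table = pd.DataFrame(rows)
    rates_arr = table["rate"].to_numpy(dtype=float)
    flux_arr = table["flux"].to_numpy(dtype=float)
    nz = rates_arr > 0
    if nz.any():
        slope = float(np.sum(flux_arr[nz] * rates_arr[nz])
                      / np.sum(rates_arr[nz] ** 2))
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.abs(flux_arr[nz] - slope * rates_arr[nz]) / np.maximum(
                np.abs(slope * rates_arr[nz]), 1e-300
            )
        deviation = float(rel.max()) if slope != 0 else float(
            np.abs(flux_arr[nz]).max()
        )
    else:
        slope, deviation = 0.0, 0.0
    return table, LinearityDiagnostic(slope=slope,
                                      max_relative_deviation=deviation)


def mixed_substrate(
    model: cobra.Model,
    uptakes: MediumSpec,
    objective: str | None = None,
    tolerance: float = 1e-6,
) -> FluxSolution:
    """Geometric FBA under a combined medium of simultaneous uptakes."""
    if objective is not None:
        set_objective(model, objective)
    set_medium(model, uptakes)
    return geometric_fba(model, tolerance=tolerance)


def pathway_attribution(
    model: cobra.Model,
    solution: FluxSolution,
    sets: PathwaySets,
    reporter: str,
    pools: dict[str, str] | None = None,
) -> dict[str, float]:
    """Share of precursor supply carried by each pathway set.

    For every named set, the precursor pool it serves is identified (by
    default: the substrates of *reporter*, or an explicit ``pool name ->
    metabolite id`` map) and the share is the set's flux-weighted production
    of (or, for purely consuming sets, draw on) that pool divided by the
    pool's total turnover on the same side.  Shares of sets feeding the same
    pool therefore sum to <= 1, with any residual unattributed.
    """
    if not sets.sets:
        return {}
    sets.validate_against(model)
    if solution.fluxes is None:
        raise InputError("attribution requires an optimal solution")
    rep = model.reactions.get_by_id(reporter)
    rep_flux = solution.fluxes[reporter]
    if abs(rep_flux) <= 1e-12:
        raise InputError(
            f"reporter {reporter!r} carries no flux; attribution undefined"
        )
    if pools:
        pool_mets = [model.metabolites.get_by_id(mid) for mid in pools.values()]
    else:
        pool_mets = [m for m, c in rep.metabolites.items() if c < 0]

    def turnover(met, producing: bool) -> tuple[float, dict[str, float]]:
        total = 0.0
        per_rxn: dict[str, float] = {}
        for rxn in met.reactions:
            if rxn.id == reporter and producing is False:
                continue  # the reporter's own draw is the demand, not supply
            coeff = rxn.metabolites[met]
            rate = coeff * solution.fluxes[rxn.id]
            side = rate if producing else -rate
            if side > 1e-12:
                per_rxn[rxn.id] = side
                total += side
        return total, per_rxn

    shares: dict[str, float] = {}
    for name, rids in sets.sets.items():
        rid_set = set(rids)
        share = 0.0
        for met in pool_mets:
            # A set is credited on the side it actually serves: its share of
            # the pool's production if it produces the pool metabolite, else
            # its share of the draw if it only consumes it.
            for producing in (True, False):
                total, per_rxn = turnover(met, producing)
                contribution = sum(v for r, v in per_rxn.items() if r in rid_set)
                if contribution > 1e-12 and total > 0:
                    share = max(share, contribution / total)
                    break
        shares[name] = share
    return shares


def compare_models(
    model_a: cobra.Model,
    model_b: cobra.Model,
    sources: list[str],
    rate: float = CONTROL_RATE,
    objective_a: str | None = None,
    objective_b: str | None = None,
    labels: tuple[str, str] = ("model_a", "model_b"),
) -> pd.DataFrame:
    """Production per carbon source for two engineered models, aligned by
    source.

    A source that fails in one model (e.g. no transport for it) yields NaN
    flux and an error message in that model's status column; the other
    model's column is still filled.
    """
    frames = {}
    for model, objective, label in (
        (model_a, objective_a, labels[0]),
        (model_b, objective_b, labels[1]),
    ):
        flux: dict[str, float] = {}
        status: dict[str, str] = {}
        # Close every listed source this model knows about, so each scan row
        # is a genuine single-source medium even when the other model lacks
        # some of the transports.
        known = [s for s in sources
                 if _resolves(model, s)]
        for source in sources:
            try:
                if objective is not None:
                    set_objective(model, objective)
                set_medium(model, _single_source_medium(model, source, rate,
                                                        known))
                sol = geometric_fba(model)
                flux[source] = sol.objective_value
                status[source] = "ok"
            except Exception as exc:
                flux[source] = float("nan")
                status[source] = str(exc)
        frames[f"flux_{label}"] = flux
        frames[f"status_{label}"] = status
    table = pd.DataFrame(frames)
    table.index.name = "source"
    return table.reindex(sources)
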