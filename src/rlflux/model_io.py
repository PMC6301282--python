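"""Reading, writing and configuring constraint-based metabolic models.

Models are held in memory as :class:`cobra.Model` objects, the standard
container for constraint-based models in Python.  Three serializations are
supported:

``sbml``
    SBML Level 3 with the FBC extension, via :mod:`cobra.io`.
``json``
    The COBRApy JSON schema, via :mod:`cobra.io`.
``tabular``
    Two tab-separated files (``metabolites.tsv``, ``reactions.tsv``) inside a
    directory, chosen so toy fixtures are diffable in code review.  The
    reaction stoichiometry is encoded as ``met_id:coeff`` pairs joined by
    ``;`` with negative coefficients for substrates.

Flux sign convention: uptake through an exchange reaction is a *negative*
flux, so a medium uptake rate ``r`` (mmol/gDW/h) maps to a lower bound of
``-r`` on the exchange.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import cobra
import cobra.io
import pandas as pd

from .errors import ConfigurationError, ModelParseError

__all__ = [
    "MediumSpec",
    "read_model",
    "write_model",
    "set_medium",
    "set_objective",
    "read_medium_tsv",
    "resolve_source",
    "validate_model",
    "stoichiometric_matrix",
]

#: Sentinel bound used for "effectively unconstrained" reactions.
DEFAULT_BOUND = 1000.0

_MET_COLUMNS = ["id", "name", "compartment", "formula", "charge"]
_RXN_COLUMNS = [
    "id",
    "name",
    "stoichiometry",
    "lower_bound",
    "upper_bound",
    "gpr",
    "subsystem",
    "objective_coefficient",
]


@dataclass
class MediumSpec:
    """A growth-medium specification.

    Parameters
    ----------
    uptakes
        Map from carbon-source name (exchange reaction id, ``EX_<source>``
        shorthand, or extracellular metabolite id/name) to a non-negative
        uptake rate in mmol/gDW/h.
    closed_sources
        Sources whose uptake is forced to zero (secretion stays open).
    """

    uptakes: Mapping[str, float] = field(default_factory=dict)
    closed_sources: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, rate in self.uptakes.items():
            if rate < 0:
                raise ConfigurationError(
                    f"uptake rate for {name!r} must be >= 0, got {rate}"
                )


def resolve_source(model: cobra.Model, source: str) -> cobra.Reaction:
    """Resolve a carbon-source name to an exchange reaction of *model*.

    Resolution order: exact reaction id, ``EX_<source>``, ``EX_<source>_e``,
    then an exchange whose single metabolite has matching id or
    (case-insensitive) name.
    """
    for rid in (source, f"EX_{source}", f"EX_{source}_e"):
        if model.reactions.has_id(rid):
            rxn = model.reactions.get_by_id(rid)
            if rxn.boundary:
                return rxn
    lowered = source.lower()
    for rxn in model.reactions:
        if not rxn.boundary:
            continue
        met = next(iter(rxn.metabolites))
        if met.id == source or (met.name or "").lower() == lowered:
            return rxn
    raise ConfigurationError(
        f"carbon source {source!r} does not resolve to an exchange reaction"
    )


def set_medium(model: cobra.Model, medium: MediumSpec) -> cobra.Model:
    """Configure uptake bounds of *model* in place according to *medium*.

    Each named source's exchange gets ``lower_bound = -rate``; each closed
    source gets ``lower_bound = 0``.  Exchanges not named are untouched, so
    non-carbon components (O2, NH4, Pi, ...) keep the model's defaults.
    Idempotent: applying the same spec twice equals applying it once.
    """
    # Resolve everything first so an unknown name leaves the model untouched.
    opened = [(resolve_source(model, s), r) for s, r in medium.uptakes.items()]
    closed = [resolve_source(model, s) for s in medium.closed_sources]
    for rxn, rate in opened:
        rxn.lower_bound = -float(rate)
    for rxn in closed:
        rxn.lower_bound = 0.0
    return model


def set_objective(model: cobra.Model, reaction_id: str) -> cobra.Model:
    """Set the objective vector *c* to the indicator of *reaction_id*."""
    if not model.reactions.has_id(reaction_id):
        raise ConfigurationError(f"unknown objective reaction {reaction_id!r}")
    model.objective = reaction_id
    return model


def read_medium_tsv(path: str | os.PathLike) -> MediumSpec:
    """Read a ``source<TAB>rate`` file; a rate of 0 closes the source."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["source", "rate"])
    uptakes: dict[str, float] = {}
    closed: list[str] = []
    for _, row in df.iterrows():
        rate = float(row["rate"])
        if rate == 0.0:
            closed.append(str(row["source"]))
        else:
            uptakes[str(row["source"])] = rate
    return MediumSpec(uptakes=uptakes, closed_sources=closed)


def validate_model(model: cobra.Model) -> None:
    """Check structural invariants; raise :class:`ModelParseError` on failure."""
    seen: set[str] = set()
    for met in model.metabolites:
        if met.id in seen:
            raise ModelParseError(f"duplicate metabolite id {met.id!r}")
        seen.add(met.id)
        if not met.compartment:
            raise ModelParseError(f"metabolite {met.id!r} has no compartment")
    seen.clear()
    for rxn in model.reactions:
        if rxn.id in seen:
            raise ModelParseError(f"duplicate reaction id {rxn.id!r}")
        seen.add(rxn.id)
        if rxn.lower_bound > rxn.upper_bound:
            raise ModelParseError(
                f"reaction {rxn.id!r} has inverted bounds "
                f"({rxn.lower_bound} > {rxn.upper_bound})"
            )
        if rxn.boundary and len(rxn.metabolites) != 1:
            raise ModelParseError(
                f"boundary reaction {rxn.id!r} must touch exactly one metabolite"
            )


def stoichiometric_matrix(model: cobra.Model) -> pd.DataFrame:
    """Dense stoichiometric matrix S (metabolites x reactions)."""
    from cobra.util.array import create_stoichiometric_matrix

    arr = create_stoichiometric_matrix(model)
    return pd.DataFrame(
        arr,
        index=[m.id for m in model.metabolites],
        columns=[r.id for r in model.reactions],
    )


def _encode_stoichiometry(rxn: cobra.Reaction) -> str:
    parts = [
        f"{met.id}:{coeff!r}"
        for met, coeff in sorted(rxn.metabolites.items(), key=lambda kv: kv[0].id)
    ]
    return ";".join(parts)


def _decode_stoichiometry(text: str, rxn_id: str) -> dict[str, float]:
    stoich: dict[str, float] = {}
    if not text:
        return stoich
    for part in text.split(";"):
        try:
            met_id, coeff = part.rsplit(":", 1)
            stoich[met_id] = float(coeff)
        except ValueError as exc:
            raise ModelParseError(
                f"reaction {rxn_id!r}: malformed stoichiometry term {part!r}"
            ) from exc
    return stoich


def write_model(model: cobra.Model, path: str | os.PathLike,
                format: str = "sbml") -> None:
    """Serialize *model* to *path* in the named dialect.

    For ``tabular``, *path* is a directory that will contain
    ``metabolites.tsv`` and ``reactions.tsv``.
    """
    validate_model(model)
    if format == "sbml":
        cobra.io.write_sbml_model(model, str(path))
    elif format == "json":
        cobra.io.save_json_model(model, str(path))
    elif format == "tabular":
        os.makedirs(path, exist_ok=True)
        mets = pd.DataFrame(
            [
                {
                    "id": m.id,
                    "name": m.name or "",
                    "compartment": m.compartment,
                    "formula": m.formula or "",
                    "charge": "" if m.charge is None else int(m.charge),
                }
                for m in model.metabolites
            ],
            columns=_MET_COLUMNS,
        )
        rxns = pd.DataFrame(
            [
                {
                    "id": r.id,
                    "name": r.name or "",
                    "stoichiometry": _encode_stoichiometry(r),
                    "lower_bound": repr(float(r.lower_bound)),
                    "upper_bound": repr(float(r.upper_bound)),
                    "gpr": r.gene_reaction_rule or "",
                    "subsystem": r.subsystem or "",
                    "objective_coefficient": repr(float(r.objective_coefficient)),
                }
                for r in model.reactions
            ],
            columns=_RXN_COLUMNS,
        )
        mets.to_csv(os.path.join(path, "metabolites.tsv"), sep="\t", index=False)
        rxns.to_csv(os.path.join(path, "reactions.tsv"), sep="\t", index=False)
    else:
        raise ConfigurationError(f"unknown model format {format!r}")


def _read_tabular(path: str | os.PathLike) -> cobra.Model:
    met_path = os.path.join(path, "metabolites.tsv")
    rxn_path = os.path.join(path, "reactions.tsv")
    for p in (met_path, rxn_path):
        if not os.path.exists(p):
            raise FileNotFoundError(p)
    mets = pd.read_csv(met_path, sep="\t", dtype=str).fillna("")
    rxns = pd.read_csv(rxn_path, sep="\t", dtype=str).fillna("")
    model = cobra.Model(os.path.basename(os.path.normpath(path)))
    metabolites = []
    for _, row in mets.iterrows():
        met = cobra.Metabolite(
            row["id"],
            name=row["name"],
            compartment=row["compartment"],
            formula=row["formula"] or None,
        )
        if row["charge"]:
            met.charge = int(float(row["charge"]))
        metabolites.append(met)
    model.add_metabolites(metabolites)
    objective: dict[str, float] = {}
    reactions = []
    for _, row in rxns.iterrows():
        lower, upper = float(row["lower_bound"]), float(row["upper_bound"])
        if lower > upper:
            raise ModelParseError(
                f"reaction {row['id']!r} has inverted bounds ({lower} > {upper})"
            )
        rxn = cobra.Reaction(
            row["id"], name=row["name"], lower_bound=lower, upper_bound=upper
        )
        reactions.append(rxn)
        coeff = float(row["objective_coefficient"] or 0.0)
        if coeff:
            objective[row["id"]] = coeff
    model.add_reactions(reactions)
    for rxn, (_, row) in zip(reactions, rxns.iterrows()):
        stoich = _decode_stoichiometry(row["stoichiometry"], row["id"])
        for met_id in stoich:
            if not model.metabolites.has_id(met_id):
                raise ModelParseError(
                    f"reaction {row['id']!r} references unknown metabolite {met_id!r}"
                )
        rxn.add_metabolites(
            {model.metabolites.get_by_id(k): v for k, v in stoich.items()}
        )
        if row["gpr"]:
            rxn.gene_reaction_rule = row["gpr"]
        if row["subsystem"]:
            rxn.subsystem = row["subsystem"]
    if objective:
        model.objective = {
            model.reactions.get_by_id(k): v for k, v in objective.items()
        }
    return model


def read_model(path: str | os.PathLike, format: str = "sbml") -> cobra.Model:
    """Read a model from *path* and validate its structural invariants."""
    if format == "tabular":
        model = _read_tabular(path)
    else:
        if not os.path.exists(path):
            raise FileNotFoundError(path)
        if format == "sbml":
            model = cobra.io.read_sbml_model(str(path))
        elif format == "json":
            model = cobra.io.load_json_model(str(path))
        else:
            raise ConfigurationError(f"unknown model format {format!r}")
    validate_model(model)
    return model
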