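"""Grafting the rhamnolipid biosynthesis pathway onto a host model.

The rhamnosyltransferase chain is installed as five irreversible core
reactions -- RHLA (acyl transfer from the carrier protein to CoA), PHAC and
3H3H (the poly(3-hydroxyalkanoic acid) synthase steps dimerizing
3-hydroxydecanoyl units into HAA), RHLB (first rhamnosylation, yielding
mono-rhamnolipid) and RHLC (second rhamnosylation, yielding
di-rhamnolipid) -- plus a transport step exporting mono-rhamnolipid across
the membrane and the matching exchange.  The stoichiometries are kept as
curated in the source reconstruction, including its known quirks (PHAC's
doubling coefficient and RHLB's spurious proton), which the mass-balance
checker reports honestly rather than silently rebalancing.

Curation checks mirror standard reconstruction practice: elemental/charge
balance per reaction, and flux-variability screening to confirm each added
reaction can carry flux under the engineered medium.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import cobra
import numpy as np
import pandas as pd

from .errors import EngineeringError, SolverError
from .fba import fva

__all__ = [
    "ReactionSpec",
    "rhamnolipid_reaction_set",
    "engineer_model",
    "check_mass_balance",
    "MassBalanceReport",
    "check_flux_carrying",
    "read_reaction_specs",
    "METABOLITE_TABLE",
]

#: Mapping from curated metabolite names to stable ids with compartment
#: suffix.  Ships with the package so reaction specs can be written with
#: readable names.
METABOLITE_TABLE: dict[str, str] = {
    "(3R)-3-Hydroxydecanoyl-acyl-carrier protein": "hdacp_c",
    "Coenzyme A": "coa_c",
    "(S)-3-Hydroxydecanoyl-CoA": "hdcoa_c",
    "acyl carrier protein": "acp_c",
    "beta-hydroxydecanoyl-beta-hydroxydecanoyl-S-CoA": "hddcoa_c",
    "3-hydroxydecanoyl-3-hydroxydecanoate": "haa_c",
    "dTDP-4-dehydro-6-deoxy-L-mannose": "ddm_c",
    "dTDP": "dtdp_c",
    "H+": "h_c",
    "H2O": "h2o_c",
    "L-rhamnosyl-3-hydroxydecanoyl-3-hydroxydecanoate": "rhl_c",
    "L-rhamnosyl-Lrhamnosyl-3-hydroxydecanoyl-3-hydroxydecanoate": "rhl2_c",
    "mono-rhamnolipid (extracellular)": "rhl_e",
    "di-rhamnolipid (extracellular)": "rhl2_e",
}

_UBIQUITOUS = {"h_c", "h_e", "h2o_c", "h2o_e"}

DEFAULT_BOUND = 1000.0


@dataclass
class ReactionSpec:
    """One reaction to graft: code, stoichiometry over metabolite ids,
    reversibility, and role (core / transport / exchange)."""

    code: str
    stoichiometry: dict[str, float]
    reversible: bool = False
    role: str = "core"
    name: str = ""

    @property
    def lower_bound(self) -> float:
        return -DEFAULT_BOUND if self.reversible else 0.0

    @property
    def upper_bound(self) -> float:
        return DEFAULT_BOUND


def rhamnolipid_reaction_set(
    include_di_rhamnolipid: bool = False,
) -> list[ReactionSpec]:
    """The curated rhamnolipid graft: five irreversible core reactions plus
    mono-rhamnolipid transport and exchange.

    With ``include_di_rhamnolipid=True`` a di-rhamnolipid transport/exchange
    pair is appended, giving RHLC a sink; by default the pipeline centres on
    the RhlA/RhlB mono-rhamnolipid product.
    """
    specs = [
        ReactionSpec(
            "RHLA",
            {"hdacp_c": -1, "coa_c": -1, "hdcoa_c": 1, "acp_c": 1},
            name="rhamnosyltransferase chain A",
        ),
        ReactionSpec(
            "RHLB",
            {"haa_c": -1, "ddm_c": -1, "h_c": -1, "dtdp_c": 1, "rhl_c": 1},
            name="rhamnosyltransferase chain B",
        ),
        ReactionSpec(
            "RHLC",
            {"ddm_c": -1, "h_c": -1, "rhl_c": -1, "dtdp_c": 1, "rhl2_c": 1},
            name="rhamnosyltransferase 2",
        ),
        ReactionSpec(
            "3H3H",
            {"hddcoa_c": -2, "h2o_c": -1, "haa_c": 1, "coa_c": 1},
            name="poly(3-hydroxyalkanoate) synthase (hydrolysis step)",
        ),
        ReactionSpec(
            "PHAC",
            {"hdcoa_c": -1, "hddcoa_c": 2, "coa_c": 1},
            name="poly(3-hydroxyalkanoate) synthase (condensation step)",
        ),
        ReactionSpec(
            "RHLtpp",
            {"rhl_c": -1, "rhl_e": 1},
            role="transport",
            name="mono-rhamnolipid export",
        ),
        ReactionSpec(
            "EX_rhl",
            {"rhl_e": -1},
            role="exchange",
            name="mono-rhamnolipid exchange",
        ),
    ]
    if include_di_rhamnolipid:
        specs += [
            ReactionSpec("RHL2tpp", {"rhl2_c": -1, "rhl2_e": 1},
                         role="transport", name="di-rhamnolipid export"),
            ReactionSpec("EX_rhl2", {"rhl2_e": -1}, role="exchange",
                         name="di-rhamnolipid exchange"),
        ]
    return specs


def core_specs(specs: list[ReactionSpec]) -> list[ReactionSpec]:
    return [s for s in specs if s.role == "core"]


def _compartment_of(met_id: str) -> str:
    return met_id.rsplit("_", 1)[-1] if "_" in met_id else "c"


def engineer_model(
    model: cobra.Model, specs: list[ReactionSpec]
) -> cobra.Model:
    """Add one reaction per spec to *model* in place.

    Metabolites absent from the host are created (without formulas, so the
    mass-balance checker reports the affected reactions as unchecked rather
    than guessing compositions).  The objective is untouched.  On any
    collision nothing is applied.
    """
    clashes = [s.code for s in specs if model.reactions.has_id(s.code)]
    if clashes:
        raise EngineeringError(
            f"reaction ids already present in the host: {clashes}"
        )
    seen: set[str] = set()
    for s in specs:
        if s.code in seen:
            raise EngineeringError(f"duplicate spec code {s.code!r}")
        seen.add(s.code)
        if s.role == "exchange" and len(s.stoichiometry) != 1:
            raise EngineeringError(
                f"exchange spec {s.code!r} must touch exactly one metabolite"
            )
    new_mets = []
    met_ids = {m.id for m in model.metabolites}
    for s in specs:
        for met_id in s.stoichiometry:
            if met_id not in met_ids:
                met_ids.add(met_id)
                new_mets.append(
                    cobra.Metabolite(met_id, compartment=_compartment_of(met_id))
                )
    if new_mets:
        model.add_metabolites(new_mets)
    for s in specs:
        rxn = cobra.Reaction(s.code, name=s.name or s.code,
                             lower_bound=s.lower_bound,
                             upper_bound=s.upper_bound)
        model.add_reactions([rxn])
        rxn.add_metabolites(
            {model.metabolites.get_by_id(k): v for k, v in s.stoichiometry.items()}
        )
    return model


_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def _parse_formula(formula: str) -> dict[str, int] | None:
    if not formula:
        return None
    elements: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_RE.finditer(formula):
        if match.start() != pos:
            return None
        pos = match.end()
        element, count = match.group(1), match.group(2)
        elements[element] = elements.get(element, 0) + (int(count) if count else 1)
    if pos != len(formula):
        return None
    return elements


@dataclass
class MassBalanceReport:
    """Outcome of the elemental/charge curation check."""

    imbalanced: dict[str, dict[str, float]] = field(default_factory=dict)
    unchecked: list[str] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not self.imbalanced and not self.unchecked


def check_mass_balance(model: cobra.Model, tolerance: float = 1e-6
                       ) -> MassBalanceReport:
    """Element (and, where annotated, charge) balance for every non-boundary
    reaction whose metabolites all carry formulas.

    Boundary (exchange/sink) reactions are exempt by definition: they are
    the reactions allowed to carry a steady-state imbalance.  Reactions
    touching any formula-less metabolite are listed as unchecked.
    """
    report = MassBalanceReport()
    for rxn in model.reactions:
        if rxn.boundary:
            continue
        totals: dict[str, float] = {}
        parsed_all = True
        have_all_charges = True
        charge_total = 0.0
        for met, coeff in rxn.metabolites.items():
            elements = _parse_formula(met.formula or "")
            if elements is None:
                parsed_all = False
                break
            for element, count in elements.items():
                totals[element] = totals.get(element, 0.0) + coeff * count
            if met.charge is None:
                have_all_charges = False
            else:
                charge_total += coeff * met.charge
        if not parsed_all:
            report.unchecked.append(rxn.id)
            continue
        imbalance = {e: t for e, t in totals.items() if abs(t) > tolerance}
        if have_all_charges and abs(charge_total) > tolerance:
            imbalance["charge"] = charge_total
        if imbalance:
            report.imbalanced[rxn.id] = imbalance
    return report


def check_flux_carrying(
    model: cobra.Model,
    reactions: list[str],
    tolerance: float = 1e-6,
    exclude_ubiquitous: bool = True,
) -> list[str]:
    """Return the subset of *reactions* that cannot carry flux.

    Runs flux variability at zero objective fraction (i.e. over the whole
    feasible polytope) and flags reactions whose maximal absolute flux stays
    below *tolerance*.  Transport/exchange steps for ubiquitous species
    (protons, water) are excluded from the report by default.
    """
    if exclude_ubiquitous:
        reactions = [
            rid for rid in reactions
            if not all(
                m.id in _UBIQUITOUS
                for m in model.reactions.get_by_id(rid).metabolites
            )
        ]
    try:
        ranges = fva(model, fraction_of_optimum=0.0, reactions=reactions)
    except SolverError as exc:
        raise SolverError(f"flux-carrying check failed: {exc}") from exc
    blocked = ranges[
        np.maximum(ranges["minimum"].abs(), ranges["maximum"].abs()) < tolerance
    ]
    return list(blocked.index)


def read_reaction_specs(path) -> list[ReactionSpec]:
    """Load reaction specs from a TSV with columns
    ``code  formula  reversibility  role``.

    The formula uses metabolite names (resolved through
    :data:`METABOLITE_TABLE`) or raw ids, e.g.
    ``2 hddcoa_c + H2O => haa_c + Coenzyme A``.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    specs = []
    for _, row in df.iterrows():
        specs.append(
            ReactionSpec(
                code=str(row["code"]),
                stoichiometry=_parse_equation(str(row["formula"])),
                reversible=str(row["reversibility"]).strip().lower()
                in ("reversible", "true", "yes"),
                role=str(row.get("role", "core")),
            )
        )
    return specs


def _parse_equation(text: str) -> dict[str, float]:
    if "<=>" in text:
        lhs, rhs = text.split("<=>")
    elif "=>" in text:
        lhs, rhs = text.split("=>")
    else:
        raise EngineeringError(f"no arrow in reaction formula {text!r}")
    stoich: dict[str, float] = {}
    for side, sign in ((lhs, -1.0), (rhs, 1.0)):
        for term in side.split(" + "):
            term = term.strip()
            if not term:
                continue
            match = re.match(r"^(\d+(?:\.\d+)?)\s+(.*)$", term)
            if match:
                coeff, name = float(match.group(1)), match.group(2).strip()
            else:
                coeff, name = 1.0, term
            met_id = METABOLITE_TABLE.get(name, name)
            stoich[met_id] = stoich.get(met_id, 0.0) + sign * coeff
    return stoich
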