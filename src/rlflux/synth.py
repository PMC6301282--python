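"""Synthetic inputs: a toy metabolic network and two-group expression matrices.

The toy network mirrors the structure of an engineered *Pseudomonas*
metabolism at the smallest scale on which every pipeline stage is exercised:
a glycolysis-like trunk from glucose, a rhamnose branch producing the
activated sugar donor, a fatty-acid branch producing the acyl-carrier-bound
lipid precursor, RhlA/RhlB-style condensation steps converging on a
mono-rhamnolipid sink, a biomass drain, and optionally a direct fatty-acid
feed and an isolated thermodynamically infeasible 3-cycle.

Every toy reaction is elementally balanced (the phosphoryl group of the
hexose-phosphate pool and the acyl-carrier protein are bookkept as implicit
or pseudo-element ``X`` species), so the curation checks pass with an empty
report by construction.

Closed-form optima used as oracles throughout the test-suite (derived by
hand from the stoichiometry and cross-checked by an independent LP solver):

* glucose at 10 mmol/gDW/h, rhamnolipid objective: each rhamnolipid costs
  one hexose-P through the rhamnose branch plus five through glycolysis and
  fatty-acid synthesis (10 acetyl-CoA -> 2 acyl units), hence 10/6.
* fatty acid alone: 0 (no route to the dTDP-sugar donor).
* glucose 10 + fatty acid 10: the fatty-acid feed supplies acyl units
  directly, so with x hexose-P routed to the rhamnose branch the lipid
  supply is 5 + (10 - x)/5 dimers; equating gives x = 35/6.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import cobra
import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .omics import ExpressionMatrix

__all__ = [
    "ToyModelSpec",
    "SyntheticTruth",
    "toy_model",
    "synth_expression",
    "null_flux_matrix",
    "TOY_PATHWAY_SETS",
]

#: Default objective reaction of the toy model.
TOY_OBJECTIVE = "EX_rhl_e"

#: Curated pathway sets for the toy network (rhamnose branch, de-novo
#: fatty-acid branch, and the external fatty-acid feed).
TOY_PATHWAY_SETS = {
    "rhamnose_pathway": ["PGM", "RMLS"],
    "fatty_acid_pathway": ["GLYC", "FAS", "HAAS"],
    "fatty_acid_uptake": ["FAT"],
}


@dataclass
class ToyModelSpec:
    """Options for :func:`toy_model`.

    Parameters
    ----------
    with_loop
        Add an isolated reversible 3-reaction cycle (bounds +/-1000) that can
        carry arbitrary circular flux without affecting the optimum.
    with_fa_source
        Add a fatty-acid exchange/uptake feeding the acyl-carrier pool
        directly (closed by default; opened via the medium).
    binding_bound_on
        Optional reaction id whose upper bound is tightened to 80% of its
        flux at the unconstrained optimum, so that expression-scaled bounds
        are phenotypically visible.
    parallel_glucose_transporters
        Duplicate the glucose transporter (``GLCT2``), creating a symmetric
        degree of freedom in the optimal flux polytope.
    """

    with_loop: bool = False
    with_fa_source: bool = False
    binding_bound_on: str | None = None
    parallel_glucose_transporters: bool = False


@dataclass
class SyntheticTruth:
    """Ground truth of a planted two-group expression experiment."""

    planted_genes: list[str]
    delta: float
    sigma: float
    wiring: dict[str, str]
    seed: int


def _met(mid: str, name: str, compartment: str, formula: str) -> cobra.Metabolite:
    return cobra.Metabolite(mid, name=name, compartment=compartment,
                            formula=formula)


def _rxn(model: cobra.Model, rid: str, name: str, stoich: dict[str, float],
         lb: float, ub: float, gpr: str = "", subsystem: str = "") -> cobra.Reaction:
    rxn = cobra.Reaction(rid, name=name, lower_bound=lb, upper_bound=ub)
    model.add_reactions([rxn])
    rxn.add_metabolites(
        {model.metabolites.get_by_id(k): v for k, v in stoich.items()}
    )
    if gpr:
        rxn.gene_reaction_rule = gpr
    if subsystem:
        rxn.subsystem = subsystem
    return rxn


def toy_model(spec: ToyModelSpec | None = None) -> cobra.Model:
    """Build the deterministic toy network described in the module docstring.

    The default medium opens glucose at 10 mmol/gDW/h; the objective is the
    mono-rhamnolipid exchange.
    """
    spec = spec or ToyModelSpec()
    model = cobra.Model("toy_rhamnolipid")
    B = 1000.0

    mets = [
        _met("glc__D_e", "glucose", "e", "C6H12O6"),
        _met("g6p_c", "hexose 6-phosphate pool (phosphoryl implicit)", "c", "C6H12O6"),
        _met("g1p_c", "hexose 1-phosphate pool (phosphoryl implicit)", "c", "C6H12O6"),
        _met("ddm_c", "dTDP-4-dehydro-6-deoxy-L-mannose", "c", "C16H24N2O15P2"),
        _met("dtdp_c", "dTDP", "c", "C10H16N2O11P2"),
        _met("accoa_c", "acetyl-CoA", "c", "C23H38N7O17P3S"),
        _met("coa_c", "Coenzyme A", "c", "C21H36N7O16P3S"),
        _met("acp_c", "acyl carrier protein", "c", "HX"),
        _met("hdacp_c", "(3R)-3-Hydroxydecanoyl-acyl-carrier protein", "c",
             "C10H19O2X"),
        _met("haa_c", "3-hydroxydecanoyl-3-hydroxydecanoate", "c", "C20H38O5"),
        _met("rhl_c", "mono-rhamnolipid", "c", "C26H46O9"),
        _met("rhl_e", "mono-rhamnolipid (extracellular)", "e", "C26H46O9"),
        _met("co2_c", "CO2", "c", "CO2"),
        _met("co2_e", "CO2 (extracellular)", "e", "CO2"),
        _met("h2_c", "reducing equivalent", "c", "H2"),
        _met("h2o_c", "H2O", "c", "H2O"),
        _met("h2o_e", "H2O (extracellular)", "e", "H2O"),
        _met("h_c", "H+", "c", "H"),
        _met("h_e", "H+ (extracellular)", "e", "H"),
        _met("biomass_c", "biomass", "c", "C10H16O8"),
    ]
    if spec.with_fa_source:
        mets.append(_met("fa_e", "fatty acid", "e", "C10H20O3"))
    if spec.with_loop:
        mets += [
            _met("loop1_c", "loop metabolite 1", "c", "C5H10O5"),
            _met("loop2_c", "loop metabolite 2", "c", "C5H10O5"),
            _met("loop3_c", "loop metabolite 3", "c", "C5H10O5"),
        ]
    model.add_metabolites(mets)

    _rxn(model, "EX_glc__D_e", "glucose exchange", {"glc__D_e": -1}, -10.0, B)
    _rxn(model, "GLCT", "glucose transport/phosphorylation",
         {"glc__D_e": -1, "g6p_c": 1}, 0, B, gpr="g_glct", subsystem="transport")
    if spec.parallel_glucose_transporters:
        _rxn(model, "GLCT2", "glucose transport/phosphorylation (isoform)",
             {"glc__D_e": -1, "g6p_c": 1}, 0, B, gpr="g_glct2",
             subsystem="transport")
    _rxn(model, "PGM", "phosphohexose mutase", {"g6p_c": -1, "g1p_c": 1},
         0, B, gpr="g_pgm", subsystem="rhamnose pathway")
    _rxn(model, "RMLS", "dTDP-sugar synthesis (lumped)",
         {"g1p_c": -1, "dtdp_c": -1, "ddm_c": 1, "h2o_c": 2},
         0, B, gpr="g_rmls", subsystem="rhamnose pathway")
    _rxn(model, "GLYC", "glycolysis + pyruvate dehydrogenase (lumped)",
         {"g6p_c": -1, "coa_c": -2, "accoa_c": 2, "co2_c": 2, "h2_c": 4},
         0, B, gpr="g_glyc", subsystem="glycolysis")
    _rxn(model, "FAS", "fatty-acid synthesis (lumped)",
         {"accoa_c": -5, "acp_c": -1, "h2_c": -7,
          "hdacp_c": 1, "coa_c": 5, "h2o_c": 3},
         0, B, gpr="g_fas", subsystem="fatty acid synthesis")
    _rxn(model, "HAAS", "HAA synthase (RhlA-like)",
         {"hdacp_c": -2, "h2o_c": -1, "haa_c": 1, "acp_c": 2},
         0, B, gpr="g_haas", subsystem="rhamnolipid synthesis")
    _rxn(model, "RHLS", "rhamnosyltransferase (RhlB-like)",
         {"ddm_c": -1, "haa_c": -1, "rhl_c": 1, "dtdp_c": 1},
         0, B, gpr="g_rhls", subsystem="rhamnolipid synthesis")
    _rxn(model, "RHLT", "rhamnolipid export", {"rhl_c": -1, "rhl_e": 1},
         0, B, gpr="g_rhlt", subsystem="transport")
    _rxn(model, "EX_rhl_e", "rhamnolipid exchange", {"rhl_e": -1}, 0, B)
    _rxn(model, "BIOMASS", "biomass drain",
         {"g6p_c": -1, "accoa_c": -2, "biomass_c": 1, "coa_c": 2},
         0, B, gpr="g_bio", subsystem="biomass")
    _rxn(model, "DM_biomass_c", "biomass sink", {"biomass_c": -1}, 0, B)
    _rxn(model, "CO2T", "CO2 diffusion", {"co2_c": -1, "co2_e": 1}, -B, B)
    _rxn(model, "EX_co2_e", "CO2 exchange", {"co2_e": -1}, -B, B)
    _rxn(model, "DM_h2_c", "respiratory sink for reducing equivalents",
         {"h2_c": -1}, 0, B)
    # CoA turnover sink. Carries zero flux in the base network (CoA release
    # by fatty-acid synthesis and the biomass drain exactly matches CoA
    # capture by glycolysis), but admits grafted chains whose curated
    # stoichiometry has a net cofactor surplus.
    _rxn(model, "DM_coa_c", "CoA turnover sink", {"coa_c": -1}, 0, B)
    _rxn(model, "H2OT", "H2O diffusion", {"h2o_c": -1, "h2o_e": 1}, -B, B)
    _rxn(model, "EX_h2o_e", "H2O exchange", {"h2o_e": -1}, -B, B)
    _rxn(model, "HT", "proton diffusion", {"h_c": -1, "h_e": 1}, -B, B)
    _rxn(model, "EX_h_e", "proton exchange", {"h_e": -1}, -B, B)
    if spec.with_fa_source:
        _rxn(model, "EX_fa_e", "fatty acid exchange", {"fa_e": -1}, 0, B)
        _rxn(model, "FAT", "fatty-acid uptake and ACP loading",
             {"fa_e": -1, "acp_c": -1, "hdacp_c": 1, "h2o_c": 1},
             0, B, gpr="g_fat", subsystem="fatty acid degradation")
    if spec.with_loop:
        _rxn(model, "LOOP1", "cycle step 1", {"loop1_c": -1, "loop2_c": 1}, -B, B)
        _rxn(model, "LOOP2", "cycle step 2", {"loop2_c": -1, "loop3_c": 1}, -B, B)
        _rxn(model, "LOOP3", "cycle step 3", {"loop3_c": -1, "loop1_c": 1}, -B, B)

    model.objective = TOY_OBJECTIVE

    if spec.binding_bound_on:
        from .fba import geometric_fba

        rid = spec.binding_bound_on
        if not model.reactions.has_id(rid):
            raise ConfigurationError(
                f"binding_bound_on: unknown reaction {rid!r}"
            )
        sol = geometric_fba(model)
        flux = abs(sol.fluxes[rid])
        if flux <= 0:
            raise ConfigurationError(
                f"binding_bound_on: reaction {rid!r} carries no flux at the "
                "unconstrained optimum"
            )
        model.reactions.get_by_id(rid).upper_bound = 0.8 * flux
    return model


def synth_expression(
    n_per_group: int = 40,
    n_genes: int = 200,
    planted: list[str] | None = None,
    delta: float = math.log(2.0),
    sigma: float = 0.25,
    seed: int = 0,
    model: cobra.Model | None = None,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate a two-group expression matrix with planted log-scale shifts.

    Expression levels are log-normal around the reference level 1:
    ``theta = exp(N(0, sigma^2))`` for every gene in both groups, with the
    planted genes shifted by ``+delta`` on the log scale in the second
    (mutant) group only.

    If *model* is given (a toy model built with
    ``parallel_glucose_transporters=True``), the planted genes are wired into
    the model: the first planted gene becomes the GPR of ``GLCT``, whose
    upper bound is tightened to 80% of its flux at the unconstrained
    geometric optimum so that expression scaling binds; the second becomes
    the GPR of the unconstrained isoform ``GLCT2``, whose flux co-varies as
    the complement.  The remaining (null) genes are assigned round-robin to
    the other enzyme-associated toy reactions, whose sentinel bounds never
    bind, so their fluxes are identical across samples.  Flux differences
    between groups are therefore confined to reactions wired to planted
    genes.

    Returns the expression matrix (genes x 2*n_per_group, groups
    ``wild_type``/``tn5_mutant``) and the ground truth.  *model* is modified
    in place.
    """
    genes = [f"g{i:04d}" for i in range(1, n_genes + 1)]
    if planted is None:
        planted = genes[:2]
    missing = [g for g in planted if g not in genes]
    if missing:
        raise ConfigurationError(
            f"planted genes not in the gene list: {missing}"
        )

    rng = np.random.default_rng(seed)
    n_samples = 2 * n_per_group
    log_theta = rng.normal(0.0, sigma, size=(n_genes, n_samples))
    planted_idx = [genes.index(g) for g in planted]
    for i in planted_idx:
        log_theta[i, n_per_group:] += delta
    samples = [f"wt_{i + 1:02d}" for i in range(n_per_group)] + [
        f"mut_{i + 1:02d}" for i in range(n_per_group)
    ]
    values = pd.DataFrame(np.exp(log_theta), index=genes, columns=samples)
    groups = pd.Series(
        ["wild_type"] * n_per_group + ["tn5_mutant"] * n_per_group,
        index=samples,
        name="group",
    )

    wiring: dict[str, str] = {}
    if model is not None:
        from .fba import geometric_fba

        for rid in ("GLCT", "GLCT2"):
            if not model.reactions.has_id(rid):
                raise ConfigurationError(
                    "synthetic wiring needs a toy model with "
                    "parallel_glucose_transporters=True"
                )
        if len(planted) < 2:
            raise ConfigurationError("need at least two planted genes to wire")
        sol = geometric_fba(model)
        glct = model.reactions.get_by_id("GLCT")
        glct.upper_bound = 0.8 * abs(sol.fluxes["GLCT"])
        glct.gene_reaction_rule = planted[0]
        model.reactions.get_by_id("GLCT2").gene_reaction_rule = planted[1]
        wiring[planted[0]] = "GLCT"
        wiring[planted[1]] = "GLCT2"
        null_targets = [
            r for r in model.reactions
            if r.gene_reaction_rule and r.id not in ("GLCT", "GLCT2")
        ]
        null_genes = [g for g in genes if g not in planted]
        for rxn, gene in zip(null_targets, null_genes):
            rxn.gene_reaction_rule = gene

    truth = SyntheticTruth(
        planted_genes=list(planted),
        delta=delta,
        sigma=sigma,
        wiring=wiring,
        seed=seed,
    )
    return ExpressionMatrix(values=values, groups=groups), truth


def null_flux_matrix(
    n_reactions: int = 200, n_per_group: int = 40, seed: int = 0
) -> tuple[pd.DataFrame, pd.Series]:
    """Flux matrix with no group effect, for false-positive calibration."""
    rng = np.random.default_rng(seed)
    samples = [f"wt_{i + 1:02d}" for i in range(n_per_group)] + [
        f"mut_{i + 1:02d}" for i in range(n_per_group)
    ]
    values = pd.DataFrame(
        rng.normal(size=(n_reactions, 2 * n_per_group)),
        index=[f"rxn_{i:03d}" for i in range(n_reactions)],
        columns=samples,
    )
    groups = pd.Series(
        ["wild_type"] * n_per_group + ["tn5_mutant"] * n_per_group,
        index=samples,
        name="group",
    )
    return values, groups
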