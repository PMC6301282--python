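"""Condition-specific models from expression profiles.

A normalized expression level theta (reference level 1, the cohort average)
is mapped to a multiplicative flux-bound coefficient

    phi(theta) = [1 + gamma * |log theta|] ** sgn(theta - 1)

with natural log and sgn(0) = 0, so phi(1) = 1, over-expression widens the
bounds sub-linearly (phi(e) = 1 + gamma) and under-expression shrinks them
reciprocally (phi is multiplicatively symmetric: phi(t) * phi(1/t) = 1).
Each gene's theta is propagated to reactions through the GPR rule with
AND = min (limiting subunit of a complex) and OR = max (best isozyme), and
the bounds of every enzyme-associated reaction are scaled:

    V_min * phi(theta_r) <= v <= V_max * phi(theta_r)

Reactions without a GPR (exchanges, diffusion, pseudo-reactions) keep their
bounds.  One geometric FBA per expression profile then yields the
condition-specific flux distribution.
"""

from __future__ import annotations

import ast
from dataclasses import dataclass, field

import cobra
import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .fba import GeometricSolver, ModelArrays

__all__ = [
    "ExpressionMatrix",
    "IntegrationParams",
    "phi",
    "reaction_expression",
    "condition_specific_model",
    "batch_condition_fba",
    "read_expression_tsv",
    "read_groups_tsv",
    "read_geo_series_matrix",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression levels with per-sample group labels."""

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise InputError(f"duplicate gene ids: {dupes[:5]}")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise InputError(
                f"samples without a group label: {missing[:5]}"
            )
        self.groups = self.groups.loc[self.values.columns]

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def normalized(self) -> "ExpressionMatrix":
        """Divide each gene by its mean over all samples (cohort reference 1).

        Genes with non-positive values or zero mean are rejected: theta must
        stay strictly positive.
        """
        vals = self.values.astype(float)
        if (vals <= 0).any().any():
            raise InputError("expression values must be positive to normalize")
        return ExpressionMatrix(vals.div(vals.mean(axis=1), axis=0), self.groups)


@dataclass
class IntegrationParams:
    """Parameters of the expression-to-bounds mapping."""

    gamma: float = 1.0
    missing_gene_theta: float = 1.0
    scale_all: bool = False  # also scale GPR-less reactions by theta = 1

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ConfigurationError(f"gamma must be >= 0, got {self.gamma}")


def phi(theta, gamma: float = 1.0):
    """Map expression level(s) theta > 0 to a bound-scaling coefficient.

    Accepts scalars or numpy arrays; natural log throughout.
    """
    theta_arr = np.asarray(theta, dtype=float)
    if np.any(theta_arr <= 0) or np.any(~np.isfinite(theta_arr)):
        raise InputError("phi requires finite theta > 0")
    base = 1.0 + gamma * np.abs(np.log(theta_arr))
    out = base ** np.sign(theta_arr - 1.0)
    if np.isscalar(theta) or np.ndim(theta) == 0:
        return float(out)
    return out


class _GPREvaluator(ast.NodeVisitor):
    def __init__(self, profile, missing: float):
        self.profile = profile
        self.missing = missing

    def visit_Name(self, node: ast.Name) -> float:
        try:
            value = self.profile[node.id]
        except KeyError:
            return self.missing
        return float(value)

    def visit_BoolOp(self, node: ast.BoolOp) -> float:
        values = [self.visit(v) for v in node.values]
        if isinstance(node.op, ast.And):
            return min(values)
        return max(values)

    def generic_visit(self, node):
        if isinstance(node, (ast.Module, ast.Expr, ast.Expression)):
            return super().generic_visit(node)
        raise ConfigurationError(
            f"unsupported GPR syntax node: {type(node).__name__}"
        )


def reaction_expression(gpr: str, profile, missing_gene_theta: float = 1.0) -> float:
    """Aggregate gene-level theta onto a reaction through its GPR rule.

    AND takes the minimum of its operands, OR the maximum; genes absent from
    *profile* contribute *missing_gene_theta*.
    """
    text = str(gpr).strip()
    if not text:
        raise ConfigurationError("empty GPR rule")
    normalized = text.replace(" AND ", " and ").replace(" OR ", " or ")
    try:
        tree = ast.parse(normalized, mode="eval")
    except SyntaxError as exc:
        raise ConfigurationError(f"unparseable GPR rule {gpr!r}") from exc
    evaluator = _GPREvaluator(profile, missing_gene_theta)
    node = tree.body
    if not isinstance(node, (ast.Name, ast.BoolOp)):
        raise ConfigurationError(f"unsupported GPR rule {gpr!r}")
    return evaluator.visit(node)


def _phi_per_reaction(
    model: cobra.Model, profile, params: IntegrationParams
) -> np.ndarray:
    factors = np.ones(len(model.reactions))
    for j, rxn in enumerate(model.reactions):
        rule = rxn.gene_reaction_rule
        if not rule:
            if params.scale_all:
                # No GPR means no measured theta; under --scale-all such
                # reactions take the missing-gene level instead of staying
                # untouched.
                factors[j] = phi(params.missing_gene_theta, params.gamma)
            continue
        try:
            theta_r = reaction_expression(rule, profile, params.missing_gene_theta)
            factors[j] = phi(theta_r, params.gamma)
        except (ConfigurationError, InputError) as exc:
            raise type(exc)(f"reaction {rxn.id!r}: {exc}") from exc
    return factors


def condition_specific_model(
    model: cobra.Model, profile, params: IntegrationParams | None = None
) -> cobra.Model:
    """Return a copy of *model* with bounds scaled by phi per reaction.

    *profile* maps gene id -> normalized theta (e.g. one column of a
    normalized :class:`ExpressionMatrix`).
    """
    params = params or IntegrationParams()
    scaled = model.copy()
    factors = _phi_per_reaction(scaled, profile, params)
    for rxn, f in zip(scaled.reactions, factors):
        rxn.lower_bound = rxn.lower_bound * f
        rxn.upper_bound = rxn.upper_bound * f
    return scaled


def batch_condition_fba(
    model: cobra.Model,
    matrix: ExpressionMatrix,
    params: IntegrationParams | None = None,
    objective: str | None = None,
    tolerance: float = 1e-6,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """One geometric FBA per sample of *matrix* on phi-scaled bounds.

    Returns ``(flux_matrix, objective_values, statuses)`` where
    ``flux_matrix`` is reactions x samples (columns in sample order, NaN for
    failed samples), and ``statuses`` records per-sample solver status so
    failures are visible rather than dropped.
    """
    from .model_io import set_objective

    params = params or IntegrationParams()
    if objective is not None:
        set_objective(model, objective)
    arrays = ModelArrays.from_cobra(model)
    solver = GeometricSolver(arrays, tolerance=tolerance)
    n = len(arrays.reaction_ids)
    fluxes = {}
    objectives = {}
    statuses = {}
    values = matrix.values
    for sample in matrix.samples:
        profile = values[sample]
        factors = _phi_per_reaction(model, profile, params)
        try:
            sol = solver.solve(arrays.lower * factors, arrays.upper * factors)
            fluxes[sample] = sol.fluxes.to_numpy()
            objectives[sample] = sol.objective_value
            statuses[sample] = sol.status
        except Exception as exc:  # infeasible sample: record, keep going
            fluxes[sample] = np.full(n, np.nan)
            objectives[sample] = np.nan
            statuses[sample] = f"failed: {exc}"
    flux_matrix = pd.DataFrame(
        fluxes, index=arrays.reaction_ids, columns=matrix.samples
    )
    return (
        flux_matrix,
        pd.Series(objectives, name="objective").reindex(matrix.samples),
        pd.Series(statuses, name="status").reindex(matrix.samples),
    )


def read_expression_tsv(path) -> pd.DataFrame:
    """Genes x samples TSV with a header row of sample ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_groups_tsv(path) -> pd.Series:
    """``sample<TAB>group`` file (no header)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"])
    return pd.Series(df["group"].values, index=df["sample"].values, name="group")


def read_geo_series_matrix(path) -> pd.DataFrame:
    """Parse the expression table of a GEO series-matrix text file.

    Reads the block between ``!series_matrix_table_begin`` and
    ``!series_matrix_table_end``; rows are probe/gene ids, columns sample
    accessions.
    """
    lines = []
    inside = False
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if stripped.startswith("!series_matrix_table_begin"):
                inside = True
                continue
            if stripped.startswith("!series_matrix_table_end"):
                break
            if inside and stripped:
                lines.append(line.rstrip("\n"))
    if not lines:
        raise InputError(f"no series-matrix table found in {path}")
    from io import StringIO

    df = pd.read_csv(StringIO("\n".join(lines)), sep="\t", index_col=0)
    df.index = [str(i).strip('"') for i in df.index]
    df.columns = [str(c).strip('"') for c in df.columns]
    return df.astype(float)
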