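"""End-to-end orchestration of the two workflows.

* **Carbon study** (:func:`run_carbon_study`): graft the rhamnolipid
  pathway, scan production over single carbon sources at a fixed uptake
  rate (for each configured objective), sweep the uptake rate of one
  source, solve mixed-substrate media, and run PCA on the reactions x
  sources flux matrix.
* **Omics study** (:func:`run_omics_study`): normalize an expression
  matrix, build one condition-specific model per sample via phi-scaled
  bounds, solve each with geometric FBA, call differentially active
  reactions between the two sample groups, and rank genes per DAR with a
  cross-validated elastic net.

Every run writes its artifacts as TSV files plus a ``run.log`` recording
package/solver versions, the seed, and numeric tolerances, so a run
directory is self-describing and reruns are bit-identical.  Numeric output
never goes to stdout; logs go to stderr and ``run.log``.
"""

from __future__ import annotations

import logging
import shutil
import sys
from dataclasses import dataclass, field
from pathlib import Path

import cobra
import numpy as np
import pandas as pd
import scipy
import sklearn
import yaml

from . import __version__
from .engineering import engineer_model, read_reaction_specs, rhamnolipid_reaction_set
from .errors import ConfigurationError, InputError, RlfluxError
from .fba import OBJECTIVE_SLACK
from .model_io import MediumSpec, read_model, set_medium, set_objective
from .omics import (
    ExpressionMatrix,
    IntegrationParams,
    batch_condition_fba,
    read_expression_tsv,
    read_geo_series_matrix,
    read_groups_tsv,
)
from .scenarios import carbon_source_scan, mixed_substrate, uptake_sweep
from .stats import elastic_net_select, identify_dars, pca_flux, top_genes

__all__ = ["PipelineConfig", "run_carbon_study", "run_omics_study"]

logger = logging.getLogger("rlflux.pipeline")


@dataclass
class PipelineConfig:
    """Validated configuration for both workflows (loadable from YAML)."""

    model_path: str
    output_dir: str
    objective: str
    sources: list[str] = field(default_factory=list)
    engineering_spec_path: str | None = None  # None: built-in graft; "": skip
    secondary_objective: str | None = None
    rate: float = 10.0
    sweep_source: str | None = None
    sweep_rates: list[float] = field(
        default_factory=lambda: [0.0, 2.5, 5.0, 10.0, 15.0, 20.0]
    )
    mixed_pairs: list[list[str]] | None = None
    omics_source: str | None = None
    model_format: str = "sbml"
    gamma: float = 1.0
    alpha: float = 0.05
    enet_alpha: float = 0.5
    folds: int = 10
    top_k: int = 10
    seed: int = 0
    tolerance: float = 1e-6

    def validate(self) -> None:
        if not Path(self.model_path).exists():
            raise ConfigurationError(f"model path not found: {self.model_path}")
        if self.engineering_spec_path and not Path(
            self.engineering_spec_path
        ).exists():
            raise ConfigurationError(
                f"engineering spec not found: {self.engineering_spec_path}"
            )
        if not self.objective:
            raise ConfigurationError("objective reaction id is required")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0.0 <= self.enet_alpha <= 1.0:
            raise ConfigurationError(
                f"enet_alpha must be in [0, 1], got {self.enet_alpha}"
            )
        if self.folds < 2:
            raise ConfigurationError(f"folds must be >= 2, got {self.folds}")
        if self.top_k < 1:
            raise ConfigurationError(f"top_k must be >= 1, got {self.top_k}")
        if self.gamma < 0:
            raise ConfigurationError(f"gamma must be >= 0, got {self.gamma}")
        if self.rate <= 0:
            raise ConfigurationError(f"rate must be > 0, got {self.rate}")
        if any(r < 0 for r in self.sweep_rates):
            raise ConfigurationError("sweep rates must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config {path} is not a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        config = cls(**raw)
        config.validate()
        return config

    def to_yaml(self, path) -> None:
        payload = {k: getattr(self, k) for k in self.__dataclass_fields__}
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)


def _setup_run(config: PipelineConfig, study: str) -> Path:
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.handlers = [handler, logging.StreamHandler(sys.stderr)]
    logger.setLevel(logging.INFO)
    logger.propagate = False
    logger.info("study=%s", study)
    logger.info(
        "versions rlflux=%s cobra=%s numpy=%s scipy=%s sklearn=%s pandas=%s",
        __version__, cobra.__version__, np.__version__, scipy.__version__,
        sklearn.__version__, pd.__version__,
    )
    logger.info(
        "seed=%d tolerance=%g objective_slack=%g gamma=%g",
        config.seed, config.tolerance, OBJECTIVE_SLACK, config.gamma,
    )
    config.to_yaml(out / "config.yaml")
    return out


def _load_and_engineer(config: PipelineConfig) -> cobra.Model:
    model = read_model(config.model_path, format=config.model_format)
    if config.engineering_spec_path is None:
        specs = rhamnolipid_reaction_set()
    elif config.engineering_spec_path == "":
        specs = []
    else:
        specs = read_reaction_specs(config.engineering_spec_path)
    if specs:
        engineer_model(model, specs)
        logger.info("engineered %d reactions: %s", len(specs),
                    [s.code for s in specs])
    return model


def _write(df: pd.DataFrame, path: Path, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", index_label=index_label)
    logger.info("wrote %s", path.name)


class _Stage:
    """Context manager that rewraps failures with the stage name while the
    artifacts written so far stay on disk."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None:
            logger.error("stage %s: failed: %s", self.name, exc)
            raise RlfluxError(f"stage {self.name!r} failed: {exc}") from exc
        logger.info("stage %s: done", self.name)


def run_carbon_study(config: PipelineConfig) -> dict[str, Path]:
    """Carbon-source workflow; returns a name -> path map of artifacts."""
    out = _setup_run(config, "carbon")
    artifacts: dict[str, Path] = {"config": out / "config.yaml",
                                  "log": out / "run.log"}
    if not config.sources:
        raise ConfigurationError("carbon study needs a non-empty source list")

    with _Stage("engineer"):
        model = _load_and_engineer(config)

    objectives = [config.objective]
    if config.secondary_objective:
        objectives.append(config.secondary_objective)
    scan_by_objective: dict[str, pd.DataFrame] = {}
    with _Stage("scan"):
        for objective in objectives:
            scan = carbon_source_scan(model, config.sources, rate=config.rate,
                                      objective=objective,
                                      tolerance=config.tolerance)
            scan_by_objective[objective] = scan
            path = out / f"scan_{objective}.tsv"
            _write(scan.drop(columns="solution").set_index("source"), path)
            artifacts[f"scan_{objective}"] = path

    with _Stage("sweep"):
        sweep_source = config.sweep_source or config.sources[0]
        sweep, diag = uptake_sweep(model, sweep_source, config.sweep_rates,
                                   objective=config.objective,
                                   tolerance=config.tolerance)
        path = out / "sweep.tsv"
        _write(sweep.drop(columns="solution").set_index("rate"), path)
        artifacts["sweep"] = path
        lin = pd.DataFrame(
            [{"source": sweep_source, "slope": diag.slope,
              "max_relative_deviation": diag.max_relative_deviation}]
        ).set_index("source")
        _write(lin, out / "linearity.tsv")
        artifacts["linearity"] = out / "linearity.tsv"

    with _Stage("mixed"):
        pairs = config.mixed_pairs
        if pairs is None:
            pairs = [[config.sources[0], s] for s in config.sources[1:]]
        rows = []
        for pair in pairs:
            medium = MediumSpec(
                uptakes={s: config.rate for s in pair},
                closed_sources=[s for s in config.sources if s not in pair],
            )
            sol = mixed_substrate(model, medium, objective=config.objective,
                                  tolerance=config.tolerance)
            rows.append({"pair": "+".join(pair), "rate_each": config.rate,
                         "flux": sol.objective_value})
        mixed = pd.DataFrame(rows,
                             columns=["pair", "rate_each", "flux"]).set_index("pair")
        _write(mixed, out / "mixed.tsv")
        artifacts["mixed"] = out / "mixed.tsv"

    with _Stage("pca"):
        scan = scan_by_objective[config.objective]
        flux_matrix = pd.DataFrame(
            {row["source"]: row["solution"].fluxes
             for _, row in scan.iterrows()}
        )
        flux_matrix.index.name = "reaction"
        _write(flux_matrix, out / "flux_matrix.tsv")
        artifacts["flux_matrix"] = out / "flux_matrix.tsv"
        spread = flux_matrix.max(axis=0) - flux_matrix.min(axis=0)
        scale = bool((spread > 1e-9).all())
        if not scale:
            logger.info(
                "constant condition column(s) %s: using covariance PCA so "
                "every source stays a variable",
                list(spread.index[spread <= 1e-9]),
            )
        pca = pca_flux(flux_matrix, scale=scale)
        summary = pd.DataFrame(
            {"eigenvalue": pca.eigenvalues,
             "variance_fraction": pca.variance_fraction},
            index=pca.variable_coords.columns,
        )
        summary.index.name = "component"
        _write(summary, out / "pca_eigenvalues.tsv")
        for name, frame in (
            ("pca_variable_coords", pca.variable_coords),
            ("pca_variable_contrib", pca.variable_contrib),
            ("pca_variable_cos2", pca.variable_cos2),
            ("pca_individual_coords", pca.individual_coords),
        ):
            _write(frame, out / f"{name}.tsv",
                   index_label="source" if "variable" in name else "reaction")
            artifacts[name] = out / f"{name}.tsv"
        artifacts["pca_eigenvalues"] = out / "pca_eigenvalues.tsv"
        logger.info("pca first-two-component variance = %.4f",
                    pca.variance_fraction[:2].sum())
    return artifacts


def _read_expression(path) -> pd.DataFrame:
    with open(path) as fh:
        head = fh.read(4096)
    if "!series_matrix_table_begin" in head or "!Series_" in head:
        return read_geo_series_matrix(path)
    return read_expression_tsv(path)


def run_omics_study(
    config: PipelineConfig, expression_path, groups_path
) -> dict[str, Path]:
    """Omics workflow; returns a name -> path map of artifacts."""
    out = _setup_run(config, "omics")
    artifacts: dict[str, Path] = {"config": out / "config.yaml",
                                  "log": out / "run.log"}

    with _Stage("read_inputs"):
        values = _read_expression(expression_path)
        groups = read_groups_tsv(groups_path)
        missing = [s for s in values.columns if s not in groups.index]
        if missing:
            raise InputError(f"groups file misses samples: {missing}")
        matrix = ExpressionMatrix(values, groups.loc[values.columns]).normalized()
        logger.info("expression: %d genes x %d samples",
                    len(matrix.genes), len(matrix.samples))

    with _Stage("engineer"):
        model = _load_and_engineer(config)
        if config.omics_source:
            set_medium(model, MediumSpec(uptakes={config.omics_source: config.rate}))
        set_objective(model, config.objective)

    with _Stage("batch_fba"):
        params = IntegrationParams(gamma=config.gamma)
        flux_matrix, objectives, statuses = batch_condition_fba(
            model, matrix, params=params, tolerance=config.tolerance
        )
        _write(flux_matrix, out / "flux_matrix.tsv", index_label="reaction")
        artifacts["flux_matrix"] = out / "flux_matrix.tsv"
        per_sample = pd.DataFrame(
            {"objective": objectives, "status": statuses,
             "group": matrix.groups.loc[objectives.index]}
        )
        _write(per_sample, out / "samples.tsv", index_label="sample")
        artifacts["samples"] = out / "samples.tsv"
        n_bad = int((statuses != "optimal").sum())
        if n_bad:
            logger.warning("%d samples failed to solve", n_bad)

    with _Stage("dars"):
        solved = statuses.index[statuses == "optimal"]
        dar = identify_dars(flux_matrix[solved], matrix.groups.loc[solved],
                            alpha=config.alpha)
        _write(dar.table, out / "dars.tsv", index_label="reaction")
        artifacts["dars"] = out / "dars.tsv"
        logger.info("%d DARs at adjusted p < %g (of %d tested, %d constant)",
                    len(dar.dars), config.alpha, len(dar.table),
                    len(dar.constant_reactions))

    with _Stage("elastic_net"):
        X = matrix.values[solved].T  # samples x genes
        top_rows = []
        beta_frames = {}
        for rid in dar.dars:
            y = flux_matrix.loc[rid, solved]
            fit = elastic_net_select(X, y, alpha=config.enet_alpha,
                                     folds=config.folds, seed=config.seed)
            beta_frames[rid] = fit.beta
            for rank, gene in enumerate(top_genes(fit, config.top_k), start=1):
                top_rows.append({"reaction": rid, "rank": rank, "gene": gene,
                                 "beta": fit.beta[gene],
                                 "lambda": fit.chosen_lambda})
        top = pd.DataFrame(top_rows,
                           columns=["reaction", "rank", "gene", "beta", "lambda"])
        top.to_csv(out / "top_genes.tsv", sep="\t", index=False)
        artifacts["top_genes"] = out / "top_genes.tsv"
        if beta_frames:
            _write(pd.DataFrame(beta_frames), out / "enet_beta.tsv",
                   index_label="gene")
            artifacts["enet_beta"] = out / "enet_beta.tsv"
        logger.info("elastic net fitted for %d DARs", len(beta_frames))

    with _Stage("boxplot_data"):
        genes = sorted(set(top["gene"])) if len(top) else []
        long_rows = []
        for gene in genes:
            for sample in matrix.samples:
                long_rows.append(
                    {"gene": gene, "sample": sample,
                     "group": matrix.groups[sample],
                     "theta": matrix.values.loc[gene, sample]}
                )
        pd.DataFrame(long_rows,
                     columns=["gene", "sample", "group", "theta"]).to_csv(
            out / "boxplot_data.tsv", sep="\t", index=False
        )
        artifacts["boxplot_data"] = out / "boxplot_data.tsv"
    return artifacts
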