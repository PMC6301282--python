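"""Statistical layer: differentially active reactions, elastic-net gene
ranking, and PCA of flux rates.

Differentially active reactions (DARs) are reactions whose predicted flux
differs between two sample groups after multiple-testing adjustment.
Because fluxes from constrained LPs are bounded and typically far from
Gaussian, the two-group comparison is a Wilcoxon rank-sum test with
Benjamini-Hochberg adjustment across all tested reactions.

The elastic-net criterion penalizes the squared-error loss with
``lambda * [(1 - alpha) * ||beta||_1 + alpha * ||beta||_2^2]``; at the
mixing value alpha = 0.5 used throughout the pipeline this coincides (up to
a constant rescaling of lambda, which the cross-validated grid absorbs)
with the lasso-weighted convention of glmnet/scikit-learn.  lambda is
chosen as the CV-error minimizer over a log-spaced grid with a seeded fold
split.

PCA follows the singular-value-decomposition convention of the standard
correlation-PCA presentation: variables (growth conditions) are centred and
unit-scaled, variable coordinates are correlations with the components, and
contributions/cos^2 quantify each variable's or reaction's share of a
component's inertia and quality of representation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, InputError

__all__ = [
    "DARResult",
    "ElasticNetResult",
    "PCAResult",
    "identify_dars",
    "bh_adjust",
    "elastic_net_select",
    "top_genes",
    "pca_flux",
]

#: Fluxes whose spread across all samples is below this are "constant" and
#: excluded from testing (rank tests are undefined on ties-only data).
CONSTANT_TOL = 1e-9


@dataclass
class DARResult:
    """Two-group reaction comparison.

    ``table`` has one row per tested reaction (columns: group means, raw and
    adjusted p-value, significance flag), sorted by adjusted p ascending;
    ``constant_reactions`` lists reactions excluded because their flux was
    identical in every sample.
    """

    table: pd.DataFrame
    constant_reactions: list[str]
    alpha: float

    @property
    def dars(self) -> list[str]:
        return list(self.table.index[self.table["p_adjusted"] < self.alpha])


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving,
    capped at 1)."""
    arr = np.asarray(pvalues, dtype=float)
    if arr.size == 0:
        return arr
    if np.any(~np.isfinite(arr)) or np.any(arr < 0) or np.any(arr > 1):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def identify_dars(
    flux_matrix: pd.DataFrame,
    groups: pd.Series,
    alpha: float = 0.05,
    annotations: pd.DataFrame | None = None,
) -> DARResult:
    """Differentially active reactions between two sample groups.

    Parameters
    ----------
    flux_matrix
        Reactions x samples flux values (e.g. from
        :func:`~rlflux.omics.batch_condition_fba`).
    groups
        Sample -> group label; exactly two groups, each with >= 2 samples.
    alpha
        Adjusted-p threshold used by :attr:`DARResult.dars`.
    annotations
        Optional reactions x (name, subsystem, ...) frame carried onto the
        output rows.
    """
    groups = groups.loc[flux_matrix.columns]
    labels = list(pd.unique(groups))
    if len(labels) != 2:
        raise ConfigurationError(
            f"need exactly two groups, got {labels}"
        )
    a_cols = groups.index[groups == labels[0]]
    b_cols = groups.index[groups == labels[1]]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ConfigurationError("each group needs at least two samples")

    values = flux_matrix.to_numpy(dtype=float)
    spread = values.max(axis=1) - values.min(axis=1)
    constant = spread <= CONSTANT_TOL
    tested = flux_matrix.index[~constant]
    rows = []
    for rid in tested:
        a = flux_matrix.loc[rid, a_cols].to_numpy(dtype=float)
        b = flux_matrix.loc[rid, b_cols].to_numpy(dtype=float)
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        rows.append(
            {
                "reaction": rid,
                f"mean_{labels[0]}": a.mean(),
                f"mean_{labels[1]}": b.mean(),
                "statistic": stat,
                "p_value": p,
            }
        )
    if rows:
        table = pd.DataFrame(rows).set_index("reaction")
        table["p_adjusted"] = bh_adjust(table["p_value"].to_numpy())
        table["significant"] = table["p_adjusted"] < alpha
        if annotations is not None:
            table = table.join(annotations, how="left")
        table = table.sort_values("p_adjusted", kind="mergesort")
    else:
        table = pd.DataFrame(
            columns=[f"mean_{labels[0]}", f"mean_{labels[1]}", "statistic",
                     "p_value", "p_adjusted", "significant"]
        )
        table.index.name = "reaction"
    return DARResult(table=table,
                     constant_reactions=list(flux_matrix.index[constant]),
                     alpha=alpha)


@dataclass
class ElasticNetResult:
    """Fitted elastic-net regression for one response vector."""

    beta: pd.Series
    intercept: float
    alpha: float               # penalty mixing (0.5: equal lasso/ridge)
    lambda_grid: np.ndarray    # overall penalty strengths, descending
    cv_error: np.ndarray       # mean CV MSE per grid lambda
    chosen_lambda: float
    seed: int
    degenerate: bool = False   # y had zero variance

    @property
    def lambda1(self) -> float:
        """Implied L1 penalty weight (lambda * (1 - alpha))."""
        return self.chosen_lambda * (1.0 - self.alpha)

    @property
    def lambda2(self) -> float:
        """Implied L2 penalty weight (lambda * alpha)."""
        return self.chosen_lambda * self.alpha

    @property
    def nonzero(self) -> pd.Series:
        return self.beta[self.beta != 0.0]


def _standardize(X: np.ndarray) -> np.ndarray:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mean) / sd


def elastic_net_select(
    X: pd.DataFrame,
    y,
    alpha: float = 0.5,
    folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 100,
) -> ElasticNetResult:
    """Cross-validated elastic net of a flux response on gene expression.

    *X* is samples x genes (column-standardized internally), *y* the flux of
    one reaction across the same samples.  Deterministic given *seed*.
    """
    y_arr = np.asarray(y, dtype=float)
    X_arr = X.to_numpy(dtype=float)
    if X_arr.shape[0] != y_arr.shape[0]:
        raise InputError(
            f"X has {X_arr.shape[0]} rows but y has {y_arr.shape[0]}"
        )
    if np.any(~np.isfinite(X_arr)) or np.any(~np.isfinite(y_arr)):
        raise InputError("X and y must be finite (no NaNs)")
    genes = list(X.columns)
    if float(np.ptp(y_arr)) == 0.0:
        warnings.warn("response has zero variance; returning all-zero beta")
        return ElasticNetResult(
            beta=pd.Series(0.0, index=genes),
            intercept=float(y_arr.mean()),
            alpha=alpha,
            lambda_grid=np.array([]),
            cv_error=np.array([]),
            chosen_lambda=float("nan"),
            seed=seed,
            degenerate=True,
        )
    X_std = _standardize(X_arr)
    l1_ratio = 1.0 - alpha  # weight of the L1 term in the mixed penalty
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    fit = ElasticNetCV(
        l1_ratio=l1_ratio,
        alphas=n_lambdas,  # grid size (lambda values generated internally)
        cv=cv,
        max_iter=50_000,
        tol=1e-6,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit.fit(X_std, y_arr)
    return ElasticNetResult(
        beta=pd.Series(fit.coef_, index=genes),
        intercept=float(fit.intercept_),
        alpha=alpha,
        lambda_grid=np.asarray(fit.alphas_),
        cv_error=np.asarray(fit.mse_path_).mean(axis=-1),
        chosen_lambda=float(fit.alpha_),
        seed=seed,
    )


def lambda_max(X: pd.DataFrame, y, alpha: float = 0.5) -> float:
    """Smallest overall penalty that zeroes every coefficient.

    Closed form from the coordinate-descent stationarity condition on
    standardized predictors: ``max_j |x_j . (y - mean(y))| / (n * l1)``
    where ``l1 = 1 - alpha`` is the L1 weight.
    """
    X_std = _standardize(X.to_numpy(dtype=float))
    y_arr = np.asarray(y, dtype=float)
    resid = y_arr - y_arr.mean()
    n = X_std.shape[0]
    return float(np.max(np.abs(X_std.T @ resid)) / (n * (1.0 - alpha)))


def elastic_net_at(X: pd.DataFrame, y, lam: float,
                   alpha: float = 0.5) -> pd.Series:
    """Single elastic-net fit at a fixed overall penalty (no CV)."""
    X_std = _standardize(X.to_numpy(dtype=float))
    fit = ElasticNet(alpha=lam, l1_ratio=1.0 - alpha, max_iter=100_000,
                     tol=1e-8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit.fit(X_std, np.asarray(y, dtype=float))
    return pd.Series(fit.coef_, index=list(X.columns))


def top_genes(result: ElasticNetResult, k: int = 10) -> list[str]:
    """The k genes with the largest |beta|, ties broken by gene id.

    If fewer than k coefficients are nonzero, all nonzero genes are
    returned with a warning.
    """
    if k <= 0:
        return []
    nonzero = result.nonzero
    if len(nonzero) < k:
        warnings.warn(
            f"only {len(nonzero)} nonzero coefficients for top-{k} request"
        )
        k = len(nonzero)
    order = sorted(nonzero.index, key=lambda g: (-abs(nonzero[g]), g))
    return order[:k]


@dataclass
class PCAResult:
    """SVD-based PCA with contributions and cos^2.

    Individuals are the rows of the input (reactions), variables the
    columns (conditions).  Per component, variable contributions sum to 100
    and individual contributions sum to 100; cos^2 of an entity over all
    kept components sums to <= 1 (exactly 1 when all components are kept).
    """

    eigenvalues: np.ndarray
    variance_fraction: np.ndarray
    variable_coords: pd.DataFrame
    individual_coords: pd.DataFrame
    variable_contrib: pd.DataFrame
    individual_contrib: pd.DataFrame
    variable_cos2: pd.DataFrame
    individual_cos2: pd.DataFrame
    dropped_constant: list[str]


def pca_flux(flux_matrix: pd.DataFrame, scale: bool = True) -> PCAResult:
    """PCA of a reactions x conditions flux matrix.

    Columns are centred (and unit-scaled for the default correlation PCA,
    matching the correlation-circle presentation); constant columns are
    dropped with a warning.  Components come from the singular value
    decomposition of the processed matrix.
    """
    X = flux_matrix.astype(float)
    spread = X.max(axis=0) - X.min(axis=0)
    dropped: list[str] = []
    if scale:
        # Unit-scaling a constant column divides by zero; such columns must
        # go.  Without scaling they are harmless (zero loadings) and stay.
        dropped = list(X.columns[spread <= CONSTANT_TOL])
        if dropped:
            warnings.warn(f"dropping constant conditions: {dropped}")
            X = X.drop(columns=dropped)
    if X.shape[1] < 2:
        raise InputError("PCA needs at least two non-constant conditions")
    n = X.shape[0]
    centred = X - X.mean(axis=0)
    if scale:
        centred = centred / centred.std(axis=0, ddof=0)
    U, s, Vt = np.linalg.svd(centred.to_numpy(), full_matrices=False)
    k = len(s)
    comps = [f"PC{i + 1}" for i in range(k)]
    eigenvalues = s**2 / n
    total = eigenvalues.sum()
    var_coords = (Vt.T * (s / np.sqrt(n)))  # correlations when scale=True
    ind_coords = U * s
    var_contrib = 100.0 * Vt.T**2
    ind_contrib = 100.0 * U**2
    var_cos2 = var_coords**2 / np.maximum(
        (var_coords**2).sum(axis=1, keepdims=True), 1e-300
    )
    row_norm2 = (centred.to_numpy() ** 2).sum(axis=1, keepdims=True)
    ind_cos2 = ind_coords**2 / np.maximum(row_norm2, 1e-300)
    as_df = lambda arr, index: pd.DataFrame(arr, index=index, columns=comps)
    return PCAResult(
        eigenvalues=eigenvalues,
        variance_fraction=eigenvalues / total,
        variable_coords=as_df(var_coords, X.columns),
        individual_coords=as_df(ind_coords, X.index),
        variable_contrib=as_df(var_contrib, X.columns),
        individual_contrib=as_df(ind_contrib, X.index),
        variable_cos2=as_df(var_cos2, X.columns),
        individual_cos2=as_df(ind_cos2, X.index),
        dropped_constant=dropped,
    )
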