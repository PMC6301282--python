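import warnings

import numpy as np
import pandas as pd
import pytest

from rlflux.errors import ConfigurationError, InputError
from rlflux.stats import (
    bh_adjust,
    elastic_net_at,
    elastic_net_select,
    identify_dars,
    lambda_max,
    pca_flux,
    top_genes,
)


def _groups(n_a, n_b):
    samples = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    return samples, pd.Series(["A"] * n_a + ["B"] * n_b, index=samples)


def test_dars_identical_groups_empty():
    samples, groups = _groups(5, 5)
    rng = np.random.default_rng(0)
    half = rng.normal(size=(10, 5))
    flux = pd.DataFrame(np.hstack([half, half]),
                        index=[f"R{i}" for i in range(10)], columns=samples)
    result = identify_dars(flux, groups)
    assert result.dars == []


def test_dars_complete_separation():
    samples, groups = _groups(40, 40)
    flux = pd.DataFrame(2.0, index=[f"R{i}" for i in range(10)],
                        columns=samples)
    flux.loc["R3", samples[:40]] = 1.0
    # All other reactions are constant and must be excluded, not tested.
    result = identify_dars(flux, groups)
    assert result.dars == ["R3"]
    assert set(result.constant_reactions) == {f"R{i}" for i in range(10)} - {"R3"}
    assert result.table.loc["R3", "p_adjusted"] < 1e-10


def test_dars_requires_two_groups():
    samples = ["a0", "a1", "a2"]
    flux = pd.DataFrame(np.eye(3), index=list("xyz"), columns=samples)
    with pytest.raises(ConfigurationError):
        identify_dars(flux, pd.Series(["A"] * 3, index=samples))


def test_dars_sorted_and_adjusted_monotone():
    samples, groups = _groups(10, 10)
    rng = np.random.default_rng(1)
    flux = pd.DataFrame(rng.normal(size=(20, 20)),
                        index=[f"R{i}" for i in range(20)], columns=samples)
    flux.iloc[0, 10:] += 10
    table = identify_dars(flux, groups).table
    assert (table["p_adjusted"].to_numpy()
            >= table["p_value"].to_numpy() - 1e-12).all()
    assert list(table["p_adjusted"]) == sorted(table["p_adjusted"])


def test_bh_printed_example():
    assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
        [0.04, 0.04, 0.04, 0.04]
    )


def test_bh_single_p_unchanged():
    assert bh_adjust([0.3]) == pytest.approx([0.3])


def test_bh_all_ones():
    assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])


def test_bh_out_of_range():
    with pytest.raises(InputError):
        bh_adjust([0.5, 1.5])


def _single_predictor():
    rng = np.random.default_rng(0)
    x = rng.normal(size=50)
    x = (x - x.mean()) / x.std()  # standardized predictor
    X = pd.DataFrame({"g1": x})
    return X, 2.0 * x


def test_enet_constant_y_zero_beta():
    X, _ = _single_predictor()
    with pytest.warns(UserWarning):
        fit = elastic_net_select(X, np.ones(50), seed=0)
    assert (fit.beta == 0).all()
    assert fit.degenerate


def test_enet_ols_limit():
    X, y = _single_predictor()
    beta = elastic_net_at(X, y, lam=1e-10)
    assert beta["g1"] == pytest.approx(2.0, abs=1e-4)


def test_enet_lambda_max_zeroes_everything():
    rng = np.random.default_rng(3)
    X = pd.DataFrame(rng.normal(size=(40, 6)),
                     columns=[f"g{i}" for i in range(6)])
    y = X["g0"] + 0.1 * rng.normal(size=40)
    lam = lambda_max(X, y)
    assert (elastic_net_at(X, y, lam * 1.001) == 0).all()
    assert (elastic_net_at(X, y, lam * 0.9) != 0).any()


def test_enet_cv_curve_one_entry_per_lambda():
    rng = np.random.default_rng(4)
    X = pd.DataFrame(rng.normal(size=(40, 5)),
                     columns=[f"g{i}" for i in range(5)])
    y = X["g1"] + 0.1 * rng.normal(size=40)
    fit = elastic_net_select(X, y, seed=7)
    assert len(fit.cv_error) == len(fit.lambda_grid)
    assert fit.chosen_lambda == pytest.approx(
        fit.lambda_grid[np.argmin(fit.cv_error)]
    )
    assert fit.lambda1 + fit.lambda2 == pytest.approx(fit.chosen_lambda)


def test_enet_deterministic_given_seed():
    rng = np.random.default_rng(5)
    X = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
    y = X["a"].to_numpy() + 0.1 * rng.normal(size=30)
    a = elastic_net_select(X, y, seed=11)
    b = elastic_net_select(X, y, seed=11)
    assert (a.beta == b.beta).all()


def test_enet_rejects_nans():
    X = pd.DataFrame({"g1": [1.0, np.nan, 3.0]})
    with pytest.raises(InputError):
        elastic_net_select(X, [1.0, 2.0, 3.0])


def test_top_genes_single_nonzero():
    fit = elastic_net_select(*_single_predictor(), seed=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        assert top_genes(fit, 1) == ["g1"]


def test_top_genes_k_zero():
    fit = elastic_net_select(*_single_predictor(), seed=0)
    assert top_genes(fit, 0) == []


def test_top_genes_ties_broken_by_id():
    from rlflux.stats import ElasticNetResult

    fit = ElasticNetResult(
        beta=pd.Series({"gB": 1.0, "gA": -1.0, "gC": 0.5}),
        intercept=0.0, alpha=0.5, lambda_grid=np.array([1.0]),
        cv_error=np.array([1.0]), chosen_lambda=1.0, seed=0,
    )
    assert top_genes(fit, 2) == ["gA", "gB"]


def test_top_genes_flags_fewer_nonzero():
    from rlflux.stats import ElasticNetResult

    fit = ElasticNetResult(
        beta=pd.Series({"gA": 1.0, "gB": 0.0}),
        intercept=0.0, alpha=0.5, lambda_grid=np.array([1.0]),
        cv_error=np.array([1.0]), chosen_lambda=1.0, seed=0,
    )
    with pytest.warns(UserWarning):
        assert top_genes(fit, 2) == ["gA"]


def test_pca_contributions_sum_to_100():
    rng = np.random.default_rng(0)
    X = pd.DataFrame(rng.normal(size=(25, 4)), columns=list("wxyz"))
    res = pca_flux(X)
    assert np.allclose(res.variable_contrib.sum(axis=0), 100.0)
    assert np.allclose(res.individual_contrib.sum(axis=0), 100.0)
    assert np.allclose(res.variance_fraction.sum(), 1.0)


def test_pca_perfectly_correlated_pair():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    X = pd.DataFrame({"a": x, "b": 3.0 * x})
    res = pca_flux(X)
    assert res.variance_fraction[0] == pytest.approx(1.0)
    assert np.allclose(res.variable_contrib.iloc[:, 0], [50.0, 50.0])


def test_pca_matches_dense_eigendecomposition():
    X = pd.DataFrame([[1.0, 2.0], [2.0, 4.0], [3.0, 7.0]], columns=["a", "b"])
    res = pca_flux(X)
    corr = np.corrcoef(X.to_numpy(), rowvar=False)
    eig = np.sort(np.linalg.eigvalsh(corr))[::-1]
    assert np.allclose(res.eigenvalues, eig, atol=1e-10)


def test_pca_reconstruction():
    rng = np.random.default_rng(2)
    X = pd.DataFrame(rng.normal(size=(15, 5)),
                     columns=[f"c{i}" for i in range(5)])
    res = pca_flux(X)
    n = X.shape[0]
    s = np.sqrt(res.eigenvalues * n)
    Vt = (res.variable_coords.to_numpy() * np.sqrt(n) / s).T
    reconstructed = res.individual_coords.to_numpy() @ Vt
    Z = (X - X.mean()) / X.std(ddof=0)
    assert np.abs(reconstructed - Z.to_numpy()).max() <= 1e-8


def test_pca_cos2_bounds():
    rng = np.random.default_rng(3)
    X = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
    res = pca_flux(X)
    assert np.allclose(res.variable_cos2.sum(axis=1), 1.0)
    assert (res.individual_cos2.sum(axis=1) <= 1.0 + 1e-9).all()


def test_pca_drops_constant_columns_with_warning():
    rng = np.random.default_rng(4)
    X = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
    X["d"] = 5.0
    with pytest.warns(UserWarning):
        res = pca_flux(X)
    assert res.dropped_constant == ["d"]
    assert list(res.variable_coords.index) == ["a", "b", "c"]


def test_pca_too_few_conditions():
    X = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 3.0]})
    with pytest.warns(UserWarning):
        with pytest.raises(InputError):
            pca_flux(X)
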