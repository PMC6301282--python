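import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rlflux.errors import ConfigurationError, InputError
from rlflux.fba import geometric_fba
from rlflux.model_io import set_objective
from rlflux.omics import (
    ExpressionMatrix,
    IntegrationParams,
    batch_condition_fba,
    condition_specific_model,
    phi,
    reaction_expression,
    read_geo_series_matrix,
)
from rlflux.synth import ToyModelSpec, toy_model

E = math.e


def test_phi_identities():
    assert phi(1.0, 1.0) == pytest.approx(1.0)
    assert phi(E, 1.0) == pytest.approx(2.0)
    assert phi(1.0 / E, 1.0) == pytest.approx(0.5)
    assert phi(E, 2.0) == pytest.approx(3.0)


@given(theta=st.floats(min_value=1e-6, max_value=1e6),
       gamma=st.floats(min_value=0.0, max_value=10.0))
@settings(max_examples=200, deadline=None)
def test_phi_multiplicative_symmetry(theta, gamma):
    assert phi(theta, gamma) * phi(1.0 / theta, gamma) == pytest.approx(
        1.0, rel=1e-9
    )


def test_phi_monotone_above_one():
    thetas = [1.5, 2.0, 5.0, 20.0]
    values = [phi(t, 1.0) for t in thetas]
    assert values == sorted(values)
    assert phi(2.0, 2.0) > phi(2.0, 1.0)


def test_phi_domain_error():
    with pytest.raises(InputError):
        phi(0.0, 1.0)
    with pytest.raises(InputError):
        phi(-1.0, 1.0)


def test_reaction_expression_single_gene():
    assert reaction_expression("gA", {"gA": 2.0}) == pytest.approx(2.0)


def test_reaction_expression_and_is_min():
    assert reaction_expression("gA and gB", {"gA": 2.0, "gB": 0.5}) == \
        pytest.approx(0.5)


def test_reaction_expression_or_is_max():
    assert reaction_expression("gA or gB", {"gA": 2.0, "gB": 0.5}) == \
        pytest.approx(2.0)


def test_reaction_expression_missing_gene_default():
    assert reaction_expression("gA and gMissing", {"gA": 2.0}) == \
        pytest.approx(1.0)


def test_reaction_expression_unparseable():
    with pytest.raises(ConfigurationError):
        reaction_expression("gA and and gB", {})


def test_condition_specific_identity_at_theta_one(toy):
    toy.reactions.GLCT.gene_reaction_rule = "gA"
    scaled = condition_specific_model(toy, {"gA": 1.0})
    for rxn in toy.reactions:
        other = scaled.reactions.get_by_id(rxn.id)
        assert other.lower_bound == rxn.lower_bound
        assert other.upper_bound == rxn.upper_bound


def test_condition_specific_scales_bounds(toy):
    toy.reactions.GLCT.gene_reaction_rule = "gA"
    toy.reactions.GLCT.upper_bound = 10.0
    scaled = condition_specific_model(toy, {"gA": E})
    assert scaled.reactions.GLCT.bounds == (0.0, pytest.approx(20.0))


def test_condition_specific_reversible_bounds(toy):
    toy.reactions.GLCT.gene_reaction_rule = "gA"
    toy.reactions.GLCT.lower_bound = -10.0
    toy.reactions.GLCT.upper_bound = 10.0
    scaled = condition_specific_model(toy, {"gA": 1.0 / E})
    assert scaled.reactions.GLCT.lower_bound == pytest.approx(-5.0)
    assert scaled.reactions.GLCT.upper_bound == pytest.approx(5.0)


def test_condition_specific_leaves_gprless_untouched(toy):
    toy.reactions.GLCT.gene_reaction_rule = "gA"
    scaled = condition_specific_model(toy, {"gA": E})
    assert scaled.reactions.EX_glc__D_e.bounds == toy.reactions.EX_glc__D_e.bounds


def _matrix(values: dict, groups: dict) -> ExpressionMatrix:
    frame = pd.DataFrame(values)
    return ExpressionMatrix(frame, pd.Series(groups))


def test_batch_all_ones_matches_unconstrained(toy):
    toy.reactions.GLCT.gene_reaction_rule = "gA"
    samples = {f"s{i}": [1.0] for i in range(3)}
    matrix = ExpressionMatrix(
        pd.DataFrame(samples, index=["gA"]),
        pd.Series({f"s{i}": "g" for i in range(3)}),
    )
    flux, objectives, statuses = batch_condition_fba(toy, matrix)
    assert (statuses == "optimal").all()
    reference = geometric_fba(toy)
    for sample in matrix.samples:
        assert np.allclose(flux[sample].to_numpy(),
                           reference.fluxes.to_numpy(), atol=1e-5)
        assert objectives[sample] == pytest.approx(10.0 / 6.0, abs=1e-6)


def test_batch_binding_bound_halves_objective():
    model = toy_model(ToyModelSpec(binding_bound_on="GLCT"))
    # GLCT upper bound is 80% of its unconstrained optimal flux (8.0), so
    # theta = 1/e on its gene halves the bound (4.0) and the optimum.
    matrix = ExpressionMatrix(
        pd.DataFrame({"ref": [1.0], "low": [1.0 / E]}, index=["g_glct"]),
        pd.Series({"ref": "a", "low": "b"}),
    )
    _, objectives, statuses = batch_condition_fba(model, matrix)
    assert (statuses == "optimal").all()
    assert objectives["ref"] == pytest.approx(8.0 / 6.0, abs=1e-6)
    assert objectives["low"] == pytest.approx(4.0 / 6.0, abs=1e-6)


def test_batch_empty_sample_set(toy):
    matrix = ExpressionMatrix(pd.DataFrame(index=["gA"]), pd.Series(dtype=object))
    flux, objectives, statuses = batch_condition_fba(toy, matrix)
    assert flux.shape[1] == 0
    assert len(objectives) == 0 and len(statuses) == 0


def test_bound_nesting_under_uniform_down_scaling(toy):
    for rxn in ("GLCT", "PGM", "RMLS", "GLYC", "FAS"):
        toy.reactions.get_by_id(rxn).gene_reaction_rule = f"g_{rxn.lower()}"
    profile = {f"g_{r.lower()}": 0.5 for r in ("GLCT", "PGM", "RMLS", "GLYC", "FAS")}
    scaled = condition_specific_model(toy, profile)
    set_objective(scaled, "EX_rhl_e")
    assert geometric_fba(scaled).objective_value <= \
        geometric_fba(toy).objective_value + 1e-9


def test_normalized_reference_is_one():
    matrix = _matrix({"s1": [2.0, 8.0], "s2": [4.0, 2.0]},
                     {"s1": "a", "s2": "b"})
    matrix.values.index = ["g1", "g2"]
    norm = ExpressionMatrix(matrix.values, matrix.groups).normalized()
    assert np.allclose(norm.values.mean(axis=1), 1.0)


def test_normalized_rejects_nonpositive():
    frame = pd.DataFrame({"s1": [0.0], "s2": [1.0]}, index=["g1"])
    matrix = ExpressionMatrix(frame, pd.Series({"s1": "a", "s2": "b"}))
    with pytest.raises(InputError):
        matrix.normalized()


def test_expression_matrix_rejects_unlabelled_samples():
    frame = pd.DataFrame({"s1": [1.0], "s2": [1.0]}, index=["g1"])
    with pytest.raises(InputError):
        ExpressionMatrix(frame, pd.Series({"s1": "a"}))


def test_read_geo_series_matrix(tmp_path):
    path = tmp_path / "series.txt"
    path.write_text(
        "!Series_title\t\"synthetic\"\n"
        "!series_matrix_table_begin\n"
        "\"ID_REF\"\t\"GSM1\"\t\"GSM2\"\n"
        "\"g1\"\t1.5\t2.5\n"
        "\"g2\"\t0.5\t1.0\n"
        "!series_matrix_table_end\n"
    )
    frame = read_geo_series_matrix(path)
    assert list(frame.index) == ["g1", "g2"]
    assert list(frame.columns) == ["GSM1", "GSM2"]
    assert frame.loc["g1", "GSM2"] == pytest.approx(2.5)


def test_scale_all_switch(toy):
    params = IntegrationParams(missing_gene_theta=1.0 / E, scale_all=True)
    scaled = condition_specific_model(toy, {}, params)
    # Without a GPR the exchange scales only under scale_all.
    assert scaled.reactions.EX_glc__D_e.lower_bound == pytest.approx(-5.0)
    default = condition_specific_model(
        toy, {}, IntegrationParams(missing_gene_theta=1.0 / E)
    )
    assert default.reactions.EX_glc__D_e.lower_bound == pytest.approx(-10.0)
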