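import pytest

from conftest import oracle_optimum
from rlflux.errors import ConfigurationError, InputError
from rlflux.model_io import MediumSpec, set_medium, set_objective
from rlflux.scenarios import (
    PathwaySets,
    carbon_source_scan,
    compare_models,
    mixed_substrate,
    pathway_attribution,
    uptake_sweep,
)
from rlflux.synth import TOY_PATHWAY_SETS, ToyModelSpec, toy_model


def test_scan_glucose(toy):
    table = carbon_source_scan(toy, ["EX_glc__D_e"], rate=10.0,
                               objective="EX_rhl_e")
    assert table["flux"].iloc[0] == pytest.approx(10.0 / 6.0, abs=1e-6)


def test_scan_fa_alone_is_zero(toy_fa):
    # No sugar means no dTDP-rhamnose precursor, so no rhamnolipid.
    set_medium(toy_fa, MediumSpec(closed_sources=["EX_glc__D_e"]))
    table = carbon_source_scan(toy_fa, ["EX_fa_e"], rate=10.0,
                               objective="EX_rhl_e")
    assert table["flux"].iloc[0] == pytest.approx(0.0, abs=1e-6)


def test_scan_closes_other_sources(toy_fa):
    table = carbon_source_scan(toy_fa, ["EX_glc__D_e", "EX_fa_e"], rate=10.0,
                               objective="EX_rhl_e")
    by_source = table.set_index("source")["flux"]
    assert by_source["EX_glc__D_e"] == pytest.approx(10.0 / 6.0, abs=1e-6)
    assert by_source["EX_fa_e"] == pytest.approx(0.0, abs=1e-6)


def test_scan_empty_sources(toy):
    table = carbon_source_scan(toy, [], objective="EX_rhl_e")
    assert len(table) == 0


def test_scan_unknown_source(toy):
    with pytest.raises(ConfigurationError):
        carbon_source_scan(toy, ["unobtainium"], objective="EX_rhl_e")


def test_scan_monotone_in_rate(toy):
    fluxes = [
        carbon_source_scan(toy, ["EX_glc__D_e"], rate=r,
                           objective="EX_rhl_e")["flux"].iloc[0]
        for r in (2.0, 5.0, 10.0)
    ]
    assert fluxes == sorted(fluxes)


def test_sweep_linearity(toy):
    rates = [float(r) for r in range(1, 11)]
    _, diag = uptake_sweep(toy, "EX_glc__D_e", rates, objective="EX_rhl_e")
    assert diag.max_relative_deviation < 1e-6
    assert diag.slope == pytest.approx(1.0 / 6.0, abs=1e-6)


def test_sweep_rate_zero(toy):
    table, _ = uptake_sweep(toy, "EX_glc__D_e", [0.0], objective="EX_rhl_e")
    assert table["flux"].iloc[0] == pytest.approx(0.0, abs=1e-9)


def test_sweep_single_rate_slope(toy):
    table, diag = uptake_sweep(toy, "EX_glc__D_e", [6.0], objective="EX_rhl_e")
    assert diag.slope == pytest.approx(table["flux"].iloc[0] / 6.0, abs=1e-9)


def test_mixed_substrate_value(toy_fa):
    sol = mixed_substrate(
        toy_fa,
        MediumSpec(uptakes={"EX_glc__D_e": 10.0, "EX_fa_e": 10.0}),
        objective="EX_rhl_e",
    )
    # LP optimum of the toy under glc 10 + FA 10, frozen from the
    # independent HiGHS oracle (hand value 35/6).
    assert sol.objective_value == pytest.approx(35.0 / 6.0, abs=1e-6)
    set_objective(toy_fa, "EX_rhl_e")
    assert oracle_optimum(toy_fa) == pytest.approx(35.0 / 6.0, abs=1e-9)


def test_mixed_substrate_synergy(toy_fa):
    glc_only = carbon_source_scan(toy_fa, ["EX_glc__D_e", "EX_fa_e"],
                                  rate=10.0, objective="EX_rhl_e")
    separate = glc_only["flux"].sum()
    mixed = mixed_substrate(
        toy_fa, MediumSpec(uptakes={"EX_glc__D_e": 10.0, "EX_fa_e": 10.0}),
        objective="EX_rhl_e",
    ).objective_value
    assert mixed > separate + 1e-6


def test_mixed_both_zero(toy_fa):
    sol = mixed_substrate(
        toy_fa, MediumSpec(closed_sources=["EX_glc__D_e", "EX_fa_e"]),
        objective="EX_rhl_e",
    )
    assert sol.objective_value == pytest.approx(0.0, abs=1e-9)


def test_attribution_glucose_only(toy_fa):
    sol = mixed_substrate(
        toy_fa,
        MediumSpec(uptakes={"EX_glc__D_e": 10.0}, closed_sources=["EX_fa_e"]),
        objective="EX_rhl_e",
    )
    shares = pathway_attribution(toy_fa, sol, PathwaySets(TOY_PATHWAY_SETS),
                                 reporter="RHLS")
    # Only the de-novo route supplies HAA; the rhamnose branch supplies all
    # dTDP-rhamnose.
    assert shares["fatty_acid_pathway"] == pytest.approx(1.0, abs=1e-6)
    assert shares["rhamnose_pathway"] == pytest.approx(1.0, abs=1e-6)


def test_attribution_mixed(toy_fa):
    sol = mixed_substrate(
        toy_fa, MediumSpec(uptakes={"EX_glc__D_e": 10.0, "EX_fa_e": 10.0}),
        objective="EX_rhl_e",
    )
    shares = pathway_attribution(
        toy_fa, sol, PathwaySets(TOY_PATHWAY_SETS), reporter="RHLS",
        pools={"acyl": "hdacp_c"},
    )
    # Acyl-carrier pool split at the optimum: 30 of 35 units come through
    # the external FA feed, 5 de novo (hand balance, oracle-checked).
    assert shares["fatty_acid_uptake"] == pytest.approx(6.0 / 7.0, abs=1e-5)
    assert shares["fatty_acid_pathway"] == pytest.approx(1.0 / 7.0, abs=1e-5)
    sugar = pathway_attribution(
        toy_fa, sol, PathwaySets(TOY_PATHWAY_SETS), reporter="RHLS",
        pools={"sugar": "g6p_c"},
    )
    # 35/6 of the 10 g6p feed the rhamnose branch.
    assert sugar["rhamnose_pathway"] == pytest.approx(35.0 / 60.0, abs=1e-5)


def test_attribution_empty_sets(toy):
    sol = mixed_substrate(toy, MediumSpec(uptakes={"EX_glc__D_e": 10.0}),
                          objective="EX_rhl_e")
    assert pathway_attribution(toy, sol, PathwaySets({}), reporter="RHLS") == {}


def test_attribution_zero_reporter_errors(toy_fa):
    sol = mixed_substrate(
        toy_fa, MediumSpec(closed_sources=["EX_glc__D_e", "EX_fa_e"]),
        objective="EX_rhl_e",
    )
    with pytest.raises(InputError):
        pathway_attribution(toy_fa, sol, PathwaySets(TOY_PATHWAY_SETS),
                            reporter="RHLS")


def test_pathway_sets_disjointness_enforced():
    with pytest.raises(ConfigurationError):
        PathwaySets({"a": ["PGM"], "b": ["PGM"]})


def test_compare_same_model_identical_columns(toy_fa):
    other = toy_model(ToyModelSpec(with_fa_source=True))
    table = compare_models(toy_fa, other, ["EX_glc__D_e", "EX_fa_e"],
                           objective_a="EX_rhl_e", objective_b="EX_rhl_e")
    assert table["flux_model_a"].tolist() == pytest.approx(
        table["flux_model_b"].tolist()
    )


def test_compare_partial_table_on_missing_transport(toy_fa, toy):
    # The second model has no FA exchange: its FA column fails with a
    # status message while the first model's column is still filled.
    table = compare_models(toy_fa, toy, ["EX_glc__D_e", "EX_fa_e"],
                           objective_a="EX_rhl_e", objective_b="EX_rhl_e")
    assert table.loc["EX_fa_e", "flux_model_a"] == pytest.approx(0.0, abs=1e-6)
    assert table.loc["EX_fa_e", "status_model_a"] == "ok"
    assert table.loc["EX_fa_e", "status_model_b"] != "ok"
    assert table.loc["EX_glc__D_e", "flux_model_b"] == pytest.approx(
        10.0 / 6.0, abs=1e-6
    )


def test_compare_symmetric_under_swap(toy_fa, toy):
    ab = compare_models(toy_fa, toy, ["EX_glc__D_e"],
                        objective_a="EX_rhl_e", objective_b="EX_rhl_e")
    ba = compare_models(toy, toy_fa, ["EX_glc__D_e"],
                        objective_a="EX_rhl_e", objective_b="EX_rhl_e")
    assert ab["flux_model_a"].tolist() == ba["flux_model_b"].tolist()
    assert ab["flux_model_b"].tolist() == ba["flux_model_a"].tolist()


def test_compare_empty_sources(toy_fa, toy):
    table = compare_models(toy_fa, toy, [])
    assert len(table) == 0
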