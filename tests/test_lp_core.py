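import numpy as np
import pandas as pd
import pytest

from fluxscreen.errors import InfeasibleModelError, ParameterError
from fluxscreen.lp_core import (
    OPTIMAL,
    fba,
    fva,
    flux_matrix,
    knockout_metabolite,
    ko_effect_matrix,
)
from fluxscreen.gpmm_bounds import BoundSet

from _oracles import (
    fba_oracle,
    fva_oracle,
    naive_ko_matrix,
    random_lp_model,
)


class TestFBA:
    def test_chain_bottleneck(self, chain_model):
        value, flux, status = fba(
            chain_model, chain_model.default_bounds(), "EX_B", "max"
        )
        assert status == OPTIMAL
        assert value == pytest.approx(3.0, abs=1e-6)
        assert flux["R1"] == pytest.approx(3.0, abs=1e-6)

    def test_closed_system_zero(self, chain_model):
        bounds = chain_model.default_bounds()
        bounds["EX_A"] = (0.0, 1000.0)
        value, _, status = fba(chain_model, bounds, "R1", "max")
        assert status == OPTIMAL
        assert value == pytest.approx(0.0, abs=1e-9)

    def test_constraint_satisfaction(self, branch_model):
        bounds = branch_model.default_bounds()
        _, flux, status = fba(branch_model, bounds, "EX_C", "max")
        assert status == OPTIMAL
        S, _, rxn_ids = branch_model.stoichiometric_matrix()
        assert np.allclose(S @ flux[rxn_ids].to_numpy(), 0.0, atol=1e-6)
        for j, r in enumerate(branch_model.reactions):
            assert bounds[r.id][0] - 1e-6 <= flux[r.id] <= bounds[r.id][1] + 1e-6

    def test_infeasible_reported_not_clamped(self, chain_model):
        bounds = chain_model.default_bounds()
        bounds["EX_A"] = (-5.0, -4.0)  # forced uptake 4..5
        bounds["R1"] = (0.0, 1.0)  # but can only drain 1
        value, flux, status = fba(chain_model, bounds, "EX_B", "max")
        assert status == "infeasible"
        assert np.isnan(value)

    def test_bad_sense_rejected(self, chain_model):
        with pytest.raises(ParameterError):
            fba(chain_model, chain_model.default_bounds(), "EX_B", "between")

    def test_unknown_objective(self, chain_model):
        with pytest.raises(KeyError):
            fba(chain_model, chain_model.default_bounds(), "nope", "max")

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_vertex_oracle(self, seed):
        model = random_lp_model(seed)
        S, _, rxn_ids = model.stoichiometric_matrix()
        lb = np.array([r.lb for r in model.reactions])
        ub = np.array([r.ub for r in model.reactions])
        rng = np.random.default_rng(seed + 1000)
        j = int(rng.integers(len(rxn_ids)))
        expected = fba_oracle(S, lb, ub, j, "max")
        value, _, status = fba(model, model.default_bounds(), rxn_ids[j], "max")
        if expected is None:
            assert status != OPTIMAL
        else:
            assert status == OPTIMAL
            assert value == pytest.approx(expected, abs=1e-6)

    def test_reproducible_to_1e9(self, branch_model):
        vals = [
            fba(branch_model, branch_model.default_bounds(), "EX_C", "max")[0]
            for _ in range(3)
        ]
        assert max(vals) - min(vals) < 1e-9


class TestFVA:
    def test_chain_range(self, chain_model):
        ranges = fva(chain_model, chain_model.default_bounds())
        assert ranges.loc["R1", "min"] == pytest.approx(0.0, abs=1e-6)
        assert ranges.loc["R1", "max"] == pytest.approx(3.0, abs=1e-6)

    def test_fixed_reaction(self, chain_model):
        bounds = chain_model.default_bounds()
        bounds["R1"] = (0.0, 0.0)
        ranges = fva(chain_model, bounds, ["R1"])
        assert tuple(ranges.loc["R1"]) == (0.0, 0.0)

    def test_infeasible_raises_with_exchanges(self, chain_model):
        bounds = chain_model.default_bounds()
        bounds["EX_A"] = (-5.0, -4.0)
        bounds["R1"] = (0.0, 1.0)
        with pytest.raises(InfeasibleModelError, match="EX_A"):
            fva(chain_model, bounds)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_vertex_oracle(self, seed):
        model = random_lp_model(seed)
        S, _, rxn_ids = model.stoichiometric_matrix()
        lb = np.array([r.lb for r in model.reactions])
        ub = np.array([r.ub for r in model.reactions])
        expected = fva_oracle(S, lb, ub)
        if expected is None:
            with pytest.raises(InfeasibleModelError):
                fva(model, model.default_bounds())
            return
        mins, maxs = expected
        ranges = fva(model, model.default_bounds())
        np.testing.assert_allclose(ranges["min"].to_numpy(), mins, atol=1e-6)
        np.testing.assert_allclose(ranges["max"].to_numpy(), maxs, atol=1e-6)

    def test_min_le_max_everywhere(self, toy_study):
        model = toy_study["model"]
        for bs in toy_study["bounded"][:3]:
            ranges = fva(model, bs)
            assert (ranges["min"] <= ranges["max"] + 1e-9).all()


class TestFluxMatrix:
    def test_columns_per_sample(self, toy_study):
        flux = flux_matrix(toy_study["model"], toy_study["bounded"][:4])
        assert list(flux.columns) == [b.sample_id for b in toy_study["bounded"][:4]]
        assert flux.attrs["provenance"] == "fva_max"

    def test_mid_summary(self, chain_model):
        bs = BoundSet("s1", chain_model.default_bounds())
        mid = flux_matrix(chain_model, [bs], summary="mid")
        full = fva(chain_model, bs)
        assert mid.loc["R1", "s1"] == pytest.approx(
            0.5 * (full.loc["R1", "min"] + full.loc["R1", "max"]), abs=1e-6
        )

    def test_bad_summary(self, chain_model):
        bs = BoundSet("s1", chain_model.default_bounds())
        with pytest.raises(ParameterError):
            flux_matrix(chain_model, [bs], summary="median")


class TestKnockoutMetabolite:
    def test_irreversible_consumer_closed(self, branch_model):
        ko = knockout_metabolite(branch_model, branch_model.default_bounds(), "A[c]")
        assert ko["R1"][1] == 0.0
        assert ko["R4"][1] == 0.0

    def test_only_produced_unchanged(self, branch_model):
        ko = knockout_metabolite(branch_model, branch_model.default_bounds(), "C[e]")
        assert ko == branch_model.default_bounds()  # EX_C is an exchange; untouched

    def test_reversible_consumer_lb_raised(self, branch_model):
        # R3: B[c] -> D[e]; reverse flux consumes D[e]
        ko = knockout_metabolite(branch_model, branch_model.default_bounds(), "D[e]")
        assert ko["R3"] == (0.0, 1000.0)
        # forward direction consumes B[c]
        ko_b = knockout_metabolite(branch_model, branch_model.default_bounds(), "B[c]")
        assert ko_b["R3"] == (-1000.0, 0.0)
        assert ko_b["R2"][1] == 0.0

    def test_exchanges_untouched(self, branch_model):
        ko = knockout_metabolite(branch_model, branch_model.default_bounds(), "A[e]")
        assert ko["EX_A"] == (-5.0, 1000.0)
        assert ko["T"][1] == 0.0

    def test_unknown_metabolite(self, branch_model):
        with pytest.raises(KeyError):
            knockout_metabolite(branch_model, branch_model.default_bounds(), "Z[c]")


class TestKOEffectMatrix:
    def test_carbon_source_ko_kills_downstream(self, chain_model):
        M = ko_effect_matrix(chain_model, chain_model.default_bounds())
        # A[e] consumed by R1 (internal): everything downstream drops
        assert M.loc["A[e]", "R1"] == -1
        assert M.loc["A[e]", "EX_B"] == -1

    def test_disconnected_metabolite_zero_row(self, branch_model):
        M = ko_effect_matrix(branch_model, branch_model.default_bounds())
        # C[e] is only consumed by its exchange: knocking it out changes nothing
        assert (M.loc["C[e]"] == 0).all()

    def test_values_in_pm1(self, branch_model):
        M = ko_effect_matrix(branch_model, branch_model.default_bounds())
        assert set(np.unique(M.to_numpy())) <= {-1, 0, 1}

    def test_matches_naive_oracle(self, branch_model):
        M = ko_effect_matrix(branch_model, branch_model.default_bounds())
        expected, met_ids, rxn_ids = naive_ko_matrix(
            branch_model, branch_model.default_bounds()
        )
        np.testing.assert_array_equal(
            M.loc[met_ids, rxn_ids].to_numpy(), expected
        )

    def test_ko_only_shrinks(self, toy_study):
        model = toy_study["model"]
        bounds = toy_study["bounded"][0]
        wt = fva(model, bounds, direction="max")["max"]
        for met in [m.id for m in model.metabolites][:6]:
            ko_bounds = knockout_metabolite(model, bounds, met)
            try:
                ko = fva(model, ko_bounds, direction="max")["max"]
            except InfeasibleModelError:
                continue
            assert (ko <= wt + 1e-6).all()
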