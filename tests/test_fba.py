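"""Stoichiometric matrix, ripening constraints, FBA and flux-range LPs."""

from __future__ import annotations

import numpy as np
import pytest

from fruitfba import (
    ModelValidationError,
    RipeningConfig,
    add_rqs_objective,
    apply_ripening_constraints,
    build_stoich_matrix,
    min_required_flux,
    parse_reaction_table,
    solve_fba,
    steady_state_residual,
)
from fruitfba.fba import RQS_ID, RQS_METABOLITES

from conftest import cobra_fba_optimum


class TestStoichMatrix:
    def test_two_reaction_chain(self):
        model = parse_reaction_table(
            "R1\ta_c --> b_c\t\t\nR2\tb_c --> c_c\t\t\n"
        )
        matrix = build_stoich_matrix(model)
        rows = {m: i for i, m in enumerate(matrix.metabolite_ids)}
        cols = {r: j for j, r in enumerate(matrix.reaction_ids)}
        expected = np.zeros((3, 2))
        expected[rows["a_c"], cols["R1"]] = -1
        expected[rows["b_c"], cols["R1"]] = 1
        expected[rows["b_c"], cols["R2"]] = -1
        expected[rows["c_c"], cols["R2"]] = 1
        assert np.array_equal(matrix.S, expected)

    def test_reference_gr_column_carries_two_gsh(self, reference_model):
        matrix = build_stoich_matrix(reference_model)
        j = matrix.reaction_index["GR_c"]
        i = matrix.metabolite_index["gsh_c"]
        assert matrix.S[i, j] == pytest.approx(2.0)
        column = matrix.S[:, j]
        assert np.count_nonzero(column) == len(
            reference_model.get_reaction("GR_c").stoichiometry
        )

    def test_empty_model_gives_empty_matrix(self):
        with pytest.warns(UserWarning):
            model = parse_reaction_table("")
        assert build_stoich_matrix(model).S.shape == (0, 0)


class TestRqsObjective:
    def test_rqs_consumes_four_traits_with_unit_coefficients(self, reference_model):
        model = add_rqs_objective(reference_model)
        rqs = model.get_reaction(RQS_ID)
        assert rqs.stoichiometry == {m: -1.0 for m in RQS_METABOLITES}
        assert not rqs.reversible
        assert len(model.reactions) == len(reference_model.reactions) + 1

    def test_adding_twice_is_an_error(self, reference_model):
        model = add_rqs_objective(reference_model)
        with pytest.raises(ModelValidationError, match=RQS_ID):
            add_rqs_objective(model)

    def test_missing_trait_metabolite_named_in_error(self, reference_model):
        crippled = reference_model.remove_reaction("ANS_c")
        # cyanidin_c only occurs in ANS_c, so it drops out of the model
        with pytest.raises(ModelValidationError, match="cyanidin_c"):
            add_rqs_objective(crippled)


class TestRipeningConstraints:
    def test_defaults_match_maintenance_regime(self, prepared_model):
        ngam = prepared_model.get_reaction("NGAM_c")
        assert ngam.lower_bound == pytest.approx(1.0)
        for pool_id in ("POOL_GLC", "POOL_QUINATE", "POOL_MET", "POOL_PECTIN"):
            assert prepared_model.get_reaction(pool_id).upper_bound == pytest.approx(10.0)
        for blocked in ("POOL_CITRATE", "POOL_CHLOROGENATE"):
            reaction = prepared_model.get_reaction(blocked)
            assert (reaction.lower_bound, reaction.upper_bound) == (0.0, 0.0)

    def test_non_positive_ngam_rejected(self):
        with pytest.raises(ModelValidationError):
            RipeningConfig(ngam_lower_bound=0.0)

    def test_unknown_reaction_ids_rejected(self, reference_model):
        model = add_rqs_objective(reference_model)
        with pytest.raises(KeyError):
            apply_ripening_constraints(model, RipeningConfig(ngam_reaction_id="NOPE"))
        with pytest.raises(KeyError):
            apply_ripening_constraints(
                model, RipeningConfig(blocked_pools=frozenset({"POOL_NOPE"}))
            )

    def test_config_json_round_trip(self):
        config = RipeningConfig(ngam_lower_bound=2.5, pool_upper_bound=7.0)
        assert RipeningConfig.from_json(config.to_json()) == config


class TestSolveFba:
    def test_bound_limited_chain(self, toy_models):
        model, objective, optimum = toy_models[0]
        solution = solve_fba(model, objective, "max")
        assert solution.status == "optimal"
        assert solution.objective_value == pytest.approx(optimum)

    def test_oracle_equivalence_on_toys_and_reference(self, toy_models, prepared_model):
        """FBA optima agree with an independent constraint-based library to 1e-6."""
        for model, objective, _ in toy_models:
            ours = solve_fba(model, objective, "max").objective_value
            theirs = cobra_fba_optimum(model, objective, "max")
            assert ours == pytest.approx(theirs, abs=1e-6)
        ours = solve_fba(prepared_model, RQS_ID, "max").objective_value
        theirs = cobra_fba_optimum(prepared_model, RQS_ID, "max")
        assert ours > 0
        assert ours == pytest.approx(theirs, abs=1e-6)

    def test_steady_state_and_bounds_hold_at_optimum(self, prepared_model, toy_models):
        for model, objective in [(prepared_model, RQS_ID)] + [
            (m, obj) for m, obj, _ in toy_models
        ]:
            solution = solve_fba(model, objective, "max")
            assert solution.status == "optimal"
            assert steady_state_residual(model, solution) <= 1e-6
            for reaction in model.reactions:
                flux = solution.fluxes[reaction.id]
                assert reaction.lower_bound - 1e-6 <= flux <= reaction.upper_bound + 1e-6

    def test_tightening_a_bound_never_increases_the_optimum(self, prepared_model):
        base = solve_fba(prepared_model, RQS_ID, "max").objective_value
        for pool_id, cap in [("POOL_GLC", 2.0), ("POOL_QUINATE", 1.5), ("POOL_MET", 0.5)]:
            tightened = prepared_model.copy()
            tightened.get_reaction(pool_id).upper_bound = cap
            reduced = solve_fba(tightened, RQS_ID, "max").objective_value
            assert reduced <= base + 1e-9

    def test_hqt_deletion_abolishes_ripening_output(self, reference_model):
        model = apply_ripening_constraints(
            add_rqs_objective(reference_model.remove_reaction("HQT_c"))
        )
        solution = solve_fba(model, RQS_ID, "max")
        assert (not solution.optimal) or solution.objective_value == pytest.approx(0.0)

    def test_infeasible_is_reported_not_zeroed(self, prepared_model):
        model = prepared_model.copy()
        # demand more RQS flux than the pools can support
        model.get_reaction(RQS_ID).lower_bound = 100.0
        solution = solve_fba(model, RQS_ID, "max")
        assert solution.status == "infeasible"
        assert solution.fluxes == {}

    def test_zero_demand_limit_all_zero_is_feasible(self, reference_model):
        model = add_rqs_objective(reference_model)  # NGAM floor not applied
        model.get_reaction(RQS_ID).upper_bound = 0.0
        solution = solve_fba(model, RQS_ID, "min")
        assert solution.status == "optimal"
        assert max(abs(v) for v in solution.fluxes.values()) == pytest.approx(0.0)


class TestMinRequiredFlux:
    def test_unique_route_reaction_is_required(self, prepared_model):
        assert min_required_flux(prepared_model, "HQT_c", 1.0) == pytest.approx(1.0)
        assert min_required_flux(prepared_model, "QDH_c", 1.0) == pytest.approx(2.0)

    def test_parallel_duplicated_path_is_not_required(self):
        text = (
            "id\tequation\tgpr\tsubsystem\tlb\tub\n"
            "POOL_A\t --> chlorogenate_c\t\t\t0\t10\n"
            "POOL_B\t --> cyanidin_c\t\t\t0\t10\n"
            "POOL_C\t --> ethylene_c\t\t\t0\t10\n"
            "POOL_D\t --> x_c\t\t\t0\t10\n"
            "RA\tx_c --> galacturonate_c\t\t\n"
            "RB\tx_c --> galacturonate_c\t\t\n"
        )
        model = add_rqs_objective(parse_reaction_table(text))
        assert min_required_flux(model, "RA", 1.0) == 0.0
        assert min_required_flux(model, "RB", 1.0) == 0.0
        # but the shared upstream supply is required
        assert min_required_flux(model, "POOL_D", 1.0) == pytest.approx(1.0)

    def test_zero_floor_requires_nothing_beyond_maintenance(self, prepared_model):
        for rid in ("HQT_c", "QDH_c", "EPSPS_c", "CAS_c", "GR_c"):
            assert min_required_flux(prepared_model, rid, 0.0) == 0.0
        # NGAM keeps respiration alive even at zero ripening output
        assert min_required_flux(prepared_model, "ACO_m", 0.0) > 0.0

    def test_infeasible_floor_raises(self, prepared_model):
        with pytest.raises(ModelValidationError):
            min_required_flux(prepared_model, "HQT_c", 1e6)
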