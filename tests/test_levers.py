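"""Weighted minimum-flux LP and regulatory-lever detection."""

from __future__ import annotations

import pytest

from fruitfba import (
    AnalysisConfig,
    ExpressionContrast,
    ModelValidationError,
    ReactionClass,
    add_rqs_objective,
    apply_ripening_constraints,
    classify_model_reactions,
    detect_levers,
    min_required_flux,
    min_weighted_flux,
    normalize_solution,
    parse_reaction_table,
    run_contrast_analysis,
    scenario_contrast,
    weights_from_classes,
)
from fruitfba.fba import RQS_ID

#: Admissible alternative weight schemes (ordering holds, max/min ratio ≤ 10).
ALT_SCHEMES = [
    {"down": 5.0, "mixed": 2.0, "neutral": 1.0, "up": 0.9},
    {"down": 1.2, "mixed": 1.1, "neutral": 1.0, "up": 0.8},
]


@pytest.fixture()
def parallel_routes_model():
    """Two equal-length routes to the same product, distinguishable by weight."""
    text = (
        "id\tequation\tgpr\tsubsystem\tlb\tub\n"
        "POOL_A\t --> a_c\t\t\t0\t10\n"
        "POOL_B\t --> chlorogenate_c\t\t\t0\t10\n"
        "POOL_C\t --> cyanidin_c\t\t\t0\t10\n"
        "POOL_D\t --> ethylene_c\t\t\t0\t10\n"
        "R_CHEAP\ta_c --> galacturonate_c\tgCheap\t\n"
        "R_DEAR\ta_c --> galacturonate_c\tgDear\t\n"
    )
    return add_rqs_objective(parse_reaction_table(text))


class TestMinWeightedFlux:
    def test_flux_avoids_the_penalized_parallel_route(self, parallel_routes_model):
        weights = {r: 1.0 for r in parallel_routes_model.reaction_ids}
        weights["R_DEAR"] = 2.0
        solution = min_weighted_flux(parallel_routes_model, weights, rqs_target=1.0)
        assert solution.optimal
        assert solution.fluxes["R_CHEAP"] == pytest.approx(1.0)
        assert solution.fluxes["R_DEAR"] == pytest.approx(0.0)

    def test_uniform_weights_reduce_to_total_flux_minimum(self, prepared_model):
        uniform = {r: 1.0 for r in prepared_model.reaction_ids}
        solution = min_weighted_flux(prepared_model, uniform, rqs_target=1.0)
        assert solution.optimal
        total = sum(abs(v) for v in solution.fluxes.values())
        assert solution.objective_value == pytest.approx(total, abs=1e-5)
        assert solution.fluxes[RQS_ID] == pytest.approx(1.0)

    def test_hqt_carries_forward_flux_despite_down_class(self, prepared_model):
        """The phenylpropanoid entry stays active even when penalized."""
        contrast = scenario_contrast("MG_E1vsE2", seed=3)
        from fruitfba import classify_genes

        classes = classify_model_reactions(
            prepared_model, classify_genes(contrast), warn_missing=False
        )
        assert classes["HQT_c"] is ReactionClass.DOWN
        weights = weights_from_classes(prepared_model, classes)
        solution = min_weighted_flux(prepared_model, weights, rqs_target=1.0)
        assert solution.fluxes["HQT_c"] == pytest.approx(1.0)

    def test_errors(self, prepared_model):
        uniform = {r: 1.0 for r in prepared_model.reaction_ids}
        with pytest.raises(ModelValidationError):
            min_weighted_flux(prepared_model, uniform, rqs_target=-1.0)
        bad = dict(uniform, HQT_c=0.0)
        with pytest.raises(ModelValidationError):
            min_weighted_flux(prepared_model, bad, rqs_target=1.0)
        assert min_weighted_flux(prepared_model, uniform, 1e6).status == "infeasible"


class TestNormalization:
    def test_rqs_normalizes_to_one_and_scaling_cancels(self, prepared_model):
        uniform = {r: 1.0 for r in prepared_model.reaction_ids}
        for target in (0.5, 1.0, 2.0):
            solution = min_weighted_flux(prepared_model, uniform, rqs_target=target)
            normalized = normalize_solution(solution, solution.fluxes[RQS_ID])
            assert normalized[RQS_ID] == pytest.approx(1.0)
            assert normalized["HQT_c"] == pytest.approx(1.0)
            assert normalized["QDH_c"] == pytest.approx(2.0)

    def test_non_positive_basis_rejected(self, prepared_model):
        uniform = {r: 1.0 for r in prepared_model.reaction_ids}
        solution = min_weighted_flux(prepared_model, uniform, rqs_target=1.0)
        with pytest.raises(ModelValidationError):
            normalize_solution(solution, 0.0)


class TestDetectLevers:
    def test_all_neutral_classes_give_no_levers(self, prepared_model):
        classes = {r: ReactionClass.NEUTRAL for r in prepared_model.reaction_ids}
        weights = weights_from_classes(prepared_model, classes)
        assert detect_levers(prepared_model, weights, classes) == []

    def test_lever_set_is_down_and_required(self, prepared_model):
        classes = {r: ReactionClass.NEUTRAL for r in prepared_model.reaction_ids}
        classes["HQT_c"] = ReactionClass.DOWN     # required → lever
        classes["PK_c"] = ReactionClass.DOWN      # bypassable? no: still required
        classes["CITtm"] = ReactionClass.DOWN     # blocked route → not a lever
        weights = weights_from_classes(prepared_model, classes)
        levers = {r.reaction_id: r for r in detect_levers(prepared_model, weights, classes)}
        assert "HQT_c" in levers and levers["HQT_c"].direction == "forward"
        assert "CITtm" not in levers
        for record in levers.values():
            assert record.required and record.reaction_class is ReactionClass.DOWN
            assert min_required_flux(prepared_model, record.reaction_id, 1.0) > 1e-6

    def test_requiredness_is_weight_scheme_invariant(self, prepared_model):
        """The required set is structural; weights only shape the solution."""
        contrast = scenario_contrast("RP_E3vsE4", seed=5)
        reference_sets = []
        for scheme in [None] + ALT_SCHEMES:
            config = AnalysisConfig(weight_scheme=scheme)
            report = run_contrast_analysis(prepared_model, contrast, config)
            records = report.levers_by_contrast["RP_E3vsE4"]
            reference_sets.append(
                {(r.reaction_id, r.direction, round(r.normalized_magnitude, 6))
                 for r in records}
            )
        assert reference_sets[0] == reference_sets[1] == reference_sets[2]

    def test_penalized_reaction_with_alternative_route_is_silenced(
        self, parallel_routes_model
    ):
        classes = {r: ReactionClass.NEUTRAL for r in parallel_routes_model.reaction_ids}
        classes["R_DEAR"] = ReactionClass.DOWN
        weights = weights_from_classes(parallel_routes_model, classes)
        solution = min_weighted_flux(parallel_routes_model, weights, 1.0)
        assert solution.fluxes["R_DEAR"] == pytest.approx(0.0)
        assert detect_levers(parallel_routes_model, weights, classes,
                             solution=solution) == []


class TestRunContrastAnalysis:
    def test_mg_e1e2_levers_and_directions(self, reference_model):
        contrast = scenario_contrast("MG_E1vsE2", seed=11)
        report = run_contrast_analysis(reference_model, contrast)
        records = {r.reaction_id: r for r in report.levers_by_contrast["MG_E1vsE2"]}
        assert set(records) == {"CAS_c", "EPSPS_c", "HQT_c", "QDH_c"}
        assert records["HQT_c"].direction == "forward"
        assert records["HQT_c"].normalized_magnitude == pytest.approx(1.0)
        assert records["QDH_c"].direction == "reverse"
        assert records["QDH_c"].normalized_magnitude == pytest.approx(2.0)
        assert report.metadata["rqs_fba_maximum"] > 1.0

    def test_qdh_not_a_lever_after_chilling_in_rp_yet_still_flows(self, reference_model):
        contrast = scenario_contrast("RP_E3vsE4", seed=11)
        report = run_contrast_analysis(reference_model, contrast)
        records = {r.reaction_id for r in report.levers_by_contrast["RP_E3vsE4"]}
        assert "QDH_c" not in records  # its gene is up-regulated here
        assert min_required_flux(
            apply_ripening_constraints(add_rqs_objective(reference_model)),
            "QDH_c", 1.0,
        ) == pytest.approx(2.0)  # flux itself is still obligatory

    def test_all_neutral_contrast_yields_empty_report(self, reference_model):
        contrast = ExpressionContrast(
            "flat", {g: (0.0, False) for g in reference_model.genes}
        )
        report = run_contrast_analysis(reference_model, contrast)
        assert report.levers_by_contrast["flat"] == []
        assert report.lever_union == set()

    def test_infeasible_target_raises(self, reference_model):
        contrast = scenario_contrast("MG_E1vsE2", seed=1)
        with pytest.raises(ModelValidationError, match="not sustainable"):
            run_contrast_analysis(
                reference_model, contrast, AnalysisConfig(rqs_target=50.0)
            )

    def test_report_frame_and_json_shapes(self, reference_model):
        contrast = scenario_contrast("MG_E3vsE4", seed=2)
        report = run_contrast_analysis(reference_model, contrast)
        frame = report.to_frame()
        assert list(frame.columns) == [
            "reaction_id", "contrast", "class", "required",
            "normalized_magnitude", "direction",
        ]
        assert set(frame["reaction_id"]) == {"HQT_c", "QDH_c"}
        import json

        payload = json.loads(report.to_json())
        assert payload["metadata"]["rqs_target"] == 1.0
        assert {r["reaction_id"] for r in payload["levers"]["MG_E3vsE4"]} \
            == {"HQT_c", "QDH_c"}
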