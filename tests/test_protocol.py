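"""Time tables, sentinel semantics, plan synthesis and flowchart export."""

import math

import pytest

from ammokin import (
    DistributionVolume,
    TableSentinel,
    TreatmentGoals,
    VolumeSource,
    build_time_table,
    export_flowchart,
    parse_structured_plan,
    recommend_setup,
    round_minutes,
    synthesize_plan,
    time_to_target,
)
from ammokin.errors import ConfigurationError
from reference_tables import BLOOD_FLOWS, STARTS, TABLE_3KG, THRESHOLDS


@pytest.fixture
def table_3kg(menu, v_3kg):
    return build_time_table(v_3kg, menu, STARTS, THRESHOLDS, BLOOD_FLOWS)


class TestTimeTable:
    def test_reference_cells_reproduced(self, table_3kg):
        """All numeric published 3 kg cells match within max(±5 min, ±1 %)."""
        for (setup, thr, start, qb), expected in TABLE_3KG.items():
            got = table_3kg.cell(setup, thr, start, qb)
            assert isinstance(got, int), (setup, thr, start, qb, got)
            tol = max(5, 0.01 * expected)
            assert abs(got - expected) <= tol, (setup, thr, start, qb, got)

    def test_not_applicable_iff_start_at_or_below_threshold(self, table_3kg, menu):
        for option in menu:
            for thr in THRESHOLDS:
                for start in STARTS:
                    cell = table_3kg.cell(option.label, thr, start, 30)
                    if start <= thr:
                        assert cell is TableSentinel.NOT_APPLICABLE
                    else:
                        assert cell is not TableSentinel.NOT_APPLICABLE

    def test_exceeds_horizon_iff_exact_time_beyond_horizon(self, table_3kg,
                                                           menu, v_3kg):
        for option in menu:
            for thr in THRESHOLDS:
                for start in STARTS:
                    if start <= thr:
                        continue
                    exact = time_to_target(start, thr,
                                           option.extraction_ratio * 30, v_3kg)
                    cell = table_3kg.cell(option.label, thr, start, 30)
                    if exact > 1440:
                        assert cell is TableSentinel.EXCEEDS_HORIZON
                    else:
                        assert cell == round_minutes(exact)

    def test_flow_outside_machine_range_is_not_applicable(self, menu, v_3kg):
        # the 4008 cannot run below 30 mL/min
        table = build_time_table(v_3kg, menu, [800], [400], [20, 30])
        assert table.cell("4008/FXPaed", 400, 800, 20) is \
            TableSentinel.NOT_APPLICABLE
        assert isinstance(table.cell("CD025", 400, 800, 20), int)

    def test_deterministic(self, menu, v_3kg):
        a = build_time_table(v_3kg, menu, STARTS, THRESHOLDS, BLOOD_FLOWS)
        b = build_time_table(v_3kg, menu, STARTS, THRESHOLDS, BLOOD_FLOWS)
        assert a.cells == b.cells

    def test_csv_export_uses_sentinel_strings(self, table_3kg, tmp_path):
        out = tmp_path / "table.csv"
        table_3kg.to_csv(out)
        text = out.read_text()
        assert ">>" in text and ",-," in text
        assert "322" in text


@pytest.fixture
def example_plan(reference_infant, local_goals, menu):
    """Staged plan for the 3 kg infant over the 4008 + CD025 menu."""
    dv = DistributionVolume(volume=2160, source=VolumeSource.explicit_volume)
    return synthesize_plan(reference_infant, dv, 3000.0, local_goals,
                           [menu[0], menu[1]])


class TestSynthesizePlan:
    def test_high_band_requires_the_high_clearance_setup(self, reference_infant,
                                                         local_goals, menu):
        dv = DistributionVolume(volume=2160, source=VolumeSource.explicit_volume)
        plan = synthesize_plan(reference_infant, dv, 3000.0, local_goals, menu)
        # only the 4008 reaches <400 µmol/L within 4 h from 3000
        assert plan.stages[0].setup.machine == "4008"
        assert plan.stages[0].feasible
        assert plan.feasible

    def test_example_plan_matches_reference_flowchart(self, example_plan):
        bands = [(s.band_low, s.band_high) for s in example_plan.stages]
        assert bands == [(400.0, math.inf), (200.0, 400.0), (0.0, 200.0)]
        assert example_plan.stages[0].blood_flow_rule == 15.0
        assert example_plan.stages[1].blood_flow_rule == 10.0
        assert example_plan.stages[2].setup.dialyzer == "HCD 025"

    def test_trivial_goals_pick_least_intensive(self, reference_infant, menu):
        dv = DistributionVolume(volume=2160, source=VolumeSource.explicit_volume)
        goals = TreatmentGoals(goals=((400.0, 100000.0),), rebound_limit=200.0)
        plan = synthesize_plan(reference_infant, dv, 3000.0, goals, menu)
        # every setup satisfies the goal; CD015 has the smallest clearance
        assert plan.stages[0].setup.dialyzer == "HCD 015"

    def test_unattainable_goal_flags_infeasible_but_recommends_fastest(
            self, reference_infant, menu):
        dv = DistributionVolume(volume=2160, source=VolumeSource.explicit_volume)
        goals = TreatmentGoals(goals=((400.0, 60.0),), rebound_limit=200.0)
        plan = synthesize_plan(reference_infant, dv, 3000.0, goals, menu)
        assert not plan.stages[0].feasible
        assert plan.stages[0].setup.machine == "4008"
        assert not plan.feasible

    def test_feasible_stages_are_sound(self, example_plan):
        """Re-check every feasible goal stage against time_to_target."""
        v = 2160.0
        seg_start = 3000.0
        for stage, (threshold, max_time) in zip(example_plan.stages,
                                                example_plan.goals.goals):
            if stage.feasible:
                t = time_to_target(seg_start, threshold,
                                   stage.setup.resolved_clearance, v)
                assert t <= max_time
            seg_start = threshold

    def test_determinism(self, reference_infant, local_goals, menu):
        dv = DistributionVolume(volume=2160, source=VolumeSource.explicit_volume)
        a = synthesize_plan(reference_infant, dv, 3000.0, local_goals, menu)
        b = synthesize_plan(reference_infant, dv, 3000.0, local_goals, menu)
        assert a == b


class TestRecommendSetup:
    def test_high_concentration_gets_4008_at_15_ml_kg_min(self, example_plan):
        stage = recommend_setup(1500.0, example_plan)
        assert stage.setup.machine == "4008"
        assert stage.blood_flow_rule == 15.0

    def test_low_concentration_gets_carpediem_025(self, example_plan):
        stage = recommend_setup(150.0, example_plan)
        assert stage.setup.machine == "CarpeDiem"
        assert stage.setup.dialyzer == "HCD 025"
        assert stage.blood_flow_rule == 10.0

    def test_boundary_belongs_to_lower_band(self, example_plan):
        # bands are (low, high]: exactly 400 is in the 200-400 band
        stage = recommend_setup(400.0, example_plan)
        assert stage.band_high == 400.0

    def test_nonpositive_concentration_has_no_band(self, example_plan):
        with pytest.raises(ConfigurationError):
            recommend_setup(0.0, example_plan)


class TestFlowchartExport:
    def test_structured_round_trip_is_identity(self, example_plan):
        doc = export_flowchart(example_plan, "structured")
        assert parse_structured_plan(doc) == example_plan

    def test_dot_has_one_node_per_stage(self, example_plan):
        dot = export_flowchart(example_plan, "dot")
        assert dot.startswith("digraph")
        assert dot.count("[label=") == 3 + 2  # 3 stage nodes + 2 edges
        assert "stage0 -> stage1" in dot and "stage1 -> stage2" in dot
        assert "C <= 400" in dot

    def test_single_stage_plan_has_no_edges(self, local_goals, menu):
        from ammokin import ProtocolPlan, ProtocolStage
        stage = ProtocolStage(band_low=0.0, band_high=math.inf,
                              setup=menu[0].at_flow(30), blood_flow_rule=10.0)
        plan = ProtocolPlan(stages=(stage,), goals=local_goals,
                            patient_band=(2.0, 4.0))
        dot = export_flowchart(plan, "dot")
        assert "->" not in dot

    def test_unknown_format_is_a_usage_error(self, example_plan):
        with pytest.raises(ValueError):
            export_flowchart(example_plan, "pdf")
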