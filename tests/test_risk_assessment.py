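"""Risk-score engine: schema validation, unknown handling, category bands."""

import pytest
import yaml

from invrisk.risk_assessment import (
    ATTRIBUTE_GROUPS,
    CATEGORIES,
    Criterion,
    CriteriaSchema,
    SchemaError,
    Scorecard,
    ScoringError,
    categorize,
    category_rank,
    load_schema,
    total_score,
)


@pytest.fixture(scope="module")
def schema():
    return load_schema()


def full_card(schema, level="max"):
    answers = {}
    for c in schema.criteria:
        if level == "max":
            answers[c.id] = max(c.levels.values())
        elif level == "min":
            answers[c.id] = 0.0
    return Scorecard(species="test species", answers=answers)


class TestDefaultSchema:
    def test_21_criteria_4_groups(self, schema):
        assert len(schema) == 21
        assert set(c.group for c in schema.criteria) == set(ATTRIBUTE_GROUPS)

    def test_total_100_points(self, schema):
        assert schema.total_max_points == pytest.approx(100.0)

    def test_every_level_within_bounds(self, schema):
        for c in schema.criteria:
            assert all(0 <= pts <= c.max_points for pts in c.levels.values())


class TestSchemaValidation:
    def base_criteria(self):
        return [
            Criterion("a", "", "ecological impact", 10, {"yes": 10, "no": 0}),
            Criterion("b", "", "invasive characteristics", 10, {"yes": 10, "no": 0}),
            Criterion("c", "", "dispersal ability", 10, {"yes": 10, "no": 0}),
            Criterion("d", "", "feasibility of control", 10, {"yes": 10, "no": 0}),
        ]

    def test_unknown_group_rejected(self):
        crits = self.base_criteria()
        crits[0].group = "economic impact"
        with pytest.raises(SchemaError, match="economic impact"):
            CriteriaSchema("s", crits)

    def test_missing_group_rejected(self):
        crits = self.base_criteria()
        crits[3].group = "ecological impact"
        with pytest.raises(SchemaError, match="4 attribute groups"):
            CriteriaSchema("s", crits)

    def test_duplicate_ids_rejected(self):
        crits = self.base_criteria()
        crits[1].id = "a"
        with pytest.raises(SchemaError, match="duplicate"):
            CriteriaSchema("s", crits)

    def test_negative_max_points_rejected(self):
        crits = self.base_criteria()
        crits[2] = Criterion("c", "", "dispersal ability", -5, {})
        with pytest.raises(SchemaError, match="negative"):
            CriteriaSchema("s", crits)

    def test_level_points_above_max_rejected(self):
        crits = self.base_criteria()
        crits[0] = Criterion("a", "", "ecological impact", 10, {"yes": 15})
        with pytest.raises(SchemaError, match="a:yes"):
            CriteriaSchema("s", crits)

    def test_load_from_yaml_file(self, tmp_path):
        doc = {
            "name": "mini",
            "criteria": [
                {"id": "a", "group": "ecological impact", "max_points": 10, "levels": {"hi": 10}},
                {"id": "b", "group": "invasive characteristics", "max_points": 5, "levels": {"hi": 5}},
                {"id": "c", "group": "dispersal ability", "max_points": 5, "levels": {"hi": 5}},
                {"id": "d", "group": "feasibility of control", "max_points": 5, "levels": {"hi": 5}},
            ],
        }
        path = tmp_path / "schema.yml"
        path.write_text(yaml.safe_dump(doc))
        loaded = load_schema(path)
        assert len(loaded) == 4 and loaded.name == "mini"


class TestTotalScore:
    def test_all_max_scores_100(self, schema):
        res = total_score(full_card(schema, "max"), schema)
        assert res.score == pytest.approx(100.0)
        assert res.category == "Extremely Invasive"
        assert res.answered_fraction == 1.0

    def test_all_zero_scores_0(self, schema):
        res = total_score(full_card(schema, "min"), schema)
        assert res.score == pytest.approx(0.0)
        assert res.category == "Very Weakly Invasive"

    def test_unknowns_excluded_from_both_sides(self, schema):
        # answer criteria worth exactly 50 points, earning 30
        answers: dict = {}
        remaining = 30.0
        total_max = 0.0
        for c in schema.criteria:
            if total_max + c.max_points <= 50.0:
                earned = min(remaining, c.max_points)
                answers[c.id] = earned
                remaining -= earned
                total_max += c.max_points
            else:
                answers[c.id] = "unknown"
        assert total_max == pytest.approx(50.0) and remaining == 0.0
        res = total_score(Scorecard("sp", answers), schema)
        assert res.score == pytest.approx(60.0)
        assert res.answered_fraction < 1.0

    def test_level_labels_resolve_to_points(self, schema):
        answers = {c.id: "unknown" for c in schema.criteria}
        answers["imp_ecosystem"] = "severe"  # 10 of 10
        answers["ctl_cost"] = "low"  # 0 of 2
        res = total_score(Scorecard("sp", answers), schema, min_answered_fraction=0.0)
        assert res.score == pytest.approx(100.0 * 10.0 / 12.0)

    def test_insufficient_information_flag(self, schema):
        answers = {c.id: "unknown" for c in schema.criteria}
        answers["imp_ecosystem"] = "severe"
        res = total_score(Scorecard("sp", answers), schema)
        assert res.insufficient_information

    def test_no_answers_rejected(self, schema):
        card = Scorecard("sp", {c.id: "unknown" for c in schema.criteria})
        with pytest.raises(ScoringError, match="no scorable"):
            total_score(card, schema)

    def test_unknown_criterion_id_rejected(self, schema):
        with pytest.raises(ScoringError, match="nonexistent"):
            total_score(Scorecard("sp", {"nonexistent": 3}), schema)

    def test_group_subtotals_sum_to_total(self, schema):
        res = total_score(full_card(schema, "max"), schema)
        earned = sum(e for e, _ in res.group_subtotals.values())
        mx = sum(m for _, m in res.group_subtotals.values())
        assert earned == pytest.approx(mx) == pytest.approx(100.0)

    def test_monotone_in_any_single_answer(self, schema):
        answers = {c.id: 0.0 for c in schema.criteria}
        base = total_score(Scorecard("sp", answers), schema)
        for cid in ("imp_trophic", "dsp_human", "ctl_eradication"):
            raised = dict(answers)
            raised[cid] = schema.criterion(cid).max_points
            res = total_score(Scorecard("sp", raised), schema)
            assert res.score >= base.score
            assert category_rank(res.category) >= category_rank(base.category)

    def test_scale_invariance(self, schema):
        answers = {c.id: c.max_points / 2.0 for c in schema.criteria}
        base = total_score(Scorecard("sp", answers), schema)
        scaled_criteria = [
            Criterion(c.id, c.prompt, c.group, c.max_points * 3.0,
                      {k: v * 3.0 for k, v in c.levels.items()})
            for c in schema.criteria
        ]
        scaled_schema = CriteriaSchema("scaled", scaled_criteria)
        scaled_answers = {k: v * 3.0 for k, v in answers.items()}
        res = total_score(Scorecard("sp", scaled_answers), scaled_schema)
        assert res.score == pytest.approx(base.score)


class TestCategorize:
    @pytest.mark.parametrize(
        "score,expected",
        [
            (39.999, "Very Weakly Invasive"),
            (40.0, "Weakly Invasive"),
            (49.999, "Weakly Invasive"),
            (50.0, "Modestly Invasive"),
            (59.999, "Modestly Invasive"),
            (60.0, "Moderately Invasive"),
            (69.999, "Moderately Invasive"),
            (70.0, "Highly Invasive"),
            (79.0, "Highly Invasive"),
            (79.999, "Highly Invasive"),
            (80.0, "Extremely Invasive"),
            (100.0, "Extremely Invasive"),
            (0.0, "Very Weakly Invasive"),
        ],
    )
    def test_band_edges(self, score, expected):
        assert categorize(score) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ScoringError):
            categorize(-0.1)
        with pytest.raises(ScoringError):
            categorize(100.1)

    def test_category_order(self):
        assert CATEGORIES[-1] == "Extremely Invasive"
        assert category_rank("Extremely Invasive") > category_rank("Highly Invasive")
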