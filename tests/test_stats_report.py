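import json

import numpy as np
import pandas as pd
import pytest

from nerveflux.stats_report import (
    aggregate_by_animal,
    build_report,
    classify_hyperglycemia,
    compare_groups,
    compare_two_factor,
    energy_map_table,
    hyperglycemia_table,
    is_censored_glucose,
    significance_tier,
    trace_summary_table,
)
from nerveflux.synthetic_data import default_config, simulate_phenotype


def well_table():
    return pd.DataFrame(
        {
            "well_id": ["w1", "w2", "w3", "w4"],
            "animal_id": ["a1", "a1", "a2", "a2"],
            "group": ["ctrl"] * 4,
            "side": ["left", "right", "left", "right"],
            "basal": [18.0, 22.0, 30.0, 34.0],
            "last_basal": [28.0, 32.0, 40.0, 44.0],
            "basal_ecar": [20.0, 24.0, 30.0, 34.0],
        }
    )


class TestAggregate:
    def test_pooled_mean(self):
        out = aggregate_by_animal(well_table())
        assert out.set_index("animal_id").loc["a1", "basal"] == 20.0
        assert (out["n_wells_included"] == 2).all()

    def test_well_order_invariance(self):
        t = well_table()
        shuffled = t.sample(frac=1, random_state=3)
        pd.testing.assert_frame_equal(
            aggregate_by_animal(t), aggregate_by_animal(shuffled)
        )

    def test_balanced_sides_pooled_equals_mean_of_side_means(self):
        t = well_table()
        pooled = aggregate_by_animal(t).set_index("animal_id")["basal"]
        by_side = aggregate_by_animal(t, by_side=True)
        side_means = by_side.groupby("animal_id")["basal"].mean()
        pd.testing.assert_series_equal(pooled, side_means, check_names=False)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            aggregate_by_animal(well_table().iloc[:0])


class TestCompareGroups:
    def _summaries(self, g1, g2):
        return pd.DataFrame(
            {
                "animal_id": [f"a{i}" for i in range(len(g1) + len(g2))],
                "group": ["g1"] * len(g1) + ["g2"] * len(g2),
                "metric": g1 + g2,
            }
        )

    def test_closed_form_student_t(self):
        out = compare_groups(self._summaries([1, 2, 3], [4, 5, 6]), ["metric"])
        row = out.iloc[0]
        assert row["statistic"] == pytest.approx(-3.6742, abs=1e-4)
        assert row["p_value"] == pytest.approx(0.02131, abs=1e-4)
        assert row["significance"] == "*"
        assert row["test"] == "student_t"

    def test_identical_groups_null(self):
        out = compare_groups(self._summaries([1, 2, 3], [1, 2, 3]), ["metric"])
        assert out.iloc[0]["statistic"] == pytest.approx(0.0)
        assert out.iloc[0]["p_value"] == pytest.approx(1.0)

    def test_mean_sd_reported(self):
        out = compare_groups(self._summaries([1, 2, 3], [4, 5, 6]), ["metric"])
        assert out.iloc[0]["mean_1"] == 2.0 and out.iloc[0]["sd_1"] == 1.0

    def test_welch_flag(self):
        out = compare_groups(self._summaries([1, 2, 3], [4, 5, 9]), ["metric"], welch=True)
        assert out.iloc[0]["test"] == "welch_t"

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_groups(self._summaries([1], [4, 5, 6]), ["metric"])

    def test_three_groups_rejected(self):
        df = self._summaries([1, 2], [3, 4])
        df.loc[len(df)] = ["a9", "g3", 9]
        with pytest.raises(ValueError, match="exactly 2"):
            compare_groups(df, ["metric"])


class TestTwoFactor:
    def test_genotype_week_design(self):
        pheno = simulate_phenotype(default_config(seed=12, n_animals_per_group=8))
        anova, pairwise = compare_two_factor(pheno, "blood_glucose_mM")
        # strong genotype effect on glucose in the emulated design
        a = anova.set_index("term")
        assert a.loc["C(A)", "PR(>F)"] < 1e-6
        assert len(pairwise) == 4  # 2x2 design -> 4 within-level comparisons
        assert (pairwise["p_sidak"] >= pairwise["p_value"] - 1e-12).all()
        for _, row in pairwise.iterrows():
            assert row["significance"] == significance_tier(row["p_sidak"])

    def test_sidak_adjustment_formula(self):
        pheno = simulate_phenotype(default_config(seed=12, n_animals_per_group=8))
        _, pairwise = compare_two_factor(pheno, "body_weight_g")
        m = len(pairwise)
        np.testing.assert_allclose(
            pairwise["p_sidak"], np.minimum(1.0, 1 - (1 - pairwise["p_value"]) ** m)
        )


class TestPhenotypeClassification:
    @pytest.mark.parametrize(
        "glucose,expected",
        [(20.1, True), (7.5, False), (16.7, False), (16.71, True), (0.0, False)],
    )
    def test_threshold_strictly_exceeding(self, glucose, expected):
        assert classify_hyperglycemia(glucose) is expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_hyperglycemia(-1.0)

    def test_ceiling_censoring(self):
        assert is_censored_glucose(33.3) and not is_censored_glucose(33.0)
        pheno = pd.DataFrame(
            {
                "animal_id": ["a1", "a2"],
                "group": ["g", "g"],
                "week": [6, 6],
                "blood_glucose_mM": [33.3, 12.0],
                "body_weight_g": [30.0, 22.0],
            }
        )
        out = hyperglycemia_table(pheno)
        assert out["hyperglycemic"].tolist() == [True, False]
        assert out["glucose_censored"].tolist() == [True, False]


class TestSignificanceTiers:
    @pytest.mark.parametrize(
        "p,tier",
        [(0.0005, "***"), (0.005, "**"), (0.049, "*"), (0.05, "ns"), (0.9, "ns")],
    )
    def test_tiers(self, p, tier):
        assert significance_tier(p) == tier

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            significance_tier(1.5)


class TestReportBundle:
    def _result(self, sim_run):
        from nerveflux.pipeline import PipelineConfig, run_pipeline

        run, _ = sim_run
        return run_pipeline(
            run, None, PipelineConfig(norm_mode="none", positive_group="BKS")
        )

    def test_energy_map_group_stats(self):
        t = well_table()
        summaries = aggregate_by_animal(t)
        em = energy_map_table(summaries)
        assert em.loc[0, "basal_ocr_mean"] == pytest.approx(36.0)
        assert em.loc[0, "n_animals"] == 2

    def test_trace_summary_marks_injections(self, sim_run):
        run, _ = sim_run
        from nerveflux.preprocess import apply_qc

        table = trace_summary_table(apply_qc(run))
        marks = table[table["injection"] != ""]
        assert set(marks["measurement_index"]) == {6, 14, 22}
        assert set(marks["injection"]) == {"Omy", "FCCP", "RotAA"}

    def test_bundle_files_and_determinism(self, tmp_path, sim_run):
        result = self._result(sim_run)
        d1, d2 = tmp_path / "r1", tmp_path / "r2"
        p1 = result.write_report(d1)
        p2 = result.write_report(d2)
        for key in ("animal_summaries", "group_comparisons", "energy_map",
                    "trace_summary", "provenance", "qc_report", "well_metrics"):
            assert p1[key].exists()
            assert p1[key].read_bytes() == p2[key].read_bytes()
        prov = json.loads(p1["provenance"].read_text())
        steps = [e["step"] for e in prov["pipeline"]]
        assert "apply_qc" in steps and "baseline_adjust" in steps

    def test_single_group_comparisons_skipped_with_note(self, tmp_path):
        t = well_table()
        summaries = aggregate_by_animal(t)
        from conftest import make_run, meta, plateau_trace

        run = make_run([(meta("W1", status="pass"), plateau_trace(30, 14, 70, 10))])
        with pytest.warns(UserWarning, match="skipped"):
            paths = build_report(tmp_path / "r", run, summaries)
        assert "note" in pd.read_csv(paths["group_comparisons"]).columns
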