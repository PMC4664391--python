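"""Synthetic trial generator and transition re-estimation."""

import copy
import math

import numpy as np
import pandas as pd
import pytest

from bfcea import (
    GeneratorConfig,
    SyntheticTrialData,
    estimate_feeding_transitions,
    estimate_health_transitions,
    prevalence_ratio,
    run_cohort,
    simulate_trial,
    tables_from_estimates,
)
from bfcea.parameters import default_parameters
from bfcea.trial import VISIT_MONTHS, VISIT_WEEKS


def config(**kw):
    defaults = dict(n_control=300, n_intervention=300, dropout_per_visit=0.0, seed=0)
    defaults.update(kw)
    return GeneratorConfig(**defaults)


def no_mortality_params():
    p = default_parameters()
    p.mortality.cumulative_6mo_control = 0.0
    p.mortality.cumulative_6mo_intervention = 0.0
    return p


class TestSimulateTrial:
    def test_visit_week_month_mapping(self):
        assert VISIT_MONTHS == {3: 1, 6: 2, 12: 3, 24: 6}

    def test_deterministic_given_seed(self):
        a = simulate_trial(config(seed=11)).table
        b = simulate_trial(config(seed=11)).table
        pd.testing.assert_frame_equal(a, b)

    def test_no_dead_records_without_mortality(self):
        d = simulate_trial(config(params=no_mortality_params()))
        assert (d.table["vital_status"] == "alive").all()

    def test_full_follow_up_without_dropout_or_mortality(self):
        g = config(params=no_mortality_params())
        d = simulate_trial(g)
        per_child = d.table.groupby("child_id")["visit_week"].agg(list)
        assert len(per_child) == g.n_control + g.n_intervention
        assert all(v == list(VISIT_WEEKS) for v in per_child)

    def test_no_records_after_death(self):
        p = default_parameters()
        p.mortality.cumulative_6mo_control = 0.4
        p.mortality.cumulative_6mo_intervention = 0.4
        d = simulate_trial(config(params=p, seed=3))
        for _, grp in d.table.groupby("child_id"):
            statuses = grp.sort_values("visit_week")["vital_status"].tolist()
            if "dead" in statuses:
                assert statuses.index("dead") == len(statuses) - 1

    def test_dropout_censors_later_visits(self):
        d = simulate_trial(config(params=no_mortality_params(), dropout_per_visit=0.3, seed=4))
        for _, grp in d.table.groupby("child_id"):
            weeks = sorted(grp["visit_week"])
            assert weeks == list(VISIT_WEEKS)[: len(weeks)]

    def test_cluster_assignment_counts(self):
        g = config(clusters_per_arm=12)
        d = simulate_trial(g)
        for arm in ("control", "intervention"):
            assert d.table[d.table["arm"] == arm]["cluster"].nunique() == 12

    def test_week12_prevalence_matches_cohort_model(self):
        """Observed EBF/PBF fraction at the week-12 visit agrees with the
        cohort model's month-3 occupancy within 3 binomial SEs."""
        p = no_mortality_params()
        g = config(n_control=5000, n_intervention=5000, params=p, seed=0)
        d = simulate_trial(g)
        for arm in ("control", "intervention"):
            sub = d.table[(d.table["arm"] == arm) & (d.table["visit_week"] == 12)]
            obs = (sub["feeding"] == "EBF/PBF").mean()
            expected = run_cohort(p, arm).ebf_occupancy()[3]
            se = math.sqrt(expected * (1 - expected) / len(sub))
            assert abs(obs - expected) < 3 * se

    def test_csv_round_trip(self, tmp_path):
        d = simulate_trial(config(seed=5))
        path = tmp_path / "trial.csv"
        d.to_csv(path)
        reread = SyntheticTrialData.from_csv(path)
        assert len(reread.table) == len(d.table)
        assert list(reread.table.columns) == list(SyntheticTrialData.COLUMNS)


class TestEstimateFeeding:
    def test_deterministic_process_recovered_exactly(self):
        p = no_mortality_params()
        for arm in ("control", "intervention"):
            for row in p.feeding[arm].months.values():
                row.alpha1, row.alpha2 = 1.0, 0.0
        d = simulate_trial(config(params=p))
        est = estimate_feeding_transitions(d)
        for arm in ("control", "intervention"):
            for m in (1, 2, 3, 4, 5, 6):
                assert est[arm][m]["alpha1"].estimate == pytest.approx(1.0)
            # nobody ever occupies MF/RF, so its row is unobservable
            assert est[arm][2]["alpha4"].flag == "missing"

    def test_month1_mf_row_flagged_missing(self):
        d = simulate_trial(config())
        est = estimate_feeding_transitions(d)
        assert est["control"][1]["alpha4"].flag == "missing"

    def test_direct_cells_recovered_within_3se(self):
        p = no_mortality_params()
        d = simulate_trial(config(n_control=5000, n_intervention=5000, params=p, seed=0))
        est = estimate_feeding_transitions(d)
        for arm in ("control", "intervention"):
            for m in (2, 3):
                for name in ("alpha1", "alpha4"):
                    cell = est[arm][m][name]
                    truth = getattr(p.feeding[arm].months[m], name)
                    assert abs(cell.estimate - truth) < 3 * cell.se, (arm, m, name)

    def test_interval_cells_match_constant_bridge_estimand(self):
        """Months 4-6 are estimated under a constant-within-interval
        assumption; the estimand is the cube root of the true three-month
        product.  Estimands and their sampling SDs at this n are frozen from
        independent linear algebra and Monte-Carlo of the root map."""
        p = no_mortality_params()
        d = simulate_trial(config(n_control=5000, n_intervention=5000, params=p, seed=0))
        est = estimate_feeding_transitions(d)
        # (estimand, true sampling SD at n = 5000/arm)
        bridge = {
            "control": {"alpha1": (0.767059, 0.0113), "alpha4": (0.327134, 0.0149)},
            "intervention": {"alpha1": (0.926727, 0.0034), "alpha4": (0.290544, 0.0104)},
        }
        for arm, cells in bridge.items():
            for name, (estimand, sd) in cells.items():
                for m in (4, 5, 6):
                    cell = est[arm][m][name]
                    assert cell.flag == "interval"
                    assert abs(cell.estimate - estimand) < 3 * sd, (arm, m, name)

    def test_estimated_rows_rebuild_valid_tables(self):
        d = simulate_trial(config(seed=6))
        rebuilt = tables_from_estimates(
            estimate_feeding_transitions(d), estimate_health_transitions(d)
        )
        from bfcea import validate_parameters

        assert validate_parameters(rebuilt) == []


class TestEstimateHealth:
    def test_recovery_within_3se(self):
        p = no_mortality_params()
        d = simulate_trial(config(n_control=5000, n_intervention=5000, params=p, seed=1))
        est = estimate_health_transitions(d)
        for (arm, fs), cells in est.items():
            truth_cell = p.health.cells[(arm, fs)]
            for name in ("beta1", "beta3"):
                cell = cells[name]
                truth = getattr(truth_cell, name)
                assert abs(cell.estimate - truth) < 3 * cell.se, (arm, fs, name)

    def test_all_well_data_flags_sick_rows_missing(self):
        p = no_mortality_params()
        for cell in p.health.cells.values():
            cell.beta3, cell.beta2 = 0.0, 1.0
        d = simulate_trial(config(params=p))
        est = estimate_health_transitions(d)
        for cells in est.values():
            assert cells["beta1"].flag == "missing"
            assert cells["beta3"].estimate == pytest.approx(0.0)


class TestPrevalenceRatio:
    @staticmethod
    def frame_with_prevalence(n, prev_control, prev_intervention):
        rows = []
        for arm, prev in (("control", prev_control), ("intervention", prev_intervention)):
            k = round(n * prev)
            for i in range(n):
                rows.append(
                    {
                        "arm": arm,
                        "cluster": i % 12,
                        "child_id": f"{arm[0]}{i:05d}",
                        "visit_week": 12,
                        "feeding": "EBF/PBF" if i < k else "MF/RF",
                        "diarrhoea": "no",
                        "vital_status": "alive",
                        "dropout": False,
                    }
                )
        return SyntheticTrialData(pd.DataFrame(rows))

    def test_identical_arms_ratio_one(self):
        d = self.frame_with_prevalence(200, 0.5, 0.5)
        assert prevalence_ratio(d, 12)["ratio"] == pytest.approx(1.0)

    def test_published_prevalences_give_published_ratio(self):
        d = self.frame_with_prevalence(1000, 0.44, 0.82)
        res = prevalence_ratio(d, 12)
        assert res["ratio"] == pytest.approx(0.82 / 0.44, abs=1e-9)
        assert res["ratio"] == pytest.approx(1.86, abs=0.005)

    def test_zero_control_prevalence_flagged(self):
        d = self.frame_with_prevalence(100, 0.0, 0.5)
        res = prevalence_ratio(d, 12)
        assert res["ratio"] is None
        assert "undefined" in res["flag"]

    def test_missing_visit_week_rejected(self):
        d = self.frame_with_prevalence(50, 0.5, 0.5)
        with pytest.raises(ValueError):
            prevalence_ratio(d, 6)

    def test_ci_coverage_of_generated_ratio(self):
        """Cluster-bootstrap 95% CI covers the model-implied prevalence
        ratio in the large majority of replicate simulations."""
        p = no_mortality_params()
        truth = {
            arm: run_cohort(p, arm).ebf_occupancy()[3] for arm in ("control", "intervention")
        }
        true_ratio = truth["intervention"] / truth["control"]
        covered = 0
        n_rep = 100
        for rep in range(n_rep):
            d = simulate_trial(config(n_control=300, n_intervention=300, params=p, seed=rep))
            res = prevalence_ratio(d, 12, n_boot=100, seed=rep)
            lo, hi = res["ci"]
            covered += lo <= true_ratio <= hi
        assert covered / n_rep >= 0.88
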