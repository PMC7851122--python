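"""Statistical engine: tests, adjusted models, descriptive and stratified tables."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import persnet as pn
from persnet.synthetic import SyntheticConfig

from conftest import make_record, oracle_mannwhitney_exact


def small_cohort(seed=11, n=60):
    cfg = pn.default_config()
    cfg = SyntheticConfig(
        players=dataclasses.replace(cfg.players, n=n),
        controls=dataclasses.replace(cfg.controls, n=n),
    )
    return pn.simulate_records(cfg, seed=seed)


class TestMannWhitney:
    def test_identical_samples_no_shift(self):
        assert pn.mann_whitney([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_complete_separation_exact(self):
        # U = 0; 2 of the C(6,3)=20 assignments are as extreme
        assert pn.mann_whitney([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    def test_exact_path_matches_permutation_enumeration(self, rng):
        for _ in range(25):
            nx_, ny = int(rng.integers(2, 9)), int(rng.integers(2, 9))
            pooled = rng.choice(1000, size=nx_ + ny, replace=False).astype(float)
            x, y = pooled[:nx_], pooled[nx_:]
            assert pn.mann_whitney(x, y) == pytest.approx(
                oracle_mannwhitney_exact(x, y), abs=1e-12
            )

    def test_large_shift_is_detected(self, rng):
        x = rng.normal(0, 1, 200)
        y = rng.normal(1.5, 1, 200)
        assert pn.mann_whitney(x, y) < 1e-3

    def test_empty_side_raises(self):
        with pytest.raises(ValueError):
            pn.mann_whitney([], [1.0])


class TestChiSquare:
    def test_proportional_table_statistic_zero(self):
        res = pn.chi_square([[10, 10], [10, 10]])
        assert res.statistic == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_statistic_equals_hand_formula(self):
        obs = np.array([[30, 10], [20, 40]], dtype=float)
        total = obs.sum()
        exp = np.outer(obs.sum(1), obs.sum(0)) / total
        assert pn.chi_square(obs).statistic == pytest.approx(((obs - exp) ** 2 / exp).sum())

    def test_degenerate_margin_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            pn.chi_square([[0, 0], [5, 3]])


def covariate_frame(n, rng, balanced_with=None):
    """Raw covariate columns; optionally an exact copy (orthogonal to group)."""
    if balanced_with is not None:
        return balanced_with.copy()
    return pd.DataFrame(
        {
            "age": rng.normal(50, 10, n),
            "race": rng.choice(["White", "Black"], n),
            "education": rng.choice(["some_college", "bachelors_degree"], n),
            "employment": rng.choice(["employed", "retired"], n),
            "income": rng.normal(70000, 15000, n),
            "domestic_status": rng.choice(["married", "not_married"], n),
        }
    )


class TestAdjustedComparison:
    def test_orthogonal_covariates_recover_raw_mean_difference(self, rng):
        n = 40
        cov1 = covariate_frame(n, rng)
        cov = pd.concat([cov1, cov1], ignore_index=True)  # identical per group
        y = np.concatenate([rng.normal(0, 1, n), rng.normal(2, 1, n)])
        g = ["a"] * n + ["b"] * n
        res = pn.adjusted_comparison(y, g, cov, metric_name="toy")
        raw_diff = y[n:].mean() - y[:n].mean()
        assert res.coef_adjusted == pytest.approx(raw_diff, abs=1e-9)

    def test_planted_shift_recovered(self, rng):
        n = 300
        cov = covariate_frame(2 * n, rng)
        y = 0.02 * cov["age"].values + rng.normal(0, 1, 2 * n)
        y[n:] += 2.0
        g = ["control"] * n + ["player"] * n
        res = pn.adjusted_comparison(y, g, cov, metric_name="toy")
        assert res.coef_adjusted == pytest.approx(2.0, abs=0.3)
        assert res.p_adjusted < 1e-6
        assert res.n_used == 2 * n

    def test_null_pvalues_are_uniform(self, rng):
        ps = []
        for _ in range(200):
            n = 25
            cov = covariate_frame(2 * n, rng)
            y = rng.normal(0, 1, 2 * n)
            g = ["a"] * n + ["b"] * n
            ps.append(pn.adjusted_comparison(y, g, cov, metric_name="toy").p_adjusted)
        assert scipy.stats.kstest(ps, "uniform").pvalue > 0.01

    def test_collinear_design_raises_naming_columns(self, rng):
        n = 30
        cov = covariate_frame(2 * n, rng)
        cov["income"] = cov["age"] * 1000  # exact collinearity with age
        y = rng.normal(0, 1, 2 * n)
        with pytest.raises(ValueError, match="income_k|age"):
            pn.adjusted_comparison(y, ["a"] * n + ["b"] * n, cov, metric_name="toy")

    def test_too_few_complete_cases_raises(self, rng):
        cov = covariate_frame(6, rng)
        with pytest.raises(ValueError, match="complete cases"):
            pn.adjusted_comparison(
                rng.normal(size=6), ["a", "a", "a", "b", "b", "b"], cov, metric_name="toy"
            )

    def test_missing_metric_values_reduce_n_used(self, rng):
        n = 50
        cov = covariate_frame(2 * n, rng)
        y = rng.normal(0, 1, 2 * n)
        y[:5] = np.nan
        res = pn.adjusted_comparison(y, ["a"] * n + ["b"] * n, cov, metric_name="toy")
        assert res.n_used == 2 * n - 5


class TestDescriptiveTable:
    def test_categorical_counts_and_percentages(self):
        records = []
        for i in range(10):
            records.append(
                make_record(pid=f"P{i}", group="player",
                            chronic_conditions=frozenset({"sleep"}) if i < 4 else frozenset())
            )
        for i in range(10):
            records.append(
                make_record(pid=f"C{i}", group="control", chronic_present=(i < 2))
            )
        df = pn.descriptive_table(records)
        row = df[(df.variable == "chronic_condition") & (df.level == "present")].iloc[0]
        assert row.player_n == 4 and row.player_pct == pytest.approx(40.0)
        assert row.control_n == 2 and row.control_pct == pytest.approx(20.0)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError, match="empty group"):
            pn.descriptive_table([make_record(group="player")])

    def test_all_missing_income_gives_empty_cell(self):
        recs = [make_record(pid=f"P{i}", group="player", income=None) for i in range(3)]
        recs += [make_record(pid=f"C{i}", group="control", income=50000.0) for i in range(3)]
        df = pn.descriptive_table(recs)
        row = df[df.variable == "income"].iloc[0]
        assert np.isnan(row.player_median)
        assert row.control_median == pytest.approx(50000.0)


class TestCompareCohorts:
    def test_results_cover_shared_metrics_with_bh_column(self):
        frame, _ = pn.metrics_frame(small_cohort())
        res = pn.compare_cohorts(frame)
        assert "q_bh" in res.columns
        assert set(res.metric) <= set(pn.ALL_METRICS)
        # football metrics exist only for players; excluded from the contrast
        assert "pct_played_football" not in set(res.metric)
        assert ((res.p_adjusted >= 0) & (res.p_adjusted <= 1)).all()
        assert (res.n_used <= len(frame)).all()


@pytest.fixture(scope="module")
def frame():
    return pn.metrics_frame(small_cohort(seed=5, n=150))[0]


class TestStratified:
    def test_race_strata_partition_players(self, frame):
        res = pn.stratified_comparison(frame, "race_2way", metrics=["network_size"])
        n_players = (frame.group == "player").sum()
        within = res[res.contrast == "Black/Other vs White players"]
        assert len(within) == 1
        assert within.iloc[0].n1 + within.iloc[0].n2 == n_players
        assert set(res.contrast) == {
            "Black/Other vs White players",
            "White players vs controls",
            "Black/Other players vs controls",
        }

    def test_illness_type_membership_matches_flags(self, frame):
        res = pn.stratified_comparison(frame, "illness_type", metrics=["network_size"])
        players = frame[frame.group == "player"]
        for cond, label in [("sleep", "sleep apnea"), ("pain", "pain"),
                            ("cardiometabolic", "cardiometabolic")]:
            sub = res[res.contrast == f"{label} vs no condition"]
            if len(sub):
                assert sub.iloc[0].n2 == (players[f"chronic_{cond}"] == True).sum()  # noqa: E712

    def test_illness_count_reference_is_no_condition(self, frame):
        res = pn.stratified_comparison(frame, "illness_count", metrics=["network_size"])
        assert all(c.endswith("vs none") for c in res.contrast)

    def test_empty_stratum_skipped_with_log(self, frame, caplog):
        sub = frame[(frame.group == "control") | (frame.race == "White")]
        res = pn.stratified_comparison(sub, "race_2way", metrics=["network_size"])
        assert "Black/Other vs White players" not in set(res.contrast)

    def test_unknown_rule_raises(self, frame):
        with pytest.raises(ValueError, match="strata rule"):
            pn.stratified_comparison(frame, "by_zodiac")
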