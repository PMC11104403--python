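import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from bartmodel import (
    CohortConfig,
    analyze_study,
    block_difference_analysis,
    correlate,
    cost_moderation,
    participant_summaries,
    previous_burst_analysis,
    simulate_study,
    skew_transform,
)
from bartmodel.model_free import block_correlations


def _summaries(pumps_by_pid_block):
    rows = [
        {"participant_id": pid, "block": b, "mean_pumps_nonburst": v,
         "n_nonburst_trials": 20}
        for (pid, b), v in pumps_by_pid_block.items()
    ]
    return pd.DataFrame(rows)


def _scores(cq_by_pid):
    return pd.DataFrame(
        [{"participant_id": pid, "cq_total": v} for pid, v in cq_by_pid.items()]
    )


class TestParticipantSummaries:
    def test_excludes_burst_trials_exactly(self, tiny_study):
        s = participant_summaries(tiny_study.trials)
        df = tiny_study.trials
        for row in s.itertuples():
            sub = df[(df.participant_id == row.participant_id) & (df.block == row.block)]
            nonburst = sub[~sub.burst.astype(bool)]
            assert row.n_nonburst_trials == len(nonburst)
            if len(nonburst):
                assert row.mean_pumps_nonburst == pytest.approx(nonburst.n_pumps.mean())

    def test_all_burst_participant_flagged_not_dropped(self):
        df = pd.DataFrame(
            {
                "participant_id": ["a"] * 2,
                "block": ["LC"] * 2,
                "trial_index": [1, 2],
                "n_pumps": [5, 5],
                "burst": [True, True],
                "burst_threshold": [5, 5],
                "points_earned": [0, 0],
            }
        )
        s = participant_summaries(df)
        assert len(s) == 1 and np.isnan(s.mean_pumps_nonburst.iloc[0])
        assert s.n_nonburst_trials.iloc[0] == 0


class TestSkewTransform:
    def test_symmetric_input_untouched(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y, label = skew_transform(x)
        assert label["transform"] == "identity"
        np.testing.assert_array_equal(x, y)

    def test_right_skew_takes_sqrt(self):
        x = np.array([0.0, 1, 4, 9, 100])
        y, label = skew_transform(x)
        assert label["transform"] == "sqrt" and not label["order_reversing"]
        np.testing.assert_allclose(y, np.sqrt(x))

    def test_left_skew_reflects_and_maps_max_to_zero(self):
        x = np.array([0.0, 90, 95, 99, 100, 100, 98])
        y, label = skew_transform(x)
        assert label["transform"] == "sqrt_reflect" and label["order_reversing"]
        assert y[np.argmax(x)] == 0.0

    def test_negative_values_shifted_before_sqrt(self):
        x = np.array([-5.0, -4, -1, 0, 30])
        y, label = skew_transform(x)
        assert label["transform"] == "sqrt" and label["shift"] == 5.0
        assert np.all(np.isfinite(y))

    def test_order_reversal_flips_correlation_sign(self):
        rng = np.random.default_rng(0)
        x = 100 - rng.exponential(5, 300)  # negatively skewed
        z = x + rng.normal(0, 1, 300)
        y, label = skew_transform(x)
        assert label["order_reversing"]
        assert np.sign(pearsonr(y, z)[0]) == -np.sign(pearsonr(x, z)[0])


class TestCorrelate:
    def test_perfect_correlations(self):
        a = np.arange(10.0)
        assert correlate(a, a)["r"] == pytest.approx(1.0)
        assert correlate(a, -a)["r"] == pytest.approx(-1.0)

    def test_df_is_n_minus_two(self):
        rng = np.random.default_rng(1)
        res = correlate(rng.normal(size=40), rng.normal(size=40))
        assert res["df"] == 38 and res["method"] == "pearson"

    def test_pairwise_complete(self):
        a = np.array([1.0, 2, np.nan, 4, 5, 6])
        b = np.array([2.0, 4, 6, np.nan, 10, 12])
        res = correlate(a, b)
        assert res["n"] == 4 and res["r"] == pytest.approx(1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            correlate(np.ones(10), np.arange(10.0))

    def test_nonnormal_residuals_fall_back_to_ranks(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=200)
        b = a + rng.standard_cauchy(200) * 5  # heavy-tailed residuals
        res = correlate(a, b)
        assert res["method"] == "spearman"

    def test_recovers_generating_link_at_study_scale(self):
        # CQ built with latent r = -0.3 to raw risk taking, n = 263
        from bartmodel import sample_questionnaires

        cfg = CohortConfig(n_participants=263, seed=8)
        rng = np.random.default_rng(12)
        raw = rng.normal(-0.6, 0.4, 263)
        scores = sample_questionnaires(raw, cfg)
        res = correlate(raw, [s.cq_total for s in scores])
        assert res["r"] == pytest.approx(-0.3, abs=0.12)


class TestBlockDifference:
    def test_identical_blocks_flagged(self):
        s = _summaries({("a", "LC"): 5.0, ("a", "HC"): 5.0,
                        ("b", "LC"): 7.0, ("b", "HC"): 7.0})
        with pytest.raises(ValueError, match="zero-variance"):
            block_difference_analysis(s, _scores({"a": 20, "b": 30}))

    def test_df_bookkeeping_uses_overlap(self):
        rng = np.random.default_rng(4)
        pids = [f"p{i}" for i in range(40)]
        summaries = _summaries(
            {(p, b): float(rng.normal(8 if b == "LC" else 7, 2))
             for p in pids for b in ("LC", "HC")}
        )
        # one participant missing the HC block: excluded from the overlap
        summaries = summaries[
            ~((summaries.participant_id == "p0") & (summaries.block == "HC"))
        ]
        scores = _scores({p: int(rng.integers(10, 80)) for p in pids})
        res = block_difference_analysis(summaries, scores)
        assert res["n"] == 39 and res["df"] == 37

    def test_constructed_link_recovered_in_sign(self):
        rng = np.random.default_rng(5)
        pids = [f"p{i:02d}" for i in range(120)]
        diff = rng.normal(1.0, 1.0, 120)
        hc = rng.normal(7, 1.5, 120)
        summaries = _summaries(
            {(p, "LC"): float(hc[i] + diff[i]) for i, p in enumerate(pids)}
            | {(p, "HC"): float(hc[i]) for i, p in enumerate(pids)}
        )
        cq = np.clip(np.round(45 - 8 * diff + rng.normal(0, 4, 120)), 0, 96)
        res = block_difference_analysis(summaries, _scores(dict(zip(pids, cq))))
        sign = -1 if res.get("difference_transform", {}).get("order_reversing") else 1
        assert sign * res["r"] < 0 and res["p"] < 0.01


class TestCostModeration:
    def test_one_participant_rejected(self):
        s = _summaries({("a", "LC"): 5.0, ("a", "HC"): 4.0})
        with pytest.raises(ValueError):
            cost_moderation(s, _scores({"a": 20}))

    def test_block_specific_link_detected(self):
        # CQ predicts pumps only in LC: the cost x CQ interaction is real
        rng = np.random.default_rng(6)
        pids = [f"p{i:03d}" for i in range(200)]
        cq = rng.integers(5, 90, 200).astype(float)
        base = rng.normal(8, 1.0, 200)
        lc = base - 0.04 * (cq - cq.mean()) + rng.normal(0, 0.5, 200)
        hc = base + rng.normal(0, 0.5, 200)
        s = _summaries(
            {(p, "LC"): float(lc[i]) for i, p in enumerate(pids)}
            | {(p, "HC"): float(hc[i]) for i, p in enumerate(pids)}
        )
        res = cost_moderation(s, _scores(dict(zip(pids, cq.astype(int)))))
        assert res["p"] < 0.01
        assert res["term"] == "cq:cost"

    def test_null_interaction_calibrated(self):
        # equal slopes in both blocks: rejection stays near the nominal rate
        rng = np.random.default_rng(7)
        rejections = 0
        n_reps = 60
        for _ in range(n_reps):
            pids = [f"p{i:02d}" for i in range(60)]
            cq = rng.integers(5, 90, 60).astype(float)
            base = rng.normal(8, 1.0, 60)
            slope = -0.02 * (cq - cq.mean())
            lc = base + slope + rng.normal(0, 0.8, 60)
            hc = base + slope + rng.normal(0, 0.8, 60)
            s = _summaries(
                {(p, "LC"): float(lc[i]) for i, p in enumerate(pids)}
                | {(p, "HC"): float(hc[i]) for i, p in enumerate(pids)}
            )
            res = cost_moderation(s, _scores(dict(zip(pids, cq.astype(int)))))
            rejections += res["p"] < 0.05
        assert rejections / n_reps <= 0.15


class TestPreviousBurst:
    def test_first_trials_excluded_from_model(self, tiny_study):
        rep = previous_burst_analysis(tiny_study.trials, tiny_study.questionnaires)
        df = tiny_study.trials
        for block in ("LC", "HC"):
            sub = df[df.block == block]
            n_participants = sub.participant_id.nunique()
            assert rep[block]["n_obs"] == len(sub) - n_participants

    def test_learning_agents_pump_less_after_burst(self):
        # strong learners under single-trial evidence: a burst raises the
        # burst belief, so the next balloon gets fewer pumps
        cohort = CohortConfig(
            n_participants=80, seed=9, evidence_window="last_trial",
            group_means={"prior_belief": -0.16, "learning_rate": 1.0,
                         "risk_taking": -0.2, "inverse_temperature": 1.2},
            group_sds={"prior_belief": 0.1, "learning_rate": 0.3,
                       "risk_taking": 0.3, "inverse_temperature": 0.2},
        )
        study = simulate_study(cohort, blocks=("LC",))
        rep = previous_burst_analysis(study.trials, study.questionnaires)
        assert rep["LC"]["prev_burst"]["coef"] < -1
        assert rep["LC"]["prev_burst"]["p"] < 1e-6

    def test_non_learning_agents_show_no_carryover(self):
        # learning rate ~ 0: belief never moves, so previous bursts carry
        # no information; effects stay null-calibrated across cohorts
        coefs, ps = [], []
        for seed in (12, 13, 14):
            cohort = CohortConfig(
                n_participants=80, seed=seed, evidence_window="last_trial",
                group_means={"prior_belief": -0.3, "learning_rate": -10.0,
                             "risk_taking": -0.2, "inverse_temperature": 1.2},
                group_sds={"prior_belief": 0.1, "learning_rate": 0.0,
                           "risk_taking": 0.3, "inverse_temperature": 0.2},
            )
            study = simulate_study(cohort, blocks=("LC",))
            d = previous_burst_analysis(study.trials, study.questionnaires)
            coefs.append(d["LC"]["prev_burst"]["coef"])
            ps.append(d["LC"]["prev_burst"]["p"])
        assert abs(np.mean(coefs)) < 0.2
        assert all(p > 0.01 for p in ps)


class TestAnalyzeStudy:
    def test_report_structure_and_outputs(self, tiny_study, tmp_path):
        rep = analyze_study(tiny_study.trials, tiny_study.questionnaires, tmp_path)
        assert set(rep["block_correlations"]) == {"LC", "HC"}
        for res in rep["block_correlations"].values():
            assert {"r", "df", "p", "method", "pumps_transform"} <= set(res)
        assert (tmp_path / "report.json").exists()
        assert (tmp_path / "summaries.csv").exists()
        assert (tmp_path / "participant_table.csv").exists()
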