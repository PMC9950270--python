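"""Trial aggregation, group tests, correlations and the sample-size rule."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr, rankdata, spearmanr

from spiralpen import (aggregate_trials, between_group, correlate_clinical,
                       sample_size_for_rho, strength_label)


def _trial_table(rows):
    defaults = {"group": "PD", "hand": "dominant"}
    return pd.DataFrame([{**defaults, **r} for r in rows])


class TestAggregateTrials:
    def test_two_trials_averaged(self):
        t = _trial_table([
            {"subject_id": "s1", "trial": 1, "NC_F": 3.0},
            {"subject_id": "s1", "trial": 2, "NC_F": 4.0}])
        agg = aggregate_trials(t, indicators=["NC_F"])
        assert agg.loc[0, "NC_F"] == 3.5
        assert not agg.loc[0, "single_trial"]

    def test_single_trial_flagged(self):
        t = _trial_table([{"subject_id": "s1", "trial": 1, "NC_F": 3.0}])
        agg = aggregate_trials(t, indicators=["NC_F"])
        assert agg.loc[0, "NC_F"] == 3.0
        assert agg.loc[0, "single_trial"]

    def test_missing_value_in_one_trial_uses_the_other(self):
        t = _trial_table([
            {"subject_id": "s1", "trial": 1, "NC_F": np.nan},
            {"subject_id": "s1", "trial": 2, "NC_F": 4.0}])
        agg = aggregate_trials(t, indicators=["NC_F"])
        assert agg.loc[0, "NC_F"] == 4.0


def _cohort(a_vals, b_vals, name="X"):
    rows = [{"subject_id": f"p{i}", "group": "PD", "hand": "dominant", name: v}
            for i, v in enumerate(a_vals)]
    rows += [{"subject_id": f"c{i}", "group": "control", "hand": "dominant", name: v}
             for i, v in enumerate(b_vals)]
    return pd.DataFrame(rows)


class TestBetweenGroup:
    def test_large_shift_detected_via_t_branch(self, rng):
        a = rng.normal(0, 1, 29)
        b = rng.normal(2, 1, 29)
        res = between_group(_cohort(a, b), indicators=["X"])
        assert res.loc[0, "test"] == "t"
        assert res.loc[0, "p_value"] < 1e-3
        assert "±" in res.loc[0, "summary_a"]

    def test_heavy_tailed_indicator_routes_to_mann_whitney(self, rng):
        a = np.exp(rng.normal(0, 1.5, 29))
        b = np.exp(rng.normal(0.2, 1.5, 29))
        res = between_group(_cohort(a, b), indicators=["X"])
        assert res.loc[0, "test"] == "mann_whitney"
        assert "(" in res.loc[0, "summary_a"]

    def test_type_one_error_rate_near_alpha(self):
        # identical populations: rejections at ~5% over repeated cohorts
        hits = 0
        reps = 200
        for seed in range(reps):
            r = np.random.default_rng(seed)
            res = between_group(_cohort(r.normal(0, 1, 29), r.normal(0, 1, 29)),
                                indicators=["X"])
            hits += res.loc[0, "p_value"] < 0.05
        assert 0.015 <= hits / reps <= 0.095

    def test_constant_indicator_skipped(self):
        res = between_group(_cohort(np.ones(10), np.ones(10)), indicators=["X"])
        assert len(res) == 0

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            between_group(_cohort([1, 2], [1, 2, 3]), indicators=["X"])


def _pd_table(score, indicator):
    return pd.DataFrame({
        "subject_id": [f"p{i}" for i in range(len(score))],
        "group": "PD", "hand": "dominant",
        "updrs3": score, "X": indicator})


class TestCorrelateClinical:
    def test_monotone_transform_perfect_rank_correlation(self):
        s = np.arange(20.0)
        res = correlate_clinical(_pd_table(s, np.exp(s / 5)),
                                 scores=["updrs3"], indicators=["X"])
        assert res.loc[0, "rho"] == pytest.approx(1.0)
        assert res.loc[0, "strength"] == "strong"

    def test_null_pairs_rarely_cross_critical_value(self):
        crossings = 0
        reps = 200
        for seed in range(reps):
            r = np.random.default_rng(1000 + seed)
            rho, _ = spearmanr(r.normal(size=29), r.normal(size=29))
            crossings += abs(rho) >= 0.37
        assert crossings / reps < 0.10  # ~5% expected at the n=29 critical value

    def test_constant_score_skipped(self):
        res = correlate_clinical(_pd_table(np.ones(10), np.arange(10.0)),
                                 scores=["updrs3"], indicators=["X"])
        assert len(res) == 0


def test_spearman_equals_pearson_on_ranks(rng):
    x = rng.integers(0, 10, 50).astype(float)  # ties present
    y = rng.integers(0, 10, 50).astype(float)
    rho, _ = spearmanr(x, y)
    r, _ = pearsonr(rankdata(x), rankdata(y))
    assert rho == pytest.approx(r, abs=1e-12)


class TestStrengthLabel:
    @pytest.mark.parametrize("rho, label", [
        (0.0, "weak"), (0.3, "weak"), (-0.3, "weak"),
        (0.31, "moderate"), (0.45, "moderate"), (-0.69, "moderate"),
        (0.7, "strong"), (-0.7, "strong"), (1.0, "strong")])
    def test_printed_rule(self, rho, label):
        assert strength_label(rho) == label

    def test_total_partition(self):
        for rho in np.linspace(-1, 1, 201):
            assert strength_label(rho) in {"weak", "moderate", "strong"}


class TestSampleSize:
    def test_published_design_value(self):
        rho = float(np.mean([0.356, 0.650]))
        assert rho == pytest.approx(0.503)
        assert sample_size_for_rho(rho, alpha=0.05, power=0.80) == 29

    def test_limit_as_rho_approaches_one(self):
        assert sample_size_for_rho(0.999) == 4

    def test_invalid_rho_rejected(self):
        for rho in (0.0, 1.0, 1.5, -0.2):
            with pytest.raises(ValueError):
                sample_size_for_rho(rho)
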