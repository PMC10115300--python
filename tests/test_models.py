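"""Random-forest scoring, shadow ranking, model selection, DTK post-hoc,
targeted species models and contribution ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from harborsound import annotations as ann
from harborsound import models as md
from harborsound import study

FAST = dict(n_trees=50, max_iter=25)


class TestModelSpec:
    def test_month_and_temperature_rejected_together(self):
        with pytest.raises(ValueError, match="collinear"):
            md.ModelSpec("y", ("month", "water_temp_c"))

    def test_empty_predictors_rejected(self):
        with pytest.raises(ValueError):
            md.ModelSpec("y", ())


class TestFitRF:
    def make(self, seed, n=500):
        rng = np.random.default_rng(seed)
        return rng, pd.DataFrame({
            "x": rng.normal(size=n), "n1": rng.normal(size=n),
            "n2": rng.normal(size=n), "n3": rng.normal(size=n)})

    def test_deterministic_response_high_variance_explained(self):
        scores = []
        for seed in range(5):
            rng, df = self.make(seed)
            df["y"] = df["x"]
            spec = md.ModelSpec("y", ("x", "n1", "n2", "n3"), n_trees=100,
                                rng_seed=seed)
            _, score = md.fit_rf(spec, df)
            scores.append(score)
        # mtry = p/3 (one candidate feature per split here) caps the OOB R2
        # well short of 100% even for a noise-free response.
        assert min(scores) > 80

    def test_independent_response_low_score(self):
        rng, df = self.make(7)
        df["y"] = rng.normal(size=len(df))
        spec = md.ModelSpec("y", ("x", "n1", "n2", "n3"), n_trees=100)
        _, score = md.fit_rf(spec, df)
        assert score <= 10

    def test_separable_classification_accuracy(self):
        rng, df = self.make(8)
        df["y"] = (df["x"] > 0).astype(int)
        spec = md.ModelSpec("y", ("x", "n1", "n2", "n3"), n_trees=100,
                            task="classification")
        _, score = md.fit_rf(spec, df)
        assert score >= 99

    def test_constant_response_degenerate(self):
        _, df = self.make(9)
        df["y"] = 1.0
        with pytest.raises(md.DegenerateModelError):
            md.fit_rf(md.ModelSpec("y", ("x",)), df)

    def test_too_few_rows(self):
        _, df = self.make(10)
        df["y"] = df["x"]
        with pytest.raises(md.InsufficientDataError):
            md.fit_rf(md.ModelSpec("y", ("x",)), df.head(20))

    def test_determinism_same_seed(self):
        _, df = self.make(11)
        df["y"] = df["x"] + 0.1 * df["n1"]
        spec = md.ModelSpec("y", ("x", "n1"), n_trees=100, rng_seed=3)
        _, a = md.fit_rf(spec, df)
        _, b = md.fit_rf(spec, df)
        assert a == b


class TestShadowRank:
    def test_strong_confirmed_noise_rejected(self):
        assert study.shadow_power_run(1234)

    def test_duplicated_informative_both_confirmed(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=300)
        df = pd.DataFrame({"x1": x, "x2": x, "n1": rng.normal(size=300),
                           "n2": rng.normal(size=300)})
        df["y"] = 3 * x + rng.normal(scale=0.5, size=300)
        spec = md.ModelSpec("y", ("x1", "x2", "n1", "n2"), rng_seed=12,
                            n_trees=50, max_iter=60)
        res = md.shadow_rank(spec, df, rough_fix=True)
        assert res.decision("x1") == "confirmed"
        assert res.decision("x2") == "confirmed"

    def test_z_statistics_ordered(self):
        rng = np.random.default_rng(13)
        df = pd.DataFrame({"x": rng.normal(size=300),
                           "n1": rng.normal(size=300)})
        df["y"] = 2 * df["x"] + rng.normal(scale=0.5, size=300)
        res = md.shadow_rank(md.ModelSpec("y", ("x", "n1"), rng_seed=13,
                                          **FAST), df)
        t = res.table.set_index("predictor")
        assert t.loc["x", "mean_z"] > t.loc["n1", "mean_z"]
        assert (t["min_z"] <= t["mean_z"]).all()
        assert (t["mean_z"] <= t["max_z"]).all()

    def test_determinism(self):
        rng = np.random.default_rng(14)
        df = pd.DataFrame({"x": rng.normal(size=200),
                           "n1": rng.normal(size=200)})
        df["y"] = df["x"] + rng.normal(scale=0.5, size=200)
        spec = md.ModelSpec("y", ("x", "n1"), rng_seed=5, **FAST)
        a = md.shadow_rank(spec, df)
        b = md.shadow_rank(spec, df)
        pd.testing.assert_frame_equal(a.table, b.table)
        assert a.score == b.score


class TestSelectMonthOrTemp:
    def make_table(self, seed=15, n=600):
        rng = np.random.default_rng(seed)
        month = rng.integers(1, 13, n)
        temp = rng.uniform(8, 30, n)   # decoupled from month
        return rng, pd.DataFrame({"month": month, "water_temp_c": temp,
                                  "z": rng.normal(size=n)})

    def test_temperature_response_chooses_temperature(self):
        rng, df = self.make_table()
        df["y"] = 0.5 * df["water_temp_c"] + rng.normal(scale=0.5, size=len(df))
        spec = md.ModelSpec("y", ("water_temp_c", "z"), rng_seed=1, **FAST)
        res = md.select_month_or_temp(spec, df)
        assert res.label == "temperature"

    def test_month_step_response_chooses_month(self):
        rng, df = self.make_table(16)
        df["y"] = (df["month"] % 3 == 0).astype(float) * 5 + rng.normal(
            scale=0.5, size=len(df))
        spec = md.ModelSpec("y", ("water_temp_c", "z"), rng_seed=1, **FAST)
        res = md.select_month_or_temp(spec, df)
        assert res.label == "month"

    def test_tie_breaks_to_temperature(self):
        rng, df = self.make_table(17)
        # identical columns -> identical designs and scores -> temperature
        df["water_temp_c"] = df["month"].astype(float)
        df["y"] = df["month"] + rng.normal(scale=0.5, size=len(df))
        spec = md.ModelSpec("y", ("water_temp_c", "z"), rng_seed=1, **FAST)
        res = md.select_month_or_temp(spec, df)
        assert res.label == "temperature"


class TestDTK:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(18)
        x = rng.normal(size=100)
        res = md.dtk_posthoc(np.concatenate([x, x]),
                             np.repeat([0, 1], 100))
        pair = res.pairs.iloc[0]
        assert pair.lower <= 0 <= pair.upper and not pair.significant

    def test_large_shift_detected_with_sign(self):
        rng = np.random.default_rng(19)
        a = rng.normal(size=50)
        b = rng.normal(loc=10, size=50)
        res = md.dtk_posthoc(np.concatenate([a, b]), np.repeat([0, 1], 50))
        assert res.significant_pair(0, 1)
        assert res.ordering == [1, 0]

    def test_balanced_equal_variance_textbook_oracle(self):
        # With two equal-size, equal-variance groups the Welch df equals the
        # pooled df, so the interval must match the hand computation exactly.
        rng = np.random.default_rng(20)
        a = rng.normal(size=40)
        b = a + 0.7      # identical sample variance by construction
        res = md.dtk_posthoc(np.concatenate([a, b]), np.repeat([0, 1], 40))
        n, k = 40, 2
        s2 = a.var(ddof=1)
        se = np.sqrt(2 * s2 / n)
        q = stats.studentized_range.ppf(0.95, k, 2 * (n - 1))
        half = q / np.sqrt(2) * se
        diff = a.mean() - b.mean()
        pair = res.pairs.iloc[0]
        assert pair["diff"] == pytest.approx(diff, abs=1e-9)
        assert pair["lower"] == pytest.approx(diff - half, abs=1e-6)
        assert pair["upper"] == pytest.approx(diff + half, abs=1e-6)

    def test_small_group_errors_with_name(self):
        with pytest.raises(ValueError, match="tiny"):
            md.dtk_posthoc([1.0, 2.0, 3.0], ["a", "a", "tiny"])


class TestTargetedAndContribution:
    def test_directions_on_one_replicate(self):
        dirs = study.direction_replicate(4321)
        assert dirs["silver_perch"] == "0 > 1"
        assert dirs["dolphin"] == "1 > 0"
        assert dirs["black_drum"] == "0 = 1"

    def test_targeted_model_with_ranking(self):
        t = study.scene_tables(99)
        hourly = ann.hourly_subsample(t.annotations)
        spec = md.ModelSpec("x", ("station", "water_temp_c", "lunar_phase",
                                  "tidal_phase", "diel", "noise"),
                            task="classification", **FAST)
        res = md.targeted_model("silver_perch", hourly, t.covariates,
                                spec=spec)
        assert res.direction == "0 > 1"
        assert res.importance is not None
        assert res.importance.decision("noise") == "confirmed"

    def test_insufficient_window_errors(self):
        t = study.scene_tables(98, days=3)
        hourly = ann.hourly_subsample(t.annotations)
        with pytest.raises(md.InsufficientDataError):
            # red drum window (Aug-Oct) is empty in a March scene
            md.targeted_model("red_drum", hourly, t.covariates, rank=False)

    def test_contribution_ranking_and_removal(self):
        # SPL driven by species A; species B suppressed by vessels (which
        # raise SPL) so B correlates negatively: B must land in `removed`.
        rng = np.random.default_rng(21)
        n = 600
        vessel = rng.integers(0, 2, n)
        a_int = rng.choice([0, 1, 2, 3], n)
        b_int = rng.poisson(np.where(vessel == 1, 0.1, 1.5))
        spl_db = 100 + 4.0 * a_int + 8.0 * vessel + rng.normal(0, 0.5, n)
        fid = [f"f{i}" for i in range(n)]
        spl = pd.DataFrame({"file_id": fid, "band": "low", "spl_db": spl_db})
        annot = pd.DataFrame({"file_id": fid, "sp_a": a_int, "sp_b": b_int,
                              "noise": vessel})
        covs = pd.DataFrame({"file_id": fid, "season": "spring",
                             "diel": "night"})
        spec = md.ModelSpec("spl_db", ("sp_a",), rng_seed=2, **FAST)
        res = md.contribution_model(spl, annot, covs, "spring", "night",
                                    contributors=("sp_a", "sp_b", "noise"),
                                    spec=spec)
        assert "sp_b" in res.removed
        ranked = res.ranked.set_index("contributor")
        assert ranked.loc["sp_a", "decision"] == "confirmed"
        assert {"sp_a", "noise"} <= set(ranked.index)

    def test_empty_stratum_skipped(self):
        t = study.scene_tables(97, days=3)
        res = md.contribution_model(t.spl, t.annotations, t.covariates,
                                    "fall", "day")
        assert res is None
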