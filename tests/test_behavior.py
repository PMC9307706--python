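"""Behavioral summaries, BIC-approximate Bayes factors, correlations."""

import numpy as np
import pandas as pd
import pytest

import motorddm as m
from motorddm.behavior import (
    bf_model_comparison,
    cell_summary,
    correlation_matrix,
    pearson_r,
)

from conftest import make_trials


def _cells_from_effects(rng, n_subj=20, spring_eff=0.0, ss_eff=0.0,
                        inter_eff=0.0, noise=1.0, base=10.0):
    rows = []
    for s in range(n_subj):
        subj_eff = rng.normal(0, 1)
        for ss in (3, 5):
            for spring in ("soft", "stiff"):
                y = (base + subj_eff
                     + (spring_eff if spring == "stiff" else 0.0)
                     + (ss_eff if ss == 5 else 0.0)
                     + (inter_eff if spring == "stiff" and ss == 5 else 0.0)
                     + rng.normal(0, noise))
                rows.append({"subject": f"s{s:02d}", "set_size": ss,
                             "spring": spring, "accuracy": y, "mean_rt": y,
                             "n_trials": 100})
    return pd.DataFrame(rows)


class TestCellSummary:
    def test_arithmetic(self):
        rows = [("s01", 1, i + 1, 3, "soft", True,
                 "match" if ok else "no-match", rt, False)
                for i, (ok, rt) in enumerate(zip(
                    [True, True, True, False], [0.5, 0.6, 0.7, 0.8]))]
        out = cell_summary(make_trials(rows))
        assert out.iloc[0]["accuracy"] == pytest.approx(0.75)
        assert out.iloc[0]["mean_rt"] == pytest.approx(0.65)
        assert out.iloc[0]["n_trials"] == 4

    def test_all_correct(self):
        rows = [("s01", 1, i + 1, 5, "stiff", True, "match", 0.6, False)
                for i in range(5)]
        assert cell_summary(make_trials(rows)).iloc[0]["accuracy"] == 1.0

    def test_against_hand_computed_table(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(20):
            ss = 3 if i < 10 else 5
            ok = i % 3 != 0
            rows.append(("s01", 1, i + 1, ss, "soft", True,
                         "match" if ok else "no-match",
                         0.5 + 0.01 * i, False))
        out = cell_summary(make_trials(rows)).set_index("set_size")
        # hand-computed: ss3 rows 0..9, misses at i = 0, 3, 6, 9
        assert out.loc[3, "accuracy"] == pytest.approx(6 / 10)
        assert out.loc[3, "mean_rt"] == pytest.approx(np.mean(0.5 + 0.01 * np.arange(10)))
        # ss5 rows 10..19, misses at i = 12, 15, 18
        assert out.loc[5, "accuracy"] == pytest.approx(7 / 10)

    def test_correct_only_switch(self):
        rows = [("s01", 1, 1, 3, "soft", True, "match", 0.4, False),
                ("s01", 1, 2, 3, "soft", True, "no-match", 2.0, False)]
        both = cell_summary(make_trials(rows))
        correct_only = cell_summary(make_trials(rows), correct_only_rt=True)
        assert both.iloc[0]["mean_rt"] == pytest.approx(1.2)
        assert correct_only.iloc[0]["mean_rt"] == pytest.approx(0.4)


class TestBayesFactors:
    def test_null_data_favors_null_in_majority(self):
        rng = np.random.default_rng(1)
        below_one = 0
        reps = 100
        for _ in range(reps):
            cells = _cells_from_effects(rng)
            bf = bf_model_comparison(cells, dv="accuracy")
            if bf.set_index("model").loc["set_size", "bf_vs_null"] < 1.0:
                below_one += 1
        assert below_one > reps / 2

    def test_strong_effect_detected(self):
        rng = np.random.default_rng(2)
        cells = _cells_from_effects(rng, n_subj=48, ss_eff=5.0, noise=1.0)
        bf = bf_model_comparison(cells, dv="accuracy").set_index("model")
        assert bf.loc["set_size", "bf_vs_null"] > 1e3

    def test_relative_bayes_factor_identity(self):
        # BF(A vs null) / BF(B vs null) equals the directly computed BF(A vs B)
        from motorddm.behavior import _bic_ols
        rng = np.random.default_rng(3)
        cells = _cells_from_effects(rng, ss_eff=1.0)
        bf = bf_model_comparison(cells, dv="mean_rt").set_index("model")
        a = bf.loc["spring+set_size", "bf_vs_null"]
        b = bf.loc["set_size", "bf_vs_null"]
        df = cells.sort_values(["subject", "set_size", "spring"])
        y = df["mean_rt"].to_numpy(dtype=float)
        subj = pd.get_dummies(df["subject"]).to_numpy(dtype=float)
        spring = (df["spring"] == "stiff").to_numpy(dtype=float)[:, None]
        ss = (df["set_size"] == 5).to_numpy(dtype=float)[:, None]
        bic_a = _bic_ols(y, np.hstack([subj, spring, ss]))
        bic_b = _bic_ols(y, np.hstack([subj, ss]))
        assert a / b == pytest.approx(float(np.exp((bic_b - bic_a) / 2)),
                                      rel=1e-9)

    def test_scale_invariance_seconds_vs_milliseconds(self):
        rng = np.random.default_rng(4)
        cells = _cells_from_effects(rng, ss_eff=0.5, noise=0.3)
        bf_s = bf_model_comparison(cells, dv="mean_rt")
        cells_ms = cells.assign(mean_rt=cells["mean_rt"] * 1000.0)
        bf_ms = bf_model_comparison(cells_ms, dv="mean_rt")
        np.testing.assert_allclose(bf_s["bf_vs_null"], bf_ms["bf_vs_null"],
                                   rtol=1e-6)

    def test_bic_matches_statsmodels_delta(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(5)
        cells = _cells_from_effects(rng, ss_eff=0.8)
        y = cells.sort_values(["subject", "set_size", "spring"])["accuracy"]
        df = cells.sort_values(["subject", "set_size", "spring"])
        X0 = pd.get_dummies(df["subject"], dtype=float)
        X1 = X0.assign(ss=(df["set_size"] == 5).astype(float))
        b0 = sm.OLS(y.to_numpy(), X0.to_numpy()).fit().bic
        b1 = sm.OLS(y.to_numpy(), X1.to_numpy()).fit().bic
        bf = bf_model_comparison(cells, dv="accuracy").set_index("model")
        assert bf.loc["set_size", "bf_vs_null"] == pytest.approx(
            float(np.exp((b0 - b1) / 2)), rel=1e-6)

    def test_missing_cells_name_subjects(self):
        rng = np.random.default_rng(6)
        cells = _cells_from_effects(rng, n_subj=4)
        broken = cells[~((cells["subject"] == "s01")
                         & (cells["spring"] == "stiff"))]
        with pytest.raises(ValueError, match="s01"):
            bf_model_comparison(broken)

    def test_inclusion_bayes_factors_present(self):
        rng = np.random.default_rng(7)
        cells = _cells_from_effects(rng, ss_eff=2.0, spring_eff=0.5)
        bf = bf_model_comparison(cells, dv="mean_rt")
        inc = bf.attrs["inclusion_bf"]
        assert set(inc) == {"spring", "set_size", "interaction"}
        assert inc["set_size"] > 1.0


class TestPearson:
    def test_perfect_positive(self):
        r, n = pearson_r([1, 2, 3, 4], [1, 2, 3, 4])
        assert r == pytest.approx(1.0)
        assert n == 4

    def test_perfect_negative(self):
        r, _ = pearson_r([1, 2, 3], [6, 4, 2])
        assert r == pytest.approx(-1.0)

    def test_pairwise_complete_handling(self):
        x = [1, 2, np.nan, 4, 5]
        y = [2, 4, 6, np.nan, 10]
        r, n = pearson_r(x, y)
        assert n == 3
        assert r == pytest.approx(np.corrcoef([1, 2, 5], [2, 4, 10])[0, 1])

    def test_manual_ten_pair_oracle(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=10)
        y = 0.6 * x + rng.normal(scale=0.5, size=10)
        r, n = pearson_r(x, y)
        assert n == 10
        assert r == pytest.approx(float(np.corrcoef(x, y)[0, 1]), abs=1e-12)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match="3 complete pairs"):
            pearson_r([1, np.nan, 3], [1, 2, np.nan])


class TestCorrelationMatrix:
    def _inputs(self, rng, n=12):
        v_true = rng.normal(2.0, 0.5, n)
        subjects = [f"s{i:02d}" for i in range(n)]
        params = pd.DataFrame({
            "v(ss3)": v_true + rng.normal(0, 0.1, n),
            "a": rng.normal(1.8, 0.2, n),
        }, index=subjects)
        assessments = pd.DataFrame({
            "subject": subjects,
            "sdmt_oral": 30 + 8 * v_true + rng.normal(0, 1, n),
            "sdmt_written": rng.normal(40, 5, n),
            "nhpt_seconds": rng.normal(20, 2, n),
        })
        return params, assessments

    def test_unit_diagonal_and_symmetry(self):
        rng = np.random.default_rng(9)
        params, assessments = self._inputs(rng)
        mat = correlation_matrix(params, assessments)
        np.testing.assert_allclose(np.diag(mat), 1.0)
        np.testing.assert_allclose(mat.to_numpy(),
                                   mat.to_numpy().T, atol=1e-12)

    def test_affine_assessment_tracks_drift(self):
        rng = np.random.default_rng(10)
        params, assessments = self._inputs(rng, n=48)
        mat = correlation_matrix(params, assessments)
        assert mat.loc["sdmt_oral", "v(ss3)"] > 0.5

    def test_caveat_attached(self):
        rng = np.random.default_rng(11)
        mat = correlation_matrix(*self._inputs(rng))
        assert "caution" in mat.attrs["caveat"]

    def test_missing_scores_propagate(self):
        rng = np.random.default_rng(12)
        params, assessments = self._inputs(rng)
        assessments.loc[0, "sdmt_oral"] = np.nan
        mat = correlation_matrix(params, assessments)
        assert np.isfinite(mat.loc["sdmt_oral", "v(ss3)"])
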