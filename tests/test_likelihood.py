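"""Wiener first-passage likelihood: series, variability mixing, outlier mixture.

Oracles: closed-form absorption probabilities, brute-force series truncation,
numerical quadrature for normalization, and Monte-Carlo simulation for the
drift-variability integral.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import motorddm as m
from motorddm.core import Condition
from motorddm.likelihood import dataset_loglik, trial_loglik
from motorddm.simulate import simulate_trials_batch

from conftest import make_trials


class TestChoiceProbability:
    def test_symmetric_drift_free_case(self):
        assert m.choice_probability(0.0, 2.0, 0.5) == pytest.approx(0.5)
        assert m.choice_probability(0.0, 1.0, 0.3) == pytest.approx(0.3)

    def test_dominant_drift_limit(self):
        assert m.choice_probability(10.0, 2.0, 0.5) == pytest.approx(1.0, abs=1e-6)

    def test_against_monte_carlo_simulation(self):
        rng = np.random.default_rng(11)
        p = m.DDMParameters(v=2.57, a=1.78, ter=0.3)
        n = 40_000
        _, bnd = simulate_trials_batch(p, n, rng, dt=2e-4)
        phat = (bnd == 1).mean()
        pref = m.choice_probability(2.57, 1.78, 0.5)
        se = math.sqrt(pref * (1 - pref) / n)
        assert abs(phat - pref) < 2 * se + 1e-3

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            m.choice_probability(1.0, -1.0, 0.5)
        with pytest.raises(ValueError):
            m.choice_probability(1.0, 1.0, 1.5)


class TestWfptDensity:
    def test_no_mass_at_nonpositive_times(self):
        assert m.wfpt_density(-0.1, "lower", 1.0, 2.0, 0.5) == 0.0
        assert m.wfpt_density(0.0, "upper", 1.0, 2.0, 0.5) == 0.0

    @pytest.mark.parametrize("v, a, z", [
        (2.57, 1.78, 0.5), (0.0, 1.0, 0.3), (1.78, 2.2, 0.5), (-1.0, 1.5, 0.6),
    ])
    def test_normalization_by_quadrature(self, v, a, z):
        t = np.concatenate([np.linspace(1e-5, 3, 60_000),
                            np.linspace(3.0001, 60, 30_000)])
        total = np.trapezoid(
            m.wfpt_density(t, "upper", v, a, z) +
            m.wfpt_density(t, "lower", v, a, z), t)
        assert total == pytest.approx(1.0, abs=1e-3)

    def test_against_brute_force_series(self):
        # large-time series truncated at 1000 terms (oracle)
        t, v, a, z = 0.5, 1.0, 2.0, 0.5
        tt = t / a**2
        s = sum(k * math.exp(-k**2 * math.pi**2 * tt / 2)
                * math.sin(k * math.pi * z) for k in range(1, 1001))
        oracle = math.pi * s / a**2 * math.exp(-v * a * z - v**2 * t / 2)
        assert m.wfpt_density(t, "lower", v, a, z) == pytest.approx(
            oracle, abs=1e-6)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        t=st.floats(0.05, 4.0),
        v=st.floats(-4.0, 4.0),
        a=st.floats(0.5, 3.0),
        z=st.floats(0.15, 0.85),
    )
    def test_reflection_symmetry(self, t, v, a, z):
        fl = m.wfpt_density(t, "lower", v, a, z)
        fu = m.wfpt_density(t, "upper", -v, a, 1.0 - z)
        assert fl == pytest.approx(fu, abs=1e-7, rel=1e-6)


class TestFullDensity:
    def test_degenerate_variabilities_match_plain_density(self):
        p = m.DDMParameters(v=1.5, a=1.8, ter=0.4)
        for rt in (0.6, 1.0, 2.5):
            assert m.full_density(rt, "upper", p) == pytest.approx(
                m.wfpt_density(rt - 0.4, "upper", 1.5, 1.8, 0.5), rel=1e-9)

    def test_zero_before_minimum_nondecision_time(self):
        p = m.DDMParameters(v=1.5, a=1.8, ter=0.4, st=0.2)
        assert m.full_density(0.29, "upper", p) == 0.0

    def test_drift_variability_against_monte_carlo(self):
        # average the plain density over 10^5 drawn drifts (oracle)
        rng = np.random.default_rng(5)
        p = m.DDMParameters(v=1.0, a=2.0, ter=0.3, sv=0.5)
        rt = 1.0
        drifts = rng.normal(1.0, 0.5, 100_000)
        mc = np.mean([m.wfpt_density(rt - 0.3, "upper", float(d), 2.0, 0.5)
                      for d in drifts[:20_000]])
        full = m.full_density(rt, "upper", p)
        assert full == pytest.approx(mc, abs=1e-3)

    def test_full_normalization_over_reference_grid(self):
        p = m.DDMParameters(v=2.57, a=1.78, ter=0.4, z=0.5, sv=0.5,
                            st=0.15, sz=0.1)
        lo = p.ter - p.st / 2
        t = np.concatenate([np.linspace(lo, 2.0, 40_000),
                            np.linspace(2.0001, 30, 15_000)])
        total = np.trapezoid(m.full_density(t, "upper", p)
                             + m.full_density(t, "lower", p), t)
        assert total == pytest.approx(1.0, abs=1e-3)


class TestTrialLoglik:
    def _trial(self, rt=0.8):
        return m.TrialRecord("s01", 1, 1, Condition(3, "soft"), match=True,
                             response="match", rt=rt)

    def test_no_contamination_reduces_to_density(self):
        p = m.DDMParameters(v=2.0, a=1.5, ter=0.3)
        ll = trial_loglik(self._trial(), p, p_outlier=0.0)
        assert ll == pytest.approx(math.log(m.full_density(0.8, "upper", p)))

    def test_pure_uniform_outlier(self):
        p = m.DDMParameters(v=2.0, a=1.5, ter=0.3)
        cfg = m.LikelihoodConfig(rt_ceiling=5.0)
        ll = trial_loglik(self._trial(), p, p_outlier=1.0, config=cfg)
        assert ll == pytest.approx(math.log(0.1))

    def test_mixture_arithmetic(self):
        p = m.DDMParameters(v=2.0, a=1.5, ter=0.3)
        cfg = m.LikelihoodConfig(rt_ceiling=5.0)
        f = m.full_density(0.8, "upper", p)
        ll = trial_loglik(self._trial(), p, p_outlier=0.05, config=cfg)
        assert ll == pytest.approx(math.log(0.95 * f + 0.05 * 0.1))

    def test_missing_rt_is_contract_error(self):
        t = m.TrialRecord("s01", 1, 1, Condition(3, "soft"), match=True,
                          response=None, rt=None)
        with pytest.raises(ValueError, match="no response time"):
            trial_loglik(t, m.DDMParameters(v=2, a=1.5, ter=0.3), 0.05)


class TestDatasetLoglik:
    def _table(self, n=10, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            ss = 3 if i % 2 == 0 else 5
            ok = rng.random() < 0.9
            rows.append(("s01", 1, i + 1, ss, "soft", True,
                         "match" if ok else "no-match",
                         float(rng.uniform(0.5, 1.5)), False))
        return make_trials(rows)

    def _params(self):
        return {c: m.DDMParameters(v=2.0 if c.set_size == 3 else 1.5,
                                   a=1.8, ter=0.35)
                for c in m.ALL_CONDITIONS}

    def test_empty_input_is_zero(self):
        assert dataset_loglik(self._table(0), self._params(), 0.05) == 0.0

    def test_additivity_over_disjoint_subsets(self):
        df = self._table(12)
        p = self._params()
        whole = dataset_loglik(df, p, 0.05)
        parts = (dataset_loglik(df.iloc[:5], p, 0.05)
                 + dataset_loglik(df.iloc[5:], p, 0.05))
        assert whole == pytest.approx(parts, rel=1e-12)

    def test_matches_per_trial_sum(self):
        df = self._table(10)
        p = self._params()
        total = 0.0
        for _, row in df.iterrows():
            t = m.TrialRecord(row.subject, row.block, row.trial,
                              Condition(int(row.set_size), row.spring),
                              bool(row.match), row.response,
                              float(row.rt_seconds))
            total += trial_loglik(t, p[Condition(int(row.set_size), row.spring)],
                                  0.05)
        assert dataset_loglik(df, p, 0.05) == pytest.approx(total, rel=1e-10)

    def test_unresolvable_condition_is_specification_error(self):
        from motorddm.core import SpecificationError
        df = self._table(4)
        partial = {c: v for c, v in self._params().items() if c.set_size == 3}
        with pytest.raises(SpecificationError):
            dataset_loglik(df, partial, 0.05)
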