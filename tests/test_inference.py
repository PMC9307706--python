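"""Priors, sampler correctness, diagnostics, summaries, predictive checks."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

import motorddm as m
from motorddm.core import ModelSpec, parameter_nodes
from motorddm.inference import (
    MCMCConfig,
    PosteriorFit,
    PriorSet,
    default_priors,
    diagnostics,
    posterior_predictive,
    summarize,
)
from motorddm.simulate import simulate_trials_batch

from conftest import make_trials


def make_fit(draws_by_node, chains=2, deviance=None, spec=None,
             subjects=("s01",)):
    """Construct a PosteriorFit directly from per-node draw arrays."""
    names = tuple(draws_by_node)
    arrs = [np.asarray(v, dtype=float) for v in draws_by_node.values()]
    nd = arrs[0].shape[-1] // 1
    stacked = np.stack(arrs, axis=-1)          # (chains, draws, nodes)
    if stacked.ndim == 2:
        stacked = np.tile(stacked[None], (chains, 1, 1))
    dev = deviance if deviance is not None else np.zeros(stacked.shape[:2])
    return PosteriorFit(
        draws=stacked, node_names=names, deviance=np.asarray(dev, dtype=float),
        spec=spec or m.build_model_space()[3],
        mcmc=MCMCConfig(iterations=stacked.shape[1] + 1,
                        burn_in=1, chains=stacked.shape[0]),
        likelihood_config=m.LikelihoodConfig(),
        p_outlier=0.05, subjects=tuple(subjects), data_fingerprint="manual",
    )


class TestDefaultPriors:
    def test_priors_are_proper(self):
        pr = default_priors()
        for dist in [pr.mu["v"], pr.mu["a"], pr.mu["ter"], pr.sd["v"],
                     pr.sd["ter"], pr.z, pr.sv, pr.st]:
            lo, hi = dist.support()
            lo = max(lo, -60.0)
            hi = min(hi, 60.0)
            total, _ = integrate.quad(dist.pdf, lo, hi, limit=200)
            assert total == pytest.approx(1.0, abs=1e-3)
        # conditional start-range prior integrates to 1 given z
        for z in (0.3, 0.5, 0.7):
            hi = min(2 * z, 2 * (1 - z))
            total = integrate.quad(
                lambda s: math.exp(PriorSet.sz_logpdf(s, z)), 0, hi * 0.9999
            )[0]
            assert total == pytest.approx(1.0, abs=1e-3)

    def test_prior_support_respects_invariants(self):
        pr = default_priors()
        rng = np.random.default_rng(0)
        assert (pr.mu["a"].rvs(500, random_state=rng) > 0).all()
        assert (pr.mu["ter"].rvs(500, random_state=rng) >= 0).all()
        z = pr.z.rvs(500, random_state=rng)
        assert ((z > 0) & (z < 1)).all()

    def test_prior_predictive_rts_are_plausible(self):
        # most prior draws should produce median RTs inside the response window
        pr = default_priors()
        rng = np.random.default_rng(1)
        ok = 0
        n_draws = 30
        for _ in range(n_draws):
            v = float(pr.mu["v"].rvs(random_state=rng))
            a = float(pr.mu["a"].rvs(random_state=rng))
            ter = float(pr.mu["ter"].rvs(random_state=rng))
            p = m.DDMParameters(v=v, a=a, ter=ter)
            rt, bnd = simulate_trials_batch(p, 100, rng, dt=2e-3)
            med = np.nanmedian(rt[bnd >= 0]) if (bnd >= 0).any() else np.nan
            if np.isfinite(med) and 0.2 <= med <= 5.0:
                ok += 1
        assert ok >= n_draws / 2


class TestSamplerConjugateOracle:
    def test_matches_closed_form_posterior(self):
        rng = np.random.default_rng(3)
        S, n_i, tau = 10, 25, 0.7
        theta = rng.normal(5.0, tau, S)
        rows = []
        for s in range(S):
            for i, y in enumerate(rng.normal(theta[s], 1.0, n_i)):
                rows.append((f"s{s:02d}", 1, i + 1, 3, "soft", True, "match",
                             y, False))
        df = make_trials(rows)
        fit = m.fit(df, ModelSpec(0),
                    mcmc=MCMCConfig(iterations=4000, burn_in=800, chains=2,
                                    seed=17),
                    likelihood_kind="gaussian", update_params=("v",),
                    sample_nuisance=False, fix_group_sd={"v": tau})
        ybar = df.groupby("subject")["rt_seconds"].mean().to_numpy()
        prec = 1 / 9 + S / (tau**2 + 1 / n_i)
        mean_cf = (2 / 9 + ybar.sum() / (tau**2 + 1 / n_i)) / prec
        post = fit.node_draws("v")
        import arviz as az
        mc_se = post.std() / math.sqrt(float(az.ess(post)))
        assert post.mean() == pytest.approx(mean_cf, abs=3 * mc_se + 1e-3)
        assert post.std() == pytest.approx(prec ** -0.5, rel=0.15)


class TestFitBookkeeping:
    def test_retained_draw_count_and_node_labels(self, tiny_fit, reference):
        spec, _ = reference
        _, fit = tiny_fit
        ch, nd, _ = fit.draws.shape
        assert ch == 2 and nd == 500 - 200
        # every node of the model's parameter-node list appears as a group
        # label; subject-level and SD nodes accompany the condition nodes
        for node in parameter_nodes(spec):
            assert node in fit.node_names
        for s in fit.subjects:
            assert f"v(ss3)[{s}]" in fit.node_names

    def test_strong_set_size_effect_recovered_in_direction(self, tiny_fit):
        _, fit = tiny_fit
        assert fit.posterior_mean("v(ss3)") > fit.posterior_mean("v(ss5)")
        assert fit.posterior_mean("ter(ss5:stiff)") > \
            fit.posterior_mean("ter(ss3:soft)")

    def test_missing_cells_rejected(self):
        rows = [("s01", 1, i, 3, "soft", True, "match", 0.6, False)
                for i in range(20)]
        with pytest.raises(ValueError, match="every design cell"):
            m.fit(make_trials(rows), m.build_model_space()[3],
                  mcmc=MCMCConfig(iterations=10, burn_in=5, chains=1))

    def test_save_load_round_trip(self, tiny_fit, tmp_path):
        _, fit = tiny_fit
        fit.save(tmp_path / "f")
        back = PosteriorFit.load(tmp_path / "f")
        assert back.node_names == fit.node_names
        np.testing.assert_allclose(back.draws, fit.draws)
        np.testing.assert_allclose(back.deviance, fit.deviance)
        assert back.spec == fit.spec


class TestDiagnostics:
    def test_identical_chains_give_unit_rhat(self):
        base = np.sin(np.linspace(0, 20, 400)) + np.linspace(0, 1, 400)
        seq = np.concatenate([base, base])       # identical split halves
        fit = make_fit({"v(ss3)": np.stack([seq, seq])})
        d = diagnostics(fit, nodes=["v(ss3)"])
        # identical chains: between-chain variance is 0, so split-R-hat is 1
        # up to the finite-sample factor sqrt((n-1)/n)
        assert d.loc["v(ss3)", "rhat"] == pytest.approx(1.0, abs=2e-3)

    def test_iid_chains_converge(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((2, 2000))
        fit = make_fit({"v(ss3)": x})
        d = diagnostics(fit, nodes=["v(ss3)"])
        assert d.loc["v(ss3)", "rhat"] < 1.01
        assert d.loc["v(ss3)", "ess"] == pytest.approx(4000, rel=0.2)

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((2, 1000))
        x[1] += 5.0
        fit = make_fit({"v(ss3)": x})
        assert diagnostics(fit, nodes=["v(ss3)"]).loc["v(ss3)", "rhat"] > 1.5

    def test_single_chain_rhat_unavailable(self):
        rng = np.random.default_rng(6)
        fit = make_fit({"v(ss3)": rng.standard_normal((1, 500))})
        assert np.isnan(diagnostics(fit, nodes=["v(ss3)"]).loc["v(ss3)", "rhat"])


class TestSummarize:
    def test_constant_draws(self):
        fit = make_fit({"v(ss3)": np.full((2, 100), 2.57)})
        row = summarize(fit).iloc[0]
        assert row["mean"] == pytest.approx(2.57)
        assert row["hi97.5"] - row["lo2.5"] == pytest.approx(0.0)

    def test_quantile_convergence_on_standard_normal(self):
        rng = np.random.default_rng(7)
        fit = make_fit({"v(ss3)": rng.standard_normal((1, 1_000_000))})
        row = summarize(fit).iloc[0]
        assert row["lo2.5"] == pytest.approx(-1.96, abs=0.01)
        assert row["hi97.5"] == pytest.approx(1.96, abs=0.01)

    def test_one_row_per_node_with_condition_keys(self, tiny_fit):
        _, fit = tiny_fit
        tab = summarize(fit)
        assert len(tab) == len(fit.node_names)
        row = tab[tab["node"] == "ter(ss5:stiff)"].iloc[0]
        assert (row["parameter"], row["set_size"], row["spring"]) == \
            ("ter", 5, "stiff")

    def test_needs_at_least_two_draws(self):
        fit = make_fit({"v(ss3)": np.full((1, 1), 1.0)})
        with pytest.raises(ValueError):
            summarize(fit)


class TestPosteriorPredictive:
    def test_self_consistency_envelope_coverage(self, tiny_fit):
        clean, fit = tiny_fit
        rng = np.random.default_rng(8)
        ppc = posterior_predictive(fit, clean, n_rep=40, rng=rng)
        scored = ppc.dropna(subset=["observed", "lo2.5", "hi97.5"])
        inside = ((scored["observed"] >= scored["lo2.5"])
                  & (scored["observed"] <= scored["hi97.5"]))
        assert inside.mean() >= 0.80

    def test_fixed_seed_reproducible(self, tiny_fit):
        clean, fit = tiny_fit
        p1 = posterior_predictive(fit, clean, 5, np.random.default_rng(9))
        p2 = posterior_predictive(fit, clean, 5, np.random.default_rng(9))
        pd.testing.assert_frame_equal(p1, p2)

    def test_absent_error_cells_are_nan_not_zero(self, tiny_fit):
        clean, fit = tiny_fit
        # force one cell to all-correct responses
        df = clean.copy()
        s = fit.subjects[0]
        sel = (df["subject"] == s) & (df["set_size"] == 3) & \
            (df["spring"] == "soft")
        df.loc[sel, "response"] = df.loc[sel, "match"].map(
            {True: "match", False: "no-match"})
        ppc = posterior_predictive(fit, df, 3, np.random.default_rng(10))
        cell = ppc[(ppc["subject"] == s) & (ppc["set_size"] == 3)
                   & (ppc["spring"] == "soft") & (ppc["kind"] == "error")]
        assert cell["observed"].isna().all()

    def test_zero_replicates_rejected(self, tiny_fit):
        clean, fit = tiny_fit
        with pytest.raises(ValueError):
            posterior_predictive(fit, clean, 0, np.random.default_rng(11))
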