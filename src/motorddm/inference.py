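"""Hierarchical Bayesian estimation of diffusion-model parameters by MCMC.

The model: for each parameter that varies by subject (v, a, ter) and each
condition cell induced by the model specification, subjects' values are
Normal(group mean, group SD); bias z and the across-trial variabilities
sv/st/sz are single group-level quantities shared by everyone; trials enter
through the Wiener first-passage likelihood contaminated by a fixed-fraction
uniform outlier mixture (p_outlier = 0.05 by default, not estimated).

Sampling is adaptive Metropolis-within-Gibbs in a centered parameterization:
subject-level nodes are updated single-site, simultaneously across subjects
(valid because subjects are conditionally independent given the group
nodes); group means and SDs have likelihood-free conditional updates; the
four group-only nuisance nodes are one joint Metropolis block so each sweep
costs four full-data likelihood passes.  Proposal scales adapt during
burn-in only, so retained draws come from a fixed Markov kernel.

A unit-variance Gaussian likelihood (``likelihood_kind="gaussian"``) can be
substituted for the Wiener likelihood; it turns the model into a conjugate
normal hierarchy whose posterior is known in closed form, which is used to
verify the sampler machinery.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import _kernels
from .core import (
    ALL_CONDITIONS,
    Condition,
    ModelSpec,
    add_correct,
    cell_label,
    condition_cells,
    node_label,
)
from .likelihood import LikelihoodConfig, DEFAULT_CONFIG, _leggauss

__all__ = [
    "MCMCConfig",
    "PosteriorFit",
    "PriorSet",
    "default_priors",
    "fit",
    "diagnostics",
    "summarize",
    "posterior_predictive",
]

LOG_2PI = math.log(2.0 * math.pi)
PARAMS = ("v", "a", "ter")
NUIS = ("z", "sv", "st", "sz")


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings (iterations include burn-in)."""

    iterations: int = 5000
    burn_in: int = 1000
    chains: int = 2
    seed: int = 0
    adapt_window: int = 50
    thinning: int = 1

    def __post_init__(self) -> None:
        if not self.burn_in < self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.chains < 1:
            raise ValueError("chains must be >= 1")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burn_in) // self.thinning


class PriorSet:
    """Proper weakly-informative priors for all node families.

    Group means: v ~ Normal(2, 3); a ~ Normal(1.5, 1) truncated positive;
    ter ~ Normal(0.4, 0.3) truncated nonnegative.  Group SDs: Half-Normal(1)
    for v and a, Half-Normal(0.2) for ter.  Nuisance: z ~ Beta(5, 5),
    sv ~ Half-Normal(2), st ~ Half-Normal(0.3) with the joint constraint
    ter - st/2 >= 0 enforced in the sampler, and
    sz | z ~ Uniform(0, min(2z, 2(1-z))).
    """

    def __init__(self) -> None:
        self.mu = {
            "v": stats.norm(2.0, 3.0),
            "a": stats.truncnorm(a=-1.5, b=np.inf, loc=1.5, scale=1.0),
            "ter": stats.truncnorm(a=-0.4 / 0.3, b=np.inf, loc=0.4, scale=0.3),
        }
        self.sd = {
            "v": stats.halfnorm(scale=1.0),
            "a": stats.halfnorm(scale=1.0),
            "ter": stats.halfnorm(scale=0.2),
        }
        self.z = stats.beta(5.0, 5.0)
        self.sv = stats.halfnorm(scale=2.0)
        self.st = stats.halfnorm(scale=0.3)

    @staticmethod
    def sz_logpdf(sz: float, z: float) -> float:
        """Conditional Uniform(0, min(2z, 2(1-z))) log density."""
        hi = min(2.0 * z, 2.0 * (1.0 - z))
        if 0.0 <= sz < hi:
            return -math.log(hi)
        return -np.inf


def default_priors(spec: ModelSpec | None = None) -> PriorSet:
    """Prior set for any model of the candidate space (spec-independent)."""
    return PriorSet()


def _fingerprint(df: pd.DataFrame) -> str:
    h = hashlib.sha256()
    cols = df[["subject", "set_size", "spring", "rt_seconds"]].reset_index(drop=True)
    h.update(pd.util.hash_pandas_object(cols, index=False).to_numpy().tobytes())
    return h.hexdigest()[:16]


def _norm_logpdf(x, mu, sd):
    return -0.5 * ((x - mu) / sd) ** 2 - math.log(sd) - 0.5 * LOG_2PI


@dataclass
class PosteriorFit:
    """Retained MCMC draws with node labels and per-draw deviance."""

    draws: np.ndarray                   # (chains, n_draws, n_nodes)
    node_names: tuple
    deviance: np.ndarray                # (chains, n_draws)
    spec: ModelSpec
    mcmc: MCMCConfig
    likelihood_config: LikelihoodConfig
    p_outlier: float
    subjects: tuple
    data_fingerprint: str
    likelihood_kind: str = "wfpt"
    acceptance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {n: i for i, n in enumerate(self.node_names)}

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    @property
    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[2])

    def node_index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"unknown node {name!r}") from None

    def node_draws(self, name: str) -> np.ndarray:
        """Draws of one node, shape (chains, n_draws) — the trace."""
        return self.draws[:, :, self.node_index(name)]

    def posterior_mean(self, name: str) -> float:
        return float(self.node_draws(name).mean())

    def means(self) -> pd.Series:
        return pd.Series(self.flat.mean(axis=0), index=list(self.node_names))

    def subject_means(self, param: str) -> pd.DataFrame:
        """Posterior means of subject-level nodes: subjects x cells."""
        cells = condition_cells(self.spec.factors_of(param))
        data = {}
        for c in cells:
            base = node_label(param, c)
            data[base] = [self.posterior_mean(f"{base}[{s}]") for s in self.subjects]
        return pd.DataFrame(data, index=list(self.subjects))

    def save(self, prefix: str | Path) -> None:
        """Write draws as delimited text plus a JSON sidecar."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        ch, nd, _ = self.draws.shape
        tab = pd.DataFrame(self.flat, columns=list(self.node_names))
        tab.insert(0, "chain", np.repeat(np.arange(ch), nd))
        tab.insert(1, "draw", np.tile(np.arange(nd), ch))
        tab.insert(2, "deviance", self.deviance.reshape(-1))
        tab.to_csv(f"{prefix}_draws.csv", index=False)
        sidecar = {
            "node_names": list(self.node_names),
            "spec": self.spec.to_json(),
            "mcmc": self.mcmc.__dict__,
            "likelihood_config": self.likelihood_config.__dict__,
            "p_outlier": self.p_outlier,
            "subjects": list(self.subjects),
            "data_fingerprint": self.data_fingerprint,
            "likelihood_kind": self.likelihood_kind,
            "chains": ch,
            "n_draws": nd,
        }
        Path(f"{prefix}.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, prefix: str | Path) -> "PosteriorFit":
        prefix = Path(prefix)
        sidecar = json.loads(Path(f"{prefix}.json").read_text())
        tab = pd.read_csv(f"{prefix}_draws.csv")
        ch, nd = sidecar["chains"], sidecar["n_draws"]
        names = sidecar["node_names"]
        return cls(
            draws=tab[names].to_numpy().reshape(ch, nd, len(names)),
            node_names=tuple(names),
            deviance=tab["deviance"].to_numpy().reshape(ch, nd),
            spec=ModelSpec.from_json(sidecar["spec"]),
            mcmc=MCMCConfig(**sidecar["mcmc"]),
            likelihood_config=LikelihoodConfig(**sidecar["likelihood_config"]),
            p_outlier=sidecar["p_outlier"],
            subjects=tuple(sidecar["subjects"]),
            data_fingerprint=sidecar["data_fingerprint"],
            likelihood_kind=sidecar["likelihood_kind"],
        )


def _ez_point(pc: float, vrt: float, mrt: float) -> tuple[float, float, float]:
    """Moment ("EZ"-style) estimates of (v, a, ter) from one cell's data.

    Used only to initialise chains at plausible values; accuracy is clamped
    away from 0.5 and 1 and the outputs clipped to a broad plausible box.
    """
    pc = min(max(pc, 0.55), 0.985)
    vrt = max(vrt, 1e-4)
    L = math.log(pc / (1.0 - pc))
    x = L * (L * pc * pc - L * pc + pc - 0.5) / vrt
    v = math.copysign(abs(x) ** 0.25, pc - 0.5)
    v = float(np.clip(v, 0.3, 6.0))
    a = float(np.clip(L / v, 0.5, 4.0))
    va = v * a
    mdt = (a / (2.0 * v)) * (1.0 - math.exp(-va)) / (1.0 + math.exp(-va))
    ter = max(mrt - mdt, 0.08)
    return v, a, ter


class _State:
    """Mutable per-chain sampler state."""

    __slots__ = ("V", "mu", "sd", "nuis", "ptr", "ll")

    def __init__(self, V, mu, sd, nuis, ptr, ll):
        self.V, self.mu, self.sd = V, mu, sd
        self.nuis, self.ptr, self.ll = nuis, ptr, ll


class _Sampler:
    """Dataset-bound sampler (data, indices and likelihood plumbing)."""

    def __init__(self, trials, spec, priors, likelihood_config, p_outlier,
                 likelihood_kind):
        self.spec = spec
        self.priors = priors
        self.cfg = likelihood_config
        self.p_outlier = p_outlier
        self.kind = likelihood_kind

        df = add_correct(trials).sort_values(
            ["subject", "block", "trial"], kind="mergesort"
        ).reset_index(drop=True)
        self.subjects = tuple(sorted(df["subject"].astype(str).unique()))
        sub_ix = {s: i for i, s in enumerate(self.subjects)}
        self.S = len(self.subjects)
        self.n = len(df)
        self.rt = df["rt_seconds"].to_numpy(dtype=float)
        self.up = df["correct"].to_numpy(dtype=bool)
        self.subj = df["subject"].astype(str).map(sub_ix).to_numpy(dtype=np.int64)
        conds = [Condition(int(ss), sp) for ss, sp in
                 zip(df["set_size"], df["spring"])]
        full_cells = condition_cells(frozenset({"SS", "SPC"}))
        f2i = {c: i for i, c in enumerate(full_cells)}
        both = frozenset({"SS", "SPC"})
        self.full_ix = np.array(
            [f2i[cell_label(both, c)] for c in conds], dtype=np.int64
        )

        self.cells = {p: condition_cells(spec.factors_of(p)) for p in PARAMS}
        self.cell_ix = {}
        self.full2cell = {}
        for p in PARAMS:
            lab2ix = {c: i for i, c in enumerate(self.cells[p])}
            fac = spec.factors_of(p)
            self.cell_ix[p] = np.array(
                [lab2ix[cell_label(fac, c)] for c in conds], dtype=np.int64
            )
            self.full2cell[p] = np.array(
                [lab2ix[cell_label(fac, c)] for c in ALL_CONDITIONS],
                dtype=np.int64,
            )

        # per-(param, cell) trial indices sorted by subject + reduceat starts
        self.upd = {}
        for p in PARAMS:
            for ci in range(len(self.cells[p])):
                idx = np.flatnonzero(self.cell_ix[p] == ci)
                subj_of = self.subj[idx]
                starts = np.searchsorted(subj_of, np.arange(self.S))
                self.upd[(p, ci)] = (idx, subj_of, starts)
        self.all_idx = np.arange(self.n)

        self.xq, self.wq = _leggauss(likelihood_config.quadrature_points)
        self.u_dens = likelihood_config.outlier_density

        names: list[str] = []
        for p in PARAMS:
            names += [node_label(p, c) for c in self.cells[p]]
        for p in PARAMS:
            names += [f"sigma[{node_label(p, c)}]" for c in self.cells[p]]
        names += list(NUIS)
        for p in PARAMS:
            for c in self.cells[p]:
                names += [f"{node_label(p, c)}[{s}]" for s in self.subjects]
        self.node_names = tuple(names)

    # -- likelihood -------------------------------------------------------
    def loglik(self, idx, v_tr, a_tr, t_tr, z, sv, st, sz):
        out = np.empty(idx.size)
        if self.kind == "gaussian":
            np.subtract(self.rt[idx], v_tr, out)
            out *= out
            out *= -0.5
            out -= 0.5 * LOG_2PI
            return out
        _kernels.mixture_loglik_batch(
            self.rt[idx], self.up[idx],
            np.ascontiguousarray(v_tr), np.ascontiguousarray(a_tr),
            np.ascontiguousarray(t_tr),
            z, sv, st, sz, self.p_outlier, self.u_dens,
            self.xq, self.wq, self.cfg.series_tolerance, out,
        )
        return out

    # -- initialisation ---------------------------------------------------
    def ez_table(self) -> np.ndarray:
        """Subject x design-cell moment estimates, shape (S, 4, 3)."""
        est = np.empty((self.S, len(ALL_CONDITIONS), 3))
        for s in range(self.S):
            sm = self.subj == s
            for j in range(len(ALL_CONDITIONS)):
                m = sm & (self.full_ix == j)
                if not m.any():
                    est[s, j] = (2.0, 1.8, 0.4)
                    continue
                pc = float(self.up[m].mean())
                r = self.rt[m & self.up]
                if r.size < 2:
                    r = self.rt[m]
                est[s, j] = _ez_point(pc, float(np.var(r)), float(np.mean(r)))
        return est

    def initial_state(self, rng: np.random.Generator,
                      fix_group_sd: dict | None = None) -> _State:
        fix_group_sd = fix_group_sd or {}
        if self.kind == "gaussian":
            V = {"v": np.zeros((self.S, len(self.cells["v"])))}
            for s in range(self.S):
                V["v"][s, :] = self.rt[self.subj == s].mean()
            V["a"] = np.full((self.S, len(self.cells["a"])), 1.5)
            V["ter"] = np.full((self.S, len(self.cells["ter"])), 0.4)
            nuis = np.array([0.5, 0.0, 0.0, 0.0])
        else:
            ez = self.ez_table()
            V = {}
            for p_i, p in enumerate(PARAMS):
                V[p] = np.zeros((self.S, len(self.cells[p])))
                for ci in range(len(self.cells[p])):
                    sel = self.full2cell[p] == ci
                    V[p][:, ci] = ez[:, sel, p_i].mean(axis=1)
            nuis = np.array([0.5, 0.3, 0.1, 0.05])
            V["ter"] = np.maximum(V["ter"], nuis[2] / 2.0 + 0.01)
        jitter = {"v": 0.05, "a": 0.05, "ter": 0.01}
        for p in PARAMS:
            V[p] = V[p] + jitter[p] * rng.standard_normal(V[p].shape)
            if p == "a":
                V[p] = np.maximum(V[p], 0.2)
            if p == "ter":
                V[p] = np.maximum(V[p], nuis[2] / 2.0 + 1e-3)
        mu = {p: V[p].mean(axis=0) for p in PARAMS}
        sd = {p: np.maximum(V[p].std(axis=0, ddof=1) if self.S > 1
                            else np.full(V[p].shape[1], 0.1), 0.05)
              for p in PARAMS}
        for p, tau in fix_group_sd.items():
            sd[p] = np.full(V[p].shape[1], float(tau))
        ptr = {p: V[p][self.subj, self.cell_ix[p]] for p in PARAMS}
        ll = self.loglik(self.all_idx, ptr["v"], ptr["a"], ptr["ter"], *nuis)
        return _State(V, mu, sd, nuis, ptr, ll)

    # -- one chain --------------------------------------------------------
    def run_chain(self, rng, mcmc: MCMCConfig, update_params,
                  sample_nuisance: bool, fix_group_sd: dict):
        for attempt in range(10):
            state = self.initial_state(rng, fix_group_sd)
            if np.isfinite(state.ll.sum()):
                break
        else:
            raise RuntimeError(
                "could not find a finite-likelihood initialisation in 10 "
                f"attempts (last total loglik {state.ll.sum()!r})"
            )

        scales = {}
        acc = {}
        for p in update_params:
            base = {"v": 0.15, "a": 0.12, "ter": 0.02}[p]
            for ci in range(len(self.cells[p])):
                scales[("subj", p, ci)] = np.full(self.S, base)
                acc[("subj", p, ci)] = np.zeros(self.S)
                scales[("mu", p, ci)] = base
                acc[("mu", p, ci)] = 0.0
                scales[("sd", p, ci)] = 0.25
                acc[("sd", p, ci)] = 0.0
        scales[("nuis",)] = 1.0
        acc[("nuis",)] = 0.0
        # nuisance block: diagonal pilot scales, then adaptive covariance
        # (Haario-style) estimated from the burn-in history
        nuis_rel = np.array([0.02, 0.10, 0.015, 0.04])
        nuis_chol = np.diag(nuis_rel)
        nuis_mean = np.zeros(4)
        nuis_cov = np.zeros((4, 4))
        nuis_count = 0

        n_rec = mcmc.n_retained
        draws = np.empty((n_rec, len(self.node_names)))
        deviance = np.empty(n_rec)
        rec = 0
        batch = 0
        window = 0

        for it in range(mcmc.iterations):
            # ---- subject-level nodes, single-site across subjects -------
            for p in update_params:
                for ci in range(len(self.cells[p])):
                    idx, subj_of, starts = self.upd[(p, ci)]
                    cur = state.V[p][:, ci]
                    step = scales[("subj", p, ci)] * rng.standard_normal(self.S)
                    prop = cur + step
                    if p == "a":
                        valid = prop > 1e-3
                    elif p == "ter":
                        valid = prop - state.nuis[2] / 2.0 >= 0.0
                    else:
                        valid = np.ones(self.S, dtype=bool)
                    prop_eval = np.where(valid, prop, cur)
                    tr = {q: state.ptr[q][idx] for q in PARAMS if q != p}
                    tr[p] = prop_eval[subj_of]
                    ll_prop = self.loglik(idx, tr["v"], tr["a"], tr["ter"],
                                          *state.nuis)
                    dll = np.add.reduceat(ll_prop - state.ll[idx], starts)
                    dpr = (_norm_logpdf(prop_eval, state.mu[p][ci], state.sd[p][ci])
                           - _norm_logpdf(cur, state.mu[p][ci], state.sd[p][ci]))
                    accept = valid & (np.log(rng.random(self.S)) < dll + dpr)
                    if accept.any():
                        state.V[p][accept, ci] = prop[accept]
                        tmask = accept[subj_of]
                        sel = idx[tmask]
                        state.ll[sel] = ll_prop[tmask]
                        state.ptr[p][sel] = tr[p][tmask]
                    acc[("subj", p, ci)] += accept

                    # ---- group mean / SD for this cell ------------------
                    th = state.V[p][:, ci]
                    m, s0 = state.mu[p][ci], state.sd[p][ci]
                    mp = m + scales[("mu", p, ci)] * rng.standard_normal()
                    dl = (self.priors.mu[p].logpdf(mp) - self.priors.mu[p].logpdf(m)
                          + np.sum(_norm_logpdf(th, mp, s0) - _norm_logpdf(th, m, s0)))
                    if np.log(rng.random()) < dl:
                        state.mu[p][ci] = mp
                        acc[("mu", p, ci)] += 1.0
                    if p not in fix_group_sd:
                        m = state.mu[p][ci]
                        sp_ = s0 * math.exp(scales[("sd", p, ci)]
                                            * rng.standard_normal())
                        dl = (self.priors.sd[p].logpdf(sp_) - self.priors.sd[p].logpdf(s0)
                              + np.sum(_norm_logpdf(th, m, sp_) - _norm_logpdf(th, m, s0))
                              + math.log(sp_ / s0))
                        if np.log(rng.random()) < dl:
                            state.sd[p][ci] = sp_
                            acc[("sd", p, ci)] += 1.0

            # ---- joint nuisance block -----------------------------------
            if sample_nuisance:
                x = state.nuis
                prop = x + scales[("nuis",)] * (nuis_chol @ rng.standard_normal(4))
                z, sv, st, sz = prop
                ok = (0.0 < z < 1.0 and sv >= 0.0 and st >= 0.0 and sz >= 0.0
                      and z - sz / 2.0 > 0.0 and z + sz / 2.0 < 1.0
                      and float(state.V["ter"].min()) - st / 2.0 >= 0.0)
                if ok:
                    dpr = (self.priors.z.logpdf(z) - self.priors.z.logpdf(x[0])
                           + self.priors.sv.logpdf(sv) - self.priors.sv.logpdf(x[1])
                           + self.priors.st.logpdf(st) - self.priors.st.logpdf(x[2])
                           + self.priors.sz_logpdf(sz, z)
                           - self.priors.sz_logpdf(x[3], x[0]))
                    ll_prop = self.loglik(self.all_idx, state.ptr["v"],
                                          state.ptr["a"], state.ptr["ter"],
                                          z, sv, st, sz)
                    dl = float(ll_prop.sum() - state.ll.sum()) + dpr
                    if np.isfinite(dl) and np.log(rng.random()) < dl:
                        state.nuis = prop
                        state.ll = ll_prop
                        acc[("nuis",)] += 1.0
                if it < mcmc.burn_in:
                    # running mean/covariance of the block (Welford)
                    nuis_count += 1
                    d_ = state.nuis - nuis_mean
                    nuis_mean += d_ / nuis_count
                    nuis_cov += np.outer(d_, state.nuis - nuis_mean)
                    if nuis_count > 200 and nuis_count % mcmc.adapt_window == 0:
                        cov = nuis_cov / (nuis_count - 1)
                        cov = (2.38**2 / 4.0) * cov + 1e-8 * np.eye(4)
                        try:
                            nuis_chol = np.linalg.cholesky(cov)
                        except np.linalg.LinAlgError:
                            pass

            # ---- adaptation (burn-in only) ------------------------------
            window += 1
            if it < mcmc.burn_in and window == mcmc.adapt_window:
                batch += 1
                gamma = min(0.5, 1.0 / math.sqrt(batch))
                for key, a_ in acc.items():
                    rate = a_ / mcmc.adapt_window
                    target = 0.25 if key == ("nuis",) else 0.44
                    if key[0] == "subj":
                        scales[key] = scales[key] * np.exp(gamma * (rate - target))
                    else:
                        scales[key] = scales[key] * math.exp(gamma * (rate - target))
                    acc[key] = np.zeros(self.S) if key[0] == "subj" else 0.0
                window = 0
            elif it == mcmc.burn_in - 1:
                for key in acc:
                    acc[key] = np.zeros(self.S) if key[0] == "subj" else 0.0

            # ---- record -------------------------------------------------
            if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thinning == 0:
                vec = [state.mu[p] for p in PARAMS] + \
                      [state.sd[p] for p in PARAMS] + [state.nuis] + \
                      [state.V[p][:, ci] for p in PARAMS
                       for ci in range(len(self.cells[p]))]
                draws[rec] = np.concatenate(vec)
                deviance[rec] = -2.0 * float(state.ll.sum())
                rec += 1

        post = mcmc.iterations - mcmc.burn_in
        rates = {}
        for key, a_ in acc.items():
            r = a_ / post
            rates["/".join(str(k) for k in key)] = (
                float(np.mean(r)) if isinstance(r, np.ndarray) else float(r)
            )
        return draws[:rec], deviance[:rec], rates


def fit(trials: pd.DataFrame, spec: ModelSpec,
        priors: PriorSet | None = None,
        mcmc: MCMCConfig = MCMCConfig(),
        likelihood_config: LikelihoodConfig = DEFAULT_CONFIG,
        p_outlier: float = 0.05,
        likelihood_kind: str = "wfpt",
        update_params: tuple = PARAMS,
        sample_nuisance: bool = True,
        fix_group_sd: dict | None = None) -> PosteriorFit:
    """Sample the joint posterior of a model's parameters from clean trials.

    Trials must be preprocessed (no practice trials, no missing response
    times) and every subject must have trials in every design cell.  The
    contaminant fraction ``p_outlier`` is fixed, not estimated.

    ``likelihood_kind="gaussian"`` replaces the trial likelihood with a
    unit-variance normal centered on the drift node (conjugate testing
    harness); combine with ``update_params=("v",)``,
    ``sample_nuisance=False`` and ``fix_group_sd={"v": tau}`` to obtain a
    model with a closed-form posterior.
    """
    if priors is None:
        priors = default_priors(spec)
    if likelihood_kind not in ("wfpt", "gaussian"):
        raise ValueError(f"unknown likelihood_kind {likelihood_kind!r}")
    if trials["rt_seconds"].isna().any():
        raise ValueError("trials contain missing response times; preprocess first")
    counts = trials.groupby(["subject", "set_size", "spring"], observed=True).size()
    n_subj = trials["subject"].nunique()
    if likelihood_kind == "wfpt" and len(counts) < 4 * n_subj:
        raise ValueError(
            "every subject needs trials in every design cell; "
            f"found {len(counts)} nonempty (subject, cell) combinations "
            f"for {n_subj} subjects"
        )

    sampler = _Sampler(trials, spec, priors, likelihood_config, p_outlier,
                       likelihood_kind)
    fix_group_sd = fix_group_sd or {}

    chains_draws, chains_dev, rates_all = [], [], {}
    for c, ss in enumerate(np.random.SeedSequence(mcmc.seed).spawn(mcmc.chains)):
        rng = np.random.default_rng(ss)
        d, dev, rates = sampler.run_chain(
            rng, mcmc, update_params, sample_nuisance, fix_group_sd
        )
        chains_draws.append(d)
        chains_dev.append(dev)
        rates_all[f"chain{c}"] = rates

    node_names = sampler.node_names
    fitted = PosteriorFit(
        draws=np.stack(chains_draws),
        node_names=node_names,
        deviance=np.stack(chains_dev),
        spec=spec,
        mcmc=mcmc,
        likelihood_config=likelihood_config,
        p_outlier=p_outlier,
        subjects=sampler.subjects,
        data_fingerprint=_fingerprint(trials),
        likelihood_kind=likelihood_kind,
        acceptance=rates_all,
    )
    # fixed group SDs are recorded at their fixed values
    for p, tau in fix_group_sd.items():
        for ci, cell in enumerate(condition_cells(spec.factors_of(p))):
            fitted.draws[:, :, fitted.node_index(f"sigma[{node_label(p, cell)}]")] = tau
    return fitted


def diagnostics(fit: PosteriorFit, nodes=None) -> pd.DataFrame:
    """Split-R-hat and effective sample size per node.

    R-hat needs at least 2 chains and is reported as NaN otherwise.  Use
    :meth:`PosteriorFit.node_draws` for trace extracts.
    """
    import arviz as az

    names = list(nodes) if nodes is not None else list(fit.node_names)
    out = pd.DataFrame(index=names, columns=["rhat", "ess"], dtype=float)
    for name in names:
        x = fit.node_draws(name)
        if np.allclose(x.std(), 0.0):
            out.loc[name] = (1.0, np.nan)
            continue
        out.loc[name, "ess"] = float(az.ess(x))
        if fit.draws.shape[0] >= 2:
            out.loc[name, "rhat"] = float(az.rhat(x))
    return out


def summarize(fit: PosteriorFit) -> pd.DataFrame:
    """Posterior mean and [2.5, 97.5] percentile interval per node.

    Group-level condition nodes carry parsed (parameter, set_size, spring)
    keys so the group-mean rows mirror the parameter-by-condition layout of
    the study's estimate tables.
    """
    if fit.n_draws < 2:
        raise ValueError("need at least 2 retained draws to summarize")
    flat = fit.flat
    mean = flat.mean(axis=0)
    lo, hi = np.percentile(flat, [2.5, 97.5], axis=0)
    rows = []
    for i, name in enumerate(fit.node_names):
        param = set_size = spring = None
        base = name
        if "[" not in name or name.startswith("sigma["):
            stripped = name.removeprefix("sigma[").removesuffix("]") \
                if name.startswith("sigma[") else name
            p = stripped.split("(")[0]
            if p in PARAMS:
                param = p
                if "(" in stripped:
                    for tok in stripped[stripped.index("(") + 1:-1].split(":"):
                        if tok.startswith("ss"):
                            set_size = int(tok[2:])
                        else:
                            spring = tok
            elif stripped in NUIS:
                param = stripped
        rows.append((name, param, set_size, spring, mean[i], lo[i], hi[i]))
    return pd.DataFrame(
        rows, columns=["node", "parameter", "set_size", "spring",
                       "mean", "lo2.5", "hi97.5"]
    )


def posterior_predictive(fit: PosteriorFit, trials: pd.DataFrame, n_rep: int,
                         rng: np.random.Generator, dt: float = 1e-3,
                         response_window: float = 5.0,
                         quantiles=(0.1, 0.3, 0.5, 0.7, 0.9)) -> pd.DataFrame:
    """Observed vs replicated RT quantiles per subject and condition.

    For each of ``n_rep`` randomly chosen posterior draws a replicate dataset
    of matching design (same trial counts per subject and condition) is
    simulated from that draw's subject-level parameters; correct- and
    error-response RT quantiles are summarised into a 2.5-97.5% simulation
    envelope.  Cells without error (or correct) trials report NaN quantiles
    rather than zeros.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    df = add_correct(trials)
    qs = np.asarray(quantiles)
    nflat = fit.n_draws
    pick = rng.choice(nflat, size=min(n_rep, nflat), replace=nflat < n_rep)
    flat = fit.flat

    cells = [(int(ss), sp) for ss in (3, 5) for sp in ("soft", "stiff")]
    node_ix = {}
    for s in fit.subjects:
        for ss, sp in cells:
            cond = Condition(ss, sp)
            node_ix[(s, ss, sp)] = tuple(
                fit.node_index(
                    f"{node_label(p, cell_label(fit.spec.factors_of(p), cond))}[{s}]"
                ) for p in PARAMS
            )
    nuis_ix = tuple(fit.node_index(k) for k in NUIS)

    groups = {
        key: grp for key, grp in df.groupby(["subject", "set_size", "spring"],
                                            observed=True)
    }
    rows = []
    for (s, ss, sp), grp in groups.items():
        n_tr = len(grp)
        obs_c = grp.loc[grp["correct"], "rt_seconds"].to_numpy()
        obs_e = grp.loc[~grp["correct"], "rt_seconds"].to_numpy()
        rep_q = {True: np.full((len(pick), len(qs)), np.nan),
                 False: np.full((len(pick), len(qs)), np.nan)}
        iv, ia, it = node_ix[(s, ss, sp)]
        for r, d_ix in enumerate(pick):
            draw = flat[d_ix]
            z, sv, st, sz = (draw[j] for j in nuis_ix)
            v = rng.normal(draw[iv], sv, n_tr) if sv > 0 else np.full(n_tr, draw[iv])
            z0 = rng.uniform(z - sz / 2, z + sz / 2, n_tr) if sz > 0 \
                else np.full(n_tr, z)
            ter = rng.uniform(draw[it] - st / 2, draw[it] + st / 2, n_tr) \
                if st > 0 else np.full(n_tr, draw[it])
            seed = int(rng.integers(2**31 - 1))
            rt, bnd = _kernels.simulate_batch(
                seed, v, np.full(n_tr, draw[ia]), z0, ter, response_window, dt
            )
            for correct in (True, False):
                r_sel = rt[bnd == (1 if correct else 0)]
                if r_sel.size:
                    rep_q[correct][r] = np.quantile(r_sel, qs)
        for correct, obs in ((True, obs_c), (False, obs_e)):
            obs_q = np.quantile(obs, qs) if obs.size else np.full(len(qs), np.nan)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN reps
                lo = np.nanpercentile(rep_q[correct], 2.5, axis=0)
                hi = np.nanpercentile(rep_q[correct], 97.5, axis=0)
            for k, q in enumerate(qs):
                rows.append((s, ss, sp, "correct" if correct else "error",
                             float(q), obs_q[k], lo[k], hi[k]))
    return pd.DataFrame(
        rows, columns=["subject", "set_size", "spring", "kind", "quantile",
                       "observed", "lo2.5", "hi97.5"]
    )
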