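"""Deviance-based model scoring (DIC / BPIC) and credible-interval checks.

BPIC is mean posterior deviance plus a doubled effective-parameter penalty:
Dbar + 2 pD, with pD = Dbar - D(posterior means), the classic plug-in
effective parameter count.  The plug-in deviance evaluates subject-level
nodes at their posterior means by default (hierarchical-DIC practice of
focusing on the subject-level likelihood); a group-level plug-in is
available as a switch.  Lower scores are better.

The credible-interval overlap report implements the independence check used
to adjudicate whether a motor manipulation moved the drift rate: two
posteriors "mutually contain" each other when each one's 95% interval
contains the other's mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ALL_CONDITIONS, Condition, cell_label, node_label
from .inference import NUIS, PARAMS, PosteriorFit
from .likelihood import dataset_loglik
from .core import DDMParameters

__all__ = [
    "ComparisonRow",
    "deviance_components",
    "bpic",
    "rank_models",
    "ci_overlap",
]


@dataclass(frozen=True)
class ComparisonRow:
    """One model's fit indices."""

    model_id: int
    dbar: float
    pd_eff: float
    dic: float
    bpic: float
    delta_bpic: float = 0.0


def _plugin_params(fit: PosteriorFit, level: str) -> dict:
    """Per (subject, condition) DDMParameters at posterior means."""
    means = fit.means()
    z, sv, st, sz = (float(means[k]) for k in NUIS)
    out = {}
    for s in fit.subjects:
        for cond in ALL_CONDITIONS:
            vals = {}
            for p in PARAMS:
                base = node_label(p, cell_label(fit.spec.factors_of(p), cond))
                key = base if level == "group" else f"{base}[{s}]"
                vals[p] = float(means[key])
            ter = max(vals["ter"], st / 2.0)
            out[(s, cond)] = DDMParameters(
                v=vals["v"], a=vals["a"], ter=ter, z=z, sv=sv, st=st, sz=sz
            )
    return out


def deviance_components(fit: PosteriorFit, trials: pd.DataFrame,
                        plugin_level: str = "subject"
                        ) -> tuple[float, float, float]:
    """(Dbar, D at posterior means, pD) for a fitted model.

    Dbar is the mean of the per-draw deviances recorded during sampling;
    the plug-in deviance re-evaluates the likelihood at the posterior means
    of all nodes (subject-level nodes at their own means when
    ``plugin_level="subject"``, at the group means when ``"group"``).
    """
    from .inference import _fingerprint

    if plugin_level not in ("subject", "group"):
        raise ValueError("plugin_level must be 'subject' or 'group'")
    if _fingerprint(trials) != fit.data_fingerprint:
        raise ValueError(
            "trial table does not match the data this model was fitted to "
            "(fingerprint mismatch)"
        )
    dbar = float(fit.deviance.mean())
    params = _plugin_params(fit, plugin_level)
    total = 0.0
    for s, grp in trials.groupby("subject", observed=True):
        per_cond = {cond: params[(str(s), cond)] for cond in ALL_CONDITIONS}
        total += dataset_loglik(grp, per_cond, fit.p_outlier,
                                fit.likelihood_config)
    d_at_mean = -2.0 * total
    return dbar, d_at_mean, dbar - d_at_mean


def bpic(fit: PosteriorFit, trials: pd.DataFrame,
         plugin_level: str = "subject") -> ComparisonRow:
    """DIC = Dbar + pD and BPIC = Dbar + 2 pD for one fitted model."""
    dbar, _, pd_eff = deviance_components(fit, trials, plugin_level)
    return ComparisonRow(
        model_id=fit.spec.model_id,
        dbar=dbar,
        pd_eff=pd_eff,
        dic=dbar + pd_eff,
        bpic=dbar + 2.0 * pd_eff,
    )


def rank_models(fits: dict, trials: pd.DataFrame,
                plugin_level: str = "subject") -> pd.DataFrame:
    """BPIC-sorted comparison table over fitted models (lower is better).

    All fits must have been estimated on the same trial table; the best
    model has delta_bpic = 0.
    """
    prints = {f.data_fingerprint for f in fits.values()}
    if len(prints) > 1:
        raise ValueError("fits were estimated on different data (fingerprints differ)")
    rows = [bpic(f, trials, plugin_level) for f in fits.values()]
    best = min(r.bpic for r in rows)
    tab = pd.DataFrame(
        [{
            "model_id": r.model_id,
            "v_factors": "+".join(sorted(fits[r.model_id].spec.v_factors)),
            "a_factors": "+".join(sorted(fits[r.model_id].spec.a_factors)),
            "ter_factors": "+".join(sorted(fits[r.model_id].spec.ter_factors)),
            "dbar": r.dbar,
            "pd": r.pd_eff,
            "dic": r.dic,
            "bpic": r.bpic,
            "delta_bpic": r.bpic - best,
        } for r in rows]
    )
    return tab.sort_values("bpic", kind="mergesort").reset_index(drop=True)


def ci_overlap(fit: PosteriorFit, node_pairs) -> pd.DataFrame:
    """Mutual mean-in-interval containment for pairs of posterior nodes.

    For each (A, B) pair: does A's 95% interval contain B's posterior mean,
    and vice versa?  ``mutual`` is True when both containments hold — the
    criterion used to conclude that two condition posteriors are
    indistinguishable.
    """
    rows = []
    for a, b in node_pairs:
        xa = fit.node_draws(a).reshape(-1)
        xb = fit.node_draws(b).reshape(-1)
        lo_a, hi_a = np.percentile(xa, [2.5, 97.5])
        lo_b, hi_b = np.percentile(xb, [2.5, 97.5])
        ma, mb = float(xa.mean()), float(xb.mean())
        a_contains_b = bool(lo_a <= mb <= hi_a)
        b_contains_a = bool(lo_b <= ma <= hi_b)
        rows.append({
            "node_a": a, "node_b": b,
            "mean_a": ma, "lo_a": lo_a, "hi_a": hi_a,
            "mean_b": mb, "lo_b": lo_b, "hi_b": hi_b,
            "a_contains_b": a_contains_b, "b_contains_a": b_contains_a,
            "mutual": a_contains_b and b_contains_a,
        })
    return pd.DataFrame(rows)


def drift_spring_pairs(fit: PosteriorFit) -> list[tuple[str, str]]:
    """Soft-vs-stiff drift node pairs at each set size, if the model has them.

    Returns an empty list when the fitted model's drift rate does not vary
    by spring pressure (the overlap check is then not applicable).
    """
    if "SPC" not in fit.spec.v_factors:
        return []
    pairs = []
    for ss in (3, 5):
        fac = fit.spec.v_factors
        a = node_label("v", cell_label(fac, Condition(ss, "soft")))
        b = node_label("v", cell_label(fac, Condition(ss, "stiff")))
        if a != b:
            pairs.append((a, b))
    return pairs
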