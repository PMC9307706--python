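"""Behavioral summaries, Bayes-factor model comparison, and correlations.

Condition-cell accuracy/RT summaries per subject; Bayes factors for the four
ANOVA-style models over the 2x2 within-subject design (spring pressure, set
size, both, both + interaction) relative to a subject-only null; and Pearson
correlations between subject-level diffusion parameter estimates and
pencil-and-paper assessments of processing speed (SDMT) and upper-extremity
motor function (NHPT).

The Bayes factors use the BIC approximation BF = exp((BIC_null - BIC_m) / 2)
over repeated-measures linear models on subject-cell means.  This is a
documented, testable stand-in for default-Cauchy-prior ANOVA Bayes factors,
approximating their behaviour (monotone in evidence, scale-invariant in the
dependent variable), not replicating any particular package's values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .core import add_correct

__all__ = [
    "CellSummary",
    "AssessmentScores",
    "cell_summary",
    "bf_model_comparison",
    "pearson_r",
    "correlation_matrix",
    "SHRINKAGE_CAVEAT",
]

SHRINKAGE_CAVEAT = (
    "Parameter estimates are derived from a hierarchical structure which may "
    "in some cases inaccurately estimate correlation strength. These values "
    "should be interpreted with a degree of caution."
)

#: Bayes-factor model labels, in presentation order.
BF_MODELS = ("spring", "set_size", "spring+set_size",
             "spring+set_size+interaction")


@dataclass(frozen=True)
class CellSummary:
    subject: str
    set_size: int
    spring: str
    accuracy: float
    mean_rt: float
    n_trials: int


@dataclass(frozen=True)
class AssessmentScores:
    """Per-subject clinical assessment scores (missing values permitted)."""

    subject: str
    sdmt_oral: float | None = None
    sdmt_written: float | None = None
    nhpt_seconds: float | None = None


def cell_summary(trials: pd.DataFrame, correct_only_rt: bool = False
                 ) -> pd.DataFrame:
    """Per subject x condition accuracy and mean RT over retained trials.

    RT means include both correct and error responses by default.  Empty
    cells yield NaN rows rather than being dropped.
    """
    df = add_correct(trials)
    rows = []
    grouped = df.groupby(["subject", "set_size", "spring"], observed=True)
    for (s, ss, sp), grp in grouped:
        rt = grp.loc[grp["correct"], "rt_seconds"] if correct_only_rt \
            else grp["rt_seconds"]
        rows.append({
            "subject": s, "set_size": int(ss), "spring": sp,
            "accuracy": float(grp["correct"].mean()),
            "mean_rt": float(rt.mean()) if len(rt) else np.nan,
            "n_trials": len(grp),
        })
    return pd.DataFrame(rows)


def _bic_ols(y: np.ndarray, X: np.ndarray) -> float:
    """BIC of an ordinary least-squares fit (Gaussian likelihood)."""
    n, k = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    return n * np.log(rss / n) + (k + 1) * np.log(n)


def bf_model_comparison(cells: pd.DataFrame, dv: str = "accuracy"
                        ) -> pd.DataFrame:
    """Bayes factors vs the subject-only null for the four effect models.

    ``cells`` is the output of :func:`cell_summary` (one row per subject and
    condition; all four cells required per subject).  Bayes factors use the
    BIC approximation over repeated-measures linear models with subject
    intercepts.  Inclusion Bayes factors for each effect compare the best
    model containing the effect against its counterpart without it,
    mirroring top-down effect adjudication.
    """
    if dv not in ("accuracy", "mean_rt"):
        raise ValueError("dv must be 'accuracy' or 'mean_rt'")
    counts = cells.groupby("subject", observed=True).size()
    bad = counts[counts != 4]
    if len(bad):
        raise ValueError(
            f"subjects without a complete 2x2 cell set: {sorted(bad.index)}"
        )
    df = cells.sort_values(["subject", "set_size", "spring"]).reset_index(drop=True)
    y = df[dv].to_numpy(dtype=float)
    subj = pd.get_dummies(df["subject"]).to_numpy(dtype=float)
    spring = (df["spring"] == "stiff").to_numpy(dtype=float)[:, None]
    ss = (df["set_size"] == 5).to_numpy(dtype=float)[:, None]
    inter = spring * ss
    designs = {
        "null": subj,
        "spring": np.hstack([subj, spring]),
        "set_size": np.hstack([subj, ss]),
        "spring+set_size": np.hstack([subj, spring, ss]),
        "spring+set_size+interaction": np.hstack([subj, spring, ss, inter]),
    }
    bic = {m: _bic_ols(y, X) for m, X in designs.items()}
    bf = {m: float(np.exp((bic["null"] - bic[m]) / 2.0)) for m in designs}

    # effect sets per model label; the interaction presupposes both mains
    effect_sets = {
        "null": frozenset(),
        "spring": frozenset({"spring"}),
        "set_size": frozenset({"set_size"}),
        "spring+set_size": frozenset({"spring", "set_size"}),
        "spring+set_size+interaction": frozenset(
            {"spring", "set_size", "interaction"}),
    }
    label_of = {v: k for k, v in effect_sets.items()}
    best = max(effect_sets, key=lambda m: bf[m])

    def toggled(model: str, effect: str) -> str:
        s = set(effect_sets[model])
        if effect in s:
            s.discard(effect)
            if effect in ("spring", "set_size"):
                s.discard("interaction")
        else:
            s.add(effect)
            if effect == "interaction":
                s |= {"spring", "set_size"}
        return label_of[frozenset(s)]

    # top-down inclusion: compare the best model with/without each effect
    inclusion = {}
    for effect in ("spring", "set_size", "interaction"):
        other = toggled(best, effect)
        with_e, without_e = (best, other) if effect in effect_sets[best] \
            else (other, best)
        inclusion[effect] = bf[with_e] / bf[without_e]
    out = pd.DataFrame({
        "model": list(BF_MODELS),
        "bf_vs_null": [bf[m] for m in BF_MODELS],
    })
    out.attrs["inclusion_bf"] = inclusion
    out.attrs["best_model"] = best
    out.attrs["dv"] = dv
    return out


def pearson_r(x, y) -> tuple[float, int]:
    """Pearson correlation with pairwise-complete handling.

    Returns (r, number of complete pairs used); fewer than 3 complete pairs
    is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    r = stats.pearsonr(x[ok], y[ok]).statistic
    return float(r), n


def correlation_matrix(subject_params: pd.DataFrame,
                       assessments: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Pearson matrix over assessments and parameter estimates.

    ``subject_params``: subject-indexed posterior means, one column per
    parameter node (e.g. from :meth:`PosteriorFit.subject_means`).
    ``assessments``: columns subject, sdmt_oral, sdmt_written, nhpt_seconds.
    Missing values are dropped pairwise.  The result carries a caveat about
    hierarchical shrinkage in ``.attrs["caveat"]``.
    """
    scores = assessments.set_index("subject")[
        ["sdmt_oral", "sdmt_written", "nhpt_seconds"]
    ]
    joined = scores.join(subject_params, how="outer")
    mat = joined.corr(method="pearson", min_periods=3)
    mat.attrs["caveat"] = SHRINKAGE_CAVEAT
    mat.attrs["n_subjects"] = len(joined)
    return mat
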