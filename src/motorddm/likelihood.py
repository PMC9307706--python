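"""Wiener first-passage-time likelihood with outlier-mixture contamination.

Public numerical API over the compiled kernels: boundary absorption
probabilities, the first-passage density with and without across-trial
parameter variability, and per-trial / per-dataset log likelihoods under the
uniform-contaminant mixture used for response-time outliers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from . import _kernels
from .core import (
    Condition,
    DDMParameters,
    SpecificationError,
    TrialRecord,
    add_correct,
)

__all__ = [
    "LikelihoodConfig",
    "choice_probability",
    "wfpt_density",
    "full_density",
    "trial_loglik",
    "dataset_loglik",
]


@dataclass(frozen=True)
class LikelihoodConfig:
    """Numerical configuration of the likelihood.

    series_tolerance : absolute truncation error bound of the density series
    quadrature_points : Gauss-Legendre nodes per active variability dimension
        (st and sz; drift variability is integrated in closed form)
    rt_ceiling : support (s) of the uniform outlier distribution; the
        contaminant density is 1 / (2 * rt_ceiling), split over both responses
    """

    series_tolerance: float = 1e-7
    quadrature_points: int = 11
    rt_ceiling: float = 5.0

    def __post_init__(self) -> None:
        if not self.series_tolerance > 0:
            raise ValueError("series_tolerance must be positive")
        if self.quadrature_points < 1:
            raise ValueError("quadrature_points must be >= 1")
        if not self.rt_ceiling > 0:
            raise ValueError("rt_ceiling must be positive")

    @property
    def outlier_density(self) -> float:
        return 1.0 / (2.0 * self.rt_ceiling)


DEFAULT_CONFIG = LikelihoodConfig()


def _leggauss(n: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.legendre.leggauss(n)
    return np.ascontiguousarray(x), np.ascontiguousarray(w)


def choice_probability(v: float, a: float, z: float) -> float:
    """Probability of absorption at the upper boundary (no variabilities).

    Standard two-barrier result for drifted Brownian motion with unit
    diffusion coefficient started at z*a between absorbing barriers 0 and a:
    P(upper) = (1 - exp(-2 v a z)) / (1 - exp(-2 v a)); the drift-free limit
    is z.
    """
    if not a > 0:
        raise ValueError(f"boundary separation must be positive, got {a}")
    if not (0.0 < z < 1.0):
        raise ValueError(f"relative start must lie in (0, 1), got {z}")
    va = v * a
    if abs(va) < 1e-9:
        return z
    # guard the large-|v| regime against overflow
    if va > 350.0:
        return 1.0
    if va < -350.0:
        return 0.0
    return float(math.expm1(-2.0 * va * z) / math.expm1(-2.0 * va))


def wfpt_density(t, boundary: str, v: float, a: float, z: float,
                 tol: float = 1e-7):
    """First-passage density (1/s) at decision time ``t`` for one boundary.

    ``t`` is decision time (non-decision time already subtracted) and may be
    a scalar or array; nonpositive times have zero density.  The lower
    boundary density under (v, a, z) equals the upper density under
    (-v, a, 1-z).
    """
    if boundary not in ("upper", "lower"):
        raise ValueError(f"boundary must be 'upper' or 'lower', got {boundary!r}")
    if not tol > 0:
        raise ValueError("tol must be positive")
    if boundary == "upper":
        v, z = -v, 1.0 - z
    tt = np.asarray(t, dtype=float)
    scalar = tt.ndim == 0
    tt = np.atleast_1d(tt)
    out = np.empty_like(tt)
    for i, ti in enumerate(tt):
        out[i] = _kernels.fptd_lower_sv(ti, v, a, z, 0.0, tol)
    return float(out[0]) if scalar else out


def full_density(rt, boundary: str, params: DDMParameters,
                 config: LikelihoodConfig = DEFAULT_CONFIG):
    """Density of (rt, boundary) integrated over across-trial variability.

    Drift variability sv is integrated analytically; st and sz by
    Gauss-Legendre quadrature with ``config.quadrature_points`` nodes per
    active dimension (zero-range dimensions are skipped exactly).  ``rt`` is
    the full response time; the non-decision time in ``params`` is subtracted
    internally.
    """
    if boundary not in ("upper", "lower"):
        raise ValueError(f"boundary must be 'upper' or 'lower', got {boundary!r}")
    xq, wq = _leggauss(config.quadrature_points)
    rr = np.asarray(rt, dtype=float)
    scalar = rr.ndim == 0
    rr = np.atleast_1d(rr).astype(float)
    n = rr.shape[0]
    up = np.full(n, boundary == "upper")
    out = np.empty(n)
    _kernels.full_density_batch(
        rr, up,
        np.full(n, params.v), np.full(n, params.a), np.full(n, params.ter),
        params.z, params.sv, params.st, params.sz,
        xq, wq, config.series_tolerance, out,
    )
    return float(out[0]) if scalar else out


def trial_loglik(trial: TrialRecord, params: DDMParameters, p_outlier: float,
                 config: LikelihoodConfig = DEFAULT_CONFIG) -> float:
    """Log density of one trial under the uniform-contaminant mixture.

    log[(1 - p_outlier) * f(rt, boundary) + p_outlier * u] with
    u = 1 / (2 * rt_ceiling).  Accuracy coding: a correct response is the
    upper boundary.  Trials without a response must be excluded upstream.
    """
    if not (0.0 <= p_outlier <= 1.0):
        raise ValueError(f"p_outlier must lie in [0, 1], got {p_outlier}")
    if trial.rt is None:
        raise ValueError(
            "trial has no response time; no-response trials must be removed "
            "before likelihood evaluation"
        )
    boundary = "upper" if trial.correct else "lower"
    f = full_density(trial.rt, boundary, params, config)
    mix = (1.0 - p_outlier) * f + p_outlier * config.outlier_density
    if mix <= 0.0:
        return -np.inf
    return float(np.log(mix))


def dataset_loglik(trials: pd.DataFrame,
                   params: Mapping[Condition, DDMParameters],
                   p_outlier: float,
                   config: LikelihoodConfig = DEFAULT_CONFIG) -> float:
    """Summed log likelihood of a trial table under per-condition parameters.

    Every trial's (set_size, spring) must resolve to an entry of ``params``;
    an empty table contributes 0.  Missing response times raise.
    """
    if not (0.0 <= p_outlier <= 1.0):
        raise ValueError(f"p_outlier must lie in [0, 1], got {p_outlier}")
    if len(trials) == 0:
        return 0.0
    if trials["rt_seconds"].isna().any():
        raise ValueError("trial table contains missing response times")
    df = add_correct(trials) if "correct" not in trials.columns else trials
    xq, wq = _leggauss(config.quadrature_points)
    total = 0.0
    for (ss, spring), grp in df.groupby(["set_size", "spring"], observed=True):
        cond = Condition(int(ss), str(spring))
        if cond not in params:
            raise SpecificationError(
                f"no parameters supplied for condition {cond}"
            )
        p = params[cond]
        n = len(grp)
        out = np.empty(n)
        _kernels.mixture_loglik_batch(
            grp["rt_seconds"].to_numpy(dtype=float),
            grp["correct"].to_numpy(dtype=bool),
            np.full(n, p.v), np.full(n, p.a), np.full(n, p.ter),
            p.z, p.sv, p.st, p.sz,
            p_outlier, config.outlier_density,
            xq, wq, config.series_tolerance, out,
        )
        total += float(out.sum())
    return total
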