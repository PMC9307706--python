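"""Synthetic data: the 2x2 experimental design and a forward diffusion model.

Generates trial-level choice/RT datasets with the statistical structure the
hierarchical analysis assumes: subjects drawn from group-level distributions,
trials simulated from a full diffusion process (with across-trial variability
in drift, starting point and non-decision time), and a small uniform
contaminant fraction.  Every run returns a ground-truth ledger (subject
parameters, contaminant flags) that the inference stage never sees.

Design emulated: ~50 subjects, 2 counterbalanced blocks (one per spring
condition), 24 practice + 300 experimental trials per block, 150 experimental
trials per design cell, half match / half no-match, 5 s response window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from . import _kernels
from .core import (
    ALL_CONDITIONS,
    Condition,
    DDMParameters,
    GroupParameters,
    ModelSpec,
    TRIAL_COLUMNS,
    build_model_space,
    resolve_node,
)

__all__ = [
    "DesignConfig",
    "reference_group_parameters",
    "simulate_trial",
    "generate_design",
    "draw_subject_params",
    "generate_dataset",
]


@dataclass(frozen=True)
class DesignConfig:
    """Trial-structure constants of the spring-pressure x set-size task."""

    n_blocks: int = 2
    practice_per_block: int = 24
    experimental_per_condition: int = 150
    response_window: float = 5.0
    iti_range: tuple[float, float] = (0.5, 3.0)
    feedback_duration: float = 0.5
    counterbalance: bool = True
    dt: float = 1e-4  # Euler step of the path simulator (s)

    def __post_init__(self) -> None:
        for name in ("n_blocks", "practice_per_block", "experimental_per_condition"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        if not self.iti_range[0] <= self.iti_range[1]:
            raise ValueError("iti_range must be ordered")
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    @property
    def trials_per_block(self) -> int:
        # one spring per block, both set sizes within it
        return self.practice_per_block + 2 * self.experimental_per_condition


def reference_group_parameters(
    between_sd_v: float = 0.3,
    between_sd_a: float = 0.25,
    between_sd_ter: float = 0.05,
    p_outlier: float = 0.05,
) -> tuple[ModelSpec, GroupParameters]:
    """Reference generating parameters for recovery studies.

    Group means are the fitted group-level posterior means for the speeded
    letter-comparison task under the model in which drift varies by set size
    only while boundary separation and non-decision time vary by both set
    size and spring pressure (model 4 of the candidate space).  Group-only
    bias/variability values and between-subject SDs are field-realistic
    defaults (the study reports only group-level condition posteriors).
    """
    spec = build_model_space()[3]  # model 4
    assert spec.model_id == 4
    means = {
        "v(ss3)": 2.57,
        "v(ss5)": 1.78,
        "a(ss3:soft)": 1.78,
        "a(ss3:stiff)": 2.14,
        "a(ss5:soft)": 2.01,
        "a(ss5:stiff)": 2.20,
        "ter(ss3:soft)": 0.58,
        "ter(ss3:stiff)": 0.62,
        "ter(ss5:soft)": 0.70,
        "ter(ss5:stiff)": 0.80,
    }
    sds = {}
    for label in means:
        if label.startswith("v"):
            sds[label] = between_sd_v
        elif label.startswith("a"):
            sds[label] = between_sd_a
        else:
            sds[label] = between_sd_ter
    group = GroupParameters(
        means=means, sds=sds, z=0.5, sv=0.5, st=0.15, sz=0.1,
        p_outlier=p_outlier,
    )
    return spec, group


def simulate_trial(params: DDMParameters, dt: float, rng: np.random.Generator,
                   response_window: float = 5.0):
    """Simulate one trial; returns (rt, 'upper'|'lower') or None if no response.

    The accumulator starts at z*a with drift drawn Normal(v, sv), start drawn
    Uniform(z +/- sz/2) and non-decision time Uniform(ter +/- st/2); the path
    is an Euler-Maruyama discretisation with within-step Brownian-bridge
    crossing detection.
    """
    v = rng.normal(params.v, params.sv) if params.sv > 0 else params.v
    z = rng.uniform(params.z - params.sz / 2, params.z + params.sz / 2) \
        if params.sz > 0 else params.z
    ter = rng.uniform(params.ter - params.st / 2, params.ter + params.st / 2) \
        if params.st > 0 else params.ter
    seed = int(rng.integers(2**31 - 1))
    rt, bnd = _kernels.simulate_batch(
        seed, np.array([v]), np.array([params.a]), np.array([z]),
        np.array([ter]), response_window, dt,
    )
    if bnd[0] < 0:
        return None
    return float(rt[0]), ("upper" if bnd[0] == 1 else "lower")


def simulate_trials_batch(params: DDMParameters, n: int,
                          rng: np.random.Generator, dt: float = 1e-4,
                          response_window: float = 5.0):
    """Vectorized simulation of n iid trials from one parameter set.

    Returns (rt, boundary) arrays; boundary is 1 upper / 0 lower / -1 missed.
    """
    v = rng.normal(params.v, params.sv, n) if params.sv > 0 else np.full(n, params.v)
    z = rng.uniform(params.z - params.sz / 2, params.z + params.sz / 2, n) \
        if params.sz > 0 else np.full(n, params.z)
    ter = rng.uniform(params.ter - params.st / 2, params.ter + params.st / 2, n) \
        if params.st > 0 else np.full(n, params.ter)
    seed = int(rng.integers(2**31 - 1))
    return _kernels.simulate_batch(
        seed, v, np.full(n, params.a), z, ter, response_window, dt
    )


def _balanced_match_flags(n: int, rng: np.random.Generator) -> np.ndarray:
    flags = np.zeros(n, dtype=bool)
    flags[: n // 2] = True
    rng.shuffle(flags)
    return flags


def generate_design(config: DesignConfig, rng: np.random.Generator,
                    block_springs: tuple[str, str] = ("soft", "stiff"),
                    ) -> pd.DataFrame:
    """Ordered trial scaffold for one subject (no responses yet).

    Each block carries one spring condition; within a block the two set sizes
    are interleaved in randomized order under exact balance: the first
    ``practice_per_block`` rows are practice (balanced across set sizes and
    match flags), followed by ``experimental_per_condition`` trials per set
    size, half match / half no-match within every (set size, practice) stratum.
    """
    rows = []
    for block_i, spring in enumerate(block_springs[: config.n_blocks], start=1):
        segments = []
        n_prac_ss = config.practice_per_block // 2
        for ss in (3, 5):
            m = _balanced_match_flags(n_prac_ss, rng)
            segments.append(pd.DataFrame({
                "set_size": ss, "match": m, "is_practice": True,
            }))
        for ss in (3, 5):
            m = _balanced_match_flags(config.experimental_per_condition, rng)
            segments.append(pd.DataFrame({
                "set_size": ss, "match": m, "is_practice": False,
            }))
        block = pd.concat(segments, ignore_index=True)
        # practice first, both strata internally shuffled
        prac = block[block["is_practice"]].sample(frac=1.0, random_state=rng)
        expe = block[~block["is_practice"]].sample(frac=1.0, random_state=rng)
        block = pd.concat([prac, expe], ignore_index=True)
        block["block"] = block_i
        block["spring"] = spring
        block["trial"] = np.arange(1, len(block) + 1)
        rows.append(block)
    design = pd.concat(rows, ignore_index=True)
    return design[["block", "trial", "set_size", "spring", "match", "is_practice"]]


def _truncated_normal(mean: float, sd: float, low: float, high: float,
                      rng: np.random.Generator, max_tries: int = 1000) -> float:
    if sd == 0:
        return float(np.clip(mean, low, high))
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if low < x < high:
            return float(x)
    return float(np.clip(mean, low + 1e-6, high - 1e-6))


def draw_subject_params(group: GroupParameters, spec: ModelSpec,
                        rng: np.random.Generator) -> dict[Condition, DDMParameters]:
    """Draw one subject's per-cell parameters from the group distribution.

    Subject values are Normal(group mean, between-SD) per node, rejected and
    redrawn until the DDMParameters invariants hold (a > 0, ter >= st/2);
    group-only nuisance values are copied verbatim.
    """
    node_vals: dict[str, float] = {}
    for label, mean in group.means.items():
        sd = group.sds.get(label, 0.0)
        if label.startswith("a"):
            node_vals[label] = _truncated_normal(mean, sd, 1e-3, np.inf, rng)
        elif label.startswith("ter"):
            node_vals[label] = _truncated_normal(mean, sd, group.st / 2.0, np.inf, rng)
        else:
            node_vals[label] = _truncated_normal(mean, sd, -np.inf, np.inf, rng)
    out: dict[Condition, DDMParameters] = {}
    for cond in ALL_CONDITIONS:
        out[cond] = DDMParameters(
            v=node_vals[resolve_node(spec, "v", cond)],
            a=node_vals[resolve_node(spec, "a", cond)],
            ter=node_vals[resolve_node(spec, "ter", cond)],
            z=group.z, sv=group.sv, st=group.st, sz=group.sz,
        )
    return out


def generate_dataset(group: GroupParameters, spec: ModelSpec, n_subjects: int,
                     config: DesignConfig, rng: np.random.Generator,
                     ) -> tuple[pd.DataFrame, dict]:
    """Simulate a full multi-subject dataset plus its ground-truth ledger.

    Block order alternates across subjects when counterbalancing is on.  With
    probability ``group.p_outlier`` a trial is replaced by a contaminant:
    rt ~ Uniform(0, response_window) and a fair-coin response.  The ledger
    records subject parameters and contaminant positions and is never exposed
    to inference.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    frames = []
    ledger: dict = {
        "spec": spec.to_json(),
        "group": {
            "means": dict(group.means), "sds": dict(group.sds),
            "z": group.z, "sv": group.sv, "st": group.st, "sz": group.sz,
            "p_outlier": group.p_outlier,
        },
        "subjects": {},
        "n_contaminants": 0,
    }
    width = max(2, len(str(n_subjects)))
    for s in range(n_subjects):
        sid = f"s{s + 1:0{width}d}"
        if config.counterbalance and s % 2 == 1:
            springs = ("stiff", "soft")
        else:
            springs = ("soft", "stiff")
        design = generate_design(config, rng, block_springs=springs)
        params = draw_subject_params(group, spec, rng)
        n = len(design)
        rt = np.full(n, np.nan)
        bnd = np.full(n, -1, dtype=np.int8)
        for cond in ALL_CONDITIONS:
            mask = (
                (design["set_size"].to_numpy() == cond.set_size)
                & (design["spring"].to_numpy() == cond.spring)
            )
            k = int(mask.sum())
            if k == 0:
                continue
            r, b = simulate_trials_batch(
                params[cond], k, rng, dt=config.dt,
                response_window=config.response_window,
            )
            rt[mask] = r
            bnd[mask] = b
        # contaminants: uniform RT, fair-coin response
        outlier = rng.random(n) < group.p_outlier
        n_out = int(outlier.sum())
        if n_out:
            rt[outlier] = rng.uniform(0.0, config.response_window, n_out)
            bnd[outlier] = 99  # sentinel; response drawn below
        match = design["match"].to_numpy()
        response = np.empty(n, dtype=object)
        for i in range(n):
            if bnd[i] == 99:
                corr = bool(rng.random() < 0.5)
            elif bnd[i] < 0:
                response[i] = None
                continue
            else:
                corr = bool(bnd[i] == 1)  # upper boundary = correct
            response[i] = ("match" if match[i] else "no-match") if corr \
                else ("no-match" if match[i] else "match")
        df = design.copy()
        df.insert(0, "subject", sid)
        df["response"] = response
        df["rt_seconds"] = rt
        frames.append(df[list(TRIAL_COLUMNS)])
        ledger["subjects"][sid] = {
            "block_springs": list(springs),
            "params": {
                f"ss{c.set_size}:{c.spring}": {
                    "v": params[c].v, "a": params[c].a, "ter": params[c].ter,
                } for c in ALL_CONDITIONS
            },
            "contaminant_rows": np.flatnonzero(outlier).tolist(),
        }
        ledger["n_contaminants"] += n_out
    data = pd.concat(frames, ignore_index=True)
    return data, ledger
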