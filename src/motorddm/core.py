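"""Domain types for the 2x2 spring-pressure x set-size diffusion-model analysis.

The experimental design crosses a cognitive-load manipulation (set size: 3 vs 5
characters per comparison string, ``SS``) with a motor-speed manipulation
(response-button spring pressure: soft vs stiff, ``SPC``) within participants.
The nine-model space enumerates which of the three principal diffusion
parameters -- drift rate ``v``, boundary separation ``a``, and non-decision
time ``ter`` -- are allowed to vary with each factor.

Response coding is accuracy coding throughout: the upper boundary of the
diffusion is the correct response, the lower boundary the error, so the
starting point ``z`` is a bias toward correct responding and is treated as a
single group-level quantity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

SET_SIZES = (3, 5)
SPRINGS = ("soft", "stiff")

#: Factor names: set size and spring pressure condition.
FACTOR_SS = "SS"
FACTOR_SPC = "SPC"
VALID_FACTORS = frozenset({FACTOR_SS, FACTOR_SPC})

#: Group-only nuisance parameters (bias + across-trial variabilities).
NUISANCE_NODES = ("z", "sv", "st", "sz")

#: Columns of the trial table exchanged between pipeline stages.
TRIAL_COLUMNS = (
    "subject",
    "block",
    "trial",
    "set_size",
    "spring",
    "match",
    "response",
    "rt_seconds",
    "is_practice",
)


class SpecificationError(ValueError):
    """A model specification or node lookup is invalid."""


@dataclass(frozen=True, order=True)
class Condition:
    """One cell of the 2 (set size) x 2 (spring pressure) design."""

    set_size: int
    spring: str

    def __post_init__(self) -> None:
        if self.set_size not in SET_SIZES:
            raise ValueError(f"set_size must be one of {SET_SIZES}, got {self.set_size}")
        if self.spring not in SPRINGS:
            raise ValueError(f"spring must be one of {SPRINGS}, got {self.spring!r}")


#: The four design cells, in canonical order (set size major, spring minor).
ALL_CONDITIONS = tuple(
    Condition(ss, spc) for ss in SET_SIZES for spc in SPRINGS
)


@dataclass(frozen=True)
class DDMParameters:
    """One accumulator's parameter set (unit diffusion coefficient).

    Parameters
    ----------
    v : drift rate (evidence units / s)
    a : boundary separation (evidence units)
    ter : non-decision time (s)
    z : relative starting point (fraction of ``a``)
    sv : across-trial SD of drift
    st : across-trial range of non-decision time (s)
    sz : across-trial range of the relative starting point
    """

    v: float
    a: float
    ter: float
    z: float = 0.5
    sv: float = 0.0
    st: float = 0.0
    sz: float = 0.0

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"boundary separation must be positive, got a={self.a}")
        if not (0.0 < self.z < 1.0):
            raise ValueError(f"relative start must lie in (0, 1), got z={self.z}")
        if self.ter < 0:
            raise ValueError(f"non-decision time must be nonnegative, got ter={self.ter}")
        for name in ("sv", "st", "sz"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.ter - self.st / 2.0 < 0:
            raise ValueError("ter - st/2 must be nonnegative (minimum non-decision time)")
        if not (self.z - self.sz / 2.0 > 0 and self.z + self.sz / 2.0 < 1):
            raise ValueError("starting-point range z +/- sz/2 must stay inside (0, 1)")


@dataclass(frozen=True)
class ModelSpec:
    """Which parameters vary by which factors (one row of the model space)."""

    model_id: int
    v_factors: frozenset = frozenset()
    a_factors: frozenset = frozenset()
    ter_factors: frozenset = frozenset()

    def __post_init__(self) -> None:
        for name in ("v_factors", "a_factors", "ter_factors"):
            factors = getattr(self, name)
            object.__setattr__(self, name, frozenset(factors))
            unknown = frozenset(factors) - VALID_FACTORS
            if unknown:
                raise SpecificationError(
                    f"unknown factor(s) {sorted(unknown)} in {name}; "
                    f"valid factors are {sorted(VALID_FACTORS)}"
                )

    def factors_of(self, param: str) -> frozenset:
        try:
            return {"v": self.v_factors, "a": self.a_factors, "ter": self.ter_factors}[param]
        except KeyError:
            raise SpecificationError(f"unknown parameter {param!r}") from None

    def to_json(self) -> str:
        return json.dumps(
            {
                "model_id": self.model_id,
                "v_factors": sorted(self.v_factors),
                "a_factors": sorted(self.a_factors),
                "ter_factors": sorted(self.ter_factors),
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "ModelSpec":
        d = json.loads(payload)
        return cls(
            model_id=int(d["model_id"]),
            v_factors=frozenset(d["v_factors"]),
            a_factors=frozenset(d["a_factors"]),
            ter_factors=frozenset(d["ter_factors"]),
        )


@dataclass(frozen=True)
class TrialRecord:
    """One behavioral trial (two-alternative string comparison)."""

    subject: str
    block: int
    trial_index: int
    condition: Condition
    match: bool
    response: str | None
    rt: float | None
    is_practice: bool = False

    def __post_init__(self) -> None:
        if self.response is not None and self.response not in ("match", "no-match"):
            raise ValueError(f"response must be 'match', 'no-match' or None, got {self.response!r}")
        if self.rt is not None and not self.rt > 0:
            raise ValueError(f"rt must be positive when present, got {self.rt}")

    @property
    def correct(self) -> bool | None:
        """Whether the response agrees with the match flag (None if no response)."""
        if self.response is None:
            return None
        return (self.response == "match") == self.match


@dataclass
class GroupParameters:
    """Group-level generating/estimated parameters under a given ModelSpec.

    ``means`` and ``sds`` map parameter-node labels (see
    :func:`condition_nodes`) to group means and between-subject SDs for the
    subject-varying parameters v, a, ter.  Bias and variability parameters are
    group-only scalars; ``p_outlier`` is the contaminant fraction of the
    uniform-outlier mixture.
    """

    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)
    z: float = 0.5
    sv: float = 0.0
    st: float = 0.0
    sz: float = 0.0
    p_outlier: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_outlier <= 1.0):
            raise ValueError(f"p_outlier must lie in [0, 1], got {self.p_outlier}")
        for label, sd in self.sds.items():
            if sd < 0:
                raise ValueError(f"between-subject SD for {label} must be >= 0, got {sd}")


def build_model_space() -> tuple[ModelSpec, ...]:
    """The nine candidate parameter-condition models, in canonical order.

    Model 1 is the full model (v, a, ter all vary by set size and spring);
    models 2-3 restrict the drift factors, models 4-8 keep a set-size effect
    on drift while varying the boundary/non-decision structure, and model 9
    frees only the drift rate.
    """
    both = frozenset({FACTOR_SS, FACTOR_SPC})
    ss = frozenset({FACTOR_SS})
    spc = frozenset({FACTOR_SPC})
    none: frozenset = frozenset()
    return (
        ModelSpec(1, both, both, both),
        ModelSpec(2, spc, both, both),
        ModelSpec(3, ss, none, both),
        ModelSpec(4, ss, both, both),
        ModelSpec(5, ss, ss, both),
        ModelSpec(6, ss, spc, both),
        ModelSpec(7, ss, both, ss),
        ModelSpec(8, ss, both, spc),
        ModelSpec(9, both, none, none),
    )


def cell_label(factors: Iterable[str], condition: Condition) -> str:
    """Label of the parameter cell a condition falls into under ``factors``.

    Empty factors collapse all conditions into one cell (empty label).
    """
    factors = frozenset(factors)
    unknown = factors - VALID_FACTORS
    if unknown:
        raise SpecificationError(f"unknown factor(s): {sorted(unknown)}")
    parts = []
    if FACTOR_SS in factors:
        parts.append(f"ss{condition.set_size}")
    if FACTOR_SPC in factors:
        parts.append(condition.spring)
    return ":".join(parts)


def condition_cells(factors: Iterable[str]) -> tuple[str, ...]:
    """Distinct cell labels induced by a factor subset, in canonical order."""
    seen: dict[str, None] = {}
    for cond in ALL_CONDITIONS:
        seen.setdefault(cell_label(factors, cond), None)
    return tuple(seen)


def node_label(param: str, cell: str) -> str:
    return f"{param}({cell})" if cell else param


def condition_nodes(spec: ModelSpec, param: str) -> tuple[str, ...]:
    """Node labels of one parameter under the spec (1, 2 or 4 nodes)."""
    return tuple(node_label(param, c) for c in condition_cells(spec.factors_of(param)))


def parameter_nodes(spec: ModelSpec) -> tuple[str, ...]:
    """All parameter-node labels of a model: condition cells then nuisance.

    One node per (parameter, induced condition cell) for v, a, ter, plus the
    four group-only nuisance nodes z, sv, st, sz.  Labels are deterministic
    and stable across calls.
    """
    nodes: list[str] = []
    for param in ("v", "a", "ter"):
        nodes.extend(condition_nodes(spec, param))
    nodes.extend(NUISANCE_NODES)
    return tuple(nodes)


def resolve_node(spec: ModelSpec, param: str, condition: Condition) -> str:
    """The node a (parameter, condition) pair maps to under the spec."""
    return node_label(param, cell_label(spec.factors_of(param), condition))


def params_for_condition(
    spec: ModelSpec, group: GroupParameters, condition: Condition
) -> DDMParameters:
    """Assemble the group-mean DDMParameters acting in one design cell."""
    return DDMParameters(
        v=group.means[resolve_node(spec, "v", condition)],
        a=group.means[resolve_node(spec, "a", condition)],
        ter=group.means[resolve_node(spec, "ter", condition)],
        z=group.z,
        sv=group.sv,
        st=group.st,
        sz=group.sz,
    )


# ---------------------------------------------------------------------------
# Trial-table helpers

def validate_trials(df: pd.DataFrame) -> None:
    """Schema check for a trial table; raises ValueError naming offenders."""
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table is missing column(s): {missing}")
    problems = []
    if not df["set_size"].isin(SET_SIZES).all():
        problems.append("set_size outside {3, 5}")
    if not df["spring"].isin(SPRINGS).all():
        problems.append("spring outside {soft, stiff}")
    responded = df["response"].notna()
    if not df.loc[responded, "response"].isin(["match", "no-match"]).all():
        problems.append("response outside {match, no-match}")
    has_rt = df["rt_seconds"].notna()
    if (df.loc[has_rt, "rt_seconds"] <= 0).any():
        problems.append("nonpositive rt_seconds")
    if problems:
        raise ValueError("invalid trial table: " + "; ".join(problems))


def add_correct(df: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with a derived boolean ``correct`` column.

    Trials without a response get ``correct = False`` (a missed response is
    scored as an error for accuracy purposes).
    """
    out = df.copy()
    responded = out["response"].notna()
    out["correct"] = False
    out.loc[responded, "correct"] = (
        (out.loc[responded, "response"] == "match") == out.loc[responded, "match"]
    )
    return out


def condition_index(df: pd.DataFrame) -> pd.Series:
    """Map each row to its Condition object (vectorized convenience)."""
    return pd.Series(
        [Condition(int(ss), sp) for ss, sp in zip(df["set_size"], df["spring"])],
        index=df.index,
    )
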