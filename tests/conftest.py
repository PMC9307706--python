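"""Shared fixtures: all fixture data is generated programmatically."""

import warnings

import numpy as np
import pandas as pd
import pytest

import motorddm as m

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


def make_trials(rows):
    """Trial table from (subject, block, trial, ss, spring, match, response,
    rt, practice) tuples."""
    return pd.DataFrame(rows, columns=[
        "subject", "block", "trial", "set_size", "spring", "match",
        "response", "rt_seconds", "is_practice",
    ])


def simple_subject(sid, rts, correct=None, set_size=3, spring="soft",
                   practice=0):
    """One-cell trial rows for one subject; all-match stimuli."""
    rows = []
    for i, rt in enumerate(rts):
        ok = True if correct is None else bool(correct[i])
        rows.append((sid, 1, i + 1, set_size, spring, True,
                     "match" if ok else "no-match", rt, i < practice))
    return rows


def balanced_subject(sid, rng, acc=0.9, rt_loc=0.7, n_per_cell=20):
    """Rows covering all four design cells with given accuracy/RT level."""
    rows = []
    t = 0
    for ss in (3, 5):
        for spring in ("soft", "stiff"):
            for _ in range(n_per_cell):
                t += 1
                ok = rng.random() < acc
                match = bool(rng.random() < 0.5)
                resp = ("match" if match else "no-match") if ok else \
                    ("no-match" if match else "match")
                rows.append((sid, 1 if spring == "soft" else 2, t, ss, spring,
                             match, resp, rng.gamma(9, rt_loc / 9), False))
    return rows


@pytest.fixture(scope="session")
def reference():
    spec, group = m.reference_group_parameters()
    return spec, group


@pytest.fixture(scope="session")
def tiny_dataset(reference):
    """Small simulated dataset: 4 subjects, 30 experimental trials/cell."""
    spec, group = reference
    rng = np.random.default_rng(2024)
    config = m.DesignConfig(practice_per_block=8, experimental_per_condition=30,
                            dt=5e-4)
    data, ledger = m.generate_dataset(group, spec, n_subjects=4, config=config,
                                      rng=rng)
    return data, ledger, config


@pytest.fixture(scope="session")
def tiny_fit(tiny_dataset, reference):
    """A short Model-4 fit on the tiny dataset (shared across test modules)."""
    spec, _ = reference
    data, _, _ = tiny_dataset
    clean, _ = m.preprocess(data)
    return clean, m.fit(
        clean, spec,
        mcmc=m.MCMCConfig(iterations=500, burn_in=200, chains=2, seed=99),
        likelihood_config=m.LikelihoodConfig(quadrature_points=5),
    )
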