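"""Pipeline stages tying simulation, preprocessing, fitting and comparison
together, driven by one YAML-style configuration and one root seed.

All randomness flows from the root seed through named per-stage substreams,
so the full pipeline (simulate -> preprocess -> fit -> compare) is
reproducible bit-for-bit.  Every output file gets a JSON sidecar with the
configuration hash and the seed that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .behavior import bf_model_comparison, cell_summary, correlation_matrix
from .comparison import drift_spring_pairs, ci_overlap, rank_models
from .core import GroupParameters, build_model_space
from .inference import MCMCConfig, PosteriorFit, diagnostics, fit as fit_model, \
    posterior_predictive, summarize
from .likelihood import LikelihoodConfig
from .preprocess import PreprocessConfig, preprocess
from .simulate import DesignConfig, generate_dataset, reference_group_parameters

log = logging.getLogger("motorddm")

__all__ = [
    "PipelineConfig",
    "cmd_simulate",
    "cmd_preprocess",
    "cmd_fit",
    "cmd_compare",
    "cmd_behave",
    "cmd_report",
]


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; see ``from_yaml`` for the layout."""

    output_dir: str = "motorddm_out"
    trials_path: str | None = None
    assessments_path: str | None = None
    seed: int = 0
    n_subjects: int = 12
    models: tuple = (4,)
    p_outlier: float = 0.05
    design: DesignConfig = field(default_factory=DesignConfig)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    likelihood: LikelihoodConfig = field(default_factory=LikelihoodConfig)
    preprocessing: PreprocessConfig = field(default_factory=PreprocessConfig)
    group: GroupParameters | None = None  # None -> reference parameters

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        kwargs = {}
        for key in ("output_dir", "trials_path", "assessments_path", "seed",
                    "n_subjects", "p_outlier"):
            if key in raw:
                kwargs[key] = raw[key]
        if "models" in raw:
            kwargs["models"] = tuple(raw["models"])
        for key, klass in (("design", DesignConfig), ("mcmc", MCMCConfig),
                           ("likelihood", LikelihoodConfig),
                           ("preprocessing", PreprocessConfig)):
            if key in raw:
                kwargs[key] = klass(**raw[key])
        if "group" in raw:
            kwargs["group"] = GroupParameters(**raw["group"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def rng(self, stage: str) -> np.random.Generator:
        """Named substream of the root seed for one pipeline stage."""
        ss = np.random.SeedSequence(
            self.seed,
            spawn_key=(int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4],
                                      "little"),),
        )
        return np.random.default_rng(ss)

    def outdir(self) -> Path:
        p = Path(self.output_dir)
        p.mkdir(parents=True, exist_ok=True)
        return p


def _sidecar(config: PipelineConfig, path: Path, **extra) -> None:
    meta = {"seed": config.seed, "config_hash": config.config_hash(),
            "created": "motorddm", **extra}
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2)
    )


def _resolved_group(config: PipelineConfig):
    if config.group is not None:
        spec, _ = reference_group_parameters()
        return spec, config.group
    spec, group = reference_group_parameters(p_outlier=config.p_outlier)
    return spec, group


def cmd_simulate(config: PipelineConfig) -> Path:
    """Simulate a dataset; writes trial table, ground-truth ledger, metadata."""
    t0 = time.time()
    spec, group = _resolved_group(config)
    rng = config.rng("simulate")
    data, ledger = generate_dataset(group, spec, config.n_subjects,
                                    config.design, rng)
    out = config.outdir()
    trials_path = out / "trials.csv"
    data.to_csv(trials_path, index=False)
    (out / "ground_truth.json").write_text(json.dumps(ledger, indent=2))
    _sidecar(config, trials_path, stage="simulate",
             n_subjects=config.n_subjects, rows=len(data))
    log.info("simulate: %d subjects, %d rows, %d contaminants (%.1fs)",
             config.n_subjects, len(data), ledger["n_contaminants"],
             time.time() - t0)
    return trials_path


def _load_trials(config: PipelineConfig) -> pd.DataFrame:
    path = config.trials_path or (config.outdir() / "trials.csv")
    df = pd.read_csv(path)
    missing = [c for c in ("subject", "rt_seconds") if c not in df.columns]
    if missing:
        raise ValueError(f"trial table {path} is missing column(s): {missing}")
    return df


def cmd_preprocess(config: PipelineConfig) -> Path:
    """Apply exclusion rules; writes the clean table and the report."""
    trials = _load_trials(config)
    clean, report = preprocess(trials, config.preprocessing)
    out = config.outdir()
    clean_path = out / "trials_clean.csv"
    clean.to_csv(clean_path, index=False)
    (out / "preprocess_report.json").write_text(report.to_json())
    _sidecar(config, clean_path, stage="preprocess")
    log.info("preprocess: %d -> %d trials (%.2f%% RT-filtered), %d subjects excluded",
             report.trials_in, report.trials_out,
             100 * report.removed_fraction, len(report.excluded_subjects))
    return clean_path


def _load_clean(config: PipelineConfig) -> pd.DataFrame:
    path = config.outdir() / "trials_clean.csv"
    if not path.exists():
        cmd_preprocess(config)
    return pd.read_csv(path)


def cmd_fit(config: PipelineConfig) -> dict[int, PosteriorFit]:
    """Fit the requested models; writes draws, summaries and diagnostics."""
    clean = _load_clean(config)
    out = config.outdir()
    space = {s.model_id: s for s in build_model_space()}
    fits = {}
    for mid in config.models:
        spec = space[int(mid)]
        t0 = time.time()
        mcfg = MCMCConfig(**{**config.mcmc.__dict__,
                             "seed": int(config.rng(f"fit{mid}").integers(2**31 - 1))})
        fitted = fit_model(clean, spec, mcmc=mcfg,
                           likelihood_config=config.likelihood,
                           p_outlier=config.p_outlier)
        fitted.save(out / f"fit_model{mid}")
        summarize(fitted).to_csv(out / f"summary_model{mid}.csv", index=False)
        diag = diagnostics(fitted)
        diag.to_csv(out / f"diagnostics_model{mid}.csv")
        bad = diag["rhat"].dropna()
        bad = bad[bad > 1.1]
        if len(bad):
            log.warning(
                "model %d: %d node(s) with split-R-hat > 1.1 (max %.3f) — "
                "treat estimates with caution", mid, len(bad), bad.max()
            )
        log.info("fit model %d: %.1f min", mid, (time.time() - t0) / 60)
        fits[int(mid)] = fitted
    return fits


def cmd_compare(config: PipelineConfig, n_rep_ppc: int = 50) -> pd.DataFrame:
    """Model-comparison table, independence verdict, posterior-predictive data."""
    clean = _load_clean(config)
    out = config.outdir()
    fits = {}
    for mid in config.models:
        prefix = out / f"fit_model{mid}"
        if not Path(f"{prefix}.json").exists():
            raise FileNotFoundError(
                f"no fit found for model {mid}; run the fit stage first "
                f"(missing {prefix}.json)"
            )
        fits[int(mid)] = PosteriorFit.load(prefix)
    table = rank_models(fits, clean)
    table.to_csv(out / "model_comparison.csv", index=False)
    _sidecar(config, out / "model_comparison.csv", stage="compare")

    verdict_rows = []
    for mid, fitted in fits.items():
        pairs = drift_spring_pairs(fitted)
        if not pairs:
            verdict_rows.append({
                "model_id": mid, "applicable": False,
                "note": "not applicable: drift rate does not vary by spring "
                        "pressure in this model",
            })
            continue
        rep = ci_overlap(fitted, pairs)
        for _, r in rep.iterrows():
            verdict_rows.append({
                "model_id": mid, "applicable": True,
                "node_a": r["node_a"], "node_b": r["node_b"],
                "mutual_containment": bool(r["mutual"]),
            })
    pd.DataFrame(verdict_rows).to_csv(out / "independence_check.csv", index=False)

    rng = config.rng("ppc")
    ppc_frames = []
    for mid, fitted in fits.items():
        ppc = posterior_predictive(fitted, clean, n_rep_ppc, rng)
        ppc.insert(0, "model_id", mid)
        ppc_frames.append(ppc)
    pd.concat(ppc_frames, ignore_index=True).to_csv(
        out / "posterior_predictive.csv", index=False
    )
    log.info("compare: best model %d", int(table.iloc[0]["model_id"]))
    return table


def cmd_behave(config: PipelineConfig) -> dict:
    """Behavioral summaries, Bayes-factor tables and (optionally) correlations."""
    clean = _load_clean(config)
    out = config.outdir()
    cells = cell_summary(clean)
    cells.to_csv(out / "cell_summary.csv", index=False)
    results = {"cells": cells}
    for dv in ("accuracy", "mean_rt"):
        bf = bf_model_comparison(cells, dv=dv)
        bf.to_csv(out / f"bayes_factors_{dv}.csv", index=False)
        results[f"bf_{dv}"] = bf
    if config.assessments_path:
        assessments = pd.read_csv(config.assessments_path)
        prefix = out / "fit_model4"
        if Path(f"{prefix}.json").exists():
            fitted = PosteriorFit.load(prefix)
            sp = pd.concat(
                [fitted.subject_means(p) for p in ("v", "a", "ter")], axis=1
            )
            mat = correlation_matrix(sp, assessments)
            mat.to_csv(out / "correlation_matrix.csv")
            (out / "correlation_matrix.caveat.txt").write_text(
                mat.attrs["caveat"] + "\n"
            )
            results["correlations"] = mat
    return results


def cmd_report(config: PipelineConfig) -> Path:
    """Collect stage outputs into a single JSON report."""
    out = config.outdir()
    report: dict = {"seed": config.seed, "config_hash": config.config_hash()}
    for name in ("preprocess_report", "ground_truth"):
        p = out / f"{name}.json"
        if p.exists():
            report[name] = json.loads(p.read_text())
    for name in ("model_comparison", "independence_check", "cell_summary"):
        p = out / f"{name}.csv"
        if p.exists():
            report[name] = pd.read_csv(p).to_dict(orient="records")
    path = out / "report.json"
    path.write_text(json.dumps(report, indent=2, default=str))
    return path
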