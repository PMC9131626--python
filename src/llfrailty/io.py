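"""Dataset reading/validation, result writers and the three-stage pipeline.

CSV (UTF-8, "." decimal) is the single tabular interchange format.  The
pipeline runs simulate (optional) -> fit -> describe and leaves every
artifact needed to reproduce the run: the dataset, the generating truth,
the regression table (CSV and aligned text), fit metadata (JSON with seed
and library versions) and the descriptive tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

from . import __version__
from .describe import describe_by_group, format_summary, overall_summary
from .fit import Covariate, FitResult, ModelSpec, fit_model, summary_table
from .simulate import SyntheticConfig, generate_population, model_spec_for

logger = logging.getLogger("llfrailty")

__all__ = [
    "DatasetSchema",
    "read_dataset",
    "write_dataset",
    "infer_spec",
    "write_fit_outputs",
    "run_pipeline",
]


@dataclass(frozen=True)
class DatasetSchema:
    """Column roles and category lists for validation."""

    time: str = "time"
    event: str = "event"
    cluster: str = "cluster"
    covariates: dict = field(default_factory=dict)  # name -> list of categories

    @classmethod
    def from_model_spec(cls, spec: ModelSpec) -> "DatasetSchema":
        return cls(
            time=spec.time_field,
            event=spec.event_field,
            cluster=spec.cluster_field,
            covariates={c.name: list(c.categories) for c in spec.covariates},
        )


def read_dataset(path, schema: DatasetSchema) -> pd.DataFrame:
    """Read and validate a survival dataset CSV.

    Rows violating the invariants (non-positive or unparseable time, event
    outside {0,1}) are reported with their row numbers; categories not in
    the schema are an error listing the offenders.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty dataset")
    required = [schema.time, schema.event, schema.cluster, *schema.covariates]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")

    problems = []
    t = pd.to_numeric(df[schema.time], errors="coerce")
    bad = df.index[~np.isfinite(t) | (t <= 0)]
    problems += [f"row {i}: time={df.loc[i, schema.time]!r} (need > 0)" for i in bad]
    ev = pd.to_numeric(df[schema.event], errors="coerce")
    bad = df.index[~ev.isin([0, 1])]
    problems += [
        f"row {i}: event={df.loc[i, schema.event]!r} (need 0/1)" for i in bad
    ]
    for name, cats in schema.covariates.items():
        offenders = sorted(set(df[name].astype(str)) - set(map(str, cats)))
        if offenders:
            problems.append(
                f"column {name!r}: categories outside schema: {offenders}"
            )
    if problems:
        raise ValueError(f"{path}: invalid rows:\n" + "\n".join(problems))

    df[schema.time] = t.astype(float)
    df[schema.event] = ev.astype(int)
    logger.info("read %d records from %s", len(df), path)
    for name in schema.covariates:
        tally = df[name].value_counts().to_dict()
        logger.info("  %s: %s", name, tally)
    return df


def write_dataset(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def infer_spec(
    df: pd.DataFrame,
    mode: str = "aft",
    frailty: bool = True,
    exclude: tuple = ("id", "time", "event", "cluster"),
) -> ModelSpec:
    """Build a ModelSpec from a dataset: every non-role column is a
    categorical covariate, reference = first category by appearance."""
    covs = []
    for name in df.columns:
        if name in exclude:
            continue
        cats = tuple(pd.unique(df[name].astype(str)))
        if len(cats) < 2:
            continue
        covs.append(Covariate(name, cats, cats[0]))
    return ModelSpec(covariates=tuple(covs), mode=mode, frailty=frailty)


def _format_p(p: float) -> str:
    # reporting convention: floor very small p-values at "<= 0.001"
    if not np.isfinite(p):
        return "NA"
    return "<= 0.001" if p < 0.001 else f"{p:.3f}"


def format_summary_text(table: pd.DataFrame) -> str:
    """Aligned plain-text regression table with footer."""
    lines = [
        f"{'covariate':<16}{'category':<16}{'coef':>12}{'st.err':>12}"
        f"{'p-value':>10}{'phi':>12}"
    ]
    for _, r in table.iterrows():
        lines.append(
            f"{r['covariate']:<16}{r['category']:<16}{r['coef']:>12.7f}"
            f"{r['se']:>12.7f}{_format_p(r['p_value']):>10}{r['phi']:>12.7f}"
        )
    f = table.attrs.get("footer", {})
    lines.append("-" * 78)
    if "theta" in f:
        lines.append(
            f"Random effects: gamma = {f['gamma']:.3f}, "
            f"theta = {f['theta']:.3f}, tau = {100 * f['tau']:.1f}%"
        )
        lines.append(
            f"LR test of theta = 0: X = {f['lr_stat']:.3f}, "
            f"p = {_format_p(f['lr_pvalue'])} "
            "(0.5*chi2_0 + 0.5*chi2_1 reference)"
        )
    else:
        lines.append(f"gamma = {f.get('gamma', float('nan')):.3f} (no frailty)")
    lines.append(f"log-likelihood = {f.get('loglik', float('nan')):.4f}")
    return "\n".join(lines) + "\n"


def write_fit_outputs(
    fit: FitResult, spec: ModelSpec, out_dir, seed=None
) -> dict:
    """Write fit_summary.csv / fit_summary.txt / fit_meta.json; returns
    the metadata dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = summary_table(fit, spec)
    table.to_csv(out / "fit_summary.csv", index=False)
    (out / "fit_summary.txt").write_text(format_summary_text(table))
    meta = {
        "loglik": fit.loglik,
        "loglik_nofrailty": fit.loglik_nofrailty,
        "intercept": fit.intercept,
        "beta": fit.beta,
        "shape_k": fit.shape_k,
        "gamma_reported": fit.gamma_reported,
        "theta": fit.theta,
        "tau": fit.tau,
        "lr_stat": fit.lr_stat,
        "lr_pvalue": fit.lr_pvalue,
        "converged": fit.converged,
        "n_iter": fit.n_iter,
        "mode": fit.mode,
        "frailty": fit.frailty,
        "n_obs": fit.n_obs,
        "n_clusters": fit.n_clusters,
        "n_events": fit.n_events,
        "seed": seed,
        "versions": {
            "llfrailty": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    (out / "fit_meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return meta


def run_pipeline(config: dict, out_dir, seed: int | None = None) -> dict:
    """simulate (optional) -> fit -> describe, writing artifacts to out_dir.

    ``config`` keys:
      simulate: dict of SyntheticConfig overrides, or absent/None to skip
      dataset:  path to a CSV (required when simulate is absent)
      model:    {"mode": "aft"|"ph", "frailty": bool}
      describe_by: list of covariate names (default: all covariates)
    Raises on any stage failure; returns the fit metadata dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        model_cfg = config.get("model", {})
        mode = model_cfg.get("mode", "aft")
        frailty = bool(model_cfg.get("frailty", True))

        if config.get("simulate") is not None:
            sim_kw = dict(config["simulate"])
            if seed is not None:
                sim_kw["seed"] = seed
            sim_cfg = SyntheticConfig(**sim_kw)
            df, truth = generate_population(sim_cfg)
            write_dataset(df, out / "cohort.csv")
            (out / "truth.json").write_text(
                json.dumps(truth, indent=2, sort_keys=True)
            )
            spec = model_spec_for(sim_cfg, frailty=frailty)
            if mode != sim_cfg.mode:
                spec = ModelSpec(
                    covariates=spec.covariates, mode=mode, frailty=frailty
                )
            logger.info(
                "simulated %d women, event fraction %.4f, cluster sizes %s",
                len(df), truth["event_fraction"], sim_cfg.cluster_sizes,
            )
        elif config.get("dataset"):
            probe = pd.read_csv(config["dataset"], nrows=5)
            spec = infer_spec(probe, mode=mode, frailty=frailty)
            schema = DatasetSchema.from_model_spec(spec)
            df = read_dataset(config["dataset"], schema)
            spec = infer_spec(df, mode=mode, frailty=frailty)
        else:
            raise ValueError("config needs either 'simulate' or 'dataset'")

        fit = fit_model(df, spec)
        logger.info(
            "fit: converged=%s loglik=%.4f theta=%.5f tau=%.5f iters=%d",
            fit.converged, fit.loglik, fit.theta, fit.tau, fit.n_iter,
        )
        meta = write_fit_outputs(fit, spec, out, seed=seed)

        cov_names = config.get(
            "describe_by", [c.name for c in spec.covariates]
        )
        format_summary(
            pd.DataFrame([overall_summary(df).__dict__])
        ).to_csv(out / "describe_overall.csv", index=False)
        for name in cov_names:
            format_summary(describe_by_group(df, name)).to_csv(
                out / f"describe_{name}.csv", index=False
            )
        return meta
    finally:
        logger.removeHandler(handler)
        handler.close()
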