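"""One-command pipeline: simulate → clean → split → clock → associate → attribute.

Configuration is a single YAML document (see ``examples/`` and
:func:`validate_config`); a master seed fans out to per-stage seeds via a
documented derivation, all logged to ``seed_log.json``. Outputs are
diffable TSV/CSV/JSON files in a results directory, each table carrying a
provenance header (config hash, master seed, package version), plus a
MANIFEST recording which stages completed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import run_disease_association
from .attribution import aggregate_psych_effect, build_design, fit_attribution
from .clock import (
    ClockHyperparams,
    compute_metrics,
    fit_en_baseline,
    mean_age_baseline,
    predict_age,
    train_clock,
    save_model,
    build_features,
)
from .cohort_io import assign_sets, binarize_covariates, exclude_invalid, load_cohort, write_cohort
from .schema import default_schema
from .synthetic import ConfigError, SyntheticConfig, generate_cohort

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "ConfigValidationError",
    "validate_config",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

STAGES = ("cohort", "exclude", "split", "clock", "associate", "attribute", "report")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class ConfigValidationError(ValueError):
    """Invalid pipeline configuration; message lists all violations."""

    def __init__(self, violations: list[str]):
        super().__init__("; ".join(violations))
        self.violations = violations


def stage_seed(master: int, stage: str) -> int:
    """Per-stage seed below 2**31, derived from the master seed."""
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([int(master), idx]).generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Validated configuration of one pipeline run."""

    master_seed: int
    results_dir: Path = Path("results")
    cohort_in: Path | None = None  # load a cohort CSV instead of simulating
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    clock_hyperparams: ClockHyperparams = field(default_factory=ClockHyperparams)
    clock_n_folds: int = 5
    train_fraction_healthy: float = 0.66
    en_baseline: bool = True
    attribution_train_fraction: float = 0.7
    attribution_n_folds: int = 10
    attribution_n_seeds: int = 10
    log_level: str = "INFO"

    def config_hash(self) -> str:
        """Hash of the scientific parameters (paths excluded)."""
        doc = dataclasses.asdict(self)
        doc.pop("results_dir", None)
        doc.pop("cohort_in", None)
        blob = yaml.safe_dump(doc, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and validate a pipeline YAML; report *all* violations at once."""
    path = Path(path)
    try:
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
    except OSError as exc:
        raise ConfigValidationError([f"cannot read config: {exc}"]) from exc

    violations: list[str] = []
    if "master_seed" not in doc or doc["master_seed"] is None:
        violations.append("master_seed is mandatory")
    master = int(doc.get("master_seed") or 0)

    synthetic = SyntheticConfig(seed=stage_seed(master, "cohort"))
    if doc.get("synthetic"):
        sdoc = dict(doc["synthetic"])
        sdoc.setdefault("seed", stage_seed(master, "cohort"))
        try:
            synthetic = SyntheticConfig.from_mapping(sdoc)
            synthetic.validate()
        except (ConfigError, TypeError) as exc:
            violations.append(f"synthetic: {exc}")

    hp = ClockHyperparams()
    if doc.get("clock"):
        cdoc = dict(doc["clock"])
        n_folds = cdoc.pop("n_folds", 5)
        try:
            hp = ClockHyperparams(**cdoc)
        except (ValueError, TypeError) as exc:
            violations.append(f"clock: {exc}")
            n_folds = 5
    else:
        n_folds = 5

    att = doc.get("attribution") or {}
    att_frac = float(att.get("train_fraction", 0.7))
    if not 0 < att_frac < 1:
        violations.append("attribution.train_fraction must lie in (0, 1)")
    split = doc.get("split") or {}
    healthy_frac = float(split.get("train_fraction_healthy", 0.66))
    if not 0 <= healthy_frac <= 1:
        violations.append("split.train_fraction_healthy must lie in [0, 1]")

    cohort_in = doc.get("cohort_in")
    if cohort_in is not None:
        cohort_in = (path.parent / cohort_in).resolve()
        if not cohort_in.exists():
            violations.append(f"cohort_in does not exist: {cohort_in}")

    if violations:
        raise ConfigValidationError(violations)

    results_dir = doc.get("results_dir", "results")
    return PipelineConfig(
        master_seed=master,
        results_dir=Path(results_dir),
        cohort_in=cohort_in,
        synthetic=synthetic,
        clock_hyperparams=hp,
        clock_n_folds=int(n_folds),
        train_fraction_healthy=healthy_frac,
        en_baseline=bool(doc.get("en_baseline", True)),
        attribution_train_fraction=att_frac,
        attribution_n_folds=int(att.get("n_folds", 10)),
        attribution_n_seeds=int(att.get("n_seeds", 10)),
        log_level=str(doc.get("log_level", "INFO")),
    )


def _write_table(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig, until: str = "report") -> Path:
    """Execute the pipeline up to (and including) stage ``until``.

    Stage order: cohort, exclude, split, clock, associate, attribute,
    report. Returns the results directory. On failure the partial outputs
    are retained and the MANIFEST marks which stages completed.
    """
    if until not in STAGES:
        raise ValueError(f"unknown stage {until!r}; choose from {STAGES}")
    out = Path(config.results_dir)
    out.mkdir(parents=True, exist_ok=True)
    schema = default_schema()
    header = (
        f"# bloodclock v{__version__} config_hash={config.config_hash()} "
        f"master_seed={config.master_seed}\n"
    )
    completed: list[str] = []
    seed_log = {s: stage_seed(config.master_seed, s) for s in STAGES}
    with open(out / "seed_log.json", "w", encoding="utf-8") as fh:
        json.dump({"master_seed": config.master_seed, "stage_seeds": seed_log}, fh, indent=2)

    def manifest() -> None:
        lines = [f"{s}\t{'complete' if s in completed else 'pending'}" for s in STAGES]
        (out / "MANIFEST").write_text("\n".join(lines) + "\n", encoding="utf-8")

    stop = STAGES.index(until)
    metrics_doc: dict = {}
    try:
        # -- cohort --------------------------------------------------------
        stage = "cohort"
        if config.cohort_in is not None:
            cohort, report = load_cohort(config.cohort_in, schema)
            truth = None
        else:
            cohort, truth = generate_cohort(config.synthetic, schema)
            write_cohort(cohort, out / "cohort.csv", schema)
            truth.to_csv(out / "truth.csv")
            config.synthetic.to_yaml(out / "synthetic_config.yaml")
        completed.append(stage)
        manifest()
        if STAGES.index(stage) >= stop:
            return out

        # -- exclude -------------------------------------------------------
        stage = "exclude"
        cohort, exclusion_log = exclude_invalid(cohort, schema)
        _write_table(exclusion_log, out / "exclusion_log.tsv", header)
        metrics_doc["n_excluded"] = int(len(exclusion_log))
        metrics_doc["n_cohort"] = int(len(cohort))
        completed.append(stage)
        manifest()
        if STAGES.index(stage) >= stop:
            return out

        # -- split ---------------------------------------------------------
        stage = "split"
        assignment = assign_sets(
            cohort, schema, config.train_fraction_healthy,
            seed=stage_seed(config.master_seed, "split"), excluded=exclusion_log,
        )
        _write_table(assignment.table, out / "splits.tsv", header)
        train = assignment.subset(cohort, "train")
        test = assignment.subset(cohort, "test")
        discovery = assignment.subset(cohort, "discovery")
        metrics_doc["split_counts"] = assignment.counts()
        completed.append(stage)
        manifest()
        if STAGES.index(stage) >= stop:
            return out

        # -- clock ---------------------------------------------------------
        stage = "clock"
        clock_seed = stage_seed(config.master_seed, "clock")
        model, cv_records = train_clock(
            train, config.clock_hyperparams, config.clock_n_folds, clock_seed, schema
        )
        save_model(model, out / "clock_model")
        preds = {
            "cv": cv_records,
            "test": predict_age(model, test, schema),
            "discovery": predict_age(model, discovery, schema),
        }
        pd.concat(
            [p.assign(cohort=k) for k, p in preds.items()], ignore_index=True
        ).to_csv(out / "predictions.csv", index=False)

        mean_pred = mean_age_baseline(train)
        rows = []
        for name, records in preds.items():
            m = compute_metrics(records)
            rows.append({"model": "neural_network", "cohort": name,
                         "mae_years": m.mae, "mape_percent": m.mape,
                         "r2": m.r2, "n": m.n})
            base = records.copy()
            base["age_predicted"] = mean_pred.predict(records)
            base["error"] = base["age_predicted"] - base["age_true"]
            bm = compute_metrics(base)
            rows.append({"model": "mean_age", "cohort": name,
                         "mae_years": bm.mae, "mape_percent": bm.mape,
                         "r2": bm.r2, "n": bm.n})
        if config.en_baseline:
            en = fit_en_baseline(train, n_folds=config.clock_n_folds,
                                 seed=clock_seed, schema=schema)
            for name, cohort_df in [("test", test), ("discovery", discovery)]:
                X, _ = build_features(cohort_df, schema)
                ok = ~X.isna().any(axis=1)
                rec = pd.DataFrame({
                    "age_true": cohort_df.loc[ok, "chronological_age"].to_numpy(float),
                    "age_predicted": en.predict(X.loc[ok]),
                })
                em = compute_metrics(rec)
                rows.append({"model": "elastic_net", "cohort": name,
                             "mae_years": em.mae, "mape_percent": em.mape,
                             "r2": em.r2, "n": em.n})
            rows.append({"model": "elastic_net", "cohort": "cv",
                         "mae_years": en.cv_mae, "mape_percent": None,
                         "r2": None, "n": len(train)})
        table1 = pd.DataFrame(rows)
        _write_table(table1, out / "table1.tsv", header)
        metrics_doc["clock"] = {
            r["model"] + "_" + r["cohort"] + "_mae": r["mae_years"] for r in rows
        }
        completed.append(stage)
        manifest()
        if STAGES.index(stage) >= stop:
            return out

        # -- associate -------------------------------------------------
        stage = "associate"
        predictions_all = pd.concat(
            [preds["test"], preds["discovery"]], ignore_index=True
        )
        table2 = run_disease_association(
            discovery, test, predictions_all, schema,
            seed=stage_seed(config.master_seed, "associate"),
        )
        _write_table(table2, out / "table2.tsv", header)
        metrics_doc["disease_deltas_years"] = (
            dict(zip(table2["condition"], table2["delta_years"])) if len(table2) else {}
        )
        completed.append(stage)
        manifest()
        if STAGES.index(stage) >= stop:
            return out

        # -- attribute -------------------------------------------------
        stage = "attribute"
        pooled = pd.concat([train, test], ignore_index=True)
        pooled_preds = pd.concat(
            [predict_age(model, train, schema), preds["test"]], ignore_index=True
        )
        covariates = binarize_covariates(pooled, schema)
        design = build_design(pooled_preds, covariates)
        result = fit_attribution(
            design,
            n_folds=config.attribution_n_folds,
            n_seeds=config.attribution_n_seeds,
            train_fraction=config.attribution_train_fraction,
            seed=stage_seed(config.master_seed, "attribute"),
        )
        table3 = result.as_table()
        _write_table(table3, out / "table3.tsv", header)
        agg = aggregate_psych_effect(result)
        metrics_doc["attribution"] = {
            "coefficients_years": result.coefficients.round(6).to_dict(),
            "sigma_years": result.sigma.round(6).to_dict(),
            "intercept_years": result.intercept,
            "alpha": result.alpha,
            "l1_ratio": result.l1_ratio,
            "cv_mae_years": result.cv_metrics.mae,
            "test_mae_years": result.test_metrics.mae,
            "aggregate_psych_effect_years": agg,
        }
        completed.append(stage)
        manifest()
        if STAGES.index(stage) >= stop:
            return out

        # -- report ----------------------------------------------------
        stage = "report"
        if truth is not None:
            merged = preds["test"].merge(
                truth.table[["id", "latent_acceleration"]], on="id"
            )
            metrics_doc["truth_check"] = {
                "corr_error_vs_latent_acceleration": float(
                    np.corrcoef(merged["error"], merged["latent_acceleration"])[0, 1]
                )
            }
        err = pd.concat([p.assign(cohort=k) for k, p in preds.items()])
        summary = (
            err.groupby("cohort")["error"]
            .describe()[["count", "mean", "std", "25%", "50%", "75%"]]
            .reset_index()
        )
        _write_table(summary, out / "error_summary.tsv", header)
        with open(out / "metrics.json", "w", encoding="utf-8") as fh:
            json.dump(metrics_doc, fh, indent=2, default=float)
        completed.append(stage)
        manifest()
        return out
    except Exception as exc:  # noqa: BLE001 - reported with stage context
        manifest()
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc
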