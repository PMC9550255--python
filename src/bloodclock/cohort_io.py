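"""Cohort table I/O, exclusion filtering, binarization and set assignment.

A cohort is a plain CSV (UTF-8, header row mandatory, missing cells empty
or ``NA``) with one row per participant and columns declared by a
:class:`~bloodclock.schema.VariableSchema`. This module covers the data
hygiene stages that precede modelling:

* :func:`load_cohort` — typed, schema-checked reading with a load report;
* :func:`average_repeated_biometrics` — collapse repeated biometric
  readings (``name__1``, ``name__2``, ...) to their per-participant mean;
* :func:`exclude_invalid` — drop rows with missing sex, missing or
  physiologically out-of-range predictors, or extreme within-column
  z-scores, with a per-rule exclusion log;
* :func:`binarize_covariates` — map raw covariates to the 13 binary
  indicators of the attribution design;
* :func:`assign_sets` — the train/test/discovery partition: any serious
  condition routes to discovery, milder conditions to test, and healthy
  participants are split between train and test at a seeded fraction.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import INDICATOR_ORDER, SchemaError, VariableSchema, default_schema

__all__ = [
    "LoadReport",
    "SplitAssignment",
    "InputError",
    "load_cohort",
    "write_cohort",
    "average_repeated_biometrics",
    "exclude_invalid",
    "binarize_covariates",
    "assign_sets",
]

logger = logging.getLogger(__name__)

NA_VALUES = ["", "NA", "na", "NaN", "nan"]


class InputError(ValueError):
    """Malformed or unusable input data."""


@dataclass
class LoadReport:
    """Bookkeeping from one :func:`load_cohort` call."""

    n_rows: int = 0
    unparseable_cells: dict[str, int] = field(default_factory=dict)
    ignored_columns: list[str] = field(default_factory=list)

    @property
    def n_unparseable(self) -> int:
        return sum(self.unparseable_cells.values())


def load_cohort(
    path: str | Path, schema: VariableSchema | None = None
) -> tuple[pd.DataFrame, LoadReport]:
    """Read a cohort CSV against a schema.

    Unknown columns are dropped with a warning; unparseable numeric cells
    become missing values and are counted in the returned report. A
    missing mandatory column raises :class:`SchemaError`; an empty file
    raises :class:`InputError`.
    """
    schema = schema or default_schema()
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=str, na_values=NA_VALUES, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise InputError(f"{path} is empty") from None
    if raw.empty and raw.columns.empty:
        raise InputError(f"{path} is empty")

    missing = [c for c in schema.column_order if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path} lacks mandatory columns: {missing}")

    report = LoadReport(n_rows=len(raw))
    extra = [c for c in raw.columns if c not in schema]
    if extra:
        report.ignored_columns = extra
        logger.warning("ignoring %d unknown column(s): %s", len(extra), extra)

    table = pd.DataFrame(index=raw.index)
    for name in schema.column_order:
        var = schema[name]
        col = raw[name]
        if var.kind in ("continuous", "ordinal", "binary"):
            parsed = pd.to_numeric(col, errors="coerce")
            bad = int((parsed.isna() & col.notna()).sum())
            if bad:
                report.unparseable_cells[name] = bad
            table[name] = parsed
        else:
            table[name] = col
    return table, report


def write_cohort(
    cohort: pd.DataFrame, path: str | Path, schema: VariableSchema | None = None
) -> None:
    """Write a cohort CSV in canonical column order."""
    schema = schema or default_schema()
    cols = [c for c in schema.column_order if c in cohort.columns]
    cohort[cols].to_csv(path, index=False, na_rep="NA")


_REPEAT_RE = re.compile(r"^(?P<base>.+)__(?P<k>\d+)$")


def average_repeated_biometrics(
    raw: pd.DataFrame, schema: VariableSchema | None = None
) -> pd.DataFrame:
    """Collapse repeated measurement columns to per-participant means.

    Repeats are tagged ``<variable>__<k>`` (e.g. ``systolic_bp__1``,
    ``systolic_bp__2``). The mean is taken over non-missing repeats; if
    every repeat is missing the result is missing. Variables without
    repeat columns pass through unchanged.
    """
    schema = schema or default_schema()
    groups: dict[str, list[str]] = {}
    for col in raw.columns:
        m = _REPEAT_RE.match(col)
        if m and m.group("base") in schema:
            groups.setdefault(m.group("base"), []).append(col)

    out = raw.drop(columns=[c for cols in groups.values() for c in cols]).copy()
    for base, cols in groups.items():
        vals = raw[cols].apply(pd.to_numeric, errors="coerce")
        out[base] = vals.mean(axis=1, skipna=True)
    return out


def exclude_invalid(
    cohort: pd.DataFrame,
    schema: VariableSchema | None = None,
    z_threshold: float | None = 5.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the exclusion rules; return (surviving cohort, exclusion log).

    Rules, in order of reporting priority per row:

    1. ``missing_sex`` — sex not recorded;
    2. ``missing_predictor:<var>`` — a clock predictor is missing;
    3. ``out_of_range:<var>`` — a predictor outside its schema range;
    4. ``outlier_z:<var>`` — |z| > ``z_threshold`` within a continuous
       predictor column (fallback outlier screen; disable with ``None``).

    The log has one row per excluded participant (``id``, ``reason``).
    An empty surviving cohort is returned as such, not raised.
    """
    schema = schema or default_schema()
    reasons = pd.Series("", index=cohort.index, dtype=object)

    def flag(mask: pd.Series, reason: str) -> None:
        fresh = mask & (reasons == "")
        reasons[fresh] = reason

    flag(cohort["sex"].isna(), "missing_sex")
    for name in schema.predictor_names:
        if name == "sex":
            continue
        flag(cohort[name].isna(), f"missing_predictor:{name}")
    for name in schema.predictor_names:
        var = schema[name]
        if var.range is None:
            continue
        low, high = var.range
        col = cohort[name]
        flag(col.notna() & ((col < low) | (col > high)), f"out_of_range:{name}")
    if z_threshold is not None:
        for name in schema.continuous_predictors:
            col = pd.to_numeric(cohort[name], errors="coerce")
            ok = col.notna() & (reasons == "")
            sd = col[ok].std(ddof=0)
            if not np.isfinite(sd) or sd == 0:
                continue
            z = (col - col[ok].mean()) / sd
            flag(ok & (z.abs() > z_threshold), f"outlier_z:{name}")

    excluded = reasons != ""
    log = pd.DataFrame(
        {"id": cohort.loc[excluded, "id"], "reason": reasons[excluded]}
    ).reset_index(drop=True)
    if excluded.any():
        counts = log["reason"].value_counts()
        logger.info("excluded %d row(s): %s", excluded.sum(), counts.to_dict())
    return cohort.loc[~excluded].reset_index(drop=True), log


def binarize_covariates(
    cohort: pd.DataFrame, schema: VariableSchema | None = None
) -> pd.DataFrame:
    """Derive the 13 binary indicators of the attribution design.

    ``is_male`` from sex; ``is_married``/``is_widowed`` from marital
    status (never-married is the reference with both zero); ``is_rural``
    from living area; ``currently_smoking`` from the smoking flag; and one
    "rarely ..." indicator per psychological frequency item, equal to 1
    iff the reported frequency is the lowest level (< 1 day / week).

    Raises :class:`SchemaError` naming any unknown categorical level.
    """
    schema = schema or default_schema()
    for name in ("sex", "area", "marital_status"):
        levels = set(schema[name].levels or ())
        seen = set(cohort[name].dropna().unique())
        bad = seen - levels
        if bad:
            raise SchemaError(f"{name}: unknown level(s) {sorted(bad)}")
    for item in schema.psych_items:
        seen = set(cohort[item].dropna().unique())
        bad = {s for s in seen if int(s) not in (schema[item].levels or ())}
        if bad:
            raise SchemaError(f"{item}: unknown level(s) {sorted(bad)}")

    out = pd.DataFrame({"id": cohort["id"]})
    out["is_male"] = (cohort["sex"] == "male").astype(int)
    out["is_married"] = (cohort["marital_status"] == "married").astype(int)
    out["is_widowed"] = (cohort["marital_status"] == "widowed").astype(int)
    out["is_rural"] = (cohort["area"] == "rural").astype(int)
    out["currently_smoking"] = (
        pd.to_numeric(cohort["smoking"], errors="coerce") > 0
    ).astype(int)
    for item in schema.psych_items:
        out[schema.indicator_for(item)] = (
            pd.to_numeric(cohort[item], errors="coerce") == 0
        ).astype(int)
    return out[["id", *INDICATOR_ORDER]]


@dataclass
class SplitAssignment:
    """Per-participant train / test / discovery / excluded labels."""

    table: pd.DataFrame  # columns: id, label, reason

    def counts(self) -> dict[str, int]:
        return self.table["label"].value_counts().to_dict()

    def ids(self, label: str) -> list:
        return self.table.loc[self.table["label"] == label, "id"].tolist()

    def subset(self, cohort: pd.DataFrame, label: str) -> pd.DataFrame:
        keep = set(self.ids(label))
        return cohort[cohort["id"].isin(keep)].reset_index(drop=True)


def assign_sets(
    cohort: pd.DataFrame,
    schema: VariableSchema | None = None,
    train_fraction_healthy: float = 0.66,
    seed: int = 0,
    excluded: pd.DataFrame | None = None,
) -> SplitAssignment:
    """Partition a (post-exclusion) cohort into train / test / discovery.

    * discovery — any history of a serious condition (cancer, heart
      disease, stroke, lung disease, liver disease);
    * test — no serious condition but any milder tracked condition
      (hypertension, arthritis, dyslipidemia, kidney disease, diabetes);
    * train / test — fully healthy participants, split by a seeded draw
      at ``train_fraction_healthy``.

    ``excluded`` may carry the exclusion log so excluded participants are
    labelled in the same assignment table.
    """
    schema = schema or default_schema()
    if not 0.0 <= train_fraction_healthy <= 1.0:
        raise InputError("train_fraction_healthy must lie in [0, 1]")
    serious = cohort[schema.serious_conditions].to_numpy(dtype=float).sum(axis=1) > 0
    mild = cohort[schema.mild_conditions].to_numpy(dtype=float).sum(axis=1) > 0

    rng = np.random.default_rng(seed)
    to_train = rng.random(len(cohort)) < train_fraction_healthy
    label = np.where(
        serious, "discovery", np.where(mild, "test", np.where(to_train, "train", "test"))
    )
    table = pd.DataFrame({"id": cohort["id"], "label": label, "reason": ""})
    if excluded is not None and len(excluded):
        table = pd.concat(
            [
                table,
                pd.DataFrame(
                    {
                        "id": excluded["id"],
                        "label": "excluded",
                        "reason": excluded["reason"],
                    }
                ),
            ],
            ignore_index=True,
        )
    return SplitAssignment(table=table)
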