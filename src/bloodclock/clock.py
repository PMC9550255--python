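"""The aging clock: training, evaluation, baselines, feature importance.

The clock is a feed-forward regressor of chronological age on 24
predictors (16 blood panel variables, sex, a fasting flag, 6 biometric
variables). Features are min-max scaled to [0, 1] on the training set
(values outside the training range extrapolate linearly and are *not*
clipped); the network minimizes mean absolute error and is trained with
five-fold cross-validation plus a final refit on all training rows, which
is the model used for all downstream "biological age" predictions.

Evaluation uses three metrics, all computed with population variance:

    MAE  = (1/N) Σ |age_true − age_pred|                     [years]
    MAPE = (100/N) Σ |age_true − age_pred| / age_true        [percent]
    R²   = 1 − Σ error² / (N · Var(age_true))

Baselines: constant mean-age assignment and an elastic net selected by
cross-validated grid search over alpha ∈ {1e-5, 1e-4, 1e-3, 1e-2, 1e-1,
0, 1, 10, 100} × l1_ratio ∈ {0.00, 0.01, ..., 0.99}. Permutation feature
importance is the change in MAE when one feature column is shuffled.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.linear_model import ElasticNet, LinearRegression
from sklearn.model_selection import KFold

from .nn import MAENetRegressor
from .schema import VariableSchema, default_schema

__all__ = [
    "ClockHyperparams",
    "ScalerParams",
    "ClockModel",
    "Metrics",
    "EN_ALPHA_GRID",
    "EN_L1_RATIO_GRID",
    "fit_scaler",
    "apply_scaler",
    "build_features",
    "train_clock",
    "grid_search",
    "predict_age",
    "compute_metrics",
    "mean_age_baseline",
    "fit_en_baseline",
    "permutation_importance",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

#: Elastic-net hyperparameter grid shared by the clock baseline and the
#: attribution stage.
EN_ALPHA_GRID: tuple[float, ...] = (1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 0.0, 1.0, 10.0, 100.0)
EN_L1_RATIO_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.0, 0.01), 2))


@dataclass(frozen=True)
class ClockHyperparams:
    """Network and training hyperparameters for the aging clock."""

    n_hidden_layers: int = 5
    units_per_layer: int = 256
    activation: str = "elu"
    dropout_rate: float = 0.35
    l2_coefficient: float = 1e-5
    loss: str = "mae"  # fixed: the clock's objective is mean absolute error
    max_epochs: int = 500
    patience: int = 20
    learning_rate: float = 1.5e-3
    batch_size: int = 128
    val_fraction: float = 0.1

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.l2_coefficient < 0:
            raise ValueError("l2_coefficient must be >= 0")
        if self.n_hidden_layers < 1 or self.units_per_layer < 1:
            raise ValueError("layers and units must be >= 1")
        if self.loss != "mae":
            raise ValueError("only the 'mae' objective is supported")

    def n_parameters(self, n_features: int = 24) -> int:
        dims = [n_features] + [self.units_per_layer] * self.n_hidden_layers + [1]
        return sum(a * b + b for a, b in zip(dims[:-1], dims[1:]))

    def make_net(self, seed: int) -> MAENetRegressor:
        return MAENetRegressor(
            hidden_layers=self.n_hidden_layers,
            units=self.units_per_layer,
            dropout=self.dropout_rate,
            l2=self.l2_coefficient,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
            val_fraction=self.val_fraction,
            seed=seed,
        )


@dataclass
class ScalerParams:
    """Per-feature training min/max for [0, 1] scaling."""

    feature_names: list[str]
    min_: np.ndarray
    max_: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.max_ < self.min_):
            raise ValueError("scaler max must be >= min per feature")


def build_features(
    cohort: pd.DataFrame, schema: VariableSchema | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Assemble the 24-column numeric predictor matrix from a cohort table.

    ``sex`` enters as a 0/1 male indicator; all other predictors are used
    as-is. Returns (matrix indexed like ``cohort``, feature names).
    """
    schema = schema or default_schema()
    cols = {}
    for name in schema.predictor_names:
        if name == "sex":
            sex = cohort["sex"]
            cols["sex"] = (sex == "male").astype(float).where(sex.notna())
        else:
            cols[name] = pd.to_numeric(cohort[name], errors="coerce")
    X = pd.DataFrame(cols, index=cohort.index)
    return X, list(X.columns)


def fit_scaler(train: pd.DataFrame) -> ScalerParams:
    """Fit per-feature min/max on training predictors.

    A constant feature (max == min) is mapped to 0 everywhere, with a
    warning — it carries no information but must not produce NaNs.
    """
    if len(train) < 2:
        raise ValueError("need at least 2 training rows to fit the scaler")
    min_ = train.min(axis=0).to_numpy(dtype=float)
    max_ = train.max(axis=0).to_numpy(dtype=float)
    constant = max_ == min_
    if constant.any():
        names = [c for c, flag in zip(train.columns, constant) if flag]
        logger.warning("constant training feature(s) mapped to 0: %s", names)
    return ScalerParams(feature_names=list(train.columns), min_=min_, max_=max_)


def apply_scaler(params: ScalerParams, X: pd.DataFrame) -> np.ndarray:
    """Scale features to the training [0, 1] range (no clipping)."""
    arr = X[params.feature_names].to_numpy(dtype=float)
    denom = params.max_ - params.min_
    out = np.zeros_like(arr)
    ok = denom > 0
    out[:, ok] = (arr[:, ok] - params.min_[ok]) / denom[ok]
    return out


@dataclass
class ClockModel:
    """A fitted aging clock: network + scaler + provenance."""

    net: MAENetRegressor
    scaler: ScalerParams
    hyperparams: ClockHyperparams
    feature_names: list[str]
    seed: int
    fold_assignment: pd.Series | None = None  # id -> CV fold of the training run

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.net.predict(apply_scaler(self.scaler, X))


def _stage_seed(master: int, stage: int) -> int:
    """Derive a per-stage seed below 2**31 from a master seed."""
    return int(np.random.SeedSequence([master, stage]).generate_state(1)[0] % (2**31))


def train_clock(
    train: pd.DataFrame,
    hp: ClockHyperparams | None = None,
    n_folds: int = 5,
    seed: int = 0,
    schema: VariableSchema | None = None,
    refit: bool = True,
) -> tuple[ClockModel | None, pd.DataFrame]:
    """Train the clock with K-fold cross-validation.

    For each fold the network is fitted on the remaining folds (with its
    own internal validation split for early stopping) and predicts the
    held-out fold, yielding out-of-fold CV prediction records. A final
    model is then refitted on all training rows (skipped if ``refit`` is
    False, in which case the first return value is None).

    Returns (model, cv_records) where cv_records has columns
    ``id, age_true, age_predicted, error, fold``.
    """
    schema = schema or default_schema()
    hp = hp or ClockHyperparams()
    if len(train) < 10 * n_folds:
        raise ValueError(f"need at least {10 * n_folds} rows for {n_folds}-fold CV")
    X, feature_names = build_features(train, schema)
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"training predictors contain missing values: {bad}")
    y = train["chronological_age"].to_numpy(dtype=float)

    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**31))
    records = []
    fold_of = pd.Series(index=train["id"].to_numpy(), dtype=int)
    for fold, (tr_idx, te_idx) in enumerate(kf.split(X)):
        scaler = fit_scaler(X.iloc[tr_idx])
        net = hp.make_net(seed=_stage_seed(seed, 100 + fold))
        net.fit(apply_scaler(scaler, X.iloc[tr_idx]), y[tr_idx])
        pred = net.predict(apply_scaler(scaler, X.iloc[te_idx]))
        ids = train["id"].to_numpy()[te_idx]
        fold_of[ids] = fold
        records.append(
            pd.DataFrame(
                {
                    "id": ids,
                    "age_true": y[te_idx],
                    "age_predicted": pred,
                    "error": pred - y[te_idx],
                    "fold": fold,
                }
            )
        )
    cv_records = pd.concat(records, ignore_index=True)

    model = None
    if refit:
        scaler = fit_scaler(X)
        net = hp.make_net(seed=_stage_seed(seed, 999))
        net.fit(apply_scaler(scaler, X), y)
        model = ClockModel(
            net=net,
            scaler=scaler,
            hyperparams=hp,
            feature_names=feature_names,
            seed=seed,
            fold_assignment=fold_of,
        )
    return model, cv_records


def grid_search(
    train: pd.DataFrame,
    grid: list[ClockHyperparams],
    n_folds: int = 5,
    seed: int = 0,
    schema: VariableSchema | None = None,
) -> tuple[ClockHyperparams, pd.DataFrame]:
    """Pick the grid point with the lowest mean CV MAE.

    Ties are broken by smaller parameter count, then grid order. Returns
    (best hyperparameters, per-point results table).
    """
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    rows = []
    for order, hp in enumerate(grid):
        _, cv = train_clock(train, hp, n_folds=n_folds, seed=seed, schema=schema, refit=False)
        mae = float(np.mean(np.abs(cv["error"])))
        rows.append(
            {"order": order, "cv_mae": mae, "n_parameters": hp.n_parameters(), "hp": hp}
        )
    results = pd.DataFrame(rows)
    best = results.sort_values(["cv_mae", "n_parameters", "order"]).iloc[0]
    return best["hp"], results.drop(columns="hp")


def predict_age(
    model: ClockModel, cohort: pd.DataFrame, schema: VariableSchema | None = None
) -> pd.DataFrame:
    """Predict biological age for every complete row of a cohort.

    Rows with any missing predictor are skipped and logged. Returns
    records with ``id, age_true, age_predicted, error`` where
    ``error = age_predicted − age_true`` (the age-acceleration estimate).
    """
    schema = schema or default_schema()
    X, _ = build_features(cohort, schema)
    complete = ~X.isna().any(axis=1)
    if (~complete).any():
        skipped = cohort.loc[~complete, "id"].tolist()
        logger.warning("skipping %d row(s) with missing predictors: %s",
                       len(skipped), skipped[:10])
    pred = model.predict(X.loc[complete])
    age = cohort.loc[complete, "chronological_age"].to_numpy(dtype=float)
    return pd.DataFrame(
        {
            "id": cohort.loc[complete, "id"].to_numpy(),
            "age_true": age,
            "age_predicted": pred,
            "error": pred - age,
        }
    )


@dataclass(frozen=True)
class Metrics:
    """MAE (years), MAPE (percent), R² (population-variance form), N."""

    mae: float
    mape: float
    r2: float | None
    n: int


def compute_metrics(records: pd.DataFrame) -> Metrics:
    """Compute MAE / MAPE / R² from prediction records.

    R² uses the population variance of ``age_true`` (R² = 1 − Σe²/(N·D)),
    so a constant prediction at the mean of the truths scores exactly 0.
    With zero variance in the truths R² is undefined and reported as None.
    """
    if len(records) == 0:
        raise ValueError("no prediction records")
    truth = records["age_true"].to_numpy(dtype=float)
    pred = records["age_predicted"].to_numpy(dtype=float)
    if np.any(truth <= 0):
        raise ValueError("MAPE requires strictly positive true ages")
    err = pred - truth
    n = len(truth)
    mae = float(np.mean(np.abs(err)))
    mape = float(100.0 * np.mean(np.abs(err) / truth))
    d = float(np.var(truth))  # population variance
    r2 = None if d == 0 else float(1.0 - np.sum(err**2) / (n * d))
    return Metrics(mae=mae, mape=mape, r2=r2, n=n)


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------


@dataclass
class MeanAgePredictor:
    """Constant predictor: the training-set mean age for every row."""

    mean_age: float

    def predict(self, X) -> np.ndarray:
        return np.full(len(X), self.mean_age)


def mean_age_baseline(train: pd.DataFrame) -> MeanAgePredictor:
    return MeanAgePredictor(mean_age=float(train["chronological_age"].mean()))


@dataclass
class ENBaseline:
    """Elastic-net age regressor on the scaled clock features."""

    model: object  # ElasticNet or LinearRegression (alpha = 0)
    scaler: ScalerParams
    alpha: float
    l1_ratio: float
    cv_mae: float

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.model.predict(apply_scaler(self.scaler, X))


def _make_en(alpha: float, l1_ratio: float, seed: int):
    if alpha == 0.0:
        return LinearRegression()
    return ElasticNet(
        alpha=alpha, l1_ratio=l1_ratio, max_iter=5000, tol=1e-4,
        random_state=seed % (2**31),
    )


def en_grid_search(
    X: np.ndarray,
    y: np.ndarray,
    alphas=EN_ALPHA_GRID,
    l1_ratios=EN_L1_RATIO_GRID,
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[float, float, float]:
    """CV grid search for elastic-net hyperparameters, scored by MAE.

    Returns (alpha, l1_ratio, cv_mae) of the best point; ties go to the
    earlier grid point (alphas outer, l1_ratios inner).
    """
    import warnings

    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**31))
    folds = list(kf.split(X))
    best = (np.inf, 0, None, None)
    for ai, alpha in enumerate(alphas):
        for li, l1 in enumerate(l1_ratios):
            abs_err = 0.0
            for tr, te in folds:
                est = _make_en(alpha, l1, seed)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est.fit(X[tr], y[tr])
                abs_err += float(np.abs(est.predict(X[te]) - y[te]).sum())
            mae = abs_err / len(X)
            key = (mae, ai * len(l1_ratios) + li)
            if key < best[:2]:
                best = (mae, key[1], alpha, l1)
            if alpha == 0.0:
                break  # l1_ratio is irrelevant at alpha = 0
    return best[2], best[3], best[0]


def fit_en_baseline(
    train: pd.DataFrame,
    alphas=EN_ALPHA_GRID,
    l1_ratios=EN_L1_RATIO_GRID,
    n_folds: int = 5,
    seed: int = 0,
    schema: VariableSchema | None = None,
) -> ENBaseline:
    """Fit the elastic-net clock baseline with CV hyperparameter selection."""
    import warnings

    schema = schema or default_schema()
    Xdf, _ = build_features(train, schema)
    scaler = fit_scaler(Xdf)
    X = apply_scaler(scaler, Xdf)
    y = train["chronological_age"].to_numpy(dtype=float)
    alpha, l1, cv_mae = en_grid_search(X, y, alphas, l1_ratios, n_folds, seed)
    est = _make_en(alpha, l1, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X, y)
    return ENBaseline(model=est, scaler=scaler, alpha=alpha, l1_ratio=l1, cv_mae=cv_mae)


# ---------------------------------------------------------------------------
# permutation feature importance
# ---------------------------------------------------------------------------


def permutation_importance(
    model: ClockModel,
    cohort: pd.DataFrame,
    n_repeats: int = 5,
    seed: int = 0,
    schema: VariableSchema | None = None,
) -> pd.DataFrame:
    """Permutation feature importance in years of MAE.

    For each feature, ΔMAE = mean over repeats of (MAE with that column
    shuffled) − (baseline MAE). Informative features have positive ΔMAE.
    Returns a table sorted by decreasing ΔMAE.
    """
    schema = schema or default_schema()
    if len(cohort) < 20:
        raise ValueError("need at least 20 rows for permutation importance")
    X, names = build_features(cohort, schema)
    X = X.loc[~X.isna().any(axis=1)]
    y = cohort.set_index(cohort.index)["chronological_age"].loc[X.index].to_numpy(float)
    base_mae = float(np.mean(np.abs(model.predict(X) - y)))
    rng = np.random.default_rng(seed)
    rows = []
    for name in names:
        deltas = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[name] = rng.permutation(Xp[name].to_numpy())
            mae = float(np.mean(np.abs(model.predict(Xp) - y)))
            deltas.append(mae - base_mae)
        rows.append(
            {
                "feature": name,
                "delta_mae": float(np.mean(deltas)),
                "delta_mae_sd": float(np.std(deltas)),
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("delta_mae", ascending=False)
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# model bundle (de)serialization
# ---------------------------------------------------------------------------


def save_model(model: ClockModel, directory: str | Path) -> None:
    """Serialize a clock to a directory (weights, scaler, hyperparams, seed)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "weights.npz", **model.net.get_params_arrays())
    pd.DataFrame(
        {
            "feature": model.scaler.feature_names,
            "min": model.scaler.min_,
            "max": model.scaler.max_,
        }
    ).to_csv(directory / "scaler.csv", index=False)
    with open(directory / "hyperparams.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(
            {"hyperparams": dataclasses.asdict(model.hyperparams), "seed": model.seed},
            fh,
            sort_keys=False,
        )


def load_model(directory: str | Path) -> ClockModel:
    directory = Path(directory)
    with open(directory / "hyperparams.yaml", "r", encoding="utf-8") as fh:
        meta = yaml.safe_load(fh)
    hp = ClockHyperparams(**meta["hyperparams"])
    scaler_df = pd.read_csv(directory / "scaler.csv")
    scaler = ScalerParams(
        feature_names=scaler_df["feature"].tolist(),
        min_=scaler_df["min"].to_numpy(dtype=float),
        max_=scaler_df["max"].to_numpy(dtype=float),
    )
    net = hp.make_net(seed=meta["seed"])
    with np.load(directory / "weights.npz") as arrays:
        net.set_params_arrays(dict(arrays))
    return ClockModel(
        net=net,
        scaler=scaler,
        hyperparams=hp,
        feature_names=scaler.feature_names,
        seed=meta["seed"],
    )
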