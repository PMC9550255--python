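"""Attribution of biological age to demographic/psychosocial factors.

The clock's predicted ("biological") age is regressed, with an elastic
net, on chronological age plus 13 binary indicators: sex, marital status
(married / widowed, never-married as reference), rural living, current
smoking, and eight "rarely ..." psychological indicators. Because every
indicator is binary, each coefficient reads directly as years of age
acceleration attributable to that factor; the clock's blood/biometric
inputs are deliberately excluded from the design since they are
implicitly present in the target itself.

Hyperparameters come from a cross-validated grid search (shared grid with
the clock's elastic-net baseline). Coefficient uncertainty (σ) is the
standard deviation over ten seeded iterations, each redoing the 70/30
train/test re-split of the pooled clock train ∪ test participants and
refitting at the selected hyperparameters; the reported coefficient is
the mean over those iterations.

The aggregate psychological effect is the sum of absolute coefficients
over the eight psychological indicators — the spread, in years, between
the most and least favourable configuration of each indicator, summed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, train_test_split

from .clock import (
    EN_ALPHA_GRID,
    EN_L1_RATIO_GRID,
    Metrics,
    _make_en,
    compute_metrics,
    en_grid_search,
)
from .cohort_io import InputError
from .schema import INDICATOR_ORDER, PSYCH_INDICATORS

__all__ = [
    "AttributionResult",
    "build_design",
    "fit_attribution",
    "aggregate_psych_effect",
]

logger = logging.getLogger(__name__)


def build_design(
    predictions: pd.DataFrame, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Inner-join predictions with binary covariates into a design table.

    ``predictions`` supplies chronological age (``age_true``) and the
    target (``age_predicted``); ``covariates`` supplies the 13 binary
    indicators keyed by ``id``. Rows with any missing covariate are
    dropped and counted; an empty join raises :class:`InputError`.
    """
    missing_ind = [c for c in INDICATOR_ORDER if c not in covariates.columns]
    if missing_ind:
        raise InputError(f"covariates lack indicator(s): {missing_ind}")
    merged = predictions[["id", "age_true", "age_predicted"]].merge(
        covariates[["id", *INDICATOR_ORDER]], on="id", how="inner"
    )
    if merged.empty:
        raise InputError("predictions and covariates share no ids")
    before = len(merged)
    merged = merged.dropna()
    dropped = before - len(merged)
    if dropped:
        logger.warning("dropped %d design row(s) with missing covariates", dropped)
    design = merged.rename(
        columns={"age_true": "chronological_age", "age_predicted": "biological_age"}
    )
    return design.reset_index(drop=True)


@dataclass
class AttributionResult:
    """Coefficients (years), cross-seed σ, and fit metrics."""

    coefficients: pd.Series  # mean over seeded iterations, by variable
    sigma: pd.Series  # SD over seeded iterations
    intercept: float
    intercept_sigma: float
    alpha: float
    l1_ratio: float
    cv_metrics: Metrics
    test_metrics: Metrics
    n_train: int
    n_test: int
    dropped_columns: list[str] = field(default_factory=list)
    per_seed: pd.DataFrame | None = None

    def as_table(self) -> pd.DataFrame:
        """Report table: variable, coefficient, σ, |β| > 2σ flag."""
        return pd.DataFrame(
            {
                "variable": self.coefficients.index,
                "coefficient_years": self.coefficients.to_numpy(),
                "sigma_years": self.sigma.to_numpy(),
                "abs_coef_gt_2sigma": (
                    self.coefficients.abs() > 2 * self.sigma
                ).to_numpy(),
            }
        )


def _design_matrix(design: pd.DataFrame, variables: list[str]):
    X = design[variables].to_numpy(dtype=float)
    y = design["biological_age"].to_numpy(dtype=float)
    return X, y


def fit_attribution(
    design: pd.DataFrame,
    alphas=EN_ALPHA_GRID,
    l1_ratios=EN_L1_RATIO_GRID,
    n_folds: int = 10,
    n_seeds: int = 10,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> AttributionResult:
    """Fit the attribution elastic net (see module docstring).

    The design is re-split ``train_fraction`` / (1 − ``train_fraction``);
    hyperparameters are selected once by ``n_folds``-fold CV grid search
    on the primary split's training part, then ``n_seeds`` seeded
    iterations redo the re-split and refit. Constant columns are dropped
    with a warning.
    """
    import warnings

    if len(design) < 10 * n_folds:
        raise InputError(f"need at least {10 * n_folds} design rows")
    variables = ["chronological_age"] + [
        c for c in INDICATOR_ORDER if c in design.columns
    ]
    dropped = [v for v in variables if design[v].nunique() <= 1]
    if dropped:
        logger.warning("dropping constant design column(s): %s", dropped)
        variables = [v for v in variables if v not in dropped]

    rng = np.random.SeedSequence([int(seed), 7])
    split_seeds = [int(s % (2**31)) for s in rng.generate_state(n_seeds + 1)]

    # primary split: hyperparameter selection + reported metrics
    train, test = train_test_split(
        design, train_size=train_fraction, random_state=split_seeds[0], shuffle=True
    )
    Xtr, ytr = _design_matrix(train, variables)
    Xte, yte = _design_matrix(test, variables)
    alpha, l1, _ = en_grid_search(Xtr, ytr, alphas, l1_ratios, n_folds, split_seeds[0])

    # CV metrics: out-of-fold predictions on the primary training part
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=split_seeds[0])
    oof = np.empty(len(ytr))
    for tr, te in kf.split(Xtr):
        est = _make_en(alpha, l1, split_seeds[0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(Xtr[tr], ytr[tr])
        oof[te] = est.predict(Xtr[te])
    cv_metrics = compute_metrics(
        pd.DataFrame({"age_true": ytr, "age_predicted": oof})
    )
    primary = _make_en(alpha, l1, split_seeds[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        primary.fit(Xtr, ytr)
    test_metrics = compute_metrics(
        pd.DataFrame({"age_true": yte, "age_predicted": primary.predict(Xte)})
    )

    # seeded iterations: re-split + refit at the selected hyperparameters
    rows = []
    for s in split_seeds[1:]:
        tr_s, _ = train_test_split(
            design, train_size=train_fraction, random_state=s, shuffle=True
        )
        Xs, ys = _design_matrix(tr_s, variables)
        est = _make_en(alpha, l1, s)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(Xs, ys)
        rows.append(
            {"seed": s, "intercept": float(est.intercept_),
             **dict(zip(variables, est.coef_))}
        )
    per_seed = pd.DataFrame(rows)
    coef_mean = per_seed[variables].mean()
    coef_sd = per_seed[variables].std(ddof=0)

    return AttributionResult(
        coefficients=coef_mean,
        sigma=coef_sd,
        intercept=float(per_seed["intercept"].mean()),
        intercept_sigma=float(per_seed["intercept"].std(ddof=0)),
        alpha=alpha,
        l1_ratio=l1,
        cv_metrics=cv_metrics,
        test_metrics=test_metrics,
        n_train=len(train),
        n_test=len(test),
        dropped_columns=dropped,
        per_seed=per_seed,
    )


def aggregate_psych_effect(
    result: AttributionResult | dict | pd.Series,
    psych_variables: tuple[str, ...] = PSYCH_INDICATORS,
) -> float:
    """Sum of |coefficient| over the psychological indicators, in years.

    Each binary indicator spans |β| years between its favourable and
    unfavourable value, so the sum is the total spread attributable to
    psychological state. Raises :class:`InputError` if any psychological
    coefficient is absent.
    """
    if isinstance(result, AttributionResult):
        coefs = result.coefficients
    else:
        coefs = pd.Series(result)
    missing = [v for v in psych_variables if v not in coefs.index]
    if missing:
        raise InputError(f"missing psychological coefficient(s): {missing}")
    return float(coefs.loc[list(psych_variables)].abs().sum())
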