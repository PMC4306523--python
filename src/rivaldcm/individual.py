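"""Individual differences: modulatory-coupling differences vs dominance duration.

For each subject the winning model's B parameters under the rivalry-switch
and replay-switch inputs are differenced (rivalry minus replay) on the four
modulable connections, and the resulting dB values enter a multiple linear
regression predicting the subject's mean percept dominance duration.
Influential subjects are removed in a single pass by Cook's distance > 1
computed on the full sample, and the model is refit on the retained
subjects; the report carries unstandardized and standardized coefficients,
R^2, adjusted R^2, the F test and both sets of distances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .inversion import PosteriorFit
from .model_space import DEFAULT_REGIONS, MODULABLE_CONNECTIONS, Connection

__all__ = [
    "DELTA_B_COLUMNS",
    "RegressionReport",
    "DominanceRegression",
    "compute_delta_b",
    "cooks_distance",
    "fit_dominance_regression",
]

DELTA_B_COLUMNS = [f"delta_b[{c}]" for c in MODULABLE_CONNECTIONS]
OUTCOME_COLUMN = "mean_duration_s"


def compute_delta_b(
    fits: Mapping[str, PosteriorFit],
    mean_durations: Mapping[str, float],
    connections: Sequence[Connection] = MODULABLE_CONNECTIONS,
) -> pd.DataFrame:
    """Per-subject B(rivalry) - B(replay) on the modulated connections.

    ``fits`` maps subject id to the winning-model posterior (which carries
    both switch conditions' B matrices); ``mean_durations`` maps subject id
    to the behavioral outcome. Raises if a subject lacks either piece.
    """
    if not connections:
        raise ValueError("need at least one modulated connection")
    rows = []
    for subj, fit in fits.items():
        if subj not in mean_durations:
            raise ValueError(f"no mean dominance duration for subject {subj}")
        b_riv = fit.b_matrix("rivalry_switch")
        b_rep = fit.b_matrix("replay_switch")
        row: dict = {"subject": subj}
        for conn in connections:
            i = DEFAULT_REGIONS.index(conn.target)
            j = DEFAULT_REGIONS.index(conn.source)
            row[f"delta_b[{conn}]"] = b_riv[i, j] - b_rep[i, j]
        row[OUTCOME_COLUMN] = mean_durations[subj]
        rows.append(row)
    return pd.DataFrame(rows)


def cooks_distance(y, X) -> np.ndarray:
    """Cook's distance D_i for each observation of an OLS fit.

    D_i = (standardized residual_i^2 / p) * h_i / (1 - h_i), with h_i the
    hat-matrix leverage and p the number of fitted coefficients (X is used
    as given; include the intercept column yourself if wanted).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than coefficients")
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("singular predictor matrix")
    H = X @ np.linalg.solve(X.T @ X, X.T)
    h = np.diag(H)
    resid = y - H @ y
    s2 = float(resid @ resid) / (n - p)
    r2_std = resid ** 2 / (s2 * (1.0 - h))
    return (r2_std / p) * (h / (1.0 - h))


@dataclass
class RegressionReport:
    """dB -> dominance-duration regression summary with exclusions."""

    predictors: list[str]
    coef: dict[str, float]
    coef_standardized: dict[str, float]
    coef_t: dict[str, float]
    coef_p: dict[str, float]
    intercept: float
    r_squared: float
    adj_r_squared: float
    f_statistic: float
    f_df: tuple[int, int]
    f_pvalue: float
    cooks_full_sample: dict[str, float]
    cooks_retained: dict[str, float]
    excluded_subjects: list[str]
    n_retained: int

    def __post_init__(self) -> None:
        # adjusted R^2 must reproduce its hand computation (self check)
        n, p = self.n_retained, len(self.predictors)
        expect = 1.0 - (1.0 - self.r_squared) * (n - 1) / (n - p - 1)
        assert abs(expect - self.adj_r_squared) < 1e-10

    def to_json(self, path) -> None:
        d = {k: v for k, v in self.__dict__.items()}
        d["f_df"] = list(self.f_df)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


class DominanceRegression(BaseEstimator):
    """OLS of mean dominance duration on dB with Cook's-distance exclusion.

    Parameters: ``cooks_threshold`` (strict exclusion cutoff, default 1.0)
    and ``iterative`` (repeat the exclude-and-refit cycle until no subject
    exceeds the cutoff; default off, single pass). ``fit(X, y)`` accepts the
    dB predictor matrix and outcome vector (or a DeltaB table DataFrame via
    :func:`fit_dominance_regression`).
    """

    def __init__(self, cooks_threshold: float = 1.0, iterative: bool = False):
        self.cooks_threshold = cooks_threshold
        self.iterative = iterative

    def fit(self, X, y, subject_ids: Sequence[str] | None = None
            ) -> "DominanceRegression":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        if subject_ids is None:
            subject_ids = [str(i) for i in range(n)]
        subject_ids = list(subject_ids)
        if n < p + 3:
            raise ValueError("too few subjects for the predictor count")
        Xc = np.column_stack([np.ones(n), X])
        d_full = cooks_distance(y, Xc)
        keep = d_full <= self.cooks_threshold
        if self.iterative:
            while True:
                if keep.sum() <= p + 2:
                    break
                d = np.full(n, np.nan)
                d[keep] = cooks_distance(y[keep], Xc[keep])
                worst = np.nanmax(d[keep]) if keep.any() else 0.0
                if worst <= self.cooks_threshold:
                    break
                keep &= ~(d > self.cooks_threshold)
        nr = int(keep.sum())
        if nr - p - 1 <= 0:
            raise ValueError(
                f"no residual degrees of freedom after exclusion "
                f"({nr} retained, {p} predictors)")
        Xr, yr = X[keep], y[keep]
        ols = sm.OLS(yr, sm.add_constant(Xr)).fit()
        d_ret = cooks_distance(yr, sm.add_constant(Xr))
        # standardized coefficients: predictors and outcome z-scored on the
        # retained sample
        zx = (Xr - Xr.mean(axis=0)) / Xr.std(axis=0, ddof=1)
        zy = (yr - yr.mean()) / yr.std(ddof=1)
        beta_std = sm.OLS(zy, sm.add_constant(zx)).fit().params[1:]

        self.subject_ids_ = subject_ids
        self.retained_mask_ = keep
        self.excluded_subjects_ = [s for s, k in zip(subject_ids, keep) if not k]
        self.cooks_full_ = d_full
        self.cooks_retained_ = d_ret
        self.coef_ = np.asarray(ols.params[1:])
        self.intercept_ = float(ols.params[0])
        self.coef_standardized_ = np.asarray(beta_std)
        self.coef_t_ = np.asarray(ols.tvalues[1:])
        self.coef_p_ = np.asarray(ols.pvalues[1:])
        self.r_squared_ = float(ols.rsquared)
        self.adj_r_squared_ = float(ols.rsquared_adj)
        self.f_statistic_ = float(ols.fvalue)
        self.f_df_ = (int(ols.df_model), int(ols.df_resid))
        self.f_pvalue_ = float(ols.f_pvalue)
        self.n_retained_ = nr
        return self

    def predict(self, X) -> np.ndarray:
        return self.intercept_ + np.asarray(X, dtype=float) @ self.coef_


def fit_dominance_regression(
    table: pd.DataFrame,
    cooks_threshold: float = 1.0,
    iterative: bool = False,
) -> RegressionReport:
    """Fit the dB -> mean-duration regression from a DeltaB table.

    The table needs the winning model's dB columns (all four for the fully
    modulated structure), ``mean_duration_s`` and (optionally) a ``subject``
    column. Subjects with full-sample Cook's distance strictly greater than
    the threshold are dropped in one pass and the model refit on the
    remainder.
    """
    predictors = [c for c in table.columns if c.startswith("delta_b[")]
    if not predictors:
        raise ValueError(f"DeltaB table lacks columns: {DELTA_B_COLUMNS}")
    if OUTCOME_COLUMN not in table.columns:
        raise ValueError(f"DeltaB table lacks columns: ['{OUTCOME_COLUMN}']")
    if table[predictors + [OUTCOME_COLUMN]].isna().any().any():
        raise ValueError("DeltaB table has missing cells")
    subs = (table["subject"].astype(str).tolist()
            if "subject" in table.columns else None)
    est = DominanceRegression(cooks_threshold=cooks_threshold,
                              iterative=iterative)
    est.fit(table[predictors].to_numpy(),
            table[OUTCOME_COLUMN].to_numpy(), subject_ids=subs)
    retained_ids = [s for s, k in zip(est.subject_ids_, est.retained_mask_) if k]
    return RegressionReport(
        predictors=predictors,
        coef=dict(zip(predictors, est.coef_.tolist())),
        coef_standardized=dict(zip(predictors,
                                   est.coef_standardized_.tolist())),
        coef_t=dict(zip(predictors, est.coef_t_.tolist())),
        coef_p=dict(zip(predictors, est.coef_p_.tolist())),
        intercept=est.intercept_,
        r_squared=est.r_squared_,
        adj_r_squared=est.adj_r_squared_,
        f_statistic=est.f_statistic_,
        f_df=est.f_df_,
        f_pvalue=est.f_pvalue_,
        cooks_full_sample=dict(zip(est.subject_ids_, est.cooks_full_.tolist())),
        cooks_retained=dict(zip(retained_ids, est.cooks_retained_.tolist())),
        excluded_subjects=est.excluded_subjects_,
        n_retained=est.n_retained_,
    )
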