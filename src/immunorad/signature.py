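"""Signature construction: z-scoring, univariate screening, L1 logistic path.

The fitting recipe is: z-score normalization (full-cohort statistics, with a
fold-safe mode available), univariate screening at p < alpha, then
L1-penalized logistic regression solved along a decreasing lambda grid with
stratified k-fold cross-validation; lambda* minimizes the mean cross-
validated binomial deviance (minimum criterion, not 1-SE), ties broken
toward the larger (sparser) lambda.  The penalized objective is

    (1/n) * sum_i -log L(y_i | b0 + x_i b)  +  lambda * ||b||_1

with an unpenalized intercept, solved by IRLS + cyclic coordinate descent
with warm starts along the path.

A fixed reference immune-score model (linear in the CD8+/CD68+ count
changes) ships as immutable constants and is never refit.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.model_selection import StratifiedKFold


# --------------------------------------------------------------------------
# Reference immune-score model (fixed constants; never refit)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ImmuneScoreModel:
    """Published linear immune score over (delta CD8, delta CD68)."""

    intercept: float = 0.4569
    coef_delta_cd8: float = 0.0041
    coef_delta_cd68: float = -0.0009
    cutoff: float = 0.307

    def score(self, delta_cd8: float, delta_cd68: float) -> float:
        if not (math.isfinite(delta_cd8) and math.isfinite(delta_cd68)):
            raise ValueError("immune score requires finite inputs")
        return (
            self.intercept
            + self.coef_delta_cd8 * delta_cd8
            + self.coef_delta_cd68 * delta_cd68
        )


REFERENCE_IMMUNE_MODEL = ImmuneScoreModel()


def immune_score(delta_cd8: float, delta_cd68: float) -> float:
    """Evaluate the fixed reference immune-score model."""
    return REFERENCE_IMMUNE_MODEL.score(delta_cd8, delta_cd68)


# --------------------------------------------------------------------------
# Normalization and screening
# --------------------------------------------------------------------------

def zscore_normalize(
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Z-score every column using population statistics (ddof=0).

    Constant columns are dropped with a warning; the returned params map
    column -> (mean, sd) for scoring new patients.
    """
    if len(table) < 2:
        raise ValueError("z-score normalization needs >= 2 rows")
    params: dict[str, tuple[float, float]] = {}
    out = {}
    for col in table.columns:
        x = table[col].to_numpy(dtype=np.float64)
        mu, sd = float(x.mean()), float(x.std(ddof=0))
        if sd == 0.0:
            warnings.warn(f"dropping constant column {col!r}", stacklevel=2)
            continue
        params[col] = (mu, sd)
        out[col] = (x - mu) / sd
    return pd.DataFrame(out, index=table.index), params


@dataclass
class ScreeningResult:
    """Univariate screening outcome at significance level alpha."""

    p_values: dict[str, float]
    retained: list[str]
    alpha: float
    flagged_separation: list[str] = field(default_factory=list)


def _wald_p_single_feature(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    """Wald p-value for the slope of a one-feature logistic regression.

    Returns (p, separation_flag); perfect separation is flagged and the
    feature reported as p=0 so it is always retained.
    """
    design = sm.add_constant(x.reshape(-1, 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        except Exception:
            return 0.0, True
    p = float(fit.pvalues[1])
    se = float(fit.bse[1])
    if not math.isfinite(p) or se > 1e3:
        return 0.0, True
    return p, False


def univariate_screen(
    table: pd.DataFrame, labels: np.ndarray, alpha: float = 0.2
) -> ScreeningResult:
    """Screen features by single-predictor logistic Wald p-value < alpha."""
    y = np.asarray(labels, dtype=np.float64)
    if len(np.unique(y)) < 2:
        raise ValueError("screening requires both classes present")
    p_values: dict[str, float] = {}
    flagged: list[str] = []
    for col in table.columns:
        p, sep = _wald_p_single_feature(table[col].to_numpy(dtype=np.float64), y)
        p_values[col] = p
        if sep:
            flagged.append(col)
    retained = [c for c, p in p_values.items() if p < alpha]
    return ScreeningResult(p_values, retained, alpha, flagged)


# --------------------------------------------------------------------------
# L1-penalized logistic path (coordinate descent)
# --------------------------------------------------------------------------

def _sigmoid(eta: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * eta))


def _lasso_logistic_irls(X, y, lam, beta0, beta, candidates=None, max_iter=25, tol=1e-5):
    """One lambda solve by IRLS with active-set coordinate descent (warm start).

    ``candidates`` restricts the coordinates ever updated (strong-rule set);
    coordinates outside it keep their warm-start value (normally zero).
    """
    n, p = X.shape

    def cd_pass(wn, denom, r, beta0, indices):
        max_delta = 0.0
        for j in indices:
            bj = beta[j]
            rho = np.dot(wn * X[:, j], r) + denom[j] * bj
            new = np.sign(rho) * max(abs(rho) - lam, 0.0) / denom[j]
            if new != bj:
                r += X[:, j] * (bj - new)
                beta[j] = new
                max_delta = max(max_delta, abs(new - bj))
        new0 = beta0 + np.dot(wn, r) / wn.sum()
        r += beta0 - new0
        return new0, max_delta

    all_idx = np.arange(p) if candidates is None else np.asarray(candidates)
    for _ in range(max_iter):
        eta = beta0 + X @ beta
        prob = _sigmoid(eta)
        w = prob * (1.0 - prob)
        resid = y - prob
        saturated = w < 1e-5  # glmnet-style: freeze saturated observations
        w[saturated] = 1e-5
        resid[saturated] = 0.0
        z = eta + resid / w
        wn = w / n
        denom = X.T**2 @ wn  # sum_i w_i x_ij^2 / n, per feature
        beta_old = beta.copy()
        beta0_old = beta0
        r = z - beta0 - X @ beta
        beta0, _ = cd_pass(wn, denom, r, beta0, all_idx)
        for _ in range(50):
            active = np.flatnonzero(beta)  # glmnet-style active-set iteration
            beta0, delta = cd_pass(wn, denom, r, beta0, active)
            if delta < tol:
                beta0, delta = cd_pass(wn, denom, r, beta0, all_idx)
                if delta < tol:
                    break
        if max(np.max(np.abs(beta - beta_old), initial=0.0), abs(beta0 - beta0_old)) < tol:
            break
    return beta0, beta


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest lambda at which every coefficient is zero."""
    n = len(y)
    return float(np.max(np.abs(X.T @ (y - y.mean()))) / n)


def default_lambda_grid(X, y, n_lambda: int = 100, ratio: float = 1e-4) -> np.ndarray:
    lmax = lambda_max(X, y)
    if lmax <= 0:
        lmax = 1e-3
    return np.geomspace(lmax, ratio * lmax, n_lambda)


def lasso_logistic_path(X, y, lambdas) -> tuple[np.ndarray, np.ndarray]:
    """Solve the full path with warm starts; returns (intercepts, coef matrix).

    The path terminates early once the training deviance falls below 1% of
    the null deviance (near-perfect separation); remaining grid points reuse
    the last solution, mirroring glmnet's saturation stop.
    """
    n, p = X.shape
    beta0 = float(np.log(y.mean() / (1 - y.mean())))
    beta = np.zeros(p)
    null_dev = binomial_deviance(y, np.full(n, beta0))
    intercepts = np.empty(len(lambdas))
    coefs = np.empty((len(lambdas), p))
    lam_prev = lambdas[0]
    for k, lam in enumerate(lambdas):
        # sequential strong rule: |grad_j| >= 2*lam - lam_prev may enter
        grad = np.abs(X.T @ (y - _sigmoid(beta0 + X @ beta))) / n
        cand = np.flatnonzero((grad >= 2.0 * lam - lam_prev) | (beta != 0.0))
        for _ in range(5):
            beta0, beta = _lasso_logistic_irls(X, y, lam, beta0, beta, cand)
            grad = np.abs(X.T @ (y - _sigmoid(beta0 + X @ beta))) / n
            mask = np.ones(p, dtype=bool)
            mask[cand] = False
            violations = np.flatnonzero(mask & (grad > lam * (1 + 1e-6)))
            if violations.size == 0:
                break
            cand = np.concatenate([cand, violations])
        lam_prev = lam
        intercepts[k] = beta0
        coefs[k] = beta
        if binomial_deviance(y, beta0 + X @ beta) < 0.01 * null_dev:
            intercepts[k + 1:] = beta0
            coefs[k + 1:] = beta
            break
    return intercepts, coefs


def binomial_deviance(y: np.ndarray, eta: np.ndarray) -> float:
    """Mean -2 log-likelihood of Bernoulli outcomes under linear predictor eta."""
    prob = np.clip(_sigmoid(eta), 1e-10, 1 - 1e-10)
    return float(np.mean(-2.0 * (y * np.log(prob) + (1 - y) * np.log(1 - prob))))


@dataclass
class SignatureModel:
    """Sparse linear signature: intercept + coefficients on the z-scale."""

    intercept: float
    coefficients: dict[str, float]
    lambda_: float
    cv_deviance_path: dict[float, float]
    normalization_params: dict[str, tuple[float, float]]
    label_definition: str
    seed: int | None = None
    n_screened: int | None = None

    @property
    def support(self) -> list[str]:
        return [k for k, v in self.coefficients.items() if v != 0.0]

    def score(self, table: pd.DataFrame) -> np.ndarray:
        """Linear score of raw-unit rows, applying stored normalization."""
        eta = np.full(len(table), self.intercept, dtype=np.float64)
        for name, coef in self.coefficients.items():
            if coef == 0.0:
                continue
            mu, sd = self.normalization_params[name]
            eta += coef * (table[name].to_numpy(dtype=np.float64) - mu) / sd
        return eta

    def raw_formula(self) -> dict[str, float]:
        """De-normalize to raw units: {'intercept': b0', name: coef/sd, ...}."""
        out = {"intercept": self.intercept}
        for name, coef in self.coefficients.items():
            mu, sd = self.normalization_params[name]
            out[name] = coef / sd
            out["intercept"] -= coef * mu / sd
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "lambda": self.lambda_,
            "cv_deviance_path": {f"{k:.10g}": v for k, v in self.cv_deviance_path.items()},
            "normalization_params": {k: list(v) for k, v in self.normalization_params.items()},
            "label_definition": self.label_definition,
            "seed": self.seed,
            "n_screened": self.n_screened,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SignatureModel":
        d = json.loads(Path(path).read_text())
        return cls(
            intercept=d["intercept"],
            coefficients=d["coefficients"],
            lambda_=d["lambda"],
            cv_deviance_path={float(k): v for k, v in d["cv_deviance_path"].items()},
            normalization_params={k: tuple(v) for k, v in d["normalization_params"].items()},
            label_definition=d["label_definition"],
            seed=d["seed"],
            n_screened=d.get("n_screened"),
        )


def fit_lasso_cv(
    table: pd.DataFrame,
    labels: np.ndarray,
    n_folds: int = 10,
    lambda_grid: Sequence[float] | None = None,
    seed: int = 0,
    normalization_params: dict[str, tuple[float, float]] | None = None,
    label_definition: str = "label",
) -> SignatureModel:
    """Cross-validated L1 logistic fit over a decreasing lambda grid.

    ``table`` must already be normalized; pass the corresponding
    ``normalization_params`` so the model can score raw-unit rows (identity
    params are assumed otherwise).
    """
    X = table.to_numpy(dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    n, p = X.shape
    if n < n_folds:
        raise ValueError(f"need at least n_folds={n_folds} rows, got {n}")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    lambdas = (
        np.asarray(lambda_grid, dtype=np.float64)
        if lambda_grid is not None
        else default_lambda_grid(X, y)
    )
    if lambdas.size < 2 or np.any(np.diff(lambdas) >= 0):
        raise ValueError("lambda grid must be strictly decreasing with >= 2 values")

    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_dev = np.zeros((n_folds, lambdas.size))
    for f, (tr, va) in enumerate(cv.split(X, y)):
        b0s, betas = lasso_logistic_path(X[tr], y[tr], lambdas)
        eta = b0s[:, None] + betas @ X[va].T  # (n_lambda, n_val)
        for k in range(lambdas.size):
            fold_dev[f, k] = binomial_deviance(y[va], eta[k])
    mean_dev = fold_dev.mean(axis=0)
    best = int(np.flatnonzero(mean_dev == mean_dev.min())[0])  # largest lambda on ties

    b0s, betas = lasso_logistic_path(X, y, lambdas)
    coef = betas[best]
    params = normalization_params or {c: (0.0, 1.0) for c in table.columns}
    return SignatureModel(
        intercept=float(b0s[best]),
        coefficients={c: float(v) for c, v in zip(table.columns, coef)},
        lambda_=float(lambdas[best]),
        cv_deviance_path={float(l): float(d) for l, d in zip(lambdas, mean_dev)},
        normalization_params={c: params[c] for c in table.columns},
        label_definition=label_definition,
        seed=seed,
    )


# --------------------------------------------------------------------------
# High-level builders
# --------------------------------------------------------------------------

#: the 13 candidate marker-change column names used by the marker classifier
MARKER_DELTA_COLUMNS = (
    "delta_cd8", "delta_cd68", "delta_pdl1", "delta_serpinb9", "delta_cd47",
    "delta_irf1", "delta_stat1", "delta_hla_a", "delta_hla_bc", "delta_b2m",
    "delta_tap1", "delta_lmp2", "delta_lmp7",
)


def marker_delta_table(records) -> pd.DataFrame:
    """13 marker-change columns from records; extras default to 0 if absent."""
    rows = []
    for r in records:
        row = {"delta_cd8": r.delta_cd8, "delta_cd68": r.delta_cd68}
        for col in MARKER_DELTA_COLUMNS[2:]:
            row[col] = float(r.extra.get(col, 0.0))
        rows.append(row)
    return pd.DataFrame(rows, columns=list(MARKER_DELTA_COLUMNS))


def build_immunomarker_classifier(
    records, seed: int = 0, n_folds: int = 10, lambda_grid=None
) -> SignatureModel:
    """Fit the marker-change classifier: z-score -> CV LASSO over 13 deltas."""
    table = marker_delta_table(records)
    labels = np.array(
        [1.0 if r.response == "CR" else 0.0 for r in records], dtype=np.float64
    )
    if any(r.response is None for r in records):
        raise ValueError("all records need a CR/PR response for supervised fitting")
    normed, params = zscore_normalize(table)
    return fit_lasso_cv(
        normed, labels, n_folds=n_folds, seed=seed, lambda_grid=lambda_grid,
        normalization_params=params, label_definition="response:CR",
    )


def build_radiomics_signature(
    feature_table: pd.DataFrame,
    target_labels: np.ndarray,
    seed: int = 0,
    alpha: float = 0.2,
    n_folds: int = 10,
    label_definition: str = "immune_group:high",
    lambda_grid=None,
) -> tuple[SignatureModel, ScreeningResult]:
    """Screen (p < alpha) -> z-score -> CV LASSO over the 97-feature table."""
    screening = univariate_screen(feature_table, target_labels, alpha=alpha)
    if not screening.retained:
        raise ValueError("no features survived univariate screening")
    normed, params = zscore_normalize(feature_table[screening.retained])
    model = fit_lasso_cv(
        normed, target_labels, n_folds=n_folds, seed=seed, lambda_grid=lambda_grid,
        normalization_params=params, label_definition=label_definition,
    )
    model.n_screened = len(screening.retained)
    return model, screening
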