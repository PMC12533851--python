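"""Stepwise-MLR enantioselectivity models, validation metrics and kNN domain.

The response is the selectivity factor α_RS = k_R / k_S (retention factor of
the R enantiomer over that of the S enantiomer, regardless of elution order)
or its log10. Models are built by forward stepwise multiple linear regression
on autoscaled descriptors, the model complexity is chosen from the LOOCV error
curve (interior minimum, else the ΔRMSECV ≤ 0.02 / bending-point rule followed
by an F-test criterion), and predictions are scored on three schemes: accuracy
(±0.05 on α_RS), separated/unseparated classification (band [0.95, 1.05]) and
elution sequence (same side of α_RS = 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import NearestNeighbors


# --------------------------------------------------------------------------
# Response table

def retention_factor(t_r: np.ndarray, t_0: float) -> np.ndarray:
    """Retention factor k = (t_R − t_0)/t_0."""
    t_r = np.asarray(t_r, dtype=float)
    if t_0 <= 0:
        raise ValueError("dead time t_0 must be positive")
    return (t_r - t_0) / t_0


def alpha_rs(k_r, k_s) -> np.ndarray:
    """Selectivity factor α_RS = k_R / k_S; >1 means R elutes last."""
    k_r = np.asarray(k_r, dtype=float)
    k_s = np.asarray(k_s, dtype=float)
    if np.any(k_r <= 0) or np.any(k_s <= 0):
        raise ValueError("retention factors must be positive")
    return k_r / k_s


# --------------------------------------------------------------------------
# Ordinary least squares helpers (intercept always included)

def _ols_fit(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    A = np.column_stack([np.ones(len(X)), X])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return beta


def _ols_predict(beta: np.ndarray, X: np.ndarray) -> np.ndarray:
    return beta[0] + X @ beta[1:]


def _partial_f_pvalue(X_base: np.ndarray, x_new: np.ndarray, y: np.ndarray) -> float:
    """p-value of the partial F-test for adding one predictor to an OLS model."""
    n = len(y)
    if X_base.shape[1] == 0:
        rss0 = float(np.sum((y - y.mean()) ** 2))
    else:
        beta0 = _ols_fit(X_base, y)
        rss0 = float(np.sum((y - _ols_predict(beta0, X_base)) ** 2))
    X1 = np.column_stack([X_base, x_new])
    beta1 = _ols_fit(X1, y)
    rss1 = float(np.sum((y - _ols_predict(beta1, X1)) ** 2))
    df_resid = n - X1.shape[1] - 1
    if df_resid <= 0 or rss1 <= 0:
        return 0.0 if rss1 < rss0 else 1.0
    f = (rss0 - rss1) / (rss1 / df_resid)
    return float(stats.f.sf(max(f, 0.0), 1, df_resid))


def _partial_f_pvalues_batch(
    X_base: np.ndarray, candidates: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """Partial-F p-values for adding each candidate column to the base model.

    Equivalent to calling :func:`_partial_f_pvalue` per column but computed in
    one pass: base design (with intercept) is orthogonalised by QR, candidates
    and response are projected onto its orthogonal complement, and the RSS
    drop for each candidate is (x⊥·y⊥)²/‖x⊥‖².
    """
    n = len(y)
    A = np.column_stack([np.ones(n), X_base])
    Q, _ = np.linalg.qr(A)
    y_perp = y - Q @ (Q.T @ y)
    C_perp = candidates - Q @ (Q.T @ candidates)
    rss0 = float(y_perp @ y_perp)
    if rss0 <= 1e-28 * n:  # base model already fits perfectly
        return np.ones(candidates.shape[1])
    norms2 = np.einsum("ij,ij->j", C_perp, C_perp)
    proj = C_perp.T @ y_perp
    with np.errstate(invalid="ignore", divide="ignore"):
        drop = np.where(norms2 > 0, proj**2 / norms2, 0.0)
    rss1 = np.maximum(rss0 - drop, 0.0)
    df_resid = n - A.shape[1] - 1
    if df_resid <= 0:
        return np.where(rss1 < rss0, 0.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(rss1 > 0, drop / (rss1 / df_resid), np.inf)
    return stats.f.sf(np.maximum(f, 0.0), 1, df_resid)


# --------------------------------------------------------------------------
# Stepwise selection

@dataclass
class StepwiseModel:
    """One member of the nested stepwise sequence (complexity = #descriptors)."""

    names: List[str]
    intercept: float
    coefficients: np.ndarray  # on autoscaled predictors
    complexity: int
    entry_pvalues: List[float] = field(default_factory=list)


def stepwise_mlr(
    X: pd.DataFrame,
    y: np.ndarray,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.10,
    max_complexity: Optional[int] = None,
    min_models: int = 0,
) -> List[StepwiseModel]:
    """Forward stepwise MLR with partial-F entry testing.

    At each step the candidate with the smallest partial-F p-value enters if
    p ≤ ``alpha_enter``; already-included terms whose p rises above
    ``alpha_remove`` are dropped. If fewer than ``min_models`` nested models
    result, ``alpha_enter`` is raised in steps of 0.05 and selection rerun, so
    enough complexities exist for the complexity-selection rule. Coefficients
    are refit by OLS at every step. ``X`` must already be autoscaled.
    """
    y = np.asarray(y, dtype=float)
    if len(X) != len(y):
        raise ValueError("X and y lengths differ")
    cap = max_complexity if max_complexity is not None else min(len(X.columns), len(y) - 2)

    Xmat = X.to_numpy(float)
    col_index = {name: j for j, name in enumerate(X.columns)}

    def run(alpha: float) -> List[StepwiseModel]:
        selected: List[str] = []
        models: List[StepwiseModel] = []
        pvals: List[float] = []
        remaining = list(X.columns)
        max_steps = 4 * cap + 8  # guard against enter/remove cycling
        steps = 0
        while remaining and len(selected) < cap and steps < max_steps:
            steps += 1
            Xb = X[selected].to_numpy() if selected else np.empty((len(y), 0))
            cand = Xmat[:, [col_index[c] for c in remaining]]
            cand_p = _partial_f_pvalues_batch(Xb, cand, y)
            k = int(np.argmin(cand_p))
            if cand_p[k] > alpha:
                break
            entered = remaining.pop(k)
            selected.append(entered)
            pvals.append(cand_p[k])
            # backward pass: drop terms that lost significance (the term
            # that just entered is exempt, which prevents enter/remove
            # cycling when alpha has been raised above alpha_remove)
            removal_p = max(alpha_remove, alpha)
            changed = True
            while changed and len(selected) > 1:
                changed = False
                for name in list(selected):
                    if name == entered:
                        continue
                    others = [s for s in selected if s != name]
                    p = _partial_f_pvalue(
                        X[others].to_numpy(), X[name].to_numpy(), y
                    )
                    if p > removal_p:
                        i = selected.index(name)
                        selected.remove(name)
                        pvals.pop(i)
                        remaining.append(name)
                        changed = True
            Xs = X[selected].to_numpy()
            beta = _ols_fit(Xs, y)
            models.append(
                StepwiseModel(
                    names=list(selected),
                    intercept=float(beta[0]),
                    coefficients=beta[1:].copy(),
                    complexity=len(selected),
                    entry_pvalues=list(pvals),
                )
            )
        return models

    alpha = alpha_enter
    models = run(alpha)
    while len(models) < min_models and alpha < 1.0:
        alpha = min(1.0, alpha + 0.05)
        models = run(alpha)
    return models


# --------------------------------------------------------------------------
# Cross-validation

def _autoscale_fit(X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    return mu, sd


def loocv_predictions(
    names: Sequence[str],
    X_raw: pd.DataFrame,
    y: np.ndarray,
    rescale_in_fold: bool = True,
) -> np.ndarray:
    """Leave-one-out predictions for a fixed descriptor subset.

    Each fold refits OLS on the n−1 remaining molecules; with
    ``rescale_in_fold`` the autoscaling of the raw descriptor columns is also
    refit inside the fold (fold-honest scaling), which makes predictions
    invariant to any affine rescaling of the raw columns.
    """
    y = np.asarray(y, dtype=float)
    Xr = X_raw[list(names)].to_numpy() if len(names) else np.empty((len(y), 0))
    n = len(y)
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr, ytr = Xr[mask], y[mask]
        if Xtr.shape[1] and rescale_in_fold:
            mu, sd = _autoscale_fit(Xtr)
            Xtr = (Xtr - mu) / sd
            Xte = (Xr[i] - mu) / sd
        else:
            Xte = Xr[i]
        if Xtr.shape[1]:
            beta = _ols_fit(Xtr, ytr)
            preds[i] = float(_ols_predict(beta, Xte[None, :])[0])
        else:
            preds[i] = ytr.mean()
    return preds


def loocv_rmsecv(
    names: Sequence[str],
    X_raw: pd.DataFrame,
    y: np.ndarray,
    rescale_in_fold: bool = True,
) -> float:
    """Root mean squared LOOCV prediction error for a descriptor subset."""
    preds = loocv_predictions(names, X_raw, y, rescale_in_fold)
    return float(np.sqrt(np.mean((np.asarray(y, float) - preds) ** 2)))


# --------------------------------------------------------------------------
# Complexity selection

def delta_rmsecv(rmsecv: Sequence[float]) -> np.ndarray:
    """Relative RMSECV change between consecutive complexities.

    Element A−1 (0-based) is (RMSECV_{A−1} − RMSECV_A) / RMSECV_{A−1} for
    A = 2..len; a sequence of length L yields L−1 deltas.
    """
    r = np.asarray(rmsecv, dtype=float)
    return (r[:-1] - r[1:]) / r[:-1]


def _knee_point(rmsecv: np.ndarray) -> int:
    """Bending point: index of maximum distance to the first–last chord."""
    n = len(rmsecv)
    x = np.arange(n, dtype=float)
    p0 = np.array([x[0], rmsecv[0]])
    p1 = np.array([x[-1], rmsecv[-1]])
    chord = p1 - p0
    chord /= np.linalg.norm(chord)
    rel = np.column_stack([x, rmsecv]) - p0
    dist = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0])
    return int(np.argmax(dist))


def select_complexity(
    rmsecv: Sequence[float],
    n_train: int,
    alpha_f: float = 0.05,
    delta_threshold: float = 0.02,
) -> int:
    """Choose the model complexity A (1-based) from an RMSECV curve.

    If the curve has a global interior minimum, that complexity is taken.
    Otherwise the first complexity where the relative RMSECV drop falls to
    ``delta_threshold`` (or the bending point of the curve) anchors a window:
    the mean squared RMSECV of the next 10 complexities defines, through an
    F(α, N, N) quantile with N = ``n_train``, a critical variance; the
    simplest model whose RMSECV² does not exceed it is returned.
    """
    r = np.asarray(rmsecv, dtype=float)
    if len(r) == 0:
        raise ValueError("empty RMSECV sequence")
    if len(r) == 1:
        return 1
    amin = int(np.argmin(r))
    if amin == 0 and np.all(r[1:] >= r[0]):
        warnings.warn("RMSECV increases from complexity 1; returning A=1")
        return 1
    # a genuine interior minimum requires the curve to rise again afterwards
    # (a flat plateau is the "continuously decreasing" case of the rule)
    if 0 < amin < len(r) - 1 and np.any(r[amin + 1 :] > r[amin]):
        return amin + 1

    deltas = delta_rmsecv(r)
    hits = np.flatnonzero(deltas <= delta_threshold)
    anchor = int(hits[0]) + 1 if len(hits) else _knee_point(r)  # 0-based index

    tail = r[anchor + 1 : anchor + 11]
    if len(tail) == 0:
        tail = r[anchor:]
    if len(tail) < 10:
        warnings.warn(
            f"only {len(tail)} complexities beyond the anchor; averaging those"
        )
    crit = stats.f.ppf(1.0 - alpha_f, n_train, n_train) * np.mean(tail**2)
    ok = np.flatnonzero(r**2 <= crit)
    return int(ok[0]) + 1 if len(ok) else anchor + 1


# --------------------------------------------------------------------------
# Metrics and evaluation schemes

@dataclass
class ModelMetrics:
    rmsec: float
    rmsecv: float
    rmsec_n: float
    rmsecv_n: float
    r2: float
    q2: float
    mean_pct_error: float


def model_metrics(
    names: Sequence[str],
    X_raw: pd.DataFrame,
    y: np.ndarray,
    response_mode: str = "alpha",
    rescale_in_fold: bool = True,
) -> ModelMetrics:
    """Calibration and cross-validation metrics for one descriptor subset.

    RMSEC_N and RMSECV_N are normalised by the experimental response range.
    The mean percentage prediction error is always reported on the α_RS scale:
    in "log_alpha" mode predictions are back-transformed (10^y) first, and the
    error is |α_exp − α_pred| / α_exp × 100 averaged over molecules.
    """
    y = np.asarray(y, dtype=float)
    rng = float(y.max() - y.min())
    if rng == 0:
        raise ValueError("zero response range")
    Xr = X_raw[list(names)].to_numpy()
    mu, sd = _autoscale_fit(Xr)
    beta = _ols_fit((Xr - mu) / sd, y)
    fitted = _ols_predict(beta, (Xr - mu) / sd)
    cv_pred = loocv_predictions(names, X_raw, y, rescale_in_fold)

    rmsec = float(np.sqrt(np.mean((y - fitted) ** 2)))
    rmsecv = float(np.sqrt(np.mean((y - cv_pred) ** 2)))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum((y - fitted) ** 2)) / tss
    q2 = 1.0 - float(np.sum((y - cv_pred) ** 2)) / tss

    if response_mode == "log_alpha":
        a_exp, a_pred = 10.0**y, 10.0**cv_pred
    elif response_mode == "alpha":
        a_exp, a_pred = y, cv_pred
    else:
        raise ValueError(f"unknown response mode {response_mode!r}")
    pct = float(np.mean(np.abs(a_exp - a_pred) / a_exp) * 100.0)

    return ModelMetrics(
        rmsec=rmsec,
        rmsecv=rmsecv,
        rmsec_n=rmsec / rng,
        rmsecv_n=rmsecv / rng,
        r2=r2,
        q2=q2,
        mean_pct_error=pct,
    )


@dataclass
class PredictionEvaluation:
    n: int
    accurate: int                # |α_pred − α_exp| ≤ accuracy_band
    correct_separation: int      # both inside or both outside [0.95, 1.05]
    elution_correct: int         # same side of 1.0, among resolved molecules
    n_resolved: int              # experimentally separated molecules


def evaluate_predictions(
    alpha_exp,
    alpha_pred,
    accuracy_band: float = 0.05,
    separation_band: Tuple[float, float] = (0.95, 1.05),
) -> PredictionEvaluation:
    """Score α_RS predictions on the three evaluation schemes.

    A prediction is *accurate* within ±0.05 of the experimental α_RS. A
    molecule is *unseparated* when α_RS lies in [0.95, 1.05]; the separation
    call is correct when experiment and prediction fall on the same side of
    that band. The *elution sequence* is correct when both lie on the same
    side of 1.0; experimentally unresolved molecules are excluded from its
    denominator.
    """
    x = np.asarray(alpha_exp, dtype=float)
    yp = np.asarray(alpha_pred, dtype=float)
    if np.any(x <= 0) or np.any(yp <= 0):
        raise ValueError("selectivity factors must be positive")
    lo, hi = separation_band
    accurate = int(np.sum(np.abs(yp - x) <= accuracy_band))
    in_x = (x >= lo) & (x <= hi)
    in_y = (yp >= lo) & (yp <= hi)
    correct_sep = int(np.sum(in_x == in_y))
    resolved = ~in_x
    elution = int(np.sum(((x > 1.0) == (yp > 1.0)) & resolved))
    return PredictionEvaluation(
        n=len(x),
        accurate=accurate,
        correct_separation=correct_sep,
        elution_correct=elution,
        n_resolved=int(resolved.sum()),
    )


# --------------------------------------------------------------------------
# Applicability domain

@dataclass
class ApplicabilityDomain:
    k: int
    threshold: float
    train_mean_distances: np.ndarray

    def check(self, distances: np.ndarray) -> np.ndarray:
        return distances <= self.threshold


def knn_applicability(
    X_train: np.ndarray,
    X_query: Optional[np.ndarray] = None,
    k: Optional[int] = None,
) -> Tuple[ApplicabilityDomain, np.ndarray, np.ndarray]:
    """kNN applicability domain on the model's descriptor columns.

    k defaults to round(n^(1/3)) with n the training-set size. The domain
    threshold is mean + 2·SD of the training molecules' mean Euclidean
    distances to their k nearest neighbours (self excluded). Returns the
    domain, per-query mean distances, and in-domain flags.
    """
    X_train = np.asarray(X_train, dtype=float)
    n = len(X_train)
    if k is None:
        k = int(round(n ** (1.0 / 3.0)))
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} training molecules, got {n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X_train)
    d_train, _ = nn.kneighbors(X_train)
    train_mean = d_train[:, 1:].mean(axis=1)  # drop self-distance
    threshold = float(train_mean.mean() + 2.0 * train_mean.std(ddof=1))
    domain = ApplicabilityDomain(k=k, threshold=threshold, train_mean_distances=train_mean)

    if X_query is None:
        return domain, train_mean, domain.check(train_mean)
    X_query = np.asarray(X_query, dtype=float)
    d_query, _ = nn.kneighbors(X_query, n_neighbors=k)
    query_mean = d_query.mean(axis=1)
    return domain, query_mean, domain.check(query_mean)


# --------------------------------------------------------------------------
# End-to-end model building

@dataclass
class QSERModel:
    """A selected stepwise model with its metrics and evaluation counts."""

    names: List[str]
    intercept: float
    coefficients: np.ndarray
    complexity: int
    response_mode: str
    metrics: ModelMetrics
    evaluation: PredictionEvaluation
    rmsecv_curve: List[float] = field(default_factory=list)

    def report(self) -> Dict:
        return {
            "response": self.response_mode,
            "descriptors": self.names,
            "intercept": self.intercept,
            "coefficients": dict(zip(self.names, map(float, self.coefficients))),
            "complexity": self.complexity,
            "RMSEC": self.metrics.rmsec,
            "RMSECV": self.metrics.rmsecv,
            "RMSEC_N": self.metrics.rmsec_n,
            "RMSECV_N": self.metrics.rmsecv_n,
            "r2": self.metrics.r2,
            "q2": self.metrics.q2,
            "prediction_error_pct": self.metrics.mean_pct_error,
            "accurate_predictions": f"{self.evaluation.accurate}/{self.evaluation.n}",
            "correct_predictions": f"{self.evaluation.correct_separation}/{self.evaluation.n}",
            "elution_sequence": f"{self.evaluation.elution_correct}/{self.evaluation.n_resolved}",
            "rmsecv_curve": self.rmsecv_curve,
        }


def build_qser_model(
    X_raw: pd.DataFrame,
    y: np.ndarray,
    response_mode: str = "alpha",
    alpha_enter: float = 0.05,
    max_complexity: Optional[int] = None,
    min_models: int = 15,
    rescale_in_fold: bool = True,
) -> QSERModel:
    """Stepwise selection + LOOCV complexity choice + metrics in one call.

    ``X_raw`` holds unscaled descriptor columns; autoscaling happens globally
    for selection and per-fold for cross-validation. ``y`` is α_RS or
    log10 α_RS according to ``response_mode``.
    """
    y = np.asarray(y, dtype=float)
    mu, sd = _autoscale_fit(X_raw.to_numpy())
    keep = sd > 0
    X_use = X_raw.loc[:, X_raw.columns[keep]]
    X_scaled = (X_use - X_use.mean()) / X_use.std(ddof=1)

    models = stepwise_mlr(
        X_scaled, y, alpha_enter=alpha_enter,
        max_complexity=max_complexity, min_models=min_models,
    )
    if not models:
        raise ValueError("stepwise selection produced no models")

    curve = [
        loocv_rmsecv(m.names, X_use, y, rescale_in_fold) for m in models
    ]
    a = select_complexity(curve, n_train=len(y))
    a = min(a, len(models))
    chosen = models[a - 1]

    metrics = model_metrics(chosen.names, X_use, y, response_mode, rescale_in_fold)
    cv_pred = loocv_predictions(chosen.names, X_use, y, rescale_in_fold)
    if response_mode == "log_alpha":
        evaluation = evaluate_predictions(10.0**y, 10.0**cv_pred)
    else:
        evaluation = evaluate_predictions(y, cv_pred)

    return QSERModel(
        names=chosen.names,
        intercept=chosen.intercept,
        coefficients=chosen.coefficients,
        complexity=chosen.complexity,
        response_mode=response_mode,
        metrics=metrics,
        evaluation=evaluation,
        rmsecv_curve=[float(c) for c in curve],
    )
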