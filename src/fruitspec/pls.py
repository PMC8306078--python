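"""Single-response partial least squares (PLS1) with leave-one-out
cross-validation and PRESS-ratio latent-variable selection.

The regression core is a NIPALS-style sequential deflation: per component
the weight vector is X'y normalised, scores are X w, loadings follow by
least squares and X (and the y residual) are deflated.  X and y are
centred internally around the training means, so cross-validation folds
automatically re-learn centering from their own rows and the model exposes
coefficients + intercept in the (pretreated, uncentred) variable space.

Latent-variable choice follows the PRESS-ratio rule: PRESS(k)/min PRESS is
treated as an F statistic on (I, I) degrees of freedom and the fewest
components whose ratio is not significantly above 1 at the configured
probability threshold (default 0.75) are retained.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PLSModel",
    "CVRecord",
    "FitMetrics",
    "fit_pls",
    "predict",
    "loo_cv",
    "select_lv",
    "metrics",
    "save_model",
    "load_model",
]


@dataclass
class PLSModel:
    """Fitted PLS1 state.

    ``coef``/``intercept`` act on pretreated but *uncentred* spectra:
    ``y_hat = X @ coef + intercept``.
    """

    weights: np.ndarray  # (p, k)
    x_loadings: np.ndarray  # (p, k)
    y_loadings: np.ndarray  # (k,)
    coef: np.ndarray  # (p,)
    intercept: float
    x_mean: np.ndarray
    y_mean: float
    n_lv: int
    var_index: np.ndarray  # retained columns, as indices into the full grid
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.coef.size != self.var_index.size:
            raise ValueError("coefficient vector length must match retained variables")
        if not (1 <= self.n_lv <= min(self.n_rows - 1, self.n_cols)):
            raise ValueError("latent-variable count outside the feasible range")


@dataclass
class CVRecord:
    """Leave-one-out results for candidate component counts 1..max_lv."""

    press: np.ndarray  # (max_lv,)
    predictions: np.ndarray  # (I, max_lv) left-out predictions
    y_nom: np.ndarray  # (I,)
    n_samples: int

    def __post_init__(self) -> None:
        if self.predictions.shape != (self.n_samples, self.press.size):
            raise ValueError("prediction matrix shape inconsistent with record")
        recomputed = ((self.predictions - self.y_nom[:, None]) ** 2).sum(axis=0)
        if not np.allclose(recomputed, self.press, rtol=1e-10, atol=1e-12):
            raise ValueError("PRESS does not match the stored per-sample predictions")

    def rmsecv(self, n_lv: int) -> float:
        return float(np.sqrt(self.press[n_lv - 1] / self.n_samples))

    def residuals(self, n_lv: int) -> np.ndarray:
        return self.predictions[:, n_lv - 1] - self.y_nom


@dataclass
class FitMetrics:
    """Goodness/error metrics; only the context-relevant fields are set."""

    r2_cal: float | None = None
    rmsec: float | None = None
    r2_cv: float | None = None
    rmsecv: float | None = None
    r2_pred: float | None = None
    rmsep: float | None = None


def _nipals(Xc: np.ndarray, yc: np.ndarray, n_lv: int, strict: bool = True):
    """Sequential PLS1 deflation on centred data.

    Returns (W, P, q, k_reached).  With ``strict`` the full ``n_lv``
    components are required; otherwise deflation stops quietly once X (or
    its covariance with y) is numerically exhausted, as happens on
    noiseless low-rank data.
    """
    n, p = Xc.shape
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    X = Xc.copy()
    y = yc.copy()
    scale = float(np.linalg.norm(Xc) * np.linalg.norm(yc)) or 1.0
    reached = 0
    for k in range(n_lv):
        w = X.T @ y
        wn = np.linalg.norm(w)
        if wn <= 1e-13 * scale:
            if strict:
                raise ValueError(
                    f"X is exhausted after {k} components; "
                    f"requested {n_lv} exceeds the data rank"
                )
            break
        w /= wn
        t = X @ w
        tt = float(t @ t)
        if tt <= 1e-26 * scale**2:
            if strict:
                raise ValueError(f"degenerate score vector at component {k + 1}")
            break
        pk = (X.T @ t) / tt
        qk = float(y @ t) / tt
        X -= np.outer(t, pk)
        y = y - qk * t
        W[:, k], P[:, k], q[k] = w, pk, qk
        reached = k + 1
    return W, P, q, reached


def _coefficients(W: np.ndarray, P: np.ndarray, q: np.ndarray, k: int) -> np.ndarray:
    """Regression vector for the first k components: b = W (P'W)^-1 q."""
    A = P[:, :k].T @ W[:, :k]
    return W[:, :k] @ np.linalg.solve(A, q[:k])


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    var_index: np.ndarray | None = None,
) -> PLSModel:
    """Fit a PLS1 model with ``n_lv`` components.

    ``X`` is pretreated spectra (rows = samples); centering is handled
    internally, so chains without an explicit MC step are still valid.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y disagree on sample count")
    if np.ptp(y) == 0:
        raise ValueError("y has zero variance; nothing to regress on")
    if not (1 <= n_lv <= min(n - 1, p)):
        raise ValueError(
            f"n_lv={n_lv} infeasible for {n} rows x {p} variables "
            f"(bound {min(n - 1, p)})"
        )
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q, _ = _nipals(X - x_mean, y - y_mean, n_lv, strict=True)
    coef = _coefficients(W, P, q, n_lv)
    intercept = y_mean - float(x_mean @ coef)
    if var_index is None:
        var_index = np.arange(p)
    return PLSModel(
        weights=W,
        x_loadings=P,
        y_loadings=q,
        coef=coef,
        intercept=intercept,
        x_mean=x_mean,
        y_mean=y_mean,
        n_lv=n_lv,
        var_index=np.asarray(var_index),
        n_rows=n,
        n_cols=p,
    )


def predict(model: PLSModel, Xnew: np.ndarray) -> np.ndarray:
    """Predict concentrations for pretreated spectra.

    Columns of ``Xnew`` must already be restricted to the model's retained
    variables (same order as ``model.var_index``).
    """
    Xnew = np.atleast_2d(np.asarray(Xnew, dtype=float))
    if Xnew.shape[1] != model.coef.size:
        raise ValueError(
            f"model expects {model.coef.size} variables, got {Xnew.shape[1]}"
        )
    return Xnew @ model.coef + model.intercept


def loo_cv(X: np.ndarray, y: np.ndarray, max_lv: int) -> CVRecord:
    """Leave-one-out cross-validation over component counts 1..max_lv.

    Every fold re-learns centering from its own I-1 rows (no leakage);
    PRESS(k) is the sum of squared left-out errors at k components and
    RMSECV(k) = sqrt(PRESS(k)/I).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 samples")
    bound = min(n - 2, p)
    if max_lv > bound:
        warnings.warn(
            f"max_lv={max_lv} infeasible with {n} samples; clipped to {bound}",
            stacklevel=2,
        )
        max_lv = bound
    if max_lv < 1:
        raise ValueError("no feasible latent-variable count")
    preds = np.empty((n, max_lv))
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        Xi, yi = X[keep], y[keep]
        xm = Xi.mean(axis=0)
        ym = yi.mean()
        W, P, q, reached = _nipals(Xi - xm, yi - ym, max_lv, strict=False)
        xc = X[i] - xm
        if reached == 0:  # fold carries no covariance with y at all
            preds[i, :] = ym
            continue
        for k in range(1, max_lv + 1):
            # beyond the fold's numerical rank further components are null,
            # so the prediction at the last feasible count carries forward
            b = _coefficients(W, P, q, min(k, reached))
            preds[i, k - 1] = ym + float(xc @ b)
    press = ((preds - y[:, None]) ** 2).sum(axis=0)
    return CVRecord(press=press, predictions=preds, y_nom=y.copy(), n_samples=n)


def select_lv(
    cv: CVRecord, prob_threshold: float = 0.75, method: str = "f_test"
) -> int:
    """Pick the component count by the PRESS-ratio rule.

    ``f_test`` (default): with k* the PRESS minimiser, the ratio
    PRESS(k)/PRESS(k*) plays the role of an F statistic with (I, I)
    degrees of freedom; the smallest k <= k* whose ratio is below the
    F quantile at ``prob_threshold`` (i.e. not significantly worse than
    the minimum) is chosen.  ``ratio`` compares the raw ratio to
    ``prob_threshold`` treated as a plain multiplier (> 1).
    """
    press = np.asarray(cv.press, dtype=float)
    k_star = int(np.argmin(press))
    floor = press[k_star]
    if floor == 0:
        return int(np.flatnonzero(press == 0)[0]) + 1
    ratios = press / floor
    if method == "f_test":
        crit = stats.f.ppf(prob_threshold, cv.n_samples, cv.n_samples)
    elif method == "ratio":
        crit = prob_threshold
    else:
        raise ValueError(f"unknown selection method {method!r}")
    for k in range(k_star + 1):
        if ratios[k] < crit:
            return k + 1
    return k_star + 1


def metrics(y_true: np.ndarray, y_hat: np.ndarray, context: str) -> FitMetrics:
    """RMSE and R-squared for one evaluation context (cal, cv or pred).

    R-squared is 1 - SSres/SStot about the mean of ``y_true``; with
    zero-variance reference values it is reported as missing.
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y_true.size != y_hat.size or y_true.size < 2:
        raise ValueError("metrics need two equal-length vectors of size >= 2")
    res = y_hat - y_true
    rmse = float(np.sqrt(np.mean(res**2)))
    sstot = float(np.sum((y_true - y_true.mean()) ** 2))
    r2 = None if sstot == 0 else float(1.0 - np.sum(res**2) / sstot)
    out = FitMetrics()
    if context == "cal":
        out.r2_cal, out.rmsec = r2, rmse
    elif context == "cv":
        out.r2_cv, out.rmsecv = r2, rmse
    elif context == "pred":
        out.r2_pred, out.rmsep = r2, rmse
    else:
        raise ValueError(f"unknown context {context!r}; expected cal, cv or pred")
    return out


def r2_correlation(y_true: np.ndarray, y_hat: np.ndarray) -> float:
    """Squared Pearson correlation — the alternative R-squared convention."""
    r = np.corrcoef(np.asarray(y_true, float), np.asarray(y_hat, float))[0, 1]
    return float(r * r)


# --------------------------------------------------------------------------
# serialization: one self-describing .npz (JSON metadata + array payload)

def save_model(model: PLSModel, path, chain=None) -> None:
    """Serialise a model (and optionally its fitted pretreatment chain)."""
    meta = {
        "intercept": model.intercept,
        "y_mean": model.y_mean,
        "n_lv": model.n_lv,
        "n_rows": model.n_rows,
        "n_cols": model.n_cols,
    }
    arrays = {
        "weights": model.weights,
        "x_loadings": model.x_loadings,
        "y_loadings": model.y_loadings,
        "coef": model.coef,
        "x_mean": model.x_mean,
        "var_index": model.var_index,
    }
    if chain is not None:
        meta["chain"] = {
            "steps": list(chain.steps),
            "window": chain.window,
            "polyorder": chain.polyorder,
            "log_base": chain.log_base,
        }
        if chain.column_means_ is not None:
            arrays["chain_column_means"] = chain.column_means_
        if chain.fitted_wavelengths_ is not None:
            arrays["chain_wavelengths"] = chain.fitted_wavelengths_
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_model(path):
    """Load a model saved by :func:`save_model`; returns (model, chain|None)."""
    from .pretreatment import PretreatmentChain

    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        model = PLSModel(
            weights=z["weights"],
            x_loadings=z["x_loadings"],
            y_loadings=z["y_loadings"],
            coef=z["coef"],
            intercept=float(meta["intercept"]),
            x_mean=z["x_mean"],
            y_mean=float(meta["y_mean"]),
            n_lv=int(meta["n_lv"]),
            var_index=z["var_index"],
            n_rows=int(meta["n_rows"]),
            n_cols=int(meta["n_cols"]),
        )
        chain = None
        if "chain" in meta:
            chain = PretreatmentChain(
                tuple(meta["chain"]["steps"]),
                window=int(meta["chain"]["window"]),
                polyorder=int(meta["chain"]["polyorder"]),
                log_base=meta["chain"]["log_base"],
            )
            if "chain_column_means" in z:
                chain.column_means_ = z["chain_column_means"]
            if "chain_wavelengths" in z:
                chain.fitted_wavelengths_ = z["chain_wavelengths"]
    return model, chain
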