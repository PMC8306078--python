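"""Wavelength-interval elimination and cross-validation outlier screening.

Two bespoke procedures sit here:

* **modified interval-PLS** — the retained spectral range is split into
  near-equal contiguous intervals; in a greedy backward loop, each round
  evaluates the cross-validated error of the model *without* each retained
  interval (re-selecting the component count per candidate) and
  permanently discards the single interval whose removal improves RMSECV
  the most, stopping when no removal helps.

* **cross-validation outlier indicator** — for each sample i, the squared
  left-out deviation relative to everyone else's:

      F_y(i) = (I - 1) (y_pred,i - y_nom,i)^2 / sum_{j != i} (y_pred,j - y_nom,j)^2

  judged against an F distribution with (1, I-1) degrees of freedom.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pls import CVRecord, loo_cv, select_lv

__all__ = [
    "IntervalScheme",
    "OutlierRecord",
    "make_intervals",
    "modified_ipls",
    "outlier_scores",
    "remove_outliers_refit",
]


@dataclass
class IntervalScheme:
    """Contiguous, non-overlapping index intervals partitioning a grid."""

    n_variables: int
    edges: tuple[tuple[int, int], ...]  # half-open [lo, hi) index ranges
    retained: np.ndarray  # boolean per interval

    def __post_init__(self) -> None:
        self.retained = np.asarray(self.retained, dtype=bool)
        if len(self.edges) != self.retained.size:
            raise ValueError("edges and retained flags disagree")
        pos = 0
        for lo, hi in self.edges:
            if lo != pos or hi <= lo:
                raise ValueError("intervals must be contiguous and non-empty")
            pos = hi
        if pos != self.n_variables:
            raise ValueError("intervals must cover the grid exactly")
        if not self.retained.any():
            raise ValueError("at least one interval must stay retained")

    @property
    def n_intervals(self) -> int:
        return len(self.edges)

    def indices(self, only_retained: bool = True) -> np.ndarray:
        sel = [
            np.arange(lo, hi)
            for (lo, hi), keep in zip(self.edges, self.retained)
            if keep or not only_retained
        ]
        return np.concatenate(sel)

    def drop(self, interval: int) -> "IntervalScheme":
        flags = self.retained.copy()
        flags[interval] = False
        return IntervalScheme(self.n_variables, self.edges, flags)

    def as_nm_ranges(self, wavelengths: np.ndarray) -> str:
        """Retained intervals as endpoint-inclusive nm ranges, merged when
        adjacent, e.g. ``"1475-1495, 1525-1545"``."""
        idx = self.indices()
        if idx.size == 0:
            return ""
        runs = []
        start = prev = idx[0]
        for i in idx[1:]:
            if i == prev + 1:
                prev = i
                continue
            runs.append((start, prev))
            start = prev = i
        runs.append((start, prev))
        return ", ".join(
            f"{wavelengths[a]:g}-{wavelengths[b]:g}" for a, b in runs
        )


def make_intervals(n_variables_or_grid, n_intervals: int) -> IntervalScheme:
    """Split a grid (or its length) into near-equal contiguous intervals.

    When the count does not divide evenly, earlier intervals take the
    extra variable (10 into 3 -> sizes 4, 3, 3).
    """
    n = (
        int(n_variables_or_grid)
        if np.isscalar(n_variables_or_grid)
        else len(n_variables_or_grid)
    )
    if n_intervals < 1:
        raise ValueError("need at least one interval")
    if n_intervals > n:
        raise ValueError(f"cannot split {n} variables into {n_intervals} intervals")
    base, rem = divmod(n, n_intervals)
    edges = []
    pos = 0
    for i in range(n_intervals):
        size = base + (1 if i < rem else 0)
        edges.append((pos, pos + size))
        pos += size
    return IntervalScheme(n, tuple(edges), np.ones(n_intervals, dtype=bool))


def _cv_rmsecv(X, y, cols, max_lv, prob_threshold):
    sub = X[:, cols]
    lv_cap = min(max_lv, sub.shape[1], sub.shape[0] - 2)
    cv = loo_cv(sub, y, lv_cap)
    k = select_lv(cv, prob_threshold=prob_threshold)
    return cv.rmsecv(k), k, cv


def modified_ipls(
    X: np.ndarray,
    y: np.ndarray,
    scheme: IntervalScheme,
    max_lv: int = 20,
    prob_threshold: float = 0.75,
    rel_tol: float = 1e-9,
) -> tuple[IntervalScheme, pd.DataFrame]:
    """Greedy backward interval elimination driven by LOO RMSECV.

    Returns the retained scheme and a full audit trace with one row per
    (round, candidate interval) evaluation.  The component count is
    re-selected for every candidate.  Ties in improvement go to the
    interval starting at the lower wavelength.  The final retained RMSECV
    can never exceed the full-spectrum RMSECV, because removals are only
    accepted when they improve it by more than ``rel_tol`` times the
    response scale (which keeps float jitter on exactly-fit data from
    triggering removals).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if scheme.n_intervals < 2:
        raise ValueError("interval elimination needs at least 2 intervals")
    tol = rel_tol * float(np.std(y))
    current = scheme
    current_rmsecv, current_lv, _ = _cv_rmsecv(
        X, y, current.indices(), max_lv, prob_threshold
    )
    rows = [
        {
            "round": 0,
            "candidate_interval": -1,
            "rmsecv": current_rmsecv,
            "n_lv": current_lv,
            "removed": False,
        }
    ]
    rnd = 0
    while current.retained.sum() > 1:
        rnd += 1
        best_i, best_rmsecv, best_lv = None, current_rmsecv, None
        for i in np.flatnonzero(current.retained):
            cand = current.drop(int(i))
            rmsecv, k, _ = _cv_rmsecv(X, y, cand.indices(), max_lv, prob_threshold)
            rows.append(
                {
                    "round": rnd,
                    "candidate_interval": int(i),
                    "rmsecv": rmsecv,
                    "n_lv": k,
                    "removed": False,
                }
            )
            if rmsecv < best_rmsecv - tol:  # ties keep the earlier candidate
                best_i, best_rmsecv, best_lv = int(i), rmsecv, k
        if best_i is None:
            break
        current = current.drop(best_i)
        current_rmsecv, current_lv = best_rmsecv, best_lv
        for r in rows:
            if r["round"] == rnd and r["candidate_interval"] == best_i:
                r["removed"] = True
    return current, pd.DataFrame(rows)


@dataclass
class OutlierRecord:
    """Per-sample cross-validation outlier statistics."""

    f_values: np.ndarray
    numerators: np.ndarray  # (y_pred,i - y_nom,i)^2
    denominators: np.ndarray  # sum over the other samples
    p_values: np.ndarray  # upper-tail probability, F(1, I-1)
    flags: np.ndarray
    alpha: float
    dof: tuple[int, int] = field(default=(1, 0))

    @property
    def n_samples(self) -> int:
        return self.f_values.size


def outlier_scores(cv: CVRecord, n_lv: int, alpha: float = 0.01) -> OutlierRecord:
    """The left-out deviation indicator F_y(i) at the chosen component count.

    A sample is flagged when the upper-tail probability of its F_y(i)
    under F(1, I-1) falls below ``alpha``.
    """
    I = cv.n_samples
    if I < 3:
        raise ValueError("outlier screening needs at least 3 samples")
    e2 = cv.residuals(n_lv) ** 2
    total = float(e2.sum())
    den = total - e2
    with np.errstate(divide="ignore", invalid="ignore"):
        f_vals = np.where(den > 0, (I - 1) * e2 / den, np.inf)
    p_vals = stats.f.sf(f_vals, 1, I - 1)
    flags = p_vals < alpha
    return OutlierRecord(
        f_values=f_vals,
        numerators=e2,
        denominators=den,
        p_values=p_vals,
        flags=flags,
        alpha=alpha,
        dof=(1, I - 1),
    )


def remove_outliers_refit(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.01,
    max_rounds: int = 10,
    floor_fraction: float = 0.8,
    max_lv: int = 20,
    prob_threshold: float = 0.75,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Iteratively drop the most significant left-out outlier and refit.

    Stops when no sample is flagged, ``max_rounds`` is reached, or the
    sample count would fall below ``floor_fraction`` of the input.
    Returns the cleaned (X, y) and a removal log carrying the original row
    indices.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    keep = np.arange(y.size)
    log_rows = []
    floor = int(np.ceil(floor_fraction * y.size))
    for rnd in range(1, max_rounds + 1):
        if keep.size <= max(floor, 3):
            break
        cv = loo_cv(X[keep], y[keep], min(max_lv, keep.size - 2, X.shape[1]))
        k = select_lv(cv, prob_threshold=prob_threshold)
        rec = outlier_scores(cv, k, alpha=alpha)
        if not rec.flags.any():
            break
        worst_local = int(np.argmax(np.where(rec.flags, rec.f_values, -np.inf)))
        log_rows.append(
            {
                "round": rnd,
                "sample_index": int(keep[worst_local]),
                "f_value": float(rec.f_values[worst_local]),
                "p_value": float(rec.p_values[worst_local]),
                "n_lv": k,
            }
        )
        keep = np.delete(keep, worst_local)
    log = pd.DataFrame(
        log_rows, columns=["round", "sample_index", "f_value", "p_value", "n_lv"]
    )
    return X[keep], y[keep], log
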