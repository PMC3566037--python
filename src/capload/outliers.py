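"""Multivariate outlier screening by Hadi's forward search.

The screen is applied at every residualisation step of the pipeline, on the
bivariate (regressor, outcome) scatter, before the least-squares line is
fitted.  The algorithm:

1. Distances from the coordinate-wise median, scaled by the covariance of
   deviations from that median; the 50% of records nearest the median then
   provide a robust mean/covariance, and distances are recomputed.
2. The p + 1 cleanest records form the basic subset.
3. The basic subset grows one record at a time: re-estimate its mean and
   covariance, re-rank all records by squared Mahalanobis distance, and take
   the cleanest (current size + 1), until it holds h = floor((n + p + 1)/2)
   records.
4. Growth then continues under the outlier test: with the basic-subset
   covariance inflated by the small-sample factor
   1 + (p+1)/(n-p) + 2/(n-1-3p), the subset keeps absorbing the cleanest
   (size + 1) records while the (size+1)-th ordered squared distance stays
   within the chi-square(p) quantile at 1 - alpha/n.  When the nearest
   outside record fails the test (or the subset holds all records), records
   whose squared distance from the final estimates exceeds the cutoff are
   declared outliers.  On outlier-free data the subset absorbs essentially
   the whole sample, so the test is calibrated against the full-sample
   covariance and the expected number of false flags per dataset is of
   order alpha.

The procedure is deterministic; ranking ties are broken by record index so
runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateGeometryError, InsufficientDataError, SchemaError

__all__ = ["OutlierReport", "hadi_outliers", "remove_outliers"]


@dataclass
class OutlierReport:
    """Outcome of one Hadi screen."""

    flags: np.ndarray                 # bool per record, True = outlier
    distances: np.ndarray             # final robust squared distances
    cutoff: float                     # chi-square threshold on squared distance
    trace: list[int] = field(default_factory=list)  # basic-subset sizes visited
    alpha: float = 0.05
    step: str = ""
    record_ids: np.ndarray | None = None  # ids aligned with flags, if known

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())

    def flagged_ids(self) -> list:
        if self.record_ids is None:
            return np.flatnonzero(self.flags).tolist()
        return np.asarray(self.record_ids)[self.flags].tolist()

    def to_dict(self) -> dict:
        return {
            "step": self.step,
            "alpha": self.alpha,
            "cutoff": self.cutoff,
            "n": int(self.flags.size),
            "n_flagged": self.n_flagged,
            "flagged_ids": self.flagged_ids(),
            "trace": list(self.trace),
        }


def _mahalanobis_sq(X: np.ndarray, mean: np.ndarray, cov: np.ndarray,
                    context: str) -> np.ndarray:
    """Squared Mahalanobis distances; analytic inverses for p <= 2."""
    d = X - mean
    p = X.shape[1]
    tol = 1e-12 * max(1.0, float(np.trace(cov)) ** p)
    if p == 1:
        v = cov[0, 0]
        if v <= tol:
            raise DegenerateGeometryError(
                f"zero variance during Hadi search ({context})")
        return d[:, 0] ** 2 / v
    if p == 2:
        det = cov[0, 0] * cov[1, 1] - cov[0, 1] ** 2
        if det <= tol:
            raise DegenerateGeometryError(
                f"singular covariance during Hadi search ({context}); "
                "columns are collinear or constant")
        return (d[:, 0] ** 2 * cov[1, 1] - 2.0 * d[:, 0] * d[:, 1] * cov[0, 1]
                + d[:, 1] ** 2 * cov[0, 0]) / det
    try:
        c = np.linalg.cholesky(cov)
        if np.any(np.diag(c) < 1e-10 * max(1.0, float(np.trace(cov)))):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        raise DegenerateGeometryError(
            f"singular covariance during Hadi search ({context}); "
            "columns are collinear or constant")
    sol = np.linalg.solve(c, d.T)
    return np.einsum("ij,ij->j", sol, sol)


def _stable_order(d: np.ndarray) -> np.ndarray:
    # mergesort is stable: ties resolved by record index
    return np.argsort(d, kind="stable")


def hadi_outliers(X, alpha: float = 0.05, step: str = "",
                  record_ids=None) -> OutlierReport:
    """Run Hadi's forward search on an (n, p) matrix with no missing values."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if p < 1:
        raise SchemaError("need at least one variable")
    if not np.isfinite(X).all():
        raise SchemaError("hadi_outliers requires complete data; handle missingness first")
    if n < p + 2:
        raise InsufficientDataError(f"need n >= p + 2 records (n={n}, p={p})")
    if not 0.0 < alpha < 1.0:
        raise SchemaError(f"alpha must be in (0, 1), got {alpha}")

    trace: list[int] = []

    # --- step 1: robust start ------------------------------------------
    med = np.median(X, axis=0)
    dev = X - med
    cov_med = dev.T @ dev / (n - 1)
    d0 = _mahalanobis_sq(X, med, cov_med, "median start")
    half = int(np.ceil((n + p + 1) / 2))
    nearest = _stable_order(d0)[:half]
    mean_h = X[nearest].mean(axis=0)
    cov_h = np.cov(X[nearest], rowvar=False, ddof=1).reshape(p, p)
    d1 = _mahalanobis_sq(X, mean_h, cov_h, "half-sample start")

    # --- steps 2-4: forward search with chi-square stopping --------------
    h = (n + p + 1) // 2
    # small-sample inflation; the last term assumes n > 3p + 1 and is dropped
    # below that (it would be zero or negative)
    cf = 1.0 + (p + 1) / (n - p)
    if n - 1 - 3 * p > 0:
        cf += 2.0 / (n - 1 - 3 * p)
    cutoff = float(stats.chi2.ppf(1.0 - alpha / n, df=p))

    def smallest(d: np.ndarray, k: int) -> np.ndarray:
        """Indices of the k smallest distances; ties broken by record index."""
        if k >= d.size:
            return np.arange(d.size)
        vmax = np.partition(d, k - 1)[:k].max()
        below = np.flatnonzero(d < vmax)
        ties = np.flatnonzero(d == vmax)[: k - below.size]
        return np.concatenate([below, ties])

    basic = smallest(d1, p + 1)
    trace.append(basic.size)
    d_prev = d1
    while True:
        r = basic.size
        Xb = X[basic]
        mean_b = Xb.mean(axis=0)
        dev_b = Xb - mean_b
        cov_b = dev_b.T @ dev_b / (r - 1)
        try:
            d = _mahalanobis_sq(X, mean_b, cf * cov_b, f"subset size {r}")
        except DegenerateGeometryError:
            if r < h:
                # a degenerate small subset (e.g. collinear p+1 points) is
                # grown by the previous ranking, as in the original method
                basic = smallest(d_prev, r + 1)
                trace.append(basic.size)
                continue
            raise
        d_prev = d
        if r >= n:
            break
        # the (r+1)-th ordered distance: the record the subset would absorb
        next_d = np.partition(d, r)[: r + 1].max()
        if r >= h and next_d > cutoff:
            # nearest outside record fails the outlier test: stop
            break
        below = np.flatnonzero(d < next_d)
        ties = np.flatnonzero(d == next_d)[: r + 1 - below.size]
        basic = np.concatenate([below, ties])
        trace.append(basic.size)

    d_final = d_prev
    flags = d_final > cutoff

    return OutlierReport(
        flags=flags,
        distances=d_final,
        cutoff=cutoff,
        trace=trace,
        alpha=alpha,
        step=step,
        record_ids=None if record_ids is None else np.asarray(record_ids),
    )


def remove_outliers(table: pd.DataFrame, columns: list[str], alpha: float = 0.05,
                    step: str = "", ledger=None,
                    id_column: str = "id") -> tuple[pd.DataFrame, OutlierReport]:
    """Screen ``columns`` of ``table`` and drop flagged records.

    Only records complete in ``columns`` are screened; incomplete records are
    retained untouched (missingness is handled per derived variable, not
    here).  Removals are recorded on the exclusion ledger under ``step``.
    """
    missing_cols = [c for c in columns if c not in table.columns]
    if missing_cols:
        raise SchemaError(f"columns absent from table: {missing_cols}")
    complete = table[columns].notna().all(axis=1)
    sub = table.loc[complete]
    ids = sub[id_column].to_numpy() if id_column in table.columns else sub.index.to_numpy()
    report = hadi_outliers(sub[columns].to_numpy(float), alpha=alpha, step=step,
                           record_ids=ids)
    flagged_index = sub.index[report.flags]
    cleaned = table.drop(index=flagged_index)
    if ledger is not None and step:
        ledger.record(step, report.flagged_ids(),
                      reason=f"Hadi screen on {columns} at alpha={alpha}")
    return cleaned, report
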