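"""Mutation-accumulation curve M(1/f) and its phase structure.

M(u) is the cumulative number of mutations with inverse allele frequency at
most u; under neutral exponential growth it is linear in u with slope
proportional to the per-division mutation rate, so changes of slope mark
phases of the expansion. Phases are estimated by continuous piecewise-linear
(segmented) regression with breakpoints optimised by Muggeo-style iterative
linearisation, their significance by Davies' bound for a slope change with a
nuisance breakpoint, and overfitting is checked by k-fold cross-validation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

BIN_HALFWIDTH = 0.25   # on u = 1/f, for the bootstrap confidence bands


@dataclass
class MafCurve:
    """Sorted inverse-allele-frequency grid with cumulative mutation counts.

    u is strictly ascending; ties in 1/f share one grid point with the
    cumulative count jumping by the tie multiplicity.
    """

    u: np.ndarray
    m: np.ndarray
    bin_centers: np.ndarray | None = None
    bin_counts: np.ndarray | None = None
    ci_lo: np.ndarray | None = None        # cumulative-count band per bin
    ci_hi: np.ndarray | None = None
    bin_halfwidth: float = BIN_HALFWIDTH

    def __post_init__(self) -> None:
        assert np.all(np.diff(self.u) > 0), "u must be strictly ascending"
        assert np.all(np.diff(self.m) >= 0), "M must be nondecreasing"


def build_maf_curve(records: pd.DataFrame) -> MafCurve:
    """Cumulative mutation count over ascending u = 1/f.

    Expects pre-filtered records with an ``f`` column in (0, 1].
    """
    if len(records) == 0:
        raise ValueError("no variants")
    f = records["f"].to_numpy(dtype=float)
    if np.any(f <= 0) or np.any(f > 1):
        raise ValueError("allele frequencies must lie in (0, 1]")
    u = np.sort(1.0 / f)
    m_all = np.arange(1, len(u) + 1, dtype=float)
    uniq, last_idx = np.unique(u[::-1], return_index=True)
    # last occurrence of each unique u in ascending order -> cumulative count
    m = m_all[len(u) - 1 - last_idx]
    return MafCurve(u=uniq, m=m)


def bootstrap_curve_ci(curve: MafCurve, B: int = 1000, seed: int = 0) -> MafCurve:
    """95% bootstrap bands on the binned and cumulative mutation counts.

    Mutations are binned on u (centres at multiples of 2*half-width,
    edges left-closed right-open); the vector of bin counts is resampled
    B times as a multinomial over bins (mutation-level resampling with
    replacement); bands are the 2.5/97.5 percentiles, propagated to the
    cumulative curve by per-replicate cumulative sums.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    rng = np.random.default_rng(seed)
    width = 2 * curve.bin_halfwidth
    # expand the tie-collapsed curve back to one entry per mutation
    counts_per_u = np.diff(curve.m, prepend=0.0)
    u_all = np.repeat(curve.u, counts_per_u.astype(int))
    lo_i = int(np.floor(u_all.min() / width + 0.5))
    hi_i = int(np.floor(u_all.max() / width + 0.5))
    centers = np.arange(lo_i, hi_i + 1) * width
    edges = np.concatenate([centers - curve.bin_halfwidth,
                            [centers[-1] + curve.bin_halfwidth]])
    bin_counts, _ = np.histogram(u_all, bins=edges)
    n = int(bin_counts.sum())
    p = bin_counts / n
    reps = rng.multinomial(n, p, size=B)
    cum = np.cumsum(reps, axis=1)
    curve.bin_centers = centers
    curve.bin_counts = bin_counts.astype(float)
    curve.ci_lo = np.percentile(cum, 2.5, axis=0)
    curve.ci_hi = np.percentile(cum, 97.5, axis=0)
    return curve


def bin_ci(counts: int, B: int = 1000, seed: int = 0) -> tuple[float, float]:
    """95% bootstrap CI of a single bin count (Poisson-like width ~2*1.96*sqrt(c))."""
    if counts == 0:
        return (0.0, 0.0)
    rng = np.random.default_rng(seed)
    reps = rng.poisson(counts, size=B)
    return (float(np.percentile(reps, 2.5)), float(np.percentile(reps, 97.5)))


# ---------------------------------------------------------------------------
# Segmented (continuous piecewise-linear) regression

@dataclass
class SegmentationFit:
    """A continuous piecewise-linear fit of M on u."""

    breakpoints: np.ndarray          # strictly ascending, interior to the u range
    slopes: np.ndarray               # one per segment (k+1)
    intercept: float                 # intercept of the first segment
    adj_r2: float
    rss: float
    n: int
    objective_met: bool = True
    davies_p: float | None = None
    cv_table: pd.DataFrame | None = None

    @property
    def k(self) -> int:
        return len(self.breakpoints)

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = self.intercept + self.slopes[0] * x
        for j, bp in enumerate(self.breakpoints):
            y += (self.slopes[j + 1] - self.slopes[j]) * np.maximum(x - bp, 0.0)
        return y

    def segment_intercepts(self) -> np.ndarray:
        """Intercept of each segment's extended line."""
        out = [self.intercept]
        for j, bp in enumerate(self.breakpoints):
            out.append(out[-1] - (self.slopes[j + 1] - self.slopes[j]) * bp)
        return np.asarray(out)


def _fit_fixed_breaks(x: np.ndarray, y: np.ndarray, psi: np.ndarray):
    """OLS with hinge terms at fixed breakpoints; returns (coef, rss)."""
    cols = [np.ones_like(x), x] + [np.maximum(x - b, 0.0) for b in psi]
    X = np.column_stack(cols)
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef, float(resid @ resid)

def _muggeo(x: np.ndarray, y: np.ndarray, psi0: np.ndarray,
            max_iter: int = 30, tol: float = 1e-6):
    """One run of iterative linearisation from initial breakpoints psi0.

    Returns (psi, coef, rss) or None when the run degenerates (breakpoints
    collapse or leave the data range).
    """
    x_lo, x_hi = x.min(), x.max()
    span = x_hi - x_lo
    psi = np.sort(psi0.astype(float))
    for _ in range(max_iter):
        U = [np.maximum(x - b, 0.0) for b in psi]
        V = [-(x > b).astype(float) for b in psi]
        X = np.column_stack([np.ones_like(x), x] + U + V)
        coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < X.shape[1]:
            return None
        k = len(psi)
        beta = coef[2:2 + k]
        gamma = coef[2 + k:]
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(np.abs(beta) > 1e-12, gamma / beta, 0.0)
        new_psi = np.sort(psi + step)
        eps = 0.02 * span
        new_psi = np.clip(new_psi, x_lo + eps, x_hi - eps)
        if np.any(np.diff(new_psi) < eps / 2):
            return None
        if np.max(np.abs(new_psi - psi)) < tol * span:
            psi = new_psi
            break
        psi = new_psi
    coef, rss = _fit_fixed_breaks(x, y, psi)
    return psi, coef, rss


def _adj_r2(rss: float, y: np.ndarray, n_params: int) -> float:
    n = len(y)
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        return 1.0
    dof = max(n - n_params, 1)
    return 1.0 - (rss / dof) / (tss / (n - 1))


def _fit_k_breaks(x: np.ndarray, y: np.ndarray, k: int, seed: int,
                  restarts: int = 5) -> tuple[np.ndarray, np.ndarray, float] | None:
    """Best continuous piecewise-linear fit with exactly k breakpoints,
    from quantile-grid starts plus random jittered restarts."""
    if k == 0:
        coef, rss = _fit_fixed_breaks(x, y, np.array([]))
        return np.array([]), coef, rss
    rng = np.random.default_rng(seed)
    quantiles = np.linspace(0, 1, k + 2)[1:-1]
    base = np.quantile(x, quantiles)
    span = x.max() - x.min()
    starts = [base]
    for _ in range(restarts - 1):
        starts.append(np.sort(base + rng.normal(0, 0.08 * span, size=k)))
    best = None
    for psi0 in starts:
        res = _muggeo(x, y, psi0)
        if res is None:
            continue
        if best is None or res[2] < best[2]:
            best = res
    return best


def fit_segmented(curve: MafCurve | tuple[np.ndarray, np.ndarray],
                  target_adj_r2: float = 0.9995,
                  max_breakpoints: int = 20,
                  seed: int = 0, restarts: int = 5) -> SegmentationFit:
    """Fit segmented regressions with increasing numbers of breakpoints and
    return the smallest k whose adjusted R^2 reaches the target.

    The parameter count for adjusted R^2 is 2(k+1): k breakpoints, k+1
    slopes and one intercept under the continuity constraint. If even
    ``max_breakpoints`` misses the target, the k = max fit is returned
    flagged ``objective_met=False``.
    """
    x, y = (curve.u, curve.m) if isinstance(curve, MafCurve) else curve
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    best_fit = None
    for k in range(max_breakpoints + 1):
        if len(x) < 2 * (k + 1):
            break
        res = _fit_k_breaks(x, y, k, seed=seed + 7 * k, restarts=restarts)
        if res is None:
            continue
        psi, coef, rss = res
        slopes = np.concatenate([[coef[1]], coef[1] + np.cumsum(coef[2:])]) \
            if k > 0 else np.array([coef[1]])
        fit = SegmentationFit(breakpoints=psi, slopes=slopes,
                              intercept=float(coef[0]),
                              adj_r2=_adj_r2(rss, y, 2 * (k + 1)),
                              rss=rss, n=len(x))
        if best_fit is None or fit.adj_r2 > best_fit.adj_r2:
            best_fit = fit
        if fit.adj_r2 >= target_adj_r2:
            return fit
    assert best_fit is not None
    best_fit.objective_met = False
    logger.warning("fit_segmented: objective adj R^2 %.5f not met (best %.5f at k=%d)",
                   target_adj_r2, best_fit.adj_r2, best_fit.k)
    return best_fit


# ---------------------------------------------------------------------------
# Davies' test for a slope change with a nuisance breakpoint

def davies_test(x: np.ndarray, y: np.ndarray, n_points: int = 10) -> float:
    """Davies (1987) bound for the significance of a change in slope.

    The t statistic for adding a hinge (x - psi)_+ to the linear model is
    evaluated on a grid of candidate breakpoints psi (quantiles of x); the
    two-sided p-value for the best candidate is adjusted for the scan with
    the bound  p <= Pr(Z > M) + V * exp(-M^2/2) / sqrt(8*pi), doubled,
    where M = max |t| and V is the total variation of the t process over
    the grid. Degenerate (constant) responses return p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.allclose(y, y[0]) or len(x) < 5:
        return 1.0
    psis = np.quantile(x, np.linspace(0.05, 0.95, n_points))
    X0 = np.column_stack([np.ones_like(x), x])
    tvals = np.empty(len(psis))
    for i, psi in enumerate(psis):
        X = np.column_stack([X0, np.maximum(x - psi, 0.0)])
        coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < 3:
            tvals[i] = 0.0
            continue
        resid = y - X @ coef
        dof = len(x) - 3
        s2 = resid @ resid / dof
        xtx_inv = np.linalg.pinv(X.T @ X)
        se = np.sqrt(s2 * xtx_inv[2, 2])
        tvals[i] = coef[2] / se if se > 0 else 0.0
    M = float(np.max(np.abs(tvals)))
    V = float(np.sum(np.abs(np.diff(tvals))))
    p_one = stats.norm.sf(M) + V * np.exp(-M * M / 2.0) / np.sqrt(8.0 * np.pi)
    return float(min(1.0, 2.0 * p_one))


def davies_test_curve(curve: MafCurve, fit: SegmentationFit | None = None,
                      n_points: int = 10) -> float:
    p = davies_test(curve.u, curve.m, n_points=n_points)
    if fit is not None:
        fit.davies_p = p
    return p


# ---------------------------------------------------------------------------
# Cross-validation of the segment count

def kfold_cv_segmentation(curve: MafCurve | tuple[np.ndarray, np.ndarray],
                          candidate_ks: list[int],
                          k_folds: int = 10, seed: int = 0,
                          restarts: int = 3) -> pd.DataFrame:
    """k-fold cross-validation of the segmented fit across breakpoint counts.

    Points are assigned to folds at random (fixed seed). For each candidate
    breakpoint count: ``test_mse`` is the held-out MSE, ``validation_mse``
    the in-sample (training) MSE, both averaged over folds; a difference
    that does not increase when adding one more phase indicates the absence
    of overfitting.
    """
    x, y = (curve.u, curve.m) if isinstance(curve, MafCurve) else curve
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    max_params = 2 * (max(candidate_ks) + 1)
    if len(x) < max(k_folds, 2) * max_params / 2:
        raise ValueError(f"too few points ({len(x)}) for {k_folds}-fold CV "
                         f"with up to {max(candidate_ks)} breakpoints")
    rng = np.random.default_rng(seed)
    fold = rng.integers(0, k_folds, size=len(x))
    rows = []
    for k in candidate_ks:
        test_mses, val_mses = [], []
        for fo in range(k_folds):
            train = fold != fo
            if train.sum() < 2 * (k + 1) or (~train).sum() == 0:
                continue
            res = _fit_k_breaks(x[train], y[train], k, seed=seed + 13 * k + fo,
                                restarts=restarts)
            if res is None:
                continue
            psi, coef, rss = res
            slopes = (np.concatenate([[coef[1]], coef[1] + np.cumsum(coef[2:])])
                      if k > 0 else np.array([coef[1]]))
            fit = SegmentationFit(breakpoints=psi, slopes=slopes,
                                  intercept=float(coef[0]), adj_r2=np.nan,
                                  rss=rss, n=int(train.sum()))
            pred_test = fit.predict(x[~train])
            test_mses.append(float(np.mean((y[~train] - pred_test) ** 2)))
            val_mses.append(rss / train.sum())
        rows.append({"k": k, "test_mse": float(np.mean(test_mses)),
                     "validation_mse": float(np.mean(val_mses)),
                     "difference": float(np.mean(test_mses) - np.mean(val_mses))})
    return pd.DataFrame(rows)


def trim_outer_phases(fit: SegmentationFit,
                      u_range: tuple[float, float] | None = None
                      ) -> tuple[float, float]:
    """Accepted u-range between the first and last breakpoints.

    Mutations below the first breakpoint (clonal / normal-tissue
    contamination) and above the last (detection limit) are excluded
    downstream. With fewer than two breakpoints the full range is returned
    with a warning.
    """
    if fit.k < 2:
        warnings.warn("fewer than 2 breakpoints; accepted range is the full range")
        if u_range is not None:
            return u_range
        return (-np.inf, np.inf)
    return (float(fit.breakpoints[0]), float(fit.breakpoints[-1]))


def restrict_to_range(records: pd.DataFrame, u_range: tuple[float, float]) -> pd.DataFrame:
    """Keep variants whose u = 1/f lies inside the accepted range (closed)."""
    u = 1.0 / records["f"].to_numpy(dtype=float)
    return records[(u >= u_range[0]) & (u <= u_range[1])].reset_index(drop=True)
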