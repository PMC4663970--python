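"""Least-squares fitting, optimal output scaling, and lasso predictor selection.

Every estimator in the hierarchy is linear in its weights once its
predictor vectors are formed, so fitting is ordinary least squares on the
clip-by-predictor matrix against the true velocities.  Accuracy is
summarized by the correlation coefficient r between estimate and velocity:
after scaling an estimator's output by r * sigma_v / sigma_R (the
MSE-optimal gain), its mean squared error is exactly

    epsilon = sigma_v^2 (1 - r^2),

so r and the MSE carry the same information and r is reported throughout.

Cross-validation is twofold with mirror pairs as atomic units: a motion
and its left-right reflection always land in the same fold, preserving the
exact symmetrization within each fold.  Repeating the split (20 times by
default) gives a standard deviation for the accuracy.

Lasso selection z-scores the predictors (so the L1 penalty is comparable
across monomials of very different magnitudes), sweeps a logarithmic
penalty grid, and refits each selected support by plain OLS -- the penalty
chooses the predictors, never their final weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import Lasso

__all__ = ["FitResult", "LassoScan", "ols_fit", "scale_output", "lasso_scan", "paired_split"]


@dataclass
class FitResult:
    """Cross-validated least-squares fit of one predictor set."""

    weights: np.ndarray
    r_train: float
    r_test: float
    mse_test: float  # after optimal scaling, (deg/s)^2
    scale: float  # r * sigma_v / sigma_R on the held-out fold
    n_splits: int
    accuracy_sd: float  # SD of r_test across splits

    def to_dict(self) -> dict:
        return {
            "weights": np.asarray(self.weights).tolist(),
            "r_train": self.r_train,
            "r_test": self.r_test,
            "mse_test": self.mse_test,
            "scale": self.scale,
            "n_splits": self.n_splits,
            "accuracy_sd": self.accuracy_sd,
        }


@dataclass
class LassoScan:
    """Support-size versus accuracy sweep from an L1 penalty grid."""

    penalties: np.ndarray
    supports: list = field(default_factory=list)  # predictor index arrays
    support_sizes: np.ndarray | None = None
    refit_r: np.ndarray | None = None  # test r after OLS refit per support
    gain_fraction: np.ndarray | None = None  # (r - r_base) / (r_full - r_base)

    def to_frame(self):
        import pandas as pd

        d = {
            "penalty": self.penalties,
            "support_size": self.support_sizes,
            "refit_r": self.refit_r,
        }
        if self.gain_fraction is not None:
            d["gain_fraction"] = self.gain_fraction
        return pd.DataFrame(d)


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return 0.0
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def scale_output(raw: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, float]:
    """Apply the MSE-optimal gain r * sigma_v / sigma_R to raw estimates.

    Returns ``(scaled, scale)``.  The gain equals cov(raw, v) / var(raw),
    so its sign follows the correlation, and it is applied about the sample
    means, which makes MSE = sigma_v^2 (1 - r^2) an exact finite-sample
    identity whenever the velocities are zero-mean (they are, exactly, on
    any mirror-paired fold).  A zero-variance (null) estimator yields all
    zeros with a warning rather than failing.
    """
    raw = np.asarray(raw, float)
    v = np.asarray(v, float)
    var_r = raw.var()
    if var_r == 0.0:
        warnings.warn("estimator output has zero variance; returning the null estimate")
        return np.zeros_like(v), 0.0
    scale = float(np.mean((raw - raw.mean()) * (v - v.mean())) / var_r)
    return v.mean() + scale * (raw - raw.mean()), scale


def paired_split(
    n_rows: int, rng: np.random.Generator, pair_size: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Random 50/50 row split keeping consecutive blocks of pair_size together."""
    if n_rows % pair_size:
        raise ValueError("row count is not a multiple of the pair size")
    n_pairs = n_rows // pair_size
    perm = rng.permutation(n_pairs)
    half = n_pairs // 2
    train = (perm[:half][:, None] * pair_size + np.arange(pair_size)).ravel()
    test = (perm[half:][:, None] * pair_size + np.arange(pair_size)).ravel()
    return np.sort(train), np.sort(test)


def _solve_ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    w, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        warnings.warn(
            f"rank-deficient design ({rank}/{X.shape[1]}); minimum-norm solution returned"
        )
    return w


def ols_fit(
    X: np.ndarray,
    v: np.ndarray,
    n_splits: int = 20,
    seed: int = 0,
    pair_size: int = 2,
) -> FitResult:
    """Twofold cross-validated least squares with mirror pairs kept intact.

    Weights minimize the training-fold MSE (no intercept: the velocity
    prior is zero-mean and constant predictors are excluded); the reported
    r is on the held-out fold, with ``accuracy_sd`` the SD of that r over
    ``n_splits`` random divisions.  The returned weights, scale, and MSE
    come from the first split; r values are means across splits.
    """
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] == np.asarray(v).size and X.ndim == 2:
        pass
    v = np.asarray(v, float)
    rng = np.random.default_rng(seed)
    r_trains, r_tests = [], []
    weights0 = scale0 = mse0 = None
    for s in range(n_splits):
        tr, te = paired_split(X.shape[0], rng, pair_size)
        w = _solve_ols(X[tr], v[tr])
        r_trains.append(_corr(X[tr] @ w, v[tr]))
        raw_te = X[te] @ w
        r_te = _corr(raw_te, v[te])
        r_tests.append(r_te)
        if s == 0:
            scaled, scale = scale_output(raw_te, v[te])
            weights0, scale0 = w, scale
            mse0 = float(np.mean((scaled - v[te]) ** 2))
    return FitResult(
        weights=weights0,
        r_train=float(np.mean(r_trains)),
        r_test=float(np.mean(r_tests)),
        mse_test=mse0,
        scale=scale0,
        n_splits=n_splits,
        accuracy_sd=float(np.std(r_tests)),
    )


def default_penalty_grid(X: np.ndarray, v: np.ndarray, n: int = 30) -> np.ndarray:
    """Log-spaced grid from the smallest all-zero penalty down 4 decades."""
    Xs = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    alpha_max = np.max(np.abs(Xs.T @ v)) / X.shape[0]
    return np.geomspace(alpha_max, alpha_max * 1e-4, n)


def lasso_scan(
    X: np.ndarray,
    v: np.ndarray,
    penalty_grid: np.ndarray | None = None,
    seed: int = 0,
    pair_size: int = 2,
    r_baseline: float | None = None,
    max_iter: int = 5000,
) -> LassoScan:
    """Sweep an L1 penalty, extract supports, and OLS-refit each support.

    Predictors are z-scored for the lasso step only; the refit uses the
    original columns, so reported weights and accuracies are penalty-free.
    ``r_baseline`` (e.g. the HRC's test r) and the full-support refit give
    the gain fraction (r - r_base) / (r_full - r_base) per support.
    """
    X = np.asarray(X, float)
    v = np.asarray(v, float)
    if penalty_grid is None:
        penalty_grid = default_penalty_grid(X, v)
    penalty_grid = np.asarray(penalty_grid, float)
    if penalty_grid.size == 0:
        raise ValueError("empty penalty grid")

    rng = np.random.default_rng(seed)
    tr, te = paired_split(X.shape[0], rng, pair_size)
    mu, sd = X[tr].mean(axis=0), X[tr].std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs_tr = (X[tr] - mu) / sd

    supports, sizes, refit_rs = [], [], []
    for alpha in np.sort(penalty_grid)[::-1]:
        lasso = Lasso(alpha=alpha, fit_intercept=False, max_iter=max_iter)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence chatter at tiny alphas
            lasso.fit(Xs_tr, v[tr])
        support = np.flatnonzero(lasso.coef_)
        supports.append(support)
        sizes.append(support.size)
        if support.size == 0:
            refit_rs.append(0.0)
            continue
        w = _solve_ols(X[tr][:, support], v[tr])
        refit_rs.append(_corr(X[te][:, support] @ w, v[te]))

    scan = LassoScan(
        penalties=np.sort(penalty_grid)[::-1],
        supports=supports,
        support_sizes=np.asarray(sizes),
        refit_r=np.asarray(refit_rs),
    )
    if r_baseline is not None:
        w_full = _solve_ols(X[tr], v[tr])
        r_full = _corr(X[te] @ w_full, v[te])
        denom = r_full - r_baseline
        if denom != 0.0:
            scan.gain_fraction = (scan.refit_r - r_baseline) / denom
    return scan
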