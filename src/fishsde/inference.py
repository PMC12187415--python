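"""Data-driven identification of the 1-D distance SDE.

Given the interindividual-distance process x(t) sampled at interval dt,
the drift and diffusion of dx = F(x) dt + G(x) dW are estimated in three
steps:

1. (optional) low-pass filter x(t);
2. pointwise Kramers–Moyal estimates from forward increments,
       F_hat(t)  = (x(t+dt) - x(t)) / dt,
       G2_hat(t) = (x(t+dt) - x(t))^2 / dt,
   each paired with the state y = x(t); G2_hat estimates the *squared*
   diffusion G^2;
3. stepwise sparse regression (SSR): a polynomial library (degree 0..p-1)
   is fit to the estimates by LASSO (cyclic coordinate descent with
   soft-thresholding), the regularisation weight chosen by K-fold
   cross-validation; small coefficients are then pruned iteratively, the
   reduced model refit, and pruning stops when the cross-validated MSE
   ceases to decrease. The sparsest model with the best CV error wins.

The drift is fit to the pooled pointwise estimates; the diffusion
polynomial is fit to the square root of the bin-averaged G2_hat (the
binned second moment is far less noisy than its pointwise square root,
whose expectation is biased below G). Bin averages over 0.1 cm state bins
also feed the empirical-potential reconstruction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .exploration import DistanceSeries
from .kinematics import butterworth_lowpass
from .potential import DiffusionParams, PolynomialModel, SDEModel

logger = logging.getLogger("fishsde")


class ConvergenceError(RuntimeError):
    """Coordinate descent failed to converge; carries the last iterate."""

    def __init__(self, message: str, coefficients: np.ndarray):
        super().__init__(message)
        self.coefficients = coefficients


class DegenerateModelError(ValueError):
    """Sparse regression pruned every term."""


@dataclass
class KMPointEstimates:
    """Pointwise conditional-moment estimates paired with the state."""

    y: np.ndarray  # state x(t), length l-1
    drift_hat: np.ndarray  # (x(t+dt)-x(t))/dt
    diff2_hat: np.ndarray  # (x(t+dt)-x(t))^2/dt, estimates G^2
    dt: float


@dataclass
class BinnedKM:
    """State-binned averages of the pointwise estimates."""

    bin_centres: np.ndarray
    mean_drift: np.ndarray
    mean_diff2: np.ndarray
    counts: np.ndarray
    bin_width: float
    dt: float = np.nan
    #: average state within each bin; in bins on a steep flank of the
    #: state density the samples pile up on one side, so this is the
    #: unbiased abscissa for regression (bin_centres serve plotting and
    #: the fixed-grid potential reconstruction)
    mean_state: np.ndarray | None = None

    @property
    def state(self) -> np.ndarray:
        return self.mean_state if self.mean_state is not None else self.bin_centres

    def diffusion_response(self) -> np.ndarray:
        """G estimate per bin: sqrt of the second moment with the
        finite-dt drift contamination removed.

        Two documented bias corrections are applied. First, the
        squared-increment estimator has expectation G^2 + F^2 dt at
        finite sampling interval; the F^2 dt term is non-negligible in
        the tails of the state distribution where the drift is strong,
        so it is subtracted bin-wise using the binned drift. Second,
        sqrt of a bin mean of n squared Gaussian increments
        underestimates G by the chi-distribution factor
        sqrt(2/n) Gamma((n+1)/2) / Gamma(n/2); low-count bins are
        divided by this factor so the tails are not spuriously pulled
        down.
        """
        from scipy.special import gammaln

        dt = 0.0 if np.isnan(self.dt) else self.dt
        n = self.counts.astype(float)
        # (binned drift)^2 overshoots F^2 by Var(drift_hat)/n ~ G^2/(n dt),
        # leaving E[corrected] = G^2 (1 - 1/n); the Bessel-style factor
        # n/(n-1) restores an unbiased G^2
        bessel = np.where(n > 1, n / np.maximum(n - 1.0, 1.0), 1.0)
        corrected = (self.mean_diff2 - self.mean_drift**2 * dt) * bessel
        root = np.sqrt(np.maximum(corrected, 0.0))
        n = self.counts.astype(float)
        chi_mean = np.exp(
            0.5 * np.log(2.0 / n) + gammaln((n + 1) / 2) - gammaln(n / 2)
        )
        return root / chi_mean


@dataclass
class SSRConfig:
    """Knobs of the sparse-regression step.

    lambda_grid defaults to 30 log-spaced points spanning
    [1e-6, 10] times the smallest lambda that zeroes every penalised
    coefficient. prune_threshold acts on standardised coefficients.
    Folds are contiguous blocks by default (the data are time series);
    set shuffle_folds for a seeded random assignment.
    """

    lambda_grid: np.ndarray | None = None
    prune_threshold: float = 1e-3
    K: int = 5
    max_degree: int = 5
    seed: int = 0
    shuffle_folds: bool = False
    rtol: float = 1e-3  # CV error allowed to stay flat within this factor

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.prune_threshold < 0:
            raise ValueError("prune_threshold must be >= 0")


@dataclass
class SSRResult:
    model: PolynomialModel
    cv_error: float
    history: list[tuple[tuple[int, ...], float]]
    lam: float = 0.0


def km_point_estimates(
    series: DistanceSeries,
    filter_cutoff: float | None = None,
    filter_order: int = 4,
) -> KMPointEstimates:
    """Pointwise Kramers–Moyal drift/diffusion estimates from increments.

    ``filter_cutoff`` (rad/s), when given, applies a zero-phase
    Butterworth low-pass to x(t) before differencing. Filtering
    suppresses the fast fluctuations that carry the diffusion signal, so
    it biases the diffusion estimate downward; it is therefore off by
    default and exposed as an explicit choice.
    """
    if len(series) < 2:
        raise ValueError("need at least 2 samples")
    x = series.x
    if filter_cutoff is not None:
        x = butterworth_lowpass(
            x, order=filter_order, cutoff=filter_cutoff, fs=1.0 / series.dt
        )
    dx = np.diff(x)
    return KMPointEstimates(
        y=x[:-1],
        drift_hat=dx / series.dt,
        diff2_hat=dx**2 / series.dt,
        dt=series.dt,
    )


def pool_estimates(estimates: Sequence[KMPointEstimates]) -> KMPointEstimates:
    """Concatenate per-trial estimates (all trials must share dt)."""
    if not estimates:
        raise ValueError("no estimates to pool")
    dts = {e.dt for e in estimates}
    if len(dts) > 1:
        raise ValueError(f"cannot pool estimates with different dt: {dts}")
    return KMPointEstimates(
        y=np.concatenate([e.y for e in estimates]),
        drift_hat=np.concatenate([e.drift_hat for e in estimates]),
        diff2_hat=np.concatenate([e.diff2_hat for e in estimates]),
        dt=estimates[0].dt,
    )


def bin_average(
    est: KMPointEstimates | Sequence[KMPointEstimates],
    bin_width: float = 0.1,
    min_count: int = 10,
) -> BinnedKM:
    """Average the pointwise estimates over fixed-width state bins.

    Bins are [k*w, (k+1)*w); bins holding fewer than ``min_count``
    samples are dropped.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not isinstance(est, KMPointEstimates):
        est = pool_estimates(list(est))
    if est.y.size == 0:
        z = np.array([])
        return BinnedKM(z, z, z, np.array([], dtype=int), bin_width, est.dt)
    idx = np.floor(est.y / bin_width).astype(np.int64)
    order = np.argsort(idx, kind="stable")
    idx_s = idx[order]
    uniq, starts = np.unique(idx_s, return_index=True)
    drift_sums = np.add.reduceat(est.drift_hat[order], starts)
    diff2_sums = np.add.reduceat(est.diff2_hat[order], starts)
    state_sums = np.add.reduceat(est.y[order], starts)
    counts = np.diff(np.append(starts, idx_s.size))
    keep = counts >= min_count
    return BinnedKM(
        bin_centres=(uniq[keep] + 0.5) * bin_width,
        mean_drift=drift_sums[keep] / counts[keep],
        mean_diff2=diff2_sums[keep] / counts[keep],
        counts=counts[keep].astype(int),
        bin_width=bin_width,
        dt=est.dt,
        mean_state=state_sums[keep] / counts[keep],
    )


def build_library(y: np.ndarray, max_degree: int) -> np.ndarray:
    """Polynomial design matrix: column j holds y**j, j = 0..max_degree."""
    if max_degree < 0:
        raise ValueError("max_degree must be >= 0")
    y = np.asarray(y, dtype=float)
    return np.vander(y, max_degree + 1, increasing=True)


# ---------------------------------------------------------------------------
# LASSO by cyclic coordinate descent (covariance updates)


def _standardize(theta: np.ndarray, weights: np.ndarray | None = None):
    """Split constant columns (unpenalised intercept) from scaled ones."""
    if weights is None:
        mu = theta.mean(axis=0)
        sd = theta.std(axis=0)
    else:
        w = weights / weights.sum()
        mu = w @ theta
        sd = np.sqrt(w @ (theta - mu) ** 2)
    const = sd < 1e-12
    return mu, sd, const


def lasso_lambda_max(
    theta: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None
) -> float:
    """Smallest lambda for which every penalised coefficient is zero.

    From the KKT conditions of ||Y - Theta Xi||^2 + lambda ||Xi||_1 on
    standardised columns: lambda_max = 2 * max_j |theta_j^T (Y - Ybar)|.
    """
    mu, sd, const = _standardize(theta, weights)
    if weights is None:
        w = np.ones(y.size)
        ybar = y.mean()
    else:
        w = weights * (y.size / weights.sum())
        ybar = (w @ y) / w.sum()
    yc = y - ybar
    vals = []
    for j in range(theta.shape[1]):
        if const[j]:
            continue
        col = (theta[:, j] - mu[j]) / sd[j]
        vals.append(abs(col @ (w * yc)))
    return 2.0 * max(vals) if vals else 0.0


def lasso_cd(
    theta: np.ndarray,
    y: np.ndarray,
    lam: float,
    tol: float = 1e-8,
    max_iter: int = 5_000,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """LASSO solution of min ||Y - Theta Xi||^2 + lambda ||Xi||_1.

    Cyclic coordinate descent with soft-thresholding on standardised
    columns (Gram/covariance updates, so each sweep is O(p^2) after a
    one-off O(n p^2) setup); constant columns act as an unpenalised
    intercept. Convergence is declared when the duality gap falls below
    ``tol`` times the centred response energy. Coefficients are returned
    on the raw scale. lambda = 0 falls back to ordinary least squares.

    ``weights`` (normalised to mean one) turn the residual term into a
    weighted sum of squares — used when the observations are bin means
    with unequal counts.
    """
    theta = np.asarray(theta, dtype=float)
    y = np.asarray(y, dtype=float)
    if theta.shape[0] != y.shape[0]:
        raise ValueError("row count of Theta must match length of Y")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    n, p = theta.shape
    sqrt_w = None
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        sqrt_w = np.sqrt(weights * (n / weights.sum()))
    if lam == 0:
        if sqrt_w is None:
            coefs, *_ = np.linalg.lstsq(theta, y, rcond=None)
        else:
            coefs, *_ = np.linalg.lstsq(
                theta * sqrt_w[:, None], y * sqrt_w, rcond=None
            )
        return coefs

    mu, sd, const = _standardize(theta, weights)
    pen = ~const
    x = (theta[:, pen] - mu[pen]) / sd[pen]
    if const.any():
        ybar = y.mean() if sqrt_w is None else float(
            (sqrt_w**2 @ y) / (sqrt_w**2).sum()
        )
    else:
        ybar = 0.0
    yc = y - ybar
    if sqrt_w is not None:
        x = x * sqrt_w[:, None]
        yc = yc * sqrt_w
    y_energy = float(yc @ yc)
    if y_energy == 0.0 or x.shape[1] == 0:
        return _destandardize(np.zeros(x.shape[1]), mu, sd, const, ybar, p)

    gram = x.T @ x
    corr = x.T @ yc
    k = x.shape[1]
    w = np.zeros(k)
    half_lam = lam / 2.0
    prev_primal = np.inf
    for it in range(max_iter):
        for j in range(k):
            rho = corr[j] - gram[j] @ w + gram[j, j] * w[j]
            w[j] = np.sign(rho) * max(abs(rho) - half_lam, 0.0) / gram[j, j]
        if it % 10 == 0 or it == max_iter - 1:
            # duality gap of 0.5||r||^2 + (lam/2)||w||_1 from the scaled
            # residual dual point; all terms from Gram quantities
            xtr = corr - gram @ w
            r_norm2 = y_energy - 2.0 * (w @ corr) + w @ (gram @ w)
            r_dot_y = y_energy - w @ corr
            xtr_inf = float(np.abs(xtr).max()) if k else 0.0
            s = 1.0 if xtr_inf <= half_lam else half_lam / xtr_inf
            primal = 0.5 * r_norm2 + half_lam * float(np.abs(w).sum())
            dual = 0.5 * y_energy - 0.5 * (
                s * s * r_norm2 - 2.0 * s * r_dot_y + y_energy
            )
            if primal - dual <= tol * max(y_energy, 1e-30):
                break
            # on a (near-)singular Gram the gap can stall while the
            # objective is fully converged: coefficients then wander
            # along a flat null-space direction with no effect on the fit
            if abs(prev_primal - primal) <= 1e-14 * max(primal, 1e-30):
                break
            prev_primal = primal
    else:
        raise ConvergenceError(
            f"coordinate descent did not converge in {max_iter} sweeps",
            _destandardize(w, mu, sd, const, ybar, p),
        )
    return _destandardize(w, mu, sd, const, ybar, p)


def _destandardize(w, mu, sd, const, ybar, p):
    coefs = np.zeros(p)
    pen_idx = np.flatnonzero(~const)
    coefs[pen_idx] = w / sd[pen_idx]
    if const.any():
        intercept = ybar - float(coefs[pen_idx] @ mu[pen_idx])
        # distribute onto the (first) constant column, scaled by its value
        j = int(np.flatnonzero(const)[0])
        coefs[j] = intercept / mu[j] if mu[j] != 0 else 0.0
    return coefs


def standardized_coefficients(
    theta: np.ndarray, coefs: np.ndarray, weights: np.ndarray | None = None
) -> np.ndarray:
    """Coefficients rescaled to the standardised-column scale (constant
    columns keep their raw value)."""
    _, sd, const = _standardize(theta, weights)
    out = np.array(coefs, dtype=float)
    out[~const] = out[~const] * sd[~const]
    return out


# ---------------------------------------------------------------------------
# cross-validation and stepwise sparse regression


def _compose_affine(coefs_z: np.ndarray, centre: float, scale: float) -> np.ndarray:
    """Coefficients of P((y - centre)/scale) in powers of y, same length.

    The composition is exact in degree, so coefficients above the
    selected degree stay exactly zero.
    """
    p = coefs_z.size
    deg = int(np.flatnonzero(coefs_z)[-1]) if np.any(coefs_z) else 0
    poly = np.polynomial.Polynomial(coefs_z[: deg + 1])(
        np.polynomial.Polynomial([-centre / scale, 1.0 / scale])
    )
    out = np.zeros(p)
    out[: poly.coef.size] = poly.coef
    return out


def _fold_indices(n: int, cfg: SSRConfig) -> list[np.ndarray]:
    idx = np.arange(n)
    if cfg.shuffle_folds:
        rng = np.random.default_rng(cfg.seed)
        rng.shuffle(idx)
    return [fold for fold in np.array_split(idx, cfg.K) if fold.size]


def cv_mse(
    theta: np.ndarray,
    y: np.ndarray,
    lam: float,
    cfg: SSRConfig,
    active: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> float:
    """K-fold cross-validated mean squared prediction error.

    delta = (1/K) sum_k (1/n_k) sum_i (Y_i - Yhat_i)^2, with the model
    refit by LASSO on each training split, restricted to the ``active``
    columns when given; with ``weights`` both fit and test error are
    weighted.
    """
    return float(np.mean(cv_fold_errors(theta, y, lam, cfg, active, weights)))


def cv_fold_errors(
    theta: np.ndarray,
    y: np.ndarray,
    lam: float,
    cfg: SSRConfig,
    active: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Per-fold test errors underlying :func:`cv_mse`."""
    n, p = theta.shape
    cols = np.flatnonzero(active) if active is not None else np.arange(p)
    folds = _fold_indices(n, cfg)
    errs = []
    mask = np.ones(n, dtype=bool)
    for fold in folds:
        mask[:] = True
        mask[fold] = False
        coefs = _lasso_cd_tolerant(
            theta[mask][:, cols], y[mask], lam,
            weights=None if weights is None else weights[mask],
        )
        pred = theta[fold][:, cols] @ coefs
        sq = (y[fold] - pred) ** 2
        if weights is None:
            errs.append(float(np.mean(sq)))
        else:
            errs.append(float(np.average(sq, weights=weights[fold])))
    return np.asarray(errs)


def _lasso_cd_tolerant(theta, y, lam, weights=None):
    """lasso_cd, but fall back to the last iterate if the sweep budget is
    exhausted (near-singular libraries during cross-validation)."""
    try:
        return lasso_cd(theta, y, lam, weights=weights)
    except ConvergenceError as exc:
        logger.debug("lasso_cd: %s; using last iterate", exc)
        return exc.coefficients


def _default_lambda_grid(
    theta: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None
) -> np.ndarray:
    lam_max = lasso_lambda_max(theta, y, weights)
    if lam_max == 0:
        return np.array([0.0])
    return np.geomspace(1e-6 * lam_max, 10 * lam_max, 30)


def _cd_kernel_py(g, c, q, pen, lam, w, max_iter, tol):
    k = g.shape[0]
    half = lam / 2.0
    prev = np.inf
    for _ in range(max_iter):
        for j in range(k):
            rho = c[j] - g[j] @ w + g[j, j] * w[j]
            if pen[j]:
                mag = abs(rho) - half
                w[j] = (mag if mag > 0.0 else 0.0) * (
                    1.0 if rho >= 0.0 else -1.0
                ) / g[j, j]
            else:
                w[j] = rho / g[j, j]
        obj = q - 2.0 * (w @ c) + w @ (g @ w)
        for j in range(k):
            if pen[j]:
                obj += lam * abs(w[j])
        if abs(prev - obj) <= tol * max(abs(obj), 1.0):
            break
        prev = obj
    return w


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _cd_kernel = njit(_cd_kernel_py)
except Exception:  # pragma: no cover
    _cd_kernel = _cd_kernel_py


class _CVEngine:
    """Gram-matrix workspace for repeated LASSO fits and K-fold CV.

    Columns are scaled to unit (weighted) standard deviation; constant
    columns are left as-is and unpenalised. All training fits and test
    errors are computed from per-fold Gram blocks, so evaluating a
    candidate model costs O(p^2) per sweep regardless of sample count.
    Coefficients live on the scaled-column ("standardised") scale until
    :meth:`raw_coefficients`.
    """

    def __init__(self, theta, y, weights, cfg: SSRConfig):
        n, p = theta.shape
        self.p = p
        w = np.ones(n) if weights is None else weights * (n / weights.sum())
        wm = w / w.sum()
        mu = wm @ theta
        sd = np.sqrt(wm @ (theta - mu) ** 2)
        self.const = sd < 1e-12
        self.sd = np.where(self.const, 1.0, sd)
        xs = theta / self.sd
        xw = xs * w[:, None]
        folds = _fold_indices(n, cfg)
        self.k = len(folds)
        self.gram_f = np.empty((self.k, p, p))
        self.corr_f = np.empty((self.k, p))
        self.q_f = np.empty(self.k)
        self.sw_f = np.empty(self.k)
        for i, fold in enumerate(folds):
            self.gram_f[i] = xw[fold].T @ xs[fold]
            self.corr_f[i] = xw[fold].T @ y[fold]
            self.q_f[i] = float(w[fold] @ y[fold] ** 2)
            self.sw_f[i] = float(w[fold].sum())
        self.gram = self.gram_f.sum(axis=0)
        self.corr = self.corr_f.sum(axis=0)
        self.q = float(self.q_f.sum())

    def lambda_max(self) -> float:
        """KKT zero-crossing threshold, intercept (if any) left free."""
        pen = ~self.const
        if self.const.any():
            j0 = int(np.flatnonzero(self.const)[0])
            w0 = self.corr[j0] / self.gram[j0, j0]
            resid_corr = self.corr - self.gram[:, j0] * w0
        else:
            resid_corr = self.corr
        vals = np.abs(resid_corr[pen])
        return 2.0 * float(vals.max()) if vals.size else 0.0

    def lambda_grid(self) -> np.ndarray:
        lam_max = self.lambda_max()
        if lam_max <= 0:
            return np.array([0.0])
        return np.geomspace(1e-6 * lam_max, 10 * lam_max, 30)

    def _fit_sub(self, gram, corr, q, cols, lam, w0=None, max_iter=2_000):
        g = np.ascontiguousarray(gram[np.ix_(cols, cols)])
        g[np.diag_indices_from(g)] = np.maximum(np.diag(g), 1e-30)
        c = np.ascontiguousarray(corr[cols])
        pen = ~self.const[cols]
        w = np.zeros(cols.size) if w0 is None else w0.copy()
        return _cd_kernel(g, c, q, pen, lam, w, max_iter, 1e-13)

    def fit(self, active, lam):
        """Full-data fit; coefficients on the standardised scale."""
        cols = np.flatnonzero(active)
        full = np.zeros(self.p)
        full[cols] = self._fit_sub(self.gram, self.corr, self.q, cols, lam)
        return full

    def _fold_error(self, w, cols, i) -> float:
        gf = self.gram_f[i][np.ix_(cols, cols)]
        cf = self.corr_f[i][cols]
        err = (self.q_f[i] - 2.0 * (w @ cf) + w @ (gf @ w)) / self.sw_f[i]
        return max(err, 0.0)

    def cv_errors(self, active, lam) -> np.ndarray:
        """Per-fold weighted mean squared prediction errors."""
        cols = np.flatnonzero(active)
        errs = np.empty(self.k)
        for i in range(self.k):
            w = self._fit_sub(
                self.gram - self.gram_f[i],
                self.corr - self.corr_f[i],
                self.q - self.q_f[i],
                cols,
                lam,
            )
            errs[i] = self._fold_error(w, cols, i)
        return errs

    def select_lambda(self, active, grid) -> tuple[float, np.ndarray]:
        """CV-optimal lambda for a candidate; returns (lam, fold errors).

        The grid is swept from the strongest penalty down with per-fold
        warm starts, so each step needs only a few coordinate sweeps.
        """
        cols = np.flatnonzero(active)
        warm = [None] * self.k
        best = None
        for lam in sorted(np.asarray(grid, dtype=float), reverse=True):
            errs = np.empty(self.k)
            for i in range(self.k):
                w = self._fit_sub(
                    self.gram - self.gram_f[i],
                    self.corr - self.corr_f[i],
                    self.q - self.q_f[i],
                    cols,
                    lam,
                    w0=warm[i],
                )
                warm[i] = w
                errs[i] = self._fold_error(w, cols, i)
            m = float(np.mean(errs))
            if best is None or m < best[0]:
                best = (m, lam, errs.copy())
        return best[1], best[2]

    def raw_coefficients(self, std_coefs) -> np.ndarray:
        return std_coefs / self.sd


def ssr_fit(
    data: "KMPointEstimates | BinnedKM",
    target: Literal["drift", "diffusion"],
    cfg: SSRConfig | None = None,
    bin_width: float = 0.1,
    min_count: int = 10,
) -> SSRResult:
    """Select a sparse polynomial for the drift or diffusion.

    Drift: fit to the pooled pointwise (state, drift_hat) pairs (or to
    binned means if a BinnedKM is passed). Diffusion: fit to
    sqrt(bin-averaged G2_hat) against the bin centres, so the reported
    parabola is G itself, not G^2.

    Procedure: for each library cap (all polynomial terms up to degree
    d, d = 0..max_degree) the stepwise sparse regression runs a greedy
    prune path — LASSO fit at the CV-optimal lambda for the current term
    set, removal of all standardised coefficients below
    ``cfg.prune_threshold`` at once (otherwise the single smallest), CV
    re-evaluation, stop once the CV error rises. Re-selecting lambda per
    term set avoids the shrinkage bias a single global lambda imposes on
    small subsets. The final model is chosen among every candidate
    visited by the paired one-standard-error rule: a candidate ties with
    the CV-best model when its mean excess fold error is within one
    standard error of the per-fold differences; among ties the fewest
    terms win, then the lower polynomial degree. Pruned coefficients are
    exactly zero in the returned model.
    """
    cfg = cfg or SSRConfig()
    if target == "drift":
        if isinstance(data, BinnedKM):
            state, response = data.state, data.mean_drift
        else:
            state, response = data.y, data.drift_hat
    elif target == "diffusion":
        if isinstance(data, KMPointEstimates):
            data = bin_average(data, bin_width=bin_width, min_count=min_count)
        state, response = data.state, data.diffusion_response()
    else:
        raise ValueError(f"unknown target {target!r}")
    # bin means are heteroscedastic (variance ~ 1/count): weight by count
    weights = data.counts.astype(float) if isinstance(data, BinnedKM) else None

    if state.size < cfg.K:
        raise ValueError("not enough samples for the requested fold count")

    # fit in a centred/scaled state variable z = (y - c) / s: monomials of
    # the raw state are so collinear that coordinate descent cannot
    # converge; the selected polynomial is mapped back to the raw scale
    # below (composition with the affine map preserves the degree)
    centre = float(state.mean())
    scale = float(state.std()) or 1.0
    z = (state - centre) / scale
    theta = build_library(z, cfg.max_degree)
    p = theta.shape[1]
    engine = _CVEngine(theta, response, weights, cfg)
    grid = (
        np.asarray(cfg.lambda_grid, dtype=float)
        if cfg.lambda_grid is not None
        else engine.lambda_grid()
    )

    seen: set[tuple[int, ...]] = set()
    # candidates: (delta, per-fold errors, n_terms, max degree, lam, coefs)
    records: list[tuple[float, np.ndarray, int, int, float, np.ndarray]] = []
    history: list[tuple[tuple[int, ...], float]] = []

    def evaluate(active: np.ndarray) -> tuple[float, np.ndarray]:
        """CV-score one term set at its own CV-optimal lambda."""
        cols = tuple(int(c) for c in np.flatnonzero(active))
        lam, fold_errs = engine.select_lambda(active, grid)
        std_coefs = engine.fit(active, lam)
        delta = float(np.mean(fold_errs))
        if cols not in seen:
            seen.add(cols)
            records.append(
                (delta, fold_errs, len(cols), max(cols), lam, std_coefs)
            )
        return delta, std_coefs

    def prune_path(start: np.ndarray) -> None:
        active = start.copy()
        top_level = bool(active.all())
        path_best = np.inf
        while True:
            cols = np.flatnonzero(active)
            delta, std_coefs = evaluate(active)
            if top_level:
                history.append((tuple(int(c) for c in cols), delta))
            if delta > path_best * (1 + cfg.rtol):
                break  # CV error ceased to decrease along this path
            path_best = min(path_best, delta)
            if active.sum() <= 1:
                break
            mags = np.abs(std_coefs[cols])
            below = mags < cfg.prune_threshold
            if below.all():
                break  # nothing credibly nonzero left on this path
            drop = cols[below] if below.any() else [cols[int(np.argmin(mags))]]
            active[drop] = False

    # greedy prune path per degree-capped library (largest cap first so
    # `history` reflects the full-library path)
    for d in range(cfg.max_degree, -1, -1):
        start = np.zeros(p, dtype=bool)
        start[: d + 1] = True
        prune_path(start)

    # paired one-standard-error rule: a candidate ties with the CV-best
    # model when its mean excess fold error is within one standard error
    # of the per-fold error differences (pairing cancels the
    # fold-to-fold variation all models share); among ties prefer the
    # lower polynomial degree (basis hierarchy), then fewer terms
    best = min(records, key=lambda r: r[0])

    def ties_with_best(rec) -> bool:
        d = rec[1] - best[1]
        mean_d = float(np.mean(d))
        if mean_d <= 0:
            return True
        if d.size < 2:
            return False
        se_d = float(np.std(d, ddof=1) / np.sqrt(d.size))
        return mean_d <= se_d

    candidates = [r for r in records if ties_with_best(r)]
    delta_best, _, _, _, lam_best, std_best = min(
        candidates, key=lambda r: (r[3], r[2], r[0])
    )
    if not np.any(std_best):
        raise DegenerateModelError("all terms pruned")
    raw_coefs = _compose_affine(engine.raw_coefficients(std_best), centre, scale)
    model = PolynomialModel(raw_coefs, target=target)
    logger.debug(
        "ssr_fit %s: lambda=%.3g, active=%s, cv_error=%.4g",
        target, lam_best, np.flatnonzero(std_best).tolist(), delta_best,
    )
    return SSRResult(
        model=model, cv_error=delta_best, history=history, lam=lam_best
    )


def identify_sde(
    series: Sequence[DistanceSeries],
    cfg: SSRConfig | None = None,
    filter_cutoff: float | None = None,
    bin_width: float = 0.1,
    min_count: int = 10,
    domain: tuple[float, float] = (0.0, 57.0),
) -> tuple[SDEModel, BinnedKM, SSRResult, SSRResult]:
    """Full identification pipeline: pooled KM estimates -> SSR fits.

    Returns the simulatable model, the binned estimates (for plots and
    the empirical potential), and the two SSR results.
    """
    cfg = cfg or SSRConfig()
    pooled = pool_estimates(
        [km_point_estimates(s, filter_cutoff=filter_cutoff) for s in series]
    )
    binned = bin_average(pooled, bin_width=bin_width, min_count=min_count)
    drift_res = ssr_fit(pooled, "drift", cfg)
    diff_res = ssr_fit(binned, "diffusion", cfg)
    dc = np.zeros(3)
    dc[: min(3, diff_res.model.coefficients.size)] = (
        diff_res.model.coefficients[:3]
    )
    if diff_res.model.coefficients.size > 3 and np.any(
        diff_res.model.coefficients[3:]
    ):
        logger.warning(
            "diffusion fit selected terms above degree 2; truncating to the "
            "parabolic form for simulation"
        )
    model = SDEModel(
        drift=drift_res.model,
        diffusion=DiffusionParams(b0=dc[0], b1=dc[1], b2=dc[2]),
        domain=domain,
    )
    return model, binned, drift_res, diff_res
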