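"""Subject-level GLM fitting under interchangeable temporal-noise models.

The fit is the classic two-pass prewhitened GLM: an ordinary least-squares
pass yields residuals, the residuals yield autocorrelation estimates under
the requested noise style, and a generalized least-squares pass on the
whitened data and design yields the final coefficients.  Four noise styles
span the pooled-vs-voxelwise and AR(1)-vs-ARMA(1,1) axes along which the
major packages differ:

``ols``
    no whitening (single pass);
``ar1_pooled``
    one lag-1 coefficient pooled (averaged) over the analysis mask,
    emulating globally pooled autocorrelation models;
``ar1_voxelwise``
    a lag-1 coefficient per voxel;
``arma11_voxelwise``
    per-voxel ARMA(1,1) via method of moments on lags 1-2, emulating
    voxelwise ARMA-style noise models.

Degrees of freedom are ``n - rank(design)`` in every style.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import linalg as sla

from .design import DesignMatrix

__all__ = ["NoiseSpec", "GlmFit", "StatMap", "ContrastResult", "estimate_noise", "fit_glm", "compute_contrast"]

logger = logging.getLogger(__name__)

_MIN_TIMEPOINTS = 20


class GlmError(ValueError):
    pass


@dataclass(frozen=True)
class NoiseSpec:
    style: Literal["ols", "ar1_pooled", "ar1_voxelwise", "arma11_voxelwise"] = "ar1_voxelwise"
    pooling_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.style not in ("ols", "ar1_pooled", "ar1_voxelwise", "arma11_voxelwise"):
            raise GlmError(f"unknown noise style {self.style!r}")
        if self.style == "ar1_pooled" and self.pooling_mask is not None:
            if int(np.asarray(self.pooling_mask).sum()) < 10:
                raise GlmError("pooled estimation requires >= 10 in-mask voxels")


@dataclass
class StatMap:
    """A statistic volume (t, z, or F) with its analysis mask.

    Values outside the mask are zero by convention.  ``df`` is a scalar for
    t/z maps and a (numerator, denominator) pair for F maps.
    """

    values: np.ndarray
    stat_kind: Literal["t", "z", "F"]
    df: float | tuple[float, float] | None
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise GlmError("values and mask shapes differ")
        if not np.isfinite(self.values[self.mask]).all():
            raise GlmError("non-finite statistic values inside the mask")
        self.values = np.where(self.mask, self.values, 0.0)

    @property
    def in_mask(self) -> np.ndarray:
        return self.values[self.mask]


@dataclass
class GlmFit:
    """Per-voxel GLM estimates on the input grid."""

    beta: np.ndarray  # (p, *grid)
    sigma2: np.ndarray  # (*grid,) residual variance of the (whitened) fit
    df: float
    xtx_inv: np.ndarray  # (*grid, p, p) or (p, p) when shared across voxels
    mask: np.ndarray
    columns: list[str]
    noise_style: str
    phi: np.ndarray | float | None = None
    theta: np.ndarray | float | None = None


@dataclass
class ContrastResult:
    stat: StatMap  # t map
    effect: np.ndarray  # contrast of parameter estimates (COPE), on the grid


def _lag_autocorr(resid: np.ndarray, lag: int) -> np.ndarray:
    """Sample autocorrelation at ``lag`` for residual columns (n, V)."""
    num = (resid[lag:] * resid[:-lag]).sum(axis=0)
    den = (resid**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / den, 0.0)
    return r


def _residual_diag_sums(x: np.ndarray, max_lag: int) -> list[np.ndarray]:
    """Diagonal sums of M S_k M for lags k = 0..max_lag, where M is the
    residual-forming matrix of the design and S_k the symmetrized lag-k
    pattern.  With these, the expected residual autocovariance under any
    noise autocorrelation acf is ``diag_sums[k] @ acf`` (up to sigma^2),
    because tr(M S_k M R) = sum over diagonals of (M S_k M) weighted by R's
    Toeplitz values.
    """
    n = x.shape[0]
    m = np.eye(n) - x @ np.linalg.pinv(x)
    out = []
    for k in range(max_lag + 1):
        if k == 0:
            s = np.eye(n)
        else:
            s = np.zeros((n, n))
            idx = np.arange(n - k)
            s[idx, idx + k] = 0.5
            s[idx + k, idx] = 0.5
        a = m @ s @ m
        ds = np.array(
            [
                np.trace(a, offset=d) + (np.trace(a, offset=-d) if d > 0 else 0.0)
                for d in range(n)
            ]
        )
        out.append(ds)
    return out


def _ar1_unbias_curve(diag_sums: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Expected residual lag-1 autocorrelation as a function of the true phi."""
    n = diag_sums[0].shape[0]
    phi_grid = np.arange(-0.4, 0.96, 0.01)
    acf = phi_grid[:, None] ** np.arange(n)[None, :]
    pred = (acf @ diag_sums[1]) / (acf @ diag_sums[0])
    return phi_grid, pred


def _correct_ar1(r1: np.ndarray, diag_sums: list[np.ndarray] | None, n: int) -> np.ndarray:
    if diag_sums is None:
        # no design available: first-order small-sample correction only
        return np.clip(r1 + (1 + 3 * r1) / n, -0.99, 0.99)
    phi_grid, pred = _ar1_unbias_curve(diag_sums)
    return np.clip(np.interp(r1, pred, phi_grid), -0.99, 0.99)


def _correct_arma(
    r1: np.ndarray, r2: np.ndarray, diag_sums: list[np.ndarray] | None, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Invert the expected (lag-1, lag-2) residual autocorrelations on an
    ARMA(1,1) parameter grid (nearest-neighbour lookup)."""
    phis = np.arange(-0.3, 0.91, 0.05)
    thetas = np.arange(-0.6, 0.61, 0.05)
    pg, tg = np.meshgrid(phis, thetas, indexing="ij")
    pg, tg = pg.ravel(), tg.ravel()
    lags = np.arange(n)
    acfs = np.empty((pg.size, n))
    for i, (p, t) in enumerate(zip(pg, tg)):
        denom = 1 + 2 * p * t + t**2
        rho1 = (1 + p * t) * (p + t) / denom
        acfs[i] = np.concatenate(([1.0], rho1 * p ** (lags[1:] - 1)))
    if diag_sums is None:
        pred1 = acfs[:, 1]
        pred2 = acfs[:, 2]
    else:
        den = acfs @ diag_sums[0]
        pred1 = (acfs @ diag_sums[1]) / den
        pred2 = (acfs @ diag_sums[2]) / den
    # nearest grid point in (r1, r2) space, chunked over voxels
    phi_out = np.empty_like(r1)
    theta_out = np.empty_like(r1)
    chunk = 4096
    for start in range(0, r1.size, chunk):
        sl = slice(start, start + chunk)
        d = (pred1[:, None] - r1[None, sl]) ** 2 + (pred2[:, None] - r2[None, sl]) ** 2
        best = np.argmin(d, axis=0)
        phi_out[sl] = pg[best]
        theta_out[sl] = tg[best]
    return phi_out, theta_out


def estimate_noise(
    residuals: np.ndarray,
    spec: NoiseSpec,
    mask: np.ndarray | None = None,
    design: np.ndarray | None = None,
) -> dict[str, np.ndarray | float]:
    """Estimate autocorrelation parameters from first-pass residuals.

    ``residuals`` is (n_timepoints, n_voxels).  AR(1) styles return the
    lag-1 coefficient phi (scalar for the pooled style, per-voxel array
    otherwise); the ARMA(1,1) style returns per-voxel (phi, theta) from the
    method of moments on lags 1 and 2.

    Residuals of a least-squares fit understate the noise autocorrelation
    because the design projection absorbs part of it.  When ``design`` is
    given, the estimates invert the expected residual autocorrelation under
    the design's residual-forming matrix; otherwise a first-order
    small-sample bias correction is applied.
    """
    resid = np.asarray(residuals, dtype=float)
    if resid.ndim == 1:
        resid = resid[:, None]
    n = resid.shape[0]
    if n < _MIN_TIMEPOINTS:
        raise GlmError(f"refusing to estimate noise from {n} < {_MIN_TIMEPOINTS} time points")
    if spec.style == "ols":
        return {}
    needs_lag2 = spec.style == "arma11_voxelwise"
    diag_sums = None if design is None else _residual_diag_sums(design, 2 if needs_lag2 else 1)
    r1 = _lag_autocorr(resid, 1)
    if spec.style in ("ar1_pooled", "ar1_voxelwise"):
        phi = _correct_ar1(r1, diag_sums, n)
        if spec.style == "ar1_voxelwise":
            return {"phi": phi}
        pool = np.ones(resid.shape[1], dtype=bool)
        if spec.pooling_mask is not None:
            pool = np.asarray(spec.pooling_mask, dtype=bool).ravel()
        elif mask is not None:
            pool = np.asarray(mask, dtype=bool).ravel()
        return {"phi": float(phi[pool].mean())}
    r2 = _lag_autocorr(resid, 2)
    phi_arma, theta = _correct_arma(r1, r2, diag_sums, n)
    return {"phi": phi_arma, "theta": theta}


def _arma_acf(phi: float, theta: float, nlags: int) -> np.ndarray:
    """ARMA(1,1) autocorrelation function out to ``nlags``."""
    acf = np.empty(nlags + 1)
    acf[0] = 1.0
    denom = 1 + 2 * phi * theta + theta**2
    if nlags >= 1:
        acf[1] = (1 + phi * theta) * (phi + theta) / denom
        for k in range(2, nlags + 1):
            acf[k] = phi * acf[k - 1]
    return acf


def _ar1_whiten(x: np.ndarray, phi: float) -> np.ndarray:
    """Exact AR(1) whitening of columns of x (first row scaled)."""
    out = np.empty_like(x, dtype=float)
    out[0] = np.sqrt(1 - phi**2) * x[0]
    out[1:] = x[1:] - phi * x[:-1]
    return out


def _ols_fit(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return beta (p, V), residuals (n, V), xtx_inv (p, p)."""
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    return beta, resid, xtx_inv


def fit_glm(bold: np.ndarray, design: DesignMatrix, spec: NoiseSpec) -> GlmFit:
    """Fit the subject-level GLM on a 4-D (or (n, V)) BOLD array.

    Non-finite voxels are dropped from the analysis mask (a count is
    logged).  When the design carries a high-pass drift-projection recipe,
    it is applied to both data and design before fitting.
    """
    y = np.asarray(bold, dtype=float)
    if y.ndim >= 2 and y.shape[-1] == len(design.frame_times) and y.ndim > 2:
        # 4-D volume with time last -> (n, V)
        grid = y.shape[:-1]
        y = np.moveaxis(y, -1, 0).reshape(y.shape[-1], -1)
    elif y.ndim == 2:
        grid = (y.shape[1],)
    else:
        raise GlmError("bold must be (n, V) or a 4-D volume with time last")
    n, n_vox = y.shape
    if n != len(design.frame_times):
        raise GlmError("volume count does not match design frames")

    x = design.matrix
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise GlmError("rank-deficient design")
    df_filter = 0.0
    if design.drift_projection is not None:
        proj = design.drift_projection
        y = proj.apply(y)
        keep = [c for c in design.data.columns if c != "constant"]
        x = np.column_stack([proj.apply(design.data[c].to_numpy()) for c in keep])
        x = np.column_stack([x, np.ones(n)])  # keep a constant for the intercept
        columns = keep + ["constant"]
        df_filter = proj.basis.shape[1]  # df consumed by the residualization
    else:
        columns = list(design.data.columns)

    finite = np.isfinite(y).all(axis=0)
    n_bad = int((~finite).sum())
    if n_bad:
        logger.warning("excluding %d non-finite voxels from the analysis mask", n_bad)
    mask_flat = finite
    yv = np.where(finite, y, 0.0)

    p = x.shape[1]
    df = float(n - np.linalg.matrix_rank(x) - df_filter)
    beta, resid, xtx_inv = _ols_fit(x, yv)
    phi: np.ndarray | float | None = None
    theta: np.ndarray | float | None = None

    if spec.style == "ols":
        sigma2 = (resid**2).sum(axis=0) / df
        xtx_inv_out: np.ndarray = xtx_inv
    else:
        # the residual-forming matrix includes any high-pass basis that was
        # residualized out of data and design
        x_for_noise = x
        if design.drift_projection is not None:
            x_for_noise = np.column_stack([x, design.drift_projection.basis])
        params = estimate_noise(resid, spec, mask=mask_flat, design=x_for_noise)
        phi = params.get("phi")
        theta = params.get("theta")
        if spec.style == "ar1_pooled":
            xw = _ar1_whiten(x, float(phi))
            yw = _ar1_whiten(yv, float(phi))
            beta, residw, xtx_inv_out = _ols_fit(xw, yw)
            sigma2 = (residw**2).sum(axis=0) / df
        elif spec.style == "ar1_voxelwise":
            beta, sigma2, xtx_inv_out = _ar1_voxelwise_gls(x, yv, np.asarray(phi), df)
        else:  # arma11_voxelwise
            beta, sigma2, xtx_inv_out = _arma_voxelwise_gls(
                x, yv, np.asarray(phi), np.asarray(theta), df, mask_flat
            )

    return GlmFit(
        beta=beta.reshape((p, *grid)),
        sigma2=sigma2.reshape(grid),
        df=df,
        xtx_inv=xtx_inv_out if xtx_inv_out.ndim == 2 else xtx_inv_out.reshape((*grid, p, p)),
        mask=mask_flat.reshape(grid),
        columns=columns,
        noise_style=spec.style,
        phi=phi,
        theta=theta,
    )


def _ar1_voxelwise_gls(
    x: np.ndarray, y: np.ndarray, phi: np.ndarray, df: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-voxel AR(1) GLS via closed-form whitened cross-products.

    The whitened normal-equation matrix is quadratic in phi, so the four
    constituent p x p cross-products are precomputed once and combined per
    voxel.
    """
    n, p = x.shape
    x0, x1 = x[:-1], x[1:]
    a11 = x1.T @ x1
    a01 = x1.T @ x0  # note: asymmetric; combined with its transpose below
    a00 = x0.T @ x0
    a_first = np.outer(x[0], x[0])

    phi = np.clip(phi, -0.99, 0.99)
    ph = phi[None, None, :]  # broadcast over (p, p, V)
    ata = (
        a11[:, :, None]
        - ph * (a01 + a01.T)[:, :, None]
        + ph**2 * a00[:, :, None]
        + (1 - ph**2) * a_first[:, :, None]
    )  # (p, p, V)

    yw_tail = y[1:] - phi[None, :] * y[:-1]
    y_first = np.sqrt(1 - phi**2) * y[0]
    # first-row contribution: (sqrt(1-phi^2) x_0) . (sqrt(1-phi^2) y_0)
    atb = (
        x1.T @ yw_tail
        - phi[None, :] * (x0.T @ yw_tail)
        + (1 - phi**2)[None, :] * np.outer(x[0], y[0])
    )

    ata_t = np.moveaxis(ata, -1, 0)  # (V, p, p)
    xtx_inv = np.linalg.inv(ata_t)  # (V, p, p)
    beta = np.einsum("vpq,qv->pv", xtx_inv, atb)

    yty = (yw_tail**2).sum(axis=0) + y_first**2
    rss = yty - np.einsum("pv,pv->v", atb, beta)
    sigma2 = np.maximum(rss, 0.0) / df
    return beta, sigma2, xtx_inv


def _arma_voxelwise_gls(
    x: np.ndarray,
    y: np.ndarray,
    phi: np.ndarray,
    theta: np.ndarray,
    df: float,
    mask: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-voxel ARMA(1,1) GLS via Cholesky whitening of the Toeplitz
    correlation matrix; (phi, theta) are binned to 0.02 so the factorization
    is shared across voxels with near-identical estimates."""
    n, p = x.shape
    n_vox = y.shape[1]
    beta = np.zeros((p, n_vox))
    sigma2 = np.zeros(n_vox)
    xtx_inv = np.zeros((n_vox, p, p))
    cache: dict[tuple[float, float], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    keys_phi = np.round(phi / 0.02) * 0.02
    keys_theta = np.round(theta / 0.02) * 0.02
    default_inv = np.linalg.inv(x.T @ x)
    for v in range(n_vox):
        if not mask[v]:
            xtx_inv[v] = default_inv
            continue
        key = (float(keys_phi[v]), float(keys_theta[v]))
        if key not in cache:
            acf = _arma_acf(key[0], key[1], n - 1)
            cov = sla.toeplitz(acf)
            chol = sla.cholesky(cov, lower=True)
            xw = sla.solve_triangular(chol, x, lower=True)
            cache[key] = (chol, xw, np.linalg.inv(xw.T @ xw))
        chol, xw, inv = cache[key]
        yw = sla.solve_triangular(chol, y[:, v], lower=True)
        b = inv @ xw.T @ yw
        resid = yw - xw @ b
        beta[:, v] = b
        sigma2[v] = resid @ resid / df
        xtx_inv[v] = inv
    return beta, sigma2, xtx_inv


def compute_contrast(fit: GlmFit, weights: np.ndarray) -> ContrastResult:
    """t statistic and effect (COPE) map for a contrast of the beta maps."""
    c = np.asarray(weights, dtype=float)
    p = fit.beta.shape[0]
    if c.shape != (p,):
        raise GlmError(f"contrast length {c.shape} does not match {p} design columns")
    if not np.any(c):
        raise GlmError("contrast weights are all zero")
    grid = fit.beta.shape[1:]
    beta_flat = fit.beta.reshape(p, -1)
    effect = c @ beta_flat
    sigma2 = fit.sigma2.ravel()
    if fit.xtx_inv.ndim == 2:
        quad = float(c @ fit.xtx_inv @ c)
        var = sigma2 * quad
    else:
        inv = fit.xtx_inv.reshape(-1, p, p)
        var = sigma2 * np.einsum("p,vpq,q->v", c, inv, c)
    mask = fit.mask.ravel() & (var > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(mask, effect / np.sqrt(np.where(var > 0, var, 1.0)), 0.0)
    stat = StatMap(t.reshape(grid), "t", fit.df, mask.reshape(grid))
    return ContrastResult(stat=stat, effect=effect.reshape(grid))
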