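"""Bivariate multi-trait mixed model (MTMM).

Stacks two z-scored traits and models cov = Vg (x) K + Ve (x) I with 2x2
genetic and residual covariance matrices estimated once by REML under the
no-SNP null, then tests each SNP by GLS in the eigenbasis of K:

* ``any``      -- 2-df Wald test of (beta1, beta2) = (0, 0)
* ``common``   -- 1-df test of a shared effect under the constraint
                  beta1 = beta2
* ``specific`` -- 1-df test of beta1 - beta2 = 0 (trait-differential effect)

Vg and Ve are parameterized by log variances and bounded correlations
rho = 0.99 * tanh(theta), which keeps every rotated 2x2 block nonsingular
(even for perfectly correlated traits) while spanning all covariance
matrices with |rho| <= 0.99.  Optimization is derivative-free Nelder-Mead
with deterministic multi-starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import GenotypeMatrix, KinshipMatrix
from .lmm import _prepare_snps
from .utils import zscore

__all__ = ["BivariateNullFit", "fit_bivariate_null", "mtmm_scan"]

RHO_CAP = 0.99
VE_FLOOR = 1e-6


@dataclass
class BivariateNullFit:
    Vg: np.ndarray
    Ve: np.ndarray
    genetic_correlation: float
    reml_loglik: float
    eigenvalues: np.ndarray = field(repr=False)
    U: np.ndarray = field(repr=False)
    y1_rot: np.ndarray = field(repr=False)
    y2_rot: np.ndarray = field(repr=False)
    ones_rot: np.ndarray = field(repr=False)


def _theta_to_cov(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vg1, vg2 = np.exp(2.0 * theta[0]), np.exp(2.0 * theta[1])
    rg = RHO_CAP * np.tanh(theta[2])
    ve1, ve2 = np.exp(2.0 * theta[3]) + VE_FLOOR, np.exp(2.0 * theta[4]) + VE_FLOOR
    re = RHO_CAP * np.tanh(theta[5])
    Vg = np.array([[vg1, rg * np.sqrt(vg1 * vg2)], [rg * np.sqrt(vg1 * vg2), vg2]])
    Ve = np.array([[ve1, re * np.sqrt(ve1 * ve2)], [re * np.sqrt(ve1 * ve2), ve2]])
    return Vg, Ve


def _block_weights(Vg, Ve, s):
    """Entries (a, b, d) of the inverse of each 2x2 block s_i*Vg + Ve,
    plus the per-block log determinant."""
    c11 = s * Vg[0, 0] + Ve[0, 0]
    c12 = s * Vg[0, 1] + Ve[0, 1]
    c22 = s * Vg[1, 1] + Ve[1, 1]
    det = c11 * c22 - c12**2
    if np.any(det <= 0):
        return None
    return c22 / det, -c12 / det, c11 / det, np.log(det)


def _reml_loglik_biv(theta, s, u, y1, y2):
    Vg, Ve = _theta_to_cov(theta)
    bw = _block_weights(Vg, Ve, s)
    if bw is None:
        return -np.inf
    a, b, d, logdet = bw
    A11 = float(np.sum(a * u * u))
    A12 = float(np.sum(b * u * u))
    A22 = float(np.sum(d * u * u))
    r1 = float(np.sum(u * (a * y1 + b * y2)))
    r2 = float(np.sum(u * (b * y1 + d * y2)))
    M = np.array([[A11, A12], [A12, A22]])
    detM = A11 * A22 - A12**2
    if detM <= 0:
        return -np.inf
    beta = np.linalg.solve(M, [r1, r2])
    e1 = y1 - beta[0] * u
    e2 = y2 - beta[1] * u
    quad = float(np.sum(a * e1 * e1 + 2.0 * b * e1 * e2 + d * e2 * e2))
    n2 = 2 * y1.size
    ll = -0.5 * ((n2 - 2) * np.log(2.0 * np.pi) + float(np.sum(logdet)) + np.log(detM) + quad)
    return float(ll)


def fit_bivariate_null(
    y1,
    y2,
    K: KinshipMatrix,
    n_starts: int = 5,
    tol: float = 1e-8,
    seed: int = 0,
) -> BivariateNullFit:
    """REML fit of the no-SNP bivariate null model (per-trait intercepts)."""
    y1 = zscore(np.asarray(y1, dtype=float))
    y2 = zscore(np.asarray(y2, dtype=float))
    n = y1.size
    Kv = (K.values + K.values.T) / 2.0
    s, U = np.linalg.eigh(Kv)
    s = np.clip(s, 0.0, None)
    y1r, y2r = U.T @ y1, U.T @ y2
    ur = U.T @ np.ones(n)

    r_obs = float(np.clip(np.corrcoef(y1, y2)[0, 1], -0.95, 0.95))
    base = np.array(
        [
            np.log(np.sqrt(0.5)),
            np.log(np.sqrt(0.5)),
            np.arctanh(r_obs / RHO_CAP),
            np.log(np.sqrt(0.5)),
            np.log(np.sqrt(0.5)),
            np.arctanh(r_obs / RHO_CAP),
        ]
    )
    rng = np.random.default_rng(seed)
    starts = [base] + [base + 0.5 * rng.standard_normal(6) for _ in range(n_starts - 1)]

    best = None
    for th0 in starts:
        res = optimize.minimize(
            lambda th: -_reml_loglik_biv(th, s, ur, y1r, y2r),
            th0,
            method="Nelder-Mead",
            options={"fatol": tol, "xatol": 1e-6, "maxiter": 6000, "maxfev": 9000},
        )
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("MTMM null optimization failed to converge from all starts")
    Vg, Ve = _theta_to_cov(best.x)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho_g = float(Vg[0, 1] / np.sqrt(Vg[0, 0] * Vg[1, 1])) if Vg[0, 0] * Vg[1, 1] > 0 else np.nan
    return BivariateNullFit(
        Vg=Vg,
        Ve=Ve,
        genetic_correlation=rho_g,
        reml_loglik=-float(best.fun),
        eigenvalues=s,
        U=U,
        y1_rot=y1r,
        y2_rot=y2r,
        ones_rot=ur,
    )


def mtmm_scan(
    y1,
    y2,
    geno: GenotypeMatrix,
    K: KinshipMatrix,
    maf_min: float = 0.05,
    null: BivariateNullFit | None = None,
    seed: int = 0,
) -> dict:
    """Per-SNP MTMM tests; returns {'any', 'common', 'specific'} results.

    Each value is an :class:`~methgwas.lmm.AssociationResult`-like frame
    with Wald chi-square p-values (the null covariance is held fixed at its
    REML estimate across SNPs).
    """
    from .lmm import AssociationResult

    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    keep = np.isfinite(y1) & np.isfinite(y2)
    keep_idx = np.where(keep)[0]
    Kv = K.values[np.ix_(keep_idx, keep_idx)]
    Ksub = KinshipMatrix(values=Kv, line_ids=[K.line_ids[i] for i in keep_idx])
    if null is None:
        null = fit_bivariate_null(y1[keep_idx], y2[keep_idx], Ksub, seed=seed)

    s = null.eigenvalues
    a, b, d, _ = _block_weights(null.Vg, null.Ve, s)
    u = null.ones_rot
    y1r, y2r = null.y1_rot, null.y2_rot

    idx, Z, mac, maf = _prepare_snps(geno, keep_idx, maf_min)
    Xr = null.U.T @ Z  # rotated, z-scored SNP columns

    # base design cross-products (per-trait intercepts)
    A11 = float(np.sum(a * u * u))
    A12 = float(np.sum(b * u * u))
    A22 = float(np.sum(d * u * u))
    c1y = float(np.sum(u * (a * y1r + b * y2r)))
    c2y = float(np.sum(u * (b * y1r + d * y2r)))
    # SNP cross-products, vectorized over SNPs
    au, bu, du = a * u, b * u, d * u
    x_c1a = Xr.T @ au  # sum a*u*x
    x_c1b = Xr.T @ bu
    x_c2d = Xr.T @ du
    X2 = Xr * Xr
    xax = X2.T @ a
    xbx = X2.T @ b
    xdx = X2.T @ d
    x1y = Xr.T @ (a * y1r + b * y2r)
    x2y = Xr.T @ (b * y1r + d * y2r)

    m = Xr.shape[1]
    stat_any = np.empty(m)
    stat_spec = np.empty(m)
    stat_comm = np.empty(m)
    beta1 = np.empty(m)
    beta2 = np.empty(m)
    beta_c = np.empty(m)
    se_c = np.empty(m)
    se_spec = np.empty(m)
    for j in range(m):
        M = np.array(
            [
                [A11, A12, x_c1a[j], x_c1b[j]],
                [A12, A22, x_c1b[j], x_c2d[j]],
                [x_c1a[j], x_c1b[j], xax[j], xbx[j]],
                [x_c1b[j], x_c2d[j], xbx[j], xdx[j]],
            ]
        )
        rhs = np.array([c1y, c2y, x1y[j], x2y[j]])
        try:
            Minv = np.linalg.inv(M)
        except np.linalg.LinAlgError:
            stat_any[j] = stat_spec[j] = stat_comm[j] = 0.0
            beta1[j] = beta2[j] = beta_c[j] = 0.0
            se_c[j] = se_spec[j] = np.nan
            continue
        coef = Minv @ rhs
        bpair = coef[2:]
        cov = Minv[2:, 2:]
        beta1[j], beta2[j] = bpair
        try:
            stat_any[j] = float(bpair @ np.linalg.solve(cov, bpair))
        except np.linalg.LinAlgError:
            stat_any[j] = 0.0
        diff = bpair[0] - bpair[1]
        vdiff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
        stat_spec[j] = (diff * diff / vdiff) if vdiff > 0 else 0.0
        se_spec[j] = np.sqrt(vdiff) if vdiff > 0 else np.nan

        # constrained fit: one shared effect column (x, x)
        Mc = np.array(
            [
                [A11, A12, x_c1a[j] + x_c1b[j]],
                [A12, A22, x_c1b[j] + x_c2d[j]],
                [
                    x_c1a[j] + x_c1b[j],
                    x_c1b[j] + x_c2d[j],
                    xax[j] + 2.0 * xbx[j] + xdx[j],
                ],
            ]
        )
        rc = np.array([c1y, c2y, x1y[j] + x2y[j]])
        try:
            Mc_inv = np.linalg.inv(Mc)
        except np.linalg.LinAlgError:
            stat_comm[j] = 0.0
            beta_c[j] = 0.0
            se_c[j] = np.nan
            continue
        cc = Mc_inv @ rc
        beta_c[j] = cc[2]
        vc = Mc_inv[2, 2]
        stat_comm[j] = (cc[2] ** 2 / vc) if vc > 0 else 0.0
        se_c[j] = np.sqrt(vc) if vc > 0 else np.nan

    def _frame(stat, df, beta, se, extra=None):
        p = np.clip(stats.chi2.sf(stat, df), np.finfo(float).tiny, 1.0)
        t = pd.DataFrame(
            {
                "snp_index": idx,
                "chrom": geno.chrom[idx],
                "pos": geno.pos[idx],
                "mac": mac,
                "maf": maf,
                "beta": beta,
                "se": se,
                "statistic": stat,
                "p_value": p,
                "neg_log10_p": -np.log10(p),
            }
        )
        if extra:
            for k, v in extra.items():
                t[k] = v
        return t

    n = keep_idx.size
    return {
        "any": AssociationResult(
            _frame(stat_any, 2, beta1, np.full(m, np.nan), {"beta2": beta2}), "mtmm-any", n
        ),
        "common": AssociationResult(_frame(stat_comm, 1, beta_c, se_c), "mtmm-common", n),
        "specific": AssociationResult(
            _frame(stat_spec, 1, beta1 - beta2, se_spec), "mtmm-specific", n
        ),
        "null": null,
    }
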