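"""Linear mixed-model association machinery.

Implements the kinship mixed model

    Y = a*L + b*X + g + e,   var(Y) = sg2*K + se2*I

with an identity-by-state kinship K, REML variance components profiled over
the variance ratio delta = se2/sg2 on the eigenbasis of K, and per-SNP Wald
tests computed by generalized least squares in the rotated space with delta
fixed at its null-model estimate (the EMMAX approximation; an exact mode
refits delta per SNP).  Y, the covariate L, and each tested SNP X are
z-scored before fitting; SNPs are filtered at MAF > maf_min (strict).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import GenotypeMatrix, KinshipMatrix
from .utils import zscore

__all__ = [
    "NullModelFit",
    "AssociationResult",
    "compute_kinship",
    "reml_fit",
    "association_scan",
    "bonferroni_threshold",
    "snp_heritability",
]

DELTA_GRID = np.logspace(-5, 5, 100)


def compute_kinship(geno: GenotypeMatrix) -> KinshipMatrix:
    """Identity-by-state kinship: per pair, the fraction of jointly
    non-missing SNPs with identical genotype.  Uses all SNPs (no MAF
    filter); missing genotypes are excluded pairwise."""
    if geno.n_lines < 2:
        raise ValueError("kinship needs at least 2 lines")
    V = geno.values
    M = np.isfinite(V)
    A1 = np.where(M, V, 0.0)
    A0 = np.where(M, 1.0 - V, 0.0)
    matches = A1 @ A1.T + A0 @ A0.T
    denom = M.astype(float) @ M.astype(float).T
    if (denom == 0).any():
        raise ValueError("a line pair shares no non-missing SNP")
    K = matches / denom
    K = (K + K.T) / 2.0
    return KinshipMatrix(values=K, line_ids=list(geno.line_ids))


@dataclass
class NullModelFit:
    """REML variance components of var(Y) = sg2*K + se2*I."""

    sigma_g2: float
    sigma_e2: float
    delta: float
    h2: float
    reml_loglik: float
    boundary: bool
    eigenvalues: np.ndarray = field(repr=False)
    U: np.ndarray = field(repr=False)
    y_rot: np.ndarray = field(repr=False)
    X_rot: np.ndarray = field(repr=False)


def _reml_loglik(delta: float, s: np.ndarray, y_rot: np.ndarray, X_rot: np.ndarray) -> float:
    """Restricted log-likelihood at variance ratio delta, sg2 profiled out."""
    n, p = X_rot.shape
    w = 1.0 / (s + delta)
    XtWX = (X_rot * w[:, None]).T @ X_rot
    XtWy = (X_rot * w[:, None]).T @ y_rot
    try:
        beta = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError:
        return -np.inf
    r = y_rot - X_rot @ beta
    rss = float(r @ (w * r))
    if rss <= 0:
        return -np.inf
    sign, logdet_XtWX = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return -np.inf
    df = n - p
    sg2 = rss / df
    ll = -0.5 * (
        df * (np.log(2.0 * np.pi * sg2) + 1.0)
        + np.sum(np.log(s + delta))
        + logdet_XtWX
    )
    return float(ll)


def _profile_delta(s: np.ndarray, y_rot: np.ndarray, X_rot: np.ndarray) -> tuple[float, float, bool]:
    """Maximize the restricted likelihood over delta (grid + Brent refine)."""
    ll_grid = np.array([_reml_loglik(d, s, y_rot, X_rot) for d in DELTA_GRID])
    if not np.isfinite(ll_grid).any():
        raise ValueError("restricted likelihood is non-finite everywhere on the delta grid")
    i = int(np.argmax(ll_grid))  # argmax returns the first (smallest-delta) tie
    lo = DELTA_GRID[max(i - 1, 0)]
    hi = DELTA_GRID[min(i + 1, len(DELTA_GRID) - 1)]
    res = optimize.minimize_scalar(
        lambda d: -_reml_loglik(d, s, y_rot, X_rot),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-8 * (hi - lo) + 1e-12},
    )
    delta = float(res.x)
    ll = _reml_loglik(delta, s, y_rot, X_rot)
    if ll < ll_grid[i]:  # Brent refinement must not lose to the grid
        delta, ll = float(DELTA_GRID[i]), float(ll_grid[i])
    boundary = bool(i == 0 or i == len(DELTA_GRID) - 1)
    return delta, float(ll), boundary


def reml_fit(y: np.ndarray, covariates, K: KinshipMatrix, eig=None) -> NullModelFit:
    """REML fit of the kinship null model.

    ``covariates`` may be None (intercept only) or an ``(n, c)`` matrix; an
    intercept column is always prepended.  The restricted likelihood is
    profiled over delta on a 100-point log grid spanning [1e-5, 1e5] and
    refined by bounded Brent optimization; grid ties break toward smaller
    delta.  Solutions at the grid boundary (h2 -> 0 or 1) are flagged.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if covariates is None:
        X = np.ones((n, 1))
    else:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        X = np.column_stack([np.ones(n), C])
    if eig is None:
        Kv = (K.values + K.values.T) / 2.0
        s, U = np.linalg.eigh(Kv)
        s = np.clip(s, 0.0, None)
    else:
        s, U = eig
    y_rot = U.T @ y
    X_rot = U.T @ X

    delta, ll, boundary = _profile_delta(s, y_rot, X_rot)
    w = 1.0 / (s + delta)
    XtWX = (X_rot * w[:, None]).T @ X_rot
    beta = np.linalg.solve(XtWX, (X_rot * w[:, None]).T @ y_rot)
    r = y_rot - X_rot @ beta
    sg2 = float(r @ (w * r)) / (n - X.shape[1])
    se2 = delta * sg2
    h2 = 1.0 / (1.0 + delta)
    return NullModelFit(
        sigma_g2=sg2,
        sigma_e2=se2,
        delta=delta,
        h2=h2,
        reml_loglik=float(ll),
        boundary=boundary,
        eigenvalues=s,
        U=U,
        y_rot=y_rot,
        X_rot=X_rot,
    )


@dataclass
class AssociationResult:
    """Per-SNP association statistics for one model."""

    table: pd.DataFrame
    model: str
    n_lines: int
    null_fit: NullModelFit | None = None

    @property
    def n_tested(self) -> int:
        return len(self.table)


def _prepare_snps(geno: GenotypeMatrix, keep_lines: np.ndarray, maf_min: float):
    """MAF-filter and z-score SNP columns over the included lines.

    Missing genotypes are mean-imputed before z-scoring.  Returns
    (snp_index, Z, mac, maf).
    """
    V = geno.values[keep_lines]
    ok = np.isfinite(V)
    n_ok = ok.sum(axis=0)
    ones = np.nansum(V, axis=0)
    mac = np.minimum(ones, n_ok - ones)
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(n_ok > 0, mac / n_ok, 0.0)
    keep = maf > maf_min
    idx = np.where(keep)[0]
    Z = V[:, idx].copy()
    col_mean = np.nanmean(Z, axis=0)
    miss = ~np.isfinite(Z)
    if miss.any():
        Z[miss] = np.broadcast_to(col_mean, Z.shape)[miss]
    Z -= Z.mean(axis=0)
    sd = Z.std(axis=0)
    sd[sd == 0] = 1.0
    Z /= sd
    return idx, Z, mac[idx].astype(int), maf[idx]


def association_scan(
    y,
    geno: GenotypeMatrix,
    K: KinshipMatrix,
    covariate=None,
    maf_min: float = 0.05,
    exact: bool = False,
    model: str | None = None,
) -> AssociationResult:
    """Univariate or conditional mixed-model scan.

    Lines with a missing phenotype (or covariate) are dropped before
    z-scoring; the kinship is subset accordingly.  For each SNP passing
    MAF > maf_min, beta is tested by GLS in the eigenbasis of K with delta
    fixed at the null REML estimate; two-sided Wald p-values come from the
    t distribution with n - p degrees of freedom.  ``exact=True`` refits
    delta per SNP.  A SNP perfectly collinear with the covariate gets p = 1
    and a flag.
    """
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(y)
    if covariate is not None:
        covariate = np.asarray(covariate, dtype=float)
        if np.all(covariate == 0):
            raise ValueError("covariate is identically zero")
        keep &= np.isfinite(covariate)
    keep_idx = np.where(keep)[0]
    n = keep_idx.size
    yz = zscore(y[keep_idx])
    Kv = K.values[np.ix_(keep_idx, keep_idx)]
    Ksub = KinshipMatrix(values=Kv, line_ids=[K.line_ids[i] for i in keep_idx])

    if covariate is not None:
        cz = zscore(covariate[keep_idx])
        X0 = cz[:, None]
        model = model or "conditional"
    else:
        X0 = None
        model = model or "univariate"

    null = reml_fit(yz, X0, Ksub)
    idx, Z, mac, maf = _prepare_snps(geno, keep_idx, maf_min)
    s, U = null.eigenvalues, null.U
    y_rot = null.y_rot
    A_rot = null.X_rot  # intercept (+ covariate), rotated
    G_rot = U.T @ Z
    p_fixed = A_rot.shape[1] + 1

    def _gls(delta: float, cols=slice(None)):
        w = 1.0 / (s + delta)
        Aw = A_rot * w[:, None]
        AtWA = Aw.T @ A_rot
        AtWA_inv = np.linalg.inv(AtWA)
        # residualize y and each SNP against the base design in the W metric
        coef_y = AtWA_inv @ (Aw.T @ y_rot)
        y_res = y_rot - A_rot @ coef_y
        if float(y_res @ (w * y_res)) < 1e-10 * n:
            # covariate explains the phenotype completely (e.g. L = Y):
            # nothing left to test
            k = G_rot.shape[1] if isinstance(cols, slice) else len(np.atleast_1d(cols))
            return (
                np.zeros(k),
                np.full(k, np.nan),
                np.ones(k),
                np.zeros(k) if A_rot.shape[1] > 1 else None,
                np.zeros(k, dtype=bool),
            )
        G = G_rot[:, cols]
        coef_G = AtWA_inv @ (Aw.T @ G)
        G_res = G - A_rot @ coef_G
        gWg = np.einsum("ij,ij->j", G_res * w[:, None], G_res)
        gWy = (G_res * w[:, None]).T @ y_res
        yWy = float(y_res @ (w * y_res))
        collinear = gWg < 1e-10
        gWg_safe = np.where(collinear, 1.0, gWg)
        beta = gWy / gWg_safe
        rss = yWy - beta**2 * gWg_safe
        df = n - p_fixed
        sigma2 = np.clip(rss, 0.0, None) / df
        se = np.sqrt(np.clip(sigma2 / gWg_safe, 0.0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(se > 0, beta / se, 0.0)
        pval = 2.0 * stats.t.sf(np.abs(tstat), df)
        # covariate coefficient at the fitted SNP effect
        alpha = None
        if A_rot.shape[1] > 1:
            alpha = coef_y[1] - coef_G[1] * beta
        pval = np.where(collinear, 1.0, pval)
        beta = np.where(collinear, 0.0, beta)
        se = np.where(collinear, np.nan, se)
        return beta, se, pval, alpha, collinear

    if exact:
        # refit delta per SNP with the SNP in the model (avoids the EMMAX
        # null absorbing a large tested effect into sigma_g2); the profiled
        # restricted likelihood is evaluated on the delta grid for every
        # SNP at once and maximized per SNP (ties toward smaller delta)
        m = Z.shape[1]
        df = n - p_fixed
        G2 = G_rot**2
        ll = np.full((len(DELTA_GRID), m), -np.inf)
        for gi, d in enumerate(DELTA_GRID):
            w = 1.0 / (s + d)
            Aw = A_rot * w[:, None]
            AtWA = Aw.T @ A_rot
            sign, logdetA = np.linalg.slogdet(AtWA)
            if sign <= 0:
                continue
            AtWA_inv = np.linalg.inv(AtWA)
            coef_y = AtWA_inv @ (Aw.T @ y_rot)
            y_res = y_rot - A_rot @ coef_y  # W-orthogonal to the base design
            yWy = float(y_res @ (w * y_res))
            AtWG = Aw.T @ G_rot
            gWg = w @ G2 - np.einsum("pm,pm->m", AtWG, AtWA_inv @ AtWG)
            gWy = (w * y_res) @ G_rot
            ok = gWg > 1e-10
            rss = yWy - np.where(ok, gWy**2 / np.where(ok, gWg, 1.0), 0.0)
            good = ok & (rss > 0)
            sg2 = rss / df
            with np.errstate(divide="ignore", invalid="ignore"):
                ll[gi] = np.where(
                    good,
                    -0.5
                    * (
                        df * (np.log(2.0 * np.pi * sg2) + 1.0)
                        + np.sum(np.log(s + d))
                        + logdetA
                        + np.log(np.where(ok, gWg, 1.0))
                    ),
                    -np.inf,
                )
        pick = np.argmax(ll, axis=0)  # first max -> smaller delta on ties
        delta_snp = DELTA_GRID[pick]
        beta = np.empty(m)
        se = np.empty(m)
        pval = np.empty(m)
        alpha = np.full(m, np.nan)
        collinear = np.zeros(m, dtype=bool)
        for gi in np.unique(pick):
            cols = np.where(pick == gi)[0]
            b, e_, p_, a_, c_ = _gls(float(DELTA_GRID[gi]), cols=cols)
            beta[cols], se[cols], pval[cols], collinear[cols] = b, e_, p_, c_
            if a_ is not None:
                alpha[cols] = a_
    else:
        delta_snp = None
        beta, se, pval, alpha, collinear = _gls(null.delta)

    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    table = pd.DataFrame(
        {
            "snp_index": idx,
            "chrom": geno.chrom[idx],
            "pos": geno.pos[idx],
            "mac": mac,
            "maf": maf,
            "beta": beta,
            "se": se,
            "p_value": pval,
            "neg_log10_p": -np.log10(pval),
            "collinear": collinear,
        }
    )
    table["delta"] = delta_snp if delta_snp is not None else null.delta
    if covariate is not None:
        table["alpha"] = np.asarray(alpha, dtype=float) if alpha is not None else np.nan
    return AssociationResult(table=table, model=model, n_lines=n, null_fit=null)


def bonferroni_threshold(result: AssociationResult, alpha: float = 0.05) -> float:
    """alpha / (number of SNPs passing the MAF filter in the scan)."""
    if result.n_tested == 0:
        raise ValueError("empty association result")
    return alpha / result.n_tested


def snp_heritability(y, K: KinshipMatrix) -> float:
    """Pseudo-heritability sg2/(sg2+se2) from an intercept-only REML fit."""
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(y)
    Kv = K.values[np.ix_(keep.nonzero()[0], keep.nonzero()[0])]
    fit = reml_fit(y[keep], None, KinshipMatrix(values=Kv))
    return fit.h2
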