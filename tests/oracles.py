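"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive (explicit matrix inverses, direct
enumeration, hand-written formulas) and shares no code path with the
package implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
import scipy.stats as st


def zscore(x):
    x = np.asarray(x, float)
    return (x - x.mean()) / x.std()


def gls_oracle_scan(y, geno_values, K_values, delta_per_snp, covariate=None, maf_min=0.05):
    """Explicit V-inverse GLS Wald test, one SNP at a time.

    Forms V = K + delta*I, inverts it, and computes the Wald t statistic for
    the z-scored SNP column given intercept (+ z-scored covariate).
    Returns {snp_index: p_value}.
    """
    y = np.asarray(y, float)
    n = y.size
    yz = zscore(y)
    base = [np.ones(n)]
    if covariate is not None:
        base.append(zscore(covariate))
    ok = np.isfinite(geno_values)
    n_ok = ok.sum(axis=0)
    ones = np.nansum(geno_values, axis=0)
    maf = np.minimum(ones, n_ok - ones) / n_ok
    out = {}
    for j in np.where(maf > maf_min)[0]:
        x = geno_values[:, j].copy()
        miss = ~np.isfinite(x)
        if miss.any():
            x[miss] = np.nanmean(x)
        xz = zscore(x)
        X = np.column_stack(base + [xz])
        V = K_values + delta_per_snp[j] * np.eye(n)
        Vi = np.linalg.inv(V)
        XtViX = X.T @ Vi @ X
        b = np.linalg.solve(XtViX, X.T @ Vi @ yz)
        r = yz - X @ b
        s2 = (r @ Vi @ r) / (n - X.shape[1])
        se = np.sqrt(s2 * np.linalg.inv(XtViX)[-1, -1])
        out[j] = 2.0 * st.t.sf(abs(b[-1] / se), n - X.shape[1])
    return out


def welch_p(a, b):
    """Hand-written Welch two-sample two-tailed t-test."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return float(t), float(2.0 * st.t.sf(abs(t), df))


def rotation_exhaustive(pvals, member, thresholds_p):
    """Exact rotation tail fraction per threshold over every circular offset."""
    pvals = np.asarray(pvals, float)
    member = np.asarray(member, bool)
    G = len(pvals)
    n_ap = member.sum()
    n_bg = G - n_ap
    below = pvals[:, None] < np.asarray(thresholds_p)[None, :]
    x_obs = below[member].sum(axis=0) / n_ap
    y_obs = below[~member].sum(axis=0) / n_bg
    exceed = np.zeros(below.shape[1], dtype=int)
    for k in range(G):
        rot = np.roll(member, k)
        x_r = below[rot].sum(axis=0) / n_ap
        y_r = below[~rot].sum(axis=0) / n_bg
        exceed += (x_r * y_obs >= x_obs * y_r).astype(int)
    return exceed / G


def matched_perm_exhaustive_p(stat_fn, candidate_lists, n_perm_equivalent):
    """Exact tail probability of a matched-SNP permutation test.

    Enumerates the full product of per-locus candidate choices, applies
    ``stat_fn(choice_tuple) -> bool`` (does this draw reach the observed
    statistic?), and converts the exceedance fraction q to the expected
    add-one permutation p-value E[(1 + Binom(R, q)) / (R + 1)].
    """
    combos = list(itertools.product(*candidate_lists))
    q = np.mean([bool(stat_fn(c)) for c in combos])
    R = n_perm_equivalent
    return (1.0 + q * R) / (R + 1.0), q
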