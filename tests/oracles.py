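"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths of :mod:`aied`: the GLM oracle is a
hand-coded IRLS fitter (no statsmodels), the exact-test oracle is a plain
nested-loop enumeration in exact integer arithmetic, and the interval oracle
is an all-pairs scan.
"""

from __future__ import annotations

from math import comb

import numpy as np
from scipy import stats


def irls_binomial(alt, ref, X, max_iter=200, tol=1e-12):
    """Fit a binomial-logit GLM to (alt, ref) counts by hand-rolled IRLS.

    Returns (beta, deviance).
    """
    alt = np.asarray(alt, dtype=float)
    ref = np.asarray(ref, dtype=float)
    n = alt + ref
    y = alt / n
    eta = np.log((alt + 0.5) / (ref + 0.5))
    beta = np.zeros(X.shape[1])
    dev_old = np.inf
    for _ in range(max_iter):
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-10, 1 - 1e-10)
        w = n * mu * (1 - mu)
        z = eta + (y - mu) / (mu * (1 - mu))
        wx = X * w[:, None]
        beta = np.linalg.solve(X.T @ wx, X.T @ (w * z))
        eta = X @ beta
        mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-10, 1 - 1e-10)
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(alt > 0, alt * np.log(alt / (n * mu)), 0.0)
            t2 = np.where(ref > 0, ref * np.log(ref / (n * (1 - mu))), 0.0)
        dev = 2.0 * float(np.sum(t1 + t2))
        if abs(dev - dev_old) < tol * (abs(dev) + 1):
            break
        dev_old = dev
    return beta, dev


def irls_lrt(alt, ref, X_full, X_null, df):
    """Likelihood-ratio p-value for the columns dropped between two designs."""
    _, dev_full = irls_binomial(alt, ref, X_full)
    _, dev_null = irls_binomial(alt, ref, X_null)
    lrt = max(0.0, dev_null - dev_full)
    return float(stats.chi2.sf(lrt, df)), dev_full, dev_null


def design_matrices(group, age=None, sex=None):
    """Treatment-coded (full, null-without-group, df_group) design matrices."""
    levels = list(dict.fromkeys(group))
    cols = [np.ones(len(group))]
    for lev in levels[1:]:
        cols.append((np.asarray(group) == lev).astype(float))
    n_group = len(levels) - 1
    for cov in (age, sex):
        if cov is None:
            continue
        lv = list(dict.fromkeys(cov))
        for lev in lv[1:]:
            cols.append((np.asarray(cov) == lev).astype(float))
    X_full = np.column_stack(cols)
    keep = [0] + list(range(1 + n_group, X_full.shape[1]))
    return X_full, X_full[:, keep], n_group


def brute_fisher(table, gate=1e-7):
    """Two-sided exact homogeneity p for a (K, 2) table of (ref, alt) totals.

    Nested-loop enumeration of every table with the observed margins; each
    table's probability numerator is an exact integer over the common
    denominator C(N, A). Tables with probability <= p_obs * (1 + gate) are
    summed (the conventional tie gate).
    """
    t = np.asarray(table, dtype=np.int64)
    n = [int(v) for v in t.sum(axis=1)]
    A = int(t[:, 1].sum())
    N = sum(n)
    denom = comb(N, A)

    def numerator(a):
        out = 1
        for nj, aj in zip(n, a):
            out *= comb(nj, aj)
        return out

    obs = numerator(t[:, 1])
    threshold = obs * (1.0 + gate)
    total = 0
    K = len(n)

    def rec(j, rem, acc):
        nonlocal total
        if j == K - 1:
            if 0 <= rem <= n[j]:
                num = numerator(acc + [rem])
                if num <= threshold:
                    total += num
            return
        for a in range(0, min(n[j], rem) + 1):
            rec(j + 1, rem - a, acc + [a])

    rec(0, A, [])
    return total / denom


def brute_repeat_overlap(sites, repeats):
    """All-pairs interval scan: first repeat (file order) covering pos-1, else None."""
    out = []
    for _, s in sites.iterrows():
        hit = None
        for _, r in repeats.iterrows():
            if r["chrom"] == s["chrom"] and r["start"] <= s["pos"] - 1 < r["end"]:
                hit = r["family"]
                break
        out.append(hit)
    return out


def membership_venn(named_sets):
    """Venn cell counts from an explicit per-id membership matrix."""
    names = list(named_sets)
    union = sorted(set().union(*named_sets.values()))
    cells = {}
    for sid in union:
        key = tuple(sorted(n for n in names if sid in named_sets[n]))
        cells[key] = cells.get(key, 0) + 1
    return cells
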