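"""Differential RNA-editing statistics.

The detection procedure is two-stage. For every included site a binomial
GLM with logit link is fitted to the per-sample edited/unedited read counts,
and the group factor is tested with a likelihood-ratio test against the
reduced model (``P_GLM``, chi-square with ``#groups - 1`` degrees of
freedom). Sites passing ``P_GLM < 0.05`` receive a confirmatory exact test
on the 2 x K table of allele counts pooled within groups (``P_Fisher``).
``P_GLM`` values are Benjamini-Hochberg adjusted across tested sites, and a
site is called differentially edited iff ``FDR < alpha`` and
``P_Fisher < 0.05``. A cross-dataset mode skips the FDR adjustment and calls
at raw ``P_GLM < 0.05``, which avoids over-correction when independently
processed datasets are compared.

Age and sex enter as covariates in the same GLM; dropping one factor at a
time gives single-degree-of-freedom likelihood-ratio p-values per covariate.

Because read counts from biological replicates are typically overdispersed
relative to the binomial, an optional quasi-binomial mode rescales the LRT
by the Pearson dispersion of the full model and refers it to an F
distribution. The default is the plain binomial LRT; see the methods note
for the calibration consequences of that choice.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError
from scipy.special import gammaln

from .catalog import SubgroupScheme
from .exceptions import ConfigurationError
from .quantify import DEFAULT_MIN_COVERAGE, build_editing_matrix, subgroup_means

__all__ = [
    "GLMResult",
    "glm_lrt_site",
    "covariate_effects",
    "fisher_pooled",
    "bh_adjust",
    "dre_inclusion_mask",
    "trend_cluster",
    "call_dre",
]

TREND_LABELS = ("early_up_then_down", "late_up", "down", "unclassified")


@dataclass
class GLMResult:
    """Outcome of one per-site GLM likelihood-ratio test."""

    p_value: float
    statistic: float
    df: int
    flag: str = ""  # "", "degenerate", "insufficient", "nonconverged"
    group_coefs: dict | None = None


def _design(group, age=None, sex=None):
    """Intercept + treatment-coded factor columns; returns (X_full, X_null, df_group, names)."""
    group = pd.Categorical(group)
    cols = [np.ones(len(group))]
    names = ["intercept"]
    for lev in group.categories[1:]:
        cols.append((group == lev).astype(float))
        names.append(f"group[{lev}]")
    df_group = len(group.categories) - 1
    n_group_cols = df_group
    for label, cov in (("age", age), ("sex", sex)):
        if cov is None:
            continue
        c = pd.Categorical(cov)
        for lev in c.categories[1:]:
            cols.append((c == lev).astype(float))
            names.append(f"{label}[{lev}]")
    X_full = np.column_stack(cols)
    keep_null = [0] + list(range(1 + n_group_cols, X_full.shape[1]))
    X_null = X_full[:, keep_null]
    return X_full, X_null, df_group, names


def _fit_binomial(alt, ref, X):
    endog = np.column_stack([alt, ref])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(endog, X, family=sm.families.Binomial())
        return model.fit(maxiter=100, tol=1e-10)


def _lrt(alt, ref, X_full, X_null, df, dispersion="none"):
    """Deviance-based LRT of the columns dropped between the two designs."""
    try:
        full = _fit_binomial(alt, ref, X_full)
        null = _fit_binomial(alt, ref, X_null)
    except (np.linalg.LinAlgError, ValueError, PerfectSeparationError):
        return GLMResult(np.nan, np.nan, df, flag="nonconverged")
    lrt = max(0.0, float(null.deviance - full.deviance))
    if dispersion == "quasi":
        df_resid = len(alt) - X_full.shape[1]
        if df_resid <= 0:
            return GLMResult(np.nan, lrt, df, flag="insufficient")
        phi = max(float(full.pearson_chi2) / df_resid, 1e-12)
        f_stat = (lrt / df) / phi
        p = float(stats.f.sf(f_stat, df, df_resid))
    elif dispersion == "none":
        p = float(stats.chi2.sf(lrt, df))
    else:
        raise ConfigurationError(f"unknown dispersion mode {dispersion!r}")
    return GLMResult(p, lrt, df, group_coefs=dict(zip(range(X_full.shape[1]), full.params)))


def glm_lrt_site(
    alt,
    ref,
    group,
    age=None,
    sex=None,
    dispersion: str = "none",
    min_per_group: int = 2,
) -> GLMResult:
    """Test the group factor at one site with a binomial GLM + LRT.

    Parameters
    ----------
    alt, ref
        Edited and unedited read counts per sample (samples below the
        coverage floor should be excluded by the caller).
    group
        Group label per sample; the LRT has ``#groups - 1`` degrees of freedom.
    age, sex
        Optional covariates kept in both the full and reduced models.
    dispersion
        ``"none"`` for the plain chi-square LRT, ``"quasi"`` for the
        Pearson-dispersion-scaled F test.

    Notes
    -----
    Sites with no edited (or no unedited) read anywhere carry no group
    information: they return ``p = 1`` with flag ``"degenerate"`` rather than
    raising. Designs with fewer than two groups having ``min_per_group``
    samples return a missing p-value with flag ``"insufficient"``.
    """
    alt = np.asarray(alt, dtype=float)
    ref = np.asarray(ref, dtype=float)
    group = np.asarray(group)
    counts = pd.Series(group).value_counts()
    if (counts >= min_per_group).sum() < 2:
        return GLMResult(np.nan, np.nan, max(1, len(counts) - 1), flag="insufficient")
    if alt.sum() == 0 or ref.sum() == 0:
        return GLMResult(1.0, 0.0, len(counts) - 1, flag="degenerate")
    X_full, X_null, df, names = _design(group, age, sex)
    res = _lrt(alt, ref, X_full, X_null, df, dispersion)
    if res.group_coefs is not None:
        res.group_coefs = {
            names[i]: float(v) for i, v in res.group_coefs.items() if names[i].startswith("group[")
        }
    return res


def covariate_effects(
    alt, ref, group, age, sex, dispersion: str = "none"
) -> dict[str, float]:
    """Age and sex likelihood-ratio p-values at one site.

    The full model is intercept + group + age + sex; each covariate is
    dropped in turn (df = 1 per two-level factor). A covariate constant
    across samples is inestimable and reported as NaN.
    """
    alt = np.asarray(alt, dtype=float)
    ref = np.asarray(ref, dtype=float)
    out: dict[str, float] = {}
    for name, dropped, kept in (("p_age", age, sex), ("p_sex", sex, age)):
        dropped = np.asarray(dropped)
        if len(pd.unique(dropped)) < 2:
            out[name] = np.nan
            continue
        full_X, _, _, _ = _design(group, age=age, sex=sex)
        if name == "p_age":
            null_X, _, _, _ = _design(group, age=None, sex=kept)
        else:
            null_X, _, _, _ = _design(group, age=kept, sex=None)
        df = len(pd.unique(dropped)) - 1
        if alt.sum() == 0 or ref.sum() == 0:
            out[name] = 1.0
            continue
        res = _lrt(alt, ref, full_X, null_X, df, dispersion)
        out[name] = res.p_value
    return out


def _log_binom(n: int) -> np.ndarray:
    a = np.arange(n + 1)
    return gammaln(n + 1) - gammaln(a + 1) - gammaln(n - a + 1)


def fisher_pooled(
    table,
    rng: np.random.Generator | None = None,
    max_tables: int = 5_000_000,
    mc_draws: int = 100_000,
) -> float:
    """Exact test of allele-count homogeneity on a pooled 2 x K table.

    ``table`` has one row per group, columns ``(ref_total, alt_total)``.
    K = 2 uses the standard two-sided hypergeometric test; K > 2 uses the
    Freeman-Halton extension by exact enumeration of all tables with the
    observed margins, summing the probabilities of tables no more probable
    than the observed one. Beyond ``max_tables`` candidate tables a seeded
    Monte-Carlo estimate over the multivariate hypergeometric null is used
    (pass ``rng`` for reproducibility).

    Groups with zero total reads are dropped with a warning; fewer than two
    remaining groups yield NaN.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[1] != 2:
        raise ConfigurationError("fisher_pooled expects a (K, 2) table of (ref, alt) totals")
    totals = t.sum(axis=1)
    if (totals == 0).any():
        warnings.warn("dropping group(s) with zero total reads", stacklevel=2)
        t = t[totals > 0]
        totals = totals[totals > 0]
    k = t.shape[0]
    if k < 2:
        return float("nan")
    if k == 2:
        return float(stats.fisher_exact(t, alternative="two-sided")[1])

    n = totals
    A = int(t[:, 1].sum())
    N = int(n.sum())
    log_tables = [_log_binom(int(nj)) for nj in n]
    log_denom = gammaln(N + 1) - gammaln(A + 1) - gammaln(N - A + 1)
    obs_logp = sum(lt[int(a)] for lt, a in zip(log_tables, t[:, 1])) - log_denom
    tol = 1e-7  # log-space gate ~ probability ratio 1 + 1e-7, the conventional tie gate

    ranges = [min(int(nj), A) + 1 for nj in n[:-1]]
    n_candidates = int(np.prod(ranges, dtype=np.float64))
    if n_candidates <= max_tables:
        # enumerate the first K-1 alt counts on a grid; the last is implied
        grids = np.meshgrid(*[np.arange(r) for r in ranges], indexing="ij")
        partial = sum(g for g in grids)
        last = A - partial
        valid = (last >= 0) & (last <= int(n[-1]))
        logp = sum(lt[g] for lt, g in zip(log_tables, grids))
        logp = logp + np.where(valid, log_tables[-1][np.clip(last, 0, int(n[-1]))], -np.inf)
        logp = logp - log_denom
        mask = valid & (logp <= obs_logp + tol)
        return float(np.exp(logp[mask]).sum())

    rng = rng or np.random.default_rng(0)
    draws = rng.multivariate_hypergeometric(n.tolist(), A, size=mc_draws)
    logp = np.array(
        [sum(lt[int(a)] for lt, a in zip(log_tables, row)) - log_denom for row in draws]
    )
    return float((1 + np.count_nonzero(logp <= obs_logp + tol)) / (mc_draws + 1))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, NaN-aware and capped at 1.

    Missing entries are excluded from the adjustment and reinserted as NaN.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    m = int(ok.sum())
    if m == 0:
        return out
    ps = p[ok]
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    result = np.empty(m)
    result[order] = np.minimum(adjusted, 1.0)
    out[ok] = result
    return out


def dre_inclusion_mask(
    matrix: pd.DataFrame, scheme: SubgroupScheme, threshold: float = 0.05
) -> pd.Series:
    """Sites eligible for differential testing: any subgroup mean >= threshold."""
    means = subgroup_means(matrix, scheme.mapping)
    return (means.max(axis=1, skipna=True) >= threshold).fillna(False)


def trend_cluster(mean_control: float, mean_d1: float, mean_d4: float) -> str:
    """Classify a temporal editing trajectory over (baseline, early, late).

    ``early_up_then_down``: up at the early point, then lower than the early
    point. ``late_up``: the late point exceeds baseline and is at least the
    early point. ``down``: both post-baseline points below baseline.
    Anything else — including exact ties that satisfy no rule strictly — is
    ``unclassified``.
    """
    m0, m1, m4 = mean_control, mean_d1, mean_d4
    if any(np.isnan(v) for v in (m0, m1, m4)):
        return "unclassified"
    if m1 > m0 and m4 < m1:
        return "early_up_then_down"
    if m4 > m0 and m4 >= m1:
        return "late_up"
    if m1 < m0 and m4 < m0:
        return "down"
    return "unclassified"


def call_dre(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    groups: tuple[str, ...] | None = None,
    scheme: SubgroupScheme | None = None,
    inclusion_threshold: float = 0.05,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    alpha_fdr: float = 0.05,
    alpha_fisher: float = 0.05,
    fdr_mode: str = "bh",
    dispersion: str = "none",
    covariates: bool = False,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Run the full two-stage differential-editing procedure.

    Parameters
    ----------
    counts
        Long oriented allele-count table (catalog sites).
    metadata
        Sample metadata with ``group`` and optionally ``age``/``sex``.
    groups
        Temporal/experimental group order; defaults to order of appearance.
        With exactly three groups, trend labels are assigned to DRE calls.
    scheme
        Subgroup scheme for the inclusion mask; when omitted every site is
        tested.
    fdr_mode
        ``"bh"``: DRE iff BH-adjusted ``P_GLM`` < ``alpha_fdr`` and
        ``P_Fisher`` < ``alpha_fisher``. ``"off"``: DRE iff raw
        ``P_GLM`` < 0.05 (cross-dataset comparisons).
    covariates
        When true and metadata has two-level age and sex, per-site covariate
        p-values are computed for every tested site.

    Returns
    -------
    One row per tested site with ``p_glm``, ``p_fisher``, ``fdr``, per-group
    mean levels (``mean_<group>``), ``max_delta``, ``delta5_flag``,
    ``trend`` and ``is_dre``.
    """
    if fdr_mode not in ("bh", "off"):
        raise ConfigurationError(f"unknown fdr_mode {fdr_mode!r}")
    meta = metadata.set_index("sample_id")
    if groups is None:
        groups = tuple(pd.unique(meta["group"]))
    matrix = build_editing_matrix(counts, min_coverage)
    if scheme is not None:
        mask = dre_inclusion_mask(matrix, scheme, inclusion_threshold)
        site_ids = list(matrix.index[mask.to_numpy()])
    else:
        site_ids = list(matrix.index)

    has_age = "age" in meta.columns and meta["age"].astype(str).nunique() >= 2
    has_sex = "sex" in meta.columns and meta["sex"].astype(str).nunique() >= 2
    do_cov = covariates and has_age and has_sex

    by_site = dict(tuple(counts.groupby("site_id", sort=False)))
    rows = []
    for sid in site_ids:
        sub = by_site[sid]
        total = (sub["ref_count"] + sub["alt_count"]).to_numpy()
        adequate = total >= min_coverage
        sub = sub[adequate]
        g = meta.loc[sub["sample_id"], "group"].to_numpy()
        alt = sub["alt_count"].to_numpy()
        ref = sub["ref_count"].to_numpy()
        res = glm_lrt_site(alt, ref, g, dispersion=dispersion)
        row = {"site_id": sid, "p_glm": res.p_value, "glm_flag": res.flag}

        gm = {}
        for grp in groups:
            cols = meta.index[meta["group"] == grp]
            vals = matrix.loc[sid, matrix.columns.intersection(cols)]
            gm[grp] = float(vals.mean()) if vals.notna().any() else np.nan
            row[f"mean_{grp}"] = gm[grp]
        deltas = [
            abs(gm[a] - gm[b])
            for a, b in itertools.combinations(groups, 2)
            if not (np.isnan(gm[a]) or np.isnan(gm[b]))
        ]
        row["max_delta"] = max(deltas) if deltas else np.nan
        row["delta5_flag"] = bool(row["max_delta"] >= 0.05) if deltas else False

        if not np.isnan(res.p_value) and res.p_value < 0.05:
            pooled = np.array(
                [
                    [ref[g == grp].sum(), alt[g == grp].sum()]
                    for grp in groups
                    if (g == grp).any()
                ]
            )
            row["p_fisher"] = fisher_pooled(pooled, rng=rng)
        else:
            row["p_fisher"] = np.nan

        if do_cov:
            cov = covariate_effects(
                alt,
                ref,
                g,
                meta.loc[sub["sample_id"], "age"].to_numpy(),
                meta.loc[sub["sample_id"], "sex"].to_numpy(),
                dispersion=dispersion,
            )
            row.update(cov)
        rows.append(row)

    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["fdr"] = bh_adjust(out["p_glm"].to_numpy())
    if fdr_mode == "off":
        out["is_dre"] = out["p_glm"] < 0.05
    else:
        out["is_dre"] = (out["fdr"] < alpha_fdr) & (out["p_fisher"] < alpha_fisher)
    out["is_dre"] = out["is_dre"].astype(bool)

    if len(groups) == 3:
        trends = []
        for _, r in out.iterrows():
            if r["is_dre"]:
                trends.append(
                    trend_cluster(
                        r[f"mean_{groups[0]}"], r[f"mean_{groups[1]}"], r[f"mean_{groups[2]}"]
                    )
                )
            else:
                trends.append("")
        out["trend"] = trends
    else:
        out["trend"] = ""
    return out
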