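"""Editing-level quantification and sample-wide summaries.

The editing level at a site in a sample is ``alt / (ref + alt)`` — the
fraction of reads supporting the edited (G) allele — and is treated as
missing wherever coverage falls below a floor (default 10 reads), so that
single-read artefacts never enter averages.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "editing_level",
    "build_editing_matrix",
    "subgroup_means",
    "sample_average_editing",
    "average_vs_counts_correlation",
    "group_anova",
]

DEFAULT_MIN_COVERAGE = 10


def editing_level(ref_count, alt_count, min_coverage: int = DEFAULT_MIN_COVERAGE):
    """Editing proportion ``alt / (ref + alt)``, or NaN below the coverage floor.

    Accepts scalars or arrays; the return matches the input shape.
    """
    ref = np.asarray(ref_count, dtype=float)
    alt = np.asarray(alt_count, dtype=float)
    total = ref + alt
    with np.errstate(divide="ignore", invalid="ignore"):
        level = np.where(total >= min_coverage, alt / np.where(total > 0, total, 1.0), np.nan)
    if np.isscalar(ref_count) and np.isscalar(alt_count):
        return float(level)
    return level


def build_editing_matrix(
    counts: pd.DataFrame, min_coverage: int = DEFAULT_MIN_COVERAGE
) -> pd.DataFrame:
    """Pivot long allele counts into a sites x samples editing-level matrix.

    Cells with coverage below ``min_coverage`` (or absent site/sample pairs)
    are NaN. Row order follows first appearance of each site in the input.
    """
    df = counts.copy()
    df["level"] = editing_level(
        df["ref_count"].to_numpy(), df["alt_count"].to_numpy(), min_coverage
    )
    matrix = df.pivot_table(index="site_id", columns="sample_id", values="level", sort=False)
    order = counts["site_id"].drop_duplicates()
    return matrix.reindex(order)


def subgroup_means(matrix: pd.DataFrame, scheme: pd.Series) -> pd.DataFrame:
    """Mean editing level per site within each subgroup, skipping missing cells.

    ``scheme`` maps sample_id to a subgroup label. A subgroup with no covered
    sample at a site contributes NaN for that site, never propagating into
    other subgroups.
    """
    labels = scheme.reindex(matrix.columns)
    if labels.isna().any():
        missing = list(matrix.columns[labels.isna()])
        raise KeyError(f"samples missing from subgroup scheme: {missing[:5]}")
    return matrix.T.groupby(labels.to_numpy()).mean().T


def sample_average_editing(
    matrix: pd.DataFrame, site_genes: pd.Series | None = None
) -> pd.DataFrame:
    """Per-sample average editing plus edited-site and edited-gene counts.

    Returns a frame indexed by sample with ``mean_editing`` (arithmetic mean
    over non-missing sites), ``n_sites`` (sites with level > 0 at adequate
    coverage) and ``n_genes`` (genes with at least one such site, when
    ``site_genes`` maps site_id to gene symbol). Samples with no covered site
    get NaN and a warning.
    """
    mean = matrix.mean(axis=0, skipna=True)
    all_missing = matrix.notna().sum(axis=0) == 0
    if all_missing.any():
        warnings.warn(
            f"{int(all_missing.sum())} sample(s) have no covered site; mean set to NaN",
            stacklevel=2,
        )
    edited = (matrix > 0).fillna(False)
    n_sites = edited.sum(axis=0).astype(int)
    out = pd.DataFrame({"mean_editing": mean, "n_sites": n_sites})
    if site_genes is not None:
        genes = site_genes.reindex(matrix.index)
        n_genes = []
        for sample in matrix.columns:
            g = genes[edited[sample].to_numpy()]
            n_genes.append(int(g[g.astype(str) != ""].nunique()))
        out["n_genes"] = n_genes
    out.index.name = "sample_id"
    return out


def average_vs_counts_correlation(summary: pd.DataFrame) -> dict[str, float]:
    """Pearson correlation of per-sample average editing with edited-site
    (and, when present, edited-gene) counts.

    Returns ``{"r_sites", "p_sites"[, "r_genes", "p_genes"]}``; a zero-variance
    vector yields NaN for that pair.
    """
    ok = summary["mean_editing"].notna()
    x = summary.loc[ok, "mean_editing"].to_numpy(dtype=float)
    out: dict[str, float] = {}
    for key, col in (("sites", "n_sites"), ("genes", "n_genes")):
        if col not in summary.columns:
            continue
        y = summary.loc[ok, col].to_numpy(dtype=float)
        if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            out[f"r_{key}"] = np.nan
            out[f"p_{key}"] = np.nan
        else:
            r, p = stats.pearsonr(x, y)
            out[f"r_{key}"] = float(r)
            out[f"p_{key}"] = float(p)
    return out


def group_anova(summary: pd.DataFrame, metadata: pd.DataFrame) -> dict:
    """Convenience one-way ANOVA of per-sample mean editing across groups,
    with Tukey HSD pairwise contrasts."""
    merged = summary.join(metadata.set_index("sample_id")["group"], how="inner").dropna(
        subset=["mean_editing"]
    )
    groups = [g["mean_editing"].to_numpy() for _, g in merged.groupby("group")]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    f, p = stats.f_oneway(*groups)
    tukey = stats.tukey_hsd(*groups)
    labels = [name for name, _ in merged.groupby("group")]
    pairs = {
        f"{labels[i]} vs {labels[j]}": float(tukey.pvalue[i, j])
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    }
    return {"F": float(f), "p": float(p), "tukey": pairs}
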