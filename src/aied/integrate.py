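"""Expression normalization, differential expression, cis-regulation,
cross-dataset comparison and treatment-rescue calling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import ConfigurationError, ValidationError
from .quantify import DEFAULT_MIN_COVERAGE, build_editing_matrix

__all__ = [
    "tpm_normalize",
    "de_gene_test",
    "edited_expression_overlap",
    "cis_correlation",
    "cis_correlation_table",
    "OverlapReport",
    "overlap_dre_sets",
    "rescue_call",
]


def tpm_normalize(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million normalization of a genes x samples count matrix.

    Per sample: length-normalized rates ``count/length`` are rescaled to sum
    to one million. Columns therefore sum to 1e6 exactly (up to float error);
    a sample with zero total rate yields an all-zero column with a warning.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(counts.index[lengths.isna()])[:5]
        raise ValidationError(f"genes without length: {missing}")
    if (lengths <= 0).any():
        raise ValidationError("gene lengths must be positive")
    rates = counts.div(lengths, axis=0)
    denom = rates.sum(axis=0)
    zero = denom == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} sample(s) have zero library; TPM set to 0", stacklevel=2)
        denom = denom.replace(0, np.nan)
    tpm = rates.div(denom, axis=1) * 1e6
    return tpm.fillna(0.0)


def _nb_alpha(y: np.ndarray, mu: np.ndarray) -> float:
    """Method-of-moments NB dispersion: Var = mu + alpha * mu^2."""
    num = float(np.sum((y - mu) ** 2 - mu))
    den = float(np.sum(mu**2))
    if den <= 0:
        return 1e-8
    return float(np.clip(num / den, 1e-8, 10.0))


def de_gene_test(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    family: str = "nb",
) -> pd.DataFrame:
    """Per-gene differential expression across groups with a count GLM + LRT.

    Fits a log-link GLM per gene with a log-library-size offset and tests the
    group factor with a likelihood-ratio test (chi-square, ``#groups - 1``
    df). ``family="nb"`` (default) uses a negative-binomial variance with a
    per-gene moment estimate of the dispersion from a Poisson pilot fit;
    ``family="poisson"`` skips the dispersion. P-values are BH-adjusted
    across genes; all-zero genes are skipped with a flag.
    """
    if family not in ("nb", "poisson"):
        raise ConfigurationError(f"unknown family {family!r}")
    meta = metadata.set_index("sample_id")
    samples = [s for s in counts.columns if s in meta.index]
    if len(samples) < len(counts.columns):
        raise ValidationError("expression columns missing from metadata")
    group = pd.Categorical(meta.loc[samples, "group"])
    sizes = pd.Series(group).value_counts()
    if len(sizes) < 2:
        raise ConfigurationError("differential expression needs at least two groups")
    if family == "nb" and (sizes < 2).any():
        raise ConfigurationError("single-sample groups: dispersion is inestimable")
    y_all = counts[samples].to_numpy(dtype=float)
    offset = np.log(np.maximum(y_all.sum(axis=0), 1.0))
    X_full = np.column_stack(
        [np.ones(len(samples))] + [(group == lev).astype(float) for lev in group.categories[1:]]
    )
    X_null = X_full[:, :1]
    df = len(group.categories) - 1

    rows = []
    from .differential import bh_adjust

    for gene, y in zip(counts.index, y_all):
        if y.sum() == 0:
            rows.append({"gene": gene, "p": np.nan, "flag": "all_zero"})
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pilot = sm.GLM(y, X_full, family=sm.families.Poisson(), offset=offset).fit()
                if family == "nb":
                    alpha = _nb_alpha(y, pilot.mu)
                    fam = sm.families.NegativeBinomial(alpha=alpha)
                else:
                    fam = sm.families.Poisson()
                full = sm.GLM(y, X_full, family=fam, offset=offset).fit()
                null = sm.GLM(y, X_null, family=fam, offset=offset).fit()
            lrt = max(0.0, float(null.deviance - full.deviance))
            rows.append({"gene": gene, "p": float(stats.chi2.sf(lrt, df)), "flag": ""})
        except (np.linalg.LinAlgError, ValueError):
            rows.append({"gene": gene, "p": np.nan, "flag": "nonconverged"})
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out


def edited_expression_overlap(
    edited_genes, de_results: pd.DataFrame, alpha: float = 0.05
) -> dict:
    """Overlap of differentially edited genes with FDR-significant DE genes."""
    edited = {g for g in edited_genes if str(g) != ""}
    de = set(de_results.loc[de_results["fdr"] < alpha, "gene"])
    both = edited & de
    pct = 100.0 * len(both) / len(edited) if edited else np.nan
    return {
        "n_edited": len(edited),
        "n_de": len(de),
        "n_both": len(both),
        "percent_edited_de": pct,
        "genes": sorted(both),
    }


def cis_correlation(levels, expression, min_pairs: int = 5) -> tuple[float, float]:
    """Spearman rank correlation between a site's editing levels and its
    gene's expression across samples.

    Uses mid-ranks for ties and a two-sided p-value. Fewer than ``min_pairs``
    complete pairs, or a constant vector, yields ``(nan, nan)``.
    """
    x = np.asarray(levels, dtype=float)
    y = np.asarray(expression, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < min_pairs or np.all(x == x[0]) or np.all(y == y[0]):
        return np.nan, np.nan
    r, p = stats.spearmanr(x, y)
    return float(r), float(p)


def cis_correlation_table(
    matrix: pd.DataFrame,
    tpm: pd.DataFrame,
    site_genes: pd.Series,
    sites=None,
    min_pairs: int = 5,
) -> pd.DataFrame:
    """Per-site cis editing-expression Spearman correlations.

    ``site_genes`` maps site_id to gene symbol; sites whose gene is absent
    from the expression matrix are skipped.
    """
    sites = list(sites) if sites is not None else list(matrix.index)
    rows = []
    for sid in sites:
        gene = site_genes.get(sid, "")
        if gene not in tpm.index:
            continue
        common = matrix.columns.intersection(tpm.columns)
        r, p = cis_correlation(
            matrix.loc[sid, common], tpm.loc[gene, common], min_pairs=min_pairs
        )
        rows.append(
            {"site_id": sid, "gene": gene, "spearman_r": r, "p": p,
             "significant": bool(p < 0.05) if not np.isnan(p) else False}
        )
    return pd.DataFrame(rows, columns=["site_id", "gene", "spearman_r", "p", "significant"])


@dataclass
class OverlapReport:
    """Venn decomposition of named site-id sets.

    ``cells`` maps each non-empty membership pattern (a frozenset of set
    names) to the ids belonging to exactly those sets; cells partition the
    union.
    """

    sets: dict[str, set] = field(default_factory=dict)
    cells: dict[frozenset, set] = field(default_factory=dict)

    @property
    def shared_by_all(self) -> set:
        return self.cells.get(frozenset(self.sets), set())

    def in_and_any_other(self, name: str) -> set:
        """Ids in ``name`` that are also in at least one other set."""
        others = set().union(*(s for k, s in self.sets.items() if k != name)) if len(self.sets) > 1 else set()
        return self.sets[name] & others

    def cell_counts(self) -> dict[tuple, int]:
        return {tuple(sorted(k)): len(v) for k, v in self.cells.items()}


def overlap_dre_sets(named_sets: dict) -> OverlapReport:
    """Compute all ``2^k - 1`` Venn cells of named DRE site-id sets.

    Duplicate ids within a set are de-duplicated with a warning.
    """
    clean: dict[str, set] = {}
    for name, ids in named_sets.items():
        ids = list(ids)
        s = set(ids)
        if len(s) < len(ids):
            warnings.warn(f"duplicate ids in set {name!r} de-duplicated", stacklevel=2)
        clean[name] = s
    union = set().union(*clean.values()) if clean else set()
    cells: dict[frozenset, set] = {}
    for sid in union:
        pattern = frozenset(n for n, s in clean.items() if sid in s)
        cells.setdefault(pattern, set()).add(sid)
    return OverlapReport(sets=clean, cells=cells)


def rescue_call(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    groups: tuple[str, str, str] = ("CON", "LPS", "FUL"),
    alpha: float = 0.05,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> pd.DataFrame:
    """Call editing sites rescued by a pre-treatment in a three-arm design.

    With arms (control, insult, pre-treated insult), a site is rescued iff

    1. insult vs control is significant (two-group binomial GLM + LRT,
       p < ``alpha``),
    2. pre-treated vs insult is significant in the opposite direction, and
    3. the pre-treated mean is closer to the control mean than the insult
       mean is.

    Requires at least two samples per arm.
    """
    from .differential import glm_lrt_site

    con, ins, ful = groups
    meta = metadata.set_index("sample_id")
    sizes = meta["group"].value_counts()
    for g in groups:
        if sizes.get(g, 0) < 2:
            raise ConfigurationError(f"group {g!r} has fewer than 2 samples")
    matrix = build_editing_matrix(counts, min_coverage)
    rows = []
    for sid, sub in counts.groupby("site_id", sort=False):
        total = (sub["ref_count"] + sub["alt_count"]).to_numpy()
        sub = sub[total >= min_coverage]
        g = meta.loc[sub["sample_id"], "group"].to_numpy()
        alt = sub["alt_count"].to_numpy()
        ref = sub["ref_count"].to_numpy()

        means = {}
        for grp in groups:
            samples = meta.index[meta["group"] == grp]
            vals = matrix.loc[sid, matrix.columns.intersection(samples)]
            means[grp] = float(vals.mean()) if vals.notna().any() else np.nan

        def _contrast(g_a, g_b):
            sel = (g == g_a) | (g == g_b)
            return glm_lrt_site(alt[sel], ref[sel], g[sel])

        r1 = _contrast(con, ins)
        r2 = _contrast(ins, ful)
        d_insult = means[ins] - means[con]
        d_treat = means[ful] - means[ins]
        sig1 = (not np.isnan(r1.p_value)) and r1.p_value < alpha
        sig2 = (not np.isnan(r2.p_value)) and r2.p_value < alpha
        opposite = d_insult * d_treat < 0
        closer = abs(means[ful] - means[con]) < abs(d_insult)
        rescued = bool(sig1 and sig2 and opposite and closer)
        rows.append(
            {
                "site_id": sid,
                f"mean_{con}": means[con],
                f"mean_{ins}": means[ins],
                f"mean_{ful}": means[ful],
                "p_insult": r1.p_value,
                "p_treatment": r2.p_value,
                "rescued": rescued,
            }
        )
    return pd.DataFrame(rows)
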