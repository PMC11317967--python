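"""Synthetic A-to-I editing studies with known ground truth.

This module generates complete synthetic studies — per-site allele counts,
sample metadata, site annotations, a known-site whitelist, a repeat BED and a
coupled gene-expression matrix — whose statistical structure matches what the
downstream analysis assumes:

* edited-read counts are beta-binomial: at a site with true editing level
  ``p`` and intra-class correlation ``rho``, a sample with coverage ``n``
  contributes ``alt ~ BetaBinomial(n, p, rho)``, which degenerates to
  ``Binomial(n, p)`` at ``rho = 0``;
* coverage is Poisson with a configurable mean, floored at one read;
* group, age and sex effects are additive shifts on the proportion scale,
  clamped so no true level leaves ``[0.001, 0.999]``;
* gene expression of coupled genes is log-normal with its log-mean shifted by
  (realized editing level x coupling coefficient), so a monotone
  editing-expression association is recoverable by rank correlation.

The default design mirrors a three-group longitudinal sepsis study
(control / day-1 / day-4) stratified by age (young, old) and sex (male,
female) with four replicates per cell, i.e. 48 samples.

Every draw flows through a single :class:`numpy.random.Generator`, so a given
seed reproduces a study byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

__all__ = [
    "DesignSpec",
    "SimConfig",
    "SyntheticStudy",
    "beta_binomial",
    "simulate_site_counts",
    "true_level",
    "generate_study",
    "generate_rescue_study",
    "write_fixtures",
]

#: Functional-consequence categories with sampling weights proportional to the
#: composition of a mouse hippocampal editing catalog (3'UTR-dominated, with
#: intronic and missense sites next).
CONSEQUENCE_WEIGHTS = {
    "3'UTR": 922,
    "intronic": 315,
    "missense": 290,
    "synonymous": 66,
    "noncoding_exonic": 43,
    "5'UTR": 15,
    "noncoding_intronic": 13,
    "stop_loss": 4,
}

#: Murine SINE families with B1 dominating, as observed for editing sites.
REPEAT_WEIGHTS = {"B1": 0.60, "B2": 0.25, "B3": 0.10, "ID": 0.05}

_CHROMS = tuple(f"chr{i}" for i in range(1, 20)) + ("chrX",)

_TREND_PATTERNS = ("early_up_then_down", "late_up", "down")
_TREND_PROBS = (0.5, 0.3, 0.2)

_LEVEL_FLOOR = 0.001
_LEVEL_CEIL = 0.999


@dataclass(frozen=True)
class DesignSpec:
    """Factorial sample layout: group x age x sex x replicate.

    ``ages`` or ``sexes`` may be empty tuples, in which case that factor is
    absent (the metadata column is left blank and no covariate effect can be
    simulated). The first entry of ``groups`` is the reference group; effect
    shifts are expressed relative to it. Covariate shifts apply to the *last*
    listed level of the factor (e.g. ``old`` and ``female`` by default).
    """

    groups: tuple[str, ...] = ("control", "D1", "D4")
    ages: tuple[str, ...] = ("young", "old")
    sexes: tuple[str, ...] = ("male", "female")
    n_replicates: int = 4

    def samples(self, dataset: str = "SIM") -> pd.DataFrame:
        """Enumerate the design cells into a sample-metadata table."""
        ages = self.ages or ("",)
        sexes = self.sexes or ("",)
        rows = []
        for g in self.groups:
            for a in ages:
                for s in sexes:
                    for r in range(1, self.n_replicates + 1):
                        parts = [p for p in (g, a, s) if p]
                        rows.append(
                            {
                                "sample_id": "_".join(parts + [f"r{r}"]),
                                "group": g,
                                "age": a,
                                "sex": s,
                                "dataset": dataset,
                            }
                        )
        return pd.DataFrame(rows)

    @property
    def n_samples(self) -> int:
        return (
            len(self.groups)
            * max(1, len(self.ages))
            * max(1, len(self.sexes))
            * self.n_replicates
        )


@dataclass(frozen=True)
class SimConfig:
    """Study-level simulation parameters.

    Parameters
    ----------
    n_sites
        Number of candidate editing sites.
    frac_known
        Fraction of sites present in the known-site whitelist.
    frac_dre
        Fraction of sites with a true group effect (differentially edited).
    frac_age_effect, frac_sex_effect
        Fractions of sites with age- or sex-dependent shifts.
    baseline_level_range
        Interval from which baseline editing levels are drawn uniformly.
    effect_size
        Additive group shift on the proportion scale (default 0.10, i.e. ten
        percentage points).
    age_effect_size, sex_effect_size
        Additive covariate shifts applied to the last level of each factor.
    coverage_mean
        Mean of the Poisson coverage law (floored at one read).
    dispersion
        Beta-binomial intra-class correlation ``rho`` in ``[0, 1)``; 0 gives
        pure binomial counts.
    design
        Factorial sample layout.
    seed
        Seed for the study-level random generator.
    frac_repeat, frac_coupled, coupling, expression_noise_sd
        Repeat-overlap fraction, fraction of sites whose host gene expression
        is coupled to the editing level, the log-scale coupling slope, and the
        log-normal expression noise s.d.
    """

    n_sites: int = 500
    frac_known: float = 0.30
    frac_dre: float = 0.20
    frac_age_effect: float = 0.05
    frac_sex_effect: float = 0.05
    baseline_level_range: tuple[float, float] = (0.02, 0.40)
    effect_size: float = 0.10
    age_effect_size: float = 0.10
    sex_effect_size: float = 0.10
    coverage_mean: float = 50.0
    dispersion: float = 0.01
    design: DesignSpec = field(default_factory=DesignSpec)
    seed: int = 0
    frac_repeat: float = 0.55
    frac_coupled: float = 0.25
    coupling: float = 2.0
    expression_noise_sd: float = 0.40
    dataset: str = "SIM"

    def validate(self) -> None:
        for name in ("frac_known", "frac_dre", "frac_age_effect", "frac_sex_effect",
                     "frac_repeat", "frac_coupled"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v!r} is not a proportion in [0, 1]")
        lo, hi = self.baseline_level_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigurationError(
                f"baseline_level_range={self.baseline_level_range!r} is not an interval in [0, 1]"
            )
        if self.n_sites < 0:
            raise ConfigurationError("n_sites must be non-negative")
        if self.coverage_mean <= 0:
            raise ConfigurationError("coverage_mean must be > 0")
        if not 0.0 <= self.dispersion < 1.0:
            raise ConfigurationError(f"dispersion rho={self.dispersion!r} must lie in [0, 1)")
        if self.design.n_replicates < 1:
            raise ConfigurationError("design has zero replicates per cell")
        if len(self.design.groups) < 1:
            raise ConfigurationError("design needs at least one group")
        lowered = [g.lower() for g in self.design.groups]
        if len(set(lowered)) != len(lowered):
            raise ConfigurationError("group labels collide after lower-casing")
        wants_covariates = self.frac_age_effect > 0 or self.frac_sex_effect > 0
        if wants_covariates and self.design.n_replicates < 2:
            raise ConfigurationError(
                "covariate effects require at least two samples per subgroup"
            )
        if self.frac_age_effect > 0 and len(self.design.ages) < 2:
            raise ConfigurationError("age effects require at least two age levels")
        if self.frac_sex_effect > 0 and len(self.design.sexes) < 2:
            raise ConfigurationError("sex effects require at least two sex levels")


@dataclass
class SyntheticStudy:
    """All tables of one simulated study, ready for the analysis pipeline."""

    sites: pd.DataFrame
    allele_counts: pd.DataFrame
    metadata: pd.DataFrame
    annotation: pd.DataFrame
    known_sites: pd.DataFrame
    repeats: pd.DataFrame
    expression: pd.DataFrame
    gene_lengths: pd.Series
    truth: pd.DataFrame
    config: SimConfig


def beta_binomial(
    n: np.ndarray, p: np.ndarray, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw beta-binomial counts with mean ``n*p`` and intra-class correlation ``rho``.

    ``rho = 0`` degenerates to the binomial; ``p`` equal to exactly 0 or 1
    yields 0 or ``n`` deterministically.
    """
    if rho >= 1.0 or rho < 0.0:
        raise ConfigurationError(f"rho={rho!r} must lie in [0, 1)")
    n = np.asarray(n)
    p = np.asarray(p, dtype=float)
    n, p = np.broadcast_arrays(n, p)
    if rho == 0.0:
        return rng.binomial(n, p)
    out = np.zeros(n.shape, dtype=np.int64)
    interior = (p > 0.0) & (p < 1.0)
    if interior.any():
        scale = (1.0 - rho) / rho
        a = p[interior] * scale
        b = (1.0 - p[interior]) * scale
        q = rng.beta(a, b)
        out[interior] = rng.binomial(n[interior], q)
    out[p >= 1.0] = n[p >= 1.0]
    return out


def true_level(
    truth_row: pd.Series, group: str, age: str, sex: str, design: DesignSpec
) -> float:
    """Realized true editing level for one design cell, with effect clamping.

    The baseline level is returned untouched when no effect applies; any
    non-zero shift is clamped into ``[0.001, 0.999]`` after addition so that
    effects never create degenerate all-or-nothing sites.
    """
    shift = 0.0
    if group != design.groups[0]:
        shift += float(truth_row.get(f"{group.lower()}_shift", 0.0))
    if design.ages and age == design.ages[-1]:
        shift += float(truth_row.get("age_shift", 0.0))
    if design.sexes and sex == design.sexes[-1]:
        shift += float(truth_row.get("sex_shift", 0.0))
    base = float(truth_row["baseline"])
    if shift == 0.0:
        return base
    return float(np.clip(base + shift, _LEVEL_FLOOR, _LEVEL_CEIL))


def simulate_site_counts(
    truth_row: pd.Series,
    metadata: pd.DataFrame,
    coverage_mean: float,
    rng: np.random.Generator,
    design: DesignSpec | None = None,
) -> pd.DataFrame:
    """Simulate per-sample allele counts for one site.

    Coverage is ``max(1, Poisson(coverage_mean))`` per sample; edited-read
    counts are beta-binomial with the sample's subgroup true level and the
    site's dispersion ``rho``.

    Returns a frame with columns ``sample_id, ref_count, alt_count``.
    """
    design = design or DesignSpec()
    rho = float(truth_row.get("rho", 0.0))
    levels = np.array(
        [
            true_level(truth_row, r.group, r.age, r.sex, design)
            for r in metadata.itertuples()
        ]
    )
    if (levels < 0).any() or (levels > 1).any():
        raise ConfigurationError("true editing levels must lie in [0, 1]")
    coverage = np.maximum(1, rng.poisson(coverage_mean, size=len(metadata)))
    alt = beta_binomial(coverage, levels, rho, rng)
    return pd.DataFrame(
        {
            "sample_id": metadata["sample_id"].to_numpy(),
            "ref_count": coverage - alt,
            "alt_count": alt,
        }
    )


def _draw_sites(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_sites
    chrom = rng.choice(_CHROMS, size=n)
    pos = np.zeros(n, dtype=np.int64)
    seen: set[tuple[str, int]] = set()
    for i in range(n):
        while True:
            p = int(rng.integers(1_000_000, 100_000_000))
            if (chrom[i], p) not in seen:
                seen.add((chrom[i], p))
                pos[i] = p
                break
    strand = rng.choice(["+", "-"], size=n)
    n_genes = max(1, int(round(n / 1.7)))
    gene_idx = np.sort(rng.integers(0, n_genes, size=n))
    genes = np.array([f"Gene{i:04d}" for i in gene_idx], dtype=object)
    cats = list(CONSEQUENCE_WEIGHTS)
    w = np.array(list(CONSEQUENCE_WEIGHTS.values()), dtype=float)
    consequence = rng.choice(cats, size=n, p=w / w.sum())
    biotype = np.where(
        np.isin(consequence, ["noncoding_exonic", "noncoding_intronic"]),
        "lincRNA",
        "protein_coding",
    )
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "strand": strand,
            "gene": genes,
            "gene_biotype": biotype,
            "consequence": consequence,
        }
    )
    df["site_id"] = df["gene"] + ":" + df["chrom"] + ":" + df["pos"].astype(str)
    return df


def _draw_truth(
    config: SimConfig, sites: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    n = config.n_sites
    lo, hi = config.baseline_level_range
    baseline = rng.uniform(lo, hi, size=n)
    alt_groups = list(config.design.groups[1:])
    shifts = {f"{g.lower()}_shift": np.zeros(n) for g in alt_groups}

    is_dre = np.zeros(n, dtype=bool)
    n_dre = int(round(config.frac_dre * n))
    dre_idx = rng.choice(n, size=n_dre, replace=False)
    is_dre[dre_idx] = True
    e = config.effect_size
    if alt_groups and e != 0.0:
        if len(alt_groups) == 2:
            # three-group temporal design: mix of trend archetypes
            patterns = rng.choice(len(_TREND_PATTERNS), size=n_dre, p=_TREND_PROBS)
            g1, g2 = (f"{g.lower()}_shift" for g in alt_groups)
            for k, i in zip(patterns, dre_idx):
                name = _TREND_PATTERNS[k]
                if name == "early_up_then_down":
                    shifts[g1][i] = e
                elif name == "late_up":
                    shifts[g2][i] = e
                else:  # down in both post-baseline groups
                    shifts[g1][i] = -e
                    shifts[g2][i] = -e
        else:
            target = rng.choice(len(alt_groups), size=n_dre)
            for k, i in zip(target, dre_idx):
                shifts[f"{alt_groups[k].lower()}_shift"][i] = e
    else:
        is_dre[:] = False

    age_shift = np.zeros(n)
    if config.frac_age_effect > 0:
        idx = rng.choice(n, size=int(round(config.frac_age_effect * n)), replace=False)
        age_shift[idx] = config.age_effect_size
    sex_shift = np.zeros(n)
    if config.frac_sex_effect > 0:
        idx = rng.choice(n, size=int(round(config.frac_sex_effect * n)), replace=False)
        sex_shift[idx] = config.sex_effect_size

    coupling = np.zeros(n)
    if config.frac_coupled > 0:
        idx = rng.choice(n, size=int(round(config.frac_coupled * n)), replace=False)
        coupling[idx] = config.coupling

    truth = pd.DataFrame({"site_id": sites["site_id"].to_numpy(), "baseline": baseline})
    for k, v in shifts.items():
        truth[k] = v
    truth["age_shift"] = age_shift
    truth["sex_shift"] = sex_shift
    truth["rho"] = config.dispersion
    truth["coupling"] = coupling
    # definitional: a site is DRE iff some group shift is non-zero
    if shifts:
        truth["is_dre"] = np.any(
            np.column_stack([v != 0 for v in shifts.values()]), axis=1
        )
    else:
        truth["is_dre"] = False
    return truth


def _draw_repeats(
    config: SimConfig, sites: pd.DataFrame, rng: np.random.Generator
) -> tuple[pd.DataFrame, np.ndarray]:
    fams = list(REPEAT_WEIGHTS)
    w = np.array(list(REPEAT_WEIGHTS.values()))
    in_repeat = rng.random(config.n_sites) < config.frac_repeat
    rows = []
    for i in np.flatnonzero(in_repeat):
        pos0 = int(sites["pos"].iat[i]) - 1  # 0-based coordinate of the site
        offset = int(rng.integers(0, 120))
        length = int(rng.integers(offset + 1, offset + 300))
        start = max(0, pos0 - offset)
        rows.append(
            {
                "chrom": sites["chrom"].iat[i],
                "start": start,
                "end": start + length,
                "family": rng.choice(fams, p=w),
            }
        )
    # decoy repeats not containing any site
    for _ in range(config.n_sites // 5):
        start = int(rng.integers(0, 900_000))
        rows.append(
            {
                "chrom": rng.choice(_CHROMS),
                "start": start,
                "end": start + int(rng.integers(80, 400)),
                "family": rng.choice(fams, p=w),
            }
        )
    cols = ["chrom", "start", "end", "family"]
    rep = pd.DataFrame(rows, columns=cols)
    return rep, in_repeat


def _draw_expression(
    config: SimConfig,
    sites: pd.DataFrame,
    truth: pd.DataFrame,
    levels: np.ndarray,
    metadata: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.Series]:
    genes = sites["gene"].drop_duplicates().to_numpy()
    n_genes, n_samples = len(genes), len(metadata)
    lengths = pd.Series(
        rng.integers(500, 5000, size=n_genes), index=pd.Index(genes, name="gene"),
        name="length",
    )
    base = rng.normal(np.log(100.0), 0.8, size=n_genes)
    # each gene tracks its most strongly coupled site (0 slope if none)
    coupling = truth["coupling"].to_numpy()
    site_of_gene = np.zeros(n_genes, dtype=int)
    gene_index = {g: k for k, g in enumerate(genes)}
    best = np.full(n_genes, -1.0)
    for i, g in enumerate(sites["gene"]):
        k = gene_index[g]
        if coupling[i] > best[k]:
            best[k] = coupling[i]
            site_of_gene[k] = i
    slope = np.where(best > 0, best, 0.0)
    log_mu = (
        base[:, None]
        + slope[:, None] * levels[site_of_gene, :]
        + rng.normal(0.0, config.expression_noise_sd, size=(n_genes, n_samples))
    )
    counts = np.rint(np.exp(log_mu)).astype(np.int64)
    expr = pd.DataFrame(counts, index=lengths.index, columns=metadata["sample_id"])
    return expr, lengths


def generate_study(
    config: SimConfig,
    truth: pd.DataFrame | None = None,
    sites: pd.DataFrame | None = None,
) -> SyntheticStudy:
    """Generate a full synthetic study from a configuration.

    Parameters
    ----------
    config
        Validated simulation parameters. Identical configs (same seed) yield
        byte-identical studies.
    truth
        Optional pre-built truth table (one row per site with ``baseline``,
        per-group ``*_shift`` columns, ``age_shift``, ``sex_shift``, ``rho``,
        ``coupling`` and ``is_dre``); drawn from ``config`` when omitted.
    sites
        Optional pre-drawn site table (e.g. from another study's ``sites``
        attribute) so replicate datasets share site identities.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if sites is None:
        sites = _draw_sites(config, rng)
    elif len(sites) != config.n_sites:
        raise ConfigurationError("site table length does not match n_sites")
    if truth is None:
        truth = _draw_truth(config, sites, rng)
    else:
        if len(truth) != config.n_sites:
            raise ConfigurationError("truth table length does not match n_sites")
        truth = truth.copy()
        truth["site_id"] = sites["site_id"].to_numpy()  # positional alignment
    metadata = config.design.samples(config.dataset)

    count_frames = []
    levels = np.zeros((config.n_sites, len(metadata)))
    for i in range(config.n_sites):
        per_sample = simulate_site_counts(
            truth.iloc[i], metadata, config.coverage_mean, rng, config.design
        )
        total = (per_sample["ref_count"] + per_sample["alt_count"]).to_numpy()
        levels[i, :] = per_sample["alt_count"].to_numpy() / total
        block = per_sample.copy()
        for col in ("site_id", "chrom", "pos", "strand"):
            block[col] = sites[col].iat[i]
        count_frames.append(block)
    if count_frames:
        counts = pd.concat(count_frames, ignore_index=True)
    else:
        counts = pd.DataFrame(
            columns=["sample_id", "ref_count", "alt_count", "site_id", "chrom", "pos", "strand"]
        )
    # minus-strand sites are observed antisense (T>C); the reader re-orients
    counts["ref"] = np.where(counts["strand"] == "-", "T", "A")
    counts["alt"] = np.where(counts["strand"] == "-", "C", "G")
    counts = counts[
        ["site_id", "chrom", "pos", "strand", "ref", "alt", "sample_id", "ref_count", "alt_count"]
    ]

    n_known = int(round(config.frac_known * config.n_sites))
    known_idx = np.sort(rng.choice(config.n_sites, size=n_known, replace=False))
    known_sites = pd.DataFrame(
        {
            "Region": sites["chrom"].to_numpy()[known_idx],
            "Position": sites["pos"].to_numpy()[known_idx],
            "Ref": "A",
            "Ed": "G",
            "Strand": sites["strand"].to_numpy()[known_idx],
        }
    )
    truth = truth.copy()
    truth["is_known"] = False
    truth.loc[truth.index[known_idx], "is_known"] = True

    repeats, _ = _draw_repeats(config, sites, rng)

    annotation = sites.copy()
    annotation["cdna_change"] = [
        f"c.{int(p) % 10000}A>G" for p in annotation["pos"]
    ]
    aa = "ARNDCQEGHILKMFPSTWYV"
    annotation["protein_change"] = [
        f"p.{aa[int(rng.integers(0, 20))]}{int(rng.integers(1, 999))}{aa[int(rng.integers(0, 20))]}"
        if c in ("missense", "stop_loss")
        else ""
        for c in annotation["consequence"]
    ]
    annotation = annotation[
        ["site_id", "gene", "gene_biotype", "consequence", "cdna_change", "protein_change"]
    ]

    if config.n_sites > 0:
        expression, gene_lengths = _draw_expression(
            config, sites, truth, levels, metadata, rng
        )
    else:
        expression = pd.DataFrame(columns=metadata["sample_id"])
        expression.index.name = "gene"
        gene_lengths = pd.Series(dtype=np.int64, name="length")
        gene_lengths.index.name = "gene"

    return SyntheticStudy(
        sites=sites,
        allele_counts=counts,
        metadata=metadata,
        annotation=annotation,
        known_sites=known_sites,
        repeats=repeats,
        expression=expression,
        gene_lengths=gene_lengths,
        truth=truth,
        config=config,
    )


def generate_rescue_study(
    n_rescued: int = 20,
    n_unrescued: int = 0,
    n_null: int = 80,
    effect_size: float = 0.15,
    coverage_mean: float = 100.0,
    n_replicates: int = 3,
    dispersion: float = 0.0,
    seed: int = 0,
    groups: tuple[str, str, str] = ("CON", "LPS", "FUL"),
) -> SyntheticStudy:
    """Three-arm pre-treatment study with built-in rescue structure.

    ``n_rescued`` sites are shifted by ``effect_size`` under the insult group
    (second group) and return to baseline under pre-treatment (third group);
    ``n_unrescued`` sites stay shifted in both arms; ``n_null`` sites are
    flat. The truth table gains an ``is_rescued`` column.
    """
    n = n_rescued + n_unrescued + n_null
    design = DesignSpec(groups=groups, ages=(), sexes=(), n_replicates=n_replicates)
    config = SimConfig(
        n_sites=n,
        frac_dre=0.0,
        frac_age_effect=0.0,
        frac_sex_effect=0.0,
        effect_size=effect_size,
        coverage_mean=coverage_mean,
        dispersion=dispersion,
        design=design,
        seed=seed,
        frac_coupled=0.0,
    )
    config.validate()
    rng = np.random.default_rng(seed ^ 0x5EED)
    lo, hi = config.baseline_level_range
    insult, treated = groups[1].lower(), groups[2].lower()
    truth = pd.DataFrame(
        {
            "baseline": rng.uniform(lo, hi, size=n),
            f"{insult}_shift": [effect_size] * (n_rescued + n_unrescued) + [0.0] * n_null,
            f"{treated}_shift": [0.0] * n_rescued
            + [effect_size] * n_unrescued
            + [0.0] * n_null,
            "age_shift": 0.0,
            "sex_shift": 0.0,
            "rho": dispersion,
            "coupling": 0.0,
        }
    )
    truth["is_dre"] = (truth[f"{insult}_shift"] != 0) | (truth[f"{treated}_shift"] != 0)
    truth["is_rescued"] = [True] * n_rescued + [False] * (n_unrescued + n_null)
    # shuffle so rescue status is not confounded with site order
    perm = rng.permutation(n)
    truth = truth.iloc[perm].reset_index(drop=True)
    return generate_study(config, truth=truth)


def write_fixtures(study: SyntheticStudy, directory: str | Path) -> dict[str, Path]:
    """Write every study table in the pipeline's external text formats.

    Returns a mapping from table name to the written path. The files
    round-trip losslessly through :mod:`aied.io`.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "allele_counts": d / "allele_counts.tsv",
        "metadata": d / "metadata.tsv",
        "annotation": d / "annotation.tsv",
        "known_sites": d / "known_sites.tsv",
        "repeats": d / "repeats.bed",
        "expression": d / "expression.tsv",
        "gene_lengths": d / "gene_lengths.tsv",
        "truth": d / "truth.tsv",
    }
    study.allele_counts.to_csv(paths["allele_counts"], sep="\t", index=False)
    study.metadata.to_csv(paths["metadata"], sep="\t", index=False)
    study.annotation.to_csv(paths["annotation"], sep="\t", index=False)
    study.known_sites.to_csv(paths["known_sites"], sep="\t", index=False)
    study.repeats.to_csv(paths["repeats"], sep="\t", index=False, header=False)
    study.expression.to_csv(paths["expression"], sep="\t")
    study.gene_lengths.rename("length").to_frame().to_csv(paths["gene_lengths"], sep="\t")
    study.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
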