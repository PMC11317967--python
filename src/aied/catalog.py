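"""High-confidence editing-site cataloguing.

A candidate A>G site enters the analysis catalog if it is a catalogued
(known) editing site, or if its mean editing level reaches 5% in at least
one design subgroup and editing is observed in at least two samples
study-wide. Subgroups are the design cells (group x age x sex, or whatever
factors the metadata provides).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .exceptions import ConfigurationError
from .io import KnownSiteIndex
from .quantify import DEFAULT_MIN_COVERAGE, build_editing_matrix, subgroup_means

__all__ = [
    "SubgroupScheme",
    "editing_observed",
    "high_confidence_filter",
    "catalog_summary",
]


@dataclass
class SubgroupScheme:
    """Assignment of every sample to exactly one subgroup label."""

    mapping: pd.Series  # sample_id -> subgroup label

    def __post_init__(self) -> None:
        if len(self.mapping) == 0:
            raise ConfigurationError("subgroup scheme is empty")
        if self.mapping.index.duplicated().any():
            raise ConfigurationError("a sample is assigned more than one subgroup")

    @classmethod
    def from_metadata(
        cls, metadata: pd.DataFrame, factors: tuple[str, ...] = ("group", "age", "sex")
    ) -> "SubgroupScheme":
        """Build subgroup labels by joining the non-blank factor values per sample."""
        present = [
            f for f in factors
            if f in metadata.columns and (metadata[f].astype(str) != "").any()
        ]
        if not present:
            raise ConfigurationError(f"none of the factors {factors!r} present in metadata")
        labels = metadata[present].astype(str).agg("_".join, axis=1)
        return cls(pd.Series(labels.to_numpy(), index=metadata["sample_id"].to_numpy()))

    @property
    def labels(self) -> list[str]:
        return sorted(self.mapping.unique())


def editing_observed(ref_count, alt_count, min_coverage: int = DEFAULT_MIN_COVERAGE):
    """Whether a single (site, sample) observation counts as edited.

    Requires at least one edited read and total coverage at or above the
    floor, so isolated single reads at thin coverage never count.
    """
    import numpy as np

    ref = np.asarray(ref_count)
    alt = np.asarray(alt_count)
    obs = (alt >= 1) & (ref + alt >= min_coverage)
    if np.isscalar(ref_count) and np.isscalar(alt_count):
        return bool(obs)
    return obs


def high_confidence_filter(
    counts: pd.DataFrame,
    known,
    scheme: SubgroupScheme,
    threshold: float = 0.05,
    min_samples: int = 2,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> pd.DataFrame:
    """Apply the high-confidence retention rule to oriented candidates.

    A site is retained iff it is known, or its mean editing level within at
    least one subgroup is >= ``threshold`` (inclusive) and editing is observed
    in >= ``min_samples`` samples study-wide. Subgroup means use only samples
    at adequate coverage.

    Parameters
    ----------
    counts
        Long oriented allele-count table.
    known
        Either a :class:`~aied.io.KnownSiteIndex` or a boolean Series indexed
        by site_id.
    scheme
        Sample-to-subgroup assignment covering every sample in ``counts``.

    Returns
    -------
    One row per retained site: ``site_id``, ``retained_reason`` ("known" or
    "level"), ``max_subgroup_mean`` and ``n_observed``.
    """
    matrix = build_editing_matrix(counts, min_coverage)
    means = subgroup_means(matrix, scheme.mapping)
    max_mean = means.max(axis=1, skipna=True)

    obs = counts.copy()
    obs["observed"] = editing_observed(
        obs["ref_count"].to_numpy(), obs["alt_count"].to_numpy(), min_coverage
    )
    n_observed = obs.groupby("site_id", sort=False)["observed"].sum().reindex(matrix.index)

    if isinstance(known, KnownSiteIndex):
        site_pos = counts.drop_duplicates("site_id").set_index("site_id")[["chrom", "pos"]]
        known_flag = pd.Series(
            [(c, p) in known for c, p in zip(site_pos["chrom"], site_pos["pos"])],
            index=site_pos.index,
        ).reindex(matrix.index, fill_value=False)
    else:
        known_flag = pd.Series(known).reindex(matrix.index, fill_value=False).astype(bool)

    by_level = (max_mean >= threshold).fillna(False) & (n_observed >= min_samples)
    retained = known_flag | by_level
    out = pd.DataFrame(
        {
            "site_id": matrix.index,
            "retained_reason": ["known" if k else "level" for k in known_flag],
            "max_subgroup_mean": max_mean.to_numpy(),
            "n_observed": n_observed.astype(int).to_numpy(),
        }
    )
    return out[retained.to_numpy()].reset_index(drop=True)


def catalog_summary(catalog: pd.DataFrame) -> tuple[int, int]:
    """Number of sites and of distinct (non-empty) genes in a catalog."""
    n_sites = len(catalog)
    if n_sites == 0 or "gene" not in catalog.columns:
        return n_sites, 0
    genes = catalog["gene"].astype(str)
    return n_sites, int(genes[genes != ""].nunique())
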