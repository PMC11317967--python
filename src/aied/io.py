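"""Readers, validation and annotation for the pipeline's input tables.

All external formats are plain TSV (BED for repeats). Coordinates in the
allele-count and known-site tables are 1-based; the repeat BED is 0-based
half-open per the BED standard. The conversion between the two conventions is
confined to :func:`overlap_repeats`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .exceptions import AmbiguityError, SchemaError, ValidationError

__all__ = [
    "ALLELE_COUNT_COLUMNS",
    "CONSEQUENCE_CATEGORIES",
    "KnownSiteIndex",
    "read_allele_counts",
    "read_metadata",
    "read_annotation",
    "read_known_sites",
    "read_repeats",
    "read_expression",
    "read_gene_lengths",
    "read_truth",
    "orient_to_sense",
    "flag_known",
    "overlap_repeats",
    "summarize_consequences",
]

ALLELE_COUNT_COLUMNS = (
    "site_id", "chrom", "pos", "strand", "ref", "alt",
    "sample_id", "ref_count", "alt_count",
)

#: Closed set of functional-consequence categories.
CONSEQUENCE_CATEGORIES = (
    "3'UTR", "5'UTR", "intronic", "missense", "synonymous",
    "stop_loss", "noncoding_exonic", "noncoding_intronic",
)


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{what}: missing required column {col!r}")


def read_allele_counts(path: str | Path) -> pd.DataFrame:
    """Read the long per-(site, sample) allele-count table.

    Counts must be non-negative integers; a violation reports the offending
    1-based file row (header is row 1). Unknown columns are preserved.
    """
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ALLELE_COUNT_COLUMNS, "allele counts")
    for col in ("ref_count", "alt_count"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0]) + 2
            raise ValidationError(f"allele counts: non-numeric {col} at file row {row}")
        if (vals < 0).any():
            row = int(vals.index[vals < 0][0]) + 2
            raise ValidationError(f"allele counts: negative {col} at file row {row}")
        df[col] = vals.astype(np.int64)
    df["pos"] = pd.to_numeric(df["pos"]).astype(np.int64)
    if (df["pos"] < 1).any():
        row = int(df.index[df["pos"] < 1][0]) + 2
        raise ValidationError(f"allele counts: position < 1 at file row {row}")
    return df


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata (sample_id, group, age, sex, dataset)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ("sample_id", "group"), "metadata")
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise ValidationError(f"metadata: duplicated sample_id {dup!r}")
    for col in ("age", "sex", "dataset"):
        if col not in df.columns:
            df[col] = ""
    return df


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read the per-site annotation (gene, biotype, consequence, changes).

    Each site must carry exactly one consequence; a duplicated site_id is an
    error rather than a silent merge.
    """
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    _require_columns(df, ("site_id", "gene", "gene_biotype", "consequence"), "annotation")
    if df["site_id"].duplicated().any():
        dup = df["site_id"][df["site_id"].duplicated()].iloc[0]
        raise ValidationError(f"annotation: duplicated site_id {dup!r}")
    bad = set(df["consequence"]) - set(CONSEQUENCE_CATEGORIES)
    if bad:
        raise ValidationError(f"annotation: unknown consequence categories {sorted(bad)!r}")
    return df


@dataclass
class KnownSiteIndex:
    """Exact-match index of catalogued editing sites keyed by (chrom, pos).

    Strand is deliberately not part of the key: public catalogues store
    sense-oriented records and candidate sites are canonicalized before
    lookup.
    """

    keys: set[tuple[str, int]] = field(default_factory=set)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "KnownSiteIndex":
        _require_columns(df, ("Region", "Position"), "known sites")
        return cls(set(zip(df["Region"].astype(str), df["Position"].astype(int))))

    def __contains__(self, key: tuple[str, int]) -> bool:
        return (str(key[0]), int(key[1])) in self.keys

    def __len__(self) -> int:
        return len(self.keys)


def read_known_sites(path: str | Path) -> KnownSiteIndex:
    """Read a REDIportal-style known-site table (Region, Position, Ref, Ed, Strand)."""
    return KnownSiteIndex.from_frame(pd.read_csv(path, sep="\t"))


def read_repeats(path: str | Path) -> pd.DataFrame:
    """Read a repeat BED (chrom, start, end, family; 0-based half-open)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValidationError(f"repeats BED: fewer than 4 fields at line {lineno}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValidationError(f"repeats BED: non-integer interval at line {lineno}") from exc
            if start < 0 or end <= start:
                raise ValidationError(f"repeats BED: invalid interval at line {lineno}")
            rows.append({"chrom": parts[0], "start": start, "end": end, "family": parts[3]})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "family"])


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples raw-count matrix (first column = gene)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValidationError("expression: negative counts")
    return df


def read_gene_lengths(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    s = df.iloc[:, 0].astype(float)
    if (s <= 0).any():
        raise ValidationError("gene lengths must be positive")
    s.name = "length"
    return s


def read_truth(path: str | Path) -> pd.DataFrame:
    """Read a simulation truth table written by :func:`aied.simulate.write_fixtures`."""
    return pd.read_csv(path, sep="\t")


def orient_to_sense(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Canonicalize candidate calls to the A>G sense representation.

    A>G on the ``+`` strand is kept; T>C on the ``-`` strand is the same
    editing event read antisense and is rewritten to A>G. Every other
    substitution is rejected (not A-to-I). A T>C call without a usable
    strand cannot be disambiguated and raises :class:`AmbiguityError`.

    Returns ``(oriented, rejected)``.
    """
    df = records.copy()
    ref = df["ref"].str.upper()
    alt = df["alt"].str.upper()
    strand = df["strand"].astype(str)
    keep_plus = (strand == "+") & (ref == "A") & (alt == "G")
    flip_minus = (strand == "-") & (ref == "T") & (alt == "C")
    ambiguous = (~strand.isin(["+", "-"])) & (ref == "T") & (alt == "C")
    if ambiguous.any():
        i = df.index[ambiguous][0]
        raise AmbiguityError(
            f"T>C call with unknown strand at {df.loc[i, 'chrom']}:{df.loc[i, 'pos']}"
        )
    oriented = df[keep_plus | flip_minus].copy()
    oriented.loc[:, "ref"] = "A"
    oriented.loc[:, "alt"] = "G"
    rejected = df[~(keep_plus | flip_minus)].copy()
    return oriented.reset_index(drop=True), rejected.reset_index(drop=True)


def flag_known(sites: pd.DataFrame, index: KnownSiteIndex) -> pd.DataFrame:
    """Add a boolean ``known`` column: exact (chrom, pos) membership in the index."""
    out = sites.copy()
    out["known"] = [
        (c, p) in index for c, p in zip(out["chrom"], out["pos"])
    ]
    return out


def overlap_repeats(sites: pd.DataFrame, repeats: pd.DataFrame) -> pd.DataFrame:
    """Assign each site the repeat family it falls in, or missing.

    A site at 1-based position ``p`` overlaps the 0-based half-open interval
    ``[start, end)`` iff ``start <= p - 1 < end``. When several repeats cover
    a site, the one appearing first in the BED wins.
    """
    trees: dict[str, IntervalTree] = {}
    for order, row in enumerate(repeats.itertuples()):
        trees.setdefault(row.chrom, IntervalTree()).addi(
            row.start, row.end, (order, row.family)
        )
    fams = []
    for c, p in zip(sites["chrom"], sites["pos"]):
        tree = trees.get(c)
        hits = tree[int(p) - 1] if tree is not None else ()
        fams.append(min(h.data for h in hits)[1] if hits else None)
    out = sites.copy()
    out["repeat_family"] = fams
    return out


def summarize_consequences(catalog: pd.DataFrame) -> pd.DataFrame:
    """Count sites per functional-consequence category.

    Returns a frame with ``consequence``, ``count`` and ``percent`` (one
    decimal, of the catalog total), sorted by decreasing count. An empty
    catalog yields an empty summary.
    """
    if len(catalog) == 0:
        return pd.DataFrame(columns=["consequence", "count", "percent"])
    counts = catalog["consequence"].value_counts()
    total = int(counts.sum())
    out = pd.DataFrame(
        {
            "consequence": counts.index,
            "count": counts.to_numpy(),
            "percent": np.round(100.0 * counts.to_numpy() / total, 1),
        }
    )
    return out.reset_index(drop=True)
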