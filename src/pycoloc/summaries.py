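"""Reading, validating, windowing and harmonising summary-statistics tables.

One table per trait, one row per variant.  Each row must carry either a
p-value plus minor allele frequency or an effect estimate plus its variance.
Frequencies above 0.5 are folded (the Bayes factors depend on z**2 only, so
allele orientation never matters and alleles are never used for matching).
Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abf import TraitSpec

__all__ = [
    "SummaryDataset",
    "Region",
    "HarmonizedPair",
    "read_summary_table",
    "extract_region",
    "harmonize_pair",
    "DEFAULT_COLUMN_MAP",
]

logger = logging.getLogger(__name__)

#: Default header-name recognition: semantic name -> column name in the file.
DEFAULT_COLUMN_MAP = {
    "variant_id": "snp",
    "chrom": "chr",
    "pos": "pos",
    "pval": "pvalues",
    "maf": "MAF",
    "beta": "beta",
    "varbeta": "varbeta",
    "rsq": "rsq",
}

_CORE_COLUMNS = ("variant_id", "chrom", "pos", "pval", "maf", "beta", "varbeta", "rsq")


@dataclass
class SummaryDataset:
    """One trait's per-region summary statistics plus trait metadata.

    ``frame`` holds canonical columns (``variant_id``, optionally ``chrom``
    and ``pos``, and per-variant statistics); any extra columns (e.g.
    alleles) are carried through untouched.
    """

    frame: pd.DataFrame
    trait_spec: TraitSpec

    def __post_init__(self) -> None:
        df = self.frame
        if "variant_id" not in df.columns:
            raise ValueError("dataset requires a variant_id column")
        dup = df["variant_id"][df["variant_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate variant_id: {dup.iloc[0]!r}")
        has_pm = pd.Series(False, index=df.index)
        if "pval" in df and "maf" in df:
            has_pm = df["pval"].notna() & df["maf"].notna()
        has_bv = pd.Series(False, index=df.index)
        if "beta" in df and "varbeta" in df:
            has_bv = df["beta"].notna() & df["varbeta"].notna()
        bad = ~(has_pm | has_bv)
        if bad.any():
            vid = df.loc[bad, "variant_id"].iloc[0]
            raise ValueError(
                f"variant {vid!r} has neither (pval, maf) nor (beta, varbeta)"
            )
        if "pval" in df:
            p = df["pval"].dropna()
            if ((p <= 0) | (p > 1)).any():
                raise ValueError("p-values must lie in (0, 1]")
        if "maf" in df:
            f = df["maf"].dropna()
            if ((f < 0) | (f > 1)).any():
                raise ValueError("allele frequencies must lie in [0, 1]")
            # fold to minor-allele convention; monomorphic (f = 0) rows are
            # dropped later during harmonisation
            self.frame = df = df.assign(maf=np.minimum(df["maf"], 1.0 - df["maf"]))
        if "varbeta" in df:
            v = df["varbeta"].dropna()
            if (v <= 0).any():
                raise ValueError("varbeta must be positive")
        if "pos" in df:
            pos = df["pos"].dropna()
            if (pos <= 0).any():
                raise ValueError("positions must be strictly positive (1-based)")
        if "rsq" in df:
            r = df["rsq"].dropna()
            if ((r < 0) | (r > 1)).any():
                raise ValueError("rsq must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.frame["variant_id"])


@dataclass(frozen=True)
class Region:
    """A genomic window with 1-based inclusive bounds."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region start {self.start} exceeds end {self.end}")
        if self.start < 1:
            raise ValueError("coordinates are 1-based; start must be >= 1")


@dataclass
class HarmonizedPair:
    """Two datasets aligned on a shared, filtered, canonically ordered set of variants."""

    dataset1: SummaryDataset
    dataset2: SummaryDataset
    audit: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def nsnps(self) -> int:
        return len(self.dataset1)

    @property
    def variant_ids(self) -> list[str]:
        return self.dataset1.variant_ids


def read_summary_table(
    path,
    trait_spec: TraitSpec,
    column_map: dict | None = None,
    sep: str | None = None,
) -> SummaryDataset:
    """Read a delimited summary-statistics file into a validated dataset.

    ``column_map`` maps semantic names (``variant_id``, ``pval``, ``maf``,
    ``beta``, ``varbeta``, ``chrom``, ``pos``, ``rsq``) to the file's header
    names; unmapped semantic columns fall back to the defaults in
    :data:`DEFAULT_COLUMN_MAP`.  Tab- and comma-separated files are
    auto-detected when ``sep`` is None.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if header.count("\t") >= header.count(",") else ","
    raw = pd.read_csv(path, sep=sep)

    rename = {src: sem for sem, src in cmap.items() if src in raw.columns}
    df = raw.rename(columns=rename)

    if "variant_id" not in df.columns:
        raise ValueError(
            f"missing mandatory column {cmap['variant_id']!r} (variant identifier) "
            f"in {path}; found columns {list(raw.columns)}"
        )
    have_pm = {"pval", "maf"} <= set(df.columns)
    have_bv = {"beta", "varbeta"} <= set(df.columns)
    if not (have_pm or have_bv):
        missing = [cmap["pval"], cmap["maf"]] if not have_bv else []
        raise ValueError(
            f"need either ({cmap['pval']}, {cmap['maf']}) or "
            f"({cmap['beta']}, {cmap['varbeta']}) columns in {path}; "
            f"missing {missing or [cmap['beta'], cmap['varbeta']]}"
        )
    for col in ("pval", "maf", "beta", "varbeta", "pos", "rsq"):
        if col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            newly_bad = coerced.isna() & df[col].notna()
            if newly_bad.any():
                rows = (np.flatnonzero(newly_bad) + 2).tolist()  # header = line 1
                raise ValueError(
                    f"non-numeric values in column {col!r} at file line(s) {rows}"
                )
            df[col] = coerced
    return SummaryDataset(frame=df.reset_index(drop=True), trait_spec=trait_spec)


def extract_region(dataset: SummaryDataset, region: Region) -> SummaryDataset:
    """Restrict a dataset to variants inside a window (bounds inclusive)."""
    df = dataset.frame
    if "pos" not in df.columns:
        raise ValueError("dataset has no positions; cannot extract a region")
    mask = (df["pos"] >= region.start) & (df["pos"] <= region.end)
    if "chrom" in df.columns:
        mask &= df["chrom"].astype(str) == str(region.chrom)
    if not mask.any():
        raise ValueError(f"no variants fall inside {region}")
    return SummaryDataset(
        frame=df[mask].reset_index(drop=True), trait_spec=dataset.trait_spec
    )


def _filter_reasons(
    df: pd.DataFrame, min_maf: float, min_rsq: float, exclude: set
) -> pd.Series:
    """Per-row drop reason, or None where the row passes."""
    reason = pd.Series([None] * len(df), index=df.index, dtype=object)
    if exclude:
        reason[df["variant_id"].isin(exclude)] = "multi_allelic"
    if "maf" in df.columns:
        f = df["maf"]
        reason[reason.isna() & f.notna() & (f == 0)] = "monomorphic"
        reason[reason.isna() & f.notna() & (f < min_maf)] = "low_maf"
    if "rsq" in df.columns:
        reason[reason.isna() & df["rsq"].notna() & (df["rsq"] < min_rsq)] = "low_rsq"
    return reason


def harmonize_pair(
    d1: SummaryDataset,
    d2: SummaryDataset,
    min_maf: float = 0.001,
    min_rsq: float = 0.3,
    exclude_variants=None,
) -> HarmonizedPair:
    """Intersect and filter two datasets into an aligned pair.

    Variants are matched on ``variant_id``.  A variant is kept only if it is
    present in both datasets and passes the MAF (>= ``min_maf``) and
    imputation-quality (Rsq >= ``min_rsq``, when an rsq column exists)
    filters in both; known multi-allelic sites may be excluded by id via
    ``exclude_variants``.  The retained set is ordered by position then id.
    The audit log records every dropped variant with a reason drawn from
    {not_shared, low_maf, monomorphic, multi_allelic, low_rsq}.
    """
    exclude = set(exclude_variants or ())
    ids1 = set(d1.variant_ids)
    ids2 = set(d2.variant_ids)
    shared = ids1 & ids2

    audit_rows = []
    for name, ds, other in (("trait1", d1, ids2), ("trait2", d2, ids1)):
        not_shared = [v for v in ds.variant_ids if v not in other]
        audit_rows.extend(
            {"variant_id": v, "dataset": name, "reason": "not_shared"}
            for v in not_shared
        )

    drop: dict[str, str] = {}
    for name, ds in (("trait1", d1), ("trait2", d2)):
        df = ds.frame[ds.frame["variant_id"].isin(shared)]
        reasons = _filter_reasons(df, min_maf, min_rsq, exclude)
        for vid, reason in zip(df["variant_id"], reasons):
            if reason is not None and vid not in drop:
                drop[vid] = reason
                audit_rows.append(
                    {"variant_id": vid, "dataset": name, "reason": reason}
                )
    if "rsq" not in d1.frame.columns and "rsq" not in d2.frame.columns:
        logger.info("no rsq column in either dataset; imputation-quality filter skipped")

    keep = shared - set(drop)
    if not keep:
        raise ValueError("no variants remain after intersection and filtering")

    f1 = d1.frame[d1.frame["variant_id"].isin(keep)].copy()
    # canonical order: position (when available) then id
    if "pos" in f1.columns:
        f1 = f1.sort_values(["pos", "variant_id"], kind="mergesort")
    else:
        f1 = f1.sort_values("variant_id", kind="mergesort")
    order = list(f1["variant_id"])
    f2 = d2.frame.set_index("variant_id").loc[order].reset_index()

    return HarmonizedPair(
        dataset1=SummaryDataset(f1.reset_index(drop=True), d1.trait_spec),
        dataset2=SummaryDataset(f2, d2.trait_spec),
        audit=pd.DataFrame(audit_rows, columns=["variant_id", "dataset", "reason"]),
    )
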