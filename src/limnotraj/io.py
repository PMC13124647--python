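"""Reading, validation, lineage filtering and rarefaction of ASV count data.

The central object is :class:`AsvCountTable`, an integer samples x ASVs count
matrix.  Companion tables are plain :class:`pandas.DataFrame` objects: sample
metadata (lake, date, water-column replicate), chlorophyll-a measurements and
an 8-rank taxonomy per ASV.  All text formats are TSV (UTF-8, "." decimal)
except chlorophyll-a, which is CSV; dates are ISO-8601.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Lineage keywords removed by default before any community analysis.  These
#: cover non-target organisms and organellar sequences picked up by general
#: eukaryote 18S primers, plus reads the classifier could not place.
DEFAULT_EXCLUDED_LINEAGES = (
    "bacteria",
    "metazoa",
    "mitochondria",
    "chloroplast",
    "streptophyta",
    "plastid",
    "nucleomorph",
    "unassigned",
)

#: 8-rank lineage convention (PR2-style); rank 4 (index 3) is the class rank
#: used for trophic-mode annotation.
RANK_NAMES = (
    "kingdom",
    "supergroup",
    "division",
    "class",
    "order",
    "family",
    "genus",
    "species",
)
CLASS_RANK_INDEX = 3

WATER_COLUMN_REPLICATES = ("W1", "W2", "W3")


class AsvCountTable:
    """Samples x ASVs matrix of non-negative integer read counts.

    Invariants enforced at construction: unique sample and ASV identifiers,
    integer-valued non-negative counts, and strictly positive row sums.
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if counts.columns.has_duplicates:
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate ASV ids: {dups}")
        values = counts.to_numpy()
        if values.size == 0:
            raise ValueError("empty count table")
        if not np.issubdtype(values.dtype, np.number):
            bad = counts.columns[
                ~counts.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())
            ].tolist()
            raise ValueError(f"non-numeric counts in columns: {bad}")
        if np.any(values < 0):
            raise ValueError("negative counts are not allowed")
        if np.any(np.mod(values, 1) != 0):
            raise ValueError("counts must be integers (no fractional reads)")
        df = counts.astype(np.int64)
        zero = df.sum(axis=1) == 0
        if zero.any():
            raise ValueError(
                f"samples with zero total reads: {df.index[zero].tolist()}"
            )
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        df.index.name = "sample_id"
        self._df = df

    @property
    def counts(self) -> pd.DataFrame:
        """The underlying samples x ASVs integer DataFrame (do not mutate)."""
        return self._df

    @property
    def sample_ids(self) -> list[str]:
        return self._df.index.tolist()

    @property
    def asv_ids(self) -> list[str]:
        return self._df.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    def sample_totals(self) -> pd.Series:
        return self._df.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        return self._df.div(self._df.sum(axis=1), axis=0)

    def subset_samples(self, sample_ids) -> "AsvCountTable":
        return AsvCountTable(self._df.loc[list(sample_ids)])

    def subset_asvs(self, asv_ids) -> "AsvCountTable":
        return AsvCountTable(self._df.loc[:, list(asv_ids)])

    def __eq__(self, other) -> bool:
        return isinstance(other, AsvCountTable) and self._df.equals(other._df)

    def __repr__(self) -> str:
        n, m = self.shape
        return f"AsvCountTable({n} samples x {m} ASVs)"


def read_asv_table(path, samples_as_rows: bool = True) -> AsvCountTable:
    """Read a TSV count table.

    Canonical orientation is samples as rows (first column sample ids, header
    row ASV ids); ``samples_as_rows=False`` transposes after reading.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed count table {path}: {exc}") from exc
    if df.columns.size == 0:
        raise ValueError(f"malformed count table {path}: header row has no ASV ids")
    if not samples_as_rows:
        df = df.T
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and not df[col].isna().any():
            bad = df.index[coerced.isna()][0]
            raise ValueError(
                f"non-numeric cell in column {col!r}, row {bad!r} of {path}"
            )
    return AsvCountTable(df)


def write_asv_table(table: AsvCountTable, path) -> None:
    """Write in the canonical dialect (samples as rows, tab-separated)."""
    table.counts.to_csv(path, sep="\t")


class TaxonomyTable:
    """ASV id -> ordered 8-rank lineage (strings; empty string = unassigned)."""

    def __init__(self, lineages: pd.DataFrame):
        if lineages.index.has_duplicates:
            raise ValueError("duplicate ASV ids in taxonomy")
        if lineages.shape[1] > len(RANK_NAMES):
            raise ValueError(
                f"lineage has {lineages.shape[1]} ranks, at most {len(RANK_NAMES)} allowed"
            )
        df = lineages.astype("string").fillna("")
        df.columns = RANK_NAMES[: df.shape[1]]
        df.index = df.index.astype(str)
        df.index.name = "asv_id"
        self._df = df

    @property
    def lineages(self) -> pd.DataFrame:
        return self._df

    def __contains__(self, asv_id) -> bool:
        return str(asv_id) in self._df.index

    def lineage(self, asv_id) -> tuple[str, ...]:
        """Ordered rank labels; empty tuple if the ASV is absent."""
        if asv_id not in self:
            return ()
        return tuple(str(v) for v in self._df.loc[str(asv_id)])

    def class_label(self, asv_id) -> str:
        """Rank-4 (class) label, or empty string when missing/unassigned."""
        lin = self.lineage(asv_id)
        if len(lin) <= CLASS_RANK_INDEX:
            return ""
        return lin[CLASS_RANK_INDEX]


def read_taxonomy(path) -> TaxonomyTable:
    """Read taxonomy TSV: first column ASV id, then either one semicolon-joined
    ``lineage`` column or up to eight rank columns."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[1] == 1 and df.columns[0].lower() == "lineage":
        split = df.iloc[:, 0].fillna("").str.split(";", expand=True)
        split = split.reindex(columns=range(len(RANK_NAMES)))
        return TaxonomyTable(split.fillna(""))
    return TaxonomyTable(df)


def filter_lineages(
    table: AsvCountTable,
    tax: TaxonomyTable,
    exclude=DEFAULT_EXCLUDED_LINEAGES,
) -> AsvCountTable:
    """Drop ASVs whose lineage matches any excluded keyword.

    Matching is case-insensitive substring match at any rank.  ASVs with no
    taxonomy row or an all-empty lineage are treated as unassigned and removed
    when ``"unassigned"`` is among the keywords.  Counts of retained ASVs are
    untouched; samples left with zero reads are dropped (and logged).
    """
    keywords = [k.lower() for k in exclude]
    if not keywords:
        return table
    drop_unassigned = "unassigned" in keywords
    keep = []
    for asv in table.asv_ids:
        lin = [r for r in tax.lineage(asv) if r.strip()]
        if not lin:
            if not drop_unassigned:
                keep.append(asv)
            continue
        hit = any(kw in rank.lower() for rank in lin for kw in keywords)
        if not hit:
            keep.append(asv)
    if not keep:
        raise ValueError("no ASVs survive lineage filtering")
    df = table.counts.loc[:, keep]
    zero = df.sum(axis=1) == 0
    if zero.any():
        dropped = df.index[zero].tolist()
        logger.warning(
            "filter_lineages: %d sample(s) left with zero reads, dropped: %s",
            len(dropped),
            dropped,
        )
        df = df.loc[~zero]
    return AsvCountTable(df)


def rarefy(table: AsvCountTable, depth: int, seed: int) -> AsvCountTable:
    """Rarefy each sample to exactly ``depth`` reads by random subsampling
    without replacement (multivariate hypergeometric draw).

    Samples whose total is below ``depth`` are dropped and logged.  A fixed
    seed gives bit-identical output across runs.
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    totals = table.sample_totals()
    low = totals[totals < depth].index.tolist()
    if low:
        logger.warning(
            "rarefy: %d sample(s) below depth %d, dropped: %s", len(low), depth, low
        )
    keep = totals.index[totals >= depth]
    if keep.empty:
        raise ValueError(f"all samples are below rarefaction depth {depth}")
    rng = np.random.default_rng(seed)
    rows = []
    for sid in keep:
        counts = table.counts.loc[sid].to_numpy()
        rows.append(rng.multivariate_hypergeometric(counts, depth))
    df = pd.DataFrame(rows, index=keep, columns=table.counts.columns)
    df.index.name = "sample_id"
    return AsvCountTable(df)


SEASONS = ("winter", "spring", "summer", "autumn")


def season_for_month(month: int) -> str:
    """Meteorological season of a calendar month (northern hemisphere)."""
    if month in (12, 1, 2):
        return "winter"
    if month in (3, 4, 5):
        return "spring"
    if month in (6, 7, 8):
        return "summer"
    if month in (9, 10, 11):
        return "autumn"
    raise ValueError(f"invalid calendar month {month}")


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate/complete a sample metadata table.

    Expects index = sample_id and columns lake, date, replicate; derives
    month_index (1..N over the whole campaign, shared across lakes) and
    season when absent.  Enforces unique (lake, date, replicate) and
    month_index increasing with date.
    """
    meta = meta.copy()
    required = {"lake", "date", "replicate"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    meta["date"] = pd.to_datetime(meta["date"])
    if meta.index.has_duplicates:
        raise ValueError("duplicate sample ids in metadata")
    bad_rep = ~meta["replicate"].isin(WATER_COLUMN_REPLICATES)
    if bad_rep.any():
        raise ValueError(
            f"invalid replicate labels: {meta['replicate'][bad_rep].unique().tolist()}"
        )
    key = meta[["lake", "date", "replicate"]]
    if key.duplicated().any():
        raise ValueError("duplicate (lake, date, replicate) rows in metadata")
    if "month_index" not in meta.columns:
        periods = meta["date"].dt.to_period("M")
        order = {p: i + 1 for i, p in enumerate(sorted(periods.unique()))}
        meta["month_index"] = periods.map(order).astype(int)
    meta["month_index"] = meta["month_index"].astype(int)
    for lake, grp in meta.groupby("lake"):
        g = grp.sort_values("date")
        if not g["month_index"].is_monotonic_increasing:
            raise ValueError(f"month_index not increasing with date in lake {lake}")
    if "season" not in meta.columns:
        meta["season"] = meta["date"].dt.month.map(season_for_month)
    meta.index = meta.index.astype(str)
    meta.index.name = "sample_id"
    return meta


def read_metadata(path) -> pd.DataFrame:
    return validate_metadata(pd.read_csv(path, sep="\t", index_col=0))


def read_chla(path) -> pd.DataFrame:
    """Read chlorophyll-a CSV with columns lake, month_index, replicate,
    chla_ug_per_l (concentrations in micrograms per litre)."""
    df = pd.read_csv(path)
    required = {"lake", "month_index", "replicate", "chla_ug_per_l"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"chlorophyll-a table missing columns: {sorted(missing)}")
    if (df["chla_ug_per_l"] < 0).any():
        raise ValueError("negative chlorophyll-a concentration")
    df["month_index"] = df["month_index"].astype(int)
    return df


def write_chla(chla: pd.DataFrame, path) -> None:
    chla.to_csv(path, index=False)


def monthly_mean_chla(chla: pd.DataFrame) -> pd.DataFrame:
    """Replicate-averaged chlorophyll-a per (lake, month_index), wide layout
    (lakes as rows, month_index as columns)."""
    return (
        chla.groupby(["lake", "month_index"])["chla_ug_per_l"]
        .mean()
        .unstack("month_index")
    )
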