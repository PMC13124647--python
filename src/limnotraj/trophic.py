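"""Trophic-state classification from chlorophyll-a and trophic-mode annotation.

Lakes are binned into Carlson trophic states from chlorophyll-a concentration
(micrograms per litre) and categorized over a whole campaign; microeukaryote
ASVs are annotated with one of four coarse trophic modes (phototroph,
mixotroph, phagotroph, parasite) by looking up their class-rank label in a
curated class -> mode map.
"""

from __future__ import annotations

import enum
import logging

import numpy as np
import pandas as pd

from .io import AsvCountTable, TaxonomyTable

logger = logging.getLogger(__name__)


class TrophicState(enum.IntEnum):
    """Carlson trophic states, totally ordered by productivity."""

    OLIGOTROPHIC = 0
    MESOTROPHIC = 1
    EUTROPHIC = 2
    HYPEREUTROPHIC = 3

    def __str__(self) -> str:
        return self.name.lower()


#: Chlorophyll-a thresholds (ug/L) between consecutive Carlson states.
#: Lower bound of each bin is inclusive: oligotrophic < 2.6, mesotrophic
#: [2.6, 7.3), eutrophic [7.3, 56], hypereutrophic > 56.
CHLA_OLIGO_MESO = 2.6
CHLA_MESO_EU = 7.3
CHLA_EU_HYPER = 56.0


class LakeCategory(enum.Enum):
    """Campaign-level trophic category of a lake."""

    OLIGO_MESO = "oligo_meso"
    MESO_EU = "meso_eu"
    EU_HYPER = "eu_hyper"

    def __str__(self) -> str:
        return self.value


TROPHIC_MODES = ("phototroph", "mixotroph", "phagotroph", "parasite")
UNASSIGNED = "unassigned"


def classify_trophic_state(chla: float) -> TrophicState:
    """Bin a chlorophyll-a concentration (ug/L) into a Carlson trophic state."""
    if not np.isfinite(chla) or chla < 0:
        raise ValueError(f"chlorophyll-a must be a non-negative number, got {chla}")
    if chla < CHLA_OLIGO_MESO:
        return TrophicState.OLIGOTROPHIC
    if chla < CHLA_MESO_EU:
        return TrophicState.MESOTROPHIC
    if chla <= CHLA_EU_HYPER:
        return TrophicState.EUTROPHIC
    return TrophicState.HYPEREUTROPHIC


def categorize_lake(monthly_chla, min_months: int = 6) -> LakeCategory:
    """Categorize a lake from its series of monthly mean chlorophyll-a values.

    Rules, applied in order:

    1. ``eu_hyper`` if at least 4 monthly states are hypereutrophic;
    2. ``oligo_meso`` if at least half of the monthly states are oligotrophic
       or mesotrophic AND the campaign mean is below the meso/eutrophic
       threshold (7.3 ug/L);
    3. ``meso_eu`` otherwise.
    """
    values = np.asarray(list(monthly_chla), dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError("empty monthly chlorophyll-a series")
    if values.size < min_months:
        raise ValueError(
            f"need at least {min_months} monthly values, got {values.size}"
        )
    states = [classify_trophic_state(v) for v in values]
    n_hyper = sum(s is TrophicState.HYPEREUTROPHIC for s in states)
    if n_hyper >= 4:
        return LakeCategory.EU_HYPER
    low = sum(
        s in (TrophicState.OLIGOTROPHIC, TrophicState.MESOTROPHIC) for s in states
    )
    if low / len(states) >= 0.5 and values.mean() < CHLA_MESO_EU:
        return LakeCategory.OLIGO_MESO
    return LakeCategory.MESO_EU


def categorize_lakes(monthly_chla_wide: pd.DataFrame) -> pd.Series:
    """Apply :func:`categorize_lake` to every row of a lakes x months table."""
    return pd.Series(
        {lake: categorize_lake(row.dropna()) for lake, row in monthly_chla_wide.iterrows()},
        name="category",
    )


def read_mode_map(path) -> dict[str, str]:
    """Read a two-column TSV mapping class-rank labels to trophic modes."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("trophic-mode map needs two columns: class, mode")
    classes = df.iloc[:, 0].str.strip()
    modes = df.iloc[:, 1].str.strip().str.lower()
    bad = ~modes.isin(TROPHIC_MODES)
    if bad.any():
        raise ValueError(f"unknown trophic modes: {modes[bad].unique().tolist()}")
    if classes.str.lower().duplicated().any():
        raise ValueError("duplicate class labels in trophic-mode map")
    return dict(zip(classes, modes))


def assign_trophic_modes(
    tax: TaxonomyTable, mode_map: dict[str, str]
) -> pd.Series:
    """Map every ASV to a trophic mode via its class-rank (rank 4) label.

    ASVs with a missing/empty class label, or a class absent from the map,
    get :data:`UNASSIGNED`.  Lookup is case-insensitive.
    """
    lookup = {k.lower(): v for k, v in mode_map.items()}
    out = {}
    n_unassigned = 0
    for asv in tax.lineages.index:
        label = tax.class_label(asv).strip().lower()
        mode = lookup.get(label, UNASSIGNED) if label else UNASSIGNED
        if mode == UNASSIGNED:
            n_unassigned += 1
        out[asv] = mode
    if n_unassigned:
        logger.info(
            "assign_trophic_modes: %d/%d ASVs left unassigned",
            n_unassigned,
            len(out),
        )
    return pd.Series(out, name="trophic_mode")


def summarize_modes(table: AsvCountTable, modes: pd.Series) -> pd.DataFrame:
    """Per-mode fractions of ASVs and of reads.

    Both columns sum to 1 over the four modes plus the unassigned category.
    ASVs absent from ``modes`` count as unassigned.
    """
    if table.counts.empty:
        raise ValueError("empty count table")
    asv_modes = modes.reindex(table.asv_ids).fillna(UNASSIGNED)
    categories = list(TROPHIC_MODES) + [UNASSIGNED]
    reads_per_asv = table.counts.sum(axis=0)
    total_reads = reads_per_asv.sum()
    n_asvs = len(table.asv_ids)
    rows = {}
    for cat in categories:
        members = asv_modes.index[asv_modes == cat]
        rows[cat] = {
            "asv_fraction": len(members) / n_asvs,
            "read_fraction": reads_per_asv[members].sum() / total_reads,
        }
    out = pd.DataFrame.from_dict(rows, orient="index").loc[categories]
    out.index.name = "trophic_mode"
    return out
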