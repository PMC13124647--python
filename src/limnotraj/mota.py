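"""Multivariate trajectory analysis (MOTA).

Each lake's community is tracked as the path of its monthly centroids through
a PCoA space shared by all lakes.  The trajectory length — the summed
Euclidean distances between consecutive monthly centroids — indexes how much
the community reorganised over the campaign; lengths are comparable across
lakes because every lake is embedded in the same ordination.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import Ordination, SpearmanResult, spearman

logger = logging.getLogger(__name__)


def select_axes(ordination: Ordination, threshold: float = 0.90) -> int:
    """Smallest number of leading PCoA axes whose cumulative variance
    fraction strictly exceeds ``threshold``.

    If even all axes do not exceed the threshold, all axes are used and a
    warning is emitted.
    """
    cumulative = np.cumsum(ordination.variance_fraction)
    above = np.flatnonzero(cumulative > threshold)
    if above.size == 0:
        warnings.warn(
            f"cumulative variance {cumulative[-1]:.4f} never exceeds "
            f"{threshold}; using all {cumulative.size} axes"
        )
        return int(cumulative.size)
    return int(above[0] + 1)


def monthly_centroids(
    coordinates: pd.DataFrame,
    meta: pd.DataFrame,
    lake: str,
    n_axes: int | None = None,
) -> pd.DataFrame:
    """Per-month centroid of one lake's replicate coordinates.

    The centroid is the arithmetic mean over whatever water-column replicates
    survived QC that month (normally three).  Months are ordered by
    month_index; months with no surviving sample are simply absent.
    """
    if lake not in set(meta["lake"]):
        raise ValueError(f"lake {lake!r} absent from metadata")
    samples = meta.index[meta["lake"] == lake]
    samples = [s for s in samples if s in coordinates.index]
    if not samples:
        raise ValueError(f"no ordination coordinates for lake {lake!r}")
    coords = coordinates.loc[samples]
    if n_axes is not None:
        coords = coords.iloc[:, :n_axes]
    months = meta.loc[samples, "month_index"]
    centroids = coords.groupby(months).mean().sort_index()
    centroids.index.name = "month_index"
    return centroids


@dataclass
class TrajectoryResult:
    """Per-lake cumulative trajectory lengths through shared PCoA space.

    ``summary`` has one row per lake: n_months, total_length and
    normalized_length (total divided by the shortest lake's total, so the
    minimum is exactly 1).  ``segments`` maps lake -> per-segment lengths.
    """

    summary: pd.DataFrame
    segments: dict[str, np.ndarray]
    centroids: dict[str, pd.DataFrame]


def trajectory_lengths(
    centroids_by_lake: dict[str, pd.DataFrame],
    start_month: int | None = None,
) -> TrajectoryResult:
    """Total trajectory length per lake.

    Consecutive *available* months are joined: a month missing from a lake's
    series contributes a single segment bridging the gap.  ``start_month``
    drops earlier months so all lakes start from a common time point.
    """
    rows = {}
    segments = {}
    kept = {}
    for lake, centroids in centroids_by_lake.items():
        c = centroids.sort_index()
        if start_month is not None:
            c = c.loc[c.index >= start_month]
        if c.shape[0] < 2:
            raise ValueError(
                f"lake {lake!r}: need at least 2 monthly centroids, got {c.shape[0]}"
            )
        deltas = np.diff(c.to_numpy(dtype=float), axis=0)
        seg = np.linalg.norm(deltas, axis=1)
        segments[lake] = seg
        kept[lake] = c
        rows[lake] = {"n_months": c.shape[0], "total_length": float(seg.sum())}
    summary = pd.DataFrame.from_dict(rows, orient="index")
    summary.index.name = "lake"
    shortest = summary["total_length"].min()
    if shortest > 0:
        summary["normalized_length"] = summary["total_length"] / shortest
    else:
        summary["normalized_length"] = np.where(
            summary["total_length"] == 0, 1.0, np.inf
        )
        logger.warning("shortest trajectory has zero length; normalization degenerate")
    return TrajectoryResult(summary=summary, segments=segments, centroids=kept)


def correlate_lengths_with_chla(
    result: TrajectoryResult, mean_chla: pd.Series
) -> SpearmanResult:
    """Spearman correlation of per-lake trajectory length with campaign-mean
    chlorophyll-a."""
    lakes = [lake for lake in result.summary.index if lake in mean_chla.index]
    if len(lakes) < 4:
        warnings.warn(f"only {len(lakes)} lakes; Spearman test is weakly powered")
    if len(lakes) < 3:
        raise ValueError("need at least 3 lakes with chlorophyll-a means")
    lengths = result.summary.loc[lakes, "total_length"].to_numpy()
    chla = mean_chla.loc[lakes].to_numpy(dtype=float)
    return spearman(lengths, chla)


def lake_trajectories(
    ordination: Ordination,
    meta: pd.DataFrame,
    threshold: float = 0.90,
    start_month: int | None = None,
) -> TrajectoryResult:
    """Convenience pipeline: axis selection, per-lake monthly centroids and
    trajectory lengths from one shared ordination."""
    k = select_axes(ordination, threshold)
    lakes = sorted(set(meta["lake"]))
    centroids = {
        lake: monthly_centroids(ordination.coordinates, meta, lake, n_axes=k)
        for lake in lakes
    }
    return trajectory_lengths(centroids, start_month=start_month)
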