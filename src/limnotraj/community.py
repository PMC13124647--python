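"""Alpha diversity, Bray-Curtis ordination, PERMANOVA and correlation tests.

Bray-Curtis dissimilarities are held in :class:`skbio.DistanceMatrix`.  PCoA
follows the classical Gower double-centering construction and keeps only axes
with positive eigenvalues (no Lingoes/Cailliez correction); variance fractions
are relative to the sum of positive eigenvalues.  PERMANOVA supports crossed
designs with interaction terms and sequential (Type-I) partitioning of the
distance-based sums of squares, with significance from free permutation of
sample labels.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.spatial.distance
import scipy.stats
from skbio import DistanceMatrix

from .io import AsvCountTable


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def richness(counts) -> int:
    """Number of ASVs with a strictly positive count in one sample."""
    values = np.asarray(counts)
    if np.any(values < 0):
        raise ValueError("negative counts")
    return int(np.count_nonzero(values > 0))


def shannon(counts) -> float:
    """Shannon diversity H = -sum p_i ln p_i (natural log) of one sample."""
    values = np.asarray(counts, dtype=float)
    if np.any(values < 0):
        raise ValueError("negative counts")
    total = values.sum()
    if total <= 0:
        raise ValueError("Shannon diversity undefined for an all-zero sample")
    p = values[values > 0] / total
    return float(-(p * np.log(p)).sum())


def alpha_diversity_table(table: AsvCountTable) -> pd.DataFrame:
    """Per-sample ASV richness and Shannon diversity."""
    return pd.DataFrame(
        {
            "richness": [richness(row) for _, row in table.counts.iterrows()],
            "shannon": [shannon(row) for _, row in table.counts.iterrows()],
        },
        index=table.counts.index,
    )


# ---------------------------------------------------------------------------
# beta diversity and ordination
# ---------------------------------------------------------------------------

def bray_curtis(table: AsvCountTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between all samples.

    BC(j, k) = sum_i |x_ij - x_ik| / sum_i (x_ij + x_ik), in [0, 1].
    """
    counts = table.counts.to_numpy(dtype=float)
    if np.any(counts.sum(axis=1) <= 0):
        raise ValueError("Bray-Curtis undefined for zero-sum samples")
    condensed = scipy.spatial.distance.pdist(counts, metric="braycurtis")
    return DistanceMatrix(
        scipy.spatial.distance.squareform(condensed), ids=table.sample_ids
    )


def gower_center(d_squared: np.ndarray) -> np.ndarray:
    """Gower-centered inner-product matrix G = -1/2 J D2 J with J = I - 11'/n."""
    n = d_squared.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    return -0.5 * j @ d_squared @ j


@dataclass
class Ordination:
    """PCoA result: sample coordinates on axes with positive eigenvalues.

    ``variance_fraction`` is each retained eigenvalue divided by the sum of
    positive eigenvalues; axes are ordered by decreasing eigenvalue.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    variance_fraction: np.ndarray


def pcoa(dm: DistanceMatrix) -> Ordination:
    """Principal coordinate analysis of a dissimilarity matrix.

    Eigendecomposition of the Gower-centered matrix; axes with eigenvalues
    <= 0 (within numerical tolerance) are dropped and coordinates are scaled
    by the square root of the eigenvalue.
    """
    d = np.asarray(dm.data, dtype=float)
    if d.shape[0] < 2:
        raise ValueError("PCoA needs at least two samples")
    g = gower_center(d**2)
    eigvals, eigvecs = np.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(eigvals.max(), 0.0) * 1e-9
    positive = eigvals > tol
    if not positive.any():
        raise ValueError("no positive eigenvalues; all samples identical?")
    lam = eigvals[positive]
    coords = eigvecs[:, positive] * np.sqrt(lam)
    columns = [f"PC{i + 1}" for i in range(lam.size)]
    return Ordination(
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=columns),
        eigenvalues=lam,
        variance_fraction=lam / lam.sum(),
    )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    """Sequential PERMANOVA table: one row per term plus residual and total."""

    table: pd.DataFrame
    n_permutations: int

    def __getitem__(self, term):
        return self.table.loc[term]


def _design_columns(factors: pd.DataFrame, term: str) -> np.ndarray:
    """Dummy-coded design block for a main effect or an a:b interaction."""
    parts = term.split(":")
    for p in parts:
        if p not in factors.columns:
            raise ValueError(f"unknown factor {p!r} in term {term!r}")
    combined = factors[parts[0]].astype(str)
    for p in parts[1:]:
        combined = combined + "\x1f" + factors[p].astype(str)
    return pd.get_dummies(combined).to_numpy(dtype=float)


def _hat(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Orthogonal projector onto the column space of x and its rank."""
    basis = scipy.linalg.orth(x)
    return basis @ basis.T, basis.shape[1]


def permanova(
    dm: DistanceMatrix,
    factors: pd.DataFrame,
    terms=("lake", "season", "lake:season"),
    n_perm: int = 999,
    seed: int | None = None,
    permutations: np.ndarray | None = None,
) -> PermanovaResult:
    """Sequential (Type-I) PERMANOVA on a dissimilarity matrix.

    Terms are fitted in the given order; an interaction is written ``a:b``.
    SS of each term is tr((H_k - H_{k-1}) G) with G the Gower-centered matrix
    and H_k the hat matrix of the design up to term k.  P-values come from
    free random permutations of rows, p = (1 + #{F* >= F}) / (n_perm + 1).

    ``permutations`` may supply an explicit (n_p, n) integer array of
    permutations (e.g. the full enumeration for small n); in that case
    p = mean(F* >= F) over exactly those permutations, which should include
    the identity.
    """
    ids = list(dm.ids)
    n = len(ids)
    factors = factors.loc[ids]
    g = gower_center(np.asarray(dm.data, dtype=float) ** 2)
    ss_total = float(np.trace(g))

    designs = [np.ones((n, 1))]
    for term in terms:
        designs.append(np.hstack([designs[-1], _design_columns(factors, term)]))
    hats, ranks = zip(*(_hat(x) for x in designs))
    projectors = [hats[k + 1] - hats[k] for k in range(len(terms))]
    dfs = [ranks[k + 1] - ranks[k] for k in range(len(terms))]
    residual_projector = np.eye(n) - hats[-1]
    df_res = n - ranks[-1]

    def term_stats(gmat):
        ss = np.array([float((p * gmat).sum()) for p in projectors])
        ss_res = float((residual_projector * gmat).sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            ms_res = ss_res / df_res if df_res > 0 else np.nan
            f = np.array(
                [
                    (ss[k] / dfs[k]) / ms_res if dfs[k] > 0 and df_res > 0 else np.nan
                    for k in range(len(terms))
                ]
            )
        return ss, ss_res, f

    ss_obs, ss_res_obs, f_obs = term_stats(g)

    if permutations is not None:
        perms = np.asarray(permutations, dtype=int)
        explicit = True
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
        explicit = False

    exceed = np.zeros(len(terms))
    chunk = max(1, int(2e7 // (n * n)))
    for start in range(0, len(perms), chunk):
        block = perms[start : start + chunk]
        gp = g[block[:, :, None], block[:, None, :]]
        ss_p = np.einsum("kij,pij->kp", np.array(projectors), gp)
        ss_res_p = np.einsum("ij,pij->p", residual_projector, gp)
        ms_res_p = ss_res_p / df_res if df_res > 0 else np.full(len(block), np.nan)
        for k in range(len(terms)):
            if dfs[k] > 0 and df_res > 0:
                f_p = (ss_p[k] / dfs[k]) / ms_res_p
                exceed[k] += np.count_nonzero(f_p >= f_obs[k] - 1e-12)

    p_values = []
    for k in range(len(terms)):
        if dfs[k] == 0 or df_res == 0 or not np.isfinite(f_obs[k]):
            p_values.append(np.nan)
        elif explicit:
            p_values.append(exceed[k] / len(perms))
        else:
            p_values.append((1 + exceed[k]) / (len(perms) + 1))

    rows = []
    for k, term in enumerate(terms):
        rows.append(
            {
                "df": dfs[k],
                "sum_sq": ss_obs[k],
                "pseudo_F": f_obs[k],
                "R2": ss_obs[k] / ss_total,
                "p_value": p_values[k],
            }
        )
    rows.append(
        {
            "df": df_res,
            "sum_sq": ss_res_obs,
            "pseudo_F": np.nan,
            "R2": ss_res_obs / ss_total,
            "p_value": np.nan,
        }
    )
    rows.append(
        {
            "df": n - 1,
            "sum_sq": ss_total,
            "pseudo_F": np.nan,
            "R2": 1.0,
            "p_value": np.nan,
        }
    )
    table = pd.DataFrame(rows, index=list(terms) + ["residual", "total"])
    return PermanovaResult(table=table, n_permutations=len(perms))


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

@dataclass
class SpearmanResult:
    """Spearman rank correlation with its two-sided p-value."""

    rho: float
    p_value: float
    n: int
    degenerate: bool = False


def spearman(x, y, exact_max_n: int = 8) -> SpearmanResult:
    """Spearman rank correlation (mid-ranks for ties).

    For n <= ``exact_max_n`` the two-sided p-value is computed by exhaustive
    enumeration of rank permutations; above that, the usual t approximation
    with n - 2 degrees of freedom is used.  Zero variance in either rank
    vector yields an undefined (NaN) rho flagged as degenerate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        return SpearmanResult(rho=np.nan, p_value=np.nan, n=n, degenerate=True)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        ax = (rx - rx.mean()) / (np.std(rx) * math.sqrt(n))
        ay = (ry - ry.mean()) / (np.std(ry) * math.sqrt(n))
        observed = abs(np.dot(ax, ay))
        hits = total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if abs(np.dot(ax, ay[list(perm)])) >= observed - 1e-12:
                hits += 1
        p = hits / total
    else:
        t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho**2))
        p = float(2 * scipy.stats.t.sf(abs(t), df=n - 2))
        p = min(1.0, p)
    return SpearmanResult(rho=rho, p_value=p, n=n)


# ---------------------------------------------------------------------------
# environmental PCA
# ---------------------------------------------------------------------------

@dataclass
class EnvPcaResult:
    """PCA of z-scored environmental variables.

    ``cos2`` holds the squared correlation of each variable with each
    component score; rows sum to 1 over all components.
    """

    scores: pd.DataFrame
    eigenvalues: np.ndarray
    variance_fraction: np.ndarray
    cos2: pd.DataFrame


def env_pca(variables: pd.DataFrame) -> EnvPcaResult:
    """PCA on centered and scaled (unit variance, ddof=1) columns."""
    if variables.shape[1] < 2:
        raise ValueError("need at least two environmental parameters")
    x = variables.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        names = [variables.columns[i] for i in constant]
        raise ValueError(f"constant environmental column(s): {names}")
    z = (x - x.mean(axis=0)) / sd
    n = z.shape[0]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    keep = s > s.max() * 1e-12
    u, s, vt = u[:, keep], s[keep], vt[keep]
    scores = u * s
    eigenvalues = s**2 / (n - 1)
    # correlation of variable v with component c; z-scored so this is the
    # loading scaled by sqrt(eigenvalue)
    corr = vt.T * (s / math.sqrt(n - 1))
    cos2 = pd.DataFrame(
        corr**2,
        index=variables.columns,
        columns=[f"PC{i + 1}" for i in range(s.size)],
    )
    return EnvPcaResult(
        scores=pd.DataFrame(
            scores, index=variables.index, columns=cos2.columns
        ),
        eigenvalues=eigenvalues,
        variance_fraction=eigenvalues / eigenvalues.sum(),
        cos2=cos2,
    )


# ---------------------------------------------------------------------------
# serialization helpers
# ---------------------------------------------------------------------------

def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(
        path, sep="\t"
    )


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(dtype=float), ids=[str(i) for i in df.index])
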