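"""Per-lake core-ASV co-occurrence networks from SparCC correlations.

SparCC estimates basis (log-abundance) correlations from compositional count
data: each Dirichlet resample converts counts to fractions, the log-ratio
variance matrix t_ij = var(ln x_i / ln x_j) is formed, approximate basis
variances are solved from the linear system implied by the sparsity
assumption, and strongly correlated pairs are iteratively excluded from the
system before re-solving.  Edges retain correlations with |rho| at or above a
threshold (default 0.6); network metrics follow the conventions used for
microbial co-occurrence tables: components include singletons, modules are
components with at least two nodes, the clustering coefficient is the global
transitivity, and modularity comes from greedy modularity maximisation on
absolute edge weights.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io import AsvCountTable
from .trophic import TROPHIC_MODES, UNASSIGNED

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# core ASV selection
# ---------------------------------------------------------------------------

def select_core_asvs(table: AsvCountTable, threshold: float = 0.01) -> list[str]:
    """ASVs reaching relative abundance >= ``threshold`` (inclusive) in at
    least one sample of the given (lake-restricted) table."""
    rel = table.relative_abundance()
    keep = rel.max(axis=0) >= threshold
    return rel.columns[keep].tolist()


# ---------------------------------------------------------------------------
# SparCC
# ---------------------------------------------------------------------------

def _sparcc_single(
    log_fracs: np.ndarray,
    exclusion_threshold: float,
    exclusion_iterations: int,
) -> np.ndarray:
    """One SparCC pass on a samples x taxa matrix of log fractions."""
    m = log_fracs.shape[1]
    cov = np.cov(log_fracs, rowvar=False)
    var = np.diag(cov)
    t_mat = var[:, None] + var[None, :] - 2 * cov
    np.fill_diagonal(t_mat, 0.0)

    m_mat = np.ones((m, m)) + (m - 2) * np.eye(m)
    s_vec = t_mat.sum(axis=1)
    m_work, s_work = m_mat.copy(), s_vec.copy()
    excluded = np.zeros((m, m), dtype=bool)

    def solve(mm, ss):
        w = np.linalg.solve(mm, ss)
        if not np.all(np.isfinite(w)):
            raise np.linalg.LinAlgError("non-finite basis variances")
        w = np.clip(w, 1e-10, None)
        denom = 2 * np.sqrt(np.outer(w, w))
        rho = (w[:, None] + w[None, :] - t_mat) / denom
        rho = np.clip(rho, -1.0, 1.0)
        np.fill_diagonal(rho, 1.0)
        return rho

    rho = solve(m_work, s_work)
    for _ in range(exclusion_iterations):
        masked = np.abs(rho).copy()
        np.fill_diagonal(masked, 0.0)
        masked[excluded] = 0.0
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] < exclusion_threshold:
            break
        excluded[i, j] = excluded[j, i] = True
        s_work[i] -= t_mat[i, j]
        s_work[j] -= t_mat[i, j]
        m_work[i, i] -= 1
        m_work[j, j] -= 1
        m_work[i, j] -= 1
        m_work[j, i] -= 1
        try:
            rho = solve(m_work, s_work)
        except np.linalg.LinAlgError:
            logger.warning(
                "SparCC exclusion made the system singular; "
                "falling back to the unexcluded solution"
            )
            rho = solve(m_mat, s_vec)
            break
    return rho


def sparcc(
    table: AsvCountTable,
    n_resamples: int = 20,
    exclusion_threshold: float = 0.1,
    exclusion_iterations: int = 10,
    seed: int | None = None,
) -> pd.DataFrame:
    """SparCC basis correlation matrix for the table's ASVs.

    Each resample draws posterior component fractions per sample from
    Dirichlet(counts + 1); the returned matrix is the mean correlation over
    resamples (symmetric, unit diagonal, entries in [-1, 1]).
    """
    counts = table.counts.to_numpy(dtype=float)
    n, m = counts.shape
    if n < 10:
        raise ValueError(f"SparCC needs at least 10 samples, got {n}")
    if m < 4:
        raise ValueError(f"SparCC needs at least 4 taxa, got {m}")
    rng = np.random.default_rng(seed)
    acc = np.zeros((m, m))
    for _ in range(n_resamples):
        # Dirichlet(counts + 1) posterior draw, per sample, via gammas
        gammas = rng.standard_gamma(counts + 1.0)
        fracs = gammas / gammas.sum(axis=1, keepdims=True)
        acc += _sparcc_single(
            np.log(fracs), exclusion_threshold, exclusion_iterations
        )
    rho = acc / n_resamples
    rho = (rho + rho.T) / 2
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=table.asv_ids, columns=table.asv_ids)


# ---------------------------------------------------------------------------
# network construction and metrics
# ---------------------------------------------------------------------------

def build_network(
    corr: pd.DataFrame,
    modes: pd.Series | None = None,
    abundances: pd.Series | None = None,
    min_corr: float = 0.6,
) -> nx.Graph:
    """Signed weighted graph over all core ASVs.

    Every ASV is a node (isolated nodes are retained so component counts
    include singletons); an edge exists iff |rho| >= ``min_corr`` (inclusive),
    weighted by rho with its sign recorded.
    """
    graph = nx.Graph()
    ids = corr.index.tolist()
    for asv in ids:
        mode = UNASSIGNED if modes is None else modes.get(asv, UNASSIGNED)
        abund = np.nan if abundances is None else float(abundances.get(asv, np.nan))
        graph.add_node(asv, trophic_mode=mode, mean_rel_abundance=abund)
    values = corr.to_numpy(dtype=float)
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            rho = values[a, b]
            if abs(rho) >= min_corr - 1e-12:
                graph.add_edge(
                    ids[a],
                    ids[b],
                    weight=float(rho),
                    abs_weight=abs(float(rho)),
                    sign=1 if rho > 0 else -1,
                )
    return graph


def network_modules(graph: nx.Graph) -> list[set]:
    """Connected components with at least two nodes."""
    return [c for c in nx.connected_components(graph) if len(c) >= 2]


def module_trophic_richness(graph: nx.Graph, module) -> int:
    """Distinct trophic modes among a module's nodes (unassigned ignored)."""
    modes = {
        graph.nodes[n]["trophic_mode"]
        for n in module
        if graph.nodes[n]["trophic_mode"] in TROPHIC_MODES
    }
    return len(modes)


def compute_network_metrics(graph: nx.Graph, lake: str | None = None) -> dict:
    """Summary metrics of one lake's co-occurrence network.

    Percentages of trophic modes are computed over connected (degree >= 1)
    nodes only; edge-dependent metrics are NaN when the network has no edge.
    """
    n_nodes = graph.number_of_nodes()
    if n_nodes == 0:
        raise ValueError("empty network")
    n_edges = graph.number_of_edges()
    components = list(nx.connected_components(graph))
    modules = [c for c in components if len(c) >= 2]
    lcc = max((len(c) for c in components), default=0)
    connected = [n for n in graph.nodes if graph.degree(n) > 0]

    record: dict = {
        "lake": lake,
        "core_asv_count": n_nodes,
        "components": len(components),
        "modules": len(modules),
        "edges": n_edges,
        "pct_lcc_nodes": 100.0 * lcc / n_nodes,
        "connected_nodes": len(connected),
    }
    if n_edges > 0:
        signs = [d["sign"] for _, _, d in graph.edges(data=True)]
        n_pos = sum(s > 0 for s in signs)
        record["pct_positive_edges"] = 100.0 * n_pos / n_edges
        record["pct_negative_edges"] = 100.0 * (n_edges - n_pos) / n_edges
        record["clustering_coefficient"] = nx.transitivity(graph)
        communities = nx.algorithms.community.greedy_modularity_communities(
            graph, weight="abs_weight"
        )
        record["modularity"] = nx.algorithms.community.modularity(
            graph, communities, weight="abs_weight"
        )
    else:
        for key in (
            "pct_positive_edges",
            "pct_negative_edges",
            "clustering_coefficient",
            "modularity",
        ):
            record[key] = np.nan

    for mode in TROPHIC_MODES:
        n_mode = sum(
            1 for n in connected if graph.nodes[n]["trophic_mode"] == mode
        )
        record[f"pct_connected_{mode}"] = (
            100.0 * n_mode / len(connected) if connected else np.nan
        )

    if modules:
        richness = [module_trophic_richness(graph, m) for m in modules]
        record["pct_modules_all_four_modes"] = (
            100.0 * sum(r == 4 for r in richness) / len(modules)
        )
        record["module_mean_trophic_richness"] = float(np.mean(richness))
    else:
        record["pct_modules_all_four_modes"] = np.nan
        record["module_mean_trophic_richness"] = np.nan
    return record


# ---------------------------------------------------------------------------
# category aggregation
# ---------------------------------------------------------------------------

def aggregate_metrics_by_category(
    records: pd.DataFrame, categories: pd.Series
) -> pd.DataFrame:
    """Mean and sample SD (n-1) of each metric, per lake category and overall.

    ``records`` is lakes x metrics; ``categories`` maps lake -> category.
    Categories with a single lake get SD = NaN.
    """
    missing = [lake for lake in records.index if lake not in categories.index]
    if missing:
        raise ValueError(f"lakes without a category: {missing}")
    cats = categories.loc[records.index].astype(str)
    numeric = records.select_dtypes(include=[np.number])
    blocks = {}
    for cat in pd.unique(cats):
        sub = numeric.loc[cats == cat]
        blocks[cat] = {"mean": sub.mean(), "sd": sub.std(ddof=1)}
    blocks["overall"] = {"mean": numeric.mean(), "sd": numeric.std(ddof=1)}
    out = pd.concat(
        {cat: pd.DataFrame(stats) for cat, stats in blocks.items()}, axis=0
    )
    out.index.names = ["category", "metric"]
    return out


def load_reference_network_metrics() -> pd.DataFrame:
    """Published per-lake co-occurrence network metrics for the nine
    peri-urban lakes of the Greater-Paris survey, with their campaign
    trophic category.  Used to validate the aggregation arithmetic."""
    path = importlib.resources.files("limnotraj").joinpath(
        "data/reference_network_metrics.tsv"
    )
    with importlib.resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", index_col=0)
    return df


def export_network(graph: nx.Graph, edge_path, node_path) -> None:
    """Edge list (asv_a, asv_b, rho, sign) and node table TSVs."""
    edges = pd.DataFrame(
        [
            {"asv_a": a, "asv_b": b, "rho": d["weight"], "sign": d["sign"]}
            for a, b, d in graph.edges(data=True)
        ]
    )
    nodes = pd.DataFrame(
        [
            {
                "asv": n,
                "trophic_mode": d["trophic_mode"],
                "mean_rel_abundance": d["mean_rel_abundance"],
                "degree": graph.degree(n),
            }
            for n, d in graph.nodes(data=True)
        ]
    )
    edges.to_csv(edge_path, sep="\t", index=False)
    nodes.to_csv(node_path, sep="\t", index=False)
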