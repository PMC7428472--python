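"""Prevalence-filtered association networks and their comparison.

Within-kingdom networks use pairwise Spearman correlation; interkingdom
networks use distance correlation with a permutation test.  Edge
significance is raw p < alpha with no multiple-testing correction (the
display convention this mirrors shows all nominally significant edges); an
optional Benjamini-Hochberg mode is provided as a documented deviation.
Networks are compared by relative connectedness (edges / nodes, nodes being
taxa with at least one significant edge) and by their degree distributions.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from crosskingdom.table_io import AbundanceTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Edge:
    taxon_a: str
    taxon_b: str
    kingdom_a: str
    kingdom_b: str
    method: str            # "spearman" | "dcor"
    value: float           # rho for spearman, dcor for dcor
    sign: int              # +1 / -1
    p_value: float

    def key(self) -> tuple[str, str]:
        return tuple(sorted((self.taxon_a, self.taxon_b)))


@dataclass(frozen=True)
class AssociationNetwork:
    """Significant-edge network over taxa from one or two kingdoms."""

    edges: tuple[Edge, ...]
    taxa: tuple[str, ...]            # candidate taxa after prevalence filtering
    kingdoms: dict[str, str]
    group_label: str = ""
    prevalence: float | None = None
    alpha: float = 0.05
    n_perm: int | None = None

    def __post_init__(self) -> None:
        keys = [e.key() for e in self.edges]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate edges")
        for e in self.edges:
            if e.taxon_a == e.taxon_b:
                raise ValueError(f"self-edge on {e.taxon_a!r}")
            if not e.p_value < self.alpha:
                raise ValueError(f"edge {e.key()} has p {e.p_value} >= alpha {self.alpha}")

    @property
    def nodes(self) -> list[str]:
        """Taxa incident to at least one significant edge."""
        seen = {t for e in self.edges for t in (e.taxon_a, e.taxon_b)}
        return [t for t in self.taxa if t in seen]

    def degrees(self) -> pd.Series:
        deg = {t: 0 for t in self.nodes}
        for e in self.edges:
            deg[e.taxon_a] += 1
            deg[e.taxon_b] += 1
        return pd.Series(deg, dtype=int)


@dataclass(frozen=True)
class NetworkComparison:
    stats_per_group: pd.DataFrame     # rows: group; cols: nodes, edges, connectedness, mean_degree, sem_degree
    degree_p_value: float | None = None


# -- distance correlation ------------------------------------------------------

def distance_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Sample distance correlation of two 1-D samples, in [0, 1].

    Double-centers each Euclidean pairwise-distance matrix; dCov^2 is the
    mean elementwise product; dCor = dCov / sqrt(dVar_x dVar_y), and 0 when
    either dVar vanishes (a constant input).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"inputs must be equal-length vectors, got {x.shape} and {y.shape}")
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    a = _centered_distances(x)
    b = _centered_distances(y)
    dcov2 = (a * b).mean()
    dvar_x = (a * a).mean()
    dvar_y = (b * b).mean()
    if dvar_x <= 0 or dvar_y <= 0:
        return 0.0
    return float(np.sqrt(max(dcov2, 0.0) / np.sqrt(dvar_x * dvar_y)))


def _centered_distances(v: np.ndarray) -> np.ndarray:
    d = np.abs(v[:, None] - v[None, :])
    return d - d.mean(axis=0, keepdims=True) - d.mean(axis=1, keepdims=True) + d.mean()


def dcor_permutation_p(x: np.ndarray, y: np.ndarray, n_perm: int = 999,
                       seed: int = 0) -> tuple[float, float]:
    """Observed dcor and its right-tail permutation p-value,
    p = (1 + #{dcor_perm >= dcor_obs}) / (1 + n_perm)."""
    if n_perm < 99:
        logger.warning("n_perm=%d gives coarse p-value resolution", n_perm)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    a = _centered_distances(x)
    b = _centered_distances(y)
    dvar_x = (a * a).mean()
    dvar_y = (b * b).mean()
    if dvar_x <= 0 or dvar_y <= 0:
        return 0.0, 1.0
    denom = np.sqrt(dvar_x * dvar_y)

    def _dcor_from_b(b_mat: np.ndarray) -> float:
        return float(np.sqrt(max((a * b_mat).mean(), 0.0) / denom))

    observed = _dcor_from_b(b)
    rng = np.random.default_rng(seed)
    hits = 0
    n = len(x)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        # permuting y permutes rows+columns of its centered distance matrix
        if _dcor_from_b(b[np.ix_(perm, perm)]) >= observed:
            hits += 1
    return observed, (1 + hits) / (1 + n_perm)


# -- Spearman edges ------------------------------------------------------------

def _spearman_exact_p(x: np.ndarray, y: np.ndarray, observed_rho: float) -> float:
    """Two-sided exact permutation p for small n (<= 9), midrank ties."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    zx = (rx - rx.mean()) / rx.std()
    zy = (ry - ry.mean()) / ry.std()
    perms = np.array(list(itertools.permutations(zy)))
    rhos = perms @ zx / len(x)
    return float((np.abs(rhos) >= abs(observed_rho) - 1e-12).mean())


def spearman_pair(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho and two-sided p: t-approximation with midranks for
    n >= 10, exact permutation below."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rho, p = stats.spearmanr(x, y)
    if len(x) < 10:
        p = _spearman_exact_p(x, y, rho)
    return float(rho), float(p)


def spearman_edges(table: AbundanceTable, alpha: float = 0.05,
                   group_label: str = "", prevalence: float | None = None,
                   fdr: bool = False) -> AssociationNetwork:
    """All-pairs Spearman network on one (already prevalence-filtered)
    table; keeps pairs with p < alpha, signed by rho."""
    if table.n_samples < 5:
        raise ValueError("need at least 5 samples")
    data = table.counts()
    taxa = table.taxon_ids
    records = []
    for i, j in itertools.combinations(range(len(taxa)), 2):
        xi, xj = data[:, i], data[:, j]
        if np.ptp(xi) == 0 or np.ptp(xj) == 0:
            logger.warning("constant taxon in pair (%s, %s); skipped", taxa[i], taxa[j])
            continue
        rho, p = spearman_pair(xi, xj)
        records.append((i, j, rho, p))
    edges = _significant(records, taxa, {t: table.kingdom for t in taxa},
                         "spearman", alpha, fdr)
    return AssociationNetwork(tuple(edges), tuple(taxa),
                              {t: table.kingdom for t in taxa},
                              group_label=group_label, prevalence=prevalence,
                              alpha=alpha)


def dcor_edges(bact: AbundanceTable, fungi: AbundanceTable, alpha: float = 0.05,
               n_perm: int = 999, seed: int = 0, group_label: str = "",
               prevalence: float | None = None, within_kingdom: bool = False,
               fdr: bool = False) -> AssociationNetwork:
    """Interkingdom distance-correlation network on two sample-aligned,
    prevalence-filtered tables.

    Edge p-values come from the permutation test; the edge sign is borrowed
    from the pair's Spearman rho because dcor itself is unsigned.  With
    ``within_kingdom=True``, same-kingdom pairs are tested too.
    """
    if bact.sample_ids != fungi.sample_ids:
        raise ValueError("tables must be sample-aligned")
    if n_perm < 99:
        logger.warning("n_perm=%d gives coarse p-value resolution", n_perm)
    merged = pd.concat([bact.data, fungi.data], axis=1)
    kingdoms = {**{t: "bacteria" for t in bact.taxon_ids},
                **{t: "fungi" for t in fungi.taxon_ids}}
    taxa = list(merged.columns)
    data = merged.to_numpy(dtype=float)
    n_samples, n_taxa = data.shape

    rng = np.random.default_rng(seed)

    centered = np.empty((n_taxa, n_samples * n_samples))
    dvars = np.empty(n_taxa)
    for k in range(n_taxa):
        c = _centered_distances(data[:, k])
        centered[k] = c.ravel()
        dvars[k] = (c * c).mean()

    records = []
    for j in range(n_taxa):           # outer: taxon whose matrix is permuted
        if dvars[j] <= 0:
            continue
        partners = [i for i in range(j)
                    if dvars[i] > 0
                    and (within_kingdom or kingdoms[taxa[i]] != kingdoms[taxa[j]])]
        if not partners:
            continue
        # A fresh permutation set per outer taxon is reused across its
        # partners: the permuted centered matrix is the expensive part, and
        # pairs with different outer taxa stay independent.
        perms = np.array([rng.permutation(n_samples) for _ in range(n_perm)])
        cj = centered[j].reshape(n_samples, n_samples)
        perm_flat = cj[perms[:, :, None], perms[:, None, :]].reshape(n_perm, -1)
        for i in partners:
            denom = np.sqrt(dvars[i] * dvars[j])
            obs = float(np.sqrt(max((centered[i] * centered[j]).mean(), 0.0) / denom))
            perm_dcov2 = perm_flat @ centered[i] / (n_samples * n_samples)
            perm_dcor = np.sqrt(np.maximum(perm_dcov2, 0.0) / denom)
            p = float((1 + (perm_dcor >= obs - 1e-12).sum()) / (1 + n_perm))
            rho = stats.spearmanr(data[:, i], data[:, j]).statistic
            records.append((i, j, obs, p, 1 if rho >= 0 else -1))
    edges = _significant(records, taxa, kingdoms, "dcor", alpha, fdr)
    return AssociationNetwork(tuple(edges), tuple(taxa), kingdoms,
                              group_label=group_label, prevalence=prevalence,
                              alpha=alpha, n_perm=n_perm)


def _significant(records, taxa, kingdoms, method, alpha, fdr) -> list[Edge]:
    if not records:
        return []
    pvals = np.array([r[3] for r in records])
    if fdr:
        keep_p = _bh_adjust(pvals) < alpha
    else:
        keep_p = pvals < alpha
    edges = []
    for rec, keep in zip(records, keep_p):
        if not keep:
            continue
        i, j, value, p = rec[0], rec[1], rec[2], rec[3]
        sign = rec[4] if len(rec) > 4 else (1 if value >= 0 else -1)
        edges.append(Edge(taxa[i], taxa[j], kingdoms[taxa[i]], kingdoms[taxa[j]],
                          method, float(value), int(sign), float(p)))
    return edges


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * n / rank)
        adj[idx] = running
    return adj


# -- summaries -----------------------------------------------------------------

def network_stats(network: AssociationNetwork) -> dict:
    """Node/edge counts, relative connectedness (edges / nodes), and the
    degree mean with its standard error."""
    degrees = network.degrees()
    n_nodes, n_edges = len(degrees), len(network.edges)
    if n_nodes == 0:
        logger.warning("empty network for group %r", network.group_label)
        return {"group": network.group_label, "nodes": 0, "edges": 0,
                "connectedness": 0.0, "mean_degree": 0.0, "sem_degree": 0.0}
    deg = degrees.to_numpy(dtype=float)
    sem = float(deg.std(ddof=1) / math.sqrt(n_nodes)) if n_nodes > 1 else 0.0
    return {"group": network.group_label, "nodes": n_nodes, "edges": n_edges,
            "connectedness": n_edges / n_nodes,
            "mean_degree": float(deg.mean()), "sem_degree": sem}


def compare_networks(net1: AssociationNetwork, net2: AssociationNetwork
                     ) -> NetworkComparison:
    """Side-by-side stats plus a two-sided Mann-Whitney test on the two
    degree distributions."""
    if (net1.alpha, net1.prevalence, net1.n_perm) != (net2.alpha, net2.prevalence, net2.n_perm):
        raise ValueError("networks were built with different parameters")
    d1, d2 = net1.degrees(), net2.degrees()
    if len(d1) < 2 or len(d2) < 2:
        raise ValueError("each network needs at least 2 connected nodes")
    rows = pd.DataFrame([network_stats(net1), network_stats(net2)]).set_index("group")
    if d1.nunique() == 1 and d2.nunique() == 1 and d1.iloc[0] == d2.iloc[0]:
        p = 1.0
    else:
        p = float(stats.mannwhitneyu(d1.to_numpy(), d2.to_numpy(),
                                     alternative="two-sided").pvalue)
    return NetworkComparison(rows, p)


# -- export --------------------------------------------------------------------

EDGE_COLUMNS = ("taxon_a", "taxon_b", "kingdom_a", "kingdom_b",
                "method", "value", "sign", "p")


def edges_frame(network: AssociationNetwork) -> pd.DataFrame:
    rows = [{"taxon_a": e.taxon_a, "taxon_b": e.taxon_b,
             "kingdom_a": e.kingdom_a, "kingdom_b": e.kingdom_b,
             "method": e.method, "value": e.value, "sign": e.sign, "p": e.p_value}
            for e in network.edges]
    return pd.DataFrame(rows, columns=list(EDGE_COLUMNS))


def write_edges(network: AssociationNetwork, path) -> None:
    edges_frame(network).to_csv(path, sep="\t", index=False)


def to_networkx(network: AssociationNetwork):
    import networkx as nx

    g = nx.Graph()
    for t in network.nodes:
        g.add_node(t, kingdom=network.kingdoms.get(t, ""))
    for e in network.edges:
        g.add_edge(e.taxon_a, e.taxon_b, weight=e.value, sign=e.sign,
                   p=e.p_value, method=e.method)
    return g


def write_graphml(network: AssociationNetwork, path) -> None:
    import networkx as nx

    nx.write_graphml(to_networkx(network), path)
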