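"""Alpha and beta diversity, ordination, and group significance tests."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity
from skbio.stats.distance import permanova as _skbio_permanova
from skbio.stats.ordination import pcoa as _skbio_pcoa

from crosskingdom.table_io import AbundanceTable, SampleMetadata, relative_abundance

logger = logging.getLogger(__name__)

ALPHA_INDICES = ("shannon", "simpson_reciprocal", "ace", "chao1")


@dataclass(frozen=True)
class AlphaDiversityResult:
    """Per-sample alpha indices plus two-group rank-sum p-values."""

    values: pd.DataFrame          # samples x indices
    p_values: dict[str, float] | None = None


@dataclass(frozen=True)
class BetaDiversityResult:
    distances: DistanceMatrix
    metric: str
    pcoa_coordinates: pd.DataFrame | None = None
    eigenvalues: np.ndarray | None = None
    proportion_explained: np.ndarray | None = None
    test_statistic: float | None = None
    p_value: float | None = None


# -- alpha ---------------------------------------------------------------------

def shannon(counts: np.ndarray) -> float:
    """Shannon entropy in nats, ignoring zero-count taxa."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def simpson_reciprocal(counts: np.ndarray) -> float:
    """Reciprocal Simpson index 1 / sum(p_i^2) (effective species count)."""
    counts = np.asarray(counts, dtype=float)
    p = counts[counts > 0] / counts.sum()
    return float(1.0 / (p ** 2).sum())


def simpson_complement(counts: np.ndarray) -> float:
    """Gini-Simpson 1 - sum(p_i^2), the complement form."""
    counts = np.asarray(counts, dtype=float)
    p = counts[counts > 0] / counts.sum()
    return float(1.0 - (p ** 2).sum())


def chao1(counts: np.ndarray, bias_corrected: bool = True) -> float:
    """Chao1 richness estimate from singleton/doubleton counts.

    Bias-corrected form S + F1 (F1 - 1) / (2 (F2 + 1)) by default; the
    classic form S + F1^2 / (2 F2) is undefined at F2 = 0 and falls back to
    the corrected form there.
    """
    counts = _require_integer(counts, "chao1")
    observed = counts[counts > 0]
    s_obs = len(observed)
    f1 = int((observed == 1).sum())
    f2 = int((observed == 2).sum())
    if bias_corrected or f2 == 0:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    return s_obs + f1 ** 2 / (2.0 * f2)


def ace(counts: np.ndarray, rare_cutoff: int = 10) -> float:
    """Abundance-based coverage estimator with the standard rare/abundant
    split at ``rare_cutoff`` individuals."""
    counts = _require_integer(counts, "ace")
    observed = counts[counts > 0]
    rare = observed[observed <= rare_cutoff]
    abundant = observed[observed > rare_cutoff]
    s_rare, s_abund = len(rare), len(abundant)
    if s_rare == 0:
        return float(s_abund)
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    if n_rare == f1:
        # coverage undefined (all rare taxa are singletons): fall back to Chao1
        return chao1(counts)
    c_ace = 1.0 - f1 / n_rare
    ks = np.arange(1, rare_cutoff + 1)
    fk = np.array([(rare == k).sum() for k in ks])
    gamma = max(
        (s_rare / c_ace) * (ks * (ks - 1) * fk).sum() / (n_rare * (n_rare - 1)) - 1.0,
        0.0,
    ) if n_rare > 1 else 0.0
    return float(s_abund + s_rare / c_ace + (f1 / c_ace) * gamma)


def _require_integer(counts, name: str) -> np.ndarray:
    arr = np.asarray(counts, dtype=float)
    if not np.allclose(arr, np.round(arr)):
        raise ValueError(f"{name} requires integer count data")
    return np.round(arr).astype(np.int64)


def alpha_indices(table: AbundanceTable, meta: SampleMetadata | None = None,
                  simpson_form: str = "reciprocal") -> AlphaDiversityResult:
    """Compute Shannon, Simpson (reciprocal by default), ACE and Chao1 per
    sample; when metadata is given, attach two-group rank-sum p-values."""
    simpson_fn = {"reciprocal": simpson_reciprocal,
                  "complement": simpson_complement}[simpson_form]
    rows = {}
    for sample in table.sample_ids:
        c = table.data.loc[sample].to_numpy()
        rows[sample] = {
            "shannon": shannon(c),
            "simpson_reciprocal": simpson_fn(c),
            "ace": ace(c),
            "chao1": chao1(c),
        }
    values = pd.DataFrame.from_dict(rows, orient="index").loc[table.sample_ids]
    p_values = None
    if meta is not None:
        meta.validate_two_groups()
        g1, g2 = meta.group_levels()
        groups = meta.groups.loc[table.sample_ids]
        p_values = {
            idx: compare_alpha(values.loc[groups == g1, idx].to_numpy(),
                               values.loc[groups == g2, idx].to_numpy())
            for idx in ALPHA_INDICES
        }
    return AlphaDiversityResult(values, p_values)


def compare_alpha(values1: np.ndarray, values2: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value for one index;
    exact for small tie-free samples."""
    from crosskingdom.lefse import ranksum_p

    values1, values2 = np.asarray(values1, float), np.asarray(values2, float)
    if len(values1) < 3 or len(values2) < 3:
        raise ValueError("each group needs at least 3 samples")
    if np.ptp(np.concatenate([values1, values2])) == 0:
        return 1.0
    return ranksum_p(values1, values2)


# -- beta ----------------------------------------------------------------------

def rarefy(table: AbundanceTable, depth: int | None = None, seed: int = 0) -> AbundanceTable:
    """Subsample each sample without replacement to a common depth
    (minimum sample total by default)."""
    counts = _require_integer(table.counts(), "rarefy")
    totals = counts.sum(axis=1)
    if depth is None:
        depth = int(totals.min())
    if (totals < depth).any():
        bad = [table.sample_ids[i] for i in np.nonzero(totals < depth)[0]]
        raise ValueError(f"samples below rarefaction depth {depth}: {bad}")
    rng = np.random.default_rng(seed)
    out = np.zeros_like(counts)
    for i, row in enumerate(counts):
        pool = np.repeat(np.arange(len(row)), row)
        pick = rng.choice(pool, size=depth, replace=False)
        out[i] = np.bincount(pick, minlength=len(row))
    from dataclasses import replace as _replace
    return _replace(table, data=pd.DataFrame(out, index=table.data.index,
                                             columns=table.data.columns))


def beta_distance(table: AbundanceTable, metric: str = "bray_curtis",
                  tree: TreeNode | None = None,
                  meta: SampleMetadata | None = None,
                  n_perm: int = 999, seed: int = 0,
                  run_pcoa: bool = True) -> BetaDiversityResult:
    """Pairwise distances (Bray-Curtis or UniFrac), optional PCoA, and an
    optional PERMANOVA group-separation test."""
    counts = table.counts()
    ids = table.sample_ids
    if metric == "bray_curtis":
        dm = beta_diversity("braycurtis", counts, ids=ids)
    elif metric in ("unweighted_unifrac", "weighted_unifrac"):
        if tree is None:
            raise ValueError(f"{metric} requires a phylogenetic tree")
        leaves = {t.name for t in tree.tips()}
        missing = sorted(set(table.taxon_ids) - leaves)
        if missing:
            raise ValueError(f"taxa absent from the tree: {missing}")
        kwargs = {"normalized": True} if metric == "weighted_unifrac" else {}
        dm = beta_diversity(metric, counts.astype(np.int64), ids=ids,
                            taxa=table.taxon_ids, tree=tree, **kwargs)
    else:
        raise ValueError(f"unknown metric {metric!r}")

    coords = eigvals = prop = None
    if run_pcoa:
        coords, eigvals, prop = pcoa(dm)
    stat = pval = None
    if meta is not None:
        meta.validate_two_groups()
        stat, pval = permanova(dm, meta.groups.loc[ids], n_perm=n_perm, seed=seed)
    return BetaDiversityResult(dm, metric, coords, eigvals, prop, stat, pval)


def pcoa(distance_matrix: DistanceMatrix | np.ndarray, ids=None
         ) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Classical multidimensional scaling of a distance matrix.

    Returns (coordinates as a samples x axes frame, eigenvalues sorted
    descending including any negative ones, proportion explained).
    Coordinates span the non-negative eigenvalues only.
    """
    if not isinstance(distance_matrix, DistanceMatrix):
        arr = np.asarray(distance_matrix, dtype=float)
        if not np.allclose(arr, arr.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        distance_matrix = DistanceMatrix(arr, ids=ids)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skbio warns on negative eigenvalues
        res = _skbio_pcoa(distance_matrix, method="eigh")
    return (res.samples, res.eigvals.to_numpy(), res.proportion_explained.to_numpy())


def permanova(distance_matrix: DistanceMatrix | np.ndarray, groups,
              n_perm: int = 999, seed: int = 0) -> tuple[float, float]:
    """Permutational MANOVA; returns (pseudo-F, permutation p-value).

    p = (1 + #{permuted F >= observed}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not isinstance(distance_matrix, DistanceMatrix):
        distance_matrix = DistanceMatrix(np.asarray(distance_matrix, dtype=float))
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if (counts < 2).any():
        raise ValueError("each group needs at least 2 samples")
    condensed = distance_matrix.condensed_form()
    if np.ptp(condensed) == 0:
        logger.warning("constant distance matrix; PERMANOVA p set to 1")
        return float("nan"), 1.0
    res = _skbio_permanova(distance_matrix, grouping=groups, permutations=n_perm,
                           seed=seed)
    return float(res["test statistic"]), float(res["p-value"])


def write_distance_matrix(result: BetaDiversityResult, path) -> None:
    frame = pd.DataFrame(result.distances.data,
                         index=result.distances.ids, columns=result.distances.ids)
    frame.index.name = "sample"
    frame.to_csv(path, sep="\t")


def group_relative_abundance(table: AbundanceTable, meta: SampleMetadata) -> pd.DataFrame:
    """Mean relative abundance per taxon within each group (taxa x groups)."""
    props = relative_abundance(table)
    groups = meta.groups.loc[table.sample_ids]
    return props.data.groupby(groups).mean().T
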