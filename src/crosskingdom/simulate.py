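"""Synthetic two-group, two-kingdom count tables with planted ground truth.

The generative model is a Gaussian copula on log abundances: each sample's
latent vector is multivariate normal with a group-specific correlation
matrix, differential taxa receive a latent log-scale shift in their enriched
group, the vector is softmax-normalized to a composition, and counts are
drawn multinomially at a uniformly sampled depth.  This allows planting an
exact latent correlation matrix (a Dirichlet-multinomial cannot) and an
exact set of differential taxa, at the cost that realized compositional
fold-changes are attenuated relative to the planted latent effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from crosskingdom.table_io import AbundanceTable, SampleMetadata

LN2 = math.log(2.0)

#: Case-enriched genera used for the default planted panels.
BACTERIAL_PANEL = ("Akkermansia", "Clostridium_sensu_stricto_1", "UBA1819", "Veillonella")
FUNGAL_PANEL = ("Candida", "Chaetomium", "Neocosmospora", "Occultifur")

#: Control-enriched genera planted alongside the panels.  They mirror the
#: reported control-side signal and, carrying equal latent mass in the other
#: direction, cancel the compositional closure shift the case panel would
#: otherwise impose on every null taxon.
BACTERIAL_CONTROL = ("Dialister", "Fusicatenibacter", "Lachnospira", "Sutterella")
FUNGAL_CONTROL = ("Scedosporium", "Purpureocillium", "Penicillium", "Aureobasidium")


@dataclass(frozen=True)
class DiffTaxon:
    """A planted differentially abundant taxon."""

    taxon: str
    kingdom: str
    log2_fold_change: float
    enriched_group: str


@dataclass(frozen=True)
class ScenarioConfig:
    """Full description of a simulation scenario.

    Taxon order in the correlation matrices and the per-taxon vectors is
    bacterial taxa first, then fungal taxa.
    """

    n_group1: int
    n_group2: int
    group_labels: tuple[str, str]
    bact_taxa: tuple[str, ...]
    fungi_taxa: tuple[str, ...]
    depth_range: tuple[int, int]
    diff_taxa: tuple[DiffTaxon, ...]
    latent_corr_group1: np.ndarray
    latent_corr_group2: np.ndarray
    base_log_abundance: np.ndarray
    latent_sd: np.ndarray
    seed: int = 0
    edge_threshold: float = 0.4

    @property
    def all_taxa(self) -> tuple[str, ...]:
        return self.bact_taxa + self.fungi_taxa

    @property
    def n_taxa(self) -> int:
        return len(self.bact_taxa) + len(self.fungi_taxa)

    def validate(self) -> None:
        n = self.n_taxa
        if self.n_group1 < 3 or self.n_group2 < 3:
            raise ValueError("each group needs at least 3 samples for rank tests")
        lo, hi = self.depth_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid depth_range {self.depth_range}")
        if len(self.base_log_abundance) != n or len(self.latent_sd) != n:
            raise ValueError("per-taxon vectors must match the taxon count")
        if (np.asarray(self.latent_sd) <= 0).any():
            raise ValueError("latent_sd must be positive")
        taxa = set(self.all_taxa)
        if len(taxa) != n:
            raise ValueError("duplicate taxon ids across kingdoms")
        for dt in self.diff_taxa:
            if dt.taxon not in taxa:
                raise ValueError(f"diff taxon {dt.taxon!r} not in the taxon set")
            if not math.isfinite(dt.log2_fold_change):
                raise ValueError(f"non-finite fold-change for {dt.taxon!r}")
            if dt.enriched_group not in self.group_labels:
                raise ValueError(f"unknown enriched group {dt.enriched_group!r}")
        for name, corr in (("group1", self.latent_corr_group1),
                           ("group2", self.latent_corr_group2)):
            corr = np.asarray(corr)
            if corr.shape != (n, n):
                raise ValueError(f"{name} correlation matrix must be {n}x{n}")
            if not np.allclose(corr, corr.T, atol=1e-10):
                raise ValueError(f"{name} correlation matrix is not symmetric")
            if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
                raise ValueError(f"{name} correlation matrix diagonal is not 1")
            smallest = float(np.linalg.eigvalsh(corr)[0])
            if smallest < -1e-10:
                raise ValueError(
                    f"{name} correlation matrix is not positive semi-definite "
                    f"(smallest eigenvalue {smallest:.3e})"
                )


@dataclass(frozen=True)
class GroundTruth:
    """Planted truth recoverable by downstream stages.

    ``edges`` holds, per group label, the latent taxon pairs whose absolute
    correlation meets the scenario's edge threshold; ``connectedness`` is
    edges divided by the number of taxa incident to at least one edge.
    """

    diff_taxa: tuple[DiffTaxon, ...]
    edges: dict[str, list[tuple[str, str, float]]]
    connectedness: dict[str, float]


def _latent_edges(corr: np.ndarray, taxa: tuple[str, ...],
                  threshold: float) -> list[tuple[str, str, float]]:
    edges = []
    n = len(taxa)
    for i in range(n):
        for j in range(i + 1, n):
            if abs(corr[i, j]) >= threshold:
                edges.append((taxa[i], taxa[j], float(corr[i, j])))
    return edges


def ground_truth_from_config(config: ScenarioConfig) -> GroundTruth:
    edges: dict[str, list[tuple[str, str, float]]] = {}
    connectedness: dict[str, float] = {}
    for label, corr in zip(config.group_labels,
                           (config.latent_corr_group1, config.latent_corr_group2)):
        es = _latent_edges(np.asarray(corr), config.all_taxa, config.edge_threshold)
        edges[label] = es
        nodes = {t for a, b, _ in es for t in (a, b)}
        connectedness[label] = len(es) / len(nodes) if nodes else 0.0
    return GroundTruth(config.diff_taxa, edges, connectedness)


def simulate_tables(config: ScenarioConfig
                    ) -> tuple[AbundanceTable, AbundanceTable, SampleMetadata, GroundTruth]:
    """Draw count tables for both kingdoms plus metadata and ground truth.

    For each sample: latent ~ MVN(mu_group, diag(sd) @ corr_group @ diag(sd)),
    where mu_group adds ``log2FC * ln 2`` to each planted taxon in its
    enriched group; the composition is softmax(latent); counts are
    multinomial at a depth drawn uniformly from ``depth_range``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_taxa
    base = np.asarray(config.base_log_abundance, dtype=float)
    sd = np.asarray(config.latent_sd, dtype=float)
    taxa = config.all_taxa
    taxon_index = {t: i for i, t in enumerate(taxa)}

    mus = {}
    for label in config.group_labels:
        mu = base.copy()
        for dt in config.diff_taxa:
            if dt.enriched_group == label:
                mu[taxon_index[dt.taxon]] += dt.log2_fold_change * LN2
        mus[label] = mu

    covs = {
        config.group_labels[0]: (sd[:, None] * np.asarray(config.latent_corr_group1) * sd[None, :]),
        config.group_labels[1]: (sd[:, None] * np.asarray(config.latent_corr_group2) * sd[None, :]),
    }

    counts = np.zeros((config.n_group1 + config.n_group2, n), dtype=np.int64)
    sample_ids, labels = [], []
    row = 0
    lo, hi = config.depth_range
    for label, n_samples in zip(config.group_labels, (config.n_group1, config.n_group2)):
        latent = rng.multivariate_normal(mus[label], covs[label], size=n_samples,
                                         method="svd")
        for k in range(n_samples):
            z = latent[k] - latent[k].max()
            p = np.exp(z)
            p /= p.sum()
            depth = int(rng.integers(lo, hi + 1))
            counts[row] = rng.multinomial(depth, p)
            sample_ids.append(f"{label}_{k + 1:03d}")
            labels.append(label)
            row += 1

    frame = pd.DataFrame(counts, index=sample_ids, columns=list(taxa))
    nb = len(config.bact_taxa)
    bact = AbundanceTable(frame.iloc[:, :nb], "bacteria",
                          taxonomy=_default_taxonomy(config.bact_taxa, "Bacteria"))
    fungi = AbundanceTable(frame.iloc[:, nb:], "fungi",
                           taxonomy=_default_taxonomy(config.fungi_taxa, "Fungi"))
    meta = SampleMetadata(pd.DataFrame({"group": labels}, index=sample_ids))
    return bact, fungi, meta, ground_truth_from_config(config)


def _default_taxonomy(taxa: tuple[str, ...], kingdom_name: str) -> dict[str, str]:
    return {t: f"k__{kingdom_name}; p__; c__; o__; f__; g__{t}" for t in taxa}


def block_correlation(n_taxa: int, blocks: list[tuple[list[int], float]]) -> np.ndarray:
    """Identity correlation with equicorrelated blocks.

    Each block is (member indices, within-block correlation r).  Blocks must
    be disjoint; equicorrelation with r in (-1/(m-1), 1] keeps each block
    positive semi-definite, and disjointness keeps the whole matrix PSD.
    """
    corr = np.eye(n_taxa)
    seen: set[int] = set()
    for members, r in blocks:
        if seen.intersection(members):
            raise ValueError("correlation blocks must be disjoint")
        seen.update(members)
        for a in members:
            for b in members:
                if a != b:
                    corr[a, b] = r
    return corr


def default_scenario(seed: int = 0,
                     n_group1: int = 24,
                     n_group2: int = 16,
                     effect_log2fc: float = 3.0,
                     depth_range: tuple[int, int] = (2_500_000, 3_000_000)) -> ScenarioConfig:
    """Study-shaped default: 24 cases (CDE) vs 16 controls (HC), ~100
    bacterial and ~60 fungal taxa, the four-genus panels planted as
    case-enriched, and denser cross-kingdom latent correlation in the
    control group.

    Design notes.  An LDA-effect threshold of 2 on the per-million scale
    corresponds to a ~100 counts-per-million group difference, so null taxa
    are kept "CPM-quiet": filler taxa get a latent standard deviation capped
    at 150 CPM-equivalents and the sequencing depth is high enough that
    multinomial noise stays below the threshold.  The planted panels are
    rare (so compositional closure barely perturbs the null taxa) and the
    correlated blocks pair non-panel bacterial with fungal taxa so planted
    differential abundance and planted correlation stay separable.
    """
    n_bact, n_fungi = 100, 60
    n_block = 32            # correlated (network-bearing) taxa per kingdom
    bact_named = BACTERIAL_PANEL + BACTERIAL_CONTROL
    fungi_named = FUNGAL_PANEL + FUNGAL_CONTROL
    bact_taxa = bact_named + tuple(f"Bact_{i:03d}" for i in range(n_bact - 8))
    fungi_taxa = fungi_named + tuple(f"Fungi_{i:03d}" for i in range(n_fungi - 8))
    n = n_bact + n_fungi

    planted_idx = list(range(8)) + list(range(n_bact, n_bact + 8))
    block_idx = (list(range(8, 8 + n_block))
                 + list(range(n_bact + 8, n_bact + 8 + n_block)))
    filler_idx = sorted(set(range(n)) - set(planted_idx) - set(block_idx))

    rng = np.random.default_rng(seed)
    base = rng.normal(0.0, 0.3, size=n)
    base[planted_idx] = -4.2
    base[block_idx] = -5.0

    approx_cpm = np.exp(base) / np.exp(base).sum() * 1e6
    sd = np.full(n, 0.35)
    sd[block_idx] = 0.6
    sd[filler_idx] = np.minimum(0.05, 60.0 / approx_cpm[filler_idx])

    diff = tuple(
        [DiffTaxon(t, "bacteria", effect_log2fc, "CDE") for t in BACTERIAL_PANEL]
        + [DiffTaxon(t, "bacteria", effect_log2fc, "HC") for t in BACTERIAL_CONTROL]
        + [DiffTaxon(t, "fungi", effect_log2fc, "CDE") for t in FUNGAL_PANEL]
        + [DiffTaxon(t, "fungi", effect_log2fc, "HC") for t in FUNGAL_CONTROL]
    )

    def mixed_blocks(n_blocks: int, r: float, half: int = 4):
        blocks = []
        for b in range(n_blocks):
            bact_part = [8 + 4 * b + j for j in range(half)]
            fungi_part = [n_bact + 8 + 4 * b + j for j in range(half)]
            blocks.append((bact_part + fungi_part, r))
        return blocks

    hc_corr = block_correlation(n, mixed_blocks(8, 0.75))
    # smaller case blocks: fewer edges AND lower edges-per-node ratio
    cde_corr = block_correlation(n, mixed_blocks(2, 0.75, half=3))

    return ScenarioConfig(
        n_group1=n_group1,
        n_group2=n_group2,
        group_labels=("CDE", "HC"),
        bact_taxa=bact_taxa,
        fungi_taxa=fungi_taxa,
        depth_range=depth_range,
        diff_taxa=diff,
        latent_corr_group1=cde_corr,
        latent_corr_group2=hc_corr,
        base_log_abundance=base,
        latent_sd=sd,
        seed=seed,
    )


def null_scenario(seed: int = 0, n_group1: int = 24, n_group2: int = 16,
                  n_bact: int = 60, n_fungi: int = 40,
                  depth_range: tuple[int, int] = (10_000, 20_000)) -> ScenarioConfig:
    """Exchangeable groups: zero effects, identical (identity) correlation."""
    bact_taxa = tuple(f"Bact_{i:03d}" for i in range(n_bact))
    fungi_taxa = tuple(f"Fungi_{i:03d}" for i in range(n_fungi))
    n = n_bact + n_fungi
    rng = np.random.default_rng(seed)
    return ScenarioConfig(
        n_group1=n_group1,
        n_group2=n_group2,
        group_labels=("CDE", "HC"),
        bact_taxa=bact_taxa,
        fungi_taxa=fungi_taxa,
        depth_range=depth_range,
        diff_taxa=(),
        latent_corr_group1=np.eye(n),
        latent_corr_group2=np.eye(n),
        base_log_abundance=rng.normal(0.0, 1.0, size=n),
        latent_sd=np.full(n, 1.0),
        seed=seed,
    )


def network_scenario(seed: int = 0, n_group1: int = 30, n_group2: int = 30,
                     n_bact: int = 20, n_fungi: int = 20, r: float = 0.75,
                     depth_range: tuple[int, int] = (50_000, 100_000)
                     ) -> ScenarioConfig:
    """Dense-vs-sparse latent correlation with no differential abundance.

    Group 1 ("dense") carries cross-kingdom equicorrelated blocks covering
    almost every taxon; group 2 ("sparse") keeps a single small block, giving
    a planted mean-degree ratio well above 4.
    """
    bact_taxa = tuple(f"Bact_{i:03d}" for i in range(n_bact))
    fungi_taxa = tuple(f"Fungi_{i:03d}" for i in range(n_fungi))
    n = n_bact + n_fungi

    def blocks(n_blocks: int):
        out = []
        for b in range(n_blocks):
            bact_part = [4 * b + j for j in range(4)]
            fungi_part = [n_bact + 4 * b + j for j in range(4)]
            out.append((bact_part + fungi_part, r))
        return out

    dense = block_correlation(n, blocks(min(n_bact, n_fungi) // 4))
    sparse = block_correlation(n, blocks(1))
    return ScenarioConfig(
        n_group1=n_group1,
        n_group2=n_group2,
        group_labels=("dense", "sparse"),
        bact_taxa=bact_taxa,
        fungi_taxa=fungi_taxa,
        depth_range=depth_range,
        diff_taxa=(),
        latent_corr_group1=dense,
        latent_corr_group2=sparse,
        base_log_abundance=np.zeros(n),
        latent_sd=np.full(n, 0.8),
        seed=seed,
    )
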