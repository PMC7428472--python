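"""Differential-abundance screen: per-taxon Kruskal-Wallis filtering followed
by a bootstrapped linear-discriminant effect size.

Features pass at ``p < alpha`` and ``|LDA score| > threshold`` (both strict).
The sign convention is positive = enriched in the reference group (the
control/HC level), negative = enriched in the case group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from crosskingdom.table_io import AbundanceTable, SampleMetadata

logger = logging.getLogger(__name__)

TARGET_SUM = 1_000_000.0


def ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact (full null distribution) for small tie-free samples, where it is
    the two-group Kruskal-Wallis equivalent; normal approximation with
    midrank tie correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (no_ties and len(pooled) <= 40) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                    method=method).pvalue)


@dataclass(frozen=True)
class DifferentialFeature:
    taxon: str
    rank: str
    kingdom: str
    mean_reference: float       # mean normalized abundance in the reference group
    mean_case: float
    kw_p: float
    lda_score: float            # log10 scale, signed (+ = reference-enriched)
    enriched_group: str


def normalize_for_lefse(table: AbundanceTable) -> AbundanceTable:
    """Scale every sample to a total of one million, the convention of the
    reference LDA-effect-size implementation."""
    totals = table.data.sum(axis=1)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-sum samples cannot be normalized: {list(zero.index)}")
    from dataclasses import replace
    return replace(table, data=table.data.div(totals, axis=0) * TARGET_SUM)


def kw_screen(table: AbundanceTable, groups: pd.Series, alpha: float = 0.05
              ) -> tuple[pd.Series, list[str]]:
    """Per-taxon two-sided Kruskal-Wallis test; returns (p-values, retained
    taxa with p < alpha).  Constant taxa get p = 1 and are never retained."""
    groups = groups.loc[table.sample_ids]
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"expected two groups, found {levels}")
    if min((groups == lv).sum() for lv in levels) < 3:
        raise ValueError("each group needs at least 3 samples")
    masks = [groups == lv for lv in levels]
    p_values = {}
    for taxon in table.taxon_ids:
        col = table.data[taxon].to_numpy(dtype=float)
        if np.ptp(col) == 0:
            p_values[taxon] = 1.0
            continue
        p_values[taxon] = ranksum_p(col[masks[0]], col[masks[1]])
    pvals = pd.Series(p_values)
    retained = [t for t in table.taxon_ids if pvals[t] < alpha]
    return pvals, retained


def _fit_lda_effect(x: np.ndarray, y: np.ndarray, ridge: float = 1e-6) -> np.ndarray:
    """Per-feature effect from a two-class linear discriminant.

    Returns the average of (a) each feature's contribution along the
    discriminant axis and (b) its raw class-mean difference, oriented as
    class1 minus class0.
    """
    m0 = x[y == 0].mean(axis=0)
    m1 = x[y == 1].mean(axis=0)
    raw_diff = m1 - m0
    centered = np.concatenate([x[y == 0] - m0, x[y == 1] - m1])
    cov = centered.T @ centered / max(len(x) - 2, 1)
    cov = cov + np.eye(cov.shape[0]) * (ridge * max(np.trace(cov), 1.0))
    w = np.linalg.solve(cov, raw_diff)
    norm = np.sqrt(w @ w)
    if norm == 0:
        return raw_diff / 2.0
    w_unit = w / norm
    proj_diff = w_unit @ raw_diff   # class-mean separation along the axis
    contribution = w_unit * proj_diff
    return (contribution + raw_diff) / 2.0


def lda_effect_size(table: AbundanceTable, groups: pd.Series,
                    reference_group: str,
                    n_boot: int = 30, boot_fraction: float = 2.0 / 3.0,
                    seed: int = 0) -> pd.Series:
    """Bootstrapped signed LDA score per taxon.

    Each round subsamples ``boot_fraction`` of every class, fits a
    ridge-regularized two-class discriminant on the (already screened)
    features, and records per-feature effects; the score is
    ``log10(1 + |mean effect|)`` signed positive when the reference group's
    mean is higher.
    """
    groups = groups.loc[table.sample_ids]
    levels = sorted(groups.unique())
    if reference_group not in levels:
        raise ValueError(f"reference group {reference_group!r} not in {levels}")
    x = table.counts()
    # y = 1 encodes the reference group so effects are reference minus case
    y = (groups == reference_group).to_numpy().astype(int)
    rng = np.random.default_rng(seed)
    idx0, idx1 = np.nonzero(y == 0)[0], np.nonzero(y == 1)[0]
    take0, take1 = int(round(len(idx0) * boot_fraction)), int(round(len(idx1) * boot_fraction))
    if min(take0, take1) < 3:
        logger.warning("boot_fraction %.2f leaves a class below 3 samples; "
                       "using full classes per round", boot_fraction)
        take0, take1 = max(take0, min(3, len(idx0))), max(take1, min(3, len(idx1)))
    effects = np.zeros((n_boot, x.shape[1]))
    for b in range(n_boot):
        sub = np.concatenate([rng.choice(idx0, size=take0, replace=False),
                              rng.choice(idx1, size=take1, replace=False)])
        effects[b] = _fit_lda_effect(x[sub], y[sub])
    mean_effect = effects.mean(axis=0)
    scores = np.sign(mean_effect) * np.log10(1.0 + np.abs(mean_effect))
    return pd.Series(scores, index=table.taxon_ids)


def lefse_report(table: AbundanceTable, kw_p: pd.Series, scores: pd.Series,
                 reference_group: str, case_group: str, groups: pd.Series,
                 lda_threshold: float = 2.0, alpha: float = 0.05,
                 rank: str = "genus") -> list[DifferentialFeature]:
    """Filter to (p < alpha, |score| > threshold) and sort by |score|
    descending.  A score of exactly the threshold is excluded."""
    groups = groups.loc[table.sample_ids]
    ref_mask = (groups == reference_group).to_numpy()
    features = []
    for taxon in scores.index:
        p = float(kw_p[taxon])
        s = float(scores[taxon])
        if not (p < alpha and abs(s) > lda_threshold):
            continue
        col = table.data[taxon].to_numpy(dtype=float)
        features.append(DifferentialFeature(
            taxon=taxon,
            rank=rank,
            kingdom=table.kingdom,
            mean_reference=float(col[ref_mask].mean()),
            mean_case=float(col[~ref_mask].mean()),
            kw_p=p,
            lda_score=s,
            enriched_group=reference_group if s > 0 else case_group,
        ))
    features.sort(key=lambda f: abs(f.lda_score), reverse=True)
    return features


def run_lefse(table: AbundanceTable, meta: SampleMetadata, reference_group: str,
              alpha: float = 0.05, lda_threshold: float = 2.0,
              n_boot: int = 30, boot_fraction: float = 2.0 / 3.0,
              seed: int = 0, rank: str = "genus",
              subclass=None) -> list[DifferentialFeature]:
    """Full screen on one table: normalize, KW filter, LDA score, report.

    ``subclass`` is reserved for a future within-class Wilcoxon stage (the
    study design has no subclass structure); passing a value raises.
    """
    if subclass is not None:
        raise NotImplementedError("subclass stage not implemented")
    meta.validate_two_groups()
    groups = meta.groups
    case_group = next(lv for lv in meta.group_levels() if lv != reference_group)
    norm = normalize_for_lefse(table)
    kw_p, retained = kw_screen(norm, groups, alpha=alpha)
    if not retained:
        return []
    scores = lda_effect_size(norm.select_taxa(retained), groups, reference_group,
                             n_boot=n_boot, boot_fraction=boot_fraction, seed=seed)
    return lefse_report(norm, kw_p, scores, reference_group, case_group, groups,
                        lda_threshold=lda_threshold, alpha=alpha, rank=rank)


def run_lefse_multirank(table: AbundanceTable, meta: SampleMetadata,
                        reference_group: str,
                        ranks: tuple[str, ...] = ("phylum", "family", "genus"),
                        **kwargs) -> list[DifferentialFeature]:
    """Screen the table collapsed at each taxonomic rank and concatenate the
    reports; per-rank provenance is retained in each feature's ``rank``."""
    features: list[DifferentialFeature] = []
    for rank in ranks:
        collapsed = table.collapse_rank(rank)
        features.extend(run_lefse(collapsed, meta, reference_group,
                                  rank=rank, **kwargs))
    features.sort(key=lambda f: abs(f.lda_score), reverse=True)
    return features


REPORT_COLUMNS = ("taxon", "rank", "kingdom", "enriched_group", "KW_p", "LDA_score")


def report_frame(features: list[DifferentialFeature]) -> pd.DataFrame:
    rows = [{
        "taxon": f.taxon, "rank": f.rank, "kingdom": f.kingdom,
        "enriched_group": f.enriched_group, "KW_p": f.kw_p, "LDA_score": f.lda_score,
    } for f in features]
    return pd.DataFrame(rows, columns=list(REPORT_COLUMNS))
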