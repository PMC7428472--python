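"""Genus-panel logistic-regression classifier with ROC AUC and bootstrap CI.

The primary output is the apparent (resubstitution) AUC of a multivariable
logistic regression on the panel genera's relative abundances, matching how
single fitted-model ROC curves are usually reported at this sample size; a
stratified cross-validated AUC is also available and is the honest estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from crosskingdom.table_io import AbundanceTable, SampleMetadata, relative_abundance

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenusPanel:
    name: str
    genera: tuple[tuple[str, str], ...]   # (genus, kingdom)

    def __post_init__(self) -> None:
        names = [g for g, _ in self.genera]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate genera in panel {self.name!r}")


_BACT4 = tuple((g, "bacteria") for g in
               ("Akkermansia", "Clostridium_sensu_stricto_1", "UBA1819", "Veillonella"))
_FUNGI4 = tuple((g, "fungi") for g in
                ("Candida", "Chaetomium", "Neocosmospora", "Occultifur"))

PANEL_PRESETS: dict[str, GenusPanel] = {
    "bacterial4": GenusPanel("bacterial4", _BACT4),
    "fungal4": GenusPanel("fungal4", _FUNGI4),
    "combined8": GenusPanel("combined8", _BACT4 + _FUNGI4),
}


@dataclass(frozen=True)
class PanelClassifierResult:
    panel: GenusPanel
    coefficients: pd.Series         # per genus, plus "intercept"
    scores: pd.Series               # per-sample predicted probability of case
    auc: float
    ci_low: float
    ci_high: float
    scheme: str                     # "apparent" | "cross-validated"
    sample_ids: tuple[str, ...]


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the Mann-Whitney rank formulation, U / (n1 n0), with midrank
    tie handling.  ``labels`` is 1 for cases, 0 for controls."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def panel_features(bact: AbundanceTable, fungi: AbundanceTable,
                   panel: GenusPanel) -> pd.DataFrame:
    """Relative abundances of the panel genera, samples x genera."""
    tables = {"bacteria": relative_abundance(bact), "fungi": relative_abundance(fungi)}
    cols = {}
    for genus, kingdom in panel.genera:
        table = tables[kingdom]
        if genus not in table.data.columns:
            raise KeyError(f"panel genus {genus!r} absent from the {kingdom} table")
        cols[genus] = table.data[genus]
    return pd.DataFrame(cols)


class _ScaledLogit:
    """Logistic regression fit on standardized features (relative abundances
    are ~1e-4 scale, which stalls lbfgs); coefficients are reported on the
    original scale."""

    def __init__(self):
        self.model: LogisticRegression | None = None
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, x: np.ndarray, y: np.ndarray) -> "_ScaledLogit":
        self.mean_ = x.mean(axis=0)
        scale = x.std(axis=0)
        scale[scale == 0] = 1.0
        self.scale_ = scale
        z = (x - self.mean_) / self.scale_
        # C=inf is an unpenalized maximum-likelihood fit; under perfect
        # separation it diverges and we fall back to a light L2 penalty.
        model = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000)
        try:
            model.fit(z, y)
            if not np.isfinite(model.coef_).all() or np.abs(model.coef_).max() > 1e8:
                raise ValueError("diverging coefficients")
        except Exception:
            logger.warning("unpenalized fit unstable (likely separation); "
                           "falling back to a light L2 penalty")
            model = LogisticRegression(C=1e4, solver="lbfgs", max_iter=5000)
            model.fit(z, y)
        self.model = model
        return self

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.model.predict_proba((x - self.mean_) / self.scale_)

    @property
    def coef_(self) -> np.ndarray:
        return self.model.coef_ / self.scale_

    @property
    def intercept_(self) -> np.ndarray:
        return (self.model.intercept_
                - (self.model.coef_ * self.mean_ / self.scale_).sum(axis=1))


def _fit_logistic(x: np.ndarray, y: np.ndarray) -> _ScaledLogit:
    return _ScaledLogit().fit(x, y)


def fit_panel(bact: AbundanceTable, fungi: AbundanceTable, meta: SampleMetadata,
              panel: GenusPanel, case_group: str | None = None,
              n_bootstrap: int = 2000, seed: int = 0,
              cv_folds: int = 0, cv_repeats: int = 5) -> PanelClassifierResult:
    """Fit the panel logistic regression and score discrimination.

    AUC uses the rank (Mann-Whitney) formulation; the 95% CI is a stratified
    bootstrap over samples (resampling within each class, refitting, and
    rescoring).  ``cv_folds > 1`` switches to stratified cross-validated
    out-of-fold scores.
    """
    meta.validate_two_groups()
    features = panel_features(bact, fungi, panel)
    sample_ids = list(features.index)
    groups = meta.groups.loc[sample_ids]
    levels = sorted(groups.unique())
    if case_group is None:
        case_group = levels[0]
    y = (groups == case_group).to_numpy().astype(int)
    x = features.to_numpy(dtype=float)

    if cv_folds and cv_folds > 1:
        # out-of-fold scores averaged over repeated splits: single-split CV
        # AUC at this sample size carries substantial fold-assignment noise
        scores = np.zeros(len(y))
        for rep in range(max(cv_repeats, 1)):
            skf = StratifiedKFold(n_splits=cv_folds, shuffle=True,
                                  random_state=seed + rep)
            for train, test in skf.split(x, y):
                fold = _fit_logistic(x[train], y[train])
                scores[test] += fold.predict_proba(x[test])[:, 1]
        scores /= max(cv_repeats, 1)
        scheme = "cross-validated"
    else:
        scheme = "apparent"

    model = _fit_logistic(x, y)
    if scheme == "apparent":
        scores = model.predict_proba(x)[:, 1]
    auc = rank_auc(scores, y)

    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        idx1, idx0 = np.nonzero(y == 1)[0], np.nonzero(y == 0)[0]
        boot_aucs = []
        for b in range(n_bootstrap):
            take = np.concatenate([rng.choice(idx1, size=len(idx1), replace=True),
                                   rng.choice(idx0, size=len(idx0), replace=True)])
            if scheme == "apparent":
                # refit on the resample and rescore, mirroring the estimator
                mb = _fit_logistic(x[take], y[take])
                boot_aucs.append(rank_auc(mb.predict_proba(x[take])[:, 1], y[take]))
            else:
                # out-of-bag: train on the resample, score the held-out
                # samples; captures the model-refit noise that dominates the
                # cross-validated estimator's variance at this sample size
                oob = np.setdiff1d(np.arange(len(y)), np.unique(take))
                if len(oob) < 4 or len(np.unique(y[oob])) < 2:
                    continue
                mb = _fit_logistic(x[take], y[take])
                boot_aucs.append(rank_auc(mb.predict_proba(x[oob])[:, 1], y[oob]))
        ci_low, ci_high = np.percentile(boot_aucs, [2.5, 97.5])
        ci_low, ci_high = min(ci_low, auc), max(ci_high, auc)
    else:
        ci_low = ci_high = auc

    coeffs = pd.Series(model.coef_[0], index=features.columns)
    coeffs["intercept"] = float(model.intercept_[0])
    return PanelClassifierResult(panel, coeffs, pd.Series(scores, index=sample_ids),
                                 float(auc), float(ci_low), float(ci_high),
                                 scheme, tuple(sample_ids))


def compare_panels(results: list[PanelClassifierResult]) -> pd.DataFrame:
    """AUC + CI per panel, ordered as given, flagging whether the last
    (combined) panel is at least as good as every other."""
    sample_sets = {r.sample_ids for r in results}
    if len(sample_sets) != 1:
        raise ValueError("panels were fitted on different sample sets")
    rows = pd.DataFrame([{
        "panel": r.panel.name, "auc": r.auc,
        "ci_low": r.ci_low, "ci_high": r.ci_high, "scheme": r.scheme,
    } for r in results]).set_index("panel")
    combined = results[-1]
    rows["combined_at_least"] = [combined.auc >= r.auc for r in results]
    return rows


def roc_points(result: PanelClassifierResult, meta: SampleMetadata,
               case_group: str) -> pd.DataFrame:
    """ROC curve points (FPR, TPR, threshold) from the per-sample scores."""
    y = (meta.groups.loc[list(result.sample_ids)] == case_group).to_numpy().astype(int)
    s = result.scores.to_numpy()
    order = np.argsort(-s)
    thresholds = np.concatenate([[np.inf], s[order]])
    tpr = [0.0]
    fpr = [0.0]
    p, n = y.sum(), (1 - y).sum()
    tp = fp = 0
    for i in order:
        if y[i]:
            tp += 1
        else:
            fp += 1
        tpr.append(tp / p)
        fpr.append(fp / n)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
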