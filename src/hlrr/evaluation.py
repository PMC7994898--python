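"""Experimental protocol: metrics, nested CV, imputation baselines and
rank-based comparison statistics.

Binary tasks are scored with seven metrics (ACC, SEN, SPE, BAC, PPV, NPV
and rank-based AUC).  Model selection follows a nested stratified
cross-validation: an outer 10-fold split for testing and an inner 10-fold
grid search on each outer training set, selecting by inner accuracy.
Zero- and KNN-imputation single-SVM baselines provide the comparison
points, and the Friedman chi-square with the Nemenyi post-hoc critical
difference compares methods across datasets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .datamodel import FeatureScaler, MultimodalDataset, partition_groups
from .solver import HLRRParams, hlrr_solve_groups
from .classifier import fit_ensemble, predict as ensemble_predict

__all__ = [
    "ConfusionSummary", "CVPlan", "confusion_summary", "compute_metrics",
    "nested_cv", "impute_baselines", "friedman_statistic", "nemenyi_cd",
    "HLRRMethod", "ImputationSVMMethod", "default_param_grid",
]

METRIC_NAMES = ("ACC", "SEN", "SPE", "BAC", "PPV", "NPV", "AUC")


@dataclass
class ConfusionSummary:
    """Binary confusion counts plus per-subject ranking scores."""

    TP: int
    FP: int
    TN: int
    FN: int
    y_true_pm: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    scores: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def confusion_summary(y_true_pm, y_pred_pm, scores=None) -> ConfusionSummary:
    """Count a +/-1-coded prediction against +/-1-coded truth."""
    yt = np.asarray(y_true_pm, int)
    yp = np.asarray(y_pred_pm, int)
    if yt.size == 0:
        raise ValueError("empty input")
    sc = np.asarray(scores, float) if scores is not None else np.zeros(yt.size)
    return ConfusionSummary(
        TP=int(((yt == 1) & (yp == 1)).sum()),
        FP=int(((yt == -1) & (yp == 1)).sum()),
        TN=int(((yt == -1) & (yp == -1)).sum()),
        FN=int(((yt == 1) & (yp == -1)).sum()),
        y_true_pm=yt, scores=sc)


def _auc_rank(y_true_pm: np.ndarray, scores: np.ndarray) -> float:
    """P(random positive outranks random negative), ties counting 1/2."""
    pos = y_true_pm == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    r = rankdata(scores)
    u = r[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def compute_metrics(cs: ConfusionSummary) -> dict[str, float]:
    """Seven named metrics; SEN/SPE/PPV/NPV are NaN when undefined."""
    if cs.n == 0:
        raise ValueError("empty confusion summary")

    def ratio(a, b):
        return a / b if b > 0 else float("nan")

    sen = ratio(cs.TP, cs.TP + cs.FN)
    spe = ratio(cs.TN, cs.TN + cs.FP)
    return {
        "ACC": (cs.TP + cs.TN) / cs.n,
        "SEN": sen,
        "SPE": spe,
        "BAC": (sen + spe) / 2.0,
        "PPV": ratio(cs.TP, cs.TP + cs.FP),
        "NPV": ratio(cs.TN, cs.TN + cs.FN),
        "AUC": _auc_rank(cs.y_true_pm, cs.scores),
    }


# ---------------------------------------------------------------- methods

class HLRRMethod:
    """Full pipeline: scale -> partition -> representation -> ensemble."""

    def __init__(self, positive_label, negative_label,
                 params: HLRRParams | None = None,
                 graph_cfg: dict | None = None,
                 svm_cfg: dict | None = None,
                 standardize: bool = True,
                 mode: str = "transductive"):
        self.positive_label = positive_label
        self.negative_label = negative_label
        self.params = params or HLRRParams()
        self.graph_cfg = graph_cfg or {}
        self.svm_cfg = svm_cfg or {}
        self.standardize = standardize
        self.mode = mode
        self.model_ = None
        self.scaler_ = None

    def set_params(self, **hp) -> "HLRRMethod":
        from dataclasses import replace
        self.params = replace(self.params, **hp)
        return self

    def fit(self, ds: MultimodalDataset) -> "HLRRMethod":
        if self.standardize:
            self.scaler_ = FeatureScaler().fit(ds)
            ds = self.scaler_.transform(ds)
        groups = partition_groups(ds)
        pairs = hlrr_solve_groups(groups, self.params, self.graph_cfg)
        solutions = [sol for _, sol in pairs]
        self.model_ = fit_ensemble(groups, solutions, self.positive_label,
                                   self.negative_label, self.svm_cfg,
                                   self.params, self.graph_cfg, self.mode)
        return self

    def predict(self, ds: MultimodalDataset):
        if self.scaler_ is not None:
            ds = self.scaler_.transform(ds)
        labels, scores, _ = ensemble_predict(self.model_, ds)
        return labels, scores


class ImputationSVMMethod:
    """Impute the block-wise missing table, then one linear SVM."""

    def __init__(self, positive_label, negative_label, kind: str = "zero",
                 k1: int = 5, svm_cfg: dict | None = None,
                 standardize: bool = True):
        if kind not in ("zero", "knn"):
            raise ValueError("kind must be 'zero' or 'knn'")
        self.positive_label = positive_label
        self.negative_label = negative_label
        self.kind = kind
        self.k1 = k1
        self.svm_cfg = svm_cfg or {}
        self.standardize = standardize
        self.svm_ = None
        self.scaler_ = None

    def set_params(self, **hp) -> "ImputationSVMMethod":
        if "C" in hp:
            self.svm_cfg["C"] = hp["C"]
        if "k1" in hp:
            self.k1 = hp["k1"]
        return self

    def _table(self, ds: MultimodalDataset) -> np.ndarray:
        if self.scaler_ is not None:
            ds = self.scaler_.transform(ds)
        return impute_baselines(ds, self.kind, self.k1)

    def fit(self, ds: MultimodalDataset) -> "ImputationSVMMethod":
        if self.standardize:
            self.scaler_ = FeatureScaler().fit(ds)
        X = self._table(ds)
        y = np.where(np.asarray(ds.labels) == self.positive_label, 1, -1)
        cfg = {"kernel": "linear", "C": 1.0}
        cfg.update(self.svm_cfg)
        self.svm_ = SVC(**cfg).fit(X, y)
        return self

    def predict(self, ds: MultimodalDataset):
        X = self._table(ds)
        scores = self.svm_.decision_function(X)
        labels = np.where(scores >= 0, self.positive_label,
                          self.negative_label)
        return labels, scores


# ---------------------------------------------------------------- nested CV

def default_param_grid(full: bool = False) -> dict[str, list[float]]:
    """Log grid over the three penalty weights.

    The full grid spans 10^-7..10^7 in decade steps per parameter; the
    default is a 5-point logarithmic sub-grid per parameter.
    """
    if full:
        pts = [10.0 ** e for e in range(-7, 8)]
    else:
        pts = [10.0 ** e for e in (-6, -3, 0, 3, 6)]
    return {"lam": pts, "beta": pts, "gamma": pts}


def _grid_combos(grid: dict[str, list]) -> list[dict]:
    from itertools import product
    keys = sorted(grid)
    return [dict(zip(keys, vals)) for vals in product(*(grid[k] for k in keys))]


@dataclass
class CVPlan:
    """Nested stratified cross-validation layout."""

    outer_folds: int = 10
    inner_folds: int = 10
    param_grid: dict[str, list] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be >= 2")


def nested_cv(ds: MultimodalDataset, plan: CVPlan, method_factory,
              positive_label) -> dict:
    """Outer stratified K-fold with an inner grid search per training set.

    ``method_factory()`` returns a fresh method exposing
    ``set_params(**hp)``, ``fit(ds)`` and ``predict(ds) -> (labels,
    scores)``.  The inner loop selects the grid point with the best inner
    accuracy (first-best tie break in grid order); with an empty or
    singleton grid the inner loop is skipped.  Predictions are pooled over
    the outer test folds before computing the seven metrics.

    Returns a dict with the pooled ``metrics``, per-fold accuracies,
    selected parameters per fold and the fold assignment log.
    """
    if ds.labels is None:
        raise ValueError("nested_cv needs labels")
    y = np.asarray(ds.labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    outer = StratifiedKFold(n_splits=plan.outer_folds, shuffle=True,
                            random_state=plan.seed)
    combos = _grid_combos(plan.param_grid)
    y_true_pm, y_pred_pm, scores_all = [], [], []
    fold_acc, fold_params, fold_log = [], [], []
    order = np.arange(ds.n_subjects)
    for fold, (tr, te) in enumerate(outer.split(order[:, None], y)):
        ds_tr, ds_te = ds.subset(tr), ds.subset(te)
        best = {}
        if len(combos) > 1:
            inner = StratifiedKFold(n_splits=plan.inner_folds, shuffle=True,
                                    random_state=plan.seed + 1)
            best_acc = -np.inf
            y_tr = np.asarray(ds_tr.labels)
            for combo in combos:
                accs = []
                for itr, ite in inner.split(np.arange(len(tr))[:, None], y_tr):
                    m = method_factory().set_params(**combo)
                    m.fit(ds_tr.subset(itr))
                    lab, _ = m.predict(ds_tr.subset(ite))
                    accs.append(float(np.mean(lab == y_tr[ite])))
                acc = float(np.mean(accs))
                if acc > best_acc:
                    best_acc, best = acc, combo
        elif combos:
            best = combos[0]
        method = method_factory()
        if best:
            method.set_params(**best)
        method.fit(ds_tr)
        lab, sc = method.predict(ds_te)
        yt = np.where(np.asarray(ds_te.labels) == positive_label, 1, -1)
        yp = np.where(np.asarray(lab) == positive_label, 1, -1)
        y_true_pm.append(yt)
        y_pred_pm.append(yp)
        scores_all.append(np.asarray(sc, float))
        fold_acc.append(float(np.mean(yt == yp)))
        fold_params.append(best)
        fold_log.append({"fold": fold, "test_idx": te.tolist()})
    cs = confusion_summary(np.concatenate(y_true_pm),
                           np.concatenate(y_pred_pm),
                           np.concatenate(scores_all))
    return {"metrics": compute_metrics(cs), "fold_acc": fold_acc,
            "fold_params": fold_params, "folds": fold_log,
            "confusion": cs}


# ---------------------------------------------------------------- baselines

def impute_baselines(ds: MultimodalDataset, method: str = "zero",
                     k1: int = 5) -> np.ndarray:
    """Complete the block-wise missing table.

    ``zero`` fills absent blocks with zeros.  ``knn`` fills a subject's
    absent block with the mean block of its k1 nearest subjects — distance
    measured on the jointly observed features of each pair — among subjects
    that observe the block; if no subject observes it, zeros are used with
    a warning.
    """
    n = ds.n_subjects
    blocks = [ds.features[m] for m in ds.modalities]
    filled = [b.copy() for b in blocks]
    if method == "zero":
        for j, b in enumerate(filled):
            b[~ds.availability[:, j]] = 0.0
        return np.concatenate(filled, axis=1)
    if method != "knn":
        raise ValueError("method must be 'zero' or 'knn'")
    av = ds.availability
    for j, m in enumerate(ds.modalities):
        donors = np.flatnonzero(av[:, j])
        for i in np.flatnonzero(~av[:, j]):
            shared = [k for k in range(len(ds.modalities))
                      if k != j and av[i, k]]
            cand = donors[av[donors][:, shared].any(axis=1)] if shared else \
                np.empty(0, int)
            # distance on jointly observed blocks
            dists = []
            for d in cand:
                common = [k for k in shared if av[d, k]]
                if not common:
                    continue
                diff = np.concatenate([blocks[k][i] - blocks[k][d]
                                       for k in common])
                dists.append((float(np.linalg.norm(diff) /
                                    np.sqrt(diff.size)), d))
            if not dists:
                warnings.warn(f"no donor observes block {m!r}; zero fill")
                filled[j][i] = 0.0
                continue
            dists.sort(key=lambda t: t[0])
            nn = [d for _, d in dists[:k1]]
            filled[j][i] = blocks[j][nn].mean(axis=0)
    return np.concatenate(filled, axis=1)


# ---------------------------------------------------- comparison statistics

def friedman_statistic(rank_table: np.ndarray) -> float:
    """Friedman chi-square from a (methods x datasets) rank table.

    chi2_F = 12 N / (k (k+1)) * sum_j (Rbar_j - (k+1)/2)^2 with k methods
    ranked 1..k (average ranks for ties) on each of N datasets.
    """
    R = np.asarray(rank_table, dtype=float)
    if R.ndim != 2 or R.shape[0] < 2 or R.shape[1] < 2:
        raise ValueError("need a k x N rank table with k, N >= 2")
    k, N = R.shape
    mean_ranks = R.mean(axis=1)
    return float(12.0 * N / (k * (k + 1)) *
                 np.sum((mean_ranks - (k + 1) / 2.0) ** 2))


def rank_methods(score_table: np.ndarray, higher_is_better: bool = True
                 ) -> np.ndarray:
    """Per-dataset ranks (1 = best) from a (methods x datasets) score table,
    with average ranks on ties."""
    S = np.asarray(score_table, dtype=float)
    sign = -1.0 if higher_is_better else 1.0
    return np.column_stack([rankdata(sign * S[:, j]) for j in range(S.shape[1])])


# Demsar (2006) critical values of the Nemenyi test, q_alpha = q_(alpha,k,inf)/sqrt(2)
_NEMENYI_Q = {
    0.05: [1.960, 2.343, 2.569, 2.728, 2.850, 2.949, 3.031, 3.102, 3.164,
           3.219, 3.268, 3.313, 3.354, 3.391, 3.426, 3.458, 3.489, 3.517,
           3.544],
    0.10: [1.645, 2.052, 2.291, 2.459, 2.589, 2.693, 2.780, 2.855, 2.920,
           2.978, 3.030, 3.077, 3.120, 3.159, 3.196, 3.230, 3.261, 3.291,
           3.319],
}


def nemenyi_cd(k: int, N: int, alpha: float = 0.05,
               mean_ranks: np.ndarray | None = None) -> dict:
    """Nemenyi critical difference CD = q_alpha * sqrt(k(k+1)/(6N)).

    With ``mean_ranks`` given, also flags which method pairs differ
    significantly and returns the data needed to draw a CD diagram.
    """
    if alpha not in _NEMENYI_Q:
        raise ValueError("alpha must be 0.05 or 0.10")
    if not 2 <= k <= 20:
        raise ValueError("k must be between 2 and 20")
    q = _NEMENYI_Q[alpha][k - 2]
    cd = q * np.sqrt(k * (k + 1) / (6.0 * N))
    out = {"cd": float(cd), "q_alpha": q, "k": k, "N": N, "alpha": alpha}
    if mean_ranks is not None:
        mr = np.asarray(mean_ranks, dtype=float)
        if mr.size != k:
            raise ValueError("mean_ranks length must equal k")
        sig = np.abs(mr[:, None] - mr[None, :]) > cd
        out["mean_ranks"] = mr.tolist()
        out["significant"] = sig.tolist()
    return out
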