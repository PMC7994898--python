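"""Model/Results facade over the representation-learning pipeline.

``HLRR`` is constructed from a block-wise missing multimodal dataset and a
binary task; ``fit()`` partitions subjects into modality-complete groups,
builds one sparse-representation hypergraph per group, solves the
hypergraph-regularized low-rank program per group and trains the per-group
SVM ensemble, returning an ``HLRRResults`` carrying the learned
representations, convergence diagnostics and the fitted ensemble.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import (FeatureScaler, MultimodalDataset, partition_groups,
                        read_dataset)
from .hypergraph import Hypergraph
from .solver import HLRRParams, HLRRSolution, hlrr_solve_groups
from .classifier import EnsembleModel, fit_ensemble, predict as _predict

__all__ = ["HLRR", "HLRRResults"]


class HLRR:
    """Hypergraph-regularized low-rank representation classifier.

    Parameters
    ----------
    dataset : MultimodalDataset
        Labelled training data.
    positive_label, negative_label
        The binary task (e.g. "AD" vs "NC").
    params : HLRRParams, optional
        Solver weights and stopping controls.
    graph_cfg : dict, optional
        Hypergraph construction options (sr_beta, theta, sum_to_one,
        max_edge_size, weight_scheme).
    standardize : bool
        z-score features per modality with training statistics.
    mode : {"transductive", "inductive"}
        How test subjects obtain representations.
    """

    def __init__(self, dataset: MultimodalDataset, positive_label,
                 negative_label, params: HLRRParams | None = None,
                 graph_cfg: dict | None = None, svm_cfg: dict | None = None,
                 standardize: bool = True, mode: str = "transductive"):
        if dataset.labels is None:
            raise ValueError("training data must carry labels")
        keep = np.isin(np.asarray(dataset.labels),
                       [positive_label, negative_label])
        if not keep.all():
            dataset = dataset.subset(np.flatnonzero(keep))
        self.dataset = dataset
        self.positive_label = positive_label
        self.negative_label = negative_label
        self.params = params or HLRRParams()
        self.graph_cfg = graph_cfg or {}
        self.svm_cfg = svm_cfg or {}
        self.standardize = standardize
        self.mode = mode

    @classmethod
    def from_files(cls, feature_table, modality_map, labels,
                   positive_label, negative_label, **kw) -> "HLRR":
        ds = read_dataset(feature_table, modality_map, labels,
                          require_labels=True)
        return cls(ds, positive_label, negative_label, **kw)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, modality_map: dict[str, str],
                       labels: pd.Series, positive_label, negative_label,
                       **kw) -> "HLRR":
        """Build from a subjects x features frame and a column -> modality map.

        Absent blocks are NaN; ``labels`` is indexed like ``df``.
        """
        modalities: list[str] = []
        cols_of: dict[str, list[str]] = {}
        for c, m in modality_map.items():
            if m not in cols_of:
                modalities.append(m)
                cols_of[m] = []
            cols_of[m].append(c)
        n = len(df)
        features, avail = {}, np.zeros((n, len(modalities)), dtype=bool)
        for j, m in enumerate(modalities):
            block = df[cols_of[m]].to_numpy(dtype=float)
            isna = np.isnan(block)
            if (isna.any(axis=1) & ~isna.all(axis=1)).any():
                raise ValueError(f"partially-missing {m!r} block")
            avail[:, j] = ~isna.all(axis=1)
            features[m] = block
        ds = MultimodalDataset([str(i) for i in df.index], modalities,
                               features, avail,
                               labels.reindex(df.index).to_numpy())
        return cls(ds, positive_label, negative_label, **kw)

    def fit(self) -> "HLRRResults":
        ds = self.dataset
        scaler = None
        if self.standardize:
            scaler = FeatureScaler().fit(ds)
            ds = scaler.transform(ds)
        groups = partition_groups(ds)
        pairs = hlrr_solve_groups(groups, self.params, self.graph_cfg)
        hypergraphs = [hg for hg, _ in pairs]
        solutions = [sol for _, sol in pairs]
        ensemble = fit_ensemble(groups, solutions, self.positive_label,
                                self.negative_label, self.svm_cfg,
                                self.params, self.graph_cfg, self.mode)
        return HLRRResults(self, groups, hypergraphs, solutions, ensemble,
                           scaler)


class HLRRResults:
    """Learned per-group representations, diagnostics and the ensemble."""

    def __init__(self, model: HLRR, groups, hypergraphs: list[Hypergraph],
                 solutions: list[HLRRSolution], ensemble: EnsembleModel,
                 scaler: FeatureScaler | None):
        self.model = model
        self.groups = groups
        self.hypergraphs = hypergraphs
        self.solutions = solutions
        self.ensemble = ensemble
        self.scaler = scaler

    @property
    def converged(self) -> bool:
        return all(s.converged for s in self.solutions)

    def diagnostics(self) -> pd.DataFrame:
        """Per-group convergence and sparsity diagnostics."""
        rows = []
        for g, s in zip(self.groups, self.solutions):
            rows.append({
                "pattern": "+".join(g.pattern),
                "n_subjects": g.n_samples,
                "dim": g.X.shape[0],
                "iterations": s.iterations,
                "converged": s.converged,
                "residual_rel": s.trace["residual_rel"][-1],
                "rank_Z": int(np.linalg.matrix_rank(s.Z, tol=1e-6))
                if s.Z.size else 0,
                "nnz_frac_J": float((s.J > 1e-8).mean()) if s.J.size else 0.0,
            })
        return pd.DataFrame(rows)

    def predict(self, dataset: MultimodalDataset):
        """Label new subjects; returns (labels, decision_scores, n_votes)."""
        if self.scaler is not None:
            dataset = self.scaler.transform(dataset)
        return _predict(self.ensemble, dataset)

    def summary(self) -> str:
        d = self.diagnostics()
        lines = [
            "Hypergraph-regularized low-rank representation ensemble",
            "=" * 56,
            f"Task: {self.model.positive_label} (+1) vs "
            f"{self.model.negative_label} (-1)",
            f"Subjects: {self.model.dataset.n_subjects}   "
            f"Groups: {len(self.groups)}   "
            f"Ensemble members: {len(self.ensemble.members)}",
            f"Penalties: lam={self.model.params.lam}  "
            f"beta={self.model.params.beta}  gamma={self.model.params.gamma}",
            f"Mode: {self.model.mode}   All groups converged: {self.converged}",
            "",
            d.to_string(index=False),
        ]
        return "\n".join(lines)
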