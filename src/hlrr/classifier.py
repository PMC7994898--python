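"""Ensemble of per-group SVMs combined by majority vote.

One binary SVM is trained per modality-availability group on the columns of
that group's learned representation (one column per subject).  A test
subject is scored by every member whose modality pattern is contained in
the subject's available modalities, each member seeing only its own
pattern's feature columns; the final label is the sign of the mean vote,
with exact ties broken by the summed real-valued margins and then by the
training majority class.

Representations for test subjects come in two modes.  In *transductive*
mode (the default, matching the representation learner's nature) the
per-group program is re-solved on the member's training columns plus the
test columns, and the member's SVM — trained on the training columns of
that joint solution — scores the test columns.  In *inductive* mode a test
subject is sparse-coded against the member's training columns and that code
vector is its representation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.svm import SVC

from .datamodel import ModalityGroup, MultimodalDataset
from .hypergraph import build_group_hypergraph, solve_sparse_codes
from .solver import HLRRParams, HLRRSolution, hlrr_solve

__all__ = ["EnsembleMember", "EnsembleModel", "fit_ensemble",
           "majority_vote", "predict"]


@dataclass
class EnsembleMember:
    pattern: tuple[str, ...]
    svm: SVC
    train_X: np.ndarray            # member's raw training columns (D x N)
    train_ids: list[str]
    train_labels_pm: np.ndarray    # +/-1 coding


@dataclass
class EnsembleModel:
    """Fitted per-group classifiers plus routing metadata."""

    members: list[EnsembleMember]
    positive_label: object
    negative_label: object
    majority_label_pm: int         # training-majority class in +/-1 coding
    mode: str = "transductive"
    params: HLRRParams = field(default_factory=HLRRParams)
    graph_cfg: dict = field(default_factory=dict)
    svm_cfg: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        if self.mode not in ("transductive", "inductive"):
            raise ValueError(f"unknown mode {self.mode!r}")


def _code_labels(labels: np.ndarray, positive, negative) -> np.ndarray:
    out = np.where(labels == positive, 1, -1)
    unknown = ~np.isin(labels, [positive, negative])
    if unknown.any():
        raise ValueError(f"labels outside {{{positive}, {negative}}}")
    return out


def _make_svm(svm_cfg: dict | None) -> SVC:
    cfg = {"kernel": "linear", "C": 1.0}
    cfg.update(svm_cfg or {})
    return SVC(**cfg)


def fit_ensemble(groups: list[ModalityGroup],
                 solutions: list[HLRRSolution],
                 positive_label, negative_label,
                 svm_cfg: dict | None = None,
                 params: HLRRParams | None = None,
                 graph_cfg: dict | None = None,
                 mode: str = "transductive") -> EnsembleModel:
    """Train one SVM per group on its learned representation columns.

    Groups with fewer than one sample of each class are skipped with a
    warning; an error is raised only if no group is trainable.
    """
    members: list[EnsembleMember] = []
    all_pm: list[np.ndarray] = []
    for g, sol in zip(groups, solutions):
        if g.labels is None:
            raise ValueError("groups must carry labels for training")
        y = _code_labels(np.asarray(g.labels), positive_label, negative_label)
        all_pm.append(y)
        if len(np.unique(y)) < 2:
            warnings.warn(
                f"group {'+'.join(g.pattern)} has a single class; skipped")
            continue
        svm = _make_svm(svm_cfg)
        svm.fit(sol.J.T, y)        # columns of J are per-subject codes
        members.append(EnsembleMember(
            pattern=g.pattern, svm=svm, train_X=g.X,
            train_ids=list(g.subject_ids), train_labels_pm=y))
    if not members:
        raise ValueError("no trainable group (every group is single-class)")
    votes_all = np.concatenate(all_pm)
    majority = 1 if votes_all.sum() >= 0 else -1
    return EnsembleModel(members=members, positive_label=positive_label,
                         negative_label=negative_label,
                         majority_label_pm=majority, mode=mode,
                         params=params or HLRRParams(),
                         graph_cfg=graph_cfg or {}, svm_cfg=svm_cfg or {})


def majority_vote(votes, margins=None, majority_label_pm: int = 1) -> int:
    """Sign of the mean vote; ties fall back to summed margins, then to the
    training-majority class."""
    votes = np.asarray(list(votes), dtype=float)
    if votes.size == 0:
        raise ValueError("empty vote list")
    s = votes.sum()
    if s > 0:
        return 1
    if s < 0:
        return -1
    if margins is not None:
        ms = float(np.sum(margins))
        if ms > 0:
            return 1
        if ms < 0:
            return -1
    return int(majority_label_pm)


def _member_test_matrix(member: EnsembleMember, ds: MultimodalDataset,
                        rows: np.ndarray) -> np.ndarray:
    blocks = [ds.features[m][rows] for m in member.pattern]
    return np.concatenate(blocks, axis=1).T


def _transductive_scores(member: EnsembleMember, X_test: np.ndarray,
                         params: HLRRParams, graph_cfg: dict) -> np.ndarray:
    """Re-solve on train+test columns jointly; refit on training columns."""
    X_joint = np.concatenate([member.train_X, X_test], axis=1)
    _, lap = build_group_hypergraph(X_joint, **graph_cfg)
    sol = hlrr_solve(X_joint, lap, params)
    n_train = member.train_X.shape[1]
    svm = _make_svm({"kernel": member.svm.kernel, "C": member.svm.C})
    svm.fit(sol.J[:, :n_train].T, member.train_labels_pm)
    return svm.decision_function(sol.J[:, n_train:].T)


def _inductive_scores(member: EnsembleMember, X_test: np.ndarray,
                      graph_cfg: dict) -> np.ndarray:
    """Sparse-code each test column against the training columns."""
    sr_beta = graph_cfg.get("sr_beta", 0.1)
    sum_to_one = graph_cfg.get("sum_to_one", True)
    n_test = X_test.shape[1]
    codes = np.zeros((member.train_X.shape[1], n_test))
    for t in range(n_test):
        joint = np.concatenate([member.train_X, X_test[:, [t]]], axis=1)
        sc = solve_sparse_codes(joint, sr_beta=sr_beta, sum_to_one=sum_to_one)
        codes[:, t] = sc.S[-1, :-1]
    return member.svm.decision_function(codes.T)


def predict(model: EnsembleModel, test_ds: MultimodalDataset,
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Label test subjects by majority vote over applicable members.

    A member votes on a subject only when the subject's available
    modalities include the member's full pattern.  Returns
    ``(labels, decision_scores, n_votes)``; ``decision_scores`` is the mean
    real-valued margin over applicable members (the ranking score used for
    AUC) and ``n_votes`` is 0 for subjects no member could score — those
    receive the training-majority label.
    """
    n = test_ds.n_subjects
    margins = np.full((len(model.members), n), np.nan)
    mod_index = {m: j for j, m in enumerate(test_ds.modalities)}
    for k, member in enumerate(model.members):
        need = [mod_index[m] for m in member.pattern]
        ok = test_ds.availability[:, need].all(axis=1)
        rows = np.flatnonzero(ok)
        if rows.size == 0:
            continue
        X_test = _member_test_matrix(member, test_ds, rows)
        if model.mode == "transductive":
            sc = _transductive_scores(member, X_test, model.params,
                                      model.graph_cfg)
        else:
            sc = _inductive_scores(member, X_test, model.graph_cfg)
        margins[k, rows] = sc

    labels_pm = np.empty(n, dtype=int)
    scores = np.zeros(n)
    n_votes = np.zeros(n, dtype=int)
    for i in range(n):
        mi = margins[:, i]
        applicable = ~np.isnan(mi)
        n_votes[i] = int(applicable.sum())
        if n_votes[i] == 0:
            labels_pm[i] = model.majority_label_pm
            scores[i] = 0.0
            continue
        votes = np.sign(mi[applicable])
        votes[votes == 0] = 1.0        # on-boundary counts as positive
        labels_pm[i] = majority_vote(votes, mi[applicable],
                                     model.majority_label_pm)
        scores[i] = float(mi[applicable].mean())
    labels = np.where(labels_pm == 1, model.positive_label,
                      model.negative_label)
    return labels, scores, n_votes


def save_model(model: EnsembleModel, out_dir: str | Path) -> None:
    """Model directory: JSON manifest + per-member coefficient text files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "positive_label": str(model.positive_label),
        "negative_label": str(model.negative_label),
        "majority_label_pm": model.majority_label_pm,
        "mode": model.mode,
        "members": [{"pattern": list(m.pattern), "n_train": len(m.train_ids),
                     "train_ids": m.train_ids} for m in model.members],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    for k, m in enumerate(model.members):
        np.savetxt(out / f"member_{k}_coef.txt",
                   np.concatenate([m.svm.coef_.ravel(), m.svm.intercept_]))
        np.savetxt(out / f"member_{k}_train.txt", m.train_X)
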