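"""Multimodal feature tables with block-wise missingness.

A *block-wise missing* multimodal dataset stores, per subject, one feature
block per modality (e.g. 90 MRI ROI volumes, 90 PET ROI means, 3 CSF
biomarkers); a subject either has a modality's whole block or lacks it
entirely.  Subjects are partitioned into modality-availability groups — with
K modalities there are up to 2**K - 1 non-empty patterns (K=3 gives the
seven classical groups) — so that each group carries a complete data matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MultimodalDataset",
    "ModalityGroup",
    "read_dataset",
    "write_dataset",
    "partition_groups",
]


@dataclass
class MultimodalDataset:
    """Subjects x (modality blocks, availability mask, labels).

    Parameters
    ----------
    subject_ids : list of str
        Unique subject identifiers, in table order.
    modalities : list of str
        Modality names in canonical order (the order of the modality map).
    features : dict of str -> ndarray, shape (n_subjects, D_k)
        One real-valued block per modality.  Rows of subjects lacking the
        modality are NaN-filled and flagged absent in ``availability``.
    availability : ndarray of bool, shape (n_subjects, n_modalities)
        True where the subject has the modality.
    labels : ndarray or None
        Class label per subject; optional for prediction-only data.
    """

    subject_ids: list[str]
    modalities: list[str]
    features: dict[str, np.ndarray]
    availability: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.availability = np.asarray(self.availability, dtype=bool)
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("duplicate subject ids")
        n = len(self.subject_ids)
        if self.availability.shape != (n, len(self.modalities)):
            raise ValueError("availability mask shape mismatch")
        if not self.availability.any(axis=1).all():
            bad = [self.subject_ids[i]
                   for i in np.flatnonzero(~self.availability.any(axis=1))]
            raise ValueError(f"no available modality for subjects {bad}")
        for m in self.modalities:
            block = np.asarray(self.features[m], dtype=float)
            if block.ndim != 2 or block.shape[0] != n:
                raise ValueError(f"block {m!r} must be (n_subjects, D)")
            self.features[m] = block
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != n:
                raise ValueError("labels length mismatch")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def dims(self) -> dict[str, int]:
        """Feature dimension per modality."""
        return {m: self.features[m].shape[1] for m in self.modalities}

    def subset(self, idx: Sequence[int]) -> "MultimodalDataset":
        """Row-subset the dataset (copies)."""
        idx = np.asarray(idx, dtype=int)
        return MultimodalDataset(
            subject_ids=[self.subject_ids[i] for i in idx],
            modalities=list(self.modalities),
            features={m: self.features[m][idx].copy() for m in self.modalities},
            availability=self.availability[idx].copy(),
            labels=None if self.labels is None else self.labels[idx].copy(),
        )


@dataclass
class ModalityGroup:
    """One availability pattern's complete sub-dataset.

    ``X`` holds samples column-wise (features x subjects), the convention
    used throughout the representation learner.
    """

    pattern: tuple[str, ...]
    X: np.ndarray                      # D_pattern x N_m, no missing entries
    member_indices: np.ndarray         # positions into the parent dataset
    subject_ids: list[str]
    labels: np.ndarray | None = None
    feature_slices: dict[str, slice] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("empty modality pattern")
        self.X = np.asarray(self.X, dtype=float)
        if not np.isfinite(self.X).all():
            raise ValueError("group data matrix contains missing entries")

    @property
    def n_samples(self) -> int:
        return self.X.shape[1]


def _stack_pattern(ds: MultimodalDataset, pattern: tuple[str, ...],
                   rows: np.ndarray) -> tuple[np.ndarray, dict[str, slice]]:
    blocks, slices, off = [], {}, 0
    for m in pattern:
        b = ds.features[m][rows]
        blocks.append(b)
        slices[m] = slice(off, off + b.shape[1])
        off += b.shape[1]
    return np.concatenate(blocks, axis=1).T, slices


def partition_groups(ds: MultimodalDataset) -> list[ModalityGroup]:
    """Partition subjects into modality-complete groups.

    One group per distinct availability pattern present in the data; each
    subject lands in exactly the group matching its exact pattern, so the
    groups are disjoint and exhaustive.  Feature columns inside a group
    concatenate the pattern's modalities in canonical (map) order.
    """
    patterns: dict[tuple[str, ...], list[int]] = {}
    for i in range(ds.n_subjects):
        pat = tuple(m for j, m in enumerate(ds.modalities)
                    if ds.availability[i, j])
        patterns.setdefault(pat, []).append(i)
    groups = []
    # deterministic order: by number of modalities desc, then canonical order
    order = {m: j for j, m in enumerate(ds.modalities)}
    for pat in sorted(patterns, key=lambda p: (-len(p), [order[m] for m in p])):
        rows = np.asarray(patterns[pat], dtype=int)
        X, slices = _stack_pattern(ds, pat, rows)
        groups.append(ModalityGroup(
            pattern=pat,
            X=X,
            member_indices=rows,
            subject_ids=[ds.subject_ids[i] for i in rows],
            labels=None if ds.labels is None else ds.labels[rows].copy(),
            feature_slices=slices,
        ))
    return groups


def read_dataset(feature_table_path: str | Path,
                 modality_map_path: str | Path,
                 labels_path: str | Path | None = None,
                 *, require_labels: bool = False,
                 sep: str | None = None) -> MultimodalDataset:
    """Read a delimited feature table + modality map (+ labels).

    The feature table has a header row whose first column is the subject id;
    an absent modality is encoded as an all-NA block.  A block that mixes NA
    and non-NA cells is rejected (partial blocks are disallowed).  The
    modality map is two-column delimited text (feature_column, modality_name)
    and fixes the canonical modality order.
    """
    table = pd.read_csv(feature_table_path, sep=sep, engine="python")
    id_col = table.columns[0]
    subject_ids = table[id_col].astype(str).tolist()

    mmap = pd.read_csv(modality_map_path, sep=sep, engine="python", header=0)
    col_names, mod_names = mmap.iloc[:, 0].astype(str), mmap.iloc[:, 1].astype(str)
    unknown = set(col_names) - set(table.columns)
    if unknown:
        raise ValueError(f"modality map references unknown columns: {sorted(unknown)}")
    modalities: list[str] = []
    columns_of: dict[str, list[str]] = {}
    for c, m in zip(col_names, mod_names):
        if m not in columns_of:
            modalities.append(m)
            columns_of[m] = []
        columns_of[m].append(c)

    n = len(subject_ids)
    features: dict[str, np.ndarray] = {}
    availability = np.zeros((n, len(modalities)), dtype=bool)
    for j, m in enumerate(modalities):
        block = table[columns_of[m]].to_numpy(dtype=float)
        isna = np.isnan(block)
        all_na, any_na = isna.all(axis=1), isna.any(axis=1)
        partial = any_na & ~all_na
        if partial.any():
            bad = [subject_ids[i] for i in np.flatnonzero(partial)]
            raise ValueError(
                f"partially-missing {m!r} block for subjects {bad}")
        availability[:, j] = ~all_na
        features[m] = block

    labels = None
    if labels_path is not None:
        lab = pd.read_csv(labels_path, sep=sep, engine="python", header=0)
        lab_map = dict(zip(lab.iloc[:, 0].astype(str), lab.iloc[:, 1]))
        missing = [s for s in subject_ids if s not in lab_map]
        if missing:
            raise ValueError(f"label missing for subjects {missing}")
        labels = np.asarray([lab_map[s] for s in subject_ids])
    elif require_labels:
        raise ValueError("labels required but no labels file given")

    return MultimodalDataset(subject_ids, modalities, features,
                             availability, labels)


def write_dataset(ds: MultimodalDataset, feature_table_path: str | Path,
                  modality_map_path: str | Path,
                  labels_path: str | Path | None = None) -> None:
    """Write a dataset back to the delimited formats ``read_dataset`` reads."""
    cols: dict[str, np.ndarray] = {}
    map_rows = []
    for m in ds.modalities:
        block = ds.features[m].copy()
        block[~ds.availability[:, ds.modalities.index(m)]] = np.nan
        for d in range(block.shape[1]):
            name = f"{m}_{d}"
            cols[name] = block[:, d]
            map_rows.append((name, m))
    out = pd.DataFrame({"subject_id": ds.subject_ids, **cols})
    out.to_csv(feature_table_path, index=False)
    pd.DataFrame(map_rows, columns=["feature_column", "modality"]).to_csv(
        modality_map_path, index=False)
    if labels_path is not None and ds.labels is not None:
        pd.DataFrame({"subject_id": ds.subject_ids, "label": ds.labels}).to_csv(
            labels_path, index=False)


def write_groups(groups: list[ModalityGroup], out_dir: str | Path) -> None:
    """Serialize groups to per-group CSV plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for g in groups:
        tag = "+".join(g.pattern)
        pd.DataFrame(g.X.T, index=g.subject_ids).to_csv(out / f"group_{tag}.csv")
        manifest.append({"pattern": list(g.pattern), "size": g.n_samples,
                         "members": g.subject_ids})
    (out / "groups.json").write_text(json.dumps(manifest, indent=2))


class FeatureScaler:
    """Per-feature z-scoring fitted on training rows only.

    The representation learner is scale-sensitive, so features are
    standardized per modality using training statistics; constant features
    get unit scale.  Disable via the model's ``standardize`` flag.
    """

    def __init__(self) -> None:
        self.mean_: dict[str, np.ndarray] = {}
        self.std_: dict[str, np.ndarray] = {}

    def fit(self, ds: MultimodalDataset) -> "FeatureScaler":
        for j, m in enumerate(ds.modalities):
            rows = ds.availability[:, j]
            block = ds.features[m][rows]
            if block.shape[0] == 0:
                self.mean_[m] = np.zeros(ds.features[m].shape[1])
                self.std_[m] = np.ones(ds.features[m].shape[1])
                continue
            mu = block.mean(axis=0)
            sd = block.std(axis=0)
            sd[sd == 0] = 1.0
            self.mean_[m], self.std_[m] = mu, sd
        return self

    def transform(self, ds: MultimodalDataset) -> MultimodalDataset:
        feats = {m: (ds.features[m] - self.mean_[m]) / self.std_[m]
                 for m in ds.modalities}
        return MultimodalDataset(list(ds.subject_ids), list(ds.modalities),
                                 feats, ds.availability.copy(),
                                 None if ds.labels is None else ds.labels.copy())
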