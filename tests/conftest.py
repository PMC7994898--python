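import numpy as np
import pytest

from hlrr.datamodel import MultimodalDataset


def make_dataset(rng, patterns, dims=(4, 3, 2), modalities=("MRI", "PET", "CSF"),
                 labels=None):
    """Small dataset with one subject per given availability pattern.

    ``patterns`` is a list of tuples of modality names present per subject.
    """
    n = len(patterns)
    feats = {m: rng.standard_normal((n, d)) for m, d in zip(modalities, dims)}
    avail = np.zeros((n, len(modalities)), dtype=bool)
    for i, pat in enumerate(patterns):
        for m in pat:
            avail[i, modalities.index(m)] = True
    for j, m in enumerate(modalities):
        feats[m][~avail[:, j]] = np.nan
    return MultimodalDataset(
        subject_ids=[f"s{i}" for i in range(n)],
        modalities=list(modalities),
        features=feats,
        availability=avail,
        labels=None if labels is None else np.asarray(labels),
    )


def subspace_matrix(rng, D=30, r=3, n_per=20, k=3):
    """Union-of-subspaces data (noiseless), returns (X, labels)."""
    blocks, labs = [], []
    for c in range(k):
        U = np.linalg.qr(rng.standard_normal((D, r)))[0]
        blocks.append(U @ rng.standard_normal((r, n_per)))
        labs += [c] * n_per
    return np.concatenate(blocks, axis=1), np.asarray(labs)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
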