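"""Synthetic block-wise missing multimodal data generator.

Emulates the data regime the representation learner assumes: per class, each
modality's clean block lies in a low-dimensional subspace (a random
orthonormal basis per class/modality pair); a configurable fraction of each
subject's latent coordinates is shared across modalities, so modalities
carry correlated information about the same subject; dense Gaussian noise
and sparse gross corruption are added on top; each subject draws one of the
2**K - 1 availability patterns from a categorical distribution.

The default configuration mirrors a three-modality dementia cohort layout:
feature dimensions (90, 90, 3), class sizes (186, 393, 226) for the
AD / MCI / NC groups, every subject observed in modality 1 and roughly half
observed in modalities 2 and 3.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .datamodel import MultimodalDataset

__all__ = ["SimulationConfig", "generate", "default_adni_like_config",
           "scaled_down_config", "all_patterns"]


def all_patterns(n_modalities: int) -> list[tuple[int, ...]]:
    """All non-empty modality index subsets, largest first, lexicographic."""
    idx = range(n_modalities)
    pats = []
    for size in range(n_modalities, 0, -1):
        pats.extend(itertools.combinations(idx, size))
    return pats


@dataclass
class SimulationConfig:
    """Generator settings.

    n_per_class : subject count per class.
    dims : per-modality feature dimensions.
    rank : subspace dimension r per (class, modality).
    shared_frac : fraction of latent variance shared across modalities.
    noise_sd : dense noise standard deviation, relative to the clean
        block's empirical scale.
    corrupt_prob : per-entry probability of gross corruption.
    corrupt_scale : corruption magnitude as a multiple of the block scale.
    pattern_probs : categorical distribution over availability patterns
        (ordered as ``all_patterns(K)``).
    mean_shift : optional class-mean separation added on top of the
        subspace structure (0 keeps separation purely subspace-based).
    """

    n_per_class: tuple[int, ...] = (186, 393, 226)
    class_names: tuple[str, ...] = ("AD", "MCI", "NC")
    dims: tuple[int, ...] = (90, 90, 3)
    modality_names: tuple[str, ...] = ("MRI", "PET", "CSF")
    rank: int = 3
    shared_frac: float = 0.5
    noise_sd: float = 0.05
    corrupt_prob: float = 0.01
    corrupt_scale: float = 0.25
    pattern_probs: tuple[float, ...] | None = None
    mean_shift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rank < 1 or any(d < 1 for d in self.dims):
            raise ValueError("rank and dims must be positive")
        if not 0.0 <= self.shared_frac <= 1.0:
            raise ValueError("shared_frac must be in [0, 1]")
        if not 0.0 <= self.corrupt_prob <= 1.0:
            raise ValueError("corrupt_prob must be a probability")
        if len(self.n_per_class) != len(self.class_names):
            raise ValueError("n_per_class / class_names length mismatch")
        if len(self.dims) != len(self.modality_names):
            raise ValueError("dims / modality_names length mismatch")
        if self.rank > min(self.dims):
            raise ValueError("rank exceeds the smallest modality dimension")
        k = len(self.dims)
        if self.pattern_probs is None:
            self.pattern_probs = tuple(
                1.0 / (2 ** k - 1) for _ in range(2 ** k - 1))
        if len(self.pattern_probs) != 2 ** k - 1:
            raise ValueError("pattern_probs must cover all non-empty patterns")
        if abs(sum(self.pattern_probs) - 1.0) > 1e-9:
            raise ValueError("pattern_probs must sum to 1")


def default_adni_like_config(seed: int = 0) -> SimulationConfig:
    """Three-modality cohort with per-modality availability ~ (1.00, 0.49, 0.50).

    Pattern probabilities over (in order) {1,2,3}, {1,2}, {1,3}, {2,3},
    {1}, {2}, {3} are chosen so modality 1 is always present and
    modalities 2 and 3 are each observed for about half the cohort,
    matching a cohort where all subjects have MRI and roughly half have
    PET / CSF.
    """
    p12 = 0.49   # expected availability of modality 2 (PET)
    p13 = 0.50   # expected availability of modality 3 (CSF)
    # all mass on patterns containing modality 1; modality 2 and 3
    # membership independent: {123}: p2*p3, {12}: p2*(1-p3), {13}: (1-p2)*p3,
    # {1}: (1-p2)*(1-p3); remaining patterns get zero mass.
    probs = (p12 * p13, p12 * (1 - p13), (1 - p12) * p13, 0.0,
             (1 - p12) * (1 - p13), 0.0, 0.0)
    return SimulationConfig(pattern_probs=probs, seed=seed)


def scaled_down_config(seed: int = 0, *, n_per_class: tuple[int, ...] = (40, 40),
                       class_names: tuple[str, ...] = ("case", "control"),
                       dims: tuple[int, ...] = (20, 20, 3),
                       shared_frac: float = 0.8,
                       mean_shift: float = 0.0) -> SimulationConfig:
    """Two-class cohort with the default config's missingness structure,
    shrunk to desk-scale sizes for end-to-end pipeline experiments."""
    base = default_adni_like_config()
    return SimulationConfig(
        n_per_class=n_per_class, class_names=class_names, dims=dims,
        modality_names=base.modality_names, rank=base.rank,
        shared_frac=shared_frac, noise_sd=base.noise_sd,
        corrupt_prob=base.corrupt_prob, corrupt_scale=base.corrupt_scale,
        pattern_probs=base.pattern_probs, mean_shift=mean_shift, seed=seed)


@dataclass
class GroundTruth:
    """Everything the generator knows: labels, corruption masks per
    modality, shared/private latents, bases and clean blocks."""

    labels: np.ndarray
    corruption_masks: dict[str, np.ndarray]
    shared_latents: np.ndarray
    private_latents: dict[str, np.ndarray]
    bases: dict[tuple[str, str], np.ndarray]
    clean: dict[str, np.ndarray] = field(default_factory=dict)
    class_means: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)


def generate(cfg: SimulationConfig) -> tuple[MultimodalDataset, GroundTruth]:
    """Draw one dataset; deterministic given ``cfg.seed``.

    Per subject i of class c and modality k the clean feature vector is
    ``U_ck (sqrt(f) a_i + sqrt(1-f) b_ik)`` with shared latent a_i, private
    latent b_ik and shared fraction f; dense noise N(0, (noise_sd*scale)^2)
    and, with probability corrupt_prob per entry, a gross offset
    ``± corrupt_scale * scale`` are added, where scale is the clean block's
    empirical standard deviation.
    """
    rng = np.random.default_rng(cfg.seed)
    K = len(cfg.dims)
    n_total = int(sum(cfg.n_per_class))
    labels = np.repeat(list(cfg.class_names), list(cfg.n_per_class))
    r = cfg.rank

    bases: dict[tuple[str, str], np.ndarray] = {}
    class_means: dict[tuple[str, str], np.ndarray] = {}
    for c in cfg.class_names:
        for m, d in zip(cfg.modality_names, cfg.dims):
            Q, _ = np.linalg.qr(rng.standard_normal((d, r)))
            bases[(c, m)] = Q
            class_means[(c, m)] = (cfg.mean_shift *
                                   rng.standard_normal(d) / np.sqrt(d))

    shared = rng.standard_normal((n_total, r))
    private = {m: rng.standard_normal((n_total, r)) for m in cfg.modality_names}

    f = cfg.shared_frac
    features: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}
    clean_blocks: dict[str, np.ndarray] = {}
    for m, d in zip(cfg.modality_names, cfg.dims):
        clean = np.empty((n_total, d))
        for c in cfg.class_names:
            rows = np.flatnonzero(labels == c)
            lat = (np.sqrt(f) * shared[rows] +
                   np.sqrt(1.0 - f) * private[m][rows])
            clean[rows] = lat @ bases[(c, m)].T
            if cfg.mean_shift:
                clean[rows] += class_means[(c, m)]
        scale = clean.std() if clean.std() > 0 else 1.0
        noise = cfg.noise_sd * scale * rng.standard_normal((n_total, d))
        mask = rng.random((n_total, d)) < cfg.corrupt_prob
        signs = rng.choice([-1.0, 1.0], size=(n_total, d))
        block = clean + noise + np.where(mask, cfg.corrupt_scale * scale * signs, 0.0)
        features[m] = block
        masks[m] = mask
        clean_blocks[m] = clean

    pats = all_patterns(K)
    pat_idx = rng.choice(len(pats), size=n_total, p=np.asarray(cfg.pattern_probs))
    availability = np.zeros((n_total, K), dtype=bool)
    for i, pi in enumerate(pat_idx):
        availability[i, list(pats[pi])] = True
    for m, col in zip(cfg.modality_names, availability.T):
        features[m][~col] = np.nan

    ds = MultimodalDataset(
        subject_ids=[f"S{i:04d}" for i in range(n_total)],
        modalities=list(cfg.modality_names),
        features=features,
        availability=availability,
        labels=labels,
    )
    gt = GroundTruth(labels=labels, corruption_masks=masks,
                     shared_latents=shared, private_latents=private,
                     bases=bases, clean=clean_blocks, class_means=class_means)
    return ds, gt
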