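"""Synthetic multi-batch LC-MS-like data with known ground truth.

The generator writes log-scale intensity tables with the structure the
correction pipeline assumes: per-batch additive location shifts and
multiplicative scale distortions (both feature-specific), a subset of
class-informative features with a controllable effect size, replicate
pooled-QC samples injected into every batch, and controllable class
imbalance. Ground truth (the drawn batch effects, the informative feature
indices and the class means) is returned alongside, so recovery tests can
check the pipeline against what was actually simulated.

Model for a study sample i in batch b, feature j (log scale):

    x_ij = baseline_j + loc_bj + s_bj * (delta_c(i),j + eps_ij)

with loc_bj ~ N(0, batch_shift_sd), s_bj = exp(g_bj), g_bj ~ N(0,
batch_scale_sd), eps_ij ~ N(0, noise_sd), and delta the class offset
(nonzero only on informative features). QC samples are copies of the
baseline profile pushed through the same batch effects with fresh noise,
so their ground-truth profile is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import QC_LABEL, OmicsDataset
from .errors import ValidationError

__all__ = ["SyntheticConfig", "SyntheticGroundTruth", "generate_synthetic",
           "fixture_adenocarcinoma_counts", "fixture_aging_mice_counts"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings. Defaults describe a small two-class, three-batch
    experiment with a moderate batch effect (shift SD twice the residual
    noise SD) and a 10% informative-feature panel of one log-unit effect."""

    n_samples: int = 300
    n_features: int = 200
    n_batches: int = 3
    class_proportions: tuple = (0.5, 0.5)
    n_informative: int = 20
    effect_size: float = 1.0
    batch_shift_sd: float = 1.0
    batch_scale_sd: float = 0.1
    noise_sd: float = 0.5
    n_qc_per_batch: int = 2
    batch_class_confound: float = 0.0
    baseline_mean: float = 20.0
    baseline_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        p = np.asarray(self.class_proportions, dtype=float)
        if len(p) < 2 or p.min() <= 0 or abs(p.sum() - 1.0) > 1e-8:
            raise ValidationError(
                "class_proportions must be >=2 positive values summing to 1")
        if self.n_informative > self.n_features:
            raise ValidationError("n_informative cannot exceed n_features")
        if min(self.batch_shift_sd, self.batch_scale_sd, self.noise_sd) < 0:
            raise ValidationError("standard deviations must be non-negative")
        if not 0.0 <= self.batch_class_confound < 1.0:
            raise ValidationError("batch_class_confound must be in [0, 1)")


@dataclass
class SyntheticGroundTruth:
    baseline: np.ndarray              # (n_features,)
    batch_location: np.ndarray        # (K, n_features) additive shifts
    batch_scale: np.ndarray           # (K, n_features) multiplicative factors
    informative_features: np.ndarray  # indices, length n_informative
    class_means: np.ndarray           # (n_classes, n_informative)


def _class_offsets(n_classes: int, effect: float) -> np.ndarray:
    """Symmetric offsets so adjacent classes differ by `effect` log units."""
    return (np.arange(n_classes) - (n_classes - 1) / 2.0) * effect


def _assemble(baseline, loc, scale, informative, offsets, batch_idx, cls_idx,
              is_qc, noise_sd, rng, batch_labels, cls_labels, sample_ids):
    n = len(batch_idx)
    f = len(baseline)
    delta = np.zeros((n, f))
    study = ~is_qc
    delta[np.ix_(study, informative)] = offsets[cls_idx[study]][:, None]
    eps = rng.normal(0.0, noise_sd, size=(n, f))
    values = (baseline[None, :] + loc[batch_idx]
              + scale[batch_idx] * (delta + eps))
    cls = np.array([QC_LABEL if q else cls_labels[c]
                    for q, c in zip(is_qc, cls_idx)], dtype=object)
    return OmicsDataset(
        values=values, sample_ids=sample_ids,
        feature_ids=[f"feat{j:04d}" for j in range(f)],
        batch=np.array([batch_labels[b] for b in batch_idx], dtype=object),
        cls=cls, is_qc=is_qc)


def _generate_from_assignments(cfg: SyntheticConfig, batch_idx, cls_idx, is_qc,
                               cls_labels, sample_ids):
    rng = np.random.default_rng(cfg.seed)
    k = cfg.n_batches
    f = cfg.n_features
    n_classes = len(cfg.class_proportions) if cls_labels is None else len(cls_labels)
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=f)
    informative = np.sort(rng.choice(f, size=cfg.n_informative, replace=False))
    loc = rng.normal(0.0, cfg.batch_shift_sd, size=(k, f))
    scale = np.exp(rng.normal(0.0, cfg.batch_scale_sd, size=(k, f)))
    offsets = _class_offsets(n_classes, cfg.effect_size)
    labels = cls_labels if cls_labels is not None else [
        f"C{c}" for c in range(n_classes)]
    ds = _assemble(baseline, loc, scale, informative, offsets, batch_idx,
                   cls_idx, is_qc, cfg.noise_sd, rng,
                   [f"B{b + 1}" for b in range(k)], labels, sample_ids)
    truth = SyntheticGroundTruth(
        baseline=baseline, batch_location=loc, batch_scale=scale,
        informative_features=informative,
        class_means=baseline[informative][None, :] + offsets[:, None])
    return ds, truth


def generate_synthetic(cfg: SyntheticConfig) -> tuple[OmicsDataset, SyntheticGroundTruth]:
    """Draw one dataset plus its ground truth; deterministic given cfg.seed.

    The output holds ``cfg.n_samples`` study samples (batches balanced up to
    rounding, classes drawn from ``class_proportions`` independently of the
    batch unless ``batch_class_confound > 0``) followed by
    ``n_qc_per_batch`` pooled-QC replicates per batch.
    """
    rng = np.random.default_rng(cfg.seed ^ 0x5EED)  # assignment stream
    k, n = cfg.n_batches, cfg.n_samples
    n_classes = len(cfg.class_proportions)
    batch_idx = rng.permutation(np.arange(n) % k)
    cls_idx = rng.choice(n_classes, size=n, p=np.asarray(cfg.class_proportions))
    if cfg.batch_class_confound > 0:
        forced = rng.random(n) < cfg.batch_class_confound
        cls_idx[forced] = batch_idx[forced] % n_classes
    qc_batches = np.repeat(np.arange(k), cfg.n_qc_per_batch)
    batch_idx = np.concatenate([batch_idx, qc_batches])
    cls_idx = np.concatenate([cls_idx, np.zeros(len(qc_batches), dtype=int)])
    is_qc = np.concatenate([np.zeros(n, dtype=bool),
                            np.ones(len(qc_batches), dtype=bool)])
    sample_ids = [f"S{i:05d}" for i in range(n)] + [
        f"QC_B{b + 1}_{r}" for b in range(k) for r in range(cfg.n_qc_per_batch)]
    return _generate_from_assignments(cfg, batch_idx, cls_idx, is_qc, None,
                                      sample_ids)


def _fixture(batch_sizes_by_class, qc_per_batch, cls_labels, cfg):
    """Build a dataset whose batch/class/QC composition is given exactly."""
    batch_idx, cls_idx, is_qc, sample_ids = [], [], [], []
    i = 0
    for b, per_class in enumerate(batch_sizes_by_class):
        for c, count in enumerate(per_class):
            for _ in range(count):
                batch_idx.append(b)
                cls_idx.append(c)
                is_qc.append(False)
                sample_ids.append(f"S{i:05d}")
                i += 1
        for r in range(qc_per_batch[b]):
            batch_idx.append(b)
            cls_idx.append(0)
            is_qc.append(True)
            sample_ids.append(f"QC_B{b + 1}_{r}")
    return _generate_from_assignments(
        cfg, np.array(batch_idx), np.array(cls_idx), np.array(is_qc),
        cls_labels, sample_ids)


def fixture_adenocarcinoma_counts(n_features: int = 200,
                                  seed: int = 0) -> OmicsDataset:
    """Synthetic stand-in mirroring the adenocarcinoma cohort composition:
    642 samples = 568 patients (497 colorectal cancer vs 71 chronic
    enteritis) + 74 pooled QCs, in three batches of 192/192/184 patients
    with 25/25/24 QCs. Feature content is simulated."""
    cfg = SyntheticConfig(n_samples=568, n_features=n_features, n_batches=3,
                          class_proportions=(497 / 568, 71 / 568),
                          n_informative=max(1, n_features // 10), seed=seed)
    ds, _ = _fixture(
        batch_sizes_by_class=[(168, 24), (168, 24), (161, 23)],
        qc_per_batch=(25, 25, 24),
        cls_labels=["cancer", "enteritis"], cfg=cfg)
    return ds


def fixture_aging_mice_counts(n_features: int = 200,
                              seed: int = 0) -> OmicsDataset:
    """Synthetic stand-in mirroring the aging-mice cohort composition:
    372 samples (171 high-fat vs 201 chow diet) in 7 batches of uneven
    size, no QCs. Feature content is simulated."""
    sizes = (88, 76, 64, 53, 42, 30, 19)        # sums to 372
    hf = (40, 35, 29, 24, 20, 14, 9)            # sums to 171
    cfg = SyntheticConfig(n_samples=372, n_features=n_features, n_batches=7,
                          class_proportions=(171 / 372, 201 / 372),
                          n_informative=max(1, n_features // 10),
                          n_qc_per_batch=0, seed=seed)
    ds, _ = _fixture(
        batch_sizes_by_class=[(h, s - h) for s, h in zip(sizes, hf)],
        qc_per_batch=(0,) * 7,
        cls_labels=["high_fat", "chow"], cfg=cfg)
    return ds
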