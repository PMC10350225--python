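"""Training protocol: unsupervised warmup on the full table, two supervised
scenarios (frozen encoder vs alternating), early stopping on validation
MCC, class-weighted minibatch sampling, repetitive batch-wise holdout,
random hyperparameter search, classical baselines and feature attribution.

Warmup deliberately sees the *feature values* of every sample — including
validation, test and QC — because reconstruction and batch confusion are
unsupervised; condition labels of validation/test samples are only ever
read at evaluation time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import LinearSVC

from ._autodiff import Adam, Tensor, cross_entropy
from .data import (OmicsDataset, SplitPlan, class_weights, make_holdout_splits)
from .errors import ValidationError
from .metrics import BatchProbe, MetricsReport, evaluate_representation, matthews_cc
from .models import BernnModel, ModelSpec, build_model, total_loss

__all__ = ["TrainConfig", "TrainHistory", "TrialResult", "warmup",
           "train_scenario", "run_repetitive_holdout", "hyperparameter_search",
           "baseline_classify", "feature_attribution", "early_stop_epoch",
           "default_search_space"]


@dataclass(frozen=True)
class TrainConfig:
    """Protocol settings: scenario, warmup length, post-warmup budget with
    early stopping, minibatch size and optimizer rates."""

    scenario: str = "alternating"          # or "frozen"
    warmup_epochs: int = 10
    max_epochs_post_warmup: int = 1000
    patience: int = 100
    batch_size: int = 32
    learning_rate: float = 3e-4
    sup_lr: float = 1e-3
    weight_decay: float = 1e-5
    disc_lr: float = 1e-2
    disc_steps: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in ("frozen", "alternating"):
            raise ValidationError(f"unknown scenario '{self.scenario}'")
        if self.warmup_epochs < 0:
            raise ValidationError("warmup_epochs must be >= 0")
        if self.patience > self.max_epochs_post_warmup:
            raise ValidationError("patience cannot exceed the epoch budget")
        if min(self.learning_rate, self.weight_decay) <= 0:
            raise ValidationError("optimizer rates must be > 0")


@dataclass
class TrainHistory:
    rec: list = field(default_factory=list)
    batch_term: list = field(default_factory=list)
    kl: list = field(default_factory=list)
    label_ce: list = field(default_factory=list)
    total: list = field(default_factory=list)
    valid_mcc: list = field(default_factory=list)
    best_epoch: int = -1


def early_stop_epoch(valid_mcc: list[float], patience: int) -> tuple[int, int]:
    """Return (best_epoch, stop_epoch) under patience-based early stopping.

    The best epoch is the earliest maximum (ties keep the earlier epoch);
    training stops once `patience` epochs pass without improvement.
    """
    best, best_i = -np.inf, 0
    for i, v in enumerate(valid_mcc):
        if v > best:
            best, best_i = v, i
        if i - best_i >= patience:
            return best_i, i
    return best_i, max(len(valid_mcc) - 1, 0)


def _minibatches(n: int, batch_size: int, rng: np.random.Generator,
                 weights: np.ndarray | None = None):
    if weights is None:
        order = rng.permutation(n)
    else:
        order = rng.choice(n, size=n, replace=True, p=weights / weights.sum())
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def _make_disc_opt(model: BernnModel, cfg: "TrainConfig") -> Adam | None:
    if model.spec.removal in ("DANN", "NormAE"):
        return Adam(model.batch_head_parameters(), lr=cfg.disc_lr)
    return None


def _unsup_step(model: BernnModel, opt: Adam, x, b_idx, rng,
                disc_opt: Adam | None, disc_steps: int):
    breakdown = total_loss(model, x, b_idx, supervised=False, train=True, rng=rng)
    opt.zero_grad()
    breakdown.tensor.backward()
    opt.step()
    if disc_opt is not None:
        # keep the batch discriminator near-optimal: several cross-entropy
        # steps on the detached bottleneck per autoencoder step, so the
        # encoder plays against a strong adversary instead of chasing a
        # weak one in circles
        for _ in range(disc_steps):
            z, _, _ = model.encode(x, stochastic=False)
            zd = Tensor(z.data)
            ce_b = cross_entropy(model.classify_batches(zd), b_idx)
            disc_opt.zero_grad()
            ce_b.backward()
            disc_opt.step()
    return breakdown


def warmup(model: BernnModel, ds_all: OmicsDataset, cfg: TrainConfig
           ) -> BernnModel:
    """Step 1: train reconstruction (+KL) and the batch-removal term on the
    whole dataset, QCs included. Condition labels are never read and the
    label classifier's parameters are untouched."""
    if cfg.warmup_epochs == 0:
        return model
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.unsupervised_parameters(), lr=cfg.learning_rate,
               weight_decay=cfg.weight_decay)
    disc_opt = _make_disc_opt(model, cfg)
    b_all = ds_all.batch_indices()
    for _ in range(cfg.warmup_epochs):
        for idx in _minibatches(ds_all.n_samples, cfg.batch_size, rng):
            _unsup_step(model, opt, ds_all.values[idx], b_all[idx], rng,
                        disc_opt, cfg.disc_steps)
    return model


def train_scenario(model: BernnModel, plan: SplitPlan, ds: OmicsDataset,
                   cfg: TrainConfig) -> tuple[BernnModel, TrainHistory]:
    """Step 2: supervised training with early stopping on validation MCC.

    scenario="frozen": only the label classifier updates (step 2a).
    scenario="alternating": each epoch runs one unsupervised pass over the
    full table followed by one supervised pass over the training split with
    gradients flowing through the encoder (step 1 / step 2b alternation).
    Supervised minibatches are drawn with class-weighted sampling. Returns
    the model restored to its best-validation-MCC parameters.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    classes = ds.classes
    cls_codes = ds.class_indices()
    b_all = ds.batch_indices()

    train_mask = plan.mask(ds, "train") & ~ds.is_qc
    valid_mask = plan.mask(ds, "valid") & ~ds.is_qc
    if len(set(ds.cls[valid_mask])) < 2:
        raise ValidationError(
            f"validation split {sorted(plan.valid_batches)} has a single "
            "condition; MCC is undefined")
    train_idx = np.flatnonzero(train_mask)
    weights = class_weights(ds.cls[train_idx])

    sup_params = (model.label_head_parameters() if cfg.scenario == "frozen"
                  else model.encoder_parameters() + model.label_head_parameters())
    sup_opt = Adam(sup_params, lr=cfg.sup_lr, weight_decay=cfg.weight_decay)
    unsup_opt = Adam(model.unsupervised_parameters(), lr=cfg.learning_rate,
                     weight_decay=cfg.weight_decay)
    disc_opt = _make_disc_opt(model, cfg)

    hist = TrainHistory()
    best_mcc, best_epoch, best_state = -np.inf, -1, model.get_state()
    y_valid = ds.cls[valid_mask]
    for epoch in range(cfg.max_epochs_post_warmup):
        sums = np.zeros(5)
        n_steps = 0
        if cfg.scenario == "alternating":
            for idx in _minibatches(ds.n_samples, cfg.batch_size, rng):
                bd = _unsup_step(model, unsup_opt, ds.values[idx], b_all[idx],
                                 rng, disc_opt, cfg.disc_steps)
                sums[:4] += (bd.rec, bd.batch_term, bd.kl, 0.0)
                n_steps += 1
        for sub in _minibatches(len(train_idx), cfg.batch_size, rng, weights):
            idx = train_idx[sub]
            z, _, _ = model.encode(ds.values[idx],
                                   stochastic=(model.spec.backbone == "VAE"),
                                   train=True, rng=rng)
            ce = cross_entropy(model.classify_labels(z), cls_codes[idx],
                               label_smoothing=model.spec.label_smoothing)
            sup_opt.zero_grad()
            ce.backward()
            sup_opt.step()
            sums[3] += ce.item()
            sums[4] += ce.item()
            n_steps += 1
        for key, v in zip(("rec", "batch_term", "kl", "label_ce", "total"), sums):
            getattr(hist, key).append(v / max(n_steps, 1))
        y_pred = model.predict_labels(ds.values[valid_mask], classes)
        mcc = matthews_cc(y_valid, y_pred)
        hist.valid_mcc.append(mcc)
        if mcc > best_mcc:  # strict: ties keep the earlier epoch
            best_mcc, best_epoch = mcc, epoch
            best_state = model.get_state()
        if epoch - best_epoch >= cfg.patience:
            break
    model.set_state(best_state)
    hist.best_epoch = best_epoch
    return model, hist


@dataclass
class TrialResult:
    """Aggregated repetitive-holdout outcome for one model configuration."""

    spec: ModelSpec
    config: TrainConfig
    valid_reports: list[MetricsReport]
    test_reports: list[MetricsReport]
    mean_valid_mcc: float
    mean_test_mcc: float
    all_reports: list[MetricsReport] = field(default_factory=list)
    strategy: str = "fixed"


def _evaluate_split(model: BernnModel, ds: OmicsDataset, plan: SplitPlan,
                    split: str, probe: BatchProbe) -> MetricsReport:
    sub = ds.subset(plan.mask(ds, split))
    emb = model.embed(sub.values)
    y_pred = model.predict_labels(sub.values[~sub.is_qc], ds.classes)
    k = min(probe.k, sub.n_samples - 1)
    return evaluate_representation(emb, sub, y_pred=y_pred,
                                   probe=BatchProbe(k=k), split=split,
                                   representation="bottleneck")


def run_repetitive_holdout(ds: OmicsDataset, spec: ModelSpec, cfg: TrainConfig,
                           n_iterations: int, seed: int,
                           probe: BatchProbe = BatchProbe()) -> TrialResult:
    """Fresh batch-wise splits, fresh model, warmup and supervised training
    for every holdout iteration; reports metrics on validation and test
    embeddings and the mean MCC across iterations."""
    plans = make_holdout_splits(ds, n_iterations, seed=seed)
    valid_reports, test_reports, all_reports = [], [], []
    for it, plan in enumerate(plans):
        it_seed = (seed + 104729 * it) % (2 ** 31)
        model = build_model(spec, ds.n_features, len(ds.batches),
                            len(ds.classes), seed=it_seed)
        it_cfg = replace(cfg, seed=it_seed)
        warmup(model, ds, it_cfg)
        model, _ = train_scenario(model, plan, ds, it_cfg)
        valid_reports.append(_evaluate_split(model, ds, plan, "valid", probe))
        test_reports.append(_evaluate_split(model, ds, plan, "test", probe))
        # batch-mixing/QC panel on the full representation: with few
        # batches a single split cannot carry a mixing signal
        all_reports.append(evaluate_representation(
            model.embed(ds.values), ds, probe=probe, split="all",
            representation="bottleneck"))
    return TrialResult(
        spec=spec, config=cfg, valid_reports=valid_reports,
        test_reports=test_reports, all_reports=all_reports,
        mean_valid_mcc=float(np.mean([r.mcc for r in valid_reports])),
        mean_test_mcc=float(np.mean([r.mcc for r in test_reports])))


def default_search_space() -> dict:
    """Bounds for the tunable hyperparameters (sampled log-uniformly where
    marked)."""
    return {
        "learning_rate": ("log", 1e-4, 1e-2),
        "weight_decay": ("log", 1e-6, 1e-3),
        "dropout": ("uniform", 0.0, 0.5),
        "warmup_epochs": ("int", 2, 20),
        "layer1": ("int", 32, 128),
        "layer2": ("int", 32, 128),
        "label_smoothing": ("uniform", 0.0, 0.2),
        "margin": ("uniform", 0.1, 2.0),
        "beta": ("log", 1e-2, 1.0),
        "gamma": ("log", 1e-2, 1.0),
    }


def _sample_space(space: dict, rng: np.random.Generator) -> dict:
    out = {}
    for key, (kind, lo, hi) in space.items():
        if kind == "log":
            out[key] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        elif kind == "int":
            out[key] = int(rng.integers(lo, hi + 1))
        else:
            out[key] = float(rng.uniform(lo, hi))
    return out


def hyperparameter_search(ds: OmicsDataset, backbone: str, removal: str,
                          space: dict | None = None, budget: int = 20,
                          seed: int = 0, n_iterations: int = 3,
                          base_cfg: TrainConfig | None = None) -> TrialResult:
    """Seeded random search over `budget` configurations of one grid cell;
    selection criterion is the mean validation MCC (test MCC is reported
    but never drives selection)."""
    if budget < 1:
        raise ValidationError("budget must be >= 1")
    space = space or default_search_space()
    base_cfg = base_cfg or TrainConfig()
    rng = np.random.default_rng(seed)
    best = None
    for trial in range(budget):
        draw = _sample_space(space, rng)
        spec_kw = {k: draw[k] for k in
                   ("dropout", "layer1", "layer2", "label_smoothing",
                    "beta", "gamma") if k in draw}
        if removal in ("invTriplet", "revTriplet") and "margin" in draw:
            spec_kw["margin"] = draw["margin"]
        spec = ModelSpec(backbone=backbone, removal=removal, **spec_kw)
        cfg_kw = {k: draw[k] for k in
                  ("learning_rate", "weight_decay", "warmup_epochs")
                  if k in draw}
        cfg = replace(base_cfg, seed=(seed + trial) % (2 ** 31), **cfg_kw)
        result = run_repetitive_holdout(ds, spec, cfg, n_iterations,
                                        seed=(seed + trial) % (2 ** 31))
        result.strategy = "random-search"
        if best is None or result.mean_valid_mcc > best.mean_valid_mcc:
            best = result
    return best


# ---------------------------------------------------------------------------
# classical baselines on non-network representations

def baseline_classify(X: np.ndarray, ds: OmicsDataset, plan: SplitPlan,
                      kind: str = "linear-SVM", seed: int = 0,
                      probe: BatchProbe = BatchProbe(), **clf_params):
    """Fit a balanced-class-weight LinearSVC or random forest on the
    training split of a feature-space representation and report metrics on
    the validation and test splits."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] != ds.n_samples:
        raise ValidationError("representation not aligned with dataset")
    train = plan.mask(ds, "train") & ~ds.is_qc
    y_train = ds.cls[train].astype(str)
    if len(set(y_train)) < 2:
        raise ValidationError("training split has a single condition")
    if kind == "linear-SVM":
        clf = LinearSVC(class_weight="balanced", random_state=seed, **clf_params)
    elif kind == "random-forest":
        clf = RandomForestClassifier(class_weight="balanced",
                                     random_state=seed, **clf_params)
    else:
        raise ValidationError(f"unknown baseline kind '{kind}'")
    clf.fit(X[train], y_train)
    out = {}
    for split in ("valid", "test"):
        sub_mask = plan.mask(ds, split)
        sub = ds.subset(sub_mask)
        Xs = X[sub_mask]
        y_pred = clf.predict(Xs[~sub.is_qc])
        k = min(probe.k, sub.n_samples - 1)
        out[split] = evaluate_representation(
            Xs, sub, y_pred=y_pred, probe=BatchProbe(k=k), split=split,
            representation="features")
    return clf, out


# ---------------------------------------------------------------------------
# feature attribution (expected gradients)

def _input_gradient(model: BernnModel, X: np.ndarray, target: int) -> np.ndarray:
    xt = Tensor(X, requires_grad=True)
    z, _, _ = model.encode(xt)
    logits = model.classify_labels(z)
    onehot = np.zeros(logits.data.shape)
    onehot[:, target] = 1.0
    (logits * Tensor(onehot)).sum().backward()
    return xt.grad


def feature_attribution(model: BernnModel, X_background: np.ndarray,
                        X_explain: np.ndarray, target_class: int | None = None,
                        steps: int = 32) -> np.ndarray:
    """Per-sample, per-feature additive contributions to a class logit.

    Integrated gradients along straight paths from each background sample,
    averaged over the background set ("expected gradients"): for each
    explained sample the contributions sum to its logit minus the mean
    background logit, exactly in the limit of many steps and very nearly at
    the default 32 for these piecewise-linear networks. Mean |attribution|
    across samples ranks features.
    """
    bg = np.atleast_2d(np.asarray(X_background, dtype=float))
    Xe = np.atleast_2d(np.asarray(X_explain, dtype=float))
    if bg.shape[0] == 0:
        raise ValidationError("background set is empty")
    alphas = (np.arange(steps) + 0.5) / steps  # midpoint rule
    attr = np.zeros_like(Xe)
    for i, x in enumerate(Xe):
        if target_class is None:
            tc = int(model.classify_labels(
                Tensor(model.embed(x[None]))).data.argmax())
        else:
            tc = int(target_class)
        total = np.zeros_like(x)
        for b in bg:
            path = b[None, :] + alphas[:, None] * (x - b)[None, :]
            grads = _input_gradient(model, path, tc)
            total += (x - b) * grads.mean(axis=0)
        attr[i] = total / bg.shape[0]
    return attr
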