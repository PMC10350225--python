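"""The 10-model grid: AE/VAE backbones crossed with five batch-removal
heads (none, DANN, NormAE-style adversary without gradient reversal,
inverse triplet, reverse triplet), plus a condition classifier on the
bottleneck.

Architecture: input -> layer1 -> bottleneck -> layer2 -> output, one hidden
layer on each side of the bottleneck with ReLU and dropout, linear output.
The decoder optionally adds a learned per-batch embedding vector to the
bottleneck before reconstruction ("batch mapping"), so the bottleneck need
not encode the batch. Both classifiers read the bottleneck (for the VAE,
the reparametrized z).

Loss contract per minibatch:

    total = rec + gamma * batch_term + beta * kl + label_ce

where rec is the mean squared reconstruction error, kl the closed-form
KL(q(z|x) || N(0, I)) (VAE only), label_ce the label-smoothed
cross-entropy on labeled non-QC samples, and batch_term depends on the
removal head. The DANN and reverse-triplet heads are made adversarial by a
gradient reversal layer; the NormAE head subtracts the batch classifier's
cross-entropy without reversal, clamped so the total cannot go negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._autodiff import (Adam, Dropout, Linear, Parameter, Tensor,
                        cross_entropy, grad_reverse, relu)
from .errors import ValidationError

BACKBONES = ("AE", "VAE")
REMOVALS = ("none", "DANN", "NormAE", "invTriplet", "revTriplet")
_TRIPLET = ("invTriplet", "revTriplet")

__all__ = ["BACKBONES", "REMOVALS", "ModelSpec", "BernnModel", "LossBreakdown",
           "build_model", "kl_divergence", "inv_triplet_loss",
           "rev_triplet_loss", "gradient_reversal", "mine_triplets",
           "total_loss", "model_grid"]


@dataclass(frozen=True)
class ModelSpec:
    """One cell of the backbone x removal grid plus its loss weights."""

    backbone: str = "AE"
    removal: str = "none"
    layer1: int = 64
    layer2: int = 64
    bottleneck_dim: int = 32
    dropout: float = 0.2
    margin: float | None = None       # triplet margin alpha
    beta: float = 1.0                 # KL weight (VAE only)
    gamma: float = 1.0                # batch-removal weight (lambda_b)
    label_smoothing: float = 0.0
    use_batch_mapping: bool = True
    z_reg: float = 0.01               # weak isotropic prior on the bottleneck

    def __post_init__(self):
        if self.backbone not in BACKBONES:
            raise ValidationError(f"unknown backbone '{self.backbone}'")
        if self.removal not in REMOVALS:
            raise ValidationError(f"unknown removal '{self.removal}'")
        if self.removal in _TRIPLET and self.margin is None:
            raise ValidationError(
                f"removal '{self.removal}' requires a triplet margin")
        if self.margin is not None and self.margin < 0:
            raise ValidationError("margin must be >= 0")
        if not 0.0 <= self.dropout < 1.0:
            raise ValidationError("dropout must be in [0, 1)")
        if min(self.beta, self.gamma) < 0:
            raise ValidationError("loss weights must be >= 0")
        if not 0.0 <= self.label_smoothing < 1.0:
            raise ValidationError("label smoothing must be in [0, 1)")
        if self.z_reg < 0:
            raise ValidationError("z_reg must be >= 0")

    @property
    def name(self) -> str:
        return f"{self.backbone}-{self.removal}"


def model_grid(**common) -> list[ModelSpec]:
    """All 10 distinct backbone x removal combinations."""
    specs = []
    for bb in BACKBONES:
        for rm in REMOVALS:
            kw = dict(common)
            if rm in _TRIPLET:
                kw.setdefault("margin", 1.0)
            specs.append(ModelSpec(backbone=bb, removal=rm, **kw))
    return specs


@dataclass
class LossBreakdown:
    rec: float
    batch_term: float
    kl: float
    label_ce: float
    total: float
    z_l2: float = 0.0
    tensor: Tensor | None = field(default=None, repr=False, compare=False)


class BernnModel:
    """Encoder/decoder pair with batch-mapping table, batch classifier and
    label classifier, all on the shared bottleneck."""

    def __init__(self, spec: ModelSpec, n_features: int, n_batches: int,
                 n_classes: int, seed: int = 0):
        self.spec = spec
        self.n_features = n_features
        self.n_batches = n_batches
        self.n_classes = n_classes
        rng = np.random.default_rng(seed)
        d = spec.bottleneck_dim
        self.enc_hidden = Linear(n_features, spec.layer1, rng)
        if spec.backbone == "VAE":
            self.enc_mu = Linear(spec.layer1, d, rng)
            self.enc_logvar = Linear(spec.layer1, d, rng)
            # start the posterior narrow (sigma ~ e^-2.5): early training is
            # then not dominated by reparameterization noise
            self.enc_logvar.W.data *= 0.1
            self.enc_logvar.b.data[:] = -5.0
        else:
            self.enc_out = Linear(spec.layer1, d, rng)
        self.dec_hidden = Linear(d, spec.layer2, rng)
        self.dec_out = Linear(spec.layer2, n_features, rng)
        # zero init => batch mapping is an exact no-op until trained
        self.batch_embedding = Parameter(np.zeros((n_batches, d)))
        # the batch discriminator gets one hidden layer: a purely linear
        # adversary can be fooled by rotations that leave clusters intact
        self.batch_hidden = Linear(d, spec.layer2, rng)
        self.batch_out = Linear(spec.layer2, n_batches, rng)
        self.label_clf = Linear(d, n_classes, rng)
        self._drop = Dropout(spec.dropout, np.random.default_rng(seed + 1))
        self.rng = np.random.default_rng(seed + 2)

    # -- parameter groups --------------------------------------------------
    def encoder_parameters(self):
        ps = self.enc_hidden.parameters()
        if self.spec.backbone == "VAE":
            ps += self.enc_mu.parameters() + self.enc_logvar.parameters()
        else:
            ps += self.enc_out.parameters()
        return ps

    def decoder_parameters(self):
        return (self.dec_hidden.parameters() + self.dec_out.parameters()
                + [self.batch_embedding])

    def batch_head_parameters(self):
        return self.batch_hidden.parameters() + self.batch_out.parameters()

    def label_head_parameters(self):
        return self.label_clf.parameters()

    def unsupervised_parameters(self):
        """Autoencoder parameters driven by the main unsupervised loss.

        The batch discriminator is excluded: it is trained by its own,
        faster optimizer so it stays near-optimal while the encoder moves
        slowly against it (see training module).
        """
        return self.encoder_parameters() + self.decoder_parameters()

    def all_parameters(self):
        return self.unsupervised_parameters() + self.label_head_parameters()

    def get_state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.all_parameters()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.all_parameters(), state):
            p.data = s.copy()

    def save(self, path) -> None:
        """Parameter archive (.npz) with a JSON sidecar holding the spec
        and dimensions next to it."""
        import json
        from dataclasses import asdict
        from pathlib import Path

        path = Path(path)
        np.savez(path, **{f"p{i}": p.data
                          for i, p in enumerate(self.all_parameters())})
        sidecar = {"spec": asdict(self.spec), "n_features": self.n_features,
                   "n_batches": self.n_batches, "n_classes": self.n_classes}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "BernnModel":
        import json
        from pathlib import Path

        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        model = cls(ModelSpec(**sidecar["spec"]), sidecar["n_features"],
                    sidecar["n_batches"], sidecar["n_classes"])
        with np.load(path.with_suffix(".npz")) as arc:
            model.set_state([arc[f"p{i}"]
                             for i in range(len(model.all_parameters()))])
        return model

    # -- forward passes ----------------------------------------------------
    def encode(self, x, stochastic: bool = False, train: bool = False,
               rng: np.random.Generator | None = None):
        """Bottleneck of a batch of inputs. For the VAE, returns
        (z, mu, logvar); for the AE, (z, None, None). ``stochastic`` draws
        one reparameterization sample z = mu + sigma * eps."""
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))
        if x.data.shape[1] != self.n_features:
            raise ValidationError(
                f"input width {x.data.shape[1]} != n_features {self.n_features}")
        h = self._drop(relu(self.enc_hidden(x)), train)
        if self.spec.backbone == "VAE":
            mu = self.enc_mu(h)
            logvar = self.enc_logvar(h)
            if stochastic:
                eps = (rng or self.rng).standard_normal(mu.data.shape)
                z = mu + (logvar * 0.5).exp() * Tensor(eps)
            else:
                z = mu
            return z, mu, logvar
        return self.enc_out(h), None, None

    def decode(self, z, batch_ids, train: bool = False) -> Tensor:
        """Reconstruct inputs from the bottleneck; with batch mapping, the
        learned embedding of each sample's batch is added to z first."""
        z = z if isinstance(z, Tensor) else Tensor(np.asarray(z, dtype=float))
        batch_ids = np.asarray(batch_ids, dtype=int)
        if batch_ids.min(initial=0) < 0 or batch_ids.max(initial=0) >= self.n_batches:
            raise ValidationError(
                f"batch ids must be in [0, {self.n_batches})")
        if self.spec.use_batch_mapping:
            z = z + self.batch_embedding.take_rows(batch_ids)
        h = self._drop(relu(self.dec_hidden(z)), train)
        return self.dec_out(h)

    def classify_labels(self, z) -> Tensor:
        return self.label_clf(z)

    def classify_batches(self, z) -> Tensor:
        return self.batch_out(relu(self.batch_hidden(z)))

    def embed(self, X) -> np.ndarray:
        """Deterministic bottleneck coordinates (VAE: the posterior mean)."""
        z, _, _ = self.encode(np.asarray(X, dtype=float))
        return z.data

    def predict_labels(self, X, classes=None) -> np.ndarray:
        logits = self.classify_labels(Tensor(self.embed(X))).data
        idx = logits.argmax(axis=1)
        if classes is None:
            return idx
        return np.array([classes[i] for i in idx], dtype=object)


def build_model(spec: ModelSpec, n_features: int, n_batches: int,
                n_classes: int, seed: int = 0) -> BernnModel:
    """Deterministically initialized model for one grid cell."""
    return BernnModel(spec, n_features, n_batches, n_classes, seed)


# ---------------------------------------------------------------------------
# loss primitives

def gradient_reversal(h, lam: float):
    """Identity forward; gradient multiplied by -lam on the way back."""
    h = h if isinstance(h, Tensor) else Tensor(np.asarray(h, dtype=float))
    return grad_reverse(h, lam)


def kl_divergence(mu, logvar) -> Tensor:
    """Mean over samples of KL(N(mu, sigma^2) || N(0, I)), closed form
    0.5 * sum_d (mu^2 + sigma^2 - 1 - log sigma^2)."""
    mu = mu if isinstance(mu, Tensor) else Tensor(np.asarray(mu, dtype=float))
    logvar = (logvar if isinstance(logvar, Tensor)
              else Tensor(np.asarray(logvar, dtype=float)))
    if mu.data.shape != logvar.data.shape:
        raise ValidationError("mu and logvar shapes differ")
    per_sample = (mu ** 2 + logvar.exp() - logvar - 1.0).sum(axis=1) * 0.5
    return per_sample.mean()


def _sq_dist(a: Tensor, b: Tensor) -> Tensor:
    return ((a - b) ** 2).sum(axis=1)


def _as_tensor_pair(*xs):
    out = [x if isinstance(x, Tensor) else Tensor(np.asarray(x, float)) for x in xs]
    w = {t.data.shape[1] for t in out}
    if len(w) != 1:
        raise ValidationError("embedding widths differ across triplet roles")
    return out


def inv_triplet_loss(fA, fP, fN, margin: float) -> Tensor:
    """Triplet hinge with positive/negative roles swapped: pulls the anchor
    toward its *different-batch* negative and pushes its *same-batch*
    positive away (preventing collapse):

        mean( max(||f(A)-f(N)||^2 - ||f(A)-f(P)||^2 + margin, 0) )
    """
    fA, fP, fN = _as_tensor_pair(fA, fP, fN)
    hinge = relu(_sq_dist(fA, fN) - _sq_dist(fA, fP) + margin)
    return hinge.mean()


def rev_triplet_loss(fA, fP, fN, margin: float, lam: float = 1.0) -> Tensor:
    """Standard batch-grouped triplet hinge routed through gradient
    reversal: the printed value clusters batches, but the reversed gradient
    drives the encoder toward batch confusion (adversarial)."""
    fA, fP, fN = _as_tensor_pair(fA, fP, fN)
    fA, fP, fN = (grad_reverse(t, lam) for t in (fA, fP, fN))
    hinge = relu(_sq_dist(fA, fP) - _sq_dist(fA, fN) + margin)
    return hinge.mean()


def mine_triplets(batch_ids: np.ndarray, rng: np.random.Generator):
    """For each anchor: one random same-batch positive and one random
    different-batch negative from the minibatch; anchors lacking either
    are skipped. Returns (anchor, positive, negative) index arrays."""
    batch_ids = np.asarray(batch_ids, dtype=int)
    anchors, positives, negatives = [], [], []
    for i, b in enumerate(batch_ids):
        same = np.flatnonzero((batch_ids == b) & (np.arange(len(batch_ids)) != i))
        diff = np.flatnonzero(batch_ids != b)
        if len(same) == 0 or len(diff) == 0:
            continue
        anchors.append(i)
        positives.append(rng.choice(same))
        negatives.append(rng.choice(diff))
    return np.array(anchors, int), np.array(positives, int), np.array(negatives, int)


def total_loss(model: BernnModel, x, batch_ids, cls_idx=None, *,
               supervised: bool = False, train: bool = True,
               rng: np.random.Generator | None = None) -> LossBreakdown:
    """Forward pass and composite loss for one minibatch.

    ``cls_idx`` holds integer class codes with -1 for unlabeled/QC samples;
    the label term is computed only when ``supervised`` and only over
    labeled samples. Returns a LossBreakdown whose ``tensor`` field backs
    propagation.
    """
    spec = model.spec
    rng = rng or model.rng
    x = np.asarray(x, dtype=float)
    batch_ids = np.asarray(batch_ids, dtype=int)
    xt = Tensor(x)
    z, mu, logvar = model.encode(xt, stochastic=(spec.backbone == "VAE"),
                                 train=train, rng=rng)
    xhat = model.decode(z, batch_ids, train=train)
    rec = ((xt - xhat) ** 2).mean()
    kl = kl_divergence(mu, logvar) if spec.backbone == "VAE" else Tensor(0.0)

    label_ce = Tensor(0.0)
    if supervised:
        if cls_idx is None or not (np.asarray(cls_idx) >= 0).any():
            raise ValidationError("supervised minibatch has no labeled samples")
        cls_idx = np.asarray(cls_idx, dtype=int)
        labeled = cls_idx >= 0
        z_lab = z.take_rows(np.flatnonzero(labeled))
        logits = model.classify_labels(z_lab)
        label_ce = cross_entropy(logits, cls_idx[labeled],
                                 label_smoothing=spec.label_smoothing)

    batch_term = Tensor(0.0)
    normae = False
    if spec.removal == "DANN":
        logits_b = model.classify_batches(grad_reverse(z, 1.0))
        batch_term = cross_entropy(logits_b, batch_ids)
    elif spec.removal == "NormAE":
        normae = True
        logits_b = model.classify_batches(z)
        batch_term = cross_entropy(logits_b, batch_ids)
    elif spec.removal in _TRIPLET:
        a, p, ngt = mine_triplets(batch_ids, rng)
        if len(a) > 0:
            fA, fP, fN = (z.take_rows(idx) for idx in (a, p, ngt))
            if spec.removal == "invTriplet":
                batch_term = inv_triplet_loss(fA, fP, fN, spec.margin)
            else:
                batch_term = rev_triplet_loss(fA, fP, fN, spec.margin)

    # weak zero-centred prior on the bottleneck: bounds the embedding scale,
    # without which the encoder can outrun the adversary by inflating z
    z_l2 = (z ** 2).mean() * spec.z_reg if spec.z_reg > 0 else Tensor(0.0)
    base = rec + label_ce + z_l2
    if spec.backbone == "VAE":
        base = base + spec.beta * kl
    if normae:
        # adversary is subtracted (no GRL); clamp so the total stays >= 0
        total = relu(base - spec.gamma * batch_term)
        reported_batch = ((total.item() - base.item()) / spec.gamma
                          if spec.gamma > 0 else 0.0)
    else:
        total = base + spec.gamma * batch_term
        reported_batch = batch_term.item()
    return LossBreakdown(rec=rec.item(), batch_term=reported_batch,
                         kl=kl.item(), label_ce=label_ce.item(),
                         total=total.item(), z_l2=z_l2.item(), tensor=total)
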