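"""Batch-mixing, QC-tightness and classification metrics.

Batch mixing is probed with a k-nearest-neighbour batch classifier (k = 20
by default): the per-sample batch-membership probabilities give the
normalized batch entropy (nBE), and the argmax predictions give
chance-adjusted partition scores (ARI, AMI) against the true batch labels.
QC tightness is measured on the pooled-QC replicates (aPCC, nMED);
classification quality is MCC and accuracy. For nBE, ARI, AMI and nMED,
*lower* means better batch mixing; for aPCC and MCC, higher is better.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist
from scipy.special import gammaln
from sklearn.metrics import accuracy_score, matthews_corrcoef

from .data import OmicsDataset
from .errors import ValidationError

__all__ = ["BatchProbe", "ContingencyTable", "MetricsReport",
           "knn_batch_probabilities", "normalized_batch_entropy",
           "adjusted_rand_index", "adjusted_mutual_information",
           "qc_average_pcc", "qc_normalized_med", "matthews_cc",
           "evaluate_representation"]


@dataclass(frozen=True)
class BatchProbe:
    """kNN batch classifier settings (Euclidean distance)."""

    k: int = 20


def knn_batch_probabilities(X: np.ndarray, batch, probe: BatchProbe = BatchProbe()
                            ) -> tuple[np.ndarray, list]:
    """Per-sample batch-membership probabilities from the k nearest
    neighbours (self excluded; distance ties broken by sample index).

    Returns (P, batch_levels) where P[i, j] is the fraction of sample i's
    k nearest neighbours that belong to batch_levels[j]; rows sum to 1.
    """
    X = np.asarray(X, dtype=float)
    batch = np.asarray(batch, dtype=object)
    n = X.shape[0]
    if probe.k < 1 or probe.k >= n:
        raise ValidationError(f"probe k={probe.k} must satisfy 1 <= k < n={n}")
    levels = sorted(set(batch))
    if len(levels) < 2:
        raise ValidationError("batch probe needs at least 2 batches")
    codes = np.array([levels.index(b) for b in batch])
    d = cdist(X, X)
    np.fill_diagonal(d, np.inf)
    # stable argsort => ties resolved by ascending sample index
    order = np.argsort(d, axis=1, kind="stable")[:, :probe.k]
    P = np.zeros((n, len(levels)))
    for j in range(len(levels)):
        P[:, j] = (codes[order] == j).mean(axis=1)
    return P, levels


def normalized_batch_entropy(P: np.ndarray, K: int) -> float:
    """nBE = (log K - mean Shannon entropy of the probability rows) / log K.

    0 means perfectly uniform batch probabilities (ideal mixing), 1 means
    every sample's neighbourhood is a single batch (perfect separation).
    """
    P = np.asarray(P, dtype=float)
    if K < 2:
        raise ValidationError("K must be at least 2")
    if (P < 0).any():
        raise ValidationError("probabilities must be non-negative")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-8):
        raise ValidationError("probability rows must sum to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(P > 0, P * np.log(P), 0.0)
    be = -plogp.sum(axis=1).mean()
    return float((math.log(K) - be) / math.log(K))


# ---------------------------------------------------------------------------
# chance-adjusted partition agreement

@dataclass
class ContingencyTable:
    """Cross-tabulation of two labelings of the same samples."""

    counts: np.ndarray

    @classmethod
    def from_labels(cls, pred, truth) -> "ContingencyTable":
        pred = np.asarray(pred, dtype=object)
        truth = np.asarray(truth, dtype=object)
        if pred.shape != truth.shape:
            raise ValidationError(
                f"label length mismatch: {pred.shape} vs {truth.shape}")
        if pred.size < 2:
            raise ValidationError("need at least 2 samples")
        pu, pi = np.unique(pred.astype(str), return_inverse=True)
        tu, ti = np.unique(truth.astype(str), return_inverse=True)
        counts = np.zeros((len(pu), len(tu)), dtype=np.int64)
        np.add.at(counts, (pi, ti), 1)
        return cls(counts=counts)

    @property
    def row_sums(self):
        return self.counts.sum(axis=1)

    @property
    def col_sums(self):
        return self.counts.sum(axis=0)

    @property
    def total(self):
        return int(self.counts.sum())


def _comb2(x):
    return x * (x - 1) / 2.0


def adjusted_rand_index(pred, truth) -> float:
    """Pair-counting Rand index adjusted for chance; 1 for identical
    partitions, expectation 0 under random labelings."""
    t = ContingencyTable.from_labels(pred, truth)
    n = t.total
    sum_ij = _comb2(t.counts.astype(float)).sum()
    sum_a = _comb2(t.row_sums.astype(float)).sum()
    sum_b = _comb2(t.col_sums.astype(float)).sum()
    expected = sum_a * sum_b / _comb2(n)
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:  # both partitions trivial (all-one-cluster etc.)
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def expected_mutual_information(table: ContingencyTable) -> float:
    """Hypergeometric expectation of MI between two random partitions with
    the table's margins."""
    a, b, n = table.row_sums, table.col_sums, table.total
    lgN = gammaln(n + 1)
    emi = 0.0
    for ai in a:
        for bj in b:
            start = max(1, ai + bj - n)
            stop = min(ai, bj)
            for nij in range(start, stop + 1):
                log_w = (gammaln(ai + 1) + gammaln(bj + 1)
                         + gammaln(n - ai + 1) + gammaln(n - bj + 1)
                         - lgN - gammaln(nij + 1) - gammaln(ai - nij + 1)
                         - gammaln(bj - nij + 1)
                         - gammaln(n - ai - bj + nij + 1))
                emi += (nij / n) * math.log(n * nij / (ai * bj)) * math.exp(log_w)
    return emi


def adjusted_mutual_information(pred, truth) -> float:
    """AMI = (MI - E[MI]) / (mean(H(U), H(V)) - E[MI]); 1 for identical
    partitions, about 0 for independent ones."""
    t = ContingencyTable.from_labels(pred, truth)
    r, c = t.counts.shape
    if r == c == 1 or (r == c == t.total):
        return 1.0  # degenerate: both partitions trivial, hence identical
    n = t.total
    nz = t.counts > 0
    p = t.counts[nz] / n
    outer = np.outer(t.row_sums, t.col_sums)[nz] / (n * n)
    mi = float((p * np.log(p / outer)).sum())
    emi = expected_mutual_information(t)
    hu, hv = _entropy(t.row_sums), _entropy(t.col_sums)
    denom = (hu + hv) / 2.0 - emi
    if abs(denom) < 1e-15:
        denom = math.copysign(1e-15, denom if denom != 0 else 1.0)
    return float((mi - emi) / denom)


# ---------------------------------------------------------------------------
# QC metrics

def qc_average_pcc(X_qc: np.ndarray) -> float:
    """Mean Pearson correlation over all unordered pairs of QC samples.

    Replicates of one pooled sample should correlate perfectly (1). Pairs
    where either profile has zero variance are dropped from the average.
    """
    X_qc = np.asarray(X_qc, dtype=float)
    if X_qc.shape[0] < 2:
        raise ValidationError("aPCC needs at least 2 QC samples")
    vals = []
    for i, j in itertools.combinations(range(X_qc.shape[0]), 2):
        xi, xj = X_qc[i], X_qc[j]
        if xi.std() == 0 or xj.std() == 0:
            continue
        vals.append(np.corrcoef(xi, xj)[0, 1])
    if not vals:
        raise ValidationError("all QC pairs have a zero-variance profile")
    return float(np.mean(vals))


def qc_normalized_med(X_qc: np.ndarray, X_nonqc: np.ndarray) -> float:
    """Median pairwise Euclidean distance among QCs divided by the same
    median among non-QC samples; lower is better, ~1 means the QCs are no
    tighter than the biology."""
    X_qc = np.asarray(X_qc, dtype=float)
    X_nonqc = np.asarray(X_nonqc, dtype=float)
    if X_qc.shape[0] < 2 or X_nonqc.shape[0] < 2:
        raise ValidationError("nMED needs >= 2 QC and >= 2 non-QC samples")
    ref = float(np.median(pdist(X_nonqc)))
    if ref == 0:
        raise ValidationError("non-QC median distance is 0 (degenerate reference)")
    return float(np.median(pdist(X_qc)) / ref)


def matthews_cc(y_true, y_pred) -> float:
    """Matthews correlation coefficient (Gorodkin form for multiclass);
    1 iff perfect, 0 for constant predictions, in [-1, 1]."""
    y_true = np.asarray(y_true, dtype=object).astype(str)
    y_pred = np.asarray(y_pred, dtype=object).astype(str)
    if y_true.size == 0:
        raise ValidationError("MCC of empty input is undefined")
    if y_true.shape != y_pred.shape:
        raise ValidationError("label length mismatch")
    return float(matthews_corrcoef(y_true, y_pred))


# ---------------------------------------------------------------------------
# composite report

@dataclass
class MetricsReport:
    """One row of the benchmark panel: batch-mixing + QC + classification
    metrics for one representation of one split."""

    nBE: float | None
    ARI: float | None
    AMI: float | None
    aPCC: float | None = None
    nMED: float | None = None
    mcc: float | None = None
    accuracy: float | None = None
    split: str = "all"
    representation: str = "features"
    probe_fit: str = "all-samples"

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def evaluate_representation(X: np.ndarray, ds: OmicsDataset,
                            y_pred=None, probe: BatchProbe = BatchProbe(),
                            split: str = "all",
                            representation: str = "features") -> MetricsReport:
    """Fill the full metric panel for one representation.

    The batch probe is fit on all supplied samples; its argmax predictions
    feed ARI/AMI and its probabilities feed nBE. QC metrics appear iff the
    dataset carries QC samples; MCC/accuracy appear iff ``y_pred`` (labels
    for the non-QC samples, aligned with them) is given.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] != ds.n_samples:
        raise ValidationError(
            f"representation has {X.shape[0]} rows, dataset {ds.n_samples}")
    if len(set(ds.batch)) >= 2:
        P, levels = knn_batch_probabilities(X, ds.batch, probe)
        pred_batch = [levels[j] for j in P.argmax(axis=1)]
        report = MetricsReport(
            nBE=normalized_batch_entropy(P, K=len(levels)),
            ARI=adjusted_rand_index(pred_batch, ds.batch),
            AMI=adjusted_mutual_information(pred_batch, ds.batch),
            split=split, representation=representation)
    else:
        # a split holding a single batch has no batch mixing to measure
        report = MetricsReport(nBE=None, ARI=None, AMI=None, split=split,
                               representation=representation)
    if ds.is_qc.sum() >= 2 and (~ds.is_qc).sum() >= 2:
        report.aPCC = qc_average_pcc(X[ds.is_qc])
        report.nMED = qc_normalized_med(X[ds.is_qc], X[~ds.is_qc])
    if y_pred is not None:
        y_true = ds.cls[~ds.is_qc]
        y_pred = np.asarray(y_pred, dtype=object)
        if y_pred.shape[0] != y_true.shape[0]:
            raise ValidationError("y_pred must align with the non-QC samples")
        report.mcc = matthews_cc(y_true, y_pred)
        report.accuracy = float(accuracy_score(y_true.astype(str),
                                               y_pred.astype(str)))
    return report
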