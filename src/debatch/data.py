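"""Multi-batch omics tables: loading, validation, normalization and
batch-wise holdout splitting.

The in-memory currency is :class:`OmicsDataset`, a samples x features float
matrix (log-scale intensities by convention) with per-sample batch labels,
condition labels, a QC flag and an optional subject id. Pooled QC samples
carry the reserved condition label :data:`QC_LABEL`; they never enter
supervised losses or classification metrics but do participate in
unsupervised training and in the QC metrics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import JoinError, SchemaError, ValidationError

#: reserved condition label for pooled quality-control samples
QC_LABEL = "QC"

_REQUIRED_META = ("sample_id", "batch", "cls", "is_qc")


@dataclass
class OmicsDataset:
    """Samples x features intensity matrix with per-sample metadata."""

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    batch: np.ndarray          # categorical, one label per sample
    cls: np.ndarray            # condition label; QC_LABEL on QC samples
    is_qc: np.ndarray          # bool per sample
    subject_id: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.batch = np.asarray(self.batch, dtype=object)
        self.cls = np.asarray(self.cls, dtype=object)
        self.is_qc = np.asarray(self.is_qc, dtype=bool)
        self.validate()

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        n = self.values.shape[0]
        if not (len(self.sample_ids) == len(self.batch) == len(self.is_qc)
                == len(self.cls) == n):
            raise ValidationError(
                f"metadata length mismatch: {n} matrix rows, "
                f"{len(self.sample_ids)} sample ids, {len(self.batch)} batch "
                f"labels, {len(self.is_qc)} QC flags")
        if self.values.shape[1] != len(self.feature_ids):
            raise ValidationError("feature id count does not match matrix width")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("sample ids are not unique")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValidationError("feature ids are not unique")
        bad = ~np.isfinite(self.values)
        if bad.any():
            rows, cols = np.nonzero(bad)
            cells = [(self.sample_ids[r], self.feature_ids[c])
                     for r, c in zip(rows[:10], cols[:10])]
            raise ValidationError(
                f"non-finite values at {len(rows)} cells, first: {cells}")
        missing = [(sid, bool(q)) for sid, c, q
                   in zip(self.sample_ids, self.cls, self.is_qc)
                   if not q and (c is None or (isinstance(c, float) and np.isnan(c)))]
        if missing:
            raise ValidationError(
                f"{len(missing)} non-QC samples lack a condition label, "
                f"first: {missing[:5]}")
        if len(self.batches) < 1:
            raise ValidationError("at least one batch is required")

    # -- convenience -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def batches(self) -> list:
        return sorted(set(self.batch))

    @property
    def classes(self) -> list:
        """Condition labels observed on non-QC samples, sorted."""
        return sorted(set(self.cls[~self.is_qc]))

    def subset(self, mask: np.ndarray) -> "OmicsDataset":
        idx = np.flatnonzero(np.asarray(mask))
        return OmicsDataset(
            values=self.values[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            feature_ids=list(self.feature_ids),
            batch=self.batch[idx],
            cls=self.cls[idx],
            is_qc=self.is_qc[idx],
            subject_id=None if self.subject_id is None else self.subject_id[idx],
        )

    def batch_indices(self) -> np.ndarray:
        """Integer batch codes in the order of :attr:`batches`."""
        lut = {b: i for i, b in enumerate(self.batches)}
        return np.array([lut[b] for b in self.batch], dtype=int)

    def class_indices(self) -> np.ndarray:
        """Integer class codes (QC samples get -1)."""
        lut = {c: i for i, c in enumerate(self.classes)}
        return np.array([lut.get(c, -1) for c in self.cls], dtype=int)

    def with_values(self, values: np.ndarray) -> "OmicsDataset":
        return replace(self, values=np.asarray(values, dtype=float))

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        mat = pd.DataFrame(self.values, index=pd.Index(self.sample_ids, name="sample_id"),
                           columns=self.feature_ids)
        meta = pd.DataFrame({
            "sample_id": self.sample_ids,
            "batch": self.batch,
            "cls": self.cls,
            "is_qc": self.is_qc.astype(int),
        })
        if self.subject_id is not None:
            meta["subject_id"] = self.subject_id
        return mat, meta

    def write_csv(self, matrix_path, metadata_path) -> None:
        mat, meta = self.to_frames()
        mat.to_csv(matrix_path)
        meta.to_csv(metadata_path, index=False)


def _read_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


def load_dataset(matrix_path, metadata_path, *,
                 features_in_rows: bool = False) -> OmicsDataset:
    """Load an intensity matrix plus metadata table into an OmicsDataset.

    The matrix file has sample rows and feature columns, first column the
    sample id (pass ``features_in_rows=True`` for the transposed layout).
    Metadata needs columns sample_id, batch, cls, is_qc (subject_id optional).
    Values are used as stored — no implicit log transform.
    """
    mat = _read_table(matrix_path)
    mat = mat.set_index(mat.columns[0])
    if features_in_rows:
        mat = mat.T
    meta = _read_table(metadata_path)
    for col in _REQUIRED_META:
        if col not in meta.columns:
            raise SchemaError(f"metadata is missing required column '{col}'")
    meta = meta.copy()
    meta["sample_id"] = meta["sample_id"].astype(str)
    mat.index = mat.index.astype(str)

    mat_ids, meta_ids = set(mat.index), set(meta["sample_id"])
    if mat_ids != meta_ids:
        raise JoinError(
            f"sample mismatch: {len(mat_ids - meta_ids)} only in matrix, "
            f"{len(meta_ids - mat_ids)} only in metadata "
            f"({len(mat_ids & meta_ids)} shared)")
    meta = meta.set_index("sample_id").loc[mat.index].reset_index()

    qc = meta["is_qc"].map(
        {0: False, 1: True, "0": False, "1": True, True: True, False: False,
         "true": True, "false": False, "True": True, "False": False})
    if qc.isna().any():
        raise SchemaError("is_qc must be one of {0,1,true,false}")
    cls = meta["cls"].astype(object).where(~qc.astype(bool), QC_LABEL)
    cls = cls.where(cls.notna(), None)
    return OmicsDataset(
        values=mat.to_numpy(dtype=float),
        sample_ids=list(mat.index),
        feature_ids=[str(c) for c in mat.columns],
        batch=meta["batch"].astype(str).to_numpy(dtype=object),
        cls=cls.to_numpy(dtype=object),
        is_qc=qc.to_numpy(dtype=bool),
        subject_id=(meta["subject_id"].astype(str).to_numpy(dtype=object)
                    if "subject_id" in meta.columns else None),
    )


# ---------------------------------------------------------------------------
# normalization

_METHODS = ("minmax", "standard", "robust")


@dataclass(frozen=True)
class NormalizationSpec:
    """One of the scaling baselines: minmax / standard (z-score) / robust
    (median–IQR), fit globally or within each batch independently."""

    method: str
    per_batch: bool = False

    def __post_init__(self):
        if self.method not in _METHODS:
            raise SchemaError(f"unknown method '{self.method}', "
                              f"expected one of {_METHODS}")

    @property
    def name(self) -> str:
        return self.method + ("_per_batch" if self.per_batch else "")


def _scale_group(x: np.ndarray, method: str) -> np.ndarray:
    # zero-spread features map to 0 (center-only) in every method
    if method == "standard":
        center = x.mean(axis=0)
        scale = x.std(axis=0)
    elif method == "robust":
        center = np.median(x, axis=0)
        q75, q25 = np.percentile(x, [75, 25], axis=0)
        scale = q75 - q25
    else:  # minmax
        center = x.min(axis=0)
        scale = x.max(axis=0) - center
    scale = np.where(scale == 0, 1.0, scale)
    return (x - center) / scale


def normalize_dataset(ds: OmicsDataset, spec: NormalizationSpec) -> OmicsDataset:
    """Scale each feature within its fit group (whole dataset or each batch).

    Per-batch z-scoring forces every batch to mean 0 and unit variance, the
    strongest of the scaling baselines against additive batch shifts. QC
    samples are transformed with the statistics of the batch they sit in.
    """
    out = np.empty_like(ds.values)
    if spec.per_batch:
        for b in ds.batches:
            m = ds.batch == b
            if spec.method in ("standard", "robust") and m.sum() < 2:
                raise ValidationError(
                    f"batch '{b}' has {int(m.sum())} sample(s); per-batch "
                    f"{spec.method} scaling needs at least 2")
            out[m] = _scale_group(ds.values[m], spec.method)
    else:
        out[:] = _scale_group(ds.values, spec.method)
    return ds.with_values(out)


# ---------------------------------------------------------------------------
# batch-wise repetitive holdout

@dataclass(frozen=True)
class SplitPlan:
    """Whole-batch assignment to train/valid/test for one holdout iteration."""

    iteration: int
    seed: int
    train_batches: frozenset
    valid_batches: frozenset
    test_batches: frozenset

    def __post_init__(self):
        sets = (self.train_batches, self.valid_batches, self.test_batches)
        if any(not s for s in sets):
            raise ValidationError("every split must receive at least one batch")
        total = sum(len(s) for s in sets)
        if len(self.train_batches | self.valid_batches | self.test_batches) != total:
            raise ValidationError("splits must be pairwise disjoint")

    def split_of(self, batch_label) -> str:
        if batch_label in self.train_batches:
            return "train"
        if batch_label in self.valid_batches:
            return "valid"
        if batch_label in self.test_batches:
            return "test"
        raise KeyError(f"batch '{batch_label}' not in this plan")

    def mask(self, ds: OmicsDataset, split: str) -> np.ndarray:
        want = {"train": self.train_batches, "valid": self.valid_batches,
                "test": self.test_batches}[split]
        return np.array([b in want for b in ds.batch])

    def to_dict(self) -> dict:
        return {"iteration": self.iteration, "seed": self.seed,
                "train_batches": sorted(self.train_batches),
                "valid_batches": sorted(self.valid_batches),
                "test_batches": sorted(self.test_batches)}


def make_holdout_splits(ds: OmicsDataset, n_iterations: int,
                        valid_fraction: float = 0.2,
                        test_fraction: float = 0.2,
                        seed: int = 0) -> list[SplitPlan]:
    """Repetitive holdout over *batches*: every batch lands wholly in one
    split and the test set is resampled each iteration (seeded)."""
    batches = ds.batches
    if len(batches) < 3:
        raise ValidationError(
            f"need at least 3 batches to form train/valid/test, got {len(batches)}")
    if not (0 < valid_fraction < 1 and 0 < test_fraction < 1
            and valid_fraction + test_fraction < 1):
        raise ValidationError("fractions must lie in (0,1) and sum below 1")
    rng = np.random.default_rng(seed)
    plans = []
    for it in range(n_iterations):
        order = list(rng.permutation(len(batches)))
        n_valid = max(1, round(valid_fraction * len(batches)))
        n_test = max(1, round(test_fraction * len(batches)))
        n_valid = min(n_valid, len(batches) - 2)
        n_test = min(n_test, len(batches) - n_valid - 1)
        valid = frozenset(batches[i] for i in order[:n_valid])
        test = frozenset(batches[i] for i in order[n_valid:n_valid + n_test])
        train = frozenset(batches[i] for i in order[n_valid + n_test:])
        plans.append(SplitPlan(iteration=it, seed=seed, train_batches=train,
                               valid_batches=valid, test_batches=test))
    return plans


def save_split_plans(plans: list[SplitPlan], path) -> None:
    with open(path, "w") as fh:
        json.dump([p.to_dict() for p in plans], fh, indent=2)


def class_weights(cls_labels) -> np.ndarray:
    """Per-sample weights inversely proportional to class frequencies,
    used for weighted sampling of supervised minibatches."""
    labels = np.asarray(cls_labels, dtype=object)
    if labels.size == 0:
        raise ValidationError("cannot weight an empty label vector")
    uniq, counts = np.unique(labels.astype(str), return_counts=True)
    lut = dict(zip(uniq, 1.0 / counts))
    return np.array([lut[str(c)] for c in labels], dtype=float)
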