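"""End-to-end benchmark: run scaling baselines and the model grid on one
dataset under the same repetitive batch-wise holdout, and collect the full
metric panel in one tidy table (one row per method x iteration x split).

Scaling baselines are evaluated in the (corrected) feature space with a
classical classifier; network models are evaluated in their bottleneck
space with their own label classifier — matching how each family is meant
to be used.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import (NormalizationSpec, OmicsDataset, load_dataset,
                   make_holdout_splits, normalize_dataset)
from .errors import ValidationError
from .metrics import BatchProbe, evaluate_representation
from .models import REMOVALS, ModelSpec, build_model
from .simulate import SyntheticConfig, generate_synthetic
from .training import (TrainConfig, baseline_classify, hyperparameter_search,
                       run_repetitive_holdout, warmup)

_SCALERS = ["minmax", "standard", "robust",
            "minmax_per_batch", "standard_per_batch", "robust_per_batch"]
_GRID = [f"{bb}-{rm}" for bb in ("AE", "VAE") for rm in REMOVALS]
KNOWN_METHODS = ["raw"] + _SCALERS + _GRID

_METRIC_COLS = ["nBE", "ARI", "AMI", "aPCC", "nMED", "mcc", "accuracy"]


@dataclass
class BenchmarkResult:
    """Tidy per-(method, iteration, split) metric rows."""

    rows: pd.DataFrame

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False, float_format="%.10g")

    def to_json(self, path) -> None:
        self.rows.to_json(path, orient="records", indent=2)


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _resolve_dataset(cfg: dict) -> OmicsDataset:
    spec = cfg.get("dataset", {})
    if "synthetic" in spec:
        ds, _ = generate_synthetic(SyntheticConfig(**spec["synthetic"]))
        return ds
    if "matrix" in spec and "metadata" in spec:
        return load_dataset(spec["matrix"], spec["metadata"])
    raise ValidationError(
        "config needs dataset.synthetic or dataset.matrix+metadata")


def _report_rows(method, representation, iteration, report) -> dict:
    row = {"method": method, "representation": representation,
           "iteration": iteration, "split": report.split}
    for col in _METRIC_COLS:
        row[col] = getattr(report, col)
    return row


def run_benchmark(config, out_dir=None) -> BenchmarkResult:
    """Run every requested method on the configured dataset.

    Config keys: ``dataset`` (synthetic cfg or matrix/metadata paths),
    ``methods`` (subset of KNOWN_METHODS), ``n_iterations``, ``seed``,
    ``baseline`` (classifier kind for non-network methods), ``train``
    (TrainConfig overrides), ``model`` (ModelSpec overrides) and optional
    ``search_budget`` to tune each grid cell by random search.
    """
    cfg = _load_config(config)
    methods = cfg.get("methods", KNOWN_METHODS)
    unknown = [m for m in methods if m not in KNOWN_METHODS]
    if unknown:
        raise ValidationError(
            f"unknown methods {unknown}; valid: {KNOWN_METHODS}")
    ds = _resolve_dataset(cfg)
    n_iterations = int(cfg.get("n_iterations", 3))
    seed = int(cfg.get("seed", 0))
    baseline_kind = cfg.get("baseline", "linear-SVM")
    train_cfg = TrainConfig(seed=seed, **cfg.get("train", {}))
    model_overrides = cfg.get("model", {})
    budget = cfg.get("search_budget")
    probe = BatchProbe(k=int(cfg.get("probe_k", 20)))

    plans = make_holdout_splits(ds, n_iterations, seed=seed)
    rows = []
    for method in methods:
        if method in ("raw", *_SCALERS):
            if method == "raw":
                X = ds.values
            else:
                parts = method.split("_per_batch")
                norm = NormalizationSpec(method=parts[0],
                                         per_batch=method.endswith("per_batch"))
                X = normalize_dataset(ds, norm).values
            panel = evaluate_representation(X, ds, probe=probe, split="all",
                                            representation="features")
            for plan in plans:
                _, reports = baseline_classify(X, ds, plan, kind=baseline_kind,
                                               seed=seed, probe=probe)
                for split in ("valid", "test"):
                    rows.append(_report_rows(method, "features",
                                             plan.iteration, reports[split]))
                rows.append(_report_rows(method, "features",
                                         plan.iteration, panel))
        else:
            backbone, removal = method.split("-")
            if budget:
                trial = hyperparameter_search(
                    ds, backbone, removal, budget=int(budget), seed=seed,
                    n_iterations=n_iterations, base_cfg=train_cfg)
            else:
                kw = dict(model_overrides)
                if removal in ("invTriplet", "revTriplet"):
                    kw.setdefault("margin", 1.0)
                spec = ModelSpec(backbone=backbone, removal=removal, **kw)
                trial = run_repetitive_holdout(ds, spec, train_cfg,
                                               n_iterations, seed=seed,
                                               probe=probe)
            for rep_list in (trial.valid_reports, trial.test_reports,
                             trial.all_reports):
                for it, report in enumerate(rep_list):
                    rows.append(_report_rows(method, "bottleneck", it, report))

    df = pd.DataFrame(rows).sort_values(
        ["method", "iteration", "split"]).reset_index(drop=True)
    result = BenchmarkResult(rows=df)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.to_csv(out / "benchmark.csv")
        result.to_json(out / "benchmark.json")
        summarize(result).to_csv(out / "summary.csv", index=False,
                                 float_format="%.10g")
    return result


def summarize(result: BenchmarkResult) -> pd.DataFrame:
    """Per-method mean +/- SD of every metric over iterations, ranked by
    mean validation MCC (single-iteration SDs are 0 by convention)."""
    if result.rows.empty:
        raise ValidationError("cannot summarize an empty result")
    df = result.rows
    agg = df.groupby(["method", "split"])[_METRIC_COLS].agg(["mean", "std"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    agg = agg.reset_index().fillna({f"{m}_std": 0.0 for m in _METRIC_COLS})
    order = (agg[agg["split"] == "valid"]
             .sort_values("mcc_mean", ascending=False)["method"].tolist())
    agg["rank"] = agg["method"].map({m: i for i, m in enumerate(order)})
    return agg.sort_values(["rank", "split"]).drop(columns="rank") \
              .reset_index(drop=True)


def export_corrected_features(model, ds: OmicsDataset,
                              reference_batch: int = 0) -> np.ndarray:
    """Decode every sample's bottleneck through a single reference batch
    mapping, yielding a "corrected" feature matrix.

    Not recommended for downstream analysis: the decoder cannot improve on
    the bottleneck, and reconstruction fidelity is only one of several
    competing loss terms. Prefer the bottleneck plus feature attribution.
    """
    z = model.embed(ds.values)
    ref = np.full(ds.n_samples, reference_batch, dtype=int)
    return model.decode(z, ref).data


def plot_mcc_tradeoff(result: BenchmarkResult, out_path,
                      metric: str = "nBE") -> None:
    """Scatter of mean validation MCC against a batch-mixing/QC metric,
    one point per method. Requires matplotlib."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = result.rows[result.rows["split"] == "valid"]
    means = df.groupby("method")[[metric, "mcc"]].mean()
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(means[metric], means["mcc"])
    for name, row in means.iterrows():
        ax.annotate(name, (row[metric], row["mcc"]), fontsize=7)
    ax.set_xlabel(metric)
    ax.set_ylabel("validation MCC")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
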