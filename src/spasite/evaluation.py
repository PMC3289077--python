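"""Evaluation: confusion-count metrics, 5-fold cross-validation, window sweep.

Metrics with a zero denominator are reported as ``None`` (explicitly
undefined), never silently zero.  Pooled cross-validation metrics are
computed from summed confusion counts rather than averaged per-fold values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyCountsError, SplitError
from .features import FeatureTable
from . import svmknn

logger = logging.getLogger(__name__)

DEFAULT_FOLDS = 5


@dataclass
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "TN", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def N(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP, self.FP + other.FP, self.TN + other.TN, self.FN + other.FN
        )

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        if y_true.shape != y_pred.shape:
            raise ValueError("y_true and y_pred must align")
        return cls(
            TP=int(np.sum((y_true == 1) & (y_pred == 1))),
            FP=int(np.sum((y_true == 0) & (y_pred == 1))),
            TN=int(np.sum((y_true == 0) & (y_pred == 0))),
            FN=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


@dataclass
class MetricsReport:
    """Q, Sen, Spe in [0,1]; MCC in [-1,1]; undefined metrics are None."""

    Q: float | None
    Sen: float | None
    Spe: float | None
    MCC: float | None
    counts: ConfusionCounts

    def as_dict(self) -> dict:
        return {
            "Q": self.Q,
            "Sen": self.Sen,
            "Spe": self.Spe,
            "MCC": self.MCC,
            "TP": self.counts.TP,
            "FP": self.counts.FP,
            "TN": self.counts.TN,
            "FN": self.counts.FN,
        }


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Accuracy Q=(TP+TN)/N, sensitivity TP/(TP+FN), specificity TN/(TN+FP),
    and Matthews correlation (TP*TN - FP*FN) / sqrt(prod of marginals)."""
    if c.N == 0:
        raise EmptyCountsError("cannot compute metrics on empty counts")
    q = (c.TP + c.TN) / c.N
    sen = c.TP / (c.TP + c.FN) if (c.TP + c.FN) > 0 else None
    spe = c.TN / (c.TN + c.FP) if (c.TN + c.FP) > 0 else None
    denom = (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    mcc = (c.TP * c.TN - c.FP * c.FN) / math.sqrt(denom) if denom > 0 else None
    return MetricsReport(q, sen, spe, mcc, c)


def _residue_folds(labels: np.ndarray, folds: int, seed: int) -> list[np.ndarray]:
    from sklearn.model_selection import StratifiedKFold

    for cls in (0, 1):
        if int(np.sum(labels == cls)) < folds:
            raise SplitError(f"class {cls} has fewer than {folds} samples")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros((len(labels), 1)), labels)]


def _chain_folds(provenance: list[tuple[str, int]], folds: int, seed: int) -> list[np.ndarray]:
    chains = sorted({cid for cid, _ in provenance})
    if len(chains) < folds:
        raise SplitError(f"{len(chains)} chains cannot form {folds} chain-level folds")
    rng = np.random.default_rng(seed)
    shuffled = list(rng.permutation(chains))
    assignment = {cid: i % folds for i, cid in enumerate(shuffled)}
    idx = np.arange(len(provenance))
    return [idx[[assignment[cid] == f for cid, _ in provenance]] for f in range(folds)]


def cross_validate(
    features: FeatureTable,
    folds: int = DEFAULT_FOLDS,
    split_unit: str = "residue",
    seed: int = 0,
    **model_params,
) -> tuple[list[MetricsReport], MetricsReport]:
    """K-fold cross-validation of the hybrid classifier.

    ``split_unit='residue'`` uses class-stratified residue-level folds;
    ``'chain'`` keeps whole chains in a single fold to control homology
    leakage.  Returns (per-fold reports, pooled report from summed counts).
    """
    if split_unit == "residue":
        test_sets = _residue_folds(features.labels, folds, seed)
    elif split_unit == "chain":
        test_sets = _chain_folds(features.provenance, folds, seed)
    else:
        raise ValueError(f"unknown split unit: {split_unit!r}")

    per_fold: list[MetricsReport] = []
    pooled = ConfusionCounts()
    all_idx = np.arange(len(features))
    for test_idx in test_sets:
        train_mask = np.ones(len(features), dtype=bool)
        train_mask[test_idx] = False
        train_idx = all_idx[train_mask]
        model = svmknn.train(
            (features.X[train_idx], features.labels[train_idx]), **model_params
        )
        y_pred, _ = svmknn.predict(model, features.X[test_idx])
        counts = ConfusionCounts.from_predictions(features.labels[test_idx], y_pred)
        per_fold.append(compute_metrics(counts))
        pooled = pooled + counts
    return per_fold, compute_metrics(pooled)


def window_sweep(
    featurize,
    w_values: list[int],
    folds: int = DEFAULT_FOLDS,
    split_unit: str = "residue",
    seed: int = 0,
    **model_params,
) -> list[dict]:
    """Cross-validate one encoding at several window widths.

    ``featurize`` is a callable ``w -> FeatureTable`` (the caller binds the
    structure, profile, annotations and encoding).  Returns one row per w
    with the pooled metrics.
    """
    results = []
    for w in w_values:
        table = featurize(w)
        _, pooled = cross_validate(
            table, folds=folds, split_unit=split_unit, seed=seed, **model_params
        )
        row = {"w": w}
        row.update(pooled.as_dict())
        results.append(row)
    return results


def write_sweep_tsv(rows: list[dict], path) -> None:
    cols = ["w", "Q", "Sen", "Spe", "MCC"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write(
                "\t".join(
                    "NA" if row[c] is None else (str(row[c]) if c == "w" else f"{row[c]:.6f}")
                    for c in cols
                )
                + "\n"
            )


def format_report(report: MetricsReport) -> str:
    """Human-readable one-block summary."""
    def fmt(v):
        return "undefined" if v is None else f"{v:.4f}"

    c = report.counts
    return (
        f"N={c.N}  TP={c.TP} FP={c.FP} TN={c.TN} FN={c.FN}\n"
        f"Q={fmt(report.Q)}  Sen={fmt(report.Sen)}  Spe={fmt(report.Spe)}  MCC={fmt(report.MCC)}"
    )
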