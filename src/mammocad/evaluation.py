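"""Classification metrics, stratified cross-validation, group comparison
and the preprocessing ablation grid.

Metric definitions (with 'abnormal' as the positive class):

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)          (recall)
    specificity = TN / (TN + FP)
    precision   = TP / (TP + FP)
    F1          = 2 * precision * sensitivity / (precision + sensitivity)

Ratios with a zero denominator are reported as 0 with a warning so that a
degenerate fold does not abort a cross-validation run. Cross-validation is
stratified: each fold's class proportions differ from the global ones by at
most one sample, and all fold assignments are deterministic in the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import LabelledDataset, LABELS, NORMAL, ABNORMAL

__all__ = ["ConfusionMatrix", "MetricsReport", "AblationConfig",
           "confusion", "compute_metrics", "stratified_kfold",
           "crossvalidate", "compare_feature_groups", "run_ablation",
           "ABLATION_STAGES"]

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision", "f1")
ABLATION_STAGES = ("contrast", "median", "otsu", "shearlet", "canny")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion matrix must contain at least one case")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    per_fold: list[dict] = field(default_factory=list)
    mean_sd: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {m: getattr(self, m) for m in METRIC_NAMES}

    def summary_frame(self) -> pd.DataFrame:
        if self.per_fold:
            df = pd.DataFrame(self.per_fold)
            df.index.name = "fold"
            return df
        return pd.DataFrame([self.as_dict()])


@dataclass(frozen=True)
class AblationConfig:
    stages_enabled: frozenset = frozenset(ABLATION_STAGES)

    def __post_init__(self) -> None:
        bad = set(self.stages_enabled) - set(ABLATION_STAGES)
        if bad:
            raise ValueError(f"unknown ablation stages: {sorted(bad)}")

    @property
    def name(self) -> str:
        if not self.stages_enabled:
            return "none"
        if set(self.stages_enabled) == set(ABLATION_STAGES):
            return "full"
        return "+".join(s for s in ABLATION_STAGES if s in self.stages_enabled)


def confusion(labels, preds, positive: str = ABNORMAL) -> ConfusionMatrix:
    """Tally a confusion matrix with ``positive`` as the disease class."""
    labels = list(labels)
    preds = list(preds)
    if len(labels) != len(preds) or not labels:
        raise ValueError("labels and predictions must be equal-length, non-empty")
    for v in set(labels) | set(preds):
        if v not in LABELS:
            raise ValueError(f"label {v!r} outside the two-class set")
    tp = sum(1 for t, p in zip(labels, preds) if t == positive and p == positive)
    tn = sum(1 for t, p in zip(labels, preds) if t != positive and p != positive)
    fp = sum(1 for t, p in zip(labels, preds) if t != positive and p == positive)
    fn = sum(1 for t, p in zip(labels, preds) if t == positive and p != positive)
    return ConfusionMatrix(tp, tn, fp, fn)


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: zero denominator, reporting 0")
        return 0.0
    return num / den


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    accuracy = (cm.tp + cm.tn) / cm.total
    sensitivity = _ratio(cm.tp, cm.tp + cm.fn, "sensitivity")
    specificity = _ratio(cm.tn, cm.tn + cm.fp, "specificity")
    precision = _ratio(cm.tp, cm.tp + cm.fp, "precision")
    if precision + sensitivity == 0:
        warnings.warn("f1: zero denominator, reporting 0")
        f1 = 0.0
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    return MetricsReport(accuracy, sensitivity, specificity, precision, f1)


def stratified_kfold(labels, k: int, seed: int) -> list[np.ndarray]:
    """Disjoint index folds with per-fold class counts within 1 of
    proportionality; deterministic in ``seed``."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < k:
            raise ValueError(f"class {cls!r} has fewer than k={k} members")
        idx = rng.permutation(idx)
        for j, i in enumerate(idx):
            folds[j % k].append(int(i))
    return [np.sort(np.array(f)) for f in folds]


def _aggregate(per_fold: list[MetricsReport]) -> MetricsReport:
    rows = [m.as_dict() for m in per_fold]
    mean_sd = {
        m: (float(np.mean([r[m] for r in rows])),
            float(np.std([r[m] for r in rows], ddof=1)) if len(rows) > 1 else 0.0)
        for m in METRIC_NAMES
    }
    agg = MetricsReport(*[mean_sd[m][0] for m in METRIC_NAMES],
                        per_fold=rows, mean_sd=mean_sd)
    return agg


def crossvalidate(data: LabelledDataset, config=None, k: int = 5,
                  seed: int = 0, features: np.ndarray | None = None,
                  images: np.ndarray | None = None) -> MetricsReport:
    """Stratified k-fold cross-validation of the full classifier.

    Per fold, the feature normaliser and the network are fitted on the
    training indices only and evaluated on the held-out fold; the report
    carries per-fold metrics plus mean +/- SD. ``config`` is a
    :class:`~mammocad.pipeline.PipelineConfig` (defaults used when None).
    ``images``/``features`` may carry precomputed deterministic pipeline
    outputs (stacked model inputs and hybrid feature rows) to avoid
    recomputing them per fold; they are produced with the config's own
    preprocessing when absent.
    """
    from .pipeline import PipelineConfig, prepare_inputs

    config = config or PipelineConfig()
    if images is None or (features is None and config.model.fusion):
        images, features = prepare_inputs(data, config)
    labels = np.asarray(data.labels)
    folds = stratified_kfold(labels, k, seed)
    per_fold = []
    for fi, test_idx in enumerate(folds):
        train_idx = np.sort(np.concatenate(
            [folds[j] for j in range(k) if j != fi]))
        model = config.build_model(seed=seed * 1000 + fi)
        model.train(
            images[train_idx],
            features=features[train_idx] if features is not None else None,
            cfg=config.train_config(seed=seed * 1000 + fi),
            labels=labels[train_idx].tolist(),
        )
        _, preds = model.predict(
            images[test_idx],
            features=features[test_idx] if features is not None else None)
        per_fold.append(compute_metrics(confusion(labels[test_idx], preds)))
    return _aggregate(per_fold)


def compare_feature_groups(features: pd.DataFrame, labels,
                           method: str = "welch", n_perm: int = 10000,
                           seed: int = 0) -> pd.DataFrame:
    """Per-feature class means and a two-sided p-value (Welch t-test or a
    seeded label-permutation test of the mean difference)."""
    from scipy import stats

    labels = np.asarray(labels)
    a = features.loc[labels == NORMAL].to_numpy(dtype=np.float64)
    b = features.loc[labels == ABNORMAL].to_numpy(dtype=np.float64)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both classes must be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 41]))
    pooled = np.concatenate([a, b], axis=0)
    na = len(a)
    obs = np.abs(b.mean(axis=0) - a.mean(axis=0))

    perm_p = None
    needs_perm = method == "permutation" or any(
        a[:, j].std(ddof=1) == 0 and b[:, j].std(ddof=1) == 0
        for j in range(pooled.shape[1]))
    if needs_perm:
        # one shared row permutation per resample, applied to every feature
        exceed = np.zeros(pooled.shape[1], dtype=np.int64)
        for _ in range(n_perm):
            perm = rng.permutation(len(pooled))
            diff = np.abs(pooled[perm[na:]].mean(axis=0)
                          - pooled[perm[:na]].mean(axis=0))
            exceed += diff >= obs - 1e-15
        perm_p = (exceed + 1) / (n_perm + 1)

    rows = []
    for j, name in enumerate(features.columns):
        xa, xb = a[:, j], b[:, j]
        use_perm = method == "permutation"
        if method == "welch" and xa.std(ddof=1) == 0 and xb.std(ddof=1) == 0:
            warnings.warn(f"{name}: zero variance, falling back to permutation")
            use_perm = True
        if use_perm:
            p = float(perm_p[j])
        else:
            p = float(stats.ttest_ind(xa, xb, equal_var=False).pvalue)
        rows.append({"feature": name, "mean_normal": float(xa.mean()),
                     "mean_abnormal": float(xb.mean()), "p_value": p})
    return pd.DataFrame(rows).set_index("feature")


def run_ablation(grid: list[AblationConfig], data: LabelledDataset,
                 config=None, k: int = 5, seed: int = 0) -> pd.DataFrame:
    """Cross-validate once per ablation configuration; rows are configs,
    columns the aggregate metrics."""
    from .pipeline import PipelineConfig

    if not grid:
        raise ValueError("ablation grid must be non-empty")
    config = config or PipelineConfig()
    rows = []
    for ab in grid:
        cfg = config.with_stages(ab.stages_enabled)
        report = crossvalidate(data, cfg, k=k, seed=seed)
        row = {"config": ab.name}
        row.update(report.as_dict())
        rows.append(row)
    return pd.DataFrame(rows).set_index("config")
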