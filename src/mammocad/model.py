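"""Model/Results facade over the classification pipeline.

`MammogramClassifier` bundles a labelled dataset with a pipeline
configuration; :meth:`fit` runs stratified k-fold cross-validation of the
BiLSTM-CNN (optionally fused with the hybrid texture features) and returns
a :class:`ClassificationResults` carrying per-fold metrics, their
mean +/- SD and a ``summary()`` table, in the spirit of statsmodels'
model/results split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import METRIC_NAMES, MetricsReport, crossvalidate
from .io_formats import LabelledDataset
from .nn import BiLstmCnn
from .pipeline import PipelineConfig, prepare_inputs

__all__ = ["MammogramClassifier", "ClassificationResults"]


class MammogramClassifier:
    """Two-class (normal/abnormal) mammogram classifier.

    Parameters
    ----------
    data:
        The labelled images.
    config:
        Pipeline configuration; defaults to the full-width published
        architecture (use ``PipelineConfig.test_scale()`` on a CPU budget).
    """

    def __init__(self, data: LabelledDataset,
                 config: PipelineConfig | None = None):
        self.data = data
        self.config = config or PipelineConfig()
        self._cache: tuple[np.ndarray, np.ndarray] | None = None

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, images: list,
                       config: PipelineConfig | None = None
                       ) -> "MammogramClassifier":
        """Build from a manifest-style frame with 'id' and 'label' columns
        plus a parallel list of GrayImage."""
        data = LabelledDataset(images, frame["label"].tolist(),
                               frame["id"].astype(str).tolist())
        return cls(data, config)

    def _inputs(self) -> tuple[np.ndarray, np.ndarray]:
        if self._cache is None:
            self._cache = prepare_inputs(self.data, self.config)
        return self._cache

    def fit(self, k: int | None = None, seed: int | None = None
            ) -> "ClassificationResults":
        """Cross-validated fit; returns the results object."""
        k = k or self.config.evaluate.k
        seed = self.config.seed if seed is None else seed
        images, feats = self._inputs()
        report = crossvalidate(self.data, self.config, k=k, seed=seed,
                               images=images, features=feats)
        return ClassificationResults(self, report, k, seed)

    def fit_full(self, seed: int | None = None) -> BiLstmCnn:
        """Train one model on the entire dataset (no held-out metrics)."""
        seed = self.config.seed if seed is None else seed
        images, feats = self._inputs()
        model = self.config.build_model(seed=seed)
        model.train(images,
                    features=feats if self.config.model.fusion else None,
                    cfg=self.config.train_config(seed=seed),
                    labels=self.data.labels)
        return model


@dataclass
class ClassificationResults:
    model: MammogramClassifier
    report: MetricsReport
    k: int
    seed: int

    def __getattr__(self, name):
        if name in METRIC_NAMES:
            return getattr(self.report, name)
        raise AttributeError(name)

    @property
    def per_fold(self) -> pd.DataFrame:
        return self.report.summary_frame()

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Mammogram BiLSTM-CNN classification (stratified "
            f"{self.k}-fold CV, seed {self.seed})",
            f"n = {len(self.model.data)} images, "
            f"fusion = {cfg.model.fusion}, "
            f"channel_scale = {cfg.model.channel_scale}",
            f"config digest = {cfg.digest()}",
            "-" * 64,
            f"{'metric':<14}{'mean':>10}{'sd':>10}",
        ]
        for m in METRIC_NAMES:
            mean, sd = self.report.mean_sd[m]
            lines.append(f"{m:<14}{mean:>10.4f}{sd:>10.4f}")
        return "\n".join(lines)
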