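"""Pipeline configuration and the preprocess->segment->features chain.

A :class:`PipelineConfig` gathers every tunable of the pipeline in nested
sections (``preprocess``, ``otsu``, ``canny``, ``features``, ``model``,
``train``, ``simulate``, ``evaluate``) plus a global seed. Configs load
from YAML with unknown keys rejected, and hash stably so runs can be
reproduced from their logged snapshot.

``prepare_inputs`` maps a labelled dataset to the two classifier inputs:
the stack of preprocessed images (CNN branch) and the table of 49 hybrid
texture features computed on the segmented ROI (fusion branch). The five
ablation stages - contrast, median, shearlet (preprocessing) and otsu,
canny (segmentation) - can be toggled; with every stage off the chain
degenerates to a bare resize and whole-image features.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .features import assemble_hybrid, hybrid_feature_names
from .io_formats import GrayImage, LabelledDataset
from .nn import ArchitectureSpec, BiLstmCnn, TrainConfig
from .preprocess import contrast_stretch, median_filter3, resize_image
from .segmentation import (BinaryMask, RoiBox, SegmentationError, canny_edges,
                           crop_breast_region, extract_roi,
                           improved_otsu_threshold)
from .shearlet import EnhanceParams, build_shearlet_system, shearlet_enhance

__all__ = ["PipelineConfig", "ConfigError", "prepare_inputs", "feature_table",
           "preprocess_image", "segment_image", "DEFAULT_STAGES"]

DEFAULT_STAGES = frozenset({"contrast", "median", "otsu", "shearlet", "canny"})


class ConfigError(ValueError):
    """Unknown or invalid configuration key."""


@dataclass(frozen=True)
class PreprocessConfig:
    target_size: int = 224
    n_scales: int = 3
    gain: float = 1.5
    scales_amplified: tuple[int, ...] = (1, 2)


@dataclass(frozen=True)
class OtsuConfig:
    alpha: float = 1.0
    window: int = 15


@dataclass(frozen=True)
class CannyConfig:
    low: float = 0.1
    high: float = 0.3
    sigma: float = 1.4


@dataclass(frozen=True)
class FeaturesConfig:
    ng: int = 32
    symmetric_glcm: bool = True


@dataclass(frozen=True)
class RoiConfig:
    pad: int = 20


@dataclass(frozen=True)
class PectoralConfig:
    # off by default: the corner heuristic is meant for views that contain a
    # pectoral wedge (MIAS MLO images, phantoms generated with pectoral=True)
    remove: bool = False


@dataclass(frozen=True)
class ModelConfig:
    input_size: int = 224
    channel_scale: float = 1.0
    bilstm_hidden_total: int = 128
    dense_units: int = 128
    head_dropout: float = 0.5
    fusion: bool = True


@dataclass(frozen=True)
class TrainSection:
    learning_rate: float = 0.001
    batch_size: int = 32
    epochs: int = 50


@dataclass(frozen=True)
class SimulateConfig:
    n_per_class: int = 50
    lesion_contrast: float = 60.0
    lesion_radius: tuple[float, float] = (20.0, 35.0)
    noise_sd: float = 5.0
    pectoral: bool = False


@dataclass(frozen=True)
class EvaluateConfig:
    k: int = 5


_SECTIONS = {
    "preprocess": PreprocessConfig,
    "otsu": OtsuConfig,
    "canny": CannyConfig,
    "features": FeaturesConfig,
    "roi": RoiConfig,
    "pectoral": PectoralConfig,
    "model": ModelConfig,
    "train": TrainSection,
    "simulate": SimulateConfig,
    "evaluate": EvaluateConfig,
}


@dataclass(frozen=True)
class PipelineConfig:
    preprocess: PreprocessConfig = PreprocessConfig()
    otsu: OtsuConfig = OtsuConfig()
    canny: CannyConfig = CannyConfig()
    features: FeaturesConfig = FeaturesConfig()
    roi: RoiConfig = RoiConfig()
    pectoral: PectoralConfig = PectoralConfig()
    model: ModelConfig = ModelConfig()
    train: TrainSection = TrainSection()
    simulate: SimulateConfig = SimulateConfig()
    evaluate: EvaluateConfig = EvaluateConfig()
    seed: int = 0
    stages: frozenset = DEFAULT_STAGES

    @classmethod
    def test_scale(cls, **overrides) -> "PipelineConfig":
        """CPU-friendly defaults: 1/8-width conv channels, short training."""
        cfg = cls(
            model=ModelConfig(channel_scale=0.125),
            train=TrainSection(batch_size=8, epochs=3),
        )
        return replace(cfg, **overrides) if overrides else cfg

    # -- (de)serialisation --------------------------------------------------

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = {}
        for key, value in (raw or {}).items():
            if key == "seed":
                kwargs["seed"] = int(value)
            elif key == "stages":
                bad = set(value) - set(DEFAULT_STAGES)
                if bad:
                    raise ConfigError(f"unknown stage(s) {sorted(bad)}")
                kwargs["stages"] = frozenset(value)
            elif key in _SECTIONS:
                section_cls = _SECTIONS[key]
                known = {f.name for f in fields(section_cls)}
                unknown = set(value) - known
                if unknown:
                    raise ConfigError(
                        f"unknown key '{key}.{sorted(unknown)[0]}'")
                coerced = dict(value)
                if key == "preprocess" and "scales_amplified" in coerced:
                    coerced["scales_amplified"] = tuple(
                        coerced["scales_amplified"])
                if key == "simulate" and "lesion_radius" in coerced:
                    coerced["lesion_radius"] = tuple(coerced["lesion_radius"])
                kwargs[key] = section_cls(**coerced)
            else:
                raise ConfigError(f"unknown key '{key}'")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        out = {name: asdict(getattr(self, name)) for name in _SECTIONS}
        out["preprocess"]["scales_amplified"] = list(
            out["preprocess"]["scales_amplified"])
        out["simulate"]["lesion_radius"] = list(
            out["simulate"]["lesion_radius"])
        out["seed"] = self.seed
        out["stages"] = sorted(self.stages)
        return out

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    # -- derived objects ----------------------------------------------------

    def with_stages(self, stages) -> "PipelineConfig":
        bad = set(stages) - set(DEFAULT_STAGES)
        if bad:
            raise ConfigError(f"unknown stage(s) {sorted(bad)}")
        return replace(self, stages=frozenset(stages))

    def architecture(self) -> ArchitectureSpec:
        m = self.model
        return ArchitectureSpec(
            input_size=m.input_size,
            channel_scale=m.channel_scale,
            bilstm_hidden_total=m.bilstm_hidden_total,
            dense_units=m.dense_units,
            head_dropout=m.head_dropout,
            fusion_dim=len(hybrid_feature_names()) if m.fusion else 0,
        )

    def build_model(self, seed: int | None = None) -> BiLstmCnn:
        return BiLstmCnn(self.architecture(),
                         seed=self.seed if seed is None else seed)

    def train_config(self, seed: int | None = None) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.train.learning_rate,
            batch_size=self.train.batch_size,
            epochs=self.train.epochs,
            seed=self.seed if seed is None else seed,
        )


# ---------------------------------------------------------------------------
# the deterministic image chain
# ---------------------------------------------------------------------------

_SHEARLET_CACHE: dict[tuple[int, int, int], object] = {}


def _shearlet_system(size: tuple[int, int], n_scales: int):
    key = (size[0], size[1], n_scales)
    if key not in _SHEARLET_CACHE:
        _SHEARLET_CACHE[key] = build_shearlet_system(size, n_scales)
    return _SHEARLET_CACHE[key]


def preprocess_image(img: GrayImage, config: PipelineConfig,
                     stages: frozenset | None = None) -> GrayImage:
    """resize -> contrast stretch -> median -> shearlet enhancement, with
    individual stages toggled by the config's stage set."""
    stages = config.stages if stages is None else stages
    p = config.preprocess
    out = resize_image(img, (p.target_size, p.target_size))
    if "contrast" in stages:
        out = contrast_stretch(out)
    if "median" in stages:
        out = median_filter3(out)
    if "shearlet" in stages:
        sys = _shearlet_system((out.height, out.width), p.n_scales)
        amplified = tuple(s for s in p.scales_amplified if s < p.n_scales)
        out = shearlet_enhance(out, sys,
                               EnhanceParams(gain=p.gain,
                                             scales_amplified=amplified))
    return out


def segment_image(img: GrayImage, config: PipelineConfig,
                  stages: frozenset | None = None
                  ) -> tuple[GrayImage, RoiBox]:
    """Breast crop plus improved-Otsu/Canny ROI extraction.

    Returns the ROI crop and its box in the coordinates of ``img``. With
    both 'otsu' and 'canny' disabled the ROI is the whole breast crop.
    """
    stages = config.stages if stages is None else stages
    crop, breast_box = crop_breast_region(img, config.pectoral.remove)
    use_otsu = "otsu" in stages
    use_canny = "canny" in stages
    if not use_otsu and not use_canny:
        return crop, breast_box
    if use_otsu:
        _, mask = improved_otsu_threshold(crop, config.otsu.alpha,
                                          config.otsu.window,
                                          exclude_zero=True)
    else:
        mask = BinaryMask(np.zeros_like(crop.pixels, dtype=np.uint8))
    if use_canny:
        # Canny refines the binarized image: edges are taken on the
        # threshold-masked crop, so they trace the boundaries of the
        # segmented structures rather than the breast silhouette
        canny_input = GrayImage(crop.pixels * mask.pixels, crop.max_value) \
            if use_otsu else crop
        edges = canny_edges(canny_input, config.canny.low, config.canny.high,
                            config.canny.sigma)
    else:
        edges = BinaryMask(np.zeros_like(crop.pixels, dtype=np.uint8))
    try:
        roi_crop, roi_box = extract_roi(crop, mask, edges, config.roi.pad)
    except SegmentationError:
        return crop, breast_box
    global_box = RoiBox(
        breast_box.row_min + roi_box.row_min,
        breast_box.row_min + roi_box.row_max,
        breast_box.col_min + roi_box.col_min,
        breast_box.col_min + roi_box.col_max,
    )
    return roi_crop, global_box


def _pipeline_features(img: GrayImage, config: PipelineConfig,
                       stages: frozenset) -> np.ndarray:
    roi_crop, _ = segment_image(img, config, stages)
    vec = assemble_hybrid(roi_crop, None, config.features.ng,
                          config.features.symmetric_glcm)
    return vec.values


def prepare_inputs(data: LabelledDataset, config: PipelineConfig,
                   stages: frozenset | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic per-image pipeline outputs for the classifier.

    Returns ``(images, features)``: the (N, S, S, 3) stack of preprocessed
    model inputs and the (N, 49) hybrid feature matrix. Both depend only on
    the image content and the config, so they are computed once and reused
    across cross-validation folds (normalisation is still fitted per fold).
    """
    from .nn import images_to_array

    stages = config.stages if stages is None else stages
    pre = [preprocess_image(img, config, stages) for img in data.images]
    images = images_to_array(pre, config.model.input_size)
    feats = np.stack([_pipeline_features(img, config, stages) for img in pre])
    return images, feats


def feature_table(data: LabelledDataset, config: PipelineConfig | None = None,
                  stages: frozenset | None = None) -> pd.DataFrame:
    """One row per image: id, label and the 49 named hybrid features."""
    config = config or PipelineConfig()
    _, feats = prepare_inputs(data, config, stages)
    df = pd.DataFrame(feats, columns=list(hybrid_feature_names()))
    df.insert(0, "label", data.labels)
    df.insert(0, "id", data.ids)
    return df
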