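"""Hybrid texture descriptors: first-order, GLCM and GLRLM blocks.

The hybrid vector concatenates, in a fixed canonical order,

* 5 first-order histogram statistics (mean, skewness, entropy, uniformity,
  smoothness),
* 6 gray-level co-occurrence features (energy, entropy, contrast,
  homogeneity, correlation, cluster shade) at each of the four principal
  directions 0/45/90/135 degrees, pixel distance 1, and
* 5 run-length features (SRE, LRE, LGRE, HGRE, GLN) at the same four
  directions,

for 49 named values per region of interest. Gray levels are quantized to
``Ng`` bins indexed from 1 (so the low-gray-level emphasis weight ``1/i^2``
is defined at the lowest level). Entropies use log base 2 with the usual
``0 log 0 = 0`` convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_formats import GrayImage
from .segmentation import BinaryMask, RoiBox

__all__ = [
    "QuantizedImage", "GLCMatrix", "RunLengthMatrix", "FeatureVector",
    "DIRECTIONS", "quantize", "compute_glcm", "glcm_features",
    "compute_glrlm", "glrlm_features", "first_order_features",
    "assemble_hybrid", "hybrid_feature_names",
]

DIRECTIONS = (0, 45, 90, 135)
# (drow, dcol) offsets; 45 deg is the anti-diagonal (up-right)
_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

FIRST_ORDER_NAMES = ("fo_mean", "fo_skewness", "fo_entropy", "fo_uniformity",
                     "fo_smoothness")
GLCM_NAMES = ("energy", "entropy", "contrast", "homogeneity", "correlation",
              "shade")
GLRLM_NAMES = ("sre", "lre", "lgre", "hgre", "gln")


@dataclass
class QuantizedImage:
    levels: np.ndarray   # integer bins in [1, Ng]
    Ng: int

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int64)
        if self.Ng < 2:
            raise ValueError("Ng must be >= 2")
        if self.levels.min() < 1 or self.levels.max() > self.Ng:
            raise ValueError("bins must lie in [1, Ng]")


@dataclass
class GLCMatrix:
    P: np.ndarray
    direction: int
    distance: int = 1
    symmetric: bool = True


@dataclass
class RunLengthMatrix:
    R: np.ndarray        # (Ng, Lmax) counts; column j-1 holds runs of length j
    direction: int
    Nr: int

    @property
    def Ng(self) -> int:
        return self.R.shape[0]

    @property
    def Lmax(self) -> int:
        return self.R.shape[1]


@dataclass
class FeatureVector:
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.names) != len(self.values):
            raise ValueError("names and values must be parallel")
        if np.isnan(self.values).any():
            raise ValueError("NaN is forbidden in a FeatureVector")

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def concat(self, other: "FeatureVector") -> "FeatureVector":
        return FeatureVector(self.names + other.names,
                             np.concatenate([self.values, other.values]))


def quantize(img: GrayImage, Ng: int = 32) -> QuantizedImage:
    """Equal-width binning of the region's own intensity range into Ng bins,
    indexed from 1. A constant region maps entirely to bin 1."""
    if Ng < 2:
        raise ValueError("Ng must be >= 2")
    x = img.pixels.astype(np.int64)
    lo, hi = int(x.min()), int(x.max())
    bins = 1 + (x - lo) * Ng // (hi - lo + 1)
    return QuantizedImage(bins, Ng)


def compute_glcm(q: QuantizedImage, direction: int, symmetric: bool = True
                 ) -> GLCMatrix:
    """Normalised co-occurrence matrix at unit distance."""
    if direction not in _OFFSETS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    dr, dc = _OFFSETS[direction]
    lv = q.levels
    h, w = lv.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        raise ValueError("region smaller than the offset span: no pixel pairs")
    a = lv[r0:r1, c0:c1].reshape(-1) - 1
    b = lv[r0 + dr:r1 + dr, c0 + dc:c1 + dc].reshape(-1) - 1
    counts = np.zeros((q.Ng, q.Ng), dtype=np.float64)
    np.add.at(counts, (a, b), 1.0)
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    return GLCMatrix(counts / total, direction, 1, symmetric)


def glcm_features(M: GLCMatrix) -> FeatureVector:
    """Haralick-style descriptors of a normalised GLCM."""
    P = M.P
    Ng = P.shape[0]
    i = np.arange(1, Ng + 1, dtype=np.float64)[:, None]
    j = np.arange(1, Ng + 1, dtype=np.float64)[None, :]
    energy = float(np.sum(P * P))
    nz = P[P > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    diff = np.abs(i - j)
    contrast = float(np.sum(diff ** 2 * P))
    homogeneity = float(np.sum(P / (1.0 + diff)))
    pi = P.sum(axis=1)
    pj = P.sum(axis=0)
    mu_i = float(np.sum(i[:, 0] * pi))
    mu_j = float(np.sum(j[0, :] * pj))
    sd_i = float(np.sqrt(np.sum((i[:, 0] - mu_i) ** 2 * pi)))
    sd_j = float(np.sqrt(np.sum((j[0, :] - mu_j) ** 2 * pj)))
    if sd_i == 0 or sd_j == 0:
        warnings.warn("glcm_features: constant texture, correlation set to 0")
        correlation = 0.0
    else:
        correlation = float(np.sum((i - mu_i) * (j - mu_j) * P) / (sd_i * sd_j))
    shade = float(np.sum((i + j - mu_i - mu_j) ** 3 * P))
    names = tuple(f"glcm_{n}_d{M.direction}" for n in GLCM_NAMES)
    return FeatureVector(names, [energy, entropy, contrast, homogeneity,
                                 correlation, shade])


def _lines(levels: np.ndarray, direction: int):
    """Yield the pixel sequences along every line of the image in a
    direction (rows, columns, diagonals or anti-diagonals)."""
    h, w = levels.shape
    if direction == 0:
        yield from levels
    elif direction == 90:
        yield from levels.T
    elif direction == 135:  # main diagonals (down-right runs)
        for off in range(-(h - 1), w):
            yield np.diagonal(levels, offset=off)
    elif direction == 45:   # anti-diagonals (up-right runs)
        flipped = levels[::-1]
        for off in range(-(h - 1), w):
            yield np.diagonal(flipped, offset=off)
    else:
        raise ValueError(f"direction must be one of {DIRECTIONS}")


def compute_glrlm(q: QuantizedImage, direction: int) -> RunLengthMatrix:
    """Count maximal runs of equal gray level along one direction."""
    lv = q.levels
    lmax = {0: lv.shape[1], 90: lv.shape[0]}.get(direction, min(lv.shape))
    R = np.zeros((q.Ng, lmax), dtype=np.int64)
    for line in _lines(lv, direction):
        n = len(line)
        if n == 0:
            continue
        boundaries = np.flatnonzero(np.diff(line)) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [n]])
        lengths = ends - starts
        np.add.at(R, (line[starts] - 1, lengths - 1), 1)
    return RunLengthMatrix(R, direction, int(R.sum()))


def glrlm_features(R: RunLengthMatrix) -> FeatureVector:
    """Galloway run-length descriptors."""
    if R.Nr < 1:
        raise ValueError("empty run-length matrix")
    mat = R.R.astype(np.float64)
    i2 = np.arange(1, R.Ng + 1, dtype=np.float64)[:, None] ** 2
    j2 = np.arange(1, R.Lmax + 1, dtype=np.float64)[None, :] ** 2
    nr = float(R.Nr)
    sre = float(np.sum(mat / j2) / nr)
    lre = float(np.sum(mat * j2) / nr)
    lgre = float(np.sum(mat / i2) / nr)
    hgre = float(np.sum(mat * i2) / nr)
    gln = float(np.sum(mat.sum(axis=1) ** 2) / nr)
    names = tuple(f"glrlm_{n}_d{R.direction}" for n in GLRLM_NAMES)
    return FeatureVector(names, [sre, lre, lgre, hgre, gln])


def first_order_features(img: GrayImage, mask: BinaryMask | None = None
                         ) -> FeatureVector:
    """Histogram statistics of the selected pixels.

    Smoothness is ``1 - 1/(1 + sigma_n^2)`` with ``sigma_n`` the standard
    deviation of intensities rescaled to [0, 1].
    """
    if mask is not None:
        vals = img.pixels[mask.pixels.astype(bool)]
    else:
        vals = img.pixels.reshape(-1)
    if vals.size < 2:
        raise ValueError("need at least 2 selected pixels")
    hist = np.bincount(vals.astype(np.int64), minlength=img.max_value + 1)
    p = hist / hist.sum()
    z = np.arange(img.max_value + 1, dtype=np.float64)
    mean = float(np.sum(z * p))
    var = float(np.sum((z - mean) ** 2 * p))
    if var == 0:
        warnings.warn("first_order_features: zero variance, skewness set to 0")
        skew = 0.0
    else:
        skew = float(np.sum((z - mean) ** 3 * p) / var ** 1.5)
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    uniformity = float(np.sum(p * p))
    sigma_n2 = var / img.max_value ** 2
    smoothness = 1.0 - 1.0 / (1.0 + sigma_n2)
    return FeatureVector(FIRST_ORDER_NAMES,
                         [mean, skew, entropy, uniformity, smoothness])


def hybrid_feature_names() -> tuple[str, ...]:
    names = list(FIRST_ORDER_NAMES)
    for d in DIRECTIONS:
        names += [f"glcm_{n}_d{d}" for n in GLCM_NAMES]
    for d in DIRECTIONS:
        names += [f"glrlm_{n}_d{d}" for n in GLRLM_NAMES]
    return tuple(names)


def assemble_hybrid(img: GrayImage, roi: RoiBox | None = None, Ng: int = 32,
                    symmetric_glcm: bool = True) -> FeatureVector:
    """The canonical 49-value hybrid descriptor of an ROI crop."""
    region = roi.crop(img) if roi is not None else img
    vec = first_order_features(region)
    q = quantize(region, Ng)
    for d in DIRECTIONS:
        vec = vec.concat(glcm_features(compute_glcm(q, d, symmetric_glcm)))
    for d in DIRECTIONS:
        vec = vec.concat(glrlm_features(compute_glrlm(q, d)))
    assert vec.names == hybrid_feature_names()
    return vec
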