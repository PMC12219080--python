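"""Seeded mammogram-like phantoms with exact ground truth.

A phantom is a half-elliptical "breast" on a dark background, filled with a
correlated Gaussian random field (smooth fibroglandular-like texture), an
optional bright pectoral wedge anchored at the top-left corner, and - for
the abnormal class - a radially decaying bright mass with optional radial
spicules, 1-2 px microcalcification specks and finer internal texture.
Additive Gaussian noise and clipping to 8 bits finish the image.

Class contrast is controlled by ``lesion_contrast`` (the peak intensity
offset of the mass, in gray levels): at 0 with no spicules/calcifications
the two classes are generated identically, giving an exact null for
calibration tests. The background, lesion and noise draws come from
independent sub-streams of the seed, so the null holds sample-by-sample.

These phantoms emulate the intensity-contrast, co-occurrence-contrast and
run-length structure that separate normal from abnormal mammograms; they do
not emulate compression artefacts, scanner noise statistics or realistic
breast-density variation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .io_formats import GrayImage, LabelledDataset, NORMAL, ABNORMAL
from .segmentation import BinaryMask, RoiBox

__all__ = ["PhantomParams", "PhantomTruth", "generate_phantom",
           "generate_dataset"]


@dataclass(frozen=True)
class PhantomParams:
    size: tuple[int, int] = (224, 224)
    lesion_radius: tuple[float, float] = (20.0, 35.0)
    lesion_contrast: float = 60.0
    spicule_count: int = 6
    calc_count: int = 5
    bg_corr_len: float = 8.0
    lesion_corr_len: float = 1.5
    noise_sd: float = 5.0
    pectoral: bool = False
    pectoral_contrast: float = 70.0
    bg_level: float = 60.0
    bg_amplitude: float = 10.0
    skin_level: float = 0.0   # > 0 paints a bright skin line at the silhouette
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lesion_radius[0] <= 0 or self.lesion_radius[1] < self.lesion_radius[0]:
            raise ValueError("lesion_radius must be a positive (lo, hi) range")
        if self.lesion_contrast < 0:
            raise ValueError("lesion_contrast must be >= 0")


@dataclass
class PhantomTruth:
    label: str
    lesion_center: tuple[int, int] | None = None
    lesion_radius: float | None = None
    lesion_mask: BinaryMask | None = None
    pectoral_mask: BinaryMask | None = None

    @property
    def lesion_box(self) -> RoiBox | None:
        if self.lesion_center is None:
            return None
        r0, c0 = self.lesion_center
        rr = int(np.ceil(self.lesion_radius))
        return RoiBox(r0 - rr, r0 + rr + 1, c0 - rr, c0 + rr + 1)


def _correlated_field(rng: np.random.Generator, shape: tuple[int, int],
                      corr_len: float) -> np.ndarray:
    """Unit-variance Gaussian random field smoothed to a correlation length."""
    field = ndimage.gaussian_filter(rng.standard_normal(shape), corr_len,
                                    mode="wrap")
    sd = field.std()
    return field / sd if sd > 0 else field


def _breast_geometry(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Half-ellipse anchored to the left edge (MLO-like silhouette).

    Returns the breast mask and the normalised elliptic radius (1 at the
    skin line), used to paint the bright skin-line band.
    """
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    a = 0.58 * h   # vertical semi-axis (reaches the top/bottom near the left edge)
    b = 0.82 * w   # horizontal semi-axis
    e = ((rr - 0.5 * h) / a) ** 2 + (cc / b) ** 2
    return e <= 1.0, e


def generate_phantom(params: PhantomParams, label: str
                     ) -> tuple[GrayImage, PhantomTruth]:
    """Render one phantom; fully determined by ``params.seed`` and label."""
    if label not in (NORMAL, ABNORMAL):
        raise ValueError(f"unknown label {label!r}")
    h, w = params.size
    ss = np.random.SeedSequence([int(params.seed) & 0x7FFFFFFF, 11])
    rng_bg, rng_lesion, rng_noise = (np.random.default_rng(c)
                                     for c in ss.spawn(3))
    mask, e = _breast_geometry(params.size)
    img = np.zeros(params.size, dtype=np.float64)
    bg = params.bg_level + params.bg_amplitude * _correlated_field(
        rng_bg, params.size, params.bg_corr_len)
    img[mask] = bg[mask]
    if params.skin_level > 0:
        # optional bright skin line along the silhouette
        skin = mask & (e >= 0.97)
        img[skin] = params.skin_level + 0.3 * params.bg_amplitude * (
            _correlated_field(rng_bg, params.size, 2.0)[skin])

    pect_mask = None
    if params.pectoral:
        rr, cc = np.mgrid[0:h, 0:w]
        wedge = (rr + 1.3 * cc < 0.55 * h) & mask
        if wedge.any():
            img[wedge] += params.pectoral_contrast
            pect_mask = BinaryMask(wedge.astype(np.uint8))

    truth = PhantomTruth(label=label)
    if label == ABNORMAL:
        delta = params.lesion_contrast
        radius = rng_lesion.uniform(*params.lesion_radius)
        eroded = ndimage.binary_erosion(
            mask, iterations=int(np.ceil(radius)) + 4)
        if params.pectoral and pect_mask is not None:
            eroded &= ~ndimage.binary_dilation(
                pect_mask.pixels.astype(bool), iterations=int(radius))
        cand = np.argwhere(eroded)
        if len(cand) == 0:
            raise RuntimeError("lesion cannot fit inside the breast mask")
        r0, c0 = cand[rng_lesion.integers(len(cand))]
        rr, cc = np.mgrid[0:h, 0:w]
        d2 = ((rr - r0) ** 2 + (cc - c0) ** 2) / radius ** 2
        d = np.sqrt(d2)
        # circumscribed-mass profile: bright plateau with a soft margin at
        # the nominal radius, truncated at 2 radii
        profile = 1.0 / (1.0 + np.exp((d - 0.85) / 0.08))
        lesion = delta * profile * (d2 <= 4.0)
        # malignant masses are heterogeneous: strong texture at a finer
        # correlation length than the background field
        tex = _correlated_field(rng_lesion, params.size, params.lesion_corr_len)
        lesion += 0.9 * delta * tex * (d2 <= 1.0)
        # radial spicules: thin bright ridges leaving the rim
        if params.spicule_count > 0 and delta > 0:
            angles = rng_lesion.uniform(0, 2 * np.pi, params.spicule_count)
            theta = np.arctan2(rr - r0, cc - c0)
            dist = np.sqrt(d2)
            for ang in angles:
                dtheta = np.angle(np.exp(1j * (theta - ang)))
                ridge = (np.abs(dtheta) < 0.06) & (dist > 0.6) & (dist < 2.2)
                lesion[ridge] += 0.5 * delta
        img += np.where(mask, lesion, 0.0)
        # microcalcifications: 1-2 px bright specks inside the lesion
        if params.calc_count > 0 and delta > 0:
            inside = np.argwhere((d2 <= 1.0) & mask)
            for _ in range(params.calc_count):
                pr, pc = inside[rng_lesion.integers(len(inside))]
                size = int(rng_lesion.integers(1, 3))
                img[pr:pr + size, pc:pc + size] += 0.8 * delta
        truth = PhantomTruth(
            label=ABNORMAL,
            lesion_center=(int(r0), int(c0)),
            lesion_radius=float(radius),
            lesion_mask=BinaryMask(((d2 <= 1.0) & mask).astype(np.uint8)),
            pectoral_mask=pect_mask,
        )
    else:
        truth.pectoral_mask = pect_mask

    img += params.noise_sd * rng_noise.standard_normal(params.size)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return GrayImage(img, 255), truth


def _child_seed(dataset_seed: int, index: int) -> int:
    """Stable per-image seed derived from (dataset seed, index)."""
    ss = np.random.SeedSequence([int(dataset_seed) & 0x7FFFFFFF, index])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def generate_dataset(params: PhantomParams, n_per_class: int, seed: int
                     ) -> tuple[LabelledDataset, list[PhantomTruth]]:
    """Balanced phantom dataset: 2*n_per_class images, deterministic in
    ``seed`` (per-image seeds are stable hashes of seed and index)."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    images, labels, ids, truths = [], [], [], []
    idx = 0
    for label in (NORMAL, ABNORMAL):
        for k in range(n_per_class):
            p = replace(params, seed=_child_seed(seed, idx))
            img, truth = generate_phantom(p, label)
            images.append(img)
            labels.append(label)
            ids.append(f"ph{idx:04d}_{label[0]}")
            truths.append(truth)
            idx += 1
    return LabelledDataset(images, labels, ids), truths
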