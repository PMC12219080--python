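"""Grayscale image I/O and MIAS-style annotation parsing.

Images are handled as :class:`GrayImage`, a thin wrapper around a 2-D
``numpy`` integer raster (row 0 at the top).  Mammography archives in the
MIAS tradition ship 8-bit PGM files plus a plain-text info file with one
whitespace-separated record per image::

    mdb001 G CIRC B 535 425 197
    mdb003 D NORM

where the optional trailing triple is the lesion centre (x, y) and
approximate radius in pixels, with the *y* origin at the bottom-left of the
image.  :func:`mias_center_to_rowcol` converts that convention to the
(row, col), top-left origin convention used everywhere in this package.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
import numpy as np
from PIL import Image

__all__ = [
    "GrayImage",
    "MiasRecord",
    "LabelledDataset",
    "PgmFormatError",
    "MiasParseError",
    "read_pgm",
    "write_image",
    "parse_mias_info",
    "mias_center_to_rowcol",
]

TISSUE_CODES = frozenset({"F", "G", "D"})
ABNORMALITY_CODES = frozenset({"NORM", "CALC", "CIRC", "SPIC", "MISC", "ARCH", "ASYM"})
SEVERITY_CODES = frozenset({"B", "M"})

NORMAL = "normal"
ABNORMAL = "abnormal"
LABELS = (NORMAL, ABNORMAL)


class PgmFormatError(ValueError):
    """Raised when a PGM file violates the P2/P5 format."""


class MiasParseError(ValueError):
    """Raised when an annotation line uses an unknown tissue/abnormality code."""


@dataclass
class GrayImage:
    """A 2-D intensity raster, row-major with row 0 at the top."""

    pixels: np.ndarray
    max_value: int = 255

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("GrayImage requires a non-empty 2-D pixel grid")
        if self.pixels.min() < 0 or self.pixels.max() > self.max_value:
            raise ValueError(
                f"intensities must lie in [0, {self.max_value}], "
                f"got [{self.pixels.min()}, {self.pixels.max()}]"
            )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def astype_float(self) -> np.ndarray:
        return self.pixels.astype(np.float64)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GrayImage):
            return NotImplemented
        return self.max_value == other.max_value and np.array_equal(
            self.pixels, other.pixels
        )


@dataclass(frozen=True)
class MiasRecord:
    """One line of a MIAS info file.

    ``severity`` is ``None`` for NORM records; lesion geometry
    (``center_x``, ``center_y``, ``radius``) is ``None`` unless the line
    carries a well-formed x/y/radius triple.  Coordinates keep the archive's
    bottom-left origin; see :func:`mias_center_to_rowcol`.
    """

    ref_id: str
    tissue: str
    abnormality: str
    severity: str | None = None
    center_x: int | None = None
    center_y: int | None = None
    radius: int | None = None

    @property
    def label(self) -> str:
        """Two-class label: NORM maps to 'normal', everything else 'abnormal'."""
        return NORMAL if self.abnormality == "NORM" else ABNORMAL


def mias_center_to_rowcol(record: MiasRecord, height: int) -> tuple[int, int]:
    """Convert a record's bottom-left-origin (x, y) centre to (row, col)."""
    if record.center_x is None or record.center_y is None:
        raise ValueError(f"record {record.ref_id} has no lesion geometry")
    return height - 1 - record.center_y, record.center_x


@dataclass
class LabelledDataset:
    """Parallel images / two-class labels / ids."""

    images: list[GrayImage]
    labels: list[str]
    ids: list[str]

    def __post_init__(self) -> None:
        if not (len(self.images) == len(self.labels) == len(self.ids)):
            raise ValueError("images, labels and ids must have equal length")
        bad = set(self.labels) - set(LABELS)
        if bad:
            raise ValueError(f"labels outside the two-class set: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.images)

    def write_manifest(self, path: str | Path, image_dir: str | Path | None = None,
                       fmt: str = "pgm") -> None:
        """Write a ``id,path,label`` manifest CSV, saving images alongside."""
        path = Path(path)
        rows = []
        for img, label, ref in zip(self.images, self.labels, self.ids):
            if image_dir is not None:
                img_path = Path(image_dir) / f"{ref}.{fmt}"
                write_image(img, img_path, fmt)
                rows.append((ref, str(img_path), label))
            else:
                rows.append((ref, "", label))
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "path", "label"])
            writer.writerows(rows)

    @classmethod
    def from_manifest(cls, path: str | Path) -> "LabelledDataset":
        images, labels, ids = [], [], []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                images.append(read_pgm(row["path"]))
                labels.append(row["label"])
                ids.append(row["id"])
        return cls(images, labels, ids)


# ---------------------------------------------------------------------------
# PGM / PNG I/O
# ---------------------------------------------------------------------------

def _pgm_tokens(data: bytes):
    """Yield (token, offset-after-token) for the ASCII header/body of a PGM,
    skipping '#' comments."""
    i, n = 0, len(data)
    while i < n:
        c = data[i : i + 1]
        if c in b" \t\r\n":
            i += 1
        elif c == b"#":
            while i < n and data[i : i + 1] != b"\n":
                i += 1
        else:
            j = i
            while j < n and data[j : j + 1] not in b" \t\r\n#":
                j += 1
            yield data[i:j].decode("ascii", "replace"), j
            i = j


def read_pgm(path: str | Path) -> GrayImage:
    """Read an ASCII (P2) or binary (P5) PGM file.

    A maxval above 255 is accepted and linearly rescaled to the 8-bit range,
    since the downstream pipeline works on 8-bit dynamics.
    """
    data = Path(path).read_bytes()
    tokens = _pgm_tokens(data)
    try:
        magic, _ = next(tokens)
    except StopIteration:
        raise PgmFormatError(f"{path}: empty file") from None
    if magic not in ("P2", "P5"):
        raise PgmFormatError(f"{path}: bad magic number {magic!r}")
    header: list[int] = []
    end = 0
    for tok, off in tokens:
        try:
            header.append(int(tok))
        except ValueError:
            raise PgmFormatError(f"{path}: non-numeric header token {tok!r}") from None
        end = off
        if len(header) == 3:
            break
    if len(header) < 3:
        raise PgmFormatError(f"{path}: truncated header")
    width, height, maxval = header
    if width < 1 or height < 1 or maxval < 1 or maxval > 65535:
        raise PgmFormatError(f"{path}: invalid dimensions/maxval {header}")
    n = width * height
    if magic == "P2":
        body = []
        for tok, _ in tokens:
            try:
                body.append(int(tok))
            except ValueError:
                raise PgmFormatError(f"{path}: non-numeric pixel token {tok!r}") from None
        if len(body) < n:
            raise PgmFormatError(f"{path}: expected {n} pixels, found {len(body)}")
        raw = np.array(body[:n], dtype=np.int64)
    else:
        # exactly one whitespace byte separates the header from binary data
        payload = data[end + 1 :]
        if maxval > 255:
            if len(payload) < 2 * n:
                raise PgmFormatError(f"{path}: truncated P5 payload")
            raw = np.frombuffer(payload[: 2 * n], dtype=">u2").astype(np.int64)
        else:
            if len(payload) < n:
                raise PgmFormatError(f"{path}: truncated P5 payload")
            raw = np.frombuffer(payload[:n], dtype=np.uint8).astype(np.int64)
    if raw.max(initial=0) > maxval:
        raise PgmFormatError(f"{path}: pixel value exceeds maxval {maxval}")
    if maxval > 255:
        raw = np.rint(raw * (255.0 / maxval)).astype(np.int64)
        maxval = 255
    pixels = raw.reshape(height, width).astype(np.uint8)
    return GrayImage(pixels, max_value=maxval)


def write_image(img: GrayImage, path: str | Path, format: str = "pgm") -> None:
    """Write ``img`` losslessly as binary PGM (P5) or PNG."""
    path = Path(path)
    arr = np.asarray(img.pixels, dtype=np.uint8)
    if format == "pgm":
        header = f"P5\n{img.width} {img.height}\n{img.max_value}\n".encode("ascii")
        path.write_bytes(header + arr.tobytes())
    elif format == "png":
        Image.fromarray(arr, mode="L").save(path, format="PNG")
    else:
        raise ValueError(f"unsupported format {format!r}")


# ---------------------------------------------------------------------------
# MIAS annotations
# ---------------------------------------------------------------------------

def parse_mias_info(text: str) -> list[MiasRecord]:
    """Parse MIAS info-file text into :class:`MiasRecord` rows.

    Lines whose geometry is absent, marked ``*NOTE*`` or malformed keep the
    id/tissue/abnormality fields with geometry set to ``None``.
    """
    records: list[MiasRecord] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        fields = line.split()
        if not fields:
            continue
        if len(fields) < 3:
            raise MiasParseError(f"line {lineno}: expected at least 3 fields: {line!r}")
        ref_id, tissue, abnormality = fields[:3]
        if tissue not in TISSUE_CODES:
            raise MiasParseError(f"line {lineno}: unknown tissue code {tissue!r}")
        if abnormality not in ABNORMALITY_CODES:
            raise MiasParseError(
                f"line {lineno}: unknown abnormality code {abnormality!r}"
            )
        severity = None
        geometry: tuple[int, int, int] | None = None
        if abnormality != "NORM":
            if len(fields) >= 4 and fields[3] in SEVERITY_CODES:
                severity = fields[3]
            rest = fields[4:] if severity else fields[3:]
            if len(rest) >= 3:
                try:
                    geometry = (int(rest[0]), int(rest[1]), int(rest[2]))
                except ValueError:
                    geometry = None  # *NOTE* or malformed geometry
        cx, cy, r = geometry if geometry else (None, None, None)
        records.append(
            MiasRecord(ref_id, tissue, abnormality, severity, cx, cy, r)
        )
    return records
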