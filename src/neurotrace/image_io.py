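"""Image loading, intensity normalization, and morphology/table export.

Conventions used throughout the package:

* coordinates are ``(row, col)`` (``(row, col, depth)`` for stacks), 0-based,
  origin at the top-left pixel; physical positions are index × microns-per-pixel.
* angles are degrees, counterclockwise from the image +x (column) axis, in
  ``(-180, 180]``; increasing row is *down*, so "north" (decreasing row) is +90°.
* intensities are min–max normalized into ``[EPS, 1]`` so that log-intensity
  (the tracing likelihood) is always finite.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Normalization floor: darkest pixel after normalization.  Keeps
#: ``log(intensity)`` finite on fully dark background.
EPS = 1e-6

__all__ = [
    "EPS",
    "ScaleInfo",
    "ImageGrid",
    "ImageStack",
    "normalize_intensities",
    "load_image",
    "load_stack",
    "write_swc",
    "read_swc",
]


@dataclass(frozen=True)
class ScaleInfo:
    """Physical pixel size.

    Parameters
    ----------
    microns_per_pixel : float
        In-plane sampling, μm per pixel (isotropic in x/y).
    microns_per_slice : float, optional
        Axial step between stack slices, μm.  Only meaningful for stacks;
        defaults to ``microns_per_pixel`` (isotropic volume).
    """

    microns_per_pixel: float
    microns_per_slice: float | None = None

    def __post_init__(self) -> None:
        if not self.microns_per_pixel > 0:
            raise ValueError("microns_per_pixel must be strictly positive")
        if self.microns_per_slice is not None and not self.microns_per_slice > 0:
            raise ValueError("microns_per_slice must be strictly positive")

    @property
    def z_step(self) -> float:
        """Axial step in μm (falls back to the in-plane sampling)."""
        return (
            self.microns_per_slice
            if self.microns_per_slice is not None
            else self.microns_per_pixel
        )

    def um_to_px(self, microns: float) -> float:
        return microns / self.microns_per_pixel

    def px_to_um(self, pixels: float) -> float:
        return pixels * self.microns_per_pixel


def normalize_intensities(raw: np.ndarray) -> np.ndarray:
    """Min–max normalize ``raw`` into ``[EPS, 1]``.

    A constant array maps to all-``EPS`` with a warning.  The map is
    idempotent: normalizing an already-normalized array returns it unchanged
    (up to floating point), and it is invariant under affine intensity
    changes ``a*I + b`` with ``a > 0``.
    """
    raw = np.asarray(raw, dtype=np.float64)
    lo = float(raw.min())
    hi = float(raw.max())
    if hi == lo:
        warnings.warn("constant image: normalized to the floor value", stacklevel=2)
        return np.full(raw.shape, EPS)
    return EPS + (1.0 - EPS) * (raw - lo) / (hi - lo)


@dataclass
class ImageGrid:
    """A normalized single-channel 2-D image with physical scale.

    ``intensities`` holds floats in ``(0, 1]`` with minimum ≥ `EPS`.
    """

    intensities: np.ndarray
    scale: ScaleInfo
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 2:
            raise ValueError("ImageGrid expects a 2-D array")
        if self.intensities.min() < EPS - 1e-12 or self.intensities.max() > 1 + 1e-12:
            raise ValueError("intensities must lie in [EPS, 1]; normalize first")

    @property
    def height(self) -> int:
        return self.intensities.shape[0]

    @property
    def width(self) -> int:
        return self.intensities.shape[1]

    @classmethod
    def from_raw(cls, raw: np.ndarray, scale: ScaleInfo) -> "ImageGrid":
        return cls(normalize_intensities(raw), scale)

    def contains(self, position) -> bool:
        r, c = position[0], position[1]
        return 0 <= r <= self.height - 1 and 0 <= c <= self.width - 1


@dataclass
class ImageStack:
    """An ordered list of equally-shaped slices sharing one scale.

    Normalization is global across the stack (one min/max), preserving
    relative slice brightness.
    """

    slices: list
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.slices) < 1:
            raise ValueError("stack needs at least one slice")
        shape = self.slices[0].intensities.shape
        for s in self.slices[1:]:
            if s.intensities.shape != shape:
                raise ValueError("all stack slices must share the same dimensions")

    @property
    def depth(self) -> int:
        return len(self.slices)

    @property
    def scale(self) -> ScaleInfo:
        return self.slices[0].scale

    def as_volume(self) -> np.ndarray:
        """(depth, height, width) float array."""
        key = "volume"
        if key not in self._cache:
            self._cache[key] = np.stack([s.intensities for s in self.slices])
        return self._cache[key]

    @classmethod
    def from_raw(cls, raw: np.ndarray, scale: ScaleInfo) -> "ImageStack":
        raw = np.asarray(raw, dtype=np.float64)
        if raw.ndim == 2:
            raw = raw[None]
        norm = normalize_intensities(raw)
        return cls([ImageGrid(page, scale) for page in norm])


def _read_raster(path: Path) -> np.ndarray:
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            import tifffile

            return tifffile.imread(path)
        import imageio.v3 as iio

        return iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - backend-specific failures
        raise ValueError(f"unreadable image file: {path}") from exc


def _to_gray(arr: np.ndarray) -> np.ndarray:
    """Collapse an RGB(A) last axis by Rec. 601 luminance."""
    if arr.ndim >= 3 and arr.shape[-1] in (3, 4):
        rgb = arr[..., :3].astype(np.float64)
        return rgb @ np.array([0.299, 0.587, 0.114])
    return arr.astype(np.float64)


def load_image(path, scale: ScaleInfo) -> ImageGrid:
    """Read a single-channel (or RGB, collapsed) raster and normalize it."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = _to_gray(_read_raster(path))
    if arr.ndim == 3 and arr.shape[0] == 1:
        arr = arr[0]
    if arr.ndim != 2:
        raise ValueError(f"expected a single 2-D image, got shape {arr.shape}")
    return ImageGrid.from_raw(arr, scale)


def load_stack(path, scale: ScaleInfo) -> ImageStack:
    """Read a multi-page TIFF or directory of numbered images as a stack."""
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p
            for p in path.iterdir()
            if p.suffix.lower() in (".tif", ".tiff", ".png")
        )
        if not files:
            raise FileNotFoundError(f"no image files in directory {path}")
        pages = [_to_gray(_read_raster(p)) for p in files]
    else:
        if not path.exists():
            raise FileNotFoundError(path)
        arr = _to_gray(_read_raster(path))
        pages = [arr] if arr.ndim == 2 else list(arr)
    shape = pages[0].shape
    for p in pages:
        if p.shape != shape:
            raise ValueError("stack pages have mixed dimensions")
    return ImageStack.from_raw(np.stack(pages), scale)


# ---------------------------------------------------------------------------
# SWC morphology export

_SOMA, _AXON, _DEND = 1, 2, 3


def write_swc(sequences, somata, path, scale: ScaleInfo | None = None) -> None:
    """Write somata and traced sequences as a standard 7-column SWC file.

    One node per soma (type 1, radius from its area); each sequence
    contributes a chain whose first node parents to its soma node (or to -1
    when it has no soma).  SWC x = col·μm/px, y = row·μm/px, z = depth·μm.
    Sequences carrying a ``label`` attribute of ``"dendrite"`` are written as
    type 3, all others as type 2 (axon).
    """
    lines = ["# generated by neurotrace", "# index type x y z radius parent"]
    node_id = 0
    soma_node: dict[int, int] = {}
    for k, soma in enumerate(somata):
        node_id += 1
        s = scale or getattr(soma, "scale", None)
        upp = s.microns_per_pixel if s else 1.0
        r_um = float(np.sqrt(max(soma.area_um2, 0.0) / np.pi))
        y, x = soma.center[0] * upp, soma.center[1] * upp
        lines.append(f"{node_id} {_SOMA} {x:.4f} {y:.4f} 0.0000 {r_um:.4f} -1")
        soma_node[k] = node_id

    for seq in sequences:
        if len(seq.points) < 2:
            continue
        s = scale or getattr(seq, "scale", None)
        upp = s.microns_per_pixel if s else 1.0
        zstep = s.z_step if s else 1.0
        kind = _DEND if getattr(seq, "label", "axon") == "dendrite" else _AXON
        parent = soma_node.get(getattr(seq, "soma_id", None), -1)
        for pt in seq.points:
            node_id += 1
            pos = pt.position
            z = pos[2] * zstep if len(pos) == 3 else 0.0
            y, x = pos[0] * upp, pos[1] * upp
            lines.append(
                f"{node_id} {kind} {x:.4f} {y:.4f} {z:.4f} 0.5000 {parent}"
            )
            parent = node_id

    Path(path).write_text("\n".join(lines) + "\n")


def read_swc(path):
    """Parse an SWC file into a list of ``(index, type, x, y, z, radius, parent)``."""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        f = line.split()
        rows.append(
            (
                int(f[0]),
                int(f[1]),
                float(f[2]),
                float(f[3]),
                float(f[4]),
                float(f[5]),
                int(f[6]),
            )
        )
    return rows
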