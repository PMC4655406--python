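"""Soma detection: LoG response ratio → NMS centers → level-set boundary.

Somata are bright, roughly elliptical blobs 15–30 μm in diameter.  The
pipeline is

1. scale-normalized (negated) Laplacian-of-Gaussian response, tuned so blobs
   of soma radius peak (LoG peaks for blobs of radius σ√2);
2. threshold on the *response ratio* — response divided by the image-maximum
   response — to isolate candidate soma regions;
3. non-maximum suppression inside those regions to pin one center pixel per
   local peak;
4. a two-phase piecewise-constant level set (Chan–Vese) evolved from a 40-μm
   circle around each center to refine the soma boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import Point, Polygon
from skimage.measure import find_contours
from skimage.morphology import disk, opening
from skimage.segmentation import morphological_chan_vese

from .image_io import ImageGrid

__all__ = [
    "SomaParams",
    "SomaCandidate",
    "Soma",
    "log_response",
    "soma_regions",
    "nms_centers",
    "refine_boundary",
    "detect_somata",
]


@dataclass
class SomaParams:
    """Tunable soma-detection parameters.

    log_sigma_um
        LoG scale in μm; default 7.5 ≈ (mid soma radius)/√2, so 15–30-μm
        blobs respond strongly.
    response_ratio_threshold
        Fraction of the maximum LoG response a pixel must reach to be part
        of a soma region; the precision/recall trade-off dial.
    init_circle_diameter_um
        Diameter of the level-set initialization circle, slightly larger
        than a soma.
    """

    log_sigma_um: float = 7.5
    response_ratio_threshold: float = 0.3
    init_circle_diameter_um: float = 40.0
    lsm_max_iter: int = 200
    lsm_tol: float = 1e-3

    def __post_init__(self) -> None:
        if not 0 < self.response_ratio_threshold < 1 + 1e-12:
            raise ValueError("response_ratio_threshold must be in (0, 1]")
        if self.log_sigma_um <= 0:
            raise ValueError("log_sigma_um must be positive")


@dataclass(frozen=True)
class SomaCandidate:
    """A putative soma center found by NMS on the response map."""

    center: tuple  # (row, col), int pixels
    response_ratio: float


@dataclass
class Soma:
    """A detected soma: center, refined closed boundary, and area."""

    center: tuple
    boundary: np.ndarray  # (N, 2) closed polygon vertices, (row, col) px
    area_um2: float
    response_ratio: float = 1.0
    has_neurite: bool = False
    fallback: bool = False
    scale: object = None

    def polygon(self) -> Polygon:
        return Polygon([(c, r) for r, c in self.boundary])


def log_response(image: ImageGrid, params: SomaParams) -> np.ndarray:
    """Scale-normalized negated LoG response; bright blobs become positive peaks."""
    sigma_px = params.log_sigma_um / image.scale.microns_per_pixel
    if sigma_px < 1:
        raise ValueError(
            f"LoG sigma {params.log_sigma_um} μm is below 1 px at this scale"
        )
    # the truncated discrete kernel does not sum exactly to zero; subtract
    # its DC response so a constant image maps to exactly zero
    m = 2 * int(np.ceil(4 * sigma_px)) + 1
    dc = ndimage.gaussian_laplace(np.ones((m, m)), sigma_px)[m // 2, m // 2]
    raw = ndimage.gaussian_laplace(image.intensities, sigma_px)
    return -(sigma_px**2) * (raw - dc * image.intensities)


def soma_regions(response: np.ndarray, params: SomaParams) -> np.ndarray:
    """Binary mask of pixels whose response ratio reaches the threshold."""
    peak = float(response.max())
    if peak <= 0:
        warnings.warn("all-zero (or negative) response: empty soma mask", stacklevel=2)
        return np.zeros(response.shape, dtype=bool)
    return (response / peak) >= params.response_ratio_threshold


def nms_centers(
    response: np.ndarray, mask: np.ndarray, window_px: int
) -> list[SomaCandidate]:
    """Strict window-maxima of the response lying inside the mask.

    A pixel survives if no pixel in its ``window_px`` × ``window_px``
    neighborhood has a larger response, and no equal-response pixel precedes
    it in (row, col) lexicographic order.  The window comparison ignores the
    mask, so raising the response-ratio threshold (shrinking the mask) can
    only remove candidates, never add them.
    """
    if window_px < 3 or window_px % 2 == 0:
        raise ValueError("window_px must be odd and >= 3")
    half = window_px // 2
    win_max = ndimage.maximum_filter(response, size=window_px, mode="nearest")
    h, w = response.shape
    out: list[SomaCandidate] = []
    peak = float(response.max())
    for r, c in np.argwhere(mask & (response == win_max)):
        val = response[r, c]
        r0, r1 = max(0, r - half), min(h, r + half + 1)
        c0, c1 = max(0, c - half), min(w, c + half + 1)
        block = response[r0:r1, c0:c1]
        ties = np.argwhere(block == val)
        first = ties[np.lexsort((ties[:, 1], ties[:, 0]))[0]]
        if (r0 + first[0], c0 + first[1]) == (r, c):
            out.append(
                SomaCandidate(center=(int(r), int(c)), response_ratio=float(val / peak))
            )
    out.sort(key=lambda cand: cand.center)
    return out


class _StabilityTracker:
    """Callback for the morphological level set: counts pixel-stable sweeps
    (the discrete analogue of mean boundary displacement below tolerance)."""

    def __init__(self, patience: int = 5):
        self.prev = None
        self.stable = 0
        self.iterations = 0

    def __call__(self, ls):
        self.iterations += 1
        cur = np.asarray(ls, dtype=bool)
        if self.prev is not None:
            self.stable = self.stable + 1 if np.array_equal(cur, self.prev) else 0
        self.prev = cur


def _largest_component_containing(mask: np.ndarray, center) -> np.ndarray | None:
    labels, n = ndimage.label(mask)
    if n == 0:
        return None
    lab_at = labels[int(round(center[0])), int(round(center[1]))]
    if lab_at > 0:
        return labels == lab_at
    return None


def refine_boundary(
    image: ImageGrid, candidate: SomaCandidate, params: SomaParams
) -> Soma:
    """Evolve a level set from a 40-μm circle to the soma boundary.

    Runs the two-phase piecewise-constant (Chan–Vese) model on a crop around
    the candidate; the output contour is the largest closed zero-level
    component containing the center.  If the contour collapses below 5 px²,
    falls back to a 15-μm circle flagged as such.
    """
    upp = image.scale.microns_per_pixel
    radius_px = params.init_circle_diameter_um / 2.0 / upp
    r0, c0 = candidate.center
    half = int(np.ceil(radius_px * 1.25))
    h, w = image.intensities.shape
    if r0 - radius_px < 0 or r0 + radius_px > h - 1 or c0 - radius_px < 0 or c0 + radius_px > w - 1:
        warnings.warn("init circle clipped to image bounds", stacklevel=2)
    rlo, rhi = max(0, r0 - half), min(h, r0 + half + 1)
    clo, chi = max(0, c0 - half), min(w, c0 + half + 1)
    crop = image.intensities[rlo:rhi, clo:chi]
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    init = radius_px - np.hypot(rr - r0, cc - c0)  # >0 inside the circle

    # two-phase piecewise-constant evolution (morphological ACWE); stops
    # early once the contour is pixel-stable for a few sweeps
    tracker = _StabilityTracker(patience=5)
    seg = morphological_chan_vese(
        crop,
        num_iter=params.lsm_max_iter,
        init_level_set=(init > 0),
        smoothing=1,
        iter_callback=tracker,
    ).astype(bool)
    if not seg[r0 - rlo, c0 - clo]:
        seg = ~seg
    # strip fingers thinner than a neurite (< 3.5 μm): the two-phase model
    # happily follows bright neurites out of the soma, but by definition
    # anything that thin is not soma
    open_r = max(1, int(round(1.75 / upp)))
    opened = opening(seg, disk(open_r))
    if opened[r0 - rlo, c0 - clo]:
        seg = opened
    comp = _largest_component_containing(seg, (r0 - rlo, c0 - clo))

    if comp is None or comp.sum() < 5:
        return _fallback_soma(candidate, image, upp)

    contours = find_contours(comp.astype(float), 0.5)
    best = None
    for cont in contours:
        poly = Polygon([(c, r) for r, c in cont])
        if not poly.is_valid:
            poly = poly.buffer(0)
        if poly.contains(Point(c0 - clo, r0 - rlo)) and (
            best is None or poly.area > best[1].area
        ):
            best = (cont, poly)
    if best is None or best[1].area < 5:
        return _fallback_soma(candidate, image, upp)

    contour, poly = best
    boundary = contour + [rlo, clo]
    return Soma(
        center=candidate.center,
        boundary=boundary,
        area_um2=float(poly.area) * upp**2,
        response_ratio=candidate.response_ratio,
        scale=image.scale,
    )


def _fallback_soma(candidate: SomaCandidate, image: ImageGrid, upp: float) -> Soma:
    # degenerate contour: report a 15-μm circle, flagged
    r_px = 7.5 / upp
    th = np.linspace(0, 2 * np.pi, 64, endpoint=False)
    r0, c0 = candidate.center
    boundary = np.column_stack([r0 + r_px * np.sin(th), c0 + r_px * np.cos(th)])
    return Soma(
        center=candidate.center,
        boundary=boundary,
        area_um2=np.pi * 7.5**2,
        response_ratio=candidate.response_ratio,
        fallback=True,
        scale=image.scale,
    )


def default_nms_window_px(image: ImageGrid, soma_radius_um: float = 10.0) -> int:
    """NMS window 2·⌈soma radius in px⌉+1: somata closer than a radius merge."""
    return 2 * int(np.ceil(soma_radius_um / image.scale.microns_per_pixel)) + 1


def detect_somata(
    image: ImageGrid, params: SomaParams | None = None, window_px: int | None = None
) -> list[Soma]:
    """Full soma-detection pass: LoG → threshold → NMS → level-set refinement."""
    params = params or SomaParams()
    resp = log_response(image, params)
    mask = soma_regions(resp, params)
    if window_px is None:
        window_px = default_nms_window_px(image)
    candidates = nms_centers(resp, mask, window_px)
    return [refine_boundary(image, cand, params) for cand in candidates]
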