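"""Shared machinery for neurite tracing.

A trace is an ordered sequence of points stepping a fixed arc length
``s1`` (default 15 px) per node, with the turn between consecutive steps
bounded by ``max_turn_deg``.  The observation model scores a step by the sum
of log pixel intensities sampled every ``arc_resolution_px`` along the
straight segment between consecutive points (bilinear interpolation in 2-D,
trilinear in 3-D; positions outside the image read the normalization floor).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ..image_io import EPS, ImageGrid, ImageStack, ScaleInfo

__all__ = [
    "TraceParams",
    "TracePoint",
    "TraceSequence",
    "segment_log_likelihood",
    "transition_prior",
    "check_termination",
    "find_initial_points",
]


@dataclass
class TraceParams:
    """Parameters shared by both tracing models.

    step_len_px
        Distance ``s1`` between consecutive tracing points, px.
    arc_resolution_px
        Sampling spacing for the segment likelihood and the angular
        quantization (Δθ = arc_resolution/s1 radians); smaller values give
        more accurate lengths at higher cost.
    max_turn_deg
        Hard bound on the direction change between consecutive steps.
    termination_window_um
        Side of the square (cube in 3-D) whose median intensity the
        termination rule compares against.
    max_candidates
        Cap on concurrently retained candidate sets in the greedy
        fully-connected-chain search.
    beam_width
        States kept per step in the dynamic program (None = exact DP).
    """

    step_len_px: float = 15.0
    arc_resolution_px: float = 0.5
    max_turn_deg: float = 60.0
    circle_diameter_um: float = 40.0
    termination_window_um: float = 10.0
    max_nodes: int = 200
    max_candidates: int = 10
    beam_width: int | None = 500
    seed: int = 0
    #: per-sample intensity floor applied in *path scoring* (not in the
    #: data): bounds the penalty of a dark sample at |log(score_floor)| so
    #: that a handful of background samples near a neurite tip cannot
    #: outweigh geometric fidelity along the whole path
    score_floor: float = 0.01
    #: override the derived heading count (used for small exactly-solvable
    #: trellises; None derives it from arc_resolution/step_len)
    n_directions_override: int | None = None

    def __post_init__(self) -> None:
        if not self.step_len_px > self.arc_resolution_px > 0:
            raise ValueError("require step_len_px > arc_resolution_px > 0")
        if not 0 < self.max_turn_deg < 180:
            raise ValueError("max_turn_deg must be in (0, 180)")
        if self.max_candidates < 1:
            raise ValueError("max_candidates must be >= 1")

    @property
    def n_directions(self) -> int:
        """Number of quantized headings: Δθ = arc_resolution/s1 radians."""
        if self.n_directions_override is not None:
            return self.n_directions_override
        return max(3, int(round(2 * np.pi * self.step_len_px / self.arc_resolution_px)))

    @property
    def samples_per_step(self) -> int:
        return max(1, int(np.ceil(self.step_len_px / self.arc_resolution_px - 1e-9)))


@dataclass
class TracePoint:
    position: np.ndarray  # (row, col[, depth]) float px
    incoming_direction: np.ndarray | None  # unit vector, None for the seed
    step_index: int


@dataclass
class TraceSequence:
    """One traced neurite as an ordered point sequence (vector representation)."""

    points: list
    log_posterior: float
    terminated: bool
    initial_point: tuple
    soma_id: int | None = None
    label: str | None = None
    scale: ScaleInfo | None = None
    diagnostics: dict = field(default_factory=dict)

    def positions(self) -> np.ndarray:
        return np.array([p.position for p in self.points], dtype=float)

    def path_length_px(self) -> float:
        pos = self.positions()
        if len(pos) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(pos, axis=0), axis=1).sum())

    @property
    def endpoint(self) -> np.ndarray:
        return np.asarray(self.points[-1].position, dtype=float)


# ---------------------------------------------------------------------------
# Fields: a uniform sampling interface over 2-D images and 3-D stacks.


class Field2D:
    """Bilinear intensity access plus the local-median termination statistic."""

    ndim = 2

    def __init__(self, image: ImageGrid):
        self.image = image
        self.arr = image.intensities
        self.scale = image.scale
        self.shape = np.array(self.arr.shape, dtype=float)

    def sample(self, positions: np.ndarray) -> np.ndarray:
        """Bilinear interpolation; positions outside read the floor EPS."""
        pos = np.asarray(positions, dtype=float)
        coords = pos.reshape(-1, 2).T
        vals = ndimage.map_coordinates(
            self.arr, coords, order=1, mode="constant", cval=EPS
        )
        return np.maximum(vals.reshape(pos.shape[:-1]), EPS)

    def inside(self, positions: np.ndarray) -> np.ndarray:
        pos = np.asarray(positions, dtype=float)
        return np.all((pos >= 0) & (pos <= self.shape - 1), axis=-1)

    def local_median(self, position, window_um: float) -> float:
        """Median intensity of the axis-aligned window (side ``window_um``,
        rounded to an odd pixel count) centered on the pixel containing
        ``position``, clipped at the image borders."""
        half = int(round(window_um / 2.0 / self.scale.microns_per_pixel))
        r = int(round(position[0]))
        c = int(round(position[1]))
        h, w = self.arr.shape
        block = self.arr[
            max(0, r - half) : min(h, r + half + 1),
            max(0, c - half) : min(w, c + half + 1),
        ]
        return float(np.median(block))


class Field3D:
    """Trilinear access over a stack, in isotropic pixel coordinates.

    Positions are ``(row, col, z)`` where ``z = depth_index * z_ratio`` and
    ``z_ratio = microns_per_slice / microns_per_pixel``, so Euclidean
    geometry (step length, turn angles) is physically isotropic.
    """

    ndim = 3

    def __init__(self, stack: ImageStack):
        self.stack = stack
        self.vol = stack.as_volume()  # (depth, h, w)
        self.scale = stack.scale
        self.z_ratio = self.scale.z_step / self.scale.microns_per_pixel
        d, h, w = self.vol.shape
        self.shape = np.array([h - 1, w - 1, (d - 1) * self.z_ratio], dtype=float)

    def sample(self, positions: np.ndarray) -> np.ndarray:
        pos = np.asarray(positions, dtype=float).reshape(-1, 3)
        coords = np.stack([pos[:, 2] / self.z_ratio, pos[:, 0], pos[:, 1]])
        vals = ndimage.map_coordinates(
            self.vol, coords, order=1, mode="constant", cval=EPS
        )
        out = np.maximum(vals, EPS)
        return out.reshape(np.asarray(positions).shape[:-1])

    def inside(self, positions: np.ndarray) -> np.ndarray:
        pos = np.asarray(positions, dtype=float)
        return np.all((pos >= 0) & (pos <= self.shape), axis=-1)

    def local_median(self, position, window_um: float) -> float:
        upp = self.scale.microns_per_pixel
        half_rc = int(round(window_um / 2.0 / upp))
        half_z = int(round(window_um / 2.0 / self.scale.z_step))
        r = int(round(position[0]))
        c = int(round(position[1]))
        z = int(round(position[2] / self.z_ratio))
        d, h, w = self.vol.shape
        block = self.vol[
            max(0, z - half_z) : min(d, z + half_z + 1),
            max(0, r - half_rc) : min(h, r + half_rc + 1),
            max(0, c - half_rc) : min(w, c + half_rc + 1),
        ]
        return float(np.median(block))


def as_field(image):
    if isinstance(image, ImageGrid):
        return Field2D(image)
    if isinstance(image, ImageStack):
        return Field3D(image)
    if isinstance(image, (Field2D, Field3D)):
        return image
    raise TypeError(f"cannot trace on {type(image)!r}")


# ---------------------------------------------------------------------------
# Elementary scores


def _segment_points(x_prev, x_curr, n: int) -> np.ndarray:
    """n points linearly interpolated on (x_prev, x_curr]: exclusive of the
    start, inclusive of the end."""
    x_prev = np.asarray(x_prev, dtype=float)
    x_curr = np.asarray(x_curr, dtype=float)
    t = (np.arange(1, n + 1) / n)[:, None]
    return x_prev[None, :] + t * (x_curr - x_prev)[None, :]


def segment_log_likelihood(image, x_prev, x_curr, arc_resolution_px: float = 0.5):
    """Sum of log intensities sampled along the segment from ``x_prev``
    (exclusive) to ``x_curr`` (inclusive) at ``arc_resolution_px`` spacing."""
    field = as_field(image)
    dist = float(np.linalg.norm(np.asarray(x_curr, float) - np.asarray(x_prev, float)))
    n = max(1, int(np.ceil(dist / arc_resolution_px - 1e-9)))
    pts = _segment_points(x_prev, x_curr, n)
    return float(np.log(field.sample(pts)).sum())


def batch_segment_ll(field, starts: np.ndarray, ends: np.ndarray, n: int,
                     floor: float = EPS) -> np.ndarray:
    """Vectorized segment log-likelihood for K equal-length segments."""
    starts = np.asarray(starts, dtype=float)
    ends = np.asarray(ends, dtype=float)
    t = np.arange(1, n + 1) / n
    pts = starts[:, None, :] + t[None, :, None] * (ends - starts)[:, None, :]
    vals = np.maximum(field.sample(pts.reshape(-1, starts.shape[1])), floor)
    return np.log(vals).reshape(len(starts), n).sum(axis=1)


def angle_between(u, v) -> float:
    """Angle between two unit vectors, degrees."""
    d = float(np.clip(np.dot(np.asarray(u, float), np.asarray(v, float)), -1.0, 1.0))
    return float(np.degrees(np.arccos(d)))


def transition_prior(dir_prev, dir_curr, params: TraceParams) -> float:
    """Hard geometric prior: 0 when the turn is within ``max_turn_deg``
    (boundary inclusive), -inf otherwise."""
    if angle_between(dir_prev, dir_curr) <= params.max_turn_deg + 1e-9:
        return 0.0
    return -np.inf


def check_termination(image, position, params: TraceParams, scale=None) -> bool:
    """Termination rule: intensity at ``position`` is equal to or lower than
    the median intensity of the surrounding window (10 × 10 μm by default),
    window clipped at image borders."""
    field = as_field(image)
    val = float(field.sample(np.asarray(position, dtype=float)[None, :])[0])
    med = field.local_median(position, params.termination_window_um)
    return val <= med + 1e-12


# ---------------------------------------------------------------------------
# Direction quantization (2-D)


def unit_from_angle(theta: np.ndarray) -> np.ndarray:
    """(row, col) unit vector for angle(s) measured CCW from +x (col),
    with +y pointing to decreasing row."""
    theta = np.asarray(theta, dtype=float)
    return np.stack([-np.sin(theta), np.cos(theta)], axis=-1)


class DirectionWheel:
    """The quantized set of 2-D headings with Δθ = arc_resolution/s1 rad."""

    def __init__(self, params: TraceParams):
        self.n = params.n_directions
        self.angles = 2 * np.pi * np.arange(self.n) / self.n
        self.vectors = unit_from_angle(self.angles)
        dtheta_deg = 360.0 / self.n
        self.max_offset = int(np.floor(params.max_turn_deg / dtheta_deg + 1e-9))

    def admissible_offsets(self) -> np.ndarray:
        return np.arange(-self.max_offset, self.max_offset + 1)

    def nearest_index(self, direction) -> int:
        d = np.asarray(direction, dtype=float)
        return int(np.argmax(self.vectors @ d))


# ---------------------------------------------------------------------------
# Initial points on the soma circle


def find_initial_points(
    image: ImageGrid,
    soma_center,
    params: TraceParams | None = None,
    merge_deg: float = 5.0,
) -> list[np.ndarray]:
    """Angular local intensity maxima on the 40-μm circle around a soma.

    The circle is sampled at an angular spacing giving at most
    ``arc_resolution_px`` arc steps; strict angular local maxima whose
    intensity exceeds the median of all circle samples are kept; maxima
    closer than ``merge_deg`` are merged keeping the brighter.
    """
    params = params or TraceParams()
    field = as_field(image)
    radius_px = params.circle_diameter_um / 2.0 / image.scale.microns_per_pixel
    center = np.asarray(soma_center, dtype=float)

    n = max(8, int(np.ceil(2 * np.pi * radius_px / params.arc_resolution_px)))
    theta = 2 * np.pi * np.arange(n) / n
    pts = center[None, :] + radius_px * unit_from_angle(theta)
    ok = field.inside(pts)
    if not ok.any():
        return []
    vals = np.where(ok, field.sample(pts), EPS)
    # smooth at roughly neurite-width scale so single noisy samples do not
    # masquerade as neurite crossings
    win = 5
    kernel = np.ones(win) / win
    padded = np.concatenate([vals[-(win // 2):], vals, vals[: win // 2]])
    vals = np.convolve(padded, kernel, mode="valid")
    med = float(np.median(vals))
    mad = float(np.median(np.abs(vals - med)))

    # margin: robust noise scale (and a floor against float roundoff on
    # flat background)
    above = vals > med + max(1e-3, 4.0 * mad)
    is_max = (vals > np.roll(vals, 1)) & (vals > np.roll(vals, -1)) & above & ok
    idx = np.flatnonzero(is_max)
    if len(idx) == 0:
        return []

    # merge maxima closer than merge_deg, brighter first
    order = idx[np.argsort(-vals[idx], kind="stable")]
    kept: list[int] = []
    min_sep = np.radians(merge_deg)
    for i in order:
        if all(_circ_dist(theta[i], theta[j]) >= min_sep for j in kept):
            kept.append(i)
    kept.sort()
    return [pts[i] for i in kept]


def _circ_dist(a: float, b: float) -> float:
    d = abs(a - b) % (2 * np.pi)
    return min(d, 2 * np.pi - d)


def sequence_segment_scores(field, positions: np.ndarray, params: TraceParams):
    """Per-step (segment log-likelihood, sample count) along a point path,
    with the scoring floor applied."""
    out = []
    for a, b in zip(positions[:-1], positions[1:]):
        dist = float(np.linalg.norm(b - a))
        n = max(1, int(np.ceil(dist / params.arc_resolution_px - 1e-9)))
        pts = _segment_points(a, b, n)
        vals = np.maximum(field.sample(pts), params.score_floor)
        out.append((float(np.log(vals).sum()), n))
    return out


def sequence_raw_score(field, positions: np.ndarray, params: TraceParams) -> float:
    """Σ segment log-likelihoods: the chain-model (HMM) path score."""
    return float(sum(s for s, _ in sequence_segment_scores(field, positions, params)))


def sequence_fcm_score(field, positions: np.ndarray, params: TraceParams) -> float:
    """Background-referenced full-sequence score used to pick among candidate
    sets: Σ (segment log-likelihood − n·log(local median at the segment
    midpoint)).  Steps brighter than local background contribute positively,
    so the maximizer favors the longest consistently-bright branch."""
    total = 0.0
    for (a, b), (ll, n) in zip(
        zip(positions[:-1], positions[1:]),
        sequence_segment_scores(field, positions, params),
    ):
        mid = (np.asarray(a, float) + np.asarray(b, float)) / 2.0
        bg = max(field.local_median(mid, params.termination_window_um),
                 params.score_floor)
        total += ll - n * np.log(bg)
    return float(total)


def sampled_background_level(field, position, window_um: float,
                             floor: float, n_grid: int = 12) -> float:
    """Lower-quartile *log* interpolated intensity on a dense grid spanning
    the window around ``position`` — a background-level estimate robust to
    the neurite itself occupying part of the window.

    The statistic uses the same interpolation as the segment likelihood:
    raw pixel medians diverge badly from bilinear-sample statistics when a
    noisy background clips at the floor (interpolation averages the clipped
    zeros away)."""
    p = np.asarray(position, dtype=float)
    half = window_um / 2.0 / field.scale.microns_per_pixel
    off = np.linspace(-half, half, n_grid)
    if field.ndim == 2:
        grid = np.stack(np.meshgrid(off, off, indexing="ij"), axis=-1).reshape(-1, 2)
    else:
        off_z = np.linspace(-half, half, max(3, n_grid // 2))
        grid = np.stack(
            np.meshgrid(off, off, off_z, indexing="ij"), axis=-1
        ).reshape(-1, 3)
    pts = p[None, :] + grid
    ok = field.inside(pts)
    if not ok.any():
        return float(np.log(floor))
    logs = np.log(np.maximum(field.sample(pts[ok]), floor))
    return float(np.quantile(logs, 0.25))


def step_background_threshold(field, x_prev, x_curr, params: TraceParams) -> float:
    """Score threshold for the step-contrast stopping test: half the
    background log-level per sample, i.e. a step continues the trace only
    while its geometric-mean intensity stays above the geometric mean of
    the local background level and full scale.

    This halfway-in-log-space criterion cleanly separates on-neurite steps
    from background steps in every background regime (noiseless floor,
    zero-clipped noise, noise on a pedestal): even the brightest of ~60
    candidate background directions — the selection bias the optimizer
    introduces, which defeats a plain median test — falls well below it,
    while tube steps sit near zero.  The price is a detectability limit:
    neurites dimmer than the square root of the background level terminate.
    """
    mid = (np.asarray(x_prev, float) + np.asarray(x_curr, float)) / 2.0
    n = params.samples_per_step
    bg_log = sampled_background_level(
        field, mid, params.termination_window_um, params.score_floor
    )
    return 0.5 * n * bg_log


def trim_tail(field, path, params: TraceParams, n_segments: int = 2,
              contrast: float = 0.5, floor: float = 0.05):
    """Localize the neurite tip after the termination rule fires.

    The fixed step length overshoots the true end of the neurite by up to
    one or two steps.  This resamples the trailing segments at
    arc_resolution and cuts the path at the last sample whose (lightly
    smoothed) intensity still exceeds the midpoint between the trace's own
    ridge brightness and the local background median — an intensity-edge
    localization that is robust both to a noise floor and to a normalized
    all-dark background.
    """
    path = [np.asarray(p, dtype=float) for p in path]
    if len(path) < 2:
        return path
    k = min(n_segments, len(path) - 1)
    prefix = path[: len(path) - k]

    # samples along the trailing k segments (exclusive of the joint start)
    tail_samples = []
    seg_bounds = []  # cumulative sample count at each trailing node
    total = 0
    for a, b in zip(path[-k - 1 : -1], path[-k:]):
        dist = float(np.linalg.norm(b - a))
        n = max(1, int(np.ceil(dist / params.arc_resolution_px - 1e-9)))
        tail_samples.append(_segment_points(a, b, n))
        total += n
        seg_bounds.append(total)
    samples = np.vstack(tail_samples)
    vals = field.sample(samples)
    kernel = np.ones(5) / 5.0
    smooth = np.convolve(np.pad(vals, 2, mode="edge"), kernel, mode="valid")

    # ridge brightness: median along the kept prefix (or the tail peak)
    if len(prefix) >= 2:
        ref = np.vstack(
            [
                _segment_points(a, b, max(1, int(np.linalg.norm(b - a))))
                for a, b in zip(prefix[:-1], prefix[1:])
            ]
        )
        ridge = float(np.median(field.sample(ref)))
    else:
        ridge = float(smooth.max())

    meds = np.array(
        [field.local_median(p, params.termination_window_um) for p in samples]
    )
    thresh = meds + np.maximum(floor, contrast * np.maximum(ridge - meds, 0.0))
    above = np.flatnonzero(smooth > thresh)
    if len(above) == 0:
        return prefix + [samples[0]]
    cut = int(above[-1])
    kept_nodes = [path[len(path) - k + j] for j, b in enumerate(seg_bounds) if b - 1 < cut]
    return prefix + kept_nodes + [samples[cut]]


def build_sequence(
    field,
    positions: list,
    params: TraceParams,
    terminated: bool,
    score: float,
    soma_id=None,
    diagnostics=None,
) -> TraceSequence:
    positions = [np.asarray(p, dtype=float) for p in positions]
    points = []
    for i, p in enumerate(positions):
        if i == 0:
            d = None
        else:
            step = p - positions[i - 1]
            nrm = np.linalg.norm(step)
            d = step / nrm if nrm > 0 else None
        points.append(TracePoint(position=p, incoming_direction=d, step_index=i))
    return TraceSequence(
        points=points,
        log_posterior=score,
        terminated=terminated,
        initial_point=tuple(positions[0]),
        soma_id=soma_id,
        scale=field.scale,
        diagnostics=diagnostics or {},
    )
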