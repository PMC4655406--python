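"""Synthetic fluorescent-neuron phantoms with exact ground truth.

The generator emulates the conditions that make real neuron images hard:
bright elliptical somata (15–30 μm), thin (<3.5 μm) curvilinear neurites
with branches, intensity steps and fading tips, debris blobs of soma-like
size, broad halos, and additive Gaussian background noise.  Every phantom
carries its ground truth (soma centers/boundaries, neurite polylines with
exact arc lengths and orientations), so detection and tracing are testable
without any external data.

Tubes are rendered by distance-to-polyline with a Gaussian cross-section,
σ = width / 2.355, i.e. the stated width is the full width at half maximum.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .image_io import ImageGrid, ImageStack, ScaleInfo

__all__ = [
    "SomaSpec",
    "NeuriteSpec",
    "SpurSpec",
    "DebrisSpec",
    "HaloSpec",
    "PhantomSpec",
    "TrueNeurite",
    "Phantom",
    "render",
    "branch_trap_spec",
    "branchy_spec",
    "snr_series",
    "render_tube_stack",
]

_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.355


def _unit(theta_deg: float) -> np.ndarray:
    t = np.radians(theta_deg)
    return np.array([-np.sin(t), np.cos(t)])


@dataclass(frozen=True)
class SomaSpec:
    center: tuple  # (row, col) px
    diameter_um: float = 20.0
    peak_intensity: float = 1.0
    axes_um: tuple | None = None  # (major, minor) μm for an ellipse
    angle_deg: float = 0.0


@dataclass(frozen=True)
class NeuriteSpec:
    """One neurite polyline attached to a soma.

    The polyline starts on the soma boundary at ``angle_deg`` and walks
    ``length_um`` of arc with optional constant curvature, heading kinks
    ``(at_um, turn_deg)``, piecewise-constant intensity changes
    ``(at_um, intensity)`` and a linear fade to zero over the final
    ``fade_tail_um``.
    """

    soma: int
    angle_deg: float
    length_um: float
    width_um: float = 2.5
    intensity: float = 1.0
    curvature_deg_per_um: float = 0.0
    kinks: tuple = ()
    intensity_breaks: tuple = ()
    fade_tail_um: float = 0.0


@dataclass(frozen=True)
class SpurSpec:
    """A side branch leaving a parent neurite ``at_um`` along its arc."""

    parent: int
    at_um: float
    turn_deg: float
    length_um: float
    intensity: float = 1.0
    width_um: float | None = None
    fade_tail_um: float = 0.0


@dataclass(frozen=True)
class DebrisSpec:
    center: tuple
    diameter_um: float = 10.0
    intensity: float = 0.8


@dataclass(frozen=True)
class HaloSpec:
    center: tuple
    radius_um: float = 60.0
    amplitude: float = 0.15


@dataclass(frozen=True)
class PhantomSpec:
    image_size_px: tuple = (512, 512)
    scale: ScaleInfo = field(default_factory=lambda: ScaleInfo(0.3125))
    somata: tuple = ()
    neurites: tuple = ()
    spurs: tuple = ()
    debris: tuple = ()
    halo: HaloSpec | None = None
    noise_sigma: float = 0.0
    background: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for n in self.neurites:
            if not n.width_um < 3.5:
                raise ValueError("neurites must be thinner than 3.5 μm")


@dataclass
class TrueNeurite:
    points: np.ndarray  # (N, 2) px polyline, starting at the soma boundary
    length_um: float  # arc length from soma boundary to tip
    orientation_deg: float
    axon: bool
    soma_id: int


@dataclass
class Phantom:
    image: ImageGrid | ImageStack
    raw: np.ndarray  # pre-normalization intensities
    true_soma_centers: list
    true_soma_boundaries: list
    true_neurites: list
    spec: PhantomSpec | None = None


# ---------------------------------------------------------------------------
# polyline construction


def _soma_radius_px(spec: SomaSpec, theta_deg: float, upp: float) -> float:
    if spec.axes_um is None:
        return spec.diameter_um / 2.0 / upp
    a, b = spec.axes_um[0] / 2.0 / upp, spec.axes_um[1] / 2.0 / upp
    t = np.radians(theta_deg - spec.angle_deg)
    return a * b / np.hypot(b * np.cos(t), a * np.sin(t))


def _build_polyline(start, heading_deg, length_um, upp, curvature=0.0, kinks=(),
                    step_px: float = 0.5):
    """Walk an arc of the requested length; returns (points, arc_um array,
    heading array)."""
    step_um = step_px * upp
    n = max(1, int(np.ceil(length_um / step_um)))
    pts = [np.asarray(start, dtype=float)]
    arcs = [0.0]
    headings = [heading_deg]
    heading = heading_deg
    s = 0.0
    pending = sorted(kinks)
    ki = 0
    for _ in range(n):
        ds_um = min(step_um, length_um - s)
        if ds_um <= 0:
            break
        while ki < len(pending) and pending[ki][0] <= s + 1e-12:
            heading += pending[ki][1]
            ki += 1
        heading += curvature * ds_um
        pts.append(pts[-1] + (ds_um / upp) * _unit(heading))
        s += ds_um
        arcs.append(s)
        headings.append(heading)
    return np.array(pts), np.array(arcs), np.array(headings)


def _clip_polyline(pts, arcs, headings, shape):
    ok = (
        (pts[:, 0] >= 0)
        & (pts[:, 0] <= shape[0] - 1)
        & (pts[:, 1] >= 0)
        & (pts[:, 1] <= shape[1] - 1)
    )
    if ok.all():
        return pts, arcs, headings
    cut = int(np.argmin(ok))  # first False
    cut = max(cut, 2)
    return pts[:cut], arcs[:cut], headings[:cut]


def _intensity_profile(arcs, base, breaks, fade_tail_um, total_um):
    vals = np.full(len(arcs), float(base))
    for at_um, inten in sorted(breaks):
        vals[arcs >= at_um - 1e-12] = inten
    if fade_tail_um > 0:
        t0 = total_um - fade_tail_um
        tail = arcs > t0
        vals[tail] *= np.clip((total_um - arcs[tail]) / fade_tail_um, 0.0, 1.0)
    return vals


# ---------------------------------------------------------------------------
# rasterization helpers


def _stamp_max(canvas, rows, cols, values):
    np.maximum.at(canvas, (rows, cols), values)


def _render_tube(canvas, pts, intensities, width_px: float):
    """Max-accumulate a Gaussian-cross-section tube along a dense polyline."""
    sigma = max(width_px / _FWHM, 0.4)
    w = int(np.ceil(3 * sigma)) + 1
    h, wd = canvas.shape
    off = np.arange(-w, w + 1)
    orr, occ = np.meshgrid(off, off, indexing="ij")
    for p, inten in zip(pts, intensities):
        if inten <= 0:
            continue
        r0, c0 = int(round(p[0])), int(round(p[1]))
        rr = r0 + orr
        cc = c0 + occ
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < wd)
        if not ok.any():
            continue
        d2 = (rr - p[0]) ** 2 + (cc - p[1]) ** 2
        vals = inten * np.exp(-d2 / (2 * sigma**2))
        _stamp_max(canvas, rr[ok], cc[ok], vals[ok])


def _render_blob(canvas, center, radius_px, peak, power, axes=None, angle_deg=0.0):
    h, w = canvas.shape
    half = int(np.ceil(radius_px * 2.5)) + 2
    r0, c0 = center
    rlo, rhi = max(0, int(r0) - half), min(h, int(r0) + half + 1)
    clo, chi = max(0, int(c0) - half), min(w, int(c0) + half + 1)
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    dr, dc = rr - r0, cc - c0
    if axes is None:
        rho = np.hypot(dr, dc) / radius_px
    else:
        a, b = axes
        t = np.radians(angle_deg)
        u = dc * np.cos(t) - dr * np.sin(t)
        v = dc * np.sin(t) + dr * np.cos(t)
        rho = np.hypot(u / a, v / b)
    vals = peak * np.exp(-np.log(2) * rho**power)
    np.maximum(canvas[rlo:rhi, clo:chi], vals, out=canvas[rlo:rhi, clo:chi])


# ---------------------------------------------------------------------------
# main entry points


def render(spec: PhantomSpec) -> Phantom:
    """Render a phantom deterministically from its spec (seeded noise)."""
    upp = spec.scale.microns_per_pixel
    h, w = spec.image_size_px
    canvas = np.full((h, w), float(spec.background))

    boundaries = []
    for s in spec.somata:
        r_px = s.diameter_um / 2.0 / upp
        axes = None
        if s.axes_um is not None:
            axes = (s.axes_um[0] / 2.0 / upp, s.axes_um[1] / 2.0 / upp)
            r_px = max(axes)
        _render_blob(canvas, s.center, r_px, s.peak_intensity, 8, axes, s.angle_deg)
        th = np.linspace(0, 360, 181)
        radii = np.array([_soma_radius_px(s, t, upp) for t in th])
        boundaries.append(
            np.column_stack(
                [
                    s.center[0] - radii * np.sin(np.radians(th)),
                    s.center[1] + radii * np.cos(np.radians(th)),
                ]
            )
        )

    # neurites (and their ground-truth polylines)
    true_neurites: list[TrueNeurite] = []
    parent_data = []
    for nspec in spec.neurites:
        soma = spec.somata[nspec.soma]
        r0 = _soma_radius_px(soma, nspec.angle_deg, upp)
        start = np.asarray(soma.center, float) + r0 * _unit(nspec.angle_deg)
        pts, arcs, headings = _build_polyline(
            start, nspec.angle_deg, nspec.length_um, upp,
            nspec.curvature_deg_per_um, nspec.kinks,
        )
        pts, arcs, headings = _clip_polyline(pts, arcs, headings, (h, w))
        inten = _intensity_profile(
            arcs, nspec.intensity, nspec.intensity_breaks,
            nspec.fade_tail_um, arcs[-1],
        )
        # densify for rendering (0.25 px)
        dense_pts, dense_int = _densify(pts, inten)
        _render_tube(canvas, dense_pts, dense_int, nspec.width_um / upp)
        parent_data.append((pts, arcs, headings, nspec))
        d = pts[-1] - pts[0]
        true_neurites.append(
            TrueNeurite(
                points=pts,
                length_um=float(arcs[-1]),
                orientation_deg=_angle_of(d),
                axon=False,
                soma_id=nspec.soma,
            )
        )

    for sp in spec.spurs:
        pts_p, arcs_p, head_p, nspec = parent_data[sp.parent]
        k = int(np.argmin(np.abs(arcs_p - sp.at_um)))
        start = pts_p[k]
        heading = head_p[k] + sp.turn_deg
        pts, arcs, _ = _build_polyline(start, heading, sp.length_um, upp)
        pts, arcs, _ = _clip_polyline(pts, arcs, np.zeros(len(pts)), (h, w))
        inten = _intensity_profile(arcs, sp.intensity, (), sp.fade_tail_um, arcs[-1])
        dense_pts, dense_int = _densify(pts, inten)
        width = sp.width_um if sp.width_um is not None else nspec.width_um
        _render_tube(canvas, dense_pts, dense_int, width / upp)
        d = pts[-1] - pts_p[0]
        true_neurites.append(
            TrueNeurite(
                points=np.vstack([pts_p[: k + 1], pts[1:]]),
                length_um=float(arcs_p[k] + arcs[-1]),
                orientation_deg=_angle_of(d),
                axon=False,
                soma_id=nspec.soma,
            )
        )

    for db in spec.debris:
        _render_blob(canvas, db.center, db.diameter_um / 2.0 / upp, db.intensity, 4)
    if spec.halo is not None:
        hl = spec.halo
        rr, cc = np.mgrid[0:h, 0:w]
        d2 = (rr - hl.center[0]) ** 2 + (cc - hl.center[1]) ** 2
        canvas = np.maximum(canvas, hl.amplitude * np.exp(-d2 / (2 * (hl.radius_um / upp) ** 2)))

    # longest true neurite per soma is the axon
    by_soma: dict[int, list[TrueNeurite]] = {}
    for t in true_neurites:
        by_soma.setdefault(t.soma_id, []).append(t)
    for items in by_soma.values():
        max(items, key=lambda t: t.length_um).axon = True

    rng = np.random.default_rng(spec.seed)
    raw = canvas
    if spec.noise_sigma > 0:
        raw = canvas + rng.normal(0.0, spec.noise_sigma, canvas.shape)
    raw = np.clip(raw, 0.0, 1.0)

    return Phantom(
        image=ImageGrid.from_raw(raw, spec.scale),
        raw=raw,
        true_soma_centers=[np.asarray(s.center, float) for s in spec.somata],
        true_soma_boundaries=boundaries,
        true_neurites=true_neurites,
        spec=spec,
    )


def _densify(pts, inten, step: float = 0.25):
    out_p, out_i = [], []
    for a, b, ia, ib in zip(pts[:-1], pts[1:], inten[:-1], inten[1:]):
        d = float(np.linalg.norm(b - a))
        n = max(1, int(np.ceil(d / step)))
        t = np.arange(n) / n
        out_p.append(a[None, :] + t[:, None] * (b - a)[None, :])
        out_i.append(ia + t * (ib - ia))
    out_p.append(pts[-1:])
    out_i.append(np.array([inten[-1]]))
    return np.vstack(out_p), np.concatenate(out_i)


def _angle_of(d) -> float:
    ang = float(np.degrees(np.arctan2(-d[0], d[1])))
    if ang <= -180.0:
        ang += 360.0
    return ang


def branch_trap_spec(
    long_len_um: float = 150.0,
    short_len_um: float = 40.0,
    long_intensity: float = 0.7,
    short_intensity: float = 1.0,
    junction_um: float = 20.0,
    seed: int = 0,
) -> PhantomSpec:
    """A Y-branch engineered so the *short* branch is locally brighter at the
    junction: the discriminating fixture for chain-DP vs candidate-set
    tracing.  Lengths are arcs from the soma boundary; the shared trunk runs
    ``junction_um`` at the short branch's intensity, after which the long
    branch continues dimmer while the bright short branch turns off."""
    if not (short_intensity > long_intensity and long_len_um > short_len_um):
        raise ValueError("need short_intensity > long_intensity and longer long branch")
    axon = NeuriteSpec(
        soma=0,
        angle_deg=0.0,
        length_um=long_len_um,
        width_um=2.5,
        intensity=short_intensity,
        kinks=((junction_um, 25.0),),
        intensity_breaks=((junction_um, long_intensity),),
        fade_tail_um=10.0,
    )
    spur = SpurSpec(
        parent=0,
        at_um=junction_um,
        turn_deg=-25.0,
        length_um=short_len_um - junction_um,
        intensity=short_intensity,
        fade_tail_um=5.0,
    )
    return PhantomSpec(
        image_size_px=(512, 640),
        scale=ScaleInfo(0.3125),
        somata=(SomaSpec(center=(384, 80), diameter_um=20.0),),
        neurites=(axon,),
        spurs=(spur,),
        seed=seed,
    )


def branchy_spec(n_branches: int = 15, seed: int = 0) -> PhantomSpec:
    """A main neurite sprouting ``n_branches`` bright side branches, for
    exercising the candidate-set cap."""
    spurs = tuple(
        SpurSpec(
            parent=0,
            at_um=25.0 + 7.0 * k,
            turn_deg=40.0 if k % 2 == 0 else -40.0,
            length_um=25.0,
            intensity=0.75,
            fade_tail_um=5.0,
        )
        for k in range(n_branches)
    )
    main = NeuriteSpec(
        soma=0, angle_deg=0.0, length_um=150.0, intensity=0.9, fade_tail_um=10.0
    )
    return PhantomSpec(
        image_size_px=(512, 704),
        scale=ScaleInfo(0.3125),
        somata=(SomaSpec(center=(256, 80), diameter_um=20.0),),
        neurites=(main,),
        spurs=spurs,
        seed=seed,
    )


def random_neuron_spec(
    seed: int,
    image_size_px: tuple = (448, 448),
    microns_per_pixel: float = 0.625,
    n_neurites: int = 2,
    n_debris: int = 3,
    noise_sigma: float = 0.05,
    background: float = 0.1,
) -> PhantomSpec:
    """A randomized one-neuron phantom with debris distractors.

    One soma (diameter 16–26 μm) near the image center, ``n_neurites``
    straight-to-gently-curved neurites (length 40–90 μm), and ``n_debris``
    blobs (6–12 μm, dimmer than the soma) placed away from the soma circle
    and the neurite paths.  Deterministic in ``seed``.
    """
    rng = np.random.default_rng(seed)
    h, w = image_size_px
    upp = microns_per_pixel
    center = (
        float(rng.uniform(0.42, 0.58) * h),
        float(rng.uniform(0.42, 0.58) * w),
    )
    soma = SomaSpec(
        center=center,
        diameter_um=float(rng.uniform(16.0, 26.0)),
        peak_intensity=1.0,
    )
    base_angle = float(rng.uniform(-180, 180))
    neurites = tuple(
        NeuriteSpec(
            soma=0,
            angle_deg=base_angle + k * (360.0 / n_neurites) + float(rng.uniform(-25, 25)),
            length_um=float(rng.uniform(40.0, 90.0)),
            width_um=float(rng.uniform(2.0, 3.0)),
            intensity=float(rng.uniform(0.85, 1.0)),
            curvature_deg_per_um=float(rng.uniform(-0.4, 0.4)),
            fade_tail_um=5.0,
        )
        for k in range(n_neurites)
    )
    # debris: keep clear of the soma circle and (coarsely) of neurite paths
    margin_px = 30.0 / upp
    debris = []
    tries = 0
    while len(debris) < n_debris and tries < 200:
        tries += 1
        pos = (float(rng.uniform(25, h - 25)), float(rng.uniform(25, w - 25)))
        if np.hypot(pos[0] - center[0], pos[1] - center[1]) < 2.2 * margin_px / 2:
            continue
        ok = True
        for n in neurites:
            ang = np.radians(n.angle_deg)
            u = np.array([-np.sin(ang), np.cos(ang)])
            rel = np.array(pos) - np.array(center)
            t = float(np.clip(rel @ u, 0, n.length_um / upp + 20))
            if np.linalg.norm(rel - t * u) < 12.0 / upp:
                ok = False
                break
        if ok:
            debris.append(
                DebrisSpec(
                    center=pos,
                    diameter_um=float(rng.uniform(6.0, 12.0)),
                    intensity=float(rng.uniform(0.5, 0.9)),
                )
            )
    return PhantomSpec(
        image_size_px=image_size_px,
        scale=ScaleInfo(upp),
        somata=(soma,),
        neurites=neurites,
        debris=tuple(debris),
        noise_sigma=noise_sigma,
        background=background,
        seed=seed,
    )


def snr_series(spec: PhantomSpec, noise_levels) -> list:
    """Re-render the same geometry (same seed) at each noise level."""
    return [render(dataclasses.replace(spec, noise_sigma=lv)) for lv in noise_levels]


def render_tube_stack(
    shape_dhw: tuple,
    polylines,
    scale: ScaleInfo,
    width_px: float = 3.0,
    intensity: float = 1.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> Phantom:
    """Render bright 3-D tubes into a stack.

    ``polylines`` are (N, 3) arrays of (row, col, depth_index) points; the
    tube cross-section is Gaussian with the given in-plane σ-equivalent
    width.  Ground truth records arc length in μm using the anisotropic
    scale.
    """
    d, h, w = shape_dhw
    vol = np.zeros((d, h, w))
    sigma = max(width_px / _FWHM, 0.4)
    half = int(np.ceil(3 * sigma)) + 1
    zr = scale.z_step / scale.microns_per_pixel
    truths = []
    for pl in polylines:
        pl = np.asarray(pl, dtype=float)
        dense = []
        for a, b in zip(pl[:-1], pl[1:]):
            seg = np.linalg.norm((b - a) * np.array([1.0, 1.0, zr]))
            n = max(1, int(np.ceil(seg / 0.5)))
            t = np.arange(n)[:, None] / n
            dense.append(a[None, :] + t * (b - a)[None, :])
        dense.append(pl[-1:])
        dense = np.vstack(dense)
        for p in dense:
            z0, r0, c0 = int(round(p[2])), int(round(p[0])), int(round(p[1]))
            for dz in range(-2, 3):
                z = z0 + dz
                if not 0 <= z < d:
                    continue
                rlo, rhi = max(0, r0 - half), max(0, min(h, r0 + half + 1))
                clo, chi = max(0, c0 - half), max(0, min(w, c0 + half + 1))
                if rlo >= rhi or clo >= chi:
                    continue
                rr, cc = np.mgrid[rlo:rhi, clo:chi]
                d2 = (rr - p[0]) ** 2 + (cc - p[1]) ** 2 + ((z - p[2]) * zr) ** 2
                np.maximum(
                    vol[z, rlo:rhi, clo:chi],
                    intensity * np.exp(-d2 / (2 * sigma**2)),
                    out=vol[z, rlo:rhi, clo:chi],
                )
        steps = np.diff(pl, axis=0) * np.array([1.0, 1.0, zr])
        length_um = float(np.linalg.norm(steps, axis=1).sum()) * scale.microns_per_pixel
        truths.append(
            TrueNeurite(
                points=pl,
                length_um=length_um,
                orientation_deg=_angle_of(pl[-1, :2] - pl[0, :2]),
                axon=True,
                soma_id=-1,
            )
        )
    rng = np.random.default_rng(seed)
    raw = vol
    if noise_sigma > 0:
        raw = vol + rng.normal(0.0, noise_sigma, vol.shape)
    raw = np.clip(raw, 0.0, 1.0)
    return Phantom(
        image=ImageStack.from_raw(raw, scale),
        raw=raw,
        true_soma_centers=[],
        true_soma_boundaries=[],
        true_neurites=truths,
    )
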