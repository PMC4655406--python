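"""Tracing in image stacks: latent positions carry (row, column, depth).

Stacks often show no soma at all (e.g. axons crossing a volume), so tracing
can start from automatically seeded neurite-like points — bright 3-D local
maxima — and the per-seed traces are greedily linked into longer sequences
afterwards.  Depth is rescaled by microns-per-slice / microns-per-pixel
internally so step lengths and turn angles are physically isotropic.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ._core import (
    TraceParams,
    angle_between,
    as_field,
    build_sequence,
    sequence_raw_score,
)
from .fcm import trace_fcm

__all__ = ["seed_neurite_points", "trace_stack", "link_sequences"]


def seed_neurite_points(stack, params: TraceParams | None = None, max_seeds: int = 50):
    """Neurite-like seed points: 3-D local intensity maxima (26-neighborhood)
    above the stack's 95th intensity percentile, subsampled uniformly at
    random to ``max_seeds`` using ``params.seed``.

    Returns positions as ``(row, col, depth_index)`` floats.
    """
    params = params or TraceParams()
    vol = stack.as_volume()
    mx = ndimage.maximum_filter(vol, size=3, mode="nearest")
    thr = float(np.quantile(vol, 0.95))
    cand = np.argwhere((vol == mx) & (vol > thr))  # (depth, row, col)
    if len(cand) == 0:
        return []
    if len(cand) > max_seeds:
        rng = np.random.default_rng(params.seed)
        pick = np.sort(rng.choice(len(cand), size=max_seeds, replace=False))
        cand = cand[pick]
    return [np.array([r, c, d], dtype=float) for d, r, c in cand]


def trace_stack(stack, seeds=None, params: TraceParams | None = None):
    """Trace neurites through a stack with the candidate-set (FCM) tracer.

    When ``seeds`` is empty or None they are generated by
    :func:`seed_neurite_points`; the per-seed traces are then linked by
    :func:`link_sequences`.  A depth-1 stack reduces to plain 2-D tracing.
    """
    params = params or TraceParams()
    if not seeds:
        seeds = seed_neurite_points(stack, params)
    sequences = [trace_fcm(stack, seed, params) for seed in seeds]
    sequences = [s for s in sequences if len(s.points) >= 2]
    return link_sequences(sequences, params, image=stack)


def _iso_positions(seq):
    pos = seq.positions()
    if pos.shape[1] == 3 and seq.scale is not None:
        zr = seq.scale.z_step / seq.scale.microns_per_pixel
        pos = pos.copy()
        pos[:, 2] *= zr
    return pos


def _end_dir(pos: np.ndarray, head: bool) -> np.ndarray:
    v = pos[0] - pos[1] if head else pos[-1] - pos[-2]
    return v / np.linalg.norm(v)


def link_sequences(sequences, params: TraceParams | None = None, image=None):
    """Greedily merge sequences whose endpoints are within 2·s1 px and whose
    terminal directions are compatible (turn ≤ max_turn_deg across the
    joint), closest pairs first, re-scoring merged sequences, to fixpoint."""
    params = params or TraceParams()
    seqs = list(sequences)
    if len(seqs) < 2:
        return seqs

    field = as_field(image) if image is not None else None
    changed = True
    while changed:
        changed = False
        pairs = []
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                pi, pj = _iso_positions(seqs[i]), _iso_positions(seqs[j])
                if len(pi) < 2 or len(pj) < 2:
                    continue
                for ei, head_i in ((pi[0], True), (pi[-1], False)):
                    for ej, head_j in ((pj[0], True), (pj[-1], False)):
                        dist = float(np.linalg.norm(ei - ej))
                        if dist > 2 * params.step_len_px:
                            continue
                        # outgoing directions at the joined ends must be
                        # anti-parallel within the turn bound
                        di = _end_dir(pi, head_i)
                        dj = _end_dir(pj, head_j)
                        if angle_between(di, -dj) > params.max_turn_deg + 1e-9:
                            continue
                        pairs.append((dist, i, j, head_i, head_j))
        if not pairs:
            break
        pairs.sort(key=lambda t: t[0])
        dist, i, j, head_i, head_j = pairs[0]
        merged = _merge(seqs[i], seqs[j], head_i, head_j, params, field)
        seqs = [s for k, s in enumerate(seqs) if k not in (i, j)] + [merged]
        changed = True
    return seqs


def _merge(sa, sb, head_a, head_b, params, field):
    pa = [p.position for p in sa.points]
    pb = [p.position for p in sb.points]
    if head_a:  # joint is at a's head: reverse a so its tail meets b
        pa = pa[::-1]
    if not head_b:  # joint must be b's head
        pb = pb[::-1]
    positions = [np.asarray(p, float) for p in pa + pb]
    terminated = sb.terminated if not head_b else sa.terminated
    if field is not None:
        iso = np.array(positions, dtype=float)
        if iso.shape[1] == 3:
            iso = iso.copy()
            iso[:, 2] *= field.z_ratio
        score = sequence_raw_score(field, iso, params)
        seq = build_sequence(field, positions, params, terminated, score)
        # build_sequence stores native positions; keep them as passed
        return seq
    score = sa.log_posterior + sb.log_posterior
    from ._core import TraceSequence, TracePoint

    points = [
        TracePoint(position=p, incoming_direction=None, step_index=k)
        for k, p in enumerate(positions)
    ]
    return TraceSequence(
        points=points,
        log_posterior=score,
        terminated=terminated,
        initial_point=tuple(positions[0]),
        scale=sa.scale,
    )
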