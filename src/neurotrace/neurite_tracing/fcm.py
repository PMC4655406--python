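"""Fully-connected chain model tracing by the variant greedy algorithm.

Unlike the chain/Viterbi tracer, which commits to the single best path and
therefore follows the locally brighter branch at a junction, this search
keeps multiple *candidate sets* of tracing points alive: at each node every
candidate advances to the locally best next position, and when the one-step
score has several local maxima over the admissible direction fan (a branch
point) the extra maxima spawn new candidate sets, up to a hard cap
(``max_candidates``, default 10).  Each candidate runs until the local-median
termination rule fires or ``max_nodes`` is reached; the returned trace is
the candidate maximizing the background-referenced full-sequence score,
which rewards every step brighter than its local background and therefore
favors the longest consistently-bright branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.spatial import cKDTree

from ._core import (
    DirectionWheel,
    Field3D,
    TraceParams,
    as_field,
    batch_segment_ll,
    build_sequence,
    check_termination,
    sequence_fcm_score,
    step_background_threshold,
    trim_tail,
)

__all__ = ["trace_fcm"]


class _Fan2D:
    """Quantized heading fan in 2-D: full circle on the first step, a
    ±max_turn window afterwards; local maxima against angular neighbors."""

    def __init__(self, params: TraceParams):
        self.wheel = DirectionWheel(params)

    def fan(self, dir_idx, outward=None):
        n = self.wheel.n
        if dir_idx is None:
            idx = np.arange(n)
            if outward is not None and np.linalg.norm(outward) > 0:
                idx = idx[self.wheel.vectors @ outward >= 0]
            circular = outward is None
        else:
            idx = (dir_idx + self.wheel.admissible_offsets()) % n
            circular = False
        return idx, self.wheel.vectors[idx], circular

    @staticmethod
    def local_maxima(scores: np.ndarray, circular: bool) -> np.ndarray:
        if len(scores) == 0:
            return np.array([], dtype=int)
        if circular:
            left, right = np.roll(scores, 1), np.roll(scores, -1)
        else:
            left = np.concatenate([[-np.inf], scores[:-1]])
            right = np.concatenate([scores[1:], [-np.inf]])
        return np.flatnonzero((scores > left) & (scores > right))


class _Fan3D:
    """Fibonacci-lattice heading fan on the unit sphere (~7.5° spacing);
    local maxima against the 6 nearest lattice neighbors."""

    def __init__(self, params: TraceParams, n: int = 700):
        i = np.arange(n) + 0.5
        z = 1.0 - 2.0 * i / n
        r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
        phi = i * np.pi * (3.0 - np.sqrt(5.0))
        self.vectors = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
        _, nb = cKDTree(self.vectors).query(self.vectors, k=7)
        self.neighbors = nb[:, 1:]
        self.cos_max = np.cos(np.radians(params.max_turn_deg)) - 1e-12

    def fan(self, dir_idx, outward=None):
        if dir_idx is None:
            idx = np.arange(len(self.vectors))
            if outward is not None and np.linalg.norm(outward) > 0:
                idx = idx[self.vectors @ outward >= 0]
        else:
            idx = np.flatnonzero(self.vectors @ self.vectors[dir_idx] >= self.cos_max)
        return idx, self.vectors[idx], False

    def local_maxima_global(self, fan_idx: np.ndarray, scores: np.ndarray) -> np.ndarray:
        full = np.full(len(self.vectors), -np.inf)
        full[fan_idx] = scores
        keep = []
        for k, gi in enumerate(fan_idx):
            if np.isfinite(scores[k]) and scores[k] > full[self.neighbors[gi]].max():
                keep.append(k)
        return np.array(keep, dtype=int)


@dataclass
class _Candidate:
    positions: list
    dir_idx: int | None = None
    terminated: bool = False
    active: bool = True
    spawned_at: int = 0
    log: dict = dc_field(default_factory=dict)


def trace_fcm(image, initial_point, params: TraceParams | None = None, soma_center=None):
    """Trace one neurite with the capped greedy candidate-set search.

    Accepts a 2-D ``ImageGrid`` or a 3-D ``ImageStack`` (positions then take
    a third, depth-index coordinate; a depth-1 stack reduces exactly to the
    2-D trace).  Returns the best candidate as a :class:`TraceSequence`;
    ``diagnostics['max_candidates']`` records the peak number of concurrent
    candidate sets.
    """
    params = params or TraceParams()
    field = as_field(image)

    if field.ndim == 3 and field.vol.shape[0] == 1:
        # depth-1 stack: exact dimensional reduction to the 2-D tracer
        from ..image_io import ImageGrid

        plane = ImageGrid(field.vol[0], field.scale)
        seq2 = trace_fcm(plane, np.asarray(initial_point, float)[:2], params,
                         soma_center=soma_center)
        pos3 = [np.array([p.position[0], p.position[1], 0.0]) for p in seq2.points]
        seq3 = build_sequence(field, pos3, params, seq2.terminated,
                              seq2.log_posterior, diagnostics=seq2.diagnostics)
        return seq3

    x0 = np.asarray(initial_point, dtype=float)
    if field.ndim == 3:
        x0 = np.array([x0[0], x0[1], x0[2] * field.z_ratio])
    if not field.inside(x0):
        raise ValueError("initial point outside image")

    if check_termination(field, x0, params):
        return _finish(field, [_Candidate([x0], terminated=True)], params, 1)

    fan_model = _Fan2D(params) if field.ndim == 2 else _Fan3D(params)
    outward = excl_center = excl_r = None
    if soma_center is not None:
        sc = np.asarray(soma_center, dtype=float)
        if field.ndim == 3:
            sc = np.array([sc[0], sc[1], sc[2] * field.z_ratio])
        outward = x0 - sc
        excl_center = sc
        excl_r = 0.9 * params.circle_diameter_um / 2.0 / field.scale.microns_per_pixel

    candidates = [_Candidate([x0])]
    max_seen = 1
    s1 = params.step_len_px
    nsamp = params.samples_per_step

    for _node in range(params.max_nodes):
        if not any(c.active for c in candidates):
            break
        for cand in list(candidates):
            if not cand.active:
                continue
            cur = cand.positions[-1]
            fan_idx, vecs, circular = fan_model.fan(
                cand.dir_idx, outward if cand.dir_idx is None else None
            )
            ends = cur[None, :] + s1 * vecs
            ok = field.inside(ends)
            if excl_center is not None:
                ok &= np.linalg.norm(ends - excl_center, axis=-1) >= excl_r
            if not ok.any():
                cand.active = False
                continue
            scores = np.full(len(fan_idx), -np.inf)
            scores[ok] = batch_segment_ll(
                field, np.broadcast_to(cur, ends[ok].shape), ends[ok], nsamp,
                params.score_floor,
            )

            if isinstance(fan_model, _Fan3D):
                maxima = fan_model.local_maxima_global(fan_idx, scores)
            else:
                maxima = fan_model.local_maxima(scores, circular)
            maxima = maxima[np.isfinite(scores[maxima])]
            if len(maxima) == 0:
                maxima = np.array([int(np.nanargmax(np.where(ok, scores, -np.inf)))])

            order = maxima[np.argsort(-scores[maxima], kind="stable")]
            best = order[0]

            # branch point: spawn candidate sets for the other local maxima
            # (only directions distinctly brighter than local background —
            # genuine ridges, not noise)
            for extra in order[1:]:
                if len(candidates) >= params.max_candidates:
                    break
                thr = step_background_threshold(field, cur, ends[extra], params)
                if float(scores[extra]) <= thr:
                    continue
                spawn = _Candidate(
                    positions=list(cand.positions) + [ends[extra]],
                    dir_idx=int(fan_idx[extra]),
                    spawned_at=len(cand.positions),
                )
                _advance_termination(field, spawn, params, float(scores[extra]))
                candidates.append(spawn)

            cand.positions.append(ends[best])
            cand.dir_idx = int(fan_idx[best])
            _advance_termination(field, cand, params, float(scores[best]))
        max_seen = max(max_seen, len(candidates))

    return _finish(field, candidates, params, max_seen)


def _advance_termination(field, cand: _Candidate, params, step_ll: float) -> None:
    if len(cand.positions) - 1 >= params.max_nodes:
        cand.active = False
    bg_thr = step_background_threshold(
        field, cand.positions[-2], cand.positions[-1], params
    )
    fired = check_termination(field, cand.positions[-1], params) or step_ll <= bg_thr
    if fired:
        cand.positions = trim_tail(field, cand.positions, params)
        cand.terminated = True
        cand.active = False


def _finish(field, candidates, params, max_seen):
    scored = []
    for cand in candidates:
        pos = np.array([np.asarray(p, float) for p in cand.positions])
        s = sequence_fcm_score(field, pos, params) if len(pos) > 1 else -np.inf
        scored.append((s, cand))
    best_score = max(s for s, _ in scored)
    tied = [(s, c) for s, c in scored if s == best_score]
    # ties: longer path first, then lexicographically smallest endpoint
    tied.sort(
        key=lambda sc: (
            -len(sc[1].positions),
            tuple(np.asarray(sc[1].positions[-1], float)),
        )
    )
    score, cand = tied[0]
    positions = [np.asarray(p, float) for p in cand.positions]
    if field.ndim == 3:
        positions = [np.array([p[0], p[1], p[2] / field.z_ratio]) for p in positions]
    seq = build_sequence(
        field,
        positions,
        params,
        terminated=cand.terminated,
        score=float(score) if np.isfinite(score) else 0.0,
        diagnostics={"max_candidates": max_seen, "n_candidates": len(candidates)},
    )
    return seq
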