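"""MAP neurite tracing as a chain (hidden-Markov) model optimized by
dynamic programming.

The latent state is the pair (tracing-point position, incoming heading): the
turn constraint couples two consecutive steps, and augmenting the position
with the heading restores the first-order Markov property the DP needs.
Headings are quantized at Δθ = arc_resolution/s1 radians and positions at
arc_resolution, which keeps the trellis finite; an optional beam keeps the
forward pass tractable on full-size images.

Tracing is terminated sequentially: after each forward step the endpoint of
the current best path is tested against the local-median rule; the first
firing stops the trace, and the terminal point is refined to the first
interpolated sample that satisfies the rule.
"""

from __future__ import annotations

import numpy as np

from ._core import (
    DirectionWheel,
    TraceParams,
    as_field,
    batch_segment_ll,
    build_sequence,
    check_termination,
    sequence_raw_score,
    step_background_threshold,
    trim_tail,
)

__all__ = ["trace_hmm"]


def _argbest(scores: np.ndarray, ends: np.ndarray) -> int:
    """Index of the max score; exact ties go to the lexicographically
    smallest endpoint."""
    best = scores.max()
    tied = np.flatnonzero(scores == best)
    if len(tied) == 1:
        return int(tied[0])
    sub = ends[tied]
    return int(tied[np.lexsort((sub[:, 1], sub[:, 0]))[0]])


def trace_hmm(image, initial_point, params: TraceParams | None = None, soma_center=None):
    """Trace one neurite from ``initial_point`` by Viterbi dynamic programming.

    Parameters
    ----------
    image : ImageGrid
        Normalized 2-D image.
    initial_point : (row, col)
        Seed position, typically from :func:`find_initial_points`.
    soma_center : (row, col), optional
        When given, first-step headings are restricted to the half-plane
        pointing away from the soma.

    Returns
    -------
    TraceSequence
        ``terminated`` is True when the local-median rule fired;
        ``log_posterior`` is the recomputed Σ segment log-likelihoods of the
        returned points.  ``diagnostics['dp_score']`` holds the unrefined DP
        path score.
    """
    params = params or TraceParams()
    field = as_field(image)
    if field.ndim != 2:
        raise ValueError("trace_hmm operates on 2-D images; use trace_stack for stacks")
    x0 = np.asarray(initial_point, dtype=float)
    if not field.inside(x0):
        raise ValueError("initial point outside image")

    if check_termination(field, x0, params):
        return build_sequence(field, [x0], params, terminated=True, score=0.0)

    wheel = DirectionWheel(params)
    s1 = params.step_len_px
    nsamp = params.samples_per_step
    arc = params.arc_resolution_px
    n_dir = wheel.n
    width_q = int(field.shape[1] / arc) + 3

    # soma-circle exclusion: once tracing has left the initial circle it may
    # not step back inside it (the soma's brightness would otherwise offer a
    # free-loitering region for the optimizer)
    excl_center = excl_r = None
    if soma_center is not None:
        excl_center = np.asarray(soma_center, dtype=float)
        excl_r = 0.9 * params.circle_diameter_um / 2.0 / field.scale.microns_per_pixel

    def _admissible(ends):
        ok = field.inside(ends)
        if excl_center is not None:
            ok &= np.linalg.norm(ends - excl_center, axis=-1) >= excl_r
        return ok

    # --- first step: all headings (outward half-plane when soma is known)
    first = np.arange(n_dir)
    if soma_center is not None:
        outward = x0 - np.asarray(soma_center, dtype=float)
        if np.linalg.norm(outward) > 0:
            first = first[wheel.vectors @ outward >= 0]
    ends = x0 + s1 * wheel.vectors[first]
    ok = _admissible(ends)
    first, ends = first[ok], ends[ok]
    if len(first) == 0:
        return build_sequence(field, [x0], params, terminated=False, score=0.0)

    scores = batch_segment_ll(
        field, np.broadcast_to(x0, ends.shape), ends, nsamp, params.score_floor
    )
    positions, dirs, parents = ends, first, np.full(len(first), -1)
    prevs, last_ll = np.broadcast_to(x0, ends.shape), scores.copy()
    history = [(positions, dirs, parents)]

    result = _maybe_finish(
        field, params, history, scores, positions, prevs, last_ll, 1, x0
    )
    if result is not None:
        return result

    offsets = wheel.admissible_offsets()
    for step in range(2, params.max_nodes + 1):
        K = len(positions)
        new_dirs = (dirs[:, None] + offsets[None, :]) % n_dir
        new_ends = positions[:, None, :] + s1 * wheel.vectors[new_dirs]
        starts = np.broadcast_to(positions[:, None, :], new_ends.shape)
        parent_idx = np.broadcast_to(np.arange(K)[:, None], new_dirs.shape)

        new_dirs = new_dirs.reshape(-1)
        new_ends = new_ends.reshape(-1, 2)
        starts = starts.reshape(-1, 2)
        parent_idx = parent_idx.reshape(-1)

        ok = _admissible(new_ends)
        if not ok.any():
            break
        new_dirs, new_ends, starts, parent_idx = (
            new_dirs[ok],
            new_ends[ok],
            starts[ok],
            parent_idx[ok],
        )
        seg = batch_segment_ll(field, starts, new_ends, nsamp, params.score_floor)
        new_scores = scores[parent_idx] + seg

        # collapse states sharing a quantized (position, heading) key
        qr = np.round(new_ends[:, 0] / arc).astype(np.int64)
        qc = np.round(new_ends[:, 1] / arc).astype(np.int64)
        keys = (qr * width_q + qc) * n_dir + new_dirs
        order = np.lexsort((new_ends[:, 1], new_ends[:, 0], -new_scores, keys))
        _, take = np.unique(keys[order], return_index=True)
        sel = order[take]

        if params.beam_width is not None and len(sel) > params.beam_width:
            top = np.argsort(-new_scores[sel], kind="stable")[: params.beam_width]
            sel = sel[top]

        positions, dirs, parents, scores = (
            new_ends[sel],
            new_dirs[sel],
            parent_idx[sel],
            new_scores[sel],
        )
        prevs, last_ll = starts[sel], seg[sel]
        history.append((positions, dirs, parents))

        result = _maybe_finish(
            field, params, history, scores, positions, prevs, last_ll, step, x0
        )
        if result is not None:
            return result

    # no termination before max_nodes: return the best full-length path
    path = _backtrack(history, _argbest(scores, positions), x0)
    return build_sequence(
        field,
        path,
        params,
        terminated=False,
        score=sequence_raw_score(field, np.array(path), params),
        diagnostics={"dp_score": float(scores.max()), "n_steps": len(history)},
    )


def _maybe_finish(field, params, history, scores, positions, prevs, last_ll, step, x0):
    """Test the current best path: stop when its endpoint satisfies the
    local-median rule or its last step no longer beats local background;
    then backtrack, localize the tip, and build the result."""
    b = _argbest(scores, positions)
    fired = check_termination(field, positions[b], params) or float(
        last_ll[b]
    ) <= step_background_threshold(field, prevs[b], positions[b], params)
    if not fired:
        return None
    path = _backtrack(history, b, x0)
    path = trim_tail(field, path, params)
    return build_sequence(
        field,
        path,
        params,
        terminated=True,
        score=sequence_raw_score(field, np.array(path), params),
        diagnostics={"dp_score": float(scores[b]), "n_steps": step},
    )


def _backtrack(history, idx, x0):
    path = []
    for positions, _dirs, parents in reversed(history):
        path.append(positions[idx])
        idx = parents[idx]
    path.reverse()
    return [np.asarray(x0, dtype=float)] + path
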