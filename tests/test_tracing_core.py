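import numpy as np
import pytest

from neurotrace.image_io import EPS, ImageGrid, ScaleInfo
from neurotrace.neurite_tracing import (
    TraceParams,
    check_termination,
    find_initial_points,
    segment_log_likelihood,
    trace_fcm,
    trace_hmm,
    transition_prior,
)
from neurotrace import synthetic as syn

from conftest import ridge_image, uniform_image


class TestSegmentLogLikelihood:
    def test_uniform_unit_intensity_is_zero(self):
        img = uniform_image(1.0)
        assert segment_log_likelihood(img, (10.0, 10.0), (10.0, 25.0)) == 0.0

    @pytest.mark.parametrize("v,dist", [(0.5, 15.0), (0.25, 7.0), (0.9, 3.3)])
    def test_uniform_closed_form(self, v, dist):
        img = uniform_image(v, shape=(64, 64))
        n = int(np.ceil(dist / 0.5 - 1e-9))
        got = segment_log_likelihood(img, (30.0, 10.0), (30.0, 10.0 + dist))
        assert got == pytest.approx(n * np.log(v), rel=1e-12)

    def test_ridge_beats_parallel_background(self):
        img = ridge_image()
        on = segment_log_likelihood(img, (64.0, 50.0), (64.0, 65.0))
        off = segment_log_likelihood(img, (100.0, 50.0), (100.0, 65.0))
        assert on > off

    def test_outside_image_reads_floor(self):
        img = uniform_image(1.0, shape=(32, 32))
        # half the segment hangs outside: those samples contribute log(EPS)
        ll = segment_log_likelihood(img, (16.0, 28.0), (16.0, 43.0))
        assert ll < 10 * np.log(EPS) / 2


class TestTransitionPrior:
    def setup_method(self):
        self.params = TraceParams(max_turn_deg=60.0)

    def _u(self, deg):
        t = np.radians(deg)
        return np.array([-np.sin(t), np.cos(t)])

    def test_identical_directions_admissible(self):
        assert transition_prior(self._u(10), self._u(10), self.params) == 0.0

    def test_boundary_angle_admissible(self):
        assert transition_prior(self._u(0), self._u(60), self.params) == 0.0

    def test_one_degree_past_boundary_forbidden(self):
        assert transition_prior(self._u(0), self._u(61), self.params) == -np.inf


class TestTermination:
    def test_uniform_image_terminates_inclusively(self):
        img = uniform_image(0.7)
        assert check_termination(img, (32.0, 32.0), TraceParams())

    def test_bright_point_on_dark_background_continues(self):
        arr = np.full((64, 64), EPS)
        arr[30:34, 30:34] = 1.0
        img = ImageGrid(arr, ScaleInfo(0.625))
        assert not check_termination(img, (32.0, 32.0), TraceParams())

    def test_matches_bruteforce_median_oracle(self):
        rng = np.random.default_rng(11)
        arr = np.clip(rng.uniform(0, 1, (60, 60)), EPS, 1.0)
        img = ImageGrid(arr, ScaleInfo(0.625))
        params = TraceParams()
        half = int(round(params.termination_window_um / 2 / 0.625))
        from neurotrace.neurite_tracing._core import Field2D

        f = Field2D(img)
        for pos in [(30.2, 29.7), (5.1, 50.9), (58.0, 3.3), (14.6, 14.4)]:
            r, c = int(round(pos[0])), int(round(pos[1]))
            block = arr[max(0, r - half) : r + half + 1, max(0, c - half) : c + half + 1]
            val = f.sample(np.array([pos]))[0]
            expected = val <= np.median(block) + 1e-12
            assert check_termination(img, pos, params) == expected


class TestInitialPoints:
    def _phantom(self, angles, scale=ScaleInfo(0.625)):
        return syn.render(
            syn.PhantomSpec(
                image_size_px=(320, 320),
                scale=scale,
                somata=(syn.SomaSpec(center=(160, 160), diameter_um=20.0),),
                neurites=tuple(
                    syn.NeuriteSpec(soma=0, angle_deg=a, length_um=60.0) for a in angles
                ),
            )
        )

    def test_three_neurites_three_points(self):
        ph = self._phantom([0.0, 90.0, 200.0])
        pts = find_initial_points(ph.image, (160.0, 160.0), TraceParams())
        assert len(pts) == 3
        got = sorted(
            np.degrees(np.arctan2(-(p[0] - 160), p[1] - 160)) % 360 for p in pts
        )
        for angle, expected in zip(got, [0.0, 90.0, 200.0]):
            assert abs(angle - expected) < 3.0

    def test_uniform_background_gives_none(self):
        img = uniform_image(0.4, shape=(256, 256))
        assert find_initial_points(img, (128.0, 128.0), TraceParams()) == []

    def test_circle_radius_at_paper_scale(self):
        # 40 um circle at 0.3125 um/px puts initial points at radius 64 px
        ph = self._phantom([30.0], scale=ScaleInfo(0.3125))
        pts = find_initial_points(ph.image, (160.0, 160.0), TraceParams())
        assert len(pts) == 1
        assert np.hypot(pts[0][0] - 160, pts[0][1] - 160) == pytest.approx(64.0, abs=0.5)

    def test_circle_outside_image_empty(self):
        img = uniform_image(0.4, shape=(64, 64))
        assert find_initial_points(img, (-500.0, -500.0), TraceParams()) == []


@pytest.fixture(scope="module")
def curved_trace():
    spec = syn.PhantomSpec(
        image_size_px=(448, 448),
        scale=ScaleInfo(0.625),
        somata=(syn.SomaSpec(center=(224, 120), diameter_um=20.0),),
        neurites=(
            syn.NeuriteSpec(
                soma=0, angle_deg=20.0, length_um=110.0,
                curvature_deg_per_um=-0.5, fade_tail_um=5.0,
            ),
        ),
    )
    ph = syn.render(spec)
    params = TraceParams()
    ips = find_initial_points(ph.image, (224.0, 120.0), params)
    seqs = [
        tracer(ph.image, ips[0], params, soma_center=(224.0, 120.0))
        for tracer in (trace_hmm, trace_fcm)
    ]
    return seqs, params

class TestTraceInvariants:
    def test_step_length_conserved(self, curved_trace):
        seqs, params = curved_trace
        lo = params.step_len_px - params.arc_resolution_px
        hi = params.step_len_px + params.arc_resolution_px
        for seq in seqs:
            pos = seq.positions()
            steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
            # interior steps keep the nominal arc; only the trimmed tail
            # may be shorter
            assert np.all(steps[:-1] >= lo - 1e-9)
            assert np.all(steps <= hi + 1e-9)

    def test_turn_bound_respected(self, curved_trace):
        seqs, params = curved_trace
        for seq in seqs:
            pos = seq.positions()
            d = np.diff(pos, axis=0)
            d = d / np.linalg.norm(d, axis=1, keepdims=True)
            cos = np.clip((d[:-1] * d[1:]).sum(axis=1), -1, 1)
            assert np.all(np.degrees(np.arccos(cos)) <= params.max_turn_deg + 1.0)

    def test_log_posterior_recomputable(self, curved_trace):
        seqs, params = curved_trace
        from neurotrace.neurite_tracing import sequence_fcm_score, sequence_raw_score
        from neurotrace.neurite_tracing._core import Field2D

        seq_hmm, seq_fcm = seqs
        # scores were computed against the image each trace ran on
        # (recomputation must agree with the stored value)
        # field reconstruction via stored scale is not possible here, so the
        # fixture keeps the phantom alive through the sequences' field refs
        # -- recompute directly:
        # (recomputing needs the image; regenerate the identical phantom)
        spec = syn.PhantomSpec(
            image_size_px=(448, 448),
            scale=ScaleInfo(0.625),
            somata=(syn.SomaSpec(center=(224, 120), diameter_um=20.0),),
            neurites=(
                syn.NeuriteSpec(
                    soma=0, angle_deg=20.0, length_um=110.0,
                    curvature_deg_per_um=-0.5, fade_tail_um=5.0,
                ),
            ),
        )
        field = Field2D(syn.render(spec).image)
        assert sequence_raw_score(field, seq_hmm.positions(), params) == pytest.approx(
            seq_hmm.log_posterior, abs=1e-9
        )
        assert sequence_fcm_score(field, seq_fcm.positions(), params) == pytest.approx(
            seq_fcm.log_posterior, abs=1e-9
        )


class TestAffineInvariance:
    def test_traced_geometry_identical_across_intensity_series(self):
        spec = syn.PhantomSpec(
            image_size_px=(384, 384),
            scale=ScaleInfo(0.625),
            somata=(syn.SomaSpec(center=(192, 140), diameter_um=20.0),),
            neurites=(syn.NeuriteSpec(soma=0, angle_deg=-10.0, length_um=80.0),),
        )
        ph = syn.render(spec)
        base = ph.image
        params = TraceParams()
        ips = find_initial_points(base, (192.0, 140.0), params)
        ref_positions = None
        for a, b in ((1.0, 0.0), (2.0, 0.25), (0.5, 0.125)):
            grid = ImageGrid.from_raw(a * base.intensities + b, base.scale)
            assert np.allclose(grid.intensities, base.intensities, atol=1e-12)
            seq = trace_fcm(grid, ips[0], params, soma_center=(192.0, 140.0))
            if ref_positions is None:
                ref_positions = seq.positions()
            else:
                assert np.allclose(seq.positions(), ref_positions, atol=1e-9)
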