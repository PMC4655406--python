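import numpy as np
import pytest
from scipy import ndimage

from neurotrace.image_io import EPS, ImageGrid, ScaleInfo
from neurotrace.soma_detection import (
    SomaCandidate,
    SomaParams,
    detect_somata,
    log_response,
    nms_centers,
    refine_boundary,
    soma_regions,
)
from neurotrace import synthetic as syn

from conftest import uniform_image


class TestLogResponse:
    def test_constant_image_zero_response(self):
        img = uniform_image(0.5)
        resp = log_response(img, SomaParams())
        assert np.allclose(resp, 0.0, atol=1e-10)

    def test_sigma_below_one_pixel_rejected(self):
        img = uniform_image(0.5, scale=ScaleInfo(10.0))
        with pytest.raises(ValueError):
            log_response(img, SomaParams(log_sigma_um=5.0))

    def test_matched_gaussian_blob_peaks_at_center(self):
        # blob sigma equals filter sigma: the response maximum must sit on
        # the blob center (checked against a brute-force convolution oracle)
        scale = ScaleInfo(1.0)
        sigma = 6.0
        rr, cc = np.mgrid[0:64, 0:64]
        blob = np.exp(-((rr - 30) ** 2 + (cc - 34) ** 2) / (2 * sigma**2))
        img = ImageGrid(np.clip(blob, EPS, 1.0), scale)
        resp = log_response(img, SomaParams(log_sigma_um=sigma))
        assert np.unravel_index(np.argmax(resp), resp.shape) == (30, 34)

        # oracle: direct convolution with an explicitly constructed
        # scale-normalized LoG kernel
        half = int(4 * sigma)
        kr, kc = np.mgrid[-half : half + 1, -half : half + 1]
        r2 = kr**2 + kc**2
        g = np.exp(-r2 / (2 * sigma**2)) / (2 * np.pi * sigma**2)
        log_kernel = -(sigma**2) * (r2 - 2 * sigma**2) / sigma**4 * g
        oracle = ndimage.convolve(img.intensities, log_kernel, mode="nearest")
        assert np.unravel_index(np.argmax(oracle), oracle.shape) == (30, 34)
        interior = (slice(10, 54), slice(10, 54))
        corr = np.corrcoef(resp[interior].ravel(), oracle[interior].ravel())[0, 1]
        assert corr > 0.999

    def test_default_sigma_detects_paper_sized_somata(self):
        # somata spanning the 15-30 um range are all found with defaults
        for d in (15.0, 22.0, 30.0):
            spec = syn.PhantomSpec(
                image_size_px=(256, 256),
                scale=ScaleInfo(0.625),
                somata=(syn.SomaSpec(center=(128, 128), diameter_um=d),),
            )
            ph = syn.render(spec)
            somata = detect_somata(ph.image)
            assert len(somata) == 1
            assert np.hypot(*(np.array(somata[0].center) - 128)) < 10.0 / 0.625


class TestSomaRegions:
    def _two_blob_response(self):
        rr, cc = np.mgrid[0:80, 0:80]
        a = np.exp(-((rr - 20) ** 2 + (cc - 20) ** 2) / 30)
        b = 0.5 * np.exp(-((rr - 60) ** 2 + (cc - 60) ** 2) / 30)
        return a + b

    def test_threshold_one_keeps_only_argmax(self):
        resp = self._two_blob_response()
        mask = soma_regions(resp, SomaParams(response_ratio_threshold=1.0))
        assert mask.sum() == 1
        assert mask[20, 20]

    def test_vanishing_threshold_keeps_positive_pixels(self):
        resp = self._two_blob_response()
        mask = soma_regions(resp, SomaParams(response_ratio_threshold=1e-12))
        assert np.array_equal(mask, resp / resp.max() >= 1e-12)

    def test_ratio_threshold_selects_regions(self):
        # peaks at ratio 1.0 and 0.5; threshold 0.6 leaves one region
        resp = self._two_blob_response()
        mask = soma_regions(resp, SomaParams(response_ratio_threshold=0.6))
        _, n = ndimage.label(mask)
        assert n == 1
        mask_lo = soma_regions(resp, SomaParams(response_ratio_threshold=0.3))
        _, n_lo = ndimage.label(mask_lo)
        assert n_lo == 2

    def test_nonpositive_response_warns_empty(self):
        with pytest.warns(UserWarning):
            mask = soma_regions(np.zeros((10, 10)), SomaParams())
        assert not mask.any()


def _nms_oracle(resp, mask, window):
    """Exhaustive scan: strict window maxima with lexicographic tie-break."""
    half = window // 2
    h, w = resp.shape
    out = []
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            block = resp[max(0, r - half) : r + half + 1, max(0, c - half) : c + half + 1]
            if resp[r, c] < block.max():
                continue
            ties = np.argwhere(block == resp[r, c])
            first = ties[np.lexsort((ties[:, 1], ties[:, 0]))[0]]
            if (max(0, r - half) + first[0], max(0, c - half) + first[1]) == (r, c):
                out.append((r, c))
    return out


class TestNms:
    def test_single_peak(self):
        resp = np.zeros((21, 21))
        resp[10, 12] = 1.0
        mask = resp > 0
        cands = nms_centers(resp, mask, 5)
        assert [c.center for c in cands] == [(10, 12)]

    def test_plateau_keeps_lexicographic_first(self):
        resp = np.zeros((21, 21))
        resp[9:12, 9:12] = 1.0
        cands = nms_centers(resp, resp > 0, 7)
        assert [c.center for c in cands] == [(9, 9)]

    def test_two_separated_peaks(self):
        resp = np.zeros((40, 40))
        resp[10, 10] = 1.0
        resp[30, 30] = 0.8
        cands = nms_centers(resp, resp > 0, 5)
        assert [c.center for c in cands] == [(10, 10), (30, 30)]

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(3)
        resp = rng.uniform(0, 1, (30, 30))
        resp[rng.uniform(size=(30, 30)) < 0.2] = 0.75  # inject ties
        mask = rng.uniform(size=(30, 30)) < 0.5
        cands = nms_centers(resp, mask, 5)
        assert [c.center for c in cands] == _nms_oracle(resp, mask, 5)

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        resp = rng.uniform(0, 1, (40, 40))
        mask = np.ones_like(resp, dtype=bool)
        cands = nms_centers(resp, mask, 7)
        again_mask = np.zeros_like(mask)
        for c in cands:
            again_mask[c.center] = True
        again = nms_centers(resp, again_mask, 7)
        assert [c.center for c in again] == [c.center for c in cands]

    def test_window_validation(self):
        with pytest.raises(ValueError):
            nms_centers(np.zeros((5, 5)), np.ones((5, 5), bool), 4)


class TestMonotoneThreshold:
    def test_candidates_nested_under_rising_threshold(self):
        ph = syn.render(syn.random_neuron_spec(7))
        resp = log_response(ph.image, SomaParams())
        prev = None
        for thr in (0.05, 0.2, 0.4, 0.6, 0.8):
            mask = soma_regions(resp, SomaParams(response_ratio_threshold=thr))
            centers = {c.center for c in nms_centers(resp, mask, 33)}
            if prev is not None:
                assert centers <= prev
            prev = centers


class TestRefineBoundary:
    def test_binary_disk_recovered_within_one_pixel(self):
        scale = ScaleInfo(0.5)  # init circle radius = 40 px
        rr, cc = np.mgrid[0:120, 0:120]
        d = np.hypot(rr - 60, cc - 60)
        img = ImageGrid(np.where(d <= 10, 0.9, EPS), scale)
        soma = refine_boundary(img, SomaCandidate(center=(60, 60), response_ratio=1.0),
                               SomaParams())
        assert not soma.fallback
        radii = np.hypot(soma.boundary[:, 0] - 60, soma.boundary[:, 1] - 60)
        assert abs(radii.mean() - 10) < 1.0

    def test_constant_image_falls_back_flagged(self):
        img = uniform_image(0.5, shape=(120, 120), scale=ScaleInfo(0.5))
        soma = refine_boundary(img, SomaCandidate(center=(60, 60), response_ratio=1.0),
                               SomaParams())
        assert soma.fallback
        assert soma.area_um2 == pytest.approx(np.pi * 7.5**2)

    def test_noisy_ellipse_area_within_ten_percent(self):
        spec = syn.PhantomSpec(
            image_size_px=(256, 256),
            scale=ScaleInfo(0.625),
            somata=(syn.SomaSpec(center=(128, 128), diameter_um=28.0,
                                 axes_um=(28.0, 20.0), angle_deg=30.0),),
            noise_sigma=0.05,
            seed=2,
        )
        ph = syn.render(spec)
        soma = refine_boundary(
            ph.image, SomaCandidate(center=(128, 128), response_ratio=1.0), SomaParams()
        )
        true_area = np.pi * 14.0 * 10.0
        assert abs(soma.area_um2 - true_area) / true_area < 0.10


class TestTranslationEquivariance:
    def test_detected_center_shifts_with_phantom(self):
        base = (120.0, 120.0)
        delta = (17.0, -9.0)
        centers = []
        for offset in ((0.0, 0.0), delta):
            spec = syn.PhantomSpec(
                image_size_px=(288, 288),
                scale=ScaleInfo(0.625),
                somata=(syn.SomaSpec(center=(base[0] + offset[0], base[1] + offset[1]),
                                     diameter_um=20.0),),
            )
            somata = detect_somata(syn.render(spec).image)
            assert len(somata) == 1
            centers.append(np.array(somata[0].center, dtype=float))
        shift = centers[1] - centers[0]
        assert np.allclose(shift, delta, atol=1.0)
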