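import numpy as np
import pytest
from scipy import ndimage as ndi

from veinwidth import ValidationError, degrade, make_vessel
from veinwidth.edges import (EdgeMap, GradientField, canny, gaussian_kernel,
                             gaussian_smooth, hysteresis_threshold,
                             mask_boundary_edges, non_maximum_suppress,
                             sobel_gradients)


class TestGaussianSmooth:
    def test_constant_invariant(self):
        img = np.full((20, 20), 77, np.uint8)
        assert np.allclose(gaussian_smooth(img, 1.0), 77.0)

    def test_kernel_center_closed_form(self):
        # unnormalized center value is 1/(2 pi eta^2) ~ 0.1592 for eta = 1
        eta = 1.0
        radius = int(np.ceil(3 * eta))
        ax = np.arange(-radius, radius + 1, dtype=float)
        xx, yy = np.meshgrid(ax, ax)
        unnorm = np.exp(-(xx ** 2 + yy ** 2) / (2 * eta ** 2)) / (2 * np.pi * eta ** 2)
        assert unnorm[radius, radius] == pytest.approx(0.1592, abs=1e-4)
        k = gaussian_kernel(eta)
        assert k.sum() == pytest.approx(1.0)
        assert np.allclose(k, unnorm / unnorm.sum())

    def test_impulse_reproduces_kernel(self):
        img = np.zeros((15, 15), np.uint8)
        img[7, 7] = 255
        out = gaussian_smooth(img, 1.0)
        k = gaussian_kernel(1.0) * 255
        assert np.allclose(out[4:11, 4:11], k)

    def test_nonpositive_eta_raises(self):
        with pytest.raises(ValidationError):
            gaussian_smooth(np.zeros((5, 5), np.uint8), 0.0)


class TestSobel:
    def test_constant_zero_magnitude(self):
        g = sobel_gradients(np.full((10, 10), 42.0))
        assert np.allclose(g.magnitude, 0.0)

    def test_vertical_step_direction_and_peak(self):
        img = np.zeros((10, 20))
        img[:, 10:] = 255.0
        g = sobel_gradients(img)
        row = 5
        peak = np.argmax(g.magnitude[row])
        # hand-convolution: gx = 4 * 255 on the two columns flanking the step
        assert peak in (9, 10)
        assert g.magnitude[row, peak] == pytest.approx(4 * 255)
        assert g.direction[row, peak] == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_ramp_direction(self):
        rr, cc = np.mgrid[0:20, 0:20]
        ramp = (rr + cc).astype(float)  # gradient along +row +col
        g = sobel_gradients(ramp)
        assert g.direction[10, 10] == pytest.approx(np.pi / 4)

    def test_magnitude_direction_consistency(self, rng):
        g = sobel_gradients(rng.random((16, 16)) * 255)
        assert np.allclose(g.magnitude, np.hypot(g.gx, g.gy))
        nz = np.abs(g.gx) > 1e-12
        assert np.allclose(np.tan(g.direction[nz]), g.gy[nz] / g.gx[nz], atol=1e-9)
        assert (g.magnitude >= 0).all()


class TestNonMaximumSuppression:
    def test_step_ridge_thin_and_matches_neighbor_oracle(self):
        img = np.zeros((12, 24))
        img[:, 12:] = 255.0
        g = sobel_gradients(gaussian_smooth(img.astype(np.uint8), 1.0))
        nms = non_maximum_suppress(g)
        # the significant ridge (tiny tie plateaus fall to the thresholds
        # later) is at most the exact-tie pair flanking the step
        for row in nms[2:-2]:
            assert (row > 0.01 * nms.max()).sum() <= 2
        # brute-force oracle: per-pixel comparison along the quantized
        # gradient direction, zero-padded borders
        mag, ang = g.magnitude, np.mod(np.degrees(g.direction), 180.0)
        pad = np.pad(mag, 1)
        for r in range(12):
            for c in range(24):
                a = ang[r, c]
                if a < 22.5 or a >= 157.5:
                    n1, n2 = pad[r + 1, c + 2], pad[r + 1, c]
                elif a < 67.5:
                    n1, n2 = pad[r + 2, c + 2], pad[r, c]
                elif a < 112.5:
                    n1, n2 = pad[r + 2, c + 1], pad[r, c + 1]
                else:
                    n1, n2 = pad[r + 2, c], pad[r, c + 2]
                expect = mag[r, c] if (mag[r, c] >= n1 and mag[r, c] >= n2
                                       and mag[r, c] > 0) else 0.0
                assert nms[r, c] == expect

    def test_zero_field_unchanged(self):
        g = sobel_gradients(np.zeros((8, 8)))
        assert not non_maximum_suppress(g).any()

    def test_output_subset_of_positive_magnitude(self, rng):
        g = sobel_gradients(rng.random((20, 20)) * 255)
        nms = non_maximum_suppress(g)
        assert ((nms > 0) <= (g.magnitude > 0)).all()


class TestHysteresis:
    def test_all_below_low_empty(self):
        nms = np.full((10, 10), 0.5)
        assert not hysteresis_threshold(nms, low=1.0, high=2.0).pixels.any()

    def test_weak_chain_anchored_by_strong(self):
        nms = np.zeros((8, 8))
        chain = [(4, 2), (4, 3), (3, 4), (4, 5)]
        for r, c in chain[:-1]:
            nms[r, c] = 1.5  # weak
        nms[4, 5] = 5.0      # strong anchor
        nms[0, 0] = 1.5      # isolated weak
        em = hysteresis_threshold(nms, low=1.0, high=2.0)
        assert all(em.pixels[r, c] for r, c in chain)
        assert not em.pixels[0, 0]

    def test_bad_thresholds_raise(self):
        with pytest.raises(ValidationError):
            hysteresis_threshold(np.zeros((4, 4)), low=2.0, high=1.0)


class TestCanny:
    def test_constant_image_no_edges(self):
        em = canny(np.full((30, 30), 128, np.uint8))
        assert not em.pixels.any() and em.edge_points == []

    def test_band_gives_two_one_pixel_chains_at_true_width(self):
        width = 7
        truth = degrade(make_vessel("straight", width=width), blur_sigma=1.0)
        em = canny(truth.image)
        labels, n = ndi.label(em.pixels, structure=np.ones((3, 3), bool))
        assert n == 2
        good = 0
        cols = range(3, 97)
        for c in cols:
            rows = np.flatnonzero(em.pixels[:, c])
            if len(rows) == 2 and abs((rows[1] - rows[0] - 1) - width) <= 1:
                good += 1
        assert good / len(cols) >= 0.9
        # chains are single-pixel wide: each column crossed at most once per chain
        for c in cols:
            for lab in (1, 2):
                assert (labels[:, c] == lab).sum() <= 1

    def test_every_edge_pixel_traceable_to_strong_seed(self, rng):
        img = (rng.random((40, 40)) * 255).astype(np.uint8)
        nms = non_maximum_suppress(sobel_gradients(gaussian_smooth(img, 1.0)))
        high = 0.4 * nms.max()
        em = hysteresis_threshold(nms, low=0.2 * nms.max(), high=high)
        labels, _ = ndi.label(em.pixels, structure=np.ones((3, 3), bool))
        for lab in np.unique(labels[labels > 0]):
            assert (nms[labels == lab] > high).any()


class TestMaskBoundary:
    def test_band_outside_and_inside_rows(self):
        mask = np.zeros((25, 30), bool)
        mask[10:15] = True  # band rows 10-14
        outside = mask_boundary_edges(mask, "outside").pixels
        inside = mask_boundary_edges(mask, "inside").pixels
        assert set(np.unique(np.nonzero(outside)[0])) == {9, 15}
        assert set(np.unique(np.nonzero(inside)[0])) == {10, 14}

    def test_disc_ring_contains_mask_within_radius(self):
        rr, cc = np.mgrid[0:40, 0:40]
        mask = (rr - 20) ** 2 + (cc - 20) ** 2 <= 8 ** 2
        ring = mask_boundary_edges(mask, "outside").pixels
        d = ndi.distance_transform_edt(~ring)
        assert d[mask].max() <= 8 + 1
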