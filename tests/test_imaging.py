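"""Fluorescence quantification tests against planted ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from spinalgaba import imaging as img
from spinalgaba import synthetic as syn

PIXEL = 0.1  # um
BG = 50.0


def _match(objects, positions, radius=5.0):
    tree = cKDTree(positions)
    d, idx = tree.query(objects[["centroid_y", "centroid_x"]].to_numpy())
    return d, idx


class TestDetectClusters:
    def test_constant_image_has_no_clusters(self):
        plane = img.ImagePlane(np.full((128, 128), 100.0), PIXEL)
        assert img.detect_clusters(plane, psf_fwhm=0.25).count == 0

    def test_all_planted_puncta_detected(self, puncta_field):
        image, truth = puncta_field
        mask = img.detect_clusters(image, psf_fwhm=0.25)
        assert mask.count == len(truth.positions)
        d, _ = _match(mask.objects, truth.positions)
        assert d.max() < 3.0  # centroids on the planted objects

    def test_cluster_density_definition(self, puncta_field):
        image, _ = puncta_field
        mask = img.detect_clusters(image, psf_fwhm=0.25)
        # 21 objects in 200 um^2 would be 10.5 per 100 um^2
        assert img.cluster_density(mask, 200.0) == pytest.approx(mask.count / 2.0)

    def test_translation_invariance(self, puncta_field):
        image, _ = puncta_field
        shifted = img.ImagePlane(np.roll(image.data, (7, -4), axis=(0, 1)), PIXEL)
        m0 = img.detect_clusters(image, psf_fwhm=0.25)
        m1 = img.detect_clusters(shifted, psf_fwhm=0.25)
        keep = ~m0.objects["touches_border"].to_numpy()
        c0 = m0.objects.loc[keep, ["centroid_y", "centroid_x"]].to_numpy()
        c0 = (c0 + [7, -4]) % image.data.shape
        d, _ = cKDTree(m1.objects[["centroid_y", "centroid_x"]].to_numpy()).query(c0)
        assert d.max() < 0.5

    def test_background_gradient_changes_count_by_under_two_percent(
        self, puncta_field
    ):
        image, truth = puncta_field
        peak = max(truth.amplitudes)
        yy, xx = np.mgrid[: image.data.shape[0], : image.data.shape[1]]
        gradient = 0.2 * peak * (xx / xx.max())
        tilted = img.ImagePlane(
            np.clip(image.data + gradient, 0, 4095), PIXEL
        )
        n0 = img.detect_clusters(image, psf_fwhm=0.25).count
        n1 = img.detect_clusters(tilted, psf_fwhm=0.25).count
        assert abs(n1 - n0) / n0 < 0.02

    def test_count_linearity_with_density(self):
        rng = np.random.default_rng(11)

        def field(n, seed):
            pos = []
            while len(pos) < n:
                y, x = rng.uniform(25, 999, 2)
                if all((y - p[0]) ** 2 + (x - p[1]) ** 2 > 25**2 for p in pos):
                    pos.append((y, x))
            truth = syn.ImageTruth(
                shape=(1024, 1024),
                positions=tuple(pos),
                amplitudes=(700.0,) * n,
                sizes=(3.5,) * n,
                seed=seed,
            )
            image, _ = syn.gen_puncta_image(truth)
            return img.detect_clusters(image, psf_fwhm=0.25).count

        n1 = field(60, 1)
        n2 = field(120, 2)
        assert abs(n2 - 2 * n1) / (2 * n1) < 0.05

    def test_sub_pixel_psf_rejected(self):
        plane = img.ImagePlane(np.zeros((64, 64)), pixel_size=0.5)
        with pytest.raises(ValueError):
            img.detect_clusters(plane, psf_fwhm=0.25)


class TestIntensityInMask:
    def test_full_frame_mask_gives_image_mean(self, puncta_field):
        image, _ = puncta_field
        full = np.ones_like(image.data, dtype=bool)
        mask = img.ClusterMask(
            mask=full,
            labels=full.astype(int),
            core_labels=full.astype(int),
            objects=pd.DataFrame({"label": [1]}),
            pixel_size=PIXEL,
        )
        overall, _, _ = img.intensity_in_mask(image, mask)
        assert overall == pytest.approx(image.data.mean())

    def test_disjoint_masks_have_zero_overlap(self, puncta_field):
        image, _ = puncta_field
        m = img.detect_clusters(image, psf_fwhm=0.25)
        other = img.ClusterMask(
            mask=~m.mask,
            labels=(~m.mask).astype(int),
            core_labels=(~m.mask).astype(int),
            objects=pd.DataFrame({"label": [1]}),
            pixel_size=PIXEL,
        )
        _, _, overlap = img.intensity_in_mask(image, m, other)
        assert overlap == 0.0

    def test_planted_amplitude_recovery_within_ten_percent(self, puncta_field):
        image, truth = puncta_field
        mask = img.detect_clusters(image, psf_fwhm=0.25)
        _, per_object, _ = img.intensity_in_mask(image, mask)
        d, idx = _match(mask.objects, truth.positions)
        planted = np.asarray(truth.amplitudes)[idx]
        rel = np.abs(per_object.to_numpy() - truth.background - planted) / planted
        assert rel.max() < 0.10

    def test_shape_mismatch_rejected(self, puncta_field):
        image, _ = puncta_field
        m = img.detect_clusters(image, psf_fwhm=0.25)
        small = img.ImagePlane(np.zeros((64, 64)), PIXEL)
        with pytest.raises(ValueError):
            img.intensity_in_mask(small, m)


@pytest.fixture(scope="module")
def ring_image():
    cells = [syn.CellGeometry((100, 100), 30), syn.CellGeometry((300, 300), 40)]
    image, truth = syn.gen_membrane_image(cells, seed=2)
    return image, cells


class TestMembraneProfile:
    def test_peak_separation_equals_planted_diameter(self, ring_image):
        image, cells = ring_image
        prof = img.membrane_profile(
            image,
            [((100, 60), (100, 140)), ((300, 250), (300, 350))],
            background=100.0,
        )
        for sep, cell in zip(prof.peak_separations_um, cells):
            assert sep == pytest.approx(2 * cell.radius * PIXEL, abs=PIXEL)

    def test_flat_image_rejected(self):
        flat = img.ImagePlane(np.full((128, 128), 200.0), PIXEL)
        with pytest.raises(ValueError):
            img.membrane_profile(flat, [((64, 10), (64, 120))])

    def test_averaging_identical_cells_is_idempotent(self, ring_image):
        image, _ = ring_image
        seg = ((100, 60), (100, 140))
        single = img.membrane_profile(image, [seg], background=100.0)
        double = img.membrane_profile(image, [seg, seg], background=100.0)
        assert np.allclose(single.intensity, double.intensity)


class TestMembraneIndex:
    def test_zero_contrast_gives_zero_index(self):
        cells = [syn.CellGeometry((100, 100), 35)]
        image, _ = syn.gen_membrane_image(
            cells, membrane_level=400.0, intracellular_level=400.0, seed=5
        )
        yy, xx = np.mgrid[:512, :512]
        r2 = (yy - 100) ** 2 + (xx - 100) ** 2
        roi = r2 <= 30**2
        intra = r2 <= 15**2
        bgreg = np.zeros((512, 512), bool)
        bgreg[400:, 400:] = True
        assert img.membrane_index(image, roi, intra, bgreg) == pytest.approx(0.0, abs=2.0)

    def test_recovers_planted_contrast(self):
        # membrane thick relative to the PSF so its plateau survives blurring
        cells = [syn.CellGeometry((100, 100), 35, membrane_thickness=6.0)]
        image, _ = syn.gen_membrane_image(cells, seed=6)
        yy, xx = np.mgrid[:512, :512]
        r2 = (yy - 100) ** 2 + (xx - 100) ** 2
        roi = (r2 <= 36**2) & (r2 >= 34**2)  # center of the membrane annulus
        intra = r2 <= 20**2
        bgreg = np.zeros((512, 512), bool)
        bgreg[400:, 400:] = True
        index = img.membrane_index(image, roi, intra, bgreg)
        assert index == pytest.approx(900.0 - 400.0, rel=0.15)

    def test_constant_shift_invariance(self):
        cells = [syn.CellGeometry((100, 100), 35)]
        image, _ = syn.gen_membrane_image(cells, seed=7)
        yy, xx = np.mgrid[:512, :512]
        r2 = (yy - 100) ** 2 + (xx - 100) ** 2
        roi, intra = r2 <= 30**2, r2 <= 15**2
        bgreg = np.zeros((512, 512), bool)
        bgreg[400:, 400:] = True
        i0 = img.membrane_index(image, roi, intra, bgreg)
        shifted = img.ImagePlane(image.data + 100.0, PIXEL)
        assert img.membrane_index(shifted, roi, intra, bgreg) == pytest.approx(i0)

    def test_empty_region_rejected(self):
        image = img.ImagePlane(np.zeros((64, 64)), PIXEL)
        full = np.ones((64, 64), bool)
        with pytest.raises(ValueError):
            img.membrane_index(image, full, full, np.zeros((64, 64), bool))


class TestRelativeDifferenceMap:
    def test_equal_images_give_zero(self):
        a = img.ImagePlane(np.random.default_rng(0).uniform(100, 200, (64, 64)), 1.0)
        delta, _, _ = img.relative_difference_map(a, a, gaussian_sigma_um=5.0)
        assert np.nanmax(np.abs(delta)) < 1e-12

    def test_half_intensity_gives_minus_fifty_percent(self):
        data = np.random.default_rng(1).uniform(100, 200, (64, 64))
        a = img.ImagePlane(data, 1.0)
        b = img.ImagePlane(data / 2.0, 1.0)
        delta, _, _ = img.relative_difference_map(a, b, gaussian_sigma_um=5.0)
        assert np.allclose(delta[~np.isnan(delta)], -0.5, atol=1e-9)

    def test_zero_sigma_is_identity_filter(self):
        data = np.random.default_rng(2).uniform(100, 200, (32, 32))
        a = img.ImagePlane(data, 1.0)
        b = img.ImagePlane(data * 1.3, 1.0)
        delta, _, _ = img.relative_difference_map(a, b, gaussian_sigma_um=0.0)
        assert np.allclose(delta, 0.3, atol=1e-9)


def _ellipse_image(area_px, eccentricity, shape=(256, 256), level=800.0):
    """Noiseless image with one bright ellipse of given area and eccentricity."""
    b = np.sqrt(area_px / np.pi * np.sqrt(1 - eccentricity**2))
    a = b / np.sqrt(1 - eccentricity**2)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    mask = ((xx - 128) / a) ** 2 + ((yy - 128) / b) ** 2 <= 1.0
    return img.ImagePlane(np.where(mask, level, 10.0), 0.094)


class TestDetectSomata:
    def test_round_large_soma_detected(self):
        labels, table = img.detect_somata(_ellipse_image(600, 0.5))
        assert len(table) == 1
        assert table["area_px"].iloc[0] > 500

    def test_small_soma_rejected(self):
        _, table = img.detect_somata(_ellipse_image(400, 0.5))
        assert len(table) == 0

    def test_elongated_soma_rejected(self):
        _, table = img.detect_somata(_ellipse_image(2000, 0.995))
        assert len(table) == 0

    def test_filter_rules_exact_on_noiseless_fixtures(self):
        """The area/eccentricity decision matches direct rule evaluation."""
        params = img.SomaDetectionParams()
        for area in (300, 450, 600, 1200):
            for ecc in (0.3, 0.9, 0.985):
                plane = _ellipse_image(area, ecc)
                _, table = img.detect_somata(plane, params)
                from skimage import measure

                rp = measure.regionprops(measure.label(plane.data > 400))[0]
                expected = (
                    rp.area > params.min_area
                    and rp.eccentricity <= params.max_eccentricity
                )
                assert (len(table) == 1) == expected, (area, ecc)

    def test_oversized_kernel_rejected(self):
        with pytest.raises(ValueError):
            img.detect_somata(img.ImagePlane(np.zeros((32, 32)), 0.094))


@pytest.fixture(scope="module")
def rnascope():
    somata = [
        syn.SomaGeometry((120, 120), 30, 25),
        syn.SomaGeometry((350, 350), 35, 28),
        syn.SomaGeometry((120, 380), 28, 24),
    ]
    dots = {"gabra2": [5, 0, 2], "slc32a1": [1, 0, 0], "slc17a6": [0, 2, 1]}
    planes, truth, table = syn.gen_rnascope_image(somata, dots, seed=4)
    labels, _ = img.detect_somata(planes["nissl"])
    return planes, labels, dots


class TestTranscriptCounting:
    def test_planted_counts_recovered(self, rnascope):
        planes, labels, dots = rnascope
        detections = {
            ch: img.detect_clusters(planes[ch], psf_fwhm=0.3)
            .objects[["centroid_y", "centroid_x"]]
            .to_numpy()
            for ch in dots
        }
        counts, _ = img.count_transcripts_per_cell(detections, labels)
        counts = counts.sort_values("centroid_y" if "centroid_y" in counts else "label")
        assert sorted(counts["n_gabra2"]) == sorted(dots["gabra2"])

    def test_type_labels_follow_marker_rule(self, rnascope):
        planes, labels, dots = rnascope
        detections = {
            ch: img.detect_clusters(planes[ch], psf_fwhm=0.3)
            .objects[["centroid_y", "centroid_x"]]
            .to_numpy()
            for ch in dots
        }
        counts, _ = img.count_transcripts_per_cell(detections, labels)
        for _, row in counts.iterrows():
            if row["n_slc32a1"] >= 1:
                assert row["cell_type"] == "inhibitory"
            elif row["n_slc17a6"] >= 1:
                assert row["cell_type"] == "excitatory"
            else:
                assert row["cell_type"] == "unclassified"

    def test_no_dots_all_counts_zero(self):
        somata = [syn.SomaGeometry((120, 120), 30, 25)]
        planes, _, _ = syn.gen_rnascope_image(somata, {"gabra2": [0]}, seed=8)
        labels, _ = img.detect_somata(planes["nissl"])
        counts, extra = img.count_transcripts_per_cell(
            {"gabra2": np.empty((0, 2))}, labels
        )
        assert counts["n_gabra2"].sum() == 0
        assert extra["gabra2"] == 0

    def test_extracellular_dots_reported_separately(self):
        labels = np.zeros((64, 64), dtype=int)
        labels[10:20, 10:20] = 1
        counts, extra = img.count_transcripts_per_cell(
            {"gabra2": np.array([[15.0, 15.0], [50.0, 50.0]])},
            labels,
        )
        assert counts["n_gabra2"].iloc[0] == 1
        assert extra["gabra2"] == 1


def test_subunit_total_count():
    assert img.subunit_total_count(10, 4) == 18
    assert img.subunit_total_count(0, 0) == 0
    assert img.subunit_total_count(6, 8) == 2 * img.subunit_total_count(3, 4)
    with pytest.raises(ValueError):
        img.subunit_total_count(-1, 0)


def test_deconvolve_bead_fwhm():
    assert img.deconvolve_bead_fwhm(420.0, 0.0) == 420.0
    assert img.deconvolve_bead_fwhm(100.0, 100.0) == 0.0
    assert img.deconvolve_bead_fwhm(500.0, 300.0) == pytest.approx(400.0)
    with pytest.raises(ValueError):
        img.deconvolve_bead_fwhm(80.0, 100.0)
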