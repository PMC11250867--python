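"""Nuclei segmentation, classification, per-cell and per-vessel signal."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from scipy import stats
from scipy.spatial import cKDTree

from ihcquant.regions import (
    NucleusRecord,
    classify_nuclei,
    cytosolic_signal,
    percent_area,
    segment_nuclei,
    vessel_endothelium,
)
from ihcquant.stains import to_inverted_gray, unmix
from ihcquant.synthetic import (
    NucleusSpec,
    PerCellField,
    SceneSpec,
    make_area_fraction_scene,
    make_nuclei_population_scene,
    make_vessel_scene,
    render_scene,
)


@pytest.fixture(scope="module")
def population():
    spec = make_nuclei_population_scene(seed=7)
    img, gt = render_scene(spec)
    hema, dab, _ = unmix(img)
    recs, labels = segment_nuclei(to_inverted_gray(hema), spec.pixel_size_um)
    return spec, gt, recs, labels, to_inverted_gray(dab)


class TestSegmentNuclei:
    def test_recovers_all_planted_nuclei(self, population):
        spec, gt, recs, labels, _ = population
        assert len(recs) == len(spec.nuclei)
        tree = cKDTree([n.center for n in spec.nuclei])
        d, _ = tree.query([r.centroid for r in recs])
        assert d.max() <= 1.0

    def test_counts_match_brute_force_flood_fill(self, population):
        spec, gt, recs, labels, _ = population
        from ihcquant.stains import auto_threshold

        img, _ = render_scene(spec)
        hema, _, _ = unmix(img)
        mask = ndi.binary_fill_holes(auto_threshold(to_inverted_gray(hema)).data)
        naive_labels, n = ndi.label(mask, structure=np.ones((3, 3), int))
        naive_areas = sorted(np.bincount(naive_labels.ravel())[1:])
        px_area = spec.pixel_size_um**2
        ours = sorted(int(round(r.area_um2 / px_area)) for r in recs)
        assert n == len(recs)
        assert naive_areas == ours

    def test_rasterized_disk_is_circular(self):
        img = np.zeros((64, 64), np.uint8)
        yy, xx = np.mgrid[0:64, 0:64]
        img[(yy - 32) ** 2 + (xx - 32) ** 2 <= 20**2] = 200
        recs, _ = segment_nuclei(img, 1.0, min_area_um2=10, max_area_um2=1e6)
        assert len(recs) == 1
        assert recs[0].circularity >= 0.95

    def test_blank_image_gives_empty_list(self):
        recs, labels = segment_nuclei(np.zeros((32, 32), np.uint8), 1.0)
        assert recs == [] and labels.max() == 0

    def test_translation_invariance_of_measurements(self):
        img = np.zeros((80, 80), np.uint8)
        yy, xx = np.mgrid[0:80, 0:80]
        img[(yy - 30) ** 2 + (xx - 30) ** 2 <= 64] = 200
        shifted = np.roll(np.roll(img, 11, axis=0), 7, axis=1)
        a, _ = segment_nuclei(img, 1.0)
        b, _ = segment_nuclei(shifted, 1.0)
        assert a[0].area_um2 == b[0].area_um2
        assert a[0].circularity == pytest.approx(b[0].circularity)


class TestClassifyNuclei:
    def test_planted_populations_fully_separated(self, population):
        spec, gt, recs, labels, _ = population
        classify_nuclei(recs, area_cut_um2=40.0, circ_cut=0.8)
        tree = cKDTree([n.center for n in spec.nuclei])
        for r in recs:
            _, i = tree.query(r.centroid)
            assert r.cls == spec.nuclei[i].cls

    def test_boundary_is_inclusive_for_hepatocyte(self):
        rec = NucleusRecord(1, area_um2=40.0, perimeter_um=1.0, circularity=0.8,
                            centroid=(0, 0))
        classify_nuclei([rec], 40.0, 0.8)
        assert rec.cls == "hepatocyte"

    def test_mixed_morphometrics_are_other(self):
        rec = NucleusRecord(1, area_um2=100.0, perimeter_um=1.0, circularity=0.5,
                            centroid=(0, 0))
        classify_nuclei([rec], 40.0, 0.8)
        assert rec.cls == "other"

    def test_empty_input(self):
        assert classify_nuclei([]) == []


class TestCytosolicSignal:
    def test_uniform_image_gives_uniform_mean(self):
        labels = np.zeros((40, 40), np.int32)
        labels[18:23, 18:23] = 1
        img = np.full((40, 40), 137.0)
        sig = cytosolic_signal(img, labels, 1, ring_um=2.0)
        assert sig.mean_signal == pytest.approx(137.0)
        assert not sig.flagged

    def test_rank_order_matches_planted_per_cell_od(self, population):
        spec, gt, recs, labels, dab_gray = population
        tree = cKDTree([n.center for n in spec.nuclei])
        measured, planted = [], []
        for r in recs:
            sig = cytosolic_signal(dab_gray, labels, r.label, ring_um=1.5,
                                   pixel_size_um=spec.pixel_size_um)
            _, i = tree.query(r.centroid)
            measured.append(sig.mean_signal)
            planted.append(spec.nuclei[i].dab_od)
        rho = stats.spearmanr(measured, planted).statistic
        assert rho == pytest.approx(1.0)

    def test_disjoint_rings_are_independent(self):
        def scene(od_b):
            return SceneSpec(
                width_px=120, height_px=60, pixel_size_um=1.0,
                nuclei=(NucleusSpec((30.0, 30.0), 5.0, dab_od=0.4, cell_radius_um=12.0),
                        NucleusSpec((90.0, 30.0), 5.0, dab_od=od_b, cell_radius_um=12.0)),
                cytoplasm=PerCellField(),
            )

        out = []
        for od_b in (0.1, 0.9):
            img, gt = render_scene(scene(od_b))
            _, dab, _ = unmix(img)
            out.append(cytosolic_signal(to_inverted_gray(dab), gt.label_image, 1,
                                        ring_um=3.0).mean_signal)
        assert out[0] == pytest.approx(out[1], abs=1e-9)


class TestVesselEndothelium:
    def test_planted_endothelial_ods_ordered(self):
        spec, boxes = make_vessel_scene((0.6, 0.1), seed=8)
        img, _ = render_scene(spec)
        hema, dab, _ = unmix(img)
        recs = vessel_endothelium(to_inverted_gray(hema), to_inverted_gray(dab),
                                  boxes, band_um=2.5, pixel_size_um=spec.pixel_size_um)
        assert not any(r.flagged for r in recs)
        assert recs[0].mean_signal > recs[1].mean_signal

    def test_zero_od_vessel_near_background(self):
        spec, boxes = make_vessel_scene((0.0,), seed=9)
        img, _ = render_scene(spec)
        hema, dab, _ = unmix(img)
        rec = vessel_endothelium(to_inverted_gray(hema), to_inverted_gray(dab),
                                 boxes, 2.5, spec.pixel_size_um)[0]
        background = to_inverted_gray(np.array([[spec.background_dab_od]]))[0, 0]
        assert rec.mean_signal <= background + 2.0

    def test_box_without_ring_flagged(self):
        sma = np.zeros((60, 60), np.uint8)
        sma[10:20, 10:20] = 200  # solid blob, no lumen
        recs = vessel_endothelium(sma, sma, [(0, 0, 59, 59)])
        assert recs[0].flagged


class TestPercentArea:
    def test_exact_count(self):
        img = np.zeros((10, 20), np.uint8)
        img[:5, :10] = 100  # 50 of 200 pixels
        frac = percent_area(img, np.ones((10, 20), bool), 50, 255)
        assert frac.percent_area == 25.0

    def test_saturated_region(self):
        img = np.full((8, 8), 255, np.uint8)
        assert percent_area(img, np.ones((8, 8), bool)).percent_area == 100.0

    def test_matches_naive_loop_on_random_inputs(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            img = rng.integers(0, 256, (16, 16)).astype(np.uint8)
            region = rng.random((16, 16)) < 0.6
            if not region.any():
                continue
            lo, hi = sorted(rng.integers(0, 256, 2))
            naive = sum(
                1
                for y in range(16)
                for x in range(16)
                if region[y, x] and lo <= img[y, x] <= hi
            )
            got = percent_area(img, region, int(lo), int(hi)).percent_area
            assert got == pytest.approx(100.0 * naive / region.sum())

    def test_recovers_planted_fraction(self):
        spec, region, analytic = make_area_fraction_scene(7.5, seed=11)
        img, _ = render_scene(spec)
        _, dab, _ = unmix(img)
        got = percent_area(to_inverted_gray(dab), region, 50, 255).percent_area
        assert got == pytest.approx(analytic, abs=0.2)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            percent_area(np.zeros((4, 4), np.uint8), np.zeros((4, 4), bool))
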