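import itertools

import numpy as np
import pytest
from scipy import ndimage as ndi

from cytoseg import (
    BinaryMask,
    GrayImage,
    OverlapConfig,
    PhantomSpec,
    compensate_overlap,
    detect_nuclei,
    evaluate_scene,
    generate_scene,
    graph_cut,
    merge_cells,
    segment_overlapping,
    separate_clumps,
    voronoi_partition,
)
from cytoseg.overlap import NucleusSet, _pairwise_weights


def cut_energy(labels, ufg, ubg, img, lam, sigma):
    """Independent energy oracle: unary + contrast-weighted Potts."""
    e = np.where(labels, ufg, ubg).sum()
    wv, wh = _pairwise_weights(img, lam, sigma)
    e += (wv * (labels[1:, :] != labels[:-1, :])).sum()
    e += (wh * (labels[:, 1:] != labels[:, :-1])).sum()
    return e


class TestGraphCut:
    def test_matches_exhaustive_enumeration_on_tiny_images(self, rng):
        for _ in range(20):
            h, w = int(rng.integers(2, 4)), int(rng.integers(2, 5))
            img = GrayImage(rng.integers(0, 256, (h, w)).astype(np.uint8))
            ufg = rng.uniform(0, 10, (h, w))
            ubg = rng.uniform(0, 10, (h, w))
            lam = float(rng.uniform(0.1, 3))
            sigma = float(rng.uniform(5, 50))
            mask = graph_cut(ufg, ubg, img, lam, sigma).pixels
            fimg = img.pixels.astype(float)
            e_cut = cut_energy(mask, ufg, ubg, fimg, lam, sigma)
            e_min = min(
                cut_energy(np.array(bits, bool).reshape(h, w), ufg, ubg,
                           fimg, lam, sigma)
                for bits in itertools.product([0, 1], repeat=h * w))
            assert e_cut == pytest.approx(e_min, abs=1e-4)

    def test_lambda_zero_is_pixelwise_maximum_likelihood(self, rng):
        img = GrayImage(rng.integers(0, 256, (6, 7)).astype(np.uint8))
        ufg = rng.uniform(0, 10, (6, 7))
        ubg = rng.uniform(0, 10, (6, 7))
        mask = graph_cut(ufg, ubg, img, 0.0, 20.0)
        assert np.array_equal(mask.pixels, ufg <= ubg)


class TestSeparateClumps:
    def test_high_contrast_scene_recovers_clump(self, multicell_scene):
        from cytoseg import zsi

        image, truth = multicell_scene
        mask = separate_clumps(image)
        assert zsi(mask, truth.cytoplasm_union()) >= 0.95

    def test_blank_noisy_background_yields_empty_mask(self):
        rng = np.random.default_rng(0)
        px = np.clip(rng.normal(220, 8, (128, 128)), 0, 255).astype(np.uint8)
        assert separate_clumps(GrayImage(px)).area == 0

    def test_single_gray_level_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            separate_clumps(GrayImage(np.full((16, 16), 100, np.uint8)))


class TestDetectNuclei:
    def test_finds_all_nuclei_with_accurate_centroids(self, multicell_scene):
        image, truth = multicell_scene
        clump = separate_clumps(image)
        nucs = detect_nuclei(image, clump)
        assert len(nucs) == truth.n_cells
        true_cents = np.array([ndi.center_of_mass(c.nucleus.pixels)
                               for c in truth.cells])
        for cy, cx in nucs.centroids:
            d = np.hypot(true_cents[:, 0] - cy, true_cents[:, 1] - cx).min()
            assert d <= 3.0

    def test_clump_without_dark_blobs_gives_empty_set(self):
        px = np.full((40, 40), 220, np.uint8)
        px[10:30, 10:30] = 150
        clump = BinaryMask(px == 150)
        nucs = detect_nuclei(GrayImage(px), clump)
        assert len(nucs) == 0

    def test_blob_below_min_area_filtered(self):
        px = np.full((40, 40), 150, np.uint8)
        px[20:22, 20:22] = 60  # 4-px blob
        clump = BinaryMask(np.ones((40, 40), bool))
        nucs = detect_nuclei(GrayImage(px), clump, min_area=30)
        assert len(nucs) == 0


class TestVoronoi:
    def seeds_at(self, points):
        nucs = []
        for r, c in points:
            m = np.zeros((1, 1), bool)  # masks unused by the partition
            nucs.append((BinaryMask(np.ones((1, 1), bool)), (float(r), float(c))))
        return NucleusSet(nuclei=tuple(nucs))

    def test_symmetric_seeds_split_at_bisector(self):
        clump = BinaryMask(np.ones((10, 21), bool))
        part = voronoi_partition(clump, self.seeds_at([(5, 5), (5, 15)]))
        assert np.all(part.labels.pixels[:, :10] == 1)
        assert np.all(part.labels.pixels[:, 11:] == 2)
        assert np.all(part.labels.pixels[:, 10] == 1)  # tie → lowest index

    def test_single_seed_takes_whole_clump(self, rng):
        clump = BinaryMask(rng.uniform(size=(20, 20)) > 0.4)
        part = voronoi_partition(clump, self.seeds_at([(3, 3)]))
        assert np.all(part.labels.pixels[clump.pixels] == 1)

    def test_agrees_with_brute_force_nearest_seed(self, rng):
        for _ in range(50):
            clump_px = rng.uniform(size=(25, 30)) > 0.3
            clump_px[0, 0] = True
            n_seeds = int(rng.integers(1, 6))
            pts = [(float(rng.uniform(0, 24)), float(rng.uniform(0, 29)))
                   for _ in range(n_seeds)]
            part = voronoi_partition(BinaryMask(clump_px), self.seeds_at(pts))
            rows, cols = np.nonzero(clump_px)
            for r, c in zip(rows[::7], cols[::7]):  # subsample pixels
                d = [np.hypot(r - pr, c - pc) for pr, pc in pts]
                assert part.labels.pixels[r, c] == int(np.argmin(d)) + 1

    def test_zero_seeds_rejected(self):
        with pytest.raises(ValueError, match="seed"):
            voronoi_partition(BinaryMask(np.ones((4, 4), bool)),
                              NucleusSet(nuclei=()))


class TestCompensation:
    def _stages(self, image, clump_mask):
        nucs = detect_nuclei(image, clump_mask)
        part = voronoi_partition(clump_mask, nucs)
        return nucs, part

    def test_zero_extension_equals_coarse_partition(self, multicell_scene):
        image, _ = multicell_scene
        clump = separate_clumps(image)
        nucs, part = self._stages(image, clump)
        comp = compensate_overlap(image, part, nucs, max_extension=0.0)
        for i, m in enumerate(comp):
            assert np.array_equal(m.pixels, part.labels.pixels == i + 1)

    def test_monotone_in_max_extension(self, multicell_scene):
        image, _ = multicell_scene
        clump = separate_clumps(image)
        nucs, part = self._stages(image, clump)
        prev = None
        for ext in (0.0, 20.0, 50.0, 90.0):
            comp = compensate_overlap(image, part, nucs, max_extension=ext)
            if prev is not None:
                for a, b in zip(prev, comp):
                    assert not np.any(a.pixels & ~b.pixels)  # never shrinks
            prev = comp

    def test_overlap_region_jointly_covered(self):
        spec = PhantomSpec(n_cells=2, overlap_fraction=0.25, seed=7)
        spec = spec.with_size((384, 384))
        image, truth = generate_scene(spec)
        clump = separate_clumps(image)
        nucs, part = self._stages(image, clump)
        comp = compensate_overlap(image, part, nucs)
        true_ov = truth.cells[0].cytoplasm.pixels & truth.cells[1].cytoplasm.pixels
        union = np.zeros_like(true_ov)
        for m in comp:
            union |= m.pixels
        assert union[true_ov].mean() >= 0.95

    def test_disjoint_cells_gain_almost_nothing(self, disjoint_scene):
        image, _ = disjoint_scene
        clump_mask = separate_clumps(image)
        lab, n = ndi.label(clump_mask.pixels)
        checked = 0
        for j in range(1, n + 1):
            clump = BinaryMask(lab == j)
            if clump.area < 200:
                continue
            nucs, part = self._stages(image, clump)
            comp = compensate_overlap(image, part, nucs)
            region = part.labels.pixels == 1
            added = comp[0].pixels & ~region
            # nothing beyond a 1-px band: each clump holds a single cell
            band = ndi.binary_dilation(region) & ~region
            assert not np.any(added & ~band)
            checked += 1
        assert checked == 3


class TestMergeAndPipeline:
    def test_single_cell_clump_gives_whole_clump(self, disjoint_scene):
        image, truth = disjoint_scene
        pred = segment_overlapping(image)
        assert pred.n_cells == truth.n_cells
        rep = evaluate_scene(pred, truth)
        assert rep.mean_zsi >= 0.9

    def test_cell_count_equals_nucleus_count(self, multicell_scene):
        image, _ = multicell_scene
        clump = separate_clumps(image)
        nucs = detect_nuclei(image, clump)
        pred = segment_overlapping(image)
        assert pred.n_cells == len(nucs)

    def test_union_covers_clump_up_to_erosion_band(self, multicell_scene):
        image, _ = multicell_scene
        clump = separate_clumps(image)
        pred = segment_overlapping(image)
        core = ndi.binary_erosion(clump.pixels, iterations=2)
        union = pred.cytoplasm_union().pixels
        assert np.count_nonzero(core & ~union) == 0

    def test_good_segmentation_on_moderate_overlap(self, multicell_scene):
        image, truth = multicell_scene
        rep = evaluate_scene(segment_overlapping(image), truth)
        assert rep.mean_zsi > 0.7

    def test_blank_image_gives_empty_scene(self):
        rng = np.random.default_rng(1)
        px = np.clip(rng.normal(220, 8, (160, 160)), 0, 255).astype(np.uint8)
        pred = segment_overlapping(GrayImage(px))
        assert pred.n_cells == 0

    def test_deterministic(self, multicell_scene):
        image, _ = multicell_scene
        a = segment_overlapping(image)
        b = segment_overlapping(image)
        assert a.n_cells == b.n_cells
        for ca, cb in zip(a.cells, b.cells):
            assert np.array_equal(ca.cytoplasm.pixels, cb.cytoplasm.pixels)
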