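import dataclasses

import numpy as np
import pytest

from breastmwi import breast_seg as bs
from breastmwi import preprocess as pp
from breastmwi.errors import DegenerateInputError, SeedError, SternumNotFoundError
from breastmwi.phantom import PhantomSpec, dice, generate_phantom
from breastmwi.volumes import ScalarVolume, binary_labelmap
from conftest import bfs_flood_fill


@pytest.fixture(scope="module")
def preprocessed(benign_phantom):
    """Bias-corrected, normalised sequences of the benign phantom."""
    from breastmwi.pipeline import body_mask_otsu

    fat_mask = body_mask_otsu(benign_phantom.dixon_f)
    bias = pp.correct_bias_field(benign_phantom.dixon_f, mask=fat_mask, n_classes=1)
    field = bias.field.data
    out = {"dixon_f": pp.minmax_normalise(bias.corrected)}
    for name in ("dixon_w", "dixon_i"):
        vol = getattr(benign_phantom, name)
        out[name] = pp.minmax_normalise(vol.with_data(vol.data / field))
    return out


@pytest.fixture(scope="module")
def sternum(preprocessed):
    return bs.locate_sternum(preprocessed["dixon_w"])


@pytest.fixture(scope="module")
def fat_mask(preprocessed, sternum):
    seed = bs.pick_fat_seed(preprocessed["dixon_f"], sternum)
    return bs.grow_fat_mask(preprocessed["dixon_f"], seed)


@pytest.fixture(scope="module")
def breast_mask(fat_mask, preprocessed, sternum):
    return bs.build_breast_mask(fat_mask, preprocessed["dixon_w"], sternum)


class TestLocateSternum:
    def test_phantom_sternum_plane_found(self, preprocessed, benign_phantom):
        loc = bs.locate_sternum(preprocessed["dixon_w"])
        assert loc.coronal_index == benign_phantom.sternum_truth.coronal_index
        assert loc.midline_index == benign_phantom.sternum_truth.midline_index

    def test_known_bright_bar_located(self):
        data = np.zeros((21, 60, 21))
        data[10, 38:43, 5:16] = 200.0  # bright bar, anterior-most face at 42
        loc = bs.locate_sternum(ScalarVolume(data))
        assert loc.coronal_index == 42
        assert loc.midline_index == 10

    def test_all_zero_volume_raises(self):
        with pytest.raises(SternumNotFoundError):
            bs.locate_sternum(ScalarVolume(np.zeros((10, 10, 10))))

    def test_posterior_shift_equivariance(self, preprocessed):
        vol = preprocessed["dixon_w"]
        shifted = np.zeros_like(vol.data)
        shifted[:, :-5, :] = vol.data[:, 5:, :]  # move body 5 voxels posterior
        a = bs.locate_sternum(vol)
        b = bs.locate_sternum(vol.with_data(shifted))
        assert a.coronal_index - b.coronal_index == 5


class TestGrowFatMask:
    def test_uniform_bright_slab_is_plateau(self):
        data = np.zeros((12, 12, 12))
        data[3:9, 3:9, 3:9] = 200.0
        vol = ScalarVolume(data)
        mask = bs.grow_fat_mask(vol, (5, 5, 5))
        expected = data == 200.0
        assert np.array_equal(mask.data.astype(bool), expected)

    def test_phantom_breast_fat_recovered(self, fat_mask, benign_phantom):
        # breast-compartment fat: everything fat-bright anterior of the
        # thoracic cavity (includes the retromammary layer)
        ys = np.arange(benign_phantom.truth.shape[1]).reshape(1, -1, 1)
        truth_fat = (benign_phantom.dixon_f.data > 100) & (ys >= 11)
        inter = (fat_mask.data.astype(bool) & truth_fat).sum()
        d = 2 * inter / (fat_mask.data.sum() + truth_fat.sum())
        assert d >= 0.9

    def test_thoracic_fat_not_reached(self, fat_mask, benign_phantom):
        # thoracic fat sits inside the cavity (posterior rows); the grown
        # mask must not leak through the dark muscle wall
        ys = np.where(fat_mask.data)[1]
        assert ys.min() >= 11

    @pytest.mark.parametrize("seed_rng", [0, 1, 2])
    def test_equals_bfs_flood_fill_oracle(self, seed_rng):
        rng = np.random.default_rng(seed_rng)
        data = rng.uniform(0, 255, (20, 20, 20))
        lo, hi = data.mean() + data.std(), data.max()
        candidates = np.argwhere((data >= lo) & (data <= hi))
        seed = tuple(candidates[rng.integers(len(candidates))])
        mask = bs.grow_fat_mask(ScalarVolume(data), seed)
        oracle = bfs_flood_fill(data, seed, lo, hi)
        assert np.array_equal(mask.data.astype(bool), oracle)

    def test_seed_outside_window_rejected(self):
        data = np.zeros((8, 8, 8))
        data[4, 4, 4] = 250.0
        with pytest.raises(SeedError):
            bs.grow_fat_mask(ScalarVolume(data), (0, 0, 0))


class TestSplitFatWatershed:
    def test_dumbbell_keeps_anterior_ball(self):
        shape = (30, 40, 30)
        xs, ys, zs = np.ogrid[:30, :40, :30]
        ball_a = (xs - 15) ** 2 + (ys - 28) ** 2 + (zs - 15) ** 2 <= 49
        ball_p = (xs - 15) ** 2 + (ys - 10) ** 2 + (zs - 15) ** 2 <= 49
        neck = (np.abs(xs - 15) < 1) & (ys >= 17) & (ys <= 21) & (np.abs(zs - 15) < 1)
        mask = binary_labelmap(ball_a | ball_p | neck, ScalarVolume(np.zeros(shape)))
        out = bs.split_fat_watershed(mask).data.astype(bool)
        assert (out & ball_a).sum() == ball_a.sum()
        assert (out & ball_p).sum() == 0

    def test_disconnected_input_returns_anterior_component(self):
        shape = (10, 20, 10)
        data = np.zeros(shape, bool)
        data[3:6, 2:5, 3:6] = True  # posterior blob
        data[3:6, 14:18, 3:6] = True  # anterior blob
        mask = binary_labelmap(data, ScalarVolume(np.zeros(shape)))
        out = bs.split_fat_watershed(mask).data.astype(bool)
        assert out[:, 14:18, :].sum() == 36
        assert out[:, 2:5, :].sum() == 0

    def test_merged_phantom_split_recovers_breast_fat(self):
        spec = dataclasses.replace(PhantomSpec(), merged_fat=True)
        ph = generate_phantom(spec)
        from breastmwi.pipeline import body_mask_otsu

        fat_mask0 = body_mask_otsu(ph.dixon_f)
        bias = pp.correct_bias_field(ph.dixon_f, mask=fat_mask0, n_classes=1)
        f = pp.minmax_normalise(bias.corrected)
        w = pp.minmax_normalise(ph.dixon_w.with_data(ph.dixon_w.data / bias.field.data))
        st = bs.locate_sternum(w)
        grown = bs.grow_fat_mask(f, bs.pick_fat_seed(f, st))
        assert np.where(grown.data)[1].min() < 11  # leaked into the thorax
        split = bs.split_fat_watershed(grown)
        ys2 = np.arange(ph.truth.shape[1]).reshape(1, -1, 1)
        truth_fat = (ph.dixon_f.data > 100) & (ys2 >= 11)
        inter = (split.data.astype(bool) & truth_fat).sum()
        d = 2 * inter / (split.data.sum() + truth_fat.sum())
        assert d >= 0.9

    def test_empty_mask_rejected(self):
        mask = binary_labelmap(np.zeros((5, 5, 5), bool), ScalarVolume(np.zeros((5, 5, 5))))
        with pytest.raises(DegenerateInputError):
            bs.split_fat_watershed(mask)


class TestBuildBreastMask:
    def test_phantom_mask_covers_breast_region(self, breast_mask, preprocessed, benign_phantom):
        truth_region = np.isin(benign_phantom.truth.data, (1, -1, -2, -3))
        i_data = preprocessed["dixon_i"].data
        # the union mask inevitably drags a one-voxel air shell along with the
        # radius-3 dilation; evaluate the tissue part (bright in-phase)
        m = breast_mask.data.astype(bool) & (i_data >= i_data.mean())
        d = 2 * (m & truth_region).sum() / (m.sum() + truth_region.sum())
        assert d >= 0.9

    def test_zero_water_volume_leaves_dilated_fat_only(self, fat_mask, sternum):
        from scipy import ndimage

        zeros = ScalarVolume(
            np.zeros(fat_mask.shape), spacing=fat_mask.spacing
        )
        out = bs.build_breast_mask(fat_mask, zeros, sternum)
        expected = ndimage.binary_dilation(fat_mask.binary(), structure=bs.ball(3))
        assert np.array_equal(out.data.astype(bool), expected)

    def test_nipple_hole_closed_by_water_term(self, fat_mask, breast_mask, benign_phantom):
        # the fibroglandular wedge reaching the skin leaves a hole in the
        # fat mask that the water-weighted term must close
        wedge = (benign_phantom.truth.data == 1) & (benign_phantom.dixon_w.data > 100)
        in_fat = (fat_mask.data.astype(bool) & wedge).sum() / wedge.sum()
        in_mask = (breast_mask.data.astype(bool) & wedge).sum() / wedge.sum()
        assert in_fat < 0.5
        assert in_mask > 0.95

    def test_empty_fat_mask_rejected(self, preprocessed, sternum):
        empty = binary_labelmap(
            np.zeros(preprocessed["dixon_w"].shape, bool), preprocessed["dixon_w"]
        )
        with pytest.raises(DegenerateInputError):
            bs.build_breast_mask(empty, preprocessed["dixon_w"], sternum)


class TestMaskSymmetry:
    def test_symmetric_mask_scores_zero(self):
        data = np.zeros((6, 5, 5), bool)
        data[1:5, 1:3, 1:3] = True  # symmetric under x-flip of a 6-wide axis
        ev = bs.mask_symmetry_mse(binary_labelmap(data, ScalarVolume(np.zeros((6, 5, 5)))))
        assert ev.mse_percent == 0.0
        assert not ev.invasive

    def test_complement_masks_score_hundred(self):
        ones = binary_labelmap(np.ones((4, 4, 4), bool), ScalarVolume(np.zeros((4, 4, 4))))
        zeros = ones.data.astype(np.float64)
        flipped = 1.0 - zeros
        mse = float(((zeros - flipped) ** 2).mean() * 100)
        assert mse == 100.0

    def test_hand_computed_two_of_four_voxels(self):
        data = np.zeros((2, 2, 1), dtype=np.int8)
        data[0, 0, 0] = 1
        data[0, 1, 0] = 1  # flip moves both to x=1: 4 of 4 voxels differ? no:
        # A = [[1,1],[0,0]], B = flip_x(A) = [[0,0],[1,1]]; all 4 differ -> 100
        ev = bs.mask_symmetry_mse(binary_labelmap(data, ScalarVolume(np.zeros((2, 2, 1)))))
        assert ev.mse_percent == pytest.approx(100.0)
        data2 = np.zeros((2, 2, 1), dtype=np.int8)
        data2[0, 0, 0] = 1
        data2[0, 1, 0] = 1
        data2[1, 1, 0] = 1  # flip leaves y=1 fixed, y=0 differs: 2 of 4 -> 50
        ev2 = bs.mask_symmetry_mse(binary_labelmap(data2, ScalarVolume(np.zeros((2, 2, 1)))))
        assert ev2.mse_percent == pytest.approx(50.0)

    def test_flip_invariance_and_bounds(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            data = rng.random((8, 8, 8)) > 0.5
            vol = ScalarVolume(np.zeros((8, 8, 8)))
            a = bs.mask_symmetry_mse(binary_labelmap(data, vol)).mse_percent
            b = bs.mask_symmetry_mse(binary_labelmap(data[::-1], vol)).mse_percent
            assert a == pytest.approx(b)
            assert 0.0 <= a <= 100.0


class TestInvasiveCompletion:
    def test_symmetric_mask_unchanged(self):
        data = np.zeros((6, 6, 6), bool)
        data[1:5, 1:4, 1:4] = True
        vol = ScalarVolume(np.full((6, 6, 6), 100.0))
        mask = binary_labelmap(data, vol)
        out = bs.complete_invasive_mask(mask, vol)
        assert np.array_equal(out.data, mask.data)

    def test_union_minus_output_is_dark_in_phase(self, invasive_phantom):
        from breastmwi.pipeline import body_mask_otsu

        fat_mask0 = body_mask_otsu(invasive_phantom.dixon_f)
        bias = pp.correct_bias_field(invasive_phantom.dixon_f, mask=fat_mask0, n_classes=1)
        f = pp.minmax_normalise(bias.corrected)
        w = pp.minmax_normalise(
            invasive_phantom.dixon_w.with_data(invasive_phantom.dixon_w.data / bias.field.data)
        )
        i = pp.minmax_normalise(
            invasive_phantom.dixon_i.with_data(invasive_phantom.dixon_i.data / bias.field.data)
        )
        st = bs.locate_sternum(w)
        grown = bs.grow_fat_mask(f, bs.pick_fat_seed(f, st))
        mask = bs.build_breast_mask(grown, w, st)
        out = bs.complete_invasive_mask(mask, i)
        m = mask.binary()
        union = m | m[::-1]
        dropped = union & ~out.data.astype(bool)
        from scipy import ndimage
        # dropped voxels (outside filled holes) must be dark in-phase
        assert np.all(i.data[dropped] < i.data.mean())

    def test_invasion_notch_filled(self, invasive_result, invasive_phantom):
        assert invasive_result.mask_eval.invasive
        tum = invasive_phantom.truth.data == -3
        labelled_tumour = invasive_result.labels.data == -3
        d = 2 * (tum & labelled_tumour).sum() / (tum.sum() + labelled_tumour.sum())
        assert d >= 0.9


class TestExtractBoundaries:
    def test_hemisphere_on_slab(self):
        shape = (40, 30, 40)
        xs, ys, zs = np.ogrid[:40, :30, :40]
        slab = (ys >= 2) & (ys <= 6) & (xs >= 4) & (xs < 36) & (zs >= 4) & (zs < 36)
        dome = ((xs - 20) ** 2 + ((ys - 6) * 1.0) ** 2 + (zs - 20) ** 2 <= 144) & (ys >= 6)
        mask = binary_labelmap(slab | dome, ScalarVolume(np.zeros(shape)))
        sternum = bs.SternumLocation(coronal_index=6, midline_index=20)
        skin, chest = bs.extract_boundaries(mask, sternum)
        s, c = skin.data.astype(bool), chest.data.astype(bool)
        assert not (s & c).any()
        assert (s | c).sum() <= mask.data.sum()
        # the dome cap is skin, the slab base is chest wall
        assert s[20, 17, 20] or s[20, 16, 20]
        assert c[20, 2:5, 20].any()

    def test_single_voxel_mask_is_all_skin(self):
        data = np.zeros((7, 7, 7), bool)
        data[3, 3, 3] = True
        mask = binary_labelmap(data, ScalarVolume(np.zeros((7, 7, 7))))
        skin, chest = bs.extract_boundaries(
            mask, bs.SternumLocation(coronal_index=1, midline_index=3)
        )
        assert skin.data[3, 3, 3] == 1
        assert chest.data.sum() == 0

    def test_skin_and_chest_disjoint_subsets_of_mask(self, benign_result):
        labels = benign_result.labels.data
        assert not ((labels == -2) & (labels == -1)).any()

    def test_phantom_skin_recovered(self, benign_result, benign_phantom):
        assert dice(benign_result.labels, benign_phantom.truth, -2) >= 0.8


class TestRefineSkin:
    def test_zero_water_empties_skin(self, fat_mask, sternum, breast_mask):
        zeros = ScalarVolume(np.zeros(breast_mask.shape), spacing=breast_mask.spacing)
        skin0, _ = bs.extract_boundaries(breast_mask, sternum)
        refined = bs.refine_skin(skin0, zeros, fat_mask)
        assert refined.data.sum() == 0

    def test_refined_skin_subset_and_thickness(self, preprocessed, fat_mask, sternum, breast_mask, benign_phantom):
        skin0, _ = bs.extract_boundaries(breast_mask, sternum)
        refined = bs.refine_skin(skin0, preprocessed["dixon_w"], fat_mask)
        r = refined.data.astype(bool)
        assert np.all(skin0.data.astype(bool) | ~r)  # subset of the dilated contour
        # anterior-ray thickness through the breast apex region: 1..3, median 2
        # near-apex columns, where the surface is perpendicular to the
        # anterior rays and the run length measures true thickness
        thicknesses = []
        for x in list(range(9, 18)) + list(range(35, 44)):
            for z in range(13, 22):
                col = r[x, :, z]
                hits = np.flatnonzero(col)
                if hits.size:  # first run of skin entered from the anterior
                    top = hits.max()
                    run = 1
                    while top - run >= 0 and col[top - run]:
                        run += 1
                    thicknesses.append(run)
        med = np.median(thicknesses)
        assert 1 <= med <= 3

    def test_never_overlaps_true_fat(self, benign_result, benign_phantom):
        fat_true = (benign_phantom.truth.data == 1) & (benign_phantom.dixon_f.data > 100)
        skin_pred = benign_result.labels.data == -2
        overlap = (fat_true & skin_pred).sum() / skin_pred.sum()
        assert overlap < 0.05


class TestAssembleLabelmap:
    def test_empty_accessories_give_binary_map(self, breast_mask):
        empty = binary_labelmap(np.zeros(breast_mask.shape, bool), breast_mask)
        labels = bs.assemble_labelmap(breast_mask, empty, empty)
        present = set(np.unique(labels.data).tolist())
        assert present <= {0, 1}
        assert np.array_equal(labels.data == 1, breast_mask.data.astype(bool))

    def test_labels_partition_the_volume(self, benign_result):
        labels = benign_result.labels.data
        sizes = sum(int((labels == v).sum()) for v in (0, 1, -1, -2, -3))
        assert sizes == labels.size

    def test_full_pipeline_per_label_dice(self, benign_result, benign_phantom):
        assert dice(benign_result.labels, benign_phantom.truth, 1) >= 0.9
        assert dice(benign_result.labels, benign_phantom.truth, -2) >= 0.8
        assert dice(benign_result.labels, benign_phantom.truth, -1) >= 0.8

    def test_tumour_outside_mask_warns_but_labels(self, breast_mask):
        outside = np.zeros(breast_mask.shape, bool)
        outside[0, 0, 0] = True
        tum = binary_labelmap(outside, breast_mask)
        empty = binary_labelmap(np.zeros(breast_mask.shape, bool), breast_mask)
        with pytest.warns(UserWarning):
            labels = bs.assemble_labelmap(breast_mask, empty, empty, tum)
        assert labels.data[0, 0, 0] == -3
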