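import numpy as np
import pytest
from scipy import ndimage

from jointseg import GenePanel
from jointseg.density import PixelGrid
from jointseg.io import NucleiSeeds, SpotTable
from jointseg.model import (
    JointSegmentationModel,
    ReassignmentParams,
    anneal_and_sample,
    border_pixels,
    counts_from_segmentation,
    rescale_pixel_probabilities,
    watershed_baseline,
    watershed_initialize,
)


def _grid(shape=(20, 20, 8), s=1.0):
    return PixelGrid(origin=np.zeros(3), pixel_size=s, shape=shape)


def _nuclei_blob(shape, blobs):
    lab = np.zeros(shape, np.int32)
    for i, (c, r) in enumerate(blobs, start=1):
        ix, iy, iz = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
        d2 = (ix - c[0]) ** 2 + (iy - c[1]) ** 2 + (iz - c[2]) ** 2
        lab[d2 <= r**2] = i
    return NucleiSeeds(lab, voxel_size=np.ones(3))


class TestWatershedInitialize:
    def test_single_nucleus_shell_capped_at_d(self):
        grid = _grid()
        nuclei = _nuclei_blob(grid.shape, [((10, 10, 4), 2)])
        labels, nuc_mask = watershed_initialize(grid, nuclei, d=2.0)
        assert set(np.unique(labels)) == {0, 1}
        edt = ndimage.distance_transform_edt(nuclei.labels == 0)
        assert np.all(edt[labels == 1] <= 2.0 + 1e-9)
        # every nucleus pixel belongs to its cell
        assert np.all(labels[nuc_mask] == 1)

    def test_two_distant_nuclei_stay_disjoint(self):
        grid = _grid((30, 12, 8))
        nuclei = _nuclei_blob(grid.shape, [((7, 6, 4), 2), ((22, 6, 4), 2)])
        labels, _ = watershed_initialize(grid, nuclei, d=2.0)
        # nuclei surfaces are ~10 um apart: 2 um caps leave a background gap
        a = np.argwhere(labels == 1)
        b = np.argwhere(labels == 2)
        assert len(a) and len(b)
        from scipy.spatial import cKDTree

        gap = cKDTree(a).query(b)[0].min()
        assert gap > 1.5

    def test_no_nuclei_rejected(self):
        grid = _grid()
        nuclei = NucleiSeeds(np.zeros(grid.shape, np.int32), np.ones(3))
        with pytest.raises(ValueError):
            watershed_initialize(grid, nuclei)


class TestWatershedBaseline:
    def test_low_density_region_stays_background(self):
        grid = _grid((24, 12, 6))
        nuclei = _nuclei_blob(grid.shape, [((6, 6, 3), 2)])
        E_p = np.full((grid.n_pixels, 1), 4.0)  # log2 = 2 >= 1
        dens = E_p[:, 0].reshape(grid.shape)
        dens[16:, :, :] = 0.5  # log2 < 1 -> masked
        E_p = dens.reshape(-1, 1)
        labels = watershed_baseline(grid, E_p, nuclei)
        assert np.all(labels[16:, :, :] == 0)

    def test_uniform_field_bisected_with_separating_line(self):
        grid = _grid((30, 10, 6))
        nuclei = _nuclei_blob(grid.shape, [((7, 5, 3), 2), ((22, 5, 3), 2)])
        E_p = np.full((grid.n_pixels, 1), 4.0)
        labels = watershed_baseline(grid, E_p, nuclei)
        n1, n2 = (labels == 1).sum(), (labels == 2).sum()
        assert abs(n1 - n2) / max(n1, n2) < 0.15
        # the one-pixel watershed line carries no label
        assert (labels == 0).sum() > 0
        touching = False
        for ax in range(3):
            a = np.moveaxis(labels, ax, 0)[:-1]
            b = np.moveaxis(labels, ax, 0)[1:]
            touching |= bool(np.any((a == 1) & (b == 2)) or np.any((a == 2) & (b == 1)))
        assert not touching

    def test_everything_masked_rejected(self):
        grid = _grid()
        nuclei = _nuclei_blob(grid.shape, [((10, 10, 4), 2)])
        E_p = np.full((grid.n_pixels, 1), 0.1)
        with pytest.raises(ValueError):
            watershed_baseline(grid, E_p, nuclei, mask_threshold=10.0)


class TestBorderPixels:
    def _two_cell_volume(self, same_type=False):
        shape = (10, 8, 6)
        labels = np.zeros(shape, np.int32)
        labels[:5] = 1
        labels[5:] = 2
        T_c = np.array([-1, 0, 0 if same_type else 1])
        nucleus = np.zeros(shape, bool)
        return labels, T_c, nucleus

    def test_interior_pixel_not_border(self):
        labels, T_c, nuc = self._two_cell_volume()
        border = border_pixels(labels, T_c, nuc)
        bset = {tuple(b) for b in border}
        assert (2, 4, 3) not in bset  # deep inside cell 1

    def test_interface_pixels_are_border_for_different_types(self):
        labels, T_c, nuc = self._two_cell_volume(same_type=False)
        border = border_pixels(labels, T_c, nuc)
        bset = {tuple(b) for b in border}
        # interior interface pixel: 9 neighbours across, 17 own -> border
        assert (4, 4, 3) in bset and (5, 4, 3) in bset

    def test_same_type_interface_frozen(self):
        labels, T_c, nuc = self._two_cell_volume(same_type=True)
        border = border_pixels(labels, T_c, nuc)
        bset = {tuple(b) for b in border}
        # interface away from the volume surface: only same-type contact
        assert (4, 4, 3) not in bset and (5, 4, 3) not in bset

    def test_nucleus_pixels_excluded(self):
        labels, T_c, nuc = self._two_cell_volume()
        nuc[4, 4, 3] = True
        border = border_pixels(labels, T_c, nuc)
        assert (4, 4, 3) not in {tuple(b) for b in border}

    def test_count_rule_five_different_two_same(self):
        # a 1-pixel tongue of cell 1 into cell 2: far more than 5 different
        # neighbours -> border; a pixel with 25 same neighbours -> not border
        shape = (9, 9, 3)
        labels = np.full(shape, 2, np.int32)
        labels[:4] = 1
        labels[4, 4, 1] = 1  # tongue pixel: same-cell contacts only behind it
        T_c = np.array([-1, 0, 1])
        border = border_pixels(labels, T_c, np.zeros(shape, bool))
        assert (4, 4, 1) in {tuple(b) for b in border}

    def test_background_accretion_candidates(self):
        shape = (8, 8, 4)
        labels = np.zeros(shape, np.int32)
        labels[:4] = 1  # slab of cell 1, rest background
        T_c = np.array([-1, 0])
        border = border_pixels(labels, T_c, np.zeros(shape, bool))
        bset = {tuple(b) for b in border}
        # background pixel face-adjacent to the slab: 9 neighbours in cell 1,
        # 17 background -> candidate
        assert (4, 4, 2) in bset
        # background far from the slab: no
        assert (7, 4, 2) not in bset


class TestRescaling:
    def test_within_d_dominates_any_probability(self):
        q = np.array([[0.01, 0.99]])
        r = np.array([[0.5, 10.0]])
        out, bg = rescale_pixel_probabilities(q, r, d=2.0, prob_floor=0.01)
        assert not bg[0]
        assert out[0, 0] > 0.9

    def test_decay_factor_half_at_six_d(self):
        d = 2.0
        # type 1 at r - d = 2.5 d has factor exactly 1 -> reference channel
        q = np.array([[0.4, 0.4]])
        r = np.array([[6 * d, 3.5 * d]])
        out, _ = rescale_pixel_probabilities(q, r, d=d, prob_floor=0.001)
        assert out[0, 0] / out[0, 1] == pytest.approx(0.5, rel=1e-12)

    def test_exponential_variant_agrees_at_six_d(self):
        d = 2.0
        q = np.array([[0.4, 0.4]])
        r = np.array([[6 * d, 3.5 * d]])
        rational, _ = rescale_pixel_probabilities(q, r, d=d, prob_floor=0.001)
        exp_out, _ = rescale_pixel_probabilities(
            q, r, d=d, prob_floor=0.001, decay="exponential"
        )
        assert rational[0, 0] == pytest.approx(0.5 * rational[0, 1], rel=1e-12)
        assert exp_out[0, 0] == pytest.approx(
            0.5 ** ((6 * d - d) / (5 * d)) * exp_out[0, 1] / 0.5 ** ((3.5 * d - d) / (5 * d)),
            rel=1e-9,
        )

    def test_no_neighbors_flags_background(self):
        q = np.array([[0.5, 0.5]])
        r = np.full((1, 2), np.inf)
        out, bg = rescale_pixel_probabilities(q, r, d=2.0, prob_floor=0.05)
        assert bg[0] and np.all(out[0] == 0.0)

    def test_probability_floor_zeroes_small_entries(self):
        q = np.array([[0.97, 0.03]])
        r = np.array([[8.0, 8.0]])
        out, bg = rescale_pixel_probabilities(q, r, d=2.0, prob_floor=0.05)
        assert out[0, 1] == 0.0 and out[0, 0] == pytest.approx(1.0)

    def test_rows_renormalized(self, rng):
        q = rng.dirichlet(np.ones(4), size=50)
        r = rng.uniform(0.1, 30.0, size=(50, 4))
        r[rng.random((50, 4)) < 0.3] = np.inf
        out, bg = rescale_pixel_probabilities(q, r, d=2.0, prob_floor=0.01)
        sums = out.sum(axis=1)
        assert np.allclose(sums[~bg], 1.0) and np.all(sums[bg] == 0.0)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            rescale_pixel_probabilities(
                np.array([[1.0]]), np.array([[-1.0]]), d=2.0, prob_floor=0.05
            )


class TestAnnealing:
    def test_one_hot_always_selected(self, rng):
        q = np.tile([[0.0, 1.0, 0.0]], (200, 1))
        out = anneal_and_sample(q, iteration=0, rng=rng)
        assert np.all(out == 1)

    def test_large_iteration_converges_to_argmax(self, rng):
        q = np.tile([[0.3, 0.7]], (500, 1))
        out = anneal_and_sample(q, iteration=1_000_000, rng=rng)
        assert np.all(out == 1)

    def test_iteration_zero_matches_multinomial_frequencies(self, rng):
        n = 100_000
        q = np.tile([[0.7, 0.3]], (n, 1))
        out = anneal_and_sample(q, iteration=0, rng=rng)
        freq = (out == 0).mean()
        sigma = np.sqrt(0.7 * 0.3 / n)
        assert abs(freq - 0.7) <= 3 * sigma

    def test_boost_changes_frequencies_as_predicted(self, rng):
        n = 100_000
        it = 10  # boost = 1.5
        q = np.tile([[0.6, 0.4]], (n, 1))
        expected = 0.6 * 1.5 / (0.6 * 1.5 + 0.4)
        out = anneal_and_sample(q, iteration=it, rng=rng)
        freq = (out == 0).mean()
        sigma = np.sqrt(expected * (1 - expected) / n)
        assert abs(freq - expected) <= 3 * sigma

    def test_zero_rows_become_background(self, rng):
        q = np.zeros((3, 2))
        out = anneal_and_sample(q, iteration=0, rng=rng)
        assert np.all(out == -1)


class TestCounts:
    def test_hand_built_two_cell_toy(self):
        grid = _grid((4, 4, 1))
        labels = np.zeros(grid.shape, np.int32)
        labels[:2] = 1
        labels[2:] = 2
        panel = GenePanel(["a", "b"])
        xyz = np.array(
            [
                [0.5, 0.5, 0.5],  # cell 1
                [1.5, 2.5, 0.5],  # cell 1
                [2.5, 0.5, 0.5],  # cell 2
                [3.5, 3.5, 0.5],  # cell 2
                [0.2, 3.8, 0.5],  # cell 1
                [3.9, 0.1, 0.5],  # cell 2
            ]
        )
        gene = np.array([0, 1, 0, 0, 1, 1])
        spots = SpotTable(xyz, gene, panel)
        E_c, assign = counts_from_segmentation(labels, grid, spots)
        np.testing.assert_array_equal(assign, [1, 1, 2, 2, 1, 2])
        np.testing.assert_array_equal(E_c[1], [1, 2])
        np.testing.assert_array_equal(E_c[2], [2, 1])

    def test_out_of_grid_spot_counts_background(self):
        grid = _grid((4, 4, 1))
        labels = np.ones(grid.shape, np.int32)
        panel = GenePanel(["a"])
        spots = SpotTable(np.array([[100.0, 0.5, 0.5]]), np.array([0]), panel)
        with pytest.warns(UserWarning):
            E_c, assign = counts_from_segmentation(labels, grid, spots)
        assert assign[0] == 0
        assert E_c[0, 0] == 1

    def test_conservation_column_sums(self, rng):
        grid = _grid((6, 6, 3))
        labels = rng.integers(0, 3, size=grid.shape).astype(np.int32)
        panel = GenePanel(["a", "b", "c"])
        xyz = rng.uniform(0, [5.9, 5.9, 2.9], size=(200, 3))
        spots = SpotTable(xyz, rng.integers(0, 3, 200), panel)
        E_c, assign = counts_from_segmentation(labels, grid, spots)
        np.testing.assert_array_equal(
            E_c.sum(axis=0), np.bincount(spots.gene, minlength=3)
        )


@pytest.fixture(scope="module")
def short_run(tiny_tissue, taxonomy6):
    """A short EM run with per-iteration conservation bookkeeping."""
    model = JointSegmentationModel(
        tiny_tissue.spots, tiny_tissue.nuclei, taxonomy6, pixel_size=1.0,
        params=ReassignmentParams.for_simulation(
            seed=2, n_train_rounds=2, n_reassign_iters=2
        ),
    )
    checks = []

    nuclei = tiny_tissue.nuclei
    nuc_vox = np.argwhere(nuclei.labels > 0)
    nuc_ids = nuclei.labels[nuc_vox[:, 0], nuc_vox[:, 1], nuc_vox[:, 2]]
    # map nucleus voxel centres into grid indices (grids are padded, so
    # the two index frames differ by the grid origin)
    centers = (nuc_vox + 0.5) * nuclei.voxel_size + nuclei.origin
    gidx = model.grid.point_to_index(centers)

    def cb(state, iteration):
        E_c, assign = counts_from_segmentation(state.labels, model.grid, model.spots)
        checks.append(
            {
                "total": int(E_c.sum()),
                "ids": set(map(int, state.cell_ids)),
                "nuclei_ok": bool(
                    np.all(
                        state.labels[gidx[:, 0], gidx[:, 1], gidx[:, 2]] == nuc_ids
                    )
                ),
            }
        )

    res = model.fit(seed=2, callback=cb)
    return model, res, checks


class TestEMInvariants:
    def test_spot_total_conserved_each_iteration(self, short_run, tiny_tissue):
        _, _, checks = short_run
        assert checks, "callback never fired"
        for c in checks:
            assert c["total"] == len(tiny_tissue.spots)

    def test_cell_ids_conserved(self, short_run):
        _, res, checks = short_run
        ids0 = checks[0]["ids"]
        for c in checks[1:]:
            assert c["ids"] == ids0
        assert set(map(int, res.cell_ids)) == ids0

    def test_nucleus_pixels_never_flip(self, short_run):
        _, _, checks = short_run
        assert all(c["nuclei_ok"] for c in checks)

    def test_fit_reproducible_under_seed(self, tiny_tissue, taxonomy6):
        def run():
            model = JointSegmentationModel(
                tiny_tissue.spots, tiny_tissue.nuclei, taxonomy6, pixel_size=1.0,
                params=ReassignmentParams.for_simulation(
                    seed=3, n_train_rounds=1, n_reassign_iters=2
                ),
            )
            return model.fit(seed=3).labels

        np.testing.assert_array_equal(run(), run())

    def test_single_type_input_keeps_watershed_boundary(
        self, tiny_tissue, taxonomy6, monkeypatch
    ):
        model = JointSegmentationModel(
            tiny_tissue.spots, tiny_tissue.nuclei, taxonomy6, pixel_size=1.0,
            params=ReassignmentParams.for_simulation(seed=4),
        )

        def all_one_type(labels):
            T = np.full(int(labels.max()) + 1, -1, dtype=np.int64)
            ids = np.unique(labels)
            T[ids[ids > 0]] = 0
            return T

        monkeypatch.setattr(model, "_classify_current_cells", all_one_type)
        res = model.fit(seed=4)
        init_labels, _ = watershed_initialize(model.grid, tiny_tissue.nuclei, d=2.0)
        np.testing.assert_array_equal(res.labels, init_labels)

    def test_summary_and_manifest(self, short_run):
        _, res, _ = short_run
        text = res.summary()
        assert "cells" in text and "method" in text
        man = res.manifest()
        assert man["method"] == "em"
        assert man["n_spots"] == len(res.spots)


def test_write_outputs_round_trip(tmp_path, tiny_tissue, taxonomy6):
    from jointseg.io import read_label_volume, write_outputs

    model = JointSegmentationModel(
        tiny_tissue.spots, tiny_tissue.nuclei, taxonomy6, pixel_size=1.0,
        params=ReassignmentParams.for_simulation(seed=1),
    )
    res = model.fit_watershed()
    paths = write_outputs(res, tmp_path / "run")
    back, _, _ = read_label_volume(paths["labels"])
    np.testing.assert_array_equal(back, res.labels)
    import pandas as pd

    assign = pd.read_csv(paths["assignments"], sep="\t")
    assert len(assign) == len(tiny_tissue.spots)
    counts = pd.read_csv(paths["counts"], sep="\t", index_col=0)
    # row sums equal spots assigned per cell; grand total + background = all
    gene_cols = [c for c in counts.columns if c != "cell_type"]
    recount = np.bincount(assign["cell"], minlength=int(res.labels.max()) + 1)
    for cell, row in counts[gene_cols].iterrows():
        assert row.sum() == recount[cell]
    assert counts[gene_cols].to_numpy().sum() + (assign["cell"] == 0).sum() == len(
        tiny_tissue.spots
    )
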