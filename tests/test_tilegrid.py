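import io

import numpy as np
import pytest

from roiselect.tilegrid import (
    NO_ANNOTATION,
    TileGrid,
    assign_tile_annotation,
    build_grid_from_label_map,
    filter_background_tiles,
    read_tile_table,
    rescale_intensity_percentiles,
    write_tile_table,
)


def brute_force_compositions(label_map, tile_size):
    """Independent oracle: per-tile label fractions by explicit pixel loops."""
    n_rows = label_map.shape[0] // tile_size
    n_cols = label_map.shape[1] // tile_size
    k = label_map.max()
    out = np.zeros((n_rows * n_cols, k))
    for t in range(n_rows * n_cols):
        r, c = divmod(t, n_cols)
        counts = np.zeros(k + 1)
        for i in range(tile_size):
            for j in range(tile_size):
                counts[label_map[r * tile_size + i, c * tile_size + j]] += 1
        if counts[1:].sum():
            out[t] = counts[1:] / counts[1:].sum()
    return out


class TestBuildGridFromLabelMap:
    def test_homogeneous_map(self):
        grid = build_grid_from_label_map(np.ones((512, 512), dtype=int), 256)
        assert (grid.n_rows, grid.n_cols) == (2, 2)
        assert np.allclose(grid.compositions, 1.0)
        assert grid.valid.all()

    def test_half_and_half_tile(self):
        m = np.ones((64, 64), dtype=int)
        m[:, 32:] = 2
        grid = build_grid_from_label_map(m, 64)
        assert np.allclose(grid.compositions, [[0.5, 0.5]])

    def test_quarters_match_pixel_count_oracle(self, rng):
        m = rng.integers(0, 4, size=(96, 96))
        grid = build_grid_from_label_map(m, 32)
        assert np.allclose(grid.compositions, brute_force_compositions(m, 32))

    def test_pixel_conservation(self, rng):
        """Summing composition * labeled-pixel-count over tiles recovers the
        map's per-id pixel counts exactly."""
        m = rng.integers(0, 5, size=(128, 128))
        grid = build_grid_from_label_map(m, 32)
        labeled_per_tile = np.array(
            [
                (m[r * 32 : (r + 1) * 32, c * 32 : (c + 1) * 32] > 0).sum()
                for r in range(4)
                for c in range(4)
            ]
        )
        totals = (grid.compositions * labeled_per_tile[:, None]).sum(axis=0)
        expected = np.bincount(m.ravel(), minlength=5)[1:]
        assert np.allclose(totals, expected)

    def test_partial_tiles_dropped(self):
        grid = build_grid_from_label_map(np.ones((70, 100), dtype=int), 32)
        assert (grid.n_rows, grid.n_cols) == (2, 3)

    def test_unlabeled_tile_invalid(self):
        m = np.zeros((64, 32), dtype=int)
        m[:32] = 1
        grid = build_grid_from_label_map(m, 32)
        assert grid.valid.tolist() == [True, False]

    def test_tile_larger_than_image_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            build_grid_from_label_map(np.ones((16, 16), dtype=int), 32)


class TestAssignTileAnnotation:
    def test_majority_and_empty(self):
        grid = build_grid_from_label_map(np.ones((10, 20), dtype=int), 10)
        ann = np.zeros((10, 20), dtype=int)
        ann[:, :10][:6] = 2
        ann[:, :10][6:] = 3
        out = assign_tile_annotation(ann, grid)
        assert out.annotations[0] == 2
        assert out.annotations[1] == NO_ANNOTATION

    def test_tie_breaks_to_lowest_id(self):
        grid = build_grid_from_label_map(np.ones((10, 10), dtype=int), 10)
        ann = np.zeros((10, 10), dtype=int)
        ann[:5] = 4
        ann[5:] = 1
        out = assign_tile_annotation(ann, grid)
        assert out.annotations[0] == 1

    def test_extent_mismatch_errors(self):
        grid = build_grid_from_label_map(np.ones((20, 20), dtype=int), 10)
        with pytest.raises(ValueError, match="extent"):
            assign_tile_annotation(np.ones((10, 10), dtype=int), grid)


class TestBackgroundFilter:
    def test_white_and_dark_tiles(self):
        white = np.full((1, 8, 8, 3), 255, dtype=np.uint8)
        dark = np.zeros((1, 8, 8, 3), dtype=np.uint8)
        assert filter_background_tiles(white).tolist() == [True]
        assert filter_background_tiles(dark).tolist() == [False]

    def test_exactly_70_percent_is_foreground(self):
        # strict "greater than": 70.0% white pixels is kept as tissue
        tile = np.zeros((1, 10, 10, 3), dtype=np.uint8)
        tile[0, :7] = 255
        assert filter_background_tiles(tile).tolist() == [False]
        tile[0, 7, 0] = 255
        assert filter_background_tiles(tile).tolist() == [True]

    def test_idempotent_and_order_independent(self, rng):
        tiles = rng.integers(0, 256, size=(12, 6, 6, 3), dtype=np.uint8)
        mask = filter_background_tiles(tiles)
        assert np.array_equal(mask, filter_background_tiles(tiles))
        perm = rng.permutation(12)
        assert np.array_equal(mask[perm], filter_background_tiles(tiles[perm]))

    def test_non_8bit_errors(self):
        with pytest.raises(ValueError, match="8-bit"):
            filter_background_tiles(np.ones((1, 4, 4, 3)) * 0.5)


class TestRescaleIntensity:
    def test_ramp_full_range_is_identity(self):
        img = np.arange(256, dtype=float).reshape(16, 16)
        out = rescale_intensity_percentiles(img, 0, 100)
        assert np.allclose(out, img / 255.0)

    def test_default_percentiles_clip(self, rng):
        img = rng.random((100, 100))
        out = rescale_intensity_percentiles(img)
        lo, hi = np.percentile(img, [70, 99.99])
        assert out.min() == 0.0 and out.max() == 1.0
        inside = (img > lo) & (img < hi)
        assert np.allclose(out[inside], (img[inside] - lo) / (hi - lo))

    def test_constant_image_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="constant"):
            out = rescale_intensity_percentiles(np.full((8, 8), 3.0))
        assert np.all(out == 0)


class TestTileTableIO:
    def _random_grid(self, rng):
        comps = rng.dirichlet(np.ones(4), size=12)
        valid = rng.random(12) > 0.2
        grid = TileGrid(3, 4, 32, comps, valid=valid,
                        annotations=rng.integers(-1, 3, 12),
                        embeddings=rng.standard_normal((12, 5)))
        return grid

    def test_round_trip_lossless(self, rng):
        grid = self._random_grid(rng)
        buf = io.StringIO()
        write_tile_table(grid, buf)
        buf.seek(0)
        back = read_tile_table(buf)
        assert (back.n_rows, back.n_cols, back.tile_size_px) == (3, 4, 32)
        assert np.allclose(back.compositions, grid.compositions)
        assert np.array_equal(back.labels, grid.labels)
        assert np.array_equal(back.annotations, grid.annotations)
        assert np.array_equal(back.valid, grid.valid)
        assert np.allclose(back.embeddings, grid.embeddings)

    def test_bad_composition_sum_rejected(self, rng):
        grid = self._random_grid(rng)
        buf = io.StringIO()
        write_tile_table(grid, buf)
        text = buf.getvalue().replace("\n", "\n", 1)
        # corrupt one valid row's first composition entry
        import pandas as pd

        header, _, body = text.partition("\n")
        df = pd.read_csv(io.StringIO(body))
        row = int(np.flatnonzero(grid.valid)[0])
        df.loc[row, "composition_0"] = df.loc[row, "composition_0"] + 0.2
        bad = io.StringIO(header + "\n" + df.to_csv(index=False))
        with pytest.raises(ValueError, match="sum to 1"):
            read_tile_table(bad)

    def test_label_only_table_one_hot(self):
        text = "row,col,valid,label\n0,0,1,2\n0,1,1,0\n"
        grid = read_tile_table(io.StringIO(text), tile_size_px=16)
        assert np.allclose(grid.compositions, [[0, 0, 1], [1, 0, 0]])

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing required"):
            read_tile_table(io.StringIO("a,b\n1,2\n"), tile_size_px=8)
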