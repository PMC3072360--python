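"""Silhouette geometry: pixel counts, the roundness operation, mask cleanup."""

import math

import numpy as np
import pytest

from pmnshape import (BinaryMask, count_area, displacement_ratio, extract_mask,
                      feret_diameter, mask_metrics, metrics_table, roundness,
                      roundness_series, trace_perimeter)
from pmnshape.exceptions import (BorderTouchError, EmptyForegroundError,
                                 FrameError)
from pmnshape.mask import centroid, masks_from_stack, read_stack, write_stack


def square_mask(side, pad=2):
    g = np.zeros((side + 2 * pad, side + 2 * pad), dtype=bool)
    g[pad:pad + side, pad:pad + side] = True
    return BinaryMask(g)


class TestRoundnessOperation:
    def test_continuous_circle_is_exactly_one(self):
        for r in (1.0, 10.0, 100.0):
            met = roundness(2.0 * math.pi * r, math.pi * r ** 2)
            assert met.R == 1.0
            assert met.r1 == pytest.approx(r)
            assert met.r2 == pytest.approx(r)

    def test_rejects_nonpositive_counts(self):
        with pytest.raises(ValueError):
            roundness(0.0, 10.0)
        with pytest.raises(ValueError):
            roundness(10.0, -1.0)

    def test_irregular_outline_raises_r(self):
        # same area, longer boundary -> larger R
        compact = roundness(40.0, 100.0).R
        ragged = roundness(80.0, 100.0).R
        assert ragged > compact


class TestPixelCounts:
    def test_square_counts(self):
        m = square_mask(5)
        assert count_area(m) == 25
        # boundary pixels of a 5x5 square: 25 - 9 interior
        assert trace_perimeter(m) == 16

    def test_single_pixel(self):
        g = np.zeros((5, 5), dtype=bool)
        g[2, 2] = True
        m = BinaryMask(g)
        assert count_area(m) == 1
        assert trace_perimeter(m) == 1

    def test_weighted_perimeter_differs_on_diagonal_edges(self):
        # a diamond has all-diagonal boundary: the weighted estimate exceeds
        # the literal count scaled appropriately
        g = np.zeros((21, 21), dtype=bool)
        yy, xx = np.mgrid[0:21, 0:21]
        g[np.abs(yy - 10) + np.abs(xx - 10) <= 7] = True
        m = BinaryMask(g)
        assert trace_perimeter(m, method="weighted") != trace_perimeter(m)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            trace_perimeter(square_mask(3), method="nope")

    def test_rasterized_circle_r_near_one(self):
        yy, xx = np.mgrid[0:101, 0:101]
        g = (yy - 50.0) ** 2 + (xx - 50.0) ** 2 <= 40.0 ** 2
        met = mask_metrics(BinaryMask(g))
        # pixel-count perimeter of a rasterized circle is biased low relative
        # to 2 pi r; R lands near but not exactly at 1
        assert 0.8 < met.R < 1.1


class TestExtractMask:
    def test_keeps_largest_component_and_fills_holes(self):
        g = np.zeros((30, 30), dtype=np.uint8)
        g[5:15, 5:15] = 1     # 100 px component
        g[8:10, 8:10] = 0     # interior hole
        g[20:23, 20:23] = 1   # 9 px distractor
        m = extract_mask(g)
        assert count_area(m) == 100          # hole filled
        assert not m.grid[21, 21]            # distractor dropped

    def test_border_touch_rejected(self):
        g = np.zeros((10, 10), dtype=bool)
        g[0:4, 3:6] = True
        with pytest.raises(BorderTouchError):
            extract_mask(g)
        m = extract_mask(g, reject_border=False)
        assert count_area(m) == 12

    def test_empty_rejected(self):
        with pytest.raises(EmptyForegroundError):
            extract_mask(np.zeros((8, 8), dtype=bool))

    def test_otsu_on_grayscale(self):
        g = np.full((20, 20), 10, dtype=np.uint8)
        g[5:15, 5:15] = 200
        m = extract_mask(g)
        assert count_area(m) == 100

    def test_numeric_threshold(self):
        g = np.full((20, 20), 10.0)
        g[5:15, 5:15] = 30.0
        m = extract_mask(g, threshold=20.0)
        assert count_area(m) == 100

    def test_component_tie_broken_row_major(self):
        g = np.zeros((20, 20), dtype=bool)
        g[2:5, 2:5] = True    # first in row-major order
        g[10:13, 10:13] = True
        m = extract_mask(g)
        assert m.grid[3, 3] and not m.grid[11, 11]


class TestSeriesExtraction:
    def test_roundness_series_length_and_labels(self, small_recording):
        series = roundness_series(small_recording.frames, dt=2.0,
                                  cell_id="c1", state_label="idling")
        assert series.n == len(small_recording.frames)
        assert series.dt == 2.0
        assert np.all(series.values > 0)

    def test_frame_error_carries_index(self):
        good = square_mask(5)
        bad = square_mask(5)
        bad.grid = bad.grid.copy()
        bad.grid[:] = False
        bad.grid[0, 0] = True  # degenerate but positive counts: fine
        frames = [good, good]
        series = roundness_series(frames)
        assert series.n == 2
        with pytest.raises(ValueError):
            roundness_series([good])

    def test_metrics_table_columns(self, small_recording):
        df = metrics_table(small_recording.frames[:5])
        assert list(df.columns) == ["frame", "time_s", "p", "A", "r1", "r2",
                                    "R", "centroid_x", "centroid_y"]
        assert len(df) == 5


class TestShapeSummaries:
    def test_centroid_of_square(self):
        m = square_mask(5, pad=2)   # rows/cols 2..6
        assert centroid(m) == (4.0, 4.0)

    def test_feret_of_square(self):
        m = square_mask(5, pad=2)
        assert feret_diameter(m) == pytest.approx(4.0 * math.sqrt(2.0))

    def test_displacement_ratio_static_is_zero(self):
        frames = [square_mask(5) for _ in range(4)]
        ratio, moving = displacement_ratio(frames)
        assert ratio == 0.0 and not moving

    def test_displacement_ratio_flags_translocation(self):
        frames = []
        for shift in (0, 10, 20, 30):
            g = np.zeros((60, 60), dtype=bool)
            g[5:10, 5 + shift:10 + shift] = True
            frames.append(BinaryMask(g))
        ratio, moving = displacement_ratio(frames)
        assert moving and ratio >= 1.5


class TestStackIO:
    def test_tiff_round_trip(self, tmp_path, small_recording):
        path = tmp_path / "movie.tif"
        frames = small_recording.frames[:6]
        write_stack(path, frames)
        back = read_stack(path)
        assert len(back) == 6
        masks = masks_from_stack(back)
        assert all((m.grid == f.grid).all() for m, f in zip(masks, frames))

    def test_png_directory(self, tmp_path, small_recording):
        import imageio.v3 as iio
        for i, f in enumerate(small_recording.frames[:3]):
            iio.imwrite(tmp_path / f"frame_{i:03d}.png",
                        f.grid.astype(np.uint8) * 255)
        back = read_stack(tmp_path)
        assert len(back) == 3

    def test_missing_frames_dir(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_stack(tmp_path)

    def test_bad_frame_in_stack_raises_frame_error(self):
        frames = [np.ones((10, 10), dtype=bool) * False]
        frames[0][:, :] = False
        with pytest.raises(FrameError) as exc:
            masks_from_stack(frames)
        assert exc.value.frame_index == 0
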