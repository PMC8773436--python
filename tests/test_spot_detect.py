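import numpy as np
import pytest

from fireflash.spot_detect import (
    DetectionParams,
    detect_sequence,
    find_maxima,
    flash_rate,
    spots_to_frame,
)
from fireflash.synth import IndividualSpec, SceneSpec, perching_profile, simulate_scene
from fireflash.video_io import FrameSequence, InputError

from conftest import PER_FRAME_DETECTION, truth_owner_of

NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


# ---------------------------------------------------------------------------
# independent brute-force oracle: plateau maxima + saddle search by
# descending-threshold BFS reachability (pure python, no labeling machinery)


def _plateaus(img):
    h, w = img.shape
    seen = np.zeros_like(img, dtype=bool)
    out = []
    for r in range(h):
        for c in range(w):
            if seen[r, c]:
                continue
            v = img[r, c]
            stack, cells = [(r, c)], [(r, c)]
            seen[r, c] = True
            is_max = True
            while stack:
                rr, cc = stack.pop()
                for dr, dc in NEIGHBORS:
                    nr, nc = rr + dr, cc + dc
                    if 0 <= nr < h and 0 <= nc < w:
                        if img[nr, nc] == v and not seen[nr, nc]:
                            seen[nr, nc] = True
                            stack.append((nr, nc))
                            cells.append((nr, nc))
                        elif img[nr, nc] > v:
                            is_max = False
            if is_max:
                out.append((v, cells))
    return out


def _reachable(img, start_cells, level):
    """Cells connected to start through pixels strictly above `level`."""
    h, w = img.shape
    seen = set(start_cells)
    stack = list(start_cells)
    while stack:
        rr, cc = stack.pop()
        for dr, dc in NEIGHBORS:
            nr, nc = rr + dr, cc + dc
            if (0 <= nr < h and 0 <= nc < w and (nr, nc) not in seen
                    and img[nr, nc] > level):
                seen.add((nr, nc))
                stack.append((nr, nc))
    return seen


def oracle_maxima(img, prominence, min_background):
    """Accepted maxima positions by exhaustive saddle reasoning.

    A plateau at value v is accepted iff nothing higher — nor an
    equal-valued plateau with a raster-earlier pixel — is reachable without
    descending to v - prominence or below, and v clears the floor.
    """
    img = np.asarray(img, dtype=float)
    accepted = []
    for v, cells in _plateaus(img):
        if v < min_background + prominence:
            continue
        region = _reachable(img, cells, v - prominence)
        if any(img[r, c] > v for (r, c) in region):
            continue
        own_first = min(r * img.shape[1] + c for (r, c) in cells)
        others_first = [r * img.shape[1] + c for (r, c) in region
                        if img[r, c] == v and (r, c) not in cells]
        if others_first and min(others_first) < own_first:
            continue
        rows = [r for r, _ in cells]
        cols = [c for _, c in cells]
        rr = int(np.ceil(np.mean(rows) - 0.5))
        cc = int(np.ceil(np.mean(cols) - 0.5))
        accepted.append((rr, cc))
    return sorted(accepted)


def spot_positions(spots):
    return sorted((int(s.y), int(s.x)) for s in spots)


class TestFindMaxima:
    def test_uniform_image_has_no_spots(self):
        img = np.full((8, 8), 10, np.uint8)
        assert find_maxima(img) == []

    def test_single_blob_gives_one_spot_at_peak(self):
        yy, xx = np.mgrid[0:21, 0:21]
        img = (10 + 190 * np.exp(-((xx - 10) ** 2 + (yy - 8) ** 2) / 18)).astype(np.uint8)
        spots = find_maxima(img)
        assert len(spots) == 1
        assert (spots[0].x, spots[0].y) == (10, 8)
        assert spots[0].peak_intensity == img.max()
        assert spots[0].area >= 1 and spots[0].elongation >= 1

    def test_ridge_joined_peaks_suppress_the_less_prominent(self):
        # peaks 200 and 150 joined by a ridge at 100: the second peak's
        # prominence is 50 < 80, so only one spot
        img = np.full((9, 16), 10, np.uint8)
        img[4, 3] = 200
        img[4, 12] = 150
        img[4, 4:12] = 100
        spots = find_maxima(img, DetectionParams(prominence=80))
        assert spot_positions(spots) == [(4, 3)]
        # at prominence 40 both qualify
        spots = find_maxima(img, DetectionParams(prominence=40))
        assert spot_positions(spots) == [(4, 3), (4, 12)]

    def test_plateau_reports_rounded_centroid(self):
        img = np.full((9, 9), 10, np.uint8)
        img[4, 3:6] = 200  # 3-pixel plateau centered at column 4
        spots = find_maxima(img)
        assert spot_positions(spots) == [(4, 4)]

    @pytest.mark.parametrize("prominence", [20, 50, 80])
    def test_matches_brute_force_oracle_on_random_grids(self, prominence):
        rng = np.random.default_rng(prominence)
        params = DetectionParams(prominence=prominence, min_background=10)
        for _ in range(40):
            img = rng.integers(0, 256, size=(12, 12)).astype(np.uint8)
            got = spot_positions(find_maxima(img, params))
            want = oracle_maxima(img, prominence, 10)
            assert got == want, f"mismatch on\n{img}"

    def test_matches_oracle_on_smooth_blobby_grids(self):
        from scipy import ndimage

        rng = np.random.default_rng(7)
        params = DetectionParams(prominence=60, min_background=0)
        for _ in range(20):
            raw = rng.integers(0, 256, size=(16, 16)).astype(float)
            img = np.round(ndimage.gaussian_filter(raw, 1.2) * 2).astype(np.uint8)
            got = spot_positions(find_maxima(img, params))
            want = oracle_maxima(img, 60, 0)
            assert got == want

    def test_raising_prominence_never_adds_spots(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            img = rng.integers(0, 256, size=(14, 14)).astype(np.uint8)
            counts = [
                len(find_maxima(img, DetectionParams(prominence=p, min_background=0)))
                for p in (10, 30, 60, 90, 140)
            ]
            assert counts == sorted(counts, reverse=True)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(13)
        inner = rng.integers(0, 256, size=(10, 10)).astype(np.uint8)
        base = np.zeros((20, 20), np.uint8)
        base[2:12, 3:13] = inner
        shifted = np.zeros((20, 20), np.uint8)
        shifted[6:16, 5:15] = inner
        params = DetectionParams(prominence=70)
        a = spot_positions(find_maxima(base, params))
        b = spot_positions(find_maxima(shifted, params))
        assert [(r + 4, c + 2) for r, c in a] == b

    def test_empty_image_is_an_error(self):
        with pytest.raises(InputError):
            find_maxima(np.empty((0, 0), np.uint8))


class TestDetectSequence:
    def test_blank_clip_yields_empty_table(self):
        seq = FrameSequence(np.full((90, 16, 16), 10, np.uint8), 1 / 30)
        table = detect_sequence(seq, DetectionParams())
        assert len(table) == 0
        assert list(table.columns) == [
            "frame_idx", "t_s", "x_px", "y_px", "peak", "area_px", "elongation"
        ]

    def test_timestamps_fall_on_decimated_grid(self):
        frames = np.full((90, 16, 16), 10, np.uint8)
        frames[0, 5, 5] = 220
        frames[30, 8, 8] = 220
        frames[60, 11, 11] = 220
        seq = FrameSequence(frames, 1 / 30)
        table = detect_sequence(seq, DetectionParams(decimation_factor=30))
        assert table["t_s"].tolist() == [0.0, 1.0, 2.0]
        assert table["frame_idx"].tolist() == [0, 30, 60]

    def test_scene_recall_and_precision(self):
        # perching individuals flash sparsely; detection per frame with
        # duplicate merging must find nearly all truth flashes and little else
        spec = SceneSpec(
            duration=15.0, fps=30.0, width=320, height=240, seed=5,
            individuals=[
                IndividualSpec(profile=perching_profile(), behavior="perching")
                for _ in range(3)
            ],
        )
        seq, truth = simulate_scene(spec)
        table = detect_sequence(seq, DetectionParams(**PER_FRAME_DETECTION))
        matched = sum(
            truth_owner_of(row, truth) is not None
            for row in table.itertuples()
        )
        recall_pool = truth.n_flashes
        assert matched / len(table) >= 0.9  # precision
        assert matched / recall_pool >= 0.9  # recall


class TestFlashRate:
    def test_no_spots_is_zero(self):
        assert flash_rate(spots_to_frame([]), 120.0) == 0.0

    def test_counts_over_duration(self):
        import pandas as pd

        table = pd.DataFrame({"t_s": np.linspace(0, 119, 302)})
        assert flash_rate(table, 120.0) == pytest.approx(302 / 120)

    def test_zero_duration_is_an_error(self):
        with pytest.raises(InputError):
            flash_rate(spots_to_frame([]), 0.0)
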