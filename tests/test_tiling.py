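import numpy as np
import pytest

from pygleason import (
    LevelConfig,
    SlideImage,
    background_ratio,
    generate_patch_groups,
    modal_tissue_label,
    select_training_patches,
)
from pygleason.tiling import (
    DEFAULT_LEVELS,
    extract_window,
    paint_group_labels,
    selection_records,
)


class TestLevelConfig:
    def test_defaults(self):
        assert [lv.S for lv in DEFAULT_LEVELS] == [100, 75, 50]

    def test_shift_step_20px_for_s100(self):
        assert LevelConfig(100, 0.2).step == 20

    def test_five_steps_per_cycle(self):
        assert LevelConfig(100, 0.2).steps_per_cycle == 5

    def test_group_count_13(self):
        for s in (100, 75, 50):
            assert LevelConfig(s).n_groups == 13

    def test_non_integral_step_rejected(self):
        with pytest.raises(ValueError, match="whole number"):
            LevelConfig(75, 0.25).validate()  # 18.75 px

    def test_non_integer_inverse_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            LevelConfig(100, 0.3).validate()


class TestGeneratePatchGroups:
    def test_13_groups_per_level_39_total(self):
        shape = (400, 400)
        per_level = [len(generate_patch_groups(shape, lv)) for lv in DEFAULT_LEVELS]
        assert per_level == [13, 13, 13]
        assert sum(per_level) == 39

    def test_12_shifted_groups_per_level(self):
        groups = generate_patch_groups((400, 400), LevelConfig(100))
        shifted = [g for g in groups if g.group_id != 0]
        assert len(shifted) == 12
        assert groups[0].offset == (0, 0)

    def test_4_groups_per_direction(self):
        groups = generate_patch_groups((400, 400), LevelConfig(100))
        xs = [g for g in groups if g.offset[0] == 0 and g.offset[1] != 0]
        ys = [g for g in groups if g.offset[1] == 0 and g.offset[0] != 0]
        diag = [g for g in groups if g.offset[0] == g.offset[1] != 0]
        assert len(xs) == len(ys) == len(diag) == 4
        assert sorted(g.offset[1] for g in xs) == [20, 40, 60, 80]

    @pytest.mark.parametrize("shape", [(400, 400), (417, 383), (100, 150)])
    def test_every_pixel_covered_exactly_once_per_group(self, shape):
        for group in generate_patch_groups(shape, LevelConfig(100)):
            cover = np.zeros(shape, dtype=int)
            s = group.level.S
            for ref in group.refs():
                r, c = ref.origin
                cover[max(r, 0) : r + s, max(c, 0) : c + s] += 1
            assert (cover == 1).all(), f"group {group.group_id} coverage broken"

    def test_vote_count_13_per_level_39_total(self):
        shape = (200, 230)
        votes = np.zeros(shape, dtype=int)
        for lv in DEFAULT_LEVELS:
            level_votes = np.zeros(shape, dtype=int)
            for group in generate_patch_groups(shape, lv):
                painted = paint_group_labels(group, [1] * len(group))
                level_votes += painted
            assert (level_votes == 13).all()
            votes += level_votes
        assert (votes == 39).all()

    def test_too_small_slide_rejected(self):
        with pytest.raises(ValueError, match="smaller"):
            generate_patch_groups((80, 400), LevelConfig(100))

    def test_group_ids_0_to_12(self):
        groups = generate_patch_groups((400, 400), LevelConfig(50))
        assert [g.group_id for g in groups] == list(range(13))


class TestBackgroundRatio:
    def test_all_background(self):
        assert background_ratio(np.zeros((10, 10), np.uint8)) == 1.0

    def test_all_tissue(self):
        assert background_ratio(np.full((10, 10), 3, np.uint8)) == 0.0

    def test_half_and_half_passes_boundary(self):
        win = np.zeros((100, 100), np.uint8)
        win[:50] = 2
        assert background_ratio(win) == 0.5  # BR <= 0.5 is selected

    def test_boolean_mask_input(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[:1] = True  # 4 tissue pixels
        assert background_ratio(mask) == 0.75


class TestModalLabel:
    def test_brute_force_oracle(self, rng):
        for _ in range(50):
            win = rng.integers(0, 6, size=(9, 9)).astype(np.uint8)
            got, tie = modal_tissue_label(win)
            # independent recount
            vals, counts = np.unique(win[win != 0], return_counts=True)
            if len(vals) == 0:
                assert got is None
            else:
                best = counts.max()
                winners = sorted(int(v) for v, c in zip(vals, counts) if c == best)
                assert got == winners[0]
                assert tie == (len(winners) > 1)

    def test_no_tissue(self):
        assert modal_tissue_label(np.zeros((5, 5), np.uint8)) == (None, False)


def _slide_with_labels(lm: np.ndarray) -> SlideImage:
    rgb = np.full((*lm.shape, 3), 250, np.uint8)
    rgb[lm != 0] = 100
    return SlideImage(rgb=rgb, label_map=lm)


class TestSelectTrainingPatches:
    def test_homogeneous_patch_selected(self):
        lm = np.full((100, 100), 3, np.uint8)
        got = select_training_patches(_slide_with_labels(lm), LevelConfig(50))
        assert len(got) == 4
        assert all(label == 3 for _, label in got)

    def test_mostly_background_removed(self):
        lm = np.zeros((50, 50), np.uint8)
        lm[:20] = 2  # 40% tissue -> BR 0.6 > 0.5
        got = select_training_patches(_slide_with_labels(lm), LevelConfig(50))
        assert got == []

    def test_modal_vs_center_mismatch_removed(self):
        # modal label 4 but the center pixel is 3
        lm = np.full((50, 50), 4, np.uint8)
        lm[20:30, 20:30] = 3
        rec = selection_records(_slide_with_labels(lm), LevelConfig(50))[0]
        assert rec.mv == 4 and rec.pc == 3 and not rec.selected

    def test_tie_removed(self):
        lm = np.zeros((50, 50), np.uint8)
        lm[:, :25] = 2
        lm[:, 25:] = 3
        rec = selection_records(_slide_with_labels(lm), LevelConfig(50))[0]
        assert rec.tie and not rec.selected

    def test_br_boundary_inclusive(self):
        lm = np.zeros((50, 50), np.uint8)
        lm[:25] = 3
        lm[24:26, :] = 3  # ensure center pixel is tissue
        rec = selection_records(_slide_with_labels(lm), LevelConfig(50))[0]
        assert rec.br <= 0.5 and rec.selected

    def test_missing_label_map_rejected(self):
        slide = SlideImage(rgb=np.zeros((60, 60, 3), np.uint8))
        with pytest.raises(ValueError, match="label map"):
            select_training_patches(slide, LevelConfig(50))

    def test_selection_soundness_brute_force(self, small_slide):
        lm = small_slide.label_map
        level = LevelConfig(50)
        for rec in selection_records(small_slide, level):
            win = extract_window(lm, rec.ref.origin, 50, 0)
            br = float((win == 0).mean())
            vals, counts = np.unique(win[win != 0], return_counts=True)
            if len(vals) == 0:
                assert not rec.selected
                continue
            best = counts.max()
            winners = [int(v) for v, c in zip(vals, counts) if c == best]
            r, c = rec.ref.origin[0] + 25, rec.ref.origin[1] + 25
            pc = int(lm[r, c]) if 0 <= r < lm.shape[0] and 0 <= c < lm.shape[1] else 0
            should = len(winners) == 1 and winners[0] == pc and br <= 0.5
            assert rec.selected == should


class TestExtractWindow:
    def test_padding_fill(self):
        arr = np.arange(16, dtype=np.uint8).reshape(4, 4)
        win = extract_window(arr, (-2, -2), 4, fill=9)
        assert (win[:2] == 9).all() and (win[:, :2] == 9).all()
        assert win[2, 2] == arr[0, 0]

    def test_interior_window_exact(self):
        arr = np.arange(100).reshape(10, 10)
        np.testing.assert_array_equal(extract_window(arr, (2, 3), 4, 0), arr[2:6, 3:7])


class TestPaintGroupLabels:
    def test_wrong_label_count_rejected(self):
        group = generate_patch_groups((100, 100), LevelConfig(50))[0]
        with pytest.raises(ValueError, match="labels"):
            paint_group_labels(group, [1])


class TestManifest:
    def test_csv_rows_match_patch_count(self, tmp_path):
        import pandas as pd

        from pygleason.tiling import write_patch_manifest

        groups = generate_patch_groups((100, 100), LevelConfig(50))
        path = tmp_path / "manifest.csv"
        write_patch_manifest(groups, path)
        df = pd.read_csv(path)
        assert len(df) == sum(len(g) for g in groups)
        assert set(df.columns) == {"level", "group_id", "row", "col", "size"}
        assert sorted(df["group_id"].unique()) == list(range(13))
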