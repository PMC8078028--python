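"""AOI classification, search-time metrics, summaries, ellipse rendering."""

import numpy as np
import pandas as pd
import pytest

from smtgaze.boards import detect_distractor_patterns
from smtgaze.fixations import extract_fixations
from smtgaze.metrics import (
    BoardMetrics,
    classify_fixation,
    effective_search_time,
    fixation_ellipse,
    game_completion_time,
    summarize_by_set_size,
    summarize_subject,
    visual_search_time,
)
from smtgaze.streams import MouseStream

from test_fixations import make_stream, steady_stream


def fixation_at(xy, t0=0.0):
    return extract_fixations(steady_stream(20, xy=xy, t0=t0))[0]


@pytest.fixture
def labeled_setup(board_5x5):
    board, target = board_5x5
    distractors = detect_distractor_patterns(board, target)
    return board, target, distractors


class TestClassifyFixation:
    def test_centroid_inside_target_tile(self, labeled_setup):
        board, target, distractors = labeled_setup
        cell = sorted(target.aoi_cells)[0]
        lf = classify_fixation(
            fixation_at(board.layout.cell_center(cell)), board, target, distractors
        )
        assert lf.target_hits == 1
        assert lf.distractor_hits == 0
        assert not lf.other

    def test_edge_between_two_target_tiles_counts_twice(self, labeled_setup):
        board, target, distractors = labeled_setup
        aoi = sorted(target.aoi_cells)
        pairs = [
            (a, b)
            for a in aoi
            for b in aoi
            if abs(a[0] - b[0]) + abs(a[1] - b[1]) == 1 and a < b
        ]
        a, b = pairs[0]
        ax, ay = board.layout.cell_center(a)
        bx, by = board.layout.cell_center(b)
        edge_point = ((ax + bx) / 2.0, (ay + by) / 2.0)
        lf = classify_fixation(fixation_at(edge_point), board, target, distractors)
        assert lf.target_hits == 2

    def test_centroid_on_distractor_tile(self, labeled_setup):
        board, target, distractors = labeled_setup
        cell = next(
            c for d in distractors for c in d.cells if c not in target.aoi_cells
        )
        lf = classify_fixation(
            fixation_at(board.layout.cell_center(cell)), board, target, distractors
        )
        assert lf.distractor_hits == 1
        assert lf.target_hits == 0

    def test_off_board_centroid_warns_and_labels_other(self, labeled_setup):
        board, target, distractors = labeled_setup
        with pytest.warns(UserWarning):
            lf = classify_fixation(fixation_at((5.0, 5.0)), board, target, distractors)
        assert lf.other


class TestVisualSearchTime:
    def _label(self, fix, target_hits=0, distractor_hits=0):
        from smtgaze.metrics import AOILabeledFixation

        return AOILabeledFixation(fix, target_hits, distractor_hits, False)

    def test_first_target_fixation(self):
        labeled = [
            self._label(fixation_at((100, 100), t0=1.0), distractor_hits=1),
            self._label(fixation_at((300, 300), t0=5.2), target_hits=1),
        ]
        assert visual_search_time(0.0, labeled) == pytest.approx(5.2)

    def test_missing_when_no_target_fixation(self):
        labeled = [self._label(fixation_at((100, 100)), distractor_hits=1)]
        assert visual_search_time(0.0, labeled) is None

    def test_earliest_target_wins_regardless_of_position(self):
        labeled = [
            self._label(fixation_at((1, 1), t0=0.5), target_hits=1),
            self._label(fixation_at((2, 2), t0=2.0), distractor_hits=1),
            self._label(fixation_at((3, 3), t0=4.0), target_hits=2),
        ]
        assert visual_search_time(0.0, labeled) == pytest.approx(0.5)


class TestEffectiveSearchTime:
    def test_stationary_mouse(self):
        n = 120
        ts = np.arange(n) / 120
        mouse = MouseStream(ts, np.full(n, 10.0), np.full(n, 20.0), np.zeros(n, bool))
        assert effective_search_time(mouse) == 0.0

    def test_continuous_motion_duration(self):
        # exactly 3.0 s of 5 px/sample motion followed by stillness
        n_move, n_still = 360, 120
        n = n_move + n_still
        ts = np.arange(n) / 120
        x = np.concatenate([np.arange(n_move) * 5.0, np.full(n_still, (n_move - 1) * 5.0)])
        mouse = MouseStream(ts, x, np.zeros(n), np.zeros(n, bool))
        assert abs(effective_search_time(mouse) - 3.0) <= 1 / 120

    def test_empty_stream_warns(self):
        with pytest.warns(UserWarning):
            assert effective_search_time(MouseStream.empty()) == 0.0

    def test_motion_after_drag_release_ignored(self):
        n = 240
        ts = np.arange(n) / 120
        x = np.arange(n) * 5.0
        clicked = np.zeros(n, bool)
        clicked[60:120] = True  # drag release at sample 119
        mouse = MouseStream(ts, x, np.zeros(n), clicked)
        assert effective_search_time(mouse) == pytest.approx(119 / 120)


class TestAggregation:
    def _bm(self, w=5, h=5, vst=None, est=0.0, bct=10.0, nf=0, nft=0, nfd=0):
        return BoardMetrics(
            width=w, height=h, visual_search_time=vst, effective_search_time=est,
            board_completion_time=bct, n_fixations=nf, n_fix_target=nft,
            n_fix_distractor=nfd,
        )

    def test_game_completion_time_sums_boards(self):
        bms = [self._bm(bct=10.0), self._bm(bct=20.0), self._bm(bct=30.0)]
        assert game_completion_time(bms) == 60.0
        assert game_completion_time([]) == 0.0

    def test_vst_cannot_exceed_completion_time(self):
        with pytest.raises(ValueError):
            self._bm(vst=11.0, bct=10.0)

    def test_single_board_sd_reported_as_zero(self):
        row = summarize_subject("s", [self._bm(vst=2.0, nf=1, nft=1)])
        assert row["fixations_mean"] == 1.0
        assert row["fixations_sd"] == 0.0
        assert row["visual_search_time_mean"] == 2.0
        assert row["visual_search_time_sd"] == 0.0

    def test_missing_vst_propagates(self):
        row = summarize_subject("s", [self._bm(vst=None), self._bm(vst=None)])
        assert np.isnan(row["visual_search_time_mean"])
        assert row["fixations_targets_mean"] == 0.0

    def test_totals_match_brute_force_recount(self, tiny_plan):
        from smtgaze.pipeline import process_session
        from smtgaze.simulate import SubjectProfile, simulate_subject

        session = simulate_subject(
            SubjectProfile("s", exec_slowness=0.4, seed=21), tiny_plan
        )
        results = process_session(session)
        row = summarize_subject("s", [r.metrics for r in results])
        all_labeled = [lf for r in results for lf in r.labeled]
        n_boards = len(results)
        assert row["fixations_mean"] * n_boards == pytest.approx(len(all_labeled))
        assert row["fixations_targets_mean"] * n_boards == pytest.approx(
            sum(lf.target_hits for lf in all_labeled)
        )
        assert row["fixations_distractors_mean"] * n_boards == pytest.approx(
            sum(lf.distractor_hits for lf in all_labeled)
        )
        # fixation count dominates each AOI category but can exceed their
        # sum (fixations on other tiles; edge double counts)
        assert row["fixations_mean"] >= max(
            row["fixations_targets_mean"], row["fixations_distractors_mean"]
        )

    def test_set_size_group_means(self):
        bms = [
            self._bm(w=4, h=5, vst=6.0),
            self._bm(w=4, h=5, vst=8.0),
            self._bm(w=6, h=6, vst=None),
        ]
        table = summarize_by_set_size(bms).set_index("set_size")
        assert table.loc["4x5", "visual_search_time_mean"] == pytest.approx(7.0)
        assert np.isnan(table.loc["6x6", "visual_search_time_mean"])

    def test_set_size_group_of_one_equals_board(self):
        bm = self._bm(w=7, h=4, vst=3.5, est=1.5, nf=4, nfd=2, nft=1)
        table = summarize_by_set_size([bm]).set_index("set_size")
        assert table.loc["7x4", "visual_search_time_mean"] == 3.5
        assert table.loc["7x4", "fixations_mean"] == 4.0
        assert table.loc["7x4", "fixations_sd"] == 0.0

    def test_set_size_matches_pandas_groupby(self):
        rng = np.random.default_rng(5)
        bms = [
            self._bm(
                w=int(rng.integers(4, 7)), h=int(rng.integers(4, 7)),
                vst=float(rng.uniform(1, 10)), est=float(rng.uniform(1, 10)),
                nf=int(rng.integers(0, 9)),
            )
            for _ in range(40)
        ]
        table = summarize_by_set_size(bms).set_index("set_size")
        df = pd.DataFrame(
            {
                "set_size": [f"{b.width}x{b.height}" for b in bms],
                "fixations": [b.n_fixations for b in bms],
            }
        )
        expected = df.groupby("set_size")["fixations"].mean()
        for label, val in expected.items():
            assert table.loc[label, "fixations_mean"] == pytest.approx(val)


class TestFixationEllipse:
    def test_degenerate_point_cloud(self):
        ell = fixation_ellipse(fixation_at((400.0, 300.0)))
        assert ell.center == (400.0, 300.0)
        assert ell.width == 0.0 and ell.height == 0.0
        assert 0 < ell.alpha <= 1

    def test_horizontal_segment(self):
        n = 20
        ts = np.arange(n) / 120
        pts = np.tile((0.0, 50.0), (n, 1))
        pts[:, 0] = np.tile([100.0, 140.0], n // 2)
        fix = extract_fixations(make_stream(ts, pts))[0]
        ell = fixation_ellipse(fix)
        assert ell.height == 0.0
        assert ell.width == pytest.approx(2 * np.std(pts[:, 0]))

    def test_random_cloud_matches_brute_force(self):
        rng = np.random.default_rng(6)
        n = 30
        ts = np.arange(n) / 120
        pts = rng.normal((600, 500), 8, size=(n, 2))
        fix = extract_fixations(make_stream(ts, pts))[0]
        ell = fixation_ellipse(fix)
        assert ell.width == pytest.approx(2 * pts[:, 0].std())
        assert ell.height == pytest.approx(2 * pts[:, 1].std())

    def test_alpha_monotone_in_duration(self):
        short = fixation_ellipse(fixation_at((1, 1)))
        long_ = fixation_ellipse(extract_fixations(steady_stream(55, xy=(1.0, 1.0)))[0])
        assert long_.alpha >= short.alpha
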