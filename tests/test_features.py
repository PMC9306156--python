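"""Windowing arithmetic, TD feature definitions, matrix assembly and the
stratified split."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import myogrid as mg
from myogrid.core import TaskLabel, Segment
from myogrid.features import (FEATURE_NAMES, FeatureRef, extract_windows,
                              features_from_windows, td_features, window_count)

FS = 2048.0


class TestExtractWindows:
    def test_4s_segment_gives_31_windows(self):
        wins = extract_windows(np.zeros((2, 8192)), FS)
        assert wins.shape == (31, 2, 512)  # floor((8192-512)/256)+1

    def test_exactly_one_window(self):
        wins = extract_windows(np.zeros((1, 512)), FS)
        assert wins.shape[0] == 1

    def test_consecutive_windows_share_half(self):
        x = np.arange(1024, dtype=float)[None, :]
        wins = extract_windows(x, FS)
        assert np.array_equal(wins[0, 0, 256:], wins[1, 0, :256])

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="shorter"):
            extract_windows(np.zeros((1, 100)), FS)

    @given(st.integers(512, 60000), st.integers(16, 1024), st.integers(8, 512))
    @settings(max_examples=100, deadline=None)
    def test_window_count_formula(self, L, W, H):
        n = window_count(L, W, H) if L >= W else None
        if n is not None:
            assert n == (L - W) // H + 1
            assert (n - 1) * H + W <= L
            assert n * H + W > L  # one more window would not fit


class TestTdFeatures:
    def test_alternating_signal_hand_computed(self):
        f = td_features([1.0, -1.0, 1.0, -1.0], eps=0.0)
        mav, zc, ssc, wl, logvar = f
        assert mav == 1.0
        assert wl == 6.0
        assert zc == 3
        assert logvar == pytest.approx(np.log(1.0), abs=1e-9)

    def test_constant_window(self):
        f = td_features([2.5] * 10, eps=0.0)
        mav, zc, ssc, wl, logvar = f
        assert mav == 2.5
        assert wl == 0.0 and zc == 0 and ssc == 0
        assert logvar == pytest.approx(np.log(1e-12))

    def test_scaling_homogeneity(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(512)
        k = 7.5
        f1 = td_features(x, eps=0.0)
        f2 = td_features(k * x, eps=0.0)
        assert f2[0] == pytest.approx(k * f1[0])  # MAV
        assert f2[3] == pytest.approx(k * f1[3])  # WL
        assert f2[1] == f1[1] and f2[2] == f1[2]  # ZC, SSC unchanged
        assert f2[4] - f1[4] == pytest.approx(2 * np.log(k), abs=1e-6)  # LogVar

    def test_deadband_suppresses_noise_crossings(self):
        t = np.arange(512) / FS
        x = np.sin(2 * np.pi * 50 * t) + 1e-4 * np.random.default_rng(1).standard_normal(512)
        dense = td_features(x, eps=0.0)
        banded = td_features(x)  # default 1% RMS deadband
        assert banded[2] <= dense[2]  # SSC drops micro-wiggles
        assert banded[1] <= dense[1]

    def test_ssc_counts_turning_points(self):
        f = td_features([0.0, 1.0, 0.0, 1.0, 0.0], eps=0.0)
        assert f[2] == 3  # three interior slope reversals


def _toy_segments(layout, n=1536):  # 0.75 s -> 5 windows per segment
    rng = np.random.default_rng(3)
    segs = []
    for g in ("PG", "OP"):
        for w in ("neutral", "pronation"):
            for lev in ("low", "moderate"):
                sig = rng.standard_normal((layout.n_channels, n))
                segs.append(Segment(sig, FS, TaskLabel(g, w, lev), layout,
                                    0, n, f"{g}_{w}_{lev}"))
    return segs


class TestBuildFeatureMatrix:
    lay = mg.build_layout(2, 2, 2)  # 8 channels

    def test_column_count_channels_times_5(self):
        fm = mg.build_feature_matrix(_toy_segments(self.lay), self.lay)
        assert fm.X.shape[1] == 8 * 5
        assert [c.name for c in fm.columns[:5]] == list(FEATURE_NAMES)

    def test_corrupted_channels_excluded(self):
        lay = mg.build_layout(2, 2, 2, corrupted={1, 5})
        fm = mg.build_feature_matrix(_toy_segments(lay), lay)
        assert fm.X.shape[1] == (8 - 2) * 5
        assert not {1, 5} & set(fm.channels)

    def test_combined_mode_merges_wrists_and_levels(self):
        fm = mg.build_feature_matrix(_toy_segments(self.lay), self.lay)
        assert set(fm.y) == {"PG", "OP"}

    def test_single_wrist_mode_filters(self):
        fm = mg.build_feature_matrix(_toy_segments(self.lay), self.lay,
                                     mode="pronation")
        assert set(fm.meta["wrist"]) == {"pronation"}
        with pytest.raises(ValueError, match="supination"):
            mg.build_feature_matrix(_toy_segments(self.lay), self.lay,
                                    mode="supination")

    def test_extraction_commutes_with_channel_subselection(self):
        segs = _toy_segments(self.lay)
        fm_all = mg.build_feature_matrix(segs, self.lay)
        cs = mg.ChannelSet((2, 6), "SFS")
        a = fm_all.select_channels(cs)
        segs_sub = [Segment(s.signal, s.fs, s.label, self.lay, s.start_sample,
                            s.end_sample, s.task_id) for s in segs]
        # selecting channels after extraction == extracting those channels
        wins = extract_windows(segs[0].signal[[2, 6]], FS)
        direct = features_from_windows(wins, None).reshape(wins.shape[0], -1)
        assert np.allclose(a.X[:wins.shape[0]], direct)

    def test_csv_roundtrip(self, tmp_path):
        fm = mg.build_feature_matrix(_toy_segments(self.lay), self.lay)
        fm.to_csv(tmp_path / "X.csv", tmp_path / "y.csv")
        back = mg.FeatureMatrix.from_csv(tmp_path / "X.csv", tmp_path / "y.csv")
        assert np.allclose(fm.X, back.X)
        assert list(fm.y) == list(back.y)
        assert [str(c) for c in fm.columns] == [str(c) for c in back.columns]


class TestStratifiedSplit:
    lay = mg.build_layout(2, 2, 2)

    def test_70_30_proportions_per_stratum(self):
        fm = mg.build_feature_matrix(_toy_segments(self.lay), self.lay)
        tr, te = mg.stratified_split(fm, 0.70, 0)
        assert tr.n_windows + te.n_windows == fm.n_windows
        for g in ("PG", "OP"):
            n_tr, n_all = np.sum(tr.y == g), np.sum(fm.y == g)
            assert n_tr / n_all == pytest.approx(0.70, abs=0.05)

    def test_same_seed_identical_different_seed_differs(self):
        fm = mg.build_feature_matrix(_toy_segments(self.lay), self.lay)
        a1, _ = mg.stratified_split(fm, 0.70, 11)
        a2, _ = mg.stratified_split(fm, 0.70, 11)
        b, _ = mg.stratified_split(fm, 0.70, 12)
        assert np.array_equal(a1.X, a2.X)
        assert not np.array_equal(a1.X, b.X)

    def test_disjoint_and_exhaustive(self):
        fm = mg.build_feature_matrix(_toy_segments(self.lay), self.lay)
        fm.meta["row"] = np.arange(fm.n_windows)
        tr, te = mg.stratified_split(fm, 0.70, 1)
        rows = np.concatenate([tr.meta["row"], te.meta["row"]])
        assert sorted(rows) == list(range(fm.n_windows))

    def test_singleton_stratum_rejected(self):
        fm = mg.build_feature_matrix(_toy_segments(self.lay)[:1], self.lay)
        solo = fm.subset_rows(np.arange(fm.n_windows) == 0)
        two = fm.subset_rows(np.arange(fm.n_windows) < 2)
        # craft a matrix with a singleton (gesture, wrist, level) stratum
        import pandas as pd
        bad = mg.FeatureMatrix(
            np.vstack([two.X, solo.X]),
            fm.columns,
            np.concatenate([two.y, ["HO"]]),
            pd.concat([two.meta, solo.meta]).reset_index(drop=True),
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            mg.stratified_split(bad, 0.70, 0)
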