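"""Trial-window extraction, seed signal, RT/FA tables, outlier exclusion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import seedpls as sp
from seedpls.datamat import VolumeSeries


def _one_voxel(ts, tr=3.0):
    data = np.zeros((1, 1, 1, len(ts)))
    data[0, 0, 0, :] = ts
    return VolumeSeries(data, np.eye(4), tr)


def _events(onsets, condition="AC", accuracy=1, rt=1000.0):
    return pd.DataFrame({
        "onset": list(onsets), "duration": 3.0,
        "condition": condition, "accuracy": accuracy, "rt": rt})


MASK1 = np.ones((1, 1, 1), bool)


class TestExtractTrialWindows:
    def test_ramp_percent_signal_change(self):
        """Series 100,101,...,105 from the onset scan gives lags 0..5 %."""
        vs = _one_voxel([100, 101, 102, 103, 104, 105])
        win = sp.extract_trial_windows({"s1": vs}, {"s1": _events([0.0])},
                                       MASK1, np.eye(4), 6, ["AC"])
        assert np.allclose(win.values[0, 0, :, 0], [0, 1, 2, 3, 4, 5])

    def test_constant_series_is_zero(self):
        vs = _one_voxel([100.0] * 8)
        win = sp.extract_trial_windows({"s1": vs}, {"s1": _events([0.0, 3.0])},
                                       MASK1, np.eye(4), 6, ["AC"])
        assert np.allclose(win.values, 0.0)

    @settings(deadline=None, max_examples=25)
    @given(scale=st.floats(0.1, 50.0))
    def test_scale_invariance(self, scale):
        """Percent signal change is invariant to global BOLD scaling."""
        ts = np.array([100, 103, 98, 110, 101, 99.0, 102, 97])
        a = sp.extract_trial_windows({"s": _one_voxel(ts)},
                                     {"s": _events([0.0])},
                                     MASK1, np.eye(4), 6, ["AC"])
        b = sp.extract_trial_windows({"s": _one_voxel(ts * scale)},
                                     {"s": _events([0.0])},
                                     MASK1, np.eye(4), 6, ["AC"])
        assert np.allclose(a.values, b.values, atol=1e-9)

    def test_trial_order_invariance(self):
        ts = np.r_[100 + np.arange(8), 100 + np.arange(8)[::-1], [100.0] * 8]
        ev1 = _events([0.0, 21.0])
        ev2 = _events([21.0, 0.0])
        a = sp.extract_trial_windows({"s": _one_voxel(ts)}, {"s": ev1},
                                     MASK1, np.eye(4), 6, ["AC"])
        b = sp.extract_trial_windows({"s": _one_voxel(ts)}, {"s": ev2},
                                     MASK1, np.eye(4), 6, ["AC"])
        assert np.allclose(a.values, b.values)

    def test_onset_jitter_maps_to_preceding_scan(self):
        """Onset 1.4 s into scan 0 still references scan 0 (3-s TR)."""
        vs = _one_voxel([100, 101, 102, 103, 104, 105])
        win = sp.extract_trial_windows({"s": vs}, {"s": _events([1.4])},
                                       MASK1, np.eye(4), 6, ["AC"])
        assert np.allclose(win.values[0, 0, :, 0], [0, 1, 2, 3, 4, 5])

    def test_window_overrun_names_trial(self):
        vs = _one_voxel([100.0] * 6)
        with pytest.raises(ValueError, match="condition 'AC'"):
            sp.extract_trial_windows({"s": vs}, {"s": _events([3.0])},
                                     MASK1, np.eye(4), 6, ["AC"])

    def test_missing_condition(self):
        vs = _one_voxel([100.0] * 8)
        with pytest.raises(ValueError, match="absent"):
            sp.extract_trial_windows({"s": vs}, {"s": _events([0.0])},
                                     MASK1, np.eye(4), 6, ["AC", "HC"])

    def test_nonpositive_reference(self):
        vs = _one_voxel([0.0, 1, 2, 3, 4, 5])
        with pytest.raises(ValueError, match="reference"):
            sp.extract_trial_windows({"s": vs}, {"s": _events([0.0])},
                                     MASK1, np.eye(4), 6, ["AC"])


class TestSeedSignal:
    def _uniform_windows(self, value=1.0):
        mask = np.ones((5, 5, 5), bool)
        values = np.full((2, 1, 6, 125), value)
        from seedpls.datamat import TrialWindowMatrix
        return TrialWindowMatrix(values, ["a", "b"], ["AC"], 6, mask,
                                 np.eye(4), np.arange(125))

    def test_constant_datamat_gives_constant_seed(self):
        win = self._uniform_windows(1.0)
        seed_mean, seed_vox = sp.extract_seed_signal(win, seed_ijk=(2, 2, 2))
        assert np.allclose(seed_mean.to_numpy(), 1.0)
        assert seed_vox.size == 27    # full 26-neighbourhood cube in-mask

    def test_mni_resolution(self):
        win = self._uniform_windows()
        aff = np.diag([2.0, 2.0, 2.0, 1.0])
        aff[:3, 3] = -4.0
        win.affine = aff
        _, seed_vox = sp.extract_seed_signal(win, seed_mni=(0.0, 0.0, 0.0))
        centre_flat = np.ravel_multi_index((2, 2, 2), (5, 5, 5))
        assert centre_flat in seed_vox

    def test_seed_outside_mask_reports_both_coordinates(self):
        win = self._uniform_windows()
        win.mask = win.mask.copy()
        win.mask[0, 0, 0] = False
        with pytest.raises(ValueError, match="MNI"):
            sp.extract_seed_signal(win, seed_ijk=(0, 0, 0))


class TestConditionRT:
    def test_mean_of_accurate_trials_only(self):
        ev = pd.DataFrame({"onset": [0, 9, 18.0], "duration": 3.0,
                           "condition": "AC",
                           "accuracy": [1, 1, 0],
                           "rt": [1000.0, 2000.0, 1500.0]})
        rt, flags = sp.compute_condition_rt({"s": ev}, ["AC"])
        assert rt.loc["s", "AC"] == 1500.0
        assert flags == []

    def test_all_inaccurate_flags_cell(self):
        ev = pd.DataFrame({"onset": [0.0], "duration": 3.0,
                           "condition": "AC", "accuracy": [0],
                           "rt": [np.nan]})
        rt, flags = sp.compute_condition_rt({"s": ev}, ["AC"])
        assert np.isnan(rt.loc["s", "AC"])
        assert flags[0]["subject"] == "s"

    def test_simulated_rt_ceiling(self, planted_dataset):
        rt, _ = sp.compute_condition_rt(planted_dataset.events,
                                        planted_dataset.truth.conditions)
        assert (rt.to_numpy() <= 3000).all()


def _block(values, variables=("seed",), conditions=("AC",)):
    from seedpls.datamat import VariableBlock
    values = np.asarray(values, float)
    return VariableBlock(values, [f"s{i}" for i in range(values.shape[0])],
                         list(conditions), tuple(variables))


class TestExcludeOutliers:
    def test_small_n_extreme_value_is_not_an_outlier(self):
        """(0, 0, 0, 100): with n = 4 the max sample |z| is 1.5 < 3."""
        block = _block(np.array([0, 0, 0, 100.0]).reshape(4, 1, 1))
        out, removed = sp.exclude_outliers(block, 3.0)
        assert removed == []
        assert len(out.subjects) == 4

    def test_zero_variance_warns_not_removes(self):
        block = _block(np.ones((5, 1, 1)))
        with pytest.warns(UserWarning, match="zero-variance"):
            out, removed = sp.exclude_outliers(block)
        assert removed == []

    def test_clear_outlier_removed_with_trigger(self):
        vals = np.zeros((30, 1, 2))
        vals[:, 0, 0] = np.linspace(-1, 1, 30)
        vals[:, 0, 1] = np.linspace(-1, 1, 30)
        vals[7, 0, 1] = 50.0
        block = _block(vals, variables=("seed", "rt"))
        out, removed = sp.exclude_outliers(block, 3.0)
        assert [r["subject"] for r in removed] == ["s7"]
        assert removed[0]["variable"] == "rt"
        assert abs(removed[0]["z"]) > 3

    def test_removal_below_three_subjects_errors(self):
        vals = np.zeros((4, 1, 1))
        vals[:, 0, 0] = [0, 0.1, 50, -50]
        # force two removals from n=4 via a permissive threshold
        with pytest.raises(ValueError, match="< 3"):
            sp.exclude_outliers(_block(vals), z_threshold=1.0)


class TestAssembleVariableBlock:
    def _tables(self, subjects=("s1", "s2", "s3")):
        conds = ["AC", "AI"]
        seed = pd.DataFrame(np.ones((len(subjects), 2)),
                            index=list(subjects), columns=conds)
        fa = pd.DataFrame({"fa": [0.5] * len(subjects)},
                          index=list(subjects))
        fa.index.name = "subject_id"
        rt = pd.DataFrame(np.full((len(subjects), 2), 1500.0),
                          index=list(subjects), columns=conds)
        return seed, fa, rt

    def test_join_and_fa_replication(self):
        seed, fa, rt = self._tables()
        block = sp.assemble_variable_block(seed, fa, rt,
                                           ("seed", "fa", "rt"))
        assert block.values.shape == (3, 2, 3)
        # FA is condition-invariant: identical in every condition row
        assert np.allclose(block.values[:, 0, 1], block.values[:, 1, 1])

    def test_missing_fa_drops_subject_listwise(self):
        seed, fa, rt = self._tables()
        fa.loc["s2", "fa"] = np.nan
        block = sp.assemble_variable_block(seed, fa, rt, ("seed", "fa", "rt"))
        assert block.subjects == ["s1", "s3"]
        assert block.dropped_subjects[0]["reason"] == "missing FA"

    def test_missing_rt_cell_drops_subject(self):
        seed, fa, rt = self._tables()
        rt.loc["s3", "AI"] = np.nan
        block = sp.assemble_variable_block(seed, fa, rt, ("seed", "fa", "rt"))
        assert "s3" not in block.subjects

    def test_empty_join_errors(self):
        seed, fa, rt = self._tables()
        fa.index = ["x1", "x2", "x3"]
        with pytest.raises(ValueError, match="empty join"):
            sp.assemble_variable_block(seed, fa, rt, ("seed", "fa", "rt"))

    def test_single_subject_identity(self):
        seed, fa, rt = self._tables(subjects=("s1",))
        block = sp.assemble_variable_block(seed, fa, rt, ("seed", "fa", "rt"))
        assert block.values.shape == (1, 2, 3)


def test_disk_round_trip_reproduces_datamat(tmp_path, truth_small):
    """Writing then ingesting a dataset reproduces the in-memory datamat."""
    ds = sp.simulate_dataset(truth_small, 3, 2, seed=31)
    sp.write_dataset(ds, tmp_path)
    from seedpls.workflow import load_dataset_dir
    bold, events, fa, mask, affine, truth = load_dataset_dir(tmp_path)
    win_disk = sp.extract_trial_windows(bold, events, mask, affine, 6,
                                        truth.conditions)
    win_mem = sp.datamat_from_dataset(ds)
    assert np.allclose(win_disk.values, win_mem.values, atol=1e-6)
    assert win_disk.subjects == win_mem.subjects
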