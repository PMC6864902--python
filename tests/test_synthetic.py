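"""Generator contract: planted structure, determinism, task-design realism."""

import json

import numpy as np
import pytest
from scipy import ndimage

import seedpls as sp
from seedpls import synthetic as syn


class TestGroundTruth:
    def test_planted_support_and_unit_norm(self):
        truth = sp.make_ground_truth(n_active_voxels=60, seed=1)
        assert truth.active_voxel_set.size == 60
        assert np.isclose(np.linalg.norm(truth.voxel_salience_true), 1.0)
        # support is exactly the nonzero set of the spatial map
        assert np.array_equal(np.flatnonzero(truth.spatial_map),
                              truth.active_voxel_set)

    def test_support_is_two_contiguous_signed_blobs(self):
        truth = sp.make_ground_truth(seed=1)
        vol = np.zeros(truth.grid_shape)
        vol[truth.mask] = truth.spatial_map
        structure = np.ones((3, 3, 3))
        for sign in (1, -1):
            labels, n = ndimage.label(vol == sign, structure=structure)
            assert n == 1, f"{sign}-pole blob is not contiguous"

    def test_determinism(self):
        a = sp.make_ground_truth(seed=7)
        b = sp.make_ground_truth(seed=7)
        assert np.array_equal(a.voxel_salience_true, b.voxel_salience_true)
        assert np.array_equal(a.variable_salience_true,
                              b.variable_salience_true)
        assert a.seed_center_ijk == b.seed_center_ijk

    def test_too_many_active_voxels(self):
        with pytest.raises(ValueError, match="exceeds"):
            sp.make_ground_truth(grid_shape=(6, 6, 6), n_active_voxels=10_000)

    def test_null_regime(self):
        truth = sp.make_ground_truth(coupling_strength=0.0)
        assert truth.is_null
        assert not sp.make_ground_truth(coupling_strength=0.8).is_null

    def test_seed_region_disjoint_from_support(self):
        truth = sp.make_ground_truth(seed=2)
        seed_vox = syn._seed_cube_indices(truth.mask, truth.seed_center_ijk)
        assert not set(seed_vox.tolist()) & set(truth.active_voxel_set.tolist())


class TestLagProfile:
    def test_shape_and_anchor(self):
        prof = sp.lag_response_profile(6)
        assert prof.shape == (6,)
        assert prof[0] == 0.0          # causal HRF: no response at onset
        assert np.isclose(prof.max(), 1.0)
        assert int(np.argmax(prof)) == 2   # peak ~6 s with a 3-s TR

    def test_window_span(self):
        # 6 lags at a 3-s repetition time span 18 s post-onset
        assert 6 * syn.TR_S == 18.0


class TestSimulatedDataset:
    def test_design_invariants(self, planted_dataset):
        ds = planted_dataset
        for sub in ds.subjects:
            ev = ds.events[sub]
            scans = ds.bold[sub].shape[-1]
            onset_scan = np.floor(ev["onset"] / ds.tr_s).astype(int)
            assert (onset_scan + ds.truth.n_lags <= scans).all()
            # rt recorded iff the trial was accurate
            assert ev.loc[ev["accuracy"] == 1, "rt"].notna().all()
            assert ev.loc[ev["accuracy"] == 0, "rt"].isna().all()
            rts = ev["rt"].dropna()
            assert ((rts > 0) & (rts <= 3000)).all()
            for cond in ds.truth.conditions:
                sel = ev[ev["condition"] == cond]
                assert len(sel) == 6
                assert sel["accuracy"].sum() >= 1
        assert ds.fa["fa"].between(0, 1).all()

    def test_determinism(self, truth_small):
        a = sp.simulate_dataset(truth_small, 4, 2, seed=9)
        b = sp.simulate_dataset(truth_small, 4, 2, seed=9)
        sub = a.subjects[0]
        assert np.array_equal(a.bold[sub], b.bold[sub])
        assert a.events[sub].equals(b.events[sub])
        assert a.fa.equals(b.fa)

    def test_validation(self, truth_small):
        with pytest.raises(ValueError):
            sp.simulate_dataset(truth_small, 2, 2, seed=0)
        with pytest.raises(ValueError):
            sp.simulate_dataset(truth_small, 4, 0, seed=0)
        bad = sp.make_ground_truth(seed=0)
        bad.noise_sd = -1.0
        with pytest.raises(ValueError):
            sp.simulate_dataset(bad, 4, 2, seed=0)

    def test_planted_coupling_sign(self, planted_dataset):
        """Mean active-voxel response correlates positively with the saved
        latent scores in every condition (sign forced by construction)."""
        ds = planted_dataset
        windows = sp.datamat_from_dataset(ds)
        peak_lag = int(np.argmax(ds.truth.lag_profile))
        pos_vox = np.flatnonzero(ds.truth.spatial_map > 0)
        signal = windows.values[:, :, peak_lag][:, :, pos_vox].mean(axis=2)
        for ci in range(len(ds.truth.conditions)):
            r = np.corrcoef(signal[:, ci], ds.latent_scores[:, ci])[0, 1]
            assert r > 0

    def test_seed_signal_tracks_latents(self, planted_dataset):
        ds = planted_dataset
        windows = sp.datamat_from_dataset(ds)
        seed_mean, _ = sp.extract_seed_signal(
            windows, seed_ijk=ds.truth.seed_center_ijk)
        for ci, cond in enumerate(ds.truth.conditions):
            r = np.corrcoef(seed_mean[cond].to_numpy(),
                            ds.latent_scores[:, ci])[0, 1]
            assert r > 0


def test_noise_free_rank_one(noise_free_dataset):
    """coupling 1, noise 0: the stacked correlation matrix is rank one."""
    win, block, _ = sp.prepare_from_dataset(noise_free_dataset)
    scm = sp.build_stacked_correlation_matrix(win, block)
    s = np.linalg.svd(scm.values, compute_uv=False)
    # volumes are stored as float32; the residual rank is storage rounding
    assert s[1] / s[0] < 1e-5


def test_null_coupling_correlations_vanish():
    """Under coupling 0 the brain-variable correlations concentrate at 0."""
    truth = sp.make_ground_truth(seed=21, coupling_strength=0.0)
    ds = sp.simulate_dataset(truth, 200, 2, seed=22)
    win, block, _ = sp.prepare_from_dataset(ds)
    scm = sp.build_stacked_correlation_matrix(win, block)
    nonzero = scm.values[:, np.abs(scm.values).sum(axis=0) > 0]
    assert abs(nonzero.mean()) < 0.05
    assert np.abs(nonzero).mean() < 0.08   # E|r| ~ 0.8/sqrt(n) at n = 200


class TestEvaluateRecovery:
    def test_identity_and_sign_invariance(self, truth_small):
        t = truth_small
        assert sp.evaluate_recovery(t.voxel_salience_true, t)["cosine"] == \
            pytest.approx(1.0)
        assert sp.evaluate_recovery(-t.voxel_salience_true, t)["cosine"] == \
            pytest.approx(1.0)

    def test_orthogonal(self, truth_small):
        t = truth_small
        other = np.zeros_like(t.voxel_salience_true)
        other[np.flatnonzero(t.voxel_salience_true == 0)[:50]] = 1.0
        assert sp.evaluate_recovery(other, t)["cosine"] == pytest.approx(0.0)

    def test_length_mismatch(self, truth_small):
        with pytest.raises(ValueError, match="mismatch"):
            sp.evaluate_recovery(np.ones(3), truth_small)

    def test_detection_scores(self, truth_small):
        t = truth_small
        rep = sp.evaluate_recovery(t.voxel_salience_true, t,
                                   detected_voxels=t.active_voxel_set)
        assert rep["sensitivity"] == 1.0
        assert rep["specificity"] == 1.0
        assert rep["false_positive_rate"] == 0.0
        rep = sp.evaluate_recovery(t.voxel_salience_true, t,
                                   detected_voxels=[])
        assert rep["sensitivity"] == 0.0


def test_write_dataset_round_trip(tmp_path, truth_small):
    ds = sp.simulate_dataset(truth_small, 3, 2, seed=13)
    manifest = sp.write_dataset(ds, tmp_path)
    assert set(manifest["subjects"]) == set(ds.subjects)
    truth2 = syn.read_truth(tmp_path / "truth.json")
    assert np.allclose(truth2.voxel_salience_true,
                       ds.truth.voxel_salience_true)
    assert truth2.seed_center_ijk == ds.truth.seed_center_ijk
    doc = json.loads((tmp_path / "manifest.json").read_text())
    assert set(doc["files"]) >= {"mask.nii", "fa.csv", "truth.json"}
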