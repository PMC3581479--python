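"""Resting-state preprocessing and functional connectivity."""
import numpy as np
import pandas as pd
import pytest

from ratconn import bold, simulate


def _roi_series(data, tr=0.5, **kw):
    return bold.BoldSeries(data=np.asarray(data, dtype=float), tr=tr, **kw)


class TestPreprocess:
    def test_constant_voxel_zero_after_detrend(self):
        s = _roi_series(np.full((3, 50), 7.0))
        out = bold.preprocess(s, fwhm=0.0)
        assert np.allclose(out.data, 0.0, atol=1e-12)

    def test_linear_trend_removed(self):
        t = np.arange(100.0)
        s = _roi_series((2.0 + 0.3 * t)[None, :])
        out = bold.preprocess(s, fwhm=0.0)
        assert np.allclose(out.data, 0.0, atol=1e-9)

    def test_impulse_smoothed_to_gaussian_sigma(self):
        """FWHM = 1.0 mm => sigma = 1.0/2.3548 mm (FWHM/sigma identity)."""
        vol = np.zeros((21, 21, 21, 3))
        vol[10, 10, 10, 1] = 1.0  # spatial impulse in the middle frame
        s = bold.BoldSeries(data=vol, tr=1.0, voxel_size=0.5)
        out = bold.preprocess(s, fwhm=1.0)
        # the detrend is linear in time, so frame1 - frame0 isolates the
        # smoothed impulse exactly
        img = out.data[..., 1] - out.data[..., 0]
        x = np.arange(21)
        profile = img[:, 10, 10]
        sigma_vox = np.sqrt((profile * (x - 10) ** 2).sum() / profile.sum())
        assert sigma_vox * 0.5 == pytest.approx(1.0 / 2.3548, rel=0.02)

    def test_fwhm_zero_only_detrends(self, rng):
        vol = rng.standard_normal((4, 4, 4, 30))
        s = bold.BoldSeries(data=vol, tr=1.0, voxel_size=0.5)
        out = bold.preprocess(s, fwhm=0.0)
        from ratconn.bold import _detrend

        assert np.allclose(out.data, _detrend(vol))

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            bold.preprocess(_roi_series(np.zeros((2, 10))), fwhm=-1.0)


class TestRegressNuisance:
    def _series_with_nuisance(self, rng, n_t=200):
        nui = pd.DataFrame({
            "global": rng.standard_normal(n_t),
            **{f"motion_{k}": rng.standard_normal(n_t) for k in range(6)},
            "trend": np.linspace(-1, 1, n_t),
        })
        return nui

    def test_global_signal_fully_removed(self, rng):
        nui = self._series_with_nuisance(rng)
        sig = nui["global"].to_numpy()[None, :]
        s = _roi_series(sig, nuisance=nui)
        out = bold.regress_nuisance(s)
        assert np.linalg.norm(out.data) / np.linalg.norm(sig) < 1e-10

    def test_orthogonal_signal_unchanged(self, rng):
        nui = self._series_with_nuisance(rng)
        X = np.column_stack([np.ones(len(nui)), nui.to_numpy()])
        target = rng.standard_normal(len(nui))
        # orthogonalize against the nuisance space
        target -= X @ np.linalg.lstsq(X, target, rcond=None)[0]
        out = bold.regress_nuisance(_roi_series(target[None], nuisance=nui))
        assert np.allclose(out.data[0], target, atol=1e-10)

    def test_known_mix_recovers_target(self, rng):
        nui = self._series_with_nuisance(rng)
        X = np.column_stack([np.ones(len(nui)), nui.to_numpy()])
        target = rng.standard_normal(len(nui))
        target -= X @ np.linalg.lstsq(X, target, rcond=None)[0]
        mixed = target + 2.0 * nui["global"].to_numpy() - 0.7 * nui["motion_3"].to_numpy()
        out = bold.regress_nuisance(_roi_series(mixed[None], nuisance=nui))
        assert np.allclose(out.data[0], target, atol=1e-8)

    def test_residuals_orthogonal_to_regressors(self, rng):
        nui = self._series_with_nuisance(rng)
        y = rng.standard_normal((5, len(nui)))
        out = bold.regress_nuisance(_roi_series(y, nuisance=nui))
        for col in nui.columns:
            assert np.abs(out.data @ nui[col].to_numpy()).max() < 1e-8

    def test_collinear_columns_dropped_with_warning(self, rng):
        nui = self._series_with_nuisance(rng)
        nui["dup"] = nui["global"]
        with pytest.warns(UserWarning, match="rank-deficient"):
            bold.regress_nuisance(
                _roi_series(rng.standard_normal((2, len(nui))), nuisance=nui))


class TestBandpass:
    def test_passband_sinusoid_preserved(self):
        t = np.arange(1200) * 0.5
        sig = np.sin(2 * np.pi * 0.05 * t)[None, :]
        out = bold.bandpass(_roi_series(sig))
        assert out.data.std() == pytest.approx(sig.std(), rel=0.05)

    def test_constant_removed(self):
        out = bold.bandpass(_roi_series(np.full((1, 600), 3.0)))
        assert np.allclose(out.data, 0.0, atol=1e-10)

    def test_stopband_attenuated(self):
        t = np.arange(1200) * 0.5
        sig = np.sin(2 * np.pi * 0.4 * t)[None, :]
        out = bold.bandpass(_roi_series(sig))
        assert out.data.std() <= 0.1 * sig.std()

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bold.bandpass(_roi_series(np.zeros((1, 100))), 0.01, 1.5)


class TestRoiTimeseries:
    def test_constant_roi_returns_constant(self, small_atlas):
        n_t = 10
        vol = np.zeros((*small_atlas.label_volume.shape, n_t))
        vol[small_atlas.label_volume == 1] = 4.2
        s = bold.BoldSeries(data=vol, tr=0.5, voxel_size=small_atlas.voxel_size)
        out, flags = bold.roi_timeseries(s, small_atlas)
        assert np.allclose(out.data[0], 4.2)

    def test_mean_of_two_voxels(self, small_atlas, rng):
        vol = rng.standard_normal((*small_atlas.label_volume.shape, 20))
        s = bold.BoldSeries(data=vol, tr=0.5, voxel_size=small_atlas.voxel_size)
        out, _ = bold.roi_timeseries(s, small_atlas)
        mask = small_atlas.label_volume == 3
        assert np.allclose(out.data[2], vol[mask].mean(axis=0))

    def test_single_voxel_roi_excluded(self):
        from ratconn.atlas import RoiAtlas

        labels = np.zeros((6, 6, 2), dtype=int)
        labels[0, 0, 0] = 1  # one voxel only
        labels[3:5, 3:5, :] = 2
        table = pd.DataFrame({
            "label_id": [1, 2], "name": ["tiny", "big"],
            "hemisphere": ["left", "right"], "homolog_label_id": [2, 1],
            "tissue": ["gray", "gray"],
        })
        atlas = RoiAtlas(label_volume=labels, voxel_size=0.5, roi_table=table)
        vol = np.ones((6, 6, 2, 5))
        s = bold.BoldSeries(data=vol, tr=0.5, voxel_size=0.5)
        with pytest.warns(UserWarning, match="excluded"):
            _, flags = bold.roi_timeseries(s, atlas, min_voxels=2)
        assert not flags.loc[flags["name"] == "tiny", "included"].iloc[0]
        assert flags.loc[flags["name"] == "big", "included"].iloc[0]


class TestFcMatrix:
    def test_fisher_z_closed_form(self, rng):
        """r = 0.5 maps to z' = atanh(0.5) = 0.5493."""
        n = 4000
        x = rng.standard_normal(n)
        y = 0.5 * x + np.sqrt(1 - 0.25) * rng.standard_normal(n)
        m = bold.fc_matrix(np.stack([x, y]))
        r = np.tanh(m.z[0, 1])
        expected_z = np.arctanh(np.corrcoef(x, y)[0, 1])
        assert m.z[0, 1] == pytest.approx(expected_z, abs=1e-12)
        assert np.arctanh(0.5) == pytest.approx(0.5493, abs=1e-4)
        assert abs(r - 0.5) < 0.05

    def test_orthogonal_series_zero(self):
        t = np.linspace(0, 2 * np.pi, 128, endpoint=False)
        m = bold.fc_matrix(np.stack([np.sin(t), np.cos(t)]))
        assert m.z[0, 1] == pytest.approx(0.0, abs=1e-10)

    def test_diagonal_missing_never_infinite(self, rng):
        m = bold.fc_matrix(rng.standard_normal((3, 50)))
        assert np.all(np.isnan(np.diag(m.z)))
        off = m.z[~np.eye(3, dtype=bool)]
        assert np.all(np.isfinite(off))

    def test_perfectly_correlated_clipped_not_infinite(self, rng):
        x = rng.standard_normal(40)
        m = bold.fc_matrix(np.stack([x, 2 * x + 1]))
        assert np.isfinite(m.z[0, 1])
        assert m.z[0, 1] == pytest.approx(np.arctanh(1 - 1e-7))

    def test_constant_series_marked_missing(self, rng):
        data = np.vstack([np.ones(30), rng.standard_normal((2, 30))])
        m = bold.fc_matrix(data)
        assert np.all(np.isnan(m.z[0])) and np.all(np.isnan(m.z[:, 0]))
        assert np.isfinite(m.z[1, 2])

    def test_affine_rescaling_invariance(self, rng):
        data = rng.standard_normal((4, 100))
        scaled = 3.7 * data + 11.0
        a, b = bold.fc_matrix(data), bold.fc_matrix(scaled)
        mask = ~np.isnan(a.z)
        assert np.allclose(a.z[mask], b.z[mask], atol=1e-12)

    def test_roi_order_permutation_equivariance(self, rng):
        data = rng.standard_normal((5, 80))
        perm = rng.permutation(5)
        a = bold.fc_matrix(data)
        b = bold.fc_matrix(data[perm])
        assert np.allclose(a.z[np.ix_(perm, perm)], b.z, equal_nan=True)


class TestSeedMap:
    def test_voxel_equal_to_seed_hits_clip_limit(self, rng):
        seed_sig = rng.standard_normal(50)
        vol = np.broadcast_to(seed_sig, (2, 2, 1, 50)).copy()
        s = bold.BoldSeries(data=vol, tr=0.5)
        zmap = bold.seed_map(s, seed_sig)
        assert np.allclose(zmap, np.arctanh(1 - 1e-7))

    def test_antisymmetric_for_negated_seed(self, rng):
        seed_sig = rng.standard_normal(50)
        vol = np.broadcast_to(-seed_sig, (2, 2, 1, 50)).copy()
        s = bold.BoldSeries(data=vol, tr=0.5)
        zmap = bold.seed_map(s, seed_sig)
        assert np.allclose(zmap, -np.arctanh(1 - 1e-7))

    def test_constant_voxel_missing(self, rng):
        vol = np.ones((2, 1, 1, 30))
        zmap = bold.seed_map(bold.BoldSeries(data=vol, tr=0.5),
                             rng.standard_normal(30))
        assert np.all(np.isnan(zmap))

    def test_map_highest_in_connected_rois(self, small_atlas):
        """Seed-map values peak inside ROIs configured to correlate with
        the seed region."""
        n = len(small_atlas.gray_table)
        fc = np.eye(n)
        fc[0, 5] = fc[5, 0] = 0.8
        data, _ = simulate.sim_rest_bold(small_atlas, fc, n_frames=1200, seed=2)
        s = bold.BoldSeries(data=data["volume"], tr=0.5,
                            nuisance=data["nuisance"],
                            voxel_size=small_atlas.voxel_size)
        s = bold.preprocess(s, fwhm=0.0)
        s = bold.regress_nuisance(s)
        s = bold.bandpass(s)
        rts, _ = bold.roi_timeseries(s, small_atlas)
        zmap = bold.seed_map(s, rts.data[0])
        labels = small_atlas.label_volume
        lab_self = int(small_atlas.gray_table.iloc[0]["label_id"])
        lab_partner = int(small_atlas.gray_table.iloc[5]["label_id"])
        lab_other = int(small_atlas.gray_table.iloc[2]["label_id"])
        assert np.nanmean(zmap[labels == lab_partner]) > \
            np.nanmean(zmap[labels == lab_other]) + 0.2
        assert np.nanmean(zmap[labels == lab_self]) > \
            np.nanmean(zmap[labels == lab_partner])


class TestAverageHomologous:
    def test_simple_average(self, small_atlas):
        n = len(small_atlas.gray_table)
        z = np.full((n, n), np.nan)
        # labels 1..8; table order L,R,L,R...; names A=rows 0/1, B=rows 2/3
        z[0, 2] = z[2, 0] = 0.4  # A_L, B_L
        z[1, 3] = z[3, 1] = 0.6  # A_R, B_R
        fc = bold.FCMatrix(z=z, roi_ids=small_atlas.gray_table["label_id"].to_numpy(),
                           n_frames_used=100)
        intra, inter = bold.average_homologous(fc, small_atlas)
        names = list(intra.index)
        assert intra.loc[names[0], names[1]] == pytest.approx(0.5)

    def test_symmetric_brain_intra_equals_either_input(self, small_atlas, rng):
        n_pairs = len(small_atlas.gray_table) // 2
        base = rng.standard_normal((n_pairs, 200))
        data = np.repeat(base, 2, axis=0)  # left == right signal
        fc = bold.fc_matrix(bold.BoldSeries(
            data=data, tr=0.5,
            roi_ids=small_atlas.gray_table["label_id"].to_numpy()))
        intra, inter = bold.average_homologous(fc, small_atlas)
        a, b = intra.index[0], intra.index[1]
        assert intra.loc[a, b] == pytest.approx(fc.z[0, 2], abs=1e-12)

    def test_matches_bruteforce_from_full_matrix(self, small_atlas, rng):
        data = rng.standard_normal((len(small_atlas.gray_table), 150))
        fc = bold.fc_matrix(bold.BoldSeries(
            data=data, tr=0.5,
            roi_ids=small_atlas.gray_table["label_id"].to_numpy()))
        intra, inter = bold.average_homologous(fc, small_atlas)
        table = small_atlas.gray_table.reset_index(drop=True)
        pos = {int(r["label_id"]): i for i, r in table.iterrows()}
        for i, a in enumerate(intra.index):
            for j, b in enumerate(intra.index):
                al = pos[int(table[(table["name"] == a)
                                   & (table["hemisphere"] == "left")]["label_id"].iloc[0])]
                ar = pos[int(table[(table["name"] == a)
                                   & (table["hemisphere"] == "right")]["label_id"].iloc[0])]
                bl = pos[int(table[(table["name"] == b)
                                   & (table["hemisphere"] == "left")]["label_id"].iloc[0])]
                br = pos[int(table[(table["name"] == b)
                                   & (table["hemisphere"] == "right")]["label_id"].iloc[0])]
                if a == b:
                    assert inter.loc[a, b] == pytest.approx(fc.z[al, ar], nan_ok=True)
                else:
                    assert intra.loc[a, b] == pytest.approx(
                        np.mean([fc.z[al, bl], fc.z[ar, br]]), nan_ok=True)
                    assert inter.loc[a, b] == pytest.approx(
                        np.mean([fc.z[al, br], fc.z[ar, bl]]), nan_ok=True)

    def test_missing_hemisphere_yields_missing_value(self, small_atlas, rng):
        data = rng.standard_normal((len(small_atlas.gray_table), 100))
        data[1] = 1.0  # right hemisphere of first ROI constant -> missing
        fc = bold.fc_matrix(bold.BoldSeries(
            data=data, tr=0.5,
            roi_ids=small_atlas.gray_table["label_id"].to_numpy()))
        intra, inter = bold.average_homologous(fc, small_atlas)
        assert np.isnan(inter.iloc[0, 0])


class TestPipelineRecovery:
    def test_full_pipeline_recovers_fc_target(self, small_atlas):
        """preprocess -> nuisance regression -> band-pass -> FC recovers
        the configured correlations with MAE < 0.1 at 1200 frames
        (FC averaged over 20 simulation seeds)."""
        n = len(small_atlas.gray_table)
        fc_target = np.eye(n)
        fc_target[0, 1] = fc_target[1, 0] = 0.6
        fc_target[2, 5] = fc_target[5, 2] = 0.4
        acc = np.zeros((n, n))
        n_seeds = 20
        for s_i in range(n_seeds):
            data, _ = simulate.sim_rest_bold(small_atlas, fc_target,
                                             n_frames=1200, seed=100 + s_i)
            s = bold.BoldSeries(data=data["volume"], tr=0.5,
                                nuisance=data["nuisance"],
                                voxel_size=small_atlas.voxel_size)
            s = bold.preprocess(s, fwhm=1.0)
            s = bold.regress_nuisance(s)
            s = bold.bandpass(s)
            rts, _ = bold.roi_timeseries(s, small_atlas)
            acc += np.tanh(np.nan_to_num(bold.fc_matrix(rts).z))
        mean_r = acc / n_seeds
        iu = np.triu_indices(n, 1)
        mae = np.abs(mean_r[iu] - fc_target[iu]).mean()
        assert mae < 0.1
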