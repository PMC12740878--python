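"""Censoring rules, nuisance regression, and the FCC statistic."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from gsdecomp.connectivity import fc_matrix
from gsdecomp.datatypes import FCMatrix, Pipeline, RoiDataset
from gsdecomp.errors import DegenerateSignalError, InputError
from gsdecomp.preproc import (
    apply_pipeline,
    build_censor_mask,
    dvars,
    extract_global_signal,
    fcc,
    framewise_displacement,
    nuisance_regress,
    sweep_wm_components,
    wm_pca_components,
)


def _dataset(data, tr=2.0, labels=None):
    t, n = data.shape
    return RoiDataset(
        data=data, tr=tr, roi_ids=[f"r{i}" for i in range(n)],
        network_labels=labels or ["net0"] * (n // 2) + ["net1"] * (n - n // 2),
    )


class TestFramewiseDisplacement:
    def test_static_motion_is_zero(self):
        assert np.all(framewise_displacement(np.ones((20, 6))) == 0)

    def test_translation_step(self):
        mp = np.zeros((10, 6))
        mp[5:, 0] = 0.3
        fd = framewise_displacement(mp)
        assert fd[5] == pytest.approx(0.3)
        assert np.all(np.delete(fd, 5) == 0)

    def test_rotation_converted_on_50mm_sphere(self):
        mp = np.zeros((10, 6))
        mp[5:, 4] = 0.002  # rad
        fd = framewise_displacement(mp)
        assert fd[5] == pytest.approx(0.1)  # 50 mm * 0.002 rad


class TestDvars:
    def test_constant_data_is_zero(self):
        assert np.all(dvars(np.ones((15, 4))) == 0)

    def test_single_offset_frame(self):
        data = np.zeros((12, 5))
        data[6] += 2.5
        dv = dvars(data)
        assert dv[6] == pytest.approx(2.5)
        assert dv[7] == pytest.approx(2.5)
        assert np.all(np.delete(dv, [6, 7]) == 0)

    def test_matches_brute_force(self, rng):
        data = rng.standard_normal((20, 5))
        dv = dvars(data)
        for k in range(1, 20):
            acc = sum((data[k, j] - data[k - 1, j]) ** 2 for j in range(5)) / 5
            assert abs(dv[k] - np.sqrt(acc)) < 1e-12


class TestCensorMask:
    def test_clean_data_keeps_all(self):
        fd = np.full(30, 0.05)
        dv = np.full(30, 1.0)
        assert build_censor_mask(fd, dv).mask.all()

    def test_flagged_frame_removes_neighbours(self):
        fd = np.full(30, 0.05)
        fd[10] = 0.5
        rep = build_censor_mask(fd, np.full(30, 1.0))
        assert not rep.mask[9] and not rep.mask[10] and not rep.mask[11]
        assert rep.mask[8] and rep.mask[12]

    def test_sandwiched_clean_frame_removed(self):
        fd = np.full(30, 0.05)
        fd[[10, 12]] = 0.5
        rep = build_censor_mask(fd, np.full(30, 1.0))
        assert not rep.mask[11]

    def test_fraction_reported(self):
        fd = np.full(20, 0.05)
        fd[10] = 0.5
        rep = build_censor_mask(fd, np.full(20, 1.0))
        assert rep.fraction_censored == pytest.approx(3 / 20)

    @given(seed=st.integers(0, 2**31 - 1))
    def test_idempotent_under_fixed_thresholds(self, seed):
        rng = np.random.default_rng(seed)
        fd = np.abs(rng.normal(0.1, 0.08, 60))
        dv = np.abs(rng.normal(1.0, 0.3, 60))
        from gsdecomp.filters import mad

        thr = np.median(dv) + 3 * mad(dv)
        rep = build_censor_mask(fd, dv, dvars_thresh=thr)
        fd2, dv2 = fd[rep.mask], dv[rep.mask]
        rule_i = (fd2 > 0.25) | (dv2 > thr)
        assert not rule_i.any()


class TestGlobalSignal:
    def test_identical_rois_equal_gs(self, rng):
        col = rng.standard_normal(40)
        ds = _dataset(np.tile(col[:, None], (1, 4)))
        gs = extract_global_signal(ds)
        np.testing.assert_allclose(gs, (col - col.mean()) / col.std(), atol=1e-12)

    def test_antisymmetric_rois_degenerate(self, rng):
        col = rng.standard_normal(40)
        ds = _dataset(np.column_stack([col, -col, col, -col]))
        with pytest.raises(DegenerateSignalError):
            extract_global_signal(ds)

    def test_matches_brute_force_mean(self, rng):
        data = rng.standard_normal((30, 6))
        ds = _dataset(data)
        gs = extract_global_signal(ds)
        manual = np.array([data[t].mean() for t in range(30)])
        manual = (manual - manual.mean()) / manual.std()
        assert np.abs(gs - manual).max() < 1e-14


class TestWmPca:
    def test_rank_one_latent_recovered(self, rng):
        latent = rng.standard_normal(60)
        wm = np.outer(latent, rng.standard_normal(8)) \
            + 0.01 * rng.standard_normal((60, 8))
        pc1 = wm_pca_components(wm, 1)[:, 0]
        assert abs(np.corrcoef(pc1, latent)[0, 1]) > 0.99

    def test_full_rank_components_orthonormal(self, rng):
        wm = rng.standard_normal((50, 6))
        comps = wm_pca_components(wm, 6)
        gram = comps.T @ comps
        assert np.abs(gram - np.eye(6)).max() < 1e-10

    def test_explained_variance_non_increasing(self, rng):
        wm = rng.standard_normal((80, 6))
        comps = wm_pca_components(wm, 6)
        wm_std = (wm - wm.mean(0)) / wm.std(0)
        explained = np.linalg.norm(wm_std.T @ comps, axis=0)
        assert np.all(np.diff(explained) <= 1e-9)

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(InputError):
            wm_pca_components(rng.standard_normal((20, 5)), 6)


class TestNuisanceRegress:
    def test_self_regression_zeroes_roi(self, rng):
        data = rng.standard_normal((40, 4))
        ds = _dataset(data)
        out = nuisance_regress(ds, data[:, [2]])
        assert np.abs(out.data[:, 2]).max() < 1e-10

    def test_residuals_orthogonal_to_nuisance(self, rng):
        data = rng.standard_normal((50, 5))
        nuis = rng.standard_normal((50, 3))
        out = nuisance_regress(_dataset(data), nuis)
        assert np.abs(out.data.T @ nuis).max() < 1e-10

    def test_zero_column_rejected(self, rng):
        data = rng.standard_normal((30, 4))
        with pytest.raises(InputError):
            nuisance_regress(_dataset(data), np.zeros((30, 1)))

    def test_orthogonal_signal_correlations_preserved(self, rng):
        # signals orthogonal to the nuisance space keep their pairwise r
        nuis = rng.standard_normal((200, 2))
        raw = rng.standard_normal((200, 4))
        design = np.column_stack([np.ones(200), nuis])
        ortho = raw - design @ np.linalg.lstsq(design, raw, rcond=None)[0]
        before = np.corrcoef(ortho, rowvar=False)
        out = nuisance_regress(_dataset(ortho), nuis)
        after = np.corrcoef(out.data, rowvar=False)
        assert np.abs(before - after).max() < 1e-10

    def test_gsr_forces_zero_global_mean(self, default_subject):
        from gsdecomp.workflow import censor_subject

        masked = censor_subject(default_subject)
        out = apply_pipeline(masked, default_subject.wm, Pipeline.WM10_GSR)
        assert np.abs(out.data.mean(axis=1)).max() < 1e-9


class TestFcc:
    @staticmethod
    def _expected_z(n1, n2):
        # closed-form standardised rank-sum statistic for full separation
        u = n1 * n2
        return (u - n1 * n2 / 2) / np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)

    def test_full_separation_matches_closed_form(self):
        n = 6
        labels = ["a"] * 3 + ["b"] * 3
        vals = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i != j and labels[i] == labels[j]:
                    vals[i, j] = 0.8
        np.fill_diagonal(vals, 1.0)
        fc = FCMatrix(values=vals, roi_ids=[str(i) for i in range(n)],
                      network_labels=labels)
        n_within = 6  # 2 networks x C(3,2)
        n_between = 15 - n_within
        assert fcc(fc) == pytest.approx(self._expected_z(n_within, n_between))

    def test_permuted_labels_have_zero_expectation(self, rng):
        n = 12
        x = rng.standard_normal((80, n))
        vals = np.corrcoef(x, rowvar=False)
        zs = []
        labels = np.array(["a"] * 6 + ["b"] * 6)
        for _ in range(200):
            rng.shuffle(labels)
            fc = FCMatrix(values=vals, roi_ids=[str(i) for i in range(n)],
                          network_labels=list(labels))
            zs.append(fcc(fc))
        assert abs(np.mean(zs)) < 0.25

    def test_single_network_rejected(self, rng):
        x = rng.standard_normal((40, 5))
        fc = FCMatrix(values=np.corrcoef(x, rowvar=False),
                      roi_ids=[str(i) for i in range(5)],
                      network_labels=["a"] * 5)
        with pytest.raises(InputError):
            fcc(fc)


class TestSweep:
    def test_k_zero_is_baseline_only(self, small_subject):
        from gsdecomp.workflow import censor_subject

        masked = censor_subject(small_subject)
        df = sweep_wm_components([masked], [small_subject.wm], [0])
        assert list(df["k"]) == [0]
        base = fcc(fc_matrix(masked.censored()))
        assert df["mean_fcc"].iloc[0] == pytest.approx(base)

    def test_wm_regression_raises_fcc_when_wm_contaminates(self, small_spec):
        # the generated WM channels share the SLFO driving the BOLD data,
        # so removing WM components must sharpen the network contrast
        from gsdecomp.synth import gen_cohort
        from gsdecomp.workflow import censor_subject

        cohort = gen_cohort(small_spec, raw_physio=False)
        datasets = [censor_subject(s) for s in cohort]
        wms = [s.wm for s in cohort]
        df = sweep_wm_components(datasets, wms, [0, 4]).set_index("k")
        assert df.loc[4, "mean_fcc"] > df.loc[0, "mean_fcc"]
        assert df.attrs["best_k"] == 4
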