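"""Group statistics: voxelwise correlation algebra, smoothness estimation,
Monte-Carlo cluster calibration, clustering, masked replication, overlap."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats

from phenoconn import groupstats as gs
from phenoconn.groupstats import ValidationError


def smooth_stack(n, shape=(16, 18, 16), fwhm_vox=1.5, seed=0):
    rng = np.random.default_rng(seed)
    sigma = fwhm_vox / np.sqrt(8 * np.log(2))
    vols = np.stack([ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
                     for _ in range(n)])
    return vols / vols.std(axis=(1, 2, 3), keepdims=True)


@pytest.fixture(scope="module")
def null_group():
    stack = smooth_stack(24, seed=1)
    rng = np.random.default_rng(2)
    cov = rng.normal(size=24)
    mask = np.ones(stack.shape[1:], bool)
    return stack, cov, mask


def test_negating_covariate_flips_signs(null_group):
    stack, cov, mask = null_group
    a = gs.voxelwise_correlate(stack, cov, mask)
    b = gs.voxelwise_correlate(stack, -cov, mask)
    assert np.allclose(a.r_map, -b.r_map)
    assert np.allclose(a.t_map, -b.t_map)
    assert np.allclose(a.p_map, b.p_map)


def test_df_and_t_identity(null_group):
    stack, cov, mask = null_group
    res = gs.voxelwise_correlate(stack, cov, mask)
    assert res.df == 22
    m = mask & (np.abs(res.r_map) < 1)
    t = res.r_map[m] * np.sqrt(res.df) / np.sqrt(1 - res.r_map[m] ** 2)
    assert np.allclose(t, res.t_map[m])


def test_null_voxel_fraction_near_alpha(null_group):
    stack, _, mask = null_group
    rng = np.random.default_rng(3)
    fracs = [ (gs.voxelwise_correlate(stack, rng.normal(size=24), mask)
               .p_map < 0.05).mean() for _ in range(40)]
    assert np.mean(fracs) == pytest.approx(0.05, abs=0.02)


def test_constant_covariate_rejected(null_group):
    stack, _, mask = null_group
    with pytest.raises(ValidationError):
        gs.voxelwise_correlate(stack, np.ones(24), mask)


def test_matches_scipy_pearson_at_single_voxel(null_group):
    stack, cov, mask = null_group
    res = gs.voxelwise_correlate(stack, cov, mask)
    r_ref, p_ref = stats.pearsonr(stack[:, 5, 5, 5], cov)
    assert res.r_map[5, 5, 5] == pytest.approx(r_ref, abs=1e-12)
    assert res.p_map[5, 5, 5] == pytest.approx(p_ref, rel=1e-9)


# ---------------------------------------------------------------- smoothness

def test_fwhm_white_noise_below_voxel_size():
    rng = np.random.default_rng(4)
    vols = rng.standard_normal((6, 20, 20, 20))
    assert gs.estimate_fwhm(vols, 3.0) <= 1.2 * 3.0


def test_fwhm_recovers_known_kernel():
    rng = np.random.default_rng(5)
    sigma_vox = 6.0 / (np.sqrt(8 * np.log(2)) * 3.0)
    vols = np.stack([ndimage.gaussian_filter(rng.standard_normal((24, 24, 24)),
                                             sigma_vox) for _ in range(6)])
    est = gs.estimate_fwhm(vols, 3.0)
    assert abs(est - 6.0) / 6.0 < 0.20


def test_fwhm_scale_invariance():
    rng = np.random.default_rng(6)
    vols = np.stack([ndimage.gaussian_filter(rng.standard_normal((20,) * 3), 1.0)
                     for _ in range(3)])
    assert gs.estimate_fwhm(vols, 3.0) == pytest.approx(
        gs.estimate_fwhm(vols * 123.4, 3.0), rel=1e-9)


# --------------------------------------------------------------- calibration

def brute_force_extent_threshold(mask, voxel_p, alpha, n_iter, seed):
    """Independent oracle at fwhm = 0: Bernoulli suprathreshold fields."""
    rng = np.random.default_rng(seed)
    struct = ndimage.generate_binary_structure(3, 1)
    maxima = np.zeros(n_iter, dtype=int)
    for i in range(n_iter):
        supra = (rng.random(mask.shape) < voxel_p) & mask
        labels, n_lab = ndimage.label(supra, structure=struct)
        if n_lab:
            maxima[i] = np.bincount(labels.ravel())[1:].max()
    k = 1
    while (maxima >= k).mean() > alpha:
        k += 1
    return k


def test_extent_threshold_matches_brute_force_oracle():
    mask = np.ones((20, 20, 20), bool)
    cal = gs.cluster_extent_threshold(mask, fwhm_mm=0.0, voxel_mm=3.0,
                                      voxel_p=0.01, corrected_alpha=0.05,
                                      n_iterations=1500, rng_seed=11)
    oracle = brute_force_extent_threshold(mask, 0.01, 0.05, 1500, seed=99)
    assert abs(cal.extent_threshold - oracle) <= 1


def test_extent_threshold_monotone_in_fwhm():
    mask = np.ones((18, 18, 18), bool)
    thr = [gs.cluster_extent_threshold(mask, f, 3.0, voxel_p=0.01,
                                       n_iterations=400, rng_seed=12).extent_threshold
           for f in (0.0, 4.5, 9.0)]
    assert thr == sorted(thr)


def test_corrected_false_positive_rate_controlled():
    """Fresh smoothed null volumes thresholded with the calibrated extent
    exceed it at rate <= alpha + 0.02."""
    mask = np.ones((16, 18, 16), bool)
    fwhm, voxel = 4.5, 3.0
    cal = gs.cluster_extent_threshold(mask, fwhm, voxel, voxel_p=0.01,
                                      corrected_alpha=0.05,
                                      n_iterations=2000, rng_seed=13)
    rng = np.random.default_rng(14)
    sigma = fwhm / (np.sqrt(8 * np.log(2)) * voxel)
    zc = stats.norm.isf(0.005)
    struct = ndimage.generate_binary_structure(3, 1)
    fps = 0
    n_vol = 1000
    for _ in range(n_vol):
        vol = ndimage.gaussian_filter(rng.standard_normal(mask.shape), sigma,
                                      mode="constant")
        vol = (vol - vol[mask].mean()) / vol[mask].std()
        labels, n_lab = ndimage.label((np.abs(vol) > zc) & mask, structure=struct)
        if n_lab and np.bincount(labels.ravel())[1:].max() >= cal.extent_threshold:
            fps += 1
    assert fps / n_vol <= 0.05 + 0.02


# ------------------------------------------------------------------ clusters

def _result_from_t(t_map, mask=None, n_subjects=30, voxel_mm=3.0, affine=None):
    r = np.tanh(t_map / 10.0)
    p = 2 * stats.t.sf(np.abs(t_map), n_subjects - 2)
    return gs.GroupResult(r_map=r, t_map=t_map, p_map=p, n_subjects=n_subjects,
                          covariate_name="x",
                          analysis_mask=(np.ones_like(t_map, bool)
                                         if mask is None else mask),
                          affine=affine, voxel_mm=voxel_mm)


def test_single_suprathreshold_voxel():
    t = np.zeros((10, 10, 10))
    t[4, 4, 4] = 8.0
    table = gs.find_clusters(_result_from_t(t), voxel_p=0.01)
    assert len(table) == 1
    assert table["extent_voxels"].iloc[0] == 1
    assert table["volume_mm3"].iloc[0] == 27.0


def test_corner_touching_voxels_are_two_clusters_under_face_adjacency():
    t = np.zeros((8, 8, 8))
    t[2, 2, 2] = 8.0
    t[3, 3, 3] = 8.0
    table = gs.find_clusters(_result_from_t(t), voxel_p=0.01)
    assert len(table) == 2
    table_corner = gs.find_clusters(_result_from_t(t), voxel_p=0.01,
                                    connectivity="corner")
    assert len(table_corner) == 1


def test_cluster_volume_follows_voxel_size():
    t = np.zeros((20, 20, 20))
    t[5:10, 5:10, 5:10] = 9.0  # 125-voxel block
    table = gs.find_clusters(_result_from_t(t), voxel_p=0.01)
    assert table["extent_voxels"].iloc[0] == 125
    assert table["volume_mm3"].iloc[0] == 125 * 27.0


def test_mask_replicate_identity_when_mask_is_full():
    stack = smooth_stack(26, seed=21)
    rng = np.random.default_rng(22)
    cov = rng.normal(size=26)
    mask = np.ones(stack.shape[1:], bool)
    res = gs.voxelwise_correlate(stack, cov, mask)
    cal = gs.cluster_extent_threshold(mask, 4.5, 3.0, voxel_p=0.05,
                                      n_iterations=300, rng_seed=23,
                                      two_tailed=False)
    direct = gs.find_clusters(res, voxel_p=0.05, calibration=cal,
                              positive_only=True)
    rep, _ = gs.mask_replicate(res, mask, voxel_p=0.05, n_iterations=300,
                               rng_seed=23, positive_only=True, fwhm_mm=4.5)
    pd.testing.assert_frame_equal(
        direct.drop(columns=["passed_correction"]),
        rep.drop(columns=["passed_correction"]))


def test_mask_replicate_empty_mask_rejected(null_group):
    stack, cov, mask = null_group
    res = gs.voxelwise_correlate(stack, cov, mask)
    with pytest.raises(ValidationError):
        gs.mask_replicate(res, np.zeros_like(mask), n_iterations=50)


def test_mask_with_no_suprathreshold_voxels_gives_empty_table(null_group):
    stack, cov, mask = null_group
    res = gs.voxelwise_correlate(stack, cov, mask)
    sub = np.zeros_like(mask)
    quiet = np.argwhere(np.abs(res.t_map) < 0.5)[:20]
    sub[tuple(quiet.T)] = True
    rep, _ = gs.mask_replicate(res, sub, voxel_p=0.001, n_iterations=50,
                               rng_seed=1, fwhm_mm=4.5)
    assert len(rep) == 0


# ------------------------------------------------------------------- overlap

def test_overlap_identities():
    rng = np.random.default_rng(30)
    a = rng.random((8, 8, 8)) > 0.7
    b = rng.random((8, 8, 8)) > 0.7
    rep = gs.overlap_report({"a": a, "b": b}).set_index("masks")
    assert rep.loc["a", "overlap_voxels"] == a.sum()
    assert rep.loc["a & b", "overlap_voxels"] == (a & b).sum()
    assert rep.loc["a & b", "overlap_voxels"] <= min(a.sum(), b.sum())
    same = gs.overlap_report({"a": a, "a2": a}).set_index("masks")
    assert same.loc["a & a2", "overlap_voxels"] == a.sum()
    disjoint = gs.overlap_report({"a": a, "na": ~a}).set_index("masks")
    assert disjoint.loc["a & na", "overlap_voxels"] == 0


def test_subset_overlap_equals_subset_size():
    a = np.zeros((6, 6, 6), bool)
    a[1:3, 1:3, 1:3] = True
    b = np.zeros_like(a)
    b[1:5, 1:5, 1:5] = True
    rep = gs.overlap_report({"a": a, "b": b}).set_index("masks")
    assert rep.loc["a & b", "overlap_voxels"] == a.sum()


def test_three_way_overlap_row_present():
    m = np.ones((4, 4, 4), bool)
    rep = gs.overlap_report({"x": m, "y": m, "z": m})
    assert (rep["masks"] == "x & y & z").any()
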