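"""Denoising stream: FD, censoring rules, Volterra design, regression on
uncensored frames, spectral reconstitution, band-pass response, seed maps."""

import numpy as np
import pytest

from phenoconn import rsfc
from phenoconn.rsfc import (BoldRun, CensorMask, IntegrityError, ValidationError,
                            bandpass, build_censor_mask, build_nuisance_matrix,
                            compute_fd, nuisance_regress, process_run,
                            seed_map, seed_sphere_voxels, spectral_interpolate,
                            subject_inclusion, volterra_motion_block)


# ---------------------------------------------------------------- FD / censor

def test_fd_constant_motion_is_zero():
    motion = np.tile([1.0, -2.0, 0.5, 0.01, -0.02, 0.03], (20, 1))
    assert np.allclose(compute_fd(motion), 0.0)


def test_fd_translation_jump():
    motion = np.zeros((10, 6))
    motion[5:, 0] = 0.1
    fd = compute_fd(motion)
    assert fd[5] == pytest.approx(0.1)
    assert fd[0] == 0.0 and fd[4] == 0.0 and fd[6] == 0.0


def test_fd_rotation_converted_on_50mm_sphere():
    motion = np.zeros((3, 6))
    motion[1:, 3] = 0.01  # 0.01 rad pitch step
    assert compute_fd(motion)[1] == pytest.approx(0.5)


def test_fd_requires_six_columns():
    with pytest.raises(ValidationError):
        compute_fd(np.zeros((10, 5)))


def test_censor_all_quiet_keeps_everything():
    cm = build_censor_mask(np.zeros(100))
    assert cm.keep.all() and cm.run_included


def test_short_surviving_island_is_censored():
    fd = np.zeros(100)
    fd[[10, 15]] = 1.0  # island of 4 frames between censored spikes
    cm = build_censor_mask(fd)
    assert not cm.keep[10] and not cm.keep[15]
    assert not cm.keep[11:15].any()
    assert cm.keep[16:].all()


def test_run_inclusion_boundary_at_50_frames():
    fd = np.zeros(60)
    fd[49:] = 1.0  # 49 uncensored frames survive
    assert not build_censor_mask(fd).run_included
    fd = np.zeros(60)
    fd[50:] = 1.0  # 50 survive
    assert build_censor_mask(fd).run_included


def test_fd_exactly_at_threshold_is_kept():
    fd = np.zeros(60)
    fd[10] = 0.25
    assert build_censor_mask(fd, threshold=0.25).keep[10]


def test_raising_threshold_never_drops_frames():
    rng = np.random.default_rng(0)
    fd = rng.exponential(0.15, size=200)
    fd[0] = 0.0
    kept = [build_censor_mask(fd, threshold=t).keep.sum()
            for t in (0.1, 0.2, 0.25, 0.4, 1.0)]
    assert kept == sorted(kept)


@pytest.mark.parametrize("tr, frames, included", [
    (2.5, 120, True),    # exactly 300 s, inclusive
    (2.5, 119, False),
    (1.19, 250, False),  # 297.5 s
])
def test_subject_inclusion_boundaries(tr, frames, included):
    cm = CensorMask(keep=np.ones(frames, bool), fd=np.zeros(frames))
    assert subject_inclusion([cm], tr) is included


# ------------------------------------------------------------------ nuisance

def test_volterra_block_has_36_columns():
    rng = np.random.default_rng(1)
    assert volterra_motion_block(rng.normal(size=(50, 6))).shape == (50, 36)


def test_volterra_zero_motion_is_zero():
    assert not volterra_motion_block(np.zeros((30, 6))).any()


def test_volterra_impulse_lag_structure():
    """Unit impulse at frame k appears in the lag columns exactly at k+1, k+2."""
    k = 7
    motion = np.zeros((20, 6))
    motion[k, 2] = 1.0
    block = volterra_motion_block(motion)
    lag1, lag2 = block[:, 12 + 2], block[:, 18 + 2]
    assert lag1[k + 1] == 1.0 and np.count_nonzero(lag1) == 1
    assert lag2[k + 2] == 1.0 and np.count_nonzero(lag2) == 1
    lag1_sq, lag2_sq = block[:, 24 + 2], block[:, 30 + 2]
    assert lag1_sq[k + 1] == 1.0 and lag2_sq[k + 2] == 1.0


def test_nuisance_matrix_has_43_columns(one_bold_run):
    _, run, _ = one_bold_run
    design = build_nuisance_matrix(run.motion, run.data, run.masks)
    assert design.shape == (run.n_frames, 43)
    assert np.allclose(design[:, -1], 1.0)


def test_empty_tissue_mask_rejected(one_bold_run):
    _, run, _ = one_bold_run
    masks = dict(run.masks)
    masks["csf"] = np.zeros_like(masks["csf"])
    with pytest.raises(IntegrityError):
        build_nuisance_matrix(run.motion, run.data, masks)


def test_regression_annihilates_a_regressor():
    rng = np.random.default_rng(2)
    t = 60
    design = np.column_stack([rng.normal(size=(t, 3)), np.ones(t)])
    cm = CensorMask(keep=np.ones(t, bool), fd=np.zeros(t))
    bold = np.tile(design[:, 1], (2, 2, 2, 1))
    resid = nuisance_regress(bold, design, cm)
    assert np.abs(resid).max() < 1e-8


def test_regression_orthogonal_signal_only_demeaned():
    # 10-frame toy with a closed-form answer: regressors orthogonal to the
    # voxel leave residual = signal - mean
    t = 10
    x = np.column_stack([np.sin(2 * np.pi * np.arange(t) / t), np.ones(t)])
    v = np.cos(2 * np.pi * np.arange(t) / t)  # orthogonal to both columns
    cm = CensorMask(keep=np.ones(t, bool), fd=np.zeros(t))
    resid = nuisance_regress(v.reshape(1, 1, 1, t), x, cm)[0, 0, 0]
    assert np.allclose(resid, v - v.mean(), atol=1e-10)


def test_censored_frames_do_not_influence_fit():
    rng = np.random.default_rng(3)
    t = 80
    design = np.column_stack([rng.normal(size=(t, 4)), np.ones(t)])
    bold = rng.normal(size=(3, 3, 3, t))
    keep = np.ones(t, bool)
    keep[10:20] = False
    cm = CensorMask(keep=keep, fd=np.zeros(t))
    resid_a = nuisance_regress(bold, design, cm)
    perturbed = bold.copy()
    perturbed[..., ~keep] += rng.normal(scale=50.0, size=(3, 3, 3, 10))
    resid_b = nuisance_regress(perturbed, design, cm)
    assert np.allclose(resid_a[..., keep], resid_b[..., keep], atol=1e-9)


def test_rank_deficient_design_reports_columns():
    t = 40
    x = np.ones((t, 3))  # three identical columns
    cm = CensorMask(keep=np.ones(t, bool), fd=np.zeros(t))
    with pytest.raises(ValidationError, match="columns"):
        nuisance_regress(np.zeros((1, 1, 1, t)), x, cm)


# ------------------------------------------------------------- interpolation

def test_interpolation_identity_without_censoring():
    rng = np.random.default_rng(4)
    y = rng.normal(size=(2, 2, 2, 50))
    cm = CensorMask(keep=np.ones(50, bool), fd=np.zeros(50))
    assert np.array_equal(spectral_interpolate(y, cm, 2.5), y)


def test_interpolation_recovers_sinusoid():
    rng = np.random.default_rng(5)
    n, tr = 240, 2.5
    t = np.arange(n) * tr
    y = np.sin(2 * np.pi * 0.03 * t)
    keep = rng.random(n) > 0.2
    keep[:2] = True
    cm = CensorMask(keep=keep, fd=np.zeros(n))
    out = spectral_interpolate(y.reshape(1, 1, 1, n), cm, tr)[0, 0, 0]
    err = out[~keep] - y[~keep]
    rms = np.sqrt(np.mean(err ** 2)) / np.sqrt(np.mean(y[~keep] ** 2))
    assert rms < 0.10


def test_interpolation_preserves_uncensored_bits():
    rng = np.random.default_rng(6)
    y = rng.normal(size=(1, 1, 4, 100))
    keep = rng.random(100) > 0.3
    keep[:2] = True
    cm = CensorMask(keep=keep, fd=np.zeros(100))
    out = spectral_interpolate(y, cm, 1.19)
    assert np.array_equal(out[..., keep], y[..., keep])


def test_interpolation_needs_uncensored_frames():
    cm = CensorMask(keep=np.zeros(30, bool), fd=np.zeros(30))
    with pytest.raises(IntegrityError):
        spectral_interpolate(np.zeros((1, 1, 1, 30)), cm, 2.5)


# ----------------------------------------------------------------- band-pass

def test_bandpass_rejects_dc():
    x = np.full((1, 200), 5.0)
    assert np.abs(bandpass(x, 2.5)).max() < 1e-6 * 5.0


def test_bandpass_frequency_response():
    n = 600
    t = np.arange(n) * 1.19
    inband = np.sin(2 * np.pi * 0.04 * t)
    outband = np.sin(2 * np.pi * 0.2 * t)
    assert bandpass(inband[None], 1.19)[0].std() >= 0.90 * inband.std()
    assert bandpass(outband[None], 1.19)[0].std() <= 0.05 * outband.std()


def test_bandpass_rejects_band_above_nyquist():
    with pytest.raises(ValidationError):
        bandpass(np.zeros((1, 100)), 10.0, f_hi=0.08)  # nyquist 0.05


# ---------------------------------------------------------------- seed tools

def test_tiny_radius_selects_single_voxel():
    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    vox = seed_sphere_voxels((9.0, 9.0, 9.0), 0.1, affine, (10, 10, 10))
    assert vox.shape == (1, 3)
    assert tuple(vox[0]) == (3, 3, 3)


def test_4mm_sphere_on_3mm_grid_is_center_plus_face_neighbors():
    """Exhaustive enumeration oracle: voxel centers within 4 mm of a voxel
    center on a 3 mm grid are the center and its 6 face neighbors."""
    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    center = (15.0, 15.0, 15.0)
    got = {tuple(v) for v in seed_sphere_voxels(center, 4.0, affine, (11, 11, 11))}
    oracle = set()
    for i in range(11):
        for j in range(11):
            for k in range(11):
                d2 = sum((3.0 * a - c) ** 2 for a, c in zip((i, j, k), center))
                if d2 <= 16.0:
                    oracle.add((i, j, k))
    assert got == oracle
    assert len(got) == 7


def test_sphere_translation_invariance():
    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    a = seed_sphere_voxels((9.0, 9.0, 9.0), 5.0, affine, (12, 12, 12))
    affine2 = affine.copy()
    affine2[:3, 3] += [7.0, -4.0, 2.0]
    b = seed_sphere_voxels((16.0, 5.0, 11.0), 5.0, affine2, (12, 12, 12))
    assert np.array_equal(a, b)


def test_empty_sphere_is_an_error():
    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    with pytest.raises(ValidationError):
        seed_sphere_voxels((500.0, 0.0, 0.0), 1.0, affine, (10, 10, 10))


# ------------------------------------------------------------------ seed map

def _toy_bold_with_seed(n=120, extra_voxels=None):
    rng = np.random.default_rng(7)
    sig = rng.normal(size=n)
    bold = rng.normal(size=(4, 4, 4, n))
    bold[0, 0, 0] = sig
    if extra_voxels:
        for (i, j, k), ts in extra_voxels.items():
            bold[i, j, k] = ts
    seed_vox = np.array([[0, 0, 0]])
    cm = CensorMask(keep=np.ones(n, bool), fd=np.zeros(n))
    return bold, seed_vox, cm, sig


def test_seed_voxel_itself_is_clipped_and_flagged():
    bold, seed_vox, cm, _ = _toy_bold_with_seed()
    sm = seed_map(bold, seed_vox, cm, np.eye(4))
    assert np.isfinite(sm.z[0, 0, 0])
    assert sm.z[0, 0, 0] == pytest.approx(np.arctanh(1 - 1e-7))
    assert sm.seed_voxel_flags[0, 0, 0]


def test_negated_signal_gives_minus_one():
    n = 120
    bold, seed_vox, cm, sig = _toy_bold_with_seed(n, {(1, 1, 1): None})
    bold[1, 1, 1] = -sig
    sm = seed_map(bold, seed_vox, cm, np.eye(4))
    assert sm.z[1, 1, 1] == pytest.approx(np.arctanh(-(1 - 1e-7)))


def test_zero_variance_voxel_flagged_zero():
    bold, seed_vox, cm, _ = _toy_bold_with_seed()
    bold[2, 2, 2] = 3.14
    sm = seed_map(bold, seed_vox, cm, np.eye(4))
    assert sm.z[2, 2, 2] == 0.0
    assert sm.zero_variance_flags[2, 2, 2]


def test_snr_one_voxel_correlates_at_inverse_sqrt2():
    """signal + equal-variance noise -> analytic r = 1/sqrt(2) ~ 0.707."""
    rng = np.random.default_rng(8)
    n = 200
    sig = rng.normal(size=n)
    bold = np.zeros((1, 1, 101, n))
    bold[0, 0, 0] = sig
    for v in range(1, 101):
        bold[0, 0, v] = sig + rng.normal(size=n)
    cm = CensorMask(keep=np.ones(n, bool), fd=np.zeros(n))
    sm = seed_map(bold, np.array([[0, 0, 0]]), cm, np.eye(4))
    mean_r = np.tanh(sm.z[0, 0, 1:]).mean()
    assert 0.6 < mean_r < 0.8


def test_seed_map_scale_invariance(one_bold_run):
    _, run, _ = one_bold_run
    sm1, _ = process_run(run)
    scaled = BoldRun(data=run.data * 4.2, tr_seconds=run.tr_seconds,
                     voxel_mm=run.voxel_mm, affine=run.affine,
                     motion=run.motion, masks=run.masks,
                     subject_id=run.subject_id)
    sm2, _ = process_run(scaled)
    assert np.allclose(sm1.z, sm2.z, atol=1e-8)


def test_full_stream_determinism_and_stage_order(one_bold_run):
    _, run, _ = one_bold_run
    sm1, _ = process_run(run)
    sm2, _ = process_run(run)
    assert np.array_equal(sm1.z, sm2.z)
    assert tuple(sm1.stage_log) == rsfc.PIPELINE_STAGES
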