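"""Resting-state functional-connectivity denoising and seed mapping.

Implements the motion-scrubbing stream applied to each BOLD run before
seed-based correlation:

1. framewise displacement (FD) from the 6 realignment parameters, with
   rotations converted to millimetres as arc length on a 50 mm sphere;
2. frame censoring at FD > 0.25 mm, with short (< 5 contiguous frames)
   surviving segments also censored, a >= 50 uncensored-frame rule per run
   and a >= 5 min uncensored rule per subject;
3. nuisance regression on uncensored frames only, using a Volterra
   expansion of the motion parameters (36 columns) plus CSF / white-matter /
   global tissue means and their first derivatives and a constant
   (43 columns total);
4. spectral reconstitution of censored frames by least-squares fitting of
   sinusoids at Lomb-Scargle frequencies estimated from uncensored frames;
5. zero-phase band-pass filtering to 0.009-0.08 Hz;
6. Pearson correlation, over uncensored frames only, between the mean
   seed time course and every voxel, Fisher z-transformed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

HEAD_RADIUS_MM = 50.0  # rotation -> mm conversion (arc length)
PIPELINE_STAGES = ("censor", "regress", "interpolate", "bandpass", "correlate")


class ValidationError(ValueError):
    pass


class IntegrityError(ValueError):
    pass


@dataclass
class BoldRun:
    """One 4D BOLD run with its realignment parameters and tissue masks.

    ``data`` is [x, y, z, t]; ``motion`` is [t, 6] as (x, y, z translations
    in mm; pitch, roll, yaw in radians); ``masks`` holds boolean 3D arrays
    under keys ``csf``, ``wm``, ``whole_brain``.
    """

    data: np.ndarray
    tr_seconds: float
    voxel_mm: float
    affine: np.ndarray
    motion: np.ndarray
    masks: dict[str, np.ndarray]
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValidationError("BOLD data must be 4D [x, y, z, t]")
        t = self.data.shape[-1]
        if self.motion.shape != (t, 6):
            raise ValidationError(
                f"motion must be [t, 6] = ({t}, 6), got {self.motion.shape}")
        for name, m in self.masks.items():
            if m.shape != self.data.shape[:3]:
                raise ValidationError(f"mask {name!r} shape mismatch")

    @property
    def n_frames(self) -> int:
        return self.data.shape[-1]


@dataclass
class CensorMask:
    keep: np.ndarray          # bool, length t
    fd: np.ndarray            # mm, length t; fd[0] = 0 by convention
    run_included: bool = True

    @property
    def n_uncensored(self) -> int:
        return int(self.keep.sum())


@dataclass
class SeedMap:
    """Fisher-z seed-connectivity image for one subject."""

    z: np.ndarray
    subject_id: str
    n_uncensored_frames: int
    seed_center_mni: tuple[float, float, float]
    seed_radius_mm: float
    seed_voxel_flags: np.ndarray | None = None   # True at seed voxels
    zero_variance_flags: np.ndarray | None = None
    stage_log: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# censoring

def compute_fd(motion: np.ndarray, head_radius_mm: float = HEAD_RADIUS_MM) -> np.ndarray:
    """Framewise displacement: sum of absolute differentiated realignment
    values, rotations expressed as arc length on a ``head_radius_mm`` sphere.
    fd[0] = 0 by convention."""
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValidationError("motion must have 6 columns")
    conv = motion.copy()
    conv[:, 3:] *= head_radius_mm
    fd = np.zeros(len(motion))
    fd[1:] = np.abs(np.diff(conv, axis=0)).sum(axis=1)
    return fd


def build_censor_mask(fd: np.ndarray, threshold: float = 0.25,
                      min_segment: int = 5,
                      min_run_uncensored: int = 50) -> CensorMask:
    """Censor frames with FD above threshold, then censor surviving
    contiguous segments shorter than ``min_segment``.  The run is flagged
    excluded when fewer than ``min_run_uncensored`` frames survive."""
    fd = np.asarray(fd, dtype=float)
    keep = fd <= threshold
    # censor surviving islands shorter than min_segment
    i = 0
    t = len(keep)
    while i < t:
        if keep[i]:
            j = i
            while j < t and keep[j]:
                j += 1
            if j - i < min_segment:
                keep[i:j] = False
            i = j
        else:
            i += 1
    return CensorMask(keep=keep, fd=fd,
                      run_included=bool(keep.sum() >= min_run_uncensored))


def subject_inclusion(censor_masks: list[CensorMask], tr_seconds: float,
                      min_uncensored_minutes: float = 5.0) -> bool:
    """Include a subject when total uncensored time across included runs
    reaches ``min_uncensored_minutes`` (inclusive boundary)."""
    total = sum(m.n_uncensored for m in censor_masks if m.run_included)
    return total * tr_seconds >= min_uncensored_minutes * 60.0


# ---------------------------------------------------------------------------
# nuisance regression

def volterra_motion_block(motion: np.ndarray) -> np.ndarray:
    """36-column Volterra expansion: the 6 motion parameters, their squares,
    the parameters at the previous two frames, and the previous two frames
    squared.  Lag columns are zero-filled at the run start."""
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValidationError("motion must have 6 columns")
    t = len(motion)
    lag1 = np.zeros_like(motion)
    lag2 = np.zeros_like(motion)
    lag1[1:] = motion[:-1]
    lag2[2:] = motion[:-2]
    return np.column_stack([motion, motion ** 2, lag1, lag2, lag1 ** 2, lag2 ** 2])


def build_nuisance_matrix(motion: np.ndarray, bold: np.ndarray,
                          masks: dict[str, np.ndarray]) -> np.ndarray:
    """[t x 43] design: 36 Volterra motion columns, CSF / WM / global tissue
    means, their first derivatives (difference from the previous frame,
    zero at frame 0), and a constant."""
    mot = volterra_motion_block(motion)
    t = len(mot)
    tissue = []
    for name in ("csf", "wm", "whole_brain"):
        mask = masks.get(name)
        if mask is None or not mask.any():
            raise IntegrityError(f"tissue mask {name!r} is empty or missing")
        tissue.append(bold[mask].mean(axis=0))
    tissue = np.column_stack(tissue)
    deriv = np.zeros_like(tissue)
    deriv[1:] = np.diff(tissue, axis=0)
    return np.column_stack([mot, tissue, deriv, np.ones(t)])


def nuisance_regress(bold: np.ndarray, regressors: np.ndarray,
                     censor: CensorMask) -> np.ndarray:
    """Fit the design by least squares on uncensored frames only; subtract
    the fitted values at *all* frames.  Censored frames therefore never
    influence the coefficients."""
    shape = bold.shape
    t = shape[-1]
    y = bold.reshape(-1, t).T  # [t, voxels]
    keep = censor.keep
    x = regressors[keep]
    # rank check on the uncensored design
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify offending columns by pivoted QR
        _, r, piv = _qr_pivot(x)
        bad = sorted(piv[rank:].tolist())
        raise ValidationError(
            f"nuisance design rank-deficient on uncensored frames; "
            f"dependent columns: {bad}")
    from scipy.linalg import lstsq as _lstsq
    beta = _lstsq(x, y[keep], lapack_driver="gelsy", check_finite=False)[0]
    resid = y - regressors @ beta
    return resid.T.reshape(shape)


def _qr_pivot(x: np.ndarray):
    from scipy.linalg import qr
    q, r, piv = qr(x, pivoting=True, mode="economic")
    return q, r, piv


# ---------------------------------------------------------------------------
# spectral interpolation of censored frames

def spectral_interpolate(bold: np.ndarray, censor: CensorMask,
                         tr_seconds: float, oversample: int = 8,
                         penalty: float = 1.0,
                         penalty_floor: float = 1e-4) -> np.ndarray:
    """Reconstitute censored frames from the spectral content of the
    uncensored frames.

    Sine/cosine amplitudes on a Lomb-Scargle frequency grid (spacing
    1 / (oversample * span), up to Nyquist) are fit jointly by penalized
    least squares to the non-uniformly sampled uncensored series; the
    penalty grows as (f / f_nyquist)^4, which suppresses high-frequency
    ringing inside censored gaps while leaving the low-frequency fit
    essentially unconstrained.  The normal equations are solved in the
    n_uncensored-dimensional dual space, so the cost is linear in the
    number of voxels.  Only censored frames are replaced; uncensored
    frames pass through bit-identical.
    """
    keep = censor.keep
    n = bold.shape[-1]
    if keep.sum() < 2:
        raise IntegrityError("fewer than 2 uncensored frames; run unrecoverable")
    if keep.all():
        return bold.copy()
    shape = bold.shape
    y = bold.reshape(-1, n).T            # [t, voxels]
    t_all = np.arange(n) * tr_seconds
    t_obs = t_all[keep]
    yk = y[keep]
    mean = yk.mean(axis=0)
    yc = yk - mean

    span = t_obs[-1] - t_obs[0]
    nyq = 1.0 / (2.0 * tr_seconds)
    n_freq = int(np.floor(oversample * keep.sum() / 2))
    freqs = np.arange(1, n_freq + 1) / (span * oversample)
    freqs = freqs[freqs <= nyq]
    w = 2.0 * np.pi * freqs

    t_cens = t_all[~keep]
    a_obs = np.concatenate([np.cos(np.outer(t_obs, w)),
                            np.sin(np.outer(t_obs, w))], axis=1)   # [m, p]
    a_cens = np.concatenate([np.cos(np.outer(t_cens, w)),
                             np.sin(np.outer(t_cens, w))], axis=1)  # [n_cens, p]
    d_inv = 1.0 / np.tile(penalty_floor + (freqs / nyq) ** 4, 2)   # [p]

    # min ||A c - y||^2 + penalty * c' D c  via the dual (push-through) form:
    # c = D^-1 A' (A D^-1 A' + penalty I)^-1 y
    from scipy.linalg import solve as _solve
    b = a_obs * d_inv                                   # [m, p]
    m_dual = b @ a_obs.T + penalty * np.eye(len(t_obs))
    alpha = _solve(m_dual, yc, assume_a="pos", check_finite=False)
    g_cens = a_cens @ b.T                               # [n_cens, m]
    recon_cens = g_cens @ alpha + mean

    out = y.copy()
    out[~keep] = recon_cens
    return out.T.reshape(shape)


# ---------------------------------------------------------------------------
# band-pass filter

def bandpass(bold: np.ndarray, tr_seconds: float, f_lo: float = 0.009,
             f_hi: float = 0.08, taper_width_hz: float = 0.002) -> np.ndarray:
    """Zero-phase FFT band-pass with raised-cosine band edges; DC removed.
    The series must already be uniformly sampled (after interpolation)."""
    nyq = 1.0 / (2.0 * tr_seconds)
    if f_hi >= nyq:
        raise ValidationError(f"f_hi={f_hi} must be below Nyquist {nyq:.4f} Hz")
    n = bold.shape[-1]
    freqs = np.fft.rfftfreq(n, d=tr_seconds)
    gain = np.zeros_like(freqs)
    inside = (freqs >= f_lo) & (freqs <= f_hi)
    gain[inside] = 1.0
    if taper_width_hz > 0:
        lo_edge = (freqs >= f_lo - taper_width_hz) & (freqs < f_lo)
        gain[lo_edge] = 0.5 * (1 + np.cos(np.pi * (f_lo - freqs[lo_edge]) / taper_width_hz))
        hi_edge = (freqs > f_hi) & (freqs <= f_hi + taper_width_hz)
        gain[hi_edge] = 0.5 * (1 + np.cos(np.pi * (freqs[hi_edge] - f_hi) / taper_width_hz))
    gain[freqs == 0] = 0.0
    spec = np.fft.rfft(bold, axis=-1)
    return np.fft.irfft(spec * gain, n=n, axis=-1)


# ---------------------------------------------------------------------------
# seed definition and seed map

def seed_sphere_voxels(center_mni, radius_mm: float, affine: np.ndarray,
                       grid_shape) -> np.ndarray:
    """Indices [k, 3] of voxels whose world-space centers lie within
    ``radius_mm`` of ``center_mni``."""
    grid_shape = tuple(grid_shape)
    idx = np.indices(grid_shape).reshape(3, -1).T.astype(float)
    world = idx @ affine[:3, :3].T + affine[:3, 3]
    d2 = ((world - np.asarray(center_mni, dtype=float)) ** 2).sum(axis=1)
    sel = idx[d2 <= radius_mm ** 2].astype(int)
    if len(sel) == 0:
        raise ValidationError(
            f"seed sphere at {tuple(center_mni)} r={radius_mm} mm selects no voxels")
    return sel


Z_CLIP = 1.0 - 1e-7


def seed_map(bold: np.ndarray, seed_voxels: np.ndarray, censor: CensorMask,
             affine: np.ndarray, subject_id: str = "",
             seed_center_mni=(0.0, 25.0, -10.0),
             seed_radius_mm: float = 4.0,
             stage_log: list[str] | None = None) -> SeedMap:
    """Fisher-z map of the correlation, over uncensored frames, between the
    mean seed time course and every voxel.  Zero-variance voxels get z = 0
    and are flagged; seed voxels are flagged."""
    keep = censor.keep
    sx, sy, sz = seed_voxels.T
    seed_ts = bold[sx, sy, sz][:, keep].mean(axis=0)
    y = bold[..., keep]
    yc = y - y.mean(axis=-1, keepdims=True)
    sc = seed_ts - seed_ts.mean()
    s_norm = np.sqrt((sc ** 2).sum())
    v_norm = np.sqrt((yc ** 2).sum(axis=-1))
    scale = np.abs(y).max(axis=-1)  # constant voxels leave rounding residue
    zero_var = (v_norm <= 1e-10 * np.maximum(scale, 1.0)) | (s_norm == 0)
    denom = np.where(v_norm == 0, 1.0, v_norm) * (s_norm if s_norm > 0 else 1.0)
    r = (yc @ sc) / denom
    r[zero_var] = 0.0
    z = np.arctanh(np.clip(r, -Z_CLIP, Z_CLIP))
    seed_flags = np.zeros(bold.shape[:3], dtype=bool)
    seed_flags[sx, sy, sz] = True
    return SeedMap(z=z, subject_id=subject_id,
                   n_uncensored_frames=int(keep.sum()),
                   seed_center_mni=tuple(float(c) for c in seed_center_mni),
                   seed_radius_mm=float(seed_radius_mm),
                   seed_voxel_flags=seed_flags,
                   zero_variance_flags=zero_var,
                   stage_log=list(stage_log or []))


# ---------------------------------------------------------------------------
# full per-run stream

def process_run(run: BoldRun, fd_threshold: float = 0.25,
                band: tuple[float, float] = (0.009, 0.08),
                seed_center_mni=(0.0, 25.0, -10.0),
                seed_radius_mm: float = 4.0,
                min_segment: int = 5,
                min_run_uncensored: int = 50) -> tuple[SeedMap | None, CensorMask]:
    """Censor -> regress -> interpolate -> bandpass -> correlate-on-uncensored.

    Returns (SeedMap, CensorMask); SeedMap is None when the run fails the
    50-uncensored-frame rule.  The stage sequence actually executed is
    recorded in the SeedMap's stage log.
    """
    log: list[str] = []
    fd = compute_fd(run.motion)
    censor = build_censor_mask(fd, threshold=fd_threshold,
                               min_segment=min_segment,
                               min_run_uncensored=min_run_uncensored)
    log.append("censor")
    if not censor.run_included:
        return None, censor
    design = build_nuisance_matrix(run.motion, run.data, run.masks)
    resid = nuisance_regress(run.data, design, censor)
    log.append("regress")
    interp = spectral_interpolate(resid, censor, run.tr_seconds)
    log.append("interpolate")
    filtered = bandpass(interp, run.tr_seconds, f_lo=band[0], f_hi=band[1])
    log.append("bandpass")
    seed_vox = seed_sphere_voxels(seed_center_mni, seed_radius_mm,
                                  run.affine, run.data.shape[:3])
    sm = seed_map(filtered, seed_vox, censor, run.affine,
                  subject_id=run.subject_id, seed_center_mni=seed_center_mni,
                  seed_radius_mm=seed_radius_mm, stage_log=log + ["correlate"])
    assert tuple(sm.stage_log) == PIPELINE_STAGES
    return sm, censor
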