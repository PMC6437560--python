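"""Voxelwise brain-behavior correlation with cluster-extent correction.

Across subjects, each voxel's Fisher-z seed-connectivity value is Pearson-
correlated with a behavioral covariate (t with df = N - 2, two-tailed p).
Multiple comparisons are controlled by a cluster-extent threshold
calibrated from a Monte-Carlo null: white-noise volumes smoothed with a
Gaussian kernel matched to the estimated map smoothness (a documented,
self-contained stand-in for AFNI 3dClustSim's ACF model — the two nulls
differ and reports carry the calibration parameters).  Replication across
cohorts is tested by masking the second cohort's map with the first
cohort's cluster and re-calibrating the extent threshold within the mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats


class ValidationError(ValueError):
    pass


@dataclass
class GroupResult:
    r_map: np.ndarray
    t_map: np.ndarray
    p_map: np.ndarray
    n_subjects: int
    covariate_name: str
    analysis_mask: np.ndarray
    affine: np.ndarray | None = None
    voxel_mm: float = 3.0
    metadata: dict = field(default_factory=dict)

    @property
    def df(self) -> int:
        return self.n_subjects - 2


@dataclass
class NullCalibration:
    fwhm_mm: float
    voxel_p: float
    n_iterations: int
    extent_threshold: int
    corrected_alpha: float
    rng_seed: int
    mask_voxels: int = 0
    n_subjects: int = 0   # 0: single smoothed z-field null; >0: correlation-field null

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("fwhm_mm", "voxel_p", "n_iterations", "extent_threshold",
                 "corrected_alpha", "rng_seed", "mask_voxels", "n_subjects")}


CLUSTER_COLUMNS = ["label", "peak_x_mm", "peak_y_mm", "peak_z_mm", "peak_t",
                   "extent_voxels", "volume_mm3", "passed_correction"]


def voxelwise_correlate(z_stack: np.ndarray, covariate: np.ndarray,
                        mask: np.ndarray, covariate_name: str = "covariate",
                        affine: np.ndarray | None = None,
                        voxel_mm: float = 3.0) -> GroupResult:
    """Per-voxel Pearson r across subjects between Fisher-z connectivity and
    the covariate; t = r sqrt(df) / sqrt(1 - r^2), p two-tailed.

    ``z_stack`` is [n_subjects, x, y, z].
    """
    cov = np.asarray(covariate, dtype=float)
    n = len(cov)
    if z_stack.shape[0] != n:
        raise ValidationError("covariate length does not match subject stack")
    if n < 3:
        raise ValidationError("need >= 3 subjects")
    if not np.all(np.isfinite(cov)) or np.ptp(cov) == 0:
        raise ValidationError("covariate must be finite and non-constant")
    shape = z_stack.shape[1:]
    y = z_stack.reshape(n, -1)
    yc = y - y.mean(axis=0)
    cc = cov - cov.mean()
    y_norm = np.sqrt((yc ** 2).sum(axis=0))
    denom = np.where(y_norm == 0, 1.0, y_norm) * np.sqrt((cc ** 2).sum())
    r = (cc @ yc) / denom
    r[y_norm == 0] = 0.0
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df) / np.sqrt(np.maximum(1 - r ** 2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    res = GroupResult(r_map=r.reshape(shape), t_map=t.reshape(shape),
                      p_map=p.reshape(shape), n_subjects=n,
                      covariate_name=covariate_name,
                      analysis_mask=np.asarray(mask, dtype=bool),
                      affine=affine, voxel_mm=voxel_mm)
    _assert_result_invariants(res)
    return res


def _assert_result_invariants(res: GroupResult) -> None:
    assert res.df == res.n_subjects - 2
    m = res.analysis_mask & (np.abs(res.r_map) < 1)
    t_check = res.r_map[m] * np.sqrt(res.df) / np.sqrt(1 - res.r_map[m] ** 2)
    assert np.allclose(t_check, res.t_map[m], rtol=1e-8, atol=1e-8)


def estimate_fwhm(maps: np.ndarray, voxel_mm: float,
                  mask: np.ndarray | None = None) -> float:
    """Gaussian-kernel-equivalent FWHM (mm) of a stack of 3D maps.

    For white noise convolved with a Gaussian of standard deviation s, the
    lag-1 spatial autocorrelation is exp(-d^2 / (4 s^2)); s is recovered
    from the variance of first differences relative to total variance and
    averaged across axes and maps.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim == 3:
        maps = maps[None]
    if maps.shape[0] < 1:
        raise ValidationError("need at least one map")
    ratios = []
    for vol in maps:
        v = vol[mask].var() if mask is not None else vol.var()
        if v == 0:
            raise ValidationError("zero spatial variance")
        for ax in range(3):
            d = np.diff(vol, axis=ax)
            ratios.append(d.var() / v)
    ratio = float(np.mean(ratios))
    rho = max(1.0 - ratio / 2.0, 1e-12)
    if rho >= 1.0:
        raise ValidationError("degenerate spatial autocorrelation")
    s2 = -voxel_mm ** 2 / (4.0 * np.log(rho))
    return float(np.sqrt(8.0 * np.log(2.0) * s2))


def _smooth_null_volume(shape, fwhm_mm: float, voxel_mm: float,
                        rng: np.random.Generator) -> np.ndarray:
    vol = rng.standard_normal(shape)
    if fwhm_mm > 0:
        sigma_vox = fwhm_mm / (np.sqrt(8 * np.log(2)) * voxel_mm)
        vol = ndimage.gaussian_filter(vol, sigma_vox, mode="constant")
    return vol


def _label_clusters(supra: np.ndarray, connectivity: str = "face"):
    if connectivity == "face":
        structure = ndimage.generate_binary_structure(3, 1)
    elif connectivity == "edge":
        structure = ndimage.generate_binary_structure(3, 2)
    elif connectivity == "corner":
        structure = ndimage.generate_binary_structure(3, 3)
    else:
        raise ValidationError(f"unknown connectivity {connectivity!r}")
    return ndimage.label(supra, structure=structure)


def cluster_extent_threshold(mask: np.ndarray, fwhm_mm: float, voxel_mm: float,
                             voxel_p: float = 0.01,
                             corrected_alpha: float = 0.05,
                             n_iterations: int = 1000,
                             rng_seed: int = 0,
                             two_tailed: bool = True,
                             connectivity: str = "face",
                             n_subjects: int = 0) -> NullCalibration:
    """Monte-Carlo minimum cluster extent controlling the family-wise rate.

    With ``n_subjects`` = 0, each iteration smooths one white-noise volume
    to ``fwhm_mm``, standardizes it over the mask and thresholds at the
    ``voxel_p`` z-quantile — the null of a smooth Gaussian z field.

    With ``n_subjects`` = n > 0, each iteration simulates the statistic the
    group stage actually computes: n independent white-noise subject
    volumes smoothed to ``fwhm_mm`` are correlated voxelwise with a random
    covariate and the r field is thresholded at the parametric ``voxel_p``
    quantile (t with df = n - 2).  At small n the suprathreshold count of a
    correlation field is heavily overdispersed — every voxel's r is a
    projection of its subject vector onto the same random covariate
    direction — and a single-field null underestimates the max cluster
    extent; simulating the correlation field reproduces that behavior.

    Either way the reported threshold is the smallest extent k whose null
    exceedance probability P(max extent >= k) is at most
    ``corrected_alpha`` (the survival form of the (1 - alpha) quantile,
    which stays valid when the extent distribution is discrete).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValidationError("empty analysis mask")
    if not (0 < voxel_p < 1 and 0 < corrected_alpha < 1):
        raise ValidationError("voxel_p and corrected_alpha must lie in (0, 1)")
    rng = np.random.default_rng(rng_seed)
    maxima = np.zeros(n_iterations, dtype=int)
    if n_subjects:
        if n_subjects < 3:
            raise ValidationError("correlation-field null needs n_subjects >= 3")
        df = n_subjects - 2
        tc = stats.t.isf(voxel_p / 2 if two_tailed else voxel_p, df)
        r_crit = tc / np.sqrt(tc ** 2 + df)
        flat_mask = mask.ravel()
        sigma_vox = fwhm_mm / (np.sqrt(8 * np.log(2)) * voxel_mm)
        for i in range(n_iterations):
            vols = rng.standard_normal((n_subjects,) + mask.shape)
            if fwhm_mm > 0:
                vols = ndimage.gaussian_filter(
                    vols, (0, sigma_vox, sigma_vox, sigma_vox), mode="constant")
            subj = vols.reshape(n_subjects, -1)[:, flat_mask]
            cov = rng.standard_normal(n_subjects)
            yc = subj - subj.mean(axis=0)
            cc = cov - cov.mean()
            norm = np.sqrt((yc ** 2).sum(axis=0)) * np.sqrt((cc ** 2).sum())
            norm[norm == 0] = 1.0
            r = (cc @ yc) / norm
            supra = np.zeros(mask.shape, dtype=bool)
            supra.ravel()[flat_mask] = (np.abs(r) if two_tailed else r) > r_crit
            labels, n_lab = _label_clusters(supra, connectivity)
            if n_lab:
                maxima[i] = np.bincount(labels.ravel())[1:].max()
    else:
        zc = stats.norm.isf(voxel_p / 2 if two_tailed else voxel_p)
        for i in range(n_iterations):
            vol = _smooth_null_volume(mask.shape, fwhm_mm, voxel_mm, rng)
            vals = vol[mask]
            z = (vol - vals.mean()) / vals.std()
            supra = (np.abs(z) if two_tailed else z) > zc
            supra &= mask
            labels, n_lab = _label_clusters(supra, connectivity)
            if n_lab:
                maxima[i] = np.bincount(labels.ravel())[1:].max()
    extent = int(np.ceil(np.quantile(maxima, 1.0 - corrected_alpha)))
    while (maxima >= extent).mean() > corrected_alpha:
        extent += 1
    return NullCalibration(fwhm_mm=float(fwhm_mm), voxel_p=float(voxel_p),
                           n_iterations=int(n_iterations),
                           extent_threshold=max(extent, 1),
                           corrected_alpha=float(corrected_alpha),
                           rng_seed=int(rng_seed),
                           mask_voxels=int(mask.sum()),
                           n_subjects=int(n_subjects))


def find_clusters(result: GroupResult, voxel_p: float = 0.01,
                  calibration: NullCalibration | None = None,
                  connectivity: str = "face",
                  positive_only: bool = False) -> pd.DataFrame:
    """Suprathreshold clusters of the t map under face adjacency.

    Voxels with |t| above the two-tailed ``voxel_p`` quantile (or t above
    the one-tailed quantile when ``positive_only``) are grouped; each row
    reports the peak world coordinate, peak t, extent and volume, plus
    whether the extent passes the calibrated correction.
    """
    df = result.df
    if positive_only:
        tc = stats.t.isf(voxel_p, df)
        supra = result.t_map > tc
    else:
        tc = stats.t.isf(voxel_p / 2, df)
        supra = np.abs(result.t_map) > tc
    supra &= result.analysis_mask
    labels, n_lab = _label_clusters(supra, connectivity)
    rows = []
    extent_thr = calibration.extent_threshold if calibration else None
    for lab in range(1, n_lab + 1):
        vox = np.argwhere(labels == lab)
        tvals = result.t_map[tuple(vox.T)]
        peak_i = int(np.argmax(np.abs(tvals)))
        peak_vox = vox[peak_i]
        if result.affine is not None:
            peak_mm = result.affine[:3, :3] @ peak_vox + result.affine[:3, 3]
        else:
            peak_mm = peak_vox * result.voxel_mm
        rows.append({
            "label": lab,
            "peak_x_mm": float(peak_mm[0]),
            "peak_y_mm": float(peak_mm[1]),
            "peak_z_mm": float(peak_mm[2]),
            "peak_t": float(tvals[peak_i]),
            "extent_voxels": int(len(vox)),
            "volume_mm3": float(len(vox) * result.voxel_mm ** 3),
            "passed_correction": bool(extent_thr is not None
                                      and len(vox) >= extent_thr),
        })
    table = pd.DataFrame(rows, columns=CLUSTER_COLUMNS)
    return table.sort_values("extent_voxels", ascending=False).reset_index(drop=True)


def cluster_mask(result: GroupResult, table: pd.DataFrame,
                 voxel_p: float = 0.01, connectivity: str = "face",
                 passed_only: bool = True,
                 positive_only: bool = False) -> np.ndarray:
    """Boolean mask of the voxels belonging to (corrected) clusters."""
    df = result.df
    if positive_only:
        tc = stats.t.isf(voxel_p, df)
        supra = result.t_map > tc
    else:
        tc = stats.t.isf(voxel_p / 2, df)
        supra = np.abs(result.t_map) > tc
    supra &= result.analysis_mask
    labels, _ = _label_clusters(supra, connectivity)
    keep = np.zeros_like(supra)
    sel = (table.loc[table["passed_correction"].astype(bool)]
           if passed_only else table)
    for lab in sel["label"]:
        keep |= labels == lab
    return keep


def mask_replicate(result_b: GroupResult, cluster_mask_a: np.ndarray,
                   voxel_p: float = 0.01, corrected_alpha: float = 0.05,
                   fwhm_mm: float | None = None,
                   n_iterations: int = 1000, rng_seed: int = 0,
                   positive_only: bool = True,
                   connectivity: str = "face") -> tuple[pd.DataFrame, NullCalibration]:
    """Replication test: threshold cohort B's map only within cohort A's
    cluster mask, with the extent threshold re-calibrated for the smaller
    search volume.  One-sided positive by default (the replication question
    is directional)."""
    cluster_mask_a = np.asarray(cluster_mask_a, dtype=bool)
    if cluster_mask_a.shape != result_b.t_map.shape:
        raise ValidationError("mask shape mismatch")
    if not cluster_mask_a.any():
        raise ValidationError("empty replication mask")
    restricted = GroupResult(
        r_map=result_b.r_map, t_map=result_b.t_map, p_map=result_b.p_map,
        n_subjects=result_b.n_subjects, covariate_name=result_b.covariate_name,
        analysis_mask=result_b.analysis_mask & cluster_mask_a,
        affine=result_b.affine, voxel_mm=result_b.voxel_mm)
    if fwhm_mm is None:
        fwhm_mm = result_b.metadata.get("fwhm_mm", 2.0 * result_b.voxel_mm)
    calib = cluster_extent_threshold(
        restricted.analysis_mask, fwhm_mm, result_b.voxel_mm,
        voxel_p=voxel_p, corrected_alpha=corrected_alpha,
        n_iterations=n_iterations, rng_seed=rng_seed,
        two_tailed=not positive_only, connectivity=connectivity,
        n_subjects=result_b.n_subjects)
    table = find_clusters(restricted, voxel_p=voxel_p, calibration=calib,
                          connectivity=connectivity, positive_only=positive_only)
    return table, calib


def overlap_report(masks: dict[str, np.ndarray],
                   affine: np.ndarray | None = None) -> pd.DataFrame:
    """Pairwise and all-way voxel intersections of named boolean masks, with
    the world coordinate of each intersection's |position| peak count."""
    names = list(masks)
    shapes = {m.shape for m in masks.values()}
    if len(shapes) != 1:
        raise ValidationError("mask shapes differ")
    rows = []

    def _entry(label: str, inter: np.ndarray):
        coords = np.argwhere(inter)
        if len(coords) and affine is not None:
            center = coords.mean(axis=0)
            world = affine[:3, :3] @ center + affine[:3, 3]
        else:
            world = (np.nan, np.nan, np.nan)
        rows.append({"masks": label, "overlap_voxels": int(inter.sum()),
                     "centroid_x_mm": float(world[0]),
                     "centroid_y_mm": float(world[1]),
                     "centroid_z_mm": float(world[2])})

    for name in names:
        _entry(name, masks[name].astype(bool))
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            inter = masks[names[i]].astype(bool) & masks[names[j]].astype(bool)
            _entry(f"{names[i]} & {names[j]}", inter)
    if len(names) > 2:
        inter = np.ones_like(next(iter(masks.values())), dtype=bool)
        for m in masks.values():
            inter &= m.astype(bool)
        _entry(" & ".join(names), inter)
    return pd.DataFrame(rows)
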