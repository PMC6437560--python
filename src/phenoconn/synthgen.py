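"""Two-cohort synthetic study generator with known ground truth.

Emulates the study conditions every downstream stage is tested against:

* per-subject phone event streams (unlock sessions, still intervals,
  location observations, hourly heartbeats) whose daily unlock totals are a
  monotone function of a latent severity trait; Cohort 2's stream is
  observed through a duty-cycled schedule sampling 1 min of every 10-min
  cycle, extended to 3 min when a (Bernoulli) conversation is detected;
* day x epoch structure (9-18 day, 18-24 evening, 0-9 night) whose
  day-to-day profile consistency is tunable so the realized circadian ICC
  tracks ``icc_consistency``;
* ordinal PHQ-8 / PHQ-4 items generated by thresholding the latent trait;
* band-limited BOLD runs in which seed-target connectivity strength
  covaries across subjects with the behavioral covariate at a target
  correlation ``effect_r``, plus motion traces with censorable spikes.

All randomness flows from ``CohortConfig.rng_seed`` through fixed
``SeedSequence`` spawn keys, so regeneration is byte-identical and adding a
stage never perturbs another stage's draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CohortConfig, ConfigurationError
from .rsfc import BoldRun, seed_sphere_voxels

# epoch boundaries, minutes from local midnight: night [0,540), day [540,1080),
# evening [1080,1440)
EPOCHS = ("day", "evening", "night")
EPOCH_BOUNDS_MIN = {"day": (540, 1080), "evening": (1080, 1440), "night": (0, 540)}
EPOCH_LENGTH_MIN = {e: b[1] - b[0] for e, b in EPOCH_BOUNDS_MIN.items()}

BASE_DATE = pd.Timestamp("2022-01-03")  # study day 0, naive local clock
BASE_LAT, BASE_LON = 43.70, -72.29

# duty-cycled schedule constants: 10-min cycles, 1-min windows, 3-min when a
# conversation is detected during the window
CYCLE_S, WINDOW_S, EXT_WINDOW_S = 600.0, 60.0, 180.0

# spawn-key domain codes (stable; never renumber)
_DOM_COHORT, _DOM_PHONE, _DOM_SURVEY, _DOM_BOLD = 0, 1, 2, 3

# BOLD signal mixture amplitudes (relative to unit-variance components):
# every brain voxel carries a shared global fluctuation so that global-signal
# regression removes the physiological component rather than the planted
# seed-target coupling (in real data the seed network is a small part of the
# global mean; with purely independent noise it would dominate it)
GLOBAL_AMPLITUDE = 0.25
SEED_NOISE_AMPLITUDE = 0.2
TARGET_NOISE_AMPLITUDE = 0.2

EVENT_COLUMNS = ["subject_id", "event_type", "start", "end", "latitude", "longitude"]


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


@dataclass
class SubjectParams:
    """Latent per-subject traits drawn once at the cohort level."""

    subject_id: str
    latent_severity: float          # z-scored trait driving phone use and PHQ
    connectivity_weight: float      # planted seed->target coupling
    epoch_offsets_still: np.ndarray  # [3], consistency-scaled profile
    epoch_offsets_loc: np.ndarray    # [3]
    index: int = 0


@dataclass
class GroundTruth:
    """Cohort-level ground truth for parameter-recovery tests.

    connectivity_weight = intercept + slope * (effect_r * severity_z +
    sqrt(1 - effect_r^2) * noise); severity_z doubles as the standardized
    latent behavior covariate.
    """

    table: pd.DataFrame             # subject_id, latent_severity, behavior_covariate, connectivity_weight
    seed_region_voxels: np.ndarray  # [k, 3]
    target_region_voxels: np.ndarray
    intercept: float
    slope: float


# ---------------------------------------------------------------------------
# subject traits

W_INTERCEPT = 0.5
W_SLOPE = 0.3


def draw_subjects(config: CohortConfig, prefix: str = "S") -> list[SubjectParams]:
    rng = _rng(config.rng_seed, _DOM_COHORT)
    n = config.n_subjects
    severity = rng.normal(size=n)
    noise = rng.normal(size=n)
    r = config.effect_r
    if r == 0.0:
        # global-null construction: no planted coupling anywhere, so the
        # target region carries no coherent across-subject signal (neither
        # behavioral nor latent-sampling) and null calibration is clean
        w = np.zeros(n)
    else:
        w = W_INTERCEPT + W_SLOPE * (r * severity + np.sqrt(1 - r ** 2) * noise)
    c = config.icc_consistency
    subs = []
    for i in range(n):
        subs.append(SubjectParams(
            subject_id=f"{prefix}{i:03d}",
            latent_severity=float(severity[i]),
            connectivity_weight=float(w[i]),
            epoch_offsets_still=np.sqrt(c) * rng.normal(size=3),
            epoch_offsets_loc=np.sqrt(c) * rng.normal(size=3),
            index=i,
        ))
    return subs


# ---------------------------------------------------------------------------
# phone streams

def _place_intervals(total_min: float, n_pieces: int, epoch: str, day: int,
                     rng: np.random.Generator):
    """Split ``total_min`` into ``n_pieces`` non-overlapping intervals inside
    the epoch window of study day ``day``; durations are log-normal weights
    scaled to sum exactly to ``total_min``."""
    lo, hi = EPOCH_BOUNDS_MIN[epoch]
    length = hi - lo
    total_min = float(min(total_min, length))
    if total_min <= 0:
        return []
    n_pieces = max(1, n_pieces)
    weights = rng.lognormal(mean=0.0, sigma=0.9, size=n_pieces)
    durs = weights / weights.sum() * total_min
    slack = length - total_min
    gaps = rng.dirichlet(np.ones(n_pieces + 1)) * slack
    out = []
    cursor = lo + gaps[0]
    day_start = BASE_DATE + pd.Timedelta(days=day)
    for k in range(n_pieces):
        start = day_start + pd.Timedelta(minutes=cursor)
        end = day_start + pd.Timedelta(minutes=cursor + durs[k])
        out.append((start, end))
        cursor += durs[k] + gaps[k + 1]
    return out


def _epoch_weights(rng: np.random.Generator) -> np.ndarray:
    base = np.array([0.45, 0.35, 0.20])  # day, evening, night
    w = base * np.exp(0.25 * rng.normal(size=3))
    return w / w.sum()


def generate_phone_stream(subject: SubjectParams, config: CohortConfig
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (events, schedule) for one subject.

    events follows the EventStream TSV schema; schedule has one row per
    (calendar day, epoch) with the realized sampling-coverage fraction
    (1.0 under continuous sampling).
    """
    if config.n_days <= 0:
        raise ConfigurationError("n_days must be positive")
    rng = _rng(config.rng_seed, _DOM_PHONE, subject.index)
    c = config.icc_consistency
    rows: list[tuple] = []
    pool = [(i, j) for i in range(6) for j in range(5)]  # 100 m location cells

    for day in range(config.n_days):
        day_start = BASE_DATE + pd.Timedelta(days=day)
        if rng.random() < config.missing_day_rate:
            continue
        # hourly heartbeats -> full quality-coverage day
        for h in range(24):
            ts = day_start + pd.Timedelta(hours=h)
            rows.append((subject.subject_id, "heartbeat", ts, ts, np.nan, np.nan))

        # unlock sessions: daily total is monotone in severity
        total = (config.unlock_mean_minutes
                 + config.unlock_per_severity_minutes * subject.latent_severity
                 + config.unlock_noise_sd_minutes * rng.normal())
        total = float(np.clip(total, 0.0, 0.75 * 1440))
        w = _epoch_weights(rng)
        for e_idx, epoch in enumerate(EPOCHS):
            alloc = total * w[e_idx]
            n_sessions = 1 + rng.poisson(5)
            for start, end in _place_intervals(alloc, n_sessions, epoch, day, rng):
                rows.append((subject.subject_id, "unlock_session", start, end,
                             np.nan, np.nan))

        # still intervals: epoch profile with tunable day-to-day consistency
        day_effect = 0.3 * config.still_profile_sd_minutes * rng.normal()
        for e_idx, epoch in enumerate(EPOCHS):
            v = (config.still_mean_minutes / 3.0
                 + config.still_profile_sd_minutes * subject.epoch_offsets_still[e_idx]
                 + np.sqrt(1 - c) * config.still_profile_sd_minutes * rng.normal()
                 + day_effect)
            v = float(np.clip(v, 0.0, EPOCH_LENGTH_MIN[epoch]))
            for start, end in _place_intervals(v, 3, epoch, day, rng):
                rows.append((subject.subject_id, "still_interval", start, end,
                             np.nan, np.nan))

        # location observations: unique-cell count per epoch with consistency
        for e_idx, epoch in enumerate(EPOCHS):
            n_loc = (4.0 + 2.0 * (subject.epoch_offsets_loc[e_idx]
                                  + np.sqrt(1 - c) * rng.normal()))
            n_loc = int(np.clip(np.round(n_loc), 0, len(pool)))
            if n_loc == 0:
                continue
            cells = rng.choice(len(pool), size=n_loc, replace=False)
            lo, hi = EPOCH_BOUNDS_MIN[epoch]
            for cell in cells:
                ci, cj = pool[cell]
                lat = BASE_LAT + ci * (100.0 / 110540.0)
                lon = BASE_LON + cj * (100.0 / (111320.0 * np.cos(np.radians(BASE_LAT))))
                ts = day_start + pd.Timedelta(minutes=float(rng.uniform(lo, hi)))
                rows.append((subject.subject_id, "location_obs", ts, ts, lat, lon))

    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    events = events.sort_values(["start", "end"], kind="stable").reset_index(drop=True)

    if config.sampling_mode == "duty_cycled":
        events, schedule = _apply_duty_cycle(events, subject, config, rng)
    else:
        schedule = _full_coverage_schedule(subject.subject_id, events)
    return events, schedule


def _full_coverage_schedule(subject_id: str, events: pd.DataFrame) -> pd.DataFrame:
    days = sorted(set(events["start"].dt.normalize())) if len(events) else []
    rows = [(subject_id, d.date().isoformat(), e, 1.0) for d in days for e in EPOCHS]
    return pd.DataFrame(rows, columns=["subject_id", "day", "epoch", "coverage"])


def duty_cycle_windows(day_start: pd.Timestamp, conversation: np.ndarray
                       ) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Sampling windows for one day: 1 min at the head of each 10-min cycle,
    3 min for cycles where ``conversation`` is True (144 cycles/day)."""
    out = []
    for i in range(144):
        t0 = day_start + pd.Timedelta(seconds=i * CYCLE_S)
        dur = EXT_WINDOW_S if conversation[i] else WINDOW_S
        out.append((t0, t0 + pd.Timedelta(seconds=dur)))
    return out


def _apply_duty_cycle(events: pd.DataFrame, subject: SubjectParams,
                      config: CohortConfig, rng: np.random.Generator
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict interval events to the duty-cycle windows and point events to
    times inside a window; heartbeats are kept (the app itself is cheap).
    Returns the observed stream and the realized per-(day, epoch) coverage."""
    days = sorted(set(events["start"].dt.normalize()))
    kept_rows: list[pd.DataFrame] = []
    sched_rows = []
    heart = events[events["event_type"] == "heartbeat"]
    kept_rows.append(heart)
    for day_start in days:
        conv = rng.random(144) < config.conversation_rate
        windows = duty_cycle_windows(day_start, conv)
        day_end = day_start + pd.Timedelta(days=1)
        # coverage per epoch (cycles align with epoch boundaries)
        for epoch in EPOCHS:
            lo, hi = EPOCH_BOUNDS_MIN[epoch]
            covered = 0.0
            for (w0, w1) in windows:
                m0 = (w0 - day_start).total_seconds() / 60.0
                if lo <= m0 < hi:
                    covered += (w1 - w0).total_seconds() / 60.0
            sched_rows.append((subject.subject_id, day_start.date().isoformat(),
                               epoch, covered / EPOCH_LENGTH_MIN[epoch]))
        day_ev = events[(events["start"] >= day_start) & (events["start"] < day_end)
                        & (events["event_type"] != "heartbeat")]
        if len(day_ev) == 0:
            continue
        pieces = []
        w_starts = np.array([(w0 - day_start).total_seconds() for w0, _ in windows])
        w_ends = np.array([(w1 - day_start).total_seconds() for _, w1 in windows])
        for _, ev in day_ev.iterrows():
            s = (ev["start"] - day_start).total_seconds()
            e = (ev["end"] - day_start).total_seconds()
            if ev["event_type"] == "location_obs":
                i = np.searchsorted(w_starts, s, side="right") - 1
                if i >= 0 and s < w_ends[i]:
                    pieces.append(ev)
                continue
            ss = np.maximum(w_starts, s)
            ee = np.minimum(w_ends, e)
            for k in np.nonzero(ee > ss)[0]:
                frag = ev.copy()
                frag["start"] = day_start + pd.Timedelta(seconds=float(ss[k]))
                frag["end"] = day_start + pd.Timedelta(seconds=float(ee[k]))
                pieces.append(frag)
        if pieces:
            kept_rows.append(pd.DataFrame(pieces))
    observed = pd.concat(kept_rows, ignore_index=True) if kept_rows else events.iloc[:0]
    observed = observed.sort_values(["start", "end"], kind="stable").reset_index(drop=True)
    schedule = pd.DataFrame(sched_rows,
                            columns=["subject_id", "day", "epoch", "coverage"])
    return observed, schedule


# ---------------------------------------------------------------------------
# surveys

PHQ4_PROMPT_DAYS = range(3, 1000, 7)  # weekly, clipped to the study window
# trait quantiles an item must cross to score 1/2/3; placed high so the
# population is predominantly minimal (PHQ-8 mean ~4-5, as in young-adult
# community samples) while extremes still reach 0 and 24
ITEM_THRESHOLDS = np.array([0.70, 0.85, 0.95])


def phq_items(trait01: float, n_items: int, noise_sd: float,
              rng: np.random.Generator) -> list[int]:
    """Ordinal 0-3 items: count of thresholds (0.25, 0.5, 0.75) crossed by
    trait + item noise.  trait at 0 with no noise -> all 0; at 1 -> all 3."""
    latent = trait01 + noise_sd * rng.normal(size=n_items)
    return (latent[:, None] >= ITEM_THRESHOLDS).sum(axis=1).astype(int).tolist()


def generate_surveys(subject: SubjectParams, config: CohortConfig) -> pd.DataFrame:
    """One pre-scan PHQ-8 plus weekly PHQ-4 EMAs, items driven by the latent
    severity trait mapped through the normal CDF."""
    from scipy.stats import norm
    rng = _rng(config.rng_seed, _DOM_SURVEY, subject.index)
    trait = float(norm.cdf(subject.latent_severity))
    rows = []
    ts = BASE_DATE - pd.Timedelta(days=2)
    for idx, score in enumerate(phq_items(trait, 8, config.survey_noise_sd, rng)):
        rows.append((subject.subject_id, "PHQ8", idx, score, ts))
    for day in PHQ4_PROMPT_DAYS:
        if day >= config.n_days:
            break
        ts = BASE_DATE + pd.Timedelta(days=day, hours=19)
        for idx, score in enumerate(phq_items(trait, 4, config.survey_noise_sd, rng)):
            rows.append((subject.subject_id, "PHQ4", idx, score, ts))
    return pd.DataFrame(rows, columns=["subject_id", "instrument", "item_index",
                                       "score", "timestamp"])


# ---------------------------------------------------------------------------
# BOLD runs

def study_affine(config: CohortConfig) -> np.ndarray:
    """Voxel -> world map placing the seed coordinate (0, 25, -10) at an
    interior voxel center of the grid."""
    v = config.voxel_mm
    nx, ny, nz = config.grid_shape
    seed_vox = np.array([nx // 2, ny // 3, nz // 2], dtype=float)
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = v
    affine[:3, 3] = np.array([0.0, 25.0, -10.0]) - v * seed_vox
    return affine


def target_center_mni(config: CohortConfig) -> np.ndarray:
    """Planted target-region center, medial-orbitofrontal-ward of the seed."""
    return np.array([-12.0, 25.0 + 7.0 * config.voxel_mm, -10.0 - config.voxel_mm])


_REGION_CACHE: dict[tuple, tuple] = {}


def region_voxels(config: CohortConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(seed voxels, target voxels, affine); raises if the grid cannot hold
    two disjoint regions.  Cached per (grid_shape, voxel_mm)."""
    key = (config.grid_shape, config.voxel_mm)
    if key in _REGION_CACHE:
        return _REGION_CACHE[key]
    affine = study_affine(config)
    inv = np.linalg.inv(affine)
    center_vox = (inv[:3, :3] @ target_center_mni(config) + inv[:3, 3])
    if not all(0 <= c <= g - 1 for c, g in zip(center_vox, config.grid_shape)):
        raise ConfigurationError("grid too small for disjoint seed/target regions")
    seed = seed_sphere_voxels((0.0, 25.0, -10.0), 4.0, affine, config.grid_shape)
    target = seed_sphere_voxels(target_center_mni(config), 2.5 * config.voxel_mm,
                                affine, config.grid_shape)
    seed_set = {tuple(v) for v in seed}
    if seed_set & {tuple(v) for v in target}:
        raise ConfigurationError("grid too small for disjoint seed/target regions")
    _REGION_CACHE[key] = (seed, target, affine)
    return seed, target, affine


def band_limited_noise(n_frames: int, n_series: int, tr: float,
                       rng: np.random.Generator,
                       f_lo: float = 0.01, f_hi: float = 0.08) -> np.ndarray:
    """Unit-variance noise restricted to [f_lo, f_hi] (inside the analysis
    passband, so filtering does not destroy planted structure).  [n_series, t]."""
    white = rng.normal(size=(n_series, n_frames))
    freqs = np.fft.rfftfreq(n_frames, d=tr)
    gain = ((freqs >= f_lo) & (freqs <= f_hi)).astype(float)
    x = np.fft.irfft(np.fft.rfft(white, axis=-1) * gain, n=n_frames, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


_MASK_CACHE: dict[tuple, dict] = {}


def make_masks(config: CohortConfig, seed: np.ndarray, target: np.ndarray
               ) -> dict[str, np.ndarray]:
    key = (config.grid_shape, config.voxel_mm)
    if key in _MASK_CACHE:
        return _MASK_CACHE[key]
    nx, ny, nz = config.grid_shape
    ii, jj, kk = np.indices((nx, ny, nz), dtype=float)
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    brain = (((ii - cx) / (0.48 * nx)) ** 2 + ((jj - cy) / (0.48 * ny)) ** 2
             + ((kk - cz) / (0.48 * nz)) ** 2) <= 1.0
    brain[tuple(seed.T)] = True
    brain[tuple(target.T)] = True
    csf = np.zeros_like(brain)
    csf[int(cx) - 1:int(cx) + 1, int(cy) - 1:int(cy) + 1, int(cz) + 3:int(cz) + 5] = True
    csf &= brain
    wm = np.zeros_like(brain)
    wm[int(cx) + 2:int(cx) + 5, int(cy) - 2:int(cy) + 1, int(cz) - 4:int(cz) - 1] = True
    wm &= brain
    for region in (seed, target):
        csf[tuple(region.T)] = False
        wm[tuple(region.T)] = False
    if not csf.any() or not wm.any():
        raise ConfigurationError("grid too small to carve CSF/WM masks")
    _MASK_CACHE[key] = {"csf": csf, "wm": wm, "whole_brain": brain}
    return _MASK_CACHE[key]


def generate_motion(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Slow random-walk realignment series plus single-frame displacement
    pulses at ``motion_spike_rate``; baseline FD stays far below 0.25 mm."""
    t = config.n_frames
    steps = np.column_stack([rng.normal(0, 0.01, size=(t, 3)),
                             rng.normal(0, 2e-4, size=(t, 3))])
    steps[0] = 0.0
    motion = np.cumsum(steps, axis=0)
    if config.motion_spike_rate > 0:
        spikes = rng.random(t) < config.motion_spike_rate
        spikes[0] = False
        amps = 0.6 + rng.exponential(0.4, size=int(spikes.sum()))
        motion[spikes, 0] += amps * np.where(rng.random(int(spikes.sum())) < 0.5, -1, 1)
    return motion


def generate_bold_run(subject: SubjectParams, config: CohortConfig
                      ) -> tuple[BoldRun, dict]:
    """One synthetic run: a shared band-limited latent signal in the seed
    voxels, the same signal scaled by the subject's connectivity weight plus
    independent noise in the target voxels, and independent band-limited
    noise elsewhere.  Returns (BoldRun, per-subject truth dict)."""
    rng = _rng(config.rng_seed, _DOM_BOLD, subject.index)
    seed, target, affine = region_voxels(config)
    masks = make_masks(config, seed, target)
    t, tr = config.n_frames, config.tr_seconds
    nx, ny, nz = config.grid_shape
    n_vox = nx * ny * nz

    latent = band_limited_noise(t, 1, tr, rng)[0]
    glob = band_limited_noise(t, 1, tr, rng)[0]   # shared physiological signal
    noise = band_limited_noise(t, n_vox, tr, rng).reshape(nx, ny, nz, t)
    brain = masks["whole_brain"]
    data = noise.copy()
    data[brain] += GLOBAL_AMPLITUDE * glob
    sx, sy, sz = seed.T
    data[sx, sy, sz] = (latent + GLOBAL_AMPLITUDE * glob
                        + SEED_NOISE_AMPLITUDE * noise[sx, sy, sz])
    tx, ty, tz = target.T
    w = subject.connectivity_weight
    data[tx, ty, tz] = (w * latent + GLOBAL_AMPLITUDE * glob
                        + TARGET_NOISE_AMPLITUDE * noise[tx, ty, tz])
    data = 1000.0 + 10.0 * data

    motion = generate_motion(config, rng)
    run = BoldRun(data=data, tr_seconds=tr, voxel_mm=config.voxel_mm,
                  affine=affine, motion=motion, masks=masks,
                  subject_id=subject.subject_id)
    truth = {"subject_id": subject.subject_id,
             "connectivity_weight": w,
             "seed_region_voxels": seed,
             "target_region_voxels": target}
    return run, truth


# ---------------------------------------------------------------------------
# cohort assembly

@dataclass
class CohortData:
    """Everything generated for one cohort.  BOLD runs are produced on
    demand (deterministically) to keep memory flat."""

    config: CohortConfig
    subjects: list[SubjectParams]
    events: pd.DataFrame
    schedules: pd.DataFrame
    surveys: pd.DataFrame
    ground_truth: GroundTruth

    def bold_run(self, subject_id: str) -> BoldRun:
        sub = next(s for s in self.subjects if s.subject_id == subject_id)
        return generate_bold_run(sub, self.config)[0]


def generate_cohort(config: CohortConfig, prefix: str = "S",
                    include_bold: bool = False) -> CohortData:
    subjects = draw_subjects(config, prefix=prefix)
    ev_frames, sched_frames, survey_frames = [], [], []
    for sub in subjects:
        ev, sched = generate_phone_stream(sub, config)
        ev_frames.append(ev)
        sched_frames.append(sched)
        survey_frames.append(generate_surveys(sub, config))
    seed, target, _ = region_voxels(config)
    r = config.effect_r
    table = pd.DataFrame({
        "subject_id": [s.subject_id for s in subjects],
        "latent_severity": [s.latent_severity for s in subjects],
        "behavior_covariate": [
            config.unlock_mean_minutes
            + config.unlock_per_severity_minutes * s.latent_severity
            for s in subjects],
        "connectivity_weight": [s.connectivity_weight for s in subjects],
    })
    gt = GroundTruth(table=table, seed_region_voxels=seed,
                     target_region_voxels=target,
                     intercept=W_INTERCEPT if r != 0 else 0.0,
                     slope=W_SLOPE if r != 0 else 0.0)
    return CohortData(config=config, subjects=subjects,
                      events=pd.concat(ev_frames, ignore_index=True),
                      schedules=pd.concat(sched_frames, ignore_index=True),
                      surveys=pd.concat(survey_frames, ignore_index=True),
                      ground_truth=gt)
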