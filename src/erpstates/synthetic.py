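"""Synthetic infant ERP cohorts with planted microstate structure.

Emulates a three-group face-processing study: groups defined by family
history of autism crossed with 3-year diagnostic outcome (noFH-noASD,
FH-noASD, FH-ASD), three stimulus conditions (face with direct gaze FD,
face with averted gaze FA, and a scrambled non-social control, Noise),
and per-subject trial-averaged 64-channel ERPs sampled at 500 Hz over a
-200..794 ms epoch. Each ERP is built from a small set of stable
topographies expressed in ordered segments whose durations and strengths
depend on group and condition, plus white sensor noise; a continuous
social-skill outcome (VABS Socialization) is a linear function of the
planted microstate features, and the binary diagnostic outcome follows
group membership. Ground-truth planted features are returned so that
downstream recovery can be tested exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .erp import CONDITIONS, ErpWaveform
from .microstates import MicrostateMaps, normalize_topography, spatial_correlation

logger = logging.getLogger(__name__)

GROUPS = ("noFH-noASD", "FH-noASD", "FH-ASD")

#: (map index 1-based, duration ms, mean GFP µV); durations per condition sum
#: to the post-stimulus window (398 samples x 2 ms = 796 ms at 500 Hz).
#: The fourth map is the "attentive" Nc-like state: shorter and weaker in the
#: FH-ASD group, especially for faces with direct gaze.
DEFAULT_SEGMENT_PLAN: dict[tuple[str, str], list[tuple[int, float, float]]] = {
    ("noFH-noASD", "FD"): [(3, 120, 2.0), (1, 180, 3.0), (4, 300, 4.0), (2, 196, 2.5)],
    ("FH-noASD", "FD"): [(3, 120, 2.0), (1, 180, 3.0), (4, 270, 3.6), (2, 226, 2.5)],
    ("FH-ASD", "FD"): [(3, 120, 2.0), (1, 180, 3.0), (4, 210, 3.0), (2, 286, 2.5)],
    ("noFH-noASD", "FA"): [(3, 120, 2.0), (1, 180, 3.0), (4, 280, 3.6), (2, 216, 2.5)],
    ("FH-noASD", "FA"): [(3, 120, 2.0), (1, 180, 3.0), (4, 260, 3.4), (2, 236, 2.5)],
    ("FH-ASD", "FA"): [(3, 120, 2.0), (1, 180, 3.0), (4, 230, 3.1), (2, 266, 2.5)],
    ("noFH-noASD", "Noise"): [(3, 120, 2.0), (1, 220, 2.8), (4, 200, 3.0), (2, 256, 2.5)],
    ("FH-noASD", "Noise"): [(3, 120, 2.0), (1, 220, 2.8), (4, 200, 3.0), (2, 256, 2.5)],
    ("FH-ASD", "Noise"): [(3, 120, 2.0), (1, 220, 2.8), (4, 200, 3.0), (2, 256, 2.5)],
}


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults mirror the emulated study: 40/72/19 subjects per group, 500 Hz,
    -200..794 ms epochs, four planted topographies, three conditions.
    The seed fully determines every output.
    """

    n_channels: int = 64
    fs: float = 500.0
    epoch: tuple[float, float] = (-200.0, 794.0)
    n_maps: int = 4
    group_sizes: tuple[int, int, int] = (40, 72, 19)
    conditions: tuple[str, ...] = CONDITIONS
    segment_plan: dict[tuple[str, str], list[tuple[int, float, float]]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_SEGMENT_PLAN.items()}
    )
    noise_sd: float = 0.5  # µV additive white sensor noise on the average
    duration_jitter_sd_ms: float = 20.0  # per-subject truncated-Gaussian jitter
    gfp_jitter_sd: float = 0.1  # multiplicative, fractional
    max_abs_map_corr: float = 0.5
    feature_window: tuple[float, float] = (300.0, 794.0)
    outcome_intercept: float = 100.0
    outcome_betas: dict[str, float] = field(
        default_factory=lambda: {"gfp_M4_FD": 5.0, "dur_M4_FD": 0.03, "sex_F": 4.0}
    )
    outcome_noise_sd: float = 10.0
    trial_count_mean: float = 25.0
    trial_count_sd: float = 8.0
    p_female: float = 0.5
    age_range_days: tuple[int, int] = (184, 351)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(g <= 0 for g in self.group_sizes):
            raise ValueError("group sizes must all be positive")
        n_span = (self.epoch[1] - self.epoch[0]) * self.fs / 1000.0
        if abs(n_span - round(n_span)) > 1e-9:
            raise ValueError("fs and epoch must give an integer sample count")
        dt = 1000.0 / self.fs
        n_post = int(round((self.epoch[1] - 0.0) / dt)) + 1 if self.epoch[1] >= 0 else 0
        post_len = n_post * dt
        for key, plan in self.segment_plan.items():
            total = sum(d for _, d, _ in plan)
            if abs(total - post_len) > 1e-6:
                raise ValueError(
                    f"segment durations for {key} sum to {total} ms, "
                    f"expected the post-stimulus window ({post_len} ms)"
                )


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    sex: str  # "F" or "M"
    age_days: int
    msel_composite: float
    vabs_socialization: float
    asd_outcome: bool
    trial_counts: dict[str, int]

    def __post_init__(self) -> None:
        if self.asd_outcome != (self.group == "FH-ASD"):
            raise ValueError("asd_outcome must be true exactly for the FH-ASD group")


def make_maps(
    n_maps: int, n_channels: int, max_abs_corr: float = 0.5, seed: int = 0
) -> MicrostateMaps:
    """Draw random average-referenced unit-GFP topographies.

    Rejection sampling keeps pairwise |spatial correlation| at or below
    ``max_abs_corr``. With exactly 2 channels the average reference forces
    every topography to +-(a, -a), so the only realisable pair is the
    polarity-reversed one (signed correlation -1); that special case is
    returned directly.
    """
    if n_maps < 2:
        raise ValueError("need at least 2 maps")
    if n_channels < n_maps:
        raise ValueError("need n_channels >= n_maps")
    if not 0 < max_abs_corr < 1:
        raise ValueError("max_abs_corr must be in (0, 1)")
    if n_channels == 2:
        if n_maps > 2:
            raise ValueError("at most 2 distinct topographies exist on 2 channels")
        m = np.array([[1.0, -1.0], [-1.0, 1.0]])[:n_maps]
        return MicrostateMaps(m, source="synthetic")
    rng = np.random.default_rng(seed)
    accepted: list[np.ndarray] = []
    max_draws = 500 * n_maps
    for _ in range(max_draws):
        cand = normalize_topography(rng.standard_normal(n_channels))
        if all(abs(spatial_correlation(cand, a)) <= max_abs_corr for a in accepted):
            accepted.append(cand)
            if len(accepted) == n_maps:
                return MicrostateMaps(np.array(accepted), source="synthetic")
    raise RuntimeError(
        f"could not draw {n_maps} maps with |corr| <= {max_abs_corr} "
        f"in {max_draws} draws; relax max_abs_corr"
    )


def _plan_to_counts(plan, fs: float, n_post: int) -> list[tuple[int, int, float]]:
    """Convert (map, duration ms, gfp) segments to integer sample counts."""
    dt = 1000.0 / fs
    out = []
    for m, dur, g in plan:
        if dur < 0 or g < 0:
            raise ValueError("segment durations and GFPs must be non-negative")
        out.append((int(m), int(round(dur / dt)), float(g)))
    if sum(c for _, c, _ in out) != n_post:
        raise ValueError("plan durations do not sum to the post-stimulus window")
    return out


def simulate_erp(
    maps: MicrostateMaps,
    plan: list[tuple[int, float, float]],
    noise_sd: float,
    fs: float = 500.0,
    epoch: tuple[float, float] = (-200.0, 794.0),
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
    **meta,
) -> ErpWaveform:
    """One averaged ERP from an ordered segment plan.

    Post-stimulus samples are (planned GFP) x (map topography) plus white
    Gaussian noise of SD ``noise_sd`` per channel; pre-stimulus samples are
    noise only. Deterministic given the seed (or the supplied generator).
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    dt = 1000.0 / fs
    n_total = int(round((epoch[1] - epoch[0]) / dt)) + 1
    n_post = int(round((epoch[1] - 0.0) / dt)) + 1
    n_pre = n_total - n_post
    segs = _plan_to_counts(plan, fs, n_post)
    nch = maps.n_channels
    data = np.zeros((nch, n_total))
    col = n_pre
    for m, cnt, g in segs:
        if not 1 <= m <= maps.k:
            raise ValueError(f"map index {m} out of range 1..{maps.k}")
        data[:, col : col + cnt] = g * maps.maps[m - 1][:, None]
        col += cnt
    if noise_sd > 0:
        data += noise_sd * rng.standard_normal(data.shape)
    return ErpWaveform(data=data, fs=fs, t0_offset=epoch[0], **meta)


def _jitter_counts(
    counts: list[int], jitter_sd_samples: float, rng: np.random.Generator
) -> list[int]:
    """Perturb segment sample counts, keeping them >= 0 and the total fixed."""
    n_post = sum(counts)
    out = [
        max(0, c + int(round(rng.normal(0.0, jitter_sd_samples)))) for c in counts
    ]
    diff = n_post - sum(out)
    # absorb the rounding remainder in the largest segment(s)
    while diff != 0:
        i = int(np.argmax(out))
        step = max(-out[i], diff) if diff < 0 else diff
        out[i] += step
        diff -= step
    return out


def _planted_features(
    segs: list[tuple[int, int, float]],
    n_maps: int,
    fs: float,
    epoch: tuple[float, float],
    feature_window: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Exact per-map duration and mean GFP of a plan inside the feature window."""
    dt = 1000.0 / fs
    labels, gfps = [], []
    for m, cnt, g in segs:
        labels.extend([m] * cnt)
        gfps.extend([g] * cnt)
    labels = np.array(labels)
    gfps = np.array(gfps)
    t = np.arange(labels.size) * dt  # post-stimulus sample times
    mask = (t >= feature_window[0] - 1e-9) & (t <= feature_window[1] + 1e-9)
    dur = np.zeros(n_maps)
    mg = np.full(n_maps, np.nan)
    for m in range(1, n_maps + 1):
        sel = mask & (labels == m)
        dur[m - 1] = sel.sum() * dt
        if sel.any():
            mg[m - 1] = float(gfps[sel].mean())
    return dur, mg


def simulate_cohort(
    config: SimConfig,
) -> tuple[list[SubjectRecord], dict[str, dict[str, ErpWaveform]], pd.DataFrame, MicrostateMaps]:
    """Generate a full cohort: subject records, ERPs, ground truth, true maps.

    Returns
    -------
    records : list of SubjectRecord
    erps : dict subject_id -> condition -> ErpWaveform
    truth : DataFrame, one row per subject with covariates, outcomes and the
        planted per-map duration/GFP features (columns ``dur_M{m}_{cond}``
        and ``gfp_M{m}_{cond}``) inside ``config.feature_window``.
    maps : the planted topographies
    """
    rng = np.random.default_rng(config.seed)
    maps = make_maps(
        config.n_maps, config.n_channels, config.max_abs_map_corr,
        seed=int(rng.integers(2**31)),
    )
    # orient the Nc-like map (map 4, or the last map) to a frontal negativity
    nc_map = min(4, config.n_maps) - 1
    frontal = maps.maps[nc_map][: max(2, config.n_channels // 4)]
    if frontal.mean() > 0:
        m = maps.maps.copy()
        m[nc_map] *= -1.0
        maps = replace(maps, maps=m)

    dt = 1000.0 / config.fs
    n_post = int(round(config.epoch[1] / dt)) + 1
    jit = config.duration_jitter_sd_ms / dt

    records: list[SubjectRecord] = []
    erps: dict[str, dict[str, ErpWaveform]] = {}
    rows: list[dict] = []
    sid_n = 0
    for group, size in zip(GROUPS, config.group_sizes):
        for _ in range(size):
            sid_n += 1
            sid = f"S{sid_n:03d}"
            sex = "F" if rng.random() < config.p_female else "M"
            age = int(rng.integers(config.age_range_days[0], config.age_range_days[1] + 1))
            msel = float(np.clip(rng.normal(100.0, 15.0), 50.0, 150.0))
            trials = {
                c: int(np.clip(round(rng.normal(config.trial_count_mean, config.trial_count_sd)), 0, 60))
                for c in config.conditions
            }
            row = {
                "subject_id": sid, "group": group, "sex": sex, "age_days": age,
                "msel_composite": msel, "asd_outcome": group == "FH-ASD",
            }
            for c in config.conditions:
                row[f"trials_{c}"] = trials[c]
            erps[sid] = {}
            for cond in config.conditions:
                plan = config.segment_plan[(group, cond)]
                segs = _plan_to_counts(plan, config.fs, n_post)
                counts = _jitter_counts([c for _, c, _ in segs], jit, rng)
                gfps = [
                    g * max(0.1, 1.0 + rng.normal(0.0, config.gfp_jitter_sd))
                    for _, _, g in segs
                ]
                segs_j = [(m, cnt, g) for (m, _, _), cnt, g in zip(segs, counts, gfps)]
                plan_j = [(m, cnt * dt, g) for m, cnt, g in segs_j]
                erps[sid][cond] = simulate_erp(
                    maps, plan_j, config.noise_sd, config.fs, config.epoch,
                    rng=rng, channel_ids=(), condition=cond, subject_id=sid,
                )
                dur, mg = _planted_features(
                    segs_j, config.n_maps, config.fs, config.epoch, config.feature_window
                )
                for m in range(1, config.n_maps + 1):
                    row[f"dur_M{m}_{cond}"] = dur[m - 1]
                    row[f"gfp_M{m}_{cond}"] = mg[m - 1]
            rows.append(row)
            records.append(
                SubjectRecord(
                    subject_id=sid, group=group, sex=sex, age_days=age,
                    msel_composite=msel, vabs_socialization=np.nan,
                    asd_outcome=group == "FH-ASD", trial_counts=trials,
                )
            )

    truth = pd.DataFrame(rows)
    truth["sex_F"] = (truth["sex"] == "F").astype(float)
    vabs = np.full(len(truth), config.outcome_intercept)
    for feat, beta in config.outcome_betas.items():
        if beta == 0:
            continue
        x = truth[feat].to_numpy(dtype=float)
        x = np.nan_to_num(x, nan=0.0)
        vabs = vabs + beta * (x - x.mean())
    if config.outcome_noise_sd > 0:
        vabs = vabs + rng.normal(0.0, config.outcome_noise_sd, size=len(truth))
    vabs = np.clip(vabs, 40.0, 140.0)
    truth["vabs_socialization"] = vabs
    truth = truth.drop(columns=["sex_F"])
    for rec, v in zip(records, vabs):
        rec.vabs_socialization = float(v)
    return records, erps, truth, maps


def apply_inclusion(records: list[SubjectRecord], min_trials: int = 10) -> list[SubjectRecord]:
    """Keep subjects with at least ``min_trials`` valid trials in every condition.

    The bound is inclusive ("at least"). A record missing a condition count is
    rejected with a logged reason. Order is preserved.
    """
    kept: list[SubjectRecord] = []
    for rec in records:
        missing = [c for c in CONDITIONS if c not in rec.trial_counts]
        if missing:
            logger.warning(
                "excluding %s: missing trial counts for %s", rec.subject_id, missing
            )
            continue
        low = {c: n for c, n in rec.trial_counts.items() if n < min_trials}
        if low:
            logger.info("excluding %s: too few trials %s", rec.subject_id, low)
            continue
        kept.append(rec)
    return kept


def records_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Subject table as a DataFrame (one row per subject)."""
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id, "group": r.group, "sex": r.sex,
            "age_days": r.age_days, "msel_composite": r.msel_composite,
            "vabs_socialization": r.vabs_socialization,
            "asd_outcome": r.asd_outcome,
        }
        for c, n in r.trial_counts.items():
            row[f"trials_{c}"] = n
        rows.append(row)
    return pd.DataFrame(rows)
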