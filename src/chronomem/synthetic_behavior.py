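"""Synthetic cohorts, bisection trials, recognition responses, score tables.

Everything the inference stage consumes can be generated here with known
parameters, so analysis code is validated by parameter recovery rather than
by fixtures. All generators are seeded and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr

from .coding import code_covariates, standardize_log_duration
from .errors import ConfigError, DataError
from .stimulus_sampler import StimulusSet

PROB_CLIP = 1e-3  # quadratic-rule probabilities are clipped into [eps, 1-eps]


@dataclass(frozen=True)
class CohortConfig:
    n_groups: int = 3
    n_subjects_per_group: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.n_groups < 1 or self.n_subjects_per_group < 1:
            raise ConfigError("cohort sizes must be positive")


@dataclass(frozen=True)
class ChoiceModelParams:
    """Generative coefficients of the logistic choice model.

    The linear predictor is
    ``b0 + b_dur*z + b_mem*mem_c + b_speed*A_z + b_int*mem_c*A_z
    + u_subj + v_subj*A_z`` with z the standardized log-duration, mem_c the
    centered memorability and A_z the standardized speed parameter.
    """

    beta0: float = 0.0
    beta_dur: float = 1.0
    beta_mem: float = 0.0
    beta_speed: float = 0.0
    beta_interaction: float = 0.0
    sd_subject_intercept: float = 0.0
    sd_subject_speed_slope: float = 0.0

    def __post_init__(self):
        if self.sd_subject_intercept < 0 or self.sd_subject_speed_slope < 0:
            raise ConfigError("random-effect sds must be >= 0")


@dataclass(frozen=True)
class InvertedUModel:
    """Quadratic duration rule ``P(long|s) = -M1*(s - M2)**2 + M3``.

    M1 scales the width (larger = narrower), M2 locates the vertex on the
    speed axis, M3 is the peak probability.
    """

    M1: float
    M2: float
    M3: float

    def __post_init__(self):
        if self.M1 <= 0:
            raise ConfigError("M1 must be > 0")
        if not 0 < self.M3 <= 1:
            raise ConfigError("M3 must be in (0, 1]")

    def p_long(self, speed) -> np.ndarray:
        s = np.asarray(speed, dtype=float)
        return np.clip(-self.M1 * (s - self.M2) ** 2 + self.M3, PROB_CLIP, 1 - PROB_CLIP)


@dataclass(frozen=True)
class RtParams:
    """Lognormal reaction times with an injectable slow-outlier fraction."""

    mu_log: float = 6.2  # exp(6.2) ~ 493 ms
    sd_log: float = 0.25
    outlier_fraction: float = 0.01
    outlier_factor: float = 5.0


def make_cohort(cfg: CohortConfig) -> pd.DataFrame:
    """Subject roster: one row per subject with a group assignment."""
    rows = [
        {"subject_id": f"g{g + 1}s{s + 1:02d}", "group": g + 1}
        for g in range(cfg.n_groups)
        for s in range(cfg.n_subjects_per_group)
    ]
    return pd.DataFrame(rows)


def make_duration_grid(lo: float = 300.0, hi: float = 900.0, n: int = 7) -> np.ndarray:
    """Logarithmically spaced durations: d_k = lo * (hi/lo)**((k-1)/(n-1))."""
    if lo <= 0:
        raise DataError("lo must be positive")
    if not lo < hi:
        raise DataError("need lo < hi")
    if n < 2:
        raise DataError("need n >= 2")
    return lo * (hi / lo) ** (np.arange(n) / (n - 1))


def _stimulus_scores(stimuli) -> pd.DataFrame:
    """Resolve test-set covariates from a StimulusSet or a score table."""
    if isinstance(stimuli, StimulusSet):
        rec = stimuli.records.set_index("image_id")
        missing = [i for i in stimuli.test if i not in rec.index]
        if missing:
            raise DataError(f"missing covariates for images: {missing[:5]}")
        scores = rec.loc[stimuli.test].reset_index()
    else:
        scores = stimuli.copy()
    for col in ("image_id", "memorability", "A"):
        if col not in scores.columns:
            raise DataError(f"stimulus table missing column {col!r}")
    return scores.reset_index(drop=True)


def _schedule(n_subjects: int, n_images: int, n_blocks: int, grid: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
    """Balanced block schedule, vectorized over subjects.

    Per subject and block: every image exactly once in shuffled order, and
    the duration grid tiled round-robin then shuffled, so each duration
    appears ``n_images / len(grid)`` times per block.
    """
    n_grid = len(grid)
    if n_images % n_grid != 0:
        raise DataError(f"{n_images} images per block not divisible by {n_grid} durations")
    rows = n_subjects * n_blocks
    img_order = np.argsort(rng.random((rows, n_images)), axis=1)
    dur_base = np.tile(np.repeat(np.arange(n_grid), n_images // n_grid), (rows, 1))
    dur_shuf = np.take_along_axis(dur_base, np.argsort(rng.random((rows, n_images)), axis=1), axis=1)
    return img_order.reshape(n_subjects, n_blocks, n_images), dur_shuf.reshape(n_subjects, n_blocks, n_images)


def _draw_rts(shape, rt: RtParams, rng) -> np.ndarray:
    rts = np.exp(rng.normal(rt.mu_log, rt.sd_log, size=shape))
    if rt.outlier_fraction > 0:
        mask = rng.random(shape) < rt.outlier_fraction
        rts = np.where(mask, rts * rt.outlier_factor, rts)
    return rts


def _assemble_trials(
    subjects: Sequence[str],
    groups: Sequence[int],
    scores: pd.DataFrame,
    p_long: np.ndarray,
    img_idx: np.ndarray,
    dur_idx: np.ndarray,
    grid: np.ndarray,
    rt: RtParams,
    rng,
) -> pd.DataFrame:
    n_subjects, n_blocks, n_images = img_idx.shape
    n_trials = n_blocks * n_images
    responses = rng.random(p_long.shape) < p_long
    rts = _draw_rts(p_long.shape, rt, rng)
    image_ids = scores["image_id"].to_numpy()
    frame = pd.DataFrame(
        {
            "subject_id": np.repeat(np.asarray(subjects, dtype=object), n_trials),
            "group": np.repeat(np.asarray(groups, dtype=int), n_trials),
            "block": np.tile(np.repeat(np.arange(1, n_blocks + 1), n_images), n_subjects),
            "trial_index": np.tile(np.arange(1, n_trials + 1), n_subjects),
            "image_id": image_ids[img_idx.reshape(-1)],
            "duration_ms": grid[dur_idx.reshape(-1)],
            "response": np.where(responses.reshape(-1), "long", "short"),
            "rt_ms": rts.reshape(-1),
        }
    )
    return frame


def simulate_bisection(
    subjects: Sequence[str] | CohortConfig,
    stimuli,
    params: ChoiceModelParams,
    seed: int = 0,
    n_blocks: int = 7,
    duration_grid: np.ndarray | None = None,
    rt: RtParams = RtParams(),
    group: int | Sequence[int] = 1,
) -> pd.DataFrame:
    """Simulate the bisection session under the logistic choice model.

    ``subjects`` is a list of subject ids (or a :class:`CohortConfig`, in
    which case the first group's roster is used). ``stimuli`` supplies the
    test images' covariates. Returns a trial table with one row per
    subject x block x image.
    """
    if isinstance(subjects, CohortConfig):
        roster = make_cohort(subjects)
        roster = roster[roster["group"] == 1]
        subjects = roster["subject_id"].tolist()
    subjects = list(subjects)
    groups = [group] * len(subjects) if np.isscalar(group) else list(group)
    scores = _stimulus_scores(stimuli)
    if duration_grid is None:
        duration_grid = make_duration_grid()
    rng = np.random.default_rng(seed)
    n_subjects, n_images = len(subjects), len(scores)

    coding = code_covariates(scores)
    mem_c = coding.memorability(scores["memorability"])
    a_z = coding.speed(scores["A"])
    z_grid = standardize_log_duration(duration_grid, duration_grid)

    u = rng.normal(0.0, params.sd_subject_intercept, size=n_subjects) if params.sd_subject_intercept > 0 else np.zeros(n_subjects)
    v = rng.normal(0.0, params.sd_subject_speed_slope, size=n_subjects) if params.sd_subject_speed_slope > 0 else np.zeros(n_subjects)

    img_idx, dur_idx = _schedule(n_subjects, n_images, n_blocks, duration_grid, rng)
    mem_t = mem_c[img_idx]  # (S, B, N)
    a_t = a_z[img_idx]
    z_t = z_grid[dur_idx]
    eta = (
        params.beta0
        + params.beta_dur * z_t
        + params.beta_mem * mem_t
        + params.beta_speed * a_t
        + params.beta_interaction * mem_t * a_t
        + u[:, None, None]
        + v[:, None, None] * a_t
    )
    return _assemble_trials(subjects, groups, scores, expit(eta), img_idx, dur_idx, duration_grid, rt, rng)


def default_inverted_u_map(memorability) -> list[InvertedUModel]:
    """Memorability-modulated quadratic rules.

    Higher memorability widens the curve (smaller M1), moves the vertex to
    faster speeds (larger M2 on the standardized-speed axis) and raises the
    peak (larger M3).
    """
    mem = np.atleast_1d(np.asarray(memorability, dtype=float))
    models = [
        InvertedUModel(M1=0.35 - 0.2 * m, M2=-0.5 + 1.0 * m, M3=min(0.45 + 0.4 * m, 1.0))
        for m in mem
    ]
    return models


def simulate_bisection_inverted_u(
    subjects: Sequence[str] | CohortConfig,
    stimuli,
    u_model_map: InvertedUModel | Callable | None = None,
    seed: int = 0,
    n_blocks: int = 7,
    duration_grid: np.ndarray | None = None,
    rt: RtParams = RtParams(),
    group: int | Sequence[int] = 1,
) -> pd.DataFrame:
    """Simulate choices from the quadratic inverted-U rule.

    P(long) depends only on the image's standardized speed (and, through the
    rule's parameters, its memorability); probabilities are clipped to
    [1e-3, 1 - 1e-3]. ``u_model_map`` is a single :class:`InvertedUModel`, a
    callable memorability -> model, or None for the default modulation.
    """
    if isinstance(subjects, CohortConfig):
        roster = make_cohort(subjects)
        roster = roster[roster["group"] == 1]
        subjects = roster["subject_id"].tolist()
    subjects = list(subjects)
    groups = [group] * len(subjects) if np.isscalar(group) else list(group)
    scores = _stimulus_scores(stimuli)
    if duration_grid is None:
        duration_grid = make_duration_grid()
    rng = np.random.default_rng(seed)
    n_subjects, n_images = len(subjects), len(scores)

    coding = code_covariates(scores)
    a_z = coding.speed(scores["A"])
    mem = scores["memorability"].to_numpy(dtype=float)
    if u_model_map is None:
        models = default_inverted_u_map(mem)
    elif isinstance(u_model_map, InvertedUModel):
        models = [u_model_map] * n_images
    else:
        models = [u_model_map(m) for m in mem]
    p_img = np.array([models[i].p_long(a_z[i]) for i in range(n_images)], dtype=float)

    img_idx, dur_idx = _schedule(n_subjects, n_images, n_blocks, duration_grid, rng)
    p = p_img[img_idx]
    return _assemble_trials(subjects, groups, scores, p, img_idx, dur_idx, duration_grid, rt, rng)


def bin_linear_hit_model(stimuli: StimulusSet, center: float = 0.5, spread: float = 0.17):
    """Hit-probability rule with a directly configurable expected bin spread.

    Expected hit rate rises linearly across sampling bins from
    ``center - spread/2`` to ``center + spread/2``, so the expected range
    (max - min) over bin means equals ``spread`` exactly.
    """
    bins = stimuli.per_bin_assignment
    uniq = sorted(set(bins.values()))
    n_bins = len(uniq)
    rank = {b: i for i, b in enumerate(uniq)}
    lo = center - spread / 2.0

    def model(image_ids) -> np.ndarray:
        frac = np.array([rank[bins[i]] for i in image_ids], dtype=float)
        frac /= max(n_bins - 1, 1)
        return np.clip(lo + spread * frac, PROB_CLIP, 1 - PROB_CLIP)

    return model


def simulate_recognition(
    subjects: Sequence[str] | CohortConfig,
    stimuli: StimulusSet,
    hit_model: Callable | None = None,
    fa_rate: float = 0.3,
    seed: int = 0,
    hit_center: float = 0.5,
    hit_spread: float = 0.17,
    group: int | Sequence[int] = 1,
) -> pd.DataFrame:
    """Simulate the day-2 old/new test: all test images plus all foils.

    Old items are endorsed "old" with probability ``hit_model(mem, speed)``
    (default: the bin-linear rule with expected per-bin spread
    ``hit_spread``); foils are endorsed "old" with ``fa_rate``.
    """
    if not 0 <= fa_rate < 1:
        raise ConfigError("fa_rate must lie in [0, 1)")
    if isinstance(subjects, CohortConfig):
        roster = make_cohort(subjects)
        roster = roster[roster["group"] == 1]
        subjects = roster["subject_id"].tolist()
    subjects = list(subjects)
    groups = [group] * len(subjects) if np.isscalar(group) else list(group)
    rng = np.random.default_rng(seed)

    rec = stimuli.records.set_index("image_id")
    old_ids = list(stimuli.test)
    foil_ids = list(stimuli.foil)
    if hit_model is None:
        p_hit = bin_linear_hit_model(stimuli, center=hit_center, spread=hit_spread)(old_ids)
    else:
        p_hit = np.asarray(
            hit_model(
                rec.loc[old_ids, "memorability"].to_numpy(dtype=float),
                rec.loc[old_ids, "A"].to_numpy(dtype=float),
            ),
            dtype=float,
        )
    if np.any((p_hit <= 0) | (p_hit > 1)):
        raise ConfigError("hit probabilities must lie in (0, 1]")

    n_old, n_foil = len(old_ids), len(foil_ids)
    frames = []
    for si, subject in enumerate(subjects):
        say_old = np.concatenate(
            [rng.random(n_old) < p_hit, rng.random(n_foil) < fa_rate]
        )
        is_old = np.concatenate([np.ones(n_old, dtype=int), np.zeros(n_foil, dtype=int)])
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": subject,
                    "group": groups[si],
                    "image_id": old_ids + foil_ids,
                    "is_old": is_old,
                    "response": np.where(say_old, "old", "new"),
                    "correct": (say_old == is_old.astype(bool)).astype(int),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


#: Gaussian-copula correlation calibrated by Monte Carlo so the sample
#: Spearman correlation of (memorability, A) lands at the -0.1134 target
#: under the default heteroscedastic scaling.
_DEFAULT_COPULA_RHO = -0.1187


def make_synthetic_score_table(
    n_images: int,
    seed: int = 0,
    rho: float = _DEFAULT_COPULA_RHO,
    a_mean: float = -2.36e-5,
    a_sd: float = 1.72e-5,
    a_dist: str = "normal",
    mem_range: tuple[float, float] = (0.2, 1.0),
    heteroscedastic: float = 1.0,
) -> pd.DataFrame:
    """Synthetic (image_id, memorability, A, B, C) table.

    Memorability is uniform on ``mem_range``; A has a weak negative rank
    dependence on memorability (Gaussian copula) and, with
    ``heteroscedastic > 0``, a spread that grows with memorability.
    ``a_dist="uniform"`` draws A uniformly (useful for strategies needing
    even coverage of the A range); heteroscedastic scaling then still
    applies multiplicatively around ``a_mean``.
    """
    if n_images < 1:
        raise ConfigError("n_images must be >= 1")
    if a_dist not in ("normal", "uniform"):
        raise ConfigError(f"unknown a_dist {a_dist!r}")
    if heteroscedastic < 0:
        raise ConfigError("heteroscedastic must be >= 0")
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n_images)
    z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(n_images)
    lo, hi = mem_range
    mem = lo + (hi - lo) * ndtr(z1)
    # spread multiplier grows with memorability, normalized to ~1 at mid-range
    mid = 0.5 * (lo + hi)
    scale = np.sqrt((1.0 + heteroscedastic * mem) / (1.0 + heteroscedastic * mid))
    if a_dist == "normal":
        a = a_mean + a_sd * scale * z2
    else:
        half_width = a_sd * np.sqrt(3.0)
        a = a_mean + half_width * scale * (2.0 * ndtr(z2) - 1.0)
    width = int(np.ceil(np.log10(max(n_images, 10))))
    return pd.DataFrame(
        {
            "image_id": [f"img{i:0{width}d}" for i in range(n_images)],
            "memorability": mem,
            "A": a,
            "B": np.full(n_images, 1.0),
            "C": np.full(n_images, 1.0),
        }
    )
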