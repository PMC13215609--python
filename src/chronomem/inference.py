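"""Analysis stage: RT filtering, mixed logistic fits, binned surfaces,
inverted-U fitting, recognition summaries and classical tests.

The mixed logistic model is fit by maximizing a Laplace approximation to the
marginal binomial-logit likelihood with independent Gaussian random effects
per subject (intercept and/or speed slope). Covariates are coded exactly as
the generator codes them (see :mod:`chronomem.coding`) so recovered
coefficients are on the generating scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit
from scipy.stats import chi2 as chi2_dist
from scipy.stats import f as f_dist
from scipy.stats import t as t_dist

from .coding import code_covariates, standardize_log_duration
from .errors import ConfigError, DataError, SeparationError

log = logging.getLogger(__name__)

FIXED_TERMS = ("memorability", "speed", "interaction")
RANDOM_TERMS = ("intercept", "speed")

_MIN_LOG_SD = np.log(1e-4)
_SEPARATION_BETA = 15.0


# ---------------------------------------------------------------------------
# RT outlier filter


def filter_rt_outliers(
    trials: pd.DataFrame,
    tail: str = "both",
    n_sd: float = 3.0,
    min_trials: int = 10,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop trials whose log-RT is beyond ``n_sd`` sds of the subject mean.

    ``tail="both"`` removes |z| > n_sd; ``tail="upper"`` removes only slow
    outliers (z > n_sd). Trials exactly at the boundary are retained.
    Subjects with fewer than ``min_trials`` trials are passed through
    unfiltered with a warning. Returns the filtered table and the per-subject
    removal counts.
    """
    if tail not in ("both", "upper"):
        raise ConfigError(f"tail must be 'both' or 'upper', got {tail!r}")
    if (trials["rt_ms"] <= 0).any():
        raise DataError("rt_ms must be positive")
    keep = np.ones(len(trials), dtype=bool)
    removed: dict[str, int] = {}
    log_rt = np.log(trials["rt_ms"].to_numpy(dtype=float))
    for subject, idx in trials.groupby("subject_id").indices.items():
        if len(idx) < min_trials:
            log.warning("subject %s has %d trials (< %d); RT filter skipped", subject, len(idx), min_trials)
            removed[subject] = 0
            continue
        x = log_rt[idx]
        mu, sd = x.mean(), x.std(ddof=1)
        if sd == 0:
            removed[subject] = 0
            continue
        z = (x - mu) / sd
        bad = (z > n_sd) if tail == "upper" else (np.abs(z) > n_sd)
        keep[idx[bad]] = False
        removed[subject] = int(bad.sum())
    return trials.loc[keep].reset_index(drop=True), removed


# ---------------------------------------------------------------------------
# Mixed logistic model


@dataclass
class GlmmFit:
    """Result of a mixed (or plain) logistic fit."""

    coefficients: dict[str, tuple[float, float, float]]  # name -> (beta, se, z)
    random_effect_sds: dict[str, float]
    loglik: float
    n_obs: int
    converged: bool
    fixed_terms: tuple[str, ...] = ()
    random_terms: tuple[str, ...] = ()

    @property
    def n_params(self) -> int:
        return len(self.coefficients) + len(self.random_effect_sds)


def _design(
    trials: pd.DataFrame,
    scores: pd.DataFrame,
    fixed: Sequence[str],
    include_duration: bool,
) -> tuple[np.ndarray, list[str], np.ndarray, np.ndarray]:
    """Build (X, column names, y, speed covariate) with generator coding."""
    unknown = set(fixed) - set(FIXED_TERMS)
    if unknown:
        raise ConfigError(f"unknown fixed terms: {sorted(unknown)}")
    merged = trials.merge(
        scores[["image_id", "memorability", "A"]], on="image_id", how="left", validate="many_to_one"
    )
    if merged["memorability"].isna().any():
        missing = merged.loc[merged["memorability"].isna(), "image_id"].unique()[:5]
        raise DataError(f"missing covariates for images: {list(missing)}")
    coding = code_covariates(merged)
    mem_c = coding.memorability(merged["memorability"])
    a_z = coding.speed(merged["A"])
    cols = [np.ones(len(merged))]
    names = ["intercept"]
    if include_duration:
        grid = np.sort(merged["duration_ms"].unique())
        cols.append(standardize_log_duration(merged["duration_ms"], grid))
        names.append("duration")
    if "memorability" in fixed:
        cols.append(mem_c)
        names.append("memorability")
    if "speed" in fixed:
        cols.append(a_z)
        names.append("speed")
    if "interaction" in fixed:
        if not {"memorability", "speed"} <= set(fixed):
            raise ConfigError("interaction requires both memorability and speed")
        cols.append(mem_c * a_z)
        names.append("interaction")
    y = (merged["response"].to_numpy() == "long").astype(float)
    return np.column_stack(cols), names, y, a_z


def _logit_newton(X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-10):
    """Plain logistic regression by Newton-Raphson; returns (beta, loglik, cov)."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = expit(eta)
        w = p * (1 - p)
        grad = X.T @ (y - p)
        hess = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    p = expit(eta)
    hess = (X * (p * (1 - p))[:, None]).T @ X
    cov = np.linalg.inv(hess)
    return beta, ll, cov


def _subject_blocks(trials, X, y, a_z, random_terms):
    blocks = []
    for subject, idx in trials.groupby("subject_id").indices.items():
        z_cols = []
        if "intercept" in random_terms:
            z_cols.append(np.ones(len(idx)))
        if "speed" in random_terms:
            z_cols.append(a_z[idx])
        Z = np.column_stack(z_cols) if z_cols else np.zeros((len(idx), 0))
        blocks.append({"subject": subject, "X": X[idx], "Z": Z, "y": y[idx], "bhat": np.zeros(Z.shape[1])})
    return blocks


def _laplace_subject(block, beta, sd2, update_cache=True):
    """Laplace-approximate marginal log-likelihood contribution of one subject."""
    X, Z, y = block["X"], block["Z"], block["y"]
    q = Z.shape[1]
    offset = X @ beta
    b = block["bhat"].copy()
    d_inv = 1.0 / sd2
    for _ in range(100):
        eta = offset + Z @ b
        p = expit(eta)
        grad = Z.T @ (y - p) - d_inv * b
        w = p * (1 - p)
        H = (Z * w[:, None]).T @ Z + np.diag(d_inv)
        step = np.linalg.solve(H, grad)
        # dampen huge steps for stability
        norm = np.max(np.abs(step))
        if norm > 5.0:
            step *= 5.0 / norm
        b = b + step
        if norm < 1e-9:
            break
    if update_cache:
        block["bhat"] = b
    eta = offset + Z @ b
    p = expit(eta)
    ll_cond = np.sum(y * eta - np.logaddexp(0.0, eta))
    w = p * (1 - p)
    H = (Z * w[:, None]).T @ Z + np.diag(d_inv)
    sign, logdet = np.linalg.slogdet(H)
    if sign <= 0:
        return -np.inf
    return float(ll_cond - 0.5 * b @ (d_inv * b) - 0.5 * np.sum(np.log(sd2)) - 0.5 * logdet)


def fit_choice_glmm(
    trials: pd.DataFrame,
    scores: pd.DataFrame,
    fixed: Sequence[str] = FIXED_TERMS,
    random: Sequence[str] = ("intercept", "speed"),
    include_duration: bool = False,
    fix_sds: Sequence[float] | None = None,
    compute_se: bool = True,
) -> GlmmFit:
    """Fit the binomial-logit choice model with subject random effects.

    ``fixed`` selects terms among memorability/speed/interaction (an
    intercept, and optionally a standardized log-duration term, are always
    or flag-added). ``random`` selects subject-level Gaussian effects among
    intercept and speed slope; pass ``()`` for a plain logistic fit.
    ``fix_sds`` pins the random-effect sds instead of estimating them (all
    zeros reduces to the plain fit while keeping the declared structure).
    Deterministic given the data.
    """
    unknown = set(random) - set(RANDOM_TERMS)
    if unknown:
        raise ConfigError(f"unknown random terms: {sorted(unknown)}")
    if trials["subject_id"].nunique() < 2:
        raise DataError("need at least 2 subjects")
    X, names, y, a_z = _design(trials, scores, fixed, include_duration)
    if y.min() == y.max():
        raise SeparationError("response is constant; model is degenerate")
    n_obs = len(y)
    p_fix = X.shape[1]
    random = tuple(random)
    if fix_sds is not None and all(s == 0 for s in fix_sds):
        random_eff = {name: 0.0 for name in random}
        random = ()
    else:
        random_eff = None

    if not random:
        beta, ll, cov = _logit_newton(X, y)
        se = np.sqrt(np.diag(cov))
        _check_separation(beta, names)
        coeffs = {n: (float(b), float(s), float(b / s)) for n, b, s in zip(names, beta, se)}
        return GlmmFit(
            coefficients=coeffs,
            random_effect_sds=random_eff or {},
            loglik=ll,
            n_obs=n_obs,
            converged=True,
            fixed_terms=tuple(fixed),
            random_terms=(),
        )

    blocks = _subject_blocks(trials, X, y, a_z, random)
    q = len(random)
    beta0, _, _ = _logit_newton(X, y)

    estimate_sds = fix_sds is None

    def unpack(params):
        beta = params[:p_fix]
        if estimate_sds:
            sd2 = np.exp(2.0 * params[p_fix:])
        else:
            sd2 = np.asarray(fix_sds, dtype=float) ** 2
            sd2 = np.maximum(sd2, np.exp(2 * _MIN_LOG_SD))
        return beta, sd2

    def nll(params):
        beta, sd2 = unpack(params)
        total = 0.0
        for block in blocks:
            total += _laplace_subject(block, beta, sd2)
        return -total

    x0 = np.concatenate([beta0, np.full(q, np.log(0.3))]) if estimate_sds else beta0.copy()
    bounds = [(None, None)] * p_fix + ([(_MIN_LOG_SD, 3.0)] * q if estimate_sds else [])
    res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds, options={"maxiter": 500, "ftol": 1e-11})
    beta, sd2 = unpack(res.x)
    _check_separation(beta, names)
    ll = -float(res.fun)

    # standard errors from the numeric Hessian of the negative log-likelihood
    se = _numeric_se(nll, res.x, p_fix) if compute_se else np.full(p_fix, np.nan)
    coeffs = {
        n: (float(b), float(s), float(b / s) if s > 0 else np.nan)
        for n, b, s in zip(names, beta, se)
    }
    sds = {name: float(np.sqrt(sd2[i])) for i, name in enumerate(random)}
    return GlmmFit(
        coefficients=coeffs,
        random_effect_sds=sds,
        loglik=ll,
        n_obs=n_obs,
        converged=bool(res.success),
        fixed_terms=tuple(fixed),
        random_terms=random,
    )


def _check_separation(beta, names):
    huge = [n for n, b in zip(names, beta) if abs(b) > _SEPARATION_BETA]
    if huge:
        raise SeparationError(f"possible complete separation on: {', '.join(huge)}")


def _numeric_se(nll, x, p_fix):
    n = len(x)
    h = 1e-4 * np.maximum(np.abs(x), 1.0)
    H = np.zeros((n, n))
    f0 = nll(x)
    for i in range(n):
        for j in range(i, n):
            xi, xj = h[i], h[j]
            if i == j:
                f1 = nll(_perturb(x, i, xi))
                f2 = nll(_perturb(x, i, -xi))
                H[i, i] = (f1 - 2 * f0 + f2) / xi**2
            else:
                fpp = nll(_perturb(_perturb(x, i, xi), j, xj))
                fpm = nll(_perturb(_perturb(x, i, xi), j, -xj))
                fmp = nll(_perturb(_perturb(x, i, -xi), j, xj))
                fmm = nll(_perturb(_perturb(x, i, -xi), j, -xj))
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * xi * xj)
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.maximum(np.diag(cov)[:p_fix], 0.0))
    except np.linalg.LinAlgError:
        se = np.full(p_fix, np.nan)
    return se


def _perturb(x, i, d):
    out = x.copy()
    out[i] += d
    return out


# ---------------------------------------------------------------------------
# Classical statistics containers


@dataclass(frozen=True)
class StatResult:
    statistic_name: str
    value: float
    df: tuple[float, ...] | float
    p: float
    correction: str = "none"
    extras: dict = field(default_factory=dict)


def lr_test(full: GlmmFit, reduced: GlmmFit) -> StatResult:
    """Nested likelihood-ratio chi-square test."""
    full_terms = set(full.coefficients) | {f"sd_{t}" for t in full.random_terms}
    red_terms = set(reduced.coefficients) | {f"sd_{t}" for t in reduced.random_terms}
    if not red_terms <= full_terms:
        extra = sorted(red_terms - full_terms)
        raise DataError(f"models are not nested; reduced has extra terms: {extra}")
    if full.n_obs != reduced.n_obs:
        raise DataError("models were fit to different data (n_obs differs)")
    df = full.n_params - reduced.n_params
    if df <= 0:
        raise DataError("full model has no extra parameters")
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    p = float(chi2_dist.sf(stat, df)) if stat > 0 else 1.0
    return StatResult("chi_square", stat, float(df), p)


# ---------------------------------------------------------------------------
# Binned psychometric surfaces


@dataclass
class BinnedSurface:
    """Binned proportion-"long" surface with subject-level means."""

    mem_edges: np.ndarray | None
    speed_edges: np.ndarray
    cell_means: np.ndarray  # (n_mem_bins, n_speed_bins) or (n_speed_bins,)
    cell_counts: np.ndarray
    subject_means: pd.DataFrame  # long format: subject_id, [mem_bin,] speed_bin, mean, count

    @property
    def speed_centers(self) -> np.ndarray:
        return 0.5 * (self.speed_edges[:-1] + self.speed_edges[1:])


def _equal_width_bins(x: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Bin on [min, max] with the top edge closed; returns (idx 0-based, edges)."""
    lo, hi = float(np.min(x)), float(np.max(x))
    if lo == hi:
        raise DataError("covariate is constant; cannot bin")
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(x, edges, right=False) - 1, 0, n_bins - 1)
    return idx, edges


def binned_psychometric(
    trials: pd.DataFrame,
    scores: pd.DataFrame,
    n_mem_bins: int | None = 7,
    n_speed_bins: int = 7,
) -> BinnedSurface:
    """Mean proportion of "long" responses over covariate bins.

    ``n_mem_bins=None`` gives the speed-only layout (e.g. the 11-bin curve).
    Bin edges are equal-width over the observed covariate range; empty cells
    get mean NaN and count 0.
    """
    merged = trials.merge(
        scores[["image_id", "memorability", "A"]], on="image_id", how="left", validate="many_to_one"
    )
    if merged["memorability"].isna().any():
        missing = merged.loc[merged["memorability"].isna(), "image_id"].unique()[:5]
        raise DataError(f"missing covariates for images: {list(missing)}")
    coding = code_covariates(merged)
    speed = coding.speed(merged["A"])
    long_resp = (merged["response"].to_numpy() == "long").astype(float)
    s_idx, s_edges = _equal_width_bins(speed, n_speed_bins)
    df = pd.DataFrame(
        {"subject_id": merged["subject_id"], "speed_bin": s_idx + 1, "long": long_resp}
    )
    if n_mem_bins is not None:
        m_idx, m_edges = _equal_width_bins(merged["memorability"].to_numpy(dtype=float), n_mem_bins)
        df["mem_bin"] = m_idx + 1
        group_cols = ["mem_bin", "speed_bin"]
        shape = (n_mem_bins, n_speed_bins)
    else:
        m_edges = None
        group_cols = ["speed_bin"]
        shape = (n_speed_bins,)

    cell = df.groupby(group_cols)["long"].agg(["mean", "count"])
    means = np.full(shape, np.nan)
    counts = np.zeros(shape, dtype=int)
    for key, row in cell.iterrows():
        pos = tuple(np.atleast_1d(key).astype(int) - 1)
        means[pos if len(shape) > 1 else pos[0]] = row["mean"]
        counts[pos if len(shape) > 1 else pos[0]] = int(row["count"])

    subj = (
        df.groupby(["subject_id"] + group_cols)["long"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "mean", "count": "count"})
    )
    return BinnedSurface(
        mem_edges=m_edges,
        speed_edges=s_edges,
        cell_means=means,
        cell_counts=counts,
        subject_means=subj,
    )


# ---------------------------------------------------------------------------
# Inverted-U fit


@dataclass(frozen=True)
class InvertedUFit:
    """Quadratic fit of a speed-only surface in vertex form.

    ``M1`` = negated curvature, ``M2`` = vertex speed, ``M3`` = vertex
    height; ``inverted_u`` is False when fitted curvature is >= 0 (the
    parameters are still reported).
    """

    M1: float
    M2: float
    M3: float
    rss: float
    inverted_u: bool


def fit_inverted_u(surface: BinnedSurface) -> InvertedUFit:
    """Count-weighted quadratic least squares on a speed-only surface."""
    if surface.cell_means.ndim != 1:
        raise DataError("fit_inverted_u expects a speed-only surface")
    x = surface.speed_centers
    y = surface.cell_means
    w = surface.cell_counts.astype(float)
    ok = ~np.isnan(y)
    x, y, w = x[ok], y[ok], w[ok]
    if len(x) < 4:
        raise DataError("need at least 4 non-missing bins")
    # center/scale the abscissa for conditioning, then map coefficients back
    mu, sc = x.mean(), x.std()
    if sc == 0:
        raise DataError("degenerate speed axis")
    xs = (x - mu) / sc
    sw = np.sqrt(np.maximum(w, 0.0))
    if np.all(sw == 0):
        sw = np.ones_like(w)
    design = np.column_stack([np.ones_like(xs), xs, xs**2])
    coef, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
    a0s, a1s, a2s = coef
    a2 = a2s / sc**2
    a1 = a1s / sc - 2.0 * a2s * mu / sc**2
    a0 = a0s - a1s * mu / sc + a2s * mu**2 / sc**2
    resid = y - (a0 + a1 * x + a2 * x**2)
    rss = float(np.sum(resid**2))
    inverted = a2 < 0
    if not inverted:
        log.warning("no inverted-U: fitted curvature %.4g >= 0", a2)
    if a2 == 0:
        return InvertedUFit(M1=0.0, M2=np.nan, M3=np.nan, rss=rss, inverted_u=False)
    m2 = -a1 / (2.0 * a2)
    m3 = a0 - a1**2 / (4.0 * a2)
    return InvertedUFit(M1=float(-a2), M2=float(m2), M3=float(m3), rss=rss, inverted_u=bool(inverted))


# ---------------------------------------------------------------------------
# Recognition summaries


@dataclass
class RecognitionSummary:
    per_bin_hit_rate: pd.Series  # bin -> mean over subjects
    overall_hit_rate: float
    spread: float  # max - min of bin means
    subject_matrix: pd.DataFrame  # subjects x bins of hit rates


def recognition_summary(recog: pd.DataFrame, bin_assignment: Mapping[str, int]) -> RecognitionSummary:
    """Per-bin hit rates on old items, their mean and range across bins.

    The per-bin hit rate is the across-subject mean of per-subject
    proportions of "old" responses to old items; ``spread`` is
    max - min over bin means. Bins with no old items are missing entries.
    """
    old = recog.loc[recog["is_old"] == 1].copy()
    if len(old) == 0:
        raise DataError("no old items in recognition table")
    unassigned = set(old["image_id"]) - set(bin_assignment)
    if unassigned:
        raise DataError(f"old items without a bin: {sorted(unassigned)[:5]}")
    old["bin"] = old["image_id"].map(bin_assignment)
    old["hit"] = (old["response"] == "old").astype(float)
    matrix = old.pivot_table(index="subject_id", columns="bin", values="hit", aggfunc="mean")
    bin_means = matrix.mean(axis=0)
    overall = float(old.groupby("subject_id")["hit"].mean().mean())
    spread = float(bin_means.max() - bin_means.min())
    return RecognitionSummary(
        per_bin_hit_rate=bin_means,
        overall_hit_rate=overall,
        spread=spread,
        subject_matrix=matrix,
    )


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA and group contrasts


def rm_anova(matrix) -> StatResult:
    """One-way repeated-measures ANOVA (subjects x conditions matrix).

    Subject is the blocking factor: F = MS_cond / MS_error with
    df = (b - 1, (b - 1)(n - 1)); partial eta squared is
    SS_cond / (SS_cond + SS_error). Rows with any missing cell are dropped
    listwise.
    """
    m = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, dtype=float)
    m = m[~np.isnan(m).any(axis=1)]
    n, b = m.shape
    if n < 2:
        raise DataError("need at least 2 complete subjects")
    if b < 2:
        raise DataError("need at least 2 conditions")
    grand = m.mean()
    cond_means = m.mean(axis=0)
    subj_means = m.mean(axis=1)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_subj = b * np.sum((subj_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    tol = 1e-20 * np.sum(m**2) + 1e-30  # swallow float residue in degenerate tables
    ss_cond = 0.0 if ss_cond < tol else ss_cond
    ss_err = 0.0 if ss_err < tol else ss_err
    df1, df2 = b - 1, (b - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    if ms_err <= 0:
        f_val = np.inf if ss_cond > 0 else 0.0
        p = 0.0 if ss_cond > 0 else 1.0
    else:
        f_val = ms_cond / ms_err
        p = float(f_dist.sf(f_val, df1, df2))
    eta_p = float(ss_cond / (ss_cond + ss_err)) if (ss_cond + ss_err) > 0 else 0.0
    return StatResult("F", float(f_val), (float(df1), float(df2)), p, extras={"partial_eta_sq": eta_p})


def group_contrast(groups: Mapping[str, Sequence[float]]) -> list[StatResult]:
    """Pairwise pooled-sd t tests with Bonferroni correction and Cohen's D."""
    names = list(groups)
    if len(names) < 2:
        raise DataError("need at least 2 groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, arr in arrays.items():
        if len(arr) < 2:
            raise DataError(f"group {g!r} has fewer than 2 subjects")
    pairs = [(names[i], names[j]) for i in range(len(names)) for j in range(i + 1, len(names))]
    n_comp = len(pairs)
    results = []
    for g1, g2 in pairs:
        x, y = arrays[g1], arrays[g2]
        n1, n2 = len(x), len(y)
        pooled_var = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
        pooled_sd = np.sqrt(pooled_var)
        diff = x.mean() - y.mean()
        if pooled_sd == 0:
            t_val, d = 0.0, 0.0
            p_raw = 1.0
        else:
            se = pooled_sd * np.sqrt(1.0 / n1 + 1.0 / n2)
            t_val = diff / se
            d = diff / pooled_sd
            p_raw = 2.0 * float(t_dist.sf(abs(t_val), n1 + n2 - 2))
        p_corr = min(1.0, p_raw * n_comp)
        results.append(
            StatResult(
                "t",
                float(t_val),
                float(n1 + n2 - 2),
                p_corr,
                correction="bonferroni",
                extras={"cohens_d": float(d), "pair": (g1, g2), "p_raw": p_raw, "n_comparisons": n_comp},
            )
        )
    return results
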