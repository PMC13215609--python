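"""Power-curve collapse model and the entropy-threshold categorization proxy.

The entropy trace of an image is summarized by ``E(T) = A * T**B + C``
fitted over timesteps T = 1..N. ``A`` is the collapse-rate ("speed") proxy:
more negative A means entropy falls faster, i.e. a "faster" image.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .entropy_engine import EntropyTrace
from .errors import ConfigError, DataError

#: deterministic multi-start grid; the model is ill-conditioned (small A can
#: trade against large B) so several inits replace a single guess.
_A_STARTS = (-1.0, -0.1, -0.01, -0.001)
_B_STARTS = (0.5, 1.0, 2.0, 4.0)


@dataclass(frozen=True)
class PowerFit:
    """Fitted collapse parameters with diagnostics.

    ``A`` < 0 for declining traces; ``B`` >= 0; ``C`` is the asymptote in
    nats. ``rss`` is the residual sum of squares of the best start.
    """

    A: float
    B: float
    C: float
    rss: float
    converged: bool
    n_starts_used: int


def power_curve(t, A: float, B: float, C: float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return A * np.power(t, B) + C


def fit_power_curve(trace) -> PowerFit:
    """Nonlinear least squares of ``A*T**B + C`` over a fixed start grid.

    Accepts an :class:`EntropyTrace` or a plain value sequence; requires at
    least 4 points (3 free parameters + 1 df). B is constrained to be
    non-negative. Deterministic: the start grid is fixed and the solver has
    no randomness; the lowest-RSS converged solution wins.
    """
    values = trace.values if isinstance(trace, EntropyTrace) else np.asarray(trace, dtype=float)
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 4:
        raise DataError("power fit needs a 1-D trace of length >= 4")
    n = len(values)
    t = np.arange(1, n + 1, dtype=float)

    if np.ptp(values) == 0.0:  # flat trace: exact solution, skip the solver
        return PowerFit(A=0.0, B=1.0, C=float(values[0]), rss=0.0, converged=True, n_starts_used=0)

    log_t = np.log(t)

    def resid(p):
        return power_curve(t, *p) - values

    def jac(p):
        a, b, _ = p
        tb = np.power(t, b)
        return np.column_stack([tb, a * tb * log_t, np.ones_like(t)])

    starts = [
        (a0, b0, c0)
        for a0 in _A_STARTS
        for b0 in _B_STARTS
        for c0 in (float(values.min()), float(values.mean()))
    ]
    best = None
    n_used = 0
    for p0 in starts:
        n_used += 1
        try:
            res = least_squares(
                resid,
                p0,
                jac=jac,
                bounds=([-np.inf, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
                method="trf",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
                max_nfev=400,
            )
        except Exception:
            continue
        if not res.success:
            continue
        rss = float(2.0 * res.cost)
        if best is None or rss < best[0]:
            best = (rss, res.x)
            if rss < 1e-18:  # numerically exact; later starts cannot improve
                break
    if best is None:
        return PowerFit(A=np.nan, B=np.nan, C=np.nan, rss=np.inf, converged=False, n_starts_used=n_used)
    rss, (a, b, c) = best
    return PowerFit(A=float(a), B=float(b), C=float(c), rss=rss, converged=True, n_starts_used=n_used)


def speed_order(fits: Sequence[PowerFit], image_ids: Sequence[str] | None = None) -> np.ndarray:
    """Indices ordering fits fastest (most negative A) to slowest.

    Ties in A are broken by lexicographic ``image_ids`` so the order is
    reproducible and independent of input position.
    """
    if image_ids is None:
        image_ids = [str(i) for i in range(len(fits))]
    if len(image_ids) != len(fits):
        raise DataError("image_ids and fits differ in length")
    bad = [str(image_ids[i]) for i, f in enumerate(fits) if not f.converged]
    if bad:
        raise DataError(f"unconverged fits for image_ids: {', '.join(bad)}")
    keys = sorted(range(len(fits)), key=lambda i: (fits[i].A, str(image_ids[i])))
    return np.asarray(keys, dtype=int)


@dataclass(frozen=True)
class CategorizationProxyConfig:
    """Threshold rule standing in for duration categorization.

    ``duration_to_timestep`` maps a probe duration (ms) onto a timestep
    index; the default linearly maps [``dur_lo``, ``dur_hi``] onto timesteps
    2..``n_timesteps``. ``max_entropy`` (ln K), when given, bounds the
    admissible threshold.
    """

    threshold: float
    n_timesteps: int = 8
    dur_lo: float = 300.0
    dur_hi: float = 900.0
    max_entropy: float | None = None
    duration_to_timestep: Callable[[float], int] | None = None

    def __post_init__(self):
        if self.threshold <= 0:
            raise ConfigError("threshold must be positive")
        if self.max_entropy is not None and self.threshold >= self.max_entropy:
            raise ConfigError(f"threshold must lie in (0, {self.max_entropy:.4f})")

    def probe_timestep(self, duration_ms: float) -> int:
        if self.duration_to_timestep is not None:
            t = int(self.duration_to_timestep(duration_ms))
        else:
            frac = (duration_ms - self.dur_lo) / (self.dur_hi - self.dur_lo)
            t = int(round(2 + frac * (self.n_timesteps - 2)))
        if not 1 <= t <= self.n_timesteps:
            raise DataError(f"duration {duration_ms} maps to timestep {t} outside [1, {self.n_timesteps}]")
        return t


def proxy_categorize(trace, cfg: CategorizationProxyConfig, duration_ms: float) -> str:
    """Return ``"long"`` iff entropy at the probe timestep is <= threshold.

    Entropy at or below the threshold means the trace has already collapsed
    by the time the probe duration elapses; a tie counts as "long".
    """
    values = trace.values if isinstance(trace, EntropyTrace) else np.asarray(trace, dtype=float)
    t = cfg.probe_timestep(duration_ms)
    return "long" if values[t - 1] <= cfg.threshold else "short"
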