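"""Covariate coding shared by the behavior generator and the inference stage.

Both sides must use the identical transformation so that recovered
coefficients are on the generating scale: memorability is centered on the
stimulus-set mean, the speed parameter A is z-scored over the stimulus set,
and log-duration is z-scored over the duration grid (equivalently, over
trials when the schedule is duration-balanced).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError


@dataclass(frozen=True)
class CovariateCoding:
    """Centering/scaling constants derived from a stimulus score table."""

    mem_center: float
    speed_center: float
    speed_scale: float

    def memorability(self, mem) -> np.ndarray:
        return np.asarray(mem, dtype=float) - self.mem_center

    def speed(self, a) -> np.ndarray:
        return (np.asarray(a, dtype=float) - self.speed_center) / self.speed_scale


def code_covariates(scores: pd.DataFrame) -> CovariateCoding:
    """Derive coding constants from the unique images of a score table.

    ``scores`` needs columns ``image_id``, ``memorability``, ``A``; duplicate
    image rows are collapsed so trial tables can be passed after a merge.
    """
    uniq = scores.drop_duplicates(subset="image_id")
    mem = uniq["memorability"].to_numpy(dtype=float)
    a = uniq["A"].to_numpy(dtype=float)
    scale = float(np.std(a))
    if scale == 0.0:
        raise DataError("speed covariate is constant; cannot standardize")
    return CovariateCoding(
        mem_center=float(np.mean(mem)),
        speed_center=float(np.mean(a)),
        speed_scale=scale,
    )


def standardize_log_duration(duration_ms, grid) -> np.ndarray:
    """z-score log-durations against the log of the duration grid."""
    logs = np.log(np.asarray(grid, dtype=float))
    sd = float(np.std(logs))
    if sd == 0.0:
        raise DataError("duration grid is degenerate")
    return (np.log(np.asarray(duration_ms, dtype=float)) - logs.mean()) / sd
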