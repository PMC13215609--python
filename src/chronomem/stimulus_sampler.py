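"""Stimulus-selection strategies over an (image_id, memorability, A) table.

Three strategies mirror the experiment's three groups:

* ``slow_speed`` — per memorability bin, take the images with the highest
  (least negative) A, i.e. the slowest collapse.
* ``high_speed_memorability`` — per memorability bin, take the lowest (most
  negative) A, i.e. the fastest collapse.
* ``constant_memorability`` — restrict to images near memorability 0.5 and
  take equal quotas across equal-width bins of the A range.

Every strategy yields 392 images split into matched test/foil halves of 196.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

STRATEGIES = ("slow_speed", "constant_memorability", "high_speed_memorability")

#: short CLI aliases
STRATEGY_ALIASES = {
    "slow": "slow_speed",
    "constmem": "constant_memorability",
    "fast": "high_speed_memorability",
}


@dataclass(frozen=True)
class SamplingPlan:
    strategy: str = "slow_speed"
    n_bins: int = 7
    mem_range: tuple[float, float] = (0.2, 1.0)
    total: int = 392
    mem_tolerance: float = 0.005  # constant_memorability band half-width
    mem_target: float = 0.5
    stratified_split: bool = True

    def __post_init__(self):
        strategy = STRATEGY_ALIASES.get(self.strategy, self.strategy)
        if strategy not in STRATEGIES:
            raise ConfigError(f"unknown strategy {self.strategy!r}")
        object.__setattr__(self, "strategy", strategy)
        if self.n_bins < 1:
            raise ConfigError("n_bins must be >= 1")
        if self.total < self.n_bins:
            raise ConfigError("total must be >= n_bins")
        if self.mem_tolerance < 0:
            raise ConfigError("mem_tolerance must be >= 0")

    def per_bin_quota(self) -> np.ndarray:
        """Quota per bin; a remainder is spread over the leading bins."""
        q, r = divmod(self.total, self.n_bins)
        quotas = np.full(self.n_bins, q, dtype=int)
        quotas[:r] += 1
        return quotas


@dataclass
class StimulusSet:
    """Test/foil id lists with bin bookkeeping and the selected records."""

    test: list[str]
    foil: list[str]
    per_bin_assignment: dict[str, int]
    records: pd.DataFrame = field(repr=False, default=None)

    def manifest(self) -> pd.DataFrame:
        """Long-format manifest: image_id, set, bin, memorability, A."""
        rows = []
        rec = self.records.set_index("image_id") if self.records is not None else None
        for set_name, ids in (("test", self.test), ("foil", self.foil)):
            for image_id in ids:
                row = {
                    "image_id": image_id,
                    "set": set_name,
                    "bin": self.per_bin_assignment[image_id],
                }
                if rec is not None:
                    row["memorability"] = rec.at[image_id, "memorability"]
                    row["A"] = rec.at[image_id, "A"]
                rows.append(row)
        return pd.DataFrame(rows)


def assign_bins(values, n_bins: int, lo: float, hi: float) -> tuple[np.ndarray, int]:
    """Equal-width bins on [lo, hi]; half-open except the last, closed at hi.

    Returns (bin indices 1..n_bins with 0 marking out-of-range, count of
    excluded out-of-range values).
    """
    if n_bins < 1:
        raise ConfigError("n_bins must be >= 1")
    if not lo < hi:
        raise ConfigError("need lo < hi")
    x = np.asarray(values, dtype=float)
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.digitize(x, edges, right=False)  # 0 below lo, n_bins+1 above hi
    idx[x == hi] = n_bins  # top edge is closed
    out_of_range = (idx == 0) | (idx == n_bins + 1)
    idx = np.where(out_of_range, 0, idx)
    return idx.astype(int), int(out_of_range.sum())


def assign_memorability_bins(records: pd.DataFrame, n_bins: int = 7, lo: float = 0.2, hi: float = 1.0):
    """Bin records by memorability; out-of-range records are dropped.

    Returns ``(bins, n_excluded)`` where ``bins`` is an int Series indexed
    like the in-range subset of ``records``.
    """
    if len(records) == 0:
        raise DataError("records table is empty")
    idx, n_excluded = assign_bins(records["memorability"].to_numpy(), n_bins, lo, hi)
    bins = pd.Series(idx, index=records.index, name="bin")
    return bins[bins > 0], n_excluded


def _validate_records(records: pd.DataFrame) -> None:
    for col in ("image_id", "memorability", "A"):
        if col not in records.columns:
            raise DataError(f"records table is missing column {col!r}")
    if records["image_id"].duplicated().any():
        dupes = records.loc[records["image_id"].duplicated(), "image_id"].tolist()[:5]
        raise DataError(f"duplicate image_id values: {dupes}")
    mem = records["memorability"].to_numpy(dtype=float)
    if np.any((mem < 0) | (mem > 1)):
        raise DataError("memorability values outside [0, 1]")


def _take_per_bin(records: pd.DataFrame, bins: pd.Series, quotas: np.ndarray, ascending_a: bool) -> pd.DataFrame:
    """Sort each bin by A (ties by image_id) and take its quota from one end."""
    picked = []
    deficits = []
    for b in range(1, len(quotas) + 1):
        quota = int(quotas[b - 1])
        members = records.loc[bins.index[bins == b]]
        if len(members) < quota:
            deficits.append((b, quota - len(members)))
            continue
        members = members.sort_values(["A", "image_id"], ascending=[ascending_a, True], kind="mergesort")
        chosen = members.head(quota).copy()
        chosen["bin"] = b
        picked.append(chosen)
    if deficits:
        msg = "; ".join(f"bin {b} short by {d}" for b, d in deficits)
        raise DataError(f"under-filled bins: {msg}")
    return pd.concat(picked, ignore_index=True)


def select_extreme_speed(records: pd.DataFrame, plan: SamplingPlan, seed: int = 0) -> StimulusSet:
    """slow_speed / high_speed_memorability selection + test/foil split."""
    if plan.strategy not in ("slow_speed", "high_speed_memorability"):
        raise ConfigError(f"select_extreme_speed got strategy {plan.strategy!r}")
    _validate_records(records)
    lo, hi = plan.mem_range
    bins, _ = assign_memorability_bins(records, plan.n_bins, lo, hi)
    # slow end = maximum A -> sort descending; fast end = minimum A -> ascending
    ascending = plan.strategy == "high_speed_memorability"
    selected = _take_per_bin(records, bins, plan.per_bin_quota(), ascending_a=ascending)
    return split_test_foil(selected, seed=seed, stratified=plan.stratified_split)


def select_constant_memorability(records: pd.DataFrame, plan: SamplingPlan, seed: int = 0) -> StimulusSet:
    """Constant-memorability selection: band filter, then A-range bins."""
    if plan.strategy != "constant_memorability":
        raise ConfigError(f"select_constant_memorability got strategy {plan.strategy!r}")
    _validate_records(records)
    band = records.loc[(records["memorability"] - plan.mem_target).abs() <= plan.mem_tolerance]
    if len(band) < plan.total:
        raise DataError(
            f"only {len(band)} records within +/-{plan.mem_tolerance} of "
            f"memorability {plan.mem_target}; need {plan.total}"
        )
    a = band["A"].to_numpy(dtype=float)
    a_lo, a_hi = float(a.min()), float(a.max())
    if a_lo == a_hi:
        raise DataError("A is constant within the memorability band; cannot bin")
    idx, _ = assign_bins(a, plan.n_bins, a_lo, a_hi)
    bins = pd.Series(idx, index=band.index, name="bin")
    selected = _take_per_bin(band, bins, plan.per_bin_quota(), ascending_a=True)
    return split_test_foil(selected, seed=seed, stratified=plan.stratified_split)


def sample_stimuli(records: pd.DataFrame, plan: SamplingPlan, seed: int = 0) -> StimulusSet:
    """Dispatch on ``plan.strategy``."""
    if plan.strategy == "constant_memorability":
        return select_constant_memorability(records, plan, seed=seed)
    return select_extreme_speed(records, plan, seed=seed)


def split_test_foil(selected: pd.DataFrame, seed: int = 0, stratified: bool = True) -> StimulusSet:
    """Seeded random split of the selection into equal test/foil halves.

    With ``stratified=True`` (default) the split is 50/50 within each bin so
    the foil set matches the test set's bin composition; odd-sized bins hand
    their extra member to whichever half is currently smaller (test first on
    a tie). Otherwise a plain shuffled half-split is used. The total must be
    even.
    """
    if selected["image_id"].duplicated().any():
        raise DataError("duplicate image ids in selection")
    if "bin" not in selected.columns:
        selected = selected.assign(bin=1)
    n = len(selected)
    if n % 2 != 0:
        raise DataError(f"cannot split {n} images into equal halves")
    rng = np.random.default_rng(seed)
    ordered = selected.sort_values("image_id", kind="mergesort").reset_index(drop=True)
    test_ids: list[str] = []
    foil_ids: list[str] = []
    if stratified:
        for b in sorted(ordered["bin"].unique()):
            members = ordered.loc[ordered["bin"] == b, "image_id"].tolist()
            perm = rng.permutation(len(members))
            half = len(members) // 2
            n_test = half
            if len(members) % 2 == 1 and len(test_ids) <= len(foil_ids):
                n_test += 1
            test_ids.extend(members[i] for i in perm[:n_test])
            foil_ids.extend(members[i] for i in perm[n_test:])
    else:
        members = ordered["image_id"].tolist()
        perm = rng.permutation(n)
        half = n // 2
        test_ids = [members[i] for i in perm[:half]]
        foil_ids = [members[i] for i in perm[half:]]
    assignment = dict(zip(ordered["image_id"], ordered["bin"].astype(int)))
    return StimulusSet(test=test_ids, foil=foil_ids, per_bin_assignment=assignment, records=ordered)
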