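"""Growth-curve statistics and community-level comparisons.

Works on replicate abundance time series (CFU counts or qPCR genome
equivalents, treated as the same semantic type with a method tag):

* maximum specific growth rate mu_max, the least-squares slope of
  ln(X/X0) versus time over the exponential phase, with the window chosen
  deterministically by a maximal-r^2 scan;
* fold increase N(48 h)/N(0 h);
* relative abundance per time point (per replicate, then averaged);
* the null-model productivity comparison: observed community yield versus
  the inoculum-weighted sum of monoculture yields, with a Welch t-test
  across replicates (observed < expected indicates net negative
  interactions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AbundanceTimeSeries",
    "GrowthEstimate",
    "NullModelComparison",
    "mu_max",
    "fold_increase",
    "relative_abundance",
    "null_model_productivity",
]


@dataclass
class AbundanceTimeSeries:
    """Long-format replicate counts: (species, time_h, replicate, count, method)."""

    data: pd.DataFrame

    REQUIRED = ("species", "time_h", "replicate", "count", "method")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if (self.data["time_h"] < 0).any():
            raise ValueError("negative times")
        if (self.data["count"] <= 0).any():
            raise ValueError("counts must be positive")
        bad = set(self.data["method"]) - {"CFU", "qPCR"}
        if bad:
            raise ValueError(f"unknown method tags: {sorted(bad)}")

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(sorted(self.data["species"].unique()))

    def mean_series(self, species: str) -> pd.DataFrame:
        """Replicate-averaged counts for one species, sorted by time."""
        sub = self.data[self.data.species == species]
        if sub.empty:
            raise KeyError(f"no data for species {species!r}")
        return (
            sub.groupby("time_h", as_index=False)["count"].mean().sort_values("time_h")
        )

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "AbundanceTimeSeries":
        return cls(pd.read_csv(path))


@dataclass
class GrowthEstimate:
    species: str
    mu_max: float  # 1/h
    window: tuple[float, float]
    r_squared: float
    fold_increase: float | None = None
    per_replicate: dict = field(default_factory=dict)
    no_growth: bool = False


#: windows whose r^2 differ by less than this are considered tied (and the
#: longer window wins); raw maximal-r^2 selection degenerates under
#: measurement noise, where a 3-point window is often spuriously collinear
R2_TIE_TOLERANCE = 5e-3


def _best_window(times: np.ndarray, log_ratio: np.ndarray) -> tuple[float, float, int, int] | None:
    """Scan all contiguous windows of >= 3 points with positive slope and pick
    the one with maximal r^2 (ties within R2_TIE_TOLERANCE: longest, then
    earliest).  Returns (slope, r2, i, j) or None if no window has positive
    slope."""
    n = len(times)
    best: tuple[float, float, int, int] | None = None
    best_key: tuple[float, int, int] | None = None
    for i in range(n - 2):
        for j in range(i + 3, n + 1):
            t, y = times[i:j], log_ratio[i:j]
            slope, intercept = np.polyfit(t, y, 1)
            if slope <= 0:
                continue
            resid = y - (slope * t + intercept)
            ss_tot = float(np.sum((y - y.mean()) ** 2))
            r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
            key = (round(r2 / R2_TIE_TOLERANCE), j - i, -i)
            if best_key is None or key > best_key:
                best_key = key
                best = (float(slope), r2, i, j)
    return best


def mu_max(
    series: AbundanceTimeSeries,
    species: str,
    min_points: int = 3,
) -> GrowthEstimate:
    """Maximum specific growth rate from the exponential phase.

    mu_max is the least-squares slope of ln(X/X0) against time over the
    contiguous window (>= ``min_points`` points, positive slope) with maximal
    r^2; ties are broken by window length, then earliest start.  A series
    with no positive-slope window yields mu_max = 0 with ``no_growth=True``.
    """
    mean = series.mean_series(species)
    if len(mean) < min_points:
        raise ValueError(f"need at least {min_points} time points")
    t = mean["time_h"].to_numpy(float)
    x = mean["count"].to_numpy(float)
    y = np.log(x / x[0])
    best = _best_window(t, y)
    per_rep: dict = {}
    for rep, sub in series.data[series.data.species == species].groupby("replicate"):
        sub = sub.sort_values("time_h")
        if len(sub) >= min_points:
            tr = sub["time_h"].to_numpy(float)
            yr = np.log(sub["count"].to_numpy(float) / sub["count"].iloc[0])
            rb = _best_window(tr, yr)
            per_rep[rep] = rb[0] if rb else 0.0
    if best is None:
        return GrowthEstimate(
            species=species,
            mu_max=0.0,
            window=(float(t[0]), float(t[-1])),
            r_squared=0.0,
            per_replicate=per_rep,
            no_growth=True,
        )
    slope, r2, i, j = best
    return GrowthEstimate(
        species=species,
        mu_max=slope,
        window=(float(t[i]), float(t[j - 1])),
        r_squared=r2,
        per_replicate=per_rep,
    )


def fold_increase(
    series: AbundanceTimeSeries,
    species: str,
    t0: float = 0.0,
    t1: float = 48.0,
) -> float:
    """Population fold increase N(t1)/N(t0) from replicate-mean counts."""
    mean = series.mean_series(species)
    times = mean["time_h"].to_numpy(float)
    for t in (t0, t1):
        if not np.any(np.isclose(times, t)):
            raise ValueError(f"no counts at t = {t} h")
    n0 = float(mean.loc[np.isclose(times, t0), "count"].iloc[0])
    n1 = float(mean.loc[np.isclose(times, t1), "count"].iloc[0])
    return n1 / n0


def relative_abundance(
    series: AbundanceTimeSeries, time: float
) -> pd.DataFrame:
    """Per-species relative abundance at one time point.

    Fractions are computed per replicate (each species' count over the
    replicate total) and then averaged, with the standard error over
    replicates.  Returns a table (species, fraction, se).
    """
    sub = series.data[np.isclose(series.data["time_h"], time)]
    if sub.empty:
        raise ValueError(f"no counts at t = {time} h")
    all_species = set(series.species)
    per_rep = []
    for rep, grp in sub.groupby("replicate"):
        if set(grp.species) != all_species:
            raise ValueError(
                f"replicate {rep!r} at t = {time} h lacks some community species"
            )
        total = grp["count"].sum()
        per_rep.append(grp.set_index("species")["count"] / total)
    frame = pd.DataFrame(per_rep)
    out = pd.DataFrame(
        {
            "species": frame.columns,
            "fraction": frame.mean(axis=0).to_numpy(),
            "se": (
                frame.std(axis=0, ddof=1) / np.sqrt(len(frame))
            ).fillna(0.0).to_numpy(),
        }
    ).sort_values("species", ignore_index=True)
    return out


@dataclass
class NullModelComparison:
    expected: float
    observed: float
    ratio: float
    p_value: float
    net_negative: bool

    @property
    def flag(self) -> str:
        return "net negative interaction" if self.net_negative else "no net loss"


def null_model_productivity(
    monoculture_yields: Mapping[str, Sequence[float]],
    initial_fractions: Mapping[str, float] | None,
    community_yields: Sequence[float],
) -> NullModelComparison:
    """Compare community productivity with the additive null model.

    ``expected = sum_i w_i * yield_i`` with weights ``w_i`` the initial
    inoculum fractions (equal weights when ``initial_fractions`` is None);
    yields must share a unit.  A two-sided Welch t-test compares the
    replicate community yields with the per-replicate null expectations.
    """
    species = sorted(monoculture_yields)
    if initial_fractions is None:
        weights = {s: 1.0 / len(species) for s in species}
    else:
        total = sum(initial_fractions[s] for s in species)
        weights = {s: initial_fractions[s] / total for s in species}
    mono = {s: np.asarray(monoculture_yields[s], float) for s in species}
    n_rep = min(len(v) for v in mono.values())
    expected_reps = np.array(
        [sum(weights[s] * mono[s][r] for s in species) for r in range(n_rep)]
    )
    observed = np.asarray(community_yields, float)
    expected = float(expected_reps.mean())
    obs_mean = float(observed.mean())
    if len(observed) > 1 and len(expected_reps) > 1:
        p = float(stats.ttest_ind(observed, expected_reps, equal_var=False).pvalue)
    else:
        p = float("nan")
    ratio = obs_mean / expected
    return NullModelComparison(
        expected=expected,
        observed=obs_mean,
        ratio=ratio,
        p_value=p,
        net_negative=ratio < 1.0,
    )
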