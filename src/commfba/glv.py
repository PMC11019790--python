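"""Generalized Lotka-Volterra simulation, inference, and interaction typing.

The gLV model is dx_i/dt = x_i (r_i + sum_j a_ij x_j): r_i is species i's
intrinsic growth rate (1/h) and the sign of the off-diagonal coupling a_ij
classifies the effect of species j on species i as positive or negative.

Parameters are inferred by gradient matching: central finite differences of
ln x_i are regressed (ridge-regularized least squares on a normalized design)
on [1, x_1, ..., x_n], per species, with replicate-averaged series and the
dilution discontinuities of a serial-transfer experiment excluded by
segmenting the series per passage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .growth_stats import AbundanceTimeSeries

__all__ = [
    "GLVParams",
    "InteractionSummary",
    "GLVBlowupError",
    "simulate_glv",
    "fit_glv",
    "interaction_signs",
]

#: couplings below this fraction of max|A| are reported as sign 0
DEFAULT_SIGN_THRESHOLD_FRACTION = 1e-6


class GLVBlowupError(RuntimeError):
    """Trajectory diverged (unbounded growth with no self-limitation)."""


@dataclass(frozen=True)
class GLVParams:
    """Growth rates r (1/h) and interaction matrix A (1/(h * abundance unit))."""

    species_ids: tuple[str, ...]
    r: np.ndarray
    A: np.ndarray
    abundance_unit: str = "CFU/mL"

    def __post_init__(self) -> None:
        r = np.asarray(self.r, float)
        A = np.asarray(self.A, float)
        n = len(self.species_ids)
        if r.shape != (n,) or A.shape != (n, n):
            raise ValueError("r must be length n and A n-by-n")
        if not (np.all(np.isfinite(r)) and np.all(np.isfinite(A))):
            raise ValueError("parameters must be finite")
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "A", A)


@dataclass
class InteractionSummary:
    species_ids: tuple[str, ...]
    sign_matrix: np.ndarray  # entries in {-1, 0, +1}; diagonal fixed at 0
    n_negative: int
    n_positive: int
    n_zero: int
    fraction_negative: float
    degenerate: bool = False  # all couplings below threshold

    @property
    def n_couplings(self) -> int:
        return self.n_negative + self.n_positive


def simulate_glv(
    params: GLVParams,
    x0: Sequence[float],
    times: Sequence[float],
    rtol: float = 1e-9,
    atol: float = 1e-12,
    blowup: float = 1e30,
) -> pd.DataFrame:
    """Integrate the gLV ODE at the requested times (log-space integration,
    so trajectories stay strictly positive).

    Returns a wide table indexed by time with one column per species.
    Raises :class:`GLVBlowupError` on finite-time divergence.
    """
    x0 = np.asarray(x0, float)
    times = np.asarray(times, float)
    if np.any(x0 <= 0):
        raise ValueError("initial abundances must be positive")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    r, A = params.r, params.A
    log_cap = np.log(blowup)

    def rhs(_t: float, u: np.ndarray) -> np.ndarray:
        # clip the exponent so a diverging trajectory saturates numerically
        # instead of overflowing; the cap crossing is detected afterwards
        return r + A @ np.exp(np.minimum(u, log_cap + 10.0))

    t0 = times[0]
    u0 = np.log(x0)
    sol = solve_ivp(
        rhs,
        (t0, times[-1]),
        u0,
        t_eval=times,
        rtol=rtol,
        atol=atol,
        method="LSODA",
    )
    if sol.y.size and np.max(sol.y) >= log_cap:
        k = int(np.argmax(np.max(sol.y, axis=0) >= log_cap))
        raise GLVBlowupError(
            f"gLV trajectory exceeded {blowup:g} near t = {sol.t[k]:.4g} h; "
            "the system lacks self-limitation (check the diagonal of A)"
        )
    if sol.status != 0:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return pd.DataFrame(
        np.exp(sol.y.T), index=pd.Index(times, name="time_h"), columns=params.species_ids
    )


def _segments(times: np.ndarray, passages: np.ndarray | None) -> list[np.ndarray]:
    """Index arrays of contiguous per-passage segments (dilution jumps excluded)."""
    if passages is None:
        return [np.arange(len(times))]
    out = []
    for p in np.unique(passages):
        idx = np.flatnonzero(passages == p)
        if len(idx) >= 3:
            out.append(idx)
    return out


def fit_glv(
    series: AbundanceTimeSeries,
    ridge_penalty: float = 1e-3,
    abundance_unit: str | None = None,
) -> GLVParams:
    """Infer gLV parameters from a replicate abundance time series.

    Replicates are averaged per (species, time).  For each species the
    central finite differences of ln x_i at interior time points are
    regressed on [1, x_1, ..., x_n] by ridge least squares; the design's
    abundance columns are normalized by their root-mean-square so the penalty
    is invariant to abundance units (the intercept is unpenalized).  When the
    series carries a ``passage`` column, differencing is segmented per
    passage so that dilution discontinuities never enter the gradient.
    """
    df = series.data
    species_ids = series.species
    n = len(species_ids)
    has_passage = "passage" in df.columns
    group_cols = ["time_h"] + (["passage"] if has_passage else [])
    wide = (
        df.groupby(group_cols + ["species"])["count"]
        .mean()
        .unstack("species")
        .reset_index()
        .sort_values(group_cols)
    )
    if wide[list(species_ids)].isna().any().any():
        raise ValueError("every species needs a count at every time point")
    times = wide["time_h"].to_numpy(float)
    passages = wide["passage"].to_numpy() if has_passage else None
    X = wide[list(species_ids)].to_numpy(float)

    rows_design: list[np.ndarray] = []
    rows_grad: list[np.ndarray] = []
    for idx in _segments(times, passages):
        if len(idx) < 3:
            continue
        t_seg, x_seg = times[idx], X[idx]
        ln_x = np.log(x_seg)
        # central differences at interior points of the segment
        interior = slice(1, len(idx) - 1)
        dt = t_seg[2:] - t_seg[:-2]
        grad = (ln_x[2:] - ln_x[:-2]) / dt[:, None]
        rows_design.append(x_seg[interior])
        rows_grad.append(grad)
    if not rows_design:
        raise ValueError("need at least one segment with >= 3 time points")
    Xd = np.vstack(rows_design)  # (m, n) abundances at interior points
    G = np.vstack(rows_grad)  # (m, n) d ln x_i / dt

    m = Xd.shape[0]
    if m < n + 1 and ridge_penalty == 0:
        raise ValueError(
            f"{m} gradient points cannot identify {n + 1} parameters per "
            "species without regularization; set ridge_penalty > 0"
        )

    # normalize abundance columns so the ridge penalty is unit-invariant
    scale = np.sqrt(np.mean(Xd**2, axis=0))
    scale[scale == 0] = 1.0
    D = np.hstack([np.ones((m, 1)), Xd / scale])
    penalty = np.diag([0.0] + [ridge_penalty] * n)  # intercept unpenalized
    lhs = D.T @ D + m * penalty
    r_out = np.empty(n)
    A_out = np.empty((n, n))
    for i in range(n):
        beta = np.linalg.solve(lhs, D.T @ G[:, i])
        r_out[i] = beta[0]
        A_out[i] = beta[1:] / scale
    return GLVParams(
        species_ids=species_ids,
        r=r_out,
        A=A_out,
        abundance_unit=abundance_unit
        or (df["method"].iloc[0] == "qPCR" and "genome-equivalents/mL" or "CFU/mL"),
    )


def interaction_signs(
    params: GLVParams | Sequence[GLVParams],
    threshold: float | None = None,
) -> InteractionSummary:
    """Classify pairwise interaction signs and pool the negative fraction.

    Off-diagonal couplings with |a_ij| below ``threshold`` (default
    ``1e-6 * max|A|`` per fit) count as sign 0.  When several fitted
    parameter sets are supplied (e.g. one per inoculum-ratio dataset) the
    counts are pooled; ``fraction_negative`` is the number of negative
    couplings over the number of nonzero off-diagonal couplings.  If every
    coupling is below threshold the fraction is reported as 0 with
    ``degenerate=True``.
    """
    fits = [params] if isinstance(params, GLVParams) else list(params)
    if not fits:
        raise ValueError("no parameter sets given")
    species_ids = fits[0].species_ids
    n = len(species_ids)
    sign_total = np.zeros((n, n))
    n_neg = n_pos = n_zero = 0
    for p in fits:
        if p.species_ids != species_ids:
            raise ValueError("parameter sets must share the species panel")
        thr = threshold
        if thr is None:
            max_a = float(np.max(np.abs(p.A))) if p.A.size else 0.0
            thr = DEFAULT_SIGN_THRESHOLD_FRACTION * max_a
        signs = np.sign(p.A) * (np.abs(p.A) >= thr)
        np.fill_diagonal(signs, 0)
        sign_total += signs
        off = ~np.eye(n, dtype=bool)
        n_neg += int(np.sum(signs[off] < 0))
        n_pos += int(np.sum(signs[off] > 0))
        n_zero += int(np.sum(signs[off] == 0))
    n_nonzero = n_neg + n_pos
    return InteractionSummary(
        species_ids=species_ids,
        sign_matrix=np.sign(sign_total),
        n_negative=n_neg,
        n_positive=n_pos,
        n_zero=n_zero,
        fraction_negative=(n_neg / n_nonzero) if n_nonzero else 0.0,
        degenerate=n_nonzero == 0,
    )
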