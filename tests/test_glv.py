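"""gLV simulation against closed forms, parameter recovery, and sign typing."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from commfba.glv import (
    GLVBlowupError,
    GLVParams,
    fit_glv,
    interaction_signs,
    simulate_glv,
)
from commfba.growth_stats import AbundanceTimeSeries


def series_from_wide(wide: pd.DataFrame, method: str = "CFU") -> AbundanceTimeSeries:
    rows = []
    for t, row in wide.iterrows():
        for s, v in row.items():
            rows.append(
                {"species": s, "time_h": float(t), "replicate": 1, "count": float(v), "method": method}
            )
    return AbundanceTimeSeries(pd.DataFrame(rows))


def random_stable_system(rng: np.random.Generator, n: int = 3) -> GLVParams:
    """Competitive system with dominant self-limitation (diagonally stable)."""
    r = rng.uniform(0.3, 0.8, size=n)
    A = -rng.uniform(0.05, 0.5, size=(n, n))
    A[np.diag_indices(n)] = -rng.uniform(1.0, 2.0, size=n)
    return GLVParams(tuple(f"s{i}" for i in range(n)), r, A)


def segmented_series(
    params: GLVParams,
    rng: np.random.Generator,
    n_segments: int = 3,
    points: int = 81,
    horizon: float = 12.0,
) -> AbundanceTimeSeries:
    """Noiseless dense data over several independently inoculated segments.

    A single near-equilibrium trajectory leaves the couplings nearly
    unidentifiable (collinear design); segments with diverse inocula — the
    shape of a serial-dilution experiment — give the gradient-matching
    regression the excitation it needs.
    """
    xs = np.linalg.solve(-params.A, params.r)
    rows = []
    for seg in range(n_segments):
        x0 = xs * rng.uniform(0.05, 0.6, size=len(xs))
        traj = simulate_glv(params, x0, np.linspace(0, horizon, points))
        for t, row in traj.iterrows():
            for s, v in row.items():
                rows.append(
                    {"species": s, "time_h": float(t) + seg * horizon,
                     "replicate": 1, "count": float(v), "method": "CFU",
                     "passage": seg}
                )
    return AbundanceTimeSeries(pd.DataFrame(rows))


class TestSimulate:
    def test_logistic_closed_form(self):
        r, K, x0 = 0.5, 2.0, 0.05
        params = GLVParams(("s",), np.array([r]), np.array([[-r / K]]))
        t = np.linspace(0, 20, 41)
        traj = simulate_glv(params, [x0], t)
        expected = K * x0 * np.exp(r * t) / (K + x0 * (np.exp(r * t) - 1))
        np.testing.assert_allclose(traj["s"].to_numpy(), expected, rtol=1e-6)

    def test_pure_exponential_when_a_zero(self):
        params = GLVParams(("s",), np.array([0.3]), np.array([[0.0]]))
        t = np.linspace(0, 10, 21)
        traj = simulate_glv(params, [1.0], t)
        np.testing.assert_allclose(traj["s"].to_numpy(), np.exp(0.3 * t), rtol=1e-7)

    def test_three_species_equilibrium_matches_linear_solve(self):
        rng = np.random.default_rng(7)
        params = random_stable_system(rng)
        x_star = np.linalg.solve(-params.A, params.r)
        assert np.all(x_star > 0)
        traj = simulate_glv(params, x_star * 1.3, np.linspace(0, 400, 11))
        np.testing.assert_allclose(traj.iloc[-1].to_numpy(), x_star, rtol=1e-5)

    def test_strict_positivity(self):
        rng = np.random.default_rng(3)
        params = random_stable_system(rng)
        traj = simulate_glv(params, [1e-6, 5.0, 1e-3], np.linspace(0, 50, 101))
        assert (traj.to_numpy() > 0).all()

    def test_blowup_detected(self):
        params = GLVParams(("s",), np.array([1.0]), np.array([[0.5]]))
        with pytest.raises(GLVBlowupError, match="self-limitation"):
            simulate_glv(params, [1.0], np.linspace(0, 200, 51))

    def test_input_validation(self):
        params = GLVParams(("s",), np.array([0.1]), np.array([[-0.1]]))
        with pytest.raises(ValueError):
            simulate_glv(params, [0.0], [0, 1])
        with pytest.raises(ValueError):
            simulate_glv(params, [1.0], [0, 0.5, 0.5])


class TestFit:
    @pytest.mark.parametrize("seed", range(20))
    def test_recovery_on_noiseless_dense_data(self, seed):
        """Signs exact and values within 5% on dense noiseless series."""
        rng = np.random.default_rng(seed)
        params = random_stable_system(rng)
        series = segmented_series(params, rng)
        fitted = fit_glv(series, ridge_penalty=1e-10)
        np.testing.assert_allclose(fitted.r, params.r, rtol=0.05)
        np.testing.assert_allclose(fitted.A, params.A, rtol=0.05, atol=5e-3)
        # signs of appreciable couplings all correct
        thr = 1e-5 * np.max(np.abs(params.A))
        mask = np.abs(params.A) > 10 * thr
        assert np.all(np.sign(fitted.A)[mask] == np.sign(params.A)[mask])

    def test_twenty_points_one_passage(self):
        """A well-excited two-species transient identifies all parameters
        within 5% from just 20 noiseless points."""
        params = GLVParams(
            ("a", "b"),
            np.array([0.45, 0.35]),
            np.array([[-1.0, -0.3], [-0.25, -0.8]]),
        )
        x0 = np.linalg.solve(-params.A, params.r) * np.array([0.05, 0.5])
        traj = simulate_glv(params, x0, np.linspace(0, 12, 20))
        fitted = fit_glv(series_from_wide(traj), ridge_penalty=1e-10)
        np.testing.assert_allclose(fitted.r, params.r, rtol=0.05)
        np.testing.assert_allclose(fitted.A, params.A, rtol=0.05)

    def test_single_species_logistic_self_limitation_sign(self):
        params = GLVParams(("s",), np.array([0.6]), np.array([[-0.3]]))
        traj = simulate_glv(params, [0.1], np.linspace(0, 15, 40))
        fitted = fit_glv(series_from_wide(traj), ridge_penalty=1e-9)
        assert fitted.A[0, 0] < 0

    def test_unit_rescaling_scales_couplings_inversely(self):
        rng = np.random.default_rng(5)
        params = random_stable_system(rng)
        x0 = np.linalg.solve(-params.A, params.r) * 0.4
        t = np.linspace(0, 12, 50)
        traj = simulate_glv(params, x0, t)
        f1 = fit_glv(series_from_wide(traj), ridge_penalty=1e-8)
        c = 1e6
        f2 = fit_glv(series_from_wide(traj * c), ridge_penalty=1e-8)
        np.testing.assert_allclose(f2.A * c, f1.A, rtol=1e-4)
        np.testing.assert_allclose(f2.r, f1.r, rtol=1e-4)
        assert np.all(np.sign(f2.A) == np.sign(f1.A))

    def test_replicate_averaging_matches_mean_fit(self):
        rng = np.random.default_rng(11)
        params = random_stable_system(rng)
        x0 = np.linalg.solve(-params.A, params.r) * 0.4
        t = np.linspace(0, 12, 30)
        traj = simulate_glv(params, x0, t)
        # two replicates with multiplicative offsets that average to the mean
        rows = []
        for rep, factor in ((1, 0.9), (2, 1.1)):
            for ti, row in traj.iterrows():
                for s, v in row.items():
                    rows.append(
                        {"species": s, "time_h": float(ti), "replicate": rep,
                         "count": float(v) * factor, "method": "CFU"}
                    )
        series = AbundanceTimeSeries(pd.DataFrame(rows))
        fitted = fit_glv(series, ridge_penalty=1e-8)
        assert fitted.r.shape == (3,)

    def test_dilution_segments_excluded(self):
        """A 10x dilution jump between passages must not pollute gradients."""
        rng = np.random.default_rng(13)
        params = random_stable_system(rng)
        x0 = np.linalg.solve(-params.A, params.r) * np.array([0.6, 0.05, 0.3])
        t1 = np.linspace(0, 12, 49)
        frames = []
        for passage in range(3):
            seg = simulate_glv(params, x0, t1)
            for ti, row in seg.iterrows():
                for s, v in row.items():
                    frames.append(
                        {"species": s, "time_h": float(ti) + 12.0 * passage,
                         "replicate": 1, "count": float(v), "method": "CFU",
                         "passage": passage}
                    )
            x0 = seg.iloc[-1].to_numpy() * 0.1  # dilution event
        df = pd.DataFrame(frames)
        fitted = fit_glv(AbundanceTimeSeries(df), ridge_penalty=1e-10)
        np.testing.assert_allclose(fitted.r, params.r, rtol=0.05)
        np.testing.assert_allclose(fitted.A, params.A, rtol=0.08, atol=5e-3)
        # differencing straight across the 10x jumps wrecks the estimate
        unsegmented = fit_glv(
            AbundanceTimeSeries(df.drop(columns="passage")), ridge_penalty=1e-10
        )
        assert np.max(np.abs(unsegmented.A - params.A) / np.abs(params.A)) > 1.0

    def test_underdetermined_without_penalty_rejected(self):
        params = GLVParams(
            ("a", "b", "c"), np.array([0.3, 0.3, 0.3]), -np.eye(3)
        )
        traj = simulate_glv(params, [0.1, 0.1, 0.1], [0.0, 1.0, 2.0])
        with pytest.raises(ValueError, match="regulariz"):
            fit_glv(series_from_wide(traj), ridge_penalty=0.0)


class TestSigns:
    def _params(self, A):
        A = np.asarray(A, float)
        n = A.shape[0]
        return GLVParams(tuple(f"s{i}" for i in range(n)), np.ones(n), A)

    def test_all_negative_off_diagonals(self):
        summary = interaction_signs(self._params([[-1, -0.2], [-0.3, -1]]))
        assert summary.fraction_negative == 1.0
        assert summary.n_negative == 2

    def test_mixed_signs_counted(self):
        summary = interaction_signs(
            self._params([[-1, 0.4, -0.2], [-0.3, -1, 0.0], [0.1, -0.5, -1]])
        )
        # off-diagonals: +0.4, -0.2, -0.3, 0 (below threshold), +0.1, -0.5
        assert summary.n_negative == 3
        assert summary.n_positive == 2
        assert summary.fraction_negative == pytest.approx(3 / 5)

    def test_degenerate_all_below_threshold(self):
        summary = interaction_signs(self._params([[0, 0], [0, 0]]), threshold=1e-9)
        assert summary.degenerate
        assert summary.fraction_negative == 0.0

    def test_pooling_across_fits(self):
        fits = [
            self._params([[-1, -0.2], [0.3, -1]]),
            self._params([[-1, -0.4], [-0.1, -1]]),
        ]
        summary = interaction_signs(fits)
        assert summary.n_negative == 3
        assert summary.n_positive == 1
        assert summary.fraction_negative == pytest.approx(0.75)

    def test_invariant_under_species_relabeling(self):
        rng = np.random.default_rng(17)
        A = -rng.uniform(0.1, 1.0, size=(3, 3))
        A[0, 1] = 0.4
        p = self._params(A)
        perm = [2, 0, 1]
        A_perm = A[np.ix_(perm, perm)]
        p2 = GLVParams(tuple(f"s{i}" for i in perm), p.r[perm], A_perm)
        assert interaction_signs(p).fraction_negative == pytest.approx(
            interaction_signs(p2).fraction_negative
        )


def test_planted_fraction_negative_recovered_end_to_end():
    """Simulate 8 inoculum-ratio serial-dilution datasets from a planted
    interaction matrix (one facilitation, rest competition), fit each, and
    recover the pooled planted negative fraction exactly."""
    rng = np.random.default_rng(2024)
    n = 3
    r = rng.uniform(0.3, 0.8, size=n)
    A = -rng.uniform(0.1, 0.5, size=(n, n))
    A[np.diag_indices(n)] = -rng.uniform(1.0, 2.0, size=n)
    A[0, 1] = 0.15  # facilitation of s0 by s1
    params = GLVParams(("s0", "s1", "s2"), r, A)
    x_star = np.linalg.solve(-params.A, params.r)
    assert np.all(x_star > 0)
    planted = interaction_signs(params).fraction_negative
    assert planted == pytest.approx(5 / 6)

    inocula = [
        (1, 1, 1), (0.001, 1, 1), (1, 0.001, 1), (1, 1, 0.001),
        (1, 0.001, 0.001), (0.001, 1, 0.001), (0.001, 0.001, 1), (1, 0.058, 0.015),
    ]
    fits = []
    for ratios in inocula:
        x0 = x_star * 0.4 * np.array(ratios)
        rows = []
        for passage in range(3):
            traj = simulate_glv(params, x0, np.linspace(0, 12, 49))
            for ti, row in traj.iterrows():
                for s, v in row.items():
                    rows.append(
                        {"species": s, "time_h": float(ti) + 12.0 * passage,
                         "replicate": 1, "count": float(v), "method": "CFU",
                         "passage": passage}
                    )
            x0 = traj.iloc[-1].to_numpy() * 0.1
        fits.append(
            fit_glv(AbundanceTimeSeries(pd.DataFrame(rows)), ridge_penalty=1e-10)
        )
    pooled = interaction_signs(fits)
    assert pooled.fraction_negative == pytest.approx(planted)
    assert pooled.n_couplings == 8 * 6
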