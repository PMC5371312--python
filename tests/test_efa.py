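import math

import numpy as np
import pytest

from physarum import (
    DriftDiffusionTable,
    ForcingSpec,
    estimate_drift_diffusion,
    estimate_from_series,
    simulate_ou,
    simulate_reduced,
    time_average_coefficients,
)
from physarum.efa_reduction import fill_gaps


def make_table(mu_rows, sigma2_rows, K=50):
    """Hand-built table on the standard grid with uniform counts."""
    edges = np.linspace(-1, 1, K + 1)
    mu = np.vstack(mu_rows)
    s2 = np.vstack(sigma2_rows)
    return DriftDiffusionTable(
        bin_edges=edges,
        mu=mu,
        sigma2=s2,
        counts=np.full_like(mu, 100, dtype=np.int64),
        weights=np.array([0.5, 0.25, 0.25]),
        lag=0.05,
        forcing=ForcingSpec(),
    )


class TestEstimator:
    def test_error_shrinks_with_sample_size(self):
        """Drift-slope error decreases roughly like 1/sqrt(n)."""
        errors = []
        for n_paths in (50, 800):
            x = simulate_ou(theta=1.0, s=0.3, n_steps=500, n_paths=n_paths, seed=4)
            coeffs, counts = estimate_from_series(x, dt=0.01, bin_width=0.1)
            good = counts > 50
            slope = np.polyfit(coeffs.centers[good], coeffs.mu[good], 1, w=counts[good])[0]
            errors.append(abs(slope + 1.0))
        assert errors[1] < errors[0]

    def test_regime_grouping_matches_schedule(self, small_ensemble):
        """Increment counts split ~(1/2, 1/4, 1/4) across forcing regimes."""
        table = estimate_drift_diffusion(small_ensemble, bin_width=0.04)
        totals = table.counts.sum(axis=1).astype(float)
        shares = totals / totals.sum()
        np.testing.assert_allclose(shares, [0.5, 0.25, 0.25], atol=0.02)

    def test_dark_regime_drift_has_interior_stable_zero(self, small_ensemble):
        """Unforced drift pushes back toward the metastable point near c = 0."""
        table = estimate_drift_diffusion(small_ensemble, bin_width=0.04)
        dark = table.regime(0)
        mu, _ = dark.filled()
        assert np.interp(-0.25, dark.centers, mu) > 0
        assert np.interp(0.35, dark.centers, mu) < 0

    def test_light_dark_regime_drift_shifted_negative(self, small_ensemble):
        table = estimate_drift_diffusion(small_ensemble, bin_width=0.04)
        mid = np.abs(table.centers) < 0.5
        mu_dark = np.nanmean(table.mu[0, mid])
        mu_lightdark = np.nanmean(table.mu[1, mid])
        assert mu_lightdark < mu_dark

    def test_diffusion_weakly_regime_dependent(self, small_ensemble):
        table = estimate_drift_diffusion(small_ensemble, bin_width=0.04)
        mid = np.abs(table.centers) < 0.5
        s2 = np.vstack([table.sigma2[r, mid] for r in range(3)])
        spread = np.nanmax(s2, axis=0) - np.nanmin(s2, axis=0)
        assert np.nanmedian(spread / np.nanmean(s2, axis=0)) < 0.5

    def test_requires_full_record(self, small_ensemble):
        import dataclasses

        bare = dataclasses.replace(small_ensemble, c=None)
        with pytest.raises(ValueError):
            estimate_drift_diffusion(bare)

    def test_invalid_lag(self, small_ensemble):
        with pytest.raises(ValueError):
            estimate_drift_diffusion(small_ensemble, lag_steps=0)


class TestTimeAveraging:
    def test_identical_regimes_average_to_themselves(self):
        K = 50
        mu = -np.linspace(-1, 1, K)
        s2 = np.full(K, 0.05)
        table = make_table([mu] * 3, [s2] * 3, K)
        avg = time_average_coefficients(table)
        np.testing.assert_allclose(avg.mu, mu)
        np.testing.assert_allclose(avg.sigma2, s2)

    def test_canonical_weights_applied(self):
        K = 50
        rows = [np.full(K, v) for v in (1.0, -2.0, 4.0)]
        s2 = np.full(K, 0.05)
        table = make_table(rows, [s2] * 3, K)
        avg = time_average_coefficients(table)
        np.testing.assert_allclose(avg.mu, 0.5 * 1.0 + 0.25 * -2.0 + 0.25 * 4.0)

    def test_common_sign_preserved(self):
        K = 50
        rows = [np.full(K, v) for v in (0.3, 0.1, 0.7)]
        table = make_table(rows, [np.full(K, 0.05)] * 3, K)
        assert np.all(time_average_coefficients(table).mu > 0)

    def test_empty_regime_rejected(self):
        K = 50
        mu = np.full(K, 0.1)
        table = make_table([mu, np.full(K, np.nan), mu], [np.full(K, 0.05)] * 3, K)
        with pytest.raises(ValueError):
            time_average_coefficients(table)


class TestGapFilling:
    def test_interior_gaps_interpolated_and_edges_clamped(self):
        centers = np.linspace(-0.9, 0.9, 10)
        vals = np.array([np.nan, 1.0, np.nan, 3.0, 4.0, 5.0, 6.0, 7.0, np.nan, np.nan])
        filled = fill_gaps(centers, vals)
        assert filled[0] == 1.0  # clamped flat to the left
        assert filled[2] == pytest.approx(2.0)  # linear between 1 and 3
        assert filled[-1] == 7.0  # clamped flat to the right

    def test_all_empty_rejected(self):
        with pytest.raises(ValueError):
            fill_gaps(np.array([0.0, 1.0]), np.array([np.nan, np.nan]))


class TestReducedSimulation:
    def test_zero_diffusion_flows_to_stable_drift_zero(self):
        K = 50
        centers = np.linspace(-1, 1, K + 1)[:-1] + 1.0 / K
        mu = -0.8 * centers  # single downgoing zero at c = 0
        table = make_table([mu] * 3, [np.zeros(K)] * 3, K)
        red = simulate_reduced(table, c0=0.6, n_paths=3, t_end=20.0, seed=1)
        np.testing.assert_allclose(red.terminal_c, 0.0, atol=1e-3)

    def test_boundaries_absorb_and_freeze(self):
        K = 50
        centers = np.linspace(-1, 1, K + 1)[:-1] + 1.0 / K
        mu = 2.0 * np.ones(K)  # strong positive drift to +1
        table = make_table([mu] * 3, [np.full(K, 0.01)] * 3, K)
        red = simulate_reduced(table, c0=0.0, n_paths=20, t_end=10.0, seed=2)
        assert np.all(red.terminal_c == 1.0)
        assert np.all(np.abs(red.c) <= 1.0)

    def test_modes_and_validation(self, small_ensemble):
        table = estimate_drift_diffusion(small_ensemble, bin_width=0.04)
        with pytest.raises(ValueError):
            simulate_reduced(table, c0=1.5, n_paths=2, t_end=1.0)
        with pytest.raises(ValueError):
            simulate_reduced(table, c0=0.0, n_paths=2, t_end=1.0, mode="magic")
        red = simulate_reduced(
            table, c0=-1 / 3, n_paths=5, t_end=4 * math.pi, seed=3, mode="averaged"
        )
        assert red.c.shape[0] == 5


def test_table_csv_roundtrip(tmp_path, small_ensemble):
    table = estimate_drift_diffusion(small_ensemble, bin_width=0.04)
    path = tmp_path / "coeffs.csv"
    table.to_csv(path)
    loaded = DriftDiffusionTable.from_csv(path)
    np.testing.assert_allclose(loaded.bin_edges, table.bin_edges, atol=1e-12)
    np.testing.assert_allclose(loaded.mu, table.mu, equal_nan=True)
    np.testing.assert_allclose(loaded.sigma2, table.sigma2, equal_nan=True)
    np.testing.assert_array_equal(loaded.counts, table.counts)
    assert loaded.forcing == table.forcing
    assert loaded.lag == pytest.approx(table.lag)
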