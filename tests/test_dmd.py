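"""Correctness of the Hankel-DMD core against closed-form oracles."""

import numpy as np
import pytest

from dmdeeg.dmd import (build_hankel, fit_dmd, eigenfrequencies, reconstruct,
                        reconstruct_series, mode_map, DMDResult,
                        BAND_NO_DELTA)
from dmdeeg.epochs import Segment

DT = 0.002  # 500 Hz


def _linear_system_data(A, x0, n):
    x = np.empty((len(x0), n))
    x[:, 0] = x0
    for k in range(n - 1):
        x[:, k + 1] = A @ x[:, k]
    return x


def _tones(freqs, amps, n=1000, m=2, dt=DT, topo=None):
    """Noise-free multichannel sum of sinusoids (rank 2 per tone)."""
    t = np.arange(n) * dt
    topo = np.ones((m, len(freqs))) if topo is None else np.asarray(topo)
    data = np.zeros((m, n))
    for j, (f, a) in enumerate(zip(freqs, amps)):
        data += a * np.outer(topo[:, j], np.sin(2 * np.pi * f * t + 0.3 * j))
    return data


class TestBuildHankel:
    def test_identity_stack(self, rng):
        X = rng.standard_normal((3, 20))
        h = build_hankel(X, S=1, dt=DT)
        np.testing.assert_array_equal(h.values, X)

    def test_dimension_law_at_reference_geometry(self, rng):
        X = rng.standard_normal((19, 1000))
        h = build_hankel(X, S=48, dt=DT)
        assert h.values.shape == (912, 953)

    def test_matches_brute_force_enumeration(self):
        """2-channel, 5-sample toy with S=2: every element equals the directly
        enumerated delay-embedding."""
        X = np.arange(10.0).reshape(2, 5)
        h = build_hankel(X, S=2, dt=DT)
        N_S = 4
        expected = np.zeros((4, N_S))
        for s in range(2):          # block row = copy delayed by s samples
            for i in range(2):
                for k in range(N_S):
                    expected[s * 2 + i, k] = X[i, k + s]
        np.testing.assert_array_equal(h.values, expected)

    def test_oversized_stack_rejected(self, rng):
        with pytest.raises(ValueError, match="S"):
            build_hankel(rng.standard_normal((2, 5)), S=5, dt=DT)


class TestFitDMD:
    def test_recovers_known_linear_map_eigenvalues(self):
        """Data from y_{k+1} = A y_k with eigenvalues {0.9, 0.5}: DMD recovers
        them to 1e-8 (direct eigendecomposition oracle)."""
        P = np.array([[1.0, 1.0], [0.0, 1.0]])
        A = P @ np.diag([0.9, 0.5]) @ np.linalg.inv(P)
        x = _linear_system_data(A, np.array([1.0, 2.0]), 40)
        res = fit_dmd(build_hankel(x, S=1, dt=DT), R=2)
        got = np.sort(res.eigenvalues.real)
        oracle = np.sort(np.linalg.eigvals(A).real)
        np.testing.assert_allclose(got, oracle, atol=1e-8)
        assert np.abs(res.eigenvalues.imag).max() < 1e-8

    def test_pure_oscillation_on_unit_circle(self):
        """A noise-free 10 Hz sinusoid yields a conjugate eigenvalue pair with
        | |lambda| - 1 | < 1e-6 (analytic: e^{+-2 pi i 10 dt})."""
        x = _tones([10.0], [1.0])
        res = fit_dmd(build_hankel(x, S=4, dt=DT), R=4)
        mags = np.abs(res.eigenvalues)
        dominant = np.argsort(np.abs(res.amplitudes))[-2:]
        assert np.all(np.abs(mags[dominant] - 1) < 1e-6)
        freqs = eigenfrequencies(res)
        assert np.allclose(np.sort(np.abs(freqs[dominant])), [10, 10],
                           atol=1e-6)

    def test_noise_free_reconstruction_exact(self):
        """Rank-4 signal (two tones), R >= 4: relative Frobenius error of the
        full-series reconstruction < 1e-6, and snapshot 1 matches y_1."""
        x = _tones([6.0, 22.0], [1.0, 0.7])
        h = build_hankel(x, S=8, dt=DT)
        res = fit_dmd(h, R=8)
        recon = reconstruct_series(res, x.shape[1])
        err = np.linalg.norm(recon - x) / np.linalg.norm(x)
        assert err < 1e-6
        y1 = reconstruct(res, 1)
        np.testing.assert_allclose(y1, h.values[:, 0], atol=1e-6)

    def test_all_zero_input_flagged_empty(self):
        h = build_hankel(np.zeros((2, 50)), S=2, dt=DT)
        with pytest.warns(UserWarning, match="all-zero"):
            res = fit_dmd(h, R=10)
        assert res.is_empty
        assert np.all(np.isfinite(reconstruct(res, 1)))

    def test_excessive_rank_clipped_with_warning(self, rng):
        h = build_hankel(rng.standard_normal((2, 20)), S=2, dt=DT)
        with pytest.warns(UserWarning, match="clip"):
            res = fit_dmd(h, R=500)
        assert res.rank <= h.n_cols - 1

    def test_projected_convention_shares_eigenvalues(self, rng):
        x = _tones([6.0, 22.0], [1.0, 0.7])
        h = build_hankel(x, S=8, dt=DT)
        exact = fit_dmd(h, R=8, mode_convention="exact")
        proj = fit_dmd(h, R=8, mode_convention="projected")
        np.testing.assert_allclose(np.sort_complex(exact.eigenvalues),
                                   np.sort_complex(proj.eigenvalues),
                                   atol=1e-9)
        assert exact.modes.shape == proj.modes.shape

    def test_conjugate_closure_on_real_data(self, rng):
        x = rng.standard_normal((3, 60))
        res = fit_dmd(build_hankel(x, S=2, dt=DT), R=6)
        lam = res.eigenvalues
        paired = np.sort_complex(lam)
        conj = np.sort_complex(lam.conj())
        np.testing.assert_allclose(paired, conj, atol=1e-8)


class TestEigenfrequencies:
    def _result(self, eigvals):
        lam = np.asarray(eigvals, dtype=complex)
        r = len(lam)
        return DMDResult(np.ones((2, r), complex), lam, np.ones(r, complex),
                         rank=r, dt=DT, M=2, S=1)

    def test_closed_forms(self):
        lam10 = np.exp(2j * np.pi * 10 * DT)
        freqs = eigenfrequencies(self._result([1.0, lam10, lam10.conjugate()]))
        assert freqs[0] == 0.0
        assert freqs[1] == pytest.approx(10.0, abs=1e-12)
        assert freqs[2] == pytest.approx(-10.0, abs=1e-12)

    def test_zero_eigenvalue_dropped_with_index_map(self):
        with pytest.warns(UserWarning, match="zero eigenvalue"):
            freqs, idx = eigenfrequencies(self._result([0.0, 1.0]),
                                          return_index=True)
        assert list(idx) == [1]
        assert freqs.tolist() == [0.0]


class TestModeMap:
    def _result_with_freqs(self, freqs_hz, mags=None):
        lam = np.exp(2j * np.pi * np.asarray(freqs_hz) * DT)
        r = len(lam)
        modes = np.ones((3, r), complex) if mags is None else mags
        return DMDResult(modes, lam, np.ones(r, complex), rank=r, dt=DT,
                         M=3, S=1)

    def test_band_limits_are_inclusive_and_filtering_forced(self):
        mm = mode_map(self._result_with_freqs([2.0, 10.0, 45.0]), (4.0, 40.0))
        assert mm.K == 1
        np.testing.assert_allclose(mm.frequencies, [10.0])

    def test_columns_sorted_ascending(self):
        mags = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]], dtype=complex)
        mm = mode_map(self._result_with_freqs([30.0, 5.0], mags), (4.0, 40.0))
        np.testing.assert_allclose(mm.frequencies, [5.0, 30.0])
        np.testing.assert_allclose(mm.magnitudes[:, 0], [2.0, 4.0, 6.0])

    def test_empty_band_is_valid(self):
        with pytest.warns(UserWarning, match="passband"):
            mm = mode_map(self._result_with_freqs([2.0]), (4.0, 40.0))
        assert mm.K == 0 and mm.magnitudes.shape == (3, 0)

    def test_magnitudes_nonnegative_and_in_band(self, rng):
        x = rng.standard_normal((4, 300))
        res = fit_dmd(build_hankel(x, S=6, dt=DT), R=30)
        mm = mode_map(res, BAND_NO_DELTA)
        assert np.all(mm.magnitudes >= 0)
        assert np.all((mm.frequencies >= 4) & (mm.frequencies <= 40))
        assert np.all(np.diff(mm.frequencies) >= 0)

    def test_two_tone_frequency_and_topography_recovery(self):
        """Noise-free 6 + 22 Hz mixture with distinct topographies at the
        reference geometry (19 ch, S=48, R=100): retained frequencies cluster
        within 0.5 Hz of the planted tones and each cluster's magnitude
        profile correlates > 0.95 with its planted topography."""
        m = 19
        topo = np.zeros((m, 2))
        topo[:10, 0] = np.linspace(1, 2, 10)      # anterior-weighted 6 Hz
        topo[9:, 1] = np.linspace(2, 1, 10)       # posterior-weighted 22 Hz
        x = _tones([6.0, 22.0], [1.0, 1.0], n=1000, m=m, topo=topo)
        res = fit_dmd(build_hankel(x, S=48, dt=DT), R=100)
        mm = mode_map(res, BAND_NO_DELTA)
        for f_true, col_true in [(6.0, topo[:, 0]), (22.0, topo[:, 1])]:
            near = np.abs(mm.frequencies - f_true) <= 0.5
            assert near.any()
            profile = mm.magnitudes[:, near].mean(axis=1)
            r = np.corrcoef(profile, col_true)[0, 1]
            assert r > 0.95

    def test_block_mean_reduction_shape(self, rng):
        x = rng.standard_normal((3, 200))
        res = fit_dmd(build_hankel(x, S=5, dt=DT), R=20)
        mm = mode_map(res, (0.5, 100.0), reduction="block_mean")
        assert mm.magnitudes.shape[0] == 3
        assert np.all(mm.magnitudes >= 0)


class TestPlantedFrequencyRecovery:
    def test_synthetic_segment_frequencies_within_half_hz(self):
        """Generator-planted component frequencies are recoverable from a
        noise-free 2-s segment at the reference geometry within 0.5 Hz."""
        from dmdeeg.synth import CohortSpec, generate_recording
        from dmdeeg.epochs import Epoch, segment_epoch

        flat = np.ones(19)
        spec = CohortSpec(
            band_components={g: [(6.0, flat, 3.0), (10.0, flat, 2.0),
                                 (21.0, flat, 1.0)]
                             for g in ("AD", "FTD", "CN")},
            noise_scale=0.0, stim_amplitude=0.0, duration=30.0, seed=5)
        rec, _ = generate_recording(spec, 0, "CN")
        seg = segment_epoch(Epoch("S0", 0, 0.0, rec.data[:, :12000], rec.fs))[0]
        res = fit_dmd(build_hankel(seg, S=48), R=100)
        mm = mode_map(res, BAND_NO_DELTA)
        strength = mm.magnitudes.mean(axis=0)
        top = mm.frequencies[np.argsort(strength)[-3:]]
        for f_true in (6.0, 10.0, 21.0):
            assert np.min(np.abs(top - f_true)) <= 0.5
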