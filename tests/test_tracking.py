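"""Rolling Floquet analysis, track matching/labelling and spatial modes."""

import numpy as np
import pytest

from floquet_ews import (
    EmbeddingConfig,
    SpatioTemporalField,
    UniformSeries,
    classify_tracks,
    detect_crossing,
    extract_spatial_mode,
    match_tracks,
    mode_change_map,
    rolling_floquet,
)
from floquet_ews.dmd import DMDFit
from floquet_ews.tracking import EigenTrack


def make_track(spectra, n_space=1):
    """EigenTrack from a list of per-window eigenvalue lists."""
    fits = []
    for w, eig in enumerate(spectra):
        eig = np.asarray(eig, dtype=complex)
        fits.append(DMDFit(
            eigenvalues=eig,
            modes=np.eye(max(len(eig), 1), len(eig), dtype=complex),
            singular_values=np.ones(len(eig)), rank_used=len(eig),
            centered=False, t_start=float(w)))
    tr = EigenTrack(window_times=np.arange(len(spectra), dtype=float),
                    fits=fits, n_space=n_space)
    tr.filtered_max = np.array([np.max(np.abs(f.eigenvalues)) for f in fits])
    return tr


class TestRollingFloquet:
    def test_pure_cosine_periodic_identity(self):
        period = 60
        t = np.arange(600, dtype=float)
        s = UniformSeries(t, np.cos(2 * np.pi * t / period))
        tr = rolling_floquet(
            s, EmbeddingConfig(m=2, tau=15, T_steps=period, window_len=120,
                               stride=40), rank="auto")
        for fit in tr.fits:
            assert abs(fit.eigenvalues[0] - 1.0) < 1e-6

    def test_ar1_period_lag_closed_form(self, ar1):
        """E[x_{t+T} | x_t] = phi^T x_t: the one-window multiplier magnitude
        matches phi^T within 3 Monte-Carlo SEs over replicates."""
        phi, T = 0.99, 100
        mags = []
        for seed in range(20):
            s = ar1(phi, 3000, seed=seed)
            tr = rolling_floquet(
                s, EmbeddingConfig(m=1, tau=1, T_steps=T, window_len=2900,
                                   stride=3000), rank=1)
            mags.append(abs(tr.fits[0].eigenvalues[0]))
        mags = np.asarray(mags)
        se = mags.std(ddof=1) / np.sqrt(len(mags))
        assert abs(mags.mean() - phi ** T) < 3 * se

    def test_windows_with_missing_data_are_skipped_not_fatal(self, rng):
        v = rng.standard_normal(500)
        v[100:180] = np.nan  # kills windows overlapping the hole
        s = UniformSeries(np.arange(500, dtype=float), v)
        tr = rolling_floquet(
            s, EmbeddingConfig(m=1, tau=1, T_steps=10, window_len=100,
                               stride=50), rank=1)
        assert tr.n_windows >= 1
        assert len(tr.skipped) >= 1

    def test_too_short_data_rejected(self, rng):
        s = UniformSeries(np.arange(50.0), rng.standard_normal(50))
        with pytest.raises(ValueError, match="shorter"):
            rolling_floquet(s, EmbeddingConfig(m=1, tau=1, T_steps=40,
                                               window_len=60, stride=10))


class TestMatchTracks:
    def test_identical_spectra_chain_fully(self):
        tr = make_track([[0.9, 0.4], [0.9, 0.4]])
        match_tracks(tr)
        assert sorted(len(c) for c in tr.tracks) == [2, 2]
        for chain in tr.tracks:
            a = tr.fits[chain[0][0]].eigenvalues[chain[0][1]]
            b = tr.fits[chain[1][0]].eigenvalues[chain[1][1]]
            assert a == b

    def test_new_eigenvalue_starts_new_track(self):
        tr = make_track([[0.9], [0.9, 0.3]])
        match_tracks(tr)
        births = [c for c in tr.tracks if c[0][0] == 1]
        assert len(births) == 1

    def test_large_jump_breaks_chain(self):
        tr = make_track([[0.9], [0.2]])
        match_tracks(tr, max_jump=0.2)
        assert all(len(c) == 1 for c in tr.tracks)

    def test_recovers_drifting_chains_against_assignment_oracle(self, rng):
        """Slowly drifting spectra in permuted storage order: greedy chains
        equal the brute-force optimal assignment's chains."""
        n_w, k = 12, 4
        base = np.array([0.95 + 0j, 0.6 + 0.2j, 0.6 - 0.2j, 0.15 + 0j])
        truth = [base + 0.005 * w * np.array([1, -1, -1, 1]) for w in range(n_w)]
        perms = [rng.permutation(k) for _ in range(n_w)]
        spectra = [truth[w][perms[w]] for w in range(n_w)]
        tr = make_track(spectra)
        match_tracks(tr, max_jump=0.2)
        long_chains = [c for c in tr.tracks if len(c) == n_w]
        assert len(long_chains) == k
        for chain in long_chains:
            # each chain must follow a single true eigenvalue
            ids = {int(np.argmin(np.abs(
                truth[w] - tr.fits[w].eigenvalues[e]))) for w, e in chain}
            assert len(ids) == 1

    def test_optimal_assignment_agrees_on_separated_spectra(self, rng):
        spectra = [[0.9, 0.5, 0.1]] * 5
        a = make_track(spectra)
        b = make_track(spectra)
        match_tracks(a, method="greedy")
        match_tracks(b, method="optimal")
        assert sorted(map(tuple, a.tracks)) == sorted(map(tuple, b.tracks))


class TestClassifyTracks:
    def test_seasonal_and_rising_candidate(self):
        spectra = [[1.0, 0.6 + 0.035 * w] for w in range(11)]
        tr = make_track(spectra)
        match_tracks(tr, max_jump=0.2)
        classify_tracks(tr, seasonal_band=0.05, min_coverage=0.9)
        assert "seasonal" in tr.labels
        assert "csd_candidate" in tr.labels
        k = tr.labels.index("seasonal")
        _, mag = tr.track_magnitudes(k)
        assert np.allclose(mag, 1.0)

    def test_all_small_tracks_are_noise(self):
        tr = make_track([[0.25, 0.1]] * 6)
        match_tracks(tr)
        classify_tracks(tr, noise_floor=0.3)
        assert set(tr.labels) == {"noise"}
        assert np.all(tr.filtered_max < 0.3)

    def test_low_coverage_track_not_seasonal(self):
        # near-1 eigenvalue present in only 40% of windows
        spectra = [[1.0, 0.5] if w < 4 else [0.5] for w in range(10)]
        tr = make_track(spectra)
        match_tracks(tr)
        classify_tracks(tr, seasonal_band=0.05, min_coverage=0.8)
        assert "seasonal" not in tr.labels

    def test_filtered_max_excludes_seasonal(self):
        spectra = [[1.0, 0.7]] * 8
        tr = make_track(spectra)
        match_tracks(tr)
        classify_tracks(tr, seasonal_band=0.05, min_coverage=0.9)
        np.testing.assert_allclose(tr.filtered_max, 0.7)


class TestDetectCrossing:
    def test_persistent_crossing_reported_at_run_start(self):
        tr = make_track([[v] for v in [0.8, 0.9, 1.01, 1.02, 1.05]])
        assert detect_crossing(tr, threshold=1.0, persistence=2) == 2.0

    def test_transient_spike_ignored(self):
        tr = make_track([[v] for v in [0.8, 1.2, 0.7, 0.8]])
        assert detect_crossing(tr, threshold=1.0, persistence=2) is None

    def test_subthreshold_series_yields_none(self):
        tr = make_track([[v] for v in [0.5, 0.9, 0.99]])
        assert detect_crossing(tr, threshold=1.0, persistence=1) is None


def _planted_field(v_list, lams, amps, n, noise_sd, rng, grid):
    tt = np.arange(n)
    data = sum(a * np.outer(v, lam ** tt)
               for v, lam, a in zip(v_list, lams, amps))
    data = data + noise_sd * rng.standard_normal(data.shape)
    return SpatioTemporalField(tt.astype(float), data, grid)


class TestSpatialModes:
    def test_rank_one_field_mode_matches_pattern(self, rng):
        grid = (8, 8)
        v = np.abs(rng.standard_normal(64)) + 0.1
        v /= np.linalg.norm(v)
        fld = _planted_field([v], [0.9], [50.0], 40, 0.0, rng, grid)
        tr = rolling_floquet(fld, EmbeddingConfig(m=1, tau=1, T_steps=1,
                                                  window_len=39, stride=40),
                             rank=1)
        mode = extract_spatial_mode(tr.fits[0], 64, 0)
        cos = np.dot(mode.values, v)
        assert cos > 0.999
        assert np.linalg.norm(mode.values) == pytest.approx(1.0)

    def test_m1_mode_equals_full_mode_magnitude(self, rng):
        grid = (4, 4)
        v = np.abs(rng.standard_normal(16)) + 0.1
        fld = _planted_field([v], [0.8], [10.0], 20, 0.0, rng, grid)
        tr = rolling_floquet(fld, EmbeddingConfig(m=1, tau=1, T_steps=1,
                                                  window_len=19, stride=20),
                             rank=1)
        fit = tr.fits[0]
        mode = extract_spatial_mode(fit, 16, 0)
        full = np.abs(fit.modes[:, 0])
        np.testing.assert_allclose(mode.values, full / np.linalg.norm(full),
                                   atol=1e-12)

    def test_mode_index_out_of_range(self, rng):
        grid = (4, 4)
        v = np.abs(rng.standard_normal(16)) + 0.1
        fld = _planted_field([v], [0.8], [10.0], 20, 0.0, rng, grid)
        tr = rolling_floquet(fld, EmbeddingConfig(m=1, tau=1, T_steps=1,
                                                  window_len=19, stride=20),
                             rank=1)
        with pytest.raises(IndexError):
            extract_spatial_mode(tr.fits[0], 16, which=5)

    def test_noise_barely_moves_dominant_eigenvalue(self, rng):
        """Spatially i.i.d. noise at half the signal SD changes the dominant
        eigenvalue by < 0.05 at the planted rank."""
        grid = (10, 10)
        v = np.abs(rng.standard_normal(100)) + 0.2
        v /= np.linalg.norm(v)
        clean = _planted_field([v], [0.95], [30.0], 60, 0.0, rng, grid)
        sd = 0.5 * clean.data.std()
        noisy = SpatioTemporalField(
            clean.times, clean.data + sd * rng.standard_normal(clean.data.shape),
            grid)
        cfg = EmbeddingConfig(m=1, tau=1, T_steps=1, window_len=59, stride=60)
        e_clean = abs(rolling_floquet(clean, cfg, rank=1).fits[0].eigenvalues[0])
        e_noisy = abs(rolling_floquet(noisy, cfg, rank=1).fits[0].eigenvalues[0])
        assert abs(e_clean - e_noisy) < 0.05

    def test_mode_change_map_stationary_pattern_is_flat(self, rng):
        grid = (8, 8)
        v = np.abs(rng.standard_normal(64)) + 0.2
        v /= np.linalg.norm(v)
        n = 200
        z = np.empty(n)
        z[0] = 0.0
        for k in range(1, n):
            z[k] = 0.9 * z[k - 1] + rng.standard_normal()
        data = np.outer(v, 5.0 * z) + 0.05 * rng.standard_normal((64, n))
        fld = SpatioTemporalField(np.arange(n, dtype=float), data, grid)
        tr = rolling_floquet(fld, EmbeddingConfig(m=1, tau=1, T_steps=1,
                                                  window_len=40, stride=20),
                             rank=1)
        match_tracks(tr, max_jump=0.5)
        classify_tracks(tr, seasonal_band=0.01, noise_floor=0.1)
        diff = mode_change_map(tr, [0, 1, 2], [tr.n_windows - 3,
                                               tr.n_windows - 2,
                                               tr.n_windows - 1])
        assert np.max(np.abs(diff)) < 0.02

    def test_mode_change_map_overlapping_sets_allowed(self, rng):
        grid = (6, 6)
        v = np.abs(rng.standard_normal(36)) + 0.2
        fld = _planted_field([v], [0.9], [20.0], 120, 0.1, rng, grid)
        tr = rolling_floquet(fld, EmbeddingConfig(m=1, tau=1, T_steps=1,
                                                  window_len=30, stride=15),
                             rank=1)
        match_tracks(tr, max_jump=0.5)
        classify_tracks(tr, seasonal_band=0.01, noise_floor=0.1)
        diff = mode_change_map(tr, [0, 1, 2], [1, 2, 3])
        assert diff.shape == (36,)

    def test_mode_change_map_requires_coverage(self):
        tr = make_track([[0.9]] * 4)
        match_tracks(tr)
        classify_tracks(tr, seasonal_band=0.01, noise_floor=0.1)
        with pytest.raises(ValueError, match="no track labelled|cover"):
            mode_change_map(tr, [0], [99])


class TestRampedPitchforkRise:
    def test_filtered_max_rises_towards_crossing(self):
        """On the ramped seasonal pitchfork, the filtered maximum multiplier
        in the final approach exceeds its pre-ramp level (the rise of the
        candidate mode towards the stability threshold)."""
        from floquet_ews import PitchforkParams, simulate_pitchfork
        from floquet_ews.experiments import PITCHFORK_ANALYSIS, _run_floquet

        ok = 0
        for seed in range(3):
            run = simulate_pitchfork(PitchforkParams(seed=seed))
            tr = _run_floquet(run.output, PITCHFORK_ANALYSIS)
            t = tr.window_times
            cross = tr.crossing_time if tr.crossing_time is not None else t[-1]
            pre = np.median(tr.filtered_max[t < 10.0])
            late = np.median(tr.filtered_max[(t > cross - 2.0) & (t <= cross)])
            ok += late > pre
        assert ok >= 2
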