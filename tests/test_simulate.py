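"""Synthetic-data generators: statistical structure and determinism."""

import numpy as np
import pandas as pd
import pytest

import spliceproof as sp
from conftest import K_FWD2, K_OFF_A, K_OFF_INT


def acq(frame_interval=3.0, n_frames=400, photobleach_rate=0.0, noise_sd=0.1, seed=0):
    return sp.AcquisitionSettings(
        frame_interval=frame_interval,
        n_frames=n_frames,
        photobleach_rate=photobleach_rate,
        noise_sd=noise_sd,
        seed=seed,
    )


class TestDwellTimes:
    def test_pure_exponential_mean(self):
        scheme = sp.KineticScheme(k_off_int=0.1, k_fwd2=0.0)
        ds = sp.simulate_dwell_times(scheme, 20_000, acq(frame_interval=0.1, n_frames=5000, seed=2))
        # discretisation floors each dwell by up to one frame
        mean = ds.durations[~ds.censored].mean()
        se = ds.durations.std() / np.sqrt(ds.n)
        assert abs(mean + 0.05 - 10.0) < 3 * se + 0.1

    def test_determinism_given_seed(self):
        scheme = sp.KineticScheme(k_off_int=K_OFF_INT, k_fwd2=K_FWD2, k_off_A=K_OFF_A)
        a = sp.simulate_dwell_times(scheme, 500, acq(seed=7))
        b = sp.simulate_dwell_times(scheme, 500, acq(seed=7))
        pd.testing.assert_frame_equal(a.to_frame(), b.to_frame())

    def test_empirical_survival_matches_closed_form(self, slow_smt_scheme):
        ds = sp.simulate_dwell_times(slow_smt_scheme, 10_000, acq(seed=3))
        kept = ds.durations
        dt = 3.0
        # detection conditions on surviving the first frame
        s_detect = float(sp.survival_bound(dt, slow_smt_scheme))
        for m in (2, 5, 10, 30, 60):
            p_emp = np.mean(kept >= m * dt)
            p_th = float(sp.survival_bound(m * dt, slow_smt_scheme)) / s_detect
            band = 2.58 * np.sqrt(p_th * (1 - p_th) / ds.n)
            assert abs(p_emp - p_th) < band + 1e-3

    def test_photobleaching_censors(self, slow_smt_scheme):
        ds = sp.simulate_dwell_times(
            slow_smt_scheme, 3000, acq(photobleach_rate=0.02, seed=4)
        )
        assert ds.censored.mean() > 0.2
        clean = sp.simulate_dwell_times(slow_smt_scheme, 3000, acq(seed=4))
        assert clean.censored.mean() < 0.05

    def test_full_scheme_mode_accumulates_e_state_time(self):
        scheme = sp.KineticScheme(
            k_off_E=1.0, k_fwd1=5.0, k_off_int=K_OFF_INT, k_fwd2=K_FWD2, k_off_A=K_OFF_A
        )
        ds = sp.simulate_dwell_times(
            scheme, 5000, acq(frame_interval=0.5, n_frames=4000, seed=5), start_state="E"
        )
        assert ds.n > 1000  # most events pass the E checkpoint at Kf = 5


class TestPifeTraces:
    def test_noise_free_thresholding_recovers_path(self):
        traces = sp.simulate_pife_traces(0.05, 0.05, acq(1.0, 500, noise_sd=0.0, seed=6), 5)
        for t in traces:
            recovered = (t.intensity > 1.25).astype(int)
            np.testing.assert_array_equal(recovered, t.true_state)

    def test_emission_scale_leaves_state_path_unchanged(self):
        a1 = sp.AcquisitionSettings(1.0, 300, emission_low=1.0, emission_high=1.5, seed=8)
        a2 = sp.AcquisitionSettings(1.0, 300, emission_low=2.0, emission_high=3.0, seed=8)
        t1 = sp.simulate_pife_traces(0.03, 0.057, a1, 10)
        t2 = sp.simulate_pife_traces(0.03, 0.057, a2, 10)
        for x, y in zip(t1, t2):
            np.testing.assert_array_equal(x.true_state, y.true_state)

    def test_high_state_dwell_matches_independent_discretised_simulation(self):
        # oracle: an independently coded grid-sampled telegraph gives the
        # discretisation-biased mean run length for the same rates
        k_on, k_off, dt = 0.03, 0.057, 1.0
        traces = sp.simulate_pife_traces(k_on, k_off, acq(dt, 500, seed=9), 300)
        def mean_interior_run(paths):
            runs = []
            for p in paths:
                change = np.flatnonzero(np.diff(p)) + 1
                starts = np.concatenate([[0], change])
                ends = np.concatenate([change, [p.size]])
                for i, (s, e) in enumerate(zip(starts, ends)):
                    if 0 < i < starts.size - 1 and p[s] == 1:
                        runs.append(e - s)
            return np.mean(runs) * dt, np.std(runs) * dt / np.sqrt(len(runs))

        got, se_got = mean_interior_run([t.true_state for t in traces])
        rng = np.random.default_rng(99)
        oracle_paths = []
        times = (np.arange(500) + 1) * dt
        for _ in range(300):
            state = int(rng.random() < k_on / (k_on + k_off))
            jumps, states, t = [0.0], [state], 0.0
            while t < times[-1]:
                t += rng.exponential(1.0 / (k_off if state else k_on))
                state = 1 - state
                jumps.append(t)
                states.append(state)
            idx = np.searchsorted(jumps, times, side="right") - 1
            oracle_paths.append(np.asarray(states)[idx])
        want, se_want = mean_interior_run(oracle_paths)
        assert got == pytest.approx(want, abs=3 * np.hypot(se_got, se_want))


class TestTitration:
    def test_exact_isotherm_values(self):
        table = sp.simulate_titration(27.0, 1.5, [0.0, 27.0, 1e9], noise_sd=0.0)
        f = table.set_index("concentration_nM")["rel_fluorescence"]
        assert f.loc[0.0] == pytest.approx(1.0)
        assert f.loc[27.0] == pytest.approx(1.25)
        assert f.loc[1e9] == pytest.approx(1.5, abs=1e-6)


class TestSiteCompetition:
    def test_symmetric_sites(self):
        p, se = sp.simulate_site_competition(
            sp.ProofreadingParams(Kf=1.0, Ks=1.0), 0.0, n_trials=20_000, seed=1
        )
        assert p == pytest.approx(0.5, abs=3 * se)

    def test_small_checkpoint_ratios_approach_full_proofreading(self):
        params = sp.ProofreadingParams(Kf=0.01, Ks=0.01)
        p, se = sp.simulate_site_competition(params, 1.0, n_trials=10_000, seed=2)
        # at Kf = Ks = 0.01 the chain sits within ~0.005 of the limiting curve
        assert p == pytest.approx(float(sp.psi_full_proofreading(1.0)), abs=3 * se + 0.005)

    def test_agrees_with_closed_form_on_grid(self):
        # per-point 4*SE bound keeps the joint false-alarm rate of the grid
        # comparison below 0.1%; most points must sit inside 3*SE
        zs = []
        for kf, ks, ddg, seed in [(10, 0.15, 1.0, 3), (1, 1, -1.0, 4), (0.15, 2.0, 0.5, 5)]:
            params = sp.ProofreadingParams(Kf=kf, Ks=ks)
            p, se = sp.simulate_site_competition(params, ddg, n_trials=40_000, seed=seed)
            zs.append(abs(p - float(sp.psi(ddg, params))) / se)
        assert max(zs) < 4.0
        assert np.mean(np.asarray(zs) < 3.0) >= 2 / 3


class TestPsiDataset:
    def test_high_depth_no_overdispersion_recovers_truth(self):
        params = sp.ProofreadingParams(Kf=10, Ks=0.15)
        table = sp.simulate_psi_dataset(params, [-1.0, 1.0], 20, depth=200_000, seed=6)
        err = (table["psi_obs"] - table["psi_true"]).abs().max()
        assert err < 0.005

    def test_binned_medians_trace_the_proofreading_sigmoid(self):
        params = sp.ProofreadingParams(Kf=10, Ks=0.15)
        grid = np.linspace(-3, 3, 13)
        binned = sp.bin_psi_table(sp.simulate_psi_dataset(params, grid, 50, 200, seed=7))
        pred = np.asarray(sp.psi(binned["ddg"].to_numpy(), params))
        assert np.max(np.abs(binned["psi"].to_numpy() - pred)) < 0.03

    def test_ks_scaling_reproduces_delta_psi(self):
        params = sp.ProofreadingParams(Kf=10, Ks=0.15)
        grid = np.linspace(-3, 3, 13)
        base = sp.bin_psi_table(
            sp.simulate_psi_dataset(params, grid, 100, 500, seed=8, condition="c")
        )
        scaled = sp.bin_psi_table(
            sp.simulate_psi_dataset(params, grid, 100, 500, seed=9, ks_scale=5.9, condition="k")
        )
        observed = scaled["psi"].to_numpy() - base["psi"].to_numpy()
        predicted = np.asarray(sp.delta_psi(grid, params, 5.9))
        assert np.max(np.abs(observed - predicted)) < 0.04


class TestRbnsReads:
    def test_uniform_model_gives_flat_enrichment(self):
        flat = sp.EnergyModel(penalties=np.zeros((4, 4)))
        pool, ip = sp.simulate_rbns_reads(flat, 20.0, 3000, read_len=20, seed=10)
        enr = sp.compute_enrichment(
            sp.KmerCountTable.from_reads(ip, 3, "ip"),
            sp.KmerCountTable.from_reads(pool, 3, "input"),
        )
        assert enr.table["r"].between(0.9, 1.1).mean() > 0.95

    def test_saturation_limit_returns_input_statistics(self):
        model = sp.u2af_like_model(k=6)
        pool, ip = sp.simulate_rbns_reads(model, np.inf, 3000, read_len=20, seed=11)
        enr = sp.compute_enrichment(
            sp.KmerCountTable.from_reads(ip, 3, "ip"),
            sp.KmerCountTable.from_reads(pool, 3, "input"),
        )
        assert enr.table["r"].between(0.9, 1.1).mean() > 0.95

    def test_concentration_compresses_dynamic_range(self):
        # saturation at high protein concentration compresses enrichment
        model = sp.u2af_like_model(k=6, u_penalty=1.2)
        r_span = {}
        for conc in (5.0, 500.0):
            pool, ip = sp.simulate_rbns_reads(model, conc, 6000, read_len=20, seed=12)
            enr = sp.compute_enrichment(
                sp.KmerCountTable.from_reads(ip, 4, "ip"),
                sp.KmerCountTable.from_reads(pool, 4, "input"),
            )
            tab = enr.table.assign(n_u=enr.table["kmer"].str.count("U"))
            med = tab.groupby("n_u")["r"].median()
            r_span[conc] = med.max() / med.min()
        assert r_span[500.0] < r_span[5.0]


class TestTranscriptionSplicingTraces:
    def test_noise_free_single_cycle_duration(self):
        a = sp.AcquisitionSettings(0.25, 2000, noise_sd=0.0, seed=13)
        traces = sp.simulate_transcription_splicing_traces(
            16.0, 1e-9 + 1 / 1e6, 1.7, 0.9, a, 1, duration_dist="fixed"
        )
        t = traces[0]
        on = t.intensity > 1.25
        if on.any():
            dur = on.sum() * 0.25
            assert dur == pytest.approx(16.0, abs=0.5)

    def test_zero_dwell_flattens_binding_channel(self):
        a = sp.AcquisitionSettings(0.25, 2000, noise_sd=0.0, seed=14)
        traces = sp.simulate_transcription_splicing_traces(16.0, 1 / 30.0, 0.0, 0.9, a, 3)
        for t in traces:
            assert np.ptp(t.intensity2) == pytest.approx(0.0)

    def test_binding_pulse_precedes_splicing_step(self):
        a = sp.AcquisitionSettings(0.25, 4800, noise_sd=0.0, seed=15)
        traces = sp.simulate_transcription_splicing_traces(16.0, 1 / 30.0, 1.7, 2.0, a, 20)
        lead = []
        for t in traces:
            ms2 = t.intensity > 1.25
            u2 = t.intensity2 > 1.25
            downs = np.flatnonzero(ms2[:-1] & ~ms2[1:])
            for d in downs:
                pulse = np.flatnonzero(u2[: d + 1])
                if pulse.size:
                    lead.append((d - pulse.mean()) * 0.25)
        assert np.median(lead) > 0  # binding happens before the down-step


class TestMetagene:
    def test_half_life_is_the_median(self):
        table = sp.simulate_metagene(20_000, 18.0, seed=16)
        med = table["splice_time"].median()
        assert med == pytest.approx(18.0, rel=0.05)

    def test_doubling_half_life_doubles_the_fitted_rate_inverse(self):
        t1 = sp.simulate_metagene(20_000, 9.0, seed=17)["splice_time"].mean()
        t2 = sp.simulate_metagene(20_000, 18.0, seed=17)["splice_time"].mean()
        assert t2 / t1 == pytest.approx(2.0, rel=0.05)

    def test_observation_limit_censors(self):
        table = sp.simulate_metagene(1000, 18.0, seed=18, observation_limit=18.0)
        assert 0.3 < table["censored"].mean() < 0.7
        assert table["splice_time"].max() <= 18.0
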