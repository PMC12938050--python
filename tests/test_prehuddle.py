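"""Roles, pre-onset features, wPersistence, HMM fitting and the clustered bootstrap."""

import numpy as np
import pytest

import huddlekit as hk
from huddlekit.prehuddle import (
    clustered_bootstrap,
    decode_windows,
    fit_hmm_select,
    stationary_distribution,
    window_displacement,
    wpersistence,
)
from conftest import dyadic_role_cases


class TestWPersistence:
    def test_identity_matrix_gives_one(self):
        assert wpersistence(np.eye(3)) == pytest.approx(1.0)

    def test_symmetric_two_state_gives_half(self):
        assert wpersistence(np.full((2, 2), 0.5)) == pytest.approx(0.5)

    def test_matches_monte_carlo_self_transition_fraction(self):
        """Random 3x3 stochastic P vs the long-run self-transition rate (10^6 steps)."""
        rng = np.random.default_rng(17)
        P = rng.dirichlet(np.ones(3) * 2, size=3)
        w = wpersistence(P)
        cdf = np.cumsum(P, axis=1)
        u = rng.random(1_000_000)
        s = 0
        selfcount = 0
        for t in range(len(u)):
            nxt = int(np.searchsorted(cdf[s], u[t]))
            selfcount += nxt == s
            s = nxt
        assert abs(w - selfcount / len(u)) <= 0.005

    def test_rejects_non_stochastic(self):
        with pytest.raises(ValueError):
            wpersistence(np.array([[0.5, 0.2], [0.5, 0.5]]))

    def test_bounds_on_random_stochastic_matrices(self):
        rng = np.random.default_rng(3)
        for k in (2, 3, 5):
            for _ in range(20):
                P = rng.dirichlet(np.ones(k), size=k)
                assert 0.0 <= wpersistence(P) <= 1.0

    def test_stationary_is_left_fixed_point(self):
        rng = np.random.default_rng(4)
        P = rng.dirichlet(np.ones(4), size=4)
        pi, ok = stationary_distribution(P)
        assert ok
        np.testing.assert_allclose(pi @ P, pi, atol=1e-10)
        assert pi.sum() == pytest.approx(1.0)


class TestRoles:
    def _scripted_dyad(self, arrive_late_s=20.0, n_s=200.0, fps=30.0):
        """Animal 0 resident at the site from t=0; animal 1 arrives later."""
        n = int(n_s * fps)
        pos = np.zeros((4, n, 2))
        pos[0, :] = [10.0, 10.0]
        t_arrive = int(arrive_late_s * fps)
        pos[1, :t_arrive, 0] = np.linspace(60, 10.5, t_arrive)
        pos[1, :t_arrive, 1] = 10.0
        pos[1, t_arrive:] = [10.5, 10.0]
        pos[2, :] = [60.0, 60.0]
        pos[3, :] = [60.0, 20.0]
        trajs = [hk.Trajectory(f"m{a}", pos[a], np.ones(n, bool), fps) for a in range(4)]
        rec = hk.GroupRecording(trajs)
        states, events = hk.classify_state_series(rec)
        return rec, [e for e in events if e.state == 2][0]

    def test_resident_is_initiator(self):
        rec, ev = self._scripted_dyad()
        ra = hk.assign_roles(rec, ev)
        assert ra.initiator == 0 and ra.follower == 1
        assert ra.entry_time[0] <= ra.entry_time[1]

    def test_brief_dip_does_not_count_as_entry(self):
        fps = 30.0
        n = int(200 * fps)
        pos = np.zeros((4, n, 2))
        pos[0, :] = [10.0, 10.0]
        pos[1, :] = [60.0, 10.0]
        dip = slice(int(5 * fps), int(5.5 * fps))  # 0.5 s inside, then leaves
        pos[1, dip] = [11.0, 10.0]
        t2 = int(40 * fps)
        pos[1, t2:] = [10.5, 10.0]  # enters for good
        trajs = [hk.Trajectory(f"m{a}", pos[a], np.ones(n, bool), fps) for a in range(4)]
        trajs[2].body[:] = [30.0, 60.0]
        trajs[3].body[:] = [60.0, 40.0]
        rec = hk.GroupRecording(trajs)
        ev = [e for e in hk.classify_state_series(rec)[1] if e.state == 2][0]
        ra = hk.assign_roles(rec, ev)
        assert ra.follower == 1
        assert ra.entry_time[1] == pytest.approx(40.0, abs=0.2)

    def test_scripted_arrival_order_recovered_on_simulations(self, dyad_sims):
        """100% agreement with the scripted growth order over >= 50 dyadic events."""
        cases = dyadic_role_cases(dyad_sims)
        assert len(cases) >= 50
        agree = 0
        for rec, ent, ev in cases:
            ra = hk.assign_roles(rec, ev)
            assert ra is not None
            agree += ra.initiator == ent.growth_order[0]
        assert agree == len(cases)

    def test_role_assignment_invariant_to_relabeling(self):
        rec, ev = self._scripted_dyad()
        ra = hk.assign_roles(rec, ev)
        perm = [1, 0, 3, 2]
        rec2 = hk.GroupRecording([rec.trajectories[p] for p in perm], arena=rec.arena)
        ev2 = [e for e in hk.classify_state_series(rec2)[1] if e.state == 2][0]
        ra2 = hk.assign_roles(rec2, ev2)
        assert rec.trajectories[ra.initiator].animal_id == rec2.trajectories[ra2.initiator].animal_id


class TestPreWindow:
    def test_stationary_initiator_zero_displacement(self):
        rec, ev = TestRoles()._scripted_dyad(arrive_late_s=20.0, n_s=200.0)
        ra = hk.assign_roles(rec, ev)
        ws = hk.pre_window_features(rec, ra, ev)
        init = [w for w in ws if w.role == "initiator"][0]
        assert window_displacement(rec, init, ev) == pytest.approx(0.0, abs=1e-9)
        assert np.nanmax(init.dist_to_center) < 1.0

    def test_straight_approach_geometry(self):
        """5 s approach at 1 cm/s aimed at the center: displacement ~5, cos ~ 1."""
        fps = 30.0
        n = int(100 * fps)
        pos = np.zeros((4, n, 2))
        pos[0, :] = [10.0, 10.0]
        onset = int(70 * fps)
        pre = slice(onset - 150, onset)
        pos[1, : onset - 150] = [16.2, 10.0]
        pos[1, pre, 0] = np.linspace(16.2, 11.2, 150)
        pos[1, pre, 1] = 10.0
        pos[1, onset:] = [11.2, 10.0]
        pos[2, :] = [60.0, 60.0]
        pos[3, :] = [60.0, 20.0]
        trajs = []
        for a in range(4):
            body = pos[a]
            nose = body + np.array([-2.5 if a == 1 else 2.5, 0.0])  # animal 1 faces the center
            trajs.append(hk.Trajectory(f"m{a}", body, np.ones(n, bool), fps, nose=nose))
        rec = hk.GroupRecording(trajs)
        ev = hk.HuddleEvent(0, 2, (0, 1), onset, n, fps, centroid=(10.6, 10.0))
        ra = hk.assign_roles(rec, ev)
        assert ra.initiator == 0
        w = [x for x in hk.pre_window_features(rec, ra, ev) if x.animal == 1][0]
        assert window_displacement(rec, w, ev) == pytest.approx(5.0, abs=0.1)
        assert np.nanmedian(w.heading_cos) > 0.99

    def test_pooled_window_row_count(self, dyad_sims):
        """n events x 150 frames x 2 roles rows in the pooled feature matrix."""
        cases = dyadic_role_cases(dyad_sims)[:10]
        windows = []
        for rec, _, ev in cases:
            ra = hk.assign_roles(rec, ev)
            windows += [w for w in hk.pre_window_features(rec, ra, ev) if not w.short]
        total = sum(w.n_frames for w in windows)
        assert total == len(windows) * 150
        assert len(windows) == 2 * len(cases)


def _generate_2state_sequences(n_seq=100, seq_len=100, seed=0):
    """Sequences from a known sticky 2-state diagonal-Gaussian HMM."""
    rng = np.random.default_rng(seed)
    P = np.array([[0.95, 0.05], [0.08, 0.92]])
    means = np.array([[8.0, 20.0], [0.5, 2.0]])  # (speed, distance)-like
    sds = np.array([[1.5, 4.0], [0.3, 0.8]])
    cdf = np.cumsum(P, axis=1)
    windows, paths = [], []
    for i in range(n_seq):
        s = int(rng.random() < 0.5)
        states = np.empty(seq_len, dtype=int)
        for t in range(seq_len):
            states[t] = s
            s = int(np.searchsorted(cdf[s], rng.random()))
        X = rng.normal(means[states], sds[states])
        windows.append(
            hk.PreHuddleWindow(
                event_id=i, animal=i % 7, role="initiator" if i % 2 else "follower",
                speed=X[:, 0], dist_to_center=X[:, 1],
                heading_cos=np.full(seq_len, np.nan),
            )
        )
        paths.append(states)
    return windows, paths, P


class TestHmm:
    def test_selects_two_states_and_decodes_accurately(self):
        """BIC picks K=2 on well-separated 2-state data; Viterbi accuracy >= 0.9;
        transition probabilities recovered within 0.05."""
        windows, paths, P_true = _generate_2state_sequences()
        fit = fit_hmm_select(windows, K_range=(2, 3, 4), n_restarts=3, seed=0)
        assert fit.K == 2
        # align labels by mean speed: state 0 of the generator is the fast one
        fast = fit.state_labels["approaching"]
        decoded = decode_windows(fit, windows)
        acc = np.mean(
            [
                ((decoded[(w.event_id, w.animal)] == fast) == (p == 0)).mean()
                for w, p in zip(windows, paths)
            ]
        )
        assert acc >= 0.9
        perm = [fast, 1 - fast]
        P_aligned = fit.P[np.ix_(perm, perm)]
        assert np.abs(P_aligned - P_true).max() <= 0.05

    def test_log_likelihood_nondecreasing_over_em(self):
        windows, _, _ = _generate_2state_sequences(n_seq=20, seq_len=50, seed=3)
        fit = fit_hmm_select(windows, K_range=(2,), n_restarts=1, seed=1)
        hist = np.array(fit.model.monitor_.history)
        assert np.all(np.diff(hist) >= -1e-6)

    def test_constant_sequences_flagged_degenerate(self):
        windows = [
            hk.PreHuddleWindow(i, i, "initiator", np.full(50, 1.0), np.full(50, 2.0), np.full(50, np.nan))
            for i in range(4)
        ]
        fit = fit_hmm_select(windows, K_range=(2,), n_restarts=1, seed=0)
        assert fit.degenerate

    def test_wpersistence_in_fit_matches_formula(self):
        windows, _, _ = _generate_2state_sequences(n_seq=30, seq_len=60, seed=5)
        fit = fit_hmm_select(windows, K_range=(2,), n_restarts=2, seed=2)
        assert fit.wpersistence == pytest.approx(wpersistence(fit.P))


class TestBootstrap:
    def test_smoke_run_returns_requested_replicates(self):
        windows, _, _ = _generate_2state_sequences(n_seq=24, seq_len=40, seed=7)
        by_animal = {}
        for w in windows:
            by_animal.setdefault(w.animal, []).append(w)
        boot = clustered_bootstrap(by_animal, B=10, seed=0, n_restarts=1)
        assert len(boot.replicates) == 10
        assert boot.ci95[0] <= boot.median <= boot.ci95[1]

    def test_single_animal_gives_zero_width_ci(self):
        windows, _, _ = _generate_2state_sequences(n_seq=6, seq_len=40, seed=8)
        for w in windows:
            w.animal = 0
        boot = clustered_bootstrap({0: windows}, B=5, seed=1, n_restarts=1)
        assert np.ptp(boot.replicates) <= 1e-6

    def test_pooled_estimate_within_bootstrap_ci(self):
        windows, _, _ = _generate_2state_sequences(n_seq=40, seq_len=50, seed=9)
        by_animal = {}
        for w in windows:
            by_animal.setdefault(w.animal, []).append(w)
        pooled = fit_hmm_select(windows, K_range=(2,), n_restarts=2, seed=3)
        boot = clustered_bootstrap(by_animal, B=30, seed=2, n_restarts=1)
        assert boot.ci95[0] - 0.01 <= pooled.wpersistence <= boot.ci95[1] + 0.01


class TestRatios:
    def _fit_and_states(self):
        windows, _, _ = _generate_2state_sequences(n_seq=20, seq_len=50, seed=11)
        fit = fit_hmm_select(windows, K_range=(2,), n_restarts=1, seed=0)
        return fit, windows, decode_windows(fit, windows)

    def test_all_stationing_window_hits_epsilon_floor(self):
        fit, windows, _ = self._fit_and_states()
        stationing = fit.state_labels["stationing"]
        states = {(0, windows[0].animal): np.full(150, stationing)}
        w = windows[0]
        w150 = hk.PreHuddleWindow(0, w.animal, w.role, np.zeros(150), np.zeros(150), np.full(150, np.nan))
        out = hk.approach_station_ratio(states, fit, [w150])
        assert out["log_ratio"].iloc[0] == pytest.approx(np.log(1 / 151))

    def test_even_split_gives_zero(self):
        fit, windows, _ = self._fit_and_states()
        app = fit.state_labels["approaching"]
        path = np.array([app] * 75 + [1 - app] * 75)
        w = windows[0]
        w150 = hk.PreHuddleWindow(0, w.animal, w.role, np.zeros(150), np.zeros(150), np.full(150, np.nan))
        out = hk.approach_station_ratio({(0, w.animal): path}, fit, [w150])
        assert out["log_ratio"].iloc[0] == pytest.approx(0.0)

    def test_followers_approach_more_than_initiators_on_simulation(self, dyad_sims):
        cases = dyadic_role_cases(dyad_sims)[:12]
        windows = []
        for rec, _, ev in cases:
            ra = hk.assign_roles(rec, ev)
            windows += [w for w in hk.pre_window_features(rec, ra, ev) if not w.short]
        fit = fit_hmm_select(windows, K_range=(2,), n_restarts=2, seed=4)
        states = decode_windows(fit, windows)
        out = hk.approach_station_ratio(states, fit, windows)
        means = out.groupby("role")["log_ratio"].mean()
        assert means["follower"] > means["initiator"]
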