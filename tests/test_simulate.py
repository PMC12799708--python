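"""Exact SSA trajectories, embedded paths, and observables."""

import numpy as np
import pandas as pd
import pytest

from copolymer import (
    DETACH,
    PolymerState,
    RateParameters,
    Trajectory,
    dtmc_speed,
    empirical_velocity,
    final_sequences_to_fasta,
    observables,
    simulate,
    simulate_embedded,
)


def hand_trajectory() -> Trajectory:
    """attach M1 at t=0.5, attach M2 at t=1.2, detach at t=2.0."""
    params = RateParameters(kplus=(1.0, 1.0), kminus=(1.0, 1.0))
    return Trajectory(
        params=params, seed=0, horizon=3.0,
        times=np.array([0.5, 1.2, 2.0]),
        moves=np.array([0, 1, DETACH], dtype=np.int64),
    )


class TestSimulate:
    def test_zero_horizon_empty(self, strong_params):
        traj = simulate(strong_params, horizon=0.0, seed=1)
        assert traj.n_events == 0
        assert traj.levels().tolist() == [0]

    def test_same_seed_bitwise_identical(self, near_critical_params):
        a = simulate(near_critical_params, horizon=50.0, seed=42)
        b = simulate(near_critical_params, horizon=50.0, seed=42)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.moves, b.moves)
        c = simulate(near_critical_params, horizon=50.0, seed=43)
        assert not np.array_equal(a.times, c.times)

    def test_times_strictly_increasing_and_positive(self, strong_params):
        traj = simulate(strong_params, horizon=20.0, seed=5)
        assert traj.times[0] > 0
        assert np.all(np.diff(traj.times) > 0)

    def test_near_pure_birth_poisson_mean(self):
        # with negligible detachment the length at T is ~ Poisson(k+ T)
        p = RateParameters(kplus=(5.0,), kminus=(1e-9,))
        finals = [simulate(p, horizon=100.0, seed=s).levels()[-1] for s in range(50)]
        se = np.sqrt(500.0 / 50)
        assert abs(np.mean(finals) - 500.0) <= 3 * se

    def test_event_count_poisson_bound(self, strong_params):
        # total events stochastically bounded by Poisson((sum k+ + max k-) T)
        rate = strong_params.total_attach + max(strong_params.kminus)
        T = 200.0
        n = simulate(strong_params, horizon=T, seed=9).n_events
        assert n <= rate * T + 6 * np.sqrt(rate * T)

    def test_replay_never_negative(self, near_critical_params):
        for seed in range(5):
            levels = simulate(near_critical_params, horizon=200.0, seed=seed).levels()
            assert levels.min() >= 0

    def test_initial_state_respected(self, strong_params):
        init = PolymerState(2, [0, 1])
        traj = simulate(strong_params, horizon=1.0, seed=3, initial_state=init)
        assert traj.levels()[0] == 2
        assert traj.initial_sequence == (0, 1)


class TestEmbedded:
    def test_zero_steps_root_only(self, strong_params):
        path = simulate_embedded(strong_params, n_steps=0, seed=1)
        assert path.levels().tolist() == [0]
        assert path.tips().tolist() == [-1]

    def test_d1_up_move_frequency(self, birth_death_params):
        path = simulate_embedded(birth_death_params, n_steps=20_000, seed=2)
        ups = np.mean(path.moves >= 0)
        p_up = 3.0 / 4.0  # k+/(k+ + k-) away from the root, slightly more at root
        se = np.sqrt(p_up * (1 - p_up) / 20_000)
        assert abs(ups - p_up) <= 3 * se + 1e-3

    def test_speed_recovers_dtmc_speed(self, strong_params):
        n = 50_000
        path = simulate_embedded(strong_params, n_steps=n, seed=4)
        vbar = dtmc_speed(strong_params)
        se = np.sqrt((1 - vbar**2) / n)
        assert abs(path.levels()[-1] / n - vbar) <= 3 * se


class TestObservables:
    def test_root_convention_at_time_zero(self):
        traj = hand_trajectory()
        obs = observables(traj, [0.0])
        assert obs.length[0] == 0
        np.testing.assert_array_equal(obs.sigma[0], [0.0, 0.0])
        assert obs.tip[0] == -1

    def test_hand_replay(self):
        traj = hand_trajectory()
        obs = observables(traj, [0.4, 1.5, 2.5])
        assert obs.length.tolist() == [0, 2, 1]
        np.testing.assert_array_equal(obs.counts[1], [1, 1])
        np.testing.assert_allclose(obs.sigma[1], [0.5, 0.5])
        np.testing.assert_array_equal(obs.counts[2], [1, 0])
        assert obs.tip.tolist() == [-1, 1, 0]

    def test_counts_sum_to_length(self, near_critical_params):
        traj = simulate(near_critical_params, horizon=300.0, seed=6)
        obs = observables(traj, np.linspace(0, 300, 61))
        np.testing.assert_array_equal(obs.counts.sum(axis=1), obs.length)
        rows = obs.length > 0
        np.testing.assert_allclose(obs.sigma[rows].sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_array_equal(obs.sigma[~rows], 0.0)

    def test_sample_time_bounds(self):
        traj = hand_trajectory()
        with pytest.raises(ValueError):
            observables(traj, [5.0])
        with pytest.raises(ValueError):
            observables(traj, [1.0, 0.5])


class TestVelocityAndExports:
    def test_empty_trajectory_zero_velocity(self, strong_params):
        traj = Trajectory(params=strong_params, seed=0, horizon=1.0,
                          times=np.array([]), moves=np.array([], dtype=np.int64))
        assert empirical_velocity(traj) == 0.0

    def test_zero_horizon_error(self, strong_params):
        traj = simulate(strong_params, horizon=0.0, seed=1)
        with pytest.raises(ValueError):
            empirical_velocity(traj)

    def test_trajectory_csv_round_trip(self, strong_params, tmp_path):
        traj = simulate(strong_params, horizon=5.0, seed=7)
        out = tmp_path / "traj.csv"
        traj.to_csv(out)
        text = out.read_text()
        assert text.startswith("# copolymer")
        assert "seed=7" in text
        df = pd.read_csv(out, comment="#")
        assert len(df) == traj.n_events
        assert df["length_after"].tolist() == traj.levels()[1:].tolist()

    def test_fasta_export(self, strong_params, tmp_path):
        trajs = [simulate(strong_params, horizon=5.0, seed=s) for s in (1, 2)]
        out = tmp_path / "final.fasta"
        final_sequences_to_fasta(trajs, out)
        lines = out.read_text().splitlines()
        assert lines[0].startswith(">replicate_0")
        assert sum(l.startswith(">") for l in lines) == 2

    def test_fasta_refused_above_26_types(self, tmp_path):
        p = RateParameters(kplus=(1.0,) * 27, kminus=(0.5,) * 27)
        traj = simulate(p, horizon=0.5, seed=1)
        with pytest.raises(ValueError, match="26"):
            final_sequences_to_fasta([traj], tmp_path / "x.fasta")
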