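"""Exact stochastic simulation of the copolymerization chain.

The continuous-time chain is simulated with the exact SSA: at each state
draw an Exp(1) variate scaled by the state's exit rate for the holding
time, then a single uniform to pick the move from the embedded-chain step
distribution.  Every event consumes exactly these two variates, in that
order, from one ``numpy.random.default_rng(seed)`` stream per trajectory,
so identical (params, seed, horizon, initial state) always give identical
event lists — bitwise reproducibility is part of the contract.

Trajectories store the event list only (time, move); states are
reconstructed by replaying the stack of attachments and detachments,
which keeps memory proportional to the number of events and comfortably
supports horizons of order 10^5–10^6 events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import DETACH, exit_rate
from .params import RateParameters
from .state import ROOT, PolymerState

__all__ = [
    "Trajectory",
    "EmbeddedPath",
    "ObservableSeries",
    "simulate",
    "simulate_embedded",
    "observables",
    "empirical_velocity",
    "final_sequences_to_fasta",
]


def _replay(initial_sequence: tuple[int, ...], moves: np.ndarray, d: int):
    """Replay an event list; return (levels, tips) arrays of length n+1.

    Position 0 is the initial state; position n the state after the n-th
    event.  Tips use -1 for the root.
    """
    n = len(moves)
    levels = np.empty(n + 1, dtype=np.int64)
    tips = np.empty(n + 1, dtype=np.int64)
    stack = list(initial_sequence)
    levels[0] = len(stack)
    tips[0] = stack[-1] if stack else -1
    for idx in range(n):
        mv = moves[idx]
        if mv == DETACH:
            if not stack:
                raise ValueError(f"event {idx}: detach at the root during replay")
            stack.pop()
        else:
            stack.append(int(mv))
        levels[idx + 1] = len(stack)
        tips[idx + 1] = stack[-1] if stack else -1
    return levels, tips


@dataclass(frozen=True, eq=False)
class Trajectory:
    """A seeded realized CTMC path, stored as an event list.

    ``times[k]`` is the (strictly increasing, positive) time of event k
    and ``moves[k]`` its move: a 0-based monomer index for an attachment,
    :data:`~copolymer.core.DETACH` (-1) for a detachment.
    """

    params: RateParameters
    seed: int
    horizon: float
    times: np.ndarray
    moves: np.ndarray
    initial_sequence: tuple[int, ...] = ()

    @property
    def n_events(self) -> int:
        return len(self.moves)

    def levels(self) -> np.ndarray:
        """Polymer length at positions 0..n (position 0 = initial state)."""
        return self._levels_tips()[0]

    def tips(self) -> np.ndarray:
        """Tip monomer index at positions 0..n (-1 for the root)."""
        return self._levels_tips()[1]

    def _levels_tips(self):
        cached = getattr(self, "_cache", None)
        if cached is None:
            cached = _replay(self.initial_sequence, self.moves, self.params.d)
            object.__setattr__(self, "_cache", cached)
        return cached

    def final_state(self) -> PolymerState:
        state = PolymerState(self.params.d, self.initial_sequence)
        for mv in self.moves:
            if mv == DETACH:
                state.detach()
            else:
                state.attach(int(mv))
        return state

    def to_csv(self, path: str | Path) -> None:
        """Event list as CSV: event_index, time, move, length_after, tip_after.

        A header comment records the parameters and seed so every output
        file is self-describing.
        """
        levels, tips = self._levels_tips()
        labels = self.params.labels
        move_lab = ["-" if mv == DETACH else labels[mv] for mv in self.moves]
        df = pd.DataFrame({
            "event_index": np.arange(1, self.n_events + 1),
            "time": self.times,
            "move": move_lab,
            "length_after": levels[1:],
            "tip_after": ["-" if t < 0 else labels[t] for t in tips[1:]],
        })
        _write_csv_with_metadata(df, path, self.params, seed=self.seed, horizon=self.horizon)


@dataclass(frozen=True, eq=False)
class EmbeddedPath:
    """A seeded path of the embedded jump chain (jump index, no clock)."""

    params: RateParameters
    seed: int
    n_steps: int
    moves: np.ndarray
    initial_sequence: tuple[int, ...] = ()

    def levels(self) -> np.ndarray:
        return self._levels_tips()[0]

    def tips(self) -> np.ndarray:
        return self._levels_tips()[1]

    def _levels_tips(self):
        cached = getattr(self, "_cache", None)
        if cached is None:
            cached = _replay(self.initial_sequence, self.moves, self.params.d)
            object.__setattr__(self, "_cache", cached)
        return cached


def simulate(
    params: RateParameters,
    horizon: float,
    seed: int,
    initial_state: Optional[PolymerState] = None,
) -> Trajectory:
    """Exact SSA simulation of the CTMC up to a time horizon.

    Stops at the first holding time that would cross the horizon (that
    event is not recorded).  ``horizon = 0`` yields an empty event list.
    """
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    d = params.d
    kplus = params.kplus_array()
    S = params.total_attach
    kminus = params.kminus_array()
    # cumulative move thresholds per tip: attach 0..d-1 then detach
    cum_attach = np.cumsum(kplus)
    rng = np.random.default_rng(seed)
    stack = list(initial_state.sequence) if initial_state is not None else []
    if initial_state is not None and initial_state.d != d:
        raise ValueError("initial_state dimension does not match params")
    times: list[float] = []
    moves: list[int] = []
    t = 0.0
    while True:
        tip = stack[-1] if stack else -1
        q = S if tip < 0 else S + kminus[tip]
        # exactly two variates per event, fixed order: holding time, move
        hold = rng.exponential() / q
        u = rng.random() * q
        if t + hold > horizon:
            break
        t += hold
        if u < S:
            i = int(np.searchsorted(cum_attach, u, side="right"))
            stack.append(i)
            moves.append(i)
        else:
            stack.pop()
            moves.append(DETACH)
        times.append(t)
    return Trajectory(
        params=params, seed=int(seed), horizon=float(horizon),
        times=np.asarray(times, dtype=float),
        moves=np.asarray(moves, dtype=np.int64),
        initial_sequence=initial_state.sequence if initial_state is not None else (),
    )


def simulate_embedded(
    params: RateParameters,
    n_steps: int,
    seed: int,
    initial_state: Optional[PolymerState] = None,
) -> EmbeddedPath:
    """Simulate n_steps moves of the embedded jump chain from the root.

    One uniform variate per step selects the move from the one-step
    distribution at the current tip.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    kplus = params.kplus_array()
    kminus = params.kminus_array()
    S = params.total_attach
    cum_attach = np.cumsum(kplus)
    rng = np.random.default_rng(seed)
    stack = list(initial_state.sequence) if initial_state is not None else []
    moves = np.empty(n_steps, dtype=np.int64)
    us = rng.random(n_steps)
    for k in range(n_steps):
        tip = stack[-1] if stack else -1
        q = S if tip < 0 else S + kminus[tip]
        u = us[k] * q
        if u < S:
            i = int(np.searchsorted(cum_attach, u, side="right"))
            stack.append(i)
            moves[k] = i
        else:
            stack.pop()
            moves[k] = DETACH
    return EmbeddedPath(
        params=params, seed=int(seed), n_steps=int(n_steps), moves=moves,
        initial_sequence=initial_state.sequence if initial_state is not None else (),
    )


@dataclass(frozen=True, eq=False)
class ObservableSeries:
    """Time-sampled observables of a trajectory.

    ``sigma[k, i]`` is the fraction of type-i monomers in the chain at
    sample time k (all zeros at the root, by convention); ``counts`` are
    the per-type monomer counts and always row-sum to ``length``.
    """

    params: RateParameters
    times: np.ndarray
    length: np.ndarray
    counts: np.ndarray
    sigma: np.ndarray
    tip: np.ndarray  # -1 for root

    def to_csv(self, path: str | Path, seed: Optional[int] = None) -> None:
        labels = self.params.labels
        data = {"time": self.times, "length": self.length}
        for i, lab in enumerate(labels):
            data[f"count_{lab}"] = self.counts[:, i]
        for i, lab in enumerate(labels):
            data[f"sigma_{lab}"] = self.sigma[:, i]
        data["tip"] = ["-" if t < 0 else labels[t] for t in self.tip]
        _write_csv_with_metadata(pd.DataFrame(data), path, self.params, seed=seed)


def observables(trajectory: Trajectory, sample_times: Sequence[float]) -> ObservableSeries:
    """Sample length, per-type counts, composition and tip on a time grid.

    The state at time t is the state after the last event at or before t
    (left-continuous step interpolation).  Sample times must be
    nondecreasing and lie in [0, horizon].
    """
    ts = np.asarray(sample_times, dtype=float)
    if ts.size and (np.any(np.diff(ts) < 0)):
        raise ValueError("sample_times must be nondecreasing")
    if ts.size and (ts[0] < 0 or ts[-1] > trajectory.horizon):
        raise ValueError("sample_times must lie within [0, horizon]")
    d = trajectory.params.d
    # position index of the state occupied at each sample time
    pos = np.searchsorted(trajectory.times, ts, side="right")
    levels, tips = trajectory._levels_tips()
    # cumulative per-type counts along the path
    n = trajectory.n_events
    delta = np.zeros((n + 1, d), dtype=np.int64)
    init = PolymerState(d, trajectory.initial_sequence)
    delta[0] = init.counts
    if n:
        attach_mask = trajectory.moves >= 0
        rows = np.arange(1, n + 1)
        # +1 for the attached type; -1 for the detached tip (= tip before event)
        delta[rows[attach_mask], trajectory.moves[attach_mask]] += 1
        det_rows = rows[~attach_mask]
        delta[det_rows, tips[det_rows - 1]] -= 1
    cum_counts = np.cumsum(delta, axis=0)
    counts = cum_counts[pos]
    length = levels[pos]
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma = np.where(length[:, None] > 0, counts / np.maximum(length, 1)[:, None], 0.0)
    return ObservableSeries(
        params=trajectory.params, times=ts, length=length,
        counts=counts, sigma=sigma, tip=tips[pos],
    )


def empirical_velocity(trajectory: Trajectory) -> float:
    """Final polymer length divided by the horizon (monomers per unit time)."""
    if trajectory.horizon <= 0:
        raise ValueError("empirical velocity requires a positive horizon")
    return float(trajectory.levels()[-1]) / trajectory.horizon


def final_sequences_to_fasta(trajectories: Sequence[Trajectory], path: str | Path) -> None:
    """Export final polymer sequences as FASTA, one record per trajectory.

    Monomer i maps to the i-th uppercase letter; refused for d > 26.
    """
    trajectories = list(trajectories)
    if not trajectories:
        raise ValueError("no trajectories to export")
    d = trajectories[0].params.d
    if d > 26:
        raise ValueError("FASTA export supports at most 26 monomer types")
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    lines = []
    for k, traj in enumerate(trajectories):
        seq = traj.final_state().sequence
        lines.append(f">replicate_{k} seed={traj.seed} horizon={traj.horizon} length={len(seq)}")
        text = "".join(alphabet[i] for i in seq) or ""
        for start in range(0, max(len(text), 1), 70):
            lines.append(text[start:start + 70])
    Path(path).write_text("\n".join(lines) + "\n")


def _write_csv_with_metadata(df: pd.DataFrame, path: str | Path,
                             params: RateParameters, **meta) -> None:
    """CSV with '#'-prefixed header comments recording params and run metadata."""
    from . import __version__

    header = [f"# copolymer {__version__}"]
    header.append(f"# labels={','.join(params.labels)}")
    header.append(f"# kplus={','.join(repr(v) for v in params.kplus)}")
    header.append(f"# kminus={','.join(repr(v) for v in params.kminus)}")
    for key, value in meta.items():
        if value is not None:
            header.append(f"# {key}={value}")
    with open(path, "w", newline="") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, index=False)
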