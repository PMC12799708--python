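"""Boundary (last-exit) process extraction from finite realized paths.

In the transient regime the chain visits each level only finitely often;
the state at the *last* visit to level k, W_k, is the length-k prefix of
the limiting infinite polymer, and its cone type U_k (the type of its
terminal monomer) forms an ergodic Markov chain whose stationary law is
the limiting composition sigma_bar.

Last-exit times are not stopping times, so a finite path can only
approximate the true boundary: a level visited late in the window might
still be revisited after the horizon.  We therefore hold back a
``safety_margin`` of levels below the maximum attained level; each
crossing of a level is undone with probability at most ``max_i F_i``, so
the probability that the returned range disagrees with the true boundary
decays geometrically in the margin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .params import RateParameters
from .simulate import EmbeddedPath, Trajectory, _write_csv_with_metadata

__all__ = [
    "BoundarySequence",
    "extract_boundary",
    "cone_frequencies",
    "cone_visit_counts",
]

logger = logging.getLogger(__name__)

PathLike = Union[Trajectory, EmbeddedPath]


@dataclass(frozen=True, eq=False)
class BoundarySequence:
    """Extracted last-exit records (one per level 0..valid_up_to).

    ``e_index[k]`` is the jump index of the last visit to level k within
    the window; ``tips[k]`` the terminal monomer of W_k (-1 for the root
    at k = 0); ``e_times`` the corresponding clock times when the source
    was a continuous-time trajectory.  ``e_index`` is strictly increasing
    and consecutive W_k satisfy the prefix property.
    """

    params: RateParameters
    levels: np.ndarray
    e_index: np.ndarray
    tips: np.ndarray
    safety_margin: int
    e_times: Optional[np.ndarray] = None

    @property
    def valid_up_to(self) -> int:
        """Largest level for which the finite-window extraction is trusted."""
        return int(self.levels[-1]) if len(self.levels) else -1

    @property
    def n_records(self) -> int:
        return len(self.levels)

    def to_csv(self, path: str | Path, seed: Optional[int] = None) -> None:
        labels = self.params.labels
        data = {
            "level": self.levels,
            "e_index": self.e_index,
        }
        if self.e_times is not None:
            data["e_time"] = self.e_times
        data["tip_label"] = ["-" if t < 0 else labels[t] for t in self.tips]
        _write_csv_with_metadata(pd.DataFrame(data), path, self.params,
                                 seed=seed, safety_margin=self.safety_margin)


def extract_boundary(path: PathLike, safety_margin: int = 10) -> BoundarySequence:
    """Extract the within-window last-exit process from a realized path.

    For each level k from 0 to (max attained level - safety_margin),
    records the last position index at which the path occupies level k.
    Positions are 0-based jump indices (0 = initial state).  Returns an
    empty result with a warning when the path never climbs past the
    margin.
    """
    if safety_margin < 0:
        raise ValueError("safety_margin must be >= 0")
    levels = path.levels()
    tips = path.tips()
    max_level = int(levels.max())
    top = max_level - safety_margin
    e_times = path.times if isinstance(path, Trajectory) else None
    if top < 0:
        logger.warning(
            "max attained level %d <= safety margin %d: no boundary levels returned",
            max_level, safety_margin,
        )
        empty = np.empty(0, dtype=np.int64)
        return BoundarySequence(params=path.params, levels=empty, e_index=empty,
                                tips=empty, safety_margin=safety_margin,
                                e_times=None if e_times is None else np.empty(0))
    # single back-to-front sweep: first occurrence in reversed order = last exit
    n = len(levels)
    e_index = np.full(top + 1, -1, dtype=np.int64)
    remaining = top + 1
    for pos in range(n - 1, -1, -1):
        lv = levels[pos]
        if lv <= top and e_index[lv] < 0:
            e_index[lv] = pos
            remaining -= 1
            if remaining == 0:
                break
    ks = np.arange(top + 1, dtype=np.int64)
    rec_tips = tips[e_index]
    rec_times = None
    if e_times is not None:
        # position 0 is the initial state at time 0; event j is at times[j-1]
        rec_times = np.where(e_index > 0, e_times[np.maximum(e_index - 1, 0)], 0.0)
    return BoundarySequence(params=path.params, levels=ks, e_index=e_index,
                            tips=rec_tips, safety_margin=safety_margin,
                            e_times=rec_times)


def cone_frequencies(boundary: BoundarySequence) -> np.ndarray:
    """Empirical distribution of the cone types U_k over the valid range.

    The k = 0 record (the root, which has no cone type) is excluded.  In
    the transient regime this converges to sigma_bar by the ergodic
    theorem for the boundary cone-type chain.
    """
    mask = boundary.tips >= 0
    if not np.any(mask):
        raise ValueError("boundary sequence has no records with a cone type")
    counts = np.bincount(boundary.tips[mask], minlength=boundary.params.d)
    return counts / counts.sum()


def cone_visit_counts(path: PathLike):
    """Cumulative cone-type visit counts chi_i(n) along an embedded path.

    Returns ``(chi, chi_root)`` where ``chi[n, i]`` counts the visits to
    states with tip i among Z_0..Z_n and ``chi_root[n]`` the root visits
    (Z_0 = root is included).  At every n the counts partition the n+1
    states visited: ``chi[n].sum() + chi_root[n] == n + 1``.
    """
    tips = path.tips()
    d = path.params.d
    n = len(tips)
    onehot = np.zeros((n, d + 1), dtype=np.int64)
    onehot[np.arange(n), np.where(tips < 0, d, tips)] = 1
    cum = np.cumsum(onehot, axis=0)
    return cum[:, :d], cum[:, d]
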