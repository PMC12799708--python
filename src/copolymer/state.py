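"""Polymer states: finite ordered monomer sequences (vertices of the tree).

The state space is the set of all finite sequences over the ``d`` monomer
types, including the empty polymer (the *root*).  All transitions act on
the tip, so the sequence is stored as a stack with append/pop at the tail.

The root is represented by the module-level sentinel :data:`ROOT` (a
distinct object, deliberately not an integer, so it can never be confused
with monomer type 0).  Arrays of tips produced by the simulator use the
integer ``-1`` for the root; scalar APIs use :data:`ROOT`.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["ROOT", "PolymerState"]


class _Root:
    """Sentinel marking the empty polymer / absence of a tip."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "ROOT"


ROOT = _Root()


class PolymerState:
    """A finite ordered monomer sequence, mutable at the tip.

    Monomer indices are 0-based (``0..d-1``).  ``PolymerState(d)`` is the
    root; ``PolymerState(d, [0, 1, 0])`` is the polymer M1 M2 M1.
    """

    __slots__ = ("d", "_seq")

    def __init__(self, d: int, sequence: Iterable[int] = ()) -> None:
        if d < 1:
            raise ValueError("d must be >= 1")
        self.d = int(d)
        self._seq: list[int] = []
        for i in sequence:
            self.attach(int(i))

    # -- structure ----------------------------------------------------------

    @property
    def sequence(self) -> tuple[int, ...]:
        return tuple(self._seq)

    @property
    def length(self) -> int:
        return len(self._seq)

    def __len__(self) -> int:
        return len(self._seq)

    @property
    def is_root(self) -> bool:
        return not self._seq

    @property
    def tip(self):
        """Terminal monomer index, or :data:`ROOT` for the empty polymer."""
        return self._seq[-1] if self._seq else ROOT

    @property
    def counts(self) -> np.ndarray:
        """Per-type occurrence counts ``beta_i(x)`` (length-``d`` vector)."""
        return np.bincount(self._seq, minlength=self.d).astype(np.int64)

    def predecessor(self) -> "PolymerState":
        """The unique neighbor closer to the root (drop the tip)."""
        if not self._seq:
            raise ValueError("the root has no predecessor")
        return PolymerState(self.d, self._seq[:-1])

    # -- tip mutations (used by the simulator) -------------------------------

    def attach(self, i: int) -> None:
        if not 0 <= i < self.d:
            raise ValueError(f"monomer index {i} out of range 0..{self.d - 1}")
        self._seq.append(i)

    def detach(self) -> int:
        if not self._seq:
            raise ValueError("cannot detach from the root")
        return self._seq.pop()

    def copy(self) -> "PolymerState":
        return PolymerState(self.d, self._seq)

    # -- niceties ------------------------------------------------------------

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PolymerState)
            and self.d == other.d
            and self._seq == other._seq
        )

    def __hash__(self) -> int:
        return hash((self.d, tuple(self._seq)))

    def label(self, labels: Sequence[str]) -> str:
        """Human-readable sequence, e.g. ``'M1M2M1'`` (``'o'`` for the root)."""
        if not self._seq:
            return "o"
        return "".join(labels[i] for i in self._seq)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PolymerState(d={self.d}, sequence={self._seq})"
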