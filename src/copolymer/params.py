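"""Model parameterization: per-type attachment and detachment rates.

The copolymerization chain is fully specified by the number of monomer
types ``d`` and two strictly positive rate vectors: ``kplus[i]`` is the
rate (events per unit time) at which a monomer of type ``i`` attaches to
the tip of any polymer, and ``kminus[i]`` is the rate at which a terminal
monomer of type ``i`` detaches.  Rates depend on the monomer type only,
never on the rest of the chain.

Indexing convention (used throughout the package): monomer types are
0-based integers ``0..d-1`` in code; human-facing labels default to
``"M1".."Md"``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = ["RateParameters"]


@dataclass(frozen=True)
class RateParameters:
    """Full parameter set ``{k_i^+, k_i^-}`` for ``d`` monomer types.

    Parameters
    ----------
    kplus, kminus
        Length-``d`` sequences of strictly positive, finite rates.
    labels
        Optional monomer names; defaults to ``M1..Md``.  Must be unique.
    """

    kplus: tuple[float, ...]
    kminus: tuple[float, ...]
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        kplus = tuple(float(v) for v in self.kplus)
        kminus = tuple(float(v) for v in self.kminus)
        if len(kplus) < 1:
            raise ValueError("need at least one monomer type (d >= 1)")
        if len(kplus) != len(kminus):
            raise ValueError(
                f"kplus and kminus must have equal length, got "
                f"{len(kplus)} and {len(kminus)}"
            )
        for name, vec in (("kplus", kplus), ("kminus", kminus)):
            for v in vec:
                if not (math.isfinite(v) and v > 0):
                    raise ValueError(f"{name} entries must be strictly positive and finite, got {v}")
        labels = tuple(self.labels) or tuple(f"M{i + 1}" for i in range(len(kplus)))
        if len(labels) != len(kplus):
            raise ValueError("labels must have one entry per monomer type")
        if len(set(labels)) != len(labels):
            raise ValueError("labels must be unique")
        object.__setattr__(self, "kplus", kplus)
        object.__setattr__(self, "kminus", kminus)
        object.__setattr__(self, "labels", labels)

    # -- derived quantities -------------------------------------------------

    @property
    def d(self) -> int:
        """Number of monomer types."""
        return len(self.kplus)

    @property
    def total_attach(self) -> float:
        """Total attachment rate ``sum_r k_r^+`` (exit rate at the root)."""
        return float(np.sum(self.kplus))

    @property
    def alpha(self) -> float:
        """Transience index ``alpha = sum_i k_i^+ / k_i^-``."""
        return float(np.sum(np.asarray(self.kplus) / np.asarray(self.kminus)))

    def kplus_array(self) -> np.ndarray:
        return np.asarray(self.kplus, dtype=float)

    def kminus_array(self) -> np.ndarray:
        return np.asarray(self.kminus, dtype=float)

    def index_of(self, label: str) -> int:
        return self.labels.index(label)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "kplus": list(self.kplus),
            "kminus": list(self.kminus),
        }

    @classmethod
    def from_mapping(cls, data: Mapping) -> "RateParameters":
        """Build from a config mapping with keys kplus, kminus, optional labels."""
        missing = [k for k in ("kplus", "kminus") if k not in data]
        if missing:
            raise ValueError(f"config missing required keys: {missing}")
        labels: Iterable[str] = data.get("labels") or ()
        return cls(kplus=tuple(data["kplus"]), kminus=tuple(data["kminus"]),
                   labels=tuple(labels))

    @classmethod
    def from_file(cls, path: str | Path) -> "RateParameters":
        """Load from a YAML or JSON config file (keys: kplus, kminus, labels)."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if not isinstance(data, Mapping):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_mapping(data)
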