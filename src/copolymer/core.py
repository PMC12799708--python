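"""Transition structure, regime classification, and stationary measure.

The chain lives on the infinite ``d``-ary tree of finite monomer
sequences.  From any state, each monomer type ``i`` attaches at rate
``k_i^+``; from a non-root state ending in type ``j``, the tip detaches
at rate ``k_j^-``.  Exit rates are uniformly bounded, so the chain is
non-explosive.

Everything here is elementary but load-bearing: the transience index
``alpha = sum_i k_i^+/k_i^-`` (the spectral radius of the rank-one
cone-type matrix A) splits the parameter space into positive-recurrent
(alpha < 1), null-recurrent (alpha = 1) and transient (alpha > 1)
regimes, and for alpha < 1 the product-form measure
``mu(x) = mu(o) * prod_i (k_i^+/k_i^-)^{beta_i(x)}`` is stationary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Union

import numpy as np

from .params import RateParameters
from .state import ROOT, PolymerState

__all__ = [
    "DETACH",
    "Regime",
    "RegimeClassification",
    "NotNormalizableError",
    "classify",
    "exit_rate",
    "dtmc_step_distribution",
    "stationary_weight",
    "stationary_normalizer",
    "cone_matrix",
]

logger = logging.getLogger(__name__)

#: Move key for "detach the tip" in step distributions (attach moves are
#: keyed by the 0-based monomer index).
DETACH = -1

Regime = str  # one of "positive_recurrent" | "null_recurrent" | "transient"

POSITIVE_RECURRENT: Regime = "positive_recurrent"
NULL_RECURRENT: Regime = "null_recurrent"
TRANSIENT: Regime = "transient"


class NotNormalizableError(ValueError):
    """The product-form measure has no finite total mass (alpha >= 1)."""


@dataclass(frozen=True)
class RegimeClassification:
    """Trichotomy of the chain by the transience index alpha."""

    alpha: float
    regime: Regime
    boundary_tolerance: float

    @property
    def is_transient(self) -> bool:
        return self.regime == TRANSIENT


def classify(params: RateParameters, boundary_tolerance: float = 1e-9) -> RegimeClassification:
    """Classify the chain as positive recurrent, null recurrent, or transient.

    alpha < 1 gives positive recurrence, alpha > 1 transience, alpha = 1
    null recurrence.  Floating-point rate inputs make exact criticality
    undecidable, so equality is declared within ``boundary_tolerance`` of 1
    (and logged, since the classification is then a judgement call).
    """
    if boundary_tolerance <= 0:
        raise ValueError("boundary_tolerance must be positive")
    alpha = params.alpha
    if alpha > 1 + boundary_tolerance:
        regime = TRANSIENT
    elif alpha < 1 - boundary_tolerance:
        regime = POSITIVE_RECURRENT
    else:
        regime = NULL_RECURRENT
        logger.warning(
            "alpha = %.17g lies within %.3g of the critical value 1; "
            "classifying as null recurrent", alpha, boundary_tolerance,
        )
    return RegimeClassification(alpha=alpha, regime=regime,
                                boundary_tolerance=boundary_tolerance)


TipLike = Union[int, type(ROOT), object]


def _check_tip(params: RateParameters, tip) -> int:
    """Normalize a tip argument to -1 (root) or a 0-based monomer index."""
    if tip is ROOT or (isinstance(tip, (int, np.integer)) and tip == -1):
        return -1
    if isinstance(tip, (int, np.integer)) and 0 <= tip < params.d:
        return int(tip)
    raise ValueError(f"invalid tip {tip!r}: expected ROOT/-1 or an index in 0..{params.d - 1}")


def exit_rate(params: RateParameters, tip) -> float:
    """Total exit rate q(x) out of a state with the given tip.

    Root: ``sum_r k_r^+``.  Tip ``j``: ``k_j^- + sum_r k_r^+``.  Uniformly
    bounded by ``sum k^+ + max k^-``, hence the chain never explodes.
    """
    j = _check_tip(params, tip)
    if j < 0:
        return params.total_attach
    return params.kminus[j] + params.total_attach


def dtmc_step_distribution(params: RateParameters, tip) -> Mapping[int, float]:
    """One-step move distribution of the embedded jump chain at a state.

    Returns a dict mapping each attach move (keyed by monomer index
    ``0..d-1``) and, away from the root, the detach move (keyed by
    :data:`DETACH`) to its probability.  Probabilities are the transition
    rates divided by the exit rate and sum to one.
    """
    j = _check_tip(params, tip)
    q = exit_rate(params, tip)
    dist = {i: params.kplus[i] / q for i in range(params.d)}
    if j >= 0:
        dist[DETACH] = params.kminus[j] / q
    return dist


def stationary_weight(params: RateParameters, state: PolymerState | np.ndarray) -> float:
    """Unnormalized stationary weight ``mu(x)/mu(o)`` of a state.

    Equals ``prod_i (k_i^+/k_i^-)^{beta_i(x)}`` where ``beta_i`` are the
    per-type monomer counts; the weight depends on the composition only,
    not the ordering.  Accepts a :class:`PolymerState` or a raw counts
    vector.
    """
    counts = state.counts if isinstance(state, PolymerState) else np.asarray(state)
    if counts.shape != (params.d,):
        raise ValueError(f"counts must have length d={params.d}")
    ratios = params.kplus_array() / params.kminus_array()
    return float(np.prod(ratios ** counts))


def stationary_normalizer(params: RateParameters, boundary_tolerance: float = 1e-9) -> float:
    """Root mass ``mu(o) = 1 - alpha`` of the normalized stationary law.

    Defined only in the positive-recurrent regime: the total mass of the
    product-form measure is the geometric series ``sum_l alpha^l``, which
    converges iff alpha < 1.  Raises :class:`NotNormalizableError`
    otherwise.
    """
    alpha = params.alpha
    if alpha >= 1 - boundary_tolerance:
        raise NotNormalizableError(
            f"stationary measure is not normalizable: alpha = {alpha:.6g} >= 1"
        )
    return 1.0 - alpha


def cone_matrix(params: RateParameters) -> np.ndarray:
    """Cone-type matrix ``A[i, j] = k_j^+ / k_i^-`` (d x d).

    A is the rank-one outer product ``u v^T`` with ``u = 1/kminus`` and
    ``v = kplus``; its single nonzero eigenvalue is the transience index
    alpha, which is why the spectral-radius criterion reduces to comparing
    alpha with 1.
    """
    return np.outer(1.0 / params.kminus_array(), params.kplus_array())
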