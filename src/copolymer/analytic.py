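"""Closed-form / numeric limit theory for the transient regime.

In the transient regime (alpha > 1) the polymer grows without bound and
the following quantities are well defined:

* the escape rate ``m`` — the unique positive root of
  ``g(m) = sum_r k_r^+ / (m + k_r^-) = 1``;
* the first-return probabilities ``F_i = k_i^- / (m + k_i^-)`` — the
  probability that a chain at a polymer ending in type ``i`` ever revisits
  its one-shorter predecessor;
* the limiting composition ``sigma_bar_i = k_i^+ / (m + k_i^-)``, the
  almost-sure limit of the fraction of type-``i`` monomers in the chain;
* the boundary (last-exit) cone-type transition matrix ``V``;
* the growth velocity ``v = sum_r k_r^+ - sum_r k_r^- sigma_bar_r``
  (monomers per unit time), the almost-sure limit of |X(t)|/t;
* the discrete speed ``v_bar`` (levels per jump) of the embedded chain;
* the limiting cone-visit fractions and Green-function ratios ``R_ij``.

Two identities shipped here are *derived* (they follow algebraically from
the formulas above but are convenient cross-checks rather than primary
definitions): ``v = m``, and "every row of V equals sigma_bar".
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .core import RegimeClassification, classify
from .params import RateParameters

__all__ = [
    "RegimeError",
    "AnalyticSummary",
    "solve_escape_rate",
    "first_return_probs",
    "limiting_composition",
    "boundary_transition_matrix",
    "growth_velocity",
    "dtmc_speed",
    "cone_visit_fractions",
    "green_ratio_matrix",
    "d2_closed_form",
    "analytic_summary",
]


class RegimeError(RuntimeError):
    """A transient-only quantity was requested outside the transient regime."""


def _require_transient(params: RateParameters) -> None:
    alpha = params.alpha
    if alpha <= 1:
        raise RegimeError(
            f"quantity defined only in the transient regime (alpha > 1); got alpha = {alpha:.6g}"
        )


def escape_rate_equation(params: RateParameters, m: float) -> float:
    """g(m) = sum_r k_r^+ / (m + k_r^-); strictly decreasing, g(0) = alpha."""
    return float(np.sum(params.kplus_array() / (m + params.kminus_array())))


def solve_escape_rate(params: RateParameters, tol: float = 1e-12) -> float:
    """Escape rate m: the unique positive root of g(m) = 1 (alpha > 1 only).

    g is strictly decreasing with g(0) = alpha > 1 and
    g(sum k^+) < sum k^+ / sum k^+ = 1, so (0, sum k^+] always brackets the
    root; Brent's method then converges unconditionally.  ``tol`` is a
    relative tolerance on m.
    """
    _require_transient(params)
    hi = params.total_attach
    lo = 1e-300 * hi  # open at zero; g(lo) ~ alpha > 1
    m = brentq(lambda x: escape_rate_equation(params, x) - 1.0, lo, hi,
               xtol=max(tol, 1e-16) * hi, rtol=max(tol, 4 * np.finfo(float).eps))
    # one Newton polish to machine precision; g is smooth and strictly
    # decreasing, so this is a contraction at the root
    kp, km = params.kplus_array(), params.kminus_array()
    for _ in range(2):
        g = float(np.sum(kp / (m + km)))
        gprime = -float(np.sum(kp / (m + km) ** 2))
        step = (g - 1.0) / gprime
        if m - step > 0:
            m -= step
    return float(m)


def first_return_probs(params: RateParameters, m: Optional[float] = None) -> np.ndarray:
    """First-return probabilities ``F_i = k_i^- / (m + k_i^-)``, each in (0,1)."""
    _require_transient(params)
    if m is None:
        m = solve_escape_rate(params)
    km = params.kminus_array()
    return km / (m + km)


def limiting_composition(params: RateParameters, m: Optional[float] = None) -> np.ndarray:
    """Almost-sure limiting monomer fractions ``sigma_bar_i = k_i^+/(m + k_i^-)``.

    These are also the stationary distribution of the boundary cone-type
    chain; the entries sum to one by the defining equation g(m) = 1.
    """
    _require_transient(params)
    if m is None:
        m = solve_escape_rate(params)
    return params.kplus_array() / (m + params.kminus_array())


def boundary_transition_matrix(params: RateParameters) -> np.ndarray:
    """Cone-type transition matrix of the boundary (last-exit) process.

    ``V[i, j] = F_i * ((1 - F_j)/(1 - F_i)) * k_j^+/k_i^-``.  Algebraically
    this reduces to ``F_j * k_j^+/k_j^- = sigma_bar_j`` independently of the
    row index, so V is strictly positive, row-stochastic, and every row
    equals sigma_bar; we evaluate the unreduced product so the reduction
    stays a testable identity rather than an assumption.
    """
    _require_transient(params)
    F = first_return_probs(params)
    kp, km = params.kplus_array(), params.kminus_array()
    V = F[:, None] * ((1.0 - F)[None, :] / (1.0 - F)[:, None]) * (kp[None, :] / km[:, None])
    return V


def growth_velocity(params: RateParameters) -> float:
    """Asymptotic growth velocity ``v = sum_r k_r^+ - sum_r k_r^- sigma_bar_r``.

    Monomers per unit time; |X(t)|/t -> v almost surely.  Substituting
    sigma_bar collapses the formula to the escape rate m — a derived
    identity checked by the validation suite, not used here.
    """
    _require_transient(params)
    sigma = limiting_composition(params)
    return float(params.total_attach - np.sum(params.kminus_array() * sigma))


def dtmc_speed(params: RateParameters) -> float:
    """Discrete speed ``v_bar`` of the embedded chain (levels per jump).

    ``v_bar = (sum_i sigma_bar_i * F_i / (p_i (1 - F_i)))^{-1}`` with
    ``p_i = k_i^-/(k_i^- + sum k^+)`` the one-step detach probability;
    |Z_n|/n -> v_bar almost surely, with 0 < v_bar < 1.
    """
    _require_transient(params)
    F = first_return_probs(params)
    sigma = limiting_composition(params)
    km, S = params.kminus_array(), params.total_attach
    p = km / (km + S)
    return float(1.0 / np.sum(sigma * F / (p * (1.0 - F))))


def _cone_visit_weights(params: RateParameters) -> np.ndarray:
    sigma = limiting_composition(params)
    return sigma * (params.kminus_array() + params.total_attach)


def cone_visit_fractions(params: RateParameters) -> np.ndarray:
    """Limiting fraction of embedded-chain steps spent at each cone type.

    chi_i(n)/n -> sigma_bar_i (k_i^- + sum k^+) / sum_j sigma_bar_j
    (k_j^- + sum k^+).  Differs from sigma_bar because the holding-time
    structure weights cone types by their exit rates.
    """
    w = _cone_visit_weights(params)
    return w / w.sum()


def green_ratio_matrix(params: RateParameters) -> np.ndarray:
    """Green-function ratios ``R[i, j] = G(o, xM_j)/G(o, xM_i)``.

    Independent of the common prefix x; equals the ratio of the cone-visit
    weights, so R[i, i] = 1 and R[i, j] R[j, i] = 1, and the cone-visit
    fractions are ``1 / sum_j R[i, j]``.
    """
    w = _cone_visit_weights(params)
    return w[None, :] / w[:, None]


def d2_closed_form(params: RateParameters) -> np.ndarray:
    """Two-monomer limiting composition in radicals (no root solve).

    For d = 2 the defining quadratic for m admits an explicit solution.
    With unequal detachment rates::

        sigma_bar_1 = (k1+ + k2+ + k1- - k2-
                       - sqrt((k1+ + k2+ + k1- - k2-)^2 + 4 k1+ k2- - 4 k1+ k1-))
                      / (2 (k1- - k2-))

    and symmetrically for sigma_bar_2.  With equal detachment rates the
    denominator vanishes and the composition degenerates to the pure
    attachment-rate ratios ``k_i^+ / (k1+ + k2+)``; the branch switch uses
    a relative threshold to avoid catastrophic cancellation near equality.
    """
    if params.d != 2:
        raise ValueError(f"d2_closed_form requires d = 2, got d = {params.d}")
    _require_transient(params)
    k1p, k2p = params.kplus
    k1m, k2m = params.kminus
    if abs(k1m - k2m) < 1e-12 * max(k1m, k2m):
        s = k1p + k2p
        return np.array([k1p / s, k2p / s])
    b1 = k1p + k2p + k1m - k2m
    s1 = (b1 - math.sqrt(b1 * b1 + 4 * k1p * k2m - 4 * k1p * k1m)) / (2 * (k1m - k2m))
    b2 = k1p + k2p + k2m - k1m
    s2 = (b2 - math.sqrt(b2 * b2 + 4 * k2p * k1m - 4 * k2p * k2m)) / (2 * (k2m - k1m))
    return np.array([s1, s2])


# ---------------------------------------------------------------------------
# aggregate summary


def _tolist(x):
    return None if x is None else np.asarray(x).tolist()


@dataclass(frozen=True, eq=False)
class AnalyticSummary:
    """All closed-form/numeric theory outputs for one parameter set.

    ``alpha`` and ``regime`` are always present.  The remaining fields are
    defined only in the transient regime and are ``None`` (explicitly
    absent, never NaN) otherwise; access them through :meth:`require` to
    fail fast with a :class:`RegimeError`.
    """

    params: RateParameters
    classification: RegimeClassification
    m: Optional[float] = None
    F: Optional[np.ndarray] = None
    sigma_bar: Optional[np.ndarray] = None
    V: Optional[np.ndarray] = None
    v: Optional[float] = None
    v_bar: Optional[float] = None
    chi_limit: Optional[np.ndarray] = None
    R: Optional[np.ndarray] = None

    @property
    def alpha(self) -> float:
        return self.classification.alpha

    @property
    def regime(self) -> str:
        return self.classification.regime

    def require(self, name: str):
        """Return a transient-only field, raising RegimeError if absent."""
        value = getattr(self, name)
        if value is None:
            raise RegimeError(
                f"{name} is only defined in the transient regime (regime = {self.regime})"
            )
        return value

    def to_dict(self) -> dict:
        return {
            "labels": list(self.params.labels),
            "kplus": list(self.params.kplus),
            "kminus": list(self.params.kminus),
            "alpha": self.alpha,
            "regime": self.regime,
            "m": self.m,
            "F": _tolist(self.F),
            "sigma_bar": _tolist(self.sigma_bar),
            "V": _tolist(self.V),
            "v": self.v,
            "v_bar": self.v_bar,
            "chi_limit": _tolist(self.chi_limit),
            "R": _tolist(self.R),
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_dict(cls, data: dict) -> "AnalyticSummary":
        params = RateParameters(kplus=tuple(data["kplus"]), kminus=tuple(data["kminus"]),
                                labels=tuple(data["labels"]))
        cl = classify(params)
        arr = lambda x: None if x is None else np.asarray(x, dtype=float)
        return cls(
            params=params, classification=cl, m=data.get("m"),
            F=arr(data.get("F")), sigma_bar=arr(data.get("sigma_bar")),
            V=arr(data.get("V")), v=data.get("v"), v_bar=data.get("v_bar"),
            chi_limit=arr(data.get("chi_limit")), R=arr(data.get("R")),
        )

    @classmethod
    def from_json(cls, source: str | Path) -> "AnalyticSummary":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))


def analytic_summary(params: RateParameters, tol: float = 1e-12) -> AnalyticSummary:
    """Compute every theory quantity available in the parameter regime."""
    cl = classify(params)
    if not cl.is_transient:
        return AnalyticSummary(params=params, classification=cl)
    m = solve_escape_rate(params, tol=tol)
    return AnalyticSummary(
        params=params,
        classification=cl,
        m=m,
        F=first_return_probs(params, m=m),
        sigma_bar=limiting_composition(params, m=m),
        V=boundary_transition_matrix(params),
        v=growth_velocity(params),
        v_bar=dtmc_speed(params),
        chi_limit=cone_visit_fractions(params),
        R=green_ratio_matrix(params),
    )
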