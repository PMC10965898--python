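"""ψ-function families for redescending M-estimation.

An M-estimator replaces the squared-error loss of ordinary least squares
with a loss ρ(r) whose derivative ψ = ρ′ caps (and, for *redescending*
families, eventually kills) the influence of large residuals.  Each family
here is a named triple of callables

    psi(r)     influence function, odd in r,
    weight(r)  ψ(r)/r with its finite limit at r = 0,
    rho(r)     the loss itself, where a closed form is available,

parameterised by a :class:`TuningSpec`.  The generalized family
(``"proposed"``) is

    ρ(r) = (k²/2a)·[1 − {1 + (r/k)²}^(−a)]
    ψ(r) = r·[1 + (r/k)²]^(−a−1)
    w(r) =   [1 + (r/k)²]^(−a−1)

with tuning constant ``k`` (residual units) and a second exponent ``a``
that controls how fast outlier weights decay: larger ``a`` means a harder
rejection of large residuals.  Its weight is strictly positive for every
finite residual, unlike the hard-rejection comparators (Tukey, Qadir, ...).

All callables accept scalars or arrays and are pure.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np

__all__ = [
    "TuningSpec",
    "PsiFamily",
    "get_family",
    "list_families",
    "default_tuning",
    "proposed_rho",
    "proposed_psi",
    "proposed_weight",
    "insha_psi",
]


class UnknownFamilyError(KeyError):
    """Requested ψ-family is not registered."""


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not (np.isfinite(value) and value > 0):
            raise ValueError(f"{name} must be a positive finite number, got {value!r}")


@dataclass(frozen=True)
class TuningSpec:
    """Tuning constants for one ψ-family.

    Parameters
    ----------
    family : str
        Registered family name (lowercase).
    k : float
        Primary tuning constant, in residual units. Must be > 0.
    a : float, optional
        Generalized exponent of the proposed family (> 0). Ignored elsewhere.
    l, m : float, optional
        Hampel's middle and outer corners; require 0 < k <= l < m.
    """

    family: str
    k: float
    a: Optional[float] = None
    l: Optional[float] = None
    m: Optional[float] = None

    def __post_init__(self) -> None:
        _check_positive(k=self.k)
        if self.family == "proposed":
            if self.a is None:
                raise ValueError("the proposed family requires the generalized constant a")
            _check_positive(a=self.a)
        if self.family == "hampel":
            if self.l is None or self.m is None:
                raise ValueError("hampel requires corners l and m (0 < k <= l < m)")
            _check_positive(l=self.l, m=self.m)
            if not (self.k <= self.l < self.m):
                raise ValueError(
                    f"hampel constants must satisfy 0 < k <= l < m, got "
                    f"k={self.k}, l={self.l}, m={self.m}"
                )


def _as_result(out: np.ndarray):
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# proposed (generalized) family
# --------------------------------------------------------------------------

def proposed_rho(r, k: float, a: float):
    """Loss ρ(r) = (k²/2a)·[1 − {1+(r/k)²}^(−a)].

    Even, zero at the origin, strictly increasing in |r| and bounded above
    by k²/(2a) — a bounded loss, hence a redescending estimator.
    """
    _check_positive(k=k, a=a)
    r = np.asarray(r, dtype=float)
    return _as_result((k * k / (2.0 * a)) * (1.0 - (1.0 + (r / k) ** 2) ** (-a)))


def proposed_psi(r, k: float, a: float):
    """Influence ψ(r) = r·[1+(r/k)²]^(−a−1), the derivative of the loss.

    Odd, maximal in magnitude at r = ±k/√(2a+1), and → 0 as |r| → ∞.
    """
    _check_positive(k=k, a=a)
    r = np.asarray(r, dtype=float)
    return _as_result(r * (1.0 + (r / k) ** 2) ** (-a - 1.0))


def proposed_weight(r, k: float, a: float):
    """Weight w(r) = [1+(r/k)²]^(−a−1) ∈ (0, 1]; never an exact zero."""
    _check_positive(k=k, a=a)
    r = np.asarray(r, dtype=float)
    return _as_result((1.0 + (r / k) ** 2) ** (-a - 1.0))


def _proposed_dpsi(r, t: TuningSpec):
    u = (np.asarray(r, dtype=float) / t.k) ** 2
    return _as_result((1.0 + u) ** (-t.a - 2.0) * (1.0 - (2.0 * t.a + 1.0) * u))


# --------------------------------------------------------------------------
# comparator families
# --------------------------------------------------------------------------

def _huber_psi(r, t):
    r = np.asarray(r, dtype=float)
    return _as_result(np.clip(r, -t.k, t.k))


def _huber_weight(r, t):
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore"):
        return _as_result(np.where(np.abs(r) < t.k, 1.0, t.k / np.maximum(np.abs(r), 1e-300)))


def _huber_dpsi(r, t):
    r = np.asarray(r, dtype=float)
    return _as_result(np.where(np.abs(r) < t.k, 1.0, 0.0))


def _hampel_psi(r, t):
    r = np.asarray(r, dtype=float)
    ar = np.abs(r)
    s = np.sign(r)
    out = np.select(
        [ar <= t.k, ar <= t.l, ar <= t.m],
        [r, t.k * s, t.k * s * (t.m - ar) / (t.m - t.l)],
        default=0.0,
    )
    return _as_result(out)


def _hampel_weight(r, t):
    r = np.asarray(r, dtype=float)
    ar = np.maximum(np.abs(r), 1e-300)
    out = np.select(
        [np.abs(r) <= t.k, np.abs(r) <= t.l, np.abs(r) <= t.m],
        [1.0, t.k / ar, t.k * (t.m - np.abs(r)) / ((t.m - t.l) * ar)],
        default=0.0,
    )
    return _as_result(out)


def _andrew_psi(r, t):
    r = np.asarray(r, dtype=float)
    return _as_result(np.where(np.abs(r) <= t.k * np.pi, t.k * np.sin(r / t.k), 0.0))


def _andrew_weight(r, t):
    r = np.asarray(r, dtype=float)
    # sin(r/k)/(r/k) -> 1 at the origin
    return _as_result(np.where(np.abs(r) <= t.k * np.pi, np.sinc(r / (t.k * np.pi)), 0.0))


def _andrew_dpsi(r, t):
    r = np.asarray(r, dtype=float)
    return _as_result(np.where(np.abs(r) <= t.k * np.pi, np.cos(r / t.k), 0.0))


def _tukey_psi(r, t):
    r = np.asarray(r, dtype=float)
    u = (r / t.k) ** 2
    return _as_result(np.where(np.abs(r) < t.k, r * (1.0 - u) ** 2, 0.0))


def _tukey_weight(r, t):
    r = np.asarray(r, dtype=float)
    u = (r / t.k) ** 2
    return _as_result(np.where(np.abs(r) < t.k, (1.0 - u) ** 2, 0.0))


def _tukey_dpsi(r, t):
    r = np.asarray(r, dtype=float)
    u = (r / t.k) ** 2
    return _as_result(np.where(np.abs(r) < t.k, (1.0 - u) * (1.0 - 5.0 * u), 0.0))


def _qadir_psi(r, t):
    r = np.asarray(r, dtype=float)
    k = t.k
    inside = r / (16.0 * k ** 4) * (k + r) ** 2 * (k - r) ** 2
    return _as_result(np.where(np.abs(r) <= k, inside, 0.0))


def _qadir_weight(r, t):
    r = np.asarray(r, dtype=float)
    k = t.k
    # psi/r = (k^2 - r^2)^2 / (16 k^4); value 1/16 at the origin
    return _as_result(np.where(np.abs(r) <= k, (k * k - r * r) ** 2 / (16.0 * k ** 4), 0.0))


def _ali_psi(r, t):
    r = np.asarray(r, dtype=float)
    u = (r / t.k) ** 4
    return _as_result(np.where(np.abs(r) <= t.k, (2.0 * r / 3.0) * (1.0 - u) ** 2, 0.0))


def _ali_weight(r, t):
    r = np.asarray(r, dtype=float)
    u = (r / t.k) ** 4
    return _as_result(np.where(np.abs(r) <= t.k, (2.0 / 3.0) * (1.0 - u) ** 2, 0.0))


def insha_psi(r, k: float, *, as_printed: bool = False):
    """Insha's ψ.

    The corrected (default) form is ψ(r) = r·[1+(r/k)⁴]^(−2): odd,
    redescending, consistent with ψ = ρ′ and w = ψ/r.  ``as_printed=True``
    returns the even form [1+(r/k)⁴]^(−2) that appears in some accounts;
    it is not a valid influence function (ψ(0) = 1, not odd) and is kept
    only for comparison.
    """
    _check_positive(k=k)
    r = np.asarray(r, dtype=float)
    base = (1.0 + (r / k) ** 4) ** (-2.0)
    return _as_result(base if as_printed else r * base)


def _insha_psi(r, t):
    return insha_psi(r, t.k)


def _insha_weight(r, t):
    r = np.asarray(r, dtype=float)
    return _as_result((1.0 + (r / t.k) ** 4) ** (-2.0))


def _alamgir_psi(r, t):
    # Discontinuous at |r| = k as written: the inner expression does not
    # vanish there. Kept as written; the jump is split over in quadrature.
    r = np.asarray(r, dtype=float)
    u = (r / t.k) ** 2
    inside = 16.0 * r * np.exp(-2.0 * u) / (1.0 + np.exp(-u)) ** 2
    return _as_result(np.where(np.abs(r) <= t.k, inside, 0.0))


def _alamgir_weight(r, t):
    r = np.asarray(r, dtype=float)
    u = (r / t.k) ** 2
    inside = 16.0 * np.exp(-2.0 * u) / (1.0 + np.exp(-u)) ** 2  # 4 at the origin
    return _as_result(np.where(np.abs(r) <= t.k, inside, 0.0))


def _khalil_core(r, t):
    u = (r / t.k) ** 4
    g = (1.0 - u) ** 2
    return 1.5 * g * np.sin((2.0 / 3.0) * g)


def _khalil_psi(r, t):
    r = np.asarray(r, dtype=float)
    return _as_result(np.where(np.abs(r) <= t.k, r * _khalil_core(r, t), 0.0))


def _khalil_weight(r, t):
    r = np.asarray(r, dtype=float)
    return _as_result(np.where(np.abs(r) <= t.k, _khalil_core(r, t), 0.0))


# --------------------------------------------------------------------------
# registry
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PsiFamily:
    """A named ψ-family with its weight (and, where closed-form, ρ and ψ′)."""

    name: str
    is_redescending: bool
    default_tuning: TuningSpec
    _psi: Callable = field(repr=False)
    _weight: Callable = field(repr=False)
    _rho: Optional[Callable] = field(default=None, repr=False)
    _dpsi: Optional[Callable] = field(default=None, repr=False)
    _breakpoints: Callable = field(default=lambda t: (), repr=False)

    @property
    def has_rho(self) -> bool:
        return self._rho is not None

    def _tuning(self, tuning: Optional[TuningSpec]) -> TuningSpec:
        t = self.default_tuning if tuning is None else tuning
        if t.family != self.name:
            raise ValueError(f"tuning is for family {t.family!r}, not {self.name!r}")
        return t

    def psi(self, r, tuning: Optional[TuningSpec] = None):
        return self._psi(r, self._tuning(tuning))

    def weight(self, r, tuning: Optional[TuningSpec] = None):
        """ψ(r)/r with the finite analytic limit at r = 0 (may exceed 1)."""
        return self._weight(r, self._tuning(tuning))

    def rho(self, r, tuning: Optional[TuningSpec] = None):
        if self._rho is None:
            raise NotImplementedError(f"{self.name} has no closed-form rho")
        return self._rho(r, self._tuning(tuning))

    def dpsi(self, r, tuning: Optional[TuningSpec] = None):
        """Analytic ψ′ where available, else a central difference."""
        t = self._tuning(tuning)
        if self._dpsi is not None:
            return self._dpsi(r, t)
        h = 1e-6
        r = np.asarray(r, dtype=float)
        hi = np.asarray(self._psi(r + h, t), dtype=float)
        lo = np.asarray(self._psi(r - h, t), dtype=float)
        return _as_result((hi - lo) / (2.0 * h))

    def breakpoints(self, tuning: Optional[TuningSpec] = None) -> tuple:
        """Points where ψ kinks or jumps (for piecewise quadrature)."""
        return tuple(self._breakpoints(self._tuning(tuning)))

    def weight_at_zero(self, tuning: Optional[TuningSpec] = None) -> float:
        return float(self.weight(0.0, tuning))


def _bp_k(t):
    return (-t.k, t.k)


_REGISTRY: dict[str, PsiFamily] = {}


def _register(fam: PsiFamily) -> None:
    _REGISTRY[fam.name] = fam


_register(PsiFamily("huber", False, TuningSpec("huber", 1.345),
                    _huber_psi, _huber_weight, _dpsi=_huber_dpsi, _breakpoints=_bp_k))
_register(PsiFamily("hampel", True, TuningSpec("hampel", 2.0, l=4.0, m=8.0),
                    _hampel_psi, _hampel_weight,
                    _breakpoints=lambda t: (-t.m, -t.l, -t.k, t.k, t.l, t.m)))
_register(PsiFamily("andrew", True, TuningSpec("andrew", 3.2),
                    _andrew_psi, _andrew_weight, _dpsi=_andrew_dpsi,
                    _breakpoints=lambda t: (-t.k * math.pi, t.k * math.pi)))
_register(PsiFamily("tukey", True, TuningSpec("tukey", 4.865),
                    _tukey_psi, _tukey_weight, _dpsi=_tukey_dpsi, _breakpoints=_bp_k))
_register(PsiFamily("qadir", True, TuningSpec("qadir", 4.0),
                    _qadir_psi, _qadir_weight, _breakpoints=_bp_k))
_register(PsiFamily("ali", True, TuningSpec("ali", 4.0),
                    _ali_psi, _ali_weight, _breakpoints=_bp_k))
_register(PsiFamily("insha", True, TuningSpec("insha", 4.0),
                    _insha_psi, _insha_weight))
_register(PsiFamily("alamgir", True, TuningSpec("alamgir", 3.0),
                    _alamgir_psi, _alamgir_weight, _breakpoints=_bp_k))
_register(PsiFamily("khalil", True, TuningSpec("khalil", 4.0),
                    _khalil_psi, _khalil_weight, _breakpoints=_bp_k))
_register(PsiFamily("proposed", True, TuningSpec("proposed", 2.0, a=8.0),
                    lambda r, t: proposed_psi(r, t.k, t.a),
                    lambda r, t: proposed_weight(r, t.k, t.a),
                    _rho=lambda r, t: proposed_rho(r, t.k, t.a),
                    _dpsi=_proposed_dpsi))


def get_family(name: str) -> PsiFamily:
    try:
        return _REGISTRY[name.lower()]
    except KeyError:
        raise UnknownFamilyError(
            f"unknown psi family {name!r}; available: {', '.join(sorted(_REGISTRY))}"
        ) from None


def list_families() -> list[str]:
    return sorted(_REGISTRY)


def default_tuning(name: str, c: Optional[float] = None,
                   a: Optional[float] = None) -> TuningSpec:
    """Build a TuningSpec from a family's single printed constant.

    For Hampel the single constant ``c`` is read as the middle corner l,
    with (k, l, m) = (c/2, c, 2c) preserving the classical 1:2:4 shape.
    For the proposed family ``a`` defaults to the registry value when not
    given.  With no arguments the registry default is returned.
    """
    fam = get_family(name)
    t = fam.default_tuning
    if c is None and a is None:
        return t
    if fam.name == "hampel":
        c = t.l if c is None else c
        return TuningSpec("hampel", k=c / 2.0, l=c, m=2.0 * c)
    if fam.name == "proposed":
        return TuningSpec("proposed", k=t.k if c is None else c,
                          a=t.a if a is None else a)
    return replace(t, k=c)
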