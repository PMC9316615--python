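"""Saturating learning-curve model functions.

Seven candidate curves describe expected performance score as a function of
the within-device trial number ``t`` (1-based).  All share a common core
vocabulary:

* ``P0`` — initial performance (score units, the level at the start of
  practice),
* ``A``  — learning plateau (the asymptote approached as ``t`` grows),
* ``r``  — learning rate on an unconstrained log scale (larger = faster
  approach to the plateau),
* ``c``  — shape exponent (> 0) for the four-parameter families.

Every curve satisfies ``f(t) -> A`` as ``t -> inf`` and is non-decreasing in
``t`` whenever ``A >= P0`` — the "rate of improvement decreasing over time"
family that learning-curve studies fit.  The modified Weibull,

    f(t) = A + (P0 - A) * exp(-(t * exp(r))**c),

is flagged as the default choice.  Parameter vectors are ordered as
``param_names``; values and analytic gradients broadcast over numpy arrays so
the mixed-effects fitter can evaluate whole subject panels at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Sequence, Tuple

import numpy as np

__all__ = [
    "CurveSpec",
    "CurveParameterError",
    "curve_menu",
    "get_curve",
    "curve_value",
    "curve_gradient",
]


class CurveParameterError(ValueError):
    """A curve parameter violates its admissibility constraint."""


def _safe_exp(x):
    """exp with the argument capped below overflow (results saturate, never inf)."""
    return np.exp(np.minimum(x, 700.0))


@dataclass(frozen=True)
class CurveSpec:
    """A named saturating learning-curve function.

    ``value(params, t)`` maps a parameter vector (ordered as ``param_names``)
    and trial numbers to expected scores; ``grad`` returns the stack of
    partial derivatives with shape ``(n_params,) + shape(t)``.
    """

    name: str
    param_names: Tuple[str, ...]
    _value: Callable[[Sequence[np.ndarray], np.ndarray], np.ndarray]
    _grad: Callable[[Sequence[np.ndarray], np.ndarray], np.ndarray]
    is_default: bool = False
    positive_params: Tuple[str, ...] = field(default=())

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def check_params(self, params: Sequence) -> list:
        """Validate a parameter vector, raising with the offending name."""
        if len(params) != self.n_params:
            raise CurveParameterError(
                f"{self.name} expects {self.n_params} parameters "
                f"{self.param_names}, got {len(params)}"
            )
        out = [np.asarray(p, dtype=float) for p in params]
        for nm, p in zip(self.param_names, out):
            if not np.all(np.isfinite(p)):
                raise CurveParameterError(f"{self.name}: parameter {nm!r} is not finite")
            if nm in self.positive_params and not np.all(p > 0):
                raise CurveParameterError(
                    f"{self.name}: parameter {nm!r} must be > 0"
                )
        return out

    def value(self, params: Sequence, t) -> np.ndarray:
        p = self.check_params(params)
        t = np.asarray(t, dtype=float)
        return self._value(p, t)

    def grad(self, params: Sequence, t) -> np.ndarray:
        p = self.check_params(params)
        t = np.asarray(t, dtype=float)
        return self._grad(p, t)


# ----------------------------------------------------------------------------
# The seven functional forms.


def _exponential_value(p, t):
    P0, A, r = p
    E = np.exp(-_safe_exp(r) * t)
    return A + (P0 - A) * E


def _exponential_grad(p, t):
    P0, A, r = p
    u = _safe_exp(r)
    E = np.exp(-u * t)
    return np.stack(
        [
            np.broadcast_to(E, np.broadcast_shapes(np.shape(E), np.shape(t))),
            np.broadcast_to(1.0 - E, np.broadcast_shapes(np.shape(E), np.shape(t))),
            -(P0 - A) * E * t * u,
        ]
    )


def _power_value(p, t):
    P0, A, r = p
    T = t ** (-_safe_exp(r))
    return A - (A - P0) * T


def _power_grad(p, t):
    P0, A, r = p
    u = _safe_exp(r)
    lnt = np.log(t)
    T = np.exp(-u * lnt)
    shape = np.broadcast_shapes(np.shape(T), np.shape(t))
    return np.stack(
        [
            np.broadcast_to(T, shape),
            np.broadcast_to(1.0 - T, shape),
            (A - P0) * u * lnt * T,
        ]
    )


def _hyperbolic_value(p, t):
    P0, A, r = p
    b = _safe_exp(-r)
    return P0 + (A - P0) * t / (t + b)


def _hyperbolic_grad(p, t):
    P0, A, r = p
    b = _safe_exp(-r)
    D = t + b
    frac = t / D
    shape = np.broadcast_shapes(np.shape(frac), np.shape(t))
    return np.stack(
        [
            np.broadcast_to(1.0 - frac, shape),
            np.broadcast_to(frac, shape),
            (A - P0) * t * b / D**2,
        ]
    )


def _logistic_value(p, t):
    P0, A, r, c = p
    k = _safe_exp(r)
    S = 1.0 / (1.0 + np.exp(-k * (t - c)))
    return P0 + (A - P0) * S


def _logistic_grad(p, t):
    P0, A, r, c = p
    k = _safe_exp(r)
    S = 1.0 / (1.0 + np.exp(-k * (t - c)))
    dS = S * (1.0 - S)
    shape = np.broadcast_shapes(np.shape(S), np.shape(t))
    return np.stack(
        [
            np.broadcast_to(1.0 - S, shape),
            np.broadcast_to(S, shape),
            (A - P0) * dS * k * (t - c),
            -(A - P0) * dS * k,
        ]
    )


def _gompertz_value(p, t):
    P0, A, r, c = p
    inner = np.exp(-_safe_exp(r) * t)
    G = np.exp(-c * inner)
    return P0 + (A - P0) * G


def _gompertz_grad(p, t):
    P0, A, r, c = p
    k = _safe_exp(r)
    inner = np.exp(-k * t)
    G = np.exp(-c * inner)
    shape = np.broadcast_shapes(np.shape(G), np.shape(t))
    return np.stack(
        [
            np.broadcast_to(1.0 - G, shape),
            np.broadcast_to(G, shape),
            (A - P0) * G * c * k * t * inner,
            -(A - P0) * G * inner,
        ]
    )


def _weibull_value(p, t):
    P0, A, r, c = p
    s = _safe_exp(r + c * np.log(t))
    return A + (P0 - A) * np.exp(-s)


def _weibull_grad(p, t):
    P0, A, r, c = p
    s = _safe_exp(r + c * np.log(t))
    E = np.exp(-s)
    shape = np.broadcast_shapes(np.shape(E), np.shape(t))
    return np.stack(
        [
            np.broadcast_to(E, shape),
            np.broadcast_to(1.0 - E, shape),
            -(P0 - A) * E * s,
            -(P0 - A) * E * s * np.log(t),
        ]
    )


def _modified_weibull_value(p, t):
    P0, A, r, c = p
    s = _safe_exp(c * (r + np.log(t)))  # == (t * exp(r))**c == (t / exp(-r))**c
    return A + (P0 - A) * np.exp(-s)


def _modified_weibull_grad(p, t):
    P0, A, r, c = p
    lt = r + np.log(t)
    s = _safe_exp(c * lt)
    E = np.exp(-s)
    shape = np.broadcast_shapes(np.shape(E), np.shape(t))
    return np.stack(
        [
            np.broadcast_to(E, shape),
            np.broadcast_to(1.0 - E, shape),
            -(P0 - A) * E * s * c,
            -(P0 - A) * E * s * lt,
        ]
    )


_MENU: Dict[str, CurveSpec] = {
    spec.name: spec
    for spec in [
        CurveSpec("exponential", ("P0", "A", "r"), _exponential_value, _exponential_grad),
        CurveSpec("power", ("P0", "A", "r"), _power_value, _power_grad),
        CurveSpec("hyperbolic", ("P0", "A", "r"), _hyperbolic_value, _hyperbolic_grad),
        CurveSpec(
            "logistic",
            ("P0", "A", "r", "c"),
            _logistic_value,
            _logistic_grad,
            positive_params=("c",),
        ),
        CurveSpec(
            "gompertz",
            ("P0", "A", "r", "c"),
            _gompertz_value,
            _gompertz_grad,
            positive_params=("c",),
        ),
        CurveSpec(
            "weibull",
            ("P0", "A", "r", "c"),
            _weibull_value,
            _weibull_grad,
            positive_params=("c",),
        ),
        CurveSpec(
            "modified_weibull",
            ("P0", "A", "r", "c"),
            _modified_weibull_value,
            _modified_weibull_grad,
            is_default=True,
            positive_params=("c",),
        ),
    ]
}


def curve_menu() -> list:
    """Return the seven candidate curve specifications."""
    return list(_MENU.values())


def get_curve(name: str) -> CurveSpec:
    try:
        return _MENU[name]
    except KeyError:
        raise KeyError(
            f"unknown curve {name!r}; valid names: {sorted(_MENU)}"
        ) from None


def curve_value(spec: CurveSpec, params: Sequence, t) -> np.ndarray:
    """Expected score of ``spec`` at trial(s) ``t`` under ``params``."""
    return spec.value(params, t)


def curve_gradient(spec: CurveSpec, params: Sequence, t) -> np.ndarray:
    """Partial derivatives of the expected score w.r.t. each parameter."""
    return spec.grad(params, t)
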