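"""Reaction kinetics, growth laws, their derivatives and equilibria.

All kinetics are vectorized over trailing axes: a state ``u`` of shape
``(m,)`` or ``(m, n_points)`` yields outputs of matching shape. Parameters
are dimensionless throughout.
"""

from __future__ import annotations

import logging

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Optional

import numpy as np

__all__ = [
    "KineticsSpec",
    "GrowthLaw",
    "Equilibrium",
    "StabilityClass",
    "evaluate_kinetics",
    "kinetics_jacobian",
    "kinetics_jacobian_field",
    "growth_gradient_field",
    "find_equilibria",
    "evaluate_growth",
    "growth_gradient",
]

logger = logging.getLogger(__name__)

_KINETICS_NAMES = {
    "schnakenberg",
    "gierer_meinhardt",
    "fitzhugh_nagumo",
    "logistic",
    "bistable",
    "custom",
}

_GROWTH_FORMS = {
    "constant",
    "prescribed_time",
    "linear",
    "thresholded_tanh",
    "quadratic_ratio",
    "difference",
    "custom",
}

_FD_STEP = 1e-6


class StabilityClass(str, Enum):
    node_stable = "node_stable"
    node_unstable = "node_unstable"
    spiral_stable = "spiral_stable"
    spiral_unstable = "spiral_unstable"
    saddle = "saddle"
    degenerate = "degenerate"


@dataclass(frozen=True)
class KineticsSpec:
    """A named reaction term f(u) with parameters.

    For ``name="custom"`` supply ``f(u) -> array`` (vectorized over trailing
    axes) and optionally ``jac(u) -> (m, m) array`` for a single state; if
    ``jac`` is omitted a finite-difference fallback is used (with a logged
    warning, once).
    """

    name: str
    params: dict = field(default_factory=dict)
    n_species: int = 2
    f: Optional[Callable] = None
    jac: Optional[Callable] = None

    def __post_init__(self) -> None:
        if self.name not in _KINETICS_NAMES:
            raise ValueError(f"unknown kinetics name: {self.name!r}")
        if self.name in ("logistic", "bistable") and self.n_species != 1:
            object.__setattr__(self, "n_species", 1)
        if self.name in ("schnakenberg", "gierer_meinhardt", "fitzhugh_nagumo"):
            if self.n_species != 2:
                raise ValueError(f"{self.name} kinetics require n_species=2")
            for key, val in self.params.items():
                if key in ("a", "b", "c", "i0") and val <= 0:
                    raise ValueError(f"parameter {key} must be positive, got {val}")
        if self.name == "custom" and self.f is None:
            raise ValueError("custom kinetics require a callable f")

    def __hash__(self) -> int:  # params dict is not hashable
        return hash((self.name, tuple(sorted(self.params.items())), self.n_species))


@dataclass(frozen=True)
class GrowthLaw:
    """Local dilation rate S(t, u) with its concentration gradient.

    Supported forms
    ---------------
    constant:          S = s0
    prescribed_time:   S = rate(t)  (user callable, purely time dependent)
    linear:            S = s0 + slope * u[species]
    thresholded_tanh:  S = s0 * (1 + tanh(k_th * (q - u_th))),
                       q = |u[species]| if use_abs else u[species]
    quadratic_ratio:   S = s0 * ((u[species] / u_ref)**2 - 1)
    difference:        S = r * (u[0] - alpha * u[1])
    custom:            S = rate(t, u) with optional grad(t, u)
    """

    form: str
    params: dict = field(default_factory=dict)
    time_dependent: bool = False
    rate: Optional[Callable] = None
    grad: Optional[Callable] = None
    species: int = 0
    use_abs: bool = False

    def __post_init__(self) -> None:
        if self.form not in _GROWTH_FORMS:
            raise ValueError(f"unknown growth-law form: {self.form!r}")
        if self.form in ("prescribed_time", "custom") and self.rate is None:
            raise ValueError(f"{self.form} growth law requires a callable rate")
        required = {
            "constant": ("s0",),
            "linear": ("s0", "slope"),
            "thresholded_tanh": ("s0", "u_th", "k_th"),
            "quadratic_ratio": ("s0", "u_ref"),
            "difference": ("r", "alpha"),
        }.get(self.form, ())
        missing = [k for k in required if k not in self.params]
        if missing:
            raise ValueError(f"growth law {self.form!r} missing parameters {missing}")
        if self.form == "prescribed_time":
            object.__setattr__(self, "time_dependent", True)

    def __hash__(self) -> int:
        return hash((self.form, tuple(sorted(self.params.items())), self.species))


@dataclass(frozen=True)
class Equilibrium:
    u_star: np.ndarray
    stability_class: StabilityClass

    def __iter__(self):
        return iter(self.u_star)


# ----------------------------------------------------------------------------
# kinetics evaluation


def evaluate_kinetics(spec: KineticsSpec, u: np.ndarray) -> np.ndarray:
    """Evaluate the reaction term f(u).

    ``u`` has shape ``(m,)`` or ``(m, ...)``; the result has the same shape.
    """
    u = np.asarray(u, dtype=float)
    if u.shape[0] != spec.n_species:
        raise ValueError(
            f"state has {u.shape[0]} species, kinetics expect {spec.n_species}"
        )
    p = spec.params
    if spec.name == "schnakenberg":
        a, b = p["a"], p["b"]
        uu, vv = u[0], u[1]
        return np.stack([a - uu + uu**2 * vv, b - uu**2 * vv])
    if spec.name == "gierer_meinhardt":
        # classical activator form a + u^2/v - b u (see README on the sign
        # of the autocatalytic term)
        a, b, c = p["a"], p["b"], p["c"]
        uu, vv = u[0], u[1]
        return np.stack([a + uu**2 / vv - b * uu, uu**2 - c * vv])
    if spec.name == "fitzhugh_nagumo":
        a, b, c, i0 = p["a"], p["b"], p["c"], p["i0"]
        uu, vv = u[0], u[1]
        return np.stack([c * (uu - uu**3 / 3.0 + vv - i0), (a - uu - b * vv) / c])
    if spec.name == "logistic":
        return u * (1.0 - u)
    if spec.name == "bistable":
        return u * (1.0 - u**2)
    # custom
    return np.asarray(spec.f(u), dtype=float)


def kinetics_jacobian(spec: KineticsSpec, u: np.ndarray) -> np.ndarray:
    """Analytic Jacobian J_ij = d f_i / d u_j at a single state ``u``."""
    u = np.asarray(u, dtype=float)
    if u.shape != (spec.n_species,):
        raise ValueError(f"expected state of shape ({spec.n_species},), got {u.shape}")
    p = spec.params
    if spec.name == "schnakenberg":
        uu, vv = u
        return np.array([
            [-1.0 + 2.0 * uu * vv, uu**2],
            [-2.0 * uu * vv, -(uu**2)],
        ])
    if spec.name == "gierer_meinhardt":
        b, c = p["b"], p["c"]
        uu, vv = u
        return np.array([
            [2.0 * uu / vv - b, -(uu**2) / vv**2],
            [2.0 * uu, -c],
        ])
    if spec.name == "fitzhugh_nagumo":
        b, c = p["b"], p["c"]
        uu = u[0]
        return np.array([
            [c * (1.0 - uu**2), c],
            [-1.0 / c, -b / c],
        ])
    if spec.name == "logistic":
        return np.array([[1.0 - 2.0 * u[0]]])
    if spec.name == "bistable":
        return np.array([[1.0 - 3.0 * u[0] ** 2]])
    if spec.jac is not None:
        return np.asarray(spec.jac(u), dtype=float)
    _warn_fd(f"custom kinetics {spec!r}")
    return _fd_jacobian(lambda x: evaluate_kinetics(spec, x), u)


def kinetics_jacobian_field(spec: KineticsSpec, u: np.ndarray) -> np.ndarray:
    """Jacobian at every point of a field: u (m, N) -> (m, m, N)."""
    u = np.asarray(u, dtype=float)
    if u.ndim == 1:
        return kinetics_jacobian(spec, u)[..., None]
    m, N = u.shape
    p = spec.params
    if spec.name == "schnakenberg":
        uu, vv = u
        return np.array([
            [-1.0 + 2.0 * uu * vv, uu**2],
            [-2.0 * uu * vv, -(uu**2)],
        ])
    if spec.name == "gierer_meinhardt":
        b, c = p["b"], p["c"]
        uu, vv = u
        return np.array([
            [2.0 * uu / vv - b, -(uu**2) / vv**2],
            [2.0 * uu, np.full(N, -c)],
        ])
    if spec.name == "fitzhugh_nagumo":
        b, c = p["b"], p["c"]
        uu = u[0]
        return np.array([
            [c * (1.0 - uu**2), np.full(N, c)],
            [np.full(N, -1.0 / c), np.full(N, -b / c)],
        ])
    if spec.name == "logistic":
        return (1.0 - 2.0 * u[0])[None, None, :]
    if spec.name == "bistable":
        return (1.0 - 3.0 * u[0] ** 2)[None, None, :]
    # custom: vectorized central differences through evaluate_kinetics
    out = np.empty((m, m, N))
    for j in range(m):
        up, um = u.copy(), u.copy()
        up[j] += _FD_STEP
        um[j] -= _FD_STEP
        out[:, j, :] = (evaluate_kinetics(spec, up) - evaluate_kinetics(spec, um)) / (
            2 * _FD_STEP
        )
    return out


def growth_gradient_field(law: GrowthLaw, t: float, u: np.ndarray) -> np.ndarray:
    """Gradient dS/du_j at every point of a field: u (m, N) -> (m, N)."""
    u = np.asarray(u, dtype=float)
    if u.ndim == 1:
        return growth_gradient(law, t, u)[:, None]
    m, N = u.shape
    p = law.params
    g = np.zeros((m, N))
    if law.form in ("constant", "prescribed_time"):
        return g
    if law.form == "linear":
        g[law.species] = p["slope"]
    elif law.form == "thresholded_tanh":
        q = u[law.species]
        arg = np.abs(q) if law.use_abs else q
        sign = np.sign(q) if law.use_abs else 1.0
        g[law.species] = (
            p["s0"] * p["k_th"] * sign / np.cosh(p["k_th"] * (arg - p["u_th"])) ** 2
        )
    elif law.form == "quadratic_ratio":
        g[law.species] = 2.0 * p["s0"] * u[law.species] / p["u_ref"] ** 2
    elif law.form == "difference":
        g[0] = p["r"]
        g[1] = -p["r"] * p["alpha"]
    else:  # custom: vectorized central differences
        for j in range(m):
            up, um = u.copy(), u.copy()
            up[j] += _FD_STEP
            um[j] -= _FD_STEP
            g[j] = (
                np.asarray(evaluate_growth(law, t, up))
                - np.asarray(evaluate_growth(law, t, um))
            ) / (2 * _FD_STEP)
    return g


_warned: set = set()


def _warn_fd(what: str) -> None:
    if what not in _warned:
        _warned.add(what)
        logger.warning("no analytic derivative for %s; using finite differences", what)


def _fd_jacobian(fun: Callable, u: np.ndarray, h: float = _FD_STEP) -> np.ndarray:
    m = len(u)
    out = np.empty((m, m))
    for j in range(m):
        up, um = u.copy(), u.copy()
        up[j] += h
        um[j] -= h
        out[:, j] = (np.asarray(fun(up)) - np.asarray(fun(um))) / (2 * h)
    return out


# ----------------------------------------------------------------------------
# equilibria


def _classify(J: np.ndarray, tol: float = 1e-12) -> StabilityClass:
    lam = np.linalg.eigvals(J)
    re = lam.real
    if np.any(np.abs(re) < tol):
        return StabilityClass.degenerate
    if J.shape[0] >= 2 and np.any(np.abs(lam.imag) > tol):
        return (
            StabilityClass.spiral_stable if np.all(re < 0)
            else StabilityClass.spiral_unstable
        )
    if np.all(re < 0):
        return StabilityClass.node_stable
    if np.all(re > 0):
        return StabilityClass.node_unstable
    return StabilityClass.saddle


def find_equilibria(spec: KineticsSpec, tol: float = 1e-12) -> list[Equilibrium]:
    """All real homogeneous equilibria f(u) = 0, sorted by first component.

    Polynomial kinetics are solved via companion-matrix root finding after
    clearing denominators; for Gierer-Meinhardt only the positive branch is
    physical and retained.
    """
    p = spec.params
    roots: list[np.ndarray] = []
    if spec.name == "schnakenberg":
        a, b = p["a"], p["b"]
        us = a + b
        if us <= 0:
            raise RuntimeError("schnakenberg equilibrium requires a + b > 0")
        roots.append(np.array([us, b / us**2]))
    elif spec.name == "gierer_meinhardt":
        a, b, c = p["a"], p["b"], p["c"]
        us = (a + c) / b
        if us <= 0:
            raise RuntimeError("gierer_meinhardt has no positive equilibrium")
        roots.append(np.array([us, us**2 / c]))
    elif spec.name == "fitzhugh_nagumo":
        a, b, c = p["a"], p["b"], p["c"]
        i0 = p["i0"]
        # u - u^3/3 + (a - u)/b - i0 = 0, then v = (a - u)/b
        poly = np.array([-1.0 / 3.0, 0.0, 1.0 - 1.0 / b, a / b - i0])
        for r in np.roots(poly):
            if abs(r.imag) < 1e-9:
                uu = r.real
                roots.append(np.array([uu, (a - uu) / b]))
    elif spec.name == "logistic":
        roots = [np.array([0.0]), np.array([1.0])]
    elif spec.name == "bistable":
        roots = [np.array([-1.0]), np.array([0.0]), np.array([1.0])]
    else:
        roots = _find_equilibria_custom(spec, tol)

    out = []
    for r in roots:
        res = evaluate_kinetics(spec, r)
        if np.max(np.abs(res)) > 1e-10:
            from scipy.optimize import fsolve

            r, info, ier, msg = fsolve(
                lambda x: evaluate_kinetics(spec, x), r, full_output=True, xtol=tol
            )
            if ier != 1 or np.max(np.abs(evaluate_kinetics(spec, r))) > 1e-10:
                raise RuntimeError(f"equilibrium polish failed: {msg}")
        out.append(Equilibrium(np.asarray(r, dtype=float), _classify(kinetics_jacobian(spec, r))))
    out.sort(key=lambda e: e.u_star[0])
    return out


def _find_equilibria_custom(spec: KineticsSpec, tol: float) -> list[np.ndarray]:
    """Multi-start Newton search for custom kinetics equilibria."""
    from scipy.optimize import fsolve

    m = spec.n_species
    found: list[np.ndarray] = []
    rng = np.random.default_rng(0)
    starts = [np.zeros(m), np.ones(m)] + [rng.uniform(-5, 5, m) for _ in range(48)]
    for x0 in starts:
        sol, _, ier, _ = fsolve(
            lambda x: evaluate_kinetics(spec, x), x0, full_output=True, xtol=tol
        )
        if ier != 1 or np.max(np.abs(evaluate_kinetics(spec, sol))) > 1e-10:
            continue
        if not any(np.allclose(sol, f, atol=1e-7) for f in found):
            found.append(sol)
    if not found:
        raise RuntimeError("no equilibria found for custom kinetics (50 starts)")
    return found


# ----------------------------------------------------------------------------
# growth laws


def evaluate_growth(law: GrowthLaw, t: float, u: np.ndarray):
    """Dilation rate S(t, u); vectorized over trailing axes of ``u``.

    Returns a scalar for a ``(m,)`` state, an array of shape ``u.shape[1:]``
    otherwise.
    """
    u = np.asarray(u, dtype=float)
    p = law.params
    scalar_in = u.ndim == 1
    if law.form == "constant":
        out = np.broadcast_to(p["s0"], u.shape[1:]).copy() if not scalar_in else p["s0"]
        return out
    if law.form == "prescribed_time":
        val = law.rate(t)
        return val if scalar_in else np.broadcast_to(val, u.shape[1:]).copy()
    q = u[law.species]
    if law.form == "linear":
        out = p["s0"] + p["slope"] * q
    elif law.form == "thresholded_tanh":
        arg = np.abs(q) if law.use_abs else q
        out = p["s0"] * (1.0 + np.tanh(p["k_th"] * (arg - p["u_th"])))
    elif law.form == "quadratic_ratio":
        out = p["s0"] * ((q / p["u_ref"]) ** 2 - 1.0)
    elif law.form == "difference":
        out = p["r"] * (u[0] - p["alpha"] * u[1])
    else:  # custom
        out = np.asarray(law.rate(t, u), dtype=float)
    return float(out) if scalar_in and np.ndim(out) == 0 else out


def growth_gradient(law: GrowthLaw, t: float, u: np.ndarray) -> np.ndarray:
    """Analytic gradient dS/du_j at a single state ``u``, shape ``(m,)``."""
    u = np.asarray(u, dtype=float)
    m = u.shape[0]
    p = law.params
    g = np.zeros(m)
    if law.form in ("constant", "prescribed_time"):
        return g
    if law.form == "linear":
        g[law.species] = p["slope"]
        return g
    if law.form == "thresholded_tanh":
        q = u[law.species]
        arg = abs(q) if law.use_abs else q
        sign = np.sign(q) if law.use_abs else 1.0
        g[law.species] = p["s0"] * p["k_th"] * sign / np.cosh(p["k_th"] * (arg - p["u_th"])) ** 2
        return g
    if law.form == "quadratic_ratio":
        g[law.species] = 2.0 * p["s0"] * u[law.species] / p["u_ref"] ** 2
        return g
    if law.form == "difference":
        g[0] = p["r"]
        g[1] = -p["r"] * p["alpha"]
        return g
    if law.grad is not None:
        return np.asarray(law.grad(t, u), dtype=float)
    _warn_fd(f"custom growth law {law!r}")
    out = np.empty(m)
    for j in range(m):
        up, um = u.copy(), u.copy()
        up[j] += _FD_STEP
        um[j] -= _FD_STEP
        out[j] = (evaluate_growth(law, t, up) - evaluate_growth(law, t, um)) / (2 * _FD_STEP)
    return out
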