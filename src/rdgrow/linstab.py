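"""Linear instability analysis about homogeneous evolving base states.

The homogeneous base state (u*(t), mu*(t)) obeys

    du*/dt  = -S(t, u*) u* + f(u*),      mu*' = S(t, u*) mu*,

and cosine-mode perturbations V_k evolve by

    dV_k/dt = -rho_k mu*(t)^{-2} D V_k + M(t) V_k,

with rho_k = (k pi / L)^2 and M = J - K - S I, where K_ij = (dS/du_j) u*_i.
A mode is flagged exponentially growing at time t when

    det M - (D2 M11 + D1 M22) rho_k / mu*^2 + D1 D2 rho_k^2 / mu*^4
      < max_{(i,j) in {(1,2),(2,1)}} M_ij d/dt[(M_ii mu*^2 - D_i rho_k) / (M_ij mu*^2)],

which requires M to have at least one nonzero off-diagonal entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import interp1d

from rdgrow.kinetics import (
    GrowthLaw,
    KineticsSpec,
    evaluate_growth,
    evaluate_kinetics,
    find_equilibria,
    growth_gradient,
    kinetics_jacobian,
)

__all__ = [
    "BaseState",
    "LinearizationMatrices",
    "ModeSpec",
    "ModeStabilityReport",
    "integrate_base_state",
    "linearization_matrices",
    "theorem1_flag",
    "unstable_modes",
    "integrate_mode_amplitudes",
]

_DIAG_TOL = 1e-12
_FD_DT = 1e-3


@dataclass
class BaseState:
    """Trajectory of the homogeneous base state."""

    t: np.ndarray
    u_star: np.ndarray  # (m, nt)
    mu_star: np.ndarray  # (nt,)
    _u_interp: object = field(default=None, repr=False)
    _mu_interp: object = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self._u_interp = interp1d(self.t, self.u_star, kind="cubic", axis=-1)
        self._mu_interp = interp1d(self.t, np.log(self.mu_star), kind="cubic")

    def u_at(self, t: float) -> np.ndarray:
        return np.asarray(self._u_interp(t))

    def mu_at(self, t: float) -> float:
        return float(np.exp(self._mu_interp(t)))

    @property
    def span(self) -> tuple[float, float]:
        return float(self.t[0]), float(self.t[-1])


@dataclass(frozen=True)
class LinearizationMatrices:
    J: np.ndarray
    K: np.ndarray
    gradS: np.ndarray
    S: float
    M: np.ndarray
    mu_star: float

    @property
    def is_diagonal(self) -> bool:
        return abs(self.M[0, 1]) < _DIAG_TOL and abs(self.M[1, 0]) < _DIAG_TOL


@dataclass(frozen=True)
class ModeSpec:
    """Cosine mode k on the reference interval [0, L]: rho_k = (k pi / L)^2."""

    k: int
    L: float

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("mode index must be nonnegative")
        if self.L <= 0:
            raise ValueError("interval length must be positive")

    @property
    def rho(self) -> float:
        return (self.k * np.pi / self.L) ** 2


@dataclass
class ModeStabilityReport:
    L: float
    t_grid: np.ndarray
    flags: np.ndarray  # (k_max + 1, nt), dtype float: 1 unstable, 0 stable, nan n/a
    intervals: dict  # k -> list of (t_start, t_end)

    def unstable_at(self, k: int, t: float) -> bool:
        i = int(np.argmin(np.abs(self.t_grid - t)))
        return bool(self.flags[k, i] == 1.0)

    def to_rows(self) -> list[tuple[int, float, float]]:
        rows = []
        for k, ivals in sorted(self.intervals.items()):
            rows.extend((k, a, b) for a, b in ivals)
        return rows


# ----------------------------------------------------------------------------


def integrate_base_state(
    spec: KineticsSpec,
    law: GrowthLaw,
    t_span: tuple[float, float],
    which_equilibrium: int = 0,
    rtol: float = 1e-10,
    n_grid: int = 801,
) -> BaseState:
    """Integrate u*' = -S u* + f from an equilibrium of f, then mu* by
    quadrature of S along the trajectory."""
    eqs = find_equilibria(spec)
    if which_equilibrium >= len(eqs):
        raise ValueError(
            f"equilibrium index {which_equilibrium} out of range ({len(eqs)} found)"
        )
    u0 = eqs[which_equilibrium].u_star
    m = len(u0)
    t0, t1 = t_span

    def rhs(t, y):
        u = y[:m]
        S = evaluate_growth(law, t, u)
        du = -S * u + evaluate_kinetics(spec, u)
        return np.concatenate([du, [S]])  # last slot: log mu*

    t_grid = np.linspace(t0, t1, n_grid)
    sol = solve_ivp(
        rhs,
        t_span,
        np.concatenate([u0, [0.0]]),
        method="LSODA",
        rtol=rtol,
        atol=rtol,
        t_eval=t_grid,
        dense_output=False,
    )
    if not sol.success:
        raise RuntimeError(
            f"base-state integration failed at t={sol.t[-1] if sol.t.size else t0} "
            f"({sol.message}); possible finite-time blow-up"
        )
    return BaseState(t=sol.t, u_star=sol.y[:m], mu_star=np.exp(sol.y[m]))


def linearization_matrices(
    spec: KineticsSpec, law: GrowthLaw, base: BaseState, t: float
) -> LinearizationMatrices:
    """Assemble J, K = u* gradS^T, and M = J - K - S I at time t."""
    lo, hi = base.span
    if not (lo - 1e-9 <= t <= hi + 1e-9):
        raise ValueError(f"t={t} outside base-state span {base.span}")
    u = base.u_at(t)
    J = kinetics_jacobian(spec, u)
    gS = growth_gradient(law, t, u)
    S = float(evaluate_growth(law, t, u))
    K = np.outer(u, gS)
    M = J - K - S * np.eye(len(u))
    return LinearizationMatrices(J=J, K=K, gradS=gS, S=S, M=M, mu_star=base.mu_at(t))


def _criterion_sides(
    mats: LinearizationMatrices,
    mats_prev: Optional[LinearizationMatrices],
    mats_next: Optional[LinearizationMatrices],
    D: np.ndarray,
    rho: float,
    dt: float,
) -> tuple[float, float]:
    """Left and right sides of the growth criterion; derivative on the right
    by centred differences of the bracketed ratios."""
    M = mats.M
    mu2 = mats.mu_star**2
    lhs = (
        np.linalg.det(M)
        - (D[1] * M[0, 0] + D[0] * M[1, 1]) * rho / mu2
        + D[0] * D[1] * rho**2 / mu2**2
    )

    def ratios(mm: LinearizationMatrices) -> tuple[float, float]:
        m2 = mm.mu_star**2
        r12 = (
            (mm.M[0, 0] * m2 - D[0] * rho) / (mm.M[0, 1] * m2)
            if abs(mm.M[0, 1]) >= _DIAG_TOL
            else np.nan
        )
        r21 = (
            (mm.M[1, 1] * m2 - D[1] * rho) / (mm.M[1, 0] * m2)
            if abs(mm.M[1, 0]) >= _DIAG_TOL
            else np.nan
        )
        return r12, r21

    if mats_prev is None or mats_next is None:
        d12 = d21 = 0.0  # constant-coefficient caller
    else:
        a12, a21 = ratios(mats_prev)
        b12, b21 = ratios(mats_next)
        d12 = (b12 - a12) / (2 * dt)
        d21 = (b21 - a21) / (2 * dt)
    branches = []
    if abs(M[0, 1]) >= _DIAG_TOL and np.isfinite(d12):
        branches.append(M[0, 1] * d12)
    if abs(M[1, 0]) >= _DIAG_TOL and np.isfinite(d21):
        branches.append(M[1, 0] * d21)
    # if both branches are ill-defined at the neighbouring times, fall back
    # to the constant-coefficient form (zero right-hand side)
    rhs = max(branches) if branches else 0.0
    return float(lhs), float(rhs)


def theorem1_flag(
    spec: KineticsSpec,
    law: GrowthLaw,
    base: BaseState,
    D: Sequence[float],
    mode: ModeSpec,
    t: float,
    fd_dt: float = _FD_DT,
) -> Optional[bool]:
    """Exponential-growth flag for mode k at time t.

    Returns True/False, or None when M is (numerically) diagonal, in which
    case the criterion's hypothesis fails and no verdict is given.
    """
    D = np.asarray(D, dtype=float)
    if len(D) != 2:
        raise ValueError("criterion is stated for two-species systems")
    mats = linearization_matrices(spec, law, base, t)
    if mats.is_diagonal:
        return None
    lo, hi = base.span
    tp, tn = max(lo, t - fd_dt), min(hi, t + fd_dt)
    mats_prev = linearization_matrices(spec, law, base, tp)
    mats_next = linearization_matrices(spec, law, base, tn)
    lhs, rhs = _criterion_sides(
        mats, mats_prev, mats_next, D, mode.rho, (tn - tp) / 2.0
    )
    return bool(lhs < rhs)


def unstable_modes(
    spec: KineticsSpec,
    law: GrowthLaw,
    D: Sequence[float],
    L: float,
    k_max: int,
    t_grid: np.ndarray,
    base: Optional[BaseState] = None,
) -> ModeStabilityReport:
    """Per-mode instability intervals over a time grid."""
    if k_max < 0:
        raise ValueError("k_max must be nonnegative")
    t_grid = np.asarray(t_grid, dtype=float)
    if base is None:
        base = integrate_base_state(spec, law, (float(t_grid[0]), float(t_grid[-1])))
    flags = np.zeros((k_max + 1, t_grid.size))
    for k in range(k_max + 1):
        mode = ModeSpec(k, L)
        for i, t in enumerate(t_grid):
            flag = theorem1_flag(spec, law, base, D, mode, float(t))
            flags[k, i] = np.nan if flag is None else float(flag)
    intervals: dict[int, list[tuple[float, float]]] = {}
    for k in range(k_max + 1):
        ivals = []
        start = None
        for i, t in enumerate(t_grid):
            on = flags[k, i] == 1.0
            if on and start is None:
                start = t
            if not on and start is not None:
                ivals.append((float(start), float(t_grid[i - 1])))
                start = None
        if start is not None:
            ivals.append((float(start), float(t_grid[-1])))
        intervals[k] = ivals
    return ModeStabilityReport(L=L, t_grid=t_grid, flags=flags, intervals=intervals)


def integrate_mode_amplitudes(
    spec: KineticsSpec,
    law: GrowthLaw,
    base: BaseState,
    D: Sequence[float],
    mode: ModeSpec,
    t_span: tuple[float, float],
    V0: Sequence[float],
    rtol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Directly integrate dV/dt = -rho mu*^-2 D V + M(t) V; returns (t, V)."""
    V0 = np.asarray(V0, dtype=float)
    if not np.any(V0):
        raise ValueError("V0 must be nonzero")
    D = np.asarray(D, dtype=float)
    rho = mode.rho

    def rhs(t, V):
        mats = linearization_matrices(spec, law, base, t)
        A = mats.M - np.diag(rho / mats.mu_star**2 * D)
        return A @ V

    sol = solve_ivp(rhs, t_span, V0, method="LSODA", rtol=rtol, atol=rtol * 1e-2)
    if not sol.success:
        raise RuntimeError(f"mode-amplitude integration failed: {sol.message}")
    return sol.t, sol.y
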