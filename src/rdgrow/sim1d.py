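"""Closed 1D Lagrangian solver for reaction-diffusion on a self-evolving interval.

The concentrations u(t, X) and the local dilation factor mu(t, X) are evolved
on a fixed reference grid X in [0, L]; the physical (Eulerian) positions are
recovered by integrating mu. Long runs are split into epochs: whenever the
mesh degrades the current Eulerian domain is adopted as a fresh reference
grid, mu is reset to one and the fields are interpolated across.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.integrate import cumulative_trapezoid, solve_ivp
from scipy.interpolate import CubicSpline, PchipInterpolator, interp1d
from scipy.signal import find_peaks

from rdgrow.kinetics import (
    GrowthLaw,
    KineticsSpec,
    evaluate_growth,
    evaluate_kinetics,
    find_equilibria,
)

__all__ = [
    "LagrangianState1D",
    "EpochSchedule",
    "InitialConditionSpec",
    "SimResult1D",
    "Sim1DConfig",
    "discretize_diffusion",
    "rhs_1d",
    "advance_epoch",
    "remesh",
    "eulerian_positions",
    "run_simulation_1d",
    "count_peaks",
    "classify_long_time_behaviour",
    "initial_state",
]

# classifier constants (exposed through classify_long_time_behaviour arguments)
SLOPE_THRESHOLD = 1e-4  # |d log L / dt| below this counts as "fixed"
OSCILLATION_AMPLITUDE = 0.01  # relative amplitude about the windowed trend


@dataclass
class LagrangianState1D:
    """Grid, fields and dilation factor at one instant.

    X is the (uniform, strictly increasing) Lagrangian grid; u has shape
    (m, N); mu is positive everywhere.
    """

    X: np.ndarray
    u: np.ndarray
    mu: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.u = np.atleast_2d(np.asarray(self.u, dtype=float))
        self.mu = np.asarray(self.mu, dtype=float)
        if self.X.ndim != 1 or self.X.size < 3:
            raise ValueError("grid must be 1D with at least 3 nodes")
        if np.any(np.diff(self.X) <= 0):
            raise ValueError("grid must be strictly increasing")
        if self.u.shape[1] != self.X.size or self.mu.shape != self.X.shape:
            raise ValueError("field shapes inconsistent with grid")
        if np.any(self.mu <= 0):
            raise ValueError("mu must be positive everywhere")

    @property
    def n_species(self) -> int:
        return self.u.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.X.size

    @property
    def length(self) -> float:
        return float(np.trapezoid(self.mu, self.X))

    def copy(self) -> "LagrangianState1D":
        return LagrangianState1D(self.X.copy(), self.u.copy(), self.mu.copy(), self.t)


@dataclass(frozen=True)
class EpochSchedule:
    """When to remesh: at a fixed epoch length, when max(mu)/min(mu) exceeds
    ``trigger_ratio``, or whichever comes first (the default hybrid)."""

    epoch_length: Optional[float] = None
    trigger_ratio: float = 2.0
    interpolation: str = "pchip"

    def __post_init__(self) -> None:
        if self.epoch_length is not None and self.epoch_length <= 0:
            raise ValueError("epoch_length must be positive")
        if self.trigger_ratio <= 1:
            raise ValueError("trigger_ratio must exceed 1")
        if self.interpolation not in ("pchip", "cubic", "linear"):
            raise ValueError(f"unknown interpolation {self.interpolation!r}")


@dataclass(frozen=True)
class InitialConditionSpec:
    """Seeded initial concentration fields.

    noisy_equilibrium: u_j(0, X) = u*_j (1 + eta_j(X)) with iid Gaussian
    noise of the given variance (counter-based Philox stream, so a fixed
    seed is bit-reproducible).
    tanh_front: u(0, x) = (1 + tanh(L/5 - x)) / 2 (scalar kinetics).
    custom: ``profile(X) -> (m, N)`` array.
    """

    mode: str = "noisy_equilibrium"
    noise_variance: float = 1e-2
    seed: int = 0
    profile: Optional[Callable] = None

    def __post_init__(self) -> None:
        if self.mode not in ("noisy_equilibrium", "tanh_front", "custom"):
            raise ValueError(f"unknown IC mode {self.mode!r}")
        if self.noise_variance < 0:
            raise ValueError("noise variance must be nonnegative")
        if self.mode == "custom" and self.profile is None:
            raise ValueError("custom IC requires a profile callable")


@dataclass
class SimResult1D:
    snapshot_times: list
    snapshots: list  # dicts with keys t, X, x, u, mu
    t_series: np.ndarray
    L_series: np.ndarray
    config_hash: str = ""
    seed: Optional[int] = None

    def peak_counts(self, species: int = 0, prominence: float = 0.1) -> np.ndarray:
        return np.array(
            [count_peaks(s["u"][species], prominence) for s in self.snapshots]
        )


@dataclass
class Sim1DConfig:
    kinetics: KineticsSpec
    growth: GrowthLaw
    D: Sequence[float]
    L: float
    n_nodes: int = 400
    t_final: float = 100.0
    ic: InitialConditionSpec = field(default_factory=InitialConditionSpec)
    epochs: EpochSchedule = field(default_factory=EpochSchedule)
    snapshot_times: Optional[Sequence[float]] = None
    n_snapshots: int = 21
    record_dt: Optional[float] = None
    rtol: float = 1e-11
    atol: float = 1e-11
    method: str = "BDF"
    # optional stopping rules on the Eulerian length (used by presets where
    # the horizon is phrased as "grow to length ...")
    stop_length_max: Optional[float] = None
    stop_length_min: Optional[float] = None
    midpoint_anchor: bool = False


# ----------------------------------------------------------------------------
# spatial operators


def _reflect(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Neighbour arrays with ghost-node reflection (a[-1] = a[1] etc.)."""
    plus = np.empty_like(arr)
    minus = np.empty_like(arr)
    plus[:-1] = arr[1:]
    plus[-1] = arr[-2]
    minus[1:] = arr[:-1]
    minus[0] = arr[1]
    return plus, minus


def _diffusion_stencil(u: np.ndarray, mu: np.ndarray, dX: float) -> np.ndarray:
    """(1/mu) d/dX((1/mu) du/dX) for each row of u, ghost-reflected ends."""
    mu_p, mu_m = _reflect(mu)
    inv, inv_p, inv_m = 1.0 / mu, 1.0 / mu_p, 1.0 / mu_m
    out = np.empty_like(u)
    for s in range(u.shape[0]):
        us = u[s]
        up, um = _reflect(us)
        out[s] = (0.5 * inv) * (
            inv * (up + um - 2.0 * us) + inv_p * (up - us) + inv_m * (um - us)
        )
    return out / dX**2


def discretize_diffusion(state: LagrangianState1D, species: int = 0) -> np.ndarray:
    """Discrete (1/mu) d/dX((1/mu) du/dX) for one species on a uniform grid."""
    if state.n_nodes < 3:
        raise ValueError("need at least 3 nodes")
    dXs = np.diff(state.X)
    dX = dXs[0]
    if not np.allclose(dXs, dX, rtol=1e-10):
        raise ValueError("grid spacing must be uniform within an epoch")
    return _diffusion_stencil(state.u[species : species + 1], state.mu, dX)[0]


def rhs_1d(
    t: float,
    state: LagrangianState1D,
    spec: KineticsSpec,
    law: GrowthLaw,
    D: Sequence[float],
) -> tuple[np.ndarray, np.ndarray]:
    """Time derivatives (du, dmu) of the Lagrangian fields."""
    dX = state.X[1] - state.X[0]
    du, dmu = _rhs_arrays(t, state.u, state.mu, dX, spec, law, np.asarray(D, float))
    if not (np.all(np.isfinite(du)) and np.all(np.isfinite(dmu))):
        raise FloatingPointError(
            f"non-finite derivative at t={t:.6g} (max |u|={np.max(np.abs(state.u)):.3g})"
        )
    return du, dmu


def _rhs_arrays(t, u, mu, dX, spec, law, D):
    S = evaluate_growth(law, t, u)
    f = evaluate_kinetics(spec, u)
    diff = _diffusion_stencil(u, mu, dX)
    du = D[:, None] * diff - u * S + f
    dmu = mu * S
    return du, dmu


def _jac_sparsity(m: int, N: int) -> sparse.spmatrix:
    T = sparse.diags_array([np.ones(N - 1), np.ones(N), np.ones(N - 1)], offsets=(-1, 0, 1))
    I = sparse.eye_array(N)
    blocks = []
    for s in range(m):
        row = [T if sp == s else I for sp in range(m)]
        row.append(T)  # coupling to mu through the metric
        blocks.append(row)
    blocks.append([I] * m + [I])
    return sparse.bmat(blocks, format="csr")


# ----------------------------------------------------------------------------
# time integration


def advance_epoch(
    state: LagrangianState1D,
    spec: KineticsSpec,
    law: GrowthLaw,
    D: Sequence[float],
    until: float,
    rtol: float = 1e-11,
    atol: float = 1e-11,
    method: str = "BDF",
    trigger_ratio: Optional[float] = None,
    t_eval: Optional[Sequence[float]] = None,
    on_sample: Optional[Callable] = None,
) -> LagrangianState1D:
    """Advance the state to ``until`` (or until the remesh trigger fires).

    ``on_sample(t, u, mu)`` is invoked at each ``t_eval`` point reached; the
    returned state carries the actual final time (< ``until`` if the
    trigger terminated the solve early).
    """
    if until <= state.t:
        raise ValueError(f"'until'={until} must exceed current time {state.t}")
    m, N = state.u.shape
    dX = state.X[1] - state.X[0]
    D = np.asarray(D, dtype=float)

    def fun(t, y):
        u = y[: m * N].reshape(m, N)
        mu = y[m * N :]
        du, dmu = _rhs_arrays(t, u, mu, dX, spec, law, D)
        return np.concatenate([du.ravel(), dmu])

    events = None
    if trigger_ratio is not None:

        def trigger(t, y):
            mu = y[m * N :]
            return np.max(mu) / max(np.min(mu), 1e-300) - trigger_ratio

        trigger.terminal = True
        trigger.direction = 1
        events = [trigger]

    y0 = np.concatenate([state.u.ravel(), state.mu])
    kwargs = {}
    if method in ("BDF", "Radau"):
        kwargs["jac_sparsity"] = _jac_sparsity(m, N)
    elif method == "LSODA":
        kwargs["lband"] = kwargs["uband"] = (m + 1) * N  # dense fallback
    te = None
    if t_eval is not None:
        te = np.asarray([t for t in t_eval if state.t < t <= until], dtype=float)
        if te.size == 0:
            te = None
    sol = solve_ivp(
        fun,
        (state.t, until),
        y0,
        method=method,
        rtol=rtol,
        atol=atol,
        t_eval=te,
        events=events,
        dense_output=te is not None and events is not None,
        **kwargs,
    )
    if not sol.success:
        raise RuntimeError(
            f"integrator failed at t={sol.t[-1] if sol.t.size else state.t}: {sol.message}"
        )
    if sol.status == 1:  # trigger fired
        t_end = float(sol.t_events[0][0])
        y_end = sol.y_events[0][0]
    else:
        t_end = until if te is None else float(sol.t[-1])
        y_end = sol.y[:, -1] if sol.y.size else sol.sol(t_end)
    if on_sample is not None and te is not None:
        for i, ti in enumerate(sol.t):
            if ti <= t_end + 1e-12 and ti > state.t:
                yi = sol.y[:, i]
                on_sample(float(ti), yi[: m * N].reshape(m, N), yi[m * N :])
    u_end = y_end[: m * N].reshape(m, N)
    mu_end = y_end[m * N :]
    if not np.all(np.isfinite(y_end)):
        raise FloatingPointError(f"non-finite state at t={t_end}")
    return LagrangianState1D(state.X.copy(), u_end, mu_end, t_end)


def eulerian_positions(state: LagrangianState1D) -> np.ndarray:
    """Material positions x(t, X) = int_0^X mu dy with x(t, 0) = 0."""
    if np.any(state.mu <= 0):
        raise ValueError("mu must be positive to define the Eulerian map")
    x = cumulative_trapezoid(state.mu, state.X, initial=0.0)
    if np.any(np.diff(x) <= 0):
        raise RuntimeError("Eulerian map is not strictly increasing")
    return x


def remesh(
    state: LagrangianState1D, schedule: EpochSchedule = EpochSchedule()
) -> LagrangianState1D:
    """Adopt the current Eulerian domain as the new reference grid.

    The new grid is uniform on [0, L(t)], mu is reset to one and the fields
    are interpolated in the Eulerian coordinate. Total length is preserved
    exactly; mass to interpolation accuracy.
    """
    x = eulerian_positions(state)
    L = x[-1]
    X_new = np.linspace(0.0, L, state.n_nodes)
    u_new = np.empty_like(state.u)
    for s in range(state.n_species):
        if schedule.interpolation == "pchip":
            u_new[s] = PchipInterpolator(x, state.u[s])(X_new)
        elif schedule.interpolation == "cubic":
            u_new[s] = CubicSpline(x, state.u[s])(X_new)
        else:
            u_new[s] = interp1d(x, state.u[s])(X_new)
    return LagrangianState1D(X_new, u_new, np.ones_like(X_new), state.t)


# ----------------------------------------------------------------------------
# initial conditions


def initial_state(
    config: "Sim1DConfig",
) -> LagrangianState1D:
    """Build the seeded t=0 state for a configuration."""
    X = np.linspace(0.0, config.L, config.n_nodes)
    ic = config.ic
    m = config.kinetics.n_species
    if ic.mode == "noisy_equilibrium":
        eqs = find_equilibria(config.kinetics)
        if m == 2:
            candidates = [e for e in eqs if np.all(np.isreal(e.u_star))]
            if len(candidates) > 1:
                # prefer a positive equilibrium (activator-inhibitor systems)
                pos = [e for e in candidates if np.all(e.u_star > 0)]
                candidates = pos or candidates
            u_star = candidates[0].u_star
        else:
            u_star = eqs[-1].u_star  # nontrivial root
        rng = np.random.Generator(np.random.Philox(ic.seed))
        eta = rng.normal(0.0, np.sqrt(ic.noise_variance), size=(m, X.size))
        u0 = u_star[:, None] * (1.0 + eta)
    elif ic.mode == "tanh_front":
        if m != 1:
            raise ValueError("tanh_front IC is defined for scalar kinetics")
        u0 = ((1.0 + np.tanh(config.L / 5.0 - X)) / 2.0)[None, :]
    else:
        u0 = np.atleast_2d(np.asarray(ic.profile(X), dtype=float))
    return LagrangianState1D(X, u0, np.ones_like(X), 0.0)


# ----------------------------------------------------------------------------
# full runs


def _config_hash(config: Sim1DConfig) -> str:
    text = repr(config).encode()
    return hashlib.sha256(text).hexdigest()[:16]


def run_simulation_1d(config: Sim1DConfig) -> SimResult1D:
    """Epoch loop: integrate, remesh, record snapshots and the length series."""
    state = initial_state(config)
    t_final = config.t_final
    if config.snapshot_times is not None:
        snap_times = sorted(t for t in config.snapshot_times if 0.0 <= t <= t_final)
    else:
        snap_times = list(np.linspace(0.0, t_final, config.n_snapshots))
    record_dt = config.record_dt or t_final / 400.0

    t_rec = [0.0]
    L_rec = [state.length]
    snapshots = []
    snap_recorded = []

    def take_snapshot(st: LagrangianState1D) -> None:
        snapshots.append(
            {
                "t": st.t,
                "X": st.X.copy(),
                "x": eulerian_positions(st),
                "u": st.u.copy(),
                "mu": st.mu.copy(),
            }
        )
        snap_recorded.append(st.t)

    if snap_times and snap_times[0] <= 0.0:
        take_snapshot(state)
        snap_times = [t for t in snap_times if t > 0.0]

    sched = config.epochs
    stopped = False
    last_remesh_t = 0.0
    while state.t < t_final - 1e-12 and not stopped:
        stops = [t_final]
        if sched.epoch_length is not None:
            stops.append(last_remesh_t + sched.epoch_length)
        pending = [t for t in snap_times if t > state.t + 1e-12]
        if pending:
            stops.append(pending[0])
        until = min(stops)

        n_samp = max(2, int(np.ceil((until - state.t) / record_dt)) + 1)
        t_eval = np.linspace(state.t, until, n_samp)[1:]

        def record(t, u, mu):
            t_rec.append(t)
            L_rec.append(float(np.trapezoid(mu, state.X)))

        state = advance_epoch(
            state,
            config.kinetics,
            config.growth,
            config.D,
            until,
            rtol=config.rtol,
            atol=config.atol,
            method=config.method,
            trigger_ratio=sched.trigger_ratio,
            t_eval=t_eval,
            on_sample=record,
        )
        if t_rec[-1] < state.t - 1e-12:
            t_rec.append(state.t)
            L_rec.append(state.length)
        reached_stop = state.t >= until - 1e-9
        if reached_stop and pending and abs(state.t - pending[0]) < 1e-9:
            take_snapshot(state)
        L_now = L_rec[-1]
        if config.stop_length_max is not None and L_now >= config.stop_length_max:
            stopped = True
        if config.stop_length_min is not None and L_now <= config.stop_length_min:
            stopped = True
        if state.t < t_final - 1e-12 and not stopped:
            ratio = np.max(state.mu) / np.min(state.mu)
            epoch_done = (
                sched.epoch_length is not None
                and state.t >= last_remesh_t + sched.epoch_length - 1e-9
            )
            if not reached_stop or ratio >= sched.trigger_ratio or epoch_done:
                state = remesh(state, sched)
                last_remesh_t = state.t

    if not snapshots or abs(snap_recorded[-1] - state.t) > 1e-9:
        take_snapshot(state)

    return SimResult1D(
        snapshot_times=snap_recorded,
        snapshots=snapshots,
        t_series=np.asarray(t_rec),
        L_series=np.asarray(L_rec),
        config_hash=_config_hash(config),
        seed=config.ic.seed,
    )


# ----------------------------------------------------------------------------
# diagnostics


def count_peaks(
    profile: np.ndarray,
    prominence: float = 0.1,
    include_boundary: bool = False,
) -> int:
    """Number of local maxima whose prominence exceeds ``prominence`` times
    the field range. Boundary extrema are excluded by default."""
    profile = np.asarray(profile, dtype=float)
    if profile.size < 3:
        raise ValueError("profile must have at least 3 samples")
    rng = float(np.ptp(profile))
    if rng == 0.0:
        return 0
    if include_boundary:
        pad = float(np.min(profile)) - rng
        profile = np.concatenate([[pad], profile, [pad]])
    peaks, _ = find_peaks(profile, prominence=prominence * rng)
    return int(len(peaks))


def classify_long_time_behaviour(
    t: np.ndarray,
    L: np.ndarray,
    window: float,
    slope_threshold: float = SLOPE_THRESHOLD,
    oscillation_amplitude: float = OSCILLATION_AMPLITUDE,
) -> str:
    """Operational classification of the domain-length trend.

    The trend of log L is fitted over the final window and the one before
    it; a relative residual amplitude above ``oscillation_amplitude``
    flags oscillation. Disagreement between the two windows (ignoring
    oscillation flags) yields "undetermined".
    """
    t = np.asarray(t, dtype=float)
    L = np.asarray(L, dtype=float)
    if t[-1] - t[0] < 2 * window:
        raise ValueError("series must span at least two windows")

    def window_class(t0, t1):
        mask = (t >= t0) & (t <= t1)
        tt, ll = t[mask], np.log(L[mask])
        if tt.size < 4:
            raise ValueError("too few samples in window")
        slope, intercept = np.polyfit(tt, ll, 1)
        resid = ll - (slope * tt + intercept)
        amp = float(np.ptp(resid)) / 2.0
        osc = amp > oscillation_amplitude
        # an oscillation-dominated window (trend drift smaller than the
        # residual amplitude) is not a genuine trend
        if osc and abs(slope) * window <= amp:
            return "oscillating"
        if slope > slope_threshold:
            return "growing"
        if slope < -slope_threshold:
            return "shrinking"
        return "oscillating" if osc else "fixed"

    c2 = window_class(t[-1] - window, t[-1])
    c1 = window_class(t[-1] - 2 * window, t[-1] - window)
    steady = ("fixed", "oscillating")
    if c1 in steady and c2 in steady:
        return c2
    if c1 != c2:
        return "undetermined"
    return c2
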