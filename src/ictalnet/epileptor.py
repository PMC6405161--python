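"""Network of 2D Epileptors with permittivity coupling.

Each brain region is a two-variable reduction of the Epileptor neural mass
model: a fast variable ``x`` (bistable between a healthy node and ictal
oscillation) and a slow permittivity variable ``z`` evolving on a timescale
``tau >> 1``. Regions are coupled through a linear difference term
``sum_j K_ij (x_j - x_i)`` acting on the slow variable:

    dx_i/dt = -x_i^3 - 2 x_i^2 + 1 - z_i + I
    dz_i/dt = (1/tau) [ 4 (x_i - x0_i) - z_i - sum_j K_ij (x_j - x_i) ]

``x0_i`` is the degree of epileptogenicity of region i: above the critical
value ``x_c`` the region's fixed point is unstable and it seizes
autonomously (it belongs to the epileptogenic zone, EZ); below, the region
is at a stable equilibrium and can only seize by recruitment through the
coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq
from scipy.signal import butter, sosfiltfilt

from .connectome import Connectome
from .errors import ConvergenceError, SimulationError, ValidationError

#: default excitability of epileptogenic-zone nodes
X0_EZ_DEFAULT = -1.6
#: default excitability of healthy nodes
X0_HEALTHY_DEFAULT = -2.2


@dataclass(frozen=True)
class ModelParams:
    """Global Epileptor parameters.

    tau : timescale separation between x and z (dimensionless, default 2857)
    I_ext : passive current setting the operating point (default 3.1)
    x_c : critical excitability separating epileptogenic from healthy
        regions (default -2.1; the analytic single-node threshold at
        I = 3.1 is ~ -2.062, x_c is the conventional labelling constant)
    """

    tau: float = 2857.0
    I_ext: float = 3.1
    x_c: float = -2.1

    def __post_init__(self) -> None:
        if not (self.tau > 1):
            raise ValidationError(f"tau must exceed 1, got {self.tau}")
        if not np.isfinite(self.I_ext):
            raise ValidationError("I_ext must be finite")


@dataclass(frozen=True)
class ExcitabilityMap:
    """Per-node excitability values and the EZ membership they imply."""

    x0: np.ndarray
    x_c: float = -2.1

    def __post_init__(self) -> None:
        x0 = np.array(self.x0, dtype=float)
        if x0.ndim != 1:
            raise ValidationError("x0 must be a vector")
        if not np.all(np.isfinite(x0)):
            raise ValidationError("x0 must be finite")
        x0.setflags(write=False)
        object.__setattr__(self, "x0", x0)

    @classmethod
    def from_ez(
        cls,
        n: int,
        ez: Iterable[int],
        x0_ez: float = X0_EZ_DEFAULT,
        x0_healthy: float = X0_HEALTHY_DEFAULT,
        x_c: float = -2.1,
    ) -> "ExcitabilityMap":
        """Two-level assignment: EZ nodes at ``x0_ez``, the rest healthy."""
        ez = list(ez)
        if any(not 0 <= i < n for i in ez):
            raise ValidationError(f"EZ indices {ez} out of range for N={n}")
        x0 = np.full(n, x0_healthy, dtype=float)
        x0[ez] = x0_ez
        return cls(x0, x_c=x_c)

    @property
    def n(self) -> int:
        return self.x0.shape[0]

    @property
    def ez(self) -> frozenset[int]:
        """Nodes whose excitability exceeds the critical value."""
        return frozenset(int(i) for i in np.flatnonzero(self.x0 > self.x_c))


@dataclass(frozen=True)
class FixedPoint:
    """Steady state of the coupled system with solver diagnostics."""

    x_bar: np.ndarray
    z_bar: np.ndarray
    residual_norm: float
    converged: bool
    iterations: int


@dataclass(frozen=True)
class Trajectory:
    """Sampled deterministic trajectory: times, x(t) and z(t) per node."""

    t: np.ndarray
    x: np.ndarray  # (times, N)
    z: np.ndarray  # (times, N)
    terminated_early: bool = False

    @property
    def n(self) -> int:
        return self.x.shape[1]

    @property
    def horizon(self) -> float:
        return float(self.t[-1])


class SeizureEvent(NamedTuple):
    node: int
    onset: float
    offset: float


@dataclass(frozen=True)
class SeizureRaster:
    """Per-node seizure onset/offset events, sorted by onset."""

    events: tuple[SeizureEvent, ...]
    horizon: float

    def nodes_with_events(self) -> frozenset[int]:
        return frozenset(e.node for e in self.events)


class Recruitment(NamedTuple):
    """Non-EZ nodes that seized, with their order of first onset."""

    nodes: frozenset[int]
    onset_order: tuple[int, ...]


# ---------------------------------------------------------------------------
# fixed points


def uncoupled_fixed_point(
    x0: float | np.ndarray, params: ModelParams = ModelParams()
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed point of an isolated node (K = 0).

    Setting the derivatives to zero gives the cubic
    ``x^3 + 2 x^2 + 4 x - (1 + I + 4 x0) = 0`` whose derivative
    ``3 x^2 + 4 x + 4`` is strictly positive, so the real root is unique;
    then ``z = 4 (x - x0)``.
    """
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    c = 1.0 + params.I_ext + 4.0 * x0
    x = np.empty_like(x0)
    for k, ck in enumerate(c):
        f = lambda v: v**3 + 2.0 * v**2 + 4.0 * v - ck  # noqa: E731
        lo, hi = -1.0, 1.0
        while f(lo) > 0:
            lo *= 2.0
        while f(hi) < 0:
            hi *= 2.0
        x[k] = brentq(f, lo, hi, xtol=1e-15, rtol=8.9e-16)
    z = 4.0 * (x - x0)
    return x, z


def network_fixed_point(
    c: Connectome,
    ex: ExcitabilityMap,
    params: ModelParams = ModelParams(),
    tol: float = 1e-12,
    max_iter: int = 200,
) -> FixedPoint:
    """Steady state of the coupled network by damped Newton iteration.

    Eliminating z through the x-nullcline ``z = -x^3 - 2x^2 + 1 + I``
    leaves the per-node algebraic system

        g_i(x) = 4 (x_i - x0_i) - z_i(x_i) - sum_j K_ij (x_j - x_i) = 0.

    Its Jacobian ``diag(3 x^2 + 4 x + 4 + s_i) - K`` (s_i = row sum of K)
    is a positive-definite M-like matrix for every x, so the solution is
    unique and Newton with backtracking converges from the uncoupled roots.
    """
    if ex.n != c.n:
        raise ValidationError(f"excitability map length {ex.n} != N={c.n}")
    K = c.weights
    s = K.sum(axis=1)
    x0 = ex.x0
    I = params.I_ext

    def g(x: np.ndarray) -> np.ndarray:
        return 4.0 * (x - x0) + x**3 + 2.0 * x**2 - 1.0 - I - K @ x + s * x

    x = uncoupled_fixed_point(x0, params)[0]
    res = float(np.abs(g(x)).max())
    it = 0
    while res > tol and it < max_iter:
        J = np.diag(3.0 * x**2 + 4.0 * x + 4.0 + s) - K
        dx = np.linalg.solve(J, g(x))
        step = 1.0
        for _ in range(60):
            x_new = x - step * dx
            res_new = float(np.abs(g(x_new)).max())
            if res_new < res:
                break
            step /= 2.0
        else:
            break  # no descent direction left; report as-is
        x, res = x_new, res_new
        it += 1
    z = -(x**3) - 2.0 * x**2 + 1.0 + I
    return FixedPoint(x, z, res, converged=res <= tol, iterations=it)


# ---------------------------------------------------------------------------
# simulation


def _rhs_factory(K: np.ndarray, s: np.ndarray, x0: np.ndarray, params: ModelParams):
    tau, I = params.tau, params.I_ext
    n = x0.shape[0]

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        x = y[:n]
        z = y[n:]
        dx = -(x**3) - 2.0 * x**2 + 1.0 - z + I
        dz = (4.0 * (x - x0) - z - (K @ x - s * x)) / tau
        return np.concatenate((dx, dz))

    return rhs


def healthy_reference_state(
    c: Connectome, ex: ExcitabilityMap, params: ModelParams = ModelParams()
) -> tuple[np.ndarray, np.ndarray]:
    """Healthy-branch fixed point of the all-healthy version of the system.

    EZ entries of x0 are replaced by the healthy excitability level (the
    minimum of the map, or x_c - 0.1 when every node is epileptogenic); the
    resulting network fixed point is the canonical initial condition: from
    there, EZ nodes drift into seizure through their own z-dynamics.
    """
    x0 = ex.x0.copy()
    ez = sorted(ex.ez)
    healthy_level = (
        float(np.delete(x0, ez).min()) if len(ez) < ex.n else ex.x_c - 0.1
    )
    x0[ez] = healthy_level
    fp = network_fixed_point(c, ExcitabilityMap(x0, ex.x_c), params)
    if not fp.converged:
        raise ConvergenceError(
            f"all-healthy reference fixed point did not converge "
            f"(residual {fp.residual_norm:.3g})"
        )
    return fp.x_bar.copy(), fp.z_bar.copy()


def simulate(
    c: Connectome,
    ex: ExcitabilityMap,
    params: ModelParams = ModelParams(),
    init: tuple[np.ndarray, np.ndarray] | None = None,
    horizon: float | None = None,
    dt_out: float = 1.0,
    method: str = "lsoda",
    rtol: float = 1e-8,
    atol: float = 1e-8,
    stop_on_seizure_outside: Iterable[int] | None = None,
    theta_on: float = 0.0,
    grace: float = 25.0,
) -> Trajectory:
    """Integrate the autonomous network deterministically.

    Parameters
    ----------
    init
        (x, z) arrays, or None for the healthy-branch fixed point of the
        all-healthy system.
    horizon
        Simulated duration (default ``10 * tau``, several seizure cycles).
    method
        "lsoda" (adaptive, stiff-capable; default) or "rk4" (fixed-step
        dt = 0.05 cross-check integrator).
    stop_on_seizure_outside
        If given (a set of nodes, typically the EZ), integration stops as
        soon as any node *outside* that set crosses ``theta_on`` upward --
        the earliest recruitment -- plus a short grace window so the event
        is resolvable in the sampled output. Used by containment tests.
    """
    if ex.n != c.n:
        raise ValidationError(f"excitability map length {ex.n} != N={c.n}")
    if horizon is None:
        horizon = 10.0 * params.tau
    if horizon <= 0:
        raise ValidationError("horizon must be positive")
    n = c.n
    K = c.weights
    s = K.sum(axis=1)
    rhs = _rhs_factory(K, s, ex.x0, params)
    if init is None:
        x_init, z_init = healthy_reference_state(c, ex, params)
    else:
        x_init, z_init = (np.asarray(a, dtype=float) for a in init)
    y0 = np.concatenate((x_init, z_init))

    if method == "rk4":
        return _simulate_rk4(rhs, y0, n, horizon, dt_out)
    if method != "lsoda":
        raise ValidationError(f"unknown integration method {method!r}")

    events = None
    watched: np.ndarray | None = None
    if stop_on_seizure_outside is not None:
        inside = set(int(i) for i in stop_on_seizure_outside)
        watched = np.array([i for i in range(n) if i not in inside], dtype=int)
        if watched.size:

            def recruit_event(t, y, w=watched):
                return float(np.max(y[w]) - theta_on)

            recruit_event.terminal = True
            recruit_event.direction = 1.0
            events = [recruit_event]

    t_eval = np.arange(0.0, horizon + 0.5 * dt_out, dt_out)
    t_eval[-1] = min(t_eval[-1], horizon)
    sol = solve_ivp(
        rhs,
        (0.0, horizon),
        y0,
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
        events=events,
        dense_output=False,
    )
    if not sol.success and sol.status != 1:
        raise SimulationError(
            f"integration failed at t={sol.t[-1] if sol.t.size else 0.0}: {sol.message}"
        )
    t, y = sol.t, sol.y
    terminated = sol.status == 1
    if terminated:
        # continue briefly past the recruitment so the raster records it
        t_ev = float(sol.t_events[0][0])
        y_ev = sol.y_events[0][0]
        t_extra = min(horizon, t_ev + grace)
        if t_extra > t_ev:
            t_eval2 = np.linspace(t_ev, t_extra, max(int(grace / dt_out), 8))
            sol2 = solve_ivp(
                rhs, (t_ev, t_extra), y_ev, method="LSODA",
                t_eval=t_eval2, rtol=rtol, atol=atol,
            )
            if sol2.success:
                t = np.concatenate((t, sol2.t))
                y = np.concatenate((y, sol2.y), axis=1)
    if not np.all(np.isfinite(y)):
        raise SimulationError(f"non-finite state encountered by t={t[-1]}")
    return Trajectory(t, y[:n].T.copy(), y[n:].T.copy(), terminated_early=terminated)


def _simulate_rk4(rhs, y0: np.ndarray, n: int, horizon: float, dt_out: float) -> Trajectory:
    dt = 0.05
    n_steps = int(np.ceil(horizon / dt))
    stride = max(int(round(dt_out / dt)), 1)
    y = y0.copy()
    ts = [0.0]
    ys = [y.copy()]
    t = 0.0
    for k in range(1, n_steps + 1):
        h = min(dt, horizon - t)
        k1 = rhs(t, y)
        k2 = rhs(t + h / 2, y + h / 2 * k1)
        k3 = rhs(t + h / 2, y + h / 2 * k2)
        k4 = rhs(t + h, y + h * k3)
        y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += h
        if k % stride == 0 or t >= horizon:
            if not np.all(np.isfinite(y)):
                raise SimulationError(f"non-finite state at t={t}")
            ts.append(t)
            ys.append(y.copy())
    arr = np.array(ys)
    return Trajectory(np.array(ts), arr[:, :n], arr[:, n:])


# ---------------------------------------------------------------------------
# event extraction


def detect_seizure_events(
    traj: Trajectory,
    theta_on: float = 0.0,
    theta_off: float = -1.0,
    min_duration: float = 5.0,
) -> SeizureRaster:
    """Threshold-crossing seizure events per node.

    An event opens at an upward crossing of ``theta_on`` and closes at the
    subsequent downward crossing of ``theta_off`` (hysteresis: the healthy
    fixed point sits below x = -4/3 while ictal oscillation visits x > 0,
    so the two thresholds separate the states unambiguously). Events still
    open at the end of the trajectory close at the final time; events
    shorter than ``min_duration`` are discarded.
    """
    if theta_off >= theta_on:
        raise ValidationError("theta_off must be below theta_on")
    t = traj.t
    events: list[SeizureEvent] = []
    for node in range(traj.n):
        x = traj.x[:, node]
        onset: float | None = None
        if x[0] > theta_on:
            onset = float(t[0])
        for k in range(1, t.size):
            if onset is None and x[k - 1] <= theta_on < x[k]:
                frac = (theta_on - x[k - 1]) / (x[k] - x[k - 1])
                onset = float(t[k - 1] + frac * (t[k] - t[k - 1]))
            elif onset is not None and x[k - 1] >= theta_off > x[k]:
                frac = (theta_off - x[k - 1]) / (x[k] - x[k - 1])
                offset = float(t[k - 1] + frac * (t[k] - t[k - 1]))
                if offset - onset >= min_duration:
                    events.append(SeizureEvent(node, onset, offset))
                onset = None
        if onset is not None and float(t[-1]) - onset >= min_duration:
            events.append(SeizureEvent(node, onset, float(t[-1])))
    events.sort(key=lambda e: (e.onset, e.node))
    return SeizureRaster(tuple(events), horizon=float(t[-1]))


def recruited_set(raster: SeizureRaster, ez: Iterable[int]) -> Recruitment:
    """Non-EZ nodes with at least one seizure event, in order of first onset."""
    ez = set(int(i) for i in ez)
    first_onset: dict[int, float] = {}
    for e in raster.events:
        if e.node not in ez and e.node not in first_onset:
            first_onset[e.node] = e.onset
    order = tuple(sorted(first_onset, key=lambda i: (first_onset[i], i)))
    return Recruitment(frozenset(order), order)


def write_raster_tsv(raster: SeizureRaster, labels: Sequence[str], path) -> None:
    lines = ["node\tlabel\tonset\toffset"]
    for e in raster.events:
        lines.append(f"{e.node}\t{labels[e.node]}\t{e.onset:.6g}\t{e.offset:.6g}")
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")


def write_trajectory_tsv(traj: Trajectory, labels: Sequence[str], path) -> None:
    from pathlib import Path

    header = (
        "time\t"
        + "\t".join(f"x:{lab}" for lab in labels)
        + "\t"
        + "\t".join(f"z:{lab}" for lab in labels)
    )
    rows = [header]
    for k in range(traj.t.size):
        vals = np.concatenate(([traj.t[k]], traj.x[k], traj.z[k]))
        rows.append("\t".join(f"{v:.10g}" for v in vals))
    Path(path).write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# clinical signal-energy PZ criterion


def pz_from_signal_energy(
    signals: np.ndarray,
    fs: float,
    ez_channels: Iterable[int],
) -> frozenset[int]:
    """Propagation-zone channels by the 30%-of-maximum signal-energy rule.

    Signals are band-pass filtered 1-50 Hz (Butterworth order 4, applied
    forward-backward for zero phase); channel energy is the sum of squared
    filtered samples. Channels whose energy reaches at least 30% of the
    maximum over all channels, and which are not EZ channels, form the PZ.
    """
    signals = np.asarray(signals, dtype=float)
    if signals.ndim != 2 or signals.shape[0] < 1 or signals.shape[1] < 1:
        raise ValidationError("signals must be a non-empty channels x samples array")
    if fs <= 100.0:
        raise ValidationError(
            f"sampling rate {fs} Hz too low: the 50 Hz band edge must lie below Nyquist"
        )
    sos = butter(4, [1.0, 50.0], btype="bandpass", fs=fs, output="sos")
    filtered = sosfiltfilt(sos, signals, axis=1)
    energy = np.sum(filtered**2, axis=1)
    max_energy = float(energy.max())
    ez = set(int(i) for i in ez_channels)
    if max_energy == 0.0:
        return frozenset()
    keep = np.flatnonzero(energy >= 0.30 * max_energy)
    return frozenset(int(i) for i in keep if int(i) not in ez)
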