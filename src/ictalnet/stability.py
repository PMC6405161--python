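"""Linear stability analysis of the network fixed point.

The Jacobian of the coupled Epileptor network, evaluated at the steady
state, has the 2N x 2N block structure (x-block first, z-block second)

    [ diag(-3 x_i^2 - 4 x_i)        -I        ]
    [ (diag(4 + s_i) - K)/tau     -I/tau      ]

with s_i the i-th row sum of K. Eigenvalues with positive real part signal
a propagating instability; the eigenvector paired with the largest
eigenvalue localizes the preferred propagation pathways, and its largest
x-block components (in modulus) identify the predicted propagation zone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import scipy.linalg

from .connectome import Connectome
from .epileptor import ExcitabilityMap, FixedPoint, ModelParams, healthy_reference_state
from .errors import ConvergenceError, NumericalError, SimulationError, ValidationError

#: eigenvalue real parts above this count as genuinely positive (not round-off)
EPS_POS_DEFAULT = 1e-8
#: eigenvector components of a unit-norm vector above this count as localized
EPS_LOC_DEFAULT = 1e-5


@dataclass(frozen=True)
class JacobianMatrix:
    """2N x 2N Jacobian with the fixed point it was evaluated at.

    State layout: indices 0..N-1 are the x-block, N..2N-1 the z-block.
    """

    entries: np.ndarray
    fixed_point: FixedPoint

    @property
    def n(self) -> int:
        return self.entries.shape[0] // 2


@dataclass(frozen=True)
class StabilityReport:
    """Eigen-decomposition summary at a network fixed point.

    node_scores[i] is the modulus of the x-block component of the leading
    (unit-norm) eigenvector; the z-components are suppressed by O(1/tau)
    and carry no extra localization information.
    """

    eigenvalues: np.ndarray  # 2N complex, sorted by descending real part
    n_positive: int
    max_eigenvector: np.ndarray  # 2N complex, unit Euclidean norm
    node_scores: np.ndarray  # N non-negative reals

    @property
    def n(self) -> int:
        return self.node_scores.shape[0]

    @property
    def max_eigenvalue(self) -> complex:
        return complex(self.eigenvalues[0])


def build_jacobian(
    c: Connectome, fp: FixedPoint, params: ModelParams = ModelParams()
) -> JacobianMatrix:
    """Assemble the analytic Jacobian at a converged fixed point."""
    if not fp.converged:
        raise ConvergenceError(
            "refusing to build a Jacobian at an unconverged fixed point "
            f"(residual {fp.residual_norm:.3g})"
        )
    n = c.n
    x = fp.x_bar
    if x.shape[0] != n:
        raise ValidationError("fixed point size does not match connectome")
    K = c.weights
    s = K.sum(axis=1)
    tau = params.tau
    J = np.zeros((2 * n, 2 * n))
    J[:n, :n] = np.diag(-3.0 * x**2 - 4.0 * x)
    J[:n, n:] = -np.eye(n)
    J[n:, :n] = (np.diag(4.0 + s) - K) / tau
    J[n:, n:] = -np.eye(n) / tau
    return JacobianMatrix(J, fp)


def eigen_analysis(J: JacobianMatrix, eps_pos: float = EPS_POS_DEFAULT) -> StabilityReport:
    """Full eigen-decomposition, sorted by descending real part.

    The leading eigenvector is the one paired with the largest-real-part
    eigenvalue (for a complex pair either member works: node scores are
    moduli, invariant under the arbitrary complex phase).
    """
    try:
        vals, vecs = scipy.linalg.eig(J.entries)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - rare
        raise NumericalError(f"eigen-decomposition failed: {exc}") from exc
    order = np.lexsort((-vals.imag, -vals.real))
    vals = vals[order]
    vecs = vecs[:, order]
    lead = vecs[:, 0]
    lead = lead / np.linalg.norm(lead)
    n = J.n
    return StabilityReport(
        eigenvalues=vals,
        n_positive=int(np.count_nonzero(vals.real > eps_pos)),
        max_eigenvector=lead,
        node_scores=np.abs(lead[:n]),
    )


def predict_pz(
    report: StabilityReport,
    ez: Iterable[int],
    eps_loc: float = EPS_LOC_DEFAULT,
    mode: str = "absolute",
) -> list[int]:
    """Predicted propagation zone from the leading eigenvector.

    Non-EZ nodes whose score reaches the localization threshold, sorted by
    descending score. In "absolute" mode (default) the threshold is
    ``eps_loc`` applied to the unit-norm eigenvector; in "relative" mode it
    is ``eps_loc`` times the maximum non-EZ score.
    """
    ez = set(int(i) for i in ez)
    scores = report.node_scores
    non_ez = [i for i in range(report.n) if i not in ez]
    if not non_ez:
        return []
    if mode == "absolute":
        thr = eps_loc
    elif mode == "relative":
        thr = eps_loc * max(scores[i] for i in non_ez)
    else:
        raise ValidationError(f"unknown localization mode {mode!r}")
    hits = [i for i in non_ez if scores[i] >= thr]
    hits.sort(key=lambda i: (-scores[i], i))
    return hits


def max_lyapunov(
    c: Connectome,
    ex: ExcitabilityMap,
    params: ModelParams = ModelParams(),
    horizon: float | None = None,
    renorm_interval: float = 50.0,
    discard_fraction: float = 0.2,
    rtol: float = 1e-8,
    atol: float = 1e-8,
) -> tuple[float, np.ndarray]:
    """Maximum Lyapunov exponent and its x-block localization profile.

    Integrates the tangent dynamics alongside the trajectory (started from
    the healthy-branch reference state) with periodic renormalization of
    the tangent vector. The exponent is the average log growth rate after a
    transient of ``discard_fraction`` of the horizon; the profile is the
    time-averaged modulus of the normalized tangent vector's x-components.
    Along a stable fixed point this reduces to the largest real part of the
    Jacobian spectrum.
    """
    from scipy.integrate import solve_ivp

    if horizon is None:
        horizon = 10.0 * params.tau
    n = c.n
    K = c.weights
    s = K.sum(axis=1)
    x0 = ex.x0
    tau, I = params.tau, params.I_ext

    def rhs(t, y):
        x = y[:n]
        z = y[n : 2 * n]
        vx = y[2 * n : 3 * n]
        vz = y[3 * n :]
        dx = -(x**3) - 2.0 * x**2 + 1.0 - z + I
        dz = (4.0 * (x - x0) - z - (K @ x - s * x)) / tau
        dvx = (-3.0 * x**2 - 4.0 * x) * vx - vz
        dvz = ((4.0 + s) * vx - K @ vx - vz) / tau
        return np.concatenate((dx, dz, dvx, dvz))

    xs, zs = healthy_reference_state(c, ex, params)
    v = np.ones(2 * n)
    v /= np.linalg.norm(v)
    y = np.concatenate((xs, zs, v))
    t = 0.0
    t_discard = discard_fraction * horizon
    log_growth = 0.0
    t_accum = 0.0
    profile = np.zeros(n)
    n_profile = 0
    while t < horizon - 1e-9:
        t_next = min(t + renorm_interval, horizon)
        sol = solve_ivp(rhs, (t, t_next), y, method="LSODA", rtol=rtol, atol=atol)
        if not sol.success:
            raise SimulationError(f"tangent integration failed at t={t}: {sol.message}")
        y = sol.y[:, -1]
        v = y[2 * n :]
        norm = float(np.linalg.norm(v))
        if norm == 0.0 or not np.isfinite(norm):
            raise SimulationError(f"tangent vector degenerate at t={t_next}")
        if t_next > t_discard:
            log_growth += np.log(norm)
            t_accum += t_next - t
            profile += np.abs(v[:n]) / norm
            n_profile += 1
        y[2 * n :] = v / norm
        t = t_next
    exponent = log_growth / t_accum if t_accum > 0 else float("nan")
    profile = profile / max(n_profile, 1)
    return exponent, profile


def single_node_oscillation_threshold(
    params: ModelParams = ModelParams(), tol: float = 1e-10
) -> float:
    """Numerically locate the excitability at which an isolated node loses
    stability (onset of sustained seizure oscillation).

    Bisection on the sign of the largest eigenvalue real part of the
    single-node Jacobian at the fixed point. The analytic limit for
    tau -> infinity is x0* = -4/3 + ((-4/3)^3 + 2 (-4/3)^2 - (1 + I))/4;
    the finite-tau correction is O(1/tau).
    """
    from .connectome import Connectome as _C
    from .epileptor import ExcitabilityMap as _Ex
    from .epileptor import network_fixed_point

    c1 = _C(np.zeros((1, 1)))

    def max_real(x0v: float) -> float:
        fp = network_fixed_point(c1, _Ex(np.array([x0v]), params.x_c), params)
        rep = eigen_analysis(build_jacobian(c1, fp, params))
        return float(rep.eigenvalues[0].real)

    lo, hi = -3.0, -1.5
    if max_real(lo) >= 0 or max_real(hi) <= 0:
        raise NumericalError("bisection bracket does not straddle the threshold")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if max_real(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
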