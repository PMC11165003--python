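"""Master Stability Function machinery.

For a network of identical units ``x_i' = f(x_i) - d * sum_j L_ij g(x_j)``
linear stability of the synchronous solution decouples, mode by mode, into the
parametric variational equation

    eta' = [Jf(x_s) - nu * Jg(x_s)] eta ,     nu = d * lambda ,

driven by the isolated trajectory ``x_s(t)``.  The largest Lyapunov exponent
of this equation as a function of ``nu`` is the Master Stability Function
``Lambda(nu)``; its sign pattern sorts every flow/output pair into one of
three classes:

* Class I   - never negative: the system defies synchronization;
* Class II  - a single crossing ``nu*``: synchronization threshold
  ``d_c = nu* / lambda_2``;
* Class III - negative only on ``(nu1*, nu2*)``: both ``d lambda_2 > nu1*``
  and ``d lambda_N < nu2*`` are required.

Exponents are estimated with the single-vector Benettin method: co-integrate
the base trajectory and one tangent vector, renormalize the tangent at fixed
intervals, and average the logarithmic growth after a transient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "DynamicalSystem",
    "LyapunovSettings",
    "MSFCurve",
    "MSFClassification",
    "rossler",
    "lorenz",
    "linear_system",
    "make_system",
    "max_lyapunov",
    "msf_curve",
    "classify_msf",
    "find_nu_star",
]


@dataclass
class DynamicalSystem:
    """A flow/output pair with analytic Jacobians.

    ``output_matrix`` is the (constant) Jacobian of the linear output function
    ``g(x) = Jg x`` through which units interact.  Optional fast paths:
    ``variational_rhs`` builds a scalar-arithmetic right-hand side for the
    combined base+tangent system at a given ``nu``; ``vector_flow`` evaluates
    the flow on all network nodes at once (rows of ``X``), honouring per-node
    parameter overrides.
    """

    name: str
    dim: int
    params: dict[str, float]
    default_initial_state: np.ndarray
    flow: Callable[[np.ndarray, dict], np.ndarray]
    flow_jacobian: Callable[[np.ndarray, dict], np.ndarray]
    output_matrix: np.ndarray
    vector_flow: Callable[[np.ndarray, dict, dict], np.ndarray] | None = None
    variational_rhs: Callable[[float, dict], Callable] | None = None
    jacobian_state_independent: bool = False

    def f(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(self.flow(x, self.params), dtype=float)

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(self.flow_jacobian(x, self.params), dtype=float)

    def g(self, x: np.ndarray) -> np.ndarray:
        return self.output_matrix @ x

    def flow_at_nodes(self, states: np.ndarray, overrides: dict[str, np.ndarray]) -> np.ndarray:
        """Flow evaluated row-wise on an (N, m) state array."""
        if self.vector_flow is not None:
            return self.vector_flow(states, self.params, overrides)
        out = np.empty_like(states)
        for i, x in enumerate(states):
            p = dict(self.params)
            for k, v in overrides.items():
                p[k] = float(v[i])
            out[i] = self.flow(x, p)
        return out

    def check_jacobian(self, rng: np.random.Generator, n_points: int = 5,
                       rtol: float = 1e-5) -> None:
        """Finite-difference consistency check of the analytic Jacobian."""
        for _ in range(n_points):
            x = self.default_initial_state + rng.uniform(-1, 1, self.dim)
            jac = self.jacobian(x)
            h = 1e-6
            num = np.empty_like(jac)
            for j in range(self.dim):
                dx = np.zeros(self.dim)
                dx[j] = h
                num[:, j] = (self.f(x + dx) - self.f(x - dx)) / (2 * h)
            scale = max(1.0, np.abs(jac).max())
            if np.abs(jac - num).max() > rtol * scale:
                raise ValueError(f"analytic Jacobian of {self.name!r} disagrees "
                                 "with finite differences")


@dataclass
class LyapunovSettings:
    """Integration controls for Benettin largest-exponent estimates.

    Times are in the natural time units of the flow.  The defaults (200-unit
    discarded transient, 2000-unit averaging window, renormalization every
    unit, adaptive eighth-order Runge-Kutta at 1e-9 tolerances) are standard
    practice for three-dimensional chaotic flows.
    """

    transient_time: float = 200.0
    total_time: float = 2000.0
    renormalization_interval: float = 1.0
    rtol: float = 1e-9
    atol: float = 1e-9
    seed: int = 0
    initial_state: np.ndarray | None = None
    jitter: float = 1e-3

    def __post_init__(self) -> None:
        if not (self.total_time > 0 and self.transient_time > 0):
            raise ValueError("total_time and transient_time must be positive")
        if self.renormalization_interval <= 0:
            raise ValueError("renormalization_interval must be positive")


@dataclass
class MSFCurve:
    """Sampled Master Stability Function Lambda(nu) on a nu grid."""

    nu_values: np.ndarray
    lambda_values: np.ndarray
    settings: LyapunovSettings

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"nu": self.nu_values, "lambda": self.lambda_values}).to_csv(
            path, index=False
        )


@dataclass
class MSFClassification:
    """Class label and located intercepts of an MSF curve."""

    class_label: str  # "I" | "II" | "III"
    curve: MSFCurve
    nu_star: float | None = None
    nu1_star: float | None = None
    nu2_star: float | None = None

    def to_dict(self) -> dict:
        return {
            "class": self.class_label,
            "nu_star": self.nu_star,
            "nu1_star": self.nu1_star,
            "nu2_star": self.nu2_star,
        }


# ---------------------------------------------------------------------------
# built-in systems
# ---------------------------------------------------------------------------

_COMPONENTS = {"x": 0, "y": 1, "z": 2}


def _selector(dim: int, component: str) -> np.ndarray:
    p = np.zeros((dim, dim))
    p[_COMPONENTS[component], _COMPONENTS[component]] = 1.0
    return p


def rossler(a: float = 0.1, b: float = 0.1, c: float = 18.0,
            coupling: str = "y") -> DynamicalSystem:
    """Roessler oscillator, chaotic at the defaults; output couples one component.

    With y-coupling (``g(x) = (0, y, 0)``) the system is Class II.
    """
    params = {"a": a, "b": b, "c": c}

    def flow(x, p):
        return np.array([-x[1] - x[2], x[0] + p["a"] * x[1],
                         p["b"] + x[2] * (x[0] - p["c"])])

    def jac(x, p):
        return np.array([[0.0, -1.0, -1.0],
                         [1.0, p["a"], 0.0],
                         [x[2], 0.0, x[0] - p["c"]]])

    def vector_flow(states, p, overrides):
        x, y, z = states[:, 0], states[:, 1], states[:, 2]
        pa = overrides.get("a", p["a"])
        pb = overrides.get("b", p["b"])
        pc = overrides.get("c", p["c"])
        return np.column_stack([-y - z, x + pa * y, pb + z * (x - pc)])

    ci = _COMPONENTS[coupling]

    def variational(nu, p):
        pa, pb, pc = p["a"], p["b"], p["c"]
        nux = nu if ci == 0 else 0.0
        nuy = nu if ci == 1 else 0.0
        nuz = nu if ci == 2 else 0.0

        def rhs(t, u):
            x, y, z, e1, e2, e3 = u
            return (
                -y - z,
                x + pa * y,
                pb + z * (x - pc),
                -e2 - e3 - nux * e1,
                e1 + pa * e2 - nuy * e2,
                z * e1 + (x - pc) * e3 - nuz * e3,
            )

        return rhs

    return DynamicalSystem(
        name="rossler", dim=3, params=params,
        default_initial_state=np.array([1.0, 1.0, 1.0]),
        flow=flow, flow_jacobian=jac, output_matrix=_selector(3, coupling),
        vector_flow=vector_flow, variational_rhs=variational,
    )


def lorenz(sigma: float = 10.0, rho: float = 28.0, beta: float = 2.0,
           coupling: str = "x") -> DynamicalSystem:
    """Lorenz oscillator ``(sigma(y-x), x(rho-z)-y, xy-beta z)``, Class II with x-coupling."""
    params = {"sigma": sigma, "rho": rho, "beta": beta}

    def flow(x, p):
        return np.array([p["sigma"] * (x[1] - x[0]),
                         x[0] * (p["rho"] - x[2]) - x[1],
                         x[0] * x[1] - p["beta"] * x[2]])

    def jac(x, p):
        return np.array([[-p["sigma"], p["sigma"], 0.0],
                         [p["rho"] - x[2], -1.0, -x[0]],
                         [x[1], x[0], -p["beta"]]])

    def vector_flow(states, p, overrides):
        x, y, z = states[:, 0], states[:, 1], states[:, 2]
        ps = overrides.get("sigma", p["sigma"])
        pr = overrides.get("rho", p["rho"])
        pb = overrides.get("beta", p["beta"])
        return np.column_stack([ps * (y - x), x * (pr - z) - y, x * y - pb * z])

    ci = _COMPONENTS[coupling]

    def variational(nu, p):
        ps, pr, pb = p["sigma"], p["rho"], p["beta"]
        nux = nu if ci == 0 else 0.0
        nuy = nu if ci == 1 else 0.0
        nuz = nu if ci == 2 else 0.0

        def rhs(t, u):
            x, y, z, e1, e2, e3 = u
            return (
                ps * (y - x),
                x * (pr - z) - y,
                x * y - pb * z,
                ps * (e2 - e1) - nux * e1,
                (pr - z) * e1 - e2 - x * e3 - nuy * e2,
                y * e1 + x * e2 - pb * e3 - nuz * e3,
            )

        return rhs

    return DynamicalSystem(
        name="lorenz", dim=3, params=params,
        default_initial_state=np.array([1.0, 1.0, 1.0]),
        flow=flow, flow_jacobian=jac, output_matrix=_selector(3, coupling),
        vector_flow=vector_flow, variational_rhs=variational,
    )


def linear_system(rate: float = 1.0) -> DynamicalSystem:
    """One-dimensional linear test system ``x' = rate * x`` with ``g(x) = x``.

    The variational kernel is the constant ``rate - nu``, so the MSF is exactly
    ``Lambda(nu) = rate - nu`` -- an analytic limit check for the Benettin
    machinery.  The Jacobian is state-independent, so no base trajectory is
    integrated (the flow itself diverges exponentially).
    """
    params = {"rate": rate}

    def flow(x, p):
        return p["rate"] * np.asarray(x, dtype=float)

    def jac(x, p):
        return np.array([[p["rate"]]])

    def variational(nu, p):
        k = p["rate"] - nu

        def rhs(t, u):
            return (0.0, k * u[1])

        return rhs

    return DynamicalSystem(
        name="linear", dim=1, params=params,
        default_initial_state=np.array([1.0]),
        flow=flow, flow_jacobian=jac, output_matrix=np.array([[1.0]]),
        variational_rhs=variational, jacobian_state_independent=True,
    )


_FACTORIES = {"rossler": rossler, "lorenz": lorenz, "linear": linear_system}


def make_system(name: str, coupling: str | None = None, **params) -> DynamicalSystem:
    """Build a named system, optionally overriding parameters and coupling component."""
    if name not in _FACTORIES:
        raise ValueError(f"unknown system {name!r}; choose from {sorted(_FACTORIES)}")
    kwargs = dict(params)
    if coupling is not None and name != "linear":
        kwargs["coupling"] = coupling
    return _FACTORIES[name](**kwargs)


# ---------------------------------------------------------------------------
# Benettin largest Lyapunov exponent
# ---------------------------------------------------------------------------


def _resolve_initial(sys: DynamicalSystem, settings: LyapunovSettings) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(settings.seed)
    if settings.initial_state is not None:
        x0 = np.asarray(settings.initial_state, dtype=float)
    else:
        x0 = sys.default_initial_state + settings.jitter * rng.standard_normal(sys.dim)
    eta0 = rng.standard_normal(sys.dim)
    eta0 /= np.linalg.norm(eta0)
    return x0, eta0


def _generic_variational(sys: DynamicalSystem, nu: float):
    jg = sys.output_matrix
    m = sys.dim

    def rhs(t, u):
        x, eta = u[:m], u[m:]
        k = sys.jacobian(x) - nu * jg
        return np.concatenate([sys.f(x), k @ eta])

    return rhs


def max_lyapunov(sys: DynamicalSystem, nu: float,
                 settings: LyapunovSettings | None = None) -> float:
    """Largest Lyapunov exponent of the parametric variational equation.

    Benettin single-vector estimate: the isolated base trajectory is advanced
    past the transient, then base and one tangent vector are co-integrated,
    with the tangent renormalized every ``renormalization_interval`` time
    units; the exponent is the time-average of the logarithmic growth factors.
    """
    if nu < 0:
        raise ValueError("nu must be nonnegative")
    settings = settings or LyapunovSettings()
    m = sys.dim
    x0, eta0 = _resolve_initial(sys, settings)

    if sys.jacobian_state_independent:
        x_start = x0
    else:
        base = solve_ivp(lambda t, x: sys.f(x), (0.0, settings.transient_time), x0,
                         method="DOP853", rtol=settings.rtol, atol=settings.atol)
        if not base.success or not np.all(np.isfinite(base.y[:, -1])):
            raise RuntimeError(f"base trajectory of {sys.name!r} diverged during "
                               "the transient (bad parameters?)")
        x_start = base.y[:, -1]

    rhs = (sys.variational_rhs(nu, sys.params) if sys.variational_rhs is not None
           else _generic_variational(sys, nu))
    tau = settings.renormalization_interval
    n_chunks = max(1, int(round(settings.total_time / tau)))
    u = np.concatenate([x_start, eta0])
    log_sum = 0.0
    for _ in range(n_chunks):
        sol = solve_ivp(rhs, (0.0, tau), u, method="DOP853",
                        rtol=settings.rtol, atol=settings.atol)
        u = sol.y[:, -1]
        if not sol.success or not np.all(np.isfinite(u)):
            raise RuntimeError(f"variational integration of {sys.name!r} produced "
                               f"non-finite values at nu={nu}")
        norm = np.linalg.norm(u[m:])
        if norm == 0.0:
            raise RuntimeError("tangent vector collapsed to zero")
        log_sum += np.log(norm)
        u[m:] /= norm
    return log_sum / (n_chunks * tau)


def msf_curve(sys: DynamicalSystem, nu_grid: np.ndarray,
              settings: LyapunovSettings | None = None) -> MSFCurve:
    """Sample Lambda(nu) on a sorted nonnegative grid (one Benettin run per point)."""
    settings = settings or LyapunovSettings()
    nu_grid = np.asarray(nu_grid, dtype=float)
    if np.any(np.diff(nu_grid) <= 0):
        raise ValueError("nu_grid must be strictly increasing")
    if nu_grid[0] < 0:
        raise ValueError("nu_grid must be nonnegative")
    lam = np.array([max_lyapunov(sys, nu, settings) for nu in nu_grid])
    return MSFCurve(nu_grid, lam, settings)


def _bisect_root(f: Callable[[float], float], lo: float, hi: float,
                 f_lo: float, f_hi: float, tol: float) -> float:
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        f_mid = f(mid)
        if (f_mid > 0) == (f_lo > 0):
            lo, f_lo = mid, f_mid
        else:
            hi, f_hi = mid, f_mid
    return 0.5 * (lo + hi)


def classify_msf(curve: MSFCurve, sys: DynamicalSystem | None = None,
                 settings: LyapunovSettings | None = None,
                 refine_tol: float = 1e-4) -> MSFClassification:
    """Classify an MSF curve and locate its horizontal-axis intercepts.

    The sign pattern of the samples determines the class (I: never negative,
    II: one +/- crossing, III: +/-/+).  When ``sys`` is given each bracketed
    root is refined by bisection on fresh :func:`max_lyapunov` evaluations
    (with ``settings``, defaulting to the curve's own) until the bracket is
    narrower than ``refine_tol``; otherwise intercepts are linearly
    interpolated from the samples.  A sign pattern with more than two changes
    is outside the three-class scenario of the first transition (the stability
    region would be a union of several intervals) and raises ``ValueError``.
    """
    nu, lam = curve.nu_values, curve.lambda_values
    signs = np.sign(lam)
    changes = [i for i in range(len(lam) - 1) if signs[i] != signs[i + 1]
               and signs[i] != 0]
    pattern = [signs[0]] + [signs[i + 1] for i in changes]
    if len(changes) > 2 or (len(changes) == 2 and not (pattern == [1, -1, 1])):
        raise ValueError(
            "MSF sign pattern is outside the three-class scenario: the region of "
            "stability could even be formed by the union of several intervals"
        )
    if signs[0] <= 0:
        raise ValueError("Lambda(0) must be positive: the method addresses chaotic units")

    def refine(i: int) -> float:
        lo, hi, f_lo, f_hi = nu[i], nu[i + 1], lam[i], lam[i + 1]
        if sys is None:
            return lo + (hi - lo) * f_lo / (f_lo - f_hi)
        st = settings or curve.settings
        f = lambda x: max_lyapunov(sys, x, st)
        f_lo2, f_hi2 = f(lo), f(hi)
        if (f_lo2 > 0) == (f_hi2 > 0):
            raise RuntimeError(
                f"sign change in [{lo}, {hi}] not reproduced at refinement settings"
            )
        return _bisect_root(f, lo, hi, f_lo2, f_hi2, refine_tol)

    if not changes:
        return MSFClassification("I", curve)
    if len(changes) == 1:
        return MSFClassification("II", curve, nu_star=refine(changes[0]))
    return MSFClassification("III", curve, nu1_star=refine(changes[0]),
                             nu2_star=refine(changes[1]))


def find_nu_star(sys: DynamicalSystem, nu_max: float,
                 n_scan: int = 11,
                 scan_settings: LyapunovSettings | None = None,
                 refine_settings: LyapunovSettings | None = None,
                 refine_tol: float = 1e-4) -> MSFClassification:
    """Two-stage intercept location: coarse scan then bisection refinement.

    A short-window grid scan over ``[0, nu_max]`` brackets the sign changes;
    bisection then refines each root with the (longer) ``refine_settings``.
    """
    scan = scan_settings or LyapunovSettings(total_time=400.0)
    refine = refine_settings or LyapunovSettings(seed=scan.seed)
    grid = np.linspace(0.0, nu_max, n_scan)
    curve = msf_curve(sys, grid, scan)
    return classify_msf(curve, sys=sys, settings=refine, refine_tol=refine_tol)
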