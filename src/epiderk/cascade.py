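"""Normalized-Hill ODE model of the ERK-MAPK cascade across the epidermis.

The model describes the fractional activation of five species —
cytoplasmic phospho-Raf-1 (``rafc``), cytoplasmic and nuclear
phospho-MEK-1/2 (``mekc``, ``mekn``) and cytoplasmic and nuclear
phospho-ERK-1/2 (``erkc``, ``erkn``) — in a single keratinocyte at a fixed
depth ``d`` within the epidermis.  Depth is measured in model units on
[0, 7]: one unit per coarse spatial partition (1 basal : 4 spinous/granular
: 2 transitional cells).  The cascade is driven by two depth-dependent
inputs, tissue Ca2+ (activating Raf-1) and plasma-membrane calmodulin
(inhibiting Raf-1), each parameterized by a baseline ``b`` and amplitude
``a`` of fractional activation.

Every activating interaction passes through a normalized Hill function
f_act with f_act(0) = 0, f_act(EC50) = 1/2 and f_act(1) = 1; inhibition is
the negative of activation, and dephosphorylation is inhibition multiplied
by the fractional activation of the output species.  The inhibitory inputs
to Raf-1 are clamped so they can cancel the Ca2+ drive but never push the
net production below zero.  Phospho-MEK and phospho-ERK shuttle between
cytoplasm and nucleus with first-order rates; the cytoplasm-to-nucleus
volume ratio r(d) (linear from 2 deep to 5 superficial) scales the fluxes
so that material is conserved between compartments of different size.

At each depth the ODE system is integrated to steady state; the collection
of steady states over a half-partition grid (15 depths) is the model's
spatial activation profile.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .exceptions import DomainError, NumericalError, ParameterError

__all__ = [
    "NormalizedHillParams",
    "CascadeParameters",
    "CascadeState",
    "SpatialSteadyState",
    "SteadyStateResult",
    "f_act",
    "ca_input",
    "cam_input",
    "volume_ratio",
    "rhs",
    "solve_steady_state",
    "steady_state_root",
    "spatial_profile",
    "knockout_cam",
    "sample_random_parameters",
]

SPECIES = ("rafc", "mekc", "mekn", "erkc", "erkn")

#: Residual tolerance below which a state counts as a steady state.
STEADY_STATE_TOL = 1e-6


@dataclass(frozen=True)
class NormalizedHillParams:
    """Hill exponent and EC50 of the normalized activating Hill function.

    The two remaining constants B and K of  f(x) = B x^n / (K^n + x^n)
    are fixed by the normalization constraints f(0) = 0, f(ec50) = 1/2,
    f(1) = 1, which solve in closed form to

        K^n = ec50^n / (1 - 2 ec50^n),      B = K^n + 1.

    The construction degenerates when 2 ec50^n = 1 (the constraints then
    force f = x^n and B, K diverge); that case is rejected.
    """

    n: float = 1.4
    ec50: float = 0.5

    def __post_init__(self) -> None:
        if not (self.n > 0):
            raise ParameterError(f"Hill exponent must be positive, got {self.n}")
        if not (0.0 < self.ec50 < 1.0):
            raise ParameterError(f"ec50 must lie in (0, 1), got {self.ec50}")
        if abs(2.0 * self.ec50**self.n - 1.0) < 1e-12:
            raise ParameterError(
                "degenerate normalized-Hill parameters: 2*ec50**n == 1"
            )

    @property
    def K_pow_n(self) -> float:
        e = self.ec50**self.n
        return e / (1.0 - 2.0 * e)

    @property
    def B(self) -> float:
        return self.K_pow_n + 1.0

    @property
    def K(self) -> float:
        kn = self.K_pow_n
        if kn <= 0:
            # K^n may legitimately be negative (ec50^n > 1/2); K itself is
            # then not a positive real, but f_act only ever uses K^n.
            return float("nan")
        return kn ** (1.0 / self.n)


def f_act(x, hill: NormalizedHillParams = NormalizedHillParams()):
    """Normalized activating Hill function.

    Monotone increasing on [0, 1] with f(0)=0, f(ec50)=1/2, f(1)=1.
    Negative inputs (which can appear transiently inside an integrator
    stage) are clamped to zero before the fractional power is taken.
    """
    xp = np.maximum(np.asarray(x, dtype=float), 0.0)
    xn = xp**hill.n
    out = hill.B * xn / (hill.K_pow_n + xn)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class CascadeParameters:
    """All constants of the spatially driven ERK-MAPK cascade model.

    Defaults are the model's standard configuration: normalized-Hill
    defaults n=1.4, EC50=0.5, unit time constants, unit reaction weights
    and unit maximal activations; shuttling rates chosen to reflect
    measured cytoplasm<->nucleus transport-coefficient ratios; volume
    ratio linear from 2 (deep) to 5 (superficial); and input baselines /
    amplitudes from the least-squares fit to cytoplasmic and nuclear
    phospho-ERK-1/2 profiles (Ca: b=0.754, a=0.092; CaM: b=0.363,
    a=0.485).
    """

    hill: NormalizedHillParams = field(default_factory=NormalizedHillParams)

    # time constants (time units) per species
    tau_rafc: float = 1.0
    tau_mekc: float = 1.0
    tau_mekn: float = 1.0
    tau_erkc: float = 1.0
    tau_erkn: float = 1.0

    # reaction weights per arc, in [0, 1]
    w_ca_rafc: float = 1.0
    w_cam_rafc: float = 1.0
    w_erkc_rafc: float = 1.0
    w_rafc_mekc: float = 1.0
    w_mekc_erkc: float = 1.0
    w_mekn_erkn: float = 1.0
    w_erkn_erkn: float = 1.0

    # maximal fractional activations
    xmax_rafc: float = 1.0
    xmax_mekc: float = 1.0
    xmax_mekn: float = 1.0
    xmax_erkc: float = 1.0
    xmax_erkn: float = 1.0

    # cytoplasm<->nucleus shuttling rates (per time unit)
    s_mekcn: float = 0.05
    s_meknc: float = 0.5
    s_erkcn: float = 0.01
    s_erknc: float = 0.01

    # cytoplasm-to-nucleus volume ratio endpoints, linear over depth [0, 7]
    r_deep: float = 2.0
    r_superficial: float = 5.0

    # input profile baselines and amplitudes (fractional activation)
    b_ca: float = 0.754
    a_ca: float = 0.092
    b_cam: float = 0.363
    a_cam: float = 0.485

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("tau_rafc", "tau_mekc", "tau_mekn", "tau_erkc", "tau_erkn"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be positive")
        for name in (
            "w_ca_rafc", "w_cam_rafc", "w_erkc_rafc", "w_rafc_mekc",
            "w_mekc_erkc", "w_mekn_erkn", "w_erkn_erkn",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")
        for name in ("xmax_rafc", "xmax_mekc", "xmax_mekn", "xmax_erkc", "xmax_erkn"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be positive")
        for name in ("s_mekcn", "s_meknc", "s_erkcn", "s_erknc"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be nonnegative")
        if self.r_deep <= 0 or self.r_superficial <= 0:
            raise ParameterError("volume-ratio endpoints must be positive")
        for b, a, tag in ((self.b_ca, self.a_ca, "ca"), (self.b_cam, self.a_cam, "cam")):
            if not (0.0 <= b <= 1.0 and 0.0 <= a <= 1.0):
                raise ParameterError(f"{tag} baseline/amplitude must lie in [0, 1]")
            if b + a > 1.0 + 1e-12:
                raise ParameterError(
                    f"{tag} baseline+amplitude exceeds 1 (fractional activation)"
                )

    def xmax_vector(self) -> np.ndarray:
        return np.array([self.xmax_rafc, self.xmax_mekc, self.xmax_mekn,
                         self.xmax_erkc, self.xmax_erkn])

    def replace(self, **changes) -> "CascadeParameters":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class CascadeState:
    """Fractional activations of the five modeled species at one depth."""

    rafc: float
    mekc: float
    mekn: float
    erkc: float
    erkn: float

    def as_array(self) -> np.ndarray:
        return np.array([self.rafc, self.mekc, self.mekn, self.erkc, self.erkn])

    @classmethod
    def from_array(cls, x) -> "CascadeState":
        return cls(*(float(v) for v in np.asarray(x)))


@dataclass(frozen=True)
class SteadyStateResult:
    state: CascadeState
    residual: float
    converged: bool


@dataclass
class SpatialSteadyState:
    """Steady states of the cascade on a grid of depths across the tissue."""

    depths: np.ndarray          # (m,) in [0, 7]
    ca: np.ndarray              # (m,) input fractional activation
    cam: np.ndarray             # (m,)
    states: np.ndarray          # (5, m), species order SPECIES
    residuals: np.ndarray       # (m,) max |dX/dt| at the returned state
    converged: np.ndarray       # (m,) bool

    def species(self, name: str) -> np.ndarray:
        return self.states[SPECIES.index(name)]


def _check_depth(d) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if np.any(d < 0.0) or np.any(d > 7.0):
        raise DomainError(f"depth must lie in [0, 7], got {d}")
    return d


def ca_input(d, b_ca: float, a_ca: float):
    """Tissue Ca2+ fractional activation at depth d.

    Rises linearly from b at the basal boundary to its peak b+a at d=5
    (the granular/transitional interface) and falls linearly back to b at
    the superficial surface:  b + a*d/5 on [0,5), b + a*(7-d)/2 on [5,7].
    """
    d = _check_depth(d)
    val = b_ca + a_ca * np.where(d < 5.0, d / 5.0, (7.0 - d) / 2.0)
    return val if val.ndim else float(val)


def cam_input(d, b_cam: float, a_cam: float):
    """Plasma-membrane calmodulin fractional activation at depth d.

    Piecewise: b + a*(d+1)/2 on [0,1) (rising through the basal layer to
    its peak b+a at d=1), b + a*exp(1-d) on [1,5) (exponential decay over
    the spinous/granular layers), and the baseline b on [5,7].  The small
    discontinuity at d=5 (left limit b + a*e^-4) is part of the profile
    definition and is not smoothed.
    """
    d = _check_depth(d)
    shape = np.where(d < 1.0, (d + 1.0) / 2.0, np.where(d < 5.0, np.exp(1.0 - d), 0.0))
    val = b_cam + a_cam * shape
    return val if val.ndim else float(val)


def volume_ratio(d, params: CascadeParameters):
    """Cytoplasm-to-nucleus volume ratio, linear in depth over [0, 7]."""
    d = _check_depth(d)
    val = params.r_deep + (params.r_superficial - params.r_deep) * d / 7.0
    return val if val.ndim else float(val)


def rhs(state, d, params: CascadeParameters):
    """Time derivatives of the five species at depth ``d``.

    ``state`` may be a length-5 vector or a (5, m) array paired with m
    depths; the function is pure and broadcasts over the trailing axis.
    The Rafc drive is max-clamped at zero so the CaM and ERKc inhibitions
    can cancel the Ca2+ activation but never become dephosphorylating.
    """
    state = np.asarray(state, dtype=float)
    rafc, mekc, mekn, erkc, erkn = state
    p = params
    hill = p.hill
    ca = np.asarray(ca_input(d, p.b_ca, p.a_ca))
    cam = np.asarray(cam_input(d, p.b_cam, p.a_cam))
    r = np.asarray(volume_ratio(d, p))

    drive = np.maximum(
        p.w_ca_rafc * f_act(ca, hill)
        - p.w_cam_rafc * f_act(cam, hill)
        - p.w_erkc_rafc * f_act(erkc, hill),
        0.0,
    )
    d_rafc = (drive * p.xmax_rafc - rafc) / p.tau_rafc
    d_mekc = (
        p.w_rafc_mekc * f_act(rafc, hill) * p.xmax_mekc
        - mekc - p.s_mekcn * mekc + p.s_meknc / r * mekn
    ) / p.tau_mekc
    d_mekn = (-mekn - p.s_meknc * mekn + r * p.s_mekcn * mekc) / p.tau_mekn
    d_erkc = (
        p.w_mekc_erkc * f_act(mekc, hill) * p.xmax_erkc
        - erkc - p.s_erkcn * erkc + p.s_erknc / r * erkn
    ) / p.tau_erkc
    d_erkn = (
        (p.w_mekn_erkn * f_act(mekn, hill) - p.w_erkn_erkn * f_act(erkn, hill) * erkn)
        * p.xmax_erkn
        - erkn - p.s_erknc * erkn + r * p.s_erkcn * erkc
    ) / p.tau_erkn
    return np.stack(np.broadcast_arrays(d_rafc, d_mekc, d_mekn, d_erkc, d_erkn))


def _make_deriv(depths: np.ndarray, params: CascadeParameters):
    """Derivative closure with the depth-dependent inputs precomputed.

    Ca, CaM and the volume ratio are constant in time at each depth, so
    only the five species Hill terms are re-evaluated per call.
    """
    p = params
    hill = p.hill
    ca = np.asarray(ca_input(depths, p.b_ca, p.a_ca))
    cam = np.asarray(cam_input(depths, p.b_cam, p.a_cam))
    r = np.asarray(volume_ratio(depths, p))
    base_drive = p.w_ca_rafc * f_act(ca, hill) - p.w_cam_rafc * f_act(cam, hill)

    def deriv(x: np.ndarray) -> np.ndarray:
        rafc, mekc, mekn, erkc, erkn = x
        drive = np.maximum(base_drive - p.w_erkc_rafc * f_act(erkc, hill), 0.0)
        return np.stack([
            (drive * p.xmax_rafc - rafc) / p.tau_rafc,
            (p.w_rafc_mekc * f_act(rafc, hill) * p.xmax_mekc
             - mekc - p.s_mekcn * mekc + p.s_meknc / r * mekn) / p.tau_mekc,
            (-mekn - p.s_meknc * mekn + r * p.s_mekcn * mekc) / p.tau_mekn,
            (p.w_mekc_erkc * f_act(mekc, hill) * p.xmax_erkc
             - erkc - p.s_erkcn * erkc + p.s_erknc / r * erkn) / p.tau_erkc,
            ((p.w_mekn_erkn * f_act(mekn, hill)
              - p.w_erkn_erkn * f_act(erkn, hill) * erkn) * p.xmax_erkn
             - erkn - p.s_erknc * erkn + r * p.s_erkcn * erkc) / p.tau_erkn,
        ])

    return deriv


def _integrate_to_steady(
    depths: np.ndarray,
    params: CascadeParameters,
    x0: np.ndarray | None = None,
    t_final: float = 50.0,
    dt: float = 0.1,
    exit_tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-step RK4 integration of all depths simultaneously.

    Integration stops early once the largest derivative falls below
    ``exit_tol`` (the trajectory no longer moves at the accuracy of
    interest).  Returns (states (5, m), residuals (m,)).
    """
    depths = np.atleast_1d(np.asarray(depths, dtype=float))
    _check_depth(depths)
    m = depths.size
    deriv = _make_deriv(depths, params)

    x = np.zeros((5, m)) if x0 is None else np.array(np.broadcast_to(
        np.asarray(x0, dtype=float).reshape(5, -1), (5, m)))
    n_steps = int(round(t_final / dt))
    check_every = 25
    for i in range(n_steps):
        k1 = deriv(x)
        k2 = deriv(x + 0.5 * dt * k1)
        k3 = deriv(x + 0.5 * dt * k2)
        k4 = deriv(x + dt * k3)
        x = x + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not np.all(np.isfinite(x)):
            raise NumericalError("non-finite state during integration")
        if (i + 1) % check_every == 0 and np.max(np.abs(deriv(x))) < exit_tol:
            break
    residuals = np.max(np.abs(deriv(x)), axis=0)
    return x, residuals


def _steady_states_fast(
    depths: np.ndarray, params: CascadeParameters
) -> tuple[np.ndarray, np.ndarray]:
    """Steady states via short integration plus a vectorized Newton polish.

    A coarse fixed-step integration brings every depth near its attractor,
    then Newton iterations on rhs = 0 (finite-difference Jacobians, solved
    batched across depths) drive the residual to ~1e-12.  Falls back to
    the full fixed-step integration if the polish fails to converge.  Used
    inside the fit objective, where thousands of steady-state evaluations
    are needed; agreement with the integrators is asserted in the test
    suite.
    """
    depths = np.atleast_1d(np.asarray(depths, dtype=float))
    deriv = _make_deriv(depths, params)
    m = depths.size
    x = np.zeros((5, m))
    dt, n_steps = 0.25, 60
    for _ in range(n_steps):
        k1 = deriv(x)
        k2 = deriv(x + 0.5 * dt * k1)
        k3 = deriv(x + 0.5 * dt * k2)
        k4 = deriv(x + dt * k3)
        x = x + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    ok = np.all(np.isfinite(x))
    if ok:
        eps = 1e-7
        for _ in range(25):
            f = deriv(x)
            if np.max(np.abs(f)) < 1e-12:
                break
            jac = np.empty((m, 5, 5))
            for j in range(5):
                xp = x.copy()
                xp[j] += eps
                jac[:, :, j] = ((deriv(xp) - f) / eps).T
            try:
                step = np.linalg.solve(jac, f.T[:, :, None])[:, :, 0].T
            except np.linalg.LinAlgError:
                ok = False
                break
            xn = x - step
            if not np.all(np.isfinite(xn)):
                ok = False
                break
            x = xn
        ok = ok and np.max(np.abs(deriv(x))) < 1e-9
    if not ok:
        return _integrate_to_steady(depths, params)
    return x, np.max(np.abs(deriv(x)), axis=0)


def solve_steady_state(
    d: float,
    params: CascadeParameters,
    x0=None,
    t_final: float = 50.0,
    max_step: float = 0.1,
) -> SteadyStateResult:
    """Integrate the cascade at one depth to steady state.

    Uses an adaptive 2(3)-order Runge-Kutta pair over ``t_final`` time
    units with maximum step ``max_step``, starting (by default) from the
    fully unphosphorylated state.  Convergence is asserted through the
    residual max|dX/dt| at the final state rather than assumed; results
    with residual >= 1e-6 are returned flagged ``converged=False``.
    """
    _check_depth(d)
    x0 = np.zeros(5) if x0 is None else np.asarray(x0, dtype=float)
    sol = solve_ivp(
        lambda t, s: rhs(s, d, params),
        (0.0, t_final),
        x0,
        method="RK23",
        max_step=max_step,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise NumericalError(f"integration failed at depth {d}: {sol.message}")
    final = sol.y[:, -1]
    residual = float(np.max(np.abs(rhs(final, d, params))))
    return SteadyStateResult(
        state=CascadeState.from_array(final),
        residual=residual,
        converged=residual < STEADY_STATE_TOL,
    )


def steady_state_root(d: float, params: CascadeParameters, x0=None) -> CascadeState:
    """Algebraic steady state: solve rhs = 0 directly with a root-finder.

    Independent of the time-stepping path; used as a cross-check.  Tries a
    few generic starting points before giving up.
    """
    _check_depth(d)
    xmax = params.xmax_vector()
    starts = [np.asarray(x0, dtype=float)] if x0 is not None else []
    starts += [0.5 * xmax, 0.1 * np.ones(5), 0.9 * xmax]
    for start in starts:
        sol = root(lambda s: rhs(s, d, params), start, method="hybr", tol=1e-13)
        resid = float(np.max(np.abs(rhs(sol.x, d, params))))
        if np.all(np.isfinite(sol.x)) and resid < 1e-9 and np.all(sol.x > -1e-9):
            return CascadeState.from_array(np.maximum(sol.x, 0.0))
    raise NumericalError(f"root-finding failed to locate a steady state at depth {d}")


def spatial_profile(
    params: CascadeParameters,
    step: float = 0.5,
    depths=None,
    method: str = "fixed",
    t_final: float = 50.0,
) -> SpatialSteadyState:
    """Solve the cascade to steady state across the depth of the tissue.

    With the default half-partition step the grid is d = 0, 0.5, ..., 7,
    i.e. 15 spatial locations.  ``method='fixed'`` integrates all depths
    simultaneously with a fixed-step RK4 (dt = 0.1); ``method='rk23'``
    calls :func:`solve_steady_state` per depth with the adaptive pair.
    Both are validated against each other and against the algebraic root.
    """
    if depths is None:
        n_intervals = 7.0 / step
        if abs(n_intervals - round(n_intervals)) > 1e-9:
            raise DomainError(f"step {step} does not divide the depth range [0, 7]")
        depths = np.linspace(0.0, 7.0, int(round(n_intervals)) + 1)
    depths = np.atleast_1d(np.asarray(depths, dtype=float))
    _check_depth(depths)
    params.validate()

    if method == "fixed":
        states, residuals = _integrate_to_steady(depths, params, t_final=t_final)
    elif method == "rk23":
        results = [solve_steady_state(float(d), params, t_final=t_final) for d in depths]
        states = np.stack([res.state.as_array() for res in results], axis=1)
        residuals = np.array([res.residual for res in results])
    else:
        raise ParameterError(f"unknown method {method!r}")

    return SpatialSteadyState(
        depths=depths,
        ca=np.asarray(ca_input(depths, params.b_ca, params.a_ca)),
        cam=np.asarray(cam_input(depths, params.b_cam, params.a_cam)),
        states=states,
        residuals=residuals,
        converged=residuals < STEADY_STATE_TOL,
    )


def knockout_cam(params: CascadeParameters) -> CascadeParameters:
    """Remove CaM-mediated inhibition of Raf-1 (set that reaction weight to 0).

    In-silico experiment: without the calmodulin brake the cascade sees
    the full Ca2+ drive, so steady-state activation can only increase.
    """
    return params.replace(w_cam_rafc=0.0)


def sample_random_parameters(rng: np.random.Generator) -> CascadeParameters:
    """Draw a random valid parameter set for robustness sweeps.

    Ranges bracket the default configuration.  Two draws are restricted so
    the sampled sets stay in the regime the steady-state analysis assumes:

    * the shuttling draw enforces r_superficial * s_cn <= s_nc for both
      shuttled species — under that condition the nuclear species (whose
      equations have no Hill-bounded production term) provably stay below
      their xmax at steady state, so the componentwise [0, xmax] bound
      holds over the whole sweep;
    * the Hill exponent is kept at n <= 2.2 — combining much steeper Hill
      kinetics with strong ERKc-to-Rafc negative feedback carries the
      cascade across a Hopf bifurcation into sustained oscillation, where
      no steady state exists to verify (the model is interpreted only at
      quasi-steady state).
    """
    hill = NormalizedHillParams(
        n=float(rng.uniform(1.0, 2.2)), ec50=float(rng.uniform(0.25, 0.45))
    )
    r_deep = float(rng.uniform(1.5, 3.0))
    r_sup = float(rng.uniform(3.0, 6.0))

    def shuttle_pair() -> tuple[float, float]:
        s_cn = float(rng.uniform(0.005, 0.08))
        s_nc = float(rng.uniform(r_sup * s_cn, 0.8))
        return s_cn, s_nc

    s_mekcn, s_meknc = shuttle_pair()
    s_erkcn, s_erknc = shuttle_pair()
    b_ca = float(rng.uniform(0.0, 0.8))
    b_cam = float(rng.uniform(0.0, 0.8))
    kwargs = dict(
        hill=hill,
        s_mekcn=s_mekcn, s_meknc=s_meknc, s_erkcn=s_erkcn, s_erknc=s_erknc,
        r_deep=r_deep, r_superficial=r_sup,
        b_ca=b_ca, a_ca=float(rng.uniform(0.0, 1.0 - b_ca)),
        b_cam=b_cam, a_cam=float(rng.uniform(0.0, 1.0 - b_cam)),
    )
    for name in ("tau_rafc", "tau_mekc", "tau_mekn", "tau_erkc", "tau_erkn"):
        kwargs[name] = float(rng.uniform(0.5, 2.0))
    for name in ("w_ca_rafc", "w_cam_rafc", "w_erkc_rafc", "w_rafc_mekc",
                 "w_mekc_erkc", "w_mekn_erkn", "w_erkn_erkn"):
        kwargs[name] = float(rng.uniform(0.2, 1.0))
    return CascadeParameters(**kwargs)
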