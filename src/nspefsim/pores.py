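"""Per-interface-node electroporation state: the asymptotic pore model.

The pore density N (m^-2) follows the Smoluchowski-derived creation ODE

    dN/dt = alpha * exp((V/U_ep)^2) * (1 - N/N0 * exp(-q (V/U_ep)^2)),

which at fixed transmembrane voltage V is linear in N and relaxes to the
closed-form fixed point N_eq = N0 * exp(q (V/U_ep)^2); the integrator uses
that exact exponential update. The representative pore radius evolves down
the gradient of the pore energy

    W(r) = -V^2 F_max (r - r_h ln(r + r_h + r_t)) + C (r*/r)^4
           + 2 pi gamma r - pi delta_eff r^2,

i.e. dr/dt = -(D/kT) dW/dr, whose expanded form is the published
pore-radius rate. The effective membrane tension delta_eff relaxes with the
fractional electroporated area A = pi r^2 N. Throughout, V is the
transmembrane voltage relative to rest: the model's rest state (V = 0,
N = N0, r = r*) is an exact fixed point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .params import EPParams

V_GUARD = 2.0        # |V_m| cap inside exp((V/U)^2), V; guards overflow
R_FLOOR_FRAC = 0.65  # radius floor as a fraction of r_star
A_FRAC_CAP = 0.999   # fractional-area cap (delta_eff diverges at 1)


@dataclass
class PoreModelState:
    """Vectorized pore state over the nodes of one membrane contour."""

    N: np.ndarray        # pore density, m^-2
    r_pore: np.ndarray   # representative pore radius, m
    A_frac: np.ndarray   # fractional electroporated area pi r^2 N

    def copy(self) -> "PoreModelState":
        return PoreModelState(self.N.copy(), self.r_pore.copy(), self.A_frac.copy())


def stationary_radius(p: EPParams, steric: bool = True) -> float:
    """Resting pore radius: the zero of dr/dt at V_m = 0 with the
    self-consistent tension delta_eff(pi r^2 N0).

    With the steric term on, the force balance 4 C r*^4/r^5 = 2 pi gamma -
    2 pi delta_eff r has a root slightly above r_star (the energy-minimum
    radius of a resting hydrophilic pore); with it off the radius rate is
    negative everywhere small, and the configured floor is the rest radius.
    """
    from scipy.optimize import brentq

    r_floor = R_FLOOR_FRAC * p.r_star

    def force(r):
        delta = effective_tension(min(np.pi * r**2 * p.N0, A_FRAC_CAP), p)
        return float(pore_radius_rate(r, 0.0, delta, p, steric))

    if force(r_floor) <= 0:
        return r_floor
    hi = 100 * p.r_star
    if force(hi) >= 0:  # pragma: no cover - not reachable for sane params
        return hi
    return float(brentq(force, r_floor, hi, xtol=1e-15))


def rest_state(n_nodes: int, p: EPParams, steric: bool = True) -> PoreModelState:
    """Rest state: N = N0 and r at the stationary resting radius, so that
    the pore model is an exact fixed point at V_m = 0."""
    N = np.full(n_nodes, p.N0)
    r = np.full(n_nodes, stationary_radius(p, steric))
    return PoreModelState(N=N, r_pore=r, A_frac=np.pi * r**2 * N)


def _vsq(V_m, p: EPParams):
    """(V/U_ep)^2 with the overflow guard; warns above the guard."""
    V = np.asarray(V_m, dtype=float)
    if np.any(np.abs(V) > V_GUARD):
        warnings.warn(f"|V_m| exceeded {V_GUARD} V; exponent clamped", RuntimeWarning,
                      stacklevel=3)
        V = np.clip(V, -V_GUARD, V_GUARD)
    return (V / p.U_ep) ** 2


def pore_density_rate(V_m, N, p: EPParams):
    """dN/dt (m^-2 s^-1) of the pore-creation ODE; symmetric in +-V_m."""
    x = _vsq(V_m, p)
    return p.alpha * np.exp(x) * (1.0 - (np.asarray(N) / p.N0) * np.exp(-p.q * x))


def equilibrium_density(V_m, p: EPParams):
    """Closed-form fixed point N_eq = N0 exp(q (V/U_ep)^2)."""
    return p.N0 * np.exp(p.q * _vsq(V_m, p))


def effective_tension(A_frac, p: EPParams):
    """Membrane tension relaxed by the open pore area:
    delta_eff = 2 sigma' - (2 sigma' - sigma0) / (1 - A)^2."""
    A = np.asarray(A_frac, dtype=float)
    if np.any(A < 0) or np.any(A >= 1):
        raise ValueError(f"A_frac must lie in [0, 1), got range "
                         f"[{A.min()}, {A.max()}]")
    two_sp = 2.0 * p.sigma_prime
    return two_sp - (two_sp - p.sigma0) / (1.0 - A) ** 2


def pore_energy(r, V_m, delta_eff, p: EPParams, steric: bool = True):
    """Pore energy W(r) (J): electric + steric + line + surface terms."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pore radius must be positive")
    V2 = _vsq(V_m, p) * p.U_ep**2
    W = -V2 * p.F_max * (r - p.r_h * np.log(r + p.r_h + p.r_t))
    if steric:
        W = W + p.steric_coeff * (p.r_star / r) ** 4
    W = W + 2.0 * np.pi * p.gamma * r - np.pi * np.asarray(delta_eff) * r**2
    return W


def pore_radius_rate(r, V_m, delta_eff, p: EPParams, steric: bool = True):
    """dr/dt (m/s) = -(D/kT) dW/dr, expanded:

    (D/kT) [ V^2 F_max / (1 + r_h/(r + r_t)) + 4 C r*^4 / r^5
             - 2 pi gamma + 2 pi delta_eff r ].
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pore radius must be positive")
    V2 = _vsq(V_m, p) * p.U_ep**2
    force = V2 * p.F_max / (1.0 + p.r_h / (r + p.r_t))
    if steric:
        force = force + 4.0 * p.steric_coeff * p.r_star**4 / r**5
    force = force - 2.0 * np.pi * p.gamma + 2.0 * np.pi * np.asarray(delta_eff) * r
    return (p.D_pore / (p.k_B * p.T)) * force


def ep_current_density(V_m, N, r, p: EPParams, d: float,
                       sigma_bulk: float | np.ndarray = None,
                       model: str = "access"):
    """Electroporation current density J_EP = N * i_pore (A m^-2).

    Per-pore current i_pore = V_m / (R_interior + R_access) with
    R_interior = d / (sigma_p pi r^2) and R_access = 1/(2 sigma_bulk r)
    (``model='ohmic'`` drops the access term). ``sigma_bulk`` is the mean of
    the conductivities on the two sides of the membrane.
    """
    return np.asarray(V_m) * areal_pore_conductance(N, r, p, d, sigma_bulk, model)


def areal_pore_conductance(N, r, p: EPParams, d: float,
                           sigma_bulk: float | np.ndarray = None,
                           model: str = "access"):
    """g_ep (S m^-2): N over the per-pore series resistance; linear in V_m."""
    N = np.asarray(N, dtype=float)
    r = np.asarray(r, dtype=float)
    R_int = d / (p.sigma_p * np.pi * r**2)
    if model == "access":
        if sigma_bulk is None:
            raise ValueError("access model needs sigma_bulk")
        R = R_int + 1.0 / (2.0 * np.asarray(sigma_bulk) * r)
    elif model == "ohmic":
        R = R_int
    else:
        raise ValueError(f"unknown pore current model {model!r}")
    return N / R


def advance_pores(state: PoreModelState, V_m: np.ndarray, dt: float,
                  p: EPParams, steric: bool = True,
                  max_rel_change: float = 0.05) -> PoreModelState:
    """Advance (N, r, A_frac) over dt at frozen V_m.

    N uses the exact exponential update of the linear-in-N creation ODE.
    Newly created density enters at r_star through an area-weighted radius
    merge; the radius then follows its ODE with adaptive explicit sub-steps
    bounded by ``max_rel_change`` relative change per sub-step.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    x = _vsq(V_m, p)
    # exact update of dN/dt = a - b N at frozen V over dt, evaluated as
    # N e^-z + a dt phi(z), phi(z) = (1-e^-z)/z, which neither overflows
    # (a <= alpha e^((2/U)^2) stays finite) nor cancels when z ~ 0
    a = p.alpha * np.exp(x)
    b = (p.alpha / p.N0) * np.exp((1.0 - p.q) * x)
    z = b * dt
    phi = np.where(z > 1e-8, -np.expm1(-z) / np.where(z > 0, z, 1.0), 1.0 - z / 2)
    N_new = state.N * np.exp(-z) + a * dt * phi
    N_new = np.maximum(N_new, 0.0)

    r = state.r_pore.copy()
    created = N_new - state.N
    grow = created > 0
    if np.any(grow):
        # area-weighted merge: incoming pores have radius r_star
        r2 = r[grow] ** 2 * state.N[grow] + p.r_star**2 * created[grow]
        r[grow] = np.sqrt(r2 / N_new[grow])
    r_floor = R_FLOOR_FRAC * p.r_star

    remaining = np.full_like(r, dt)
    for _ in range(10_000):
        active = remaining > 0
        if not np.any(active):
            break
        A = np.minimum(np.pi * r**2 * N_new, A_FRAC_CAP)
        delta_eff = effective_tension(A, p)
        rate = pore_radius_rate(np.maximum(r, r_floor), V_m, delta_eff, p, steric)
        # sub-step so each node's relative radius change stays bounded
        with np.errstate(divide="ignore"):
            dt_node = max_rel_change * r / np.maximum(np.abs(rate), 1e-300)
        h = np.minimum(remaining, np.where(active, dt_node, np.inf))
        h = np.where(active, np.maximum(h, 1e-18), 0.0)
        if np.any(active & (h < 1e-17) & (remaining > 1e-12 * dt)):
            raise RuntimeError("pore radius sub-step underflow "
                               f"(min h = {h[active].min():.3e} s)")
        r = np.where(active, np.maximum(r + rate * h, r_floor), r)
        remaining = remaining - h

    A = np.minimum(np.pi * r**2 * N_new, A_FRAC_CAP)
    return PoreModelState(N=N_new, r_pore=r, A_frac=A)
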