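"""Central parameter registry for the nsPEF + CNT electroporation model.

All quantities are stored in SI units. Defaults reproduce the published
five-layer single-cell model: the cell geometry (radii, membrane
thicknesses), the per-region dielectric properties, the asymptotic
electroporation constants, and the trapezoidal 6 kV/cm / 300 ns / 2 ns-rise
pulse. Entries that deviate from, or extend, the printed tables are recorded
in a machine-readable corrections ledger (``ModelParams.corrections``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from typing import Any

import numpy as np
import yaml


class ParamError(ValueError):
    """Raised when a parameter value violates a model invariant."""


@dataclass
class DielectricProps:
    """Bulk ohmic + dielectric properties of one homogeneous region."""

    sigma: float  # conductivity, S/m
    eps_r: float  # relative permittivity, dimensionless

    def validate(self, name: str) -> None:
        if not (self.sigma >= 0.0):
            raise ParamError(f"sigma_{name}: conductivity must be >= 0, got {self.sigma}")
        if not (self.eps_r >= 1.0):
            raise ParamError(f"eps_{name}: relative permittivity must be >= 1, got {self.eps_r}")


@dataclass
class EPParams:
    """Constants of the asymptotic electroporation (pore) model.

    ``alpha``, ``U_ep``, ``N0`` and ``q`` drive the pore-density ODE;
    ``r_star`` … ``steric_coeff`` parameterize the pore energy landscape whose
    gradient drives the pore-radius ODE; ``sigma_p`` sets the conductivity of
    the electrolyte filling a pore.
    """

    alpha: float = 1.0e9          # pore creation-rate coefficient, m^-2 s^-1
    U_ep: float = 0.170           # characteristic electroporation voltage, V
    N0: float = 1.5e9             # equilibrium pore density at rest, m^-2
    q: float = 2.46               # creation-rate exponent, dimensionless
    r_star: float = 0.8e-9        # minimum hydrophilic pore radius, m
    r_h: float = 0.97e-9          # advection-velocity geometry constant, m
    r_t: float = 0.31e-9          # advection-velocity geometry constant, m
    F_max: float = 0.7e-9         # max electric force on a pore at 1 V, N V^-2
    gamma: float = 1.8e-11        # pore edge (line) energy, J m^-1
    sigma_prime: float = 2.0e-2   # lipid-water interface tension, J m^-2
    sigma0: float = 1.0e-6        # membrane tension without pores, J m^-2
    D_pore: float = 5.0e-14       # pore-radius diffusion coefficient, m^2 s^-1
    k_B: float = 1.38e-23         # Boltzmann constant, J K^-1
    T: float = 295.0              # temperature, K
    sigma_p: float = 0.22         # pore-interior conductivity, S/m
    U_rest: float = -80e-3        # resting transmembrane potential, V
    steric_coeff: float = 1.4e-19  # steric repulsion energy coefficient, J

    def validate(self, name: str = "ep") -> None:
        for f_name in ("alpha", "U_ep", "N0", "q", "r_star", "r_h", "r_t", "F_max",
                       "gamma", "sigma_prime", "sigma0", "D_pore", "k_B", "T",
                       "sigma_p", "steric_coeff"):
            v = getattr(self, f_name)
            if not (v > 0.0):
                raise ParamError(f"{name}.{f_name}: must be strictly positive, got {v}")
        if not (self.U_rest < 0.0):
            raise ParamError(f"{name}.U_rest: resting potential must be negative, got {self.U_rest}")
        if not (self.r_star > self.r_t):
            raise ParamError(f"{name}.r_star: must exceed r_t ({self.r_t}), got {self.r_star}")


@dataclass
class PulseSpec:
    """Trapezoidal pulse: nominal field = applied voltage / electrode gap."""

    E_applied: float = 6.0e5   # plateau field, V/m (6 kV/cm)
    t_rise: float = 2.0e-9     # s
    t_width: float = 300.0e-9  # s
    t_fall: float = 2.0e-9     # s
    t_end: float = 400.0e-9    # total simulated time, s

    def validate(self) -> None:
        for f_name in ("E_applied", "t_rise", "t_width", "t_fall", "t_end"):
            v = getattr(self, f_name)
            if not (v >= 0.0):
                raise ParamError(f"pulse.{f_name}: must be non-negative, got {v}")
        if self.t_end < self.t_width + self.t_rise + self.t_fall:
            raise ParamError(
                f"pulse.t_end ({self.t_end}) must cover rise+width+fall "
                f"({self.t_width + self.t_rise + self.t_fall})")


@dataclass
class Geometry:
    """Cell and domain geometry (Table-1 values by default)."""

    r_c: float = 10e-6          # cell radius, m
    r_n: float = 5e-6           # nucleus radius, m
    d_mem: float = 5e-9         # plasma-membrane thickness, m
    d_ne: float = 40e-9         # nuclear-envelope thickness, m
    domain_side: float = 200e-6  # square domain side length, m

    def validate(self) -> None:
        for f_name in ("r_c", "r_n", "d_mem", "d_ne", "domain_side"):
            v = getattr(self, f_name)
            if not (v > 0.0):
                raise ParamError(f"geometry.{f_name}: must be positive, got {v}")
        if self.r_n >= self.r_c:
            raise ParamError(f"geometry.r_n ({self.r_n}) must be < r_c ({self.r_c})")
        if 2 * self.r_c >= self.domain_side:
            raise ParamError("geometry: cell does not fit inside the domain")


@dataclass
class CNTConfig:
    """Monte Carlo CNT capsule sampling configuration."""

    n: int = 5                     # capsules per scene
    L_min: float = 0.5e-6          # tip-to-tip length range, m
    L_max: float = 2.0e-6
    D_min: float = 20e-9           # diameter range, m
    D_max: float = 100e-9
    band_min: float = 11e-6        # radial band for capsule centers, m from cell center
    band_max: float = 25e-6
    clearance: float = 100e-9      # min capsule-capsule / capsule-membrane gap, m
    max_attempts: int = 10_000     # rejection budget per capsule

    def validate(self) -> None:
        if self.n < 0:
            raise ParamError(f"cnt.n: must be >= 0, got {self.n}")
        for lo, hi, nm in ((self.L_min, self.L_max, "L"), (self.D_min, self.D_max, "D"),
                           (self.band_min, self.band_max, "band")):
            if not (0 < lo <= hi):
                raise ParamError(f"cnt.{nm}_min/{nm}_max: need 0 < min <= max, got ({lo}, {hi})")
        if self.clearance <= 0:
            raise ParamError(f"cnt.clearance: must be positive, got {self.clearance}")


@dataclass
class MeshConfig:
    """Target element sizes for the graded triangulation."""

    h_far: float = 8e-6        # far-field element size, m
    h_membrane: float = 0.4e-6  # element size on membrane contours, m
    h_tip_frac: float = 0.35   # tip element size as a fraction of capsule radius
    min_angle_deg: float = 5.0  # mesh quality floor

    def validate(self) -> None:
        if not (0 < self.h_membrane <= self.h_far):
            raise ParamError("mesh: need 0 < h_membrane <= h_far")
        if not (0 < self.h_tip_frac <= 1.0):
            raise ParamError("mesh.h_tip_frac: must lie in (0, 1]")


@dataclass
class ModelParams:
    """Full registry: per-region dielectrics, electroporation constants,
    geometry, pulse, CNT sampling and meshing configuration, plus the
    machine-readable corrections ledger."""

    medium: DielectricProps = field(default_factory=lambda: DielectricProps(1.0, 80.0))
    cytoplasm: DielectricProps = field(default_factory=lambda: DielectricProps(0.3, 154.4))
    nucleoplasm: DielectricProps = field(default_factory=lambda: DielectricProps(1.35, 52.0))
    membrane: DielectricProps = field(default_factory=lambda: DielectricProps(3.0e-7, 8.57))
    nuclear_envelope: DielectricProps = field(default_factory=lambda: DielectricProps(6.0e-3, 28.0))
    cnt: DielectricProps = field(default_factory=lambda: DielectricProps(1.0e8, 1.0e4))
    pore: DielectricProps = field(default_factory=lambda: DielectricProps(0.22, 80.0))
    ep: EPParams = field(default_factory=EPParams)           # outer membrane
    ep_inner: EPParams = field(default_factory=EPParams)     # nuclear envelope (same constants)
    geometry: Geometry = field(default_factory=Geometry)
    pulse: PulseSpec = field(default_factory=PulseSpec)
    cnt_config: CNTConfig = field(default_factory=CNTConfig)
    mesh: MeshConfig = field(default_factory=MeshConfig)
    pore_current_model: str = "access"   # "access" | "ohmic"
    steric: bool = True
    corrections: list[dict[str, Any]] = field(default_factory=list)
    unused: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        for name, code in (("medium", "m"), ("cytoplasm", "c"), ("nucleoplasm", "np"),
                           ("membrane", "mem"), ("nuclear_envelope", "ne"),
                           ("cnt", "cnt"), ("pore", "pore")):
            getattr(self, name).validate(code)
        self.ep.validate("ep")
        self.ep_inner.validate("ep_inner")
        self.geometry.validate()
        self.pulse.validate()
        self.cnt_config.validate()
        self.mesh.validate()
        if self.pore_current_model not in ("access", "ohmic"):
            raise ParamError(f"pore_current_model: must be 'access' or 'ohmic', "
                             f"got {self.pore_current_model!r}")


EPS0 = 8.85e-12  # vacuum permittivity as printed in the source table, F/m


_CORRECTIONS = [
    {"symbol": "F (Faraday constant)", "printed": "9.65e-4 C/mol", "used": "9.6485e4 C/mol",
     "justification": "printed exponent is a typo; value unused by any implemented equation"},
    {"symbol": "R (gas constant)", "printed": "8314 J/(K mol)", "used": "8314 J/(K kmol)",
     "justification": "8314 is the kmol-based gas constant; unused by any implemented equation"},
    {"symbol": "r_t", "printed": "absent", "used": "0.31e-9 m",
     "justification": "required by the pore force term 1/(1+r_h/(r+r_t)); value from the "
                      "asymptotic pore-dynamics literature the model builds on"},
    {"symbol": "lambda (steric)", "printed": "no value", "used": "force 4*C*r_star^4/r^5, C=1.4e-19 J",
     "justification": "printed steric term '4*lambda*r^4*(1/r)' is dimensionally inconsistent "
                      "unless lambda carries units; standard asymptotic-model form adopted with "
                      "lambda := C*r_star^4"},
    {"symbol": "Q = 2.46", "printed": "'Pore creation rate'", "used": "q exponent of the pore-density ODE",
     "justification": "the ODE has exactly one unnamed exponent; mapping flagged, not silent"},
    {"symbol": "t_fall", "printed": "unspecified", "used": "2 ns (= t_rise)",
     "justification": "fall time not stated; symmetric trapezoid assumed"},
    {"symbol": "t_end", "printed": "unspecified", "used": "400 ns",
     "justification": "100 ns of post-pulse time so pore resealing is visible"},
]

_UNUSED = {
    "relative_pore_density": 0.15,   # 'Relative density of pores' — no implemented equation
    "energy_barrier_coeff": 2.65,    # 'Energy barrier coefficient of the pore' — no implemented equation
    "faraday_constant": 9.6485e4,    # C/mol, corrected; unused
    "gas_constant": 8314.0,          # J/(K kmol); unused
}


def default_params() -> ModelParams:
    """Registry loaded with the published defaults and populated corrections ledger."""
    p = ModelParams(corrections=[dict(c) for c in _CORRECTIONS], unused=dict(_UNUSED))
    p.validate()
    return p


def pulse_value(p: PulseSpec, t):
    """Trapezoidal pulse amplitude (V/m) at time(s) ``t`` (s).

    Zero for t <= 0, linear rise over ``t_rise``, flat plateau, linear fall
    ending at ``t_rise + t_width``, zero afterwards. Accepts scalars or arrays.
    """
    xp = [0.0, p.t_rise, p.t_rise + p.t_width - p.t_fall, p.t_rise + p.t_width]
    fp = [0.0, p.E_applied, p.E_applied, 0.0]
    out = np.interp(t, xp, fp, left=0.0, right=0.0)
    if np.isscalar(t):
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Flat key/unit/value config I/O
# ---------------------------------------------------------------------------

# unit name -> multiplier to SI
_UNITS = {
    "": 1.0, "1": 1.0, "-": 1.0,
    "S/m": 1.0, "V": 1.0, "mV": 1e-3, "V/m": 1.0, "kV/m": 1e3, "kV/cm": 1e5,
    "m": 1.0, "um": 1e-6, "µm": 1e-6, "μm": 1e-6, "nm": 1e-9,
    "s": 1.0, "us": 1e-6, "ns": 1e-9,
    "m^-2": 1.0, "1/m^2": 1.0, "m^-2 s^-1": 1.0,
    "J": 1.0, "J/m": 1.0, "J/m^2": 1.0, "J/K": 1.0, "K": 1.0,
    "N/V^2": 1.0, "m^2/s": 1.0,
}

# flat key -> (attribute path, SI unit label written on save)
_KEYS: dict[str, tuple[str, str]] = {
    "sigma_m": ("medium.sigma", "S/m"), "eps_m": ("medium.eps_r", ""),
    "sigma_c": ("cytoplasm.sigma", "S/m"), "eps_c": ("cytoplasm.eps_r", ""),
    "sigma_np": ("nucleoplasm.sigma", "S/m"), "eps_np": ("nucleoplasm.eps_r", ""),
    "sigma_mem": ("membrane.sigma", "S/m"), "eps_mem": ("membrane.eps_r", ""),
    "sigma_ne": ("nuclear_envelope.sigma", "S/m"), "eps_ne": ("nuclear_envelope.eps_r", ""),
    "sigma_cnt": ("cnt.sigma", "S/m"), "eps_cnt": ("cnt.eps_r", ""),
    "sigma_pore": ("pore.sigma", "S/m"), "eps_pore": ("pore.eps_r", ""),
    "alpha": ("ep.alpha", "m^-2 s^-1"), "U_ep": ("ep.U_ep", "V"),
    "N0": ("ep.N0", "m^-2"), "q": ("ep.q", ""),
    "r_star": ("ep.r_star", "m"), "r_h": ("ep.r_h", "m"), "r_t": ("ep.r_t", "m"),
    "F_max": ("ep.F_max", "N/V^2"), "gamma": ("ep.gamma", "J/m"),
    "sigma_prime": ("ep.sigma_prime", "J/m^2"), "sigma0": ("ep.sigma0", "J/m^2"),
    "D_pore": ("ep.D_pore", "m^2/s"), "k_B": ("ep.k_B", "J/K"), "T": ("ep.T", "K"),
    "sigma_p": ("ep.sigma_p", "S/m"), "U_rest": ("ep.U_rest", "V"),
    "steric_coeff": ("ep.steric_coeff", "J"),
    "r_c": ("geometry.r_c", "m"), "r_n": ("geometry.r_n", "m"),
    "d_mem": ("geometry.d_mem", "m"), "d_ne": ("geometry.d_ne", "m"),
    "domain_side": ("geometry.domain_side", "m"),
    "E_applied": ("pulse.E_applied", "V/m"), "t_rise": ("pulse.t_rise", "s"),
    "t_width": ("pulse.t_width", "s"), "t_fall": ("pulse.t_fall", "s"),
    "t_end": ("pulse.t_end", "s"),
    "n_cnts": ("cnt_config.n", ""),
    "cnt_L_min": ("cnt_config.L_min", "m"), "cnt_L_max": ("cnt_config.L_max", "m"),
    "cnt_D_min": ("cnt_config.D_min", "m"), "cnt_D_max": ("cnt_config.D_max", "m"),
    "cnt_band_min": ("cnt_config.band_min", "m"), "cnt_band_max": ("cnt_config.band_max", "m"),
    "cnt_clearance": ("cnt_config.clearance", "m"),
    "cnt_max_attempts": ("cnt_config.max_attempts", ""),
    "h_far": ("mesh.h_far", "m"), "h_membrane": ("mesh.h_membrane", "m"),
    "h_tip_frac": ("mesh.h_tip_frac", ""), "min_angle_deg": ("mesh.min_angle_deg", ""),
    "pore_current_model": ("pore_current_model", ""), "steric": ("steric", ""),
}


def _get_path(p: ModelParams, path: str):
    obj = p
    for part in path.split("."):
        obj = getattr(obj, part)
    return obj


def _set_path(p: ModelParams, path: str, value) -> None:
    parts = path.split(".")
    obj = p
    for part in parts[:-1]:
        obj = getattr(obj, part)
    cur = getattr(obj, parts[-1])
    if isinstance(cur, bool):
        value = bool(value)
    elif isinstance(cur, int) and not isinstance(cur, bool):
        value = int(value)
    elif isinstance(cur, float):
        value = float(value)
    setattr(obj, parts[-1], value)


def _parse_value(key: str, raw) -> Any:
    """Parse a config value: a bare number (SI) or a '<number> <unit>' string."""
    if isinstance(raw, bool) or isinstance(raw, (int, float)):
        return raw
    if isinstance(raw, str):
        parts = raw.split()
        if len(parts) == 1:
            try:
                return float(parts[0])
            except ValueError:
                return parts[0]  # enum-valued keys
        if len(parts) == 2:
            try:
                num = float(parts[0])
            except ValueError as exc:
                raise ParamError(f"{key}: cannot parse value {raw!r}") from exc
            unit = parts[1]
            if unit not in _UNITS:
                raise ParamError(f"{key}: unknown unit {unit!r}")
            return num * _UNITS[unit]
    raise ParamError(f"{key}: cannot parse value {raw!r}")


def save_params(p: ModelParams, path) -> None:
    """Write the registry as a flat key/value YAML document (SI units)."""
    lines = ["# nspefsim parameter file; values in SI units unless a unit suffix is given"]
    for key, (attr, unit) in _KEYS.items():
        val = _get_path(p, attr)
        if isinstance(val, bool):
            sval = "true" if val else "false"
        elif isinstance(val, float):
            sval = repr(val)
        else:
            sval = str(val)
        comment = f"  # {unit}" if unit else ""
        lines.append(f"{key}: {sval}{comment}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_params(path) -> ModelParams:
    """Load a config file: defaults overridden by any keys present.

    Unknown keys and invariant violations raise :class:`ParamError` naming
    the offending field.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ParamError(f"config {path}: expected a key/value mapping")
    p = default_params()
    for key, raw in doc.items():
        if key not in _KEYS:
            raise ParamError(f"unknown config key {key!r}")
        _set_path(p, _KEYS[key][0], _parse_value(key, raw))
    p.validate()
    return p


def corrections_table(p: ModelParams) -> str:
    """Human-readable rendering of the corrections ledger."""
    rows = ["symbol | printed | used | justification", "-" * 72]
    for c in p.corrections:
        rows.append(f"{c['symbol']} | {c['printed']} | {c['used']} | {c['justification']}")
    return "\n".join(rows)
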