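"""Derived quantities: field-strength area histograms, electroporated area
and permeabilized flux, the analytic tip-enhancement and induced-TMV
diagnostics.

Units note for the 2D model: the membrane contour integral S = sum of
pi r^2 N over contour length has units of area per unit out-of-plane depth
(m^2 per m, i.e. m); it is reported in um^2/um. Comparisons (with vs without
CNTs) are made within-model, where the unit convention cancels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .solver import SimResult, SolverContext, field_magnitude


@dataclass
class AreaHistogram:
    """Field-magnitude histogram weighted by triangle area."""

    bin_edges: np.ndarray   # V/m, length B+1
    fraction: np.ndarray    # area fraction per bin, sums to 1
    region: str


@dataclass
class PorationSummary:
    """Electroporated area S(t) and its running time integral (flux)."""

    t: np.ndarray
    S: np.ndarray      # pore area per unit depth, m
    flux: np.ndarray   # time integral of S, m*s
    membrane: str


def field_area_histogram(ctx: SolverContext, psi: np.ndarray,
                         region_mask: np.ndarray | None = None,
                         n_bins: int = 30, log_bins: bool = True,
                         region: str = "domain") -> AreaHistogram:
    """Bin per-triangle |E| weighted by triangle area, normalized to 1."""
    E, _ = field_magnitude(ctx, psi)
    area = ctx.area
    if region_mask is not None:
        if not region_mask.any():
            raise ValueError("empty region for histogram")
        E = E[region_mask]
        area = area[region_mask]
    e_max = float(E.max())
    e_min = max(float(E.min()), 1e-12 * e_max) if e_max > 0 else 1.0
    if e_max <= 0 or (e_max - e_min) < 1e-9 * e_max:
        # uniform field: center one bin on the value so it carries all area
        e_max = max(e_max, 1.0)
        w = 0.02 * e_max / n_bins
        edges = e_max + (np.arange(n_bins + 1) - (n_bins // 2) - 0.5) * w
    elif log_bins:
        lo = max(e_min, 1e-6 * e_max)
        edges = np.geomspace(lo, e_max, n_bins + 1)
        edges[0] = min(edges[0], e_min)
    else:
        edges = np.linspace(e_min, e_max, n_bins + 1)
    edges[-1] = np.nextafter(edges[-1], np.inf)
    idx = np.clip(np.searchsorted(edges, E, side="right") - 1, 0, n_bins - 1)
    frac = np.bincount(idx, weights=area, minlength=n_bins)
    frac = frac / frac.sum()
    return AreaHistogram(bin_edges=edges, fraction=frac, region=region)


def electroporated_area(result: SimResult, which: str = "outer_membrane") -> PorationSummary:
    """S(t) = discrete contour integral of pi r^2 N over the membrane."""
    mem = result.membranes[which]
    w = mem["lumped_len"]                        # (K,)
    S = (np.pi * mem["r_pore"] ** 2 * mem["N"]) @ w   # (T,)
    flux = cumulative_flux(result.times, S)
    return PorationSummary(t=result.times, S=S, flux=flux, membrane=which)


def cumulative_flux(t: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Cumulative trapezoidal integral of S over t (non-decreasing for S >= 0)."""
    out = np.zeros_like(S)
    out[1:] = np.cumsum(0.5 * (S[1:] + S[:-1]) * np.diff(t))
    return out


def permeabilized_flux(summary: PorationSummary) -> np.ndarray:
    return summary.flux


def tip_enhancement(L: float, D: float, beta: float, E0: float) -> float:
    """Field-emission estimate of the tip field: E_tip = beta (L/D) E0."""
    if L <= 0 or D <= 0 or E0 <= 0:
        raise ValueError("L, D, E0 must be positive")
    return beta * (L / D) * E0


def schwan_tmv(radius: float, E: float, theta, factor: float = 1.5):
    """Steady-state induced transmembrane voltage of an insulating shell:
    dphi = factor * radius * E * cos(theta). ``factor=1.5`` is the spherical
    (3D) coefficient; a 2D cylinder cross-section obeys ``factor=2.0``.

    The published relation states the coefficient against the cell
    *diameter*; the standard steady-state result uses the radius, which is
    what this function takes.
    """
    if radius < 0 or E < 0:
        raise ValueError("radius and E must be non-negative")
    return factor * radius * E * np.cos(theta)
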