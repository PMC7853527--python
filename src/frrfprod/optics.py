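"""Underwater light field: PAR attenuation, spectral irradiance and the SCF.

Three pieces:

* ``fit_kd`` — diffuse attenuation coefficient(s) of PAR from a depth profile,
  with automatic detection of a two-layer structure (the log-linear slope of
  E(z) changing at some depth).
* absorption budget + ``spectral_irradiance`` — Beer-Lambert propagation of
  the incident spectrum through water, CDOM, non-algal particles and
  phytoplankton absorption.
* ``spectral_correction_factor`` — reconciles the instrument excitation
  spectrum with the in-situ (or incubator) light spectrum through the
  phytoplankton absorption spectrum, as a ratio of plain grid sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .spectra import SpectrumOnGrid, aphy_star, water_absorption

KD_MINIMUM = 1e-6  # m^-1; floor for profiles with no measurable attenuation

CDOM_REFERENCE_NM = 320.0
CDOM_SLOPE = 0.017  # nm^-1
CDOM_A320 = {"north": 1.03, "south": 2.28}  # m^-1, basin averages

NAP_REFERENCE_NM = 440.0
NAP_SLOPE = 0.004  # nm^-1
NAP_A440 = 0.264  # m^-1


@dataclass(frozen=True)
class LayeredKd:
    """Diffuse PAR attenuation, one coefficient per layer.

    ``layer_breaks[i]`` is the top depth of layer i (ascending, starting at
    0); layer i spans [layer_breaks[i], layer_breaks[i+1]) and the deepest
    layer extends downward without bound.
    """

    layer_breaks: tuple[float, ...]
    kd_per_layer: tuple[float, ...]
    flagged: bool = False  # True when a K_d hit the lower clamp

    def __post_init__(self) -> None:
        breaks = tuple(float(b) for b in self.layer_breaks)
        kds = tuple(float(k) for k in self.kd_per_layer)
        object.__setattr__(self, "layer_breaks", breaks)
        object.__setattr__(self, "kd_per_layer", kds)
        if len(breaks) != len(kds):
            raise ValueError("need one break (layer top) per layer")
        if breaks[0] != 0.0:
            raise ValueError("layer breaks must start at 0")
        if any(a <= b for a, b in zip(breaks[1:], breaks[:-1])):
            raise ValueError("layer breaks must be ascending")
        if any(k <= 0 for k in kds):
            raise ValueError("all K_d must be positive")

    def attenuation(self, z: float | np.ndarray) -> np.ndarray:
        """E(z)/E(0): exponential decay accumulated through the layers."""
        z = np.atleast_1d(np.asarray(z, dtype=float))
        optical_depth = np.zeros_like(z)
        for i, kd in enumerate(self.kd_per_layer):
            top = self.layer_breaks[i]
            bottom = self.layer_breaks[i + 1] if i + 1 < len(self.layer_breaks) else np.inf
            thickness = np.clip(np.minimum(z, bottom) - top, 0.0, None)
            optical_depth += kd * thickness
        return np.exp(-optical_depth)

    def par_at(self, e0: float, z: float | np.ndarray) -> np.ndarray:
        return e0 * self.attenuation(z)


def _loglinear_kd(depths: np.ndarray, log_e: np.ndarray) -> tuple[float, float, float]:
    """Least-squares slope fit; returns (kd, intercept, rss)."""
    slope, intercept = np.polyfit(depths, log_e, 1)
    resid = log_e - (slope * depths + intercept)
    return -slope, intercept, float(resid @ resid)


def fit_kd(
    depths: np.ndarray,
    par: np.ndarray,
    alpha: float = 0.05,
    min_points_per_layer: int = 2,
) -> LayeredKd:
    """Fit K_d from a (depth, PAR) profile, allowing a two-layer structure.

    ln E is regressed on depth. Every observed depth is tried as a breakpoint
    (both segments keep the break point and need at least
    ``min_points_per_layer`` additional... at least ``min_points_per_layer+1``
    points each); the two-segment model is adopted when an F-test on the
    residual sum of squares is significant at ``alpha``.

    K_d estimates below ``KD_MINIMUM`` (no attenuation, or increasing light
    with depth) are clamped and the result flagged.
    """
    depths = np.asarray(depths, dtype=float)
    par = np.asarray(par, dtype=float)
    if depths.size != par.size or depths.size < 3:
        raise ValueError("need at least 3 (depth, PAR) points")
    if (par <= 0).any():
        raise ValueError("PAR values must be positive for a log-linear fit")
    order = np.argsort(depths)
    depths, par = depths[order], par[order]
    if np.unique(depths).size < 3:
        raise ValueError("need at least 3 distinct depths")
    log_e = np.log(par)

    kd1, _, rss1 = _loglinear_kd(depths, log_e)
    n = depths.size

    best = None  # (rss2, break_depth, kd_top, kd_bottom)
    for b in np.unique(depths)[1:-1]:
        top = depths <= b
        bottom = depths >= b
        if top.sum() < min_points_per_layer + 1 or bottom.sum() < min_points_per_layer + 1:
            continue
        kd_t, _, rss_t = _loglinear_kd(depths[top], log_e[top])
        kd_b, _, rss_b = _loglinear_kd(depths[bottom], log_e[bottom])
        rss2 = rss_t + rss_b
        if best is None or rss2 < best[0]:
            best = (rss2, float(b), kd_t, kd_b)

    two_layer = False
    if best is not None and n > 4:
        rss2 = best[0]
        if rss1 <= n * 1e-24:
            two_layer = False  # single layer already explains the profile
        elif rss2 <= n * 1e-24:
            two_layer = True  # exact two-segment fit of a truly broken profile
        else:
            f_stat = ((rss1 - rss2) / 2.0) / (rss2 / (n - 4))
            p = float(stats.f.sf(f_stat, 2, n - 4))
            two_layer = p < alpha

    def clamp(kd: float) -> tuple[float, bool]:
        return (kd, False) if kd >= KD_MINIMUM else (KD_MINIMUM, True)

    if two_layer and best is not None:
        _, break_depth, kd_t, kd_b = best
        kd_t, f1 = clamp(kd_t)
        kd_b, f2 = clamp(kd_b)
        return LayeredKd((0.0, break_depth), (kd_t, kd_b), flagged=f1 or f2)
    kd1, flagged = clamp(kd1)
    return LayeredKd((0.0,), (kd1,), flagged=flagged)


# ---------------------------------------------------------------------------
# Absorption budget and spectral irradiance
# ---------------------------------------------------------------------------


def a_cdom(wavelength: float | np.ndarray, basin: str) -> np.ndarray | float:
    """CDOM absorption (m^-1): a_CDOM(320) exp(-S (lambda - 320))."""
    if basin not in CDOM_A320:
        raise ValueError(f"unknown basin {basin!r}; expected one of {sorted(CDOM_A320)}")
    wavelength = np.asarray(wavelength, dtype=float)
    out = CDOM_A320[basin] * np.exp(-CDOM_SLOPE * (wavelength - CDOM_REFERENCE_NM))
    return out if out.ndim else float(out)


def a_nap(wavelength: float | np.ndarray) -> np.ndarray | float:
    """Non-algal particle absorption (m^-1): a_NAP(440) exp(-S (lambda - 440))."""
    wavelength = np.asarray(wavelength, dtype=float)
    out = NAP_A440 * np.exp(-NAP_SLOPE * (wavelength - NAP_REFERENCE_NM))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class AbsorptionBudget:
    """Component absorption spectra entering the underwater light model."""

    a_w: SpectrumOnGrid
    a_cdom: SpectrumOnGrid
    a_nap: SpectrumOnGrid
    a_phy_star: SpectrumOnGrid  # m^2 mg Chl-a^-1
    chl: float  # mg m^-3

    def __post_init__(self) -> None:
        for s in (self.a_cdom, self.a_nap, self.a_phy_star):
            if not self.a_w.same_grid(s):
                raise ValueError("all budget spectra must share one grid")
        if self.chl < 0:
            raise ValueError("chl must be non-negative")

    def total(self) -> SpectrumOnGrid:
        return SpectrumOnGrid(
            self.a_w.grid,
            self.a_w.values
            + self.a_cdom.values
            + self.a_nap.values
            + self.chl * self.a_phy_star.values,
        )


def absorption_budget(
    basin: str,
    chl: float,
    aphy_kind: str = "eukaryote",
    step: float = 1.0,
) -> AbsorptionBudget:
    """Assemble the default budget for a basin and chlorophyll concentration."""
    a_w = water_absorption(step)
    grid = a_w.grid
    return AbsorptionBudget(
        a_w=a_w,
        a_cdom=SpectrumOnGrid(grid, np.asarray(a_cdom(grid, basin))),
        a_nap=SpectrumOnGrid(grid, np.asarray(a_nap(grid))),
        a_phy_star=aphy_star(aphy_kind, step),
        chl=chl,
    )


def spectral_irradiance(
    e0_spectrum: SpectrumOnGrid,
    budget: AbsorptionBudget,
    z: float,
    observed_par: float | None = None,
) -> SpectrumOnGrid:
    """Beer-Lambert propagation of the surface spectrum to depth ``z``.

    When ``observed_par`` is given, the attenuated spectrum is rescaled so its
    trapezoid PAR integral matches the PAR measured at that depth.
    """
    if z < 0:
        raise ValueError("depth must be non-negative")
    if not e0_spectrum.same_grid(budget.a_w):
        raise ValueError("surface spectrum and budget must share one grid")
    attenuated = SpectrumOnGrid(
        e0_spectrum.grid, e0_spectrum.values * np.exp(-budget.total().values * z)
    )
    if observed_par is not None:
        attenuated = attenuated.normalised_to_par(observed_par)
    return attenuated


def spectral_correction_factor(
    a_phy: SpectrumOnGrid,
    e_insitu: SpectrumOnGrid,
    e_frrf: SpectrumOnGrid,
) -> float:
    """Spectral correction factor between ambient light and excitation flash.

    SCF = [sum(a*phy E_insitu) x sum(E_FRRf)] / [sum(a*phy E_FRRf) x sum(E_insitu)]
    with plain sums over the shared wavelength grid. Dimensionless; equals 1
    when the two light spectra are proportional or a*phy is flat.
    """
    if not (a_phy.same_grid(e_insitu) and a_phy.same_grid(e_frrf)):
        raise ValueError("SCF spectra must share one grid")
    num = float((a_phy.values * e_insitu.values).sum()) * e_frrf.grid_sum()
    den = float((a_phy.values * e_frrf.values).sum()) * e_insitu.grid_sum()
    if den <= 0 or e_insitu.grid_sum() <= 0:
        raise ValueError("SCF denominator sums must be positive")
    return num / den


def scf_at_depth(
    e0_spectrum: SpectrumOnGrid,
    budget: AbsorptionBudget,
    z: float,
    e_frrf: SpectrumOnGrid,
    observed_par: float | None = None,
) -> float:
    """SCF for an in-situ measurement at depth z (convenience composition)."""
    e_insitu = spectral_irradiance(e0_spectrum, budget, z, observed_par=observed_par)
    return spectral_correction_factor(budget.a_phy_star, e_insitu, e_frrf)
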