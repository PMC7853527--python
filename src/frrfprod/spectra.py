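"""Spectra on a fixed 400-700 nm grid.

`SpectrumOnGrid` is the common container for irradiance spectra
(umol photons m^-2 s^-1 nm^-1), absorption spectra (m^-1) and
chlorophyll-specific phytoplankton absorption (m^2 mg Chl-a^-1).

The generator functions at the bottom provide smooth synthetic stand-ins for
the literature spectral models (pure-water absorption, phytoplankton
absorption of cyanobacteria-dominated vs eukaryote-dominated communities,
instrument LED excitation, growth-chamber light, incident sunlight). They are
synthetic: shaped like the real curves but not reproducing any tabulated literature
coefficient set, so tests never depend on literature tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GRID_MIN = 400.0
GRID_MAX = 700.0


def default_grid(step: float = 1.0) -> np.ndarray:
    """Wavelength grid from 400 to 700 nm inclusive at a uniform step."""
    n = round((GRID_MAX - GRID_MIN) / step)
    if not np.isclose(GRID_MIN + n * step, GRID_MAX):
        raise ValueError(f"step {step} does not tile [400, 700] nm exactly")
    return GRID_MIN + step * np.arange(n + 1)


@dataclass(frozen=True)
class SpectrumOnGrid:
    """Non-negative function of wavelength on the 400-700 nm grid."""

    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "values", values)
        if grid.ndim != 1 or grid.size < 2 or values.shape != grid.shape:
            raise ValueError("grid and values must be matching 1-d arrays")
        steps = np.diff(grid)
        if not (steps > 0).all() or not np.allclose(steps, steps[0]):
            raise ValueError("grid must be strictly increasing with uniform step")
        if not (np.isclose(grid[0], GRID_MIN) and np.isclose(grid[-1], GRID_MAX)):
            raise ValueError("grid endpoints must be 400 and 700 nm")
        if not np.isfinite(values).all() or (values < 0).any():
            raise ValueError("spectrum values must be finite and non-negative")

    @property
    def step(self) -> float:
        return float(self.grid[1] - self.grid[0])

    def par_integral(self) -> float:
        """Trapezoid integral over 400-700 nm (PAR when values are irradiance)."""
        return float(np.trapezoid(self.values, self.grid))

    def grid_sum(self) -> float:
        """Plain sum over grid points (the summation operator of the SCF)."""
        return float(self.values.sum())

    def scaled(self, k: float) -> "SpectrumOnGrid":
        if k < 0:
            raise ValueError("scale factor must be non-negative")
        return SpectrumOnGrid(self.grid, self.values * k)

    def normalised_to_par(self, e0: float) -> "SpectrumOnGrid":
        """Rescale so the trapezoid PAR integral equals ``e0``."""
        total = self.par_integral()
        if total <= 0:
            raise ValueError("cannot normalise a zero spectrum")
        return self.scaled(e0 / total)

    def same_grid(self, other: "SpectrumOnGrid") -> bool:
        return self.grid.shape == other.grid.shape and np.allclose(self.grid, other.grid)

    # -- delimited-text I/O (two columns: wavelength_nm, value) --------------

    def write(self, path: str | Path) -> None:
        pd.DataFrame({"wavelength_nm": self.grid, "value": self.values}).to_csv(
            path, index=False
        )

    @classmethod
    def read(cls, path: str | Path) -> "SpectrumOnGrid":
        df = pd.read_csv(path)
        return cls(df["wavelength_nm"].to_numpy(), df["value"].to_numpy())


def _gaussian(grid: np.ndarray, centre: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((grid - centre) / width) ** 2)


# ---------------------------------------------------------------------------
# Synthetic spectral models (stand-ins shaped like the literature curves)
# ---------------------------------------------------------------------------


def water_absorption(step: float = 1.0) -> SpectrumOnGrid:
    """Synthetic pure-water absorption spectrum (m^-1).

    Exponential rise from ~0.004 m^-1 in the blue to ~0.7 m^-1 at 700 nm,
    mimicking the shape of measured pure-water absorption.
    """
    grid = default_grid(step)
    values = 0.004 * np.exp((grid - GRID_MIN) / 58.0)
    return SpectrumOnGrid(grid, values)


def aphy_star(kind: str = "eukaryote", step: float = 1.0) -> SpectrumOnGrid:
    """Synthetic Chl-a-specific phytoplankton absorption a*phy (m^2 mg^-1).

    ``kind='cyanobacteria'`` adds a phycocyanin shoulder near 625 nm in place
    of part of the red Chl-a peak; ``kind='eukaryote'`` is a classic
    two-peaked (440/675 nm) green-algae/diatom shape.
    """
    grid = default_grid(step)
    if kind == "cyanobacteria":
        values = (
            0.004
            + 0.020 * _gaussian(grid, 440.0, 32.0)
            + 0.012 * _gaussian(grid, 625.0, 22.0)
            + 0.008 * _gaussian(grid, 678.0, 12.0)
        )
    elif kind == "eukaryote":
        values = (
            0.003
            + 0.025 * _gaussian(grid, 440.0, 34.0)
            + 0.006 * _gaussian(grid, 490.0, 25.0)
            + 0.014 * _gaussian(grid, 675.0, 12.0)
        )
    else:
        raise ValueError(f"unknown a*phy kind {kind!r}")
    return SpectrumOnGrid(grid, values)


LED_PEAKS = {444: 18.0, 512: 16.0, 633: 16.0}


def led_spectrum(combination: tuple[int, ...] = (444, 512, 633), step: float = 1.0) -> SpectrumOnGrid:
    """Excitation-flash spectrum for a set of instrument LEDs.

    Each LED is a Gaussian line; the result is normalised to a unit PAR
    integral (only the shape matters in the spectral correction factor).
    """
    grid = default_grid(step)
    values = np.zeros_like(grid)
    for peak in combination:
        if peak not in LED_PEAKS:
            raise ValueError(f"no LED at {peak} nm (available: {sorted(LED_PEAKS)})")
        values = values + _gaussian(grid, float(peak), LED_PEAKS[peak])
    return SpectrumOnGrid(grid, values).normalised_to_par(1.0)


def chamber_spectrum(step: float = 1.0) -> SpectrumOnGrid:
    """Broad white growth-chamber light source, unit PAR integral."""
    grid = default_grid(step)
    values = (
        0.4
        + 0.8 * _gaussian(grid, 450.0, 30.0)
        + 1.0 * _gaussian(grid, 560.0, 70.0)
        + 0.5 * _gaussian(grid, 630.0, 40.0)
    )
    return SpectrumOnGrid(grid, values).normalised_to_par(1.0)


def generate_sunlight_spectrum(
    date_index: int,
    kind: str = "clear",
    e0: float = 1.0,
    step: float = 1.0,
) -> SpectrumOnGrid:
    """Synthetic incident-sunlight spectrum, normalised to PAR ``e0``.

    A Planck-like daylight envelope with a smooth, date-dependent modulation
    so that different sampling dates see (reproducibly) different spectral
    shapes. ``kind='overcast'`` flattens and blue-shifts the envelope.
    Deterministic in (date_index, kind).
    """
    if kind not in ("clear", "overcast"):
        raise ValueError("kind must be 'clear' or 'overcast'")
    grid = default_grid(step)
    # Planck radiance at T=5800 K, wavelength in m, arbitrary scale.
    lam = grid * 1e-9
    hc_over_kT = 6.62607015e-34 * 2.99792458e8 / (1.380649e-23 * 5800.0)
    envelope = lam**-5 / np.expm1(hc_over_kT / lam)
    envelope = envelope / envelope.max()
    phase = 2.0 * np.pi * (date_index % 14) / 14.0
    modulation = 1.0 + 0.08 * np.sin(2.0 * np.pi * (grid - GRID_MIN) / 300.0 + phase)
    values = envelope * modulation
    if kind == "overcast":
        values = values * (1.3 - 0.6 * (grid - GRID_MIN) / (GRID_MAX - GRID_MIN))
    return SpectrumOnGrid(grid, values).normalised_to_par(e0)
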