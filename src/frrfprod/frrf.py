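"""FRRf yields to photophysiology, RCII concentration and electron transport.

Works on tidy tables (one row per fluorescence observation) with the columns
documented in :data:`FRRF_COLUMNS`. The quality gate keeps observations whose
single-turnover closure probabilities (Rsigma) fall inside the instrument's
trustworthy band, inclusive at both ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import SIGMA_UNIT_SCALE
from .spectra import SpectrumOnGrid, led_spectrum

RSIGMA_LO = 0.03
RSIGMA_HI = 0.08

#: Expected columns of a raw FRRf table.
FRRF_COLUMNS = [
    "date",
    "station_id",
    "basin",
    "depth_m",
    "excitation_combo",
    "fo",
    "fm",
    "fo_prime",
    "fm_prime",
    "f_prime",
    "sigma_psii",
    "sigma_psii_prime",
    "rsigma_psii",
    "rsigma_psii_prime",
    "par",
]


@dataclass(frozen=True)
class InstrumentConfig:
    """Fluorometer constants entering the RCII and ETR calculations.

    kr: instrument constant K_R (photons m^-3 s^-1).
    e_frrf_power: excitation flashlet intensity E_FRRf (photons m^-2 s^-1).
    e_frrf_spectrum: spectral shape of the excitation flash.
    led_combination: LED peaks in use, subset of {444, 512, 633} nm.
    sigma_unit_scale: nm^2 <-> m^2 unit bridge applied inside J_f.
    """

    kr: float = 1.0e12
    e_frrf_power: float = 1.0
    e_frrf_spectrum: SpectrumOnGrid = field(default_factory=led_spectrum)
    led_combination: tuple[int, ...] = (444, 512, 633)
    sigma_unit_scale: float = SIGMA_UNIT_SCALE

    def __post_init__(self) -> None:
        if self.kr <= 0 or self.e_frrf_power <= 0:
            raise ValueError("K_R and E_FRRf must be positive")
        if self.e_frrf_spectrum.par_integral() <= 0:
            raise ValueError("excitation spectrum must integrate to a positive value")
        if not set(self.led_combination) <= {444, 512, 633}:
            raise ValueError("LED combination must be a subset of {444, 512, 633}")

    @property
    def kr_over_efrrf(self) -> float:
        return self.kr / self.e_frrf_power


def qc_filter(
    records: pd.DataFrame,
    lo: float = RSIGMA_LO,
    hi: float = RSIGMA_HI,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Partition an FRRf table by the Rsigma quality gate.

    Keeps rows with lo <= Rsigma_PSII <= hi and lo <= Rsigma_PSII' <= hi
    (bounds inclusive; the gate rejects strictly outside the band). Rows with
    a missing Rsigma are rejected with reason ``missing_rsigma``.

    Returns (kept, rejected, summary); ``rejected`` gains a ``reject_reason``
    column and ``summary`` reports N, medians and ranges of both Rsigma per
    excitation combination, plus a note column when a cyanobacteria fraction
    is present and large (the dark-state bias caveat: Fo of cyanobacteria can
    be overestimated after brief dark acclimation — flagged, not corrected).
    """
    records = records.copy()
    rs, rs_p = records["rsigma_psii"], records["rsigma_psii_prime"]
    missing = rs.isna() | rs_p.isna()
    in_band = rs.between(lo, hi) & rs_p.between(lo, hi)
    kept = records.loc[~missing & in_band].copy()
    rejected = records.loc[missing | ~in_band].copy()
    rejected["reject_reason"] = np.where(
        missing.loc[rejected.index], "missing_rsigma", "rsigma_out_of_band"
    )

    rows = []
    for combo, grp in kept.groupby("excitation_combo", sort=True):
        row = {
            "excitation_combo": combo,
            "n": len(grp),
            "rsigma_median": grp["rsigma_psii"].median(),
            "rsigma_min": grp["rsigma_psii"].min(),
            "rsigma_max": grp["rsigma_psii"].max(),
            "rsigma_prime_median": grp["rsigma_psii_prime"].median(),
            "rsigma_prime_min": grp["rsigma_psii_prime"].min(),
            "rsigma_prime_max": grp["rsigma_psii_prime"].max(),
        }
        if "fraction_cyanobacteria" in grp:
            row["n_cyanobacteria_dominated"] = int(
                (grp["fraction_cyanobacteria"] > 50.0).sum()
            )
        rows.append(row)
    summary = pd.DataFrame(rows)
    return kept, rejected, summary


def derive_photophys(records: pd.DataFrame) -> pd.DataFrame:
    """Add Fv/Fm, qP and NPQ_NSV columns derived from the raw yields.

    Fv/Fm = (Fm - Fo)/Fm, qP = (F' - Fo')/(Fm' - Fo'),
    NPQ_NSV = Fo'/(Fm' - Fo').

    Rows with Fm' == Fo' have an undefined qP/NPQ; they get ``qp_defined =
    False`` (NaN values) and should be excluded downstream.
    """
    out = records.copy()
    fv_prime = out["fm_prime"] - out["fo_prime"]
    defined = fv_prime > 0
    out["fv_fm"] = (out["fm"] - out["fo"]) / out["fm"]
    out["qp"] = np.where(defined, (out["f_prime"] - out["fo_prime"]) / fv_prime, np.nan)
    out["npq_nsv"] = np.where(defined, out["fo_prime"] / fv_prime, np.nan)
    out["qp_defined"] = defined
    return out


def rcii_concentration(
    fo: float | np.ndarray,
    sigma_psii: float | np.ndarray,
    instrument: InstrumentConfig,
) -> float | np.ndarray:
    """RCII concentration (nmol m^-3) from the dark minimum yield.

    RCII = K_R / E_FRRf x Fo / sigma_PSII x 1e-9.
    """
    sigma_psii = np.asarray(sigma_psii, dtype=float)
    if (sigma_psii <= 0).any():
        raise ValueError("sigma_PSII must be positive")
    out = instrument.kr_over_efrrf * np.asarray(fo, dtype=float) / sigma_psii * 1e-9
    return out if out.ndim else float(out)


def electron_transport(
    par: float | np.ndarray,
    sigma_psii_prime_scf: float | np.ndarray,
    qp: float | np.ndarray,
    sigma_unit_scale: float = SIGMA_UNIT_SCALE,
) -> float | np.ndarray:
    """RCII-specific electron transport rate J_f = E x sigma_PSII' x qP.

    ``sigma_psii_prime_scf`` is the SCF-adjusted cross-section in nm^2;
    ``sigma_unit_scale`` carries the nm^2/photon-flux unit bridge so J_f comes
    out in umol e- nmol RCII^-1 s^-1.
    """
    out = (
        np.asarray(par, dtype=float)
        * np.asarray(sigma_psii_prime_scf, dtype=float)
        * sigma_unit_scale
        * np.asarray(qp, dtype=float)
    )
    return out if out.ndim else float(out)


def photophys_table(
    records: pd.DataFrame,
    instrument: InstrumentConfig,
    scf: pd.Series | np.ndarray | float = 1.0,
) -> pd.DataFrame:
    """Full per-record photophysiology: yields -> qP, RCII, J_f, JV_f.

    ``scf`` is the spectral correction factor per row (or a scalar); it
    multiplies sigma_PSII' before the electron-transport product.
    """
    out = derive_photophys(records)
    if isinstance(scf, pd.Series):
        out["scf"] = scf
    else:
        out["scf"] = np.broadcast_to(np.asarray(scf, dtype=float), (len(out),)).copy()
    out = out.loc[out["qp_defined"]].copy()
    out["sigma_psii_prime_scf"] = out["sigma_psii_prime"] * out["scf"]
    out["rcii"] = rcii_concentration(
        out["fo"].to_numpy(), out["sigma_psii"].to_numpy(), instrument
    )
    out["j_f"] = electron_transport(
        out["par"].to_numpy(),
        out["sigma_psii_prime_scf"].to_numpy(),
        out["qp"].to_numpy(),
        instrument.sigma_unit_scale,
    )
    out["jv_f"] = out["j_f"] * out["rcii"]
    return out
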