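"""Synthetic field campaigns with known ground truth.

Generates internally consistent tables mirroring a two-basin lake campaign:
FRRf casts (four excitation-wavelength combinations), water-quality/PAR
profiles, bottle incubations (light-dark O2 and 13C tracer) and a truth table
of every latent quantity. The default scenario reproduces the reference field-campaign
design: 14 sampling dates (7 per basin) with the printed sub-surface PAR and
layered K_d of each date, covariates spanning the printed ancillary ranges,
and true electron-requirement coefficients equal to the field-calibrated best-model
estimates on the log-link scale.

Ground-truth structure: phi_e,C = exp(X beta) x gamma noise (mean 1, shape =
``phi_dispersion``), where X is the standardised log covariate matrix — the
exact error family and link the downstream GLM assumes, so coefficient
recovery is well-posed. The fluorescence observables are constructed so that
each date's RCII-specific electron transport J_f(E) lies on a Webb-form
photosynthesis-irradiance curve, making the whole chain (yields -> qP -> J_f
-> P-E fit -> phi) exactly invertible when noise is off.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import optics
from .constants import O2_TO_ELECTRON_FACTOR, PHI_CONVERSION_FACTOR
from .frrf import InstrumentConfig
from .incubation import LIGHT_LEVELS, NATURAL_13C_ATOM_PERCENT
from .optics import LayeredKd, absorption_budget
from .phimodel import CANDIDATE_TERMS, transform_standardise
from .spectra import SpectrumOnGrid, chamber_spectrum, generate_sunlight_spectrum, led_spectrum

__all__ = [
    "CovariateSpec",
    "DateSpec",
    "SyntheticScenario",
    "generate_campaign",
    "generate_sunlight_spectrum",
]

EXCITATION_COMBOS = ("444", "444+512", "444+633", "444+512+633")
ANALYSIS_COMBO = "444+512+633"

#: Per-combination medians of the closure probabilities (dark, ambient),
#: matching the field quality-control benchmarks.
RSIGMA_MEDIANS = {
    "444": (0.036, 0.037),
    "444+512": (0.039, 0.041),
    "444+633": (0.041, 0.043),
    "444+512+633": (0.045, 0.048),
}

#: Field-calibrated best-model coefficients on the log-link scale over standardised
#: log covariates; PAR was not in the best model, hence 0.
TRUE_PHI_COEFFICIENTS = {
    "intercept": 1.83,
    "temperature": 0.51,
    "par": 0.0,
    "turbidity": 0.10,
    "do_percent": 0.13,
    "nh4": -0.02,
    "no3_no2": 0.13,
    "po4": -0.02,
    "fv_fm": -0.10,
    "sigma_psii": 0.17,
    "chl_a": 0.10,
    "fraction_diatom": -0.11,
    "fraction_cyanobacteria": -0.20,
    "fraction_cryptophyte": 0.14,
}

STATION_BASIN = {"12B": "north", "17B": "north", "9B": "south", "6B": "south"}
STATION_BOTTOM = {"12B": 62.0, "17B": 89.0, "9B": 5.6, "6B": 4.0}

#: Incubator source depths per station (m), one per nominal light level.
SOURCE_DEPTHS = {
    "12B": (0.0, 0.0, 2.5, 5.0, 10.0),
    "17B": (0.0, 0.0, 2.5, 5.0, 10.0),
    "9B": (0.0, 0.0, 2.0, 2.0, 4.0),
    "6B": (0.0, 0.0, 2.0, 2.0, 3.0),
}


@dataclass(frozen=True)
class CovariateSpec:
    """Distribution of one covariate across the campaign.

    Values are drawn as low + (high - low) u with u in (0, 1) composed of a
    seasonal term (month-driven sinusoid, sign ``season_sign``), a per-date
    jitter and a linear vertical gradient (fraction of the range per metre).
    """

    low: float
    high: float
    season_sign: float = 0.0  # +1 peaks in summer, -1 in winter, 0 aseasonal
    vertical_gradient: float = 0.0  # d(u)/dz per metre
    jitter_sd: float = 0.08  # per-date jitter, fraction of range
    depth_jitter_sd: float = 0.06  # independent per-depth patchiness

    def __post_init__(self) -> None:
        if not (self.high > self.low):
            raise ValueError("degenerate covariate spec: need high > low")
        if self.jitter_sd < 0 or self.depth_jitter_sd < 0:
            raise ValueError("jitter standard deviations must be non-negative")


def default_covariate_generators() -> dict[str, CovariateSpec]:
    """Campaign covariate distributions matched to the field-observed ranges."""
    return {
        "temperature": CovariateSpec(7.5, 30.2, season_sign=1.0, vertical_gradient=-0.02,
                                     jitter_sd=0.12),
        "do_percent": CovariateSpec(79.0, 136.0, season_sign=0.2, vertical_gradient=-0.015,
                                    jitter_sd=0.18),
        "turbidity": CovariateSpec(0.1, 8.2, season_sign=0.2, vertical_gradient=0.012,
                                   jitter_sd=0.18),
        "chl_a": CovariateSpec(2.4, 41.9, season_sign=0.25, vertical_gradient=-0.012,
                               jitter_sd=0.18),
        "no3_no2": CovariateSpec(0.1, 7.1, season_sign=-0.35, vertical_gradient=0.012,
                                 jitter_sd=0.18),
        "nh4": CovariateSpec(0.05, 1.3, season_sign=-0.25, vertical_gradient=0.01,
                             jitter_sd=0.18),
        "po4": CovariateSpec(0.01, 0.04, season_sign=0.0, vertical_gradient=0.006,
                             jitter_sd=0.18),
        "fv_fm": CovariateSpec(0.30, 0.65, season_sign=-0.2, vertical_gradient=0.012,
                               jitter_sd=0.18),
        "sigma_psii": CovariateSpec(2.5, 8.0, season_sign=0.2, vertical_gradient=0.008,
                                    jitter_sd=0.18),
        "fraction_diatom": CovariateSpec(5.0, 60.0, season_sign=0.25, vertical_gradient=0.0,
                                         jitter_sd=0.18),
        "fraction_cyanobacteria": CovariateSpec(0.5, 15.0, season_sign=0.3,
                                                vertical_gradient=0.0, jitter_sd=0.18),
        "fraction_cryptophyte": CovariateSpec(0.5, 10.0, season_sign=-0.2,
                                              vertical_gradient=0.0, jitter_sd=0.18),
        "fraction_zygnematophyte": CovariateSpec(0.5, 25.0, season_sign=0.2,
                                                 vertical_gradient=0.0, jitter_sd=0.18),
    }

BLOOM_OVERRIDES = {
    "fraction_cyanobacteria": CovariateSpec(60.0, 75.0),
    "fraction_diatom": CovariateSpec(2.0, 10.0),
    "fraction_cryptophyte": CovariateSpec(0.5, 5.0),
    "fraction_zygnematophyte": CovariateSpec(0.5, 5.0),
}


@dataclass(frozen=True)
class DateSpec:
    """One sampling date: station, light field and sky condition."""

    date: str  # ISO date
    station_id: str
    e0: float  # sub-surface PAR, umol photons m^-2 s^-1
    kd: LayeredKd
    sky: str = "clear"
    bloom: bool = False  # cyanobacteria-dominated (phycobilin absorption)

    @property
    def basin(self) -> str:
        return STATION_BASIN[self.station_id]

    @property
    def month(self) -> int:
        return int(self.date.split("-")[1])


def default_dates() -> tuple[DateSpec, ...]:
    """The 14-date two-basin campaign with its tabulated field E_0 and K_d."""
    def d(date, st, e0, *layers, sky="clear", bloom=False):
        breaks = tuple(b for b, _ in layers)
        kds = tuple(k for _, k in layers)
        return DateSpec(date, st, e0, LayeredKd(breaks, kds), sky=sky, bloom=bloom)

    return (
        d("2018-07-23", "12B", 1630.0, (0.0, 0.433)),
        d("2018-07-30", "17B", 705.0, (0.0, 0.328)),
        d("2018-08-28", "9B", 650.0, (0.0, 1.727), (2.0, 0.971), bloom=True),
        d("2018-09-13", "12B", 440.0, (0.0, 0.541), (6.0, 0.261)),
        d("2018-09-18", "6B", 124.0, (0.0, 1.029), sky="overcast"),
        d("2018-10-10", "9B", 176.0, (0.0, 1.001), sky="overcast"),
        d("2018-10-25", "9B", 1090.0, (0.0, 0.881)),
        d("2018-11-16", "12B", 901.0, (0.0, 1.198), (2.0, 0.375)),
        d("2018-12-10", "6B", 221.0, (0.0, 1.117), sky="overcast"),
        d("2018-12-19", "17B", 255.0, (0.0, 0.451), (6.0, 0.224)),
        d("2019-01-28", "9B", 235.0, (0.0, 1.029), (2.0, 0.387), sky="overcast"),
        d("2019-02-07", "12B", 279.0, (0.0, 0.536), (2.0, 0.252)),
        d("2019-04-19", "9B", 445.0, (0.0, 1.916), (1.0, 0.607)),
        d("2019-05-10", "12B", 1711.0, (0.0, 0.894), (2.0, 0.263)),
    )


@dataclass(frozen=True)
class SyntheticScenario:
    """Complete specification of a synthetic campaign."""

    seed: int = 0
    dates: tuple[DateSpec, ...] = field(default_factory=default_dates)
    true_phi_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(TRUE_PHI_COEFFICIENTS)
    )
    phi_dispersion: float = 5.0  # gamma shape; np.inf disables phi noise
    covariate_generators: dict[str, CovariateSpec] = field(
        default_factory=default_covariate_generators
    )
    frrf_noise_cv: float = 0.05
    instrument: InstrumentConfig = field(default_factory=InstrumentConfig)
    replicates: int = 5
    combos: tuple[str, ...] = EXCITATION_COMBOS
    rsigma_medians: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(RSIGMA_MEDIANS)
    )
    qp_scale: float = 0.8  # open fraction in the low-light limit
    sigma_prime_ratio: float = 0.9  # sigma_PSII' / sigma_PSII under ambient light
    incubation_duration_h: float = 3.0

    def __post_init__(self) -> None:
        if not self.phi_dispersion > 0:
            raise ValueError("phi_dispersion (gamma shape) must be positive")
        if self.frrf_noise_cv < 0:
            raise ValueError("frrf_noise_cv must be non-negative")
        if self.replicates < 1:
            raise ValueError("need at least one replicate per depth")
        for name, spec in self.covariate_generators.items():
            if not isinstance(spec, CovariateSpec):
                raise ValueError(f"covariate generator for {name!r} is not a CovariateSpec")

    @classmethod
    def noise_free(cls, seed: int = 0) -> "SyntheticScenario":
        """Self-consistency configuration: all noise off, flat depth profiles.

        Vertical covariate gradients are zeroed so the electron requirement is
        constant within each date's P-E fit group; the pipeline then inverts
        the generator exactly (round trip to numerical precision).
        """
        gens = {
            name: replace(spec, vertical_gradient=0.0, depth_jitter_sd=0.0)
            for name, spec in default_covariate_generators().items()
        }
        return cls(
            seed=seed,
            phi_dispersion=np.inf,
            frrf_noise_cv=0.0,
            covariate_generators=gens,
        )


def _stream(seed: int, *keys: object) -> np.random.Generator:
    """Counter-based stream splitting: one child stream per string key path."""
    key = zlib.crc32("|".join(str(k) for k in keys).encode())
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def _season_weight(month: int) -> float:
    """0 in mid-winter to 1 in mid-summer (northern hemisphere)."""
    return 0.5 - 0.5 * np.cos(2.0 * np.pi * (month - 1.5) / 12.0)


class _CampaignBuilder:
    def __init__(self, scenario: SyntheticScenario):
        self.sc = scenario
        self.chamber = chamber_spectrum()
        # per-(date, covariate) jitters, drawn independently of table order
        self._jitter: dict[tuple[int, str], float] = {}
        # per-depth patchiness on a canonical 0.25 m grid, so a covariate
        # evaluated at the same depth agrees across different depth grids
        self._depth_jitter: dict[tuple[int, str], np.ndarray] = {}
        for i, _ in enumerate(scenario.dates):
            rng = _stream(scenario.seed, "covariate_jitter", i)
            for name in sorted(self._generators(scenario.dates[i])):
                self._jitter[(i, name)] = float(rng.normal(0.0, 1.0))
                self._depth_jitter[(i, name)] = rng.normal(0.0, 1.0, size=81)

    def _generators(self, date: DateSpec) -> dict[str, CovariateSpec]:
        gens = dict(self.sc.covariate_generators)
        if date.bloom:
            for name, spec in BLOOM_OVERRIDES.items():
                if name in gens:
                    gens[name] = replace(
                        spec,
                        vertical_gradient=gens[name].vertical_gradient,
                        jitter_sd=gens[name].jitter_sd,
                        depth_jitter_sd=gens[name].depth_jitter_sd,
                    )
        return gens

    def covariate(self, i_date: int, name: str, z: np.ndarray) -> np.ndarray:
        """Deterministic covariate field at depth(s) z for one date."""
        date = self.sc.dates[i_date]
        spec = self._generators(date)[name]
        u = self._u(i_date, name, z)
        if name == "fraction_zygnematophyte":
            # zygnematophytes wax when diatoms wane: a collinear (rho ~ -0.7)
            # pair for the screen to resolve, diatoms acting as the proxy
            u_diat = self._u(i_date, "fraction_diatom", z)
            u = np.clip(1.0 - u_diat + (u - 0.5), 0.02, 0.98)
        return spec.low + (spec.high - spec.low) * u

    def _u(self, i_date: int, name: str, z: np.ndarray) -> np.ndarray:
        date = self.sc.dates[i_date]
        spec = self._generators(date)[name]
        z = np.asarray(z, dtype=float)
        u = (
            0.5
            + 0.45 * spec.season_sign * (2.0 * _season_weight(date.month) - 1.0)
            + spec.jitter_sd * self._jitter[(i_date, name)]
            + spec.vertical_gradient * z
        )
        if spec.depth_jitter_sd > 0:
            idx = np.clip(np.rint(z / 0.25).astype(int), 0, 80)
            u = u + spec.depth_jitter_sd * self._depth_jitter[(i_date, name)][idx]
        return np.clip(u, 0.02, 0.98)

    # -- depth grids --------------------------------------------------------

    def sampling_depths(self, date: DateSpec) -> np.ndarray:
        if date.basin == "north":
            return np.array([0.0, 2.5, 5.0, 7.5, 10.0, 12.5, 15.0, 17.5])
        bottom = min(STATION_BOTTOM[date.station_id], 5.5)
        return np.arange(0.0, bottom + 1e-9, 0.5)

    def profile_depths(self, date: DateSpec) -> np.ndarray:
        top = self.sampling_depths(date)[-1]
        return np.arange(0.0, top + 1e-9, 0.5)

    # -- optical chain ------------------------------------------------------

    def aphy_kind(self, date: DateSpec) -> str:
        return "cyanobacteria" if date.bloom else "eukaryote"

    def scf_at(self, i_date: int, z: float, chl: float) -> float:
        date = self.sc.dates[i_date]
        budget = absorption_budget(date.basin, chl, self.aphy_kind(date))
        e0_spec = generate_sunlight_spectrum(i_date, date.sky, e0=date.e0)
        return optics.scf_at_depth(
            e0_spec, budget, z, self.sc.instrument.e_frrf_spectrum
        )

    def scf_chamber(self, i_date: int, chl: float) -> float:
        date = self.sc.dates[i_date]
        budget = absorption_budget(date.basin, chl, self.aphy_kind(date))
        return optics.spectral_correction_factor(
            budget.a_phy_star, self.chamber, self.sc.instrument.e_frrf_spectrum
        )


def _combo_sensitivity(combo: str, fraction_cyano: np.ndarray) -> np.ndarray:
    """Fluorescence sensitivity of an excitation combination.

    Combinations lacking the 633 nm (phycocyanin-targeting) LED under-excite
    cyanobacteria, scaling the whole fluorescence signal down in proportion to
    the cyanobacterial share of the community.
    """
    if "633" in combo:
        return np.ones_like(np.asarray(fraction_cyano, dtype=float))
    return 1.0 - 0.5 * np.asarray(fraction_cyano, dtype=float) / 100.0


def generate_campaign(
    scenario: SyntheticScenario,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (frrf_table, profile_table, incubation_table, truth_table).

    Identical scenarios (same seed) give bit-identical tables. The truth
    table records every latent quantity per analysis-combination record:
    phi_e_c, J_f, JV_f, RCII, PB_C, qP, SCF and the candidate covariates.
    """
    b = _CampaignBuilder(scenario)
    sc = scenario
    cov_names = CANDIDATE_TERMS[:]  # the 13 candidates; par filled from K_d
    extra_names = ["fraction_zygnematophyte"]

    # ---- latent per-record table (analysis combination) -------------------
    latent_rows = []
    for i, date in enumerate(sc.dates):
        depths = b.sampling_depths(date)
        par = date.kd.par_at(date.e0, depths)
        cov = {
            name: b.covariate(i, name, depths)
            for name in cov_names + extra_names
            if name not in ("par", "fv_fm", "sigma_psii")
        }
        cov["fv_fm"] = b.covariate(i, "fv_fm", depths)
        cov["sigma_psii"] = b.covariate(i, "sigma_psii", depths)
        scf = np.array([b.scf_at(i, z, c) for z, c in zip(depths, cov["chl_a"])])
        for j, z in enumerate(depths):
            for r in range(sc.replicates):
                row = {
                    "i_date": i,
                    "date": date.date,
                    "station_id": date.station_id,
                    "basin": date.basin,
                    "depth_m": float(z),
                    "replicate": r,
                    "par": float(par[j]),
                    "scf": float(scf[j]),
                }
                for name in cov:
                    row[name] = float(cov[name][j])
                latent_rows.append(row)
    latent = pd.DataFrame(latent_rows)

    # ---- true electron requirement ----------------------------------------
    x, _ = transform_standardise(latent, cov_names)
    beta = sc.true_phi_coefficients
    eta = np.full(len(latent), float(beta.get("intercept", 0.0)))
    for name in cov_names:
        eta += float(beta.get(name, 0.0)) * x[name].to_numpy()
    phi = np.exp(eta)
    if np.isfinite(sc.phi_dispersion):
        rng = _stream(sc.seed, "phi_noise")
        phi = phi * rng.gamma(sc.phi_dispersion, 1.0 / sc.phi_dispersion, size=len(phi))
    latent["phi_e_c"] = phi

    # ---- per-date Webb electron-transport curves --------------------------
    scale = sc.instrument.sigma_unit_scale
    latent["sigma_psii_prime"] = latent["sigma_psii"] * sc.sigma_prime_ratio
    latent["s_eff"] = latent["sigma_psii_prime"] * latent["scf"] * scale
    date_curves = {}
    for i, date in enumerate(sc.dates):
        grp = latent.loc[latent["i_date"] == i]
        alpha_j = sc.qp_scale * float(grp["s_eff"].min())
        e_k = date.e0 / 3.0
        date_curves[i] = (alpha_j, alpha_j * e_k)  # (alpha, J_s)

    def j_curve(i: int, e: np.ndarray) -> np.ndarray:
        alpha_j, j_s = date_curves[i]
        return j_s * -np.expm1(-alpha_j * np.asarray(e, dtype=float) / j_s)

    latent["j_f"] = j_curve(0, latent["par"].to_numpy()) * 0.0
    for i in range(len(sc.dates)):
        m = latent["i_date"] == i
        latent.loc[m, "j_f"] = j_curve(i, latent.loc[m, "par"].to_numpy())
    latent["qp"] = latent["j_f"] / (latent["par"] * latent["s_eff"])
    latent["pb_c"] = latent["j_f"] / latent["phi_e_c"] * PHI_CONVERSION_FACTOR

    # ---- fluorescence yields ----------------------------------------------
    latent["fm"] = 0.03 * latent["chl_a"]
    latent["fo"] = latent["fm"] * (1.0 - latent["fv_fm"])
    npq_boost = 1.0 + latent["par"] / 400.0  # ambient-light quenching rises with E
    latent["fo_prime"] = latent["fo"]
    latent["fm_prime"] = latent["fo"] + (latent["fm"] - latent["fo"]) / npq_boost
    latent["f_prime"] = latent["fo_prime"] + latent["qp"] * (
        latent["fm_prime"] - latent["fo_prime"]
    )
    latent["rcii"] = (
        sc.instrument.kr_over_efrrf * latent["fo"] / latent["sigma_psii"] * 1e-9
    )
    latent["jv_f"] = latent["j_f"] * latent["rcii"]

    # ---- FRRf table over excitation combinations --------------------------
    frrf_parts = []
    yield_cols = ["fo", "fm", "fo_prime", "fm_prime", "f_prime"]
    for combo in sc.combos:
        part = latent[
            ["date", "station_id", "basin", "depth_m", "replicate", "par"]
        ].copy()
        part.insert(4, "excitation_combo", combo)
        n = len(part)
        # measurement noise enters through the latent photophysiology, so the
        # reconstructed yields stay internally consistent (Fm >= F' >= Fo')
        fm = latent["fm"].to_numpy()
        fv_fm = latent["fv_fm"].to_numpy()
        qp = latent["qp"].to_numpy()
        boost = npq_boost.to_numpy()
        sigma = latent["sigma_psii"].to_numpy()
        sigma_p = latent["sigma_psii_prime"].to_numpy()
        med_dark, med_amb = sc.rsigma_medians[combo]
        if sc.frrf_noise_cv > 0:
            rng = _stream(sc.seed, "frrf_noise", combo)
            cv = sc.frrf_noise_cv
            fm = fm * rng.lognormal(0.0, cv, n)
            fv_fm = np.clip(fv_fm * rng.lognormal(0.0, cv, n), 0.02, 0.95)
            qp = np.clip(qp * rng.lognormal(0.0, cv, n), 0.0, 1.0)
            boost = 1.0 + (boost - 1.0) * rng.lognormal(0.0, cv, n)
            sigma = sigma * rng.lognormal(0.0, cv, n)
            sigma_p = sigma_p * rng.lognormal(0.0, cv, n)
            part["rsigma_psii"] = med_dark + rng.uniform(-0.008, 0.014, n)
            part["rsigma_psii_prime"] = med_amb + rng.uniform(-0.008, 0.014, n)
        else:
            part["rsigma_psii"] = med_dark
            part["rsigma_psii_prime"] = med_amb
        sens = _combo_sensitivity(combo, latent["fraction_cyanobacteria"].to_numpy())
        fm = fm * sens
        fo = fm * (1.0 - fv_fm)
        fo_prime = fo
        fm_prime = fo + (fm - fo) / boost
        part["fo"] = fo
        part["fm"] = fm
        part["fo_prime"] = fo_prime
        part["fm_prime"] = fm_prime
        part["f_prime"] = fo_prime + qp * (fm_prime - fo_prime)
        part["sigma_psii"] = sigma
        part["sigma_psii_prime"] = sigma_p
        frrf_parts.append(part)
    frrf_table = pd.concat(frrf_parts, ignore_index=True)

    # ---- profile table ------------------------------------------------------
    profile_rows = []
    for i, date in enumerate(sc.dates):
        grid = b.profile_depths(date)
        par = date.kd.par_at(date.e0, grid)
        cols = {
            name: b.covariate(i, name, grid)
            for name in [
                "temperature", "do_percent", "turbidity", "chl_a",
                "nh4", "no3_no2", "po4",
                "fraction_diatom", "fraction_cyanobacteria",
                "fraction_cryptophyte", "fraction_zygnematophyte",
            ]
        }
        for j, z in enumerate(grid):
            row = {
                "date": date.date,
                "station_id": date.station_id,
                "basin": date.basin,
                "depth_m": float(z),
                "par": float(par[j]),
            }
            for name, vals in cols.items():
                row[name] = float(vals[j])
            profile_rows.append(row)
    profile_table = pd.DataFrame(profile_rows)

    # ---- incubation table ---------------------------------------------------
    inc_rows = []
    for i, date in enumerate(sc.dates):
        source = SOURCE_DEPTHS[date.station_id]
        grp0 = latent.loc[(latent["i_date"] == i) & (latent["replicate"] == 0)]
        grp0 = grp0.set_index("depth_m")
        chl0 = float(grp0["chl_a"].iloc[0])
        scf_ch = b.scf_chamber(i, chl0)
        for level, z_src in zip(LIGHT_LEVELS, source):
            src = grp0.loc[z_src]
            e_bottle = level * date.e0 * scf_ch
            alpha_j, j_s = date_curves[i]
            j_b = float(j_s * -np.expm1(-alpha_j * e_bottle / j_s))
            pb_b = j_b / float(src["phi_e_c"]) * PHI_CONVERSION_FACTOR
            rcii_src = float(src["rcii"])
            gp_b = pb_b * rcii_src  # mg C m^-3 h^-1
            jv_b = j_b * rcii_src  # umol e- m^-3 s^-1
            gross_o2 = jv_b / O2_TO_ELECTRON_FACTOR  # mg O2 m^-3 h^-1
            resp = 0.1 * gross_o2 + 2.0
            dur = sc.incubation_duration_h
            o2_0 = 8000.0
            poc = 50.0 * float(src["chl_a"])
            atom_nat = NATURAL_13C_ATOM_PERCENT
            atom_dic = atom_nat + 9.9  # ~10% of ambient DIC spiked as 13C
            atom_inc = atom_nat + gp_b * dur / poc * (atom_dic - atom_nat)
            inc_rows.append(
                {
                    "date": date.date,
                    "station_id": date.station_id,
                    "basin": date.basin,
                    "light_level": level,
                    "source_depth_m": z_src,
                    "e_incubator_scf": e_bottle,
                    "scf_chamber": scf_ch,
                    "o2_start_light": o2_0,
                    "o2_end_light": o2_0 + (gross_o2 - resp) * dur,
                    "o2_start_dark": o2_0,
                    "o2_end_dark": o2_0 - resp * dur,
                    "poc": poc,
                    "dic": 900.0,
                    "atom13c_natural": atom_nat,
                    "atom13c_dic_enriched": atom_dic,
                    "atom13c_incubated": atom_inc,
                    "duration_h": dur,
                }
            )
    incubation_table = pd.DataFrame(inc_rows)

    # ---- truth table --------------------------------------------------------
    truth_cols = (
        ["date", "station_id", "basin", "depth_m", "replicate", "par", "scf"]
        + [c for c in cov_names if c != "par"]
        + extra_names
        + ["phi_e_c", "qp", "j_f", "jv_f", "rcii", "pb_c",
           "sigma_psii_prime", "fv_fm"]
    )
    truth_table = latent[list(dict.fromkeys(truth_cols))].copy()
    truth_table["npq_nsv"] = (
        latent["fo_prime"] / (latent["fm_prime"] - latent["fo_prime"])
    )
    return frrf_table, profile_table, incubation_table, truth_table
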