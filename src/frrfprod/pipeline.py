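"""End-to-end orchestration: campaign tables to phi model and daily GPP.

Stage order mirrors the measurement chain: QC gate -> spectral correction ->
photophysiology/ETR -> incubation productivity -> P-E fits -> electron
requirement per record -> stratified bootstrap + gamma GLM (all-subsets AIC)
-> daily depth-integrated GPP by the fluorescence and 13C routes.

Every stage's output table is kept on the result object and (optionally)
written as CSV; a manifest records the seed, a config digest and a digest of
every table, so identical configurations yield identical manifests.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import optics
from .constants import PHI_CONVERSION_FACTOR
from .frrf import qc_filter, photophys_table
from .gpp import DEPTH_STEP, DailyGppInput, daily_gpp, half_sine_par, pb_f_from_phi, relative_gpp
from .incubation import productivity_table
from .pecurve import PhotosynthesisIrradianceModel, phi_e_c
from .phimodel import (
    AUXILIARY_TERMS,
    CANDIDATE_TERMS,
    ElectronRequirementModel,
    collinearity_screen,
    default_schemes,
    rank_all_submodels,
    stratified_bootstrap,
)
from .spectra import generate_sunlight_spectrum
from .synthetic import ANALYSIS_COMBO, SyntheticScenario, generate_campaign


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration of a full synthetic-campaign run."""

    scenario: SyntheticScenario = field(default_factory=SyntheticScenario)
    bootstrap_seed: int = 1
    analysis_combo: str = ANALYSIS_COMBO
    rsigma_lo: float = 0.03
    rsigma_hi: float = 0.08
    rho_cutoff: float = 0.7
    vif_bound: float = 10.0
    photoinhibition_tol: float = 0.05
    rank_submodels: bool = True
    run_gpp: bool = True
    day_length_h: int = 12
    outdir: str | None = None
    schemes: dict | None = None  # basin -> BootstrapScheme; None = defaults

    def digest(self) -> str:
        payload = {
            "scenario": repr(self.scenario),
            "bootstrap_seed": self.bootstrap_seed,
            "analysis_combo": self.analysis_combo,
            "rsigma": [self.rsigma_lo, self.rsigma_hi],
            "rho_cutoff": self.rho_cutoff,
            "vif_bound": self.vif_bound,
            "photoinhibition_tol": self.photoinhibition_tol,
            "rank_submodels": self.rank_submodels,
            "run_gpp": self.run_gpp,
            "day_length_h": self.day_length_h,
            "schemes": repr(self.schemes),
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


@dataclass
class PipelineResult:
    """Bundle of every stage's tables, fits and the run manifest."""

    frrf_table: pd.DataFrame
    profile_table: pd.DataFrame
    incubation_table: pd.DataFrame
    truth_table: pd.DataFrame
    qc_kept: pd.DataFrame
    qc_rejected: pd.DataFrame
    qc_summary: pd.DataFrame
    records: pd.DataFrame  # photophysiology + covariates + phi per record
    productivity: pd.DataFrame
    pe_fits: dict  # date -> dict of PECurveResults ('pb_c', 'j_f')
    phi_records: pd.DataFrame
    bootstrap: pd.DataFrame
    screen: object
    glm_full: object
    ranking: object | None
    gpp_table: pd.DataFrame | None
    warnings: list[str]
    manifest: dict

    @property
    def manifest_hash(self) -> str:
        return self.manifest["hash"]


def _table_digest(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()


def _date_index(scenario: SyntheticScenario) -> dict[str, int]:
    return {d.date: i for i, d in enumerate(scenario.dates)}


def _scf_for_records(records: pd.DataFrame, profile: pd.DataFrame,
                     scenario: SyntheticScenario) -> pd.Series:
    """Spectral correction factor per record, from the campaign's light model.

    The phytoplankton absorption model follows community composition: the
    cyanobacteria-type spectrum when the date-mean cyanobacterial biomass
    fraction exceeds 50%, the eukaryote-type otherwise.
    """
    idx = _date_index(scenario)
    cyano_mean = profile.groupby("date")["fraction_cyanobacteria"].mean()
    out = np.empty(len(records))
    cache: dict[tuple, float] = {}
    dates = {d.date: d for d in scenario.dates}
    for pos, (_, row) in enumerate(records.iterrows()):
        key = (row["date"], row["depth_m"], row["chl_a"])
        if key not in cache:
            spec_date = dates[row["date"]]
            kind = "cyanobacteria" if cyano_mean.loc[row["date"]] > 50.0 else "eukaryote"
            budget = optics.absorption_budget(row["basin"], row["chl_a"], kind)
            e0_spec = generate_sunlight_spectrum(idx[row["date"]], spec_date.sky, e0=spec_date.e0)
            cache[key] = optics.scf_at_depth(
                e0_spec, budget, row["depth_m"], scenario.instrument.e_frrf_spectrum
            )
        out[pos] = cache[key]
    return pd.Series(out, index=records.index, name="scf")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full chain on a synthetic campaign. Pure in (config, seeds)."""
    sc = config.scenario
    warnings_log: list[str] = []

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        return wrap

    frrf_table, profile_table, incubation_table, truth_table = stage("simulate")(
        lambda: generate_campaign(sc)
    )

    qc_kept, qc_rejected, qc_summary = stage("qc")(
        lambda: qc_filter(frrf_table, config.rsigma_lo, config.rsigma_hi)
    )

    def _records():
        rec = qc_kept.loc[qc_kept["excitation_combo"] == config.analysis_combo].copy()
        if rec.empty:
            raise ValueError(f"no kept rows for combination {config.analysis_combo!r}")
        env_cols = [
            "temperature", "do_percent", "turbidity", "chl_a", "nh4", "no3_no2",
            "po4", "fraction_diatom", "fraction_cyanobacteria",
            "fraction_cryptophyte", "fraction_zygnematophyte",
        ]
        rec = rec.merge(
            profile_table[["date", "station_id", "depth_m"] + env_cols],
            on=["date", "station_id", "depth_m"],
            how="left",
            validate="many_to_one",
        )
        if rec[env_cols].isna().any().any():
            raise ValueError("FRRf depths missing from the profile table")
        scf = _scf_for_records(rec, profile_table, sc)
        return photophys_table(rec, sc.instrument, scf)

    records = stage("optics")(_records)

    def _productivity():
        rcii_by_depth = (
            records.groupby(["date", "depth_m"])["rcii"].mean().rename("rcii_source")
        )
        inc = incubation_table.merge(
            rcii_by_depth,
            left_on=["date", "source_depth_m"],
            right_index=True,
            how="left",
        )
        if inc["rcii_source"].isna().any():
            raise ValueError("incubation source depth has no FRRf-derived RCII")
        return productivity_table(inc, inc["rcii_source"])

    productivity = stage("incubation")(_productivity)

    def _pe_fits():
        fits: dict[str, dict] = {}
        for date, grp in productivity.groupby("date"):
            pb_fit = PhotosynthesisIrradianceModel(
                grp["e_incubator_scf"], grp["pb_c"], form="auto",
                photoinhibition_tol=config.photoinhibition_tol,
            ).fit()
            rec = records.loc[records["date"] == date]
            jf_fit = PhotosynthesisIrradianceModel(
                rec["par"], rec["j_f"], form="auto",
                photoinhibition_tol=config.photoinhibition_tol,
            ).fit()
            if not (pb_fit.converged and jf_fit.converged):
                warnings_log.append(f"P-E fit did not converge on {date}")
            fits[date] = {"pb_c": pb_fit, "j_f": jf_fit}
        return fits

    pe_fits = stage("pe_fit")(_pe_fits)

    def _phi_records():
        rec = records.copy()
        rec["pb_c_at_e"] = np.nan
        for date, grp in rec.groupby("date"):
            rec.loc[grp.index, "pb_c_at_e"] = pe_fits[date]["pb_c"].predict(
                grp["par"].to_numpy()
            )
        bad = rec["pb_c_at_e"] <= 0
        if bad.any():
            warnings_log.append(f"dropped {int(bad.sum())} records with PB_C <= 0")
            rec = rec.loc[~bad]
        rec["phi_e_c"] = phi_e_c(rec["j_f"].to_numpy(), rec["pb_c_at_e"].to_numpy())
        n_apparent = int((rec["phi_e_c"] < 4.0).sum())
        if n_apparent:
            warnings_log.append(
                f"{n_apparent} records with apparent phi_e_c < 4 retained in analysis"
            )
        return rec

    phi_records = stage("phi")(_phi_records)

    bootstrap = stage("phi_glm")(
        lambda: stratified_bootstrap(
            phi_records, config.schemes or default_schemes(), config.bootstrap_seed
        )
    )

    screen = stage("phi_glm")(
        lambda: collinearity_screen(
            bootstrap,
            [c for c in CANDIDATE_TERMS + AUXILIARY_TERMS if c in bootstrap],
            rho_threshold=config.rho_cutoff,
        )
    )

    def _glm():
        terms = [c for c in CANDIDATE_TERMS if c in screen.retained]
        model = ElectronRequirementModel.from_dataframe(bootstrap, terms)
        res = model.fit()
        high_vif = res.vif[res.vif >= config.vif_bound]
        if len(high_vif):
            warnings_log.append(f"VIF >= {config.vif_bound} for {list(high_vif.index)}")
        return model, res

    glm_model, glm_full = stage("phi_glm")(_glm)

    ranking = None
    if config.rank_submodels:
        ranking = stage("phi_glm")(
            lambda: rank_all_submodels(
                glm_model.phi, glm_model.x, transform=glm_model.transform
            )
        )

    gpp_table = None
    if config.run_gpp:
        gpp_table = stage("gpp")(
            lambda: _gpp_stage(config, records, profile_table, pe_fits, glm_full, ranking)
        )

    tables = {
        "frrf": frrf_table,
        "profiles": profile_table,
        "incubations": incubation_table,
        "truth": truth_table,
        "qc_kept": qc_kept,
        "records": records,
        "productivity": productivity,
        "phi_records": phi_records,
        "bootstrap": bootstrap,
    }
    if gpp_table is not None:
        tables["gpp"] = gpp_table
    manifest = {
        "seed": sc.seed,
        "bootstrap_seed": config.bootstrap_seed,
        "config_digest": config.digest(),
        "tables": {k: _table_digest(v) for k, v in tables.items()},
        "counts": {k: len(v) for k, v in tables.items()},
        "warnings": list(warnings_log),
    }
    manifest["hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()

    result = PipelineResult(
        frrf_table=frrf_table,
        profile_table=profile_table,
        incubation_table=incubation_table,
        truth_table=truth_table,
        qc_kept=qc_kept,
        qc_rejected=qc_rejected,
        qc_summary=qc_summary,
        records=records,
        productivity=productivity,
        pe_fits=pe_fits,
        phi_records=phi_records,
        bootstrap=bootstrap,
        screen=screen,
        glm_full=glm_full,
        ranking=ranking,
        gpp_table=gpp_table,
        warnings=warnings_log,
        manifest=manifest,
    )
    if config.outdir is not None:
        write_outputs(result, config.outdir)
    return result


def _phi_models(glm_full, ranking) -> dict[str, object]:
    models = {"full": glm_full}
    if ranking is not None:
        models = {
            "best": ranking.best,
            "model2": ranking.best_without_nutrients,
            "model3": ranking.best_without_nutrients_and_phyto,
        }
        models = {k: v for k, v in models.items() if v is not None}
    return models


def _gpp_stage(config, records, profile_table, pe_fits, glm_full, ranking) -> pd.DataFrame:
    """Daily GPP per date from the fluorescence and 13C routes."""
    sc = config.scenario
    models = _phi_models(glm_full, ranking)
    rows = []
    for spec in sc.dates:
        date = spec.date
        prof = profile_table.loc[profile_table["date"] == date]
        rec = records.loc[records["date"] == date]
        if rec.empty:
            continue
        kd = optics.fit_kd(prof["depth_m"].to_numpy(), prof["par"].to_numpy())
        step = DEPTH_STEP[spec.basin]
        z_max = float(rec["depth_m"].max())
        grid = np.arange(0.0, z_max + 1e-9, step)
        if grid[-1] < z_max:
            grid = np.append(grid, z_max)

        by_depth = rec.groupby("depth_m").mean(numeric_only=True)
        z_obs = by_depth.index.to_numpy()
        rcii_z = np.interp(grid, z_obs, by_depth["rcii"].to_numpy())

        # covariates on the integration grid, for the phi-model prediction
        cov = {}
        for c in CANDIDATE_TERMS:
            if c in prof.columns:
                cov[c] = np.interp(grid, prof["depth_m"].to_numpy(), prof[c].to_numpy())
            elif c in by_depth.columns:
                cov[c] = np.interp(grid, z_obs, by_depth[c].to_numpy())
        cov_df = pd.DataFrame(cov)

        hours = half_sine_par(spec.e0, config.day_length_h)
        e_zt = kd.attenuation(grid)[:, None] * hours[None, :]

        pb13 = pe_fits[date]["pb_c"].predict(e_zt)
        gpp_13c = daily_gpp(DailyGppInput(spec.basin, grid, rcii_z, pb13))

        row = {"date": date, "station_id": spec.station_id, "basin": spec.basin,
               "gpp_13c": gpp_13c}
        for name, model in models.items():
            phi_pred = model.predict_from_raw(cov_df.assign(par=np.clip(cov_df["par"], 1e-6, None)))
            j_zt = pe_fits[date]["j_f"].predict(e_zt)
            pb_f = pb_f_from_phi(j_zt, phi_pred[:, None])
            gpp_f = daily_gpp(DailyGppInput(spec.basin, grid, rcii_z, pb_f))
            row[f"gpp_f_{name}"] = gpp_f
            row[f"ratio_{name}"] = relative_gpp(gpp_f, gpp_13c)
        rows.append(row)
    return pd.DataFrame(rows)


def write_outputs(result: PipelineResult, outdir: str | Path) -> None:
    """Write every stage table and the manifest under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    named = {
        "frrf.csv": result.frrf_table,
        "profiles.csv": result.profile_table,
        "incubations.csv": result.incubation_table,
        "truth.csv": result.truth_table,
        "qc_kept.csv": result.qc_kept,
        "qc_rejected.csv": result.qc_rejected,
        "qc_summary.csv": result.qc_summary,
        "records.csv": result.records,
        "productivity.csv": result.productivity,
        "phi_records.csv": result.phi_records,
        "bootstrap.csv": result.bootstrap,
    }
    if result.gpp_table is not None:
        named["gpp.csv"] = result.gpp_table
    for name, df in named.items():
        df.to_csv(out / name, index=False)
    if result.ranking is not None:
        table = result.ranking.table.copy()
        table["terms"] = table["terms"].map(lambda t: "+".join(t) if t else "(intercept)")
        table.to_csv(out / "ranking.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# Excitation-combination comparison report
# ---------------------------------------------------------------------------


def excitation_report(config: PipelineConfig) -> dict:
    """Compare the excitation-wavelength combinations on one campaign.

    Returns per-combination QC statistics (N kept, Rsigma medians/ranges),
    dark-yield (Fo) depth profiles for the bloom dates, and the volumetric
    electron transport of each combination against the oxygen-based rate
    JV_O at the incubator light levels.
    """
    sc = config.scenario
    frrf_table, profile_table, incubation_table, _ = generate_campaign(sc)
    kept, _, summary = qc_filter(frrf_table, config.rsigma_lo, config.rsigma_hi)

    bloom_dates = [d.date for d in sc.dates if d.bloom]
    fo_profiles = (
        kept.loc[kept["date"].isin(bloom_dates)]
        .groupby(["date", "excitation_combo", "depth_m"])["fo"]
        .median()
        .reset_index()
    )

    env = profile_table[["date", "station_id", "depth_m", "chl_a"]]
    overlays = []
    for combo in sc.combos:
        rec = kept.loc[kept["excitation_combo"] == combo].merge(
            env, on=["date", "station_id", "depth_m"], how="left"
        )
        scf = _scf_for_records(
            rec.assign(basin=rec["basin"]), profile_table, sc
        )
        phys = photophys_table(rec, sc.instrument, scf)
        jv = (
            phys.groupby(["date", "depth_m"])[["par", "jv_f"]]
            .median()
            .reset_index()
            .assign(excitation_combo=combo)
        )
        overlays.append(jv)
    jv_f_by_combo = pd.concat(overlays, ignore_index=True)

    rcii_by_depth = (
        photophys_table(
            kept.loc[kept["excitation_combo"] == ANALYSIS_COMBO].merge(
                env, on=["date", "station_id", "depth_m"], how="left"
            ),
            sc.instrument,
            1.0,
        )
        .groupby(["date", "depth_m"])["rcii"]
        .mean()
        .rename("rcii_source")
    )
    inc = incubation_table.merge(
        rcii_by_depth, left_on=["date", "source_depth_m"], right_index=True, how="left"
    )
    jv_o_table = productivity_table(inc, inc["rcii_source"])[
        ["date", "station_id", "basin", "light_level", "e_incubator_scf", "jv_o"]
    ]
    return {
        "qc_summary": summary,
        "fo_profiles": fo_profiles,
        "jv_f_by_combo": jv_f_by_combo,
        "jv_o": jv_o_table,
    }
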