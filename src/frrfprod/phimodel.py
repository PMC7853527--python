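"""Statistical model for the electron requirement for carbon fixation.

The response (phi_e_c, mol e- mol C^-1, strictly positive and right-skewed)
is modelled with a gamma GLM and log link over standardised log-transformed
covariates. The surrounding procedure:

1. stratified bootstrap — equal per-date resampling from fixed depth strata,
   removing the sampling bias against bright shallow layers;
2. Spearman collinearity screen (|rho| >= 0.7 and p < 0.05);
3. detection-limit substitution, log transform, z-standardisation;
4. gamma GLM fit with VIF diagnostics;
5. all-subsets enumeration ranked by AIC, with named extracts for the best
   model, the best without nutrients, and the best without nutrients and
   phytoplankton composition.

`ElectronRequirementModel` / `ElectronRequirementResults` follow the
statsmodels Model/Results idiom; the GLM itself is fitted by statsmodels.
"""

from __future__ import annotations

import itertools
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

#: The candidate covariates of the phi model, in screening priority order.
CANDIDATE_TERMS = [
    "temperature",
    "par",
    "turbidity",
    "do_percent",
    "nh4",
    "no3_no2",
    "po4",
    "fv_fm",
    "sigma_psii",
    "chl_a",
    "fraction_diatom",
    "fraction_cyanobacteria",
    "fraction_cryptophyte",
]

#: Auxiliary covariates screened out as proxies of retained ones.
AUXILIARY_TERMS = ["npq_nsv", "rcii", "fraction_zygnematophyte"]

NUTRIENT_TERMS = {"nh4", "no3_no2", "po4"}
PHYTOPLANKTON_TERMS = {"fraction_diatom", "fraction_cyanobacteria", "fraction_cryptophyte"}

#: Detection-limit substitutions applied before the log transform.
DETECTION_LIMITS = {
    "nh4": 0.1,  # umol L^-1
    "fraction_diatom": 0.1,  # percent of community biomass
    "fraction_cyanobacteria": 0.1,
    "fraction_cryptophyte": 0.1,
    "fraction_zygnematophyte": 0.1,
}


# ---------------------------------------------------------------------------
# Stratified bootstrap
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BootstrapScheme:
    """Per-date resampling design: (depth_min, depth_max, n_resample) strata."""

    basin: str
    strata: tuple[tuple[float, float, int], ...]

    @property
    def n_per_date(self) -> int:
        return sum(n for _, _, n in self.strata)

    @classmethod
    def north(cls) -> "BootstrapScheme":
        return cls("north", ((0.0, 3.75, 60), (3.75, 7.5, 60), (7.5, 12.5, 60), (12.5, 17.5, 60)))

    @classmethod
    def south(cls) -> "BootstrapScheme":
        return cls("south", ((0.0, 1.0, 80), (1.0, 3.0, 80), (3.0, 5.5, 80)))


def default_schemes() -> dict[str, BootstrapScheme]:
    return {"north": BootstrapScheme.north(), "south": BootstrapScheme.south()}


def _stratum_seed(seed: int, date: str, i_stratum: int) -> np.random.Generator:
    """Reproducible per-(date, stratum) stream, independent of iteration order."""
    key = zlib.crc32(f"{date}|{i_stratum}".encode())
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def stratified_bootstrap(
    records: pd.DataFrame,
    schemes: dict[str, BootstrapScheme] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Resample records with replacement, per date and depth stratum.

    Each date contributes exactly its basin scheme's ``n_per_date`` rows. A
    stratum is [depth_min, depth_max); the deepest stratum of a scheme is
    closed on the right. Raises if any (date, stratum) has no source rows.
    """
    schemes = schemes or default_schemes()
    chunks = []
    for (date, basin), grp in records.groupby(["date", "basin"], sort=True):
        if basin not in schemes:
            raise ValueError(f"no bootstrap scheme for basin {basin!r}")
        scheme = schemes[basin]
        for i, (lo, hi, n) in enumerate(scheme.strata):
            last = i == len(scheme.strata) - 1
            depth = grp["depth_m"]
            mask = (depth >= lo) & ((depth <= hi) if last else (depth < hi))
            pool = grp.loc[mask]
            if pool.empty:
                raise ValueError(
                    f"empty bootstrap stratum [{lo}, {hi}] m on {date} ({basin})"
                )
            rng = _stratum_seed(seed, str(date), i)
            idx = rng.integers(0, len(pool), size=n)
            chunks.append(pool.iloc[idx])
    out = pd.concat(chunks, ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# Collinearity screen and transformation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreenResult:
    retained: tuple[str, ...]
    dropped: tuple[str, ...]
    flagged_pairs: tuple[tuple[str, str, float], ...]  # (kept, dropped-or-peer, rho)
    rho: pd.DataFrame
    p_values: pd.DataFrame
    constant_columns: tuple[str, ...]


def collinearity_screen(
    covariates: pd.DataFrame,
    terms: list[str] | None = None,
    rho_threshold: float = 0.7,
    alpha: float = 0.05,
) -> ScreenResult:
    """Spearman collinearity screen over candidate covariates.

    Pairs with |rho| >= 0.7 and p < 0.05 are flagged; for each flagged pair
    the column listed later in ``terms`` is dropped, so the priority list
    encodes which member acts as the proxy (e.g. a diatom fraction retained as
    proxy for a collinear zygnematophyte fraction). Constant columns have an
    undefined rho and are reported separately (and dropped).
    """
    if terms is None:
        terms = [c for c in CANDIDATE_TERMS + AUXILIARY_TERMS if c in covariates]
    data = covariates[terms]
    if len(data) < 3:
        raise ValueError("need at least 3 rows for a Spearman screen")

    constant = tuple(c for c in terms if data[c].nunique() <= 1)
    live = [c for c in terms if c not in constant]
    if len(live) >= 3:
        rho, p = stats.spearmanr(data[live].to_numpy(), axis=0)
    elif len(live) == 2:
        r, pv = stats.spearmanr(data[live[0]], data[live[1]])
        rho = np.array([[1.0, r], [r, 1.0]])
        p = np.array([[0.0, pv], [pv, 0.0]])
    else:
        rho = np.eye(len(live))
        p = np.zeros((len(live), len(live)))
    rho_df = pd.DataFrame(rho, index=live, columns=live)
    p_df = pd.DataFrame(p, index=live, columns=live)

    dropped: list[str] = list(constant)
    flagged: list[tuple[str, str, float]] = []
    for i, a in enumerate(live):
        for j in range(i + 1, len(live)):
            b = live[j]
            r = float(rho_df.loc[a, b])
            if abs(r) >= rho_threshold and float(p_df.loc[a, b]) < alpha:
                flagged.append((a, b, r))
                if b not in dropped and a not in dropped:
                    dropped.append(b)
    retained = tuple(c for c in terms if c not in dropped)
    return ScreenResult(retained, tuple(dropped), tuple(flagged), rho_df, p_df, constant)


@dataclass(frozen=True)
class TransformInfo:
    """Log-standardisation parameters, kept for predicting on new raw data."""

    terms: tuple[str, ...]
    means: pd.Series  # of log-transformed covariates
    sds: pd.Series
    detection_limits: dict[str, float] = field(default_factory=dict)

    def apply(self, df: pd.DataFrame) -> pd.DataFrame:
        x = df[list(self.terms)].astype(float).copy()
        for col, lod in self.detection_limits.items():
            if col in x:
                x[col] = x[col].clip(lower=lod)
        if (x <= 0).any().any():
            bad = [c for c in x if (x[c] <= 0).any()]
            raise ValueError(f"non-positive values before log transform in {bad}")
        logged = np.log(x)
        return (logged - self.means) / self.sds


def transform_standardise(
    covariates: pd.DataFrame,
    terms: list[str] | None = None,
    detection_limits: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, TransformInfo]:
    """Detection-limit substitution, natural log, then per-column z-scoring.

    Returns the model matrix (mean 0, sd 1 per column) and the
    :class:`TransformInfo` needed to apply the identical transform to new
    data. A constant column (sd = 0) is an error.
    """
    if terms is None:
        terms = [c for c in CANDIDATE_TERMS if c in covariates]
    lods = DETECTION_LIMITS if detection_limits is None else detection_limits
    lods = {k: v for k, v in lods.items() if k in terms}

    x = covariates[terms].astype(float).copy()
    for col, lod in lods.items():
        x[col] = x[col].clip(lower=lod)
    if (x <= 0).any().any():
        bad = [c for c in x if (x[c] <= 0).any()]
        raise ValueError(f"non-positive values before log transform in {bad}")
    logged = np.log(x)
    means = logged.mean()
    sds = logged.std(ddof=1)
    degenerate = sds[sds == 0].index.tolist()
    if degenerate:
        raise ValueError(f"constant columns cannot be standardised: {degenerate}")
    info = TransformInfo(tuple(terms), means, sds, lods)
    return (logged - means) / sds, info


# ---------------------------------------------------------------------------
# Gamma GLM model object
# ---------------------------------------------------------------------------


def _vif(exog: pd.DataFrame) -> pd.Series:
    """Variance inflation factors via the OLS R^2 of each term on the rest."""
    out = {}
    x = sm.add_constant(exog, has_constant="add")
    for col in exog.columns:
        others = x.drop(columns=[col])
        r2 = sm.OLS(x[col], others).fit().rsquared
        out[col] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


@dataclass
class ElectronRequirementResults:
    """Fitted gamma GLM for phi_e_c with the diagnostics the procedure reports."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    aic: float
    pseudo_r2_pearson: float
    pseudo_r2_deviance: float
    vif: pd.Series
    n: int
    terms: tuple[str, ...]
    transform: TransformInfo | None = None
    _glm_results: object | None = None

    def predict(self, x: pd.DataFrame) -> np.ndarray:
        """Mean phi_e_c at already-standardised covariates."""
        exog = sm.add_constant(x[list(self.terms)], has_constant="add")
        return np.asarray(self._glm_results.predict(exog))

    def predict_from_raw(self, df: pd.DataFrame) -> np.ndarray:
        """Mean phi_e_c at raw covariates, via the stored transform."""
        if self.transform is None:
            raise ValueError("model was built from a pre-standardised matrix")
        return self.predict(self.transform.apply(df))

    def summary(self) -> str:
        table = pd.DataFrame(
            {
                "Coefficient": self.params,
                "Std. Error": self.bse,
                "t value": self.tvalues,
                "P": self.pvalues,
            }
        )
        vif = self.vif.reindex(table.index)
        table["VIF"] = vif
        lines = [
            "Gamma GLM (log link) for the electron requirement for carbon fixation",
            f"n = {self.n}   AIC = {self.aic:.1f}   "
            f"R2(Pearson) = {self.pseudo_r2_pearson:.3f}   "
            f"R2(deviance) = {self.pseudo_r2_deviance:.3f}",
            table.to_string(float_format=lambda v: f"{v:.3g}"),
        ]
        return "\n".join(lines)


class ElectronRequirementModel:
    """Gamma GLM (log link) for phi_e_c over a standardised model matrix.

    Build either from a standardised matrix (``__init__``) or from a raw
    record table (:meth:`from_dataframe`, which applies the detection-limit /
    log / z-score transform and remembers it for prediction).
    """

    def __init__(self, phi: np.ndarray, x: pd.DataFrame,
                 transform: TransformInfo | None = None):
        phi = np.asarray(phi, dtype=float)
        if (phi <= 0).any() or not np.isfinite(phi).all():
            raise ValueError("phi_e_c must be strictly positive and finite")
        if len(phi) != len(x):
            raise ValueError("response and model matrix lengths differ")
        exog = sm.add_constant(x, has_constant="add")
        rank = np.linalg.matrix_rank(exog.to_numpy())
        if rank < exog.shape[1]:
            corr = x.corr().abs()
            np.fill_diagonal(corr.values, 0.0)
            aliased = sorted(set(corr.stack().loc[lambda s: s > 0.9999].index.get_level_values(0)))
            raise ValueError(f"model matrix is rank deficient (aliased terms: {aliased})")
        self.phi = phi
        self.x = x
        self.transform = transform

    @classmethod
    def from_dataframe(
        cls,
        records: pd.DataFrame,
        terms: list[str] | None = None,
        response: str = "phi_e_c",
    ) -> "ElectronRequirementModel":
        x, info = transform_standardise(records, terms)
        return cls(records[response].to_numpy(), x, transform=info)

    def fit(self) -> ElectronRequirementResults:
        exog = sm.add_constant(self.x, has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = sm.GLM(self.phi, exog, family=sm.families.Gamma(link=sm.families.links.Log()))
            res = glm.fit()
            null = sm.GLM(
                self.phi,
                np.ones((len(self.phi), 1)),
                family=sm.families.Gamma(link=sm.families.links.Log()),
            ).fit()
        fitted = np.asarray(res.fittedvalues)
        if self.x.shape[1] > 0 and np.var(fitted) > 0:
            r_pearson = float(np.corrcoef(self.phi, fitted)[0, 1] ** 2)
        else:
            r_pearson = 0.0
        r_deviance = float(1.0 - res.deviance / null.deviance) if null.deviance > 0 else 0.0
        vif = _vif(self.x) if self.x.shape[1] > 1 else pd.Series(
            {c: 1.0 for c in self.x.columns}, name="vif", dtype=float
        )
        return ElectronRequirementResults(
            params=res.params,
            bse=res.bse,
            tvalues=res.tvalues,
            pvalues=res.pvalues,
            aic=float(res.aic),
            pseudo_r2_pearson=r_pearson,
            pseudo_r2_deviance=r_deviance,
            vif=vif,
            n=len(self.phi),
            terms=tuple(self.x.columns),
            transform=self.transform,
            _glm_results=res,
        )


def fit_gamma_glm(
    phi: np.ndarray, x: pd.DataFrame, transform: TransformInfo | None = None
) -> ElectronRequirementResults:
    """Functional entry point over :class:`ElectronRequirementModel`."""
    return ElectronRequirementModel(phi, x, transform=transform).fit()


# ---------------------------------------------------------------------------
# All-subsets AIC ranking
# ---------------------------------------------------------------------------


@dataclass
class ModelRanking:
    """All 2^k sub-models ranked by AIC, with the three named extracts."""

    table: pd.DataFrame  # columns: terms, k, aic, delta_aic, pseudo_r2
    best: ElectronRequirementResults
    best_without_nutrients: ElectronRequirementResults | None
    best_without_nutrients_and_phyto: ElectronRequirementResults | None
    failures: tuple[tuple[str, ...], ...] = ()


def rank_all_submodels(
    phi: np.ndarray,
    x: pd.DataFrame,
    candidate_terms: list[str] | None = None,
    transform: TransformInfo | None = None,
) -> ModelRanking:
    """Fit every subset of the candidate terms and rank by AIC.

    Enumerates all 2^k subsets (k <= 16), fits each gamma GLM, and sorts
    ascending by AIC. Alongside the overall best model, the best subsets
    containing no nutrient terms, and neither nutrient nor phytoplankton
    composition terms, are refitted and returned (the parsimonious-model
    comparison). Subset fit failures are recorded and excluded.
    """
    terms = list(candidate_terms) if candidate_terms is not None else list(x.columns)
    if len(terms) > 16:
        raise ValueError("all-subsets enumeration is limited to 16 candidate terms")
    phi = np.asarray(phi, dtype=float)
    n = len(phi)
    const = np.ones((n, 1))
    columns = {t: x[t].to_numpy()[:, None] for t in terms}
    rows = []
    failures = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        family = sm.families.Gamma(link=sm.families.links.Log())
        null_dev = sm.GLM(phi, const, family=family).fit().deviance
        for k in range(len(terms) + 1):
            for subset in itertools.combinations(terms, k):
                exog = np.hstack([const] + [columns[t] for t in subset])
                try:
                    res = sm.GLM(phi, exog, family=family).fit()
                    if not np.isfinite(res.aic):
                        raise ValueError("non-finite AIC")
                except Exception:
                    failures.append(subset)
                    continue
                rows.append(
                    {
                        "terms": subset,
                        "k": k,
                        "aic": float(res.aic),
                        "pseudo_r2": float(1.0 - res.deviance / null_dev)
                        if null_dev > 0
                        else 0.0,
                    }
                )
    table = pd.DataFrame(rows).sort_values("aic", kind="mergesort").reset_index(drop=True)
    table["delta_aic"] = table["aic"] - table["aic"].iloc[0]

    def refit(subset: tuple[str, ...]) -> ElectronRequirementResults:
        return fit_gamma_glm(phi, x[list(subset)], transform=transform)

    best = refit(tuple(table["terms"].iloc[0]))

    def best_excluding(excluded: set[str]) -> ElectronRequirementResults | None:
        ok = table["terms"].map(lambda t: not (set(t) & excluded))
        sub = table.loc[ok]
        return refit(tuple(sub["terms"].iloc[0])) if not sub.empty else None

    return ModelRanking(
        table=table,
        best=best,
        best_without_nutrients=best_excluding(NUTRIENT_TERMS),
        best_without_nutrients_and_phyto=best_excluding(NUTRIENT_TERMS | PHYTOPLANKTON_TERMS),
        failures=tuple(failures),
    )
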