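"""Photosynthesis-irradiance (P-E) curve models.

Two forms are supported, both passing through the origin:

* ``webb2`` — saturating exponential, P = P_s (1 - exp(-alpha E / P_s));
* ``platt3`` — the same with an exponential photoinhibition term,
  P = P_s (1 - exp(-alpha E / P_s)) exp(-beta E / P_s).

`PhotosynthesisIrradianceModel` is a small statsmodels-style model object:
construct it from (E, P) data and call :meth:`fit` for a
:class:`PECurveResults` carrying the parameters, diagnostics and a
``summary()`` table. ``platt3`` with beta = 0 predicts identically to
``webb2`` (nested forms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .constants import PHI_CONVERSION_FACTOR

#: Relative decline past the observed maximum that counts as photoinhibition.
PHOTOINHIBITION_TOL = 0.05


def webb(e, alpha, p_s):
    """Webb saturating form; exactly 0 at E = 0 and -> P_s as E -> inf."""
    e = np.asarray(e, dtype=float)
    return p_s * -np.expm1(-alpha * e / p_s)


def platt(e, alpha, p_s, beta):
    """Platt photoinhibition form; reduces to the Webb form at beta = 0."""
    e = np.asarray(e, dtype=float)
    return webb(e, alpha, p_s) * np.exp(-beta * e / p_s)


def choose_model(e_values, p_values, tol: float = PHOTOINHIBITION_TOL) -> str:
    """Pick 'platt3' iff the response declines past its peak by more than tol.

    The rule: the response observed at the highest irradiance must fall below
    the maximum observed response by more than ``tol`` (relative), and at
    least 4 points are needed for the 3-parameter form.
    """
    e = np.asarray(e_values, dtype=float)
    p = np.asarray(p_values, dtype=float)
    if e.size < 4:
        return "webb2"
    p_at_emax = p[np.argmax(e)]
    p_max = p.max()
    if p_max <= 0:
        return "webb2"
    return "platt3" if p_at_emax < (1.0 - tol) * p_max else "webb2"


@dataclass(frozen=True)
class PECurveResults:
    """Fitted P-E curve: parameters, diagnostics, prediction."""

    model_form: str  # 'webb2' | 'platt3'
    alpha: float  # initial slope, response units per umol photons m^-2 s^-1
    p_s: float  # scale parameter, response units
    beta: float  # photoinhibition parameter (0 for webb2)
    residual_ss: float
    converged: bool
    n_points: int

    def predict(self, e):
        if self.model_form == "webb2":
            return webb(e, self.alpha, self.p_s)
        return platt(e, self.alpha, self.p_s, self.beta)

    def summary(self) -> str:
        lines = [
            f"P-E curve fit ({self.model_form})",
            f"  n points     {self.n_points}",
            f"  alpha        {self.alpha:.6g}",
            f"  P_s          {self.p_s:.6g}",
        ]
        if self.model_form == "platt3":
            lines.append(f"  beta         {self.beta:.6g}")
        lines += [
            f"  residual SS  {self.residual_ss:.6g}",
            f"  converged    {self.converged}",
        ]
        return "\n".join(lines)


class PhotosynthesisIrradianceModel:
    """Least-squares P-E curve model for a response (J_f, PB_C, JV_O) vs E.

    form='auto' applies the photoinhibition rule of :func:`choose_model`.
    Initialisation is deterministic: alpha0 from the slope through the two
    lowest-irradiance points, P_s0 = max observed response, beta0 = 0.01
    alpha0; optimisation is bounded to positive alpha and P_s.
    """

    def __init__(self, e_values, p_values, form: str = "auto",
                 photoinhibition_tol: float = PHOTOINHIBITION_TOL):
        e = np.asarray(e_values, dtype=float)
        p = np.asarray(p_values, dtype=float)
        if e.shape != p.shape or e.ndim != 1:
            raise ValueError("E and P must be matching 1-d arrays")
        keep = np.isfinite(e) & np.isfinite(p)
        e, p = e[keep], p[keep]
        if np.unique(e[e > 0]).size < 3:
            raise ValueError("need at least 3 distinct positive irradiance values")
        if form not in ("auto", "webb2", "platt3"):
            raise ValueError(f"unknown model form {form!r}")
        self.e = e
        self.p = p
        self.form = choose_model(e, p, photoinhibition_tol) if form == "auto" else form

    def _initial_guess(self) -> tuple[float, ...]:
        order = np.argsort(self.e)
        e_lo, p_lo = self.e[order[:2]], self.p[order[:2]]
        de = e_lo[1] - e_lo[0]
        slope = (p_lo[1] - p_lo[0]) / de if de > 0 else 0.0
        if not np.isfinite(slope) or slope <= 0:
            positive = self.e > 0
            slope = float(np.median(self.p[positive] / self.e[positive]))
        alpha0 = max(slope, 1e-12)
        p_s0 = max(float(self.p.max()), alpha0 * float(self.e.max()) * 1e-3, 1e-12)
        if self.form == "webb2":
            return alpha0, p_s0
        return alpha0, p_s0, 0.01 * alpha0

    def fit(self, max_nfev: int = 2000) -> PECurveResults:
        x0 = np.array(self._initial_guess())

        if self.form == "webb2":
            def residuals(x):
                return webb(self.e, x[0], x[1]) - self.p
            lower = [1e-15, 1e-15]
            upper = [np.inf, np.inf]
        else:
            def residuals(x):
                return platt(self.e, x[0], x[1], x[2]) - self.p
            lower = [1e-15, 1e-15, 0.0]
            upper = [np.inf, np.inf, np.inf]

        sol = least_squares(
            residuals, x0, bounds=(lower, upper), method="trf",
            xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=max_nfev,
        )
        alpha, p_s = float(sol.x[0]), float(sol.x[1])
        beta = float(sol.x[2]) if self.form == "platt3" else 0.0
        return PECurveResults(
            model_form=self.form,
            alpha=alpha,
            p_s=p_s,
            beta=beta,
            residual_ss=float(sol.fun @ sol.fun),
            converged=bool(sol.status > 0),
            n_points=int(self.e.size),
        )


def fit_webb2(e_values, p_values) -> PECurveResults:
    return PhotosynthesisIrradianceModel(e_values, p_values, form="webb2").fit()


def fit_platt3(e_values, p_values) -> PECurveResults:
    return PhotosynthesisIrradianceModel(e_values, p_values, form="platt3").fit()


def phi_e_c(
    j_f_at_e: float | np.ndarray,
    pb_c_at_e: float | np.ndarray,
    factor: float = PHI_CONVERSION_FACTOR,
) -> float | np.ndarray:
    """Electron requirement for carbon fixation (mol e- mol C^-1).

    phi = J_f / PB_C x 43.2 with J_f and PB_C evaluated at the same
    irradiance. The mechanistic floor is 4; smaller values are apparent
    (method artifacts) but are retained by callers for analysis.
    """
    pb = np.asarray(pb_c_at_e, dtype=float)
    if (pb <= 0).any():
        raise ValueError("PB_C must be positive to form the electron requirement")
    out = np.asarray(j_f_at_e, dtype=float) / pb * factor
    return out if out.ndim else float(out)
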