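"""Hill (agonist-versus-response) fitting of plateau responses.

The model is parameterised on a linear dose axis,

.. math:: r(I) = bottom + (top - bottom)\\,\\frac{I^n}{I^n + EC_{50}^n}

with the Hill slope ``n`` fixed to 1 by default (Michaelis–Menten form), so
the zero-irradiance point enters the fit directly instead of requiring a
pseudo-dose on a log axis.  Weighted least squares uses replicate counts as
weights; confidence intervals come from a seeded parametric bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .core import ValidationError


class UnidentifiableFitError(ValueError):
    """The response range is too flat to identify an EC50."""


def hill(I, bottom, top, ec50, n=1.0):
    I = np.asarray(I, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(I > 0, I ** n / (I ** n + ec50 ** n), 0.0)
    return bottom + (top - bottom) * frac


@dataclass
class DoseResponseFit:
    """Fitted Hill curve over (irradiance, plateau response) points."""

    irradiance: np.ndarray
    response: np.ndarray
    n_replicates: np.ndarray
    bottom: float
    top: float
    ec50: float
    hill_n: float
    converged: bool
    residual_norm: float
    ci_bottom: tuple = (np.nan, np.nan)
    ci_top: tuple = (np.nan, np.nan)
    ci_ec50: tuple = (np.nan, np.nan)

    def predict(self, irradiance):
        """Model response at the given irradiance(s)."""
        if not self.converged:
            raise ValidationError("fit did not converge; cannot predict")
        irr = np.asarray(irradiance, dtype=float)
        if np.any(irr < 0):
            raise ValidationError("irradiance must be non-negative")
        out = hill(irr, self.bottom, self.top, self.ec50, self.hill_n)
        return float(out) if np.ndim(irradiance) == 0 else out

    def to_dict(self) -> dict:
        return {
            "bottom": self.bottom, "top": self.top, "ec50": self.ec50,
            "hill_n": self.hill_n, "converged": self.converged,
            "residual_norm": self.residual_norm,
            "ci_ec50": list(self.ci_ec50), "ci_top": list(self.ci_top),
            "ci_bottom": list(self.ci_bottom),
            "points": [
                {"irradiance_uW_mm2": float(i), "response_fold": float(r),
                 "n": int(n)}
                for i, r, n in zip(self.irradiance, self.response,
                                   self.n_replicates)],
        }


def predict_response(fit: DoseResponseFit, irradiance):
    """Functional alias for :meth:`DoseResponseFit.predict`."""
    return fit.predict(irradiance)


def _wls_fit(I, r, w, fix_hill):
    sigma = 1.0 / np.sqrt(w)
    b0, t0 = float(r[I == I.min()].mean()), float(r[I == I.max()].mean())
    pos = I[I > 0]
    ec0 = float(np.exp(np.mean(np.log(pos)))) if len(pos) else 1.0
    if fix_hill:
        p0 = [b0, t0, ec0]
        popt, _ = curve_fit(lambda x, b, t, e: hill(x, b, t, e, 1.0),
                            I, r, p0=p0, sigma=sigma, absolute_sigma=False,
                            bounds=([-np.inf, -np.inf, 1e-9],
                                    [np.inf, np.inf, np.inf]),
                            maxfev=20000)
        return popt[0], popt[1], popt[2], 1.0
    p0 = [b0, t0, ec0, 1.0]
    popt, _ = curve_fit(hill, I, r, p0=p0, sigma=sigma, absolute_sigma=False,
                        bounds=([-np.inf, -np.inf, 1e-9, 0.1],
                                [np.inf, np.inf, np.inf, 10.0]),
                        maxfev=20000)
    return tuple(popt)


def fit_dose_response(irradiance, response, n_replicates=None,
                      fix_hill: bool = True,
                      noise_floor: float = 1e-3,
                      n_bootstrap: int = 200,
                      seed: int = 0) -> DoseResponseFit:
    """Fit the Hill model to plateau responses at each irradiance level.

    Requires at least 4 distinct irradiance levels including zero dose.
    ``noise_floor`` sets the minimum top−bottom span below which the EC50
    is declared unidentifiable.  Bootstrap CIs resample residuals
    parametrically (Gaussian with the fit's RMS error), seeded.
    """
    I = np.asarray(irradiance, dtype=float)
    r = np.asarray(response, dtype=float)
    if len(I) != len(r):
        raise ValidationError("irradiance and response lengths differ")
    w = (np.ones(len(I)) if n_replicates is None
         else np.asarray(n_replicates, dtype=float))
    if np.any(I < 0):
        raise ValidationError("irradiance must be non-negative")
    if len(np.unique(I)) < 4:
        raise ValidationError("need >= 4 distinct irradiance levels")
    if I.min() > 0:
        raise ValidationError("a zero-dose point is required")
    if np.ptp(r) < noise_floor:
        raise UnidentifiableFitError(
            "response range is below the noise floor; EC50 unidentifiable")
    order = np.argsort(I)
    I, r, w = I[order], r[order], w[order]
    try:
        bottom, top, ec50, hn = _wls_fit(I, r, w, fix_hill)
        converged = True
    except RuntimeError:
        return DoseResponseFit(I, r, w.astype(int), np.nan, np.nan, np.nan,
                               1.0 if fix_hill else np.nan, False, np.nan)
    resid = r - hill(I, bottom, top, ec50, hn)
    rms = float(np.sqrt(np.mean(resid ** 2)))
    cis = {}
    if n_bootstrap > 0 and rms > 0:
        rng = np.random.default_rng(seed)
        boots = []
        for _ in range(n_bootstrap):
            rb = hill(I, bottom, top, ec50, hn) + rng.normal(0, rms, len(I))
            try:
                boots.append(_wls_fit(I, rb, w, fix_hill)[:3])
            except RuntimeError:
                continue
        if len(boots) >= 10:
            arr = np.array(boots)
            for k, name in enumerate(("bottom", "top", "ec50")):
                cis[name] = tuple(np.percentile(arr[:, k], [2.5, 97.5]))
    return DoseResponseFit(
        I, r, w.astype(int), float(bottom), float(top), float(ec50),
        float(hn), converged, rms,
        ci_bottom=cis.get("bottom", (np.nan, np.nan)),
        ci_top=cis.get("top", (np.nan, np.nan)),
        ci_ec50=cis.get("ec50", (np.nan, np.nan)))
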