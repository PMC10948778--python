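"""Second-stage analyses on fitted rates.

* :func:`quencher_slope` — error-weighted linear regression of the fitted
  radical recovery rate against reductant concentration (Stern–Volmer-type
  titration), yielding the bimolecular quenching constant k_Qred and the
  intrinsic recovery rate k_red0.
* :func:`dark_fraction` — equilibrium radical (dark-state) occupancy of
  the two-state model, k'_ox/(k'_ox + k_red).
* :func:`conformation_contrast` — the accessibility readout used for
  calmodulin: compare k_red fitted with and without reductant for one
  protein conformation; a significant increase means the tyrosine residues
  are solvent-exposed and reachable by the reductant, no change within
  errors means they are shielded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .fitting import FitResult

__all__ = [
    "TitrationResult",
    "ConformationReadout",
    "quencher_slope",
    "dark_fraction",
    "conformation_contrast",
    "contrast_from_pair_fit",
]


@dataclass
class TitrationResult:
    concentrations: np.ndarray  # M
    k_red: np.ndarray  # s⁻¹
    k_red_err: np.ndarray  # s⁻¹
    slope: float  # k_Qred, M⁻¹ s⁻¹
    slope_err: float
    intercept: float  # k_red0, s⁻¹
    intercept_err: float
    chi2: float
    dof: int

    def to_dict(self) -> dict:
        return {
            "concentrations_M": self.concentrations.tolist(),
            "k_red_per_us": (self.k_red * 1e-6).tolist(),
            "k_red_err_per_us": (self.k_red_err * 1e-6).tolist(),
            "k_qred_per_M_s": self.slope,
            "k_qred_err_per_M_s": self.slope_err,
            "k_red0_per_us": self.intercept * 1e-6,
            "k_red0_err_per_us": self.intercept_err * 1e-6,
            "chi2": self.chi2,
            "dof": self.dof,
        }


def quencher_slope(
    concentrations: Sequence[float],
    k_red: Sequence[float],
    errors: Sequence[float],
) -> TitrationResult:
    """Error-weighted linear regression k_red(c) = k_red0 + k_Qred·c.

    Standard closed-form weighted least squares with weights 1/err²;
    parameter errors derive from the stated per-point errors (not rescaled
    by the fit quality, which is reported separately as chi²/dof).
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(k_red, dtype=float)
    e = np.asarray(errors, dtype=float)
    if not (len(c) == len(y) == len(e)):
        raise ValueError("concentrations, k_red and errors must match in length")
    if len(c) < 3:
        raise ValueError("need at least 3 titration points for a slope with error")
    if np.any(c < 0):
        raise ValueError("concentrations must be >= 0")
    if np.any(e <= 0):
        raise ValueError("errors must be > 0")
    if np.allclose(c, c[0]):
        raise ValueError("all concentrations equal; slope undefined")

    w = 1.0 / e**2
    Sw, Sx, Sy = w.sum(), (w * c).sum(), (w * y).sum()
    Sxx, Sxy = (w * c * c).sum(), (w * c * y).sum()
    delta = Sw * Sxx - Sx**2
    slope = (Sw * Sxy - Sx * Sy) / delta
    intercept = (Sxx * Sy - Sx * Sxy) / delta
    slope_err = math.sqrt(Sw / delta)
    intercept_err = math.sqrt(Sxx / delta)
    resid = y - (intercept + slope * c)
    chi2 = float((w * resid**2).sum())
    return TitrationResult(
        concentrations=c,
        k_red=y,
        k_red_err=e,
        slope=float(slope),
        slope_err=slope_err,
        intercept=float(intercept),
        intercept_err=intercept_err,
        chi2=chi2,
        dof=len(c) - 2,
    )


def dark_fraction(kox_eff: float, k_red: float) -> float:
    """Equilibrium dark-state (radical) probability k'_ox/(k'_ox + k_red)."""
    if kox_eff < 0 or k_red < 0:
        raise ValueError("rates must be >= 0")
    if kox_eff == 0 and k_red == 0:
        raise ValueError("dark fraction undefined when both rates are 0")
    return kox_eff / (kox_eff + k_red)


@dataclass
class ConformationReadout:
    """Accessibility verdict for one protein conformation (±quencher pair)."""

    label: str
    k_red_minus: float  # s⁻¹, without quencher
    k_red_minus_err: float
    k_red_plus: float  # s⁻¹, with quencher
    k_red_plus_err: float
    delta_k_red: float  # s⁻¹
    delta_err: float
    dark_fraction_minus: float
    dark_fraction_plus: float
    verdict: Literal["shielded", "exposed", "indeterminate"]
    threshold: float
    resolvability_ceiling: float  # s⁻¹

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "k_red_minus_per_us": self.k_red_minus * 1e-6,
            "k_red_minus_err_per_us": self.k_red_minus_err * 1e-6,
            "k_red_plus_per_us": self.k_red_plus * 1e-6,
            "k_red_plus_err_per_us": self.k_red_plus_err * 1e-6,
            "delta_k_red_per_us": self.delta_k_red * 1e-6,
            "delta_err_per_us": self.delta_err * 1e-6,
            "dark_fraction_minus": self.dark_fraction_minus,
            "dark_fraction_plus": self.dark_fraction_plus,
            "verdict": self.verdict,
            "threshold": self.threshold,
            "resolvability_ceiling_per_us": self.resolvability_ceiling * 1e-6,
        }


def conformation_contrast(
    k_red_minus: float,
    k_red_minus_err: float,
    k_red_plus: float,
    k_red_plus_err: float,
    kox_eff: float,
    label: str = "",
    threshold: float = 3.0,
    resolvability_ceiling: float = 5e3,
) -> ConformationReadout:
    """Verdict rule on Δk_red = k_red(+q) − k_red(−q).

    ``exposed`` when Δ exceeds ``threshold`` propagated errors;
    ``shielded`` when |Δ| is within threshold errors *and* the propagated
    error itself is small enough (below the resolvability ceiling) to have
    detected an effect of titration scale; ``indeterminate`` otherwise.
    Per-condition equilibrium dark fractions are reported separately and
    never pooled across conformations, since the baseline radical
    population itself depends on the conformation.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    delta = k_red_plus - k_red_minus
    delta_err = math.hypot(k_red_minus_err, k_red_plus_err)
    if delta > threshold * delta_err:
        verdict = "exposed"
    elif abs(delta) <= threshold * delta_err and delta_err <= resolvability_ceiling:
        verdict = "shielded"
    else:
        verdict = "indeterminate"
    return ConformationReadout(
        label=label,
        k_red_minus=k_red_minus,
        k_red_minus_err=k_red_minus_err,
        k_red_plus=k_red_plus,
        k_red_plus_err=k_red_plus_err,
        delta_k_red=delta,
        delta_err=delta_err,
        dark_fraction_minus=dark_fraction(kox_eff, k_red_minus),
        dark_fraction_plus=dark_fraction(kox_eff, k_red_plus),
        verdict=verdict,
        threshold=threshold,
        resolvability_ceiling=resolvability_ceiling,
    )


def contrast_from_pair_fit(
    fit: FitResult,
    label: str = "",
    threshold: float = 3.0,
    resolvability_ceiling: float = 5e3,
) -> ConformationReadout:
    """Build the readout from a two-curve (±quencher) global fit.

    The curve without quencher is identified by ``quencher_conc_M == 0`` in
    its metadata; the fit must have k_red per curve.
    """
    if len(fit.curve_meta) != 2:
        raise ValueError("pair fit must contain exactly two curves")
    concs = [float(m.get("quencher_conc_M", 0.0)) for m in fit.curve_meta]
    if not (min(concs) == 0.0 and max(concs) > 0.0):
        raise ValueError(
            "pair must contain one curve at zero and one at nonzero "
            f"quencher concentration, got {concs}"
        )
    j_minus = concs.index(0.0)
    j_plus = 1 - j_minus
    k_red = np.atleast_1d(np.asarray(fit.params["k_red"], dtype=float))
    k_err = np.atleast_1d(np.asarray(fit.stderr["k_red"], dtype=float))
    if k_red.size != 2:
        raise ValueError("pair fit requires k_red fitted per curve")
    return conformation_contrast(
        k_red_minus=float(k_red[j_minus]),
        k_red_minus_err=float(k_err[j_minus]),
        k_red_plus=float(k_red[j_plus]),
        k_red_plus_err=float(k_err[j_plus]),
        kox_eff=float(np.mean(fit.kox_eff)),
        label=label or str(fit.curve_meta[j_minus].get("label", "")),
        threshold=threshold,
        resolvability_ceiling=resolvability_ceiling,
    )
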