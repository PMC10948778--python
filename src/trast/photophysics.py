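"""Electronic-state models for tyrosine blinking kinetics.

Tyrosine under continuous 280 nm excitation cycles between the ground (S0)
and excited (S1) singlet states, with a minor triplet (T1) branch and a
long-lived photo-induced neutral radical (Ṙ) formed by photo-oxidation with
concomitant proton transfer. The radical is the dominant dark state: its
formation and reductant-driven recovery produce the 100 µs–1 ms decay seen
in TRAST curves.

Two state graphs are supported:

* ``four_state`` — S0, S1, T1, Ṙ with edges S0→S1 (k01), S1→S0 (k10),
  S1→T1 (k_isc), T1→S0 (k_t), T1→Ṙ (k_ox), Ṙ→S0 (k_red);
* ``two_state`` — a fluorescent manifold Tyr(F) (within which the singlet
  and triplet transitions equilibrate fast) and the radical Ṫyr, coupled by
  an effective oxidation rate ``k'_ox = k_ox · k01/(k01 + k10)`` and the
  excitation-independent reduction rate ``k_red``.

The two-state model admits a closed-form pulse-averaged fluorescence,
:func:`two_state_closed_form`, used as the analytic oracle for the numeric
forward model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import yaml

from .constants import (
    C_LIGHT,
    H_PLANCK,
    K10_DEFAULT,
    KT_DEFAULT,
    SIGMA_TYR_CM2,
)

__all__ = [
    "RateConstants",
    "StateModel",
    "ExcitationConditions",
    "photon_flux",
    "excitation_rate",
    "steady_state_singlet",
    "effective_kox",
    "build_rate_matrix",
    "two_state_closed_form",
    "reduce_model",
    "FOUR_STATE_LABELS",
    "TWO_STATE_LABELS",
]

FOUR_STATE_LABELS = ("S0", "S1", "T1", "R_dot")
TWO_STATE_LABELS = ("TyrF", "TyrR")


def _check_finite_nonneg(name: str, value: float) -> None:
    if not math.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be finite and >= 0, got {value!r}")


@dataclass(frozen=True)
class RateConstants:
    """Photophysical rate constants (s⁻¹) and excitation cross section (cm²).

    Attributes
    ----------
    k10 : float
        Excited-singlet decay rate (radiative + non-radiative), s⁻¹.
    k_isc : float
        Intersystem crossing rate S1→T1, s⁻¹.
    k_t : float
        Triplet decay rate T1→S0, s⁻¹.
    k_ox : float
        Photo-oxidation rate (with concomitant proton transfer) into the
        radical dark state, s⁻¹.
    k_red : float
        Reduction/recovery rate of the radical back to the fluorescent
        state, s⁻¹. Not excitation driven; rises linearly with reductant
        concentration.
    sigma : float
        Excitation cross section, cm².
    """

    k10: float = K10_DEFAULT
    k_isc: float = 0.0
    k_t: float = KT_DEFAULT
    k_ox: float = 0.0
    k_red: float = 0.0
    sigma: float = SIGMA_TYR_CM2

    def __post_init__(self) -> None:
        for name in ("k10", "k_isc", "k_t", "k_ox", "k_red"):
            _check_finite_nonneg(name, getattr(self, name))
        if not math.isfinite(self.sigma) or self.sigma <= 0:
            raise ValueError(f"sigma must be finite and > 0, got {self.sigma!r}")


@dataclass(frozen=True)
class StateModel:
    """A state-graph topology together with its rate constants.

    For ``two_state`` topology, ``kox_eff`` (the effective oxidation rate
    Tyr(F)→Ṫyr, s⁻¹) must be given; it normally comes from
    :func:`effective_kox` or :func:`reduce_model`.
    """

    topology: Literal["four_state", "two_state"]
    rates: RateConstants = field(default_factory=RateConstants)
    kox_eff: float | None = None

    def __post_init__(self) -> None:
        if self.topology not in ("four_state", "two_state"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.topology == "two_state":
            if self.kox_eff is None:
                raise ValueError("two_state model requires kox_eff")
            _check_finite_nonneg("kox_eff", self.kox_eff)
        elif self.kox_eff is not None:
            raise ValueError("kox_eff is only meaningful for two_state topology")

    @property
    def n_states(self) -> int:
        return 2 if self.topology == "two_state" else 4

    @property
    def state_labels(self) -> tuple[str, ...]:
        return TWO_STATE_LABELS if self.topology == "two_state" else FOUR_STATE_LABELS

    @property
    def fluorescent_states(self) -> tuple[int, ...]:
        """Indices of the fluorescent-manifold states (ground + excited singlet)."""
        return (0,) if self.topology == "two_state" else (0, 1)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "topology": self.topology,
            "k10_per_s": self.rates.k10,
            "k_isc_per_s": self.rates.k_isc,
            "k_t_per_s": self.rates.k_t,
            "k_ox_per_s": self.rates.k_ox,
            "k_red_per_s": self.rates.k_red,
            "sigma_cm2": self.rates.sigma,
        }
        if self.topology == "two_state":
            d["kox_eff_per_s"] = self.kox_eff
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StateModel":
        rates = RateConstants(
            k10=d["k10_per_s"],
            k_isc=d.get("k_isc_per_s", 0.0),
            k_t=d.get("k_t_per_s", KT_DEFAULT),
            k_ox=d.get("k_ox_per_s", 0.0),
            k_red=d.get("k_red_per_s", 0.0),
            sigma=d["sigma_cm2"],
        )
        return cls(
            topology=d["topology"], rates=rates, kox_eff=d.get("kox_eff_per_s")
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "StateModel":
        return cls.from_dict(yaml.safe_load(text))

    def with_k_red(self, k_red: float) -> "StateModel":
        return replace(self, rates=replace(self.rates, k_red=k_red))


@dataclass(frozen=True)
class ExcitationConditions:
    """Excitation irradiance and wavelength; derives the pumping rate k01."""

    I_exc: float  # kW/cm²
    wavelength: float = 280.0  # nm

    def __post_init__(self) -> None:
        if not math.isfinite(self.I_exc) or self.I_exc < 0:
            raise ValueError(f"I_exc must be finite and >= 0, got {self.I_exc!r}")
        if not math.isfinite(self.wavelength) or self.wavelength <= 0:
            raise ValueError(f"wavelength must be > 0, got {self.wavelength!r}")

    def k01(self, sigma: float) -> float:
        """Peak ground→excited pumping rate σΦ (s⁻¹) for cross section sigma (cm²)."""
        return excitation_rate(sigma, photon_flux(self.I_exc, self.wavelength))


def photon_flux(I_exc: float, wavelength: float) -> float:
    """Photon flux (photons cm⁻² s⁻¹) of irradiance ``I_exc`` (kW/cm²) at
    wavelength ``wavelength`` (nm).

    flux = (I·10³ W/cm²)·λ/(h·c).
    """
    if not math.isfinite(I_exc) or I_exc < 0:
        raise ValueError(f"I_exc must be finite and >= 0, got {I_exc!r}")
    if not math.isfinite(wavelength) or wavelength <= 0:
        raise ValueError(f"wavelength must be > 0, got {wavelength!r}")
    return I_exc * 1e3 * (wavelength * 1e-9) / (H_PLANCK * C_LIGHT)


def excitation_rate(sigma: float, flux: float) -> float:
    """Pumping rate k01 = σ·Φ (s⁻¹)."""
    if sigma <= 0 or not math.isfinite(sigma):
        raise ValueError(f"sigma must be > 0, got {sigma!r}")
    if flux < 0 or not math.isfinite(flux):
        raise ValueError(f"flux must be >= 0, got {flux!r}")
    return sigma * flux


def steady_state_singlet(k01: float, k10: float) -> float:
    """Excited-singlet occupancy k01/(k01 + k10) at the onset of excitation,
    after singlet equilibration but before any dark-state build-up."""
    if k10 <= 0 or not math.isfinite(k10):
        raise ValueError(f"k10 must be > 0, got {k10!r}")
    if k01 < 0 or not math.isfinite(k01):
        raise ValueError(f"k01 must be >= 0, got {k01!r}")
    return k01 / (k01 + k10)


def effective_kox(k_ox: float, k01: float, k10: float) -> float:
    """Effective oxidation rate out of the fluorescent manifold,
    k'_ox = k_ox · k01/(k01 + k10).

    Monotonically increasing in k01 and saturating at k_ox.
    """
    _check_finite_nonneg("k_ox", k_ox)
    return k_ox * steady_state_singlet(k01, k10)


def build_rate_matrix(model: StateModel, k01: float) -> np.ndarray:
    """Generator matrix K (s⁻¹) such that dP/dt = K·P.

    Columns sum to zero (probability conservation); off-diagonals are the
    transition rates between states in the order of ``model.state_labels``.
    """
    _check_finite_nonneg("k01", k01)
    r = model.rates
    if model.topology == "two_state":
        kox_eff = float(model.kox_eff)  # validated at construction
        K = np.array(
            [
                [-kox_eff, r.k_red],
                [kox_eff, -r.k_red],
            ]
        )
    else:
        # states: S0, S1, T1, R_dot
        K = np.zeros((4, 4))
        K[1, 0] = k01  # S0 -> S1
        K[0, 1] = r.k10  # S1 -> S0
        K[2, 1] = r.k_isc  # S1 -> T1
        K[0, 2] = r.k_t  # T1 -> S0
        K[3, 2] = r.k_ox  # T1 -> R
        K[0, 3] = r.k_red  # R -> S0
        np.fill_diagonal(K, -K.sum(axis=0))
    return K


def two_state_closed_form(kox_eff, k_red, w):
    """Pulse-averaged normalized fluorescence of the two-state model.

    With λ = k'_ox + k_red and equilibrium fluorescent fraction
    S_eq = k_red/λ (S_eq := 1 when λ = 0):

        F_norm(w) = S_eq + (1 − S_eq)·(1 − e^{−λw})/(λw)

    F_norm is 1 at w → 0, decays monotonically, and plateaus at S_eq.
    Vectorized over ``w``.
    """
    kox_eff = float(kox_eff)
    k_red = float(k_red)
    _check_finite_nonneg("kox_eff", kox_eff)
    _check_finite_nonneg("k_red", k_red)
    w_arr = np.asarray(w, dtype=float)
    if np.any(w_arr <= 0) or not np.all(np.isfinite(w_arr)):
        raise ValueError("pulse width w must be finite and > 0")
    lam = kox_eff + k_red
    if lam == 0.0:
        out = np.ones_like(w_arr)
        return float(out) if np.isscalar(w) else out
    s_eq = k_red / lam
    x = lam * w_arr
    # (1 - exp(-x))/x, numerically stable for small x
    g = np.where(x < 1e-12, 1.0, -np.expm1(-x) / np.where(x == 0, 1.0, x))
    out = s_eq + (1.0 - s_eq) * g
    return float(out) if np.isscalar(w) else out


def reduce_model(
    four: StateModel, k01: float, mode: Literal["direct", "via_T1"] = "direct"
) -> StateModel:
    """Reduce a four-state model to the two-state (fluorescent ↔ radical) model.

    Modes
    -----
    ``direct``
        k'_ox = k_ox·k01/(k01 + k10): the oxidation rate acts directly
        against the singlet occupancy ratio. This matches the form actually
        used in fitting.
    ``via_T1``
        Mechanistic lumping under a fast singlet–triplet pre-equilibrium with
        oxidation proceeding from T1: the lumped rate is
        k_isc·k_ox/(k_ox + k_t), scaled by the same singlet occupancy. When
        k_ox is not ≫ k_t (k_ox ≤ 10·k_t) the pre-equilibrium assumption is
        questionable and a warning is emitted.
    """
    if four.topology != "four_state":
        raise ValueError("reduce_model expects a four_state model")
    r = four.rates
    if mode == "direct":
        kox_eff = effective_kox(r.k_ox, k01, r.k10)
    elif mode == "via_T1":
        if r.k_ox <= 10.0 * r.k_t:
            warnings.warn(
                "via_T1 reduction assumes k_ox >> k_t; "
                f"k_ox={r.k_ox:g} <= 10*k_t={10 * r.k_t:g}",
                stacklevel=2,
            )
        denom = r.k_ox + r.k_t
        lumped = 0.0 if denom == 0 else r.k_isc * r.k_ox / denom
        kox_eff = lumped * steady_state_singlet(k01, r.k10)
    else:
        raise ValueError(f"unknown reduction mode {mode!r}")
    return StateModel(topology="two_state", rates=r, kox_eff=kox_eff)
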