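"""Synthetic pulse-train photon-count recordings.

Emulates the statistical structure of a confocal TRAST measurement so the
preprocessing, fitting, and readout stages are testable end-to-end without
instrument data: per-point Poisson shot noise on the detected counts, a
constant detector dark-count contribution, a slow multiplicative bleaching
drift across the measurement series, and interleaved reference
measurements at a short pulse width w0 used downstream for drift
correction and normalization.

Each recording point accumulates a fixed illuminated time T_ill (the pulse
count per point scales as M_i ≈ T_ill/w_i), so the expected signal counts
at F_norm = 1 are the same at every pulse width.

Three scenario presets mirror the study designs:

* ``fig2a_intensity_series`` — free tyrosine at six irradiances
  2.0–22.9 kW/cm², shared photo-oxidation rate k_ox, shared k_red;
* ``fig2b_naac_titration`` — six sodium-ascorbate concentrations 0–500 µM
  at 10.3 kW/cm², with k_red(c) = k_red0 + k_Qred·c;
* ``fig3a_cam`` — calmodulin ± Ca²⁺ ± 500 µM ascorbate: the
  calcium-saturated (holo) pair shares k_red (tyrosines shielded from the
  reductant) while the calcium-free (apo) pair gains k_Qred·c·accessibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import (
    KOX_TYR,
    KQRED_NAAC,
    KRED0_TYR,
    SIGMA_TYR_CM2,
    K10_DEFAULT,
)
from .forward import (
    BeamProfile,
    PulseScheme,
    average_excitation_rate,
    default_w_grid,
    trast_point,
)
from .photophysics import (
    ExcitationConditions,
    RateConstants,
    StateModel,
    effective_kox,
)

__all__ = [
    "NoiseModel",
    "RawPoint",
    "RawRecording",
    "Scenario",
    "simulate_recording",
    "scenario",
    "SCENARIO_NAMES",
]

SCENARIO_NAMES = ("fig2a_intensity_series", "fig2b_naac_titration", "fig3a_cam")

#: Interior irradiance points of the intensity series; endpoints are the
#: published range, interior points are a design choice (kW/cm²).
FIG2A_I_EXC = (2.0, 4.0, 7.0, 10.3, 16.0, 22.9)

#: Ascorbate concentrations of the titration (M); endpoints published.
FIG2B_NAAC_M = (0.0, 50e-6, 100e-6, 200e-6, 350e-6, 500e-6)

#: Apo-calmodulin baseline k_red without reductant (s⁻¹): higher than free
#: tyrosine, encoding the observation that the radical population is lower
#: in the calcium-free conformation even before adding reductant.
CAM_APO_KRED0 = 7.4e3
CAM_HOLO_KRED0 = KRED0_TYR
CAM_NAAC_M = 500e-6


@dataclass(frozen=True)
class NoiseModel:
    """Counting-noise configuration for one recording.

    counts_at_unity: expected detected signal counts per point at
    F_norm = 1; dark_rate: dark counts per point; bleach_per_step:
    multiplicative signal loss per successive point; poisson: draw Poisson
    counts (False gives the noiseless expectation, as floats).
    """

    counts_at_unity: float = 1e5
    dark_rate: float = 100.0
    bleach_per_step: float = 0.002
    seed: int = 0
    poisson: bool = True

    def __post_init__(self) -> None:
        if self.counts_at_unity <= 0:
            raise ValueError("counts_at_unity must be > 0")
        if self.dark_rate < 0:
            raise ValueError("dark_rate must be >= 0")
        if not (0 <= self.bleach_per_step < 0.05):
            raise ValueError("bleach_per_step must be in [0, 0.05)")


@dataclass(frozen=True)
class RawPoint:
    w: float  # s
    is_reference: bool
    raw_counts: float  # integer-valued when Poisson noise is on
    index: int  # acquisition order
    exposure_s: float  # illuminated time M_i * w_i


@dataclass
class RawRecording:
    points: list[RawPoint]
    scheme: PulseScheme
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = [p.index for p in self.points]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("acquisition indices must be strictly increasing")
        for p in self.points:
            if p.raw_counts < 0:
                raise ValueError("raw_counts must be >= 0")
            if p.is_reference and not math.isclose(p.w, self.scheme.w0):
                raise ValueError("reference points must use w = w0")

    @property
    def science_points(self) -> list[RawPoint]:
        return [p for p in self.points if not p.is_reference]

    @property
    def reference_points(self) -> list[RawPoint]:
        return [p for p in self.points if p.is_reference]


def _expected_fnorm(
    model: StateModel,
    conditions: ExcitationConditions,
    beam: BeamProfile,
    w: np.ndarray,
) -> np.ndarray:
    kbar01 = average_excitation_rate(
        beam, model.rates, conditions.I_exc, conditions.wavelength
    )
    return np.atleast_1d(trast_point(model, kbar01, w))


def simulate_recording(
    model: StateModel,
    conditions: ExcitationConditions,
    beam: BeamProfile,
    scheme: PulseScheme,
    w_list: Sequence[float],
    noise: NoiseModel,
    ref_every: int = 3,
    t_ill: float = 1.0,
    meta: dict | None = None,
) -> RawRecording:
    """Simulate one pulse-train recording over the pulse-width grid.

    A reference point at w0 opens the sequence, recurs after every
    ``ref_every`` science points, and closes it, so references span the
    acquisition for drift interpolation. Expected counts at point i:

        counts_at_unity · F_norm(w_i) · (exposure_i/T_ill)
        · (1 − bleach_per_step)^i + dark_rate

    with exposure_i = M_i·w_i and M_i = ceil(T_ill/w_i) pulses. Counts are
    Poisson-distributed (or the expectation itself when ``noise.poisson``
    is off). Fully reproducible for a fixed ``noise.seed``.
    """
    if ref_every < 1:
        raise ValueError("ref_every must be >= 1")
    w_arr = np.asarray(w_list, dtype=float)
    f_science = _expected_fnorm(model, conditions, beam, w_arr)
    f_ref = float(_expected_fnorm(model, conditions, beam, np.array([scheme.w0]))[0])

    # acquisition plan: (w, is_ref, f_norm)
    plan: list[tuple[float, bool, float]] = [(scheme.w0, True, f_ref)]
    for j, (wj, fj) in enumerate(zip(w_arr, f_science)):
        plan.append((wj, False, fj))
        if (j + 1) % ref_every == 0 and j != len(w_arr) - 1:
            plan.append((scheme.w0, True, f_ref))
    plan.append((scheme.w0, True, f_ref))

    rng = np.random.default_rng(noise.seed)
    points: list[RawPoint] = []
    for i, (wi, is_ref, fi) in enumerate(plan):
        m_i = max(1, math.ceil(t_ill / wi))
        exposure = m_i * wi
        expected = (
            noise.counts_at_unity
            * fi
            * (exposure / t_ill)
            * (1.0 - noise.bleach_per_step) ** i
            + noise.dark_rate
        )
        counts = float(rng.poisson(expected)) if noise.poisson else expected
        points.append(
            RawPoint(
                w=wi, is_reference=is_ref, raw_counts=counts, index=i,
                exposure_s=exposure,
            )
        )
    rec_meta = {
        "i_exc_kw_cm2": conditions.I_exc,
        "wavelength_nm": conditions.wavelength,
        "dark_rate": noise.dark_rate,
        "t_ill_s": t_ill,
        "seed": noise.seed,
    }
    if meta:
        rec_meta.update(meta)
    return RawRecording(points=points, scheme=scheme, meta=rec_meta)


@dataclass
class Scenario:
    """A generated measurement series plus its generating ground truth."""

    name: str
    recordings: list[RawRecording]
    ground_truth: dict
    beam: BeamProfile
    scheme: PulseScheme


def _child_seed(master_seed: int, index: int) -> int:
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def _two_state_for(
    k_ox: float, k_red: float, rates: RateConstants, kbar01: float
) -> StateModel:
    full = RateConstants(
        k10=rates.k10, k_isc=rates.k_isc, k_t=rates.k_t, k_ox=k_ox,
        k_red=k_red, sigma=rates.sigma,
    )
    return StateModel(
        topology="two_state",
        rates=full,
        kox_eff=effective_kox(k_ox, kbar01, rates.k10),
    )


def scenario(
    name: str,
    seed: int = 0,
    noise: NoiseModel | None = None,
    w_list: Sequence[float] | None = None,
    k_ox: float = KOX_TYR,
    k_red0: float = KRED0_TYR,
    k_qred: float = KQRED_NAAC,
    apo_kred0: float = CAM_APO_KRED0,
    accessibility: float = 1.0,
    beam: BeamProfile | None = None,
    scheme_eta: float = 0.01,
    w0: float = 5e-8,
) -> Scenario:
    """Generate one of the preset measurement series.

    Per-recording RNG seeds are derived from ``(seed, recording index)``
    through a :class:`numpy.random.SeedSequence`, so recordings are
    independent and the whole scenario is reproducible from the master
    seed. The ground-truth dict carries the generating rates per curve.
    """
    if name not in SCENARIO_NAMES:
        raise ValueError(
            f"unknown scenario {name!r}; valid names: {', '.join(SCENARIO_NAMES)}"
        )
    noise = noise or NoiseModel()
    beam = beam or BeamProfile()
    w_arr = np.asarray(w_list if w_list is not None else default_w_grid(), dtype=float)
    scheme = PulseScheme(w=float(w_arr[-1]), eta=scheme_eta, M=1, w0=w0)
    base_rates = RateConstants(k_ox=k_ox, sigma=SIGMA_TYR_CM2, k10=K10_DEFAULT)

    if name == "fig2a_intensity_series":
        conds = [
            {"i_exc": i, "k_red": k_red0, "label": "Tyr", "quencher_conc_M": 0.0}
            for i in FIG2A_I_EXC
        ]
    elif name == "fig2b_naac_titration":
        conds = [
            {
                "i_exc": 10.3,
                "k_red": k_red0 + k_qred * c,
                "label": "Tyr+NaAc",
                "quencher_conc_M": c,
            }
            for c in FIG2B_NAAC_M
        ]
    else:  # fig3a_cam
        conds = [
            {"i_exc": 10.3, "k_red": CAM_HOLO_KRED0, "label": "CaM+Ca",
             "quencher_conc_M": 0.0, "condition": "holo"},
            {"i_exc": 10.3, "k_red": CAM_HOLO_KRED0 + 0.0 * k_qred * CAM_NAAC_M,
             "label": "CaM+Ca+NaAc", "quencher_conc_M": CAM_NAAC_M,
             "condition": "holo"},
            {"i_exc": 10.3, "k_red": apo_kred0, "label": "CaM-apo",
             "quencher_conc_M": 0.0, "condition": "apo"},
            {"i_exc": 10.3,
             "k_red": apo_kred0 + accessibility * k_qred * CAM_NAAC_M,
             "label": "CaM-apo+NaAc", "quencher_conc_M": CAM_NAAC_M,
             "condition": "apo"},
        ]

    recordings = []
    truth_curves = []
    for idx, cond in enumerate(conds):
        conditions = ExcitationConditions(I_exc=cond["i_exc"])
        kbar01 = average_excitation_rate(beam, base_rates, cond["i_exc"])
        model = _two_state_for(k_ox, cond["k_red"], base_rates, kbar01)
        rec_noise = NoiseModel(
            counts_at_unity=noise.counts_at_unity,
            dark_rate=noise.dark_rate,
            bleach_per_step=noise.bleach_per_step,
            seed=_child_seed(seed, idx),
            poisson=noise.poisson,
        )
        meta = {
            "label": cond["label"],
            "quencher": "NaAc",
            "quencher_conc_M": cond["quencher_conc_M"],
            "solvent": "H2O",
            "scenario": name,
        }
        if "condition" in cond:
            meta["condition"] = cond["condition"]
        recordings.append(
            simulate_recording(
                model, conditions, beam, scheme, w_arr, rec_noise, meta=meta
            )
        )
        truth_curves.append(
            {
                "label": cond["label"],
                "i_exc_kw_cm2": cond["i_exc"],
                "quencher_conc_M": cond["quencher_conc_M"],
                "k_red_per_s": cond["k_red"],
                "kbar01_per_s": kbar01,
                "kox_eff_per_s": model.kox_eff,
            }
        )
    ground_truth = {
        "k_ox_per_s": k_ox,
        "k_red0_per_s": k_red0,
        "k_qred_per_M_s": k_qred,
        "k10_per_s": base_rates.k10,
        "sigma_cm2": base_rates.sigma,
        "curves": truth_curves,
    }
    if name == "fig3a_cam":
        ground_truth["apo_kred0_per_s"] = apo_kred0
        ground_truth["accessibility"] = accessibility
    return Scenario(
        name=name, recordings=recordings, ground_truth=ground_truth,
        beam=beam, scheme=scheme,
    )
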