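"""Global nonlinear least-squares fitting of TRAST curves.

Multiple curves are fitted simultaneously with each rate designated
``global`` (one value shared by all curves), ``per_curve`` (one value per
curve) or ``fixed``. The default specification mirrors the study analysis
of free tyrosine: two-state model, photo-oxidation rate k_ox global,
radical recovery rate k_red per curve, with the cross section σ and the
singlet decay rate k10 fixed.

For each curve the detection-volume-averaged excitation rate k̄01 is
computed from its irradiance metadata (and cached — it depends only on σ,
k10 and the beam geometry, all fixed during a fit), the effective
oxidation rate follows as k'_ox = k_ox·k̄01/(k̄01 + k10), and the model
curve is the two-state pulse-averaged fluorescence, renormalized by its
value at the reference width w0 to match the preprocessing convention.

Optimization runs on log10-transformed rates (they span decades), with a
trust-region reflective solver and optional multistart. Standard errors
come from the Jacobian-based covariance scaled by the reduced chi-square;
a residual-resampling bootstrap is available as a cross-check.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .constants import K10_DEFAULT, SIGMA_TYR_CM2, WAVELENGTH_DEFAULT_NM
from .forward import BeamProfile, TrastCurve, average_excitation_rate
from .photophysics import RateConstants, two_state_closed_form

__all__ = ["FitSpec", "FitResult", "residuals", "fit_global", "estimate_uncertainty"]

Role = Literal["global", "per_curve", "fixed"]


@dataclass(frozen=True)
class FitSpec:
    """Parameter roles, bounds, initial values and weighting for a fit."""

    topology: str = "two_state"
    roles: Mapping[str, Role] = field(
        default_factory=lambda: {"k_ox": "global", "k_red": "per_curve"}
    )
    bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"k_ox": (1e2, 1e10), "k_red": (1e0, 1e7)}
    )
    initial: Mapping[str, float] = field(
        default_factory=lambda: {"k_ox": 1e7, "k_red": 1e3}
    )
    sigma: float = SIGMA_TYR_CM2
    k10: float = K10_DEFAULT
    weighting: Literal["sem", "uniform"] = "sem"
    multistart: int = 5
    seed: int = 0
    beam: BeamProfile = field(default_factory=BeamProfile)
    wavelength: float = WAVELENGTH_DEFAULT_NM
    allow_k10_free: bool = False

    def __post_init__(self) -> None:
        if self.topology != "two_state":
            raise NotImplementedError(
                "only the two_state topology is currently fittable"
            )
        free = [p for p, r in self.roles.items() if r != "fixed"]
        if not free:
            raise ValueError("at least one parameter must be free")
        if "k10" in free and not self.allow_k10_free:
            raise ValueError(
                "k_ox and k10 are degenerate through the effective-oxidation "
                "relation at low saturation; freeing k10 requires "
                "allow_k10_free=True"
            )
        for p in free:
            lo, hi = self.bounds[p]
            if not (math.isfinite(lo) and math.isfinite(hi) and 0 < lo < hi):
                raise ValueError(f"bounds for {p} must be finite with 0 < lo < hi")
            x0 = self.initial[p]
            if not (lo <= x0 <= hi):
                raise ValueError(f"initial value for {p} outside bounds")

    def param_layout(self, n_curves: int) -> list[tuple[str, int | None]]:
        """Ordered free-parameter slots: (name, curve index or None)."""
        layout: list[tuple[str, int | None]] = []
        for name in ("k_ox", "k_red"):
            role = self.roles.get(name, "fixed")
            if role == "global":
                layout.append((name, None))
            elif role == "per_curve":
                layout.extend((name, j) for j in range(n_curves))
        return layout


@dataclass
class FitResult:
    """Fitted rates with uncertainties and diagnostics."""

    params: dict  # {"k_ox": float | ndarray, "k_red": float | ndarray}
    stderr: dict  # same shapes; NaN when unavailable
    kbar01: np.ndarray  # per curve, s⁻¹
    kox_eff: np.ndarray  # per curve at the solution, s⁻¹
    residual: np.ndarray
    redchi: float
    cost: float
    success: bool
    message: str
    nfev: int
    cov_log10: np.ndarray | None  # covariance of log10-parameters
    layout: list  # (name, curve index or None) per free parameter
    curve_meta: list
    spec: FitSpec
    starts: list = field(default_factory=list)  # (x0, cost) per multistart

    def value(self, name: str, curve: int | None = None) -> float:
        v = self.params[name]
        return float(v if np.isscalar(v) else v[curve if curve is not None else 0])

    def error(self, name: str, curve: int | None = None) -> float:
        v = self.stderr[name]
        return float(v if np.isscalar(v) else v[curve if curve is not None else 0])

    def to_dict(self) -> dict:
        """JSON-ready summary; rates reported in µs⁻¹."""

        def per_us(v):
            return (np.asarray(v) * 1e-6).tolist() if not np.isscalar(v) else v * 1e-6

        return {
            "params_per_us": {k: per_us(v) for k, v in self.params.items()},
            "stderr_per_us": {k: per_us(v) for k, v in self.stderr.items()},
            "kbar01_per_us": (self.kbar01 * 1e-6).tolist(),
            "kox_eff_per_us": (self.kox_eff * 1e-6).tolist(),
            "redchi": self.redchi,
            "success": self.success,
            "message": self.message,
            "nfev": self.nfev,
            "curve_meta": self.curve_meta,
        }


# ---------------------------------------------------------------------------


def _kbar01_for_curve(curve: TrastCurve, spec: FitSpec) -> float:
    try:
        i_exc = float(curve.meta["i_exc_kw_cm2"])
    except KeyError:
        raise ValueError(
            "curve metadata lacks 'i_exc_kw_cm2'; the excitation irradiance "
            "is required to compute the volume-averaged excitation rate"
        ) from None
    rates = RateConstants(k10=spec.k10, sigma=spec.sigma)
    wavelength = float(curve.meta.get("wavelength_nm", spec.wavelength))
    return average_excitation_rate(spec.beam, rates, i_exc, wavelength)


def _expand_params(
    params: Mapping, n_curves: int
) -> tuple[np.ndarray, np.ndarray]:
    """Broadcast k_ox / k_red entries to per-curve arrays."""
    out = []
    for name in ("k_ox", "k_red"):
        v = np.asarray(params[name], dtype=float)
        out.append(np.broadcast_to(v, (n_curves,)).astype(float))
    return out[0], out[1]


def _model_fnorm(
    k_ox_j: float, k_red_j: float, kbar: float, k10: float, curve: TrastCurve
) -> np.ndarray:
    kox_eff = k_ox_j * kbar / (kbar + k10)
    f = two_state_closed_form(kox_eff, k_red_j, curve.w_values)
    w0 = curve.meta.get("w0_s")
    if w0 is not None:
        f = f / two_state_closed_form(kox_eff, k_red_j, float(w0))
    return f


def _whitener(curve: TrastCurve) -> np.ndarray | None:
    """Cholesky factor L of the per-curve error covariance, or None.

    When preprocessing exported the normalization-level covariance factor
    (``drift_cov_factor``, or the rank-one ``anchor_rel_var``), the curve's
    errors are Σ = diag(f²/N) + (f∘U)(f∘U)ᵀ — per-point shot noise plus
    the correlated normalization error. Solving L·y = r whitens the
    residuals so the least-squares covariance stays calibrated.
    """
    meta = curve.meta
    if "n_net_counts" not in meta:
        return None
    n_w = np.asarray(meta["n_net_counts"], dtype=float)
    f = curve.f_norm
    if "drift_cov_factor" in meta:
        U = np.asarray(meta["drift_cov_factor"], dtype=float)
        fU = f[:, None] * U
        cov = np.diag(f**2 / n_w) + fU @ fU.T
    elif "anchor_rel_var" in meta:
        arv = float(meta["anchor_rel_var"])
        cov = np.diag(f**2 / n_w) + arv * np.outer(f, f)
    else:
        return None
    return np.linalg.cholesky(cov)


def _weighting_ops(curves: Sequence[TrastCurve], spec: FitSpec) -> list:
    """Per-curve residual-weighting operators: a Cholesky factor (whitened
    GLS), a sem vector (diagonal), or None (uniform)."""
    ops = []
    for c in curves:
        if spec.weighting == "uniform":
            ops.append(None)
            continue
        L = _whitener(c)
        if L is not None:
            ops.append(L)
        else:
            ops.append(np.where(np.isfinite(c.sem) & (c.sem > 0), c.sem, 1.0))
    return ops


def _apply_weight(op, r: np.ndarray) -> np.ndarray:
    if op is None:
        return r
    if op.ndim == 2:
        from scipy.linalg import solve_triangular

        return solve_triangular(op, r, lower=True)
    return r / op


def residuals(
    params: Mapping,
    curves: Sequence[TrastCurve],
    spec: FitSpec,
    kbar01: np.ndarray | None = None,
    weight_ops: list | None = None,
) -> np.ndarray:
    """Weighted residual vector over all curves.

    ``params`` maps "k_ox"/"k_red" to a scalar (shared) or a length-n_curves
    array. With ``weighting="sem"`` each curve's residuals are whitened by
    its error covariance when the preprocessing metadata provides it, and
    divided by sem otherwise; ``"uniform"`` applies no weighting.
    """
    n = len(curves)
    if kbar01 is None:
        kbar01 = np.array([_kbar01_for_curve(c, spec) for c in curves])
    if weight_ops is None:
        weight_ops = _weighting_ops(curves, spec)
    k_ox, k_red = _expand_params(params, n)
    parts = []
    for j, curve in enumerate(curves):
        f_model = _model_fnorm(k_ox[j], k_red[j], kbar01[j], spec.k10, curve)
        parts.append(_apply_weight(weight_ops[j], f_model - curve.f_norm))
    return np.concatenate(parts)


def _params_from_x(
    x: np.ndarray, layout: list, spec: FitSpec, n_curves: int
) -> dict:
    vals = {"k_ox": np.empty(n_curves), "k_red": np.empty(n_curves)}
    for name in ("k_ox", "k_red"):
        if spec.roles.get(name, "fixed") == "fixed":
            vals[name][:] = spec.initial.get(name, 0.0)
    for xi, (name, j) in zip(x, layout):
        v = 10.0**xi
        if j is None:
            vals[name][:] = v
        else:
            vals[name][j] = v
    return vals


def fit_global(curves: Sequence[TrastCurve], spec: FitSpec | None = None) -> FitResult:
    """Fit one or many TRAST curves per the given specification.

    Runs a trust-region-reflective least-squares solve from the specified
    initial point plus ``spec.multistart − 1`` seeded log-uniform draws
    within the bounds; the best-cost solution is returned with every start
    logged. Non-convergence flags the result rather than raising; a free
    parameter ending on a bound raises a warning.
    """
    spec = spec or FitSpec()
    if not curves:
        raise ValueError("need at least one curve")
    n = len(curves)
    kbar01 = np.array([_kbar01_for_curve(c, spec) for c in curves])
    layout = spec.param_layout(n)
    p = len(layout)

    lo = np.array([math.log10(spec.bounds[name][0]) for name, _ in layout])
    hi = np.array([math.log10(spec.bounds[name][1]) for name, _ in layout])
    x_init = np.array([math.log10(spec.initial[name]) for name, _ in layout])
    weight_ops = _weighting_ops(curves, spec)

    def fun(x: np.ndarray) -> np.ndarray:
        return residuals(
            _params_from_x(x, layout, spec, n), curves, spec, kbar01, weight_ops
        )

    rng = np.random.default_rng(spec.seed)
    starts = [x_init]
    for _ in range(max(0, spec.multistart - 1)):
        starts.append(lo + (hi - lo) * rng.random(p))

    best = None
    start_log = []
    for x0 in starts:
        res = least_squares(
            fun, x0, bounds=(lo, hi), method="trf",
            xtol=1e-14, ftol=1e-12, gtol=1e-10, max_nfev=2000 * p,
        )
        start_log.append((x0.copy(), float(res.cost)))
        if best is None or res.cost < best.cost:
            best = res

    x = best.x
    if np.any(np.isclose(x, lo, atol=1e-9)) or np.any(np.isclose(x, hi, atol=1e-9)):
        warnings.warn("fitted parameter(s) at a bound", stacklevel=2)

    n_data = sum(len(c) for c in curves)
    dof = max(n_data - p, 1)
    cost = float(best.cost)
    redchi = 2.0 * cost / dof

    # covariance of log10-parameters from the Gauss-Newton approximation,
    # scaled by the reduced chi-square
    J = best.jac
    cov_log10 = None
    stderr_log = np.full(p, np.nan)
    try:
        JTJ = J.T @ J
        cov_log10 = np.linalg.pinv(JTJ) * redchi
        stderr_log = np.sqrt(np.maximum(np.diag(cov_log10), 0.0))
    except np.linalg.LinAlgError:
        pass

    vals = _params_from_x(x, layout, spec, n)
    errs = {"k_ox": np.zeros(n), "k_red": np.zeros(n)}
    ln10 = math.log(10.0)
    for (name, j), xi, se in zip(layout, x, stderr_log):
        e = (10.0**xi) * ln10 * se
        if j is None:
            errs[name][:] = e
        else:
            errs[name][j] = e

    def collapse(name: str, arr: np.ndarray):
        role = spec.roles.get(name, "fixed")
        return float(arr[0]) if role in ("global", "fixed") else arr

    params_out = {k: collapse(k, v) for k, v in vals.items()}
    err_out = {k: collapse(k, v) for k, v in errs.items()}
    k_ox_arr, _ = _expand_params(params_out, n)
    kox_eff = k_ox_arr * kbar01 / (kbar01 + spec.k10)

    converged = bool(best.status > 0)
    return FitResult(
        params=params_out,
        stderr=err_out,
        kbar01=kbar01,
        kox_eff=kox_eff,
        residual=best.fun,
        redchi=redchi,
        cost=cost,
        success=converged,
        message=best.message,
        nfev=int(best.nfev),
        cov_log10=cov_log10,
        layout=layout,
        curve_meta=[dict(c.meta) for c in curves],
        spec=spec,
        starts=start_log,
    )


def estimate_uncertainty(
    result: FitResult,
    method: Literal["covariance", "bootstrap"] = "covariance",
    curves: Sequence[TrastCurve] | None = None,
    n_boot: int = 100,
    seed: int = 0,
) -> dict:
    """Standard errors (covariance) or percentile intervals (bootstrap).

    The bootstrap resamples the weighted residuals at the solution, adds
    them back onto the model curves, and refits; it requires the original
    curves. Reported per parameter slot in the layout order, in s⁻¹.
    """
    if not result.success:
        raise ValueError("uncertainty requires a converged fit")
    if method == "covariance":
        if result.cov_log10 is None:
            raise ValueError(
                "covariance unavailable (singular Jacobian); try bootstrap"
            )
        return {"method": "covariance", "stderr": result.stderr}
    if method != "bootstrap":
        raise ValueError(f"unknown method {method!r}")
    if curves is None:
        raise ValueError("bootstrap needs the fitted curves")

    spec = result.spec
    n = len(curves)
    kbar01 = result.kbar01
    k_ox, k_red = _expand_params(result.params, n)
    models = [
        _model_fnorm(k_ox[j], k_red[j], kbar01[j], spec.k10, c)
        for j, c in enumerate(curves)
    ]
    resid = result.residual  # weighted/whitened; iid under the error model
    weight_ops = _weighting_ops(curves, spec)
    rng = np.random.default_rng(seed)
    refit_spec = replace(spec, multistart=1)
    samples = []
    for _ in range(n_boot):
        rs = rng.choice(resid, size=resid.size, replace=True)
        boot_curves = []
        pos = 0
        for j, c in enumerate(curves):
            m = len(c)
            op = weight_ops[j]
            z = rs[pos : pos + m]
            if op is None:
                noise = z
            elif op.ndim == 2:
                noise = op @ z  # color the resampled whitened residuals
            else:
                noise = z * op
            f = np.clip(models[j] + noise, 1e-9, None)
            boot_curves.append(
                TrastCurve(w_values=c.w_values, f_norm=f, sem=c.sem, meta=c.meta)
            )
            pos += m
        fr = fit_global(boot_curves, refit_spec)
        ka, kr = _expand_params(fr.params, n)
        samples.append(np.concatenate([[ka[0]], kr]))
    S = np.array(samples)
    lo_q, hi_q = np.percentile(S, [2.5, 97.5], axis=0)
    return {
        "method": "bootstrap",
        "n_boot": n_boot,
        "std": S.std(axis=0, ddof=1),
        "ci95_low": lo_q,
        "ci95_high": hi_q,
        "columns": ["k_ox"] + [f"k_red[{j}]" for j in range(n)],
    }
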