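"""From concentration profiles to predicted transfection efficiency (%TR).

The fraction of cells transfected at depth z scales with the local plasmid
concentration at pulse time, P1(z) = K * c(z, t_inc), and the well-level
efficiency is the depth integral

    %TR = K * integral_0^d g(c(z, t_inc)) dz,

where K (units %TR per µg/ml per mm, so a uniform concentration times the gel
thickness gives %TR directly) absorbs cell density and pulse-protocol
efficacy, and g is a dose-response correction: linear up to ``c_linear_max``
(10 µg/ml), a plateau up to the toxicity onset ``c_toxic`` (40 µg/ml), then a
linear decline to extinction at ``c_extinct``.  K is a condition-dependent
calibration constant, never a universal number; :func:`calibrate_K` fits it
from observed efficiencies, and :func:`calibrate_K_D` jointly recovers K and
the gel diffusivity from a mixed-administration experiment set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .diffusion import (
    ConcentrationProfile,
    GelGeometry,
    convolve_profile,
    halfspace_profile,
    injection_profile,
    standard_grid,
)
from .electrokinetics import PulseProtocol, advect_diffuse_pulse
from .media import GelMedium, diffusion_coefficient, electrophoretic_mobility

__all__ = [
    "DoseResponse",
    "PredictionRecord",
    "CalibrationRecord",
    "CalibrationResult",
    "dose_response",
    "transfection_probability",
    "percent_transfection",
    "predict_protocol",
    "calibrate_K",
    "calibrate_K_D",
    "compare_predictions",
]


@dataclass(frozen=True)
class DoseResponse:
    """Transfection dose-response parameters.

    ``K``: %TR per (µg/ml · mm); ``c_linear_max``: top of the linear regime;
    ``c_toxic``: toxicity onset; ``c_extinct``: concentration at which the
    toxic decline reaches zero.
    """

    K: float = 1.0
    c_linear_max: float = 10.0
    c_toxic: float = 40.0
    c_extinct: float = 200.0

    def __post_init__(self):
        if self.K <= 0:
            raise ValueError("K must be > 0")
        if not (0 < self.c_linear_max <= self.c_toxic < self.c_extinct):
            raise ValueError("require 0 < c_linear_max <= c_toxic < c_extinct")


@dataclass
class PredictionRecord:
    """One predicted (optionally observed) experimental condition."""

    label: str
    t_inc_s: float
    administration: str
    predicted_tr_pct: float
    c0_ug_ml: float | None = None
    dose_ug: float | None = None
    protocol: str | None = None
    observed_tr_pct: float | None = None
    observed_sd: float | None = None
    profile: ConcentrationProfile | None = field(default=None, repr=False)

    def __post_init__(self):
        if not (0.0 <= self.predicted_tr_pct <= 100.0):
            raise ValueError("%TR must lie in [0, 100]")


@dataclass(frozen=True)
class CalibrationRecord:
    """One observed well/condition used for calibration."""

    t_inc_s: float
    observed_tr_pct: float
    c0_ug_ml: float | None = None
    dose_ug: float | None = None
    administration: str = "top"


@dataclass
class CalibrationResult:
    K: float
    D_cm2_s: float | None
    rmse: float
    residuals: np.ndarray
    n_records: int


def dose_response(c_ug_ml, dr: DoseResponse):
    """Effective (dose-response-corrected) concentration g(c), in µg/ml.

    Identity in the linear regime, constant plateau between the linear top
    and the toxicity onset, then a continuous linear decline to zero at
    ``c_extinct``.  Accepts scalars or arrays.
    """
    c = np.asarray(c_ug_ml, dtype=float)
    decline = dr.c_linear_max * np.clip(
        1.0 - (c - dr.c_toxic) / (dr.c_extinct - dr.c_toxic), 0.0, 1.0
    )
    g = np.where(
        c <= dr.c_linear_max, c, np.where(c <= dr.c_toxic, dr.c_linear_max, decline)
    )
    return float(g) if np.isscalar(c_ug_ml) else g


def transfection_probability(
    profile: ConcentrationProfile, dr: DoseResponse
) -> np.ndarray:
    """Per-node transfection probability (fraction in [0, 1]).

    Each node's probability is its trapezoid-weighted contribution to the
    %TR integral, K * g(c) * w / 100 with w the local quadrature weight in
    mm, clipped at 1.  Zero wherever the local concentration is zero.
    """
    z = profile.z_um
    w = np.empty_like(z)
    w[1:-1] = (z[2:] - z[:-2]) / 2.0
    w[0] = (z[1] - z[0]) / 2.0
    w[-1] = (z[-1] - z[-2]) / 2.0
    p = dr.K * dose_response(profile.c_ug_ml, dr) * (w / 1000.0) / 100.0
    return np.clip(p, 0.0, 1.0)


def percent_transfection(
    profile: ConcentrationProfile,
    dr: DoseResponse,
    geometry: GelGeometry | None = None,
    clip: bool = True,
) -> float:
    """Well-level efficiency %TR = K * integral_0^d g(c) dz (trapezoid rule).

    The profile must span the full gel depth [0, d]; clipping to [0, 100] is
    applied after integration (set ``clip=False`` for the raw linear value,
    used internally by the calibration).
    """
    geometry = geometry or GelGeometry()
    z = profile.z_um
    d = geometry.thickness_um
    tol = 1e-6 * d
    if z[0] > tol or z[-1] < d - tol:
        raise ValueError(
            f"profile grid [{z[0]}, {z[-1]}] µm does not span the gel [0, {d}] µm"
        )
    mask = z <= d + tol
    integral_mm = np.trapezoid(dose_response(profile.c_ug_ml[mask], dr), z[mask]) / 1000.0
    tr = dr.K * integral_mm
    return float(np.clip(tr, 0.0, 100.0)) if clip else float(tr)


def predict_protocol(
    t_inc_s: float,
    *,
    dr: DoseResponse,
    administration: str = "top",
    c0_ug_ml: float | None = None,
    dose_ug: float | None = None,
    geometry: GelGeometry | None = None,
    medium: GelMedium | None = None,
    D_cm2_s: float | None = None,
    protocol: PulseProtocol | None = None,
    apply_pulse: bool = False,
    injection_depth_um: float | None = None,
    injection_spread_um: float = 250.0,
    applied_volume_ml: float = 0.2,
    label: str | None = None,
    observed_tr_pct: float | None = None,
    observed_sd: float | None = None,
) -> PredictionRecord:
    """End-to-end efficiency prediction for one experimental condition.

    Builds the pre-pulse profile — the half-space reservoir solution for
    plasmid applied on top, or a reflected Gaussian bolus spread by diffusion
    for plasmid injected into the gel — optionally transports it through the
    pulse protocol (drift + diffusion), and integrates the dose-response
    weighted profile into %TR.

    Either ``c0_ug_ml`` or ``dose_ug`` must be given; for top administration a
    dose is converted to a reservoir concentration via ``applied_volume_ml``.
    ``D_cm2_s`` overrides the medium lookup (exactly one of the two sources
    must be available).
    """
    if t_inc_s < 0:
        raise ValueError("incubation time must be >= 0")
    geometry = geometry or GelGeometry()
    if D_cm2_s is None:
        if medium is None:
            raise ValueError("provide either D_cm2_s or a medium")
        D_cm2_s = diffusion_coefficient(medium)

    if administration == "top":
        if c0_ug_ml is None:
            if dose_ug is None:
                raise ValueError("top administration needs c0_ug_ml or dose_ug")
            c0_ug_ml = dose_ug / applied_volume_ml
        profile = halfspace_profile(c0_ug_ml, D_cm2_s, t_inc_s, geometry=geometry)
    elif administration == "injected":
        if dose_ug is None:
            raise ValueError("injected administration needs dose_ug")
        initial = injection_profile(
            dose_ug, injection_depth_um, injection_spread_um, geometry
        )
        profile = (
            convolve_profile(initial, D_cm2_s, t_inc_s, boundary="reflect")
            if t_inc_s > 0
            else initial
        )
    else:
        raise ValueError("administration must be 'top' or 'injected'")

    if apply_pulse:
        if protocol is None:
            raise ValueError("apply_pulse requires a protocol")
        if medium is None:
            raise ValueError("pulse transport requires a medium for mobility lookup")
        mobility = lambda seg: electrophoretic_mobility(
            medium, pulse_duration_s=seg.t_p_s
        )
        profile = advect_diffuse_pulse(
            profile, protocol, mobility, D_cm2_s, geometry
        ).profile

    tr = percent_transfection(profile, dr, geometry)
    return PredictionRecord(
        label=label or f"{administration}, t_inc={t_inc_s:g}s",
        t_inc_s=t_inc_s,
        administration=administration,
        predicted_tr_pct=tr,
        c0_ug_ml=c0_ug_ml,
        dose_ug=dose_ug,
        protocol=protocol.name if protocol is not None else None,
        observed_tr_pct=observed_tr_pct,
        observed_sd=observed_sd,
        profile=profile,
    )


def _as_calibration_records(records) -> list[CalibrationRecord]:
    out = []
    for r in records:
        if isinstance(r, CalibrationRecord):
            out.append(r)
        else:
            t_inc, c0, obs = r
            out.append(CalibrationRecord(t_inc_s=t_inc, c0_ug_ml=c0, observed_tr_pct=obs))
    return out


def _design_response(
    records: list[CalibrationRecord],
    D_cm2_s: float,
    dr: DoseResponse,
    geometry: GelGeometry,
) -> np.ndarray:
    """Unclipped %TR per record at K = 1 (the model is linear in K)."""
    unit = replace(dr, K=1.0)
    out = np.empty(len(records))
    for j, rec in enumerate(records):
        pred = predict_protocol(
            rec.t_inc_s,
            dr=unit,
            administration=rec.administration,
            c0_ug_ml=rec.c0_ug_ml,
            dose_ug=rec.dose_ug,
            geometry=geometry,
            D_cm2_s=D_cm2_s,
        )
        out[j] = percent_transfection(pred.profile, unit, geometry, clip=False)
    return out


def calibrate_K(
    records,
    D_cm2_s: float,
    dr: DoseResponse | None = None,
    geometry: GelGeometry | None = None,
) -> CalibrationResult:
    """Least-squares fit of the proportionality constant K.

    ``records`` is a sequence of :class:`CalibrationRecord` (or
    ``(t_inc_s, c0_ug_ml, observed_tr_pct)`` tuples for top administration).
    All other dose-response parameters stay fixed; since the prediction is
    linear in K, the optimum is the closed-form projection
    ``K = sum(I_j y_j) / sum(I_j^2)`` with I_j the unit-K prediction.
    """
    geometry = geometry or GelGeometry()
    dr = dr or DoseResponse()
    recs = _as_calibration_records(records)
    if not recs:
        raise ValueError("at least one calibration record is required")
    y = np.array([r.observed_tr_pct for r in recs], dtype=float)
    if np.all(y == 0):
        raise ValueError("all observed efficiencies are zero; K is unidentifiable")
    I = _design_response(recs, D_cm2_s, dr, geometry)
    denom = float(np.dot(I, I))
    if denom == 0:
        raise ValueError("model predicts zero for every record; K is unidentifiable")
    K = float(np.dot(I, y)) / denom
    resid = y - K * I
    return CalibrationResult(
        K=K,
        D_cm2_s=D_cm2_s,
        rmse=float(np.sqrt(np.mean(resid**2))),
        residuals=resid,
        n_records=len(recs),
    )


def calibrate_K_D(
    records,
    dr: DoseResponse | None = None,
    geometry: GelGeometry | None = None,
    D_bounds_cm2_s: tuple[float, float] = (1e-10, 1e-6),
) -> CalibrationResult:
    """Joint fit of (K, D) by profiling K out of a 1-D search over log10 D.

    For each trial diffusivity the optimal K is closed-form (the model is
    linear in K), so the joint problem reduces to a bounded scalar
    minimization of the residual sum of squares over log10 D.  Identifying D
    requires records whose profile *shape* responds to D — e.g. a mix of
    top-applied (which constrains K·sqrt(D)) and injected (dose-conserving,
    which pins K) conditions.
    """
    geometry = geometry or GelGeometry()
    dr = dr or DoseResponse()
    recs = _as_calibration_records(records)
    y = np.array([r.observed_tr_pct for r in recs], dtype=float)
    if np.all(y == 0):
        raise ValueError("all observed efficiencies are zero; fit is unidentifiable")

    def sse(log10_D: float) -> float:
        I = _design_response(recs, 10.0**log10_D, dr, geometry)
        denom = float(np.dot(I, I))
        if denom == 0:
            return float(np.dot(y, y))
        K = float(np.dot(I, y)) / denom
        r = y - K * I
        return float(np.dot(r, r))

    lo, hi = np.log10(D_bounds_cm2_s[0]), np.log10(D_bounds_cm2_s[1])
    opt = minimize_scalar(sse, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-4})
    D_hat = 10.0**opt.x
    result = calibrate_K(recs, D_hat, dr, geometry)
    result.D_cm2_s = D_hat
    return result


def compare_predictions(predictions) -> tuple[pd.DataFrame, dict]:
    """Align predictions with observations and summarize the agreement.

    Returns the comparison table and metrics: RMSE over observed records and
    rank agreement (fraction of concordant prediction/observation pairs; ties
    count half).  With fewer than two observed records the rank agreement is
    undefined (None) and flagged.
    """
    rows = []
    for p in predictions:
        rows.append(
            {
                "condition": p.label,
                "t_inc_s": p.t_inc_s,
                "administration": p.administration,
                "c0_ug_ml": p.c0_ug_ml,
                "dose_ug": p.dose_ug,
                "protocol": p.protocol,
                "predicted_TR_pct": p.predicted_tr_pct,
                "observed_TR_pct": p.observed_tr_pct,
                "residual": (
                    p.predicted_tr_pct - p.observed_tr_pct
                    if p.observed_tr_pct is not None
                    else np.nan
                ),
            }
        )
    table = pd.DataFrame(rows)
    observed = table.dropna(subset=["observed_TR_pct"])
    metrics: dict = {"n_observed": len(observed)}
    if len(observed) == 0:
        metrics.update(rmse=None, rank_agreement=None, rank_agreement_defined=False)
        return table, metrics
    metrics["rmse"] = float(np.sqrt(np.mean(observed["residual"] ** 2)))
    if len(observed) < 2:
        metrics.update(rank_agreement=None, rank_agreement_defined=False)
        return table, metrics
    pred = observed["predicted_TR_pct"].to_numpy()
    obs = observed["observed_TR_pct"].to_numpy()
    concordant = 0.0
    total = 0
    for i in range(len(pred)):
        for j in range(i + 1, len(pred)):
            total += 1
            s = (pred[i] - pred[j]) * (obs[i] - obs[j])
            if s > 0:
                concordant += 1.0
            elif s == 0:
                concordant += 0.5
    metrics.update(
        rank_agreement=concordant / total, rank_agreement_defined=True
    )
    return table, metrics
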