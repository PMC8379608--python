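"""Synthetic gene-electrotransfer experiments for pipeline and calibration tests.

The experimental readout this emulates is a per-well percentage of
transfected cells: fluorescent cells counted manually over several fields
divided by the total count.  The generator computes a true efficiency for
each condition from the transport + dose-response model, then draws the
number of transfected cells per well from a binomial (optionally
beta-binomial, for well-to-well overdispersion) distribution.  Random streams
are keyed per (seed, condition, replicate), so adding conditions never
perturbs existing draws and a fixed seed reproduces a dataset byte for byte.

Also houses the frozen reference tables used throughout the tests: the
published pulse-schedule table (mobilities, displacements, energy factors and
measured efficiencies for the 0.35 % and 3 % gels) and the study's condition
grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffusion import GelGeometry
from .transfection import DoseResponse, predict_protocol

__all__ = [
    "SyntheticExperiment",
    "TruthConfig",
    "Condition",
    "generate_experiment",
    "experiments_to_frame",
    "frame_to_calibration_records",
    "experiments_to_calibration_records",
    "table2_fixture",
    "study_conditions_fixture",
    "default_calibration_conditions",
]


@dataclass(frozen=True)
class Condition:
    """One experimental condition (a point on the study grid)."""

    label: str
    t_inc_s: float
    administration: str = "top"
    c0_ug_ml: float | None = None
    dose_ug: float | None = None
    protocol: str | None = None
    observed_tr_pct: float | None = None


@dataclass(frozen=True)
class TruthConfig:
    """Ground truth for the generator.

    ``overdispersion`` is the variance inflation factor relative to binomial
    counting noise (1 = pure binomial); ``wells_per_condition`` defaults to
    triplicate wells.
    """

    true_K: float = 1.0
    true_D_cm2_s: float = 3.0e-8
    c_linear_max: float = 10.0
    c_toxic: float = 40.0
    c_extinct: float = 200.0
    overdispersion: float = 1.0
    wells_per_condition: int = 3

    def __post_init__(self):
        if self.true_K <= 0 or self.true_D_cm2_s <= 0:
            raise ValueError("true K and D must be > 0")
        if self.overdispersion < 1.0:
            raise ValueError("overdispersion factor must be >= 1")
        if self.wells_per_condition < 1:
            raise ValueError("wells_per_condition must be >= 1")

    @property
    def dose_response(self) -> DoseResponse:
        return DoseResponse(
            K=self.true_K,
            c_linear_max=self.c_linear_max,
            c_toxic=self.c_toxic,
            c_extinct=self.c_extinct,
        )


@dataclass(frozen=True)
class SyntheticExperiment:
    """One simulated well."""

    label: str
    t_inc_s: float
    administration: str
    c0_ug_ml: float | None
    dose_ug: float | None
    protocol: str | None
    n_cells: int
    n_transfected: int
    replicate: int
    seed: int
    true_tr_pct: float

    @property
    def tr_pct(self) -> float:
        return 100.0 * self.n_transfected / self.n_cells


def _draw_count(rng, n_cells: int, p: float, overdispersion: float) -> int:
    if p <= 0.0:
        return 0
    if p >= 1.0:
        return n_cells
    if overdispersion > 1.0 and n_cells > 1:
        # beta-binomial with variance n p (1-p) * overdispersion
        rho = (overdispersion - 1.0) / (n_cells - 1)
        if rho >= 1.0:
            raise ValueError("overdispersion too large for this cell count")
        a = p * (1.0 - rho) / rho
        b = (1.0 - p) * (1.0 - rho) / rho
        p = rng.beta(a, b)
    return int(rng.binomial(n_cells, p))


def generate_experiment(
    truth: TruthConfig,
    conditions,
    n_cells: int = 500,
    seed: int = 0,
    geometry: GelGeometry | None = None,
    wells_per_condition: int | None = None,
) -> list[SyntheticExperiment]:
    """Simulate counted wells for every condition.

    The true efficiency per condition comes from :func:`predict_protocol`
    with the truth's K and D; each well then draws its transfected count
    from binomial(n_cells, %TR/100), beta-inflated when the truth's
    overdispersion factor exceeds 1.  Fully reproducible: well (i, r) uses
    the stream ``default_rng([seed, i, r])``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if seed is None:
        raise ValueError("a seed is required; there is no hidden global RNG")
    geometry = geometry or GelGeometry()
    wells = wells_per_condition or truth.wells_per_condition
    dr = truth.dose_response
    out = []
    for i, cond in enumerate(conditions):
        pred = predict_protocol(
            cond.t_inc_s,
            dr=dr,
            administration=cond.administration,
            c0_ug_ml=cond.c0_ug_ml,
            dose_ug=cond.dose_ug,
            geometry=geometry,
            D_cm2_s=truth.true_D_cm2_s,
            label=cond.label,
        )
        p = pred.predicted_tr_pct / 100.0
        if not (0.0 <= p <= 1.0) or not np.isfinite(p):
            raise RuntimeError(
                f"internal consistency error: true %TR {pred.predicted_tr_pct} "
                f"outside [0, 100] for condition {cond.label!r}"
            )
        for r in range(wells):
            rng = np.random.default_rng([seed, i, r])
            k = _draw_count(rng, n_cells, p, truth.overdispersion)
            out.append(
                SyntheticExperiment(
                    label=cond.label,
                    t_inc_s=cond.t_inc_s,
                    administration=cond.administration,
                    c0_ug_ml=cond.c0_ug_ml,
                    dose_ug=cond.dose_ug,
                    protocol=cond.protocol,
                    n_cells=n_cells,
                    n_transfected=k,
                    replicate=r,
                    seed=seed,
                    true_tr_pct=pred.predicted_tr_pct,
                )
            )
    return out


def experiments_to_frame(experiments) -> pd.DataFrame:
    """Tabulate synthetic wells (CSV-ready; includes the observed %TR)."""
    rows = []
    for e in experiments:
        rows.append(
            {
                "label": e.label,
                "t_inc_s": e.t_inc_s,
                "administration": e.administration,
                "c0_ug_ml": e.c0_ug_ml,
                "dose_ug": e.dose_ug,
                "protocol": e.protocol,
                "n_cells": e.n_cells,
                "n_transfected": e.n_transfected,
                "tr_pct": e.tr_pct,
                "replicate": e.replicate,
                "seed": e.seed,
            }
        )
    return pd.DataFrame(rows)


def experiments_to_calibration_records(experiments):
    """Map synthetic wells onto the calibration-record schema."""
    from .transfection import CalibrationRecord

    return [
        CalibrationRecord(
            t_inc_s=e.t_inc_s,
            observed_tr_pct=e.tr_pct,
            c0_ug_ml=e.c0_ug_ml,
            dose_ug=e.dose_ug,
            administration=e.administration,
        )
        for e in experiments
    ]


def frame_to_calibration_records(frame: pd.DataFrame):
    """Calibration records from a synthetic-experiment table (e.g. read from CSV)."""
    from .transfection import CalibrationRecord

    recs = []
    for r in frame.itertuples():
        c0 = None if pd.isna(r.c0_ug_ml) else float(r.c0_ug_ml)
        dose = None if pd.isna(r.dose_ug) else float(r.dose_ug)
        recs.append(
            CalibrationRecord(
                t_inc_s=float(r.t_inc_s),
                observed_tr_pct=float(r.tr_pct),
                c0_ug_ml=c0,
                dose_ug=dose,
                administration=str(r.administration),
            )
        )
    return recs


def table2_fixture() -> pd.DataFrame:
    """The published pulse-schedule table for the 0.35 % and 3 % gels.

    Columns: pulse schedule (8 pulses at 0.8 kV/cm of the stated duration),
    electrophoretic mobilities in the two gels, the resulting displacements,
    the energy factor U²·t_E at 160 V, and the measured efficiency in the
    0.35 % gel.  Returned as a fresh DataFrame each call (regression fixture).
    """
    rows = [
        ("8x200us", 8, 200e-6, 0.8, 160.0, 0.2e-8, 0.03e-8, 0.256, 0.0384, 40.96, 0.65),
        ("8x1ms", 8, 1e-3, 0.8, 160.0, 1.0e-8, 0.03e-8, 6.4, 0.192, 204.8, 1.55),
        ("8x5ms", 8, 5e-3, 0.8, 160.0, 2.4e-8, 0.03e-8, 76.8, 0.96, 1024.0, 3.58),
        ("8x10ms", 8, 10e-3, 0.8, 160.0, 2.8e-8, 0.03e-8, 179.2, 1.92, 2048.0, 2.16),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "label",
            "n_pulses",
            "t_p_s",
            "E_kV_per_cm",
            "U_V",
            "mu_gel035_m2_per_Vs",
            "mu_gel3_m2_per_Vs",
            "L_E_gel035_um",
            "L_E_gel3_um",
            "U2tE_V2s",
            "TR_pct_gel035",
        ],
    )


def study_conditions_fixture() -> list[Condition]:
    """The study's experimental condition grid, with observed efficiencies
    where the study reports them.

    Three cell models pulsed with 8 pulses of 200 µs / 1 ms / 5 ms at
    0.8 kV/cm with plasmid at 90 µg/ml on top; HV/LV combinations and
    single-vs-orthogonal polarity protocols on the embedded model; and
    top-vs-injected administration of an 18.2 µg dose at 8 x 1 ms and
    8 x 2 ms for 0.6 / 0.8 / 1.0 kV/cm.  The default pre-pulse incubation
    was 30 min.
    """
    t30 = 1800.0
    conds: list[Condition] = []
    for model in ("plated", "collagen-top", "embedded"):
        for dur_label, t_p in (("200us", 200e-6), ("1ms", 1e-3), ("5ms", 5e-3)):
            obs = {
                ("plated", "5ms"): 54.2,
                ("collagen-top", "5ms"): 12.5,
                ("embedded", "5ms"): 2.5,
            }.get((model, dur_label))
            conds.append(
                Condition(
                    label=f"{model}, 8 x {dur_label}, 0.8 kV/cm, top, 90 ug/ml",
                    t_inc_s=t30,
                    administration="top",
                    c0_ug_ml=90.0,
                    protocol=f"8x{dur_label}",
                    observed_tr_pct=obs,
                )
            )
    for proto, obs in (
        ("HV1", None),
        ("HV2", None),
        ("HV1+LV1", None),
        ("HV2+LV2", 3.5),
        ("SP", None),
        ("OBP", 1.88),
    ):
        conds.append(
            Condition(
                label=f"embedded, {proto} (HV-LV lag 20 ms), top, 90 ug/ml",
                t_inc_s=t30,
                administration="top",
                c0_ug_ml=90.0,
                protocol=proto,
                observed_tr_pct=obs,
            )
        )
    for admin in ("top", "injected"):
        for dur in ("1ms", "2ms"):
            for e_field in (0.6, 0.8, 1.0):
                obs = None
                if dur == "2ms" and e_field == 1.0:
                    obs = 6.7 if admin == "injected" else 4.3
                conds.append(
                    Condition(
                        label=f"embedded, 8 x {dur}, {e_field} kV/cm, {admin}, 18.2 ug",
                        t_inc_s=t30,
                        administration=admin,
                        dose_ug=18.2,
                        c0_ug_ml=91.0 if admin == "top" else None,
                        protocol=f"8x{dur}@{e_field}",
                        observed_tr_pct=obs,
                    )
                )
    return conds


def default_calibration_conditions() -> list[Condition]:
    """Condition grid used for (K, D) parameter-recovery studies.

    Mixes top administration (whose half-space profiles are self-similar, so
    they constrain the product K·sqrt(D)) with injected boluses (whose
    efficiency level is dose-conserving and therefore pins K on its own);
    combining the two arms separates K from D.  Ten conditions over a
    15–240 min incubation ladder; with five wells each this is the 50-well
    recovery design.
    """
    conds = []
    for minutes in (15, 30, 60, 120, 240):
        conds.append(
            Condition(
                f"top, 90 ug/ml, {minutes} min", 60.0 * minutes, "top", c0_ug_ml=90.0
            )
        )
    for minutes in (15, 30, 60, 120, 240):
        conds.append(
            Condition(
                f"injected, 18.2 ug, {minutes} min",
                60.0 * minutes,
                "injected",
                dose_ug=18.2,
            )
        )
    return conds
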