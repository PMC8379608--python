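"""Pulse protocols and field-driven plasmid transport.

During a pulse the negatively charged plasmid drifts toward the anode-facing
gel bottom at v = mu * E (steady state is reached in ~3e-11 s, so the drift is
effectively instantaneous on pulse time scales).  This module represents
pulse trains (high-voltage permeabilizing and low-voltage electrophoretic
segments, single-polarity or orthogonal-both-polarity), and computes the
quantities derived from them:

* per-train electrophoretic displacement L_E = mu * E * N * t_p;
* the number of plasmid copies swept past a permeabilized membrane patch,
  N_DNA = c * L_E * S;
* the electrophoresis-to-diffusion ratio P_EE = mu * E * L / D over a
  transport distance L (a Péclet number);
* protocol dosimetry: the pulse energy factor U² * t_E, Joule heating
  I² R N t_p with the resulting temperature rise, and the coulomb dosage
  I N t_p (a proxy for electrode pH fronts);
* combined drift–diffusion transport of a concentration profile through a
  whole pulse train (operator splitting: upwind drift during pulses,
  Crank–Nicolson diffusion throughout).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._constants import (
    AVOGADRO,
    DNA_G_PER_MOL_PER_BP,
    KV_PER_CM_TO_V_PER_M,
    M_TO_UM,
    CM2_TO_UM2,
)
from .diffusion import ConcentrationProfile, GelGeometry, _cn_evolve
from .media import ConfigurationError, GelMedium, PlasmidSpec, effective_charge_coulombs
from .media import electrophoretic_mobility as _mobility_lookup

__all__ = [
    "PulseSegment",
    "PulseProtocol",
    "DosimetryInputs",
    "PulseTransportResult",
    "electrophoretic_force",
    "electrophoretic_velocity",
    "electrophoretic_displacement",
    "protocol_displacement",
    "available_dna",
    "pee_ratio",
    "pulse_energy_factor",
    "joule_heating",
    "coulomb_dosage",
    "advect_diffuse_pulse",
    "dosimetry_report",
    "table1_protocols",
    "table2_protocols",
]


@dataclass(frozen=True)
class PulseSegment:
    """One homogeneous train of identical pulses.

    ``E_kV_cm`` is the field strength; ``U_V`` is the generator voltage,
    carried independently of E because the two are related only through the
    electrode geometry and published energy factors need not use E * gap.
    ``polarity`` is "SP" (all pulses along +z) or "OBP" (orthogonal both
    polarities: no net displacement along the gel depth).
    """

    E_kV_cm: float
    t_p_s: float
    N: int
    repetition_frequency_hz: float = 1.0
    U_V: float | None = None
    polarity: str = "SP"
    role: str = "HV"

    def __post_init__(self):
        if self.E_kV_cm < 0:
            raise ValueError("field strength must be >= 0")
        if self.t_p_s <= 0:
            raise ValueError("pulse duration must be > 0")
        if int(self.N) != self.N or self.N < 1:
            raise ValueError("pulse count must be a positive integer")
        if self.repetition_frequency_hz <= 0:
            raise ValueError("repetition frequency must be > 0")
        if self.U_V is not None and self.U_V < 0:
            raise ValueError("voltage must be >= 0")
        if self.polarity not in ("SP", "OBP"):
            raise ValueError("polarity must be 'SP' or 'OBP'")
        if self.role not in ("HV", "LV"):
            raise ValueError("role must be 'HV' or 'LV'")
        if self.t_p_s > 1.0 / self.repetition_frequency_hz:
            raise ValueError("pulse duration exceeds the repetition period")

    @property
    def t_E_s(self) -> float:
        """Cumulative field-on time N * t_p."""
        return self.N * self.t_p_s

    @property
    def duration_s(self) -> float:
        """Wall-clock span of the train: (N-1) periods plus one pulse."""
        return (self.N - 1) / self.repetition_frequency_hz + self.t_p_s


@dataclass(frozen=True)
class PulseProtocol:
    """Ordered pulse segments, e.g. an HV train followed by an LV pulse."""

    segments: tuple
    inter_segment_lag_s: float = 0.02
    name: str = ""

    def __post_init__(self):
        if len(self.segments) == 0:
            raise ValueError("protocol must contain at least one segment")
        if self.inter_segment_lag_s < 0:
            raise ValueError("inter-segment lag must be >= 0")
        object.__setattr__(self, "segments", tuple(self.segments))

    @property
    def total_duration_s(self) -> float:
        lags = self.inter_segment_lag_s * (len(self.segments) - 1)
        return sum(s.duration_s for s in self.segments) + lags


@dataclass(frozen=True)
class DosimetryInputs:
    """Electrical and thermal sample parameters for dosimetry."""

    current_a: float
    resistance_ohm: float | None = None
    sample_mass_kg: float | None = None
    specific_heat_j_kg_k: float = 4186.0


def electrophoretic_force(plasmid: PlasmidSpec, E_kV_cm: float) -> float:
    """Force on the plasmid, F = e_eff * E, in newtons."""
    if E_kV_cm < 0:
        raise ValueError("field strength must be >= 0")
    return effective_charge_coulombs(plasmid) * E_kV_cm * KV_PER_CM_TO_V_PER_M


def electrophoretic_velocity(mu_m2_vs: float, E_kV_cm: float) -> float:
    """Steady drift velocity v = mu * E, in m/s."""
    if mu_m2_vs < 0 or E_kV_cm < 0:
        raise ValueError("mobility and field strength must be >= 0")
    return mu_m2_vs * E_kV_cm * KV_PER_CM_TO_V_PER_M


def electrophoretic_displacement(segment: PulseSegment, mu_m2_vs: float) -> float:
    """Displacement over one segment, L_E = mu * E * N * t_p, in µm."""
    return electrophoretic_velocity(mu_m2_vs, segment.E_kV_cm) * segment.t_E_s * M_TO_UM


def protocol_displacement(protocol: PulseProtocol, mobility) -> tuple[float, dict]:
    """Net depth displacement of a whole protocol, plus per-axis metadata.

    ``mobility`` is either one mobility (m²/Vs) or a callable
    ``segment -> mobility`` (so LV segments can use the mobility at their own
    pulse duration).  Single-polarity segments add along +z; orthogonal
    both-polarity segments cancel along every axis and contribute zero net
    displacement — their gross per-axis sweep (N/2 pulses per axis) is
    reported in the metadata instead.
    """
    mu_of = mobility if callable(mobility) else (lambda seg: float(mobility))
    net_z = 0.0
    per_axis: dict = {}
    for i, seg in enumerate(protocol.segments):
        L = electrophoretic_displacement(seg, mu_of(seg))
        if seg.polarity == "SP":
            net_z += L
        else:
            per_axis[f"segment{i}_obp_gross_per_axis_um"] = L / 2.0
    return net_z, per_axis


def available_dna(
    c_ug_ml: float,
    mu_m2_vs: float,
    E_kV_cm: float,
    t_E_s: float,
    S_cm2: float,
    plasmid: PlasmidSpec,
) -> float:
    """Plasmid copies swept through a membrane patch, N_DNA = c * L_E * S.

    The local mass concentration is converted to a molecule number density
    using 650 g/mol per base pair; the swept volume is the electrophoretic
    displacement times the permeabilized area S.
    """
    if min(c_ug_ml, mu_m2_vs, E_kV_cm, t_E_s, S_cm2) < 0:
        raise ValueError("all inputs must be >= 0")
    mw_g_mol = DNA_G_PER_MOL_PER_BP * plasmid.length_bp
    n_per_cm3 = c_ug_ml * 1e-6 / mw_g_mol * AVOGADRO
    L_E_cm = electrophoretic_velocity(mu_m2_vs, E_kV_cm) * t_E_s * 100.0
    return n_per_cm3 * L_E_cm * S_cm2


def pee_ratio(mu_m2_vs: float, E_kV_cm: float, L_um: float, D_cm2_s: float) -> float:
    """Electrophoresis-to-diffusion ratio P_EE = mu * E * L / D (dimensionless)."""
    if D_cm2_s <= 0:
        raise ValueError("D must be > 0")
    v_m_s = electrophoretic_velocity(mu_m2_vs, E_kV_cm)
    return v_m_s * (L_um * 1e-6) / (D_cm2_s * 1e-4)


def pulse_energy_factor(segment: PulseSegment) -> float:
    """Pulse energy factor U² * N * t_p, in V²·s.

    Requires the generator voltage U to be set explicitly: it is *not*
    derived from E times the electrode gap, because published energy factors
    and the field strength need not be mutually consistent.
    """
    if segment.U_V is None:
        raise ConfigurationError(
            "segment has no voltage U; the energy factor cannot be derived "
            "from E and an electrode gap (set U_V explicitly)"
        )
    return segment.U_V**2 * segment.t_E_s


def joule_heating(inputs: DosimetryInputs, segment: PulseSegment) -> tuple[float, float]:
    """Joule heat Q = I² R N t_p (J) and temperature rise Q / (m c_p) (K)."""
    if inputs.current_a <= 0:
        raise ValueError("current must be > 0")
    if inputs.resistance_ohm is None or inputs.resistance_ohm <= 0:
        raise ValueError("resistance must be set and > 0")
    if inputs.sample_mass_kg is None or inputs.sample_mass_kg <= 0:
        raise ValueError("sample mass must be set and > 0")
    if inputs.specific_heat_j_kg_k <= 0:
        raise ValueError("specific heat must be > 0")
    q = inputs.current_a**2 * inputs.resistance_ohm * segment.t_E_s
    return q, q / (inputs.sample_mass_kg * inputs.specific_heat_j_kg_k)


def coulomb_dosage(inputs: DosimetryInputs, segment: PulseSegment) -> float:
    """Transferred charge q = I * N * t_p, in coulombs."""
    if inputs.current_a <= 0:
        raise ValueError("current must be > 0")
    return inputs.current_a * segment.t_E_s


@dataclass
class PulseTransportResult:
    """Outcome of drift–diffusion transport through a pulse train."""

    profile: ConcentrationProfile
    exited_mass_ug: float
    per_axis_displacement: dict = field(default_factory=dict)


def _upwind_drift(
    c: np.ndarray, v_um_s: float, dz_um: float, duration_s: float
) -> tuple[np.ndarray, float]:
    """First-order upwind advection toward +z with automatic CFL sub-stepping.

    Returns the advected field and the (rectangle-rule) concentration·length
    that flowed out of the bottom.  Positivity-preserving; the centroid shift
    is exactly v * duration away from the boundaries.
    """
    if v_um_s == 0 or duration_s <= 0:
        return c, 0.0
    n_sub = max(1, int(np.ceil(v_um_s * duration_s / (0.9 * dz_um))))
    dt = duration_s / n_sub
    lam = v_um_s * dt / dz_um
    out = 0.0
    for _ in range(n_sub):
        out += lam * c[-1] * dz_um
        c[1:] -= lam * (c[1:] - c[:-1])
        c[0] -= lam * c[0]
    return c, out


def advect_diffuse_pulse(
    profile: ConcentrationProfile,
    protocol: PulseProtocol,
    mobility,
    D_cm2_s: float,
    geometry: GelGeometry | None = None,
    dt_s: float = 1.0,
) -> PulseTransportResult:
    """Transport a profile through a pulse protocol by operator splitting.

    During each pulse the profile drifts at v = mu(segment) * E (upwind
    scheme, CFL-sub-stepped); diffusion acts during pulses, between pulses
    (at the segment repetition period) and across inter-segment lags via
    Crank–Nicolson with no-flux walls.  Mass pushed past the gel bottom is
    accumulated in ``exited_mass_ug`` rather than silently lost.  ``mobility``
    is a value in m²/Vs or a callable ``segment -> mobility``.
    """
    geometry = geometry or GelGeometry()
    if D_cm2_s < 0:
        raise ValueError("D must be >= 0")
    mu_of = mobility if callable(mobility) else (lambda seg: float(mobility))
    dz = profile.dz_um
    c = profile.c_ug_ml.copy()
    D_um2 = D_cm2_s * CM2_TO_UM2
    exited_cz = 0.0  # µg/ml · µm
    per_axis: dict = {}
    elapsed = 0.0

    def diffuse(duration):
        nonlocal c
        if D_um2 > 0 and duration > 0:
            c = _cn_evolve(c, D_um2, dz, duration, dt_s, "noflux", None)

    for i, seg in enumerate(protocol.segments):
        mu = mu_of(seg)
        v = 0.0
        if seg.polarity == "SP":
            v = electrophoretic_velocity(mu, seg.E_kV_cm) * M_TO_UM  # µm/s
        else:
            per_axis[f"segment{i}_obp_gross_per_axis_um"] = (
                electrophoretic_displacement(seg, mu) / 2.0
            )
        gap = 1.0 / seg.repetition_frequency_hz - seg.t_p_s
        for pulse in range(seg.N):
            c, out = _upwind_drift(c, v, dz, seg.t_p_s)
            exited_cz += out
            diffuse(seg.t_p_s)
            if pulse < seg.N - 1:
                diffuse(gap)
        elapsed += seg.duration_s
        if i < len(protocol.segments) - 1:
            diffuse(protocol.inter_segment_lag_s)
            elapsed += protocol.inter_segment_lag_s

    out_profile = ConcentrationProfile(
        profile.z_um.copy(), c, profile.time_s + elapsed
    )
    exited_ug = exited_cz * 1e-4 * geometry.surface_area_cm2  # µm·µg/cm³ -> µg
    return PulseTransportResult(out_profile, exited_ug, per_axis)


# ---------------------------------------------------------------------------
# canonical protocols


def table1_protocols() -> dict[str, PulseProtocol]:
    """The study's named pulse protocols (HV/LV building blocks and combos).

    The lag between an HV and a following LV segment is 20 ms.
    """
    hv1 = PulseSegment(E_kV_cm=0.8, t_p_s=1e-3, N=5, role="HV")
    hv2 = PulseSegment(E_kV_cm=0.8, t_p_s=200e-6, N=8, role="HV")
    lv1 = PulseSegment(E_kV_cm=0.075, t_p_s=100e-3, N=1, role="LV")
    lv2 = PulseSegment(E_kV_cm=0.150, t_p_s=100e-3, N=1, role="LV")
    sp = PulseSegment(E_kV_cm=0.8, t_p_s=1e-3, N=8, polarity="SP")
    obp = PulseSegment(E_kV_cm=0.8, t_p_s=1e-3, N=8, polarity="OBP")
    return {
        "HV1": PulseProtocol((hv1,), name="HV1"),
        "HV2": PulseProtocol((hv2,), name="HV2"),
        "LV1": PulseProtocol((lv1,), name="LV1"),
        "LV2": PulseProtocol((lv2,), name="LV2"),
        "HV1+LV1": PulseProtocol((hv1, lv1), name="HV1+LV1"),
        "HV2+LV2": PulseProtocol((hv2, lv2), name="HV2+LV2"),
        "SP": PulseProtocol((sp,), name="SP"),
        "OBP": PulseProtocol((obp,), name="OBP"),
    }


def table2_protocols(U_V: float = 160.0) -> dict[str, PulseProtocol]:
    """The four 8-pulse schedules (200 µs, 1 ms, 5 ms, 10 ms) at 0.8 kV/cm.

    ``U_V`` defaults to 160 V, the voltage consistent with the published
    energy factors for these schedules.
    """
    out = {}
    for label, t_p in (
        ("8x200us", 200e-6),
        ("8x1ms", 1e-3),
        ("8x5ms", 5e-3),
        ("8x10ms", 10e-3),
    ):
        seg = PulseSegment(E_kV_cm=0.8, t_p_s=t_p, N=8, U_V=U_V)
        out[label] = PulseProtocol((seg,), name=label)
    return out


def dosimetry_report(
    protocols,
    medium: GelMedium | None = None,
    inputs: DosimetryInputs | None = None,
    include_energy_factor: bool = True,
) -> pd.DataFrame:
    """Tabulate per-segment displacement and dosimetry for a set of protocols.

    ``protocols`` maps name -> :class:`PulseProtocol`.  Mobility is looked up
    in ``medium`` at each segment's own pulse duration.  Electrical dosimetry
    columns are filled only when ``inputs`` is given.
    """
    medium = medium or GelMedium()
    rows = []
    for name, protocol in protocols.items():
        for i, seg in enumerate(protocol.segments):
            mu = _mobility_lookup(medium, pulse_duration_s=seg.t_p_s)
            le = electrophoretic_displacement(seg, mu)
            row = {
                "protocol": name,
                "segment": i,
                "role": seg.role,
                "polarity": seg.polarity,
                "N": seg.N,
                "t_p_s": seg.t_p_s,
                "E_kV_per_cm": seg.E_kV_cm,
                "mu_m2_per_Vs": mu,
                "L_E_um": le if seg.polarity == "SP" else 0.0,
                "U2tE_V2s": (
                    pulse_energy_factor(seg)
                    if include_energy_factor and seg.U_V is not None
                    else np.nan
                ),
                "Q_J": np.nan,
                "dT_K": np.nan,
                "q_C": np.nan,
            }
            if inputs is not None:
                if inputs.resistance_ohm is not None and inputs.sample_mass_kg is not None:
                    row["Q_J"], row["dT_K"] = joule_heating(inputs, seg)
                row["q_C"] = coulomb_dosage(inputs, seg)
            rows.append(row)
    return pd.DataFrame(rows)
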