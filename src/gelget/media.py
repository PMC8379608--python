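"""Transport properties of collagen gels and of the plasmid that moves through them.

A plasmid in a fibrous hydrogel diffuses and electrophoreses much more slowly
than in free solution, and both coefficients fall roughly exponentially with
gel density.  This module anchors the diffusivity ``D`` and electrophoretic
mobility ``mu`` of plasmid DNA on published gel measurements and interpolates
between the anchors linearly in ``(gel fraction, log10 value)`` space.  It also
provides the molecular-scale quantities that control hindered transport: the
plasmid's effective charge, its free-solution Stokes mobility, the mean gel
pore radius from the sieving relation ``R_p = 118 * A**-0.74`` (nm, with A the
gel concentration in % w/w), and the Ogston-vs-reptation regime classification
based on the ratio of the radius of gyration to the pore radius.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from math import pi

import numpy as np

from ._constants import ELEMENTARY_CHARGE_C

__all__ = [
    "GelMedium",
    "PlasmidSpec",
    "ExtrapolationWarning",
    "ConfigurationError",
    "diffusion_coefficient",
    "electrophoretic_mobility",
    "effective_charge",
    "effective_charge_coulombs",
    "stokes_mobility",
    "pore_radius",
    "transport_regime",
    "medium_from_csv",
]


class ExtrapolationWarning(UserWarning):
    """Raised when a property is evaluated outside the anchored range."""


class ConfigurationError(ValueError):
    """A model object is missing data it needs (e.g. no anchors, no voltage)."""


# Diffusivity anchors (gel fraction % w/w, D in cm²/s): free solution,
# the 0.35 % w/w collagen gel used as the reference tissue model, and a
# dense 3 % gel.  The same values ship as data/diffusivity_anchors.csv.
DEFAULT_DIFFUSIVITY_ANCHORS = (
    (0.0, 5.0e-8),
    (0.35, 3.0e-8),
    (3.0, 0.01e-8),
)

# Mobility anchors (gel fraction % w/w, pulse duration s, mu in m²/Vs).
# The dense-gel mobility is duration-independent at 0.03e-8 m²/Vs.
DEFAULT_MOBILITY_ANCHORS = (
    (0.35, 200e-6, 0.2e-8),
    (0.35, 1e-3, 1.0e-8),
    (0.35, 5e-3, 2.4e-8),
    (0.35, 10e-3, 2.8e-8),
    (3.0, 200e-6, 0.03e-8),
    (3.0, 1e-3, 0.03e-8),
    (3.0, 5e-3, 0.03e-8),
    (3.0, 10e-3, 0.03e-8),
)

# pulse-duration window over which the mobility anchors are trusted
_DURATION_WINDOW_S = (100e-6, 100e-3)

_PORE_PREFACTOR_NM = 118.0
_PORE_EXPONENT = -0.74


@dataclass(frozen=True)
class GelMedium:
    """A collagen (or agarose-like) gel with anchored transport properties.

    Parameters
    ----------
    collagen_fraction : float
        Gel density in % w/w. 0.35 corresponds to a soft tissue-mimicking gel.
    diffusivity_anchors : tuple of (fraction, D_cm2_per_s)
    mobility_anchors : tuple of (fraction, pulse_duration_s, mu_m2_per_Vs)
    viscosity_pa_s : float
        Free-solution reference viscosity used by :func:`stokes_mobility`.
    """

    collagen_fraction: float = 0.35
    diffusivity_anchors: tuple = DEFAULT_DIFFUSIVITY_ANCHORS
    mobility_anchors: tuple = DEFAULT_MOBILITY_ANCHORS
    viscosity_pa_s: float = 1.0e-3

    def __post_init__(self):
        if self.collagen_fraction < 0:
            raise ValueError("collagen_fraction must be >= 0")
        if self.viscosity_pa_s <= 0:
            raise ValueError("viscosity must be > 0")
        fr = [a[0] for a in self.diffusivity_anchors]
        if any(d <= 0 for _, d in self.diffusivity_anchors):
            raise ValueError("diffusivity anchors must be strictly positive")
        if sorted(set(fr)) != list(fr):
            raise ValueError("diffusivity anchor fractions must be strictly increasing")
        by_frac: dict = {}
        for f, t, m in self.mobility_anchors:
            if m <= 0 or t <= 0:
                raise ValueError("mobility anchors must have positive duration and value")
            by_frac.setdefault(f, []).append(t)
        for f, ts in by_frac.items():
            if sorted(set(ts)) != ts:
                raise ValueError(
                    f"mobility anchor durations at fraction {f} must be strictly increasing"
                )


@dataclass(frozen=True)
class PlasmidSpec:
    """Size and charge of the delivered plasmid.

    Defaults describe a 4.7 kbp GFP-encoding plasmid with an effective
    (counterion-screened) charge of 0.066 elementary charges per base pair
    and a radius of gyration of about 100 nm.
    """

    length_bp: int = 4700
    charge_per_bp: float = 0.066
    gyration_radius_nm: float = 100.0

    def __post_init__(self):
        if self.length_bp <= 0:
            raise ValueError("length_bp must be > 0")
        if self.charge_per_bp <= 0:
            raise ValueError("charge_per_bp must be > 0")
        if self.gyration_radius_nm <= 0:
            raise ValueError("gyration_radius_nm must be > 0")


def _interp_with_extension(x: float, xs, ys) -> float:
    """Piecewise-linear interpolation; beyond the ends the nearest segment
    is continued (linear extrapolation)."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size == 1:
        return float(ys[0])
    if x <= xs[0]:
        i = 0
    elif x >= xs[-1]:
        i = xs.size - 2
    else:
        return float(np.interp(x, xs, ys))
    t = (x - xs[i]) / (xs[i + 1] - xs[i])
    return float(ys[i] + t * (ys[i + 1] - ys[i]))


def diffusion_coefficient(medium: GelMedium, fraction: float | None = None) -> float:
    """Plasmid diffusivity (cm²/s) at a gel fraction (% w/w).

    Interpolates linearly in ``(fraction, log10 D)`` through the medium's
    anchors, reflecting the near-exponential decrease of diffusivity with gel
    density; anchor fractions are reproduced exactly.  Evaluation beyond the
    anchored range continues the nearest segment and emits an
    :class:`ExtrapolationWarning`.
    """
    f = medium.collagen_fraction if fraction is None else float(fraction)
    if f < 0:
        raise ValueError("gel fraction must be >= 0")
    anchors = sorted(medium.diffusivity_anchors)
    if len(anchors) < 2:
        raise ConfigurationError("at least two diffusivity anchors are required")
    for af, ad in anchors:
        if f == af:
            return ad
    fr = [a[0] for a in anchors]
    dv = [a[1] for a in anchors]
    if f < fr[0] or f > fr[-1]:
        warnings.warn(
            f"gel fraction {f} outside anchored range [{fr[0]}, {fr[-1]}]; extrapolating",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return 10.0 ** _interp_with_extension(f, fr, np.log10(dv))


def _mobility_at_duration(durations, mobilities, t_p: float) -> float:
    """Mobility at one gel fraction: log-log interpolation over pulse duration."""
    durations = list(durations)
    mobilities = list(mobilities)
    for t, m in zip(durations, mobilities):
        if t == t_p:
            return m
    if len(set(mobilities)) == 1:
        # duration-independent series (dense-gel plateau)
        return mobilities[0]
    return 10.0 ** _interp_with_extension(
        np.log10(t_p), np.log10(durations), np.log10(mobilities)
    )


def electrophoretic_mobility(
    medium: GelMedium, fraction: float | None = None, pulse_duration_s: float = 1e-3
) -> float:
    """Plasmid electrophoretic mobility (m²/Vs) at a gel fraction and pulse duration.

    Tabulated (fraction, duration) anchors are reproduced exactly.  Otherwise
    the mobility is interpolated log-linearly in pulse duration within each
    anchored gel fraction, then linearly in ``(fraction, log10 mu)`` across
    fractions.  Durations outside 100 µs – 100 ms are clamped to that window
    with an :class:`ExtrapolationWarning`.
    """
    f = medium.collagen_fraction if fraction is None else float(fraction)
    t_p = float(pulse_duration_s)
    if f < 0:
        raise ValueError("gel fraction must be >= 0")
    if t_p <= 0:
        raise ValueError("pulse duration must be > 0")
    lo, hi = _DURATION_WINDOW_S
    if not (lo <= t_p <= hi):
        warnings.warn(
            f"pulse duration {t_p} s outside [{lo}, {hi}] s; clamped",
            ExtrapolationWarning,
            stacklevel=2,
        )
        t_p = min(max(t_p, lo), hi)

    groups: dict = {}
    for gf, t, m in medium.mobility_anchors:
        groups.setdefault(gf, []).append((t, m))
    if not groups:
        raise ConfigurationError("no mobility anchors configured")

    per_fraction = []
    for gf in sorted(groups):
        ts, ms = zip(*sorted(groups[gf]))
        per_fraction.append((gf, _mobility_at_duration(ts, ms, t_p)))

    for gf, mu in per_fraction:
        if f == gf:
            return mu

    fracs = [p[0] for p in per_fraction]
    vals = [p[1] for p in per_fraction]
    if f < fracs[0] or f > fracs[-1]:
        warnings.warn(
            f"gel fraction {f} outside anchored range [{fracs[0]}, {fracs[-1]}]; extrapolating",
            ExtrapolationWarning,
            stacklevel=2,
        )
    if len(fracs) == 1:
        return vals[0]
    return 10.0 ** _interp_with_extension(f, fracs, np.log10(vals))


def effective_charge(plasmid: PlasmidSpec) -> float:
    """Effective (screened) charge of the plasmid, in elementary charges."""
    return plasmid.charge_per_bp * plasmid.length_bp


def effective_charge_coulombs(plasmid: PlasmidSpec) -> float:
    return effective_charge(plasmid) * ELEMENTARY_CHARGE_C


def stokes_mobility(plasmid: PlasmidSpec, viscosity_pa_s: float = 1.0e-3) -> float:
    """Free-solution mobility (m²/Vs) from the Stokes drag on a coil of radius R_g.

    mu = e_eff / (6 pi eta R_g), with e_eff in coulombs.  Valid for a
    globular supercoiled plasmid in unconfined solution; in a gel the drag is
    dominated by the matrix and the anchored mobilities should be used instead.
    """
    if viscosity_pa_s <= 0:
        raise ValueError("viscosity must be > 0")
    r_m = plasmid.gyration_radius_nm * 1e-9
    return effective_charge_coulombs(plasmid) / (6.0 * pi * viscosity_pa_s * r_m)


def pore_radius(fraction: float) -> float:
    """Mean gel pore radius (nm) from the sieving relation 118 * A**-0.74.

    ``fraction`` is the gel concentration A in % w/w and must be positive.
    """
    if fraction <= 0:
        raise ValueError("gel fraction must be > 0 for the pore-size relation")
    return _PORE_PREFACTOR_NM * fraction**_PORE_EXPONENT


def transport_regime(plasmid: PlasmidSpec, fraction: float) -> str:
    """Classify transport as Ogston sieving or reptation.

    A coil with radius of gyration larger than half the mean pore radius is
    significantly hindered and crawls through the network (reptation);
    otherwise it sieves through the voids (Ogston).  The tie R_g == R_p/2 is
    classified as "ogston" (the hindrance criterion is a strict inequality).
    """
    r_p = pore_radius(fraction)
    return "reptation" if plasmid.gyration_radius_nm > r_p / 2.0 else "ogston"


def medium_from_csv(
    diffusivity_csv=None,
    mobility_csv=None,
    collagen_fraction: float = 0.35,
    viscosity_pa_s: float = 1.0e-3,
) -> GelMedium:
    """Build a :class:`GelMedium` from anchor tables on disk.

    With no paths given, the package's shipped anchor tables are used
    (``data/diffusivity_anchors.csv``: gel_fraction_pct, D_cm2_per_s;
    ``data/mobility_anchors.csv``: gel_fraction_pct, pulse_duration_s,
    mobility_m2_per_Vs).
    """
    import pandas as pd

    data_dir = resources.files("gelget") / "data"
    if diffusivity_csv is None:
        diffusivity_csv = str(data_dir / "diffusivity_anchors.csv")
    if mobility_csv is None:
        mobility_csv = str(data_dir / "mobility_anchors.csv")
    ddf = pd.read_csv(diffusivity_csv)
    mdf = pd.read_csv(mobility_csv)
    d_anchors = tuple(
        (float(r.gel_fraction_pct), float(r.D_cm2_per_s)) for r in ddf.itertuples()
    )
    m_anchors = tuple(
        (float(r.gel_fraction_pct), float(r.pulse_duration_s), float(r.mobility_m2_per_Vs))
        for r in mdf.itertuples()
    )
    return GelMedium(
        collagen_fraction=collagen_fraction,
        diffusivity_anchors=d_anchors,
        mobility_anchors=m_anchors,
        viscosity_pa_s=viscosity_pa_s,
    )
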