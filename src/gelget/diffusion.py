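"""Field-free plasmid transport in the gel: concentration profiles over depth.

Before any pulse is applied, plasmid motion in the gel is pure diffusion.
Three routes to the depth-resolved concentration c(z, t) are provided:

* :func:`halfspace_profile` — the analytic solution for a constant surface
  reservoir, ``c(z, t) = c0 * erfc(z / (2 sqrt(D t)))``, appropriate when the
  plasmid solution sits on top of the gel and the diffusion front stays well
  away from the gel bottom;
* :func:`convolve_profile` — evolution of an arbitrary initial profile by
  convolution with the Gaussian heat kernel (free space, or with reflecting
  boundaries via the method of images);
* :func:`fd_diffusion_solve` — a Crank–Nicolson finite-difference solver on
  the bounded gel domain [0, d], which serves as the numerical oracle for the
  analytic forms and handles the no-flux gel bottom exactly.

The depth coordinate z is in µm, z = 0 at the gel top, increasing downward;
concentrations are in µg/ml.  The default grid spacing of 2 µm resolves the
diffusion front for incubation times of a minute and longer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded
from scipy.ndimage import gaussian_filter1d
from scipy.special import erfc

from ._constants import CM2_TO_UM2, MM_TO_UM, UM_TO_CM

__all__ = [
    "GelGeometry",
    "ConcentrationProfile",
    "TruncationWarning",
    "standard_grid",
    "halfspace_profile",
    "convolve_profile",
    "fd_diffusion_solve",
    "penetration_depth",
    "injection_profile",
    "profile_to_csv",
    "profile_from_csv",
]

DEFAULT_DZ_UM = 2.0


class TruncationWarning(UserWarning):
    """The computational grid clipped a non-negligible amount of mass."""


@dataclass(frozen=True)
class GelGeometry:
    """Gel slab geometry: thickness (mm) and well cross-section (cm²).

    Defaults correspond to a 0.95 mm gel in a 24-well plate
    (180 µl of gel over ~1.9 cm²).
    """

    thickness_mm: float = 0.95
    surface_area_cm2: float = 1.9

    def __post_init__(self):
        if self.thickness_mm <= 0:
            raise ValueError("thickness must be > 0")
        if self.surface_area_cm2 <= 0:
            raise ValueError("surface area must be > 0")

    @property
    def thickness_um(self) -> float:
        return self.thickness_mm * MM_TO_UM


@dataclass
class ConcentrationProfile:
    """Depth-resolved plasmid concentration at one time point.

    ``z_um`` is strictly increasing (µm, 0 at the gel top); ``c_ug_ml`` holds
    the matching concentrations (µg/ml, non-negative); ``time_s`` is the time
    since plasmid application.
    """

    z_um: np.ndarray
    c_ug_ml: np.ndarray
    time_s: float = 0.0

    def __post_init__(self):
        self.z_um = np.asarray(self.z_um, dtype=float)
        self.c_ug_ml = np.asarray(self.c_ug_ml, dtype=float)
        if self.z_um.ndim != 1 or self.z_um.size < 2:
            raise ValueError("depth grid must be 1-D with at least two nodes")
        if self.z_um.shape != self.c_ug_ml.shape:
            raise ValueError("depth grid and values must have the same shape")
        if not np.all(np.diff(self.z_um) > 0):
            raise ValueError("depth grid must be strictly increasing")
        if not np.all(np.isfinite(self.c_ug_ml)):
            raise ValueError("concentrations must be finite")
        # round solver noise up to zero; anything genuinely negative is a bug
        tiny = 1e-9 * max(1.0, float(np.max(np.abs(self.c_ug_ml))))
        if np.any(self.c_ug_ml < -tiny):
            raise ValueError("concentrations must be non-negative")
        np.clip(self.c_ug_ml, 0.0, None, out=self.c_ug_ml)

    @property
    def dz_um(self) -> float:
        """Grid spacing; raises if the grid is not uniform."""
        d = np.diff(self.z_um)
        if not np.allclose(d, d[0], rtol=1e-9, atol=1e-12):
            raise ValueError("operation requires a uniform depth grid")
        return float(d[0])

    def column_mass_ug(self, geometry: GelGeometry, rule: str = "trapezoid") -> float:
        """Total plasmid mass in the column S * integral(c dz), in µg."""
        if rule == "trapezoid":
            integral = np.trapezoid(self.c_ug_ml, self.z_um)
        elif rule == "sum":
            integral = float(np.sum(self.c_ug_ml)) * self.dz_um
        else:
            raise ValueError("rule must be 'trapezoid' or 'sum'")
        # c [µg/cm³] * dz [µm -> cm] * S [cm²]
        return integral * UM_TO_CM * geometry.surface_area_cm2

    def copy(self) -> "ConcentrationProfile":
        return ConcentrationProfile(self.z_um.copy(), self.c_ug_ml.copy(), self.time_s)


def standard_grid(geometry: GelGeometry | None = None, dz_um: float = DEFAULT_DZ_UM) -> np.ndarray:
    """Uniform depth grid spanning [0, d] with spacing dz (endpoint included)."""
    geometry = geometry or GelGeometry()
    d = geometry.thickness_um
    n = int(round(d / dz_um)) + 1
    return np.linspace(0.0, d, n)


def halfspace_profile(
    c0_ug_ml: float,
    D_cm2_s: float,
    t_s: float,
    z_um: np.ndarray | None = None,
    geometry: GelGeometry | None = None,
) -> ConcentrationProfile:
    """Diffusion from a constant surface reservoir into a half space.

    c(z, t) = c0 * erfc(z / (2 sqrt(D t))).  At t = 0 the profile is c0 at
    z = 0 and zero below.  Valid on the bounded gel while the penetration
    depth stays well short of the gel thickness.
    """
    if c0_ug_ml < 0:
        raise ValueError("c0 must be >= 0")
    if D_cm2_s <= 0:
        raise ValueError("D must be > 0")
    if t_s < 0:
        raise ValueError("time must be >= 0")
    z = standard_grid(geometry) if z_um is None else np.asarray(z_um, dtype=float)
    if t_s == 0:
        c = np.where(z == 0.0, float(c0_ug_ml), 0.0)
    else:
        s = 2.0 * np.sqrt(D_cm2_s * CM2_TO_UM2 * t_s)  # µm
        c = c0_ug_ml * erfc(z / s)
    return ConcentrationProfile(z, c, time_s=t_s)


def convolve_profile(
    initial: ConcentrationProfile,
    D_cm2_s: float,
    t_s: float,
    boundary: str = "open",
) -> ConcentrationProfile:
    """Evolve a profile by convolution with the Gaussian diffusion kernel.

    ``boundary='open'`` treats the grid as part of an infinite line with zero
    concentration beyond its ends (a warning reports any kernel mass clipped
    at the edges); ``boundary='reflect'`` imposes no-flux walls at both grid
    edges via the method of images, conserving mass exactly — appropriate for
    a profile inside the closed gel slab.
    """
    if t_s < 0:
        raise ValueError("time must be >= 0")
    if D_cm2_s < 0:
        raise ValueError("D must be >= 0")
    if boundary not in ("open", "reflect"):
        raise ValueError("boundary must be 'open' or 'reflect'")
    out = initial.copy()
    out.time_s = initial.time_s + t_s
    if t_s == 0 or D_cm2_s == 0:
        return out
    dz = initial.dz_um
    sigma_um = np.sqrt(2.0 * D_cm2_s * CM2_TO_UM2 * t_s)
    mode = "constant" if boundary == "open" else "reflect"
    # truncate=8 keeps the clipped kernel tail below ~1e-15 of its mass
    out.c_ug_ml = gaussian_filter1d(
        initial.c_ug_ml, sigma_um / dz, mode=mode, truncate=8.0
    )
    np.clip(out.c_ug_ml, 0.0, None, out=out.c_ug_ml)
    if boundary == "open":
        m0 = float(np.sum(initial.c_ug_ml))
        m1 = float(np.sum(out.c_ug_ml))
        if m0 > 0 and (m0 - m1) / m0 > 1e-6:
            warnings.warn(
                f"grid clipped {(m0 - m1) / m0:.3e} of the profile mass at its "
                "edges; widen the grid or use boundary='reflect'",
                TruncationWarning,
                stacklevel=2,
            )
    return out


def _cn_evolve(
    c: np.ndarray,
    D_um2_s: float,
    dz_um: float,
    duration_s: float,
    dt_s: float,
    top: str,
    c0: float | None,
) -> np.ndarray:
    """Crank–Nicolson steps on a uniform grid; bottom is always no-flux.

    ``top`` is 'dirichlet' (held at c0) or 'noflux'.  Unconditionally stable,
    so dt controls accuracy only.
    """
    if duration_s <= 0:
        return c
    n = c.size
    nsteps = max(1, int(np.ceil(duration_s / dt_s)))
    dt = duration_s / nsteps
    lam = 0.5 * D_um2_s * dt / dz_um**2

    # banded LHS (I - lam * L)
    ab = np.zeros((3, n))
    ab[0, 1:] = -lam          # upper diagonal
    ab[1, :] = 1.0 + 2.0 * lam
    ab[2, :-1] = -lam         # lower diagonal
    # no-flux bottom: mirror ghost doubles the inner coupling
    ab[2, n - 2] = -2.0 * lam
    if top == "dirichlet":
        ab[1, 0] = 1.0
        ab[0, 1] = 0.0
        if c0 is None:
            raise ValueError("dirichlet top boundary requires c0")
        c = c.copy()
        c[0] = c0
    elif top == "noflux":
        ab[0, 1] = -2.0 * lam
    else:
        raise ValueError("top boundary must be 'dirichlet' or 'noflux'")

    for _ in range(nsteps):
        r = np.empty_like(c)
        r[1:-1] = c[1:-1] + lam * (c[2:] - 2.0 * c[1:-1] + c[:-2])
        r[-1] = c[-1] + 2.0 * lam * (c[-2] - c[-1])
        if top == "dirichlet":
            r[0] = c0
        else:
            r[0] = c[0] + 2.0 * lam * (c[1] - c[0])
        c = solve_banded((1, 1), ab, r)
    return c


def fd_diffusion_solve(
    initial: ConcentrationProfile,
    D_cm2_s: float,
    duration_s: float,
    geometry: GelGeometry | None = None,
    top_boundary: str = "dirichlet",
    c0_ug_ml: float | None = None,
    dt_s: float = 1.0,
) -> ConcentrationProfile:
    """Diffuse an initial profile on the bounded gel domain.

    Crank–Nicolson in time on the profile's (uniform) grid; the bottom
    boundary is always no-flux, the top is either a fixed-concentration
    reservoir (``'dirichlet'``, held at ``c0_ug_ml``, defaulting to the
    initial surface value) or ``'noflux'``.
    """
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    if dt_s <= 0:
        raise ValueError("dt must be > 0")
    if D_cm2_s <= 0:
        raise ValueError("D must be > 0")
    dz = initial.dz_um
    if geometry is not None and not np.isclose(initial.z_um[-1], geometry.thickness_um):
        raise ValueError("profile grid does not span the gel thickness")
    if top_boundary == "dirichlet" and c0_ug_ml is None:
        c0_ug_ml = float(initial.c_ug_ml[0])
    c = _cn_evolve(
        initial.c_ug_ml.copy(),
        D_cm2_s * CM2_TO_UM2,
        dz,
        duration_s,
        dt_s,
        top_boundary,
        c0_ug_ml,
    )
    return ConcentrationProfile(initial.z_um.copy(), c, initial.time_s + duration_s)


def penetration_depth(D_cm2_s: float, t_s: float) -> float:
    """Characteristic diffusion penetration depth 2 sqrt(D t), in µm."""
    if D_cm2_s <= 0:
        raise ValueError("D must be > 0")
    if t_s < 0:
        raise ValueError("time must be >= 0")
    return 2.0 * np.sqrt(D_cm2_s * CM2_TO_UM2 * t_s)


def injection_profile(
    dose_ug: float,
    depth_um: float | None = None,
    spread_um: float = 250.0,
    geometry: GelGeometry | None = None,
    dz_um: float = DEFAULT_DZ_UM,
) -> ConcentrationProfile:
    """1-D idealization of a bolus injected into the gel.

    A Gaussian depth distribution centred at ``depth_um`` (default: mid-gel)
    with standard deviation ``spread_um``; mass falling beyond either gel face
    is reflected back (method of images), and the profile is normalized so the
    column holds exactly ``dose_ug`` over the well cross-section.
    """
    geometry = geometry or GelGeometry()
    if dose_ug < 0:
        raise ValueError("dose must be >= 0")
    if spread_um <= 0:
        raise ValueError("spread must be > 0")
    d = geometry.thickness_um
    depth = d / 2.0 if depth_um is None else float(depth_um)
    if not (0.0 <= depth <= d):
        raise ValueError("injection depth must lie inside the gel")
    z = standard_grid(geometry, dz_um)
    # enough image sources that the clipped Gaussian tail is negligible
    kmax = max(4, int(np.ceil((8.0 * spread_um + d) / (2.0 * d))))
    c = np.zeros_like(z)
    for k in range(-kmax, kmax + 1):
        for centre in (2.0 * k * d + depth, 2.0 * k * d - depth):
            c += np.exp(-0.5 * ((z - centre) / spread_um) ** 2)
    if dose_ug == 0:
        return ConcentrationProfile(z, np.zeros_like(z), 0.0)
    mass = np.trapezoid(c, z) * UM_TO_CM * geometry.surface_area_cm2
    c *= dose_ug / mass
    return ConcentrationProfile(z, c, 0.0)


def profile_to_csv(profile: ConcentrationProfile, path) -> None:
    """Write a profile as two-column CSV (z_um, c_ug_per_ml) with a time header."""
    with open(path, "w") as fh:
        fh.write(f"# time_s = {profile.time_s!r}\n")
        fh.write("z_um,c_ug_per_ml\n")
        for z, c in zip(profile.z_um, profile.c_ug_ml):
            fh.write(f"{float(z)!r},{float(c)!r}\n")


def profile_from_csv(path) -> ConcentrationProfile:
    time_s = 0.0
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                if "time_s" in line:
                    time_s = float(line.split("=", 1)[1])
                continue
            if not line or line.startswith("z_um"):
                continue
            z, c = line.split(",")
            rows.append((float(z), float(c)))
    z, c = map(np.array, zip(*rows))
    return ConcentrationProfile(z, c, time_s)
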