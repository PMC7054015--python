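"""Nuclear geometry: confinement spheres, landmark restraint regions and shells.

The interphase budding-yeast nucleus is modelled as a rigid sphere of radius
``R_nuc`` = 1000 nm.  Two landmark regions are carved out of it:

* the spindle-pole-body (SPB) region, a 150-nm sphere internally tangent to
  the nuclear envelope (NE) at (-1000, 0, 0), inside which centromeres are
  confined, and
* the nucleolus, the lens-shaped intersection of the nucleus with a sphere
  centred on the NE point opposite the SPB, sized so the lens holds 10% of
  the nuclear volume.  rDNA beads are kept inside the lens, all other beads
  outside it.

For positional statistics the nucleus is divided into three concentric
shells of equal volume; the outermost ("peripheral") shell is the 126-nm
layer under the NE.  All restraints act through the same quadratic "indent"
force law, F = K (r - R)^2 applied only when a bead violates its condition.

Lengths are nanometres throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "lens_volume",
    "solve_nucleolus_radius",
    "equal_volume_shell_radii",
    "classify_shell",
    "RestraintSphere",
    "indent_force",
    "NuclearGeometry",
]

#: Default nuclear radius, nm (2-um-diameter G1 nucleus).
R_NUC_DEFAULT = 1000.0
#: Default indent restraint stiffness, reduced force units per nm^2.
INDENT_K_DEFAULT = 10.0


def lens_volume(r: float, R: float, d: float) -> float:
    """Volume of the intersection of two spheres (a spherical lens).

    Parameters
    ----------
    r, R
        Radii of the two spheres, nm.
    d
        Distance between their centres, nm.

    Returns
    -------
    float
        Intersection volume in nm^3: zero for disjoint spheres, the volume
        of the smaller sphere when one contains the other, and the
        closed-form lens volume otherwise.
    """
    if r < 0 or R < 0:
        raise ValueError("sphere radii must be non-negative")
    if d < 0:
        raise ValueError("centre distance must be non-negative")
    if d >= r + R:
        return 0.0
    if d <= abs(R - r):
        rmin = min(r, R)
        return 4.0 / 3.0 * math.pi * rmin**3
    # standard two-sphere intersection formula
    return (
        math.pi
        * (R + r - d) ** 2
        * (d**2 + 2 * d * r - 3 * r**2 + 2 * d * R + 6 * r * R - 3 * R**2)
        / (12 * d)
    )


def solve_nucleolus_radius(
    volume_fraction: float, R_nuc: float = R_NUC_DEFAULT, tol: float = 0.001
) -> float:
    """Radius of an NE-centred sphere whose lens with the nucleus holds
    ``volume_fraction`` of the nuclear volume.

    The nucleolar sphere is centred on the nuclear envelope (centre distance
    ``d = R_nuc``), so its intersection with the nucleus is a lens hugging
    the envelope.  The radius is found by bracketed root finding on
    :func:`lens_volume` to better than ``tol`` nm.

    For the default 10% fraction and a 1000-nm nucleus this gives 640.92 nm.
    """
    if not 0.0 < volume_fraction < 1.0:
        raise ValueError("volume fraction must lie strictly between 0 and 1")
    if R_nuc <= 0:
        raise ValueError("nuclear radius must be positive")
    target = volume_fraction * 4.0 / 3.0 * math.pi * R_nuc**3

    def f(r: float) -> float:
        return lens_volume(r, R_nuc, R_nuc) - target

    lo, hi = 1e-9 * R_nuc, 2.0 * R_nuc
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError("no root bracketed in (0, 2 R_nuc)")
    return brentq(f, lo, hi, xtol=min(tol, 0.005))


def equal_volume_shell_radii(R_nuc: float = R_NUC_DEFAULT) -> tuple[float, float, float]:
    """Radii bounding three concentric equal-volume shells.

    Returns ``(r1, r2, thickness)`` where the central sphere ``|x| <= r1``,
    the middle shell ``r1 < |x| <= r2`` and the peripheral shell
    ``r2 < |x| <= R_nuc`` each hold one-third of the nuclear volume, and
    ``thickness = R_nuc - r2`` is the depth of the peripheral layer
    (126 nm for a 1000-nm nucleus).
    """
    if R_nuc <= 0:
        raise ValueError("nuclear radius must be positive")
    r1 = (1.0 / 3.0) ** (1.0 / 3.0) * R_nuc
    r2 = (2.0 / 3.0) ** (1.0 / 3.0) * R_nuc
    return r1, r2, R_nuc - r2


def classify_shell(
    points: np.ndarray, R_nuc: float = R_NUC_DEFAULT
) -> np.ndarray:
    """Classify points into equal-volume shells by radial distance.

    Parameters
    ----------
    points
        Array of shape (..., 3), nm, in nucleus-centred coordinates.

    Returns
    -------
    numpy.ndarray
        Integer codes of shape ``points.shape[:-1]``: 0 central, 1 middle,
        2 peripheral, 3 outside the nucleus.  Points exactly on a boundary
        are assigned to the inner region.
    """
    pts = np.asarray(points, dtype=float)
    r = np.linalg.norm(pts, axis=-1)
    r1, r2, _ = equal_volume_shell_radii(R_nuc)
    out = np.full(r.shape, 3, dtype=np.int8)
    out[r <= R_nuc] = 2
    out[r <= r2] = 1
    out[r <= r1] = 0
    return out


SHELL_NAMES = ("central", "middle", "peripheral", "outside")


@dataclass(frozen=True)
class RestraintSphere:
    """A spherical confinement region with a one-sided quadratic restoring force.

    ``mode`` is ``"keep_inside"`` (beads are pushed back in once their centre
    leaves the sphere) or ``"keep_outside"`` (beads inside are expelled).
    """

    center: tuple[float, float, float]
    radius: float
    mode: Literal["keep_inside", "keep_outside"]
    stiffness: float = INDENT_K_DEFAULT

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("restraint radius must be positive")
        if self.mode not in ("keep_inside", "keep_outside"):
            raise ValueError(f"unknown mode {self.mode!r}")


# unit vector used when a keep_outside bead sits exactly at the centre and
# the restoring direction is undefined
_DEGENERATE_DIR = np.array([1.0, 0.0, 0.0])


def indent_force(points: np.ndarray, sphere: RestraintSphere) -> np.ndarray:
    """One-sided quadratic restraint force, F = K (r - R)^2 toward compliance.

    Zero wherever the confinement condition already holds.  A violating bead
    is pushed radially (relative to the sphere centre) back toward the
    surface; the magnitude grows quadratically with the overshoot.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    dx = pts - np.asarray(sphere.center, dtype=float)
    r = np.linalg.norm(dx, axis=-1)
    force = np.zeros_like(pts)
    if sphere.mode == "keep_inside":
        viol = r > sphere.radius
        if np.any(viol):
            mag = sphere.stiffness * (r[viol] - sphere.radius) ** 2
            force[viol] = -(dx[viol] / r[viol, None]) * mag[:, None]
    else:
        viol = r < sphere.radius
        if np.any(viol):
            mag = sphere.stiffness * (sphere.radius - r[viol]) ** 2
            unit = np.where(
                r[viol, None] > 0, dx[viol] / np.where(r[viol, None] > 0, r[viol, None], 1.0),
                _DEGENERATE_DIR,
            )
            force[viol] = unit * mag[:, None]
    return force.reshape(np.shape(points))


@dataclass
class NuclearGeometry:
    """All nuclear landmark geometry, with derived radii solved at build time.

    Attributes
    ----------
    R_nuc : float
        Nuclear radius, nm.
    c_spb, R_spb : tuple, float
        Centre and radius of the SPB confinement sphere; the sphere is
        internally tangent to the NE on the -x axis.
    c_nucl, R_nucl : tuple, float
        Centre (on the NE, opposite the SPB) and solved radius of the
        nucleolar sphere.
    nucleolar_volume_fraction : float
        Fraction of nuclear volume occupied by the nucleolar lens.
    shell_r1, shell_r2, R_per : float
        Equal-volume shell boundaries and peripheral-shell thickness.
    """

    R_nuc: float = R_NUC_DEFAULT
    R_spb: float = 150.0
    nucleolar_volume_fraction: float = 0.10
    indent_stiffness: float = INDENT_K_DEFAULT

    c_spb: tuple[float, float, float] = field(init=False)
    c_nucl: tuple[float, float, float] = field(init=False)
    R_nucl: float = field(init=False)
    shell_r1: float = field(init=False)
    shell_r2: float = field(init=False)
    R_per: float = field(init=False)

    def __post_init__(self) -> None:
        if self.R_spb >= self.R_nuc:
            raise ValueError("SPB sphere must fit inside the nucleus")
        self.c_spb = (-(self.R_nuc - self.R_spb), 0.0, 0.0)
        self.c_nucl = (self.R_nuc, 0.0, 0.0)
        self.R_nucl = solve_nucleolus_radius(self.nucleolar_volume_fraction, self.R_nuc)
        self.shell_r1, self.shell_r2, self.R_per = equal_volume_shell_radii(self.R_nuc)

    # restraint spheres consumed by the simulator -------------------------
    def nucleus_restraint(self) -> RestraintSphere:
        return RestraintSphere((0.0, 0.0, 0.0), self.R_nuc, "keep_inside", self.indent_stiffness)

    def spb_restraint(self) -> RestraintSphere:
        return RestraintSphere(self.c_spb, self.R_spb, "keep_inside", self.indent_stiffness)

    def nucleolus_inside_restraint(self) -> RestraintSphere:
        """Restraint keeping rDNA beads inside the nucleolar sphere."""
        return RestraintSphere(self.c_nucl, self.R_nucl, "keep_inside", self.indent_stiffness)

    def nucleolus_outside_restraint(self) -> RestraintSphere:
        """Restraint keeping non-rDNA beads out of the nucleolar sphere."""
        return RestraintSphere(self.c_nucl, self.R_nucl, "keep_outside", self.indent_stiffness)

    def describe(self) -> dict:
        return {
            "R_nuc_nm": self.R_nuc,
            "c_spb_nm": list(self.c_spb),
            "R_spb_nm": self.R_spb,
            "c_nucl_nm": list(self.c_nucl),
            "R_nucl_nm": round(self.R_nucl, 2),
            "nucleolar_volume_fraction": self.nucleolar_volume_fraction,
            "shell_r1_nm": round(self.shell_r1, 2),
            "shell_r2_nm": round(self.shell_r2, 2),
            "R_per_nm": round(self.R_per, 2),
        }
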