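"""Spherocylinder cell geometry and contour-based size measurement.

Wild-type fission yeast is well approximated by a cylinder of radius R
capped with two hemispheres, so total membrane area is A_cor = 2*pi*R*L
(the hemispherical caps exactly make up for the cylinder ends) and the
area of the medial nodal band of axial width w_nod is A_nod = 2*pi*R*w_nod.
Cell sizes can also be measured directly from a traced mid-plane contour
by treating the cell as a solid of revolution about its long axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CellGeometry",
    "Contour",
    "InvalidGeometryError",
    "spherocylinder",
    "measure_contour",
    "spherocylinder_contour",
    "contour_from_perimeter",
    "read_contour_csv",
    "write_contour_csv",
    "population_frame",
]


class InvalidGeometryError(ValueError):
    """Raised when cell dimensions violate the spherocylinder constraints."""


@dataclass(frozen=True)
class CellGeometry:
    """Spherocylinder dimensions with derived areas and volume.

    Attributes
    ----------
    L : float
        Total cell length including the hemispherical caps (um).
    R : float
        Cell radius (um).
    w_nod : float
        Axial width of the medial nodal band (um); must fit on the
        cylindrical part of the cell.
    A_cor : float
        Total membrane (cortical) area, 2*pi*R*L (um^2).
    V : float
        Cell volume, pi*R^2*(L - 2R) + (4/3)*pi*R^3 (um^3).
    A_nod : float
        Membrane area of the nodal band, 2*pi*R*w_nod (um^2).
    """

    L: float
    R: float
    w_nod: float
    A_cor: float = field(init=False)
    V: float = field(init=False)
    A_nod: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.R > 0:
            raise InvalidGeometryError(f"radius must be positive, got R={self.R}")
        if self.L < 2 * self.R:
            raise InvalidGeometryError(
                f"length must cover both caps: need L >= 2R, got L={self.L}, R={self.R}"
            )
        if self.w_nod < 0:
            raise InvalidGeometryError(f"nodal band width must be >= 0, got {self.w_nod}")
        if self.w_nod > self.L - 2 * self.R + 1e-12:
            raise InvalidGeometryError(
                "nodal band must lie on the cylindrical part: "
                f"need w_nod <= L - 2R = {self.L - 2 * self.R:.4g}, got {self.w_nod}"
            )
        object.__setattr__(self, "A_cor", 2.0 * np.pi * self.R * self.L)
        object.__setattr__(
            self,
            "V",
            np.pi * self.R**2 * (self.L - 2 * self.R) + (4.0 / 3.0) * np.pi * self.R**3,
        )
        object.__setattr__(self, "A_nod", 2.0 * np.pi * self.R * self.w_nod)


def spherocylinder(L: float, R: float, w_nod: float = 0.0) -> CellGeometry:
    """Build a :class:`CellGeometry` for a cylinder-with-caps cell.

    Parameters are the total length ``L`` (um), radius ``R`` (um) and the
    axial nodal-band width ``w_nod`` (um, default 0). Raises
    :class:`InvalidGeometryError` when ``L < 2R``, ``R <= 0`` or the band
    does not fit on the cylindrical part.
    """
    return CellGeometry(L=float(L), R=float(R), w_nod=float(w_nod))


@dataclass(frozen=True)
class Contour:
    """Traced cell outline reduced to an axial radius profile.

    ``x`` are axial positions (um, strictly increasing) and ``r`` the local
    radius (half the traced width) at each position; ``r`` is zero at both
    tips. Radial symmetry about the long axis is assumed downstream.
    """

    x: np.ndarray
    r: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        r = np.asarray(self.r, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "r", r)
        if x.ndim != 1 or x.shape != r.shape:
            raise InvalidGeometryError("contour x and r must be 1-D arrays of equal length")
        if x.size < 4:
            raise InvalidGeometryError(f"contour needs >= 4 points, got {x.size}")
        if np.any(np.diff(x) <= 0):
            raise InvalidGeometryError("contour x must be strictly increasing")
        if np.any(r < 0):
            raise InvalidGeometryError("contour radii must be non-negative")
        if r[0] != 0 or r[-1] != 0:
            raise InvalidGeometryError("contour radius must be zero at both tips")


def measure_contour(c: Contour) -> tuple[float, float]:
    """Surface area and volume of the solid of revolution of a contour.

    Each segment contributes a frustum: lateral area ``2*pi*r_mid*slant``
    and volume ``pi*r_mid^2*dx`` with the midpoint radius ``r_mid``
    (second-order accurate against the closed-form spherocylinder).

    Returns
    -------
    (area, volume) : tuple of float
        Surface area (um^2) and volume (um^3).
    """
    dx = np.diff(c.x)
    dr = np.diff(c.r)
    r_mid = 0.5 * (c.r[1:] + c.r[:-1])
    area = float(np.sum(2.0 * np.pi * r_mid * np.hypot(dx, dr)))
    volume = float(np.sum(np.pi * r_mid**2 * dx))
    return area, volume


def spherocylinder_contour(L: float, R: float, step: float = 0.01) -> Contour:
    """Sample the ideal spherocylinder outline as a Contour at ``step`` um."""
    if L < 2 * R or R <= 0:
        raise InvalidGeometryError(f"need L >= 2R > 0, got L={L}, R={R}")
    x = np.arange(0.0, L + step / 2, step)
    x[-1] = min(x[-1], L)
    if x[-1] < L:
        x = np.append(x, L)
    r = np.empty_like(x)
    # hemispherical caps on [0, R] and [L-R, L], cylinder in between
    left = x < R
    right = x > L - R
    mid = ~(left | right)
    r[left] = np.sqrt(np.clip(R**2 - (R - x[left]) ** 2, 0.0, None))
    r[right] = np.sqrt(np.clip(R**2 - (x[right] - (L - R)) ** 2, 0.0, None))
    r[mid] = R
    r[0] = 0.0
    r[-1] = 0.0
    return Contour(x=x, r=r)


def contour_from_perimeter(px: np.ndarray, py: np.ndarray) -> Contour:
    """Convert a traced closed 2-D perimeter into an axial (x, r) contour.

    The closed trace is split at its two extreme-x points; the two halves
    are interpreted as upper and lower outlines and their absolute offsets
    from the cell axis (the mean y of the trace) are averaged onto the
    x-grid of the upper half. This is how a hand-traced mid-plane perimeter
    is reduced under the radial-symmetry assumption.
    """
    px = np.asarray(px, dtype=float)
    py = np.asarray(py, dtype=float)
    if px.size != py.size or px.size < 8:
        raise InvalidGeometryError("perimeter needs >= 8 matched points")
    i_min = int(np.argmin(px))
    i_max = int(np.argmax(px))
    axis_y = 0.5 * (py[i_min] + py[i_max])
    order = np.roll(np.arange(px.size), -i_min)
    px_o, py_o = px[order], py[order]
    j_max = int(np.argmax(px_o))
    half1 = slice(0, j_max + 1)
    half2 = slice(j_max, px_o.size)
    x1, r1 = px_o[half1], np.abs(py_o[half1] - axis_y)
    x2, r2 = px_o[half2][::-1], np.abs(py_o[half2][::-1] - axis_y)
    # average the lower half onto the upper half's x grid
    k1 = np.argsort(x1)
    k2 = np.argsort(x2)
    x_grid = x1[k1]
    r_avg = 0.5 * (r1[k1] + np.interp(x_grid, x2[k2], r2[k2]))
    # de-duplicate and pin tips to zero radius
    x_grid, idx = np.unique(x_grid, return_index=True)
    r_avg = r_avg[idx]
    r_avg[0] = 0.0
    r_avg[-1] = 0.0
    return Contour(x=x_grid - x_grid[0], r=r_avg)


def read_contour_csv(path) -> Contour:
    """Read a contour from CSV with columns ``x_um, r_um``."""
    df = pd.read_csv(path)
    return Contour(x=df["x_um"].to_numpy(), r=df["r_um"].to_numpy())


def write_contour_csv(c: Contour, path) -> None:
    pd.DataFrame({"x_um": c.x, "r_um": c.r}).to_csv(path, index=False)


def population_frame(cells) -> pd.DataFrame:
    """Tabulate an iterable of CellGeometry as the population CSV dialect."""
    rows = [
        {
            "cell_id": i,
            "length_um": g.L,
            "radius_um": g.R,
            "area_um2": g.A_cor,
            "volume_um3": g.V,
        }
        for i, g in enumerate(cells)
    ]
    return pd.DataFrame(rows)
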