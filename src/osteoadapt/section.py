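"""Cross-section geometry and beam-theory strain amplitudes.

The mid-diaphyseal section is a cortical annulus bounded by a periosteal
(outer) and an endocortical (inner) polygon, both in micrometres, in a
centroidal coordinate system with x pointing lateral and y anterior.  Loads
are an axial force amplitude ``Fz0`` (N) plus bending moment amplitudes
``Mx0`` (about the medial-lateral x axis) and ``My0`` (about the
anterior-posterior y axis), both in N mm.  Sign convention: positive Mx0
produces tension at y > 0 (anterior side).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon

__all__ = [
    "CrossSection",
    "SectionLoads",
    "section_properties",
    "strain_amplitude_at",
    "neutral_axis_angle",
]


@dataclass(frozen=True)
class SectionLoads:
    """Sectional load amplitudes scaling the unit waveform u(t)."""

    Fz0_n: float = 0.0
    Mx0_nmm: float = 0.0
    My0_nmm: float = 0.0

    def as_array(self):
        return np.array([self.Fz0_n, self.Mx0_nmm, self.My0_nmm], dtype=float)

    @classmethod
    def from_array(cls, arr):
        return cls(float(arr[0]), float(arr[1]), float(arr[2]))


@dataclass(frozen=True)
class CrossSection:
    """Annular cross-section with centroidal area properties (um, um^2, um^4)."""

    periosteal_um: np.ndarray
    endocortical_um: np.ndarray
    centroid_um: tuple
    area_um2: float
    Ix_um4: float
    Iy_um4: float
    Ixy_um4: float

    @property
    def bending_determinant_um8(self) -> float:
        return self.Ix_um4 * self.Iy_um4 - self.Ixy_um4**2


def _polygon_raw_properties(vertices):
    """Signed shoelace area, first and second moments about the origin."""
    v = np.asarray(vertices, dtype=float)
    x0, y0 = v[:, 0], v[:, 1]
    x1, y1 = np.roll(x0, -1), np.roll(y0, -1)
    cross = x0 * y1 - x1 * y0
    area = 0.5 * np.sum(cross)
    sx = np.sum((x0 + x1) * cross) / 6.0          # integral of x dA
    sy = np.sum((y0 + y1) * cross) / 6.0          # integral of y dA
    ixx = np.sum((y0**2 + y0 * y1 + y1**2) * cross) / 12.0   # integral of y^2 dA
    iyy = np.sum((x0**2 + x0 * x1 + x1**2) * cross) / 12.0   # integral of x^2 dA
    ixy = np.sum((x0 * y1 + 2 * x0 * y0 + 2 * x1 * y1 + x1 * y0) * cross) / 24.0
    return area, sx, sy, ixx, iyy, ixy


def _normalize_winding(vertices):
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
        raise ValueError("polygon needs >= 3 (x, y) vertices")
    area = _polygon_raw_properties(v)[0]
    if area < 0:
        v = v[::-1]
    return v


def section_properties(periosteal_polygon, endocortical_polygon) -> CrossSection:
    """Area, centroid and centroidal second moments of the cortical annulus.

    Both polygons are validated (simple, inner strictly inside outer); winding
    is normalized internally; the annulus is outer-minus-inner by Green's
    theorem and the moments are transferred to the combined centroid.
    """
    peri = _normalize_winding(periosteal_polygon)
    endo = _normalize_winding(endocortical_polygon)

    sp_peri = _ShapelyPolygon(peri)
    sp_endo = _ShapelyPolygon(endo)
    if not sp_peri.is_valid:
        raise ValueError("periosteal polygon is self-intersecting or degenerate")
    if not sp_endo.is_valid:
        raise ValueError("endocortical polygon is self-intersecting or degenerate")
    if not sp_peri.contains(sp_endo):
        raise ValueError("endocortical polygon must lie strictly inside the periosteal polygon")

    a_o, sx_o, sy_o, ixx_o, iyy_o, ixy_o = _polygon_raw_properties(peri)
    a_i, sx_i, sy_i, ixx_i, iyy_i, ixy_i = _polygon_raw_properties(endo)

    area = a_o - a_i
    if area <= 0:
        raise ValueError("annulus area must be positive")
    cx = (sx_o - sx_i) / area
    cy = (sy_o - sy_i) / area
    # parallel-axis transfer to the annulus centroid
    ix = (ixx_o - ixx_i) - area * cy**2
    iy = (iyy_o - iyy_i) - area * cx**2
    ixy = (ixy_o - ixy_i) - area * cx * cy

    if ix * iy - ixy**2 <= 0:
        raise ValueError("degenerate section: Ix*Iy - Ixy^2 must be positive")

    return CrossSection(
        periosteal_um=peri - [cx, cy],
        endocortical_um=endo - [cx, cy],
        centroid_um=(float(cx), float(cy)),
        area_um2=float(area),
        Ix_um4=float(ix),
        Iy_um4=float(iy),
        Ixy_um4=float(ixy),
    )


def strain_amplitude_at(loads: SectionLoads, section: CrossSection,
                        E_gpa: float, points_um):
    """Normal-strain amplitude (microstrain) at in-plane points.

    Unsymmetric bending superposed on the axial term::

        eps = Fz0/(E A) + [(Mx0 Iy + My0 Ixy) y - (My0 Ix + Mx0 Ixy) x]
              / (E (Ix Iy - Ixy^2))

    Points are centroidal (x lateral, y anterior), in micrometres.  Returns a
    scalar for a single point or an array for an (n, 2) array of points.
    """
    det = section.bending_determinant_um8
    if det <= 0:
        raise ValueError("Ix*Iy - Ixy^2 must be positive")
    pts = np.atleast_2d(np.asarray(points_um, dtype=float))
    x_mm = pts[:, 0] * 1e-3
    y_mm = pts[:, 1] * 1e-3

    e_mpa = E_gpa * 1e3
    a_mm2 = section.area_um2 * 1e-6
    ix = section.Ix_um4 * 1e-12
    iy = section.Iy_um4 * 1e-12
    ixy = section.Ixy_um4 * 1e-12
    det_mm8 = ix * iy - ixy**2

    eps = loads.Fz0_n / (e_mpa * a_mm2)
    eps = eps + ((loads.Mx0_nmm * iy + loads.My0_nmm * ixy) * y_mm
                 - (loads.My0_nmm * ix + loads.Mx0_nmm * ixy) * x_mm) / (e_mpa * det_mm8)
    eps_ue = eps * 1e6
    if np.ndim(points_um) == 1:
        return float(eps_ue[0])
    return eps_ue


def neutral_axis_angle(Mx0_nmm: float, My0_nmm: float) -> float:
    """Orientation of the bending neutral axis, degrees from the medial-lateral
    (x) axis, in (-90, 90]: atan(My0/Mx0)."""
    if Mx0_nmm == 0.0 and My0_nmm == 0.0:
        raise ValueError("neutral axis undefined for zero bending moments")
    angle = np.degrees(np.arctan2(My0_nmm, Mx0_nmm))
    # fold into (-90, 90]: the axis is a line, not a direction
    if angle > 90.0:
        angle -= 180.0
    elif angle <= -90.0:
        angle += 180.0
    return float(angle)
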