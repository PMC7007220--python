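"""Clustering indices for motor neuron soma maps.

Phrenic motor neurons normally form a tightly packed column; genetic
perturbations disperse it.  Two complementary clustering indices quantify
this on 2-D section maps of soma/nucleus positions (μm):

* contact index - the fraction of labelled neurons in membrane contact with
  at least one other labelled neuron (1 = fully clustered), suited to
  membrane labels where soma outlines and radii are visible;
* density index - neurons per 1000 μm² of the area occupied by the column,
  suited to nuclear labels, with the occupied area taken as the convex hull
  of nucleus centres (an alpha-shape dialect is available for concave
  columns).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, QhullError
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "SomaMap",
    "ClusterReport",
    "contact_clustering_index",
    "pmc_perimeter_area",
    "alpha_shape_area",
    "density_clustering_index",
    "cluster_report",
]

#: effective radius assigned to point (nuclear) data without membrane outlines
DEFAULT_NUCLEAR_RADIUS_UM = 5.0


@dataclass
class SomaMap:
    """Soma/nucleus positions and radii in one section, in μm.

    ``x_um`` is mediolateral (positive lateral, midline at 0) and ``y_um``
    dorsoventral (positive dorsal).  Radii default to an effective nuclear
    radius when the stain shows no membrane outline.
    """

    x_um: np.ndarray
    y_um: np.ndarray
    radius_um: np.ndarray | float = DEFAULT_NUCLEAR_RADIUS_UM
    section_id: str = ""

    def __post_init__(self) -> None:
        self.x_um = np.atleast_1d(np.asarray(self.x_um, dtype=float))
        self.y_um = np.atleast_1d(np.asarray(self.y_um, dtype=float))
        if np.isscalar(self.radius_um) or np.ndim(self.radius_um) == 0:
            self.radius_um = np.full(self.x_um.size, float(self.radius_um))
        else:
            self.radius_um = np.asarray(self.radius_um, dtype=float)
        if not (self.x_um.size == self.y_um.size == self.radius_um.size):
            raise ValueError("x, y, and radius arrays must have equal length")
        if self.x_um.size < 1:
            raise ValueError("soma map must contain at least one entry")
        if np.any(self.radius_um <= 0):
            raise ValueError("radii must be positive")
        if not (np.all(np.isfinite(self.x_um)) and np.all(np.isfinite(self.y_um))):
            raise ValueError("coordinates must be finite")

    @property
    def n(self) -> int:
        return self.x_um.size

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.x_um, self.y_um])


@dataclass
class ClusterReport:
    contact_index: float
    n_neurons: int
    hull_area_um2: float | None
    density_index: float | None  # neurons per 1000 um^2
    params: dict = field(default_factory=dict)


def contact_clustering_index(soma_map: SomaMap, tol_um: float = 0.0) -> float:
    """Fraction of neurons in contact with at least one other neuron.

    Neuron i is in contact with j when their centre distance is at most
    ``r_i + r_j + tol_um``.  An index of 1 means every labelled neuron is
    clustered; a single-neuron map scores 0 by convention.
    """
    n = soma_map.n
    if n == 1:
        return 0.0
    d = squareform(pdist(soma_map.points))
    rsum = soma_map.radius_um[:, None] + soma_map.radius_um[None, :]
    contact = d <= rsum + tol_um
    np.fill_diagonal(contact, False)
    return float(np.sum(contact.any(axis=1))) / n


def pmc_perimeter_area(soma_map: SomaMap, shape: str = "hull",
                       alpha_um: float = 30.0) -> float:
    """Area (μm²) occupied by the column, from the outline of nucleus centres.

    The occupied region is the convex hull of the centres by default; the
    ``alpha`` dialect uses an alpha shape (Delaunay triangles with
    circumradius below ``alpha_um``) to follow concave outlines.
    """
    pts = soma_map.points
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 nuclei to define an occupied area")
    if shape == "alpha":
        return alpha_shape_area(pts, alpha_um)
    if shape != "hull":
        raise ValueError("shape must be 'hull' or 'alpha'")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise ValueError("nuclei are collinear; occupied area undefined") from exc
    return float(hull.volume)  # 2-D: volume is the area


def alpha_shape_area(points: np.ndarray, alpha_um: float) -> float:
    """Area of the alpha shape of a 2-D point set.

    Keeps Delaunay triangles whose circumradius is below ``alpha_um``; as
    ``alpha_um`` grows the result converges to the convex hull area.
    """
    if alpha_um <= 0:
        raise ValueError("alpha_um must be positive")
    pts = np.asarray(points, dtype=float)
    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        raise ValueError("degenerate point set for alpha shape") from exc
    area = 0.0
    for ia, ib, ic in tri.simplices:
        a, b, c = pts[ia], pts[ib], pts[ic]
        la, lb, lc = (np.linalg.norm(b - c), np.linalg.norm(a - c),
                      np.linalg.norm(a - b))
        u, v = b - a, c - a
        t_area = 0.5 * abs(float(u[0] * v[1] - u[1] * v[0]))
        if t_area <= 0:
            continue
        circum_r = la * lb * lc / (4.0 * t_area)
        if circum_r < alpha_um:
            area += t_area
    return float(area)


def density_clustering_index(soma_map: SomaMap, shape: str = "hull",
                             alpha_um: float = 30.0) -> float:
    """Neurons per 1000 μm² of occupied area: ``1000 * n / hull_area``."""
    area = pmc_perimeter_area(soma_map, shape=shape, alpha_um=alpha_um)
    if area <= 0:
        raise ValueError("occupied area is zero; density index undefined")
    return 1000.0 * soma_map.n / area


def cluster_report(soma_map: SomaMap, tol_um: float = 0.0, shape: str = "hull",
                   alpha_um: float = 30.0) -> ClusterReport:
    """Both clustering indices for one section.

    Area-based quantities are reported as None for degenerate maps (fewer
    than 3 nuclei), where the contact index is still defined.
    """
    contact = contact_clustering_index(soma_map, tol_um=tol_um)
    area: float | None
    density: float | None
    try:
        area = pmc_perimeter_area(soma_map, shape=shape, alpha_um=alpha_um)
        density = 1000.0 * soma_map.n / area
    except ValueError:
        area = None
        density = None
    return ClusterReport(
        contact, soma_map.n, area, density,
        params={"tol_um": tol_um, "shape": shape, "alpha_um": alpha_um},
    )
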