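"""Grid-based quantification of dendritic orientation.

Phrenic dendrites normally project in two major directions, dorsolateral and
ventromedial, and stay ipsilateral.  Orientation is quantified on a 2-D
fluorescence image by superimposing a 3x3 grid centred on the soma cluster,
spanning 200 μm from the centroid in each cardinal direction, and expressing
the intensity of each of the 8 peripheral squares as a fraction of the total
peripheral intensity (the centre square holds the cell bodies and is
excluded).  The fixed square numbering follows the standard layout in which
squares 5 and 6 form the dorsolateral pair and square 8 faces the midline.

Image convention: row 0 is the dorsal edge; on the ipsilateral side columns
increase laterally away from the midline column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

__all__ = [
    "DendriteImage",
    "GridQuantification",
    "MidlineStats",
    "DEFAULT_GRID_LAYOUT",
    "grid_quantify",
    "dorsal_fraction",
    "midline_crossing_stats",
    "coverage_area",
    "binarize",
]

# (row_band, col_band) -> square number; bands ordered dorsal->ventral and
# medial->lateral.  Squares 5+6 are the dorsolateral pair, 8 the medial
# (midline-facing) square; a different key can be loaded to match another
# numbering without corrupting downstream labels.
DEFAULT_GRID_LAYOUT: dict[tuple[int, int], int] = {
    (0, 0): 7, (0, 1): 6, (0, 2): 5,
    (1, 0): 8, (1, 2): 4,
    (2, 0): 1, (2, 1): 2, (2, 2): 3,
}

DORSOLATERAL_SQUARES = (5, 6)
MIDLINE_SQUARE = 8


@dataclass
class DendriteImage:
    """2-D dendritic fluorescence field with spatial metadata.

    ``soma_centroid`` is (row, col) in pixels; ``midline_col`` is the pixel
    column of the spinal cord midline.  Row 0 is dorsal.
    """

    intensity: np.ndarray
    pixel_size_um: float
    soma_centroid: tuple[float, float]
    midline_col: float

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("intensity field must be 2-D")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if np.any(~np.isfinite(self.intensity)) or np.any(self.intensity < 0):
            raise ValueError("intensities must be finite and non-negative")
        r, c = self.soma_centroid
        h, w = self.intensity.shape
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError("soma centroid outside image")
        if not (0 <= self.midline_col < w):
            raise ValueError("midline column outside image")

    @property
    def ipsilateral_sign(self) -> int:
        """+1 when the ipsilateral side is at columns above the midline."""
        return 1 if self.soma_centroid[1] >= self.midline_col else -1


@dataclass
class GridQuantification:
    fractions: dict[int, float]  # square number -> intensity fraction
    span_um: float
    square_size_um: float
    clipped: bool

    @property
    def dorsolateral_fraction(self) -> float:
        return sum(self.fractions[k] for k in DORSOLATERAL_SQUARES)

    @property
    def midline_fraction(self) -> float:
        return self.fractions[MIDLINE_SQUARE]


@dataclass
class MidlineStats:
    n_crossing_components: int
    max_contralateral_distance_um: float
    params: dict = field(default_factory=dict)

    @property
    def crossing_flag(self) -> bool:
        return self.n_crossing_components >= 1


def binarize(intensity: np.ndarray, method: str = "otsu",
             threshold: float | None = None) -> np.ndarray:
    """Foreground mask of a fluorescence field.

    ``otsu`` picks the threshold from the intensity histogram; ``fixed``
    uses the supplied absolute threshold.  A constant image has no
    foreground.
    """
    intensity = np.asarray(intensity, dtype=float)
    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed binarization requires a threshold")
        return intensity > threshold
    if method != "otsu":
        raise ValueError("threshold_method must be 'otsu' or 'fixed'")
    if intensity.max() == intensity.min():
        return np.zeros_like(intensity, dtype=bool)
    return intensity > threshold_otsu(intensity)


def grid_quantify(img: DendriteImage, span_um: float = 200.0,
                  layout: dict[tuple[int, int], int] | None = None) -> GridQuantification:
    """Intensity fraction of each of the 8 peripheral grid squares.

    The grid spans ``span_um`` from the soma centroid in each direction
    (3 equal squares per axis, so each square is 2*span/3 wide); the centre
    square is excluded and fractions are normalized to the summed peripheral
    intensity.  Grids exceeding the image are clipped with a warning.
    """
    layout = DEFAULT_GRID_LAYOUT if layout is None else layout
    if sorted(layout.values()) != list(range(1, 9)):
        raise ValueError("grid layout must assign squares 1-8 exactly once")
    h, w = img.intensity.shape
    r0, c0 = img.soma_centroid
    half_px = span_um / img.pixel_size_um
    cell_px = 2.0 * half_px / 3.0

    top, left = r0 - half_px, c0 - half_px
    clipped = top < 0 or left < 0 or r0 + half_px > h or c0 + half_px > w
    if clipped:
        warnings.warn("grid exceeds image bounds; clipped at the borders",
                      stacklevel=2)

    rows = np.arange(h)
    cols = np.arange(w)
    row_band = np.floor((rows - top) / cell_px).astype(int)
    col_band = np.floor((cols - left) / cell_px).astype(int)
    # row bands are dorsal->ventral already (row 0 dorsal); column bands must
    # run medial->lateral, so flip when the midline is on the high-column side
    if img.ipsilateral_sign < 0:
        col_band = 2 - col_band

    sums = {sq: 0.0 for sq in range(1, 9)}
    valid_r = (row_band >= 0) & (row_band <= 2)
    valid_c = (col_band >= 0) & (col_band <= 2)
    for rb in range(3):
        rsel = valid_r & (row_band == rb)
        if not rsel.any():
            continue
        for cb in range(3):
            if (rb, cb) == (1, 1):
                continue  # centre square: cell bodies
            csel = valid_c & (col_band == cb)
            if not csel.any():
                continue
            sums[layout[(rb, cb)]] += float(
                img.intensity[np.ix_(rsel, csel)].sum()
            )
    total = sum(sums.values())
    if total <= 0:
        raise ValueError("no dendritic signal in the peripheral grid squares")
    fractions = {sq: s / total for sq, s in sums.items()}
    return GridQuantification(fractions, span_um, cell_px * img.pixel_size_um,
                              clipped)


def dorsal_fraction(img: DendriteImage, soma_row: float | None = None) -> float:
    """Intensity dorsal to the cell bodies as a fraction of total intensity.

    Rows strictly above ``soma_row`` (default: the soma centroid row) are
    dorsal; the complement is the ventral fraction, so the two sum to 1.
    """
    soma_row = img.soma_centroid[0] if soma_row is None else soma_row
    if not (0 <= soma_row < img.intensity.shape[0]):
        raise ValueError("soma_row outside image")
    total = img.intensity.sum()
    if total <= 0:
        raise ValueError("image has zero total intensity")
    dorsal = img.intensity[: int(np.ceil(soma_row)), :].sum()
    return float(dorsal / total)


def midline_crossing_stats(img: DendriteImage, threshold_method: str = "otsu",
                           threshold: float | None = None) -> MidlineStats:
    """Count dendrite components crossing the midline and their farthest reach.

    The image is binarized and 8-connected components are counted when they
    have foreground strictly on both sides of the midline column.  The
    maximum contralateral distance is the farthest contralateral extent (in
    columns beyond the midline) over crossing components, in μm.
    """
    fg = binarize(img.intensity, threshold_method, threshold)
    labels = label(fg, connectivity=2)
    sign = img.ipsilateral_sign
    mid = img.midline_col
    n_crossing = 0
    max_dist_px = 0.0
    for region in regionprops(labels):
        cols = region.coords[:, 1]
        contra = sign * (mid - cols)  # positive on the contralateral side
        if (contra > 0).any() and (contra < 0).any():
            n_crossing += 1
            max_dist_px = max(max_dist_px, float(contra.max()))
    return MidlineStats(
        n_crossing, max_dist_px * img.pixel_size_um,
        params={"threshold_method": threshold_method},
    )


def coverage_area(img: DendriteImage, threshold_method: str = "otsu",
                  threshold: float | None = None) -> float:
    """Total dendritic footprint: suprathreshold pixel count x pixel area (μm²)."""
    fg = binarize(img.intensity, threshold_method, threshold)
    return float(fg.sum()) * img.pixel_size_um ** 2
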