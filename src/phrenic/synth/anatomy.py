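"""Synthetic soma maps, dendrite images, and synaptic puncta fields.

Each generator reproduces one anatomical readout with exact ground truth:

* soma maps - tightly contact-packed (control-like) vs. dispersed
  (mutant-like) configurations with the true contact graph;
* dendrite images - Gaussian-profile intensity rays leaving the soma
  centroid at set angles (dorsolateral/ventromedial by default), with the
  analytic intensity share of each grid square, the dorsal share, the
  rendered footprint, and any midline-crossing segment recorded;
* puncta fields - paired pre/post synaptic puncta placed in perisomatic
  shells plus unpaired distractors, rendered as Gaussian spots in two
  channels.

Coordinates follow the package convention: x mediolateral (positive
lateral), y dorsoventral (positive dorsal); image row 0 is the dorsal edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..dendrites import DendriteImage
from ..puncta import SomaOutline
from ..topography import SomaMap

__all__ = [
    "simulate_soma_map",
    "DendriteSimResult",
    "simulate_dendrite_image",
    "PunctaFieldTruth",
    "simulate_puncta_field",
]

_CONTACT_EPS = 1e-6  # tangent somata are placed this far into overlap (μm)


# ---------------------------------------------------------------------------
# soma maps


def simulate_soma_map(n: int = 10, condition: str = "clustered",
                      radius_um: float = 15.0, field_um: float = 500.0,
                      margin_um: float = 5.0, seed: int = 0,
                      ) -> tuple[SomaMap, list[tuple[int, int]]]:
    """Simulate a soma map plus its ground-truth contact graph.

    ``clustered`` packs each soma into membrane contact with at least one
    previously placed soma (sequential tangent packing); ``dispersed``
    enforces centre separations above ``2*radius + margin`` by rejection
    sampling.  The contact graph holds an edge (i, j) whenever the centre
    distance is at most the sum of radii plus a small tolerance.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if radius_um <= 0:
        raise ValueError("radius_um must be positive")
    rng = np.random.default_rng(seed)
    if condition == "clustered":
        pts = [np.zeros(2)]
        for _ in range(1, n):
            for _ in range(2000):
                anchor = pts[rng.integers(len(pts))]
                theta = rng.uniform(0, 2 * np.pi)
                cand = anchor + (2 * radius_um - _CONTACT_EPS) * np.array(
                    [np.cos(theta), np.sin(theta)]
                )
                d = np.linalg.norm(np.asarray(pts) - cand, axis=1)
                if np.all(d >= 2 * radius_um - 2 * _CONTACT_EPS):
                    pts.append(cand)
                    break
            else:  # pragma: no cover - packing equal disks always succeeds
                raise RuntimeError("contact packing failed")
        pts = np.asarray(pts)
        pts = pts - pts.mean(axis=0) + field_um / 2.0
    elif condition == "dispersed":
        min_sep = 2 * radius_um + margin_um
        # crude feasibility bound for rejection sampling
        if n * min_sep ** 2 > 0.5 * field_um ** 2:
            raise ValueError(
                "cannot disperse that many somata in the field with this margin"
            )
        pts_list: list[np.ndarray] = []
        for _ in range(n):
            for _ in range(10000):
                cand = rng.uniform(radius_um, field_um - radius_um, 2)
                if not pts_list or np.all(
                    np.linalg.norm(np.asarray(pts_list) - cand, axis=1) > min_sep
                ):
                    pts_list.append(cand)
                    break
            else:
                raise ValueError("dispersed placement failed; margin too large")
        pts = np.asarray(pts_list)
    else:
        raise ValueError("condition must be 'clustered' or 'dispersed'")

    soma_map = SomaMap(pts[:, 0], pts[:, 1], radius_um,
                       section_id=f"sim-{condition}-{seed}")
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(pts[i] - pts[j]) <= 2 * radius_um + _CONTACT_EPS:
                edges.append((i, j))
    return soma_map, edges


# ---------------------------------------------------------------------------
# dendrite images


@dataclass
class DendriteSimResult:
    """Rendered dendrite image plus analytic ground truth."""

    image: DendriteImage
    square_fractions: dict[int, float]
    dorsal_fraction: float
    footprint_um2: float
    footprint_threshold: float
    n_crossing: int
    max_contralateral_um: float
    rays: list[tuple[float, float, float]] = field(default_factory=list)


def _ray_field(rows_um: np.ndarray, cols_um: np.ndarray,
               soma_um: tuple[float, float],
               rays: list[tuple[float, float, float]],
               sigma_um: float) -> np.ndarray:
    """Analytic intensity at (row, col) positions: sum of Gaussian-profile rays.

    Angles are in degrees with 0 = lateral (increasing column) and
    90 = dorsal (decreasing row).
    """
    rr, cc = np.meshgrid(rows_um, cols_um, indexing="ij")
    dr = rr - soma_um[0]
    dc = cc - soma_um[1]
    out = np.zeros_like(rr)
    for angle_deg, weight, length_um in rays:
        a = np.deg2rad(angle_deg)
        ur, uc = -np.sin(a), np.cos(a)  # dorsal is -row
        s = dr * ur + dc * uc
        perp = np.abs(dr * uc - dc * ur)
        inside = (s >= 0) & (s <= length_um)
        out += weight * inside * np.exp(-(perp ** 2) / (2 * sigma_um ** 2))
    return out


def simulate_dendrite_image(
    rays: list[tuple[float, float, float]] | None = None,
    contralateral_extent_um: float = 0.0,
    pixel_size_um: float = 2.0,
    shape_um: tuple[float, float] = (600.0, 600.0),
    soma_centroid_um: tuple[float, float] = (300.0, 400.0),
    midline_um: float = 100.0,
    ray_sigma_um: float = 12.0,
    angle_jitter_deg: float = 3.0,
    footprint_rel_threshold: float = 0.05,
    supersample: int = 3,
    seed: int = 0,
) -> DendriteSimResult:
    """Render a dendritic intensity field with analytic per-square truth.

    ``rays`` is a list of (angle_deg, weight, length_um) with weights summing
    to 1; the default pair points dorsolaterally and ventromedially.  With
    ``contralateral_extent_um > 0`` a medial ray is added that crosses the
    midline by that distance (weights renormalized).  Ground-truth square
    fractions, the dorsal share, and the footprint area (region above
    ``footprint_rel_threshold`` of the field maximum) are integrated on a
    ``supersample``-times finer grid than the rendered image, so they are
    independent of the rendering raster.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    if not (0 <= soma_centroid_um[0] < shape_um[0]
            and 0 <= soma_centroid_um[1] < shape_um[1]):
        raise ValueError("soma centroid outside image")
    rng = np.random.default_rng(seed)
    if rays is None:
        rays = [(45.0, 0.5, 180.0), (225.0, 0.5, 180.0)]
    rays = [(a + rng.normal(0.0, angle_jitter_deg), w, L) for a, w, L in rays]
    if contralateral_extent_um > 0:
        cross_len = (soma_centroid_um[1] - midline_um) + contralateral_extent_um
        rays = [(a, 0.75 * w, L) for a, w, L in rays]
        rays.append((180.0, 0.25, cross_len))
    wsum = sum(w for _, w, _ in rays)
    if not np.isclose(wsum, 1.0):
        raise ValueError("ray weights must sum to 1")

    h = int(round(shape_um[0] / pixel_size_um))
    w_px = int(round(shape_um[1] / pixel_size_um))
    rows_um = np.arange(h) * pixel_size_um
    cols_um = np.arange(w_px) * pixel_size_um
    intensity = _ray_field(rows_um, cols_um, soma_centroid_um, rays, ray_sigma_um)
    image = DendriteImage(
        intensity, pixel_size_um,
        (soma_centroid_um[0] / pixel_size_um, soma_centroid_um[1] / pixel_size_um),
        midline_um / pixel_size_um,
    )

    # ground truth on a finer, offset grid (independent of the render raster)
    fine = pixel_size_um / supersample
    rows_f = np.arange(h * supersample) * fine + fine / 2
    cols_f = np.arange(w_px * supersample) * fine + fine / 2
    field_f = _ray_field(rows_f, cols_f, soma_centroid_um, rays, ray_sigma_um)

    # per-square shares over the 3x3 grid centred on the soma (span 200 μm)
    span = 200.0
    cell = 2 * span / 3.0
    rb = np.floor((rows_f - (soma_centroid_um[0] - span)) / cell).astype(int)
    cb = np.floor((cols_f - (soma_centroid_um[1] - span)) / cell).astype(int)
    from ..dendrites import DEFAULT_GRID_LAYOUT

    sums = {sq: 0.0 for sq in range(1, 9)}
    for rband in range(3):
        rsel = rb == rband
        if not rsel.any():
            continue
        for cband in range(3):
            if (rband, cband) == (1, 1):
                continue
            csel = cb == cband
            if not csel.any():
                continue
            # medial side has lower x only when soma is lateral of midline
            cb_key = cband if soma_centroid_um[1] >= midline_um else 2 - cband
            sums[DEFAULT_GRID_LAYOUT[(rband, cb_key)]] += float(
                field_f[np.ix_(rsel, csel)].sum()
            )
    total = sum(sums.values())
    square_fractions = {sq: s / total for sq, s in sums.items()}

    dorsal = float(field_f[rows_f < soma_centroid_um[0], :].sum() / field_f.sum())
    thr = footprint_rel_threshold * float(field_f.max())
    footprint = float((field_f > thr).sum()) * fine ** 2

    return DendriteSimResult(
        image, square_fractions, dorsal, footprint, thr,
        n_crossing=1 if contralateral_extent_um > 0 else 0,
        max_contralateral_um=float(contralateral_extent_um),
        rays=rays,
    )


# ---------------------------------------------------------------------------
# puncta fields


@dataclass
class PunctaFieldTruth:
    """Ground truth of a simulated pre/post puncta field."""

    soma_centers_um: np.ndarray  # (n, 2)
    soma_radius_um: float
    outlines: list[SomaOutline]
    pre_xy_um: np.ndarray
    post_xy_um: np.ndarray
    pair_pre_idx: np.ndarray
    pair_post_idx: np.ndarray
    pairs_per_soma: dict[str, int]
    min_unpaired_sep_um: float  # min pre-post distance among non-pair combos
    field_um: float
    pixel_size_um: float


def _render_spots(xy_um: np.ndarray, amps: np.ndarray, field_um: float,
                  pixel_size_um: float, sigma_um: float) -> np.ndarray:
    n_px = int(round(field_um / pixel_size_um))
    img = np.zeros((n_px, n_px))
    if xy_um.size == 0:
        return img
    half = int(np.ceil(4 * sigma_um / pixel_size_um))
    for (x, y), a in zip(xy_um, amps):
        r0 = int(round(y / pixel_size_um))
        c0 = int(round(x / pixel_size_um))
        rr = np.arange(max(0, r0 - half), min(n_px, r0 + half + 1))
        cc = np.arange(max(0, c0 - half), min(n_px, c0 + half + 1))
        if rr.size == 0 or cc.size == 0:
            continue
        dr = rr * pixel_size_um - y
        dc = cc * pixel_size_um - x
        img[np.ix_(rr, cc)] += a * np.exp(
            -(dr[:, None] ** 2 + dc[None, :] ** 2) / (2 * sigma_um ** 2)
        )
    return img


def simulate_puncta_field(
    n_somata: int = 3,
    paired_per_soma: int = 8,
    distractor_density_per_um2: float = 0.0,
    apposition_sep_um: float = 0.3,
    field_um: float = 60.0,
    pixel_size_um: float = 0.1,
    soma_radius_um: float = 7.0,
    shell_width_um: float = 1.0,
    punctum_diameter_um: float = 0.5,
    amplitude_jitter: float = 0.2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, PunctaFieldTruth]:
    """Simulate pre/post channel images and their ground-truth pairing.

    Paired puncta sit in the perisomatic shell (radial band of width
    ``shell_width_um`` around each soma membrane) with pair centre
    separation at most ``apposition_sep_um``; distractors are unpaired spots
    kept away from every other punctum.  Returns (pre_image, post_image,
    truth); puncta are rendered as 2-D Gaussian spots.
    """
    if shell_width_um <= 0:
        raise ValueError("shell_width_um must be positive")
    if paired_per_soma < 0 or distractor_density_per_um2 < 0:
        raise ValueError("densities must be non-negative")
    rng = np.random.default_rng(seed)

    # soma centres, mutually separated (whole-configuration restarts so an
    # unlucky first placement cannot wedge the sampler)
    min_sep = 2 * (soma_radius_um + shell_width_um) + 2.0
    pad = soma_radius_um + shell_width_um + 1.0
    if field_um <= 2 * pad:
        raise ValueError("field too small for the soma radius and shell")
    centers: list[np.ndarray] = []
    for _ in range(200):
        centers = []
        for _ in range(n_somata):
            for _ in range(500):
                cand = rng.uniform(pad, field_um - pad, 2)
                if not centers or np.all(
                    np.linalg.norm(np.asarray(centers) - cand, axis=1) >= min_sep
                ):
                    centers.append(cand)
                    break
            else:
                break
        if len(centers) == n_somata:
            break
    else:
        raise ValueError("field too small for that many somata")
    centers_arr = np.asarray(centers).reshape(-1, 2)
    outlines = []
    theta = np.linspace(0, 2 * np.pi, 64, endpoint=False)
    for i, c in enumerate(centers_arr):
        verts = c + soma_radius_um * np.column_stack([np.cos(theta), np.sin(theta)])
        outlines.append(SomaOutline(verts, soma_id=f"soma{i}"))

    pre_xy: list[np.ndarray] = []
    post_xy: list[np.ndarray] = []
    pair_pre, pair_post = [], []
    pairs_per_soma: dict[str, int] = {}
    for i, c in enumerate(centers_arr):
        k = paired_per_soma
        angles = (np.arange(k) + rng.uniform(0, 1)) / max(k, 1) * 2 * np.pi
        angles += rng.normal(0, 0.2 / max(soma_radius_um, 1.0), k)
        radii = soma_radius_um + rng.uniform(-shell_width_um / 2,
                                             shell_width_um / 2, k)
        for ang, rad in zip(angles, radii):
            p = c + rad * np.array([np.cos(ang), np.sin(ang)])
            off_dir = rng.uniform(0, 2 * np.pi)
            off = rng.uniform(0.2, 0.9) * apposition_sep_um
            q = p + off * np.array([np.cos(off_dir), np.sin(off_dir)])
            pair_pre.append(len(pre_xy))
            pair_post.append(len(post_xy))
            pre_xy.append(p)
            post_xy.append(q)
        pairs_per_soma[f"soma{i}"] = k

    # unpaired distractors, kept clear of all other puncta in both channels
    n_distract = rng.poisson(distractor_density_per_um2 * field_um ** 2)
    for channel in (pre_xy, post_xy):
        placed = 0
        while placed < n_distract:
            for _ in range(10000):
                cand = rng.uniform(1.0, field_um - 1.0, 2)
                existing = np.asarray(pre_xy + post_xy).reshape(-1, 2)
                if existing.size == 0 or np.all(
                    np.linalg.norm(existing - cand, axis=1) >= 1.5
                ):
                    channel.append(cand)
                    placed += 1
                    break
            else:
                break  # field saturated; fewer distractors than requested

    pre_arr = np.asarray(pre_xy).reshape(-1, 2)
    post_arr = np.asarray(post_xy).reshape(-1, 2)

    # minimum pre-post separation outside true pairs (for matching-radius
    # arguments in tests)
    min_unpaired = np.inf
    pair_set = set(zip(pair_pre, pair_post))
    for i in range(pre_arr.shape[0]):
        d = np.linalg.norm(post_arr - pre_arr[i], axis=1)
        for j in range(post_arr.shape[0]):
            if (i, j) not in pair_set:
                min_unpaired = min(min_unpaired, float(d[j]))

    sigma = punctum_diameter_um / 4.0
    amp_pre = 1.0 + rng.uniform(-amplitude_jitter, amplitude_jitter, pre_arr.shape[0])
    amp_post = 1.0 + rng.uniform(-amplitude_jitter, amplitude_jitter, post_arr.shape[0])
    pre_img = _render_spots(pre_arr, amp_pre, field_um, pixel_size_um, sigma)
    post_img = _render_spots(post_arr, amp_post, field_um, pixel_size_um, sigma)

    truth = PunctaFieldTruth(
        centers_arr, soma_radius_um, outlines, pre_arr, post_arr,
        np.asarray(pair_pre, dtype=int), np.asarray(pair_post, dtype=int),
        pairs_per_soma, min_unpaired, field_um, pixel_size_um,
    )
    return pre_img, post_img, truth
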