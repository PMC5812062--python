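"""Segmentation and per-particle morphometry of composite images.

Particles are extracted as connected components of below-threshold pixels,
diatom chains split by the segmentation are re-connected by proximity, and
each region is measured: filled area, equivalent spherical diameter,
major/minor axes from the particle extrema line, aspect ratio, convex hull
area, and orientation relative to the image horizontal (positive slope =
positive angle, origin at the bottom-left).  Orientations are corrected for
platform pitch before any statistics are computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import ConvexHull, QhullError, cKDTree
from skimage.filters import threshold_otsu
from skimage.morphology import convex_hull_image, skeletonize

__all__ = [
    "Region",
    "ParticleRecord",
    "PARTICLE_CSV_COLUMNS",
    "lowpass_2x2",
    "segment",
    "reconnect_chains",
    "measure_region",
    "correct_orientation",
    "wrap_theta",
]

PARTICLE_CSV_COLUMNS = [
    "id",
    "hologram_id",
    "depth_m",
    "x_um",
    "y_um",
    "z_mm",
    "area_px",
    "filled_area_um2",
    "equiv_diam_um",
    "major_um",
    "minor_um",
    "aspect_ratio",
    "theta_deg",
    "hull_area_um2",
    "chain_flag",
    "overlap_flag",
    "curvature_flag",
]


@dataclass(frozen=True)
class Region:
    """A segmented pixel set, prior to morphometry."""

    pixels: np.ndarray  # (m, 2) array of (y, x) indices
    chain_flag: bool = False  # set when assembled from re-connected cells

    def __len__(self) -> int:
        return len(self.pixels)


@dataclass
class ParticleRecord:
    """Morphometry and orientation of one segmented particle.

    Lengths are in micrometres; ``theta_deg`` lies in (-90, +90] with 0
    horizontal and is pitch-corrected by the caller when platform pitch is
    known.  ``equiv_diam_um`` is the diameter of the circle with the
    particle's filled area, sqrt(4 A / pi).
    """

    id: int = -1
    hologram_id: str = ""
    depth_m: float = float("nan")
    x_um: float = float("nan")
    y_um: float = float("nan")
    z_mm: float = float("nan")
    area_px: int = 0
    filled_area_um2: float = float("nan")
    equiv_diam_um: float = float("nan")
    major_um: float = float("nan")
    minor_um: float = float("nan")
    aspect_ratio: float = float("nan")
    theta_deg: float = float("nan")
    hull_area_um2: float = float("nan")
    chain_flag: bool = False
    overlap_flag: bool = False
    curvature_flag: bool = False


def lowpass_2x2(image: np.ndarray) -> np.ndarray:
    """2 x 2 box smoothing applied before segmentation.

    The smallest mean-preserving low-pass kernel: a single hot pixel
    spreads to four pixels of a quarter its amplitude and a checkerboard
    collapses to its mean.
    """
    return ndimage.uniform_filter(np.asarray(image, dtype=float), size=2, mode="nearest")


def segment(
    image: np.ndarray, intensity_threshold: float | str | None = None, min_px: int = 5
) -> list[Region]:
    """8-connected components of below-threshold pixels.

    Opaque particles are dark against the illuminated background, so
    segmentation keeps pixels strictly below the threshold and discards
    components smaller than ``min_px`` pixels, below which noise and true
    particles are not reliably distinguishable.  The default threshold is
    0.4 x the image median: particle silhouettes sit near zero while the
    background (median) is bright, and — unlike a bimodal-histogram rule —
    a fixed fraction of the background level is immune to the extreme
    class imbalance of sparse scenes (a permissive cut also attaches the
    diffraction halo to each silhouette, biasing the minor axis wide).
    Pass a float for an absolute threshold or ``"otsu"`` for Otsu's rule.
    """
    image = np.asarray(image)
    if intensity_threshold is None:
        intensity_threshold = 0.4 * float(np.median(image))
    elif intensity_threshold == "otsu":
        intensity_threshold = float(threshold_otsu(image))
    binary = image < intensity_threshold
    labels, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    regions: list[Region] = []
    for sl, lab in zip(ndimage.find_objects(labels), range(1, n + 1)):
        ys, xs = np.nonzero(labels[sl] == lab)
        if len(ys) < min_px:
            continue
        pix = np.column_stack([ys + sl[0].start, xs + sl[1].start])
        regions.append(Region(pixels=pix))
    return regions


def reconnect_chains(regions: list[Region], max_gap_px: float) -> list[Region]:
    """Merge regions whose boundary-to-boundary distance is within a gap.

    Diatom chains segment into discrete cells because the narrow linkages
    sit above the intensity threshold; cells closer than ``max_gap_px``
    (boundary to boundary: centre distance minus one pixel, so touching
    pixels are at gap 0) are merged transitively, union-find style, so the
    result does not depend on merge order.  ``max_gap_px = 0`` is the
    identity on disjoint regions.
    """
    if max_gap_px < 0:
        raise ValueError("max_gap_px must be >= 0")
    n = len(regions)
    if n <= 1 or max_gap_px == 0:
        return list(regions)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    trees = [cKDTree(r.pixels) for r in regions]
    for i in range(n):
        for j in range(i + 1, n):
            if find(i) == find(j):
                continue
            dist = trees[i].query(regions[j].pixels, k=1)[0].min() - 1.0
            if dist <= max_gap_px:
                parent[find(j)] = find(i)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    merged: list[Region] = []
    for members in groups.values():
        if len(members) == 1:
            merged.append(regions[members[0]])
        else:
            pix = np.vstack([regions[m].pixels for m in members])
            merged.append(Region(pixels=pix, chain_flag=True))
    return merged


def _extrema_line(points: np.ndarray) -> tuple[float, float]:
    """Longest-chord length (px) and its angle (deg) from pixel coordinates.

    The major-axis *length* is the distance between the two mutually
    farthest boundary pixels.  The *angle* of that extrema line is refined
    by iterated tip-cap centroids: the centroid of the pixels within a cap
    at each end of the particle lies on the symmetry axis, so the line
    between the two cap centroids localises the axis to sub-pixel
    precision, where the raw farthest pair carries ~atan(1/L) of
    quantisation jitter.
    """
    pts = points.astype(float)
    try:
        hull = ConvexHull(pts)
        verts = pts[hull.vertices]
    except QhullError:  # collinear / degenerate region
        verts = pts
    d = np.linalg.norm(verts[:, None, :] - verts[None, :, :], axis=2)
    dmax = float(d.max())
    i0, j0 = np.unravel_index(np.argmax(d), d.shape)
    a, b = verts[i0], verts[j0]
    for _ in range(3):
        norm = np.linalg.norm(b - a)
        if norm == 0:
            break
        u = (b - a) / norm
        proj = pts @ u
        cap = max(2.0, 0.15 * (proj.max() - proj.min()))
        a = pts[proj <= proj.min() + cap].mean(axis=0)
        b = pts[proj >= proj.max() - cap].mean(axis=0)
    dy, dx = b[0] - a[0], b[1] - a[1]
    if dx == 0 and dy == 0:
        return dmax, 0.0
    theta = wrap_theta(math.degrees(math.atan2(dy, dx)))
    return dmax, theta


def _skeleton_geodesic_px(mask: np.ndarray) -> float:
    """Longest geodesic path length along the skeleton of a mask (px)."""
    skel = skeletonize(mask)
    coords = np.column_stack(np.nonzero(skel))
    m = len(coords)
    if m < 2:
        return 0.0
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=1.5, output_type="ndarray")
    if len(pairs) == 0:
        return 0.0
    w = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    graph = coo_matrix(
        (np.concatenate([w, w]), (np.concatenate([pairs[:, 0], pairs[:, 1]]),
                                  np.concatenate([pairs[:, 1], pairs[:, 0]]))),
        shape=(m, m),
    )
    # double sweep: farthest node from an arbitrary start, then farthest from it
    d0 = dijkstra(graph, indices=0, directed=False)
    d0[~np.isfinite(d0)] = 0
    far = int(np.argmax(d0))
    d1 = dijkstra(graph, indices=far, directed=False)
    d1[~np.isfinite(d1)] = 0
    return float(d1.max())


def measure_region(region: Region, pitch_um: float, min_px: int = 5) -> ParticleRecord:
    """Morphometry of one segmented region.

    Filled area counts interior holes back in before computing the
    equivalent diameter; the major axis is the particle-extrema line, the
    minor axis the maximal extent perpendicular to it; slightly curved
    chains are flagged (skeleton length > 110% of the chord) but their
    straight-line major axis is retained.
    """
    pix = region.pixels
    if len(pix) < min_px:
        raise ValueError(f"region has {len(pix)} px; at least {min_px} required")
    y0, x0 = pix.min(axis=0)
    y1, x1 = pix.max(axis=0)
    crop = np.zeros((y1 - y0 + 2, x1 - x0 + 2), dtype=bool)
    crop[pix[:, 0] - y0, pix[:, 1] - x0] = True
    filled = ndimage.binary_fill_holes(crop)
    filled_px = int(filled.sum())
    hull_px = int(convex_hull_image(filled).sum()) if filled_px > 2 else filled_px

    major_px, theta = _extrema_line(pix)
    t = math.radians(theta)
    perp = pix[:, 1] * (-math.sin(t)) + pix[:, 0] * math.cos(t)
    minor_px = float(perp.max() - perp.min())
    degenerate = minor_px < 0.5
    # half-pixel extent correction: rotation stair-stepping already widens
    # the centre-to-centre spread, so a full +1 px overestimates the width
    minor_px = max(minor_px + 0.5, 1.0)
    major_px = major_px + 1.0

    chord_px = major_px - 1.0
    geo = _skeleton_geodesic_px(filled)
    curvature = chord_px > 0 and geo > 1.10 * chord_px

    area_um2 = filled_px * pitch_um**2
    cy, cx = pix.mean(axis=0)
    return ParticleRecord(
        x_um=float(cx * pitch_um),
        y_um=float(cy * pitch_um),
        area_px=len(pix),
        filled_area_um2=area_um2,
        equiv_diam_um=math.sqrt(4.0 * area_um2 / math.pi),
        major_um=major_px * pitch_um,
        minor_um=minor_px * pitch_um,
        aspect_ratio=major_px / minor_px,
        theta_deg=theta,
        hull_area_um2=hull_px * pitch_um**2,
        chain_flag=region.chain_flag,
        # degenerate 1-px-wide regions share the quality flag: their minor
        # axis is forced to one pixel and the aspect ratio is a lower bound
        curvature_flag=bool(curvature) or degenerate,
    )


def wrap_theta(theta: float) -> float:
    """Map an orientation angle in degrees to (-90, +90]."""
    return -((-theta + 90.0) % 180.0 - 90.0)


def correct_orientation(raw_theta: float, pitch: float) -> float:
    """Remove platform pitch from a measured orientation angle.

    The profiler tilts as it descends, so the instrument's tilt-sensor
    pitch is subtracted from the raw image-plane angle; the result is
    wrapped back to (-90, +90].
    """
    if abs(pitch) >= 45:
        raise ValueError("platform pitch must satisfy |pitch| < 45 degrees")
    return wrap_theta(raw_theta - pitch)
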