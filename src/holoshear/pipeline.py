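"""End-to-end processing of one hologram into a particle table.

Chains the stages in the order the data demands: background removal,
numerical reconstruction, focus consolidation, 2x2 smoothing, segmentation,
chain re-connection, overlap resolution against the depth stack, per-region
morphometry and platform-pitch correction of the orientation angle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .holography import (
    Hologram,
    consolidate,
    normalize_hologram,
    reconstruct_stack,
    region_focus_plane,
    resolve_overlaps,
)
from .metrics import (
    ParticleRecord,
    Region,
    correct_orientation,
    lowpass_2x2,
    measure_region,
    reconnect_chains,
    segment,
)
from .optics import OpticalConfig

__all__ = ["ProcessingResult", "process_hologram"]

FRINGE_CONTRAST = 0.15  # pale = darkest pixel above this fraction of background
FRINGE_SIZE_RATIO = 5  # satellite must be this much smaller than its parent
FRINGE_REACH_UM = 200.0  # maximum parent-satellite boundary distance


def _suppress_fringe_satellites(pale, pale_mins, parents, med, pitch_um):
    """Drop low-contrast blobs sitting in the fringe halo of a big particle."""
    from scipy.spatial import cKDTree

    if not parents:
        return pale
    trees = [(len(r), cKDTree(r.pixels)) for r in parents]
    reach_px = FRINGE_REACH_UM / pitch_um
    kept = []
    for region, m in zip(pale, pale_mins):
        if m <= FRINGE_CONTRAST * med:  # decent contrast: keep as a particle
            kept.append(region)
            continue
        is_satellite = False
        for n_parent, tree in trees:
            if n_parent < FRINGE_SIZE_RATIO * len(region):
                continue
            if tree.query(region.pixels, k=1)[0].min() <= reach_px:
                is_satellite = True
                break
        if not is_satellite:
            kept.append(region)
    return kept


@dataclass
class ProcessingResult:
    """Particles from one hologram plus processing bookkeeping."""

    records: list[ParticleRecord]
    n_segmented: int
    n_overlap_discarded: int
    composite: object = None


def process_hologram(
    holo: Hologram,
    optics: OpticalConfig,
    background: np.ndarray | None = None,
    *,
    window_size: int = 128,
    focus_threshold: float | None = None,
    seg_threshold: float | None = None,
    min_px: int = 5,
    chain_gap_um: float = 30.0,
    hull_ratio_threshold: float = 1.5,
    hologram_id: str = "",
    keep_composite: bool = False,
) -> ProcessingResult:
    """Run the full reconstruction-to-morphometry chain on one hologram.

    Each particle's depth along the optical axis is the plane maximising
    the Tenengrad edge energy over its own pixels; the raw
    intensity-versus-depth minimum is biased toward the sensor by the dark
    shadow column elongated particles cast.  The water-column depth is the
    hologram's field-of-view centre depth.  Regions whose
    convex-hull-to-filled-area ratio exceeds ``hull_ratio_threshold`` are
    examined for two distinct focus depths and split, or discarded when
    inseparable.
    """
    frame = normalize_hologram(holo, background) if background is not None else holo.intensity
    stack = reconstruct_stack(frame, optics)
    composite = consolidate(stack, window_size=window_size, focus_threshold=focus_threshold)
    smoothed = lowpass_2x2(composite.image)
    regions = segment(smoothed, intensity_threshold=seg_threshold, min_px=min_px)
    pitch_um = optics.pixel_pitch * 1e6
    # chain re-connection is restricted to solidly dark regions: opaque cell
    # silhouettes reach near zero, whereas residual diffraction-fringe blobs
    # hover just below the segmentation threshold and must not be absorbed
    # into a neighbouring particle
    med = float(np.median(smoothed))
    dark_cut = 0.05 * med
    mins = np.array([smoothed[r.pixels[:, 0], r.pixels[:, 1]].min() for r in regions])
    dark = [r for r, m in zip(regions, mins) if m <= dark_cut]
    pale = [r for r, m in zip(regions, mins) if m > dark_cut]
    pale_mins = [m for m in mins if m > dark_cut]
    # fringe-satellite suppression: a large in-focus particle surrounds
    # itself with residual diffraction rings whose fragments segment as
    # small pale blobs; a pale region much smaller than a nearby solidly
    # dark region is such an artefact, not a particle
    pale = _suppress_fringe_satellites(pale, pale_mins, dark, med, pitch_um)
    regions = reconnect_chains(dark, max_gap_px=chain_gap_um / pitch_um) + pale

    records: list[ParticleRecord] = []
    n_discarded = 0
    next_id = 0
    for region in regions:
        probe = measure_region(region, pitch_um, min_px=min_px)
        parts = resolve_overlaps(
            region.pixels,
            stack,
            hull_area=probe.hull_area_um2,
            filled_area=probe.filled_area_um2,
            hull_ratio_threshold=hull_ratio_threshold,
        )
        if not parts:
            n_discarded += 1
            continue
        split = len(parts) > 1
        if not split:
            parts = [(region.pixels, region_focus_plane(stack, region.pixels))]
        for pixels, plane_idx in parts:
            sub = Region(pixels=pixels, chain_flag=region.chain_flag)
            if split:
                try:
                    rec = measure_region(sub, pitch_um, min_px=min_px)
                except ValueError:
                    continue
            else:
                rec = probe
            rec = replace(
                rec,
                id=next_id,
                hologram_id=hologram_id,
                depth_m=holo.depth,
                z_mm=float(stack.offsets[plane_idx] * 1e3),
                theta_deg=correct_orientation(rec.theta_deg, holo.pitch),
                overlap_flag=split,
            )
            records.append(rec)
            next_id += 1
    return ProcessingResult(
        records=records,
        n_segmented=len(regions),
        n_overlap_discarded=n_discarded,
        composite=composite if keep_composite else None,
    )
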