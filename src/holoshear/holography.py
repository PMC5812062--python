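"""Hologram normalisation, numerical reconstruction and focus consolidation.

The processing chain is: ensemble background subtraction, back-propagation
of each frame to a ladder of depth planes (excluding the window-boundary
margins), and consolidation of the plane stack into one composite image in
which every 128 x 128 sub-window is taken from its sharpest-focus plane.
In-focus opaque particles appear as compact clusters of low-intensity
pixels, so focus is scored per sub-window by the count of pixels darker
than a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .optics import OpticalConfig, propagate

__all__ = [
    "Hologram",
    "ReconstructionStack",
    "CompositeImage",
    "ensemble_background",
    "normalize_hologram",
    "reconstruct_stack",
    "default_focus_threshold",
    "consolidate",
    "depth_intensity_profile",
    "resolve_overlaps",
]


@dataclass(frozen=True)
class Hologram:
    """One recorded frame plus the acquisition metadata used downstream."""

    intensity: np.ndarray  # 2D, values in [0, 1]
    timestamp: float = 0.0  # s
    depth: float = 0.0  # m, centre of the field of view
    pitch: float = 0.0  # deg, platform inclination at acquisition
    cast: str = "down"  # "down" | "up"

    def __post_init__(self) -> None:
        if self.intensity.ndim != 2:
            raise ValueError("hologram intensity must be a 2D array")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.cast not in ("down", "up"):
            raise ValueError("cast must be 'down' or 'up'")


@dataclass(frozen=True)
class ReconstructionStack:
    """Ordered reconstructed intensity planes with their depth offsets."""

    offsets: np.ndarray  # m from the sensor-side window, strictly increasing
    planes: np.ndarray  # (n_planes, ny, nx) intensity

    def __post_init__(self) -> None:
        if len(self.offsets) != len(self.planes):
            raise ValueError("one offset per plane required")
        if np.any(np.diff(self.offsets) <= 0):
            raise ValueError("plane offsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.planes)


@dataclass(frozen=True)
class CompositeImage:
    """Single focused image assembled from per-sub-window best planes."""

    image: np.ndarray
    depth_index: np.ndarray  # per-sub-window (or per-pixel) chosen plane index
    offsets: np.ndarray  # plane offsets of the source stack, m
    window_size: int = 128

    def plane_of_pixel(self, y: int, x: int) -> int:
        """Chosen plane index for the sub-window containing pixel (y, x)."""
        if self.depth_index.shape == self.image.shape:
            return int(self.depth_index[y, x])
        return int(self.depth_index[y // self.window_size, x // self.window_size])


def ensemble_background(holograms) -> np.ndarray:
    """Pixel-wise mean frame over a sequence of holograms.

    With many frames, moving particles average out and the stationary
    illumination pattern (vignetting, window blemishes) remains.
    """
    frames = [h.intensity if isinstance(h, Hologram) else np.asarray(h) for h in holograms]
    if len(frames) < 2:
        raise ValueError("ensemble background needs at least 2 holograms")
    shape = frames[0].shape
    if any(f.shape != shape for f in frames):
        raise ValueError("all holograms must share the same dimensions")
    acc = np.zeros(shape, dtype=float)
    for f in frames:
        acc += f
    return acc / len(frames)


def normalize_hologram(h, background: np.ndarray) -> np.ndarray:
    """Subtract the ensemble background, re-centred at the background level.

    ``out = frame - background + mean(background)`` removes stationary
    non-uniformities without rescaling the interference contrast; a frame
    equal to the background maps to a constant.
    """
    frame = h.intensity if isinstance(h, Hologram) else np.asarray(h)
    background = np.asarray(background)
    if frame.shape != background.shape:
        raise ValueError("hologram and background dimensions differ")
    return frame - background + background.mean()


def reconstruct_stack(frame: np.ndarray, optics: OpticalConfig) -> ReconstructionStack:
    """Back-propagate one normalised frame to every retained depth plane.

    The recorded (real-valued) frame is treated as the field at the sensor
    and refocused with the conjugate angular-spectrum kernel at each plane
    offset; plane intensities are the squared magnitude.  The plane ladder
    excludes both window margins, giving ``optics.n_planes`` planes (70 at
    the default configuration).
    """
    frame = np.asarray(frame)
    if frame.shape != tuple(optics.sensor_px):
        raise ValueError(
            f"frame shape {frame.shape} does not match sensor {tuple(optics.sensor_px)}"
        )
    offsets = optics.plane_offsets()
    planes = np.empty((len(offsets), *frame.shape), dtype=np.float32)
    for i, z in enumerate(offsets):
        field = propagate(frame.astype(complex), -z, optics)
        planes[i] = (np.abs(field) ** 2).astype(np.float32)
    return ReconstructionStack(offsets=offsets, planes=planes)


def default_focus_threshold(stack: ReconstructionStack) -> float:
    """Background-relative focus threshold for counting dark pixels.

    Reconstructed backgrounds carry long non-Gaussian tails from residual
    fringes and twin images, so a dispersion-based cut sits far too close
    to the background level; worse, a permissive threshold makes the
    pixel-count criterion favour *defocused* planes, whose shallower but
    wider shadows cover more pixels.  The threshold is therefore pinned
    close to the darkest stack intensities (in-focus opaque silhouettes):
    dark + 0.15 x (background median - dark), which only sharp shadows
    reach.
    """
    sub = stack.planes[:: max(1, len(stack) // 8)]
    med = float(np.median(sub))
    dark = float(min(np.percentile(sub, 1e-3), np.min(stack.planes.min(axis=(1, 2)))))
    return dark + 0.15 * (med - dark)


FOCUS_DARK_FRACTION = 0.1  # per-window threshold position between dark and background


def consolidate(
    stack: ReconstructionStack,
    window_size: int = 128,
    focus_threshold: float | None = None,
    mode: str = "window",
) -> CompositeImage:
    """Collapse a reconstruction stack into a single in-focus composite.

    ``mode="window"`` (default): each sub-window takes the plane scoring
    highest on the focus criterion below; ties go to the plane with lower
    total intensity, then to the smaller depth.  Sub-windows with no
    below-threshold pixel anywhere default to the first plane.
    ``mode="min"`` is the simple per-pixel minimum-intensity fallback.

    Focus criterion: in-focus particles are clusters of sub-threshold
    pixels *with sharp boundaries*, so each plane is scored by the count
    of below-threshold pixels weighted by the local intensity-gradient
    energy (Tenengrad).  Darkness alone cannot discriminate: the shadow
    column an elongated particle casts toward the sensor stays as dark as
    the focused silhouette over many planes, but only the focused plane
    has sharp edges.  With ``focus_threshold=None`` each sub-window gets
    its own threshold, ``dark_w + 0.1 x (background_median - dark_w)``
    with ``dark_w`` the window's darkest intensity over all planes; a
    global threshold either misses faint particles or lets wide defocused
    shadows dominate the count.  Passing a float applies it globally.
    """
    planes = stack.planes
    n, ny, nx = planes.shape
    if mode == "min":
        idx = planes.argmin(axis=0)
        image = np.take_along_axis(planes, idx[None], axis=0)[0]
        return CompositeImage(image=image, depth_index=idx, offsets=stack.offsets, window_size=1)
    if mode != "window":
        raise ValueError("mode must be 'window' or 'min'")
    if ny % window_size or nx % window_size:
        raise ValueError("window_size must divide the frame dimensions")
    wy, wx = ny // window_size, nx // window_size
    blocks = planes.reshape(n, wy, window_size, wx, window_size)
    grad = np.empty_like(planes)
    for k in range(n):  # Tenengrad edge energy per plane
        gy = ndimage.sobel(planes[k], axis=0)
        gx = ndimage.sobel(planes[k], axis=1)
        grad[k] = gy * gy + gx * gx
    gblocks = grad.reshape(n, wy, window_size, wx, window_size)
    if focus_threshold is None:
        med = float(np.median(planes[:: max(1, n // 8)]))
        dark = blocks.min(axis=(0, 2, 4))  # (wy, wx) per-window darkest intensity
        thr = dark + FOCUS_DARK_FRACTION * (med - dark)
        below = blocks < thr[None, :, None, :, None]
    else:
        below = blocks < focus_threshold
    scores = (below * gblocks).sum(axis=(2, 4), dtype=np.float64)  # (n, wy, wx)
    sums = blocks.sum(axis=(2, 4), dtype=np.float64)
    chosen = np.zeros((wy, wx), dtype=int)
    for j in range(wy):
        for i in range(wx):
            c = scores[:, j, i]
            cmax = c.max()
            if cmax == 0:
                chosen[j, i] = 0
                continue
            tied = np.flatnonzero(c == cmax)
            chosen[j, i] = tied[np.argmin(sums[tied, j, i])]  # then smallest z: argmin is first
    image = np.empty((ny, nx), dtype=planes.dtype)
    for j in range(wy):
        for i in range(wx):
            ys, xs = j * window_size, i * window_size
            image[ys : ys + window_size, xs : xs + window_size] = planes[
                chosen[j, i], ys : ys + window_size, xs : xs + window_size
            ]
    return CompositeImage(image=image, depth_index=chosen, offsets=stack.offsets, window_size=window_size)


def region_focus_plane(stack: ReconstructionStack, pixels: np.ndarray) -> int:
    """Sharpest-focus plane index for one segmented region.

    Scores every plane by the Tenengrad edge energy (squared Sobel
    gradients) summed over the region's pixels and returns the argmax.
    Restricted to the particle's own pixels this is a clean unimodal focus
    curve; intensity-minimum criteria are biased toward the sensor by the
    particle's dark shadow column.
    """
    y0, x0 = pixels.min(axis=0)
    y1, x1 = pixels.max(axis=0)
    pad = 3
    ya, xa = max(0, y0 - pad), max(0, x0 - pad)
    sub = stack.planes[:, ya : y1 + pad + 1, xa : x1 + pad + 1].astype(float)
    ly, lx = pixels[:, 0] - ya, pixels[:, 1] - xa
    scores = np.empty(len(sub))
    for k in range(len(sub)):
        gy = ndimage.sobel(sub[k], axis=0)
        gx = ndimage.sobel(sub[k], axis=1)
        scores[k] = ((gy * gy + gx * gx)[ly, lx]).sum()
    return int(np.argmax(scores))


def depth_intensity_profile(stack: ReconstructionStack, pixels: np.ndarray) -> np.ndarray:
    """Mean intensity over a set of pixels at every reconstructed plane.

    ``pixels`` is an (m, 2) array of (y, x) indices.  In-focus depths of
    opaque particles show up as minima of this profile.
    """
    ys, xs = pixels[:, 0], pixels[:, 1]
    return stack.planes[:, ys, xs].mean(axis=1)


def _profile_minima(profile: np.ndarray, min_separation: int = 2) -> list[int]:
    """Indices of prominent local minima, deepest first."""
    n = len(profile)
    cands = [
        i
        for i in range(n)
        if (i == 0 or profile[i] <= profile[i - 1]) and (i == n - 1 or profile[i] < profile[i + 1])
    ]
    cands.sort(key=lambda i: profile[i])
    depth_span = float(profile.max() - profile.min()) or 1.0
    kept: list[int] = []
    for i in cands:
        if all(abs(i - j) > min_separation for j in kept):
            # require a real dip relative to the profile's dynamic range
            if profile[i] <= profile.min() + 0.5 * depth_span:
                kept.append(i)
    return kept


def resolve_overlaps(
    pixels: np.ndarray,
    stack: ReconstructionStack,
    hull_area: float,
    filled_area: float,
    hull_ratio_threshold: float = 1.5,
):
    """Split or discard a candidate region flagged as overlapping particles.

    Particles that overlap in projection but live at different depths show a
    high convex-hull-to-filled-area ratio.  If the ratio is at or below the
    threshold the region passes through unchanged.  Otherwise the per-pixel
    intensity-versus-depth profile over the region is inspected: two
    prominent minima at distinct depths split the region into two pixel
    sets (each pixel assigned to the depth at which it is darker); a single
    minimum means the region cannot be separated and both putative
    particles are discarded.

    Returns
    -------
    list of (pixels, plane_index)
        One element (the input region at its best-focus plane) when no
        overlap is detected, two when split, empty when discarded.
    """
    profile = depth_intensity_profile(stack, pixels)
    if hull_area <= hull_ratio_threshold * filled_area:
        return [(pixels, int(np.argmin(profile)))]
    minima = _profile_minima(profile)
    if len(minima) < 2:
        return []  # unresolvable overlap: eliminate both
    i1, i2 = sorted(minima[:2])
    ys, xs = pixels[:, 0], pixels[:, 1]
    closer_first = stack.planes[i1, ys, xs] <= stack.planes[i2, ys, xs]
    out = []
    for plane, sel in ((i1, closer_first), (i2, ~closer_first)):
        if sel.sum() >= 5:
            out.append((pixels[sel], plane))
    if len(out) < 2:
        return []
    return out
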