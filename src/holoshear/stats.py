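"""Depth-binned particle statistics: concentration, size spectra, orientation.

Works on particle tables in the dialect written by the morphometry stage
(one row per particle, lengths in micrometres, ``depth_m`` positive down,
``theta_deg`` pitch-corrected in (-90, +90]).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .jeffery import ANGLE_BIN_EDGES

__all__ = [
    "ASPECT_BIN_EDGES",
    "SizeDistribution",
    "subsample_cast",
    "concentration_profile",
    "concentration_by_aspect",
    "build_psd",
    "fit_junge",
    "fit_junge_segments",
    "orientation_pdf",
]

# aspect-ratio classes: small particles, short / medium / long diatom chains
ASPECT_BIN_EDGES = [1.0, 3.0, 6.0, 10.0, np.inf]

PSD_RANGE_UM = (11.6, 1000.0)  # smallest reliable D (5 px) to largest binned


def subsample_cast(holograms: list, cast: str) -> list:
    """Thin a hologram sequence to avoid counting a particle twice.

    Between consecutive frames the platform moves less than one field of
    view, so statistics use every third hologram on downcasts and every
    second on the (faster) upcasts, starting from the first frame.
    """
    if cast not in ("down", "up"):
        raise ValueError("cast must be 'down' or 'up'")
    stride = 3 if cast == "down" else 2
    return list(holograms[::stride])


def concentration_profile(
    particles: pd.DataFrame,
    hologram_depths: np.ndarray,
    bin_height: float = 0.2,
    hologram_volume_ml: float = 3.53,
) -> pd.DataFrame:
    """Particle concentration Pv = P / (n V) per depth bin (per mL).

    ``P`` counts particles whose hologram depth falls in the bin, ``n`` the
    holograms in that bin, ``V`` the volume of one hologram.  Bins with no
    hologram are omitted (concentration there is unobserved, not zero).
    """
    depths = np.asarray(hologram_depths, dtype=float)
    hbin = np.floor(depths / bin_height).astype(int)
    pbin = np.floor(particles["depth_m"].to_numpy(dtype=float) / bin_height).astype(int)
    rows = []
    for k in np.unique(hbin):
        n = int((hbin == k).sum())
        p = int((pbin == k).sum())
        rows.append(
            {
                "depth_m": (k + 0.5) * bin_height,
                "count": p,
                "n_holograms": n,
                "pv_per_ml": p / (n * hologram_volume_ml),
            }
        )
    return pd.DataFrame(rows).sort_values("depth_m", ignore_index=True)


def concentration_by_aspect(
    particles: pd.DataFrame,
    bin_height: float = 0.2,
    r_edges: list | None = None,
) -> pd.DataFrame:
    """Depth distribution of each aspect-ratio class, as percentages.

    Particles are classed into (1,3], (3,6], (6,10], (10,inf) by aspect
    ratio; within each class, the count per depth bin is expressed as a
    percentage of the class total, so every class column sums to 100
    (classes with no particles yield an all-zero, flagged column).
    """
    if r_edges is None:
        r_edges = ASPECT_BIN_EDGES
    r = particles["aspect_ratio"].to_numpy(dtype=float)
    depth = particles["depth_m"].to_numpy(dtype=float)
    dbin = np.floor(depth / bin_height).astype(int)
    bins = sorted(np.unique(dbin))
    out = pd.DataFrame({"depth_m": [(k + 0.5) * bin_height for k in bins]})
    for lo, hi in zip(r_edges[:-1], r_edges[1:]):
        label = f"r_{lo:g}_{hi:g}" if np.isfinite(hi) else f"r_gt_{lo:g}"
        sel = (r > lo) & (r <= hi)
        total = int(sel.sum())
        col = np.array([((dbin == k) & sel).sum() for k in bins], dtype=float)
        out[label] = col / total * 100.0 if total else col
        out.attrs.setdefault("empty_classes", [])
        if total == 0:
            out.attrs["empty_classes"].append(label)
    return out


@dataclass(frozen=True)
class SizeDistribution:
    """Log-binned particle size distribution n(D) in L^-1 um^-1."""

    bin_edges_um: np.ndarray
    density: np.ndarray  # counts / (volume * bin width)
    counts: np.ndarray
    volume_l: float
    n_excluded: int  # particles outside the binned size range

    @property
    def bin_centers_um(self) -> np.ndarray:
        return np.sqrt(self.bin_edges_um[:-1] * self.bin_edges_um[1:])

    @property
    def bin_widths_um(self) -> np.ndarray:
        return np.diff(self.bin_edges_um)


def build_psd(
    diameters_um: np.ndarray,
    volume_sampled_l: float,
    n_bins: int = 24,
    d_range: tuple[float, float] = PSD_RANGE_UM,
) -> SizeDistribution:
    """Bin equivalent diameters into a logarithmic size spectrum.

    Counts per bin are nondimensionalised by the sampled volume and the
    bin width, giving the differential number density n(D); particles
    outside ``d_range`` are excluded and their count recorded.
    """
    if volume_sampled_l <= 0:
        raise ValueError("volume_sampled_l must be > 0")
    d = np.asarray(diameters_um, dtype=float)
    edges = np.logspace(np.log10(d_range[0]), np.log10(d_range[1]), n_bins + 1)
    inside = (d >= edges[0]) & (d <= edges[-1])
    counts, _ = np.histogram(d[inside], bins=edges)
    density = counts / (volume_sampled_l * np.diff(edges))
    return SizeDistribution(
        bin_edges_um=edges,
        density=density,
        counts=counts,
        volume_l=volume_sampled_l,
        n_excluded=int((~inside).sum()),
    )


@dataclass(frozen=True)
class JungeFit:
    """Fitted power-law segment n(D) = n0 (D/D0)^-gamma."""

    gamma: float
    n0: float
    d0_um: float
    size_range_um: tuple[float, float]
    n_bins_used: int


def fit_junge(
    psd: SizeDistribution, size_range_um: tuple[float, float] | None = None
) -> JungeFit | None:
    """Least-squares Junge slope over the occupied bins of a size range.

    Fits log10 n(D) against log10 D and returns the (positive) exponent
    gamma; requires at least 4 occupied bins, otherwise returns None
    (a no-fit outcome, not an error).  D0 is the geometric-mean diameter
    of the fitted bins.
    """
    centers = psd.bin_centers_um
    if size_range_um is None:
        size_range_um = (centers[0], centers[-1])
    sel = (centers >= size_range_um[0]) & (centers <= size_range_um[1]) & (psd.density > 0)
    if sel.sum() < 4:
        return None
    x = np.log10(centers[sel])
    y = np.log10(psd.density[sel])
    slope, intercept = np.polyfit(x, y, 1)
    d0 = 10 ** x.mean()
    return JungeFit(
        gamma=float(-slope),
        n0=float(10 ** (intercept + slope * np.log10(d0))),
        d0_um=float(d0),
        size_range_um=size_range_um,
        n_bins_used=int(sel.sum()),
    )


def fit_junge_segments(
    psd: SizeDistribution, knee_um: float = 250.0
) -> tuple[JungeFit | None, JungeFit | None]:
    """Two-segment Junge fit below and above a knee diameter.

    Natural spectra commonly show distinct slopes for small and large
    particles with a knee around 250 um; both segments are fitted
    independently over the occupied bins on each side.
    """
    lo = fit_junge(psd, (psd.bin_edges_um[0], knee_um))
    hi = fit_junge(psd, (knee_um, psd.bin_edges_um[-1]))
    return lo, hi


def orientation_pdf(
    particles: pd.DataFrame,
    depth_bin_height: float = 1.0,
    r_min: float = 3.0,
    low_count_threshold: int = 30,
) -> pd.DataFrame:
    """Depth-resolved orientation PDFs over nine 20-degree angle bins.

    Only particles with aspect ratio above ``r_min`` are used, since
    near-round particles carry no meaningful orientation.  Each depth
    bin's histogram is normalised to a density per degree (sum of
    pdf x 20 = 1); bins with fewer than ``low_count_threshold`` particles
    are flagged, because a handful of particles can fabricate spurious
    orientation peaks.
    """
    sel = particles["aspect_ratio"].to_numpy(dtype=float) > r_min
    theta = particles["theta_deg"].to_numpy(dtype=float)[sel]
    depth = particles["depth_m"].to_numpy(dtype=float)[sel]
    # (-90, 90]: fold the closed left edge into the top bin
    theta = np.where(theta <= -90.0, theta + 180.0, theta)
    dbin = np.floor(depth / depth_bin_height).astype(int)
    centers = 0.5 * (ANGLE_BIN_EDGES[:-1] + ANGLE_BIN_EDGES[1:])
    rows = []
    for k in np.unique(dbin):
        th = theta[dbin == k]
        counts, _ = np.histogram(th, bins=ANGLE_BIN_EDGES)
        total = counts.sum()
        pdf = counts / total / 20.0 if total else np.zeros_like(counts, dtype=float)
        for c, cnt, p in zip(centers, counts, pdf):
            rows.append(
                {
                    "depth_bin_m": (k + 0.5) * depth_bin_height,
                    "angle_bin_center_deg": c,
                    "pdf_per_deg": p,
                    "count": int(cnt),
                    "low_count_flag": bool(total < low_count_threshold),
                }
            )
    return pd.DataFrame(rows)
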