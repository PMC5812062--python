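"""Turbulence and stratification diagnostics from point velocity and density.

A single-point velocimeter cannot resolve spatial spectra directly, so the
dissipation rate is estimated by fitting the -5/3 inertial subrange of the
velocity *frequency* spectrum and mapping frequency to wavenumber with
Taylor's frozen-turbulence hypothesis, kappa = 2 pi f / U.  The spectrum
level convention is S(f) = C eps^(2/3) kappa(f)^(-5/3), whose exact
algebraic inversion is

    eps = [S(f) f^(5/3) / C]^(3/2) (2 pi / U)^(5/2)

with C = 0.65 for the vertical component (0.49 horizontal).  The same
module provides the Kolmogorov and Batchelor microscales, shear profiles,
the squared buoyancy frequency, the gradient Richardson number and the
descent-platform Reynolds number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "SpectrumFit",
    "PlatformConfig",
    "bin_series_by_depth",
    "estimate_spectrum",
    "fit_epsilon",
    "kolmogorov_scale",
    "batchelor_scale",
    "shear_profile",
    "richardson",
    "platform_reynolds",
]

MIN_SPECTRUM_SAMPLES = 256  # minimum points for a usable dissipation spectrum


@dataclass(frozen=True)
class SpectrumFit:
    """Result of an inertial-subrange dissipation fit.

    ``epsilon`` is None when the fit was rejected because the log-log
    slope over the fit band deviated from -5/3 beyond tolerance.
    """

    frequencies: np.ndarray
    spectral_density: np.ndarray
    mean_speed: float
    constant: float
    fit_band: tuple[float, float]
    epsilon: float | None
    local_slope: float
    depth_bin: float | None = None

    @property
    def rejected(self) -> bool:
        return self.epsilon is None


@dataclass(frozen=True)
class PlatformConfig:
    """Descent geometry of the profiling platform."""

    descent_rate: float = 0.05  # m/s
    tower_diameter: float = 0.2  # m
    nu: float = 1.1e-6  # kinematic viscosity of seawater, m^2/s

    def __post_init__(self) -> None:
        if min(self.descent_rate, self.tower_diameter, self.nu) <= 0:
            raise ValueError("all platform parameters must be > 0")


def bin_series_by_depth(
    series: pd.DataFrame, bin_height: float = 3.0, depth_col: str = "depth_m"
) -> list[dict]:
    """Split a depth-tagged series into contiguous depth bins.

    Returns one dict per occupied bin with keys ``depth_bin`` (bin centre,
    m), ``data`` (the rows), and ``usable`` (False when the bin holds
    fewer than 256 samples, too short for a spectrum).
    """
    if depth_col not in series:
        raise ValueError(f"series must carry a {depth_col!r} column")
    idx = np.floor(series[depth_col].to_numpy(dtype=float) / bin_height).astype(int)
    out = []
    for k in np.unique(idx):
        rows = series.loc[idx == k]
        out.append(
            {
                "depth_bin": (k + 0.5) * bin_height,
                "data": rows,
                "usable": len(rows) >= MIN_SPECTRUM_SAMPLES,
            }
        )
    return out


def estimate_spectrum(w: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided velocity spectral density by Welch's method.

    Hann-windowed 256-sample segments with 50% overlap; the zero-frequency
    bin is dropped.  The density convention satisfies Parseval: the
    integral of S(f) over f approximates the series variance.
    """
    w = np.asarray(w, dtype=float)
    if w.size < MIN_SPECTRUM_SAMPLES:
        raise ValueError(
            f"need at least {MIN_SPECTRUM_SAMPLES} samples for a spectrum, got {w.size}"
        )
    f, s = signal.welch(
        w, fs=fs, window="hann", nperseg=MIN_SPECTRUM_SAMPLES, noverlap=MIN_SPECTRUM_SAMPLES // 2,
        detrend="constant", scaling="density",
    )
    return f[1:], s[1:]


def default_fit_band(f: np.ndarray) -> tuple[float, float]:
    """Default inertial-subrange band: upper 40% of frequencies below Nyquist/1.5.

    The subrange sits at the high-frequency end of the resolved spectrum;
    the top of the band stays clear of the Nyquist roll-off.
    """
    f_hi = f.max() / 1.5
    return (0.6 * f_hi, f_hi)


def fit_epsilon(
    f: np.ndarray,
    s: np.ndarray,
    mean_speed: float,
    constant: float = 0.65,
    band: tuple[float, float] | None = None,
    slope_tolerance: float = 0.3,
    depth_bin: float | None = None,
) -> SpectrumFit:
    """Dissipation rate from an inertial-subrange fit.

    Per-frequency estimates eps(f) = [S f^(5/3)/C]^(3/2) (2 pi/U)^(5/2) are
    averaged over the fit band.  The fit is rejected (epsilon None) when
    the band's log-log slope deviates from -5/3 by more than
    ``slope_tolerance``, e.g. for white noise or motion-contaminated bins.
    """
    f = np.asarray(f, dtype=float)
    s = np.asarray(s, dtype=float)
    if mean_speed <= 0:
        raise ValueError("mean_speed must be > 0")
    if band is None:
        band = default_fit_band(f)
    lo, hi = band
    sel = (f >= lo) & (f <= hi) & (s > 0)
    if sel.sum() < 3:
        raise ValueError("fit band contains fewer than 3 usable spectral points")
    fb, sb = f[sel], s[sel]
    slope = float(np.polyfit(np.log10(fb), np.log10(sb), 1)[0])
    if abs(slope + 5.0 / 3.0) > slope_tolerance:
        eps = None
    else:
        per_f = (sb * fb ** (5.0 / 3.0) / constant) ** 1.5 * (2 * np.pi / mean_speed) ** 2.5
        eps = float(per_f.mean())
    return SpectrumFit(
        frequencies=f,
        spectral_density=s,
        mean_speed=mean_speed,
        constant=constant,
        fit_band=(lo, hi),
        epsilon=eps,
        local_slope=slope,
        depth_bin=depth_bin,
    )


def kolmogorov_scale(epsilon: float, nu: float = 1.1e-6) -> float:
    """Kolmogorov length eta = (nu^3 / eps)^(1/4), the smallest eddy scale (m)."""
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    return (nu**3 / epsilon) ** 0.25


def batchelor_scale(epsilon: float, nu: float = 1.1e-6, diffusivity: float = 1e-9) -> float:
    """Batchelor length (nu D^2 / eps)^(1/4), where diffusion balances turbulence (m)."""
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    return (nu * diffusivity**2 / epsilon) ** 0.25


def shear_profile(depth_bins: np.ndarray, u_mean: np.ndarray, v_mean: np.ndarray) -> pd.DataFrame:
    """Vertical gradients of bin-mean horizontal velocities.

    Centred finite differences over the depth-bin centres (one-sided at the
    ends) give du/dz and dv/dz and the squared total shear S^2.
    """
    depth_bins = np.asarray(depth_bins, dtype=float)
    if depth_bins.size < 2:
        raise ValueError("shear profile needs at least 2 depth bins")
    dudz = np.gradient(np.asarray(u_mean, dtype=float), depth_bins)
    dvdz = np.gradient(np.asarray(v_mean, dtype=float), depth_bins)
    return pd.DataFrame(
        {"depth_m": depth_bins, "dudz": dudz, "dvdz": dvdz, "s2": dudz**2 + dvdz**2}
    )


def richardson(n2: np.ndarray, s2: np.ndarray) -> pd.DataFrame:
    """Gradient Richardson number Ri = N^2 / S^2 on aligned depth bins.

    Bins with zero shear are flagged undefined; ``stable`` marks Ri >= 0.25,
    the linear-stability criterion for stratified shear flow.
    """
    n2 = np.asarray(n2, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if n2.shape != s2.shape:
        raise ValueError("N^2 and S^2 must be on aligned depth bins")
    undefined = s2 == 0
    ri = np.divide(n2, s2, out=np.full_like(n2, np.nan), where=~undefined)
    return pd.DataFrame(
        {"ri": ri, "undefined": undefined, "stable": ~undefined & (ri >= 0.25)}
    )


def platform_reynolds(cfg: PlatformConfig) -> float:
    """Reynolds number Re = w D_H / nu of the descending instrument tower."""
    return cfg.descent_rate * cfg.tower_diameter / cfg.nu
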