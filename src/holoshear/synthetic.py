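"""Ground-truthed synthetic scenes, holograms, velocity and density series.

Every downstream stage of the pipeline (reconstruction, segmentation,
morphometry, spectral dissipation fits, orientation statistics) is exercised
against data produced here, where the truth is known exactly: particle
positions, sizes and 3D orientations; the dissipation rate behind a
synthesised inertial subrange; the buoyancy frequency of a two-layer
density profile.

Conventions
-----------
Image arrays are indexed ``[y, x]`` with the y index increasing upward, so
the origin sits at the bottom-left corner and a particle whose major axis
has positive slope carries a positive orientation angle.  The optical axis
is z, measured from the sensor-side sampling window into the volume.  The
polar angle ``theta_p`` is measured from the vertical (y) axis; the azimuth
``theta_a`` rotates about y, with 0 in the image plane and 90 deg pointing
along the optical axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .optics import OpticalConfig, propagate

__all__ = [
    "SyntheticParticle",
    "SceneConfig",
    "FlowSynthConfig",
    "UndefinedProjectionError",
    "project_to_2d",
    "sample_junge_diameters",
    "draw_orientation",
    "make_scene",
    "render_hologram",
    "synth_velocity",
    "model_velocity_spectrum",
    "synth_density",
    "brunt_vaisala_profile",
]


class UndefinedProjectionError(ValueError):
    """Raised when a 3D line projects to a point (no in-plane angle exists)."""


def project_to_2d(theta_p: float, theta_a: float) -> float:
    """Project a 3D line orientation onto the image plane.

    A line at polar angle ``theta_p`` (deg, from vertical, in (0, 180)) and
    azimuth ``theta_a`` (deg, in [0, 180), 0 = in-plane) appears in the
    image at ``theta = atan(cot(theta_p) / cos(theta_a))``, mapped to
    (-90, +90] with 0 horizontal.

    Raises
    ------
    UndefinedProjectionError
        When ``theta_a`` is 90 deg but ``theta_p`` is not: the line points
        straight down the optical axis and has no projected direction.
    """
    if not 0 < theta_p < 180:
        raise ValueError("theta_p must lie in (0, 180) degrees")
    if not 0 <= theta_a < 180:
        raise ValueError("theta_a must lie in [0, 180) degrees")
    tp = math.radians(theta_p)
    ta = math.radians(theta_a)
    if abs(math.cos(ta)) < 1e-12:
        if abs(theta_p - 90.0) < 1e-9:
            return 0.0  # horizontal line seen end-on along the optical axis
        raise UndefinedProjectionError(
            f"orientation (theta_p={theta_p}, theta_a={theta_a}) projects to a point"
        )
    theta = math.degrees(math.atan2(1.0 / math.tan(tp), math.cos(ta)))
    return wrap_angle(theta)


def wrap_angle(theta: float | np.ndarray) -> float | np.ndarray:
    """Map an angle in degrees to the interval (-90, +90]."""
    w = -((-np.asarray(theta) + 90.0) % 180.0 - 90.0)
    return float(w) if np.isscalar(theta) or np.ndim(theta) == 0 else w


@dataclass(frozen=True)
class SyntheticParticle:
    """One opaque spheroid (or diatom-like chain) in the sample volume."""

    center_xyz: tuple[float, float, float]  # m; (x, y) in-plane, z along optical axis
    major_len: float  # m
    minor_len: float  # m
    theta_p: float  # deg, polar angle from vertical, (0, 180)
    theta_a: float  # deg, azimuth, [0, 180)
    shape: str = "spheroid"  # "spheroid" | "chain"
    n_cells: int = 1
    cell_gap: float = 0.0  # m, inter-cell gap along the major axis

    def __post_init__(self) -> None:
        if not self.major_len >= self.minor_len > 0:
            raise ValueError("require major_len >= minor_len > 0")
        if self.shape not in ("spheroid", "chain"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.shape == "chain" and self.n_cells < 2:
            raise ValueError("a chain needs at least 2 cells")

    @property
    def aspect_ratio(self) -> float:
        return self.major_len / self.minor_len

    @property
    def equiv_diameter(self) -> float:
        """Diameter of the circle with the same projected area (m)."""
        return math.sqrt(self.major_len * self.minor_len)

    def projected(self) -> tuple[float, float]:
        """(projected major length in m, projected angle in deg)."""
        tp = math.radians(self.theta_p)
        ta = math.radians(self.theta_a)
        factor = math.hypot(math.sin(tp) * math.cos(ta), math.cos(tp))
        length = max(self.major_len * factor, self.minor_len)
        if factor < 1e-9:
            return length, 0.0  # end-on: circular silhouette, angle arbitrary
        try:
            angle = project_to_2d(self.theta_p, self.theta_a)
        except UndefinedProjectionError:
            angle = 90.0  # limiting value: projection collapses toward vertical
        return length, angle


@dataclass(frozen=True)
class SceneConfig:
    """Statistical description of a particle population in one volume.

    ``orientation_model`` is one of ``("uniform3d",)``,
    ``("fixed", theta_p, theta_a)`` or ``("jeffery", shear, aspect)``; the
    Jeffery model draws in-plane angles from the laminar-shear occupancy
    distribution, the study's default comparison case.
    """

    concentration: float = 20.0  # particles per mL
    junge_gamma: float = 1.8  # PSD power-law exponent (positive)
    size_range: tuple[float, float] = (30e-6, 300e-6)  # equivalent diameter, m
    aspect_range: tuple[float, float] = (2.0, 8.0)  # log-uniform aspect ratios
    orientation_model: tuple = ("uniform3d",)
    chain_fraction: float = 0.0
    chain_gap: float = 7e-6  # m, ~1.5 px at the default magnification
    seed: int = 0

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")
        if self.junge_gamma <= 0:
            raise ValueError("junge_gamma must be > 0")
        if not self.size_range[0] < self.size_range[1]:
            raise ValueError("size_range must be increasing")


def sample_junge_diameters(
    rng: np.random.Generator, n: int, gamma: float, d_range: tuple[float, float]
) -> np.ndarray:
    """Draw diameters from a power-law (Junge) density ~ D**-gamma.

    Inverse-CDF sampling of the truncated Pareto-type law on ``d_range``;
    the ``gamma == 1`` case is the logarithmic limit.
    """
    lo, hi = d_range
    u = rng.random(n)
    if abs(gamma - 1.0) < 1e-12:
        return lo * (hi / lo) ** u
    a = 1.0 - gamma
    return (lo**a + u * (hi**a - lo**a)) ** (1.0 / a)


def jeffery_angle_quantile(u: np.ndarray, r: float) -> np.ndarray:
    """Inverse CDF of the Jeffery in-plane occupancy law on (-90, 90]."""
    return np.degrees(np.arctan(np.tan(np.pi * (np.asarray(u) - 0.5)) / r))


def draw_orientation(rng: np.random.Generator, model: tuple, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` (theta_p, theta_a) pairs in degrees from an orientation model."""
    kind = model[0]
    if kind == "uniform3d":
        # both angles uniform: this is the conventional "random orientation"
        # assumption for projection-bias arguments; it oversamples near-polar
        # directions relative to a truly isotropic axis distribution, and its
        # 2D projection piles up toward +-90 deg
        theta_p = rng.uniform(0.0, 180.0, n)
        theta_a = rng.uniform(0.0, 180.0, n)
        return theta_p, theta_a
    if kind == "isotropic":
        # directions uniform on the sphere; projects to a uniform 2D angle
        cos_tp = rng.uniform(-1.0, 1.0, n)
        theta_p = np.degrees(np.arccos(cos_tp))
        theta_a = rng.uniform(0.0, 180.0, n)
        return theta_p, theta_a
    if kind == "fixed":
        _, tp, ta = model
        return np.full(n, float(tp)), np.full(n, float(ta))
    if kind == "jeffery":
        _, _, r = model
        theta = jeffery_angle_quantile(rng.random(n), float(r))
        return 90.0 - theta, np.zeros(n)  # in-plane orientations
    raise ValueError(f"unknown orientation model {model!r}")


def make_scene(cfg: SceneConfig, volume: OpticalConfig) -> list[SyntheticParticle]:
    """Generate one Poisson scene of particles fully inside the volume.

    The particle count is Poisson with mean ``concentration x volume``;
    diameters follow the Junge law; orientations follow
    ``cfg.orientation_model``.  Particles that cannot fit inside the usable
    volume are skipped, and a volume too small for any particle yields an
    empty scene rather than an error.
    """
    rng = np.random.default_rng(cfg.seed)
    height, width = volume.fov
    n = rng.poisson(cfg.concentration * volume.sample_volume_ml)
    if n == 0:
        return []
    diam = sample_junge_diameters(rng, n, cfg.junge_gamma, cfg.size_range)
    la, lb = np.log(cfg.aspect_range[0]), np.log(cfg.aspect_range[1])
    aspect = np.exp(rng.uniform(la, lb, n))
    theta_p, theta_a = draw_orientation(rng, cfg.orientation_model, n)
    is_chain = rng.random(n) < cfg.chain_fraction

    z_lo = volume.window_margin + volume.z_step
    z_hi = volume.path_length - volume.window_margin - volume.z_step
    particles: list[SyntheticParticle] = []
    for i in range(n):
        major = diam[i] * math.sqrt(aspect[i])
        minor = diam[i] / math.sqrt(aspect[i])
        margin = major / 2 + 2 * volume.pixel_pitch
        if 2 * margin >= min(height, width) or z_lo >= z_hi:
            continue  # volume cannot hold this particle
        x = rng.uniform(margin, width - margin)
        y = rng.uniform(margin, height - margin)
        z = rng.uniform(z_lo, z_hi)
        shape, cells, gap = "spheroid", 1, 0.0
        # colonial chains are the large elongated particles; small cells
        # would be unresolvable at the default magnification
        if is_chain[i] and aspect[i] > 3 and major >= 150e-6:
            cells = int(rng.integers(3, 8))
            gap = cfg.chain_gap
            shape = "chain"
        particles.append(
            SyntheticParticle(
                center_xyz=(x, y, z),
                major_len=major,
                minor_len=minor,
                theta_p=float(theta_p[i]),
                theta_a=float(theta_a[i]),
                shape=shape,
                n_cells=cells,
                cell_gap=gap,
            )
        )
    return particles


def _paint_ellipse(
    mask: np.ndarray,
    cx_px: float,
    cy_px: float,
    a_px: float,
    b_px: float,
    angle_deg: float,
) -> None:
    """Set pixels inside a rotated ellipse (axes in px) to True, in place."""
    ny, nx = mask.shape
    a_px, b_px = max(a_px, 0.5), max(b_px, 0.5)
    ext = max(a_px, b_px) + 2
    x0, x1 = int(max(0, cx_px - ext)), int(min(nx, cx_px + ext + 1))
    y0, y1 = int(max(0, cy_px - ext)), int(min(ny, cy_px + ext + 1))
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx = xx - cx_px
    dy = yy - cy_px
    t = math.radians(angle_deg)
    u = dx * math.cos(t) + dy * math.sin(t)
    v = -dx * math.sin(t) + dy * math.cos(t)
    inside = (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0
    mask[y0:y1, x0:x1] |= inside


def particle_silhouette(p: SyntheticParticle, optics: OpticalConfig) -> np.ndarray:
    """Opaque amplitude mask (True = blocked) of one particle at its plane."""
    ny, nx = optics.sensor_px
    pitch = optics.pixel_pitch
    mask = np.zeros((ny, nx), dtype=bool)
    proj_len, angle = p.projected()
    cx, cy = p.center_xyz[0] / pitch, p.center_xyz[1] / pitch
    b = p.minor_len / (2 * pitch)
    if p.shape == "spheroid":
        _paint_ellipse(mask, cx, cy, proj_len / (2 * pitch), b, angle)
        return mask
    # chain: collinear cells along the projected major axis
    factor = proj_len / p.major_len
    cell_len = (p.major_len - (p.n_cells - 1) * p.cell_gap) / p.n_cells
    step = (cell_len + p.cell_gap) * factor / pitch
    t = math.radians(angle)
    ux, uy = math.cos(t), math.sin(t)
    start = -(p.n_cells - 1) / 2
    for k in range(p.n_cells):
        off = (start + k) * step
        _paint_ellipse(mask, cx + off * ux, cy + off * uy, cell_len * factor / (2 * pitch), b, angle)
    return mask


def render_hologram(
    scene: list[SyntheticParticle],
    optics: OpticalConfig,
    noise_sd: float = 0.0,
    seed: int | None = None,
    vignette: np.ndarray | None = None,
) -> np.ndarray:
    """Render an in-line hologram of opaque particles.

    A unit plane wave enters at the far window; at each particle plane the
    silhouette blocks the field, which is then propagated onward by the
    angular-spectrum kernel; the sensor records intensity.  Additive
    Gaussian sensor noise and an optional multiplicative vignette (to
    exercise background subtraction) are applied before normalisation of
    the frame to [0, 1].
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    ny, nx = optics.sensor_px
    max_px = min(ny, nx) * optics.pixel_pitch
    for i, p in enumerate(scene):
        if p.projected()[0] >= max_px:
            raise ValueError(f"particle {i} silhouette larger than the sensor")
    field = np.ones((ny, nx), dtype=complex)
    order = sorted(range(len(scene)), key=lambda i: -scene[i].center_xyz[2])
    z_prev: float | None = None
    for i in order:
        z = scene[i].center_xyz[2]
        if z_prev is not None and z_prev - z > 1e-12:
            field = propagate(field, z_prev - z, optics)
        field[particle_silhouette(scene[i], optics)] = 0.0
        z_prev = z
    if z_prev is not None and z_prev > 0:
        field = propagate(field, z_prev, optics)
    intensity = np.abs(field) ** 2
    if vignette is not None:
        intensity = intensity * vignette
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sd, intensity.shape)
    peak = intensity.max()
    if peak > 0:
        intensity = intensity / peak
    return np.clip(intensity, 0.0, 1.0)


@dataclass(frozen=True)
class FlowSynthConfig:
    """Parameters of a synthesised inertial-subrange velocity series."""

    epsilon_true: float = 1e-7  # TKE dissipation rate, m^2 s^-3
    mean_speed: float = 0.05  # advection speed U for the frozen-turbulence mapping, m/s
    sample_rate: float = 16.0  # Hz
    duration: float = 60.0  # s
    spectral_constant: float = 0.65  # 0.65 vertical, 0.49 horizontal
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epsilon_true <= 0 or self.mean_speed <= 0 or self.sample_rate <= 0:
            raise ValueError("epsilon_true, mean_speed and sample_rate must be > 0")
        if self.spectral_constant not in (0.49, 0.65):
            raise ValueError("spectral_constant must be 0.49 (horizontal) or 0.65 (vertical)")


def model_velocity_spectrum(
    f: np.ndarray, epsilon: float, mean_speed: float, constant: float = 0.65
) -> np.ndarray:
    """Inertial-subrange frequency spectrum C eps^(2/3) kappa^(-5/3).

    Frequency maps to wavenumber through the frozen-turbulence relation
    kappa = 2 pi f / U; the spectrum level is quoted at the mapped
    wavenumber, which is the convention the dissipation fit inverts.
    """
    kappa = 2 * np.pi * np.asarray(f, dtype=float) / mean_speed
    return constant * epsilon ** (2.0 / 3.0) * kappa ** (-5.0 / 3.0)


def synth_velocity(cfg: FlowSynthConfig) -> np.ndarray:
    """Synthesise a velocity series with a -5/3 inertial subrange.

    Fourier modes carry amplitudes set by the model spectrum and uniformly
    random phases; the one-sided spectral density of the output therefore
    matches ``model_velocity_spectrum`` across the whole synthesised band.
    Requires at least 256 samples, the minimum for a usable spectrum.
    """
    n = int(round(cfg.duration * cfg.sample_rate))
    if n < 256:
        raise ValueError(
            f"duration x sample_rate = {n} < 256 samples: too short for a spectrum"
        )
    rng = np.random.default_rng(cfg.seed)
    f = np.fft.rfftfreq(n, d=1.0 / cfg.sample_rate)
    amp = np.zeros_like(f)
    psd = model_velocity_spectrum(f[1:], cfg.epsilon_true, cfg.mean_speed, cfg.spectral_constant)
    # one-sided density S(f) = 2 |X|^2 / (fs n)  =>  |X| = sqrt(S fs n / 2)
    amp[1:] = np.sqrt(psd * cfg.sample_rate * n / 2.0)
    if n % 2 == 0:
        amp[-1] = 0.0  # leave the Nyquist bin empty
    phase = rng.uniform(0.0, 2 * np.pi, f.size)
    spectrum = amp * np.exp(1j * phase)
    spectrum[0] = 0.0
    return np.fft.irfft(spectrum, n)


def synth_density(
    surface_sigma: float,
    deep_sigma: float,
    pycnocline_top: float,
    pycnocline_bottom: float,
    dz: float = 0.05,
    max_depth: float | None = None,
) -> pd.DataFrame:
    """Two-layer density-anomaly profile with a linear pycnocline ramp.

    Returns columns ``depth_m`` (positive down) and ``sigma_t`` (kg/m^3):
    constant above ``pycnocline_top``, a linear ramp to
    ``pycnocline_bottom``, constant below.  Statically unstable inputs
    (``deep_sigma < surface_sigma``) are rejected.
    """
    if deep_sigma < surface_sigma:
        raise ValueError("deep_sigma must be >= surface_sigma (stable stratification)")
    if not 0 < pycnocline_top < pycnocline_bottom:
        raise ValueError("require 0 < pycnocline_top < pycnocline_bottom")
    if max_depth is None:
        max_depth = pycnocline_bottom * 2
    depth = np.arange(0.0, max_depth + dz / 2, dz)
    sigma = np.interp(
        depth,
        [0.0, pycnocline_top, pycnocline_bottom, max_depth],
        [surface_sigma, surface_sigma, deep_sigma, deep_sigma],
    )
    return pd.DataFrame({"depth_m": depth, "sigma_t": sigma})


def brunt_vaisala_profile(
    density: pd.DataFrame, g: float = 9.81, rho0: float = 1025.0
) -> pd.DataFrame:
    """Squared buoyancy frequency N^2 from a density-anomaly profile.

    N^2 = -(g/rho0) d(rho)/dz with z positive upward; with depth positive
    downward this is +(g/rho0) d(sigma_t)/d(depth), evaluated by centred
    differences (one-sided at the ends).
    """
    depth = density["depth_m"].to_numpy(dtype=float)
    sigma = density["sigma_t"].to_numpy(dtype=float)
    n2 = (g / rho0) * np.gradient(sigma, depth)
    return pd.DataFrame({"depth_m": depth, "n2": n2})
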