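"""Optical configuration and scalar diffraction propagation.

The imaging model is collimated in-line holography: a plane wave crosses a
sample path, particles block part of the beam, and the sensor records the
interference between the undisturbed beam and the light diffracted by the
particles.  Numerical refocusing uses the angular-spectrum propagator, the
exact scalar solution of the Helmholtz equation for a homogeneous medium; it
reduces to Fresnel propagation in the paraxial regime and stays valid over
the whole sample path.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = ["OpticalConfig", "propagate"]


@dataclass(frozen=True)
class OpticalConfig:
    """Geometry and wavelength of the in-line holographic channel.

    Defaults describe a 660 nm collimated beam imaged at 4.59 um/pixel on a
    2048 x 2048 sensor across a 4 cm sample path, refocused in 500 um steps
    with 2.5 mm exclusion margins at both sampling windows.
    """

    wavelength: float = 660e-9
    pixel_pitch: float = 4.59e-6
    sensor_px: tuple[int, int] = (2048, 2048)
    path_length: float = 0.04
    z_step: float = 500e-6
    window_margin: float = 2.5e-3

    def __post_init__(self) -> None:
        for name in ("wavelength", "pixel_pitch", "path_length", "z_step", "window_margin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        ny, nx = self.sensor_px
        if ny < 64 or nx < 64:
            raise ValueError("sensor must be at least 64 px in each dimension")
        if self.z_step >= self.path_length:
            raise ValueError("z_step must be smaller than path_length")
        if 2 * self.window_margin >= self.path_length:
            raise ValueError("window margins leave no usable path")

    @property
    def usable_path(self) -> float:
        """Sample path minus the two window-boundary exclusion margins."""
        return self.path_length - 2 * self.window_margin

    @property
    def n_planes(self) -> int:
        """Number of retained reconstruction planes."""
        ratio = self.usable_path / self.z_step
        n = round(ratio)
        if abs(ratio - n) > 1e-6:
            raise ValueError(
                "z_step does not divide the usable path "
                f"({self.usable_path:.6g} m / {self.z_step:.6g} m = {ratio:.6g}); "
                "adjust z_step, path_length or window_margin"
            )
        return int(n)

    def plane_offsets(self) -> np.ndarray:
        """Depths (m, from the sensor-side window) of the retained planes.

        Planes are the centres of the z_step intervals tiling the usable
        path, so none falls inside a window margin.
        """
        n = self.n_planes
        return self.window_margin + (np.arange(n) + 0.5) * self.z_step

    @property
    def fov(self) -> tuple[float, float]:
        """Field of view (m) as (height, width)."""
        ny, nx = self.sensor_px
        return (ny * self.pixel_pitch, nx * self.pixel_pitch)

    @property
    def sample_volume_ml(self) -> float:
        """Volume imaged by one hologram, in millilitres."""
        h, w = self.fov
        return h * w * self.path_length * 1e6


@lru_cache(maxsize=64)
def _kz_grid(shape: tuple[int, int], pitch: float, wavelength: float) -> np.ndarray:
    """Axial wavenumber k_z for each spatial frequency; evanescent set to 0."""
    ny, nx = shape
    fy = np.fft.fftfreq(ny, d=pitch)
    fx = np.fft.fftfreq(nx, d=pitch)
    fy2 = (wavelength * fy[:, None]) ** 2
    fx2 = (wavelength * fx[None, :]) ** 2
    arg = 1.0 - fy2 - fx2
    np.clip(arg, 0.0, None, out=arg)
    return (2 * np.pi / wavelength) * np.sqrt(arg)


def propagate(field: np.ndarray, dz: float, optics: OpticalConfig) -> np.ndarray:
    """Angular-spectrum propagation of a complex field by a signed distance.

    Positive ``dz`` propagates toward the sensor; negative ``dz``
    back-propagates (numerical refocusing).  The transfer function is
    unitary on propagating modes, so a forward step followed by the equal
    backward step restores the field to numerical precision.
    """
    field = np.asarray(field)
    if field.ndim != 2:
        raise ValueError("field must be a 2D array")
    kz = _kz_grid(field.shape, optics.pixel_pitch, optics.wavelength)
    kernel = np.exp(1j * kz * dz)
    return np.fft.ifft2(np.fft.fft2(field) * kernel)
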