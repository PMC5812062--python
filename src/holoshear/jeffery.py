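"""Jeffery-orbit dynamics of a spheroid in constant laminar shear.

A rigid spheroid of aspect ratio r in a simple shear S tumbles periodically
with in-plane angular velocity

    omega(theta) = S / (r^2 + 1) * (r^2 sin^2 theta + cos^2 theta)

minimal when flow-aligned (theta = 0) and maximal at theta = +-90 deg, so
elongated particles dwell near the flow direction.  One full rotation takes
T = (2 pi / S)(r + 1/r).  The occupancy-time distribution of theta over a
period — the model orientation PDF compared against measured histograms —
is proportional to 1/omega(theta) and is independent of both S and the
initial orientation.

Assumptions inherited from the model (not checked at runtime): rotational
Peclet number >> 1, negligible particle inertia and interactions, particle
Reynolds number << 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "JefferyParams",
    "ANGLE_BIN_EDGES",
    "angular_velocity",
    "rotation_period",
    "integrate_orbit",
    "model_pdf",
    "analytic_bin_probabilities",
]

# nine 20-degree orientation bins spanning (-90, +90]
ANGLE_BIN_EDGES = np.arange(-90.0, 91.0, 20.0)


@dataclass(frozen=True)
class JefferyParams:
    """Shear, particle aspect ratio and integration resolution."""

    shear: float = 0.1  # s^-1, representative oceanic value
    aspect_ratio: float = 1.0
    theta0: float = 0.0  # deg; initial orientation assumed horizontal
    n_steps: int = 10000

    def __post_init__(self) -> None:
        if self.shear <= 0:
            raise ValueError("shear must be > 0")
        if self.aspect_ratio < 1:
            raise ValueError("aspect_ratio must be >= 1")
        if self.n_steps < 100:
            raise ValueError("n_steps must be >= 100")


def angular_velocity(theta_deg, shear: float, aspect_ratio: float):
    """Instantaneous rotation rate omega(theta) in s^-1 (theta in degrees)."""
    if shear <= 0 or aspect_ratio < 1:
        raise ValueError("require shear > 0 and aspect_ratio >= 1")
    t = np.radians(theta_deg)
    r2 = aspect_ratio**2
    return shear / (r2 + 1.0) * (r2 * np.sin(t) ** 2 + np.cos(t) ** 2)


def rotation_period(shear: float, aspect_ratio: float) -> float:
    """Period T = (2 pi / S)(r + 1/r) of one full rotation (s)."""
    if shear <= 0 or aspect_ratio < 1:
        raise ValueError("require shear > 0 and aspect_ratio >= 1")
    return 2 * np.pi / shear * (aspect_ratio + 1.0 / aspect_ratio)


def integrate_orbit(p: JefferyParams) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-step RK4 integration of d(theta)/dt = omega(theta) over one period.

    Returns (t, theta_deg) with theta unwrapped and monotone increasing:
    one period is one complete rotation, theta(T) = theta0 + 360.  The
    step dt = T / n_steps resolves the fast flips; a coarser step than
    T/1000 is refused.
    """
    T = rotation_period(p.shear, p.aspect_ratio)
    dt = T / p.n_steps
    if dt > T / 1000.0:
        raise ValueError("n_steps too small: dt must not exceed T/1000")
    t = np.arange(p.n_steps + 1) * dt
    theta = np.empty(p.n_steps + 1)
    theta[0] = p.theta0
    for i in range(p.n_steps):
        y = theta[i]
        k1 = angular_velocity(y, p.shear, p.aspect_ratio)
        k2 = angular_velocity(y + np.degrees(0.5 * dt * k1), p.shear, p.aspect_ratio)
        k3 = angular_velocity(y + np.degrees(0.5 * dt * k2), p.shear, p.aspect_ratio)
        k4 = angular_velocity(y + np.degrees(dt * k3), p.shear, p.aspect_ratio)
        theta[i + 1] = y + np.degrees(dt * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0)
    return t, theta


def model_pdf(
    aspect_ratio: float, shear: float = 0.1, n_steps: int = 10000, theta0: float = 0.0
) -> np.ndarray:
    """Occupancy-time orientation PDF over nine 20-degree bins (per degree).

    The orbit is integrated over exactly one rotation period and the time
    spent in each angle bin is accumulated, distributing each integration
    step across bin boundaries by linear interpolation (theta is monotone,
    so this is exact to second order in dt).  The result depends only on
    the aspect ratio: shear rescales time uniformly and the starting angle
    only shifts the (periodic) trajectory.
    """
    p = JefferyParams(shear=shear, aspect_ratio=aspect_ratio, theta0=theta0, n_steps=n_steps)
    t, theta = integrate_orbit(p)
    T = t[-1]
    occupancy = np.zeros(len(ANGLE_BIN_EDGES) - 1)
    # map the unwrapped angle onto (-90, 90] via periodic images of the bin grid
    for i in range(len(theta) - 1):
        a, b = theta[i], theta[i + 1]
        dt = t[i + 1] - t[i]
        # boundaries crossed within [a, b): grid points -90 + 20k
        k0 = int(np.ceil((a + 90.0) / 20.0))
        k1 = int(np.ceil((b + 90.0) / 20.0))
        cuts = [a] + [-90.0 + 20.0 * k for k in range(k0, k1)] + [b]
        for j in range(len(cuts) - 1):
            mid = 0.5 * (cuts[j] + cuts[j + 1])
            idx = int(np.floor((mid + 90.0) / 20.0)) % 9
            occupancy[idx] += dt * (cuts[j + 1] - cuts[j]) / (b - a)
    pdf = occupancy / T / 20.0  # density per degree
    return pdf


def analytic_bin_probabilities(aspect_ratio: float) -> np.ndarray:
    """Closed-form occupancy probability of each 20-degree bin.

    The dwell density is proportional to 1/omega(theta); its integral has
    the closed form atan(r tan theta)/pi (branch-corrected at +-90), so the
    probability of bin (a, b] is [atan(r tan b) - atan(r tan a)] / pi.
    Serves as the independent oracle for ``model_pdf``.
    """
    r = float(aspect_ratio)

    def cdf(theta_deg: float) -> float:
        if theta_deg <= -90.0:
            return -0.5
        if theta_deg >= 90.0:
            return 0.5
        return np.arctan(r * np.tan(np.radians(theta_deg))) / np.pi

    edges = ANGLE_BIN_EDGES
    return np.array([cdf(edges[i + 1]) - cdf(edges[i]) for i in range(len(edges) - 1)])
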