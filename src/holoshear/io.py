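"""Readers and writers for the pipeline's on-disk formats.

Holograms travel as 16-bit grayscale TIFF with a plain-text metadata
sidecar; particle tables, scenes, velocity and density series are CSV with
a single header row.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .holography import Hologram
from .metrics import PARTICLE_CSV_COLUMNS, ParticleRecord
from .synthetic import SyntheticParticle

__all__ = [
    "write_hologram",
    "read_hologram",
    "write_particles",
    "read_particles",
    "write_scene",
    "read_scene",
]


def write_hologram(path: str | Path, holo: Hologram) -> None:
    """Write a hologram as 16-bit TIFF plus a text metadata sidecar."""
    path = Path(path)
    data = np.clip(holo.intensity, 0.0, 1.0)
    tifffile.imwrite(path, (data * 65535).astype(np.uint16))
    meta = (
        f"timestamp_s: {holo.timestamp}\n"
        f"depth_m: {holo.depth}\n"
        f"pitch_deg: {holo.pitch}\n"
        f"cast: {holo.cast}\n"
    )
    path.with_suffix(".txt").write_text(meta)


def read_hologram(path: str | Path) -> Hologram:
    """Read a TIFF hologram and its metadata sidecar back into memory."""
    path = Path(path)
    data = tifffile.imread(path).astype(float) / 65535.0
    meta: dict[str, str] = {}
    sidecar = path.with_suffix(".txt")
    if sidecar.exists():
        for line in sidecar.read_text().splitlines():
            key, _, value = line.partition(":")
            meta[key.strip()] = value.strip()
    return Hologram(
        intensity=data,
        timestamp=float(meta.get("timestamp_s", 0.0)),
        depth=float(meta.get("depth_m", 0.0)),
        pitch=float(meta.get("pitch_deg", 0.0)),
        cast=meta.get("cast", "down"),
    )


def write_particles(path: str | Path, records: list[ParticleRecord]) -> None:
    """Write particle records to CSV in the pipeline's fixed column dialect."""
    rows = [asdict(r) for r in records]
    df = pd.DataFrame(rows, columns=PARTICLE_CSV_COLUMNS)
    df.to_csv(path, index=False)


def read_particles(path: str | Path) -> pd.DataFrame:
    """Read a particle CSV back as a DataFrame."""
    return pd.read_csv(path)


def write_scene(path: str | Path, scene: list[SyntheticParticle]) -> None:
    """Write a synthetic scene's ground truth, one particle per row (SI units)."""
    rows = [
        {
            "id": i,
            "x": p.center_xyz[0],
            "y": p.center_xyz[1],
            "z": p.center_xyz[2],
            "major": p.major_len,
            "minor": p.minor_len,
            "theta_p": p.theta_p,
            "theta_a": p.theta_a,
            "shape": p.shape,
            "n_cells": p.n_cells,
            "cell_gap": p.cell_gap,
        }
        for i, p in enumerate(scene)
    ]
    pd.DataFrame(
        rows,
        columns=["id", "x", "y", "z", "major", "minor", "theta_p", "theta_a", "shape", "n_cells", "cell_gap"],
    ).to_csv(path, index=False)


def read_scene(path: str | Path) -> list[SyntheticParticle]:
    """Read a ground-truth scene CSV back into particle objects."""
    df = pd.read_csv(path)
    return [
        SyntheticParticle(
            center_xyz=(row.x, row.y, row.z),
            major_len=row.major,
            minor_len=row.minor,
            theta_p=row.theta_p,
            theta_a=row.theta_a,
            shape=getattr(row, "shape", "spheroid"),
            n_cells=int(getattr(row, "n_cells", 1)),
            cell_gap=float(getattr(row, "cell_gap", 0.0)),
        )
        for row in df.itertuples()
    ]
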