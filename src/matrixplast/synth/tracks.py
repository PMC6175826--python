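"""Synthetic 3D cell-centroid tracks with known motility ground truth.

Two subpopulations emulate time-lapse centroid data from cells embedded in a
confining hydrogel: non-motile cells jitter around their origin following a
bounded Ornstein-Uhlenbeck walk (net displacement stays well below the one
cell-radius motility threshold of ~14 um), while motile cells execute a
persistent run at a constant speed drawn from 2-40 um/h with slow angular
diffusion of the heading, the speed range reported for 3D cancer-cell
invasion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..cells import CellTrack

__all__ = ["TrackSimParams", "generate_tracks", "tracks_to_table"]


@dataclass(frozen=True)
class TrackSimParams:
    """Track-simulation settings.

    speed_range is in um/h; persistence_time (min) sets how slowly a motile
    cell's heading decorrelates; dt (min) the sampling interval; duration in
    hours.  jitter_sd (um) is the stationary per-axis amplitude of the
    non-motile jitter, jitter_relaxation (min) its correlation time.
    """

    n_cells: int = 100
    motile_fraction: float = 0.3
    speed_range: tuple[float, float] = (2.0, 40.0)
    persistence_time: float = 720.0
    dt: float = 5.0
    duration: float = 12.0
    seed: int | None = None
    jitter_sd: float = 1.5
    jitter_relaxation: float = 30.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.motile_fraction <= 1.0:
            raise ValueError("motile_fraction must be in [0, 1]")
        lo, hi = self.speed_range
        if not (0 < lo <= hi):
            raise ValueError("speed_range must be a positive interval")
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be positive")
        if self.n_cells < 1:
            raise ValueError("need at least one cell")


def _unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def generate_tracks(params: TrackSimParams) -> list[CellTrack]:
    """Simulate 3D centroid tracks; each track carries its ground-truth label
    in ``track.condition`` ("motile" / "non-motile")."""
    rng = np.random.default_rng(params.seed)
    n_steps = int(round(params.duration * 60.0 / params.dt))
    t = np.arange(n_steps + 1) * params.dt  # min
    tracks: list[CellTrack] = []
    for cid in range(params.n_cells):
        motile = rng.random() < params.motile_fraction
        origin = rng.uniform(0, 500, size=3)
        if motile:
            speed = rng.uniform(*params.speed_range) / 60.0  # um/min
            heading = _unit_vector(rng)
            # heading decorrelates over persistence_time via small random
            # rotations: angular step sd = sqrt(2 dt / P)
            ang_sd = np.sqrt(2.0 * params.dt / params.persistence_time)
            pos = np.empty((n_steps + 1, 3))
            pos[0] = origin
            for k in range(n_steps):
                perturb = rng.normal(0.0, ang_sd, size=3)
                heading = heading + np.cross(perturb, heading)
                heading /= np.linalg.norm(heading)
                pos[k + 1] = pos[k] + speed * params.dt * heading
        else:
            # OU jitter per axis, stationary sd jitter_sd
            theta = params.dt / params.jitter_relaxation
            a = np.exp(-theta)
            step_sd = params.jitter_sd * np.sqrt(1.0 - a * a)
            dev = np.zeros((n_steps + 1, 3))
            noise = rng.normal(0.0, step_sd, size=(n_steps, 3))
            for k in range(n_steps):
                dev[k + 1] = a * dev[k] + noise[k]
            pos = origin + dev
        samples = pd.DataFrame({
            "t_min": t, "x_um": pos[:, 0], "y_um": pos[:, 1], "z_um": pos[:, 2],
        })
        tracks.append(CellTrack(cell_id=cid, samples=samples,
                                condition="motile" if motile else "non-motile"))
    return tracks


def tracks_to_table(tracks: list[CellTrack]) -> pd.DataFrame:
    """Flatten tracks into one long table (cell_id, t_min, x/y/z_um,
    motile_truth) matching the on-disk CSV schema."""
    frames = []
    for tr in tracks:
        df = tr.samples.copy()
        df.insert(0, "cell_id", tr.cell_id)
        df["motile_truth"] = tr.condition == "motile"
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
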