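"""Synthetic single-molecule trajectories along a microtubule axis.

Four motion modes mirror the phenotypes seen in motility assays:

* ``directional`` — constant drift v along the filament axis (a processive
  motor), optionally ending after a set run length;
* ``diffusive`` — 1-D Brownian motion along the axis with diffusion
  coefficient D and zero expected drift (thermally driven back-and-forth);
* ``transient`` — static binding events whose dwell times are exponential
  with mean 1/k_off, invisible while unbound;
* ``static`` — a rigor-bound, immobile molecule.

Localization error is modelled as isotropic Gaussian noise added to the true
positions; when trajectories are later rendered into movies, noise instead
arises from photon statistics alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GroundTruthTrack", "SyntheticMotilityDataset", "simulate_tracks"]

MODES = ("directional", "diffusive", "transient", "static")


@dataclass
class GroundTruthTrack:
    track_id: int
    t: np.ndarray        # s
    x: np.ndarray        # nm, observed (noise included)
    y: np.ndarray        # nm
    true_x: np.ndarray   # nm, noise-free
    true_y: np.ndarray
    mode: str
    dwell: float = None  # s, transient events only


@dataclass
class SyntheticMotilityDataset:
    tracks: list
    mode: str
    frame_interval: float           # s
    params: dict = field(default_factory=dict)
    loc_noise_sd: float = 0.0       # nm
    pixel_size: float = 159.0       # nm, camera geometry for rendering
    seed: int = 0

    def as_table(self):
        """Track table as a DataFrame (track_id, frame, t_s, x_nm, y_nm)."""
        import pandas as pd

        rows = []
        for tr in self.tracks:
            frames = np.rint(tr.t / self.frame_interval).astype(int)
            for f, t, x, y in zip(frames, tr.t, tr.x, tr.y):
                rows.append((tr.track_id, f, t, x, y))
        return pd.DataFrame(rows, columns=["track_id", "frame", "t_s", "x_nm", "y_nm"])


def _axis_unit(params, rng):
    angle = params.get("angle_deg")
    if angle is None:
        angle = 0.0
    theta = np.radians(float(angle))
    return np.array([np.cos(theta), np.sin(theta)])


def simulate_tracks(mode, params=None, duration=60.0, frame_interval=1.0,
                    n_tracks=1, loc_noise_sd=0.0, seed=0):
    """Simulate ``n_tracks`` trajectories of one motion mode.

    ``params`` by mode: directional {v (nm/s), run_length (nm, optional),
    angle_deg}; diffusive {D (nm²/s), angle_deg}; transient {k_off (1/s),
    n_events}; static {}. All modes accept ``origin`` (nm pair) and
    ``angle_deg`` for the filament axis direction.
    """
    params = dict(params or {})
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if duration <= 0 or frame_interval <= 0:
        raise ValueError("duration and frame_interval must be positive")
    if loc_noise_sd < 0:
        raise ValueError("loc_noise_sd must be non-negative")
    if mode == "directional" and params.get("v", 0.0) < 0:
        raise ValueError("directional velocity v must be non-negative")
    if mode == "diffusive" and params.get("D", 0.0) < 0:
        raise ValueError("diffusion coefficient D must be non-negative")

    rng = np.random.default_rng(seed)
    axis = _axis_unit(params, rng)
    origin = np.asarray(params.get("origin", (0.0, 0.0)), dtype=float)
    tracks = []
    tid = 0

    if mode == "transient":
        k_off = float(params.get("k_off", 1.0))
        if k_off <= 0:
            raise ValueError("transient mode requires k_off > 0")
        n_events = int(params.get("n_events", n_tracks))
        for _ in range(n_events):
            dwell = rng.exponential(1.0 / k_off)
            n_frames = max(1, int(np.floor(dwell / frame_interval)) + 1)
            t = np.arange(n_frames) * frame_interval
            pos = origin + rng.uniform(-500.0, 500.0) * axis
            tx = np.full(n_frames, pos[0])
            ty = np.full(n_frames, pos[1])
            x, y = _add_noise(tx, ty, loc_noise_sd, rng)
            tracks.append(GroundTruthTrack(
                track_id=tid, t=t, x=x, y=y, true_x=tx, true_y=ty,
                mode=mode, dwell=float(dwell)))
            tid += 1
    else:
        n_frames = int(np.floor(duration / frame_interval)) + 1
        t = np.arange(n_frames) * frame_interval
        for _ in range(n_tracks):
            if mode == "directional":
                v = float(params.get("v", 100.0))
                s = v * t
                run_length = params.get("run_length")
                if run_length is not None:
                    keep = s <= float(run_length)
                    s = s[keep]
                else:
                    keep = slice(None)
                tt = t[keep]
            elif mode == "diffusive":
                D = float(params.get("D", 1.0e4))
                steps = rng.normal(0.0, np.sqrt(2.0 * D * frame_interval),
                                   size=n_frames - 1)
                s = np.concatenate([[0.0], np.cumsum(steps)])
                tt = t
            else:  # static
                s = np.zeros(n_frames)
                tt = t
            tx = origin[0] + s * axis[0]
            ty = origin[1] + s * axis[1]
            x, y = _add_noise(tx, ty, loc_noise_sd, rng)
            tracks.append(GroundTruthTrack(
                track_id=tid, t=tt, x=x, y=y, true_x=tx, true_y=ty, mode=mode))
            tid += 1

    return SyntheticMotilityDataset(
        tracks=tracks, mode=mode, frame_interval=float(frame_interval),
        params=params, loc_noise_sd=float(loc_noise_sd), seed=int(seed),
    )


def _add_noise(tx, ty, sd, rng):
    if sd > 0:
        return tx + rng.normal(0, sd, tx.shape), ty + rng.normal(0, sd, ty.shape)
    return tx.copy(), ty.copy()
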