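"""Render trajectories into camera frames with a Gaussian PSF.

Each emitter contributes an integrated symmetric 2-D Gaussian (the PSF
integral over each pixel, via the error function), a uniform background is
added, and each pixel is Poisson-sampled — the noise model the localization
stage assumes. Geometry defaults to the 159 nm pixel size of the EMCCD
acquisition the package emulates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

__all__ = ["SyntheticMovie", "gaussian_spot", "render_movie"]


@dataclass
class SyntheticMovie:
    frames: np.ndarray        # (n_frames, ny, nx) counts
    emitters: list            # per frame: array of (x_px, y_px, photons)
    pixel_size: float         # nm
    psf_sigma: float          # nm
    photons: float
    background: float         # counts / pixel
    n_clipped: int            # emitter-frames outside the field of view
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def save_tiff(self, path):
        import tifffile

        tifffile.imwrite(str(path), self.frames.astype(np.float32),
                         photometric="minisblack")


def gaussian_spot(shape, x_px, y_px, sigma_px, photons):
    """Expected counts of one emitter: PSF integrated over each pixel.

    Pixel (i, j) covers [j, j+1) x [i, i+1) in pixel units; the emitter sits
    at (x_px, y_px). The spot integrates to ``photons`` over the full plane.
    """
    ny, nx = shape
    xs = np.arange(nx + 1)
    ys = np.arange(ny + 1)
    sq2 = np.sqrt(2.0) * sigma_px
    fx = 0.5 * (erf((xs - x_px) / sq2))
    fy = 0.5 * (erf((ys - y_px) / sq2))
    px = np.diff(fx)
    py = np.diff(fy)
    return photons * np.outer(py, px)


def render_movie(dataset, psf_sigma=170.0, photons=1000.0, background=10.0,
                 fov_px=32, pixel_size=None, poisson=True, seed=0,
                 origin_nm=None):
    """Render a :class:`~dynstalk.synth.tracks.SyntheticMotilityDataset`.

    Parameters
    ----------
    psf_sigma : PSF standard deviation in nm.
    photons : expected photons per emitter per frame.
    background : expected background counts per pixel.
    fov_px : square field of view in pixels.
    pixel_size : nm per pixel; defaults to the dataset's (159 nm).
    poisson : sample Poisson noise; when False, frames are the noiseless
        expectation (for noise-free localization fixtures).
    origin_nm : nm coordinates mapped to the FOV centre; defaults to the
        mean position of all localizations.

    Emitters falling outside the field of view are silently clipped; the
    clip count is recorded on the returned movie.
    """
    if pixel_size is None:
        pixel_size = dataset.pixel_size
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be positive")
    rng = np.random.default_rng(seed)
    sigma_px = psf_sigma / pixel_size

    # Frame index per localization from acquisition timing.
    per_frame = {}
    all_xy = []
    for tr in dataset.tracks:
        frames = np.rint(tr.t / dataset.frame_interval).astype(int)
        for f, x, y in zip(frames, tr.true_x, tr.true_y):
            per_frame.setdefault(int(f), []).append((x, y))
            all_xy.append((x, y))
    if not per_frame:
        raise ValueError("dataset contains no localizations to render")
    n_frames = max(per_frame) + 1
    if origin_nm is None:
        origin_nm = np.mean(np.asarray(all_xy), axis=0)
    origin_nm = np.asarray(origin_nm, dtype=float)

    half = fov_px / 2.0
    frames = np.zeros((n_frames, fov_px, fov_px))
    emitters = []
    n_clipped = 0
    for f in range(n_frames):
        expected = np.full((fov_px, fov_px), float(background))
        kept = []
        for x, y in per_frame.get(f, []):
            x_px = (x - origin_nm[0]) / pixel_size + half
            y_px = (y - origin_nm[1]) / pixel_size + half
            if not (0.0 <= x_px < fov_px and 0.0 <= y_px < fov_px):
                n_clipped += 1
                continue
            expected += gaussian_spot((fov_px, fov_px), x_px, y_px,
                                      sigma_px, photons)
            kept.append((x_px, y_px, photons))
        if poisson:
            frames[f] = rng.poisson(expected)
        else:
            frames[f] = expected
        emitters.append(np.asarray(kept, dtype=float).reshape(-1, 3))

    return SyntheticMovie(
        frames=frames, emitters=emitters, pixel_size=float(pixel_size),
        psf_sigma=float(psf_sigma), photons=float(photons),
        background=float(background), n_clipped=n_clipped, seed=int(seed),
        meta={"origin_nm": origin_nm.tolist(), "fov_px": int(fov_px)},
    )
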