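"""Sub-pixel emitter localization by Gaussian maximum likelihood.

Candidate spots are local maxima of a band-pass (difference-of-Gaussians)
filtered frame; each candidate is then fit in a small window by maximizing
the Poisson likelihood of an integrated symmetric 2-D Gaussian plus a
constant background. The per-localization precision is the
information-theoretic bound for that model (a Mortensen-style estimate for
an integrated Gaussian under Poisson noise); it is a package-defined
estimator, reported in nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from ..synth.movies import gaussian_spot

__all__ = ["Localization", "localize_emitters", "localize_movie"]


@dataclass
class Localization:
    frame: int
    t: float              # s
    x: float              # nm, within-frame coordinates
    y: float              # nm
    x_px: float
    y_px: float
    photons: float
    background: float     # counts / pixel
    fit_sigma: float      # nm, PSF sigma used by the fit
    precision: float      # nm, information-bound estimate
    saturated: bool = False
    loglik: float = field(default=np.nan, repr=False)


def _detect_candidates(frame, sigma_px, detect_threshold):
    """Local maxima of the DoG-filtered frame above a robust noise threshold."""
    lo = ndimage.gaussian_filter(frame.astype(float), sigma_px)
    hi = ndimage.gaussian_filter(frame.astype(float), 2.0 * sigma_px)
    band = lo - hi
    mad = np.median(np.abs(band - np.median(band)))
    noise_sd = 1.4826 * mad
    if noise_sd == 0.0:
        noise_sd = band.std() or 1.0
    footprint = np.ones((3, 3), dtype=bool)
    is_max = band == ndimage.maximum_filter(band, footprint=footprint)
    above = band > detect_threshold * noise_sd
    ys, xs = np.nonzero(is_max & above)
    order = np.argsort(-band[ys, xs])
    return list(zip(xs[order], ys[order]))


def _neg_loglik(params, window, sigma_px):
    x, y, n_phot, bg = params
    mu = bg + gaussian_spot(window.shape, x, y, sigma_px, n_phot)
    mu = np.maximum(mu, 1e-12)
    return float(np.sum(mu - window * np.log(mu)))


def _precision_nm(sigma_px, n_phot, bg, pixel_size):
    # Information bound for an integrated Gaussian with Poisson noise:
    # var = (s^2 + a^2/12)/N * (16/9 + 8*pi*(s^2 + a^2/12)*b / (N*a^2)),
    # in pixel units with a = 1.
    sa2 = sigma_px ** 2 + 1.0 / 12.0
    var = sa2 / n_phot * (16.0 / 9.0 + 8.0 * np.pi * sa2 * bg / n_phot)
    return float(np.sqrt(var) * pixel_size)


def localize_emitters(frame, psf_sigma, pixel_size=159.0, detect_threshold=5.0,
                      fit_window=7, frame_index=0, t=0.0,
                      saturation_level=None, min_separation=None):
    """Detect and fit emitters in one 2-D frame.

    Parameters
    ----------
    frame : 2-D array of counts.
    psf_sigma : PSF standard deviation in nm.
    pixel_size : nm per pixel.
    detect_threshold : detection cut in robust noise SDs of the band-pass
        filtered image.
    fit_window : odd window size (pixels) for the maximum-likelihood fit.
    saturation_level : counts at which a pixel is considered saturated; a
        localization whose window contains one is flagged, not dropped.

    Returns a list of :class:`Localization`; non-converged or out-of-window
    fits are dropped (their count is available from the difference with the
    candidate count only through logging by the caller).
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("localize_emitters expects a single 2-D image")
    if psf_sigma <= 0 or pixel_size <= 0:
        raise ValueError("psf_sigma and pixel_size must be positive")
    if fit_window % 2 == 0 or fit_window < 3:
        raise ValueError("fit_window must be an odd integer >= 3")
    sigma_px = psf_sigma / pixel_size
    half = fit_window // 2
    ny, nx = frame.shape
    if min_separation is None:
        min_separation = max(1.0, sigma_px)

    results = []
    for cx, cy in _detect_candidates(frame, sigma_px, detect_threshold):
        x0, y0 = int(cx), int(cy)
        if not (half <= x0 < nx - half and half <= y0 < ny - half):
            x0 = min(max(x0, half), nx - half - 1)
            y0 = min(max(y0, half), ny - half - 1)
        if any(np.hypot(r.x_px - x0, r.y_px - y0) < min_separation
               for r in results):
            continue
        window = frame[y0 - half:y0 + half + 1, x0 - half:x0 + half + 1]
        saturated = bool(saturation_level is not None
                         and np.any(window >= saturation_level))
        bg0 = float(np.median(np.concatenate([window[0], window[-1],
                                              window[:, 0], window[:, -1]])))
        n0 = max(float(window.sum() - bg0 * window.size), 1.0)
        p0 = np.array([half + 0.5, half + 0.5, n0, max(bg0, 1e-3)])
        bounds = [(0.5, fit_window - 0.5), (0.5, fit_window - 0.5),
                  (1.0, None), (0.0, None)]
        res = optimize.minimize(
            _neg_loglik, p0, args=(window, sigma_px), method="L-BFGS-B",
            bounds=bounds,
        )
        if not res.success:
            continue
        xf, yf, n_phot, bg = res.x
        # Reject fits stuck on the window edge (ambiguous neighbour spot).
        if not (0.6 <= xf <= fit_window - 0.6 and 0.6 <= yf <= fit_window - 0.6):
            continue
        x_px = x0 - half + xf
        y_px = y0 - half + yf
        if any(np.hypot(r.x_px - x_px, r.y_px - y_px) < min_separation
               for r in results):
            continue
        results.append(Localization(
            frame=int(frame_index), t=float(t),
            x=float(x_px * pixel_size), y=float(y_px * pixel_size),
            x_px=float(x_px), y_px=float(y_px),
            photons=float(n_phot), background=float(bg),
            fit_sigma=float(psf_sigma),
            precision=_precision_nm(sigma_px, n_phot, bg, pixel_size),
            saturated=saturated, loglik=-float(res.fun),
        ))
    return results


def localize_movie(frames, psf_sigma, pixel_size=159.0, frame_interval=1.0,
                   **kwargs):
    """Run :func:`localize_emitters` over a (n_frames, ny, nx) stack."""
    out = []
    for i, frame in enumerate(np.asarray(frames, dtype=float)):
        out.extend(localize_emitters(
            frame, psf_sigma, pixel_size=pixel_size,
            frame_index=i, t=i * frame_interval, **kwargs,
        ))
    return out
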