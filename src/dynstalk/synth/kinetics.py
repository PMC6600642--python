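"""Synthetic saturation-kinetics datasets.

Generates concentration/response curves from the hyperbolic law used for
microtubule-stimulated ATPase and cosedimentation binding assays,

    y = (amplitude - basal) * x / (K + x) + basal,

with optional zero-mean Gaussian noise and replicates, carrying the
generating parameters as ground truth for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["KineticTruth", "SyntheticKineticDataset", "hyperbola", "simulate_kinetics"]


@dataclass(frozen=True)
class KineticTruth:
    """Generating parameters of a hyperbolic saturation curve.

    amplitude : plateau rate/fraction (kcat or B_M), units of y
    K         : half-saturation constant (K_M or K_d), µM tubulin dimer
    basal     : microtubule-independent baseline (k_basal), units of y
    """

    amplitude: float
    K: float
    basal: float


@dataclass
class SyntheticKineticDataset:
    x: np.ndarray          # µM, one entry per observation (replicates expanded)
    y: np.ndarray          # observed rate (1/s) or bound fraction
    replicate: np.ndarray  # replicate index per observation
    truth: KineticTruth
    noise_sd: float
    seed: int
    x_grid: np.ndarray = field(default=None)  # distinct concentrations


def hyperbola(x, amplitude, K, basal):
    """Saturation law y = (amplitude - basal) * x / (K + x) + basal."""
    x = np.asarray(x, dtype=float)
    return (amplitude - basal) * x / (K + x) + basal


def simulate_kinetics(truth, x_grid, noise_sd=0.0, replicates=1, seed=0):
    """Sample a saturation dataset with known ground truth.

    Parameters
    ----------
    truth : KineticTruth or (amplitude, K, basal) tuple
    x_grid : concentrations in µM; must be non-negative and span at least
        four times ``truth.K`` so the plateau is constrained.
    noise_sd : standard deviation of additive Gaussian noise (units of y).
    replicates : independent noisy copies per concentration.
    seed : RNG seed; fixed seed gives bit-identical output.
    """
    if not isinstance(truth, KineticTruth):
        truth = KineticTruth(*truth)
    if truth.K <= 0:
        raise ValueError("truth.K must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    x_grid = np.asarray(x_grid, dtype=float)
    if np.any(x_grid < 0):
        raise ValueError("concentrations must be non-negative")
    if x_grid.max() < 4.0 * truth.K:
        raise ValueError(
            f"x_grid must extend to at least 4*K = {4.0 * truth.K:g} µM "
            f"(got max {x_grid.max():g})"
        )

    rng = np.random.default_rng(seed)
    x = np.tile(x_grid, replicates)
    rep = np.repeat(np.arange(replicates), x_grid.size)
    y = hyperbola(x, truth.amplitude, truth.K, truth.basal)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return SyntheticKineticDataset(
        x=x, y=y, replicate=rep, truth=truth,
        noise_sd=float(noise_sd), seed=int(seed), x_grid=x_grid,
    )
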