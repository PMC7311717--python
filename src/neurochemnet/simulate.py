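"""Synthetic two-state microdialysis panels.

The generator draws, for every mouse, a latent 8-vector from a Gaussian
copula with the state's correlation matrix and maps each coordinate through
a moment-matched lognormal, so the mouse-level marginal has exactly the
target mean and SD. Each of the five sequential samples multiplies the
mouse level by unit-mean lognormal noise (within-mouse variability, sized
by ``icc``) and adds the state's linear time trend centered on the middle
sample, so neither the noise nor the trend biases the mouse-level mean.
Values below the analyte's LLOQ are censored (flagged, concentration
absent), emulating the ~10.5% below-quantification missingness seen in
LC-MS/MS panels of this kind.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .config import SyntheticConfig, lognormal_params
from .panel import STATES, ConcentrationTable, ValidationError

__all__ = ["generate_dataset", "generate_probe_sites", "draw_mouse_levels"]


def _log_moments(config: SyntheticConfig, state: str) -> tuple[np.ndarray, np.ndarray]:
    mus, sigmas = [], []
    for mean, sd in zip(config.mean_nM[state], config.sd_nM[state]):
        mu, sigma = lognormal_params(float(mean), float(sd))
        mus.append(mu)
        sigmas.append(sigma)
    return np.array(mus), np.array(sigmas)


def _chol(config: SyntheticConfig, state: str) -> np.ndarray:
    corr = config.corr[state]
    # corr is PSD after repair; jitter only if strictly singular
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(corr)
        w = np.clip(w, 1e-12, None)
        return v @ np.diag(np.sqrt(w))


def draw_mouse_levels(
    config: SyntheticConfig, state: str, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` mouse-level concentration vectors (n x panel), in nM.

    These are the latent per-mouse levels: correlated on the copula scale
    by the state's matrix, with each marginal lognormal at the target
    mean/SD. Sample-level noise and trend are added by
    :func:`generate_dataset`, not here.
    """
    if state not in STATES:
        raise ValidationError(f"unknown state {state!r}")
    mu, sigma = _log_moments(config, state)
    z = rng.standard_normal((n, len(config.panel))) @ _chol(config, state).T
    return np.exp(mu + sigma * z)


def generate_dataset(config: SyntheticConfig, seed: int | None = None) -> ConcentrationTable:
    """Generate a full long-form concentration table for the configured design.

    Deterministic for fixed (config, seed); ``seed=None`` uses
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_samples = config.samples_per_mouse
    p = len(config.panel)
    offsets = np.arange(1, n_samples + 1) - (n_samples + 1) / 2.0

    frames = []
    for state, n_mice, prefix in (
        ("wake", config.n_wake, "w"),
        ("iso", config.n_iso, "i"),
    ):
        mu, sigma = _log_moments(config, state)
        chol = _chol(config, state)
        tau = sigma * math.sqrt((1.0 - config.icc) / config.icc)

        z_mouse = rng.standard_normal((n_mice, p)) @ chol.T
        levels = np.exp(mu + sigma * z_mouse)  # (mice, p)
        z_noise = rng.standard_normal((n_mice, n_samples, p)) @ chol.T
        noise = np.exp(tau * z_noise - tau**2 / 2.0)  # unit-mean factors
        trend = config.slope_nM_per_sample[state][None, None, :] * offsets[None, :, None]
        values = levels[:, None, :] * noise + trend  # (mice, samples, p)

        below = values < config.lloq_nM[None, None, :]
        mouse_ids = [f"{prefix}{m + 1:02d}" for m in range(n_mice)]
        frames.append(
            pd.DataFrame(
                {
                    "mouse_id": np.repeat(mouse_ids, n_samples * p),
                    "state": state,
                    "sample_index": np.tile(np.repeat(np.arange(1, n_samples + 1), p), n_mice),
                    "analyte": np.tile(list(config.panel), n_mice * n_samples),
                    "concentration_nM": np.where(below, np.nan, values).ravel(),
                    "below_lloq": below.ravel(),
                    "imputed": False,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    return ConcentrationTable(df, config.panel)


def generate_probe_sites(config: SyntheticConfig, seed: int | None = None) -> pd.DataFrame:
    """One dialysis-site coordinate triple (AP/ML/DV mm from bregma) per mouse.

    Coordinates are independent Gaussians with the per-state means/SDs.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    rows = []
    for state, n_mice, prefix in (
        ("wake", config.n_wake, "w"),
        ("iso", config.n_iso, "i"),
    ):
        mean = config.probe_mean_mm[state]
        sd = config.probe_sd_mm[state]
        coords = mean + sd * rng.standard_normal((n_mice, 3))
        for m in range(n_mice):
            rows.append(
                {
                    "mouse_id": f"{prefix}{m + 1:02d}",
                    "state": state,
                    "ap_mm": coords[m, 0],
                    "ml_mm": coords[m, 1],
                    "dv_mm": coords[m, 2],
                }
            )
    return pd.DataFrame(rows)
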