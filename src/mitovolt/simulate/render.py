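"""Optical blur and photon noise."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .scenario import SimScenario

FWHM_TO_SIGMA = 2.3548  # 2*sqrt(2*ln 2)


def render_frame(
    concentration: np.ndarray,
    scenario: SimScenario,
    rng: np.random.Generator | None = None,
    noise_free: bool = False,
) -> np.ndarray:
    """Blur a (C, H, W) concentration map and add shot/read noise.

    Gaussian PSF with sigma = FWHM/2.3548 (in pixels); intensities are in
    photon units after scaling by ``photons_per_unit``; Poisson shot noise
    plus additive Gaussian read noise; clipped at zero.  Deterministic
    given the generator state.  ``noise_free`` returns the blurred,
    photon-scaled image with no stochastic terms.
    """
    concentration = np.asarray(concentration, dtype=float)
    if not np.all(np.isfinite(concentration)):
        raise ValueError("concentration map contains non-finite values")
    if scenario.psf_fwhm_nm < scenario.pixel_size_nm:
        raise ValueError("psf_fwhm_nm must be >= pixel_size_nm")
    sigma = scenario.psf_sigma_px
    blurred = np.stack(
        [ndimage.gaussian_filter(ch, sigma=sigma, mode="nearest")
         for ch in concentration]
    )
    # channel 0 is structural, channel 1 potentiometric; their raw units
    # differ by orders of magnitude, so each gets its own photon gain
    gains = np.array([scenario.struct_photons_per_unit, scenario.photons_per_unit])
    if blurred.shape[0] != 2:
        gains = np.full(blurred.shape[0], scenario.photons_per_unit)
    expected = blurred * gains[:, None, None]
    if noise_free:
        return expected
    if rng is None:
        rng = np.random.default_rng(scenario.rng_seed)
    noisy = rng.poisson(expected).astype(float)
    if scenario.read_noise_sd > 0:
        noisy += rng.normal(0.0, scenario.read_noise_sd, size=noisy.shape)
    return np.clip(noisy, 0.0, None)
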