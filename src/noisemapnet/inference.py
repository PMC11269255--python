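"""Full-frame denoising with a trained noise-map network.

Per frame the chain is: standardize -> zero-pad to a divisible size ->
predict the standardized noise map -> crop -> rescale the map to raw
intensity units -> subtract from the input. The network is fully
convolutional, so whole frames are processed at once (no tiling).

Negative denoised pixels are clipped to zero by default (the outputs are
magnitude images), but the unclipped noise map is always preserved so
``input = denoised + noise map`` remains auditable with clipping off.
Standardization is per frame by default, mirroring training, so
bolus-driven intensity swings do not leak between dynamics. Denoising is
not idempotent: applying the model to its own output is a different
input distribution and is neither needed nor asserted.
"""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .phantom import ImageSeries
from .preprocess import (PadSpec, StandardizationParams, crop_with,
                         destandardize_noise, pad_to_multiple, standardize)

logger = logging.getLogger(__name__)

__all__ = ["DenoiseResult", "denoise_frame", "denoise_series"]


@dataclass
class DenoiseResult:
    denoised: ImageSeries
    noise_maps: np.ndarray                 # raw intensity units, same shape
    standardizations: list = field(default_factory=list)  # per (slice, dynamic)
    pad_specs: list = field(default_factory=list)
    clip_applied: bool = True


def denoise_frame(model, frame: np.ndarray, clip: bool = True):
    """Denoise one raw-intensity 2D frame.

    Returns ``(denoised, noise_map, params, pad_spec)`` with the noise map
    in raw intensity units; ``denoised = frame - noise_map`` before the
    optional clipping of negatives. ``model`` needs a ``predict(frame_std)``
    method and a config exposing ``size_multiple`` (a stub predicting the
    true standardized noise map reproduces the clean image exactly).
    """
    frame = np.asarray(frame, dtype=np.float64)
    frame_std, params = standardize(frame)   # rejects constant frames
    multiple = getattr(getattr(model, "config", model), "size_multiple", 16)
    padded, pad_spec = pad_to_multiple(frame_std, multiple)
    map_std = crop_with(model.predict(padded), pad_spec)
    noise_map = destandardize_noise(map_std, params)
    denoised = frame - noise_map
    if clip:
        denoised = np.maximum(denoised, 0.0)
    return denoised, noise_map, params, pad_spec


def denoise_series(model, series: ImageSeries, clip: bool = True) -> DenoiseResult:
    """Frame-by-frame denoising of a whole multi-slice dynamic series."""
    t0 = time.perf_counter()
    out = np.empty_like(series.voxels)
    maps = np.empty_like(series.voxels)
    result = DenoiseResult(denoised=None, noise_maps=maps, clip_applied=clip)
    for s in range(series.n_slices):
        for d in range(series.n_dynamics):
            try:
                den, nmap, params, pad_spec = denoise_frame(model, series.voxels[s, d],
                                                            clip=clip)
            except Exception as exc:
                raise RuntimeError(f"denoising failed at slice {s}, dynamic {d}: {exc}") from exc
            out[s, d] = den
            maps[s, d] = nmap
            result.standardizations.append(params)
            result.pad_specs.append(pad_spec)
        logger.info("denoised slice %d (%d dynamics)", s, series.n_dynamics)
    result.denoised = ImageSeries(out, series.pixel_spacing_mm, series.frame_interval_s)
    logger.info("denoised %d frames in %.2f s", series.n_slices * series.n_dynamics,
                time.perf_counter() - t0)
    return result
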