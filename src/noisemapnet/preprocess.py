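"""Invertible preprocessing: standardization, zero-padding, patching.

The denoiser is trained and run in a standardized intensity domain.
Noise is injected in the raw domain (where the SNR calibration lives);
the noisy frame is then z-scored and the clean frame is scaled with the
*same* parameters, so the ground-truth noise map is simply their
standardized difference and the train-time and inference-time scaling
are identical. Because a noise map is a difference of two images scaled
with the same parameters, mapping it back to raw intensities needs only
the multiplication by sigma (the mean offset cancels).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StandardizationParams",
    "PadSpec",
    "PatchSet",
    "standardize",
    "apply_standardization",
    "destandardize",
    "destandardize_noise",
    "pad_to_multiple",
    "crop_with",
    "extract_patches",
]


@dataclass(frozen=True)
class StandardizationParams:
    mu: float
    sigma: float
    scope: str = "per-frame"   # or "per-series"

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.scope not in ("per-frame", "per-series"):
            raise ValueError(f"unknown standardization scope {self.scope!r}")


@dataclass(frozen=True)
class PadSpec:
    original_size: tuple
    padded_size: tuple
    offsets: tuple   # (top, left)


@dataclass
class PatchSet:
    patches: list          # list of (patch_size, patch_size) arrays
    origins: list          # list of (row, col)
    source_frame_id: int = 0
    patch_size: int = 64


def standardize(frame: np.ndarray, scope: str = "per-frame") -> tuple:
    """Z-score an array; returns ``(standardized, StandardizationParams)``.

    ``scope`` is recorded in the params; pass a whole series array with
    ``scope='per-series'`` to compute series-level statistics. A constant
    input has no defined scale and is rejected.
    """
    frame = np.asarray(frame, dtype=np.float64)
    mu = float(frame.mean())
    sigma = float(frame.std())
    if sigma == 0.0:
        raise ValueError("degenerate intensity: frame is constant, standardization undefined")
    params = StandardizationParams(mu=mu, sigma=sigma, scope=scope)
    return (frame - mu) / sigma, params


def apply_standardization(frame: np.ndarray, params: StandardizationParams) -> np.ndarray:
    """Scale ``frame`` with existing parameters (e.g. the noisy frame's)."""
    return (np.asarray(frame, dtype=np.float64) - params.mu) / params.sigma


def destandardize(frame_std: np.ndarray, params: StandardizationParams) -> np.ndarray:
    return np.asarray(frame_std, dtype=np.float64) * params.sigma + params.mu


def destandardize_noise(noise_map_std: np.ndarray, params: StandardizationParams) -> np.ndarray:
    """Map a standardized noise map back to raw intensity units.

    No mean shift: the map is a difference of two images standardized with
    the same parameters, so only the sigma scaling survives.
    """
    return np.asarray(noise_map_std, dtype=np.float64) * params.sigma


def pad_to_multiple(frame: np.ndarray, multiple: int = 16) -> tuple:
    """Zero-pad symmetrically so both sides divide ``multiple``.

    Odd remainders put the extra pixel on the bottom/right. Returns the
    padded frame and a :class:`PadSpec` that :func:`crop_with` inverts
    exactly. 16 = 2^4 lets a depth-4 network pool evenly.
    """
    if multiple < 1:
        raise ValueError("multiple must be >= 1")
    frame = np.asarray(frame)
    h, w = frame.shape
    ph = -h % multiple
    pw = -w % multiple
    top, left = ph // 2, pw // 2
    padded = np.pad(frame, ((top, ph - top), (left, pw - left)))
    spec = PadSpec(original_size=(h, w), padded_size=(h + ph, w + pw), offsets=(top, left))
    return padded, spec


def crop_with(frame: np.ndarray, spec: PadSpec) -> np.ndarray:
    top, left = spec.offsets
    h, w = spec.original_size
    return np.asarray(frame)[top:top + h, left:left + w]


def extract_patches(frame: np.ndarray, patch_size: int = 64, strategy: str = "random-n",
                    n_or_stride: int = 4, seed=0) -> PatchSet:
    """Select square patches from a frame.

    ``random-n``: ``n_or_stride`` origins drawn uniformly over all valid
    placements, reproducible for a given seed (PCG64). ``grid``: raster
    origins at stride ``n_or_stride``, with the last row/column snapped
    inward so the frame edge is always covered.
    """
    frame = np.asarray(frame)
    h, w = frame.shape
    if h < patch_size or w < patch_size:
        raise ValueError(
            f"frame {h}x{w} is smaller than patch size {patch_size}")
    if strategy == "random-n":
        rng = np.random.default_rng(seed)
        rows = rng.integers(0, h - patch_size + 1, size=n_or_stride)
        cols = rng.integers(0, w - patch_size + 1, size=n_or_stride)
        origins = list(zip(rows.tolist(), cols.tolist()))
    elif strategy == "grid":
        stride = n_or_stride
        if stride < 1:
            raise ValueError("stride must be >= 1")

        def axis_origins(n):
            pts = list(range(0, n - patch_size + 1, stride))
            if pts[-1] != n - patch_size:
                pts.append(n - patch_size)
            return pts

        origins = [(r, c) for r in axis_origins(h) for c in axis_origins(w)]
    else:
        raise ValueError(f"unknown patch strategy {strategy!r}")
    patches = [frame[r:r + patch_size, c:c + patch_size].copy() for r, c in origins]
    return PatchSet(patches=patches, origins=origins, patch_size=patch_size)
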