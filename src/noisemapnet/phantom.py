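"""Synthetic cardiac phantoms and Gaussian noise simulation.

Two generators provide image-domain stand-ins for the data a noise-map
denoiser is trained and evaluated on:

* :func:`generate_cine_phantom` — high-SNR cine-like frames of a
  short-axis heart (bright left-ventricular blood pool, darker myocardial
  ring, dim background) whose ventricle radius varies smoothly over the
  frames to mimic a contraction/relaxation cycle. Tissue intensities are
  piecewise constant: the frames act as noise-free training references.
* :func:`generate_perfusion_phantom` — a dynamic first-pass perfusion
  series in which blood-pool and myocardial signal follow gamma-variate
  bolus kinetics, the blood pool enhancing earlier and more strongly than
  the myocardium.

Noise is added to magnitude images as zero-mean Gaussian with either a
uniform standard deviation calibrated to a target blood-pool SNR, or a
spatially varying (g-factor-like) sigma map. SNR here is defined as the
ROI mean signal at the frame of maximum enhancement divided by the noise
standard deviation. Negative noisy pixels are kept so that
``noisy = clean + noise`` holds exactly; clipping is a display concern.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ImageSeries",
    "PhantomSpec",
    "NoisySample",
    "generate_cine_phantom",
    "generate_perfusion_phantom",
    "blood_pool_mask",
    "myocardium_mask",
    "make_sigma_map",
    "add_noise",
    "gamma_variate",
]


@dataclass
class ImageSeries:
    """Multi-slice dynamic magnitude image stack.

    ``voxels`` is indexed ``(slice, dynamic, row, col)``. ``pixel_spacing_mm``
    is ``(row_mm, col_mm)``. ``frame_interval_s`` is the time between
    dynamics (1.0 for cine stand-ins where "dynamic" means cardiac phase).
    """

    voxels: np.ndarray
    pixel_spacing_mm: tuple = (1.0, 1.0)
    frame_interval_s: float = 1.0

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 4:
            raise ValueError(
                f"voxels must be (slice, dynamic, row, col), got ndim={self.voxels.ndim}")
        if min(self.voxels.shape[2:]) < 16:
            raise ValueError("row/col dimensions must be >= 16")
        if not all(s > 0 for s in self.pixel_spacing_mm):
            raise ValueError("pixel spacing must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame interval must be positive")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def n_dynamics(self) -> int:
        return self.voxels.shape[1]

    @property
    def frame_shape(self) -> tuple:
        return self.voxels.shape[2:]

    def validate_magnitude(self):
        """Assert the magnitude-image invariant (all intensities >= 0)."""
        if np.any(self.voxels < 0):
            raise ValueError("magnitude series contains negative intensities")


@dataclass
class PhantomSpec:
    """Geometry, intensity and bolus-kinetic parameters of the phantom.

    Bolus kinetics are gamma-variate per tissue: onset ``t0`` (dynamics),
    shape ``a`` (dimensionless), scale ``tau`` (dynamics). Baselines are
    the pre-contrast tissue intensities of the perfusion phantom.
    """

    image_size: tuple = (128, 128)
    lv_center: tuple | None = None       # (row, col); image center if None
    lv_radius: float = 18.0              # pixels
    myocardium_outer_radius: float = 28.0
    background_level: float = 40.0       # intensity a.u.
    blood_peak: float = 400.0
    myo_peak: float = 200.0
    blood_baseline: float = 60.0
    myo_baseline: float = 80.0
    blood_t0: float = 8.0                # dynamics
    blood_a: float = 3.0
    blood_tau: float = 4.0
    myo_t0: float = 12.0
    myo_a: float = 3.0
    myo_tau: float = 6.0
    n_dynamics: int = 40
    n_slices: int = 1
    radius_variation: float = 0.15       # cine contraction fraction
    pixel_spacing_mm: tuple = (1.0, 1.0)
    frame_interval_s: float = 1.0
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self):
        if self.lv_radius >= self.myocardium_outer_radius:
            raise ValueError(
                "invalid geometry: lv_radius must be < myocardium_outer_radius "
                f"({self.lv_radius} >= {self.myocardium_outer_radius})")
        if self.myocardium_outer_radius >= min(self.image_size) / 2:
            raise ValueError(
                "invalid geometry: myocardium_outer_radius must be < min(image_size)/2 "
                f"({self.myocardium_outer_radius} >= {min(self.image_size) / 2})")
        for name in ("blood_a", "blood_tau", "myo_a", "myo_tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"bolus parameter {name} must be > 0")
        if self.blood_t0 > self.myo_t0:
            raise ValueError(
                "blood onset must not be later than myocardial onset "
                f"(blood_t0={self.blood_t0} > myo_t0={self.myo_t0})")
        if self.n_dynamics < 1 or self.n_slices < 1:
            raise ValueError("n_dynamics and n_slices must be >= 1")
        if not 0.0 <= self.radius_variation < 1.0:
            raise ValueError("radius_variation must be in [0, 1)")

    @property
    def center(self) -> tuple:
        if self.lv_center is not None:
            return tuple(self.lv_center)
        return ((self.image_size[0] - 1) / 2.0, (self.image_size[1] - 1) / 2.0)


@dataclass
class NoisySample:
    """A (clean, noise, noisy) triple: ``noisy = clean + noise`` exactly."""

    clean: ImageSeries
    noise: np.ndarray
    noisy: ImageSeries
    sigma_map: np.ndarray     # scalar broadcast allowed; >= 0
    target_snr: float
    roi_mask: np.ndarray
    seed: int


def _radius_scale(spec: PhantomSpec, dynamic: int) -> float:
    """Smooth contraction/relaxation factor in [1 - variation, 1]."""
    if spec.n_dynamics == 1:
        return 1.0
    phase = 2.0 * np.pi * dynamic / spec.n_dynamics
    return 1.0 - 0.5 * spec.radius_variation * (1.0 - np.cos(phase))


def _dist2(spec: PhantomSpec) -> np.ndarray:
    rows, cols = np.ogrid[: spec.image_size[0], : spec.image_size[1]]
    cr, cc = spec.center
    return (rows - cr) ** 2 + (cols - cc) ** 2


def blood_pool_mask(spec: PhantomSpec, dynamic: int = 0, cine: bool = False) -> np.ndarray:
    """Boolean LV blood-pool disc mask, from the same geometry the
    generators fill, so ROI statistics on clean phantoms are exact.

    The perfusion phantom is static; the cine phantom contracts, so for
    ``cine=True`` the radius of the requested dynamic is used.
    """
    r = spec.lv_radius * (_radius_scale(spec, dynamic) if cine else 1.0)
    return _dist2(spec) <= r ** 2


def myocardium_mask(spec: PhantomSpec, dynamic: int = 0, cine: bool = False) -> np.ndarray:
    """Boolean myocardial-ring mask (between LV and outer radius)."""
    s = _radius_scale(spec, dynamic) if cine else 1.0
    d2 = _dist2(spec)
    return (d2 > (spec.lv_radius * s) ** 2) & (d2 <= (spec.myocardium_outer_radius * s) ** 2)


def generate_cine_phantom(spec: PhantomSpec) -> ImageSeries:
    """Piecewise-constant cine-like frames with a contracting ventricle.

    Each dynamic is one cardiac phase: the LV and myocardial radii are
    scaled by a smooth cosine cycle while tissue intensities stay exactly
    constant (blood_peak inside the LV, myo_peak in the ring,
    background_level outside). Deterministic for a given spec.
    """
    spec.validate()
    h, w = spec.image_size
    vox = np.empty((spec.n_slices, spec.n_dynamics, h, w))
    d2 = _dist2(spec)
    for t in range(spec.n_dynamics):
        s = _radius_scale(spec, t)
        frame = np.full((h, w), spec.background_level)
        frame[d2 <= (spec.myocardium_outer_radius * s) ** 2] = spec.myo_peak
        frame[d2 <= (spec.lv_radius * s) ** 2] = spec.blood_peak
        vox[:, t] = frame
    return ImageSeries(vox, spec.pixel_spacing_mm, spec.frame_interval_s)


def gamma_variate(t: np.ndarray, t0: float, a: float, tau: float) -> np.ndarray:
    """Gamma-variate bolus curve normalized to unit peak.

    ``g(t) = ((t-t0)/tau)^a * exp(-(t-t0)/tau)`` for ``t > t0``, else 0,
    divided by its maximum ``a^a e^{-a}`` (attained at ``t = t0 + a*tau``).
    """
    if a <= 0 or tau <= 0:
        raise ValueError("gamma-variate requires a > 0 and tau > 0")
    t = np.asarray(t, dtype=np.float64)
    x = np.maximum(t - t0, 0.0) / tau
    with np.errstate(invalid="ignore"):
        g = np.where(x > 0, x ** a * np.exp(-x), 0.0)
    return g / (a ** a * np.exp(-a))


def generate_perfusion_phantom(spec: PhantomSpec) -> ImageSeries:
    """First-pass perfusion series with gamma-variate enhancement.

    Tissue signal over dynamics is ``baseline + (peak - baseline) * g(t)``
    with per-tissue kinetics; blood enhancement precedes and exceeds the
    myocardial one (enforced by the spec invariants and defaults).
    Geometry is static across dynamics.
    """
    spec.validate()
    h, w = spec.image_size
    t = np.arange(spec.n_dynamics, dtype=np.float64)
    blood = spec.blood_baseline + (spec.blood_peak - spec.blood_baseline) * gamma_variate(
        t, spec.blood_t0, spec.blood_a, spec.blood_tau)
    myo = spec.myo_baseline + (spec.myo_peak - spec.myo_baseline) * gamma_variate(
        t, spec.myo_t0, spec.myo_a, spec.myo_tau)
    lv = blood_pool_mask(spec)
    ring = myocardium_mask(spec)
    vox = np.empty((spec.n_slices, spec.n_dynamics, h, w))
    for k in range(spec.n_dynamics):
        frame = np.full((h, w), spec.background_level)
        frame[ring] = myo[k]
        frame[lv] = blood[k]
        vox[:, k] = frame
    return ImageSeries(vox, spec.pixel_spacing_mm, spec.frame_interval_s)


def make_sigma_map(shape, mode: str, sigma0: float, gradient_factor: float = 1.0) -> np.ndarray:
    """Noise standard-deviation field: uniform, or rising with radius.

    ``radial-gradient`` mimics the spatially varying noise amplification of
    parallel-imaging reconstructions: sigma0 at the center pixel, growing
    linearly with distance to ``sigma0 * gradient_factor`` at the farthest
    corner.
    """
    if sigma0 <= 0:
        raise ValueError("sigma0 must be > 0")
    h, w = shape
    if mode == "uniform":
        return np.full((h, w), float(sigma0))
    if mode != "radial-gradient":
        raise ValueError(f"unknown sigma map mode {mode!r}")
    if gradient_factor < 1:
        raise ValueError("gradient_factor must be >= 1")
    cr, cc = h // 2, w // 2
    rows, cols = np.ogrid[:h, :w]
    r = np.sqrt((rows - cr) ** 2 + (cols - cc) ** 2)
    corners = [(0, 0), (0, w - 1), (h - 1, 0), (h - 1, w - 1)]
    rmax = max(np.hypot(pr - cr, pc - cc) for pr, pc in corners)
    return sigma0 * (1.0 + (gradient_factor - 1.0) * r / rmax)


def add_noise(clean: ImageSeries, target_snr: float, roi_mask: np.ndarray,
              sigma_map: np.ndarray | None = None, seed: int = 0) -> NoisySample:
    """Corrupt a magnitude series with zero-mean Gaussian noise.

    When ``sigma_map`` is absent, a uniform sigma is calibrated so the
    blood-pool SNR equals ``target_snr``: sigma = (ROI mean at the frame of
    maximum ROI mean over the series) / target_snr. When ``sigma_map`` is
    given it is used per pixel and ``target_snr`` is ignored for
    calibration (kept for bookkeeping).

    Each (slice, dynamic) frame draws from its own counter-based
    substream of ``seed``, so realizations do not depend on frame order.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != clean.frame_shape:
        raise ValueError("roi_mask shape must match the frame shape")
    if not roi_mask.any():
        raise ValueError("roi_mask is empty (all false)")
    roi_means = clean.voxels[:, :, roi_mask].mean(axis=2)  # (slice, dynamic)
    ref_mean = float(roi_means.max())
    if sigma_map is None:
        if target_snr <= 0:
            raise ValueError("target_snr must be > 0")
        if ref_mean <= 0:
            raise ValueError("ROI mean is zero: SNR is undefined")
        sigma = np.full(clean.frame_shape, ref_mean / target_snr)
    else:
        sigma = np.broadcast_to(np.asarray(sigma_map, dtype=np.float64),
                                clean.frame_shape).copy()
        if np.any(sigma < 0):
            raise ValueError("sigma_map must be nonnegative")
    noise = np.empty_like(clean.voxels)
    for s in range(clean.n_slices):
        for d in range(clean.n_dynamics):
            rng = np.random.default_rng([seed, s, d])
            noise[s, d] = rng.standard_normal(clean.frame_shape) * sigma
    noisy = ImageSeries(clean.voxels + noise, clean.pixel_spacing_mm,
                        clean.frame_interval_s)  # negatives kept by design
    return NoisySample(clean=clean, noise=noise, noisy=noisy, sigma_map=sigma,
                       target_snr=float(target_snr), roi_mask=roi_mask, seed=seed)
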