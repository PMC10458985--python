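"""Fourier ptychographic image formation.

Simulates the standard FPM acquisition: a programmable LED array illuminates a
thin sample from a grid of angles; for each LED the objective low-pass filters
the tilted-illumination field (a circular pupil of radius NA/lambda in the
coherent transfer function), and the camera records the intensity of the
low-resolution image.  In the Fourier picture each LED selects a circular
sub-region of the sample's high-resolution spectrum, so the stack of captures
tiles frequency space with overlapping discs.

Conventions
-----------
* Spectra are stored *centered* (DC at ``grid//2``, i.e. fftshift layout).
* The sub-spectrum for an LED is cropped at the nearest HR frequency pixel to
  the LED's (kx, ky) offset; sub-pixel shifts are not modelled.
* Cropped spectra are scaled by ``(lr_size / hr_size)**2`` so that a constant
  object of amplitude c yields a capture of intensity ``|c|**2`` and mean LR
  intensity equals mean low-passed HR intensity (Parseval-consistent).
* LEDs are ordered center-outward (bright field before dark field), ties
  broken clockwise starting at +x; this is the update order phase retrieval
  uses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "OpticsGeometry",
    "ComplexField",
    "LRStack",
    "led_spiral_order",
    "led_wavevectors",
    "make_pupil",
    "forward_capture",
    "simulate_stack",
    "spectral_overlap",
    "DEFAULT_GEOMETRY",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OpticsGeometry:
    """Geometry of the FPM acquisition.

    Parameters
    ----------
    numerical_aperture : objective NA (dimensionless, in (0, 1)).
    wavelength : illumination wavelength in micrometers.
    led_grid : LEDs per side of the square array (odd).
    led_pitch : center-to-center LED spacing in millimeters.
    led_height : LED plane to sample distance in millimeters.
    camera_pixel : sensor pixel size in micrometers.
    magnification : objective magnification (maps camera pixel to object plane).
    downsample_factor : ratio between the HR object grid and the LR capture grid.
    hr_size : pixels per side of the HR object grid.
    """

    numerical_aperture: float = 0.13
    wavelength: float = 0.505
    led_grid: int = 13
    led_pitch: float = 4.0
    led_height: float = 100.0
    camera_pixel: float = 6.5
    magnification: float = 4.0
    downsample_factor: int = 4
    hr_size: int = 192

    def __post_init__(self) -> None:
        if not (0.0 < self.numerical_aperture < 1.0):
            raise ValueError("numerical_aperture must be in (0, 1)")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if self.led_grid < 1 or self.led_grid % 2 == 0:
            raise ValueError("led_grid must be odd and >= 1")
        if self.led_height <= 0 or self.led_pitch <= 0:
            raise ValueError("led_height and led_pitch must be positive")
        if self.camera_pixel <= 0 or self.magnification <= 0:
            raise ValueError("camera_pixel and magnification must be positive")
        if self.downsample_factor < 1 or self.hr_size % self.downsample_factor:
            raise ValueError("downsample_factor must be >= 1 and divide hr_size")
        # Nyquist for the coherent cutoff on the LR (camera) grid
        if 1.0 / (2.0 * self.lr_pixel) < self.cutoff_frequency:
            raise ValueError(
                "LR pixel violates Nyquist for the coherent cutoff NA/lambda"
            )

    # -- derived quantities ------------------------------------------------
    @property
    def lr_size(self) -> int:
        return self.hr_size // self.downsample_factor

    @property
    def lr_pixel(self) -> float:
        """Object-plane LR pixel size (um)."""
        return self.camera_pixel / self.magnification

    @property
    def hr_pixel(self) -> float:
        """Object-plane HR pixel size (um)."""
        return self.lr_pixel / self.downsample_factor

    @property
    def cutoff_frequency(self) -> float:
        """Coherent cutoff NA/lambda (cycles/um)."""
        return self.numerical_aperture / self.wavelength

    @property
    def freq_step(self) -> float:
        """Frequency-grid pixel size, identical on HR and LR grids (cycles/um)."""
        return 1.0 / (self.hr_size * self.hr_pixel)

    @property
    def center_led(self) -> tuple[int, int]:
        c = self.led_grid // 2
        return (c, c)

    def to_dict(self) -> dict:
        return {
            "numerical_aperture": self.numerical_aperture,
            "wavelength": self.wavelength,
            "led_grid": self.led_grid,
            "led_pitch": self.led_pitch,
            "led_height": self.led_height,
            "camera_pixel": self.camera_pixel,
            "magnification": self.magnification,
            "downsample_factor": self.downsample_factor,
            "hr_size": self.hr_size,
        }

    def with_hr_size(self, hr_size: int) -> "OpticsGeometry":
        return replace(self, hr_size=hr_size)


DEFAULT_GEOMETRY = OpticsGeometry()


@dataclass
class ComplexField:
    """A square 2-D complex grid: object transmission (space) or spectrum
    (frequency, centered / fftshift layout).  ``pixel_size`` is um per pixel
    in space and cycles/um per pixel in frequency."""

    values: np.ndarray
    domain: str = "space"
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("ComplexField requires a square 2-D grid")
        if self.domain not in ("space", "frequency"):
            raise ValueError("domain must be 'space' or 'frequency'")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ComplexField values must be finite")

    @property
    def size(self) -> int:
        return self.values.shape[0]

    def to_frequency(self) -> "ComplexField":
        if self.domain == "frequency":
            return self
        spec = np.fft.fftshift(np.fft.fft2(self.values))
        return ComplexField(spec, "frequency", 1.0 / (self.size * self.pixel_size))

    def to_space(self) -> "ComplexField":
        if self.domain == "space":
            return self
        vals = np.fft.ifft2(np.fft.ifftshift(self.values))
        return ComplexField(vals, "space", 1.0 / (self.size * self.pixel_size))


@dataclass
class LRStack:
    """Low-resolution intensity captures, one per LED, in spiral order."""

    images: np.ndarray  # (N, lr, lr) non-negative
    led_indices: list  # [(row, col)] aligned with images
    geometry: OpticsGeometry
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float64)
        n = self.geometry.lr_size
        if self.images.ndim != 3 or self.images.shape[1:] != (n, n):
            raise ValueError(f"stack images must have shape (N, {n}, {n})")
        if len(self.led_indices) != self.images.shape[0]:
            raise ValueError("led_indices length must match image count")
        if np.any(self.images < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_leds(self) -> int:
        return self.images.shape[0]

    def led_position(self, led: tuple) -> int:
        try:
            return self.led_indices.index(tuple(led))
        except ValueError:
            raise KeyError(f"LED {led} not in stack") from None


# ---------------------------------------------------------------------------
# LED geometry
# ---------------------------------------------------------------------------

def led_spiral_order(geometry: OpticsGeometry) -> list:
    """All (row, col) LED indices sorted center-outward, ties clockwise from +x.

    Row increases with +y, column with +x; the array center is the on-axis LED.
    """
    c = geometry.led_grid // 2
    leds = [(r, q) for r in range(geometry.led_grid) for q in range(geometry.led_grid)]

    def key(led):
        x = led[1] - c
        y = led[0] - c
        ang = math.atan2(-y, x) % (2.0 * math.pi)  # clockwise starting at +x
        return (x * x + y * y, ang)

    return sorted(leds, key=key)


def led_wavevector(geometry: OpticsGeometry, led: tuple) -> tuple:
    """Spatial-frequency offset (kx, ky) in cycles/um for one LED.

    kx = sin(theta_x)/lambda with sin(theta_x) = x / sqrt(x^2 + y^2 + h^2)
    where (x, y) is the LED's in-plane position and h the array height.
    """
    c = geometry.led_grid // 2
    x = (led[1] - c) * geometry.led_pitch
    y = (led[0] - c) * geometry.led_pitch
    rho = math.sqrt(x * x + y * y + geometry.led_height**2)
    return (x / rho / geometry.wavelength, y / rho / geometry.wavelength)


def led_wavevectors(geometry: OpticsGeometry) -> np.ndarray:
    """(kx, ky) offsets for every LED, in spiral order; center LED -> (0, 0)."""
    return np.array([led_wavevector(geometry, led) for led in led_spiral_order(geometry)])


# ---------------------------------------------------------------------------
# Pupil and forward model
# ---------------------------------------------------------------------------

def make_pupil(geometry: OpticsGeometry, size: int | None = None) -> np.ndarray:
    """Binary coherent transfer function on the (centered) LR frequency grid.

    1 inside radius NA/lambda, 0 outside.  Raises if the pupil would not fit
    inside the grid's Nyquist range.
    """
    n = geometry.lr_size if size is None else size
    df = geometry.freq_step
    radius_px = geometry.cutoff_frequency / df
    if radius_px > n // 2:
        raise ValueError("pupil radius exceeds the LR grid's Nyquist frequency")
    u = (np.arange(n) - n // 2) * df
    uu, vv = np.meshgrid(u, u, indexing="xy")
    return (uu**2 + vv**2 <= geometry.cutoff_frequency**2).astype(np.float64)


def _crop_bounds(geometry: OpticsGeometry, led: tuple) -> tuple:
    """(row_lo, col_lo) of the LR-size crop window in the HR spectrum for an LED."""
    kx, ky = led_wavevector(geometry, led)
    df = geometry.freq_step
    n, N = geometry.lr_size, geometry.hr_size
    cx = N // 2 + int(round(kx / df))
    cy = N // 2 + int(round(ky / df))
    row_lo = cy - n // 2
    col_lo = cx - n // 2
    if row_lo < 0 or col_lo < 0 or row_lo + n > N or col_lo + n > N:
        raise ValueError(f"shifted pupil support for LED {led} exceeds HR spectrum")
    return row_lo, col_lo


def forward_capture(
    obj: ComplexField,
    geometry: OpticsGeometry,
    led: tuple,
    hr_spectrum: np.ndarray | None = None,
    pupil: np.ndarray | None = None,
) -> np.ndarray:
    """Noise-free LR intensity capture for one LED.

    The HR spectrum is cropped around the LED's (kx, ky) offset, multiplied by
    the pupil, scaled by (lr/hr)^2, and inverse-transformed; the capture is the
    squared modulus.  ``hr_spectrum``/``pupil`` may be precomputed to amortize
    work across LEDs.
    """
    if obj is not None:
        if obj.domain != "space":
            raise ValueError("object must be in the space domain")
        if obj.size != geometry.hr_size:
            raise ValueError("object side must equal hr_size")
    if hr_spectrum is None:
        hr_spectrum = np.fft.fftshift(np.fft.fft2(obj.values))
    if pupil is None:
        pupil = make_pupil(geometry)
    n, N = geometry.lr_size, geometry.hr_size
    r, c = _crop_bounds(geometry, led)
    crop = hr_spectrum[r : r + n, c : c + n] * pupil * (n / N) ** 2
    field = np.fft.ifft2(np.fft.ifftshift(crop))
    return np.abs(field) ** 2


def simulate_stack(
    obj: ComplexField,
    geometry: OpticsGeometry,
    noise_sigma: float = 3e-4,
    seed: int = 0,
) -> LRStack:
    """Simulate the full acquisition: one capture per LED in spiral order.

    Intensities are normalized to a stack-wide peak of 1, then i.i.d. Gaussian
    noise of standard deviation ``noise_sigma`` is added and negative values
    are clipped to zero (a camera cannot record negative counts).
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    order = led_spiral_order(geometry)
    spectrum = np.fft.fftshift(np.fft.fft2(obj.values))
    pupil = make_pupil(geometry)
    images = np.stack(
        [forward_capture(obj, geometry, led, spectrum, pupil) for led in order]
    )
    peak = images.max()
    if peak > 0:
        images = images / peak
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        images = images + rng.normal(0.0, noise_sigma, size=images.shape)
        np.clip(images, 0.0, None, out=images)
    return LRStack(images, order, geometry, noise_sigma)


def synthetic_aperture_mask(geometry: OpticsGeometry) -> np.ndarray:
    """Union of all LED-shifted pupil discs on the HR frequency grid.

    This is the passband FPM can synthesize: objective NA extended by the
    maximum illumination NA.  Content outside it is invisible to every capture
    and hence unrecoverable by any reconstruction method.
    """
    N = geometry.hr_size
    df = geometry.freq_step
    u = (np.arange(N) - N // 2) * df
    uu, vv = np.meshgrid(u, u, indexing="xy")
    mask = np.zeros((N, N), dtype=bool)
    r2 = geometry.cutoff_frequency**2
    for kx, ky in led_wavevectors(geometry):
        mask |= (uu - kx) ** 2 + (vv - ky) ** 2 <= r2
    return mask


def bandlimit_field(obj: ComplexField, geometry: OpticsGeometry) -> ComplexField:
    """Project a space-domain field onto the synthetic aperture passband.

    Useful for building test objects that are fully recoverable, so
    reconstruction quality reflects the solver rather than missing physics.
    """
    spec = np.fft.fftshift(np.fft.fft2(obj.values)) * synthetic_aperture_mask(geometry)
    return ComplexField(
        np.fft.ifft2(np.fft.ifftshift(spec)), "space", obj.pixel_size
    )


def spectral_overlap(geometry: OpticsGeometry) -> float:
    """Pupil-disc area overlap fraction between horizontally adjacent LEDs.

    Uses the circle-circle intersection area with both discs of radius
    NA/lambda and centers separated by the adjacent-LED wavevector offset.
    Values >= ~0.6 indicate a well-posed phase-retrieval dataset.
    """
    if geometry.led_grid < 2:
        raise ValueError("spectral_overlap requires led_grid >= 2")
    c = geometry.center_led
    k0 = led_wavevector(geometry, c)
    k1 = led_wavevector(geometry, (c[0], c[1] + 1))
    d = math.hypot(k1[0] - k0[0], k1[1] - k0[1])
    r = geometry.cutoff_frequency
    if d >= 2.0 * r:
        return 0.0
    area = 2.0 * r * r * math.acos(d / (2.0 * r)) - 0.5 * d * math.sqrt(
        4.0 * r * r - d * d
    )
    return area / (math.pi * r * r)
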