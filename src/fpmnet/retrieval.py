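"""Iterative phase retrieval (spectrum stitching) for FPM.

Recovers the high-resolution complex object from the LED intensity stack by
sequentially replacing, inside each LED's pupil support, the modulus of the
estimated low-resolution field with the measured one (Gerchberg-Saxton-style
alternating projections), sweeping LEDs center-outward so low frequencies are
fixed before dark-field extensions.

Two solvers are provided:

* ``gs_reconstruct`` -- plain sequential amplitude replacement ("GS").
* ``as_reconstruct`` -- the same update damped by a step size alpha that halves
  whenever an iteration improves the data-fidelity error by less than 1%
  ("AS", adaptive step size); damping suppresses the noise-floor oscillation
  of the plain update.

``one_iteration_init`` runs a single GS sweep and converts the field to the
two-channel (intensity, phase) image representation: this is the
low-resolution complex-amplitude input the reconstruction network consumes.

Note the global phase gauge: all captures are invariant to multiplying the
object by exp(i*phi0), so phase comparisons must use
``align_global_phase`` first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .optics import ComplexField, LRStack, _crop_bounds, make_pupil

__all__ = [
    "ReconResult",
    "initialize_spectrum",
    "gs_reconstruct",
    "as_reconstruct",
    "one_iteration_init",
    "complex_to_channels",
    "channels_to_complex",
    "align_global_phase",
    "stack_error",
]


@dataclass
class ReconResult:
    """Space-domain HR field plus the per-iteration data-fidelity trace.

    ``error_history[i]`` is E = sum((sqrt(I_est) - sqrt(I_meas))^2) / sum(I_meas)
    accumulated over all LEDs during sweep i (estimates taken just before each
    LED's update).
    """

    field: ComplexField
    error_history: np.ndarray
    iterations_run: int

    def __post_init__(self) -> None:
        self.error_history = np.asarray(self.error_history, dtype=np.float64)
        if len(self.error_history) != self.iterations_run:
            raise ValueError("error_history length must equal iterations_run")
        if np.any(self.error_history < 0) or not np.all(np.isfinite(self.error_history)):
            raise ValueError("errors must be finite and non-negative")


def initialize_spectrum(stack: LRStack) -> ComplexField:
    """Standard FPM initialization: Fourier-upsampled center-LED amplitude,
    zero phase; the HR spectrum is zero outside the center pupil support."""
    g = stack.geometry
    idx = stack.led_position(g.center_led)
    amp = np.sqrt(stack.images[idx])
    n, N, D = g.lr_size, g.hr_size, g.downsample_factor
    spec_lr = np.fft.fftshift(np.fft.fft2(amp)) * D**2 * make_pupil(g)
    spec = np.zeros((N, N), dtype=np.complex128)
    r, c = _crop_bounds(g, g.center_led)
    spec[r : r + n, c : c + n] = spec_lr
    return ComplexField(spec, "frequency", g.freq_step)


def _sweep(
    spectrum: np.ndarray,
    stack: LRStack,
    pupil: np.ndarray,
    alpha: float,
) -> float:
    """One pass over all LEDs, updating ``spectrum`` in place.

    Returns the data-fidelity error accumulated with pre-update estimates.
    """
    g = stack.geometry
    n, N, D = g.lr_size, g.hr_size, g.downsample_factor
    scale = (n / N) ** 2
    mask = pupil > 0
    num = 0.0
    den = 0.0
    for led, meas in zip(stack.led_indices, stack.images):
        r, c = _crop_bounds(g, led)
        region = spectrum[r : r + n, c : c + n]
        psi = np.fft.ifft2(np.fft.ifftshift(region * pupil * scale))
        amp_est = np.abs(psi)
        amp_meas = np.sqrt(meas)
        num += float(np.sum((amp_est - amp_meas) ** 2))
        den += float(np.sum(meas))
        # replace modulus, keep phase (zero-amplitude pixels get the measured modulus)
        phase = np.where(amp_est > 1e-30, psi / np.maximum(amp_est, 1e-300), 1.0)
        psi_new = amp_meas * phase
        phi = np.fft.fftshift(np.fft.fft2(psi_new)) / scale
        region[mask] = region[mask] + alpha * (phi[mask] - region[mask])
    return num / max(den, 1e-300)


def _run(
    stack: LRStack,
    n_iter: int,
    alpha0: float,
    decay: float | None,
) -> ReconResult:
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    g = stack.geometry
    spectrum = initialize_spectrum(stack).values
    pupil = make_pupil(g)
    alpha = alpha0
    errors = []
    for _ in range(n_iter):
        err = _sweep(spectrum, stack, pupil, alpha)
        errors.append(err)
        if decay is not None and len(errors) >= 2:
            prev, cur = errors[-2], errors[-1]
            if (prev - cur) < 0.01 * max(prev, 1e-300):
                alpha *= decay
    field = np.fft.ifft2(np.fft.ifftshift(spectrum))
    return ReconResult(
        ComplexField(field, "space", g.hr_pixel), np.array(errors), n_iter
    )


def gs_reconstruct(stack: LRStack, n_iter: int = 50) -> ReconResult:
    """Plain sequential amplitude-replacement reconstruction (GS baseline)."""
    return _run(stack, n_iter, alpha0=1.0, decay=None)


def as_reconstruct(
    stack: LRStack, n_iter: int = 50, alpha0: float = 1.0, decay: float = 0.5
) -> ReconResult:
    """Adaptive step-size reconstruction (AS baseline).

    Identical update to :func:`gs_reconstruct` but spectrum writes are scaled
    by a step alpha, halved (by ``decay``) whenever an iteration's relative
    error improvement falls below 1%.
    """
    if alpha0 <= 0:
        raise ValueError("alpha0 must be positive")
    if not (0.0 < decay < 1.0):
        raise ValueError("decay must be in (0, 1)")
    return _run(stack, n_iter, alpha0=alpha0, decay=decay)


def stack_error(field_or_spectrum: ComplexField, stack: LRStack) -> float:
    """Data-fidelity error E of a fixed HR field against a measured stack."""
    g = stack.geometry
    spec = field_or_spectrum.to_frequency().values
    n, N = g.lr_size, g.hr_size
    pupil = make_pupil(g)
    scale = (n / N) ** 2
    num = 0.0
    den = 0.0
    for led, meas in zip(stack.led_indices, stack.images):
        r, c = _crop_bounds(g, led)
        psi = np.fft.ifft2(np.fft.ifftshift(spec[r : r + n, c : c + n] * pupil * scale))
        num += float(np.sum((np.abs(psi) - np.sqrt(meas)) ** 2))
        den += float(np.sum(meas))
    return num / max(den, 1e-300)


# ---------------------------------------------------------------------------
# Channel encoding
# ---------------------------------------------------------------------------

def complex_to_channels(f: ComplexField) -> np.ndarray:
    """Encode a space-domain field as a (2, N, N) image.

    Channel 0 is intensity |f|^2 normalized to peak 1; channel 1 is the phase
    mapped linearly from [-pi, pi] to [0, 1].
    """
    if f.domain != "space":
        raise ValueError("field must be in the space domain")
    intensity = np.abs(f.values) ** 2
    peak = intensity.max()
    if peak > 0:
        intensity = intensity / peak
    phase = (np.angle(f.values) + np.pi) / (2.0 * np.pi)
    return np.stack([intensity, phase])


def channels_to_complex(image: np.ndarray, pixel_size: float = 1.0) -> ComplexField:
    """Inverse of :func:`complex_to_channels`: sqrt(intensity)*exp(i*phase)."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3 or image.shape[0] != 2:
        raise ValueError("expected a (2, N, N) channel image")
    if np.any(image[1] < 0) or np.any(image[1] > 1):
        raise ValueError("phase channel values must lie in [0, 1]")
    amp = np.sqrt(np.clip(image[0], 0.0, None))
    phase = image[1] * 2.0 * np.pi - np.pi
    return ComplexField(amp * np.exp(1j * phase), "space", pixel_size)


def one_iteration_init(stack: LRStack) -> np.ndarray:
    """One GS sweep, channel-encoded: the network's LR complex-amplitude input."""
    result = gs_reconstruct(stack, n_iter=1)
    return complex_to_channels(result.field)


def align_global_phase(est: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Rotate ``est`` by the phase of <est, ref> so phase metrics are gauge-free."""
    inner = np.vdot(ref, est)
    if np.abs(inner) == 0:
        return est
    return est * np.exp(-1j * np.angle(inner))
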