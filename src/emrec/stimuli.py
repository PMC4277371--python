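"""Stimulus synthesis: binarization and weighted-mean-phase degradation.

Emergent-recognition stimuli are two-tone images made by thresholding a
grayscale image (monochromatic binarization).  Perceptual-decision stimuli
are graded degradations made in the Fourier domain by the weighted mean
phase (WMP) technique: each spectral phase is replaced by the angle of
``w*e^{i*theta_image} + (1-w)*e^{i*theta_noise}`` with uniform noise phase,
and each magnitude by ``w*|F_image| + (1-w)*avg_magnitude`` where the
average magnitude is taken over the whole stimulus set.  The signal weight
``w`` in [0.2, 0.6] is binned into classes 1-10 of width 0.04.  Outputs
are normalized to a target mean luminance and RMS contrast.
"""

from __future__ import annotations

import numpy as np

from .coincidence import ParameterError

__all__ = [
    "binarize",
    "average_magnitude",
    "wmp_degrade",
    "normalize_image",
    "assign_sn_class",
    "load_gray",
    "save_gray",
]


def _as_float_image(image) -> np.ndarray:
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2:
        raise ParameterError("expected a 2-D grayscale image")
    if not np.all(np.isfinite(arr)):
        raise ParameterError("image contains non-finite values")
    return arr


def binarize(image, threshold: float) -> np.ndarray:
    """Monochromatic binarization: pixel >= threshold -> 255, else 0."""
    arr = _as_float_image(image)
    return np.where(arr >= threshold, 255, 0).astype(np.uint8)


def average_magnitude(images) -> np.ndarray:
    """Element-wise mean of discrete-Fourier magnitude spectra.

    Under the unnormalized transform convention the zero-frequency element
    equals mean luminance times pixel count.
    """
    mags = None
    shape = None
    n = 0
    for img in images:
        arr = _as_float_image(img)
        if shape is None:
            shape = arr.shape
            mags = np.zeros(shape)
        elif arr.shape != shape:
            raise ParameterError(f"shape mismatch: {arr.shape} vs {shape}")
        mags += np.abs(np.fft.fft2(arr))
        n += 1
    if n == 0:
        raise ParameterError("need at least one image")
    return mags / n


def _hermitian_uniform_phases(shape, rng: np.random.Generator) -> np.ndarray:
    """Uniform(-pi, pi] phases with phi(-k) = -phi(k) so outputs stay real.

    Realised as the phase field of the FFT of white Gaussian noise: the
    transform of a real field is Hermitian by construction and the phases
    of complex-Gaussian spectral entries are uniform.  Self-conjugate
    elements (DC, Nyquist) come out 0 or pi, as Hermitian symmetry demands.
    """
    return np.angle(np.fft.fft2(rng.standard_normal(shape)))


def wmp_degrade(
    image,
    w: float,
    avg_magnitude: np.ndarray,
    rng_seed: int | np.random.Generator | None = None,
    imag_tol: float = 1e-8,
) -> np.ndarray:
    """Weighted-mean-phase degradation of one image.

    New phase: angle of ``w*e^{i*theta} + (1-w)*e^{i*theta_noise}`` with
    Hermitian-symmetric uniform noise phases (one draw per conjugate pair).
    New magnitude: ``w*|F| + (1-w)*avg_magnitude``.  Returns the real part
    of the inverse transform; raises if the imaginary residue exceeds
    ``imag_tol`` of the dynamic range.
    """
    if not (0.0 <= w <= 1.0):
        raise ParameterError("w must lie in [0, 1]")
    arr = _as_float_image(image)
    avg = np.asarray(avg_magnitude, dtype=float)
    if avg.shape != arr.shape:
        raise ParameterError("avg_magnitude shape must match the image")
    rng = np.random.default_rng(rng_seed)
    spec = np.fft.fft2(arr)
    theta = np.angle(spec)
    theta_noise = _hermitian_uniform_phases(arr.shape, rng)
    mixed = w * np.exp(1j * theta) + (1.0 - w) * np.exp(1j * theta_noise)
    # w=0 must take the noise phase even where the mixed vector vanishes
    new_phase = np.angle(np.where(np.abs(mixed) > 0, mixed, np.exp(1j * theta_noise)))
    # self-conjugate entries (DC, Nyquist) must stay real: their two phase
    # components are each 0 or pi, and at w ~ 0.5 they can cancel, leaving a
    # numerically arbitrary angle -- snap to the sign of the real part
    n0, n1 = arr.shape
    ii = np.arange(n0)[:, None]
    jj = np.arange(n1)[None, :]
    selfconj = ((-ii) % n0 == ii) & ((-jj) % n1 == jj)
    snapped = np.where(np.real(mixed) >= 0.0, 0.0, np.pi)
    new_phase = np.where(selfconj, snapped, new_phase)
    new_mag = w * np.abs(spec) + (1.0 - w) * avg
    out = np.fft.ifft2(new_mag * np.exp(1j * new_phase))
    scale = max(np.ptp(out.real), 1.0)
    if np.max(np.abs(out.imag)) > imag_tol * scale:
        raise RuntimeError("Hermitian symmetry violated: imaginary residue above tolerance")
    return out.real


def normalize_image(image, target_mean: float, target_rms: float) -> np.ndarray:
    """Affine map to an exact target mean luminance and RMS contrast.

    RMS contrast is the standard deviation of luminance.  Zero-contrast
    inputs have no such map and raise.
    """
    arr = _as_float_image(image)
    sd = arr.std()
    if sd == 0:
        raise ParameterError("zero-contrast image cannot be normalized")
    if target_rms < 0:
        raise ParameterError("target_rms must be nonnegative")
    return (arr - arr.mean()) / sd * target_rms + target_mean


def assign_sn_class(w: float) -> int:
    """Signal-to-noise class 1-10 for weight w in [0.2, 0.6].

    Half-open bins of width 0.04 starting at 0.2 ([0.2, 0.24) is class 1),
    with the last bin closed at 0.6.
    """
    if not (0.2 <= w <= 0.6):
        raise ParameterError("w must lie in [0.2, 0.6]")
    cls = int(np.floor((w - 0.2) / 0.04 + 1e-12)) + 1
    return min(cls, 10)


def load_gray(path) -> np.ndarray:
    """Read a PNG/TIFF image as a float grayscale array (0-255 scale)."""
    from PIL import Image

    with Image.open(path) as im:
        return np.asarray(im.convert("F"), dtype=float)


def save_gray(image, path) -> None:
    """Write a float grayscale array as 8-bit PNG/TIFF (clipped to 0-255)."""
    from PIL import Image

    arr = np.clip(_as_float_image(image), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)
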