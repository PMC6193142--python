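"""Per-particle corrections applied before alignment.

The fixed order is phase-flip CTF correction, then edge-mean
normalization, then top-hat band-pass filtering (600 Angstrom high-pass /
20 Angstrom low-pass defaults).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import ParticleStack

__all__ = [
    "CTFParams",
    "ctf_function",
    "phase_flip",
    "edge_mean_normalize",
    "bandpass_tophat",
    "preprocess_stack",
]


@dataclass
class CTFParams:
    """Contrast transfer function parameters.

    ``defocus`` follows the printed convention where negative values mean
    underfocus (e.g. -0.75 um); ``amplitude_contrast`` is the fractional
    amplitude-contrast term.
    """

    defocus: float = -0.75  # um, negative = underfocus
    voltage: float = 120.0  # kV
    spherical_aberration: float = 2.0  # mm
    amplitude_contrast: float = 0.10
    pixel_size: float = 4.0  # Angstrom / px

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")
        if not 0.0 <= self.amplitude_contrast <= 1.0:
            raise ValueError("amplitude contrast must be in [0, 1]")

    @property
    def wavelength(self) -> float:
        """Relativistic electron wavelength in Angstrom."""
        v = self.voltage * 1e3
        return 12.2639 / np.sqrt(v * (1.0 + 0.97845e-6 * v))


def ctf_function(ctf: CTFParams, k: np.ndarray) -> np.ndarray:
    """CTF value at spatial frequency ``k`` (1/Angstrom).

    CTF(k) = sqrt(1 - A^2) sin(chi) + A cos(chi) with the standard phase
    chi(k) = pi lambda dz k^2 - (pi/2) Cs lambda^3 k^4, underfocus dz > 0
    (the printed negative defocus convention maps to positive dz).  The
    sign is chosen positive at low frequency, so an image whose band lies
    entirely before the first zero is left unchanged by phase flipping.
    """
    lam = ctf.wavelength
    dz = -ctf.defocus * 1e4  # um -> Angstrom, printed negative = underfocus
    cs = ctf.spherical_aberration * 1e7  # mm -> Angstrom
    chi = np.pi * lam * dz * k ** 2 - 0.5 * np.pi * cs * lam ** 3 * k ** 4
    a = ctf.amplitude_contrast
    return np.sqrt(1.0 - a * a) * np.sin(chi) + a * np.cos(chi)


def first_ctf_zero(ctf: CTFParams, k_max: float | None = None) -> float:
    """Smallest positive frequency (1/Angstrom) where the CTF crosses zero."""
    if k_max is None:
        k_max = 1.0 / (2.0 * ctf.pixel_size)
    ks = np.linspace(1e-5, k_max, 20000)
    vals = ctf_function(ctf, ks)
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if len(sign_change) == 0:
        raise ValueError("CTF has no zero below Nyquist")
    i = sign_change[0]
    # linear interpolation of the crossing
    k0, k1 = ks[i], ks[i + 1]
    v0, v1 = vals[i], vals[i + 1]
    return float(k0 - v0 * (k1 - k0) / (v1 - v0))


def phase_flip(image: np.ndarray, ctf: CTFParams) -> np.ndarray:
    """Multiply Fourier coefficients by the sign of the CTF.

    The DC term is left untouched; applying the operation twice returns the
    original image to machine precision.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("phase_flip expects a square 2D image")
    n = image.shape[0]
    f = np.fft.fftfreq(n, d=ctf.pixel_size)
    kx, ky = np.meshgrid(f, f, indexing="ij")
    k = np.hypot(kx, ky)
    sign = np.where(ctf_function(ctf, k) < 0.0, -1.0, 1.0)
    sign[0, 0] = 1.0  # DC untouched
    out = np.fft.ifft2(np.fft.fft2(image) * sign).real
    return out


def edge_mean_normalize(image: np.ndarray) -> np.ndarray:
    """Zero the 1-px border-ring mean and scale to unit global S.D.

    Output = (input - border mean) / S.D.(input - border mean).  A constant
    input maps to all zeros (with a RuntimeWarning).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or min(image.shape) < 3:
        raise ValueError("edge_mean_normalize expects an image of at least 3x3")
    border = np.concatenate([image[0, :], image[-1, :],
                             image[1:-1, 0], image[1:-1, -1]])
    out = image - border.mean()
    sd = out.std()
    if sd == 0.0:
        warnings.warn("constant image: normalized output is all zeros",
                      RuntimeWarning, stacklevel=2)
        return np.zeros_like(image)
    return out / sd


def bandpass_tophat(image: np.ndarray, pixel_size: float,
                    highpass: float = 600.0, lowpass: float = 20.0) -> np.ndarray:
    """Hard (top-hat) band-pass in cycles/Angstrom.

    Fourier amplitudes at radial frequencies outside
    ``[1/highpass, 1/lowpass]`` are set to zero (hard edges, DC removed).
    """
    image = np.asarray(image, dtype=np.float64)
    nyquist = 1.0 / (2.0 * pixel_size)
    if not highpass > lowpass:
        raise ValueError("highpass wavelength must exceed lowpass wavelength")
    if 1.0 / lowpass > nyquist:
        raise ValueError(
            f"lowpass of {lowpass} A is beyond Nyquist ({1.0 / nyquist:.2f} A "
            f"at {pixel_size} A/px)"
        )
    fy = np.fft.fftfreq(image.shape[0], d=pixel_size)
    fx = np.fft.fftfreq(image.shape[1], d=pixel_size)
    k = np.hypot(*np.meshgrid(fy, fx, indexing="ij"))
    keep = (k >= 1.0 / highpass) & (k <= 1.0 / lowpass)
    return np.fft.ifft2(np.fft.fft2(image) * keep).real


def preprocess_stack(stack: ParticleStack, ctf: CTFParams | None = None,
                     highpass: float = 600.0, lowpass: float = 20.0) -> ParticleStack:
    """Apply phase-flip (if ``ctf`` given), edge-mean normalize, band-pass."""
    out = np.empty_like(stack.data, dtype=np.float32)
    for i in range(len(stack)):
        img = stack.data[i].astype(np.float64)
        if ctf is not None:
            img = phase_flip(img, ctf)
        img = edge_mean_normalize(img)
        img = bandpass_tophat(img, stack.pixel_size, highpass, lowpass)
        out[i] = img
    return ParticleStack(out, stack.pixel_size,
                         provenance=stack.provenance + " | preprocessed")
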