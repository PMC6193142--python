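"""Resolution estimation and class-average diagnostics.

Resolution is quoted where the Fourier shell correlation between two
half-set reconstructions first crosses 0.5.  Class averages come from a
reference-free classifier (principal components of aligned, masked pixels
followed by k-means) — a deliberate simplification of multivariate
statistical classification, adequate for diagnosing alignment quality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import FSCCurve, ParticleStack, Volume3D

__all__ = [
    "compute_fsc",
    "resolution_at_threshold",
    "ResolutionEstimate",
    "classify_and_average",
]


def compute_fsc(v1: Volume3D, v2: Volume3D) -> FSCCurve:
    """Fourier shell correlation between two volumes on the same grid.

    Per concentric shell of width one Fourier pixel, the normalized real
    part of the complex correlation of the two transforms.
    ``compute_fsc(v, v)`` is 1 in every shell and the operation is
    symmetric in its arguments.
    """
    if v1.shape != v2.shape:
        raise ValueError("volumes must share a grid")
    if abs(v1.voxel_size - v2.voxel_size) > 1e-6:
        raise ValueError("volumes must share a voxel size")
    n = v1.shape[0]
    f1 = np.fft.fftn(v1.data.astype(np.float64))
    f2 = np.fft.fftn(v2.data.astype(np.float64))
    freqs = [np.fft.fftfreq(s) * s for s in v1.shape]
    kz, ky, kx = np.meshgrid(*freqs, indexing="ij")
    shell = np.round(np.sqrt(kz ** 2 + ky ** 2 + kx ** 2)).astype(int).ravel()
    n_shells = n // 2
    cross = np.bincount(shell, weights=(f1 * np.conj(f2)).real.ravel(),
                        minlength=n_shells + 1)
    p1 = np.bincount(shell, weights=(np.abs(f1) ** 2).ravel(), minlength=n_shells + 1)
    p2 = np.bincount(shell, weights=(np.abs(f2) ** 2).ravel(), minlength=n_shells + 1)
    s = np.arange(1, n_shells + 1)
    den = np.sqrt(p1[s] * p2[s])
    vals = np.where(den > 0, cross[s] / np.where(den > 0, den, 1.0), 0.0)
    freqs_inv_a = s / (n * v1.voxel_size)
    return FSCCurve(freqs_inv_a, vals)


@dataclass
class ResolutionEstimate:
    resolution: float  # Angstrom
    reached: bool  # False when the curve never crosses the threshold


def resolution_at_threshold(curve: FSCCurve, threshold: float = 0.5) -> ResolutionEstimate:
    """Resolution (Angstrom) at the first crossing below ``threshold``.

    The crossing frequency is located by linear interpolation between
    adjacent shells.  A curve that never crosses returns the Nyquist limit
    flagged as not reached.
    """
    if len(curve.values) == 0:
        raise ValueError("empty FSC curve")
    vals, freqs = curve.values, curve.frequencies
    below = np.nonzero(vals < threshold)[0]
    if len(below) == 0:
        return ResolutionEstimate(resolution=1.0 / freqs[-1], reached=False)
    i = int(below[0])
    if i == 0:
        return ResolutionEstimate(resolution=1.0 / freqs[0], reached=False)
    f1, f2 = freqs[i - 1], freqs[i]
    v1, v2 = vals[i - 1], vals[i]
    fc = f1 + (v1 - threshold) / (v1 - v2) * (f2 - f1)
    return ResolutionEstimate(resolution=float(1.0 / fc), reached=True)


def classify_and_average(stack: ParticleStack, k: int, seed: int = 0,
                         mask: np.ndarray | None = None,
                         n_components: int = 20):
    """Reference-free classification of an aligned stack.

    Masked pixels are reduced by principal components and clustered with
    k-means; each class average is the mean of its members.  Deterministic
    for a fixed seed.

    Returns ``(averages, labels)`` with ``averages`` of shape (k, h, w).
    """
    n = len(stack)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the stack size {n}")
    data = stack.data.reshape(n, -1).astype(np.float64)
    if mask is not None:
        data = data[:, np.asarray(mask).astype(bool).ravel()]
    if k == 1:
        labels = np.zeros(n, dtype=int)
    else:
        from sklearn.cluster import KMeans
        from sklearn.decomposition import PCA
        n_comp = min(n_components, n - 1, data.shape[1])
        feats = PCA(n_components=n_comp, random_state=seed).fit_transform(data)
        labels = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(feats)
    averages = np.stack([stack.data[labels == c].mean(axis=0) for c in range(k)])
    return averages, labels
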