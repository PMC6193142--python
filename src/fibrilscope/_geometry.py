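"""Raster rotation/shift primitives with exact paths for right angles.

Linear (order-1) interpolation throughout; two rotations are never composed
on rasters — angles are composed first, then applied once.  Rotations by
multiples of 90 degrees use flip/transpose paths so that imposed symmetries
can be exact to machine precision on even-sized grids.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "rotate_image",
    "rotate_volume_z",
    "rotate_volume_y",
    "shift_image",
]


def _right_angle_k(angle: float) -> int | None:
    a = angle % 360.0
    k = round(a / 90.0)
    if abs(a - 90.0 * k) < 1e-9:
        return k % 4
    return None


def rotate_image(image: np.ndarray, angle: float, order: int = 1) -> np.ndarray:
    """Rotate a 2D image about its center; exact for multiples of 90 deg.

    The rotation direction matches ``skimage.transform.radon``'s ``theta``:
    ``rotate_image(im, a).sum(axis=0) == radon(im, [a])`` for square ``im``.
    """
    k = _right_angle_k(angle)
    if k is not None:
        if image.shape[0] == image.shape[1]:
            return np.ascontiguousarray(np.rot90(image, k=k))
        if k == 0:
            return image.copy()
        if k == 2:
            return np.ascontiguousarray(image[::-1, ::-1])
    return ndimage.rotate(image, angle, axes=(0, 1), reshape=False, order=order,
                          mode="constant", cval=0.0)


def rotate_volume_z(volume: np.ndarray, angle: float, order: int = 1) -> np.ndarray:
    """Rotate a (z, y, x) volume about the z axis."""
    k = _right_angle_k(angle)
    if k is not None and volume.shape[1] == volume.shape[2]:
        return np.ascontiguousarray(np.rot90(volume, k=k, axes=(1, 2)))
    return ndimage.rotate(volume, angle, axes=(1, 2), reshape=False, order=order,
                          mode="constant", cval=0.0)


def rotate_volume_y(volume: np.ndarray, angle: float, order: int = 1) -> np.ndarray:
    """Rotate a (z, y, x) volume about the y axis (the tilt axis)."""
    k = _right_angle_k(angle)
    if k is not None and volume.shape[0] == volume.shape[2]:
        return np.ascontiguousarray(np.rot90(volume, k=k, axes=(0, 2)))
    return ndimage.rotate(volume, angle, axes=(0, 2), reshape=False, order=order,
                          mode="constant", cval=0.0)


def shift_image(image: np.ndarray, dy: float, dx: float, order: int = 1) -> np.ndarray:
    """Shift a 2D image by (dy, dx) pixels; exact for integer shifts."""
    if float(dy).is_integer() and float(dx).is_integer():
        out = np.zeros_like(image)
        dy_i, dx_i = int(dy), int(dx)
        src_y = slice(max(0, -dy_i), min(image.shape[0], image.shape[0] - dy_i))
        src_x = slice(max(0, -dx_i), min(image.shape[1], image.shape[1] - dx_i))
        dst_y = slice(src_y.start + dy_i, src_y.stop + dy_i)
        dst_x = slice(src_x.start + dx_i, src_x.stop + dx_i)
        out[dst_y, dst_x] = image[src_y, src_x]
        return out
    return ndimage.shift(image, (dy, dx), order=order, mode="constant", cval=0.0)
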