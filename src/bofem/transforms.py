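"""In-plane image transforms shared by the simulator and the aligner.

The forward transform R(phi) with phi = (alpha, tx, ty) rotates by ``alpha``
degrees about the box center and then shifts by ``(tx, ty)`` pixels
(x = column, y = row).  The inverse applies the exact reverse order:
shift by (-tx, -ty), then rotate by -alpha.  Rotation interpolation is
bilinear; integer shifts are applied exactly with zero fill.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["rotate_image", "shift_image", "apply_transform", "apply_inverse_transform"]


def rotate_image(img: np.ndarray, alpha_deg: float, order: int = 1) -> np.ndarray:
    """Rotate counter-clockwise by ``alpha_deg`` about the box center."""
    if alpha_deg % 360.0 == 0.0:
        return img.copy()
    return ndimage.rotate(
        img, alpha_deg, reshape=False, order=order, mode="constant", cval=0.0,
        prefilter=(order > 1),
    )


def shift_image(img: np.ndarray, tx: int, ty: int) -> np.ndarray:
    """Shift by integer pixels (x=column, y=row), filling with zeros."""
    tx, ty = int(tx), int(ty)
    out = np.zeros_like(img)
    ny, nx = img.shape
    if abs(tx) >= nx or abs(ty) >= ny:
        return out
    src_y = slice(max(0, -ty), min(ny, ny - ty))
    src_x = slice(max(0, -tx), min(nx, nx - tx))
    dst_y = slice(max(0, ty), min(ny, ny + ty))
    dst_x = slice(max(0, tx), min(nx, nx + tx))
    out[dst_y, dst_x] = img[src_y, src_x]
    return out


def apply_transform(img: np.ndarray, alpha_deg: float, tx: int, ty: int,
                    order: int = 1) -> np.ndarray:
    """R(phi) = shift(tx, ty) o rotate(alpha)."""
    return shift_image(rotate_image(img, alpha_deg, order=order), tx, ty)


def apply_inverse_transform(img: np.ndarray, alpha_deg: float, tx: int, ty: int,
                            order: int = 1) -> np.ndarray:
    """R^{-1}(phi) = rotate(-alpha) o shift(-tx, -ty)."""
    return rotate_image(shift_image(img, -tx, -ty), -alpha_deg, order=order)
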