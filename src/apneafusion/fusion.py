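"""Fusing scalogram and spectrogram images into one RGB image.

The fused image carries the grayscale scalogram in its red channel, the
grayscale spectrogram in its green channel, and their saturating sum in
the blue channel, so both representations remain recoverable from the
result.
"""

from __future__ import annotations

import numpy as np

#: ITU-R BT.601 luma coefficients
_LUMA = np.array([0.2989, 0.5870, 0.1140])


def to_gray(image: np.ndarray) -> np.ndarray:
    """Convert an (H, W, 3) RGB image in [0, 1] to (H, W, 1) grayscale.

    gray = 0.2989 R + 0.5870 G + 0.1140 B.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) image, got shape {image.shape}")
    gray = image @ _LUMA
    return np.clip(gray, 0.0, 1.0)[..., None]


def fuse(scalogram_gray: np.ndarray, spectrogram_gray: np.ndarray) -> np.ndarray:
    """Build the fused RGB image from two grayscale images.

    R = scalogram gray (bit-exact), G = spectrogram gray (bit-exact),
    B = min(1, R + G) (saturating addition).
    """
    a = np.asarray(scalogram_gray, dtype=np.float64)
    b = np.asarray(spectrogram_gray, dtype=np.float64)
    if a.ndim == 3 and a.shape[-1] == 1:
        a = a[..., 0]
    if b.ndim == 3 and b.shape[-1] == 1:
        b = b[..., 0]
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError(f"grayscale shapes must match, got {a.shape} vs {b.shape}")
    for name, g in (("scalogram", a), ("spectrogram", b)):
        if g.min() < 0 or g.max() > 1:
            raise ValueError(f"{name} gray values must lie in [0, 1]")
    return np.stack([a, b, np.minimum(1.0, a + b)], axis=-1)
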