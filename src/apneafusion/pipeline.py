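"""End-to-end imaging pipeline: one-minute segment -> preprocessed signal
-> time-frequency representation(s) -> rendered (and possibly fused) RGB
image -> on-disk dataset with a CSV manifest."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import io as skio

from .fusion import fuse, to_gray
from .io import Segment
from .preprocess import PreprocessConfig, preprocess
from .synthetic import SynthSegment
from .tfr import (
    CWTConfig,
    SPWVDConfig,
    STFTConfig,
    cwt_scalogram,
    render_image,
    spwvd,
    stft_spectrogram,
)

IMAGE_KINDS = ("spectrogram", "scalogram", "spwvd", "fused")


@dataclass
class ImagingConfig:
    """All knobs of the segment -> image pathway."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    stft: STFTConfig = field(default_factory=STFTConfig)
    cwt: CWTConfig = field(default_factory=CWTConfig)
    spwvd: SPWVDConfig = field(default_factory=SPWVDConfig)
    dynamic_range: float = 80.0
    size: tuple[int, int] = (128, 128)


def segment_image(
    samples: np.ndarray, fs: float, kind: str, config: ImagingConfig | None = None
) -> np.ndarray:
    """Turn raw segment samples into one (H, W, 3) image of the given kind.

    ``fused`` renders both the scalogram and the spectrogram, grayscales
    each and blends them (R = scalogram, G = spectrogram, B = saturating
    sum).
    """
    config = config or ImagingConfig()
    if kind not in IMAGE_KINDS:
        raise ValueError(f"kind must be one of {IMAGE_KINDS}")
    x = preprocess(samples, config.preprocess)
    kwargs = {"dynamic_range": config.dynamic_range, "size": config.size}
    if kind == "spectrogram":
        return render_image(stft_spectrogram(x, fs, config.stft), **kwargs)
    if kind == "scalogram":
        return render_image(cwt_scalogram(x, fs, config.cwt), **kwargs)
    if kind == "spwvd":
        return render_image(spwvd(x, fs, config.spwvd), **kwargs)
    scal = render_image(cwt_scalogram(x, fs, config.cwt), **kwargs)
    spec = render_image(stft_spectrogram(x, fs, config.stft), **kwargs)
    return fuse(to_gray(scal), to_gray(spec))


def build_image_dataset(
    segments: list[Segment | SynthSegment],
    kind: str = "fused",
    config: ImagingConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Image every segment; returns (images float32 (n, H, W, 3), labels 'N'/'A')."""
    config = config or ImagingConfig()
    images, labels = [], []
    for seg in segments:
        s = seg.segment if isinstance(seg, SynthSegment) else seg
        images.append(
            segment_image(s.samples, s.sampling_rate, kind, config).astype(np.float32)
        )
        labels.append(s.label)
    return np.stack(images), np.asarray(labels)


def save_image_dataset(
    images: np.ndarray,
    labels: np.ndarray,
    directory: str | Path,
    kind: str,
    record_ids=None,
    minute_indices=None,
) -> Path:
    """Write PNGs plus a manifest.csv (record_id, minute_index, label, kind, file)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n = len(images)
    record_ids = list(record_ids) if record_ids is not None else ["unknown"] * n
    minute_indices = list(minute_indices) if minute_indices is not None else list(range(n))
    rows = []
    for i in range(n):
        fname = f"{kind}_{i:05d}.png"
        skio.imsave(
            directory / fname,
            (np.clip(images[i], 0, 1) * 255).round().astype(np.uint8),
            check_contrast=False,
        )
        rows.append(
            {
                "record_id": record_ids[i],
                "minute_index": minute_indices[i],
                "label": labels[i],
                "kind": kind,
                "file": fname,
            }
        )
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_image_dataset(directory: str | Path) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Read back a saved dataset; returns (images in [0,1], labels, manifest)."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    images = np.stack(
        [
            skio.imread(directory / f).astype(np.float32) / 255.0
            for f in manifest["file"]
        ]
    )
    return images, manifest["label"].to_numpy(), manifest
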