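"""Pixel-level colocalization of two channels: Pearson's score and Li's ICQ.

Both scores treat a 3D stack as one pooled pixel population and use
channel means taken over the whole included region (optionally restricted
by a mask).  No thresholding or background subtraction is applied.

Pearson's score is the standard correlation of per-pixel intensities.
Li's intensity correlation quotient (ICQ) is the fraction of pixels whose
mean-centered intensities ``(A_i − a)(B_i − b)`` have a positive product,
minus 0.5; it ranges over [−0.5, 0.5].  Pixels sitting exactly on a
channel mean produce a zero product, which counts in the denominator but
not as positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .model import DomainError


@dataclass
class ChannelPair:
    """Two equal-shape intensity arrays with an optional inclusion mask."""

    channel_a: np.ndarray
    channel_b: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.channel_a = np.asarray(self.channel_a, dtype=float)
        self.channel_b = np.asarray(self.channel_b, dtype=float)
        if self.channel_a.shape != self.channel_b.shape:
            raise DomainError(
                f"channel shapes differ: {self.channel_a.shape} vs "
                f"{self.channel_b.shape}"
            )
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.channel_a.shape:
                raise DomainError("mask shape must match the channels")
        if self.included_pixels()[0].size < 2:
            raise DomainError("need at least 2 included pixels")

    def included_pixels(self) -> tuple[np.ndarray, np.ndarray]:
        if self.mask is None:
            return self.channel_a.ravel(), self.channel_b.ravel()
        return self.channel_a[self.mask], self.channel_b[self.mask]


def pearson_score(pair: ChannelPair) -> float:
    """Pearson correlation of per-pixel intensities across channels."""
    a, b = pair.included_pixels()
    da = a - a.mean()
    db = b - b.mean()
    denom = np.sqrt((da**2).sum() * (db**2).sum())
    if denom == 0:
        raise DomainError("Pearson's score undefined for a constant channel")
    return float(np.clip((da * db).sum() / denom, -1.0, 1.0))


def li_icq(pair: ChannelPair) -> float:
    """Li's intensity correlation quotient, in [−0.5, 0.5]."""
    a, b = pair.included_pixels()
    products = (a - a.mean()) * (b - b.mean())
    return float(np.count_nonzero(products > 0) / products.size - 0.5)


def load_channel_pair(
    path_a: str | Path,
    path_b: str | Path | None = None,
    *,
    channel_axis: int = 0,
    channels: tuple[int, int] = (0, 1),
) -> ChannelPair:
    """Load a channel pair from TIFF files.

    Either two single-channel files (possibly multi-page stacks), or one
    multi-channel file with ``channels`` indexed along ``channel_axis``.
    """
    import tifffile

    img_a = tifffile.imread(str(path_a))
    if path_b is not None:
        img_b = tifffile.imread(str(path_b))
    else:
        img_a, img_b = (
            np.take(img_a, channels[0], axis=channel_axis),
            np.take(img_a, channels[1], axis=channel_axis),
        )
    return ChannelPair(img_a, img_b)
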