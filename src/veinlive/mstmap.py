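"""Multi-scale spatial-temporal map (MSTmap) construction.

Each selected vein-edge block contributes a per-frame, per-channel mean gray
value; stacking blocks over time gives a p x T x 3 signal matrix.  Rows are
then aggregated at several spatial scales (non-overlapping group means of
1, 2, 4 and 8 consecutive blocks), min-max normalised per row and channel to
the 8-bit range, and resampled to the fixed (224, 180, 3) map consumed by
the classifier (rows: 56+28+14+7 = 105 multi-scale signals upsampled to 224;
columns: the 180-frame static window).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as sk_resize

from .blocks import BlockSet
from .video import VideoClip

__all__ = ["BlockSignalMatrix", "MSTmap", "block_mean_signals",
           "multiscale_aggregate", "normalize_rows", "to_mstmap",
           "clip_to_mstmap", "SCALES", "MAP_ROWS", "MAP_COLS"]

SCALES = (1, 2, 4, 8)
MAP_ROWS = 224
MAP_COLS = 180


@dataclass
class BlockSignalMatrix:
    """p blocks x T frames x 3 channels of block-mean gray values."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or self.values.shape[-1] != 3:
            raise ValueError(f"expected (p, T, 3), got {self.values.shape}")


@dataclass
class MSTmap:
    """8-bit spatial-temporal map, (224, 180, 3) under the default pipeline.

    Rows are multi-scale region signals, columns are frames, channels RGB.
    """

    map: np.ndarray
    provenance: dict | None = None

    def __post_init__(self):
        self.map = np.asarray(self.map)
        if self.map.ndim != 3 or self.map.shape[-1] != 3:
            raise ValueError(f"MSTmap must be (rows, cols, 3), "
                             f"got {self.map.shape}")


def block_mean_signals(clip: VideoClip, blocks: BlockSet) -> BlockSignalMatrix:
    """values[b, t, c] = mean of channel c over block b's pixels in frame t."""
    frames = clip.frames
    T = frames.shape[0]
    out = np.empty((blocks.p, T, 3), dtype=np.float64)
    for b, (rs, cs) in enumerate(blocks.slices()):
        out[b] = frames[:, rs, cs, :].mean(axis=(1, 2), dtype=np.float64)
    return BlockSignalMatrix(out)


def multiscale_aggregate(matrix: BlockSignalMatrix,
                         scales=SCALES) -> BlockSignalMatrix:
    """Concatenate non-overlapping group means of s consecutive block rows
    for each scale s (floor(p/s) rows per scale, in scale order)."""
    vals = matrix.values
    p = vals.shape[0]
    rows = []
    for s in scales:
        s = int(s)
        if s < 1 or s > p:
            raise ValueError(f"scale {s} out of range for p={p}")
        n = p // s
        rows.append(vals[:n * s].reshape(n, s, *vals.shape[1:]).mean(axis=1))
    return BlockSignalMatrix(np.concatenate(rows, axis=0))


def normalize_rows(matrix: BlockSignalMatrix, neutral: float = 128.0
                   ) -> BlockSignalMatrix:
    """Min-max scale each (row, channel) series to [0, 255]; constant series
    map to the neutral mid-gray."""
    vals = matrix.values
    lo = vals.min(axis=1, keepdims=True)
    hi = vals.max(axis=1, keepdims=True)
    span = hi - lo
    out = np.full_like(vals, neutral)
    nz = np.broadcast_to(span > 0, vals.shape)
    out[nz] = (255.0 * (vals - lo) / np.where(span > 0, span, 1.0))[nz]
    return BlockSignalMatrix(out)


def to_mstmap(matrix: BlockSignalMatrix, out_rows: int = MAP_ROWS,
              out_cols: int = MAP_COLS, provenance: dict | None = None
              ) -> MSTmap:
    """Bilinearly resample the row axis to `out_rows` (and the column axis to
    `out_cols` only when T differs), then quantise to 8 bits."""
    vals = matrix.values
    if vals.size == 0:
        raise ValueError("empty signal matrix")
    rows, T = vals.shape[:2]
    target = (out_rows, out_cols if T != out_cols else T, 3)
    if vals.shape == target:
        resampled = vals
    else:
        resampled = sk_resize(vals, target, order=1, mode="edge",
                              anti_aliasing=False, preserve_range=True)
    return MSTmap(np.clip(np.round(resampled), 0, 255).astype(np.uint8),
                  provenance=provenance)


def clip_to_mstmap(clip: VideoClip, blocks: BlockSet, scales=SCALES,
                   provenance: dict | None = None
                   ) -> tuple[MSTmap, BlockSignalMatrix]:
    """Full map construction; also returns the pre-normalisation multi-scale
    matrix (used by the spectral liveness diagnostics)."""
    signals = block_mean_signals(clip, blocks)
    multi = multiscale_aggregate(signals, scales=scales)
    normed = normalize_rows(multi)
    return to_mstmap(normed, provenance=provenance), multi
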