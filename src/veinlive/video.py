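"""Video clip container and on-disk formats.

A clip is a (T, H, W, 3) intensity stack with a frame rate.  The canonical
lossless on-disk forms are a directory of numbered PNG frames
(``frame_0000.png`` ...) and a compressed NPZ stack; MP4/AVI is read through
imageio when an ffmpeg plugin is available.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v2 as iio
import numpy as np

__all__ = ["VideoClip", "load_clip", "save_clip"]

_FRAME_RE = re.compile(r"frame_(\d+)\.png$")


@dataclass
class VideoClip:
    """A (T, H, W, 3) intensity stack sampled at `fps` frames per second."""

    frames: np.ndarray
    fps: float = 120.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError(f"expected (T, H, W, 3) stack, got {self.frames.shape}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape

    @property
    def duration(self) -> float:
        return self.n_frames / self.fps

    def channel_mean(self) -> np.ndarray:
        """(T, H, W) mean over the three channels, float32."""
        return self.frames.mean(axis=-1, dtype=np.float32)

    def __getitem__(self, key) -> "VideoClip":
        return VideoClip(self.frames[key], fps=self.fps)


def save_clip(clip: VideoClip, path: str | Path, fmt: str = "png") -> Path:
    """Write a clip as a PNG frame directory (``fmt='png'``) or NPZ stack."""
    path = Path(path)
    frames = clip.frames
    if frames.dtype != np.uint8:
        frames = np.clip(np.round(frames), 0, 255).astype(np.uint8)
    if fmt == "png":
        path.mkdir(parents=True, exist_ok=True)
        for t in range(frames.shape[0]):
            iio.imwrite(path / f"frame_{t:04d}.png", frames[t])
        (path / "clip.json").write_text(json.dumps({"fps": clip.fps}))
        return path
    if fmt == "npz":
        path = path if path.suffix == ".npz" else path.with_suffix(".npz")
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(path, frames=frames, fps=np.float64(clip.fps))
        return path
    raise ValueError(f"unknown clip format {fmt!r}")


def load_clip(path: str | Path, fps: float | None = None) -> VideoClip:
    """Load a clip from a PNG frame directory, an NPZ stack, or a video file."""
    path = Path(path)
    if path.is_dir():
        frames_files = sorted(
            (p for p in path.iterdir() if _FRAME_RE.search(p.name)),
            key=lambda p: int(_FRAME_RE.search(p.name).group(1)))
        if not frames_files:
            raise FileNotFoundError(f"no frame_*.png files in {path}")
        frames = np.stack([iio.imread(p) for p in frames_files])
        if frames.ndim == 3:  # grayscale frames -> replicate channels
            frames = np.repeat(frames[..., None], 3, axis=-1)
        meta = path / "clip.json"
        if fps is None:
            fps = json.loads(meta.read_text())["fps"] if meta.exists() else 120.0
        return VideoClip(frames, fps=fps)
    if path.suffix == ".npz":
        with np.load(path) as z:
            return VideoClip(z["frames"], fps=float(z["fps"]) if fps is None else fps)
    # fall back to imageio for container formats (requires an ffmpeg plugin)
    reader = iio.get_reader(path)
    frames = np.stack([np.asarray(f)[..., :3] for f in reader])
    meta = reader.get_meta_data()
    return VideoClip(frames, fps=fps or float(meta.get("fps", 120.0)))
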