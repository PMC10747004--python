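"""Static-window extraction via the three-frame difference method.

A finger presentation is usable only while the finger is stationary; the
three-frame difference flags each interior frame as moving when both its
backward and forward absolute frame differences exceed a gray-level threshold
on more than a small fraction of pixels.  The longest static run is then
center-cropped to the target window length (180 frames at 120 fps = 1.5 s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .video import VideoClip

__all__ = ["MotionTrace", "StaticWindowError", "three_frame_difference",
           "extract_static_window"]

DIFF_THRESH = 10.0     # gray levels; sensor noise (sigma ~ 2) never triggers
RATIO_THRESH = 0.002   # fraction of moving pixels tolerated in a static frame
T_TARGET = 180


@dataclass
class MotionTrace:
    """Per-frame fraction of moving pixels and the static/moving flags.
    Boundary frames carry the values of their nearest interior neighbour."""

    ratio: np.ndarray
    static_flags: np.ndarray

    def __post_init__(self):
        if len(self.ratio) != len(self.static_flags):
            raise ValueError("ratio and static_flags lengths differ")


class StaticWindowError(RuntimeError):
    """Raised when the longest static run is shorter than the target window."""

    def __init__(self, longest_run: int, t_target: int):
        self.longest_run = int(longest_run)
        self.t_target = int(t_target)
        super().__init__(
            f"longest static run is {longest_run} frames, need {t_target}")


def three_frame_difference(clip: VideoClip, diff_thresh: float = DIFF_THRESH,
                           ratio_thresh: float = RATIO_THRESH) -> MotionTrace:
    """Motion trace of a clip by the three-frame difference.

    For interior frame t the moving-pixel map is
    ``(|f_t - f_{t-1}| > diff_thresh) AND (|f_{t+1} - f_t| > diff_thresh)``
    on the channel-mean image; ``ratio_t`` is its mean and a frame is static
    when ``ratio_t < ratio_thresh``.
    """
    T = clip.n_frames
    if T < 3:
        raise ValueError(f"clip too short: {T} frames, need at least 3")
    frames = clip.frames
    ratio = np.empty(T, dtype=np.float64)
    # frame-at-a-time to keep the working set small
    prev_gray = frames[0].mean(axis=-1, dtype=np.float32)
    cur_gray = frames[1].mean(axis=-1, dtype=np.float32)
    prev_d = np.abs(cur_gray - prev_gray) > diff_thresh
    for t in range(1, T - 1):
        next_gray = frames[t + 1].mean(axis=-1, dtype=np.float32)
        next_d = np.abs(next_gray - cur_gray) > diff_thresh
        ratio[t] = np.mean(prev_d & next_d)
        prev_d, cur_gray = next_d, next_gray
    ratio[0], ratio[-1] = ratio[1], ratio[-2]
    flags = ratio < ratio_thresh
    return MotionTrace(ratio=ratio, static_flags=flags)


def _longest_true_run(flags: np.ndarray) -> tuple[int, int]:
    """(start, length) of the longest run of True; earliest run wins ties."""
    best_start, best_len = 0, 0
    start = None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            if i - start > best_len:
                best_start, best_len = start, i - start
            start = None
    if start is not None and len(flags) - start > best_len:
        best_start, best_len = start, len(flags) - start
    return best_start, best_len


def extract_static_window(clip: VideoClip, trace: MotionTrace,
                          t_target: int = T_TARGET) -> VideoClip:
    """Central `t_target` frames of the longest static run (earliest run on
    ties; center crop when the run is longer).  Raises
    :class:`StaticWindowError` carrying the achievable run length otherwise."""
    if len(trace.static_flags) != clip.n_frames:
        raise ValueError("trace was not computed on this clip")
    start, length = _longest_true_run(np.asarray(trace.static_flags, bool))
    if length < t_target:
        raise StaticWindowError(length, t_target)
    lo = start + (length - t_target) // 2
    return clip[lo:lo + t_target]
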