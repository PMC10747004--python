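"""Synthetic NIR finger-vein video generator.

Emulates the statistical structure of transilluminated finger-vein clips as
the liveness pipeline assumes it: a bright finger-shaped transmission region
crossed by dark curvilinear veins; bona fide clips carry a small periodic
modulation of vein absorption at the cardiac frequency (with channel-dependent
amplitude), presentation-attack clips are static; both are corrupted by
per-channel sensor noise.  Also implements the print-preparation transform
used to fabricate paper/film prostheses from real vein images (Gaussian blur,
contrast-limited equalisation, adaptive thresholding, masked power law).

The transmission model is Beer-Lambert-like: a frame is

    I_c(x, y, t) = B(x, y) * exp(-A(x, y) * (1 + live*m*s(t)) * w_c) + noise

with ``A`` the vein absorption map, ``w_c`` per-channel weights,
``s(t) = sin(2*pi*f*t) + harmonic_ratio*sin(4*pi*f*t)`` the cardiac waveform
and ``m`` the relative modulation depth (default 0.02, ~1-3 gray levels at
8-bit scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from skimage import exposure, filters

from .video import VideoClip, save_clip

__all__ = [
    "SceneConfig",
    "PulseModel",
    "NoiseModel",
    "GroundTruth",
    "generate_vein_pattern",
    "finger_transmission",
    "render_clip",
    "prepare_print_pattern",
    "species_allocation",
    "iter_dataset",
    "generate_dataset",
    "SPECIES",
]

SPECIES = ("a4_paper", "pvc", "laser_film")


# ---------------------------------------------------------------------------
# Configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneConfig:
    """Geometry and sampling of a synthetic acquisition.

    ``n_main_veins=None`` draws 2-4 main veins per scene; widths are full
    ridge widths in pixels.  The finger axis is horizontal (root at the left
    column, tip at the right).
    """

    width: int = 640
    height: int = 480
    fps: float = 120.0
    duration: float = 1.5
    n_main_veins: int | None = None
    vein_width_range: tuple[float, float] = (3.5, 6.5)
    finger_axis: str = "horizontal"
    seed: int = 0

    def __post_init__(self):
        if min(self.width, self.height) <= 0 or self.fps <= 0 or self.duration <= 0:
            raise ValueError("width, height, fps and duration must be positive")
        if self.finger_axis != "horizontal":
            raise ValueError("only a horizontal finger axis is supported")

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration))


@dataclass(frozen=True)
class PulseModel:
    """Cardiac modulation of vein absorption.

    ``f_heart=None`` samples the heart rate uniformly in [1.0, 1.7] Hz per
    clip.  ``depth`` is the relative modulation of the absorption coefficient;
    ``channel_weights`` scale absorption per RGB channel (the NIR filter
    leaks differently into the three sensor channels).
    """

    f_heart: float | None = None
    depth: float = 0.02
    harmonic_ratio: float = 0.3
    channel_weights: tuple[float, float, float] = (1.0, 0.7, 0.5)

    def __post_init__(self):
        if not (0.0 <= self.depth < 0.5):
            raise ValueError("modulation depth must satisfy 0 <= m < 0.5")
        if any(w <= 0 for w in self.channel_weights):
            raise ValueError("channel weights must be positive")


@dataclass(frozen=True)
class NoiseModel:
    """Sensor corruption: per-channel Gaussian noise (gray levels), optional
    shot noise, slow global intensity drift, and sub-pixel residual jitter."""

    gaussian_sigma: float | tuple[float, float, float] = 2.0
    shot_noise: bool = False
    drift_amplitude: float = 0.0
    drift_freq: float = 0.3
    jitter_px: float = 0.0

    def __post_init__(self):
        sig = np.atleast_1d(np.asarray(self.gaussian_sigma, float))
        if (sig < 0).any() or self.drift_amplitude < 0 or self.drift_freq < 0 \
                or self.jitter_px < 0:
            raise ValueError("noise parameters must be non-negative")

    def sigma3(self) -> np.ndarray:
        sig = np.asarray(self.gaussian_sigma, dtype=np.float32)
        return np.broadcast_to(sig, (3,)).astype(np.float32)


@dataclass
class GroundTruth:
    """Per-clip ground truth: vein mask, label, PAI species and the injected
    (noise-free) vein-region mean trace per channel."""

    vein_mask: np.ndarray
    label: str
    species: str = "none"
    mean_trace: np.ndarray | None = None
    f_heart: float | None = None

    def __post_init__(self):
        if (self.species == "none") != (self.label == "bona_fide"):
            raise ValueError("species must be 'none' iff label is 'bona_fide'")


# ---------------------------------------------------------------------------
# Scene geometry
# ---------------------------------------------------------------------------

def _scene_geometry(config: SceneConfig, rng: np.random.Generator):
    """Finger half-height profile and vein centerlines for one scene."""
    W, H = config.width, config.height
    x = np.arange(W, dtype=np.float64)
    cy = H / 2.0 + rng.uniform(-0.04, 0.04) * H
    ry0 = 0.30 * H * rng.uniform(0.9, 1.1)
    # mild elliptical taper; the finger extends past both image borders
    rx = 0.75 * W
    half = ry0 * np.sqrt(np.clip(1.0 - ((x - W / 2.0) / rx) ** 2, 0.0, None))
    top, bot = cy - half, cy + half

    if config.n_main_veins is None:
        n_veins = int(rng.integers(2, 5))
    else:
        n_veins = int(config.n_main_veins)

    wlo, whi = config.vein_width_range
    veins = []  # (x_lo, x_hi, y_of_x, sigma, amplitude)
    for _ in range(n_veins):
        frac = rng.uniform(0.2, 0.8)  # vertical station inside the finger
        n_ctrl = 6
        xc = np.linspace(0, W - 1, n_ctrl)
        yc = top + frac * (bot - top)
        yc = yc[np.clip(xc.astype(int), 0, W - 1)]
        yc = yc + np.cumsum(rng.normal(0.0, 0.035 * H, n_ctrl))
        yc -= np.linspace(0, yc[-1] - yc[0], n_ctrl) * 0.5  # detrend half-way
        spline = CubicSpline(xc, yc)
        width = rng.uniform(wlo, whi)
        veins.append((0.0, float(W - 1), spline, width / 2.5,
                      rng.uniform(0.55, 0.95)))

    n_branch = int(rng.integers(0, 3))
    for _ in range(n_branch):
        if not veins:
            break
        parent = veins[int(rng.integers(0, n_veins))]
        x0 = rng.uniform(0.1, 0.7) * W
        dx = rng.uniform(0.12, 0.25) * W
        n_ctrl = 4
        xb = np.linspace(x0, min(x0 + dx, W - 1), n_ctrl)
        slope = rng.choice([-1.0, 1.0]) * rng.uniform(0.05, 0.25)
        yb = parent[2](xb) + slope * (xb - x0)
        spline = CubicSpline(xb, yb)
        veins.append((float(xb[0]), float(xb[-1]), spline,
                      parent[3] * 0.7, parent[4] * 0.7))
    return cy, half, top, bot, veins


def generate_vein_pattern(config: SceneConfig) -> tuple[np.ndarray, np.ndarray]:
    """Render the vein absorption map and its binary mask for one scene.

    Returns ``(absorption_map, vein_mask)``: a float H x W map in [0, 1],
    zero outside the finger region, whose ridges have Gaussian cross-section;
    and the mask ``absorption_map > 0.1 * max``.  Deterministic in
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    W, H = config.width, config.height
    cy, half, top, bot, veins = _scene_geometry(config, rng)

    rows = np.arange(H, dtype=np.float64)[:, None]
    finger = (rows >= top[None, :]) & (rows <= bot[None, :])
    if not finger.any():
        raise ValueError("degenerate geometry: finger region is empty")

    absorption = np.zeros((H, W), dtype=np.float64)
    x = np.arange(W, dtype=np.float64)
    for x_lo, x_hi, spline, sigma, amp in veins:
        lo, hi = int(np.ceil(x_lo)), int(np.floor(x_hi))
        xs = x[lo:hi + 1]
        y_c = spline(xs)
        ridge = amp * np.exp(-((rows - y_c[None, :]) ** 2) / (2.0 * sigma ** 2))
        np.maximum(absorption[:, lo:hi + 1], ridge, out=absorption[:, lo:hi + 1])

    absorption = np.clip(absorption, 0.0, 1.0)
    absorption[~finger] = 0.0
    peak = absorption.max()
    vein_mask = absorption > 0.1 * peak if peak > 0 else np.zeros_like(finger)
    return absorption.astype(np.float32), vein_mask


def finger_transmission(config: SceneConfig, peak: float = 180.0,
                        background: float = 30.0) -> np.ndarray:
    """Base transmission image B(x, y): bright finger tissue on a dark
    housing background, with a smooth roll-off at the finger silhouette.
    Shares the scene geometry (and seed) of :func:`generate_vein_pattern`."""
    rng = np.random.default_rng(config.seed)
    W, H = config.width, config.height
    cy, half, top, bot, _ = _scene_geometry(config, rng)
    rows = np.arange(H, dtype=np.float64)[:, None]
    # smooth transverse profile: ~1 in the core, 0 outside the silhouette
    u = (rows - cy) / np.maximum(half[None, :], 1e-9)
    profile = np.clip(1.0 - np.abs(u) ** 6, 0.0, 1.0)
    profile *= np.clip(1.0 - 0.25 * u ** 2, 0.0, None)  # thinner tissue off-axis
    return (background + (peak - background) * profile).astype(np.float32)


def finger_region_mask(config: SceneConfig) -> np.ndarray:
    """Boolean H x W mask of the finger silhouette for `config`."""
    rng = np.random.default_rng(config.seed)
    cy, half, top, bot, _ = _scene_geometry(config, rng)
    rows = np.arange(config.height, dtype=np.float64)[:, None]
    return (rows >= top[None, :]) & (rows <= bot[None, :])


# ---------------------------------------------------------------------------
# Clip rendering
# ---------------------------------------------------------------------------

def pulse_waveform(t: np.ndarray, f_heart: float, harmonic_ratio: float) -> np.ndarray:
    """s(t) = sin(2*pi*f*t) + harmonic_ratio * sin(4*pi*f*t)."""
    return np.sin(2.0 * np.pi * f_heart * t) \
        + harmonic_ratio * np.sin(4.0 * np.pi * f_heart * t)


def render_clip(absorption_map: np.ndarray, vein_mask: np.ndarray,
                pulse: PulseModel, noise: NoiseModel, live: bool, *,
                base_transmission: np.ndarray | float = 180.0,
                absorption_strength: float = 0.55,
                fps: float = 120.0, n_frames: int = 180,
                seed: int = 0, quantize: bool = True
                ) -> tuple[VideoClip, GroundTruth]:
    """Render one clip from a vein pattern.

    Bona fide clips (``live=True``) modulate the vein absorption by
    ``1 + m*s(t)``; attack clips render the same static pattern.  With equal
    seeds and ``m=0`` the two are bit-identical.  The returned ground truth
    records the noise-free vein-region mean per channel (``mean_trace``).
    """
    A = np.asarray(absorption_map, dtype=np.float32)
    mask = np.asarray(vein_mask, bool)
    if A.shape != mask.shape:
        raise ValueError("absorption map and vein mask shapes differ")
    H, W = A.shape
    rng = np.random.default_rng(seed)

    f_heart = pulse.f_heart
    if f_heart is None:  # drawn for every clip so live/attack consume equal rng
        f_heart = float(rng.uniform(1.0, 1.7))
    t = np.arange(n_frames, dtype=np.float64) / fps
    s = pulse_waveform(t, f_heart, pulse.harmonic_ratio)
    m = pulse.depth if live else 0.0

    B = np.broadcast_to(np.asarray(base_transmission, np.float32), (H, W))
    w_c = np.asarray(pulse.channel_weights, dtype=np.float32)
    Aeff = absorption_strength * A

    static = (B[..., None] * np.exp(-Aeff[..., None] * w_c)).astype(np.float32)

    rr, cc = np.nonzero(mask)
    Bv, Av = B[rr, cc], Aeff[rr, cc]
    # (T, nv, 3) noise-free vein pixels under modulation
    mod = (Bv[None, :, None] * np.exp(
        -(1.0 + m * s)[:, None, None] * Av[None, :, None] * w_c)
    ).astype(np.float32)
    if len(rr):
        mean_trace = mod.mean(axis=1)
        delta = mod - static[rr, cc][None]   # vein-pixel deviation per frame
    else:
        mean_trace = np.zeros((n_frames, 3), np.float32)
        delta = None

    drift = noise.drift_amplitude * np.sin(2 * np.pi * noise.drift_freq * t) \
        if noise.drift_amplitude > 0 else None
    sig = noise.sigma3()
    jitter = noise.jitter_px > 0
    if jitter:
        from scipy.ndimage import shift as nd_shift

    # frame-at-a-time assembly keeps the working set cache-resident
    frames = np.empty((n_frames, H, W, 3),
                      np.uint8 if quantize else np.float32)
    buf = np.empty((H, W, 3), np.float32)
    noise_buf = np.empty((H, W, 3), np.float32) if sig.any() else None
    for ti in range(n_frames):
        np.copyto(buf, static)
        if delta is not None:
            buf[rr, cc] += delta[ti]
        if drift is not None:
            buf += np.float32(drift[ti])
        if noise_buf is not None:
            rng.standard_normal((H, W, 3), dtype=np.float32, out=noise_buf)
            noise_buf *= sig
            buf += noise_buf
        if noise.shot_noise:
            buf += rng.standard_normal((H, W, 3), dtype=np.float32) \
                * np.sqrt(np.clip(buf, 0, None) / 8.0)
        if jitter:
            dy, dx = rng.normal(0.0, noise.jitter_px, 2)
            buf = nd_shift(buf, (dy, dx, 0.0), order=1, mode="nearest")
        if quantize:
            np.clip(buf, 0, 255, out=buf)
            np.rint(buf, out=buf)
        frames[ti] = buf

    gt = GroundTruth(vein_mask=mask, label="bona_fide" if live else "attack",
                     species="none" if live else "a4_paper",
                     mean_trace=mean_trace, f_heart=f_heart)
    return VideoClip(frames, fps=fps), gt


# ---------------------------------------------------------------------------
# Print-preparation transform (prosthesis fabrication emulation)
# ---------------------------------------------------------------------------

def prepare_print_pattern(image: np.ndarray, blur_sigma: float = 2.0,
                          clahe_clip: float = 0.01, gamma: float = 1.5
                          ) -> np.ndarray:
    """Prosthesis print preparation: Gaussian blur, contrast-limited adaptive
    histogram equalisation, adaptive regional threshold, then a power-law
    transform (exponent `gamma`) applied inside the thresholded (dark/vein)
    mask only.  Output has the input's shape, dtype and range."""
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a single-channel image")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    orig_dtype = img.dtype
    imgf = img.astype(np.float64)
    lo, hi = imgf.min(), imgf.max()
    span = hi - lo if hi > lo else 1.0
    x = (imgf - lo) / span

    if blur_sigma > 0:
        x = filters.gaussian(x, sigma=blur_sigma)
    x = exposure.equalize_adapthist(np.clip(x, 0, 1), clip_limit=clahe_clip)

    block = min(35, (min(x.shape) // 2) * 2 - 1)
    if block >= 3:
        thresh = filters.threshold_local(x, block_size=block)
        dark = x < thresh
    else:
        dark = np.zeros(x.shape, bool)
    out = x.copy()
    out[dark] = x[dark] ** gamma

    out = out * span + lo
    if np.issubdtype(orig_dtype, np.integer):
        info = np.iinfo(orig_dtype)
        out = np.clip(np.round(out), info.min, info.max)
    return out.astype(orig_dtype)


def species_texture(shape: tuple[int, int], species: str,
                    rng: np.random.Generator) -> np.ndarray:
    """Print-grain texture field (gray levels) for a PAI species.  Species
    differ only by grain scale and amplitude."""
    params = {"a4_paper": (1.0, 2.0), "pvc": (2.0, 1.2), "laser_film": (0.5, 0.8)}
    if species not in params:
        raise ValueError(f"unknown PAI species {species!r}")
    corr, amp = params[species]
    grain = rng.standard_normal(shape)
    if corr > 0:
        grain = filters.gaussian(grain, sigma=corr)
        grain /= max(grain.std(), 1e-12)
    return (amp * grain).astype(np.float32)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def species_allocation(n_attack: int, species=SPECIES) -> dict[str, int]:
    """Largest-remainder proportional allocation of attack clips over the PAI
    species (equal thirds by default; earlier species win the remainder)."""
    k = len(species)
    quota = n_attack / k
    counts = [int(np.floor(quota))] * k
    rem = n_attack - sum(counts)
    for i in range(rem):
        counts[i] += 1
    return dict(zip(species, counts))


def iter_dataset(n_live: int, n_attack: int, *,
                 species_mix: dict[str, int] | None = None,
                 config: SceneConfig = SceneConfig(),
                 pulse: PulseModel = PulseModel(),
                 noise: NoiseModel = NoiseModel(),
                 seed: int = 0,
                 print_transform: bool = False,
                 texture: bool = False,
                 ) -> Iterator[tuple[VideoClip, GroundTruth, dict]]:
    """Yield labelled clips one at a time (clip, ground truth, manifest row).

    Live clips reuse each finger identity exactly twice (two presentations of
    the same vein pattern with independent noise and pulse phase); attack
    clips get one presentation per prosthesis.  Fully deterministic in
    ``seed``.
    """
    if n_live < 0 or n_attack < 0:
        raise ValueError("counts must be non-negative")
    if species_mix is None:
        species_mix = species_allocation(n_attack)
    if sum(species_mix.values()) != n_attack:
        raise ValueError(f"species_mix sums to {sum(species_mix.values())}, "
                         f"expected n_attack={n_attack}")

    ss = np.random.SeedSequence(seed)
    n_live_fingers = (n_live + 1) // 2
    n_fingers = n_live_fingers + n_attack
    child = ss.generate_state(n_fingers + n_live + n_attack)

    attack_species = [s for s in species_mix for _ in range(species_mix[s])]

    idx = 0
    for i in range(n_live):
        finger_id = i // 2
        scene = replace(config, seed=int(child[finger_id] % (2 ** 31)))
        A, mask = generate_vein_pattern(scene)
        B = finger_transmission(scene)
        clip_seed = int(child[n_fingers + idx] % (2 ** 31))
        clip, gt = render_clip(A, mask, pulse, noise, live=True,
                               base_transmission=B, fps=config.fps,
                               n_frames=config.n_frames, seed=clip_seed)
        row = {"path": f"live_{i:04d}", "label": "bona_fide", "species": "none",
               "finger_id": int(finger_id), "seed": clip_seed}
        yield clip, gt, row
        idx += 1

    for j in range(n_attack):
        finger_id = n_live_fingers + j
        scene = replace(config, seed=int(child[finger_id] % (2 ** 31)))
        A, mask = generate_vein_pattern(scene)
        B = finger_transmission(scene)
        spec = attack_species[j]
        if print_transform:
            printed = prepare_print_pattern((A * 255).astype(np.uint8))
            A = printed.astype(np.float32) / 255.0
            A[~finger_region_mask(scene)] = 0.0
        clip_seed = int(child[n_fingers + idx] % (2 ** 31))
        clip, gt = render_clip(A, mask, pulse, noise, live=False,
                               base_transmission=B, fps=config.fps,
                               n_frames=config.n_frames, seed=clip_seed)
        if texture:
            grain = species_texture(A.shape, spec,
                                    np.random.default_rng(clip_seed + 1))
            frames = clip.frames.astype(np.float32) + grain[None, :, :, None]
            clip = VideoClip(np.clip(np.round(frames), 0, 255).astype(np.uint8),
                             fps=clip.fps)
        gt.species = spec
        row = {"path": f"attack_{j:04d}", "label": "attack", "species": spec,
               "finger_id": int(finger_id), "seed": clip_seed}
        yield clip, gt, row
        idx += 1


def generate_dataset(n_live: int, n_attack: int, *,
                     species_mix: dict[str, int] | None = None,
                     config: SceneConfig = SceneConfig(),
                     pulse: PulseModel = PulseModel(),
                     noise: NoiseModel = NoiseModel(),
                     seed: int = 0,
                     out_dir: str | Path | None = None,
                     fmt: str = "npz",
                     print_transform: bool = False,
                     texture: bool = False) -> pd.DataFrame:
    """Generate a labelled clip collection and its CSV manifest.

    With ``out_dir`` set, clips are written (PNG frame directories or NPZ
    stacks), each with a ground-truth mask PNG and JSON sidecar, and the
    manifest is written as ``manifest.csv``.  Returns the manifest frame
    (columns: path, label, species, finger_id, seed).
    """
    import imageio.v2 as iio
    import json

    rows = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for clip, gt, row in iter_dataset(
            n_live, n_attack, species_mix=species_mix, config=config,
            pulse=pulse, noise=noise, seed=seed,
            print_transform=print_transform, texture=texture):
        if out is not None:
            clip_path = save_clip(clip, out / row["path"], fmt=fmt)
            iio.imwrite(out / (row["path"] + "_mask.png"),
                        (gt.vein_mask * np.uint8(255)))
            sidecar = {"label": gt.label, "species": gt.species,
                       "f_heart": gt.f_heart, "finger_id": row["finger_id"],
                       "seed": row["seed"]}
            (out / (row["path"] + "_gt.json")).write_text(json.dumps(sidecar))
            row = dict(row, path=str(clip_path.relative_to(out)))
        rows.append(row)
    manifest = pd.DataFrame(rows, columns=["path", "label", "species",
                                           "finger_id", "seed"])
    if out is not None:
        manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
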