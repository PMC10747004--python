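"""DC-free Gabor bank construction and vein segmentation.

Veins appear as dark curvilinear ridges in the transilluminated mean frame.
They are enhanced with a bank of real (cosine-phase) Gabor kernels at several
wavelengths and orientations; each kernel has its arithmetic mean subtracted
so the filter rejects the (large, spatially varying) DC transmission level
and responds only to ridge-scale structure.  The response is thresholded by
Otsu's rule inside the finger region and cleaned morphologically.

Kernel form (centered integer grid, side ``ksize``):

    G(x, y) = exp(-(x1^2 + gamma^2 * y1^2) / (2 sigma^2)) * cos(2 pi x1 / lambda + phi)
    x1 =  x cos(theta) + y sin(theta)
    y1 = -x sin(theta) + y cos(theta)
    G' = G - mean(G)

``sigma`` is tied to the half-response spatial-frequency bandwidth ``b`` (in
octaves) by ``sigma/lambda = (1/pi) * sqrt(ln 2 / 2) * (2^b + 1)/(2^b - 1)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sp_fft
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

__all__ = ["GaborParams", "GaborBank", "VeinMask", "gabor_kernel", "remove_dc",
           "sigma_from_bandwidth", "build_bank", "segment_veins",
           "SegmentConfig"]


@dataclass(frozen=True)
class GaborParams:
    """Parameters of one real Gabor kernel."""

    lam: float            # sinusoid wavelength, px
    theta: float          # orientation, radians
    sigma: float          # Gaussian std, px
    gamma: float = 0.5    # spatial aspect ratio
    phi: float = 0.0      # sinusoid phase, radians
    ksize: int = 0        # odd kernel side; 0 -> derived from sigma

    def __post_init__(self):
        if self.lam <= 0 or self.sigma <= 0 or self.gamma <= 0:
            raise ValueError("lambda, sigma and gamma must be positive")
        if self.ksize and (self.ksize < 3 or self.ksize % 2 == 0):
            raise ValueError("ksize must be odd and >= 3")

    def resolved_ksize(self) -> int:
        return self.ksize or 2 * math.ceil(3.0 * self.sigma) + 1


@dataclass
class GaborBank:
    """A list of (params, DC-free kernel) pairs."""

    kernels: list[tuple[GaborParams, np.ndarray]]

    def __post_init__(self):
        for p, k in self.kernels:
            if abs(k.sum()) >= 1e-9 * k.size:
                raise ValueError("bank kernel is not mean-free")

    def __len__(self):
        return len(self.kernels)


@dataclass
class VeinMask:
    """Binary vein segmentation (Ibw), same shape as the source image."""

    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, bool)


def gabor_kernel(params: GaborParams) -> np.ndarray:
    """Real Gabor kernel sampled on the centered integer grid."""
    k = params.resolved_ksize()
    half = k // 2
    y, x = np.mgrid[-half:half + 1, -half:half + 1].astype(np.float64)
    ct, st = math.cos(params.theta), math.sin(params.theta)
    x1 = x * ct + y * st
    y1 = -x * st + y * ct
    env = np.exp(-(x1 ** 2 + params.gamma ** 2 * y1 ** 2)
                 / (2.0 * params.sigma ** 2))
    carrier = np.cos(2.0 * np.pi * x1 / params.lam + params.phi)
    return env * carrier


def remove_dc(kernel: np.ndarray) -> np.ndarray:
    """Subtract the kernel's arithmetic mean; the result sums to ~0."""
    kernel = np.asarray(kernel, dtype=np.float64)
    if kernel.size == 0:
        raise ValueError("empty kernel")
    return kernel - kernel.mean()


def sigma_from_bandwidth(lam: float, bandwidth: float) -> float:
    """Gaussian std from wavelength and bandwidth in octaves."""
    b = 2.0 ** bandwidth
    return lam * (1.0 / math.pi) * math.sqrt(math.log(2.0) / 2.0) \
        * (b + 1.0) / (b - 1.0)


def build_bank(lambdas=(4.0, 8.0, 12.0), n_orient: int = 8,
               bandwidth: float = 1.0, gamma: float = 0.5,
               phi: float = 0.0) -> GaborBank:
    """Multi-scale, multi-orientation DC-free bank.

    Orientations are ``theta_k = k*pi/n_orient``; sigma follows the bandwidth
    relation; ``ksize = 2*ceil(3*sigma) + 1``.  Every kernel is mean-free.
    """
    lambdas = tuple(lambdas)
    if not lambdas:
        raise ValueError("at least one wavelength is required")
    if n_orient < 1:
        raise ValueError("n_orient must be >= 1")
    kernels = []
    for lam in lambdas:
        sigma = sigma_from_bandwidth(lam, bandwidth)
        for k in range(n_orient):
            params = GaborParams(lam=lam, theta=k * math.pi / n_orient,
                                 sigma=sigma, gamma=gamma, phi=phi)
            kernels.append((params, remove_dc(gabor_kernel(params))))
    return GaborBank(kernels=kernels)


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentConfig:
    """Post-processing of the bank response."""

    min_component_px: int = 64     # drop specks smaller than this
    opening_radius: int = 1        # 3x3 opening
    max_components: int = 8        # keep at most the k largest components


def _fft_bank_response(image: np.ndarray, bank: GaborBank) -> np.ndarray:
    """R = sum over lambda of max over theta of (image * G'), computed with a
    single forward FFT of the reflect-padded image ("same" output size)."""
    H, W = image.shape
    kmax = max(p.resolved_ksize() for p, _ in bank.kernels)
    pad = kmax // 2
    padded = np.pad(image, pad, mode="reflect")
    fshape = (sp_fft.next_fast_len(padded.shape[0] + kmax - 1),
              sp_fft.next_fast_len(padded.shape[1] + kmax - 1))
    Fimg = sp_fft.rfft2(padded, fshape)

    by_lambda: dict[float, np.ndarray] = {}
    for params, kern in bank.kernels:
        k = kern.shape[0]
        Fk = sp_fft.rfft2(kern, fshape)
        full = sp_fft.irfft2(Fimg * Fk, fshape)
        # 'same'-mode correlation center for the padded image, then unpad.
        # FFT computes convolution; cosine-phase kernels are symmetric under
        # point reflection for phi=0, and we build the response with the
        # convolution convention throughout.
        lo_r = (k - 1) // 2 + pad
        lo_c = (k - 1) // 2 + pad
        resp = full[lo_r:lo_r + H, lo_c:lo_c + W]
        key = params.lam
        if key in by_lambda:
            np.maximum(by_lambda[key], resp, out=by_lambda[key])
        else:
            by_lambda[key] = resp.copy()
    return np.sum(list(by_lambda.values()), axis=0)


def bank_response(mean_image: np.ndarray, bank: GaborBank) -> np.ndarray:
    """Ridge response of the photometrically inverted image: max over
    orientations, summed over wavelengths."""
    img = np.asarray(mean_image, dtype=np.float64)
    inverted = -img  # veins darker than tissue -> positive ridge response
    return _fft_bank_response(inverted, bank)


def _finger_region(mean_image: np.ndarray) -> np.ndarray:
    """Bright-foreground finger silhouette of the mean frame (Otsu)."""
    img = np.asarray(mean_image, dtype=np.float64)
    if img.max() - img.min() < 1e-9:
        return np.ones(img.shape, bool)
    t = threshold_otsu(img)
    region = img > t
    region = ndimage.binary_closing(region, np.ones((5, 5)))
    region = ndimage.binary_fill_holes(region)
    return region


def segment_veins(mean_image: np.ndarray, bank: GaborBank,
                  config: SegmentConfig = SegmentConfig(),
                  finger_region: np.ndarray | None = None) -> VeinMask:
    """Segment the vein region of a temporal-mean, channel-mean frame.

    The DC-free bank response is thresholded by Otsu's rule restricted to the
    finger region, then cleaned by a 3x3 opening and small-component removal.
    A flat image yields an empty mask (the mean-free kernels respond with
    exactly zero, up to float tolerance).
    """
    img = np.asarray(mean_image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a single-channel image")
    R = bank_response(img, bank)

    scale = max(1.0, float(np.abs(img).max()))
    if R.max() - R.min() < 1e-8 * scale:  # flat input: exact DC rejection
        return VeinMask(np.zeros(img.shape, bool))

    region = _finger_region(img) if finger_region is None else \
        np.asarray(finger_region, bool)
    vals = R[region]
    if vals.size == 0 or vals.max() - vals.min() < 1e-8 * scale:
        return VeinMask(np.zeros(img.shape, bool))
    t = threshold_otsu(vals)
    mask = (R > t) & region

    if config.opening_radius > 0:
        se = np.ones((2 * config.opening_radius + 1,) * 2)
        mask = ndimage.binary_opening(mask, se)
    if config.min_component_px > 0 or config.max_components:
        lab, n = cc_label(mask, return_num=True, connectivity=2)
        if n:
            sizes = np.bincount(lab.ravel())[1:]
            keep = np.argsort(sizes)[::-1][:config.max_components] + 1
            keep = [i for i in keep if sizes[i - 1] >= config.min_component_px]
            mask = np.isin(lab, keep)
    return VeinMask(mask)
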