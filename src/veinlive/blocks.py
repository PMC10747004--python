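"""Vein-edge map and ordered edge-block selection.

The edge map is the set difference between the binary vein segmentation and
its morphological erosion with a full 3x3 structuring element
(``Iedge = Ibw AND NOT erode(Ibw)``); erosion treats out-of-image pixels as
foreground so the image border does not create an artificial edge.  Blocks
are then picked along the main vein (largest connected component) from
finger root to tip: the component's column span is divided into ``p`` equal
strips and each strip contributes the edge pixel closest to the strip's
vein centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label

from .gabor import VeinMask

__all__ = ["EdgeMask", "BlockSet", "BlockSelectionError", "edge_map",
           "select_blocks", "P_BLOCKS", "BLOCK_SIZE"]

P_BLOCKS = 56      # rows at scales {1,2,4,8} total 105 and resize cleanly to 224
BLOCK_SIZE = 16    # px, square


@dataclass
class EdgeMask:
    """Binary vein-edge image (Iedge); a pixelwise subset of Ibw."""

    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, bool)


@dataclass
class BlockSet:
    """Ordered square blocks along the main vein, root to tip.

    Centers are (row, col) pairs with non-decreasing columns; every block
    lies fully inside the image.
    """

    centers: list[tuple[int, int]]
    block_size: int

    def __post_init__(self):
        cols = [c for _, c in self.centers]
        if any(b > a for a, b in zip(cols[1:], cols[:-1])):
            raise ValueError("block centers must have non-decreasing columns")

    @property
    def p(self) -> int:
        return len(self.centers)

    def slices(self) -> list[tuple[slice, slice]]:
        h = self.block_size
        out = []
        for r, c in self.centers:
            r0, c0 = r - h // 2, c - h // 2
            out.append((slice(r0, r0 + h), slice(c0, c0 + h)))
        return out


class BlockSelectionError(RuntimeError):
    """Raised when fewer strips contain edge pixels than blocks requested."""

    def __init__(self, achievable: int, requested: int):
        self.achievable = int(achievable)
        self.requested = int(requested)
        super().__init__(
            f"only {achievable} of {requested} strips contain edge pixels")


def edge_map(ibw: VeinMask | np.ndarray) -> EdgeMask:
    """Iedge = Ibw AND NOT erode(Ibw, 3x3); border treated as foreground."""
    mask = ibw.mask if isinstance(ibw, VeinMask) else np.asarray(ibw, bool)
    eroded = ndimage.binary_erosion(mask, np.ones((3, 3)), border_value=1)
    return EdgeMask(mask & ~eroded)


def _clip_center(r: int, c: int, h: int, shape: tuple[int, int]) -> tuple[int, int]:
    """Shift a block center so the block lies fully inside the image."""
    H, W = shape
    r = min(max(r, h // 2), H - 1 - (h - 1) // 2)
    c = min(max(c, h // 2), W - 1 - (h - 1) // 2)
    return int(r), int(c)


def select_blocks(iedge: EdgeMask | np.ndarray, ibw: VeinMask | np.ndarray,
                  p: int = P_BLOCKS, block_size: int = BLOCK_SIZE) -> BlockSet:
    """Select `p` ordered edge blocks along the main vein.

    The column span of the largest connected component of Ibw is split into
    `p` equal strips; in each strip the block center is the edge pixel
    closest to the strip's vein-component centroid.  Blocks are clip-shifted
    inside the image; strip order runs root (left) to tip (right).
    """
    edge = iedge.mask if isinstance(iedge, EdgeMask) else np.asarray(iedge, bool)
    vein = ibw.mask if isinstance(ibw, VeinMask) else np.asarray(ibw, bool)
    if p < 1:
        raise ValueError("p must be >= 1")
    if not edge.any():
        raise BlockSelectionError(0, p)

    lab, n = cc_label(vein, return_num=True, connectivity=2)
    if n == 0:
        raise BlockSelectionError(0, p)
    sizes = np.bincount(lab.ravel())[1:]
    main = lab == (int(np.argmax(sizes)) + 1)

    rows, cols = np.nonzero(main)
    c0, c1 = cols.min(), cols.max()
    bounds = np.linspace(c0, c1 + 1, p + 1)

    erows, ecols = np.nonzero(edge & main) if (edge & main).any() \
        else np.nonzero(edge)
    centers: list[tuple[int, int]] = []
    missing = 0
    for i in range(p):
        lo, hi = bounds[i], bounds[i + 1]
        in_strip = (ecols >= lo) & (ecols < hi)
        if not in_strip.any():
            missing += 1
            continue
        comp_in_strip = (cols >= lo) & (cols < hi)
        if comp_in_strip.any():
            cr = rows[comp_in_strip].mean()
            ccol = cols[comp_in_strip].mean()
        else:
            cr, ccol = erows[in_strip].mean(), ecols[in_strip].mean()
        er, ec = erows[in_strip], ecols[in_strip]
        d2 = (er - cr) ** 2 + (ec - ccol) ** 2
        j = int(np.argmin(d2))
        centers.append(_clip_center(er[j], ec[j], block_size, edge.shape))
    if missing:
        raise BlockSelectionError(p - missing, p)
    return BlockSet(centers=centers, block_size=block_size)
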