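"""Wavelet transform modulus maxima (WTMM) detection and chaining.

A pixel is a WTMM point at scale ``a`` when its modulus is a local maximum
along its own gradient direction: the modulus there is >= the bilinearly
interpolated modulus one pixel away on both sides along the unit vector of
the argument, with strict inequality on at least one side (so exactly flat
plateaus are discarded but single-pixel-wide discrete ridges are kept).
Probes that fall off the raster wrap periodically, consistent with the
FFT-based transform.

At each scale the retained points organize into 8-connected "maxima chains"
that trace the intensity edges of the image.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Iterator, List, NamedTuple, Optional

import numpy as np
from scipy import ndimage

from .transform import GradientField

__all__ = [
    "WtmmPoint",
    "WtmmPoints",
    "MaximaChain",
    "detect_wtmm",
    "detect_wtmm_mask",
    "chain_maxima",
    "label_chains",
]


class WtmmPoint(NamedTuple):
    row: int
    col: int
    modulus: float
    angle: float


@dataclass(frozen=True)
class WtmmPoints:
    """Columnar set of WTMM points at one scale (vectorized container)."""

    scale: float
    rows: np.ndarray
    cols: np.ndarray
    modulus: np.ndarray
    angle: np.ndarray
    shape: tuple[int, int]

    def __len__(self) -> int:
        return self.rows.size

    def __iter__(self) -> Iterator[WtmmPoint]:
        for r, c, m, a in zip(self.rows, self.cols, self.modulus, self.angle):
            yield WtmmPoint(int(r), int(c), float(m), float(a))

    def mask(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=bool)
        out[self.rows, self.cols] = True
        return out


def _bilinear_periodic(raster: np.ndarray, r: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Bilinear interpolation with periodic wrap on a square raster."""
    n = raster.shape[0]
    r0 = np.floor(r)
    c0 = np.floor(c)
    fr = r - r0
    fc = c - c0
    r0 = r0.astype(np.intp) % n
    c0 = c0.astype(np.intp) % n
    r1 = (r0 + 1) % n
    c1 = (c0 + 1) % n
    return (
        (1.0 - fr) * (1.0 - fc) * raster[r0, c0]
        + (1.0 - fr) * fc * raster[r0, c1]
        + fr * (1.0 - fc) * raster[r1, c0]
        + fr * fc * raster[r1, c1]
    )


def detect_wtmm_mask(field: GradientField) -> np.ndarray:
    """Boolean raster of directional-maximum pixels (modulus > 0 only)."""
    mod = field.modulus
    n = mod.shape[0]
    rows = np.arange(n, dtype=np.float64)[:, None]
    cols = np.arange(n, dtype=np.float64)[None, :]
    # unit probe vector along the argument: x = col direction, y = row direction
    ux = np.cos(field.argument)
    uy = np.sin(field.argument)
    ahead = _bilinear_periodic(mod, rows + uy, cols + ux)
    behind = _bilinear_periodic(mod, rows - uy, cols - ux)
    keep = (mod > 0.0) & (mod >= ahead) & (mod >= behind)
    keep &= (mod > ahead) | (mod > behind)
    return keep


def detect_wtmm(field: GradientField) -> WtmmPoints:
    """Detect WTMM points of a gradient field (empty result is valid)."""
    keep = detect_wtmm_mask(field)
    rows, cols = np.nonzero(keep)
    return WtmmPoints(
        scale=field.scale,
        rows=rows,
        cols=cols,
        modulus=field.modulus[rows, cols],
        angle=field.argument[rows, cols],
        shape=field.modulus.shape,
    )


@dataclass
class MaximaChain:
    """Connected sequence of WTMM points at one scale.

    Consecutive points are 8-adjacent (possibly across the periodic
    boundary); the traversal order is reported for display/export but carries
    no meaning downstream.
    """

    scale: float
    points: List[WtmmPoint] = dc_field(default_factory=list)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def angles(self) -> np.ndarray:
        return np.array([p.angle for p in self.points])


_EIGHT = ndimage.generate_binary_structure(2, 2)


def label_chains(mask: np.ndarray, periodic: bool = True) -> tuple[np.ndarray, int]:
    """8-connected component labels of a WTMM mask, merged across the wrap.

    Returns ``(labels, n_chains)`` with labels 1..n (0 = background).
    """
    labels, n = ndimage.label(mask, structure=_EIGHT)
    if not periodic or n == 0:
        return labels, n
    # union-find over labels touching across the periodic seam
    parent = np.arange(n + 1)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    nrow, ncol = mask.shape
    for a_lab, b_lab, offsets in (
        (labels[0, :], labels[-1, :], (-1, 0, 1)),   # top row vs bottom row
        (labels[:, 0], labels[:, -1], (-1, 0, 1)),   # left col vs right col
    ):
        idx_a = np.nonzero(a_lab)[0]
        for i in idx_a:
            for off in offsets:
                j = (i + off) % len(b_lab)
                if b_lab[j]:
                    union(int(a_lab[i]), int(b_lab[j]))
    # the two seams meet at the corners; the offsets above already cover them
    roots = np.array([find(i) for i in range(n + 1)])
    # compress to consecutive ids
    uniq = np.unique(roots[1:])
    remap = np.zeros(n + 1, dtype=labels.dtype)
    remap[uniq] = np.arange(1, uniq.size + 1)
    return remap[roots[labels]], int(uniq.size)


_NEIGHBOR_STEPS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _order_component(coords: set[tuple[int, int]], shape: tuple[int, int]) -> list[tuple[int, int]]:
    """Depth-first traversal order of one 8-connected component (periodic)."""
    nrow, ncol = shape

    def neighbors(p: tuple[int, int]) -> list[tuple[int, int]]:
        r, c = p
        out = []
        for dr, dc in _NEIGHBOR_STEPS:
            q = ((r + dr) % nrow, (c + dc) % ncol)
            if q in coords:
                out.append(q)
        return out

    # start at a degree-1 endpoint when one exists, else the smallest point
    start = min(coords)
    for p in sorted(coords):
        if len(neighbors(p)) == 1:
            start = p
            break
    order: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    stack = [start]
    while stack:
        p = stack.pop()
        if p in seen:
            continue
        seen.add(p)
        order.append(p)
        for q in sorted(neighbors(p), reverse=True):
            if q not in seen:
                stack.append(q)
    return order


def chain_maxima(points: WtmmPoints, scale: Optional[float] = None, periodic: bool = True,
                 min_length: int = 1) -> List[MaximaChain]:
    """Partition WTMM points into 8-connected maxima chains.

    ``min_length`` optionally drops short chains (default keeps everything).
    """
    scale = points.scale if scale is None else float(scale)
    if len(points) == 0:
        return []
    mask = points.mask()
    labels, n = label_chains(mask, periodic=periodic)
    value = {(int(r), int(c)): (float(m), float(a))
             for r, c, m, a in zip(points.rows, points.cols, points.modulus, points.angle)}
    chains: List[MaximaChain] = []
    for lab in range(1, n + 1):
        rr, cc = np.nonzero(labels == lab)
        coords = set(zip(rr.tolist(), cc.tolist()))
        if len(coords) < min_length:
            continue
        ordered = _order_component(coords, mask.shape)
        pts = [WtmmPoint(r, c, *value[(r, c)]) for r, c in ordered]
        chains.append(MaximaChain(scale=scale, points=pts))
    return chains
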