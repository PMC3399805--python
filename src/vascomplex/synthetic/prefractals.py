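"""Deterministic rasterizations of exactly self-similar prefractals.

These serve as analytic oracles: the depth-k approximants of the
Sierpinski carpet (D = log 8 / log 3), Sierpinski triangle
(D = log 3 / log 2) and Koch curve (D = log 4 / log 3) have known
dimensions, so estimator output can be checked against closed forms.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "sierpinski_carpet",
    "sierpinski_triangle",
    "koch_curve",
    "generate_prefractal",
]

_MAX_CANVAS = 4096  # rasters beyond this are pointless for the estimators


def sierpinski_carpet(depth: int) -> np.ndarray:
    """Depth-k carpet on a 3^k x 3^k canvas; exactly 8^k foreground pixels."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if 3**depth > _MAX_CANVAS:
        raise ValueError(f"depth {depth} exceeds the canvas limit")
    cell = np.ones((3, 3), dtype=np.uint8)
    cell[1, 1] = 0
    img = np.array([[1]], dtype=np.uint8)
    for _ in range(depth):
        img = np.kron(img, cell)
    return img


def sierpinski_triangle(depth: int) -> np.ndarray:
    """Depth-k triangle on a 2^k x 2^k canvas; exactly 3^k foreground pixels."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if 2**depth > _MAX_CANVAS:
        raise ValueError(f"depth {depth} exceeds the canvas limit")
    cell = np.array([[1, 0], [1, 1]], dtype=np.uint8)
    img = np.array([[1]], dtype=np.uint8)
    for _ in range(depth):
        img = np.kron(img, cell)
    return img


def _koch_points(depth: int) -> np.ndarray:
    """Vertices of the depth-k Koch curve over [0, 3^k] as complex numbers."""
    pts = np.array([0.0 + 0.0j, 3.0**depth + 0.0j])
    rot = np.exp(-1j * np.pi / 3)  # bump upward in image coordinates (y down)
    for _ in range(depth):
        new = [pts[0]]
        for a, b in zip(pts[:-1], pts[1:]):
            d = (b - a) / 3.0
            p1 = a + d
            p2 = p1 + d * rot
            p3 = a + 2 * d
            new.extend([p1, p2, p3, b])
        pts = np.array(new)
    return pts


def koch_curve(depth: int, scale: int = 1, margin: int = 0) -> np.ndarray:
    """Depth-k Koch curve rasterized at ``scale`` pixels per unit segment.

    Depth 0 is a straight line.  ``scale`` > 1 renders the shortest
    segments with several pixels, which preserves the fine structure the
    dilation estimator probes; ``margin`` pads the canvas so dilations
    are not clipped at the border.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if scale < 1 or margin < 0:
        raise ValueError("scale must be >= 1 and margin >= 0")
    if 3**depth * scale > _MAX_CANVAS:
        raise ValueError(f"depth {depth} at scale {scale} exceeds the canvas limit")
    from skimage.draw import line as _line

    pts = _koch_points(depth) * scale
    xs, ys = pts.real, pts.imag
    y0 = ys.min()
    height = int(np.ceil(ys.max() - y0)) + 1
    width = int(np.ceil(xs.max())) + 1
    img = np.zeros((height, width), dtype=np.uint8)
    cols = np.round(xs).astype(int)
    rows = np.round(ys - y0).astype(int)
    for i in range(len(pts) - 1):
        rr, cc = _line(rows[i], cols[i], rows[i + 1], cols[i + 1])
        img[rr, cc] = 1
    if margin:
        img = np.pad(img, margin)
    return img


def generate_prefractal(kind: str, depth: int) -> np.ndarray:
    """Dispatch by name: sierpinski_carpet, sierpinski_triangle, koch_curve."""
    makers = {
        "sierpinski_carpet": sierpinski_carpet,
        "sierpinski_triangle": sierpinski_triangle,
        "koch_curve": koch_curve,
    }
    try:
        return makers[kind](depth)
    except KeyError:
        raise ValueError(f"unknown prefractal kind {kind!r}") from None
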