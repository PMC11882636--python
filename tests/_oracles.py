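"""Independent brute-force oracles used to validate the fast operators.

Everything here is deliberately naive (flood fill with an explicit stack,
exhaustive scans, all-pairs distances) and shares no code with the
implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def flood_fill_label(binary: np.ndarray, connectivity: int) -> np.ndarray:
    """Label 3D components by raster-scan seeded flood fill."""
    offsets = []
    for dz, dy, dx in itertools.product((-1, 0, 1), repeat=3):
        if (dz, dy, dx) == (0, 0, 0):
            continue
        order = abs(dz) + abs(dy) + abs(dx)
        if connectivity == 6 and order > 1:
            continue
        if connectivity == 18 and order > 2:
            continue
        offsets.append((dz, dy, dx))
    binary = np.asarray(binary).astype(bool)
    labels = np.zeros(binary.shape, dtype=np.int32)
    next_label = 0
    for idx in zip(*np.nonzero(binary)):
        if labels[idx]:
            continue
        next_label += 1
        stack = [idx]
        labels[idx] = next_label
        while stack:
            z, y, x = stack.pop()
            for dz, dy, dx in offsets:
                n = (z + dz, y + dy, x + dx)
                if all(0 <= c < s for c, s in zip(n, binary.shape)):
                    if binary[n] and not labels[n]:
                        labels[n] = next_label
                        stack.append(n)
    return labels


def yen_cut_scan(counts) -> int:
    """Exhaustive scan of Yen's criterion over every cut point."""
    counts = np.asarray(counts, dtype=float)
    p = counts / counts.sum()
    best_t, best_val = None, -math.inf
    for t in range(len(p) - 1):
        P = p[: t + 1].sum()
        a = (p[: t + 1] ** 2).sum()
        b = (p[t + 1:] ** 2).sum()
        if P <= 0 or P >= 1 or a <= 0 or b <= 0:
            continue
        val = -math.log((a * b) / (P ** 2 * (1 - P) ** 2))
        if val > best_val + 1e-12:  # strict: ties keep the lower cut
            best_t, best_val = t, val
    if best_t is None:
        raise ValueError("no valid cut")
    return best_t


def ball_profile(radius: int):
    pts = []
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            d2 = dy * dy + dx * dx
            if d2 <= radius * radius:
                pts.append((dy, dx, math.sqrt(radius * radius - d2)))
    return pts


def grey_opening_ball(img: np.ndarray, radius: int) -> np.ndarray:
    """Brute-force grayscale opening by a spherical-cap ball element.

    Reflect padding, matching the implementation's border mode.
    """
    img = np.asarray(img, dtype=float)
    pts = ball_profile(radius)
    padded = np.pad(img, radius, mode="reflect")
    h, w = img.shape
    eroded = np.empty_like(img)
    for y in range(h):
        for x in range(w):
            eroded[y, x] = min(
                padded[y + radius + dy, x + radius + dx] - hh for dy, dx, hh in pts
            )
    padded_e = np.pad(eroded, radius, mode="reflect")
    opened = np.empty_like(img)
    for y in range(h):
        for x in range(w):
            opened[y, x] = max(
                padded_e[y + radius + dy, x + radius + dx] + hh for dy, dx, hh in pts
            )
    return opened


def feret_all_pairs(pixels) -> float:
    """Max distance over every pair of pixel corners, no hull shortcut."""
    corners = set()
    for y, x in pixels:
        for dy in (0, 1):
            for dx in (0, 1):
                corners.add((y + dy, x + dx))
    corners = list(corners)
    best = 0.0
    for i in range(len(corners)):
        for j in range(i, len(corners)):
            d = math.dist(corners[i], corners[j])
            best = max(best, d)
    return best


def dilate_disk(mask: np.ndarray, radius: int) -> np.ndarray:
    """Brute-force binary dilation by a Euclidean disk."""
    mask = np.asarray(mask).astype(bool)
    out = np.zeros_like(mask)
    ys, xs = np.nonzero(mask)
    h, w = mask.shape
    for y, x in zip(ys, xs):
        for dy in range(-radius, radius + 1):
            for dx in range(-radius, radius + 1):
                if dy * dy + dx * dx <= radius * radius:
                    ny, nx = y + dy, x + dx
                    if 0 <= ny < h and 0 <= nx < w:
                        out[ny, nx] = True
    return out


def fill_and_erode(mask: np.ndarray) -> np.ndarray:
    """Brute-force hole fill (4-connected background) then 3×3 erosion."""
    mask = np.asarray(mask).astype(bool)
    h, w = mask.shape
    outside = np.zeros((h, w), dtype=bool)
    stack = [(y, x) for y in range(h) for x in (0, w - 1) if not mask[y, x]]
    stack += [(y, x) for y in (0, h - 1) for x in range(w) if not mask[y, x]]
    for s in stack:
        outside[s] = True
    while stack:
        y, x = stack.pop()
        for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and not mask[ny, nx] and not outside[ny, nx]:
                outside[ny, nx] = True
                stack.append((ny, nx))
    filled = mask | ~outside
    eroded = np.zeros_like(filled)
    for y in range(h):
        for x in range(w):
            if all(
                0 <= y + dy < h and 0 <= x + dx < w and filled[y + dy, x + dx]
                for dy in (-1, 0, 1)
                for dx in (-1, 0, 1)
            ):
                eroded[y, x] = True
    return eroded


def signed_distance_blend_slice(mask0: np.ndarray, mask1: np.ndarray, w: float) -> np.ndarray:
    """Brute-force signed-distance blend of two slices at weight w."""

    def signed(mask):
        mask = np.asarray(mask).astype(bool)
        h, ww = mask.shape
        ins = np.argwhere(mask)
        outs = np.argwhere(~mask)
        sd = np.empty(mask.shape)
        for y in range(h):
            for x in range(ww):
                if mask[y, x]:
                    d = min(math.dist((y, x), p) for p in outs) if len(outs) else math.inf
                    sd[y, x] = d
                else:
                    d = min(math.dist((y, x), p) for p in ins) if len(ins) else math.inf
                    sd[y, x] = -d
        return sd

    return ((1 - w) * signed(mask0) + w * signed(mask1)) >= 0
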