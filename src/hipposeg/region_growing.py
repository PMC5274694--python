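"""Seed-based initialization of the level set.

From a single manually placed seed the stage (1) crops a square window
centered on the seed, (2) grows an 8-connected region under an adaptive
standard-deviation criterion, (3) extracts the region's inner perimeter,
(4) fits its filled convex hull, and (5) builds the initial level-set field
as a binary step: −c0 inside the hull, +c0 outside.  The hull, rather than
the raw grown region, starts the contour because a convex start resists the
local minima a noisy concave perimeter would create.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull, QhullError
from skimage.draw import line as draw_line

from .errors import UsageError

#: fixed 8-neighborhood enumeration: N, NE, E, SE, S, SW, W, NW
NEIGHBORS_8 = (
    (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1),
)


@dataclass(frozen=True)
class SliceWindow:
    """A w×w crop of the full image with its origin in full-image coords."""

    window: np.ndarray
    offset: tuple[int, int]


@dataclass(frozen=True)
class GrowthResult:
    """Region grown from the seed, with the criterion that produced it."""

    region: np.ndarray  # bool, window-local
    threshold: float  # ξ·σ_Global in intensity units
    final_mean: float  # running mean after the last admission
    visit_count: int  # pixels whose admission was tested


def extract_slice(
    image: np.ndarray, seed: tuple[int, int], window: int = 45
) -> SliceWindow:
    """Crop an odd ``window``×``window`` box centered on ``seed``.

    Near the image border the box is clamped inside the image (the seed is
    then off-center); the returned offset records the actual origin.
    """
    image = np.asarray(image)
    h, w = image.shape
    if window % 2 == 0 or window < 3:
        raise UsageError(f"window must be odd and >= 3, got {window}")
    if window > h or window > w:
        raise UsageError(f"window {window} exceeds image shape {h}x{w}")
    r, c = seed
    if not (0 <= r < h and 0 <= c < w):
        raise UsageError(f"seed {seed} outside image of shape {h}x{w}")
    half = window // 2
    r0 = int(np.clip(r - half, 0, h - window))
    c0 = int(np.clip(c - half, 0, w - window))
    return SliceWindow(
        window=image[r0 : r0 + window, c0 : c0 + window].astype(np.float64),
        offset=(r0, c0),
    )


def global_stats(window: np.ndarray | SliceWindow) -> tuple[float, float]:
    """Mean and population standard deviation of the window intensities.

    σ_Global = sqrt((1/MN) ΣΣ (I − mean)²) — the divide-by-MN form.
    """
    arr = window.window if isinstance(window, SliceWindow) else np.asarray(window)
    mean = float(arr.mean())
    sigma = float(np.sqrt(np.mean((arr - mean) ** 2)))
    return mean, sigma


def grow(
    window: np.ndarray | SliceWindow,
    seed_local: tuple[int, int],
    xi: float,
    *,
    adaptive_mean: bool = True,
) -> GrowthResult:
    """Grow an 8-connected region from the seed under |I − X̄| ≤ ξ·σ_Global.

    X̄ is the running mean of all pixels admitted so far ("current seed
    points"), updated after every admission; with ``adaptive_mean=False``
    it stays frozen at the seed intensity.  The frontier is processed FIFO
    and neighbors are enumerated N, NE, E, SE, S, SW, W, NW, so the member
    set is fully deterministic.  A pixel is tested at most once, at the
    moment it is first reached.
    """
    arr = window.window if isinstance(window, SliceWindow) else np.asarray(window)
    arr = arr.astype(np.float64)
    h, w = arr.shape
    r0, c0 = seed_local
    if not (0 <= r0 < h and 0 <= c0 < w):
        raise UsageError(f"seed {seed_local} outside window of shape {h}x{w}")
    if not xi > 0:
        raise UsageError(f"xi must be > 0, got {xi}")
    _, sigma_global = global_stats(arr)
    threshold = xi * sigma_global

    region = np.zeros((h, w), dtype=bool)
    visited = np.zeros((h, w), dtype=bool)
    visited[r0, c0] = True
    region[r0, c0] = True
    total = arr[r0, c0]
    count = 1
    visit_count = 1
    queue: deque[tuple[int, int]] = deque([(r0, c0)])
    while queue:
        r, c = queue.popleft()
        for dr, dc in NEIGHBORS_8:
            rr, cc = r + dr, c + dc
            if not (0 <= rr < h and 0 <= cc < w) or visited[rr, cc]:
                continue
            visited[rr, cc] = True
            visit_count += 1
            mean = total / count if adaptive_mean else arr[r0, c0]
            if abs(arr[rr, cc] - mean) <= threshold:
                region[rr, cc] = True
                total += arr[rr, cc]
                count += 1
                queue.append((rr, cc))
    return GrowthResult(
        region=region,
        threshold=float(threshold),
        final_mean=float(total / count if adaptive_mean else arr[r0, c0]),
        visit_count=visit_count,
    )


def extract_perimeter(region: np.ndarray) -> np.ndarray:
    """Inner boundary: members with a non-member 4-neighbor or on the border."""
    region = np.asarray(region, dtype=bool)
    if not region.any():
        raise UsageError("cannot extract the perimeter of an empty region")
    cross = ndi.generate_binary_structure(2, 1)
    interior = ndi.binary_erosion(region, structure=cross, border_value=0)
    return region & ~interior


def convex_init(perimeter: np.ndarray) -> np.ndarray:
    """Filled convex hull of the perimeter pixels.

    A pixel belongs to the output iff its center lies inside or on the hull
    of the perimeter pixel centers (ties on a hull edge included).
    Collinear input degenerates to the rasterized segment; a single pixel
    to itself.
    """
    perimeter = np.asarray(perimeter, dtype=bool)
    pts = np.argwhere(perimeter)
    if len(pts) == 0:
        raise UsageError("cannot fit a hull to an empty perimeter")
    out = np.zeros_like(perimeter)
    if len(pts) == 1:
        out[pts[0, 0], pts[0, 1]] = True
        return out
    try:
        hull = ConvexHull(pts.astype(np.float64))
    except QhullError:
        # collinear: rasterize the segment between the two extreme points
        d = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
        i, j = np.unravel_index(np.argmax(d), d.shape)
        rr, cc = draw_line(pts[i, 0], pts[i, 1], pts[j, 0], pts[j, 1])
        out[rr, cc] = True
        out |= perimeter
        return out
    rmin, cmin = pts.min(axis=0)
    rmax, cmax = pts.max(axis=0)
    rr, cc = np.mgrid[rmin : rmax + 1, cmin : cmax + 1]
    coords = np.stack([rr.ravel(), cc.ravel(), np.ones(rr.size)], axis=1)
    # hull.equations rows are (a, b, offset) with a·x + b·y + offset <= 0 inside
    inside = (coords @ hull.equations.T <= 1e-9).all(axis=1)
    out[rmin : rmax + 1, cmin : cmax + 1] = inside.reshape(rr.shape)
    out |= perimeter
    return out


def init_level_set(
    init_mask: np.ndarray,
    c0: float,
    full_shape: tuple[int, int],
    offset: tuple[int, int] = (0, 0),
) -> np.ndarray:
    """Binary-step initial field: −c0 on mask pixels, +c0 elsewhere.

    Deliberately not a signed distance function — the distance-penalty term
    regularizes φ toward one during evolution.
    """
    if not c0 > 0:
        raise UsageError(f"c0 must be > 0, got {c0}")
    init_mask = np.asarray(init_mask, dtype=bool)
    h, w = full_shape
    r0, c0_off = offset
    mh, mw = init_mask.shape
    if r0 < 0 or c0_off < 0 or r0 + mh > h or c0_off + mw > w:
        raise UsageError(
            f"mask of shape {mh}x{mw} at offset {offset} exceeds frame {h}x{w}"
        )
    phi = np.full((h, w), float(c0))
    phi[r0 : r0 + mh, c0_off : c0_off + mw][init_mask] = -float(c0)
    return phi
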