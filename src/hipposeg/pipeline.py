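"""End-to-end orchestration: seed → grown region → hull → level set → mask."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io, level_set, region_growing
from .errors import UsageError
from .metrics import dsc
from .params import ModelParams


@dataclass
class PipelineResult:
    window: region_growing.SliceWindow
    growth: region_growing.GrowthResult
    perimeter: np.ndarray
    hull: np.ndarray
    phi0: np.ndarray
    segmentation: level_set.SegmentationResult

    @property
    def mask(self) -> np.ndarray:
        """Final segmentation in the full image frame."""
        return self.segmentation.mask


def build_initialization(
    image: np.ndarray, seed: tuple[int, int], p: ModelParams
) -> tuple[region_growing.SliceWindow, region_growing.GrowthResult, np.ndarray, np.ndarray, np.ndarray]:
    """Stages 1–5: crop, grow, perimeter, hull, φ₀ (in the full frame)."""
    win = region_growing.extract_slice(image, seed, p.window)
    seed_local = (seed[0] - win.offset[0], seed[1] - win.offset[1])
    growth = region_growing.grow(win, seed_local, p.xi,
                                 adaptive_mean=p.adaptive_mean)
    perimeter = region_growing.extract_perimeter(growth.region)
    hull = region_growing.convex_init(perimeter)
    phi0 = region_growing.init_level_set(hull, p.c0, image.shape, win.offset)
    return win, growth, perimeter, hull, phi0


def segment(
    image: np.ndarray,
    seed: tuple[int, int],
    p: ModelParams | None = None,
    *,
    debug_dir: str | Path | None = None,
) -> PipelineResult:
    """Segment one 2-D image from a single seed point.

    With ``debug_dir``, every intermediate (window, grown region,
    perimeter, hull, initial and final mask) is dumped as PNG for
    inspection.
    """
    p = p or ModelParams()
    image = np.asarray(image, dtype=np.float64)
    win, growth, perimeter, hull, phi0 = build_initialization(image, seed, p)
    seg = level_set.evolve(phi0, image, p)
    result = PipelineResult(window=win, growth=growth, perimeter=perimeter,
                            hull=hull, phi0=phi0, segmentation=seg)
    if debug_dir is not None:
        debug_dir = Path(debug_dir)
        debug_dir.mkdir(parents=True, exist_ok=True)
        io.write_grayscale(win.window, debug_dir / "window.png")
        io.write_mask(growth.region, debug_dir / "region.png")
        io.write_mask(perimeter, debug_dir / "perimeter.png")
        io.write_mask(hull, debug_dir / "hull.png")
        io.write_mask(phi0 < 0, debug_dir / "init_mask.png")
        io.write_mask(seg.mask, debug_dir / "final_mask.png")
        level_set.write_history_csv(seg.history, debug_dir / "iterations.csv")
    return result


def seed_robustness(
    image: np.ndarray,
    seeds: list[tuple[int, int]],
    p: ModelParams | None = None,
    *,
    reference: np.ndarray | None = None,
) -> tuple[list[PipelineResult], np.ndarray, list[float] | None]:
    """Segment once per seed; report the pairwise-DSC matrix.

    Returns ``(results, pairwise, vs_reference)`` where ``pairwise`` is
    the symmetric n×n DSC matrix between the per-seed masks and
    ``vs_reference`` the per-seed DSC against an optional reference mask.
    """
    if len(seeds) < 2:
        raise UsageError("seed-robustness analysis needs at least 2 seeds")
    results = [segment(image, s, p) for s in seeds]
    n = len(results)
    pairwise = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pairwise[i, j] = pairwise[j, i] = dsc(results[i].mask, results[j].mask)
    vs_ref = None
    if reference is not None:
        vs_ref = [dsc(r.mask, reference) for r in results]
    return results, pairwise, vs_ref
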