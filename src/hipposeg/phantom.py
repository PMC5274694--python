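"""Synthetic MR-like 2-D phantoms with known ground truth.

The phantoms emulate what makes small medial-temporal structures hard to
segment in T1 slices: a compact target whose intensities are Gaussian with
a mean/variance contrast against background, smooth multiplicative
intensity inhomogeneity (coil shading), partially blurred boundaries, and
optionally a contiguous boundary gap blended into background (broken
boundary).  They deliberately do not simulate Rician noise statistics,
partial-volume mixtures, or neighboring confounder structures.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import binary_dilation, binary_erosion, gaussian_filter
from skimage.draw import ellipse as draw_ellipse

from .errors import UsageError


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of one phantom image.

    ``axes`` are the ellipse semi-axes in pixels (row, col); a ``crescent``
    target subtracts a second, shifted ellipse (shift fraction ``bend`` of
    the row semi-axis) to mimic the curved hippocampal body.  The bias
    field is 1 + bias_amplitude·P₂(x, y) with P₂ a fixed second-order
    polynomial normalized to max |P₂| = 1.
    """

    name: str = "phantom"
    shape: tuple[int, int] = (157, 189)
    target: str = "ellipse"  # "ellipse" | "crescent"
    center: tuple[float, float] | None = None  # defaults to image center
    axes: tuple[float, float] = (14.0, 20.0)
    angle_deg: float = 20.0
    bend: float = 0.55
    fg_mean: float = 160.0
    fg_std: float = 10.0
    bg_mean: float = 80.0
    bg_std: float = 10.0
    bias_amplitude: float = 0.0
    edge_blur: float = 1.0
    gap_fraction: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.fg_std < 0 or self.bg_std < 0:
            raise UsageError("fg_std and bg_std must be >= 0")
        if self.target not in ("ellipse", "crescent"):
            raise UsageError(f"unknown target kind {self.target!r}")
        if not 0.0 <= self.gap_fraction < 1.0:
            raise UsageError("gap_fraction must be in [0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["shape"] = list(self.shape)
        if self.center is not None:
            d["center"] = list(self.center)
        d["axes"] = list(self.axes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        for key in ("shape", "center", "axes"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise UsageError(f"unknown phantom key(s): {', '.join(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _target_mask(spec: PhantomSpec) -> np.ndarray:
    h, w = spec.shape
    cr, cc = spec.center if spec.center is not None else ((h - 1) / 2, (w - 1) / 2)
    rot = np.deg2rad(spec.angle_deg)
    rr, cc_idx = draw_ellipse(cr, cc, spec.axes[0], spec.axes[1],
                              shape=spec.shape, rotation=rot)
    mask = np.zeros(spec.shape, dtype=bool)
    mask[rr, cc_idx] = True
    if spec.target == "crescent":
        # carve with a shifted copy to leave a curved, elongated remainder
        shift = spec.bend * spec.axes[0]
        rr2, cc2 = draw_ellipse(cr - shift, cc, spec.axes[0] * 0.95,
                                spec.axes[1] * 0.95, shape=spec.shape,
                                rotation=rot)
        carve = np.zeros(spec.shape, dtype=bool)
        carve[rr2, cc2] = True
        mask &= ~carve
    if not mask.any():
        raise UsageError("phantom target is empty")
    edge = mask.copy()
    edge[1:-1, 1:-1] = False
    if edge.any():
        raise UsageError("phantom target touches the image border")
    return mask


def _bias_field(shape: tuple[int, int], amplitude: float) -> np.ndarray:
    h, w = shape
    y, x = np.mgrid[0:h, 0:w]
    X = 2.0 * x / max(w - 1, 1) - 1.0
    Y = 2.0 * y / max(h - 1, 1) - 1.0
    p = X**2 - 0.5 * Y**2 + 0.8 * X * Y + 0.4 * X
    p = p / np.abs(p).max()
    return 1.0 + amplitude * p


def _boundary_ring(mask: np.ndarray, width: int) -> np.ndarray:
    return binary_dilation(mask, iterations=width) & ~binary_erosion(
        mask, iterations=width, border_value=0
    )


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    """Render one phantom.

    Returns ``(image, truth, seed)`` where ``seed`` is the truth pixel
    nearest the target centroid (always inside the target, also for
    crescents whose centroid may fall in the carved hollow).  Identical
    specs, including ``rng_seed``, give bit-identical output.
    """
    truth = _target_mask(spec)
    rng = np.random.default_rng(spec.rng_seed)

    # noiseless anatomy first; acquisition noise is added after the PSF
    # blur, as in MR, so blurring never manufactures low-variance halos
    anatomy = np.where(truth, spec.fg_mean, spec.bg_mean).astype(np.float64)

    if spec.gap_fraction > 0:
        boundary = truth & ~binary_erosion(truth, border_value=0)
        pts = np.argwhere(boundary)
        crow, ccol = pts.mean(axis=0)
        angles = np.arctan2(pts[:, 0] - crow, pts[:, 1] - ccol)
        start = rng.uniform(-np.pi, np.pi)
        span = 2 * np.pi * spec.gap_fraction
        rel = np.mod(angles - start, 2 * np.pi)
        arc = pts[rel <= span]
        gap = np.zeros(spec.shape, dtype=bool)
        gap[arc[:, 0], arc[:, 1]] = True
        gap = binary_dilation(gap, iterations=3)
        anatomy = np.where(gap, spec.bg_mean, anatomy)
        smeared = gaussian_filter(anatomy, 1.5, mode="reflect")
        anatomy = np.where(binary_dilation(gap, iterations=2), smeared, anatomy)

    if spec.edge_blur > 0:
        width = int(np.ceil(2 * spec.edge_blur)) + 1
        band = _boundary_ring(truth, width)
        blurred = gaussian_filter(anatomy, spec.edge_blur, mode="reflect")
        anatomy = np.where(band, blurred, anatomy)

    if spec.bias_amplitude != 0:
        anatomy = anatomy * _bias_field(spec.shape, spec.bias_amplitude)

    noise_std = np.where(truth, spec.fg_std, spec.bg_std)
    image = anatomy + rng.standard_normal(spec.shape) * noise_std

    members = np.argwhere(truth)
    centroid = members.mean(axis=0)
    nearest = members[np.argmin(((members - centroid) ** 2).sum(axis=1))]
    # emulate manual seeding: a rater picks a representative-looking point,
    # not a noise speckle — take the median-intensity target pixel among
    # the 3x3 neighborhood of the centroid
    rr = slice(max(nearest[0] - 1, 0), nearest[0] + 2)
    cc = slice(max(nearest[1] - 1, 0), nearest[1] + 2)
    local = np.argwhere(truth[rr, cc]) + [rr.start, cc.start]
    values = image[local[:, 0], local[:, 1]]
    pick = local[np.argsort(values, kind="stable")[len(values) // 2]]
    seed = (int(pick[0]), int(pick[1]))
    return image, truth, seed


def analytic_area(spec: PhantomSpec) -> float:
    """Continuous area of the target blob in px² (ellipse only)."""
    if spec.target != "ellipse":
        raise UsageError("analytic area available for ellipse targets only")
    return float(np.pi * spec.axes[0] * spec.axes[1])


def phantom_suite(base_seed: int = 0) -> list[PhantomSpec]:
    """The fixed 5-family × 3-replicate test corpus.

    Families: "easy" (means 160/80), "low-contrast" (120/100),
    "equal-means-different-vars" (120/120, stds 8 vs 25), "bias-field"
    (easy + 20% shading), "broken-boundary" (easy + 20% boundary gap).
    Replicates differ only in the noise seed.
    """
    families = [
        dict(name="easy"),
        dict(name="low-contrast", fg_mean=120.0, bg_mean=100.0),
        dict(name="equal-means-different-vars", fg_mean=120.0, bg_mean=120.0,
             fg_std=8.0, bg_std=25.0),
        dict(name="bias-field", bias_amplitude=0.2),
        dict(name="broken-boundary", gap_fraction=0.2),
    ]
    specs = []
    for fam in families:
        for rep in range(3):
            d = dict(fam)
            d["rng_seed"] = int(base_seed) + rep
            d["name"] = f"{fam['name']}-s{rep}"
            specs.append(PhantomSpec(**d))
    return specs
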