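"""Model parameters for the growth + level-set pipeline.

All weights are dimensionless unless noted. ``epsilon`` (Heaviside/Dirac
width) and ``sigma`` (edge-map Gaussian kernel) are in pixels; ``dt`` is the
explicit time step of the forward-Euler evolution.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

from .errors import UsageError

#: keys that must be strictly positive numbers
_POSITIVE = ("dt", "c0", "mu", "lam", "epsilon", "sigma", "xi", "window")
#: keys that must be non-negative
_NON_NEGATIVE = ("tau", "tol")


@dataclass(frozen=True)
class ModelParams:
    """Scalar weights and numerical settings of the hybrid model.

    Defaults are the standard operating point of the method: time step
    ``dt=4`` with initial step height ``c0=2``, distance-regularization
    weight ``mu=0.05``, edge-length weight ``lam=10``, balloon weight
    ``nu=2`` (positive shrinks the inside region under the φ<0-inside
    convention), Gaussian-region weight ``tau=0.01``, mollifier width
    ``epsilon=2`` px and edge-kernel ``sigma=1`` px.  ``window`` is the
    side of the square crop centered on the seed; ``xi`` scales the global
    standard deviation of that crop into the growth threshold.
    """

    dt: float = 4.0
    c0: float = 2.0
    mu: float = 0.05
    lam: float = 10.0
    nu: float = 2.0
    tau: float = 0.01
    epsilon: float = 2.0
    sigma: float = 1.0
    xi: float = 0.6
    window: int = 45
    max_iters: int = 1000
    tol: float = 1e-3
    patience: int = 60
    adaptive_mean: bool = True

    def __post_init__(self):
        bad = []
        for key in _POSITIVE:
            v = getattr(self, key)
            if not isinstance(v, (int, float)) or isinstance(v, bool) or not v > 0:
                bad.append(key)
        for key in _NON_NEGATIVE:
            v = getattr(self, key)
            if not isinstance(v, (int, float)) or isinstance(v, bool) or v < 0:
                bad.append(key)
        if "nu" not in bad and not isinstance(self.nu, (int, float)):
            bad.append("nu")
        if "window" not in bad and (self.window < 3 or self.window % 2 == 0):
            bad.append("window")
        if self.max_iters < 0 or self.patience < 1:
            bad.append("max_iters" if self.max_iters < 0 else "patience")
        if bad:
            raise UsageError(f"invalid parameter value(s): {', '.join(sorted(bad))}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise UsageError(f"unknown parameter key(s): {', '.join(unknown)}")
        return cls(**d)

    def replace(self, **kwargs) -> "ModelParams":
        return dataclasses.replace(self, **kwargs)


def load_params(path: str | Path | None) -> ModelParams:
    """Read a flat-JSON parameter file; missing keys take the defaults.

    ``None`` returns pure defaults.  Invalid values raise
    :class:`~hipposeg.errors.UsageError` listing the offending keys.
    """
    if path is None:
        return ModelParams()
    path = Path(path)
    try:
        d = json.loads(path.read_text())
    except OSError as exc:
        raise IOError(f"cannot read parameter file {path}: {exc}") from exc
    except json.JSONDecodeError as exc:
        raise UsageError(f"malformed JSON in {path}: {exc}") from exc
    if not isinstance(d, dict):
        raise UsageError(f"parameter file {path} must contain a JSON object")
    return ModelParams.from_dict(d)


def save_params(params: ModelParams, path: str | Path) -> None:
    Path(path).write_text(json.dumps(params.to_dict(), indent=2) + "\n")
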