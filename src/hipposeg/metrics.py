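"""Overlap metrics for segmentation evaluation."""

from __future__ import annotations

import numpy as np

from .errors import UsageError


def dsc(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2·|A∩B| / (|A|+|B|), in [0, 1].

    Two empty masks agree perfectly (1.0); empty vs non-empty gives 0.0.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise UsageError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)
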