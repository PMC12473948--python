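"""Small shared numerics: commercial rounding and minimum-image arithmetic."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero at the given decimal place.

    Printed tables in this domain use commercial (half-up) rounding, not
    banker's rounding: e.g. the mean 7.645 is reported as 7.65.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def min_image_vector(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap a displacement (or array of displacements) into [-L/2, L/2) per axis."""
    delta = np.asarray(delta, dtype=float)
    box = np.asarray(box, dtype=float)
    return delta - box * np.floor(delta / box + 0.5)


def min_image_distance(p: np.ndarray, q: np.ndarray, box: np.ndarray) -> float:
    """Euclidean distance between two points under orthorhombic periodic boundaries."""
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ValueError("box edge lengths must be positive")
    d = min_image_vector(np.asarray(p, float) - np.asarray(q, float), box)
    return float(np.linalg.norm(d))
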