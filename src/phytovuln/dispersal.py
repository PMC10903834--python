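"""Dispersal limitation as an exponential distance decay.

Under the unlimited-dispersal assumption a species can occupy any newly
suitable cell; under limited dispersal, projected future suitability is
damped by ``exp(-d / alpha)`` where *d* is the distance (km) to the nearest
known presence and *alpha* is the e-folding distance.  Damping is applied
to the continuous future suitability before binarization, with the
binarization threshold unchanged, so the limited-dispersal range is always
a subset of the unlimited one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt

from .grids import GridSpec


@dataclass
class DispersalConfig:
    """Exponential decay parameters.

    decay_scale_km is the e-folding distance alpha (suitability is damped by
    1/e at that distance); km_per_cell converts grid distance to km.
    """

    decay_scale_km: float = 100.0
    km_per_cell: float = 5.0

    def __post_init__(self) -> None:
        if self.decay_scale_km <= 0:
            raise ValueError(f"decay scale must be positive, got {self.decay_scale_km}")
        if self.km_per_cell <= 0:
            raise ValueError("km_per_cell must be positive")


def distance_to_presence(
    presence_rows: np.ndarray,
    presence_cols: np.ndarray,
    shape: tuple[int, int],
    km_per_cell: float = 5.0,
) -> np.ndarray:
    """Euclidean distance (km) from every cell to the nearest presence cell."""
    presence_rows = np.atleast_1d(presence_rows)
    presence_cols = np.atleast_1d(presence_cols)
    if presence_rows.size == 0:
        raise ValueError("no presence cells supplied")
    occupied = np.zeros(shape, dtype=bool)
    occupied[presence_rows, presence_cols] = True
    return distance_transform_edt(~occupied) * km_per_cell


def apply_decay(
    future_suitability: np.ndarray,
    distance_map: np.ndarray,
    decay_scale_km: float = 100.0,
) -> np.ndarray:
    """Damp suitability: s' = s * exp(-d / alpha).

    Cells at distance zero are unchanged; output stays within [0, 1] when
    the input does.
    """
    if decay_scale_km <= 0:
        raise ValueError(f"decay scale must be positive, got {decay_scale_km}")
    distance_map = np.asarray(distance_map, dtype=float)
    if np.any(distance_map < 0):
        raise ValueError("distance map contains negative distances")
    return np.asarray(future_suitability) * np.exp(-distance_map / decay_scale_km)
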