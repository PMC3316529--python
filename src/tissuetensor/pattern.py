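"""Nucleus point patterns: the common currency between segmentation and graphs.

A :class:`PointPattern` holds 2-D nucleus centroids in micron coordinates over a
bounded rectangular field, together with the metadata (class label, time point,
sample id) that downstream tensor assembly keys on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

HEALTHY = "healthy"
CANCER = "cancer"
CLASS_LABELS = (HEALTHY, CANCER)


@dataclass
class PointPattern:
    """2-D nucleus centroids (microns) in a rectangular field.

    Parameters
    ----------
    coordinates:
        Array of shape ``(n, 2)`` with ``(x, y)`` positions in microns.
        ``x`` grows rightward and ``y`` downward (image convention).
    field_size:
        ``(width, height)`` of the observation window in microns.
    label:
        Functional state, one of ``"healthy"`` or ``"cancer"``.
    time_hours:
        Culture age for in vitro samples; ``None`` for histology.
    sample_id:
        Free-form identifier used to key tensor assembly.
    """

    coordinates: np.ndarray
    field_size: tuple[float, float]
    label: str = HEALTHY
    time_hours: Optional[float] = None
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "coordinates", coords)
        w, h = self.field_size
        if w <= 0 or h <= 0:
            raise ValueError(f"field dimensions must be positive, got {self.field_size}")
        if self.label not in CLASS_LABELS:
            raise ValueError(f"label must be one of {CLASS_LABELS}, got {self.label!r}")
        if self.time_hours is not None and self.time_hours < 0:
            raise ValueError("time_hours must be non-negative")
        if coords.size and (
            coords[:, 0].min() < 0
            or coords[:, 1].min() < 0
            or coords[:, 0].max() > w
            or coords[:, 1].max() > h
        ):
            raise ValueError("coordinates must lie inside the field")

    @property
    def n_points(self) -> int:
        return self.coordinates.shape[0]

    @property
    def area_mm2(self) -> float:
        w, h = self.field_size
        return (w / 1000.0) * (h / 1000.0)

    def with_metadata(self, **kwargs) -> "PointPattern":
        return replace(self, **kwargs)
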