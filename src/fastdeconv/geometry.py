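"""Per-spot geometry: planar coordinates plus optional histology intensity."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SpotGeometry:
    """Spatial coordinates and optional grey-scale intensity of capture spots.

    Parameters
    ----------
    spot_ids
        Ordered spot identifiers, length ``M``.
    x, y
        Planar coordinates of each spot, in the array units of the platform.
    z
        Optional grey-scale median intensity per spot, dimensionless and
        expected in ``[0, 1]`` after normalization. ``None`` when no
        histology image is available.
    """

    spot_ids: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.spot_ids = np.asarray(self.spot_ids)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        m = len(self.spot_ids)
        if self.x.shape != (m,) or self.y.shape != (m,):
            raise ValueError(
                f"coordinate vectors must have length {m}; "
                f"got x {self.x.shape}, y {self.y.shape}"
            )
        if len(np.unique(self.spot_ids)) != m:
            raise ValueError("duplicated spot_ids")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("non-finite spot coordinates")
        if self.z is not None:
            self.z = np.asarray(self.z, dtype=float)
            if self.z.shape != (m,):
                raise ValueError(f"z must have length {m}, got {self.z.shape}")
            if not np.isfinite(self.z).all():
                raise ValueError("non-finite intensities in z")

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)
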