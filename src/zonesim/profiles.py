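"""1D traces of a quantity along the centreline of the cell disc."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SurfaceProfile"]


@dataclass
class SurfaceProfile:
    """Samples of shear stress (Pa) or oxygen (mol/m^3) across the cell disc.

    ``positions`` are x-coordinates (m) along the disc centreline, strictly
    increasing and spanning the disc diameter.  ``weights`` are the segment
    lengths used for length-weighted means; they default to midpoint spacing.
    """

    positions: np.ndarray
    values: np.ndarray
    quantity: str  # "shear" | "oxygen"
    units: str
    weights: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.ndim != 1 or self.positions.shape != self.values.shape:
            raise ValueError("positions and values must be 1D arrays of equal length")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.weights is None and self.positions.size:
            x = self.positions
            edges = np.concatenate([[x[0]], 0.5 * (x[1:] + x[:-1]), [x[-1]]])
            # extend half a spacing beyond the end samples
            edges[0] -= 0.5 * (x[1] - x[0]) if x.size > 1 else 0.0
            edges[-1] += 0.5 * (x[-1] - x[-2]) if x.size > 1 else 0.0
            self.weights = np.diff(edges)
        elif self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != self.values.shape:
                raise ValueError("weights must match values in length")

    def __len__(self) -> int:
        return self.positions.size

    def mean(self) -> float:
        """Length-weighted mean of the quantity over the disc centreline."""
        if len(self) == 0:
            raise ValueError("empty profile has no mean")
        return float(np.sum(self.weights * self.values) / np.sum(self.weights))

    def min(self) -> float:
        """Pointwise minimum over the sampled centreline."""
        if len(self) == 0:
            raise ValueError("empty profile has no minimum")
        return float(np.min(self.values))

    def span(self) -> float:
        """Extent covered by the samples (m), including end half-segments."""
        return float(np.sum(self.weights))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position_m": self.positions,
                "value": self.values,
                "quantity": self.quantity,
                "units": self.units,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)
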