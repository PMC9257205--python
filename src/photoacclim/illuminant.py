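"""Daylight illuminant weighting for broadband spectral integration.

Spectral quantities are collapsed to broadband photosynthetically active
radiation by weighting with a daylight spectral power distribution.  A
nominal D55 table (typical daytime sky, correlated colour temperature
5500 K) is bundled at 10 nm resolution and interpolated onto the working
grid; weights are renormalized to sum to one so the broadband profile is a
convex combination of the per-wavelength profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidInputError
from .optics import SpectralGrid

__all__ = ["Illuminant", "D55_TABLE"]

# Nominal relative spectral power distribution of the D55 daylight
# illuminant (wavelength nm, relative power with 100 at 560 nm).
D55_TABLE = np.array(
    [
        [380.0, 32.58], [390.0, 38.09], [400.0, 60.95], [410.0, 68.55],
        [420.0, 71.58], [430.0, 67.91], [440.0, 85.61], [450.0, 97.99],
        [460.0, 100.46], [470.0, 99.91], [480.0, 102.74], [490.0, 98.08],
        [500.0, 100.68], [510.0, 100.70], [520.0, 100.34], [530.0, 104.41],
        [540.0, 102.02], [550.0, 103.00], [560.0, 100.00], [570.0, 97.22],
        [580.0, 97.75], [590.0, 91.43], [600.0, 94.42], [610.0, 95.14],
        [620.0, 94.22], [630.0, 90.45], [640.0, 92.33], [650.0, 88.85],
        [660.0, 90.32], [670.0, 93.95], [680.0, 89.96], [690.0, 79.68],
        [700.0, 82.84], [710.0, 84.84], [720.0, 70.24], [730.0, 79.30],
        [740.0, 84.84], [750.0, 71.60], [760.0, 56.89], [770.0, 77.54],
        [780.0, 72.42],
    ]
)


@dataclass(frozen=True)
class Illuminant:
    """Normalized spectral weights on a wavelength grid."""

    grid: SpectralGrid
    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.shape != self.grid.wavelengths.shape:
            raise InvalidInputError("weights must match the spectral grid")
        if np.any(w < 0):
            raise InvalidInputError("illuminant weights must be nonnegative")
        s = w.sum()
        if s <= 0:
            raise InvalidInputError("illuminant weights must not all be zero")
        object.__setattr__(self, "weights", w / s)

    def __len__(self) -> int:
        return self.weights.size

    @classmethod
    def d55(cls, grid: SpectralGrid) -> "Illuminant":
        """Bundled nominal D55 daylight distribution on ``grid``."""
        w = np.interp(grid.wavelengths, D55_TABLE[:, 0], D55_TABLE[:, 1])
        return cls(grid, w)

    @classmethod
    def flat(cls, grid: SpectralGrid) -> "Illuminant":
        return cls(grid, np.ones_like(grid.wavelengths))

    @classmethod
    def delta(cls, grid: SpectralGrid, wavelength: float) -> "Illuminant":
        """All weight on the grid node nearest ``wavelength``."""
        w = np.zeros_like(grid.wavelengths)
        w[int(np.argmin(np.abs(grid.wavelengths - wavelength)))] = 1.0
        return cls(grid, w)
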