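"""Turn discrete peak lists into comparable representations.

Two preprocessing steps precede any similarity computation: intensity
normalization to a common [0, 1] scale, and convolution of the stick
spectrum with Lorentzian line shapes onto a regular wavenumber grid so
that whole-spectrum methods (cross-correlation) can operate.

Each stick is given a unit-peak-height Lorentzian

    L(x) = I_k * gamma^2 / ((x - nu_k)^2 + gamma^2),   gamma = fwhm / 2

so the convolved maximum of an isolated line equals its stick intensity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .errors import ValidationError
from .records import Peak, SpectrumRecord

__all__ = [
    "ContinuousSpectrum",
    "DEFAULT_GRID",
    "normalize_intensities",
    "lorentzian_convolve",
    "read_continuous",
    "write_continuous",
]

logger = logging.getLogger(__name__)

#: Default wavenumber grid (start, end, step) in cm-1, covering the
#: 400-3755 cm-1 experimental range with margin.
DEFAULT_GRID = (300.0, 3800.0, 1.0)


@dataclass(frozen=True)
class ContinuousSpectrum:
    """Intensities sampled on a regular wavenumber grid."""

    grid_start: float
    grid_step: float
    values: np.ndarray

    def __post_init__(self) -> None:
        if not self.grid_step > 0:
            raise ValidationError(f"grid_step must be > 0, got {self.grid_step}")
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 1:
            raise ValidationError("values must be a non-empty 1-D array")
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise ValidationError("values must be finite and >= 0")
        object.__setattr__(self, "values", values)

    @property
    def grid(self) -> np.ndarray:
        return self.grid_start + self.grid_step * np.arange(self.values.size)

    @property
    def grid_end(self) -> float:
        return float(self.grid[-1])

    def __len__(self) -> int:
        return self.values.size


def normalize_intensities(record: SpectrumRecord) -> SpectrumRecord:
    """Divide all intensities by the maximum, so the strongest peak is 1.

    Idempotent; raises :class:`ValidationError` when every intensity is
    zero (nothing to normalize against).
    """
    if not record.peaks:
        raise ValidationError("cannot normalize an empty record")
    peak_max = max(p.intensity for p in record.peaks)
    if peak_max <= 0:
        raise ValidationError(
            f"record {record.species}/{record.conformer} has all-zero intensities"
        )
    if peak_max == 1.0:
        return record
    return record.with_peaks(
        Peak(p.frequency, p.intensity / peak_max, fwhm=p.fwhm, snr=p.snr,
             channel=p.channel)
        for p in record.peaks
    )


def lorentzian_convolve(
    record: SpectrumRecord,
    fwhm: float = 4.0,
    grid_start: float = DEFAULT_GRID[0],
    grid_end: float = DEFAULT_GRID[1],
    grid_step: float = DEFAULT_GRID[2],
) -> ContinuousSpectrum:
    """Convolve a stick spectrum with unit-height Lorentzians.

    ``fwhm`` (cm-1) is the full width at half maximum of each line; the
    result is sampled on ``[grid_start, grid_end]`` with ``grid_step``
    spacing.  A warning is emitted when a peak sits closer than
    5*fwhm to a grid edge (truncated wings).
    """
    if grid_step <= 0:
        raise ValidationError(f"grid_step must be > 0, got {grid_step}")
    if fwhm <= 0:
        raise ValidationError(f"fwhm must be > 0, got {fwhm}")
    if grid_end <= grid_start:
        raise ValidationError("grid_end must exceed grid_start")
    grid = np.arange(grid_start, grid_end + 0.5 * grid_step, grid_step)
    values = np.zeros_like(grid)
    gamma = fwhm / 2.0
    margin = 5.0 * fwhm
    for peak in record.peaks:
        if peak.frequency < grid_start + margin or peak.frequency > grid_end - margin:
            warnings.warn(
                f"peak at {peak.frequency:.1f} cm-1 lies within {margin:.0f} cm-1 "
                "of the grid edge; Lorentzian wings are truncated",
                stacklevel=2,
            )
        values += peak.intensity * gamma**2 / ((grid - peak.frequency) ** 2 + gamma**2)
    return ContinuousSpectrum(grid_start=grid_start, grid_step=grid_step, values=values)


PathLike = Union[str, Path]


def write_continuous(spectrum: ContinuousSpectrum, path: PathLike) -> None:
    """Write a convolved spectrum as a 2-column (wavenumber, intensity) CSV."""
    frame = pd.DataFrame(
        {"wavenumber": spectrum.grid, "intensity": spectrum.values}
    )
    frame.to_csv(path, index=False)


def read_continuous(path: PathLike) -> ContinuousSpectrum:
    """Read a 2-column CSV written by :func:`write_continuous`."""
    frame = pd.read_csv(path)
    for col in ("wavenumber", "intensity"):
        if col not in frame.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    grid = frame["wavenumber"].to_numpy(dtype=float)
    if grid.size < 2:
        raise ValidationError(f"{path}: need at least 2 grid points")
    steps = np.diff(grid)
    if not np.allclose(steps, steps[0]):
        raise ValidationError(f"{path}: wavenumber grid is not regular")
    return ContinuousSpectrum(
        grid_start=float(grid[0]),
        grid_step=float(steps[0]),
        values=frame["intensity"].to_numpy(dtype=float),
    )
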