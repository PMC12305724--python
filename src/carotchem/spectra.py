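"""Containers for FT-NIR absorbance spectra on a shared wavenumber grid."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpectraSet", "default_grid", "GRID_MIN", "GRID_MAX", "GRID_STEP"]

# Scan range of the FT-NIR instrument (cm^-1).  The spectrometer records
# 3594-12489 cm^-1 at 16 cm^-1 optical resolution; the digitisation step
# below is a free choice and is configurable in default_grid().
GRID_MIN = 3594.0
GRID_MAX = 12489.7
GRID_STEP = 7.7


def default_grid(step: float = GRID_STEP) -> np.ndarray:
    """Ascending wavenumber grid (cm^-1) covering the instrument range."""
    if step <= 0:
        raise ValueError("grid step must be positive")
    n = int(np.floor((GRID_MAX - GRID_MIN) / step)) + 1
    return GRID_MIN + step * np.arange(n)


@dataclass
class SpectraSet:
    """A stack of absorbance spectra sharing one wavenumber grid.

    Attributes
    ----------
    wavenumbers : (p,) ascending grid in cm^-1.
    absorbance : (n, p) matrix, one row per recorded scan.
    sample_ids : length-n sample identifiers (replicate scans share an id).
    replicate_ids : length-n replicate indices within each sample.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    sample_ids: np.ndarray
    replicate_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.sample_ids = np.asarray(self.sample_ids)
        if self.replicate_ids is None:
            self.replicate_ids = np.ones(len(self.sample_ids), dtype=int)
        else:
            self.replicate_ids = np.asarray(self.replicate_ids)
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumber grid must be strictly increasing")
        n, p = self.absorbance.shape
        if p != self.wavenumbers.size:
            raise ValueError(
                f"absorbance has {p} columns but grid has {self.wavenumbers.size} points"
            )
        if len(self.sample_ids) != n or len(self.replicate_ids) != n:
            raise ValueError("sample/replicate ids must match number of spectra")

    @property
    def n_spectra(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_points(self) -> int:
        return self.absorbance.shape[1]

    def column_labels(self) -> list[str]:
        """'sample.rep' labels, one per spectrum (used as CSV headers)."""
        return [
            f"{s}.{r}" for s, r in zip(self.sample_ids, self.replicate_ids)
        ]

    def select(self, mask: np.ndarray) -> "SpectraSet":
        """Subset spectra (rows) by boolean mask or index array."""
        return SpectraSet(
            wavenumbers=self.wavenumbers,
            absorbance=self.absorbance[mask],
            sample_ids=self.sample_ids[mask],
            replicate_ids=self.replicate_ids[mask],
        )

    def with_absorbance(self, absorbance: np.ndarray, wavenumbers: np.ndarray | None = None) -> "SpectraSet":
        """Copy of this set with a new absorbance matrix (and optional grid)."""
        return SpectraSet(
            wavenumbers=self.wavenumbers if wavenumbers is None else wavenumbers,
            absorbance=absorbance,
            sample_ids=self.sample_ids,
            replicate_ids=self.replicate_ids,
        )
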