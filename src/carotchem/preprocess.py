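"""Spectral preprocessing operators and per-analyte chains.

The operators are the standard NIR toolbox: standard normal variate
(SNV), multiplicative scatter correction (MSC), Savitzky-Golay first
derivative, Euclidean vector normalisation, and wavenumber-window
selection.  A :class:`PreprocessChain` composes them in a fixed order
(derivative -> scatter correction -> window selection), learns any
data-dependent state (the MSC reference spectrum, the window column
mask) from the calibration set only, and replays bitwise-identically at
prediction time.

Per-analyte default chains (``default_chains``) mirror the preprocessing
and analyte-correlated wavenumber windows used for the ten carrot
pigment/phenolic calibration models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy.signal import savgol_filter

from carotchem.spectra import SpectraSet

__all__ = [
    "snv",
    "msc",
    "msc_fit",
    "first_derivative",
    "vector_normalize",
    "window_mask",
    "select_windows",
    "PreprocessChain",
    "default_chains",
    "DEFAULT_WINDOWS",
]


def snv(spectrum: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-spectrum centering and unit scaling.

    Uses the sample standard deviation (ddof=1), so ``snv([1,2,3])`` is
    exactly ``[-1, 0, 1]``.  Accepts a single spectrum or a (n, p) matrix
    (rows treated independently).
    """
    x = np.asarray(spectrum, dtype=float)
    one_d = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] < 2:
        raise ValueError("SNV needs at least 2 spectral points")
    sd = x.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("SNV undefined for a constant spectrum (zero variance)")
    out = (x - x.mean(axis=1, keepdims=True)) / sd
    return out[0] if one_d else out


def msc_fit(spectra: np.ndarray) -> np.ndarray:
    """Mean spectrum of a calibration set, the default MSC reference."""
    x = np.atleast_2d(np.asarray(spectra, dtype=float))
    return x.mean(axis=0)


def msc(spectra: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum is regressed on the reference by ordinary least squares
    (intercept a, slope b); the corrected spectrum is (x - a)/b.  The
    reference must come from the calibration set (typically its mean) and
    be reused unchanged at prediction time.
    """
    x = np.asarray(spectra, dtype=float)
    one_d = x.ndim == 1
    x = np.atleast_2d(x)
    ref = np.asarray(reference, dtype=float)
    if ref.shape != (x.shape[1],):
        raise ValueError("MSC reference must be on the same grid as the spectra")
    ref_c = ref - ref.mean()
    denom = ref_c @ ref_c
    if denom == 0:
        raise ValueError("MSC reference is constant")
    out = np.empty_like(x)
    for i, row in enumerate(x):
        slope = (ref_c @ (row - row.mean())) / denom
        if abs(slope) < 1e-12:
            raise ValueError(f"MSC slope ~ 0 for spectrum {i}; cannot correct")
        intercept = row.mean() - slope * ref.mean()
        out[i] = (row - intercept) / slope
    return out[0] if one_d else out


def first_derivative(
    spectrum: np.ndarray, window: int = 17, polyorder: int = 2
) -> np.ndarray:
    """Savitzky-Golay first derivative with respect to grid index.

    Same-length output; the edges are handled by fitting the edge
    polynomial over the terminal window ('interp' mode), so window masks
    stay aligned with the input grid.
    """
    x = np.asarray(spectrum, dtype=float)
    if window % 2 == 0:
        raise ValueError("Savitzky-Golay window must be odd")
    if window > x.shape[-1]:
        raise ValueError("Savitzky-Golay window exceeds spectrum length")
    if polyorder >= window:
        raise ValueError("polyorder must be smaller than window")
    return savgol_filter(x, window, polyorder, deriv=1, delta=1.0, mode="interp", axis=-1)


def vector_normalize(spectrum: np.ndarray) -> np.ndarray:
    """Scale each spectrum to unit Euclidean norm."""
    x = np.asarray(spectrum, dtype=float)
    one_d = x.ndim == 1
    x = np.atleast_2d(x)
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("cannot normalize a zero spectrum")
    out = x / norms
    return out[0] if one_d else out


def window_mask(
    wavenumbers: np.ndarray, windows: Sequence[Sequence[float]]
) -> np.ndarray:
    """Boolean mask of grid points falling in any closed [lo, hi] window."""
    wn = np.asarray(wavenumbers, dtype=float)
    if len(windows) == 0:
        raise ValueError("window list must be non-empty")
    mask = np.zeros(wn.size, dtype=bool)
    for lo, hi in windows:
        if not lo < hi:
            raise ValueError(f"window [{lo}, {hi}] must have lo < hi")
        mask |= (wn >= lo) & (wn <= hi)
    if not mask.any():
        raise ValueError("windows select zero grid points")
    return mask


def select_windows(spectra: SpectraSet, windows: Sequence[Sequence[float]]) -> SpectraSet:
    """Restrict a spectra set to grid points inside the given windows."""
    mask = window_mask(spectra.wavenumbers, windows)
    return spectra.with_absorbance(
        spectra.absorbance[:, mask], wavenumbers=spectra.wavenumbers[mask]
    )


# ---------------------------------------------------------------------------
# chains

_SCATTER_OPS = ("snv", "msc", "vector_normalize")


@dataclass
class PreprocessChain:
    """Ordered preprocessing pipeline for one analyte's calibration model.

    steps is a list of (name, params) descriptors with names among
    'first_derivative', 'snv', 'msc', 'vector_normalize', 'select_windows'.
    At most one window step is allowed and it always runs last.  ``fit``
    learns data-dependent state from the calibration set; ``transform``
    replays the stored chain.
    """

    analyte: str
    steps: list[tuple[str, dict[str, Any]]] = field(default_factory=list)
    msc_reference_: np.ndarray | None = None
    mask_: np.ndarray | None = None

    def __post_init__(self) -> None:
        names = [s[0] for s in self.steps]
        n_win = names.count("select_windows")
        if n_win > 1:
            raise ValueError("at most one select_windows step per chain")
        if n_win == 1 and names[-1] != "select_windows":
            raise ValueError("select_windows must be the last step")

    def fit(self, spectra: SpectraSet) -> "PreprocessChain":
        """Learn MSC reference / window mask from the calibration set."""
        x = spectra.absorbance
        wn = spectra.wavenumbers
        for name, params in self.steps:
            if name == "first_derivative":
                x = first_derivative(x, **params)
            elif name == "snv":
                x = snv(x)
            elif name == "vector_normalize":
                x = vector_normalize(x)
            elif name == "msc":
                self.msc_reference_ = msc_fit(x)
                x = msc(x, self.msc_reference_)
            elif name == "select_windows":
                self.mask_ = window_mask(wn, params["windows"])
                x = x[:, self.mask_]
            else:
                raise ValueError(f"unknown preprocessing step {name!r}")
        return self

    def transform(self, spectra: SpectraSet) -> SpectraSet:
        """Apply the stored chain; never re-estimates from the input."""
        x = spectra.absorbance
        wn = spectra.wavenumbers
        for name, params in self.steps:
            if name == "first_derivative":
                x = first_derivative(x, **params)
            elif name == "snv":
                x = snv(x)
            elif name == "vector_normalize":
                x = vector_normalize(x)
            elif name == "msc":
                if self.msc_reference_ is None:
                    raise RuntimeError("chain has an MSC step but was not fitted")
                x = msc(x, self.msc_reference_)
            elif name == "select_windows":
                if self.mask_ is None:
                    raise RuntimeError("chain has a window step but was not fitted")
                if self.mask_.size != wn.size:
                    raise ValueError("window mask does not match input grid")
                wn = wn[self.mask_]
                x = x[:, self.mask_]
        return spectra.with_absorbance(np.atleast_2d(x), wavenumbers=wn)

    def fit_transform(self, spectra: SpectraSet) -> SpectraSet:
        return self.fit(spectra).transform(spectra)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "analyte": self.analyte,
            "steps": [[name, params] for name, params in self.steps],
        }
        if self.msc_reference_ is not None:
            d["msc_reference"] = self.msc_reference_.tolist()
        if self.mask_ is not None:
            d["mask"] = self.mask_.astype(int).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PreprocessChain":
        chain = cls(
            analyte=d["analyte"],
            steps=[(name, dict(params)) for name, params in d["steps"]],
        )
        if "msc_reference" in d:
            chain.msc_reference_ = np.asarray(d["msc_reference"], dtype=float)
        if "mask" in d:
            chain.mask_ = np.asarray(d["mask"], dtype=bool)
        return chain


# Analyte-correlated wavenumber windows (cm^-1) for the ten modeled
# responses, as identified on the optimized calibration models.
DEFAULT_WINDOWS: dict[str, list[list[float]]] = {
    "Total_ACN": [[8925.6, 12489.7], [4482.1, 7159.0]],
    "Total_AcA": [[8925.6, 12489.7], [4482.1, 7159.0]],
    "Cy3XSGG": [[9820.5, 10715.5], [4482.1, 6264.1]],
    "Cy3XFGG": [[8925.6, 12489.7], [7151.3, 8046.2], [5369.2, 6264.1]],
    "Cy3XCGG": [[11594.8, 12489.7], [7151.3, 10715.4], [4482.1, 5377.0]],
    "Cy3XG": [[11594.8, 12489.7], [8038.4, 10715.4]],
    "Cy3XGG": [[11594.8, 12489.7], [8038.4, 10715.4]],
    "Total_PHEN": [[4597.8, 9403.9]],
    "3CQA": [[6819.6, 9403.9], [3610.4, 4242.9]],
    "CA": [[8887.0, 9403.9], [7336.4, 7861.0], [4752.9, 6827.3]],
}

# Scatter/derivative treatment per analyte: SNV alone for the anthocyanin
# totals and Cy3XSGG/Cy3XCGG/Cy3XG/Cy3XGG; first derivative + vector
# normalization for Cy3XFGG; first derivative + MSC for Total_PHEN; first
# derivative + SNV for 3CQA and CA.
_CHAIN_RECIPES: dict[str, list[str]] = {
    "Total_ACN": ["snv"],
    "Total_AcA": ["snv"],
    "Cy3XSGG": ["snv"],
    "Cy3XFGG": ["first_derivative", "vector_normalize"],
    "Cy3XCGG": ["snv"],
    "Cy3XG": ["snv"],
    "Cy3XGG": ["snv"],
    "Total_PHEN": ["first_derivative", "msc"],
    "3CQA": ["first_derivative", "snv"],
    "CA": ["first_derivative", "snv"],
}


def default_chains(
    derivative_window: int = 17,
    derivative_polyorder: int = 2,
    scatter_steps: bool = True,
) -> dict[str, PreprocessChain]:
    """Default per-analyte preprocessing chains.

    With ``scatter_steps=False`` the SNV/MSC/vector-normalization steps are
    omitted (derivative and windows kept) - the appropriate configuration
    for spectra simulated without scatter, where there is nothing for a
    scatter correction to remove.
    """
    chains: dict[str, PreprocessChain] = {}
    for analyte, recipe in _CHAIN_RECIPES.items():
        steps: list[tuple[str, dict[str, Any]]] = []
        for op in recipe:
            if op == "first_derivative":
                steps.append(
                    (op, {"window": derivative_window, "polyorder": derivative_polyorder})
                )
            elif op in _SCATTER_OPS:
                if scatter_steps:
                    steps.append((op, {}))
            else:  # pragma: no cover - recipes are static
                raise AssertionError(op)
        steps.append(("select_windows", {"windows": DEFAULT_WINDOWS[analyte]}))
        chains[analyte] = PreprocessChain(analyte=analyte, steps=steps)
    return chains
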