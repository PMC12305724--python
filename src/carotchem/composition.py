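"""Composition, correlation, and color statistics for pigment tables.

Downstream analysis of per-sample metabolite concentrations and color
extracts: degree of acylation and pigment percentage shares, Pearson
correlations, PCA, per-phenotype group summaries, and the colorimetric
quantities color density CD = (A420-A700)+(A520-A700) and hue
H = (A520-A700)/(A420-A700) of pigment extracts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "ACYLATED",
    "NON_ACYLATED",
    "PIGMENTS",
    "degree_of_acylation",
    "composition_table",
    "pearson",
    "correlation_matrix",
    "pca",
    "color_density",
    "hue",
    "extraction_efficiency",
    "group_summary",
]

ACYLATED = ["Cy3XSGG", "Cy3XFGG", "Cy3XCGG"]
NON_ACYLATED = ["Cy3XG", "Cy3XGG"]
PIGMENTS = ACYLATED + NON_ACYLATED


def degree_of_acylation(acA, naa):
    """Percent of total anthocyanin mass that is acylated, 100*AcA/(AcA+NAA).

    Element-wise on arrays.  Undefined (NaN) where both inputs are zero;
    negative inputs are a contract error.
    """
    acA = np.asarray(acA, dtype=float)
    naa = np.asarray(naa, dtype=float)
    if np.any(acA < 0) or np.any(naa < 0):
        raise ValueError("concentrations must be non-negative")
    total = acA + naa
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, 100.0 * acA / np.where(total > 0, total, 1.0), np.nan)
    return float(out) if out.ndim == 0 else out


def composition_table(
    profiles: pd.DataFrame, detection_floor: float = 0.5
) -> pd.DataFrame:
    """Per-sample pigment shares (% of total ACN) and degree of acylation.

    Samples whose total anthocyanin falls at or below ``detection_floor``
    (ug/100 g dw) are dropped: percentage composition is meaningless for
    trace/non-detected totals.  Shares of the five cyanidins sum to 100.
    """
    total = profiles[PIGMENTS].sum(axis=1)
    keep = total > detection_floor
    sub = profiles.loc[keep]
    total = total[keep]
    out = pd.DataFrame(index=sub.index)
    if "sample_id" in sub:
        out["sample_id"] = sub["sample_id"]
    if "phenotype" in sub:
        out["phenotype"] = sub["phenotype"]
    for pigment in PIGMENTS:
        out[f"pct_{pigment}"] = 100.0 * sub[pigment] / total
    out["pct_acylation"] = degree_of_acylation(
        sub[ACYLATED].sum(axis=1).to_numpy(), sub[NON_ACYLATED].sum(axis=1).to_numpy()
    )
    return out


def pearson(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided p-value.

    The p-value comes from the exact t-transform with n-2 degrees of
    freedom (scipy's convention).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("Pearson correlation undefined for constant input")
    r, p = _sps.pearsonr(x, y)
    return float(r), float(p)


def correlation_matrix(table: pd.DataFrame, columns: list[str] | None = None):
    """Square Pearson r matrix with a parallel p-value matrix."""
    cols = columns if columns is not None else [
        c for c in table.columns if np.issubdtype(table[c].dtype, np.number)
    ]
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            rij, pij = pearson(table[cols[i]], table[cols[j]])
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )


def pca(table, scale: bool = False):
    """Principal component analysis by SVD of the centered data matrix.

    Returns (variance_explained_percent, loadings) where loadings has one
    column per component (rows follow the input columns).  With
    ``scale=True`` columns are divided by their standard deviation first.
    """
    if isinstance(table, pd.DataFrame):
        X = table.to_numpy(dtype=float)
        names = list(table.columns)
    else:
        X = np.asarray(table, dtype=float)
        names = None
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs at least a 2x2 matrix")
    if not np.isfinite(X).all():
        raise ValueError("PCA input must be finite")
    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("cannot unit-scale a constant column")
        Xc = Xc / sd
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    explained = 100.0 * var / var.sum()
    loadings = vt.T
    if names is not None:
        loadings = pd.DataFrame(
            loadings, index=names, columns=[f"PC{i + 1}" for i in range(loadings.shape[1])]
        )
    return explained, loadings


def color_density(a420, a520, a700):
    """Color density CD = (A420 - A700) + (A520 - A700) of an extract."""
    a420, a520, a700 = (np.asarray(a, dtype=float) for a in (a420, a520, a700))
    _check_absorbance(a420, a520, a700)
    out = (a420 - a700) + (a520 - a700)
    return float(out) if out.ndim == 0 else out


def hue(a420, a520, a700):
    """Hue H = (A520 - A700)/(A420 - A700), a browning/oxidation index.

    Lower hue indicates more browning.  Undefined (NaN) where A420 = A700.
    """
    a420, a520, a700 = (np.asarray(a, dtype=float) for a in (a420, a520, a700))
    _check_absorbance(a420, a520, a700)
    denom = a420 - a700
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom != 0, (a520 - a700) / np.where(denom != 0, denom, 1.0), np.nan)
    return float(out) if out.ndim == 0 else out


def _check_absorbance(*arrays: np.ndarray) -> None:
    for a in arrays:
        if np.any(a < 0):
            raise ValueError("absorbances must be non-negative")


def extraction_efficiency(extract_conc, puree_conc):
    """Percent of the puree concentration recovered in the color extract.

    Values above 100 % are possible with measurement noise; they are kept
    but flagged with a warning.
    """
    extract_conc = np.asarray(extract_conc, dtype=float)
    puree_conc = np.asarray(puree_conc, dtype=float)
    if np.any(puree_conc <= 0):
        raise ValueError("puree concentration must be positive")
    if np.any(extract_conc < 0):
        raise ValueError("extract concentration must be non-negative")
    out = 100.0 * extract_conc / puree_conc
    if np.any(out > 100.0):
        warnings.warn("extraction efficiency above 100 % (measurement noise)", stacklevel=2)
    return float(out) if out.ndim == 0 else out


def group_summary(
    table: pd.DataFrame, by: str = "phenotype", analytes: list[str] | None = None
) -> pd.DataFrame:
    """Per-phenotype mean/median/min/max of each analyte column.

    Groups are ordered by their code string; the result has a
    (group, statistic) row MultiIndex.
    """
    if by not in table:
        raise ValueError(f"grouping column {by!r} missing")
    if analytes is None:
        analytes = [
            c for c in table.columns if np.issubdtype(table[c].dtype, np.number)
        ]
    grouped = table.groupby(by, sort=True)[analytes]
    out = grouped.agg(["mean", "median", "min", "max"])
    # -> rows (group, stat), columns analytes
    return out.stack(level=1, future_stack=True).sort_index()
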