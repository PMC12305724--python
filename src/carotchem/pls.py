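"""NIPALS partial least squares regression for a single response (PLS1).

One calibration model is built per analyte: the preprocessed spectra
matrix X (n scans x p retained grid points) is regressed on a single
concentration vector y.  NIPALS extracts latent variables one at a time
from column-centered X and centered y, deflating X after each component;
the regression coefficient vector is b = W (P'W)^-1 q and predictions
are yhat = ybar + (x - xbar) . b.

Replicate scans of the same sample are kept as separate rows but are
always assigned to the same cross-validation fold (grouping by sample
id) so that rank selection is not inflated by replicate leakage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["CalibrationModel", "fit_pls1", "predict", "select_rank", "make_folds"]

# NIPALS component iteration stops when the score vector moves less than
# this (relative norm) or after _MAX_ITER sweeps.  For a single response
# the iteration converges in one sweep; the loop guards the general case.
_TOL = 1e-12
_MAX_ITER = 500


@dataclass
class CalibrationModel:
    """A fitted PLS1 calibration for one analyte.

    Holds the centering vectors, the per-component weights W, X-loadings
    P and y-loadings q, the collapsed regression coefficients, and
    training metadata.  ``chain`` optionally stores the serialized
    preprocessing chain so a saved model is self-contained.
    """

    analyte: str
    rank: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray       # (p, rank)
    x_loadings: np.ndarray    # (p, rank)
    y_loadings: np.ndarray    # (rank,)
    coef: np.ndarray          # (p,)
    n_samples: int
    wavenumbers: np.ndarray | None = None
    chain: dict[str, Any] | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.coef.size:
            raise ValueError(
                f"model expects {self.coef.size} spectral points, got {X.shape[1]}"
            )
        return self.y_mean + (X - self.x_mean) @ self.coef

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = {
            "analyte": self.analyte,
            "rank": self.rank,
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "coef": self.coef.tolist(),
            "n_samples": self.n_samples,
            "metadata": self.metadata,
        }
        if self.wavenumbers is not None:
            d["wavenumbers"] = self.wavenumbers.tolist()
        if self.chain is not None:
            d["chain"] = self.chain
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "CalibrationModel":
        return cls(
            analyte=d["analyte"],
            rank=d["rank"],
            x_mean=np.asarray(d["x_mean"], dtype=float),
            y_mean=float(d["y_mean"]),
            weights=np.asarray(d["weights"], dtype=float),
            x_loadings=np.asarray(d["x_loadings"], dtype=float),
            y_loadings=np.asarray(d["y_loadings"], dtype=float),
            coef=np.asarray(d["coef"], dtype=float),
            n_samples=int(d["n_samples"]),
            wavenumbers=(
                np.asarray(d["wavenumbers"], dtype=float) if "wavenumbers" in d else None
            ),
            chain=d.get("chain"),
            metadata=d.get("metadata", {}),
        )

    def config_hash(self) -> str:
        """Short stable hash of the model definition (for manifests)."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def fit_pls1(
    X: np.ndarray,
    y: np.ndarray,
    rank: int,
    analyte: str = "",
    wavenumbers: np.ndarray | None = None,
    chain: dict[str, Any] | None = None,
    metadata: dict[str, Any] | None = None,
) -> CalibrationModel:
    """Fit a PLS1 model with `rank` latent variables by NIPALS deflation.

    Stops early (with the achieved rank recorded) if a component carries
    no remaining X variance.  `rank=0` is a contract error; use the model
    mean directly if a mean-only prediction is wanted.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if rank < 1:
        raise ValueError("rank must be >= 1 (mean-only prediction is not a PLS model)")
    if y.size != n:
        raise ValueError("X rows and y length differ")
    if n < rank + 1:
        raise ValueError(f"need at least rank+1={rank + 1} samples, got {n}")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("X and y must be finite (no missing values)")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    E = X - x_mean
    f = y - y_mean

    W = np.zeros((p, rank))
    P = np.zeros((p, rank))
    q = np.zeros(rank)
    achieved = 0
    for a in range(rank):
        w = E.T @ f
        w_norm = np.linalg.norm(w)
        if w_norm < 1e-14 * max(1.0, np.abs(f).max(initial=0.0)):
            break  # no covariance left to model
        w /= w_norm
        t = E @ w
        # NIPALS refinement loop; for a single y this converges immediately,
        # the loop is kept for robustness against degenerate scalings.
        for _ in range(_MAX_ITER):
            tt = t @ t
            if tt == 0:
                break
            w_new = E.T @ f
            nrm = np.linalg.norm(w_new)
            if nrm == 0:
                break
            w_new /= nrm
            t_new = E @ w_new
            if np.linalg.norm(t_new - t) <= _TOL * max(1.0, np.linalg.norm(t)):
                w, t = w_new, t_new
                break
            w, t = w_new, t_new
        tt = t @ t
        if tt == 0:
            break
        p_a = E.T @ t / tt
        q_a = f @ t / tt
        E = E - np.outer(t, p_a)
        f = f - q_a * t
        W[:, a], P[:, a], q[a] = w, p_a, q_a
        achieved += 1

    if achieved == 0:
        raise ValueError("no PLS component could be extracted (y uncorrelated or constant)")
    W, P, q = W[:, :achieved], P[:, :achieved], q[:achieved]
    coef = W @ np.linalg.solve(P.T @ W, q)
    return CalibrationModel(
        analyte=analyte,
        rank=achieved,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        coef=coef,
        n_samples=n,
        wavenumbers=None if wavenumbers is None else np.asarray(wavenumbers, float),
        chain=chain,
        metadata=metadata or {},
    )


def predict(model: CalibrationModel, X: np.ndarray) -> np.ndarray:
    """Predict concentrations from preprocessed spectra rows."""
    return model.predict(X)


def scores(model: CalibrationModel, X: np.ndarray) -> np.ndarray:
    """Latent-variable scores T = (X - xbar) W (P'W)^-1 for diagnostics."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    R = model.weights @ np.linalg.inv(model.x_loadings.T @ model.weights)
    return (X - model.x_mean) @ R


def make_folds(
    sample_ids: np.ndarray,
    k: int,
    seed: int,
    y: np.ndarray | None = None,
) -> np.ndarray:
    """Assign a fold (0..k-1) to every row, grouping replicates by sample.

    All rows sharing a sample id land in the same fold.  When `y` is
    given, distinct samples are ordered by their mean concentration and
    dealt round-robin into folds within a small shuffled window, i.e. a
    seeded concentration-stratified assignment; otherwise samples are
    shuffled uniformly.
    """
    sample_ids = np.asarray(sample_ids)
    uniq, inverse = np.unique(sample_ids, return_inverse=True)
    n_samples = uniq.size
    if k < 2:
        raise ValueError("need at least 2 folds")
    if k > n_samples:
        raise ValueError(f"k={k} folds but only {n_samples} distinct samples")
    rng = np.random.default_rng(seed)
    if y is None:
        order = rng.permutation(n_samples)
    else:
        y = np.asarray(y, dtype=float).ravel()
        means = np.zeros(n_samples)
        counts = np.zeros(n_samples)
        np.add.at(means, inverse, y)
        np.add.at(counts, inverse, 1.0)
        means /= counts
        order = np.argsort(means, kind="stable")
        # shuffle within consecutive blocks of k so each fold samples every
        # concentration stratum
        for start in range(0, n_samples, k):
            block = order[start : start + k].copy()
            rng.shuffle(block)
            order[start : start + k] = block
    sample_fold = np.empty(n_samples, dtype=int)
    sample_fold[order] = np.arange(n_samples) % k
    return sample_fold[inverse]


def select_rank(
    X: np.ndarray,
    y: np.ndarray,
    sample_ids: np.ndarray | None = None,
    k: int = 5,
    max_rank: int = 10,
    seed: int = 0,
) -> int:
    """Pick the PLS rank minimizing grouped k-fold RMSECV over 1..max_rank.

    Ties break toward the smaller rank.  If a fold cannot support a rank
    (too few samples) the sweep stops at the largest feasible rank.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if max_rank < 1:
        raise ValueError("max_rank must be >= 1")
    if sample_ids is None:
        sample_ids = np.arange(len(y))
    folds = make_folds(sample_ids, k=k, seed=seed, y=y)
    max_feasible = min(max_rank, min(np.sum(folds != f) for f in range(k)) - 1, X.shape[1])
    press = np.full(max_feasible, np.inf)
    for rank in range(1, max_feasible + 1):
        sse = 0.0
        for f in range(k):
            tr, te = folds != f, folds == f
            model = fit_pls1(X[tr], y[tr], rank=rank)
            resid = model.predict(X[te]) - y[te]
            sse += float(resid @ resid)
        press[rank - 1] = sse
    best = int(np.argmin(press)) + 1  # argmin takes the first (smallest) minimiser
    return best
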