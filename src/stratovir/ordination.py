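"""Nonmetric multidimensional scaling (NMDS) by iterative majorization.

Embeds a sample dissimilarity matrix in k dimensions so that embedded
distances preserve the rank order of the dissimilarities, minimizing
Kruskal stress-1:

    stress = sqrt( sum_(i<j) (d_ij - dhat_ij)^2 / sum_(i<j) d_ij^2 )

where d are configuration distances and dhat are the isotonic (monotone)
disparities fitted to d against the dissimilarity ranks. Each iteration
alternates an isotonic regression step (optimal dhat given d) with a
Guttman transform (configuration update given dhat); the best of several
random restarts is returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression


@dataclass
class NmdsResult:
    coordinates: np.ndarray          # n x k
    stress: float
    stress_history: list[float]      # per-iteration stress of the best run
    converged: bool


def _validate(diss: np.ndarray) -> np.ndarray:
    d = np.asarray(diss, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    if (d < 0).any():
        raise ValueError("dissimilarities must be non-negative")
    return d


def _stress1(d: np.ndarray, dhat: np.ndarray) -> float:
    denom = float((d ** 2).sum())
    if denom == 0.0:
        return 0.0
    return float(np.sqrt(((d - dhat) ** 2).sum() / denom))


def nmds(beta, k: int = 2, seed: int = 0, n_restarts: int = 10,
         max_iter: int = 500, tol: float = 1e-6) -> NmdsResult:
    """Nonmetric MDS of a dissimilarity matrix.

    Accepts a square array or a labelled DataFrame; needs at least k+1
    samples. Stress is recorded per iteration and is non-increasing: a run
    stops at convergence (improvement < ``tol``) or at the first
    non-improving step, whichever comes first. Same seed, same output.
    """
    labels = None
    if isinstance(beta, pd.DataFrame):
        labels = list(beta.index)
        beta = beta.values
    d0 = _validate(beta)
    n = d0.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} samples for k={k}")
    if not d0.any():
        return NmdsResult(coordinates=np.zeros((n, k)), stress=0.0,
                          stress_history=[0.0], converged=True)

    iu = np.triu_indices(n, k=1)
    dvec = d0[iu]
    # secondary tie handling: equal dissimilarities share one disparity,
    # so e.g. three equidistant samples embed as an equilateral triangle
    uniq, block = np.unique(dvec, return_inverse=True)
    n_blocks = len(uniq)
    block_w = np.bincount(block).astype(float)
    block_x = np.arange(n_blocks, dtype=float)
    rng = np.random.default_rng(seed)

    best: NmdsResult | None = None
    for _ in range(n_restarts):
        X = rng.normal(size=(n, k))
        history: list[float] = []
        converged = False
        prev_stress = np.inf
        prev_X = X
        for _ in range(max_iter):
            d = pdist(X)
            # monotone disparities: weighted isotonic fit of per-block mean
            # distances on dissimilarity ranks, broadcast back to pairs
            block_mean = np.bincount(block, weights=d) / block_w
            iso = IsotonicRegression(increasing=True)
            dhat = iso.fit_transform(block_x, block_mean,
                                     sample_weight=block_w)[block]
            # rescale so disparities live on the distance scale
            ss = float((dhat ** 2).sum())
            if ss > 0:
                dhat = dhat * np.sqrt(float((d ** 2).sum()) / ss)
            stress = _stress1(d, dhat)
            if stress > prev_stress:       # no improvement: keep previous X
                X = prev_X
                converged = True
                break
            history.append(stress)
            if prev_stress - stress < tol:
                converged = True
                break
            prev_stress = stress
            prev_X = X
            # Guttman transform
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(d > 0, dhat / d, 0.0)
            B = -squareform(ratio)
            np.fill_diagonal(B, -B.sum(axis=1))
            X = (B @ X) / n
        final = history[-1] if history else _stress1(pdist(X), pdist(X))
        if best is None or final < best.stress:
            best = NmdsResult(coordinates=X, stress=final,
                              stress_history=history, converged=converged)
    assert best is not None
    if labels is not None:
        best.coordinates = pd.DataFrame(
            best.coordinates, index=labels,
            columns=[f"dim{i + 1}" for i in range(k)])
    return best
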