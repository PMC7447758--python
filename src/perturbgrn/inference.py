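"""Sparse network estimators and the sign-constrained refit.

All estimators fit the regression form ``-P = A Y`` of the steady-state
model, ignoring the error terms (the errors-in-variables structure is
handled downstream, in validation).  Sparsity is induced either by a
magnitude cutoff on the least-squares / total-least-squares estimate
(LSCO, TLSCO) or by an L1 penalty (LASSO).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import nnls
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso

from .model import ZERO_TOL, GeneNetwork, PerturbationDataset, pseudo_inverse


def _apply_cutoff(A: np.ndarray, zeta: float) -> np.ndarray:
    """Zero out entries with |a| < zeta (ties at the threshold are kept)."""
    if zeta < 0:
        raise ValueError("cutoff must be nonnegative")
    out = A.copy()
    out[np.abs(out) < zeta] = 0.0
    return out


def lsco(ds: PerturbationDataset, zeta: float = 0.0) -> GeneNetwork:
    """Least squares with a cutoff.

    The full estimate is ``A = -P @ pinv(Y)``, the least-squares solution
    of ``-P = A Y``; entries below ``zeta`` in magnitude are then removed.
    """
    if not np.any(ds.Y):
        raise ValueError("all-zero expression matrix: regression is degenerate")
    A = -ds.P @ np.linalg.pinv(ds.Y)
    A = _apply_cutoff(A, zeta)
    return GeneNetwork(A, list(ds.genes), {"method": "lsco", "zeta": zeta})


def lasso_infer(ds: PerturbationDataset, lam: float) -> GeneNetwork:
    """Row-wise LASSO: min ||(-P_i)^T - Y^T a||^2 + lam * ||a||_1.

    No intercept and no standardization — fold changes are already
    relative to control, so the model is physically scaled.  lam = 0
    reduces to ordinary least squares.
    """
    if lam < 0:
        raise ValueError("penalty must be nonnegative")
    n, m = ds.Y.shape
    X = ds.Y.T  # m x n predictors
    B = -ds.P.T  # m x n responses, one column per gene row of A
    if lam == 0.0:
        A = np.linalg.lstsq(X, B, rcond=None)[0].T
    else:
        # sklearn minimizes (1/2m)||r - Xa||^2 + alpha||a||_1
        model = Lasso(alpha=lam / (2.0 * m), fit_intercept=False,
                      max_iter=100_000, tol=1e-10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(X, B)
        A = np.atleast_2d(model.coef_)
    A = A.copy()
    A[np.abs(A) < ZERO_TOL] = 0.0
    return GeneNetwork(A, list(ds.genes), {"method": "lasso", "lambda": lam})


def tlsco(ds: PerturbationDataset, zeta: float = 0.0) -> GeneNetwork:
    """Total least squares with a cutoff (errors in both Y and P).

    Classical multivariate TLS for ``Y^T A^T ~ (-P)^T``: take the SVD of
    the augmented matrix ``[Y^T | (-P)^T]``, partition the right singular
    vectors into N x N blocks and set ``A^T = -V12 @ inv(V22)``.  Reduces
    to the least-squares solution when the residual is zero.
    """
    n, m = ds.Y.shape
    if m < 2 * n:
        warnings.warn(
            f"TLS with {m} experiments for {n} genes (< 2N) may be unreliable",
            stacklevel=2,
        )
    C = np.hstack([ds.Y.T, -ds.P.T])  # m x 2n
    _, _, Vt = np.linalg.svd(C, full_matrices=True)
    V = Vt.T
    V12 = V[:n, n:]
    V22 = V[n:, n:]
    if np.linalg.matrix_rank(V22) < n:
        raise np.linalg.LinAlgError(
            "TLS V22 block is singular: augmented matrix is rank deficient"
        )
    At = -V12 @ np.linalg.inv(V22)
    A = _apply_cutoff(At.T, zeta)
    return GeneNetwork(A, list(ds.genes), {"method": "tlsco", "zeta": zeta})


_METHODS = {"lsco": lsco, "lasso": lasso_infer, "tlsco": tlsco}


def infer(ds: PerturbationDataset, method: str, penalty: float) -> GeneNetwork:
    """Dispatch to one of the estimators by name."""
    try:
        fn = _METHODS[method]
    except KeyError:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(_METHODS)}")
    return fn(ds, penalty)


def cls_refit(topology: GeneNetwork, ds: PerturbationDataset) -> GeneNetwork:
    """Constrained least squares: refit weights on a fixed signed topology.

    Per target gene (row) ``i``, minimize ``||P_i + a_i Y||^2`` over the
    entries of ``a_i`` restricted to the topology's support, subject to
    the sign constraints ``s_ij * a_ij >= 0``.  Solved by substituting
    ``a_ij = s_ij * b_ij`` with ``b >= 0`` (nonnegative least squares).
    The zero pattern and link signs of the topology are preserved; a
    constrained coefficient may shrink to exactly zero.
    """
    if topology.n_genes != ds.n_genes:
        raise ValueError("topology and dataset gene counts differ")
    signs = topology.signs
    A = np.zeros_like(topology.A)
    for i in range(topology.n_genes):
        j_idx = np.flatnonzero(signs[i])
        if j_idx.size == 0:
            continue
        # design: columns s_j * Y_j ; target: -P_i
        X = (signs[i, j_idx][:, None] * ds.Y[j_idx, :]).T
        b, _ = nnls(X, -ds.P[i, :])
        A[i, j_idx] = signs[i, j_idx] * b
    A[np.abs(A) < ZERO_TOL] = 0.0
    meta = dict(topology.metadata)
    meta["refit"] = "cls"
    return GeneNetwork(A, list(topology.genes), meta)


def sparsity_sweep(
    ds: PerturbationDataset, method: str = "lsco", n_points: int = 10
) -> list[tuple[float, GeneNetwork]]:
    """Penalty grid spanning the empty-to-full network range.

    Returns ``(penalty, network)`` pairs ordered by increasing density;
    the first network is empty and the last has at least 90% of all
    possible links.
    """
    if n_points < 2:
        raise ValueError("need at least 2 grid points")
    n = ds.n_genes
    if method in ("lsco", "tlsco"):
        full = _METHODS[method](ds, 0.0)
        mags = np.abs(full.A).ravel()
        top = mags.max()
        # quantile grid over the magnitudes, plus an above-max endpoint
        qs = np.linspace(0.0, 1.0, n_points - 1)
        zetas = np.unique(np.quantile(mags, qs))
        grid = sorted(set(zetas.tolist()) | {top * 1.0000001 + 1e-30}, reverse=True)
        out = [(z, _METHODS[method](ds, z)) for z in grid]
    elif method == "lasso":
        m = ds.n_samples
        corr = np.abs(ds.Y @ (-ds.P.T))
        lam_max = 2.0 * corr.max()  # kills every row
        lams = list(np.geomspace(lam_max, lam_max * 1e-6, n_points - 1)) + [0.0]
        out = [(lam, lasso_infer(ds, lam)) for lam in lams]
    else:
        raise ValueError(f"unknown method {method!r}")
    out.sort(key=lambda t: t[1].n_links())
    if out[0][1].n_links() != 0:
        raise RuntimeError("sweep failed to reach the empty network")
    if out[-1][1].n_links() < 0.9 * n * n:
        # only possible when the data are exactly consistent with a sparse
        # model, so the unpenalized estimate itself is sparse
        warnings.warn("densest sweep network has fewer than 0.9*N^2 links",
                      stacklevel=2)
    return out
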