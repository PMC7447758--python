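"""Core data structures and the linear steady-state perturbation model.

The model relates a genes x experiments matrix of log2 fold changes ``Y``
to a known perturbation design ``P`` through a square interaction matrix
``A`` whose element ``a_ij`` is the regulatory effect of gene ``j`` on
gene ``i``::

    Y = -pinv(A) @ (P - F) + E

where ``F`` is process error (noise in the realized perturbation, e.g.
variable siRNA efficiency) and ``E`` is measurement error in the observed
expression.  Equivalently, in errors-in-variables regression form,
``-(P - F) = A (Y - E)``.  The Moore-Penrose pseudo-inverse is used
throughout because sparse interaction matrices may be rank deficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

#: entries smaller than this in magnitude are treated as structural zeros
ZERO_TOL = 1e-12


@dataclass
class GeneNetwork:
    """A signed, weighted, directed gene regulatory network.

    Parameters
    ----------
    A
        N x N interaction matrix; ``A[i, j]`` is the effect of gene ``j``
        on gene ``i`` (log2 fold-change response per unit perturbation).
        A link is any entry with ``|a_ij| >= ZERO_TOL``; the diagonal
        (self-links) counts.
    genes
        Ordered gene identifiers aligned with the rows/columns of ``A``.
    metadata
        Free-form provenance: inference method, sparsity penalty,
        bootstrap support cutoff, etc.
    """

    A: np.ndarray
    genes: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2 or self.A.shape[0] != self.A.shape[1]:
            raise ValueError(f"interaction matrix must be square, got {self.A.shape}")
        if len(self.genes) != self.A.shape[0]:
            raise ValueError(
                f"{len(self.genes)} gene labels for a {self.A.shape[0]}-gene matrix"
            )
        if not np.all(np.isfinite(self.A)):
            raise ValueError("interaction matrix contains non-finite entries")

    @property
    def n_genes(self) -> int:
        return self.A.shape[0]

    @property
    def support(self) -> np.ndarray:
        """Boolean N x N link indicator (the topology)."""
        return np.abs(self.A) >= ZERO_TOL

    @property
    def signs(self) -> np.ndarray:
        """Integer N x N sign pattern in {-1, 0, +1}."""
        return np.sign(self.A) * self.support

    def n_links(self) -> int:
        return int(self.support.sum())

    def copy(self) -> "GeneNetwork":
        return GeneNetwork(self.A.copy(), list(self.genes), dict(self.metadata))


@dataclass
class PerturbationDataset:
    """Paired fold-change and design matrices from knockdown experiments.

    ``Y[i, m]`` is the log2 fold change of gene ``i`` in experiment ``m``;
    ``P[i, m]`` is negative when gene ``i`` was deliberately knocked down
    in experiment ``m`` and zero otherwise.  ``groups`` maps each sample
    identifier to the set of targeted genes, so replicate columns of the
    same target can be recognised.
    """

    Y: np.ndarray
    P: np.ndarray
    genes: list[str]
    samples: list[str]
    groups: Mapping[str, frozenset] = field(default_factory=dict)
    sigmaE: float | None = None
    sigmaF: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        if self.Y.shape != self.P.shape:
            raise ValueError(f"Y {self.Y.shape} and P {self.P.shape} differ in shape")
        if self.Y.ndim != 2:
            raise ValueError("Y and P must be 2-D (genes x experiments)")
        n, m = self.Y.shape
        if len(self.genes) != n:
            raise ValueError(f"{len(self.genes)} gene labels for {n} rows")
        if len(self.samples) != m:
            raise ValueError(f"{len(self.samples)} sample labels for {m} columns")
        if m and np.any(np.all(self.P == 0, axis=0)):
            bad = [self.samples[j] for j in np.flatnonzero(np.all(self.P == 0, axis=0))]
            raise ValueError(f"experiments without any perturbation: {bad}")
        if not self.groups:
            self.groups = {
                s: frozenset(np.flatnonzero(self.P[:, j] != 0).tolist())
                for j, s in enumerate(self.samples)
            }

    @property
    def n_genes(self) -> int:
        return self.Y.shape[0]

    @property
    def n_samples(self) -> int:
        return self.Y.shape[1]

    def target_columns(self) -> dict[frozenset, list[int]]:
        """Column indices grouped by targeted gene set (replicate groups)."""
        out: dict[frozenset, list[int]] = {}
        for j, s in enumerate(self.samples):
            out.setdefault(frozenset(self.groups[s]), []).append(j)
        return out

    def subset_columns(self, cols: Sequence[int], relabel: bool = False) -> "PerturbationDataset":
        """Dataset restricted to the given experiment columns (in order)."""
        cols = list(cols)
        if relabel:
            samples = [f"{self.samples[j]}_b{k}" for k, j in enumerate(cols)]
        else:
            samples = [self.samples[j] for j in cols]
        groups = {s: frozenset(self.groups[self.samples[j]]) for s, j in zip(samples, cols)}
        return PerturbationDataset(
            self.Y[:, cols], self.P[:, cols], list(self.genes), samples, groups,
            self.sigmaE, self.sigmaF, dict(self.metadata),
        )


def pseudo_inverse(A: np.ndarray) -> np.ndarray:
    """Moore-Penrose pseudo-inverse of a square matrix.

    Coincides with the ordinary inverse for nonsingular ``A`` and
    satisfies the four Penrose conditions in general.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {A.shape}")
    if not np.all(np.isfinite(A)):
        raise ValueError("matrix contains non-finite entries")
    return np.linalg.pinv(A)


def steady_state_response(
    net: GeneNetwork,
    P: np.ndarray,
    F: np.ndarray | None = None,
    E: np.ndarray | None = None,
) -> np.ndarray:
    """Steady-state fold-change response ``Y = -pinv(A) (P - F) + E``."""
    P = np.asarray(P, dtype=float)
    if P.shape[0] != net.n_genes:
        raise ValueError(f"design has {P.shape[0]} rows for a {net.n_genes}-gene network")
    F = np.zeros_like(P) if F is None else np.asarray(F, dtype=float)
    E = np.zeros_like(P) if E is None else np.asarray(E, dtype=float)
    if F.shape != P.shape or E.shape != P.shape:
        raise ValueError("P, F and E must share one shape")
    return -pseudo_inverse(net.A) @ (P - F) + E


def sparsity_stat(net: GeneNetwork) -> dict:
    """Link count, linked-gene count and links per linked gene.

    A gene is *linked* when it is source or target of at least one link
    (self-links included).  The density denominator is the number of
    linked genes, not the matrix dimension, so a 125-link network over
    39 linked genes reports 3.2 links/gene.
    """
    s = net.support
    links = int(s.sum())
    linked = np.flatnonzero(s.any(axis=0) | s.any(axis=1))
    linked_genes = int(linked.size)
    lpg = links / linked_genes if linked_genes else 0.0
    return {"links": links, "linked_genes": linked_genes, "links_per_gene": lpg}
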