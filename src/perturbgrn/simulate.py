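"""Synthetic stable GRNs and simulated knockdown datasets.

The generator emulates a systematic siRNA knockdown screen: every gene is
targeted in turn (optionally in pairs), with replicate columns, and the
observed fold changes follow the linear steady-state model with Gaussian
process error F (perturbation variability) and measurement error E
(expression/readout variability).  Noise scales are set through a single
Frobenius-norm signal-to-noise ratio per error matrix.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .model import GeneNetwork, PerturbationDataset, pseudo_inverse, steady_state_response

#: off-diagonal shrinkage factor applied per iteration until stable
STABILITY_SHRINK = 0.9


def _gene_names(n: int) -> list[str]:
    width = len(str(n - 1)) if n > 1 else 1
    return [f"G{str(i).zfill(width)}" for i in range(n)]


def random_grn(
    n_genes: int,
    links_per_gene: float = 3.0,
    activating_fraction: float = 0.5,
    seed: int = 0,
) -> GeneNetwork:
    """Random sparse stable GRN with self-degradation on the diagonal.

    All diagonal entries are -1; ``round(n_genes * (links_per_gene - 1))``
    off-diagonal links are placed uniformly at random without duplication,
    with magnitudes uniform in [0.5, 1.5] and sign + with probability
    ``activating_fraction``.  Off-diagonal weights are shrunk by a common
    factor until every eigenvalue has negative real part, so the linear
    ODE system is stable.  Typical natural networks carry about 3-5 links
    per gene, hence the default density.
    """
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    n_off = int(round(n_genes * (links_per_gene - 1.0)))
    max_off = n_genes * (n_genes - 1)
    if n_off < 0 or n_off > max_off:
        raise ValueError(
            f"links_per_gene={links_per_gene} infeasible for {n_genes} genes"
        )
    rng = np.random.default_rng(seed)
    A = -np.eye(n_genes)
    if n_off:
        offdiag = [(i, j) for i in range(n_genes) for j in range(n_genes) if i != j]
        pick = rng.choice(len(offdiag), size=n_off, replace=False)
        mags = rng.uniform(0.5, 1.5, size=n_off)
        signs = np.where(rng.random(n_off) < activating_fraction, 1.0, -1.0)
        for k, idx in enumerate(pick):
            i, j = offdiag[idx]
            A[i, j] = signs[k] * mags[k]
    # uniform shrinkage (not rejection) guarantees termination: as the
    # off-diagonal goes to zero the spectrum converges to {-1}
    off_mask = ~np.eye(n_genes, dtype=bool)
    while np.max(np.linalg.eigvals(A).real) >= 0:
        A[off_mask] *= STABILITY_SHRINK
    return GeneNetwork(A, _gene_names(n_genes), {"generator": "random_grn", "seed": seed})


def make_design(
    n_genes: int,
    mode: str = "single",
    replicates: int = 3,
    pairs: Sequence[tuple[int, int]] | None = None,
    strength: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, list[str], dict[str, frozenset]]:
    """Knockdown design matrix plus sample labels and replicate groups.

    ``single`` mode targets every gene in turn with ``replicates``
    replicate columns (entry ``-strength`` at the targeted gene).
    ``pairs`` mode knocks down two genes per column, single replicate;
    if no pair list is given a random perfect matching covers all genes.
    """
    genes = _gene_names(n_genes)
    if mode == "single":
        if replicates < 1:
            raise ValueError("replicates must be >= 1")
        m = n_genes * replicates
        P = np.zeros((n_genes, m))
        samples, groups = [], {}
        for g in range(n_genes):
            for r in range(replicates):
                col = g * replicates + r
                P[g, col] = -strength
                name = f"{genes[g]}_kd_r{r + 1}"
                samples.append(name)
                groups[name] = frozenset({g})
        return P, samples, groups
    if mode == "pairs":
        if pairs is None:
            rng = np.random.default_rng(seed)
            perm = rng.permutation(n_genes)
            pairs = [(int(perm[k]), int(perm[k + 1])) for k in range(0, n_genes - 1, 2)]
        P = np.zeros((n_genes, len(pairs)))
        samples, groups = [], {}
        for c, (a, b) in enumerate(pairs):
            if not (0 <= a < n_genes and 0 <= b < n_genes) or a == b:
                raise ValueError(f"invalid gene pair {(a, b)}")
            P[a, c] = -strength
            P[b, c] = -strength
            name = f"{genes[a]}+{genes[b]}_kd"
            samples.append(name)
            groups[name] = frozenset({a, b})
        return P, samples, groups
    raise ValueError(f"unknown design mode {mode!r}")


def simulate_dataset(
    net: GeneNetwork,
    P: np.ndarray,
    samples: list[str] | None = None,
    groups: dict[str, frozenset] | None = None,
    snr: float = math.inf,
    seed: int = 0,
) -> PerturbationDataset:
    """Simulate fold changes for a design under the steady-state model.

    Process error F and measurement error E are i.i.d. zero-mean Gaussian
    with standard deviations chosen so that the Frobenius-norm ratio
    ``||signal|| / ||noise||`` equals ``snr`` for each matrix: the signal
    for F is the design P, the signal for E is the noiseless response
    ``-pinv(A) P``.  ``snr=inf`` yields the exact noiseless response.
    """
    P = np.asarray(P, dtype=float)
    n, m = P.shape
    if n != net.n_genes:
        raise ValueError("design rows must match network genes")
    if samples is None:
        samples = [f"S{j}" for j in range(m)]
    rng = np.random.default_rng(seed)
    meta = {"snr": snr, "seed": seed}
    Y0 = -pseudo_inverse(net.A) @ P
    if not np.all(np.isfinite(Y0)):
        meta["degenerate"] = True
    if math.isinf(snr):
        ds = PerturbationDataset(Y0, P, list(net.genes), samples, groups or {},
                                 sigmaE=0.0, sigmaF=0.0, metadata=meta)
        return ds
    if snr <= 0:
        raise ValueError("snr must be positive")
    n_el = n * m
    sigmaF = float(np.linalg.norm(P) / (snr * math.sqrt(n_el)))
    sigmaE = float(np.linalg.norm(Y0) / (snr * math.sqrt(n_el)))
    F = rng.normal(0.0, sigmaF, size=(n, m))
    E = rng.normal(0.0, sigmaE, size=(n, m))
    Y = steady_state_response(net, P, F, E)
    return PerturbationDataset(Y, P, list(net.genes), samples, groups or {},
                               sigmaE=sigmaE, sigmaF=sigmaF, metadata=meta)


def simulate_knockdown_study(
    n_genes: int = 40,
    links_per_gene: float = 3.0,
    replicates: int = 3,
    snr: float = 7.0,
    seed: int = 0,
    drop_columns: int = 0,
) -> tuple[GeneNetwork, PerturbationDataset]:
    """Network plus single-knockdown dataset in one call.

    The defaults mirror a 40-gene siRNA screen with 3 biological
    replicates per target; ``drop_columns=5`` emulates discarding outlier
    replicates (40 x 3 - 5 = 115 samples).
    """
    ss = np.random.SeedSequence(seed)
    s_net, s_data, s_drop = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3))
    net = random_grn(n_genes, links_per_gene, seed=s_net)
    P, samples, groups = make_design(n_genes, "single", replicates)
    ds = simulate_dataset(net, P, samples, groups, snr=snr, seed=s_data)
    if drop_columns:
        rng = np.random.default_rng(s_drop)
        # never drop every replicate of a target
        keep = set(range(ds.n_samples))
        by_target = ds.target_columns()
        droppable = [j for cols in by_target.values() if len(cols) > 1 for j in cols]
        drop = rng.choice(droppable, size=drop_columns, replace=False)
        keep -= set(int(j) for j in drop)
        ds = ds.subset_columns(sorted(keep))
    return net, ds


def shuffle_dataset(ds: PerturbationDataset, seed: int = 0) -> PerturbationDataset:
    """Shuffled-data null: permute each gene row of Y across experiments.

    Destroys the gene-to-perturbation correspondence while preserving each
    gene's marginal fold-change distribution exactly; P and the replicate
    grouping are untouched.
    """
    rng = np.random.default_rng(seed)
    Y = ds.Y.copy()
    for i in range(Y.shape[0]):
        Y[i, :] = Y[i, rng.permutation(Y.shape[1])]
    meta = dict(ds.metadata)
    meta["shuffled"] = True
    return PerturbationDataset(Y, ds.P.copy(), list(ds.genes), list(ds.samples),
                               dict(ds.groups), ds.sigmaE, ds.sigmaF, meta)
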