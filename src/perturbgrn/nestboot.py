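"""Nested bootstrap support, FDR estimation and network selection.

An inner bootstrap resamples experiment columns (stratified by
perturbation target) and reinfers the network, yielding per-link support
fractions.  Outer ("nested") repetitions of the whole inner bootstrap
measure how reproducible those supports are.  Running the identical
machinery on row-shuffled data gives a null support distribution from
which the false discovery rate at each support cutoff is estimated; the
selected network keeps the links whose aggregate support clears the
smallest cutoff with estimated FDR at or below the nominal level, with
weights refit by constrained least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .inference import cls_refit, infer
from .model import GeneNetwork, PerturbationDataset
from .simulate import shuffle_dataset

#: default support grid: 0 to 1 in steps of 0.025
DEFAULT_GRID = np.round(np.arange(0.0, 1.0 + 1e-9, 0.025), 3)


@dataclass
class SupportMatrix:
    """Per-link bootstrap support fractions with majority signs."""

    support: np.ndarray  # N x N in [0, 1]
    sign: np.ndarray  # N x N in {-1, 0, +1}
    genes: list[str]
    source: str = "measured"  # or "shuffled"
    run_id: int = 0
    n_boot: int = 0

    def __post_init__(self) -> None:
        if np.any((self.support < 0) | (self.support > 1)):
            raise ValueError("support values must lie in [0, 1]")
        if np.any((self.sign == 0) != (self.support == 0)):
            raise ValueError("sign must be 0 exactly where support is 0")

    def link_set(self, cutoff: float) -> set[tuple[int, int]]:
        return set(zip(*np.nonzero(self.support >= cutoff)))


@dataclass
class FDRCurve:
    """Estimated FDR as a function of the bootstrap support cutoff."""

    grid: np.ndarray
    fdr: np.ndarray
    alpha: float
    cutoff: float | None = field(default=None)

    def __post_init__(self) -> None:
        ok = np.flatnonzero(self.fdr <= self.alpha)
        self.cutoff = float(self.grid[ok[0]]) if ok.size else None


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def bootstrap_networks(
    ds: PerturbationDataset,
    method: str,
    penalty: float | None,
    n_boot: int,
    seed: int = 0,
    density: float | None = None,
) -> list[GeneNetwork]:
    """Networks inferred from stratified column resamples.

    Columns are resampled with replacement within each perturbation-target
    group, so every target keeps at least one experiment in every
    resample and (Y, P) columns stay paired.

    With ``density`` set (LSCO/TLSCO only) the magnitude cutoff is chosen
    per resample as the quantile of the full estimate that keeps that
    fraction of entries.  Density matching keeps measured and shuffled
    bootstrap networks at the same native sparsity, which a fixed cutoff
    cannot (coefficient scales differ between the two), and is required
    for the shuffled-support null to be comparable.
    """
    if n_boot < 2:
        raise ValueError("need at least 2 bootstrap resamples")
    if density is None and penalty is None:
        raise ValueError("give either a penalty or a density")
    if density is not None and method not in ("lsco", "tlsco"):
        raise ValueError("density matching is only defined for cutoff methods")
    rng = np.random.default_rng(seed)
    groups = ds.target_columns()
    nets = []
    for _ in range(n_boot):
        cols: list[int] = []
        for g_cols in groups.values():
            cols.extend(rng.choice(g_cols, size=len(g_cols), replace=True).tolist())
        resample = ds.subset_columns(sorted(cols), relabel=True)
        if density is not None:
            full = infer(resample, method, 0.0)
            zeta = float(np.quantile(np.abs(full.A), 1.0 - density))
            nets.append(infer(resample, method, zeta))
        else:
            nets.append(infer(resample, method, penalty))
    return nets


def link_support(nets: list[GeneNetwork]) -> SupportMatrix:
    """Sign-aware support: fraction of networks carrying each link with
    its majority sign (ties broken toward +)."""
    if len(nets) < 2:
        raise ValueError("need at least 2 networks")
    genes = nets[0].genes
    for net in nets[1:]:
        if net.genes != genes:
            raise ValueError("networks must share gene order")
    pos = np.sum([net.signs > 0 for net in nets], axis=0)
    neg = np.sum([net.signs < 0 for net in nets], axis=0)
    sign = np.where(pos >= neg, 1, -1)
    sign[(pos + neg) == 0] = 0
    count = np.where(sign > 0, pos, neg)
    support = count / len(nets)
    return SupportMatrix(support, sign.astype(int), list(genes), n_boot=len(nets))


def nested_support(
    ds: PerturbationDataset,
    method: str,
    penalty: float | None,
    n_nested: int = 8,
    n_boot: int = 25,
    seed: int = 0,
    source: str = "measured",
    density: float | None = None,
) -> tuple[list[SupportMatrix], SupportMatrix]:
    """Outer repetitions of the inner bootstrap plus their aggregate.

    With ``source="shuffled"`` each nested run first draws a fresh
    row-shuffled copy of the data (the NestBoot null).  The aggregate is
    the element-wise mean of run supports; aggregate signs follow the
    majority across runs (ties toward +).
    """
    if n_nested < 2:
        raise ValueError("need at least 2 nested runs")
    seeds = _spawn_seeds(seed, 2 * n_nested)
    runs = []
    for r in range(n_nested):
        data = ds if source == "measured" else shuffle_dataset(ds, seeds[n_nested + r])
        nets = bootstrap_networks(data, method, penalty, n_boot, seeds[r],
                                  density=density)
        sm = link_support(nets)
        sm.source = source
        sm.run_id = r
        runs.append(sm)
    mean_support = np.mean([r.support for r in runs], axis=0)
    pos = np.sum([(r.sign > 0) & (r.support > 0) for r in runs], axis=0)
    neg = np.sum([(r.sign < 0) & (r.support > 0) for r in runs], axis=0)
    sign = np.where(pos >= neg, 1, -1)
    sign[(pos + neg) == 0] = 0
    sign[mean_support == 0] = 0
    agg = SupportMatrix(mean_support, sign.astype(int), list(runs[0].genes),
                        source=source, run_id=-1, n_boot=n_boot)
    return runs, agg


def fdr_curve(
    measured: SupportMatrix,
    shuffled_runs: list[SupportMatrix],
    grid: np.ndarray | None = None,
    alpha: float = 0.05,
) -> FDRCurve:
    """FDR(s) = mean shuffled link count at support >= s over the measured
    link count, clipped to [0, 1]; 1 by convention when nothing measured
    clears the cutoff."""
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0) or grid.min() < 0 or grid.max() > 1:
        raise ValueError("grid must be ascending within [0, 1]")
    fdr = np.empty_like(grid)
    for k, s in enumerate(grid):
        n_meas = int(np.sum(measured.support >= s))
        if n_meas == 0:
            fdr[k] = 1.0
        else:
            n_null = float(np.mean([np.sum(r.support >= s) for r in shuffled_runs]))
            fdr[k] = min(1.0, n_null / n_meas)
    return FDRCurve(grid, fdr, alpha)


def select_network(
    ds: PerturbationDataset,
    method: str,
    penalty: float,
    fdr: FDRCurve,
    aggregate: SupportMatrix,
) -> GeneNetwork | None:
    """Support-thresholded topology with CLS-refit weights.

    Returns None when no cutoff reaches the nominal FDR or no link
    clears the selected cutoff.
    """
    if fdr.cutoff is None:
        return None
    keep = aggregate.support >= fdr.cutoff
    if not keep.any():
        return None
    topo = GeneNetwork(np.where(keep, aggregate.sign, 0).astype(float),
                       list(aggregate.genes))
    net = cls_refit(topo, ds)
    # CLS may shrink a constrained weight to zero; keep the selected
    # topology explicit in the metadata
    net.metadata.update({
        "method": method,
        "penalty": penalty,
        "support_cutoff": fdr.cutoff,
        "alpha": fdr.alpha,
        "name": f"{method}_support{100 * fdr.cutoff:g}_penalty{penalty:g}",
        "selected_links": int(keep.sum()),
    })
    return net


def nestboot_select(
    ds: PerturbationDataset,
    method: str = "lsco",
    penalty: float | None = None,
    n_nested: int = 8,
    n_boot: int = 25,
    alpha: float = 0.05,
    seed: int = 0,
    grid: np.ndarray | None = None,
    density: float | None = None,
    native_links_per_gene: float = 4.5,
) -> dict:
    """Full nested-bootstrap procedure on one dataset.

    Runs measured and shuffled nested supports, estimates the FDR curve
    and selects the network.  When neither ``penalty`` nor ``density``
    is given, LSCO/TLSCO run density-matched at a native sparsity of
    ``native_links_per_gene`` links per gene (within the 3-5 links/gene
    range typical of natural networks, with headroom for pruning);
    support and FDR do the final pruning.
    """
    if penalty is None and density is None:
        if method in ("lsco", "tlsco"):
            density = min(1.0, native_links_per_gene / ds.n_genes)
        else:
            raise ValueError("penalty must be given for lasso")
    s_meas, s_shuf = _spawn_seeds(seed, 2)
    runs_m, agg_m = nested_support(ds, method, penalty, n_nested, n_boot,
                                   seed=s_meas, source="measured", density=density)
    runs_s, agg_s = nested_support(ds, method, penalty, n_nested, n_boot,
                                   seed=s_shuf, source="shuffled", density=density)
    curve = fdr_curve(agg_m, runs_s, grid=grid, alpha=alpha)
    net = select_network(ds, method, penalty if penalty is not None else 0.0,
                         curve, agg_m)
    return {
        "penalty": penalty,
        "density": density,
        "measured_runs": runs_m,
        "measured_aggregate": agg_m,
        "shuffled_runs": runs_s,
        "shuffled_aggregate": agg_s,
        "fdr_curve": curve,
        "network": net,
    }


def overlap_curve(
    runs: list[SupportMatrix], grid: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Mean pairwise Jaccard index of thresholded link sets per cutoff.

    Returns (grid, jaccard); entries are NaN where every run's link set
    is empty.
    """
    if len(runs) < 2:
        raise ValueError("need at least 2 runs")
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    out = np.full(grid.shape, np.nan)
    for k, s in enumerate(grid):
        sets = [r.link_set(s) for r in runs]
        if all(len(x) == 0 for x in sets):
            continue
        vals = []
        for a in range(len(sets)):
            for b in range(a + 1, len(sets)):
                union = sets[a] | sets[b]
                vals.append(len(sets[a] & sets[b]) / len(union) if union else np.nan)
        vals = [v for v in vals if not np.isnan(v)]
        out[k] = float(np.mean(vals)) if vals else np.nan
    return grid, out
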