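"""Gold-standard-free network assessment by balanced-error cross-validation.

The inferred interaction matrix A is scored by leaving out, in turn, all
experiments that target one gene, balancing the measurement error E and
process error F on the remaining experiments, and predicting the left-out
gene's intended perturbation and observed response.  The errors are
balanced by solving, per fold, the convex minimax program

    minimize  max( ||E||_F^2 / ||Y'||_F^2 ,  ||F||_F^2 / ||P'||_F^2 )
    subject to  -(P' - F) = A (Y' - E)

with F eliminated through the constraint (F = P' + A(Y' - E)), so the
error is not simply pushed from the measurement side to the process side
or vice versa.  The weighted residual sum of squares (wRSS) of the
assembled predictions, compared against shuffled-topology and
shuffled-data null distributions, measures how predictive the network is
without any gold standard.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .inference import cls_refit
from .model import GeneNetwork, PerturbationDataset, pseudo_inverse
from .simulate import shuffle_dataset

_EPS_VAR = 1e-8  # variance floor for wRSS weights (guards the noiseless case)


@dataclass
class FitResult:
    """Cross-validated fit of one network to one dataset."""

    wRSS: float
    R2: float
    E_rel: float  # mean relative measurement error across folds
    F_rel: float  # mean relative process error across folds
    Y_pred: np.ndarray  # N x M assembled predicted responses (NaN if never predicted)
    P_pred: np.ndarray  # N x M assembled predicted perturbations
    truncated: bool
    rank: int
    folds: dict = field(default_factory=dict)  # gene index -> per-fold diagnostics


@dataclass
class NullDistribution:
    """wRSS null samples plus comparison statistics for an observed fit."""

    kind: str  # "shuffled_topology" or "shuffled_data"
    wrss_samples: list[float]
    observed: float
    n_failed: int = 0

    def __post_init__(self) -> None:
        if not self.wrss_samples:
            raise ValueError("empty null distribution")
        arr = np.asarray(self.wrss_samples)
        self.median = float(np.median(arr))
        q75, q25 = np.percentile(arr, [75, 25])
        self.iqr = float(q75 - q25)
        cmp = compare_to_null(self.observed, self)
        self.ratio_to_median = cmp["ratio_to_median"]
        self.empirical_p = cmp["empirical_p"]


def compare_to_null(observed_wrss: float, null) -> dict:
    """Ratio of observed wRSS to the null median and an add-one empirical p.

    ``empirical_p = (1 + #{samples <= observed}) / (n + 1)`` — small when
    the observed error beats almost every null sample.
    """
    samples = np.asarray(null.wrss_samples if hasattr(null, "wrss_samples") else null,
                         dtype=float)
    if samples.size == 0:
        raise ValueError("empty null distribution")
    med = float(np.median(samples))
    ratio = float(observed_wrss / med) if med > 0 else float("inf")
    p = (1 + int(np.sum(samples <= observed_wrss))) / (samples.size + 1)
    return {"ratio_to_median": ratio, "empirical_p": p}


# ---------------------------------------------------------------------------
# balanced errors


class _BalanceSolver:
    """Minimax error balancing with the SVD of A precomputed once.

    The scalarized problem  min_E  w*||E||^2/y2 + (1-w)*||B - A E||^2/p2
    (B = P' + A Y') is a per-column ridge system solved in the SVD basis;
    the minimax optimum is the weight w* where the two relative errors
    cross, found by bisection (the difference is monotone in w).  When
    even the minimum-norm minimizer of the process term leaves the
    measurement term smaller, no crossing exists and that minimizer is
    already minimax-optimal.
    """

    def __init__(self, A: np.ndarray):
        self.A = A
        self.U, self.s, self.Vt = np.linalg.svd(A)

    def _solve_w(self, w: float, B: np.ndarray, y2: float, p2: float) -> np.ndarray:
        c1 = w / y2
        c2 = (1.0 - w) / p2
        d = c2 * self.s / (c1 + c2 * self.s**2)
        return self.Vt.T @ (d[:, None] * (self.U.T @ B))

    def balance(self, Yp: np.ndarray, Pp: np.ndarray,
                tol: float = 1e-14, max_iter: int = 200):
        y2 = float(np.sum(Yp**2))
        p2 = float(np.sum(Pp**2))
        if y2 == 0 or p2 == 0:
            raise ValueError("relative error undefined for all-zero Y' or P'")
        B = Pp + self.A @ Yp
        if not np.any(np.abs(B) > 1e-300):
            Z = np.zeros_like(Yp)
            return Z, np.zeros_like(Pp), 0.0, 0.0

        def errs(E):
            f1 = float(np.sum(E**2)) / y2
            F = B - self.A @ E
            f2 = float(np.sum(F**2)) / p2
            return f1, f2, F

        lo, hi = 1e-12, 1.0 - 1e-12
        E = self._solve_w(lo, B, y2, p2)
        f1, f2, F = errs(E)
        if f1 <= f2:  # no crossing: minimum of the process term is minimax
            return E, F, float(np.sqrt(f1)), float(np.sqrt(f2))
        for _ in range(max_iter):
            w = 0.5 * (lo + hi)
            E = self._solve_w(w, B, y2, p2)
            f1, f2, F = errs(E)
            if abs(f1 - f2) <= tol * max(f1, f2, 1e-300):
                break
            if f1 > f2:
                lo = w
            else:
                hi = w
        return E, F, float(np.sqrt(f1)), float(np.sqrt(f2))


def balance_errors(
    net: GeneNetwork, Yp: np.ndarray, Pp: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Balanced measurement/process error estimates for one fold.

    Returns ``(E_hat, F_hat, E_rel, F_rel)`` where
    ``F_hat = P' + A (Y' - E_hat)`` and the relative errors
    ``E_rel = ||E_hat||_F/||Y'||_F``, ``F_rel = ||F_hat||_F/||P'||_F``
    are equal (to solver tolerance) whenever both are nonzero.
    """
    Yp = np.asarray(Yp, dtype=float)
    Pp = np.asarray(Pp, dtype=float)
    if Yp.shape != Pp.shape or Yp.shape[0] != net.n_genes:
        raise ValueError("Y' and P' must be N x M' with N matching the network")
    return _BalanceSolver(net.A).balance(Yp, Pp)


# ---------------------------------------------------------------------------
# prediction and wRSS


def predict_leftout(
    net: GeneNetwork, ds: PerturbationDataset, g: int
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Predict gene ``g``'s experiments from the network alone.

    For each experiment column targeting ``g``, the predicted response is
    ``y_hat = -pinv(A) p`` (from the intended perturbation) and the
    predicted perturbation is ``p_hat = -A y`` (from the observed
    response).  Returns the two N x (n experiments) blocks and the column
    indices they correspond to.
    """
    cols = [j for j, s in enumerate(ds.samples) if g in ds.groups[s]]
    if not cols:
        raise ValueError(f"gene index {g} has no experiments")
    Apinv = pseudo_inverse(net.A)
    Y_pred = -Apinv @ ds.P[:, cols]
    P_pred = -net.A @ ds.Y[:, cols]
    return Y_pred, P_pred, cols


def svd_truncate(net: GeneNetwork, ds: PerturbationDataset) -> GeneNetwork:
    """Drop small singular values of A until predictions stay bounded.

    Keeps the largest number of leading singular values such that every
    entry of ``-pinv(A_trunc) P`` lies within the observed expression
    range widened by 10% of its span.  Small singular values of an
    ill-conditioned network blow up the pseudo-inverse; removing them
    keeps predicted responses on the scale of the measured data.  If no
    truncation satisfies the bound, rank 1 is retained and flagged.
    """
    U, s, Vt = np.linalg.svd(net.A)
    n = net.n_genes
    lo, hi = float(ds.Y.min()), float(ds.Y.max())
    delta = 0.1 * (hi - lo)
    chosen, ok = 1, False
    for k in range(n, 0, -1):
        if s[k - 1] <= 0:
            continue
        pred = -(Vt[:k].T @ ((U[:, :k].T @ ds.P) / s[:k, None]))
        if pred.min() >= lo - delta and pred.max() <= hi + delta:
            chosen, ok = k, True
            break
    A_t = (U[:, :chosen] * s[:chosen]) @ Vt[:chosen]
    meta = dict(net.metadata)
    meta.update({"truncated_rank": chosen, "truncation_bounded": ok})
    return GeneNetwork(A_t, list(net.genes), meta)


def bfecv_wrss(
    net: GeneNetwork,
    ds: PerturbationDataset,
    truncate: bool = True,
    weights: tuple[float, float] | None = None,
) -> FitResult:
    """Balanced-error leave-one-gene-out goodness of fit.

    For every targeted gene ``g``: balance E and F on the data with
    ``g``'s experiments removed, then predict those experiments; assemble
    the per-gene predictions into full matrices.  The wRSS weighs the
    squared response and perturbation residuals by the inverse balanced
    error variances (floored at 1e-8).  When comparing several networks
    on one dataset the weights must be a common scale — pass the
    ``(w_E, w_F)`` of the reference fit as ``weights`` (a poor topology
    would otherwise shrink its own weights through its larger balanced
    errors).  R^2 is computed over response entries, always from the
    SVD-truncated network; wRSS uses the truncated network only when
    ``truncate`` is set.
    """
    A_trunc_net = svd_truncate(net, ds)
    work_net = A_trunc_net if truncate else net
    solver = _BalanceSolver(work_net.A)
    Apinv_w = pseudo_inverse(work_net.A)
    Apinv_r = pseudo_inverse(A_trunc_net.A)

    n, m = ds.Y.shape
    targeted = sorted({g for s in ds.samples for g in ds.groups[s]})
    Y_pred = np.full((n, m), np.nan)
    P_pred = np.full((n, m), np.nan)
    Y_pred_r2 = np.full((n, m), np.nan)
    counts = np.zeros(m)
    folds: dict[int, dict] = {}
    e_vars, f_vars, e_rels, f_rels = [], [], [], []
    resid_y = resid_p = 0.0

    for g in targeted:
        cols = [j for j, s in enumerate(ds.samples) if g in ds.groups[s]]
        rest = [j for j in range(m) if j not in cols]
        if not rest:
            continue
        Yp, Pp = ds.Y[:, rest], ds.P[:, rest]
        E_hat, F_hat, e_rel, f_rel = solver.balance(Yp, Pp)
        e_vars.append(float(np.mean(E_hat**2)))
        f_vars.append(float(np.mean(F_hat**2)))
        e_rels.append(e_rel)
        f_rels.append(f_rel)
        yhat = -Apinv_w @ ds.P[:, cols]
        phat = -work_net.A @ ds.Y[:, cols]
        yhat_r2 = yhat if truncate else -Apinv_r @ ds.P[:, cols]
        resid_y += float(np.sum((yhat - ds.Y[:, cols]) ** 2))
        resid_p += float(np.sum((phat - ds.P[:, cols]) ** 2))
        for k, j in enumerate(cols):
            w_old = counts[j]
            counts[j] += 1
            for M_acc, blk in ((Y_pred, yhat), (P_pred, phat), (Y_pred_r2, yhat_r2)):
                if w_old == 0:
                    M_acc[:, j] = blk[:, k]
                else:  # pairwise designs predict a column once per target
                    M_acc[:, j] = (M_acc[:, j] * w_old + blk[:, k]) / (w_old + 1)
        folds[g] = {"E_rel": e_rel, "F_rel": f_rel, "cols": cols,
                    "E_hat": E_hat, "F_hat": F_hat}

    if not folds:
        raise ValueError("no targeted gene can be left out")
    if weights is None:
        w_e = 1.0 / max(float(np.mean(e_vars)), _EPS_VAR)
        w_f = 1.0 / max(float(np.mean(f_vars)), _EPS_VAR)
    else:
        w_e, w_f = weights
    wrss = w_e * resid_y + w_f * resid_p

    seen = counts > 0
    y_obs = ds.Y[:, seen]
    y_fit = Y_pred_r2[:, seen]
    ss_res = float(np.sum((y_fit - y_obs) ** 2))
    ss_tot = float(np.sum((y_obs - y_obs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")

    result = FitResult(
        wRSS=wrss, R2=r2,
        E_rel=float(np.mean(e_rels)), F_rel=float(np.mean(f_rels)),
        Y_pred=Y_pred, P_pred=P_pred,
        truncated=truncate or A_trunc_net.metadata["truncated_rank"] < n,
        rank=A_trunc_net.metadata["truncated_rank"],
        folds=folds,
    )
    result.weights = (w_e, w_f)
    return result


# ---------------------------------------------------------------------------
# null models


def shuffle_topology(net: GeneNetwork, seed: int = 0,
                     hub_weighting: bool = True) -> GeneNetwork:
    """In-degree-preserving link shuffle with hub preservation.

    Self-links stay in place.  For each target gene (row) the same number
    of incoming off-diagonal links is redrawn; candidate sources are
    sampled without replacement with probability proportional to their
    original out-degree + 1 (hubs keep attracting links), or uniformly
    when ``hub_weighting`` is off.  Each moved link keeps its original
    sign and weight, so per-row in-degrees and the overall weight
    multiset are preserved exactly.
    """
    rng = np.random.default_rng(seed)
    n = net.n_genes
    A = net.A
    off = net.support & ~np.eye(n, dtype=bool)
    outdeg = off.sum(axis=0).astype(float)
    new = np.diag(np.diag(A)).copy()
    for i in range(n):
        j_old = np.flatnonzero(off[i])
        k = j_old.size
        if k == 0:
            continue
        cand = np.array([j for j in range(n) if j != i])
        w = outdeg[cand] + 1.0 if hub_weighting else np.ones(cand.size)
        j_new = rng.choice(cand, size=k, replace=False, p=w / w.sum())
        weights = A[i, j_old].copy()
        rng.shuffle(weights)
        new[i, j_new] = weights
    meta = dict(net.metadata)
    meta["shuffled_topology"] = True
    return GeneNetwork(new, list(net.genes), meta)


def null_distribution(
    net: GeneNetwork,
    ds: PerturbationDataset,
    kind: str = "shuffled_topology",
    n: int = 100,
    seed: int = 0,
    truncate: bool = True,
    hub_weighting: bool = True,
) -> NullDistribution:
    """wRSS null distribution for an inferred network.

    ``shuffled_topology``: each replicate shuffles the network's links
    (in-degree preserving), refits weights by CLS to the original data
    and scores with the balanced-error cross-validation.
    ``shuffled_data``: each replicate row-shuffles the data, refits the
    inferred topology to it and scores against the shuffled data.
    The observed wRSS is computed identically on the inferred network
    (also CLS-refit), and its wRSS weights are reused for every null
    replicate so all fits are measured on one common error scale.
    """
    if n < 10:
        raise ValueError("need at least 10 null replicates")
    if kind not in ("shuffled_topology", "shuffled_data"):
        raise ValueError(f"unknown null kind {kind!r}")
    obs_fit = bfecv_wrss(cls_refit(net, ds), ds, truncate=truncate)
    observed = obs_fit.wRSS
    w = obs_fit.weights
    ss = np.random.SeedSequence(seed)
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]
    samples: list[float] = []
    failed = 0
    for s in seeds:
        try:
            if kind == "shuffled_topology":
                topo = shuffle_topology(net, s, hub_weighting=hub_weighting)
                fit = bfecv_wrss(cls_refit(topo, ds), ds, truncate=truncate, weights=w)
            else:
                ds_s = shuffle_dataset(ds, s)
                fit = bfecv_wrss(cls_refit(net, ds_s), ds_s, truncate=truncate, weights=w)
            samples.append(fit.wRSS)
        except (ValueError, np.linalg.LinAlgError):
            failed += 1
    return NullDistribution(kind=kind, wrss_samples=samples,
                            observed=observed, n_failed=failed)


# ---------------------------------------------------------------------------
# auxiliary validation statistics


def knockdown_qc(
    ds: PerturbationDataset, p_thresh: float = 0.1, lfc_thresh: float = -2.0
) -> pd.DataFrame:
    """Per-target knockdown significance table.

    For each targeted gene: the mean log2 fold change of the target
    across its replicate experiments and a one-sided one-sample t-test
    against 0 (alternative: downregulated).  A target is flagged
    significant when ``p < p_thresh`` and ``mean < lfc_thresh``.
    """
    rows = []
    for targets, cols in sorted(ds.target_columns().items(),
                                key=lambda t: sorted(t[0])):
        for g in sorted(targets):
            vals = ds.Y[g, cols]
            mean = float(vals.mean())
            if len(vals) >= 2 and np.ptp(vals) > 0:
                t, p = stats.ttest_1samp(vals, 0.0, alternative="less")
                t, p = float(t), float(p)
            elif len(vals) >= 2:
                t, p = (-np.inf, 0.0) if mean < 0 else (np.inf, 1.0)
            else:
                t, p = float("nan"), float("nan")
            rows.append({
                "gene": ds.genes[g], "n_replicates": len(cols),
                "mean_lfc": mean, "t_stat": t, "p_value": p,
                "significant": bool(p < p_thresh and mean < lfc_thresh)
                if not np.isnan(p) else False,
            })
    return pd.DataFrame(rows).drop_duplicates(subset="gene").reset_index(drop=True)


def network_overlap_test(
    net: GeneNetwork,
    reference: set,
    universe_size: int,
    directed: bool = True,
) -> dict:
    """Hypergeometric overlap between the network and a reference link set.

    Links are (source, target) gene-label pairs; with ``directed=False``
    both sets collapse to unordered pairs (self-links stay as pairs)
    before intersecting.  p is the upper-tail probability of at least the
    observed overlap when ``|net|`` links are drawn from a universe of
    ``universe_size`` possible links containing the reference.
    """
    if universe_size <= 0:
        raise ValueError("universe size must be positive")
    links = {(net.genes[j], net.genes[i]) for i, j in zip(*np.nonzero(net.support))}
    ref = {tuple(t) for t in reference}
    if not directed:
        links = {tuple(sorted(t)) for t in links}
        ref = {tuple(sorted(t)) for t in ref}
    if universe_size < max(len(links), len(ref)):
        raise ValueError("universe smaller than one of the link sets")
    k = len(links & ref)
    p = float(stats.hypergeom.sf(k - 1, universe_size, len(ref), len(links)))
    return {"overlap": k, "n_network": len(links), "n_reference": len(ref), "p": p}
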