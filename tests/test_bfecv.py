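import numpy as np
import pytest
from scipy import stats
from scipy.optimize import minimize

from perturbgrn import (
    GeneNetwork,
    balance_errors,
    bfecv_wrss,
    cls_refit,
    compare_to_null,
    knockdown_qc,
    make_design,
    network_overlap_test,
    null_distribution,
    predict_leftout,
    random_grn,
    shuffle_topology,
    simulate_dataset,
    simulate_knockdown_study,
    svd_truncate,
)
from perturbgrn.model import PerturbationDataset


def _slsqp_minimax(A, Yp, Pp):
    """Independent oracle: epigraph form of the error-balancing program
    solved by a generic NLP solver (variables t and vec(E))."""
    n, m = Yp.shape
    y2, p2 = np.sum(Yp**2), np.sum(Pp**2)
    B = Pp + A @ Yp

    def unpack(x):
        return x[0], x[1:].reshape(n, m)

    def obj(x):
        return x[0]

    cons = [
        {"type": "ineq",
         "fun": lambda x: x[0] - np.sum(unpack(x)[1] ** 2) / y2},
        {"type": "ineq",
         "fun": lambda x: x[0] - np.sum((B - A @ unpack(x)[1]) ** 2) / p2},
    ]
    x0 = np.zeros(1 + n * m)
    x0[0] = np.sum(B**2) / p2
    res = minimize(obj, x0, constraints=cons, method="SLSQP",
                   options={"maxiter": 500, "ftol": 1e-14})
    return res.x[0]


class TestBalanceErrors:
    def test_noiseless_data_zero_errors(self, study15_clean):
        net, ds = study15_clean
        E, F, e_rel, f_rel = balance_errors(net, ds.Y, ds.P)
        assert e_rel == pytest.approx(0.0, abs=1e-10)
        assert f_rel == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(E, 0.0, atol=1e-10)
        np.testing.assert_allclose(F, 0.0, atol=1e-10)

    def test_scaling_homogeneity(self, study15):
        net, ds = study15
        E1, F1, e1, f1 = balance_errors(net, ds.Y, ds.P)
        E2, F2, e2, f2 = balance_errors(net, 3.0 * ds.Y, 3.0 * ds.P)
        np.testing.assert_allclose(E2, 3.0 * E1, atol=1e-8)
        np.testing.assert_allclose(F2, 3.0 * F1, atol=1e-8)
        assert e2 == pytest.approx(e1, abs=1e-9)
        assert f2 == pytest.approx(f1, abs=1e-9)

    def test_matches_generic_convex_solver(self):
        rng = np.random.default_rng(0)
        for k in range(20):
            net = random_grn(5, 2.5, seed=300 + k)
            P, s, g = make_design(5, "single", replicates=2)
            ds = simulate_dataset(net, P, s, g, snr=3.0, seed=400 + k)
            E, F, e_rel, f_rel = balance_errors(net, ds.Y, ds.P)
            t_ours = max(e_rel**2, f_rel**2)
            t_oracle = _slsqp_minimax(net.A, ds.Y, ds.P)
            assert t_ours <= t_oracle + 1e-6
            assert abs(t_ours - t_oracle) <= 1e-6

    def test_balance_property(self):
        """At the minimax optimum with both error terms nonzero the
        relative errors are equal (active-constraint equalization)."""
        rng = np.random.default_rng(1)
        for k in range(20):
            net = random_grn(6, 3.0, seed=500 + k)
            P, s, g = make_design(6, "single", replicates=3)
            ds = simulate_dataset(net, P, s, g, snr=4.0, seed=600 + k)
            _, _, e_rel, f_rel = balance_errors(net, ds.Y, ds.P)
            if e_rel > 0 and f_rel > 0:
                assert abs(e_rel - f_rel) <= 1e-6

    def test_constraint_residual_small(self, study15):
        net, ds = study15
        E, F, *_ = balance_errors(net, ds.Y, ds.P)
        resid = np.linalg.norm((ds.P - F) + net.A @ (ds.Y - E))
        assert resid <= 1e-6 * np.linalg.norm(ds.P)

    def test_all_zero_inputs_rejected(self, chain_net):
        with pytest.raises(ValueError):
            balance_errors(chain_net, np.zeros((2, 2)), -np.eye(2))


class TestPredictLeftout:
    def test_pure_decay_prediction(self):
        net = GeneNetwork(-np.eye(3), list("abc"))
        P, s, g = make_design(3, "single", replicates=1)
        ds = simulate_dataset(net, P, s, g)
        Y_pred, P_pred, cols = predict_leftout(net, ds, 1)
        np.testing.assert_allclose(Y_pred[:, 0], [0, -1, 0], atol=1e-12)

    def test_noiseless_consistency(self, study15_clean):
        net, ds = study15_clean
        for gene in (0, 7):
            Y_pred, P_pred, cols = predict_leftout(net, ds, gene)
            np.testing.assert_allclose(Y_pred, ds.Y[:, cols], atol=1e-8)
            np.testing.assert_allclose(P_pred, ds.P[:, cols], atol=1e-8)

    def test_perturbation_from_response(self, chain_net, chain_dataset):
        _, P_pred, cols = predict_leftout(chain_net, chain_dataset, 0)
        # p_hat = -A y with y = (-1, -1): (-1, 0) for the chain matrix
        y = np.array([-1.0, -1.0])
        np.testing.assert_allclose(-chain_net.A @ y, [-1.0, 0.0], atol=1e-12)


class TestBfecvWrss:
    def test_true_network_noiseless_perfect(self, study15_clean):
        net, ds = study15_clean
        fit = bfecv_wrss(net, ds)
        assert fit.wRSS == pytest.approx(0.0, abs=1e-8)
        assert fit.R2 == pytest.approx(1.0, abs=1e-10)

    def test_disconnected_network_fits_worse(self):
        net, ds = simulate_knockdown_study(10, 3.0, 3, snr=10.0, seed=11)
        fit_true = bfecv_wrss(cls_refit(net, ds), ds)
        diag = GeneNetwork(-np.eye(10), list(net.genes))
        fit_diag = bfecv_wrss(cls_refit(diag, ds), ds,
                              weights=fit_true.weights)
        assert fit_diag.wRSS > fit_true.wRSS

    def test_wrss_decreases_with_snr(self):
        means = []
        for snr in (2.0, 5.0, 10.0):
            vals = []
            for seed in range(10):
                net, ds = simulate_knockdown_study(8, 2.5, 3, snr=snr,
                                                   seed=700 + seed)
                ref = bfecv_wrss(cls_refit(net, ds), ds)
                # raw residuals on a fixed weight scale across snr levels
                vals.append(bfecv_wrss(cls_refit(net, ds), ds,
                                       weights=(1.0, 1.0)).wRSS)
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]


class TestSvdTruncate:
    def test_well_conditioned_unchanged(self, study15):
        net, ds = study15
        out = svd_truncate(net, ds)
        np.testing.assert_allclose(out.A, net.A, atol=1e-10)
        assert out.metadata["truncated_rank"] == net.n_genes

    def test_near_singular_value_removed(self):
        # 3x3 with controlled spectrum: one singular value at 1e-9 makes
        # pinv predictions explode; truncation must drop it
        rng = np.random.default_rng(5)
        U, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        V, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        A = (U * np.array([2.0, 1.0, 1e-9])) @ V.T
        net = GeneNetwork(A, list("abc"))
        P = -np.eye(3)
        Y = np.clip(-np.linalg.pinv((U * np.array([2.0, 1.0, 1.0])) @ V.T) @ P,
                    -2, 2)
        ds = PerturbationDataset(Y, P, list("abc"), ["s1", "s2", "s3"])
        out = svd_truncate(net, ds)
        assert out.metadata["truncated_rank"] < 3
        pred = -np.linalg.pinv(out.A) @ P
        delta = 0.1 * (Y.max() - Y.min())
        assert pred.min() >= Y.min() - delta and pred.max() <= Y.max() + delta


class TestShuffleTopology:
    @pytest.mark.parametrize("hub_weighting", [True, False])
    def test_structure_preserved(self, study15, hub_weighting):
        net, _ = study15
        shuf = shuffle_topology(net, seed=3, hub_weighting=hub_weighting)
        np.testing.assert_array_equal(np.diag(shuf.A), np.diag(net.A))
        off_old = net.support & ~np.eye(15, dtype=bool)
        off_new = shuf.support & ~np.eye(15, dtype=bool)
        np.testing.assert_array_equal(off_old.sum(axis=1), off_new.sum(axis=1))
        np.testing.assert_allclose(np.sort(shuf.A[off_new]),
                                   np.sort(net.A[off_old]))

    def test_reproducible(self, study15):
        net, _ = study15
        a = shuffle_topology(net, seed=8)
        b = shuffle_topology(net, seed=8)
        np.testing.assert_array_equal(a.A, b.A)


class TestNullDistribution:
    def test_reproducible_samples(self, study15):
        net, ds = study15
        a = null_distribution(net, ds, "shuffled_topology", n=10, seed=1)
        b = null_distribution(net, ds, "shuffled_topology", n=10, seed=1)
        assert a.wrss_samples == b.wrss_samples

    def test_true_network_beats_topology_null(self, study15):
        net, ds = study15
        null = null_distribution(net, ds, "shuffled_topology", n=30, seed=2)
        assert null.ratio_to_median < 1.0

    def test_true_network_beats_data_null(self, study15):
        net, ds = study15
        null = null_distribution(net, ds, "shuffled_data", n=20, seed=3)
        assert null.ratio_to_median < 1.0

    def test_r2_true_above_shuffled_median(self, study15):
        net, ds = study15
        fit_true = bfecv_wrss(cls_refit(net, ds), ds)
        r2s = [bfecv_wrss(cls_refit(shuffle_topology(net, s), ds), ds).R2
               for s in range(11)]
        assert fit_true.R2 > np.median(r2s)

    def test_refit_preserves_shuffled_pattern(self, study15):
        net, ds = study15
        shuf = shuffle_topology(net, seed=4)
        refit = cls_refit(shuf, ds)
        assert np.all(refit.support <= shuf.support)
        prod = refit.A * shuf.A
        assert np.all(prod[refit.support] > 0)  # signs preserved


class TestCompareToNull:
    def test_observed_zero(self):
        res = compare_to_null(0.0, [1.0, 2.0, 3.0])
        assert res["ratio_to_median"] == 0.0
        assert res["empirical_p"] == pytest.approx(1 / 4)

    def test_observed_at_maximum(self):
        res = compare_to_null(4.0, [1.0, 2.0, 3.0, 4.0])
        assert res["empirical_p"] == 1.0

    def test_direct_count_example(self):
        res = compare_to_null(2.0, [1.0, 2.0, 3.0, 4.0])
        assert res["ratio_to_median"] == pytest.approx(2 / 2.5)
        assert res["empirical_p"] == pytest.approx(3 / 5)


class TestKnockdownQc:
    def _ds_with_target_values(self, vals):
        n, reps = 2, len(vals)
        P, s, g = make_design(n, "single", replicates=reps)
        Y = np.zeros((n, n * reps))
        Y[0, :reps] = vals
        Y[1, :] = -3.0  # make the second target clearly down
        Y[1, :reps] = 0.1
        return PerturbationDataset(Y, P, ["t", "u"], s, g)

    @pytest.mark.parametrize(
        "vals, mean, tstat, significant",
        [
            ((-3.0, -3.1, -2.9), -3.0, -51.96, True),
            ((-0.1, 0.1, 0.0), 0.0, 0.0, False),
            ((1.0, -6.0, -2.5), -2.5, -1.2372, False),  # one-sided p ~ 0.17
        ],
    )
    def test_printed_triplets(self, vals, mean, tstat, significant):
        ds = self._ds_with_target_values(vals)
        table = knockdown_qc(ds).set_index("gene")
        row = table.loc["t"]
        assert row["mean_lfc"] == pytest.approx(mean, abs=1e-9)
        assert row["t_stat"] == pytest.approx(tstat, abs=5e-3)
        assert bool(row["significant"]) is significant

    def test_textbook_t_statistic(self):
        t, p = stats.ttest_1samp([-3.0, -3.1, -2.9], 0.0, alternative="less")
        assert t == pytest.approx(-3.0 / (0.1 / np.sqrt(3)), rel=1e-6)


class TestNetworkOverlap:
    def test_identical_sets_point_mass(self):
        genes = [f"g{i}" for i in range(20)]
        A = np.zeros((20, 20))
        links = [(i, i + 1) for i in range(10)]
        for i, j in links:
            A[j, i] = 1.0
        net = GeneNetwork(A, genes)
        ref = {(genes[i], genes[j]) for i, j in links}
        res = network_overlap_test(net, ref, universe_size=100)
        from math import comb

        assert res["overlap"] == 10
        assert res["p"] == pytest.approx(1 / comb(100, 10), rel=1e-9)

    def test_disjoint_sets_p_near_one(self):
        genes = [f"g{i}" for i in range(10)]
        A = np.zeros((10, 10))
        A[1, 0] = 1.0
        net = GeneNetwork(A, genes)
        res = network_overlap_test(net, {("g5", "g6")}, universe_size=90)
        assert res["overlap"] == 0
        assert res["p"] == pytest.approx(1.0)

    def test_matches_direct_hypergeometric_sum(self):
        # overlap 3 with |A|=5, |B|=4 in a universe of 30
        genes = [f"g{i}" for i in range(10)]
        A = np.zeros((10, 10))
        for i in range(5):
            A[i + 1, i] = 1.0
        net = GeneNetwork(A, genes)
        ref = {("g0", "g1"), ("g1", "g2"), ("g2", "g3"), ("g8", "g9")}
        res = network_overlap_test(net, ref, universe_size=30)
        assert res["overlap"] == 3
        from math import comb

        expected = sum(comb(4, k) * comb(26, 5 - k) for k in (3, 4)) / comb(30, 5)
        assert res["p"] == pytest.approx(expected, rel=1e-9)

    def test_undirected_collapse(self):
        genes = ["a", "b"]
        A = np.zeros((2, 2))
        A[1, 0] = 1.0  # a -> b
        net = GeneNetwork(A, genes)
        res = network_overlap_test(net, {("b", "a")}, universe_size=10,
                                   directed=False)
        assert res["overlap"] == 1
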