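import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from betaspace.beta_partition import beta_matrices
from betaspace.cap_ordination import (adjusted_r2, cap_fit, forward_select,
                                      pcoa)
from betaspace.core_data import DistMatrix

from conftest import random_incidence


def euclid_dm(Y, labels=None):
    Y = np.atleast_2d(np.asarray(Y, float))
    if Y.shape[0] == 1:
        Y = Y.T
    labels = labels or [f"s{i}" for i in range(Y.shape[0])]
    return DistMatrix(labels, squareform(pdist(Y)))


def ols_r2(y, X):
    """Independent multiple-regression R^2 oracle."""
    Xd = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ beta
    return 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))


class TestPcoa:
    def test_recovers_planted_configuration(self):
        rng = np.random.default_rng(0)
        config = rng.standard_normal((5, 2))
        axes, eigvals, neg = pcoa(euclid_dm(config))
        assert axes.shape[1] == 2 and neg == pytest.approx(0, abs=1e-9)
        # classical-MDS identity: recovered axes match the centred original
        # configuration up to rotation
        from scipy.linalg import orthogonal_procrustes
        C = config - config.mean(axis=0)
        R, _ = orthogonal_procrustes(axes, C)
        assert np.max(np.abs(axes @ R - C)) < 1e-8

    def test_all_zero_matrix_degenerate(self):
        with pytest.raises(ValueError, match="degenerate|positive"):
            pcoa(DistMatrix(list("abcd"), np.zeros((4, 4))))

    def test_jaccard_type_matrix_near_euclidean(self):
        inc = random_incidence(12, 18, seed=1)
        bt = beta_matrices(inc)
        D = bt.beta_total
        n = D.n
        H = np.eye(n) - np.ones((n, n)) / n
        G = -0.5 * H @ (D.values**2) @ H
        w = np.linalg.eigvalsh(G)
        assert w[w > 0].sum() >= -w[w < 0].sum()


class TestCapFit:
    def test_single_axis_predictor_projection_identity(self):
        inc = random_incidence(14, 20, seed=2)
        beta = beta_matrices(inc).beta_repl
        axes, eigvals, _ = pcoa(beta)
        fit = cap_fit(beta, axes[:, [0]])
        assert fit.r2 == pytest.approx(eigvals[0] / eigvals.sum(), abs=1e-10)

    def test_orthogonal_predictor_null(self):
        inc = random_incidence(14, 20, seed=3)
        beta = beta_matrices(inc).beta_repl
        axes, _, _ = pcoa(beta)
        rng = np.random.default_rng(3)
        x = rng.standard_normal(14)
        xc = x - x.mean()
        # project out every axis to construct an orthogonal predictor
        Q, _ = np.linalg.qr(axes - axes.mean(axis=0))
        x_orth = xc - Q @ (Q.T @ xc)
        fit = cap_fit(beta, x_orth, n_perm=199, seed=0)
        assert fit.r2 == pytest.approx(0, abs=1e-10)
        assert fit.perm_p > 0.5

    def test_ols_equivalence_on_euclidean_distance(self):
        rng = np.random.default_rng(4)
        y = rng.standard_normal(15)
        X = rng.standard_normal((15, 3))
        fit = cap_fit(euclid_dm(y), X)
        assert fit.r2 == pytest.approx(ols_r2(y, X), abs=1e-8)

    def test_rank_deficient_names_columns(self):
        inc = random_incidence(12, 15, seed=5)
        beta = beta_matrices(inc).beta_repl
        rng = np.random.default_rng(5)
        X = pd.DataFrame({"a": rng.standard_normal(12)})
        X["b"] = 2 * X["a"]
        with pytest.raises(ValueError, match="'b'"):
            cap_fit(beta, X)

    def test_too_many_predictors(self):
        inc = random_incidence(8, 12, seed=6)
        beta = beta_matrices(inc).beta_repl
        with pytest.raises(ValueError, match="too many"):
            cap_fit(beta, np.random.default_rng(0).standard_normal((8, 7)))

    def test_seed_reproducibility(self):
        inc = random_incidence(12, 15, seed=7)
        beta = beta_matrices(inc).beta_repl
        X = np.random.default_rng(7).standard_normal((12, 2))
        p1 = cap_fit(beta, X, n_perm=99, seed=11).perm_p
        p2 = cap_fit(beta, X, n_perm=99, seed=11).perm_p
        assert p1 == p2

    def test_monotone_r2_in_predictors(self):
        inc = random_incidence(15, 20, seed=8)
        beta = beta_matrices(inc).beta_repl
        X = np.random.default_rng(8).standard_normal((15, 4))
        r2s = [cap_fit(beta, X[:, :m]).r2 for m in range(1, 5)]
        assert np.all(np.diff(r2s) >= -1e-12)


class TestAdjustedR2:
    def test_hand_arithmetic(self):
        assert adjusted_r2(0.2, 26, 4) == pytest.approx(1 - 0.8 * 25 / 21)
        assert adjusted_r2(0.2, 26, 4) == pytest.approx(0.047619, abs=1e-6)

    def test_endpoints(self):
        assert adjusted_r2(1.0, 26, 4) == 1.0
        assert adjusted_r2(0.0, 26, 4) == pytest.approx(1 - 25 / 21)

    def test_guard(self):
        with pytest.raises(ValueError):
            adjusted_r2(0.5, 6, 5)


class TestForwardSelect:
    def test_null_candidates_fail_global_gate(self):
        inc = random_incidence(16, 22, seed=9)
        beta = beta_matrices(inc).beta_repl
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.standard_normal((16, 4)), columns=list("abcd"))
        res = forward_select(beta, X, alpha=0.05, n_perm=199, seed=1)
        assert res.stopping_reason in ("global_ns", "alpha")
        if res.stopping_reason == "global_ns":
            assert res.selected == []

    def test_planted_predictor_selected_first(self):
        rng = np.random.default_rng(10)
        driver = rng.standard_normal(20)
        beta = euclid_dm(driver + 0.05 * rng.standard_normal(20))
        X = pd.DataFrame({"driver": driver,
                          "noise1": rng.standard_normal(20),
                          "noise2": rng.standard_normal(20)})
        res = forward_select(beta, X, alpha=0.1, n_perm=199, seed=2)
        assert res.variables[0] == "driver"

    def test_adj_r2_ceiling_rule_fires(self):
        # one strong predictor among many pure-noise ones: the global model's
        # adjusted R^2 is heavily penalised, so the first accepted step would
        # already exceed it
        rng = np.random.default_rng(0)
        driver = rng.standard_normal(18)
        beta = euclid_dm(driver + 0.6 * rng.standard_normal(18))
        X = pd.DataFrame(rng.standard_normal((18, 11)),
                         columns=[f"n{i:02d}" for i in range(11)])
        X["driver"] = driver
        res = forward_select(beta, X, alpha=0.1, n_perm=199, seed=3)
        assert res.stopping_reason == "adjR2_ceiling"

    def test_selected_steps_all_significant_and_monotone(self):
        rng = np.random.default_rng(12)
        y1, y2 = rng.standard_normal(22), rng.standard_normal(22)
        beta = euclid_dm(np.column_stack([y1, y2])
                         + 0.1 * rng.standard_normal((22, 2)))
        X = pd.DataFrame({"a": y1, "b": y2, "c": rng.standard_normal(22)})
        res = forward_select(beta, X, alpha=0.1, n_perm=199, seed=4)
        assert all(s["p"] < 0.1 for s in res.selected)
        r2s = [s["r2"] for s in res.selected]
        assert np.all(np.diff(r2s) >= -1e-12)
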