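"""Dichotomization, the penalized-logistic solver, eLASSO and network IO."""

import numpy as np
import pandas as pd
import pytest

from profilenet._logistic import fit_logistic_lasso, lambda_max
from profilenet.datasets import ResponseDataset
from profilenet.ising import (
    BinaryMatrix,
    IsingModel,
    IsingNetwork,
    combine_directed,
    dichotomize,
    fit_elasso,
    read_network,
    write_network,
)
from profilenet.simulate import sample_ising


def _tiny_dataset(rows, labels=("a", "b", "c", "d", "e")):
    table = pd.DataFrame(rows, columns=list(labels))
    return ResponseDataset(table, item_labels=labels)


class TestDichotomize:
    def test_midpoint_rule(self):
        data = _tiny_dataset([[1, 2, 3, 4, 5]] * 30)
        # column-wise: 1,2,3 -> 0 and 4,5 -> 1; constant cols then dropped
        b = dichotomize(data, drop_constant=False)
        assert b.values[0].tolist() == [0, 0, 0, 1, 1]

    def test_constant_column_flagged(self):
        rng = np.random.default_rng(0)
        rows = rng.integers(1, 6, size=(40, 5))
        rows[:, 2] = 5  # everyone fully confident on item c
        b = dichotomize(_tiny_dataset(rows))
        assert "c" in b.dropped_constant
        assert b.n_nodes == len(b.labels)

    def test_median_split_strictly_greater(self):
        rows = np.array([[1, 1, 1, 1, 1], [3, 3, 3, 3, 3], [5, 5, 5, 5, 5]])
        b = dichotomize(_tiny_dataset(rows), rule="median", drop_constant=False)
        # median 3: only the strictly greater row becomes 1
        assert b.values[:, 0].tolist() == [0, 0, 1]

    def test_unknown_rule(self):
        with pytest.raises(ValueError):
            dichotomize(_tiny_dataset([[1, 2, 3, 4, 5]]), rule="tertile")


class TestSolver:
    def test_matches_sklearn_saga(self, chain_network):
        """Dual route: our coordinate descent vs sklearn at matched penalty."""
        from sklearn.linear_model import LogisticRegression

        x = sample_ising(chain_network, 2000, seed=4, method="exact")
        X = x.values[:, 1:].astype(float)
        y = x.values[:, 0].astype(float)
        for lam in (0.05, 0.01):
            beta, b = fit_logistic_lasso(X, y, lam)
            sk = LogisticRegression(
                solver="saga", l1_ratio=1.0, C=1 / (len(y) * lam),
                tol=1e-10, max_iter=50_000,
            ).fit(X, y)
            assert np.allclose(beta, sk.coef_[0], atol=1e-5)
            assert b == pytest.approx(float(sk.intercept_[0]), abs=1e-5)

    def test_lambda_max_gives_empty_model(self):
        rng = np.random.default_rng(2)
        X = rng.integers(0, 2, (500, 4)).astype(float)
        y = rng.integers(0, 2, 500).astype(float)
        lam = lambda_max(X, y) * 1.001
        beta, _ = fit_logistic_lasso(X, y, lam)
        assert (beta == 0).all()


class TestElasso:
    def test_two_node_edge_recovery(self):
        net = IsingNetwork(
            np.array([-0.75, -0.75]),
            np.array([[0.0, 1.5], [1.5, 0.0]]),
            ("a", "b"),
        )
        x = sample_ising(net, 2000, seed=5, method="exact")
        fit = fit_elasso(x)
        assert 0.8 < fit.weights[0, 1] < 2.2

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_specificity_on_independent_columns(self, seed):
        rng = np.random.default_rng(seed)
        x = BinaryMatrix(rng.integers(0, 2, (1000, 6)), tuple("abcdef"))
        fit = fit_elasso(x)
        assert fit.n_edges <= 2  # at most 2 false edges out of 15 pairs

    def test_or_vs_and_rule_semantics(self):
        directed = np.zeros((3, 3))
        directed[0, 1] = 0.8  # node 0 selects 1; node 1 does not select 0
        directed[1, 2] = 0.5
        directed[2, 1] = 0.7  # mutual pair
        and_w = combine_directed(directed, "and")
        or_w = combine_directed(directed, "or")
        assert and_w[0, 1] == 0.0 and or_w[0, 1] == pytest.approx(0.4)
        assert and_w[1, 2] == or_w[1, 2] == pytest.approx(0.6)

    def test_gamma_monotone_in_sparsity(self, chain_network):
        x = sample_ising(chain_network, 1500, seed=6, method="exact")
        counts = [
            fit_elasso(x, gamma=g).n_edges for g in (0.0, 0.25, 0.5)
        ]
        assert counts[0] >= counts[1] >= counts[2]

    def test_symmetry_and_zero_diagonal(self, chain_network):
        x = sample_ising(chain_network, 800, seed=7, method="exact")
        fit = fit_elasso(x)
        assert (fit.weights == fit.weights.T).all()
        assert (np.diag(fit.weights) == 0).all()
        assert fit.meta["gamma"] == 0.25 and fit.meta["rule"] == "and"

    def test_constant_column_rejected(self):
        vals = np.ones((100, 3), dtype=np.int8)
        vals[:, 1] = np.random.default_rng(0).integers(0, 2, 100)
        with pytest.raises(ValueError, match="constant"):
            fit_elasso(BinaryMatrix(vals, ("a", "b", "c")))


class TestNetworkIO:
    def test_round_trip(self, chain_network, tmp_path):
        x = sample_ising(chain_network, 500, seed=8, method="exact")
        net = fit_elasso(x)
        path = tmp_path / "net.txt"
        write_network(net, path)
        back = read_network(path)
        assert back.labels == net.labels
        assert np.array_equal(back.thresholds, net.thresholds)
        assert np.array_equal(back.weights, net.weights)
        assert back.meta == net.meta

    def test_empty_network_round_trip(self, tmp_path):
        net = IsingNetwork(np.array([0.3, -0.2]), np.zeros((2, 2)), ("a", "b"))
        path = tmp_path / "empty.txt"
        write_network(net, path)
        back = read_network(path)
        assert back.n_edges == 0
        assert np.array_equal(back.thresholds, net.thresholds)

    def test_hand_authored_file(self, tmp_path):
        path = tmp_path / "hand.txt"
        path.write_text(
            "# profilenet ising network v1\n"
            'meta\t{"n": 10}\n'
            "node\tA\t0.5\nnode\tB\t-0.5\nnode\tC\t0.0\n"
            "edge\tA\tB\t1.25\n"
        )
        net = read_network(path)
        expected = IsingNetwork(
            np.array([0.5, -0.5, 0.0]),
            np.array([[0, 1.25, 0], [1.25, 0, 0], [0, 0, 0.0]]),
            ("A", "B", "C"),
            meta={"n": 10},
        )
        assert net.labels == expected.labels
        assert np.array_equal(net.weights, expected.weights)

    def test_malformed_file_reports_line(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text(
            "# profilenet ising network v1\nnode\tA\t0.5\nedge\tA\n"
        )
        with pytest.raises(ValueError, match="line 3"):
            read_network(path)

    def test_wrong_header(self, tmp_path):
        path = tmp_path / "x.txt"
        path.write_text("nope\n")
        with pytest.raises(ValueError, match="line 1"):
            read_network(path)


class TestModelObject:
    def test_model_results_surface(self, three_class_data):
        data, _ = three_class_data
        res = IsingModel.from_responses(data).fit(n_lambda=30)
        assert res.network.n_nodes == 27
        text = res.summary()
        assert "Ising network" in text and "edges" in text
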