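"""Predictor contract: KNN graph, equivariances, gradients, oracle double."""

import numpy as np
import pytest

from pifgen.molecule import Molecule
from pifgen.predictor import (
    EGNNPredictor,
    OraclePredictor,
    PredictorInput,
    build_knn_graph,
    oracle_predictor,
)
from pifgen.training import TrainConfig, _instance_loss


def brute_force_knn(coords, k):
    coords = np.asarray(coords)
    n = len(coords)
    k = min(k, n - 1)
    edges = []
    for i in range(n):
        pairs = sorted(
            ((np.linalg.norm(coords[i] - coords[j]), j) for j in range(n) if j != i)
        )
        edges.extend((i, j) for _, j in pairs[:k])
    return edges


class TestKNN:
    def test_collinear_example(self):
        coords = np.array([[0, 0, 0], [1, 0, 0], [3, 0, 0]], dtype=float)
        edges = build_knn_graph(coords, 1)
        assert set(map(tuple, edges)) == {(0, 1), (1, 0), (2, 1)}

    def test_matches_brute_force(self, rng):
        for _ in range(10):
            coords = rng.normal(size=(8, 3))
            k = int(rng.integers(1, 7))
            got = set(map(tuple, build_knn_graph(coords, k)))
            assert got == set(brute_force_knn(coords, k))

    def test_k_clamped_to_complete_digraph(self, rng):
        coords = rng.normal(size=(4, 3))
        edges = build_knn_graph(coords, 99)
        assert len(edges) == 4 * 3

    def test_duplicate_coords_tie_break_by_index(self):
        coords = np.zeros((3, 3))
        edges = build_knn_graph(coords, 1)
        assert set(map(tuple, edges)) == {(0, 1), (1, 0), (2, 0)}

    def test_too_few_atoms_rejected(self):
        with pytest.raises(ValueError):
            build_knn_graph(np.zeros((1, 3)), 1)


def _random_input(rng, n=6, K=4, pocket=True, t=0.5):
    tp = rng.dirichlet(np.ones(K), size=n)
    return PredictorInput(
        coords=rng.normal(size=(n, 3)),
        type_probs=tp,
        fixed=np.zeros(n, dtype=bool),
        t=t,
        pocket_coords=rng.normal(size=(4, 3)) if pocket else None,
        pocket_types=np.array([0, 1, 0, 1]) if pocket else None,
        frame_origin=rng.normal(size=3),
    )


class TestEGNNContract:
    def test_translation_equivariance(self, rng):
        model = EGNNPredictor(K=4, hidden_dim=16, n_layers=2, knn_k=4, seed=0)
        for _ in range(20):
            inp = _random_input(rng)
            out = model.predict(inp)
            u = rng.normal(size=3)
            inp2 = PredictorInput(
                coords=inp.coords + u,
                type_probs=inp.type_probs,
                fixed=inp.fixed,
                t=inp.t,
                pocket_coords=inp.pocket_coords + u,
                pocket_types=inp.pocket_types,
                frame_origin=inp.frame_origin + u,
            )
            out2 = model.predict(inp2)
            assert np.max(np.abs(out2.mu_hat - out.mu_hat - u)) < 1e-5
            assert np.max(np.abs(out2.alpha_hat - out.alpha_hat)) < 1e-8

    def test_permutation_equivariance(self, rng):
        model = EGNNPredictor(K=4, hidden_dim=16, n_layers=2, knn_k=4, seed=0)
        inp = _random_input(rng)
        out = model.predict(inp)
        perm = rng.permutation(6)
        inp2 = PredictorInput(
            coords=inp.coords[perm],
            type_probs=inp.type_probs[perm],
            fixed=inp.fixed[perm],
            t=inp.t,
            pocket_coords=inp.pocket_coords,
            pocket_types=inp.pocket_types,
            frame_origin=inp.frame_origin,
        )
        out2 = model.predict(inp2)
        assert np.allclose(out2.mu_hat, out.mu_hat[perm], atol=1e-10)
        assert np.allclose(out2.alpha_hat, out.alpha_hat[perm], atol=1e-10)

    def test_untrained_output_is_simplex(self, rng):
        model = EGNNPredictor(K=5, hidden_dim=8, n_layers=1, knn_k=3, seed=2)
        out = model.predict(_random_input(rng, K=5, pocket=False))
        assert np.all(out.alpha_hat >= 0)
        assert np.allclose(out.alpha_hat.sum(axis=1), 1.0, atol=1e-6)

    def test_deterministic_given_weights_and_input(self, rng):
        model = EGNNPredictor(K=4, hidden_dim=8, n_layers=1, knn_k=3, seed=0)
        inp = _random_input(rng)
        a = model.predict(inp)
        b = model.predict(inp)
        assert np.array_equal(a.mu_hat, b.mu_hat)

    def test_gradient_flow_all_parameters(self, small_dataset):
        """Every parameter receives a finite, non-zero gradient on a batch."""
        model = EGNNPredictor(K=4, hidden_dim=8, n_layers=2, knn_k=4, seed=1)
        cfg = TrainConfig(steps=1, batch_size=1, seed=0)
        rng = np.random.default_rng(3)
        total = None
        for inst in small_dataset[:4]:
            li, _ = _instance_loss(model, inst, cfg, rng)
            total = li if total is None else total + li
        model.zero_grad()
        total.backward()
        for name, p in model.params.items():
            assert p.grad is not None, name
            assert np.all(np.isfinite(p.grad)), name
            assert np.any(p.grad != 0.0), name

    def test_autodiff_matches_finite_differences(self, small_dataset):
        model = EGNNPredictor(K=4, hidden_dim=8, n_layers=2, knn_k=4, seed=1)
        cfg = TrainConfig(steps=1, batch_size=1, seed=0)

        def loss_value():
            return _instance_loss(model, small_dataset[0], cfg, np.random.default_rng(7))[0]

        l0 = loss_value()
        model.zero_grad()
        l0.backward()
        eps = 1e-6
        for name in ("embed_W", "e1_W0", "x_W1", "v_W", "g_W0"):
            p = model.params[name]
            i, j = 1, 0
            g_an = p.grad[i, j]
            p.data[i, j] += eps
            lp = loss_value().data
            p.data[i, j] -= 2 * eps
            lm = loss_value().data
            p.data[i, j] += eps
            g_fd = (lp - lm) / (2 * eps)
            assert g_an == pytest.approx(g_fd, rel=1e-4, abs=1e-9), name


class TestOraclePredictor:
    def _mol(self, rng, n=5):
        return Molecule(coords=rng.normal(size=(n, 3)), types=rng.integers(0, 4, n), K=4)

    def test_emits_exact_data_parameters(self, rng):
        mol = self._mol(rng)
        oracle = oracle_predictor({"a": mol})
        inp = PredictorInput(
            coords=rng.normal(size=(5, 3)),
            type_probs=rng.dirichlet(np.ones(4), size=5),
            fixed=np.zeros(5, dtype=bool),
            t=0.2,
            instance_id="a",
        )
        out = oracle.predict(inp)
        assert np.array_equal(out.mu_hat, mol.coords)
        assert np.array_equal(out.alpha_hat, mol.onehot_types())

    def test_unknown_instance_rejected(self, rng):
        oracle = OraclePredictor({"a": self._mol(rng)})
        inp = PredictorInput(
            coords=np.zeros((5, 3)),
            type_probs=np.full((5, 4), 0.25),
            fixed=np.zeros(5, dtype=bool),
            t=0.2,
            instance_id="missing",
        )
        with pytest.raises(KeyError):
            oracle.predict(inp)

    def test_loss_zero_under_oracle(self, small_dataset):
        """An oracle-quality prediction yields zero total loss at any time."""
        from pifgen.losses import total_loss

        inst = small_dataset[0]
        mol = inst.molecule
        onehot = mol.onehot_types()
        for t in (0.1, 0.5, 0.9):
            f = 1 - 0.009**t
            a_t = f * onehot + (1 - f) / 4
            assert total_loss(
                mol.coords, a_t, mol.coords, a_t, t, 0.009, 1.0
            ) == pytest.approx(0.0, abs=1e-12)
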