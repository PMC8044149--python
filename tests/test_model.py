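"""DCGRU cell semantics, encoder-decoder contracts, checkpoints."""

import numpy as np
import pytest

from neurocast import autodiff as ad
from neurocast.graph import Graph, build_transition_matrix
from neurocast.model import (DCGRUCell, Seq2SeqModel, dcgru_step,
                             load_checkpoint, save_checkpoint)

from conftest import random_graph


def make_model(rng, n=5, q=4, order=1, seed=3, dtype=np.float64, layers=2):
    op = build_transition_matrix(random_graph(rng, n))
    return Seq2SeqModel(op, hidden_size=q, order=order, n_layers=layers,
                        seed=seed, dtype=dtype)


class TestCellStep:
    def test_closed_update_gate_keeps_state(self, rng):
        op = build_transition_matrix(random_graph(rng, 4))
        cell = DCGRUCell(1, 3, op, order=1, rng=rng, dtype=np.float64)
        for name in ("w_r", "w_u", "w_c"):
            cell.params[name].value[:] = 0.0
        cell.params["b_u"].value[:] = 50.0  # u ~= 1 -> H' = H
        h = rng.uniform(-1, 1, size=(1, 4, 3))
        out = dcgru_step(rng.normal(size=(1, 4, 1)), h, cell)
        np.testing.assert_allclose(out, h, atol=1e-12)

    def test_open_gate_output_tanh_bounded(self, rng):
        op = build_transition_matrix(random_graph(rng, 4))
        cell = DCGRUCell(1, 3, op, order=1, rng=rng, dtype=np.float64)
        cell.params["b_u"].value[:] = -50.0  # u ~= 0 -> H' = c
        h = rng.uniform(-1, 1, size=(1, 4, 3))
        out = dcgru_step(10 * rng.normal(size=(1, 4, 1)), h, cell)
        assert np.all(np.abs(out) < 1.0)

    def test_single_node_order_zero_matches_plain_gru(self, rng):
        # with N=1 and K=0 the cell is an ordinary GRU; replicate one step
        # with an independently coded scalar-loop GRU
        op = build_transition_matrix(Graph(np.array([[0.0, 1], [1, 0]])))
        # restrict to one node by probing node 0 of a 2-node graph with K=0
        cell = DCGRUCell(1, 3, op, order=0, rng=rng, dtype=np.float64)
        x = rng.normal(size=(1, 2, 1))
        h = rng.uniform(-1, 1, size=(1, 2, 3))
        out = dcgru_step(x, h, cell)

        w_r = cell.params["w_r"].value
        w_u = cell.params["w_u"].value
        w_c = cell.params["w_c"].value
        b_r = cell.params["b_r"].value
        b_u = cell.params["b_u"].value
        b_c = cell.params["b_c"].value

        def sig(v):
            return 1 / (1 + np.exp(-v))

        for node in range(2):
            xh = np.concatenate([x[0, node], h[0, node]])
            r = sig(xh @ w_r + b_r)
            u = sig(xh @ w_u + b_u)
            xrh = np.concatenate([x[0, node], r * h[0, node]])
            c = np.tanh(xrh @ w_c + b_c)
            expected = u * h[0, node] + (1 - u) * c
            np.testing.assert_allclose(out[0, node], expected, atol=1e-10)

    def test_hidden_state_stays_bounded_over_many_steps(self, rng):
        op = build_transition_matrix(random_graph(rng, 4))
        cell = DCGRUCell(1, 3, op, order=1, rng=rng, dtype=np.float64)
        h = rng.uniform(-1, 1, size=(1, 4, 3))
        for _ in range(50):
            h = dcgru_step(rng.normal(size=(1, 4, 1)), h, cell)
        assert np.all(np.abs(h) <= 1.0)


class TestEncodeDecode:
    def test_zero_input_zero_params_zero_states(self, rng):
        model = make_model(rng)
        model.set_weights({k: np.zeros_like(v)
                           for k, v in model.get_weights().items()})
        states = model.encode(np.zeros((5, 6)))
        for s in states:
            np.testing.assert_allclose(s.value, 0.0)

    def test_single_frame_encoding_equals_manual_steps(self, rng):
        model = make_model(rng)
        x = rng.normal(size=(5, 1))
        states = model.encode(x)
        h0 = ad.const(np.zeros((1, 5, 4)))
        s0 = model.encoder_cells[0].step(ad.const(x.T[None].swapaxes(1, 2)), h0)
        s1 = model.encoder_cells[1].step(s0, h0)
        np.testing.assert_allclose(states[0].value, s0.value, atol=1e-12)
        np.testing.assert_allclose(states[1].value, s1.value, atol=1e-12)

    def test_node_permutation_equivariance(self, rng):
        n = 6
        g = random_graph(rng, n)
        perm = rng.permutation(n)
        op = build_transition_matrix(g)
        op_p = build_transition_matrix(Graph(g.adjacency[np.ix_(perm, perm)]))
        m1 = Seq2SeqModel(op, hidden_size=4, order=1, seed=9, dtype=np.float64)
        m2 = Seq2SeqModel(op_p, hidden_size=4, order=1, seed=9,
                          dtype=np.float64)
        m2.set_weights(m1.get_weights())  # filters are node-independent
        x = rng.normal(size=(n, 7))
        np.testing.assert_allclose(m1.forecast(x, 4)[perm],
                                   m2.forecast(x[perm], 4), atol=1e-9)

    def test_decode_zero_horizon_empty(self, rng):
        model = make_model(rng)
        out = model.decode(model.encode(rng.normal(size=(5, 3))), 0)
        assert out == []

    def test_zero_params_zero_predictions(self, rng):
        model = make_model(rng)
        model.set_weights({k: np.zeros_like(v)
                           for k, v in model.get_weights().items()})
        pred = model.forecast(rng.normal(size=(5, 6)), 4)
        np.testing.assert_allclose(pred, 0.0)

    def test_teacher_mode_matches_free_running_at_first_step(self, rng):
        model = make_model(rng)
        x = rng.normal(size=(5, 6))
        teacher = rng.normal(size=(5, 4))
        states = model.encode(x)
        forced = model.decode(states, 4, teacher=teacher,
                              use_teacher=[True] * 4)
        free = model.decode(model.encode(x), 4)
        np.testing.assert_allclose(forced[0].value, free[0].value, atol=1e-12)
        assert not np.allclose(forced[1].value, free[1].value)

    def test_teacher_required_when_requested(self, rng):
        model = make_model(rng)
        with pytest.raises(ValueError, match="teacher"):
            model.decode(model.encode(rng.normal(size=(5, 3))), 2,
                         use_teacher=[True, False])


class TestForecast:
    def test_purity(self, rng):
        model = make_model(rng)
        x = rng.normal(size=(5, 6))
        np.testing.assert_array_equal(model.forecast(x, 3),
                                      model.forecast(x, 3))

    def test_order_zero_predictions_are_node_local(self, rng):
        model = make_model(rng, order=0)
        x = rng.normal(size=(5, 6))
        x2 = x.copy()
        x2[1:] += rng.normal(size=(4, 6))  # change every node but node 0
        p1 = model.forecast(x, 4)
        p2 = model.forecast(x2, 4)
        np.testing.assert_allclose(p1[0], p2[0], atol=1e-9)
        assert not np.allclose(p1[1:], p2[1:])

    def test_parameter_count_independent_of_graph_size(self, rng):
        small = make_model(rng, n=4)
        large = make_model(rng, n=12)
        assert small.n_parameters() == large.n_parameters()

    def test_gradients_finite_on_random_batch(self, rng):
        model = make_model(rng, dtype=np.float64)
        x = rng.normal(size=(3, 5, 6))
        y = rng.normal(size=(3, 5, 4))
        outs = model.decode(model.encode(x), 4, teacher=y,
                            use_teacher=[True, False, True, False])
        loss = ad.mean_abs_error(ad.concat(outs, axis=-1), y)
        ad.backward(loss)
        for name, p in model.parameters().items():
            assert p.grad is not None, name
            assert np.all(np.isfinite(p.grad)), name


class TestCheckpoint:
    def test_round_trip(self, rng, tmp_path):
        model = make_model(rng)
        path = tmp_path / "model.npz"
        save_checkpoint(model, str(path))
        loaded = load_checkpoint(str(path), model.operator)
        x = rng.normal(size=(5, 6))
        np.testing.assert_allclose(model.forecast(x, 3),
                                   loaded.forecast(x, 3), atol=1e-7)

    def test_load_onto_larger_graph(self, rng, tmp_path):
        model = make_model(rng, n=5)
        path = tmp_path / "model.npz"
        save_checkpoint(model, str(path))
        op12 = build_transition_matrix(random_graph(rng, 12))
        loaded = load_checkpoint(str(path), op12)
        assert loaded.forecast(rng.normal(size=(12, 6)), 3).shape == (12, 3)

    def test_direction_mismatch_rejected(self, rng, tmp_path):
        model = make_model(rng)
        path = tmp_path / "model.npz"
        save_checkpoint(model, str(path))
        op = build_transition_matrix(random_graph(rng, 5),
                                     include_reverse=False)
        with pytest.raises(ValueError, match="directions"):
            load_checkpoint(str(path), op)
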