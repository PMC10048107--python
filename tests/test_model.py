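"""Generative model: APD contract, KL loss, training dynamics, sampling."""

import math

import numpy as np
import pytest

from flavorgen.apd import APDLayout
from flavorgen.errors import ConfigError, ContractError, SizeError
from flavorgen.graphs import (
    Action,
    ActionKind,
    MolecularGraph,
    deconstruction_route,
    parse_smiles,
    to_canonical_smiles,
)
from flavorgen.model import (
    GenerativeModel,
    actions_to_route,
    init_model,
    kl_loss,
    route_nll,
    sample,
    train,
)
from tests.conftest import tiny_model_config


class TestLayout:
    def test_add_block_index_arithmetic(self):
        layout = APDLayout(("C", "O"), max_nodes=13)
        assert layout.n_add == 13 * 2 * 3 * 3  # slots x elements x charges x bonds
        assert layout.n_first == 2 * 3
        assert layout.n_conn == 13 * 3
        assert layout.size == layout.n_add + layout.n_first + layout.n_conn + 1

    def test_encode_decode_round_trip(self):
        layout = APDLayout(("C", "N", "O"), max_nodes=6)
        actions = [
            Action.add(None, "N", 1, None),
            Action.add(3, "O", -1, 2),
            Action.connect(1, 5, 3),
            Action.terminate(),
        ]
        for action, n_nodes in zip(actions, (0, 4, 6, 4)):
            idx = layout.encode(action, n_nodes)
            back = layout.decode(idx, n_nodes)
            assert back.kind == action.kind
            if action.kind is ActionKind.ADD:
                assert (back.attach_to, back.element, back.charge,
                        back.bond_order) == (action.attach_to, action.element,
                                             action.charge, action.bond_order)
            if action.kind is ActionKind.CONNECT:
                assert {back.i, back.j} == {action.i, action.j}
                assert back.bond_order == action.bond_order

    def test_mask_rules(self):
        layout = APDLayout(("C",), max_nodes=4)
        empty_mask = layout.mask(MolecularGraph())
        # empty graph: only first-atom block and terminate are open
        open_idx = np.flatnonzero(empty_mask == 0)
        assert set(open_idx) == set(
            range(layout.n_add, layout.n_add + layout.n_first)) | {layout.size - 1}
        g2 = parse_smiles("CC")
        g2.terminated = False
        mask2 = layout.mask(g2)
        assert (mask2[:layout.n_add].reshape(4, 1, 3, 3)[:2] == 0).all()
        assert (mask2[:layout.n_add].reshape(4, 1, 3, 3)[2:] != 0).all()
        conn = mask2[layout.n_add + layout.n_first:-1].reshape(4, 3)
        assert (conn[0] == 0).all() and (conn[1:] != 0).all()


class TestInitAndForward:
    def test_same_seed_identical_first_apd(self):
        cfg = tiny_model_config()
        g = parse_smiles("CCO")
        g.terminated = False
        a = init_model(cfg, ["C", "O"], seed=9).forward_apd(g)
        b = init_model(cfg, ["C", "O"], seed=9).forward_apd(g)
        np.testing.assert_array_equal(a.probabilities, b.probabilities)

    def test_empty_vocabulary_rejected(self):
        with pytest.raises(ConfigError):
            init_model(tiny_model_config(), [], seed=0)

    @pytest.mark.parametrize("smiles", ["C", "CCO", "C1CC1", "CC(=O)C"])
    def test_apd_normalized_and_nonnegative(self, smiles):
        model = init_model(tiny_model_config(), ["C", "O"], seed=0)
        g = parse_smiles(smiles)
        g.terminated = False
        apd = model.forward_apd(g)
        assert apd.probabilities.min() >= 0
        assert apd.probabilities.sum() == pytest.approx(1.0, abs=1e-6)

    def test_empty_graph_has_no_connect_mass(self):
        model = init_model(tiny_model_config(), ["C", "O"], seed=0)
        apd = model.forward_apd(MolecularGraph())
        assert apd.f_conn.sum() == 0.0
        assert apd.f_add.sum() == 0.0
        assert apd.f_first.sum() + apd.f_term == pytest.approx(1.0, abs=1e-6)

    def test_masked_slots_hold_no_probability(self):
        model = init_model(tiny_model_config(max_nodes=8), ["C", "O"], seed=1)
        g = parse_smiles("CCC")
        g.terminated = False
        apd = model.forward_apd(g)
        assert apd.f_add[3:].sum() == 0.0     # slots beyond current size
        assert apd.f_conn[2:].sum() == 0.0    # cannot connect to self/absent
        assert apd.f_first.sum() == 0.0       # graph is not empty

    def test_oversize_graph_raises(self):
        model = init_model(tiny_model_config(max_nodes=3), ["C", "O"], seed=0)
        g = parse_smiles("CCCCCO")
        g.terminated = False
        with pytest.raises(SizeError):
            model.forward_apd(g)

    def test_apd_normalization_over_many_random_partial_graphs(self, records200):
        model = init_model(tiny_model_config(max_nodes=16),
                           ["C", "N", "O", "S"], seed=3)
        rng = np.random.default_rng(0)
        for rec in [records200[i] for i in rng.choice(200, 40, replace=False)]:
            route = deconstruction_route(parse_smiles(rec.smiles))
            step = int(rng.integers(len(route.steps)))
            graph = route.steps[step][0]
            apd = model.forward_apd(graph)
            assert apd.probabilities.sum() == pytest.approx(1.0, abs=1e-6)


class TestKLLoss:
    def test_uniform_prediction_gives_log_k(self, pentanol_route):
        model = init_model(tiny_model_config(), ["C", "N", "O", "S"], seed=0)
        for p in model.parameters():
            p.data[...] = 0.0  # constant logits => uniform over open actions
        graph, action = pentanol_route.steps[2][0], pentanol_route.steps[2][1]
        k_open = int((model.layout.mask(graph) == 0).sum())
        single = kl_loss(model, [actions_to_route([
            a for _, a in pentanol_route.steps[:3]])])
        # mean over the 3 steps; each step uniform over its own open count
        per_step = []
        for g, a in pentanol_route.steps[:3]:
            per_step.append(math.log((model.layout.mask(g) == 0).sum()))
        assert float(single.data) == pytest.approx(np.mean(per_step), rel=1e-9)
        assert math.log(k_open) == per_step[2]

    def test_loss_nonnegative_on_random_models(self, records200):
        model = init_model(tiny_model_config(max_nodes=16),
                           ["C", "N", "O", "S"], seed=11)
        routes = [deconstruction_route(parse_smiles(r.smiles))
                  for r in records200[:5]]
        assert float(kl_loss(model, routes).data) >= 0.0

    def test_empty_batch_rejected(self):
        model = init_model(tiny_model_config(), ["C"], seed=0)
        with pytest.raises(ContractError):
            kl_loss(model, [])


class TestTraining:
    def test_zero_epochs_leaves_model_unchanged(self, pentanol_route):
        model = init_model(tiny_model_config(), ["C", "O"], seed=0)
        before = [a.copy() for a in model.state_arrays()]
        train(model, [pentanol_route], epochs=0, seed=0)
        for a, b in zip(before, model.state_arrays()):
            np.testing.assert_array_equal(a, b)

    def test_overfit_drives_loss_down_and_recovers_molecule(
            self, pentanol_overfit):
        model, result = pentanol_overfit
        assert result.losses[-1] < 0.05
        draws = sample(model, 100, seed=1)
        hits = sum(1 for m in draws
                   if m.valid and m.properly_terminated
                   and to_canonical_smiles(m.graph) == "CCCCCO")
        assert hits >= 90

    def test_loss_trend_non_increasing_in_moving_average(
            self, small_trained_model):
        _, routes = small_trained_model
        model = init_model(
            tiny_model_config(ggnn_hidden_dim=16, ggnn_width=16,
                              message_size=16, mlp_hidden_dim=32,
                              max_nodes=16),
            ["C", "N", "O", "S"], seed=5)
        result = train(model, routes, epochs=100, seed=5)
        losses = np.asarray(result.losses)
        ma = np.convolve(losses, np.ones(50) / 50, mode="valid")
        assert np.all(np.diff(ma) <= 1e-9)

    def test_learning_rate_after_twenty_steps(self, pentanol_route):
        from flavorgen.model import make_optimizer

        model = init_model(tiny_model_config(learning_rate=1e-4),
                           ["C", "O"], seed=0)
        opt = make_optimizer(model)
        train(model, [pentanol_route], epochs=20, seed=0, optimizer=opt)
        assert opt.lr == pytest.approx(1e-4 * 0.99 ** 2)

    def test_snapshots_recorded_at_interval(self, pentanol_route):
        model = init_model(tiny_model_config(), ["C", "O"], seed=0)
        result = train(model, [pentanol_route], epochs=10,
                       snapshot_interval=5, seed=0,
                       validation_routes=[pentanol_route])
        assert [e for e, _ in result.snapshots] == [5, 10]
        assert [e for e, _ in result.validation] == [5, 10]


class TestSampling:
    def test_sample_count_and_flags(self, small_trained_model):
        model, _ = small_trained_model
        draws = sample(model, 200, seed=2)
        assert len(draws) == 200
        for m in draws:
            assert m.log_probability <= 0.0
            if m.properly_terminated:
                assert m.actions[-1].kind is ActionKind.TERMINATE

    def test_overfit_model_modal_sample_is_pentanol(self, pentanol_overfit):
        model, _ = pentanol_overfit
        draws = sample(model, 50, seed=3)
        smiles = [to_canonical_smiles(m.graph) for m in draws
                  if m.valid and m.properly_terminated]
        modal = max(set(smiles), key=smiles.count)
        assert modal == "CCCCCO"

    def test_deterministic_in_seed(self, small_trained_model):
        model, _ = small_trained_model
        a = sample(model, 20, seed=9)
        b = sample(model, 20, seed=9)
        assert [m.log_probability for m in a] == [m.log_probability for m in b]

    def test_invalid_count_requires_at_least_one(self, small_trained_model):
        model, _ = small_trained_model
        with pytest.raises(ContractError):
            sample(model, 0, seed=0)


class TestRouteNLL:
    def test_matches_sampled_log_probability(self, small_trained_model):
        model, _ = small_trained_model
        for m in sample(model, 10, seed=4):
            route = actions_to_route(m.actions)
            assert route_nll(model, route) == pytest.approx(
                -m.log_probability, abs=1e-6)

    def test_overfit_route_nll_near_zero(self, pentanol_overfit, pentanol_route):
        model, _ = pentanol_overfit
        assert route_nll(model, pentanol_route) < 0.5

    def test_uniform_model_gives_sum_log_k(self, pentanol_route):
        model = init_model(tiny_model_config(), ["C", "N", "O", "S"], seed=0)
        for p in model.parameters():
            p.data[...] = 0.0
        expected = sum(math.log((model.layout.mask(g) == 0).sum())
                       for g, _ in pentanol_route.steps)
        assert route_nll(model, pentanol_route) == pytest.approx(expected,
                                                                 rel=1e-9)


class TestPersistence:
    def test_save_load_round_trip(self, small_trained_model, tmp_path):
        model, routes = small_trained_model
        model.save(tmp_path / "m")
        back = GenerativeModel.load(tmp_path / "m.npz")
        assert route_nll(back, routes[0]) == pytest.approx(
            route_nll(model, routes[0]))
        assert back.training_step == model.training_step
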