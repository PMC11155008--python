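"""FedAvg aggregation and the synchronous federated simulation."""

import numpy as np
import pytest

from fedcrt.federated import ClientUpdate, FederatedConfig, aggregate_fedavg, run_federated
from fedcrt.network import Conv3DNet, ModelConfig, ParameterSet, reduced_config
from fedcrt.training import TrainConfig, train_local

TINY = ModelConfig(input_size=8, conv_channels=(2, 3, 4), fc_hidden=5, init_seed=0)


def random_params(rng, scale=1.0):
    return ParameterSet(
        [
            ("a", scale * rng.standard_normal((3, 4))),
            ("b", scale * rng.standard_normal(5)),
            ("c", scale * rng.standard_normal((2, 2, 2))),
        ]
    )


class TestAggregate:
    def test_identical_clients_return_theta(self, rng):
        theta = random_params(rng)
        updates = [ClientUpdate(f"c{i}", theta.copy(), n_samples=i + 1) for i in range(3)]
        out = aggregate_fedavg(updates)
        for (_, a), (_, b) in zip(out, theta):
            assert np.allclose(a, b, atol=1e-15)

    def test_scalar_weighted_mean(self):
        u0 = ClientUpdate("c0", ParameterSet([("w", np.array([0.0]))]), n_samples=1)
        u1 = ClientUpdate("c1", ParameterSet([("w", np.array([1.0]))]), n_samples=3)
        out = aggregate_fedavg([u0, u1])
        assert out.entries[0][1][0] == pytest.approx(0.75, abs=1e-15)

    def test_matches_elementwise_loop_oracle(self, rng):
        updates = [
            ClientUpdate(f"c{i}", random_params(rng), n_samples=int(rng.integers(1, 50)))
            for i in range(3)
        ]
        out = aggregate_fedavg(updates)
        total = sum(u.n_samples for u in updates)
        for j, (name, got) in enumerate(out):
            expected = np.zeros_like(got)
            for pos in np.ndindex(got.shape):
                acc = 0.0
                for u in updates:
                    acc += (u.n_samples / total) * u.parameters.entries[j][1][pos]
                expected[pos] = acc
            assert np.abs(got - expected).max() < 1e-12

    def test_permutation_invariant(self, rng):
        updates = [
            ClientUpdate(f"c{i}", random_params(rng), n_samples=int(rng.integers(1, 9)))
            for i in range(4)
        ]
        a = aggregate_fedavg(updates)
        b = aggregate_fedavg(updates[::-1])
        for (_, x), (_, y) in zip(a, b):
            assert np.abs(x - y).max() < 1e-12

    def test_output_within_convex_envelope(self, rng):
        updates = [
            ClientUpdate(f"c{i}", random_params(rng), n_samples=int(rng.integers(1, 9)))
            for i in range(3)
        ]
        out = aggregate_fedavg(updates)
        for j, (_, got) in enumerate(out):
            stack = np.stack([u.parameters.entries[j][1] for u in updates])
            assert np.all(got >= stack.min(axis=0) - 1e-12)
            assert np.all(got <= stack.max(axis=0) + 1e-12)

    def test_equal_sizes_give_unweighted_mean(self, rng):
        updates = [ClientUpdate(f"c{i}", random_params(rng), n_samples=7) for i in range(3)]
        out = aggregate_fedavg(updates)
        for j, (_, got) in enumerate(out):
            mean = np.mean([u.parameters.entries[j][1] for u in updates], axis=0)
            assert np.abs(got - mean).max() < 1e-12

    def test_empty_list_fails(self):
        with pytest.raises(ValueError, match="empty"):
            aggregate_fedavg([])

    def test_shape_mismatch_names_client_and_entry(self, rng):
        good = ClientUpdate("good", random_params(rng), n_samples=1)
        bad_params = random_params(rng)
        bad_params.entries[1] = ("b", np.zeros(6))
        bad = ClientUpdate("bad", bad_params, n_samples=1)
        with pytest.raises(ValueError, match="bad"):
            aggregate_fedavg([good, bad])


def small_client_data(n=12, seed=0, size=8):
    rng = np.random.default_rng(seed)
    y = np.arange(n) % 2
    x = np.clip(
        np.stack([np.full((size,) * 3, 0.25 + 0.5 * t) for t in y])
        + rng.normal(0, 0.05, (n, size, size, size)),
        0,
        1,
    )
    return x, y


class TestRunFederated:
    def test_single_client_reduces_to_centralized(self):
        """One client, R rounds of L epochs == centralized R*L epochs, bit for bit."""
        x, y = small_client_data(14, seed=1)
        fed = FederatedConfig(
            n_rounds=3,
            local_epochs=2,
            seed=11,
            client_train_cfg=TrainConfig(batch_size=4, optimizer="sgd"),
        )
        gp, _, _ = run_federated([("solo", (x, y), None)], TINY, fed, server_eval=False)
        central_cfg = TrainConfig(batch_size=4, optimizer="sgd", epochs=6, seed=11)
        cp, _ = train_local(Conv3DNet(TINY), (x, y), None, central_cfg)
        for (_, a), (_, b) in zip(gp, cp):
            assert np.array_equal(a, b)

    def test_zero_local_epochs_leaves_global_unchanged(self):
        x, y = small_client_data(8)
        fed = FederatedConfig(n_rounds=2, local_epochs=0, seed=0,
                              client_train_cfg=TrainConfig(optimizer="sgd"))
        gp, _, _ = run_federated([("c", (x, y), None)], TINY, fed, server_eval=False)
        init = Conv3DNet(TINY).get_parameters()
        for (_, a), (_, b) in zip(gp, init):
            assert np.array_equal(a, b)

    def test_identical_clients_produce_identical_updates(self):
        x, y = small_client_data(10, seed=2)
        fed = FederatedConfig(
            n_rounds=2, local_epochs=1, seed=4,
            client_train_cfg=TrainConfig(batch_size=5, optimizer="sgd"),
        )
        gp1, _, _ = run_federated([("a", (x, y), None)], TINY, fed, server_eval=False)
        gp2, _, _ = run_federated(
            [("a", (x, y), None), ("b", (x.copy(), y.copy()), None)],
            TINY, fed, server_eval=False,
        )
        for (_, a), (_, b) in zip(gp1, gp2):
            assert np.array_equal(a, b)

    def test_round_log_structure(self):
        x, y = small_client_data(8)
        fed = FederatedConfig(n_rounds=2, local_epochs=1, seed=0,
                              client_train_cfg=TrainConfig(batch_size=4, optimizer="sgd"))
        _, rlog, glog = run_federated(
            [("c1", (x, y), (x, y)), ("c2", (x, y), None)], TINY, fed
        )
        assert list(rlog.columns) == ["round", "client_id", "train_loss", "n_samples"]
        assert len(rlog) == 4  # 2 rounds x 2 clients
        assert list(glog["round"]) == [0, 1]

    def test_failing_client_is_named(self):
        x, y = small_client_data(8)
        bad = (np.zeros((0, 8, 8, 8)), np.zeros(0))
        fed = FederatedConfig(n_rounds=1, local_epochs=1, seed=0,
                              client_train_cfg=TrainConfig(optimizer="sgd"))
        with pytest.raises(ValueError, match="flaky"):
            run_federated([("ok", (x, y), None), ("flaky", bad, None)], TINY, fed)

    def test_validation_loss_improves_on_shifted_sites(self, desk_patches):
        """Median final-round pooled validation loss beats round 0 across seeds."""
        x, y, sites = desk_patches["x"], desk_patches["y"], desk_patches["sites"]
        clients = []
        for s in ("S1", "S2", "S3"):
            m = sites == s
            xs, ys = x[m], y[m]
            n_tr = int(0.7 * len(ys))
            clients.append((s, (xs[:n_tr], ys[:n_tr]), (xs[n_tr:], ys[n_tr:])))
        deltas = []
        for seed in (0, 1, 2):
            fed = FederatedConfig(
                n_rounds=3, local_epochs=1, seed=seed,
                client_train_cfg=TrainConfig(batch_size=8, optimizer="adam"),
            )
            _, _, glog = run_federated(clients, reduced_config(seed), fed)
            deltas.append(glog.val_loss.iloc[-1] - glog.val_loss.iloc[0])
        assert np.median(deltas) < 0
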