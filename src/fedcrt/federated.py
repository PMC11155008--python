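"""Synchronous in-process federated averaging (FedAvg).

Each communication round: the server broadcasts the global weights to every
client; each client trains locally for ``local_epochs`` epochs on its own
training split; the server replaces the global weights with the
sample-size-weighted average of the client weights,

    theta_global = sum_k (n_k / sum_j n_j) * theta_k,

accumulated in double precision.  All clients participate every round
(no sampling, no stragglers) and client optimiser state is reset after each
broadcast.  The client/server boundary is an explicit ParameterSet hand-off,
so a networked transport could replace the in-process loop without touching
the training code.

With a single client, aggregation is the identity and the protocol reduces
exactly to centralized training for ``n_rounds * local_epochs`` epochs
(the local epoch counter continues across rounds via ``epoch_offset``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .network import Conv3DNet, ModelConfig, ParameterSet
from .training import TrainConfig, federated_sim_config, train_local

__all__ = ["FederatedConfig", "ClientUpdate", "aggregate_fedavg", "run_federated"]


@dataclass
class FederatedConfig:
    """Round structure of the simulation; defaults follow the study protocol
    (10 communication rounds of 50 local epochs per client)."""

    n_rounds: int = 10
    local_epochs: int = 50
    client_train_cfg: TrainConfig = field(default_factory=federated_sim_config)
    aggregation: str = "fedavg"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rounds < 1 or self.local_epochs < 0:
            raise ValueError("n_rounds >= 1 and local_epochs >= 0 required")
        if self.aggregation != "fedavg":
            raise ValueError("only 'fedavg' aggregation is implemented")


@dataclass
class ClientUpdate:
    """One client's contribution to a round."""

    client_id: str
    parameters: ParameterSet
    n_samples: int
    train_loss: float = float("nan")

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError(f"client {self.client_id!r}: n_samples must be positive")


def aggregate_fedavg(updates: list[ClientUpdate]) -> ParameterSet:
    """Sample-size-weighted elementwise average of client parameters.

    Weights are ``n_k / sum_j n_j``; accumulation is in float64 and the
    result keeps the clients' dtype.  Fails on an empty list or on any
    name/shape mismatch, naming the first offending entry.
    """
    if not updates:
        raise ValueError("cannot aggregate an empty list of client updates")
    ref = updates[0].parameters
    total = float(sum(u.n_samples for u in updates))
    out: list[tuple[str, np.ndarray]] = []
    for i, (name, ref_arr) in enumerate(ref):
        acc = np.zeros(ref_arr.shape, dtype=np.float64)
        for u in updates:
            if i >= len(u.parameters.entries):
                raise ValueError(f"client {u.client_id!r}: missing parameter {name!r}")
            uname, arr = u.parameters.entries[i]
            if uname != name or arr.shape != ref_arr.shape:
                raise ValueError(
                    f"client {u.client_id!r}: parameter mismatch at {uname!r} "
                    f"{arr.shape}, expected {name!r} {ref_arr.shape}"
                )
            acc += (u.n_samples / total) * arr.astype(np.float64)
        out.append((name, acc.astype(ref_arr.dtype)))
    return ParameterSet(out)


def run_federated(
    clients: list[tuple[str, tuple, tuple]],
    model_cfg: ModelConfig,
    fed_cfg: FederatedConfig,
    server_eval: bool = True,
) -> tuple[ParameterSet, pd.DataFrame, pd.DataFrame]:
    """Run the synchronous FedAvg protocol.

    Parameters
    ----------
    clients : list of (client_id, (X_train, y_train), (X_val, y_val) or None)
        One entry per site; every client participates in every round.
    model_cfg : ModelConfig
        Architecture and initialisation seed of the global model.
    fed_cfg : FederatedConfig
        Round structure and the shared client training configuration.
    server_eval : bool
        After each round, evaluate the global model on the pooled client
        validation splits.

    Returns
    -------
    (global ParameterSet, round log, global metrics log)
        Round log rows: (round, client_id, train_loss, n_samples).  Global
        log rows: (round, val_loss, val_acc) on the pooled validation data.
    """
    if not clients:
        raise ValueError("at least one client is required")
    for cid, train, _ in clients:
        if len(train[0]) == 0:
            raise ValueError(f"client {cid!r} has an empty training set")

    model = Conv3DNet(model_cfg)
    global_params = model.get_parameters()
    # One shared client seed: identical clients then produce identical
    # updates, and a single-client run matches the centralized seed schedule.
    client_cfg = replace(
        fed_cfg.client_train_cfg, seed=fed_cfg.seed, epochs=fed_cfg.local_epochs
    )

    pooled_val = None
    if server_eval:
        vals = [v for _, _, v in clients if v is not None and len(v[0]) > 0]
        if vals:
            pooled_val = (
                np.concatenate([np.asarray(v[0]) for v in vals]),
                np.concatenate([np.asarray(v[1], dtype=int) for v in vals]),
            )

    round_rows, global_rows = [], []
    for r in range(fed_cfg.n_rounds):
        updates = []
        for cid, train, _val in clients:
            model.set_parameters(global_params)
            try:
                params, history = train_local(
                    model, train, None, client_cfg, epoch_offset=r * fed_cfg.local_epochs
                )
            except Exception as err:
                raise RuntimeError(f"round {r}: client {cid!r} failed: {err}") from err
            loss = float(history["train_loss"].iloc[-1]) if len(history) else float("nan")
            updates.append(
                ClientUpdate(
                    client_id=cid, parameters=params, n_samples=len(train[0]), train_loss=loss
                )
            )
            round_rows.append(
                {"round": r, "client_id": cid, "train_loss": loss, "n_samples": len(train[0])}
            )
        global_params = aggregate_fedavg(updates)

        if pooled_val is not None:
            model.set_parameters(global_params)
            xv, yv = pooled_val
            global_rows.append(
                {
                    "round": r,
                    "val_loss": model.cross_entropy(xv, yv),
                    "val_acc": float((model.predict_proba(xv).argmax(axis=1) == yv).mean()),
                }
            )

    round_log = pd.DataFrame(round_rows, columns=["round", "client_id", "train_loss", "n_samples"])
    global_log = pd.DataFrame(global_rows, columns=["round", "val_loss", "val_acc"])
    return global_params, round_log, global_log
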