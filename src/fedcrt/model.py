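"""Experiment-level modelling interface.

:class:`ResponseModel` is built from a cohort manifest plus an experiment
topology (which sites train, which site is the held-out external test set,
centralized vs federated mode); :meth:`ResponseModel.fit` runs the full
pipeline — preprocessing, splitting, training or federated simulation,
evaluation — and returns a :class:`ResponseResults` carrying the final
weights, per-epoch/per-round histories, and train/validation/test metric
reports with a ``summary()`` table.

Topology presets mirror the six reference experiments: DL1/DL2 are
centralized baselines pooling two hospitals, FL1/FL3 the matching two-client
federated runs, FL2/FL4 three-client federated runs including the shifted
fourth site; hospital C (or B) is always the untouched external test set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .federated import FederatedConfig, run_federated
from .metrics import MetricsReport, evaluate_scores, paired_auc_diff_ci
from .network import Conv3DNet, ModelConfig, ParameterSet, reduced_config
from .preprocess import DEFAULT_WINDOW, cohort_window, patches_from_manifest
from .training import (
    TrainConfig,
    centralized_config,
    federated_real_config,
    federated_sim_config,
    split_cohort,
    train_local,
)

__all__ = ["ExperimentPreset", "ResponseModel", "ResponseResults", "compare_runs", "PRESETS"]


@dataclass
class ExperimentPreset:
    """A named experiment topology over a multi-site cohort."""

    name: str
    train_sites: tuple[str, ...]
    test_site: str
    mode: str  # "centralized" | "federated"

    def __post_init__(self) -> None:
        if self.mode not in ("centralized", "federated"):
            raise ValueError("mode must be 'centralized' or 'federated'")
        if self.test_site in self.train_sites:
            raise ValueError(f"test site {self.test_site!r} overlaps the training sites")


PRESETS: dict[str, ExperimentPreset] = {
    "DL1": ExperimentPreset("DL1", ("A", "B"), "C", "centralized"),
    "FL1": ExperimentPreset("FL1", ("A", "B"), "C", "federated"),
    "FL2": ExperimentPreset("FL2", ("A", "B", "D"), "C", "federated"),
    "DL2": ExperimentPreset("DL2", ("A", "C"), "B", "centralized"),
    "FL3": ExperimentPreset("FL3", ("A", "C"), "B", "federated"),
    "FL4": ExperimentPreset("FL4", ("A", "C", "D"), "B", "federated"),
    # desk-scale analogues on the three-site synthetic cohort (test site "T")
    "DESK-DL": ExperimentPreset("DESK-DL", ("S1", "S2", "S3"), "T", "centralized"),
    "DESK-FL": ExperimentPreset("DESK-FL", ("S1", "S2", "S3"), "T", "federated"),
}


class ResponseModel:
    """Treatment-response classifier over a multi-site cohort manifest.

    Parameters
    ----------
    manifest : DataFrame
        Cohort manifest (patient_id, site_id, label, image/mask paths).
    preset : ExperimentPreset
        Training topology: train sites, held-out test site, mode.
    net_config, train_config, fed_config :
        Architecture and optimisation settings; ``fed_config`` is required
        in federated mode (its ``client_train_cfg`` is used per client).
    window : (lo, hi) or "cohort"
        Intensity normalisation window.  ``"cohort"`` derives the window
        from the training sites' volumes (phantom data); the default is the
        fixed CT window.
    """

    def __init__(
        self,
        manifest: pd.DataFrame,
        preset: ExperimentPreset,
        net_config: ModelConfig | None = None,
        train_config: TrainConfig | None = None,
        fed_config: FederatedConfig | None = None,
        window="cohort",
        split_ratio: float = 0.7,
        positive_label: int = 1,
        seed: int = 0,
    ):
        self.manifest = manifest.reset_index(drop=True)
        self.preset = preset
        self.net_config = net_config or ModelConfig()
        self.seed = int(seed)
        if preset.mode == "centralized":
            self.train_config = train_config or centralized_config(seed=self.seed)
            self.fed_config = None
        else:
            base = fed_config or FederatedConfig(
                client_train_cfg=(
                    federated_real_config() if len(preset.train_sites) >= 3 else federated_sim_config()
                )
            )
            self.fed_config = replace(base, seed=self.seed)
            self.train_config = self.fed_config.client_train_cfg
        self.window = window
        self.split_ratio = split_ratio
        self.positive_label = positive_label

        sites = set(self.manifest["site_id"])
        for s in (*preset.train_sites, preset.test_site):
            if s not in sites:
                raise ValueError(f"site {s!r} required by preset {preset.name!r} is not in the cohort")

    @classmethod
    def from_preset(cls, name: str, manifest: pd.DataFrame, **kw) -> "ResponseModel":
        if name not in PRESETS:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
        return cls(manifest, PRESETS[name], **kw)

    # ------------------------------------------------------------------

    def _site_rows(self, site: str) -> pd.DataFrame:
        return self.manifest[self.manifest["site_id"] == site]

    def _resolve_window(self) -> tuple[float, float]:
        if self.window == "cohort":
            train_rows = self.manifest[self.manifest["site_id"].isin(self.preset.train_sites)]
            return cohort_window(train_rows)
        if self.window is None:
            return DEFAULT_WINDOW
        return tuple(self.window)

    def fit(self) -> "ResponseResults":
        """Run the experiment end to end and return its results."""
        window = self._resolve_window()
        size = self.net_config.input_size

        # per-site stratified 7:3 splits (the test site is never split)
        splits = {
            s: split_cohort(self._site_rows(s), ratio=self.split_ratio, seed=self.seed)
            for s in self.preset.train_sites
        }
        train_ids = {s: set(sp.train_ids) for s, sp in splits.items()}
        test_rows = self._site_rows(self.preset.test_site)
        leak = set(test_rows["patient_id"]) & set().union(*train_ids.values())
        if leak:
            raise RuntimeError(f"data leakage: test patients also in training: {sorted(leak)[:5]}")

        def load(rows: pd.DataFrame):
            x, y, _, ids = patches_from_manifest(rows, size=size, window=window)
            return x, y, ids

        model = Conv3DNet(self.net_config)
        per_site = {}
        for s in self.preset.train_sites:
            rows = self._site_rows(s)
            tr = rows[rows["patient_id"].isin(train_ids[s])]
            va = rows[rows["patient_id"].isin(set(splits[s].val_ids))]
            per_site[s] = (load(tr), load(va))

        round_log = global_log = None
        if self.preset.mode == "centralized":
            xtr = np.concatenate([per_site[s][0][0] for s in self.preset.train_sites])
            ytr = np.concatenate([per_site[s][0][1] for s in self.preset.train_sites])
            xva = np.concatenate([per_site[s][1][0] for s in self.preset.train_sites])
            yva = np.concatenate([per_site[s][1][1] for s in self.preset.train_sites])
            params, history = train_local(model, (xtr, ytr), (xva, yva), self.train_config)
        else:
            clients = [
                (s, per_site[s][0][:2], per_site[s][1][:2]) for s in self.preset.train_sites
            ]
            params, round_log, global_log = run_federated(
                clients, self.net_config, self.fed_config
            )
            history = global_log.rename(columns={"round": "epoch"})
            xtr = np.concatenate([per_site[s][0][0] for s in self.preset.train_sites])
            ytr = np.concatenate([per_site[s][0][1] for s in self.preset.train_sites])
            xva = np.concatenate([per_site[s][1][0] for s in self.preset.train_sites])
            yva = np.concatenate([per_site[s][1][1] for s in self.preset.train_sites])

        model.set_parameters(params)
        xte, yte, te_ids = load(test_rows)

        def report(x, y, tag: str) -> MetricsReport:
            scores = model.predict_proba(x)[:, self.positive_label]
            return evaluate_scores(y, scores, positive_label=self.positive_label, seed=self.seed)

        # pooled reports; per-client reports for federated runs are kept too
        metrics = {
            "training": report(xtr, ytr, "training"),
            "validation": report(xva, yva, "validation"),
            "testing": report(xte, yte, "testing"),
        }
        per_client_metrics = None
        if self.preset.mode == "federated":
            per_client_metrics = {
                s: {
                    "training": report(*per_site[s][0][:2], "training"),
                    "validation": report(*per_site[s][1][:2], "validation"),
                }
                for s in self.preset.train_sites
            }

        test_scores = pd.DataFrame(
            {
                "patient_id": te_ids,
                "label": yte,
                "score": model.predict_proba(xte)[:, self.positive_label],
            }
        )
        return ResponseResults(
            model=self,
            params=params,
            history=history,
            round_log=round_log,
            metrics=metrics,
            per_client_metrics=per_client_metrics,
            test_scores=test_scores,
            window=window,
        )


@dataclass
class ResponseResults:
    """Fitted-experiment results: weights, histories, and metric reports."""

    model: ResponseModel
    params: ParameterSet
    history: pd.DataFrame
    round_log: pd.DataFrame | None
    metrics: dict[str, MetricsReport]
    per_client_metrics: dict | None
    test_scores: pd.DataFrame
    window: tuple[float, float]

    @property
    def name(self) -> str:
        return self.model.preset.name

    def to_frame(self) -> pd.DataFrame:
        """One row per split with Acc / AUC / Spe / Recall columns."""
        rows = []
        for split in ("training", "validation", "testing"):
            m = self.metrics[split]
            rows.append(
                {
                    "model": self.name,
                    "split": split,
                    "Acc": m.accuracy,
                    "AUC": m.auc,
                    "Spe": m.specificity,
                    "Recall": m.recall,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable report in the Training/Validation/Testing layout."""
        p = self.model.preset
        lines = [
            f"Experiment {p.name}: {p.mode}, train sites {'+'.join(p.train_sites)}, "
            f"external test site {p.test_site}",
            f"patch {self.model.net_config.input_size}^3, "
            f"{self.params.n_parameters()} parameters, window "
            f"[{self.window[0]:.1f}, {self.window[1]:.1f}]",
            "",
            f"{'split':<12}{'Acc':>8}{'AUC':>8}{'Spe':>8}{'Recall':>8}   AUC 95% CI",
        ]
        for split in ("training", "validation", "testing"):
            m = self.metrics[split]
            ci = f"({m.auc_ci[0]:.2f}, {m.auc_ci[1]:.2f})" if m.auc_ci else ""
            auc = f"{m.auc:.3f}" if m.auc is not None else "   --"
            lines.append(
                f"{split:<12}{m.accuracy:>8.3f}{auc:>8}{m.specificity:>8.3f}"
                f"{m.recall:>8.3f}   {ci}"
            )
        tm = self.metrics["testing"]
        lines += ["", "test confusion matrix [[TN, FP], [FN, TP]]:",
                  str(np.asarray(tm.confusion))]
        return "\n".join(lines)


def compare_runs(results: list[ResponseResults], n_boot: int = 2000, seed: int = 0):
    """Side-by-side comparison of runs sharing the same external test set.

    Returns ``(table, auc_diffs)``: the metric table with one row per
    (model, split), and for each pair of runs the test-AUC difference with a
    paired-bootstrap 95% interval (resampling test patients jointly).
    """
    if len(results) < 2:
        raise ValueError("need at least two runs to compare")
    test_sites = {r.model.preset.test_site for r in results}
    if len(test_sites) != 1:
        raise ValueError(f"runs have different test sites: {sorted(test_sites)}")
    ids0 = list(results[0].test_scores["patient_id"])
    for r in results[1:]:
        if list(r.test_scores["patient_id"]) != ids0:
            raise ValueError("runs score different test cohorts; cannot pair them")

    table = pd.concat([r.to_frame() for r in results], ignore_index=True)

    y = results[0].test_scores["label"].to_numpy()
    diffs = {}
    for i in range(len(results)):
        for j in range(i + 1, len(results)):
            si = results[i].test_scores["score"].to_numpy()
            sj = results[j].test_scores["score"].to_numpy()
            d0, ci = paired_auc_diff_ci(y, si, sj, n_boot=n_boot, seed=seed)
            diffs[(results[i].name, results[j].name)] = {"auc_diff": d0, "ci": ci}
    return table, diffs
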