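"""High-level Model/Results interface over the training pipeline.

`PrognosisCNN` is constructed from data (a slice manifest or the synthetic
generator) plus an architecture variant; ``fit()`` runs the training recipe
and returns a `PrognosisCNNResults` carrying the fitted weights, the
per-epoch history, test-set metrics and a ``summary()`` table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_io import SplitSpec, read_manifest, split_dataset
from .network import build_variant, count_parameters, save_checkpoint
from .synthetic import SynthConfig, generate_arrays
from .train_eval import (
    MetricsReport,
    TrainConfig,
    TrainHistory,
    evaluate,
    load_split_arrays,
    predict_log_probs,
    train_model,
)


class PrognosisCNN:
    """Binary prognosis classifier over labelled 2D slices.

    Parameters
    ----------
    data : dict
        Mapping split name -> (images, labels) with images (N,1,H,W) in
        [0,1] and labels 0 (favourable) / 1 (poor).
    variant : str
        Architecture variant (``full`` = all four CAAFE blocks).
    """

    def __init__(self, data: dict, variant: str = "full"):
        for split in ("train", "val", "test"):
            if split not in data:
                raise ValueError(f"data lacks the {split!r} split")
        self.data = data
        self.variant = variant

    @classmethod
    def from_manifest(cls, manifest: pd.DataFrame | str,
                      variant: str = "full") -> "PrognosisCNN":
        if isinstance(manifest, str):
            manifest = read_manifest(manifest)
        data = {s: load_split_arrays(manifest, s)
                for s in ("train", "val", "test")}
        return cls(data, variant=variant)

    @classmethod
    def from_synthetic(cls, cfg: SynthConfig | None = None,
                       split_spec: SplitSpec | None = None,
                       variant: str = "full") -> "PrognosisCNN":
        cfg = cfg or SynthConfig()
        split_spec = split_spec or SplitSpec(seed=cfg.seed)
        images, labels, pids = generate_arrays(cfg)
        frame = pd.DataFrame({
            "patient_id": pids,
            "slice_index": range(len(pids)),
            "label": np.where(labels == 1, "poor", "favourable"),
            "path": "",
            "split": "unassigned",
        })
        frame = split_dataset(frame, split_spec)
        data = {
            s: (images[(frame["split"] == s).to_numpy()],
                labels[(frame["split"] == s).to_numpy()])
            for s in ("train", "val", "test")
        }
        return cls(data, variant=variant)

    def fit(self, train_config: TrainConfig | None = None,
            seed: int = 0) -> "PrognosisCNNResults":
        cfg = train_config or TrainConfig(seed=seed)
        network = build_variant(self.variant, seed=seed)
        history = train_model(network, *self.data["train"],
                              *self.data["val"], cfg)
        test_report = evaluate(network, *self.data["test"], cfg.batch_size)
        return PrognosisCNNResults(self, network, cfg, history, test_report)


class PrognosisCNNResults:
    """Fitted classifier: weights, history, held-out metrics, summary."""

    def __init__(self, model: PrognosisCNN, network, train_config,
                 history: TrainHistory, test_report: MetricsReport):
        self.model = model
        self.network = network
        self.train_config = train_config
        self.history = history
        self.test_report = test_report
        self.n_parameters = count_parameters(network)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Class probabilities (N, 2) for [0,1] images of shape (N,1,H,W)."""
        return np.exp(predict_log_probs(self.network, images))

    def predict(self, images: np.ndarray) -> np.ndarray:
        return self.predict_proba(images).argmax(axis=1)

    def save(self, path) -> None:
        save_checkpoint(self.network, path,
                        extra={"variant": self.model.variant})

    def summary(self) -> str:
        r = self.test_report
        c = r.confusion
        lines = [
            "         Prognosis CNN fit summary",
            "=" * 46,
            f"{'Variant:':<28}{self.model.variant}",
            f"{'Trainable parameters:':<28}{self.n_parameters:,}",
            f"{'Epochs run:':<28}{len(self.history)}",
            f"{'Best epoch (val acc):':<28}{self.history.best_epoch}",
            f"{'Best val accuracy (%):':<28}"
            f"{self.history.best_val_accuracy:.2f}",
            "-" * 46,
            "Test-set metrics (positive = poor prognosis)",
            f"{'Accuracy (%):':<28}{r.accuracy:.2f}",
            f"{'Precision (%):':<28}{r.precision:.2f}",
            f"{'Recall (%):':<28}{r.recall:.2f}",
            f"{'F1 score (%):':<28}{r.f1:.2f}",
            f"{'AUC:':<28}"
            + ("n/a" if r.auc is None else f"{r.auc:.4f}"),
            f"{'Confusion TP/TN/FP/FN:':<28}"
            f"{c.tp}/{c.tn}/{c.fp}/{c.fn}",
            "=" * 46,
        ]
        return "\n".join(lines)
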