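"""High-level modelling interface.

``VirtualStainingModel`` is constructed from data (a list of paired fields
or a dataset manifest) plus configuration; ``fit()`` runs the selected
training regime and returns a ``VirtualStainingResults`` carrying the
fitted generator, the per-epoch validation history, the selected best
epoch and a ``summary()`` table — the estimate/uncertainty/diagnostics
bundle of this model family is the checkpoint plus its validation metrics.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import PairedField, load_field, preprocess
from .image_metrics import aggregate_reports, evaluate_field
from .model_zoo import GeneratorConfig, count_trainable_parameters
from .tiling import predict_field
from .trainer import TrainingConfig, TrainResult, train_cwgan, train_unet


class VirtualStainingModel:
    """Brightfield → Cell Painting translation model bound to a dataset."""

    def __init__(self, fields: list[PairedField],
                 config: TrainingConfig | None = None,
                 generator_config: GeneratorConfig | None = None,
                 preprocessed: bool = True):
        if not fields:
            raise ValueError("need at least one paired field")
        self.config = config or TrainingConfig()
        self.generator_config = generator_config or GeneratorConfig()
        self.fields = fields if preprocessed else [preprocess(f) for f in fields]

    @classmethod
    def from_manifest(cls, manifest: pd.DataFrame | str | Path,
                      config: TrainingConfig | None = None,
                      generator_config: GeneratorConfig | None = None) -> "VirtualStainingModel":
        if not isinstance(manifest, pd.DataFrame):
            manifest = pd.read_csv(manifest)
        fields = [preprocess(load_field(row)) for _, row in manifest.iterrows()]
        return cls(fields, config, generator_config, preprocessed=True)

    def fit(self, mode: str = "l1", init_state: dict | None = None,
            **overrides) -> "VirtualStainingResults":
        """Train with the chosen regime: 'l1' (U-Net) or 'cwgan' (adversarial)."""
        if mode == "l1":
            result = train_unet(self.fields, self.config,
                                generator_config=self.generator_config, **overrides)
        elif mode == "cwgan":
            result = train_cwgan(self.fields, self.config, init_state=init_state,
                                 generator_config=self.generator_config, **overrides)
        else:
            raise ValueError(f"unknown training mode {mode!r}; use 'l1' or 'cwgan'")
        return VirtualStainingResults(self, mode, result)


class VirtualStainingResults:
    """Fitted generator + validation history from one training run."""

    def __init__(self, model: VirtualStainingModel, mode: str, result: TrainResult):
        self.model = model
        self.mode = mode
        self.train_result = result
        self.generator = result.restore_best()
        self.history = result.history
        self.best_epoch = result.best_epoch if result.history else 0

    @property
    def params(self) -> dict:
        return self.train_result.best_state

    @property
    def n_parameters(self) -> int:
        return count_trainable_parameters(self.generator)

    def predict(self, field: PairedField, patch: int | None = None,
                stride: int | None = None) -> np.ndarray:
        """Tiled median-stitched prediction for one (preprocessed) field."""
        H, W = field.shape
        d = self.generator.config.size_divisor
        if patch is None and H % d == 0 and W % d == 0 and max(H, W) <= 512:
            return self.generator.predict(field.brightfield.astype(np.float32))
        patch = patch or min(256, H, W)
        return predict_field(self.generator, field, patch=patch,
                             stride=stride or patch // 2)

    def evaluate(self, fields: list[PairedField]) -> pd.DataFrame:
        """Mean ± sd of the five image metrics per channel over ``fields``."""
        reports = [evaluate_field(self.predict(f), f.fluorescent) for f in fields]
        return aggregate_reports(reports)

    def validation_curve(self) -> pd.DataFrame:
        rows = []
        for h in self.history:
            row = {"epoch": h["epoch"]}
            if h.get("train_l1") is not None:
                row["train_l1"] = h.get("train_l1")
            if h.get("val") is not None:
                row.update({f"val_{m}": v for m, v in h["val"].means.items()})
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"VirtualStainingModel results ({'U-Net / L1' if self.mode == 'l1' else 'cWGAN-GP'})",
            "=" * 58,
            f"fields: {len(self.model.fields)}   "
            f"trainable parameters: {self.n_parameters:,}",
            f"epochs run: {len(self.history)}   best epoch (mean val PCC): {self.best_epoch}",
        ]
        if self.history and self.history[-1].get("val") is not None:
            best = self.history[self.best_epoch - 1]["val"]
            lines.append("")
            lines.append("validation metrics at best epoch (per channel):")
            lines.append(best.per_channel.round(4).to_string())
            lines.append("")
            lines.append("channel means: " +
                         "  ".join(f"{m}={v:.4f}" for m, v in best.means.items()))
        return "\n".join(lines)
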