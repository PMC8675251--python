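"""Model/Results front-end over the training and evaluation pipeline.

``MeniscusTearModel`` is constructed from a labelled cohort (phantoms, or any
samples exposing ``image``, ``mask``, ``labels``, ``boxes``, ``sample_id``)
plus a training configuration; ``fit()`` runs the full pipeline —
preprocessing, augmentation, optimisation, best-validation selection — and
returns a ``TearDetectionResults`` carrying the checkpoint, the held-out
diagnostics (per-sub-region AUCs, aggregated AUCs, box quality) and a
``summary()`` table.  Prediction and saliency mapping hang off the results
object.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluate import evaluate_checkpoint, predict
from .phantom import SUBREGION_NAMES
from .preprocess import minmax_normalize, standardize
from .saliency import SaliencyConfig, smoothgrad
from .train import (TrainConfig, load_checkpoint, model_from_checkpoint,
                    prepare_sample, save_checkpoint, train_model)

__all__ = ["MeniscusTearModel", "TearDetectionResults"]


class MeniscusTearModel:
    """Sub-region meniscal tear detector fitted to a labelled cohort.

    Parameters
    ----------
    samples : list of PhantomSample
        The cohort; ground-truth masks are required for training targets.
    manifest : DataFrame
        One row per sample (id, six labels, twelve box values).
    approach : {"full_scale", "bb_crop", "bb_loss"}
        Whole-volume classification, RoI-cropped classification, or the
        multi-task variant with an auxiliary bounding-box regression head.
    config : TrainConfig, optional
        Full hyper-parameter control; `approach` is taken from it if given.
    """

    def __init__(self, samples, manifest: pd.DataFrame,
                 approach: str = "bb_loss", config: TrainConfig | None = None):
        if config is None:
            config = TrainConfig(approach=approach)
        elif config.approach != approach and approach != "bb_loss":
            config.approach = approach
        self.samples = list(samples)
        self.manifest = manifest
        self.config = config

    @classmethod
    def from_cohort(cls, cohort: tuple, **kwargs) -> "MeniscusTearModel":
        """Build from the ``(samples, manifest)`` pair of generate_cohort."""
        samples, manifest = cohort
        return cls(samples, manifest, **kwargs)

    def fit(self, split=None) -> "TearDetectionResults":
        """Train, select the best-validation epoch, evaluate on held-out data."""
        checkpoint = train_model(self.config, self.samples, self.manifest,
                                 split=split)
        by_id = {s.sample_id: s for s in self.samples}
        test = [by_id[sid] for sid in checkpoint["split"]["test"]]
        report = evaluate_checkpoint(checkpoint, test) if test else None
        return TearDetectionResults(self, checkpoint, report)


class TearDetectionResults:
    """Fitted detector: checkpoint, held-out diagnostics, prediction API."""

    def __init__(self, model: MeniscusTearModel, checkpoint: dict, report: dict | None):
        self.model = model
        self.checkpoint = checkpoint
        self.report = report
        self.log: pd.DataFrame = checkpoint["log"]
        self.best_epoch: int = checkpoint["best_epoch"]

    # -- diagnostics ---------------------------------------------------------
    @property
    def aucs(self) -> pd.Series:
        """Held-out AUC per sub-region."""
        if self.report is None:
            raise ValueError("no held-out test split was evaluated")
        return pd.Series(self.report["auc"], name="auc")

    @property
    def aggregated_aucs(self) -> pd.Series:
        if self.report is None:
            raise ValueError("no held-out test split was evaluated")
        return pd.Series(self.report["aggregated_auc"], name="auc")

    @property
    def box_quality(self) -> dict | None:
        return None if self.report is None else self.report.get("box_quality")

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Meniscal tear detection results",
            "=" * 47,
            f"approach:            {cfg.approach}",
            f"encoder width:       {cfg.width_multiplier}",
            f"cohort size:         {len(self.model.samples)}",
            f"best epoch:          {self.best_epoch}"
            f"  (val loss {self.checkpoint['best_val_loss']:.4f})",
        ]
        if self.report is not None:
            lines.append(f"test volumes:        {self.report['n_test']}")
            lines.append("-" * 47)
            lines.append("held-out AUC per sub-region:")
            for name in SUBREGION_NAMES:
                lines.append(f"  {name:<8} {self.report['auc'][name]:.3f}")
            lines.append("aggregated (max rule):")
            for key, val in self.report["aggregated_auc"].items():
                lines.append(f"  {key:<12} {val:.3f}")
            bq = self.report.get("box_quality")
            if bq:
                lines.append("-" * 47)
                lines.append("bounding-box quality (pooled menisci):")
                lines.append(f"  mean IoU  {bq['mean_iou']:.3f}"
                             f"  (95% CI {bq['ci95_low']:.3f}-{bq['ci95_high']:.3f},"
                             f" sd {bq['sd_iou']:.3f})")
                lines.append(f"  IoU > 0.5 success rate  {bq['success_rate']:.1%}")
        return "\n".join(lines)

    # -- prediction & explanation -------------------------------------------
    def predict(self, samples):
        """Tear probabilities (N, 6) and, for bb_loss, predicted box pairs."""
        return predict(self.checkpoint, samples)

    def saliency_map(self, sample, target_subregion: int,
                     cfg: SaliencyConfig | None = None, seed: int = 0):
        """SmoothGrad saliency volume for one sample, on the network grid.

        Returns ``(saliency, prepared input volume)``.
        """
        img = standardize(minmax_normalize(sample.image), self.checkpoint["stats"])
        prepared, _, _ = prepare_sample(img, sample.mask, sample.labels,
                                        self.model.config,
                                        self.checkpoint["crop_shape"])
        net = model_from_checkpoint(self.checkpoint)
        if cfg is None:
            cfg = SaliencyConfig()
        rng = np.random.default_rng(seed)
        smap = smoothgrad(net, prepared, cfg, rng,
                          target_subregion=target_subregion)
        return smap, prepared

    def save(self, path):
        return save_checkpoint(self.checkpoint, path)

    @classmethod
    def from_file(cls, path, samples=None, manifest=None) -> "TearDetectionResults":
        ckpt = load_checkpoint(path)
        model = MeniscusTearModel(samples or [], manifest,
                                  approach=ckpt["config"].approach,
                                  config=ckpt["config"])
        return cls(model, ckpt, None)
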