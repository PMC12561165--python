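"""End-to-end orchestration: simulate -> preprocess -> balance -> transform ->
split -> train -> evaluate (-> explain, genqc).

Class balancing runs strictly before the split is finalized, and synthetic
beats are pinned to the training partition, so generated data can never leak
into evaluation.  A run directory always receives a copy of the exact config
used plus per-stage counts in the log.
"""
from __future__ import annotations

import json
import logging
import os

import numpy as np

from . import ddpm as ddpm_mod
from . import train as train_mod
from .config import RunConfig
from .explain import grad_cam, overlay
from .genmetrics import quality_report
from .io import CLASSES, save_beats
from .model import RTCN, RtcnConfig
from .preprocess import DenoiseConfig, record_to_beats
from .stransform import TimeFreqImage, transform_beat, to_model_input
from .synth import generate_class_dataset

log = logging.getLogger(__name__)

LABEL_TO_INDEX = {label: i for i, label in enumerate(CLASSES)}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage, cause):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def beats_to_images(beats, cfg: RunConfig, sampling_rate_hz: float = 1000.0):
    tf = cfg.transform
    images = np.empty((len(beats), 3, tf.side, tf.side))
    for i, b in enumerate(beats):
        img = transform_beat(b.samples, sampling_rate_hz, method=tf.method,
                             f_max_hz=tf.f_max_hz)
        images[i] = to_model_input(img, side=tf.side)
    labels = np.array([LABEL_TO_INDEX[b.label] for b in beats], dtype=int)
    return images, labels


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the full pipeline; returns the metrics payload.

    Artifacts written to ``out_dir``: config.yaml, beats.npz, balanced.npz,
    curves.csv, metrics.json (and optional explain figure / genqc report).
    """
    os.makedirs(out_dir, exist_ok=True)
    config.to_yaml(os.path.join(out_dir, "config.yaml"))

    stage = "simulate"
    try:
        counts = config.data.records_per_class
        if isinstance(counts, int):
            counts = {c: counts for c in CLASSES}
        records = generate_class_dataset(
            counts,
            spec_overrides={
                "duration_s": config.data.duration_s,
                "heart_rate_bpm": config.data.heart_rate_bpm,
                "hr_jitter_frac": config.data.hr_jitter_frac,
                "noise": {
                    "baseline_amp_mv": config.data.baseline_amp_mv,
                    "powerline_amp_mv": config.data.powerline_amp_mv,
                    "white_sigma_mv": config.data.white_sigma_mv,
                },
            },
            seed=config.stage_seed(stage),
        )
        log.info("simulate: %d records", len(records))

        stage = "preprocess"
        dn = DenoiseConfig(wavelet=config.preprocess.wavelet,
                           n_levels=config.preprocess.n_levels)
        beats = []
        for rec in records:
            beats.extend(record_to_beats(rec, lead=config.preprocess.lead, config=dn))
        if not beats:
            raise ValueError("no beats segmented")
        save_beats(beats, os.path.join(out_dir, "beats.npz"))
        log.info("preprocess: %d beats from %d records", len(beats), len(records))

        stage = "balance"
        if config.ddpm.enabled:
            schedule = ddpm_mod.make_schedule(config.ddpm.T, config.ddpm.beta_start,
                                              config.ddpm.beta_end)
            plan = ddpm_mod.make_balance_plan(
                beats, target=config.ddpm.target_per_class,
                seed=config.stage_seed("balance"))
            by_class: dict = {}
            for b in beats:
                by_class.setdefault(b.label, []).append(b)
            models = {}
            tcfg = ddpm_mod.DdpmTrainConfig(
                steps=config.ddpm.train_steps, batch_size=config.ddpm.batch_size,
                lr=config.ddpm.lr, hidden=config.ddpm.hidden)
            for label, group in by_class.items():
                if plan.targets[label] > len(group):
                    models[label], _ = ddpm_mod.train_denoiser(
                        group, schedule, tcfg,
                        seed=config.stage_seed(f"ddpm-{label}"))
            beats = ddpm_mod.balance_dataset(beats, plan, models, schedule)
            save_beats(beats, os.path.join(out_dir, "balanced.npz"))
            log.info("balance: %d beats after balancing (%d synthetic)",
                     len(beats), sum(b.source == "synthetic" for b in beats))

        stage = "split"
        spec = train_mod.SplitSpec(config.split.paradigm,
                                   config.split.train_fraction,
                                   seed=config.stage_seed(stage))
        train_beats, test_beats = train_mod.split_dataset(beats, spec)
        log.info("split: %d train / %d test beats", len(train_beats), len(test_beats))

        stage = "transform"
        xtr, ytr = beats_to_images(train_beats, config)
        xte, yte = beats_to_images(test_beats, config)

        stage = "train"
        mc = config.model
        model = RTCN(RtcnConfig(
            input_side=config.transform.side, width_divisor=mc.width_divisor,
            compressed_dim=mc.compressed_dim, n_heads=mc.n_heads,
            n_encoder_layers=mc.n_encoder_layers, dropout=mc.dropout,
            variant=mc.variant, vit_patch=mc.vit_patch,
            seed=config.stage_seed("model-init")))
        tcfg = train_mod.TrainConfig(
            lr=config.train.lr, momentum=config.train.momentum,
            batch_size=config.train.batch_size, epochs=config.train.epochs,
            val_fraction=config.train.val_fraction, seed=config.stage_seed(stage))
        model, curves = train_mod.train_model(model, xtr, ytr, tcfg)
        _write_curves(curves, os.path.join(out_dir, "curves.csv"))

        stage = "evaluate"
        cm = train_mod.evaluate(model, xte, yte)
        report = train_mod.compute_metrics(cm)
        payload = {
            "acc_total_pct": report.acc_total,
            "macro": report.macro,
            "per_class": report.per_class,
            "confusion_matrix": cm.matrix.tolist(),
            "n_train": len(train_beats),
            "n_test": len(test_beats),
        }
        with open(os.path.join(out_dir, "metrics.json"), "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True, allow_nan=True)

        if config.explain_enabled and len(xte):
            stage = "explain"
            hm = grad_cam(model, xte[0], int(yte[0]), layer="conv5")
            base = transform_beat(test_beats[0].samples, 1000.0,
                                  method=config.transform.method,
                                  f_max_hz=config.transform.f_max_hz)
            overlay(hm, base, os.path.join(out_dir, "gradcam.png"))

        if config.genqc_enabled and config.ddpm.enabled:
            stage = "genqc"
            real = [b for b in beats if b.source == "real"]
            synth = [b for b in beats if b.source == "synthetic"]
            if synth:
                qc = quality_report(real, synth,
                                    seed=config.stage_seed(stage))
                with open(os.path.join(out_dir, "genqc.json"), "w") as fh:
                    json.dump(qc.per_class, fh, indent=2, sort_keys=True)
        return payload
    except Exception as exc:  # surface the failing stage
        raise StageError(stage, exc) from exc


def _write_curves(curves, path):
    rows = ["epoch,train_loss,train_acc,val_loss,val_acc"]
    for i in range(len(curves.train_loss)):
        vl = curves.val_loss[i] if i < len(curves.val_loss) else ""
        va = curves.val_acc[i] if i < len(curves.val_acc) else ""
        rows.append(f"{i},{curves.train_loss[i]},{curves.train_acc[i]},{vl},{va}")
    with open(path, "w") as fh:
        fh.write("\n".join(rows) + "\n")
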