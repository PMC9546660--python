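"""End-to-end orchestration: normalize → extract → select → train → evaluate.

The pipeline runs one or two normalization conditions (with/without Reinhard
stain transfer against a template), featurizes the images through the
configured backbone, optionally performs BPSO feature selection on the
training partition, and trains/evaluates the configured classifier across
``runs`` independently seeded repetitions.  The report carries per-run
metrics, aggregate means, the before/after-selection accuracy delta, and a
Welch t-test comparing conditions.

Configuration is a strictly validated schema (unknown keys rejected);
:func:`parse_and_validate` accepts YAML/JSON files or plain dicts and echoes
the fully-defaulted config for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import bpso as _bpso
from . import classify as _classify
from . import features as _features
from . import stain_norm as _stain
from . import synth as _synth
from .datasets import FeatureDataset

__all__ = ["PipelineConfig", "parse_and_validate", "run_pipeline", "ConfigurationError"]

log = logging.getLogger("oralcad")


class ConfigurationError(ValueError):
    """Invalid or unknown pipeline configuration."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class NormalizeConfig(_Strict):
    enabled: bool = True
    #: template image: a path, or "first" for the first manifest entry
    template: str = "first"
    compare: bool = False  # run both with- and without-normalization conditions


class BackboneConfig(_Strict):
    name: Literal["vgg16", "alexnet", "resnet50", "inceptionv3", "stub"] = "stub"
    seed: int = 0
    feature_dim: int | None = None  # override (stub only)


class SelectionConfig(_Strict):
    enabled: bool = False
    swarm_size: int = 20
    max_iter: int = 100
    c1: float = 2.0
    c2: float = 2.0
    w_start: float = 0.9
    w_end: float = 0.4
    v_max: float = 6.0
    knn_k: int = 5
    per_run: bool = False  # re-run BPSO in every repetition (slower)


class ClassifierConfig(_Strict):
    kind: Literal["xgboost", "random_forest", "ann"] = "xgboost"
    params: dict = Field(default_factory=dict)


class SplitConfig(_Strict):
    train_fraction: float = 0.8
    cv_folds: int = 10

    @field_validator("train_fraction")
    @classmethod
    def _frac(cls, v: float) -> float:
        if not 0 < v < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        return v


class SynthConfig(_Strict):
    n_per_class: int = 20
    image_size: tuple[int, int] = (64, 64)
    color_jitter: float = 0.0


class PipelineConfig(_Strict):
    """Validated, fully-defaulted configuration for :func:`run_pipeline`."""

    seed: int = 0
    runs: int = 1
    normalize: NormalizeConfig = Field(default_factory=NormalizeConfig)
    backbone: BackboneConfig = Field(default_factory=BackboneConfig)
    selection: SelectionConfig = Field(default_factory=SelectionConfig)
    classifier: ClassifierConfig = Field(default_factory=ClassifierConfig)
    split: SplitConfig = Field(default_factory=SplitConfig)
    synth: SynthConfig | None = None


def parse_and_validate(source, echo_dir: str | Path | None = None) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML/JSON path or a dict.

    Unknown keys are rejected with the offending key named.  When
    ``echo_dir`` is given the fully-defaulted config is written there as
    ``config_echo.yaml`` for provenance.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    elif isinstance(source, dict):
        raw = source
    elif isinstance(source, PipelineConfig):
        raw = source.model_dump()
    else:
        raise ConfigurationError(f"unsupported config source {type(source)!r}")
    try:
        cfg = PipelineConfig.model_validate(raw)
    except Exception as exc:  # pydantic ValidationError carries the key name
        raise ConfigurationError(str(exc)) from exc
    if echo_dir is not None:
        echo_dir = Path(echo_dir)
        echo_dir.mkdir(parents=True, exist_ok=True)
        with open(echo_dir / "config_echo.yaml", "w") as fh:
            yaml.safe_dump(cfg.model_dump(mode="json"), fh, sort_keys=False)
    return cfg


def _load_images(manifest_path: str | Path, root: str | Path | None):
    from PIL import Image

    df = _features.load_manifest(manifest_path)
    base = Path(root) if root is not None else Path(manifest_path).parent
    images = []
    for p in df["path"]:
        full = Path(p) if Path(p).is_absolute() else base / p
        images.append(np.asarray(Image.open(full).convert("RGB")))
    return images, df["label"].to_numpy(), df


def _make_backbone(cfg: PipelineConfig) -> tuple[_features.Backbone, _features.BackboneSpec]:
    spec = _features.BACKBONE_SPECS[cfg.backbone.name]
    if cfg.backbone.name != "stub":
        raise ConfigurationError(
            f"backbone {cfg.backbone.name!r} requires a pretrained-network "
            "adapter; pass a custom backbone to run_pipeline or use 'stub'"
        )
    if cfg.backbone.feature_dim is not None:
        spec = dataclasses.replace(spec, feature_dim=cfg.backbone.feature_dim)
    return _features.stub_backbone(spec, seed=cfg.backbone.seed), spec


def _evaluate_runs(
    ds: FeatureDataset, cfg: PipelineConfig
) -> dict:
    """Train/evaluate across runs; optionally with BPSO-selected features."""
    runs = []
    sel_result = None
    for r in range(cfg.runs):
        run_seed = cfg.seed + r
        plan = _classify.SplitPlan(
            train_fraction=cfg.split.train_fraction,
            cv_folds=cfg.split.cv_folds,
            seed=run_seed,
        )
        train, test = _classify.split_data(ds, plan)
        train, test = _features.standardize_features(train, test)

        entry = {"seed": run_seed}
        model = _classify.train_classifier(
            train, cfg.classifier.kind, cfg.classifier.params, seed=run_seed
        )
        counts = _classify.evaluate(model, test)
        entry["all_features"] = _report_metrics(counts)

        if cfg.selection.enabled:
            if sel_result is None or cfg.selection.per_run:
                sel_cfg = _bpso.BpsoConfig(
                    swarm_size=cfg.selection.swarm_size,
                    max_iter=cfg.selection.max_iter,
                    c1=cfg.selection.c1,
                    c2=cfg.selection.c2,
                    w_start=cfg.selection.w_start,
                    w_end=cfg.selection.w_end,
                    v_max=cfg.selection.v_max,
                    knn_k=cfg.selection.knn_k,
                    seed=run_seed,
                )
                t0 = time.perf_counter()
                sel_result = _bpso.bpso_select(train, sel_cfg)
                log.info(
                    "BPSO selected %d/%d features (fitness %.4f) in %.1fs",
                    sel_result.n_selected,
                    ds.n_features,
                    sel_result.gbest_fitness,
                    time.perf_counter() - t0,
                )
            mask = sel_result.gbest_mask
            model_sel = _classify.train_classifier(
                train.subset_columns(mask),
                cfg.classifier.kind,
                cfg.classifier.params,
                seed=run_seed,
            )
            counts_sel = _classify.evaluate(model_sel, test.subset_columns(mask))
            entry["selected_features"] = _report_metrics(counts_sel)
            entry["n_selected"] = int(mask.sum())
            entry["delta_accuracy"] = (
                entry["selected_features"]["accuracy"]
                - entry["all_features"]["accuracy"]
            )
        runs.append(entry)

    out = {"runs": runs}
    for key in ("all_features", "selected_features"):
        accs = [r[key]["accuracy"] for r in runs if key in r]
        if accs:
            out[f"mean_accuracy_{key}"] = float(np.mean(accs))
    if cfg.selection.enabled:
        out["delta_accuracy_mean"] = (
            out["mean_accuracy_selected_features"] - out["mean_accuracy_all_features"]
        )
    return out


def _report_metrics(counts: _classify.ConfusionCounts) -> dict:
    m = _classify.compute_metrics(counts)
    return {
        "TP": counts.TP,
        "TN": counts.TN,
        "FP": counts.FP,
        "FN": counts.FN,
        "sensitivity": m.sensitivity,
        "precision": m.precision,
        "accuracy": m.accuracy,
    }


def run_pipeline(
    config,
    manifest: str | Path | None = None,
    images: list[np.ndarray] | None = None,
    labels: np.ndarray | None = None,
    backbone: _features.Backbone | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Execute the full pipeline and return a JSON-serializable report.

    Inputs are either a ``path,label`` manifest, in-memory ``images`` +
    ``labels``, or (if both are absent and ``config.synth`` is set) a
    generated synthetic image set.  When ``normalize.compare`` is on, both
    normalization conditions are evaluated and compared with a Welch t-test
    on per-run accuracies.
    """
    cfg = parse_and_validate(config, echo_dir=out_dir)

    if images is None and manifest is not None:
        images, labels, _ = _load_images(manifest, None)
    elif images is None:
        if cfg.synth is None:
            raise ConfigurationError("no manifest, images or synth config given")
        spec = _synth.ImageFixtureSpec(
            n_per_class=cfg.synth.n_per_class,
            image_size=tuple(cfg.synth.image_size),
            color_jitter=cfg.synth.color_jitter,
            seed=cfg.seed,
        )
        images, labels, _ = _synth.make_image_fixture(spec)
    if labels is None:
        raise ConfigurationError("labels are required with in-memory images")

    if backbone is None:
        backbone, spec = _make_backbone(cfg)
    else:
        spec = _features.BACKBONE_SPECS.get(
            cfg.backbone.name, _features.BACKBONE_SPECS["stub"]
        )

    conditions: list[str] = (
        ["normalized", "unnormalized"]
        if cfg.normalize.compare
        else (["normalized"] if cfg.normalize.enabled else ["unnormalized"])
    )

    template = None
    if "normalized" in conditions:
        if cfg.normalize.template == "first":
            template = images[0]
        else:
            from PIL import Image

            template = np.asarray(
                Image.open(cfg.normalize.template).convert("RGB")
            )

    report: dict = {"config": cfg.model_dump(mode="json"), "conditions": {}}
    for cond in conditions:
        t0 = time.perf_counter()
        imgs = images
        if cond == "normalized":
            imgs = [_stain.reinhard_normalize(im, template) for im in images]
        resized = [_features.resize_for_backbone(im, spec) for im in imgs]
        ds = _features.extract_features(resized, backbone, labels=labels)
        log.info("condition %s: extracted %dx%d features in %.1fs",
                 cond, ds.n_samples, ds.n_features, time.perf_counter() - t0)
        report["conditions"][cond] = _evaluate_runs(ds, cfg)

    if len(conditions) == 2:
        acc_n = [r["all_features"]["accuracy"]
                 for r in report["conditions"]["normalized"]["runs"]]
        acc_u = [r["all_features"]["accuracy"]
                 for r in report["conditions"]["unnormalized"]["runs"]]
        comp = {
            "mean_accuracy_normalized": float(np.mean(acc_n)),
            "mean_accuracy_unnormalized": float(np.mean(acc_u)),
        }
        if len(acc_n) >= 2:
            t, p = _classify.compare_runs(acc_n, acc_u)
            comp.update({"t_statistic": t, "p_value": p})
        report["normalization_comparison"] = comp

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report
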