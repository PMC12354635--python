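"""End-to-end pipeline: generate -> train -> evaluate -> LC50."""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from pathlib import Path

from . import dose_response as dr
from .classifier import BackboneSpec, train_three_phase
from .config import RunConfig
from .phenotypes import PhenotypeClass
from .synthetic import (
    DoseResponseTable,
    generate_dataset,
    generate_dose_response,
    write_image_dataset,
)

logger = logging.getLogger("danioscope")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-labelled and re-raised
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return result

        return inner

    return wrap


def run_pipeline(cfg: RunConfig, run_dir: str | Path | None = None) -> Path:
    """Execute all stages under a timestamped run directory.

    The resolved configuration is echoed verbatim into the run directory, so
    the directory plus the master seed fully determine every deterministic
    artifact.  Returns the run directory path.
    """
    if run_dir is None:
        stamp = datetime.datetime.now().strftime("%Y%m%d-%H%M%S")
        run_dir = Path(cfg.out_dir) / f"run-{stamp}"
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(run_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        cfg.to_yaml(run_dir / "config.yaml")
        backbone = BackboneSpec(name=cfg.backbone)
        size = cfg.image_size or backbone.input_size

        external, own, test = _generate_images(cfg, run_dir, size)
        model = _train(cfg, backbone, external, own)
        model.save(run_dir / "model")
        _evaluate(cfg, model, test, run_dir)
        _lc50(cfg, run_dir)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return run_dir


@_stage("generate")
def _generate_images(cfg: RunConfig, run_dir: Path, size: int):
    counts = {cls: cfg.images_per_class for cls in PhenotypeClass}
    test_counts = {cls: cfg.test_images_per_class for cls in PhenotypeClass}
    external = generate_dataset(counts, image_size=size, seed=cfg.master_seed)
    own = generate_dataset(counts, image_size=size, seed=cfg.master_seed + 1)
    test = generate_dataset(test_counts, image_size=size, seed=cfg.master_seed + 2)
    data_dir = run_dir / "data"
    manifest = {}
    for name, images in (("external", external), ("own", own), ("test", test)):
        paths = write_image_dataset(images, data_dir / name)
        manifest[name] = [str(p.relative_to(run_dir)) for p in paths]
    (run_dir / "split_manifest.json").write_text(json.dumps(manifest, indent=2))
    return external, own, test


@_stage("train")
def _train(cfg: RunConfig, backbone: BackboneSpec, external, own):
    model = train_three_phase(
        backbone,
        external,
        own,
        seed=cfg.master_seed,
        phase_overrides=cfg.phase_overrides,
        augment=cfg.augmentation,
        red_boost=cfg.red_boost,
    )
    for phase, history in model.histories.items():
        logger.info("%s: %d epochs, final val_acc=%.3f", phase, len(history), history[-1]["val_accuracy"])
    return model


@_stage("evaluate")
def _evaluate(cfg: RunConfig, model, test, run_dir: Path):
    from .evaluation import evaluate_model

    reports = evaluate_model(model, test, ks=cfg.evaluation_ks)
    for k, report in reports.items():
        report.save(run_dir / f"report_top{k}")
        logger.info("top-%d accuracy: %.3f", k, report.accuracy)
    return reports


@_stage("lc50")
def _lc50(cfg: RunConfig, run_dir: Path):
    if cfg.dose_response_csv:
        table = DoseResponseTable.from_csv(cfg.dose_response_csv)
    else:
        table = generate_dose_response(
            cfg.lc50_true,
            cfg.slope_true,
            cfg.concentrations,
            cfg.n_per_dose,
            seed=cfg.master_seed,
        )
    table.to_csv(run_dir / "dose_response.csv")
    lc50, fit = dr.estimate_lc50(table)
    fit.save(run_dir / "lc50.json")
    dr.plot_fit(table, fit, run_dir / "lc50.png")
    logger.info("LC50 = %.4g mg/mL (r^2 = %.3f)", lc50, fit.r_squared)
    return lc50
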