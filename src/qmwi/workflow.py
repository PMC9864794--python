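"""End-to-end runs: configuration, logging, persistence, external prediction.

A :class:`RunConfig` captures everything needed to reproduce an experiment —
scene family, grid, measurement geometry, class binning, network and training
hyperparameters, fold count and seed — and round-trips losslessly through
YAML.  :func:`run_pipeline` executes dataset build → cross-validation →
prediction → metric report, logging parameters at every stage;
:func:`predict_external` applies a trained model to scattered-field data from
outside the pipeline (e.g. a parsed Fresnel-style file) after OSM
pre-processing with the homogeneous-background Green's table.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .geometry import ImagingGrid, MeasurementConfig, circular_config
from .metrics import evaluate_folds, format_report
from .nn import (
    NetworkSpec,
    TrainingConfig,
    UNet,
    predict,
    run_cross_validation,
)
from .osm import analytic_green_table, compute_indicator_stack
from .synth import (
    ClassBinning,
    CorpusSetup,
    Dataset,
    build_brain_dataset,
    build_cylinder_dataset,
    dataset_manifest,
    easy_corpus_setup,
    load_dataset,
    save_dataset,
)

log = logging.getLogger("qmwi")


@dataclass
class RunConfig:
    """Complete, serializable description of one experiment run."""

    family: str = "easy-cylinders"  # cylinders | brain | easy-cylinders
    n_samples: int = 40
    n_folds: int = 2
    seed: int = 0
    output_dir: str = "runs/default"
    # geometry (ignored for presets that carry their own)
    grid_n: int = 32
    grid_side: float = 0.25
    n_tx: int = 8
    n_rx: int = 64
    ring_radius: float = 1.67
    frequencies_ghz: tuple[float, ...] = (2.0, 3.0, 4.0, 5.0)
    binning_edges: tuple[float, ...] = (0.0, 0.85, 1.6, 2.5)
    # network / training
    depth: int = 2
    base_channels: int = 16
    learning_rate: float = 1e-3
    batch_size: int = 16
    epochs: int = 60
    validation_fraction: float = 0.1

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["frequencies_ghz"] = list(self.frequencies_ghz)
        d["binning_edges"] = list(self.binning_edges)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("frequencies_ghz", "binning_edges"):
            if key in d:
                d[key] = tuple(float(v) for v in d[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    # -- derived objects ----------------------------------------------------
    def build_geometry(self) -> tuple[ImagingGrid, MeasurementConfig, CorpusSetup | None]:
        if self.family == "easy-cylinders":
            return (*easy_corpus_setup(),)
        grid = ImagingGrid(self.grid_n, self.grid_n, self.grid_side)
        cfg = circular_config(
            self.n_tx, self.n_rx, self.ring_radius,
            [f * 1e9 for f in self.frequencies_ghz],
        )
        if self.family == "cylinders":
            return grid, cfg, CorpusSetup(binning=ClassBinning(self.binning_edges))
        return grid, cfg, None

    def network_spec(self, n_freq: int, n_classes: int, side: int) -> NetworkSpec:
        return NetworkSpec(
            n_freq, n_classes, side, depth=self.depth,
            base_channels=self.base_channels, preset="reduced",
        )

    def training_config(self) -> TrainingConfig:
        return TrainingConfig(
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            epochs=self.epochs,
            seed=self.seed,
            validation_fraction=self.validation_fraction,
        )


def build_run_dataset(cfg: RunConfig) -> Dataset:
    grid, mcfg, setup = cfg.build_geometry()
    if cfg.family in ("cylinders", "easy-cylinders"):
        return build_cylinder_dataset(cfg.n_samples, cfg.seed, grid, mcfg, setup)
    if cfg.family == "brain":
        return build_brain_dataset(cfg.n_samples, cfg.seed, grid=grid, config=mcfg)
    raise ValueError(f"unknown family {cfg.family!r}")


def run_pipeline(cfg: RunConfig, dataset: Dataset | None = None) -> dict:
    """Execute the full experiment; returns paths and the metrics report."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("run config: %s", cfg.to_dict())
        cfg.save(out / "config.yaml")

        if dataset is None:
            ds_path = out / "dataset.h5"
            if ds_path.exists():
                log.info("loading existing dataset %s", ds_path)
                dataset = load_dataset(ds_path)
            else:
                log.info("building %s dataset with %d samples, seed %d",
                         cfg.family, cfg.n_samples, cfg.seed)
                dataset = build_run_dataset(cfg)
                save_dataset(dataset, ds_path)
            dataset_manifest(dataset).to_csv(out / "manifest.csv", index=False)

        x, t = dataset.inputs(), dataset.targets()
        spec = cfg.network_spec(x.shape[1], dataset.binning.n_classes, x.shape[-1])
        log.info("network %s: %d levels, base %d", spec.preset, spec.depth, spec.base_channels)
        result = run_cross_validation(
            x, t, spec, cfg.training_config(), n_folds=cfg.n_folds, seed=cfg.seed
        )
        models_dir = out / "models"
        for fi, net in enumerate(result.models):
            net.save(models_dir / f"fold_{fi}.npz")
            np.savetxt(
                models_dir / f"fold_{fi}_loss.tsv",
                np.column_stack(
                    [result.histories[fi].train_loss,
                     result.histories[fi].val_loss or np.full(len(result.histories[fi].train_loss), np.nan)]
                ),
                header="train_loss\tval_loss", delimiter="\t",
            )

        fold_of_sample = {
            int(i): fi for fi, (_, te) in enumerate(result.plan.folds) for i in te
        }
        preds = {i: p.labels for i, p in result.predictions.items()}
        report = evaluate_folds(preds, t, fold_of_sample, dataset.binning)
        report.to_csv(out / "report.csv", index=False)
        (out / "report.txt").write_text(format_report(report) + "\n")
        log.info("metrics report:\n%s", format_report(report))
        return {"output_dir": str(out), "report": report, "cv": result, "dataset": dataset}
    finally:
        log.removeHandler(handler)
        handler.close()


def predict_external(
    model_path,
    es_data: np.ndarray,
    config: MeasurementConfig,
    grid: ImagingGrid,
    eps_background: complex = 1.0 + 0.0j,
):
    """OSM-process external scattered-field data and apply a trained model.

    The data must carry as many frequencies as the model has input channels;
    select or interpolate frequencies upstream if the acquisition grid
    differs.  Aspect-limited data (zeros at unavailable receivers) are
    processed as-is.
    """
    net = UNet.load(model_path)
    es_data = np.asarray(es_data)
    if es_data.ndim != 3 or es_data.shape[:2] != (config.n_rx, config.n_tx):
        raise ValueError(f"expected data shaped ({config.n_rx}, {config.n_tx}, Nf)")
    if es_data.shape[2] != net.spec.input_channels:
        raise ValueError(
            f"model expects {net.spec.input_channels} frequency channels, data has "
            f"{es_data.shape[2]}; select or interpolate frequencies to match"
        )
    tables = [
        analytic_green_table(config, grid, fi, eps_background)
        for fi in range(config.n_freq)
    ]
    stack = compute_indicator_stack(es_data, tables, config)
    return predict(net, stack)
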