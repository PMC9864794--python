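"""Training-set construction: scene → scattered field → indicator stack → labels.

Every sample is simulated noiselessly, OSM-processed, and paired with its
thresholded ground-truth class map.  All randomness flows from a single
per-dataset seed through a counter-based per-sample derivation, so datasets
are bit-reproducible and any individual sample can be re-derived.

Two families are provided:

* ``cylinders`` — two possibly overlapping lossless cylinders in free space,
  analytic background Green's functions, 7 contrast classes;
* ``brain`` — head phantom with one stroke in a matching medium, numerical
  Green's function of the nominal healthy head, differential data (stroke
  minus per-sample healthy baseline), 3 classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from ..geometry import ImagingGrid, MeasurementConfig, circular_config
from ..forward.solver import scattered_field
from ..osm import (
    BackgroundGreenTable,
    IndicatorStack,
    analytic_green_table,
    compute_indicator_stack,
    differential_data,
    numerical_green_table,
)
from .cylinders import (
    SEVEN_CLASS_BINNING,
    ClassBinning,
    sample_cylinder_scene,
    segment_ground_truth,
)
from .head import brain_config, brain_grid, nominal_healthy_scenes, sample_head_phantom

DATASET_SOLVER_TOL = 1e-5  # forward-solve tolerance for corpus generation


@dataclass
class TrainingPair:
    """One (indicator stack, class map) supervision pair with provenance."""

    indicators: IndicatorStack
    labels: np.ndarray  # (ny, nx) int
    seed: int
    provenance: dict


@dataclass
class Dataset:
    family: str
    pairs: list[TrainingPair]
    grid: ImagingGrid
    config: MeasurementConfig
    binning: ClassBinning
    seed: int

    def __len__(self) -> int:
        return len(self.pairs)

    def inputs(self) -> np.ndarray:
        """Network inputs, shape (N, Nf, ny, nx)."""
        return np.stack([p.indicators.images() for p in self.pairs])

    def targets(self) -> np.ndarray:
        """Class maps, shape (N, ny, nx)."""
        return np.stack([p.labels for p in self.pairs])

    def class_histogram(self) -> np.ndarray:
        return np.bincount(self.targets().ravel(), minlength=self.binning.n_classes)


def sample_seed(dataset_seed: int, index: int) -> int:
    """Counter-based per-sample seed derivation (stable, below 2^31)."""
    return int(np.random.SeedSequence([dataset_seed, index]).generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class CorpusSetup:
    """Sampling options for the cylinder family."""

    radius_range: tuple[float, float] = (0.012, 0.05)
    eps_range: tuple[float, float] = (1.3, 3.5)
    eps_choices: tuple[float, ...] | None = None
    min_separation: float | None = None
    binning: ClassBinning = SEVEN_CLASS_BINNING


def easy_corpus_setup() -> tuple[ImagingGrid, MeasurementConfig, CorpusSetup]:
    """Desk-scale study conditions: well-separated cylinders, 3 target classes.

    32×32 grid on the 25 cm domain, 8 transmitters / 64 receivers on the
    167 cm ring, 4 frequencies 2–5 GHz; ε drawn from {1.5, 2.2, 3.0} (contrasts
    0.5, 1.2, 2.0 — one per target class of the (0,0.85], (0.85,1.6],
    (1.6,2.5] binning), cylinders kept ≥2 cm apart.
    """
    grid = ImagingGrid(32, 32, 0.25)
    config = circular_config(8, 64, 1.67, [2e9, 3e9, 4e9, 5e9])
    setup = CorpusSetup(
        radius_range=(0.025, 0.045),
        eps_choices=(1.5, 2.2, 3.0),
        min_separation=0.02,
        binning=ClassBinning((0.0, 0.85, 1.6, 2.5)),
    )
    return grid, config, setup


def build_cylinder_dataset(
    n_samples: int,
    seed: int,
    grid: ImagingGrid,
    config: MeasurementConfig,
    setup: CorpusSetup = CorpusSetup(),
    tol: float = DATASET_SOLVER_TOL,
) -> Dataset:
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    tables = [
        analytic_green_table(config, grid, fi) for fi in range(config.n_freq)
    ]
    pairs = []
    for i in range(n_samples):
        s = sample_seed(seed, i)
        scene, spec = sample_cylinder_scene(
            s,
            grid,
            radius_range=setup.radius_range,
            eps_range=setup.eps_range,
            eps_choices=setup.eps_choices,
            min_separation=setup.min_separation,
        )
        es = scattered_field(scene, config, tol=tol)
        stack = compute_indicator_stack(es, tables, config)
        labels = segment_ground_truth(scene, setup.binning)
        prov = {
            "cylinders": [
                {"center": list(c.center), "radius": c.radius, "eps": c.eps}
                for c in spec.cylinders
            ]
        }
        pairs.append(TrainingPair(stack, labels, s, prov))
    return Dataset("cylinders", pairs, grid, config, setup.binning, seed)


BRAIN_BINNING = ClassBinning((0.0, 1.0, 3.0))  # labels come from the phantom, not thresholds


def build_brain_dataset(
    n_samples: int,
    seed: int,
    grid: ImagingGrid | None = None,
    config: MeasurementConfig | None = None,
    tol: float = DATASET_SOLVER_TOL,
) -> Dataset:
    """Differential stroke-imaging corpus; stroke kind alternates deterministically."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    grid = grid or brain_grid()
    config = config or brain_config()
    background = nominal_healthy_scenes(grid, config.frequencies)
    tables: list[BackgroundGreenTable] = [
        numerical_green_table(background[fi], config, fi, tol=tol)
        for fi in range(config.n_freq)
    ]
    pairs = []
    for i in range(n_samples):
        s = sample_seed(seed, i)
        kind = "ischemic" if i % 2 == 0 else "hemorrhagic"
        sample = sample_head_phantom(s, grid, kind, config.frequencies)
        es_stroke = scattered_field(None, config, tol=tol, dispersive_scenes=sample.stroke_scenes)
        es_healthy = scattered_field(None, config, tol=tol, dispersive_scenes=sample.healthy_scenes)
        es = differential_data(es_stroke, es_healthy)
        stack = compute_indicator_stack(es, tables, config, green_norm=True)
        prov = {
            "stroke": {
                "kind": kind,
                "center": list(sample.spec.stroke.center),
                "radius": sample.spec.stroke.radius,
            }
        }
        pairs.append(TrainingPair(stack, sample.labels, s, prov))
    return Dataset("brain", pairs, grid, config, BRAIN_BINNING, seed)


def build_dataset(family: str, n_samples: int, seed: int, config=None, grid=None, **kw) -> Dataset:
    if family == "cylinders":
        from ..geometry import benchmark_config, benchmark_grid

        return build_cylinder_dataset(
            n_samples, seed, grid or benchmark_grid(), config or benchmark_config(), **kw
        )
    if family == "brain":
        return build_brain_dataset(n_samples, seed, grid=grid, config=config, **kw)
    raise ValueError(f"unknown dataset family {family!r}")


# ----------------------------------------------------------------------------
# persistence: hierarchical container + plain-text manifest


def save_dataset(ds: Dataset, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as h:
        h.attrs["family"] = ds.family
        h.attrs["seed"] = ds.seed
        h.attrs["binning_edges"] = list(ds.binning.edges)
        h.attrs["grid"] = [ds.grid.nx, ds.grid.ny, ds.grid.side_length]
        h.create_dataset("frequencies", data=ds.config.frequencies, track_times=False)
        h.create_dataset("tx_positions", data=ds.config.tx_positions, track_times=False)
        h.create_dataset("rx_positions", data=ds.config.rx_positions, track_times=False)
        for i, p in enumerate(ds.pairs):
            g = h.create_group(f"sample_{i:05d}")
            g.create_dataset("indicators", data=p.indicators.values, track_times=False)
            g.create_dataset("labels", data=p.labels, track_times=False)
            g.attrs["seed"] = p.seed
            g.attrs["provenance"] = json.dumps(p.provenance, sort_keys=True)


def load_dataset(path) -> Dataset:
    with h5py.File(path, "r") as h:
        grid = ImagingGrid(int(h.attrs["grid"][0]), int(h.attrs["grid"][1]), float(h.attrs["grid"][2]))
        config = MeasurementConfig(h["tx_positions"][:], h["rx_positions"][:], h["frequencies"][:])
        binning = ClassBinning(tuple(float(e) for e in h.attrs["binning_edges"]))
        pairs = []
        for name in sorted(k for k in h.keys() if k.startswith("sample_")):
            g = h[name]
            stack = IndicatorStack(g["indicators"][:], grid, config.frequencies, normalized=True)
            pairs.append(
                TrainingPair(stack, g["labels"][:], int(g.attrs["seed"]), json.loads(g.attrs["provenance"]))
            )
        return Dataset(str(h.attrs["family"]), pairs, grid, config, binning, int(h.attrs["seed"]))


def dataset_manifest(ds: Dataset) -> pd.DataFrame:
    """Plain-text tabular summary: one row per sample with its class histogram."""
    rows = []
    for i, p in enumerate(ds.pairs):
        hist = np.bincount(p.labels.ravel(), minlength=ds.binning.n_classes)
        row = {"sample": i, "seed": p.seed}
        row.update({f"class_{c}": int(n) for c, n in enumerate(hist)})
        rows.append(row)
    return pd.DataFrame(rows)


def dataset_content_hash(ds: Dataset) -> str:
    """Order-stable hash of the numerical content (for reproducibility audits)."""
    import hashlib

    hsh = hashlib.sha256()
    for p in ds.pairs:
        hsh.update(np.ascontiguousarray(p.indicators.values).tobytes())
        hsh.update(np.ascontiguousarray(p.labels).tobytes())
    return hsh.hexdigest()
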