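"""End-to-end experiment orchestration and the dilution-design arithmetic.

``run_experiment`` chains the full study: synthesize (or load) a labeled
spectral dataset, preprocess (trim -> SG -> SNV), split 3:1:1, grid-tune the
three classical models, train the CNN and ResNet, evaluate all five on the
three splits, and compute gradient-saliency wavelength profiles for the deep
models. ``mixture_concentrations`` reproduces the spray-design concentration
table: each pesticide's standard solution is 1 g of product per `ratio` mL
of water (1000/ratio g/L), and residue levels are fixed fractions of the
standard (level 0 is distilled water).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classical import ModelResult, SearchSpace, tune_and_train
from .dataset import SpectralDataset
from .deep import CnnSpec, ResNetSpec, TrainConfig, build_cnn, build_resnet, train_model
from .evaluation import SaliencyProfile, split_dataset, saliency_map
from .preprocessing import preprocess
from .synthetic import SceneConfig, generate_dataset, nir_config, visnir_config

#: product dilution ratios (1 g per N mL) and residue-level fractions of the
#: standard mixture
DEFAULT_DILUTION_RATIOS = {"Jiatu": 4000.0, "Xishuangke": 6000.0, "Huiyin": 2400.0}
DEFAULT_LEVEL_FRACTIONS = (0.0, 0.15, 0.30, 0.50)


@dataclass
class ExperimentConfig:
    """Everything needed to rerun one full experiment deterministically."""

    instrument: str = "visnir"
    scene: SceneConfig | None = None
    trim_lo_nm: float | None = None
    trim_hi_nm: float | None = None
    sg_window: int = 3
    sg_polyorder: int = 0
    snv_enabled: bool = True
    split_seed: int = 0
    stratify_on: str = "level"
    search_space: SearchSpace = field(default_factory=SearchSpace)
    cnn_train: TrainConfig = field(default_factory=lambda: TrainConfig(epochs=100))
    resnet_train: TrainConfig = field(
        default_factory=lambda: TrainConfig(epochs=30, learning_rate=1e-3))
    models: tuple[str, ...] = ("svm", "lr", "rf", "cnn", "resnet")
    dilution_ratios: dict = field(default_factory=lambda: dict(DEFAULT_DILUTION_RATIOS))
    level_fractions: tuple[float, ...] = DEFAULT_LEVEL_FRACTIONS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.instrument not in ("visnir", "nir"):
            raise ValueError("instrument must be 'visnir' or 'nir'")
        if self.scene is None:
            maker = visnir_config if self.instrument == "visnir" else nir_config
            self.scene = maker(seed=self.seed)
        if any(r <= 0 for r in self.dilution_ratios.values()):
            raise ValueError("dilution ratios must be positive")
        fr = np.asarray(self.level_fractions)
        if np.any(fr < 0) or np.any(fr > 1) or np.any(np.diff(fr) < 0):
            raise ValueError("level fractions must be nondecreasing in [0, 1]")

    def config_hash(self) -> str:
        payload = {
            "instrument": self.instrument, "seed": self.seed,
            "split_seed": self.split_seed, "sg": [self.sg_window, self.sg_polyorder],
            "snv": self.snv_enabled, "models": list(self.models),
            "n_bands": int(self.scene.n_bands),
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def mixture_concentrations(cfg: ExperimentConfig | None = None) -> pd.DataFrame:
    """Per-level, per-pesticide concentrations in g/L, rounded to 4 decimals.

    Standard concentration = 1000 / dilution_ratio; each level's value is
    its fraction of the exact standard, rounded only for reporting.
    """
    cfg = cfg or ExperimentConfig()
    rows = {}
    labels = [f"Level {i} ({f:.0%})" for i, f in enumerate(cfg.level_fractions)]
    labels.append("Standard solution (100%)")
    fractions = list(cfg.level_fractions) + [1.0]
    for name, ratio in cfg.dilution_ratios.items():
        if ratio <= 0:
            raise ValueError(f"dilution ratio for {name} must be positive")
        standard = 1000.0 / ratio
        rows[name] = [round(f * standard, 4) for f in fractions]
    return pd.DataFrame(rows, index=labels)


@dataclass
class ExperimentReport:
    """Per-model accuracies and parameters plus saliency profiles."""

    results: dict[str, ModelResult]
    saliency: dict[str, SaliencyProfile]
    config_hash: str
    seeds: dict[str, int]

    def to_table(self) -> pd.DataFrame:
        rows = []
        for kind, res in self.results.items():
            rows.append({
                "model": kind,
                "parameters": json.dumps(res.best_params),
                "train": round(res.accuracies["train"], 4),
                "val": round(res.accuracies["val"], 4),
                "test": round(res.accuracies["test"], 4),
            })
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        payload = {
            "config_hash": self.config_hash,
            "seeds": self.seeds,
            "models": {
                kind: {"params": dict(res.best_params),
                       "accuracies": res.accuracies,
                       "predictions": {k: v.tolist() for k, v in res.predictions.items()}}
                for kind, res in self.results.items()
            },
            "saliency": {
                kind: {"wavelength_nm": prof.wavelengths_nm.tolist(),
                       "importance": prof.importance.tolist(),
                       "n_samples_used": prof.n_samples_used}
                for kind, prof in self.saliency.items()
            },
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def run_experiment(cfg: ExperimentConfig, out_dir: str | Path | None = None,
                   ds: SpectralDataset | None = None) -> ExperimentReport:
    """Execute every stage in study order on synthetic (or provided) spectra."""
    if ds is None:
        ds = generate_dataset(cfg.scene)
    prep = preprocess(ds, lo_nm=cfg.trim_lo_nm, hi_nm=cfg.trim_hi_nm,
                      window=cfg.sg_window, polyorder=cfg.sg_polyorder,
                      apply_snv=cfg.snv_enabled)
    split = split_dataset(prep, seed=cfg.split_seed, stratify_on=cfg.stratify_on)

    results: dict[str, ModelResult] = {}
    saliency: dict[str, SaliencyProfile] = {}
    test_ds = prep.subset(split.test)
    for kind in cfg.models:
        try:
            if kind in ("svm", "lr", "rf"):
                results[kind] = tune_and_train(kind, prep, split,
                                               space=cfg.search_space, seed=cfg.seed)
            elif kind == "cnn":
                net = build_cnn(prep.n_bands, CnnSpec(), seed=cfg.cnn_train.seed)
                results[kind] = train_model(net, prep, split, cfg.cnn_train)
                saliency[kind] = saliency_map(net, test_ds)
            elif kind == "resnet":
                net = build_resnet(prep.n_bands, ResNetSpec(), seed=cfg.resnet_train.seed)
                results[kind] = train_model(net, prep, split, cfg.resnet_train)
                saliency[kind] = saliency_map(net, test_ds)
            else:
                raise ValueError(f"unknown model kind {kind!r}")
        except Exception as exc:
            raise RuntimeError(f"stage '{kind}' failed: {exc}") from exc

    report = ExperimentReport(
        results=results, saliency=saliency, config_hash=cfg.config_hash(),
        seeds={"data": cfg.scene.seed, "split": cfg.split_seed,
               "cnn": cfg.cnn_train.seed, "resnet": cfg.resnet_train.seed},
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        prep.to_csv(out_dir / "spectra_preprocessed.csv")
        split.to_json(out_dir / "split.json")
        (out_dir / "report.json").write_text(report.to_json())
        report.to_table().to_csv(out_dir / "report_table.csv", index=False)
        for kind, prof in saliency.items():
            prof.to_csv(out_dir / f"saliency_{kind}.csv")
    return report
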