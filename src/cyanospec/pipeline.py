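"""End-to-end experiment orchestration.

generate -> resample -> train Full/P1/P2 per product per data type ->
attribute -> select bands -> merge -> report, with seeded reproducibility
throughout.  Attribution is computed once per (product, data type) on the
decimated Full configuration; the P1/P2 models are retrained from scratch
on the selected channels, since the input dimensionality changes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .attribution import permutation_importance
from .bands import BandSelection, SelectionError, merge_configs, select_p1, select_p2
from .instrument import cyanosat_centers, decimate, srf_matrix
from .metrics import append_metrics_csv
from .retrieval import PRODUCTS, TrainConfig, evaluate
from .synth import DATA_TYPES, GeneratorConfig, generate_dataset
from .optics import default_grid

__all__ = ["ExperimentConfig", "run_experiment", "compare_fwhm", "derive_seed"]

log = logging.getLogger("cyanospec")


def derive_seed(master_seed: int, *tags) -> int:
    """Deterministic sub-seed (< 2^31) for a pipeline stage."""
    h = zlib.crc32("/".join(str(t) for t in tags).encode())
    return int((master_seed * 2654435761 + h) % (2 ** 31))


@dataclass
class ExperimentConfig:
    """Everything one experiment run needs, in one (YAML-loadable) place."""

    n_waters: int = 2000
    master_seed: int = 0
    products: tuple = PRODUCTS
    data_types: tuple = ("RRS",)
    fwhm: tuple = (12.0,)
    decimate_step: int = 3
    train: TrainConfig = field(default_factory=TrainConfig)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    n_repeats: int = 5
    p1_n: int = 9
    p1_min_sep_nm: float = 9.0
    p2_n: int = 3
    p2_min_sep_nm: float = 30.0
    smooth_window: int = 3
    run_cv: bool = False
    out_dir: Optional[str] = None

    def __post_init__(self):
        bad = set(self.products) - set(PRODUCTS)
        if bad:
            raise ValueError(
                f"unknown products {sorted(bad)}; valid products: {PRODUCTS}")
        bad = set(self.data_types) - set(DATA_TYPES)
        if bad:
            raise ValueError(
                f"unknown data types {sorted(bad)}; valid: {DATA_TYPES}")
        if not self.fwhm:
            raise ValueError("fwhm list must be non-empty")
        # only generate the record variants the experiment will consume
        self.generator = dataclasses.replace(
            self.generator, data_types=tuple(self.data_types))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "train" in raw:
            raw["train"] = TrainConfig(**raw["train"])
        if "generator" in raw:
            raw["generator"] = GeneratorConfig(**raw["generator"])
        for key in ("products", "data_types", "fwhm"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("products", "data_types", "fwhm"):
            d[key] = list(d[key])
        d["generator"]["data_types"] = list(d["generator"]["data_types"])
        return d


def _band_config_for(centers, fwhm, grid, name):
    return srf_matrix(np.asarray(centers, dtype=float), fwhm, grid, name=name)


def run_experiment(config: ExperimentConfig) -> dict:
    """Run the full experiment; returns (and optionally writes) artifacts.

    Per (product x data_type): train the Full (decimated) model, compute the
    attribution profile on its held-out partition, derive P1/P2, retrain on
    the selected channels, and report metrics for all three configurations.
    Per data type, the P2 selections merge into the minimum viable
    configuration and the P1 selections into the optimal configuration.
    """
    t0 = time.time()
    grid = default_grid()
    fwhm = config.fwhm[0]
    full = decimate(srf_matrix(cyanosat_centers(), fwhm, grid, name="300ch"),
                    config.decimate_step)
    full = dataclasses.replace(full, name="Full")
    gen_seed = derive_seed(config.master_seed, "generate")
    log.info("generating %d waters (seed %d)", config.n_waters, gen_seed)
    dataset = generate_dataset(config.n_waters, gen_seed, config=config.generator,
                               grid=grid)
    reports, profiles, selections = [], [], {}
    for data_type in config.data_types:
        sub = dataset.filter(data_type)
        for product in config.products:
            seed = derive_seed(config.master_seed, "train", product, data_type)
            log.info("Full model: %s / %s", product, data_type)
            res = evaluate(sub, product, full, config.train, seed=seed,
                           run_cv=config.run_cv)
            reports.append(res.report)
            profile = permutation_importance(
                res.model, res.X_test, res.y_test, full.centers,
                n_repeats=config.n_repeats,
                seed=derive_seed(config.master_seed, "attr", product, data_type),
                product=product, data_type=data_type)
            profiles.append(profile)
            for name, selector, n, sep in (
                    ("P1", select_p1, config.p1_n, config.p1_min_sep_nm),
                    ("P2", select_p2, config.p2_n, config.p2_min_sep_nm)):
                try:
                    sel = selector(profile, n=n, min_sep_nm=sep,
                                   smooth_window=config.smooth_window)
                except SelectionError as err:
                    log.warning("selection fallback for %s/%s: %s",
                                product, data_type, err)
                    continue
                selections[(name, product, data_type)] = sel
                reduced = _band_config_for(sel.centers, fwhm, grid, name=name)
                # paired comparison: reduced configs train with the same
                # seed (and data split) as the Full model
                res_r = evaluate(sub, product, reduced, config.train,
                                 seed=seed, run_cv=config.run_cv)
                reports.append(res_r.report)
    merged = {}
    for data_type in config.data_types:
        for name in ("P2", "P1"):
            sels = [selections[k] for k in selections
                    if k[0] == name and k[2] == data_type]
            if sels:
                label = "minimum_viable" if name == "P2" else "optimal"
                merged[(label, data_type)] = merge_configs(sels, tol_nm=0.0)
    artifacts = {
        "dataset": dataset,
        "reports": reports,
        "profiles": profiles,
        "selections": selections,
        "merged": merged,
        "manifest": {
            "package_version": __version__,
            "master_seed": config.master_seed,
            "config": config.to_dict(),
            "generator_hash": config.generator.hash(),
            "n_records": len(dataset),
        },
    }
    if config.out_dir:
        _write_artifacts(artifacts, Path(config.out_dir))
    log.info("experiment finished in %.1f s", time.time() - t0)
    return artifacts


def _write_artifacts(artifacts: dict, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    metrics_path = out / "metrics.csv"
    if metrics_path.exists():
        metrics_path.unlink()
    append_metrics_csv(artifacts["reports"], metrics_path)
    prof_rows = []
    for p in artifacts["profiles"]:
        for c, v in zip(p.channel_centers, p.fi):
            prof_rows.append({"product": p.product, "data_type": p.data_type,
                              "center_nm": c, "fi": v})
    pd.DataFrame(prof_rows).to_csv(out / "profiles.csv", index=False)
    sel_rows = []
    for (name, product, data_type), sel in artifacts["selections"].items():
        for c in sel.centers:
            sel_rows.append({"name": name, "product": product,
                             "data_type": data_type, "center_nm": c,
                             "n_sources": 1})
    for (label, data_type), sel in artifacts["merged"].items():
        for c, k in zip(sel.centers, sel.counts):
            sel_rows.append({"name": label, "product": "all",
                             "data_type": data_type, "center_nm": c,
                             "n_sources": k})
    pd.DataFrame(sel_rows).to_csv(out / "selections.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(artifacts["manifest"], indent=2))


def compare_fwhm(config: ExperimentConfig) -> pd.DataFrame:
    """Full-configuration retrieval at each FWHM on identical waters.

    Emits one row per product per FWHM (R^2, MAPE, RMSELE) plus the
    per-product deltas; no ordering is asserted — narrower bands are not
    automatically better.
    """
    if len(config.fwhm) < 2:
        raise ValueError("compare_fwhm needs at least two FWHM values")
    grid = default_grid()
    gen = dataclasses.replace(config.generator, data_types=("RRS",))
    dataset = generate_dataset(config.n_waters,
                               derive_seed(config.master_seed, "generate"),
                               config=gen, grid=grid)
    rows = []
    for fwhm in config.fwhm:
        full = decimate(srf_matrix(cyanosat_centers(), fwhm, grid,
                                   name=f"Full{fwhm:g}nm"), config.decimate_step)
        for product in config.products:
            res = evaluate(dataset, product, full, config.train,
                           seed=derive_seed(config.master_seed, "fwhm",
                                            product, fwhm),
                           run_cv=config.run_cv)
            rows.append({"product": product, "fwhm_nm": fwhm,
                         "r2": res.report.r2,
                         "mape_percent": res.report.mape_percent,
                         "rmsele": res.report.rmsele})
    frame = pd.DataFrame(rows)
    deltas = []
    for product in config.products:
        sub = frame[frame["product"] == product].sort_values("fwhm_nm")
        for metric in ("r2", "mape_percent", "rmsele"):
            vals = sub[metric].to_numpy()
            deltas.append({"product": product, "metric": metric,
                           "abs_delta": float(abs(vals[-1] - vals[0]))})
    frame.attrs["deltas"] = pd.DataFrame(deltas)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out / "fwhm_comparison.csv", index=False)
        frame.attrs["deltas"].to_csv(out / "fwhm_deltas.csv", index=False)
    return frame
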