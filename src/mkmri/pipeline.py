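"""End-to-end pipeline: simulate -> extract -> evaluate -> maps.

One :class:`RunConfig` drives all stages; every random draw flows from its
single seed, so identical configs give byte-identical reports.  A provenance
record (config echo, seed, version, per-stage checksums) is written next to
the outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortConfig, cohort_labels, default_paper_config, full_mask, generate_cohort
from .evaluation import metrics_report, improvement_over_best_single, loocv, round_half_up
from .features import FEATURE_NAMES, extract_feature_matrices
from .io import load_cohort, load_mask, save_cohort, write_nifti
from .maps import fit_full_and_map

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    out_dir: str = "mkmri_out"
    cohort_dir: str | None = None      # read an existing cohort instead of simulating
    mask_path: str | None = None
    comparison: str = "pos-vs-neg"
    features: tuple = FEATURE_NAMES
    band: tuple = (0.01, 0.08)
    fwhm: float = 4.0
    n_discard: int = 10
    C: float = 100.0
    theta: float = 0.30
    seed: int = 0
    cohort: CohortConfig = field(default_factory=default_paper_config)

    def validate(self) -> None:
        if not self.features:
            raise ValueError("feature set must be non-empty")
        unknown = set(self.features) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown features {sorted(unknown)}")
        if self.C <= 0:
            raise ValueError("C must be positive")
        nyquist = 1.0 / (2.0 * self.cohort.tr)
        if not (0 <= self.band[0] < self.band[1] <= nyquist + 1e-12):
            raise ValueError(f"band {self.band} outside (0, Nyquist={nyquist:g}]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort_raw = raw.pop("cohort", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v
                     for k, v in raw.items()})
        if cohort_raw is not None:
            cfg.cohort = CohortConfig.from_dict(cohort_raw)
        return cfg

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["features"] = list(self.features)
        d["band"] = list(self.band)
        d["cohort"] = self.cohort.to_dict()
        return d


def _checksum(arr) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write reports; returns a summary dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance: dict = {"version": __version__, "seed": config.seed,
                        "config": config.to_dict(), "stages": {}}
    timings = {}

    # -- stage 1: cohort -----------------------------------------------------
    t0 = time.perf_counter()
    if config.cohort_dir is not None:
        cohort_dir = Path(config.cohort_dir)
        if not cohort_dir.exists():
            raise FileNotFoundError(f"cohort directory {cohort_dir} not found")
        scans = load_cohort(cohort_dir)
        mask = load_mask(config.mask_path) if config.mask_path else full_mask(
            scans[0].structural.shape)
    else:
        cohort_cfg = CohortConfig.from_dict({**config.cohort.to_dict(),
                                             "seed": config.seed})
        scans = generate_cohort(cohort_cfg)
        mask = full_mask(cohort_cfg.grid_dims)
        save_cohort(scans, out / "cohort", mask=mask)
    labels = cohort_labels(scans)
    timings["cohort"] = time.perf_counter() - t0
    provenance["stages"]["cohort"] = {
        "n_subjects": len(scans),
        "checksum": _checksum(np.concatenate([s.structural.ravel() for s in scans])),
    }
    logger.info("cohort: %d subjects (%.2fs)", len(scans), timings["cohort"])

    # -- stage 2: features ---------------------------------------------------
    t0 = time.perf_counter()
    mats = extract_feature_matrices(scans, mask, band=config.band,
                                    fwhm=config.fwhm, n_discard=config.n_discard,
                                    features=config.features)
    timings["features"] = time.perf_counter() - t0
    provenance["stages"]["features"] = {
        f: {"shape": list(m.values.shape), "checksum": _checksum(m.values)}
        for f, m in mats.items()}
    logger.info("features: %s (%.2fs)", list(mats), timings["features"])

    # -- stage 3: evaluation -------------------------------------------------
    t0 = time.perf_counter()
    reports = {}
    for name in config.features:
        folds = loocv({name: mats[name]}, labels, C=config.C)
        reports[name] = metrics_report(folds)
    combined_name = "Combined"
    if len(config.features) > 1:
        folds = loocv({f: mats[f] for f in config.features}, labels, C=config.C)
        reports[combined_name] = metrics_report(folds)
    timings["evaluate"] = time.perf_counter() - t0

    table = pd.DataFrame(
        [{"feature": name, **rep.formatted()} for name, rep in reports.items()])
    table.to_csv(out / "metrics.tsv", sep="\t", index=False, float_format="%.2f")
    for name, rep in reports.items():
        pd.DataFrame(rep.roc_points, columns=["fpr", "tpr"]).to_csv(
            out / f"roc_{name}.csv", index=False)
    provenance["stages"]["evaluate"] = {
        name: rep.formatted() for name, rep in reports.items()}
    logger.info("evaluate: %s (%.2fs)",
                {k: v.formatted()["ACC"] for k, v in reports.items()},
                timings["evaluate"])

    # -- stage 4: maps -------------------------------------------------------
    t0 = time.perf_counter()
    dmaps, beta = fit_full_and_map({f: mats[f] for f in config.features}, labels,
                                   mask, C=config.C, theta=config.theta)
    for dmap in dmaps:
        write_nifti(dmap.weights, scans[0].voxel_size,
                    out / f"weights_{dmap.feature}.nii")
        write_nifti(dmap.retained.astype(float), scans[0].voxel_size,
                    out / f"discrimination_{dmap.feature}.nii")
    timings["maps"] = time.perf_counter() - t0
    provenance["stages"]["maps"] = {
        "beta": {f: float(b) for f, b in zip(config.features, beta)},
        "checksum": _checksum(np.concatenate([m.weights.ravel() for m in dmaps])),
    }

    summary = {
        "comparison": config.comparison,
        "metrics": {name: rep.formatted() for name, rep in reports.items()},
        "beta": {f: float(b) for f, b in zip(config.features, beta)},
    }
    if combined_name in reports:
        singles = [reports[f].accuracy for f in config.features]
        summary["improvement_over_best_single"] = round_half_up(
            improvement_over_best_single(reports[combined_name].accuracy, singles))
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    return summary
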