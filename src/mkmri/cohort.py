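"""Synthetic two-group MRI cohorts with modality-specific group effects.

Real multimodal PTSD cohorts are not publicly deposited, so this module
generates labeled stand-in cohorts on a desk-scale voxel grid: each subject
gets a non-negative structural volume (a GMV surrogate) and a 4-D
resting-state functional series.  Group differences are injected separately
into the three quantities the downstream features measure:

* ``volume``     — a mean shift of the structural values inside a box,
  in units of the noise SD (patients only);
* ``amplitude``  — a sinusoid at an in-band frequency whose amplitude is a
  configurable fraction larger for patients (raises ALFF);
* ``synchrony``  — a shared latent time series mixed into every box voxel
  for patients (raises ReHo).

The functional baseline is temporally white Gaussian noise; first-order
autoregressive noise is available behind ``ar_coeff`` and off by default.
Patients carry label +1 and receive the altered value; controls are -1.
Everything is driven by a single integer seed (per-subject substreams are
spawned deterministically), so identical configs give bit-identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as _signal

from .features import BrainMask, smooth_gaussian

EFFECT_TARGETS = ("volume", "amplitude", "synchrony")


class ConfigurationError(ValueError):
    """Invalid cohort configuration."""


@dataclass(frozen=True)
class EffectRegion:
    """A box-shaped group effect.

    ``box`` holds inclusive 0-based voxel-index bounds per axis,
    ``((x0, x1), (y0, y1), (z0, z1))``.  The meaning of ``effect_size``
    depends on ``target``: mean shift in noise-SD units (volume), fractional
    oscillation-amplitude increase (amplitude), or shared-signal mixing
    coefficient in [0, 1] (synchrony).
    """

    box: tuple
    target: str
    effect_size: float

    def validate(self, grid_dims) -> None:
        if self.target not in EFFECT_TARGETS:
            raise ConfigurationError(f"unknown effect target {self.target!r}")
        if len(self.box) != 3:
            raise ConfigurationError("box needs bounds for exactly 3 axes")
        for (lo, hi), dim in zip(self.box, grid_dims):
            if not (0 <= lo <= hi < dim):
                raise ConfigurationError(
                    f"box bounds ({lo}, {hi}) fall outside grid axis of size {dim}")
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be non-negative")
        if self.target == "synchrony" and self.effect_size > 1:
            raise ConfigurationError("synchrony mixing coefficient must be <= 1")

    @property
    def slices(self) -> tuple:
        return tuple(slice(lo, hi + 1) for lo, hi in self.box)

    def box_mask(self, grid_dims) -> np.ndarray:
        m = np.zeros(grid_dims, dtype=bool)
        m[self.slices] = True
        return m


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the emulated acquisition: two groups of 17 patients and
    20 controls, 200 functional volumes at TR = 2 s with the first 10
    discarded, on a 12x12x12 grid of 3 mm isotropic voxels.
    """

    n_pos: int = 17
    n_neg: int = 20
    grid_dims: tuple = (12, 12, 12)
    voxel_size: tuple = (3.0, 3.0, 3.0)
    tr: float = 2.0
    n_volumes: int = 200
    n_discard: int = 10
    effects: tuple = ()
    noise_sd: float = 1.0
    seed: int = 0
    # generator conditions beyond the acquisition geometry, fixed once:
    structural_baseline: float = 5.0   # mean GMV level, in noise-SD units
    structural_fwhm: float = 8.0       # mm; GMV maps are smoothed at source
    amplitude_base: float = 1.0        # baseline sinusoid amplitude, x noise_sd
    amplitude_freq: float = 0.05       # Hz; inside the 0.01-0.08 Hz band
    ar_coeff: float = 0.0              # AR(1) noise coefficient, 0 = white

    def validate(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ConfigurationError("group sizes must be positive")
        if any(d < 1 for d in self.grid_dims) or len(self.grid_dims) != 3:
            raise ConfigurationError("grid_dims must be 3 positive integers")
        if self.tr <= 0:
            raise ConfigurationError("tr must be positive")
        if self.n_volumes <= self.n_discard:
            raise ConfigurationError("n_volumes must exceed n_discard")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if not (0 <= self.ar_coeff < 1):
            raise ConfigurationError("ar_coeff must lie in [0, 1)")
        for eff in self.effects:
            eff.validate(self.grid_dims)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["grid_dims"] = list(self.grid_dims)
        d["voxel_size"] = list(self.voxel_size)
        d["effects"] = [
            {"box": [list(b) for b in e.box], "target": e.target,
             "effect_size": e.effect_size}
            for e in self.effects
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "effects" in d:
            d["effects"] = tuple(
                EffectRegion(box=tuple(tuple(b) for b in e["box"]),
                             target=e["target"], effect_size=e["effect_size"])
                for e in d["effects"]
            )
        for k in ("grid_dims", "voxel_size"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class SubjectScan:
    """One subject: structural 3-D volume plus functional (x, y, z, t) series."""

    subject_id: str
    label: int  # +1 patient-class, -1 control-class
    structural: np.ndarray
    functional: np.ndarray
    tr: float
    voxel_size: tuple

    def __post_init__(self):
        if self.label not in (-1, 1):
            raise ValueError("label must be -1 or +1")
        if self.structural.shape != self.functional.shape[:3]:
            raise ValueError("structural and functional spatial dims differ")


def _simulate_subject(subject_id: str, label: int, cfg: CohortConfig,
                      rng: np.random.Generator) -> SubjectScan:
    dims = cfg.grid_dims
    n_t = cfg.n_volumes

    structural = cfg.structural_baseline + rng.normal(0.0, cfg.noise_sd, dims)
    for eff in cfg.effects:
        if eff.target == "volume" and label == 1:
            structural[eff.slices] += eff.effect_size * cfg.noise_sd
    if cfg.structural_fwhm > 0:
        structural = smooth_gaussian(structural, cfg.structural_fwhm, cfg.voxel_size)
    np.clip(structural, 0.0, None, out=structural)

    functional = rng.normal(0.0, cfg.noise_sd, (*dims, n_t))
    if cfg.ar_coeff > 0:
        # AR(1) along time, rescaled back to the configured marginal SD
        functional = _signal.lfilter([1.0], [1.0, -cfg.ar_coeff], functional, axis=-1)
        functional *= math.sqrt(1.0 - cfg.ar_coeff ** 2)

    t = np.arange(n_t) * cfg.tr
    for eff in cfg.effects:
        # draws happen for every subject so substreams stay aligned across labels
        if eff.target == "amplitude":
            box = functional[eff.slices]
            phases = rng.uniform(0.0, 2.0 * np.pi, box.shape[:3])
            gain = 1.0 + (eff.effect_size if label == 1 else 0.0)
            amp = cfg.amplitude_base * cfg.noise_sd * gain
            box += amp * np.sin(2.0 * np.pi * cfg.amplitude_freq * t + phases[..., None])
        elif eff.target == "synchrony":
            latent = rng.normal(0.0, 1.0, n_t)
            c = eff.effect_size if label == 1 else 0.0
            if c > 0:
                box = functional[eff.slices]
                box *= math.sqrt(1.0 - c * c)
                box += c * cfg.noise_sd * latent

    return SubjectScan(subject_id=subject_id, label=label, structural=structural,
                       functional=functional, tr=cfg.tr, voxel_size=cfg.voxel_size)


def generate_cohort(config: CohortConfig) -> list[SubjectScan]:
    """Simulate a full labeled cohort (patients first, then controls).

    Identical ``config`` (including ``seed``) gives bit-identical arrays.
    """
    config.validate()
    n = config.n_pos + config.n_neg
    children = np.random.SeedSequence(config.seed).spawn(n)
    labels = [1] * config.n_pos + [-1] * config.n_neg
    return [
        _simulate_subject(f"sub-{i + 1:03d}", label, config,
                          np.random.default_rng(child))
        for i, (label, child) in enumerate(zip(labels, children))
    ]


def cohort_labels(scans) -> np.ndarray:
    return np.asarray([s.label for s in scans], dtype=int)


def full_mask(grid_dims) -> BrainMask:
    """Whole-grid brain mask (the generator has no out-of-brain voxels)."""
    return BrainMask(np.ones(grid_dims, dtype=bool))


def default_paper_config(seed: int = 0) -> CohortConfig:
    """Study-scale conditions: 17 patients vs 20 controls, 200 volumes at
    TR = 2 s (first 10 discarded), 12x12x12 grid at 3 mm, one effect region
    per target type in disjoint boxes."""
    effects = (
        EffectRegion(box=((1, 4), (1, 4), (1, 4)), target="volume", effect_size=0.8),
        EffectRegion(box=((7, 10), (7, 10), (1, 4)), target="amplitude", effect_size=0.5),
        EffectRegion(box=((7, 10), (1, 4), (7, 10)), target="synchrony", effect_size=0.8),
    )
    return CohortConfig(effects=effects, seed=seed)


def single_effect_config(target: str, effect_size: float | None = None,
                         seed: int = 0, **overrides) -> CohortConfig:
    """Conditions with signal in exactly one modality (others pure noise)."""
    defaults = {"volume": 0.8, "amplitude": 0.5, "synchrony": 0.8}
    if target not in defaults:
        raise ConfigurationError(f"unknown effect target {target!r}")
    size = defaults[target] if effect_size is None else effect_size
    eff = EffectRegion(box=((1, 4), (1, 4), (1, 4)), target=target, effect_size=size)
    return replace(CohortConfig(effects=(eff,), seed=seed), **overrides)
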