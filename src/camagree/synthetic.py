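"""Synthetic soft-boundary tissue-damage image generator.

Emulates the statistical structure of a freeze-thaw tissue-damage MRI study
on grayscale image stacks, at desk scale:

* each *sample* is an elliptical tissue cross-section on a dark background,
  imaged as a stack of slices, first "fresh" (class y=0) and then after a
  damaging treatment (class y=1);
* treatment severity is a scalar in [0, 1]; three ordered levels emulate
  slow/medium/fast freezing (severe, intermediate, mild damage);
* damage is a spatially smooth random field biased toward the slice centre
  (where real freeze damage concentrates), thresholded into a per-pixel
  ground-truth mask whose boundary is soft by construction -- the image
  perturbation fades continuously to zero at the mask edge;
* a per-sample liquid-loss percentage is coupled to the realised damage
  fraction through an affine model with Gaussian noise, mirroring drip loss
  as an external damage proxy.

Fresh and damaged slices share the same base texture, so the only class
signal is the damage perturbation itself; a classifier cannot separate the
classes via sample identity.

Intensities are floats in [0, 1]; an optional 12-bit quantisation emulates
scanner bit depth.  Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .exceptions import ConfigurationError, DomainError

__all__ = [
    "TextureParams",
    "LLCoupling",
    "GeneratorConfig",
    "SliceImage",
    "SyntheticSample",
    "generate_dataset",
    "simulate_liquid_loss",
    "liquid_loss_percent",
    "save_hdf5",
    "load_hdf5",
    "export_png",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TextureParams:
    """Base tissue texture: Gaussian-random-field correlation length (pixels)
    and amplitude (intensity units)."""

    correlation_length: float = 3.0
    amplitude: float = 0.06


@dataclass(frozen=True)
class LLCoupling:
    """Affine link from damage fraction to liquid loss (%):
    LL = base + slope * damage_fraction + N(0, noise_sd)."""

    base: float = 2.0
    slope: float = 20.0
    noise_sd: float = 1.5

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design parameters of the synthetic dataset.

    Defaults mirror the emulated study: three treatment groups of 11/11/10
    samples at severities 0.9/0.5/0.1 (slow to fast freezing), 8 slices per
    sample at 64x64 (desk-scale stand-ins for 54 slices at 256x256).
    """

    image_size: int = 64
    n_samples_per_group: int | tuple = (11, 11, 10)
    slices_per_sample: int = 8
    treatment_levels: tuple = (0.9, 0.5, 0.1)
    texture_params: TextureParams = field(default_factory=TextureParams)
    damage_field_smoothness: float = 8.0
    center_bias: float = 1.0
    ll_coupling: LLCoupling = field(default_factory=LLCoupling)
    acquisition_noise_sd: float = 0.01
    quantize_12bit: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 32:
            raise ConfigurationError("image_size must be >= 32")
        if self.slices_per_sample < 1:
            raise ConfigurationError("slices_per_sample must be >= 1")
        levels = tuple(self.treatment_levels)
        if any(not 0.0 <= s <= 1.0 for s in levels):
            raise ConfigurationError("severity values must lie in [0, 1]")
        diffs = np.diff(levels)
        if len(levels) > 1 and not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ConfigurationError("treatment_levels must be strictly ordered")
        if self.center_bias < 0:
            raise ConfigurationError("center_bias must be >= 0")
        if self.acquisition_noise_sd < 0:
            raise ConfigurationError("acquisition_noise_sd must be >= 0")

    def group_sizes(self) -> tuple:
        n = self.n_samples_per_group
        if isinstance(n, int):
            return tuple(n for _ in self.treatment_levels)
        n = tuple(n)
        if len(n) != len(self.treatment_levels):
            raise ConfigurationError(
                "n_samples_per_group must be an int or match treatment_levels"
            )
        return n


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class SliceImage:
    """One 2-D grayscale slice with its identity and image-level label."""

    image: np.ndarray
    sample_id: str
    slice_index: int
    y: int                    # 0 = fresh, 1 = damaged
    treatment_level: float


@dataclass
class SyntheticSample:
    """Paired fresh/damaged slice stacks for one sample, with ground truth.

    ``fresh_slices[i]`` and ``damaged_slices[i]`` share geometry and base
    texture; ``truth_masks[i]`` and ``damage_fields[i]`` (the continuous
    pre-threshold field) belong to ``damaged_slices[i]``.
    """

    sample_id: str
    treatment_level: float
    fresh_slices: list
    damaged_slices: list
    truth_masks: list         # uint8 0/1, confined to foreground
    foreground_masks: list    # uint8 0/1 tissue region, one per slice index
    damage_fields: list       # float continuous field in [0,1]
    damage_fraction: float    # mean fraction of foreground pixels damaged
    liquid_loss_pct: float


# ---------------------------------------------------------------------------
# Field helpers
# ---------------------------------------------------------------------------

def _smooth_field(rng: np.random.Generator, size: int, corr: float) -> np.ndarray:
    """Standardised Gaussian random field with correlation length ``corr``."""
    f = gaussian_filter(rng.standard_normal((size, size)), sigma=max(corr, 1e-9))
    sd = f.std()
    return f / sd if sd > 0 else f


def _ellipse_geometry(rng: np.random.Generator, size: int):
    """Random fillet-like ellipse: centre, semi-axes, orientation."""
    cy = size / 2 + rng.uniform(-0.03, 0.03) * size
    cx = size / 2 + rng.uniform(-0.03, 0.03) * size
    a = rng.uniform(0.34, 0.42) * size   # semi-axis (columns)
    b = rng.uniform(0.26, 0.34) * size   # semi-axis (rows)
    theta = rng.uniform(0, np.pi)
    return cy, cx, a, b, theta


def _ellipse_rho(size: int, geom) -> np.ndarray:
    """Normalised elliptical radius: <=1 inside the foreground."""
    cy, cx, a, b, theta = geom
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - cy, xx - cx
    xr = dx * np.cos(theta) + dy * np.sin(theta)
    yr = -dx * np.sin(theta) + dy * np.cos(theta)
    return np.sqrt((xr / a) ** 2 + (yr / b) ** 2)


# ---------------------------------------------------------------------------
# Liquid loss
# ---------------------------------------------------------------------------

def liquid_loss_percent(m0: float, mL: float) -> float:
    """Percent mass lost after freeze-thaw: 100 * (m0 - mL) / m0."""
    if m0 <= 0:
        raise DomainError("initial mass m0 must be > 0")
    if not 0 <= mL <= m0:
        raise DomainError("final mass mL must satisfy 0 <= mL <= m0")
    return 100.0 * (m0 - mL) / m0


def simulate_liquid_loss(
    damage_fraction: float, coupling: LLCoupling, rng: np.random.Generator
) -> float:
    """Draw a liquid-loss percentage coupled to the realised damage fraction."""
    if not 0.0 <= damage_fraction <= 1.0:
        raise DomainError("damage_fraction must lie in [0, 1]")
    ll = coupling.base + coupling.slope * damage_fraction
    if coupling.noise_sd > 0:
        ll += rng.normal(0.0, coupling.noise_sd)
    return float(np.clip(ll, 0.0, 100.0))


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

# Damaged area as a fraction of the foreground.  Each sample draws one
# damage *extent* (severity-scaled with biological spread between fillets);
# each slice realises that extent with mild jitter, and the mask keeps the
# top area-quantile of the smooth damage field, so every damaged slice of a
# treated sample carries damage while samples differ in how much.
_EXTENT_RANGE = (0.18, 0.50)    # severity-scaled foreground fraction damaged
_EXTENT_FLOOR = 0.05            # any treated sample shows some damage
_SLICE_JITTER = 0.10


def _sample_extent(severity: float, rng: np.random.Generator) -> float:
    if severity <= 0:
        return 0.0
    lo, hi = _EXTENT_RANGE
    return _EXTENT_FLOOR + severity * rng.uniform(lo, hi)


def _generate_sample(sample_id, severity, cfg: GeneratorConfig,
                     rng: np.random.Generator) -> SyntheticSample:
    size = cfg.image_size
    tex = cfg.texture_params
    geom = _ellipse_geometry(rng, size)
    rho = _ellipse_rho(size, geom)
    fg = (rho <= 1.0).astype(np.uint8)
    fg_f = fg.astype(float)
    # radial centre-bias kernel in [0,1]; center_bias=0 disables the bias
    kernel = np.exp(-cfg.center_bias * (rho / 0.7) ** 2)

    fresh_slices, damaged_slices = [], []
    truth_masks, foreground_masks, damage_fields = [], [], []
    fractions = []
    n_fg = int(fg.sum())
    extent = _sample_extent(severity, rng)
    for s in range(cfg.slices_per_sample):
        base = _smooth_field(rng, size, tex.correlation_length)
        tissue = 0.55 + tex.amplitude * base
        clean = tissue * fg_f + 0.04 * (1.0 - fg_f)

        raw = _smooth_field(rng, size, cfg.damage_field_smoothness)
        lo, hi = raw.min(), raw.max()
        grf01 = (raw - lo) / (hi - lo) if hi > lo else np.zeros_like(raw)
        dfield = grf01 * kernel                       # continuous, soft by design
        area = float(np.clip(extent * (1.0 + _SLICE_JITTER * rng.standard_normal()),
                             0.0, 0.95))
        if severity > 0 and area > 0:
            # keep the top area-quantile of the field inside the foreground
            thr = float(np.quantile(dfield[fg > 0], 1.0 - area))
            mask = ((dfield >= thr) & (fg > 0)).astype(np.uint8)
        else:
            thr = float("inf")
            mask = np.zeros_like(fg)
        # perturbation fades to zero at the mask boundary (soft edge) and is
        # exactly confined to the mask.  Its interior magnitude has a floor:
        # milder treatments damage *less area*, but tissue that is damaged
        # transforms visibly regardless of treatment severity
        excess = np.clip(dfield - thr, 0.0, None) * mask
        top = excess.max()
        if top > 0:
            excess = excess / top
        magnitude = 0.35 + 0.65 * severity if severity > 0 else 0.0
        blotch = _smooth_field(rng, size, 2.0 * tex.correlation_length)
        perturbed = clean * (1.0 + 0.3 * magnitude * excess)
        perturbed = perturbed + magnitude * excess * (0.40 + 0.20 * blotch) * fg_f

        if cfg.acquisition_noise_sd > 0:
            clean = clean + rng.normal(0.0, cfg.acquisition_noise_sd, clean.shape)
            perturbed = perturbed + rng.normal(0.0, cfg.acquisition_noise_sd, perturbed.shape)
        clean = np.clip(clean, 0.0, 1.0)
        perturbed = np.clip(perturbed, 0.0, 1.0)
        if cfg.quantize_12bit:
            clean = np.round(clean * 4095) / 4095
            perturbed = np.round(perturbed * 4095) / 4095

        fresh_slices.append(SliceImage(clean, sample_id, s, 0, severity))
        damaged_slices.append(SliceImage(perturbed, sample_id, s, 1, severity))
        truth_masks.append(mask)
        foreground_masks.append(fg.copy())
        damage_fields.append(dfield)
        fractions.append(mask.sum() / n_fg if n_fg else 0.0)

    damage_fraction = float(np.mean(fractions))
    ll = simulate_liquid_loss(damage_fraction, cfg.ll_coupling, rng)
    return SyntheticSample(
        sample_id=sample_id,
        treatment_level=severity,
        fresh_slices=fresh_slices,
        damaged_slices=damaged_slices,
        truth_masks=truth_masks,
        foreground_masks=foreground_masks,
        damage_fields=damage_fields,
        damage_fraction=damage_fraction,
        liquid_loss_pct=ll,
    )


def generate_dataset(cfg: GeneratorConfig) -> list:
    """Generate all samples of all treatment groups; deterministic in cfg.seed."""
    sizes = cfg.group_sizes()
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(sum(sizes))
    samples = []
    at = 0
    for gi, (severity, n) in enumerate(zip(cfg.treatment_levels, sizes)):
        for si in range(n):
            rng = np.random.default_rng(children[at])
            at += 1
            samples.append(_generate_sample(f"g{gi}s{si}", float(severity), cfg, rng))
    return samples


# ---------------------------------------------------------------------------
# Persistence: HDF5 + PNG export with JSON sidecar
# ---------------------------------------------------------------------------

def save_hdf5(samples: list, path) -> None:
    """Write images, masks and per-sample metadata to an HDF5 file."""
    import h5py

    with h5py.File(path, "w") as f:
        for s in samples:
            grp = f.create_group(s.sample_id)
            grp.attrs["treatment_level"] = s.treatment_level
            grp.attrs["damage_fraction"] = s.damage_fraction
            grp.attrs["liquid_loss_pct"] = s.liquid_loss_pct
            grp.create_dataset("fresh", data=np.stack([x.image for x in s.fresh_slices]),
                               compression="gzip")
            grp.create_dataset("damaged", data=np.stack([x.image for x in s.damaged_slices]),
                               compression="gzip")
            grp.create_dataset("truth_masks", data=np.stack(s.truth_masks),
                               compression="gzip")
            grp.create_dataset("foreground_masks", data=np.stack(s.foreground_masks),
                               compression="gzip")
            grp.create_dataset("damage_fields", data=np.stack(s.damage_fields),
                               compression="gzip")


def load_hdf5(path) -> list:
    import h5py

    samples = []
    with h5py.File(path, "r") as f:
        for sid in f:
            grp = f[sid]
            sev = float(grp.attrs["treatment_level"])
            fresh = [
                SliceImage(img, sid, i, 0, sev)
                for i, img in enumerate(np.asarray(grp["fresh"]))
            ]
            damaged = [
                SliceImage(img, sid, i, 1, sev)
                for i, img in enumerate(np.asarray(grp["damaged"]))
            ]
            samples.append(SyntheticSample(
                sample_id=sid,
                treatment_level=sev,
                fresh_slices=fresh,
                damaged_slices=damaged,
                truth_masks=list(np.asarray(grp["truth_masks"])),
                foreground_masks=list(np.asarray(grp["foreground_masks"])),
                damage_fields=list(np.asarray(grp["damage_fields"])),
                damage_fraction=float(grp.attrs["damage_fraction"]),
                liquid_loss_pct=float(grp.attrs["liquid_loss_pct"]),
            ))
    return samples


def export_png(samples: list, outdir) -> Path:
    """Per-slice 16-bit PNG export with a JSON metadata sidecar."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = []
    for s in samples:
        for sl in s.fresh_slices + s.damaged_slices:
            name = f"{s.sample_id}_slice{sl.slice_index:02d}_y{sl.y}.png"
            iio.imwrite(outdir / name, (sl.image * 65535).astype(np.uint16))
        meta.append({
            "sample_id": s.sample_id,
            "treatment_level": s.treatment_level,
            "damage_fraction": s.damage_fraction,
            "liquid_loss_pct": s.liquid_loss_pct,
            "n_slices": len(s.fresh_slices),
        })
    sidecar = outdir / "metadata.json"
    sidecar.write_text(json.dumps(meta, indent=2))
    return sidecar
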