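"""Synthetic hyperspectral liver-tissue phantom generator.

Emulates the statistical structure of 40x H&E brightfield hyperspectral
microscopy that the classification pipeline assumes, without any real data:

* transmittance endmembers in (0, 1] for five components — blank glass,
  normal/tumor background tissue (eosin-dominated) and normal/tumor cell
  nuclei (hematoxylin-dominated) — each tissue spectrum carrying the two
  characteristic H&E absorption dips near 540 nm and 650 nm;
* tumor-vs-normal spectral contrast controlled by a single knob ``delta``:
  dip centres shift by +/- 20*delta nm and tumor dips deepen by a factor
  (1 + 0.5*delta), so ``delta = 0`` makes the classes spectrally identical
  (the negative control);
* optional metameric mode (default on) that projects the tumor-minus-normal
  difference onto the orthogonal complement of the Gaussian RGB synthesis
  weights, so the class contrast is purely spectral: invisible to the
  synthesized RGB channels by construction while remaining obvious at full
  band resolution;
* nucleus disks 12-18 px in diameter at 0.55 um/px, a blank-glass strip, and
  additive band-wise Gaussian noise;
* a case-level split design of 1 healthy + 9 unhealthy cases per split with
  two sample images per case (6 healthy vs 54 unhealthy samples over 30
  cases in total), matching the imbalance the focal loss is meant to handle.

Spatial texture statistics are identical across classes by default so that
HSI-vs-RGB and 3D-vs-2D comparisons isolate spectral information; a per-class
nucleus-density override provides a combined spectral+spatial signal when
wanted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, ParameterError
from .hsi_io import HyperspectralCube, WavelengthGrid, write_envi_cube
from .preprocess import rgb_weights

__all__ = [
    "COMPONENTS",
    "MASK_CODES",
    "CaseEffect",
    "EndmemberSpectrum",
    "PhantomConfig",
    "PhantomSample",
    "PhantomDataset",
    "endmember_library",
    "render_tissue_cube",
    "generate_dataset",
]

COMPONENTS = ("glass", "normal_background", "normal_cell", "tumor_background", "tumor_cell")
MASK_CODES = {name: code for code, name in enumerate(COMPONENTS)}

# Dip geometry shared by all tissue endmembers: (centre nm, sigma nm).
_DIPS = ((540.0, 12.0), (650.0, 14.0))
# Dip depths per tissue component at delta = 0: eosin-rich background shows
# the strong 540 nm dip, hematoxylin-rich nuclei absorb more around 650 nm.
_DIP_DEPTHS = {
    "background": (0.18, 0.12),
    "cell": (0.10, 0.15),
}


@dataclass(frozen=True)
class EndmemberSpectrum:
    """A pure-component transmittance spectrum sampled on a band grid."""

    component: str
    values: np.ndarray


@dataclass(frozen=True)
class CaseEffect:
    """Per-case (per-patient) spectral idiosyncrasy, shared by both sample
    images of a case: dip-depth scaling, small dip-centre offsets and a
    baseline tilt.  Emulates biological/staining variability, which is what
    makes generalization to held-out cases non-trivial."""

    depth_scale: np.ndarray  # (2 kinds, 2 dips), positive
    center_off_nm: np.ndarray  # (2 dips,)
    tilt: tuple[float, float] = (0.0, 0.0)  # baseline offset, slope

    @classmethod
    def none(cls) -> "CaseEffect":
        return cls(depth_scale=np.ones((2, 2)), center_off_nm=np.zeros(2))

    @classmethod
    def draw(cls, cfg: "PhantomConfig", rng: np.random.Generator) -> "CaseEffect":
        return cls(
            depth_scale=np.exp(rng.normal(0.0, cfg.case_depth_jitter, (2, 2))),
            center_off_nm=rng.normal(0.0, cfg.case_center_jitter_nm, 2),
            tilt=(rng.normal(0.0, cfg.case_tilt_sd), rng.normal(0.0, cfg.case_tilt_sd)),
        )


def _tissue_spectrum(
    centers: np.ndarray,
    kind: str,
    shift_nm: float,
    depth_factor: float,
    case: CaseEffect,
) -> np.ndarray:
    u = (centers - 400.0) / 400.0
    base = (0.60 + 0.10 * u) if kind == "background" else (0.42 + 0.08 * u)
    out = base + case.tilt[0] + case.tilt[1] * u
    kind_idx = 0 if kind == "background" else 1
    for d, ((mu, sigma), depth) in enumerate(zip(_DIPS, _DIP_DEPTHS[kind])):
        centre = mu + shift_nm + case.center_off_nm[d]
        scale = depth_factor * case.depth_scale[kind_idx, d]
        out -= depth * scale * np.exp(-((centers - centre) ** 2) / (2 * sigma**2))
    return out


def endmember_library(
    delta: float,
    grid: WavelengthGrid | np.ndarray,
    metameric: bool = True,
    case: CaseEffect | None = None,
) -> dict[str, EndmemberSpectrum]:
    """Build the five component spectra for a given spectral contrast ``delta``.

    ``delta < 0`` is a parameter error; ``delta = 0`` degenerates to tumor
    and normal components being identical.  With ``metameric`` the tumor
    spectra are adjusted so their synthesized RGB equals the normal ones
    exactly, leaving a contrast only a full-spectrum observer can see.  An
    optional :class:`CaseEffect` perturbs both class variants coherently.
    """
    if delta < 0:
        raise ParameterError(f"spectral contrast delta must be >= 0, got {delta}")
    case = case or CaseEffect.none()
    centers = grid.centers if isinstance(grid, WavelengthGrid) else np.asarray(grid, dtype=float)
    shift = 20.0 * delta
    u = (centers - 400.0) / 400.0
    spectra = {"glass": 0.95 + 0.01 * u}
    for kind in ("background", "cell"):
        normal = _tissue_spectrum(centers, kind, -shift, 1.0, case)
        tumor = _tissue_spectrum(centers, kind, +shift, 1.0 + 0.5 * delta, case)
        if metameric and delta > 0:
            w = rgb_weights(centers)
            q, _ = np.linalg.qr(w.T)  # orthonormal basis of the RGB weight span
            diff = tumor - normal
            tumor = normal + diff - q @ (q.T @ diff)
        spectra[f"normal_{kind}"] = normal
        spectra[f"tumor_{kind}"] = tumor
    return {name: EndmemberSpectrum(name, np.clip(vals, 1e-4, 1.0)) for name, vals in spectra.items()}


@dataclass(frozen=True)
class PhantomConfig:
    """Scene geometry, spectral contrast and split design of the phantom.

    Defaults are the desk-scale study conditions: 64 x 64 px sample images on
    a 30-band 400-800 nm grid, nuclei 12-18 px wide at 0.55 um/px, a 10%
    blank-glass strip, class contrast ``delta = 0.4``, mild case-level
    spectral variability, per-image band noise, and three case-disjoint
    splits of 1 healthy + 9 unhealthy cases with two sample images each.
    """

    height: int = 64
    width: int = 64
    n_bands: int = 30
    wavelength_range: tuple[float, float] = (400.0, 800.0)
    nucleus_diameter_px: tuple[int, int] = (12, 18)
    nucleus_fraction: float = 0.30
    nucleus_fraction_unhealthy: float | None = None  # spatial-contrast knob
    blank_fraction: float = 0.10
    delta: float = 0.4
    noise_sd: float = 0.02
    band_noise_sd: float = 0.01  # per-image, per-band offset (sensor banding)
    case_depth_jitter: float = 0.12
    case_center_jitter_nm: float = 1.0
    case_tilt_sd: float = 0.003
    metameric: bool = True
    cases_per_split: tuple[int, int] = (1, 9)  # (healthy, unhealthy)
    n_splits: int = 3
    samples_per_case: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.blank_fraction <= 1.0 or not 0.0 <= self.nucleus_fraction <= 1.0:
            raise ConfigError("fractions must lie in [0, 1]")
        if self.nucleus_diameter_px[1] > min(self.height, self.width):
            raise ConfigError("nucleus diameter exceeds the image")
        if self.delta < 0 or self.noise_sd < 0:
            raise ConfigError("delta and noise_sd must be non-negative")
        if self.n_splits != 3:
            raise ConfigError("the split design partitions cases into exactly 3 splits")

    @property
    def wavelengths(self) -> WavelengthGrid:
        lo, hi = self.wavelength_range
        return WavelengthGrid(np.linspace(lo, hi, self.n_bands))


@dataclass
class PhantomSample:
    cube: HyperspectralCube
    mask: np.ndarray
    case_id: str
    label: str
    split: str


@dataclass
class PhantomDataset:
    samples: list[PhantomSample]
    config: PhantomConfig

    def __len__(self) -> int:
        return len(self.samples)

    def cases(self) -> list[tuple[str, str]]:
        seen: dict[str, str] = {}
        for s in self.samples:
            seen.setdefault(s.case_id, s.label)
        return sorted(seen.items())

    def split_of(self) -> dict[str, str]:
        return {s.case_id: s.split for s in self.samples}

    def by_split(self, split: str) -> list[PhantomSample]:
        return [s for s in self.samples if s.split == split]

    def write(self, directory: str | Path) -> Path:
        """Persist cubes + masks as ENVI rasters with a CSV manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = []
        for i, s in enumerate(self.samples):
            stem = f"{s.case_id}_s{i % self.config.samples_per_case}"
            write_envi_cube(s.cube, directory / f"{stem}.raw")
            mask_cube = HyperspectralCube(
                values=s.mask[:, :, None].astype(np.int16),
                wavelengths=WavelengthGrid([1.0]),
            )
            write_envi_cube(mask_cube, directory / f"{stem}_mask.raw")
            rows.append(
                {"case_id": s.case_id, "label": s.label, "split": s.split, "path": f"{stem}.raw"}
            )
        manifest = directory / "manifest.csv"
        pd.DataFrame(rows).to_csv(manifest, index=False)
        return manifest


def render_tissue_cube(
    cfg: PhantomConfig,
    label: str,
    case_id: str,
    rng: np.random.Generator,
    case: CaseEffect | None = None,
) -> tuple[HyperspectralCube, np.ndarray]:
    """Render one sample image: background canvas, nucleus disks, glass strip.

    Returns the calibrated-transmittance cube and an integer component mask
    (codes per :data:`MASK_CODES`).  Identical generator state yields
    bit-identical output.
    """
    h, w = cfg.height, cfg.width
    lo_d, hi_d = cfg.nucleus_diameter_px
    if hi_d > min(h, w):
        raise ConfigError("nucleus diameter exceeds the image")
    prefix = "tumor" if label == "unhealthy" else "normal"
    frac = cfg.nucleus_fraction
    if label == "unhealthy" and cfg.nucleus_fraction_unhealthy is not None:
        frac = cfg.nucleus_fraction_unhealthy

    mask = np.full((h, w), MASK_CODES[f"{prefix}_background"], dtype=np.int16)
    mean_diameter = 0.5 * (lo_d + hi_d)
    mean_area = np.pi * (mean_diameter / 2.0) ** 2
    n_nuclei = int(round(frac * h * w / mean_area))
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n_nuclei):
        d = rng.uniform(lo_d, hi_d)
        cy = rng.uniform(d / 2, h - d / 2)
        cx = rng.uniform(d / 2, w - d / 2)
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= (d / 2.0) ** 2
        mask[disk] = MASK_CODES[f"{prefix}_cell"]
    glass_cols = int(round(cfg.blank_fraction * w))
    if glass_cols:
        mask[:, :glass_cols] = MASK_CODES["glass"]

    grid = cfg.wavelengths
    library = endmember_library(cfg.delta, grid, metameric=cfg.metameric, case=case)
    palette = np.stack([library[name].values for name in COMPONENTS])
    values = palette[mask]
    if cfg.band_noise_sd > 0:
        values = values + rng.normal(0.0, cfg.band_noise_sd, cfg.n_bands)
    if cfg.noise_sd > 0:
        values = values + rng.normal(0.0, cfg.noise_sd, values.shape)
    values = np.clip(values, 1e-4, 1.0).astype(np.float32)
    cube = HyperspectralCube(values=values, wavelengths=grid, calibrated=True)
    return cube, mask


def generate_dataset(cfg: PhantomConfig | None = None) -> PhantomDataset:
    """Emit the full case/sample collection with case-disjoint splits.

    The default configuration produces 60 sample cubes over 30 cases: each of
    the train/val/test splits holds 1 healthy and 9 unhealthy cases with two
    sample images per case (2 healthy + 18 unhealthy samples per split).
    """
    cfg = cfg or PhantomConfig()
    rng = np.random.default_rng(cfg.seed)
    samples: list[PhantomSample] = []
    case_idx = 0
    for split in ("train", "val", "test"):
        n_healthy, n_unhealthy = cfg.cases_per_split
        for label, count in (("healthy", n_healthy), ("unhealthy", n_unhealthy)):
            for _ in range(count):
                case_id = f"case{case_idx:02d}"
                case_idx += 1
                case_effect = CaseEffect.draw(cfg, rng)
                for _ in range(cfg.samples_per_case):
                    cube, mask = render_tissue_cube(cfg, label, case_id, rng, case=case_effect)
                    samples.append(PhantomSample(cube, mask, case_id, label, split))
    return PhantomDataset(samples=samples, config=cfg)
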