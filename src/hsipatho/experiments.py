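"""Experiment orchestration: case-level splits, spectral variants, grids.

Runs the full pipeline — calibrate (when raw), band-window, reduce, tile,
blank-filter, train, evaluate — under a declarative configuration, with two
hard guarantees enforced by construction and by runtime checks:

* case-level split hygiene: every case sits in exactly one of train/val/test
  and any overlap raises :class:`~hsipatho.errors.LeakageError`;
* no fitted component sees validation or test data: the PCA basis is fitted
  on training-split pixel spectra only, and blank thresholds are computed
  per source image (an unsupervised, image-local statistic).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError, LeakageError, SplitError
from .hsi_io import HyperspectralCube, calibrate_reflectance, crop_band_window
from .metrics import MetricsReport, compute_metrics, confusion_from_labels
from .model import (
    FocalLossParams,
    TopologySpec,
    TrainConfig,
    build_classifier,
    predict_patches,
    train_classifier,
)
from .phantom import PhantomDataset, PhantomSample
from .preprocess import (
    PatchSet,
    blank_fraction,
    blank_threshold,
    extract_patches,
    fit_pca,
    sample_bands,
    synthesize_rgb,
)

__all__ = [
    "SplitPlan",
    "ExperimentConfig",
    "ExperimentResult",
    "split_by_case",
    "rotate_splits",
    "run_experiment",
    "run_grid",
]

ROLES = ("train", "val", "test")


@dataclass(frozen=True)
class SplitPlan:
    """Assignment of every case id to exactly one of train/val/test."""

    assignment: dict[str, str]
    rotation_index: int = 1

    def __post_init__(self) -> None:
        bad = {c: r for c, r in self.assignment.items() if r not in ROLES}
        if bad:
            raise ConfigError(f"invalid roles in split plan: {bad}")

    def cases(self, role: str) -> set[str]:
        return {c for c, r in self.assignment.items() if r == role}


def split_by_case(
    cases: list[tuple[str, str]],
    counts: dict[str, tuple[int, int]] | None = None,
    seed: int = 0,
) -> SplitPlan:
    """Randomly assign cases to splits under (healthy, unhealthy) count constraints.

    ``counts`` maps each role to its (healthy, unhealthy) case counts and
    defaults to 1 + 9 per split.  The counts must partition the case list
    exactly; fewer than 3 cases is a split error.
    """
    if len(cases) < 3:
        raise SplitError(f"need at least 3 cases to split, got {len(cases)}")
    counts = counts or {role: (1, 9) for role in ROLES}
    healthy = [c for c, lab in cases if lab == "healthy"]
    unhealthy = [c for c, lab in cases if lab != "healthy"]
    need_h = sum(v[0] for v in counts.values())
    need_u = sum(v[1] for v in counts.values())
    if need_h != len(healthy) or need_u != len(unhealthy):
        raise ConfigError(
            f"split counts need {need_h} healthy / {need_u} unhealthy cases, "
            f"dataset has {len(healthy)} / {len(unhealthy)}"
        )
    rng = np.random.default_rng(seed)
    rng.shuffle(healthy)
    rng.shuffle(unhealthy)
    assignment: dict[str, str] = {}
    ih = iu = 0
    for role in ROLES:
        nh, nu = counts[role]
        for c in healthy[ih : ih + nh]:
            assignment[c] = role
        for c in unhealthy[iu : iu + nu]:
            assignment[c] = role
        ih, iu = ih + nh, iu + nu
    return SplitPlan(assignment=assignment)


def rotate_splits(plan: SplitPlan) -> list[SplitPlan]:
    """The three cyclic role rotations train -> val -> test -> train."""
    cycle = {"train": "val", "val": "test", "test": "train"}
    plans = [replace(plan, rotation_index=1)]
    current = plan.assignment
    for i in (2, 3):
        current = {c: cycle[r] for c, r in current.items()}
        plans.append(SplitPlan(assignment=current, rotation_index=i))
    return plans


@dataclass(frozen=True)
class ExperimentConfig:
    """One cell of the experiment grid.

    ``variant`` names the spectral representation: ``HSI`` (full bands),
    ``HSI-<k>`` (constant-stride sampling to k bands), ``PCA-<n>`` (n
    principal components) or ``RGB`` (Gaussian-synthesized channels).
    """

    variant: str = "HSI"
    patch_size: int = 16
    loss: FocalLossParams = field(default_factory=FocalLossParams)
    conv: str = "3d"  # "3d" | "2d"
    train: TrainConfig = field(default_factory=TrainConfig.desk)
    seed: int = 0
    max_blank: float = 0.5
    band_window: tuple[float, float] = (400.0, 800.0)
    standardize: bool = False  # optional per-band z-scoring fitted on the training split

    def __post_init__(self) -> None:
        if self.conv not in ("3d", "2d"):
            raise ConfigError(f"conv variant must be '2d' or '3d', got {self.conv!r}")
        if not re.fullmatch(r"HSI(-\d+)?|PCA-\d+|RGB", self.variant):
            raise ConfigError(f"unknown dataset variant {self.variant!r}")

    def describe(self) -> dict:
        return {
            "variant": self.variant,
            "patch_size": self.patch_size,
            "conv": self.conv,
            "gamma": self.loss.gamma,
            "alpha": self.loss.alpha,
            "balanced": self.loss.balanced,
            "epochs": self.train.epochs,
            "seed": self.seed,
        }


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    metrics: dict[str, MetricsReport]
    history: pd.DataFrame
    n_patches: dict[str, int]
    removed_blank: int

    def as_row(self) -> dict:
        row = self.config.describe()
        row["removed_blank"] = self.removed_blank
        for split, report in self.metrics.items():
            for name, value in report.__dict__.items():
                row[f"{split}_{name}"] = value
        return row


def _reduce_cube(cube: HyperspectralCube, cfg: ExperimentConfig, pca_model) -> np.ndarray:
    if cfg.variant == "HSI":
        return cube.values
    if cfg.variant.startswith("HSI-"):
        return sample_bands(cube, int(cfg.variant.split("-")[1])).values
    if cfg.variant.startswith("PCA-"):
        from .preprocess import apply_pca

        return apply_pca(pca_model, cube.values)
    return synthesize_rgb(cube)


def _prepare_patchsets(
    data: PhantomDataset, plan: SplitPlan, cfg: ExperimentConfig, pca_model
) -> tuple[dict[str, PatchSet], int]:
    per_role: dict[str, list] = {role: [] for role in ROLES}
    removed = 0
    for sample in data.samples:
        role = plan.assignment.get(sample.case_id)
        if role is None:
            raise ConfigError(f"case {sample.case_id} missing from the split plan")
        cube = crop_band_window(sample.cube, *cfg.band_window)
        threshold = blank_threshold(cube)  # image-local, unsupervised
        intensity = cube.values.mean(axis=-1)
        reduced = _reduce_cube(cube, cfg, pca_model)
        patches = extract_patches(reduced, cfg.patch_size, sample.case_id, sample.label)
        gates = extract_patches(intensity[:, :, None], cfg.patch_size)
        for patch, gate in zip(patches, gates):
            if blank_fraction(gate.values, threshold) > cfg.max_blank:
                removed += 1
            else:
                per_role[role].append(patch)
    sets = {}
    for role in ROLES:
        if not per_role[role]:
            raise ConfigError(f"no patches left in the {role} split")
        sets[role] = PatchSet.from_patches(per_role[role])
    return sets, removed


def run_experiment(
    cfg: ExperimentConfig,
    data: PhantomDataset,
    plan: SplitPlan | None = None,
    calibration=None,
) -> ExperimentResult:
    """Run one configuration end to end and evaluate on held-out cases.

    The split plan defaults to the dataset's own case-disjoint assignment.
    Test metrics are computed once, from the final model.
    """
    if calibration is not None:
        data = PhantomDataset(
            samples=[
                PhantomSample(
                    calibrate_reflectance(s.cube, calibration), s.mask, s.case_id, s.label, s.split
                )
                for s in data.samples
            ],
            config=data.config,
        )
    if plan is None:
        plan = SplitPlan(assignment=data.split_of())
    for a, b in (("train", "val"), ("train", "test"), ("val", "test")):
        overlap = plan.cases(a) & plan.cases(b)
        if overlap:
            raise LeakageError(f"cases {sorted(overlap)} shared between {a} and {b}")

    pca_model = None
    if cfg.variant.startswith("PCA-"):
        n_comp = int(cfg.variant.split("-")[1])
        train_cubes = [
            crop_band_window(s.cube, *cfg.band_window).values
            for s in data.samples
            if plan.assignment[s.case_id] == "train"
        ]
        pca_model = fit_pca(train_cubes, n_components=n_comp)

    sets, removed = _prepare_patchsets(data, plan, cfg, pca_model)
    if cfg.standardize:
        # per-band standardization, fitted on training patches only
        mean = sets["train"].values.mean(axis=(0, 1, 2))
        std = sets["train"].values.std(axis=(0, 1, 2)) + 1e-8
        for role in ROLES:
            sets[role] = PatchSet(
                (sets[role].values - mean) / std,
                sets[role].labels,
                sets[role].case_ids,
                sets[role].origins,
            )
    s = cfg.patch_size
    bands = sets["train"].values.shape[-1]
    train_cfg = replace(cfg.train, seed=cfg.seed, patch_size=s, n_bands=bands)
    spec = (
        TopologySpec.default_3d(bands) if cfg.conv == "3d" else TopologySpec.default_2d()
    )
    network = build_classifier(spec, cfg.conv, (s, s, bands), seed=cfg.seed)
    network, history = train_classifier(network, sets["train"], sets["val"], cfg.loss, train_cfg)

    metrics: dict[str, MetricsReport] = {}
    for role in ("val", "test"):
        labels, _ = predict_patches(network, sets[role])
        metrics[role] = compute_metrics(confusion_from_labels(sets[role].labels, labels))
    return ExperimentResult(
        config=cfg,
        metrics=metrics,
        history=history,
        n_patches={role: len(sets[role]) for role in ROLES},
        removed_blank=removed,
    )


def run_grid(
    configs: list[ExperimentConfig], data: PhantomDataset, plan: SplitPlan | None = None
) -> pd.DataFrame:
    """One result row per configuration; failures are recorded, not fatal."""
    if not configs:
        raise InputError("empty experiment grid")
    rows = []
    for cfg in configs:
        try:
            rows.append(run_experiment(cfg, data, plan=plan).as_row())
        except Exception as exc:  # partial failures keep the grid going
            rows.append({**cfg.describe(), "error": f"{type(exc).__name__}: {exc}"})
    return pd.DataFrame(rows)
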