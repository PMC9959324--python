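"""Patch tiling, blank-glass rejection and spectral dimensionality reduction.

Four spectral representations of a calibrated cube are supported, mirroring
the comparisons the pipeline is built for:

* full spectrum (no reduction),
* constant-stride band sampling (``sample_bands``),
* incremental PCA over pixel spectra (``fit_pca`` / ``apply_pca``),
* Gaussian-weighted RGB synthesis (``synthesize_rgb``), with channel means
  630/540/480 nm and a 25 nm standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from sklearn.decomposition import IncrementalPCA

from .errors import EmptySelectionError, InputError, RankError, ShapeError, SizeError
from .hsi_io import HyperspectralCube, WavelengthGrid

__all__ = [
    "Patch",
    "PatchSet",
    "ReducerSpec",
    "PcaModel",
    "extract_patches",
    "blank_threshold",
    "blank_fraction",
    "filter_blank_patches",
    "sample_bands",
    "select_components",
    "fit_pca",
    "apply_pca",
    "rgb_weights",
    "synthesize_rgb",
    "save_patchset",
    "load_patchset",
    "patch_manifest",
    "RGB_MEANS_NM",
    "RGB_SD_NM",
]

#: Channel means (R, G, B) and shared standard deviation, in nm, of the
#: Gaussian band-synthesis weights.
RGB_MEANS_NM: tuple[float, float, float] = (630.0, 540.0, 480.0)
RGB_SD_NM: float = 25.0

Label = Literal["healthy", "unhealthy"]


@dataclass
class Patch:
    """An ``S x S x B`` sub-cube with provenance and a tissue-level label."""

    values: np.ndarray
    origin: tuple[int, int]
    case_id: str
    label: Label

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or self.values.shape[0] != self.values.shape[1]:
            raise ShapeError(f"patch values must be S x S x B, got {self.values.shape}")

    @property
    def size(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]


@dataclass
class PatchSet:
    """A stack of same-sized patches with labels and case identifiers.

    ``y`` encodes the positive (unhealthy/tumor) class as 1.
    """

    values: np.ndarray  # (N, S, S, B)
    labels: np.ndarray  # (N,) of {"healthy", "unhealthy"}
    case_ids: np.ndarray  # (N,) of str
    origins: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.labels = np.asarray(self.labels)
        self.case_ids = np.asarray(self.case_ids)
        if self.origins is None:
            self.origins = np.zeros((len(self.labels), 2), dtype=int)
        if self.values.ndim != 4:
            raise ShapeError(f"PatchSet values must be (N, S, S, B), got {self.values.shape}")
        n = self.values.shape[0]
        if not (len(self.labels) == len(self.case_ids) == n):
            raise InputError("labels/case_ids length must match the number of patches")

    @classmethod
    def from_patches(cls, patches: Sequence[Patch]) -> "PatchSet":
        if not patches:
            raise InputError("cannot build a PatchSet from zero patches")
        return cls(
            values=np.stack([p.values for p in patches]),
            labels=np.array([p.label for p in patches]),
            case_ids=np.array([p.case_id for p in patches]),
            origins=np.array([p.origin for p in patches]),
        )

    @property
    def y(self) -> np.ndarray:
        return (self.labels == "unhealthy").astype(int)

    def __len__(self) -> int:
        return self.values.shape[0]

    def cases(self) -> set[str]:
        return set(self.case_ids.tolist())

    def subset(self, mask: np.ndarray) -> "PatchSet":
        return PatchSet(self.values[mask], self.labels[mask], self.case_ids[mask], self.origins[mask])


@dataclass
class ReducerSpec:
    """Which spectral representation to produce and with what parameters."""

    mode: Literal["full", "sample", "pca", "rgb"] = "full"
    k: int | None = None
    n_components: int | None = None
    variance_threshold: float | None = None
    rgb_means: tuple[float, float, float] = RGB_MEANS_NM
    rgb_sd: float = RGB_SD_NM

    def __post_init__(self) -> None:
        if self.mode == "sample" and (self.k is None or self.k < 1):
            raise InputError("sample mode requires k >= 1")
        if self.variance_threshold is not None and not 0 < self.variance_threshold < 1:
            raise InputError("variance_threshold must lie in (0, 1)")
        if self.rgb_sd <= 0:
            raise InputError("rgb_sd must be positive")


def _values_of(obj) -> np.ndarray:
    if isinstance(obj, (HyperspectralCube, Patch)):
        return obj.values
    return np.asarray(obj)


def extract_patches(
    cube: HyperspectralCube | np.ndarray,
    S: int,
    case_id: str = "",
    label: Label = "unhealthy",
) -> list[Patch]:
    """Tile the cube into non-overlapping ``S x S`` patches in row-major order.

    The grid is anchored at (0, 0) with stride ``S``; trailing rows/columns
    that do not fill a whole patch are discarded, so ``floor(H/S)*floor(W/S)``
    patches are returned.
    """
    values = _values_of(cube)
    h, w = values.shape[:2]
    if S < 1 or S > h or S > w:
        raise SizeError(f"patch size {S} incompatible with image {h} x {w}")
    patches = []
    for i in range(h // S):
        for j in range(w // S):
            patches.append(
                Patch(
                    values=values[i * S : (i + 1) * S, j * S : (j + 1) * S],
                    origin=(i * S, j * S),
                    case_id=case_id,
                    label=label,
                )
            )
    return patches


def blank_threshold(source: HyperspectralCube | np.ndarray) -> float:
    """Intensity threshold separating bright glass from absorbing tissue.

    Otsu's two-class threshold on the band-averaged calibrated image: blank
    glass transmits (bright), stained tissue absorbs (dark), so the histogram
    is bimodal and the threshold sits between the two modes.
    """
    mean_img = _values_of(source).mean(axis=-1)
    return float(threshold_otsu(mean_img))


def blank_fraction(patch: Patch | np.ndarray, threshold: float) -> float:
    """Fraction of pixels whose band-averaged transmittance exceeds ``threshold``."""
    mean_img = _values_of(patch).mean(axis=-1)
    return float(np.mean(mean_img > threshold))


def filter_blank_patches(
    patches: Sequence[Patch],
    max_blank: float = 0.5,
    threshold: float | None = None,
) -> tuple[list[Patch], int]:
    """Drop patches with *more than* ``max_blank`` blank area (strict inequality).

    When ``threshold`` is not given it is derived with :func:`blank_threshold`
    from the pooled pixels of the supplied patches.  Order is preserved.
    """
    if not patches:
        return [], 0
    if threshold is None:
        pooled = np.concatenate([p.values.reshape(-1, p.n_bands) for p in patches])
        threshold = blank_threshold(pooled.reshape(1, -1, patches[0].n_bands))
    kept = [p for p in patches if blank_fraction(p, threshold) <= max_blank]
    return kept, len(patches) - len(kept)


def sample_bands(obj, k: int):
    """Constant-stride band subsampling: stride ``floor(B/k)``, phase 0.

    Bands at indices ``i * stride`` for ``i = 0..k-1`` are retained; for a
    cube the wavelength grid is cropped in lockstep.  The input type is
    preserved.
    """
    values = _values_of(obj)
    B = values.shape[-1]
    if not 1 <= k <= B:
        raise EmptySelectionError(f"cannot sample {k} bands from {B}")
    stride = B // k
    idx = np.arange(k) * stride
    out = values[..., idx]
    if isinstance(obj, HyperspectralCube):
        return HyperspectralCube(
            values=out,
            wavelengths=WavelengthGrid(obj.wavelengths.centers[idx]),
            calibrated=obj.calibrated,
        )
    if isinstance(obj, Patch):
        return Patch(values=out, origin=obj.origin, case_id=obj.case_id, label=obj.label)
    return out


@dataclass
class PcaModel:
    """Mean spectrum plus orthonormal components over pixel spectra."""

    mean: np.ndarray
    components: np.ndarray  # (n_components, B)
    explained_variance_ratio: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.components = np.asarray(self.components, dtype=float)
        self.explained_variance_ratio = np.asarray(self.explained_variance_ratio, dtype=float)
        ratios = self.explained_variance_ratio
        if np.any(np.diff(ratios) > 1e-9) or np.any(ratios < -1e-12) or ratios.sum() > 1 + 1e-9:
            raise InputError("explained-variance ratios must be non-increasing, in [0,1], sum <= 1")
        gram = self.components @ self.components.T
        if not np.allclose(gram, np.eye(len(self.components)), atol=1e-6):
            raise InputError("components must be mutually orthonormal")

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    @property
    def n_bands(self) -> int:
        return self.components.shape[1]


def select_components(ratios: np.ndarray, variance_threshold: float) -> int:
    """Number of leading components whose explained-variance ratio meets the threshold."""
    ratios = np.asarray(ratios, dtype=float)
    below = np.nonzero(ratios < variance_threshold)[0]
    return int(below[0]) if below.size else len(ratios)


def _pixel_spectra(data) -> np.ndarray:
    if isinstance(data, PatchSet):
        return data.values.reshape(-1, data.values.shape[-1])
    if isinstance(data, (HyperspectralCube, Patch)):
        return data.values.reshape(-1, data.values.shape[-1])
    if isinstance(data, (list, tuple)):
        return np.concatenate([_pixel_spectra(d) for d in data])
    arr = np.asarray(data)
    return arr.reshape(-1, arr.shape[-1])


def fit_pca(
    training_data,
    variance_threshold: float | None = None,
    n_components: int | None = None,
    chunk_size: int = 4096,
) -> PcaModel:
    """Incremental PCA over training-split pixel spectra.

    Each pixel is one length-B observation; fitting is chunked (default 4096
    spectra) so arbitrarily large training sets stream through.  Components
    are retained while their explained-variance ratio is ``>= variance_threshold``
    or, when ``n_components`` is given, exactly that many.
    """
    X = _pixel_spectra(training_data).astype(np.float64, copy=False)
    n_obs, B = X.shape
    if n_obs < 2:
        raise RankError("PCA requires at least 2 pixel spectra")
    max_rank = min(n_obs, B)
    if n_components is not None and n_components > max_rank:
        raise RankError(f"requested {n_components} components from rank-{max_rank} data")
    ipca = IncrementalPCA(n_components=max_rank, batch_size=max(chunk_size, max_rank))
    ipca.fit(X)
    ratios = ipca.explained_variance_ratio_
    if n_components is not None:
        keep = n_components
    elif variance_threshold is not None:
        keep = max(1, select_components(ratios, variance_threshold))
    else:
        keep = max_rank
    return PcaModel(
        mean=ipca.mean_,
        components=ipca.components_[:keep],
        explained_variance_ratio=ratios[:keep],
    )


def apply_pca(model: PcaModel, obj):
    """Project every pixel spectrum onto the retained components.

    Spatial layout is unchanged; the band axis becomes ``n_components``
    pseudo-bands of PCA scores.  The input type is preserved (cubes get a
    nominal 1..k pseudo-wavelength grid).
    """
    values = _values_of(obj)
    if values.shape[-1] != model.n_bands:
        raise ShapeError(
            f"data has {values.shape[-1]} bands but the PCA model expects {model.n_bands}"
        )
    flat = values.reshape(-1, model.n_bands)
    scores = (flat - model.mean) @ model.components.T
    out = scores.reshape(values.shape[:-1] + (model.n_components,))
    if isinstance(obj, HyperspectralCube):
        return HyperspectralCube(
            values=out,
            wavelengths=WavelengthGrid(np.arange(1, model.n_components + 1, dtype=float)),
            calibrated=False,
        )
    if isinstance(obj, Patch):
        return Patch(values=out, origin=obj.origin, case_id=obj.case_id, label=obj.label)
    return out


def rgb_weights(
    grid: WavelengthGrid | np.ndarray,
    means: tuple[float, float, float] = RGB_MEANS_NM,
    sd: float = RGB_SD_NM,
) -> np.ndarray:
    """Gaussian channel weights, one row per (R, G, B), normalized to unit sum.

    Unit-sum normalization makes a spectrally flat input map onto itself.  A
    warning is emitted when the grid does not reach a channel mean +/- 3 sd;
    the channel is still computed over the available support.
    """
    centers = grid.centers if isinstance(grid, WavelengthGrid) else np.asarray(grid, dtype=float)
    weights = np.empty((3, centers.size))
    for c, mu in enumerate(means):
        if centers.min() > mu - 3 * sd or centers.max() < mu + 3 * sd:
            warnings.warn(
                f"wavelength grid [{centers.min()}, {centers.max()}] nm does not cover "
                f"{mu} +/- {3 * sd} nm; channel computed over available support",
                stacklevel=2,
            )
        w = np.exp(-((centers - mu) ** 2) / (2.0 * sd**2))
        weights[c] = w / w.sum()
    return weights


def synthesize_rgb(obj, grid: WavelengthGrid | np.ndarray | None = None):
    """Collapse the spectrum into 3 synthesized (R, G, B) channels.

    Channel ``c`` is the weight-averaged spectrum under a Gaussian centred at
    630/540/480 nm with a 25 nm standard deviation.  Cubes must carry their
    own grid; plain arrays and patches need ``grid``.
    """
    if isinstance(obj, HyperspectralCube):
        grid = obj.wavelengths
    if grid is None:
        raise InputError("synthesize_rgb needs a wavelength grid for non-cube input")
    weights = rgb_weights(grid)
    values = _values_of(obj)
    if values.shape[-1] != weights.shape[1]:
        raise ShapeError("band count does not match the wavelength grid")
    out = np.tensordot(values, weights, axes=([-1], [1]))
    if isinstance(obj, Patch):
        return Patch(values=out, origin=obj.origin, case_id=obj.case_id, label=obj.label)
    return out


def save_patchset(patches: PatchSet, path: str | Path, fmt: str = "container") -> Path:
    """Persist a PatchSet either as one chunked .npz container (default) or as
    a directory of per-patch ENVI sub-cubes with a manifest."""
    from .hsi_io import HyperspectralCube, WavelengthGrid, write_envi_cube

    path = Path(path)
    if fmt == "container":
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(
            path,
            values=patches.values,
            labels=patches.labels,
            case_ids=patches.case_ids,
            origins=patches.origins,
        )
        return path
    if fmt == "envi":
        path.mkdir(parents=True, exist_ok=True)
        grid = WavelengthGrid(np.arange(1, patches.values.shape[-1] + 1, dtype=float))
        rows = []
        for i in range(len(patches)):
            stem = f"patch{i:05d}.raw"
            write_envi_cube(HyperspectralCube(patches.values[i], grid), path / stem)
            rows.append(
                {
                    "path": stem,
                    "label": patches.labels[i],
                    "case_id": patches.case_ids[i],
                    "origin_row": patches.origins[i][0],
                    "origin_col": patches.origins[i][1],
                }
            )
        pd.DataFrame(rows).to_csv(path / "patches.csv", index=False)
        return path
    raise InputError(f"unknown patch persistence format {fmt!r}")


def load_patchset(path: str | Path) -> PatchSet:
    """Load a PatchSet written by :func:`save_patchset` (either format)."""
    from .hsi_io import read_envi_cube

    path = Path(path)
    if path.is_dir():
        frame = pd.read_csv(path / "patches.csv")
        values = np.stack([read_envi_cube(path / p).values for p in frame["path"]])
        return PatchSet(
            values=values,
            labels=frame["label"].to_numpy(),
            case_ids=frame["case_id"].astype(str).to_numpy(),
            origins=frame[["origin_row", "origin_col"]].to_numpy(),
        )
    with np.load(path, allow_pickle=False) as data:
        return PatchSet(
            values=data["values"],
            labels=data["labels"],
            case_ids=data["case_ids"],
            origins=data["origins"],
        )


def patch_manifest(
    patches: Sequence[Patch],
    kept: Iterable[bool],
    source: str = "",
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Tabulate patch provenance (case, label, origin, kept flag) as CSV-ready rows."""
    rows = [
        {
            "case_id": p.case_id,
            "label": p.label,
            "source": source,
            "origin_row": p.origin[0],
            "origin_col": p.origin[1],
            "S": p.size,
            "kept": bool(k),
        }
        for p, k in zip(patches, kept)
    ]
    frame = pd.DataFrame(rows)
    if path is not None:
        frame.to_csv(path, index=False)
    return frame
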