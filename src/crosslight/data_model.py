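"""Core data containers and NIfTI-1/CSV input-output.

The unit of analysis is a :class:`LabeledDataset`: a samples x voxels matrix
with binary labels and the trial/run bookkeeping needed for leakage-free
cross-validation.  Voxels are mapped to matrix columns in a fixed, documented
order: a C-order scan of the in-mask voxel coordinates (``np.argwhere`` order),
0-based.  All volumetric files are NIfTI-1, handled by nibabel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "BrainMask",
    "LabeledDataset",
    "StandardizationParams",
    "AccuracyMap",
    "DegenerateFeatureWarning",
    "read_mask",
    "read_dataset",
    "write_dataset",
    "standardize_cross_domain",
    "write_map",
    "read_map",
]

META_COLUMNS = ("sample_id", "label", "trial_id", "run_id", "domain")

#: features with source standard deviation below this are treated as constant
DEGENERATE_SD = 1e-12


class DegenerateFeatureWarning(UserWarning):
    """Raised when a voxel has (near-)zero variance in the source domain."""


@dataclass
class BrainMask:
    """A 3-D binary brain mask on an isotropic voxel grid.

    Parameters
    ----------
    inside : ndarray of bool, shape (nx, ny, nz)
        True for voxels inside the brain.
    voxel_size_mm : float
        Isotropic voxel edge length in millimetres.
    affine : ndarray, shape (4, 4), optional
        Voxel-to-world affine.  Defaults to a diagonal scaling by the voxel
        size (axis-aligned grid at the stated resolution).
    """

    inside: np.ndarray
    voxel_size_mm: float = 3.0
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.inside = np.asarray(self.inside, dtype=bool)
        if self.inside.ndim != 3:
            raise ValueError("mask grid must be 3-D")
        if not self.inside.any():
            raise ValueError("mask contains no inside voxels")
        if not self.voxel_size_mm > 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.affine is None:
            self.affine = np.diag([self.voxel_size_mm] * 3 + [1.0])
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.inside.shape)

    @property
    def n_voxels(self) -> int:
        return int(self.inside.sum())

    @property
    def coords(self) -> np.ndarray:
        """In-mask voxel coordinates, C-order: the feature ordering."""
        return np.argwhere(self.inside)

    def feature_index_volume(self) -> np.ndarray:
        """Volume mapping voxel coordinate -> feature index (-1 outside)."""
        vol = np.full(self.shape, -1, dtype=np.int64)
        vol[self.inside] = np.arange(self.n_voxels)
        return vol


@dataclass
class LabeledDataset:
    """Samples x voxels data matrix plus labels and trial/run structure.

    ``domain`` tags the dataset as coming from the source distribution
    (e.g. perception) or the target distribution (e.g. imagery).
    ``voxel_index`` maps feature columns to 3-D voxel coordinates and is
    absent for pure-matrix (non-spatial) datasets.
    """

    X: np.ndarray
    y: np.ndarray
    trial_id: np.ndarray
    run_id: np.ndarray
    domain: str
    voxel_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.trial_id = np.asarray(self.trial_id, dtype=int)
        self.run_id = np.asarray(self.run_id, dtype=int)
        n = self.X.shape[0]
        if not (len(self.y) == len(self.trial_id) == len(self.run_id) == n):
            raise ValueError("metadata vectors must match n_samples")
        if self.domain not in ("source", "target"):
            raise ValueError("domain must be 'source' or 'target'")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("labels must be binary {0,1}")
        if len(np.unique(self.y)) < 2:
            raise ValueError("both classes must be present")
        for t in np.unique(self.trial_id):
            if len(np.unique(self.y[self.trial_id == t])) != 1:
                raise ValueError(f"trial {t} maps to more than one label")
        if self.voxel_index is not None:
            self.voxel_index = np.asarray(self.voxel_index, dtype=int)
            if self.voxel_index.shape != (self.X.shape[1], 3):
                raise ValueError("voxel_index must be (n_features, 3)")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        """Row subset without re-validating the both-classes invariant
        (train subsets produced by the splitter may transiently hold one
        class; estimators enforce their own preconditions)."""
        out = object.__new__(LabeledDataset)
        out.X = self.X[idx]
        out.y = self.y[idx]
        out.trial_id = self.trial_id[idx]
        out.run_id = self.run_id[idx]
        out.domain = self.domain
        out.voxel_index = self.voxel_index
        return out


@dataclass
class StandardizationParams:
    """Per-voxel mean and (population) standard deviation of the source."""

    mean: np.ndarray
    sd: np.ndarray
    degenerate: np.ndarray = field(default=None)  # boolean flags, sd < 1e-12

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if not (np.isfinite(self.mean).all() and np.isfinite(self.sd).all()):
            raise ValueError("standardization parameters must be finite")
        if (self.sd < 0).any():
            raise ValueError("sd must be nonnegative")
        if self.degenerate is None:
            self.degenerate = self.sd < DEGENERATE_SD


@dataclass
class AccuracyMap:
    """Per-center balanced accuracies from a searchlight run.

    ``per_partition`` holds one column per data partition; ``mean`` is its
    row mean and is the map that gets written to NIfTI.
    """

    center_index: np.ndarray
    per_partition: np.ndarray
    method: str
    radius_mm: float

    def __post_init__(self) -> None:
        self.center_index = np.asarray(self.center_index, dtype=int)
        self.per_partition = np.asarray(self.per_partition, dtype=float)
        if self.per_partition.ndim != 2:
            raise ValueError("per_partition must be (n_centers, n_partitions)")
        if len(self.center_index) != self.per_partition.shape[0]:
            raise ValueError("center_index length must match per_partition rows")
        if ((self.per_partition < 0) | (self.per_partition > 1)).any():
            raise ValueError("accuracies must lie in [0, 1]")

    @property
    def mean(self) -> np.ndarray:
        return self.per_partition.mean(axis=1)

    @property
    def n_partitions(self) -> int:
        return self.per_partition.shape[1]


# ---------------------------------------------------------------------------
# I/O


def read_mask(path) -> BrainMask:
    """Load a binary brain mask from a NIfTI-1 file (isotropic voxels only)."""
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0]):
        raise ValueError(f"anisotropic voxels not supported: {zooms}")
    data = np.asarray(img.dataobj)
    return BrainMask(inside=data > 0, voxel_size_mm=float(zooms[0]),
                     affine=img.affine)


def _validate_meta(meta: pd.DataFrame) -> None:
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing required columns: {missing}")


def read_dataset(bold_path, meta_path, mask: BrainMask,
                 label_map: dict | None = None) -> LabeledDataset:
    """Read a 4-D NIfTI volume stack plus its per-sample CSV metadata.

    Columns of ``X`` follow the C-order scan of in-mask voxel coordinates.
    Labels are mapped to {0,1}; by default the two sorted unique metadata
    label values map to 0 and 1, or an explicit ``label_map`` may be given.
    """
    img = nib.load(str(bold_path))
    if img.ndim != 4:
        raise ValueError(f"expected a 4-D volume stack, got {img.ndim}-D")
    if img.shape[:3] != mask.shape:
        raise ValueError(
            f"volume grid {img.shape[:3]} does not match mask {mask.shape}")
    meta = pd.read_csv(meta_path)
    _validate_meta(meta)
    n_vol = img.shape[3]
    if len(meta) != n_vol:
        raise ValueError(
            f"metadata has {len(meta)} rows for {n_vol} volumes")
    data = np.asarray(img.dataobj)
    X = data[mask.inside, :].T.astype(float)  # (n_samples, n_voxels), C-order

    raw = meta["label"].to_numpy()
    if label_map is None:
        uniq = sorted(pd.unique(raw))
        if len(uniq) != 2:
            raise ValueError(f"expected exactly 2 label values, got {uniq}")
        label_map = {uniq[0]: 0, uniq[1]: 1}
    try:
        y = np.array([label_map[v] for v in raw], dtype=int)
    except KeyError as e:
        raise ValueError(f"unknown label value: {e.args[0]!r}") from None

    domains = pd.unique(meta["domain"])
    if len(domains) != 1 or domains[0] not in ("source", "target"):
        raise ValueError("domain column must be constant 'source' or 'target'")

    return LabeledDataset(
        X=X, y=y,
        trial_id=meta["trial_id"].to_numpy(),
        run_id=meta["run_id"].to_numpy(),
        domain=str(domains[0]),
        voxel_index=mask.coords,
    )


def write_dataset(data: LabeledDataset, mask: BrainMask,
                  bold_path, meta_path) -> None:
    """Write a LabeledDataset back to a 4-D NIfTI + CSV pair (float32)."""
    if data.n_features != mask.n_voxels:
        raise ValueError("dataset feature count does not match mask voxels")
    vol = np.zeros(mask.shape + (data.n_samples,), dtype=np.float32)
    vol[mask.inside, :] = data.X.T.astype(np.float32)
    img = nib.Nifti1Image(vol, affine=mask.affine)
    img.header.set_zooms((mask.voxel_size_mm,) * 3 + (1.0,))
    nib.save(img, str(bold_path))
    meta = pd.DataFrame({
        "sample_id": np.arange(data.n_samples),
        "label": data.y,
        "trial_id": data.trial_id,
        "run_id": data.run_id,
        "domain": data.domain,
    })
    meta.to_csv(meta_path, index=False)


def standardize_cross_domain(
    source: LabeledDataset, target: LabeledDataset
) -> tuple[LabeledDataset, LabeledDataset, StandardizationParams]:
    """Z-score both domains with the SOURCE mean and standard deviation.

    The source output has per-feature mean 0 / sd 1 (population convention,
    divide by n); the target is transformed with the same source parameters so
    the two domains remain on a directly comparable scale.  Degenerate
    features (source sd < 1e-12) are set to 0 in both outputs and reported via
    :class:`DegenerateFeatureWarning` and the returned params.
    """
    if source.n_features != target.n_features:
        raise ValueError("source and target feature counts differ")
    if source.n_samples < 2:
        raise ValueError("source needs at least 2 samples")
    mean = source.X.mean(axis=0)
    sd = source.X.std(axis=0)  # population sd (ddof=0)
    params = StandardizationParams(mean=mean, sd=sd)
    if params.degenerate.any():
        warnings.warn(
            f"{int(params.degenerate.sum())} degenerate (constant) voxel(s) "
            "in source; set to 0 in both domains",
            DegenerateFeatureWarning, stacklevel=2)
    safe_sd = np.where(params.degenerate, 1.0, sd)

    def _apply(ds: LabeledDataset) -> LabeledDataset:
        Z = (ds.X - mean) / safe_sd
        Z[:, params.degenerate] = 0.0
        out = ds.subset(np.arange(ds.n_samples))
        out.X = Z
        return out

    return _apply(source), _apply(target), params


def write_map(values, mask: BrainMask, path, centers=None) -> None:
    """Write per-center values as a NIfTI-1 map; out-of-mask voxels are NaN.

    ``values`` may be an :class:`AccuracyMap` (its mean map is written) or a
    flat vector paired with ``centers`` (list of 3-D coordinates).
    """
    if isinstance(values, AccuracyMap):
        centers = values.center_index
        values = values.mean
    values = np.asarray(values, dtype=float)
    centers = np.asarray(centers, dtype=int)
    if len(centers) == 0:
        raise ValueError("empty center list")
    if centers.ndim != 2 or centers.shape[1] != 3:
        raise ValueError("centers must be (n, 3) coordinates")
    if not mask.inside[tuple(centers.T)].all():
        raise ValueError("a center lies outside the mask")
    vol = np.full(mask.shape, np.nan, dtype=np.float32)
    vol[tuple(centers.T)] = values.astype(np.float32)
    img = nib.Nifti1Image(vol, affine=mask.affine)
    img.header.set_zooms((mask.voxel_size_mm,) * 3)
    nib.save(img, str(path))


def read_map(path) -> np.ndarray:
    """Read a 3-D map written by :func:`write_map` (returns the volume)."""
    return np.asarray(nib.load(str(path)).dataobj)
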