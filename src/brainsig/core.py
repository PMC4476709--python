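"""Core data containers and I/O for masked brain images.

The whole package works on *masked, vectorized* images: a 3-D grid plus a
boolean inclusion mask defines a fixed linear ordering of in-brain voxels,
and every image becomes a length-``n_voxels`` vector in that order.  The
ordering is C-order (last axis fastest) over the mask's ``True`` cells, a
pure function of the mask, so two loads of the same mask always agree.

NIfTI-1 is the on-disk format for grids (via :mod:`nibabel`); weight-map
intercepts, which NIfTI cannot hold, live in a JSON sidecar next to the
image file.  Tabular inputs (ratings, pattern responses) are plain CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "BrainMask",
    "BetaImageSet",
    "WeightMap",
    "load_mask",
    "read_image_set",
    "write_weight_map",
    "load_weight_map",
    "load_response_table",
    "load_rating_table",
    "resample_to_grid",
]


@dataclass(frozen=True)
class BrainMask:
    """Boolean inclusion grid defining the in-brain voxel space.

    Parameters
    ----------
    inclusion
        3-D boolean array; ``True`` marks in-brain voxels.
    affine
        4x4 voxel-to-world (mm) transform; must be invertible.
    """

    inclusion: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        inc = np.asarray(self.inclusion, dtype=bool)
        if inc.ndim != 3:
            raise ValueError(f"mask grid must be 3-D, got shape {inc.shape}")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(aff)) < 1e-12:
            raise ValueError("affine is not invertible")
        object.__setattr__(self, "inclusion", inc)
        object.__setattr__(self, "affine", aff)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.inclusion.shape

    @property
    def n_voxels(self) -> int:
        return int(self.inclusion.sum())

    def vectorize(self, volume: np.ndarray) -> np.ndarray:
        """Extract in-mask values of a 3-D (or 4-D, last axis = time) grid."""
        volume = np.asarray(volume)
        if volume.shape[:3] != self.grid_shape:
            raise ValueError(
                f"volume shape {volume.shape[:3]} does not match mask grid "
                f"{self.grid_shape}"
            )
        return volume[self.inclusion]

    def devectorize(self, vector: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Place a length-``n_voxels`` vector back on the 3-D grid."""
        vector = np.asarray(vector)
        if vector.shape[0] != self.n_voxels:
            raise ValueError(
                f"vector length {vector.shape[0]} != n_voxels {self.n_voxels}"
            )
        out = np.full(self.grid_shape + vector.shape[1:], fill, dtype=float)
        out[self.inclusion] = vector
        return out

    def voxel_coordinates(self) -> np.ndarray:
        """(n_voxels, 3) array of 0-based voxel indices in vector order."""
        return np.argwhere(self.inclusion)

    def same_grid(self, other: "BrainMask", atol: float = 1e-4) -> bool:
        return self.grid_shape == other.grid_shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def __eq__(self, other) -> bool:  # value equality, used by containers
        return (
            isinstance(other, BrainMask)
            and self.grid_shape == other.grid_shape
            and np.array_equal(self.inclusion, other.inclusion)
            and np.allclose(self.affine, other.affine)
        )

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.inclusion.astype(np.uint8), self.affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))


def load_mask(path) -> BrainMask:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    return BrainMask(inclusion=data > 0, affine=np.asarray(img.affine))


@dataclass
class BetaImageSet:
    """Observations x voxels matrix of condition-level images plus metadata.

    Each row is one vectorized beta map.  ``condition_label`` holds the
    ordinal rating (1-5) for the emotion modality or the stimulation level
    (``low``/``medium``/``high``) for pain; ``rating`` exposes a numeric view
    of it for modelling.
    """

    data: np.ndarray
    subject_id: np.ndarray
    condition_label: np.ndarray
    mask: BrainMask
    modality: str = "emotion"
    split: str = "none"
    trial_id: np.ndarray | None = None

    PAIN_LEVELS = {"low": 1.0, "medium": 2.0, "high": 3.0}

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.subject_id = np.asarray(self.subject_id)
        self.condition_label = np.asarray(self.condition_label)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (observations x voxels)")
        if self.data.shape[1] != self.mask.n_voxels:
            raise ValueError(
                f"data has {self.data.shape[1]} columns but mask has "
                f"{self.mask.n_voxels} voxels"
            )
        n = self.data.shape[0]
        if len(self.subject_id) != n or len(self.condition_label) != n:
            raise ValueError("metadata length does not match number of rows")
        if not np.all(np.isfinite(self.data)):
            bad = np.unique(np.nonzero(~np.isfinite(self.data))[0])
            raise ValueError(
                f"non-finite values inside the mask in observations {bad.tolist()}"
            )
        if self.trial_id is not None:
            self.trial_id = np.asarray(self.trial_id)
            if len(self.trial_id) != n:
                raise ValueError("trial_id length does not match number of rows")

    @property
    def n_observations(self) -> int:
        return self.data.shape[0]

    @property
    def rating(self) -> np.ndarray:
        """Numeric condition value per observation (pain levels -> 1/2/3)."""
        out = np.empty(self.n_observations, dtype=float)
        for i, lab in enumerate(self.condition_label):
            if isinstance(lab, str) and lab in self.PAIN_LEVELS:
                out[i] = self.PAIN_LEVELS[lab]
            else:
                out[i] = float(lab)
        return out

    @property
    def subjects(self) -> np.ndarray:
        return np.unique(self.subject_id)

    def select(self, rows: np.ndarray) -> "BetaImageSet":
        rows = np.asarray(rows)
        return BetaImageSet(
            data=self.data[rows],
            subject_id=self.subject_id[rows],
            condition_label=self.condition_label[rows],
            mask=self.mask,
            modality=self.modality,
            split=self.split,
            trial_id=None if self.trial_id is None else self.trial_id[rows],
        )

    def subset_subjects(self, subjects: Iterable) -> "BetaImageSet":
        keep = np.isin(self.subject_id, list(subjects))
        return self.select(np.nonzero(keep)[0])


@dataclass
class WeightMap:
    """Voxel weight vector plus intercept on a mask grid.

    ``predict`` of a signature on an image is the dot product of the weights
    with the vectorized image plus the intercept, in the units of the
    training outcome (rating units when trained on ratings).
    """

    weights: np.ndarray
    intercept: float
    mask: BrainMask
    provenance: str = ""

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if self.weights.shape[0] != self.mask.n_voxels:
            raise ValueError(
                f"weights length {self.weights.shape[0]} != mask n_voxels "
                f"{self.mask.n_voxels}"
            )
        if not np.isfinite(self.intercept):
            raise ValueError("intercept must be finite")
        self.intercept = float(self.intercept)

    def to_volume(self) -> np.ndarray:
        return self.mask.devectorize(self.weights)

    def restrict(self, voxel_index: np.ndarray, keep: bool = True) -> "WeightMap":
        """Zero weights outside (``keep=True``) or inside a voxel index set."""
        sel = np.zeros(self.mask.n_voxels, dtype=bool)
        sel[np.asarray(voxel_index)] = True
        w = np.where(sel if keep else ~sel, self.weights, 0.0)
        return WeightMap(w, self.intercept, self.mask, provenance=self.provenance)


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            return path.with_name(name[: -len(ext)] + ".json")
    return path.with_suffix(".json")


def write_weight_map(wmap: WeightMap, path) -> Path:
    """Write a weight map to NIfTI with a JSON sidecar for the intercept.

    Out-of-mask voxels are written as zero.  Returns the sidecar path.
    """
    path = Path(path)
    img = nib.Nifti1Image(wmap.to_volume().astype(np.float64), wmap.mask.affine)
    nib.save(img, str(path))
    sidecar = _sidecar_path(path)
    sidecar.write_text(
        json.dumps(
            {"intercept": wmap.intercept, "provenance": wmap.provenance}, indent=2
        )
    )
    return sidecar


def load_weight_map(path, mask: BrainMask | None = None) -> WeightMap:
    """Load a weight map written by :func:`write_weight_map`.

    If ``mask`` is omitted, all nonzero voxels define the mask — adequate
    for published maps distributed without one.
    """
    path = Path(path)
    img = nib.load(str(path))
    vol = np.asanyarray(img.dataobj, dtype=float)
    if mask is None:
        mask = BrainMask(inclusion=vol != 0, affine=np.asarray(img.affine))
    elif vol.shape != mask.grid_shape:
        raise ValueError(
            f"{path.name}: grid {vol.shape} does not match mask {mask.grid_shape}"
        )
    intercept, provenance = 0.0, ""
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        intercept = float(meta.get("intercept", 0.0))
        provenance = str(meta.get("provenance", ""))
    return WeightMap(mask.vectorize(vol), intercept, mask, provenance=provenance)


def read_image_set(
    image_paths: Sequence,
    metadata: pd.DataFrame,
    mask: BrainMask,
    modality: str = "emotion",
    atol: float = 1e-4,
) -> BetaImageSet:
    """Load NIfTI beta maps into a masked, vectorized image set.

    ``metadata`` must have one row per image (aligned by position) with at
    least ``subject`` and ``condition`` columns.  Images must share the
    mask's grid shape and affine; resample first (:func:`resample_to_grid`)
    if they do not.
    """
    required = {"subject", "condition"}
    missing = required - set(metadata.columns)
    if missing:
        raise ValueError(f"metadata is missing required columns: {sorted(missing)}")
    if len(image_paths) != len(metadata):
        raise ValueError(
            f"{len(image_paths)} images but {len(metadata)} metadata rows"
        )
    rows = []
    for p in image_paths:
        img = nib.load(str(p))
        vol = np.asanyarray(img.dataobj, dtype=float)
        if vol.shape != mask.grid_shape or not np.allclose(
            img.affine, mask.affine, atol=atol
        ):
            raise ValueError(
                f"{Path(str(p)).name}: grid/affine mismatch with mask "
                f"(image {vol.shape}, mask {mask.grid_shape}); resample first"
            )
        vec = mask.vectorize(vol)
        n_bad = int((~np.isfinite(vec)).sum())
        if n_bad:
            raise ValueError(
                f"{Path(str(p)).name}: {n_bad} non-finite voxels inside the mask"
            )
        rows.append(vec)
    return BetaImageSet(
        data=np.vstack(rows),
        subject_id=metadata["subject"].to_numpy(),
        condition_label=metadata["condition"].to_numpy(),
        mask=mask,
        modality=modality,
        trial_id=metadata["trial"].to_numpy() if "trial" in metadata else None,
    )


def resample_to_grid(path, target: BrainMask, kind: str = "continuous"):
    """Resample an image onto a target grid (nearest for masks, trilinear
    for continuous maps).  Returns the resampled :class:`nibabel` image."""
    from nilearn.image import resample_img

    interp = "nearest" if kind == "mask" else "continuous"
    return resample_img(
        nib.load(str(path)),
        target_affine=target.affine,
        target_shape=target.grid_shape,
        interpolation=interp,
        force_resample=True,
        copy_header=True,
    )


def load_response_table(path, required: Sequence[str] = ("subject",)) -> pd.DataFrame:
    """Load a CSV of per-subject/trial responses or ratings.

    Column names are matched case-insensitively for the required set; all
    other columns pass through untouched (pattern-response columns such as
    cluster scores ``C_*`` are sniffed by name downstream).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path.name}: file is empty") from None
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise ValueError(f"{path.name}: no data rows")
    lower = {c.lower(): c for c in df.columns}
    missing = [c for c in required if c.lower() not in lower]
    if missing:
        raise ValueError(f"{path.name}: missing required columns: {missing}")
    return df.rename(columns={lower[c.lower()]: c for c in required})


def load_rating_table(
    path, scale: tuple[float, float] = (1, 5)
) -> pd.DataFrame:
    """Load a ratings CSV (``subject``, ``trial``, ``rating`` [, ``item``])
    and validate that ratings fall within the declared scale bounds."""
    df = load_response_table(path, required=("subject", "rating"))
    r = pd.to_numeric(df["rating"], errors="coerce")
    if r.isna().any():
        raise ValueError("non-numeric ratings present")
    lo, hi = scale
    if (r < lo).any() or (r > hi).any():
        raise ValueError(f"ratings outside declared scale [{lo}, {hi}]")
    df["rating"] = r
    return df
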