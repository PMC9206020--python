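"""Lesion-mask and atlas I/O, hemisphere flipping, overlays and per-structure damage.

All volumes in a cohort live on one shared template grid (the masks are assumed
to be spatially normalized upstream; registration is out of scope here). The
grid carries a NIfTI-style affine mapping voxel indices to world millimetres;
by convention world x increases to the right, y to anterior, z to superior, so
the left hemisphere sits at negative world x.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VolumeGrid",
    "LesionMask",
    "AtlasVolume",
    "Cohort",
    "read_mask",
    "write_volume",
    "read_atlas",
    "read_scores",
    "flip_to_left",
    "unify_hemisphere",
    "overlay_map",
    "percent_damage",
    "FMA_UL_MAX",
]

#: Ceiling of the upper-limb Fugl-Meyer motor score (33 items x 2 points).
FMA_UL_MAX = 66.0

#: Voxel-index axis treated as left-right unless a grid says otherwise.
DEFAULT_LR_AXIS = 0


@dataclass(frozen=True)
class VolumeGrid:
    """Geometry of a 3D volume: dimensions plus a voxel-to-world affine."""

    dims: tuple[int, int, int]
    affine: np.ndarray  # 4x4, voxel index -> world mm
    lr_axis: int = DEFAULT_LR_AXIS

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        object.__setattr__(self, "dims", dims)
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        object.__setattr__(self, "affine", aff)
        if any(d < 1 for d in dims):
            raise ValueError(f"all dims must be >= 1, got {dims}")
        if abs(np.linalg.det(aff)) < 1e-12:
            raise ValueError("affine is singular")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if not 0 <= self.lr_axis <= 2:
            raise ValueError("lr_axis must be 0, 1 or 2")

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        return tuple(float(np.linalg.norm(self.affine[:3, i])) for i in range(3))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map voxel indices (..., 3) to world mm coordinates (..., 3)."""
        idx = np.asarray(idx, dtype=float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def matches(self, other: "VolumeGrid", atol: float = 1e-4) -> bool:
        return self.dims == other.dims and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def require_match(self, other: "VolumeGrid", what: str = "volume") -> None:
        if not self.matches(other):
            raise ValueError(
                f"grid mismatch for {what}: dims {self.dims} vs {other.dims} "
                "or affines differ"
            )


@dataclass(frozen=True)
class LesionMask:
    """One subject's binary lesion volume on the cohort grid."""

    subject_id: str
    grid: VolumeGrid
    data: np.ndarray  # 3D uint8, values in {0, 1}

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.shape != self.grid.dims:
            raise ValueError(
                f"mask shape {data.shape} does not match grid dims {self.grid.dims}"
            )
        if not np.isin(data, (0, 1)).all():
            raise ValueError("lesion mask values must be 0 or 1")
        object.__setattr__(self, "data", data.astype(np.uint8))

    @property
    def volume_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def volume_cc(self) -> float:
        return self.volume_voxels * self.grid.voxel_volume_mm3 / 1000.0


@dataclass(frozen=True)
class AtlasVolume:
    """Label volume plus label-id -> structure-name table (0 = unlabeled)."""

    grid: VolumeGrid
    labels: np.ndarray  # 3D int
    names: dict[int, str]

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.shape != self.grid.dims:
            raise ValueError("atlas labels shape does not match grid dims")
        object.__setattr__(self, "labels", labels.astype(np.int32))
        present = set(np.unique(labels).tolist()) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"atlas labels without names: {sorted(missing)}")

    def name_of(self, label: int) -> str:
        return "unlabeled" if label == 0 else self.names[label]


@dataclass
class Cohort:
    """Aligned lesion masks and behavioral scores for one study cohort.

    ``scores`` is a long table with columns ``subject_id``, ``score``,
    ``value`` (e.g. FMA_UL on [0, 66], TSRT in degrees, optional MAS).
    """

    masks: list[LesionMask]
    scores: pd.DataFrame
    _by_id: dict[str, LesionMask] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ids = [m.subject_id for m in self.masks]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject_ids in cohort")
        required = {"subject_id", "score", "value"}
        if not required.issubset(self.scores.columns):
            raise ValueError(f"scores table must have columns {sorted(required)}")
        scored = set(self.scores["subject_id"].astype(str))
        masked = set(ids)
        if scored != masked:
            raise ValueError(
                "subjects with scores and subjects with masks differ: "
                f"only-scored={sorted(scored - masked)} "
                f"only-masked={sorted(masked - scored)}"
            )
        grid = self.masks[0].grid
        for m in self.masks[1:]:
            grid.require_match(m.grid, f"mask {m.subject_id}")
        fma = self.scores.loc[self.scores["score"] == "FMA_UL", "value"]
        if len(fma) and ((fma < 0) | (fma > FMA_UL_MAX)).any():
            raise ValueError(f"FMA_UL values must lie in [0, {FMA_UL_MAX:g}]")
        self._by_id = {m.subject_id: m for m in self.masks}

    @property
    def n_subjects(self) -> int:
        return len(self.masks)

    @property
    def grid(self) -> VolumeGrid:
        return self.masks[0].grid

    @property
    def subject_ids(self) -> list[str]:
        return [m.subject_id for m in self.masks]

    def mask(self, subject_id: str) -> LesionMask:
        return self._by_id[subject_id]

    def score_vector(self, score_name: str) -> np.ndarray:
        """Scores for ``score_name`` ordered like ``subject_ids``."""
        sub = self.scores[self.scores["score"] == score_name]
        values = dict(zip(sub["subject_id"].astype(str), sub["value"].astype(float)))
        missing = [sid for sid in self.subject_ids if sid not in values]
        if missing:
            raise KeyError(f"score '{score_name}' missing for subjects {missing}")
        return np.array([values[sid] for sid in self.subject_ids], dtype=float)

    def lesion_matrix(self) -> np.ndarray:
        """(n_subjects, n_voxels) uint8 matrix of flattened lesion data."""
        return np.stack([m.data.ravel() for m in self.masks]).astype(np.uint8)


# ---------------------------------------------------------------------------
# I/O


def read_mask(
    path: str | Path,
    expected_grid: VolumeGrid | None = None,
    subject_id: str | None = None,
    lr_axis: int = DEFAULT_LR_AXIS,
) -> LesionMask:
    """Load a NIfTI lesion volume and binarize it (values > 0.5 become 1).

    The 0.5 cut handles interpolated masks symmetrically; genuinely binary
    inputs pass through unchanged.
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    if not np.isfinite(data).all():
        raise ValueError(f"{path}: volume contains non-finite values")
    grid = VolumeGrid(dims=data.shape, affine=img.affine, lr_axis=lr_axis)
    if expected_grid is not None:
        expected_grid.require_match(grid, str(path))
        grid = expected_grid
    binary = (data > 0.5).astype(np.uint8)
    sid = subject_id if subject_id is not None else path.name.split(".")[0]
    return LesionMask(subject_id=sid, grid=grid, data=binary)


def write_volume(path: str | Path, data: np.ndarray, grid: VolumeGrid) -> None:
    """Write a volume on ``grid`` as NIfTI (.nii or .nii.gz)."""
    data = np.asarray(data)
    if data.shape != grid.dims:
        raise ValueError("data shape does not match grid dims")
    dtype = np.uint8 if data.dtype == bool else data.dtype
    img = nib.Nifti1Image(data.astype(dtype), grid.affine)
    nib.save(img, str(path))


def read_atlas(
    labels_path: str | Path,
    names_path: str | Path,
    expected_grid: VolumeGrid | None = None,
    lr_axis: int = DEFAULT_LR_AXIS,
) -> AtlasVolume:
    """Load an atlas label volume (NIfTI) and its label/name TSV."""
    img = nib.load(str(labels_path))
    labels = np.rint(np.asarray(img.get_fdata())).astype(np.int32)
    grid = VolumeGrid(dims=labels.shape, affine=img.affine, lr_axis=lr_axis)
    if expected_grid is not None:
        expected_grid.require_match(grid, str(labels_path))
        grid = expected_grid
    table = pd.read_csv(names_path, sep="\t")
    if not {"label", "name"}.issubset(table.columns):
        raise ValueError("atlas names TSV must have columns 'label' and 'name'")
    names = dict(zip(table["label"].astype(int), table["name"].astype(str)))
    return AtlasVolume(grid=grid, labels=labels, names=names)


def read_scores(path: str | Path) -> pd.DataFrame:
    """Read a long scores TSV with columns subject_id, score, value."""
    df = pd.read_csv(path, sep="\t")
    required = {"subject_id", "score", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"scores TSV must have columns {sorted(required)}")
    df["subject_id"] = df["subject_id"].astype(str)
    return df


# ---------------------------------------------------------------------------
# Transforms and summaries


def flip_to_left(mask: LesionMask) -> LesionMask:
    """Mirror a mask about the mid-plane of the left-right axis.

    Index i maps to X-1-i on an X-wide axis, which is exact for both even and
    odd X, preserves lesion volume, and is an involution. Applied to a
    right-hemisphere lesion on an MNI-style grid this moves it onto the left
    hemisphere template (negative world x); see :func:`unify_hemisphere` for
    the conditional cohort-level flip.
    """
    flipped = np.flip(mask.data, axis=mask.grid.lr_axis).copy()
    return dataclasses.replace(mask, data=flipped)


def _lesion_world_x(mask: LesionMask) -> float:
    """Mean world-x coordinate of the lesioned voxels (nan if empty)."""
    idx = np.argwhere(mask.data > 0)
    if len(idx) == 0:
        return float("nan")
    return float(mask.grid.voxel_to_world(idx)[:, 0].mean())

def unify_hemisphere(masks: list[LesionMask]) -> tuple[list[LesionMask], list[str]]:
    """Flip right-hemisphere lesions (mean world x > 0) onto the left.

    Returns the flipped cohort and the ids of subjects that were mirrored.
    Masks already on the left (or empty) pass through unchanged.
    """
    out: list[LesionMask] = []
    flipped_ids: list[str] = []
    for m in masks:
        cx = _lesion_world_x(m)
        if np.isfinite(cx) and cx > 0:
            out.append(flip_to_left(m))
            flipped_ids.append(m.subject_id)
        else:
            out.append(m)
    return out, flipped_ids


def overlay_map(cohort: Cohort) -> np.ndarray:
    """Per-voxel count of subjects lesioned there (the Fig-1-style overlay)."""
    if cohort.n_subjects < 1:
        raise ValueError("overlay_map needs at least one subject")
    counts = np.zeros(cohort.grid.dims, dtype=np.int32)
    for m in cohort.masks:
        counts += m.data
    return counts


def percent_damage(mask: LesionMask, atlas: AtlasVolume) -> pd.DataFrame:
    """Per-structure lesion load: lesioned voxels, structure size, percent.

    Rows appear for every named structure, including untouched ones (0%).
    A structure named in the atlas table but absent from the label volume has
    undefined percent damage and is reported as NaN, not 0.
    """
    mask.grid.require_match(atlas.grid, "atlas")
    lab = atlas.labels.ravel()
    les = mask.data.ravel().astype(bool)
    n_labels = max(atlas.names, default=0) + 1
    struct_sizes = np.bincount(lab, minlength=n_labels)
    lesioned = np.bincount(lab[les], minlength=n_labels)
    rows = []
    for label in sorted(atlas.names):
        size = int(struct_sizes[label])
        hit = int(lesioned[label])
        pct = 100.0 * hit / size if size > 0 else np.nan
        rows.append(
            {
                "label": label,
                "name": atlas.names[label],
                "structure_voxels": size,
                "lesioned_voxels": hit,
                "percent": pct,
            }
        )
    return pd.DataFrame(rows)
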