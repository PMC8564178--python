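"""Shared data model for the neurovascular-coupling pipeline.

All volumes live on a single index-addressed voxel grid (0-based); no
world-coordinate resampling is performed anywhere in the package, so every
volume belonging to one cohort must share one grid shape and one analysis
mask.  Masks (typically a gray-matter mask) are always supplied explicitly
and never inferred from image intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MaskedVolume",
    "BoldSeries",
    "AslAcqParams",
    "AslSeries",
    "AtlasParcellation",
    "SubjectRecord",
    "CohortTable",
    "GROUP_FAZEKAS_BANDS",
    "group_for_fazekas",
    "ValidationError",
]

#: Fazekas-total bands defining the severity groups (deep 0-3 + periventricular
#: 0-3; total 0-6).  A total of 0 means no visible lesions and is outside the
#: cohort definition.
GROUP_FAZEKAS_BANDS: dict[str, tuple[int, int]] = {
    "mild": (1, 2),
    "moderate": (3, 4),
    "severe": (5, 6),
}

GROUPS: tuple[str, ...] = ("mild", "moderate", "severe")


class ValidationError(ValueError):
    """A data-model invariant was violated."""


def group_for_fazekas(total: int) -> str:
    """Return the severity group implied by a total Fazekas score (1-6)."""
    for name, (lo, hi) in GROUP_FAZEKAS_BANDS.items():
        if lo <= total <= hi:
            return name
    raise ValidationError(f"Fazekas total {total} outside the 1-6 cohort range")


@dataclass
class MaskedVolume:
    """A scalar field on a 3D voxel grid restricted to a boolean mask.

    Units depend on content: CBF maps are ml/100g/min; FCS and z-score maps
    are unitless.  Out-of-mask voxels are carried along for I/O convenience
    but are ignored by every statistic in the package.
    """

    data: np.ndarray
    mask: np.ndarray
    voxel_size_mm: np.ndarray = field(
        default_factory=lambda: np.array([3.0, 3.0, 3.0])
    )

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.voxel_size_mm = np.asarray(self.voxel_size_mm, dtype=float)
        if self.data.ndim != 3:
            raise ValidationError(f"volume must be 3D, got {self.data.ndim}D")
        if self.data.shape != self.mask.shape:
            raise ValidationError(
                f"data shape {self.data.shape} != mask shape {self.mask.shape}"
            )
        if self.voxel_size_mm.shape != (3,) or np.any(self.voxel_size_mm <= 0):
            raise ValidationError("voxel_size_mm must be 3 positive values")
        if not np.all(np.isfinite(self.data[self.mask])):
            raise ValidationError("non-finite values inside the mask")

    @property
    def in_mask(self) -> np.ndarray:
        """In-mask values as a flat array (view order: C)."""
        return self.data[self.mask]

    def with_data(self, data: np.ndarray) -> "MaskedVolume":
        """New volume with the same mask/grid and different values."""
        return MaskedVolume(data, self.mask, self.voxel_size_mm)


@dataclass
class BoldSeries:
    """A 4D resting-state BOLD series (time first) with rigid-body motion.

    ``motion_params`` holds one 6-vector per frame: three translations in mm
    followed by three rotations in degrees.
    """

    data: np.ndarray
    tr_s: float
    motion_params: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.motion_params = np.asarray(self.motion_params, dtype=float)
        if self.data.ndim != 4:
            raise ValidationError(f"BOLD series must be 4D, got {self.data.ndim}D")
        if self.tr_s <= 0:
            raise ValidationError("tr_s must be positive")
        if self.motion_params.shape != (self.n_frames, 6):
            raise ValidationError(
                "motion_params must have one 6-vector per frame "
                f"(expected {(self.n_frames, 6)}, got {self.motion_params.shape})"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]


@dataclass(frozen=True)
class AslAcqParams:
    """pCASL acquisition/quantification parameters (single-compartment model).

    Defaults follow the consensus quantification for pseudo-continuous
    labeling: blood-brain partition coefficient lambda = 0.9 ml/g, labeling
    efficiency alpha = 0.85, arterial blood T1 = 1.65 s, labeling duration
    tau = 1.45 s, post-label delay = 2.025 s.  All are overridable in config.
    """

    labeling_duration_s: float = 1.45
    post_label_delay_s: float = 2.025
    labeling_efficiency: float = 0.85
    blood_t1_s: float = 1.65
    partition_coefficient: float = 0.9

    def __post_init__(self) -> None:
        for name in (
            "labeling_duration_s",
            "post_label_delay_s",
            "labeling_efficiency",
            "blood_t1_s",
            "partition_coefficient",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.labeling_efficiency > 1:
            raise ValidationError("labeling_efficiency must be in (0, 1]")


@dataclass
class AslSeries:
    """Interleaved label/control ASL frames plus a proton-density reference."""

    frames: np.ndarray              # (n_frames, x, y, z)
    tags: Sequence[str]             # 'label' or 'control' per frame
    pd_reference: np.ndarray        # (x, y, z)
    acq_params: AslAcqParams = field(default_factory=AslAcqParams)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.pd_reference = np.asarray(self.pd_reference, dtype=float)
        self.tags = list(self.tags)
        if self.frames.ndim != 4:
            raise ValidationError("ASL frames must be a 4D stack")
        if len(self.tags) != self.frames.shape[0]:
            raise ValidationError("one tag per frame required")
        bad = set(self.tags) - {"label", "control"}
        if bad:
            raise ValidationError(f"unknown frame tags: {sorted(bad)}")
        n_label = sum(t == "label" for t in self.tags)
        n_control = len(self.tags) - n_label
        if n_label != n_control or n_label == 0:
            raise ValidationError(
                f"need equal, nonzero label/control counts (got {n_label}/{n_control})"
            )
        if self.pd_reference.shape != self.frames.shape[1:]:
            raise ValidationError("PD reference grid differs from ASL frames")

    @property
    def n_pairs(self) -> int:
        return len(self.tags) // 2

    def label_frames(self) -> np.ndarray:
        idx = [i for i, t in enumerate(self.tags) if t == "label"]
        return self.frames[idx]

    def control_frames(self) -> np.ndarray:
        idx = [i for i, t in enumerate(self.tags) if t == "control"]
        return self.frames[idx]


@dataclass
class AtlasParcellation:
    """Integer-labeled parcellation (0 = background) with a region table.

    ``regions`` is a DataFrame with columns ``id``, ``name`` and ``is_hub``.
    Hub regions model highly connected cortical/subcortical nodes (default
    mode / salience / executive network cores) where perfusion and
    connectivity losses concentrate.
    """

    labels: np.ndarray
    regions: pd.DataFrame

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.allclose(self.labels, np.round(self.labels)):
                raise ValidationError("atlas labels must be integers")
            self.labels = np.round(self.labels).astype(int)
        if self.labels.ndim != 3:
            raise ValidationError("atlas label volume must be 3D")
        required = {"id", "name", "is_hub"}
        if not required.issubset(self.regions.columns):
            raise ValidationError(f"region table needs columns {sorted(required)}")
        ids = self.regions["id"].to_numpy()
        if len(np.unique(ids)) != len(ids):
            raise ValidationError("region ids must be unique")
        present = np.unique(self.labels)
        present = present[present != 0]
        missing = set(present.tolist()) - set(ids.tolist())
        if missing:
            raise ValidationError(f"labels missing from region table: {sorted(missing)}")

    @property
    def region_ids(self) -> np.ndarray:
        return self.regions["id"].to_numpy()

    @property
    def hub_ids(self) -> np.ndarray:
        return self.regions.loc[self.regions["is_hub"].astype(bool), "id"].to_numpy()

    def region_mask(self, region_id: int) -> np.ndarray:
        return self.labels == region_id


@dataclass
class SubjectRecord:
    """Demographics, risk factors and cognition for one cohort member."""

    id: str
    fazekas_total: int
    group: str
    age: float
    sex: str
    education_years: float
    hypertension: bool = False
    diabetes: bool = False
    smoking: bool = False
    drinking: bool = False
    cognition_raw: Mapping[str, float] = field(default_factory=dict)
    cognition_z: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.fazekas_total <= 6:
            raise ValidationError(
                f"subject {self.id}: Fazekas total {self.fazekas_total} outside 0-6"
            )
        if self.group not in GROUPS:
            raise ValidationError(f"subject {self.id}: unknown group {self.group!r}")
        expected = group_for_fazekas(self.fazekas_total)
        if expected != self.group:
            raise ValidationError(
                f"subject {self.id}: Fazekas total {self.fazekas_total} implies "
                f"group {expected!r}, record says {self.group!r}"
            )
        if self.sex not in ("M", "F"):
            raise ValidationError(f"subject {self.id}: sex must be 'M' or 'F'")


@dataclass
class CohortTable:
    """Ordered subjects plus per-subject imaging artifacts on one shared grid."""

    subjects: list[SubjectRecord]
    volumes: dict[str, dict[str, object]] = field(default_factory=dict)
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate subject ids: {dupes}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            for sid, artifacts in self.volumes.items():
                for key, vol in artifacts.items():
                    shape = getattr(vol, "grid_shape", None)
                    if shape is None and hasattr(vol, "data"):
                        shape = vol.data.shape
                    if shape is not None and tuple(shape) != self.mask.shape:
                        raise ValidationError(
                            f"subject {sid}: {key} grid {tuple(shape)} does not "
                            f"match cohort mask grid {self.mask.shape}"
                        )

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.subjects]

    def groups(self) -> np.ndarray:
        return np.array([s.group for s in self.subjects])

    def to_frame(self) -> pd.DataFrame:
        """Tabular view of the demographic/cognitive fields."""
        rows = []
        for s in self.subjects:
            row: dict[str, object] = {
                "id": s.id,
                "fazekas_total": s.fazekas_total,
                "group": s.group,
                "age": s.age,
                "sex": s.sex,
                "education_years": s.education_years,
                "hypertension": s.hypertension,
                "diabetes": s.diabetes,
                "smoking": s.smoking,
                "drinking": s.drinking,
            }
            row.update({f"raw_{k}": v for k, v in s.cognition_raw.items()})
            row.update({f"z_{k}": v for k, v in s.cognition_z.items()})
            rows.append(row)
        return pd.DataFrame(rows)
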