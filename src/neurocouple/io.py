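"""NIfTI volume and table I/O plus cohort-config loading.

Volumes travel as NIfTI-1 (.nii/.nii.gz); region and cohort tables as TSV;
configuration as JSON or YAML.  All volumes referenced by one cohort must
already share a single voxel grid — this module validates that eagerly and
never resamples.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .types import (
    AtlasParcellation,
    BoldSeries,
    CohortTable,
    MaskedVolume,
    SubjectRecord,
    ValidationError,
)

log = logging.getLogger("neurocouple")

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "read_atlas",
    "write_atlas",
    "read_cohort_table",
    "write_cohort_table",
    "load_config",
    "load_cohort",
]


class FormatError(ValueError):
    """File is not a readable NIfTI-1 volume."""


class DimensionError(ValueError):
    """Volume dimensionality is not 3D or 4D."""


def _load_nifti(path: str | Path) -> nib.Nifti1Image:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"{path}: not a readable NIfTI file ({exc})") from exc
    return img


def read_volume(
    path: str | Path,
    mask: np.ndarray | None = None,
    tr_s: float | None = None,
    motion_params: np.ndarray | None = None,
) -> MaskedVolume | BoldSeries:
    """Read a NIfTI file as a :class:`MaskedVolume` (3D) or :class:`BoldSeries` (4D).

    For 3D volumes an explicit ``mask`` may be supplied; otherwise the whole
    grid is in-mask.  For 4D volumes the repetition time is taken from the
    header unless ``tr_s`` overrides it, and ``motion_params`` default to
    zero motion (they normally come from a separate TSV).
    """
    img = _load_nifti(path)
    data = np.asanyarray(img.dataobj, dtype=float)
    zooms = img.header.get_zooms()
    if data.ndim == 3:
        if mask is None:
            mask = np.ones(data.shape, dtype=bool)
        return MaskedVolume(data, mask, np.asarray(zooms[:3], dtype=float))
    if data.ndim == 4:
        # stored x,y,z,t -> time-first in memory
        series = np.moveaxis(data, -1, 0)
        if tr_s is None:
            tr_s = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
        if motion_params is None:
            motion_params = np.zeros((series.shape[0], 6))
        return BoldSeries(series, tr_s, motion_params)
    raise DimensionError(f"{path}: expected 3D or 4D volume, got {data.ndim}D")


def write_volume(vol: MaskedVolume | BoldSeries | np.ndarray, path: str | Path) -> Path:
    """Write a volume to NIfTI-1; 4D series are stored time-last."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    if isinstance(vol, BoldSeries):
        data = np.moveaxis(vol.data, 0, -1)
        img = nib.Nifti1Image(data, affine)
        img.header.set_zooms((1.0, 1.0, 1.0, vol.tr_s))
    elif isinstance(vol, MaskedVolume):
        affine[0, 0], affine[1, 1], affine[2, 2] = vol.voxel_size_mm
        img = nib.Nifti1Image(vol.data, affine)
        img.header.set_zooms(tuple(vol.voxel_size_mm))
    else:
        img = nib.Nifti1Image(np.asarray(vol, dtype=float), affine)
    nib.save(img, str(path))
    return path


def read_mask(path: str | Path) -> np.ndarray:
    vol = read_volume(path)
    if not isinstance(vol, MaskedVolume):
        raise DimensionError(f"{path}: mask must be a 3D volume")
    return vol.data > 0.5


def read_atlas(labels_path: str | Path, regions_path: str | Path) -> AtlasParcellation:
    vol = read_volume(labels_path)
    regions = pd.read_csv(regions_path, sep="\t")
    return AtlasParcellation(np.round(vol.data).astype(int), regions)


def write_atlas(atlas: AtlasParcellation, labels_path: str | Path, regions_path: str | Path) -> None:
    write_volume(atlas.labels.astype(np.int16), labels_path)
    Path(regions_path).parent.mkdir(parents=True, exist_ok=True)
    atlas.regions.to_csv(regions_path, sep="\t", index=False)


def write_cohort_table(cohort: CohortTable, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort.to_frame().to_csv(path, sep="\t", index=False)
    return path


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_config(path: str | Path) -> dict:
    """Load a JSON or YAML configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _subject_from_row(row: pd.Series) -> SubjectRecord:
    raw = {c[4:]: row[c] for c in row.index if c.startswith("raw_")}
    z = {c[2:]: row[c] for c in row.index if c.startswith("z_")}
    return SubjectRecord(
        id=str(row["id"]),
        fazekas_total=int(row["fazekas_total"]),
        group=str(row["group"]),
        age=float(row["age"]),
        sex=str(row["sex"]),
        education_years=float(row["education_years"]),
        hypertension=bool(row.get("hypertension", False)),
        diabetes=bool(row.get("diabetes", False)),
        smoking=bool(row.get("smoking", False)),
        drinking=bool(row.get("drinking", False)),
        cognition_raw=raw,
        cognition_z=z,
    )


def load_cohort(config_path: str | Path) -> CohortTable:
    """Build and validate a :class:`CohortTable` from a config file.

    The config must contain ``cohort_table`` (TSV path) and ``mask``
    (NIfTI path), plus optional per-subject volume path templates, e.g.::

        cohort_table: cohort.tsv
        mask: gm_mask.nii.gz
        volumes:
          cbf: "{id}_cbf.nii.gz"
          bold: "{id}_bold.nii.gz"

    Paths are resolved relative to the config file.  Every invariant
    (unique ids, Fazekas/group consistency, one shared grid) is checked
    eagerly; violations raise :class:`ValidationError` naming the subject.
    """
    config_path = Path(config_path)
    cfg = load_config(config_path)
    base = config_path.parent
    table = read_cohort_table(base / cfg["cohort_table"])
    subjects = [_subject_from_row(row) for _, row in table.iterrows()]
    mask = read_mask(base / cfg["mask"]) if "mask" in cfg else None

    volumes: dict[str, dict[str, object]] = {}
    for key, template in cfg.get("volumes", {}).items():
        for subj in subjects:
            vpath = base / template.format(id=subj.id)
            if not vpath.exists():
                raise FileNotFoundError(f"subject {subj.id}: missing {key} file {vpath}")
            try:
                vol = read_volume(vpath, mask=mask)
            except ValidationError as exc:
                raise ValidationError(f"subject {subj.id}: {key} volume invalid: {exc}") from exc
            shape = vol.grid_shape if isinstance(vol, BoldSeries) else vol.data.shape
            if mask is not None and tuple(shape) != mask.shape:
                raise ValidationError(
                    f"subject {subj.id}: {key} grid {tuple(shape)} does not match "
                    f"cohort mask grid {mask.shape}"
                )
            volumes.setdefault(subj.id, {})[key] = vol

    cohort = CohortTable(subjects, volumes, mask)
    log.info(
        "stage=load_cohort subjects=%d volumes_per_subject=%d grid=%s",
        len(cohort),
        len(cfg.get("volumes", {})),
        None if mask is None else mask.shape,
    )
    return cohort
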