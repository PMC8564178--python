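"""CBF-FCS neurovascular coupling.

Per subject, coupling is the Pearson correlation between the z-scored CBF
and FCS maps across gray-matter voxels — globally over the whole mask, and
regionally within each atlas parcel.  Before z-scoring, both maps are
smoothed with a 6-mm FWHM Gaussian kernel (mask-renormalized so out-of-mask
voxels carry zero weight).

The regional statistic is a per-subject, per-region across-voxel
correlation; a group-level mode (one across-subject correlation per voxel,
averaged within regions) is available through :func:`group_coupling_map`
but is not part of the default pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .types import AtlasParcellation, MaskedVolume, ValidationError

log = logging.getLogger("neurocouple")

__all__ = [
    "CouplingResult",
    "smooth_map",
    "global_coupling",
    "regional_coupling",
    "subject_coupling",
    "group_coupling_map",
]

#: Minimum voxels for a regional correlation; smaller regions are reported
#: as missing (NaN) rather than fabricated.
MIN_REGION_VOXELS = 3


@dataclass
class CouplingResult:
    """Per-subject coupling: one global r plus one r per atlas region."""

    subject_id: str
    global_r: float
    regional_r: dict[int, float] = field(default_factory=dict)
    n_voxels: dict[int, int] = field(default_factory=dict)


def smooth_map(vol: MaskedVolume, fwhm_mm: float = 6.0) -> MaskedVolume:
    """Gaussian-smooth a masked map, renormalizing at the mask boundary.

    sigma per axis is fwhm / (2 * sqrt(2 ln 2)) in mm, converted to voxels
    with the volume's voxel size.  Out-of-mask voxels contribute zero
    weight, so a constant in-mask map is left unchanged.
    """
    if fwhm_mm < 0:
        raise ValidationError("fwhm must be nonnegative")
    if fwhm_mm == 0:
        return vol
    sigma_mm = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_vox = sigma_mm / vol.voxel_size_mm

    masked = np.where(vol.mask, vol.data, 0.0)
    num = ndimage.gaussian_filter(masked, sigma=sigma_vox, truncate=6.0)
    den = ndimage.gaussian_filter(vol.mask.astype(float), sigma=sigma_vox, truncate=6.0)
    data = np.zeros_like(vol.data)
    inside = vol.mask & (den > 0)
    data[inside] = num[inside] / den[inside]
    return MaskedVolume(data, vol.mask, vol.voxel_size_mm)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0 or sy == 0:
        return np.nan
    r = float(np.dot(x - x.mean(), y - y.mean()) / ((x.size - 1) * sx * sy))
    return float(np.clip(r, -1.0, 1.0))


def global_coupling(cbf_z: MaskedVolume, fcs_z: MaskedVolume, mask: np.ndarray | None = None) -> float:
    """Pearson r between two maps across all in-mask voxels."""
    if mask is None:
        mask = cbf_z.mask & fcs_z.mask
    else:
        mask = np.asarray(mask, dtype=bool) & cbf_z.mask & fcs_z.mask
    if np.count_nonzero(mask) < MIN_REGION_VOXELS:
        raise ValidationError("fewer than 3 in-mask voxels for coupling")
    return _pearson(cbf_z.data[mask], fcs_z.data[mask])


def regional_coupling(
    cbf_z: MaskedVolume,
    fcs_z: MaskedVolume,
    atlas: AtlasParcellation,
) -> tuple[dict[int, float], dict[int, int]]:
    """Per-region across-voxel correlation of a subject's z-maps.

    Returns ``(regional_r, n_voxels)``; regions with fewer than 3 in-mask
    voxels get NaN.
    """
    if atlas.labels.shape != cbf_z.data.shape:
        raise ValidationError("atlas grid differs from map grid")
    mask = cbf_z.mask & fcs_z.mask
    regional: dict[int, float] = {}
    counts: dict[int, int] = {}
    for rid in atlas.region_ids:
        rmask = (atlas.labels == rid) & mask
        n = int(np.count_nonzero(rmask))
        counts[int(rid)] = n
        if n < MIN_REGION_VOXELS:
            regional[int(rid)] = np.nan
            continue
        regional[int(rid)] = _pearson(cbf_z.data[rmask], fcs_z.data[rmask])
    return regional, counts


def subject_coupling(
    subject_id: str,
    cbf: MaskedVolume,
    fcs: MaskedVolume,
    atlas: AtlasParcellation | None = None,
    mask: np.ndarray | None = None,
    fwhm_mm: float = 6.0,
) -> CouplingResult:
    """Full per-subject coupling: smooth both maps, z-score within the GM
    mask, then correlate globally and per region."""
    from .connectivity import zscore_map

    gm = mask if mask is not None else (cbf.mask & fcs.mask)
    cbf_s = smooth_map(cbf, fwhm_mm)
    fcs_s = smooth_map(fcs, fwhm_mm)
    cbf_z = zscore_map(cbf_s, gm)
    fcs_z = zscore_map(fcs_s, gm)
    result = CouplingResult(subject_id, global_coupling(cbf_z, fcs_z))
    if atlas is not None:
        result.regional_r, result.n_voxels = regional_coupling(cbf_z, fcs_z, atlas)
    log.info(
        "stage=subject_coupling subject=%s global_r=%.4f regions=%d fwhm=%g",
        subject_id,
        result.global_r,
        len(result.regional_r),
        fwhm_mm,
    )
    return result


def group_coupling_map(
    cbf_maps: list[MaskedVolume],
    fcs_maps: list[MaskedVolume],
    atlas: AtlasParcellation,
    mask: np.ndarray,
) -> dict[int, float]:
    """Across-subject coupling, averaged within regions (group-level mode).

    For each voxel, the Pearson r across subjects between CBF and FCS; the
    regional value is the mean of that voxelwise coupling map over the
    region's in-mask voxels.
    """
    if len(cbf_maps) != len(fcs_maps) or len(cbf_maps) < 3:
        raise ValidationError("need >= 3 paired subject maps")
    mask = np.asarray(mask, dtype=bool)
    c = np.stack([m.data[mask] for m in cbf_maps])  # subjects x voxels
    f = np.stack([m.data[mask] for m in fcs_maps])
    c = c - c.mean(axis=0)
    f = f - f.mean(axis=0)
    num = (c * f).sum(axis=0)
    den = np.sqrt((c**2).sum(axis=0) * (f**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        vox_r = np.where(den > 0, num / den, np.nan)
    labels = atlas.labels[mask]
    out: dict[int, float] = {}
    for rid in atlas.region_ids:
        vals = vox_r[labels == rid]
        vals = vals[np.isfinite(vals)]
        out[int(rid)] = float(vals.mean()) if vals.size >= MIN_REGION_VOXELS else np.nan
    return out
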