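"""Voxelwise functional connectivity strength (FCS).

FCS is a weighted degree-centrality measure: for each gray-matter voxel,
the mean of its Pearson correlations with every other gray-matter voxel,
after setting correlations below a positive threshold (default 0.2) to
zero.  A correlation exactly at the threshold is kept.  No spatial
smoothing is applied at this stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import blas

from .types import BoldSeries, MaskedVolume, ValidationError

log = logging.getLogger("neurocouple")

__all__ = ["FcsParams", "compute_fcs", "zscore_map"]


@dataclass
class FcsParams:
    """FCS computation parameters.

    ``denominator`` selects the averaging convention: ``"all"`` divides the
    suprathreshold sum by N-1 (every other voxel, zeroed edges included),
    ``"suprathreshold"`` divides by the number of surviving edges.
    """

    threshold: float = 0.2
    denominator: str = "all"

    def __post_init__(self) -> None:
        if not 0 <= self.threshold < 1:
            raise ValidationError("threshold must be in [0, 1)")
        if self.denominator not in ("all", "suprathreshold"):
            raise ValidationError("denominator must be 'all' or 'suprathreshold'")


def compute_fcs(
    bold: BoldSeries,
    mask: np.ndarray,
    params: FcsParams | None = None,
) -> MaskedVolume:
    """Compute the FCS map of a preprocessed BOLD series within a mask.

    Voxels with zero temporal variance cannot enter a Pearson correlation;
    they are dropped from the output mask (the count is logged).  With the
    default ``denominator="all"``,

        FCS_i = (1 / (N - 1)) * sum_{j != i} r_ij * [r_ij >= threshold].

    Sample (n-1) normalization is used throughout, so FCS lies in [0, 1].
    """
    params = params or FcsParams()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != bold.grid_shape:
        raise ValidationError("mask grid differs from BOLD grid")

    series = bold.data.reshape(bold.n_frames, -1)[:, mask.ravel()]
    t, n_all = series.shape
    sd = series.std(axis=0, ddof=1)
    keep = sd > 0
    n_dropped = int(np.count_nonzero(~keep))
    if n_dropped:
        log.info("stage=compute_fcs zero_variance_voxels_dropped=%d", n_dropped)
    series = series[:, keep]
    n = series.shape[1]
    if n < 2:
        raise ValidationError("need at least 2 in-mask voxels with nonzero variance")

    z = (series - series.mean(axis=0)) / sd[keep]
    # one triangle of the correlation matrix via a symmetric rank-k update
    corr = blas.dsyrk(1.0 / (t - 1), np.asfortranarray(z), trans=1, lower=1)
    np.fill_diagonal(corr, 0.0)
    np.minimum(corr, 1.0, out=corr)
    corr[corr < params.threshold] = 0.0  # also zeros the empty triangle

    sums = corr.sum(axis=0) + corr.sum(axis=1)
    if params.denominator == "all":
        fcs = sums / (n - 1)
    else:
        counts = np.count_nonzero(corr, axis=0) + np.count_nonzero(corr, axis=1)
        with np.errstate(invalid="ignore"):
            fcs = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)

    out_mask = mask.copy()
    out_mask.ravel()[np.flatnonzero(mask.ravel())[~keep]] = False
    data = np.zeros(mask.shape)
    data[out_mask] = fcs
    log.info(
        "stage=compute_fcs voxels=%d frames=%d threshold=%g denominator=%s",
        n,
        t,
        params.threshold,
        params.denominator,
    )
    return MaskedVolume(data, out_mask)


def zscore_map(vol: MaskedVolume, mask: np.ndarray | None = None) -> MaskedVolume:
    """Standardize a map by the mean and sample SD of its in-mask values.

    The result has in-mask mean 0 and SD 1; out-of-mask voxels are zeroed.
    """
    mask = vol.mask if mask is None else (np.asarray(mask, dtype=bool) & vol.mask)
    vals = vol.data[mask]
    if vals.size < 2:
        raise ValidationError("need at least 2 in-mask voxels to z-score")
    sd = vals.std(ddof=1)
    if sd == 0:
        raise ValidationError("cannot z-score a constant map")
    data = np.zeros_like(vol.data)
    data[mask] = (vals - vals.mean()) / sd
    return MaskedVolume(data, mask, vol.voxel_size_mm)
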