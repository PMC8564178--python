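"""Single-compartment pCASL quantification.

Perfusion-weighted signal is the mean control-minus-label difference over
acquired pairs; cerebral blood flow follows the standard single-compartment
(consensus) model for pseudo-continuous labeling,

    CBF = 6000 * lambda * dM * exp(PLD / T1b)
          / (2 * alpha * T1b * PD * (1 - exp(-tau / T1b)))   [ml/100g/min]

with lambda the blood-brain partition coefficient (ml/g), alpha the labeling
efficiency, T1b the longitudinal relaxation time of arterial blood (s), PLD
the post-label delay (s), tau the labeling duration (s) and PD the
proton-density reference signal.  A single global alpha is used.  Negative
quantified values (noise can drive dM below zero) are clamped to zero and
counted in the log.
"""

from __future__ import annotations

import logging

import numpy as np

from .types import AslAcqParams, AslSeries, MaskedVolume, ValidationError

log = logging.getLogger("neurocouple")

__all__ = ["perfusion_difference", "quantify_cbf", "cbf_from_asl"]


def perfusion_difference(asl: AslSeries) -> MaskedVolume:
    """Voxelwise mean of (control - label) over all acquired pairs."""
    control = asl.control_frames()
    label = asl.label_frames()
    dm = control.mean(axis=0) - label.mean(axis=0)
    mask = np.ones(dm.shape, dtype=bool)
    return MaskedVolume(dm, mask)


def quantify_cbf(
    dm: MaskedVolume,
    pd_ref: MaskedVolume,
    acq_params: AslAcqParams | None = None,
    clamp_negative: bool = True,
) -> MaskedVolume:
    """Convert a perfusion difference map and PD reference into CBF.

    Voxels where the PD reference is not positive cannot be quantified and
    are removed from the output mask (reported in the log).
    """
    params = acq_params or AslAcqParams()
    if dm.data.shape != pd_ref.data.shape:
        raise ValidationError("dM and PD reference grids differ")

    pd_vals = pd_ref.data
    valid = dm.mask & pd_ref.mask & (pd_vals > 0)
    n_bad = int(np.count_nonzero(dm.mask & pd_ref.mask & ~(pd_vals > 0)))
    if n_bad:
        log.warning("stage=quantify_cbf nonpositive_pd_voxels=%d (masked out)", n_bad)

    t1b = params.blood_t1_s
    scale = (
        6000.0
        * params.partition_coefficient
        * np.exp(params.post_label_delay_s / t1b)
        / (2.0 * params.labeling_efficiency * t1b * (1.0 - np.exp(-params.labeling_duration_s / t1b)))
    )
    cbf = np.zeros_like(dm.data)
    cbf[valid] = scale * dm.data[valid] / pd_vals[valid]

    if clamp_negative:
        n_neg = int(np.count_nonzero(cbf[valid] < 0))
        if n_neg:
            log.info("stage=quantify_cbf negative_voxels_clamped=%d", n_neg)
        np.clip(cbf, 0.0, None, out=cbf)

    return MaskedVolume(cbf, valid, dm.voxel_size_mm)


def cbf_from_asl(asl: AslSeries, clamp_negative: bool = True) -> MaskedVolume:
    """Full quantification: pairwise subtraction then single-compartment model."""
    dm = perfusion_difference(asl)
    pd_ref = MaskedVolume(asl.pd_reference, np.ones(asl.pd_reference.shape, bool))
    return quantify_cbf(dm, pd_ref, asl.acq_params, clamp_negative=clamp_negative)
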