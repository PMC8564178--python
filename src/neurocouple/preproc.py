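"""Temporal BOLD preprocessing and motion quality control.

The fixed stage order is: discard initial frames -> nuisance regression ->
band-pass filtering.  Spatial steps (slice timing, realignment, spatial
normalization) are out of scope: inputs are assumed to be on a common grid
with motion parameters supplied alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .types import BoldSeries, ValidationError

log = logging.getLogger("neurocouple")

__all__ = [
    "NuisanceSet",
    "discard_initial",
    "regress_nuisance",
    "bandpass",
    "framewise_displacement",
    "motion_exclusion",
    "preprocess",
]

#: Head radius (mm) used to convert rotations into arc displacement for FD.
FD_HEAD_RADIUS_MM = 50.0

#: Motion-exclusion limits: any |translation| above 3 mm or |rotation| above
#: 3 degrees on any axis fails the subject ("no more than" -> the boundary
#: itself passes).
MAX_TRANSLATION_MM = 3.0
MAX_ROTATION_DEG = 3.0


@dataclass
class NuisanceSet:
    """Confound regressors for one BOLD series.

    ``motion_regressors`` may hold 3 columns (translations only, the literal
    x/y/z-axes reading) or 6 (full rigid-body, the default elsewhere).
    """

    linear_trend: bool = True
    wm_mean: np.ndarray | None = None
    csf_mean: np.ndarray | None = None
    motion_regressors: np.ndarray | None = None

    def design(self, n_frames: int) -> tuple[np.ndarray, list[str]]:
        """Assemble the nuisance design matrix (without intercept)."""
        cols: list[np.ndarray] = []
        names: list[str] = []
        if self.linear_trend:
            cols.append(np.linspace(-1.0, 1.0, n_frames))
            names.append("trend")
        for name, vec in (("wm", self.wm_mean), ("csf", self.csf_mean)):
            if vec is not None:
                vec = np.asarray(vec, dtype=float)
                if vec.shape != (n_frames,):
                    raise ValidationError(f"{name} regressor length != frame count")
                cols.append(vec)
                names.append(name)
        if self.motion_regressors is not None:
            mp = np.atleast_2d(np.asarray(self.motion_regressors, dtype=float))
            if mp.shape[0] != n_frames:
                raise ValidationError("motion regressor length != frame count")
            for j in range(mp.shape[1]):
                cols.append(mp[:, j])
                names.append(f"mp{j + 1}")
        if not cols:
            return np.empty((n_frames, 0)), []
        return np.column_stack(cols), names

    @classmethod
    def from_bold(
        cls,
        bold: BoldSeries,
        wm_mean: np.ndarray | None = None,
        csf_mean: np.ndarray | None = None,
        n_motion: int = 6,
    ) -> "NuisanceSet":
        if n_motion not in (3, 6):
            raise ValidationError("motion_regressors flag must be 3 or 6")
        return cls(
            linear_trend=True,
            wm_mean=wm_mean,
            csf_mean=csf_mean,
            motion_regressors=bold.motion_params[:, :n_motion],
        )


def discard_initial(bold: BoldSeries, n: int = 10) -> BoldSeries:
    """Drop the first ``n`` frames (magnetization-equilibration discard)."""
    if n < 0:
        raise ValidationError("discard count must be nonnegative")
    if bold.n_frames - n < 20:
        raise ValidationError(
            f"discarding {n} of {bold.n_frames} frames leaves fewer than 20"
        )
    return BoldSeries(bold.data[n:], bold.tr_s, bold.motion_params[n:])


def regress_nuisance(bold: BoldSeries, nuisance: NuisanceSet) -> BoldSeries:
    """Replace each voxel series by its OLS residual on [intercept + nuisance].

    Residuals are exactly orthogonal to every regressor column.  A
    rank-deficient design is rejected with the offending columns named.
    """
    t = bold.n_frames
    nmat, names = nuisance.design(t)
    design = np.column_stack([np.ones(t), nmat])
    names = ["intercept"] + names

    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify columns that do not increase the rank when added
        collinear = []
        r = 0
        for j in range(design.shape[1]):
            rj = np.linalg.matrix_rank(design[:, : j + 1])
            if rj == r:
                collinear.append(names[j])
            r = rj
        raise ValidationError(f"rank-deficient nuisance design; collinear: {collinear}")

    flat = bold.data.reshape(t, -1)
    beta, *_ = np.linalg.lstsq(design, flat, rcond=None)
    resid = flat - design @ beta
    log.info("stage=regress_nuisance frames=%d regressors=%s", t, names)
    return BoldSeries(resid.reshape(bold.data.shape), bold.tr_s, bold.motion_params)


def bandpass(bold: BoldSeries, low_hz: float = 0.01, high_hz: float = 0.08) -> BoldSeries:
    """Zero-phase band-pass filter retaining [low_hz, high_hz].

    Implemented as an ideal (rectangular) filter in the frequency domain —
    the convention of resting-state fMRI toolchains — applied after
    reflection padding to suppress edge leakage.  The passband is preserved
    exactly at bin frequencies; everything outside (including DC) is
    removed.
    """
    nyquist = 0.5 / bold.tr_s
    if not (0 <= low_hz < high_hz <= nyquist):
        raise ValidationError(
            f"invalid band [{low_hz}, {high_hz}] for Nyquist {nyquist:.4f} Hz"
        )
    t = bold.n_frames
    flat = bold.data.reshape(t, -1)

    # reflect the series at both ends (without repeating edge samples)
    padded = np.concatenate([flat[1:][::-1], flat, flat[:-1][::-1]], axis=0)
    n = padded.shape[0]
    freqs = np.fft.rfftfreq(n, d=bold.tr_s)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    spectrum = np.fft.rfft(padded, axis=0)
    spectrum[~keep] = 0.0
    filtered = np.fft.irfft(spectrum, n=n, axis=0)[t - 1 : 2 * t - 1]
    return BoldSeries(filtered.reshape(bold.data.shape), bold.tr_s, bold.motion_params)


def framewise_displacement(motion_params: np.ndarray) -> np.ndarray:
    """Per-frame framewise displacement (Power-style).

    FD_t = sum |delta translation| + r * sum |delta rotation in rad|, with
    r = 50 mm; FD of the first frame is 0.  Rotations arrive in degrees.
    """
    mp = np.asarray(motion_params, dtype=float)
    if mp.ndim != 2 or mp.shape[1] != 6:
        raise ValidationError("motion parameters must be (n_frames, 6)")
    if mp.shape[0] < 2:
        raise ValidationError("need at least 2 frames for framewise displacement")
    delta = np.diff(mp, axis=0)
    trans = np.abs(delta[:, :3]).sum(axis=1)
    rot = np.abs(np.deg2rad(delta[:, 3:])).sum(axis=1) * FD_HEAD_RADIUS_MM
    return np.concatenate([[0.0], trans + rot])


def motion_exclusion(motion_params: np.ndarray) -> dict:
    """Apply the 3 mm / 3 degree exclusion rule.

    Returns ``{'passed': bool, 'max_translation_mm': float,
    'max_rotation_deg': float}``; a subject passes when every axis stays
    within the limits (the limits themselves are allowed).
    """
    mp = np.asarray(motion_params, dtype=float)
    if mp.ndim != 2 or mp.shape[1] != 6:
        raise ValidationError("motion parameters must be (n_frames, 6)")
    max_trans = float(np.abs(mp[:, :3]).max())
    max_rot = float(np.abs(mp[:, 3:]).max())
    passed = max_trans <= MAX_TRANSLATION_MM and max_rot <= MAX_ROTATION_DEG
    return {
        "passed": passed,
        "max_translation_mm": max_trans,
        "max_rotation_deg": max_rot,
    }


def preprocess(
    bold: BoldSeries,
    nuisance: NuisanceSet | None = None,
    n_discard: int = 10,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    n_motion: int = 6,
) -> BoldSeries:
    """Full temporal pipeline: discard -> nuisance regression -> band-pass."""
    out = discard_initial(bold, n_discard)
    if nuisance is None:
        nuisance = NuisanceSet.from_bold(out, n_motion=n_motion)
    out = regress_nuisance(out, nuisance)
    out = bandpass(out, low_hz, high_hz)
    log.info(
        "stage=preprocess frames_in=%d frames_out=%d band=[%g,%g]Hz",
        bold.n_frames,
        out.n_frames,
        low_hz,
        high_hz,
    )
    return out
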