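"""Synthetic three-group WMH cohort generator.

Everything downstream of image acquisition is testable against this module:
it produces an atlas parcellation with hub regions, per-subject BOLD series
with community covariance structure, CBF maps coupled to each subject's FCS
map at a group-specific strength, ASL label/control series that invert the
single-compartment quantification, and Table-1-like demographic/cognitive
records.

Design notes
------------
* Coupling is induced directly on z-scored maps (cbf_z = rho * fcs_z +
  sqrt(1 - rho^2) * noise), so the generating rho is exactly the population
  value of the per-subject coupling statistic before hub effects.
* Hub effects enter CBF as a fixed reduction of ``hub_effect_d`` times the
  map SD (10 ml/100g/min) in hub-region voxels, and FCS indirectly through
  a mild down-weighting of the community signal in hub voxels.
* ASL noise is additive Gaussian on the frames; the quantification is a
  deterministic map, so unbiased round-trip recovery is the only property
  that matters here.
* All randomness flows from one integer seed through ``numpy``
  SeedSequence spawning, so full generation is bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import reference
from .types import (
    AslAcqParams,
    AslSeries,
    AtlasParcellation,
    BoldSeries,
    CohortTable,
    MaskedVolume,
    SubjectRecord,
    ValidationError,
    GROUP_FAZEKAS_BANDS,
)

log = logging.getLogger("neurocouple")

__all__ = [
    "CohortSpec",
    "generate_atlas",
    "generate_subject_bold",
    "generate_fcs_field",
    "generate_subject_cbf",
    "generate_subject_asl",
    "generate_tables",
    "generate_coupling_cohort",
    "iter_subject_data",
    "simulate_to_dir",
    "simulate_regional_values",
]

#: target CBF scale of a generated map (ml/100g/min)
CBF_MEAN = 50.0
CBF_SD = 10.0


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort.

    Defaults reproduce the emulated study design: 32/24/30 subjects in the
    mild/moderate/severe groups, BOLD at TR = 2 s with 130 frames (10 to
    discard), and per-group global CBF-FCS coupling of 0.225/0.209/0.156.
    ``hub_effect_d`` is the standardized hub CBF reduction per group (in
    units of the within-map SD); the severe-group default of 1.2 puts hub
    perfusion loss well above the detection threshold of the region-wise
    permutation ANCOVA at these sample sizes, with the moderate group
    halfway.
    """

    group_sizes: dict[str, int] = dc_field(
        default_factory=lambda: dict(reference.GROUP_SIZES)
    )
    atlas_shape: tuple[int, int, int] = (18, 18, 18)
    mask_margin: int = 0
    n_regions: int = 24
    hub_fraction: float = 0.25
    n_communities: int = 4
    n_frames: int = 130
    n_discard: int = 10
    tr_s: float = 2.0
    community_weight: float = 0.6
    coupling_by_group: dict[str, float] = dc_field(
        default_factory=lambda: dict(reference.COUPLING_BY_GROUP)
    )
    hub_effect_d: dict[str, float] = dc_field(
        default_factory=lambda: {"mild": 0.0, "moderate": 0.6, "severe": 1.2}
    )
    asl_n_pairs: int = 40
    asl_noise_sd: float = 2.0
    asl_m0: float = 1000.0
    acq_params: AslAcqParams = dc_field(default_factory=AslAcqParams)
    risk_prevalences: dict[str, dict[str, float]] = dc_field(
        default_factory=lambda: {k: dict(v) for k, v in reference.RISK_PREVALENCES.items()}
    )
    male_prevalence: dict[str, float] = dc_field(
        default_factory=lambda: dict(reference.MALE_PREVALENCE)
    )
    cognition_params: dict[str, list[tuple[float, float]]] = dc_field(
        default_factory=lambda: {k: list(v) for k, v in reference.COGNITION_RAW_PARAMS.items()}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if n < 3:
                raise ValidationError(f"group {g}: size must be >= 3")
        for g, rho in self.coupling_by_group.items():
            if not -1.0 < rho < 1.0:
                raise ValidationError(f"group {g}: coupling must be in (-1, 1)")
        if self.n_frames <= self.n_discard:
            raise ValidationError("n_frames must exceed the discard count")

    @property
    def groups(self) -> list[str]:
        return [g for g in ("mild", "moderate", "severe") if g in self.group_sizes]


def _factor_triple(n: int) -> tuple[int, int, int]:
    """Most cube-like factorization n = a*b*c."""
    best = None
    for a in range(1, n + 1):
        if n % a:
            continue
        m = n // a
        for b in range(1, m + 1):
            if m % b:
                continue
            c = m // b
            spread = max(a, b, c) / min(a, b, c)
            if best is None or spread < best[0]:
                best = (spread, (a, b, c))
    return best[1]


def generate_atlas(spec: CohortSpec) -> tuple[AtlasParcellation, np.ndarray]:
    """Tile the in-mask grid into contiguous, roughly equal regions.

    The analysis mask (standing in for a gray-matter mask) is the whole grid
    by default, or the grid interior when ``spec.mask_margin`` excludes a
    border; regions are axis-aligned blocks of the masked part.  Hub regions
    are the ``hub_fraction`` of regions closest to the grid center.
    """
    shape = tuple(spec.atlas_shape)
    m = spec.mask_margin
    if min(shape) <= 2 * m:
        raise ValidationError("atlas grid too small for the mask margin")
    mask = np.zeros(shape, dtype=bool)
    core = tuple(slice(m, s - m) for s in shape)
    mask[core] = True
    n_in = int(mask.sum())
    if spec.n_regions > n_in // 8:
        raise ValidationError(
            f"{spec.n_regions} regions infeasible for {n_in} in-mask voxels"
        )

    splits = _factor_triple(spec.n_regions)
    interior = [s - 2 * m for s in shape]
    if any(splits[i] > interior[i] for i in range(3)):
        raise ValidationError("infeasible tiling: more blocks than voxels on an axis")

    bounds = [
        np.array_split(np.arange(m, shape[i] - m), splits[i]) for i in range(3)
    ]
    labels = np.zeros(shape, dtype=int)
    centers = []
    rid = 0
    for ix in bounds[0]:
        for iy in bounds[1]:
            for iz in bounds[2]:
                rid += 1
                labels[np.ix_(ix, iy, iz)] = rid
                centers.append([ix.mean(), iy.mean(), iz.mean()])
    centers = np.array(centers)

    n_hubs = max(1, int(round(spec.hub_fraction * spec.n_regions)))
    grid_center = (np.array(shape) - 1) / 2.0
    dist = np.linalg.norm(centers - grid_center, axis=1)
    hub_ids = set((np.argsort(dist, kind="stable")[:n_hubs] + 1).tolist())

    regions = pd.DataFrame(
        {
            "id": np.arange(1, spec.n_regions + 1),
            "name": [f"region_{i:03d}" for i in range(1, spec.n_regions + 1)],
            "is_hub": [i in hub_ids for i in range(1, spec.n_regions + 1)],
        }
    )
    atlas = AtlasParcellation(labels, regions)
    log.info(
        "stage=generate_atlas shape=%s regions=%d hubs=%d in_mask=%d",
        shape,
        spec.n_regions,
        n_hubs,
        n_in,
    )
    return atlas, mask


def _community_of_region(spec: CohortSpec) -> np.ndarray:
    """Contiguous mapping region index (0-based) -> community index."""
    return (
        np.arange(spec.n_regions) * spec.n_communities // spec.n_regions
    )


def generate_subject_bold(
    atlas: AtlasParcellation,
    mask: np.ndarray,
    spec: CohortSpec,
    subject_seed: int | np.random.SeedSequence,
    weight: float | None = None,
    hub_weight_scale: float = 1.0,
    nuisance_leak: float = 0.1,
) -> tuple[BoldSeries, dict[str, np.ndarray]]:
    """Simulate a BOLD series with community covariance structure.

    Each in-mask voxel's signal is ``w * latent(community) + (1 - w) *
    white noise``, so suprathreshold positive correlations concentrate
    within communities.  Hub-region voxels get their community weight
    multiplied by ``hub_weight_scale`` (< 1 lowers their FCS).  Small
    white-matter/CSF nuisance series leak into every voxel and are returned
    for the preprocessing stage to regress out.  Motion parameters are
    bounded random walks.
    """
    rng = np.random.default_rng(subject_seed)
    w = spec.community_weight if weight is None else weight
    if not 0 <= w <= 1:
        raise ValidationError("community weight must be in [0, 1]")

    t = spec.n_frames
    region_comm = _community_of_region(spec)
    latents = rng.standard_normal((spec.n_communities, t))
    wm = rng.standard_normal(t)
    csf = rng.standard_normal(t)

    flat_labels = atlas.labels.ravel()
    flat_mask = np.asarray(mask, bool).ravel()
    n_vox = flat_labels.size
    data = np.zeros((t, n_vox))

    in_idx = np.flatnonzero(flat_mask)
    vox_regions = flat_labels[in_idx]
    vox_comm = region_comm[vox_regions - 1]
    vox_w = np.full(in_idx.size, w)
    hub_set = set(atlas.hub_ids.tolist())
    is_hub_vox = np.isin(vox_regions, list(hub_set))
    vox_w[is_hub_vox] *= hub_weight_scale

    noise = rng.standard_normal((t, in_idx.size))
    signal = vox_w * latents[vox_comm].T + (1.0 - vox_w) * noise
    signal += nuisance_leak * (wm + csf)[:, None]
    data[:, in_idx] = signal

    # bounded random-walk motion (mm / degrees), reflecting at +/- 1.5
    steps = rng.normal(0.0, 0.04, size=(t, 6))
    walk = np.cumsum(steps, axis=0)
    walk = 1.5 - np.abs(np.mod(walk + 1.5, 6.0) - 3.0)
    bold = BoldSeries(data.reshape((t, *atlas.labels.shape)), spec.tr_s, walk)
    return bold, {"wm": wm, "csf": csf}


def generate_fcs_field(
    atlas: AtlasParcellation,
    mask: np.ndarray,
    seed: int | np.random.SeedSequence,
    region_sd: float = 0.3,
) -> MaskedVolume:
    """Fast FCS-like z-map: regional means plus voxel noise, z-scored.

    A lightweight stand-in for the BOLD-derived FCS map used by coupling
    parameter-recovery studies, where thousands of subjects are simulated
    and the full BOLD pathway would dominate runtime.
    """
    rng = np.random.default_rng(seed)
    mask = np.asarray(mask, bool)
    region_means = rng.normal(0.0, region_sd, size=atlas.region_ids.size)
    data = np.zeros(atlas.labels.shape)
    lab = atlas.labels[mask]
    data[mask] = region_means[lab - 1] + rng.standard_normal(lab.size)
    vals = data[mask]
    data[mask] = (vals - vals.mean()) / vals.std(ddof=1)
    return MaskedVolume(data, mask)


def generate_subject_cbf(
    fcs_zmap: MaskedVolume,
    rho: float,
    group_effect: float,
    seed: int | np.random.SeedSequence,
    atlas: AtlasParcellation | None = None,
    mean: float = CBF_MEAN,
    sd: float = CBF_SD,
) -> MaskedVolume:
    """CBF map coupled to a subject's FCS z-map at strength ``rho``.

    In-mask: cbf_z = rho * fcs_z + sqrt(1 - rho^2) * noise, restandardized
    and rescaled to mean 50, SD 10 ml/100g/min; hub-region voxels are then
    reduced by ``group_effect * SD``.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValidationError("coupling rho must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    mask = fcs_zmap.mask
    f = fcs_zmap.data[mask]
    eps = rng.standard_normal(f.size)
    z = rho * f + np.sqrt(1.0 - rho**2) * eps
    z = (z - z.mean()) / z.std(ddof=1)
    cbf_vals = mean + sd * z
    data = np.zeros_like(fcs_zmap.data)
    data[mask] = cbf_vals
    if atlas is not None and group_effect != 0.0:
        hub_vox = np.isin(atlas.labels, atlas.hub_ids) & mask
        data[hub_vox] -= group_effect * sd
    return MaskedVolume(np.clip(data, 0.0, None), mask, fcs_zmap.voxel_size_mm)


def generate_subject_asl(
    cbf_map: MaskedVolume,
    acq_params: AslAcqParams | None = None,
    n_pairs: int = 40,
    noise_sd: float = 2.0,
    seed: int | np.random.SeedSequence = 0,
    m0: float = 1000.0,
) -> AslSeries:
    """Invert the single-compartment model into label/control frames.

    The expected control-minus-label difference satisfies the
    quantification equation exactly, so quantify(generate(cbf)) is the
    identity at zero noise and unbiased otherwise (Gaussian frame noise).
    """
    if np.any(cbf_map.data[cbf_map.mask] < 0):
        raise ValidationError("CBF map must be nonnegative")
    params = acq_params or AslAcqParams()
    rng = np.random.default_rng(seed)

    t1b = params.blood_t1_s
    scale = (
        6000.0
        * params.partition_coefficient
        * np.exp(params.post_label_delay_s / t1b)
        / (2.0 * params.labeling_efficiency * t1b * (1.0 - np.exp(-params.labeling_duration_s / t1b)))
    )
    pd_ref = np.full(cbf_map.data.shape, m0)
    dm = cbf_map.data * pd_ref / scale

    frames = []
    tags = []
    for _ in range(n_pairs):
        label = m0 - dm / 2.0
        control = m0 + dm / 2.0
        if noise_sd > 0:
            label = label + rng.normal(0.0, noise_sd, size=dm.shape)
            control = control + rng.normal(0.0, noise_sd, size=dm.shape)
        frames.extend([label, control])
        tags.extend(["label", "control"])
    return AslSeries(np.stack(frames), tags, pd_ref, params)


def _draw_group_rows(
    spec: CohortSpec, group: str, n: int, rng: np.random.Generator, start: int
) -> list[SubjectRecord]:
    gi = spec.groups.index(group)
    lo, hi = GROUP_FAZEKAS_BANDS[group]
    age_m, age_s = reference.CONTINUOUS_SUMMARIES["age_years"][gi]
    edu_m, edu_s = reference.CONTINUOUS_SUMMARIES["education_years"][gi]
    rows = []
    for j in range(n):
        raw = {
            test: float(rng.normal(m, s))
            for test, per_group in spec.cognition_params.items()
            for (m, s) in [per_group[gi]]
        }
        rows.append(
            SubjectRecord(
                id=f"sub-{start + j:03d}",
                fazekas_total=int(rng.integers(lo, hi + 1)),
                group=group,
                age=float(np.clip(rng.normal(age_m, age_s), 50, 80)),
                sex="M" if rng.random() < spec.male_prevalence[group] else "F",
                education_years=float(np.clip(rng.normal(edu_m, edu_s), 5, 22)),
                hypertension=bool(rng.random() < spec.risk_prevalences["hypertension"][group]),
                diabetes=bool(rng.random() < spec.risk_prevalences["diabetes"][group]),
                smoking=bool(rng.random() < spec.risk_prevalences["smoking"][group]),
                drinking=bool(rng.random() < spec.risk_prevalences["drinking"][group]),
                cognition_raw=raw,
            )
        )
    return rows


def generate_tables(spec: CohortSpec, seed: int | np.random.SeedSequence | None = None) -> CohortTable:
    """Draw the demographic/cognitive table for the whole cohort.

    Risk factors are Bernoulli with per-group prevalences; raw cognition
    scores are Gaussian with per-group means/SDs (timed tests on a seconds
    scale, larger = worse); Fazekas totals are uniform within each group's
    band.  Cohort-wide cognition z-scores are filled in afterwards.
    """
    from .group_stats import zscore_cognition

    rng = np.random.default_rng(spec.seed if seed is None else seed)
    subjects: list[SubjectRecord] = []
    start = 1
    for group in spec.groups:
        n = spec.group_sizes[group]
        subjects.extend(_draw_group_rows(spec, group, n, rng, start))
        start += n

    raw = pd.DataFrame([dict(s.cognition_raw) for s in subjects])
    z = zscore_cognition(raw)
    for i, subj in enumerate(subjects):
        subj.cognition_z = {
            domain: float(z.iloc[i][test])
            for domain, test in reference.DOMAIN_TESTS.items()
        }
    return CohortTable(subjects)


def generate_coupling_cohort(
    spec: CohortSpec,
    atlas: AtlasParcellation,
    mask: np.ndarray,
    seed: int | np.random.SeedSequence,
) -> tuple[list[MaskedVolume], list[MaskedVolume], np.ndarray]:
    """Fast cohort of paired (FCS z-map, CBF map) volumes for coupling studies.

    Uses :func:`generate_fcs_field` instead of the BOLD pathway; CBF maps
    carry the per-group coupling strength and hub reduction of ``spec``.
    Returns (fcs_maps, cbf_maps, group_labels).
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    fcs_maps: list[MaskedVolume] = []
    cbf_maps: list[MaskedVolume] = []
    groups: list[str] = []
    n_total = sum(spec.group_sizes[g] for g in spec.groups)
    children = ss.spawn(2 * n_total)
    i = 0
    for group in spec.groups:
        rho = spec.coupling_by_group[group]
        d = spec.hub_effect_d.get(group, 0.0)
        for _ in range(spec.group_sizes[group]):
            fcs = generate_fcs_field(atlas, mask, children[i])
            cbf = generate_subject_cbf(fcs, rho, d, children[i + 1], atlas=atlas)
            fcs_maps.append(fcs)
            cbf_maps.append(cbf)
            groups.append(group)
            i += 2
    return fcs_maps, cbf_maps, np.array(groups)


def iter_subject_data(
    spec: CohortSpec,
    cohort: CohortTable,
    atlas: AtlasParcellation,
    mask: np.ndarray,
    seed: int | np.random.SeedSequence | None = None,
):
    """Yield full per-subject raw data, one subject at a time.

    For each subject: the BOLD series (with nuisance series), the subject's
    FCS z-map computed through the real preprocessing + FCS pipeline, a CBF
    map coupled to it at the group's strength, and the ASL series encoding
    that CBF map.  Streaming keeps memory flat for large cohorts.
    """
    from .connectivity import compute_fcs, zscore_map
    from .preproc import NuisanceSet, discard_initial, preprocess

    base = spec.seed if seed is None else seed
    ss = base if isinstance(base, np.random.SeedSequence) else np.random.SeedSequence(base)
    children = ss.spawn(3 * len(cohort))
    for i, subj in enumerate(cohort.subjects):
        d = spec.hub_effect_d.get(subj.group, 0.0)
        rho = spec.coupling_by_group[subj.group]
        hub_scale = max(0.0, 1.0 - 0.05 * d)
        bold, nuis = generate_subject_bold(
            atlas, mask, spec, children[3 * i], hub_weight_scale=hub_scale
        )
        kept = slice(spec.n_discard, None)
        nuisance = NuisanceSet(
            linear_trend=True,
            wm_mean=nuis["wm"][kept],
            csf_mean=nuis["csf"][kept],
            motion_regressors=bold.motion_params[kept],
        )
        clean = preprocess(bold, nuisance, n_discard=spec.n_discard)
        fcs = compute_fcs(clean, mask)
        fcs_z = zscore_map(fcs)
        cbf = generate_subject_cbf(fcs_z, rho, d, children[3 * i + 1], atlas=atlas)
        asl = generate_subject_asl(
            cbf,
            spec.acq_params,
            n_pairs=spec.asl_n_pairs,
            noise_sd=spec.asl_noise_sd,
            seed=children[3 * i + 2],
            m0=spec.asl_m0,
        )
        yield {
            "subject": subj,
            "bold": bold,
            "nuisance": nuisance,
            "fcs": fcs,
            "true_cbf": cbf,
            "asl": asl,
        }


def simulate_to_dir(spec: CohortSpec, out_dir, seed: int | None = None) -> CohortTable:
    """Write a complete synthetic cohort (NIfTI volumes + TSV tables) to disk."""
    from pathlib import Path

    from .io import write_atlas, write_cohort_table, write_volume
    from .types import MaskedVolume as MV

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base_seed = spec.seed if seed is None else seed
    ss = np.random.SeedSequence(base_seed)
    table_seed, data_seed = ss.spawn(2)

    atlas, mask = generate_atlas(spec)
    cohort = generate_tables(spec, table_seed)
    write_atlas(atlas, out / "atlas.nii.gz", out / "regions.tsv")
    write_volume(MV(mask.astype(float), np.ones(mask.shape, bool)), out / "gm_mask.nii.gz")
    write_cohort_table(cohort, out / "cohort.tsv")

    for data in iter_subject_data(spec, cohort, atlas, mask, data_seed):
        sid = data["subject"].id
        write_volume(data["bold"], out / f"{sid}_bold.nii.gz")
        write_volume(data["asl"].frames.mean(axis=0), out / f"{sid}_asl_mean.nii.gz")
        asl = data["asl"]
        write_volume(
            BoldSeries(asl.frames, 1.0, np.zeros((asl.frames.shape[0], 6))),
            out / f"{sid}_asl.nii.gz",
        )
        write_volume(MV(asl.pd_reference, np.ones(mask.shape, bool)), out / f"{sid}_pd.nii.gz")
        np.savetxt(
            out / f"{sid}_motion.tsv", data["bold"].motion_params, delimiter="\t"
        )
    log.info("stage=simulate_to_dir subjects=%d out=%s seed=%s", len(cohort), out, base_seed)
    return cohort


def simulate_regional_values(
    group_sizes: dict[str, int],
    effect_by_group: dict[str, float],
    n_regions: int,
    seed: int | np.random.SeedSequence,
    covariate_beta: tuple[float, float] = (0.3, 0.3),
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Regional measurement values for inference-calibration studies.

    Each region column is ``group_shift + beta_age * age_z + beta_sex * sex
    + N(0,1)`` across subjects, with group shifts ``-effect_by_group[g]``
    (standardized units).  With all effects zero the group null holds while
    the covariates still matter, which is the configuration used for
    type-I-error calibration of the permutation ANCOVA.

    Returns (values frame with one column per region, group labels,
    covariate matrix [age_z, sex]).
    """
    rng = np.random.default_rng(seed)
    groups = np.concatenate([[g] * n for g, n in group_sizes.items()])
    n = groups.size
    age_z = rng.standard_normal(n)
    sex = rng.integers(0, 2, size=n).astype(float)
    shift = np.array([-effect_by_group.get(g, 0.0) for g in groups])
    base = covariate_beta[0] * age_z + covariate_beta[1] * sex + shift
    values = base[:, None] + rng.standard_normal((n, n_regions))
    frame = pd.DataFrame(values, columns=[f"region_{i + 1:03d}" for i in range(n_regions)])
    return frame, groups, np.column_stack([age_z, sex])
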