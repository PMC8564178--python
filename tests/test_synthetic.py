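"""Synthetic cohort generator: structure, parameter encoding, reproducibility."""

import numpy as np
import pytest

from neurocouple.asl import cbf_from_asl
from neurocouple.connectivity import zscore_map
from neurocouple.coupling import global_coupling
from neurocouple.synthetic import (
    CohortSpec,
    generate_atlas,
    generate_fcs_field,
    generate_subject_asl,
    generate_subject_bold,
    generate_subject_cbf,
    generate_tables,
)
from neurocouple.types import ValidationError


class TestAtlas:
    def test_eight_regions_on_8cube(self):
        spec = CohortSpec(atlas_shape=(8, 8, 8), n_regions=8)
        atlas, mask = generate_atlas(spec)
        sizes = np.bincount(atlas.labels[mask], minlength=9)[1:]
        assert len(sizes) == 8
        assert (sizes >= 32).all()

    def test_partition_property(self, small_atlas):
        atlas, mask = small_atlas
        assert (atlas.labels[mask] > 0).all()
        assert (atlas.labels[~mask] == 0).all()
        present = np.unique(atlas.labels[mask])
        np.testing.assert_array_equal(np.sort(present), atlas.region_ids)

    def test_region_sizes_within_factor_two(self, small_atlas):
        atlas, mask = small_atlas
        sizes = np.bincount(atlas.labels[mask])[1:]
        assert sizes.max() <= 2 * sizes.min()

    def test_infeasible_tiling_rejected(self):
        with pytest.raises(ValidationError, match="infeasible"):
            generate_atlas(CohortSpec(atlas_shape=(4, 4, 4), n_regions=24))


class TestBold:
    def test_single_community_full_weight_perfect_correlation(self, small_atlas, small_spec):
        atlas, mask = small_atlas
        spec = CohortSpec(**{**small_spec.__dict__, "n_communities": 1, "community_weight": 1.0})
        bold, _ = generate_subject_bold(atlas, mask, spec, 1, nuisance_leak=0.0)
        series = bold.data.reshape(bold.n_frames, -1)[:, mask.ravel()]
        corr = np.corrcoef(series[:, :50].T)
        assert corr.min() > 0.999

    def test_zero_weight_uncorrelated(self, small_atlas, small_spec):
        atlas, mask = small_atlas
        bold, _ = generate_subject_bold(
            atlas, mask, small_spec, 2, weight=0.0, nuisance_leak=0.0
        )
        series = bold.data.reshape(bold.n_frames, -1)[:, mask.ravel()][:, :100]
        corr = np.corrcoef(series.T)
        off = corr[np.triu_indices_from(corr, 1)]
        assert abs(off.mean()) < 0.02

    def test_within_community_exceeds_between(self, small_atlas, small_spec):
        atlas, mask = small_atlas
        bold, _ = generate_subject_bold(atlas, mask, small_spec, 3, weight=0.8)
        series = bold.data.reshape(bold.n_frames, -1)[:, mask.ravel()]
        labels = atlas.labels[mask]
        comm = (labels - 1) * small_spec.n_communities // small_spec.n_regions
        # sample a fixed number of voxels per region so both communities appear
        pick = np.concatenate(
            [np.flatnonzero(labels == rid)[:20] for rid in atlas.region_ids]
        )
        series = series[:, pick]
        comm = comm[pick]
        corr = np.corrcoef(series.T)
        same = comm[:, None] == comm[None, :]
        iu = np.triu_indices_from(corr, 1)
        within = corr[iu][same[iu]].mean()
        between = corr[iu][~same[iu]].mean()
        assert within > between + 0.2

    def test_motion_bounded(self, small_atlas, small_spec):
        atlas, mask = small_atlas
        bold, _ = generate_subject_bold(atlas, mask, small_spec, 4)
        assert np.abs(bold.motion_params).max() <= 1.5


class TestCbfGeneration:
    def test_rho_one_gives_perfect_coupling(self, small_atlas):
        atlas, mask = small_atlas
        fcs = generate_fcs_field(atlas, mask, 10)
        cbf = generate_subject_cbf(fcs, 1.0, 0.0, 11)
        r = global_coupling(zscore_map(cbf), fcs)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_rho_zero_uncorrelated(self, small_atlas):
        atlas, mask = small_atlas
        fcs = generate_fcs_field(atlas, mask, 12)
        cbf = generate_subject_cbf(fcs, 0.0, 0.0, 13)
        r = global_coupling(zscore_map(cbf), fcs)
        assert abs(r) < 0.05

    def test_rho_recovery_at_study_value(self, small_atlas):
        # mild-group coupling strength: r = 0.225 across >= 4000 voxels
        atlas, mask = small_atlas
        assert mask.sum() >= 1000
        rs = []
        for seed in range(5):
            fcs = generate_fcs_field(atlas, mask, 100 + seed)
            cbf = generate_subject_cbf(fcs, 0.225, 0.0, 200 + seed)
            rs.append(global_coupling(zscore_map(cbf), fcs))
        assert np.mean(rs) == pytest.approx(0.225, abs=0.05)

    def test_scale_and_hub_reduction(self, small_atlas):
        atlas, mask = small_atlas
        fcs = generate_fcs_field(atlas, mask, 14)
        cbf = generate_subject_cbf(fcs, 0.2, 1.0, 15, atlas=atlas)
        hub_vox = np.isin(atlas.labels, atlas.hub_ids) & mask
        non_hub = mask & ~hub_vox
        assert cbf.data[non_hub].mean() == pytest.approx(50.0, abs=1.0)
        assert cbf.data[non_hub].mean() - cbf.data[hub_vox].mean() == pytest.approx(
            10.0, abs=1.5
        )

    def test_invalid_rho(self, small_atlas):
        atlas, mask = small_atlas
        fcs = generate_fcs_field(atlas, mask, 16)
        with pytest.raises(ValidationError):
            generate_subject_cbf(fcs, 1.5, 0.0, 17)


class TestAslGeneration:
    def test_round_trip_zero_noise(self, small_atlas):
        atlas, mask = small_atlas
        fcs = generate_fcs_field(atlas, mask, 20)
        cbf = generate_subject_cbf(fcs, 0.2, 0.0, 21)
        asl = generate_subject_asl(cbf, n_pairs=2, noise_sd=0.0, seed=22)
        rec = cbf_from_asl(asl)
        np.testing.assert_allclose(rec.data[mask], cbf.data[mask], rtol=1e-10)

    def test_zero_cbf_zero_difference(self, small_atlas):
        atlas, mask = small_atlas
        zero = generate_subject_cbf(generate_fcs_field(atlas, mask, 23), 0.0, 0.0, 24)
        zero = zero.with_data(np.zeros_like(zero.data))
        asl = generate_subject_asl(zero, n_pairs=3, noise_sd=0.0, seed=25)
        dm = asl.control_frames().mean(axis=0) - asl.label_frames().mean(axis=0)
        np.testing.assert_allclose(dm, 0.0, atol=1e-12)

    def test_noisy_recovery_unbiased(self, small_atlas):
        atlas, mask = small_atlas
        fcs = generate_fcs_field(atlas, mask, 26)
        cbf = generate_subject_cbf(fcs, 0.2, 0.0, 27)
        asl = generate_subject_asl(cbf, n_pairs=40, noise_sd=2.0, seed=28)
        rec = cbf_from_asl(asl, clamp_negative=False)
        err = rec.data[mask] - cbf.data[mask]
        assert abs(err.mean()) < 0.01 * cbf.data[mask].mean()


class TestTables:
    def test_group_sizes_exact(self, small_spec):
        cohort = generate_tables(small_spec, 5)
        frame = cohort.to_frame()
        assert frame.groupby("group").size().to_dict() == small_spec.group_sizes

    def test_prevalence_one_all_positive(self, small_spec):
        spec = CohortSpec(**{**small_spec.__dict__})
        spec.risk_prevalences = {
            k: {g: 1.0 for g in spec.groups} for k in spec.risk_prevalences
        }
        frame = generate_tables(spec, 6).to_frame()
        assert frame["hypertension"].all() and frame["diabetes"].all()

    def test_severe_group_worst_cognition(self):
        # aggregate over 100 seeds: severe lowest mean z in >= 4 of 5 domains
        spec = CohortSpec()
        domains = None
        sums = {}
        for seed in range(100):
            frame = generate_tables(spec, seed).to_frame()
            z_cols = [c for c in frame.columns if c.startswith("z_")]
            domains = z_cols
            means = frame.groupby("group")[z_cols].mean()
            for c in z_cols:
                sums.setdefault(c, []).append(
                    means.loc["severe", c] == means[c].min()
                )
        lowest = sum(np.mean(v) > 0.5 for v in sums.values())
        assert lowest >= 4

    def test_fazekas_within_group_band(self, small_spec):
        frame = generate_tables(small_spec, 7).to_frame()
        for group, (lo, hi) in {"mild": (1, 2), "moderate": (3, 4), "severe": (5, 6)}.items():
            vals = frame.loc[frame["group"] == group, "fazekas_total"]
            assert vals.between(lo, hi).all()

    def test_timed_tests_sign_flipped(self, small_spec):
        frame = generate_tables(small_spec, 8).to_frame()
        # fastest TMT-A subject carries the highest processing-speed z
        fastest = frame["raw_tmt_a"].idxmin()
        assert frame.loc[fastest, "z_processing_speed"] == frame["z_processing_speed"].max()


def test_generation_bit_reproducible(small_spec, small_atlas):
    atlas, mask = small_atlas
    a = generate_tables(small_spec, 9).to_frame()
    b = generate_tables(small_spec, 9).to_frame()
    assert a.equals(b)
    b1, _ = generate_subject_bold(atlas, mask, small_spec, 99)
    b2, _ = generate_subject_bold(atlas, mask, small_spec, 99)
    np.testing.assert_array_equal(b1.data, b2.data)
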