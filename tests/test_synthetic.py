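"""Synthetic atlas, lesion and cohort generators."""

import numpy as np
import pandas as pd
import pytest

from cst_recovery import (
    CohortSpec,
    SyntheticAtlasSpec,
    TemplateSpace,
    cst_injury,
    lesion_side,
    make_atlas,
    make_cohort,
    make_lesion,
    partial_correlation,
)
from cst_recovery.synthetic import GROUP_NAMES
from conftest import brute_force_injury


class TestAtlas:
    def test_hemispheres_disjoint_nonempty_and_equal(self, space, atlas):
        left, right = atlas
        assert not (left.data & right.data).any()
        # mirrored default spec: equal voxel counts, verified by brute count
        assert int(left.data.sum()) == int(right.data.sum()) > 0
        zs = left.data.any(axis=(0, 1))
        assert zs.sum() >= 16

    def test_mirrored_spec_reflects_across_midline(self, space, atlas):
        left, right = atlas
        assert np.array_equal(right.data, np.flip(left.data, axis=0))

    def test_zero_radius_gives_single_voxel_per_slice(self, space):
        spec = SyntheticAtlasSpec.default(space, radius_mm=0.0)
        left, _ = make_atlas(space, spec)
        per_slice = left.data.sum(axis=(0, 1))
        assert set(np.unique(per_slice[per_slice > 0])) == {1}
        from cst_recovery import partition_tract

        assert partition_tract(left, n=16).n_subsections == 16

    def test_midline_crossing_rejected(self, space):
        spec = SyntheticAtlasSpec.default(space)
        bad = SyntheticAtlasSpec(
            centerline_left=spec.centerline_left + [space.midline_index, 0],
            z_range=spec.z_range,
            radius_mm=spec.radius_mm,
        )
        with pytest.raises(ValueError, match="midline"):
            make_atlas(space, bad)


class TestLesion:
    @pytest.mark.parametrize("k", range(17))
    def test_generator_scorer_round_trip_exact(self, space, atlas, k):
        lesion = make_lesion(space, "left", k / 16, atlas, seed=100 + k)
        assert cst_injury(lesion, atlas[0]).injured_count == k

    def test_round_trip_matches_brute_force_oracle(self, space, atlas):
        lesion = make_lesion(space, "left", 5 / 16, atlas, seed=7)
        injured, _ = brute_force_injury(lesion.data, atlas[0].data)
        assert injured == 5
        assert cst_injury(lesion, atlas[0]).value == 0.3125

    def test_target_zero_is_disjoint_from_tract_but_nonempty(self, space, atlas):
        lesion = make_lesion(space, "right", 0.0, atlas, seed=3, spill=False)
        assert not (lesion.data & atlas[1].data).any()
        assert lesion.count() > 0
        assert cst_injury(lesion, atlas[1]).value == 0.0

    def test_lesion_is_unilateral(self, space, atlas):
        for side, expect in (("left", "left"), ("right", "right")):
            lesion = make_lesion(space, side, 8 / 16, atlas, seed=11)
            assert lesion_side(lesion, space.midline_index) == expect

    def test_off_grid_target_rejected(self, space, atlas):
        with pytest.raises(ValueError, match="grid"):
            make_lesion(space, "left", 0.3, atlas, seed=0)

    def test_forced_spill_impossible_for_small_subsections(self, space):
        spec = SyntheticAtlasSpec.default(space, radius_mm=0.0)  # 1-2 voxels/slab
        tiny = make_atlas(space, spec)
        with pytest.raises(ValueError, match="subsection 0"):
            make_lesion(space, "left", 2 / 16, tiny, seed=0, spill=True)

    def test_reproducible_under_seed(self, space, atlas):
        a = make_lesion(space, "left", 6 / 16, atlas, seed=42)
        b = make_lesion(space, "left", 6 / 16, atlas, seed=42)
        assert np.array_equal(a.data, b.data)


class TestCohort:
    def test_reproducible_and_bounded(self):
        a = make_cohort(CohortSpec(n_patients=80, seed=5))
        b = make_cohort(CohortSpec(n_patients=80, seed=5))
        pd.testing.assert_frame_equal(a.patients, b.patients)
        pd.testing.assert_frame_equal(a.assessments, b.assessments)
        p = a.patients
        for col, hi in [
            ("initial_fma_ue", 66),
            ("followup_fma_ue", 66),
            ("initial_fma_le", 34),
            ("followup_fma_le", 34),
        ]:
            assert p[col].between(0, hi).all()
            assert (p[col] == p[col].astype(int)).all()
        assert set(p.latent_group) <= set(GROUP_NAMES)

    def test_injury_exactly_on_sixteenth_grid(self):
        p = make_cohort(CohortSpec(n_patients=200, seed=1)).patients
        assert ((p.cst_injury * 16) == p.cst_injured_count).all()
        assert p.cst_injured_count.between(0, 16).all()

    def test_followup_rarely_decreases(self):
        p = make_cohort(CohortSpec(n_patients=1000, seed=2)).patients
        assert (p.followup_fma_ue >= p.initial_fma_ue).mean() >= 0.9
        assert (p.followup_fma_le >= p.initial_fma_le).mean() >= 0.9

    def test_null_injury_effect_gives_null_severe_partial_correlation(self):
        spec = CohortSpec(n_patients=500, seed=9, injury_effect=0.0)
        p = make_cohort(spec).patients
        sev = p[(p.cst_injury < 1.0) & (p.initial_fma_ue < 35)]
        r, _, _ = partial_correlation(
            sev.cst_injury.to_numpy(), sev.followup_fma_ue.to_numpy(),
            sev.initial_fma_ue.to_numpy(),
        )
        assert abs(r) < 0.15

    def test_ceiling_filter_yields_reference_cohort_size(self):
        # 67 patients, ~half the mild group above the UE ceiling
        sizes = [
            (make_cohort(CohortSpec(n_patients=67, seed=s)).patients
             .query("initial_fma_ue <= 59").shape[0])
            for s in range(15)
        ]
        assert abs(np.mean(sizes) - 53) <= 4  # ~53 within sampling error

    def test_initial_followup_correlation_near_generating_value(self):
        # defaults are calibrated to r ~ 0.8 overall
        p = make_cohort(CohortSpec(n_patients=1000, seed=4)).patients
        r = np.corrcoef(p.initial_fma_ue, p.followup_fma_ue)[0, 1]
        assert abs(r - 0.8) <= 0.03

    def test_parameter_recovery_within_two_se(self):
        # pooled severe-stratum standardized injury slope ~ injury_effect
        from cst_recovery import multiple_regression

        spec = CohortSpec(n_patients=300, seed=6)
        p = make_cohort(spec).patients
        sev = p[(p.cst_injury < 1.0) & (p.initial_fma_ue < 35)]
        rep = multiple_regression(
            sev.followup_fma_ue, sev[["initial_fma_ue", "cst_injury"]]
        )
        se = np.sqrt((1 - rep.r2) / (len(sev) - 3))
        assert abs(rep.beta["cst_injury"] - spec.injury_effect) <= 2 * se

    def test_small_cohort_rejected(self):
        with pytest.raises(ValueError, match="n_patients"):
            CohortSpec(n_patients=9)

    def test_bad_mix_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            CohortSpec(cluster_mix=(0.5, 0.4, 0.4))

    def test_masks_match_tabulated_injury(self, space, atlas):
        cohort = make_cohort(
            CohortSpec(n_patients=10, seed=12), space=space, atlas=atlas, with_masks=True
        )
        assert cohort.masks is not None and len(cohort.masks) == 10
        for _, row in cohort.patients.iterrows():
            lesion = cohort.masks[row.patient_id]
            tract = atlas[0] if row.lesion_side == "left" else atlas[1]
            assert cst_injury(lesion, tract).injured_count == row.cst_injured_count

    def test_assessments_reproduce_selected_scores(self):
        from cst_recovery import select_followup

        cohort = make_cohort(CohortSpec(n_patients=60, seed=13))
        selected, audit = select_followup(cohort.assessments)
        assert audit.n_excluded == 0
        merged = cohort.patients.merge(selected, on="patient_id", suffixes=("", "_sel"))
        assert (merged.initial_fma_ue == merged.initial_fma_ue_sel).all()
        assert (merged.followup_fma_ue == merged.followup_fma_ue_sel).all()

    def test_missing_followup_rate_produces_exclusions(self):
        from cst_recovery import select_followup

        cohort = make_cohort(CohortSpec(n_patients=100, seed=14, missing_followup_rate=0.2))
        _, audit = select_followup(cohort.assessments)
        assert audit.n_excluded > 0
        assert all(v == "incomplete FMA data" for v in audit.reasons.values())
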