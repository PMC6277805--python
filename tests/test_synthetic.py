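import numpy as np
import pytest

from motorgraph.stats import pearson_with_p
from motorgraph.synthetic import (
    CohortSpec,
    build_target_correlation,
    default_communities,
    generate_cohort,
    node_effect_edges,
    read_cohort,
    within_community_effect_edges,
    write_cohort,
)


class TestTargetCorrelation:
    def test_no_effect_means_identical_sessions(self, atlas):
        spec = CohortSpec(atlas=atlas)
        np.testing.assert_array_equal(
            build_target_correlation(spec, "pre"), build_target_correlation(spec, "post")
        )

    def test_single_community_constant_offdiagonal(self, atlas):
        spec = CohortSpec(atlas=atlas, communities={"all": atlas.labels})
        t = build_target_correlation(spec, "pre")
        off = t[~np.eye(20, dtype=bool)]
        np.testing.assert_allclose(off, 0.45)
        np.testing.assert_allclose(np.diag(t), 1.0)

    def test_effect_edge_raises_post_entry(self, atlas):
        spec = CohortSpec(atlas=atlas, effect_edges=(("M1_R", "SMA_R", 0.2),))
        pre = build_target_correlation(spec, "pre")
        post = build_target_correlation(spec, "post")
        i, j = atlas.labels.index("M1_R"), atlas.labels.index("SMA_R")
        # both in the ipsilesional cortical community: base + 0.2
        assert pre[i, j] == pytest.approx(0.45)
        assert post[i, j] == pytest.approx(0.65, abs=0.02)  # PD repair may nudge

    def test_positive_definiteness_enforced(self, atlas):
        spec = CohortSpec(atlas=atlas, effect_edges=node_effect_edges(atlas, "M1_R", 0.25))
        t = build_target_correlation(spec, "post")
        assert np.linalg.eigvalsh(t).min() > 0

    def test_impossible_targets_rejected(self, atlas):
        with pytest.raises(ValueError):
            CohortSpec(atlas=atlas, effect_edges=(("M1_R", "SMA_R", 0.7),))

    def test_default_communities_partition_all_rois(self, atlas):
        groups = default_communities(atlas)
        members = [lab for labs in groups.values() for lab in labs]
        assert sorted(members) == sorted(atlas.labels)
        assert "M1_R" in groups["ipsilesional_cortical"]
        assert "Th_L" in groups["subcortical"]


class TestGenerateCohort:
    def test_same_seed_is_bit_identical(self, atlas):
        spec = CohortSpec(atlas=atlas, n_subjects=2, n_timepoints=50, seed=9)
        a = generate_cohort(spec)
        b = generate_cohort(spec)
        for (pre_a, post_a), (pre_b, post_b) in zip(a.sessions, b.sessions):
            np.testing.assert_array_equal(pre_a.data, pre_b.data)
            np.testing.assert_array_equal(post_a.data, post_b.data)
        assert a.behavior == b.behavior

    def test_long_series_recovers_target_correlation(self, atlas):
        # AR smoothing off and noise off: the sampler alone must hit the
        # target within Monte-Carlo tolerance at T = 5000.  Per-entry
        # sigma = (1 - r^2)/sqrt(T) <= 0.014; a 4-sigma bound over the 190
        # distinct entries holds with ~99% probability for any seed.
        spec = CohortSpec(
            atlas=atlas, n_subjects=1, n_timepoints=5000,
            ar_coefficient=0.0, noise_sd=0.0, seed=21,
        )
        cohort = generate_cohort(spec)
        target = build_target_correlation(spec, "pre")
        empirical = np.corrcoef(cohort.sessions[0][0].data.to_numpy(), rowvar=False)
        assert np.abs(empirical - target).max() < 0.06
        assert np.abs(empirical - target).mean() < 0.02

    def test_noise_attenuates_correlations(self, atlas):
        common = dict(atlas=atlas, n_subjects=1, n_timepoints=4000, seed=3)
        clean = generate_cohort(CohortSpec(noise_sd=0.0, **common))
        noisy = generate_cohort(CohortSpec(noise_sd=1.0, **common))
        iu = np.triu_indices(20, k=1)
        r_clean = np.corrcoef(clean.sessions[0][0].data.to_numpy(), rowvar=False)[iu]
        r_noisy = np.corrcoef(noisy.sessions[0][0].data.to_numpy(), rowvar=False)[iu]
        assert r_noisy.mean() < r_clean.mean()

    def test_effect_edge_shifts_sample_correlation(self, atlas):
        # +0.3 on one edge, study-sized sessions: mean post-pre shift positive
        # in nearly all replicates
        hits = 0
        reps = 25
        for rep in range(reps):
            spec = CohortSpec(
                atlas=atlas, n_subjects=13,
                effect_edges=(("M1_R", "SMA_R", 0.3),), seed=500 + rep,
            )
            cohort = generate_cohort(spec)
            hits += np.mean(cohort.effect_strengths) > 0
        assert hits >= 0.9 * reps

    def test_zero_coupling_gives_weak_brain_behavior_correlation(self, atlas):
        rs = []
        for rep in range(15):
            spec = CohortSpec(
                atlas=atlas, n_subjects=13, behavior_coupling=0.0,
                effect_edges=(("M1_R", "SMA_R", 0.3),), seed=700 + rep,
            )
            cohort = generate_cohort(spec)
            x = np.array(cohort.effect_strengths)
            y = np.array([r.arat_post - r.arat_pre for r in cohort.behavior])
            if np.std(y) == 0:
                continue
            rs.append(abs(pearson_with_p(x, y).R))
        assert np.median(rs) < 0.3


class TestRoundTrip:
    def test_write_then_read_preserves_cohort(self, atlas, tmp_path):
        spec = CohortSpec(atlas=atlas, n_subjects=3, n_timepoints=40, seed=2)
        cohort = generate_cohort(spec)
        write_cohort(cohort, tmp_path)
        sessions, behavior = read_cohort(tmp_path)
        assert len(sessions) == 3
        assert len(behavior) == 3
        for (pre_w, post_w), (pre_r, post_r) in zip(cohort.sessions, sessions):
            np.testing.assert_allclose(pre_w.data, pre_r.data, atol=1e-12)
            np.testing.assert_allclose(post_w.data, post_r.data, atol=1e-12)
        assert [b.subject_id for b in behavior] == [b.subject_id for b in cohort.behavior]

    def test_within_community_edges_cover_expected_count(self, atlas):
        groups = default_communities(atlas)
        edges = within_community_effect_edges(groups, 0.1)
        # communities of 5, 5, 4, 6 ROIs: 10 + 10 + 6 + 15 pairs
        assert len(edges) == 41
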