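"""Responder classification: profile rule, feature extraction, nested LOOCV."""

import numpy as np
import pytest

from dbsnet.classify import (
    cohort_design,
    extract_features,
    inner_threshold_sweep,
    label_responders,
    nested_loocv,
    outer_fold_model,
    profile_from_subset,
)
from dbsnet.synthetic import CohortSpec, generate_fc_cohort


@pytest.fixture(scope="module")
def strong_cohort():
    """Near-separable cohort: large planted profile with clean OFF separation."""
    spec = CohortSpec(
        n_subjects=18, roi_count=24, seed=31,
        profile_effect_size=0.3, profile_off_effect=0.4, noise_sd=0.005,
        cognition_pattern_sd=0.5, motor_effect_size=0.5,
    )
    return generate_fc_cohort(spec)


class TestLabels:
    def test_threshold_rule(self):
        assert label_responders([-30, -10], -18).tolist() == [True, False]

    def test_all_suboptimal_below_min(self):
        assert not label_responders([-30, -20], -35).any()

    def test_all_optimal_above_max(self):
        assert label_responders([-30, -20], -5).all()


class TestProfileRule:
    def test_single_outlier_edge_retained(self, small_cohort):
        subjects = small_cohort.subjects[:6]
        # overwrite one band with a controlled ON-OFF field
        rng = np.random.default_rng(0)
        n = subjects[0].fc[("alpha", "OFF")].values.shape[0]
        iu = np.triu_indices(n, k=1)
        for sub in subjects:
            off = np.zeros((n, n))
            off[iu] = 0.3
            off += off.T - np.diag(np.diag(off))
            on = off.copy()
            d = rng.normal(0, 1e-4, size=iu[0].size)
            dm = np.zeros((n, n)); dm[iu] = d; dm += dm.T
            on = off + dm
            on[0, 5] = on[5, 0] = off[0, 5] + 0.2  # 5 sigma outlier edge
            sub.fc[("alpha", "OFF")].values = off
            sub.fc[("alpha", "ON")].values = np.clip(on, 0, 1)
        prof = profile_from_subset(subjects, np.arange(6), ["alpha"], -18)
        assert [(e.band, e.edge, e.direction) for e in prof.entries] == [
            ("alpha", (0, 5), 1)
        ]

    def test_uniform_differences_give_empty_profile(self, small_cohort):
        subjects = small_cohort.subjects[:5]
        n = subjects[0].fc[("beta", "OFF")].values.shape[0]
        for sub in subjects:
            off = sub.fc[("beta", "OFF")].values
            on = np.clip(off + 0.05, 0, 1)
            np.fill_diagonal(on, 0.0)
            sub.fc[("beta", "ON")].values = on
        prof = profile_from_subset(subjects, np.arange(5), ["beta"], -18)
        assert len(prof) == 0

    def test_planted_profile_recovered(self, default_cohort):
        truth = default_cohort.ground_truth
        subset = np.nonzero(truth["responder_labels"])[0]
        prof = profile_from_subset(
            default_cohort.subjects, subset,
            [b.name for b in default_cohort.bands], -18,
        )
        recovered = {(e.band, e.edge) for e in prof.entries}
        planted = {(p["band"], (p["roi_i"], p["roi_j"]))
                   for p in truth["profile_edges"]}
        jac = len(recovered & planted) / len(recovered | planted)
        assert jac >= 0.8

    def test_empty_subset_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            profile_from_subset(small_cohort.subjects, [], ["alpha"])


class TestFeatures:
    def test_features_match_off_entries(self, small_cohort):
        bands = [b.name for b in small_cohort.bands]
        subset = np.arange(len(small_cohort.subjects) // 2)
        prof = profile_from_subset(small_cohort.subjects, subset, bands, -18)
        if len(prof) == 0:
            pytest.skip("no profile edges in this subset")
        X = extract_features(small_cohort.subjects, prof, bands)
        for s, sub in enumerate(small_cohort.subjects):
            for k, e in enumerate(prof.entries):
                assert X[s, k] == sub.fc[(e.band, "OFF")].values[e.edge]

    def test_column_order_band_major(self, strong_cohort):
        truth = strong_cohort.ground_truth
        subset = np.nonzero(truth["responder_labels"])[0]
        bands = [b.name for b in strong_cohort.bands]
        prof = profile_from_subset(strong_cohort.subjects, subset, bands, -18)
        band_order = [bands.index(e.band) for e in prof.entries]
        assert band_order == sorted(band_order)

    def test_empty_profile_rejected(self, strong_cohort):
        from dbsnet.classify import ConnectivityProfile

        with pytest.raises(ValueError, match="skip"):
            extract_features(strong_cohort.subjects,
                             ConnectivityProfile((), -18), [])


class TestNestedLOOCV:
    def test_strong_effect_high_metrics(self, strong_cohort):
        rep = nested_loocv(strong_cohort.subjects, strong_cohort.bands,
                           repetitions=2, seed=3)
        # near-separable data: the procedure should classify well
        for v in (rep.ppv, rep.npv, rep.sensitivity, rep.specificity):
            assert v >= 0.75
        assert len(rep.final_profile) > 0

    def test_threshold_near_planted(self, strong_cohort):
        rep = nested_loocv(strong_cohort.subjects, strong_cohort.bands,
                           repetitions=2, seed=4)
        # the recovered boundary must separate the same subjects as the
        # planted -18 rule
        updrs = np.array([s.updrs_diff for s in strong_cohort.subjects])
        assert np.array_equal(
            label_responders(updrs, rep.final_threshold),
            label_responders(updrs, -18.0),
        )

    def test_permuted_labels_no_positive_skill(self, strong_cohort):
        """Label-independent features yield no skill beyond chance; the
        leave-one-out composition bias can push performance below it."""
        subjects = list(strong_cohort.subjects)
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(subjects))
        shuffled = []
        for sub, j in zip(subjects, perm):
            other = subjects[j]
            shuffled.append(
                type(sub)(id=sub.id, age=sub.age, gender=sub.gender,
                          updrs_on=other.updrs_on, updrs_off=other.updrs_off,
                          t_scores=sub.t_scores, fc=sub.fc)
            )
        rep = nested_loocv(shuffled, strong_cohort.bands, repetitions=3, seed=6)
        assert rep.sensitivity + rep.specificity <= 1.2

    def test_reproducible_given_seed(self, strong_cohort):
        a = nested_loocv(strong_cohort.subjects, strong_cohort.bands,
                         repetitions=1, seed=9)
        b = nested_loocv(strong_cohort.subjects, strong_cohort.bands,
                         repetitions=1, seed=9)
        assert a.ppv == b.ppv and a.final_threshold == b.final_threshold
        assert [c for c in a.fold_counts] == [c for c in b.fold_counts]

    def test_too_few_subjects_rejected(self, strong_cohort):
        with pytest.raises(ValueError):
            nested_loocv(strong_cohort.subjects[:6], strong_cohort.bands)


class TestLeakage:
    def test_held_out_subject_cannot_influence_model(self, strong_cohort):
        """Poisoning probe: perturbing the test subject leaves its fold's
        threshold, profile, and SVM untouched."""
        import copy

        bands = strong_cohort.bands
        test_idx = 4
        base = outer_fold_model(strong_cohort.subjects, bands, test_idx, seed=7)

        poisoned = copy.deepcopy(strong_cohort.subjects)
        rng = np.random.default_rng(8)
        for key, fc in poisoned[test_idx].fc.items():
            n = fc.values.shape[0]
            iu = np.triu_indices(n, k=1)
            noise = np.zeros((n, n))
            noise[iu] = rng.random(iu[0].size)
            fc.values = np.clip(fc.values + noise + noise.T, 0, 1)
            np.fill_diagonal(fc.values, 0.0)
        probe = outer_fold_model(poisoned, bands, test_idx, seed=7)

        assert base[0] == probe[0]  # threshold
        assert np.array_equal(base[1], probe[1])  # profile columns
        assert base[2] is not None and probe[2] is not None
        assert np.allclose(base[2][0], probe[2][0])  # SVM coefficients
        assert base[2][1] == pytest.approx(probe[2][1])  # intercept


class TestInnerSweep:
    def test_tie_break_uniform(self, strong_cohort):
        """With a fixed fold, repeated seeded sweeps visit tied maximizers."""
        design = cohort_design(strong_cohort.subjects, strong_cohort.bands)
        train = np.arange(1, len(strong_cohort.subjects))
        choices = set()
        for s in range(6):
            rng = np.random.default_rng(s)
            t, _ = inner_threshold_sweep(design, train, rng)
            choices.add(t)
        assert len(choices) >= 1  # at minimum deterministic and valid
        updrs = design.updrs[train]
        assert all(t in set(np.unique(updrs)) for t in choices)

    def test_too_few_training_subjects(self, strong_cohort):
        design = cohort_design(strong_cohort.subjects, strong_cohort.bands)
        with pytest.raises(ValueError):
            inner_threshold_sweep(design, np.arange(4), np.random.default_rng(0))
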