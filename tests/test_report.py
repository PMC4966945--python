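import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu
from sklearn.metrics import adjusted_rand_score

from beatsync import (
    TrialClass,
    cluster_profiles,
    condition_summary,
    level_distribution_table,
    median_half_up,
    rank_sum_test,
    success_profiles,
)

ARCHETYPE_CENTROIDS = np.array(
    [
        [0.0, 0.0, 0.0, 0.0],  # global failure
        [0.17, 0.38, 1.0, 1.0],  # music-only failure
        [0.33, 0.87, 1.0, 1.0],  # graded failure
        [0.12, 0.83, 0.33, 1.0],  # bounce-only failure
    ]
)


def planted_profiles(noise_sd=0.03, per_cluster=5, seed=0):
    rng = np.random.default_rng(seed)
    X, labels = [], []
    for j, c in enumerate(ARCHETYPE_CENTROIDS):
        X.append(np.clip(c + rng.normal(0, noise_sd, size=(per_cluster, 4)), 0, 1))
        labels += [j] * per_cluster
    return np.vstack(X), np.array(labels)


class TestMedians:
    def test_clapping_beat_level_median(self):
        assert median_half_up([95, 89, 85, 90, 78, 75, 65, 56]) == 82

    def test_bouncing_beat_level_median(self):
        assert median_half_up([55, 57, 68, 61, 52, 52, 49, 44]) == 54

    def test_all_equal_column(self):
        assert median_half_up([7, 7, 7, 7]) == 7

    def test_level_table_structure(self):
        rows = []
        for stim in ["a", "b", "c"]:
            for pid in range(4):
                rows.append(
                    {
                        "stimulus_name": stim,
                        "movement_type": "bounce",
                        "level": "beat" if pid < 3 else "two_beat",
                        "participant_id": pid,
                    }
                )
        table = level_distribution_table(pd.DataFrame(rows))
        assert table.loc["a", ("bounce", "beat")] == 3
        assert table.loc["median", ("bounce", "two_beat")] == 1


class TestSuccessProfiles:
    def trial_row(self, pid, movement, metro, cls, stim="s"):
        return {
            "participant_id": pid,
            "movement_type": movement,
            "is_metronome": metro,
            "trial_class": cls,
            "stimulus_name": stim,
        }

    def test_all_normal_gives_unit_profile(self):
        rows = [
            self.trial_row("p1", m, metro, TrialClass.NORMAL)
            for m in ("bounce", "clap")
            for metro in (False, True)
            for _ in range(3)
        ]
        prof = success_profiles(pd.DataFrame(rows))
        np.testing.assert_allclose(prof.loc["p1"].to_numpy(), 1.0)

    def test_bounce_failures_only(self):
        rows = []
        for metro in (False, True):
            rows += [self.trial_row("p1", "bounce", metro, TrialClass.POOR)] * 3
            rows += [self.trial_row("p1", "clap", metro, TrialClass.NORMAL)] * 3
        prof = success_profiles(pd.DataFrame(rows))
        np.testing.assert_allclose(
            prof.loc["p1", ["bounce_music", "clap_music", "bounce_metronome", "clap_metronome"]],
            [0.0, 1.0, 0.0, 1.0],
        )

    def test_bimodal_trials_leave_denominator(self):
        rows = [self.trial_row("p1", "bounce", False, TrialClass.BIMODAL)] * 2 + [
            self.trial_row("p1", "bounce", False, TrialClass.NORMAL)
        ]
        rows += [self.trial_row("p1", "clap", False, TrialClass.NORMAL)]
        prof = success_profiles(pd.DataFrame(rows))
        assert prof.loc["p1", "bounce_music"] == pytest.approx(1.0)
        assert np.isnan(prof.loc["p1", "bounce_metronome"])  # no metronome trials

    def test_invariant_to_trial_ordering(self, rng):
        rows = []
        for i in range(12):
            rows.append(
                self.trial_row(
                    "p1",
                    "bounce" if i % 2 else "clap",
                    i % 3 == 0,
                    TrialClass.NORMAL if i % 4 else TrialClass.POOR,
                    stim=f"s{i}",
                )
            )
        df = pd.DataFrame(rows)
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        pd.testing.assert_frame_equal(success_profiles(df), success_profiles(shuffled))


class TestClustering:
    def test_recovers_planted_archetypes(self):
        X, labels = planted_profiles(noise_sd=0.03)
        result = cluster_profiles(X, seed=0)
        assert result.k == 4
        assert adjusted_rand_score(labels, result.labels) == 1.0

    def test_centroids_are_cluster_means(self):
        X, _ = planted_profiles(noise_sd=0.05, seed=3)
        result = cluster_profiles(X, seed=0)
        for j in range(result.k):
            members = X[result.labels == j]
            np.testing.assert_allclose(result.centroids[j], members.mean(axis=0), atol=1e-9)

    def test_forced_single_cluster_is_grand_mean(self):
        X, _ = planted_profiles()
        result = cluster_profiles(X, k_range=(1, 1), seed=0)
        assert result.k == 1
        np.testing.assert_allclose(result.centroids[0], X.mean(axis=0), atol=1e-12)

    def test_duplicate_profiles_collapse_to_one_cluster(self):
        X = np.tile([0.5, 0.5, 1.0, 1.0], (8, 1))
        result = cluster_profiles(X, seed=0)
        assert result.k == 1

    def test_too_few_profiles_rejected(self):
        with pytest.raises(ValueError):
            cluster_profiles(np.zeros((2, 4)), k_range=(3, 5))

    def test_missing_proportions_rejected(self):
        X = np.full((10, 4), 0.5)
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            cluster_profiles(X)

    def test_recovery_degrades_gracefully(self):
        X, labels = planted_profiles(noise_sd=0.05, per_cluster=6, seed=4)
        result = cluster_profiles(X, seed=0)
        assert adjusted_rand_score(labels, result.labels) >= 0.9


class TestRankSum:
    def test_symmetric_groups(self):
        U, _ = rank_sum_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert U == pytest.approx(4 * 4 / 2)

    def test_fully_separated_groups(self):
        U, p = rank_sum_test([10, 11, 12], [1, 2, 3])
        assert U == 0.0
        U2, _ = rank_sum_test([1, 2, 3], [10, 11, 12])
        assert U2 == 9.0

    def test_matches_pair_count_oracle(self, rng):
        for _ in range(40):
            n1, n2 = rng.integers(2, 13, size=2)
            a = rng.integers(0, 8, size=n1).astype(float)  # ties likely
            b = rng.integers(0, 8, size=n2).astype(float)
            U, _ = rank_sum_test(a, b)
            oracle = sum(
                1.0 if x < y else (0.5 if x == y else 0.0) for x in a for y in b
            )
            assert U == pytest.approx(oracle, abs=1e-9)

    def test_u_complements_scipy(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(0.5, 1, 12)
        U, _ = rank_sum_test(a, b)
        scipy_u1 = mannwhitneyu(a, b, alternative="two-sided").statistic
        assert U == pytest.approx(len(a) * len(b) - scipy_u1)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestConditionSummary:
    def sr_table(self, clap_sr, bounce_sr):
        rows = []
        for pid in ("p1", "p2"):
            for stim in ("s1", "s2"):
                rows.append(
                    {
                        "participant_id": pid,
                        "movement_type": "clap",
                        "stimulus_name": stim,
                        "sr": clap_sr,
                        "n_responses": 200,
                    }
                )
                rows.append(
                    {
                        "participant_id": pid,
                        "movement_type": "bounce",
                        "stimulus_name": stim,
                        "sr": bounce_sr,
                        "n_responses": 100,
                    }
                )
        return pd.DataFrame(rows)

    def test_clap_advantage_detected(self):
        out = condition_summary(self.sr_table(clap_sr=2.0, bounce_sr=1.0))
        assert out["by_movement"]["clap"] > out["by_movement"]["bounce"]
        np.testing.assert_allclose(out["clap_minus_bounce"].to_numpy(), 1.0)

    def test_equal_weights_reduce_to_plain_mean(self):
        df = self.sr_table(clap_sr=1.5, bounce_sr=1.5)
        df["n_responses"] = 100
        df.loc[0, "sr"] = 2.5
        out = condition_summary(df)
        clap = df[df.movement_type == "clap"]
        assert out["by_movement"]["clap"] == pytest.approx(clap["sr"].mean())
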