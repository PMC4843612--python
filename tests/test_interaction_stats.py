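"""Agreement, surrogate baselines, profiles, bouts and co-occurrence."""

import dataclasses
import math

import numpy as np
import pytest

from dyadannot.annotation_model import SENTINEL, Session
from dyadannot.errors import (
    GridError,
    InsufficientDataError,
    MissingTierError,
    PairingError,
    VocabularyError,
)
from dyadannot.interaction_stats import (
    agreement_vs_baseline,
    bout_stats,
    compare_stages,
    percent_agreement,
    profiles_to_frame,
    session_profile,
    shared_pulse_of_sound,
    surrogate_agreements,
    tier_overlap,
)
from dyadannot.timeline_ops import SampledTimeline, Window, sample_tier

from conftest import make_tier, random_session, random_tier


def tl(labels, dt=0.1, t0=0.0):
    return SampledTimeline(dt=dt, t0=t0, labels=tuple(labels))


class TestPercentAgreement:
    def test_identical_is_100(self):
        a = tl(["x"] * 50)
        assert percent_agreement(a, a) == 100.0

    def test_disjoint_is_0(self):
        assert percent_agreement(tl(["x"] * 50), tl(["y"] * 50)) == 0.0

    def test_symmetric_and_bounded(self, rng):
        labels = ["a", "b", "c"]
        a = tl(rng.choice(labels, 200))
        b = tl(rng.choice(labels, 200))
        assert percent_agreement(a, b) == percent_agreement(b, a)
        assert 0.0 <= percent_agreement(a, b) <= 100.0

    def test_sentinel_counts_as_matchable_by_default(self):
        a = tl([SENTINEL, "x", SENTINEL, "y"])
        b = tl([SENTINEL, "x", "z", "y"])
        assert percent_agreement(a, b) == 75.0
        # Excluding sentinel samples drops indices where either is a gap.
        assert percent_agreement(a, b, include_sentinel=False) == 100.0

    def test_mismatched_grids_raise(self):
        with pytest.raises(GridError):
            percent_agreement(tl(["x"] * 10), tl(["x"] * 11))
        with pytest.raises(GridError):
            percent_agreement(tl(["x"] * 10, dt=0.1), tl(["x"] * 10, dt=0.2))

    def test_independent_uniform_five_labels_agree_20pct(self, rng):
        """Chance agreement of independent uniform k-label timelines is 1/k."""
        labels = np.array(["a", "b", "c", "d", "e"], dtype=object)
        means = []
        for _ in range(200):
            a = tl(rng.choice(labels, 1800))
            b = tl(rng.choice(labels, 1800))
            means.append(percent_agreement(a, b))
        assert np.mean(means) == pytest.approx(20.0, abs=0.5)


class TestSurrogates:
    def _corpus_of(self, tiers, duration=10.0):
        return [
            Session(f"P{i}", "early", duration, {"client pulse": t})
            for i, t in enumerate(tiers)
        ]

    def test_identical_sessions_give_100(self):
        t = make_tier("client pulse", "client", "individual pulse", [(0, 10, "regular")], 10.0)
        corpus = self._corpus_of([t, t])
        assert surrogate_agreements(corpus, "client pulse", Window(0, 10), 0.1) == [
            100.0,
            100.0,
        ]

    def test_disjoint_label_usage_gives_0(self):
        a = make_tier("client pulse", "client", "individual pulse", [(0, 10, "regular")], 10.0)
        b = make_tier("client pulse", "client", "individual pulse", [(0, 10, "silence")], 10.0)
        assert surrogate_agreements(
            self._corpus_of([a, b]), "client pulse", Window(0, 10), 0.1
        ) == [0.0, 0.0]

    def test_fewer_than_two_sessions_raises(self):
        t = make_tier("client pulse", "client", "individual pulse", [], 10.0)
        with pytest.raises(InsufficientDataError):
            surrogate_agreements(self._corpus_of([t]), "client pulse", Window(0, 10), 0.1)

    def test_subsampling_is_seeded(self, rng):
        tiers = [
            random_tier(rng, "client pulse", "client", "individual pulse", 20.0)
            for _ in range(6)
        ]
        corpus = self._corpus_of(tiers, 20.0)
        w = Window(0, 20)
        first = surrogate_agreements(corpus, "client pulse", w, 0.1, max_pairs=10, seed=5)
        second = surrogate_agreements(corpus, "client pulse", w, 0.1, max_pairs=10, seed=5)
        assert first == second and len(first) == 10


class TestAgreementVsBaseline:
    def test_identical_coders_give_100_and_positive_ci(self, rng):
        corpus = [random_session(rng, 30.0, pair_id=f"P{i}") for i in range(5)]
        res = agreement_vs_baseline(corpus, corpus, "client pulse", Window(0, 30), 0.1)
        assert res.observed_pct == 100.0
        assert all(x == 100.0 for x in res.observed_per_session)
        # Baseline below 100 -> the difference CI sits strictly above zero.
        assert res.surrogate_mean_pct < 100.0
        assert res.diff_ci95[0] > 0.0
        assert res.p_value < 0.05

    def test_missing_counterpart_raises(self, rng):
        corpus = [random_session(rng, 30.0, pair_id=f"P{i}") for i in range(3)]
        with pytest.raises(PairingError):
            agreement_vs_baseline(corpus, corpus[:2], "client pulse", Window(0, 30), 0.1)

    def test_paired_variant_agrees_directionally(self, rng):
        corpus = [random_session(rng, 30.0, pair_id=f"P{i}") for i in range(5)]
        res = agreement_vs_baseline(
            corpus, corpus, "client pulse", Window(0, 30), 0.1, paired=True
        )
        assert res.test == "paired"
        assert res.p_value < 0.05


class TestProfiles:
    def test_full_coverage_label_has_proportion_1(self):
        tier = make_tier("musical structure", "dyad", "musical structure", [(0, 10, "song")], 10.0)
        session = Session("OD", "early", 10.0, {"musical structure": tier})
        prof = session_profile(session)
        assert prof.proportions["musical structure"]["song"] == pytest.approx(1.0)

    def test_half_coverage_is_half(self):
        tier = make_tier("musical structure", "dyad", "musical structure", [(0, 5, "song")], 10.0)
        session = Session("OD", "early", 10.0, {"musical structure": tier})
        prof = session_profile(session)
        assert prof.proportions["musical structure"]["song"] == pytest.approx(0.5)
        assert prof.proportions["musical structure"][SENTINEL] == pytest.approx(0.5)

    def test_proportions_sum_to_one(self, rng):
        session = random_session(rng, 60.0)
        prof = session_profile(session)
        for labmap in prof.proportions.values():
            assert sum(labmap.values()) == pytest.approx(1.0, abs=1e-9)

    def test_exact_proportions_match_sampling_oracle(self, rng):
        session = random_session(rng, 60.0)
        prof = session_profile(session)
        dt = 0.01
        for name, tier in session.tiers.items():
            sampled = sample_tier(tier, Window(0.0, 60.0), dt).labels
            for label, prop in prof.proportions[name].items():
                est = sampled.count(label) / len(sampled)
                assert prop == pytest.approx(est, abs=2 * dt * 60 / 60.0 + 1e-3)

    def test_tidy_frame_layout(self, rng):
        frame = profiles_to_frame([session_profile(random_session(rng, 30.0))])
        assert list(frame.columns) == ["pair_id", "stage", "tier", "label", "proportion"]
        assert len(frame) > 0


class TestSharedPulseOfSound:
    def _session(self, shared_spans, client_spans, mt_spans, duration=100.0):
        return Session(
            "OD",
            "early",
            duration,
            {
                "shared pulse": make_tier("shared pulse", "dyad", "shared pulse", shared_spans, duration),
                "client pulse": make_tier("client pulse", "client", "individual pulse", client_spans, duration),
                "MT pulse": make_tier("MT pulse", "therapist", "individual pulse", mt_spans, duration),
            },
        )

    def test_basic_ratio(self):
        session = self._session(
            [(0, 10, "shared pulse")],
            [(0, 100, "regular")],
            [(0, 100, "silence")],
        )
        assert shared_pulse_of_sound(session) == pytest.approx(0.10)

    def test_no_sound_is_undefined(self):
        session = self._session([], [(0, 100, "silence")], [(0, 100, "silence")])
        assert shared_pulse_of_sound(session) is None

    def test_denominator_is_union_of_sound_supports(self, rng):
        session = random_session(rng, 60.0)
        value = shared_pulse_of_sound(session)
        # Oracle: per-sample union length at fine resolution.
        dt = 0.01
        sound = {"regular", "irregular", "non-pulsed musical sounds"}
        c = sample_tier(session.tiers["client pulse"], Window(0, 60), dt).labels
        m = sample_tier(session.tiers["MT pulse"], Window(0, 60), dt).labels
        denom = sum(1 for a, b in zip(c, m) if a in sound or b in sound) * dt
        s = sample_tier(session.tiers["shared pulse"], Window(0, 60), dt).labels
        num = s.count("shared pulse") * dt
        if denom == 0:
            assert value is None
        else:
            assert value == pytest.approx(num / denom, abs=0.02)

    def test_missing_tier_raises(self):
        session = Session("OD", "early", 10.0, {})
        with pytest.raises(MissingTierError):
            shared_pulse_of_sound(session)


class TestBouts:
    def test_count_total_mean(self):
        tier = make_tier(
            "shared pulse",
            "dyad",
            "shared pulse",
            [(0, 1, "shared pulse"), (5, 7, "shared pulse"), (10, 13, "shared pulse")],
            20.0,
        )
        stats = bout_stats(tier, "shared pulse")
        assert (stats.count, stats.total_s, stats.mean_s) == (3, 6.0, 2.0)
        assert stats.median_s == 2.0 and stats.max_s == 3.0

    def test_abutting_intervals_merge_into_one_bout(self):
        tier = make_tier(
            "shared pulse",
            "dyad",
            "shared pulse",
            [(0, 1, "shared pulse"), (1, 2, "shared pulse")],
            10.0,
        )
        stats = bout_stats(tier, "shared pulse")
        assert stats.count == 1 and stats.total_s == pytest.approx(2.0)

    def test_absent_label_summaries_undefined(self):
        tier = make_tier("shared pulse", "dyad", "shared pulse", [], 10.0)
        stats = bout_stats(tier, "shared pulse")
        assert stats.count == 0 and stats.total_s == 0.0
        assert stats.mean_s is None and stats.median_s is None and stats.max_s is None

    def test_unknown_label_raises(self):
        tier = make_tier("shared pulse", "dyad", "shared pulse", [], 10.0)
        with pytest.raises(VocabularyError):
            bout_stats(tier, "groove")

    def test_bout_totals_match_profile_proportions(self, rng):
        session = random_session(rng, 60.0)
        prof = session_profile(session)
        for name, tier in session.tiers.items():
            for label in tier.vocabulary.labels:
                stats = bout_stats(tier, label)
                key = label  # vocab labels are already normalized
                expected = prof.proportions[name].get(key, 0.0) * session.duration
                assert stats.total_s == pytest.approx(expected, abs=1e-6)


class TestOverlap:
    def test_song_contains_shared_pulse(self):
        structure = make_tier("musical structure", "dyad", "musical structure", [(0, 10, "song")], 20.0)
        shared = make_tier("shared pulse", "dyad", "shared pulse", [(5, 8, "shared pulse")], 20.0)
        res = tier_overlap(structure, "song", shared, "shared pulse")
        assert res.overlap_s == pytest.approx(3.0)
        assert res.frac_of_b == pytest.approx(1.0)
        assert res.frac_of_a == pytest.approx(0.3)

    def test_disjoint_supports(self):
        a = make_tier("musical structure", "dyad", "musical structure", [(0, 5, "song")], 20.0)
        b = make_tier("shared pulse", "dyad", "shared pulse", [(10, 12, "shared pulse")], 20.0)
        res = tier_overlap(a, "song", b, "shared pulse")
        assert res.overlap_s == 0.0

    def test_overlap_bound_and_sampling_oracle(self, rng):
        for _ in range(25):
            a = random_tier(rng, "a", "dyad", "musical structure", 40.0, mean_len=5.0)
            b = random_tier(rng, "b", "dyad", "shared pulse", 40.0, mean_len=3.0)
            res = tier_overlap(a, "song", b, "shared pulse")
            dt = 0.01
            la = sample_tier(a, Window(0, 40), dt).labels
            lb = sample_tier(b, Window(0, 40), dt).labels
            sampled = sum(
                1 for x, y in zip(la, lb) if x == "song" and y == "shared pulse"
            ) * dt
            assert res.overlap_s == pytest.approx(sampled, abs=2 * dt * 40)
            total_a = sum(iv.duration for iv in a.intervals if iv.label == "song")
            total_b = sum(iv.duration for iv in b.intervals if iv.label == "shared pulse")
            assert res.overlap_s <= min(total_a, total_b) + 1e-9


class TestCompareStages:
    def _profile(self, pair, stage, prop):
        tier = make_tier(
            "client pulse", "client", "individual pulse", [(0, prop * 100, "regular")], 100.0
        )
        return session_profile(Session(pair, stage, 100.0, {"client pulse": tier}))

    def test_identical_profiles_give_zero_deltas(self):
        early = self._profile("OD", "early", 0.10)
        late = self._profile("OD", "late", 0.10)
        deltas = compare_stages(early, late)
        assert all(
            d == pytest.approx(0.0) for labmap in deltas.values() for d in labmap.values()
        )

    def test_percentage_point_convention(self):
        """10% -> 26.3% of the session is a +16.3 percentage-point change."""
        early = self._profile("OD", "early", 0.10)
        late = self._profile("OD", "late", 0.263)
        deltas = compare_stages(early, late)
        assert deltas["client pulse"]["regular"] == pytest.approx(16.3)

    def test_antisymmetric_under_swap(self):
        early = self._profile("OD", "early", 0.10)
        late = self._profile("OD", "late", 0.25)
        fwd = compare_stages(early, late)
        rev = compare_stages(late, early)
        for tier in fwd:
            for lab in fwd[tier]:
                assert fwd[tier][lab] == pytest.approx(-rev[tier][lab])

    def test_pair_mismatch_raises(self):
        with pytest.raises(PairingError):
            compare_stages(self._profile("OD", "early", 0.1), self._profile("SC", "late", 0.1))
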