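"""Synthetic session generator and the two-coder noise model."""

import dataclasses

import numpy as np
import pytest

from dyadannot.annotation_model import SENTINEL, sessions_equal, validate_session
from dyadannot.errors import ConfigError
from dyadannot.interaction_stats import (
    _intersect_length,
    _merged_support,
    _span_length,
    percent_agreement,
    session_profile,
)
from dyadannot.synthetic import (
    ALL_TIERS,
    CoderNoiseConfig,
    DwellConfig,
    SessionGeneratorConfig,
    TierGeneratorConfig,
    default_session_config,
    generate_corpus,
    generate_session,
    generate_tier,
    make_structure_plan,
    second_coder_corpus,
    simulate_second_coder,
)
from dyadannot.timeline_ops import Window, derive_candidate_shared_pulse, sample_tier


class TestTierGenerator:
    def test_absorbing_silence_yields_all_silence(self):
        cfg = TierGeneratorConfig(
            vocabulary="individual pulse",
            initial={"silence": 1.0},
            transition={"silence": {"silence": 1.0}},
            dwell={"silence": DwellConfig(5.0)},
        )
        tier = generate_tier(cfg, "client pulse", "client", 60.0, np.random.default_rng(0))
        assert {iv.label for iv in tier.intervals} == {"silence"}

    def test_invalid_transition_row_rejected(self):
        cfg = TierGeneratorConfig(
            vocabulary="individual pulse",
            initial={"silence": 1.0},
            transition={"silence": {"silence": 0.5}},
            dwell={"silence": DwellConfig(5.0)},
        )
        with pytest.raises(ConfigError):
            cfg.validate()

    def test_stationary_proportions_sum_to_one(self):
        cfg = default_session_config("early").tier_configs["MT pulse"]
        props = cfg.stationary_proportions()
        assert sum(props.values()) == pytest.approx(1.0)
        assert all(v >= 0 for v in props.values())

    def test_empirical_proportions_converge_to_stationary(self):
        """Label time shares converge to pi_i * m_i / sum over long runs."""
        cfg = default_session_config("early").tier_configs["MT pulse"]
        expected = cfg.stationary_proportions()
        duration = 16_680.0  # 10x session duration
        tier = generate_tier(cfg, "MT pulse", "therapist", duration, np.random.default_rng(7))
        durs = tier.label_durations()
        for label, exp in expected.items():
            if label == SENTINEL:
                continue
            got = durs.get(label, 0.0) / duration
            assert got == pytest.approx(exp, abs=0.04), label


class TestGenerateSession:
    def test_all_protocol_tiers_present_and_valid(self):
        session = generate_session(default_session_config("early"), seed=1)
        assert set(session.tiers) == set(ALL_TIERS)
        assert validate_session(session) == []

    def test_same_seed_is_deterministic(self):
        cfg = default_session_config("early")
        a = generate_session(cfg, seed=42)
        b = generate_session(cfg, seed=42)
        assert sessions_equal(a, b)

    def test_tier_subset_matches_full_run(self):
        cfg = default_session_config("early")
        full = generate_session(cfg, seed=9)
        subset = generate_session(cfg, seed=9, tiers=("MT pulse", "shared pulse"))
        assert sessions_equal(
            dataclasses.replace(full, tiers={k: full.tiers[k] for k in subset.tiers}),
            subset,
        )

    def test_structure_follows_plan(self):
        cfg = default_session_config("early")
        session = generate_session(cfg, seed=0, tiers=("musical structure",))
        tier = session.tiers["musical structure"]
        assert tier.intervals[0].label == "song"  # hello song
        assert tier.intervals[-1].label == "song"  # goodbye song
        assert tier.intervals[-1].offset == pytest.approx(cfg.duration)
        total = sum(iv.duration for iv in tier.intervals)
        assert total == pytest.approx(cfg.duration)

    def test_shared_pulse_contained_in_derived_candidate(self):
        for seed in range(10):
            session = generate_session(
                default_session_config("early"),
                seed=seed,
                tiers=("MT pulse", "client pulse", "shared pulse"),
            )
            candidate = derive_candidate_shared_pulse(
                session.tiers["client pulse"], session.tiers["MT pulse"]
            )
            annotated = _merged_support(session.tiers["shared pulse"], "shared pulse")
            cand = _merged_support(candidate, "candidate shared pulse")
            assert _intersect_length(annotated, cand) == pytest.approx(
                _span_length(annotated), abs=1e-6
            )

    def test_bad_plan_rejected(self):
        cfg = dataclasses.replace(
            default_session_config("early"), structure_plan=(("song", 100.0),)
        )
        with pytest.raises(ConfigError):
            generate_session(cfg, seed=0)


class TestSecondCoder:
    def _pulse_tier(self, seed=3):
        cfg = default_session_config("early")
        session = generate_session(cfg, seed=seed, tiers=("MT pulse",))
        return session.tiers["MT pulse"]

    def test_zero_noise_is_identity(self):
        tier = self._pulse_tier()
        noisy = simulate_second_coder(tier, CoderNoiseConfig(0.0, 0.0, 0.0, seed=1))
        assert noisy.intervals == tier.intervals
        w = Window(0.0, tier.session_duration)
        assert percent_agreement(sample_tier(tier, w), sample_tier(noisy, w)) == 100.0

    def test_full_deletion_agreement_equals_gap_fraction(self):
        tier = self._pulse_tier()
        empty = simulate_second_coder(tier, CoderNoiseConfig(0.0, 0.0, 1.0, seed=1))
        assert empty.intervals == ()
        w = Window(0.0, tier.session_duration)
        a = sample_tier(tier, w)
        b = sample_tier(empty, w)
        gap_fraction = 100.0 * a.labels.count(SENTINEL) / len(a)
        assert percent_agreement(a, b) == pytest.approx(gap_fraction)

    def test_agreement_decreases_monotonically_with_jitter(self):
        """More boundary jitter -> lower agreement, on a tier of 1 s bouts."""
        from dyadannot.annotation_model import LabeledInterval, Tier, standard_vocabularies

        vocab = standard_vocabularies()["individual pulse"]
        labels = ("regular", "silence")
        intervals = tuple(
            LabeledInterval(float(i), float(i + 1), labels[i % 2]) for i in range(120)
        )
        tier = Tier("client pulse", "client", vocab, intervals, 120.0)
        w = Window(0.0, 120.0)
        base = sample_tier(tier, w)
        means = []
        for sd in (0.0, 0.1, 0.2, 0.4):
            vals = []
            for seed in range(40):
                noisy = simulate_second_coder(tier, CoderNoiseConfig(sd, 0.0, 0.0, seed=seed))
                vals.append(percent_agreement(base, sample_tier(noisy, w)))
            means.append(np.mean(vals))
        assert means[0] == 100.0
        assert means[0] > means[1] > means[2] > means[3]

    def test_determinism_given_seed(self):
        tier = self._pulse_tier()
        cfg = CoderNoiseConfig(0.3, 0.05, 0.02, seed=77)
        assert simulate_second_coder(tier, cfg).intervals == simulate_second_coder(tier, cfg).intervals


class TestCorpus:
    def test_corpus_shape(self):
        corpus = generate_corpus(5, seed=7, tiers=("MT pulse",))
        assert len(corpus) == 10
        assert len({s.pair_id for s in corpus}) == 5
        assert {s.stage for s in corpus} == {"early", "late"}

    def test_identical_configs_give_exchangeable_stages(self):
        cfg = default_session_config("early")
        corpus = generate_corpus(6, early_cfg=cfg, late_cfg=cfg, seed=3,
                                 tiers=("MT pulse", "client pulse", "shared pulse", "musical structure"))
        early = [session_profile(s).proportions["shared pulse"].get("shared pulse", 0.0)
                 for s in corpus if s.stage == "early"]
        late = [session_profile(s).proportions["shared pulse"].get("shared pulse", 0.0)
                for s in corpus if s.stage == "late"]
        # Same config on both stages: means differ only by sampling noise.
        assert abs(np.mean(early) - np.mean(late)) < 0.08

    def test_second_coder_corpus_is_seeded(self):
        corpus = generate_corpus(2, seed=5, tiers=("MT pulse",))
        noise = CoderNoiseConfig(0.3, 0.05)
        a = second_coder_corpus(corpus, ("MT pulse",), noise, seed=11)
        b = second_coder_corpus(corpus, ("MT pulse",), noise, seed=11)
        for x, y in zip(a, b):
            assert sessions_equal(x, y)


def test_structure_plan_tiles_duration():
    plan = make_structure_plan(duration=1668.0, middle_song_frac=0.4)
    assert sum(d for _, d in plan) == pytest.approx(1668.0)
    assert plan[0][0] == "song" and plan[-1][0] == "song"
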