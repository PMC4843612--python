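"""Shared fixtures: hand-built and randomly generated sessions.

The random builders here are deliberately independent of the package's
synthetic module so they can serve as neutral fixtures for oracle tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from dyadannot.annotation_model import (
    LabeledInterval,
    Session,
    Tier,
    standard_vocabularies,
)

VOCABS = standard_vocabularies()


def make_tier(name, role, vocab_name, spans, duration):
    """Tier from a list of (onset, offset, label) triples."""
    return Tier(
        name=name,
        role=role,
        vocabulary=VOCABS[vocab_name],
        intervals=tuple(LabeledInterval(a, b, lab) for a, b, lab in spans),
        session_duration=duration,
    )


def random_tier(rng, name, role, vocab_name, duration, mean_len=2.0, gap_frac=0.3):
    """Random non-overlapping tier; occasional abutting intervals."""
    vocab = VOCABS[vocab_name]
    spans = []
    t = float(rng.uniform(0.0, mean_len))
    while t < duration - 0.2:
        length = float(rng.uniform(0.2, 2 * mean_len))
        end = min(t + length, duration)
        if end - t > 0.05:
            spans.append((t, end, str(rng.choice(vocab.labels))))
        t = end
        if rng.random() < gap_frac:
            t += float(rng.uniform(0.1, mean_len))
    return make_tier(name, role, vocab_name, spans, duration)


def random_session(rng, duration=60.0, pair_id="XX", stage="early"):
    tiers = {
        "client facing": random_tier(rng, "client facing", "client", "individual facing", duration),
        "MT facing": random_tier(rng, "MT facing", "therapist", "individual facing", duration),
        "client pulse": random_tier(rng, "client pulse", "client", "individual pulse", duration),
        "MT pulse": random_tier(rng, "MT pulse", "therapist", "individual pulse", duration),
        "shared pulse": random_tier(
            rng, "shared pulse", "dyad", "shared pulse", duration, mean_len=4.0, gap_frac=0.7
        ),
        "musical structure": make_tier(
            "musical structure",
            "dyad",
            "musical structure",
            [(0.0, duration / 2, "song"), (duration / 2, duration, "free improvisation")],
            duration,
        ),
    }
    return Session(pair_id=pair_id, stage=stage, duration=duration, tiers=tiers)


@pytest.fixture
def rng():
    return np.random.default_rng(20160505)


@pytest.fixture
def small_session():
    """Two-tier hand-built session satisfying every invariant."""
    duration = 10.0
    return Session(
        pair_id="OD",
        stage="early",
        duration=duration,
        tiers={
            "client pulse": make_tier(
                "client pulse",
                "client",
                "individual pulse",
                [(0.0, 2.0, "silence"), (2.0, 5.0, "regular"), (6.0, 9.0, "irregular")],
                duration,
            ),
            "musical structure": make_tier(
                "musical structure",
                "dyad",
                "musical structure",
                [(0.0, 10.0, "song")],
                duration,
            ),
        },
    )
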