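"""Rasterization of tiers to a fixed grid and derivation of dyad-level tiers.

The reliability analysis compares two coders' annotations of the same tier by
sampling both at a fixed resolution (default 0.1 s) over a common window and
counting matching samples.  Sampling uses the half-open convention: grid point
``t`` belongs to interval ``[a, b)`` iff ``a <= t < b``, so abutting intervals
never double-count a sample.

Dyad-level tiers (mutual facing, mutual still, a candidate shared-pulse tier)
can be derived from the two individual tiers by an exact interval-boundary
sweep; a per-sample derivation exists only as a test oracle, since it would
inherit dt-dependent artefacts.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, replace
from typing import Callable, List, Sequence, Tuple

import numpy as np

from .annotation_model import (
    MUSICAL_SOUND_LABELS,
    OUT_OF_VIEW,
    SENTINEL,
    LabeledInterval,
    Tier,
    Vocabulary,
    normalize_label,
    standard_vocabularies,
)
from .errors import RangeError, VocabularyError

__all__ = [
    "Window",
    "SampledTimeline",
    "RELIABILITY_WINDOW",
    "DEFAULT_DT",
    "CANDIDATE_SHARED_PULSE_VOCAB",
    "sample_tier",
    "mutual_facing_label",
    "mutual_still_label",
    "candidate_shared_pulse_label",
    "derive_mutual_facing",
    "derive_mutual_still",
    "derive_candidate_shared_pulse",
    "intervals_from_samples",
]

#: Default sampling resolution in seconds.
DEFAULT_DT = 0.1

#: Numerical slack for grid/boundary comparisons; far below any dt in use.
_EPS = 1e-6


@dataclass(frozen=True)
class Window:
    """Half-open analysis window ``[start, end)`` in seconds."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if self.start < 0 or not self.end > self.start:
            raise ValueError(f"invalid window [{self.start}, {self.end})")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def n_samples(self, dt: float = DEFAULT_DT) -> int:
        return int(math.floor(self.duration / dt + _EPS))


#: The re-coded reliability section: minutes 5 to 8 of each session.
RELIABILITY_WINDOW = Window(300.0, 480.0)

#: Vocabulary of the derived upper-bound shared-pulse tier.  "candidate"
#: because identical tempo cannot be verified from categorical labels alone:
#: both sides playing a regular pulse is necessary, not sufficient.
CANDIDATE_SHARED_PULSE_VOCAB = Vocabulary(
    "candidate shared pulse", ("candidate shared pulse", "not shared pulse")
)


@dataclass(frozen=True)
class SampledTimeline:
    """A tier rasterized on the grid ``t0 + k*dt``, k = 0..n-1."""

    dt: float
    t0: float
    labels: Tuple[str, ...]

    def __len__(self) -> int:
        return len(self.labels)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=object)

    def same_grid(self, other: "SampledTimeline") -> bool:
        return (
            abs(self.dt - other.dt) < _EPS
            and abs(self.t0 - other.t0) < _EPS
            and len(self) == len(other)
        )


def sample_tier(tier: Tier, window: Window, dt: float = DEFAULT_DT) -> SampledTimeline:
    """Rasterize *tier* over *window* at resolution *dt*.

    Each grid point takes the (normalized) label of the unique interval
    covering it under the half-open convention, or the ``"(none)"`` sentinel.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if window.end > tier.session_duration + _EPS:
        raise RangeError(
            f"window [{window.start}, {window.end}) exceeds session duration "
            f"{tier.session_duration}"
        )
    n = window.n_samples(dt)
    t = window.start + dt * np.arange(n)
    labels = np.full(n, SENTINEL, dtype=object)
    if tier.intervals:
        onsets = np.array([iv.onset for iv in tier.intervals])
        offsets = np.array([iv.offset for iv in tier.intervals])
        toks = np.array(
            [normalize_label(iv.label) for iv in tier.intervals], dtype=object
        )
        idx = np.searchsorted(onsets, t + _EPS, side="right") - 1
        valid = idx >= 0
        covered = np.zeros(n, dtype=bool)
        covered[valid] = (t[valid] + _EPS) < offsets[idx[valid]]
        labels[covered] = toks[idx[covered]]
    return SampledTimeline(dt=dt, t0=window.start, labels=tuple(labels))


def intervals_from_samples(timeline: SampledTimeline) -> List[LabeledInterval]:
    """Run-length decode a sampled timeline back to intervals (gaps dropped)."""
    out: List[LabeledInterval] = []
    labels = timeline.labels
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and labels[j] == labels[i]:
            j += 1
        if labels[i] != SENTINEL:
            out.append(
                LabeledInterval(
                    timeline.t0 + i * timeline.dt,
                    timeline.t0 + j * timeline.dt,
                    labels[i],
                )
            )
        i = j
    return out


# ---------------------------------------------------------------------------
# Mutual-tier derivation
# ---------------------------------------------------------------------------

def mutual_facing_label(client: str, therapist: str) -> str:
    """Combine two individual facing labels into the dyad-level label.

    Out-of-view or unannotated time on either side makes the dyad state
    unanalyzable, hence "out of view"; this takes precedence over the
    facing/not-facing combinations.
    """
    if client in (SENTINEL, OUT_OF_VIEW) or therapist in (SENTINEL, OUT_OF_VIEW):
        return OUT_OF_VIEW
    if client == "facing" and therapist == "facing":
        return "both facing each other"
    if client == "not facing" and therapist == "not facing":
        return "both not facing each other"
    return "one facing the other and one not"


def mutual_still_label(client: str, therapist: str) -> str:
    if client in (SENTINEL, OUT_OF_VIEW) or therapist in (SENTINEL, OUT_OF_VIEW):
        return OUT_OF_VIEW
    if client == "still" and therapist == "still":
        return "both still"
    if client == "not still" and therapist == "not still":
        return "both not still"
    return "one still and one not"


def candidate_shared_pulse_label(client: str, therapist: str) -> str:
    """Upper bound on shared pulse from categorical pulse labels.

    Both sides "regular" is a necessary condition for a shared pulse (the
    same tempo cannot be checked from labels); other jointly musical-sounding
    time is "not shared pulse"; everything else is a gap.
    """
    if client == "regular" and therapist == "regular":
        return "candidate shared pulse"
    if client in MUSICAL_SOUND_LABELS and therapist in MUSICAL_SOUND_LABELS:
        return "not shared pulse"
    return SENTINEL


def _require_vocab(tier: Tier, vocab_name: str) -> None:
    if tier.vocabulary.name != vocab_name:
        raise VocabularyError(
            f"tier {tier.name!r} uses vocabulary {tier.vocabulary.name!r}; "
            f"expected {vocab_name!r}"
        )


def _sweep(
    a: Tier, b: Tier, combine: Callable[[str, str], str]
) -> List[LabeledInterval]:
    """Exact boundary sweep: evaluate *combine* on every elementary segment
    between consecutive interval boundaries, then merge equal-label runs."""
    if abs(a.session_duration - b.session_duration) > _EPS:
        raise VocabularyError(
            "tiers must share session_duration for mutual derivation"
        )
    duration = a.session_duration
    bounds = {0.0, duration}
    for tier in (a, b):
        for iv in tier.intervals:
            bounds.add(min(iv.onset, duration))
            bounds.add(min(iv.offset, duration))
    cuts = sorted(bounds)

    def label_lookup(tier: Tier):
        onsets = [iv.onset for iv in tier.intervals]
        offsets = [iv.offset for iv in tier.intervals]
        toks = [normalize_label(iv.label) for iv in tier.intervals]

        def at(t: float) -> str:
            i = bisect_right(onsets, t) - 1
            if i >= 0 and t < offsets[i]:
                return toks[i]
            return SENTINEL

        return at

    at_a, at_b = label_lookup(a), label_lookup(b)
    out: List[LabeledInterval] = []
    for s, e in zip(cuts[:-1], cuts[1:]):
        if e - s <= _EPS * 1e-3:
            continue
        mid = 0.5 * (s + e)
        lab = combine(at_a(mid), at_b(mid))
        if lab == SENTINEL:
            continue
        if out and out[-1].label == lab and abs(out[-1].offset - s) <= _EPS:
            out[-1] = LabeledInterval(out[-1].onset, e, lab)
        else:
            out.append(LabeledInterval(s, e, lab))
    return out


def _derive(
    client: Tier,
    therapist: Tier,
    in_vocab: str,
    combine: Callable[[str, str], str],
    out_name: str,
    out_vocab: Vocabulary,
) -> Tier:
    _require_vocab(client, in_vocab)
    _require_vocab(therapist, in_vocab)
    intervals = _sweep(client, therapist, combine)
    return Tier(
        name=out_name,
        role="dyad",
        vocabulary=out_vocab,
        intervals=tuple(intervals),
        session_duration=client.session_duration,
    )


def derive_mutual_facing(client: Tier, therapist: Tier) -> Tier:
    """Dyad facing tier from the two individual facing tiers (exact sweep).

    The derived tier partitions the session: every instant carries one of the
    four mutual-facing labels (unannotated/out-of-view time maps to
    "out of view").  Named "... (derived)" so it can coexist with a manually
    annotated mutual tier.
    """
    return _derive(
        client,
        therapist,
        "individual facing",
        mutual_facing_label,
        "mutual facing (derived)",
        standard_vocabularies()["mutual facing"],
    )


def derive_mutual_still(client: Tier, therapist: Tier) -> Tier:
    return _derive(
        client,
        therapist,
        "individual still",
        mutual_still_label,
        "mutual still (derived)",
        standard_vocabularies()["mutual still"],
    )


def derive_candidate_shared_pulse(client_pulse: Tier, therapist_pulse: Tier) -> Tier:
    """Necessary-condition shared-pulse tier from the individual pulse tiers.

    Annotated shared pulse is always contained (as a set of time points) in
    this tier's "candidate shared pulse" support, which makes it a cheap
    consistency check on manual shared-pulse coding.
    """
    return _derive(
        client_pulse,
        therapist_pulse,
        "individual pulse",
        candidate_shared_pulse_label,
        "candidate shared pulse (derived)",
        CANDIDATE_SHARED_PULSE_VOCAB,
    )
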