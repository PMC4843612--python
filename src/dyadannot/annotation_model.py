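"""Domain model for tier-based interval annotation of dyadic therapy sessions.

A session video is annotated on several *tiers*, one per observed behaviour
(facing, stillness, rhythmic pulse, musical structure), each belonging either
to one participant (client or therapist) or to the dyad as a whole.  Every
tier carries a closed, controlled vocabulary; an annotation is a half-open
time interval ``[onset, offset)`` in seconds with one label from that
vocabulary.  Unannotated time is permitted on every tier and represented
implicitly as gaps between intervals; the gaps only materialise as the
sentinel label ``"(none)"`` when a tier is rasterized to a fixed grid.

Labels are compared case-insensitively after whitespace normalization, since
hand-made annotation files vary in capitalisation and spacing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Tuple

__all__ = [
    "SENTINEL",
    "OUT_OF_VIEW",
    "MUSICAL_SOUND_LABELS",
    "ROLES",
    "STAGES",
    "normalize_label",
    "LabeledInterval",
    "Vocabulary",
    "Tier",
    "Session",
    "Violation",
    "validate_session",
    "standard_vocabularies",
    "sessions_equal",
]

#: Reserved label used for unannotated time when a tier is sampled.
SENTINEL = "(none)"

#: First-class label on facing/still tiers: the participant cannot be coded.
OUT_OF_VIEW = "out of view"

#: Individual-pulse labels that count as *musical* sound production.
MUSICAL_SOUND_LABELS = frozenset(
    {"regular", "irregular", "non-pulsed musical sounds"}
)

ROLES = ("client", "therapist", "dyad")
STAGES = ("early", "late")

#: Tolerance (seconds) used when checking overlap/duration invariants, well
#: below the 1 ms on-disk time quantum.
_EPS = 1e-9


def normalize_label(label: str) -> str:
    """Canonical form of a label: lower case, single internal spaces."""
    return " ".join(label.split()).lower()


@dataclass(frozen=True)
class LabeledInterval:
    """One annotation: half-open ``[onset, offset)`` in seconds with a label.

    Zero-length and inverted intervals are rejected at construction; label
    membership in the owning tier's vocabulary is checked by
    :func:`validate_session`, since an interval does not know its tier.
    """

    onset: float
    offset: float
    label: str

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError(f"negative onset {self.onset!r}")
        if not self.offset > self.onset:
            raise ValueError(
                f"zero-length or inverted interval [{self.onset}, {self.offset})"
            )
        if not str(self.label).strip():
            raise ValueError("empty label")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class Vocabulary:
    """A named, ordered, closed label set for one tier type.

    ``exhaustive`` records whether the protocol expects the tier to cover the
    whole session (e.g. individual pulse, which includes an explicit
    ``silence`` label) or to be sparse.  It is descriptive metadata: gaps are
    tolerated on every tier.
    """

    name: str
    labels: Tuple[str, ...]
    exhaustive: bool = False

    def __post_init__(self) -> None:
        norm = [normalize_label(l) for l in self.labels]
        if any(not l for l in norm):
            raise ValueError(f"vocabulary {self.name!r} has an empty label")
        if len(set(norm)) != len(norm):
            raise ValueError(f"vocabulary {self.name!r} has duplicate labels")

    def __contains__(self, label: object) -> bool:
        if not isinstance(label, str):
            return False
        return normalize_label(label) in {normalize_label(l) for l in self.labels}

    def canonical(self, label: str) -> str:
        """Return the canonical spelling of *label* from this vocabulary."""
        key = normalize_label(label)
        for l in self.labels:
            if normalize_label(l) == key:
                return l
        raise KeyError(f"label {label!r} not in vocabulary {self.name!r}")


@dataclass(frozen=True)
class Tier:
    """A named stream of non-overlapping labelled intervals for one role."""

    name: str
    role: str
    vocabulary: Vocabulary
    intervals: Tuple[LabeledInterval, ...]
    session_duration: float

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if self.session_duration <= 0:
            raise ValueError("session_duration must be positive")
        object.__setattr__(self, "intervals", tuple(self.intervals))

    def label_at(self, t: float) -> str:
        """Label covering time *t* under the half-open convention, else sentinel."""
        # Linear scan is fine for ad-hoc queries; bulk queries go through
        # timeline_ops.sample_tier which vectorises the lookup.
        for iv in self.intervals:
            if iv.onset <= t < iv.offset:
                return normalize_label(iv.label)
            if iv.onset > t:
                break
        return SENTINEL

    def label_durations(self) -> Dict[str, float]:
        """Total annotated seconds per (normalized) label, plus the sentinel gap."""
        out: Dict[str, float] = {}
        covered = 0.0
        for iv in self.intervals:
            key = normalize_label(iv.label)
            out[key] = out.get(key, 0.0) + iv.duration
            covered += iv.duration
        out[SENTINEL] = max(self.session_duration - covered, 0.0)
        return out


@dataclass(frozen=True)
class Session:
    """One annotated video: a pair, a stage in therapy, and its tiers."""

    pair_id: str
    stage: str
    duration: float
    tiers: Mapping[str, Tier]

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        object.__setattr__(self, "tiers", dict(self.tiers))

    def tier(self, name: str) -> Tier:
        from .errors import MissingTierError

        try:
            return self.tiers[name]
        except KeyError:
            raise MissingTierError(
                f"session {self.pair_id}/{self.stage} has no tier {name!r}; "
                f"available: {sorted(self.tiers)}"
            ) from None


@dataclass(frozen=True)
class Violation:
    """One structural rule broken by a session; returned, never raised."""

    tier: str
    index: Optional[int]
    rule: str
    message: str

    def __str__(self) -> str:
        where = f"{self.tier}[{self.index}]" if self.index is not None else self.tier
        return f"{where}: {self.rule}: {self.message}"


def validate_session(session: Session) -> list[Violation]:
    """Check every tier invariant; return the (possibly empty) violation list.

    Rules checked per tier: ``duration-mismatch`` (tier duration differs from
    the session's), ``unsorted`` / ``overlap`` (interval ordering and
    exclusivity), ``beyond-duration`` (offset past the session end) and
    ``unknown-label`` (label outside the tier's vocabulary).
    """
    violations: list[Violation] = []
    for name, tier in session.tiers.items():
        if abs(tier.session_duration - session.duration) > _EPS:
            violations.append(
                Violation(
                    name,
                    None,
                    "duration-mismatch",
                    f"tier duration {tier.session_duration} != session "
                    f"duration {session.duration}",
                )
            )
        prev: Optional[LabeledInterval] = None
        for i, iv in enumerate(tier.intervals):
            if prev is not None:
                if iv.onset < prev.onset - _EPS:
                    violations.append(
                        Violation(name, i, "unsorted", "intervals not sorted by onset")
                    )
                elif iv.onset < prev.offset - _EPS:
                    violations.append(
                        Violation(
                            name,
                            i,
                            "overlap",
                            f"[{iv.onset}, {iv.offset}) overlaps previous "
                            f"[{prev.onset}, {prev.offset})",
                        )
                    )
            if iv.offset > tier.session_duration + _EPS:
                violations.append(
                    Violation(
                        name,
                        i,
                        "beyond-duration",
                        f"offset {iv.offset} exceeds duration {tier.session_duration}",
                    )
                )
            if iv.label not in tier.vocabulary:
                violations.append(
                    Violation(
                        name,
                        i,
                        "unknown-label",
                        f"label {iv.label!r} not in vocabulary "
                        f"{tier.vocabulary.name!r}",
                    )
                )
            prev = iv
    return violations


def standard_vocabularies() -> Dict[str, Vocabulary]:
    """The protocol's eight controlled vocabularies.

    Individual facing/still/pulse apply separately to client and therapist;
    mutual facing/still, shared pulse and synchrony describe the dyad; the
    musical-structure tier distinguishes songs from free improvisation.
    """
    vocabs = (
        Vocabulary("individual facing", ("facing", "not facing", OUT_OF_VIEW)),
        Vocabulary("individual still", ("still", "not still", OUT_OF_VIEW)),
        Vocabulary(
            "individual pulse",
            (
                "regular",
                "irregular",
                "non-pulsed musical sounds",
                "non-musical sounds",
                "silence",
            ),
            exhaustive=True,
        ),
        Vocabulary(
            "mutual facing",
            (
                "both facing each other",
                "both not facing each other",
                "one facing the other and one not",
                OUT_OF_VIEW,
            ),
        ),
        Vocabulary(
            "mutual still",
            ("both still", "both not still", "one still and one not", OUT_OF_VIEW),
        ),
        Vocabulary("shared pulse", ("shared pulse", "not shared pulse")),
        Vocabulary("synchrony", ("synchrony", "turn-taking")),
        Vocabulary("musical structure", ("song", "free improvisation"), exhaustive=True),
    )
    return {v.name: v for v in vocabs}


def sessions_equal(a: Session, b: Session, time_tol: float = 0.0) -> bool:
    """Structural equality of two sessions, with a time tolerance in seconds.

    Used to state round-trip contracts: file formats quantize times to 1 ms,
    so equality after a disk round trip holds with ``time_tol=5e-4``.
    """
    if (a.pair_id, a.stage) != (b.pair_id, b.stage):
        return False
    if abs(a.duration - b.duration) > max(time_tol, _EPS):
        return False
    if set(a.tiers) != set(b.tiers):
        return False
    for name, ta in a.tiers.items():
        tb = b.tiers[name]
        if ta.role != tb.role or ta.vocabulary.name != tb.vocabulary.name:
            return False
        if len(ta.intervals) != len(tb.intervals):
            return False
        for ia, ib in zip(ta.intervals, tb.intervals):
            if normalize_label(ia.label) != normalize_label(ib.label):
                return False
            if abs(ia.onset - ib.onset) > max(time_tol, _EPS):
                return False
            if abs(ia.offset - ib.offset) > max(time_tol, _EPS):
                return False
    return True
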