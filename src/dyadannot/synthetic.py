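"""Synthetic dyadic therapy sessions and simulated second coders.

Real annotated therapy videos are confidential, so every analysis stage is
exercised on simulated sessions instead.  Each behaviour tier is generated by
a *semi-Markov* process: a Markov chain over the tier's labels with an
explicit log-normal dwell-time distribution per label (plain Markov chains at
0.1 s resolution would give geometric bout lengths, far shorter than the long
facing/stillness bouts seen in real sessions).  A session consists of:

* a musical-structure tier following a fixed segment plan — a "hello" song,
  a middle section alternating free improvisation and songs, and a "goodbye"
  song book-ending the session;
* individual facing / still / pulse tiers for client and therapist;
* a client pulse tier *coupled* to the therapist: inside each
  therapist-regular stretch the client is regenerated as "regular" with a
  configurable probability, higher during songs than outside them;
* a dyad shared-pulse tier emitted only on runs where both pulse tiers are
  "regular" (and an annotation draw succeeds), so annotated shared pulse is
  always contained in the derived candidate shared-pulse support;
* derived mutual facing / still tiers and a sparse synchrony tier.

Default durations and densities emulate the study conditions: ~27.8 min
sessions, ~50 annotations per 3-minute window on the individual pulse tiers
and ~11 on the sparse shared-pulse and synchrony tiers.  The second-coder
model perturbs a tier with Gaussian boundary jitter, random relabelling and
random deletion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .annotation_model import (
    SENTINEL,
    LabeledInterval,
    Session,
    Tier,
    normalize_label,
    standard_vocabularies,
)
from .errors import ConfigError
from .interaction_stats import _intersect_length, _merge_spans, _merged_support
from .timeline_ops import derive_mutual_facing, derive_mutual_still

__all__ = [
    "DwellConfig",
    "TierGeneratorConfig",
    "SessionGeneratorConfig",
    "CoderNoiseConfig",
    "make_structure_plan",
    "default_session_config",
    "generate_tier",
    "generate_session",
    "simulate_second_coder",
    "second_coder_corpus",
    "generate_corpus",
]

_EPS = 1e-6

#: Minimum emitted bout length (seconds); sub-0.05 s slivers are not
#: annotatable by a human coder and only create raster noise.
_MIN_BOUT = 0.05


@dataclass(frozen=True)
class DwellConfig:
    """Log-normal dwell distribution parameterized by its mean in seconds."""

    mean_s: float
    sigma_log: float = 0.6

    def __post_init__(self) -> None:
        if self.mean_s <= 0 or self.sigma_log < 0:
            raise ConfigError("dwell mean must be positive, sigma non-negative")

    @property
    def mu(self) -> float:
        # ln-scale location giving E[dwell] = mean_s exactly.
        return math.log(self.mean_s) - self.sigma_log**2 / 2.0


@dataclass(frozen=True)
class TierGeneratorConfig:
    """Semi-Markov generator for one tier.

    ``gap_probability`` inserts an unannotated gap (own dwell distribution)
    after a bout, which is how sparse tiers such as synchrony are produced.
    """

    vocabulary: str
    initial: Mapping[str, float]
    transition: Mapping[str, Mapping[str, float]]
    dwell: Mapping[str, DwellConfig]
    gap_probability: float = 0.0
    gap_dwell: DwellConfig = field(default_factory=lambda: DwellConfig(8.0))

    @property
    def states(self) -> Tuple[str, ...]:
        """All chain states: the transition matrix's keys (the initial
        distribution may cover only a subset, e.g. sessions start silent)."""
        return tuple(self.transition)

    def validate(self) -> None:
        states = self.states
        if not states or not self.initial:
            raise ConfigError("empty transition matrix or initial distribution")
        vocabs = standard_vocabularies()
        if self.vocabulary in vocabs:
            vocab = vocabs[self.vocabulary]
            for l in states:
                if l not in vocab:
                    raise ConfigError(
                        f"label {l!r} not in vocabulary {self.vocabulary!r}"
                    )
        if abs(sum(self.initial.values()) - 1.0) > 1e-6:
            raise ConfigError("initial distribution must sum to 1")
        for l in self.initial:
            if l not in states:
                raise ConfigError(f"initial state {l!r} has no transition row")
        for l in states:
            row = self.transition[l]
            if abs(sum(row.values()) - 1.0) > 1e-6:
                raise ConfigError(f"transition row for {l!r} must sum to 1")
            if any(p < 0 for p in row.values()):
                raise ConfigError(f"negative transition probability from {l!r}")
            for tgt in row:
                if tgt not in states:
                    raise ConfigError(
                        f"transition {l!r} -> {tgt!r} targets an unknown state"
                    )
            if l not in self.dwell:
                raise ConfigError(f"no dwell distribution for state {l!r}")
        if not 0.0 <= self.gap_probability <= 1.0:
            raise ConfigError("gap_probability must be in [0, 1]")

    def stationary_proportions(self) -> Dict[str, float]:
        """Long-run time share per label (plus the ``"(none)"`` gap share).

        Computed from the embedded chain's stationary distribution pi and the
        mean dwells m: share_i = pi_i * m_i / (sum_j pi_j * m_j + g * m_gap),
        where g is the gap probability.
        """
        self.validate()
        labels = list(self.states)
        k = len(labels)
        P = np.zeros((k, k))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                P[i, j] = self.transition[a].get(b, 0.0)
        A = np.vstack([(P.T - np.eye(k))[:-1], np.ones(k)])
        b = np.zeros(k)
        b[-1] = 1.0
        pi = np.linalg.lstsq(A, b, rcond=None)[0]
        pi = np.clip(pi, 0.0, None)
        pi = pi / pi.sum()
        means = np.array([self.dwell[l].mean_s for l in labels])
        gap_time = self.gap_probability * self.gap_dwell.mean_s
        denom = float(pi @ means) + gap_time
        out = {l: float(pi[i] * means[i] / denom) for i, l in enumerate(labels)}
        out[SENTINEL] = gap_time / denom
        return out


@dataclass(frozen=True)
class CoderNoiseConfig:
    """Disagreement model for a simulated second coder."""

    jitter_sd: float = 0.3
    relabel_prob: float = 0.05
    deletion_prob: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.jitter_sd < 0:
            raise ConfigError("jitter_sd must be non-negative")
        for p in (self.relabel_prob, self.deletion_prob):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("probabilities must be in [0, 1]")


def make_structure_plan(
    duration: float = 1668.0,
    hello_s: float = 150.0,
    goodbye_s: float = 150.0,
    n_middle: int = 8,
    middle_song_frac: float = 0.5,
) -> Tuple[Tuple[str, float], ...]:
    """Segment plan tiling [0, duration): hello song, alternating middle,
    goodbye song.  The middle alternates free improvisation and songs, with
    ``middle_song_frac`` of the middle time given to songs."""
    middle = duration - hello_s - goodbye_s
    if middle <= 0 or n_middle < 2 or n_middle % 2:
        raise ConfigError("plan needs positive middle time and even n_middle")
    n_song = n_middle // 2
    song_d = middle * middle_song_frac / n_song
    free_d = middle * (1.0 - middle_song_frac) / (n_middle - n_song)
    plan: List[Tuple[str, float]] = [("song", hello_s)]
    for i in range(n_middle):
        plan.append(("free improvisation", free_d) if i % 2 == 0 else ("song", song_d))
    plan.append(("song", goodbye_s))
    return tuple(plan)


@dataclass(frozen=True)
class SessionGeneratorConfig:
    """Everything needed to simulate one session deterministically.

    ``coupling_in_song`` / ``coupling_outside`` are the probabilities that a
    therapist-regular stretch pulls the client into a regular pulse, inside
    and outside song segments; ``shared_pulse_prob`` is the probability that
    a both-regular run is annotated "shared pulse" rather than "not shared
    pulse" on the dyad tier.
    """

    duration: float = 1668.0
    tier_configs: Mapping[str, TierGeneratorConfig] = field(default_factory=dict)
    structure_plan: Tuple[Tuple[str, float], ...] = ()
    coupling_in_song: float = 0.50
    coupling_outside: float = 0.20
    shared_pulse_prob: float = 0.75
    min_shared_run_s: float = 0.3
    seed: Optional[int] = None

    def validate(self) -> None:
        if self.duration <= 0:
            raise ConfigError("duration must be positive")
        for p in (self.coupling_in_song, self.coupling_outside, self.shared_pulse_prob):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("coupling probabilities must be in [0, 1]")
        total = sum(d for _, d in self.structure_plan)
        if abs(total - self.duration) > 1e-6:
            raise ConfigError(
                f"structure plan covers {total} s but session lasts {self.duration} s"
            )
        vocabs = standard_vocabularies()
        for name, d in self.structure_plan:
            if name not in vocabs["musical structure"]:
                raise ConfigError(f"unknown structure segment label {name!r}")
        for cfg in self.tier_configs.values():
            cfg.validate()


# ---------------------------------------------------------------------------
# Default study-condition configs
# ---------------------------------------------------------------------------

def _therapist_pulse_config() -> TierGeneratorConfig:
    # Therapists keep a regular pulse much of the time; mean bout lengths are
    # set so the tier carries ~50 annotations per 3-minute window.
    return TierGeneratorConfig(
        vocabulary="individual pulse",
        initial={"silence": 0.6, "regular": 0.25, "non-musical sounds": 0.15},
        transition={
            "regular": {
                "irregular": 0.20,
                "non-pulsed musical sounds": 0.25,
                "non-musical sounds": 0.10,
                "silence": 0.45,
            },
            "irregular": {
                "regular": 0.50,
                "non-pulsed musical sounds": 0.20,
                "silence": 0.30,
            },
            "non-pulsed musical sounds": {
                "regular": 0.45,
                "irregular": 0.15,
                "silence": 0.40,
            },
            "non-musical sounds": {"regular": 0.40, "silence": 0.60},
            "silence": {
                "regular": 0.50,
                "irregular": 0.10,
                "non-pulsed musical sounds": 0.20,
                "non-musical sounds": 0.20,
            },
        },
        dwell={
            "regular": DwellConfig(4.0),
            "irregular": DwellConfig(2.5),
            "non-pulsed musical sounds": DwellConfig(3.0),
            "non-musical sounds": DwellConfig(2.0),
            "silence": DwellConfig(3.5),
        },
    )


def _client_pulse_config() -> TierGeneratorConfig:
    # Clients produce more silence and unpitched sound, less regular pulse.
    return TierGeneratorConfig(
        vocabulary="individual pulse",
        initial={"silence": 0.7, "non-musical sounds": 0.2, "irregular": 0.1},
        transition={
            "regular": {"irregular": 0.30, "silence": 0.50, "non-musical sounds": 0.20},
            "irregular": {
                "regular": 0.25,
                "non-pulsed musical sounds": 0.20,
                "silence": 0.40,
                "non-musical sounds": 0.15,
            },
            "non-pulsed musical sounds": {
                "irregular": 0.30,
                "silence": 0.50,
                "non-musical sounds": 0.20,
            },
            "non-musical sounds": {"silence": 0.70, "irregular": 0.30},
            "silence": {
                "regular": 0.15,
                "irregular": 0.25,
                "non-pulsed musical sounds": 0.20,
                "non-musical sounds": 0.40,
            },
        },
        dwell={
            "regular": DwellConfig(3.0),
            "irregular": DwellConfig(2.5),
            "non-pulsed musical sounds": DwellConfig(2.5),
            "non-musical sounds": DwellConfig(2.5),
            "silence": DwellConfig(5.0),
        },
    )


def _facing_config(role: str) -> TierGeneratorConfig:
    if role == "therapist":
        dwell = {
            "facing": DwellConfig(60.0, 0.8),
            "not facing": DwellConfig(8.0),
            "out of view": DwellConfig(5.0),
        }
        transition = {
            "facing": {"not facing": 0.8, "out of view": 0.2},
            "not facing": {"facing": 0.9, "out of view": 0.1},
            "out of view": {"facing": 0.9, "not facing": 0.1},
        }
        initial = {"facing": 0.9, "not facing": 0.1}
    else:
        dwell = {
            "facing": DwellConfig(10.0, 0.8),
            "not facing": DwellConfig(25.0, 0.8),
            "out of view": DwellConfig(6.0),
        }
        transition = {
            "facing": {"not facing": 0.8, "out of view": 0.2},
            "not facing": {"facing": 0.75, "out of view": 0.25},
            "out of view": {"facing": 0.4, "not facing": 0.6},
        }
        initial = {"facing": 0.3, "not facing": 0.7}
    return TierGeneratorConfig(
        vocabulary="individual facing", initial=initial, transition=transition, dwell=dwell
    )


def _still_config(role: str) -> TierGeneratorConfig:
    if role == "therapist":
        dwell = {
            "still": DwellConfig(80.0, 0.8),
            "not still": DwellConfig(12.0),
            "out of view": DwellConfig(4.0),
        }
        initial = {"still": 0.95, "not still": 0.05}
    else:
        dwell = {
            "still": DwellConfig(30.0, 0.8),
            "not still": DwellConfig(15.0, 0.8),
            "out of view": DwellConfig(5.0),
        }
        initial = {"still": 0.6, "not still": 0.4}
    transition = {
        "still": {"not still": 0.85, "out of view": 0.15},
        "not still": {"still": 0.85, "out of view": 0.15},
        "out of view": {"still": 0.6, "not still": 0.4},
    }
    return TierGeneratorConfig(
        vocabulary="individual still", initial=initial, transition=transition, dwell=dwell
    )


def _synchrony_config() -> TierGeneratorConfig:
    # Sparse: ~11 annotations per 3-minute window (bouts separated by long
    # unannotated gaps).
    return TierGeneratorConfig(
        vocabulary="synchrony",
        initial={"synchrony": 0.5, "turn-taking": 0.5},
        transition={
            "synchrony": {"turn-taking": 1.0},
            "turn-taking": {"synchrony": 1.0},
        },
        dwell={"synchrony": DwellConfig(5.0), "turn-taking": DwellConfig(7.0)},
        gap_probability=0.85,
        gap_dwell=DwellConfig(12.0, 0.8),
    )


def default_session_config(stage: str = "early", seed: Optional[int] = None) -> SessionGeneratorConfig:
    """Study-condition defaults for one stage.

    Early sessions are more dominated by structured songs and less coupled;
    late sessions have freer improvisation and stronger pulse coupling.
    """
    if stage == "early":
        plan = make_structure_plan(middle_song_frac=0.5)
        coupling_in_song, coupling_outside = 0.50, 0.20
    elif stage == "late":
        plan = make_structure_plan(middle_song_frac=0.3)
        coupling_in_song, coupling_outside = 0.60, 0.30
    else:
        raise ConfigError(f"stage must be 'early' or 'late', got {stage!r}")
    return SessionGeneratorConfig(
        duration=1668.0,
        tier_configs={
            "MT facing": _facing_config("therapist"),
            "MT still": _still_config("therapist"),
            "MT pulse": _therapist_pulse_config(),
            "client facing": _facing_config("client"),
            "client still": _still_config("client"),
            "client pulse": _client_pulse_config(),
            "synchrony": _synchrony_config(),
        },
        structure_plan=plan,
        coupling_in_song=coupling_in_song,
        coupling_outside=coupling_outside,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate_tier(
    cfg: TierGeneratorConfig,
    name: str,
    role: str,
    duration: float,
    rng: np.random.Generator,
) -> Tier:
    """Simulate one semi-Markov tier over [0, duration)."""
    cfg.validate()
    vocabs = standard_vocabularies()
    vocab = vocabs[cfg.vocabulary]
    labels = list(cfg.initial)
    p0 = np.array([cfg.initial[l] for l in labels], dtype=float)
    state = labels[int(rng.choice(len(labels), p=p0 / p0.sum()))]
    t = 0.0
    intervals: List[LabeledInterval] = []
    while t < duration - _EPS:
        dw = cfg.dwell[state]
        d = float(rng.lognormal(dw.mu, dw.sigma_log))
        end = min(t + d, duration)
        if end - t > _MIN_BOUT:
            intervals.append(LabeledInterval(t, end, state))
        t = end
        if t >= duration - _EPS:
            break
        if cfg.gap_probability > 0 and rng.random() < cfg.gap_probability:
            g = float(rng.lognormal(cfg.gap_dwell.mu, cfg.gap_dwell.sigma_log))
            t = min(t + g, duration)
        row = cfg.transition[state]
        nxt = list(row)
        pr = np.array([row[l] for l in nxt], dtype=float)
        state = nxt[int(rng.choice(len(nxt), p=pr / pr.sum()))]
    return Tier(name, role, vocab, tuple(intervals), duration)


def _overlay(
    intervals: Sequence[LabeledInterval],
    spans: Sequence[Tuple[float, float]],
    label: str,
) -> Tuple[LabeledInterval, ...]:
    """Replace *spans* of a tier by *label*, merging abutting same-label runs."""
    spans = _merge_spans(list(spans))
    carved: List[LabeledInterval] = []
    for iv in intervals:
        pieces = [(iv.onset, iv.offset)]
        for s, e in spans:
            if e <= iv.onset or s >= iv.offset:
                continue
            nxt = []
            for a, b in pieces:
                if e <= a or s >= b:
                    nxt.append((a, b))
                    continue
                if a < s:
                    nxt.append((a, s))
                if e < b:
                    nxt.append((e, b))
            pieces = nxt
        for a, b in pieces:
            if b - a > _MIN_BOUT:
                carved.append(LabeledInterval(a, b, iv.label))
    for s, e in spans:
        if e - s > _EPS:
            carved.append(LabeledInterval(s, e, label))
    carved.sort(key=lambda iv: iv.onset)
    out: List[LabeledInterval] = []
    for iv in carved:
        if (
            out
            and normalize_label(out[-1].label) == normalize_label(iv.label)
            and abs(out[-1].offset - iv.onset) <= _EPS
        ):
            out[-1] = LabeledInterval(out[-1].onset, iv.offset, iv.label)
        else:
            out.append(iv)
    return tuple(out)


_TIER_STREAMS = (
    "MT facing",
    "MT still",
    "MT pulse",
    "client facing",
    "client still",
    "client pulse",
    "synchrony",
    "coupling",
    "shared pulse",
)

ALL_TIERS = (
    "musical structure",
    "MT facing",
    "MT still",
    "MT pulse",
    "client facing",
    "client still",
    "client pulse",
    "mutual facing",
    "mutual still",
    "shared pulse",
    "synchrony",
)


def generate_session(
    cfg: SessionGeneratorConfig,
    pair_id: str = "P00",
    stage: str = "early",
    seed: Optional[int] = None,
    tiers: Optional[Sequence[str]] = None,
) -> Session:
    """Simulate a full session (or a subset of its tiers), deterministically.

    Every tier draws from its own child random stream, spawned in a fixed
    order from the session seed, so generating a subset of tiers yields
    exactly the tiers a full run would produce.
    """
    cfg.validate()
    requested = tuple(tiers) if tiers is not None else ALL_TIERS
    for name in requested:
        if name not in ALL_TIERS:
            raise ConfigError(f"unknown tier {name!r}; choose from {ALL_TIERS}")
    if seed is None:
        seed = cfg.seed if cfg.seed is not None else 0
    root = np.random.default_rng(seed)
    streams = dict(zip(_TIER_STREAMS, root.spawn(len(_TIER_STREAMS))))
    duration = cfg.duration
    vocabs = standard_vocabularies()

    # Musical structure follows the plan exactly (no randomness).
    t = 0.0
    structure_ivs = []
    for lab, d in cfg.structure_plan:
        structure_ivs.append(LabeledInterval(t, t + d, lab))
        t += d
    structure = Tier(
        "musical structure", "dyad", vocabs["musical structure"],
        tuple(structure_ivs), duration,
    )
    song_spans = _merged_support(structure, "song")

    need = set(requested)
    if "mutual facing" in need:
        need |= {"MT facing", "client facing"}
    if "mutual still" in need:
        need |= {"MT still", "client still"}
    if "shared pulse" in need:
        need |= {"MT pulse", "client pulse"}
    if "client pulse" in need:
        need.add("MT pulse")

    built: Dict[str, Tier] = {"musical structure": structure}

    def build_simple(name: str, role: str) -> None:
        if name in need and name not in built:
            built[name] = generate_tier(
                cfg.tier_configs[name], name, role, duration, streams[name]
            )

    build_simple("MT facing", "therapist")
    build_simple("MT still", "therapist")
    build_simple("MT pulse", "therapist")
    build_simple("client facing", "client")
    build_simple("client still", "client")
    build_simple("synchrony", "dyad")

    if "client pulse" in need:
        base = generate_tier(
            cfg.tier_configs["client pulse"], "client pulse", "client",
            duration, streams["client pulse"],
        )
        mt_regular = _merged_support(built["MT pulse"], "regular")
        crng = streams["coupling"]
        chosen: List[Tuple[float, float]] = []
        for s, e in mt_regular:
            # Split the therapist-regular run at song boundaries; each piece
            # pulls the client into a regular pulse with the stage's coupling
            # probability.
            in_song = [
                (max(s, a), min(e, b))
                for a, b in song_spans
                if min(e, b) > max(s, a)
            ]
            pieces = [(x, y, True) for x, y in in_song]
            outside = _subtract_span((s, e), in_song)
            pieces += [(x, y, False) for x, y in outside]
            for x, y, song in sorted(pieces):
                if y - x <= 2 * _MIN_BOUT:
                    continue
                p = cfg.coupling_in_song if song else cfg.coupling_outside
                if crng.random() < p:
                    chosen.append((x, y))
        built["client pulse"] = Tier(
            "client pulse", "client", vocabs["individual pulse"],
            _overlay(base.intervals, chosen, "regular"), duration,
        )

    if "shared pulse" in need:
        both = _intersect_spans(
            _merged_support(built["client pulse"], "regular"),
            _merged_support(built["MT pulse"], "regular"),
        )
        srng = streams["shared pulse"]
        shared_ivs = []
        for s, e in both:
            if e - s < cfg.min_shared_run_s:
                continue
            lab = (
                "shared pulse"
                if srng.random() < cfg.shared_pulse_prob
                else "not shared pulse"
            )
            shared_ivs.append(LabeledInterval(s, e, lab))
        built["shared pulse"] = Tier(
            "shared pulse", "dyad", vocabs["shared pulse"],
            tuple(shared_ivs), duration,
        )

    if "mutual facing" in need:
        derived = derive_mutual_facing(built["client facing"], built["MT facing"])
        built["mutual facing"] = replace(derived, name="mutual facing")
    if "mutual still" in need:
        derived = derive_mutual_still(built["client still"], built["MT still"])
        built["mutual still"] = replace(derived, name="mutual still")

    return Session(
        pair_id=pair_id,
        stage=stage,
        duration=duration,
        tiers={name: built[name] for name in requested},
    )


def _subtract_span(
    span: Tuple[float, float], holes: Sequence[Tuple[float, float]]
) -> List[Tuple[float, float]]:
    pieces = [span]
    for s, e in sorted(holes):
        nxt = []
        for a, b in pieces:
            if e <= a or s >= b:
                nxt.append((a, b))
                continue
            if a < s:
                nxt.append((a, s))
            if e < b:
                nxt.append((e, b))
        pieces = nxt
    return [(a, b) for a, b in pieces if b - a > _EPS]


def _intersect_spans(
    a: Sequence[Tuple[float, float]], b: Sequence[Tuple[float, float]]
) -> List[Tuple[float, float]]:
    out, i, j = [], 0, 0
    while i < len(a) and j < len(b):
        lo, hi = max(a[i][0], b[j][0]), min(a[i][1], b[j][1])
        if hi > lo:
            out.append((lo, hi))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def simulate_second_coder(tier: Tier, noise: CoderNoiseConfig) -> Tier:
    """Perturb a tier the way an independent human coder would disagree.

    Per annotation, in order: possible deletion, Gaussian jitter on both
    boundaries (clipped to keep order, non-overlap and the session bounds),
    possible relabelling to a uniformly chosen *other* vocabulary label.
    Deterministic given ``noise.seed``.
    """
    rng = np.random.default_rng(noise.seed)
    out: List[LabeledInterval] = []
    prev_off = 0.0
    others_cache = {}
    for iv in tier.intervals:
        delete = rng.random() < noise.deletion_prob
        jo = float(rng.normal(0.0, noise.jitter_sd)) if noise.jitter_sd > 0 else 0.0
        jf = float(rng.normal(0.0, noise.jitter_sd)) if noise.jitter_sd > 0 else 0.0
        relabel = rng.random() < noise.relabel_prob
        label = iv.label
        if relabel:
            key = normalize_label(iv.label)
            if key not in others_cache:
                others_cache[key] = [
                    l
                    for l in tier.vocabulary.labels
                    if normalize_label(l) != key
                ]
            others = others_cache[key]
            if others:
                label = others[int(rng.integers(len(others)))]
        if delete:
            continue
        a = max(iv.onset + jo, prev_off, 0.0)
        b = min(iv.offset + jf, tier.session_duration)
        if b - a < 1e-3:
            continue
        out.append(LabeledInterval(a, b, label))
        prev_off = b
    return Tier(tier.name, tier.role, tier.vocabulary, tuple(out), tier.session_duration)


def second_coder_corpus(
    corpus: Sequence[Session],
    tier_names: Sequence[str],
    noise: CoderNoiseConfig,
    seed: int = 0,
) -> List[Session]:
    """Apply the coder-noise model to the named tiers of every session.

    Each (session, tier) combination gets its own derived seed, so the whole
    simulated second coder is reproducible from one integer.
    """
    out: List[Session] = []
    children = np.random.SeedSequence(seed).spawn(max(len(corpus), 1))
    for sess, child in zip(corpus, children):
        tier_seeds = child.spawn(max(len(tier_names), 1))
        tiers = dict(sess.tiers)
        for name, ts in zip(tier_names, tier_seeds):
            if name in tiers:
                n2 = replace(noise, seed=int(ts.generate_state(1)[0] % (2**31)))
                tiers[name] = simulate_second_coder(tiers[name], n2)
        out.append(Session(sess.pair_id, sess.stage, sess.duration, tiers))
    return out


_DEFAULT_PAIR_IDS = ("OD", "SC", "MK", "EC", "TR")


def generate_corpus(
    n_pairs: int,
    early_cfg: Optional[SessionGeneratorConfig] = None,
    late_cfg: Optional[SessionGeneratorConfig] = None,
    seed: int = 0,
    tiers: Optional[Sequence[str]] = None,
) -> List[Session]:
    """Simulate ``2 * n_pairs`` sessions (each pair early and late)."""
    if n_pairs < 1:
        raise ConfigError("n_pairs must be >= 1")
    early_cfg = early_cfg or default_session_config("early")
    late_cfg = late_cfg or default_session_config("late")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * n_pairs)
    sessions: List[Session] = []
    for i in range(n_pairs):
        pid = (
            _DEFAULT_PAIR_IDS[i]
            if i < len(_DEFAULT_PAIR_IDS)
            else f"P{i + 1:02d}"
        )
        for j, (stage, cfg) in enumerate((("early", early_cfg), ("late", late_cfg))):
            child_seed = int(children[2 * i + j].generate_state(1)[0] % (2**31))
            sessions.append(
                generate_session(cfg, pair_id=pid, stage=stage, seed=child_seed, tiers=tiers)
            )
    return sessions
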