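"""Inter-rater agreement with surrogate baselines, session profiles, bout and
co-occurrence statistics.

Agreement between two coders of the same session is the percentage of
fixed-resolution time samples at which both carry the same label (the
unannotated sentinel counts as a matchable label by default).  Because sparse
tiers inflate raw percentage agreement — two coders agree trivially on long
stretches of silence — observed agreement is compared against a *surrogate
baseline*: the same tier paired across unrelated sessions.  The comparison is
a one-sided Welch t-test with a 95% confidence interval on the mean
difference.

Profiles, bouts and overlaps are computed by exact interval arithmetic, never
from the raster; the raster is reserved for agreement (where the protocol
defines it) and for test oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .annotation_model import (
    MUSICAL_SOUND_LABELS,
    SENTINEL,
    Session,
    Tier,
    normalize_label,
)
from .errors import (
    GridError,
    InsufficientDataError,
    MissingTierError,
    PairingError,
    VocabularyError,
)
from .timeline_ops import DEFAULT_DT, RELIABILITY_WINDOW, SampledTimeline, Window, sample_tier

__all__ = [
    "AgreementResult",
    "SessionProfile",
    "BoutStats",
    "OverlapResult",
    "percent_agreement",
    "surrogate_agreements",
    "agreement_vs_baseline",
    "session_profile",
    "shared_pulse_of_sound",
    "bout_stats",
    "tier_overlap",
    "compare_stages",
    "profiles_to_frame",
]


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgreementResult:
    """Observed two-coder agreement for one tier against its surrogate baseline."""

    tier_name: str
    observed_pct: float
    surrogate_mean_pct: float
    surrogate_sem_pct: float
    diff_ci95: Tuple[float, float]
    t_stat: float
    p_value: float
    n_pairs: int
    observed_per_session: Tuple[float, ...] = ()
    test: str = "welch"

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SessionProfile:
    """Per-tier label proportions of one session (exact interval durations).

    ``proportions[tier][label]`` includes the ``"(none)"`` gap share, so each
    tier's map sums to 1.  ``shared_pulse_of_sound`` is the proportion of
    shared pulse out of time when at least one participant produced musical
    sound; ``None`` when the session has no pulse tiers or no sound.
    """

    pair_id: str
    stage: str
    duration: float
    proportions: Mapping[str, Mapping[str, float]]
    shared_pulse_of_sound: Optional[float] = None


@dataclass(frozen=True)
class BoutStats:
    """Bout (maximal same-label run) summary for one label on one tier."""

    tier_name: str
    label: str
    count: int
    total_s: float
    mean_s: Optional[float]
    median_s: Optional[float]
    max_s: Optional[float]


@dataclass(frozen=True)
class OverlapResult:
    """Exact co-occurrence of two label supports across two tiers."""

    tier_a: str
    label_a: str
    tier_b: str
    label_b: str
    overlap_s: float
    frac_of_a: Optional[float]
    frac_of_b: Optional[float]


# ---------------------------------------------------------------------------
# Interval helpers (exact arithmetic)
# ---------------------------------------------------------------------------

_EPS = 1e-9


def _merged_support(tier: Tier, label: str) -> List[Tuple[float, float]]:
    """Sorted, merged [start, end) spans where *tier* carries *label*;
    abutting same-label intervals are merged into one bout."""
    key = normalize_label(label)
    spans = [
        (iv.onset, iv.offset)
        for iv in tier.intervals
        if normalize_label(iv.label) == key
    ]
    return _merge_spans(spans)


def _merge_spans(spans: Sequence[Tuple[float, float]]) -> List[Tuple[float, float]]:
    out: List[Tuple[float, float]] = []
    for s, e in sorted(spans):
        if out and s <= out[-1][1] + _EPS:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _intersect_length(
    a: Sequence[Tuple[float, float]], b: Sequence[Tuple[float, float]]
) -> float:
    total, i, j = 0.0, 0, 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if hi > lo:
            total += hi - lo
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return total


def _span_length(spans: Sequence[Tuple[float, float]]) -> float:
    return sum(e - s for s, e in spans)


# ---------------------------------------------------------------------------
# Agreement
# ---------------------------------------------------------------------------

def percent_agreement(
    a: SampledTimeline, b: SampledTimeline, include_sentinel: bool = True
) -> float:
    """Percentage of grid points at which both timelines carry the same label.

    With ``include_sentinel=False``, samples where either timeline is
    unannotated are dropped before computing the percentage (sensitivity
    analysis); the result is ``nan`` if nothing remains.
    """
    if not a.same_grid(b):
        raise GridError(
            f"timelines on different grids: dt {a.dt}/{b.dt}, t0 {a.t0}/{b.t0}, "
            f"n {len(a)}/{len(b)}"
        )
    xa, xb = a.as_array(), b.as_array()
    if not include_sentinel:
        keep = (xa != SENTINEL) & (xb != SENTINEL)
        if not keep.any():
            return float("nan")
        xa, xb = xa[keep], xb[keep]
    return 100.0 * float(np.mean(xa == xb))


def surrogate_agreements(
    corpus: Sequence[Session],
    tier_name: str,
    window: Window = RELIABILITY_WINDOW,
    dt: float = DEFAULT_DT,
    max_pairs: Optional[int] = None,
    seed: Optional[int] = None,
    include_sentinel: bool = True,
) -> List[float]:
    """Chance-level agreements: the same tier paired across unrelated sessions.

    Uses all ordered pairs of distinct sessions holding *tier_name* (the
    pairing scheme is stated, not sampled); if ``max_pairs`` is given the
    pair list is subsampled with the seeded generator.
    """
    eligible = [s for s in corpus if tier_name in s.tiers]
    if len(eligible) < 2:
        raise InsufficientDataError(
            f"need >=2 sessions with tier {tier_name!r}; found {len(eligible)}"
        )
    rasters = [sample_tier(s.tier(tier_name), window, dt) for s in eligible]
    pairs = [
        (i, j)
        for i in range(len(eligible))
        for j in range(len(eligible))
        if i != j
    ]
    if max_pairs is not None and max_pairs < len(pairs):
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[k] for k in sorted(keep)]
    return [
        percent_agreement(rasters[i], rasters[j], include_sentinel=include_sentinel)
        for i, j in pairs
    ]


def _welch_ci(obs: np.ndarray, sur: np.ndarray, alpha: float = 0.05):
    """Welch t statistic, one-sided p (obs > sur) and two-sided CI of the
    mean difference, with degenerate (zero-variance) inputs handled."""
    n1, n2 = len(obs), len(sur)
    m1, m2 = float(np.mean(obs)), float(np.mean(sur))
    v1 = float(np.var(obs, ddof=1)) if n1 > 1 else 0.0
    v2 = float(np.var(sur, ddof=1)) if n2 > 1 else 0.0
    diff = m1 - m2
    se2 = v1 / n1 + v2 / n2
    if se2 <= 0:
        t = math.inf if diff > 0 else (-math.inf if diff < 0 else 0.0)
        p = 0.0 if diff > 0 else (1.0 if diff < 0 else 0.5)
        return t, p, (diff, diff)
    se = math.sqrt(se2)
    # Welch-Satterthwaite degrees of freedom.
    num = se2**2
    den = 0.0
    if n1 > 1:
        den += (v1 / n1) ** 2 / (n1 - 1)
    if n2 > 1:
        den += (v2 / n2) ** 2 / (n2 - 1)
    df = num / den if den > 0 else float(n1 + n2 - 2)
    t = diff / se
    p = float(sps.t.sf(t, df))
    crit = float(sps.t.ppf(1 - alpha / 2, df))
    return t, p, (diff - crit * se, diff + crit * se)


def agreement_vs_baseline(
    coder1: Sequence[Session],
    coder2: Sequence[Session],
    tier_name: str,
    window: Window = RELIABILITY_WINDOW,
    dt: float = DEFAULT_DT,
    include_sentinel: bool = True,
    paired: bool = False,
) -> AgreementResult:
    """Observed two-coder agreement per session vs. the surrogate baseline.

    Sessions are aligned across coders by (pair_id, stage).  The default test
    is a one-sided Welch two-sample t-test of the observed agreements against
    the surrogate agreements (alternative: observed > baseline); ``paired``
    instead pairs each session's observed agreement with the mean of the
    surrogate pairings in which that session participates (paired t-test).
    """
    index2 = {(s.pair_id, s.stage): s for s in coder2}
    aligned: List[Tuple[Session, Session]] = []
    for s1 in coder1:
        key = (s1.pair_id, s1.stage)
        if key not in index2:
            raise PairingError(f"coder2 corpus lacks session {key}")
        if tier_name in s1.tiers:
            aligned.append((s1, index2[key]))
    if not aligned:
        raise InsufficientDataError(f"no aligned sessions with tier {tier_name!r}")

    observed = []
    for s1, s2 in aligned:
        r1 = sample_tier(s1.tier(tier_name), window, dt)
        r2 = sample_tier(s2.tier(tier_name), window, dt)
        observed.append(percent_agreement(r1, r2, include_sentinel=include_sentinel))
    observed_arr = np.asarray(observed)

    eligible = [s for s, _ in aligned]
    surrogate = surrogate_agreements(
        eligible, tier_name, window, dt, include_sentinel=include_sentinel
    )
    sur_arr = np.asarray(surrogate)

    if paired:
        n = len(eligible)
        per_session = []
        k = 0
        mat = np.full((n, n), np.nan)
        for i in range(n):
            for j in range(n):
                if i != j:
                    mat[i, j] = sur_arr[k]
                    k += 1
        for i in range(n):
            row = np.concatenate([mat[i, :], mat[:, i]])
            per_session.append(float(np.nanmean(row)))
        diffs = observed_arr - np.asarray(per_session)
        m = float(np.mean(diffs))
        sd = float(np.std(diffs, ddof=1)) if len(diffs) > 1 else 0.0
        if sd == 0:
            t = math.inf if m > 0 else (-math.inf if m < 0 else 0.0)
            p = 0.0 if m > 0 else (1.0 if m < 0 else 0.5)
            ci = (m, m)
        else:
            se = sd / math.sqrt(len(diffs))
            df = len(diffs) - 1
            t = m / se
            p = float(sps.t.sf(t, df))
            crit = float(sps.t.ppf(0.975, df))
            ci = (m - crit * se, m + crit * se)
        test = "paired"
    else:
        t, p, ci = _welch_ci(observed_arr, sur_arr)
        test = "welch"

    sem = (
        float(np.std(sur_arr, ddof=1) / math.sqrt(len(sur_arr)))
        if len(sur_arr) > 1
        else 0.0
    )
    return AgreementResult(
        tier_name=tier_name,
        observed_pct=float(np.mean(observed_arr)),
        surrogate_mean_pct=float(np.mean(sur_arr)),
        surrogate_sem_pct=sem,
        diff_ci95=(float(ci[0]), float(ci[1])),
        t_stat=float(t),
        p_value=float(p),
        n_pairs=len(observed),
        observed_per_session=tuple(float(x) for x in observed_arr),
        test=test,
    )


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

def session_profile(session: Session, dt: Optional[float] = None) -> SessionProfile:
    """Label proportions per tier from exact interval durations.

    ``dt`` is accepted for interface symmetry but unused: profiles are exact,
    the raster is reserved for agreement computations and test oracles.
    """
    proportions: Dict[str, Dict[str, float]] = {}
    for name, tier in session.tiers.items():
        durs = tier.label_durations()
        proportions[name] = {k: v / session.duration for k, v in durs.items()}
    spos: Optional[float]
    try:
        spos = shared_pulse_of_sound(session)
    except MissingTierError:
        spos = None
    return SessionProfile(
        pair_id=session.pair_id,
        stage=session.stage,
        duration=session.duration,
        proportions=proportions,
        shared_pulse_of_sound=spos,
    )


def _find_tier_by_vocab(session: Session, vocab_name: str, role: str) -> Tier:
    for tier in session.tiers.values():
        if tier.vocabulary.name == vocab_name and tier.role == role:
            return tier
    raise MissingTierError(
        f"session {session.pair_id}/{session.stage} has no {role!r} tier with "
        f"vocabulary {vocab_name!r}"
    )


def shared_pulse_of_sound(session: Session) -> Optional[float]:
    """Proportion of shared pulse out of time with any musical sound.

    Numerator: total "shared pulse" time on the dyad shared-pulse tier.
    Denominator: length of the union of the two participants' musical-sound
    supports (regular, irregular or non-pulsed musical sounds).  ``None``
    (undefined) when the denominator is zero.
    """
    shared = _find_tier_by_vocab(session, "shared pulse", "dyad")
    client = _find_tier_by_vocab(session, "individual pulse", "client")
    therapist = _find_tier_by_vocab(session, "individual pulse", "therapist")

    def sound_spans(tier: Tier) -> List[Tuple[float, float]]:
        return _merge_spans(
            [
                (iv.onset, iv.offset)
                for iv in tier.intervals
                if normalize_label(iv.label) in MUSICAL_SOUND_LABELS
            ]
        )

    union = _merge_spans(sound_spans(client) + sound_spans(therapist))
    denom = _span_length(union)
    if denom <= 0:
        return None
    num = _span_length(_merged_support(shared, "shared pulse"))
    return num / denom


def compare_stages(
    early: SessionProfile, late: SessionProfile
) -> Dict[str, Dict[str, float]]:
    """Late-minus-early change per tier and label, in percentage points."""
    if early.pair_id != late.pair_id:
        raise PairingError(
            f"profiles belong to different pairs: {early.pair_id!r} vs "
            f"{late.pair_id!r}"
        )
    deltas: Dict[str, Dict[str, float]] = {}
    tiers = set(early.proportions) | set(late.proportions)
    for tname in tiers:
        pe = early.proportions.get(tname, {})
        pl = late.proportions.get(tname, {})
        labels = set(pe) | set(pl)
        deltas[tname] = {
            lab: 100.0 * (pl.get(lab, 0.0) - pe.get(lab, 0.0)) for lab in labels
        }
    return deltas


# ---------------------------------------------------------------------------
# Bouts and co-occurrence
# ---------------------------------------------------------------------------

def bout_stats(tier: Tier, label: str) -> BoutStats:
    """Count and summarize maximal runs of *label* on *tier*.

    Abutting same-label intervals merge into one bout.  Summary statistics
    are ``None`` when the label never occurs.
    """
    if label not in tier.vocabulary:
        raise VocabularyError(
            f"label {label!r} not in vocabulary {tier.vocabulary.name!r}"
        )
    bouts = _merged_support(tier, label)
    durs = [e - s for s, e in bouts]
    if not durs:
        return BoutStats(tier.name, label, 0, 0.0, None, None, None)
    return BoutStats(
        tier_name=tier.name,
        label=label,
        count=len(durs),
        total_s=float(sum(durs)),
        mean_s=float(np.mean(durs)),
        median_s=float(np.median(durs)),
        max_s=float(max(durs)),
    )


def tier_overlap(a: Tier, label_a: str, b: Tier, label_b: str) -> OverlapResult:
    """Exact intersection length of two label supports and its share of each."""
    if abs(a.session_duration - b.session_duration) > _EPS:
        raise PairingError("tiers must share session_duration")
    for tier, label in ((a, label_a), (b, label_b)):
        if label not in tier.vocabulary:
            raise VocabularyError(
                f"label {label!r} not in vocabulary {tier.vocabulary.name!r}"
            )
    sa = _merged_support(a, label_a)
    sb = _merged_support(b, label_b)
    overlap = _intersect_length(sa, sb)
    la, lb = _span_length(sa), _span_length(sb)
    return OverlapResult(
        tier_a=a.name,
        label_a=label_a,
        tier_b=b.name,
        label_b=label_b,
        overlap_s=overlap,
        frac_of_a=overlap / la if la > 0 else None,
        frac_of_b=overlap / lb if lb > 0 else None,
    )


# ---------------------------------------------------------------------------
# Tidy export
# ---------------------------------------------------------------------------

def profiles_to_frame(profiles: Iterable[SessionProfile]):
    """Tidy DataFrame: one row per (pair, stage, tier, label, proportion)."""
    import pandas as pd

    rows = []
    for p in profiles:
        for tname, labmap in p.proportions.items():
            for lab, prop in labmap.items():
                rows.append(
                    {
                        "pair_id": p.pair_id,
                        "stage": p.stage,
                        "tier": tname,
                        "label": lab,
                        "proportion": prop,
                    }
                )
        if p.shared_pulse_of_sound is not None:
            rows.append(
                {
                    "pair_id": p.pair_id,
                    "stage": p.stage,
                    "tier": "(derived)",
                    "label": "shared pulse of sound",
                    "proportion": p.shared_pulse_of_sound,
                }
            )
    return pd.DataFrame(rows, columns=["pair_id", "stage", "tier", "label", "proportion"])
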