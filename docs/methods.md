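# Methods

This note documents the models, conventions and numerical choices behind
`dyadannot`, and what the synthetic-data experiments do and do not show.

## Annotation model

A session is a set of named tiers; a tier is an ordered sequence of
non-overlapping labelled intervals over `[0, duration)` with a closed
controlled vocabulary. Conventions:

* **Half-open intervals.** An interval covers `[onset, offset)`; abutting
  intervals do not overlap, so rasterization and boundary arithmetic are
  unambiguous.
* **Gaps are implicit.** Unannotated time is permitted on every tier and is
  represented as gaps between intervals; it materialises as the sentinel
  label `"(none)"` only when a tier is sampled. Sparse dyad tiers (shared
  pulse, synchrony) consist mostly of gaps.
* **Label normalization.** Labels compare case-insensitively after
  whitespace collapsing, because hand-made annotation files vary.
* **"out of view" is a label, not a gap**, on facing/still tiers: it marks
  time that was watched but could not be coded, which is different from
  time that was never annotated.
* **Mutual exclusivity per tier.** One label at a time per tier; a sound
  that could be described two ways must be coded with a single category.
  This is enforced by the non-overlap invariant (overlaps inside one EAF
  tier are an error, not silently merged).

## File formats

EAF stores integer milliseconds; in memory times are float seconds.
Writing rounds half-up to whole milliseconds, so EAF↔model↔CSV round trips
are lossless to 1 ms, and time-slot ordering is fully deterministic
(sorted by time, then tier name), which makes simulated EAF output
byte-identical across runs for a fixed seed. Session metadata (pair id,
stage, duration) travels in EAF HEADER `PROPERTY` elements and in `#`
comment lines of the CSV dialect (`tier, role, label, onset_s, offset_s`).
Tier names map to (role, vocabulary) through an overridable table; EAF
`LINGUISTIC_TYPE_REF`/`PARTICIPANT` declarations take precedence when they
name a standard vocabulary. The default names ("client pulse", "MT pulse",
"shared pulse", …) are a documented convention, not a requirement.

## Rasterization and mutual-tier derivation

`sample_tier` places grid points at `t0 + kΔt` (default Δt = 0.1 s) and
assigns each point the label of the unique interval with
`onset ≤ t < offset`, else the sentinel. A small epsilon (10⁻⁶ s, far below
any Δt in use) absorbs float accumulation at interval boundaries. The
standard reliability window is minutes 5–8 of the session — 180 s, hence
exactly 1800 samples at 0.1 s.

Dyad-level tiers are derived from individual tiers by an **exact
interval-boundary sweep**: evaluate the label-pair mapping on every
elementary segment between consecutive boundaries of either input, then
merge equal-label runs. A per-sample derivation (rasterize both inputs,
map, run-length encode) exists only as a test oracle — the sweep avoids
Δt-dependent artefacts. Mapping rules: out-of-view or unannotated time on
either side makes the dyad state "out of view" (unanalyzable time takes
precedence); otherwise (facing, facing) → "both facing each other",
(not facing, not facing) → "both not facing each other", mixed → "one
facing the other and one not" (the mapping is unordered, so derivation is
symmetric under role swap); analogously for stillness. Derived tiers are
named "… (derived)" and never overwrite annotated mutual tiers.

The **candidate shared-pulse** tier marks time when both pulse tiers are
"regular" — a necessary condition for a shared pulse, not a sufficient one,
since identical tempo cannot be verified from categorical labels. Time when
both sides produce musical sound without being jointly regular is "not
shared pulse"; the rest is a gap. Any honestly annotated shared-pulse tier
must be contained in the candidate support, which makes the derivation a
cheap consistency check on manual coding.

## Agreement and surrogate baselines

Percentage agreement between two coders is
`100 · #{k : a_k = b_k} / n` over a common grid. The sentinel counts as a
matchable label by default — two coders agreeing that nothing happens *is*
agreement under a literal reading of "same annotation at a time point" —
and a flag excludes sentinel samples for sensitivity analysis.

Sparse tiers inflate raw agreement (fewer annotations → more trivially
matching gap samples), so observed agreement is compared with a surrogate
baseline: the same tier paired across unrelated sessions, same window, all
ordered pairs of distinct sessions by default (subsampling is seeded). For
independent stationary processes with marginal label distribution *p* the
expected surrogate agreement is Σᵢ pᵢ²; the sparser the tier, the larger
the sentinel share and hence the higher the baseline — the package's tests
verify this closed form and the sparsity effect directionally at densities
matching ~50 vs ~11 annotations per 3-minute window.

The default test is a one-sided Welch (unequal-variance) two-sample t-test
of observed > surrogate with a Welch–Satterthwaite 95% CI on the mean
difference. Welch was chosen because the two samples (n sessions vs
n·(n−1) pairings) have very different sizes and variances; a per-video
paired variant (each session's observed agreement against the mean of the
surrogate pairings it participates in) is implemented behind a flag for
sensitivity analysis. Degenerate zero-variance inputs yield ±∞ t and a
point CI rather than NaNs.

## Profiles, bouts, overlaps

Profiles, bout statistics and co-occurrence are computed by **exact
interval arithmetic**, never from the raster. Per-tier label proportions
include the sentinel share and sum to 1. `shared_pulse_of_sound` divides
total annotated shared-pulse time by the length of the union of the two
participants' musical-sound supports (regular, irregular, non-pulsed
musical sounds — non-musical sounds and silence are excluded), returning
an undefined marker (`None`) on a zero denominator. Bouts are maximal
same-label runs with abutting intervals merged; empty labels have
undefined mean/median/max. Stage comparisons report late − early in
**percentage points** (a 10% → 26.3% change is +16.3 points), and are
antisymmetric under argument swap.

## Synthetic sessions

Each generated tier is a semi-Markov process: an embedded Markov chain over
the tier's labels with independent log-normal dwell times per label,
parameterized by the dwell *mean* in seconds (μ = ln m − σ²/2, σ default
0.6). Explicit dwells are essential: plain Markov chains at raster
resolution produce geometric bout lengths, far too short for the long
facing/stillness bouts of real sessions. Log-normal was chosen as a
positive, right-skewed two-parameter family. The long-run time share of
label *i* is πᵢmᵢ / (Σⱼπⱼmⱼ + g·m_gap) with π the embedded-chain
stationary distribution, m the mean dwells and g the per-bout gap
probability — the package computes this in closed form and the tests
check empirical recovery within 3 standard errors.

Session assembly: the musical-structure tier follows a deterministic
segment plan (a hello song and a goodbye song of 150 s book-ending the
session, a middle alternating free improvisation and songs); individual
facing/still/pulse tiers are independent semi-Markov draws; the client
pulse is then **coupled** to the therapist by regenerating it as "regular"
on each therapist-regular stretch with probability `coupling_in_song`
inside songs and `coupling_outside` elsewhere (the reverse, client-led
direction is available by swapping roles). The shared-pulse tier covers
maximal both-regular runs (≥ 0.3 s), each annotated "shared pulse" with
probability 0.75, else "not shared pulse". Mutual facing/still tiers are
the exact derivations of the individual tiers. Each tier consumes its own
child random stream spawned in fixed order from the session seed, so
generating any subset of tiers reproduces exactly what a full run would
produce.

**Default conditions (calibrated once, then frozen).** Session duration
1668 s (27.8 min). Dwell means and transition matrices were set so that the
individual pulse tiers carry ≈50 annotations per 3-minute window and the
sparse dyad tiers (shared pulse, synchrony) ≈11 — the densities of the
protocol's reliability section — and so that the shared-pulse time share
falls in the low-teens of a session. Early sessions use a song-heavier
middle (50% vs 30%) and weaker coupling (0.5/0.2 vs 0.6/0.3) than late
sessions, reflecting the design in which early sessions are more dominated
by structural songs and later ones by freer, more coupled improvisation.

**Coder-noise model.** A simulated second coder deletes each annotation
with probability `deletion_prob`, jitters both boundaries with
N(0, `jitter_sd`²) clipped to preserve ordering, non-overlap and the
session bounds (intervals shrunk below 1 ms are dropped), and relabels
with probability `relabel_prob` to a uniformly chosen other vocabulary
label. The defaults used in the power experiments (jitter 0.3 s, relabel
0.05) produce observed agreements in the mid-80s% against surrogate
baselines near 28%, and the observed-vs-baseline test rejects essentially
always over 10-session corpora.

**What the generator does not emulate.** Real coder disagreement is not
independent across annotations (systematic category confusions, drift over
a session); real behaviour streams are cross-correlated in many more ways
than the single pulse-coupling mechanism; bout lengths need not be
log-normal; and there is no audio or movement signal at all. Passing tests
therefore demonstrate that the *analysis machinery* is correct and
adequately powered under plausible conditions — not that any particular
empirical finding about therapy sessions would replicate.

## Figures and numerics

SVG is the reference figure format: output is deterministic (fixed
`svg.hashsalt`, no embedded date) and every span/bar carries a `gid`, so
tests can parse the file and verify that span coordinates are linear in
data time. Time axes display minutes; all internal arithmetic is seconds.
Figure-producing paths always return/emit the underlying numbers.

Numerical tolerances: interval arithmetic uses 10⁻⁹ s epsilons (far below
the 1 ms disk quantum); rasterization uses 10⁻⁶ s at grid boundaries;
generated bouts shorter than 0.05 s are suppressed as humanly
un-annotatable.

## Problem sizes used in the shipped experiments

Oracle-equivalence suites use 1000 random 30 s tier pairs at Δt = 0.01 s;
chance-agreement checks use 1000 independent length-1800 timelines;
surrogate/sparsity checks use 20–30 simulated 8-minute sessions; the power
experiment uses 200 replicate corpora of 10 full-length sessions;
parameter recovery uses 50 full-length sessions and 200 two-session
corpora. These sizes give Monte-Carlo errors comfortably below the margins
being tested while keeping a full run in the minutes range on one core.

## Known limitations

* Chance-corrected coefficients (Cohen's κ and relatives) are deliberately
  not the headline statistic; the surrogate-baseline design plays that
  role. κ can be computed from the same rasters if needed.
* The candidate shared-pulse tier is an upper bound only; deriving true
  shared pulse (same tempo) requires audio, which is out of scope.
* Entrainment (mutual adaptation of onset times) is not estimated;
  only annotated synchrony/shared-pulse states are analysed.
* With two sessions per pair, stage comparisons are descriptive deltas;
  no significance claims are attached to per-pair change.
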