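"""Timeline and profile figures.

``render_timeline`` draws one horizontal lane per tier with coloured spans
per annotation on a shared time axis in minutes — the moment-by-moment view
of a session.  ``render_profiles`` draws grouped stacked bars of label
proportions per pair and stage — the at-a-glance session profile view.

SVG is the reference format: output is deterministic (fixed hash salt, no
embedded date) and every drawn span carries a ``gid`` so tests can parse the
file and check coordinates.  Both functions also return the plotted numbers
as rows, so a figure is never the only output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib import rc_context

from .annotation_model import OUT_OF_VIEW, SENTINEL, Session, normalize_label
from .errors import MissingTierError, DyadannotError
from .interaction_stats import SessionProfile
from .timeline_ops import Window

__all__ = ["RenderSpec", "render_timeline", "render_profiles"]

_SVG_RC = {"svg.hashsalt": "dyadannot"}

#: Fixed label palette; unlisted labels cycle through tab20.
_BASE_COLORS = {
    "regular": "#1f77b4",
    "irregular": "#ff7f0e",
    "non-pulsed musical sounds": "#2ca02c",
    "non-musical sounds": "#bcbd22",
    "silence": "#c7c7c7",
    "facing": "#1f77b4",
    "not facing": "#aec7e8",
    "still": "#9467bd",
    "not still": "#c5b0d5",
    "both facing each other": "#1f77b4",
    "both not facing each other": "#aec7e8",
    "one facing the other and one not": "#ffbb78",
    "both still": "#9467bd",
    "both not still": "#c5b0d5",
    "one still and one not": "#f7b6d2",
    "shared pulse": "#d62728",
    "not shared pulse": "#ff9896",
    "candidate shared pulse": "#e377c2",
    "synchrony": "#17becf",
    "turn-taking": "#9edae5",
    "song": "#8c564b",
    "free improvisation": "#c49c94",
    OUT_OF_VIEW: "#eeeeee",
}


@dataclass(frozen=True)
class RenderSpec:
    """What to draw and where to write it."""

    tiers: Tuple[str, ...]
    path: Union[str, Path]
    window: Optional[Window] = None
    colors: Mapping[str, str] = field(default_factory=dict)
    format: str = "svg"
    dpi: int = 150

    def __post_init__(self) -> None:
        if self.format not in ("svg", "png"):
            raise ValueError("format must be 'svg' or 'png'")
        seen: Dict[str, str] = {}
        for lab, col in self.colors.items():
            key = normalize_label(lab)
            if key in seen and seen[key] != col:
                raise ValueError(f"conflicting colors for label {lab!r}")
            seen[key] = col


def _color_for(label: str, overrides: Mapping[str, str], fallback: Dict[str, str]) -> str:
    key = normalize_label(label)
    norm_overrides = {normalize_label(k): v for k, v in overrides.items()}
    if key in norm_overrides:
        return norm_overrides[key]
    if key in _BASE_COLORS:
        return _BASE_COLORS[key]
    if key not in fallback:
        cmap = plt.get_cmap("tab20")
        fallback[key] = matplotlib.colors.to_hex(cmap(len(fallback) % 20))
    return fallback[key]


def _save(fig, spec: RenderSpec) -> Path:
    path = Path(spec.path)
    if spec.format == "svg":
        with rc_context(_SVG_RC):
            fig.savefig(path, format="svg", metadata={"Date": None})
    else:
        fig.savefig(path, format="png", dpi=spec.dpi)
    plt.close(fig)
    return path


def render_timeline(session: Session, spec: RenderSpec) -> Tuple[Path, List[dict]]:
    """Draw the requested tiers as stacked lanes; return (path, span rows).

    Out-of-view spans are hatched so unanalyzable time is visually distinct.
    Each span is tagged with ``gid="span::<tier>::<index>"`` in the SVG.
    """
    for name in spec.tiers:
        if name not in session.tiers:
            raise MissingTierError(f"session has no tier {name!r}")
    window = spec.window or Window(0.0, session.duration)
    fallback: Dict[str, str] = {}
    fig, ax = plt.subplots(figsize=(12, 0.6 * max(len(spec.tiers), 1) + 1.5))
    rows: List[dict] = []
    for lane, name in enumerate(spec.tiers):
        tier = session.tiers[name]
        y = len(spec.tiers) - 1 - lane
        for i, iv in enumerate(tier.intervals):
            s = max(iv.onset, window.start)
            e = min(iv.offset, window.end)
            if e <= s:
                continue
            key = normalize_label(iv.label)
            bar = ax.broken_barh(
                [(s / 60.0, (e - s) / 60.0)],
                (y + 0.1, 0.8),
                facecolors=_color_for(iv.label, spec.colors, fallback),
                hatch="//" if key == OUT_OF_VIEW else None,
                edgecolor="none",
                gid=f"span::{name}::{i}",
            )
            rows.append(
                {"tier": name, "label": iv.label, "onset_s": s, "offset_s": e}
            )
    ax.set_yticks([len(spec.tiers) - 1 - k + 0.5 for k in range(len(spec.tiers))])
    ax.set_yticklabels(spec.tiers)
    ax.set_ylim(0, max(len(spec.tiers), 1))
    ax.set_xlim(window.start / 60.0, window.end / 60.0)
    ax.set_xlabel("time (min)")
    ax.set_title(f"{session.pair_id} — {session.stage} session")
    fig.tight_layout()
    return _save(fig, spec), rows


def render_profiles(
    profiles: Sequence[SessionProfile], spec: RenderSpec
) -> Tuple[Path, List[dict]]:
    """Grouped stacked bars of one tier's label proportions, per pair x stage.

    ``spec.tiers`` must name exactly one tier; bars are ordered by pair, with
    the early bar left of the late bar.  Stacks sum to 100%.
    """
    if not profiles:
        raise DyadannotError("need at least one profile")
    if len(spec.tiers) != 1:
        raise DyadannotError("render_profiles draws exactly one tier per figure")
    tier_name = spec.tiers[0]
    stage_order = {"early": 0, "late": 1}
    keyed = sorted(profiles, key=lambda p: (p.pair_id, stage_order.get(p.stage, 2)))
    labels: List[str] = []
    for p in keyed:
        if tier_name not in p.proportions:
            raise MissingTierError(f"profile {p.pair_id}/{p.stage} lacks {tier_name!r}")
        for lab in p.proportions[tier_name]:
            if lab not in labels:
                labels.append(lab)
    fallback: Dict[str, str] = {}
    fig, ax = plt.subplots(figsize=(1.2 * len(keyed) + 2, 5))
    rows: List[dict] = []
    xticks, xticklabels = [], []
    for x, p in enumerate(keyed):
        bottom = 0.0
        for lab in labels:
            frac = 100.0 * p.proportions[tier_name].get(lab, 0.0)
            if frac > 0:
                color = (
                    "#ffffff" if lab == SENTINEL
                    else _color_for(lab, spec.colors, fallback)
                )
                ax.bar(
                    x, frac, bottom=bottom, width=0.8, color=color,
                    edgecolor="#555555", linewidth=0.4,
                    gid=f"bar::{p.pair_id}::{p.stage}::{lab}",
                )
            rows.append(
                {
                    "pair_id": p.pair_id,
                    "stage": p.stage,
                    "tier": tier_name,
                    "label": lab,
                    "percent": frac,
                }
            )
            bottom += frac
        xticks.append(x)
        xticklabels.append(f"{p.pair_id}\n{p.stage}")
    ax.set_xticks(xticks)
    ax.set_xticklabels(xticklabels, fontsize=8)
    ax.set_ylabel("% of session")
    ax.set_ylim(0, 100)
    ax.set_title(tier_name)
    handles = [
        plt.Rectangle(
            (0, 0), 1, 1,
            color="#ffffff" if lab == SENTINEL else _color_for(lab, spec.colors, fallback),
            ec="#555555",
        )
        for lab in labels
    ]
    ax.legend(handles, labels, fontsize=7, loc="upper left", bbox_to_anchor=(1.01, 1.0))
    fig.tight_layout()
    return _save(fig, spec), rows
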