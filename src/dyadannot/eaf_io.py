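"""Read and write sessions as ELAN EAF (XML) files or flat CSV interval tables.

EAF stores times as integer milliseconds in a TIME_ORDER table of TIME_SLOTs;
each tier's ALIGNABLE_ANNOTATIONs reference two slot ids.  In memory times are
seconds; at write time they are rounded half-up to whole milliseconds, so a
disk round trip is lossless to 1 ms.

Because ELAN projects name their tiers freely, the mapping from tier name to
(role, vocabulary) lives in an overridable table.  The defaults cover the
standard dyadic-protocol names ("client pulse", "MT pulse", "shared pulse",
"musical structure", ...).  When an EAF tier declares a LINGUISTIC_TYPE_REF
that names one of the standard vocabularies, that declaration wins over the
name-based mapping.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Mapping, Optional, Tuple, Union

from lxml import etree

from .annotation_model import (
    LabeledInterval,
    Session,
    Tier,
    Vocabulary,
    normalize_label,
    standard_vocabularies,
    validate_session,
)
from .errors import (
    CsvFormatError,
    CsvRowError,
    EafParseError,
    EafReferenceError,
    SessionValidationError,
    VocabularyError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FileManifest",
    "DEFAULT_TIER_MAP",
    "load_tier_map",
    "read_eaf",
    "write_eaf",
    "read_csv",
    "write_csv",
]

#: Fixed document date so that identical sessions serialize byte-identically.
_EAF_DATE = "1970-01-01T00:00:00+00:00"

CSV_COLUMNS = ("tier", "role", "label", "onset_s", "offset_s")

#: normalized tier name -> (role, vocabulary name).  "MT" = music therapist.
DEFAULT_TIER_MAP: Dict[str, Tuple[str, str]] = {
    "client facing": ("client", "individual facing"),
    "client still": ("client", "individual still"),
    "client pulse": ("client", "individual pulse"),
    "mt facing": ("therapist", "individual facing"),
    "mt still": ("therapist", "individual still"),
    "mt pulse": ("therapist", "individual pulse"),
    "therapist facing": ("therapist", "individual facing"),
    "therapist still": ("therapist", "individual still"),
    "therapist pulse": ("therapist", "individual pulse"),
    "mutual facing": ("dyad", "mutual facing"),
    "mutual still": ("dyad", "mutual still"),
    "mutual facing (annotated)": ("dyad", "mutual facing"),
    "mutual still (annotated)": ("dyad", "mutual still"),
    "mutual facing (derived)": ("dyad", "mutual facing"),
    "mutual still (derived)": ("dyad", "mutual still"),
    "shared pulse": ("dyad", "shared pulse"),
    "synchrony": ("dyad", "synchrony"),
    "musical structure": ("dyad", "musical structure"),
}


@dataclass(frozen=True)
class FileManifest:
    """Where one session lives on disk and who coded it."""

    path: Union[str, Path]
    format: str  # "eaf" | "csv"
    pair_id: str
    stage: str
    coder_id: str = "coder1"

    def __post_init__(self) -> None:
        if not self.pair_id or not self.stage:
            raise ValueError("pair_id and stage must be non-empty")
        if self.format not in ("eaf", "csv"):
            raise ValueError(f"format must be 'eaf' or 'csv', got {self.format!r}")


def load_tier_map(path: Union[str, Path]) -> Dict[str, Tuple[str, str]]:
    """Load a tier-name -> (role, vocabulary) mapping from YAML or JSON.

    File schema: ``{tier name: {role: ..., vocabulary: ...}}``.  Names are
    normalized; entries extend (and may override) the defaults.
    """
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    table = dict(DEFAULT_TIER_MAP)
    for name, entry in raw.items():
        table[normalize_label(str(name))] = (
            str(entry["role"]),
            str(entry["vocabulary"]),
        )
    return table


def _resolve_tier(
    tier_name: str,
    tier_map: Mapping[str, Tuple[str, str]],
    vocabs: Mapping[str, Vocabulary],
    participant: Optional[str] = None,
    ltype: Optional[str] = None,
) -> Tuple[str, Vocabulary]:
    """Role and vocabulary for a tier, from declared attributes or the map."""
    role: Optional[str] = None
    vocab: Optional[Vocabulary] = None
    if ltype and normalize_label(ltype) in {normalize_label(k) for k in vocabs}:
        for k, v in vocabs.items():
            if normalize_label(k) == normalize_label(ltype):
                vocab = v
                break
    if participant and participant in ("client", "therapist", "dyad"):
        role = participant
    key = normalize_label(tier_name)
    if key in tier_map:
        mapped_role, mapped_vocab = tier_map[key]
        role = role or mapped_role
        if vocab is None:
            try:
                vocab = vocabs[mapped_vocab]
            except KeyError:
                raise VocabularyError(
                    f"tier map points {tier_name!r} at unknown vocabulary "
                    f"{mapped_vocab!r}"
                ) from None
    if role is None or vocab is None:
        raise VocabularyError(
            f"cannot resolve role/vocabulary for tier {tier_name!r}; add it to "
            f"the tier map or declare PARTICIPANT/LINGUISTIC_TYPE_REF"
        )
    return role, vocab


def _round_ms(seconds: float) -> int:
    """Seconds -> integer milliseconds, round half up (stable across runs)."""
    return int(math.floor(seconds * 1000.0 + 0.5))


# ---------------------------------------------------------------------------
# EAF
# ---------------------------------------------------------------------------

def read_eaf(
    path: Union[str, Path],
    tier_map: Optional[Mapping[str, Tuple[str, str]]] = None,
    pair_id: Optional[str] = None,
    stage: Optional[str] = None,
    duration: Optional[float] = None,
) -> Session:
    """Parse an EAF file into a :class:`Session`.

    Session metadata (pair id, stage, duration) is taken from HEADER
    PROPERTY elements when present, falling back to the keyword overrides;
    duration falls back to the last time slot.  Symbolic (unaligned)
    annotations are skipped with a warning; an annotation referencing a
    missing time slot raises :class:`EafReferenceError`.
    """
    tier_map = tier_map or DEFAULT_TIER_MAP
    vocabs = standard_vocabularies()
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise EafParseError(f"malformed EAF {path}: {exc}") from exc
    root = tree.getroot()

    props: Dict[str, str] = {}
    header = root.find("HEADER")
    if header is not None:
        for p in header.findall("PROPERTY"):
            if p.get("NAME"):
                props[p.get("NAME")] = p.text or ""

    slots: Dict[str, int] = {}
    time_order = root.find("TIME_ORDER")
    if time_order is not None:
        for ts in time_order.findall("TIME_SLOT"):
            sid = ts.get("TIME_SLOT_ID")
            val = ts.get("TIME_VALUE")
            if sid is None:
                raise EafParseError(f"{path}: TIME_SLOT without TIME_SLOT_ID")
            if val is not None:
                slots[sid] = int(val)

    pair_id = pair_id or props.get("pair_id", "unknown")
    stage = stage or props.get("stage", "early")
    if duration is None:
        if "duration_ms" in props:
            duration = int(props["duration_ms"]) / 1000.0
        elif slots:
            duration = max(slots.values()) / 1000.0
        else:
            duration = 1.0

    tiers: Dict[str, Tier] = {}
    for tier_el in root.findall("TIER"):
        tier_id = tier_el.get("TIER_ID")
        if tier_id is None:
            raise EafParseError(f"{path}: TIER without TIER_ID")
        role, vocab = _resolve_tier(
            tier_id,
            tier_map,
            vocabs,
            participant=tier_el.get("PARTICIPANT"),
            ltype=tier_el.get("LINGUISTIC_TYPE_REF"),
        )
        intervals = []
        for ann in tier_el.findall("ANNOTATION"):
            alignable = ann.find("ALIGNABLE_ANNOTATION")
            if alignable is None:
                logger.warning(
                    "%s: tier %r: skipping non-alignable annotation", path, tier_id
                )
                continue
            ref1 = alignable.get("TIME_SLOT_REF1")
            ref2 = alignable.get("TIME_SLOT_REF2")
            if ref1 not in slots or ref2 not in slots:
                missing = ref1 if ref1 not in slots else ref2
                raise EafReferenceError(
                    f"{path}: tier {tier_id!r}: annotation references missing "
                    f"time slot {missing!r}"
                )
            value_el = alignable.find("ANNOTATION_VALUE")
            label = (value_el.text or "") if value_el is not None else ""
            intervals.append(
                LabeledInterval(slots[ref1] / 1000.0, slots[ref2] / 1000.0, label)
            )
        intervals.sort(key=lambda iv: (iv.onset, iv.offset))
        tiers[tier_id] = Tier(tier_id, role, vocab, tuple(intervals), duration)

    session = Session(pair_id, stage, duration, tiers)
    overlap = [v for v in validate_session(session) if v.rule == "overlap"]
    if overlap:
        raise EafParseError(
            f"{path}: overlapping annotations within one tier: "
            + "; ".join(str(v) for v in overlap)
        )
    return session


def write_eaf(session: Session, path: Union[str, Path]) -> Path:
    """Serialize a validated session as a schema-valid EAF file.

    Times are rounded half-up to milliseconds; time slots are ordered by
    (time, tier name, onset-before-offset) so output is deterministic.
    """
    violations = validate_session(session)
    if violations:
        raise SessionValidationError(violations)

    root = etree.Element(
        "ANNOTATION_DOCUMENT",
        AUTHOR="dyadannot",
        DATE=_EAF_DATE,
        FORMAT="3.0",
        VERSION="3.0",
    )
    header = etree.SubElement(
        root, "HEADER", MEDIA_FILE="", TIME_UNITS="milliseconds"
    )
    for name, value in (
        ("pair_id", session.pair_id),
        ("stage", session.stage),
        ("duration_ms", str(_round_ms(session.duration))),
    ):
        prop = etree.SubElement(header, "PROPERTY", NAME=name)
        prop.text = value

    # One slot per annotation endpoint, globally sorted for determinism.
    endpoints = []  # (ms, tier_name, ann_index, which)
    tier_names = sorted(session.tiers)
    for tname in tier_names:
        for i, iv in enumerate(session.tiers[tname].intervals):
            endpoints.append((_round_ms(iv.onset), tname, i, 0))
            endpoints.append((_round_ms(iv.offset), tname, i, 1))
    endpoints.sort()
    slot_ids: Dict[Tuple[str, int, int], str] = {}
    time_order = etree.SubElement(root, "TIME_ORDER")
    for k, (ms, tname, i, which) in enumerate(endpoints, start=1):
        sid = f"ts{k}"
        slot_ids[(tname, i, which)] = sid
        etree.SubElement(
            time_order, "TIME_SLOT", TIME_SLOT_ID=sid, TIME_VALUE=str(ms)
        )

    ann_counter = 0
    used_vocabs = []
    for tname in tier_names:
        tier = session.tiers[tname]
        if tier.vocabulary.name not in used_vocabs:
            used_vocabs.append(tier.vocabulary.name)
        tier_el = etree.SubElement(
            root,
            "TIER",
            LINGUISTIC_TYPE_REF=tier.vocabulary.name,
            PARTICIPANT=tier.role,
            TIER_ID=tname,
        )
        for i, iv in enumerate(tier.intervals):
            ann_counter += 1
            ann = etree.SubElement(tier_el, "ANNOTATION")
            alignable = etree.SubElement(
                ann,
                "ALIGNABLE_ANNOTATION",
                ANNOTATION_ID=f"a{ann_counter}",
                TIME_SLOT_REF1=slot_ids[(tname, i, 0)],
                TIME_SLOT_REF2=slot_ids[(tname, i, 1)],
            )
            value = etree.SubElement(alignable, "ANNOTATION_VALUE")
            value.text = iv.label

    for vname in sorted(used_vocabs):
        etree.SubElement(
            root,
            "LINGUISTIC_TYPE",
            GRAPHIC_REFERENCES="false",
            LINGUISTIC_TYPE_ID=vname,
            TIME_ALIGNABLE="true",
        )

    path = Path(path)
    path.write_bytes(
        etree.tostring(
            root, xml_declaration=True, encoding="UTF-8", pretty_print=True
        )
    )
    return path


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def write_csv(session: Session, path: Union[str, Path]) -> Path:
    """Write the 5-column interval table (tier, role, label, onset_s, offset_s).

    Session metadata goes into ``#`` comment lines before the header so the
    format stays lossless with respect to the session model; times are printed
    with millisecond precision.
    """
    violations = validate_session(session)
    if violations:
        raise SessionValidationError(violations)
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# pair_id={session.pair_id}\n")
        fh.write(f"# stage={session.stage}\n")
        fh.write(f"# duration_s={_round_ms(session.duration) / 1000.0:.3f}\n")
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for tname in sorted(session.tiers):
            tier = session.tiers[tname]
            for iv in tier.intervals:
                writer.writerow(
                    [
                        tname,
                        tier.role,
                        iv.label,
                        f"{_round_ms(iv.onset) / 1000.0:.3f}",
                        f"{_round_ms(iv.offset) / 1000.0:.3f}",
                    ]
                )
    return path


def read_csv(
    path: Union[str, Path],
    tier_map: Optional[Mapping[str, Tuple[str, str]]] = None,
    pair_id: Optional[str] = None,
    stage: Optional[str] = None,
    duration: Optional[float] = None,
) -> Session:
    """Parse the 5-column CSV dialect back into a :class:`Session`.

    A missing column raises :class:`CsvFormatError`; a bad value raises
    :class:`CsvRowError` naming the 1-based file row.
    """
    tier_map = tier_map or DEFAULT_TIER_MAP
    vocabs = standard_vocabularies()
    meta: Dict[str, str] = {}
    rows = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        lineno = 0
        header: Optional[list] = None
        for raw in csv.reader(fh):
            lineno += 1
            if not raw:
                continue
            if raw[0].startswith("#"):
                text = ",".join(raw).lstrip("#").strip()
                if "=" in text:
                    k, v = text.split("=", 1)
                    meta[k.strip()] = v.strip()
                continue
            if header is None:
                header = [c.strip() for c in raw]
                if tuple(header) != CSV_COLUMNS:
                    raise CsvFormatError(
                        f"{path}: expected columns {CSV_COLUMNS}, got {tuple(header)}"
                    )
                continue
            rows.append((lineno, raw))
    if header is None:
        raise CsvFormatError(f"{path}: missing header row {CSV_COLUMNS}")

    pair_id = pair_id or meta.get("pair_id", "unknown")
    stage = stage or meta.get("stage", "early")
    parsed = []
    max_off = 0.0
    for lineno, raw in rows:
        if len(raw) != len(CSV_COLUMNS):
            raise CsvRowError(f"{path}:{lineno}: expected {len(CSV_COLUMNS)} fields")
        tname, role, label, onset_s, offset_s = [c.strip() for c in raw]
        try:
            onset, offset = float(onset_s), float(offset_s)
        except ValueError:
            raise CsvRowError(
                f"{path}:{lineno}: non-numeric time ({onset_s!r}, {offset_s!r})"
            ) from None
        if not offset > onset:
            raise CsvRowError(
                f"{path}:{lineno}: offset_s {offset} must exceed onset_s {onset}"
            )
        parsed.append((tname, role, label, onset, offset))
        max_off = max(max_off, offset)

    if duration is None:
        duration = float(meta["duration_s"]) if "duration_s" in meta else max_off

    grouped: Dict[str, list] = {}
    roles: Dict[str, str] = {}
    for tname, role, label, onset, offset in parsed:
        grouped.setdefault(tname, []).append(LabeledInterval(onset, offset, label))
        roles[tname] = role
    tiers = {}
    for tname, ivs in grouped.items():
        declared_role = roles[tname] if roles[tname] in ("client", "therapist", "dyad") else None
        role, vocab = _resolve_tier(
            tname, tier_map, vocabs, participant=declared_role
        )
        ivs.sort(key=lambda iv: (iv.onset, iv.offset))
        tiers[tname] = Tier(tname, role, vocab, tuple(ivs), duration)
    return Session(pair_id, stage, duration, tiers)
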