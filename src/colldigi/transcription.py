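"""Verbatim label transcription: allocation, capture, completeness.

Transcription captures what the label says, not what it means: site and
collector strings are stored byte-for-byte as typed, matched case-sensitively
against the existing variant lists so each distinct string is keyed only
once, and interpretation is deferred to the normalisation stage.  The only
derived value is the calendar date range parsed from an *unambiguous*
verbatim date; anything else is flagged uncertain for later scrutiny.

Date grammar (common Lepidoptera label conventions):

* ``14.vi.1921`` or ``14.6.1921``  -> a single day,
* ``vi.1921`` / ``6.1921``        -> the whole month,
* ``1921``                          -> the whole year,
* dash ranges at any of those granularities (``14-16.vi.1921``,
  ``vi-vii.1921``, ``1921-1923``),
* two-digit years are refused (a wrongly assumed century is a known error
  source) and flag the record instead.
"""

from __future__ import annotations

import calendar
import re
from dataclasses import dataclass, field
from datetime import date

import pandas as pd

from .datastore import RoleError, Store, ValidationError

_ROMAN_MONTHS = {
    "i": 1, "ii": 2, "iii": 3, "iv": 4, "v": 5, "vi": 6,
    "vii": 7, "viii": 8, "ix": 9, "x": 10, "xi": 11, "xii": 12,
}


@dataclass
class TranscriptionInput:
    """One specimen's verbatim capture, exactly as typed."""

    site_verbatim: str | None = None
    date_verbatim: str | None = None
    collectors: list[str] = field(default_factory=list)
    registration: str | None = None
    type_status: str | None = None
    breeding_info: str | None = None
    uncertain_fields: set[str] = field(default_factory=set)
    escalate: str = "none"  # none | for_scrutiny | refer_to_admin

    def is_empty(self) -> bool:
        return not any(
            [
                self.site_verbatim,
                self.date_verbatim,
                self.collectors,
                self.registration,
                self.type_status,
                self.breeding_info,
            ]
        )


# ---------------------------------------------------------------------------
# Date parsing
# ---------------------------------------------------------------------------


def _month(tok: str) -> int | None:
    tok = tok.strip().lower()
    if tok in _ROMAN_MONTHS:
        return _ROMAN_MONTHS[tok]
    if tok.isdigit() and 1 <= int(tok) <= 12:
        return int(tok)
    return None


def _year(tok: str) -> int | None:
    tok = tok.strip()
    if re.fullmatch(r"\d{4}", tok):
        return int(tok)
    return None  # two-digit (or odd) years are ambiguous -> refused


def _month_span(year: int, month: int) -> tuple[date, date]:
    last = calendar.monthrange(year, month)[1]
    return date(year, month, 1), date(year, month, last)


def parse_verbatim_date(text: str) -> tuple[date, date] | None:
    """Parse a verbatim label date into a (start, end) range.

    Returns ``None`` when the string is ambiguous or unparseable; the caller
    flags the record rather than guessing.
    """
    s = text.strip()
    if not s:
        return None
    parts = [p.strip() for p in s.split(".")]
    try:
        if len(parts) == 3:  # day[.range].month[.range].year
            d_tok, m_tok, y_tok = parts
            y = _year(y_tok)
            if y is None:
                return None
            if "-" in m_tok:
                m1, m2 = (_month(t) for t in m_tok.split("-", 1))
                if None in (m1, m2) or m2 < m1 or "-" in d_tok:
                    return None
                return None  # day given with a month range is ambiguous
            m = _month(m_tok)
            if m is None:
                return None
            if "-" in d_tok:
                d1s, d2s = d_tok.split("-", 1)
                d1, d2 = int(d1s), int(d2s)
                if not (1 <= d1 <= d2):
                    return None
                return date(y, m, d1), date(y, m, d2)
            return date(y, m, int(d_tok)), date(y, m, int(d_tok))
        if len(parts) == 2:  # month[.range].year
            m_tok, y_tok = parts
            y = _year(y_tok)
            if y is None:
                return None
            if "-" in m_tok:
                m1, m2 = (_month(t) for t in m_tok.split("-", 1))
                if m1 is None or m2 is None or m2 < m1:
                    return None
                return _month_span(y, m1)[0], _month_span(y, m2)[1]
            m = _month(m_tok)
            if m is None:
                return None
            return _month_span(y, m)
        if len(parts) == 1:  # year or year range
            tok = parts[0]
            if "-" in tok:
                y1s, y2s = tok.split("-", 1)
                y1, y2 = _year(y1s), _year(y2s)
                if y1 is None or y2 is None or y2 < y1:
                    return None
                return date(y1, 1, 1), date(y2, 12, 31)
            y = _year(tok)
            if y is None:
                return None
            return date(y, 1, 1), date(y, 12, 31)
    except ValueError:
        return None
    return None


# ---------------------------------------------------------------------------
# Allocation and capture
# ---------------------------------------------------------------------------


def allocate_records(
    store: Store, manager: str, transcriber: str, specimen_ids: list[int]
) -> int:
    """Assign specimens to one transcriber's work queue.

    Reallocation is permitted and audited; the latest allocation wins.
    """
    store.require_role(manager, "data_manager")
    store.require_role(transcriber, "transcriber")
    uid = store.db.execute(
        "SELECT id FROM users WHERE name=?", (transcriber,)
    ).fetchone()["id"]
    n = 0
    for sid in specimen_ids:
        store.specimen(sid)  # existence check
        store.update_specimen(sid, assigned_to=uid)
        n += 1
    store.audit(manager, "allocate_records", f"{n} specimen(s) -> {transcriber}")
    return n


def visible_records(store: Store, user: str) -> list[int]:
    """Specimens a transcriber may open: their allocation plus past work."""
    row = store.db.execute("SELECT id FROM users WHERE name=?", (user,)).fetchone()
    if row is None:
        raise ValidationError(f"unknown user {user!r}")
    allocated = store.db.execute(
        "SELECT id FROM specimens WHERE assigned_to=?", (row["id"],)
    ).fetchall()
    past = store.db.execute(
        "SELECT DISTINCT detail FROM audit WHERE action='transcribe' AND user=?", (user,)
    ).fetchall()
    past_ids = {int(r["detail"].split()[1]) for r in past}
    return sorted({r["id"] for r in allocated} | past_ids)


def transcribe(
    store: Store, user: str, specimen_id: int, tinput: TranscriptionInput
) -> None:
    """Record one specimen's verbatim transcription.

    Site and collector strings are matched case-sensitively against the
    existing variants; a miss creates a new variant that is immediately
    visible to every transcriber.  The parsed date range is stored only when
    the verbatim string is unambiguous.
    """
    store.require_role(user, "transcriber")
    if specimen_id not in visible_records(store, user):
        raise RoleError(f"specimen {specimen_id} is not allocated to {user!r}")
    if tinput.escalate not in ("none", "for_scrutiny", "refer_to_admin"):
        raise ValidationError(f"bad escalation {tinput.escalate!r}")
    if tinput.is_empty():
        if tinput.escalate == "none":
            raise ValidationError("empty transcription with no escalation flag")
        store.add_flag(specimen_id, tinput.escalate)
        store.audit(user, "transcribe", f"specimen {specimen_id} escalated ({tinput.escalate})")
        return

    fields: dict = {}
    if tinput.site_verbatim is not None:
        fields["site_variant_id"] = store.ensure_variant("site", tinput.site_verbatim)
    if tinput.collectors:
        for c in tinput.collectors:
            store.ensure_variant("party", c)
        fields["collectors"] = ";".join(tinput.collectors)
    if tinput.date_verbatim is not None:
        fields["date_verbatim"] = tinput.date_verbatim
        rng = parse_verbatim_date(tinput.date_verbatim)
        if rng is None:
            store.add_flag(specimen_id, "uncertain:date")
        else:
            fields["date_start"] = rng[0].isoformat()
            fields["date_end"] = rng[1].isoformat()
    for name in ("registration", "type_status", "breeding_info"):
        val = getattr(tinput, name)
        if val is not None:
            fields[name] = val
    store.update_specimen(specimen_id, **fields)
    for f in tinput.uncertain_fields:
        store.add_flag(specimen_id, f"uncertain:{f}")
    if tinput.escalate != "none":
        store.add_flag(specimen_id, tinput.escalate)
    store.set_status(specimen_id, "transcribed", user=user)
    store.audit(user, "transcribe", f"specimen {specimen_id} transcribed")


def transcribe_batch(store: Store, user: str, csv_path) -> int:
    """Non-interactive transcription from a CSV keyed by barcode.

    Columns mirror :class:`TranscriptionInput` (``barcode, site_verbatim,
    date_verbatim, collectors, registration, type_status, breeding_info,
    uncertain_fields, escalate``); collectors and uncertain_fields are
    ``;``-separated.
    """
    df = pd.read_csv(csv_path, dtype=str).fillna("")
    n = 0
    for row in df.itertuples(index=False):
        spec = store.specimen_by_barcode(row.barcode)
        if spec is None:
            raise ValidationError(f"no specimen with barcode {row.barcode}")
        t = TranscriptionInput(
            site_verbatim=row.site_verbatim or None,
            date_verbatim=row.date_verbatim or None,
            collectors=[c for c in getattr(row, "collectors", "").split(";") if c],
            registration=getattr(row, "registration", "") or None,
            type_status=getattr(row, "type_status", "") or None,
            breeding_info=getattr(row, "breeding_info", "") or None,
            uncertain_fields={
                f for f in getattr(row, "uncertain_fields", "").split(";") if f
            },
            escalate=getattr(row, "escalate", "") or "none",
        )
        transcribe(store, user, spec["id"], t)
        n += 1
    return n


# ---------------------------------------------------------------------------
# Completeness reporting
# ---------------------------------------------------------------------------

CATEGORIES: list[tuple[str, frozenset[str]]] = [
    ("Site + Date + Collector", frozenset({"site", "date", "collector"})),
    ("Site + Date only", frozenset({"site", "date"})),
    ("Site + Collector only", frozenset({"site", "collector"})),
    ("Site only", frozenset({"site"})),
    ("Collector only", frozenset({"collector"})),
    ("Date only", frozenset({"date"})),
    ("Date + Collector only", frozenset({"date", "collector"})),
    ("None", frozenset()),
]


def _pct(count: int, total: int) -> int:
    from .analytics import round_half_up

    return int(round_half_up(100.0 * count / total, 0))


def completeness_table(counts: dict[str, int]) -> pd.DataFrame:
    """Percent breakdown of the eight site/date/collector presence classes.

    ``counts`` maps category label (as in :data:`CATEGORIES`) to record
    count; percents are rounded half-up to whole numbers of the grand total.
    """
    total = sum(counts.values())
    if total == 0:
        raise ValidationError("no records")
    rows = [
        {"category": name, "count": counts.get(name, 0), "percent": _pct(counts.get(name, 0), total)}
        for name, _ in CATEGORIES
    ]
    return pd.DataFrame(rows)


def completeness_categories(records) -> pd.DataFrame:
    """Classify finalized records by which of site/date/collector they carry.

    ``records`` is an iterable of objects (or mappings/sqlite rows) exposing
    ``site_variant_id``, ``date_verbatim`` and ``collectors``; each record
    falls in exactly one category, so the counts partition the total.
    """
    counts = {name: 0 for name, _ in CATEGORIES}
    n = 0
    for rec in records:
        present = set()
        if rec["site_variant_id"] is not None:
            present.add("site")
        if rec["date_verbatim"]:
            present.add("date")
        if rec["collectors"]:
            present.add("collector")
        for name, combo in CATEGORIES:
            if present == combo:
                counts[name] += 1
                break
        n += 1
    if n == 0:
        raise ValidationError("no records")
    return completeness_table(counts)
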