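"""Allocation visibility, verbatim capture, date grammar, completeness."""

from datetime import date
from itertools import product

import numpy as np
import pytest

from colldigi.datastore import RoleError, ValidationError
from colldigi.transcription import (
    CATEGORIES,
    TranscriptionInput,
    allocate_records,
    completeness_categories,
    completeness_table,
    parse_verbatim_date,
    transcribe,
    visible_records,
)
from tests.conftest import add_plain_specimen

# ---------------------------------------------------------------------------
# Date grammar: expected ranges derived by hand from the calendar
# ---------------------------------------------------------------------------

DATE_CASES = [
    ("14.vi.1921", (date(1921, 6, 14), date(1921, 6, 14))),
    ("14.6.1921", (date(1921, 6, 14), date(1921, 6, 14))),
    ("1.i.1900", (date(1900, 1, 1), date(1900, 1, 1))),
    ("vi.1921", (date(1921, 6, 1), date(1921, 6, 30))),
    ("ii.1920", (date(1920, 2, 1), date(1920, 2, 29))),  # leap year
    ("ii.1921", (date(1921, 2, 1), date(1921, 2, 28))),
    ("12.1921", (date(1921, 12, 1), date(1921, 12, 31))),
    ("1921", (date(1921, 1, 1), date(1921, 12, 31))),
    ("14-16.vi.1921", (date(1921, 6, 14), date(1921, 6, 16))),
    ("vi-vii.1921", (date(1921, 6, 1), date(1921, 7, 31))),
    ("1921-1923", (date(1921, 1, 1), date(1923, 12, 31))),
    (" vi.1921 ", (date(1921, 6, 1), date(1921, 6, 30))),
    # refused forms
    ("14.vi.21", None),  # two-digit year: century would be a guess
    ("6.21", None),
    ("31.ii.1921", None),  # impossible day
    ("xiii.1921", None),
    ("13.1921", None),  # 13 cannot be a month in month.year position
    ("16-14.vi.1921", None),  # inverted day range
    ("vii-vi.1921", None),
    ("1923-1921", None),
    ("no date", None),
    ("", None),
]


@pytest.mark.parametrize("text,expected", DATE_CASES)
def test_verbatim_date_grammar(text, expected):
    assert parse_verbatim_date(text) == expected


# ---------------------------------------------------------------------------
# Allocation and capture
# ---------------------------------------------------------------------------


def test_allocation_controls_visibility(store):
    store.add_user("tr2", {"transcriber"})
    ids = [add_plain_specimen(store, None) for _ in range(10)]
    assert allocate_records(store, "dm", "tr", ids) == 10
    assert visible_records(store, "tr") == sorted(ids)
    assert visible_records(store, "tr2") == []
    # reallocate half: partition moves with the latest allocation
    allocate_records(store, "dm", "tr2", ids[:5])
    assert visible_records(store, "tr") == sorted(ids[5:])
    assert visible_records(store, "tr2") == sorted(ids[:5])


def test_allocation_requires_roles(store):
    sid = add_plain_specimen(store, None)
    with pytest.raises(RoleError):
        allocate_records(store, "tr", "tr", [sid])  # caller not a manager
    with pytest.raises(RoleError):
        allocate_records(store, "dm", "geo", [sid])  # target not a transcriber


def test_transcriber_keeps_access_to_past_work(store):
    sid = add_plain_specimen(store, None)
    allocate_records(store, "dm", "tr", [sid])
    transcribe(store, "tr", sid, TranscriptionInput(site_verbatim="Reading"))
    store.add_user("tr2", {"transcriber"})
    allocate_records(store, "dm", "tr2", [sid])  # reallocated away
    assert sid in visible_records(store, "tr")  # still revisitable
    transcribe(store, "tr", sid, TranscriptionInput(site_verbatim="Reading, Berks"))


def test_site_variant_created_once_and_shared(store):
    a, b = (add_plain_specimen(store, None) for _ in range(2))
    allocate_records(store, "dm", "tr", [a, b])
    transcribe(store, "tr", a, TranscriptionInput(site_verbatim="Reading, Berks"))
    n_before = len(store.table("variants"))
    transcribe(store, "tr", b, TranscriptionInput(site_verbatim="Reading, Berks"))
    assert len(store.table("variants")) == n_before  # exact string reused
    va = store.specimen(a)["site_variant_id"]
    vb = store.specimen(b)["site_variant_id"]
    assert va == vb
    # case differs -> new variant (verbatim capture is case-sensitive)
    c = add_plain_specimen(store, None)
    allocate_records(store, "dm", "tr", [c])
    transcribe(store, "tr", c, TranscriptionInput(site_verbatim="reading, berks"))
    assert len(store.table("variants")) == n_before + 1


def test_verbatim_strings_stored_byte_identical(store):
    sid = add_plain_specimen(store, None)
    allocate_records(store, "dm", "tr", [sid])
    odd = "  Nr. Chobham,  Surrey "  # spacing preserved exactly
    transcribe(store, "tr", sid, TranscriptionInput(site_verbatim=odd))
    vid = store.specimen(sid)["site_variant_id"]
    row = store.db.execute("SELECT text FROM variants WHERE id=?", (vid,)).fetchone()
    assert row["text"] == odd


def test_escalation_without_fields_flags_without_advancing(store):
    sid = add_plain_specimen(store, None)
    allocate_records(store, "dm", "tr", [sid])
    transcribe(store, "tr", sid, TranscriptionInput(escalate="for_scrutiny"))
    spec = store.specimen(sid)
    assert spec["status"] == "imaged"
    assert "for_scrutiny" in store.specimen_flags(sid)


def test_empty_input_and_unallocated_user_rejected(store):
    sid = add_plain_specimen(store, None)
    allocate_records(store, "dm", "tr", [sid])
    with pytest.raises(ValidationError):
        transcribe(store, "tr", sid, TranscriptionInput())
    other = add_plain_specimen(store, None)
    with pytest.raises(RoleError):
        transcribe(store, "tr", other, TranscriptionInput(site_verbatim="X"))


def test_ambiguous_date_flags_uncertain(store):
    sid = add_plain_specimen(store, None)
    allocate_records(store, "dm", "tr", [sid])
    transcribe(
        store, "tr", sid,
        TranscriptionInput(site_verbatim="X", date_verbatim="14.vi.21"),
    )
    spec = store.specimen(sid)
    assert spec["date_verbatim"] == "14.vi.21"  # verbatim kept regardless
    assert spec["date_start"] is None
    assert "uncertain:date" in store.specimen_flags(sid)


# ---------------------------------------------------------------------------
# Completeness categories
# ---------------------------------------------------------------------------


def test_completeness_published_counts():
    counts = dict(
        zip(
            [name for name, _ in CATEGORIES],
            [100_798, 39_869, 16_942, 8_966, 3_968, 771, 688, 9_543],
        )
    )
    table = completeness_table(counts)
    assert table["count"].sum() == 181_545
    assert table["percent"].tolist() == [56, 22, 9, 5, 2, 0, 0, 5]


def test_single_full_record_is_100_percent(store):
    sid = add_plain_specimen(
        store, None, site="Reading", date_verbatim="1921", collectors=["A. Smith"]
    )
    table = completeness_categories([store.specimen(sid)])
    assert table.iloc[0]["percent"] == 100
    assert table["count"].sum() == 1


def test_completeness_against_triple_loop_oracle(store):
    rng = np.random.default_rng(17)
    records = []
    for _ in range(300):
        has_site, has_date, has_coll = rng.random(3) < [0.7, 0.6, 0.5]
        records.append(
            {
                "site_variant_id": 1 if has_site else None,
                "date_verbatim": "1921" if has_date else None,
                "collectors": "A" if has_coll else None,
            }
        )
    table = completeness_categories(records).set_index("category")
    # independent brute-force census over the 8 presence patterns
    for s, d, c in product([True, False], repeat=3):
        want = sum(
            (r["site_variant_id"] is not None) == s
            and (r["date_verbatim"] is not None) == d
            and (r["collectors"] is not None) == c
            for r in records
        )
        combo = {name for flag, name in [(s, "site"), (d, "date"), (c, "collector")] if flag}
        label = next(name for name, cset in CATEGORIES if cset == frozenset(combo))
        assert table.loc[label, "count"] == want
    assert table["count"].sum() == 300
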