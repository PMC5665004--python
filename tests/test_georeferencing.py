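"""Triage queue, georeference capture, and double-blind QA agreement."""

import math

import pytest

from colldigi.datastore import ConflictError, RoleError, ValidationError
from colldigi.georeferencing import (
    build_triage_queue,
    clear_ungeoreferenceable,
    haversine_m,
    mark_ungeoreferenceable,
    qa_agreement,
    set_georeference,
)
from colldigi.normalization import assign_variant
from tests.conftest import add_plain_specimen


def _site_with_specimens(store, master, n, variant=None):
    variant = variant or master
    for _ in range(n):
        add_plain_specimen(store, None, site=variant)
    assign_variant(store, "geo", "site", variant, master)


# ---------------------------------------------------------------------------
# Haversine against an independent spherical-law-of-cosines computation
# ---------------------------------------------------------------------------


def test_haversine_known_values():
    assert haversine_m(51.5, -0.1, 51.5, -0.1) == 0.0
    # one degree of latitude on the R=6371 km sphere
    assert haversine_m(0, 0, 1, 0) == pytest.approx(6371000 * math.pi / 180, rel=1e-9)
    # law-of-cosines cross-check for a mid-range pair (London - Reading)
    lat1, lon1, lat2, lon2 = 51.5074, -0.1278, 51.4543, -0.9781
    loc = 6371000 * math.acos(
        math.sin(math.radians(lat1)) * math.sin(math.radians(lat2))
        + math.cos(math.radians(lat1))
        * math.cos(math.radians(lat2))
        * math.cos(math.radians(lon2 - lon1))
    )
    assert haversine_m(lat1, lon1, lat2, lon2) == pytest.approx(loc, rel=1e-6)


# ---------------------------------------------------------------------------
# Triage
# ---------------------------------------------------------------------------


def test_threshold_boundary_and_partition(store):
    _site_with_specimens(store, "Aviemore", 8)
    _site_with_specimens(store, "Bath", 5)      # at threshold: high-frequency
    _site_with_specimens(store, "Neath", 4)     # just below: split pass, N-Z
    _site_with_specimens(store, "Chobham", 1)   # split pass, A-M
    q = build_triage_queue(store)
    hi = [e.master for e in q.stage_entries("high_frequency")]
    assert hi == ["Aviemore", "Bath"]  # descending count
    split = {e.master: e.partition for e in q.stage_entries("split_pass")}
    assert split == {"Neath": "N-Z", "Chobham": "A-M"}
    assert all(e.budget_minutes == 15 for e in q.stage_entries("split_pass"))
    assert q.coverage_fraction() == pytest.approx(13 / 18)


def test_m_n_letter_boundary(store):
    _site_with_specimens(store, "Malvern", 1)
    _site_with_specimens(store, "Norwich", 1)
    q = build_triage_queue(store)
    parts = {e.master: e.partition for e in q.entries}
    assert parts == {"Malvern": "A-M", "Norwich": "N-Z"}


def test_done_and_hopeless_sites_leave_queue(store):
    _site_with_specimens(store, "Bath", 6)
    _site_with_specimens(store, "York", 6)
    _site_with_specimens(store, "Lost Mill", 2)
    set_georeference(store, "geo", "Bath", 51.38, -2.36, 1000)
    mark_ungeoreferenceable(store, "geo", "Lost Mill", "not on any map")
    q = build_triage_queue(store)
    assert [e.master for e in q.entries] == ["York"]


def test_coverage_monotone_in_threshold(store):
    for name, n in [("A", 9), ("B", 7), ("C", 4), ("D", 2), ("E", 1)]:
        _site_with_specimens(store, name, n)
    fracs = [build_triage_queue(store, threshold=t).coverage_fraction()
             for t in (1, 3, 5, 8, 100)]
    assert fracs == sorted(fracs, reverse=True)
    assert fracs[0] == 1.0 and fracs[-1] == 0.0


# ---------------------------------------------------------------------------
# Capture
# ---------------------------------------------------------------------------


def test_georeference_advances_all_variant_specimens(store):
    _site_with_specimens(store, "Reading, Berks, UK", 3, variant="Reading")
    for _ in range(2):
        add_plain_specimen(store, None, site="Redding")
    assign_variant(store, "geo", "site", "Redding", "Reading, Berks, UK")
    n = set_georeference(store, "geo", "Reading, Berks, UK", 51.45, -0.97, 2000)
    assert n == 5
    statuses = store.table("specimens")["status"]
    assert (statuses == "georeferenced").sum() == 5


def test_georeference_validation(store):
    store.ensure_master("site", "X")
    with pytest.raises(ValidationError):
        set_georeference(store, "geo", "X", 91.0, 0.0, 100)
    with pytest.raises(ValidationError):
        set_georeference(store, "geo", "X", 0.0, 181.0, 100)
    with pytest.raises(ValidationError):
        set_georeference(store, "geo", "X", 0.0, 0.0, 0)
    with pytest.raises(ValidationError):
        set_georeference(store, "geo", "No Such Site", 0.0, 0.0, 100)


def test_regeoreference_keeps_history(store):
    store.ensure_master("site", "Bath")
    set_georeference(store, "geo", "Bath", 51.0, -2.0, 500)
    set_georeference(store, "geo", "Bath", 51.38, -2.36, 250)
    replaced = store.audit_entries("georeference_replaced")
    assert replaced and "51.0" in replaced[-1]["detail"]
    row = store.db.execute(
        "SELECT latitude, extent_m FROM masters WHERE name='Bath'"
    ).fetchone()
    assert (row["latitude"], row["extent_m"]) == (51.38, 250)


def test_ungeoreferenceable_lifecycle(store):
    store.ensure_master("site", "Lost Mill")
    mark_ungeoreferenceable(store, "geo", "Lost Mill", "ambiguous")
    with pytest.raises(ConflictError):
        set_georeference(store, "geo", "Lost Mill", 50.0, 0.0, 100)
    with pytest.raises(RoleError):
        clear_ungeoreferenceable(store, "geo", "Lost Mill")  # needs scrutineer
    clear_ungeoreferenceable(store, "scr", "Lost Mill")
    set_georeference(store, "geo", "Lost Mill", 50.0, 0.0, 100)
    # the reverse refusal: located sites cannot be flagged hopeless
    with pytest.raises(ConflictError):
        mark_ungeoreferenceable(store, "geo", "Lost Mill", "?")


# ---------------------------------------------------------------------------
# Double-blind QA
# ---------------------------------------------------------------------------


def _offset_east(lat, lon, metres):
    """Move ``metres`` east along the parallel (small-offset approximation)."""
    return lat, lon + metres / (6371000 * math.cos(math.radians(lat))) * 180 / math.pi


def test_qa_agreement_against_haversine_oracle():
    lat, lon = 51.0, -1.0
    near = _offset_east(lat, lon, 50.0)
    far = _offset_east(lat, lon, 5000.0)
    a = {"same": (lat, lon, 100.0), "near": (lat, lon, 100.0), "far": (lat, lon, 100.0)}
    b = {
        "same": (lat, lon, 100.0),
        "near": (*near, 100.0),
        "far": (*far, 100.0),
    }
    # default threshold = max extent (100 m): same and near agree, far does not
    assert qa_agreement(a, b, sample_n=100) == pytest.approx(2 / 3)
    # a tight 10 m threshold leaves only the identical point
    assert qa_agreement(a, b, sample_n=100, distance_threshold_m=10.0) == pytest.approx(1 / 3)
    # a generous 10 km threshold is still capped by extent-circle overlap
    assert qa_agreement(a, b, sample_n=100, distance_threshold_m=10_000.0) == pytest.approx(2 / 3)


def test_qa_agreement_symmetric_and_seeded():
    import numpy as np

    rng = np.random.default_rng(3)
    a, b = {}, {}
    for i in range(250):
        lat = float(rng.uniform(50, 55))
        lon = float(rng.uniform(-5, 1))
        a[f"s{i}"] = (lat, lon, 200.0)
        jitter = float(rng.uniform(0, 400))
        b[f"s{i}"] = (*_offset_east(lat, lon, jitter), 200.0)
    r1 = qa_agreement(a, b, sample_n=100, seed=9)
    r2 = qa_agreement(b, a, sample_n=100, seed=9)
    assert r1 == r2  # symmetric
    assert qa_agreement(a, b, sample_n=100, seed=9) == r1  # reproducible
    assert 0.0 < r1 < 1.0  # the jitter distribution straddles the threshold


def test_qa_agreement_no_common_sites():
    with pytest.raises(ValidationError):
        qa_agreement({"a": (0, 0, 1)}, {"b": (0, 0, 1)})
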