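"""CMS export ordering, IRN round trip, embargo soundness, archival."""

import numpy as np
import pandas as pd
import pytest

from colldigi.datastore import ConflictError
from colldigi.georeferencing import set_georeference
from colldigi.ingest import (
    DEPENDENCIES,
    ENTITY_TYPES,
    IngestOrderError,
    MockCMS,
    archive_project,
    export_new_entities,
    import_irns,
    order_is_valid,
    publish_occurrences,
    replace_existing_specimens,
    run_full_export,
    taxon_rule,
    year_from_rule,
)
from colldigi.normalization import assign_variant
from tests.conftest import add_plain_specimen


def _populate(store, n=4):
    """A few fully-worked specimens: sited, dated, collected, georeferenced."""
    sids = []
    for i in range(n):
        code = store.allocate_barcodes("dm", 1)[0]
        sid = add_plain_specimen(
            store,
            code,
            drawer=f"Drawer{i % 2 + 1:02d}",
            taxon="Pieris brassicae",
            site="Reading" if i % 2 == 0 else "Box Hill",
            date_verbatim="vi.1921",
            collectors=["A. Smith"],
        )
        store.update_specimen(sid, date_start="1921-06-01", date_end="1921-06-30")
        sids.append(sid)
    assign_variant(store, "geo", "site", "Reading", "Reading, Berks, UK")
    assign_variant(store, "geo", "site", "Box Hill", "Box Hill, Surrey, UK")
    assign_variant(store, "scr", "taxon", "Pieris brassicae", "Pieris brassicae")
    set_georeference(store, "geo", "Reading, Berks, UK", 51.45, -0.97, 2000)
    set_georeference(store, "geo", "Box Hill, Surrey, UK", 51.25, -0.32, 1000)
    return sids


def _cms_for(store):
    cms = MockCMS()
    drawers = pd.read_sql_query("SELECT DISTINCT drawer FROM specimens", store.db)
    cms.register_existing("locations", drawers["drawer"].tolist())
    return cms


# ---------------------------------------------------------------------------
# Ordering
# ---------------------------------------------------------------------------


def test_order_validity_matches_set_based_oracle():
    """order_is_valid agrees with a direct dependency check on random
    permutations of the entity types."""
    rng = np.random.default_rng(13)
    types = list(ENTITY_TYPES)
    perms = {tuple(types)}
    while len(perms) < 60:
        perms.add(tuple(rng.permutation(types)))
    for perm in perms:
        seen, ok = set(), True
        for t in perm:
            ok = ok and set(DEPENDENCIES[t]) <= seen
            seen.add(t)
        assert order_is_valid(list(perm)) == ok
    # declared export order is itself valid; a missing type is not
    assert order_is_valid(list(ENTITY_TYPES))
    assert not order_is_valid(list(ENTITY_TYPES[:-1]))


def test_premature_export_names_blockers(store):
    _populate(store)
    with pytest.raises(IngestOrderError) as exc:
        export_new_entities(store, "catalogue")
    assert "sites" in exc.value.blocking
    with pytest.raises(IngestOrderError) as exc2:
        export_new_entities(store, "collection_events")
    assert set(exc2.value.blocking) <= {"sites", "parties"}


# ---------------------------------------------------------------------------
# Round trip
# ---------------------------------------------------------------------------


def test_full_round_trip_links_everything(store):
    sids = _populate(store)
    cms = _cms_for(store)
    counts = run_full_export(store, cms)
    assert counts["catalogue"] == len(sids)
    assert counts["sites"] == 2 and counts["taxonomy"] == 1
    for sid in sids:
        spec = store.specimen(sid)
        assert spec["cms_irn"] is not None
        assert spec["event_irn"] is not None
        assert spec["status"] == "exported"
    # nothing left to export anywhere
    for t in ENTITY_TYPES:
        assert len(export_new_entities(store, t)) == 0


def test_import_rejects_unknown_and_duplicate_rows(store):
    _populate(store)
    export = export_new_entities(store, "sites")
    lid = export.iloc[0]["local_id"]
    pairs = pd.DataFrame(
        [
            (lid, "sit-1"),
            ("sites:99999", "sit-2"),  # unknown local id
            (export.iloc[1]["local_id"], "sit-1"),  # duplicate irn
        ],
        columns=["local_id", "irn"],
    )
    assert import_irns(store, "sites", pairs) == 1
    rejected = store.audit_entries("import_irns_rejected")
    assert len(rejected) == 2
    # idempotent: importing the accepted pair again links nothing
    assert import_irns(store, "sites", pairs.iloc[:1]) == 0


def test_match_or_create_deduplicates_on_remote(store):
    """Three local taxon variants assigned to one master export one row, and
    a taxon the CMS already knows is matched, not recreated."""
    for v in ("P. brassicae", "Pieris brassicae", "Pieris brassicae L."):
        add_plain_specimen(store, None, taxon=v)
        assign_variant(store, "scr", "taxon", v, "Pieris brassicae")
    export = export_new_entities(store, "taxonomy")
    assert len(export) == 1
    cms = MockCMS()
    cms.register_existing("taxonomy", ["Pieris brassicae"])
    returned = cms.ingest("taxonomy", export)
    assert returned.iloc[0]["irn"] == "tax-1"  # the pre-registered IRN


def test_match_existing_locations_only(store):
    _populate(store)
    cms = MockCMS()
    cms.register_existing("locations", ["Drawer01"])  # Drawer02 unknown remotely
    export = export_new_entities(store, "locations")
    returned = cms.ingest("locations", export)
    assert set(returned["local_id"]) == {"locations:Drawer01"}


def test_collectors_exported_verbatim(store):
    add_plain_specimen(store, None, collectors=["A. Smith", "E. B. Ford"])
    export = export_new_entities(store, "parties")
    assert sorted(export["name"]) == ["A. Smith", "E. B. Ford"]


# ---------------------------------------------------------------------------
# Replacement of pre-databased records
# ---------------------------------------------------------------------------


def test_replace_existing_specimens(store):
    tv = store.ensure_variant("taxon", "Aus bus")
    store.create_specimen(None, "Drawer01", tv,
                          registration="1923.44.12", pre_databased=True)
    keep = store.create_specimen(None, "Drawer01", tv,
                                 registration="1923.44.12")  # not pre-databased
    assert replace_existing_specimens(store, "dm", ["1923.44.12", "no.such"]) == 1
    remaining = store.table("specimens")["id"].tolist()
    assert remaining == [keep]


# ---------------------------------------------------------------------------
# Embargo and publication
# ---------------------------------------------------------------------------


def test_publish_requires_export_and_is_sound(store):
    sids = _populate(store)
    assert len(publish_occurrences(store)) == 0  # nothing exported yet
    run_full_export(store, _cms_for(store))
    df = publish_occurrences(store)
    assert len(df) == len(sids)
    assert list(df.columns)[0] == "occurrenceID"
    # verbatim and standardised localities both survive publication intact
    assert set(df["verbatimLocality"]) == {"Reading", "Box Hill"}
    assert set(df["locality"]) == {"Reading, Berks, UK", "Box Hill, Surrey, UK"}
    assert (df["eventDate"] == "1921-06-01/1921-06-30").all()
    assert (df["recordedBy"] == "A. Smith").all()


def test_embargo_partition_is_exact(store):
    _populate(store, n=4)
    late = add_plain_specimen(store, store.allocate_barcodes("dm", 1)[0],
                              taxon="Pieris brassicae", site="Reading")
    store.update_specimen(late, date_start="1960-05-01", date_end="1960-05-01")
    run_full_export(store, _cms_for(store))
    full = publish_occurrences(store)
    held = publish_occurrences(store, [year_from_rule(1950)])
    assert len(full) == 5
    assert len(held) == 4
    assert store.specimen(late)["status"] == "exported"  # withheld, not deleted
    # published ∪ withheld == exported, and no withheld row leaks
    late_code = store.specimen(late)["barcode"]
    assert late_code in set(full["occurrenceID"])
    assert late_code not in set(held["occurrenceID"])


def test_taxon_embargo(store):
    _populate(store)
    run_full_export(store, _cms_for(store))
    held = publish_occurrences(store, [taxon_rule({"Pieris brassicae"})])
    assert len(held) == 0


# ---------------------------------------------------------------------------
# Archival
# ---------------------------------------------------------------------------


def test_archive_refuses_unexported_then_freezes(store, tmp_path):
    sids = _populate(store)
    with pytest.raises(ConflictError):
        archive_project(store, tmp_path / "bundle")
    run_full_export(store, _cms_for(store))
    bundle = archive_project(store, tmp_path / "bundle")
    assert (bundle / "specimens.csv").is_file()
    assert (bundle / "irns.csv").is_file()
    spec_csv = pd.read_csv(bundle / "specimens.csv")
    assert len(spec_csv) == len(sids)
    with pytest.raises(ConflictError):
        add_plain_specimen(store, None)  # frozen
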