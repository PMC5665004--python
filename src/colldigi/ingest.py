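"""Dependency-ordered export to a collection management system (CMS).

The CMS references records across modules by IRN (Internal Record Number),
so a record must exist -- and have its IRN known locally -- before anything
referencing it can be exported.  The implemented reference graph is::

    catalogue -> taxonomy, sites, collection_events, parties, multimedia, locations
    collection_events -> sites, parties

The round trip is CSV-mediated, as in production: each entity type exports a
CSV of records lacking an IRN (carrying a stable local id), the CMS ingests
it and returns (local_id, IRN) pairs which are imported back.  Per-type
policies control duplication: catalogue, multimedia, collection events and
sites are always created new; taxonomy and parties are matched to existing
CMS records by exact name or created; locations (drawers) are only matched
to the pre-registered set.  :class:`MockCMS` emulates the remote side with
sequential IRNs so the whole round trip is testable offline.

After ingest, embargo rules withhold selected specimens, and the remainder
is published as a Darwin Core occurrence table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import pandas as pd

from .datastore import ConflictError, Store, ValidationError

ENTITY_TYPES = (
    "multimedia",
    "parties",
    "taxonomy",
    "sites",
    "collection_events",
    "locations",
    "catalogue",
)

DEPENDENCIES: dict[str, tuple[str, ...]] = {
    "multimedia": (),
    "parties": (),
    "taxonomy": (),
    "sites": (),
    "locations": (),
    "collection_events": ("sites", "parties"),
    "catalogue": (
        "taxonomy",
        "sites",
        "collection_events",
        "parties",
        "multimedia",
        "locations",
    ),
}

POLICIES: dict[str, str] = {
    "catalogue": "create_new",
    "multimedia": "create_new",
    "collection_events": "create_new",
    "sites": "create_new",
    "taxonomy": "match_or_create",
    "parties": "match_or_create",
    "locations": "match_existing",
}


class IngestOrderError(ConflictError):
    """Export attempted before a prerequisite type has its IRNs."""

    def __init__(self, entity_type: str, blocking: list[str]):
        self.blocking = blocking
        super().__init__(
            f"cannot export {entity_type!r}: waiting on IRNs for {', '.join(blocking)}"
        )


def order_is_valid(order: list[str]) -> bool:
    """True iff every type appears after all types it references."""
    seen: set[str] = set()
    for t in order:
        if any(dep not in seen for dep in DEPENDENCIES[t]):
            return False
        seen.add(t)
    return set(order) == set(ENTITY_TYPES)


# ---------------------------------------------------------------------------
# Local entity framing: rows per type, with stable local ids
# ---------------------------------------------------------------------------


def _entity_frame(store: Store, entity_type: str) -> pd.DataFrame:
    """All local records of a type as (local_id, name/other columns, irn)."""
    db = store.db
    if entity_type == "multimedia":
        df = pd.read_sql_query("SELECT id, path, role, cms_irn FROM images", db)
        df["local_id"] = "multimedia:" + df["id"].astype(str)
        return df
    if entity_type in ("taxonomy", "sites", "parties"):
        kind = {"taxonomy": "taxon", "sites": "site", "parties": "party"}[entity_type]
        if entity_type == "parties":
            # collectors are exported verbatim (never augmented); masters when
            # assigned, raw variants otherwise
            df = pd.read_sql_query(
                "SELECT v.id, COALESCE(m.name, v.text) AS name, "
                " COALESCE(m.cms_irn, v.id * 0) AS _x, m.cms_irn AS cms_irn"
                " FROM variants v LEFT JOIN masters m ON v.master_id = m.id"
                " WHERE v.kind='party'",
                db,
            )
            # deduplicate by name; carry irn if any duplicate has one
            df = (
                df.sort_values("id")
                .groupby("name", as_index=False)
                .agg(id=("id", "min"), cms_irn=("cms_irn", "first"))
            )
            df["local_id"] = "parties:" + df["id"].astype(str)
            return df[["local_id", "id", "name", "cms_irn"]]
        df = pd.read_sql_query(
            "SELECT id, name, cms_irn FROM masters WHERE kind=?", db, params=(kind,)
        )
        df["local_id"] = f"{entity_type}:" + df["id"].astype(str)
        return df
    if entity_type == "locations":
        df = pd.read_sql_query(
            "SELECT DISTINCT drawer FROM specimens WHERE drawer IS NOT NULL", db
        )
        df["local_id"] = "locations:" + df["drawer"]
        irns = _irn_map(store, "locations")
        df["cms_irn"] = df["local_id"].map(irns)
        return df
    if entity_type == "collection_events":
        # one event per specimen: the (site, date, collector) tuple of its capture
        df = pd.read_sql_query(
            "SELECT s.id, s.date_verbatim, s.collectors, s.event_irn AS cms_irn,"
            " sv.text AS site_verbatim"
            " FROM specimens s LEFT JOIN variants sv ON s.site_variant_id = sv.id",
            db,
        )
        df["local_id"] = "collection_events:" + df["id"].astype(str)
        return df
    if entity_type == "catalogue":
        df = pd.read_sql_query("SELECT id, barcode, cms_irn FROM specimens", db)
        df["local_id"] = "catalogue:" + df["id"].astype(str)
        return df
    raise ValidationError(f"unknown entity type {entity_type!r}")


def _irn_map(store: Store, entity_type: str) -> dict[str, str]:
    rows = store.db.execute(
        "SELECT local_id, irn FROM irns WHERE entity_type=?", (entity_type,)
    ).fetchall()
    return {r["local_id"]: r["irn"] for r in rows}


def _ensure_irn_table(store: Store) -> None:
    store.db.execute(
        "CREATE TABLE IF NOT EXISTS irns ("
        " entity_type TEXT NOT NULL, local_id TEXT NOT NULL, irn TEXT NOT NULL,"
        " UNIQUE (entity_type, local_id), UNIQUE (entity_type, irn))"
    )
    store.db.commit()


def _missing_irns(store: Store, entity_type: str) -> pd.DataFrame:
    df = _entity_frame(store, entity_type)
    irns = _irn_map(store, entity_type)
    if "cms_irn" not in df:
        df["cms_irn"] = pd.NA
    # a record counts as linked if either its stored IRN column or the
    # round-trip ledger carries one (pre-matched records arrive via the
    # stored column)
    linked = df["cms_irn"].notna() | df["local_id"].map(irns).notna()
    return df[~linked]


def export_new_entities(
    store: Store, entity_type: str, path: str | Path | None = None
) -> pd.DataFrame:
    """CSV of this type's records that still lack an IRN.

    Refused (naming the blockers) while any prerequisite type has records
    without IRNs -- the CMS cannot ingest a record whose references do not
    resolve yet.
    """
    if entity_type not in ENTITY_TYPES:
        raise ValidationError(f"unknown entity type {entity_type!r}")
    _ensure_irn_table(store)
    blocking = [
        dep for dep in DEPENDENCIES[entity_type] if len(_missing_irns(store, dep)) > 0
    ]
    if blocking:
        raise IngestOrderError(entity_type, blocking)
    out = _missing_irns(store, entity_type).drop(columns=["cms_irn"], errors="ignore")
    if path is not None:
        out.to_csv(path, index=False, encoding="utf-8")
    return out.reset_index(drop=True)


def import_irns(store: Store, entity_type: str, pairs: pd.DataFrame | list[tuple[str, str]]) -> int:
    """Link returned (local_id, irn) pairs back to the local records.

    Unknown local ids and duplicate IRNs are rejected row by row (logged in
    the audit trail); re-importing the same file links nothing new.
    """
    _ensure_irn_table(store)
    if not isinstance(pairs, pd.DataFrame):
        pairs = pd.DataFrame(pairs, columns=["local_id", "irn"])
    frame = _entity_frame(store, entity_type)
    known = set(frame["local_id"])
    existing = _irn_map(store, entity_type)
    used_irns = set(existing.values())
    n = 0
    for row in pairs.itertuples(index=False):
        lid, irn = str(row.local_id), str(row.irn)
        if lid not in known:
            store.audit("SYSTEM", "import_irns_rejected", f"{entity_type}: unknown id {lid}")
            continue
        if lid in existing:
            continue  # idempotent re-import
        if irn in used_irns:
            store.audit("SYSTEM", "import_irns_rejected", f"{entity_type}: duplicate irn {irn}")
            continue
        store.db.execute(
            "INSERT INTO irns (entity_type, local_id, irn) VALUES (?,?,?)",
            (entity_type, lid, irn),
        )
        existing[lid] = irn
        used_irns.add(irn)
        n += 1
    store.db.commit()
    _write_back_irns(store, entity_type)
    return n


def _write_back_irns(store: Store, entity_type: str) -> None:
    irns = _irn_map(store, entity_type)
    db = store.db
    for lid, irn in irns.items():
        raw = lid.split(":", 1)[1]
        if entity_type == "multimedia":
            db.execute("UPDATE images SET cms_irn=? WHERE id=?", (irn, int(raw)))
        elif entity_type in ("taxonomy", "sites"):
            db.execute("UPDATE masters SET cms_irn=? WHERE id=?", (irn, int(raw)))
        elif entity_type == "parties":
            row = db.execute("SELECT master_id FROM variants WHERE id=?", (int(raw),)).fetchone()
            if row and row["master_id"]:
                db.execute("UPDATE masters SET cms_irn=? WHERE id=?", (irn, row["master_id"]))
        elif entity_type == "collection_events":
            db.execute("UPDATE specimens SET event_irn=? WHERE id=?", (irn, int(raw)))
        elif entity_type == "catalogue":
            db.execute("UPDATE specimens SET cms_irn=? WHERE id=?", (irn, int(raw)))
        # locations IRNs live only in the irns table
    db.commit()


class MockCMS:
    """Offline stand-in for the remote CMS side of the CSV round trip.

    Assigns sequential IRNs per entity type; honours the per-type policy:
    ``match_or_create`` types are matched by exact name against records the
    mock already knows, ``match_existing`` types must match (unmatched rows
    get no IRN), ``create_new`` types always get fresh IRNs.
    """

    def __init__(self):
        self._counters: dict[str, int] = {t: 0 for t in ENTITY_TYPES}
        self._known: dict[str, dict[str, str]] = {t: {} for t in ENTITY_TYPES}

    def register_existing(self, entity_type: str, names: list[str]) -> None:
        """Pre-populate the remote side (e.g. the drawer location set)."""
        for name in names:
            if name not in self._known[entity_type]:
                self._counters[entity_type] += 1
                self._known[entity_type][name] = f"{entity_type[:3]}-{self._counters[entity_type]}"

    def _fresh(self, entity_type: str) -> str:
        self._counters[entity_type] += 1
        return f"{entity_type[:3]}-{self._counters[entity_type]}"

    def ingest(self, entity_type: str, export: pd.DataFrame) -> pd.DataFrame:
        policy = POLICIES[entity_type]
        out = []
        for row in export.itertuples(index=False):
            name = getattr(row, "name", None) or getattr(row, "drawer", None)
            if policy == "create_new":
                irn = self._fresh(entity_type)
                if name is not None:
                    self._known[entity_type].setdefault(str(name), irn)
            elif policy == "match_or_create":
                irn = self._known[entity_type].get(str(name))
                if irn is None:
                    irn = self._fresh(entity_type)
                    self._known[entity_type][str(name)] = irn
            else:  # match_existing
                irn = self._known[entity_type].get(str(name))
                if irn is None:
                    continue  # no match: row comes back without an IRN
            out.append({"local_id": row.local_id, "irn": irn})
        return pd.DataFrame(out, columns=["local_id", "irn"])


def run_full_export(store: Store, cms: MockCMS) -> dict[str, int]:
    """Drive the complete dependency-ordered round trip; returns link counts."""
    counts = {}
    for t in ENTITY_TYPES:  # ENTITY_TYPES is a valid topological order
        export = export_new_entities(store, t)
        returned = cms.ingest(t, export)
        counts[t] = import_irns(store, t, returned)
    for spec in store.all_specimens():
        if spec["cms_irn"] is not None and spec["status"] != "exported":
            store.set_status(spec["id"], "exported")
    return counts


def replace_existing_specimens(store: Store, user: str, registrations: list[str]) -> int:
    """Delete pre-existing CMS specimen records slated for replacement.

    Matching is by registration string; the deletions are audited.  A list
    that matches nothing is a warning, not an error.
    """
    store.require_role(user, "data_manager")
    n = 0
    for reg in registrations:
        rows = store.db.execute(
            "SELECT id FROM specimens WHERE registration=? AND pre_databased=1", (reg,)
        ).fetchall()
        for r in rows:
            store.db.execute("DELETE FROM images WHERE specimen_id=?", (r["id"],))
            store.db.execute("DELETE FROM processed WHERE specimen_id=?", (r["id"],))
            store.db.execute("DELETE FROM specimens WHERE id=?", (r["id"],))
            n += 1
    store.db.commit()
    store.audit(user, "replace_existing_specimens", f"{n} deleted of {len(registrations)} listed")
    return n


# ---------------------------------------------------------------------------
# Embargo and publication
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EmbargoRule:
    """Withhold specimens matching ``predicate`` from publication."""

    name: str
    predicate: Callable[[dict], bool]


def year_from_rule(cutoff: int) -> EmbargoRule:
    """Withhold specimens collected in or after ``cutoff``."""

    def pred(rec: dict) -> bool:
        ds = rec.get("date_start")
        return bool(ds) and int(str(ds)[:4]) >= cutoff

    return EmbargoRule(f"year >= {cutoff}", pred)


def taxon_rule(names: set[str]) -> EmbargoRule:
    """Withhold flagged (e.g. sensitive) taxa."""
    return EmbargoRule(
        f"taxa {sorted(names)}", lambda rec: rec.get("scientificName") in names
    )


DWC_COLUMNS = [
    "occurrenceID",
    "scientificName",
    "verbatimLocality",
    "locality",
    "decimalLatitude",
    "decimalLongitude",
    "coordinateUncertaintyInMeters",
    "eventDate",
    "recordedBy",
]


def publish_occurrences(
    store: Store, embargo_rules: list[EmbargoRule] | None = None
) -> pd.DataFrame:
    """Darwin Core occurrence table of all exported, non-embargoed specimens.

    One row per specimen: the barcode as occurrenceID, the taxon master (or
    verbatim taxon) as scientificName, the verbatim label string and the
    standardised site master, the point-radius georeference, and the event
    date range.  Withheld records stay in the store but appear in no output.
    """
    q = """
        SELECT s.id, s.barcode, s.collectors, s.date_start, s.date_end,
               tv.text AS taxon_verbatim, tm.name AS taxon_master,
               sv.text AS site_verbatim, sm.name AS site_master,
               sm.latitude, sm.longitude, sm.extent_m,
               s.cms_irn
        FROM specimens s
        LEFT JOIN variants tv ON s.taxon_variant_id = tv.id
        LEFT JOIN masters tm ON tv.master_id = tm.id
        LEFT JOIN variants sv ON s.site_variant_id = sv.id
        LEFT JOIN masters sm ON sv.master_id = sm.id
        WHERE s.cms_irn IS NOT NULL
    """
    rows = store.db.execute(q).fetchall()
    out = []
    rules = embargo_rules or []
    for r in rows:
        rec = {
            "occurrenceID": r["barcode"],
            "scientificName": r["taxon_master"] or r["taxon_verbatim"],
            "verbatimLocality": r["site_verbatim"],
            "locality": r["site_master"],
            "decimalLatitude": r["latitude"],
            "decimalLongitude": r["longitude"],
            "coordinateUncertaintyInMeters": r["extent_m"],
            "eventDate": _event_date(r["date_start"], r["date_end"]),
            "recordedBy": (r["collectors"] or "").replace(";", " | ") or None,
            "date_start": r["date_start"],
        }
        if any(rule.predicate(rec) for rule in rules):
            continue
        del rec["date_start"]
        out.append(rec)
    return pd.DataFrame(out, columns=DWC_COLUMNS)


def _event_date(start: str | None, end: str | None) -> str | None:
    if not start:
        return None
    if end and end != start:
        return f"{start}/{end}"
    return start


def archive_project(store: Store, bundle_dir: str | Path) -> Path:
    """Bundle every table as CSV and freeze the store read-only.

    Refused while any specimen remains unexported.  The bundle directory can
    be diffed table-by-table against a re-opened store.
    """
    unexported = [s["id"] for s in store.all_specimens() if s["status"] != "exported"]
    if unexported:
        raise ConflictError(f"{len(unexported)} specimen(s) not yet exported")
    bundle = Path(bundle_dir)
    bundle.mkdir(parents=True, exist_ok=True)
    for table in Store.TABLES:
        store.export_table(table, bundle / f"{table}.csv")
    _ensure_irn_table(store)
    pd.read_sql_query("SELECT * FROM irns", store.db).to_csv(
        bundle / "irns.csv", index=False, encoding="utf-8"
    )
    store.mark_readonly()
    return bundle
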