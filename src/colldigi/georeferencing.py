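"""Georeferencing triage, point-and-extent capture, and double-blind QA.

Georeferencing works against site *masters*, never variants, so each
physical place is located once.  Work is triaged by payoff: masters with at
least five specimens are done first (in real collections this covers most
of the holdings), the remainder is split alphabetically A-M / N-Z between
two georeferencers with an advisory 15-minute budget per site, then expert
and final-check passes mop up.  Sites that cannot be located are marked
un-georeferenceable and drop out of the queue.  Quality is assessed by
re-georeferencing a random sample of sites independently and measuring
agreement between the two sets of points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timezone

import numpy as np

from .config import EARTH_RADIUS_M, SPLIT_PASS_MINUTES, TRIAGE_THRESHOLD
from .datastore import ConflictError, Store, ValidationError
from .normalization import specimens_per_master

STAGES = ("high_frequency", "split_pass", "expert_pass", "final_check", "export")


def haversine_m(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in metres (spherical Earth, R = 6371 km)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_M * math.asin(math.sqrt(a))


@dataclass(frozen=True)
class QueueEntry:
    master: str
    specimen_count: int
    stage: str
    partition: str  # 'A-M', 'N-Z' or 'none'
    budget_minutes: int | None = None  # advisory only


@dataclass
class TriageQueue:
    threshold: int
    entries: list[QueueEntry] = field(default_factory=list)

    def stage_entries(self, stage: str) -> list[QueueEntry]:
        return [e for e in self.entries if e.stage == stage]

    def coverage_fraction(self) -> float:
        """Fraction of sited specimens covered by the high-frequency stage."""
        total = sum(e.specimen_count for e in self.entries)
        if total == 0:
            return 0.0
        hi = sum(e.specimen_count for e in self.entries if e.stage == "high_frequency")
        return hi / total


def build_triage_queue(store: Store, threshold: int = TRIAGE_THRESHOLD) -> TriageQueue:
    """Order site masters for georeferencing by expected payoff.

    Masters at or above ``threshold`` specimens form the high-frequency
    stage, ordered by descending count (ties by name); the rest go to the
    split pass, partitioned by first letter into A-M and N-Z.  Masters
    already georeferenced or marked un-georeferenceable are excluded.
    """
    per_master = specimens_per_master(store, "site")
    done = {
        r["name"]
        for r in store.db.execute(
            "SELECT name FROM masters WHERE kind='site'"
            " AND (ungeoreferenceable=1 OR latitude IS NOT NULL)"
        ).fetchall()
    }
    items = sorted(per_master.items(), key=lambda kv: (-kv[1], kv[0]))
    q = TriageQueue(threshold=threshold)
    for name, count in items:
        if name in done:
            continue
        if count >= threshold:
            q.entries.append(QueueEntry(name, int(count), "high_frequency", "none"))
        else:
            first = name.lstrip()[:1].upper()
            part = "A-M" if first and first <= "M" else "N-Z"
            q.entries.append(
                QueueEntry(name, int(count), "split_pass", part, SPLIT_PASS_MINUTES)
            )
    return q


def set_georeference(
    store: Store,
    user: str,
    master_name: str,
    lat: float,
    lon: float,
    extent_m: float,
    method: str = "",
) -> int:
    """Attach a point + extent to a site master.

    All specimens of all the master's variants become georeferenced (their
    workflow status advances).  Re-georeferencing keeps the previous value
    in the audit history.
    """
    store.require_role(user, "georeferencer")
    if not (-90.0 <= lat <= 90.0):
        raise ValidationError(f"latitude {lat} out of range")
    if not (-180.0 <= lon <= 180.0):
        raise ValidationError(f"longitude {lon} out of range")
    if extent_m <= 0:
        raise ValidationError("extent must be positive")
    row = store.db.execute(
        "SELECT * FROM masters WHERE kind='site' AND name=?", (master_name,)
    ).fetchone()
    if row is None:
        raise ValidationError(f"no site master {master_name!r}")
    if row["ungeoreferenceable"]:
        raise ConflictError(f"{master_name!r} is marked un-georeferenceable")
    if row["latitude"] is not None:
        store.audit(
            user,
            "georeference_replaced",
            f"{master_name}: ({row['latitude']}, {row['longitude']}, {row['extent_m']})",
        )
    store.db.execute(
        "UPDATE masters SET latitude=?, longitude=?, extent_m=?, georef_method=?,"
        " georef_by=?, georef_ts=? WHERE id=?",
        (
            lat,
            lon,
            extent_m,
            method,
            user,
            datetime.now(timezone.utc).isoformat(timespec="seconds"),
            row["id"],
        ),
    )
    store.db.commit()
    store.audit(user, "georeference", f"{master_name}: ({lat}, {lon}, {extent_m})")
    # advance every linked specimen
    n = 0
    specs = store.db.execute(
        "SELECT s.id, s.status FROM specimens s JOIN variants v ON s.site_variant_id=v.id"
        " WHERE v.kind='site' AND v.master_id=?",
        (row["id"],),
    ).fetchall()
    for s in specs:
        if s["status"] in ("imaged", "transcribed", "normalized"):
            store.set_status(s["id"], "georeferenced", user=user)
        n += 1
    return n


def mark_ungeoreferenceable(store: Store, user: str, master_name: str, note: str) -> None:
    """Flag a site master nobody could locate; it leaves the triage queue.

    Un-flagging requires a scrutineer override (:func:`clear_ungeoreferenceable`).
    """
    store.require_role(user, "georeferencer")
    row = store.db.execute(
        "SELECT * FROM masters WHERE kind='site' AND name=?", (master_name,)
    ).fetchone()
    if row is None:
        raise ValidationError(f"no site master {master_name!r}")
    if row["latitude"] is not None:
        raise ConflictError(f"{master_name!r} already has a georeference")
    store.db.execute(
        "UPDATE masters SET ungeoreferenceable=1, note=? WHERE id=?", (note, row["id"])
    )
    store.db.commit()
    store.audit(user, "mark_ungeoreferenceable", f"{master_name}: {note}")


def clear_ungeoreferenceable(store: Store, user: str, master_name: str) -> None:
    store.require_role(user, "scrutineer")
    row = store.db.execute(
        "SELECT id FROM masters WHERE kind='site' AND name=?", (master_name,)
    ).fetchone()
    if row is None:
        raise ValidationError(f"no site master {master_name!r}")
    store.db.execute("UPDATE masters SET ungeoreferenceable=0 WHERE id=?", (row["id"],))
    store.db.commit()
    store.audit(user, "clear_ungeoreferenceable", master_name)


def qa_agreement(
    results_a: dict[str, tuple[float, float, float]],
    results_b: dict[str, tuple[float, float, float]],
    sample_n: int = 100,
    seed: int = 0,
    distance_threshold_m: float | None = None,
) -> float:
    """Agreement rate between two independent georeferencers.

    A seeded random sample of ``sample_n`` sites is drawn from those both
    sets cover (all of them, with a warning, when fewer are available).
    Two results agree when their points lie within
    ``distance_threshold_m`` -- by default the larger of the two extents --
    great-circle distance, and their extent circles overlap.  Symmetric in
    (a, b) by construction.
    """
    common = sorted(set(results_a) & set(results_b))
    if not common:
        raise ValidationError("no sites common to both result sets")
    rng = np.random.default_rng(seed)
    if sample_n >= len(common):
        sample = common
    else:
        sample = [common[i] for i in rng.choice(len(common), size=sample_n, replace=False)]
    agree = 0
    for site in sample:
        la, lo, ea = results_a[site]
        lb, lob, eb = results_b[site]
        d = haversine_m(la, lo, lb, lob)
        threshold = distance_threshold_m if distance_threshold_m is not None else max(ea, eb)
        if d <= threshold and d <= ea + eb:
            agree += 1
    return agree / len(sample)
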