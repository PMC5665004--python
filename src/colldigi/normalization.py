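"""Variant-to-master normalisation and deduplication reporting.

Transcription leaves behind many verbatim renderings of the same logical
concept ("Reading", "Reading, Berks", "Redding").  Normalisation is the
expert-driven step that assigns each such variant to a single standardised
*master* record, so every specimen from one place (or of one taxon) resolves
to one concept -- which is what makes georeferencing and CMS ingest
tractable.  The assignment is many-to-one and replaceable: reassigning a
variant moves it, keeping exactly one current master per variant, with the
history kept in the assignments table.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .analytics import round_half_up
from .datastore import Store, ValidationError

# which expert role may normalise which variant kind
_ROLE_FOR_KIND = {"site": "georeferencer", "taxon": "scrutineer", "party": "data_manager"}


def reduction_percent(n_variants: int, n_masters: int) -> int:
    """Percent reduction achieved by deduplication, rounded half-up."""
    if n_masters > n_variants:
        raise ValidationError("masters cannot outnumber variants")
    if n_variants == 0:
        return 0
    return int(round_half_up(100.0 * (n_variants - n_masters) / n_variants, 0))


def assign_variant(
    store: Store, expert: str, kind: str, variant_text: str, master_name: str
) -> int:
    """Assign one verbatim variant to a master (created on first use).

    Returns the master id.  Site variants need the georeferencer role,
    taxon variants the scrutineer role; assigning a variant of one kind to
    a master of another kind is refused by construction (masters are keyed
    by kind).
    """
    if kind not in _ROLE_FOR_KIND:
        raise ValidationError(f"bad variant kind {kind!r}")
    store.require_role(expert, _ROLE_FOR_KIND[kind])
    row = store.db.execute(
        "SELECT id FROM variants WHERE kind=? AND text=?", (kind, variant_text)
    ).fetchone()
    if row is None:
        raise ValidationError(f"no {kind} variant {variant_text!r}")
    vid = row["id"]
    mid = store.ensure_master(kind, master_name)
    store.db.execute("UPDATE variants SET master_id=? WHERE id=?", (mid, vid))
    store.db.execute(
        "INSERT INTO assignments (variant_id, master_id, assigned_by, ts) VALUES (?,?,?,?)",
        (vid, mid, expert, datetime.now(timezone.utc).isoformat(timespec="seconds")),
    )
    store.db.commit()
    return mid


def specimens_per_master(store: Store, kind: str) -> pd.Series:
    """Linked-specimen count per master name (specimens without the variant
    type are excluded)."""
    col = "site_variant_id" if kind == "site" else "taxon_variant_id"
    q = f"""
        SELECT m.name AS master, COUNT(s.id) AS n
        FROM specimens s
        JOIN variants v ON s.{col} = v.id
        JOIN masters m ON v.master_id = m.id
        WHERE v.kind = ?
        GROUP BY m.id
    """
    df = pd.read_sql_query(q, store.db, params=(kind,))
    return df.set_index("master")["n"].sort_values(ascending=False)


@dataclass(frozen=True)
class DedupReport:
    kind: str
    n_variants: int
    n_masters: int
    n_unassigned: int
    pct_reduction: int
    specimens_median: float
    specimens_mean: float
    top_k_coverage: list[tuple[int, int]]


def dedup_report(
    store: Store, kind: str, partial: bool = False, top_k: tuple[int, ...] = (10, 100)
) -> DedupReport:
    """Deduplication statistics for one variant type.

    With ``partial=False`` every variant must already have a master;
    ``partial=True`` permits a report during the parallel-running phase,
    counting unassigned variants separately (they do not count as masters).
    """
    rows = store.db.execute(
        "SELECT master_id FROM variants WHERE kind=?", (kind,)
    ).fetchall()
    n_variants = len(rows)
    unassigned = sum(1 for r in rows if r["master_id"] is None)
    if unassigned and not partial:
        raise ValidationError(
            f"{unassigned} {kind} variant(s) not yet assigned; pass partial=True"
        )
    n_masters = len({r["master_id"] for r in rows if r["master_id"] is not None})
    per_master = specimens_per_master(store, kind)
    counts = per_master.to_numpy(dtype=float)
    coverage = []
    sorted_counts = np.sort(counts)[::-1]
    for k in top_k:
        coverage.append((k, int(sorted_counts[:k].sum()) if len(sorted_counts) else 0))
    return DedupReport(
        kind=kind,
        n_variants=n_variants,
        n_masters=n_masters,
        n_unassigned=unassigned,
        pct_reduction=reduction_percent(n_variants - unassigned, n_masters)
        if n_variants
        else 0,
        specimens_median=float(np.median(counts)) if len(counts) else 0.0,
        specimens_mean=float(counts.mean()) if len(counts) else 0.0,
        top_k_coverage=coverage,
    )


def seed_taxon_masters(store: Store, checklist: str | Path | list[str]) -> int:
    """Create taxon masters from an accepted-names checklist before
    transcription starts; duplicates are skipped with a warning.

    ``checklist`` is a CSV path (first column = accepted name, header row
    optional under the name ``name``) or a plain list of names.
    """
    if isinstance(checklist, (str, Path)):
        df = pd.read_csv(checklist, dtype=str)
        col = "name" if "name" in df.columns else df.columns[0]
        names = [n for n in df[col].tolist() if isinstance(n, str) and n.strip()]
    else:
        names = [n for n in checklist if n and n.strip()]
    created = 0
    seen: set[str] = set()
    for name in names:
        name = name.strip()
        if name in seen:
            continue
        seen.add(name)
        before = store.db.execute(
            "SELECT 1 FROM masters WHERE kind='taxon' AND name=?", (name,)
        ).fetchone()
        if before is None:
            store.ensure_master("taxon", name)
            created += 1
    return created
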