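"""Embedded relational store for the digitisation pipeline.

A single SQLite file holds every pipeline entity: barcode allocations,
specimen and image records, verbatim variants and their master assignments,
users and roles, and an append-only audit trail.  The original project ran a
client-server database, but nothing in the workflow needs more than an
embedded store at desk scale.

Access control is role-based: operations that the workflow restricts to data
managers, transcribers, georeferencers or scrutineers take a user name and
raise :class:`RoleError` when the account lacks the role.  A special
``SYSTEM`` account (created with every store) carries all roles and is used
by the automated overnight scripts.
"""

from __future__ import annotations

import hashlib
import sqlite3
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from .config import BARCODE_DIGITS, BARCODE_PREFIX, ROLES, STATUSES, format_barcode


class StoreError(Exception):
    """Base class for datastore failures."""


class RoleError(StoreError):
    """Operation attempted by a user lacking the required role."""


class ConflictError(StoreError):
    """Operation conflicts with existing state (e.g. attached barcode)."""


class ValidationError(StoreError):
    """Input rejected before touching the store."""


SYSTEM_USER = "SYSTEM"

_SCHEMA = """
PRAGMA foreign_keys = ON;

CREATE TABLE IF NOT EXISTS meta (
    key TEXT PRIMARY KEY, value TEXT
);
CREATE TABLE IF NOT EXISTS users (
    id INTEGER PRIMARY KEY,
    name TEXT UNIQUE NOT NULL,
    roles TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS barcodes (
    code TEXT PRIMARY KEY,
    number INTEGER UNIQUE NOT NULL,
    state TEXT NOT NULL CHECK (state IN ('allocated','attached','discarded'))
);
CREATE TABLE IF NOT EXISTS masters (
    id INTEGER PRIMARY KEY,
    kind TEXT NOT NULL CHECK (kind IN ('site','taxon','party')),
    name TEXT NOT NULL,
    latitude REAL, longitude REAL, extent_m REAL,
    georef_method TEXT, georef_by TEXT, georef_ts TEXT,
    ungeoreferenceable INTEGER NOT NULL DEFAULT 0,
    note TEXT,
    cms_irn TEXT,
    UNIQUE (kind, name)
);
CREATE TABLE IF NOT EXISTS variants (
    id INTEGER PRIMARY KEY,
    kind TEXT NOT NULL CHECK (kind IN ('site','taxon','party')),
    text TEXT NOT NULL,
    master_id INTEGER REFERENCES masters(id),
    UNIQUE (kind, text)
);
CREATE TABLE IF NOT EXISTS assignments (
    id INTEGER PRIMARY KEY,
    variant_id INTEGER NOT NULL REFERENCES variants(id),
    master_id INTEGER NOT NULL REFERENCES masters(id),
    assigned_by TEXT NOT NULL,
    ts TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS specimens (
    id INTEGER PRIMARY KEY,
    barcode TEXT UNIQUE REFERENCES barcodes(code),
    drawer TEXT,
    taxon_variant_id INTEGER REFERENCES variants(id),
    site_variant_id INTEGER REFERENCES variants(id),
    collectors TEXT,
    date_verbatim TEXT,
    date_start TEXT, date_end TEXT,
    registration TEXT,
    type_status TEXT,
    breeding_info TEXT,
    status TEXT NOT NULL DEFAULT 'imaged',
    assigned_to INTEGER REFERENCES users(id),
    flags TEXT NOT NULL DEFAULT '',
    pre_databased INTEGER NOT NULL DEFAULT 0,
    cms_irn TEXT,
    event_irn TEXT
);
CREATE TABLE IF NOT EXISTS images (
    id INTEGER PRIMARY KEY,
    path TEXT NOT NULL,
    role TEXT NOT NULL CHECK (role IN ('full','label','label_back')),
    width INTEGER, height INTEGER,
    specimen_id INTEGER NOT NULL REFERENCES specimens(id),
    cms_irn TEXT
);
CREATE TABLE IF NOT EXISTS processed (
    hash TEXT PRIMARY KEY,
    path TEXT NOT NULL,
    orig_path TEXT,
    specimen_id INTEGER REFERENCES specimens(id)
);
CREATE TABLE IF NOT EXISTS audit (
    id INTEGER PRIMARY KEY,
    ts TEXT NOT NULL,
    user TEXT NOT NULL,
    action TEXT NOT NULL,
    detail TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS irns (
    entity_type TEXT NOT NULL,
    local_id TEXT NOT NULL,
    irn TEXT NOT NULL,
    UNIQUE (entity_type, local_id),
    UNIQUE (entity_type, irn)
);
CREATE TABLE IF NOT EXISTS timings (
    id INTEGER PRIMARY KEY,
    specimen TEXT,
    stage TEXT NOT NULL,
    seconds REAL NOT NULL,
    user TEXT,
    ts TEXT
);
"""


def _now() -> str:
    return datetime.now(timezone.utc).isoformat(timespec="seconds")


@dataclass
class UserAccount:
    name: str
    roles: frozenset[str]


@dataclass
class SpecimenView:
    """Read-only snapshot of a specimen row."""

    id: int
    barcode: str | None
    drawer: str | None
    status: str
    flags: set[str] = field(default_factory=set)
    site_variant: str | None = None
    taxon_variant: str | None = None


class Store:
    """One project's relational store.

    Parameters
    ----------
    path:
        SQLite file path, or ``":memory:"`` for an ephemeral store.
    barcode_prefix, barcode_digits:
        Payload format for newly allocated barcodes.
    """

    def __init__(
        self,
        path: str | Path = ":memory:",
        barcode_prefix: str = BARCODE_PREFIX,
        barcode_digits: int = BARCODE_DIGITS,
    ):
        self.path = str(path)
        self.prefix = barcode_prefix
        self.digits = barcode_digits
        try:
            self.db = sqlite3.connect(self.path)
        except sqlite3.Error as exc:  # pragma: no cover - depends on OS state
            raise StoreError(f"cannot open store at {self.path}: {exc}") from exc
        self.db.row_factory = sqlite3.Row
        self.db.executescript(_SCHEMA)
        self.db.execute(
            "INSERT OR IGNORE INTO users (name, roles) VALUES (?, ?)",
            (SYSTEM_USER, ",".join(sorted(ROLES))),
        )
        self.db.commit()

    def close(self) -> None:
        self.db.close()

    # -- guards ------------------------------------------------------------

    def _check_writable(self) -> None:
        row = self.db.execute("SELECT value FROM meta WHERE key='readonly'").fetchone()
        if row is not None and row["value"] == "1":
            raise ConflictError("store has been archived and is read-only")

    def require_role(self, user: str, role: str) -> None:
        row = self.db.execute("SELECT roles FROM users WHERE name=?", (user,)).fetchone()
        if row is None:
            raise RoleError(f"unknown user {user!r}")
        if role not in row["roles"].split(","):
            raise RoleError(f"user {user!r} lacks role {role!r}")

    def audit(self, user: str, action: str, detail: str) -> None:
        self.db.execute(
            "INSERT INTO audit (ts, user, action, detail) VALUES (?,?,?,?)",
            (_now(), user, action, detail),
        )
        self.db.commit()

    def audit_entries(self, action: str | None = None) -> list[sqlite3.Row]:
        if action is None:
            return self.db.execute("SELECT * FROM audit ORDER BY id").fetchall()
        return self.db.execute(
            "SELECT * FROM audit WHERE action=? ORDER BY id", (action,)
        ).fetchall()

    # -- users -------------------------------------------------------------

    def add_user(self, name: str, roles: set[str] | frozenset[str]) -> UserAccount:
        bad = set(roles) - ROLES
        if bad:
            raise ValidationError(f"unknown roles: {sorted(bad)}")
        self._check_writable()
        self.db.execute(
            "INSERT INTO users (name, roles) VALUES (?, ?)", (name, ",".join(sorted(roles)))
        )
        self.db.commit()
        return UserAccount(name, frozenset(roles))

    def get_user(self, name: str) -> UserAccount:
        row = self.db.execute("SELECT * FROM users WHERE name=?", (name,)).fetchone()
        if row is None:
            raise ValidationError(f"unknown user {name!r}")
        return UserAccount(row["name"], frozenset(r for r in row["roles"].split(",") if r))

    # -- barcodes ----------------------------------------------------------

    def allocate_barcodes(self, user: str, n: int) -> list[str]:
        """Issue ``n`` fresh barcode identifiers, strictly increasing.

        Discarded numbers are never re-issued: the counter only moves
        forward, so uniqueness over the project lifetime holds by
        construction.
        """
        if n < 1:
            raise ValidationError("n must be >= 1")
        self.require_role(user, "data_manager")
        self._check_writable()
        row = self.db.execute("SELECT MAX(number) AS m FROM barcodes").fetchone()
        start = (row["m"] or 0) + 1
        codes = []
        for i in range(start, start + n):
            code = format_barcode(i, self.prefix, self.digits)
            self.db.execute(
                "INSERT INTO barcodes (code, number, state) VALUES (?,?,'allocated')",
                (code, i),
            )
            codes.append(code)
        self.db.commit()
        self.audit(user, "allocate_barcodes", f"{codes[0]}..{codes[-1]}")
        return codes

    def discard_barcodes(self, user: str, codes: list[str]) -> int:
        """Mark misplaced labels' codes as discarded; they cannot return."""
        self.require_role(user, "data_manager")
        self._check_writable()
        n = 0
        for code in codes:
            row = self.db.execute("SELECT state FROM barcodes WHERE code=?", (code,)).fetchone()
            if row is None:
                raise ValidationError(f"unknown barcode {code}")
            if row["state"] == "attached":
                raise ConflictError(f"barcode {code} is attached to a specimen")
            if row["state"] == "allocated":
                self.db.execute("UPDATE barcodes SET state='discarded' WHERE code=?", (code,))
                n += 1
        self.db.commit()
        if codes:
            self.audit(user, "discard_barcodes", ",".join(codes))
        return n

    def barcode_state(self, code: str) -> str | None:
        row = self.db.execute("SELECT state FROM barcodes WHERE code=?", (code,)).fetchone()
        return None if row is None else row["state"]

    def register_decoded_barcode(self, code: str) -> None:
        """Attach a code read off a physical label.

        Codes printed before the store existed (or by another project
        instance) are inserted on first sight; an already-attached code is a
        collision and raises.
        """
        self._check_writable()
        row = self.db.execute(
            "SELECT state, number FROM barcodes WHERE code=?", (code,)
        ).fetchone()
        if row is None:
            digits = "".join(ch for ch in code if ch.isdigit())
            number = int(digits) if digits else None
            if number is not None:
                clash = self.db.execute(
                    "SELECT code FROM barcodes WHERE number=?", (number,)
                ).fetchone()
                if clash is not None:
                    number = None  # foreign numbering scheme; store code only
            if number is None:
                row_max = self.db.execute("SELECT MIN(number) AS m FROM barcodes").fetchone()
                number = min(0, (row_max["m"] or 0)) - 1  # synthetic negative slot
            self.db.execute(
                "INSERT INTO barcodes (code, number, state) VALUES (?,?,'attached')",
                (code, number),
            )
        elif row["state"] == "attached":
            raise ConflictError(f"barcode {code} already attached")
        elif row["state"] == "discarded":
            raise ConflictError(f"barcode {code} was discarded and cannot be attached")
        else:
            self.db.execute("UPDATE barcodes SET state='attached' WHERE code=?", (code,))
        self.db.commit()

    # -- variants and masters ----------------------------------------------

    def ensure_variant(self, kind: str, text: str) -> int:
        """Return the id of the (kind, text) variant, creating it once.

        Matching is exact and case-sensitive: transcription is verbatim and
        deduplication of near-matches belongs to normalisation.
        """
        if kind not in ("site", "taxon", "party"):
            raise ValidationError(f"bad variant kind {kind!r}")
        row = self.db.execute(
            "SELECT id FROM variants WHERE kind=? AND text=?", (kind, text)
        ).fetchone()
        if row is not None:
            return row["id"]
        self._check_writable()
        cur = self.db.execute("INSERT INTO variants (kind, text) VALUES (?,?)", (kind, text))
        self.db.commit()
        return cur.lastrowid

    def ensure_master(self, kind: str, name: str) -> int:
        row = self.db.execute(
            "SELECT id FROM masters WHERE kind=? AND name=?", (kind, name)
        ).fetchone()
        if row is not None:
            return row["id"]
        self._check_writable()
        cur = self.db.execute("INSERT INTO masters (kind, name) VALUES (?,?)", (kind, name))
        self.db.commit()
        return cur.lastrowid

    # -- specimens ----------------------------------------------------------

    def create_specimen(
        self,
        barcode: str | None,
        drawer: str | None,
        taxon_variant_id: int | None,
        flags: set[str] | None = None,
        registration: str | None = None,
        pre_databased: bool = False,
    ) -> int:
        self._check_writable()
        if barcode is not None:
            self.register_decoded_barcode(barcode)
        cur = self.db.execute(
            "INSERT INTO specimens (barcode, drawer, taxon_variant_id, flags,"
            " registration, pre_databased) VALUES (?,?,?,?,?,?)",
            (
                barcode,
                drawer,
                taxon_variant_id,
                ",".join(sorted(flags or set())),
                registration,
                int(pre_databased),
            ),
        )
        self.db.commit()
        return cur.lastrowid

    def specimen(self, specimen_id: int) -> sqlite3.Row:
        row = self.db.execute("SELECT * FROM specimens WHERE id=?", (specimen_id,)).fetchone()
        if row is None:
            raise ValidationError(f"no specimen {specimen_id}")
        return row

    def specimen_by_barcode(self, code: str) -> sqlite3.Row | None:
        return self.db.execute("SELECT * FROM specimens WHERE barcode=?", (code,)).fetchone()

    def specimen_flags(self, specimen_id: int) -> set[str]:
        return set(f for f in self.specimen(specimen_id)["flags"].split(",") if f)

    def add_flag(self, specimen_id: int, flag: str) -> None:
        self._check_writable()
        flags = self.specimen_flags(specimen_id)
        flags.add(flag)
        self.db.execute(
            "UPDATE specimens SET flags=? WHERE id=?", (",".join(sorted(flags)), specimen_id)
        )
        self.db.commit()

    def set_status(self, specimen_id: int, new_status: str, user: str = SYSTEM_USER) -> None:
        """Advance a specimen along the workflow; backward moves are refused."""
        if new_status not in STATUSES:
            raise ValidationError(f"unknown status {new_status!r}")
        self._check_writable()
        row = self.specimen(specimen_id)
        old_i = STATUSES.index(row["status"])
        new_i = STATUSES.index(new_status)
        if new_i < old_i:
            raise ConflictError(
                f"cannot move specimen {specimen_id} backwards: {row['status']} -> {new_status}"
            )
        skipped = list(STATUSES[old_i + 1 : new_i])
        self.db.execute("UPDATE specimens SET status=? WHERE id=?", (new_status, specimen_id))
        self.db.commit()
        detail = f"specimen {specimen_id}: {row['status']} -> {new_status}"
        if skipped:
            detail += f" (skipped: {','.join(skipped)})"
        self.audit(user, "set_status", detail)

    def update_specimen(self, specimen_id: int, **fields) -> None:
        allowed = {
            "barcode",
            "drawer",
            "taxon_variant_id",
            "site_variant_id",
            "collectors",
            "date_verbatim",
            "date_start",
            "date_end",
            "registration",
            "type_status",
            "breeding_info",
            "assigned_to",
            "cms_irn",
            "event_irn",
        }
        bad = set(fields) - allowed
        if bad:
            raise ValidationError(f"cannot update fields {sorted(bad)}")
        self._check_writable()
        sets = ", ".join(f"{k}=?" for k in fields)
        self.db.execute(
            f"UPDATE specimens SET {sets} WHERE id=?", (*fields.values(), specimen_id)
        )
        self.db.commit()

    def all_specimens(self) -> list[sqlite3.Row]:
        return self.db.execute("SELECT * FROM specimens ORDER BY id").fetchall()

    # -- images --------------------------------------------------------------

    def add_image(
        self, path: str, role: str, width: int, height: int, specimen_id: int
    ) -> int:
        if role == "label" and (width, height) != (800, 1219):
            raise ValidationError("label crops must be exactly 800x1219 pixels")
        n_role = self.db.execute(
            "SELECT COUNT(*) AS n FROM images WHERE specimen_id=? AND role=?",
            (specimen_id, role),
        ).fetchone()["n"]
        limit = {"full": 1, "label": 2, "label_back": 1}[role]
        if n_role >= limit:
            raise ConflictError(f"specimen {specimen_id} already has {n_role} {role} image(s)")
        self._check_writable()
        cur = self.db.execute(
            "INSERT INTO images (path, role, width, height, specimen_id) VALUES (?,?,?,?,?)",
            (path, role, width, height, specimen_id),
        )
        self.db.commit()
        return cur.lastrowid

    def images_for(self, specimen_id: int) -> list[sqlite3.Row]:
        return self.db.execute(
            "SELECT * FROM images WHERE specimen_id=? ORDER BY id", (specimen_id,)
        ).fetchall()

    def update_image_path(self, image_id: int, path: str) -> None:
        self._check_writable()
        self.db.execute("UPDATE images SET path=? WHERE id=?", (path, image_id))
        self.db.commit()

    # -- idempotency ----------------------------------------------------------

    @staticmethod
    def content_hash(path: str | Path) -> str:
        return hashlib.sha256(Path(path).read_bytes()).hexdigest()

    def is_processed(self, file_hash: str) -> bool:
        return (
            self.db.execute("SELECT 1 FROM processed WHERE hash=?", (file_hash,)).fetchone()
            is not None
        )

    def mark_processed(
        self,
        file_hash: str,
        path: str,
        orig_path: str | None = None,
        specimen_id: int | None = None,
    ) -> None:
        self._check_writable()
        self.db.execute(
            "INSERT OR IGNORE INTO processed (hash, path, orig_path, specimen_id)"
            " VALUES (?,?,?,?)",
            (file_hash, path, orig_path or path, specimen_id),
        )
        self.db.commit()

    def specimen_for_original_path(self, orig_path: str) -> int | None:
        row = self.db.execute(
            "SELECT specimen_id FROM processed WHERE orig_path=?", (orig_path,)
        ).fetchone()
        return None if row is None or row["specimen_id"] is None else row["specimen_id"]

    # -- generic helpers -------------------------------------------------------

    TABLES = (
        "users",
        "barcodes",
        "masters",
        "variants",
        "assignments",
        "specimens",
        "images",
        "processed",
        "audit",
        "timings",
    )

    def table(self, name: str) -> pd.DataFrame:
        if name not in self.TABLES:
            raise ValidationError(f"unknown table {name!r}")
        return pd.read_sql_query(f"SELECT * FROM {name}", self.db)

    def export_table(self, name: str, path: str | Path) -> None:
        self.table(name).to_csv(path, index=False, encoding="utf-8")

    def delete_row(self, table: str, row_id: int) -> None:
        """Delete one row; refused (IntegrityError) if anything references it."""
        if table not in self.TABLES:
            raise ValidationError(f"unknown table {table!r}")
        self._check_writable()
        key = "code" if table == "barcodes" else "hash" if table == "processed" else "id"
        try:
            self.db.execute(f"DELETE FROM {table} WHERE {key}=?", (row_id,))
            self.db.commit()
        except sqlite3.IntegrityError as exc:
            self.db.rollback()
            raise ConflictError(f"row {row_id} of {table} is referenced: {exc}") from exc

    def mark_readonly(self) -> None:
        self.db.execute(
            "INSERT OR REPLACE INTO meta (key, value) VALUES ('readonly','1')"
        )
        self.db.commit()

    # -- timing log -------------------------------------------------------------

    def log_timing(
        self, stage: str, seconds: float, specimen: str | None = None, user: str | None = None
    ) -> None:
        self._check_writable()
        self.db.execute(
            "INSERT INTO timings (specimen, stage, seconds, user, ts) VALUES (?,?,?,?,?)",
            (specimen, stage, seconds, user, _now()),
        )
        self.db.commit()
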