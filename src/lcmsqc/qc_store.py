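"""Persistent QC store: files, schedule state, metrics, readings, warnings, log.

An embedded single-file SQLite database sits at the center of the
pipeline.  All timestamps are stored as UTC ISO-8601 strings; schema
versioning runs through a migrations table so the portable SQL can move
to a server backend with a configuration swap.
"""

from __future__ import annotations

import re
import sqlite3
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .compound_tracking import PeakMetrics
from .contaminant_screen import ContaminantReading
from .errors import QueryError, StorageError
from .file_intake import FileRecord

_MIGRATIONS: list[tuple[int, str]] = [
    (1, """
    CREATE TABLE files (
        id INTEGER PRIMARY KEY,
        checksum TEXT NOT NULL UNIQUE,
        path TEXT NOT NULL,
        instrument TEXT, project TEXT, ionization_mode TEXT, sample_id TEXT,
        acquisition_time TEXT, acquisition_time_is_fallback INTEGER DEFAULT 0,
        discovered_at TEXT, parsed INTEGER DEFAULT 1
    );
    CREATE TABLE schedule (
        id INTEGER PRIMARY KEY,
        file_id INTEGER NOT NULL REFERENCES files(id),
        module TEXT NOT NULL,
        status TEXT NOT NULL DEFAULT 'pending',
        attempts INTEGER NOT NULL DEFAULT 0,
        last_error TEXT,
        UNIQUE (file_id, module)
    );
    CREATE TABLE peak_metrics (
        id INTEGER PRIMARY KEY,
        file_id INTEGER NOT NULL REFERENCES files(id),
        compound TEXT NOT NULL,
        found INTEGER NOT NULL,
        mz_target REAL, mz_observed REAL, mz_dev_ppm REAL,
        rt_expected REAL, rt_observed REAL, rt_dev REAL,
        intensity_apex REAL, area REAL,
        tailing_factor REAL, asymmetry_factor REAL, shape_reason TEXT,
        UNIQUE (file_id, compound)
    );
    CREATE TABLE contaminant_readings (
        id INTEGER PRIMARY KEY,
        file_id INTEGER NOT NULL REFERENCES files(id),
        contaminant TEXT NOT NULL,
        mz REAL NOT NULL,
        eic_max REAL NOT NULL,
        eic_mean REAL NOT NULL,
        UNIQUE (file_id, contaminant, mz)
    );
    CREATE TABLE warning_events (
        id INTEGER PRIMARY KEY,
        rule_key TEXT NOT NULL,
        file_id INTEGER NOT NULL REFERENCES files(id),
        metric TEXT NOT NULL,
        target TEXT,
        value REAL NOT NULL,
        fired_at TEXT NOT NULL,
        UNIQUE (rule_key, file_id, metric, target)
    );
    CREATE TABLE warning_deliveries (
        id INTEGER PRIMARY KEY,
        event_id INTEGER NOT NULL REFERENCES warning_events(id),
        sink TEXT NOT NULL,
        delivered INTEGER NOT NULL,
        detail TEXT
    );
    CREATE TABLE log (
        id INTEGER PRIMARY KEY,
        ts TEXT NOT NULL,
        module TEXT NOT NULL,
        level TEXT NOT NULL,
        message TEXT NOT NULL
    );
    """),
]


@dataclass
class QueryFilter:
    """Declarative row filter shared by queries, reports and warning scopes.

    The empty filter selects everything.  ``sample_id_pattern`` is a
    regular expression (validated up front); ``date_range`` is half-open
    ``[from, to)`` on acquisition time.
    """

    projects: list[str] = field(default_factory=list)
    polarity: str | None = None
    instrument: str | None = None
    sample_id_pattern: str | None = None
    date_range: tuple[datetime | None, datetime | None] = (None, None)
    keyword: str | None = None

    def compiled_pattern(self) -> re.Pattern | None:
        if self.sample_id_pattern is None:
            return None
        try:
            return re.compile(self.sample_id_pattern)
        except re.error as exc:
            raise QueryError(f"invalid sample_id regex: {exc}") from exc


def _iso(dt: datetime | None) -> str | None:
    if dt is None:
        return None
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return dt.astimezone(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")


def _now() -> str:
    return _iso(datetime.now(timezone.utc))


class QCStore:
    """SQLite-backed store; ``path`` may be ':memory:' for tests."""

    def __init__(self, path: str | Path = ":memory:"):
        try:
            self._conn = sqlite3.connect(str(path))
        except sqlite3.Error as exc:
            raise StorageError(f"cannot open database {path}: {exc}") from exc
        self._conn.row_factory = sqlite3.Row
        self._conn.execute("PRAGMA foreign_keys = ON")
        self._migrate()

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "QCStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- schema -------------------------------------------------------

    def _migrate(self) -> None:
        cur = self._conn.cursor()
        cur.execute("""CREATE TABLE IF NOT EXISTS migrations (
            version INTEGER PRIMARY KEY, applied_at TEXT NOT NULL)""")
        applied = {r[0] for r in cur.execute("SELECT version FROM migrations")}
        for version, sql in _MIGRATIONS:
            if version not in applied:
                cur.executescript(sql)
                cur.execute("INSERT INTO migrations VALUES (?, ?)", (version, _now()))
        self._conn.commit()

    def schema_version(self) -> int:
        row = self._conn.execute("SELECT MAX(version) FROM migrations").fetchone()
        return row[0] or 0

    def info(self) -> dict:
        """Diagnostics summary: schema version and per-table row counts."""
        tables = ["files", "schedule", "peak_metrics", "contaminant_readings",
                  "warning_events", "log"]
        counts = {t: self._conn.execute(f"SELECT COUNT(*) FROM {t}").fetchone()[0]
                  for t in tables}
        return {"schema_version": self.schema_version(), "rows": counts}

    # -- files --------------------------------------------------------

    def upsert_file(self, rec: FileRecord) -> int:
        """Insert a new file, or refresh path/metadata for a known checksum."""
        cur = self._conn.cursor()
        row = cur.execute("SELECT id FROM files WHERE checksum = ?",
                          (rec.checksum,)).fetchone()
        values = (rec.path, rec.instrument, rec.project, rec.ionization_mode,
                  rec.sample_id, _iso(rec.acquisition_time),
                  int(rec.acquisition_time_is_fallback),
                  _iso(rec.discovered_at), int(rec.parsed))
        if row:
            cur.execute("""UPDATE files SET path=?, instrument=?, project=?,
                ionization_mode=?, sample_id=?, acquisition_time=?,
                acquisition_time_is_fallback=?, discovered_at=?, parsed=?
                WHERE id=?""", values + (row["id"],))
            self._conn.commit()
            return row["id"]
        cur.execute("""INSERT INTO files (path, instrument, project,
            ionization_mode, sample_id, acquisition_time,
            acquisition_time_is_fallback, discovered_at, parsed, checksum)
            VALUES (?,?,?,?,?,?,?,?,?,?)""", values + (rec.checksum,))
        self._conn.commit()
        return cur.lastrowid

    def known_checksums(self) -> set[str]:
        return {r[0] for r in self._conn.execute("SELECT checksum FROM files")}

    def file_by_checksum(self, checksum: str) -> sqlite3.Row | None:
        return self._conn.execute(
            "SELECT * FROM files WHERE checksum = ?", (checksum,)).fetchone()

    def set_acquisition_time(self, file_id: int, when: datetime,
                             fallback: bool = False) -> None:
        self._conn.execute(
            "UPDATE files SET acquisition_time=?, acquisition_time_is_fallback=? "
            "WHERE id=?", (_iso(when), int(fallback), file_id))
        self._conn.commit()

    # -- schedule -----------------------------------------------------

    def ensure_schedule(self, file_id: int, modules: Sequence[str]) -> list[int]:
        cur = self._conn.cursor()
        created = []
        for mod in modules:
            cur.execute(
                "INSERT OR IGNORE INTO schedule (file_id, module) VALUES (?,?)",
                (file_id, mod))
            if cur.rowcount:
                created.append(cur.lastrowid)
        self._conn.commit()
        return created

    def pending_entries(self, module: str | None = None) -> list[sqlite3.Row]:
        sql = "SELECT * FROM schedule WHERE status='pending'"
        args: tuple = ()
        if module:
            sql += " AND module=?"
            args = (module,)
        return list(self._conn.execute(sql + " ORDER BY id", args))

    def set_entry_status(self, entry_id: int, status: str,
                         error: str | None = None) -> None:
        bump = 1 if status == "running" else 0
        self._conn.execute(
            "UPDATE schedule SET status=?, last_error=?, attempts=attempts+? "
            "WHERE id=?", (status, error, bump, entry_id))
        self._conn.commit()

    def requeue_failed(self, limit: int) -> int:
        cur = self._conn.execute(
            "UPDATE schedule SET status='pending' "
            "WHERE status='failed' AND attempts < ?", (limit,))
        self._conn.commit()
        return cur.rowcount

    def schedule_counts(self) -> dict[str, int]:
        return {r["status"]: r["n"] for r in self._conn.execute(
            "SELECT status, COUNT(*) AS n FROM schedule GROUP BY status")}

    # -- metrics ------------------------------------------------------

    def insert_metrics(self, file_id: int, metrics: Iterable[PeakMetrics]) -> int:
        """Store tracking results; idempotent per (file, compound)."""
        cur = self._conn.cursor()
        n = 0
        for m in metrics:
            cur.execute("""INSERT OR IGNORE INTO peak_metrics
                (file_id, compound, found, mz_target, mz_observed, mz_dev_ppm,
                 rt_expected, rt_observed, rt_dev, intensity_apex, area,
                 tailing_factor, asymmetry_factor, shape_reason)
                VALUES (?,?,?,?,?,?,?,?,?,?,?,?,?,?)""",
                (file_id, m.compound, int(m.found), m.mz_target, m.mz_observed,
                 m.mz_dev_ppm, m.rt_expected, m.rt_observed, m.rt_dev,
                 m.intensity_apex, m.area, m.tailing_factor,
                 m.asymmetry_factor, m.shape_reason))
            n += cur.rowcount
        self._conn.commit()
        return n

    def insert_readings(self, file_id: int,
                        readings: Iterable[ContaminantReading]) -> int:
        cur = self._conn.cursor()
        n = 0
        for r in readings:
            cur.execute("""INSERT OR IGNORE INTO contaminant_readings
                (file_id, contaminant, mz, eic_max, eic_mean)
                VALUES (?,?,?,?,?)""",
                (file_id, r.contaminant, r.mz, r.eic_max, r.eic_mean))
            n += cur.rowcount
        self._conn.commit()
        return n

    # -- queries ------------------------------------------------------

    def _file_filter_sql(self, flt: QueryFilter) -> tuple[str, list]:
        clauses, args = [], []
        if flt.projects:
            clauses.append("f.project IN (%s)" % ",".join("?" * len(flt.projects)))
            args.extend(flt.projects)
        if flt.polarity:
            clauses.append("f.ionization_mode = ?")
            args.append(flt.polarity)
        if flt.instrument:
            clauses.append("f.instrument = ?")
            args.append(flt.instrument)
        frm, to = flt.date_range
        if frm is not None:
            clauses.append("f.acquisition_time >= ?")
            args.append(_iso(frm))
        if to is not None:
            clauses.append("f.acquisition_time < ?")
            args.append(_iso(to))
        sql = (" AND " + " AND ".join(clauses)) if clauses else ""
        return sql, args

    def _post_filter(self, df: pd.DataFrame, flt: QueryFilter) -> pd.DataFrame:
        pattern = flt.compiled_pattern()
        if pattern is not None and not df.empty:
            df = df[df["sample_id"].fillna("").map(
                lambda s: pattern.search(s) is not None)]
        if flt.keyword and not df.empty:
            hay = df[["path", "project", "sample_id"]].fillna("").agg(" ".join, axis=1)
            df = df[hay.str.contains(re.escape(flt.keyword), case=False)]
        return df.reset_index(drop=True)

    def query_metrics(self, flt: QueryFilter | None = None) -> pd.DataFrame:
        """Peak metrics joined to file metadata, acquisition-time ordered."""
        flt = flt or QueryFilter()
        flt.compiled_pattern()  # fail fast before touching storage
        where, args = self._file_filter_sql(flt)
        df = pd.read_sql_query(
            f"""SELECT m.*, f.path, f.project, f.instrument,
                       f.ionization_mode, f.sample_id, f.acquisition_time
                FROM peak_metrics m JOIN files f ON f.id = m.file_id
                WHERE 1=1 {where}
                ORDER BY f.acquisition_time, m.file_id, m.compound""",
            self._conn, params=args)
        return self._post_filter(df, flt)

    def query_readings(self, flt: QueryFilter | None = None) -> pd.DataFrame:
        flt = flt or QueryFilter()
        flt.compiled_pattern()
        where, args = self._file_filter_sql(flt)
        df = pd.read_sql_query(
            f"""SELECT r.*, f.path, f.project, f.instrument,
                       f.ionization_mode, f.sample_id, f.acquisition_time
                FROM contaminant_readings r JOIN files f ON f.id = r.file_id
                WHERE 1=1 {where}
                ORDER BY f.acquisition_time, r.file_id, r.contaminant""",
            self._conn, params=args)
        return self._post_filter(df, flt)

    def query_files(self, flt: QueryFilter | None = None) -> pd.DataFrame:
        flt = flt or QueryFilter()
        flt.compiled_pattern()
        where, args = self._file_filter_sql(flt)
        df = pd.read_sql_query(
            f"""SELECT f.* FROM files f WHERE 1=1 {where}
                ORDER BY f.acquisition_time, f.id""",
            self._conn, params=args)
        return self._post_filter(df, flt)

    # -- warnings -----------------------------------------------------

    def record_warning_events(self, events: Iterable) -> list:
        """Insert events, dropping duplicates; returns the new ones only."""
        cur = self._conn.cursor()
        new = []
        for e in events:
            cur.execute("""INSERT OR IGNORE INTO warning_events
                (rule_key, file_id, metric, target, value, fired_at)
                VALUES (?,?,?,?,?,?)""",
                (e.rule_key, e.file_id, e.metric, e.target, e.value,
                 e.fired_at or _now()))
            if cur.rowcount:
                e.event_id = cur.lastrowid
                new.append(e)
        self._conn.commit()
        return new

    def record_delivery(self, event_id: int, sink: str, delivered: bool,
                        detail: str | None = None) -> None:
        self._conn.execute(
            "INSERT INTO warning_deliveries (event_id, sink, delivered, detail) "
            "VALUES (?,?,?,?)", (event_id, sink, int(delivered), detail))
        self._conn.commit()

    def list_warning_events(self) -> pd.DataFrame:
        return pd.read_sql_query(
            "SELECT * FROM warning_events ORDER BY id", self._conn)

    # -- log ----------------------------------------------------------

    def log_event(self, module: str, level: str, message: str) -> None:
        """Append-only activity log; must never raise into processing."""
        try:
            self._conn.execute(
                "INSERT INTO log (ts, module, level, message) VALUES (?,?,?,?)",
                (_now(), module, level, message))
            self._conn.commit()
        except sqlite3.Error:  # pragma: no cover
            pass

    def query_log(self, module: str | None = None, level: str | None = None,
                  limit: int | None = None) -> pd.DataFrame:
        sql = "SELECT * FROM log WHERE 1=1"
        args: list = []
        if module:
            sql += " AND module=?"
            args.append(module)
        if level:
            sql += " AND level=?"
            args.append(level)
        sql += " ORDER BY id"
        if limit:
            sql += f" LIMIT {int(limit)}"
        return pd.read_sql_query(sql, self._conn, params=args)
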