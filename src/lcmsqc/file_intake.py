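"""Discovery, filename parsing and per-module scheduling of new runs.

Files arrive in a watched directory (or are listed in a plain-text path
file); each new file is recognized by its content checksum, its metadata
parsed from the filename with a user-defined naming pattern, and one
pending schedule entry created per enabled processing module.  Files
whose name does not match the pattern are ingested anyway and flagged,
so QC coverage is never silently reduced.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping

from .errors import ConfigurationError, InputError
from .mzml_io import file_checksum

logger = logging.getLogger(__name__)

ACCEPTED_EXTENSIONS = (".mzml", ".mzml.gz")
DEFAULT_POLL_INTERVAL = 15.0  # seconds
DEFAULT_RETRY_LIMIT = 3

_PLACEHOLDER_RE = re.compile(r"\{([A-Za-z_][A-Za-z0-9_]*)\}")


@dataclass
class FileRecord:
    """One ingested run and the metadata parsed from its filename."""

    path: str
    checksum: str
    instrument: str | None = None
    project: str | None = None
    ionization_mode: str | None = None
    sample_id: str | None = None
    acquisition_time: datetime | None = None
    acquisition_time_is_fallback: bool = False
    discovered_at: datetime = field(
        default_factory=lambda: datetime.now(timezone.utc))
    parsed: bool = True


class NamingPattern:
    """Brace-placeholder filename template compiled to an anchored regex.

    ``{project}_{date}_{instrument}_{mode}_{sample_id}`` matches
    ``ProjA_20220501_SYNAPT1_POS_QC007`` field by field.  Literal text is
    escaped, fields are non-greedy and must be non-empty, and the file
    extension is stripped before matching, so patterns describe the stem.
    """

    FIELD_ALIASES = {"mode": "ionization_mode"}

    def __init__(self, pattern: str):
        self.pattern = pattern
        names = _PLACEHOLDER_RE.findall(pattern)
        if not names:
            raise ConfigurationError(f"pattern has no placeholders: {pattern!r}")
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate placeholder in pattern: {pattern!r}")
        parts = []
        pos = 0
        for m in _PLACEHOLDER_RE.finditer(pattern):
            literal = pattern[pos:m.start()]
            if "{" in literal or "}" in literal:
                raise ConfigurationError(f"unbalanced braces in pattern: {pattern!r}")
            parts.append(re.escape(literal))
            parts.append(f"(?P<{m.group(1)}>.+?)")
            pos = m.end()
        tail = pattern[pos:]
        if "{" in tail or "}" in tail:
            raise ConfigurationError(f"unbalanced braces in pattern: {pattern!r}")
        parts.append(re.escape(tail))
        try:
            self._regex = re.compile("^" + "".join(parts) + "$")
        except re.error as exc:
            raise ConfigurationError(f"invalid pattern {pattern!r}: {exc}") from exc
        self.fields = names

    def match(self, name: str) -> dict[str, str] | None:
        stem = name
        low = stem.lower()
        for ext in ACCEPTED_EXTENSIONS:
            if low.endswith(ext):
                stem = stem[: len(stem) - len(ext)]
                break
        m = self._regex.match(stem)
        return m.groupdict() if m else None


def parse_filename(name: str, pattern: NamingPattern) -> dict[str, str] | None:
    """Extract metadata fields from a filename; None on mismatch.

    Callers should store non-matching files flagged as unparsed rather
    than dropping them.
    """
    return pattern.match(Path(name).name)


def _accepted(path: Path) -> bool:
    return path.name.lower().endswith(ACCEPTED_EXTENSIONS)


def discover_files(source: str | Path, known: set[str],
                   size_state: dict[str, int] | None = None) -> list[Path]:
    """Find new acquisition files under a directory or in a path-list file.

    Parameters
    ----------
    source : path
        A directory to scan recursively, or a UTF-8 text file with one
        absolute path per line.
    known : set of str
        Content checksums already in the store; matching files are
        skipped.
    size_state : dict, optional
        Poller state mapping path -> last seen size.  When given, a file
        is deferred until its size is unchanged between two calls
        (write-quiescence check); omit for one-shot discovery.

    Returns new paths ordered by modification time, then name.
    """
    src = Path(source)
    if not src.exists():
        raise InputError(f"source does not exist: {source}")
    if src.is_dir():
        candidates = [p for p in src.rglob("*") if p.is_file() and _accepted(p)]
    else:
        candidates = []
        try:
            lines = src.read_text(encoding="utf-8").splitlines()
        except OSError as exc:
            raise InputError(f"cannot read path list {source}: {exc}") from exc
        for line in lines:
            line = line.strip()
            if not line:
                continue
            p = Path(line)
            if p.is_file():
                candidates.append(p)
            else:
                logger.warning("listed file missing: %s", line)

    fresh: list[Path] = []
    for p in candidates:
        if size_state is not None:
            size = p.stat().st_size
            if size_state.get(str(p)) != size:
                size_state[str(p)] = size
                logger.debug("deferring %s until size is stable", p)
                continue
        if file_checksum(p) not in known:
            fresh.append(p)
    fresh.sort(key=lambda p: (p.stat().st_mtime, p.name))
    return fresh


def build_record(path: str | Path, pattern: NamingPattern,
                 checksum: str | None = None) -> FileRecord:
    """Assemble a FileRecord from a path and the naming pattern."""
    path = Path(path)
    fields = parse_filename(path.name, pattern)
    rec = FileRecord(path=str(path),
                     checksum=checksum or file_checksum(path),
                     parsed=fields is not None)
    if fields:
        aliases = NamingPattern.FIELD_ALIASES
        for key, value in fields.items():
            attr = aliases.get(key, key)
            if hasattr(rec, attr) and attr not in ("path", "checksum"):
                setattr(rec, attr, value)
    return rec


def schedule(store, file_id: int, enabled_modules: Iterable[str]) -> list[int]:
    """Create one pending schedule entry per enabled module; idempotent.

    Returns ids of the entries created by *this* call (an empty list on
    re-scheduling).
    """
    return store.ensure_schedule(file_id, list(enabled_modules))


def retry_failed(store, limit: int = DEFAULT_RETRY_LIMIT) -> int:
    """Re-queue failed schedule entries whose attempts are under the limit."""
    return store.requeue_failed(limit)
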