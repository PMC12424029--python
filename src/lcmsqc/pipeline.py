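"""End-to-end processing: discover -> ingest -> track -> screen -> warn.

The pipeline is content-addressed: a file whose checksum is already in
the store is never reprocessed, so repeated polling of an unchanged
directory is a no-op at every level (files, schedule, metrics, events).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import file_intake, mzml_io
from .compound_tracking import TrackedCompound, TrackingParams, track_file
from .contaminant_screen import ContaminantIon, screen_file
from .errors import LcmsQcError
from .file_intake import NamingPattern, build_record
from .qc_store import QCStore
from .warner import WarningRule, evaluate_rules, notify

logger = logging.getLogger(__name__)

MODULE_TRACK = "track"
MODULE_CONTAMINANTS = "contaminants"
MODULE_INFO = "info"
DEFAULT_MODULES = (MODULE_INFO, MODULE_TRACK, MODULE_CONTAMINANTS)


@dataclass
class PipelineConfig:
    pattern: NamingPattern
    compounds: Sequence[TrackedCompound] = ()
    contaminants: Sequence[ContaminantIon] = ()
    rules: Sequence[WarningRule] = ()
    tracking: TrackingParams = field(default_factory=TrackingParams)
    enabled_modules: Sequence[str] = DEFAULT_MODULES
    retry_limit: int = file_intake.DEFAULT_RETRY_LIMIT


@dataclass
class ProcessResult:
    new_files: int = 0
    processed_entries: int = 0
    failed_entries: int = 0
    warning_events: int = 0


def ingest_paths(store: QCStore, paths: Sequence[Path],
                 config: PipelineConfig) -> list[int]:
    """Store FileRecords and schedule entries for new paths."""
    ids = []
    for path in paths:
        rec = build_record(path, config.pattern)
        file_id = store.upsert_file(rec)
        file_intake.schedule(store, file_id, config.enabled_modules)
        if not rec.parsed:
            store.log_event("intake", "warning",
                            f"filename did not match pattern: {path}")
        else:
            store.log_event("intake", "info", f"ingested {path}")
        ids.append(file_id)
    return ids


def run_pending(store: QCStore, config: PipelineConfig) -> ProcessResult:
    """Execute every pending schedule entry, module by module."""
    result = ProcessResult()
    spectra_cache: dict[int, list] = {}

    def _spectra(file_id: int, path: str):
        if file_id not in spectra_cache:
            spectra_cache[file_id] = mzml_io.read_spectra(path)
        return spectra_cache[file_id]

    files = {int(r["id"]): r for r in
             store.query_files().to_dict("records")}  # type: ignore[arg-type]
    for entry in store.pending_entries():
        entry_id, file_id = entry["id"], entry["file_id"]
        frow = files.get(file_id)
        if frow is None:
            store.set_entry_status(entry_id, "failed", "file row missing")
            result.failed_entries += 1
            continue
        store.set_entry_status(entry_id, "running")
        try:
            module = entry["module"]
            if module == MODULE_INFO:
                md = mzml_io.read_run_metadata(frow["path"])
                store.set_acquisition_time(file_id, md.acquisition_time,
                                           md.acquisition_time_is_fallback)
            elif module == MODULE_TRACK:
                targets = [c for c in config.compounds if c.in_scope(
                    frow.get("instrument") or "", frow.get("ionization_mode") or "")]
                metrics = track_file(_spectra(file_id, frow["path"]), None,
                                     targets, config.tracking)
                store.insert_metrics(file_id, metrics)
            elif module == MODULE_CONTAMINANTS:
                ions = [i for i in config.contaminants if i.polarity in
                        ("*", frow.get("ionization_mode") or "")]
                readings = screen_file(_spectra(file_id, frow["path"]), ions,
                                       config.tracking.tol_ppm)
                store.insert_readings(file_id, readings)
            else:
                raise LcmsQcError(f"unknown module {module!r}")
            store.set_entry_status(entry_id, "done")
            result.processed_entries += 1
        except Exception as exc:
            logger.error("module %s failed on file %s: %s",
                         entry["module"], frow["path"], exc)
            store.log_event(entry["module"], "error", str(exc))
            store.set_entry_status(entry_id, "failed", str(exc))
            result.failed_entries += 1
    return result


def process_source(store: QCStore, source: str | Path,
                   config: PipelineConfig, sinks=None) -> ProcessResult:
    """One full pass: discover, ingest, process, evaluate warning rules."""
    new = file_intake.discover_files(source, store.known_checksums())
    ingest_paths(store, new, config)
    result = run_pending(store, config)
    result.new_files = len(new)
    if config.rules:
        events = evaluate_rules(store.query_metrics(), list(config.rules),
                                store.query_readings())
        fresh = store.record_warning_events(events)
        notify(fresh, sinks, store=store)
        result.warning_events = len(fresh)
    return result


def watch(store: QCStore, source: str | Path, config: PipelineConfig,
          poll_interval: float = file_intake.DEFAULT_POLL_INTERVAL,
          max_polls: int | None = None, sinks=None) -> None:
    """Polling service loop with a write-quiescence check between polls."""
    size_state: dict[str, int] = {}
    polls = 0
    while max_polls is None or polls < max_polls:
        try:
            new = file_intake.discover_files(source, store.known_checksums(),
                                             size_state=size_state)
            ingest_paths(store, new, config)
            run_pending(store, config)
            file_intake.retry_failed(store, config.retry_limit)
            if config.rules:
                events = evaluate_rules(store.query_metrics(), list(config.rules),
                                        store.query_readings())
                notify(store.record_warning_events(events), sinks, store=store)
        except LcmsQcError as exc:
            logger.error("poll failed, continuing: %s", exc)
            store.log_event("intake", "error", str(exc))
        polls += 1
        if max_polls is None or polls < max_polls:
            time.sleep(poll_interval)
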