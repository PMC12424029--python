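"""Threshold warning rules and pluggable notification sinks.

Rules compare a QC metric against a user-defined threshold — e.g. fire
when the absolute m/z deviation exceeds 20 ppm, a level at which mass
accuracy problems call for prompt intervention.  Comparators are strict
("exceeds"): a value exactly at the threshold does not fire.  Events are
deduplicated per (rule, file, metric, target) in the store, so
reprocessing a file never re-alarms.  Delivery is through pluggable
sinks (log by default, webhook and SMTP optional); a sink failure is
recorded and isolated, never blocking processing.
"""

from __future__ import annotations

import csv
import json
import logging
import smtplib
import sys
from dataclasses import dataclass, field
from email.message import EmailMessage
from pathlib import Path
from typing import Iterable, Protocol, Sequence

import pandas as pd

from .errors import ConfigurationError
from .qc_store import QCStore, QueryFilter

logger = logging.getLogger(__name__)

VALID_METRICS = frozenset({
    "mz_dev_ppm", "rt_dev", "intensity_apex", "tailing_factor",
    "asymmetry_factor", "eic_max", "eic_mean",
})
_CONTAMINANT_METRICS = frozenset({"eic_max", "eic_mean"})
VALID_COMPARATORS = frozenset({"abs_gt", "gt", "lt"})

DEFAULT_PPM_RULE_THRESHOLD = 20.0


@dataclass
class WarningRule:
    """One threshold rule over a tracked-compound or contaminant metric."""

    metric: str
    comparator: str
    threshold: float
    scope: QueryFilter = field(default_factory=QueryFilter)
    target: str | None = None  # compound or contaminant name; None = any

    def __post_init__(self) -> None:
        if self.metric not in VALID_METRICS:
            raise ConfigurationError(
                f"unknown metric {self.metric!r}; valid: {sorted(VALID_METRICS)}")
        if self.comparator not in VALID_COMPARATORS:
            raise ConfigurationError(
                f"unknown comparator {self.comparator!r}; valid: {sorted(VALID_COMPARATORS)}")
        try:
            self.threshold = float(self.threshold)
        except (TypeError, ValueError):
            raise ConfigurationError("threshold must be a finite number")
        if self.threshold != self.threshold or self.threshold in (float("inf"), float("-inf")):
            raise ConfigurationError("threshold must be finite")

    @property
    def rule_key(self) -> str:
        return f"{self.metric}|{self.comparator}|{self.threshold!r}|{self.target or '*'}"

    def fires(self, value: float) -> bool:
        """Strict-inequality comparison; NaN never fires."""
        if value is None or value != value:
            return False
        if self.comparator == "abs_gt":
            return abs(value) > self.threshold
        if self.comparator == "gt":
            return value > self.threshold
        return value < self.threshold


@dataclass
class WarningEvent:
    rule_key: str
    file_id: int
    metric: str
    value: float
    target: str | None = None
    fired_at: str | None = None
    event_id: int | None = None


def default_rules() -> list[WarningRule]:
    """The one rule the monitoring data itself motivates: |m/z dev| > 20 ppm."""
    return [WarningRule("mz_dev_ppm", "abs_gt", DEFAULT_PPM_RULE_THRESHOLD)]


def load_rules(path: str | Path) -> list[WarningRule]:
    """Load rules from CSV (metric,comparator,threshold[,target]) or TOML.

    Metric and comparator names are validated here, at load time — a bad
    rule is a configuration error, never an evaluation-time surprise.
    """
    path = Path(path)
    rules: list[WarningRule] = []
    if path.suffix.lower() == ".toml":
        import tomllib
        data = tomllib.loads(path.read_text())
        for entry in data.get("rule", []):
            rules.append(WarningRule(
                metric=entry["metric"], comparator=entry["comparator"],
                threshold=entry["threshold"], target=entry.get("target"),
                scope=_scope_from_dict(entry.get("scope", {}))))
    else:
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            required = {"metric", "comparator", "threshold"}
            if reader.fieldnames is None or not required.issubset(reader.fieldnames):
                raise ConfigurationError(
                    f"rules file needs columns {sorted(required)}")
            for row in reader:
                rules.append(WarningRule(
                    metric=row["metric"].strip(),
                    comparator=row["comparator"].strip(),
                    threshold=row["threshold"],
                    target=(row.get("target") or "").strip() or None))
    return rules


def _scope_from_dict(d: dict) -> QueryFilter:
    return QueryFilter(
        projects=list(d.get("projects", [])),
        polarity=d.get("polarity"),
        instrument=d.get("instrument"),
        sample_id_pattern=d.get("sample_id_pattern"),
    )


def _in_scope(row: pd.Series, scope: QueryFilter) -> bool:
    if scope.projects and row.get("project") not in scope.projects:
        return False
    if scope.polarity and row.get("ionization_mode") != scope.polarity:
        return False
    if scope.instrument and row.get("instrument") != scope.instrument:
        return False
    pattern = scope.compiled_pattern()
    if pattern is not None and not pattern.search(str(row.get("sample_id") or "")):
        return False
    return True


def evaluate_rules(metric_rows: pd.DataFrame, rules: Sequence[WarningRule],
                   readings_rows: pd.DataFrame | None = None) -> list[WarningEvent]:
    """Pure rule evaluation: same rows + rules -> identical event list.

    ``metric_rows`` come from :meth:`QCStore.query_metrics` (per-compound
    records); ``readings_rows`` from :meth:`QCStore.query_readings` for
    the contaminant metrics.  Deduplication against previously fired
    events happens in the store, not here.
    """
    events: list[WarningEvent] = []
    for rule in rules:
        if rule.metric in _CONTAMINANT_METRICS:
            rows, name_col = readings_rows, "contaminant"
        else:
            rows, name_col = metric_rows, "compound"
        if rows is None or rows.empty:
            continue
        for _, row in rows.iterrows():
            if rule.target and row[name_col] != rule.target:
                continue
            if not _in_scope(row, rule.scope):
                continue
            value = row.get(rule.metric)
            if value is None or pd.isna(value):
                continue
            if rule.fires(float(value)):
                events.append(WarningEvent(
                    rule_key=rule.rule_key, file_id=int(row["file_id"]),
                    metric=rule.metric, value=float(value),
                    target=str(row[name_col])))
    return events


# ---------------------------------------------------------------------------
# notification sinks

class Sink(Protocol):
    name: str

    def deliver(self, event: WarningEvent) -> None: ...


class LogSink:
    """Default sink: one structured warning line per event."""

    name = "log"

    def __init__(self, store: QCStore | None = None, stream=None):
        self._store = store
        self._stream = stream if stream is not None else sys.stderr

    def deliver(self, event: WarningEvent) -> None:
        line = (f"WARNING rule={event.rule_key} file_id={event.file_id} "
                f"metric={event.metric} target={event.target} value={event.value:g}")
        if self._store is not None:
            self._store.log_event("warner", "warning", line)
        print(line, file=self._stream)


class WebhookSink:
    """POSTs the event as JSON; failures are reported, never raised past notify."""

    name = "webhook"

    def __init__(self, url: str, timeout: float = 5.0):
        self.url = url
        self.timeout = timeout

    def deliver(self, event: WarningEvent) -> None:
        import urllib.request
        payload = json.dumps(event.__dict__).encode()
        req = urllib.request.Request(
            self.url, data=payload, headers={"Content-Type": "application/json"})
        urllib.request.urlopen(req, timeout=self.timeout).close()


class SmtpSink:
    """Thin e-mail notifier; deliberately minimal (host, port, addresses)."""

    name = "smtp"

    def __init__(self, host: str, port: int, sender: str, recipients: list[str]):
        self.host, self.port = host, port
        self.sender, self.recipients = sender, recipients

    def deliver(self, event: WarningEvent) -> None:
        msg = EmailMessage()
        msg["Subject"] = f"QC warning: {event.metric} = {event.value:g}"
        msg["From"] = self.sender
        msg["To"] = ", ".join(self.recipients)
        msg.set_content(
            f"Rule {event.rule_key} fired on file {event.file_id}: "
            f"{event.metric}={event.value:g} (target {event.target})")
        with smtplib.SMTP(self.host, self.port, timeout=10) as smtp:
            smtp.send_message(msg)


@dataclass
class Delivery:
    event: WarningEvent
    sink: str
    delivered: bool
    error: str | None = None


def notify(events: Iterable[WarningEvent], sinks: Sequence[Sink] | None = None,
           store: QCStore | None = None) -> list[Delivery]:
    """Deliver each event to each sink at most once; failures are isolated."""
    sinks = list(sinks) if sinks is not None else [LogSink(store)]
    report: list[Delivery] = []
    for event in events:
        for sink in sinks:
            try:
                sink.deliver(event)
                d = Delivery(event, sink.name, True)
            except Exception as exc:
                logger.error("sink %s failed for %s: %s", sink.name,
                             event.rule_key, exc)
                d = Delivery(event, sink.name, False, str(exc))
            report.append(d)
            if store is not None and event.event_id is not None:
                store.record_delivery(event.event_id, sink.name,
                                      d.delivered, d.error)
    return report
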