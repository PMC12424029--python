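"""Reading mzML runs into in-memory spectra and run-level metadata.

The reader is deliberately narrow: centroided MS1 (or any single MS level)
spectra with base64-encoded binary arrays, 32- or 64-bit floats, zlib or no
compression, plain or gzip-compressed files.  Scan times are converted to
minutes on read, which is the canonical retention-time unit throughout the
package.  Writing mzML lives in :mod:`lcmsqc.synthetic_data`.
"""

from __future__ import annotations

import base64
import gzip
import hashlib
import logging
import os
import zlib
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import IO, Iterator, Sequence

import numpy as np
from lxml import etree

from .errors import EmptyRunError, InputError, ParseError

logger = logging.getLogger(__name__)

_NS = "{http://psi.hupo.org/ms/mzml}"

# PSI-MS controlled-vocabulary accessions understood by the reader.
_ACC_MS_LEVEL = "MS:1000511"
_ACC_SCAN_START = "MS:1000016"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_ACC_64BIT = "MS:1000523"
_ACC_32BIT = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_NOCOMP = "MS:1000576"


@dataclass
class Spectrum:
    """One MS scan: retention time plus parallel m/z / intensity arrays.

    Attributes
    ----------
    rt : float
        Scan start time in minutes, non-negative.
    mz : numpy.ndarray
        Strictly increasing m/z values (Th).
    intensity : numpy.ndarray
        Non-negative intensities, same length as ``mz``.
    ms_level : int
        MS level of the scan (1 for survey scans).
    """

    rt: float
    mz: np.ndarray
    intensity: np.ndarray
    ms_level: int = 1

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")


@dataclass
class RunMetadata:
    """Run-level metadata extracted from one mzML file."""

    path: str
    acquisition_time: datetime
    n_spectra: int
    rt_range: tuple[float, float]
    checksum: str
    acquisition_time_is_fallback: bool = field(default=False)


def file_checksum(path: str | os.PathLike) -> str:
    """SHA-1 of the file *content* (moved files keep their identity)."""
    h = hashlib.sha1()
    try:
        with open(path, "rb") as fh:
            for chunk in iter(lambda: fh.read(1 << 20), b""):
                h.update(chunk)
    except OSError as exc:
        raise InputError(f"cannot read {path}: {exc}") from exc
    return h.hexdigest()


def _open_maybe_gzip(path: str | os.PathLike) -> IO[bytes]:
    fh = open(path, "rb")
    magic = fh.read(2)
    fh.seek(0)
    if magic == b"\x1f\x8b":
        return gzip.open(fh, "rb")  # type: ignore[return-value]
    return fh


def _cv_params(elem: etree._Element) -> dict[str, str]:
    out = {}
    for cv in elem.iterfind(f"{_NS}cvParam"):
        out[cv.get("accession")] = cv.get("value", "")
    return out


def _scan_time_minutes(spectrum_elem: etree._Element, index: int) -> float:
    for scan in spectrum_elem.iter(f"{_NS}scan"):
        for cv in scan.iterfind(f"{_NS}cvParam"):
            if cv.get("accession") == _ACC_SCAN_START:
                value = float(cv.get("value"))
                unit = (cv.get("unitName") or "").lower()
                if unit.startswith("second"):
                    return value / 60.0
                return value
    raise ParseError(f"spectrum index {index}: no scan start time")


def _decode_binary(bda: etree._Element, index: int) -> np.ndarray:
    accs = _cv_params(bda)
    binary = bda.find(f"{_NS}binary")
    if binary is None:
        raise ParseError(f"spectrum index {index}: missing <binary> payload")
    if not (binary.text or "").strip():
        return np.empty(0, dtype=np.float64)
    raw = base64.b64decode(binary.text)
    if _ACC_ZLIB in accs:
        raw = zlib.decompress(raw)
    dtype = np.float32 if _ACC_32BIT in accs else np.float64
    return np.frombuffer(raw, dtype=dtype).astype(np.float64)


def _parse_spectrum(elem: etree._Element, index: int) -> Spectrum:
    accs = _cv_params(elem)
    ms_level = int(accs.get(_ACC_MS_LEVEL, "1") or "1")
    rt = _scan_time_minutes(elem, index)
    mz = intensity = None
    for bda in elem.iter(f"{_NS}binaryDataArray"):
        arr_accs = _cv_params(bda)
        if _ACC_MZ_ARRAY in arr_accs:
            mz = _decode_binary(bda, index)
        elif _ACC_INT_ARRAY in arr_accs:
            intensity = _decode_binary(bda, index)
    if mz is None or intensity is None:
        raise ParseError(f"spectrum index {index}: missing m/z or intensity array")
    if len(mz) != len(intensity):
        raise ParseError(f"spectrum index {index}: array length mismatch")
    if len(mz) > 1 and np.any(np.diff(mz) <= 0):
        logger.warning("spectrum index %d: unsorted m/z array, sorting", index)
        order = np.argsort(mz, kind="stable")
        mz, intensity = mz[order], intensity[order]
    return Spectrum(rt=rt, mz=mz, intensity=intensity, ms_level=ms_level)


def _iter_spectra(path: str | os.PathLike) -> Iterator[Spectrum]:
    with _open_maybe_gzip(path) as fh:
        try:
            context = etree.iterparse(fh, events=("end",), tag=f"{_NS}spectrum")
            for _, elem in context:
                index = int(elem.get("index", "-1"))
                yield _parse_spectrum(elem, index)
                elem.clear(keep_tail=True)
        except etree.XMLSyntaxError as exc:
            raise ParseError(f"{path}: malformed mzML: {exc}") from exc


def read_spectra(path: str | os.PathLike, ms_level_filter: int = 1) -> list[Spectrum]:
    """Read all spectra of one MS level, sorted by retention time.

    Parameters
    ----------
    path : path-like
        mzML or gzip-compressed mzML file.
    ms_level_filter : int
        Only spectra of this MS level are returned (default 1).

    Returns
    -------
    list of Spectrum
        In ascending retention-time order; m/z arrays sorted ascending
        (unsorted files are fixed up with a logged warning).

    Raises
    ------
    InputError
        The file does not exist.
    ParseError
        Malformed XML or missing binary arrays (the message names the
        offending scan index).
    EmptyRunError
        No spectra at the requested MS level.
    """
    if not Path(path).is_file():
        raise InputError(f"no such file: {path}")
    spectra = [s for s in _iter_spectra(path) if s.ms_level == ms_level_filter]
    if not spectra:
        raise EmptyRunError(f"{path}: no MS{ms_level_filter} spectra")
    spectra.sort(key=lambda s: s.rt)
    return spectra


def read_run_metadata(path: str | os.PathLike) -> RunMetadata:
    """Extract run-level metadata: acquisition time, scan count, RT range.

    The acquisition time comes from the run ``startTimeStamp`` attribute
    when present; otherwise the file modification time is used and the
    record is flagged as a fallback.
    """
    if not Path(path).is_file():
        raise InputError(f"no such file: {path}")
    checksum = file_checksum(path)

    start_time: datetime | None = None
    rts: list[float] = []
    n = 0
    with _open_maybe_gzip(path) as fh:
        try:
            for event, elem in etree.iterparse(
                fh, events=("start", "end"), tag=(f"{_NS}run", f"{_NS}spectrum")
            ):
                if elem.tag == f"{_NS}run":
                    if event == "start":
                        stamp = elem.get("startTimeStamp")
                        if stamp and start_time is None:
                            start_time = _parse_timestamp(stamp)
                elif event == "end":
                    rts.append(_scan_time_minutes(elem, n))
                    n += 1
                    elem.clear(keep_tail=True)
        except etree.XMLSyntaxError as exc:
            raise ParseError(f"{path}: malformed mzML: {exc}") from exc

    fallback = start_time is None
    if fallback:
        start_time = datetime.fromtimestamp(os.path.getmtime(path), tz=timezone.utc)
        logger.warning("%s: no startTimeStamp, falling back to file mtime", path)
    rt_range = (min(rts), max(rts)) if rts else (0.0, 0.0)
    return RunMetadata(
        path=str(path),
        acquisition_time=start_time,
        n_spectra=n,
        rt_range=rt_range,
        checksum=checksum,
        acquisition_time_is_fallback=fallback,
    )


def _parse_timestamp(stamp: str) -> datetime:
    s = stamp.replace("Z", "+00:00")
    dt = datetime.fromisoformat(s)
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return dt.astimezone(timezone.utc)


def rt_sorted(spectra: Sequence[Spectrum]) -> list[Spectrum]:
    """Return spectra sorted by retention time (stable)."""
    return sorted(spectra, key=lambda s: s.rt)
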