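"""Targeted tracking of user-defined compounds across runs.

For each file and each tracked compound an extracted-ion chromatogram
(EIC) is built inside a ppm window, the peak located by windowed argmax
around the expected retention time, and the diagnostic quality metrics
computed: observed m/z and its ppm deviation, observed RT and its
deviation, apex intensity, trapezoidal area, and the pharmacopeial peak
shape factors (USP tailing factor at 5% height, asymmetry factor at 10%
height).

Peak location is deliberately a windowed argmax rather than a general
chromatographic peak picker: tracked compounds have known retention
times, which keeps detection deterministic and parameter-free.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, EmptyRunError, InputError
from .mzml_io import RunMetadata, Spectrum

logger = logging.getLogger(__name__)

DEFAULT_TOL_PPM = 20.0
DEFAULT_RT_WINDOW = 0.5  # minutes


@dataclass
class TrackedCompound:
    """A monitoring target: name, target m/z, expected RT and scope."""

    name: str
    mz_target: float
    rt_expected: float
    instrument: str = "*"
    polarity: str = "*"

    def __post_init__(self) -> None:
        if self.mz_target <= 0:
            raise ConfigurationError(f"{self.name}: mz_target must be > 0")
        if self.rt_expected < 0:
            raise ConfigurationError(f"{self.name}: rt_expected must be >= 0")

    def in_scope(self, instrument: str, polarity: str) -> bool:
        return (self.instrument in ("*", instrument or "")) and (
            self.polarity in ("*", polarity or ""))


@dataclass
class EIC:
    """Extracted-ion chromatogram: one point per MS1 scan, zero-filled.

    ``mz_per_scan`` holds the intensity-weighted mean m/z of the in-window
    centroids of each scan (NaN where the scan has no signal in window).
    """

    rt: np.ndarray
    intensity: np.ndarray
    mz_lo: float
    mz_hi: float
    mz_per_scan: np.ndarray


@dataclass
class ShapeMetrics:
    tailing_factor: float | None
    asymmetry_factor: float | None
    reason: str | None = None


@dataclass
class PeakMetrics:
    """Per-file-per-compound QC record."""

    compound: str
    found: bool
    mz_target: float
    rt_expected: float
    mz_observed: float | None = None
    mz_dev_ppm: float | None = None
    rt_observed: float | None = None
    rt_dev: float | None = None
    intensity_apex: float | None = None
    area: float | None = None
    tailing_factor: float | None = None
    asymmetry_factor: float | None = None
    shape_reason: str | None = None


@dataclass
class TrackingParams:
    """Tunables for targeted extraction; defaults suit ESI-TOF data."""

    tol_ppm: float = DEFAULT_TOL_PPM
    rt_window: float = DEFAULT_RT_WINDOW
    min_intensity: float = 0.0
    min_consecutive_scans: int = 3   # reject single-spike noise
    integration_floor: float = 0.01  # fraction of apex bounding the integration


def ppm_deviation(mz_observed: float, mz_target: float) -> float:
    """Signed relative mass error in parts per million.

    (observed - target) / target * 1e6.
    """
    if mz_target <= 0:
        raise InputError("mz_target must be positive")
    return (mz_observed - mz_target) / mz_target * 1e6


def extract_eic(spectra: Sequence[Spectrum], mz_target: float,
                tol_ppm: float = DEFAULT_TOL_PPM) -> EIC:
    """Extract the chromatogram of ions within ±tol_ppm of ``mz_target``.

    The m/z window is half-open, ``[mz_target*(1-tol*1e-6),
    mz_target*(1+tol*1e-6))``, so window membership is deterministic.
    Per scan, intensity is the sum over in-window centroids and the
    observed m/z their intensity-weighted mean.
    """
    if not spectra:
        raise EmptyRunError("no spectra to extract from")
    lo = mz_target * (1.0 - tol_ppm * 1e-6)
    hi = mz_target * (1.0 + tol_ppm * 1e-6)
    n = len(spectra)
    rt = np.fromiter((s.rt for s in spectra), dtype=np.float64, count=n)
    intensity = np.zeros(n)
    mz_per_scan = np.full(n, np.nan)
    for i, s in enumerate(spectra):
        a = np.searchsorted(s.mz, lo, side="left")
        b = np.searchsorted(s.mz, hi, side="left")
        if b > a:
            w = s.intensity[a:b]
            total = float(w.sum())
            intensity[i] = total
            if total > 0:
                mz_per_scan[i] = float((s.mz[a:b] * w).sum() / total)
            else:
                mz_per_scan[i] = float(s.mz[a:b].mean())
    return EIC(rt=rt, intensity=intensity, mz_lo=lo, mz_hi=hi, mz_per_scan=mz_per_scan)


def find_peak(eic: EIC, rt_expected: float, rt_window: float = DEFAULT_RT_WINDOW,
              min_intensity: float = 0.0, min_consecutive_scans: int = 1,
              ) -> tuple[float, float, int] | None:
    """Locate the apex inside ``rt_expected ± rt_window``.

    Returns (rt_apex, intensity_apex, apex_index) or None when nothing
    rises above ``min_intensity`` (or the apex is an isolated spike when
    ``min_consecutive_scans`` > 1).  Ties are broken by proximity to the
    expected RT, then by the earlier scan.
    """
    if rt_window <= 0:
        raise InputError("rt_window must be positive")
    if len(eic.rt) == 0:
        return None
    mask = (eic.rt >= rt_expected - rt_window) & (eic.rt <= rt_expected + rt_window)
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return None
    seg = eic.intensity[idx]
    peak = float(seg.max())
    if peak <= min_intensity or peak <= 0:
        return None
    ties = idx[seg == peak]
    apex = int(min(ties, key=lambda i: (abs(eic.rt[i] - rt_expected), eic.rt[i])))
    if min_consecutive_scans > 1 and len(eic.rt) >= min_consecutive_scans:
        lo = hi = apex
        while lo > 0 and eic.intensity[lo - 1] > 0:
            lo -= 1
        while hi < len(eic.intensity) - 1 and eic.intensity[hi + 1] > 0:
            hi += 1
        if hi - lo + 1 < min_consecutive_scans:
            return None
    return float(eic.rt[apex]), peak, apex


def _crossing(eic: EIC, apex: int, level: float, side: int) -> float | None:
    """RT where the EIC crosses ``level`` walking from the apex outward.

    ``side`` is -1 (leading edge) or +1 (trailing edge); linear
    interpolation between the bracketing scans; None if the crossing is
    not bracketed inside the chromatogram.
    """
    i = apex
    n = len(eic.intensity)
    while 0 <= i + side < n:
        j = i + side
        if eic.intensity[j] <= level:
            y0, y1 = eic.intensity[i], eic.intensity[j]
            if y0 == y1:
                return float(eic.rt[j])
            frac = (y0 - level) / (y0 - y1)
            return float(eic.rt[i] + frac * (eic.rt[j] - eic.rt[i]))
        i = j
    return None


def peak_shape(eic: EIC, apex_index: int) -> ShapeMetrics:
    """USP tailing factor (5% height) and asymmetry factor (10% height).

    tailing = W05 / (2 f) with W05 the full width at 5% of apex height
    and f the apex-to-leading-edge distance at that height; asymmetry =
    b/a, the trailing over leading half-width at 10% height.  Crossings
    are located by linear interpolation; when a crossing is not bracketed
    inside the EIC both factors are None with a reason.
    """
    apex_i = int(apex_index)
    h = float(eic.intensity[apex_i])
    if h <= 0:
        return ShapeMetrics(None, None, "zero apex intensity")
    if apex_i in (0, len(eic.intensity) - 1):
        return ShapeMetrics(None, None, "apex on chromatogram boundary")
    t_apex = float(eic.rt[apex_i])
    left5 = _crossing(eic, apex_i, 0.05 * h, -1)
    right5 = _crossing(eic, apex_i, 0.05 * h, +1)
    left10 = _crossing(eic, apex_i, 0.10 * h, -1)
    right10 = _crossing(eic, apex_i, 0.10 * h, +1)
    if None in (left5, right5, left10, right10):
        return ShapeMetrics(None, None, "unbracketed crossing")
    f = t_apex - left5
    a = t_apex - left10
    if f <= 0 or a <= 0:
        return ShapeMetrics(None, None, "degenerate leading edge")
    tailing = (right5 - left5) / (2.0 * f)
    asymmetry = (right10 - t_apex) / a
    return ShapeMetrics(tailing, asymmetry)


def integration_bounds(eic: EIC, apex_index: int, floor_frac: float = 0.01
                       ) -> tuple[int, int]:
    """Contiguous scan range [lo, hi] around the apex.

    Extends while the signal stays above ``floor_frac`` of the apex and
    keeps falling; stops at the first local minimum or the floor,
    whichever comes first.
    """
    h = eic.intensity[apex_index]
    floor = floor_frac * h
    lo = apex_index
    while lo > 0 and eic.intensity[lo - 1] >= floor and eic.intensity[lo - 1] <= eic.intensity[lo]:
        lo -= 1
    hi = apex_index
    n = len(eic.intensity)
    while hi < n - 1 and eic.intensity[hi + 1] >= floor and eic.intensity[hi + 1] <= eic.intensity[hi]:
        hi += 1
    return lo, hi


def track_file(spectra: Sequence[Spectrum], run: RunMetadata | None,
               targets: Sequence[TrackedCompound],
               params: TrackingParams | None = None) -> list[PeakMetrics]:
    """Compute one PeakMetrics record per tracked compound for one run.

    ``targets`` should already be filtered to the file's instrument and
    polarity scope.  Observed m/z is the EIC-intensity-weighted mean of
    the per-scan m/z values inside the integration bounds; the area is
    the trapezoidal integral of the EIC over the same bounds.  A failure
    on one target never aborts the others.
    """
    params = params or TrackingParams()
    out: list[PeakMetrics] = []
    for t in targets:
        rec = PeakMetrics(compound=t.name, found=False,
                          mz_target=t.mz_target, rt_expected=t.rt_expected)
        try:
            eic = extract_eic(spectra, t.mz_target, params.tol_ppm)
            hit = find_peak(eic, t.rt_expected, params.rt_window,
                            params.min_intensity, params.min_consecutive_scans)
            if hit is None:
                out.append(rec)
                continue
            rt_apex, apex_int, apex_i = hit
            lo, hi = integration_bounds(eic, apex_i, params.integration_floor)
            seg = slice(lo, hi + 1)
            w = eic.intensity[seg]
            mzs = eic.mz_per_scan[seg]
            valid = ~np.isnan(mzs) & (w > 0)
            if valid.any():
                mz_obs = float((mzs[valid] * w[valid]).sum() / w[valid].sum())
            else:
                mz_obs = float(eic.mz_per_scan[apex_i])
            if math.isnan(mz_obs):
                out.append(rec)
                continue
            area = float(np.trapezoid(eic.intensity[seg], eic.rt[seg]))
            shape = peak_shape(eic, apex_i)
            rec = PeakMetrics(
                compound=t.name, found=True,
                mz_target=t.mz_target, rt_expected=t.rt_expected,
                mz_observed=mz_obs,
                mz_dev_ppm=ppm_deviation(mz_obs, t.mz_target),
                rt_observed=rt_apex,
                rt_dev=rt_apex - t.rt_expected,
                intensity_apex=apex_int,
                area=area,
                tailing_factor=shape.tailing_factor,
                asymmetry_factor=shape.asymmetry_factor,
                shape_reason=shape.reason,
            )
        except EmptyRunError:
            raise
        except Exception as exc:  # pragma: no cover - per-target isolation
            logger.error("tracking %s failed: %s", t.name, exc)
        out.append(rec)
    return out


def load_compound_list(path: str | Path) -> list[TrackedCompound]:
    """Read the tracked-compound CSV: name, mz, rt, instrument, polarity.

    ``rt`` is in minutes; ``*`` is the wildcard scope for instrument and
    polarity.
    """
    required = {"name", "mz", "rt"}
    compounds: list[TrackedCompound] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ConfigurationError(
                f"compound list needs columns {sorted(required)}, got {reader.fieldnames}")
        for row in reader:
            compounds.append(TrackedCompound(
                name=row["name"].strip(),
                mz_target=float(row["mz"]),
                rt_expected=float(row["rt"]),
                instrument=(row.get("instrument") or "*").strip() or "*",
                polarity=(row.get("polarity") or "*").strip() or "*",
            ))
    return compounds
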