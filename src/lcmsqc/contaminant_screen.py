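"""Per-file screening of known contaminant ions.

Each contaminant on the list gets an EIC over the whole run (shared
extractor with compound tracking) summarized two ways: the EIC maximum,
a good peak-height estimate for retained, peak-like contaminants such as
nylon oligomers, and the EIC mean over *all* MS1 scans (zero-filled),
which discriminates pervasive background such as polyethylene glycols
from transient signals.  The mean's denominator is the total scan count
by design — a contaminant present in one scan out of a hundred averages
to 1% of its height, while a constant trace keeps its full level.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

from .compound_tracking import DEFAULT_TOL_PPM, extract_eic
from .errors import ConfigurationError, EmptyRunError
from .mzml_io import Spectrum

logger = logging.getLogger(__name__)

_REQUIRED_COLUMNS = {"name", "mz", "polarity", "source_class"}


@dataclass(frozen=True)
class ContaminantIon:
    name: str
    mz: float
    polarity: str = "*"
    source_class: str = ""

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ConfigurationError(f"{self.name}: mz must be > 0")


@dataclass
class ContaminantReading:
    """Per-file-per-contaminant summary; eic_max >= eic_mean always."""

    contaminant: str
    mz: float
    eic_max: float
    eic_mean: float


def load_contaminant_list(path: str | Path | None = None) -> list[ContaminantIon]:
    """Load and validate a contaminant-ion CSV; None loads the bundled list.

    Required columns: ``name,mz,polarity,source_class``.  Duplicate
    (name, mz, polarity) rows are dropped first-wins with a warning.
    """
    if path is None:
        ref = resources.files("lcmsqc.data").joinpath("contaminants.csv")
        with resources.as_file(ref) as p:
            return load_contaminant_list(p)
    ions: list[ContaminantIon] = []
    seen: set[tuple[str, float, str]] = set()
    with open(path, newline="") as fh:
        rows = (line for line in fh if not line.startswith("#"))
        reader = csv.DictReader(rows)
        if reader.fieldnames is None or not _REQUIRED_COLUMNS.issubset(reader.fieldnames):
            raise ConfigurationError(
                f"contaminant list needs columns {sorted(_REQUIRED_COLUMNS)}, "
                f"got {reader.fieldnames}")
        for row in reader:
            ion = ContaminantIon(
                name=row["name"].strip(),
                mz=float(row["mz"]),
                polarity=(row["polarity"] or "*").strip() or "*",
                source_class=(row["source_class"] or "").strip(),
            )
            key = (ion.name, ion.mz, ion.polarity)
            if key in seen:
                logger.warning("duplicate contaminant row dropped: %s", key)
                continue
            seen.add(key)
            ions.append(ion)
    return ions


def screen_file(spectra: Sequence[Spectrum], ions: Sequence[ContaminantIon],
                tol_ppm: float = DEFAULT_TOL_PPM) -> list[ContaminantReading]:
    """Screen one run against a contaminant list.

    ``ions`` should already be restricted to the file's polarity.  Per
    ion: eic_max is the maximum over scans, eic_mean the arithmetic mean
    over all MS1 scans including the zero-filled ones.
    """
    if not spectra:
        raise EmptyRunError("no spectra to screen")
    readings = []
    for ion in ions:
        eic = extract_eic(spectra, ion.mz, tol_ppm)
        readings.append(ContaminantReading(
            contaminant=ion.name,
            mz=ion.mz,
            eic_max=float(np.max(eic.intensity)),
            eic_mean=float(np.mean(eic.intensity)),
        ))
    return readings
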