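"""Ground-truthed synthetic mzML acquisition batches.

Every other module in the package is exercised against data produced here:
multi-run injection sequences with Gaussian or exponentially-modified
Gaussian (EMG) chromatographic peaks at configured m/z and RT, per-run
mass-calibration offsets (ppm), per-run retention-time shifts, exponential
intensity decay across the injection sequence, constant-baseline /
peak-like / single-scan-spike contaminants, and Poisson-like random noise
centroids.  The generator writes PSI-conformant mzML (64-bit, zlib,
centroid mode) plus a JSON ground-truth manifest recording the true drift
parameters of every run, which downstream tests use as the oracle.
"""

from __future__ import annotations

import base64
import json
import math
import zlib
from dataclasses import dataclass, field, asdict
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import erfcx

from .errors import ConfigurationError

_SQRT2 = math.sqrt(2.0)


@dataclass
class CompoundSpec:
    """A chromatographic peak to synthesize: position, height and shape.

    ``sigma`` is the Gaussian width in minutes; ``tau`` the exponential
    tailing constant in minutes (0 gives a pure Gaussian).
    """

    name: str
    mz: float
    rt: float
    height: float
    sigma: float = 0.05
    tau: float = 0.0


@dataclass
class ContaminantSpec:
    """A background ion: constant trace, retained peak, or one-scan spike.

    profile 'constant' puts ``level`` counts in every scan (PEG-like),
    'peak' a Gaussian peak of height ``level`` at mid-run (nylon-like),
    'spike' ``level`` counts in the single scan closest to mid-run.
    ``active_runs`` restricts the contaminant to those run indices
    (None = all runs).
    """

    name: str
    mz: float
    profile: str = "constant"
    level: float = 1000.0
    active_runs: Sequence[int] | None = None
    rt: float | None = None
    sigma: float | None = None


@dataclass
class BatchConfig:
    """Study conditions for one synthetic acquisition batch.

    Defaults describe a small but realistic QC sequence: 10 injections of
    50 scans at 3 s spacing (2.5 min runs), three tracked compounds
    spanning the m/z range, no drift, modest noise.
    """

    n_runs: int = 10
    scans_per_run: int = 50
    scan_interval: float = 0.05  # minutes
    compounds: list[CompoundSpec] = field(default_factory=lambda: [
        CompoundSpec("tryptophan", 205.0972, 1.20, 2.0e5),
        CompoundSpec("hippurate", 180.0655, 0.80, 1.0e5),
        CompoundSpec("lpc_18_0", 524.3711, 2.00, 3.0e5),
    ])
    ppm_offsets: Sequence[float] | None = None     # per run; None = all zero
    rt_shifts: Sequence[float] | None = None       # minutes per run; None = all zero
    intensity_decay: float = 1.0                   # multiplicative factor per injection
    contaminants: list[ContaminantSpec] = field(default_factory=list)
    noise_baseline: float = 0.0                    # mean of exponential noise intensities
    noise_centroids_per_scan: int = 0
    mz_noise_range: tuple[float, float] = (50.0, 1000.0)
    seed: int = 0
    start_time: datetime = field(
        default_factory=lambda: datetime(2022, 5, 1, 12, 0, 0, tzinfo=timezone.utc))
    injection_spacing: timedelta = field(default_factory=lambda: timedelta(minutes=15))
    project: str = "DemoProj"
    instrument: str = "SIM1"
    polarity: str = "POS"
    filename_pattern: str = "{project}_{date}_{instrument}_{mode}_{sample_id}.mzML"

    def validate(self) -> None:
        bad = []
        if self.n_runs <= 0:
            bad.append("n_runs must be positive")
        if self.scans_per_run <= 0:
            bad.append("scans_per_run must be positive")
        if self.scan_interval <= 0:
            bad.append("scan_interval must be positive")
        for c in self.compounds:
            if c.sigma <= 0:
                bad.append(f"compound {c.name}: sigma must be > 0")
            if c.tau < 0:
                bad.append(f"compound {c.name}: tau must be >= 0")
            if c.height < 0:
                bad.append(f"compound {c.name}: height must be >= 0")
        for c in self.contaminants:
            if c.level < 0:
                bad.append(f"contaminant {c.name}: level must be >= 0")
            if c.profile not in ("constant", "peak", "spike"):
                bad.append(f"contaminant {c.name}: unknown profile {c.profile!r}")
        for name, seq in (("ppm_offsets", self.ppm_offsets), ("rt_shifts", self.rt_shifts)):
            if seq is not None and len(seq) != self.n_runs:
                bad.append(f"{name} must have length n_runs ({self.n_runs})")
        if self.intensity_decay < 0:
            bad.append("intensity_decay must be >= 0")
        if bad:
            raise ConfigurationError("; ".join(bad))


def emg_shape(t: np.ndarray, mu: float, sigma: float, tau: float) -> np.ndarray:
    """Exponentially-modified Gaussian, normalized to unit peak height.

    Evaluated via the scaled complementary error function ``erfcx`` for
    numerical stability: with u = (t-mu)/sigma and v = sigma/tau the EMG
    density is proportional to ``v * erfcx((v - u)/sqrt(2)) * exp(-u^2/2)``.
    tau = 0 degenerates to a pure Gaussian.
    """
    t = np.asarray(t, dtype=np.float64)
    u = (t - mu) / sigma
    if tau <= 0:
        return np.exp(-0.5 * u * u)
    v = sigma / tau
    raw = erfcx((v - u) / _SQRT2) * np.exp(-0.5 * u * u)
    # normalize to unit apex on a dense grid spanning the peak
    grid = np.linspace(mu - 6 * sigma, mu + 6 * sigma + 8 * tau, 20001)
    ug = (grid - mu) / sigma
    peak = float(np.max(erfcx((v - ug) / _SQRT2) * np.exp(-0.5 * ug * ug)))
    return raw / peak


def simulate_run_arrays(
    config: BatchConfig, run_index: int
) -> tuple[np.ndarray, list[np.ndarray], list[np.ndarray]]:
    """Build one run's scan grid and per-scan centroid arrays.

    Pure function of (config, run_index): the writer serializes exactly
    these arrays, and tests use the same call as the round-trip oracle.

    Returns
    -------
    (rt, mz_arrays, intensity_arrays)
        ``rt`` in minutes, one (mz, intensity) centroid pair of arrays
        per scan, m/z sorted ascending.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, run_index]))
    rt = np.arange(config.scans_per_run) * config.scan_interval
    ppm = config.ppm_offsets[run_index] if config.ppm_offsets is not None else 0.0
    shift = config.rt_shifts[run_index] if config.rt_shifts is not None else 0.0
    decay = config.intensity_decay ** run_index

    mz_cols: list[np.ndarray] = []
    int_cols: list[np.ndarray] = []
    for c in config.compounds:
        profile = c.height * decay * emg_shape(rt, c.rt + shift, c.sigma, c.tau)
        profile[profile < 1e-6 * max(c.height, 1.0)] = 0.0
        mz_cols.append(np.full_like(rt, c.mz * (1.0 + ppm * 1e-6)))
        int_cols.append(profile)

    mid = config.scans_per_run // 2
    for c in config.contaminants:
        if c.active_runs is not None and run_index not in c.active_runs:
            continue
        if c.profile == "constant":
            profile = np.full_like(rt, c.level)
        elif c.profile == "spike":
            profile = np.zeros_like(rt)
            profile[mid] = c.level
        else:  # peak
            mu = c.rt if c.rt is not None else rt[mid]
            sigma = c.sigma if c.sigma is not None else 4 * config.scan_interval
            profile = c.level * emg_shape(rt, mu, sigma, 0.0)
            profile[profile < 1e-6 * max(c.level, 1.0)] = 0.0
        mz_cols.append(np.full_like(rt, c.mz))
        int_cols.append(profile)

    mz_scans: list[np.ndarray] = []
    int_scans: list[np.ndarray] = []
    for i in range(config.scans_per_run):
        mzs = [col[i] for col, icol in zip(mz_cols, int_cols) if icol[i] > 0]
        ints = [icol[i] for icol in int_cols if icol[i] > 0]
        if config.noise_centroids_per_scan > 0 and config.noise_baseline > 0:
            nm = rng.uniform(*config.mz_noise_range, size=config.noise_centroids_per_scan)
            ni = rng.exponential(config.noise_baseline, size=config.noise_centroids_per_scan)
            mzs.extend(nm.tolist())
            ints.extend(ni.tolist())
        mza = np.asarray(mzs, dtype=np.float64)
        ina = np.asarray(ints, dtype=np.float64)
        order = np.argsort(mza, kind="stable")
        mz_scans.append(mza[order])
        int_scans.append(ina[order])
    return rt, mz_scans, int_scans


# ---------------------------------------------------------------------------
# mzML writing

def _b64(arr: np.ndarray) -> str:
    if len(arr) == 0:
        return ""  # pwiz-compatible empty payload
    return base64.b64encode(zlib.compress(np.asarray(arr, np.float64).tobytes())).decode()


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
<cvList count="2">
<cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
<cv id="UO" fullName="Unit Ontology" URI="http://ontologies.berkeleybop.org/uo.obo"/>
</cvList>
<fileDescription><fileContent><cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/></fileContent></fileDescription>
<softwareList count="1"><software id="lcmsqc_sim" version="0.1"><cvParam cvRef="MS" accession="MS:1000799" name="custom unreleased software tool" value="lcmsqc synthetic generator"/></software></softwareList>
<instrumentConfigurationList count="1"><instrumentConfiguration id="IC1"><cvParam cvRef="MS" accession="MS:1000031" name="instrument model" value=""/></instrumentConfiguration></instrumentConfigurationList>
<dataProcessingList count="1"><dataProcessing id="DP1"><processingMethod order="1" softwareRef="lcmsqc_sim"><cvParam cvRef="MS" accession="MS:1000544" name="Conversion to mzML" value=""/></processingMethod></dataProcessing></dataProcessingList>
"""


def _spectrum_xml(index: int, rt_min: float, mz: np.ndarray, inten: np.ndarray,
                  ms_level: int = 1) -> str:
    b_mz, b_in = _b64(mz), _b64(inten)
    return (
        f'<spectrum index="{index}" id="scan={index + 1}" defaultArrayLength="{len(mz)}">\n'
        f'<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{ms_level}"/>\n'
        f'<cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>\n'
        f'<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>\n'
        f'<scanList count="1"><cvParam cvRef="MS" accession="MS:1000795" name="no combination" value=""/>\n'
        f'<scan><cvParam cvRef="MS" accession="MS:1000016" name="scan start time" '
        f'value="{rt_min!r}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/></scan>'
        f'</scanList>\n<binaryDataArrayList count="2">\n'
        f'<binaryDataArray encodedLength="{len(b_mz)}">\n'
        f'<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>\n'
        f'<cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>\n'
        f'<cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" '
        f'unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>\n'
        f'<binary>{b_mz}</binary></binaryDataArray>\n'
        f'<binaryDataArray encodedLength="{len(b_in)}">\n'
        f'<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>\n'
        f'<cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>\n'
        f'<cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" '
        f'unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>\n'
        f'<binary>{b_in}</binary></binaryDataArray>\n'
        f'</binaryDataArrayList></spectrum>\n'
    )


def write_mzml(
    path: str | Path,
    rt: np.ndarray,
    mz_scans: Sequence[np.ndarray],
    int_scans: Sequence[np.ndarray],
    start_time: datetime | None = None,
    run_id: str = "run1",
) -> None:
    """Serialize one run as centroid-mode mzML (64-bit floats, zlib)."""
    stamp = ""
    if start_time is not None:
        stamp = f' startTimeStamp="{start_time.strftime("%Y-%m-%dT%H:%M:%SZ")}"'
    parts = [_MZML_HEADER,
             f'<run id="{run_id}"{stamp} defaultInstrumentConfigurationRef="IC1">\n'
             f'<spectrumList count="{len(rt)}" defaultDataProcessingRef="DP1">\n']
    for i, (t, mza, ina) in enumerate(zip(rt, mz_scans, int_scans)):
        parts.append(_spectrum_xml(i, float(t), mza, ina))
    parts.append("</spectrumList></run></mzML>\n")
    Path(path).write_text("".join(parts))


# ---------------------------------------------------------------------------
# batch generation

def generate_batch(config: BatchConfig, out_dir: str | Path) -> tuple[list[Path], dict]:
    """Write a full acquisition batch and its ground-truth manifest.

    Returns the generated mzML paths (injection order) and the manifest
    dictionary; the manifest is also written to ``manifest.json`` next to
    the files.  Identical seeds produce byte-identical manifests.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    runs = []
    for r in range(config.n_runs):
        rt, mz_scans, int_scans = simulate_run_arrays(config, r)
        acq = config.start_time + r * config.injection_spacing
        name = config.filename_pattern.format(
            project=config.project,
            date=acq.strftime("%Y%m%d"),
            instrument=config.instrument,
            mode=config.polarity,
            sample_id=f"QC{r + 1:03d}",
        )
        path = out / name
        write_mzml(path, rt, mz_scans, int_scans, start_time=acq, run_id=f"run{r + 1}")
        paths.append(path)

        ppm = float(config.ppm_offsets[r]) if config.ppm_offsets is not None else 0.0
        shift = float(config.rt_shifts[r]) if config.rt_shifts is not None else 0.0
        decay = config.intensity_decay ** r
        runs.append({
            "filename": name,
            "acquisition_time": acq.strftime("%Y-%m-%dT%H:%M:%SZ"),
            "ppm_offset": ppm,
            "rt_shift": shift,
            "apex_intensity": {c.name: c.height * decay for c in config.compounds},
            "contaminant_levels": {
                c.name: (c.level if (c.active_runs is None or r in c.active_runs) else 0.0)
                for c in config.contaminants
            },
        })
    manifest = {
        "config": _config_dict(config),
        "runs": runs,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return paths, manifest


def _config_dict(config: BatchConfig) -> dict:
    d = asdict(config)
    d["start_time"] = config.start_time.strftime("%Y-%m-%dT%H:%M:%SZ")
    d["injection_spacing"] = config.injection_spacing.total_seconds()
    d["ppm_offsets"] = list(map(float, config.ppm_offsets)) if config.ppm_offsets is not None else None
    d["rt_shifts"] = list(map(float, config.rt_shifts)) if config.rt_shifts is not None else None
    return json.loads(json.dumps(d))  # normalize tuples to JSON types
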