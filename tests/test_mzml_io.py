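"""mzML reading: round-trip fidelity, filtering, robustness, metadata."""

import gzip
from datetime import datetime, timezone

import numpy as np
import pytest

from lcmsqc import mzml_io
from lcmsqc.errors import EmptyRunError, InputError
from lcmsqc.synthetic_data import (BatchConfig, generate_batch,
                                   simulate_run_arrays, write_mzml)


def _tiny_run(tmp_path, n=10, stamp=datetime(2022, 5, 1, 12, 0, tzinfo=timezone.utc)):
    rt = np.arange(n) * 0.1
    mz = [np.array([100.0, 200.0 + i]) for i in range(n)]
    inten = [np.array([1000.0, 500.0]) for _ in range(n)]
    path = tmp_path / "run.mzML"
    write_mzml(path, rt, mz, inten, start_time=stamp)
    return path, rt, mz, inten


def test_round_trip_recovers_generated_ground_truth(batch):
    """Scan counts, RTs and all centroid values survive the write/read cycle."""
    config = batch["config"]
    for run_index, path in enumerate(batch["paths"]):
        rt, mz_scans, int_scans = simulate_run_arrays(config, run_index)
        spectra = mzml_io.read_spectra(path)
        assert len(spectra) == config.scans_per_run
        for s, t, mza, ina in zip(spectra, rt, mz_scans, int_scans):
            assert s.rt == pytest.approx(t, abs=1e-6)
            np.testing.assert_allclose(s.mz, mza, rtol=1e-6)
            np.testing.assert_allclose(s.intensity, ina, rtol=1e-6)


def test_ten_scan_file_yields_ten_spectra_with_expected_rts(tmp_path):
    path, rt, _, _ = _tiny_run(tmp_path)
    spectra = mzml_io.read_spectra(path)
    assert [s.rt for s in spectra] == pytest.approx(list(rt))


def test_ms_level_filter_keeps_only_requested_level(tmp_path):
    # hand-craft a file with one MS2 scan interleaved
    from lcmsqc.synthetic_data import _MZML_HEADER, _spectrum_xml
    parts = [_MZML_HEADER, '<run id="r" startTimeStamp="2022-05-01T12:00:00Z" '
             'defaultInstrumentConfigurationRef="IC1">'
             '<spectrumList count="3" defaultDataProcessingRef="DP1">']
    parts.append(_spectrum_xml(0, 0.0, np.array([100.0]), np.array([10.0]), ms_level=1))
    parts.append(_spectrum_xml(1, 0.1, np.array([50.0]), np.array([5.0]), ms_level=2))
    parts.append(_spectrum_xml(2, 0.2, np.array([100.0]), np.array([20.0]), ms_level=1))
    parts.append("</spectrumList></run></mzML>")
    path = tmp_path / "mixed.mzML"
    path.write_text("".join(parts))
    spectra = mzml_io.read_spectra(path, ms_level_filter=1)
    assert len(spectra) == 2
    assert all(s.ms_level == 1 for s in spectra)


def test_shuffled_mz_array_is_returned_sorted(tmp_path, caplog):
    """An unsorted scan is fixed up to the sorting oracle's order and logged."""
    rt = np.array([0.0])
    mz = np.array([300.0, 100.0, 200.0])
    inten = np.array([3.0, 1.0, 2.0])
    path = tmp_path / "shuffled.mzML"
    write_mzml(path, rt, [mz], [inten])
    with caplog.at_level("WARNING", logger="lcmsqc.mzml_io"):
        spectra = mzml_io.read_spectra(path)
    order = np.argsort(mz)
    np.testing.assert_array_equal(spectra[0].mz, mz[order])
    np.testing.assert_array_equal(spectra[0].intensity, inten[order])
    assert any("unsorted" in r.message for r in caplog.records)


def test_spectra_returned_rt_ascending_even_if_file_is_not(tmp_path):
    rt = np.array([0.5, 0.1, 0.3])
    path = tmp_path / "unordered.mzML"
    write_mzml(path, rt, [np.array([100.0])] * 3, [np.array([1.0])] * 3)
    spectra = mzml_io.read_spectra(path)
    assert [s.rt for s in spectra] == sorted(rt.tolist())


def test_gzip_compressed_file_is_accepted(tmp_path):
    path, rt, _, _ = _tiny_run(tmp_path)
    gz = tmp_path / "run.mzML.gz"
    gz.write_bytes(gzip.compress(path.read_bytes()))
    assert len(mzml_io.read_spectra(gz)) == len(rt)


def test_missing_file_and_empty_run_errors(tmp_path):
    with pytest.raises(InputError):
        mzml_io.read_spectra(tmp_path / "nope.mzML")
    path, *_ = _tiny_run(tmp_path, n=3)
    with pytest.raises(EmptyRunError):
        mzml_io.read_spectra(path, ms_level_filter=2)


def test_run_metadata_round_trip(tmp_path):
    stamp = datetime(2022, 5, 1, 12, 0, tzinfo=timezone.utc)
    path, rt, _, _ = _tiny_run(tmp_path, stamp=stamp)
    md = mzml_io.read_run_metadata(path)
    assert md.acquisition_time == stamp
    assert not md.acquisition_time_is_fallback
    assert md.n_spectra == len(rt)
    assert md.rt_range == pytest.approx((rt[0], rt[-1]))


def test_missing_timestamp_falls_back_to_mtime(tmp_path):
    path, *_ = _tiny_run(tmp_path, stamp=None)
    md = mzml_io.read_run_metadata(path)
    assert md.acquisition_time_is_fallback
    assert md.acquisition_time is not None


def test_checksum_stable_and_content_addressed(tmp_path):
    path, *_ = _tiny_run(tmp_path)
    first = mzml_io.read_run_metadata(path).checksum
    assert mzml_io.read_run_metadata(path).checksum == first
    moved = tmp_path / "renamed.mzML"
    moved.write_bytes(path.read_bytes())
    assert mzml_io.file_checksum(moved) == first


def test_generated_mzml_is_readable_by_independent_reader(tmp_path):
    """Cross-check the writer against Bioconductor mzR (ProteoWizard code)."""
    import subprocess
    from lcmsqc.synthetic_data import CompoundSpec
    config = BatchConfig(n_runs=1, scans_per_run=8, seed=5,
                         compounds=[CompoundSpec("probe", 205.0972, 0.0, 1e5)])
    paths, _ = generate_batch(config, tmp_path)
    script = (
        'suppressMessages(library(mzR)); h <- openMSfile("%s"); '
        'hd <- header(h); p <- peaks(h, 1); '
        'cat(nrow(hd), paste(hd$retentionTime, collapse=","), '
        'paste(sprintf("%%.6f", p[,1]), collapse=","), sep="\\n")'
        % paths[0]
    )
    out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                         text=True, timeout=300)
    assert out.returncode == 0, out.stderr
    nscans, rts_sec, mz1 = out.stdout.strip().splitlines()[-3:]
    assert int(nscans) == 8
    rt, mz_scans, _ = simulate_run_arrays(config, 0)
    np.testing.assert_allclose(
        [float(x) for x in rts_sec.split(",")], rt * 60.0, atol=1e-6)
    np.testing.assert_allclose(
        [float(x) for x in mz1.split(",")], mz_scans[0], atol=1e-5)
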