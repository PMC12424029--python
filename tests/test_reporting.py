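"""Report views: time-lines, composition, heatmap clustering, calendar, render."""

from datetime import datetime, timezone

import numpy as np
import pandas as pd
import pytest

from lcmsqc import QCStore, QueryFilter
from lcmsqc.contaminant_screen import ContaminantReading
from lcmsqc.errors import QueryError
from lcmsqc.file_intake import FileRecord
from lcmsqc.reporting import (contaminant_heatmap, contaminant_timeseries,
                              metric_timeseries, productivity_calendar,
                              render_report, sample_composition)


def _store_with_readings(profiles: dict[str, list[float]],
                         projects=None) -> tuple[QCStore, list[int]]:
    """profiles: contaminant name -> per-file intensity list."""
    store = QCStore()
    n_files = len(next(iter(profiles.values())))
    ids = []
    for i in range(n_files):
        rec = FileRecord(
            path=f"/d/f{i}.mzML", checksum=f"c{i}",
            project=(projects[i] if projects else "ProjA"),
            ionization_mode="POS", sample_id=f"QC{i:03d}",
            acquisition_time=datetime(2022, 5, 1 + i // 12, 8 + i % 12,
                                      tzinfo=timezone.utc))
        fid = store.upsert_file(rec)
        store.insert_readings(fid, [
            ContaminantReading(name, 100.0 + k, levels[i], levels[i] / 2)
            for k, (name, levels) in enumerate(sorted(profiles.items()))])
        ids.append(fid)
    return store, ids


def test_metric_timeseries_monotone_under_linear_drift(processed):
    """A batch with per-run RT shifts reproduces those shifts in time order."""
    store = processed["store"]
    config = processed["config"]
    points, gaps = metric_timeseries(store, QueryFilter(), "rt_dev",
                                     config.compounds[0].name)
    truth = [r["rt_shift"] for r in processed["manifest"]["runs"]]
    assert len(points) + len(gaps) == len(truth)
    assert np.allclose(points["value"], truth[:len(points)],
                       atol=config.scan_interval)


def test_timeseries_unknown_compound_is_query_error(processed):
    with pytest.raises(QueryError):
        metric_timeseries(processed["store"], QueryFilter(), "rt_dev", "nope")


def test_timeseries_empty_filter_empty_series(processed):
    flt = QueryFilter(projects=["NoSuchProject"])
    points, gaps = metric_timeseries(processed["store"], flt, "rt_dev",
                                     processed["config"].compounds[0].name)
    assert points.empty and gaps.empty


def test_contaminant_timeseries_tracks_active_runs():
    store, _ = _store_with_readings({"peg": [0, 0, 500, 500, 500]})
    series = contaminant_timeseries(store, QueryFilter(), "peg", mode="max")
    assert list(series["value"]) == [0, 0, 500, 500, 500]
    with pytest.raises(QueryError):
        contaminant_timeseries(store, QueryFilter(), "peg", mode="median")


def test_sample_composition_sorted_truncated_zeros_suppressed():
    store, ids = _store_with_readings(
        {"A": [100.0], "B": [300.0], "C": [50.0], "Z": [0.0]})
    comp = sample_composition(store, ids[0], mode="max")
    assert list(comp["contaminant"]) == ["B", "A", "C"]
    top2 = sample_composition(store, ids[0], mode="max", top_n=2)
    assert list(top2["contaminant"]) == ["B", "A"]


def test_sample_composition_mean_sums_match_store(processed):
    store = processed["store"]
    readings = store.query_readings()
    for fid in readings["file_id"].unique():
        comp = sample_composition(store, int(fid), mode="mean", top_n=10**6)
        expected = readings[(readings["file_id"] == fid)
                            & (readings["eic_mean"] > 0)]["eic_mean"].sum()
        assert comp["intensity"].sum() == pytest.approx(expected)


def test_identical_profiles_merge_at_zero_and_sit_adjacent():
    profile = [100.0, 200.0, 400.0, 800.0]
    store, _ = _store_with_readings(
        {"twin1": profile, "twin2": profile, "other": [800.0, 10.0, 900.0, 5.0]})
    spec = contaminant_heatmap(store, QueryFilter(), mode="max")
    assert spec.linkage is not None
    assert spec.linkage[0, 2] == pytest.approx(0.0, abs=1e-10)  # first merge
    names = list(spec.ordered.index)
    assert abs(names.index("twin1") - names.index("twin2")) == 1


def test_correlated_pair_merges_before_anticorrelated():
    up = [10.0, 20.0, 40.0, 80.0]
    store, _ = _store_with_readings({
        "up_a": up, "up_b": [11.0, 22.0, 44.0, 88.0],
        "down": [80.0, 40.0, 20.0, 10.0]})
    spec = contaminant_heatmap(store, QueryFilter(), mode="max")
    # brute-force correlation distances on the log-transformed matrix
    mat = spec.matrix.to_numpy()
    names = list(spec.matrix.index)
    def dist(i, j):
        return 1 - np.corrcoef(mat[i], mat[j])[0, 1]
    i_a, i_b, i_d = names.index("up_a"), names.index("up_b"), names.index("down")
    assert dist(i_a, i_b) < dist(i_a, i_d)
    first = set(spec.linkage[0, :2].astype(int))
    assert first == {i_a, i_b}


def test_heatmap_row_order_invariant_under_input_permutation():
    profiles = {"a": [1.0, 5.0, 2.0, 9.0], "b": [9.0, 1.0, 8.0, 2.0],
                "c": [1.2, 5.5, 2.1, 9.9], "d": [5.0, 5.0, 5.0, 4.0]}
    store1, _ = _store_with_readings(profiles)
    store2, _ = _store_with_readings(
        dict(reversed(list(profiles.items()))))
    h1 = contaminant_heatmap(store1, QueryFilter(), mode="max")
    h2 = contaminant_heatmap(store2, QueryFilter(), mode="max")
    assert list(h1.ordered.index) == list(h2.ordered.index)
    np.testing.assert_allclose(h1.ordered.to_numpy(), h2.ordered.to_numpy())


def test_single_nonzero_contaminant_takes_degenerate_path():
    store, _ = _store_with_readings({"only": [5.0, 6.0], "zero": [0.0, 0.0]})
    spec = contaminant_heatmap(store, QueryFilter(), mode="max")
    assert spec.degenerate and spec.linkage is None
    assert list(spec.matrix.index) == ["only"]


def test_calendar_counts_and_conservation(processed):
    store = processed["store"]
    cal = productivity_calendar(store, QueryFilter())
    assert cal["injections"].sum() == len(store.query_files())
    assert set(cal.columns) == {"date", "project", "injections"}


def test_calendar_two_projects_same_day():
    store, _ = _store_with_readings({"x": [1.0, 1.0]}, projects=["P1", "P2"])
    cal = productivity_calendar(store, QueryFilter())
    assert len(cal) == 2
    assert set(cal["project"]) == {"P1", "P2"}


def test_calendar_empty_store():
    with QCStore() as store:
        assert productivity_calendar(store, QueryFilter()).empty


def test_render_report_contains_all_five_views(processed, tmp_path):
    index = render_report(processed["store"], QueryFilter(), tmp_path,
                          config_snapshot={"demo": True})
    html = index.read_text()
    for heading in ("Tracked compound time-lines", "Contaminant time view",
                    "Sample composition", "Contaminant heatmap",
                    "Productivity calendar", "Log excerpt"):
        assert heading in html
    for table in ("metric_timeseries.csv", "contaminant_timeseries.csv",
                  "sample_composition.csv", "contaminant_heatmap.csv",
                  "productivity_calendar.csv"):
        assert (tmp_path / table).is_file()


def test_render_report_empty_store_says_no_data(tmp_path):
    with QCStore() as store:
        index = render_report(store, QueryFilter(), tmp_path)
        assert "no data" in index.read_text()


def test_rerender_tables_byte_identical(processed, tmp_path):
    a, b = tmp_path / "a", tmp_path / "b"
    render_report(processed["store"], QueryFilter(), a)
    render_report(processed["store"], QueryFilter(), b)
    for name in ("metric_timeseries.csv", "contaminant_timeseries.csv",
                 "sample_composition.csv", "contaminant_heatmap.csv",
                 "productivity_calendar.csv"):
        assert (a / name).read_bytes() == (b / name).read_bytes()
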