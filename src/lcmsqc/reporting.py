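"""Analytical views over the QC store, rendered as static HTML + figures.

Five views mirror what an instrument operator needs at the desk: tracked
metric time-lines, a single-contaminant time view, the intensity-sorted
contaminant composition of one sample, a clustered contaminant heatmap,
and a productivity calendar of injections per project per day.  Every
view exists both as a machine-readable table (CSV, byte-deterministic)
and as a figure in the rendered HTML report.
"""

from __future__ import annotations

import html as _html
import json
import logging
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform

from .errors import QueryError
from .qc_store import QCStore, QueryFilter

logger = logging.getLogger(__name__)

TRACKED_METRICS = ("mz_dev_ppm", "rt_dev", "intensity_apex",
                   "tailing_factor", "asymmetry_factor", "area")


@dataclass
class HeatmapSpec:
    """Clustered contaminants (rows) over acquisition time (columns).

    ``matrix`` holds log10(1+x)-transformed intensities, rows ordered by
    ``row_order`` (hierarchical clustering: correlation distance, average
    linkage), columns strictly acquisition-time ascending.  ``linkage``
    is None on the degenerate path (fewer than two non-zero rows).
    """

    matrix: pd.DataFrame
    row_order: list[int]
    linkage: np.ndarray | None
    degenerate: bool = False

    @property
    def ordered(self) -> pd.DataFrame:
        return self.matrix.iloc[self.row_order]


def metric_timeseries(store: QCStore, flt: QueryFilter, metric: str,
                      compound: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Time-ordered (time, value, file) series for one compound metric.

    Returns (points, gaps): one point per file where the compound was
    found; files where it was not found are listed separately so a
    sequence of missed detections is visible rather than silently thin.
    """
    if metric not in TRACKED_METRICS:
        raise QueryError(f"unknown metric {metric!r}; valid: {TRACKED_METRICS}")
    df = store.query_metrics(flt)
    df = df[df["compound"] == compound]
    if df.empty and not _compound_known(store, compound):
        raise QueryError(f"unknown compound {compound!r}")
    found = df[df["found"] == 1]
    gaps = df[df["found"] == 0][["acquisition_time", "path", "sample_id"]]
    points = found[["acquisition_time", metric, "path", "sample_id"]].rename(
        columns={metric: "value"})
    return points.reset_index(drop=True), gaps.reset_index(drop=True)


def _compound_known(store: QCStore, compound: str) -> bool:
    all_rows = store.query_metrics(QueryFilter())
    return bool((all_rows["compound"] == compound).any())


def contaminant_timeseries(store: QCStore, flt: QueryFilter, contaminant: str,
                           mode: str = "max") -> pd.DataFrame:
    """Time view for one contaminant, using EIC max or mean intensity."""
    col = _mode_column(mode)
    df = store.query_readings(flt)
    sel = df[df["contaminant"] == contaminant]
    if sel.empty and not (store.query_readings(QueryFilter())["contaminant"]
                          == contaminant).any():
        raise QueryError(f"unknown contaminant {contaminant!r}")
    out = sel[["acquisition_time", col, "path", "sample_id"]].rename(
        columns={col: "value"})
    return out.reset_index(drop=True)


def _mode_column(mode: str) -> str:
    if mode not in ("max", "mean"):
        raise QueryError(f"mode must be 'max' or 'mean', got {mode!r}")
    return f"eic_{mode}"


def sample_composition(store: QCStore, file_id: int, mode: str = "max",
                       top_n: int = 20) -> pd.DataFrame:
    """Intensity-sorted contaminant table for a single sample.

    Descending by the chosen intensity mode, ties broken by name, zeros
    suppressed, truncated to ``top_n`` rows.
    """
    col = _mode_column(mode)
    df = store.query_readings(QueryFilter())
    sel = df[df["file_id"] == file_id]
    if sel.empty:
        files = store.query_files(QueryFilter())
        if file_id not in set(files["id"]):
            raise QueryError(f"unknown file id {file_id}")
    sel = sel[sel[col] > 0]
    sel = sel.sort_values([col, "contaminant"], ascending=[False, True])
    return sel[["contaminant", col]].rename(
        columns={col: "intensity"}).head(top_n).reset_index(drop=True)


def _correlation_distance_matrix(rows: np.ndarray) -> np.ndarray:
    """Pairwise correlation distances with a guard for flat profiles.

    Zero-variance rows have no defined correlation: two identical flat
    rows get distance 0, a flat row vs anything else distance 1.
    """
    n = rows.shape[0]
    centered = rows - rows.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered ** 2).sum(axis=1))
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if norms[i] == 0 or norms[j] == 0:
                d = 0.0 if np.allclose(rows[i], rows[j]) else 1.0
            else:
                r = float(centered[i] @ centered[j] / (norms[i] * norms[j]))
                d = 1.0 - min(1.0, max(-1.0, r))
            dist[i, j] = dist[j, i] = d
    return dist


def contaminant_heatmap(store: QCStore, flt: QueryFilter,
                        mode: str = "max") -> HeatmapSpec:
    """Contaminant × file matrix with clustered rows.

    Intensities are log10(1+x)-transformed (they span orders of
    magnitude); all-zero rows are dropped; rows are canonically sorted by
    name before clustering so the result is invariant under input row
    permutation.  With fewer than two non-zero rows the matrix is
    returned unclustered (degenerate path).
    """
    col = _mode_column(mode)
    df = store.query_readings(flt)
    if df.empty:
        return HeatmapSpec(pd.DataFrame(), [], None, degenerate=True)
    files = df[["file_id", "acquisition_time"]].drop_duplicates().sort_values(
        ["acquisition_time", "file_id"])
    pivot = df.pivot_table(index="contaminant", columns="file_id",
                           values=col, aggfunc="first", fill_value=0.0)
    pivot = pivot[files["file_id"].tolist()]
    pivot = pivot.loc[(pivot != 0).any(axis=1)]
    pivot = pivot.sort_index()  # canonical order: clustering is permutation-proof
    mat = np.log10(1.0 + pivot.to_numpy(dtype=float))
    logm = pd.DataFrame(mat, index=pivot.index, columns=pivot.columns)
    if logm.shape[0] < 2:
        return HeatmapSpec(logm, list(range(logm.shape[0])), None, degenerate=True)
    dist = _correlation_distance_matrix(mat)
    link = average(squareform(dist, checks=False))
    order = [int(i) for i in leaves_list(link)]
    return HeatmapSpec(logm, order, link)


def productivity_calendar(store: QCStore,
                          flt: QueryFilter | None = None) -> pd.DataFrame:
    """Injections per (calendar day, project); zero-count days omitted."""
    files = store.query_files(flt or QueryFilter())
    if files.empty:
        return pd.DataFrame(columns=["date", "project", "injections"])
    files = files.dropna(subset=["acquisition_time"])
    dates = files["acquisition_time"].str.slice(0, 10)
    counts = (files.assign(date=dates)
              .groupby(["date", "project"], dropna=False)
              .size().reset_index(name="injections"))
    return counts.sort_values(["date", "project"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# static report rendering

_PAGE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>LC-MS QC report</title>
<style>
body {{ font-family: sans-serif; margin: 2em; max-width: 70em; }}
table {{ border-collapse: collapse; }} td, th {{ border: 1px solid #999; padding: 2px 8px; }}
h2 {{ border-bottom: 1px solid #ccc; }} .nodata {{ color: #888; font-style: italic; }}
img {{ max-width: 100%; }}
</style></head><body>
<h1>LC-MS quality-control report</h1>
{sections}
<h2>Configuration snapshot</h2><pre>{config}</pre>
<h2>Log excerpt</h2><pre>{log}</pre>
</body></html>
"""


def _df_html(df: pd.DataFrame, max_rows: int = 50) -> str:
    if df.empty:
        return '<p class="nodata">no data</p>'
    return df.head(max_rows).to_html(index=False, border=0,
                                     float_format=lambda x: f"{x:.6g}")


def render_report(store: QCStore, flt: QueryFilter, output_dir: str | Path,
                  mode: str = "max", config_snapshot: dict | None = None) -> Path:
    """Render the full static report: index.html, figures, CSV tables.

    Tables are written deterministically (re-rendering an unchanged store
    reproduces them byte for byte); figures may embed matplotlib
    metadata and are not required to be byte-stable.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(output_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise IOError(f"output dir not writable: {exc}") from exc

    sections: list[str] = []
    metrics = store.query_metrics(flt)

    # 1. tracked metric time-lines
    sections.append("<h2>Tracked compound time-lines</h2>")
    compounds = sorted(metrics["compound"].unique()) if not metrics.empty else []
    ts_tables = []
    for compound in compounds:
        for metric in ("mz_dev_ppm", "rt_dev", "intensity_apex"):
            points, gaps = metric_timeseries(store, flt, metric, compound)
            ts_tables.append(points.assign(compound=compound, metric=metric))
    if ts_tables:
        ts_all = pd.concat(ts_tables, ignore_index=True)
        ts_all.to_csv(out / "metric_timeseries.csv", index=False)
        fig, axes = plt.subplots(3, 1, figsize=(9, 8), sharex=True)
        for metric, ax in zip(("mz_dev_ppm", "rt_dev", "intensity_apex"), axes):
            for compound in compounds:
                sel = ts_all[(ts_all["compound"] == compound)
                             & (ts_all["metric"] == metric)]
                sel = sel.dropna(subset=["acquisition_time"])
                ax.plot(pd.to_datetime(sel["acquisition_time"]), sel["value"],
                        marker="o", ms=3, label=compound)
            ax.set_ylabel(metric)
            ax.legend(fontsize=7)
        fig.autofmt_xdate()
        fig.savefig(out / "metric_timeseries.png", dpi=110)
        plt.close(fig)
        sections.append('<img src="metric_timeseries.png" alt="metric time-lines">')
        sections.append(_df_html(ts_all))
    else:
        sections.append('<p class="nodata">no data</p>')

    # 2. contaminant time view
    sections.append(f"<h2>Contaminant time view (EIC {mode})</h2>")
    readings = store.query_readings(flt)
    if not readings.empty:
        col = _mode_column(mode)
        top = (readings.groupby("contaminant")[col].max()
               .sort_values(ascending=False).head(5).index.tolist())
        tv = readings[readings["contaminant"].isin(top)][
            ["acquisition_time", "contaminant", col]]
        tv = tv.sort_values(["contaminant", "acquisition_time"])
        tv.to_csv(out / "contaminant_timeseries.csv", index=False)
        fig, ax = plt.subplots(figsize=(9, 4))
        for name in top:
            sel = tv[tv["contaminant"] == name].dropna(subset=["acquisition_time"])
            ax.plot(pd.to_datetime(sel["acquisition_time"]), sel[col],
                    marker="o", ms=3, label=name)
        ax.set_yscale("symlog")
        ax.set_ylabel(f"EIC {mode} intensity")
        ax.legend(fontsize=7)
        fig.autofmt_xdate()
        fig.savefig(out / "contaminant_timeseries.png", dpi=110)
        plt.close(fig)
        sections.append('<img src="contaminant_timeseries.png" alt="contaminant time view">')
        sections.append(_df_html(tv))
    else:
        sections.append('<p class="nodata">no data</p>')

    # 3. sample composition of the most recent file
    sections.append(f"<h2>Sample composition (EIC {mode})</h2>")
    if not readings.empty:
        last_file = int(readings.sort_values("acquisition_time")["file_id"].iloc[-1])
        comp = sample_composition(store, last_file, mode=mode)
        comp.to_csv(out / "sample_composition.csv", index=False)
        if not comp.empty:
            fig, ax = plt.subplots(figsize=(7, 0.3 * len(comp) + 1.2))
            ax.barh(comp["contaminant"][::-1], comp["intensity"][::-1])
            ax.set_xlabel(f"EIC {mode} intensity")
            fig.tight_layout()
            fig.savefig(out / "sample_composition.png", dpi=110)
            plt.close(fig)
            sections.append('<img src="sample_composition.png" alt="sample composition">')
        sections.append(_df_html(comp))
    else:
        sections.append('<p class="nodata">no data</p>')

    # 4. clustered contaminant heatmap
    sections.append(f"<h2>Contaminant heatmap (log10(1+EIC {mode}))</h2>")
    spec = contaminant_heatmap(store, flt, mode=mode)
    if not spec.matrix.empty:
        ordered = spec.ordered
        ordered.to_csv(out / "contaminant_heatmap.csv")
        fig, ax = plt.subplots(figsize=(9, 0.25 * len(ordered) + 1.5))
        im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap="viridis")
        ax.set_yticks(range(len(ordered)), ordered.index, fontsize=6)
        ax.set_xlabel("injection (acquisition-time order)")
        fig.colorbar(im, ax=ax, label="log10(1+intensity)")
        fig.tight_layout()
        fig.savefig(out / "contaminant_heatmap.png", dpi=110)
        plt.close(fig)
        note = " (unclustered: fewer than two non-zero rows)" if spec.degenerate else ""
        sections.append(f'<img src="contaminant_heatmap.png" alt="heatmap">{note}')
    else:
        sections.append('<p class="nodata">no data</p>')

    # 5. productivity calendar
    sections.append("<h2>Productivity calendar</h2>")
    cal = productivity_calendar(store, flt)
    cal.to_csv(out / "productivity_calendar.csv", index=False)
    sections.append(_df_html(cal, max_rows=100))

    log = store.query_log(limit=40)
    log_txt = "\n".join(
        f"{r.ts} [{r.module}/{r.level}] {r.message}" for r in log.itertuples())
    page = _PAGE.format(
        sections="\n".join(sections),
        config=_html.escape(json.dumps(config_snapshot or {}, indent=1, sort_keys=True)),
        log=_html.escape(log_txt) or "(empty)",
    )
    index = out / "index.html"
    index.write_text(page)
    return index
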