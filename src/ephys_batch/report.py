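"""Per-session QA metrics and HTML report generation.

Two self-contained HTML documents are produced per batch: a *subject*
report with one navigable section per session (metrics table, figures,
embedded session log) and a *summary* report with one sortable table row
per session plus the config, any custom-function sources, and error logs
for failed sessions.  All assets are local files; table sorting is a small
inline script, so reports can be shared as a single directory.
"""

from __future__ import annotations

import html
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SubjectReportData",
    "SummaryTable",
    "compute_session_metrics",
    "render_subject_report",
    "render_summary_report",
    "generate_session_figures",
]

METRIC_KEYS = (
    "n_sensors",
    "duration_s",
    "n_bad_channels",
    "pct_bad_segments",
    "n_bad_ics_total",
    "n_bad_ics_ecg",
    "n_bad_ics_eog",
    "n_epochs",
    "n_epochs_dropped",
)


@dataclass
class SubjectReportData:
    session_id: str
    metrics: dict[str, float] = field(default_factory=dict)
    figure_paths: list[str] = field(default_factory=list)
    log_text: str = ""

    def __post_init__(self):
        for k, v in self.metrics.items():
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"metric {k} must be finite and >= 0, got {v}")
        pct = self.metrics.get("pct_bad_segments", 0.0)
        if not 0 <= pct <= 100:
            raise ValueError("pct_bad_segments must lie in [0, 100]")


@dataclass
class SummaryTable:
    rows: list[SubjectReportData]
    config_text: str = ""
    custom_function_sources: str = ""
    error_traces: dict[str, str] = field(default_factory=dict)


def compute_session_metrics(state, session_id: str = "",
                            log_text: str = "") -> SubjectReportData:
    """Derive the QA metric map from a DatasetState-like mapping.

    Every metric key is always present — 0 when the corresponding stage was
    skipped — so summary tables are rectangular.  Metrics are pure
    functions of the state: recomputation yields identical values.
    """
    metrics = {k: 0.0 for k in METRIC_KEYS}
    rec = state.get("raw")
    if rec is not None:
        metrics["n_sensors"] = float(rec.n_channels)
        metrics["duration_s"] = float(rec.duration)
        metrics["n_bad_channels"] = float(len(rec.bad_channels))
        bad_dur = sum(
            a.duration for a in rec.annotations if a.label.startswith("bad")
        )
        if rec.duration > 0:
            metrics["pct_bad_segments"] = min(
                100.0, 100.0 * bad_dur / rec.duration
            )
    ica = state.get("ica")
    if ica is not None:
        counts = ica.label_counts()
        metrics["n_bad_ics_ecg"] = float(counts.get("ecg", 0))
        metrics["n_bad_ics_eog"] = float(counts.get("eog", 0))
        metrics["n_bad_ics_total"] = float(
            sum(v for k, v in counts.items() if k != "none")
        )
    ep = state.get("epochs")
    if ep is not None:
        metrics["n_epochs"] = float(ep.n_trials)
        metrics["n_epochs_dropped"] = float(ep.n_dropped)
    return SubjectReportData(session_id=session_id, metrics=metrics,
                             log_text=log_text)


def generate_session_figures(state, figdir: str | Path,
                             session_id: str) -> list[str]:
    """Render QA figures (channel power spectra, bad-segment timeline) from
    whatever the state contains; returns the written file paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy import signal as sp_signal

    figdir = Path(figdir) / session_id
    figdir.mkdir(parents=True, exist_ok=True)
    paths = []
    rec = state.get("raw")
    if rec is not None:
        picks = rec.picks("meg")
        if picks.size:
            nper = min(rec.n_samples, int(2 * rec.sfreq))
            f, pxx = sp_signal.welch(rec.data[picks], rec.sfreq, nperseg=nper)
            fig, ax = plt.subplots(figsize=(6, 3))
            ax.semilogy(f, pxx.T, lw=0.4, alpha=0.6)
            ax.set_xlabel("frequency (Hz)")
            ax.set_ylabel("PSD")
            ax.set_title(f"{session_id}: sensor power spectra")
            p = figdir / "psd.png"
            fig.savefig(p, dpi=80)
            plt.close(fig)
            paths.append(str(p))
        fig, ax = plt.subplots(figsize=(6, 1.6))
        ax.set_xlim(0, max(rec.duration, 1))
        ax.set_ylim(0, 1)
        ax.set_yticks([])
        for a in rec.annotations:
            if a.label.startswith("bad"):
                ax.axvspan(a.onset, a.end, color="tab:red", alpha=0.5)
        ax.set_xlabel("time (s)")
        ax.set_title(f"{session_id}: bad segments")
        p = figdir / "bad_segments.png"
        fig.savefig(p, dpi=80)
        plt.close(fig)
        paths.append(str(p))
    return paths


_SORT_JS = """
function sortTable(tbl, col) {
  var rows = Array.prototype.slice.call(tbl.tBodies[0].rows);
  var dir = tbl.getAttribute('data-dir') === 'desc' ? 1 : -1;
  tbl.setAttribute('data-dir', dir === 1 ? 'asc' : 'desc');
  rows.sort(function(a, b) {
    var x = a.cells[col].textContent, y = b.cells[col].textContent;
    var nx = parseFloat(x), ny = parseFloat(y);
    if (!isNaN(nx)) { if (!isNaN(ny)) { return dir * (nx - ny); } }
    return dir * x.localeCompare(y);
  });
  rows.forEach(function(r) { tbl.tBodies[0].appendChild(r); });
}
"""

_PAGE = """<!DOCTYPE html>
<html>
<head>
<meta charset="utf-8"/>
<title>{title}</title>
<style>
body {{ font-family: sans-serif; margin: 2em; }}
table {{ border-collapse: collapse; }}
th, td {{ border: 1px solid #999; padding: 0.3em 0.6em; }}
th {{ cursor: pointer; background: #eee; }}
pre {{ background: #f6f6f6; padding: 1em; overflow-x: auto; }}
img {{ max-width: 100%; }}
</style>
<script>{script}</script>
</head>
<body>
<h1>{title}</h1>
{body}
</body>
</html>
"""


def _metric_table(metrics: dict) -> str:
    rows = "".join(
        f"<tr><td>{html.escape(k)}</td><td>{v:g}</td></tr>"
        for k, v in metrics.items()
    )
    return (
        "<table><thead><tr><th>metric</th><th>value</th></tr></thead>"
        f"<tbody>{rows}</tbody></table>"
    )


def render_subject_report(
    data: list[SubjectReportData], outdir: str | Path
) -> Path:
    """Write ``subject_report.html``: a session index plus one anchored
    section per session with metrics, figures (placeholder text when a
    figure file is missing) and the embedded session log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nav = "".join(
        f'<li><a href="#session-{html.escape(d.session_id)}">'
        f"{html.escape(d.session_id)}</a></li>"
        for d in data
    )
    sections = []
    for d in data:
        figs = []
        for fp in d.figure_paths:
            p = Path(fp)
            if p.exists():
                try:
                    rel = p.relative_to(outdir)
                except ValueError:
                    rel = p
                figs.append(f'<img src="{html.escape(str(rel))}" alt="figure"/>')
            else:
                figs.append(
                    f"<p><em>figure missing: {html.escape(str(fp))}</em></p>"
                )
        sections.append(
            f'<section id="session-{html.escape(d.session_id)}">'
            f"<h2>{html.escape(d.session_id)}</h2>"
            + _metric_table(d.metrics)
            + "".join(figs)
            + "<h3>session log</h3>"
            + f"<pre>{html.escape(d.log_text)}</pre>"
            + "</section>"
        )
    body = f"<ul>{nav}</ul>" + "".join(sections)
    out = outdir / "subject_report.html"
    out.write_text(_PAGE.format(title="Subject report", script="", body=body))
    return out


def render_summary_report(
    table: SummaryTable,
    outdir: str | Path,
    sort_by: str | None = None,
    descending: bool = True,
) -> Path:
    """Write ``summary_report.html`` with one sortable row per session.

    ``sort_by`` pre-sorts the table rows by a metric (clicking a column
    header re-sorts client-side); the config text and custom-function
    sources are shown verbatim, and an error-log section appears when any
    session failed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = list(table.rows)
    if sort_by is not None:
        rows.sort(key=lambda d: d.metrics.get(sort_by, 0.0), reverse=descending)
    cols = list(METRIC_KEYS)
    head = "<tr><th onclick=\"sortTable(this.closest('table'), 0)\">session</th>"
    for j, c in enumerate(cols, start=1):
        head += (
            f"<th onclick=\"sortTable(this.closest('table'), {j})\">"
            f"{html.escape(c)}</th>"
        )
    head += "</tr>"
    body_rows = []
    for d in rows:
        cells = f"<td>{html.escape(d.session_id)}</td>" + "".join(
            f"<td>{d.metrics.get(c, 0.0):g}</td>" for c in cols
        )
        body_rows.append(f"<tr>{cells}</tr>")
    parts = [
        f'<p>{len(rows)} sessions processed.</p>',
        '<table id="summary" data-dir="asc"><thead>' + head + "</thead>"
        "<tbody>" + "".join(body_rows) + "</tbody></table>",
        "<h2>pipeline config</h2>",
        f"<pre>{html.escape(table.config_text)}</pre>",
    ]
    if table.custom_function_sources:
        parts += [
            "<h2>custom functions</h2>",
            f"<pre>{html.escape(table.custom_function_sources)}</pre>",
        ]
    if table.error_traces:
        parts.append("<h2>error logs</h2>")
        for sid, trace in table.error_traces.items():
            parts.append(f"<h3>{html.escape(sid)}</h3>")
            parts.append(f"<pre>{html.escape(trace)}</pre>")
    out = outdir / "summary_report.html"
    out.write_text(
        _PAGE.format(title="Summary report", script=_SORT_JS,
                     body="".join(parts))
    )
    csv_path = outdir / "summary_metrics.csv"
    lines = ["session," + ",".join(cols)]
    for d in rows:
        lines.append(
            d.session_id + "," + ",".join(f"{d.metrics.get(c, 0.0):g}" for c in cols)
        )
    csv_path.write_text("\n".join(lines) + "\n")
    (outdir / "summary_metrics.json").write_text(
        json.dumps(
            {d.session_id: d.metrics for d in rows}, sort_keys=True, indent=1
        )
        + "\n"
    )
    return out
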