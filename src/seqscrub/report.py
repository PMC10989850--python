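"""JSON and HTML quality-control reports.

The JSON report is the single source of truth: every number shown in the
HTML report is taken from (and embedded verbatim into) the same payload,
so the HTML is strictly a view. Key order is fixed, making repeated runs
diff cleanly except for the timestamp/command fields.
"""

from __future__ import annotations

import html as _html
import json
from datetime import datetime, timezone
from typing import Any

from .pipeline import PipelineResult
from .qc import QcAccumulator, content_curves, kmer_table, quality_curves
from .trim import FilterStatus

__all__ = ["build_payload", "build_json", "build_html", "SCHEMA_VERSION"]

SCHEMA_VERSION = "1.0"


def _read_set_block(acc: QcAccumulator, overrep: list | None = None) -> dict:
    used = acc.cycle_count > 0
    cycles = int(used.nonzero()[0].max() + 1) if used.any() else 0
    block = {
        "total_reads": acc.total_reads,
        "total_bases": acc.total_bases,
        "q20_bases": acc.q20_bases,
        "q30_bases": acc.q30_bases,
        "total_cycles": cycles,
        "quality_curves": quality_curves(acc),
        "content_curves": content_curves(acc),
        "kmer_count": kmer_table(acc),
    }
    if overrep is not None:
        block["overrepresented_sequences"] = overrep
    return block


def _summary_side(*accs: QcAccumulator) -> dict:
    reads = sum(a.total_reads for a in accs)
    bases = sum(a.total_bases for a in accs)
    q20 = sum(a.q20_bases for a in accs)
    q30 = sum(a.q30_bases for a in accs)
    gc = sum(a.gc_bases for a in accs)
    return {
        "total_reads": reads,
        "total_bases": bases,
        "q20_bases": q20,
        "q30_bases": q30,
        "q20_rate": round(q20 / bases, 6) if bases else 0.0,
        "q30_rate": round(q30 / bases, 6) if bases else 0.0,
        "gc_content": round(gc / bases, 6) if bases else 0.0,
    }


def build_payload(
    result: PipelineResult,
    command: str = "",
    timestamp: str | None = None,
) -> dict[str, Any]:
    """Assemble the report payload from a finished pipeline run."""
    cfg = result.config
    before = _summary_side(result.acc_before_r1, result.acc_before_r2)
    after = _summary_side(result.acc_after_r1, result.acc_after_r2, result.acc_merged)
    cycles1 = _read_set_block(result.acc_before_r1)["total_cycles"]
    cycles2 = _read_set_block(result.acc_before_r2)["total_cycles"]
    sequencing = (
        f"paired end ({cycles1} cycles + {cycles2} cycles)"
        if result.paired
        else f"single end ({cycles1} cycles)"
    )
    fc = result.filter_counts
    payload: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "summary": {
            "sequencing": sequencing,
            "before_filtering": before,
            "after_filtering": after,
        },
        "filtering_result": {
            "passed_filter_reads": fc.get(FilterStatus.PASS, 0),
            "low_quality_reads": fc.get(FilterStatus.LOW_QUALITY, 0),
            "too_many_N_reads": fc.get(FilterStatus.TOO_MANY_N, 0),
            "too_short_reads": fc.get(FilterStatus.TOO_SHORT, 0),
            "too_long_reads": fc.get(FilterStatus.TOO_LONG, 0),
            "duplicate_reads": fc.get(FilterStatus.DUPLICATE, 0),
        },
        "duplication": {
            "rate": round(result.duplication_rate, 6),
            "raw_rate": round(result.duplication_rate_raw, 6),
            "flagged_reads": result.duplicates_flagged,
        },
        "adapter_cutting": {
            "adapter_trimmed_reads": result.adapter_trimmed_reads,
            "adapter_trimmed_bases": result.adapter_trimmed_bases,
            "adapter_sequence_r1": cfg.adapter_sequence if cfg else None,
            "adapter_sequence_r2": cfg.adapter_sequence_r2 if cfg else None,
        },
        "base_correction": {
            "corrected_reads": result.corrected_reads,
            "corrected_bases": result.corrected_bases,
        },
    }
    if result.paired:
        hist = result.insert_hist
        sizes = sorted(hist.counts)
        payload["insert_size"] = {
            "peak": hist.peak(),
            "unknown": hist.unknown,
            "histogram": {str(s): hist.counts[s] for s in sizes},
        }
    if result.config and result.config.merge:
        payload["merging"] = {
            "merged_pairs": result.merged_pairs,
            "unmerged_pairs_written": result.unmerged_pairs_written,
            "unmerged_pairs_dropped": result.unmerged_pairs_dropped,
        }
    payload["read1_before_filtering"] = _read_set_block(
        result.acc_before_r1, result.overrep_r1 if result.overrep_r1 else None
    )
    payload["read1_after_filtering"] = _read_set_block(result.acc_after_r1)
    if result.paired:
        payload["read2_before_filtering"] = _read_set_block(
            result.acc_before_r2, result.overrep_r2 if result.overrep_r2 else None
        )
        payload["read2_after_filtering"] = _read_set_block(result.acc_after_r2)
    if result.config and result.config.merge:
        payload["merged_and_filtered"] = _read_set_block(result.acc_merged)
    payload["command"] = command
    payload["timestamp"] = timestamp or datetime.now(timezone.utc).isoformat()
    return payload


def build_json(payload: dict[str, Any]) -> str:
    """Serialize the payload with stable key order."""
    return json.dumps(payload, indent=2, sort_keys=False) + "\n"


# ---------------------------------------------------------------------------
# HTML rendering: small self-contained SVG line charts; the full JSON payload
# is embedded so the HTML never disagrees with the machine-readable report.
# ---------------------------------------------------------------------------

_PALETTE = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728",
            "N": "#7f7f7f", "GC": "#9467bd", "mean": "#17becf"}


def _svg_line_chart(
    series: dict[str, list[float]],
    width: int = 640,
    height: int = 220,
    y_max: float | None = None,
    title: str = "",
) -> str:
    pad = 36
    points_max = max((len(v) for v in series.values()), default=0)
    if points_max == 0:
        return "<p>no data</p>"
    vals = [v for vv in series.values() for v in vv if v is not None]
    top = y_max if y_max is not None else (max(vals) * 1.05 if vals else 1.0)
    top = top or 1.0
    parts = [
        f'<svg viewBox="0 0 {width} {height}" role="img" aria-label="{_html.escape(title)}">',
        f'<rect x="{pad}" y="8" width="{width - pad - 8}" height="{height - pad - 8}" '
        'fill="#fafafa" stroke="#ccc"/>',
    ]
    x_span = width - pad - 8
    y_span = height - pad - 8
    for name, values in series.items():
        color = _PALETTE.get(name, "#000")
        pts = []
        for i, v in enumerate(values):
            if v is None:  # gap: base never called at this cycle
                continue
            x = pad + (i / max(1, points_max - 1)) * x_span
            y = 8 + y_span - (min(v, top) / top) * y_span
            pts.append(f"{x:.1f},{y:.1f}")
        if pts:
            parts.append(
                f'<polyline fill="none" stroke="{color}" stroke-width="1.5" '
                f'points="{" ".join(pts)}"><title>{_html.escape(name)}</title></polyline>'
            )
    legend_x = pad + 4
    for name in series:
        color = _PALETTE.get(name, "#000")
        parts.append(
            f'<text x="{legend_x}" y="{height - 10}" fill="{color}" '
            f'font-size="11">{_html.escape(name)}</text>'
        )
        legend_x += 10 * max(2, len(name))
    parts.append(f'<text x="{pad}" y="{height - 24}" font-size="10" fill="#666">'
                 f"0 .. {top:.3g} (y), cycle 1 .. {points_max} (x)</text>")
    parts.append("</svg>")
    return "".join(parts)


def _table(rows: list[tuple[str, Any]]) -> str:
    body = "".join(
        f"<tr><td>{_html.escape(str(k))}</td><td>{_html.escape(str(v))}</td></tr>"
        for k, v in rows
    )
    return f"<table>{body}</table>"


def build_html(payload: dict[str, Any], title: str | None = None) -> str:
    """Render a self-contained HTML report with the four core QC panels:
    per-cycle quality curves, per-cycle content curves, insert-size
    distribution (with the unknown category) and the overrepresented
    sequence table with per-cycle distribution."""
    title = title or "seqscrub report"
    summary = payload["summary"]
    filt = payload["filtering_result"]
    qual_panels = []
    content_panels = []
    for key, label in (
        ("read1_before_filtering", "read1 before filtering"),
        ("read2_before_filtering", "read2 before filtering"),
        ("read1_after_filtering", "read1 after filtering"),
        ("read2_after_filtering", "read2 after filtering"),
        ("merged_and_filtered", "merged"),
    ):
        block = payload.get(key)
        if not block or not block["total_reads"]:
            continue
        qual_panels.append(
            f"<h3>{label}</h3>"
            + _svg_line_chart(block["quality_curves"], y_max=42, title=f"quality {label}")
        )
        content_panels.append(
            f"<h3>{label}</h3>"
            + _svg_line_chart(block["content_curves"], y_max=1.0, title=f"content {label}")
        )
    if "insert_size" in payload:
        hist = payload["insert_size"]["histogram"]
        if hist:
            sizes = [int(s) for s in hist]
            lo, hi = min(sizes), max(sizes)
            series = {"count": [float(hist.get(str(s), 0)) for s in range(lo, hi + 1)]}
            insert_html = _svg_line_chart(series, title="insert size")
            insert_html += (
                f"<p>peak: {payload['insert_size']['peak']}, pairs with unknown "
                f"insert size (mates not overlapped): {payload['insert_size']['unknown']}</p>"
            )
        else:
            insert_html = (
                f"<p>all {payload['insert_size']['unknown']} pairs have unknown "
                "insert size (no overlap evaluated)</p>"
            )
    else:
        insert_html = "<p>insert size is only evaluated for paired-end input</p>"
    overrep_rows = []
    for key in ("read1_before_filtering", "read2_before_filtering"):
        block = payload.get(key, {})
        for entry in block.get("overrepresented_sequences", []) or []:
            hits = entry["per_cycle_hits"]
            spark = _svg_line_chart(
                {"count": [float(h) for h in hits]}, width=200, height=60,
                title=f"per-cycle {entry['sequence']}",
            )
            overrep_rows.append(
                f"<tr><td><code>{_html.escape(entry['sequence'])}</code></td>"
                f"<td>{entry['count']}</td><td>{entry['expected']:.4g}</td>"
                f"<td>{spark}</td></tr>"
            )
    overrep_html = (
        "<table><tr><th>sequence</th><th>count</th><th>expected</th>"
        "<th>per-cycle distribution</th></tr>" + "".join(overrep_rows) + "</table>"
        if overrep_rows
        else "<p>no overrepresented sequences detected (or analysis disabled)</p>"
    )
    summary_rows = [("sequencing", summary["sequencing"])]
    for side in ("before_filtering", "after_filtering"):
        for k, v in summary[side].items():
            summary_rows.append((f"{side}.{k}", v))
    summary_rows.append(("duplication rate", payload["duplication"]["rate"]))
    filter_rows = list(filt.items())
    # "<\/" keeps a literal "</script>" inside data from closing our tag
    embedded = json.dumps(payload, indent=None, sort_keys=False).replace("</", "<\\/")
    return f"""<!DOCTYPE html>
<html lang="en"><head><meta charset="utf-8">
<title>{_html.escape(title)}</title>
<style>
body {{ font-family: sans-serif; margin: 1.5em; color: #222; }}
table {{ border-collapse: collapse; margin: 0.5em 0; }}
td, th {{ border: 1px solid #ccc; padding: 2px 8px; font-size: 13px; }}
section {{ margin-bottom: 1.5em; }}
svg {{ max-width: 100%; }}
</style></head><body>
<h1>{_html.escape(title)}</h1>
<section id="summary"><h2>Summary</h2>{_table(summary_rows)}</section>
<section id="filtering_result"><h2>Filtering result (reads)</h2>{_table(filter_rows)}</section>
<section id="quality_curves"><h2>Per-cycle quality curves</h2>{''.join(qual_panels)}</section>
<section id="content_curves"><h2>Per-cycle base content curves</h2>{''.join(content_panels)}</section>
<section id="insert_size"><h2>Insert size distribution</h2>{insert_html}</section>
<section id="overrepresented"><h2>Overrepresented sequences</h2>{overrep_html}</section>
<script id="report-data" type="application/json">{embedded}</script>
<script>
/* the full JSON payload above is the data source for this page; a viewer
   can load it via document.getElementById('report-data').textContent */
</script>
</body></html>
"""
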