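"""Static HTML/SVG reporting of evaluation curves.

The report is a pure view: every number rendered in the HTML or drawn in
a figure is also present in an adjacent TSV.  Figures are sensitivity vs
false discovery rate (MAPQ as the curve parameter) and precision vs the
MAPQ threshold.
"""

from __future__ import annotations

import html
import os
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from . import io as rio
from .evaluation import CATEGORY_ORDER, CurvePoint, write_curve_tsv

__all__ = ["render_report"]


def _plot_fdr_sensitivity(curves, path):
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    for label, points in curves.items():
        xs = [p.fdr for p in points]
        ys = [p.sensitivity for p in points]
        ax.plot(xs, ys, marker="o", markersize=3, label=label)
    ax.set_xlabel("false discovery rate")
    ax.set_ylabel("sensitivity")
    ax.set_title("sensitivity vs FDR (MAPQ-parametrized)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None})
    plt.close(fig)


def _plot_precision_q(curves, path):
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    for label, points in curves.items():
        xs = [p.q for p in points]
        ys = [p.precision for p in points]
        ax.plot(xs, ys, marker="o", markersize=3, label=label)
    ax.set_xlabel("MAPQ threshold")
    ax.set_ylabel("precision")
    ax.set_title("precision vs MAPQ threshold")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None})
    plt.close(fig)


def _curve_table(label: str, points: Sequence[CurvePoint]) -> str:
    head = (["q"] + [c.value for c in CATEGORY_ORDER]
            + ["sensitivity", "precision", "fdr"])
    rows = []
    for p in points:
        cells = [str(p.q)]
        cells += [str(p.counts[c]) for c in CATEGORY_ORDER]
        cells += [f"{p.sensitivity:.6f}", f"{p.precision:.6f}",
                  f"{p.fdr:.6f}"]
        rows.append("<tr>" + "".join(f"<td>{c}</td>" for c in cells)
                    + "</tr>")
    return (
        f"<h3>{html.escape(label)}</h3>\n<table border='1' "
        "cellspacing='0' cellpadding='3'>\n<tr>"
        + "".join(f"<th>{html.escape(h)}</th>" for h in head)
        + "</tr>\n" + "\n".join(rows) + "\n</table>\n"
    )


def render_report(
    curves: Mapping[str, Sequence[CurvePoint]],
    out_dir: str,
    metadata: Mapping[str, str] | None = None,
) -> str:
    """Write TSVs, SVG figures and report.html; returns the HTML path."""
    rio.ensure_dir(out_dir)
    for label, points in curves.items():
        write_curve_tsv(points, os.path.join(out_dir, f"{label}.curve.tsv"))
    fig1 = os.path.join(out_dir, "fdr_sensitivity.svg")
    fig2 = os.path.join(out_dir, "precision_mapq.svg")
    _plot_fdr_sensitivity(curves, fig1)
    _plot_precision_q(curves, fig2)

    meta_rows = "".join(
        f"<tr><td>{html.escape(str(k))}</td><td>{html.escape(str(v))}</td></tr>"
        for k, v in (metadata or {}).items()
    )
    body = [
        "<h1>Mapper evaluation report</h1>",
        ("<table border='1' cellspacing='0' cellpadding='3'>"
         f"{meta_rows}</table>" if meta_rows else ""),
        "<h2>Curves</h2>",
        f"<img src='{os.path.basename(fig1)}' alt='sensitivity vs FDR'/>",
        f"<img src='{os.path.basename(fig2)}' alt='precision vs MAPQ'/>",
        "<h2>Per-threshold tables</h2>",
    ]
    body += [_curve_table(label, points) for label, points in curves.items()]
    html_path = os.path.join(out_dir, "report.html")
    with open(html_path, "w") as out:
        out.write(
            "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
            "<title>Mapper evaluation report</title></head>\n<body>\n"
            + "\n".join(body) + "\n</body></html>\n"
        )
    return html_path
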