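"""Boxplot graphics for per-node bootstrap-support distributions.

One horizontal box per full-tree node (nodes on the vertical axis), drawn
from the same Tukey hinges and fences used for outlier detection, with
outliers as dots annotated by the exclusion that produced them.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

__all__ = ["plot_node_boxplots", "plot_custom_node"]

_PER_PAGE = 25


def _bxp_stats(summary):
    vals = list(summary.values.values())
    inside = [v for v in vals
              if summary.lower_fence <= v <= summary.upper_fence]
    fliers = [v for v in vals if v not in inside or v in
              {r.value for r in summary.upper_outliers + summary.lower_outliers}]
    return {
        "label": summary.node_id,
        "med": summary.median,
        "q1": summary.q1,
        "q3": summary.q3,
        "whislo": min(inside) if inside else summary.q1,
        "whishi": max(inside) if inside else summary.q3,
        "fliers": [r.value for r in
                   summary.upper_outliers + summary.lower_outliers],
    }


def plot_node_boxplots(table, summaries, path):
    """Write a (multi-page) PDF of per-node BS boxplots."""
    from matplotlib.backends.backend_pdf import PdfPages

    with PdfPages(path) as pdf:
        for start in range(0, max(len(summaries), 1), _PER_PAGE):
            chunk = summaries[start:start + _PER_PAGE]
            fig, ax = plt.subplots(
                figsize=(8, max(2.0, 0.35 * len(chunk) + 1.2))
            )
            if chunk:
                stats = [_bxp_stats(s) for s in chunk]
                ax.bxp(stats, vert=False, showfliers=True)
                for pos, s in enumerate(chunk, start=1):
                    for rec in s.upper_outliers + s.lower_outliers:
                        ax.annotate(
                            rec.exclusion, (rec.value, pos),
                            textcoords="offset points", xytext=(0, 5),
                            fontsize=6, ha="center",
                        )
                full = [float(table.df.loc[s.node_id, "full"]) for s in chunk]
                ax.plot(full, range(1, len(chunk) + 1), "k|", markersize=8,
                        label="full tree")
                ax.legend(loc="lower left", fontsize=7)
            ax.set_xlabel("bootstrap support (%)")
            ax.set_xlim(-3, 103)
            fig.tight_layout()
            pdf.savefig(fig)
            plt.close(fig)


def plot_custom_node(values: dict, path, title=""):
    """Boxplot for a single queried bipartition across series."""
    from .support import tukey_hinges

    numeric = {k: v for k, v in values.items()
               if k != "full" and not isinstance(v, str)}
    fig, ax = plt.subplots(figsize=(8, 2))
    if len(numeric) >= 2:
        q1, med, q3 = tukey_hinges(list(numeric.values()))
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = [v for v in numeric.values() if lo <= v <= hi]
        stats = [{
            "label": title or "node",
            "med": med, "q1": q1, "q3": q3,
            "whislo": min(inside) if inside else q1,
            "whishi": max(inside) if inside else q3,
            "fliers": [v for v in numeric.values() if v < lo or v > hi],
        }]
        ax.bxp(stats, vert=False, showfliers=True)
    ax.set_xlabel("bootstrap support (%)")
    ax.set_xlim(-3, 103)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
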