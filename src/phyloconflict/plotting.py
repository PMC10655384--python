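"""Optional matplotlib figures: per-node concordance pies, quartet
frequency bars, and monophyly stacked bars. Import requires matplotlib."""

from __future__ import annotations

from typing import Mapping, Sequence

from .concordance import NodeConcordance, pie_fractions
from .quartet_analysis import MONOPHYLY_CATEGORIES, QuartetFrequencies

PIE_COLORS = ("#3B6FB6", "#4CA64C", "#C23B3B", "#9E9E9E")
CATEGORY_COLORS = {
    "strong_support": "#1B5E20",
    "weak_support": "#26A69A",
    "weak_reject": "#F48FB1",
    "strong_reject": "#7B1F2B",
    "no_data": "#4A90D9",
}


def concordance_pie(nc: NodeConcordance, ax=None):
    """One pie per species-tree node: concordant / top alternative /
    other conflict / uninformative."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(2.5, 2.5))
    ax.pie(pie_fractions(nc), colors=PIE_COLORS, startangle=90)
    ax.set_title(f"{nc.concordant}/{nc.conflicting}", fontsize=9)
    return ax


def quartet_bars(freqs: QuartetFrequencies, ax=None, labels=("T1", "T2", "T3")):
    """Relative frequency bars for the three quartet resolutions, with a
    dotted line at 1/3."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(3, 2.5))
    colors = ("#4CA64C", "#26A69A", "#7EC8E3")
    ax.bar(labels, freqs.frequencies, color=colors)
    ax.axhline(1 / 3, linestyle=":", color="black", linewidth=1)
    ax.set_ylim(0, 1)
    ax.set_ylabel("relative frequency")
    return ax


def monophyly_stacked_bars(
    totals: Mapping[str, Mapping[str, int]], ax=None, order: Sequence[str] = None
):
    """Stacked per-group category counts across gene trees."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(max(4, len(totals)), 3))
    names = list(order or sorted(totals))
    bottoms = [0] * len(names)
    for cat in MONOPHYLY_CATEGORIES:
        heights = [totals[n].get(cat, 0) for n in names]
        ax.bar(names, heights, bottom=bottoms, label=cat,
               color=CATEGORY_COLORS[cat])
        bottoms = [b + h for b, h in zip(bottoms, heights)]
    ax.set_ylabel("gene trees")
    ax.legend(fontsize=7)
    ax.tick_params(axis="x", rotation=45)
    return ax
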