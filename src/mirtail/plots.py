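"""Figure-style rendering: bubble matrices and stacked composition panels."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from mirtail.summarize import NUCLEOTIDES, ProfileMatrix, TailCompositionSummary

NT_COLORS = {"A": "#66c2a5", "C": "#fc8d62", "G": "#8da0cb", "U": "#e78ac3"}


def render_bubble_matrix(
    matrix: ProfileMatrix,
    path: str | Path,
    scale: str = "diameter",
    max_diameter_pt: float = 28.0,
    trim_cap: int = 8,
    tail_cap: int = 14,
) -> None:
    """Draw a (trim, tail) abundance matrix as a bubble plot.

    X = trim, Y = tail length, circle size encodes percent abundance —
    by default diameter-proportional (``scale='diameter'``);
    ``scale='area'`` is offered because diameter scaling visually
    exaggerates differences. Coordinates beyond the display caps are
    aggregated into the edge bins for plotting only; stored matrices are
    never truncated.
    """
    if scale not in ("diameter", "area"):
        raise ValueError(f"unknown scale {scale!r}")
    shown: dict[tuple[int, int], float] = {}
    for (t, l), pct in matrix.mass.items():
        key = (min(t, trim_cap), min(l, tail_cap))
        shown[key] = shown.get(key, 0.0) + pct
    max_pct = max(shown.values())
    xs, ys, sizes = [], [], []
    for (t, l), pct in sorted(shown.items()):
        if pct <= 0:
            continue
        xs.append(t)
        ys.append(l)
        rel = pct / max_pct
        diameter = max_diameter_pt * (rel if scale == "diameter" else rel ** 0.5)
        sizes.append(diameter ** 2)  # scatter sizes are areas in points^2
    fig, ax = plt.subplots(figsize=(4.2, 4.8))
    ax.scatter(xs, ys, s=sizes, color="#3b6ea5", alpha=0.85, edgecolors="none")
    ax.set_xlabel("trimmed nucleotides")
    ax.set_ylabel("tailed nucleotides")
    ax.set_title(matrix.scope + (" (no annotated reads)" if matrix.renormalized_without_origin else ""))
    ax.set_xlim(-0.8, trim_cap + 0.8)
    ax.set_ylim(-0.8, tail_cap + 0.8)
    ax.set_xticks(range(trim_cap + 1))
    ax.grid(True, linewidth=0.3, alpha=0.4)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def render_composition_bars(
    panels: dict[str, Sequence[TailCompositionSummary]],
    path: str | Path,
) -> None:
    """Stacked tailing-extent bars split by tail nucleotide composition.

    One panel per genotype; bar height at tail length l is the percent of
    analyzed reads carrying an l-nt tail, partitioned by the nucleotide
    fractions of those tails (so the stack height equals the extent). A
    panel with no tailing is annotated with its unmodified mass.
    """
    n = max(len(panels), 1)
    fig, axes = plt.subplots(1, n, figsize=(3.2 * n, 3.2), squeeze=False, sharey=True)
    for ax, (label, series) in zip(axes[0], panels.items()):
        tailed = [s for s in series if s.scope != "tail-length-0" and s.extent_percent > 0]
        if not any(not s.empty for s in tailed):
            untailed = next((s for s in series if s.scope == "tail-length-0"), None)
            note = f"unmodified: {untailed.extent_percent:.1f}%" if untailed else "no tails"
            ax.text(0.5, 0.5, note, ha="center", va="center", transform=ax.transAxes)
            ax.set_title(label)
            continue
        for summary in tailed:
            length = int(summary.scope.rsplit("-", 1)[1])
            bottom = 0.0
            for nt in NUCLEOTIDES:
                frac = summary.fraction_by_nucleotide.get(nt, 0.0)
                height = summary.extent_percent * frac
                if height > 0:
                    ax.bar(length, height, bottom=bottom, color=NT_COLORS[nt], width=0.8)
                    bottom += height
        ax.set_title(label)
        ax.set_xlabel("tail length (nt)")
    axes[0][0].set_ylabel("% of analyzed reads")
    handles = [plt.Rectangle((0, 0), 1, 1, color=NT_COLORS[nt]) for nt in NUCLEOTIDES]
    fig.legend(handles, NUCLEOTIDES, loc="upper right", ncol=4, frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
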