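"""Optional density-style plots of end-offset histograms.

Overlaid per-protocol histograms around the anchor (TSS or TES), one
panel per size fraction, with a dashed vertical line at offset 0.
"""

from __future__ import annotations

from typing import Dict, Sequence

from .profiling import OffsetProfile


def plot_profiles(profiles: Dict[str, OffsetProfile], path, title: str = "") -> None:
    """Overlay one histogram per protocol label and save to ``path`` (PNG).

    ``profiles`` maps a protocol label to an :class:`OffsetProfile` built
    on the same anchor/window/bin grid.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3.2))
    for label, prof in sorted(profiles.items()):
        centers = (prof.bin_edges[:-1] + prof.bin_edges[1:]) / 2.0
        total = prof.counts.sum() or 1
        ax.step(centers, prof.counts / total, where="mid", label=label, alpha=0.7)
    ax.axvline(0, linestyle="--", color="green", linewidth=1)
    any_prof = next(iter(profiles.values()))
    ax.set_xlabel(f"offset from annotated {any_prof.anchor} (bp)")
    ax.set_ylabel("fraction of reads")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
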