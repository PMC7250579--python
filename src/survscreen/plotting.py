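"""Minimal visual summary: rank versus % overrepresented guides."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt


def plot_rank_vs_pct(ranked, path, highlight_top: int = 10) -> None:
    """Scatter of gene rank against % overrepresented guides.

    The top ``highlight_top`` genes are emphasised, echoing how screen
    results are usually presented as a ranked leaderboard.
    """
    frame = ranked.frame
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(frame["rank"], frame["pct_overrepresented"], s=8, alpha=0.5, color="grey")
    top = frame.head(highlight_top)
    ax.scatter(top["rank"], top["pct_overrepresented"], s=20, color="crimson")
    ax.set_xlabel("gene rank")
    ax.set_ylabel("% overrepresented guides")
    ax.set_title("Survivor-screen gene ranking")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
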