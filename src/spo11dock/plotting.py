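"""Plots for the spacing analysis."""

from __future__ import annotations

from pathlib import Path

from .scan import ScanResult

__all__ = ["plot_clash_vs_length"]


def plot_clash_vs_length(scan: list[ScanResult], path: str | Path,
                         title: str = "Inter-complex clashes vs duplex length"):
    """Clash count against duplex length, with co-oriented lengths marked."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lengths = [r.length for r in scan]
    clashes = [r.n_clashes for r in scan]
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(lengths, clashes, "o-", color="firebrick", lw=1.5, ms=4)
    co = [r.length for r in scan if r.co_oriented]
    for x in co:
        ax.axvline(x, color="steelblue", alpha=0.3, lw=1)
    ax.set_xlabel("duplex length (bp)")
    ax.set_ylabel("steric clashes")
    ax.set_title(title, fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
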