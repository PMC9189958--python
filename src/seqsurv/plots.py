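"""Calibration and discrimination dot charts from decile tables.

Plotting is optional: these helpers import matplotlib lazily and are
never required by the metric computations or the tests.
"""

from __future__ import annotations

from pathlib import Path

from .metrics import DecileTable


def _axes(title: str):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.set_title(title)
    return fig, ax


def calibration_plot(tables: dict[str, DecileTable], path: str | Path,
                     title: str = "Calibration") -> Path:
    """Mean predicted 5-year risk vs observed event proportion per decile.

    ``tables`` maps a model label to its decile table; the diagonal marks
    perfect calibration.
    """
    fig, ax = _axes(title)
    lim = 0.0
    for label, table in tables.items():
        ax.plot(table.mean_predicted, table.observed_proportion, "o-",
                label=label, alpha=0.8)
        lim = max(lim, table.mean_predicted.max(),
                  table.observed_proportion.max())
    ax.plot([0, lim], [0, lim], "k--", linewidth=0.8)
    ax.set_xlabel("mean predicted 5-year risk")
    ax.set_ylabel("observed 5-year event proportion")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    return Path(path)


def discrimination_plot(tables: dict[str, DecileTable], path: str | Path,
                        title: str = "Discrimination") -> Path:
    """Share of all observed events per decile of predicted risk."""
    fig, ax = _axes(title)
    for label, table in tables.items():
        deciles = range(1, len(table.event_share) + 1)
        ax.plot(deciles, table.event_share, "o", label=label, alpha=0.8)
    ax.set_xlabel("decile of predicted risk")
    ax.set_ylabel("share of observed events")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    return Path(path)
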