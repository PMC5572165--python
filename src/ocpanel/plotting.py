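"""Optional figure output (non-interactive Agg backend)."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .survival import KMCurve  # noqa: E402


def plot_km_pair(
    breachers: Optional[KMCurve],
    non_breachers: Optional[KMCurve],
    path: str | Path,
    title: str = "Survival by threshold breach",
) -> None:
    """Two-arm step plot of post-diagnosis survival (solid = breachers)."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for curve, style, label in (
        (breachers, "-", "breached threshold"),
        (non_breachers, "--", "did not breach"),
    ):
        if curve is None:
            continue
        xs = [0.0] + list(curve.times)
        ys = [1.0] + list(curve.survival)
        ax.step(xs, ys, where="post", linestyle=style, color="black", label=label)
    ax.set_xlabel("days from diagnosis")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.05)
    ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_sensitivity_by_bin(
    rows, bin_order: Sequence[str], path: str | Path, stratum: str = "pan"
) -> None:
    """Sensitivity of each panel across tDx bins for one stratum."""
    fig, ax = plt.subplots(figsize=(6, 4))
    panels = sorted({r.panel for r in rows})
    for panel in panels:
        ys = []
        for label in bin_order:
            match = [
                r.sensitivity for r in rows
                if r.panel == panel and r.stratum == stratum and r.bin == label
            ]
            ys.append(match[0] if match and match[0] is not None else float("nan"))
        ax.plot(range(len(bin_order)), ys, marker="o", label=panel)
    ax.set_xticks(range(len(bin_order)), bin_order)
    ax.set_xlabel("time to diagnosis")
    ax.set_ylabel("sensitivity")
    ax.set_ylim(0, 1.05)
    ax.set_title(f"Sensitivity by tDx bin ({stratum})")
    ax.legend(frameon=False, fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
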