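"""Optional figure output: CE plane with ellipse, acceptability curves, tornado."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .cea import CeacCurve, EllipseSpec
from .sensitivity import TornadoEntry


def plot_ce_plane(samples: np.ndarray, ellipse: EllipseSpec, path: str | Path,
                  wtpt: float | None = None) -> None:
    """Scatter of (ΔE, ΔC) draws with the 95 % confidence ellipse."""
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(samples[:, 1], samples[:, 0], s=6, alpha=0.4,
               label="PSA replicates")
    boundary = ellipse.boundary()
    ax.plot(boundary[:, 0], boundary[:, 1], "r-",
            label=f"{ellipse.level:.0%} confidence ellipse")
    if wtpt is not None:
        de = np.linspace(*ax.get_xlim(), 10)
        ax.plot(de, wtpt * de, "k--", lw=0.8, label=f"WTPT {wtpt:,.0f} EUR/QALY")
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("Incremental effectiveness (QALY per patient-year)")
    ax.set_ylabel("Incremental cost (EUR per patient-year)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(curve: CeacCurve, path: str | Path) -> None:
    """Acceptability curves of the two scenarios over the threshold grid."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for name, acc in curve.acceptance.items():
        ax.plot(curve.wtpt_values, acc, label=f"Scenario {name}")
    ax.set_xlabel("Willingness-to-pay threshold (EUR/QALY)")
    ax.set_ylabel("Acceptance probability")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_tornado(entries: list[TornadoEntry], base_icer: float,
                 path: str | Path, top: int = 15) -> None:
    """Horizontal-bar tornado of the ICER under ±10 % parameter changes."""
    shown = [e for e in entries if e.max_abs_pct_change > 0][:top][::-1]
    fig, ax = plt.subplots(figsize=(7, 0.4 * max(len(shown), 4) + 1.5))
    for y, e in enumerate(shown):
        lo, hi = sorted([e.icer_low, e.icer_high])
        ax.barh(y, hi - lo, left=lo, height=0.6, color="#4878d0")
    ax.axvline(base_icer, color="k", lw=1, label="base ICER")
    ax.set_yticks(range(len(shown)))
    ax.set_yticklabels([e.parameter_id for e in shown], fontsize=7)
    ax.set_xlabel("ICER (EUR/QALY)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
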