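"""Minimal Kaplan-Meier and ROC figures for pipeline reports."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_km(km_tables: dict, path: str | Path) -> None:
    """Step plot of one KM curve per group (time, survival columns)."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, km in km_tables.items():
        ax.step(km["time"], km["survival"], where="post", label=str(label))
    ax.set_xlabel("months")
    ax.set_ylabel("relapse-free survival")
    ax.set_ylim(0, 1.05)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def plot_roc(rocs: dict, path: str | Path) -> None:
    """ROC curves for each named marker (ROCResult values)."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    for label, res in rocs.items():
        ax.plot(res.fpr, res.tpr, label=f"{label} (AUC {res.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
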