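"""Dose-response figures: label counts and reader quality vs. CTDIvol."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_detection_counts(detection_tab: pd.DataFrame, path: str | Path) -> None:
    """Per-lesion true-positive label counts vs. dose, one panel per
    reconstruction."""
    recons = sorted(detection_tab["reconstruction"].unique())
    fig, axes = plt.subplots(1, len(recons), figsize=(5 * len(recons), 3.5),
                             sharey=True, squeeze=False)
    for ax, recon in zip(axes[0], recons):
        sub = detection_tab[detection_tab["reconstruction"] == recon]
        for lid, s in sub.groupby("lesion_id"):
            ax.plot(s["dose_mGy"], s["n_matched"], marker="o", label=lid)
        ax.set_title(recon)
        ax.set_xlabel("CTDIvol (mGy)")
        ax.set_ylabel("true positive labels")
    axes[0][0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_reader_quality(reader_agg: pd.DataFrame, path: str | Path) -> None:
    """Mean reader quality (error bars: SEM across readers) vs. dose."""
    recons = sorted(reader_agg["reconstruction"].unique())
    fig, axes = plt.subplots(1, len(recons), figsize=(5 * len(recons), 3.5),
                             sharey=True, squeeze=False)
    for ax, recon in zip(axes[0], recons):
        sub = reader_agg[reader_agg["reconstruction"] == recon]
        for lid, s in sub.groupby("lesion_id"):
            ax.errorbar(s["dose_mGy"], s["mean_quality"], yerr=s["sem_quality"],
                        marker="o", capsize=2, label=lid)
        ax.set_title(recon)
        ax.set_xlabel("CTDIvol (mGy)")
        ax.set_ylabel("image quality rating")
        ax.set_ylim(0, 3.2)
    axes[0][0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
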