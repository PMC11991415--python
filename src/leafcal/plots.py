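"""Basic plots: LV scans, score heatmaps, learning curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from .validation import LearningCurveResult, LVScanResult

__all__ = ["plot_lv_scan", "plot_learning_curve", "plot_score_heatmap"]


def plot_lv_scan(result: LVScanResult, path) -> None:
    """AIC and leaf-level test R2 against the LV count."""
    fig, ax1 = plt.subplots(figsize=(6, 4))
    ax2 = ax1.twinx()
    k = result.lv_values
    ax1.plot(k, result.mean_aic, color="tab:green", label="AIC")
    ax1.fill_between(k, result.mean_aic - result.sd_aic,
                     result.mean_aic + result.sd_aic,
                     color="tab:green", alpha=0.2)
    ax2.plot(k, result.mean_r2, color="tab:orange", label="test R2")
    ax2.fill_between(k, result.mean_r2 - result.sd_r2,
                     result.mean_r2 + result.sd_r2,
                     color="tab:orange", alpha=0.2)
    ax1.axvline(result.chosen_lv, color="k", linestyle="--")
    ax1.set_xlabel("latent variables")
    ax1.set_ylabel("AIC")
    ax2.set_ylabel("test R2")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_learning_curve(result: LearningCurveResult, path) -> None:
    """Train/test MAE versus training-set size."""
    fig, ax = plt.subplots(figsize=(6, 4))
    s = result.sizes
    ax.plot(s, result.train_mae_mean, color="tab:blue", label="train")
    ax.fill_between(s, result.train_mae_mean - result.train_mae_sd,
                    result.train_mae_mean + result.train_mae_sd,
                    color="tab:blue", alpha=0.2)
    ax.plot(s, result.test_mae_mean, color="tab:orange", label="test")
    ax.fill_between(s, result.test_mae_mean - result.test_mae_sd,
                    result.test_mae_mean + result.test_mae_sd,
                    color="tab:orange", alpha=0.2)
    ax.set_xlabel("training leaves")
    ax.set_ylabel("MAE (ug/cm2)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_score_heatmap(table: pd.DataFrame, value: str, path) -> None:
    """Sensor x species heatmap of a validation score column."""
    pivot = table.pivot(index="species", columns="sensor", values=value)
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(pivot.to_numpy(), cmap="viridis", aspect="auto")
    ax.set_xticks(range(len(pivot.columns)), pivot.columns)
    ax.set_yticks(range(len(pivot.index)), pivot.index)
    for i in range(pivot.shape[0]):
        for j in range(pivot.shape[1]):
            ax.text(j, i, f"{pivot.iat[i, j]:.2f}", ha="center", va="center",
                    color="w", fontsize=8)
    fig.colorbar(im, ax=ax, label=value)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
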