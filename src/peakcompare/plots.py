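"""Matplotlib figures for every analysis, one function per plot.

Each function draws onto a fresh figure, saves it as PNG to ``path`` and
returns the path. Figures are deliberately plain — the report embeds
them as static images.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .annotation import FeatureAnnotation, StateAnnotation, TSSProfile
from .binning import CorrelationMatrix
from .comparison import OverlapMatrix, PRCurve, StatSplit, UpsetCounts


def _save(fig, path) -> Path:
    path = Path(path)
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_upset(upset: UpsetCounts, path) -> Path:
    frame = upset.to_frame()
    fig, ax = plt.subplots(figsize=(7, 3.5))
    ax.bar(frame["membership"], frame["count"], color="#4878d0")
    ax.set_ylabel("merged regions")
    ax.set_xlabel("sample membership")
    ax.tick_params(axis="x", rotation=45)
    ax.set_title("Overlap combinations")
    return _save(fig, path)


def _heatmap(values: pd.DataFrame, title: str, path, cmap="viridis",
             fmt="{:.1f}") -> Path:
    fig, ax = plt.subplots(figsize=(1.2 * len(values.columns) + 2,
                                    0.9 * len(values.index) + 2))
    im = ax.imshow(values.to_numpy(dtype=float), cmap=cmap, aspect="auto")
    ax.set_xticks(range(len(values.columns)), values.columns, rotation=45)
    ax.set_yticks(range(len(values.index)), values.index)
    for i in range(values.shape[0]):
        for j in range(values.shape[1]):
            v = values.iat[i, j]
            if pd.notna(v):
                ax.text(j, i, fmt.format(v), ha="center", va="center",
                        color="white", fontsize=8)
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_title(title)
    return _save(fig, path)


def overlap_heatmap(matrix: OverlapMatrix, path) -> Path:
    """Percent of row-sample peaks overlapping each column sample."""
    return _heatmap(matrix.values, "Pairwise percent overlap", path)


def plot_corr(matrix: CorrelationMatrix, path) -> Path:
    return _heatmap(matrix.values, f"Pairwise {matrix.method} correlation",
                    path, cmap="RdBu_r", fmt="{:.2f}")


def plot_stat(splits: Mapping[str, StatSplit], path) -> Path:
    fig, ax = plt.subplots(figsize=(1.6 * max(1, len(splits)) + 2, 4))
    data, labels = [], []
    for label, split in splits.items():
        data += [split.overlapping_q, split.nonoverlapping_q]
        labels += [f"{label}\noverlap", f"{label}\nnon-overlap"]
    ax.boxplot(data, tick_labels=labels)
    ax.set_ylabel("-log10 q-value")
    ax.set_title("Significance of peaks by reference overlap")
    return _save(fig, path)


def plot_precision_recall(curves: Mapping[str, PRCurve], path) -> Path:
    fig, ax = plt.subplots(figsize=(5, 4.5))
    for label, curve in curves.items():
        ax.plot(curve.recall, curve.precision, "o-", label=label)
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.05)
    ax.legend()
    ax.set_title("Precision-recall across strength thresholds")
    return _save(fig, path)


def plot_chromhmm(annotations: Mapping[str, StateAnnotation], path) -> Path:
    frame = pd.DataFrame({label: ann.fractions
                          for label, ann in annotations.items()})
    return _heatmap(frame, "Chromatin-state composition (fraction of bases)",
                    path, fmt="{:.2f}")


def plot_features(annotations: Mapping[str, FeatureAnnotation], path) -> Path:
    frame = pd.DataFrame({label: ann.fractions
                          for label, ann in annotations.items()})
    fig, ax = plt.subplots(figsize=(6, 4))
    bottom = np.zeros(len(frame.columns))
    for feature in frame.index:
        ax.bar(frame.columns, frame.loc[feature], bottom=bottom, label=feature)
        bottom += frame.loc[feature].to_numpy()
    ax.set_ylabel("fraction of peaks")
    ax.legend(bbox_to_anchor=(1.02, 1), loc="upper left", fontsize=8)
    ax.set_title("Genomic feature annotation")
    return _save(fig, path)


def plot_tss(profiles: Mapping[str, TSSProfile], path) -> Path:
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, prof in profiles.items():
        centers = prof.bin_starts + prof.bin_width / 2
        ax.plot(centers, prof.normalized, label=label)
    ax.set_xlabel("distance from TSS (bp)")
    ax.set_ylabel("peak incidences per TSS")
    ax.axvline(0, color="grey", lw=0.8, ls="--")
    ax.legend()
    ax.set_title("Peak frequency around transcription starts")
    return _save(fig, path)


def plot_enrichment(results: Mapping[str, pd.DataFrame], path,
                    max_sets: int = 10) -> Path:
    """Dot plot: -log10 q per gene set, dot size = overlap count."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ytick, ylab = [], []
    y = 0
    for label, frame in results.items():
        top = frame.head(max_sets)
        for _, row in top.iterrows():
            q = max(row["q_value"], 1e-300)
            ax.scatter(-np.log10(q), y, s=20 + 12 * row["k"], alpha=0.7,
                       color="#4878d0")
            ytick.append(y)
            ylab.append(f"{label}: {row['set']}")
            y += 1
    ax.set_yticks(ytick, ylab, fontsize=8)
    ax.set_xlabel("-log10 adjusted p")
    ax.set_title("Gene-set enrichment")
    return _save(fig, path)
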