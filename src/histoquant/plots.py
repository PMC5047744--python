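"""Optional figures: per-family abundance bar charts and a sample scatter matrix."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .quantification import AbundanceTable

__all__ = ["abundance_barplots", "scatter_matrix"]


def abundance_barplots(table: AbundanceTable, outdir: str | Path) -> list[Path]:
    """Mean relative abundance per form, grouped by condition, one panel per
    family; error bars show SD for n > 2 and the range for n = 2."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    d = table.data
    for fam in d["backbone"].unique():
        sub = d[d["backbone"] == fam]
        forms = sorted(sub["form"].unique())
        conditions = list(dict.fromkeys(sub["condition"]))
        x = np.arange(len(forms))
        width = 0.8 / max(len(conditions), 1)
        fig, ax = plt.subplots(figsize=(max(6, 0.6 * len(forms) * len(conditions)), 4))
        for ci, cond in enumerate(conditions):
            means, errs = [], []
            for form in forms:
                v = sub[(sub["condition"] == cond) & (sub["form"] == form)]["fraction"].to_numpy()
                means.append(v.mean() if len(v) else np.nan)
                if len(v) > 2:
                    errs.append(v.std(ddof=1))
                elif len(v) == 2:
                    errs.append(np.ptp(v) / 2)
                else:
                    errs.append(0.0)
            ax.bar(x + ci * width, means, width, yerr=errs, capsize=2, label=cond)
        ax.set_xticks(x + 0.4 - width / 2)
        ax.set_xticklabels([f.split(":", 1)[-1] for f in forms], rotation=60, ha="right", fontsize=7)
        ax.set_ylabel("relative abundance")
        ax.set_title(fam)
        ax.legend(fontsize=7)
        fig.tight_layout()
        path = outdir / f"abundance_{fam.replace('/', '_').replace('.', '_')}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written


def scatter_matrix(table: AbundanceTable, path: str | Path) -> Path:
    """Pairwise sample-vs-sample scatter of per-form abundances."""
    wide = table.wide()
    samples = list(wide.index)
    k = len(samples)
    fig, axes = plt.subplots(k, k, figsize=(1.6 * k, 1.6 * k), squeeze=False)
    for i in range(k):
        for j in range(k):
            ax = axes[i][j]
            if i == j:
                ax.annotate(samples[i], (0.5, 0.5), ha="center", va="center", fontsize=6)
            else:
                ax.scatter(wide.iloc[j], wide.iloc[i], s=4)
            ax.set_xticks([])
            ax.set_yticks([])
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
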