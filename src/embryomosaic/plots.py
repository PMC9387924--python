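"""Figure generation: per-cell segmentation plots, VS distributions,
incidence/type bar charts."""

from __future__ import annotations

import numpy as np

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .bin_io import BinGrid
from .copynumber import CopyNumberStates, CorrectedProfile, chrom_baseline
from .qc import VariabilityScore


def segmentation_plot(profile: CorrectedProfile, states: CopyNumberStates | None,
                      grid: BinGrid, path, title: str = "") -> None:
    """Log2 corrected bin values along the genome, colored by call direction
    (red gain, green loss, grey baseline), with chromosome boundaries."""
    fig, ax = plt.subplots(figsize=(14, 3))
    x = np.arange(grid.n_bins)
    vals = np.where(profile.values > 0, profile.values, np.nan)
    log2 = np.log2(vals)
    color = np.full(grid.n_bins, "0.5", dtype=object)
    if states is not None:
        for chrom in grid.chrom_names:
            idx = grid.chrom_index(chrom)
            base = chrom_baseline(chrom, profile.sex)
            st = states.states[idx]
            color[idx[st > base]] = "tab:red"
            color[idx[(st >= 0) & (st < base)]] = "tab:green"
    ax.scatter(x, log2, s=2, c=list(color), rasterized=True)
    boundaries, labels, pos = [], [], []
    for chrom in grid.chrom_names:
        idx = grid.chrom_index(chrom)
        boundaries.append(idx[-1] + 0.5)
        labels.append(chrom.replace("chr", ""))
        pos.append(idx.mean())
    for b in boundaries[:-1]:
        ax.axvline(b, color="0.85", lw=0.5)
    ax.set_xticks(pos, labels, fontsize=7)
    ax.set_ylim(-2.5, 2.5)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_ylabel("log2 corrected count")
    ax.set_title(title or (profile.cell_id or ""))
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def vs_plot(scores: list[VariabilityScore], path) -> None:
    """VS distribution of a batch, split by retained/excluded."""
    vs = np.array([s.vs for s in scores])
    kept = np.array([s.retained for s in scores])
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 3))
    ax1.hist([vs[kept], vs[~kept]], bins=30, stacked=True,
             label=[f"analyzed (n={kept.sum()})", f"excluded (n={(~kept).sum()})"],
             color=["tab:blue", "tab:orange"])
    ax1.set_xlabel("variability score")
    ax1.legend(fontsize=7)
    data = [vs[kept]] + ([vs[~kept]] if (~kept).any() else [])
    ax2.boxplot(data, tick_labels=["analyzed", "excluded"][:len(data)])
    ax2.set_ylabel("VS")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def incidence_plot(incidence: dict, type_distribution: dict, path) -> None:
    """Mosaicism incidence per lineage and mosaic-type composition."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 3))
    lineages = list(incidence)
    pct = [incidence[lin]["pct"] for lin in lineages]
    ax1.bar(lineages, pct, color="tab:blue")
    for i, (lin, p) in enumerate(zip(lineages, pct)):
        ax1.text(i, p, f"{p:.2f}%\n({incidence[lin]['n_mosaic']}/{incidence[lin]['n_evaluable']})",
                 ha="center", va="bottom", fontsize=7)
    ax1.set_ylabel("mosaic incidence (%)")
    ax1.set_ylim(0, 110)
    bottom = np.zeros(len(lineages))
    for subtype, col in (("whole", "tab:blue"), ("segmental", "tab:orange"),
                         ("complex", "tab:green")):
        vals = np.array([type_distribution.get(lin, {}).get(subtype, 0) or 0
                         for lin in lineages])
        vals = np.nan_to_num(vals)
        ax2.bar(lineages, vals, bottom=bottom, label=subtype, color=col)
        bottom += vals
    ax2.set_ylabel("% of mosaic embryos")
    ax2.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
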