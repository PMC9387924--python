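"""Per-cell amplification-variability QC.

Low-coverage whole-genome-amplified single cells differ wildly in how
evenly they amplify; cells with very uneven coverage produce unreliable
copy-number calls. The variability score (VS) summarizes this: for each
chromosome the corrected bin values are covered by 30 equal-length sliding
windows, the sample SD within each window is averaged, and the VS is the
mean of the five largest per-chromosome averages. The noisiest fraction of
a batch (default: top 15% by VS) is excluded before any mosaicism
analysis.

Window recipe (frozen here since "30 sliding windows" admits several
readings): a chromosome with n unmasked bins is covered by exactly 30
windows of length ceil(n/30) whose starts are evenly spaced over
[0, n - L] — disjoint when 30·L == n, overlapping otherwise. Chromosomes
with fewer than 30 unmasked bins fall back to n windows of length 1
(all-zero SDs) and are flagged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .bin_io import BinGrid
from .copynumber import CorrectedProfile

N_WINDOWS = 30
TOP_CHROMS = 5
EXCLUDE_FRACTION = 0.15


@dataclass
class VariabilityScore:
    cell_id: str | None
    per_chrom: dict[str, float]     # windowed-SD average per chromosome
    vs: float                       # mean of the TOP_CHROMS largest averages
    retained: bool = True
    short_chroms: tuple[str, ...] = ()   # chromosomes with < n_windows bins


def _window_starts(n: int, length: int, n_windows: int) -> np.ndarray:
    return np.round(np.linspace(0, n - length, n_windows)).astype(int)


def windowed_sd_average(x: np.ndarray, n_windows: int = N_WINDOWS) -> float:
    """Mean over evenly spaced windows of the within-window sample SD."""
    n = len(x)
    if n == 0:
        return float("nan")
    if n < n_windows:
        return 0.0
    length = math.ceil(n / n_windows)
    starts = _window_starts(n, length, n_windows)
    windows = x[starts[:, None] + np.arange(length)[None, :]]
    return float(np.std(windows, axis=1, ddof=1).mean())


def variability_score(profile: CorrectedProfile, grid: BinGrid,
                      n_windows: int = N_WINDOWS,
                      top_chroms: int = TOP_CHROMS) -> VariabilityScore:
    """Variability score of one cell from its corrected profile."""
    per_chrom: dict[str, float] = {}
    short: list[str] = []
    for chrom in grid.chrom_names:
        idx = grid.chrom_index(chrom)
        x = profile.values[idx][~profile.masked[idx]]
        if len(x) == 0:
            continue
        if len(x) < n_windows:
            short.append(chrom)
        per_chrom[chrom] = windowed_sd_average(x, n_windows)
    if len(per_chrom) < top_chroms:
        raise ValueError(
            f"only {len(per_chrom)} analyzable chromosomes; "
            f"need >= {top_chroms} to form the variability score")
    top = sorted(per_chrom.values(), reverse=True)[:top_chroms]
    return VariabilityScore(profile.cell_id, per_chrom, float(np.mean(top)),
                            short_chroms=tuple(short))


def filter_cells(scores: list[VariabilityScore],
                 exclude_fraction: float = EXCLUDE_FRACTION
                 ) -> tuple[list[VariabilityScore], list[VariabilityScore]]:
    """Split a batch into (retained, excluded) by cohort-relative VS rank.

    Exactly floor(n * exclude_fraction) cells with the highest VS are
    excluded; ties at the boundary are broken by stable input order (a
    warning is emitted when the boundary falls inside a tie). Both returned
    lists preserve input order, and every score's ``retained`` flag is set.
    """
    if not scores:
        raise ValueError("no scores to filter")
    if not (0 <= exclude_fraction < 1):
        raise ValueError(f"exclude_fraction {exclude_fraction} outside [0, 1)")
    n = len(scores)
    k = math.floor(n * exclude_fraction)
    vs = np.array([s.vs for s in scores])
    order = np.argsort(-vs, kind="stable")
    excluded_idx = set(order[:k].tolist())
    if 0 < k < n and vs[order[k - 1]] == vs[order[k]]:
        warnings.warn("VS tie at the exclusion boundary; resolved by stable input order")
    for i, s in enumerate(scores):
        s.retained = i not in excluded_idx
    retained = [s for s in scores if s.retained]
    excluded = [s for s in scores if not s.retained]
    return retained, excluded


def filter_cells_absolute(scores: list[VariabilityScore], max_vs: float
                          ) -> tuple[list[VariabilityScore], list[VariabilityScore]]:
    """Absolute-threshold variant for reuse outside batch settings."""
    for s in scores:
        s.retained = s.vs <= max_vs
    return ([s for s in scores if s.retained], [s for s in scores if not s.retained])
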