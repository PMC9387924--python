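"""Per-cell copy-number inference from binned read counts.

The stages mirror a standard low-coverage single-cell CNV workflow:

1. ``correct_counts`` — divide raw bin counts by mappability, remove the
   GC-content bias with a smooth median curve, and normalize so the median
   of unmasked autosomal bins equals 1 (i.e. corrected value 1.0 means the
   cell's baseline ploidy, copy 2 for a mostly-diploid cell).
2. ``infer_copy_number`` — Viterbi decoding of a 6-state HMM (copy 0..5)
   per chromosome; emissions are Gaussian centred at state/2 with a robust
   per-cell scale, and a single self-transition probability controls
   segmentation granularity.
3. ``segment_states`` — run-length encoding into maximal constant-state
   segments.
4. ``call_karyotype`` — drop calls below the minimum reportable size
   (default 10 Mb), merge calls separated only by masked bins, and class
   each retained call as whole-chromosome or segmental.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .bin_io import BinGrid, ReferenceTracks

# -- defaults -------------------------------------------------------------
MIN_MAPPABILITY = 0.8       # bins below this are masked
N_GC_BINS = 20              # quantile bins for the GC median curve
MIN_FIT_BINS = 200          # unmasked autosomal bins needed to fit the curve
MAX_STATE = 5               # HMM states 0..5 copies
SELF_TRANSITION = 1.0 - 1e-5
MIN_SIGMA = 0.02            # floor on the per-cell emission scale
MIN_CNV_SIZE = 10_000_000   # bp; smaller calls are not reported
WHOLE_FRACTION = 0.9        # call covers >= this fraction of the chromosome


def chrom_baseline(chrom: str, sex: str) -> int:
    """Expected copy number of a chromosome for a declared sex."""
    if chrom == "chrX":
        return 2 if sex == "XX" else 1
    if chrom == "chrY":
        return 1 if sex == "XY" else 0
    return 2


@dataclass
class CorrectedProfile:
    """GC/mappability-corrected bin values for one cell.

    ``values`` is NaN on masked bins; on unmasked autosomal bins the median
    is 1 for an analyzable cell.
    """

    values: np.ndarray
    masked: np.ndarray            # True = excluded bin
    analyzable: bool = True
    sex: str = "XX"
    cell_id: str | None = None


@dataclass
class CopyNumberStates:
    """Per-bin integer copy state (-1 on masked bins) plus optional posterior."""

    states: np.ndarray
    posterior: np.ndarray         # P(state | data) of the decoded state; NaN if not computed
    sex: str = "XX"


@dataclass(frozen=True)
class Segment:
    chrom: str
    start_bin: int                # global bin index, half-open
    end_bin: int
    state: int
    length_bp: int


@dataclass(frozen=True)
class CNVCall:
    chrom: str
    start: int                    # bp, half-open
    end: int
    delta: int                    # copy change vs baseline
    cls: str                      # 'whole' | 'segmental'

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Karyotype:
    """A cell's reportable CNV calls relative to the euploid baseline."""

    calls: tuple[CNVCall, ...] = ()
    sex: str = "XX"
    analyzable: bool = True

    @property
    def euploid(self) -> bool:
        return len(self.calls) == 0


# ---------------------------------------------------------------------------
# bias correction
# ---------------------------------------------------------------------------

def _gc_median_curve(gc: np.ndarray, y: np.ndarray, n_gc_bins: int) -> np.ndarray:
    """Smooth multiplicative GC-bias estimate ghat(gc), median-normalized to 1.

    Medians of ``y`` are taken in GC quantile bins and linearly interpolated;
    a median curve is robust to the minority of bins sitting on true CNVs.
    """
    order_qs = np.linspace(0, 1, n_gc_bins + 1)
    edges = np.unique(np.quantile(gc, order_qs))
    if len(edges) < 3:                      # (near-)constant GC: no bias to fit
        return np.ones_like(gc)
    which = np.clip(np.searchsorted(edges, gc, side="right") - 1, 0, len(edges) - 2)
    centers, medians = [], []
    for b in range(len(edges) - 1):
        sel = which == b
        if sel.sum() >= 5:
            centers.append(gc[sel].mean())
            medians.append(np.median(y[sel]))
    if len(centers) < 2:
        return np.ones_like(gc)
    centers = np.asarray(centers)
    medians = np.asarray(medians)
    scale = np.median(y)
    if scale <= 0:
        return np.ones_like(gc)
    rel = medians / scale
    ghat = np.interp(gc, centers, rel)
    # linear extrapolation beyond the outermost bin centers (np.interp clamps,
    # which leaves a residual trend in the GC tails)
    lo = gc < centers[0]
    hi = gc > centers[-1]
    if lo.any():
        slope = (rel[1] - rel[0]) / (centers[1] - centers[0])
        ghat[lo] = rel[0] + slope * (gc[lo] - centers[0])
    if hi.any():
        slope = (rel[-1] - rel[-2]) / (centers[-1] - centers[-2])
        ghat[hi] = rel[-1] + slope * (gc[hi] - centers[-1])
    return np.maximum(ghat, 1e-3)


def correct_counts(raw: np.ndarray, tracks: ReferenceTracks, grid: BinGrid, *,
                   sex: str = "XX",
                   min_mappability: float = MIN_MAPPABILITY,
                   n_gc_bins: int = N_GC_BINS,
                   min_fit_bins: int = MIN_FIT_BINS,
                   mask_zero_bins: bool = True,
                   cell_id: str | None = None) -> CorrectedProfile:
    """GC/mappability correction and median normalization for one cell.

    Zero-count bins are masked by default: at the working depths a zero bin
    is an amplification dropout, not a biological signal, and leaving it in
    fragments whole-chromosome events at decoding time.

    A cell that cannot be normalized (all-zero counts, or too few usable
    bins to fit the bias curve) is returned flagged ``analyzable=False``
    rather than raising, so batch callers can skip it.
    """
    raw = np.asarray(raw, dtype=float)
    tracks.check_grid(grid)
    if raw.shape != (grid.n_bins,):
        raise ValueError(f"counts length {raw.shape} does not match grid ({grid.n_bins} bins)")

    masked = (np.isnan(tracks.gc) | np.isnan(tracks.mappability)
              | (tracks.mappability < min_mappability))
    if mask_zero_bins:
        masked |= raw == 0
    if sex == "XX":
        masked |= grid.chroms.astype(str) == "chrY"

    values = np.full(grid.n_bins, np.nan)
    ok = ~masked
    values[ok] = raw[ok] / tracks.mappability[ok]

    auto = ok & grid.is_autosome()
    if auto.sum() < min_fit_bins or np.nansum(values[auto]) <= 0:
        return CorrectedProfile(values * np.nan, masked, analyzable=False, sex=sex, cell_id=cell_id)

    ghat = _gc_median_curve(tracks.gc[auto], values[auto], n_gc_bins)
    full_ghat = np.ones(grid.n_bins)
    full_ghat[auto] = ghat
    # sex-chromosome bins are corrected with the curve evaluated at their GC
    sexbins = ok & ~grid.is_autosome()
    if sexbins.any():
        fit_gc = tracks.gc[auto]
        fit_ghat = ghat
        order = np.argsort(fit_gc)
        full_ghat[sexbins] = np.maximum(
            np.interp(tracks.gc[sexbins], fit_gc[order], fit_ghat[order]), 1e-3)
    values[ok] = values[ok] / full_ghat[ok]

    med = np.median(values[auto])
    if not np.isfinite(med) or med <= 0:
        return CorrectedProfile(values * np.nan, masked, analyzable=False, sex=sex, cell_id=cell_id)
    values /= med
    return CorrectedProfile(values, masked, analyzable=True, sex=sex, cell_id=cell_id)


# ---------------------------------------------------------------------------
# HMM decoding
# ---------------------------------------------------------------------------

def viterbi(log_emit: np.ndarray, log_trans: np.ndarray,
            log_start: np.ndarray) -> np.ndarray:
    """Most probable state path for one chromosome.

    ``log_emit`` is (n_obs, n_states); ties are broken toward the lower
    state index so decoding is deterministic.
    """
    n, k = log_emit.shape
    if n == 0:
        return np.zeros(0, dtype=int)
    score = log_start + log_emit[0]
    back = np.zeros((n, k), dtype=int)
    for t in range(1, n):
        cand = score[:, None] + log_trans          # (from, to)
        back[t] = np.argmax(cand, axis=0)
        score = cand[back[t], np.arange(k)] + log_emit[t]
    path = np.zeros(n, dtype=int)
    path[-1] = int(np.argmax(score))
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def _log_forward_backward(log_emit, log_trans, log_start):
    """Posterior state probabilities (log-space forward-backward)."""
    from scipy.special import logsumexp

    n, k = log_emit.shape
    fwd = np.zeros((n, k))
    fwd[0] = log_start + log_emit[0]
    for t in range(1, n):
        fwd[t] = logsumexp(fwd[t - 1][:, None] + log_trans, axis=0) + log_emit[t]
    bwd = np.zeros((n, k))
    for t in range(n - 2, -1, -1):
        bwd[t] = logsumexp(log_trans + (log_emit[t + 1] + bwd[t + 1])[None, :], axis=1)
    post = fwd + bwd
    post -= logsumexp(post, axis=1, keepdims=True)
    return np.exp(post)


def robust_sigma(values: np.ndarray) -> float:
    """Per-cell emission scale from first differences (insensitive to segments)."""
    x = values[np.isfinite(values)]
    if len(x) < 3:
        return MIN_SIGMA
    d = np.abs(np.diff(x))
    sigma = 1.4826 * np.median(d) / math.sqrt(2)
    return float(max(sigma, MIN_SIGMA))


def infer_copy_number(profile: CorrectedProfile, grid: BinGrid, *,
                      max_state: int = MAX_STATE,
                      self_transition: float = SELF_TRANSITION,
                      sigma: float | None = None,
                      compute_posterior: bool = False) -> CopyNumberStates:
    """Viterbi copy-number states per chromosome for one corrected profile.

    Emission means sit at state/2 on the corrected scale (copy 2 == 1.0);
    the shared emission SD defaults to a robust per-cell estimate. Each
    chromosome is decoded independently with a uniform start distribution.
    """
    if not profile.analyzable:
        raise ValueError("profile flagged unanalyzable; cannot infer copy number")
    vals = profile.values
    if np.any(np.isinf(vals)):
        raise ValueError("non-finite values in corrected profile")

    k = max_state + 1
    if sigma is None:
        sigma = robust_sigma(vals)
    means = np.arange(k) / 2.0

    off = (1.0 - self_transition) / (k - 1)
    log_trans = np.full((k, k), math.log(off))
    np.fill_diagonal(log_trans, math.log(self_transition))
    log_start = np.full(k, -math.log(k))

    states = np.full(grid.n_bins, -1, dtype=int)
    posterior = np.full(grid.n_bins, np.nan)
    for chrom in grid.chrom_names:
        idx = grid.chrom_index(chrom)
        sub = idx[~profile.masked[idx]]
        if sub.size == 0:
            continue
        x = vals[sub]
        log_emit = -((x[:, None] - means[None, :]) ** 2) / (2 * sigma * sigma)
        path = viterbi(log_emit, log_trans, log_start)
        states[sub] = path
        if compute_posterior:
            post = _log_forward_backward(log_emit, log_trans, log_start)
            posterior[sub] = post[np.arange(len(path)), path]
    return CopyNumberStates(states, posterior, sex=profile.sex)


# ---------------------------------------------------------------------------
# segmentation and karyotype calling
# ---------------------------------------------------------------------------

def segment_states(states: CopyNumberStates, grid: BinGrid) -> list[Segment]:
    """Maximal runs of constant state; masked bins split runs.

    Concatenating the returned segments reproduces the state vector on every
    unmasked bin.
    """
    segments: list[Segment] = []
    s = states.states
    for chrom in grid.chrom_names:
        idx = grid.chrom_index(chrom)
        run_start = None
        prev_state = None
        for i in idx:
            st = s[i]
            if st < 0:                         # masked bin terminates any run
                if run_start is not None:
                    segments.append(_make_segment(grid, chrom, run_start, i, prev_state))
                    run_start = None
                prev_state = None
                continue
            if prev_state is None or st != prev_state:
                if run_start is not None:
                    segments.append(_make_segment(grid, chrom, run_start, i, prev_state))
                run_start = i
                prev_state = st
        if run_start is not None:
            segments.append(_make_segment(grid, chrom, run_start, idx[-1] + 1, prev_state))
    return segments


def _make_segment(grid, chrom, start_bin, end_bin, state) -> Segment:
    return Segment(chrom, int(start_bin), int(end_bin), int(state),
                   int(grid.ends[end_bin - 1] - grid.starts[start_bin]))


def call_karyotype(segments: list[Segment], grid: BinGrid, *,
                   sex: str = "XX",
                   masked: np.ndarray | None = None,
                   min_cnv_size: int = MIN_CNV_SIZE,
                   whole_fraction: float = WHOLE_FRACTION,
                   analyzable: bool = True) -> Karyotype:
    """Reportable CNV calls from one cell's segments.

    Adjacent same-state calls separated only by masked bins are merged
    before the size test; calls spanning less than ``min_cnv_size`` are
    dropped; a retained call is 'whole' if its unmasked bins cover at least
    ``whole_fraction`` of the chromosome's analyzable (unmasked) length.
    """
    if masked is None:
        masked = np.zeros(grid.n_bins, dtype=bool)
    calls: list[CNVCall] = []
    by_chrom: dict[str, list[Segment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom, segs in by_chrom.items():
        base = chrom_baseline(chrom, sex)
        segs = sorted(segs, key=lambda s: s.start_bin)
        cand = [s for s in segs if s.state != base]
        # merge same-state candidates with only masked bins between them
        merged: list[Segment] = []
        for seg in cand:
            if merged and merged[-1].state == seg.state and \
                    masked[merged[-1].end_bin:seg.start_bin].all():
                last = merged.pop()
                merged.append(Segment(chrom, last.start_bin, seg.end_bin, seg.state,
                                      int(grid.ends[seg.end_bin - 1] - grid.starts[last.start_bin])))
            else:
                merged.append(seg)
        chrom_idx = grid.chrom_index(chrom)
        chrom_unmasked = int((~masked[chrom_idx]).sum())
        for seg in merged:
            if seg.length_bp < min_cnv_size:
                continue
            covered = int((~masked[seg.start_bin:seg.end_bin]).sum())
            cls = "whole" if chrom_unmasked > 0 and \
                covered >= whole_fraction * chrom_unmasked else "segmental"
            calls.append(CNVCall(chrom, int(grid.starts[seg.start_bin]),
                                 int(grid.ends[seg.end_bin - 1]),
                                 seg.state - base, cls))
    calls.sort(key=lambda c: (str(c.chrom), c.start))
    return Karyotype(tuple(calls), sex=sex, analyzable=analyzable)


def karyotype_from_copy_profile(copy: np.ndarray, grid: BinGrid, *,
                                sex: str = "XX",
                                masked: np.ndarray | None = None,
                                min_cnv_size: int = MIN_CNV_SIZE,
                                whole_fraction: float = WHOLE_FRACTION) -> Karyotype:
    """Karyotype implied by an integer copy-number profile (e.g. simulation truth).

    Applies the same reporting rules (size filter, whole/segmental classing)
    as the caller, so truth profiles and called karyotypes are comparable.
    """
    st = CopyNumberStates(np.where(masked, -1, copy) if masked is not None
                          else np.asarray(copy, dtype=int), np.full(grid.n_bins, np.nan), sex=sex)
    segs = segment_states(st, grid)
    return call_karyotype(segs, grid, sex=sex, masked=masked,
                          min_cnv_size=min_cnv_size, whole_fraction=whole_fraction)


def format_karyotype(k: Karyotype) -> str:
    """ISCN-like one-line summary, e.g. ``47,XX,+chr21`` or
    ``46,XX,chr2:20000000-60000000(+1)``."""
    if not k.analyzable:
        return "unanalyzable"
    total = 46 + sum(c.delta for c in k.calls if c.cls == "whole")
    parts = [f"{total},{k.sex}"]
    for c in k.calls:
        if c.cls == "whole":
            parts.append(f"{'+' if c.delta > 0 else '-'}{c.chrom}" +
                         (f"x{abs(c.delta)}" if abs(c.delta) > 1 else ""))
        else:
            parts.append(f"{c.chrom}:{c.start}-{c.end}({c.delta:+d})")
    return ",".join(parts)


def call_cell(raw: np.ndarray, tracks: ReferenceTracks, grid: BinGrid, *,
              sex: str = "XX", cell_id: str | None = None,
              min_cnv_size: int = MIN_CNV_SIZE,
              whole_fraction: float = WHOLE_FRACTION,
              self_transition: float = SELF_TRANSITION,
              min_mappability: float = MIN_MAPPABILITY):
    """Full per-cell pipeline: correct -> decode -> segment -> call.

    Returns (CorrectedProfile, CopyNumberStates | None, segments, Karyotype);
    unanalyzable cells yield an unanalyzable empty karyotype.
    """
    profile = correct_counts(raw, tracks, grid, sex=sex, cell_id=cell_id,
                             min_mappability=min_mappability)
    if not profile.analyzable:
        return profile, None, [], Karyotype((), sex=sex, analyzable=False)
    states = infer_copy_number(profile, grid, self_transition=self_transition)
    segments = segment_states(states, grid)
    karyo = call_karyotype(segments, grid, sex=sex, masked=profile.masked,
                           min_cnv_size=min_cnv_size, whole_fraction=whole_fraction)
    return profile, states, segments, karyo
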