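"""Synthetic embryo cohorts with known copy-number truth.

Each embryo develops as a balanced binary lineage tree. Meiotic errors
(arising before the first cleavage) sit on the root and are carried by
every cell; mitotic errors arise at a division and affect exactly the
descendants of one daughter: a non-disjunction gives the two daughters
reciprocal +1/-1 copies of the same region, an anaphase lag gives a single
daughter a loss. Sequenced cells are a random sample of leaves, labelled
TE or ICM by random partition; hESC cells are resampled from ICM-descended
leaves, optionally with a fitness penalty against aneuploid genomes.

Read counts emulate low-coverage (~0.3x) whole-genome-amplified single
cells: the expected count of a bin is proportional to its true copy
number, a smooth GC-bias curve and the bin's mappability, with
negative-binomial overdispersion whose level is drawn per cell (MALBAC
amplification evenness varies strongly between cells) and a small dropout
fraction of zero bins.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .bin_io import (BinGrid, CountMatrix, ReferenceTracks, write_bin_grid,
                     write_counts, write_metadata, write_tracks)
from . import copynumber
from .copynumber import Karyotype, CNVCall, chrom_baseline


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CNVEvent:
    """One planted copy-number event on the bin grid (0-based, half-open)."""

    event_id: int
    chrom: str
    start_bin: int                  # global bin index
    end_bin: int
    delta: int
    origin: str                     # 'meiotic' | 'mitotic'
    division_index: int | None = None   # generation of the division (mitotic only)
    reciprocal_partner: int | None = None  # event_id of the sister event

    def __post_init__(self):
        if self.end_bin <= self.start_bin:
            raise ValueError("event end_bin must exceed start_bin")
        if self.delta == 0:
            raise ValueError("event delta must be nonzero")
        if self.origin == "meiotic" and self.division_index is not None:
            raise ValueError("meiotic events carry no division_index")


@dataclass
class NoiseModel:
    """Emission model for binned single-cell WGA read counts.

    ``dispersion`` is the negative-binomial alpha at the cohort median
    (variance = m + alpha * m^2); each cell draws its own alpha from a
    log-normal around it with log-SD ``dispersion_spread``. ``deterministic``
    replaces sampling by the rounded expectation (the noiseless limit).
    """

    mean_depth: float = 500.0        # expected reads per bin at copy 2
    dispersion: float = 0.03
    dispersion_spread: float = 0.4
    dropout_rate: float = 0.01
    gc_mid: float = 0.45             # GC bias: floor + exp Gaussian bump
    gc_width: float = 0.12
    gc_floor: float = 0.3
    deterministic: bool = False

    def gc_bias_curve(self, gc: np.ndarray) -> np.ndarray:
        gc = np.asarray(gc, dtype=float)
        out = self.gc_floor + np.exp(-((gc - self.gc_mid) ** 2) / (2 * self.gc_width ** 2))
        out = np.where(np.isnan(gc), 1.0, out)
        if np.any(out <= 0):
            raise ValueError("gc_bias_curve must be positive on [0,1]")
        return out


@dataclass
class ForcedMeiotic:
    chrom: str
    delta: int = 1
    start_mb: int | None = None      # None -> whole chromosome
    end_mb: int | None = None


@dataclass
class ForcedMitotic:
    generation: int                  # 1-based division index; attaches at the
    kind: str = "nondisjunction"     # leftmost node of that generation
    chrom: str = "chr1"
    delta: int = 1                   # magnitude of the gain side
    start_mb: int | None = None
    end_mb: int | None = None


@dataclass
class SimConfig:
    """Study conditions for one simulated cohort."""

    n_te: int = 8
    n_icm: int = 7
    n_hesc: int = 0
    n_generations: int = 6           # 2^g leaves per embryo
    p_mitotic: float = 0.02          # per-division error probability (assumption,
    p_meiotic: float = 0.35          # not an estimate of any real cohort)
    p_whole: float = 0.5             # whole-chromosome vs segmental event mix
    p_nondisjunction: float = 0.5    # vs anaphase lag, given a mitotic error
    seg_min_mb: int = 15
    seg_max_mb: int = 80
    sex: str = "XX"
    hesc_selection: float = 0.0      # fitness penalty per aneuploid chromosome
    hesc_extra_generations: int = 0
    grid: BinGrid | None = None
    noise: NoiseModel = field(default_factory=NoiseModel)
    forced_meiotic: list[ForcedMeiotic] = field(default_factory=list)
    forced_mitotic: list[ForcedMitotic] = field(default_factory=list)

    def resolved_grid(self) -> BinGrid:
        return self.grid if self.grid is not None else BinGrid.human(self.sex)


@dataclass
class SimTruth:
    """Ground truth for one embryo: events, per-cell copy profiles, labels."""

    embryo_id: str
    grid: BinGrid
    baseline: np.ndarray             # per-bin euploid copy number
    events: list[CNVEvent]
    cell_ids: list[str]
    lineages: list[str]
    cell_truth: np.ndarray           # (n_cells, n_bins) integer copies
    carriers: dict[int, list[int]]   # event_id -> cell row indices

    @property
    def labels(self) -> pd.DataFrame:
        return pd.DataFrame({"cell_id": self.cell_ids,
                             "embryo_id": self.embryo_id,
                             "lineage": self.lineages})

    def verify(self) -> None:
        """Assert cell_truth == baseline + sum of carried event deltas."""
        recon = np.tile(self.baseline, (len(self.cell_ids), 1)).astype(np.int16)
        for ev in self.events:
            for c in self.carriers.get(ev.event_id, []):
                recon[c, ev.start_bin:ev.end_bin] += ev.delta
        assert np.array_equal(recon, self.cell_truth), "truth bookkeeping mismatch"


# ---------------------------------------------------------------------------
# lineage tree helpers (heap indexing: root 0, children 2i+1 / 2i+2)
# ---------------------------------------------------------------------------

def leaf_heap_range(n_generations: int) -> tuple[int, int]:
    n_leaves = 2 ** n_generations
    return n_leaves - 1, 2 * n_leaves - 1


def node_depth(node: int) -> int:
    return int(math.floor(math.log2(node + 1)))


def descendant_leaves(node: int, n_generations: int) -> np.ndarray:
    """Leaf numbers (0..2^g-1) below a heap node (inclusive of itself if leaf)."""
    first, _ = leaf_heap_range(n_generations)
    lo = node
    while lo < first:
        lo = 2 * lo + 1
    count = 2 ** (n_generations - node_depth(node))
    return np.arange(lo - first, lo - first + count)


def _ancestors(leaf_heap_idx: int):
    v = leaf_heap_idx
    while True:
        yield v
        if v == 0:
            return
        v = (v - 1) // 2


# ---------------------------------------------------------------------------
# embryo simulation
# ---------------------------------------------------------------------------

def _place_region(rng, grid: BinGrid, config: SimConfig, chrom=None,
                  start_mb=None, end_mb=None, whole=None):
    """Pick (chrom, start_bin, end_bin, is_whole) for an event."""
    chrom_names = grid.chrom_names
    if chrom is None:
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
    idx = grid.chrom_index(chrom)
    if start_mb is not None and end_mb is not None:
        s = grid.bin_of(chrom, start_mb * 1_000_000)
        e = grid.bin_of(chrom, end_mb * 1_000_000 - 1) + 1
        return chrom, s, e, (e - s) == len(idx)
    if whole is None:
        whole = rng.random() < config.p_whole
    if whole or len(idx) <= config.seg_min_mb:
        return chrom, int(idx[0]), int(idx[-1] + 1), True
    width_bins = max(1, grid.bin_width // 1_000_000)
    max_len = min(config.seg_max_mb // width_bins, len(idx) - 1)
    min_len = min(config.seg_min_mb // width_bins, max_len)
    length = int(rng.integers(min_len, max_len + 1))
    start = int(rng.integers(0, len(idx) - length + 1))
    return chrom, int(idx[0] + start), int(idx[0] + start + length), False


def simulate_embryo(config: SimConfig, seed, embryo_id: str = "E1") -> SimTruth:
    """One embryo's ground truth: events on a balanced lineage tree plus the
    sampled, lineage-labelled per-cell copy profiles."""
    rng = np.random.default_rng(seed)
    grid = config.resolved_grid()
    nb = grid.n_bins
    baseline = np.full(nb, 2, dtype=np.int16)
    chrom_str = grid.chroms.astype(str)
    baseline[chrom_str == "chrX"] = 2 if config.sex == "XX" else 1
    baseline[chrom_str == "chrY"] = 1 if config.sex == "XY" else 0

    g = config.n_generations
    n_leaves = 2 ** g
    if config.n_te + config.n_icm > n_leaves:
        raise ValueError("n_te + n_icm exceeds the number of tree leaves")

    leaf_copy = np.tile(baseline, (n_leaves, 1)).astype(np.int16)
    events: list[CNVEvent] = []
    leaf_events: list[list[int]] = [[] for _ in range(n_leaves)]
    next_id = [0]

    def add_event(leaves: np.ndarray, chrom, s, e, delta, origin,
                  division_index=None, partner=None) -> CNVEvent | None:
        if delta < 0 and (leaf_copy[np.ix_(leaves, np.arange(s, e))] + delta < 0).any():
            return None
        ev = CNVEvent(next_id[0], chrom, s, e, delta, origin,
                      division_index=division_index, reciprocal_partner=partner)
        next_id[0] += 1
        leaf_copy[np.ix_(leaves, np.arange(s, e))] += delta
        for lf in leaves:
            leaf_events[lf].append(ev.event_id)
        events.append(ev)
        return ev

    all_leaves = np.arange(n_leaves)

    # meiotic events: carried by every cell of the embryo
    meiotic_specs: list[ForcedMeiotic] = list(config.forced_meiotic)
    if not meiotic_specs and rng.random() < config.p_meiotic:
        meiotic_specs.append(ForcedMeiotic(
            chrom=None, delta=int(rng.choice([-1, 1]))))  # type: ignore[arg-type]
    for spec in meiotic_specs:
        forced_whole = True if (spec.chrom is not None and spec.start_mb is None) else None
        chrom, s, e, _ = _place_region(rng, grid, config, chrom=spec.chrom,
                                       start_mb=spec.start_mb, end_mb=spec.end_mb,
                                       whole=forced_whole)
        if add_event(all_leaves, chrom, s, e, spec.delta, "meiotic") is None:
            raise ValueError(
                f"meiotic event {chrom}:{s}-{e} delta {spec.delta} would drive copy number below 0")

    # forced mitotic events attach at the leftmost node of their generation
    def apply_mitotic(node: int, kind: str, chrom=None, start_mb=None, end_mb=None,
                      delta: int = 1, forced: bool = False) -> None:
        k = node_depth(node) + 1
        c1, c2 = 2 * node + 1, 2 * node + 2
        if not forced and rng.random() < 0.5:
            c1, c2 = c2, c1
        forced_whole = True if (forced and start_mb is None) else None
        for _ in range(30):
            ch, s, e, _ = _place_region(rng, grid, config, chrom=chrom,
                                        start_mb=start_mb, end_mb=end_mb,
                                        whole=forced_whole)
            if kind == "nondisjunction":
                gain = add_event(descendant_leaves(c1, g), ch, s, e, delta,
                                 "mitotic", division_index=k)
                if gain is None:
                    continue
                loss = add_event(descendant_leaves(c2, g), ch, s, e, -delta,
                                 "mitotic", division_index=k,
                                 partner=gain.event_id)
                if loss is None:   # loss side would go negative: undo the gain
                    leaf_copy[np.ix_(descendant_leaves(c1, g), np.arange(s, e))] -= delta
                    events.remove(gain)
                    for lf in descendant_leaves(c1, g):
                        leaf_events[lf].remove(gain.event_id)
                    continue
                gain.reciprocal_partner = loss.event_id
            else:                  # anaphase lag: a single daughter loses a copy
                if add_event(descendant_leaves(c1, g), ch, s, e, -abs(delta),
                             "mitotic", division_index=k) is None:
                    continue
            return
        # all placements would break the copy floor: skip this error

    for spec in config.forced_mitotic:
        if not (1 <= spec.generation <= g):
            raise ValueError(f"forced mitotic generation {spec.generation} outside 1..{g}")
        node = 2 ** (spec.generation - 1) - 1
        apply_mitotic(node, spec.kind, chrom=spec.chrom, start_mb=spec.start_mb,
                      end_mb=spec.end_mb, delta=spec.delta, forced=True)

    if config.p_mitotic > 0:
        for node in range(n_leaves - 1):   # every dividing cell
            if rng.random() < config.p_mitotic:
                kind = "nondisjunction" if rng.random() < config.p_nondisjunction \
                    else "anaphase_lag"
                apply_mitotic(node, kind)

    # sample sequenced cells and assign lineages by random leaf partition
    perm = rng.permutation(n_leaves)
    te_leaves = perm[:config.n_te]
    icm_leaves = perm[config.n_te:config.n_te + config.n_icm]

    cell_ids: list[str] = []
    lineages: list[str] = []
    rows: list[np.ndarray] = []
    carriers: dict[int, list[int]] = {ev.event_id: [] for ev in events}

    def add_cell(leaf: int, lineage: str, label: str) -> int:
        row = len(cell_ids)
        cell_ids.append(f"{embryo_id}_{label}")
        lineages.append(lineage)
        rows.append(leaf_copy[leaf].copy())
        for eid in leaf_events[leaf]:
            carriers[eid].append(row)
        return row

    for i, lf in enumerate(te_leaves):
        add_cell(int(lf), "TE", f"TE{i + 1}")
    for i, lf in enumerate(icm_leaves):
        add_cell(int(lf), "ICM", f"ICM{i + 1}")

    if config.n_hesc > 0:
        if config.n_icm == 0:
            raise ValueError("hESC cells require ICM leaves to derive from")
        weights = np.ones(len(icm_leaves))
        if config.hesc_selection > 0:
            for j, lf in enumerate(icm_leaves):
                diff = leaf_copy[lf] != baseline
                n_aneu = sum(diff[grid.chrom_index(c)].any() for c in grid.chrom_names)
                weights[j] = (1.0 - config.hesc_selection) ** n_aneu
        if weights.sum() == 0:          # every ICM leaf aneuploid: no selection
            weights[:] = 1.0
        weights = weights / weights.sum()
        picks = rng.choice(len(icm_leaves), size=config.n_hesc, replace=True, p=weights)
        for i, j in enumerate(picks):
            row = add_cell(int(icm_leaves[j]), "hESC", f"hESC{i + 1}")
            for extra in range(config.hesc_extra_generations):
                if rng.random() < config.p_mitotic:
                    ch, s, e, _ = _place_region(rng, grid, config)
                    delta = int(rng.choice([-1, 1]))
                    if rows[row][s:e].min() + delta < 0:
                        continue
                    ev = CNVEvent(next_id[0], ch, s, e, delta, "mitotic",
                                  division_index=g + extra + 1)
                    next_id[0] += 1
                    events.append(ev)
                    carriers[ev.event_id] = [row]
                    rows[row][s:e] += delta

    truth = SimTruth(embryo_id, grid, baseline, events, cell_ids, lineages,
                     np.vstack(rows) if rows else np.zeros((0, nb), dtype=np.int16),
                     carriers)
    truth.verify()
    return truth


# ---------------------------------------------------------------------------
# count emission
# ---------------------------------------------------------------------------

def emit_counts(truth: SimTruth, noise: NoiseModel, tracks: ReferenceTracks,
                seed, per_cell_alpha: np.ndarray | None = None) -> np.ndarray:
    """Noisy (cells x bins) integer read counts for one embryo's truth.

    Expected count in bin b of cell c is
    ``cell_truth[c,b]/2 * gc_bias_curve(gc[b]) * mappability[b] * mean_depth``.
    """
    tracks.check_grid(truth.grid)
    rng = np.random.default_rng(seed)
    n_cells, nb = truth.cell_truth.shape
    curve = noise.gc_bias_curve(tracks.gc)
    mapp = np.where(np.isnan(tracks.mappability), 1.0, tracks.mappability)
    mean = truth.cell_truth / 2.0 * curve[None, :] * mapp[None, :] * noise.mean_depth

    if noise.deterministic:
        counts = np.rint(mean).astype(np.int64)
    else:
        if per_cell_alpha is None:
            if noise.dispersion > 0:
                per_cell_alpha = noise.dispersion * np.exp(
                    rng.normal(0.0, noise.dispersion_spread, size=n_cells))
            else:
                per_cell_alpha = np.zeros(n_cells)
        counts = np.zeros((n_cells, nb), dtype=np.int64)
        for c in range(n_cells):
            m = mean[c]
            pos = m > 0
            alpha = per_cell_alpha[c]
            if alpha > 0:
                r = 1.0 / alpha
                p = r / (r + m[pos])
                counts[c, pos] = rng.negative_binomial(r, p)
            else:
                counts[c, pos] = rng.poisson(m[pos])
        if noise.dropout_rate > 0:
            counts[rng.random((n_cells, nb)) < noise.dropout_rate] = 0
    return counts


def make_tracks(grid: BinGrid, seed, low_map_fraction: float = 0.02) -> ReferenceTracks:
    """Synthetic GC and mappability tracks with a small low-mappability tail."""
    rng = np.random.default_rng(seed)
    gc = np.clip(rng.normal(0.41, 0.05, grid.n_bins), 0.30, 0.65)
    mapp = rng.uniform(0.92, 1.0, grid.n_bins)
    low = rng.random(grid.n_bins) < low_map_fraction
    mapp[low] = rng.uniform(0.2, 0.7, low.sum())
    return ReferenceTracks(gc, mapp)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    grid: BinGrid
    tracks: ReferenceTracks
    counts: CountMatrix
    metadata: pd.DataFrame
    truths: dict[str, SimTruth]
    config: SimConfig


def make_cohort(n_embryos: int, config: SimConfig, seed) -> Cohort:
    """Simulate ``n_embryos`` embryos and emit one pooled count matrix.

    Fully reproducible: all randomness derives from ``seed`` via spawned
    child generators.
    """
    if n_embryos < 1:
        raise ValueError("n_embryos must be >= 1")
    grid = config.resolved_grid()
    ss = np.random.SeedSequence(seed)
    track_seed, *embryo_seeds = ss.spawn(1 + n_embryos)
    tracks = make_tracks(grid, track_seed)

    truths: dict[str, SimTruth] = {}
    blocks, ids, meta_rows = [], [], []
    width = max(2, len(str(n_embryos)))
    for i, es in enumerate(embryo_seeds):
        eid = f"E{i + 1:0{width}d}"
        t_seed, c_seed = es.spawn(2)
        truth = simulate_embryo(config, t_seed, embryo_id=eid)
        truths[eid] = truth
        blocks.append(emit_counts(truth, config.noise, tracks, c_seed))
        ids.extend(truth.cell_ids)
        meta_rows.append(truth.labels)
    counts = CountMatrix(grid, np.vstack(blocks), ids)
    metadata = pd.concat(meta_rows, ignore_index=True)
    return Cohort(grid, tracks, counts, metadata, truths, config)


def _rle(copy: np.ndarray) -> list[list[int]]:
    out, start = [], 0
    for i in range(1, len(copy) + 1):
        if i == len(copy) or copy[i] != copy[start]:
            out.append([start, i, int(copy[start])])
            start = i
    return out


def write_cohort(cohort: Cohort, outdir, config_hash: str | None = None) -> dict[str, Path]:
    """Write grid (BED), counts/tracks/metadata (TSV) and truth (JSON).

    When ``config_hash`` is given it is stamped into every file (comment
    line in the text tables, key in the JSON) for provenance.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"grid": outdir / "grid.bed", "counts": outdir / "counts.tsv",
             "tracks": outdir / "tracks.tsv", "metadata": outdir / "metadata.tsv",
             "truth": outdir / "truth.json"}
    write_bin_grid(cohort.grid, paths["grid"])
    write_counts(cohort.counts, paths["counts"])
    write_tracks(cohort.tracks, cohort.grid, paths["tracks"])
    write_metadata(cohort.metadata, paths["metadata"])
    if config_hash:
        for key in ("grid", "counts", "tracks", "metadata"):
            body = paths[key].read_text()
            paths[key].write_text(f"# config_hash={config_hash}\n" + body)
    truth_doc: dict = {"_config_hash": config_hash} if config_hash else {}
    for eid, t in cohort.truths.items():
        truth_doc[eid] = {
            "events": [asdict(ev) for ev in t.events],
            "carriers": {str(k): v for k, v in t.carriers.items()},
            "cells": {cid: {"lineage": lin, "copy_rle": _rle(t.cell_truth[i])}
                      for i, (cid, lin) in enumerate(zip(t.cell_ids, t.lineages))},
        }
    paths["truth"].write_text(json.dumps(truth_doc))
    return paths


# ---------------------------------------------------------------------------
# truth-recovery evaluation
# ---------------------------------------------------------------------------

def evaluate_recovery(cohort: Cohort, karyotypes: dict[str, Karyotype],
                      min_seg_mb: int = 20, match_cover: float = 0.5) -> dict:
    """Recovery of planted events among the called cells.

    An (event, carrier-cell) pair counts as recovered when the cell's called
    karyotype contains a call on the event's chromosome with the same delta
    sign covering at least ``match_cover`` of the event span. Pairs where the
    event is not individually visible in that cell's truth (e.g. cancelled by
    an overlapping event of opposite sign) are skipped. Only cells present in
    ``karyotypes`` (i.e. QC-retained, analyzable) are considered.
    """
    grid = cohort.grid
    whole_tot = whole_hit = seg_tot = seg_hit = 0
    eup_cells = eup_called = 0
    for truth in cohort.truths.values():
        for row, cid in enumerate(truth.cell_ids):
            if cid not in karyotypes:
                continue
            if np.array_equal(truth.cell_truth[row], truth.baseline):
                eup_cells += 1
                if not karyotypes[cid].euploid:
                    eup_called += 1
        for ev in truth.events:
            span_bp = int(grid.ends[ev.end_bin - 1] - grid.starts[ev.start_bin])
            idx = grid.chrom_index(ev.chrom)
            is_whole = (ev.end_bin - ev.start_bin) == len(idx)
            if not is_whole and span_bp < min_seg_mb * 1_000_000:
                continue
            ev_start = int(grid.starts[ev.start_bin])
            ev_end = int(grid.ends[ev.end_bin - 1])
            base = truth.baseline[ev.start_bin:ev.end_bin]
            for row in truth.carriers.get(ev.event_id, []):
                cid = truth.cell_ids[row]
                if cid not in karyotypes:
                    continue
                net = truth.cell_truth[row, ev.start_bin:ev.end_bin] - base
                if not np.all(np.sign(net) == np.sign(ev.delta)):
                    continue                    # cancelled / not visible here
                hit = any(
                    c.chrom == ev.chrom and np.sign(c.delta) == np.sign(ev.delta)
                    and (min(c.end, ev_end) - max(c.start, ev_start)) >= match_cover * span_bp
                    for c in karyotypes[cid].calls)
                if is_whole:
                    whole_tot += 1
                    whole_hit += hit
                else:
                    seg_tot += 1
                    seg_hit += hit
    return {
        "whole_recovery": whole_hit / whole_tot if whole_tot else float("nan"),
        "n_whole_pairs": whole_tot,
        "segmental_recovery": seg_hit / seg_tot if seg_tot else float("nan"),
        "n_segmental_pairs": seg_tot,
        "euploid_false_call_rate": eup_called / eup_cells if eup_cells else float("nan"),
        "n_euploid_cells": eup_cells,
    }


# ---------------------------------------------------------------------------
# constructed karyotype cohort at the published study's scale
# ---------------------------------------------------------------------------

def paper_shaped_cohort(grid: BinGrid | None = None):
    """Deterministic cohort of constructed per-cell karyotypes.

    Synthetic stand-in for the study's real cell-by-cell calls: 39 embryos
    with TE sampled in 35, ICM in 15 (12 overlapping TE) and hESC in 6,
    with per-embryo truth chosen so the downstream classifiers yield the
    published embryo-level counts (23/35 mosaic TE, 9/15 ICM, 2/6 hESC,
    16/23 complex TE, 4/4/1 complex/segmental/whole ICM, 10/12 TE-ICM
    discordant, 4/19/11 meiotic/mitotic/both among 34 aneuploid embryos).
    Returns a list of :class:`~embryomosaic.mosaicism.LineageSet`.
    """
    from .mosaicism import LineageSet

    if grid is None:
        grid = BinGrid.human()

    def whole(chrom, delta=1):
        lo, hi = grid.chrom_span(chrom)
        return CNVCall(chrom, lo, hi, delta, "whole")

    def seg(chrom, s_mb, e_mb, delta=1):
        return CNVCall(chrom, s_mb * 1_000_000, e_mb * 1_000_000, delta, "segmental")

    EUP = Karyotype()
    MEI = Karyotype((whole("chr21"),))                       # meiotic trisomy 21
    DIV_W = Karyotype((whole("chr16"),))                     # mitotic whole gain
    DIV_S = Karyotype((seg("chr2", 20, 60),))                # mitotic segmental gain
    DIV_C = Karyotype((seg("chr2", 20, 60), whole("chr16")))
    MEI_C = Karyotype((seg("chr2", 20, 60), whole("chr16"), whole("chr21")))
    ALT_S = Karyotype((seg("chr5", 30, 70),))                # a different region,
    ALT_C = Karyotype((seg("chr5", 30, 70), whole("chr17")))  # for TE-ICM contrast

    euploid_ids = [f"U{i}" for i in range(1, 6)]
    meiotic_ids = [f"M{i}" for i in range(1, 5)]
    mitotic_ids = [f"T{i}" for i in range(1, 20)]
    both_ids = [f"B{i}" for i in range(1, 12)]

    def cells(eid, lin, *karyos):
        return LineageSet(eid, lin, [(f"{eid}_{lin}{i + 1}", k)
                                     for i, k in enumerate(karyos)])

    def uniform(eid, lin, k, n=4):
        return cells(eid, lin, *([k] * n))

    def mosaic(eid, lin, major, divergent):
        return cells(eid, lin, major, major, major, divergent)

    sets: list[LineageSet] = []
    # --- TE (35 embryos; 23 mosaic: 16 complex, 4 whole, 3 segmental) ---
    for eid in ["U1", "U2", "U3", "U4"]:
        sets.append(uniform(eid, "TE", EUP))
    for eid in ["M1", "M2", "M3"]:
        sets.append(uniform(eid, "TE", MEI))
    sets.append(mosaic("T1", "TE", EUP, DIV_W))
    sets.append(uniform("T2", "TE", EUP))
    for eid in ["T3", "T4", "T5", "T6", "T7"]:
        sets.append(mosaic(eid, "TE", EUP, DIV_C))
    for eid in ["T8", "T9", "T10"]:
        sets.append(mosaic(eid, "TE", EUP, DIV_W))
    for eid in ["T11", "T12", "T13"]:
        sets.append(mosaic(eid, "TE", EUP, DIV_S))
    for eid in ["T14", "T15", "T16", "T17"]:
        sets.append(uniform(eid, "TE", EUP))
    for eid in both_ids:
        sets.append(mosaic(eid, "TE", MEI, MEI_C))
    # --- ICM (15 embryos; 9 mosaic: 4 complex, 4 segmental, 1 whole) ---
    for eid in ["U2", "U3"]:
        sets.append(uniform(eid, "ICM", EUP))
    sets.append(uniform("M4", "ICM", MEI))
    for eid in ["B2", "B3", "B4"]:
        sets.append(uniform(eid, "ICM", MEI))
    for eid in ["T11", "T12"]:
        sets.append(mosaic(eid, "ICM", EUP, ALT_C))
    sets.append(mosaic("T13", "ICM", EUP, ALT_S))
    for eid in ["T14", "T15"]:
        sets.append(mosaic(eid, "ICM", EUP, DIV_C))
    for eid in ["T16", "T17", "T18"]:
        sets.append(mosaic(eid, "ICM", EUP, DIV_S))
    sets.append(mosaic("T19", "ICM", EUP, DIV_W))
    # --- hESC (6 embryos; 2 mosaic, both complex) ---
    for eid in ["T1", "T2"]:
        sets.append(mosaic(eid, "hESC", EUP, DIV_C))
    sets.append(uniform("B1", "hESC", MEI))
    sets.append(uniform("M1", "hESC", MEI))
    for eid in ["U1", "U5"]:
        sets.append(uniform(eid, "hESC", EUP))
    return sets
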