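"""Embryo-level mosaicism analytics.

Works on per-cell karyotypes grouped by embryo and lineage (TE = outer
trophectoderm, ICM = inner cell mass, hESC = ICM-derived stem cells):

* karyotype equivalence under a reciprocal-overlap rule;
* mosaic calling (an embryo lineage is mosaic as soon as one analyzed cell
  diverges from the rest), mosaic typing (whole / segmental / complex) and
  the per-lineage mosaic rate;
* cohort incidence with the >= 3 analyzed cells evaluability rule;
* meiotic vs mitotic origin of each CNV event (meiotic = carried by every
  analyzed cell of the embryo, all lineages pooled);
* TE-ICM discordance by equal-size resampling;
* complementary (reciprocal gain/loss) CNV pairs and the in-silico
  multi-cell biopsy that demonstrates how they mask each other in bulk;
* per-chromosome aneuploidy tabulation and two-sample rate comparisons.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bin_io import BinGrid, CountMatrix, ReferenceTracks
from .copynumber import (CNVCall, Karyotype, MIN_CNV_SIZE, WHOLE_FRACTION,
                         SELF_TRANSITION, call_cell)

MIN_CELLS = 3                  # a lineage set is evaluable with >= 3 cells
RECIPROCAL_OVERLAP = 0.8

LINEAGES = ("TE", "ICM", "hESC")


# ---------------------------------------------------------------------------
# karyotype comparison
# ---------------------------------------------------------------------------

def reciprocal_overlap(a: CNVCall, b: CNVCall) -> float:
    """min(overlap/len_a, overlap/len_b); 0 when on different chromosomes."""
    if a.chrom != b.chrom:
        return 0.0
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return 0.0
    return min(ov / a.span, ov / b.span)


def calls_match(a: CNVCall, b: CNVCall, threshold: float = RECIPROCAL_OVERLAP) -> bool:
    """Same chromosome, identical delta (sign and magnitude), reciprocal overlap."""
    return a.chrom == b.chrom and a.delta == b.delta and \
        reciprocal_overlap(a, b) >= threshold


def karyotypes_equal(k1: Karyotype, k2: Karyotype,
                     threshold: float = RECIPROCAL_OVERLAP) -> bool:
    """True iff a bijection of mutually matching calls exists (euploid==euploid)."""
    if len(k1.calls) != len(k2.calls):
        return False
    if not k1.calls:
        return True
    return _bijection_exists(list(k1.calls), list(k2.calls), threshold)


def _bijection_exists(calls1, calls2, threshold) -> bool:
    # backtracking bipartite matching; call lists are tiny in practice
    def extend(i, used):
        if i == len(calls1):
            return True
        for j, c2 in enumerate(calls2):
            if j not in used and calls_match(calls1[i], c2, threshold):
                if extend(i + 1, used | {j}):
                    return True
        return False
    return extend(0, frozenset())


def cluster_karyotypes(karyos: list[Karyotype],
                       threshold: float = RECIPROCAL_OVERLAP) -> np.ndarray:
    """Greedy class labels: each karyotype joins the first class whose
    representative (its first member) it equals, else founds a new class."""
    labels = np.full(len(karyos), -1, dtype=int)
    reps: list[Karyotype] = []
    for i, k in enumerate(karyos):
        for lab, rep in enumerate(reps):
            if karyotypes_equal(k, rep, threshold):
                labels[i] = lab
                break
        else:
            labels[i] = len(reps)
            reps.append(k)
    return labels


# ---------------------------------------------------------------------------
# embryo / lineage containers and classification
# ---------------------------------------------------------------------------

@dataclass
class LineageSet:
    """All analyzed cells of one embryo lineage."""

    embryo_id: str
    lineage: str                        # 'TE' | 'ICM' | 'hESC'
    cells: list[tuple[str, Karyotype]]  # (cell_id, karyotype)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def evaluable(self) -> bool:
        return self.n_cells >= MIN_CELLS

    @property
    def karyotypes(self) -> list[Karyotype]:
        return [k for _, k in self.cells]


@dataclass
class MosaicClassification:
    embryo_id: str
    lineage: str
    n_cells: int
    status: str          # non_mosaic_euploid | non_mosaic_aneuploid | mosaic | insufficient_cells
    subtype: str         # whole | segmental | complex | none
    mosaic_rate: float   # fraction of cells off the major karyotype
    major_karyotype: Karyotype | None


def classify_embryo_lineage(ls: LineageSet,
                            threshold: float = RECIPROCAL_OVERLAP) -> MosaicClassification:
    """Mosaic status, subtype and mosaic rate of one embryo lineage.

    Mosaic as soon as two karyotype classes coexist; the major karyotype is
    the most frequent class (ties go to the class containing the euploid
    karyotype, else to the earliest cell, with a warning); the subtype comes
    from the classes of calls by which divergent cells differ from the
    major karyotype: whole-chromosome only -> whole, segmental only ->
    segmental, both -> complex.
    """
    if not ls.evaluable:
        return MosaicClassification(ls.embryo_id, ls.lineage, ls.n_cells,
                                    "insufficient_cells", "none", float("nan"), None)
    karyos = ls.karyotypes
    labels = cluster_karyotypes(karyos, threshold)
    counts = np.bincount(labels)
    best = counts.max()
    tied = np.flatnonzero(counts == best)
    if len(tied) > 1:
        eup = [lab for lab in tied if karyos[int(np.flatnonzero(labels == lab)[0])].euploid]
        if eup:
            major_lab = eup[0]
        else:
            major_lab = int(tied[0])
            warnings.warn(f"{ls.embryo_id}/{ls.lineage}: major-karyotype tie "
                          "resolved by stable cell order")
    else:
        major_lab = int(tied[0])
    major = karyos[int(np.flatnonzero(labels == major_lab)[0])]
    n = ls.n_cells
    n_major = int(counts[major_lab])
    rate = (n - n_major) / n

    if len(counts) == 1:
        status = "non_mosaic_euploid" if major.euploid else "non_mosaic_aneuploid"
        return MosaicClassification(ls.embryo_id, ls.lineage, n, status, "none", 0.0, major)

    divergent_classes: set[str] = set()
    for i, k in enumerate(karyos):
        if labels[i] == major_lab:
            continue
        diff = _symmetric_difference_calls(k, major, threshold)
        divergent_classes.update(c.cls for c in diff)
    if divergent_classes == {"whole"}:
        subtype = "whole"
    elif divergent_classes == {"segmental"}:
        subtype = "segmental"
    else:
        subtype = "complex"
    return MosaicClassification(ls.embryo_id, ls.lineage, n, "mosaic", subtype, rate, major)


def _symmetric_difference_calls(k1: Karyotype, k2: Karyotype, threshold) -> list[CNVCall]:
    """Calls present in one karyotype but unmatched in the other."""
    out = []
    for a, b in ((k1, k2), (k2, k1)):
        for c in a.calls:
            if not any(calls_match(c, d, threshold) for d in b.calls):
                out.append(c)
    return out


def cohort_incidence(lineage_sets: list[LineageSet], lineage: str | None = None,
                     threshold: float = RECIPROCAL_OVERLAP
                     ) -> tuple[int, int, float]:
    """(n_mosaic, n_evaluable, percentage to 2 dp) over evaluable sets.

    Only lineage sets with >= 3 cells enter the denominator.
    """
    sets = [ls for ls in lineage_sets if lineage is None or ls.lineage == lineage]
    results = [classify_embryo_lineage(ls, threshold) for ls in sets if ls.evaluable]
    n_eval = len(results)
    if n_eval == 0:
        warnings.warn("no evaluable lineage sets; incidence undefined")
        return 0, 0, float("nan")
    n_mosaic = sum(r.status == "mosaic" for r in results)
    return n_mosaic, n_eval, round(100.0 * n_mosaic / n_eval, 2)


def mosaic_type_distribution(lineage_sets: list[LineageSet], lineage: str | None = None,
                             threshold: float = RECIPROCAL_OVERLAP) -> dict[str, float]:
    """Percentage of whole / segmental / complex among mosaic lineage sets."""
    sets = [ls for ls in lineage_sets if lineage is None or ls.lineage == lineage]
    subtypes = [classify_embryo_lineage(ls, threshold).subtype
                for ls in sets if ls.evaluable]
    subtypes = [s for s in subtypes if s != "none"]
    n = len(subtypes)
    return {t: (round(100.0 * subtypes.count(t) / n, 2) if n else float("nan"))
            for t in ("whole", "segmental", "complex")}


# ---------------------------------------------------------------------------
# meiotic / mitotic origin
# ---------------------------------------------------------------------------

@dataclass
class EventOrigin:
    call: CNVCall              # cluster representative
    n_carriers: int
    n_cells: int
    origin: str                # 'meiotic' | 'mitotic'


@dataclass
class OriginClass:
    embryo_id: str
    origin: str                # meiotic_only | mitotic_only | both | euploid
    events: list[EventOrigin] = field(default_factory=list)


def classify_origin(embryo_sets: list[LineageSet],
                    threshold: float = RECIPROCAL_OVERLAP,
                    meiotic_tolerance: float = 0.0) -> OriginClass:
    """Label each CNV event of an embryo meiotic or mitotic.

    Cells of all lineages are pooled. Single calls are clustered across
    cells with the reciprocal-overlap rule; a cluster carried by at least
    (1 - meiotic_tolerance) of all analyzed cells is meiotic (it predates
    the first cleavage), otherwise mitotic. Default tolerance 0 = strictly
    every cell.
    """
    if not embryo_sets:
        raise ValueError("no lineage sets supplied")
    embryo_id = embryo_sets[0].embryo_id
    cells: list[Karyotype] = []
    for ls in embryo_sets:
        if ls.embryo_id != embryo_id:
            raise ValueError("classify_origin expects lineage sets from one embryo")
        cells.extend(ls.karyotypes)
    n_cells = len(cells)

    reps: list[CNVCall] = []
    carriers: list[set[int]] = []
    for ci, k in enumerate(cells):
        for call in k.calls:
            for ei, rep in enumerate(reps):
                if calls_match(call, rep, threshold):
                    carriers[ei].add(ci)
                    break
            else:
                reps.append(call)
                carriers.append({ci})

    events = []
    for rep, car in zip(reps, carriers):
        origin = "meiotic" if len(car) >= (1.0 - meiotic_tolerance) * n_cells \
            else "mitotic"
        events.append(EventOrigin(rep, len(car), n_cells, origin))
    origins = {e.origin for e in events}
    if not events:
        label = "euploid"
    elif origins == {"meiotic"}:
        label = "meiotic_only"
    elif origins == {"mitotic"}:
        label = "mitotic_only"
    else:
        label = "both"
    return OriginClass(embryo_id, label, events)


def origin_distribution(origin_classes: list[OriginClass]) -> dict[str, float]:
    """Percentages of meiotic-only / mitotic-only / both among aneuploid embryos."""
    aneu = [o for o in origin_classes if o.origin != "euploid"]
    n = len(aneu)
    return {lab: (round(100.0 * sum(o.origin == lab for o in aneu) / n, 2)
                  if n else float("nan"))
            for lab in ("meiotic_only", "mitotic_only", "both")}


# ---------------------------------------------------------------------------
# TE-ICM discordance
# ---------------------------------------------------------------------------

def te_icm_discordance(te: list[Karyotype], icm: list[Karyotype],
                       n_resamples: int = 10_000, seed: int = 0,
                       threshold: float = RECIPROCAL_OVERLAP) -> float:
    """Mean fraction of unmatched karyotypes between equal-size TE/ICM draws.

    Each resample draws m = min(|TE|, |ICM|) cells without replacement from
    each lineage, pairs them at random, and records the fraction of pairs
    with unequal karyotypes; the mean over resamples is returned. Its
    expectation equals the mean of the pairwise-unequal indicator over all
    TE x ICM cell pairs (see :func:`te_icm_discordance_exact`).
    """
    if not te or not icm:
        raise ValueError("both lineages need at least one karyotype")
    unequal = np.array([[0.0 if karyotypes_equal(a, b, threshold) else 1.0
                         for b in icm] for a in te])
    m = min(len(te), len(icm))
    rng = np.random.default_rng(seed)
    total = 0.0
    for _ in range(n_resamples):
        ti = rng.permutation(len(te))[:m]
        ii = rng.permutation(len(icm))[:m]
        total += unequal[ti, ii].mean()
    return total / n_resamples


def te_icm_discordance_exact(te: list[Karyotype], icm: list[Karyotype],
                             threshold: float = RECIPROCAL_OVERLAP) -> float:
    """Analytic expectation of the resampled discordance statistic."""
    if not te or not icm:
        raise ValueError("both lineages need at least one karyotype")
    return float(np.mean([[0.0 if karyotypes_equal(a, b, threshold) else 1.0
                           for b in icm] for a in te]))


def lineages_concordant(a: list[Karyotype], b: list[Karyotype],
                        threshold: float = RECIPROCAL_OVERLAP) -> bool:
    """Embryo-level concordance: both lineages show the same set of
    karyotype classes."""
    labels = cluster_karyotypes(list(a) + list(b), threshold)
    set_a = set(labels[:len(a)].tolist())
    set_b = set(labels[len(a):].tolist())
    return set_a == set_b


def concordance_with_reference(cells: list[Karyotype], reference: Karyotype,
                               threshold: float = RECIPROCAL_OVERLAP) -> bool:
    """Concordant with an initial bulk diagnosis iff no analyzed cell
    diverges from the reference karyotype."""
    return all(karyotypes_equal(k, reference, threshold) for k in cells)


# ---------------------------------------------------------------------------
# complementary CNVs and pseudo-bulk masking
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComplementaryPair:
    cell_a: str
    cell_b: str
    chrom: str
    start: int
    end: int
    delta: int                  # magnitude carried +delta by cell_a, -delta by cell_b
    overlap: float


def find_complementary_pairs(cells: list[tuple[str, Karyotype]],
                             threshold: float = RECIPROCAL_OVERLAP
                             ) -> list[ComplementaryPair]:
    """Reciprocal gain/loss pairs — the signature of mitotic non-disjunction.

    Reports every unordered cell pair with at least one pair of calls on
    the same chromosome with opposite equal-magnitude deltas and reciprocal
    overlap >= threshold, with their shared region.
    """
    pairs = []
    for (id_a, ka), (id_b, kb) in itertools.combinations(cells, 2):
        for ca in ka.calls:
            for cb in kb.calls:
                if ca.chrom != cb.chrom or ca.delta != -cb.delta:
                    continue
                ov = reciprocal_overlap(ca, cb)
                if ov >= threshold:
                    a_first = ca.delta > 0
                    pairs.append(ComplementaryPair(
                        id_a if a_first else id_b,
                        id_b if a_first else id_a,
                        ca.chrom, max(ca.start, cb.start), min(ca.end, cb.end),
                        abs(ca.delta), ov))
    return pairs


def simulate_multicell_biopsy(counts: CountMatrix, tracks: ReferenceTracks, *,
                              biopsy_size: int = 5, seed: int = 0,
                              cell_ids: list[str] | None = None,
                              sex: str = "XX",
                              min_cnv_size: int = MIN_CNV_SIZE,
                              whole_fraction: float = WHOLE_FRACTION,
                              self_transition: float = SELF_TRANSITION
                              ) -> tuple[Karyotype, list[str]]:
    """Karyotype of an in-silico multi-cell biopsy (pseudo-bulk).

    Sums the raw bin counts of a sampled subset of cells (clinical TE
    biopsies remove an estimated 5-10 cells) and re-runs the full
    correction/HMM/reporting pipeline on the summed profile. Reciprocal
    gain/loss cells cancel in the sum, so the bulk call can be euploid
    where single cells are not.
    """
    pool = counts.cell_ids if cell_ids is None else cell_ids
    if biopsy_size > len(pool):
        raise ValueError(f"biopsy_size {biopsy_size} exceeds available cells ({len(pool)})")
    rng = np.random.default_rng(seed)
    sampled = [pool[i] for i in rng.choice(len(pool), size=biopsy_size, replace=False)]
    summed = np.sum([counts.cell(c) for c in sampled], axis=0)
    _, _, _, karyo = call_cell(summed, tracks, counts.grid, sex=sex,
                               cell_id="pseudo_bulk", min_cnv_size=min_cnv_size,
                               whole_fraction=whole_fraction,
                               self_transition=self_transition)
    return karyo, sampled


# ---------------------------------------------------------------------------
# tabulation and rate comparison
# ---------------------------------------------------------------------------

def chromosome_aneuploidy_table(lineage_sets: list[LineageSet],
                                grid: BinGrid) -> pd.DataFrame:
    """Cells carrying whole vs segmental events, per chromosome and lineage."""
    chroms = grid.chrom_names
    cols = pd.MultiIndex.from_product([LINEAGES, ("whole", "segmental")])
    table = pd.DataFrame(0, index=chroms, columns=cols)
    for ls in lineage_sets:
        for _, k in ls.cells:
            seen = set()
            for call in k.calls:
                key = (call.chrom, call.cls)
                if key in seen:       # count each cell once per (chrom, class)
                    continue
                seen.add(key)
                if call.chrom in table.index and ls.lineage in LINEAGES:
                    table.loc[call.chrom, (ls.lineage, call.cls)] += 1
    return table


def compare_rates(group_a, group_b) -> tuple[float, float]:
    """Two-tailed unpaired Student's t-test between two groups of rates."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("insufficient observations: each group needs >= 2 values")
    if np.var(a) == 0 and np.var(b) == 0:
        warnings.warn("both groups have zero variance; degenerate t-test")
        return (0.0, 1.0) if a.mean() == b.mean() else (float("inf"), 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
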