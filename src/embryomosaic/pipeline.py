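"""End-to-end orchestration: QC + calling over a cohort, then embryo analytics.

This is the library layer behind the command-line interface; each function
is usable on its own with in-memory objects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bin_io import BinGrid, CountMatrix, ReferenceTracks
from . import copynumber, mosaicism, qc
from .copynumber import (CorrectedProfile, Karyotype, call_karyotype,
                         correct_counts, infer_copy_number, segment_states)
from .mosaicism import LineageSet

log = logging.getLogger("embryomosaic")


@dataclass
class CallParams:
    sex: str = "XX"
    exclude_fraction: float = qc.EXCLUDE_FRACTION
    n_windows: int = qc.N_WINDOWS
    min_mappability: float = copynumber.MIN_MAPPABILITY
    self_transition: float = copynumber.SELF_TRANSITION
    min_cnv_size: int = copynumber.MIN_CNV_SIZE
    whole_fraction: float = copynumber.WHOLE_FRACTION


@dataclass
class CallResult:
    qc: pd.DataFrame                      # cell_id, vs, analyzable, retained
    karyotypes: dict[str, Karyotype]      # retained analyzable cells only
    profiles: dict[str, CorrectedProfile]


def run_call(counts: CountMatrix, tracks: ReferenceTracks,
             params: CallParams | None = None) -> CallResult:
    """Correct, QC-filter and karyotype every cell of a cohort.

    Cells that cannot be normalized are flagged unanalyzable and skipped;
    the top ``exclude_fraction`` of analyzable cells by variability score is
    excluded; copy number is called for the rest.
    """
    params = params or CallParams()
    grid = counts.grid
    profiles: dict[str, CorrectedProfile] = {}
    scores = []
    analyzable_ids = []
    for i, cid in enumerate(counts.cell_ids):
        prof = correct_counts(counts.counts[i], tracks, grid, sex=params.sex,
                              cell_id=cid, min_mappability=params.min_mappability)
        profiles[cid] = prof
        if prof.analyzable:
            scores.append(qc.variability_score(prof, grid, n_windows=params.n_windows))
            analyzable_ids.append(cid)
    log.info("cells: %d input, %d analyzable", counts.n_cells, len(analyzable_ids))

    retained, excluded = qc.filter_cells(scores, params.exclude_fraction)
    log.info("QC: %d retained, %d excluded (top %.0f%% VS)",
             len(retained), len(excluded), 100 * params.exclude_fraction)

    karyotypes: dict[str, Karyotype] = {}
    for s in retained:
        prof = profiles[s.cell_id]
        states = infer_copy_number(prof, grid, self_transition=params.self_transition)
        segs = segment_states(states, grid)
        karyotypes[s.cell_id] = call_karyotype(
            segs, grid, sex=params.sex, masked=prof.masked,
            min_cnv_size=params.min_cnv_size, whole_fraction=params.whole_fraction)

    vs_by_id = {s.cell_id: s for s in scores}
    qc_df = pd.DataFrame({
        "cell_id": counts.cell_ids,
        "vs": [vs_by_id[c].vs if c in vs_by_id else np.nan for c in counts.cell_ids],
        "analyzable": [profiles[c].analyzable for c in counts.cell_ids],
        "retained": [c in karyotypes for c in counts.cell_ids],
    })
    return CallResult(qc_df, karyotypes, profiles)


def build_lineage_sets(metadata: pd.DataFrame,
                       karyotypes: dict[str, Karyotype]) -> list[LineageSet]:
    """Group the retained cells' karyotypes by (embryo, lineage).

    Cells absent from ``karyotypes`` (QC-excluded or unanalyzable) never
    enter any lineage set, and hence no downstream statistic.
    """
    sets: list[LineageSet] = []
    for (eid, lin), sub in metadata.groupby(["embryo_id", "lineage"], sort=True):
        cells = [(cid, karyotypes[cid]) for cid in sub["cell_id"] if cid in karyotypes]
        if cells:
            sets.append(LineageSet(str(eid), str(lin), cells))
    return sets


@dataclass
class AnalysisParams:
    reciprocal_overlap: float = mosaicism.RECIPROCAL_OVERLAP
    discordance_resamples: int = 10_000
    seed: int = 0


def analyze_cohort(lineage_sets: list[LineageSet],
                   params: AnalysisParams | None = None) -> dict:
    """Embryo summaries, incidence, origin, discordance and pair detection."""
    params = params or AnalysisParams()
    thr = params.reciprocal_overlap

    classifications = [mosaicism.classify_embryo_lineage(ls, thr) for ls in lineage_sets]
    summary = pd.DataFrame([{
        "embryo_id": c.embryo_id, "lineage": c.lineage, "n_cells": c.n_cells,
        "status": c.status, "subtype": c.subtype,
        "mosaic_rate_pct": round(100 * c.mosaic_rate, 2) if np.isfinite(c.mosaic_rate) else np.nan,
    } for c in classifications])

    incidence = {}
    type_dist = {}
    for lin in mosaicism.LINEAGES:
        if any(ls.lineage == lin for ls in lineage_sets):
            n_mos, n_eval, pct = mosaicism.cohort_incidence(lineage_sets, lin, thr)
            incidence[lin] = {"n_mosaic": n_mos, "n_evaluable": n_eval, "pct": pct}
            type_dist[lin] = mosaicism.mosaic_type_distribution(lineage_sets, lin, thr)

    by_embryo: dict[str, list[LineageSet]] = {}
    for ls in lineage_sets:
        by_embryo.setdefault(ls.embryo_id, []).append(ls)
    origins = {eid: mosaicism.classify_origin(sets, thr)
               for eid, sets in sorted(by_embryo.items())}
    origin_dist = mosaicism.origin_distribution(list(origins.values()))

    discordance_rows = []
    n_disc = n_shared = 0
    for eid, sets in sorted(by_embryo.items()):
        te = next((s for s in sets if s.lineage == "TE" and s.evaluable), None)
        icm = next((s for s in sets if s.lineage == "ICM" and s.evaluable), None)
        if te is None or icm is None:
            continue
        n_shared += 1
        conc = mosaicism.lineages_concordant(te.karyotypes, icm.karyotypes, thr)
        n_disc += not conc
        disc = mosaicism.te_icm_discordance(te.karyotypes, icm.karyotypes,
                                            n_resamples=params.discordance_resamples,
                                            seed=params.seed, threshold=thr)
        discordance_rows.append({"embryo_id": eid, "n_te": te.n_cells,
                                 "n_icm": icm.n_cells, "concordant": conc,
                                 "discordance_pct": round(100 * disc, 2)})

    pairs = []
    for eid, sets in sorted(by_embryo.items()):
        cells = [cell for ls in sets for cell in ls.cells]
        for p in mosaicism.find_complementary_pairs(cells, thr):
            pairs.append({"embryo_id": eid, "cell_a": p.cell_a, "cell_b": p.cell_b,
                          "chrom": p.chrom, "start": p.start, "end": p.end,
                          "delta": p.delta, "overlap": round(p.overlap, 3)})

    return {
        "summary": summary,
        "classifications": classifications,
        "incidence": incidence,
        "type_distribution": type_dist,
        "origins": origins,
        "origin_distribution": origin_dist,
        "discordance": pd.DataFrame(discordance_rows),
        "n_te_icm_shared": n_shared,
        "n_te_icm_discordant": n_disc,
        "te_icm_discordant_pct": round(100 * n_disc / n_shared, 2) if n_shared else float("nan"),
        "pairs": pd.DataFrame(pairs),
    }
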