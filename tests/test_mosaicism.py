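import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from embryomosaic import (CNVCall, Karyotype, LineageSet, NoiseModel, SimConfig,
                          chromosome_aneuploidy_table, classify_embryo_lineage,
                          classify_origin, cohort_incidence, compare_rates,
                          concordance_with_reference, emit_counts,
                          find_complementary_pairs, karyotype_from_copy_profile,
                          karyotypes_equal, lineages_concordant,
                          simulate_embryo, simulate_multicell_biopsy,
                          te_icm_discordance, te_icm_discordance_exact)
from embryomosaic.bin_io import CountMatrix
from embryomosaic.synthetic import ForcedMeiotic, ForcedMitotic, SimTruth

MB = 1_000_000
EUP = Karyotype()


def whole(chrom, delta=1, size=50):
    return CNVCall(chrom, 0, size * MB, delta, "whole")


def seg(chrom, s, e, delta=1):
    return CNVCall(chrom, s * MB, e * MB, delta, "segmental")


class TestKaryotypeEquality:
    def test_euploid_equal(self):
        assert karyotypes_equal(EUP, Karyotype())

    def test_opposite_signs_unequal(self):
        assert not karyotypes_equal(Karyotype((whole("chr16", 1),)),
                                    Karyotype((whole("chr16", -1),)))

    def test_reciprocal_overlap_interval_arithmetic(self):
        # overlap 46 Mb; 46/50 = 0.92 and 46/46 = 1.0, both above 0.8
        a = Karyotype((seg("chr2", 10, 60),))
        b = Karyotype((seg("chr2", 12, 58),))
        assert karyotypes_equal(a, b, 0.8)
        assert not karyotypes_equal(a, b, 0.95)

    def test_call_count_mismatch_unequal(self):
        assert not karyotypes_equal(Karyotype((whole("chr16"),)), EUP)

    def test_bijection_handles_same_chromosome_calls(self):
        a = Karyotype((seg("chr1", 0, 20), seg("chr1", 30, 50)))
        b = Karyotype((seg("chr1", 30, 50), seg("chr1", 0, 20)))
        assert karyotypes_equal(a, b)


@settings(derandomize=True, max_examples=100)
@given(st.integers(0, 200), st.integers(1, 100), st.integers(0, 200), st.integers(1, 100))
def test_reciprocal_overlap_symmetric_and_bounded(a_start, a_len, b_start, b_len):
    from embryomosaic.mosaicism import reciprocal_overlap
    a = seg("chr1", a_start, a_start + a_len)
    b = seg("chr1", b_start, b_start + b_len)
    ab, ba = reciprocal_overlap(a, b), reciprocal_overlap(b, a)
    assert ab == ba
    assert 0.0 <= ab <= 1.0
    if (a_start, a_len) == (b_start, b_len):
        assert ab == 1.0


@settings(derandomize=True, max_examples=60)
@given(st.lists(st.sampled_from(["chr1", "chr2"]), min_size=0, max_size=4),
       st.data())
def test_karyotype_equality_reflexive_and_symmetric(chroms, data):
    calls = []
    for chrom in chroms:
        s = data.draw(st.integers(0, 30))
        length = data.draw(st.integers(10, 25))
        delta = data.draw(st.sampled_from([-1, 1]))
        calls.append(seg(chrom, s, s + length, delta))
    k1 = Karyotype(tuple(calls))
    k2 = Karyotype(tuple(reversed(calls)))
    assert karyotypes_equal(k1, k1)
    assert karyotypes_equal(k1, k2) and karyotypes_equal(k2, k1)


def lset(eid, lineage, karyos):
    return LineageSet(eid, lineage, [(f"{eid}_{lineage}{i}", k)
                                     for i, k in enumerate(karyos)])


class TestClassifyEmbryoLineage:
    def test_identical_euploid_cells(self):
        c = classify_embryo_lineage(lset("E1", "TE", [EUP] * 5))
        assert c.status == "non_mosaic_euploid"
        assert c.subtype == "none" and c.mosaic_rate == 0.0

    def test_single_divergent_whole_gain(self):
        c = classify_embryo_lineage(
            lset("E1", "TE", [EUP, EUP, EUP, Karyotype((whole("chr21", 1, 47),))]))
        assert c.status == "mosaic" and c.subtype == "whole"
        assert c.mosaic_rate == pytest.approx(0.25)

    def test_mosaic_rate_direct_count(self):
        major = Karyotype((whole("chr16"),))
        cells = [major] * 6 + [EUP, EUP, Karyotype((seg("chr1", 0, 30),)),
                               Karyotype((seg("chr4", 10, 45),))]
        c = classify_embryo_lineage(lset("E1", "ICM", cells))
        assert c.mosaic_rate == pytest.approx(0.40)
        assert karyotypes_equal(c.major_karyotype, major)

    def test_complex_subtype_from_union_of_divergent_classes(self):
        cells = [EUP, EUP, EUP, Karyotype((whole("chr16"),)),
                 Karyotype((seg("chr2", 20, 60),))]
        assert classify_embryo_lineage(lset("E1", "TE", cells)).subtype == "complex"

    def test_aneuploid_major_with_euploid_divergent(self):
        # the divergent cells differ from the major by a whole-chromosome call
        major = Karyotype((whole("chr16"),))
        c = classify_embryo_lineage(lset("E1", "TE", [major, major, major, EUP]))
        assert c.status == "mosaic" and c.subtype == "whole"

    def test_insufficient_cells_flagged(self):
        c = classify_embryo_lineage(lset("E1", "TE", [EUP, EUP]))
        assert c.status == "insufficient_cells"

    def test_tie_prefers_euploid_class(self):
        c = classify_embryo_lineage(lset("E1", "TE", [Karyotype((whole("chr16"),))] * 2
                                         + [EUP] * 2))
        assert c.major_karyotype.euploid


class TestCohortIncidence:
    def test_paper_style_fractions(self):
        mosaic = lset("M", "TE", [EUP, EUP, Karyotype((whole("chr16"),))])
        sets = [lset(f"E{i}", "TE", [EUP] * 3) for i in range(12)] + \
               [LineageSet(f"F{i}", "TE", mosaic.cells) for i in range(23)]
        assert cohort_incidence(sets, "TE") == (23, 35, 65.71)

    def test_two_of_six(self):
        mosaic_cells = [EUP, EUP, Karyotype((whole("chr16"),))]
        sets = [lset(f"E{i}", "hESC", mosaic_cells) for i in range(2)] + \
               [lset(f"F{i}", "hESC", [EUP] * 3) for i in range(4)]
        assert cohort_incidence(sets, "hESC") == (2, 6, 33.33)

    def test_zero_incidence(self):
        sets = [lset(f"E{i}", "TE", [EUP] * 4) for i in range(5)]
        assert cohort_incidence(sets, "TE") == (0, 5, 0.0)

    def test_small_sets_excluded_from_denominator(self):
        sets = [lset("E1", "TE", [EUP] * 3), lset("E2", "TE", [EUP] * 2)]
        assert cohort_incidence(sets, "TE")[1] == 1


class TestClassifyOrigin:
    def test_event_in_all_cells_is_meiotic(self):
        k = Karyotype((whole("chr21", 1, 47),))
        oc = classify_origin([lset("E1", "TE", [k] * 4)])
        assert oc.origin == "meiotic_only"
        assert all(e.origin == "meiotic" for e in oc.events)

    def test_subset_event_is_mitotic(self):
        cells = [EUP, EUP, EUP, Karyotype((whole("chr16"),))]
        oc = classify_origin([lset("E1", "TE", cells)])
        assert oc.origin == "mitotic_only"

    def test_no_events_is_euploid(self):
        assert classify_origin([lset("E1", "TE", [EUP] * 3)]).origin == "euploid"

    def test_synthetic_embryo_with_both_error_types(self, mini_grid):
        # noiseless route: karyotypes derived from the planted truth itself
        cfg = SimConfig(grid=mini_grid, p_mitotic=0, p_meiotic=0, n_te=4, n_icm=4,
                        n_generations=3,
                        forced_meiotic=[ForcedMeiotic("chr21", delta=1)],
                        forced_mitotic=[ForcedMitotic(generation=1, chrom="chr2")])
        truth = simulate_embryo(cfg, seed=9)
        karyos = {cid: karyotype_from_copy_profile(truth.cell_truth[i], mini_grid)
                  for i, cid in enumerate(truth.cell_ids)}
        sets = [LineageSet("E1", lin,
                           [(c, karyos[c]) for c, l in zip(truth.cell_ids, truth.lineages)
                            if l == lin])
                for lin in ("TE", "ICM")]
        oc = classify_origin(sets)
        assert oc.origin == "both"
        by_chrom = {e.call.chrom: e.origin for e in oc.events}
        assert by_chrom["chr21"] == "meiotic"
        assert by_chrom["chr2"] == "mitotic"

    def test_tolerance_knob_relaxes_meiotic_rule(self):
        k = Karyotype((whole("chr21", 1, 47),))
        cells = [k] * 9 + [EUP]
        strict = classify_origin([lset("E1", "TE", cells)])
        assert strict.events[0].origin == "mitotic"
        lenient = classify_origin([lset("E1", "TE", cells)], meiotic_tolerance=0.15)
        assert lenient.events[0].origin == "meiotic"


def exhaustive_discordance(te, icm):
    """Oracle: enumerate every equal-size draw and every pairing."""
    m = min(len(te), len(icm))
    fracs = []
    for ti in itertools.combinations(range(len(te)), m):
        for ii in itertools.combinations(range(len(icm)), m):
            for perm in itertools.permutations(ii):
                unmatched = sum(not karyotypes_equal(te[a], icm[b])
                                for a, b in zip(ti, perm))
                fracs.append(unmatched / m)
    return float(np.mean(fracs))


class TestDiscordance:
    A = Karyotype((whole("chr16"),))
    B = Karyotype((seg("chr2", 20, 60),))

    def test_identical_lineages_zero(self):
        assert te_icm_discordance([EUP] * 3, [EUP] * 4, 200, seed=0) == 0.0

    def test_disjoint_lineages_one(self):
        assert te_icm_discordance([self.A] * 3, [self.B] * 3, 200, seed=0) == 1.0

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        te = [self.A, self.A, self.B]
        icm = [self.A, self.B, self.B]
        oracle = exhaustive_discordance(te, icm)
        mc = te_icm_discordance(te, icm, n_resamples=20_000, seed=3)
        assert mc == pytest.approx(oracle, abs=0.01)
        assert te_icm_discordance_exact(te, icm) == pytest.approx(oracle, abs=1e-12)

    def test_unequal_sizes(self):
        te = [self.A] * 5
        icm = [self.A, self.B]
        oracle = exhaustive_discordance(te, icm)
        mc = te_icm_discordance(te, icm, n_resamples=20_000, seed=4)
        assert mc == pytest.approx(oracle, abs=0.01)

    def test_empty_lineage_rejected(self):
        with pytest.raises(ValueError):
            te_icm_discordance([], [EUP], 10, seed=0)

    def test_lineages_concordant_set_comparison(self):
        assert lineages_concordant([EUP, EUP], [EUP])
        assert not lineages_concordant([EUP, self.A], [EUP])

    def test_concordance_with_reference(self):
        assert concordance_with_reference([self.A, self.A], self.A)
        assert not concordance_with_reference([self.A, EUP], self.A)


class TestComplementaryPairs:
    def test_reciprocal_whole_pair_found(self):
        cells = [("a", Karyotype((whole("chr16", 1),))),
                 ("b", Karyotype((whole("chr16", -1),))),
                 ("c", EUP)]
        pairs = find_complementary_pairs(cells)
        assert len(pairs) == 1
        p = pairs[0]
        assert (p.cell_a, p.cell_b) == ("a", "b")
        assert p.delta == 1 and p.overlap == 1.0

    def test_same_sign_not_paired(self):
        cells = [("a", Karyotype((whole("chr16", 1),))),
                 ("b", Karyotype((whole("chr16", 1),)))]
        assert find_complementary_pairs(cells) == []

    def test_low_overlap_not_paired(self):
        cells = [("a", Karyotype((seg("chr2", 0, 30, 1),))),
                 ("b", Karyotype((seg("chr2", 25, 60, -1),)))]
        assert find_complementary_pairs(cells) == []


def _counts_from_truth(truth: SimTruth, tracks, noise, seed) -> CountMatrix:
    return CountMatrix(truth.grid, emit_counts(truth, noise, tracks, seed),
                       list(truth.cell_ids))


class TestMulticellBiopsy:
    def _pair_truth(self, grid):
        cfg = SimConfig(grid=grid, p_mitotic=0, p_meiotic=0, n_te=2, n_icm=0,
                        n_generations=1,
                        forced_mitotic=[ForcedMitotic(generation=1, chrom="chr2")])
        return simulate_embryo(cfg, seed=2)

    def test_balanced_pair_masks_to_euploid_bulk(self, mini_grid, flat_tracks):
        # the Fig-4 phenomenon: reciprocal +1/-1 daughters sum to a flat
        # profile, so the 2-cell pseudo-bulk is euploid while each single
        # cell is aneuploid
        truth = self._pair_truth(mini_grid)
        chr2 = mini_grid.chrom_index("chr2")
        assert sorted(truth.cell_truth[:, chr2[0]]) == [1, 3]
        noise = NoiseModel(mean_depth=800, deterministic=True)
        counts = _counts_from_truth(truth, flat_tracks, noise, seed=0)
        from embryomosaic import call_cell
        singles = [call_cell(counts.counts[i], flat_tracks, mini_grid)[3]
                   for i in range(2)]
        assert all(not k.euploid for k in singles)
        bulk, sampled = simulate_multicell_biopsy(counts, flat_tracks,
                                                  biopsy_size=2, seed=1)
        assert set(sampled) == set(truth.cell_ids)
        assert bulk.euploid

    def test_uniform_trisomy_survives_bulk(self, mini_grid, flat_tracks):
        cfg = SimConfig(grid=mini_grid, p_mitotic=0, p_meiotic=0, n_te=8, n_icm=2,
                        n_generations=4,
                        forced_meiotic=[ForcedMeiotic("chr21", delta=1)])
        truth = simulate_embryo(cfg, seed=3)
        counts = _counts_from_truth(truth, flat_tracks, NoiseModel(), seed=4)
        bulk, _ = simulate_multicell_biopsy(counts, flat_tracks, biopsy_size=10, seed=5)
        assert any(c.chrom == "chr21" and c.delta == 1 and c.cls == "whole"
                   for c in bulk.calls)

    def test_minority_aneuploidy_hidden_in_bulk(self, mini_grid, flat_tracks):
        # 2 trisomic of 10 cells: a 20% mosaic fraction shifts the bulk mean
        # by 5%, below what the caller flags at default settings
        base = np.full(mini_grid.n_bins, 2, dtype=np.int16)
        tri = base.copy()
        tri[mini_grid.chrom_index("chr21")] = 3
        cell_truth = np.vstack([base] * 8 + [tri] * 2)
        truth = SimTruth("E1", mini_grid, base, [], [f"c{i}" for i in range(10)],
                         ["TE"] * 10, cell_truth, {})
        counts = _counts_from_truth(truth, flat_tracks, NoiseModel(), seed=6)
        bulk, _ = simulate_multicell_biopsy(counts, flat_tracks, biopsy_size=10, seed=7)
        assert bulk.euploid

    def test_biopsy_larger_than_pool_rejected(self, mini_grid, flat_tracks):
        truth = self._pair_truth(mini_grid)
        counts = _counts_from_truth(truth, flat_tracks, NoiseModel(), seed=8)
        with pytest.raises(ValueError, match="exceeds"):
            simulate_multicell_biopsy(counts, flat_tracks, biopsy_size=5, seed=0)


class TestAneuploidyTable:
    def test_events_only_on_chr21(self, mini_grid):
        sets = [lset("E1", "TE", [EUP, EUP, Karyotype((whole("chr21", 1, 47),))])]
        table = chromosome_aneuploidy_table(sets, mini_grid)
        assert table.loc["chr21", ("TE", "whole")] == 1
        assert table.to_numpy().sum() == 1

    def test_empty_cohort_all_zero(self, mini_grid):
        table = chromosome_aneuploidy_table([], mini_grid)
        assert table.to_numpy().sum() == 0

    def test_matches_direct_truth_tally(self, mini_grid):
        cfg = SimConfig(grid=mini_grid, p_mitotic=0.15, p_meiotic=0.5,
                        n_te=6, n_icm=4, n_generations=4)
        sets, tally = [], {}
        for s in range(6):
            truth = simulate_embryo(cfg, seed=s, embryo_id=f"E{s}")
            karyos = {cid: karyotype_from_copy_profile(truth.cell_truth[i], mini_grid)
                      for i, cid in enumerate(truth.cell_ids)}
            for lin in ("TE", "ICM"):
                sets.append(LineageSet(f"E{s}", lin,
                                       [(c, karyos[c]) for c, l in
                                        zip(truth.cell_ids, truth.lineages) if l == lin]))
            for cid, k in karyos.items():
                lin = truth.lineages[truth.cell_ids.index(cid)]
                for chrom, cls in {(c.chrom, c.cls) for c in k.calls}:
                    tally[(chrom, lin, cls)] = tally.get((chrom, lin, cls), 0) + 1
        table = chromosome_aneuploidy_table(sets, mini_grid)
        for (chrom, lin, cls), n in tally.items():
            assert table.loc[chrom, (lin, cls)] == n
        assert table.to_numpy().sum() == sum(tally.values())


class TestCompareRates:
    def test_identical_groups_give_p_one(self):
        with pytest.warns(UserWarning):
            t, p = compare_rates([0.3, 0.3, 0.3], [0.3, 0.3])
        assert (t, p) == (0.0, 1.0)

    def test_matches_closed_form(self):
        a = np.array([2.1, 2.5, 2.3, 2.9])
        b = np.array([1.8, 2.0, 1.6])
        t, p = compare_rates(a, b)
        # hand-computed pooled-variance t statistic
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / \
            (len(a) + len(b) - 2)
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        assert t == pytest.approx(t_hand, abs=1e-12)
        from scipy import stats as ss
        p_hand = 2 * ss.t.sf(abs(t_hand), len(a) + len(b) - 2)
        assert p == pytest.approx(p_hand, abs=1e-12)

    def test_single_observation_rejected(self):
        with pytest.raises(ValueError, match="insufficient observations"):
            compare_rates([1.0], [1.0, 2.0])
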