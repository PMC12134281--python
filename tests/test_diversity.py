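"""Diversity indices, profiles, overlaps, reconstruction and ordination."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endodiv import (
    CommunityTable,
    berger_parker,
    camargo,
    colonization_frequency,
    diversity_profile,
    evenness,
    occurrence_percent,
    pca_ordination,
    profile_table,
    reconstruct_abundances,
    shannon,
    simpson_complement,
    tissue_overlaps,
)
from endodiv.community import IsolateRecord, TaxonRecord, ValidationError
from endodiv.diversity import (
    DegenerateInputError,
    UndefinedInputError,
    genus_tissue_matrix,
    round_value,
)

abundance_vectors = st.lists(st.integers(1, 50), min_size=1, max_size=8)


def _small_vectors(max_s=5, max_n=12):
    """All non-increasing positive integer vectors with S <= max_s, N <= max_n."""
    for s in range(1, max_s + 1):
        for combo in itertools.combinations_with_replacement(range(1, max_n + 1), s):
            vec = tuple(sorted(combo, reverse=True))
            if sum(vec) <= max_n:
                yield vec


class TestIndexValues:
    @pytest.mark.parametrize(
        "vec, expected_H",
        [
            ((2, 2, 2, 2), 1.39),      # equal abundances: ln 4
            ((6, 4, 2, 1, 1, 1, 1, 1), 1.79),
            ((2, 2, 2, 1, 1, 1), 1.74),
            ((5,), 0.0),
        ],
    )
    def test_shannon_reproduces_published_rows(self, vec, expected_H):
        assert round_value(shannon(vec), 2) == expected_H

    @pytest.mark.parametrize(
        "vec, expected",
        [((2, 1, 1), 0.625), ((6, 4, 2, 1, 1, 1, 1, 1), 0.789), ((7,), 0.0)],
    )
    def test_simpson_complement_values(self, vec, expected):
        assert round_value(simpson_complement(vec), 3) == expected

    @pytest.mark.parametrize(
        "vec, expected",
        [((6, 4, 2, 1, 1, 1, 1, 1), 0.35), ((5, 5), 0.5), ((2, 1, 1), 0.5)],
    )
    def test_berger_parker_values(self, vec, expected):
        assert round_value(berger_parker(vec), 2) == expected

    @pytest.mark.parametrize(
        "S, decimals, mode, expected",
        [(8, 3, "half_up", 0.125), (1, 1, "half_up", 1.0), (3, 2, "half_up", 0.33),
         (6, 2, "truncate", 0.16)],
    )
    def test_camargo_with_table_rounding_conventions(self, S, decimals, mode, expected):
        assert round_value(camargo(S), decimals, mode=mode) == expected

    def test_evenness_published_value(self):
        assert round_value(evenness(1.79, 8), 3) == 0.861

    @pytest.mark.parametrize("H, S, expected", [(math.log(4), 4, 1.0), (0.0, 5, 0.0)])
    def test_evenness_bounds_cases(self, H, S, expected):
        assert evenness(H, S) == pytest.approx(expected)

    def test_evenness_undefined_below_two_species(self):
        assert evenness(0.0, 1) is None

    def test_undefined_inputs_raise(self):
        for fn in (shannon, simpson_complement, berger_parker):
            with pytest.raises(UndefinedInputError):
                fn([0, 0])
        with pytest.raises(UndefinedInputError):
            camargo(0)


class TestOccurrenceAndCF:
    @pytest.mark.parametrize("n, total, expected", [(3, 12, 25.0), (0, 12, 0.0)])
    def test_occurrence_simple(self, n, total, expected):
        assert occurrence_percent(n, total) == expected

    def test_occurrence_sums_to_100_over_a_table(self, table1):
        counts = {}
        for r in table1.isolates:
            counts[r.taxon.morphospecies_id] = counts.get(r.taxon.morphospecies_id, 0) + r.colony_count
        total = sum(counts.values())
        assert sum(occurrence_percent(n, total) for n in counts.values()) == pytest.approx(100.0)

    def test_occurrence_zero_total_undefined(self):
        with pytest.raises(UndefinedInputError):
            occurrence_percent(0, 0)

    @pytest.mark.parametrize("col, n, expected", [(9, 36, 25.0), (0, 36, 0.0)])
    def test_cf_simple(self, col, n, expected):
        assert colonization_frequency(col, n) == expected

    def test_cf_rejects_more_colonized_than_examined(self):
        with pytest.raises(ValidationError):
            colonization_frequency(10, 9)

    def test_cf_monte_carlo_recovers_binomial_rate(self):
        # mean CF over many binomial draws tracks 100 p within 3 standard errors
        rng = np.random.default_rng(7)
        n, p, reps = 36, 0.3, 1000
        draws = rng.binomial(n, p, size=reps)
        cfs = [colonization_frequency(int(x), n, decimals=None) for x in draws]
        se = 100 * math.sqrt(p * (1 - p) / n) / math.sqrt(reps)
        assert abs(np.mean(cfs) - 100 * p) < 3 * se


class TestIndexInvariants:
    """Exhaustive verification on all small abundance vectors (S<=5, N<=12)."""

    def test_shannon_bounded_by_log_richness_with_equality_iff_even(self):
        for vec in _small_vectors():
            H, S = shannon(vec), len(vec)
            assert H <= math.log(S) + 1e-12
            assert (abs(H - math.log(S)) < 1e-12) == (len(set(vec)) == 1)

    def test_simpson_bounded_with_equality_iff_even(self):
        for vec in _small_vectors():
            d, S = simpson_complement(vec), len(vec)
            assert d <= 1 - 1 / S + 1e-12
            assert (abs(d - (1 - 1 / S)) < 1e-12) == (len(set(vec)) == 1)

    def test_berger_parker_at_least_reciprocal_richness(self):
        for vec in _small_vectors():
            bp, S = berger_parker(vec), len(vec)
            assert bp >= 1 / S - 1e-12
            assert (abs(bp - 1 / S) < 1e-12) == (len(set(vec)) == 1)

    @given(vec=abundance_vectors, k=st.integers(2, 9), seed=st.integers(0, 10_000))
    @settings(max_examples=150, deadline=None)
    def test_permutation_and_scale_invariance(self, vec, k, seed):
        rng = np.random.default_rng(seed)
        perm = list(rng.permutation(vec))
        scaled = [k * n for n in vec]
        for fn in (shannon, simpson_complement, berger_parker):
            assert fn(perm) == pytest.approx(fn(vec), abs=1e-12)
            assert fn(scaled) == pytest.approx(fn(vec), abs=1e-12)


class TestProfiles:
    def test_reconstructed_fixture_reproduces_published_row(self, reconstructed):
        printed = diversity_profile(reconstructed, "Anabasis setifera").as_printed()
        assert printed["shannon"] == 1.79
        assert printed["simpson_complement"] == 0.789
        assert printed["camargo"] == 0.125
        assert printed["berger_parker"] == 0.35
        assert printed["abundance_N"] == 17 and printed["richness_S"] == 8

    def test_single_species_plant_profile(self):
        table = CommunityTable(
            isolates=[IsolateRecord("p", "PAWD", "leaf", TaxonRecord("A sp.", "A"), 5)]
        )
        prof = diversity_profile(table, "p")
        assert prof.shannon_H == 0.0
        assert prof.simpson_complement == 0.0
        assert prof.berger_parker == 1.0
        assert prof.evenness_E is None

    def test_zero_isolate_plant_reports_no_data_not_zeros(self):
        table = CommunityTable(
            isolates=[IsolateRecord("p", "PAWD", "leaf", TaxonRecord("A sp.", "A"), 0)]
        )
        prof = diversity_profile(table, "p")
        assert prof.no_data
        assert prof.shannon_H is None and prof.berger_parker is None

    def test_unknown_plant_raises_key_error(self, table1):
        with pytest.raises(KeyError):
            diversity_profile(table1, "Nonexistent plant")

    def test_profile_table_one_row_per_plant(self, table1):
        df = profile_table(table1)
        assert len(df) == len(table1.plants)
        assert set(df["plant"]) == set(table1.plants)


class TestOverlaps:
    def test_regions_partition_the_union(self, table1):
        ov = tissue_overlaps(table1)
        assert sum(ov.regions.values()) == len(ov.union)

    def test_exhaustive_membership_oracle(self, table1):
        # set-algebra oracle: rebuild every region size by direct membership checks
        ov = tissue_overlaps(table1)
        for subset, size in ov.regions.items():
            expected = sum(
                1
                for sp in ov.union
                if {t for t, s in ov.tissue_sets.items() if sp in s} == set(subset)
            )
            assert size == expected

    def test_species_in_multiple_plants_counted_once_per_tissue(self, table1):
        ov = tissue_overlaps(table1)
        # Aspergillus sp.3 occurs in stems of three plants and leaf of one
        assert "Aspergillus sp.3" in ov.tissue_sets["stem"]
        assert sum("Aspergillus sp.3" in s for s in ov.tissue_sets.values()) == 2

    def test_disjoint_tissues_have_empty_higher_regions(self):
        recs = [
            IsolateRecord("p", "PAWD", "leaf", TaxonRecord("A sp.", "A"), 1),
            IsolateRecord("p", "PAWD", "stem", TaxonRecord("B sp.", "B"), 1),
        ]
        ov = tissue_overlaps(CommunityTable(isolates=recs))
        assert all(v == 0 for k, v in ov.regions.items() if len(k) >= 2)

    def test_inclusion_exclusion_identity(self, table1):
        ov = tissue_overlaps(table1)
        union_ie = 0
        tissues = list(ov.tissue_sets)
        for r in range(1, len(tissues) + 1):
            for combo in itertools.combinations(tissues, r):
                union_ie += (-1) ** (r + 1) * ov.intersection_size(combo)
        assert union_ie == len(ov.union)


class TestReconstruction:
    def test_recovers_published_dominant_plant_vector(self):
        result = reconstruct_abundances(
            8,
            {"shannon": 1.79, "simpson_complement": 0.789, "berger_parker": 0.35},
            n_range=(1, 20),
        )
        assert (6, 4, 2, 1, 1, 1, 1, 1) in result
        assert sum((6, 4, 2, 1, 1, 1, 1, 1)) == 17

    def test_even_targets_admit_only_equal_vectors(self):
        result = reconstruct_abundances(
            4, {"shannon": 1.39, "simpson_complement": 0.75, "berger_parker": 0.25},
            n_range=(1, 20),
        )
        assert result and all(len(set(v)) == 1 for v in result)

    def test_impossible_dominance_target_yields_empty_set(self):
        result = reconstruct_abundances(
            2, {"berger_parker": 1.0}, n_range=(1, 30), rounding={"berger_parker": 2}
        )
        assert result == []

    def test_round_trip_through_the_indices(self):
        # every returned vector, re-scored and re-rounded, hits its own targets
        targets = {"shannon": 1.74, "simpson_complement": 0.82, "berger_parker": 0.22}
        for vec in reconstruct_abundances(6, targets, n_range=(1, 20)):
            assert round_value(shannon(vec), 2) == targets["shannon"]
            assert round_value(simpson_complement(vec), 2) == targets["simpson_complement"]
            assert round_value(berger_parker(vec), 2) == targets["berger_parker"]

    def test_empty_n_range_rejected(self):
        with pytest.raises(ValidationError):
            reconstruct_abundances(3, {"shannon": 1.0}, n_range=(5, 4))

    def test_brute_force_enumeration_oracle(self):
        # independent oracle: filter all compositions via itertools, unordered
        S, n_max = 3, 9
        targets = {"berger_parker": 0.5}
        expected = set()
        for total in range(S, n_max + 1):
            for comp in itertools.product(range(1, total + 1), repeat=S):
                if sum(comp) == total and round_value(max(comp) / total, 1) == 0.5:
                    expected.add(tuple(sorted(comp, reverse=True)))
        got = set(reconstruct_abundances(S, targets, n_range=(1, n_max),
                                         rounding={"berger_parker": 1}))
        assert got == expected


class TestOrdination:
    def test_single_varying_column_explains_everything(self):
        recs = [
            IsolateRecord("p", "PAWD", "leaf", TaxonRecord("A sp.", "A"), 5),
            IsolateRecord("p", "PAWD", "leaf", TaxonRecord("B sp.", "B"), 1),
        ]
        res = pca_ordination(CommunityTable(isolates=recs))
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_fixture_variance_fractions_are_a_spectrum(self, table1):
        res = pca_ordination(table1)
        evr = res.explained_variance_ratio
        assert np.all(evr >= 0) and np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() <= 1 + 1e-9

    def test_scores_match_eigendecomposition_oracle(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 6, size=(6, 4))
        recs = []
        for i in range(6):
            for j, tissue in enumerate(("flower", "leaf", "stem", "root")):
                if counts[i, j]:
                    recs.append(
                        IsolateRecord(
                            "p", "PAWD", tissue,
                            TaxonRecord(f"G{i} sp.", f"G{i}"), int(counts[i, j]),
                        )
                    )
        table = CommunityTable(isolates=recs)
        res = pca_ordination(table)
        X = genus_tissue_matrix(table).to_numpy(dtype=float)
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc / (X.shape[0] - 1)
        w, V = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        w, V = w[order], V[:, order]
        for j in range(res.scores.shape[1]):
            i = int(np.argmax(np.abs(V[:, j])))
            if V[i, j] < 0:
                V[:, j] *= -1
        oracle_scores = Xc @ V
        k = res.scores.shape[1]
        assert np.allclose(res.scores, oracle_scores[:, :k], atol=1e-8)
        assert np.allclose(
            res.explained_variance_ratio, (w / w.sum())[:k], atol=1e-10
        )

    def test_constant_matrix_is_degenerate(self):
        recs = [
            IsolateRecord("p", "PAWD", "leaf", TaxonRecord("A sp.", "A"), 2),
            IsolateRecord("p", "PAWD", "leaf", TaxonRecord("B sp.", "B"), 2),
        ]
        with pytest.raises(DegenerateInputError):
            pca_ordination(CommunityTable(isolates=recs))


def test_merging_disjoint_plants_never_decreases_union_richness(table1):
    from endodiv import merge_tables

    sub = CommunityTable(isolates=table1.records_for("Lantana camara"))
    merged = merge_tables(
        sub, CommunityTable(isolates=table1.records_for("Suaeda vermiculata"))
    )

    def union_richness(t):
        return len({r.taxon.morphospecies_id for r in t.isolates})

    assert union_richness(merged) >= union_richness(sub)
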