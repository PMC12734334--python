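"""Generators: planted-SSR genomes, structured populations, trait tables."""

import numpy as np
import pytest

from conftest import brute_force_ssrs
from ssrcore.clustering import cut_at_similarity, simple_matching, upgma_from_similarity
from ssrcore.genotypes import to_band_matrix, write_genotypes
from ssrcore.mining import find_ssrs
from ssrcore.molecular_id import default_codebook, molecular_ids
from ssrcore.simulate import (
    CalibrationError,
    GenomeSpec,
    PopulationSpec,
    SpecError,
    simulate_genome,
    simulate_population,
    simulate_traits,
)

PLANT = [(100, "AG", 8), (500, "T", 12), (900, "ACG", 6), (2000, "AAAG", 5)]


class TestGenomeSimulator:
    def test_mining_recovers_exactly_the_planted_catalog(self):
        records, truth = simulate_genome(GenomeSpec(length=5000, planted=PLANT, seed=2))
        catalog = find_ssrs(records)
        assert {(l.start, l.end, l.motif) for l in catalog.loci} == {
            (l.start, l.end, l.motif) for l in truth.loci
        }
        assert len(truth) == len(PLANT)

    def test_brute_force_confirms_no_extra_tracts(self):
        records, truth = simulate_genome(GenomeSpec(length=3000, planted=PLANT[:2], seed=5))
        seq = str(records[0].seq)
        assert brute_force_ssrs(seq) == {
            (l.start, l.end, l.motif) for l in truth.loci
        }

    def test_zero_plantings_gives_empty_catalog(self):
        records, truth = simulate_genome(GenomeSpec(length=2000, planted=[], seed=0))
        assert len(truth) == 0
        assert len(find_ssrs(records)) == 0

    def test_below_threshold_planting_rejected(self):
        with pytest.raises(SpecError):
            simulate_genome(GenomeSpec(length=1000, planted=[(100, "AG", 5)]))

    def test_overlapping_plantings_rejected(self):
        with pytest.raises(SpecError):
            GenomeSpec(length=1000, planted=[(100, "AG", 8), (110, "T", 12)])

    def test_seed_determinism(self):
        r1, _ = simulate_genome(GenomeSpec(length=2000, planted=PLANT[:2], seed=9))
        r2, _ = simulate_genome(GenomeSpec(length=2000, planted=PLANT[:2], seed=9))
        assert str(r1[0].seq) == str(r2[0].seq)


class TestPopulationSimulator:
    def test_default_spec_has_115_band_columns(self, default_population):
        g, _ = default_population
        assert to_band_matrix(g).n_columns == 115
        assert len(g.accessions) == 57
        assert len(g.markers) == 15

    def test_similarity_calibration_within_tolerance(self):
        """Mean within/between-group simple matching lands within ±0.03 of
        the spec levels, and the closed-form expectation is tighter still."""
        wm, bm = [], []
        for seed in (0, 1, 2):
            spec = PopulationSpec(seed=seed)
            g, truth = simulate_population(spec)
            s = simple_matching(to_band_matrix(g))
            labels = np.array([truth.group_labels[a] for a in s.labels])
            iu = np.triu_indices(len(labels), 1)
            same = labels[iu[0]] == labels[iu[1]]
            wm.append(s.values[iu][same].mean())
            bm.append(s.values[iu][~same].mean())
            assert abs(truth.expected_within - spec.within_group_similarity) < 1e-6
            assert abs(truth.expected_between - spec.between_group_similarity) < 0.01
        assert abs(np.mean(wm) - 0.90) < 0.03
        assert abs(np.mean(bm) - 0.72) < 0.03

    def test_similarity_range_resembles_a_germplasm_panel(self, default_population):
        g, _ = default_population
        s = simple_matching(to_band_matrix(g))
        off = s.values[np.triu_indices(len(g.accessions), 1)]
        assert 0.60 <= off.min() <= 0.78
        assert off.max() >= 0.90

    def test_single_group_population_is_one_cluster(self):
        spec = PopulationSpec(n_accessions=30, n_groups=1, seed=4)
        g, _ = simulate_population(spec)
        t = upgma_from_similarity(simple_matching(to_band_matrix(g)))
        assert set(cut_at_similarity(t, 0.76).values()) == {1}

    def test_cut_at_planted_threshold_recovers_groups(self, default_population):
        from sklearn.metrics import adjusted_rand_score

        g, truth = default_population
        t = upgma_from_similarity(simple_matching(to_band_matrix(g)))
        assign = cut_at_similarity(t, 0.76)
        truth_labels = [truth.group_labels[a] for a in g.accessions]
        pred = [assign[a] for a in g.accessions]
        assert adjusted_rand_score(truth_labels, pred) == 1.0
        assert len(set(pred)) == 5

    def test_seed_determinism_bytes(self, tmp_path):
        g1, _ = simulate_population(PopulationSpec(seed=13))
        g2, _ = simulate_population(PopulationSpec(seed=13))
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_genotypes(g1, p1)
        write_genotypes(g2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_missing_rate_preserves_allele_coverage(self):
        spec = PopulationSpec(missing_rate=0.05, seed=6)
        g, _ = simulate_population(spec)
        assert to_band_matrix(g).n_columns == 115
        n_missing = sum(
            g.is_missing(a, m) for a in g.accessions for m in g.marker_names
        )
        assert n_missing > 0

    def test_unattainable_targets_raise_calibration_error(self):
        with pytest.raises(CalibrationError):
            simulate_population(
                PopulationSpec(within_group_similarity=0.9,
                               between_group_similarity=0.05, seed=0)
            )

    def test_invalid_spec_rejected(self):
        with pytest.raises(SpecError):
            PopulationSpec(within_group_similarity=0.7,
                           between_group_similarity=0.8)
        with pytest.raises(SpecError):
            PopulationSpec(na_per_locus=[0, 5], marker_names=["a", "b"])


class TestTraitSimulator:
    def test_default_color_counts(self):
        meta = simulate_traits(57, seed=0)
        assert (meta["color"] == "brown").sum() == 39
        assert (meta["color"] == "white").sum() == 18

    def test_full_correlation_colors_the_designated_group(self, default_population):
        _, truth = default_population
        meta = simulate_traits(
            57, group_labels=truth.group_labels, seed=0,
            color_group_correlation=1.0,
        )
        tally = {}
        for acc, g in truth.group_labels.items():
            tally[g] = tally.get(g, 0) + 1
        designated = max(sorted(tally), key=lambda g: tally[g])
        members = [a for a, g in truth.group_labels.items() if g == designated]
        assert all(meta.loc[a, "color"] == "white" for a in members)

    def test_levels_round_trip_through_id_encoding(self, default_population, default_bands):
        _, truth = default_population
        book = default_codebook()
        meta = simulate_traits(57, codebook=book,
                               group_labels=truth.group_labels, seed=3)
        ids = molecular_ids(default_bands, meta, book)
        assert len(ids) == 57
        assert all(m.trait_code and m.supplementary_code for m in ids)

    def test_seed_determinism(self):
        a = simulate_traits(57, seed=8)
        b = simulate_traits(57, seed=8)
        assert a.equals(b)
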