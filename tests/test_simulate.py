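"""The synthetic RH world: breakage calibration, retention, determinism,
and rearrangement truth."""

import numpy as np
import pandas as pd
import pytest

from radmap import (ConfigError, SimulationConfig, SpeciesSpec, detect_cs,
                    filter_hits, simulate_dataset, simulate_genetic_map,
                    simulate_genome, simulate_model_species, simulate_panel)
from radmap.matrix import AMBIGUOUS, PRESENT

from conftest import NOISE_FREE, controlled_genome, controlled_panel


class TestGenome:
    def test_positions_strictly_increasing_and_ids_unique(self):
        cfg = SimulationConfig(n_chromosomes=3, markers_per_chromosome=5,
                               seed=1)
        g = simulate_genome(cfg)
        for chrom in g.chromosomes:
            assert np.all(np.diff(chrom.positions_kb) > 0)
        ids = g.all_markers()
        assert len(set(ids)) == len(ids) == 15

    def test_microsatellite_fraction_zero_means_none(self):
        cfg = SimulationConfig(microsatellite_fraction=0.0, seed=2)
        g = simulate_genome(cfg)
        assert all(c != "microsatellite" for chrom in g.chromosomes
                   for c in chrom.classes)

    def test_same_seed_same_genome(self):
        cfg = SimulationConfig(seed=7)
        g1, g2 = simulate_genome(cfg), simulate_genome(cfg)
        for c1, c2 in zip(g1.chromosomes, g2.chromosomes):
            assert c1.markers == c2.markers
            assert np.array_equal(c1.positions_kb, c2.positions_kb)
            assert c1.classes == c2.classes

    @pytest.mark.parametrize("kwargs", [
        dict(n_chromosomes=0), dict(markers_per_chromosome=0),
        dict(retention_rate=1.5), dict(kb_per_cr=0.0), dict(n_clones=0),
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            simulate_genome(SimulationConfig(**kwargs))


class TestPanel:
    def test_zero_distance_markers_always_corecent(self):
        # two markers at (almost) the same position: never discordant
        genome, matrix, _ = controlled_panel(2, [1e-8], seed=0,
                                             n_clones=2000)
        a, b = (matrix.vector(m) for m in matrix.markers)
        assert np.array_equal(a, b)

    def test_breakage_probability_matches_closed_form(self):
        # theta = 1 - exp(-d / (100 kb_per_cr)); d = 2750 kb -> 1 - 1/e
        n = 10_000
        genome, matrix, _ = controlled_panel(2, [100.0], seed=1, n_clones=n)
        a, b = (matrix.vector(m) == PRESENT for m in matrix.markers)
        theta = 1.0 - np.exp(-1.0)          # gap of 100 cR = 2750 kb
        r = 0.117
        # P(discordant) = 2 r theta (1 - r)
        p = 2 * r * theta * (1 - r)
        observed = np.mean(a != b)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(observed - p) < 3 * se

    def test_presence_fraction_matches_retention(self):
        cfg = SimulationConfig(n_chromosomes=1, markers_per_chromosome=10,
                               chromosome_length_kb=30_000.0, n_clones=5000,
                               seed=4, **NOISE_FREE)
        genome = simulate_genome(cfg)
        matrix, _ = simulate_panel(genome, cfg)
        assert matrix.calls.size == 50_000   # clone-markers
        p = matrix.presence_fraction()
        # calls within a clone share fragments, so the standard error of
        # the panel mean comes from the spread of per-clone fractions
        clone_frac = (matrix.calls == PRESENT).mean(axis=1)
        se = clone_frac.std(ddof=1) / np.sqrt(matrix.n_clones)
        assert abs(p - 0.117) < 3 * se

    def test_fragments_disjoint_and_inside_chromosome(self, clean_dataset):
        frags = clean_dataset.truth_fragments
        L = clean_dataset.config.chromosome_length_kb
        assert (frags["start_kb"] >= 0).all()
        assert (frags["end_kb"] <= L).all()
        for (_, _), grp in frags.groupby(["clone", "chrom"]):
            srt = grp.sort_values("start_kb")
            assert (srt["end_kb"].to_numpy()[:-1]
                    <= srt["start_kb"].to_numpy()[1:] + 1e-9).all()

    def test_seed_determinism_full_dataset(self):
        cfg = SimulationConfig(n_chromosomes=2, markers_per_chromosome=8,
                               chromosome_length_kb=6000.0, seed=9)
        d1, d2 = simulate_dataset(cfg), simulate_dataset(cfg)
        assert d1.call_matrix == d2.call_matrix
        pd.testing.assert_frame_equal(d1.truth_fragments, d2.truth_fragments)
        pd.testing.assert_frame_equal(d1.genetic_map, d2.genetic_map)
        pd.testing.assert_frame_equal(d1.hit_tables, d2.hit_tables)

    def test_noise_rates_produce_flips_and_ambiguity(self):
        cfg = SimulationConfig(n_chromosomes=1, markers_per_chromosome=20,
                               chromosome_length_kb=15_000.0, seed=12,
                               n_clones=500, false_positive_rate=0.05,
                               false_negative_rate=0.1, ambiguous_rate=0.08)
        genome = simulate_genome(cfg)
        noisy, _ = simulate_panel(genome, cfg)
        amb = np.mean(noisy.calls == AMBIGUOUS)
        assert abs(amb - 0.08) < 0.01


class TestGeneticMap:
    def test_cm_is_kb_over_kb_per_cm(self):
        genome = controlled_genome(3, [10.0, 20.0])
        genome.chromosomes[0].classes = ["microsatellite"] * 3
        genome.chromosomes[0].positions_kb = np.array([840.0, 1680.0,
                                                       4200.0])
        cfg = SimulationConfig(n_chromosomes=1, markers_per_chromosome=3,
                               chromosome_length_kb=5000.0, seed=0)
        gmap = simulate_genetic_map(genome, cfg)
        assert gmap["cm"].tolist() == [1.0, 2.0, 5.0]
        assert set(gmap["lg"]) == {"LG1"}

    def test_split_chromosome_gets_two_lg_labels(self):
        cfg = SimulationConfig(n_chromosomes=2, markers_per_chromosome=20,
                               microsatellite_fraction=0.5, seed=3,
                               split_chromosome="chr01")
        genome = simulate_genome(cfg)
        gmap = simulate_genetic_map(genome, cfg)
        labels = set(gmap["lg"])
        assert "LG1a" in labels and "LG1b" in labels and "LG2" in labels

    def test_no_jitter_keeps_kb_order(self, clean_dataset):
        gmap = clean_dataset.genetic_map
        pos = clean_dataset.genome.marker_positions().set_index("marker")
        for lg, grp in gmap.groupby("lg"):
            kb = pos.loc[grp["marker"], "pos_kb"].to_numpy()
            assert np.all(np.diff(kb[np.argsort(grp["cm"].to_numpy())]) > 0)

    def test_no_microsatellites_warns_empty(self):
        cfg = SimulationConfig(microsatellite_fraction=0.0, seed=2)
        genome = simulate_genome(cfg)
        with pytest.warns(UserWarning, match="no microsatellite"):
            gmap = simulate_genetic_map(genome, cfg)
        assert gmap.empty


class TestModelSpecies:
    def _dataset(self, specs, seed=0, n=12):
        cfg = SimulationConfig(
            n_chromosomes=2, markers_per_chromosome=n,
            chromosome_length_kb=8000.0, seed=seed, species_specs=specs,
            **NOISE_FREE)
        genome = simulate_genome(cfg)
        hits, truth = simulate_model_species(genome, cfg)
        return genome, hits, truth

    def test_zero_rearrangements_one_cs_per_chromosome(self):
        specs = [SpeciesSpec("target")]
        genome, hits, truth = self._dataset(specs)
        anchors = filter_hits(hits)
        for chrom in genome.chromosomes:
            segments, singles = detect_cs(chrom.markers, anchors, "target")
            assert len(segments) == 1 and not singles
            assert segments[0].markers == chrom.markers

    def test_fusion_joins_two_donor_chromosomes(self):
        specs = [SpeciesSpec("target", n_fusions=1)]
        genome, hits, truth = self._dataset(specs)
        anchors = filter_hits(hits)
        model_chroms = set()
        for chrom in genome.chromosomes:
            segments, _ = detect_cs(chrom.markers, anchors, "target")
            assert len(segments) == 1
            model_chroms.add(segments[0].model_chromosome)
        assert len(model_chroms) == 1  # both donors on one model chromosome

    def test_inversion_keeps_cs_and_adds_cso_boundary(self):
        from radmap import detect_cso
        specs = [SpeciesSpec("target", n_inversions=1)]
        genome, hits, truth = self._dataset(specs, seed=5)
        anchors = filter_hits(hits)
        inverted = set(truth["target"]["inversion_spans"][0])
        chrom = next(c for c in genome.chromosomes
                     if inverted <= set(c.markers))
        segments, _ = detect_cs(chrom.markers, anchors, "target")
        assert len(segments) == 1
        runs = detect_cso(segments[0], anchors, "target")
        assert len(runs) >= 2
        directions = {r.direction for r in runs}
        assert len(directions) == 2  # the inverted block flips orientation

    def test_missing_rate_drops_orthologs(self):
        specs = [SpeciesSpec("target", missing_ortholog_rate=0.5)]
        genome, hits, truth = self._dataset(specs, n=40)
        assert 15 <= len(hits) <= 65  # ~50% of 80 markers

    def test_infeasible_recipe_raises(self):
        cfg = SimulationConfig(
            n_chromosomes=1, markers_per_chromosome=4,
            species_specs=[SpeciesSpec("bad", n_fusions=1)], seed=0)
        genome = simulate_genome(cfg)
        with pytest.raises(ConfigError):
            simulate_model_species(genome, cfg)

    def test_cs_truth_matches_detected_segments(self):
        specs = [SpeciesSpec("target", n_fissions=1, n_translocations=1,
                             n_inversions=1)]
        genome, hits, truth = self._dataset(specs, seed=8)
        anchors = filter_hits(hits)
        for chrom in genome.chromosomes:
            segments, singles = detect_cs(chrom.markers, anchors, "target")
            got = ([(s.model_chromosome, s.markers) for s in segments]
                   + [(mc, [m]) for m, mc in singles])
            want = truth["target"]["cs_truth"][chrom.name]
            # both in donor order; rebuild interleaved order from truth
            assert sorted(map(str, got)) == sorted(map(str, want))
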