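"""Hit filtering, Venn partition, CS/CSO decomposition and Oxford grids."""

import itertools

import numpy as np
import pandas as pd
import pytest

from radmap import (AnchorTable, ConservedSegment, SimulationConfig,
                    SpeciesSpec, detect_cs, detect_cso, filter_hits,
                    monotone_runs, oxford_grid, simulate_genome,
                    simulate_model_species, summarize_chromosome,
                    summarize_cs_cso, venn_partition)

HIT_COLS = ["marker", "species", "chromosome", "start", "end", "score",
            "length", "strand"]


def _hits(rows):
    return pd.DataFrame(rows, columns=HIT_COLS)


def _anchors(rows):
    """AnchorTable from (marker, species, chromosome, position) rows."""
    df = pd.DataFrame(rows, columns=["marker", "species", "chromosome",
                                     "position"])
    return AnchorTable(df, df[["marker", "species"]])


class TestFilterHits:
    def test_score_and_length_window(self):
        hits = _hits([
            ("m1", "s", "chr1", 0, 100, 249, 100, "+"),   # score too low
            ("m2", "s", "chr1", 0, 100, 250, 100, "+"),   # boundary: kept
            ("m3", "s", "chr1", 0, 79, 400, 79, "+"),     # too short
            ("m4", "s", "chr1", 0, 301, 400, 301, "+"),   # too long
            ("m5", "s", "chr1", 0, 300, 400, 300, "+"),   # boundary: kept
            ("m6", "s", "chr1", 0, 80, 400, 80, "+"),     # boundary: kept
        ])
        table = filter_hits(hits)
        assert sorted(table.anchors["marker"]) == ["m2", "m5", "m6"]

    def test_best_hit_per_marker_species(self):
        hits = _hits([
            ("m1", "s", "chr2", 500, 650, 280, 150, "+"),
            ("m1", "s", "chr1", 100, 250, 300, 150, "+"),
        ])
        table = filter_hits(hits)
        assert len(table.anchors) == 1
        row = table.anchors.iloc[0]
        assert row["chromosome"] == "chr1"
        assert row["position"] == 175.0          # interval midpoint

    def test_score_tie_broken_by_chromosome_then_start(self):
        hits = _hits([
            ("m1", "s", "chr2", 0, 150, 300, 150, "+"),
            ("m1", "s", "chr1", 900, 1050, 300, 150, "+"),
            ("m1", "s", "chr1", 100, 250, 300, 150, "+"),
        ])
        table = filter_hits(hits)
        assert table.anchors.iloc[0]["position"] == 175.0

    def test_toy_table_of_six_hits_keeps_four_markers(self):
        hits = _hits([
            ("m1", "s", "chr1", 0, 120, 300, 120, "+"),
            ("m2", "s", "chr1", 0, 200, 251, 200, "+"),
            ("m3", "s", "chr2", 0, 90, 500, 90, "+"),
            ("m4", "s", "chr2", 0, 250, 249, 250, "+"),   # fails score
            ("m5", "s", "chr3", 0, 60, 400, 60, "+"),     # fails length
            ("m6", "s", "chr3", 0, 290, 260, 290, "+"),
        ])
        table = filter_hits(hits)
        assert len(table.venn_hits) == 4

    def test_unknown_chromosome_counts_for_venn_not_anchors(self):
        hits = _hits([
            ("m1", "s", "Unknown", 0, 100, 400, 100, "+"),
            ("m2", "s", "chr1", 0, 100, 400, 100, "+"),
        ])
        table = filter_hits(hits)
        assert table.anchors["marker"].tolist() == ["m2"]
        assert sorted(table.venn_hits["marker"]) == ["m1", "m2"]


class TestVenn:
    def test_percentage_rounding(self):
        rows = [(f"m{i}", "stickleback") for i in range(1920)]
        rows += [(f"x{i}", "medaka") for i in range(555)]
        table = AnchorTable(pd.DataFrame(), pd.DataFrame(
            rows, columns=["marker", "species"]))
        out = venn_partition(table, ["stickleback", "medaka"])
        assert out["grand_total"] == 2475
        assert out["totals"]["stickleback"] == 1920
        assert out["percentages"]["stickleback"] == 77.6

    def test_subset_counts_sum_to_grand_total(self):
        rng = np.random.default_rng(0)
        species = ["a", "b", "c"]
        rows = []
        for i in range(200):
            for s in species:
                if rng.random() < 0.6:
                    rows.append((f"m{i}", s))
        table = AnchorTable(pd.DataFrame(), pd.DataFrame(
            rows, columns=["marker", "species"]))
        out = venn_partition(table, species)
        assert sum(out["subset_counts"].values()) == out["grand_total"]

    def test_species_required(self):
        table = _anchors([])
        with pytest.raises(ValueError):
            venn_partition(table, [])


class TestConservedSegments:
    def test_aabaa_pattern(self):
        anchors = _anchors([(f"m{i}", "s", c, float(i * 10))
                            for i, c in enumerate("AABAA")])
        segments, singles = detect_cs([f"m{i}" for i in range(5)],
                                      anchors, "s")
        assert [(s.model_chromosome, s.markers) for s in segments] == [
            ("A", ["m0", "m1"]), ("A", ["m3", "m4"])]
        assert singles == [("m2", "B")]

    def test_single_anchored_marker_is_singleton(self):
        anchors = _anchors([("m1", "s", "A", 10.0)])
        segments, singles = detect_cs(["m0", "m1", "m2"], anchors, "s")
        assert not segments and singles == [("m1", "A")]

    def test_non_anchored_markers_do_not_break_runs(self):
        anchors = _anchors([("m0", "s", "A", 0.0), ("m2", "s", "A", 10.0)])
        segments, singles = detect_cs(["m0", "m1", "m2"], anchors, "s")
        assert len(segments) == 1 and segments[0].markers == ["m0", "m2"]


def minimal_monotone_decomposition(values):
    """Brute-force minimum number of consecutive strictly monotone pieces."""
    n = len(values)
    best = n
    for cuts in itertools.product([0, 1], repeat=n - 1):
        pieces = []
        start = 0
        for i, c in enumerate(cuts, start=1):
            if c:
                pieces.append(values[start:i])
                start = i
        pieces.append(values[start:])
        if all(_is_monotone(p) for p in pieces):
            best = min(best, len(pieces))
    return best


def _is_monotone(p):
    d = np.diff(p)
    return len(p) < 2 or np.all(d > 0) or np.all(d < 0)


class TestCSO:
    def test_increasing_run(self):
        runs = monotone_runs([10, 20, 30])
        assert runs == [(0, 3, "increasing")]

    def test_decreasing_run_is_inverted_cso(self):
        seg = ConservedSegment("A", ["m0", "m1", "m2"])
        anchors = _anchors([("m0", "s", "A", 30.0), ("m1", "s", "A", 20.0),
                            ("m2", "s", "A", 10.0)])
        runs = detect_cso(seg, anchors, "s")
        assert len(runs) == 1 and runs[0].direction == "decreasing"

    def test_spec_pattern_two_runs(self):
        values = [10, 20, 30, 25, 35]
        runs = monotone_runs(values)
        assert [(a, b) for a, b, _ in runs] == [(0, 3), (3, 5)]
        assert len(runs) == minimal_monotone_decomposition(values)

    def test_tied_coordinates_rejected(self):
        with pytest.raises(ValueError, match="tied"):
            monotone_runs([10, 20, 20, 30])

    def test_runs_partition_and_are_monotone(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            values = rng.permutation(12).tolist()
            runs = monotone_runs(values)
            assert [a for a, _, _ in runs][0] == 0
            assert runs[-1][1] == len(values)
            for (a, b, d), (a2, _, _) in zip(runs, runs[1:]):
                assert b == a2
            for a, b, d in runs:
                assert _is_monotone(values[a:b])


class TestOxfordGrid:
    def _summaries(self, chrom_letters, species="s"):
        sums = []
        for ci, letters in enumerate(chrom_letters):
            markers = [f"c{ci}m{i}" for i in range(len(letters))]
            anchors = _anchors([(m, species, c, float(i * 10))
                                for i, (m, c) in
                                enumerate(zip(markers, letters))])
            sums.append(summarize_chromosome(f"chr{ci}", markers, anchors,
                                             species))
        return sums

    def test_fully_syntenic_single_cell(self):
        grid = oxford_grid(self._summaries(["AAAA"]), "s")
        assert len(grid) == 1
        assert grid.iloc[0]["total"] == 4

    def test_totals_conserve_anchor_count(self):
        grid = oxford_grid(self._summaries(["AABAA", "BBCC", "A"]), "s")
        assert grid["total"].sum() == 10

    def test_translocation_two_cs_cells(self):
        grid = oxford_grid(self._summaries(["AAABBB"]), "s")
        cs_cells = grid[grid["cs_markers"] > 0]
        assert len(cs_cells) == 2


class TestSummaries:
    def test_zero_rearrangement_one_cs_one_cso(self):
        cfg = SimulationConfig(
            n_chromosomes=2, markers_per_chromosome=10,
            chromosome_length_kb=8000.0, seed=1,
            species_specs=[SpeciesSpec("target")])
        genome = simulate_genome(cfg)
        hits, _ = simulate_model_species(genome, cfg)
        table = filter_hits(hits)
        sums = [summarize_chromosome(c.name, c.markers, table, "target")
                for c in genome.chromosomes]
        out = summarize_cs_cso(sums, ["target"]).set_index("chromosome")
        assert (out["target_cs"] == 1).all()
        assert (out["target_cso"] == 1).all()

    def test_species_without_anchors_reported_un(self):
        anchors = _anchors([("m0", "s1", "A", 0.0), ("m1", "s1", "A", 5.0)])
        sums = [summarize_chromosome("chr0", ["m0", "m1"], anchors, sp)
                for sp in ("s1", "s2")]
        out = summarize_cs_cso(sums, ["s1", "s2"]).iloc[0]
        assert out["s1_cs"] == 1 and out["s2_cs"] == "un"

    def test_k_short_inversions_give_k_plus_1_cso(self):
        # two non-adjacent 2-marker inversions in an otherwise colinear
        # chromosome: greedy and minimal decompositions agree on k + 1
        order = [f"m{i}" for i in range(12)]
        pos = list(range(12))
        for start in (3, 8):                     # invert pairs (3,4), (8,9)
            pos[start], pos[start + 1] = pos[start + 1], pos[start]
        anchors = _anchors([(m, "s", "A", float(p * 100))
                            for m, p in zip(order, pos)])
        summary = summarize_chromosome("chr0", order, anchors, "s")
        assert len(summary.segments) == 1
        assert summary.cso_count == 3
        values = [p * 100.0 for p in pos]
        assert minimal_monotone_decomposition(values) == 3

    def test_map_reversal_keeps_cs_flips_cso_direction(self):
        order = [f"m{i}" for i in range(8)]
        anchors = _anchors([(m, "s", "A", float(i * 10))
                            for i, m in enumerate(order)])
        fwd = summarize_chromosome("chr0", order, anchors, "s")
        rev = summarize_chromosome("chr0", order[::-1], anchors, "s")
        assert len(fwd.segments) == len(rev.segments)
        assert fwd.cso[0][0].direction == "increasing"
        assert rev.cso[0][0].direction == "decreasing"
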