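"""Ortholog-hit filtering, Venn partition, conserved segments and Oxford
grids.

A marker's putative ortholog in a model species is the best-scoring
alignment hit that survives a score floor and an alignment-length window
(the window discards overly long hits that tend to be retrogenes). Walking
a chromosome map in order, maximal runs of two or more consecutive anchored
markers whose orthologs share a model chromosome are conserved segments
(CS); lone markers are singletons. Within a CS, maximal strictly monotone
runs of ortholog coordinates (increasing or decreasing) of length >= 2 are
conserved segments ordered (CSO). Oxford grids cross-tabulate marker counts
between the chromosome sets of the two species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_MIN_SCORE = 250.0
DEFAULT_MIN_LEN = 80
DEFAULT_MAX_LEN = 300
UNKNOWN_LABELS = frozenset({"unknown", "un", "chrun", "chr_unknown"})

HIT_COLUMNS = ["marker", "species", "chromosome", "start", "end", "score",
               "length", "strand"]


@dataclass
class AnchorTable:
    """Best-hit ortholog locations per (marker, species).

    ``anchors`` excludes hits on an 'unknown' chromosome; ``venn_hits``
    keeps them, so species totals for the Venn partition count every marker
    with a retained hit anywhere in the assembly.
    """

    anchors: pd.DataFrame       # marker, species, chromosome, position
    venn_hits: pd.DataFrame     # marker, species (retained best hits)

    def for_species(self, species: str) -> pd.DataFrame:
        return self.anchors[self.anchors["species"] == species]


@dataclass
class ConservedSegment:
    model_chromosome: str
    markers: list[str]          # in chromosome-map order

    def __len__(self) -> int:
        return len(self.markers)


@dataclass
class CSORun:
    direction: str              # 'increasing' | 'decreasing'
    markers: list[str]


@dataclass
class SyntenySummary:
    """CS / singleton / CSO decomposition of one chromosome against one
    model species."""

    chromosome: str
    species: str
    segments: list[ConservedSegment] = field(default_factory=list)
    singletons: list[tuple[str, str]] = field(default_factory=list)
    cso: dict[int, list[CSORun]] = field(default_factory=dict)

    @property
    def n_anchored(self) -> int:
        return sum(len(s) for s in self.segments) + len(self.singletons)

    @property
    def cso_count(self) -> int:
        return sum(len(runs) for runs in self.cso.values())


def _is_unknown(chromosome: str) -> bool:
    return str(chromosome).lower() in UNKNOWN_LABELS


def filter_hits(hits: pd.DataFrame, min_score: float = DEFAULT_MIN_SCORE,
                min_len: int = DEFAULT_MIN_LEN,
                max_len: int = DEFAULT_MAX_LEN) -> AnchorTable:
    """Score/length-filter hits and keep the best per (marker, species).

    Survivors need ``score >= min_score`` and ``min_len <= length <=
    max_len``; among them, the highest score wins, ties broken by
    (chromosome, start) ascending. The anchor coordinate is the hit
    interval midpoint. Hits on an 'unknown' chromosome survive for Venn
    counting but are excluded from the anchor table.
    """
    missing = [c for c in HIT_COLUMNS[:7] if c not in hits.columns]
    if missing:
        raise ValueError(f"hit table missing columns {missing}")
    ok = hits[(hits["score"] >= min_score)
              & (hits["length"] >= min_len)
              & (hits["length"] <= max_len)].copy()
    ok = ok.sort_values(["marker", "species", "score", "chromosome",
                         "start"],
                        ascending=[True, True, False, True, True],
                        kind="stable")
    best = ok.drop_duplicates(["marker", "species"], keep="first")
    venn_hits = best[["marker", "species"]].reset_index(drop=True)
    located = best[~best["chromosome"].map(_is_unknown)].copy()
    located["position"] = (located["start"] + located["end"]) / 2.0
    anchors = located[["marker", "species", "chromosome",
                       "position"]].reset_index(drop=True)
    return AnchorTable(anchors, venn_hits)


def venn_partition(table: AnchorTable, species: list[str]) -> dict:
    """Distribution of markers over species subsets.

    Returns subset counts (keyed by a sorted species tuple), per-species
    totals and their percentages of the grand total (markers with at least
    one retained hit), rounded to one decimal.
    """
    if not species:
        raise ValueError("need at least one species")
    hits = table.venn_hits[table.venn_hits["species"].isin(species)]
    subset_of: dict[str, set] = {}
    for row in hits.itertuples(index=False):
        subset_of.setdefault(row.marker, set()).add(row.species)
    counts: dict[tuple, int] = {}
    for sub in subset_of.values():
        key = tuple(sorted(sub))
        counts[key] = counts.get(key, 0) + 1
    grand_total = len(subset_of)
    totals = {s: sum(n for sub, n in counts.items() if s in sub)
              for s in species}
    percents = {s: round(100.0 * totals[s] / grand_total, 1)
                if grand_total else float("nan") for s in species}
    return {"subset_counts": counts, "totals": totals,
            "percentages": percents, "grand_total": grand_total}


def detect_cs(map_order: list[str], table: AnchorTable, species: str
              ) -> tuple[list[ConservedSegment], list[tuple[str, str]]]:
    """Conserved segments and singletons along one chromosome map.

    Walks the map-ordered markers restricted to those anchored in the
    species; non-anchored markers are skipped and do not break runs.
    Maximal same-model-chromosome runs of length >= 2 become CS; length-1
    runs are singletons (marker, model chromosome).
    """
    sp = table.for_species(species)
    chrom_of = dict(zip(sp["marker"], sp["chromosome"]))
    runs: list[ConservedSegment] = []
    for m in map_order:
        if m not in chrom_of:
            continue
        mc = chrom_of[m]
        if runs and runs[-1].model_chromosome == mc:
            runs[-1].markers.append(m)
        else:
            runs.append(ConservedSegment(mc, [m]))
    segments = [r for r in runs if len(r) >= 2]
    singletons = [(r.markers[0], r.model_chromosome) for r in runs
                  if len(r) == 1]
    return segments, singletons


def monotone_runs(values: list[float]) -> list[tuple[int, int, str]]:
    """Greedy left-to-right maximal strictly monotone runs.

    Returns (start, stop, direction) index triples partitioning ``values``
    (stop exclusive); the direction of a run is fixed by its first two
    members. Tied values are an error: ortholog coordinates must be unique
    on a chromosome.
    """
    v = list(values)
    if len(set(v)) != len(v):
        raise ValueError("tied ortholog coordinates; cannot decompose "
                         "into strictly monotone runs")
    runs = []
    i = 0
    while i < len(v):
        if i == len(v) - 1:
            runs.append((i, i + 1, "increasing"))
            break
        direction = "increasing" if v[i + 1] > v[i] else "decreasing"
        j = i + 1
        while j + 1 < len(v) and (
                (direction == "increasing" and v[j + 1] > v[j])
                or (direction == "decreasing" and v[j + 1] < v[j])):
            j += 1
        runs.append((i, j + 1, direction))
        i = j + 1
    return runs


def detect_cso(segment: ConservedSegment, table: AnchorTable,
               species: str) -> list[CSORun]:
    """CSO decomposition of one conserved segment.

    Maximal strictly monotone runs of ortholog coordinates of length >= 2
    are CSO (a decreasing run is an inverted but ordered segment); isolated
    members between runs belong to no CSO.
    """
    sp = table.for_species(species)
    pos_of = dict(zip(sp["marker"], sp["position"]))
    missing = [m for m in segment.markers if m not in pos_of]
    if missing:
        raise ValueError(f"segment markers lack coordinates: {missing[:3]}")
    values = [pos_of[m] for m in segment.markers]
    out = []
    for start, stop, direction in monotone_runs(values):
        if stop - start >= 2:
            out.append(CSORun(direction, segment.markers[start:stop]))
    return out


def summarize_chromosome(chromosome: str, map_order: list[str],
                         table: AnchorTable, species: str
                         ) -> SyntenySummary:
    """Full CS + CSO decomposition of one chromosome for one species."""
    segments, singletons = detect_cs(map_order, table, species)
    summary = SyntenySummary(chromosome, species, segments, singletons)
    for i, seg in enumerate(segments):
        summary.cso[i] = detect_cso(seg, table, species)
    return summary


def oxford_grid(summaries: list[SyntenySummary], species: str
                ) -> pd.DataFrame:
    """Marker-count grid: rows = map chromosomes, columns = model
    chromosomes; each cell holds ``cs_markers + singletons`` with separate
    columns per kind plus row/column margins."""
    rows = []
    for s in summaries:
        if s.species != species:
            continue
        for seg in s.segments:
            rows.append((s.chromosome, seg.model_chromosome, len(seg), 0))
        for marker, mc in s.singletons:
            rows.append((s.chromosome, mc, 0, 1))
    df = pd.DataFrame(rows, columns=["chromosome", "model_chromosome",
                                     "cs_markers", "singletons"])
    if df.empty:
        return pd.DataFrame()
    grid = df.groupby(["chromosome", "model_chromosome"],
                      as_index=False).sum()
    grid["total"] = grid["cs_markers"] + grid["singletons"]
    return grid


def summarize_cs_cso(summaries: list[SyntenySummary],
                     species: list[str]) -> pd.DataFrame:
    """Per-chromosome CS and CSO counts for each species.

    Chromosomes without anchors in a species are reported as 'un'
    (unknown), matching comparative-map summary-table convention.
    """
    chromosomes = sorted({s.chromosome for s in summaries})
    by_key = {(s.chromosome, s.species): s for s in summaries}
    rows = []
    for chrom in chromosomes:
        row: dict = {"chromosome": chrom}
        for sp in species:
            s = by_key.get((chrom, sp))
            if s is None or s.n_anchored == 0:
                row[f"{sp}_cs"] = "un"
                row[f"{sp}_cso"] = "un"
            else:
                row[f"{sp}_cs"] = len(s.segments)
                row[f"{sp}_cso"] = s.cso_count
        rows.append(row)
    return pd.DataFrame(rows)
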