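"""The centiray / centimorgan / kilobase calibration chain and map
summary statistics.

Marker pairs measured on both the RH map (cR) and the genetic map (cM)
give the cR/cM ratio; combined with an externally estimated kb/cM constant
this yields kb/cR, hence the physical size of the RH map and its coverage
of the genome. Reported ratios follow fixed rounding conventions (one
decimal for ratios, integer percent for coverage) so that report-level
comparisons are exact; the unrounded fields satisfy the chain identities
exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .errors import NoDataError
from .ordering import OrderedGroupMap

DEFAULT_KB_PER_CM = 840.0
DEFAULT_GENOME_SIZE_KB = 1_060_000.0


@dataclass(frozen=True)
class CalibrationSummary:
    """The cR-cM-kb calibration chain.

    ``cr_per_cm``, ``kb_per_cr`` etc. are exact; the ``reported_*`` fields
    apply the rounding conventions, with the physical map size computed
    from the 1-decimal kb/cR ratio (the convention under which the chain's
    printed numbers are self-consistent).
    """

    n_pairs: int
    sum_cr: float
    sum_cm: float
    kb_per_cm: float
    cr_per_cm: float
    kb_per_cr: float
    total_map_cr: float
    map_physical_size_kb: float
    genome_size_kb: float
    coverage_percent: float
    reported_cr_per_cm: float
    reported_kb_per_cr: float
    reported_map_size_kb: float
    reported_coverage_percent: int


@dataclass(frozen=True)
class MapStats:
    """Whole-map summary counts and densities."""

    n_genotyped: int
    n_mapped: int
    n_unlinked: int
    n_groups: int
    n_positions: int
    n_colocalized_positions: int
    total_cr: float
    marker_density_per_mb: float
    kb_per_marker: float
    mean_spacing_cr: float
    reported_kb_per_marker: int
    reported_mean_spacing_cr: int


def shared_pairs(maps: list[OrderedGroupMap], gmap: pd.DataFrame
                 ) -> pd.DataFrame:
    """Consecutive shared-marker pairs with both cR and cM distances.

    Within each RH group, markers also present on the genetic map are
    taken in map order; consecutive pairs lying on the same LG contribute
    (|delta cR|, |delta cM|). Pairs with zero cM separation are excluded
    (they carry no ratio information).
    """
    lg_of = dict(zip(gmap["marker"], gmap["lg"]))
    cm_of = dict(zip(gmap["marker"], gmap["cm"]))
    rows = []
    for ogm in maps:
        shared = [(m, float(c)) for m, c in zip(ogm.markers, ogm.coords)
                  if m in lg_of]
        for (ma, ca), (mb, cb) in zip(shared[:-1], shared[1:]):
            if lg_of[ma] != lg_of[mb]:
                continue
            d_cm = abs(cm_of[ma] - cm_of[mb])
            if d_cm == 0:
                continue
            rows.append((ogm.group_id, ma, mb, abs(cb - ca), d_cm))
    if not rows:
        warnings.warn("no shared marker pairs between RH and genetic maps")
    return pd.DataFrame(rows, columns=["group", "marker_a", "marker_b",
                                       "d_cr", "d_cm"])


def calibrate(pairs: pd.DataFrame, total_map_cr: float,
              kb_per_cm: float = DEFAULT_KB_PER_CM,
              genome_size_kb: float = DEFAULT_GENOME_SIZE_KB
              ) -> CalibrationSummary:
    """Run the calibration chain from a shared-pair table.

    cR/cM is the ratio of summed cR to summed cM distances (pooled, not a
    mean of ratios); kb/cR = kb/cM divided by cR/cM; the physical map size
    is the total map length times kb/cR; coverage is the physical size as
    a percentage of the genome size.
    """
    sum_cr = float(pairs["d_cr"].sum())
    sum_cm = float(pairs["d_cm"].sum())
    if sum_cm <= 0:
        raise NoDataError("total cM separation is zero; cannot calibrate")
    if genome_size_kb <= 0:
        raise ValueError("genome_size_kb must be positive")
    cr_per_cm = sum_cr / sum_cm
    kb_per_cr = kb_per_cm / cr_per_cm
    size = total_map_cr * kb_per_cr
    coverage = 100.0 * size / genome_size_kb
    rep_ratio = round(cr_per_cm, 1)
    rep_kb_per_cr = round(kb_per_cm / rep_ratio, 1)
    rep_size = total_map_cr * rep_kb_per_cr
    rep_cov = int(round(100.0 * rep_size / genome_size_kb))
    return CalibrationSummary(
        n_pairs=len(pairs), sum_cr=sum_cr, sum_cm=sum_cm,
        kb_per_cm=kb_per_cm, cr_per_cm=cr_per_cm, kb_per_cr=kb_per_cr,
        total_map_cr=total_map_cr, map_physical_size_kb=size,
        genome_size_kb=genome_size_kb, coverage_percent=coverage,
        reported_cr_per_cm=rep_ratio, reported_kb_per_cr=rep_kb_per_cr,
        reported_map_size_kb=rep_size,
        reported_coverage_percent=rep_cov)


def calibrate_from_sums(n_pairs: int, sum_cr: float, sum_cm: float,
                        total_map_cr: float,
                        kb_per_cm: float = DEFAULT_KB_PER_CM,
                        genome_size_kb: float = DEFAULT_GENOME_SIZE_KB
                        ) -> CalibrationSummary:
    """Calibration chain from pre-summed pair distances."""
    pairs = pd.DataFrame({"d_cr": [sum_cr], "d_cm": [sum_cm]})
    summary = calibrate(pairs, total_map_cr, kb_per_cm, genome_size_kb)
    return CalibrationSummary(**{**summary.__dict__, "n_pairs": n_pairs})


def map_stats_from_counts(n_genotyped: int, n_mapped: int, n_groups: int,
                          n_positions: int, total_cr: float,
                          genome_size_kb: float = DEFAULT_GENOME_SIZE_KB,
                          n_colocalized_positions: int = 0) -> MapStats:
    """Map statistics from already-tabulated counts (no map objects)."""
    density = n_genotyped / (genome_size_kb / 1000.0)
    kb_per_marker = genome_size_kb / n_genotyped
    spacing = total_cr / n_positions if n_positions else float("nan")
    return MapStats(
        n_genotyped=n_genotyped, n_mapped=n_mapped,
        n_unlinked=n_genotyped - n_mapped, n_groups=n_groups,
        n_positions=n_positions,
        n_colocalized_positions=n_colocalized_positions,
        total_cr=total_cr, marker_density_per_mb=density,
        kb_per_marker=kb_per_marker, mean_spacing_cr=spacing,
        reported_kb_per_marker=int(kb_per_marker),
        reported_mean_spacing_cr=int(round(spacing)))


def map_stats(maps: list[OrderedGroupMap], n_genotyped: int,
              genome_size_kb: float = DEFAULT_GENOME_SIZE_KB) -> MapStats:
    """Whole-map marker counts, density and spacing.

    Marker density and kb-per-marker use the genotyped total (density of
    typed markers over the genome); the mean inter-marker spacing is total
    map cR over the number of map positions. Reported kb-per-marker is
    truncated to the kilobase, the spacing rounded to the centiray.
    """
    if not maps:
        raise NoDataError("no ordered group maps")
    n_mapped = sum(len(o.markers) for o in maps)
    positions = sum(len(o.positions) if o.positions else len(o.markers)
                    for o in maps)
    n_coloc = sum(1 for o in maps for _, ms in (o.positions or [])
                  if len(ms) > 1)
    total_cr = sum(o.length_cr for o in maps)
    density = n_genotyped / (genome_size_kb / 1000.0)
    kb_per_marker = genome_size_kb / n_genotyped
    spacing = total_cr / positions if positions else float("nan")
    return MapStats(
        n_genotyped=n_genotyped, n_mapped=n_mapped,
        n_unlinked=n_genotyped - n_mapped, n_groups=len(maps),
        n_positions=positions, n_colocalized_positions=n_coloc,
        total_cr=total_cr, marker_density_per_mb=density,
        kb_per_marker=kb_per_marker, mean_spacing_cr=spacing,
        reported_kb_per_marker=int(kb_per_marker),
        reported_mean_spacing_cr=int(round(spacing)))
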