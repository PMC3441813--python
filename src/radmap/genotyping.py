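"""Intensity scoring, retention statistics and panel clone selection.

Bead-array RH genotyping yields one fluorescence pair (x, y) per
(marker, clone). Because the donor line is clonal and homozygous, a single
allele-specific probe is used and only one axis carries signal for a given
marker: clones above a threshold on that axis are scored present, below it
absent, and calls inside an explicit ambiguity band around the threshold
are scored ambiguous ('2').
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import NoDataError
from .matrix import ABSENT, AMBIGUOUS, PRESENT, RHCallMatrix

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.30


@dataclass(frozen=True)
class CloneStats:
    """Retention summary for one hybrid clone."""

    clone: str
    retention: float
    n_informative: int


def score_intensities(records: pd.DataFrame,
                      threshold: float = DEFAULT_THRESHOLD,
                      ambiguous_halfwidth: float = 0.05,
                      axis: str | dict[str, str] = "y",
                      overrides: dict[str, float] | None = None,
                      ) -> RHCallMatrix:
    """Threshold-score an intensity table into a call matrix.

    Parameters
    ----------
    records : long table with columns marker, clone, x, y (one row per pair).
    threshold : default scoring threshold on the chosen axis.
    ambiguous_halfwidth : half-width of the ambiguity band; values within
        ``threshold +/- halfwidth`` (inclusive) are scored '2'.
    axis : 'x' or 'y' for all markers, or a per-marker mapping. A table with
        an ``axis`` column overrides this argument.
    overrides : optional per-marker threshold overrides, e.g. lowered to
        0.20 when the dot cloud sits low on the axis.

    Missing (marker, clone) pairs are scored ambiguous with a warning.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    overrides = overrides or {}
    markers = list(dict.fromkeys(records["marker"]))
    clones = list(dict.fromkeys(records["clone"]))
    mi = {m: j for j, m in enumerate(markers)}
    ci = {c: i for i, c in enumerate(clones)}

    if "axis" in records.columns:
        axis_of = dict(zip(records["marker"], records["axis"]))
    elif isinstance(axis, dict):
        axis_of = axis
    else:
        axis_of = {m: axis for m in markers}

    calls = np.full((len(clones), len(markers)), AMBIGUOUS, dtype=np.int8)
    seen = np.zeros_like(calls, dtype=bool)
    for row in records.itertuples(index=False):
        t = overrides.get(row.marker, threshold)
        value = getattr(row, axis_of.get(row.marker, "y"))
        if value > t + ambiguous_halfwidth:
            call = PRESENT
        elif value < t - ambiguous_halfwidth:
            call = ABSENT
        else:
            call = AMBIGUOUS
        i, j = ci[row.clone], mi[row.marker]
        calls[i, j] = call
        seen[i, j] = True
    n_missing = int((~seen).sum())
    if n_missing:
        logger.warning("%d (marker, clone) pairs missing from the intensity "
                       "table; scored ambiguous", n_missing)
    return RHCallMatrix(clones, markers, calls)


def separation_diagnostic(records: pd.DataFrame,
                          axis: str | dict[str, str] = "y",
                          min_gap: float = 0.15) -> pd.DataFrame:
    """Flag markers whose intensities do not split into two clusters.

    For each marker the chosen-axis values are split at their midrange into
    a low and a high group; the gap between the groups' means is compared
    with ``min_gap``. Markers below the gap are candidates for removal
    (typing profiles without clear present/absent clouds), mirroring the
    manual rejection of badly separating markers. This is a diagnostic:
    nothing is removed automatically.
    """
    if "axis" in records.columns:
        axis_of = dict(zip(records["marker"], records["axis"]))
    elif isinstance(axis, dict):
        axis_of = axis
    else:
        axis_of = None
    rows = []
    for marker, grp in records.groupby("marker", sort=False):
        a = axis_of[marker] if axis_of else axis
        v = grp[a].to_numpy(dtype=float)
        mid = (v.min() + v.max()) / 2.0
        lo, hi = v[v <= mid], v[v > mid]
        gap = float(hi.mean() - lo.mean()) if len(lo) and len(hi) else 0.0
        rows.append((marker, gap, gap < min_gap))
    return pd.DataFrame(rows, columns=["marker", "gap", "flagged"])


def retention_frequency(matrix: RHCallMatrix, clone: str) -> CloneStats:
    """Fraction of informative markers called present in one clone.

    Ambiguous calls are excluded from both numerator and denominator.
    """
    i = matrix.clones.index(clone)
    row = matrix.calls[i, :]
    n_present = int((row == PRESENT).sum())
    n_absent = int((row == ABSENT).sum())
    n_inf = n_present + n_absent
    if n_inf == 0:
        raise NoDataError(f"clone {clone}: all calls ambiguous, retention "
                          "undefined")
    return CloneStats(clone, n_present / n_inf, n_inf)


def panel_retention(matrix: RHCallMatrix) -> list[CloneStats]:
    """Retention statistics for every clone in the panel."""
    return [retention_frequency(matrix, c) for c in matrix.clones]


def select_clones(stats: list[CloneStats], matrix: RHCallMatrix,
                  min_retention: float = 0.05,
                  max_retention: float = 0.40) -> list[str]:
    """Select panel clones by retention band plus genome-representation
    rescue.

    Clones with retention inside ``[min_retention, max_retention]`` are
    kept; an excluded clone is then rescued if it is the sole carrier of
    any marker (dropping it would lose that marker entirely). Output order
    follows the input clone order, so selection is deterministic.
    """
    by_clone = {s.clone: s for s in stats}
    missing = [c for c in matrix.clones if c not in by_clone]
    if missing:
        raise ValueError(f"stats missing for clones: {missing[:5]}")
    keep = {s.clone for s in stats
            if min_retention <= s.retention <= max_retention}
    # rescue: markers whose only present call sits in an excluded clone
    present = matrix.calls == PRESENT
    carriers_per_marker = present.sum(axis=0)
    for j in np.nonzero(carriers_per_marker == 1)[0]:
        i = int(np.nonzero(present[:, j])[0][0])
        clone = matrix.clones[i]
        if clone not in keep:
            logger.info("rescuing clone %s: sole carrier of marker %s",
                        clone, matrix.markers[j])
            keep.add(clone)
    selected = [c for c in matrix.clones if c in keep]
    if not selected:
        raise NoDataError("no clone passed selection; widen the retention "
                          "band [min_retention, max_retention]")
    return selected
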