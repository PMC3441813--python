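"""Helpers for scoring pipeline output against simulator ground truth.

Markers with identical informative call vectors are indistinguishable to
an RH panel (their breakage fraction is exactly zero), so order recovery
is judged on distinguishable marker pairs only, and a map is correct if
every such pair keeps its true relative order, possibly with the whole
group reversed.
"""

from __future__ import annotations

import numpy as np

from .matrix import AMBIGUOUS, RHCallMatrix


def _distinguishable(matrix: RHCallMatrix, a: str, b: str) -> bool:
    va, vb = matrix.vector(a), matrix.vector(b)
    inf = (va != AMBIGUOUS) & (vb != AMBIGUOUS)
    return bool(np.any(va[inf] != vb[inf]))


def order_matches_truth(found: list[str], truth: list[str],
                        matrix: RHCallMatrix) -> bool:
    """True when ``found`` equals the true order up to whole reversal and
    permutations of mutually indistinguishable markers."""
    if set(found) != set(truth):
        return False
    pos = {m: i for i, m in enumerate(found)}
    tpos = {m: i for i, m in enumerate(truth)}
    signs = set()
    for i, a in enumerate(truth):
        for b in truth[i + 1:]:
            if not _distinguishable(matrix, a, b):
                continue
            signs.add(np.sign((pos[a] - pos[b]) * (tpos[a] - tpos[b])))
            if len(signs) > 1:
                return False
    # all distinguishable pairs agree (sign +1) or all are reversed (-1)
    return len(signs) <= 1


def partition_errors(groups: list[list[str]],
                     truth: dict[str, list[str]]) -> tuple[int, int]:
    """(splits, merges) of a recovered grouping against true chromosomes.

    A *merge* is a recovered group containing markers from more than one
    true chromosome; a *split* is a true chromosome scattered over more
    than one recovered group.
    """
    chrom_of = {m: c for c, ms in truth.items() for m in ms}
    merges = 0
    hit_groups: dict[str, set[int]] = {c: set() for c in truth}
    for gi, g in enumerate(groups):
        chroms = {chrom_of[m] for m in g if m in chrom_of}
        if len(chroms) > 1:
            merges += 1
        for c in chroms:
            hit_groups[c].add(gi)
    splits = sum(1 for c, gs in hit_groups.items() if len(gs) > 1)
    return splits, merges
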