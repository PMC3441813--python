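"""Anchoring RH groups to the genetic linkage map and assembling
chromosomes.

Microsatellites shared by name between an RH group and a linkage group (LG)
anchor the group to a chromosome. A group whose anchors fall on two LGs is
evidence that the two LGs are a single chromosome (the classic merged-LG
signal); groups without anchors remain orphans. Within a chromosome, groups
are ordered by the mean genetic position of their anchors and oriented by
the rank correlation between their internal order and the genetic order,
falling back to end-marker two-point LOD with the neighbouring group. FISH
constraints, when available, are authoritative: they override statistical
ordering and any contradiction is reported rather than silently resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import kendalltau

from .linkage import TwoPointEstimate
from .ordering import OrderedGroupMap


@dataclass(frozen=True)
class FISHConstraint:
    """A BAC probe located on a physical chromosome by in situ
    hybridization; rank counts outward from the centromere along an arm."""

    bac_marker: str
    chromosome: str
    arm: str = "unknown"            # long | short | unknown
    rank: int = 1

    def __post_init__(self):
        if self.rank < 1:
            raise ValueError("FISH rank must be >= 1")
        if self.arm not in ("long", "short", "unknown"):
            raise ValueError(f"invalid arm {self.arm!r}")


@dataclass
class GroupAssignment:
    group_id: str
    lg: str | None                  # None -> orphan
    anchors: dict[str, list[str]]   # lg -> shared microsatellite ids
    conflict: bool = False


@dataclass
class OrientedGroup:
    group_id: str
    flipped: bool
    oriented: bool
    evidence: str                   # anchors | end_lod | fish | none


@dataclass
class ChromosomeAssembly:
    chromosome: str
    lgs: list[str]
    groups: list[OrientedGroup]
    conflicts: list[str] = field(default_factory=list)


def _validate_gmap(gmap: pd.DataFrame) -> pd.DataFrame:
    required = {"lg", "marker", "cm"}
    if not required.issubset(gmap.columns):
        raise ValueError(f"genetic map needs columns {sorted(required)}")
    if (gmap["cm"] < 0).any():
        raise ValueError("cM positions must be non-negative")
    if gmap.duplicated(["lg", "marker"]).any():
        raise ValueError("duplicate (lg, marker) entries in genetic map")
    return gmap


def anchor_groups(maps: list[OrderedGroupMap], gmap: pd.DataFrame
                  ) -> list[GroupAssignment]:
    """Assign each RH group to the LG holding the majority of its shared
    markers.

    Ties are broken toward the LG whose anchors span the smaller cM range
    (conservative: the tighter cluster), then lexicographically. Groups
    with anchors on more than one LG are flagged as conflicts (input to
    merge detection); groups with no anchors are orphans.
    """
    _validate_gmap(gmap)
    lg_of = dict(zip(gmap["marker"], gmap["lg"]))
    cm_of = dict(zip(gmap["marker"], gmap["cm"]))
    out = []
    for ogm in maps:
        anchors: dict[str, list[str]] = {}
        for m in ogm.markers:
            if m in lg_of:
                anchors.setdefault(lg_of[m], []).append(m)
        if not anchors:
            out.append(GroupAssignment(ogm.group_id, None, {}))
            continue

        def rank(lg: str):
            cms = [cm_of[m] for m in anchors[lg]]
            span = max(cms) - min(cms)
            return (-len(anchors[lg]), span, lg)

        best = min(anchors, key=rank)
        out.append(GroupAssignment(ogm.group_id, best, anchors,
                                   conflict=len(anchors) > 1))
    return out


def detect_lg_merges(assignments: list[GroupAssignment],
                     min_anchors_per_lg: int = 2) -> list[set[str]]:
    """LG sets that behave as single chromosomes.

    Two LGs merge when one RH group carries at least ``min_anchors_per_lg``
    shared markers from each (a single shared marker could be a genotyping
    artefact); merging is closed transitively.
    """
    g = nx.Graph()
    for a in assignments:
        lgs = [lg for lg, ms in a.anchors.items()
               if len(ms) >= min_anchors_per_lg]
        for i in range(len(lgs)):
            for j in range(i + 1, len(lgs)):
                g.add_edge(lgs[i], lgs[j], group=a.group_id)
    return [set(c) for c in nx.connected_components(g)]


def chromosome_partition(assignments: list[GroupAssignment],
                         merges: list[set[str]]
                         ) -> tuple[dict[str, list[str]], list[str]]:
    """Chromosome name -> RH group ids, plus the orphan group list.

    Chromosomes are named after their LGs; merged sets join their LG names
    with '-'. Assignment plus orphans partition the input groups.
    """
    merged_name = {}
    for s in merges:
        name = "-".join(sorted(s))
        for lg in s:
            merged_name[lg] = name
    chromosomes: dict[str, list[str]] = {}
    orphans: list[str] = []
    for a in assignments:
        if a.lg is None:
            orphans.append(a.group_id)
        else:
            chrom = merged_name.get(a.lg, a.lg)
            chromosomes.setdefault(chrom, []).append(a.group_id)
    return chromosomes, orphans


def _orientation_by_anchors(ogm: OrderedGroupMap, cm_of: dict[str, float]
                            ) -> tuple[bool | None, str]:
    shared = [m for m in ogm.markers if m in cm_of]
    if len(shared) < 2:
        return None, "none"
    internal = [ogm.markers.index(m) for m in shared]
    cms = [cm_of[m] for m in shared]
    tau, _ = kendalltau(internal, cms)
    if not np.isfinite(tau) or tau == 0:
        return None, "none"
    return bool(tau < 0), "anchors"


def _end_lod(two_point: dict[tuple[str, str], float], a: str, b: str
             ) -> float:
    return max(two_point.get((a, b), -np.inf),
               two_point.get((b, a), -np.inf))


def assemble_chromosome(chromosome: str, lgs: list[str],
                        maps: list[OrderedGroupMap], gmap: pd.DataFrame,
                        two_point: list[TwoPointEstimate] | None = None,
                        constraints: list[FISHConstraint] | None = None
                        ) -> ChromosomeAssembly:
    """Order and orient the RH groups of one chromosome.

    Groups are ordered by the mean cM of their anchors; orientation comes
    from the anchor rank correlation, else from the strongest end-marker
    two-point LOD to the neighbouring group, else the group is flagged
    unoriented. FISH constraints override both order and orientation;
    contradictions between FISH and anchors are reported in
    ``assembly.conflicts``.
    """
    _validate_gmap(gmap)
    sub = gmap[gmap["lg"].isin(lgs)]
    cm_of = dict(zip(sub["marker"], sub["cm"]))
    tp = {}
    for est in (two_point or []):
        tp[(est.marker_a, est.marker_b)] = est.lod

    def mean_cm(ogm: OrderedGroupMap) -> float:
        cms = [cm_of[m] for m in ogm.markers if m in cm_of]
        return float(np.mean(cms)) if cms else np.inf

    ordered = sorted(maps, key=lambda o: (mean_cm(o), o.group_id))
    conflicts: list[str] = []

    # FISH: rank of the first constrained BAC in each group drives order
    fish_rank: dict[str, int] = {}
    for c in (constraints or []):
        if c.chromosome != chromosome:
            continue
        for ogm in ordered:
            if c.bac_marker in ogm.markers:
                prev = fish_rank.get(ogm.group_id)
                if prev is not None and prev != c.rank:
                    conflicts.append(
                        f"FISH ranks {prev} and {c.rank} both hit group "
                        f"{ogm.group_id}")
                fish_rank[ogm.group_id] = c.rank
    if fish_rank:
        stat_order = [o.group_id for o in ordered]
        ordered = sorted(
            ordered, key=lambda o: (fish_rank.get(o.group_id, np.inf),
                                    mean_cm(o), o.group_id))
        if [o.group_id for o in ordered] != stat_order:
            conflicts.append(
                "FISH order overrides anchor-based order: "
                f"{stat_order} -> {[o.group_id for o in ordered]}")

    oriented_groups: list[OrientedGroup] = []
    for idx, ogm in enumerate(ordered):
        flip, evidence = _orientation_by_anchors(ogm, cm_of)
        if flip is None and tp:
            # orient so the end with the stronger linkage faces the
            # neighbouring group
            first, last = ogm.markers[0], ogm.markers[-1]
            score_fwd = score_rev = 0.0
            n_edges = 0
            if idx > 0:
                prev_end = ordered[idx - 1].markers[-1]
                f, l = _end_lod(tp, first, prev_end), _end_lod(tp, last,
                                                               prev_end)
                if np.isfinite(f) or np.isfinite(l):
                    score_fwd += max(f, -1e9)
                    score_rev += max(l, -1e9)
                    n_edges += 1
            if idx < len(ordered) - 1:
                nxt = ordered[idx + 1].markers[0]
                f, l = _end_lod(tp, last, nxt), _end_lod(tp, first, nxt)
                if np.isfinite(f) or np.isfinite(l):
                    score_fwd += max(f, -1e9)
                    score_rev += max(l, -1e9)
                    n_edges += 1
            if n_edges and score_fwd != score_rev:
                flip, evidence = score_rev > score_fwd, "end_lod"
        if flip is None:
            oriented_groups.append(OrientedGroup(ogm.group_id, False,
                                                 False, "none"))
        else:
            oriented_groups.append(OrientedGroup(ogm.group_id, flip, True,
                                                 evidence))
    return ChromosomeAssembly(chromosome, list(lgs), oriented_groups,
                              conflicts)


def compare_orders(rh_order: list[str], gmap: pd.DataFrame, lgs: list[str]
                   ) -> dict:
    """Discordance between the RH and genetic marker orders.

    ``rh_order`` is the chromosome-wide RH marker order (groups
    concatenated with their flips applied). Returns the longest common
    subsequence length between the shared-marker orders and the adjacent
    genetic pairs that appear locally inverted on the RH map.
    """
    _validate_gmap(gmap)
    sub = gmap[gmap["lg"].isin(lgs)].sort_values("cm", kind="stable")
    genetic = [m for m in sub["marker"] if m in set(rh_order)]
    rh = [m for m in rh_order if m in set(genetic)]
    if len(genetic) < 2:
        return {"n_shared": len(genetic), "lcs": len(genetic),
                "inversions": []}
    lcs = _lcs_length(rh, genetic)
    rh_pos = {m: i for i, m in enumerate(rh)}
    inversions = [(a, b) for a, b in zip(genetic[:-1], genetic[1:])
                  if rh_pos[a] > rh_pos[b]]
    return {"n_shared": len(genetic), "lcs": lcs, "inversions": inversions}


def _lcs_length(a: list[str], b: list[str]) -> int:
    """Dynamic-programming longest common subsequence length."""
    n, m = len(a), len(b)
    dp = np.zeros((n + 1, m + 1), dtype=int)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if a[i - 1] == b[j - 1]:
                dp[i, j] = dp[i - 1, j - 1] + 1
            else:
                dp[i, j] = max(dp[i - 1, j], dp[i, j - 1])
    return int(dp[n, m])
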