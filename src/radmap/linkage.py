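"""Two-point breakage/retention estimation and RH group formation.

The model is the haploid equal-retention RH model: between two markers a
radiation break falls with probability ``theta``; fragments are retained
independently with probability ``r``. The joint call probabilities are::

    P(1,1) = r(1-theta) + r^2 theta
    P(1,0) = P(0,1) = r theta (1-r)
    P(0,0) = (1-theta)(1-r) + theta (1-r)^2

The LOD score compares this linked model at its MLE against an unlinked
model in which each marker keeps its own empirical retention, which guards
against spurious linkage driven by retention differences. Distances are
``d(cR) = -100 ln(1 - theta)``, the centiray transform at the panel's dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.optimize import minimize

from .errors import NoDataError, UninformativeMarkerError
from .matrix import ABSENT, PRESENT, RHCallMatrix

LN10 = math.log(10.0)
THETA_CAP = 1.0 - 1e-6
DEFAULT_MAX_DISTANCE_CR = 300.0
DEFAULT_MIN_INFORMATIVE = 25


@dataclass(frozen=True)
class TwoPointEstimate:
    """Maximum-likelihood two-point summary for a marker pair."""

    marker_a: str
    marker_b: str
    theta: float
    retention: float
    lod: float
    n_informative: int
    distance_cr: float


@dataclass
class RHGroup:
    """A connected set of markers at a two-point LOD threshold."""

    group_id: str
    markers: list[str]
    lod_threshold: float
    flags: list[str] = None

    def __post_init__(self):
        if self.flags is None:
            self.flags = []

    def __len__(self) -> int:
        return len(self.markers)


def pair_counts(vec_a: np.ndarray, vec_b: np.ndarray
                ) -> tuple[int, int, int, int]:
    """Counts (n11, n10, n01, n00) over clones informative at both markers.

    Ambiguous calls drop the clone for this pair only (pairwise deletion).
    """
    inf = (vec_a != 2) & (vec_b != 2)
    a = vec_a[inf] == PRESENT
    b = vec_b[inf] == PRESENT
    n11 = int(np.sum(a & b))
    n10 = int(np.sum(a & ~b))
    n01 = int(np.sum(~a & b))
    n00 = int(np.sum(~a & ~b))
    return n11, n10, n01, n00


def _loglik(theta: float, r: float, n11: int, nd: int, n00: int) -> float:
    """Multinomial log-likelihood; ``nd = n10 + n01`` (discordant)."""
    p11 = r * (1.0 - theta * (1.0 - r))
    p10 = r * theta * (1.0 - r)
    p00 = (1.0 - r) * (1.0 - theta * r)
    ll = 0.0
    for n, p in ((n11, p11), (nd, p10), (n00, p00)):
        if n:
            if p <= 0.0:
                return -np.inf
            ll += n * math.log(p)
    return ll


def _negloglik_grad(x, n11, nd, n00):
    theta, r = x
    p11 = r * (1.0 - theta * (1.0 - r))
    p10 = r * theta * (1.0 - r)
    p00 = (1.0 - r) * (1.0 - theta * r)
    eps = 1e-300
    ll = 0.0
    g_t = 0.0
    g_r = 0.0
    for n, p, dpdt, dpdr in (
            (n11, p11, -r * (1.0 - r), 1.0 - theta + 2.0 * r * theta),
            (nd, p10, r * (1.0 - r), theta * (1.0 - 2.0 * r)),
            (n00, p00, -r * (1.0 - r), -1.0 - theta + 2.0 * theta * r)):
        if n:
            p = max(p, eps)
            ll += n * math.log(p)
            g_t += n * dpdt / p
            g_r += n * dpdr / p
    return -ll, (-g_t, -g_r)


def _fit_linked(n11: int, nd: int, n00: int) -> tuple[float, float, float]:
    """Maximize the linked-model likelihood; returns (theta, r, loglik)."""
    N = n11 + nd + n00
    if nd == 0:
        # no discordant clones: theta-hat is exactly 0 and r-hat closes
        r = min(max(n11 / N, 1e-9), 1.0 - 1e-9)
        return 0.0, r, _loglik(0.0, r, n11, nd, n00)
    r0 = (2 * n11 + nd) / (2 * N)
    r0 = min(max(r0, 1e-6), 1.0 - 1e-6)
    t0 = min(1.0, nd / (2 * N * r0 * (1.0 - r0)))
    bounds = [(1e-9, 1.0), (1e-9, 1.0 - 1e-9)]
    best = None
    for start in ((t0, r0), (0.9, r0), (0.5, 0.5)):
        res = minimize(_negloglik_grad, x0=np.clip(start, 1e-6, 1 - 1e-6),
                       args=(n11, nd, n00), jac=True, method="L-BFGS-B",
                       bounds=bounds,
                       options={"ftol": 1e-14, "gtol": 1e-10,
                                "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    theta, r = float(best.x[0]), float(best.x[1])
    ll = -float(best.fun)
    # the theta = 1 boundary has a closed form (independent retention per
    # marker side): r-hat is the present-allele margin; L-BFGS-B can stop
    # marginally short of the boundary, so evaluate it exactly
    r_b = min(max((2 * n11 + nd) / (2 * N), 1e-9), 1.0 - 1e-9)
    ll_b = _loglik(1.0, r_b, n11, nd, n00)
    if ll_b > ll:
        theta, r, ll = 1.0, r_b, ll_b
    return theta, r, ll


def _loglik_unlinked(n11: int, n10: int, n01: int, n00: int) -> float:
    """Independence model with marker-specific retentions."""
    N = n11 + n10 + n01 + n00
    ra = (n11 + n10) / N
    rb = (n11 + n01) / N
    ll = 0.0
    for n, p in ((n11, ra * rb), (n10, ra * (1 - rb)),
                 (n01, (1 - ra) * rb), (n00, (1 - ra) * (1 - rb))):
        if n:
            ll += n * math.log(p)
    return ll


def theta_to_cr(theta: float,
                max_distance_cr: float = DEFAULT_MAX_DISTANCE_CR) -> float:
    """Centiray transform ``-100 ln(1-theta)``, capped for theta -> 1."""
    theta = min(theta, THETA_CAP)
    return min(-100.0 * math.log1p(-theta), max_distance_cr)


def estimate_from_counts(marker_a: str, marker_b: str, n11: int, n10: int,
                         n01: int, n00: int,
                         max_distance_cr: float = DEFAULT_MAX_DISTANCE_CR
                         ) -> TwoPointEstimate:
    """Two-point MLE from a 2x2 count table."""
    N = n11 + n10 + n01 + n00
    if N == 0:
        raise NoDataError(f"{marker_a}/{marker_b}: no clone informative at "
                          "both markers")
    if n11 + n10 in (0, N) or n11 + n01 in (0, N):
        raise UninformativeMarkerError(
            f"{marker_a}/{marker_b}: a vector is constant over the "
            "informative clones")
    theta, r, ll = _fit_linked(n11, n10 + n01, n00)
    lod = (ll - _loglik_unlinked(n11, n10, n01, n00)) / LN10
    theta = min(theta, THETA_CAP)
    return TwoPointEstimate(marker_a, marker_b, theta, r, lod, N,
                            theta_to_cr(theta, max_distance_cr))


def estimate_two_point(vec_a: np.ndarray, vec_b: np.ndarray,
                       marker_a: str = "A", marker_b: str = "B",
                       max_distance_cr: float = DEFAULT_MAX_DISTANCE_CR
                       ) -> TwoPointEstimate:
    """Two-point MLE for a pair of per-clone call vectors."""
    n11, n10, n01, n00 = pair_counts(np.asarray(vec_a), np.asarray(vec_b))
    return estimate_from_counts(marker_a, marker_b, n11, n10, n01, n00,
                                max_distance_cr)


def all_pairs(matrix: RHCallMatrix,
              min_informative: int = DEFAULT_MIN_INFORMATIVE,
              max_distance_cr: float = DEFAULT_MAX_DISTANCE_CR
              ) -> tuple[list[TwoPointEstimate], list[tuple[str, str, str]]]:
    """Two-point estimates for every unordered marker pair.

    Returns (estimates, flagged) where ``flagged`` lists pairs excluded
    from grouping as (marker_a, marker_b, reason): too few informative
    clones or an uninformative (constant) vector.
    """
    if matrix.n_markers < 2:
        raise ValueError("need at least two markers")
    estimates: list[TwoPointEstimate] = []
    flagged: list[tuple[str, str, str]] = []
    calls = matrix.calls
    informative = calls != 2
    present = (calls == PRESENT).astype(np.int32)
    absent = (calls == ABSENT).astype(np.int32)
    # vectorized pairwise counts
    n11 = present.T @ present
    n10 = present.T @ absent
    n01 = absent.T @ present
    n00 = absent.T @ absent
    for a in range(matrix.n_markers):
        for b in range(a + 1, matrix.n_markers):
            ma, mb = matrix.markers[a], matrix.markers[b]
            N = n11[a, b] + n10[a, b] + n01[a, b] + n00[a, b]
            if N < min_informative:
                flagged.append((ma, mb, "too_few_informative"))
                continue
            try:
                est = estimate_from_counts(
                    ma, mb, int(n11[a, b]), int(n10[a, b]), int(n01[a, b]),
                    int(n00[a, b]), max_distance_cr)
            except UninformativeMarkerError:
                flagged.append((ma, mb, "constant_vector"))
                continue
            estimates.append(est)
    del informative
    return estimates, flagged


def build_groups(estimates: list[TwoPointEstimate], markers: list[str],
                 lod_threshold: float = 4.0
                 ) -> tuple[list[RHGroup], list[str]]:
    """Single-linkage RH groups at a LOD threshold.

    Markers are nodes; pairs with ``lod >= lod_threshold`` are edges;
    connected components of size >= 2 become groups (ordered by input
    marker order of their first member) and singletons are unlinked.
    """
    g = nx.Graph()
    g.add_nodes_from(markers)
    for est in estimates:
        if est.lod >= lod_threshold:
            g.add_edge(est.marker_a, est.marker_b)
    order = {m: i for i, m in enumerate(markers)}
    groups: list[RHGroup] = []
    unlinked: list[str] = []
    comps = sorted((sorted(c, key=order.get) for c in
                    nx.connected_components(g)),
                   key=lambda c: order[c[0]])
    k = 0
    for comp in comps:
        if len(comp) == 1:
            unlinked.append(comp[0])
        else:
            k += 1
            groups.append(RHGroup(f"RH{k:02d}", comp, lod_threshold))
    return groups, unlinked


def group_and_refine(matrix: RHCallMatrix,
                     estimates: list[TwoPointEstimate],
                     markers: list[str] | None = None,
                     lod_threshold: float = 4.0,
                     lod_schedule: tuple[float, ...] = (4.5, 5.0, 5.5, 6.0,
                                                        6.5, 7.0),
                     theta_ceiling: float = 0.8, seed: int = 0
                     ) -> tuple[list[RHGroup], list[str], list[dict]]:
    """Grouping at a base LOD threshold followed by stepwise refinement.

    Groups whose best order shows an adjacent breakage fraction above
    ``theta_ceiling`` (a spurious bridge between unlinked segments) are
    re-analysed at increasing LOD thresholds up to the end of the
    schedule. Returns (groups, unlinked markers, split history).
    """
    markers = list(markers) if markers is not None else list(matrix.markers)
    groups, unlinked = build_groups(estimates, markers, lod_threshold)
    refined: list[RHGroup] = []
    history: list[dict] = []
    test = lambda grp: default_aberration_test(  # noqa: E731
        grp, matrix, theta_ceiling=theta_ceiling, seed=seed)
    for group in groups:
        gs, us, hist = refine_group(group, estimates, matrix,
                                    lod_schedule=lod_schedule,
                                    aberration_test=test, seed=seed)
        refined.extend(gs)
        unlinked.extend(us)
        history.extend(hist)
    return refined, unlinked, history


def default_aberration_test(group: RHGroup, matrix: RHCallMatrix,
                            theta_ceiling: float = 0.8, seed: int = 0
                            ) -> bool:
    """True when the group's best order contains an adjacent breakage
    fraction above ``theta_ceiling`` — the stand-in for an 'obvious
    aberration' (a bridge between segments that should not be linked)."""
    from .ordering import search_order  # local import; circular otherwise
    # a diagnostic order: one restart is enough to expose a bridge edge
    ogm = search_order(group.markers, matrix, group_id=group.group_id,
                       seed=seed, n_restarts=1)
    return bool(ogm.thetas.size and float(ogm.thetas.max()) > theta_ceiling)


def refine_group(group: RHGroup, estimates: list[TwoPointEstimate],
                 matrix: RHCallMatrix,
                 lod_schedule: tuple[float, ...] = (4.5, 5.0, 5.5, 6.0,
                                                   6.5, 7.0),
                 aberration_test=None, seed: int = 0
                 ) -> tuple[list[RHGroup], list[str], list[dict]]:
    """Re-analyse an aberrant group at stepwise-higher LOD thresholds.

    If the aberration test fires, connected components are recomputed over
    the group's members at the next threshold in the schedule, recursively,
    until every resulting group is clean or the schedule is exhausted (then
    the group is returned flagged ``persistent-aberration``). Returns
    (groups, newly unlinked markers, split history records).
    """
    if aberration_test is None:
        aberration_test = lambda grp: default_aberration_test(  # noqa: E731
            grp, matrix, seed=seed)
    member_set = set(group.markers)
    pair_lod = {}
    for est in estimates:
        if est.marker_a in member_set and est.marker_b in member_set:
            pair_lod[(est.marker_a, est.marker_b)] = est.lod

    history: list[dict] = []

    def _refine(grp: RHGroup, schedule) -> tuple[list[RHGroup], list[str]]:
        if len(grp) < 2 or not aberration_test(grp):
            return [grp], []
        if not schedule:
            grp.flags.append("persistent-aberration")
            history.append({"group": grp.group_id, "action": "flagged",
                            "threshold": grp.lod_threshold})
            return [grp], []
        threshold = schedule[0]
        ests = [TwoPointEstimate(a, b, 0, 0, lod, 0, 0)
                for (a, b), lod in pair_lod.items()]
        subgroups, single = build_groups(ests, grp.markers, threshold)
        if len(subgroups) == 1 and not single:
            # no split at this threshold; climb the schedule
            sub = subgroups[0]
            sub.group_id = grp.group_id
            return _refine(sub, schedule[1:])
        history.append({"group": grp.group_id, "action": "split",
                        "threshold": threshold,
                        "n_subgroups": len(subgroups),
                        "n_unlinked": len(single)})
        out_groups: list[RHGroup] = []
        out_unlinked = list(single)
        for i, sub in enumerate(subgroups):
            sub.group_id = f"{grp.group_id}.{i + 1}"
            gs, us = _refine(sub, schedule[1:])
            out_groups.extend(gs)
            out_unlinked.extend(us)
        return out_groups, out_unlinked

    groups, unlinked = _refine(group, tuple(lod_schedule))
    return groups, unlinked, history
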