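"""Multipoint likelihood and marker-order search within RH groups.

Along a candidate order, each clone's retention pattern is modelled as a
two-state Markov chain (fragment retained / lost). The chain starts from
the stationary retention probabilities ``(r, 1-r)``; across the interval
between adjacent markers ``i`` and ``i+1`` a break occurs with probability
``theta_i``, after which the new fragment is retained afresh with
probability ``r``::

    P(retained -> retained) = (1 - theta) + theta * r
    P(retained -> lost)     = theta * (1 - r)
    P(lost     -> retained) = theta * r
    P(lost     -> lost)     = (1 - theta) + theta * (1 - r)

Observed calls are emissions (optionally with a per-call flip error);
ambiguous calls contribute no emission factor, i.e. they are marginalized
over both states. Because the chain is stationary and reversible, the
likelihood of an order equals that of its reversal.

When the error rate is zero and no call is ambiguous the chain is fully
observed and the profile log-likelihood decomposes into per-edge terms,
which turns order search into a symmetric maximum-weight Hamiltonian path
problem; this fast path is used whenever it is exact.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .linkage import (DEFAULT_MAX_DISTANCE_CR, estimate_from_counts,
                      theta_to_cr)
from .matrix import ABSENT, AMBIGUOUS, PRESENT, RHCallMatrix

THETA_HI = 1.0 - 1e-9


@dataclass
class MultipointModel:
    """Fitted parameters of the retention chain along one marker order."""

    markers: list[str]
    thetas: np.ndarray          # length = len(markers) - 1, each in [0, 1)
    retention: float
    error_rate: float = 0.0
    loglik: float = float("nan")

    def __post_init__(self):
        self.thetas = np.asarray(self.thetas, dtype=float)
        if self.thetas.shape != (max(len(self.markers) - 1, 0),):
            raise ValueError("thetas length must be n_markers - 1")


@dataclass
class OrderedGroupMap:
    """An RH group's final order with cumulative centiray coordinates."""

    group_id: str
    markers: list[str]
    thetas: np.ndarray
    coords: np.ndarray          # cumulative cR, starts at 0
    loglik: float
    retention: float
    positions: list[tuple[float, list[str]]] = field(default_factory=list)

    @property
    def length_cr(self) -> float:
        return float(self.coords[-1]) if len(self.coords) else 0.0

    def reversed_(self) -> "OrderedGroupMap":
        L = self.length_cr
        return OrderedGroupMap(
            self.group_id, self.markers[::-1], self.thetas[::-1].copy(),
            L - self.coords[::-1], self.loglik, self.retention,
            [(L - c, list(ms)) for c, ms in reversed(self.positions)])


def _coords_from_thetas(thetas: np.ndarray,
                        max_distance_cr: float = DEFAULT_MAX_DISTANCE_CR
                        ) -> np.ndarray:
    gaps = [theta_to_cr(t, max_distance_cr) for t in thetas]
    return np.concatenate(([0.0], np.cumsum(gaps)))


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def multipoint_loglik(order: list[str], matrix: RHCallMatrix,
                      model: MultipointModel) -> float:
    """Forward-algorithm log-likelihood of the calls under the model."""
    if list(order) != list(model.markers):
        raise ValueError("order does not match the model's marker order")
    sub = matrix.subset_markers(order)
    return _forward_loglik(sub.calls, model.thetas, model.retention,
                           model.error_rate)


def _forward_loglik(calls: np.ndarray, thetas: np.ndarray, r: float,
                    eps: float) -> float:
    """Vectorized forward pass over clones; states [lost, retained]."""
    n_clones, k = calls.shape
    if k != len(thetas) + 1:
        raise ValueError("thetas length must be n_markers - 1")
    # emission probabilities per call value, per state
    e_lost = np.array([1.0 - eps, eps, 1.0])
    e_ret = np.array([eps, 1.0 - eps, 1.0])
    alpha = np.empty((n_clones, 2))
    alpha[:, 0] = (1.0 - r) * e_lost[calls[:, 0]]
    alpha[:, 1] = r * e_ret[calls[:, 0]]
    log_total = np.zeros(n_clones)
    for j in range(1, k):
        t = thetas[j - 1]
        t_ll = (1.0 - t) + t * (1.0 - r)   # lost -> lost
        t_lr = t * r                       # lost -> retained
        t_rl = t * (1.0 - r)
        t_rr = (1.0 - t) + t * r
        new0 = alpha[:, 0] * t_ll + alpha[:, 1] * t_rl
        new1 = alpha[:, 0] * t_lr + alpha[:, 1] * t_rr
        obs = calls[:, j]
        alpha[:, 0] = new0 * e_lost[obs]
        alpha[:, 1] = new1 * e_ret[obs]
        scale = alpha.sum(axis=1)
        bad = scale <= 0.0
        if bad.any():
            return -np.inf
        alpha /= scale[:, None]
        log_total += np.log(scale)
    final = alpha.sum(axis=1)
    if (final <= 0.0).any():
        return -np.inf
    return float(log_total.sum() + np.log(final).sum())


# ---------------------------------------------------------------------------
# observed-chain fast path
# ---------------------------------------------------------------------------

def _edge_term(counts: tuple[int, int, int, int], r: float, theta: float
               ) -> float:
    """Log-probability of the observed transitions across one interval.

    ``counts`` = (n_ll, n_lr, n_rl, n_rr): lost/retained at the left and
    right marker respectively.
    """
    n_ll, n_lr, n_rl, n_rr = counts
    t_ll = (1.0 - theta) + theta * (1.0 - r)
    t_lr = theta * r
    t_rl = theta * (1.0 - r)
    t_rr = (1.0 - theta) + theta * r
    ll = 0.0
    for n, p in ((n_ll, t_ll), (n_lr, t_lr), (n_rl, t_rl), (n_rr, t_rr)):
        if n:
            if p <= 0.0:
                return -np.inf
            ll += n * math.log(p)
    return ll


def _edge_mle(counts: tuple[int, int, int, int], r: float
              ) -> tuple[float, float]:
    """Maximize the edge term over theta; returns (theta_hat, term)."""
    n_ll, n_lr, n_rl, n_rr = counts
    if n_lr + n_rl == 0:
        return 0.0, 0.0
    if n_ll + n_rr == 0:
        return THETA_HI, _edge_term(counts, r, THETA_HI)
    res = minimize_scalar(lambda t: -_edge_term(counts, r, t),
                          bounds=(1e-9, THETA_HI), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x), -float(res.fun)


class _GroupScorer:
    """Precomputed scoring machinery for one group's submatrix.

    In the fully observed case the profile log-likelihood of an order
    m1..mk is ``sum_i W(m_i, m_i+1) + (phi(m1) + phi(mk)) / 2`` where
    ``W`` is a symmetric edge weight and ``phi`` the stationary initial
    term; otherwise scoring falls back to the forward algorithm with
    coordinate-ascent refitting of the adjacent thetas.
    """

    def __init__(self, matrix: RHCallMatrix, markers: list[str],
                 error_rate: float = 0.0, retention: float | None = None):
        self.sub = matrix.subset_markers(markers)
        self.markers = list(markers)
        self.k = len(markers)
        self.error_rate = error_rate
        calls = self.sub.calls
        informative = calls != AMBIGUOUS
        if retention is None:
            # presence fraction over unique call vectors: markers typed at
            # the same position (identical columns) count once, so adding a
            # duplicated marker never shifts the retention estimate
            uniq = np.unique(calls.T, axis=0).T
            n_inf = (uniq != AMBIGUOUS).sum()
            retention = float((uniq == PRESENT).sum() / n_inf) \
                if n_inf else 0.5
        self.r = min(max(retention, 1e-9), 1.0 - 1e-9)
        self.exact_decomposition = (error_rate == 0.0
                                    and bool(informative.all()))
        pres = (calls == PRESENT).astype(np.int32)
        abse = (calls == ABSENT).astype(np.int32)
        # pairwise transition counts (lost/retained at left vs right)
        self.n_rr = pres.T @ pres
        self.n_rl = pres.T @ abse
        self.n_lr = abse.T @ pres
        self.n_ll = abse.T @ abse
        logr, log1r = math.log(self.r), math.log(1.0 - self.r)
        self.phi = pres.sum(axis=0) * logr + abse.sum(axis=0) * log1r
        self._w = None
        self._theta_edge = None

    # -- pairwise quantities ------------------------------------------------

    def counts(self, a: int, b: int) -> tuple[int, int, int, int]:
        return (int(self.n_ll[a, b]), int(self.n_lr[a, b]),
                int(self.n_rl[a, b]), int(self.n_rr[a, b]))

    def _build_pairwise(self) -> None:
        k = self.k
        self._w = np.zeros((k, k))
        self._theta_edge = np.zeros((k, k))
        for a in range(k):
            for b in range(a + 1, k):
                theta, term = _edge_mle(self.counts(a, b), self.r)
                w = term + (self.phi[a] - self.phi[b]) / 2.0
                self._w[a, b] = self._w[b, a] = w
                self._theta_edge[a, b] = self._theta_edge[b, a] = theta

    @property
    def w(self) -> np.ndarray:
        if self._w is None:
            self._build_pairwise()
        return self._w

    @property
    def theta_edge(self) -> np.ndarray:
        if self._theta_edge is None:
            self._build_pairwise()
        return self._theta_edge

    def pairwise_lod(self) -> np.ndarray:
        """Two-point LOD matrix inside the group (for search seeding)."""
        k = self.k
        lod = np.full((k, k), -np.inf)
        for a in range(k):
            for b in range(a + 1, k):
                n_ll, n_lr, n_rl, n_rr = self.counts(a, b)
                try:
                    est = estimate_from_counts("a", "b", n_rr, n_rl, n_lr,
                                               n_ll)
                    lod[a, b] = lod[b, a] = est.lod
                except Exception:
                    pass
        return lod

    # -- scoring ------------------------------------------------------------

    def path_score(self, order: list[int]) -> float:
        """Profile log-likelihood of an order (exact on the fast path)."""
        if self.exact_decomposition:
            w = self.w
            s = (self.phi[order[0]] + self.phi[order[-1]]) / 2.0
            for a, b in zip(order[:-1], order[1:]):
                s += w[a, b]
            return float(s)
        return self.fit(order).loglik

    def plugin_score(self, order: list[int]) -> float:
        """Forward log-likelihood with plug-in pairwise thetas (a cheap
        lower bound on the profile log-likelihood)."""
        if self.exact_decomposition:
            return self.path_score(order)
        te = self.theta_edge
        thetas = np.array([te[a, b] for a, b in zip(order[:-1], order[1:])])
        return _forward_loglik(self.sub.calls[:, order], thetas, self.r,
                               self.error_rate)

    def fit(self, order: list[int], max_sweeps: int = 10,
            tol: float = 1e-6) -> MultipointModel:
        """Fit adjacent thetas for an order by maximum likelihood."""
        names = [self.markers[i] for i in order]
        if self.exact_decomposition:
            thetas = []
            total = (self.phi[order[0]] + self.phi[order[-1]]) / 2.0
            w = self.w
            te = self.theta_edge
            for a, b in zip(order[:-1], order[1:]):
                thetas.append(te[a, b])
                total += w[a, b]
            return MultipointModel(names, np.array(thetas), self.r,
                                   self.error_rate, float(total))
        calls = self.sub.calls[:, order]
        te = self.theta_edge
        thetas = np.array([te[a, b] for a, b in zip(order[:-1], order[1:])])
        ll = _forward_loglik(calls, thetas, self.r, self.error_rate)
        converged = False
        for sweep in range(max_sweeps):
            for i in range(len(thetas)):
                def neg(t, i=i):
                    th = thetas.copy()
                    th[i] = t
                    return -_forward_loglik(calls, th, self.r,
                                            self.error_rate)
                res = minimize_scalar(neg, bounds=(0.0, THETA_HI),
                                      method="bounded",
                                      options={"xatol": 1e-9})
                if -res.fun > ll:
                    thetas[i] = float(res.x)
            new_ll = _forward_loglik(calls, thetas, self.r, self.error_rate)
            gain, ll = new_ll - ll, new_ll
            if sweep >= 1 and gain < tol:
                converged = True
                break
        if not converged and max_sweeps > 2:
            warnings.warn(f"theta fit did not converge in {max_sweeps} "
                          "sweeps; returning last iterate")
        # snap near-zero thetas so identical vectors co-localize exactly
        thetas[thetas < 1e-8] = 0.0
        return MultipointModel(names, thetas, self.r, self.error_rate, ll)


def fit_adjacent_thetas(order: list[str], matrix: RHCallMatrix,
                        error_rate: float = 0.0,
                        retention: float | None = None) -> MultipointModel:
    """Fit the retention chain along a fixed marker order.

    Retention defaults to the group's presence fraction over unique call
    vectors; each adjacent theta is then maximized (independently
    when the chain is fully observed, by coordinate ascent otherwise).
    """
    if len(order) < 2:
        raise ValueError("need at least two markers")
    scorer = _GroupScorer(matrix, list(order), error_rate, retention)
    return scorer.fit(list(range(len(order))))


# ---------------------------------------------------------------------------
# order search
# ---------------------------------------------------------------------------

def _greedy_insertion(scorer: _GroupScorer, lod: np.ndarray,
                      rng: np.random.Generator, randomize: bool
                      ) -> list[int]:
    k = scorer.k
    pairs = [(lod[a, b], a, b) for a in range(k) for b in range(a + 1, k)
             if np.isfinite(lod[a, b])]
    if not pairs:
        return list(range(k))
    pairs.sort(reverse=True)
    if randomize and len(pairs) > 1:
        top = pairs[:min(10, len(pairs))]
        _, a, b = top[rng.integers(len(top))]
    else:
        _, a, b = pairs[0]
    order = [a, b]
    placed = {a, b}
    while len(order) < k:
        # next marker: strongest linkage to anything already placed
        best_m, best_link = -1, -np.inf
        candidates = [m for m in range(k) if m not in placed]
        if randomize:
            rng.shuffle(candidates)
        for m in candidates:
            link = max(lod[m, p] for p in order)
            if link > best_link:
                best_link, best_m = link, m
        m = best_m
        best_pos, best_score = 0, -np.inf
        for pos in range(len(order) + 1):
            cand = order[:pos] + [m] + order[pos:]
            s = scorer.plugin_score(cand)
            if s > best_score:
                best_score, best_pos = s, pos
        order.insert(best_pos, m)
        placed.add(m)
    return order


def _improve(scorer: _GroupScorer, order: list[int],
             max_passes: int = 30) -> tuple[list[int], float]:
    """2-opt segment reversals plus a sliding-window (width 4) ripple."""
    k = len(order)
    exact = scorer.exact_decomposition
    score_fn = scorer.path_score if exact or k <= 10 else scorer.plugin_score
    best = list(order)
    best_score = score_fn(best)
    for _ in range(max_passes):
        improved = False
        # 2-opt
        for i in range(k - 1):
            for j in range(i + 1, k):
                cand = best[:i] + best[i:j + 1][::-1] + best[j + 1:]
                s = score_fn(cand)
                if s > best_score + 1e-9:
                    best, best_score, improved = cand, s, True
        # ripple: all permutations of each 4-wide window
        for start in range(0, max(k - 3, 0) + 1):
            window = best[start:start + 4]
            if len(window) < 3:
                continue
            for perm in itertools.permutations(window):
                if list(perm) == window:
                    continue
                cand = best[:start] + list(perm) + best[start + len(window):]
                s = score_fn(cand)
                if s > best_score + 1e-9:
                    best, best_score, improved = cand, s, True
        if not improved:
            break
    return best, best_score


def search_order(markers: list[str], matrix: RHCallMatrix,
                 group_id: str = "RH", seed: int = 0, n_restarts: int = 10,
                 error_rate: float = 0.0,
                 max_distance_cr: float = DEFAULT_MAX_DISTANCE_CR
                 ) -> OrderedGroupMap:
    """Best marker order for one RH group.

    Construction is greedy best-insertion seeded from the highest-LOD pair,
    improved by 2-opt and a window-4 ripple to a local optimum; the best of
    ``n_restarts`` seeded restarts wins. The final map is reported in
    canonical orientation (lexicographically smaller end marker first) and
    carries cumulative centiray coordinates from the refit thetas.
    """
    markers = list(markers)
    if len(markers) == 1:
        return OrderedGroupMap(group_id, markers, np.empty(0),
                               np.zeros(1), 0.0, float("nan"),
                               [(0.0, markers)])
    scorer = _GroupScorer(matrix, markers, error_rate)
    lod = scorer.pairwise_lod()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    best_order, best_score = None, -np.inf
    for restart in range(max(n_restarts, 1)):
        start = _greedy_insertion(scorer, lod, rng, randomize=restart > 0)
        cand, _ = _improve(scorer, start)
        s = scorer.path_score(cand)
        if s > best_score + 1e-9:
            best_order, best_score = cand, s
    model = scorer.fit(best_order)
    ogm = OrderedGroupMap(group_id, model.markers, model.thetas,
                          _coords_from_thetas(model.thetas, max_distance_cr),
                          model.loglik, scorer.r)
    if ogm.markers[0] > ogm.markers[-1]:
        ogm = ogm.reversed_()
    return colocalize(ogm)


def colocalize(ogm: OrderedGroupMap, theta_tol: float = 0.0
               ) -> OrderedGroupMap:
    """Merge markers whose fitted adjacent theta is (near) zero into one
    map position; with the default tolerance this merges exactly the
    markers with identical informative call vectors."""
    positions: list[tuple[float, list[str]]] = []
    for i, m in enumerate(ogm.markers):
        if i > 0 and ogm.thetas[i - 1] <= theta_tol:
            positions[-1][1].append(m)
        else:
            positions.append((float(ogm.coords[i]), [m]))
    ogm.positions = positions
    return ogm
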