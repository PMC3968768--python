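"""Weighted rich-club analysis of positive-weight functional networks.

The weighted rich-club ratio at strength threshold ``s`` is

    phi_w(s) = W_>s / sum_{l=1}^{E_>s} w_l^rank

where the club is the set of nodes whose strength (sum of incident edge
weights) is strictly larger than ``s``, ``E_>s`` and ``W_>s`` count and sum
the edges internal to the club, and ``w_l^rank`` are the edge weights of
the *whole* network ranked in descending order. phi_w is therefore the
fraction of weight the club members share relative to the maximum they
could share if they were joined by the globally strongest connections.

phi_w alone is not evidence of rich-club organisation: high-strength nodes
share strong links partly by chance. The normalized effect

    rho_w(s) = phi_w(s) / mean(phi_w_random(s))

divides by the average ratio over topology-preserving null networks in
which the edge weights are globally reshuffled (default 1000 draws).
rho_w(s) > 1 indicates a positive weighted rich-club effect.

Pre/post condition curves are compared with a paired sign-flip permutation
test at the animal level: each permutation swaps the condition labels of a
random subset of animals, re-averages the FC matrices, rebuilds networks
and recomputes both rho_w curves. When the number of distinct label
assignments (2^n_animals) does not exceed the permutation budget the null
distribution is enumerated exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .fc_network import (
    EmptyNetworkError,
    FCMatrix,
    WeightedNetwork,
    average_fc,
    extract_subnetwork,
    to_network,
)

__all__ = [
    "StrengthVector",
    "ClubSummary",
    "RichClubCurve",
    "CurveComparison",
    "ProminenceRanking",
    "node_strength",
    "club_members",
    "phi_w",
    "null_reshuffle",
    "threshold_grid",
    "rho_w",
    "compare_curves",
    "prominence_ranking",
]


@dataclass
class StrengthVector:
    node_ids: list[str]
    s: np.ndarray

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        if len(self.s) != len(self.node_ids):
            raise ValueError("one strength per node required")


@dataclass
class ClubSummary:
    """Club membership and internal connectivity at one threshold.

    ``phi`` is ``None`` when the ratio is undefined (empty or edgeless club).
    """

    threshold_s: float
    members: frozenset[str]
    E_gt_s: int
    W_gt_s: float
    phi: float | None


@dataclass
class RichClubCurve:
    thresholds: np.ndarray
    phi: np.ndarray
    phi_random_mean: np.ndarray
    phi_random_samples: np.ndarray  # (n_null, n_thresholds)
    rho: np.ndarray
    n_null: int
    seed: int | None

    @property
    def defined(self) -> np.ndarray:
        """Thresholds where the observed and every null phi are defined."""
        return np.isfinite(self.rho)


@dataclass
class CurveComparison:
    thresholds: np.ndarray
    delta_rho: np.ndarray  # observed rho_pre - rho_post
    p_values: np.ndarray
    n_permutations: int
    alpha: float
    scope: str
    exact: bool

    @property
    def significant(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(np.isfinite(self.p_values), self.p_values < self.alpha, False)


@dataclass
class ProminenceRanking:
    node_ids: list[str]
    strengths: np.ndarray
    k: int

    @property
    def top_k(self) -> list[str]:
        return self.node_ids[: self.k]


# ---------------------------------------------------------------------------
# vectorized phi kernel

def _strength_array(net: WeightedNetwork, weights: np.ndarray | None = None) -> np.ndarray:
    w = net.weights if weights is None else weights
    s = np.bincount(net.edge_i, weights=w, minlength=net.n_nodes)
    s += np.bincount(net.edge_j, weights=w, minlength=net.n_nodes)
    return s


def _phi_batch(
    edge_i: np.ndarray,
    edge_j: np.ndarray,
    W: np.ndarray,
    n_nodes: int,
    thresholds: np.ndarray,
    chunk: int = 128,
) -> np.ndarray:
    """phi_w for B weight assignments on a fixed topology.

    Parameters
    ----------
    W : (B, E) array
        One row of edge weights per network; rows may be reshuffles of a
        common multiset or arbitrary positive weights.

    Returns
    -------
    (B, K) array of phi values, NaN where the club has no internal edge.
    """
    W = np.atleast_2d(np.asarray(W, dtype=float))
    B, E = W.shape
    K = len(thresholds)
    thr = np.asarray(thresholds, dtype=float)

    inc = np.zeros((E, n_nodes))
    inc[np.arange(E), edge_i] = 1.0
    inc[np.arange(E), edge_j] = 1.0

    cum = np.cumsum(np.sort(W, axis=1)[:, ::-1], axis=1)  # top-l weight sums
    out = np.empty((B, K))
    for lo in range(0, B, chunk):
        hi = min(lo + chunk, B)
        Wb = W[lo:hi]
        S = Wb @ inc  # (b, N) node strengths
        member = S[:, :, None] > thr[None, None, :]  # strict club rule
        internal = member[:, edge_i, :] & member[:, edge_j, :]  # (b, E, K)
        E_gt = internal.sum(axis=1)
        W_gt = (internal * Wb[:, :, None]).sum(axis=1)
        denom = np.where(E_gt > 0, cum[lo:hi][np.arange(hi - lo)[:, None], np.maximum(E_gt - 1, 0)], np.nan)
        out[lo:hi] = np.where(E_gt > 0, W_gt / denom, np.nan)
    return out


# ---------------------------------------------------------------------------
# operations

def node_strength(net: WeightedNetwork) -> StrengthVector:
    """Per-node sum of incident edge weights (isolated nodes get 0)."""
    return StrengthVector(node_ids=list(net.node_ids), s=_strength_array(net))


def club_members(sv: StrengthVector, threshold_s: float) -> set[str]:
    """Nodes whose strength is strictly larger than the threshold."""
    return {nid for nid, s in zip(sv.node_ids, sv.s) if s > threshold_s}


def phi_w(net: WeightedNetwork, threshold_s: float) -> ClubSummary:
    """Weighted rich-club ratio at one strength threshold.

    Returns a :class:`ClubSummary`; ``phi`` is ``None`` (undefined, not 0)
    when the club is empty or has no internal edges.
    """
    s = _strength_array(net)
    member = s > threshold_s
    members = frozenset(nid for nid, m in zip(net.node_ids, member) if m)
    internal = member[net.edge_i] & member[net.edge_j]
    e_gt = int(internal.sum())
    w_gt = float(net.weights[internal].sum())
    if e_gt == 0:
        return ClubSummary(float(threshold_s), members, 0, 0.0, None)
    denom = float(net.ranked_weights[:e_gt].sum())
    return ClubSummary(float(threshold_s), members, e_gt, w_gt, w_gt / denom)


def null_reshuffle(net: WeightedNetwork, rng: np.random.Generator) -> WeightedNetwork:
    """Topology-preserving null: permute the edge weights globally.

    Node set and edge set are untouched; the weight multiset is conserved.
    """
    if net.E < 2:
        raise ValueError("reshuffle requires at least 2 edges")
    return WeightedNetwork(
        node_ids=list(net.node_ids),
        node_hemisphere=list(net.node_hemisphere),
        edge_i=net.edge_i.copy(),
        edge_j=net.edge_j.copy(),
        weights=rng.permutation(net.weights),
    )


def _t_break(net: WeightedNetwork, min_club_nodes: int, min_club_edges: int) -> float:
    """Smallest threshold at which the club falls below the size minima.

    The grid of defined thresholds is the half-open interval [0, t_break).
    """
    s = _strength_array(net)

    def ok(t: float) -> bool:
        member = s > t
        if member.sum() < min_club_nodes:
            return False
        internal = member[net.edge_i] & member[net.edge_j]
        return int(internal.sum()) >= min_club_edges

    if not ok(0.0):
        raise EmptyNetworkError(
            f"network is already below the club minima "
            f"({min_club_nodes} nodes, {min_club_edges} edges) at s=0"
        )
    for t in np.unique(s):  # club changes only at strength values
        if not ok(t):
            return float(t)
    return float(s.max())


def threshold_grid(
    net: WeightedNetwork,
    n_points: int = 20,
    min_club_nodes: int = 3,
    min_club_edges: int = 2,
) -> np.ndarray:
    """Evenly spaced strength thresholds up to network disintegration.

    Thresholds run from 0 toward (but never reaching) the smallest strength
    value at which the club drops below ``min_club_nodes`` members or
    ``min_club_edges`` internal edges.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    tb = _t_break(net, min_club_nodes, min_club_edges)
    return np.linspace(0.0, tb, n_points, endpoint=False)


def rho_w(
    net: WeightedNetwork,
    thresholds: np.ndarray | None = None,
    n_null: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    n_points: int = 20,
    min_club_nodes: int = 3,
    min_club_edges: int = 2,
) -> RichClubCurve:
    """Normalized weighted rich-club curve rho_w(s) = phi / mean(phi_null).

    Strengths and club membership are recomputed on every reshuffled null
    network. Thresholds at which the observed phi or any null phi is
    undefined are reported as NaN in ``rho`` rather than imputed.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    if thresholds is None:
        thresholds = threshold_grid(net, n_points, min_club_nodes, min_club_edges)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(thresholds) <= 0) and len(thresholds) > 1:
        raise ValueError("thresholds must be strictly increasing")

    phi_obs = _phi_batch(net.edge_i, net.edge_j, net.weights[None, :], net.n_nodes, thresholds)[0]
    W_null = rng.permuted(np.broadcast_to(net.weights, (n_null, net.E)), axis=1)
    phi_null = _phi_batch(net.edge_i, net.edge_j, W_null, net.n_nodes, thresholds)
    phi_random_mean = phi_null.mean(axis=0)  # NaN when any null is undefined
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = phi_obs / phi_random_mean
    return RichClubCurve(
        thresholds=thresholds,
        phi=phi_obs,
        phi_random_mean=phi_random_mean,
        phi_random_samples=phi_null,
        rho=rho,
        n_null=n_null,
        seed=seed,
    )


def prominence_ranking(net: WeightedNetwork, k: int = 10) -> ProminenceRanking:
    """Nodes ranked by descending strength; ties broken by node label."""
    if k > net.n_nodes:
        raise ValueError(f"k={k} exceeds node count {net.n_nodes}")
    sv = node_strength(net)
    order = sorted(range(net.n_nodes), key=lambda i: (-sv.s[i], net.node_ids[i]))
    return ProminenceRanking(
        node_ids=[net.node_ids[i] for i in order],
        strengths=sv.s[order],
        k=k,
    )


# ---------------------------------------------------------------------------
# pre/post permutation comparison

def _scoped_network(fc: FCMatrix, scope: str) -> WeightedNetwork:
    net = to_network(fc)
    if scope == "whole":
        return net
    return extract_subnetwork(net, scope)


def _rho_for_groups(
    pre: list[FCMatrix],
    post: list[FCMatrix],
    scope: str,
    thresholds: np.ndarray,
    n_null: int,
    rng: np.random.Generator,
    mode: str,
) -> tuple[np.ndarray, np.ndarray]:
    # common random numbers: both condition curves see the same null draws,
    # so delta rho is free of between-curve Monte-Carlo noise (and exactly
    # zero for identical groups)
    pair_seed = int(rng.integers(2**31))
    rhos = []
    for group in (pre, post):
        avg = average_fc(group, mode=mode, same_condition=False)
        net = _scoped_network(avg, scope)
        curve = rho_w(
            net, thresholds=thresholds, n_null=n_null,
            rng=np.random.default_rng(pair_seed),
        )
        rhos.append(curve.rho)
    return rhos[0], rhos[1]


def compare_curves(
    group_pre: list[FCMatrix],
    group_post: list[FCMatrix],
    n_permutations: int = 999,
    seed: int | None = None,
    alpha: float = 0.01,
    scope: str = "whole",
    n_null: int = 200,
    n_points: int = 20,
    min_club_nodes: int = 3,
    min_club_edges: int = 2,
    mode: str = "mean",
) -> CurveComparison:
    """Paired sign-flip permutation test of the pre-vs-post rho_w curves.

    Animals are paired by list position. Each permutation swaps the
    condition labels of a random subset of animals, then repeats the full
    average -> network -> rho_w derivation in the requested ``scope``
    (``whole``, ``ipsi`` or ``contra``). Two-sided p-values per threshold
    compare |delta rho| against the permutation distribution; with Monte
    Carlo sampling the (b+1)/(m+1) correction is applied, while exact
    enumeration of all 2^n assignments (used whenever 2^n <=
    ``n_permutations``) needs no correction. Thresholds undefined in the
    observed curves or in any permutation get NaN p-values.
    """
    if len(group_pre) != len(group_post) or not group_pre:
        raise ValueError("pre and post groups must be nonempty and paired 1:1")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    n_animals = len(group_pre)
    ss = np.random.SeedSequence(seed)
    rng_curves, rng_perm = [np.random.default_rng(c) for c in ss.spawn(2)]

    # common grid: up to the earlier disintegration of the two observed nets
    net_pre = _scoped_network(average_fc(group_pre, mode=mode), scope)
    net_post = _scoped_network(average_fc(group_post, mode=mode), scope)
    tb = min(
        _t_break(net_pre, min_club_nodes, min_club_edges),
        _t_break(net_post, min_club_nodes, min_club_edges),
    )
    thresholds = np.linspace(0.0, tb, n_points, endpoint=False)

    # observed curves = the identity label assignment
    rho_pre, rho_post = _rho_for_groups(
        group_pre, group_post, scope, thresholds, n_null, rng_curves, mode
    )
    delta_obs = rho_pre - rho_post

    exact = 2**n_animals <= n_permutations
    if exact:
        # every non-identity assignment; the identity is the observed curve
        flips = [f for f in product((False, True), repeat=n_animals) if any(f)]
    else:
        flips = list(rng_perm.random((n_permutations, n_animals)) < 0.5)

    abs_obs = np.abs(delta_obs)
    count = np.zeros(len(thresholds))
    all_defined = np.isfinite(delta_obs)
    for flip in flips:
        p_group = [post if f else pre for f, pre, post in zip(flip, group_pre, group_post)]
        q_group = [pre if f else post for f, pre, post in zip(flip, group_pre, group_post)]
        try:
            r1, r2 = _rho_for_groups(
                p_group, q_group, scope, thresholds, n_null, rng_curves, mode
            )
        except EmptyNetworkError:
            all_defined &= False
            continue
        d = r1 - r2
        all_defined &= np.isfinite(d)
        with np.errstate(invalid="ignore"):
            count += np.abs(d) >= abs_obs

    # the observed assignment always matches itself, hence the +1
    denom = 2**n_animals if exact else len(flips) + 1
    p = (count + 1.0) / denom
    p = np.where(all_defined, p, np.nan)
    return CurveComparison(
        thresholds=thresholds,
        delta_rho=delta_obs,
        p_values=p,
        n_permutations=denom - 1,
        alpha=alpha,
        scope=scope,
        exact=exact,
    )
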