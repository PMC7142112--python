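"""Network measures separating modular, transition and centralized topologies.

Scalar measures: clustering coefficient C, global efficiency E, null-normalized
small-worldness S = (C/<C_rand>)(E/<E_rand>), Newman spectral modularity Q
(strength-based modularity matrix), degree-outlier proportion (Poisson
dispersion criterion), and topological assortativity r.

Rich-club structure: topological Φ(k) against degree-preserving
(Maslov–Sneppen) rewired controls, and weighted Φ_w(k) against
topology-preserving weight-shuffled controls.

Heavy tails: maximum-likelihood power-law fit with KS-selected x_min
(Clauset-Shalizi-Newman procedure) and Vuong loglikelihood-ratio comparisons
against lognormal and exponential alternatives.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import optimize, sparse, special, stats
from scipy.sparse.csgraph import shortest_path

from .graph import WeightedGraph

__all__ = [
    "NullEnsembleConfig",
    "MetricsReport",
    "clustering_coefficient",
    "efficiency",
    "small_worldness",
    "modularity_spectral",
    "modularity_value",
    "outlier_proportion",
    "assortativity",
    "rich_club_topological",
    "rich_club_curve",
    "rich_club_normalized",
    "rich_club_weighted",
    "rich_club_weighted_normalized",
    "degree_preserving_null",
    "shuffle_weights",
    "fit_heavy_tail",
    "HeavyTailFit",
    "compute_metrics",
]


@dataclass
class NullEnsembleConfig:
    """Size and seeding of the random-control ensembles."""

    n_nulls: int = 100
    swaps_per_edge: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nulls < 1:
            raise ValueError("need at least one null network")


# ---------------------------------------------------------------------------
# clustering, efficiency, small-worldness


def clustering_coefficient(g: WeightedGraph) -> float:
    """Mean local clustering coefficient.

    Binary graphs use the triangle density around each node.  Weighted graphs
    use the Onnela geometric-mean generalization on weights normalized by the
    network maximum; the two coincide when all weights are equal.  Nodes with
    degree < 2 contribute 0.
    """
    n = g.node_count
    if n < 3:
        raise ValueError("clustering requires at least 3 nodes")
    A = g.adjacency
    d = g.degrees.astype(float)
    if g.is_binary or A.max() == 0:
        M = (A > 0).astype(float)
    else:
        M = np.cbrt(A / A.max())
    tri = np.einsum("ij,jk,ki->i", M, M, M)
    denom = d * (d - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, tri / denom, 0.0)
    return float(c.mean())


def efficiency(g: WeightedGraph) -> float:
    """Global efficiency: mean of 1/d_ij over ordered node pairs.

    Path lengths use edge length 1/weight, so heavier edges carry flow more
    efficiently; disconnected pairs contribute 0.
    """
    n = g.node_count
    if n < 2:
        raise ValueError("efficiency requires at least 2 nodes")
    A = g.adjacency
    i, j = np.nonzero(A)
    lengths = sparse.csr_matrix((1.0 / A[i, j], (i, j)), shape=A.shape)
    D = shortest_path(lengths, directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum() / (n * (n - 1)))


def _er_null(g: WeightedGraph, rng: np.random.Generator) -> WeightedGraph:
    """ER control: same n and m, the original weight multiset randomly placed."""
    n, m = g.node_count, g.edge_count
    iu, ju = np.triu_indices(n, k=1)
    chosen = rng.choice(iu.size, size=m, replace=False)
    w = rng.permutation(g.weights)
    A = np.zeros((n, n))
    A[iu[chosen], ju[chosen]] = w
    A[ju[chosen], iu[chosen]] = w
    return WeightedGraph(A, is_binary=g.is_binary)


def small_worldness(g: WeightedGraph, null_cfg: NullEnsembleConfig | None = None) -> float:
    """Small-world coefficient S = (C / <C_rand>) · (E / <E_rand>).

    The baseline is an ensemble of Erdős–Rényi graphs with the same node and
    edge count carrying the same weight multiset in random positions; a random
    graph therefore scores S ≈ 1.
    """
    null_cfg = null_cfg or NullEnsembleConfig()
    rng = np.random.default_rng(null_cfg.seed)
    c_null, e_null = [], []
    for _ in range(null_cfg.n_nulls):
        null = _er_null(g, rng)
        c_null.append(clustering_coefficient(null))
        e_null.append(efficiency(null))
    c_bar, e_bar = float(np.mean(c_null)), float(np.mean(e_null))
    if c_bar == 0:
        raise ValueError("null ensemble has zero clustering: density too low for S")
    return (clustering_coefficient(g) / c_bar) * (efficiency(g) / e_bar)


# ---------------------------------------------------------------------------
# Newman spectral modularity (strength-based)


def modularity_value(g: WeightedGraph, labels: np.ndarray) -> float:
    """Modularity Q of a given partition with the strength-based null term.

    Q = (1/2W) Σ_ij [A_ij − s_i s_j / 2W] δ(c_i, c_j) with 2W = Σ_ij A_ij.
    """
    A = g.adjacency
    s = g.strengths
    w2 = s.sum()
    labels = np.asarray(labels)
    q = 0.0
    for c in np.unique(labels):
        mask = labels == c
        q += A[np.ix_(mask, mask)].sum() / w2 - (s[mask].sum() / w2) ** 2
    return float(q)


def _refine_split(Bg: np.ndarray, sv: np.ndarray) -> np.ndarray:
    # Kernighan-Lin-style fine tuning: greedily flip each node once per pass,
    # keep the best intermediate state, repeat while it improves s^T B s.
    nv = sv.size
    best = sv.copy()
    best_score = best @ Bg @ best
    improved = True
    while improved:
        improved = False
        s = best.copy()
        score = best_score
        bs = Bg @ s
        moved = np.zeros(nv, dtype=bool)
        pass_best_score = score
        pass_best = s.copy()
        for _ in range(nv):
            gains = -4.0 * s * bs + 4.0 * np.diagonal(Bg)
            gains[moved] = -np.inf
            i = int(np.argmax(gains))
            score += gains[i]
            bs -= 2.0 * s[i] * Bg[:, i]
            s[i] = -s[i]
            moved[i] = True
            if score > pass_best_score:
                pass_best_score = score
                pass_best = s.copy()
        if pass_best_score > best_score + 1e-12:
            best_score = pass_best_score
            best = pass_best
            improved = True
    return best


def modularity_spectral(g: WeightedGraph) -> tuple[float, np.ndarray]:
    """Community detection by Newman's leading-eigenvector bisection.

    Recursively splits communities along the sign of the leading eigenvector
    of the (generalized) modularity matrix, with Kernighan–Lin-style node
    moves after each split, stopping when no split yields a positive
    modularity gain.  Weighted graphs use strengths in place of degrees in
    the modularity matrix.  Returns (Q, integer community labels).
    """
    A = g.adjacency
    if A.max() == 0:
        raise ValueError("modularity undefined for an empty graph")
    n = g.node_count
    s = g.strengths
    w2 = s.sum()
    B = A - np.outer(s, s) / w2
    labels = np.zeros(n, dtype=int)
    next_label = 1
    stack = [np.arange(n)]
    while stack:
        idx = stack.pop()
        if idx.size < 2:
            continue
        Bg = B[np.ix_(idx, idx)].copy()
        Bg[np.diag_indices_from(Bg)] -= Bg.sum(axis=1)
        lam, V = np.linalg.eigh(Bg)
        if lam[-1] <= 1e-10:
            continue  # indivisible
        sv = np.where(V[:, -1] >= 0, 1.0, -1.0)
        sv = _refine_split(Bg, sv)
        gain = sv @ Bg @ sv / (2.0 * w2)
        if gain <= 1e-12 or np.all(sv == sv[0]):
            continue
        left = idx[sv > 0]
        right = idx[sv < 0]
        labels[right] = next_label
        next_label += 1
        stack.append(left)
        stack.append(right)
    # relabel communities densely
    _, labels = np.unique(labels, return_inverse=True)
    return modularity_value(g, labels), labels


# ---------------------------------------------------------------------------
# degree outliers and assortativity


def outlier_proportion(g: WeightedGraph) -> float:
    """Fraction of nodes with degree outside <k> ± 3·sqrt(<k>).

    The dispersion is the Poisson value sqrt(<k>), the baseline appropriate
    for a random graph; a high proportion marks a centralized topology.
    Degrees (not strengths) are used for all weight regimes.
    """
    d = g.degrees
    k_mean = 2.0 * g.edge_count / g.node_count
    spread = 3.0 * math.sqrt(k_mean)
    return float(np.mean((d < k_mean - spread) | (d > k_mean + spread)))


def assortativity(g: WeightedGraph) -> float:
    """Topological assortativity r: Pearson correlation of degrees across edges.

    Each undirected edge contributes both orientations.  Returns NaN when the
    endpoint degrees have no variance (e.g. regular graphs).
    """
    A = g.adjacency
    d = g.degrees.astype(float)
    i, j = np.triu_indices(g.node_count, k=1)
    mask = A[i, j] > 0
    x = np.concatenate([d[i[mask]], d[j[mask]]])
    y = np.concatenate([d[j[mask]], d[i[mask]]])
    if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# rich clubs


def rich_club_topological(g: WeightedGraph, k: int) -> float:
    """Edge density Φ(k) among nodes of degree strictly greater than k.

    Returns NaN when fewer than two nodes exceed the threshold.
    """
    d = g.degrees
    club = np.flatnonzero(d > k)
    if club.size < 2:
        return float("nan")
    sub = g.adjacency[np.ix_(club, club)]
    e_club = np.count_nonzero(np.triu(sub, k=1))
    return 2.0 * e_club / (club.size * (club.size - 1))


def rich_club_weighted(g: WeightedGraph, k: int) -> float:
    """Total weight Φ_w(k) on edges internal to the degree-> k club."""
    d = g.degrees
    club = np.flatnonzero(d > k)
    if club.size < 2:
        return float("nan")
    sub = g.adjacency[np.ix_(club, club)]
    return float(np.triu(sub, k=1).sum())


def rich_club_curve(g: WeightedGraph, weighted: bool = False) -> pd.Series:
    """Φ(k) (or Φ_w(k)) for every threshold k with a club of at least 2 nodes."""
    d = np.sort(g.degrees)
    k_max = d[-2]  # last k with >= 2 club members
    fn = rich_club_weighted if weighted else rich_club_topological
    ks = np.arange(0, k_max)
    return pd.Series([fn(g, int(k)) for k in ks], index=ks, name="phi_w" if weighted else "phi")


def degree_preserving_null(
    g: WeightedGraph, swaps_per_edge: int = 10, rng: np.random.Generator | None = None
) -> WeightedGraph:
    """Maslov–Sneppen randomization: double-edge swaps preserving every degree.

    Weights travel with their edges, so the weight multiset is preserved too.
    """
    rng = rng or np.random.default_rng()
    A = g.adjacency.copy()
    iu, ju = np.nonzero(np.triu(A, k=1))
    edges = np.column_stack([iu, ju])
    m = len(edges)
    if m < 2:
        raise ValueError("not enough edges to randomize")
    target = swaps_per_edge * m
    done = attempts = 0
    max_attempts = 100 * target
    while done < target and attempts < max_attempts:
        attempts += 1
        e1, e2 = rng.integers(0, m, size=2)
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, dd = edges[e2]
        if rng.random() < 0.5:
            c, dd = dd, c
        # propose (a,b),(c,dd) -> (a,dd),(c,b)
        if a == dd or c == b or A[a, dd] > 0 or A[c, b] > 0:
            continue
        w1, w2 = A[a, b], A[c, dd]
        A[a, b] = A[b, a] = 0.0
        A[c, dd] = A[dd, c] = 0.0
        A[a, dd] = A[dd, a] = w1
        A[c, b] = A[b, c] = w2
        edges[e1] = (a, dd)
        edges[e2] = (c, b)
        done += 1
    return WeightedGraph(A, is_binary=g.is_binary)


def rich_club_normalized(
    g: WeightedGraph, null_cfg: NullEnsembleConfig | None = None
) -> pd.DataFrame:
    """Φ_norm(k) = Φ(k) / <Φ_random(k)> over degree-preserving rewired controls.

    Values above 1 mean high-degree nodes interconnect more densely than
    expected from the degree sequence alone.  Returns a per-k table with the
    observed Φ, the null mean and s.e.m., and the normalized curve.
    """
    null_cfg = null_cfg or NullEnsembleConfig()
    rng = np.random.default_rng(null_cfg.seed)
    phi = rich_club_curve(g)
    null_curves = []
    for _ in range(null_cfg.n_nulls):
        null = degree_preserving_null(g, null_cfg.swaps_per_edge, rng)
        null_curves.append(rich_club_curve(null))
    nulls = pd.concat(null_curves, axis=1)
    mean = nulls.mean(axis=1)
    sem = nulls.std(axis=1, ddof=1) / math.sqrt(null_cfg.n_nulls)
    return pd.DataFrame(
        {"phi": phi, "phi_rand_mean": mean, "phi_rand_sem": sem, "phi_norm": phi / mean}
    )


def shuffle_weights(g: WeightedGraph, rng: np.random.Generator) -> WeightedGraph:
    """Same topology, edge weights permuted uniformly at random."""
    A = g.adjacency
    i, j = np.nonzero(np.triu(A, k=1))
    w = rng.permutation(A[i, j])
    out = np.zeros_like(A)
    out[i, j] = w
    out[j, i] = w
    return WeightedGraph(out, is_binary=g.is_binary)


def rich_club_weighted_normalized(
    g: WeightedGraph, null_cfg: NullEnsembleConfig | None = None
) -> pd.DataFrame:
    """Φ_w,norm(k) = Φ_w(k) / <Φ_w(k)> over topology-preserving weight shuffles.

    Above 1 means the club's internal edges carry larger weights than a random
    placement of the same weights on the same topology would give.  Undefined
    for binary graphs.
    """
    if g.is_binary:
        raise ValueError("weighted rich club is undefined for binary graphs")
    null_cfg = null_cfg or NullEnsembleConfig()
    rng = np.random.default_rng(null_cfg.seed)
    phi_w = rich_club_curve(g, weighted=True)
    null_curves = [
        rich_club_curve(shuffle_weights(g, rng), weighted=True)
        for _ in range(null_cfg.n_nulls)
    ]
    nulls = pd.concat(null_curves, axis=1)
    mean = nulls.mean(axis=1)
    sem = nulls.std(axis=1, ddof=1) / math.sqrt(null_cfg.n_nulls)
    return pd.DataFrame(
        {"phi_w": phi_w, "phi_w_rand_mean": mean, "phi_w_rand_sem": sem, "phi_w_norm": phi_w / mean}
    )


# ---------------------------------------------------------------------------
# heavy-tail fitting (Clauset-Shalizi-Newman)


@dataclass
class HeavyTailFit:
    """Power-law tail fit plus likelihood-ratio comparisons.

    ``comparisons`` maps alternative name -> (normalized Vuong statistic,
    two-sided p-value); a positive statistic favors the power law.
    """

    alpha: float
    x_min: float
    ks_distance: float
    n_tail: int
    comparisons: dict[str, tuple[float, float]] = field(default_factory=dict)

    def prefers_power_law_over(self, alternative: str, significance: float = 0.1) -> bool:
        r, p = self.comparisons[alternative]
        return r > 0 and p < significance


def _powerlaw_mle(x: np.ndarray, x_min: float, discrete: bool) -> float:
    if discrete:
        # Clauset's discrete approximation, accurate for x_min >~ 6
        return 1.0 + x.size / np.sum(np.log(x / (x_min - 0.5)))
    return 1.0 + x.size / np.sum(np.log(x / x_min))


def _ks_powerlaw(x: np.ndarray, x_min: float, alpha: float) -> float:
    xs = np.sort(x)
    cdf = 1.0 - (xs / x_min) ** (1.0 - alpha)
    ecdf_hi = np.arange(1, xs.size + 1) / xs.size
    ecdf_lo = np.arange(0, xs.size) / xs.size
    return float(max(np.max(np.abs(ecdf_hi - cdf)), np.max(np.abs(ecdf_lo - cdf))))


def _loglik_powerlaw(x: np.ndarray, x_min: float, alpha: float) -> np.ndarray:
    return np.log(alpha - 1.0) - np.log(x_min) - alpha * np.log(x / x_min)


def _loglik_exponential(x: np.ndarray, x_min: float) -> np.ndarray:
    lam = 1.0 / max(np.mean(x) - x_min, 1e-12)
    return np.log(lam) - lam * (x - x_min)


def _loglik_lognormal(x: np.ndarray, x_min: float) -> np.ndarray:
    logx = np.log(x)

    def nll(theta):
        mu, log_sigma = theta
        sigma = math.exp(log_sigma)
        ll = stats.norm.logpdf(logx, mu, sigma) - logx
        tail = stats.norm.sf((math.log(x_min) - mu) / sigma)
        if tail <= 0:
            return np.inf
        return -(ll - math.log(tail)).sum()

    res = optimize.minimize(
        nll, x0=[logx.mean(), math.log(max(logx.std(), 1e-3))], method="Nelder-Mead"
    )
    mu, sigma = res.x[0], math.exp(res.x[1])
    tail = stats.norm.sf((math.log(x_min) - mu) / sigma)
    return stats.norm.logpdf(logx, mu, sigma) - logx - math.log(tail)


def _vuong(l1: np.ndarray, l2: np.ndarray) -> tuple[float, float]:
    diff = l1 - l2
    n = diff.size
    r = float(diff.sum())
    sd = float(diff.std())
    if sd == 0:
        return r, 1.0
    p = float(special.erfc(abs(r) / (math.sqrt(2.0 * n) * sd)))
    return r / (math.sqrt(n) * sd), p


def fit_heavy_tail(
    values: Iterable[float],
    discrete: bool = False,
    x_min: float | None = None,
) -> HeavyTailFit:
    """Fit P(x) ~ x^{-alpha} to the tail of a sample.

    x_min is chosen to minimize the Kolmogorov–Smirnov distance between the
    tail data and the fitted power law unless given explicitly; alpha is the
    (continuous-approximation) maximum-likelihood exponent on x >= x_min.
    Loglikelihood-ratio tests compare the power law against lognormal and
    exponential alternatives fitted to the same tail.
    """
    x = np.asarray(list(values), dtype=float)
    x = x[x > 0]
    if x.size < 10:
        raise ValueError("need at least 10 positive values")
    if np.unique(x).size == 1:
        raise ValueError("all values identical: no tail to fit")

    if x_min is None:
        candidates = np.unique(x)[:-1]
        best = (np.inf, None, None)
        for xm in candidates:
            tail = x[x >= xm]
            if tail.size < 10:
                break
            denom = np.sum(np.log(tail / xm))
            if denom <= 0:
                continue
            alpha = _powerlaw_mle(tail, xm, discrete)
            ks = _ks_powerlaw(tail, xm, alpha)
            if ks < best[0]:
                best = (ks, xm, alpha)
        ks_best, x_min, alpha = best
        if x_min is None:
            raise ValueError("could not select x_min")
    else:
        tail = x[x >= x_min]
        alpha = _powerlaw_mle(tail, x_min, discrete)
        ks_best = _ks_powerlaw(tail, x_min, alpha)

    tail = x[x >= x_min]
    l_pl = _loglik_powerlaw(tail, x_min, alpha)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        comparisons = {
            "lognormal": _vuong(l_pl, _loglik_lognormal(tail, x_min)),
            "exponential": _vuong(l_pl, _loglik_exponential(tail, x_min)),
        }
    return HeavyTailFit(
        alpha=float(alpha),
        x_min=float(x_min),
        ks_distance=float(ks_best),
        n_tail=int(tail.size),
        comparisons=comparisons,
    )


# ---------------------------------------------------------------------------
# aggregate report


@dataclass
class MetricsReport:
    """All scalar measures of one network, plus optional per-k curves."""

    clustering: float
    efficiency: float
    small_worldness: float
    modularity: float
    communities: np.ndarray
    outlier_proportion: float
    assortativity: float
    rich_club: pd.DataFrame | None = None
    rich_club_weighted: pd.DataFrame | None = None
    heavy_tail: HeavyTailFit | None = None

    def to_dict(self) -> dict:
        out = {
            "clustering": self.clustering,
            "efficiency": self.efficiency,
            "small_worldness": self.small_worldness,
            "modularity": self.modularity,
            "n_communities": int(np.unique(self.communities).size),
            "outlier_proportion": self.outlier_proportion,
            "assortativity": self.assortativity,
        }
        if self.rich_club is not None:
            out["rich_club"] = self.rich_club.reset_index(names="k").to_dict("list")
        if self.rich_club_weighted is not None:
            out["rich_club_weighted"] = (
                self.rich_club_weighted.reset_index(names="k").to_dict("list")
            )
        if self.heavy_tail is not None:
            out["heavy_tail"] = {
                "alpha": self.heavy_tail.alpha,
                "x_min": self.heavy_tail.x_min,
                "ks_distance": self.heavy_tail.ks_distance,
                "n_tail": self.heavy_tail.n_tail,
                "comparisons": {
                    k: list(v) for k, v in self.heavy_tail.comparisons.items()
                },
            }
        return out


def compute_metrics(
    g: WeightedGraph,
    null_cfg: NullEnsembleConfig | None = None,
    rich_club: bool = False,
    heavy_tail: bool = False,
) -> MetricsReport:
    """Evaluate the full metric suite on one network."""
    null_cfg = null_cfg or NullEnsembleConfig()
    q, labels = modularity_spectral(g)
    report = MetricsReport(
        clustering=clustering_coefficient(g),
        efficiency=efficiency(g),
        small_worldness=small_worldness(g, null_cfg),
        modularity=q,
        communities=labels,
        outlier_proportion=outlier_proportion(g),
        assortativity=assortativity(g),
    )
    if rich_club:
        report.rich_club = rich_club_normalized(g, null_cfg)
        if not g.is_binary:
            report.rich_club_weighted = rich_club_weighted_normalized(g, null_cfg)
    if heavy_tail:
        report.heavy_tail = fit_heavy_tail(g.degrees[g.degrees > 0])
    return report
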