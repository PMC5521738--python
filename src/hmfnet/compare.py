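"""Agreement between identified networks and graph-topology metrics.

Robustness of the identification is quantified by comparing interaction
matrices obtained under different hyperparameters or data subsets: after
filtering to coefficients well clear of the bulk (beyond two standard
deviations from the median), agreement is measured by Spearman rank
correlation and by a Fisher exact test on the 2x2 sign-concordance
table, with the odds ratio reported as +inf when no sign discrepancy
exists.  Graph metrics (mean shortest path, transitivity, power-law
degree fit) describe the topology of a thresholded network.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

#: Minimum number of coefficients shared by both filtered networks.
MIN_SHARED = 5


def filter_coefficients(K: np.ndarray) -> np.ndarray:
    """Boolean mask of coefficients with |k| > |2 sd(k) - median(k)|.

    The criterion keeps entries more than roughly two standard deviations
    out of the bulk; with a median near zero (the typical case for sparse
    estimates) it reduces to the plain two-sigma rule.  Statistics are
    taken over all matrix entries, zeros included.
    """
    flat = np.asarray(K, dtype=float)
    if flat.size == 0:
        raise ValueError("empty coefficient matrix")
    thr = abs(2.0 * flat.std(ddof=1) - np.median(flat))
    return np.abs(flat) > thr


@dataclass
class ComparisonStats:
    """Pairwise agreement between two filtered coefficient sets."""

    n_compared: int
    spearman_rho: float
    spearman_p: float
    fisher_p: float
    odds_ratio: float
    agree_pp: int
    agree_nn: int
    disagree_pn: int
    disagree_np: int
    skipped: bool = False
    rho_undefined: bool = False

    @property
    def sign_table(self) -> np.ndarray:
        """Rows: sign in A (+, -); columns: sign in B (+, -)."""
        return np.array(
            [[self.agree_pp, self.disagree_pn], [self.disagree_np, self.agree_nn]]
        )


def compare_networks(K_a: np.ndarray, K_b: np.ndarray) -> ComparisonStats:
    """Spearman and sign-concordance comparison of two interaction matrices.

    Only coefficients passing :func:`filter_coefficients` in *both*
    networks enter; fewer than :data:`MIN_SHARED` shared coefficients
    yields a skipped comparison.  The odds ratio (agree x agree) /
    (disagree x disagree) is +inf when there is no sign discrepancy.
    """
    K_a = np.asarray(K_a, dtype=float)
    K_b = np.asarray(K_b, dtype=float)
    if K_a.shape != K_b.shape:
        raise ValueError("networks must share node set and shape")
    shared = filter_coefficients(K_a) & filter_coefficients(K_b)
    n = int(shared.sum())
    if n < MIN_SHARED:
        return ComparisonStats(n, np.nan, np.nan, np.nan, np.nan, 0, 0, 0, 0, skipped=True)
    a = K_a[shared]
    b = K_b[shared]

    rho_undefined = np.all(a == a[0]) or np.all(b == b[0])
    if rho_undefined:
        rho, rho_p = np.nan, np.nan
    else:
        rho, rho_p = stats.spearmanr(a, b)

    sa = np.sign(a)
    sb = np.sign(b)
    app = int(np.sum((sa > 0) & (sb > 0)))
    ann = int(np.sum((sa < 0) & (sb < 0)))
    apn = int(np.sum((sa > 0) & (sb <= 0)))
    anp = int(np.sum((sa <= 0) & (sb > 0)))
    table = np.array([[app, apn], [anp, ann]])
    fisher_p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    if apn * anp == 0:
        odds = float("inf") if app * ann > 0 else float("nan")
    else:
        odds = (app * ann) / (apn * anp)
    return ComparisonStats(
        n_compared=n,
        spearman_rho=float(rho),
        spearman_p=float(rho_p),
        fisher_p=fisher_p,
        odds_ratio=odds,
        agree_pp=app,
        agree_nn=ann,
        disagree_pn=apn,
        disagree_np=anp,
        rho_undefined=bool(rho_undefined),
    )


def compare_batch(pairs: dict[str, tuple[np.ndarray, np.ndarray]]) -> pd.DataFrame:
    """Run a batch of comparisons with BH adjustment across the batch.

    Returns one row per pair id with Spearman and Fisher p- and q-values,
    the odds ratio, and the number of compared coefficients.
    """
    rows = []
    for pair_id, (K_a, K_b) in pairs.items():
        cs = compare_networks(K_a, K_b)
        rows.append(
            {
                "pair": pair_id,
                "n_compared": cs.n_compared,
                "spearman_rho": cs.spearman_rho,
                "spearman_p": cs.spearman_p,
                "fisher_p": cs.fisher_p,
                "odds_ratio": cs.odds_ratio,
                "skipped": cs.skipped,
            }
        )
    df = pd.DataFrame(rows)
    for col in ("spearman_p", "fisher_p"):
        q = np.full(len(df), np.nan)
        ok = df[col].notna().to_numpy()
        if ok.any():
            q[ok] = multipletests(df.loc[ok, col].to_numpy(), method="fdr_bh")[1]
        df[col.replace("_p", "_q")] = q
    return df


@dataclass
class GraphMetrics:
    """Topology summary of one thresholded network."""

    n_nodes: int
    n_edges: int
    avg_path_length: float
    transitivity: float
    in_degree: np.ndarray
    out_degree: np.ndarray
    power_exponent: float
    ks_p: float
    powerlaw_acceptable: bool
    empty: bool = False


def _mean_shortest_path(G: nx.Graph) -> float:
    """Mean shortest-path length over connected ordered node pairs."""
    total = 0
    count = 0
    for src, dists in nx.all_pairs_shortest_path_length(G):
        for dst, d in dists.items():
            if dst != src:
                total += d
                count += 1
    return total / count if count else float("nan")


def _zeta_cdf(k: np.ndarray, gamma: float, x_min: int) -> np.ndarray:
    """CDF of the discrete power law P(X = x) = x^-gamma / zeta(gamma, x_min).

    Closed form via the Hurwitz zeta function; safe for arbitrarily large
    k (heavy tails), unlike term-by-term summation.
    """
    norm = special.zeta(gamma, x_min)
    return 1.0 - special.zeta(gamma, np.asarray(k, dtype=float) + 1.0) / norm


def _zeta_sample(n: int, gamma: float, x_min: int, rng) -> np.ndarray:
    """Exact inverse-transform sampling by bisection on the closed-form CDF."""
    u = rng.random(n)
    lo = np.full(n, x_min - 1, dtype=float)  # cdf(lo) < u always
    hi = np.full(n, float(x_min), dtype=float)
    while True:
        mask = _zeta_cdf(hi, gamma, x_min) < u
        if not mask.any():
            break
        hi[mask] *= 2.0
    for _ in range(64):  # bisect to the unique integer quantile
        mid = np.floor((lo + hi) / 2.0)
        below = _zeta_cdf(mid, gamma, x_min) < u
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
        if np.all(hi - lo <= 1.0):
            break
    return hi.astype(int)


def fit_power_law(
    degrees: np.ndarray,
    x_min: int = 1,
    n_boot: int = 200,
    seed: int | None = None,
) -> tuple[float, float]:
    """Discrete power-law fit P(k) ~ k^-gamma with a K-S goodness test.

    Maximum likelihood under the zeta (discrete Pareto) distribution with
    lower cutoff ``x_min``; the goodness-of-fit p-value comes from a
    parametric bootstrap of the K-S statistic (each replicate refit by
    the same MLE).  Returns (gamma, ks_p).
    """
    x = np.asarray(degrees, dtype=int)
    x = x[x >= x_min]
    if x.size < 2:
        return float("nan"), float("nan")

    def mle(sample: np.ndarray) -> float:
        log_sum = float(np.sum(np.log(sample)))

        def nll(gamma: float) -> float:
            return sample.size * np.log(special.zeta(gamma, x_min)) + gamma * log_sum

        res = optimize.minimize_scalar(nll, bounds=(1.05, 10.0), method="bounded")
        return float(res.x)

    def ks_stat(sample: np.ndarray, gamma: float) -> float:
        vals, counts = np.unique(sample, return_counts=True)
        ecdf = np.cumsum(counts) / sample.size
        return float(np.max(np.abs(ecdf - _zeta_cdf(vals, gamma, x_min))))

    gamma_hat = mle(x)
    d_obs = ks_stat(x, gamma_hat)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_boot):
        sample = _zeta_sample(x.size, gamma_hat, x_min, rng)
        if ks_stat(sample, mle(sample)) >= d_obs:
            exceed += 1
    return gamma_hat, exceed / n_boot if n_boot else float("nan")


def graph_metrics(
    K: np.ndarray,
    apply_filter: bool = False,
    n_boot: int = 200,
    seed: int | None = None,
    ks_accept: float = 0.8,
) -> GraphMetrics:
    """Topology metrics of the network defined by the nonzero entries of K.

    The adjacency keeps direction for in/out degrees; mean path length
    and transitivity are computed on the undirected skeleton.  Self-loops
    (the diagonal self-decay) are excluded.  The power-law exponent of
    the total-degree sequence is reported together with its K-S p-value;
    the fit is flagged acceptable only when ks_p exceeds ``ks_accept``.
    """
    K = np.asarray(K, dtype=float)
    A = filter_coefficients(K).reshape(K.shape) if apply_filter else K != 0.0
    np.fill_diagonal(A, False)
    n = K.shape[0]
    # K[i, j]: source j -> target i, so the directed edge is (j, i).
    edges = [(j, i) for i, j in zip(*np.nonzero(A))]
    if not edges:
        return GraphMetrics(
            n_nodes=n,
            n_edges=0,
            avg_path_length=float("nan"),
            transitivity=float("nan"),
            in_degree=np.zeros(n, dtype=int),
            out_degree=np.zeros(n, dtype=int),
            power_exponent=float("nan"),
            ks_p=float("nan"),
            powerlaw_acceptable=False,
            empty=True,
        )
    D = nx.DiGraph()
    D.add_nodes_from(range(n))
    D.add_edges_from(edges)
    U = D.to_undirected()
    in_deg = np.array([D.in_degree(v) for v in range(n)], dtype=int)
    out_deg = np.array([D.out_degree(v) for v in range(n)], dtype=int)
    gamma, ks_p = fit_power_law(in_deg + out_deg, n_boot=n_boot, seed=seed)
    return GraphMetrics(
        n_nodes=n,
        n_edges=len(edges),
        avg_path_length=_mean_shortest_path(U),
        transitivity=float(nx.transitivity(U)),
        in_degree=in_deg,
        out_degree=out_deg,
        power_exponent=gamma,
        ks_p=ks_p,
        powerlaw_acceptable=bool(ks_p > ks_accept) if np.isfinite(ks_p) else False,
    )
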