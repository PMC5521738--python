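"""Network identification: block regression, elastic net, model selection.

The HMF spectra of all scaled profiles of one strain assemble into the
block-diagonal regression y = X beta: one block per target node, whose
response entries are the derivative spectra Hbar^1(m omega0) of the
target, and whose design columns are the spectra Hbar(m omega0) of every
candidate source node.  Every block shares the same design matrix, so the
global elastic-net problem separates exactly into per-target fits.

Candidate interaction matrices from a (m-set, alpha, lambda) grid are
ranked by simulating dE/dt = K E from the first-sample state and scoring

    J_sim = sum_nodes sum_t (yhat - ybar)^2 / (Var(yhat) + eps_var),

where the per-node variance of the simulated trajectory penalizes the
do-nothing flat model that an unpenalized residual criterion would favor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, Ridge

from hmfnet.containers import Profile, ProfileSet, node_label
from hmfnet.hmf import ModulatingFunctionSpec, spectra_matrix

#: Variance-penalty regularizer in the simulation objective.
DEFAULT_EPS_VAR = 1e-10

#: Stand-in mixing weight when computing lambda_max for pure ridge (alpha=0),
#: which otherwise has no finite all-zero lambda.
RIDGE_ALPHA_FLOOR = 1e-3

DEFAULT_ALPHA_GRID = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass
class RegressionSystem:
    """Block-diagonal HMF regression for one strain.

    Because all blocks share one design, the system is stored as a single
    ``X_block`` of shape (|m_set|, n_nodes) plus a response matrix ``Y``
    of the same shape whose column t holds the derivative spectra of
    target node t.
    """

    nodes: list[tuple[str, str]]
    m_set: list[int]
    X_block: np.ndarray
    Y: np.ndarray
    spec: ModulatingFunctionSpec

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def full_X(self) -> np.ndarray:
        """Materialized block-diagonal design (tests/small systems only)."""
        n = self.n_nodes
        r, c = self.X_block.shape
        X = np.zeros((n * r, n * c))
        for b in range(n):
            X[b * r : (b + 1) * r, b * c : (b + 1) * c] = self.X_block
        return X

    def full_y(self) -> np.ndarray:
        return self.Y.T.reshape(-1)


@dataclass
class FitResult:
    """One grid point: estimated K with its objectives and provenance."""

    K: np.ndarray
    lam: float
    alpha: float
    M: int
    J_reg: float
    J_sim: float
    n_nonzero: int
    diverged: bool = False
    ridge_lambda_standin: bool = False


@dataclass
class NetworkModel:
    """Identified interaction matrix with frozen node order and provenance.

    ``K[i, j]`` is the influence of node j (source) on node i (target);
    initial conditions are the scaled data at the first sample time.
    """

    node_labels: list[tuple[str, str]]
    K: np.ndarray
    E0: np.ndarray
    strain: str
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        labels = [node_label(o, g) for o, g in self.node_labels]
        return pd.DataFrame(self.K, index=labels, columns=labels).rename_axis(
            index="to", columns="from"
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path, strain: str = "") -> "NetworkModel":
        df = pd.read_csv(path, index_col=0)
        labels = [tuple(s.split("|", 1)) for s in df.index]
        return cls(
            node_labels=labels,
            K=df.to_numpy(dtype=float),
            E0=np.zeros(len(labels)),
            strain=strain,
        )


def build_m_sets(
    n_nodes: int, n_grid: int = 10, M_max: int | None = None
) -> list[list[int]]:
    """Evenly spaced modulating-index sets {0, +/-1, ..., +/-M}.

    The regression needs at least as many spectral equations as unknowns
    per block, so M ranges from M_min = ceil(n_nodes / 2) (giving
    2M + 1 >= n_nodes + 1 equations) up to ``M_max`` (default n_nodes).
    Returns ``n_grid`` m-sets for distinct rounded M values.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be positive")
    M_min = math.ceil(n_nodes / 2)
    if M_max is None:
        M_max = max(n_nodes, M_min)
    if M_max < M_min:
        raise ValueError(f"M_max={M_max} below M_min={M_min}")
    Ms = np.unique(np.round(np.linspace(M_min, M_max, n_grid)).astype(int))
    return [list(range(-M, M + 1)) for M in Ms]


def build_regression_system(
    profiles: ProfileSet,
    strain: str,
    m_set: list[int],
    spec: ModulatingFunctionSpec | None = None,
) -> RegressionSystem:
    """Assemble the HMF regression for one strain's scaled profiles.

    Times are shifted so the strain's earliest sample age is t = 0; the
    record length T defaults to the span of the strain's time grid, also
    for profiles missing an interior time point.
    """
    nodes = profiles.nodes(strain)
    if not nodes:
        raise ValueError(f"no profiles for strain {strain!r}")
    if len(m_set) < len(nodes):
        raise ValueError(
            f"underdetermined block: {len(m_set)} m values for {len(nodes)} nodes"
        )
    plist = profiles.for_strain(strain)
    for p in plist:
        if p.scaled is None:
            raise ValueError("profiles must be scaled before identification")
    t0 = profiles.t0(strain)
    T = max(float(p.times[-1]) - t0 for p in plist)
    if spec is None:
        spec = ModulatingFunctionSpec(T=T)
    shifted = [(p.times - t0, p.scaled) for p in plist]
    H, H1 = spectra_matrix(shifted, m_set, spec)
    return RegressionSystem(nodes=nodes, m_set=list(m_set), X_block=H, Y=H1, spec=spec)


def _sklearn_params(lam: float, alpha: float, n: int) -> tuple[float, float]:
    """Map the objective ||r||^2 + lam(alpha |b|_1 + (1-alpha)|b|_2^2)
    onto scikit-learn's (alpha, l1_ratio) parameterization."""
    sk_alpha = lam * (2.0 - alpha) / (2.0 * n)
    l1_ratio = alpha / (2.0 - alpha)
    return sk_alpha, l1_ratio


def elastic_net_solve(
    system: RegressionSystem,
    lam: float,
    alpha: float,
    standardize: bool = False,
    max_iter: int = 100_000,
    tol: float = 1e-6,
) -> np.ndarray:
    """Solve every block of the system; returns the interaction matrix K.

    Minimizes ||y - X b||^2 + lam * (alpha ||b||_1 + (1 - alpha) ||b||_2^2)
    per block with no intercept.  Predictors are left on the spectral
    scale by default (``standardize=False``) so coefficients are directly
    the interaction rates; standardization is available for glmnet-style
    behavior.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if lam < 0.0:
        raise ValueError("lambda must be non-negative")
    X = system.X_block
    n, p = X.shape
    scale = np.ones(p)
    if standardize:
        scale = X.std(axis=0, ddof=0)
        scale[scale == 0.0] = 1.0
        X = X / scale

    K = np.empty((system.n_nodes, p))
    if lam == 0.0:
        beta, *_ = np.linalg.lstsq(X, system.Y, rcond=None)
        K = beta.T
    elif alpha == 0.0:
        model = Ridge(alpha=lam, fit_intercept=False, solver="svd")
        model.fit(X, system.Y)
        K = np.atleast_2d(model.coef_)
    else:
        sk_alpha, l1_ratio = _sklearn_params(lam, alpha, n)
        for t in range(system.n_nodes):
            model = ElasticNet(
                alpha=sk_alpha,
                l1_ratio=l1_ratio,
                fit_intercept=False,
                max_iter=max_iter,
                tol=tol,
            )
            y = system.Y[:, t]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                model.fit(X, y)
            _check_converged(model, y, system.nodes[t], lam, alpha)
            K[t] = model.coef_
    return K / scale


#: Coordinate descent is accepted when the duality gap is below this
#: fraction of ||y||^2 (a <1% objective suboptimality is immaterial to
#: simulation-based model selection); beyond it the fit is treated as failed.
RELATIVE_GAP_TOL = 1e-2


def _check_converged(model, y, node, lam: float, alpha: float) -> None:
    gap = float(np.ravel(model.dual_gap_)[0])
    limit = RELATIVE_GAP_TOL * float(y @ y)
    if gap > limit:
        raise RuntimeError(
            f"elastic net failed to converge for target {node} "
            f"(lam={lam:g}, alpha={alpha:g}): duality gap {gap:g} > {limit:g}"
        )


def elastic_net_path_solve(
    system: RegressionSystem,
    lams: np.ndarray,
    alpha: float,
    standardize: bool = False,
    max_iter: int = 100_000,
    tol: float = 1e-8,
) -> dict[float, np.ndarray]:
    """Solve all blocks along a descending lambda path with warm starts.

    Coordinate descent converges slowly when restarted cold at the small
    end of the path; re-using the previous solution (glmnet-style) keeps
    every fit converged.  Returns {lambda: K}.
    """
    X = system.X_block
    n, p = X.shape
    scale = np.ones(p)
    if standardize:
        scale = X.std(axis=0, ddof=0)
        scale[scale == 0.0] = 1.0
        X = X / scale
    lams_desc = np.sort(np.asarray(lams, dtype=float))[::-1]
    out = {float(lam): np.empty((system.n_nodes, p)) for lam in lams_desc}
    if alpha == 0.0:
        for lam in lams_desc:
            model = Ridge(alpha=lam, fit_intercept=False, solver="svd")
            model.fit(X, system.Y)
            out[float(lam)] = np.atleast_2d(model.coef_) / scale
        return out
    for t in range(system.n_nodes):
        model = ElasticNet(
            alpha=1.0,
            l1_ratio=alpha / (2.0 - alpha),
            fit_intercept=False,
            max_iter=max_iter,
            tol=tol,
            warm_start=True,
        )
        y = system.Y[:, t]
        for lam in lams_desc:
            model.alpha, model.l1_ratio = _sklearn_params(float(lam), alpha, n)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                model.fit(X, y)
            _check_converged(model, y, system.nodes[t], float(lam), alpha)
            out[float(lam)][t] = model.coef_ / scale
    return out


def regularized_objective(
    system: RegressionSystem, K: np.ndarray, lam: float, alpha: float
) -> float:
    """Value of the elastic-net objective J_reg at a candidate K."""
    resid = system.Y - system.X_block @ K.T
    b = K.ravel()
    return float(
        np.sum(resid**2)
        + lam * (alpha * np.sum(np.abs(b)) + (1.0 - alpha) * np.sum(b**2))
    )


def lambda_max(system: RegressionSystem, alpha: float) -> tuple[float, bool]:
    """Smallest lambda driving every coefficient to zero, from the KKT bound
    |2 X^T y|_inf <= lam * alpha.  For alpha below the ridge floor the
    bound uses the floor value instead (flagged), since pure ridge never
    reaches an exactly zero solution at finite lambda."""
    standin = alpha < RIDGE_ALPHA_FLOOR
    alpha_eff = max(alpha, RIDGE_ALPHA_FLOOR)
    grad = 2.0 * np.abs(system.X_block.T @ system.Y)
    return float(grad.max() / alpha_eff), standin


def lambda_path(
    system: RegressionSystem, alpha: float, n_lambda: int = 10
) -> np.ndarray:
    """Log-spaced lambda grid over four decades below lambda_max."""
    lmax, _ = lambda_max(system, alpha)
    return np.geomspace(lmax * 1e-4, lmax, n_lambda)


def simulate_linear(K: np.ndarray, E0: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Trajectory of dE/dt = K E at the requested times (columns).

    Linear dynamics are propagated exactly with matrix exponentials
    between consecutive sample times; ``times`` are relative to the
    initial state (first entry 0).
    """
    times = np.asarray(times, dtype=float)
    out = np.empty((E0.size, times.size))
    state = np.asarray(E0, dtype=float)
    prev = times[0]
    out[:, 0] = state if prev == 0.0 else expm(K * prev) @ state
    state = out[:, 0]
    for i in range(1, times.size):
        state = expm(K * (times[i] - prev)) @ state
        out[:, i] = state
        prev = times[i]
    return out


def simulate_and_score(
    K: np.ndarray,
    profiles: ProfileSet,
    strain: str,
    eps_var: float = DEFAULT_EPS_VAR,
) -> tuple[float, np.ndarray]:
    """Variance-penalized simulation objective J_sim for a candidate K.

    Integrates from the scaled data at the first sample age, evaluates
    the simulation at each profile's own sample times, and accumulates
    (yhat - ybar)^2 / (Var(yhat) + eps_var) per node, with the sample
    variance taken across the node's simulated time points.  Divergent
    simulations score +inf.
    """
    plist = profiles.for_strain(strain)
    t0 = profiles.t0(strain)
    all_times = np.unique(
        np.concatenate([np.asarray(p.times, dtype=float) - t0 for p in plist])
    )
    E0 = np.array([p.scaled[0] for p in plist])
    with np.errstate(over="ignore", invalid="ignore"):
        traj = simulate_linear(K, E0, all_times)
    if not np.all(np.isfinite(traj)) or np.max(np.abs(traj)) > 1e6:
        return float("inf"), traj
    time_index = {t: i for i, t in enumerate(all_times)}
    total = 0.0
    for row, p in enumerate(plist):
        idx = [time_index[float(t) - t0] for t in p.times]
        yhat = traj[row, idx]
        ybar = p.scaled
        var = float(np.var(yhat, ddof=1)) if yhat.size > 1 else 0.0
        total += float(np.sum((yhat - ybar) ** 2)) / (var + eps_var)
    return total, traj


def grid_search_identify(
    profiles: ProfileSet,
    strain: str,
    alpha_grid=DEFAULT_ALPHA_GRID,
    n_lambda: int = 10,
    n_m_sets: int = 10,
    M_max: int | None = None,
    organs=None,
    genes=None,
    standardize: bool = False,
    eps_var: float = DEFAULT_EPS_VAR,
) -> tuple[NetworkModel, pd.DataFrame, list[FitResult]]:
    """Full hyperparameter sweep; returns the J_sim-optimal model.

    For every (m-set, alpha, lambda) triple the block regression is
    solved and the candidate network simulated and scored.  Returns the
    best :class:`NetworkModel`, a tidy score table over the whole grid,
    and the list of :class:`FitResult` (for robustness comparisons).
    ``organs``/``genes`` restrict identification to a subnetwork.
    """
    if len(alpha_grid) == 0 or n_lambda < 1 or n_m_sets < 1:
        raise ValueError("grids must be non-empty")
    if organs is not None or genes is not None:
        profiles = profiles.subset(organs=organs, genes=genes)
    nodes = profiles.nodes(strain)
    m_sets = build_m_sets(len(nodes), n_grid=n_m_sets, M_max=M_max)

    fits: list[FitResult] = []
    for m_set in m_sets:
        system = build_regression_system(profiles, strain, m_set)
        M = max(m_set)
        for alpha in alpha_grid:
            lams = lambda_path(system, alpha, n_lambda=n_lambda)
            _, standin = lambda_max(system, alpha)
            solutions = elastic_net_path_solve(
                system, lams, float(alpha), standardize
            )
            for lam in lams:
                K = solutions[float(lam)]
                j_sim, _ = simulate_and_score(K, profiles, strain, eps_var=eps_var)
                fits.append(
                    FitResult(
                        K=K,
                        lam=float(lam),
                        alpha=float(alpha),
                        M=M,
                        J_reg=regularized_objective(system, K, float(lam), float(alpha)),
                        J_sim=j_sim,
                        n_nonzero=int(np.count_nonzero(K)),
                        diverged=not np.isfinite(j_sim),
                        ridge_lambda_standin=standin,
                    )
                )
    finite = [f for f in fits if np.isfinite(f.J_sim)]
    if not finite:
        raise RuntimeError("every candidate fit diverged in simulation")
    best = min(finite, key=lambda f: f.J_sim)
    plist = profiles.for_strain(strain)
    model = NetworkModel(
        node_labels=nodes,
        K=best.K,
        E0=np.array([p.scaled[0] for p in plist]),
        strain=strain,
        meta={
            "lambda": best.lam,
            "alpha": best.alpha,
            "M": best.M,
            "J_sim": best.J_sim,
            "J_reg": best.J_reg,
            "n_m_values": 2 * best.M + 1,
            "standardize": standardize,
            "node_order": "organ-major, gene-minor",
        },
    )
    table = pd.DataFrame(
        {
            "M": [f.M for f in fits],
            "alpha": [f.alpha for f in fits],
            "lambda": [f.lam for f in fits],
            "J_reg": [f.J_reg for f in fits],
            "J_sim": [f.J_sim for f in fits],
            "n_nonzero": [f.n_nonzero for f in fits],
            "diverged": [f.diverged for f in fits],
        }
    )
    return model, table, fits
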