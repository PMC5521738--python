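"""Standard synthetic benchmarks exercising the full pipeline.

Each function regenerates its inputs from a seed, runs the relevant
pipeline stages, and returns measured quantities.  The same entry points
back both the acceptance test suite and ``scripts/acceptance.py`` so the
reported numbers always come from one code path.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import spearmanr

from hmfnet import preprocess, synthetic
from hmfnet.compare import filter_coefficients
from hmfnet.diffnet import differential_edges
from hmfnet.dynamics import permutation_p
from hmfnet.hmf import (
    ModulatingFunctionSpec,
    derivative_spectrum_oracle,
    hmf_derivative_spectrum,
    hmf_spectrum,
    modulating_function,
)
from hmfnet.identify import grid_search_identify, simulate_and_score
from hmfnet.patterns import classify_profiles, order_cascade

#: Reduced hyperparameter grid for the recovery benchmark: 3 m-sets x
#: 5 lambdas x 2 alphas (a ridge-leaning and a lasso-leaning mix).
BENCH_ALPHA_GRID = (0.2, 0.6)
BENCH_N_LAMBDA = 5
BENCH_N_M_SETS = 3


def recovery_benchmark(seed: int = 1) -> dict:
    """Ground-truth parameter recovery on the standard 12-node benchmark.

    Conditions: 12 nodes (3 organs x 4 genes), off-diagonal density 0.15,
    5 sample ages (4/6/8/12/16 weeks), 3 replicates, replicate noise
    0.05 Ct.  The full pipeline runs from Ct emission through
    normalization, imputation, scaling and grid-search identification;
    the J_sim-optimal interaction matrix is mapped back to expression
    units with the stored per-profile scaling ranges and compared with
    the ground truth:

    * ``sign_agreement`` over the |support(K_true)| largest-|k| nonzero
      estimated coefficients (an entry at a true zero counts as a
      disagreement);
    * ``spearman_rho`` on the union of the true support and the filtered
      estimated support;
    * ``j_best``/``j_null`` for the variance-penalty contract (the
      all-zero model must be astronomically worse).
    """
    truth = synthetic.generate_network(3, 4, density=0.15, seed=seed)
    profiles = synthetic.simulate_truth(truth)
    ct = synthetic.generate_ct_dataset(
        profiles, replicates=3, noise_sd=0.05, missing_rate=0.0, seed=seed + 1
    )
    expr = preprocess.impute_missing(preprocess.normalize_ct(ct))
    ps = preprocess.scale_profiles(preprocess.mean_profiles(expr))
    model, table, fits = grid_search_identify(
        ps,
        "disease",
        alpha_grid=BENCH_ALPHA_GRID,
        n_lambda=BENCH_N_LAMBDA,
        n_m_sets=BENCH_N_M_SETS,
    )
    K_true = truth.K_true
    ranges = np.array([p.smax - p.smin for p in ps.for_strain("disease")])
    K_back = np.diag(ranges) @ model.K @ np.diag(1.0 / ranges)

    support = K_true != 0.0
    n_top = int(support.sum())
    mags = np.abs(K_back).ravel()
    order = np.argsort(mags)[::-1]
    top = [i for i in order if mags[i] > 0.0][:n_top]
    if top:
        sign_agreement = float(
            np.mean(np.sign(K_back.ravel()[top]) == np.sign(K_true.ravel()[top]))
        )
    else:
        sign_agreement = 0.0

    union = support | filter_coefficients(K_back)
    if np.unique(K_back[union]).size > 1:
        rho = float(spearmanr(K_back[union], K_true[union])[0])
    else:
        rho = float("nan")

    j_null, _ = simulate_and_score(np.zeros_like(model.K), ps, "disease")
    return {
        "sign_agreement": sign_agreement,
        "spearman_rho": rho,
        "n_top": n_top,
        "union_size": int(union.sum()),
        "j_best": float(model.meta["J_sim"]),
        "j_null": float(j_null),
        "n_fits": len(fits),
        "best_alpha": model.meta["alpha"],
        "best_lambda": model.meta["lambda"],
    }


def hmf_equivalence_error(seed: int = 0, n_profiles: int = 20, m_half_range: int = 5) -> dict:
    """Max |frequency-domain - time-domain| spectral error over random profiles.

    20 random piecewise-linear profiles on the study time grid x the
    10 m values {-5..4}; the spectrum is checked against the quadrature
    inner product and the derivative spectrum against the
    integration-by-parts oracle.
    """
    from scipy.integrate import quad

    rng = np.random.default_rng(seed)
    times = np.array([0.0, 2.0, 4.0, 8.0, 12.0])
    spec = ModulatingFunctionSpec(T=12.0)
    m_values = list(range(-m_half_range, m_half_range))
    err_spectrum = 0.0
    err_derivative = 0.0
    for _ in range(n_profiles):
        values = rng.normal(size=times.size)
        for m in m_values:
            ref = 0.0
            for k in range(times.size - 1):
                a = (values[k + 1] - values[k]) / (times[k + 1] - times[k])
                b = values[k] - a * times[k]
                val, _ = quad(
                    lambda x: modulating_function(spec, m, x, degenerate_eps=True)
                    * (a * x + b),
                    times[k],
                    times[k + 1],
                    epsabs=1e-13,
                    limit=200,
                )
                ref += val
            err_spectrum = max(
                err_spectrum, abs(hmf_spectrum(times, values, m, spec) - ref)
            )
            err_derivative = max(
                err_derivative,
                abs(
                    hmf_derivative_spectrum(times, values, m, spec)
                    - derivative_spectrum_oracle(times, values, m, spec)
                ),
            )
    return {"spectrum_max_error": err_spectrum, "derivative_max_error": err_derivative}


def lambda_contract(seed: int = 0) -> dict:
    """Empty network at lambda_max and four-decade log-spaced path."""
    from hmfnet.identify import (
        build_m_sets,
        build_regression_system,
        elastic_net_solve,
        lambda_max,
        lambda_path,
    )

    truth = synthetic.generate_network(2, 3, density=0.2, seed=seed)
    ps = preprocess.scale_profiles(synthetic.simulate_truth(truth))
    system = build_regression_system(ps, "disease", build_m_sets(6, n_grid=1)[0])
    lmax, _ = lambda_max(system, alpha=0.4)
    K = elastic_net_solve(system, lmax, 0.4)
    path = lambda_path(system, alpha=0.4, n_lambda=10)
    ratios = np.diff(np.log10(path))
    return {
        "nnz_at_lambda_max": int(np.count_nonzero(K)),
        "path_decades": float(np.log10(path[-1] / path[0])),
        "log_spacing_spread": float(ratios.max() - ratios.min()),
    }


def cascade_recovery() -> dict:
    """Planted peak cascade (4/6/8/10 weeks) through classification/ordering."""
    planted = (4.0, 6.0, 8.0, 10.0)
    ps = preprocess.scale_profiles(synthetic.make_cascade_profiles(peak_times=planted))
    calls = classify_profiles(ps)
    ordered, _ = order_cascade(calls, by="peak", reference_strain="disease")
    recovered = [c.time for c in ordered]
    genes = [c.gene for c in ordered]
    correct = genes == sorted(genes) and recovered == sorted(recovered)
    first = next(c for c in calls if c.gene == "cascade01")
    return {
        "order_correct": bool(correct and len(ordered) == len(planted)),
        "fraction_in_order": float(
            np.mean([g == e for g, e in zip(genes, sorted(genes))]) if genes else 0.0
        ),
        "monotone_peak_at_t0": bool(
            first.call == "monotone_decay" and first.time == 4.0
        ),
    }


def rewiring_recovery(seed: int = 7) -> dict:
    """Precision/recall of differential-edge calls on planted rewiring."""
    K_d, K_c, truth = synthetic.make_rewired_pair(seed=seed)
    edges = differential_edges(K_d, K_c)
    called = set(zip(edges["target_idx"], edges["source_idx"], edges["class"]))
    wanted = set(zip(truth["target"], truth["source"], truth["cls"]))
    tp = len(called & wanted)
    return {
        "precision": tp / len(called) if called else 0.0,
        "recall": tp / len(wanted),
        "n_called": len(called),
        "n_planted": len(wanted),
    }


def permutation_calibration(
    seed: int = 0,
    n_rep: int = 200,
    n_perm: int = 499,
    effects: tuple = (0.0, 0.6, 1.2),
    n_rep_power: int = 50,
) -> dict:
    """Type-I error at alpha = 0.05 under the null, plus a power curve.

    Both strains share one generative law under the null; the planted
    alternative adds a strain-specific temporal component of increasing
    amplitude.
    """
    rng = np.random.default_rng(seed)
    times = np.repeat([4.0, 6.0, 8.0, 12.0, 16.0], 6)
    labels = np.tile(np.repeat(["a", "b"], 3), 5)

    rejections = 0
    for _ in range(n_rep):
        values = np.cos(times / 5.0) + rng.normal(0.0, 0.5, times.size)
        p, _ = permutation_p(times, values, labels, n_perm=n_perm, rng=rng)
        rejections += p <= 0.05
    type1 = rejections / n_rep

    power = []
    for eff in effects:
        rej = 0
        for _ in range(n_rep_power):
            values = (
                np.cos(times / 5.0)
                + rng.normal(0.0, 0.5, times.size)
                + eff * (labels == "b") * np.sin(times / 2.0)
            )
            p, _ = permutation_p(times, values, labels, n_perm=n_perm, rng=rng)
            rej += p <= 0.05
        power.append(rej / n_rep_power)
    return {
        "type1_rate": type1,
        "n_rep": n_rep,
        "effects": list(effects),
        "power": power,
    }
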