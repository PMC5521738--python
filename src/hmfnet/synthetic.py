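"""Ground-truth networks, simulated dynamics, and Ct-style replicate data.

This module is the no-download test bed for the whole pipeline.  It draws
sparse stable interaction matrices, integrates the resulting linear ODEs,
and converts the trajectories into long-format qPCR cycle-threshold (Ct)
tables with per-gene abundance offsets, per-sample technical offsets,
replicate noise, and configurable missingness — the structure of a
two-strain, multi-organ expression time-course study.

Expression values are on a centered log2-like scale (what a -ddCt value
measures), so initial conditions are drawn symmetrically around zero and
one expression unit corresponds to one PCR cycle (a two-fold change).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from hmfnet.containers import Profile, ProfileSet

#: Default sample ages (weeks) mirroring a five-point developmental design.
DEFAULT_TIMES = (4.0, 6.0, 8.0, 12.0, 16.0)

_ORGAN_NAMES = ("adrenal", "brainstem", "kidney", "liver", "ventricle")


def _organ_names(n: int) -> list[str]:
    names = list(_ORGAN_NAMES[:n])
    names += [f"organ{i + 1}" for i in range(len(names), n)]
    return names


def _gene_names(n: int) -> list[str]:
    return [f"gene{i + 1:02d}" for i in range(n)]


@dataclass
class GroundTruthModel:
    """A known sparse interaction matrix with stable dynamics.

    ``K_true[i, j]`` is the influence (1/week) of node j (source) on node i
    (target); self-decay is folded into the strictly negative diagonal.
    All eigenvalues have non-positive real part so trajectories stay
    bounded over the record.
    """

    node_labels: list[tuple[str, str]]
    K_true: np.ndarray
    E0: np.ndarray
    times: np.ndarray
    seed: int | None = None
    params: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    def spectral_abscissa(self) -> float:
        return float(np.max(np.linalg.eigvals(self.K_true).real))

    def to_json(self, path) -> None:
        """Sidecar recording the ground truth, seed, and parameters."""
        payload = {
            "node_labels": [list(l) for l in self.node_labels],
            "K_true": self.K_true.tolist(),
            "E0": self.E0.tolist(),
            "times": np.asarray(self.times, dtype=float).tolist(),
            "seed": self.seed,
            "params": self.params,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruthModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            node_labels=[tuple(l) for l in payload["node_labels"]],
            K_true=np.asarray(payload["K_true"], dtype=float),
            E0=np.asarray(payload["E0"], dtype=float),
            times=np.asarray(payload["times"], dtype=float),
            seed=payload.get("seed"),
            params=payload.get("params", {}),
        )


def generate_network(
    n_organs: int,
    n_genes: int,
    density: float,
    coeff_scale: float = 0.5,
    seed: int | None = None,
    times=DEFAULT_TIMES,
) -> GroundTruthModel:
    """Draw a sparse stable interaction matrix over an organ x gene grid.

    Parameters
    ----------
    density:
        Requested fraction of nonzero off-diagonal entries.
    coeff_scale:
        Magnitude scale of the interaction coefficients (1/week).  The
        default of 0.5/week makes typical relaxation times a few weeks,
        i.e. visible but unfinished dynamics over a 12-week record.

    Off-diagonal coefficients are drawn symmetrically around zero;
    diagonal entries are strictly negative (self-decay).  If the spectral
    abscissa is positive the off-diagonal block is shrunk until every
    eigenvalue has non-positive real part.
    """
    if n_organs < 1 or n_genes < 1:
        raise ValueError("n_organs and n_genes must be positive")
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    organs = _organ_names(n_organs)
    genes = _gene_names(n_genes)
    labels = [(o, g) for o in organs for g in genes]
    n = len(labels)

    K = np.zeros((n, n))
    diag = -rng.uniform(0.3, 1.0, size=n) * coeff_scale
    np.fill_diagonal(K, diag)

    n_edges = int(round(density * n * (n - 1)))
    off_positions = [(i, j) for i in range(n) for j in range(n) if i != j]
    if n_edges > 0:
        chosen = rng.choice(len(off_positions), size=n_edges, replace=False)
        for idx in chosen:
            i, j = off_positions[idx]
            K[i, j] = rng.uniform(0.2, 1.0) * coeff_scale * rng.choice((-1.0, 1.0))

    # Enforce bounded trajectories: shrink interactions, not self-decay.
    off_mask = ~np.eye(n, dtype=bool)
    for _ in range(200):
        if np.max(np.linalg.eigvals(K).real) <= 0.0:
            break
        K[off_mask] *= 0.9
    else:  # pragma: no cover - extremely unlikely with negative diagonal
        raise RuntimeError("could not stabilize generated network")

    E0 = rng.normal(0.0, 1.0, size=n)
    return GroundTruthModel(
        node_labels=labels,
        K_true=K,
        E0=E0,
        times=np.asarray(times, dtype=float),
        seed=seed,
        params={
            "n_organs": n_organs,
            "n_genes": n_genes,
            "density": density,
            "coeff_scale": coeff_scale,
        },
    )


def simulate_truth(
    model: GroundTruthModel, times=None, strain: str = "disease"
) -> ProfileSet:
    """Integrate dE/dt = K_true E from E0 and sample at the given ages.

    Uses an adaptive stiff/non-stiff solver (LSODA) at tight tolerance;
    the matrix-exponential closed form serves as an independent oracle in
    the test suite.  A ground truth with positive spectral abscissa is
    rejected: unbounded trajectories would make (0, 1) scaling
    meaningless.
    """
    t = np.asarray(model.times if times is None else times, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if model.spectral_abscissa() > 1e-9:
        raise ValueError("ground-truth network is unstable (spectral abscissa > 0)")
    t0 = t[0]
    sol = solve_ivp(
        lambda _t, e: model.K_true @ e,
        (t0, t[-1]),
        model.E0,
        t_eval=t,
        method="LSODA",
        rtol=1e-10,
        atol=1e-12,
    )
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"trajectory integration failed: {sol.message}")
    ps = ProfileSet()
    for idx, (organ, gene) in enumerate(model.node_labels):
        ps.add(
            Profile(
                strain=strain,
                organ=organ,
                gene=gene,
                times=t,
                mean=sol.y[idx],
            )
        )
    return ps


def generate_ct_dataset(
    profiles: ProfileSet,
    replicates: int = 3,
    noise_sd: float = 0.05,
    missing_rate: float = 0.0,
    drop_cells: list[tuple[str, float]] | None = None,
    seed: int | None = None,
    baseline: float = 25.0,
    gene_offset_sd: float = 1.0,
    sample_offset_sd: float = 0.3,
) -> pd.DataFrame:
    """Emit a long-format Ct table emulating a qPCR study.

    Ct = baseline - expression + per-gene offset + per-sample offset
    + Gaussian replicate noise.  Higher expression therefore lowers Ct, so
    -ddCt normalization recovers the input up to median centering.  The
    per-gene offset emulates abundance differences between transcripts;
    the per-sample offset emulates loading/efficiency variation, which is
    exactly what pseudo-reference normalization removes.  Cells listed in
    ``drop_cells`` (organ, age) are absent entirely, emulating a tissue
    collected for another purpose; a further ``missing_rate`` fraction of
    the remaining entries is set missing at random.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    drop = {(organ, float(age)) for organ, age in (drop_cells or [])}

    genes = sorted({p.gene for p in profiles})
    gene_offset = dict(zip(genes, rng.normal(0.0, gene_offset_sd, size=len(genes))))

    # One animal contributes every organ/gene at a single age; the
    # technical offset is drawn per (animal, organ) sample.
    sample_offset: dict[tuple[str, float, int, str], float] = {}

    rows = []
    for p in profiles:
        for i, t in enumerate(p.times):
            t = float(t)
            if (p.organ, t) in drop:
                continue
            for rep in range(1, replicates + 1):
                key = (p.strain, t, rep, p.organ)
                if key not in sample_offset:
                    sample_offset[key] = rng.normal(0.0, sample_offset_sd)
                ct = (
                    baseline
                    - p.mean[i]
                    + gene_offset[p.gene]
                    + sample_offset[key]
                    + rng.normal(0.0, noise_sd)
                )
                rows.append(
                    {
                        "animal": f"{p.strain[:3]}_{t:g}w_r{rep}",
                        "strain": p.strain,
                        "organ": p.organ,
                        "age_weeks": t,
                        "gene": p.gene,
                        "Ct": ct,
                    }
                )
    df = pd.DataFrame(rows)
    if missing_rate > 0.0 and len(df):
        df.loc[rng.random(len(df)) < missing_rate, "Ct"] = np.nan
    # Deterministic row order regardless of dict iteration details.
    df = df.sort_values(["strain", "organ", "age_weeks", "animal", "gene"]).reset_index(
        drop=True
    )
    return df


def make_strain_pair(
    n_organs: int,
    n_genes: int,
    density: float = 0.15,
    rewire_fraction: float = 0.3,
    coeff_scale: float = 0.5,
    seed: int | None = None,
    times=DEFAULT_TIMES,
) -> dict[str, GroundTruthModel]:
    """Matched control/disease ground truths differing by rewired edges.

    The disease network starts from the control network; a fraction of its
    interactions is removed, an equal number of new interactions is added
    elsewhere, and a smaller number has its sign flipped — the three
    differential-edge classes the analysis is meant to recover.
    """
    rng = np.random.default_rng(seed)
    control = generate_network(
        n_organs, n_genes, density, coeff_scale, seed=int(rng.integers(2**31)), times=times
    )
    K = control.K_true.copy()
    n = K.shape[0]
    off = [(i, j) for i in range(n) for j in range(n) if i != j]
    present = [p for p in off if K[p] != 0.0]
    absent = [p for p in off if K[p] == 0.0]
    n_rewire = int(round(rewire_fraction * len(present)))
    n_switch = max(1, n_rewire // 4) if n_rewire else 0

    removed = [present[i] for i in rng.choice(len(present), size=min(n_rewire, len(present)), replace=False)]
    for p in removed:
        K[p] = 0.0
    if absent and n_rewire:
        added = [absent[i] for i in rng.choice(len(absent), size=min(n_rewire, len(absent)), replace=False)]
        for p in added:
            K[p] = rng.uniform(0.2, 1.0) * coeff_scale * rng.choice((-1.0, 1.0))
    still = [p for p in off if K[p] != 0.0 and p not in removed]
    if still and n_switch:
        switched = [still[i] for i in rng.choice(len(still), size=min(n_switch, len(still)), replace=False)]
        for p in switched:
            K[p] = -K[p]

    off_mask = ~np.eye(n, dtype=bool)
    for _ in range(200):
        if np.max(np.linalg.eigvals(K).real) <= 0.0:
            break
        K[off_mask] *= 0.9
    disease = GroundTruthModel(
        node_labels=list(control.node_labels),
        K_true=K,
        E0=control.E0.copy(),
        times=np.asarray(times, dtype=float),
        seed=seed,
        params=dict(control.params, rewire_fraction=rewire_fraction),
    )
    return {"control": control, "disease": disease}


def make_rewired_pair(
    n_nodes: int = 20,
    n_added: int = 10,
    n_removed: int = 10,
    n_switched: int = 5,
    n_shared: int = 20,
    edge_scale: float = 1.0,
    background_sd: float = 0.01,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Matrix pair with planted added/removed/switched edges for benchmarking.

    Returns (K_disease, K_control, truth) where ``truth`` lists the planted
    changes with columns (target, source, cls).  Shared edges are
    identical in both matrices; a small dense Gaussian background sits far
    below every detection threshold.
    """
    rng = np.random.default_rng(seed)
    n = n_nodes
    need = n_added + n_removed + n_switched + n_shared
    off = [(i, j) for i in range(n) for j in range(n) if i != j]
    if need > len(off):
        raise ValueError("too many planted edges for the matrix size")
    chosen = rng.choice(len(off), size=need, replace=False)
    positions = [off[i] for i in chosen]

    def draw():
        return rng.uniform(0.7, 1.0) * edge_scale * rng.choice((-1.0, 1.0))

    K_dis = rng.normal(0.0, background_sd, size=(n, n))
    K_con = rng.normal(0.0, background_sd, size=(n, n))
    records = []
    k = 0
    for _ in range(n_shared):
        v = draw()
        K_dis[positions[k]] += v
        K_con[positions[k]] += v
        k += 1
    for _ in range(n_added):
        K_dis[positions[k]] += draw()
        records.append((*positions[k], "added"))
        k += 1
    for _ in range(n_removed):
        K_con[positions[k]] += draw()
        records.append((*positions[k], "removed"))
        k += 1
    for _ in range(n_switched):
        v = draw()
        K_dis[positions[k]] += v
        K_con[positions[k]] += -v
        records.append((*positions[k], "switched"))
        k += 1
    truth = pd.DataFrame(records, columns=["target", "source", "cls"])
    return K_dis, K_con, truth


def make_cascade_profiles(
    peak_times=(4.0, 6.0, 8.0, 10.0),
    times=(4.0, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0),
    width: float = 1.5,
    strain: str = "disease",
    organ: str = "brainstem",
) -> ProfileSet:
    """Profiles with planted Gaussian activity bumps at known peak times.

    A bump centered on the first sample age yields a monotonically
    decaying profile, exercising the rule that such profiles peak at t0.
    """
    t = np.asarray(times, dtype=float)
    ps = ProfileSet()
    for idx, tp in enumerate(peak_times):
        values = np.exp(-((t - tp) ** 2) / (2.0 * width**2))
        ps.add(
            Profile(
                strain=strain,
                organ=organ,
                gene=f"cascade{idx + 1:02d}",
                times=t,
                mean=values,
            )
        )
    return ps
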