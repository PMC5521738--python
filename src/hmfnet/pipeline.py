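"""End-to-end pipeline orchestration with reproducible seeding.

A single :class:`PipelineConfig` drives every stage: synthetic data
generation (or CSV ingest), Ct normalization, imputation and scaling,
differential-dynamics testing, per-strain network identification,
robustness comparison, dynamic-pattern cascades, differential-network
calls, and motif enumeration.  One master seed fans out to per-stage
child seeds so any stage can be re-run in isolation yet reproducibly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from hmfnet import compare, diffnet, dynamics, motifs, patterns, preprocess, synthetic
from hmfnet.identify import grid_search_identify

logger = logging.getLogger(__name__)

_STAGES = (
    "synthetic",
    "normalize",
    "dynamics",
    "identify",
    "compare",
    "patterns",
    "diffnet",
    "motifs",
)


@dataclass
class SyntheticConfig:
    """Study-design block of the synthetic generator."""

    n_organs: int = 2
    n_genes: int = 6
    density: float = 0.15
    coeff_scale: float = 0.5
    rewire_fraction: float = 0.3
    replicates: int = 3
    noise_sd: float = 0.05
    missing_rate: float = 0.02
    drop_cells: list = field(default_factory=list)
    times: list = field(default_factory=lambda: list(synthetic.DEFAULT_TIMES))


@dataclass
class PipelineConfig:
    """All knobs of the pipeline, every default a documented constant."""

    seed: int = 0
    ct_csv: str | None = None  # ingest a real Ct table instead of simulating
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    stages: list = field(default_factory=lambda: list(_STAGES))
    # dynamics test
    spline_df: int = 3
    n_perm: int = 499
    q_threshold: float = 0.1
    # identification
    alpha_grid: list = field(default_factory=lambda: [0.2, 1.0])
    n_lambda: int = 5
    n_m_sets: int = 3
    standardize: bool = False
    # pattern analysis
    e_th: float = 0.5
    e_th0: float = 0.1
    # differential network
    cutoff_added: float = 0.15
    cutoff_removed: float = 0.15
    cutoff_switched: float = 0.2
    # robustness comparison
    n_refits_compare: int = 5
    ks_accept: float = 0.8
    strains: list = field(default_factory=lambda: ["disease", "control"])

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn = SyntheticConfig(**raw.pop("synthetic", {}))
        return cls(synthetic=syn, **raw)


def _child_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds below 2**31 derived from one master."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(_STAGES))
    return {
        stage: int(child.generate_state(1)[0] % (2**31))
        for stage, child in zip(_STAGES, children)
    }


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Execute the configured stages, writing every table plus a manifest.

    Stage outputs are plain CSV (networks as labeled matrices, edge lists
    as tidy tables, exports as SIF); the manifest records the config,
    child seeds, per-stage row counts and timings.  A stage failure
    raises with the stage name; disabled stages are skipped with a
    notice, and downstream stages that need their outputs are skipped
    too.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "child_seeds": seeds,
        "stages": {},
    }
    state: dict = {}

    def record(stage: str, t_start: float, **counts) -> None:
        manifest["stages"][stage] = {
            "elapsed_s": round(time.time() - t_start, 3),
            **counts,
        }

    def enabled(stage: str) -> bool:
        if stage in config.stages:
            return True
        logger.info("stage %s disabled; skipping", stage)
        return False

    try:
        # --- data acquisition -------------------------------------------
        if config.ct_csv is not None:
            t = time.time()
            state["ct"] = pd.read_csv(config.ct_csv)
            record("synthetic", t, n_rows=len(state["ct"]), source=config.ct_csv)
        elif enabled("synthetic"):
            t = time.time()
            sc = config.synthetic
            truths = synthetic.make_strain_pair(
                sc.n_organs,
                sc.n_genes,
                density=sc.density,
                rewire_fraction=sc.rewire_fraction,
                coeff_scale=sc.coeff_scale,
                seed=seeds["synthetic"],
                times=tuple(sc.times),
            )
            tables = []
            for i, (strain, model) in enumerate(sorted(truths.items())):
                model.to_json(out / f"truth_{strain}.json")
                profs = synthetic.simulate_truth(model, strain=strain)
                tables.append(
                    synthetic.generate_ct_dataset(
                        profs,
                        replicates=sc.replicates,
                        noise_sd=sc.noise_sd,
                        missing_rate=sc.missing_rate,
                        drop_cells=[tuple(c) for c in sc.drop_cells],
                        seed=seeds["synthetic"] + i + 1,
                    )
                )
            state["ct"] = pd.concat(tables, ignore_index=True)
            state["ct"].to_csv(out / "ct_raw.csv", index=False)
            record("synthetic", t, n_rows=len(state["ct"]))

        # --- normalization ----------------------------------------------
        if enabled("normalize") and "ct" in state:
            t = time.time()
            expr = preprocess.normalize_ct(state["ct"])
            expr = preprocess.impute_missing(expr)
            expr.to_csv(out / "expression.csv", index=False)
            stability = preprocess.rank_pseudo_reference(state["ct"])
            stability.to_csv(out / "pseudo_reference_ranks.csv", index=False)
            profiles = preprocess.scale_profiles(preprocess.mean_profiles(expr))
            profiles.to_frame().to_csv(out / "profiles.csv", index=False)
            state["expr"] = expr
            state["profiles"] = profiles
            record("normalize", t, n_rows=len(expr), n_profiles=len(profiles))

        # --- differential dynamics --------------------------------------
        if enabled("dynamics") and "expr" in state:
            t = time.time()
            res = dynamics.run_dynamics_tests(
                state["expr"],
                df=config.spline_df,
                n_perm=config.n_perm,
                seed=seeds["dynamics"],
                q_threshold=config.q_threshold,
            )
            res.to_csv(out / "dynamics_tests.csv", index=False)
            record("dynamics", t, n_tests=len(res))

        # --- identification ---------------------------------------------
        if enabled("identify") and "profiles" in state:
            t = time.time()
            state["models"] = {}
            state["fits"] = {}
            for strain in config.strains:
                model, table, fits = grid_search_identify(
                    state["profiles"],
                    strain,
                    alpha_grid=tuple(config.alpha_grid),
                    n_lambda=config.n_lambda,
                    n_m_sets=config.n_m_sets,
                    standardize=config.standardize,
                )
                model.to_csv(out / f"K_{strain}.csv")
                table.to_csv(out / f"fit_scores_{strain}.csv", index=False)
                state["models"][strain] = model
                state["fits"][strain] = fits
            record(
                "identify",
                t,
                n_fits=sum(len(f) for f in state["fits"].values()),
            )

        # --- robustness comparison --------------------------------------
        if enabled("compare") and "models" in state:
            t = time.time()
            pairs = {}
            for strain, model in state["models"].items():
                finite = [f for f in state["fits"][strain] if np.isfinite(f.J_sim)]
                near = sorted(finite, key=lambda f: f.J_sim)[
                    1 : config.n_refits_compare + 1
                ]
                for rank, fit in enumerate(near, start=1):
                    pairs[f"{strain}_best_vs_rank{rank}"] = (model.K, fit.K)
            if pairs:
                report = compare.compare_batch(pairs)
                report.to_csv(out / "robustness_comparison.csv", index=False)
            metrics = {}
            for strain, model in state["models"].items():
                gm = compare.graph_metrics(
                    model.K, seed=seeds["compare"], ks_accept=config.ks_accept
                )
                metrics[strain] = {
                    "n_edges": gm.n_edges,
                    "avg_path_length": gm.avg_path_length,
                    "transitivity": gm.transitivity,
                    "power_exponent": gm.power_exponent,
                    "ks_p": gm.ks_p,
                    "powerlaw_acceptable": gm.powerlaw_acceptable,
                }
            with open(out / "graph_metrics.json", "w") as fh:
                json.dump(metrics, fh, indent=1, default=float)
            record("compare", t, n_pairs=len(pairs))

        # --- dynamic patterns -------------------------------------------
        if enabled("patterns") and "profiles" in state:
            t = time.time()
            calls = patterns.classify_profiles(
                state["profiles"], e_th=config.e_th, e_th0=config.e_th0
            )
            patterns.calls_frame(calls).to_csv(out / "extremum_calls.csv", index=False)
            ref = config.strains[0]
            for by in ("peak", "valley"):
                _, timing = patterns.order_cascade(calls, by=by, reference_strain=ref)
                timing.to_csv(out / f"cascade_{by}.csv", index=False)
            record("patterns", t, n_calls=len(calls))

        # --- differential network ---------------------------------------
        if enabled("diffnet") and "models" in state and len(state["models"]) >= 2:
            t = time.time()
            dis = state["models"][config.strains[0]]
            con = state["models"][config.strains[1]]
            edges = diffnet.differential_edges(
                dis.K,
                con.K,
                node_labels=dis.node_labels,
                cutoffs={
                    "added": config.cutoff_added,
                    "removed": config.cutoff_removed,
                    "switched": config.cutoff_switched,
                },
            )
            edges.to_csv(out / "differential_edges.csv", index=False)
            diffnet.write_sif(edges, out / "differential_edges.sif")
            record("diffnet", t, n_edges=len(edges))

        # --- motifs ------------------------------------------------------
        if enabled("motifs") and "models" in state:
            t = time.time()
            n_motifs = 0
            for strain, model in state["models"].items():
                S = diffnet.threshold_and_scale(model.K)
                found = motifs.enumerate_ffl(S, node_labels=model.node_labels)
                motifs.motifs_frame(found).to_csv(
                    out / f"motifs_{strain}.csv", index=False
                )
                n_motifs += len(found)
            record("motifs", t, n_motifs=n_motifs)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    config.to_yaml(out / "config.yaml")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=float)
    return out
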